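import pytest
from hypothesis import settings

from mthfrvar.variant_table import deduplicate, load_packaged_table

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def packaged_records():
    """All 72 printed rows, duplicates included."""
    return load_packaged_table()


@pytest.fixture(scope="session")
def unique_records(packaged_records):
    """Deduplicated records used by all downstream statistics."""
    unique, _ = deduplicate(packaged_records)
    return unique
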