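"""Data model and TSV parser for the per-variant annotation table.

The packaged table transcribes the published list of 72 missense variations
associated with MTHFR deficiency (UniProt P42898 numbering).  Each row carries
the variant, its domain, a free-text functional effect, three per-method
stability predictions (kcal/mol, order INPS3D / FoldX / PoPMuSiC2), an
interaction-site flag (I/N) and the relative solvent accessibility in percent.
The table is kept bit-faithful to the printed source: the duplicated M338T row
is preserved by the parser and removed only by the explicit
:func:`deduplicate` step.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Last position of the catalytic domain; the regulatory domain (including the
#: inter-domain linker) starts at the next position.
CATALYTIC_LAST = 335
REGULATORY_FIRST = 336

#: Reference-sequence span of the regulatory domain profile model.
REGULATORY_MODEL_SPAN = (336, 566)

HEADER = (
    "variant",
    "domain",
    "effect",
    "ddg_inps3d",
    "ddg_foldx",
    "ddg_popmusic2",
    "ispred4",
    "rsa_percent",
)

_VARIANT_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")

PACKAGED_TABLE = "mthfr_variants.tsv"


class VariantTableError(ValueError):
    """Raised for malformed variant-table content; carries the 1-based line."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


def domain_for_position(position: int) -> str:
    """Domain implied by the position rule (<=335 catalytic, >=336 regulatory)."""
    return "catalytic" if position <= CATALYTIC_LAST else "regulatory"


@dataclass(frozen=True)
class VariantRecord:
    """One missense variant with its printed annotations.

    ``ddg`` holds the three stability predictions in kcal/mol, negative values
    meaning the mutant is less stable (ddG = dG_wt - dG_mut).
    """

    wt_residue: str
    position: int
    mut_residue: str
    domain: str
    effect: str
    ddg: tuple[float, float, float]
    interaction: bool
    rsa_percent: int

    def __post_init__(self):
        if self.wt_residue not in AMINO_ACIDS:
            raise ValueError(f"invalid wild-type residue {self.wt_residue!r}")
        if self.mut_residue not in AMINO_ACIDS:
            raise ValueError(f"invalid mutant residue {self.mut_residue!r}")
        if self.wt_residue == self.mut_residue:
            raise ValueError(f"synonymous substitution {self.variant}")
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.domain not in ("catalytic", "regulatory"):
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.domain != domain_for_position(self.position):
            raise ValueError(
                f"{self.variant}: domain {self.domain!r} inconsistent with "
                f"position rule (<= {CATALYTIC_LAST} catalytic)"
            )
        if len(self.ddg) != 3 or not all(
            isinstance(v, float) and v == v for v in self.ddg
        ):
            raise ValueError(f"{self.variant}: ddg must be three finite floats")
        if not 0 <= self.rsa_percent <= 100:
            raise ValueError(f"{self.variant}: RSA% out of [0, 100]")

    @property
    def variant(self) -> str:
        return f"{self.wt_residue}{self.position}{self.mut_residue}"

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.wt_residue, self.position, self.mut_residue)


def _parse_variant_token(token: str, line: int) -> tuple[str, int, str]:
    m = _VARIANT_RE.match(token.strip())
    if not m:
        raise VariantTableError(f"malformed variant token {token!r}", line)
    wt, pos, mut = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    if wt not in AMINO_ACIDS or mut not in AMINO_ACIDS:
        raise VariantTableError(f"non-amino-acid letter in {token!r}", line)
    return wt, pos, mut


def _normalize_minus(text: str) -> str:
    # U+2212 (minus), U+2013 (en dash) occasionally survive table extraction
    return text.replace("−", "-").replace("–", "-")


def parse_variant_table(source: str | Path | io.TextIOBase) -> list[VariantRecord]:
    """Parse a variant TSV into an ordered list of :class:`VariantRecord`.

    Duplicated rows are preserved in file order.  A header-only file yields an
    empty list.  Malformed rows raise :class:`VariantTableError` with the
    offending 1-based line number.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as handle:
            return parse_variant_table(handle)
    reader = csv.reader(source, delimiter="\t")
    try:
        header = next(reader)
    except StopIteration:
        raise VariantTableError("empty file: missing header row", 1)
    header = tuple(h.strip() for h in header)
    if header != HEADER:
        raise VariantTableError(
            f"unexpected header {header!r}; expected {HEADER!r}", 1
        )
    records: list[VariantRecord] = []
    for line_no, row in enumerate(reader, start=2):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) != len(HEADER):
            raise VariantTableError(
                f"expected {len(HEADER)} columns, found {len(row)}", line_no
            )
        variant, domain, effect, d1, d2, d3, flag, rsa = (
            _normalize_minus(cell).strip() for cell in row
        )
        wt, pos, mut = _parse_variant_token(variant, line_no)
        try:
            ddg = (float(d1), float(d2), float(d3))
        except ValueError:
            raise VariantTableError(
                f"non-numeric ddG value in {(d1, d2, d3)!r}", line_no
            )
        if flag not in ("I", "N"):
            raise VariantTableError(
                f"interaction flag must be I or N, got {flag!r}", line_no
            )
        try:
            rsa_value = int(rsa)
        except ValueError:
            raise VariantTableError(f"non-integer RSA {rsa!r}", line_no)
        try:
            record = VariantRecord(
                wt_residue=wt,
                position=pos,
                mut_residue=mut,
                domain=domain,
                effect=effect,
                ddg=ddg,
                interaction=(flag == "I"),
                rsa_percent=rsa_value,
            )
        except ValueError as exc:
            raise VariantTableError(str(exc), line_no)
        records.append(record)
    return records


def _format_float(value: float) -> str:
    return format(value, "g")


def serialize_variant_table(records: Iterable[VariantRecord]) -> str:
    """Render records back to the TSV dialect consumed by the parser."""
    lines = ["\t".join(HEADER)]
    for rec in records:
        lines.append(
            "\t".join(
                (
                    rec.variant,
                    rec.domain,
                    rec.effect,
                    _format_float(rec.ddg[0]),
                    _format_float(rec.ddg[1]),
                    _format_float(rec.ddg[2]),
                    "I" if rec.interaction else "N",
                    str(rec.rsa_percent),
                )
            )
        )
    return "\n".join(lines) + "\n"


def write_variant_table(records: Iterable[VariantRecord], path: str | Path) -> None:
    Path(path).write_text(serialize_variant_table(records), encoding="utf-8")


def deduplicate(
    records: Sequence[VariantRecord],
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Drop repeated (wt, position, mut) rows, keeping the first occurrence.

    Returns ``(unique_records, removed_rows)``; order is stable.  Distinct
    substitutions at the same position (e.g. R46Q and R46W) are both retained.
    """
    seen: set[tuple[str, int, str]] = set()
    unique: list[VariantRecord] = []
    removed: list[VariantRecord] = []
    for rec in records:
        if rec.key in seen:
            removed.append(rec)
        else:
            seen.add(rec.key)
            unique.append(rec)
    return unique, removed


def packaged_table_path() -> Path:
    """Filesystem path of the packaged variant table."""
    return Path(str(resources.files("mthfrvar") / "data" / PACKAGED_TABLE))


def load_packaged_table() -> list[VariantRecord]:
    """Parse the packaged 72-row variant table."""
    return parse_variant_table(packaged_table_path())
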