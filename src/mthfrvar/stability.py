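"""Consensus destabilization calls from per-method ddG predictions.

Sign convention: ddG = dG_wt - dG_mut, so negative values mean the mutant is
less stable than the wild type.  A variant is called destabilizing when at
least ``min_votes`` of the three predictions are at or below the threshold
(default -1 kcal/mol, inclusive).  Predictions computed on a structure that
carries the mutant allele are mapped back with the antisymmetric principle
(:func:`reverse_variant`), i.e. ddG(A->B) = -ddG(B->A).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .variant_table import VariantRecord

DEFAULT_DDG_THRESHOLD = -1.0
DEFAULT_MIN_VOTES = 2

DdgTriplet = tuple[float, float, float]


@dataclass(frozen=True)
class ConsensusCall:
    destabilizing: bool
    votes: int
    threshold: float
    min_votes: int

    def __post_init__(self):
        if self.destabilizing != (self.votes >= self.min_votes):
            raise ValueError("destabilizing flag inconsistent with votes")


def consensus_call(
    ddg: Sequence[float],
    threshold: float = DEFAULT_DDG_THRESHOLD,
    min_votes: int = DEFAULT_MIN_VOTES,
) -> ConsensusCall:
    """Unweighted vote over the per-method ddG values (inclusive threshold)."""
    votes = sum(1 for value in ddg if value <= threshold)
    return ConsensusCall(
        destabilizing=votes >= min_votes,
        votes=votes,
        threshold=threshold,
        min_votes=min_votes,
    )


def reverse_variant(ddg_of_reverse: Sequence[float]) -> DdgTriplet:
    """Antisymmetric image of a triplet computed for the reverse substitution."""
    a, b, c = ddg_of_reverse
    return (-a, -b, -c)


@dataclass
class StabilitySummary:
    """Per-domain destabilization counts over deduplicated records."""

    catalytic: int
    regulatory: int
    destabilizing: list[VariantRecord]
    destabilizing_and_interaction: list[VariantRecord]
    n_records: int

    @property
    def total(self) -> int:
        return self.catalytic + self.regulatory

    @property
    def fraction(self) -> float:
        if self.n_records == 0:
            raise ValueError("no records")
        return self.total / self.n_records


def destabilizing_counts(
    records: Iterable[VariantRecord],
    threshold: float = DEFAULT_DDG_THRESHOLD,
    min_votes: int = DEFAULT_MIN_VOTES,
) -> StabilitySummary:
    """Count consensus-destabilizing variants per domain.

    Expects deduplicated records; also returns the subset that is both
    destabilizing and flagged as an interaction site.
    """
    counts = {"catalytic": 0, "regulatory": 0}
    hits: list[VariantRecord] = []
    dual: list[VariantRecord] = []
    n = 0
    for rec in records:
        n += 1
        call = consensus_call(rec.ddg, threshold=threshold, min_votes=min_votes)
        if call.destabilizing:
            counts[rec.domain] += 1
            hits.append(rec)
            if rec.interaction:
                dual.append(rec)
    return StabilitySummary(
        catalytic=counts["catalytic"],
        regulatory=counts["regulatory"],
        destabilizing=hits,
        destabilizing_and_interaction=dual,
        n_records=n,
    )
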