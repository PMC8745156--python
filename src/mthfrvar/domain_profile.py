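"""Light profile model of a protein domain built from a multiple alignment.

The regulatory domain of MTHFR has no public family model; a profile is
estimated here directly from an alignment of homologous sequences.  Columns
whose gap fraction is at most 50% become match columns; per-column residue
emission frequencies use Laplace (+1) pseudocounts; transition frequencies
between match/insert/delete states are estimated the same way from the
observed column-to-column paths.  The reference (human) row anchors a mapping
from reference-sequence positions to model columns, which is what the
variant-to-architecture view needs.  No scoring or database search is done.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .variant_table import (
    CATALYTIC_LAST,
    REGULATORY_MODEL_SPAN,
    VariantRecord,
)
from .vartype import variation_type

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_ALPHA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}
GAP = "-"

TRANSITION_LABELS = ("MM", "MI", "MD", "IM", "II", "ID", "DM", "DI", "DD")


class MsaError(ValueError):
    """Ragged alignment or missing reference row."""


@dataclass(frozen=True)
class Msa:
    """A multiple alignment with a designated reference row."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    reference_id: str

    def __post_init__(self):
        if not self.rows:
            raise MsaError("alignment has no sequences")
        width = len(self.rows[0])
        for seq_id, row in zip(self.ids, self.rows):
            if len(row) != width:
                raise MsaError(
                    f"ragged alignment: row {seq_id!r} has length "
                    f"{len(row)}, expected {width}"
                )
        if self.reference_id not in self.ids:
            raise MsaError(f"reference {self.reference_id!r} not in alignment")

    @property
    def width(self) -> int:
        return len(self.rows[0])

    @property
    def depth(self) -> int:
        return len(self.rows)

    @property
    def reference_row(self) -> str:
        return self.rows[self.ids.index(self.reference_id)]


def _normalize_row(seq: str) -> str:
    return seq.upper().replace(".", GAP).replace("~", GAP)


def read_msa(
    path: str | Path,
    fmt: str | None = None,
    reference_id: str | None = None,
) -> Msa:
    """Read an aligned FASTA or Stockholm file.

    ``fmt`` is inferred from the suffix when omitted (.sto/.stk -> stockholm,
    otherwise fasta).  The reference defaults to the first sequence.  Gap
    symbols are normalized to '-'.
    """
    from Bio import AlignIO

    path = Path(path)
    if fmt is None:
        fmt = "stockholm" if path.suffix.lower() in (".sto", ".stk") else "fasta"
    try:
        alignment = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise MsaError(f"cannot parse {path} as {fmt}: {exc}")
    ids = tuple(rec.id for rec in alignment)
    rows = tuple(_normalize_row(str(rec.seq)) for rec in alignment)
    return Msa(ids=ids, rows=rows, reference_id=reference_id or ids[0])


@dataclass(frozen=True)
class ProfileModel:
    """Match-column profile with a reference-position mapping.

    ``emissions`` is (n_match, 20) over :data:`ALPHABET`, each row summing to
    1.  ``transitions`` is (n_match, 9) over :data:`TRANSITION_LABELS`; each
    source-state group (MM,MI,MD), (IM,II,ID), (DM,DI,DD) sums to 1.
    ``ref_map`` sends reference positions (1-based, offset by the model's
    start position) to a match-column index, or None for positions that fall
    in insert columns.
    """

    match_columns: tuple[int, ...]
    emissions: np.ndarray
    transitions: np.ndarray
    ref_map: dict[int, int | None]
    ref_start: int

    def __post_init__(self):
        m = len(self.match_columns)
        if self.emissions.shape != (m, 20):
            raise ValueError("emissions must be (n_match, 20)")
        if self.transitions.shape != (m, 9):
            raise ValueError("transitions must be (n_match, 9)")
        if not np.allclose(self.emissions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("emission rows must sum to 1")
        for k in range(0, 9, 3):
            if not np.allclose(
                self.transitions[:, k : k + 3].sum(axis=1), 1.0, atol=1e-9
            ):
                raise ValueError("transition groups must sum to 1")
        mapped = [col for col in self.ref_map.values() if col is not None]
        if mapped != sorted(mapped) or len(set(mapped)) != len(mapped):
            raise ValueError("ref_map must be strictly increasing over mapped positions")

    @property
    def n_match(self) -> int:
        return len(self.match_columns)

    @property
    def mapped_positions(self) -> list[int]:
        return sorted(p for p, col in self.ref_map.items() if col is not None)

    def column_for_position(self, position: int) -> int | None:
        return self.ref_map.get(position)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "alphabet": ALPHABET,
            "ref_start": self.ref_start,
            "match_columns": list(self.match_columns),
            "emissions": self.emissions.tolist(),
            "transition_labels": list(TRANSITION_LABELS),
            "transitions": self.transitions.tolist(),
            "ref_map": {str(k): v for k, v in sorted(self.ref_map.items())},
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ProfileModel":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text(encoding="utf-8")
        payload = json.loads(text)
        return cls(
            match_columns=tuple(payload["match_columns"]),
            emissions=np.array(payload["emissions"], dtype=float),
            transitions=np.array(payload["transitions"], dtype=float),
            ref_map={int(k): v for k, v in payload["ref_map"].items()},
            ref_start=int(payload["ref_start"]),
        )


def _state_path(row: str, match_set: set[int]) -> list[tuple[int, str]]:
    """Sequence of (match-interval index, state) visited by one aligned row.

    Interval k is match column k; inserts between match columns k and k+1 are
    attributed to source column k (inserts before the first match column are
    ignored, matching the usual profile convention of a begin state).
    """
    path: list[tuple[int, str]] = []
    match_index = -1
    for col, symbol in enumerate(row):
        if col in match_set:
            match_index += 1
            path.append((match_index, "M" if symbol != GAP else "D"))
        elif symbol != GAP and match_index >= 0:
            path.append((match_index, "I"))
    return path


def build_profile(
    msa: Msa,
    match_gap_fraction: float = 0.5,
    pseudocount: float = 1.0,
    ref_start: int = 1,
) -> ProfileModel:
    """Estimate a profile from an alignment.

    A column is a match column iff its gap fraction is <= ``match_gap_fraction``.
    Emissions per match column are (count + pseudocount) / (total + 20 *
    pseudocount); transitions are estimated analogously over the three targets
    of each source state.  ``ref_start`` is the reference-sequence position of
    the first reference residue (336 for the regulatory-domain alignment).
    """
    gap_fraction = np.array(
        [
            sum(1 for row in msa.rows if row[col] == GAP) / msa.depth
            for col in range(msa.width)
        ]
    )
    match_columns = tuple(
        int(col) for col in np.flatnonzero(gap_fraction <= match_gap_fraction)
    )
    if not match_columns:
        raise MsaError("alignment yields zero match columns")
    match_set = set(match_columns)
    col_to_index = {col: k for k, col in enumerate(match_columns)}
    n_match = len(match_columns)

    emission_counts = np.zeros((n_match, 20))
    transition_counts = np.zeros((n_match, 9))
    label_index = {label: i for i, label in enumerate(TRANSITION_LABELS)}
    for row in msa.rows:
        for col in match_columns:
            symbol = row[col]
            if symbol in _ALPHA_INDEX:
                emission_counts[col_to_index[col], _ALPHA_INDEX[symbol]] += 1
        path = _state_path(row, match_set)
        for (idx_a, state_a), (_, state_b) in zip(path, path[1:]):
            transition_counts[idx_a, label_index[state_a + state_b]] += 1

    emissions = (emission_counts + pseudocount) / (
        emission_counts.sum(axis=1, keepdims=True) + 20 * pseudocount
    )
    transitions = np.empty_like(transition_counts)
    for k in range(0, 9, 3):
        block = transition_counts[:, k : k + 3]
        transitions[:, k : k + 3] = (block + pseudocount) / (
            block.sum(axis=1, keepdims=True) + 3 * pseudocount
        )

    ref_map: dict[int, int | None] = {}
    position = ref_start - 1
    for col, symbol in enumerate(msa.reference_row):
        if symbol == GAP:
            continue
        position += 1
        ref_map[position] = col_to_index.get(col)

    return ProfileModel(
        match_columns=match_columns,
        emissions=emissions,
        transitions=transitions,
        ref_map=ref_map,
        ref_start=ref_start,
    )


@dataclass(frozen=True)
class ArchitectureAnnotation:
    """A variant placed on the two-domain architecture."""

    variant: str
    position: int
    domain_model: str | None      # 'catalytic', 'regulatory', or None
    column: int | None            # regulatory match column, when applicable
    variation_type: tuple[str, str]
    mapped: bool


def map_variants_to_architecture(
    records: Iterable[VariantRecord],
    profile_regulatory: ProfileModel,
    catalytic_span: tuple[int, int] = (1, CATALYTIC_LAST),
) -> list[ArchitectureAnnotation]:
    """Assign each variant to a domain model and (regulatory) profile column.

    Catalytic variants are placed by span membership; regulatory variants are
    mapped through the profile's reference mapping.  Variants outside both the
    catalytic span and the regulatory model's mapped positions are flagged
    unmapped (e.g. C-terminal positions beyond the model span).
    """
    lo, hi = catalytic_span
    annotations: list[ArchitectureAnnotation] = []
    for rec in records:
        vtype = variation_type(rec.wt_residue, rec.mut_residue)
        if lo <= rec.position <= hi:
            annotations.append(
                ArchitectureAnnotation(
                    variant=rec.variant,
                    position=rec.position,
                    domain_model="catalytic",
                    column=None,
                    variation_type=vtype,
                    mapped=True,
                )
            )
            continue
        column = profile_regulatory.column_for_position(rec.position)
        annotations.append(
            ArchitectureAnnotation(
                variant=rec.variant,
                position=rec.position,
                domain_model="regulatory" if column is not None else None,
                column=column,
                variation_type=vtype,
                mapped=column is not None,
            )
        )
    return annotations
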