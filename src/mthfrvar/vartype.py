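"""Physicochemical variation-type fingerprints and the pseudocount chi-square.

Each missense substitution is mapped to an ordered pair of residue classes
(apolar a, polar p, aromatic r, charged c), giving 16 possible variation
types.  Per-domain 4x4 count matrices are compared with a Pearson chi-square
homogeneity test on the 2x16 flattened table after adding a 0.5 pseudocount to
every cell (df = 15), which keeps the statistic finite for the sparse counts
typical of a single protein.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .variant_table import AMINO_ACIDS, VariantRecord

RESIDUE_CLASSES: dict[str, frozenset[str]] = {
    "apolar": frozenset("GAVILPM"),
    "polar": frozenset("STCNQH"),
    "aromatic": frozenset("FWY"),
    "charged": frozenset("DEKR"),
}

#: Short labels in fixed order (apolar, polar, aromatic, charged).
CLASS_LABELS = ("a", "p", "r", "c")
CLASS_ORDER = ("apolar", "polar", "aromatic", "charged")

_CLASS_OF: dict[str, str] = {
    aa: name for name, members in RESIDUE_CLASSES.items() for aa in members
}

# the four classes must partition the 20-letter alphabet
assert sum(len(m) for m in RESIDUE_CLASSES.values()) == 20
assert frozenset(_CLASS_OF) == AMINO_ACIDS

DEFAULT_PSEUDOCOUNT = 0.5


def residue_class(aa: str) -> str:
    try:
        return _CLASS_OF[aa]
    except KeyError:
        raise ValueError(f"not a standard amino acid: {aa!r}")


def variation_type(wt: str, mut: str) -> tuple[str, str]:
    """Ordered (source class, target class) pair of a substitution."""
    return residue_class(wt), residue_class(mut)


@dataclass(frozen=True)
class TypeMatrix:
    """4x4 counts over (source class, target class), rows/cols a,p,r,c."""

    counts: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.counts, dtype=float)
        if arr.shape != (4, 4):
            raise ValueError("TypeMatrix must be 4x4")
        if np.any(arr < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", arr)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def frequencies(self) -> np.ndarray:
        """Cell frequencies summing to 1; undefined (error) for empty matrices."""
        if self.total == 0:
            raise ValueError("frequencies undefined: all counts are zero")
        return self.counts / self.total

    def flatten(self) -> np.ndarray:
        """Row-major 16-vector in (a,p,r,c) x (a,p,r,c) order."""
        return self.counts.reshape(-1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(CLASS_LABELS), columns=list(CLASS_LABELS)
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="src")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(CLASS_LABELS) or list(df.columns) != list(
            CLASS_LABELS
        ):
            raise ValueError(
                f"matrix file must be labelled {CLASS_LABELS} on both axes"
            )
        return cls(df.to_numpy(dtype=float))


def type_matrix(
    records: Iterable[VariantRecord], domain: str | None = None
) -> TypeMatrix:
    """Count variants per variation type, optionally restricted to one domain.

    Expects deduplicated records; distinct substitutions at one position count
    separately.  An empty selection yields an all-zero matrix (frequencies are
    then flagged as undefined by :meth:`TypeMatrix.frequencies`).
    """
    index = {name: i for i, name in enumerate(CLASS_ORDER)}
    counts = np.zeros((4, 4))
    for rec in records:
        if domain is not None and rec.domain != domain:
            continue
        src, tgt = variation_type(rec.wt_residue, rec.mut_residue)
        counts[index[src], index[tgt]] += 1
    return TypeMatrix(counts)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    pseudocount: float


def chi_square_pseudocount(
    counts_a: TypeMatrix,
    counts_b: TypeMatrix,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> ChiSquareResult:
    """Pearson homogeneity chi-square on the regularized 2x16 table.

    Both matrices are flattened to 16-vectors, ``pseudocount`` is added to
    every cell, and the standard two-sample test is applied (df = 15, no
    continuity correction).  Identical matrices give statistic 0, p = 1.
    """
    table = np.vstack([counts_a.flatten(), counts_b.flatten()]) + pseudocount
    if np.any(table.sum(axis=1) <= 0):
        raise ValueError("group totals must be positive after pseudocounts")
    statistic, p_value, df, _ = chi2_contingency(table, correction=False)
    return ChiSquareResult(
        statistic=float(statistic),
        df=int(df),
        p_value=float(p_value),
        pseudocount=pseudocount,
    )


def background_matrix(source) -> TypeMatrix:
    """Background variation-type distribution for comparison.

    ``source`` may be a :class:`TypeMatrix` (passed through), a path to a
    labelled 4x4 TSV, or any object with a ``sample_type_matrix()`` method
    (e.g. :class:`mthfrvar.synthetic_data.BackgroundSampler`, which emulates a
    large pathogenic-variant background).
    """
    if isinstance(source, TypeMatrix):
        return source
    if isinstance(source, (str, Path)):
        return TypeMatrix.from_tsv(source)
    if hasattr(source, "sample_type_matrix"):
        return source.sample_type_matrix()
    raise TypeError(f"unsupported background source: {type(source).__name__}")


def plot_type_heatmap(
    matrices: Mapping[str, TypeMatrix],
    image_path: str | Path,
    tsv_path: str | Path | None = None,
) -> None:
    """Render frequency heatmaps (one panel per named matrix) plus numeric TSV."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(matrices)
    fig, axes = plt.subplots(1, len(names), figsize=(4 * len(names), 4), squeeze=False)
    rows = []
    for ax, name in zip(axes[0], names):
        freq = matrices[name].frequencies()
        im = ax.imshow(freq, cmap="viridis", vmin=0)
        ax.set_xticks(range(4), CLASS_LABELS)
        ax.set_yticks(range(4), CLASS_LABELS)
        ax.set_xlabel("target class")
        ax.set_ylabel("source class")
        ax.set_title(name)
        fig.colorbar(im, ax=ax, fraction=0.046)
        for i, src in enumerate(CLASS_LABELS):
            for j, tgt in enumerate(CLASS_LABELS):
                rows.append(
                    {"set": name, "src": src, "tgt": tgt, "frequency": freq[i, j]}
                )
    fig.tight_layout()
    fig.savefig(image_path, dpi=150)
    plt.close(fig)
    if tsv_path is not None:
        pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
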