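"""Structure I/O, Shrake-Rupley accessibility and interface detection.

Solvent-accessible surface area (SASA) is computed with the Shrake-Rupley
method: each heavy atom's van der Waals sphere is inflated by the probe radius
(water, 1.4 A) and sampled with a deterministic golden-spiral quadrature; a
sample point contributes accessible area iff it lies outside every other
atom's inflated sphere.  Relative accessibility (RSA) normalizes residue SASA
by a residue-type theoretical maximum and is reported as an integer percent.
A residue belongs to the homodimer interface when it loses at least 1 A^2 of
absolute SASA upon complex formation relative to the isolated component.

Coordinates are expressed in a canonical molecule-fixed frame (centroid
origin, principal axes) before quadrature, which makes the computed areas
exactly invariant under rigid motion of the input.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

#: Van der Waals radii (A) for protein heavy atoms (Chothia-style values).
DEFAULT_VDW_RADII: dict[str, float] = {"C": 1.76, "N": 1.65, "O": 1.40, "S": 1.85}

#: Theoretical maximum accessibility per residue type (A^2), Gly-X-Gly based
#: (Tien et al. 2013, theoretical column); the normalization table is a
#: configuration item and can be replaced wholesale.
MAX_ASA_THEORETICAL: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_N_POINTS = 960
DEFAULT_DELTA_ASA = 1.0


class StructureError(ValueError):
    """Unreadable file, unknown element, or empty atom selection."""


@dataclass(frozen=True)
class Structure:
    """Heavy-atom coordinate set with per-atom van der Waals radii."""

    chain_ids: tuple[str, ...]
    res_nums: np.ndarray          # (n,) int
    res_names: tuple[str, ...]
    atom_names: tuple[str, ...]
    elements: tuple[str, ...]
    coords: np.ndarray            # (n, 3) float, Angstrom
    het_flags: np.ndarray         # (n,) bool
    radii: np.ndarray             # (n,) float, Angstrom

    def __post_init__(self):
        n = len(self.chain_ids)
        if not (
            len(self.res_names) == len(self.atom_names) == len(self.elements) == n
            and self.coords.shape == (n, 3)
            and self.res_nums.shape == (n,)
            and self.het_flags.shape == (n,)
            and self.radii.shape == (n,)
        ):
            raise ValueError("inconsistent atom array lengths")
        if n == 0:
            raise StructureError("structure contains no atoms")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if not np.all(self.radii > 0):
            raise ValueError("all radii must be positive")
        keys = set(zip(self.chain_ids, self.res_nums.tolist(), self.atom_names))
        if len(keys) != n:
            raise ValueError("(chain, residue, atom name) keys are not unique")

    @property
    def n_atoms(self) -> int:
        return len(self.chain_ids)

    @property
    def chains(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(c)
        return tuple(seen)

    def subset(self, mask: np.ndarray) -> "Structure":
        idx = np.flatnonzero(np.asarray(mask, dtype=bool))
        if idx.size == 0:
            raise StructureError("empty atom selection")
        take = lambda seq: tuple(seq[i] for i in idx)
        return Structure(
            chain_ids=take(self.chain_ids),
            res_nums=self.res_nums[idx],
            res_names=take(self.res_names),
            atom_names=take(self.atom_names),
            elements=take(self.elements),
            coords=self.coords[idx],
            het_flags=self.het_flags[idx],
            radii=self.radii[idx],
        )

    def select_chains(self, chains: Iterable[str]) -> "Structure":
        wanted = set(chains)
        mask = np.array([c in wanted for c in self.chain_ids])
        if not mask.any():
            raise StructureError(f"no atoms in chains {sorted(wanted)}")
        return self.subset(mask)

    def residue_keys(self) -> list[tuple[str, int]]:
        """Residue identifiers in atom order, each once."""
        seen: dict[tuple[str, int], None] = {}
        for c, r in zip(self.chain_ids, self.res_nums.tolist()):
            seen.setdefault((c, r))
        return list(seen)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Rigidly moved copy: x -> x @ rotation.T + translation."""
        return dataclasses.replace(
            self, coords=self.coords @ np.asarray(rotation).T + translation
        )


@dataclass
class SasaResult:
    """Per-atom and per-residue accessibility for one structure.

    ``residues`` is a DataFrame with columns chain, resnum, resname, asa and
    (after :func:`relative_accessibility`) integer rsa.
    """

    per_atom_asa: np.ndarray
    residues: pd.DataFrame
    probe_radius: float
    n_points: int

    @property
    def total_asa(self) -> float:
        return float(self.per_atom_asa.sum())

    def residue_asa(self) -> dict[tuple[str, int], float]:
        return {
            (row.chain, int(row.resnum)): float(row.asa)
            for row in self.residues.itertuples()
        }

    def residue_rsa(self) -> dict[tuple[str, int], int]:
        if "rsa" not in self.residues:
            raise ValueError("RSA not computed; call relative_accessibility first")
        return {
            (row.chain, int(row.resnum)): int(row.rsa)
            for row in self.residues.itertuples()
        }

    def write_residue_table(self, path: str | Path) -> None:
        self.residues.to_csv(path, sep="\t", index=False)


def read_structure(
    path: str | Path,
    chains: Iterable[str] | None = None,
    keep_ligands: bool = False,
    radii: Mapping[str, float] | None = None,
) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Waters and hydrogens are always dropped; other heteroatom residues
    (cofactors such as FAD or SAH) are dropped unless ``keep_ligands``.
    Alternate locations are resolved to the highest-occupancy conformer,
    ties broken by the lowest altloc identifier.
    """
    import gemmi

    radii_table = dict(DEFAULT_VDW_RADII)
    if radii:
        radii_table.update(radii)
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:  # gemmi raises RuntimeError/ValueError variants
        raise StructureError(f"unreadable structure file {path}: {exc}")
    st.setup_entities()
    if len(st) == 0:
        raise StructureError(f"no models in {path}")
    model = st[0]
    wanted = set(chains) if chains is not None else None

    best: dict[tuple[str, int, str], tuple[float, str, dict]] = {}
    order: list[tuple[str, int, str]] = []
    for chain in model:
        if wanted is not None and chain.name not in wanted:
            continue
        for residue in chain:
            if residue.is_water():
                continue
            is_het = residue.het_flag == "H"
            if is_het and not keep_ligands:
                continue
            for atom in residue:
                element = atom.element.name.upper()
                if element == "H" or element == "D":
                    continue
                key = (chain.name, residue.seqid.num, atom.name)
                entry = (
                    float(atom.occ),
                    atom.altloc or "",
                    dict(
                        resname=residue.name,
                        element=element,
                        pos=(atom.pos.x, atom.pos.y, atom.pos.z),
                        het=is_het,
                    ),
                )
                if key not in best:
                    best[key] = entry
                    order.append(key)
                else:
                    occ0, alt0, _ = best[key]
                    if (entry[0], _alt_rank(entry[1])) > (occ0, _alt_rank(alt0)):
                        best[key] = entry
    if not order:
        raise StructureError(f"empty selection after filtering in {path}")

    chain_ids, res_nums, res_names, atom_names, elements, coords, hets, rad = (
        [], [], [], [], [], [], [], []
    )
    for key in order:
        cname, rnum, aname = key
        _, _, info = best[key]
        element = info["element"]
        if element not in radii_table:
            raise StructureError(
                f"no van der Waals radius for element {element!r} "
                f"(atom {aname} in {cname}/{rnum}); extend the radii table"
            )
        chain_ids.append(cname)
        res_nums.append(rnum)
        res_names.append(info["resname"])
        atom_names.append(aname)
        elements.append(element)
        coords.append(info["pos"])
        hets.append(info["het"])
        rad.append(radii_table[element])
    return Structure(
        chain_ids=tuple(chain_ids),
        res_nums=np.array(res_nums, dtype=int),
        res_names=tuple(res_names),
        atom_names=tuple(atom_names),
        elements=tuple(elements),
        coords=np.array(coords, dtype=float),
        het_flags=np.array(hets, dtype=bool),
        radii=np.array(rad, dtype=float),
    )


def _alt_rank(altloc: str) -> float:
    # higher is better: empty altloc outranks none; 'A' outranks 'B'
    return -ord(altloc) if altloc else 1.0


def golden_spiral_points(n_points: int) -> np.ndarray:
    """Deterministic near-uniform unit-sphere quadrature (golden spiral)."""
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    k = np.arange(n_points, dtype=float)
    z = 1.0 - 2.0 * (k + 0.5) / n_points
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack((rho * np.cos(phi), rho * np.sin(phi), z))


def canonical_frame(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and principal-axes rotation defining the molecule-fixed frame.

    Axis signs are fixed by the third central moment along each axis (falling
    back to the largest-magnitude coordinate) and the basis is made
    right-handed, so any rigidly moved copy of the structure maps to the same
    canonical coordinates up to floating-point error.
    """
    coords = np.asarray(coords, dtype=float)
    center = coords.mean(axis=0)
    centered = coords - center
    if len(coords) == 1:
        return center, np.eye(3)
    cov = centered.T @ centered
    eigvals, eigvecs = np.linalg.eigh(cov)
    axes = eigvecs[:, np.argsort(eigvals)[::-1]]  # columns, descending variance
    for j in range(3):
        proj = centered @ axes[:, j]
        skew = float(np.sum(proj**3))
        if abs(skew) > 1e-9:
            sign = np.sign(skew)
        else:
            sign = np.sign(proj[np.argmax(np.abs(proj))]) or 1.0
        axes[:, j] *= sign
    if np.linalg.det(axes) < 0:
        axes[:, 2] *= -1.0
    return center, axes


def _accessible_fractions(
    coords: np.ndarray,
    expanded: np.ndarray,
    n_points: int,
    neighbor_search: str,
) -> np.ndarray:
    """Fraction of quadrature points of each inflated sphere left uncovered."""
    n = len(coords)
    sphere = golden_spiral_points(n_points)
    fractions = np.empty(n)
    if neighbor_search == "kdtree":
        tree = cKDTree(coords)
        max_e = expanded.max()
        neighbor_lists = tree.query_ball_point(coords, expanded + max_e)
    elif neighbor_search == "all_pairs":
        neighbor_lists = [list(range(n))] * n
    else:
        raise ValueError("neighbor_search must be 'kdtree' or 'all_pairs'")
    for i in range(n):
        cand = [j for j in neighbor_lists[i] if j != i]
        if cand:
            cand = np.asarray(cand)
            d = np.linalg.norm(coords[cand] - coords[i], axis=1)
            cand = cand[d < expanded[i] + expanded[cand]]
        if len(cand) == 0:
            fractions[i] = 1.0
            continue
        points = coords[i] + expanded[i] * sphere
        diff = points[:, None, :] - coords[cand][None, :, :]
        covered = np.any(
            np.einsum("pnk,pnk->pn", diff, diff) < expanded[cand][None, :] ** 2,
            axis=1,
        )
        fractions[i] = 1.0 - covered.mean()
    return fractions


def _sasa_atoms(
    structure: Structure,
    probe_radius: float,
    n_points: int,
    neighbor_search: str,
    frame: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    if probe_radius < 0:
        raise ValueError("probe_radius must be >= 0")
    center, axes = canonical_frame(structure.coords) if frame is None else frame
    coords = (structure.coords - center) @ axes
    expanded = structure.radii + probe_radius
    fractions = _accessible_fractions(coords, expanded, n_points, neighbor_search)
    return 4.0 * np.pi * expanded**2 * fractions


def _residue_frame(structure: Structure, atom_asa: np.ndarray) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "chain": structure.chain_ids,
            "resnum": structure.res_nums,
            "resname": structure.res_names,
            "asa": atom_asa,
        }
    )
    grouped = (
        df.groupby(["chain", "resnum"], sort=False)
        .agg(resname=("resname", "first"), asa=("asa", "sum"))
        .reset_index()
    )
    return grouped


def shrake_rupley(
    structure: Structure,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    neighbor_search: str = "kdtree",
) -> SasaResult:
    """Shrake-Rupley SASA of every atom, aggregated per residue.

    ``neighbor_search='all_pairs'`` disables the KD-tree pruning; both modes
    are required to give bit-identical results.
    """
    atom_asa = _sasa_atoms(structure, probe_radius, n_points, neighbor_search)
    return SasaResult(
        per_atom_asa=atom_asa,
        residues=_residue_frame(structure, atom_asa),
        probe_radius=probe_radius,
        n_points=n_points,
    )


def relative_accessibility(
    sasa: SasaResult, max_table: Mapping[str, float] | None = None
) -> SasaResult:
    """Fill integer RSA% = round(100 * ASA / max_ASA(residue)), clamped to 100."""
    table = MAX_ASA_THEORETICAL if max_table is None else max_table
    residues = sasa.residues.copy()
    rsa = []
    for row in residues.itertuples():
        if row.resname not in table:
            raise ValueError(
                f"no maximal accessibility for residue type {row.resname!r} "
                f"({row.chain}/{row.resnum})"
            )
        value = 100.0 * row.asa / table[row.resname]
        rsa.append(int(np.clip(round(value), 0, 100)))
    residues["rsa"] = rsa
    return SasaResult(
        per_atom_asa=sasa.per_atom_asa,
        residues=residues,
        probe_radius=sasa.probe_radius,
        n_points=sasa.n_points,
    )


def classify_exposure(rsa_percent: float, threshold_percent: float = 20.0) -> str:
    """Exposure class of a residue: 'exposed' iff RSA >= threshold (inclusive)."""
    if not 0 <= rsa_percent <= 100:
        raise ValueError("RSA% must lie in [0, 100]")
    return "exposed" if rsa_percent >= threshold_percent else "buried"


def interface_residues(
    complex_structure: Structure,
    component_chain_sets: tuple[Sequence[str], Sequence[str]],
    delta_threshold: float = DEFAULT_DELTA_ASA,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    neighbor_search: str = "kdtree",
) -> set[tuple[str, int]]:
    """Residues losing >= ``delta_threshold`` A^2 of ASA upon complexation.

    Both isolated components are evaluated with the same quadrature settings
    and in the complex's canonical frame, so per-residue burial is exactly
    non-negative.
    """
    group_a, group_b = (set(g) for g in component_chain_sets)
    if not group_a or not group_b:
        raise ValueError("both chain groups must be non-empty")
    if group_a & group_b:
        raise ValueError(f"chain groups overlap: {sorted(group_a & group_b)}")
    present = set(complex_structure.chains)
    for group in (group_a, group_b):
        missing = group - present
        if missing:
            raise StructureError(f"chains absent from structure: {sorted(missing)}")

    frame = canonical_frame(complex_structure.coords)
    complex_asa = _sasa_atoms(
        complex_structure, probe_radius, n_points, neighbor_search, frame=frame
    )
    complex_res = _residue_frame(complex_structure, complex_asa)
    complex_map = {
        (r.chain, int(r.resnum)): float(r.asa) for r in complex_res.itertuples()
    }

    interface: set[tuple[str, int]] = set()
    for group in (group_a, group_b):
        component = complex_structure.select_chains(group)
        iso_asa = _sasa_atoms(
            component, probe_radius, n_points, neighbor_search, frame=frame
        )
        iso_res = _residue_frame(component, iso_asa)
        for row in iso_res.itertuples():
            key = (row.chain, int(row.resnum))
            if float(row.asa) - complex_map[key] >= delta_threshold:
                interface.add(key)
    return interface


def component_sasa(
    complex_structure: Structure,
    chains: Sequence[str],
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    neighbor_search: str = "kdtree",
) -> tuple[SasaResult, SasaResult]:
    """SASA of the full complex and of one isolated chain group.

    Both are evaluated in the complex's canonical frame with identical
    quadrature, so every atom's isolated ASA is >= its complex ASA.
    Returns ``(complex_result, component_result)``.
    """
    frame = canonical_frame(complex_structure.coords)
    complex_asa = _sasa_atoms(
        complex_structure, probe_radius, n_points, neighbor_search, frame=frame
    )
    component = complex_structure.select_chains(chains)
    iso_asa = _sasa_atoms(
        component, probe_radius, n_points, neighbor_search, frame=frame
    )
    return (
        SasaResult(complex_asa, _residue_frame(complex_structure, complex_asa),
                   probe_radius, n_points),
        SasaResult(iso_asa, _residue_frame(component, iso_asa),
                   probe_radius, n_points),
    )


def write_interface(interface: Iterable[tuple[str, int]], path: str | Path) -> None:
    rows = sorted(interface)
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("chain\tresidue\n")
        for chain, resnum in rows:
            handle.write(f"{chain}\t{resnum}\n")
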