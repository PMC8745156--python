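"""Deterministic fixture generators: toy structures, dimers, variant tables.

Everything here is seed-reproducible and emits the same dialects the pipeline
consumes (the variant TSV, PDB text, alignments), so every stage is testable
without downloads.  The ddG simulation distributions (normal with mean -2 or
0, sd 0.5, resampled until the consensus label is unambiguous) are not a
thermodynamic model; they exist to guarantee label separability so that
classifier recovery is exact by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .structure_sasa import DEFAULT_VDW_RADII, Structure
from .variant_table import (
    AMINO_ACIDS,
    CATALYTIC_LAST,
    VariantRecord,
    domain_for_position,
)
from .vartype import CLASS_LABELS, TypeMatrix

#: Idealized backbone geometry (Angstrom) used by the toy residue builder.
BACKBONE_GEOMETRY = {
    "N-CA": 1.46,
    "CA-C": 1.52,
    "C-O": 1.23,
    "CA-CB": 1.53,
    "CA-CA": 3.8,
}

#: Chain-B translation (A) at which every toy-dimer residue buries >= 1 A^2.
DIMER_CONTACT_OFFSET = 5.0

_AA_LIST = sorted(AMINO_ACIDS)

#: Residue positions available to the simulated table (UniProt-like span).
_MAX_POSITION = 656


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the simulated variant table.

    Defaults mirror the published table: 72 variants, 41 of them catalytic,
    42 destabilizing, 3 at the homodimer interface.
    """

    seed: int = 0
    n_variants: int = 72
    destabilizing_fraction: float = 42 / 72
    interface_fraction: float = 3 / 72
    domain_split: float = 41 / 72
    peptide_length: int = 3
    contact_offset: float = DIMER_CONTACT_OFFSET

    def __post_init__(self):
        for name in ("destabilizing_fraction", "interface_fraction", "domain_split"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.n_variants < 0:
            raise ValueError("n_variants must be >= 0")
        if self.n_variants == 0 and (
            self.destabilizing_fraction > 0 or self.interface_fraction > 0
        ):
            raise ValueError("cannot request positive fractions of zero variants")
        if self.peptide_length < 1:
            raise ValueError("peptide_length must be >= 1")
        if self.contact_offset <= 0:
            raise ValueError("contact_offset must be > 0")


def _residue_atoms(resnum: int, x0: float, with_sidechain: bool = True):
    """Heavy atoms of one idealized alanine-like residue at CA x-offset x0."""
    atoms = [
        ("N", "N", (x0 - 0.96, 1.10, 0.0)),
        ("CA", "C", (x0, 0.0, 0.0)),
        ("C", "C", (x0 + 1.52, 0.0, 0.0)),
        ("O", "O", (x0 + 2.12, -1.07, 0.0)),
    ]
    if with_sidechain:
        atoms.append(("CB", "C", (x0, -0.76, 1.33)))
    return [(resnum, "ALA", name, el, xyz) for name, el, xyz in atoms]


def _assemble(atom_tuples, chain_id="A", radii=None) -> Structure:
    radii_table = dict(DEFAULT_VDW_RADII)
    if radii:
        radii_table.update(radii)
    chain_ids, res_nums, res_names, atom_names, elements, coords = (
        [], [], [], [], [], []
    )
    for entry in atom_tuples:
        if len(entry) == 6:
            cid, rnum, rname, aname, el, xyz = entry
        else:
            rnum, rname, aname, el, xyz = entry
            cid = chain_id
        chain_ids.append(cid)
        res_nums.append(rnum)
        res_names.append(rname)
        atom_names.append(aname)
        elements.append(el)
        coords.append(xyz)
    n = len(chain_ids)
    return Structure(
        chain_ids=tuple(chain_ids),
        res_nums=np.array(res_nums, dtype=int),
        res_names=tuple(res_names),
        atom_names=tuple(atom_names),
        elements=tuple(elements),
        coords=np.array(coords, dtype=float),
        het_flags=np.zeros(n, dtype=bool),
        radii=np.array([radii_table[e] for e in elements], dtype=float),
    )


def structure_to_pdb(structure: Structure) -> str:
    """Serialize a toy structure as PDB text (via gemmi)."""
    import gemmi

    st = gemmi.Structure()
    st.name = "toy"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for i in range(structure.n_atoms):
        cid = structure.chain_ids[i]
        if cid not in chains:
            chains[cid] = gemmi.Chain(cid)
        chain = chains[cid]
        rnum = int(structure.res_nums[i])
        if len(chain) == 0 or chain[-1].seqid.num != rnum:
            residue = gemmi.Residue()
            residue.name = structure.res_names[i]
            residue.seqid = gemmi.SeqId(rnum, " ")
            chain.add_residue(residue)
        atom = gemmi.Atom()
        atom.name = structure.atom_names[i]
        atom.element = gemmi.Element(structure.elements[i])
        x, y, z = structure.coords[i]
        atom.pos = gemmi.Position(float(x), float(y), float(z))
        atom.occ = 1.0
        atom.b_iso = 0.0
        chain[-1].add_atom(atom)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    for chain in st[0]:
        for residue in chain:
            residue.het_flag = "A"  # force ATOM records for toy polymers
    return st.make_pdb_string()


def make_toy_structure(
    kind: str,
    peptide_length: int = 3,
    shell_gap: float = 1.4,
    n_shell_atoms: int = 100,
) -> tuple[Structure, str]:
    """Deterministic idealized structures with known surface behaviour.

    kinds: ``single_atom`` (one carbon at the origin), ``single_residue``
    (5 heavy atoms), ``tripeptide`` (``peptide_length`` residues, ideal
    backbone), ``shell`` (a central carbon fully buried by a dense shell for
    any probe radius <= ``shell_gap``).  Returns the structure and PDB text.
    """
    if kind == "single_atom":
        structure = _assemble([(1, "GLY", "CA", "C", (0.0, 0.0, 0.0))])
    elif kind == "single_residue":
        structure = _assemble(_residue_atoms(1, 0.0))
    elif kind == "tripeptide":
        atoms = []
        for i in range(peptide_length):
            atoms.extend(_residue_atoms(i + 1, BACKBONE_GEOMETRY["CA-CA"] * i))
        structure = _assemble(atoms)
    elif kind == "shell":
        from .structure_sasa import golden_spiral_points

        atoms = [(1, "GLY", "CA", "C", (0.0, 0.0, 0.0))]
        directions = golden_spiral_points(n_shell_atoms)
        for j, direction in enumerate(directions):
            atoms.append((2 + j, "GLY", "CA", "C", tuple(1.0 * direction)))
        structure = _assemble(atoms)
    else:
        raise ValueError(f"unknown toy structure kind {kind!r}")
    return structure, structure_to_pdb(structure)


def make_toy_dimer(
    contact_offset: float = DIMER_CONTACT_OFFSET, peptide_length: int = 3
) -> Structure:
    """Two tripeptide copies (chains A, B) related by a y-translation.

    At large offsets no residue loses any area; at :data:`DIMER_CONTACT_OFFSET`
    every residue of both chains loses >= 1 A^2, and because the two chains are
    exact translates the chain-A and chain-B interface sets mirror each other
    residue for residue.
    """
    if contact_offset <= 0:
        raise ValueError("contact_offset must be > 0")
    monomer, _ = make_toy_structure("tripeptide", peptide_length=peptide_length)
    atoms = []
    for i in range(monomer.n_atoms):
        atoms.append(
            (
                "A",
                int(monomer.res_nums[i]),
                monomer.res_names[i],
                monomer.atom_names[i],
                monomer.elements[i],
                tuple(monomer.coords[i]),
            )
        )
    for i in range(monomer.n_atoms):
        x, y, z = monomer.coords[i]
        atoms.append(
            (
                "B",
                int(monomer.res_nums[i]),
                monomer.res_names[i],
                monomer.atom_names[i],
                monomer.elements[i],
                (x, y + contact_offset, z),
            )
        )
    return _assemble(atoms)


def _sample_ddg(rng: np.random.Generator, destabilizing: bool) -> tuple[float, float, float]:
    """Resample a triplet until its consensus label matches the target."""
    mean = -2.0 if destabilizing else 0.0
    while True:
        values = rng.normal(mean, 0.5, size=3)
        votes = int(np.sum(values <= -1.0))
        if destabilizing and votes >= 2:
            return tuple(round(float(v), 2) for v in values)
        if not destabilizing and votes <= 1:
            return tuple(round(float(v), 2) for v in values)


def simulate_variant_table(
    config: SimulationConfig,
) -> tuple[list[VariantRecord], list[bool]]:
    """Simulated variant table with ground-truth destabilization labels.

    Exactly ``round(n * destabilizing_fraction)`` variants are destabilizing;
    positions are unique, split between domains per ``domain_split``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_variants
    if n == 0:
        return [], []
    n_destab = round(n * config.destabilizing_fraction)
    n_cat = round(n * config.domain_split)
    n_interface = round(n * config.interface_fraction)

    cat_positions = rng.choice(
        np.arange(1, CATALYTIC_LAST + 1), size=n_cat, replace=False
    )
    reg_positions = rng.choice(
        np.arange(CATALYTIC_LAST + 1, _MAX_POSITION + 1),
        size=n - n_cat,
        replace=False,
    )
    positions = np.concatenate([cat_positions, reg_positions])

    labels = np.zeros(n, dtype=bool)
    labels[:n_destab] = True
    rng.shuffle(labels)
    interface = np.zeros(n, dtype=bool)
    interface[:n_interface] = True
    rng.shuffle(interface)

    records: list[VariantRecord] = []
    for i in range(n):
        wt, mut = rng.choice(_AA_LIST, size=2, replace=False)
        position = int(positions[i])
        records.append(
            VariantRecord(
                wt_residue=str(wt),
                position=position,
                mut_residue=str(mut),
                domain=domain_for_position(position),
                effect="",
                ddg=_sample_ddg(rng, bool(labels[i])),
                interaction=bool(interface[i]),
                rsa_percent=int(rng.integers(0, 101)),
            )
        )
    return records, labels.tolist()


def simulate_alignment(
    n_sequences: int = 20,
    ref_length: int = 231,
    substitution_rate: float = 0.2,
    insert_rate: float = 0.05,
    delete_rate: float = 0.05,
    seed: int = 0,
    reference_id: str = "HUMAN_REF",
):
    """Synthetic domain-like alignment around an ungapped reference row.

    The reference (first row) is an ungapped random sequence of
    ``ref_length`` residues; homologs substitute residues at
    ``substitution_rate``, delete at ``delete_rate``, and occasional insert
    columns (gap in the reference) are added at ``insert_rate`` per reference
    column.  Defaults give a regulatory-domain-sized alignment (231 columns
    matching the human 336-566 span before inserts).  Returns an
    :class:`mthfrvar.domain_profile.Msa`.
    """
    from .domain_profile import Msa

    rng = np.random.default_rng(seed)
    ref = rng.choice(_AA_LIST, size=ref_length)
    columns: list[list[str]] = []
    for j in range(ref_length):
        column = [str(ref[j])]
        for _ in range(n_sequences - 1):
            if rng.random() < delete_rate:
                column.append("-")
            elif rng.random() < substitution_rate:
                column.append(str(rng.choice(_AA_LIST)))
            else:
                column.append(str(ref[j]))
        columns.append(column)
        if rng.random() < insert_rate:
            # insert column: residue in one non-reference row only
            insert = ["-"] * n_sequences
            insert[int(rng.integers(1, n_sequences))] = str(rng.choice(_AA_LIST))
            columns.append(insert)
    rows = tuple("".join(col[i] for col in columns) for i in range(n_sequences))
    ids = tuple(
        [reference_id] + [f"seq{i}" for i in range(1, n_sequences)]
    )
    return Msa(ids=ids, rows=rows, reference_id=reference_id)


@dataclass(frozen=True)
class BackgroundSampler:
    """Emulates a large pathogenic-variant background type distribution.

    Samples ``n_variants`` variation types from ``probs`` (16 cell
    probabilities in row-major a/p/r/c order; uniform when omitted) and
    returns the 4x4 count matrix.  Identical seeds give identical matrices.
    """

    n_variants: int = 22763
    seed: int = 0
    probs: tuple[float, ...] | None = None

    def sample_type_matrix(self) -> TypeMatrix:
        rng = np.random.default_rng(self.seed)
        if self.probs is None:
            probs = np.full(16, 1.0 / 16.0)
        else:
            probs = np.asarray(self.probs, dtype=float)
            if probs.shape != (16,) or not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
                raise ValueError("probs must be 16 values summing to 1")
        counts = rng.multinomial(self.n_variants, probs)
        return TypeMatrix(counts.reshape(4, 4).astype(float))
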