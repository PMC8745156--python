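"""Orchestration: run the full annotation on a variant table and a structure.

``run_table_analysis`` reproduces the headline statistics of the study from
the table alone (destabilizing counts per domain, the destabilizing-and-
interface subset, the exposure breakdown and the variation-type chi-square).
``run_structure_analysis`` adds structure-derived quantities (per-residue
RSA, the homodimer interface set, computed-vs-printed RSA comparison).
Reports serialize to deterministic JSON: fixed inputs give byte-identical
output, with no timestamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from . import __version__
from .stability import (
    DEFAULT_DDG_THRESHOLD,
    DEFAULT_MIN_VOTES,
    destabilizing_counts,
)
from .structure_sasa import (
    DEFAULT_DELTA_ASA,
    DEFAULT_N_POINTS,
    DEFAULT_PROBE_RADIUS,
    classify_exposure,
    interface_residues,
    read_structure,
    relative_accessibility,
    shrake_rupley,
)
from .variant_table import VariantRecord, deduplicate, parse_variant_table
from .vartype import chi_square_pseudocount, type_matrix

DEFAULT_EXPOSURE_THRESHOLD = 20.0


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable thresholds of the annotation pipeline."""

    ddg_threshold: float = DEFAULT_DDG_THRESHOLD       # kcal/mol, inclusive
    min_votes: int = DEFAULT_MIN_VOTES                 # of 3 predictors
    exposure_threshold: float = DEFAULT_EXPOSURE_THRESHOLD  # RSA %, inclusive
    pseudocount: float = 0.5                           # chi-square regularizer
    probe_radius: float = DEFAULT_PROBE_RADIUS         # A
    n_points: int = DEFAULT_N_POINTS                   # quadrature points/atom
    delta_asa: float = DEFAULT_DELTA_ASA               # A^2 interface rule


@dataclass
class Report:
    """Machine-readable analysis report with provenance."""

    provenance: dict
    table: dict
    stability: dict
    exposure: dict
    variation_types: dict
    structure: dict | None = None

    def to_dict(self) -> dict:
        payload = {
            "provenance": self.provenance,
            "table": self.table,
            "stability": self.stability,
            "exposure": self.exposure,
            "variation_types": self.variation_types,
        }
        if self.structure is not None:
            payload["structure"] = self.structure
        return payload

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _exposure_breakdown(
    records: Sequence[VariantRecord], threshold: float
) -> dict:
    by_domain: dict[str, dict] = {}
    for domain in ("catalytic", "regulatory"):
        subset = [r for r in records if r.domain == domain]
        exposed = [
            r for r in subset
            if classify_exposure(r.rsa_percent, threshold) == "exposed"
        ]
        exposed_not_interaction = [r for r in exposed if not r.interaction]
        by_domain[domain] = {
            "total": len(subset),
            "exposed": len(exposed),
            "buried": len(subset) - len(exposed),
            "exposed_not_interaction": len(exposed_not_interaction),
            "exposed_not_interaction_variants": sorted(
                r.variant for r in exposed_not_interaction
            ),
        }
    return {"threshold_percent": threshold, "by_domain": by_domain}


def analyze_records(
    records: Sequence[VariantRecord],
    config: AnalysisConfig | None = None,
    provenance: dict | None = None,
) -> Report:
    """Full table-level analysis of already-parsed records (raw, with dups)."""
    config = config or AnalysisConfig()
    unique, removed = deduplicate(records)
    summary = destabilizing_counts(
        unique, threshold=config.ddg_threshold, min_votes=config.min_votes
    )
    cat_matrix = type_matrix(unique, domain="catalytic")
    reg_matrix = type_matrix(unique, domain="regulatory")
    if cat_matrix.total > 0 and reg_matrix.total > 0:
        chi = chi_square_pseudocount(
            cat_matrix, reg_matrix, pseudocount=config.pseudocount
        )
        chi_payload = {
            "statistic": chi.statistic,
            "df": chi.df,
            "p_value": chi.p_value,
            "pseudocount": chi.pseudocount,
        }
    else:
        chi_payload = None

    table_counts = {
        "rows": len(records),
        "unique_variants": len(unique),
        "duplicates_removed": sorted(r.variant for r in removed),
        "by_domain_rows": {
            domain: sum(1 for r in records if r.domain == domain)
            for domain in ("catalytic", "regulatory")
        },
        "by_domain_unique": {
            domain: sum(1 for r in unique if r.domain == domain)
            for domain in ("catalytic", "regulatory")
        },
    }
    stability_payload = {
        "ddg_threshold": config.ddg_threshold,
        "min_votes": config.min_votes,
        "catalytic": summary.catalytic,
        "regulatory": summary.regulatory,
        "total": summary.total,
        "fraction_of_unique": (
            summary.fraction if summary.n_records else None
        ),
        "destabilizing_variants": sorted(
            r.variant for r in summary.destabilizing
        ),
        "destabilizing_and_interaction": sorted(
            r.variant for r in summary.destabilizing_and_interaction
        ),
    }
    vt_payload = {
        "catalytic_counts": cat_matrix.counts.tolist(),
        "regulatory_counts": reg_matrix.counts.tolist(),
        "chi_square": chi_payload,
    }
    base_prov = {
        "tool": "mthfrvar",
        "version": __version__,
        "parameters": dataclasses.asdict(config),
    }
    if provenance:
        base_prov.update(provenance)
    return Report(
        provenance=base_prov,
        table=table_counts,
        stability=stability_payload,
        exposure=_exposure_breakdown(unique, config.exposure_threshold),
        variation_types=vt_payload,
    )


def run_table_analysis(
    table_path: str | Path, config: AnalysisConfig | None = None
) -> Report:
    """Parse a variant TSV and compute the table-level report."""
    records = parse_variant_table(table_path)
    return analyze_records(
        records,
        config=config,
        provenance={"table": str(table_path), "table_sha256": _sha256(table_path)},
    )


def run_structure_analysis(
    structure_path: str | Path,
    chain_groups: tuple[Sequence[str], Sequence[str]] | None,
    config: AnalysisConfig | None = None,
    records: Sequence[VariantRecord] | None = None,
    chains: Sequence[str] | None = None,
) -> dict:
    """Structure-level report fragment: RSA table, interface, RSA comparison.

    ``chain_groups`` names the two components of the complex for interface
    detection (None skips it); ``chains`` optionally restricts reading.  When
    ``records`` is given, computed RSA values (first chain of the structure)
    are compared with the printed ones per variant position.
    """
    config = config or AnalysisConfig()
    structure = read_structure(structure_path, chains=chains)
    sasa = relative_accessibility(
        shrake_rupley(
            structure,
            probe_radius=config.probe_radius,
            n_points=config.n_points,
        )
    )
    fragment: dict = {
        "structure": str(structure_path),
        "structure_sha256": _sha256(structure_path),
        "chains": list(structure.chains),
        "n_atoms": structure.n_atoms,
        "residue_rsa": [
            {
                "chain": row.chain,
                "resnum": int(row.resnum),
                "resname": row.resname,
                "asa": round(float(row.asa), 3),
                "rsa": int(row.rsa),
            }
            for row in sasa.residues.itertuples()
        ],
    }
    if chain_groups is not None:
        group_a, group_b = chain_groups
        present = set(structure.chains)
        if not (set(group_a) <= present and set(group_b) <= present):
            raise ValueError(
                "interface requested but structure lacks the named chains "
                f"(has {sorted(present)})"
            )
        interface = interface_residues(
            structure,
            (tuple(group_a), tuple(group_b)),
            delta_threshold=config.delta_asa,
            probe_radius=config.probe_radius,
            n_points=config.n_points,
        )
        fragment["interface"] = {
            "delta_asa_threshold": config.delta_asa,
            "residues": [
                {"chain": c, "resnum": r} for c, r in sorted(interface)
            ],
        }
    if records is not None:
        first_chain = structure.chains[0]
        rsa_map = sasa.residue_rsa()
        comparison = []
        for rec in records:
            key = (first_chain, rec.position)
            computed = rsa_map.get(key)
            comparison.append(
                {
                    "variant": rec.variant,
                    "printed_rsa": rec.rsa_percent,
                    "computed_rsa": computed,
                    "abs_difference": (
                        abs(computed - rec.rsa_percent)
                        if computed is not None
                        else None
                    ),
                }
            )
        fragment["rsa_comparison"] = comparison
    return fragment
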