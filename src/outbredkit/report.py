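"""Pipeline orchestration: per-colony summary reports.

``run_pipeline`` executes metrics -> LD -> structure -> mosaic (when a
founder panel is supplied) -> QTL (when phenotypes are supplied) and
returns one report row per colony plus a provenance record of every
input, parameter and seed, so each reported number is traceable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from .genotypes import ColonyPanel, FounderPanel, PhenotypeTable, align_to_founders
from .ld import ld_decay_radius, ld_pairs
from .metrics import ColonyMetrics, SuitabilityVerdict, classify_suitability, colony_metrics
from .mosaic import FounderContribution, MosaicModel, founder_contributions, mosaic_posteriors
from .structure import detect_structure

logger = logging.getLogger(__name__)


@dataclass
class ColonyReport:
    metrics: ColonyMetrics
    decay_radius_bp: float
    decay_status: str
    structured: bool | None
    verdict: SuitabilityVerdict
    contributions: FounderContribution | None
    provenance: dict


def run_pipeline(
    colonies: list[ColonyPanel],
    founders: FounderPanel | None = None,
    phenotypes: PhenotypeTable | None = None,
    hwe_alpha: float = 0.05,
    bin_width_bp: int = 100_000,
    min_pairs_per_bin: int = 10,
    structure_threshold: float = 0.40,
    mosaic_generations: float = 30.0,
    genotype_error: float = 0.01,
    seed: int = 0,
) -> list[ColonyReport]:
    """Run the characterization battery over each colony."""
    reports = []
    for colony in colonies:
        prov: dict = {
            "version": __version__,
            "colony_id": colony.colony_id,
            "n_samples": colony.genotypes.n_samples,
            "n_markers": colony.genotypes.n_markers,
            "parameters": {
                "hwe_alpha": hwe_alpha,
                "bin_width_bp": bin_width_bp,
                "min_pairs_per_bin": min_pairs_per_bin,
                "structure_threshold": structure_threshold,
                "mosaic_generations": mosaic_generations,
                "genotype_error": genotype_error,
                "seed": seed,
            },
            "stages": [],
        }
        m = colony_metrics(colony, alpha=hwe_alpha)
        prov["stages"].append("metrics")

        pairs = ld_pairs(colony.genotypes)
        profile = ld_decay_radius(pairs, bin_width_bp, min_pairs_per_bin)
        prov["stages"].append("ld")

        structured: bool | None = None
        if colony.genotypes.n_samples >= 10:
            structured = detect_structure(
                colony.genotypes, threshold=structure_threshold, seed=seed
            )
            prov["stages"].append("structure")
        else:
            logger.info("%s: too few samples for structure stage", colony.colony_id)

        verdict = classify_suitability(m, structured=bool(structured))

        contrib = None
        if founders is not None:
            g2, f2 = align_to_founders(colony.genotypes, founders)
            model = MosaicModel(f2, G=mosaic_generations, genotype_error=genotype_error)
            posts = mosaic_posteriors(g2, model)
            contrib = founder_contributions(posts, g2.markers, colony.colony_id)
            prov["stages"].append("mosaic")
        else:
            logger.info("%s: mosaic stage skipped (no founder panel)", colony.colony_id)
        if phenotypes is None:
            logger.info("%s: QTL stage skipped (no phenotypes)", colony.colony_id)

        reports.append(
            ColonyReport(
                metrics=m,
                decay_radius_bp=profile.radius_bp,
                decay_status=profile.status,
                structured=structured,
                verdict=verdict,
                contributions=contrib,
                provenance=prov,
            )
        )
    return reports


REPORT_COLUMNS = [
    "Colony",
    "No.",
    "Mk.",
    "Mean MAF",
    "LD decay radius",
    "Het.",
    "Pct fail HWE",
    "In-breeding coef",
    "Struct.",
    "Usable",
]


def reports_to_table(reports: list[ColonyReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        m = r.metrics
        radius_mb = r.decay_radius_bp / 1e6 if np.isfinite(r.decay_radius_bp) else np.nan
        rows.append(
            {
                "Colony": m.colony_id,
                "No.": m.n_samples,
                "Mk.": m.n_markers,
                "Mean MAF": round(m.mean_maf, 3),
                "LD decay radius": round(radius_mb, 2) if np.isfinite(radius_mb) else "NA",
                "Het.": round(m.mean_het, 2),
                "Pct fail HWE": round(m.pct_fail_hwe, 2),
                "In-breeding coef": round(m.mean_inbreeding_coef_pct, 2),
                "Struct.": {True: "Y", False: "", None: "NA"}[r.structured],
                "Usable": "Y" if r.verdict.usable_for_mapping else "N",
            }
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def load_config(path: str) -> dict:
    """Read a keyed YAML config naming inputs, thresholds, and seeds.

    Recognized keys: genotypes, format, founders, colony_labels,
    phenotypes, and any keyword parameter of :func:`run_pipeline`
    (hwe_alpha, bin_width_bp, min_pairs_per_bin, structure_threshold,
    mosaic_generations, genotype_error, seed).
    """
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def write_report(reports: list[ColonyReport], tsv_path: str, provenance_path: str) -> None:
    reports_to_table(reports).to_csv(tsv_path, sep="\t", index=False)
    with open(provenance_path, "w") as fh:
        json.dump([r.provenance for r in reports], fh, indent=2, default=str)
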