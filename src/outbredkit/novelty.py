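"""Fraction of colony sequence variants absent from an inbred-strain
catalogue, after read-level quality filters and an FDR adjustment.

Reduced-representation SNP calls are filtered on three conjunctive
criteria before comparison: distance from the read end must exceed 3 bp,
the call must lie within 32 bp of a known restriction site, and read
depth must exceed 10x.  The novel fraction is the share of filtered calls
whose (position, alternate allele) is absent from the catalogue; the
adjusted rate subtracts the library protocol's estimated false-discovery
rate (floored at zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CALL_COLUMNS = [
    "chromosome",
    "position_bp",
    "ref",
    "alt",
    "depth",
    "dist_to_read_end_bp",
    "dist_to_restriction_site_bp",
]


@dataclass
class NoveltyResult:
    n_input: int
    n_pass_filters: int
    n_novel: int
    raw_rate: float
    adjusted_rate: float


def filter_calls(
    calls: pd.DataFrame,
    min_depth: int = 10,
    max_end_dist_excl: int = 3,
    max_site_dist: int = 32,
) -> pd.DataFrame:
    """Keep calls with read-end distance > ``max_end_dist_excl``,
    restriction-site distance <= ``max_site_dist`` (NA distance discarded),
    and depth strictly greater than ``min_depth``."""
    site = pd.to_numeric(calls["dist_to_restriction_site_bp"], errors="coerce")
    keep = (
        (calls["dist_to_read_end_bp"] > max_end_dist_excl)
        & site.notna()
        & (site <= max_site_dist)
        & (calls["depth"] > min_depth)
    )
    return calls.loc[keep].reset_index(drop=True)


def novelty_rate(
    filtered: pd.DataFrame,
    catalogue: set[tuple[str, int, str]],
    fdr: float = 0.0,
) -> NoveltyResult:
    """Novel-variant rate against a catalogue of known
    (chromosome, position, alt allele) triples."""
    n = len(filtered)
    if n == 0:
        return NoveltyResult(0, 0, 0, 0.0, 0.0)
    novel = ~filtered.apply(
        lambda r: (str(r["chromosome"]), int(r["position_bp"]), str(r["alt"])) in catalogue,
        axis=1,
    )
    n_novel = int(novel.sum())
    raw = n_novel / n
    return NoveltyResult(
        n_input=n,
        n_pass_filters=n,
        n_novel=n_novel,
        raw_rate=raw,
        adjusted_rate=max(0.0, raw - fdr),
    )


def assess_novelty(
    calls: pd.DataFrame,
    catalogue: set[tuple[str, int, str]],
    fdr: float = 0.0,
    min_depth: int = 10,
    max_end_dist_excl: int = 3,
    max_site_dist: int = 32,
) -> NoveltyResult:
    """Filter then rate, keeping the pre-filter input count."""
    filtered = filter_calls(calls, min_depth, max_end_dist_excl, max_site_dist)
    res = novelty_rate(filtered, catalogue, fdr)
    return NoveltyResult(
        n_input=len(calls),
        n_pass_filters=res.n_pass_filters,
        n_novel=res.n_novel,
        raw_rate=res.raw_rate,
        adjusted_rate=res.adjusted_rate,
    )


def read_catalogue_tsv(path: str) -> set[tuple[str, int, str]]:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    return {
        (str(r.chromosome), int(r.position_bp), str(r.alt)) for r in df.itertuples()
    }


def read_calls_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    missing = [c for c in CALL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing call columns {missing}")
    return df
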