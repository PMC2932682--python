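"""Per-colony inbreeding and diversity metrics.

Implements the battery used to judge whether a closed outbred colony is
usable for association mapping: mean minor allele frequency, observed
heterozygosity, the fraction of polymorphic markers failing an exact
Hardy-Weinberg test, and a per-individual inbreeding coefficient
F = (O_hom - E_hom) / (L - E_hom) comparing observed with expected
homozygote counts under colony-level allele frequencies.  F is reported
x100 (percent-like; negative values indicate excess heterozygosity).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .genotypes import MISSING, ColonyPanel, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class ColonyMetrics:
    colony_id: str
    mean_maf: float
    mean_het: float
    pct_low_maf: float
    pct_fail_hwe: float
    mean_inbreeding_coef_pct: float
    n_samples: int
    n_markers: int


@dataclass
class SuitabilityVerdict:
    flags: set[str] = field(default_factory=set)
    usable_for_mapping: bool = True


def genotype_counts(column: np.ndarray) -> tuple[int, int, int]:
    """(n_hom_a, n_het, n_hom_b) over non-missing calls of one marker."""
    return (
        int((column == 0).sum()),
        int((column == 1).sum()),
        int((column == 2).sum()),
    )


def minor_allele_freq(column: np.ndarray) -> float:
    """MAF of one marker column; NaN if every call is missing."""
    nm = column != MISSING
    n = int(nm.sum())
    if n == 0:
        return float("nan")
    p = (2 * (column[nm] == 2).sum() + (column[nm] == 1).sum()) / (2 * n)
    return float(min(p, 1.0 - p))


def hwe_exact_test(n_hom_a: int, n_het: int, n_hom_b: int) -> float:
    """Two-sided exact test of Hardy-Weinberg equilibrium.

    Sums the conditional probabilities (given allele counts and N) of every
    heterozygote count whose probability does not exceed that of the
    observed count.  Monomorphic markers return p = 1 by convention.

    Probabilities are computed with exact integer weights
    ``N! / (naa! nab! nbb!) * 2**nab`` (all shared factors cancel), so the
    test agrees with full enumeration to floating-point rounding only in
    the final division.
    """
    n = n_hom_a + n_het + n_hom_b
    if n < 1:
        raise ValueError("need at least one genotype")
    n_b = 2 * n_hom_b + n_het  # copies of allele B
    n_rare = min(n_b, 2 * n - n_b)
    if n_rare == 0:
        return 1.0
    # het counts share the parity of the rare-allele count
    weights: dict[int, int] = {}
    for h in range(n_rare % 2, n_rare + 1, 2):
        n_rare_hom = (n_rare - h) // 2
        n_common_hom = n - h - n_rare_hom
        if n_common_hom < 0:
            continue
        weights[h] = (
            math.factorial(n)
            // (math.factorial(n_rare_hom) * math.factorial(h) * math.factorial(n_common_hom))
            * 2**h
        )
    total = sum(weights.values())
    w_obs = weights[n_het]
    p = sum(w for w in weights.values() if w <= w_obs) / total
    return min(1.0, p)


def observed_heterozygosity(g: GenotypeMatrix) -> float:
    """Proportion of non-missing calls that are heterozygous, averaged over
    markers (markers with no calls are skipped)."""
    calls = g.calls
    nm = (calls != MISSING).sum(axis=0)
    het = (calls == 1).sum(axis=0)
    ok = nm > 0
    if not ok.any():
        raise ValueError("no non-missing calls")
    return float(np.mean(het[ok] / nm[ok]))


def allele_b_freqs(g: GenotypeMatrix) -> np.ndarray:
    """Plug-in allele-B frequency per marker (NaN where all missing)."""
    calls = g.calls
    nm = (calls != MISSING).sum(axis=0)
    nb = (2 * (calls == 2) + (calls == 1)).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(nm > 0, nb / (2 * nm), np.nan)


def inbreeding_coefficient(row: np.ndarray, freqs: np.ndarray) -> float:
    """F for one individual given colony-level allele frequencies.

    Uses the individual's non-missing calls at polymorphic markers
    (0 < p < 1).  Returns NaN when E_hom equals the marker count (no
    information).
    """
    poly = (freqs > 0) & (freqs < 1)
    use = poly & (row != MISSING)
    L = int(use.sum())
    if L == 0:
        return float("nan")
    p = freqs[use]
    e_hom = float(np.sum(1.0 - 2.0 * p * (1.0 - p)))
    o_hom = int((row[use] != 1).sum())
    denom = L - e_hom
    if denom <= 0:
        return float("nan")
    return (o_hom - e_hom) / denom


def colony_metrics(
    colony: ColonyPanel,
    alpha: float = 0.05,
    low_maf_cut: float = 0.05,
    hwe_include_monomorphic: bool = False,
) -> ColonyMetrics:
    """Aggregate the per-marker / per-individual statistics for one colony.

    Monomorphic markers contribute MAF = 0 to the mean MAF but are excluded
    from the HWE-failure denominator by default (they cannot fail HWE).
    """
    g = colony.genotypes
    if g.n_samples < 2:
        raise ValueError("need at least 2 samples")
    calls = g.calls
    mafs = np.array([minor_allele_freq(calls[:, j]) for j in range(g.n_markers)])
    informative = ~np.isnan(mafs)
    n_excluded = int((~informative).sum())
    if n_excluded:
        logger.info("%s: %d all-missing markers excluded", colony.colony_id, n_excluded)
    mean_maf = float(np.mean(mafs[informative]))
    pct_low_maf = 100.0 * float(np.mean(mafs[informative] < low_maf_cut))

    mean_het = observed_heterozygosity(g)

    poly = informative & (mafs > 0)
    hwe_cols = informative if hwe_include_monomorphic else poly
    n_fail = 0
    n_tested = 0
    for j in np.flatnonzero(hwe_cols):
        p = hwe_exact_test(*genotype_counts(calls[:, j]))
        n_tested += 1
        n_fail += p < alpha
    pct_fail_hwe = 100.0 * n_fail / n_tested if n_tested else 0.0

    freqs = allele_b_freqs(g)
    fvals = np.array([inbreeding_coefficient(calls[i], freqs) for i in range(g.n_samples)])
    ok = ~np.isnan(fvals)
    if not ok.all():
        logger.info(
            "%s: %d individuals with undefined F excluded", colony.colony_id, int((~ok).sum())
        )
    mean_f_pct = 100.0 * float(np.mean(fvals[ok])) if ok.any() else float("nan")

    return ColonyMetrics(
        colony_id=colony.colony_id,
        mean_maf=mean_maf,
        mean_het=mean_het,
        pct_low_maf=pct_low_maf,
        pct_fail_hwe=pct_fail_hwe,
        mean_inbreeding_coef_pct=mean_f_pct,
        n_samples=g.n_samples,
        n_markers=g.n_markers,
    )


def classify_suitability(m: ColonyMetrics, structured: bool = False) -> SuitabilityVerdict:
    """Apply the suitability cut-offs.

    Heterozygosity below 5% marks a colony as almost inbred; 5-10% as
    low-heterozygosity; mean F above 20% (or 10-20%) flags inbreeding.
    A colony is usable for mapping when none of {almost_inbred,
    low_het_5_10, high_inbreeding_gt20} applies.
    """
    flags: set[str] = set()
    if m.mean_het < 0.05:
        flags.add("almost_inbred")
    elif m.mean_het < 0.10:
        flags.add("low_het_5_10")
    if m.mean_inbreeding_coef_pct > 20:
        flags.add("high_inbreeding_gt20")
    elif m.mean_inbreeding_coef_pct > 10:
        flags.add("elevated_inbreeding_gt10")
    if structured:
        flags.add("structured")
    usable = not flags & {"almost_inbred", "low_het_5_10", "high_inbreeding_gt20"}
    return SuitabilityVerdict(flags=flags, usable_for_mapping=usable)
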