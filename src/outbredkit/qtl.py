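"""Association scans: single-marker ANOVA, conditional scans,
founder-dosage (haplotype) scans, region-wide permutation thresholds, and
the multi-colony shared-founder-effect partial F test.

Traits are rank-transformed to Gaussian deviates within colony and
standardized; covariates pass a one-way ANOVA screen (p < 0.01) before
entering the base model.  Every scan reports logP (the negative base-10
logarithm of a partial F-test p-value, capped at 300) and the variance
explained (partial R^2) per test position.  Region-wide 5% significance is
the 95th percentile of the per-permutation maximum logP over permuted
traits (permuted within colony, covariates staying attached to samples).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MISSING, GenotypeMatrix, PhenotypeTable
from .mosaic import MosaicPosterior

logger = logging.getLogger(__name__)

LOGP_CAP = 300.0


@dataclass
class TraitModel:
    samples: list[str]
    y: np.ndarray                      # transformed trait, mean 0 sd 1 within colony
    covariates: np.ndarray             # n x p design (no intercept column)
    covariate_names: list[str]
    colony: np.ndarray                 # colony label per sample


@dataclass
class ScanResult:
    positions: list[str]               # marker ids or interval labels
    logp: np.ndarray
    df: list[tuple[int, int]]
    variance_explained: np.ndarray
    threshold_logp: float | None = None
    skipped: list[str] = field(default_factory=list)

    @property
    def peak_index(self) -> int:
        return int(np.nanargmax(self.logp))


def rank_inverse_normal(x: np.ndarray) -> np.ndarray:
    """Rank-based Gaussian deviates (average ranks for ties), then
    standardized to mean 0, sd 1."""
    x = np.asarray(x, dtype=float)
    r = stats.rankdata(x, method="average")
    z = stats.norm.ppf((r - 0.5) / len(x))
    z = z - z.mean()
    sd = z.std()
    return z / sd if sd > 0 else z


def _covariate_anova_p(y: np.ndarray, cov: pd.Series) -> float:
    """One-way ANOVA p for a categorical covariate; regression F (1 df) for
    a continuous one."""
    if cov.dtype.kind in "OUSb" or cov.nunique() <= min(10, max(2, len(cov) // 10)):
        groups = [y[(cov == lv).to_numpy()] for lv in cov.unique()]
        groups = [g for g in groups if len(g) > 0]
        if len(groups) < 2:
            return 1.0
        return float(stats.f_oneway(*groups).pvalue)
    x = cov.to_numpy(dtype=float)
    if np.std(x) == 0:
        return 1.0
    res = stats.linregress(x, y)
    return float(res.pvalue)


def prepare_trait(
    pheno: PhenotypeTable,
    trait: str,
    covariates: Sequence[str] = (),
    colony_col: str | None = None,
    alpha: float = 0.01,
) -> TraitModel:
    """Transform a raw trait and screen covariates.

    The trait is rank-inverse-normal transformed within colony; covariates
    whose one-way ANOVA p-value is below ``alpha`` are retained
    (categoricals enter as dummy columns, numerics standardized).
    """
    df = pheno.data
    keep = df[trait].notna()
    if int(keep.sum()) < 20:
        raise ValueError("need at least 20 phenotyped samples")
    df = df.loc[keep]
    colony = (
        df[colony_col].astype(str).to_numpy()
        if colony_col is not None
        else np.array(["_all"] * len(df))
    )
    y = np.empty(len(df))
    for c in np.unique(colony):
        sel = colony == c
        y[sel] = rank_inverse_normal(df[trait].to_numpy(dtype=float)[sel])

    retained: list[str] = []
    blocks: list[np.ndarray] = []
    for cov in covariates:
        p = _covariate_anova_p(y, df[cov])
        if p < alpha:
            retained.append(cov)
            s = df[cov]
            if s.dtype.kind in "OUSb":
                dummies = pd.get_dummies(s.astype(str), drop_first=True)
                blocks.append(dummies.to_numpy(dtype=float))
            else:
                x = s.to_numpy(dtype=float)
                blocks.append(((x - x.mean()) / (x.std() or 1.0))[:, None])
    X = np.hstack(blocks) if blocks else np.empty((len(df), 0))
    return TraitModel(
        samples=list(df.index.astype(str)),
        y=y,
        covariates=X,
        covariate_names=retained,
        colony=colony,
    )


# ---------------------------------------------------------------------------
# Partial F machinery
# ---------------------------------------------------------------------------

def _rss_multi(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, int]:
    """Residual sums of squares of Y's columns under design X, plus rank."""
    if X.shape[1] == 0:
        return (Y**2).sum(axis=0), 0
    beta, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return (resid**2).sum(axis=0), int(rank)


def _partial_f_logp(
    X0: np.ndarray, X1: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    """logP and partial R^2 of the nested comparison X0 vs X1 for each
    column of Y.  Returns (logp, varexp, (df1, df2))."""
    n = Y.shape[0]
    rss0, rank0 = _rss_multi(X0, Y)
    rss1, rank1 = _rss_multi(X1, Y)
    df1 = rank1 - rank0
    df2 = n - rank1
    if df1 <= 0:
        # the added term contributes nothing beyond the null design
        return np.zeros(Y.shape[1]), np.zeros(Y.shape[1]), (df1, df2)
    if df2 <= 0:
        return np.full(Y.shape[1], np.nan), np.full(Y.shape[1], np.nan), (df1, df2)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss0 - rss1) / df1) / (rss1 / df2)
        f = np.clip(f, 0.0, None)
        logp = -stats.f.logsf(f, df1, df2) / np.log(10)
        varexp = np.where(rss0 > 0, (rss0 - rss1) / rss0, np.nan)
    logp = np.where(np.isfinite(logp), np.minimum(logp, LOGP_CAP), LOGP_CAP)
    return logp, np.clip(varexp, 0.0, 1.0), (df1, df2)


def _with_intercept(X: np.ndarray) -> np.ndarray:
    return np.hstack([np.ones((X.shape[0], 1)), X])


def _genotype_dummies(col: np.ndarray) -> np.ndarray | None:
    """Dummy columns for the genotype factor (reference = lowest level);
    None when fewer than two levels are present."""
    levels = np.unique(col)
    if len(levels) < 2:
        return None
    return np.column_stack([(col == lv).astype(float) for lv in levels[1:]])


def single_marker_scan(
    t: TraitModel,
    g: GenotypeMatrix,
    Y: np.ndarray | None = None,
    extra_covariates: np.ndarray | None = None,
) -> ScanResult:
    """Per-marker ANOVA: F test of the genotype factor added to the
    covariate-only model.

    Samples are matched by id; per-marker missing genotypes drop those
    samples from that marker's test.  ``Y`` (n x C) substitutes trait
    columns for permutation use; the returned arrays then refer to Y's
    last column.
    """
    idx = [g.samples.index(s) for s in t.samples]
    calls = g.calls[idx, :]
    Yb = t.y[:, None] if Y is None else Y
    base = t.covariates
    if extra_covariates is not None:
        base = np.hstack([base, extra_covariates])
    X0 = _with_intercept(base)
    m = g.n_markers
    logp = np.full((m, Yb.shape[1]), np.nan)
    varexp = np.full((m, Yb.shape[1]), np.nan)
    dfs: list[tuple[int, int]] = []
    skipped: list[str] = []
    ids = list(g.markers.marker_ids)
    for j in range(m):
        col = calls[:, j]
        ok = col != MISSING
        dummies = _genotype_dummies(col[ok])
        if dummies is None:
            dfs.append((0, 0))
            skipped.append(ids[j])
            continue
        X0j = X0[ok]
        X1j = np.hstack([X0j, dummies])
        lp, ve, df = _partial_f_logp(X0j, X1j, Yb[ok])
        logp[j], varexp[j] = lp, ve
        dfs.append(df)
    return ScanResult(ids, logp[:, -1], dfs, varexp[:, -1]) if Y is None else ScanResult(
        ids, logp, dfs, varexp
    )


def conditional_scan(
    t: TraitModel, g: GenotypeMatrix, conditioning_marker: str, Y: np.ndarray | None = None
) -> ScanResult:
    """Single-marker scan with the conditioning marker's genotype factor
    added to the covariates."""
    jc = int(np.flatnonzero(g.markers.marker_ids == conditioning_marker)[0])
    idx = [g.samples.index(s) for s in t.samples]
    col = g.calls[idx, jc].astype(float)
    col[col == MISSING] = np.nan
    # missing conditioning genotypes: mean-filled dummies keep sample count
    dummies = _genotype_dummies(np.nan_to_num(col, nan=-9).astype(int))
    if dummies is None:
        raise ValueError("conditioning marker is monomorphic")
    return single_marker_scan(t, g, Y=Y, extra_covariates=dummies)


def haplotype_scan(
    t: TraitModel,
    posteriors: list[MosaicPosterior],
    Y: np.ndarray | None = None,
    extra_covariates: np.ndarray | None = None,
) -> ScanResult:
    """Founder-dosage regression at every marker interval.

    The expected dosage of each founder (from the pair posteriors) enters
    as S regression columns, one dropped for identifiability; the partial
    F against the covariate-only model is reported.  Rank-deficient
    intervals (no dosage variation beyond the base model) are skipped.
    """
    by_sample = {p.sample: p for p in posteriors}
    dosages = np.stack(
        [by_sample[s].founder_dosages() for s in t.samples]
    )  # n x m x S
    Yb = t.y[:, None] if Y is None else Y
    base = t.covariates
    if extra_covariates is not None:
        base = np.hstack([base, extra_covariates])
    X0 = _with_intercept(base)
    n, m, S = dosages.shape
    rank0 = np.linalg.matrix_rank(X0)
    logp = np.full((m, Yb.shape[1]), np.nan)
    varexp = np.full((m, Yb.shape[1]), np.nan)
    dfs: list[tuple[int, int]] = []
    skipped: list[str] = []
    for j in range(m):
        D = dosages[:, j, :-1]  # drop last founder column
        X1 = np.hstack([X0, D])
        if np.linalg.matrix_rank(X1) <= rank0:
            dfs.append((0, 0))
            skipped.append(str(j))
            logger.info("interval %d skipped: degenerate founder-dosage design", j)
            continue
        lp, ve, df = _partial_f_logp(X0, X1, Yb)
        logp[j], varexp[j] = lp, ve
        dfs.append(df)
    labels = [str(j) for j in range(m)]
    if Y is None:
        return ScanResult(labels, logp[:, -1], dfs, varexp[:, -1], skipped=skipped)
    return ScanResult(labels, logp, dfs, varexp, skipped=skipped)


# ---------------------------------------------------------------------------
# Permutation thresholds
# ---------------------------------------------------------------------------

def permuted_traits(t: TraitModel, n_perm: int, seed: int) -> np.ndarray:
    """n x n_perm matrix of within-colony permutations of the trait;
    covariates stay attached to samples."""
    rng = np.random.default_rng(seed)
    Y = np.empty((len(t.y), n_perm))
    for c in np.unique(t.colony):
        sel = np.flatnonzero(t.colony == c)
        for k in range(n_perm):
            Y[sel, k] = t.y[sel[rng.permutation(len(sel))]]
    return Y


def permutation_threshold(
    multi_scan: Callable[[np.ndarray], ScanResult],
    t: TraitModel,
    n_perm: int = 1000,
    seed: int = 0,
    quantile: float = 0.95,
) -> float:
    """Region-wide significance threshold.

    ``multi_scan`` maps an n x C matrix of trait columns to a ScanResult
    whose ``logp`` is (markers x C); the threshold is the ``quantile`` of
    the per-column maximum logP over ``n_perm`` within-colony permutations.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    Y = permuted_traits(t, n_perm, seed)
    res = multi_scan(Y)
    maxes = np.nanmax(res.logp, axis=0)
    return float(np.quantile(maxes, quantile))


# ---------------------------------------------------------------------------
# Shared-founder-effect partial F test
# ---------------------------------------------------------------------------

def shared_effect_test(
    traits: list[TraitModel],
    posteriors: list[list[MosaicPosterior]],
    interval: int | None = None,
) -> tuple[float, int]:
    """Test whether one set of founder effects fits all colonies.

    Null model: covariates + colony + shared founder dosages; full model:
    covariates + colony + colony-specific founder dosages.  Returns the
    partial-F p-value and the peak interval used (argmax of the pooled
    haplotype scan when ``interval`` is None).  Non-rejection supports
    identical QTL alleles segregating in every colony.
    """
    if len(traits) < 2:
        raise ValueError("need >= 2 colonies")
    n_colonies = len(traits)
    ys, dosage_blocks, cov_blocks, colony_labels = [], [], [], []
    for c, (t, ps) in enumerate(zip(traits, posteriors)):
        by_sample = {p.sample: p for p in ps}
        D = np.stack([by_sample[s].founder_dosages() for s in t.samples])
        ys.append(t.y)
        dosage_blocks.append(D)
        cov_blocks.append(t.covariates)
        colony_labels.append(np.full(len(t.y), c))
    y = np.concatenate(ys)
    colony = np.concatenate(colony_labels)
    n = len(y)
    # block-diagonal covariates (colonies may retain different covariates)
    p_tot = sum(b.shape[1] for b in cov_blocks)
    C = np.zeros((n, p_tot))
    off_r = off_c = 0
    for b in cov_blocks:
        C[off_r : off_r + b.shape[0], off_c : off_c + b.shape[1]] = b
        off_r += b.shape[0]
        off_c += b.shape[1]
    colony_dummies = np.column_stack(
        [(colony == c).astype(float) for c in range(1, n_colonies)]
    )
    base = _with_intercept(np.hstack([C, colony_dummies]))

    D_all = np.concatenate(dosage_blocks)  # n x m x S
    if interval is None:
        # pooled haplotype scan with colony in the base model
        m = D_all.shape[1]
        best, best_lp = 0, -np.inf
        rank0 = np.linalg.matrix_rank(base)
        for j in range(m):
            X1 = np.hstack([base, D_all[:, j, :-1]])
            if np.linalg.matrix_rank(X1) <= rank0:
                continue
            lp, _, _ = _partial_f_logp(base, X1, y[:, None])
            if lp[0] > best_lp:
                best, best_lp = j, lp[0]
        interval = best

    Dj = D_all[:, interval, :-1]  # shared dosages, one founder dropped
    X_null = np.hstack([base, Dj])
    per_colony = np.hstack(
        [Dj * (colony == c).astype(float)[:, None] for c in range(n_colonies)]
    )
    X_full = np.hstack([base, per_colony])
    rss_null, rank_null = _rss_multi(X_null, y[:, None])
    rss_full, rank_full = _rss_multi(X_full, y[:, None])
    df1 = rank_full - rank_null
    df2 = n - rank_full
    if df1 <= 0 or df2 <= 0:
        return float("nan"), interval
    f = ((rss_null[0] - rss_full[0]) / df1) / (rss_full[0] / df2)
    p = float(stats.f.sf(max(f, 0.0), df1, df2))
    return p, interval
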