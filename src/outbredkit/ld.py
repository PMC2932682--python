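"""Linkage disequilibrium: pairwise r², the LD decay radius, and
confidence-interval haplotype blocks.

r² is the squared Pearson correlation of genotype dosages over
pairwise-complete samples (composite/genotypic r²; no phasing needed for
unphased colony data).  The decay radius is the physical separation at
which the distance-binned, isotonically smoothed mean r² first drops below
0.5.  Blocks follow the confidence-interval rule used in human LD studies:
pairs are classified by a likelihood-based CI on |D'| (strong LD when the
CI lies within [0.70, 1] with upper bound >= 0.98; strong recombination
when the upper bound < 0.90), and maximal marker runs in which >= 95% of
informative pairs are in strong LD form blocks, assigned greedily longest
first without overlap.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .genotypes import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class DecayProfile:
    bin_mid_bp: np.ndarray
    mean_r2: np.ndarray          # raw binned means
    smoothed_r2: np.ndarray      # isotonic non-increasing fit
    n_pairs: np.ndarray
    radius_bp: float             # NaN when undefined; see status
    status: str                  # "ok" | "gt_span" | "lt_first_bin" | "insufficient"


@dataclass
class HaplotypeBlock:
    chromosome: str
    start_bp: int
    end_bp: int
    n_markers: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


# ---------------------------------------------------------------------------
# r² and decay radius
# ---------------------------------------------------------------------------

def pairwise_r2(col_i: np.ndarray, col_j: np.ndarray) -> float:
    """Squared dosage correlation over pairwise-complete samples.

    NaN when fewer than two complete pairs remain or either marker is
    monomorphic within the complete subset.
    """
    ok = (col_i != MISSING) & (col_j != MISSING)
    if ok.sum() < 2:
        return float("nan")
    x = col_i[ok].astype(float)
    y = col_j[ok].astype(float)
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_pairs(g: GenotypeMatrix, max_dist_bp: int | None = None) -> pd.DataFrame:
    """All within-chromosome marker pairs with defined r².

    Returns columns marker_i, marker_j, distance_bp, r2.
    """
    chroms = g.markers.chromosomes
    pos = g.markers.positions_bp
    ids = g.markers.marker_ids
    rows = []
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        for a, b in itertools.combinations(idx, 2):
            d = int(abs(pos[b] - pos[a]))
            if max_dist_bp is not None and d > max_dist_bp:
                continue
            r2 = pairwise_r2(g.calls[:, a], g.calls[:, b])
            if np.isnan(r2):
                continue
            rows.append((ids[a], ids[b], d, r2))
    return pd.DataFrame(rows, columns=["marker_i", "marker_j", "distance_bp", "r2"])


def ld_decay_radius(
    pairs: pd.DataFrame,
    bin_width_bp: int = 100_000,
    min_pairs_per_bin: int = 10,
    threshold: float = 0.5,
) -> DecayProfile:
    """Distance-binned decay curve and the 0.5-crossing radius.

    Bins of ``bin_width_bp`` are formed from zero; bins with fewer than
    ``min_pairs_per_bin`` pairs are dropped.  An isotonic (non-increasing)
    regression weighted by pair counts smooths the binned means before the
    crossing is located by linear interpolation between bin midpoints.
    """
    empty = DecayProfile(
        np.array([]), np.array([]), np.array([]), np.array([], dtype=int),
        float("nan"), "insufficient",
    )
    if len(pairs) == 0:
        return empty
    d = pairs["distance_bp"].to_numpy()
    r2 = pairs["r2"].to_numpy()
    which = (d // bin_width_bp).astype(int)
    mids, means, counts = [], [], []
    for b in np.unique(which):
        sel = which == b
        if sel.sum() < min_pairs_per_bin:
            continue
        mids.append((b + 0.5) * bin_width_bp)
        means.append(float(r2[sel].mean()))
        counts.append(int(sel.sum()))
    if len(mids) < 2:
        return empty
    mids_a = np.asarray(mids)
    means_a = np.asarray(means)
    counts_a = np.asarray(counts)
    iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
    smooth = iso.fit_transform(mids_a, means_a, sample_weight=counts_a)

    if smooth[0] < threshold:
        return DecayProfile(mids_a, means_a, smooth, counts_a, float("nan"), "lt_first_bin")
    if smooth[-1] >= threshold:
        return DecayProfile(mids_a, means_a, smooth, counts_a, float("nan"), "gt_span")
    k = int(np.argmax(smooth < threshold))  # first bin below threshold
    x0, x1 = mids_a[k - 1], mids_a[k]
    y0, y1 = smooth[k - 1], smooth[k]
    radius = x0 + (y0 - threshold) / (y0 - y1) * (x1 - x0)
    return DecayProfile(mids_a, means_a, smooth, counts_a, float(radius), "ok")


# ---------------------------------------------------------------------------
# Two-locus haplotype EM, D' and its likelihood CI
# ---------------------------------------------------------------------------

def _pair_table(col_i: np.ndarray, col_j: np.ndarray) -> np.ndarray:
    """3x3 genotype-pair counts over complete samples."""
    ok = (col_i != MISSING) & (col_j != MISSING)
    t = np.zeros((3, 3), dtype=int)
    for a, b in zip(col_i[ok], col_j[ok]):
        t[a, b] += 1
    return t


def _em_haplotypes(table: np.ndarray, max_iter: int = 50, tol: float = 1e-8
                   ) -> tuple[np.ndarray, float]:
    """EM for two-SNP haplotype frequencies from unphased genotype counts.

    Haplotype order: (11, 10, 01, 00) where 1 = allele_b at that locus.
    Returns (frequencies, log-likelihood).  Initialized at linkage
    equilibrium; 50 iterations or delta log-likelihood < 1e-8.
    """
    n = table.sum()
    if n == 0:
        return np.full(4, 0.25), 0.0
    # allele-b frequencies
    p1 = (table.sum(axis=1) @ np.array([0, 1, 2])) / (2 * n)
    p2 = (table.sum(axis=0) @ np.array([0, 1, 2])) / (2 * n)
    h = np.array([p1 * p2, p1 * (1 - p2), (1 - p1) * p2, (1 - p1) * (1 - p2)])
    h = np.clip(h, 1e-12, None)
    h /= h.sum()
    ll_prev = -np.inf
    dh = table[1, 1]  # double heterozygotes: ambiguous phase
    for _ in range(max_iter):
        # expected counts of each haplotype among the 2n gametes
        c = np.zeros(4)
        # unambiguous contributions
        # genotype (g1, g2): haplotypes determined unless g1 == g2 == 1
        for g1 in range(3):
            for g2 in range(3):
                cnt = table[g1, g2]
                if cnt == 0 or (g1 == 1 and g2 == 1):
                    continue
                # each individual contributes 2 haplotypes; enumerate them
                h1s = [1, 1] if g1 == 2 else [0, 0] if g1 == 0 else [1, 0]
                h2s = [1, 1] if g2 == 2 else [0, 0] if g2 == 0 else [1, 0]
                if g1 == 1:
                    # het at locus 1, hom at locus 2: haplotypes (1, a2), (0, a2)
                    a2 = h2s[0]
                    c[_hidx(1, a2)] += cnt
                    c[_hidx(0, a2)] += cnt
                elif g2 == 1:
                    a1 = h1s[0]
                    c[_hidx(a1, 1)] += cnt
                    c[_hidx(a1, 0)] += cnt
                else:
                    c[_hidx(h1s[0], h2s[0])] += 2 * cnt
        if dh:
            # phase 1: (11, 00); phase 2: (10, 01)
            p_cis = h[0] * h[3]
            p_trans = h[1] * h[2]
            tot = p_cis + p_trans
            w = 0.5 if tot == 0 else p_cis / tot
            c[0] += dh * w
            c[3] += dh * w
            c[1] += dh * (1 - w)
            c[2] += dh * (1 - w)
        h = c / (2 * n)
        h = np.clip(h, 1e-12, None)
        h /= h.sum()
        ll = _table_loglik(table, h)
        if abs(ll - ll_prev) < tol:
            break
        ll_prev = ll
    return h, _table_loglik(table, h)


def _hidx(x1: int, x2: int) -> int:
    """Index into haplotype order (11, 10, 01, 00)."""
    return {(1, 1): 0, (1, 0): 1, (0, 1): 2, (0, 0): 3}[(x1, x2)]


def _table_loglik(table: np.ndarray, h: np.ndarray) -> float:
    """Log-likelihood of the 3x3 genotype-pair table under haplotype freqs
    (order 11, 10, 01, 00), assuming random union of gametes."""
    f11, f10, f01, f00 = h
    p = np.empty((3, 3))
    p[0, 0] = f00 * f00
    p[0, 1] = 2 * f00 * f01
    p[0, 2] = f01 * f01
    p[1, 0] = 2 * f00 * f10
    p[1, 1] = 2 * (f00 * f11 + f01 * f10)
    p[1, 2] = 2 * f01 * f11
    p[2, 0] = f10 * f10
    p[2, 1] = 2 * f10 * f11
    p[2, 2] = f11 * f11
    p = np.clip(p, 1e-300, None)
    return float((table * np.log(p)).sum())


def d_prime(h: np.ndarray) -> float:
    """Normalized |D'| from haplotype frequencies (order 11, 10, 01, 00)."""
    p1 = h[0] + h[1]
    p2 = h[0] + h[2]
    D = h[0] - p1 * p2
    if D >= 0:
        dmax = min(p1 * (1 - p2), (1 - p1) * p2)
    else:
        dmax = min(p1 * p2, (1 - p1) * (1 - p2))
    if dmax <= 0:
        return float("nan")
    return float(abs(D) / dmax)


def d_prime_ci(
    col_i: np.ndarray, col_j: np.ndarray, grid_size: int = 101
) -> tuple[float, float, float]:
    """(|D'| MLE, CI lower, CI upper) by likelihood profiling.

    Allele frequencies are fixed at their sample estimates; the likelihood
    of the genotype-pair table is evaluated on a ``grid_size``-point grid
    of |D'| in [0, 1] (with the sign of the EM MLE), normalized into a
    distribution whose 5th and 95th cumulative points give the bounds.
    """
    table = _pair_table(col_i, col_j)
    n = table.sum()
    if n == 0:
        return float("nan"), float("nan"), float("nan")
    h_mle, _ = _em_haplotypes(table)
    p1 = h_mle[0] + h_mle[1]
    p2 = h_mle[0] + h_mle[2]
    if not (0 < p1 < 1) or not (0 < p2 < 1):
        return float("nan"), float("nan"), float("nan")
    D_mle = h_mle[0] - p1 * p2
    sign = 1.0 if D_mle >= 0 else -1.0
    dmax = min(p1 * (1 - p2), (1 - p1) * p2) if sign > 0 else min(p1 * p2, (1 - p1) * (1 - p2))
    grid = np.linspace(0.0, 1.0, grid_size)
    lls = np.empty(grid_size)
    for k, dp in enumerate(grid):
        D = sign * dp * dmax
        h = np.array(
            [
                p1 * p2 + D,
                p1 * (1 - p2) - D,
                (1 - p1) * p2 - D,
                (1 - p1) * (1 - p2) + D,
            ]
        )
        h = np.clip(h, 1e-12, None)
        h /= h.sum()
        lls[k] = _table_loglik(table, h)
    w = np.exp(lls - lls.max())
    cdf = np.cumsum(w) / w.sum()
    lower = float(grid[int(np.argmax(cdf >= 0.05))])
    upper = float(grid[int(np.argmax(cdf >= 0.95))])
    return d_prime(h_mle), lower, upper


# ---------------------------------------------------------------------------
# Confidence-interval blocks
# ---------------------------------------------------------------------------

def classify_pairs(
    g: GenotypeMatrix,
    idx: np.ndarray,
    strong_lower: float = 0.70,
    strong_upper: float = 0.98,
    recomb_upper: float = 0.90,
) -> np.ndarray:
    """Pair classification matrix over markers ``idx``.

    1 = strong LD, -1 = strong recombination, 0 = uninformative.
    """
    m = len(idx)
    cls = np.zeros((m, m), dtype=int)
    for a in range(m):
        for b in range(a + 1, m):
            _, lo, hi = d_prime_ci(g.calls[:, idx[a]], g.calls[:, idx[b]])
            if np.isnan(hi):
                c = 0
            elif lo >= strong_lower and hi >= strong_upper:
                c = 1
            elif hi < recomb_upper:
                c = -1
            else:
                c = 0
            cls[a, b] = cls[b, a] = c
    return cls


def find_blocks(
    g: GenotypeMatrix,
    chromosome: str | None = None,
    strong_fraction: float = 0.95,
    strong_lower: float = 0.70,
    strong_upper: float = 0.98,
    recomb_upper: float = 0.90,
    min_maf: float = 0.0,
) -> list[HaplotypeBlock]:
    """Confidence-interval haplotype blocks on one chromosome (or every
    chromosome when ``chromosome`` is None).

    A candidate window qualifies when at least ``strong_fraction`` of its
    informative pairs are in strong LD (and it contains at least one
    informative pair); accepted windows are taken greedily longest (in bp)
    first, without overlap.
    """
    blocks: list[HaplotypeBlock] = []
    chroms = g.markers.chromosomes
    targets = [chromosome] if chromosome is not None else list(pd.unique(chroms))
    for chrom in targets:
        idx = np.flatnonzero(chroms == chrom)
        if min_maf > 0:
            from .metrics import minor_allele_freq

            idx = np.array(
                [j for j in idx if minor_allele_freq(g.calls[:, j]) >= min_maf], dtype=int
            )
        if len(idx) < 2:
            continue
        pos = g.markers.positions_bp[idx]
        cls = classify_pairs(g, idx, strong_lower, strong_upper, recomb_upper)
        m = len(idx)
        candidates = []
        for a in range(m):
            for b in range(a + 1, m):
                sub = cls[a : b + 1, a : b + 1]
                iu = np.triu_indices(b - a + 1, k=1)
                vals = sub[iu]
                n_inf = int((vals != 0).sum())
                if n_inf == 0:
                    continue
                frac = (vals == 1).sum() / n_inf
                if frac >= strong_fraction:
                    candidates.append((int(pos[b] - pos[a]), a, b))
        candidates.sort(key=lambda t: (-t[0], t[1]))
        used = np.zeros(m, dtype=bool)
        for _, a, b in candidates:
            if used[a : b + 1].any():
                continue
            used[a : b + 1] = True
            blocks.append(
                HaplotypeBlock(
                    chromosome=str(chrom),
                    start_bp=int(pos[a]),
                    end_bp=int(pos[b]),
                    n_markers=b - a + 1,
                )
            )
    blocks.sort(key=lambda b: (b.chromosome, b.start_bp))
    return blocks


def mean_block_length(blocks: list[HaplotypeBlock]) -> tuple[float, float]:
    """Arithmetic mean and (population) sd of block lengths in bp."""
    if not blocks:
        raise ValueError("no blocks")
    lengths = np.array([b.length_bp for b in blocks], dtype=float)
    return float(lengths.mean()), float(lengths.std())


def write_blocks_bed(blocks: list[HaplotypeBlock], path: str) -> None:
    """BED output (0-based half-open, converted from internal 1-based)."""
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(f"{b.chromosome}\t{b.start_bp - 1}\t{b.end_bp}\tn_markers={b.n_markers}\n")
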