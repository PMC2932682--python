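"""Within- and between-colony structure.

Pairwise identity-by-state (IBS) distances, classical multidimensional
scaling, a silhouette-based structure flag, the Weir-Cockerham Fst
estimator (ratio-of-sums across loci), average-linkage colony trees, and a
maximum-likelihood K-ancestral-population admixture model fitted by EM.

The admixture model treats each of an individual's 2 alleles at marker j
as drawn from ancestral population k with probability q_ik, then carrying
allele B with probability p_kj — the standard binomial admixture
likelihood maximized by frequency programs of the FRAPPE/ADMIXTURE family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .genotypes import MISSING, ColonyPanel, GenotypeMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# IBS distances and MDS
# ---------------------------------------------------------------------------

def ibs_distance_matrix(g: GenotypeMatrix) -> np.ndarray:
    """n x n matrix of 1 - (shared alleles / 2) averaged over
    pairwise-complete markers.

    With dosage coding, two genotypes share ``2 - |d_i - d_j|`` alleles, so
    the distance is ``mean(|d_i - d_j|) / 2``.
    """
    if g.n_samples < 2:
        raise ValueError("need at least 2 samples")
    d = g.dosages()
    n = g.n_samples
    out = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(d - d[i])  # NaN where either is missing
        cnt = np.sum(~np.isnan(diff), axis=1)
        if (cnt == 0).any():
            j = int(np.argmax(cnt == 0))
            raise ValueError(
                f"no complete markers for pair ({g.samples[i]}, {g.samples[j]})"
            )
        out[i] = np.nansum(diff, axis=1) / cnt / 2.0
    out = (out + out.T) / 2.0
    np.fill_diagonal(out, 0.0)
    return out


def mds_coordinates(dist: np.ndarray, dims: int = 2) -> np.ndarray:
    """Classical metric scaling: double-centering + eigendecomposition.

    Coordinates are ordered by eigenvalue (deterministic up to sign);
    non-positive eigenvalues yield zero coordinates.
    """
    n = dist.shape[0]
    if dims >= n:
        raise ValueError("dims must be < n")
    d2 = dist**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:dims]
    vals_o = np.clip(vals[order], 0.0, None)
    coords = vecs[:, order] * np.sqrt(vals_o)
    # sign convention: make the largest-magnitude loading positive
    for k in range(coords.shape[1]):
        col = coords[:, k]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            coords[:, k] = -col
    return coords


def flag_structure(
    coords: np.ndarray,
    threshold: float = 0.40,
    k_range: tuple[int, ...] = (2, 3, 4),
    seed: int = 0,
) -> bool:
    """True when the best k-means silhouette over ``k_range`` exceeds
    ``threshold``.  Degenerate (all-equal) coordinates never flag."""
    if coords.shape[0] < 10:
        raise ValueError("need at least 10 samples")
    if np.allclose(coords, coords[0]):
        return False
    best = -1.0
    # (k-means silhouettes on very low-dimensional noise run high; callers
    # should pass >= 4 MDS dimensions — see detect_structure)
    for k in k_range:
        if k >= coords.shape[0]:
            continue
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(coords)
        if len(np.unique(labels)) < 2:
            continue
        best = max(best, silhouette_score(coords, labels))
    return bool(best > threshold)


def detect_structure(
    g: GenotypeMatrix, threshold: float = 0.40, dims: int = 4, seed: int = 0
) -> bool:
    """End-to-end structure check: IBS distances -> classical MDS on the
    leading ``dims`` axes -> silhouette flag.

    Four dimensions by default: silhouettes of k-means partitions of pure
    noise stay well below 0.40 there, while genuinely clustered colonies
    score far above it.
    """
    dist = ibs_distance_matrix(g)
    coords = mds_coordinates(dist, dims=min(dims, g.n_samples - 1))
    return flag_structure(coords, threshold=threshold, seed=seed)


# ---------------------------------------------------------------------------
# Weir-Cockerham Fst
# ---------------------------------------------------------------------------

@dataclass
class FstResult:
    colony_a: str
    colony_b: str
    theta: float
    n_loci: int


def _wc_components(counts_a, counts_b) -> tuple[float, float, float]:
    """Weir-Cockerham variance components (a, b, c) for one biallelic locus
    and two populations.  ``counts_*`` are (n_hom_a, n_het, n_hom_b)."""
    r = 2
    n_i = np.array([sum(counts_a), sum(counts_b)], dtype=float)
    if (n_i == 0).any():
        return 0.0, 0.0, 0.0
    p_i = np.array(
        [
            (2 * counts_a[2] + counts_a[1]) / (2 * n_i[0]),
            (2 * counts_b[2] + counts_b[1]) / (2 * n_i[1]),
        ]
    )
    h_i = np.array([counts_a[1] / n_i[0], counts_b[1] / n_i[1]])
    n_bar = n_i.mean()
    n_c = (r * n_bar - (n_i**2).sum() / (r * n_bar)) / (r - 1)
    p_bar = (n_i * p_i).sum() / (r * n_bar)
    s2 = (n_i * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar)
    h_bar = (n_i * h_i).sum() / (r * n_bar)
    if n_bar <= 1 or n_c == 0:
        return 0.0, 0.0, 0.0
    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2
    return float(a), float(b), float(c)


def pairwise_fst(a: ColonyPanel, b: ColonyPanel) -> FstResult:
    """Weir-Cockerham theta for two colonies, combining loci as the ratio
    of summed variance components (not the mean of per-locus ratios)."""
    ga, gb = a.genotypes, b.genotypes
    shared = [m for m in ga.markers.marker_ids if m in set(gb.markers.marker_ids)]
    if not shared:
        raise ValueError("no shared markers")
    ia = {m: i for i, m in enumerate(ga.markers.marker_ids)}
    ib = {m: i for i, m in enumerate(gb.markers.marker_ids)}
    num = 0.0
    den = 0.0
    n_used = 0
    for m in shared:
        ca = ga.calls[:, ia[m]]
        cb = gb.calls[:, ib[m]]
        counts_a = ((ca == 0).sum(), (ca == 1).sum(), (ca == 2).sum())
        counts_b = ((cb == 0).sum(), (cb == 1).sum(), (cb == 2).sum())
        tot_b = 2 * (counts_a[2] + counts_b[2]) + counts_a[1] + counts_b[1]
        tot = 2 * (sum(counts_a) + sum(counts_b))
        if tot == 0 or tot_b == 0 or tot_b == tot:
            continue  # monomorphic overall: no information
        va, vb, vc = _wc_components(counts_a, counts_b)
        num += va
        den += va + vb + vc
        n_used += 1
    if n_used == 0:
        raise ValueError("no shared polymorphic markers")
    theta = num / den if den != 0 else 0.0
    return FstResult(a.colony_id, b.colony_id, float(theta), n_used)


def fst_matrix(colonies: list[ColonyPanel]) -> pd.DataFrame:
    ids = [c.colony_id for c in colonies]
    m = pd.DataFrame(0.0, index=ids, columns=ids)
    for i in range(len(colonies)):
        for j in range(i + 1, len(colonies)):
            th = pairwise_fst(colonies[i], colonies[j]).theta
            m.iloc[i, j] = m.iloc[j, i] = th
    return m


# ---------------------------------------------------------------------------
# Colony tree
# ---------------------------------------------------------------------------

def colony_tree(fst: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Average-linkage agglomerative clustering of the Fst matrix.

    Negative entries are clamped to zero; colonies are processed in
    lexicographic id order so ties break deterministically.  Returns the
    scipy linkage matrix and the leaf order used.
    """
    if fst.shape[0] < 3:
        raise ValueError("need at least 3 colonies")
    ids = sorted(fst.index)
    m = fst.loc[ids, ids].to_numpy().clip(min=0.0)
    iu = np.triu_indices(len(ids), k=1)
    Z = hierarchy.linkage(m[iu], method="average")
    return Z, ids


def tree_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix to Newick with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_height) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            length = parent_height
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{max(length, 0.0):.6g}"

    s = rec(tree, tree.dist)
    # root has no parent: strip its trailing length
    s = s.rsplit(":", 1)[0]
    return s + ";"


# ---------------------------------------------------------------------------
# Admixture EM
# ---------------------------------------------------------------------------

class AdmixtureEM(BaseEstimator):
    """Maximum-likelihood K-ancestral-population admixture model.

    Each individual i has ancestry proportions q_i (summing to 1) and each
    ancestral population k has allele-B frequencies p_k.  Genotype dosages
    are binomial(2, sum_k q_ik p_kj).  Fitted by EM with multiple restarts;
    the log-likelihood is non-decreasing within a run and the best restart
    is kept.

    Parameters
    ----------
    K : number of ancestral populations (>= 1).
    max_iter : EM iteration cap per restart (default 10,000).
    tol : stop when the log-likelihood improves by less than this.
    n_restarts : random restarts; best final likelihood wins.
    random_state : seed for the restart initializations.

    Attributes (after ``fit``)
    --------------------------
    Q_ : (n_samples, K) ancestry proportions, rows summing to 1.
    P_ : (K, n_markers) ancestral allele-B frequencies in [1e-6, 1 - 1e-6].
    log_likelihood_ : final log-likelihood.
    log_likelihood_path_ : per-iteration log-likelihoods of the best run.
    """

    def __init__(
        self,
        K: int = 2,
        max_iter: int = 10_000,
        tol: float = 1e-6,
        n_restarts: int = 5,
        random_state: int = 0,
    ):
        self.K = K
        self.max_iter = max_iter
        self.tol = tol
        self.n_restarts = n_restarts
        self.random_state = random_state

    def _validate(self, X) -> np.ndarray:
        if isinstance(X, GenotypeMatrix):
            X = X.calls
        X = np.asarray(X)
        if X.ndim != 2:
            raise ValueError("expected a 2-D genotype array")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.K > X.shape[0]:
            raise ValueError("K exceeds the number of samples")
        if ((X == MISSING).all(axis=1)).any():
            raise ValueError("fully missing sample")
        return X

    def fit(self, X, y=None) -> "AdmixtureEM":
        X = self._validate(X)
        n, m = X.shape
        obs = X != MISSING
        G = np.where(obs, X, 0).astype(float)  # dosage of allele B
        W = obs.astype(float)                  # 2*W alleles observed
        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(max(1, self.n_restarts)):
            Q = rng.dirichlet(np.ones(self.K), size=n)
            P = rng.uniform(0.05, 0.95, size=(self.K, m))
            if self.K == 1:
                Q = np.ones((n, 1))
            lls: list[float] = []
            ll_prev = -np.inf
            for _it in range(self.max_iter):
                theta = np.clip(Q @ P, 1e-9, 1 - 1e-9)  # n x m
                # expected ancestral-origin counts for B and A alleles
                rb = G / theta          # n x m
                ra = (2 * W - G) / (1 - theta)
                # A_ik = sum_j q_ik p_kj * rb_ij ; B_ik likewise for A alleles
                Ab = Q * (rb @ P.T)            # n x K
                Aa = Q * (ra @ (1 - P).T)      # n x K
                Q_new = (Ab + Aa)
                Q_new /= Q_new.sum(axis=1, keepdims=True)
                # P update: expected B-origin counts / total origin counts
                numer = (rb.T @ Q).T * P      # K x m : sum_i rb_ij q_ik p_kj
                denom = numer + (ra.T @ Q).T * (1 - P)
                P_new = np.where(denom > 0, numer / np.clip(denom, 1e-300, None), P)
                P_new = np.clip(P_new, 1e-6, 1 - 1e-6)
                Q = Q_new if self.K > 1 else Q
                P = P_new
                theta = np.clip(Q @ P, 1e-9, 1 - 1e-9)
                ll = float(
                    np.sum(W * (G * np.log(theta) + (2 * W - G) * np.log(1 - theta)))
                )
                lls.append(ll)
                if ll - ll_prev < self.tol and _it > 0:
                    break
                ll_prev = ll
            if best is None or lls[-1] > best[0]:
                best = (lls[-1], Q.copy(), P.copy(), lls)
        assert best is not None
        self.log_likelihood_, self.Q_, self.P_, self.log_likelihood_path_ = best
        self.n_iter_ = len(self.log_likelihood_path_)
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).Q_


def admixture_em(
    g: GenotypeMatrix | np.ndarray,
    K: int,
    seed: int = 0,
    max_iter: int = 10_000,
    n_restarts: int = 5,
    tol: float = 1e-6,
) -> AdmixtureEM:
    """Functional wrapper over :class:`AdmixtureEM`."""
    return AdmixtureEM(
        K=K, max_iter=max_iter, tol=tol, n_restarts=n_restarts, random_state=seed
    ).fit(g)
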