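"""IBS/MDS, structure flagging, Weir-Cockerham Fst, trees, admixture EM."""

import numpy as np
import pytest
from sklearn.base import clone

from outbredkit.genotypes import ColonyPanel
from outbredkit.structure import (
    AdmixtureEM,
    colony_tree,
    detect_structure,
    flag_structure,
    fst_matrix,
    ibs_distance_matrix,
    mds_coordinates,
    pairwise_fst,
    tree_to_newick,
)

from conftest import make_matrix


def hwe_calls(rng, p, n):
    """Equilibrium diploid dosages for allele-B frequencies p."""
    a = (rng.random((n, len(p))) < p).astype(np.int8)
    b = (rng.random((n, len(p))) < p).astype(np.int8)
    return a + b


class TestIbs:
    def test_identical_individuals_zero(self):
        g = make_matrix([[0, 1, 2], [0, 1, 2]])
        d = ibs_distance_matrix(g)
        assert d[0, 1] == 0.0

    def test_opposite_homozygotes_one(self):
        g = make_matrix([[0, 0, 0], [2, 2, 2]])
        assert ibs_distance_matrix(g)[0, 1] == 1.0

    def test_hand_count_one_het_mismatch(self):
        # 10 markers, one hom-vs-het difference: 1 of 20 alleles mismatched
        a = [0] * 10
        b = [1] + [0] * 9
        d = ibs_distance_matrix(make_matrix([a, b]))
        assert d[0, 1] == pytest.approx(0.05)

    def test_invariants(self, bred_colony):
        colony, _ = bred_colony
        d = ibs_distance_matrix(colony.genotypes)
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)
        assert d.min() >= 0 and d.max() <= 1


class TestMds:
    def test_planted_geometry_recovered(self):
        rng = np.random.default_rng(0)
        pts = rng.random((12, 2))
        dist = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        coords = mds_coordinates(dist, dims=2)
        re_dist = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        assert np.allclose(re_dist, dist, atol=1e-6)

    def test_all_equal_distances_degenerate_not_flagged(self):
        n = 12
        d = np.ones((n, n)) - np.eye(n)
        coords = mds_coordinates(d, dims=2)
        assert flag_structure(coords) is False

    def test_two_cluster_silhouette_and_labels(self):
        """MDS of a planted 2-cluster IBS design separates the clusters
        (silhouette > 0.5, >= 95% label agreement)."""
        rng = np.random.default_rng(7)
        p1 = rng.uniform(0.05, 0.95, 120)
        p2 = np.clip(p1 + rng.choice([-0.6, 0.6], 120), 0.02, 0.98)
        g = make_matrix(np.vstack([hwe_calls(rng, p1, 25), hwe_calls(rng, p2, 25)]))
        coords = mds_coordinates(ibs_distance_matrix(g), dims=2)
        from sklearn.cluster import KMeans
        from sklearn.metrics import silhouette_score

        labels = KMeans(2, n_init=10, random_state=0).fit_predict(coords)
        assert silhouette_score(coords, labels) > 0.5
        truth = np.array([0] * 25 + [1] * 25)
        agreement = max((labels == truth).mean(), (labels != truth).mean())
        assert agreement >= 0.95


class TestFlagStructure:
    def test_panmictic_colony_not_flagged(self):
        rng = np.random.default_rng(3)
        g = make_matrix(hwe_calls(rng, rng.uniform(0.1, 0.9, 150), 40))
        assert detect_structure(g, seed=0) is False

    def test_mixture_flagged(self):
        rng = np.random.default_rng(4)
        p1 = rng.uniform(0.05, 0.95, 150)
        p2 = np.clip(p1 + rng.choice([-0.55, 0.55], 150), 0.02, 0.98)
        g = make_matrix(np.vstack([hwe_calls(rng, p1, 20), hwe_calls(rng, p2, 20)]))
        assert detect_structure(g, seed=0) is True

    def test_deterministic_same_seed(self, bred_colony):
        colony, _ = bred_colony
        coords = mds_coordinates(ibs_distance_matrix(colony.genotypes), dims=2)
        assert flag_structure(coords, seed=5) == flag_structure(coords, seed=5)


class TestFst:
    def test_self_comparison_near_zero(self):
        rng = np.random.default_rng(1)
        g = make_matrix(hwe_calls(rng, rng.uniform(0.2, 0.8, 300), 200))
        c = ColonyPanel("a", g)
        th = pairwise_fst(c, ColonyPanel("b", g)).theta
        # WC theta of a sample vs itself is slightly negative, O(1/n)
        assert abs(th) < 2.0 / g.n_samples

    def test_fixed_differences_give_one(self):
        a = ColonyPanel("a", make_matrix(np.zeros((10, 5), dtype=np.int8)))
        b = ColonyPanel("b", make_matrix(np.full((10, 5), 2, dtype=np.int8)))
        assert pairwise_fst(a, b).theta == pytest.approx(1.0)

    def test_hand_evaluated_single_locus(self):
        """One-locus toy with printed genotype counts matches a direct
        evaluation of the variance-component formulas."""
        # colony A: 10/6/4 ; colony B: 2/8/10
        a_calls = np.array([[0]] * 10 + [[1]] * 6 + [[2]] * 4, dtype=np.int8)
        b_calls = np.array([[0]] * 2 + [[1]] * 8 + [[2]] * 10, dtype=np.int8)
        th = pairwise_fst(
            ColonyPanel("a", make_matrix(a_calls)), ColonyPanel("b", make_matrix(b_calls))
        ).theta
        # independent hand evaluation
        n1 = n2 = 20.0
        p1, p2 = (2 * 4 + 6) / 40, (2 * 10 + 8) / 40
        h1, h2 = 6 / 20, 8 / 20
        r, nbar = 2, 20.0
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        assert th == pytest.approx(a / (a + b + c), abs=1e-12)

    def test_theta_grows_with_divergence_time(self, small_founders):
        """Theta increases monotonically with the number of generations two
        colonies have drifted apart."""
        from outbredkit.simulate import SimConfig, breed_colony

        thetas = []
        for G in (5, 30, 90):
            cols = []
            for s in (0, 1):
                cfg = SimConfig(
                    n_founders=4, n_markers=120, region_span_bp=12_000_000,
                    generations=G, census_size=30, seed=100 + 10 * s + G,
                )
                c, _ = breed_colony(small_founders, cfg, colony_id=f"d{s}")
                cols.append(c)
            thetas.append(pairwise_fst(cols[0], cols[1]).theta)
        assert thetas[0] < thetas[1] < thetas[2]


class TestColonyTree:
    def _colonies(self, rng):
        p = rng.uniform(0.2, 0.8, 200)
        near = np.clip(p + rng.normal(0, 0.02, 200), 0.01, 0.99)
        far = np.clip(p + rng.choice([-0.5, 0.5], 200), 0.01, 0.99)
        return [
            ColonyPanel("A", make_matrix(hwe_calls(rng, p, 30))),
            ColonyPanel("B", make_matrix(hwe_calls(rng, near, 30))),
            ColonyPanel("C", make_matrix(hwe_calls(rng, far, 30))),
        ]

    def test_planted_distances_merge_near_pair_first(self):
        rng = np.random.default_rng(9)
        fm = fst_matrix(self._colonies(rng))
        Z, ids = colony_tree(fm)
        first = sorted(ids[int(Z[0, 0])] + ids[int(Z[0, 1])])
        assert first == ["A", "B"]

    def test_identical_colonies_merge_at_zero(self):
        rng = np.random.default_rng(10)
        g = make_matrix(hwe_calls(rng, rng.uniform(0.2, 0.8, 200), 30))
        cols = [ColonyPanel(n, g) for n in ("A", "B", "C")]
        Z, _ = colony_tree(fst_matrix(cols))
        assert np.all(Z[:, 2] < 0.05)

    def test_newick_serialization_valid(self):
        rng = np.random.default_rng(11)
        Z, ids = colony_tree(fst_matrix(self._colonies(rng)))
        nwk = tree_to_newick(Z, ids)
        assert nwk.endswith(";")
        # parses with a standard phylogenetics reader
        from io import StringIO

        from Bio import Phylo

        tree = Phylo.read(StringIO(nwk), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == ["A", "B", "C"]


class TestAdmixtureEM:
    def test_k1_forces_unit_ancestry(self):
        rng = np.random.default_rng(0)
        X = hwe_calls(rng, rng.uniform(0.2, 0.8, 50), 15)
        fit = AdmixtureEM(K=1, n_restarts=1, max_iter=200).fit(X)
        assert np.allclose(fit.Q_, 1.0)

    def test_loglik_monotone_and_invariants(self):
        rng = np.random.default_rng(1)
        X = hwe_calls(rng, rng.uniform(0.1, 0.9, 80), 30)
        fit = AdmixtureEM(K=3, n_restarts=2, max_iter=300, random_state=1).fit(X)
        assert np.all(np.diff(fit.log_likelihood_path_) >= -1e-8)
        assert np.allclose(fit.Q_.sum(axis=1), 1.0, atol=1e-6)
        assert fit.P_.min() >= 1e-6 and fit.P_.max() <= 1 - 1e-6

    def test_two_source_mixture_recovered(self):
        """Ancestry proportions of a 2-source mix (sources near Fst 0.3,
        200 markers) are recovered within 0.1 mean absolute error."""
        rng = np.random.default_rng(2)
        p1 = rng.uniform(0.05, 0.95, 200)
        p2 = np.clip(p1 + rng.choice([-0.5, 0.5], 200) * rng.random(200), 0.02, 0.98)
        q_true = np.concatenate([np.zeros(20), np.ones(20), rng.random(20)])
        P = np.vstack([p1, p2])
        theta = q_true[:, None] * P[1] + (1 - q_true)[:, None] * P[0]
        X = ((rng.random(theta.shape) < theta).astype(np.int8)
             + (rng.random(theta.shape) < theta).astype(np.int8))
        fit = AdmixtureEM(K=2, n_restarts=3, max_iter=2000, random_state=0).fit(X)
        q_hat = fit.Q_[:, 1]
        err = min(
            np.abs(q_hat - q_true).mean(), np.abs((1 - q_hat) - q_true).mean()
        )
        assert err < 0.1

    def test_sklearn_estimator_contract(self):
        est = AdmixtureEM(K=4, max_iter=50)
        params = est.get_params()
        assert params["K"] == 4
        cloned = clone(est)
        assert cloned.get_params() == params
        est.set_params(K=2)
        assert est.K == 2

    def test_k_larger_than_samples_errors(self):
        X = np.zeros((3, 5), dtype=np.int8)
        with pytest.raises(ValueError, match="K exceeds"):
            AdmixtureEM(K=4).fit(X)
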