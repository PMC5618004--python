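"""Fingerprint statistics: Jaccard, NMDS, Procrustes, PERMANOVA, VPR."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import isotonic_regression, minimize
from scipy.spatial import procrustes as scipy_procrustes
from scipy.spatial.distance import pdist, squareform

from pentaweb import fingerprints as fp


def band_frame(rows, prefix="b"):
    arr = np.asarray(rows)
    return pd.DataFrame(arr, index=[f"s{i}" for i in range(arr.shape[0])],
                        columns=[f"{prefix}{j}" for j in range(arr.shape[1])])


def random_binary(rng, n, m):
    vals = (rng.random((n, m)) < 0.5).astype(int)
    vals[vals.sum(axis=1) == 0, 0] = 1
    return vals


class TestBandMatrix:
    def test_rejects_nonbinary_and_empty(self):
        with pytest.raises(ValueError, match="non-binary"):
            fp.BandMatrix(band_frame([[0, 2], [1, 0]]))
        with pytest.raises(ValueError, match="no bands"):
            fp.BandMatrix(band_frame([[0, 0], [1, 0]]))

    def test_metadata_defaults_filled(self):
        bm = fp.BandMatrix(band_frame([[1, 0], [0, 1]]))
        assert list(bm.metadata.columns) == list(fp.METADATA_COLUMNS)
        assert (bm.metadata["glucose_x"] == 0.0).all()


class TestJaccard:
    def test_pair_values(self):
        dm = fp.jaccard_distances(band_frame([[1, 1, 0], [1, 0, 1]]))
        assert dm[0, 1] == pytest.approx(1 - 1 / 3, rel=1e-12)

    def test_identical_and_disjoint(self):
        dm = fp.jaccard_distances(band_frame([[1, 1, 0], [1, 1, 0], [0, 0, 1]]))
        assert dm[0, 1] == 0.0
        assert dm[0, 2] == 1.0

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError):
            fp.jaccard_distances(np.array([[1, 0], [0, 0]]))

    def test_metric_axioms(self, rng):
        vals = random_binary(rng, 10, 15)
        d = fp.jaccard_distances(vals).data
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)
        assert np.all(d >= 0) and np.all(d <= 1)
        for i, j, k in itertools.permutations(range(10), 3):
            assert d[i, k] <= d[i, j] + d[j, k] + 1e-12


def oracle_stress(dist, k, seed, n_starts=30, maxiter=2000):
    """Independent stress-1 minimizer: L-BFGS on coordinates with the
    monotone fit recomputed at every evaluation."""
    n = dist.shape[0]
    iu = np.triu_indices(n, k=1)
    delta = dist[iu]

    def stress(flat):
        d = pdist(flat.reshape(n, k))
        order = np.lexsort((d, delta))
        dhat = np.empty_like(d)
        dhat[order] = isotonic_regression(d[order]).x
        denom = np.sum(d ** 2)
        return math.sqrt(np.sum((d - dhat) ** 2) / denom) if denom else 0.0

    rng = np.random.default_rng(seed)
    best = math.inf
    for _ in range(n_starts):
        res = minimize(stress, rng.standard_normal(n * k), method="L-BFGS-B",
                       options={"maxiter": maxiter})
        best = min(best, res.fun)
    return best


class TestNmds:
    def test_perfectly_embeddable_configurations(self):
        # collinear points with exact Euclidean distances
        pts = np.array([[0.0], [1.0], [2.0]])
        res = fp.nmds(squareform(pdist(pts)), k=2, seed=0)
        assert res.stress < 1e-4

    def test_duplicate_samples_coincide(self, rng):
        base = rng.normal(size=(7, 2))
        pts = np.vstack([base, base[0]])
        res = fp.nmds(squareform(pdist(pts)), k=2, seed=0,
                      tol=1e-12, max_iter=5000)
        coords = res.array()
        assert np.linalg.norm(coords[0] - coords[-1]) < 1e-6

    def test_stress_matches_gradient_descent_oracle(self, rng):
        vals = random_binary(rng, 6, 8)
        dist = fp.jaccard_distances(vals).data
        ours = fp.nmds(dist, k=2, n_restarts=20, seed=1, tol=1e-10,
                       max_iter=2000).stress
        reference = oracle_stress(dist, k=2, seed=2)
        assert ours == pytest.approx(reference, abs=1e-3)

    def test_permutation_leaves_stress_invariant(self, rng):
        pts = rng.normal(size=(9, 2))
        dist = squareform(pdist(pts))
        perm = rng.permutation(9)
        res = fp.nmds(dist, k=2, seed=3)
        res_p = fp.nmds(dist[np.ix_(perm, perm)], k=2, seed=3)
        assert res_p.stress == pytest.approx(res.stress, abs=1e-5)
        # fitted inter-point distances are the permuted originals
        d = squareform(pdist(res.array()))
        d_p = squareform(pdist(res_p.array()))
        assert np.allclose(d_p, d[np.ix_(perm, perm)], atol=1e-4)

    def test_deterministic_given_seed(self, rng):
        vals = random_binary(rng, 8, 12)
        dist = fp.jaccard_distances(vals)
        a = fp.nmds(dist, seed=7)
        b = fp.nmds(dist, seed=7)
        assert np.array_equal(a.array(), b.array()) and a.stress == b.stress

    def test_dimension_bounds(self, rng):
        dist = squareform(pdist(rng.normal(size=(4, 2))))
        with pytest.raises(ValueError):
            fp.nmds(dist, k=4)
        with pytest.raises(ValueError):
            fp.nmds(dist, k=0)


class TestProcrustes:
    def test_self_superposition(self, rng):
        X = rng.normal(size=(6, 2))
        fit = fp.procrustes(X, X)
        assert fit.m2 == pytest.approx(0.0, abs=1e-12)
        assert fit.correlation == pytest.approx(1.0, abs=1e-12)

    def test_similarity_invariance(self, rng):
        X = rng.normal(size=(6, 2))
        R = np.array([[0.0, -1.0], [1.0, 0.0]])  # 90 degree rotation
        fit = fp.procrustes(X, 2.5 * X @ R.T + np.array([3.0, -7.0]))
        assert fit.m2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_svd_oracle(self, rng):
        X = rng.normal(size=(4, 2))
        Y = rng.normal(size=(4, 2))
        _, _, disparity = scipy_procrustes(X, Y)
        assert fp.procrustes(X, Y).m2 == pytest.approx(disparity, abs=1e-10)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            fp.procrustes(rng.normal(size=(4, 2)), rng.normal(size=(5, 2)))


class TestProtest:
    def test_identical_configurations_minimum_p(self, rng):
        X = rng.normal(size=(10, 2))
        res = fp.protest(X, X, n_perm=999, seed=0)
        assert res.p == pytest.approx(1 / 1000)
        assert res.correlation == pytest.approx(1.0)

    def test_matches_enumeration_on_three_samples(self, rng):
        X = rng.normal(size=(3, 2))
        Y = rng.normal(size=(3, 2))
        obs = fp.procrustes(X, Y).correlation
        exact = np.mean([
            fp.procrustes(X, Y[list(p)]).correlation >= obs - 1e-12
            for p in itertools.permutations(range(3))])
        mc = fp.protest(X, Y, n_perm=19999, seed=1).p
        # Monte-Carlo p concentrates on the enumeration value
        assert mc == pytest.approx(exact, abs=3 * math.sqrt(exact * (1 - exact) / 20000) + 1e-4)

    def test_requires_permutations(self, rng):
        X = rng.normal(size=(4, 2))
        with pytest.raises(ValueError):
            fp.protest(X, X, n_perm=0)


class TestPermanova:
    def test_pure_between_group_structure(self):
        # two distinct rows, each duplicated: all variance is between groups
        vals = band_frame([[1, 0, 0], [1, 0, 0], [0, 1, 1], [0, 1, 1]])
        res = fp.permanova(fp.jaccard_distances(vals), ["a", "a", "b", "b"],
                           n_perm=99, seed=0)
        assert res.R2 == pytest.approx(1.0, abs=1e-12)

    def test_f_and_p_match_enumeration_oracle(self, rng):
        vals = random_binary(rng, 6, 12)
        dm = fp.jaccard_distances(vals)
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        res = fp.permanova(dm, labels, n_perm=49999, seed=2)

        def direct_F(lab):  # direct-summation pseudo-F
            d2 = dm.data ** 2
            sst = d2[np.triu_indices(6, 1)].sum() / 6
            ssw = 0.0
            for g in np.unique(lab):
                idx = np.flatnonzero(lab == g)
                ssw += d2[np.ix_(idx, idx)][np.triu_indices(len(idx), 1)].sum() / len(idx)
            return ((sst - ssw) / 1) / (ssw / 4)

        assert res.pseudo_F == pytest.approx(direct_F(labels), abs=1e-10)
        Fs = []
        for comb in itertools.combinations(range(6), 3):
            lab = np.array(["b"] * 6)
            lab[list(comb)] = "a"
            Fs.append(direct_F(lab))
        exact_p = np.mean(np.asarray(Fs) >= res.pseudo_F - 1e-12)
        assert res.p == pytest.approx(exact_p, abs=0.02)
        assert res.R2 + (1 - res.R2) == pytest.approx(1.0, abs=1e-12)

    def test_matches_skbio(self, rng):
        from skbio.stats.distance import permanova as sk_permanova
        vals = random_binary(rng, 10, 20)
        dm = fp.jaccard_distances(vals)
        labels = np.array(["a"] * 5 + ["b"] * 5)
        mine = fp.permanova(dm, labels, n_perm=999, seed=3)
        ref = sk_permanova(dm, labels, permutations=999)
        assert mine.pseudo_F == pytest.approx(ref["test statistic"], rel=1e-10)

    def test_degenerate_inputs_rejected(self):
        vals = band_frame([[1, 0], [0, 1], [1, 1]])
        dm = fp.jaccard_distances(vals)
        with pytest.raises(ValueError):
            fp.permanova(dm, ["a", "a", "a"], n_perm=9)
        same = band_frame([[1, 0], [1, 0], [1, 0]])
        with pytest.raises(ValueError):
            fp.permanova(fp.jaccard_distances(same), ["a", "a", "b"], n_perm=9)


class TestEnsemble:
    def test_identical_matrices_fully_coupled(self, rng):
        bm = fp.BandMatrix(band_frame(random_binary(rng, 10, 18)))
        res = fp.nmds_procrustes_ensemble(bm, bm, n_repeats=10, n_perm=199,
                                          seed=4)
        assert res.median_correlation == pytest.approx(1.0, abs=1e-9)
        assert res.pct_significant == 100.0
        assert res.median_p == pytest.approx(1 / 200)

    def test_sample_mismatch_rejected(self, rng):
        a = fp.BandMatrix(band_frame(random_binary(rng, 6, 10)))
        frame = band_frame(random_binary(rng, 6, 10))
        frame.index = [f"t{i}" for i in range(6)]
        b = fp.BandMatrix(frame)
        with pytest.raises(ValueError):
            fp.nmds_procrustes_ensemble(a, b, n_repeats=2, n_perm=9)


class TestPearsonAndVpr:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert fp.pearson_test(x, 2 * x)[0] == pytest.approx(1.0)
        assert fp.pearson_test(x, -x + 5)[0] == pytest.approx(-1.0)

    def test_matches_longhand_formula(self, rng):
        x = rng.normal(size=10)
        y = 0.5 * x + rng.normal(size=10)
        rho, p = fp.pearson_test(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        rho_hand = (xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc))
        t = rho_hand * math.sqrt(8 / (1 - rho_hand ** 2))
        from scipy.stats import t as tdist
        p_hand = 2 * tdist.sf(abs(t), df=8)
        assert rho == pytest.approx(rho_hand, abs=1e-12)
        assert p == pytest.approx(p_hand, abs=1e-12)

    def test_degenerate_series_rejected(self):
        with pytest.raises(ValueError):
            fp.pearson_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            fp.pearson_test([1.0, 2.0], [1.0, 2.0])

    def test_vpr_values_and_homogeneity(self):
        out = fp.vpr([1e7, 0.0], [1e6, 5e5])
        assert out[0] == pytest.approx(10.0) and out[1] == 0.0
        a = fp.vpr([3.0, 6.0], [1.5, 2.0])
        b = fp.vpr([9.0, 18.0], [4.5, 6.0])
        assert np.allclose(a, b)

    def test_vpr_zero_prokaryotes_rejected(self):
        with pytest.raises(ValueError, match="index 1"):
            fp.vpr([1.0, 1.0], [2.0, 0.0])
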