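import itertools

import numpy as np
import pytest

from msrobust.data_model import Recording
from msrobust import microstates as ms
from msrobust.microstates import _normalize_maps


class TestGfp:
    def test_hand_computed_value(self, montage12):
        # frame (1, 0, -1, 0...0): GFP = sqrt(mean(x^2)) = sqrt(2/12)
        data = np.zeros((12, 2))
        data[0, 0], data[2, 0] = 1.0, -1.0
        rec = Recording(data, 250.0, montage12)
        g = ms.gfp(rec)
        assert np.isclose(g.values[0], np.sqrt(2.0 / 12.0))
        assert g.values[1] == 0.0
        # and the spatial-SD formula on a 3-value frame: sqrt(2/3)
        assert np.isclose(np.std([1.0, 0.0, -1.0]), np.sqrt(2.0 / 3.0))

    def test_zero_frame_and_homogeneity(self, montage12):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((12, 100))
        data[:, 0] = 0.0
        rec = Recording(data, 250.0, montage12)
        g = ms.gfp(rec)
        assert g.values[0] == 0.0
        g3 = ms.gfp(Recording(-3.0 * data, 250.0, montage12))
        assert np.allclose(g3.values, 3.0 * g.values)


class TestGfpPeaks:
    def test_monotone_series_has_no_peaks(self):
        s = ms.GFPSeries(np.arange(50, dtype=float), 250.0)
        assert len(ms.gfp_peaks(s)) == 0

    def test_single_bump(self):
        v = np.concatenate([np.arange(10.0), np.arange(9.0)[::-1]])
        s = ms.GFPSeries(v, 250.0)
        assert list(ms.gfp_peaks(s)) == [9]

    def test_planted_bumps_recovered(self):
        v = np.zeros(300)
        apex = np.arange(7, 300, 15)
        for a in apex:
            v[a - 2 : a + 3] += np.array([0.2, 0.6, 1.0, 0.6, 0.2]) * (1 + 0.01 * a)
        got = ms.gfp_peaks(ms.GFPSeries(v, 250.0))
        assert np.array_equal(got, apex)

    def test_min_distance_keeps_higher_peak(self):
        v = np.zeros(20)
        v[[5, 7]] = [1.0, 2.0]
        got = ms.gfp_peaks(ms.GFPSeries(v, 250.0), min_distance_samples=3)
        assert list(got) == [7]


class TestSpatialCorrelation:
    def test_identity_polarity_and_hand_value(self):
        rng = np.random.default_rng(1)
        v = rng.standard_normal(8)
        assert np.isclose(ms.spatial_correlation(v, v), 1.0)
        assert np.isclose(ms.spatial_correlation(v, -v), 1.0)
        assert np.isclose(ms.spatial_correlation(v, -v, ignore_polarity=False), -1.0)
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 1.0, 4.0, 3.0])
        am, bm = a - a.mean(), b - b.mean()
        expected = am @ bm / np.sqrt((am @ am) * (bm @ bm))
        assert np.isclose(ms.spatial_correlation(a, b, ignore_polarity=False), expected)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ms.spatial_correlation(np.ones(5), np.arange(5.0))


def _sign_aligned_centroids(M, assign, k):
    T = np.zeros((k, M.shape[1]))
    for j in range(k):
        sel = assign == j
        if not sel.any():
            return None
        ref = M[sel][0]
        sg = np.sign(M[sel] @ ref)
        sg[sg == 0] = 1.0
        m = (sg[:, None] * M[sel]).mean(axis=0)
        T[j] = m / np.linalg.norm(m)
    return T


def brute_force_best_gev(M, w, k, max_iter=200):
    """Independent oracle: start the sign-aligned-mean / winner-takes-all
    iteration from EVERY valid partition, run it to its fixed point, and
    report the best final GEV.  Exhausts every basin of attraction."""
    M = _normalize_maps(M)
    w2 = w**2
    best = -1.0
    for assign0 in itertools.product(range(k), repeat=len(M)):
        assign = np.asarray(assign0)
        if len(np.unique(assign)) < k:
            continue
        for _ in range(max_iter):
            T = _sign_aligned_centroids(M, assign, k)
            if T is None:
                break
            new = np.argmax(np.abs(T @ M.T), axis=0)
            if np.array_equal(new, assign) or len(np.unique(new)) < k:
                break
            assign = new
        T = _sign_aligned_centroids(M, assign, k)
        if T is None:
            continue
        re = np.argmax(np.abs(T @ M.T), axis=0)
        r = np.einsum("nc,nc->n", M, T[re])
        best = max(best, float((w2 * r**2).sum() / w2.sum()))
    return best


def separated_instance(seed, k, n_maps, n_ch=10, noise=0.1):
    """Maps drawn (with random sign) from k orthogonal templates + noise."""
    rng = np.random.default_rng(seed)
    Q, _ = np.linalg.qr(rng.standard_normal((n_ch, k)))
    base = _normalize_maps(Q.T)
    signs = rng.choice([-1.0, 1.0], n_maps)
    maps = np.array(
        [signs[i] * base[i % k] + noise * rng.standard_normal(n_ch) for i in range(n_maps)]
    )
    return maps, rng.uniform(1.0, 3.0, n_maps)


class TestModifiedKmeans:
    def test_identical_maps_k1(self, montage12):
        v = _normalize_maps(np.random.default_rng(2).standard_normal((1, 12)))[0]
        maps = np.vstack([v, -v, v, v, -v])
        tpl, assign = ms.modified_kmeans(maps, 1, n_restarts=5, seed=0)
        assert np.isclose(abs(tpl.maps[0] @ v), 1.0)
        assert np.isclose(tpl.gev, 1.0)
        assert np.all(assign == 0)

    @pytest.mark.parametrize("k,n_maps,seed", [(2, 8, 12), (3, 7, 13), (2, 8, 20)])
    def test_matches_exhaustive_enumeration(self, k, n_maps, seed):
        maps, w = separated_instance(seed, k, n_maps)
        tpl, _ = ms.modified_kmeans(maps, k, weights=w, n_restarts=200, seed=1)
        assert np.isclose(tpl.gev, brute_force_best_gev(maps, w, k), atol=1e-12)

    def test_more_restarts_never_worse(self):
        rng = np.random.default_rng(5)
        maps = rng.standard_normal((40, 12))
        w = rng.uniform(0.5, 2.0, 40)
        g1 = ms.modified_kmeans(maps, 4, weights=w, n_restarts=1, seed=3)[0].gev
        g200 = ms.modified_kmeans(maps, 4, weights=w, n_restarts=200, seed=3)[0].gev
        assert g200 >= g1 - 1e-12

    def test_gev_nondecreasing_in_k(self):
        rng = np.random.default_rng(6)
        maps = rng.standard_normal((60, 12))
        for seed in range(5):
            gevs = [
                ms.modified_kmeans(maps, k, n_restarts=40, seed=seed)[0].gev
                for k in (2, 3, 4, 5)
            ]
            assert all(b >= a - 1e-9 for a, b in zip(gevs, gevs[1:]))

    def test_invariance_to_sign_flips_and_channel_permutation(self):
        rng = np.random.default_rng(7)
        maps = rng.standard_normal((30, 12))
        tpl, assign = ms.modified_kmeans(maps, 3, n_restarts=50, seed=2)
        flips = rng.choice([-1.0, 1.0], 30)[:, None]
        perm = rng.permutation(12)
        tpl2, assign2 = ms.modified_kmeans(flips * maps[:, perm], 3, n_restarts=50, seed=2)
        assert np.array_equal(assign, assign2)
        assert np.allclose(np.abs(np.einsum("kc,kc->k", tpl.maps[:, perm], tpl2.maps)), 1.0, atol=1e-9)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(8)
        maps = rng.standard_normal((50, 12))
        a = ms.modified_kmeans(maps, 4, n_restarts=20, seed=9)
        b = ms.modified_kmeans(maps, 4, n_restarts=20, seed=9)
        assert np.array_equal(a[0].maps, b[0].maps) and np.array_equal(a[1], b[1])


class TestGev:
    def test_perfect_and_null_fits(self):
        rng = np.random.default_rng(9)
        T = _normalize_maps(rng.standard_normal((3, 10)))
        assert np.isclose(ms.compute_gev(T, np.ones(3), T, np.arange(3)), 1.0)
        # orthogonal complement maps
        M = _normalize_maps(np.eye(10)[:3] - 0.1)
        Q, _ = np.linalg.qr(np.vstack([M, rng.standard_normal((5, 10))]).T)
        orth = _normalize_maps(Q.T[4:7])
        gev = ms.compute_gev(M, np.ones(3), orth, np.zeros(3, int))
        assert gev < 0.3  # nearly orthogonal templates explain little

    def test_hand_evaluated_toy(self):
        # 3 maps with known GFPs and correlations to one template
        t = _normalize_maps(np.array([[1.0, -1.0, 0.0, 0.0]]))[0]
        maps = np.array(
            [t, _normalize_maps(np.array([[0.0, 0.0, 1.0, -1.0]]))[0], t]
        )
        w = np.array([2.0, 1.0, 3.0])
        # r = 1, 0 (orthogonal after centering), 1
        expected = (4 * 1 + 1 * 0 + 9 * 1) / (4 + 1 + 9)
        got = ms.compute_gev(maps, w, t[None, :], np.zeros(3, int))
        assert np.isclose(got, expected, atol=1e-12)

    def test_zero_weight_rejected(self):
        t = _normalize_maps(np.random.default_rng(0).standard_normal((1, 6)))
        with pytest.raises(ValueError):
            ms.compute_gev(t, np.zeros(1), t, np.zeros(1, int))


class TestMetaCriterion:
    def test_unanimous(self):
        curves = [
            ms.CriterionCurve(name, np.arange(2, 9), np.eye(7)[3], 5)
            for name in ms.CRITERION_NAMES
        ]
        meta_k, mean_k, cand = ms.meta_criterion(curves)
        assert (meta_k, mean_k, cand) == (5, 5.0, [5])

    def test_median_and_mean(self):
        opts = [4, 5, 5, 6, 7, 5]
        curves = [
            ms.CriterionCurve(name, np.arange(2, 9), np.eye(7)[o - 2], o)
            for name, o in zip(ms.CRITERION_NAMES, opts)
        ]
        meta_k, mean_k, cand = ms.meta_criterion(curves)
        assert meta_k == 5
        assert np.isclose(mean_k, np.mean(opts))
        assert cand == [4, 5, 6, 7]

    def test_lower_median_on_even_tie(self):
        opts = [4, 4, 5, 5]
        curves = [
            ms.CriterionCurve(name, np.arange(2, 9), np.eye(7)[o - 2], o)
            for name, o in zip(ms.CRITERION_NAMES[:4], opts)
        ]
        assert ms.meta_criterion(curves)[0] == 4

    def test_too_few_curves_rejected(self):
        with pytest.raises(ValueError):
            ms.meta_criterion([ms.CriterionCurve("gamma", np.arange(2, 9), np.zeros(7), 2)])


class TestTwoLevel:
    def test_identical_subjects_give_identical_group_maps(self):
        rng = np.random.default_rng(11)
        base = _normalize_maps(rng.standard_normal((4, 12)))
        maps = np.vstack([base + 0.01 * rng.standard_normal((4, 12)) for _ in range(20)])
        subject = (maps, None)
        res = ms.two_level_cluster([subject, subject, subject], k_range=(3, 4, 5),
                                   seed=0, level1_k=4, n_restarts=30)
        tpl = res["templates_per_k"][4]
        C = np.abs(tpl.maps @ base.T)
        # each group template matches one planted map nearly perfectly
        assert np.allclose(np.sort(C.max(axis=1)), 1.0, atol=1e-3)

    def test_needs_two_subjects(self):
        with pytest.raises(ValueError):
            ms.two_level_cluster([(np.eye(4), None)], k_range=(2,), seed=0)
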