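import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from salrad.saliency import SaliencyMap, SaliencyParams
from salrad.survival import (CoxConvergenceError, bootstrap_ci, c_index,
                             c_index_bruteforce, cox_fit, km_logrank,
                             saliency_peak_distance)
from salrad.volume_io import TumorMask

from conftest import sphere_mask


class TestCIndex:
    def test_perfect_ordering(self):
        t = np.array([1.0, 2, 3, 4, 5])
        e = np.ones(5)
        s = np.array([5.0, 4, 3, 2, 1])  # highest risk fails first
        assert c_index(t, e, s) == 1.0

    def test_random_scores_near_half(self, rng):
        n = 2000
        t = rng.exponential(1, n)
        e = np.ones(n)
        s = rng.normal(0, 1, n)
        assert abs(c_index(t, e, s) - 0.5) < 0.03

    def test_censored_hand_example(self):
        # 5 patients, one censored: exhaustive enumeration gives 5 permissible
        # pairs of which 4 are concordant
        t = np.array([2.0, 4.0, 3.0, 5.0, 1.0])
        e = np.array([1.0, 1.0, 0.0, 1.0, 1.0])
        s = np.array([0.9, 0.3, 0.5, 0.1, 1.2])
        assert c_index(t, e, s) == c_index_bruteforce(t, e, s)
        assert c_index(t, e, s) == pytest.approx(1.0)  # all permissible concordant

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        t = np.round(rng.exponential(1, n), 2) + 0.01  # induce ties
        e = rng.integers(0, 2, n).astype(float)
        s = np.round(rng.normal(0, 1, n), 1)  # induce score ties
        if e.sum() == 0:
            e[0] = 1.0
        a, b = c_index(t, e, s), c_index_bruteforce(t, e, s)
        if np.isnan(a):
            assert np.isnan(b)
        else:
            assert a == pytest.approx(b, abs=1e-14)

    def test_no_permissible_pairs_flagged(self):
        assert np.isnan(c_index(np.array([1.0, 2.0]), np.array([0.0, 0.0]),
                                np.array([1.0, 2.0])))


class TestCoxFit:
    def test_recovers_log_hazard_ratio_two(self):
        rng = np.random.default_rng(5)
        n = 4000  # SE(beta) ~ 0.03 at this size
        g = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1 / np.exp(g * np.log(2)))
        c = rng.exponential(2.0, n)
        fit = cox_fit(g[:, None], np.minimum(t, c) + 1e-9, (t <= c).astype(float))
        assert fit.coef[0] == pytest.approx(np.log(2), abs=0.1)

    def test_null_covariate_beta_zero(self, rng):
        n = 300
        x = rng.normal(0, 1, n)
        t = rng.exponential(1, n)
        fit = cox_fit(x[:, None], t, np.ones(n))
        assert abs(fit.coef[0]) < 0.15
        assert fit.loglik == pytest.approx(fit.loglik_null, abs=2.0)

    def test_duplicating_rows_leaves_beta_unchanged(self, rng):
        n = 80
        x = rng.normal(0, 1, (n, 2))
        t = rng.exponential(1 / np.exp(x @ [0.5, -0.5]))
        e = np.ones(n)
        single = cox_fit(x, t, e)
        double = cox_fit(np.vstack([x, x]), np.concatenate([t, t]),
                         np.concatenate([e, e]))
        # duplication creates ties, so under the Efron correction the
        # doubled-weight equivalence holds only approximately
        np.testing.assert_allclose(single.coef, double.coef, atol=0.02)

    def test_loglik_path_monotone(self, rng):
        n = 200
        x = rng.normal(0, 1, (n, 3))
        t = rng.exponential(1 / np.exp(x @ [1.0, -0.7, 0.3]))
        fit = cox_fit(x, t, np.ones(n))
        assert all(np.diff(fit.loglik_path) >= -1e-9)

    def test_matches_lifelines_with_ties(self, rng):
        n = 150
        x = rng.normal(0, 1, (n, 3))
        t = np.ceil(rng.exponential(5 / np.exp(x @ [0.4, -0.3, 0.6])))  # heavy ties
        c = np.ceil(rng.exponential(10, n))
        tt, ee = np.minimum(t, c), (t <= c).astype(float)
        fit = cox_fit(x, tt, ee)
        df = pd.DataFrame(x, columns=list("abc"))
        df["T"], df["E"] = tt, ee
        ref = CoxPHFitter().fit(df, "T", "E")  # lifelines uses Efron ties too
        np.testing.assert_allclose(fit.coef, ref.params_.to_numpy(), atol=1e-4)

    def test_constant_column_rejected(self, rng):
        with pytest.raises(CoxConvergenceError):
            cox_fit(np.ones((20, 1)), rng.exponential(1, 20), np.ones(20))

    def test_separation_detected(self):
        # perfectly separated covariate: monotone likelihood, no finite MLE
        t = np.arange(1.0, 21.0)
        x = (t > 10).astype(float)[:, None]
        with pytest.raises(CoxConvergenceError):
            cox_fit(x, t, np.ones(20))


class TestScoreTestAgainstLogrank:
    def test_cox_score_test_matches_logrank(self, rng):
        """The Cox score test at beta=0 for a binary covariate equals the
        two-group log-rank chi-square (no ties in this draw)."""
        from salrad.survival import cox_loglik
        from lifelines.statistics import logrank_test
        n = 120
        g = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1 / np.exp(0.6 * g))
        e = np.ones(n)
        _, grad, hess = cox_loglik(np.zeros(1), g[:, None], t, e)
        score_chi2 = grad[0] ** 2 / (-hess[0, 0])
        ref = logrank_test(t[g == 1], t[g == 0], e[g == 1], e[g == 0])
        assert score_chi2 == pytest.approx(ref.test_statistic, abs=1e-6)


class TestKmLogrank:
    def test_identical_groups_chi_square_zero(self):
        t = np.array([1.0, 2, 3, 4] * 2)
        e = np.array([1.0, 1, 0, 1] * 2)
        score = np.array([1.0] * 4 + [0.0] * 4)  # same survival in both groups
        res = km_logrank(score, 0.5, t, e)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_eight_patient_hand_table(self):
        """Log-rank O-E computed by hand over the ordered event times.

        Group H = {1,3,5,7} all events; group L = {2,4,6,8} all events.
        Walking the risk sets: E_H = 4/8+3/7+3/6+2/5+2/4+1/3+1/2+0,
        V = sum of n1*n2*(N-d)/(N^2*(N-1)) terms with d=1.
        """
        t = np.array([1.0, 3, 5, 7, 2, 4, 6, 8])
        e = np.ones(8)
        score = np.array([1.0] * 4 + [0.0] * 4)
        e_h = 4 / 8 + 3 / 7 + 3 / 6 + 2 / 5 + 2 / 4 + 1 / 3 + 1 / 2 + 0 / 1
        o_h = 4.0
        fracs = [(4 * 4, 8), (4 * 3, 7), (3 * 3, 6), (3 * 2, 5), (2 * 2, 4),
                 (2 * 1, 3), (1 * 1, 2), (0 * 1, 1)]
        v = sum(a / (N * N) for a, N in fracs)  # d=1, (N-d)/(N-1)=1
        expected_chi2 = (o_h - e_h) ** 2 / v
        res = km_logrank(score, 0.5, t, e)
        assert res.chi_square == pytest.approx(expected_chi2, abs=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            km_logrank(np.ones(4), 0.5, np.arange(1.0, 5.0), np.ones(4))

    def test_hazard_ratio_direction(self, rng):
        n = 400
        g = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1 / np.exp(g * 1.0))
        res = km_logrank(g, 0.5, t, np.ones(n))
        assert res.hazard_ratio > 1.5  # high-score group at higher risk


class TestBootstrap:
    def test_constant_metric_zero_width(self, rng):
        point, (lo, hi) = bootstrap_ci(lambda d: 42.0, {"x": np.arange(50.0)},
                                       rng=0, B=100)
        assert point == lo == hi == 42.0

    def test_ci_width_shrinks_with_n(self):
        widths = []
        for n in (100, 400):
            rng = np.random.default_rng(n)
            x = rng.normal(0, 1, n)
            _, (lo, hi) = bootstrap_ci(lambda d: d["x"].mean(), {"x": x},
                                       rng=7, B=200)
            widths.append(hi - lo)
        # ~ 1/sqrt(n): quadrupling n halves the width
        assert widths[1] < widths[0] * 0.75

    def test_undefined_replicates_redrawn(self, rng):
        calls = {"n": 0}

        def flaky(d):
            calls["n"] += 1
            return np.nan if calls["n"] % 3 == 0 else 1.0

        point, _ = bootstrap_ci(flaky, {"x": np.arange(10.0)}, rng=0, B=10)
        assert point == 1.0

    def test_b_minimum(self):
        with pytest.raises(ValueError):
            bootstrap_ci(lambda d: 0.0, {"x": np.arange(3.0)}, rng=0, B=1)


class TestSaliencyPeakDistance:
    def _map_peaking_at(self, shape, peak):
        grids = np.indices(shape).astype(float)
        d = sum((g - p) ** 2 for g, p in zip(grids, peak))
        return -d  # maximum at `peak`

    def test_peak_at_centroid_zero(self):
        mask = sphere_mask((21, 21, 21), (10, 10, 10), 8.0)
        sal = self._map_peaking_at((21, 21, 21), (10, 10, 10))
        assert saliency_peak_distance(sal, mask) == 0.0

    def test_peak_at_farthest_voxel_one(self):
        mask = sphere_mask((21, 21, 21), (10, 10, 10), 8.0)
        coords = np.argwhere(mask.voxels)
        far = coords[np.argmax(np.linalg.norm(coords - 10.0, axis=1))]
        sal = self._map_peaking_at((21, 21, 21), far)
        assert saliency_peak_distance(sal, mask) == pytest.approx(1.0)

    def test_half_radius_peak(self):
        mask = sphere_mask((41, 41, 41), (20, 20, 20), 16.0)
        sal = self._map_peaking_at((41, 41, 41), (28, 20, 20))  # r/2 along x
        assert saliency_peak_distance(sal, mask) == pytest.approx(0.5, abs=0.05)

    def test_single_voxel_mask(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        sal = np.zeros((5, 5, 5))
        assert saliency_peak_distance(sal, TumorMask(m, (1, 1, 1))) == 0.0

    def test_anisotropic_spacing_uses_physical_distance(self):
        # slab mask; with z-spacing 5 the farthest voxel is along z
        m = np.zeros((11, 11, 5), bool)
        m[3:8, 3:8, 1:4] = True
        mask = TumorMask(m, (1.0, 1.0, 5.0))
        sal = np.zeros((11, 11, 5))
        sal[5, 5, 3] = 1.0  # one z-step = 5 mm from centroid
        d = saliency_peak_distance(sal, mask)
        phys = np.argwhere(m) * np.array([1.0, 1.0, 5.0])
        centroid = phys.mean(axis=0)
        rmax = np.linalg.norm(phys - centroid, axis=1).max()
        assert d == pytest.approx(5.0 / rmax)
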