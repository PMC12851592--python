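"""Pair-correlation estimator, null ensembles and curve comparisons."""

import numpy as np
import pytest

from ommaquant.datatypes import PointPattern, Window
from ommaquant.errors import BinningMismatchError, InsufficientDataError, UndefinedScoreError
from ommaquant.rdf import (
    RDFCurve,
    compare_rdf_wilcoxon,
    estimate_rdf,
    mean_rdf,
    rdf_r_squared,
    simulate_null_rdfs,
)
from ommaquant.synthetic import gen_hardcore_pattern, gen_poisson_pattern

from conftest import brute_force_min_distance


class TestEstimator:
    def test_single_pair_occupies_one_bin(self):
        win = Window(0, 40, 0, 40)
        pat = PointPattern([[10.0, 10.0], [15.0, 10.0]], win)  # distance 5
        curve = estimate_rdf(pat, bin_width=1.0, r_max=8.0)
        hot = (curve.r_centers > 5.0) & (curve.r_centers < 6.0)  # bin [5, 6)
        assert (curve.g_values[~hot] == 0).all()
        # oracle: 2 ordered pairs normalised by N² / |W|² times the exact
        # pair-distance measure of the bin, with the direction-averaged
        # window set covariance evaluated by numerical quadrature
        from scipy.integrate import quad

        W = H = 40.0

        def set_cov(r):
            th = np.linspace(0, 2 * np.pi, 4001)
            return np.trapezoid(
                (W - np.abs(r * np.cos(th))) * (H - np.abs(r * np.sin(th))), th
            ) / (2 * np.pi)

        measure, _ = quad(lambda r: 2 * np.pi * r * set_cov(r), 5.0, 6.0)
        expected = 2.0 * win.area**2 / (2**2 * measure)
        assert curve.g_values[hot][0] == pytest.approx(expected, rel=1e-6)

    def test_csr_calibrates_to_unity(self):
        win = Window(0, 200, 0, 200)
        gs = []
        for seed in range(5):
            pat = gen_poisson_pattern(1000, win, seed)
            gs.append(estimate_rdf(pat, 1.0, 25.0).g_values)
        assert 0.9 < np.mean(gs) < 1.1

    def test_estimator_bias_shrinks_with_n(self):
        """|mean g − 1| for CSR decreases from n=200 to n=2000."""
        win = Window(0, 200, 0, 200)

        def bias(n):
            gs = [estimate_rdf(gen_poisson_pattern(n, win, s), 1.0, 25.0).g_values for s in range(8)]
            return abs(np.mean(gs) - 1.0)

        assert bias(2000) < bias(200)

    def test_hardcore_exclusion_zone_empty(self, square_window):
        pat = gen_hardcore_pattern(300, square_window, 2.0, seed=4)
        assert brute_force_min_distance(pat.points) >= 2.0
        curve = estimate_rdf(pat, bin_width=0.25, r_max=10.0)
        below = curve.r_centers < 2.0 - 0.125  # bins fully below d_min
        assert (curve.g_values[below] == 0.0).all()

    def test_too_few_points(self, small_window):
        pat = PointPattern([[1.0, 1.0]], small_window)
        with pytest.raises(InsufficientDataError):
            estimate_rdf(pat, 0.5, 2.0)

    def test_r_max_clipped_to_quarter_window(self, small_window):
        pat = gen_poisson_pattern(100, small_window, 0)
        curve = estimate_rdf(pat, 0.5, 50.0)
        assert curve.r_max <= 0.25 * 20.0 + 1e-12

    def test_rigid_motion_invariance(self, square_window):
        """Translation and 90° rotation of pattern + window leave g(r) unchanged."""
        pat = gen_poisson_pattern(400, square_window, 9)
        base = estimate_rdf(pat, 0.5, 20.0)
        shifted = PointPattern(pat.points + [7.0, -3.0], Window(7, 107, -3, 97))
        rot = PointPattern(
            np.column_stack([-pat.points[:, 1], pat.points[:, 0]]), Window(-100, 0, 0, 100)
        )
        np.testing.assert_allclose(base.g_values, estimate_rdf(shifted, 0.5, 20.0).g_values)
        np.testing.assert_allclose(base.g_values, estimate_rdf(rot, 0.5, 20.0).g_values)


class TestNullEnsemble:
    def test_single_sim_mean_is_the_curve(self, square_window):
        pat = gen_poisson_pattern(200, square_window, 2)
        ens = simulate_null_rdfs(pat, 1.0, 1, 0.5, 10.0, seed=0)
        np.testing.assert_array_equal(ens.mean.g_values, ens.curves[0].g_values)

    def test_density_matching(self, square_window):
        pat = gen_poisson_pattern(321, square_window, 2)
        ens = simulate_null_rdfs(pat, 1.0, 3, 0.5, 10.0, seed=0)
        assert all(c.n_points == 321 for c in ens.curves)

    def test_zero_dmin_reduces_to_csr(self, square_window):
        pat = gen_poisson_pattern(500, square_window, 2)
        ens = simulate_null_rdfs(pat, 0.0, 10, 1.0, 20.0, seed=1)
        assert np.abs(ens.mean.g_values - 1.0).mean() < 0.1

    def test_exclusion_below_dmin(self, square_window):
        pat = gen_poisson_pattern(300, square_window, 2)
        ens = simulate_null_rdfs(pat, 3.0, 3, 0.5, 10.0, seed=1)
        below = ens.mean.r_centers < 3.0 - 0.25
        assert (ens.mean.g_values[below] == 0.0).all()


class TestWilcoxon:
    def test_identity_gives_p_one(self, square_window):
        pat = gen_poisson_pattern(300, square_window, 5)
        curve = estimate_rdf(pat, 0.5, 15.0)
        res = compare_rdf_wilcoxon(curve, curve)
        assert res.p_value == 1.0 and res.n_bins_paired == 0

    def test_csr_vs_hardcore_null_detected(self, square_window):
        pat = gen_poisson_pattern(500, square_window, 6)
        curve = estimate_rdf(pat, 0.5, 20.0)  # 40 bins
        ens = simulate_null_rdfs(pat, 3.0, 20, 0.5, 20.0, seed=2)
        res = compare_rdf_wilcoxon(curve, ens.mean)
        assert res.p_value < 0.05

    def test_mismatched_binning_rejected(self, square_window):
        pat = gen_poisson_pattern(300, square_window, 5)
        a = estimate_rdf(pat, 0.5, 15.0)
        b = estimate_rdf(pat, 1.0, 15.0)
        with pytest.raises(BinningMismatchError):
            compare_rdf_wilcoxon(a, b)

    def test_p_values_valid_and_symmetric(self):
        """p ∈ (0, 1] always and the comparison is symmetric in its arguments.

        (The per-bin paired Wilcoxon is descriptive here: replicate curves
        share within-curve bin correlations, so its p-values are not
        calibrated for replicate-vs-replicate null comparisons.)
        """
        win = Window(0, 100, 0, 100)
        for s in range(20):
            a = estimate_rdf(gen_poisson_pattern(400, win, 2 * s), 1.0, 25.0)
            b = estimate_rdf(gen_poisson_pattern(400, win, 2 * s + 1), 1.0, 25.0)
            res_ab = compare_rdf_wilcoxon(a, b)
            res_ba = compare_rdf_wilcoxon(b, a)
            assert 0.0 < res_ab.p_value <= 1.0
            assert res_ab.p_value == pytest.approx(res_ba.p_value, rel=1e-12)


class TestOrderScore:
    def _curve(self, g):
        g = np.asarray(g, float)
        r = np.arange(g.size) * 0.5 + 0.25
        return RDFCurve(r, g, 0.5, r[-1] + 0.25, 100, 0.1)

    def test_identity_r_squared_one(self):
        c = self._curve([0, 0.5, 2.0, 1.2, 0.9, 1.0])
        score = rdf_r_squared(c, c)
        assert score.r_squared == 1.0 and not score.deviates

    def test_matches_sum_of_squares_oracle(self, square_window):
        """R² equals the direct arithmetic definition computed independently."""
        pat = gen_hardcore_pattern(400, square_window, 3.0, seed=8)
        emp = estimate_rdf(pat, 0.5, 20.0)
        ref = np.ones_like(emp.g_values)  # flat CSR reference
        score = rdf_r_squared(emp, ref)
        g = list(emp.g_values)
        mean_g = sum(g) / len(g)
        ss_res = sum((gi - ri) ** 2 for gi, ri in zip(g, ref))
        ss_tot = sum((gi - mean_g) ** 2 for gi in g)
        assert score.r_squared == pytest.approx(1 - ss_res / ss_tot, rel=1e-12)
        assert score.deviates == (score.r_squared < 0.9)

    def test_below_threshold_deviates(self):
        """A curve whose R² against the reference is ~0.85 is called deviating."""
        ref = self._curve([1.0, 2.0, 1.0, 0.5, 1.0, 1.2])
        # perturb until R² lands below 0.9 but above 0
        emp = self._curve([1.0, 1.55, 1.0, 0.75, 1.15, 1.2])
        score = rdf_r_squared(emp, ref)
        assert 0.0 < score.r_squared < 0.9
        assert score.deviates

    def test_constant_curve_undefined(self):
        flat = self._curve([1.0, 1.0, 1.0, 1.0])
        with pytest.raises(UndefinedScoreError):
            rdf_r_squared(flat, self._curve([1.0, 2.0, 1.0, 1.0]))


def test_mean_rdf_pools_binwise(square_window):
    curves = [
        estimate_rdf(gen_poisson_pattern(300, square_window, s), 0.5, 15.0) for s in range(3)
    ]
    pooled = mean_rdf(curves)
    np.testing.assert_allclose(
        pooled.g_values, np.mean([c.g_values for c in curves], axis=0)
    )
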