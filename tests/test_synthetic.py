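"""Generators: reproducibility, geometric constraints, sampling distributions."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from ommaquant.circular import circ_mean_resultant
from ommaquant.datatypes import Window
from ommaquant.errors import SaturationError
from ommaquant.morphometrics import polygon_descriptors
from ommaquant.synthetic import (
    gen_hardcore_pattern,
    gen_hexagon_polygon,
    gen_jittered_hex_lattice,
    gen_orientation_dataset,
    gen_phototaxis_counts,
    gen_poisson_pattern,
)

from conftest import brute_force_min_distance


@pytest.mark.parametrize(
    "gen",
    [
        lambda w, s: gen_poisson_pattern(200, w, s).points,
        lambda w, s: gen_hardcore_pattern(100, w, 2.0, s).points,
        lambda w, s: gen_jittered_hex_lattice(2.0, 0.2, w, s).points,
        lambda w, s: gen_orientation_dataset(4, 5, 30.0, 4.0, "g", s).angles(),
        lambda w, s: np.array(gen_phototaxis_counts(35, 0.7, s).tube_counts),
        lambda w, s: gen_hexagon_polygon(1.0, 0.1, s),
    ],
    ids=["poisson", "hardcore", "hex", "angles", "assay", "polygon"],
)
def test_generators_seed_reproducible(gen, square_window):
    """Fixed seed gives bitwise-identical output; a different seed does not."""
    a = gen(square_window, 42)
    b = gen(square_window, 42)
    c = gen(square_window, 43)
    np.testing.assert_array_equal(a, b)
    assert not np.array_equal(a, c)


class TestPoisson:
    def test_empty_and_containment(self, square_window):
        assert gen_poisson_pattern(0, square_window, 0).n == 0
        pat = gen_poisson_pattern(1000, square_window, 1)
        assert pat.n == 1000
        assert square_window.contains(pat.points).all()

    def test_negative_n_rejected(self, square_window):
        with pytest.raises(ValueError):
            gen_poisson_pattern(-1, square_window, 0)

    def test_nearest_neighbor_distance_matches_csr_expectation(self):
        """For CSR the mean nearest-neighbour distance is 0.5/√ρ."""
        win = Window(0, 200, 0, 200)
        means = []
        for seed in range(20):
            pts = gen_poisson_pattern(2000, win, seed).points
            d, _ = cKDTree(pts).query(pts, k=2)
            means.append(d[:, 1].mean())
        rho = 2000 / win.area
        expected = 0.5 / np.sqrt(rho)
        assert np.mean(means) == pytest.approx(expected, rel=0.05)


class TestHardCore:
    def test_two_points_respect_separation(self, small_window):
        pat = gen_hardcore_pattern(2, small_window, 3.0, seed=7)
        assert brute_force_min_distance(pat.points) >= 3.0

    def test_min_pairwise_distance_brute_force(self, square_window):
        pat = gen_hardcore_pattern(500, square_window, 2.0, seed=11)
        assert pat.n == 500
        assert brute_force_min_distance(pat.points) >= 2.0

    def test_infeasible_packing_saturates(self):
        with pytest.raises(SaturationError):
            gen_hardcore_pattern(10_000, Window(0, 10, 0, 10), 2.0, seed=0)

    def test_saturation_reports_achieved_count(self):
        # modest density but a tiny attempt budget: must report partial placement
        with pytest.raises(SaturationError) as exc:
            gen_hardcore_pattern(200, Window(0, 30, 0, 30), 2.0, seed=0, max_attempts=10)
        assert 0 <= exc.value.achieved < 200


class TestHexLattice:
    def test_zero_jitter_interior_spacing(self, square_window):
        pat = gen_jittered_hex_lattice(2.0, 0.0, square_window, seed=0)
        pts = pat.points
        interior = pts[
            (pts[:, 0] > 5) & (pts[:, 0] < 95) & (pts[:, 1] > 5) & (pts[:, 1] < 95)
        ]
        d, _ = cKDTree(pts).query(interior, k=2)
        np.testing.assert_allclose(d[:, 1], 2.0, rtol=1e-9)

    def test_invalid_spacing(self, square_window):
        with pytest.raises(ValueError):
            gen_jittered_hex_lattice(0.0, 0.1, square_window, seed=0)

    def test_first_rdf_peak_near_spacing(self):
        """Short-range order: first g(r) peak within 10% of the lattice spacing."""
        from ommaquant.rdf import estimate_rdf

        win = Window(0, 80, 0, 80)
        pat = gen_jittered_hex_lattice(2.0, 0.15, win, seed=3)
        curve = estimate_rdf(pat, bin_width=0.1, r_max=10.0)
        peak_r = curve.r_centers[np.argmax(curve.g_values)]
        assert 1.8 <= peak_r <= 2.2

    def test_large_jitter_destroys_order(self):
        """jitter ≫ spacing: g(r) flattens towards the CSR value 1."""
        from ommaquant.rdf import estimate_rdf

        win = Window(0, 80, 0, 80)
        pat = gen_jittered_hex_lattice(2.0, 8.0, win, seed=3)
        curve = estimate_rdf(pat, bin_width=0.25, r_max=10.0)
        beyond = curve.r_centers > 1.0
        assert np.abs(curve.g_values[beyond] - 1.0).mean() < 0.1


class TestOrientation:
    def test_degenerate_concentration_aligns(self):
        data = gen_orientation_dataset(2, 50, 30.0, 1e6, "wt", seed=0)
        assert circ_mean_resultant(data.angles()).R > 0.999

    def test_uniform_angles_disperse(self):
        data = gen_orientation_dataset(1, 10_000, 0.0, 0.0, "wt", seed=1)
        # E[R] ≈ √π / (2√n) for circular-uniform data
        assert circ_mean_resultant(data.angles()).R < 0.03

    def test_mean_direction_recovered(self):
        for seed in range(10):
            data = gen_orientation_dataset(8, 5, 30.0, 4.0, "wt", seed=seed)
            mu = circ_mean_resultant(data.angles()).mu_deg
            delta = (mu - 30.0 + 180.0) % 360.0 - 180.0
            assert abs(delta) < 15.0

    def test_nested_structure(self):
        data = gen_orientation_dataset(8, 5, 0.0, 1.0, "wt", seed=0)
        counts = data.records.groupby("eye_id").size()
        assert len(counts) == 8 and (counts == 5).all()


class TestHexagonPolygon:
    def test_noiseless_closed_form(self):
        verts = gen_hexagon_polygon(1.0, 0.0, seed=0)
        d = polygon_descriptors(verts)
        assert d.area == pytest.approx(3 * np.sqrt(3) / 2, rel=1e-12)
        assert d.perimeter == pytest.approx(6.0, rel=1e-12)
        assert d.circularity == pytest.approx(np.pi * np.sqrt(3) / 6, rel=1e-12)

    def test_noise_decreases_circularity(self):
        """Monte-Carlo: mean circularity falls as vertex noise grows."""
        def mean_circ(sd, n=200):
            vals = []
            for s in range(n):
                try:
                    vals.append(polygon_descriptors(gen_hexagon_polygon(1.0, sd, s)).circularity)
                except Exception:
                    continue  # rare self-intersection at high noise
            return np.mean(vals)

        c_low, c_mid, c_high = mean_circ(0.02), mean_circ(0.1), mean_circ(0.25)
        assert c_low > c_mid > c_high


class TestPhototaxisCounts:
    def test_certainty_endpoints(self):
        all_in = gen_phototaxis_counts(35, 1.0, seed=0)
        none_in = gen_phototaxis_counts(35, 0.0, seed=0)
        assert all_in.tube_counts == (0, 0, 0, 35)
        assert none_in.tube_counts == (35, 0, 0, 0)

    def test_counts_sum_to_n(self):
        a = gen_phototaxis_counts(35, 0.6, seed=5)
        assert a.n_total == 35

    def test_tube_fractions_binomial(self):
        """Tube-k occupancy converges to C(3,k) p^k (1-p)^(3-k)."""
        from scipy.stats import binom

        p = 0.7
        totals = np.zeros(4)
        n_assays, n_flies = 1000, 35
        for s in range(n_assays):
            totals += gen_phototaxis_counts(n_flies, p, seed=s).tube_counts
        frac = totals / (n_assays * n_flies)
        np.testing.assert_allclose(frac, binom.pmf(np.arange(4), 3, p), atol=0.01)
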