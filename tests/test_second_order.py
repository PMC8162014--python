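"""Second-order statistics: K, L, g, CSR envelopes and classification."""

import numpy as np
import pytest

import fcspat as f
from fcspat.errors import (
    BadBandwidthError,
    BadRankError,
    StatisticMismatchError,
    TooFewPointsError,
    UnknownCorrectionError,
)
from fcspat.secondorder import Excursion, EnvelopeResult, find_excursions

from conftest import brute_force_k


def matern_g_theoretical(r, kappa, R):
    """Closed-form pair correlation of the Matern cluster process."""
    r = np.asarray(r, float)
    z = np.clip(r / (2 * R), 0, 1)
    overlap = 2 * R**2 * np.arccos(z) - (r / 2) * np.sqrt(
        np.maximum(4 * R**2 - r**2, 0)
    )
    return 1 + overlap / (kappa * (np.pi * R**2) ** 2)


class TestDistanceGrid:
    def test_regular_grid(self):
        g = f.DistanceGrid.regular(r_max=50, step=0.5)
        assert len(g) == 100
        assert g.r[0] == 0.5 and g.r_max == 50.0

    def test_zero_excluded(self):
        with pytest.raises(ValueError):
            f.DistanceGrid(r=np.array([0.0, 1.0]))

    def test_defaults_capped_by_window(self):
        win = f.ObservationWindow(0, 0, 800, 330)
        assert f.default_grid("g", win).r_max == 50.0
        assert f.default_grid("L", win).r_max == 165.0


class TestRipleyK:
    def test_zero_below_minimum_spacing(self, square_lattice):
        grid = f.DistanceGrid(r=np.array([0.5, 0.9]))
        k = f.ripley_k(square_lattice, grid, correction="none")
        assert np.all(k.values == 0)

    def test_three_point_hand_count(self):
        # (0,0),(0,1),(1,0): all 6 ordered pairs within 1.5 -> K = A/ (n(n-1)) * 6
        win = f.ObservationWindow(0, 0, 10, 10)
        pat = f.make_pattern([(0, 0), (0, 1), (1, 0)], win)
        k = f.ripley_k(pat, f.DistanceGrid(r=np.array([1.5])), correction="none")
        assert k.values[0] == pytest.approx(100.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_uncorrected_matches_brute_force(self, seed, plot_window):
        pat = f.simulate_csr(20, plot_window, seed=seed)
        grid = f.DistanceGrid.regular(200, 10.0)
        k = f.ripley_k(pat, grid, correction="none")
        assert np.allclose(k.values, brute_force_k(pat, grid.r), rtol=1e-12)

    def test_k_nonnegative_nondecreasing(self, random_pattern):
        k = f.ripley_k(random_pattern, f.DistanceGrid.regular(100, 2.0))
        assert np.all(k.values >= 0)
        assert np.all(np.diff(k.values) >= -1e-9)

    @pytest.mark.parametrize("correction", ["translation", "isotropic"])
    def test_csr_tracks_theory(self, correction, plot_window):
        pat = f.simulate_csr(800, plot_window, seed=9)
        grid = f.DistanceGrid.regular(100, 5.0)
        k = f.ripley_k(pat, grid, correction)
        assert np.max(np.abs(k.values / (np.pi * grid.r**2) - 1)) < 0.12

    def test_unknown_correction(self, random_pattern):
        with pytest.raises(UnknownCorrectionError):
            f.ripley_k(random_pattern, correction="border")

    def test_too_few_points(self, unit_window):
        pat = f.make_pattern([(1, 1)], unit_window)
        with pytest.raises(TooFewPointsError):
            f.ripley_k(pat)


class TestLFunction:
    def test_identity_on_csr_theory(self):
        grid = f.DistanceGrid.regular(50, 1.0)
        k = f.SecondOrderEstimate(
            "K", grid, np.pi * grid.r**2, edge_correction="none"
        )
        assert np.allclose(f.l_from_k(k).values, 0.0)

    def test_no_pairs_gives_minus_r(self):
        grid = f.DistanceGrid.regular(10, 1.0)
        k = f.SecondOrderEstimate("K", grid, np.zeros(10), edge_correction="none")
        assert np.allclose(f.l_from_k(k).values, -grid.r)

    def test_l_is_deterministic_transform_of_k(self, random_pattern):
        grid = f.DistanceGrid.regular(100, 2.0)
        k = f.ripley_k(random_pattern, grid)
        l = f.l_function(random_pattern, grid)
        assert np.array_equal(np.sqrt(k.values / np.pi) - grid.r, l.values)

    def test_cluster_process_positive_l(self, plot_window):
        pat = f.simulate_matern_cluster(
            40 / 250_000.0, 15.0, 4.0, plot_window, seed=6
        )
        l = f.l_function(pat, f.DistanceGrid.regular(60, 2.0))
        assert np.all(l.values[l.grid.r <= 30] > 0)


class TestPairCorrelation:
    def test_theoretical_reference_is_one(self, random_pattern):
        g = f.pair_correlation(random_pattern)
        assert np.all(g.theoretical == 1.0)

    def test_csr_band_around_one(self, plot_window):
        # band pinned by a pre-build simulation oracle (max dev 0.13 over 10 seeds)
        pat = f.simulate_csr(1000, plot_window, seed=100)
        g = f.pair_correlation(pat, f.DistanceGrid.regular(50, 0.5))
        sel = g.grid.r >= 5
        assert np.max(np.abs(g.values[sel] - 1)) < 0.15

    def test_perturbed_hex_trough_then_peak(self, plot_window):
        # spatially periodic signature: empty immediate neighborhood, then a
        # density peak near the lattice spacing
        pat = f.simulate_perturbed_lattice(12.0, 0.8, "hexagonal", plot_window, seed=1)
        g = f.pair_correlation(pat, f.DistanceGrid.regular(25, 0.5))
        r = g.grid.r
        assert np.all(g.values[r < 6] < 0.05)
        peak_r = r[np.argmax(g.values)]
        assert 10.0 <= peak_r <= 14.0
        assert g.values.max() > 1.5

    def test_hardcore_empty_below_inhibition(self, plot_window):
        pat = f.simulate_hardcore(200, 15.0, plot_window, seed=2)
        g = f.pair_correlation(pat, f.DistanceGrid.regular(30, 0.5), bandwidth=2.0)
        assert np.all(g.values[g.grid.r < 13.0] == 0)

    def test_matches_matern_closed_form(self, plot_window):
        kappa, R, mu = 100 / 250_000.0, 15.0, 12.0
        grid = f.DistanceGrid.regular(40, 1.0)
        est = np.zeros(len(grid))
        reps = 5
        for s in range(reps):
            p = f.simulate_matern_cluster(kappa, R, mu, plot_window, seed=s)
            est += f.pair_correlation(p, grid, bandwidth=1.5).values
        est /= reps
        theo = matern_g_theoretical(grid.r, kappa, R)
        sel = grid.r >= 3
        assert np.max(np.abs(est[sel] - theo[sel]) / theo[sel]) < 0.15

    def test_integrates_to_pair_count(self, plot_window):
        # sum g(r) 2 pi r lambda dr * n recovers the ordered pair count
        pat = f.simulate_csr(400, plot_window, seed=11)
        grid = f.DistanceGrid.regular(50, 0.5)
        g = f.pair_correlation(pat, grid, bandwidth=2.0, correction="none")
        lam = f.intensity(pat)
        approx = np.sum(g.values * 2 * np.pi * grid.r * lam * 0.5) * pat.n
        d = f.pairwise_distances(pat)
        exact = np.sum((d > 0) & (d <= 50))
        assert approx == pytest.approx(exact, rel=0.1)

    def test_bandwidth_validation(self, random_pattern):
        with pytest.raises(BadBandwidthError):
            f.pair_correlation(random_pattern, bandwidth=-1.0)

    def test_stoyan_auto_bandwidth_recorded(self, random_pattern):
        g = f.pair_correlation(random_pattern)
        lam = f.intensity(random_pattern)
        assert g.bandwidth == pytest.approx(0.15 / np.sqrt(lam))
        assert g.unreliable_mask.sum() > 0


class TestEnvelope:
    def test_lower_not_above_upper(self, random_pattern):
        env = f.csr_envelope(
            random_pattern, "g", n_sim=39, rank=2,
            grid=f.DistanceGrid.regular(30, 1.0), seed=0,
        )
        assert np.all(env.lower <= env.upper)

    def test_pointwise_level_rank_rule(self, random_pattern):
        env = f.csr_envelope(
            random_pattern, "g", n_sim=199, rank=5,
            grid=f.DistanceGrid.regular(20, 2.0), seed=0,
        )
        assert env.pointwise_level == pytest.approx(0.05)

    def test_deterministic_given_seed(self, random_pattern):
        grid = f.DistanceGrid.regular(20, 2.0)
        e1 = f.csr_envelope(random_pattern, "L", n_sim=39, rank=1, grid=grid, seed=3)
        e2 = f.csr_envelope(random_pattern, "L", n_sim=39, rank=1, grid=grid, seed=3)
        assert np.array_equal(e1.lower, e2.lower)
        assert np.array_equal(e1.upper, e2.upper)

    def test_bad_rank(self, random_pattern):
        with pytest.raises(BadRankError):
            f.csr_envelope(random_pattern, "g", n_sim=39, rank=25, seed=0)

    def test_cluster_l_overshoots_upper_envelope(self, plot_window):
        # strong aggregation pushes the cumulative statistic far above CSR
        pat = f.simulate_matern_cluster(
            40 / 250_000.0, 15.0, 4.0, plot_window, seed=8
        )
        env = f.csr_envelope(
            pat, "L", n_sim=99, rank=3,
            grid=f.DistanceGrid.regular(100, 2.0), seed=9,
        )
        above = [e for e in env.excursions if e.sign == "above"]
        assert above and min(e.r_start for e in above) < 30


class TestExcursions:
    def test_runs_merged_and_signed(self):
        r = np.arange(1.0, 8.0)
        lower = np.zeros(7)
        upper = np.ones(7)
        obs = np.array([0.5, -1.0, -2.0, 0.5, 2.0, 2.0, 0.5])
        exc = find_excursions(r, obs, lower, upper)
        assert [(e.sign, e.r_start, e.r_end) for e in exc] == [
            ("below", 2.0, 3.0),
            ("above", 5.0, 6.0),
        ]
        assert exc[0].n_points == 2

    def test_strict_inequality(self):
        r = np.arange(1.0, 4.0)
        exc = find_excursions(r, np.zeros(3), np.zeros(3), np.ones(3))
        assert exc == []


def _mk_envelope(r, obs, lower, upper):
    grid = f.DistanceGrid(r=r)
    est = f.SecondOrderEstimate("g", grid, obs, edge_correction="translation",
                                bandwidth=1.0)
    return EnvelopeResult(
        estimate=est, lower=lower, upper=upper, n_sim=199, rank=5,
        excursions=find_excursions(r, obs, lower, upper),
    )


def _mk_nn(pattern_label, mean_nn=10.0):
    return f.ClarkEvansResult(
        label="x", n=100, mean_nn_observed=mean_nn, mean_nn_expected=10.0,
        R=mean_nn / 10.0, cv_nn=20.0, p_value=0.002, n_sim=999, alpha=0.05,
        pattern_label=pattern_label,
    )


class TestClassifyPattern:
    r = np.arange(1.0, 21.0)
    lower = np.full(20, 0.8)
    upper = np.full(20, 1.2)

    def test_trough_then_peak_is_periodic(self):
        obs = np.ones(20)
        obs[2:7] = 0.0     # trough at small r
        obs[8:12] = 2.0    # peak near mean NN distance (10 m)
        env = _mk_envelope(self.r, obs, self.lower, self.upper)
        assert f.classify_pattern(env, _mk_nn("Regular")) == "spatially_periodic"

    def test_periodic_requires_regular_nn_label(self):
        obs = np.ones(20)
        obs[2:7] = 0.0
        obs[8:12] = 2.0
        env = _mk_envelope(self.r, obs, self.lower, self.upper)
        assert f.classify_pattern(env, _mk_nn("Random")) == "mixed"

    def test_peak_without_preceding_trough_is_not_periodic(self):
        obs = np.ones(20)
        obs[0:5] = 3.0     # immediate aggregation
        env = _mk_envelope(self.r, obs, self.lower, self.upper)
        assert f.classify_pattern(env, _mk_nn("Clustered")) == "clustered"

    def test_peak_far_from_mean_nn_not_periodic(self):
        obs = np.ones(20)
        obs[2:5] = 0.0
        obs[17:20] = 2.0   # peak at ~2x mean NN: outside the window
        env = _mk_envelope(self.r, obs, self.lower, self.upper)
        assert f.classify_pattern(env, _mk_nn("Regular")) == "mixed"

    def test_quiet_curve_follows_nn_label(self):
        obs = np.ones(20)
        env = _mk_envelope(self.r, obs, self.lower, self.upper)
        assert f.classify_pattern(env, _mk_nn("Random")) == "random"
        assert f.classify_pattern(env, _mk_nn("Regular")) == "regular"

    def test_single_point_blips_ignored(self):
        obs = np.ones(20)
        obs[3] = 0.0
        obs[10] = 2.0      # 1-point excursions are envelope noise
        env = _mk_envelope(self.r, obs, self.lower, self.upper)
        assert f.classify_pattern(env, _mk_nn("Random")) == "random"

    def test_requires_g_statistic(self, random_pattern):
        env = f.csr_envelope(
            random_pattern, "L", n_sim=39, rank=1,
            grid=f.DistanceGrid.regular(20, 2.0), seed=0,
        )
        with pytest.raises(StatisticMismatchError):
            f.classify_pattern(env, _mk_nn("Random"))

    def test_perturbed_hex_end_to_end(self, plot_window):
        pat = f.simulate_perturbed_lattice(12.0, 1.5, "hexagonal", plot_window, seed=5)
        nn = f.clark_evans_test(pat, n_sim=199, seed=6)
        env = f.csr_envelope(
            pat, "g", n_sim=199, rank=5,
            grid=f.DistanceGrid.regular(25, 0.5), seed=7,
        )
        assert f.classify_pattern(env, nn) == "spatially_periodic"

    def test_matern_end_to_end(self, plot_window):
        pat = f.REGIME_PRESETS["Euphorbia_clustered"].simulate(seed=5)
        nn = f.clark_evans_test(pat, n_sim=199, seed=6)
        env = f.csr_envelope(
            pat, "g", n_sim=199, rank=5,
            grid=f.DistanceGrid.regular(25, 0.5), seed=7,
        )
        assert f.classify_pattern(env, nn) == "clustered"
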