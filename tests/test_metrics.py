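"""Spike-density, windowed rates, activation tests, sparseness, peak maps."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import sniffcode as sc
from sniffcode import metrics as met
from conftest import make_raster


class TestSpikeDensity:
    def test_empty_train_is_zero(self):
        grid, rate = sc.single_trial_sdf([], window=(-0.1, 0.3))
        assert np.all(rate == 0)

    def test_single_spike_peak_matches_gaussian(self):
        # unit-area Gaussian: peak = 1/(sigma*sqrt(2*pi)) ~ 39.89 spikes/s
        grid, rate = sc.single_trial_sdf([0.1], window=(-0.1, 0.3),
                                         sigma=0.010)
        peak = rate.max()
        assert peak == pytest.approx(1 / (0.010 * np.sqrt(2 * np.pi)),
                                     rel=0.01)
        assert abs(grid[np.argmax(rate)] - 0.1) <= 0.001

    def test_integral_equals_spike_count(self):
        rng = np.random.default_rng(0)
        spikes = rng.uniform(0.0, 0.2, size=37)
        grid, rate = sc.single_trial_sdf(spikes, window=(-0.3, 0.5),
                                         sigma=0.010, step=0.001)
        assert rate.sum() * 0.001 == pytest.approx(37, rel=1e-3)

    def test_sigma_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            sc.single_trial_sdf([0.1], window=(-0.1, 0.3), sigma=0.0)

    def test_linearity_in_spike_trains(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 0.25, size=11)
        b = rng.uniform(0, 0.25, size=7)
        _, ra = sc.single_trial_sdf(a, window=(-0.1, 0.3))
        _, rb = sc.single_trial_sdf(b, window=(-0.1, 0.3))
        _, rab = sc.single_trial_sdf(np.concatenate([a, b]),
                                     window=(-0.1, 0.3))
        assert np.allclose(rab, ra + rb, atol=1e-9)

    def test_condition_sdf_matches_trial_average(self):
        raster = make_raster({("u0", 0): [0.05, 0.10], ("u0", 1): [0.06]})
        sdf = sc.condition_sdf(raster)
        _, r0 = sc.single_trial_sdf([0.05, 0.10], window=(-0.1, 0.3))
        _, r1 = sc.single_trial_sdf([0.06], window=(-0.1, 0.3))
        assert np.allclose(sdf.rate[0], (r0 + r1) / 2, atol=1e-6)


class TestWindowRate:
    def test_counts_over_length(self):
        raster = make_raster({("u0", 0): [0.06, 0.07, 0.12]})
        out = sc.window_rate(raster, (0.05, 0.10))
        assert out["rate"].iloc[0] == pytest.approx(40.0)

    def test_empty_train_zero(self):
        raster = make_raster({("u0", 0): []})
        out = sc.window_rate(raster, (0.05, 0.10))
        assert out["rate"].iloc[0] == 0.0

    def test_right_edge_excluded(self):
        raster = make_raster({("u0", 0): [0.10]})
        out = sc.window_rate(raster, (0.05, 0.10))
        assert out["rate"].iloc[0] == 0.0

    def test_zero_length_window_rejected(self):
        raster = make_raster({("u0", 0): [0.06]})
        with pytest.raises(ValueError):
            sc.window_rate(raster, (0.05, 0.05))


class TestActivatedUnits:
    def _tables(self, odor, blank):
        n = len(odor)
        trials = pd.DataFrame({
            "trial_id": np.arange(2 * n),
            "odor_id": ["odor01"] * n + ["blank"] * n,
            "concentration": [1.0] * n + [0.0] * n,
        })
        rates = pd.DataFrame({
            "unit_id": ["u0"] * 2 * n,
            "trial_id": np.arange(2 * n),
            "rate": np.concatenate([odor, blank]),
        })
        return rates, trials

    def test_identical_rates_not_activated(self):
        r = np.array([5.0, 6.0, 4.0, 5.0, 7.0])
        rates, trials = self._tables(r, r)
        out = sc.activated_units(rates, trials)
        assert not out["activated"].iloc[0]

    def test_uniform_shift_activated(self):
        blank = np.full(25, 5.0) + np.arange(25) * 0.01
        rates, trials = self._tables(blank + 10.0, blank)
        out = sc.activated_units(rates, trials)
        assert out["activated"].iloc[0]
        assert out["delta_rate"].iloc[0] == pytest.approx(10.0)

    def test_type_one_error_near_alpha(self):
        # equal-rate Poisson counts: one-sided test flags ~5% of pairs
        rng = np.random.default_rng(42)
        n_pairs, n_trials = 1000, 25
        odor = rng.poisson(3.0, size=(n_pairs, n_trials)).astype(float)
        blank = rng.poisson(3.0, size=(n_pairs, n_trials)).astype(float)
        delta, p = met.paired_increase_test(odor, blank)
        frac = np.mean((delta > 0) & (p < 0.05))
        ci = 2.576 * np.sqrt(0.05 * 0.95 / n_pairs)
        assert abs(frac - 0.05) < ci


class TestLifetimeSparseness:
    def test_single_responsive_odor_is_one(self):
        r = np.zeros(11)
        r[0] = 3.5
        assert sc.lifetime_sparseness(r) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_response_is_zero(self):
        assert sc.lifetime_sparseness(np.full(11, 2.0)) == pytest.approx(
            0.0, abs=1e-12)

    def test_hand_evaluated_example(self):
        # r=[2,1,0,0]: S = (1 - (3/4)^2/(5/4)) / (3/4) = 11/15
        assert sc.lifetime_sparseness([2, 1, 0, 0]) == pytest.approx(11 / 15)

    def test_negative_clipped_before_formula(self):
        assert sc.lifetime_sparseness([-1, 2]) == pytest.approx(
            sc.lifetime_sparseness([0, 2]))
        assert sc.lifetime_sparseness([-1, 2]) == pytest.approx(1.0)

    def test_all_zero_undefined(self):
        assert np.isnan(sc.lifetime_sparseness([0.0, 0.0, 0.0]))

    def test_fewer_than_two_odors_rejected(self):
        with pytest.raises(ValueError):
            sc.lifetime_sparseness([1.0])

    @given(st.lists(st.floats(min_value=-50, max_value=50,
                              allow_nan=False)
                    .filter(lambda x: x == 0 or abs(x) > 1e-3),
                    min_size=2, max_size=12),
           st.floats(min_value=0.1, max_value=10))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_scale_invariant_and_bounded(self, r, scale):
        r = np.asarray(r)
        s = sc.lifetime_sparseness(r)
        if np.isnan(s):
            return
        assert -1e-9 <= s <= 1 + 1e-9
        assert sc.lifetime_sparseness(r * scale) == pytest.approx(s, abs=1e-9)


class TestHistogram:
    def _activation(self, activated):
        units, odors = activated.shape
        rows = [(f"u{i}", f"odor{j}", 1.0, 0.01, 1.0, bool(activated[i, j]),
                 True)
                for i in range(units) for j in range(odors)]
        return pd.DataFrame(rows, columns=["unit_id", "odor_id",
                                           "concentration", "p",
                                           "delta_rate", "activated",
                                           "test_valid"])

    def test_no_activation_all_in_bin_zero(self):
        hist, per_odor = sc.responsive_count_histogram(
            self._activation(np.zeros((5, 3), dtype=bool)))
        assert hist[0] == 5 and hist[1:].sum() == 0
        assert (per_odor["pct_activated"] == 0).all()

    def test_full_activation_all_in_top_bin(self):
        hist, per_odor = sc.responsive_count_histogram(
            self._activation(np.ones((5, 3), dtype=bool)))
        assert hist[3] == 5 and hist.sum() == 5
        assert (per_odor["pct_activated"] == 100).all()

    def test_mean_responsive_count_matches_binomial(self):
        rng = np.random.default_rng(3)
        act = rng.random((400, 11)) < 0.15
        hist, _ = sc.responsive_count_histogram(self._activation(act))
        mean_count = np.average(np.arange(12), weights=hist)
        se = np.sqrt(11 * 0.15 * 0.85 / 400)
        assert abs(mean_count - 11 * 0.15) < 3 * se


class TestRankOrder:
    def test_identical_trials_give_diagonal_ridge(self):
        spike_map = {}
        peaks = {"u0": 0.05, "u1": 0.15, "u2": 0.25}
        for u, pk in peaks.items():
            for t in range(4):
                spike_map[(u, t)] = [pk]
        out = sc.rank_order_crossval(make_raster(spike_map))
        assert np.allclose(out["peak_time_odd"], out["peak_time_even"])
        assert list(out["pairs"]["unit_id"]) == ["u0", "u1", "u2"]
        # even-trial row maxima at the odd-trial sort key
        ridge = out["grid"][np.argmax(out["matrix"], axis=1)]
        assert np.allclose(ridge, out["peak_time_odd"], atol=1e-9)

    def test_distinct_programmed_latencies_crossvalidate(self):
        # units with widely spread programmed latencies: odd-trial peak
        # times predict even-trial peaks (Spearman > 0.9 over pairs)
        cfg = sc.GeneratorConfig(
            classes={"fan": sc.ClassParams(n_units=30, latency_mean=0.15)},
            n_odors=3, concentrations=(1.0,), trials_per_condition=25,
            response_prob=1.0, amplitude_mean=30.0, amplitude_sd=0.0,
            latency_sd=0.06, latency_sd_shift_per_doubling=0.0,
            n_blank_trials=0)
        trace, trials, spikes, gt = sc.simulate_session(cfg, seed=77)
        raster = sc.build_raster(
            spikes, sc.align_trials(trials, trace.true_onsets))
        out = sc.rank_order_crossval(raster)
        rho, _ = stats.spearmanr(out["peak_time_odd"], out["peak_time_even"])
        assert rho > 0.9

    def test_shuffled_spikes_decorrelate(self):
        rng = np.random.default_rng(8)
        spike_map = {(f"u{i}", t): list(rng.uniform(-0.1, 0.3, size=5))
                     for i in range(40) for t in range(10)}
        out = sc.rank_order_crossval(make_raster(spike_map))
        rho, p = stats.spearmanr(out["peak_time_odd"],
                                 out["peak_time_even"])
        assert abs(rho) < 0.35  # ~null correlation for 40 random pairs


class TestEarlyLate:
    def test_early_only_responses(self, small_raster):
        act_early = sc.activated_units(
            sc.window_rate(small_raster, (0.0, 0.100)), small_raster.trials)
        act_late = sc.activated_units(
            sc.window_rate(small_raster, (0.200, 0.300)),
            small_raster.trials)
        out = sc.early_late_fractions(act_early, act_late)
        # generator bumps are early (<100 ms): early fraction dominates and
        # the late fraction stays near the false-positive level
        assert out["early_pct"].mean() > out["late_pct"].mean()
        assert out["late_pct"].mean() < 15.0

    def test_identical_matrices_equal_percentages(self, small_raster):
        act = sc.activated_units(
            sc.window_rate(small_raster, (0.0, 0.100)), small_raster.trials)
        out = sc.early_late_fractions(act, act)
        assert np.allclose(out["early_pct"], out["late_pct"])
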