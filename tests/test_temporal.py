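"""Peak-time extraction, concentration trends, synchrony statistics."""

import numpy as np
import pandas as pd
import pytest

import sniffcode as sc
from sniffcode import metrics as met
from sniffcode import temporal as tem
from conftest import make_raster


def sdf_from_rows(rows, grid=None):
    """SpikeDensity from {(unit, odor, conc): rate_array}."""
    keys = list(rows)
    rate = np.vstack([rows[k] for k in keys])
    if grid is None:
        grid = (np.arange(rate.shape[1]) + 0.5) * 0.001
    index = pd.DataFrame(keys, columns=["unit_id", "odor_id",
                                        "concentration"])
    return sc.SpikeDensity(grid=grid, rate=rate, index=index, sigma=0.010,
                           step=0.001)


def peaks_frame(records):
    """PeakStats frame from (unit, odor, conc, peak_time[, activated])."""
    rows = []
    for r in records:
        u, o, c, t = r[:4]
        act = r[4] if len(r) > 4 else True
        rows.append((u, o, c, t, 10.0, act))
    return pd.DataFrame(rows, columns=["unit_id", "odor_id", "concentration",
                                       "peak_time_s", "peak_rate",
                                       "activated"])


class TestPeakStats:
    def test_gaussian_bump_peak_time(self):
        grid = (np.arange(300) + 0.5) * 0.001
        rate = 20 * np.exp(-0.5 * ((grid - 0.080) / 0.02) ** 2)
        sdf = sdf_from_rows({("u0", "o0", 1.0): rate}, grid=grid)
        out = tem.peak_stats(sdf)
        assert out["peak_time_s"].iloc[0] == pytest.approx(0.080, abs=0.001)
        assert out["peak_rate"].iloc[0] == pytest.approx(20.0, rel=1e-3)

    def test_tie_resolves_to_earliest(self):
        rate = np.zeros(300)
        rate[60] = rate[120] = 5.0
        sdf = sdf_from_rows({("u0", "o0", 1.0): rate})
        out = tem.peak_stats(sdf)
        assert out["peak_time_s"].iloc[0] == pytest.approx(0.0605)

    def test_generator_latency_recovered(self):
        cfg = sc.GeneratorConfig(
            classes={"fan": sc.ClassParams(n_units=1, latency_mean=0.075)},
            n_odors=1, concentrations=(1.0,), trials_per_condition=25,
            response_prob=1.0, amplitude_mean=30.0, amplitude_sd=0.0,
            latency_sd=0.0, latency_sd_shift_per_doubling=0.0,
            n_blank_trials=0)
        trace, trials, spikes, gt = sc.simulate_session(cfg, seed=5)
        raster = sc.build_raster(
            spikes, sc.align_trials(trials, trace.true_onsets))
        sdf = met.condition_sdf(raster)
        out = tem.peak_stats(sdf)
        assert abs(out["peak_time_s"].iloc[0] - 0.075) <= 0.005

    def test_empty_window_rejected(self):
        sdf = sdf_from_rows({("u0", "o0", 1.0): np.zeros(300)})
        with pytest.raises(ValueError):
            tem.peak_stats(sdf, search_window=(0.1, 0.1))


class TestConcentrationTrend:
    def test_perfect_monotone_decrease(self):
        recs = [(f"u{i}", "o0", c, 0.1 - 0.01 * k)
                for i in range(10) for k, c in enumerate([0.25, 0.5, 1.0])]
        out = tem.concentration_trend(peaks_frame(recs))
        assert out.rho == pytest.approx(-1.0)

    def test_independent_variable_near_zero(self):
        rng = np.random.default_rng(0)
        recs = [(f"u{i}", "o0", c, rng.uniform(0.05, 0.15))
                for i in range(200) for c in [0.25, 0.5, 1.0]]
        out = tem.concentration_trend(peaks_frame(recs))
        # null CI for Spearman with n=600: ~2.58/sqrt(n)
        assert abs(out.rho) < 2.58 / np.sqrt(out.n) + 0.02

    def test_constant_variable_flagged_undefined(self):
        recs = [(f"u{i}", "o0", c, 0.08)
                for i in range(10) for c in [0.5, 1.0]]
        out = tem.concentration_trend(peaks_frame(recs))
        assert out.undefined and np.isnan(out.rho)

    def test_class_dissociation_recovered(self):
        # shifting class: significantly negative trend; invariant class:
        # trend inside the null interval (the tagged-population contrast)
        rng = np.random.default_rng(1)
        concs = [0.25, 0.5, 1.0]
        pyr = [(f"p{i}", "o0", c, 0.078 - 0.010 * np.log2(c)
                + rng.normal(0, 0.008))
               for i in range(150) for c in concs]
        fan = [(f"f{i}", "o0", c, 0.072 + rng.normal(0, 0.008))
               for i in range(150) for c in concs]
        t_pyr = tem.concentration_trend(peaks_frame(pyr))
        t_fan = tem.concentration_trend(peaks_frame(fan))
        assert t_pyr.rho < 0 and t_pyr.p_value < 0.001
        assert abs(t_fan.rho) < 2.58 / np.sqrt(t_fan.n) + 0.02


class TestPairwiseDiff:
    def test_three_peaks_enumeration(self):
        recs = [("u0", "o0", 1.0, 0.010), ("u1", "o0", 1.0, 0.020),
                ("u2", "o0", 1.0, 0.040)]
        mean, tab = tem.pairwise_peak_time_diff(peaks_frame(recs), 1.0)
        assert mean == pytest.approx(0.020)  # (10+30+20)/3 ms

    def test_equal_peaks_zero(self):
        recs = [(f"u{i}", "o0", 1.0, 0.080) for i in range(5)]
        mean, _ = tem.pairwise_peak_time_diff(peaks_frame(recs), 1.0)
        assert mean == pytest.approx(0.0, abs=1e-12)

    def test_shrinking_variance_decreases_diff(self):
        rng = np.random.default_rng(2)
        recs = []
        for k, (c, sd) in enumerate(zip([0.25, 0.5, 1.0],
                                        [0.030, 0.020, 0.010])):
            for i in range(60):
                recs.append((f"u{i}", "o0", c,
                             0.08 + rng.normal(0, sd)))
        df = peaks_frame(recs)
        means = [tem.pairwise_peak_time_diff(df, c)[0]
                 for c in [0.25, 0.5, 1.0]]
        assert means[0] > means[1] > means[2]

    def test_single_response_undefined(self):
        recs = [("u0", "o0", 1.0, 0.08)]
        mean, tab = tem.pairwise_peak_time_diff(peaks_frame(recs), 1.0)
        assert np.isnan(mean) and len(tab) == 0


class TestCrossPopulation:
    def test_constant_offset(self):
        a = peaks_frame([(f"a{i}", "o0", 1.0, 0.072) for i in range(4)])
        b = peaks_frame([(f"b{i}", "o0", 1.0, 0.092) for i in range(3)])
        out = sc.cross_population_synchrony(a, b)
        assert out["mean_diff_s"].iloc[0] == pytest.approx(0.020)

    def test_shift_arithmetic(self):
        # class B moves 10 ms earlier at the doubled concentration while
        # class A stays fixed: the between-class gap shrinks by 10 ms
        a = peaks_frame([(f"a{i}", "o0", c, 0.072)
                         for i in range(3) for c in [0.5, 1.0]])
        b = peaks_frame([(f"b{i}", "o0", 0.5, 0.092) for i in range(3)]
                        + [(f"b{i}", "o0", 1.0, 0.082) for i in range(3)])
        out = sc.cross_population_synchrony(a, b).set_index("concentration")
        assert out.loc[0.5, "mean_diff_s"] - out.loc[1.0, "mean_diff_s"] \
            == pytest.approx(0.010)

    def test_generator_classes_synchronize_with_concentration(self):
        # fan-like fixed latency, pyramidal-like shifting earlier: the
        # between-class peak-time gap decreases monotonically
        rng = np.random.default_rng(3)
        concs = [0.25, 0.33, 0.5, 1.0]
        fan = [(f"f{i}", f"o{j}", c, 0.072 + rng.normal(0, 0.002))
               for i in range(25) for j in range(3) for c in concs]
        pyr = [(f"p{i}", f"o{j}", c,
                0.078 - 0.010 * np.log2(c / 1.0) + rng.normal(0, 0.002))
               for i in range(25) for j in range(3) for c in concs]
        out = sc.cross_population_synchrony(
            peaks_frame(fan), peaks_frame(pyr)).sort_values("concentration")
        d = out["mean_diff_s"].to_numpy()
        assert np.all(np.diff(d) < 0)

    def test_empty_class_rejected(self):
        a = peaks_frame([("a0", "o0", 1.0, 0.072)])
        with pytest.raises(ValueError):
            sc.cross_population_synchrony(a, peaks_frame([]))


class TestShiftRegression:
    def test_programmed_shift_recovered(self):
        rng = np.random.default_rng(4)
        recs = [(f"u{i}", "o0", c,
                 0.078 - 0.010 * np.log2(c) + rng.normal(0, 0.005))
                for i in range(100) for c in [0.25, 0.33, 0.5, 1.0]]
        slope, se = tem.latency_shift_regression(peaks_frame(recs))
        assert slope == pytest.approx(-0.010, abs=0.003)


class TestInvariances:
    def test_peak_time_invariant_to_rate_scaling(self):
        grid = (np.arange(300) + 0.5) * 0.001
        rate = np.exp(-0.5 * ((grid - 0.07) / 0.02) ** 2)
        a = tem.peak_stats(sdf_from_rows({("u0", "o0", 1.0): rate},
                                         grid=grid))
        b = tem.peak_stats(sdf_from_rows({("u0", "o0", 1.0): 7 * rate},
                                         grid=grid))
        assert a["peak_time_s"].iloc[0] == b["peak_time_s"].iloc[0]

    def test_zero_diff_iff_all_equal(self):
        same = peaks_frame([(f"u{i}", "o0", 1.0, 0.08) for i in range(4)])
        diff = peaks_frame([(f"u{i}", "o0", 1.0, 0.08 + 0.001 * i)
                            for i in range(4)])
        assert tem.pairwise_peak_time_diff(same, 1.0)[0] == 0.0
        assert tem.pairwise_peak_time_diff(diff, 1.0)[0] > 0.0
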