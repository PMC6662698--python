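import numpy as np
import pytest

import attractormem as am
from attractormem.model_free import (
    attractor_alignment,
    bias_precision_profile,
    circular_entropy_bits,
    circular_kde,
    clustering_metric,
    error_growth_at_fixed_points,
    find_response_peaks,
    fit_basic_mixture,
    hodges_ajne_pvalue,
    kuiper_two_sample_stat,
    nonuniformity_tests,
)


def make_dataset(targets, reports, load=1, delay=1.0):
    trials = [am.TrialRecord("s", load, delay, float(t % 360), (),
                             float(r % 360), i)
              for i, (t, r) in enumerate(zip(targets, reports))]
    return am.Dataset(trials)


class TestClusteringMetric:
    def test_identical_samples_give_zero(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 360, 5000)
        res = clustering_metric(x, x)
        assert res.C == 0.0
        assert res.H_resp == res.H_targ

    def test_resampled_targets_near_zero(self):
        rng = np.random.default_rng(1)
        targets = rng.uniform(0, 360, 5000)
        reports = rng.choice(targets, 5000, replace=True)
        res = clustering_metric(reports, targets)
        assert abs(res.C) < 0.02

    def test_clustered_reports_negative(self):
        rng = np.random.default_rng(2)
        targets = rng.uniform(0, 360, 4000)
        modes = np.array([10.0, 100.0, 190.0, 280.0])
        reports = (modes[rng.integers(4, size=4000)]
                   + np.rad2deg(rng.vonmises(0, 1 / np.deg2rad(15) ** 2, 4000)))
        res = clustering_metric(reports % 360, targets)
        assert res.C < -0.05

    def test_guess_rate_subtraction(self):
        """Adding uniform lapses and then removing a matched uniform component
        restores the clustering estimate of the lapse-free reports."""
        rng = np.random.default_rng(3)
        n = 6000
        targets = rng.uniform(0, 360, n)
        modes = np.array([0.0, 90.0, 180.0, 270.0])
        clean = (modes[rng.integers(4, size=n)]
                 + np.rad2deg(rng.vonmises(0, 1 / np.deg2rad(12) ** 2, n))) % 360
        lapse = rng.random(n) < 0.3
        mixed = np.where(lapse, rng.uniform(0, 360, n), clean)
        c_clean = clustering_metric(clean, targets).C
        c_raw = clustering_metric(mixed, targets).C
        c_corr = clustering_metric(mixed, targets, guess_rate=0.3).C
        assert abs(c_corr - c_clean) < abs(c_raw - c_clean)

    def test_subsampling_equalizes_conditions(self):
        rng = np.random.default_rng(4)
        targets = rng.uniform(0, 360, 900)
        conditions = np.array([0] * 600 + [1] * 300)
        res = clustering_metric(targets, targets, conditions=conditions, seed=0)
        assert res.n_trials_used == 600  # 300 per condition

    def test_invalid_guess_rate(self):
        with pytest.raises(ValueError):
            clustering_metric([0.0] * 10, [0.0] * 10, guess_rate=1.0)


class TestMixtureScreen:
    def test_clean_reports_low_guess_rate(self):
        rng = np.random.default_rng(5)
        targets = rng.uniform(0, 360, 2000)
        reports = (targets + np.rad2deg(rng.vonmises(0, 30, 2000))) % 360
        fit = fit_basic_mixture(make_dataset(targets, reports))
        assert fit.p_guess < 0.05
        assert fit.exclude is False

    def test_uniform_reports_excluded(self):
        rng = np.random.default_rng(6)
        targets = rng.uniform(0, 360, 2000)
        reports = rng.uniform(0, 360, 2000)
        fit = fit_basic_mixture(make_dataset(targets, reports))
        assert fit.p_guess > 0.9
        assert fit.exclude is True

    def test_half_blend_recovers_rate(self):
        rng = np.random.default_rng(7)
        n = 2000
        targets = rng.uniform(0, 360, n)
        guessing = rng.random(n) < 0.5
        reports = np.where(guessing, rng.uniform(0, 360, n),
                           (targets + np.rad2deg(rng.vonmises(0, 30, n))) % 360)
        fit = fit_basic_mixture(make_dataset(targets, reports))
        assert fit.p_guess == pytest.approx(0.5, abs=0.05)

    def test_swap_component_detected(self):
        rng = np.random.default_rng(8)
        n = 2000
        targets = rng.uniform(0, 360, n)
        nontargets = (targets + 120.0) % 360
        swap = rng.random(n) < 0.25
        reports = (np.where(swap, nontargets, targets)
                   + np.rad2deg(rng.vonmises(0, 30, n))) % 360
        trials = [am.TrialRecord("s", 2, 1.0, float(t), (float(nt),), float(r), i)
                  for i, (t, nt, r) in enumerate(zip(targets, nontargets, reports))]
        fit = fit_basic_mixture(am.Dataset(trials))
        assert fit.p_swap == pytest.approx(0.25, abs=0.05)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            fit_basic_mixture(make_dataset(np.zeros(10), np.zeros(10)))


class TestNonuniformity:
    def test_half_circle_concentration(self):
        rng = np.random.default_rng(9)
        reports = rng.uniform(0, 170, 50)
        assert hodges_ajne_pvalue(reports) < 1e-6

    def test_evenly_spaced_is_uniform(self):
        reports = np.arange(0, 360, 3.6)
        assert hodges_ajne_pvalue(reports) == pytest.approx(1.0)

    def test_kuiper_detects_shifted_distribution(self):
        rng = np.random.default_rng(10)
        targets = rng.uniform(0, 360, 300)
        reports = (np.rad2deg(rng.vonmises(np.pi, 2.0, 300))) % 360
        out = nonuniformity_tests(reports, targets, n_perm=200, seed=0)
        assert out["kuiper_perm_p"] < 0.01

    def test_kuiper_stat_rotation_invariant(self):
        rng = np.random.default_rng(11)
        a = rng.uniform(0, 360, 200)
        b = rng.vonmises(1.0, 1.0, 200)
        b = np.rad2deg(b) % 360
        v1 = kuiper_two_sample_stat(a, b)
        v2 = kuiper_two_sample_stat((a + 77.0) % 360, (b + 77.0) % 360)
        assert v2 == pytest.approx(v1, abs=0.02)

    def test_seed_reproducible(self):
        rng = np.random.default_rng(12)
        t = rng.uniform(0, 360, 150)
        r = rng.uniform(0, 360, 150)
        p1 = nonuniformity_tests(r, t, n_perm=150, seed=5)["kuiper_perm_p"]
        p2 = nonuniformity_tests(r, t, n_perm=150, seed=5)["kuiper_perm_p"]
        assert p1 == p2


class TestResponsePeaks:
    def test_four_mode_mixture_found(self):
        rng = np.random.default_rng(13)
        n = 4000
        targets = rng.uniform(0, 360, n)
        modes = np.array([17.0, 107.0, 197.0, 287.0])
        memory = rng.random(n) < 0.7
        reports = np.where(
            memory,
            (modes[rng.integers(4, size=n)]
             + np.rad2deg(rng.vonmises(0, 1 / np.deg2rad(10) ** 2, n))) % 360,
            rng.uniform(0, 360, n))
        peaks = find_response_peaks(reports, targets, n_boot=300, seed=1)
        assert len(peaks) == 4
        for m in modes:
            assert np.min(np.abs(am.circ_error(peaks.angles_deg, m))) < 5.0

    def test_same_seed_identical(self):
        rng = np.random.default_rng(14)
        t = rng.uniform(0, 360, 400)
        r = rng.uniform(0, 360, 400)
        p1 = find_response_peaks(r, t, n_boot=100, seed=3)
        p2 = find_response_peaks(r, t, n_boot=100, seed=3)
        assert np.array_equal(p1.angles_deg, p2.angles_deg)
        assert p1.threshold == p2.threshold


class TestBiasProfile:
    def test_rotation_equivariance(self, strong_drift_dataset):
        ds = strong_drift_dataset
        delta = 36.0  # multiple of the bin width, so bins relabel exactly
        rotated = am.Dataset([
            am.TrialRecord(t.subject, t.load, t.delay_s,
                           (t.target_deg + delta) % 360, t.nontargets_deg,
                           (t.report_deg + delta) % 360, t.trial_index)
            for t in ds.trials])
        anchors = np.array([0.0, 90.0])
        p1 = bias_precision_profile(ds, 4.0, anchors)
        p2 = bias_precision_profile(rotated, 4.0, (anchors + delta) % 360)
        assert np.allclose(p1.slopes, p2.slopes, atol=1e-9)
        shift = int(delta / 4.0)
        assert np.allclose(np.roll(p1.bias_deg, shift), p2.bias_deg,
                           atol=1e-9, equal_nan=True)

    def test_no_drift_slopes_near_zero(self):
        rng = np.random.default_rng(15)
        n = 20000
        targets = rng.uniform(0, 360, n)
        reports = (targets + np.rad2deg(rng.vonmises(0, 20, n))) % 360
        prof = bias_precision_profile(make_dataset(targets, reports), 4.0,
                                      anchors_deg=[0.0, 90.0, 180.0, 270.0])
        assert np.all(np.abs(prof.slopes) < 0.08)

    def test_bad_bin_width_rejected(self, strong_drift_dataset):
        with pytest.raises(ValueError):
            bias_precision_profile(strong_drift_dataset, 7.0)

    def test_counts_partition_trials(self, strong_drift_dataset):
        prof = bias_precision_profile(strong_drift_dataset, 6.0)
        assert prof.counts.sum() == len(strong_drift_dataset)


class TestErrorGrowth:
    def test_no_drift_no_differential_growth(self, drift4):
        rng = np.random.default_rng(16)
        n = 8000
        targets = rng.uniform(0, 360, n)
        delays = rng.choice([1.0, 7.0], n)
        reports = (targets + np.rad2deg(
            0.25 * np.sqrt(delays) * rng.standard_normal(n))) % 360
        trials = [am.TrialRecord("s", 1, float(d), float(t), (), float(r), i)
                  for i, (d, t, r) in enumerate(zip(delays, targets, reports))]
        fps = am.find_fixed_points(drift4)
        out = error_growth_at_fixed_points(am.Dataset(trials), fps,
                                           n_boot=300, seed=0)
        assert abs(out["delta_err_ufp"] - out["delta_err_sfp"]) < 1.5
        assert out["p_value"] > 0.05

    def test_same_seed_identical_p(self, strong_drift_dataset, drift4):
        fps = am.find_fixed_points(drift4)
        a = error_growth_at_fixed_points(strong_drift_dataset, fps,
                                         n_boot=200, seed=4)
        b = error_growth_at_fixed_points(strong_drift_dataset, fps,
                                         n_boot=200, seed=4)
        assert a == b

    def test_single_delay_rejected(self, drift4):
        ds = make_dataset(np.arange(100, dtype=float),
                          np.arange(100, dtype=float))
        with pytest.raises(ValueError):
            error_growth_at_fixed_points(ds, am.find_fixed_points(drift4))


class TestAlignment:
    def test_exact_match_minimal_p(self):
        refs = [np.array([0.0, 90.0, 180.0, 270.0])] * 8
        atts = [r.copy() for r in refs]
        out = attractor_alignment(atts, refs, n_perm=300, seed=0)
        assert out["mean_distance_deg"] == pytest.approx(0.0)
        assert out["p_value"] <= 1.0 / 300

    def test_aligned_units_detected(self):
        rng = np.random.default_rng(17)
        refs, atts = [], []
        for _ in range(40):
            phase = rng.uniform(0, 90)
            r = (phase + np.arange(4) * 90.0) % 360
            refs.append(r)
            atts.append((r + rng.uniform(-10, 10, 4)) % 360)
        out = attractor_alignment(atts, refs, n_perm=400, seed=1)
        assert out["p_value"] < 0.01


class TestExports:
    def test_profile_frame(self, strong_drift_dataset):
        prof = bias_precision_profile(strong_drift_dataset, 6.0)
        frame = prof.to_frame()
        assert list(frame.columns) == ["bin_center_deg", "bias_deg", "sd_deg",
                                       "n_trials"]
        assert frame["n_trials"].sum() == len(strong_drift_dataset)

    def test_peak_frame(self):
        rng = np.random.default_rng(30)
        t = rng.uniform(0, 360, 400)
        r = (np.rad2deg(rng.vonmises(0.5, 3.0, 400))) % 360
        pk = find_response_peaks(r, t, n_boot=100, seed=0)
        frame = pk.to_frame()
        assert len(frame) == len(pk)
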