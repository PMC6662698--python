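import numpy as np
import pytest

import attractormem as am
from attractormem.core_io import ProbabilityField, TrialRecord
from attractormem.drift_field import eval_drift
from attractormem.dynamics import (
    DynamicsParams,
    LikelihoodEngine,
    MixtureParams,
    build_generator,
    encode,
    initial_density,
    propagate,
    report_distribution,
    trial_loglik,
)


def one_load_params(beta=0.5, sigma=0.2, beta_star=0.5, sigma_star=0.2):
    return DynamicsParams(beta={1: beta}, sigma={1: sigma},
                          beta_star={1: beta_star}, sigma_star={1: sigma_star})


def no_mixture():
    return MixtureParams(guess_slope={1: 0.0, 3: 0.0},
                         guess_intercept={1: 0.0, 3: 0.0})


class TestGenerator:
    def test_columns_conserve_and_offdiagonals_nonneg(self, drift4, grid100):
        rng = np.random.default_rng(8)
        for _ in range(5):
            beta = rng.uniform(0, 3)
            sigma = rng.uniform(0.05, 1.0)
            M = build_generator(drift4, beta, sigma, grid100).matrix
            assert np.all(np.abs(M.sum(axis=0)) < 1e-10)
            off = M - np.diag(np.diag(M))
            assert off.min() >= 0.0

    def test_pure_diffusion_symmetric_circulant(self, drift4, grid100):
        M = build_generator(drift4, 0.0, 0.3, grid100).matrix
        assert np.allclose(M, M.T)
        # circulant: every row is a rotation of the first
        for k in range(1, 5):
            assert np.allclose(np.roll(M[0], k), M[k])

    def test_negative_sigma_rejected(self, drift4):
        with pytest.raises(ValueError):
            build_generator(drift4, 1.0, -0.1)


class TestPropagate:
    def test_t_zero_identity(self, drift4, grid100):
        p0 = initial_density(1.0, grid100)
        p = propagate(p0, build_generator(drift4, 1.0, 0.2), 0.0)
        assert np.allclose(p.values, p0.values)

    def test_negative_t_rejected(self, drift4, grid100):
        p0 = initial_density(1.0, grid100)
        with pytest.raises(ValueError):
            propagate(p0, build_generator(drift4, 1.0, 0.2), -1.0)

    def test_mass_conserved(self, drift4, grid100):
        p0 = initial_density(2.0, grid100)
        M = build_generator(drift4, 2.0, 0.3)
        for t in (0.1, 1.0, 5.0):
            assert propagate(p0, M, t).mass() == pytest.approx(1.0, abs=1e-8)

    def test_diffusion_long_time_uniform(self, drift4, grid100):
        p0 = initial_density(0.5, grid100)
        M = build_generator(drift4, 0.0, 0.5)
        p = propagate(p0, M, 200.0)
        assert np.max(np.abs(p.values - 1.0 / (2 * np.pi))) < 1e-6

    def test_semigroup(self, drift4, grid100):
        p0 = initial_density(1.2, grid100)
        M = build_generator(drift4, 1.5, 0.25)
        once = propagate(p0, M, 3.0)
        twice = propagate(propagate(p0, M, 1.2), M, 1.8)
        assert np.max(np.abs(once.values - twice.values)) < 1e-8

    def test_sfp_start_tighter_than_ufp_start(self, drift4, grid100):
        """Mirrors the fixed-point stability effect: a memory initialized at
        an attractor stays narrower than one initialized at a repellor."""
        M = build_generator(drift4, 2.0, 0.15)
        at_sfp = propagate(initial_density(0.0, grid100), M, 5.0)
        at_ufp = propagate(initial_density(np.pi / 4, grid100), M, 5.0)
        assert at_sfp.circular_sd_rad() < at_ufp.circular_sd_rad()


class TestEncode:
    def test_no_dynamics_returns_initial_density(self, drift4, grid100):
        p = encode(1.0, drift4, one_load_params(beta_star=0.0, sigma_star=0.0),
                   load=1)
        assert np.rad2deg(p.circular_mean_rad()) == pytest.approx(
            np.rad2deg(1.0), abs=1.0)
        assert p.circular_sd_rad() == pytest.approx(0.1, rel=0.1)
        assert p.mass() == pytest.approx(1.0, abs=1e-8)

    def test_encoding_drift_pulls_toward_attractor(self, drift4, grid100):
        # target at 60 deg: nearest attractor 90 deg, drift should be clockwise
        target = np.deg2rad(60.0)
        p = encode(target, drift4, one_load_params(beta_star=1.0,
                                                   sigma_star=0.05), load=1)
        shift = am.circ_error(np.rad2deg(p.circular_mean_rad()), 60.0)
        assert shift > 2.0


class TestReportDistribution:
    def test_full_guessing_is_uniform(self, drift4):
        trial = TrialRecord("s", 1, 2.0, 100.0, (), 30.0)
        mix = MixtureParams(guess_slope={1: 0.0}, guess_intercept={1: 1.0})
        p = report_distribution(trial, drift4, one_load_params(), mix)
        assert np.allclose(p.values, 1.0 / (2 * np.pi), atol=1e-12)

    def test_pure_memory_equals_propagated_field(self, drift4, grid100):
        trial = TrialRecord("s", 1, 2.0, 100.0, (), 30.0)
        dyn = one_load_params()
        p = report_distribution(trial, drift4, dyn, no_mixture())
        m_star = build_generator(drift4, dyn.beta_star[1], dyn.sigma_star[1])
        m_mem = build_generator(drift4, dyn.beta[1], dyn.sigma[1])
        expected = propagate(propagate(
            initial_density(np.deg2rad(100.0), grid100), m_star, 1.0),
            m_mem, 2.0)
        assert np.max(np.abs(p.values - expected.values)) < 1e-10

    def test_swap_mixture_is_bimodal(self, grid100, basis12):
        field = eval_drift(np.zeros(12), basis12)  # no drift: clean modes
        trial = TrialRecord("s", 2, 1.0, 90.0, (270.0,), 0.0)
        dyn = DynamicsParams(beta={2: 0.0}, sigma={2: 0.1},
                             beta_star={2: 0.0}, sigma_star={2: 0.1})
        mix = MixtureParams(guess_slope={2: 0.0}, guess_intercept={2: 0.0},
                            swap_slope=0.0, swap_intercept=0.5)
        p = report_distribution(trial, field, dyn, mix)
        d_target = p.density_at(np.deg2rad(90.0))
        d_swap = p.density_at(np.deg2rad(270.0))
        d_between = p.density_at(np.deg2rad(0.0))
        assert d_target > 5 * d_between and d_swap > 5 * d_between
        assert d_swap == pytest.approx(d_target, rel=0.05)

    def test_swap_probability_forced_to_zero_at_load_one(self):
        mix = MixtureParams(guess_slope={1: 0.0}, guess_intercept={1: 0.0},
                            swap_slope=0.0, swap_intercept=0.5)
        lam, alpha = mix.weights(1, 1.0)
        assert alpha == 0.0

    def test_lambda_alpha_clipping_preserves_ratio(self):
        mix = MixtureParams(guess_slope={2: 0.2}, guess_intercept={2: 0.4},
                            swap_slope=0.1, swap_intercept=0.2)
        lam, alpha = mix.weights(2, 4.0)  # raw lam=1.2->1.0, alpha=0.6
        assert lam + alpha == pytest.approx(1.0)
        assert lam / alpha == pytest.approx(1.0 / 0.6, rel=1e-9)


class TestTrialLoglik:
    def test_guess_only_closed_form(self, drift4):
        trial = TrialRecord("s", 1, 2.0, 100.0, (), 214.0)
        mix = MixtureParams(guess_slope={1: 0.0}, guess_intercept={1: 1.0})
        ll = trial_loglik(trial, drift4, one_load_params(), mix)
        assert ll == pytest.approx(np.log(1.0 / (2 * np.pi)), abs=1e-12)

    def test_matches_interpolated_distribution(self, drift4):
        trial = TrialRecord("s", 1, 3.0, 45.0, (), 60.0)
        dyn = one_load_params()
        mix = MixtureParams(guess_slope={1: 0.01}, guess_intercept={1: 0.05})
        p = report_distribution(trial, drift4, dyn, mix)
        ll = trial_loglik(trial, drift4, dyn, mix)
        assert ll == pytest.approx(np.log(p.density_at(np.deg2rad(60.0))))

    def test_engine_agrees_with_per_trial_path(self, truth, small_dataset):
        eng = LikelihoodEngine(small_dataset, truth.drift.grid)
        lls = eng.per_trial_loglik(truth.drift, truth.dyn, truth.mix)
        for i in (0, 57, 311):
            direct = trial_loglik(small_dataset.trials[i], truth.drift,
                                  truth.dyn, truth.mix)
            assert lls[i] == pytest.approx(direct, abs=1e-8)

    def test_rotation_invariance_with_decoding(self, basis12, grid100):
        """Rotating the drift field, target, and report together leaves the
        likelihood unchanged (decoding convolution included)."""
        rng = np.random.default_rng(4)
        w = rng.normal(size=12)
        shift_idx = 3  # rotate by 3 basis spacings = 90 deg
        field = eval_drift(w, basis12)
        field_rot = eval_drift(np.roll(w, shift_idx), basis12)
        dyn = one_load_params()
        mix = MixtureParams(guess_slope={1: 0.0}, guess_intercept={1: 0.02},
                            decode_sd=0.15)
        t = TrialRecord("s", 1, 2.5, 33.0, (), 50.0)
        t_rot = TrialRecord("s", 1, 2.5, 123.0, (), 140.0)
        ll = trial_loglik(t, field, dyn, mix)
        ll_rot = trial_loglik(t_rot, field_rot, dyn, mix)
        assert ll_rot == pytest.approx(ll, abs=1e-6)

    def test_truth_dominates_perturbed_params(self, drift4):
        """Mean log-likelihood at the generating parameters beats the same
        model with the memory drift gain doubled, in most replicates."""
        dyn = one_load_params(beta=0.5, sigma=0.25)
        dyn_bad = one_load_params(beta=1.0, sigma=0.25)
        mix = MixtureParams(guess_slope={1: 0.0}, guess_intercept={1: 0.03})
        gt = am.GroundTruth(drift4, dyn, mix)
        design = am.TaskDesign(loads=(1,), delays_s=(1.0, 7.0),
                               n_trials_per_condition=150)
        wins = 0
        for rep in range(10):
            ds = am.simulate_trials(gt, design, seed=500 + rep)
            eng = LikelihoodEngine(ds)
            ll_true = eng.total_loglik(drift4, dyn, mix)
            ll_bad = eng.total_loglik(drift4, dyn_bad, mix)
            wins += ll_true > ll_bad
        assert wins >= 8
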