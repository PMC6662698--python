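"""Synthetic delayed-estimation data with known ground truth.

Generates trial tables from the full generative process -- encoding drift and
diffusion, memory drift and diffusion, guesses, swaps, decoding blur -- either
by sampling the analytic per-trial report distribution (mixture mode) or by
direct Euler-Maruyama simulation of the underlying stochastic differential
equation (sde mode). The two modes are statistically interchangeable; the SDE
path doubles as an independent oracle for the Fokker-Planck machinery.

Also provides the normative simulations: expected absolute memory error over
time for the full model versus a diffusion-only model, in uniform and biased
color environments, plus the graded juice-reward schedule used to train
monkeys on the task.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .core_io import (
    TWO_PI,
    Dataset,
    Grid,
    TrialRecord,
    circ_dist_rad,
    log_run_seed,
    wrap_deg,
)
from .drift_field import (
    DriftField,
    build_basis,
    eval_drift,
    find_fixed_points,
    fit_drift_to_profile,
    von_mises_density,
)
from .dynamics import (
    ENCODE_SD_RAD,
    DynamicsParams,
    MixtureParams,
    build_generator,
    initial_density,
    memory_operator,
)

DEFAULT_SDE_DT_S = 0.01


# ---------------------------------------------------------------------------
# task designs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaskDesign:
    """Trial structure of a delayed-estimation experiment.

    ``delays_s`` lists discrete delay levels; alternatively ``delay_range_s``
    draws delays uniformly from an interval (as in designs with continuously
    varying delays). ``environment`` is "uniform", or "biased" for the
    common-color manipulation: four equally spaced 20-degree-wide clusters at
    a random per-experiment phase, each sample drawn from the cluster mixture
    with probability ``biased_fraction``. Same-trial colors are constrained to
    be at least ``min_separation_deg`` apart. ``n_colors`` discretizes the
    hue wheel (64 evenly spaced hues in the monkey task); None keeps it
    continuous.
    """

    loads: tuple[int, ...] = (1, 3)
    delays_s: tuple[float, ...] = (1.0, 7.0)
    delay_range_s: tuple[float, float] | None = None
    n_trials_per_condition: int = 100
    environment: Literal["uniform", "biased"] = "uniform"
    n_clusters: int = 4
    cluster_width_deg: float = 20.0
    biased_fraction: float = 0.5
    cluster_phase_deg: float | None = None  # None: drawn from the seed
    min_separation_deg: float = 22.0
    species: Literal["human", "monkey"] = "human"
    n_colors: int | None = None

    def __post_init__(self):
        if self.environment == "biased":
            spacing = 360.0 / self.n_clusters
            if self.cluster_width_deg > spacing:
                raise ValueError("cluster width must not exceed cluster spacing")
        if max(self.loads) * self.min_separation_deg >= 360.0:
            raise ValueError(
                "same-trial separation constraint unsatisfiable at this load"
            )


def human_design_exp1a(n_trials_per_condition: int = 50) -> TaskDesign:
    """Uniform-environment human design: loads 1 and 3, delays 1 and 7 s."""
    return TaskDesign(loads=(1, 3), delays_s=(1.0, 7.0),
                      n_trials_per_condition=n_trials_per_condition)


def human_design_exp1b(n_trials_per_condition: int = 200) -> TaskDesign:
    """Two-sample design with delays drawn continuously from 1-7 s."""
    return TaskDesign(loads=(2,), delays_s=(), delay_range_s=(1.0, 7.0),
                      n_trials_per_condition=n_trials_per_condition)


def human_design_exp2(n_trials_per_condition: int = 100,
                      cluster_phase_deg: float | None = None) -> TaskDesign:
    """Biased-environment design: two samples, delays 0.5 and 4 s, four
    20-degree-wide common-color clusters hit with probability 0.5."""
    return TaskDesign(loads=(2,), delays_s=(0.5, 4.0),
                      n_trials_per_condition=n_trials_per_condition,
                      environment="biased", cluster_phase_deg=cluster_phase_deg)


def monkey_design(n_trials_per_condition: int = 500) -> TaskDesign:
    """Monkey design: loads 1 and 2, delays 0.5 and 1.5 s, 64 discrete hues."""
    return TaskDesign(loads=(1, 2), delays_s=(0.5, 1.5),
                      n_trials_per_condition=n_trials_per_condition,
                      species="monkey", n_colors=64)


def cluster_centers_deg(design: TaskDesign, rng: np.random.Generator) -> np.ndarray:
    spacing = 360.0 / design.n_clusters
    phase = (design.cluster_phase_deg if design.cluster_phase_deg is not None
             else float(rng.uniform(0.0, spacing)))
    return wrap_deg(phase + spacing * np.arange(design.n_clusters))


def _draw_color(design: TaskDesign, centers: np.ndarray,
                rng: np.random.Generator) -> float:
    if design.environment == "biased" and rng.random() < design.biased_fraction:
        c = centers[rng.integers(design.n_clusters)]
        col = c + rng.uniform(-0.5, 0.5) * design.cluster_width_deg
    else:
        col = rng.uniform(0.0, 360.0)
    if design.n_colors is not None:
        step = 360.0 / design.n_colors
        col = np.round(col / step) * step
    return float(wrap_deg(col))


def sample_trial_colors(design: TaskDesign, load: int, centers: np.ndarray,
                        rng: np.random.Generator,
                        max_attempts: int = 10_000) -> list[float]:
    """Colors for one trial, pairwise >= min_separation_deg apart (rejection)."""
    for _ in range(max_attempts):
        cols = [_draw_color(design, centers, rng) for _ in range(load)]
        ok = all(
            abs(circ_dist_rad(np.deg2rad(a), np.deg2rad(b))) * 180.0 / np.pi
            >= design.min_separation_deg
            for i, a in enumerate(cols) for b in cols[:i]
        )
        if ok:
            return cols
    raise RuntimeError("could not satisfy the same-trial separation constraint")


def sample_targets(design: TaskDesign, n_trials: int, seed: int,
                   load: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """(targets, nontargets) for ``n_trials`` trials of one load.

    ``targets`` has shape (n_trials,), ``nontargets`` (n_trials, load - 1);
    all angles in degrees.
    """
    rng = np.random.default_rng(seed)
    load = load if load is not None else max(design.loads)
    centers = cluster_centers_deg(design, rng)
    targets = np.empty(n_trials)
    nontargets = np.empty((n_trials, load - 1))
    for i in range(n_trials):
        cols = sample_trial_colors(design, load, centers, rng)
        targets[i] = cols[0]
        nontargets[i] = cols[1:]
    return targets, nontargets


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroundTruth:
    """Frozen generating model: drift field plus dynamics/observation params."""

    drift: DriftField
    dyn: DynamicsParams
    mix: MixtureParams
    seed: int = 0


def four_attractor_field(grid: Grid | None = None, n_basis: int = 12,
                         phase_rad: float = 0.0) -> DriftField:
    """A drift field with four evenly spaced attractors.

    Built the way a representative drift function is derived from data: fit
    the basis to the (normalized) derivative of a four-mode von Mises mixture
    density, which places attractors at the density's modes.
    """
    grid = grid or Grid()
    basis = build_basis(n_basis, grid)
    modes = phase_rad + TWO_PI / 4 * np.arange(4)
    dens = np.zeros(grid.n_bins)
    for m in modes:
        dens += von_mises_density(grid.centers, m, np.deg2rad(15.0)) / 4.0
    deriv = np.gradient(dens, grid.delta)
    field = fit_drift_to_profile(deriv, basis)
    # weights are scale-free (G is max-normalized); rescale them into the
    # fitting bounds so the truth is representable by the estimator
    w = field.weights / np.abs(field.weights).max()
    return eval_drift(w, basis)


def default_truth(grid: Grid | None = None, n_basis: int = 12,
                  seed: int = 0) -> GroundTruth:
    """Canonical generating model for recovery studies.

    Four attractors; drift gains increase with load and are faster during
    encoding than in memory (as rates); diffusion increases with load;
    modest, delay-increasing guess and swap probabilities; no decoding blur.

    Drift gains are moderate (beta_L |G'| ~ 0.7-1.5 per second) so that at
    the task's 1-s and 7-s delays memories are mid-transient: with much
    stronger drift every delay condition sits at the stationary density and
    only the width sigma_L / sqrt(2 beta_L |G'|) is identified, leaving the
    maximum-likelihood estimate free to slide along a beta-sigma ridge.
    """
    drift = four_attractor_field(grid, n_basis)
    dyn = DynamicsParams(
        beta={1: 0.2, 3: 0.4},
        sigma={1: 0.2, 3: 0.35},
        beta_star={1: 0.3, 3: 0.5},
        sigma_star={1: 0.1, 3: 0.15},
    )
    mix = MixtureParams(
        guess_slope={1: 0.01, 3: 0.01},
        guess_intercept={1: 0.05, 3: 0.05},
        swap_slope=0.005,
        swap_intercept=0.05,
        decode_sd=None,
    )
    return GroundTruth(drift, dyn, mix, seed)


def representative_params(include_drift: bool = True) -> DynamicsParams:
    """Single-condition parameters for the normative error simulations.

    Magnitudes are set so that the model's attraction produces bias of the
    size seen in human reports (a few degrees over a 7-s delay): modest
    memory drift, stronger encoding drift, diffusion dominating at long
    delays. ``include_drift=False`` zeroes both drift gains.
    """
    b, bs = (0.25, 0.5) if include_drift else (0.0, 0.0)
    return DynamicsParams(beta={1: b}, sigma={1: 0.15},
                          beta_star={1: bs}, sigma_star={1: 0.30})


# ---------------------------------------------------------------------------
# trial simulation
# ---------------------------------------------------------------------------

def _sample_from_density(values: np.ndarray, grid: Grid,
                         rng: np.random.Generator) -> float:
    """One draw from a per-bin density: bin by mass, uniform within the bin."""
    mass = np.clip(values, 0.0, None)
    mass = mass / mass.sum()
    k = rng.choice(grid.n_bins, p=mass)
    return float((k + rng.random()) * grid.delta)


def _von_mises_noise(sd_rad: float, size, rng: np.random.Generator):
    kappa = 1.0 / sd_rad**2
    return rng.vonmises(0.0, kappa, size)


def simulate_trials(truth: GroundTruth, design: TaskDesign, seed: int,
                    mode: Literal["mixture", "sde"] = "mixture",
                    dt: float = DEFAULT_SDE_DT_S,
                    subject: str = "sim") -> Dataset:
    """Simulate a full dataset from a known generating model.

    mixture mode samples each report from the analytic report distribution;
    sde mode runs Euler-Maruyama on every memory item and applies guesses,
    swaps and decoding noise at the sample level. Reproducible from ``seed``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    log_run_seed(seed, f"simulate_trials mode={mode}")
    grid = truth.drift.grid
    delays_of = (lambda n: rng.uniform(*design.delay_range_s, n)) \
        if design.delay_range_s is not None else None
    trials: list[TrialRecord] = []
    index = 0
    for load in design.loads:
        delay_levels = ([None] if design.delay_range_s is not None
                        else list(design.delays_s))
        for delay_level in delay_levels:
            n = design.n_trials_per_condition
            targets, nontargets = sample_targets(
                design, n, int(rng.integers(2**31)), load=load
            )
            delays = (delays_of(n) if delay_level is None
                      else np.full(n, float(delay_level)))
            if mode == "mixture":
                reports = _simulate_mixture(truth, load, targets, nontargets,
                                            delays, grid, rng)
            elif mode == "sde":
                reports = _simulate_sde(truth, load, targets, nontargets,
                                        delays, dt, rng)
            else:
                raise ValueError(f"unknown simulation mode {mode!r}")
            for i in range(n):
                trials.append(TrialRecord(
                    subject=subject, load=load, delay_s=float(delays[i]),
                    target_deg=float(targets[i]),
                    nontargets_deg=tuple(float(x) for x in nontargets[i]),
                    report_deg=float(wrap_deg(reports[i])),
                    trial_index=index,
                ))
                index += 1
    return Dataset(trials, species=design.species)


def _simulate_mixture(truth: GroundTruth, load, targets, nontargets, delays,
                      grid: Grid, rng) -> np.ndarray:
    n = len(targets)
    reports = np.empty(n)
    m = load - 1
    for delay in np.unique(delays):
        idx = np.where(delays == delay)[0]
        T = memory_operator(truth.drift, truth.dyn, load, float(delay), grid)
        lam, alpha = truth.mix.weights(load, float(delay))
        for i in idx:
            u = rng.random()
            if u < lam:
                reports[i] = np.rad2deg(rng.uniform(0.0, TWO_PI))
                continue
            if u < lam + alpha and m > 0:
                src = nontargets[i][rng.integers(m)]
            else:
                src = targets[i]
            p = T @ initial_density(np.deg2rad(src), grid).values
            rep = _sample_from_density(p, grid, rng)
            if truth.mix.decode_sd is not None:
                rep += _von_mises_noise(truth.mix.decode_sd, None, rng)
            reports[i] = np.rad2deg(rep)
    return reports


def _sde_stage(theta, field: DriftField, beta, sigma, duration, dt, rng):
    n_steps = int(round(duration / dt))
    for _ in range(n_steps):
        g = np.asarray(field(theta))
        theta = theta + beta * g * dt \
            + sigma * np.sqrt(dt) * rng.standard_normal(theta.shape)
    return theta


def _simulate_sde(truth: GroundTruth, load, targets, nontargets, delays,
                  dt, rng) -> np.ndarray:
    n = len(targets)
    m = load - 1
    items = np.column_stack([targets, nontargets]) if m else targets[:, None]
    theta = np.deg2rad(items) + _von_mises_noise(ENCODE_SD_RAD, items.shape, rng)
    theta = _sde_stage(theta, truth.drift, truth.dyn.beta_star[load],
                       truth.dyn.sigma_star[load], truth.dyn.encode_duration,
                       dt, rng)
    reports = np.empty(n)
    for delay in np.unique(delays):
        idx = np.where(delays == delay)[0]
        th = _sde_stage(theta[idx], truth.drift, truth.dyn.beta[load],
                        truth.dyn.sigma[load], float(delay), dt, rng)
        lam, alpha = truth.mix.weights(load, float(delay))
        for row, i in enumerate(idx):
            u = rng.random()
            if u < lam:
                reports[i] = np.rad2deg(rng.uniform(0.0, TWO_PI))
                continue
            if u < lam + alpha and m > 0:
                rep = th[row, 1 + rng.integers(m)]
            else:
                rep = th[row, 0]
            if truth.mix.decode_sd is not None:
                rep += _von_mises_noise(truth.mix.decode_sd, None, rng)
            reports[i] = np.rad2deg(rep)
    return reports


# ---------------------------------------------------------------------------
# normative simulations: expected error over time
# ---------------------------------------------------------------------------

def environment_weights(field: DriftField, bias_fraction: float,
                        within_deg: float = 10.0) -> np.ndarray:
    """Per-grid-bin target probabilities for a partially biased environment.

    A weighted average of a uniform distribution over the circle and a
    distribution uniform within ``within_deg`` of the field's attractors and
    zero elsewhere.
    """
    grid = field.grid
    uni = np.full(grid.n_bins, 1.0 / grid.n_bins)
    if bias_fraction == 0.0:
        return uni
    fps = find_fixed_points(field)
    if len(fps.stable) == 0:
        raise ValueError("environment bias needs a field with attractors")
    near = np.zeros(grid.n_bins, dtype=bool)
    for a in fps.stable:
        near |= np.abs(circ_dist_rad(grid.centers, a)) <= np.deg2rad(within_deg)
    biased = near / near.sum()
    return (1.0 - bias_fraction) * uni + bias_fraction * biased


def error_over_time(drift: DriftField, params: DynamicsParams, t_grid,
                    env_weights=None, load: int | None = None,
                    include_drift: bool = True) -> np.ndarray:
    """Expected mean absolute memory error (degrees) at each delay in t_grid.

    Computed by quadrature: for every target on the grid, propagate the
    encoded density and integrate |circular error|; then average over the
    target environment. Guesses and swaps are excluded -- this isolates error
    in the memory of the target itself. ``include_drift=False`` zeroes both
    drift gains (the diffusion-only comparison model).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    grid = drift.grid
    load = load if load is not None else min(params.beta)
    beta = params.beta[load] if include_drift else 0.0
    beta_star = params.beta_star[load] if include_drift else 0.0
    w = (np.full(grid.n_bins, 1.0 / grid.n_bins) if env_weights is None
         else np.asarray(env_weights, dtype=float))
    m_star = build_generator(drift, beta_star, params.sigma_star[load], grid)
    m_mem = build_generator(drift, beta, params.sigma[load], grid)
    # initial densities for a target at every grid bin, as columns
    p0 = von_mises_density(grid.centers[:, None], grid.centers[None, :],
                           ENCODE_SD_RAD)
    p0 /= p0.sum(axis=0, keepdims=True) * grid.delta
    enc = m_star.expm_t(params.encode_duration) @ p0
    dist = np.abs(circ_dist_rad(grid.centers[:, None], grid.centers[None, :]))
    out = np.empty(len(t_grid))
    for k, t in enumerate(t_grid):
        p = m_mem.expm_t(float(t)) @ enc
        p = np.clip(p, 0.0, None)
        p /= p.sum(axis=0, keepdims=True) * grid.delta
        per_target = (dist * p).sum(axis=0) * grid.delta
        out[k] = np.rad2deg(per_target @ w)
    return out


def error_heatmap(drift: DriftField, params: DynamicsParams, t_grid,
                  bias_fractions, load: int | None = None) -> np.ndarray:
    """Percent increase in error of the diffusion-only model relative to the
    full model, over (bias_fraction, t). Positive values mean attractors help.

    The diffusion-only model is translation invariant, so its error does not
    depend on the environment and is computed once.
    """
    bias_fractions = np.asarray(bias_fractions, dtype=float)
    err_diff = error_over_time(drift, params, t_grid, include_drift=False,
                               load=load)
    out = np.empty((len(bias_fractions), len(t_grid)))
    for i, f in enumerate(bias_fractions):
        w = environment_weights(drift, float(f))
        err_full = error_over_time(drift, params, t_grid, env_weights=w,
                                   load=load)
        out[i] = 100.0 * (err_diff - err_full) / err_full
    return out


# ---------------------------------------------------------------------------
# monkey reward schedule
# ---------------------------------------------------------------------------

JUICE_SD_DEG = 22.0
JUICE_PEAK_DROPS = 12
JUICE_CUTOFF_DEG = 60.0


def juice_reward(error_deg: float) -> int:
    """Drops of juice for a report with the given angular error.

    A von Mises profile centered on zero error (circular SD 22 deg) scaled to
    a peak of 12 drops, rounded up; errors beyond 60 deg earn nothing.
    """
    e = abs(float(np.rad2deg(circ_dist_rad(np.deg2rad(error_deg), 0.0))))
    if e > JUICE_CUTOFF_DEG:
        return 0
    kappa = 1.0 / np.deg2rad(JUICE_SD_DEG) ** 2
    profile = np.exp(kappa * (np.cos(np.deg2rad(e)) - 1.0))
    return int(np.ceil(JUICE_PEAK_DROPS * profile))
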