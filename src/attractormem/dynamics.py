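"""Generative engine: drift-diffusion dynamics of a memory on the hue circle.

A remembered hue theta evolves as  d(theta) = beta_L * G(theta) dt + sigma_L dW
with periodic boundaries. Its probability density follows the corresponding
Fokker-Planck equation, discretized on the grid into a continuous-time Markov
generator M (columns sum to zero, off-diagonals nonnegative) and solved in
closed form by the matrix exponential, p(theta, t) = expm(M t) p(theta, 0).

Encoding is a fixed 1-s drift-diffusion stage with its own gains (beta*,
sigma*) applied to a narrow von Mises initialization (SD 0.1 rad) at the
target hue. The observed report mixes the target memory with non-target
memories (swaps, probability alpha), a uniform lapse component (guesses,
probability lambda; both linear in delay), and an optional von Mises decoding
blur applied by circular convolution.

The advection term is discretized with the exponential-fitting
(Scharfetter-Gummel) flux, which keeps the generator valid (nonnegative
off-diagonals) at any drift-to-diffusion ratio, reduces to first-order upwind
differencing in the advection-dominated limit, and reproduces the stationary
density of the continuous process essentially exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping

import numpy as np
from scipy.linalg import expm

from .core_io import (
    TWO_PI,
    Dataset,
    Grid,
    ProbabilityField,
    TrialRecord,
    circ_dist_rad,
    wrap_rad,
)
from .drift_field import DriftField, von_mises_density

ENCODE_SD_RAD = 0.1  # SD of the stimulus-evoked initial density, radians
DEFAULT_ENCODE_DURATION_S = 1.0


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DynamicsParams:
    """Per-load drift/diffusion gains for the memory and encoding stages.

    All four gains are rates: beta/beta* in rad/s (maximum instantaneous
    drift, since G is normalized to max |G| = 1), sigma/sigma* in rad/sqrt(s).
    Encoding runs for a fixed ``encode_duration`` (1 s by default) while the
    memory stage runs for the trial's delay.
    """

    beta: Mapping[int, float]
    sigma: Mapping[int, float]
    beta_star: Mapping[int, float]
    sigma_star: Mapping[int, float]
    encode_duration: float = DEFAULT_ENCODE_DURATION_S

    def __post_init__(self):
        if not (self.encode_duration > 0):
            raise ValueError("encode_duration must be positive")
        for name in ("sigma", "sigma_star"):
            for L, v in getattr(self, name).items():
                if v < 0:
                    raise ValueError(f"{name}[{L}] must be nonnegative")

    @property
    def loads(self) -> list[int]:
        return sorted(self.beta)


@dataclass(frozen=True)
class MixtureParams:
    """Observation-stage parameters: guesses, swaps, decoding blur.

    The guess probability lambda(t) = b_guess[L] + a_guess[L] * t and the swap
    probability alpha(t) = b_swap + a_swap * t (shared across loads > 1, and
    identically zero at load 1) are evaluated per trial, clipped to [0, 1],
    and rescaled proportionally if their sum exceeds 1. ``decode_sd`` is the
    circular SD (radians) of the von Mises decoding blur, or None to disable.
    """

    guess_slope: Mapping[int, float]
    guess_intercept: Mapping[int, float]
    swap_slope: float = 0.0
    swap_intercept: float = 0.0
    decode_sd: float | None = None

    def weights(self, load: int, t: float) -> tuple[float, float]:
        """(lambda, alpha) for a trial with this load and delay."""
        lam = float(np.clip(self.guess_intercept[load] + self.guess_slope[load] * t,
                            0.0, 1.0))
        if load == 1:
            alpha = 0.0
        else:
            alpha = float(np.clip(self.swap_intercept + self.swap_slope * t, 0.0, 1.0))
        total = lam + alpha
        if total > 1.0:
            lam, alpha = lam / total, alpha / total
        return lam, alpha


# ---------------------------------------------------------------------------
# generator matrix and propagation
# ---------------------------------------------------------------------------

def _bernoulli(x: np.ndarray) -> np.ndarray:
    """B(x) = x / (exp(x) - 1), the exponential-fitting flux weight; B(0) = 1."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-10
    safe = np.where(small, 1.0, x)
    with np.errstate(over="ignore"):  # expm1 overflow -> B(x) underflows to 0
        out = np.where(small, 1.0 - x / 2.0, safe / np.expm1(safe))
    return out


@dataclass
class GeneratorMatrix:
    """Continuous-time Markov generator for drift-diffusion on the ring.

    ``matrix[i, j]`` is the probability flow rate from bin j into bin i
    (units 1/s); columns sum to zero and off-diagonals are nonnegative.
    Matrix exponentials are cached per propagation time.
    """

    matrix: np.ndarray
    grid: Grid
    beta: float
    sigma: float
    _expm_cache: dict = dc_field(default_factory=dict, repr=False)

    def expm_t(self, t: float) -> np.ndarray:
        """expm(M * t), cached by t (few distinct delays per experiment).

        When a cached time divides t evenly, the result is obtained as an
        integer matrix power of the cached exponential (exact for the
        semigroup, and much cheaper than a fresh Pade evaluation).
        """
        key = round(float(t), 12)
        if key not in self._expm_cache:
            for t0, E0 in self._expm_cache.items():
                if t0 <= 0:
                    continue
                ratio = t / t0
                k = round(ratio)
                if 1 < k <= 64 and abs(ratio - k) < 1e-9:
                    self._expm_cache[key] = np.linalg.matrix_power(E0, k)
                    break
            else:
                self._expm_cache[key] = expm(self.matrix * t)
        return self._expm_cache[key]


def build_generator(field: DriftField, beta: float, sigma: float,
                    grid: Grid | None = None) -> GeneratorMatrix:
    """Discretize d/dt p = -d/dtheta[beta G p] + (sigma^2/2) d2p/dtheta2.

    Uses the Scharfetter-Gummel flux between neighboring bins: the rate from
    bin j to j+1 is (D/delta^2) B(-v delta / D) with interface velocity v and
    D = sigma^2 / 2, and symmetrically for the reverse rate. sigma = 0 falls
    back to pure upwind advection.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    grid = grid or field.grid
    if grid.n_bins != field.grid.n_bins:
        raise ValueError("grid does not match the drift field's grid")
    n = grid.n_bins
    delta = grid.delta
    g = field.values
    # velocity at the interface between bin j and bin j+1 (circular)
    v = beta * 0.5 * (g + np.roll(g, -1))
    D = 0.5 * sigma**2
    if D == 0.0:
        rate_fwd = np.maximum(v, 0.0) / delta          # j -> j+1
        rate_bwd = np.maximum(-v, 0.0) / delta         # j+1 -> j
    else:
        w = v * delta / D
        rate_fwd = (D / delta**2) * _bernoulli(-w)
        rate_bwd = (D / delta**2) * _bernoulli(w)
    M = np.zeros((n, n))
    j = np.arange(n)
    jp = (j + 1) % n
    M[jp, j] += rate_fwd
    M[j, j] -= rate_fwd
    M[j, jp] += rate_bwd
    M[jp, jp] -= rate_bwd
    return GeneratorMatrix(M, grid, beta, sigma)


def propagate(p0: ProbabilityField, M: GeneratorMatrix, t: float) -> ProbabilityField:
    """Evolve a density for ``t`` seconds: expm(M t) p0, renormalized."""
    if t < 0:
        raise ValueError("propagation time must be nonnegative")
    if t == 0:
        return ProbabilityField(p0.values.copy(), p0.grid)
    out = M.expm_t(t) @ p0.values
    return ProbabilityField.from_unnormalized(out, p0.grid)


def initial_density(target_rad: float, grid: Grid,
                    sd_rad: float = ENCODE_SD_RAD) -> ProbabilityField:
    """Narrow von Mises density at the target hue (stimulus-evoked state)."""
    return ProbabilityField.from_unnormalized(
        von_mises_density(grid.centers, target_rad, sd_rad), grid
    )


def encode(target_rad: float, field: DriftField, params: DynamicsParams,
           load: int, grid: Grid | None = None) -> ProbabilityField:
    """Memory state at the start of the delay: the initial von Mises density
    propagated for the encoding duration under the encoding-stage generator."""
    grid = grid or field.grid
    p0 = initial_density(target_rad, grid)
    m_star = build_generator(field, params.beta_star[load], params.sigma_star[load],
                             grid)
    return propagate(p0, m_star, params.encode_duration)


def decode_kernel_fft(decode_sd: float, grid: Grid) -> np.ndarray:
    """FFT of the von Mises decoding kernel (for circular convolution)."""
    offsets = circ_dist_rad(grid.centers, grid.centers[0])
    k = von_mises_density(offsets, 0.0, decode_sd)
    k = k / (k.sum() * grid.delta)
    return np.fft.rfft(k) * grid.delta


def convolve_decode(values: np.ndarray, kernel_fft: np.ndarray) -> np.ndarray:
    """Circular convolution of per-bin densities (columns) with the kernel."""
    n = values.shape[0]
    return np.fft.irfft(np.fft.rfft(values, axis=0) * kernel_fft.reshape(-1, *([1] * (values.ndim - 1))), n=n, axis=0)


# ---------------------------------------------------------------------------
# per-trial report distribution and likelihood
# ---------------------------------------------------------------------------

def memory_operator(field: DriftField, dyn: DynamicsParams, load: int,
                    delay_s: float, grid: Grid | None = None) -> np.ndarray:
    """Matrix mapping the initial density to the memory density at delay end:
    expm(M_L t) expm(M*_L tau_enc)."""
    grid = grid or field.grid
    m_star = build_generator(field, dyn.beta_star[load], dyn.sigma_star[load], grid)
    m_mem = build_generator(field, dyn.beta[load], dyn.sigma[load], grid)
    return m_mem.expm_t(delay_s) @ m_star.expm_t(dyn.encode_duration)


def report_distribution(trial: TrialRecord, field: DriftField, dyn: DynamicsParams,
                        mix: MixtureParams, grid: Grid | None = None) -> ProbabilityField:
    """Predicted density of the report for one trial (per radian).

    Mixture of the propagated target memory, the propagated non-target
    memories (weight alpha split evenly), and a uniform guess component of
    weight lambda; optionally blurred by the decoding kernel.
    """
    grid = grid or field.grid
    m = trial.load - 1
    lam, alpha = mix.weights(trial.load, trial.delay_s)
    if alpha > 0 and m == 0:
        raise ValueError("swap probability must be zero when there are no non-targets")
    T = memory_operator(field, dyn, trial.load, trial.delay_s, grid)
    target_rad = np.deg2rad(trial.target_deg)
    p = T @ initial_density(target_rad, grid).values
    out = (1.0 - lam - alpha) * p
    if alpha > 0:
        swap = np.zeros(grid.n_bins)
        for nt in trial.nontargets_deg:
            swap += T @ initial_density(np.deg2rad(nt), grid).values
        out += alpha * swap / m
    out += lam / TWO_PI
    if mix.decode_sd is not None:
        out = convolve_decode(out, decode_kernel_fft(mix.decode_sd, grid))
    return ProbabilityField.from_unnormalized(out, grid)


def trial_loglik(trial: TrialRecord, field: DriftField, dyn: DynamicsParams,
                 mix: MixtureParams, grid: Grid | None = None) -> float:
    """Log density (nats, per radian) of the observed report under the model."""
    dist = report_distribution(trial, field, dyn, mix, grid)
    d = dist.density_at(np.deg2rad(trial.report_deg))
    if d <= 0:
        return -np.inf
    return float(np.log(d))


# ---------------------------------------------------------------------------
# batched likelihood over a dataset
# ---------------------------------------------------------------------------

class LikelihoodEngine:
    """Precomputed structures for fast repeated likelihood evaluation.

    Trials are grouped by (load, delay); the initial densities of targets and
    non-targets and the interpolation stencil of each report are computed once,
    so each evaluation only rebuilds the generators (which depend on the
    parameters) and applies two matrix exponentials per group.
    """

    def __init__(self, dataset: Dataset, grid: Grid | None = None):
        if len(dataset) == 0:
            raise ValueError("dataset is empty")
        self.grid = grid or Grid()
        self.n_trials = len(dataset)
        g = self.grid
        self.groups = []
        loads = dataset.loads
        delays = dataset.delays
        targets = np.deg2rad(dataset.targets_deg)
        reports = np.deg2rad(dataset.reports_deg)
        for load in np.unique(loads):
            for delay in np.unique(delays[loads == load]):
                idx = np.where((loads == load) & (delays == delay))[0]
                tg = targets[idx]
                p0 = von_mises_density(g.centers[:, None], tg[None, :], ENCODE_SD_RAD)
                p0 /= p0.sum(axis=0, keepdims=True) * g.delta
                m = int(load) - 1
                if m > 0:
                    nts = np.deg2rad(np.array(
                        [dataset.trials[i].nontargets_deg for i in idx], dtype=float
                    ))  # (n_group, m)
                    p0_nt = von_mises_density(
                        g.centers[:, None], nts.reshape(1, -1), ENCODE_SD_RAD
                    )
                    p0_nt /= p0_nt.sum(axis=0, keepdims=True) * g.delta
                else:
                    p0_nt = None
                rep = reports[idx]
                pos = wrap_rad(rep) / g.delta - 0.5
                lo = np.floor(pos).astype(int)
                frac = pos - lo
                lo %= g.n_bins
                hi = (lo + 1) % g.n_bins
                self.groups.append({
                    "load": int(load), "delay": float(delay), "idx": idx, "m": m,
                    "p0": p0, "p0_nt": p0_nt, "lo": lo, "hi": hi, "frac": frac,
                })

    def per_trial_loglik(self, field: DriftField, dyn: DynamicsParams,
                         mix: MixtureParams) -> np.ndarray:
        out = np.empty(self.n_trials)
        kern = (decode_kernel_fft(mix.decode_sd, self.grid)
                if mix.decode_sd is not None else None)
        # generators are shared across delays within a load
        gens: dict[int, tuple[GeneratorMatrix, GeneratorMatrix]] = {}
        for grp in self.groups:
            L = grp["load"]
            if L not in gens:
                gens[L] = (
                    build_generator(field, dyn.beta_star[L], dyn.sigma_star[L], self.grid),
                    build_generator(field, dyn.beta[L], dyn.sigma[L], self.grid),
                )
            m_star, m_mem = gens[L]
            T = m_mem.expm_t(grp["delay"]) @ m_star.expm_t(dyn.encode_duration)
            lam, alpha = mix.weights(L, grp["delay"])
            F = (1.0 - lam - alpha) * (T @ grp["p0"])
            if alpha > 0 and grp["m"] > 0:
                nt = T @ grp["p0_nt"]
                nt = nt.reshape(self.grid.n_bins, len(grp["idx"]), grp["m"])
                F += alpha * nt.mean(axis=2)
            F += lam / TWO_PI
            if kern is not None:
                F = convolve_decode(F, kern)
            F = np.clip(F, 0.0, None)
            cols = np.arange(len(grp["idx"]))
            dens = ((1.0 - grp["frac"]) * F[grp["lo"], cols]
                    + grp["frac"] * F[grp["hi"], cols])
            with np.errstate(divide="ignore"):
                out[grp["idx"]] = np.log(dens)
        return out

    def total_loglik(self, field: DriftField, dyn: DynamicsParams,
                     mix: MixtureParams) -> float:
        return float(np.sum(self.per_trial_loglik(field, dyn, mix)))


def dataset_loglik(dataset: Dataset, field: DriftField, dyn: DynamicsParams,
                   mix: MixtureParams, grid: Grid | None = None) -> float:
    """Joint log-likelihood of a dataset (sum of per-trial log densities)."""
    return LikelihoodEngine(dataset, grid or field.grid).total_loglik(field, dyn, mix)
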