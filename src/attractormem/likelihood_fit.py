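"""Maximum-likelihood fitting, model variants, comparison, and bootstrap.

All free parameters of the generative model -- basis weights w_j, per-load
drift/diffusion gains (beta_L, sigma_L, beta*_L, sigma*_L), guess and swap
linear coefficients, and the decoding SD -- are estimated jointly by
bound-constrained quasi-Newton optimization of the joint log-likelihood
across trials, from multiple starting points. Reduced model variants freeze
the drift gains or simplify the guess parameterization; variants are ranked
by AIC/BIC (with Akaike/Schwarz weights) and by stratified cross-validated
log-likelihood. Uncertainty comes from nonparametric bootstrap, either by
resampling trials and refitting or by resampling per-subject fitted
parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from .core_io import Dataset, Grid, circ_sd_deg, get_logger, log_run_seed
from .drift_field import DriftBasis, DriftField, build_basis, eval_drift, \
    fit_drift_to_profile
from .dynamics import DynamicsParams, LikelihoodEngine, MixtureParams
from .model_free import circular_kde

GuessParameterization = Literal[
    "linear-per-load", "constant-per-load", "constant-shared", "zero"
]

# optimization bounds per parameter family
BOUNDS = {
    "w": (-5.0, 5.0),
    "beta": (0.0, 10.0),
    "sigma": (1e-3, 3.0),
    "beta_star": (0.0, 10.0),
    "sigma_star": (1e-3, 3.0),
    "a_guess": (-0.5, 0.5),
    "b_guess": (1e-4, 1.0),
    "a_swap": (-0.5, 0.5),
    "b_swap": (1e-4, 1.0),
    "decode_sd": (1e-3, 1.0),
}


@dataclass(frozen=True)
class ModelVariant:
    """Which parts of the full model are free.

    ``memory_drift``/``encoding_drift`` toggle beta_L / beta*_L (frozen at 0
    when off); ``decoding_error`` toggles the decoding blur sigma-dagger
    (humans: on; monkeys: off); ``guess_parameterization`` selects how the
    guess probability depends on load and delay.
    """

    name: str = "full"
    memory_drift: bool = True
    encoding_drift: bool = True
    decoding_error: bool = False
    guess_parameterization: GuessParameterization = "linear-per-load"
    n_basis: int = 12

    def param_names(self, loads: Sequence[int]) -> list[str]:
        loads = sorted(loads)
        names: list[str] = []
        if self.memory_drift or self.encoding_drift:
            names += [f"w[{j}]" for j in range(self.n_basis)]
        for L in loads:
            if self.memory_drift:
                names.append(f"beta[{L}]")
            names.append(f"sigma[{L}]")
            if self.encoding_drift:
                names.append(f"beta_star[{L}]")
            names.append(f"sigma_star[{L}]")
        gp = self.guess_parameterization
        if gp == "linear-per-load":
            for L in loads:
                names += [f"a_guess[{L}]", f"b_guess[{L}]"]
        elif gp == "constant-per-load":
            names += [f"b_guess[{L}]" for L in loads]
        elif gp == "constant-shared":
            names.append("b_guess[*]")
        elif gp != "zero":
            raise ValueError(f"unknown guess parameterization {gp!r}")
        if any(L > 1 for L in loads):
            names += ["a_swap", "b_swap"]
        if self.decoding_error:
            names.append("decode_sd")
        return names

    def n_params(self, loads: Sequence[int]) -> int:
        return len(self.param_names(loads))


FULL_HUMAN = ModelVariant("full+decode", decoding_error=True)
FULL_MONKEY = ModelVariant("full")
NO_MEMORY_DRIFT = ModelVariant("beta=0", memory_drift=False)
NO_ENCODING_DRIFT = ModelVariant("beta*=0", encoding_drift=False)
DIFFUSION_ONLY = ModelVariant("beta=beta*=0", memory_drift=False,
                              encoding_drift=False)


def _bound_for(name: str) -> tuple[float, float]:
    base = name.split("[")[0]
    return BOUNDS[base]


def unpack_params(x: np.ndarray, names: Sequence[str], variant: ModelVariant,
                  loads: Sequence[int], basis: DriftBasis
                  ) -> tuple[DriftField, DynamicsParams, MixtureParams]:
    """Translate a flat optimizer vector into model parameter objects."""
    loads = sorted(loads)
    d = dict(zip(names, x))
    if variant.memory_drift or variant.encoding_drift:
        w = np.array([d[f"w[{j}]"] for j in range(variant.n_basis)])
    else:
        w = np.zeros(basis.n_basis)
    field = eval_drift(w, basis)
    beta = {L: (d[f"beta[{L}]"] if variant.memory_drift else 0.0) for L in loads}
    beta_star = {L: (d[f"beta_star[{L}]"] if variant.encoding_drift else 0.0)
                 for L in loads}
    sigma = {L: d[f"sigma[{L}]"] for L in loads}
    sigma_star = {L: d[f"sigma_star[{L}]"] for L in loads}
    dyn = DynamicsParams(beta=beta, sigma=sigma, beta_star=beta_star,
                         sigma_star=sigma_star)
    gp = variant.guess_parameterization
    if gp == "linear-per-load":
        gs = {L: d[f"a_guess[{L}]"] for L in loads}
        gi = {L: d[f"b_guess[{L}]"] for L in loads}
    elif gp == "constant-per-load":
        gs = {L: 0.0 for L in loads}
        gi = {L: d[f"b_guess[{L}]"] for L in loads}
    elif gp == "constant-shared":
        gs = {L: 0.0 for L in loads}
        gi = {L: d["b_guess[*]"] for L in loads}
    else:  # zero
        gs = {L: 0.0 for L in loads}
        gi = {L: 0.0 for L in loads}
    a_swap = d.get("a_swap", 0.0)
    b_swap = d.get("b_swap", 0.0)
    mix = MixtureParams(guess_slope=gs, guess_intercept=gi,
                        swap_slope=a_swap, swap_intercept=b_swap,
                        decode_sd=d.get("decode_sd") if variant.decoding_error
                        else None)
    return field, dyn, mix


@dataclass
class FitResult:
    """Fitted model for one dataset: parameters, likelihood, criteria."""

    variant: ModelVariant
    param_names: list[str]
    param_values: np.ndarray
    field: DriftField
    dyn: DynamicsParams
    mix: MixtureParams
    loglik: float
    n_params: int
    n_trials: int
    dataset_fingerprint: tuple
    n_starts: int
    converged: bool
    seed: int
    start_logliks: list[float] = dc_field(default_factory=list)

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    @property
    def bic(self) -> float:
        return self.n_params * np.log(self.n_trials) - 2.0 * self.loglik

    @property
    def params(self) -> dict[str, float]:
        return dict(zip(self.param_names, map(float, self.param_values)))

    def to_json(self) -> str:
        return json.dumps({
            "variant": self.variant.name,
            "params": self.params,
            "loglik": self.loglik,
            "n_params": self.n_params,
            "n_trials": self.n_trials,
            "aic": self.aic,
            "bic": self.bic,
            "n_starts": self.n_starts,
            "converged": self.converged,
            "seed": self.seed,
            "drift_weights": list(map(float, self.field.weights)),
        }, indent=2)


def _dataset_fingerprint(dataset: Dataset) -> tuple:
    return (len(dataset), round(float(dataset.reports_deg.sum()), 6),
            round(float(dataset.targets_deg.sum()), 6))


def heuristic_start(dataset: Dataset, names: Sequence[str],
                    variant: ModelVariant, basis: DriftBasis) -> np.ndarray:
    """Data-informed starting point.

    Drift weights come from fitting the basis to the numerical derivative of
    the response-density estimate (attractors sit where reports pile up);
    diffusion scales from the dispersion of errors; mixture terms start small.
    """
    x = np.empty(len(names))
    if variant.memory_drift or variant.encoding_drift:
        dens = circular_kde(np.deg2rad(dataset.reports_deg), n_grid=basis.grid.n_bins)
        deriv = np.gradient(dens, basis.grid.delta)
        f = fit_drift_to_profile(deriv, basis)
        w = f.weights if len(f.weights) else np.zeros(basis.n_basis)
        # weights are scale-free (G is max-normalized), so rescale the often
        # huge near-canceling least-squares solution into the bounds box
        wmax = np.abs(w).max()
        if wmax > 0:
            w = w / wmax * 2.0
    err_sd_rad = np.deg2rad(max(circ_sd_deg(dataset.errors_deg), 1.0))
    mean_delay = float(np.mean(dataset.delays))
    sigma0 = float(np.clip(err_sd_rad / np.sqrt(mean_delay + 1.0), 0.01, 2.9))
    for i, name in enumerate(names):
        base = name.split("[")[0]
        if base == "w":
            x[i] = w[int(name[2:-1])]
        elif base in ("beta", "beta_star"):
            x[i] = 0.5
        elif base in ("sigma", "sigma_star"):
            x[i] = sigma0
        elif base in ("a_guess", "a_swap"):
            x[i] = 0.01
        elif base in ("b_guess", "b_swap"):
            x[i] = 0.05
        elif base == "decode_sd":
            x[i] = 0.1
        else:  # pragma: no cover
            raise AssertionError(name)
    return x


def _nested_fill_value(name: str) -> float | None:
    """Start value for a parameter absent from a nested variant's optimum,
    chosen so the richer model initially reproduces the nested fit exactly
    (drift gains and slopes at 0, intercepts and the decoding SD at their
    lower bounds). Weights return None (fall back to the heuristic)."""
    base = name.split("[")[0]
    if base in ("beta", "beta_star", "a_guess", "a_swap"):
        return 0.0
    if base in ("b_guess", "b_swap", "decode_sd"):
        return _bound_for(name)[0]
    return None


def fit_mle(dataset: Dataset, variant: ModelVariant | None = None,
            n_starts: int = 10, seed: int = 0, grid: Grid | None = None,
            maxiter: int = 200, use_heuristic_start: bool = True,
            extra_starts: Sequence[Mapping[str, float]] = (),
            polish_rounds: int = 4) -> FitResult:
    """Maximum-likelihood fit of a model variant to one dataset.

    Runs ``n_starts`` bound-constrained L-BFGS-B optimizations with central
    finite-difference gradients (relative step 1e-5): one start from a
    data-informed heuristic, the rest from a Latin hypercube over the bounds.
    Each start is optimized in two stages -- rate and mixture parameters
    first with the drift shape frozen, then everything jointly, restarting
    the quasi-Newton state until the likelihood stops improving -- and the
    best optimum wins. Fully reproducible given ``seed``.
    """
    if len(dataset) == 0:
        raise ValueError("cannot fit an empty dataset")
    if variant is None:
        variant = FULL_HUMAN if dataset.species == "human" else FULL_MONKEY
    loads = dataset.loads_present
    grid = grid or Grid()
    basis = build_basis(variant.n_basis, grid)
    engine = LikelihoodEngine(dataset, grid)
    names = variant.param_names(loads)
    bounds = [_bound_for(n) for n in names]
    log_run_seed(seed, f"fit_mle variant={variant.name}")

    def negloglik(x: np.ndarray) -> float:
        field, dyn, mix = unpack_params(x, names, variant, loads, basis)
        ll = engine.total_loglik(field, dyn, mix)
        if not np.isfinite(ll):
            return 1e12
        return -ll

    rng = np.random.default_rng(seed)
    starts = []  # (x0, is_warm) pairs
    heur = heuristic_start(dataset, names, variant, basis)
    if use_heuristic_start:
        starts.append((heur, False))
    # warm starts from (typically nested) fits: absent parameters are filled
    # so that the richer model initially reproduces the nested optimum
    for mapping in extra_starts:
        x = heur.copy()
        for i, n in enumerate(names):
            if n in mapping:
                x[i] = mapping[n]
            else:
                fill = _nested_fill_value(n)
                if fill is not None:
                    x[i] = fill
        starts.append((x, True))
    n_lhs = max(n_starts - (1 if use_heuristic_start else 0), 0)
    if n_lhs:
        sampler = qmc.LatinHypercube(d=len(names), seed=rng)
        # draw random starts inside a plausible sub-box (the optimization box
        # is unchanged): extreme drift/diffusion values put the likelihood on
        # flat plateaus where quasi-Newton steps stall immediately
        start_box = {
            "w": (-2.0, 2.0), "beta": (0.0, 1.5), "beta_star": (0.0, 1.5),
            "sigma": (0.05, 0.6), "sigma_star": (0.05, 0.6),
            "a_guess": (-0.02, 0.05), "b_guess": (0.01, 0.3),
            "a_swap": (-0.02, 0.05), "b_swap": (0.01, 0.3),
            "decode_sd": (0.05, 0.5),
        }
        lo = np.array([start_box[n.split("[")[0]][0] for n in names])
        hi = np.array([start_box[n.split("[")[0]][1] for n in names])
        starts += [(x, False) for x in lo + sampler.random(n_lhs) * (hi - lo)]
    opts = {"maxiter": maxiter, "ftol": 1e-13,
            "finite_diff_rel_step": 1e-5}
    w_mask = np.array([n.startswith("w[") for n in names])

    def optimize_start(x0: np.ndarray, do_stage1: bool = True):
        x0 = np.clip(np.asarray(x0, dtype=float),
                     [b[0] for b in bounds], [b[1] for b in bounds])
        # stage 1: freeze the drift shape, fit rates and mixture (cheap, and
        # it pulls the rate parameters off their generic starting values);
        # warm starts from other fits are already balanced and skip it
        if do_stage1 and np.any(w_mask):
            frozen = x0.copy()

            def nll_rates(xr):
                xx = frozen.copy()
                xx[~w_mask] = xr
                return negloglik(xx)

            r = minimize(nll_rates, x0[~w_mask], method="L-BFGS-B",
                         bounds=[b for b, m in zip(bounds, w_mask) if not m],
                         jac="3-point", options=opts)
            x0 = frozen
            x0[~w_mask] = r.x
        # stage 2: joint optimization; restart the quasi-Newton state until
        # the likelihood stops improving (the normalized-weight ravine tends
        # to stall single L-BFGS-B runs prematurely)
        best_res = None
        x = x0
        for _ in range(max(polish_rounds, 1)):
            res = minimize(negloglik, x, method="L-BFGS-B", bounds=bounds,
                           jac="3-point", options=opts)
            if best_res is None or res.fun < best_res.fun - 1e-12:
                improved = best_res is None or best_res.fun - res.fun > 0.3
                best_res = res
                x = res.x
                if not improved:
                    break
            else:
                break
        return best_res

    best = None
    start_lls = []
    any_converged = False
    if not starts:
        starts.append((heur, False))
    for x0, is_warm in starts:
        res = optimize_start(x0, do_stage1=not is_warm)
        start_lls.append(-res.fun)
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("no optimizer start produced a finite likelihood")
    field, dyn, mix = unpack_params(best.x, names, variant, loads, basis)
    return FitResult(
        variant=variant, param_names=names, param_values=np.asarray(best.x),
        field=field, dyn=dyn, mix=mix, loglik=float(-best.fun),
        n_params=len(names), n_trials=len(dataset),
        dataset_fingerprint=_dataset_fingerprint(dataset),
        n_starts=len(starts), converged=any_converged, seed=seed,
        start_logliks=start_lls,
    )


def fit_variant_family(dataset: Dataset, variants: Sequence[ModelVariant],
                       n_starts: int = 1, seed: int = 0,
                       grid: Grid | None = None, maxiter: int = 200,
                       polish_rounds: int = 4) -> list[FitResult]:
    """Fit a family of (typically nested) variants to one dataset.

    Variants are fitted in order of increasing parameter count with every
    richer model receiving the already-fitted optima as additional warm
    starts; a second, downward pass then re-optimizes each variant from the
    other variants' optima (projected onto its own parameterization). A model
    that nests another can therefore never score a lower likelihood merely
    because its own optimization stalled, which would bias information
    criteria toward the richer model. Returns fits in the order given.
    """
    loads = dataset.loads_present
    order = np.argsort([v.n_params(loads) for v in variants], kind="stable")
    fits: dict[int, FitResult] = {}
    prior: list[dict[str, float]] = []
    for i in order:
        fit = fit_mle(dataset, variants[i], n_starts=n_starts, seed=seed,
                      grid=grid, maxiter=maxiter, extra_starts=prior,
                      polish_rounds=polish_rounds)
        fits[i] = fit
        prior.append(fit.params)
    for i in order[::-1]:
        others = [fits[j].params for j in fits if j != i]
        refit = fit_mle(dataset, variants[i], n_starts=0, seed=seed,
                        grid=grid, maxiter=maxiter, use_heuristic_start=False,
                        extra_starts=others, polish_rounds=1)
        if refit.loglik > fits[i].loglik:
            fits[i] = refit
    return [fits[i] for i in range(len(variants))]


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

def _criterion_weights(values: np.ndarray) -> np.ndarray:
    delta = values - values.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def compare_models(fits: Sequence[FitResult],
                   cv_logliks: Sequence[float] | None = None) -> pd.DataFrame:
    """Rank fitted variants of one dataset by AIC/BIC weights.

    Weights are normalized relative likelihoods exp(-Delta/2) / sum, read as
    the probability that a variant is the best of the set. Optional
    ``cv_logliks`` (mean held-out log-likelihood per trial) are carried along.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    fps = {f.dataset_fingerprint for f in fits}
    if len(fps) != 1:
        raise ValueError("fits were not computed on the same dataset")
    aic = np.array([f.aic for f in fits])
    bic = np.array([f.bic for f in fits])
    table = pd.DataFrame({
        "variant": [f.variant.name for f in fits],
        "n_params": [f.n_params for f in fits],
        "loglik": [f.loglik for f in fits],
        "delta_aic": aic - aic.min(),
        "delta_bic": bic - bic.min(),
        "aic_weight": _criterion_weights(aic),
        "bic_weight": _criterion_weights(bic),
    })
    if cv_logliks is not None:
        table["cv_loglik_per_trial"] = list(cv_logliks)
    return table


def crossval_loglik(dataset: Dataset, variant: ModelVariant,
                    k_folds: int = 10, seed: int = 0,
                    **fit_kwargs) -> float:
    """Mean held-out log-likelihood per trial, k-fold stratified by
    load x delay. Reproducible given ``seed``."""
    if k_folds < 2:
        raise ValueError("k_folds must be at least 2")
    rng = np.random.default_rng(seed)
    loads = dataset.loads
    delays = dataset.delays
    fold = np.empty(len(dataset), dtype=int)
    for L in np.unique(loads):
        for t in np.unique(delays[loads == L]):
            idx = np.where((loads == L) & (delays == t))[0]
            idx = rng.permutation(idx)
            fold[idx] = np.arange(len(idx)) % k_folds
    for k in range(k_folds):
        train_loads = set(loads[fold != k])
        test_loads = set(loads[fold == k])
        if not test_loads <= train_loads or len(test_loads) == 0:
            raise ValueError(
                f"fold {k} lacks trials of some load; use fewer folds"
            )
    total_ll = 0.0
    for k in range(k_folds):
        train = dataset.subset(fold != k)
        test = dataset.subset(fold == k)
        fit = fit_mle(train, variant, seed=seed + 1000 * (k + 1), **fit_kwargs)
        engine = LikelihoodEngine(test, fit.field.grid)
        total_ll += float(np.sum(engine.per_trial_loglik(fit.field, fit.dyn,
                                                         fit.mix)))
    return total_ll / len(dataset)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    """Bootstrap distributions of model parameters.

    ``samples`` maps parameter name to an array of length n_iter. CI and
    contrast p-values are percentile-based; contrasts are one-sided
    (p = fraction of bootstrap samples in which the contrast is <= 0).
    """

    samples: dict[str, np.ndarray]
    mode: str
    seed: int

    @property
    def n_iter(self) -> int:
        return len(next(iter(self.samples.values())))

    def ci(self, name: str, level: float = 0.95) -> tuple[float, float]:
        a = (1.0 - level) / 2.0
        s = self.samples[name]
        return (float(np.quantile(s, a)), float(np.quantile(s, 1.0 - a)))

    def contrast_pvalue(self, name_a: str, name_b: str) -> float:
        """One-sided bootstrap p-value for the contrast a - b > 0."""
        diff = self.samples[name_a] - self.samples[name_b]
        return float(np.mean(diff <= 0.0))


def bootstrap_fit(data, mode: Literal["trials", "subject_params"],
                  n_iter: int = 1000, seed: int = 0,
                  **fit_kwargs) -> BootstrapResult:
    """Bootstrap parameter distributions.

    mode="trials": resample one dataset's trials with replacement and refit
    each time (per-session uncertainty, as used for individually fit
    subjects with many trials). mode="subject_params": resample a list of
    per-subject FitResults with replacement and average their parameters
    (population-level uncertainty).
    """
    if n_iter < 100:
        get_logger().warning("bootstrap with n_iter=%d (<100) is unreliable",
                             n_iter)
    rng = np.random.default_rng(seed)
    log_run_seed(seed, f"bootstrap_fit mode={mode}")
    if mode == "subject_params":
        fits: Sequence[FitResult] = data
        if len(fits) < 2:
            raise ValueError("subject_params mode needs at least 2 fits")
        names = fits[0].param_names
        if any(f.param_names != names for f in fits):
            raise ValueError("fits have mismatched parameterizations")
        mat = np.stack([f.param_values for f in fits])
        idx = rng.integers(len(fits), size=(n_iter, len(fits)))
        means = mat[idx].mean(axis=1)  # (n_iter, n_params)
        samples = {n: means[:, j] for j, n in enumerate(names)}
        return BootstrapResult(samples, mode, seed)
    if mode == "trials":
        dataset: Dataset = data
        samples_list = []
        names = None
        for it in range(n_iter):
            idx = rng.integers(len(dataset), size=len(dataset))
            boot = Dataset([dataset.trials[i] for i in idx], dataset.species)
            fit = fit_mle(boot, seed=seed + it + 1, **fit_kwargs)
            names = fit.param_names
            samples_list.append(fit.param_values)
        mat = np.stack(samples_list)
        samples = {n: mat[:, j] for j, n in enumerate(names)}
        return BootstrapResult(samples, mode, seed)
    raise ValueError(f"unknown bootstrap mode {mode!r}")
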