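"""Model-free statistics for continuous-report data.

Everything here works directly on reports and targets without reference to
the dynamical model: a three-component mixture screen for task engagement, an
entropy-based clustering metric, omnibus nonuniformity tests (Hodges-Ajne and
a permutation Kuiper test), response-histogram peak detection against a
resampled-target null, bias/precision profiles across color space with local
slopes, differential error growth near stable versus unstable fixed points,
and the alignment of fitted attractors with externally defined reference
colors.

Angles at this interface are degrees (matching the trial tables); densities
are per radian, which is what makes the entropy of a uniform circular
distribution come out at log2(2*pi) ~ 2.65 bits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln, i0e, i1e

from .core_io import (
    TWO_PI,
    Dataset,
    circ_dist_rad,
    circ_error,
    circ_mean_deg,
    circ_sd_deg,
    get_logger,
    log_run_seed,
    wrap_deg,
)
from .drift_field import FixedPointSet, von_mises_density

KDE_KERNEL_SD_DEG = 10.0
ENTROPY_GRID = 360


# ---------------------------------------------------------------------------
# circular KDE and entropy
# ---------------------------------------------------------------------------

def circular_kde(angles_rad, kernel_sd_rad: float | None = None,
                 n_grid: int = ENTROPY_GRID) -> np.ndarray:
    """Von Mises kernel density estimate on an evenly spaced circular grid.

    Returns densities per radian at ``n_grid`` points ``2*pi*k/n_grid``.
    The kernel's circular SD defaults to 10 degrees. Samples are binned at
    the grid resolution first, which is exact to within one grid step (well
    below the kernel width).
    """
    if kernel_sd_rad is None:
        kernel_sd_rad = np.deg2rad(KDE_KERNEL_SD_DEG)
    a = np.asarray(angles_rad, dtype=float) % TWO_PI
    step = TWO_PI / n_grid
    hist = np.bincount(np.round(a / step).astype(int) % n_grid,
                       minlength=n_grid).astype(float)
    hist /= hist.sum() * step  # empirical density per radian
    grid = np.arange(n_grid) * step
    kernel = von_mises_density(circ_dist_rad(grid, 0.0), 0.0, kernel_sd_rad)
    kernel /= kernel.sum() * step
    dens = np.fft.irfft(np.fft.rfft(hist) * np.fft.rfft(kernel), n=n_grid) * step
    return np.clip(dens, 0.0, None)


def circular_entropy_bits(density: np.ndarray) -> float:
    """Discrete entropy -sum f log2 f dtheta of a per-radian density."""
    f = np.asarray(density, dtype=float)
    step = TWO_PI / len(f)
    mask = f > 0
    return float(-np.sum(f[mask] * np.log2(f[mask])) * step)


def _remove_guess_component(density: np.ndarray, guess_rate: float) -> np.ndarray:
    """Subtract a uniform component of total area ``guess_rate``, floor at
    zero, renormalize to unit area."""
    f = density - guess_rate / TWO_PI
    f = np.clip(f, 0.0, None)
    step = TWO_PI / len(f)
    total = f.sum() * step
    if total <= 0:
        raise ValueError("guess-rate correction removed all density")
    return f / total


@dataclass(frozen=True)
class ClusterResult:
    """Clustering metric C = H(responses) - H(targets), in bits (negative C
    means responses pile up at preferred colors)."""

    C: float
    H_resp: float
    H_targ: float
    guess_rate: float
    n_trials_used: int


def clustering_metric(reports_deg, targets_deg, guess_rate: float = 0.0,
                      conditions=None, seed: int = 0) -> ClusterResult:
    """Entropy difference between response and target distributions.

    Both distributions are estimated with a 10-degree von Mises KDE on a
    360-point grid (densities per radian); a uniform component equal in area
    to ``guess_rate`` is removed from both and each is renormalized. If
    ``conditions`` labels are given, trials are first subsampled (seeded) to
    an equal count per condition, which equates the entropy-estimator bias
    across conditions.
    """
    if not (0.0 <= guess_rate < 1.0):
        raise ValueError("guess_rate must be in [0, 1)")
    reports = np.asarray(reports_deg, dtype=float)
    targets = np.asarray(targets_deg, dtype=float)
    if reports.shape != targets.shape:
        raise ValueError("reports and targets must have matching length")
    if conditions is not None:
        conditions = np.asarray(conditions)
        rng = np.random.default_rng(seed)
        counts = {c: np.sum(conditions == c) for c in np.unique(conditions)}
        n_min = min(counts.values())
        keep = np.concatenate([
            rng.choice(np.where(conditions == c)[0], size=n_min, replace=False)
            for c in np.unique(conditions)
        ])
        reports, targets = reports[keep], targets[keep]
    f_resp = circular_kde(np.deg2rad(reports))
    f_targ = circular_kde(np.deg2rad(targets))
    if guess_rate > 0:
        f_resp = _remove_guess_component(f_resp, guess_rate)
        f_targ = _remove_guess_component(f_targ, guess_rate)
    h_resp = circular_entropy_bits(f_resp)
    h_targ = circular_entropy_bits(f_targ)
    return ClusterResult(C=h_resp - h_targ, H_resp=h_resp, H_targ=h_targ,
                         guess_rate=guess_rate, n_trials_used=len(reports))


# ---------------------------------------------------------------------------
# engagement screen: three-component mixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MixtureFit:
    """Target / guess / swap mixture of reports (delay-independent screen)."""

    p_target: float
    p_guess: float
    p_swap: float
    concentration: float
    converged: bool

    @property
    def exclude(self) -> bool | None:
        """Screening verdict at the 20% guess-rate cutoff (None if the fit
        did not converge)."""
        if not self.converged:
            return None
        return self.p_guess > 0.20


def _kappa_from_resultant(r: float) -> float:
    """Solve I1(k)/I0(k) = r for the von Mises concentration."""
    r = float(np.clip(r, 0.0, 1.0 - 1e-10))
    if r < 1e-6:
        return 0.0
    return float(brentq(lambda k: i1e(k) / i0e(k) - r, 1e-8, 1e4))


def fit_basic_mixture(dataset: Dataset, max_iter: int = 1000,
                      tol: float = 1e-7) -> MixtureFit:
    """EM fit of the uniform + von Mises(target) [+ von Mises(non-target)]
    mixture, pooled across all trials; used to screen out disengaged subjects
    (estimated guess rate above 20%)."""
    if len(dataset) < 50:
        raise ValueError("mixture screen needs at least 50 trials")
    err_t = np.deg2rad(dataset.errors_deg)
    nt_errs = []  # per trial: array of report - nontarget deviations
    for t in dataset.trials:
        if t.nontargets_deg:
            nt_errs.append(np.deg2rad(circ_error(
                t.report_deg, np.asarray(t.nontargets_deg))))
        else:
            nt_errs.append(np.empty(0))
    has_swaps = any(len(e) for e in nt_errs)
    n = len(dataset)
    p_g, p_s, kappa = 0.2, 0.1 if has_swaps else 0.0, 8.0
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        sd = 1.0 / np.sqrt(max(kappa, 1e-12))
        d_t = von_mises_density(err_t, 0.0, sd)
        d_u = np.full(n, 1.0 / TWO_PI)
        d_s = np.array([von_mises_density(e, 0.0, sd).mean() if len(e) else 0.0
                        for e in nt_errs])
        p_t = 1.0 - p_g - p_s
        num_t, num_g, num_s = p_t * d_t, p_g * d_u, p_s * d_s
        tot = num_t + num_g + num_s
        ll = float(np.sum(np.log(tot)))
        r_t, r_g, r_s = num_t / tot, num_g / tot, num_s / tot
        p_g = float(r_g.mean())
        p_s = float(r_s.mean()) if has_swaps else 0.0
        # concentration from the responsibility-weighted resultant of both
        # memory components (swap deviations share the same kappa)
        c = np.sum(r_t * np.cos(err_t))
        s = np.sum(r_t * np.sin(err_t))
        wsum = np.sum(r_t)
        for i, e in enumerate(nt_errs):
            if len(e) and r_s[i] > 0:
                c += r_s[i] * np.cos(e).mean()
                s += r_s[i] * np.sin(e).mean()
                wsum += r_s[i]
        r_len = np.hypot(c, s) / max(wsum, 1e-12)
        kappa = _kappa_from_resultant(r_len)
        if abs(ll - ll_old) < tol * max(1.0, abs(ll)):
            converged = True
            break
        ll_old = ll
    return MixtureFit(p_target=1.0 - p_g - p_s, p_guess=p_g, p_swap=p_s,
                      concentration=kappa, converged=converged)


# ---------------------------------------------------------------------------
# nonuniformity tests
# ---------------------------------------------------------------------------

def hodges_ajne_pvalue(angles_deg) -> float:
    """Omnibus test against circular uniformity (count-based, closed form).

    The statistic m is the smallest number of observations inside any closed
    half circle; p = (n - 2m) * C(n, m) * 2^(1-n), capped at 1.
    """
    a = np.sort(np.deg2rad(wrap_deg(angles_deg)))
    n = len(a)
    if n < 10:
        raise ValueError("need at least 10 observations")
    ext = np.concatenate([a, a + TWO_PI])
    # observations in the half circle [a_i, a_i + pi); the 1e-9 tolerance
    # keeps points that land on the boundary (e.g. perfectly even spacing)
    # out of the half circle despite floating-point jitter
    hi = np.searchsorted(ext, a + np.pi - 1e-9, side="left")
    counts = hi - np.arange(n)
    m = int(min(counts.min(), n - counts.max()))
    if n - 2 * m <= 0:
        return 1.0
    logp = (np.log(n - 2.0 * m) + gammaln(n + 1) - gammaln(m + 1)
            - gammaln(n - m + 1) - (n - 1) * np.log(2.0))
    return float(min(np.exp(logp), 1.0))


def kuiper_two_sample_stat(a_deg, b_deg) -> float:
    """Two-sample Kuiper statistic V = D+ + D- (rotation invariant)."""
    a = np.sort(np.deg2rad(wrap_deg(a_deg)))
    b = np.sort(np.deg2rad(wrap_deg(b_deg)))
    grid = np.concatenate([a, b])
    fa = np.searchsorted(a, grid, side="right") / len(a)
    fb = np.searchsorted(b, grid, side="right") / len(b)
    d = fa - fb
    return float(d.max() - d.min())


def nonuniformity_tests(reports_deg, targets_deg, n_perm: int = 1000,
                        seed: int = 0) -> dict:
    """Hodges-Ajne test of the reports against uniformity, plus a permutation
    Kuiper test of reports against the target distribution (pooled
    relabeling null). Seed-reproducible."""
    if n_perm < 100:
        get_logger().warning("kuiper permutation test with n_perm=%d (<100)",
                             n_perm)
    rng = np.random.default_rng(seed)
    reports = np.asarray(reports_deg, dtype=float)
    targets = np.asarray(targets_deg, dtype=float)
    v_obs = kuiper_two_sample_stat(reports, targets)
    pooled = np.concatenate([reports, targets])
    n = len(reports)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if kuiper_two_sample_stat(perm[:n], perm[n:]) >= v_obs:
            count += 1
    return {
        "hodges_ajne_p": hodges_ajne_pvalue(reports),
        "kuiper_perm_p": (1 + count) / (n_perm + 1),
    }


# ---------------------------------------------------------------------------
# response-histogram peaks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakSet:
    """Significant local maxima of the response density."""

    angles_deg: np.ndarray
    amplitudes: np.ndarray
    threshold: float          # 95th percentile of null peak amplitudes
    candidate_angles_deg: np.ndarray

    def __len__(self) -> int:
        return len(self.angles_deg)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"angle_deg": self.angles_deg,
                             "amplitude": self.amplitudes,
                             "threshold": self.threshold})


def _kde_peaks(density: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices and amplitudes of samples larger than both circular neighbors."""
    left = np.roll(density, 1)
    right = np.roll(density, -1)
    idx = np.where((density > left) & (density > right))[0]
    return idx, density[idx]


def find_response_peaks(reports_deg, targets_deg, n_boot: int = 1000,
                        seed: int = 0) -> PeakSet:
    """Response-density peaks exceeding a resampled-target null.

    Candidate peaks are KDE samples above both neighbors; the null pools the
    peak amplitudes obtained from ``n_boot`` resamples (with replacement) of
    the target distribution, and candidates above its 95th percentile are
    retained.
    """
    reports = np.asarray(reports_deg, dtype=float)
    targets = np.asarray(targets_deg, dtype=float)
    if len(reports) < 100:
        raise ValueError("peak detection needs at least 100 trials")
    rng = np.random.default_rng(seed)
    log_run_seed(seed, "find_response_peaks")
    dens = circular_kde(np.deg2rad(reports))
    idx, amps = _kde_peaks(dens)
    null_amps = []
    for _ in range(n_boot):
        resamp = rng.choice(targets, size=len(reports), replace=True)
        _, a = _kde_peaks(circular_kde(np.deg2rad(resamp)))
        null_amps.append(a)
    threshold = float(np.percentile(np.concatenate(null_amps), 95))
    keep = amps > threshold
    step_deg = 360.0 / len(dens)
    return PeakSet(
        angles_deg=idx[keep] * step_deg,
        amplitudes=amps[keep],
        threshold=threshold,
        candidate_angles_deg=idx * step_deg,
    )


# ---------------------------------------------------------------------------
# bias and precision across color space
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BiasProfile:
    """Binned bias (mean signed error) and precision (circular SD) of reports
    as a function of target color, with local slopes at anchor points.

    Slopes are dimensionless (degrees of bias per degree of target offset);
    a negative slope at an anchor is the signature of attraction toward it.
    Empty bins hold NaN.
    """

    bin_centers_deg: np.ndarray
    bias_deg: np.ndarray
    sd_deg: np.ndarray
    counts: np.ndarray
    anchors_deg: np.ndarray
    slopes: np.ndarray
    mean_sd_near_anchors: float
    window_deg: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"bin_center_deg": self.bin_centers_deg,
                             "bias_deg": self.bias_deg,
                             "sd_deg": self.sd_deg,
                             "n_trials": self.counts})

    def slope_at(self, anchor_deg: float) -> float:
        i = int(np.argmin(np.abs(circ_error(self.anchors_deg, anchor_deg))))
        return float(self.slopes[i])


def bias_precision_profile(dataset: Dataset, bin_width_deg: float = 4.0,
                           anchors_deg: Sequence[float] = (),
                           window_deg: float = 15.0) -> BiasProfile:
    """Bias and SD of reports per target-color bin, plus slopes at anchors.

    Bias per bin is the circular mean of signed errors, SD the circular
    standard deviation. The slope at each anchor is an ordinary
    least-squares line through the (target offset, bias) pairs of the bins
    within +/-``window_deg``; the precision summary is the mean SD over the
    same window.
    """
    if abs(360.0 / bin_width_deg - round(360.0 / bin_width_deg)) > 1e-9:
        raise ValueError("bin width must divide 360")
    n_bins = int(round(360.0 / bin_width_deg))
    targets = dataset.targets_deg
    errors = dataset.errors_deg
    which = np.floor(targets / bin_width_deg).astype(int) % n_bins
    centers = (np.arange(n_bins) + 0.5) * bin_width_deg
    bias = np.full(n_bins, np.nan)
    sd = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for k in range(n_bins):
        e = errors[which == k]
        counts[k] = len(e)
        if len(e) == 0:
            continue
        bias[k] = circ_error(circ_mean_deg(e), 0.0)
        if len(e) > 1:
            sd[k] = circ_sd_deg(e)
    anchors = np.asarray(anchors_deg, dtype=float)
    slopes = np.full(len(anchors), np.nan)
    sds_near = []
    for i, a in enumerate(anchors):
        off = circ_error(centers, a)
        sel = (np.abs(off) <= window_deg) & ~np.isnan(bias)
        if np.sum(sel) >= 2:
            slopes[i] = float(np.polyfit(off[sel], bias[sel], 1)[0])
        sds_near.extend(sd[sel & ~np.isnan(sd)])
    mean_sd = float(np.mean(sds_near)) if sds_near else np.nan
    return BiasProfile(centers, bias, sd, counts, anchors, slopes, mean_sd,
                       window_deg)


# ---------------------------------------------------------------------------
# error growth near fixed points
# ---------------------------------------------------------------------------

def _near(targets_deg: np.ndarray, points_deg: np.ndarray,
          window_deg: float) -> np.ndarray:
    d = np.abs(circ_error(targets_deg[:, None], points_deg[None, :]))
    return d.min(axis=1) <= window_deg


def error_growth_at_fixed_points(dataset: Dataset, fixed_points: FixedPointSet,
                                 window_deg: float = 15.0, n_boot: int = 1000,
                                 seed: int = 0) -> dict:
    """Delay-related error growth for targets near stable vs unstable fixed
    points.

    delta_err = mean |error| on longest-delay trials minus shortest-delay
    trials, separately for targets within ``window_deg`` of a stable or an
    unstable fixed point. One-sided bootstrap p for growth(UFP) > growth(SFP)
    (trials resampled with replacement).
    """
    if len(fixed_points.stable) == 0 or len(fixed_points.unstable) == 0:
        raise ValueError("need both stable and unstable fixed points")
    delays = dataset.delays
    levels = np.unique(delays)
    if len(levels) < 2:
        raise ValueError("need at least two delay levels")
    short, long_ = levels.min(), levels.max()
    targets = dataset.targets_deg
    abserr = np.abs(dataset.errors_deg)
    near_s = _near(targets, fixed_points.stable_deg, window_deg)
    near_u = _near(targets, fixed_points.unstable_deg, window_deg)
    is_short = delays == short
    is_long = delays == long_

    def growth(idx) -> tuple[float, float]:
        res = []
        for near in (near_s[idx], near_u[idx]):
            e, sh, lg = abserr[idx], is_short[idx], is_long[idx]
            if not (np.any(near & sh) and np.any(near & lg)):
                res.append(np.nan)
            else:
                res.append(float(e[near & lg].mean() - e[near & sh].mean()))
        return tuple(res)

    all_idx = np.arange(len(dataset))
    d_sfp, d_ufp = growth(all_idx)
    rng = np.random.default_rng(seed)
    log_run_seed(seed, "error_growth_at_fixed_points")
    count, valid = 0, 0
    for _ in range(n_boot):
        idx = rng.integers(len(dataset), size=len(dataset))
        bs, bu = growth(idx)
        if np.isnan(bs) or np.isnan(bu):
            continue
        valid += 1
        if bu - bs <= 0:
            count += 1
    p = (1 + count) / (valid + 1) if valid else np.nan
    return {"delta_err_sfp": d_sfp, "delta_err_ufp": d_ufp,
            "p_value": p, "n_boot_valid": valid}


# ---------------------------------------------------------------------------
# attractor / common-color alignment
# ---------------------------------------------------------------------------

def attractor_alignment(attractors_deg: Sequence[np.ndarray],
                        references_deg: Sequence[np.ndarray],
                        n_perm: int = 1000, seed: int = 0) -> dict:
    """Do fitted attractors sit closer to reference colors than chance?

    The statistic is the mean (over units and attractors) absolute circular
    distance from each attractor to its nearest reference point. The null
    re-pairs each unit's attractor set with a randomly chosen unit's
    reference set rotated by a random phase; p is the fraction of null
    statistics at least as small (i.e. as aligned) as observed.
    """
    if n_perm < 100:
        get_logger().warning("alignment test with n_perm=%d (<100)", n_perm)
    if len(attractors_deg) != len(references_deg) or len(attractors_deg) == 0:
        raise ValueError("need matched, non-empty attractor/reference lists")
    rng = np.random.default_rng(seed)
    log_run_seed(seed, "attractor_alignment")

    def mean_nearest(atts, refs, shifts):
        total, count = 0.0, 0
        for a, r, s in zip(atts, refs, shifts):
            a = np.atleast_1d(np.asarray(a, dtype=float))
            r = wrap_deg(np.atleast_1d(np.asarray(r, dtype=float)) + s)
            d = np.abs(circ_error(a[:, None], r[None, :])).min(axis=1)
            total += d.sum()
            count += len(d)
        return total / count

    zero = np.zeros(len(attractors_deg))
    obs = mean_nearest(attractors_deg, references_deg, zero)
    null = np.empty(n_perm)
    n_units = len(attractors_deg)
    for k in range(n_perm):
        order = rng.permutation(n_units)
        shifts = rng.uniform(0.0, 360.0, n_units)
        null[k] = mean_nearest(attractors_deg,
                               [references_deg[i] for i in order], shifts)
    p = (1 + int(np.sum(null <= obs))) / (n_perm + 1)
    return {"mean_distance_deg": float(obs), "p_value": float(p),
            "null_mean_deg": float(null.mean())}
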