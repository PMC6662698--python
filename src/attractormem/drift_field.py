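"""Drift function G(theta) on the hue circle.

The deterministic component of memory dynamics is a velocity field over the
circular feature space, expressed as a weighted sum of the first derivatives
of ``n_basis`` von Mises densities whose means tile the circle one circular SD
apart. After summation the field is divided by its maximum absolute value, so
the drift gain beta is read directly as the maximum instantaneous drift rate
(radians per second).

Stable fixed points (attractors) are negative-slope zero crossings of G --
equivalently peaks of its antiderivative -- and unstable fixed points are the
positive-slope crossings in between. Shallow attractors are pruned with a
prominence rule on the antiderivative's peaks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks
from scipy.special import i0e

from .core_io import Grid, get_logger, periodic_interp, wrap_rad

DEFAULT_N_BASIS = 12


def sd_to_kappa(sd_rad: float) -> float:
    """Map a circular SD to a von Mises concentration, kappa = 1/sd^2.

    This is the standard high-concentration approximation; it keeps the basis
    bumps smoothly overlapping at the default spacing of one SD.
    """
    if sd_rad <= 0:
        raise ValueError("circular SD must be positive")
    return 1.0 / sd_rad**2


def von_mises_density(theta, mean_rad: float, sd_rad: float):
    """Von Mises density (per radian) with the SD -> kappa = 1/SD^2 convention."""
    kappa = sd_to_kappa(sd_rad)
    d = np.asarray(theta, dtype=float) - mean_rad
    # exponentially scaled Bessel keeps this finite for kappa up to ~1e6
    return np.exp(kappa * (np.cos(d) - 1.0)) / (2.0 * np.pi * i0e(kappa))


def von_mises_density_derivative(theta, mean_rad: float, sd_rad: float):
    """d/dtheta of :func:`von_mises_density` (analytic, not finite-differenced)."""
    kappa = sd_to_kappa(sd_rad)
    d = np.asarray(theta, dtype=float) - mean_rad
    return -kappa * np.sin(d) * von_mises_density(theta, mean_rad, sd_rad)


@dataclass(frozen=True)
class DriftBasis:
    """Von Mises derivative basis sampled on a grid (matrix n_bins x n_basis)."""

    grid: Grid
    means: np.ndarray          # basis means, radians
    sd: float                  # shared circular SD, radians
    matrix: np.ndarray         # column j = derivative curve of basis j

    @property
    def n_basis(self) -> int:
        return len(self.means)


def build_basis(n_basis: int = DEFAULT_N_BASIS, grid: Grid | None = None) -> DriftBasis:
    """Basis of ``n_basis`` von Mises density derivatives, means 2*pi*j/n_basis
    (j = 1..n_basis) spaced one circular SD (2*pi/n_basis) apart."""
    if n_basis < 2:
        raise ValueError("need at least 2 basis functions")
    grid = grid or Grid()
    sd = 2.0 * np.pi / n_basis
    means = wrap_rad(2.0 * np.pi / n_basis * np.arange(1, n_basis + 1))
    cols = [von_mises_density_derivative(grid.centers, m, sd) for m in means]
    return DriftBasis(grid=grid, means=means, sd=sd, matrix=np.column_stack(cols))


@dataclass(frozen=True)
class DriftField:
    """Normalized drift function: values of G per grid bin, max |G| = 1.

    ``norm_constant`` is the maximum absolute value of the raw weighted sum;
    it is 0 for the everywhere-zero field (no division was performed).
    """

    weights: np.ndarray
    values: np.ndarray
    grid: Grid
    norm_constant: float

    @property
    def is_zero(self) -> bool:
        return self.norm_constant == 0.0

    def __call__(self, theta_rad):
        """G interpolated at arbitrary angles (periodic linear interpolation)."""
        return periodic_interp(theta_rad, self.grid, self.values)

    def rotated(self, delta_rad: float) -> "DriftField":
        """The same field rotated by ``delta_rad`` (values resampled on grid)."""
        vals = periodic_interp(self.grid.centers - delta_rad, self.grid, self.values)
        return DriftField(self.weights.copy(), np.asarray(vals), self.grid,
                          self.norm_constant)

    def to_table(self, path: str | Path) -> None:
        """Two-column text table: angle (deg), G value."""
        arr = np.column_stack([self.grid.centers_deg, self.values])
        np.savetxt(path, arr, header="angle_deg G", comments="# ")

    def weights_to_json(self) -> str:
        return json.dumps({"weights": list(map(float, self.weights)),
                           "norm_constant": self.norm_constant})


def drift_field_from_table(path: str | Path) -> DriftField:
    arr = np.loadtxt(path)
    n = arr.shape[0]
    grid = Grid(n)
    values = arr[:, 1]
    m = float(np.max(np.abs(values)))
    return DriftField(np.array([]), values, grid, m)


def eval_drift(weights, basis: DriftBasis) -> DriftField:
    """Weighted basis sum, normalized so max |G| = 1 (G == 0 stays 0)."""
    w = np.asarray(weights, dtype=float)
    if w.shape != (basis.n_basis,):
        raise ValueError(f"expected {basis.n_basis} weights, got {w.shape}")
    raw = basis.matrix @ w
    m = float(np.max(np.abs(raw)))
    if m == 0.0:
        return DriftField(w, np.zeros_like(raw), basis.grid, 0.0)
    return DriftField(w, raw / m, basis.grid, m)


@dataclass(frozen=True)
class FixedPointSet:
    """Stable (attracting) and unstable (repelling) zeros of a drift field.

    Angles are radians; ``stable_slopes``/``unstable_slopes`` hold dG/dtheta
    at each point. Stable and unstable points alternate around the circle.
    """

    stable: np.ndarray
    unstable: np.ndarray
    stable_slopes: np.ndarray
    unstable_slopes: np.ndarray

    @property
    def stable_deg(self) -> np.ndarray:
        return np.rad2deg(self.stable)

    @property
    def unstable_deg(self) -> np.ndarray:
        return np.rad2deg(self.unstable)

    def __len__(self) -> int:
        return len(self.stable) + len(self.unstable)


def _zero_crossings(values: np.ndarray, grid: Grid):
    """Circular sign-change scan; returns (angles, slopes, direction) arrays.

    direction -1 marks a +to- crossing (stable), +1 a -to+ crossing (unstable).
    Crossing angles are localized by linear interpolation between bin centers.
    Bins where G is exactly zero are treated by the sign of the neighbors.
    """
    n = grid.n_bins
    c = grid.centers
    g0 = values
    g1 = np.roll(values, -1)
    angles, slopes, direction = [], [], []
    for i in range(n):
        a, b = g0[i], g1[i]
        if a == 0.0 and b == 0.0:
            continue
        if (a > 0 and b <= 0) or (a < 0 and b >= 0) or (a == 0.0 and b != 0.0):
            if a == 0.0:
                theta = c[i]
            else:
                theta = c[i] + grid.delta * a / (a - b)
            # skip the crossing if it belongs to the next interval start (a==0
            # handled once: only when previous interval did not already cross)
            slope = (b - a) / grid.delta
            if slope == 0.0:
                continue
            angles.append(wrap_rad(theta))
            slopes.append(slope)
            direction.append(-1 if slope < 0 else +1)
    return np.array(angles), np.array(slopes), np.array(direction, dtype=int)


def find_fixed_points(field: DriftField,
                      prominence_percentile: float = 0.20) -> FixedPointSet:
    """Locate attractors (SFPs) and repellors (UFPs) of a drift field.

    SFPs are peaks of the numerical antiderivative of G; peaks whose
    prominence falls strictly below the ``prominence_percentile`` quantile of
    this field's peak prominences are excluded, and the unstable points are
    re-paired so that stable and unstable points alternate.
    """
    empty = np.array([])
    if field.is_zero:
        return FixedPointSet(empty, empty, empty, empty)
    angles, slopes, direction = _zero_crossings(field.values, field.grid)
    if len(angles) == 0:
        return FixedPointSet(empty, empty, empty, empty)

    sfp_mask = direction < 0
    sfp_angles, sfp_slopes = angles[sfp_mask], slopes[sfp_mask]
    ufp_angles, ufp_slopes = angles[~sfp_mask], slopes[~sfp_mask]

    # prominence of each SFP as a peak of the antiderivative of G
    g = field.values - field.values.mean()     # enforce exact periodicity
    integral = np.cumsum(g) * field.grid.delta
    tiled = np.concatenate([integral, integral, integral])
    peaks, props = find_peaks(tiled, prominence=0.0)
    n = field.grid.n_bins
    mid = (peaks >= n) & (peaks < 2 * n)
    peak_bins = peaks[mid] - n
    peak_prom = props["prominences"][mid]

    if len(peak_bins) and len(sfp_angles):
        # match each SFP crossing to the nearest antiderivative peak bin
        prom = np.empty(len(sfp_angles))
        for k, th in enumerate(sfp_angles):
            d = np.abs(np.angle(np.exp(1j * (field.grid.centers[peak_bins] - th))))
            prom[k] = peak_prom[np.argmin(d)]
        # exclude peaks whose prominence percentile-rank is at or below the
        # cutoff; prominences within 5% of each other count as tied (midrank),
        # so the members of a near-symmetric attractor set are never dropped
        close = np.isclose(prom[None, :], prom[:, None], rtol=0.05)
        rank = (np.sum((prom[None, :] < prom[:, None]) & ~close, axis=1)
                + 0.5 * np.sum(close, axis=1)) / len(prom)
        keep = rank > prominence_percentile
        sfp_angles, sfp_slopes = sfp_angles[keep], sfp_slopes[keep]

    if len(sfp_angles) == 0:
        return FixedPointSet(empty, empty, empty, empty)

    # re-pair: between consecutive surviving SFPs keep the deepest UFP
    order = np.argsort(sfp_angles)
    sfp_angles, sfp_slopes = sfp_angles[order], sfp_slopes[order]
    kept_u_angles, kept_u_slopes = [], []
    k = len(sfp_angles)
    for i in range(k):
        lo = sfp_angles[i]
        hi = sfp_angles[(i + 1) % k]
        if k == 1:
            in_arc = np.ones(len(ufp_angles), dtype=bool)
        else:
            span = (ufp_angles - lo) % (2 * np.pi)
            arc = (hi - lo) % (2 * np.pi)
            in_arc = span < arc
        if not np.any(in_arc):
            continue
        cand_angles = ufp_angles[in_arc]
        cand_slopes = ufp_slopes[in_arc]
        depth = periodic_interp(cand_angles, field.grid, integral)
        j = int(np.argmin(np.atleast_1d(depth)))
        kept_u_angles.append(cand_angles[j])
        kept_u_slopes.append(cand_slopes[j])
    return FixedPointSet(
        sfp_angles, np.array(kept_u_angles), sfp_slopes, np.array(kept_u_slopes)
    )


def fit_drift_to_profile(profile, basis: DriftBasis) -> DriftField:
    """Least-squares basis weights for a target drift profile on the grid.

    The returned field is re-normalized to max |G| = 1. A (near-)constant
    profile is degenerate -- every basis column is orthogonal to constants --
    and yields the zero field with a logged warning.
    """
    y = np.asarray(profile, dtype=float)
    if y.shape != (basis.grid.n_bins,):
        raise ValueError("profile must be sampled on the basis grid")
    if not np.all(np.isfinite(y)):
        raise ValueError("profile must be finite")
    if np.ptp(y) < 1e-14:
        get_logger().warning(
            "fit_drift_to_profile: constant profile is degenerate; returning G == 0"
        )
        return eval_drift(np.zeros(basis.n_basis), basis)
    w, *_ = np.linalg.lstsq(basis.matrix, y, rcond=None)
    return eval_drift(w, basis)
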