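"""Control model: nonlinear stimulus-to-perceptual mapping with pure diffusion.

An alternative (non-attractor) account of response clustering: the circular
stimulus parameterization maps onto a hypothetical perceptual space shaped
like a square, memories diffuse in that space, and reports are projected
back. Regions of the circle that the mapping compresses accumulate reports,
so this model also clusters -- but it cannot produce attractive bias around
the cluster peaks, which is the dissociating signature of real attractor
dynamics.

The mapping is a radial projection between a circle and a concentric unit
square; the perceptual coordinate is arc length along the square's perimeter,
discretized into ``n_points`` sites for the random walk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import Dataset, TrialRecord, TWO_PI, log_run_seed, wrap_deg

SQUARE_PERIMETER = 4.0  # unit square


@dataclass(frozen=True)
class WarpConfig:
    """Simulation settings for the warped-space diffusion control."""

    n_points: int = 1024      # perimeter discretization
    n_angles: int = 100_000   # simulated targets
    n_steps: int = 1000       # diffusion timesteps
    step_max: int = 4         # max |step| in perimeter points per timestep
    seed: int = 0

    def __post_init__(self):
        if min(self.n_points, self.n_angles, self.n_steps) <= 0:
            raise ValueError("all counts must be positive")
        if self.step_max < 0 or self.step_max >= self.n_points / 2:
            raise ValueError("step_max must be in [0, n_points/2)")


def circle_to_square(angle_rad):
    """Arc-length coordinate on the unit square's perimeter for a stimulus
    angle, by radial projection from the common center.

    The perimeter is traversed counterclockwise starting at (0.5, 0); total
    length is 4. Angle 45 degrees lands exactly on the (0.5, 0.5) corner.
    """
    th = np.asarray(angle_rad, dtype=float) % TWO_PI
    x = np.cos(th)
    y = np.sin(th)
    scale = 0.5 / np.maximum(np.abs(x), np.abs(y))
    bx, by = x * scale, y * scale
    s = np.empty_like(th)
    right = np.abs(bx - 0.5) < 1e-12
    top = np.abs(by - 0.5) < 1e-12
    left = np.abs(bx + 0.5) < 1e-12
    bottom = np.abs(by + 0.5) < 1e-12
    # corners satisfy two masks; later assignments win and agree by continuity
    s[bottom] = 2.5 + (bx[bottom] + 0.5)
    s[left] = 1.5 + (0.5 - by[left])
    s[top] = 0.5 + (0.5 - bx[top])
    s[right] = by[right]
    out = s % SQUARE_PERIMETER
    return out if np.ndim(angle_rad) else float(out)


def square_to_circle(s):
    """Inverse of :func:`circle_to_square`: perimeter coordinate to angle."""
    q = (np.asarray(s, dtype=float) + 0.5) % SQUARE_PERIMETER
    side = np.floor(q).astype(int) % 4
    u = q - np.floor(q)
    x = np.empty_like(q)
    y = np.empty_like(q)
    m = side == 0          # right side, traversed upward
    x[m], y[m] = 0.5, u[m] - 0.5
    m = side == 1          # top, right to left
    x[m], y[m] = 0.5 - u[m], 0.5
    m = side == 2          # left, downward
    x[m], y[m] = -0.5, 0.5 - u[m]
    m = side == 3          # bottom, left to right
    x[m], y[m] = u[m] - 0.5, -0.5
    out = np.arctan2(y, x) % TWO_PI
    return out if np.ndim(s) else float(out)


def perimeter_pushforward_density(angles_rad) -> np.ndarray:
    """Density over stimulus angle of a uniform distribution on the square's
    perimeter (the long-time limit of the warp model), per radian."""
    th = np.asarray(angles_rad, dtype=float)
    # |ds/dtheta| = 0.5 / max(|cos|,|sin|)^2  (sec^2 on each side)
    dsdth = 0.5 / np.maximum(np.abs(np.cos(th)), np.abs(np.sin(th))) ** 2
    return dsdth / SQUARE_PERIMETER


def simulate_warp(config: WarpConfig = WarpConfig()) -> tuple[np.ndarray, np.ndarray]:
    """(targets_deg, reports_deg) from the warped-space diffusion model.

    Targets are uniform on the circle, projected to the discretized perimeter,
    random-walked for ``n_steps`` steps of uniform{-step_max..step_max} sites
    with wraparound, and projected back to stimulus angles.
    """
    rng = np.random.default_rng(config.seed)
    log_run_seed(config.seed, "simulate_warp")
    targets = rng.uniform(0.0, TWO_PI, config.n_angles)
    s = circle_to_square(targets)
    pos = np.floor(s / SQUARE_PERIMETER * config.n_points).astype(np.int64)
    if config.step_max > 0:
        for _ in range(config.n_steps):
            pos += rng.integers(-config.step_max, config.step_max + 1,
                                size=config.n_angles)
        pos %= config.n_points
    reports = square_to_circle((pos + 0.5) / config.n_points * SQUARE_PERIMETER)
    return np.rad2deg(targets), np.rad2deg(reports)


def warp_dataset(config: WarpConfig = WarpConfig(),
                 subject: str = "warp") -> Dataset:
    """Package warp-model samples as a standard load-1 trial table (delay
    codes the number of diffusion steps) so the model-free analyses apply
    unchanged."""
    targets, reports = simulate_warp(config)
    trials = [
        TrialRecord(subject=subject, load=1, delay_s=float(config.n_steps),
                    target_deg=float(wrap_deg(t)), nontargets_deg=(),
                    report_deg=float(wrap_deg(r)), trial_index=i)
        for i, (t, r) in enumerate(zip(targets, reports))
    ]
    return Dataset(trials, species="human")
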