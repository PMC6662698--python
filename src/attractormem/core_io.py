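"""Core data model for continuous-report working-memory experiments.

Angles live in two conventions: user-facing values (stimulus hues, reports,
errors) are degrees in [0, 360); everything internal to the dynamical model is
radians on [0, 2*pi). Positive angular error means clockwise deviation.

This module holds the circular-angle arithmetic, the discretized state space
(:class:`Grid`), normalized densities over it (:class:`ProbabilityField`), the
trial-level data model (:class:`TrialRecord` / :class:`Dataset`), CSV round-trip
IO, and small config/logging plumbing shared by the rest of the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

TWO_PI = 2.0 * np.pi

#: CSV column order for trial tables.
TRIAL_COLUMNS = [
    "subject",
    "load",
    "delay_s",
    "target_deg",
    "nontarget1_deg",
    "nontarget2_deg",
    "report_deg",
    "trial_index",
]

logger = logging.getLogger("attractormem")


def get_logger() -> logging.Logger:
    """Package logger; callers may attach handlers, we never do so implicitly."""
    return logger


def log_run_seed(seed: int, context: str = "") -> None:
    """Record the master seed of a randomized run in the package log."""
    logger.info("run seed=%d %s", seed, context)


def load_config(path: str | Path) -> dict:
    """Load a YAML (or JSON, a YAML subset) configuration file into a dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return cfg


# ---------------------------------------------------------------------------
# circular-angle arithmetic
# ---------------------------------------------------------------------------

def wrap_deg(angle):
    """Wrap angles (degrees) into [0, 360)."""
    return np.asarray(angle, dtype=float) % 360.0


def wrap_rad(angle):
    """Wrap angles (radians) into [0, 2*pi)."""
    return np.asarray(angle, dtype=float) % TWO_PI


def circ_error(report, target):
    """Signed angular deviation report - target, in degrees, in (-180, 180].

    Positive values are clockwise deviations. The antipodal tie (difference of
    exactly 180 deg) is broken to +180 by convention.

    Scalars in give a scalar out; arrays broadcast.
    """
    report = np.asarray(report, dtype=float)
    target = np.asarray(target, dtype=float)
    if not (np.all(np.isfinite(report)) and np.all(np.isfinite(target))):
        raise ValueError("circ_error requires finite angles")
    d = (report - target) % 360.0
    out = np.where(d > 180.0, d - 360.0, d)
    if out.ndim == 0:
        return float(out)
    return out


def circ_dist_rad(a, b):
    """Signed circular difference a - b in radians, in (-pi, pi]."""
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % TWO_PI
    return np.where(d > np.pi, d - TWO_PI, d)


def circ_mean_deg(angles_deg, weights=None) -> float:
    """Circular mean of angles in degrees, result in [0, 360)."""
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))
    w = np.ones_like(a) if weights is None else np.asarray(weights, dtype=float)
    s = np.sum(w * np.sin(a))
    c = np.sum(w * np.cos(a))
    return float(np.rad2deg(np.arctan2(s, c)) % 360.0)


def circ_resultant(angles_rad, weights=None) -> float:
    """Mean resultant length R of a circular sample (or weighted sample)."""
    a = np.asarray(angles_rad, dtype=float)
    w = np.ones_like(a) if weights is None else np.asarray(weights, dtype=float)
    wsum = np.sum(w)
    s = np.sum(w * np.sin(a)) / wsum
    c = np.sum(w * np.cos(a)) / wsum
    return float(np.hypot(s, c))


def circ_sd_deg(angles_deg, weights=None) -> float:
    """Circular standard deviation sqrt(-2 ln R) of a sample, in degrees."""
    r = circ_resultant(np.deg2rad(np.asarray(angles_deg, dtype=float)), weights)
    r = min(max(r, 1e-12), 1.0)
    return float(np.rad2deg(np.sqrt(-2.0 * np.log(r))))


# ---------------------------------------------------------------------------
# state-space grid and densities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Grid:
    """Evenly spaced circular partition of [0, 2*pi) into ``n_bins`` bins.

    Bin k covers [k*delta, (k+1)*delta) with its center at (k + 1/2)*delta;
    the default 100 bins discretize the hue circle the way the dynamical model
    does.
    """

    n_bins: int = 100

    def __post_init__(self):
        if self.n_bins < 2:
            raise ValueError("Grid needs at least 2 bins")

    @property
    def delta(self) -> float:
        return TWO_PI / self.n_bins

    @property
    def centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.delta

    @property
    def centers_deg(self) -> np.ndarray:
        return np.rad2deg(self.centers)

    def bin_of(self, angle_rad) -> np.ndarray:
        """Index of the bin containing each angle (radians, any real value)."""
        return (np.floor(wrap_rad(angle_rad) / self.delta).astype(int)) % self.n_bins


@dataclass
class ProbabilityField:
    """Nonnegative density over a :class:`Grid`, per radian, integrating to 1."""

    values: np.ndarray
    grid: Grid

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_bins,):
            raise ValueError("values must have one entry per grid bin")
        if np.any(self.values < 0):
            raise ValueError("density values must be nonnegative")
        if abs(self.mass() - 1.0) > 1e-8:
            raise ValueError(f"density must integrate to 1 (got {self.mass()!r})")

    def mass(self) -> float:
        return float(np.sum(self.values) * self.grid.delta)

    @classmethod
    def from_unnormalized(cls, values, grid: Grid) -> "ProbabilityField":
        v = np.asarray(values, dtype=float).copy()
        # expm round-off can leave tiny negatives; anything larger is a bug
        if np.any(v < -1e-12):
            raise ValueError(
                f"density has significantly negative entries (min {v.min()!r})"
            )
        v = np.clip(v, 0.0, None)
        total = v.sum() * grid.delta
        if total <= 0:
            raise ValueError("cannot normalize an all-zero density")
        return cls(v / total, grid)

    @classmethod
    def uniform(cls, grid: Grid) -> "ProbabilityField":
        return cls(np.full(grid.n_bins, 1.0 / TWO_PI), grid)

    @classmethod
    def von_mises(cls, mean_rad: float, sd_rad: float, grid: Grid) -> "ProbabilityField":
        """Von Mises density with the package's SD -> kappa = 1/SD^2 convention."""
        from .drift_field import von_mises_density  # local import, no cycle at runtime

        return cls.from_unnormalized(
            von_mises_density(grid.centers, mean_rad, sd_rad), grid
        )

    def circular_mean_rad(self) -> float:
        c = self.grid.centers
        w = self.values
        return float(np.arctan2(np.sum(w * np.sin(c)), np.sum(w * np.cos(c))) % TWO_PI)

    def circular_sd_rad(self) -> float:
        r = circ_resultant(self.grid.centers, self.values)
        r = min(max(r, 1e-12), 1.0)
        return float(np.sqrt(-2.0 * np.log(r)))

    def density_at(self, angle_rad) -> np.ndarray:
        """Density interpolated linearly (and periodically) between bin centers."""
        return periodic_interp(angle_rad, self.grid, self.values)

    def to_table(self, path: str | Path) -> None:
        """Two-column text table: angle (deg), density (per deg)."""
        arr = np.column_stack([self.grid.centers_deg,
                               self.values * np.pi / 180.0])
        np.savetxt(path, arr, header="angle_deg density_per_deg",
                   comments="# ")

    def mean_abs_error_deg(self, reference_rad: float) -> float:
        """E|circular distance to ``reference_rad``| under this density, degrees."""
        d = np.abs(circ_dist_rad(self.grid.centers, reference_rad))
        return float(np.rad2deg(np.sum(d * self.values) * self.grid.delta))


def periodic_interp(angle_rad, grid: Grid, values: np.ndarray):
    """Linear interpolation of per-bin values at arbitrary angles, circularly."""
    a = wrap_rad(angle_rad)
    pos = a / grid.delta - 0.5
    lo = np.floor(pos).astype(int)
    frac = pos - lo
    lo = lo % grid.n_bins
    hi = (lo + 1) % grid.n_bins
    out = (1.0 - frac) * values[lo] + frac * values[hi]
    return out if np.ndim(angle_rad) else float(out)


# ---------------------------------------------------------------------------
# trial data model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialRecord:
    """One behavioral trial of the delayed-estimation task.

    ``target_deg`` is the cued sample's hue, ``nontargets_deg`` the other
    sample hues (length ``load - 1``), ``report_deg`` the reproduced hue and
    ``delay_s`` the memory delay in seconds.
    """

    subject: str
    load: int
    delay_s: float
    target_deg: float
    nontargets_deg: tuple[float, ...]
    report_deg: float
    trial_index: int = 0

    def __post_init__(self):
        if self.load not in (1, 2, 3):
            raise ValueError(f"load must be 1, 2 or 3 (got {self.load})")
        if len(self.nontargets_deg) != self.load - 1:
            raise ValueError(
                f"trial with load {self.load} must carry {self.load - 1} "
                f"non-targets (got {len(self.nontargets_deg)})"
            )
        if not (self.delay_s > 0):
            raise ValueError("delay_s must be positive")
        # range violations are wrapped away at IO time and *reported* (not
        # raised) by validate_dataset; only non-finite angles are fatal here
        for v in (self.target_deg, self.report_deg, *self.nontargets_deg):
            if not np.isfinite(v):
                raise ValueError(f"non-finite angle {v!r} in trial")

    @property
    def error_deg(self) -> float:
        return circ_error(self.report_deg, self.target_deg)


@dataclass
class Dataset:
    """A collection of trials sharing one angle convention, plus metadata.

    ``species`` controls the observation model default: ``"human"`` enables
    the decoding-error convolution, ``"monkey"`` disables it.
    """

    trials: list[TrialRecord]
    species: str = "human"

    def __post_init__(self):
        if self.species not in ("human", "monkey"):
            raise ValueError("species must be 'human' or 'monkey'")

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    # -- columnar views -----------------------------------------------------
    @property
    def loads(self) -> np.ndarray:
        return np.array([t.load for t in self.trials], dtype=int)

    @property
    def delays(self) -> np.ndarray:
        return np.array([t.delay_s for t in self.trials], dtype=float)

    @property
    def targets_deg(self) -> np.ndarray:
        return np.array([t.target_deg for t in self.trials], dtype=float)

    @property
    def reports_deg(self) -> np.ndarray:
        return np.array([t.report_deg for t in self.trials], dtype=float)

    @property
    def errors_deg(self) -> np.ndarray:
        return circ_error(self.reports_deg, self.targets_deg)

    @property
    def loads_present(self) -> list[int]:
        return sorted(set(t.load for t in self.trials))

    @property
    def delays_present(self) -> list[float]:
        return sorted(set(t.delay_s for t in self.trials))

    @property
    def subjects(self) -> list[str]:
        return sorted(set(t.subject for t in self.trials))

    def subset(self, mask) -> "Dataset":
        mask = np.asarray(mask, dtype=bool)
        return Dataset([t for t, m in zip(self.trials, mask) if m], self.species)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            nt = list(t.nontargets_deg) + [np.nan, np.nan]
            rows.append(
                (t.subject, t.load, t.delay_s, t.target_deg, nt[0], nt[1],
                 t.report_deg, t.trial_index)
            )
        return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def _row_to_trial(row, irow: int) -> TrialRecord:
    load = int(row["load"])
    nts = []
    for col in ("nontarget1_deg", "nontarget2_deg"):
        v = row[col]
        if v is not None and np.isfinite(v):
            nts.append(float(wrap_deg(v)))
    if load not in (1, 2, 3):
        raise ValueError(f"row {irow}: load {load} out of range (1-3)")
    if len(nts) != load - 1:
        raise ValueError(
            f"row {irow}: load {load} requires {load - 1} non-targets, found {len(nts)}"
        )
    return TrialRecord(
        subject=str(row["subject"]),
        load=load,
        delay_s=float(row["delay_s"]),
        target_deg=float(wrap_deg(row["target_deg"])),
        nontargets_deg=tuple(nts),
        report_deg=float(wrap_deg(row["report_deg"])),
        trial_index=int(row["trial_index"]) if np.isfinite(row["trial_index"]) else 0,
    )


def read_trials(path: str | Path, species: str = "human") -> Dataset:
    """Read a trial-table CSV. Angles are normalized into [0, 360) on input."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns and c != "trial_index"]
    if missing:
        raise ValueError(f"trial table {path} missing required columns: {missing}")
    if "trial_index" not in df.columns:
        df["trial_index"] = np.arange(len(df))
    trials = [_row_to_trial(row, i) for i, (_, row) in enumerate(df.iterrows())]
    return Dataset(trials, species=species)


def write_trials(dataset: Dataset, path: str | Path) -> None:
    # %.17g guarantees bit-exact float round trips through the CSV
    dataset.to_frame().to_csv(path, index=False, float_format="%.17g")


@dataclass
class ValidationReport:
    n_trials: int
    counts: pd.DataFrame  # trials per load x delay
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_dataset(dataset: Dataset) -> ValidationReport:
    """Summarize a dataset and list integrity violations (reporting only)."""
    violations: list[str] = []
    seen = set()
    for i, t in enumerate(dataset.trials):
        for name, v in (("target", t.target_deg), ("report", t.report_deg)):
            if not (0.0 <= v < 360.0):
                violations.append(f"trial {i}: {name} angle {v} outside [0, 360)")
        for v in t.nontargets_deg:
            if not (0.0 <= v < 360.0):
                violations.append(f"trial {i}: non-target angle {v} outside [0, 360)")
        key = (t.subject, t.load, t.delay_s, t.target_deg, t.nontargets_deg,
               t.report_deg, t.trial_index)
        if key in seen:
            violations.append(f"trial {i}: exact duplicate of an earlier trial")
        seen.add(key)
    if dataset.trials:
        df = dataset.to_frame()
        counts = df.groupby(["load", "delay_s"]).size().rename("n_trials").reset_index()
    else:
        counts = pd.DataFrame(columns=["load", "delay_s", "n_trials"])
    return ValidationReport(len(dataset), counts, violations)
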