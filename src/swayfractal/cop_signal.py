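"""Center-of-pressure signal construction and classical sway metrics.

The raw posturographic observable is a 2-D center-of-pressure (COP)
trajectory sampled on a force platform.  Fractal analysis here operates on
the *magnitude series*: the Euclidean displacement between consecutive COP
samples, a 1-D non-negative series one sample shorter than the trajectory.
Classical summary metrics (mean speed, 95% confidence-ellipse area) are
computed from the same trajectory for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import stats

__all__ = [
    "CopTrajectory",
    "MagnitudeSeries",
    "Profile",
    "SwaySummary",
    "magnitude_series",
    "cumulative_profile",
    "cop_speed",
    "cop_area_95",
    "sway_summary",
]

# 0.95 quantile of chi-square with 2 dof; equals -2*ln(0.05)
CHI2_95_2DOF = float(stats.chi2.ppf(0.95, df=2))


@dataclass
class CopTrajectory:
    """A timestamped 2-D center-of-pressure path.

    Parameters
    ----------
    x, y
        Mediolateral and anteroposterior displacement, mm.  Equal length,
        at least 2 samples, all finite.
    sample_rate
        Sampling frequency in Hz (positive).
    meta
        Free-form trial annotations (subject id, condition label, ...).
    """

    x: np.ndarray
    y: np.ndarray
    sample_rate: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.ndim != 1 or self.y.ndim != 1:
            raise ValueError("x and y must be one-dimensional")
        if self.x.size != self.y.size:
            raise ValueError(
                f"x and y lengths differ ({self.x.size} vs {self.y.size})"
            )
        if self.x.size < 2:
            raise ValueError("trajectory needs at least 2 samples")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("trajectory contains non-finite samples")
        if not (np.isfinite(self.sample_rate) and self.sample_rate > 0):
            raise ValueError("sample_rate must be a positive real")
        self.sample_rate = float(self.sample_rate)

    def __len__(self) -> int:
        return self.x.size

    @property
    def duration(self) -> float:
        """Elapsed time between the first and last sample, seconds."""
        return (len(self) - 1) / self.sample_rate


@dataclass
class MagnitudeSeries:
    """1-D series of per-sample COP displacement magnitudes, mm."""

    values: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if not np.isfinite(self.values).all():
            raise ValueError("magnitude series contains non-finite values")
        if (self.values < 0).any():
            raise ValueError("magnitudes must be non-negative")
        if not (np.isfinite(self.sample_rate) and self.sample_rate > 0):
            raise ValueError("sample_rate must be a positive real")
        self.sample_rate = float(self.sample_rate)

    def __len__(self) -> int:
        return self.values.size


@dataclass
class Profile:
    """Cumulative sum of the mean-removed series (the DFA 'profile').

    The final element is zero up to floating-point accumulation error,
    because deviations from the mean sum to zero.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return self.values.size


@dataclass
class SwaySummary:
    """Per-trial posturographic summary row."""

    speed: float  # mm/s
    area: float  # mm^2
    alpha_short: float
    alpha_long: float
    crossover_ms: float


def magnitude_series(traj: CopTrajectory) -> MagnitudeSeries:
    """Euclidean displacement between consecutive COP samples.

    ``values[i] = sqrt((x[i+1]-x[i])^2 + (y[i+1]-y[i])^2)``; output is one
    sample shorter than the trajectory.
    """
    d = np.sqrt(np.diff(traj.x) ** 2 + np.diff(traj.y) ** 2)
    return MagnitudeSeries(values=d, sample_rate=traj.sample_rate)


def cumulative_profile(series: MagnitudeSeries | np.ndarray) -> Profile:
    """Cumulative sum of the mean-removed series.

    ``Y[k] = sum_{i<=k} (d[i] - mean(d))``.  Accepts a
    :class:`MagnitudeSeries` or any 1-D array.
    """
    v = series.values if isinstance(series, MagnitudeSeries) else np.asarray(
        series, dtype=float
    )
    if v.size < 2:
        raise ValueError("series must have at least 2 samples")
    return Profile(values=np.cumsum(v - v.mean()))


def cop_speed(traj: CopTrajectory) -> float:
    """Mean COP speed: total path length divided by trial duration, mm/s."""
    duration = traj.duration
    if duration <= 0:
        raise ValueError("trajectory duration must be positive")
    return float(magnitude_series(traj).values.sum() / duration)


def cop_area_95(traj: CopTrajectory) -> float:
    """Area of the 95% confidence ellipse of the COP point cloud, mm^2.

    area = pi * q * sqrt(det(S)) where S is the unbiased 2x2 sample
    covariance of (x, y) and q the 0.95 chi-square quantile with 2 dof.
    A degenerate (collinear) cloud yields 0 with a RuntimeWarning rather
    than an exception, so batch pipelines survive flat trials.
    """
    pts = np.column_stack([traj.x, traj.y])
    cov = np.cov(pts, rowvar=False, ddof=1)
    det = float(np.linalg.det(cov))
    if det <= 0 or not np.isfinite(det):
        warnings.warn(
            "degenerate COP cloud (collinear or constant): ellipse area set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    return float(np.pi * CHI2_95_2DOF * np.sqrt(det))


def sway_summary(
    traj: CopTrajectory,
    alpha_short: float = float("nan"),
    alpha_long: float = float("nan"),
    crossover_ms: float = float("nan"),
) -> SwaySummary:
    """Bundle classical metrics with scaling exponents into one row."""
    return SwaySummary(
        speed=cop_speed(traj),
        area=cop_area_95(traj),
        alpha_short=float(alpha_short),
        alpha_long=float(alpha_long),
        crossover_ms=float(crossover_ms),
    )
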