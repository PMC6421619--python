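"""Summaries of simulation trajectories.

Clinical time is measured in months (one month = 30.44 days); the model runs
in dimensionless time units of the matrix-production time scale (~266.7 h,
i.e. ~11.1 days, for the default parameters), so 1 month is ~2.74 time
units. The conversions here are used everywhere months appear.
"""

from __future__ import annotations

import numpy as np

from chondrosim.params import default_dimensional, matrix_timescale_hours
from chondrosim.pde import FIELDS, State, Trajectory

__all__ = [
    "MONTH_HOURS",
    "DEFAULT_TIMESCALE_HOURS",
    "months_to_tbar",
    "tbar_to_months",
    "profile_at",
    "spatial_mean",
    "mean_series",
    "percent_difference",
    "front_position",
    "fill_time",
]

#: Hours in one month (30.44 days).
MONTH_HOURS = 30.44 * 24.0

#: Matrix-production time scale of the default parameter set (hours).
DEFAULT_TIMESCALE_HOURS = matrix_timescale_hours(default_dimensional())


def months_to_tbar(months, timescale_hours: float = DEFAULT_TIMESCALE_HOURS):
    """Convert months of healing to dimensionless model time."""
    return np.asarray(months, dtype=float) * MONTH_HOURS / timescale_hours


def tbar_to_months(tbar, timescale_hours: float = DEFAULT_TIMESCALE_HOURS):
    """Convert dimensionless model time to months of healing."""
    return np.asarray(tbar, dtype=float) * timescale_hours / MONTH_HOURS


def profile_at(traj: Trajectory, name: str, t_months: float) -> np.ndarray:
    """Field profile at a time in months, linearly interpolated between the
    stored stamps."""
    tbar = float(months_to_tbar(t_months))
    times = traj.times
    if tbar < times[0] - 1e-9 or tbar > times[-1] + 1e-9:
        raise ValueError(
            f"t = {t_months} months (tbar = {tbar:.4g}) lies outside the "
            f"trajectory span [{times[0]:.4g}, {times[-1]:.4g}]")
    tbar = min(max(tbar, times[0]), times[-1])
    mat = traj.field_matrix(name)
    i = int(np.searchsorted(times, tbar, side="right") - 1)
    if i >= len(times) - 1:
        return mat[-1]
    w = (tbar - times[i]) / (times[i + 1] - times[i])
    return (1.0 - w) * mat[i] + w * mat[i + 1]


def spatial_mean(traj: Trajectory, name: str, t_months: float) -> float:
    """Trapezoidal spatial average of a field over the defect at a given
    time (months)."""
    profile = profile_at(traj, name, t_months)
    return float(np.trapezoid(profile, traj.grid.x))


def mean_series(traj: Trajectory, name: str) -> tuple[np.ndarray, np.ndarray]:
    """Spatial-mean time series at the stored stamps.

    Returns ``(months, means)``.
    """
    mat = traj.field_matrix(name)
    means = np.trapezoid(mat, traj.grid.x, axis=1)
    return tbar_to_months(traj.times), means


def percent_difference(a: Trajectory, b: Trajectory, name: str,
                       t_months: float) -> float:
    """Percent difference of spatial means, 100 * (mean_a - mean_b) / mean_b.

    ``b`` is the baseline; raises if its mean vanishes.
    """
    mean_a = spatial_mean(a, name, t_months)
    mean_b = spatial_mean(b, name, t_months)
    if mean_b == 0.0:
        raise ZeroDivisionError(
            f"baseline spatial mean of {name!r} at {t_months} months is zero; "
            "percent difference undefined")
    return 100.0 * (mean_a - mean_b) / mean_b


def front_position(state: State, name: str, level: float = 0.5) -> float | None:
    """Position of the advancing front of a field profile.

    The front is the largest x at which the profile crosses ``level`` times
    its maximum, linearly interpolated between nodes. Returns None when the
    profile has no positive maximum (no front to locate).
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must lie in (0, 1), got {level!r}")
    if name not in FIELDS:
        raise KeyError(f"unknown field {name!r}")
    u = getattr(state, name)
    umax = float(np.max(u))
    if umax <= 0.0:
        return None
    thr = level * umax
    x = np.linspace(0.0, 1.0, len(u))
    above = np.flatnonzero(u >= thr)
    i = int(above[-1])
    if i == len(u) - 1:
        return float(x[-1])
    # interpolate the downward crossing between nodes i and i+1
    u0, u1 = float(u[i]), float(u[i + 1])
    frac = (u0 - thr) / (u0 - u1)
    return float(x[i] + frac * (x[i + 1] - x[i]))


def fill_time(traj: Trajectory, threshold: float = 0.9) -> float | None:
    """Earliest stored time (months) at which the matrix density exceeds
    ``threshold`` of its maximum everywhere in the defect; None if never.

    The default 0.9 operationalises "the defect fills with matrix".
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold!r}")
    m = traj.field_matrix("m")
    filled = np.flatnonzero(np.min(m, axis=1) >= threshold)
    if filled.size == 0:
        return None
    return float(tbar_to_months(traj.times[filled[0]]))
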