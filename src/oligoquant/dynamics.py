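"""Hill-equation modeling of cumulative apoptosis dynamics.

The fraction of apoptotic cells after death-ligand addition follows a
sigmoidal time course

    P(t) = P_max − (P_max − P_min)/(1 + (t/t_half)^n),

where t_half is the time at which half of all eventually apoptotic cells
have died and the Hill coefficient n measures how switch-like the
population response is.  Input is a list of per-cell death times (from
time-lapse annotation) plus the total number of observed cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import lmfit
import numpy as np

__all__ = ["HillParams", "ApoptosisSeries", "hill_model", "cumulative_fraction", "fit_hill"]


@dataclass
class HillParams:
    """Hill fit parameters; fractions in [0, 1], times in hours."""

    p_min: float
    p_max: float
    t_half_h: float
    n: float
    stderr: dict | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_min <= self.p_max <= 1.0:
            raise ValueError("need 0 <= P_min <= P_max <= 1")
        if self.t_half_h <= 0 or self.n <= 0:
            raise ValueError("t_half and n must be positive")


@dataclass
class ApoptosisSeries:
    """Death times (hours) of the cells that died, out of ``n_cells`` total."""

    event_times_h: np.ndarray
    n_cells: int
    censor_time_h: float | None = None

    def __post_init__(self) -> None:
        self.event_times_h = np.sort(np.asarray(self.event_times_h, dtype=float))
        if np.any(self.event_times_h < 0):
            raise ValueError("event times must be non-negative")
        if self.event_times_h.size > self.n_cells:
            raise ValueError("more events than cells")


def hill_model(t_h: np.ndarray | float, params: HillParams) -> np.ndarray | float:
    """Cumulative apoptotic fraction P(t); monotone from P_min to P_max."""
    t = np.asarray(t_h, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(t > 0, (t / params.t_half_h) ** params.n, 0.0)
    out = params.p_max - (params.p_max - params.p_min) / (1.0 + ratio)
    return float(out) if np.isscalar(t_h) else out


def cumulative_fraction(
    series: ApoptosisSeries, grid_h: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Right-continuous cumulative apoptotic fraction with binomial weights.

    Returns (times, fractions, standard errors).  The standard error per
    time point is the binomial √(p(1−p)/N) with a small floor so that
    boundary points (p = 0 or 1) keep finite weight.
    """
    events = series.event_times_h
    if grid_h is None:
        grid_h = np.unique(events)
    grid_h = np.asarray(grid_h, dtype=float)
    frac = np.searchsorted(events, grid_h, side="right") / series.n_cells
    se = np.sqrt(np.clip(frac * (1.0 - frac), 1e-4, None) / series.n_cells)
    return grid_h, frac, se


def fit_hill(series: ApoptosisSeries, grid_h: np.ndarray | None = None) -> HillParams:
    """Weighted least-squares Hill fit of the cumulative apoptosis curve.

    A series without events returns a flat fit (P_max ≈ P_min ≈ 0) with a
    warning.  Otherwise at least 5 distinct event times are required.
    """
    if series.event_times_h.size == 0:
        warnings.warn("no apoptosis events; returning a flat Hill curve")
        return HillParams(p_min=0.0, p_max=1e-6, t_half_h=1.0, n=1.0)
    t, frac, se = cumulative_fraction(series, grid_h)
    if np.unique(t).size < 5:
        raise ValueError("need at least 5 distinct event time points")

    params = lmfit.Parameters()
    params.add("p_min", value=0.0, min=0.0, max=1.0)
    params.add("delta", value=float(max(frac[-1], 0.05)), min=1e-6, max=1.0)
    params.add("p_max", expr="p_min + delta")
    params.add("t_half", value=float(np.median(series.event_times_h)), min=1e-3)
    params.add("n", value=2.0, min=0.05, max=50.0)

    def residual(p: lmfit.Parameters) -> np.ndarray:
        p_min = p["p_min"].value
        p_max = min(max(p["p_max"].value, p_min + 1e-9), 1.0)
        hp = HillParams(
            p_min=min(p_min, p_max), p_max=p_max, t_half_h=p["t_half"].value, n=p["n"].value
        )
        return (hill_model(t, hp) - frac) / se

    result = lmfit.minimize(residual, params, method="least_squares")
    v = result.params
    stderr = {
        name: (v[name].stderr if v[name].stderr is not None else np.nan)
        for name in ("p_min", "p_max", "t_half", "n")
    }
    return HillParams(
        p_min=float(np.clip(v["p_min"].value, 0.0, 1.0)),
        p_max=float(np.clip(max(v["p_max"].value, v["p_min"].value), 0.0, 1.0)),
        t_half_h=float(v["t_half"].value),
        n=float(v["n"].value),
        stderr=stderr,
    )
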