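"""Fluorescence correlation spectroscopy: two-component model and fitting.

Membrane-receptor FCS curves are described by the sum of a cytoplasmic and
a membrane diffusion term,

    G(t_c) = 1 + Σ_s ρ_s (1 + t_c/t_s)⁻¹ (1 + t_c/(κ² t_s))^(−1/2) + G_∞,

without a triplet/bunching term (omitting it stabilizes fits of noisy
live-cell data without biasing the diffusion times).  Curve weighting uses
the standard error over recording chunks; the membrane diffusion time can
be kept globally fixed (0.60 ms from the global calibration fit).
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np

from . import constants

__all__ = [
    "FCSParams",
    "CorrelationCurve",
    "CalibrationResult",
    "fcs_model",
    "fit_fcs",
    "diffusion_coefficient",
    "diffusion_time",
    "simulate_fcs_curve",
]


@dataclass
class FCSParams:
    """Two-component FCS model parameters (diffusion times in ms)."""

    rho_cp: float
    rho_mem: float
    tdiff_cp_ms: float
    tdiff_mem_ms: float
    kappa: float = 5.0
    g_inf: float = 0.0

    def __post_init__(self) -> None:
        if self.rho_cp < 0 or self.rho_mem < 0:
            raise ValueError("correlation amplitudes must be non-negative")
        if self.tdiff_cp_ms <= 0 or self.tdiff_mem_ms <= 0:
            raise ValueError("diffusion times must be positive")
        if self.kappa < 1:
            raise ValueError("focus aspect ratio must be >= 1")


@dataclass
class CorrelationCurve:
    """Lag times (s, increasing), correlation amplitudes, per-point errors."""

    lag_s: np.ndarray
    g: np.ndarray
    stderr: np.ndarray | None = None
    n_chunks: int = 0

    def __post_init__(self) -> None:
        self.lag_s = np.asarray(self.lag_s, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if np.any(np.diff(self.lag_s) <= 0):
            raise ValueError("lag times must be strictly increasing")
        if self.stderr is not None:
            self.stderr = np.asarray(self.stderr, dtype=float)


@dataclass
class CalibrationResult:
    """Confocal volume calibration from a free-dye reference measurement."""

    omega0_um: float
    kappa: float
    volume_fl: float
    reference_d_um2_s: float


def _component(t_c_ms: np.ndarray, tdiff_ms: float, kappa: float) -> np.ndarray:
    return (1.0 + t_c_ms / tdiff_ms) ** -1 * (
        1.0 + t_c_ms / (kappa**2 * tdiff_ms)
    ) ** -0.5


def fcs_model(t_c_s: np.ndarray, params: FCSParams) -> np.ndarray:
    """Two-component correlation curve G(t_c); lag times in seconds."""
    t_ms = np.asarray(t_c_s, dtype=float) * 1e3
    return (
        1.0
        + params.rho_cp * _component(t_ms, params.tdiff_cp_ms, params.kappa)
        + params.rho_mem * _component(t_ms, params.tdiff_mem_ms, params.kappa)
        + params.g_inf
    )


def _make_params(
    guess: FCSParams, fix_membrane_time: float | None, prefix: str = ""
) -> lmfit.Parameters:
    p = lmfit.Parameters()
    p.add(prefix + "rho_cp", value=guess.rho_cp, min=0.0)
    p.add(prefix + "rho_mem", value=guess.rho_mem, min=0.0)
    p.add(prefix + "tdiff_cp", value=guess.tdiff_cp_ms, min=1e-4)
    if fix_membrane_time is not None:
        p.add(prefix + "tdiff_mem", value=fix_membrane_time, vary=False)
    else:
        p.add(prefix + "tdiff_mem", value=guess.tdiff_mem_ms, min=1e-4)
    p.add(prefix + "kappa", value=guess.kappa, vary=False)
    p.add(prefix + "g_inf", value=guess.g_inf, vary=True)
    return p


def _params_from(values: dict, prefix: str = "") -> FCSParams:
    return FCSParams(
        rho_cp=values[prefix + "rho_cp"],
        rho_mem=values[prefix + "rho_mem"],
        tdiff_cp_ms=values[prefix + "tdiff_cp"],
        tdiff_mem_ms=values[prefix + "tdiff_mem"],
        kappa=values[prefix + "kappa"],
        g_inf=values[prefix + "g_inf"],
    )


def fit_fcs(
    curves: CorrelationCurve | list[CorrelationCurve],
    guess: FCSParams | None = None,
    fix_membrane_time: float | None = None,
    global_times: bool = False,
) -> list[FCSParams]:
    """Weighted least-squares fit of one or several correlation curves.

    With ``global_times`` the two diffusion times are shared across all
    curves while the amplitudes stay per-curve.  ``fix_membrane_time``
    pins the membrane diffusion time (ms); pass
    ``constants.FCS_MEMBRANE_TDIFF_MS`` for the calibrated 0.60 ms value.
    No bunching/triplet term is fitted.
    """
    if isinstance(curves, CorrelationCurve):
        curves = [curves]
    for c in curves:
        if c.lag_s.size < 8:
            raise ValueError("need at least 8 lag points per curve")
    guess = guess or FCSParams(
        rho_cp=0.5,
        rho_mem=0.5,
        tdiff_cp_ms=0.1,
        tdiff_mem_ms=constants.FCS_MEMBRANE_TDIFF_MS,
    )

    params = lmfit.Parameters()
    for i in range(len(curves)):
        prefix = f"c{i}_"
        for name, par in _make_params(guess, fix_membrane_time, prefix).items():
            params[name] = par
        if global_times and i > 0:
            params[f"{prefix}tdiff_cp"].expr = "c0_tdiff_cp"
            if fix_membrane_time is None:
                params[f"{prefix}tdiff_mem"].expr = "c0_tdiff_mem"

    def residual(p: lmfit.Parameters) -> np.ndarray:
        out = []
        vals = p.valuesdict()
        for i, c in enumerate(curves):
            model = fcs_model(c.lag_s, _params_from(vals, f"c{i}_"))
            w = c.stderr
            if w is None or np.all(w == 0):
                out.append(c.g - model)
            else:
                out.append((c.g - model) / np.maximum(w, 1e-12))
        return np.concatenate(out)

    result = lmfit.minimize(residual, params, method="leastsq")
    if not result.success:
        raise RuntimeError("FCS fit did not converge: " + str(result.message))
    vals = result.params.valuesdict()
    return [_params_from(vals, f"c{i}_") for i in range(len(curves))]


def diffusion_coefficient(tdiff_ms: float, omega0_um: float) -> float:
    """D = ω₀²/(4·t_diff) in μm²/s for a lateral focal radius ω₀ (μm)."""
    if tdiff_ms <= 0 or omega0_um <= 0:
        raise ValueError("inputs must be positive")
    return omega0_um**2 / (4.0 * tdiff_ms * 1e-3)


def diffusion_time(d_um2_s: float, omega0_um: float) -> float:
    """Inverse relation: t_diff (ms) from D (μm²/s) and ω₀ (μm)."""
    if d_um2_s <= 0 or omega0_um <= 0:
        raise ValueError("inputs must be positive")
    return omega0_um**2 / (4.0 * d_um2_s) * 1e3


def simulate_fcs_curve(
    params: FCSParams,
    lag_s: np.ndarray | None = None,
    n_chunks: int = 15,
    noise_level: float = 0.01,
    rng: np.random.Generator | int | None = None,
) -> CorrelationCurve:
    """Simulate a chunk-averaged correlation curve.

    Each of the ``n_chunks`` recording chunks yields the model curve plus
    i.i.d. Gaussian noise of absolute scale ``noise_level``; the returned
    curve is the chunk mean with standard-error weights (so errors shrink
    as 1/√n_chunks).  Zero noise returns the exact model with zero errors.
    """
    if n_chunks < 2:
        raise ValueError("need at least 2 chunks")
    if lag_s is None:
        lag_s = np.logspace(-6, 0, 64)
    lag_s = np.asarray(lag_s, dtype=float)
    rng = np.random.default_rng(rng)
    model = fcs_model(lag_s, params)
    chunks = model[None, :] + noise_level * rng.standard_normal((n_chunks, lag_s.size))
    mean = chunks.mean(axis=0)
    stderr = chunks.std(axis=0, ddof=1) / np.sqrt(n_chunks)
    return CorrelationCurve(lag_s=lag_s, g=mean, stderr=stderr, n_chunks=n_chunks)
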