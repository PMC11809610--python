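"""Cell lifetime FRET image spectroscopy (CELFIS).

Per-cell oligomerization read-out from whole-membrane TCSPC decays: a
"pattern fit" in which the donor-only decay pattern, the FRET rate pattern
and the fundamental anisotropy are frozen to calibrated values and only the
FRET-quenched donor fraction x_FRET, one depolarization time and nuisance
amplitudes stay free.  x_FRET is then converted into the fraction of
receptors residing in oligomers via the dimer-sample maximum x_FRET,max,
and fluorescence count rates into receptor surface densities.

The calibration itself (joint donor-only fits over many regions of
interest) is also implemented here, so the full pipeline runs on synthetic
photon data end to end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from . import constants
from .decay_models import (
    AnisotropyPattern,
    DecayHistogram,
    DonorPattern,
    FitDiagnostics,
    FretPattern,
    InstrumentProfiles,
    NuisanceParams,
    chi2_ls,
    chi2_ml,
    circular_convolve,
    ideal_donor_decay,
    model_polarized,
)

__all__ = [
    "PatternLibrary",
    "ConversionConstants",
    "CellRecord",
    "XFretFit",
    "fit_donor_pattern",
    "fit_xfret",
    "xfret_max_theoretical",
    "oligomer_fraction",
    "surface_density",
    "oligomerization_rate",
    "filter_proximity",
]


@dataclass
class PatternLibrary:
    """Frozen fit pattern: donor lifetimes, FRET rates, anisotropy."""

    donor: DonorPattern
    fret: FretPattern
    aniso: AnisotropyPattern

    @classmethod
    def default(cls) -> "PatternLibrary":
        return cls(
            donor=constants.donor_pattern(),
            fret=constants.fret_pattern(),
            aniso=constants.anisotropy_pattern(),
        )


@dataclass
class ConversionConstants:
    """Constants converting x_FRET into oligomer fractions.

    x_FRET,max for a 100% dimer sample is taken from the experimental dimer
    titration when available, else derived as ξ·p_AD (donor maturation
    cancels because immature donors are invisible; acceptor maturation is
    treated as complete).
    """

    xi: float = constants.XI_CLOUD
    p_ad: float = constants.P_AD["CD95"]
    eta_donor: float = constants.ETA_MEGFP
    x_fret_max: float | None = None

    def __post_init__(self) -> None:
        for name in ("xi", "p_ad", "eta_donor"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")

    def resolve_x_fret_max(self) -> float:
        if self.x_fret_max is not None:
            return self.x_fret_max
        return xfret_max_theoretical(self)


@dataclass
class CellRecord:
    """Per-cell CELFIS result row."""

    cell_id: str
    x_fret: float
    x_fret_err: float = np.nan
    oligomer_fraction: float = np.nan
    density_per_um2: float = np.nan
    time_h: float = np.nan
    fate: str = "alive"
    proximity_flagged: bool = False


@dataclass
class XFretFit:
    x_fret: float
    rho_depol: float
    a0: float
    diagnostics: FitDiagnostics = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# calibration: joint donor-only fits


def fit_donor_pattern(
    decays: list[DecayHistogram],
    profiles: InstrumentProfiles,
    g_factor: float = constants.G_FACTOR,
    polarized_pairs: list[tuple[DecayHistogram, DecayHistogram]] | None = None,
    r0_start: float = constants.R0,
) -> tuple[DonorPattern, AnisotropyPattern | None]:
    """Joint two-component donor-only fit over a set of VM decays.

    All decays share the two lifetimes and species fractions; each decay
    keeps its own free amplitude, which is profiled out analytically under
    the weighted least-squares objective.  If polarized {VV, VH} pairs are
    supplied, the final donor parameters together with the anisotropy (r0
    and one depolarization time) are subsequently refined with the
    Poisson-deviance objective, which stays unbiased in the low-count
    decay tails where count-based least-squares weights are not.
    """
    if len(decays) < 2:
        raise ValueError("joint donor fit requires at least two decays")
    grids = [d.bin_times for d in decays]
    if any(g.shape != grids[0].shape or not np.allclose(g, grids[0]) for g in grids):
        raise ValueError("all decays must share one bin grid")
    t = grids[0]
    dt = float(t[1] - t[0])
    irf_vm, _ = profiles.composed_vm(g_factor)
    weights = [
        d.weights if d.weights is not None else np.maximum(d.counts, 0.0)
        for d in decays
    ]

    def shape(theta: np.ndarray) -> np.ndarray:
        tau = np.exp(theta[:2])
        p1 = 1.0 / (1.0 + np.exp(-theta[2]))
        pat = DonorPattern(lifetimes=tau, fractions=np.array([p1, 1.0 - p1]))
        return circular_convolve(
            ideal_donor_decay(pat, t), irf_vm, profiles.t_sh_vv, dt
        )

    def objective(theta: np.ndarray) -> float:
        m = shape(theta)
        total = 0.0
        for d, w in zip(decays, weights):
            mask = w > 0
            a0 = _profiled_amplitude(d.counts, m, w, mask)
            total += np.sum((d.counts[mask] - a0 * m[mask]) ** 2 / w[mask])
        return total

    x0 = np.array([np.log(1.5), np.log(3.0), 0.0])
    res = optimize.minimize(
        objective, x0, method="Nelder-Mead", options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000}
    )
    if not res.success:
        warnings.warn("joint donor fit did not fully converge: " + res.message)
    tau = np.exp(res.x[:2])
    p1 = 1.0 / (1.0 + np.exp(-res.x[2]))
    fractions = np.array([p1, 1.0 - p1])
    order = np.argsort(tau)
    tau, fractions = tau[order], fractions[order]
    if np.isclose(tau[0], tau[1], rtol=1e-2):
        warnings.warn("donor lifetimes are degenerate; data may be single-exponential")
    pattern = DonorPattern(lifetimes=tau, fractions=fractions)

    aniso = None
    if polarized_pairs:
        pattern, aniso = _refine_polarized(
            polarized_pairs, pattern, profiles, g_factor, r0_start
        )
    return pattern, aniso


def _profiled_amplitude(
    counts: np.ndarray, m: np.ndarray, w: np.ndarray, mask: np.ndarray
) -> float:
    denom = np.sum(m[mask] ** 2 / w[mask])
    if denom <= 0:
        return 0.0
    return max(np.sum(counts[mask] * m[mask] / w[mask]) / denom, 0.0)


def _refine_polarized(
    pairs: list[tuple[DecayHistogram, DecayHistogram]],
    donor: DonorPattern,
    profiles: InstrumentProfiles,
    g_factor: float,
    r0_start: float,
) -> tuple[DonorPattern, AnisotropyPattern]:
    """Joint {VV, VH} refinement of donor + anisotropy parameters (χ²_ML).

    Each pair keeps one amplitude, profiled out exactly: for a free scale
    the Poisson deviance is minimized at matching total counts.
    """
    grid = pairs[0][0].bin_times

    def unpack(theta: np.ndarray):
        tau = np.exp(theta[:2])
        p1 = 1.0 / (1.0 + np.exp(-theta[2]))
        r0 = float(np.clip(theta[3], 0.0, 0.4))
        rho = float(np.exp(theta[4]))
        pat = DonorPattern(lifetimes=tau, fractions=np.array([p1, 1.0 - p1]))
        aniso = AnisotropyPattern(r0=r0, rho=np.array([rho]), g_factor=g_factor)
        return pat, aniso

    def objective(theta: np.ndarray) -> float:
        pat, aniso = unpack(theta)
        total = 0.0
        for vv, vh in pairs:
            m = {
                ch: model_polarized(
                    pat, None, aniso, NuisanceParams(a0=1.0), profiles, grid, ch
                )
                for ch in ("VV", "VH")
            }
            a0 = (vv.total_counts + vh.total_counts) / (m["VV"].sum() + m["VH"].sum())
            total += chi2_ml(vv, np.maximum(a0 * m["VV"], 1e-12))
            total += chi2_ml(vh, np.maximum(a0 * m["VH"], 1e-12))
        return total

    x0 = np.array(
        [
            np.log(donor.lifetimes[0]),
            np.log(donor.lifetimes[-1]),
            _logit(donor.fractions[0]),
            r0_start,
            np.log(45.0),
        ]
    )
    res = optimize.minimize(
        objective, x0, method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-7, "maxiter": 4000, "maxfev": 4000},
    )
    pat, aniso = unpack(res.x)
    order = np.argsort(pat.lifetimes)
    pat = DonorPattern(pat.lifetimes[order], pat.fractions[order])
    return pat, aniso


def _logit(p: float) -> float:
    p = min(max(p, 1e-6), 1.0 - 1e-6)
    return float(np.log(p / (1.0 - p)))


# ---------------------------------------------------------------------------
# the pattern fit


def fit_xfret(
    vv: DecayHistogram,
    vh: DecayHistogram,
    library: PatternLibrary,
    profiles: InstrumentProfiles,
    min_total_counts: float = 1e5,
    x_starts: tuple[float, ...] = (0.05, 0.2),
) -> XFretFit:
    """Pattern fit of one polarized decay pair for the quenched fraction.

    Donor and FRET patterns are frozen; free parameters are x_FRET, a single
    depolarization time (started from the library value) and the decay
    amplitude.  The objective is the summed Poisson deviance of the VV and
    VH channels, minimized from multiple x_FRET starts to avoid local
    minima.  Photon-starved pairs are rejected.
    """
    total = vv.total_counts + vh.total_counts
    if total < min_total_counts:
        raise ValueError(
            f"decay pair has {total:.0f} photons; minimum is {min_total_counts:.0f}"
        )
    grid = vv.bin_times
    lib = library

    def models(x: float, rho: float, a0: float) -> tuple[np.ndarray, np.ndarray]:
        fret = lib.fret.with_x(x)
        aniso = AnisotropyPattern(
            r0=lib.aniso.r0, rho=np.array([rho]), g_factor=lib.aniso.g_factor
        )
        nuis = NuisanceParams(a0=a0)
        m_vv = model_polarized(lib.donor, fret, aniso, nuis, profiles, grid, "VV")
        m_vh = model_polarized(lib.donor, fret, aniso, nuis, profiles, grid, "VH")
        return m_vv, m_vh

    # amplitude scale reference at a0 = 1
    m_vv1, m_vh1 = models(0.1, float(lib.aniso.rho[0]), 1.0)
    a0_guess = total / (m_vv1.sum() + m_vh1.sum())

    def objective(theta: np.ndarray) -> float:
        x = float(np.clip(theta[0], 0.0, 1.0))
        rho = float(np.exp(theta[1]))
        a0 = float(np.exp(theta[2]))
        m_vv, m_vh = models(x, rho, a0)
        return chi2_ml(vv, np.maximum(m_vv, 1e-12)) + chi2_ml(
            vh, np.maximum(m_vh, 1e-12)
        )

    best = None
    for x0 in x_starts:
        res = optimize.minimize(
            objective,
            np.array([x0, np.log(float(lib.aniso.rho[0])), np.log(a0_guess)]),
            method="L-BFGS-B",
            bounds=[(0.0, 1.0), (np.log(1.0), np.log(2000.0)), (None, None)],
        )
        if best is None or res.fun < best.fun:
            best = res
    x = float(np.clip(best.x[0], 0.0, 1.0))
    rho = float(np.exp(best.x[1]))
    a0 = float(np.exp(best.x[2]))
    m_vv, m_vh = models(x, rho, a0)
    n_par = 3
    diag = FitDiagnostics(
        chi2_r_ls=chi2_ls(
            np.concatenate([vv.counts, vh.counts]),
            np.concatenate([m_vv, m_vh]),
            n_par,
        ),
        chi2_ml=float(best.fun),
        n_par=n_par,
        residuals=np.concatenate([vv.counts - m_vv, vh.counts - m_vh]),
    )
    return XFretFit(x_fret=x, rho_depol=rho, a0=a0, diagnostics=diag)


# ---------------------------------------------------------------------------
# conversion to molecular quantities


def xfret_max_theoretical(consts: ConversionConstants) -> float:
    """x_FRET of a 100% dimer sample: ξ·p_AD.

    Donor maturation cancels (immature donors emit nothing and so never
    enter the decay); incomplete acceptor maturation is absorbed into p_AD
    because immature acceptors still absorb.
    """
    return consts.xi * consts.p_ad


def oligomer_fraction(x_fret: float, x_fret_max: float) -> float:
    """Fraction of receptors in oligomers: x_FRET / x_FRET,max, clipped at 1."""
    if x_fret < 0:
        raise ValueError("x_FRET must be non-negative")
    if x_fret_max <= 0:
        raise ValueError("x_FRET,max must be positive")
    frac = x_fret / x_fret_max
    if frac > 1.0:
        warnings.warn(
            f"x_FRET {x_fret:.3f} exceeds x_FRET,max {x_fret_max:.3f}; clipping to 1"
        )
        frac = 1.0
    return frac


def surface_density(
    count_rate_hz: float,
    power_uw: float,
    brightness_hz_per_molecule_uw: float,
    maturation: float = constants.ETA_MEGFP,
    membrane_fraction: float = 1.0,
    pixel_area_um2: float = 1.0,
) -> float:
    """Receptor surface density (molecules/μm²) from a mean pixel count rate.

    density = rate / (brightness · power · maturation) · membrane_fraction
    / pixel_area.  Dividing by the maturation efficiency converts visible
    fluorophores into total receptors; the membrane fraction removes the
    cytoplasmic pool from the count rate.
    """
    if count_rate_hz < 0:
        raise ValueError("count rate must be non-negative")
    for name, v in (
        ("power", power_uw),
        ("brightness", brightness_hz_per_molecule_uw),
        ("maturation", maturation),
        ("pixel area", pixel_area_um2),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    molecules = count_rate_hz / (brightness_hz_per_molecule_uw * power_uw * maturation)
    return molecules * membrane_fraction / pixel_area_um2


def oligomerization_rate(
    times_h: np.ndarray, fractions: np.ndarray, window_h: float = 3.0
) -> float:
    """Oligomerization rate in percent per hour.

    Least-squares slope of the oligomer fraction against time over the
    first ``window_h`` hours of the series (anchored at the earliest time
    point); negative rates are allowed.
    """
    times_h = np.asarray(times_h, dtype=float)
    fractions = np.asarray(fractions, dtype=float)
    mask = times_h - times_h.min() <= window_h
    t, f = times_h[mask], fractions[mask]
    if t.size < 2:
        raise ValueError("rate requires at least two time points inside the window")
    slope = np.polyfit(t, f, 1)[0]
    return float(slope * 100.0)


def filter_proximity(
    records: list[CellRecord],
    threshold: float = constants.PROXIMITY_DENSITY_THRESHOLD,
) -> list[CellRecord]:
    """Flag cells above the proximity-FRET density threshold; return the rest.

    At surface densities beyond ~1000 receptors/μm² random close packing
    produces FRET without binding, so such cells are excluded from oligomer
    statistics.  Flags are set in place.
    """
    kept = []
    for rec in records:
        if np.isfinite(rec.density_per_um2) and rec.density_per_um2 > threshold:
            rec.proximity_flagged = True
        else:
            kept.append(rec)
    return kept
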