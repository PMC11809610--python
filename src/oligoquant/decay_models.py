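"""Forward models for polarization-resolved TCSPC fluorescence decays.

The donor fluorescence decay of a membrane receptor labelled with a
fluorescent protein is multi-exponential; FRET to a nearby acceptor adds
quenching rate constants on top of the intrinsic depopulation rates.  All
models here operate on uniformly binned photon-count histograms, evaluate
the continuous decay at bin centers, and account for the pulsed-excitation
repetition period by circular convolution with the measured instrument
response function (IRF).

Channels
--------
VV / VH are the parallel / perpendicular polarization detection channels
(excitation polarizer vertical).  VM is the composed total-intensity
("magic-angle-equivalent") signal VV + 2G·VH, in which rotational
depolarization cancels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DecayHistogram",
    "InstrumentProfiles",
    "DonorPattern",
    "FretPattern",
    "AnisotropyPattern",
    "NuisanceParams",
    "FitDiagnostics",
    "circular_convolve",
    "ideal_donor_decay",
    "ideal_fret_decay",
    "model_donor",
    "model_fret",
    "model_polarized",
    "compose_vm",
    "chi2_ls",
    "chi2_ml",
]

P_VV = 2.0
P_VH = -1.0


@dataclass
class DecayHistogram:
    """Binned photon counts for one polarization channel.

    Parameters
    ----------
    counts : array of non-negative photon counts per bin.
    bin_times : bin-center times in ns, uniformly spaced.
    period : excitation repetition period T in ns (>= last bin time).
    channel : one of ``{"VV", "VH", "VM"}``.
    weights : optional per-bin variance weights (used for composed VM
        signals where counts are no longer Poisson).
    """

    counts: np.ndarray
    bin_times: np.ndarray
    period: float
    channel: str = "VM"
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.bin_times = np.asarray(self.bin_times, dtype=float)
        if self.counts.shape != self.bin_times.shape:
            raise ValueError("counts and bin_times must have the same length")
        if np.any(self.counts < 0):
            raise ValueError("photon counts must be non-negative")
        dt = np.diff(self.bin_times)
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("bin grid must be uniform")
        if self.period < self.bin_times[-1]:
            raise ValueError("repetition period must cover the bin grid")
        if self.channel not in ("VV", "VH", "VM"):
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != self.counts.shape:
                raise ValueError("weights must match counts")

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def bin_width(self) -> float:
        return float(self.bin_times[1] - self.bin_times[0])

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())


@dataclass
class InstrumentProfiles:
    """Measured IRF and autofluorescence profiles per polarization channel.

    IRFs are normalized to unit integral (sum × bin width = 1 is not
    required; unit *sum* is used since all models work on binned counts).
    Time shifts ``t_sh_*`` (ns) are applied to the IRF as sub-bin phase
    shifts in frequency space.
    """

    irf_vv: np.ndarray
    irf_vh: np.ndarray
    af_vv: np.ndarray | None = None
    af_vh: np.ndarray | None = None
    t_sh_vv: float = 0.0
    t_sh_vh: float = 0.0

    def __post_init__(self) -> None:
        self.irf_vv = _normalize_irf(self.irf_vv, "irf_vv")
        self.irf_vh = _normalize_irf(self.irf_vh, "irf_vh")
        if self.irf_vv.shape != self.irf_vh.shape:
            raise ValueError("VV and VH IRFs must share one bin grid")
        for name in ("af_vv", "af_vh"):
            af = getattr(self, name)
            if af is not None:
                af = np.asarray(af, dtype=float)
                if af.shape != self.irf_vv.shape:
                    raise ValueError(f"{name} must match the IRF grid")
                setattr(self, name, af)

    def irf(self, channel: str) -> np.ndarray:
        if channel == "VV":
            return self.irf_vv
        if channel == "VH":
            return self.irf_vh
        raise ValueError(f"no per-channel IRF for {channel!r}")

    def af(self, channel: str) -> np.ndarray | None:
        return self.af_vv if channel == "VV" else self.af_vh

    def t_sh(self, channel: str) -> float:
        return self.t_sh_vv if channel == "VV" else self.t_sh_vh

    def composed_vm(self, g_factor: float) -> tuple[np.ndarray, np.ndarray | None]:
        """IRF and AF for the composed VM channel (VV + 2G·VH, renormalized)."""
        irf = self.irf_vv + 2.0 * g_factor * self.irf_vh
        irf = irf / irf.sum()
        af = None
        if self.af_vv is not None and self.af_vh is not None:
            af = self.af_vv + 2.0 * g_factor * self.af_vh
        return irf, af


def _normalize_irf(irf: np.ndarray, name: str) -> np.ndarray:
    irf = np.asarray(irf, dtype=float)
    if np.any(irf < 0):
        raise ValueError(f"{name} must be non-negative")
    total = irf.sum()
    if total <= 0:
        raise ValueError(f"{name} must have positive integral")
    if not np.isclose(total, 1.0, rtol=1e-6):
        irf = irf / total
    return irf


@dataclass
class DonorPattern:
    """Donor-only (DO) decay pattern: lifetimes (ns) and species fractions."""

    lifetimes: np.ndarray
    fractions: np.ndarray

    def __post_init__(self) -> None:
        self.lifetimes = np.atleast_1d(np.asarray(self.lifetimes, dtype=float))
        self.fractions = np.atleast_1d(np.asarray(self.fractions, dtype=float))
        if self.lifetimes.shape != self.fractions.shape:
            raise ValueError("lifetimes and fractions must have equal length")
        if np.any(self.lifetimes <= 0):
            raise ValueError("lifetimes must be positive")
        if np.any(self.fractions < 0) or not np.isclose(self.fractions.sum(), 1.0):
            raise ValueError("fractions must be non-negative and sum to 1")

    @property
    def rates(self) -> np.ndarray:
        """S1 depopulation rate constants k_i = 1/τ_i in ns⁻¹."""
        return 1.0 / self.lifetimes

    @property
    def n_components(self) -> int:
        return self.lifetimes.size

    @property
    def mean_lifetime(self) -> float:
        """Amplitude-weighted mean lifetime Σ p_i τ_i (ns)."""
        return float(np.dot(self.fractions, self.lifetimes))


@dataclass
class FretPattern:
    """FRET quenching pattern: rate constants, normalized amplitudes, x_FRET.

    ``x_FRET`` is the fraction of donors quenched by FRET; the per-state
    species fractions are p_j = x_FRET·a_j for j ≥ 1 and p_0 = 1 − x_FRET
    for the unquenched donors.
    """

    rates: np.ndarray
    amplitudes: np.ndarray
    x_fret: float

    def __post_init__(self) -> None:
        self.rates = np.atleast_1d(np.asarray(self.rates, dtype=float))
        self.amplitudes = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        if self.rates.shape != self.amplitudes.shape:
            raise ValueError("rates and amplitudes must have equal length")
        if np.any(self.rates <= 0):
            raise ValueError("FRET rate constants must be positive")
        if np.any(self.amplitudes < 0) or not np.isclose(self.amplitudes.sum(), 1.0):
            raise ValueError("FRET amplitudes must be non-negative and sum to 1")
        if not 0.0 <= self.x_fret <= 1.0:
            raise ValueError("x_FRET must lie in [0, 1]")

    def with_x(self, x_fret: float) -> "FretPattern":
        """Same rate pattern with a different quenched fraction."""
        return FretPattern(self.rates, self.amplitudes, x_fret)

    @property
    def species_fractions(self) -> np.ndarray:
        """p_j for j = 0..n_f (first entry: unquenched fraction)."""
        return np.concatenate(([1.0 - self.x_fret], self.x_fret * self.amplitudes))


@dataclass
class AnisotropyPattern:
    """Rotational depolarization pattern for polarized detection.

    r0 is the fundamental anisotropy (≤ 0.4), ``rho`` the depolarization
    correlation times in ns with fractions ``fractions``, G the
    VH/VV detection-efficiency ratio, and l1/l2 the high-NA lens mixing
    factors (zero for the calibrated instrument).
    """

    r0: float
    rho: np.ndarray
    fractions: np.ndarray | None = None
    g_factor: float = 1.0
    l1: float = 0.0
    l2: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.r0 <= 0.4:
            raise ValueError("r0 must lie in [0, 0.4]")
        self.rho = np.atleast_1d(np.asarray(self.rho, dtype=float))
        if np.any(self.rho <= 0):
            raise ValueError("depolarization times must be positive")
        if self.fractions is None:
            self.fractions = np.full(self.rho.size, 1.0 / self.rho.size)
        self.fractions = np.atleast_1d(np.asarray(self.fractions, dtype=float))
        if self.fractions.shape != self.rho.shape:
            raise ValueError("rho and fractions must have equal length")
        if not np.isclose(self.fractions.sum(), 1.0):
            raise ValueError("anisotropy fractions must sum to 1")

    @property
    def depol_rates(self) -> np.ndarray:
        return 1.0 / self.rho


@dataclass
class NuisanceParams:
    """Per-fit nuisance amplitudes: decay scale, AF, scatter and background."""

    a0: float = 1.0
    a_af: float = 0.0
    a_sc: float = 0.0
    bg: float = 0.0

    def __post_init__(self) -> None:
        for name in ("a0", "a_af", "a_sc", "bg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class FitDiagnostics:
    chi2_r_ls: float
    chi2_ml: float
    n_par: int
    residuals: np.ndarray = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# convolution and ideal decays


def circular_convolve(
    ideal: np.ndarray, irf: np.ndarray, shift: float = 0.0, bin_width: float = 1.0
) -> np.ndarray:
    """Circular convolution of a decay with a (time-shifted) IRF.

    Implemented as multiplication in frequency space; the shift is applied
    to the IRF as a phase factor, so sub-bin shifts are exact in the
    band-limited sense.  For a unit-sum IRF the total signal is preserved.

    Parameters
    ----------
    ideal, irf : arrays of equal length covering one repetition period.
    shift : IRF time shift in the units of ``bin_width``.
    bin_width : time per bin (ns); only the ratio shift/bin_width matters.
    """
    ideal = np.asarray(ideal, dtype=float)
    irf = np.asarray(irf, dtype=float)
    if ideal.shape != irf.shape:
        raise ValueError("ideal decay and IRF must have equal length")
    n = ideal.size
    fi = np.fft.rfft(ideal)
    fh = np.fft.rfft(irf)
    if shift != 0.0:
        freqs = np.fft.rfftfreq(n)  # cycles per bin
        fh = fh * np.exp(-2j * np.pi * freqs * (shift / bin_width))
    return np.fft.irfft(fi * fh, n=n)


def ideal_donor_decay(pattern: DonorPattern, t: np.ndarray) -> np.ndarray:
    """Ideal multi-exponential donor decay Σ p_i exp(−k_i t)."""
    t = np.asarray(t, dtype=float)
    return np.einsum(
        "i,it->t", pattern.fractions, np.exp(-np.outer(pattern.rates, t))
    )


def ideal_fret_decay(
    donor: DonorPattern, fret: FretPattern, t: np.ndarray
) -> np.ndarray:
    """Ideal donor decay for a mixture where a fraction x_FRET is quenched.

    Species (i, j) decays with rate k_i + k_j^FRET (j ≥ 1) or k_i (j = 0,
    the unquenched donors) and fraction p_i·p_j.
    """
    t = np.asarray(t, dtype=float)
    p_j = fret.species_fractions
    k_j = np.concatenate(([0.0], fret.rates))
    rates = donor.rates[:, None] + k_j[None, :]  # (n_d, n_f+1)
    p_ij = donor.fractions[:, None] * p_j[None, :]
    return np.einsum("ij,ijt->t", p_ij, np.exp(-rates[..., None] * t))


def _polarized_ideal(
    donor: DonorPattern,
    fret: FretPattern | None,
    aniso: AnisotropyPattern,
    t: np.ndarray,
    channel: str,
) -> np.ndarray:
    """Ideal polarized decay f_pa = f_iso + P_pa·r0·Σ p·exp(−(k+k_AN)t)."""
    if fret is None:
        fret = FretPattern(np.array([1.0]), np.array([1.0]), 0.0)
    p_pa = {"VV": P_VV, "VH": P_VH}[channel]
    iso = ideal_fret_decay(donor, fret, t)
    p_j = fret.species_fractions
    k_j = np.concatenate(([0.0], fret.rates))
    rates_ij = donor.rates[:, None] + k_j[None, :]
    p_ij = donor.fractions[:, None] * p_j[None, :]
    # add each depolarization rate: shape (n_d, n_f+1, n_a, n_t)
    rates = rates_ij[..., None] + aniso.depol_rates[None, None, :]
    weights = p_ij[..., None] * aniso.fractions[None, None, :]
    depol = np.einsum("ijl,ijlt->t", weights, np.exp(-rates[..., None] * t))
    return iso + p_pa * aniso.r0 * depol


def _assemble(
    ideal: np.ndarray,
    nuisance: NuisanceParams,
    irf: np.ndarray,
    af: np.ndarray | None,
    t_sh: float,
    bin_width: float,
    scatter: bool,
) -> np.ndarray:
    """Convolve and add nuisance terms: (a0·f + a_AF·AF) ⊛ IRF + a_sc·IRF + BG."""
    model = nuisance.a0 * circular_convolve(ideal, irf, t_sh, bin_width)
    if nuisance.a_af > 0:
        if af is None:
            raise ValueError("autofluorescence amplitude set but no AF profile")
        model = model + nuisance.a_af * circular_convolve(af, irf, t_sh, bin_width)
    if scatter and nuisance.a_sc > 0:
        n = irf.size
        shifted = circular_convolve(
            np.concatenate(([1.0], np.zeros(n - 1))), irf, t_sh, bin_width
        )
        model = model + nuisance.a_sc * shifted
    return np.clip(model + nuisance.bg, 0.0, None)


def model_donor(
    pattern: DonorPattern,
    nuisance: NuisanceParams,
    profiles: InstrumentProfiles,
    grid: DecayHistogram | np.ndarray,
    g_factor: float = 1.0,
) -> np.ndarray:
    """DO-VM model: donor-only total-intensity decay with all nuisance terms."""
    t, dt = _grid(grid, profiles)
    irf, af = profiles.composed_vm(g_factor)
    ideal = ideal_donor_decay(pattern, t)
    return _assemble(ideal, nuisance, irf, af, profiles.t_sh_vv, dt, scatter=True)


def model_fret(
    donor: DonorPattern,
    fret: FretPattern,
    nuisance: NuisanceParams,
    profiles: InstrumentProfiles,
    grid: DecayHistogram | np.ndarray,
    g_factor: float = 1.0,
) -> np.ndarray:
    """DA-VM model: donor decay with a FRET-quenched fraction, VM channel."""
    t, dt = _grid(grid, profiles)
    irf, af = profiles.composed_vm(g_factor)
    ideal = ideal_fret_decay(donor, fret, t)
    return _assemble(ideal, nuisance, irf, af, profiles.t_sh_vv, dt, scatter=True)


def model_polarized(
    donor: DonorPattern,
    fret: FretPattern | None,
    aniso: AnisotropyPattern,
    nuisance: NuisanceParams,
    profiles: InstrumentProfiles,
    grid: DecayHistogram | np.ndarray,
    channel: str,
) -> np.ndarray:
    """{DA-VV, DA-VH} model for one polarized channel.

    VV uses the polarization prefactor P = +2 and carries the scattered-light
    term; VH uses P = −1 and is scaled by the detection-efficiency ratio G.
    Channel-specific IRF, AF, time shift and background apply.  Lens mixing
    (l1, l2) follows the standard detection-mixing form and is inactive at
    the calibrated defaults l1 = l2 = 0.
    """
    if channel not in ("VV", "VH"):
        raise ValueError(f"unknown polarized channel {channel!r}")
    t, dt = _grid(grid, profiles)
    f_vv = _polarized_ideal(donor, fret, aniso, t, "VV")
    if channel == "VV":
        ideal = f_vv
        if aniso.l1 != 0.0:
            f_vh = _polarized_ideal(donor, fret, aniso, t, "VH")
            ideal = f_vv + aniso.l1 * (f_vh - f_vv)
    else:
        f_vh = _polarized_ideal(donor, fret, aniso, t, "VH")
        ideal = f_vh
        if aniso.l2 != 0.0:
            ideal = f_vh + aniso.l2 * (f_vv - f_vh)
        ideal = aniso.g_factor * ideal
    return _assemble(
        ideal,
        nuisance,
        profiles.irf(channel),
        profiles.af(channel),
        profiles.t_sh(channel),
        dt,
        scatter=(channel == "VV"),
    )


def _grid(
    grid: DecayHistogram | np.ndarray, profiles: InstrumentProfiles
) -> tuple[np.ndarray, float]:
    if isinstance(grid, DecayHistogram):
        t = grid.bin_times
    else:
        t = np.asarray(grid, dtype=float)
    if t.size != profiles.irf_vv.size:
        raise ValueError("time grid does not match instrument profiles")
    return t, float(t[1] - t[0])


# ---------------------------------------------------------------------------
# VM composition and goodness of fit


def compose_vm(
    vv: DecayHistogram, vh: DecayHistogram, g_factor: float
) -> DecayHistogram:
    """Compose the total-intensity signal VM = VV + 2G·VH.

    Per-bin variance weights follow Gaussian error propagation of the two
    Poisson channels: w_i = VV_i + 4G²·VH_i.
    """
    if vv.counts.shape != vh.counts.shape or not np.allclose(
        vv.bin_times, vh.bin_times
    ):
        raise ValueError("VV and VH histograms must share one bin grid")
    counts = vv.counts + 2.0 * g_factor * vh.counts
    weights = vv.counts + 4.0 * g_factor**2 * vh.counts
    return DecayHistogram(
        counts=counts,
        bin_times=vv.bin_times.copy(),
        period=vv.period,
        channel="VM",
        weights=weights,
    )


def chi2_ls(
    data: DecayHistogram | np.ndarray,
    model: np.ndarray,
    n_par: int,
    weights: np.ndarray | None = None,
) -> float:
    """Reduced least-squares χ²_r with per-bin variance weights.

    For raw polarized channels the Poisson choice w_i = counts_i applies;
    composed VM histograms carry propagated weights.  Bins with zero weight
    are excluded from both the sum and the bin count.
    """
    if isinstance(data, DecayHistogram):
        counts = data.counts
        if weights is None:
            weights = data.weights if data.weights is not None else counts
    else:
        counts = np.asarray(data, dtype=float)
        if weights is None:
            weights = counts
    model = np.asarray(model, dtype=float)
    mask = weights > 0
    n_used = int(mask.sum())
    if n_par >= n_used:
        raise ValueError("more parameters than usable bins")
    resid2 = (counts[mask] - model[mask]) ** 2 / weights[mask]
    return float(resid2.sum() / (n_used - n_par))


def chi2_ml(data: DecayHistogram | np.ndarray, model: np.ndarray) -> float:
    """Poisson deviance 2[N_mod − N_exp + Σ n_i ln(n_i/m_i)].

    Zero-count bins contribute their model counts only; the estimator is
    non-negative and vanishes iff model ≡ data.
    """
    counts = data.counts if isinstance(data, DecayHistogram) else np.asarray(data, float)
    model = np.asarray(model, dtype=float)
    pos = counts > 0
    if np.any(model[pos] <= 0):
        raise ValueError("model must be positive wherever data has counts")
    term = counts[pos] * np.log(counts[pos] / model[pos])
    return float(2.0 * (model.sum() - counts.sum() + term.sum()))
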