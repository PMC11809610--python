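"""Seeded synthetic-data generation shared across modules.

The TCSPC generator draws photon arrival-time histograms from the polarized
forward models by multinomial sampling, which is exactly the Poisson photon
statistics of a pulsed TCSPC experiment conditioned on the total count.
A Gaussian IRF stands in for the measured instrument response; its ~0.3 ns
width matches a typical hybrid-detector confocal setup.
"""

from __future__ import annotations

import numpy as np

from .decay_models import (
    AnisotropyPattern,
    DecayHistogram,
    DonorPattern,
    FretPattern,
    InstrumentProfiles,
    NuisanceParams,
    model_polarized,
)

__all__ = [
    "default_grid",
    "gaussian_irf_profiles",
    "generate_tcspc_photons",
]


def default_grid(n_bins: int = 256, period: float = 25.0) -> np.ndarray:
    """Bin-center time grid (ns) over one excitation period."""
    dt = period / n_bins
    return (np.arange(n_bins) + 0.5) * dt


def gaussian_irf_profiles(
    t: np.ndarray,
    center: float = 2.0,
    fwhm: float = 0.3,
    t_sh_vv: float = 0.0,
    t_sh_vh: float = 0.0,
) -> InstrumentProfiles:
    """Unit-integral Gaussian IRF, identical in both polarized channels."""
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    irf = np.exp(-0.5 * ((t - center) / sigma) ** 2)
    irf = irf / irf.sum()
    return InstrumentProfiles(
        irf_vv=irf, irf_vh=irf.copy(), t_sh_vv=t_sh_vv, t_sh_vh=t_sh_vh
    )


def generate_tcspc_photons(
    donor: DonorPattern,
    fret: FretPattern | None,
    aniso: AnisotropyPattern,
    profiles: InstrumentProfiles,
    grid: np.ndarray,
    period: float,
    total_photons: int,
    rng: np.random.Generator | int | None = None,
    nuisance: NuisanceParams | None = None,
) -> tuple[DecayHistogram, DecayHistogram]:
    """Sample a polarized {VV, VH} decay-histogram pair.

    Photons are split between channels according to the model channel
    intensities and distributed over bins multinomially, reproducing
    Poisson counting statistics at fixed total.  ``total_photons = 0``
    yields all-zero histograms.
    """
    rng = np.random.default_rng(rng)
    nuisance = nuisance or NuisanceParams(a0=1.0)
    curves = {
        ch: model_polarized(donor, fret, aniso, nuisance, profiles, grid, ch)
        for ch in ("VV", "VH")
    }
    totals = {ch: c.sum() for ch, c in curves.items()}
    grand = totals["VV"] + totals["VH"]
    if grand <= 0:
        raise ValueError("model curves carry no intensity")
    n_vv = rng.binomial(int(total_photons), totals["VV"] / grand)
    out = []
    for ch, n_ch in (("VV", n_vv), ("VH", int(total_photons) - n_vv)):
        p = curves[ch] / totals[ch]
        counts = rng.multinomial(n_ch, p) if n_ch > 0 else np.zeros(grid.size, int)
        out.append(
            DecayHistogram(counts=counts, bin_times=grid, period=period, channel=ch)
        )
    return out[0], out[1]
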