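"""Calibrated reference constants for the CD95/CD86/CTLA4 study system.

These are the frozen calibration values the pattern-fit pipeline relies on:
the donor-only decay pattern and FRET rate pattern obtained from the joint
calibration fits, the instrument polarization factor, and the photophysical
conversion constants used to turn x_FRET into oligomer fractions and count
rates into surface densities.  They form an immutable registry; analysis
code should read them from here rather than hard-coding numbers.
"""

from __future__ import annotations

from types import MappingProxyType

import numpy as np

from .decay_models import AnisotropyPattern, DonorPattern, FretPattern


def donor_pattern() -> DonorPattern:
    """Two-component mEGFP donor-only pattern from the joint calibration fit."""
    return DonorPattern(lifetimes=np.array([1.68, 2.75]), fractions=np.array([0.5, 0.5]))


def fret_pattern(x_fret: float = 0.0) -> FretPattern:
    """Two-state FRET rate pattern from the joint donor-acceptor calibration fit."""
    return FretPattern(
        rates=np.array([0.154, 1.346]), amplitudes=np.array([0.75, 0.25]), x_fret=x_fret
    )


def anisotropy_pattern(rho: float = 45.0) -> AnisotropyPattern:
    """Single-depolarization-time anisotropy of a flexibly tethered FP."""
    return AnisotropyPattern(r0=R0, rho=np.array([rho]), g_factor=G_FACTOR)


#: VH/VV detection-efficiency ratio G = g_VH/g_VV of the calibrated instrument.
G_FACTOR = 1.087

#: Fundamental anisotropy of the tethered fluorescent protein (start value).
R0 = 0.37

#: Typical depolarization correlation time of a flexibly tethered FP (ns).
RHO_DEPOL_NS = 45.0

#: Cloud correction ξ: fraction of donor-acceptor linker-cloud configurations
#: within FRET range for a true dimer (accessible-volume result, consumed as
#: a constant).
XI_CLOUD = 0.465

#: Probability that a dimer with an observable donor carries a FRET-capable
#: acceptor, given label stoichiometry and maturation (per receptor system).
P_AD = MappingProxyType({"CD95": 0.71, "CD86": 0.71, "CTLA4": 0.78})

#: mEGFP maturation efficiency.
ETA_MEGFP = 0.80

#: Experimentally determined x_FRET,max for a 100% dimer sample, from the
#: concentration-dependence fit of the dimer control (per receptor system).
X_FRET_MAX_EXPERIMENTAL = MappingProxyType({"CTLA4": 0.393, "CD95": 0.36})

#: Molecular brightness in Hz per molecule per μW of excitation power.
BRIGHTNESS_HZ_PER_UW = MappingProxyType({"mEGFP": 814.0, "mCherry": 264.0})

#: Fraction of fluorescent-protein receptor constructs localizing to the
#: plasma membrane (FCS-derived).
MEMBRANE_FRACTION = 0.60

#: Surface density (receptors/μm²) above which proximity FRET sets in;
#: FRET data beyond this threshold are excluded from oligomer statistics.
PROXIMITY_DENSITY_THRESHOLD = 1000.0

#: Fixed membrane diffusion time (ms) from the global FCS covariance fit.
FCS_MEMBRANE_TDIFF_MS = 0.60

#: Rhodamine 110 diffusion coefficients (μm²/s) used to calibrate the
#: confocal detection volume.
RHODAMINE110_D = MappingProxyType({22.5: 430.0, 37.0: 600.0})

#: cPBSA minimum step size: counts per 5-ms bin per μW reference (50 counts
#: per bin at 1.36 μW of 485-nm excitation).
PBSA_MIN_STEP_COUNTS = 50.0
PBSA_REFERENCE_POWER_UW = 1.36
PBSA_T_BIN_S = 5e-3
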