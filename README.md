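# oligoquant

A quantitative fluorescence toolbox for measuring the oligomerization of
membrane receptors (such as the death receptor CD95) on live cells.  It
bundles the analysis chains of four complementary single-cell techniques:

- **celfis** — pattern-based FRET-FLIM: polarization-resolved TCSPC decay
  models, a calibrated pattern fit that extracts the FRET-quenched donor
  fraction `x_FRET` per cell, and the conversion of `x_FRET` into an
  oligomerized-receptor fraction, surface density and oligomerization rate.
- **pbsa** — confocal photobleaching-step analysis: spot selection on
  overview scans, Kalafut–Visscher (KV) change-point step counting with a
  laser-power-scaled minimum step size, counts-per-step regression and a
  crowding correction for co-localized molecules.
- **sted** — STED-like spot simulation and analysis: composite-image
  simulation of labeled oligomers, Gaussian spot characterization, a
  kernel-smoothed pair-correlation estimate `g(r)` with rectangular-window
  border correction, and steady-state anisotropy.
- **fcs** — fluorescence correlation spectroscopy: a two-component
  (cytoplasm + membrane) diffusion model, single/global curve fitting and
  focal-volume diffusion calibration.
- **dynamics** — Hill-equation fitting of cumulative apoptosis time courses,
  linking receptor occupancy to the population death response.

Shared infrastructure (calibration constants, synthetic data generators,
text/TIFF I/O and an umbrella CLI) lives in `constants`, `synth`, `io` and
`cli`.

## Core models

Donor-only decays are multi-exponential, `f_DO(t) = Σ_i p_i e^(−k_i t)`;
FRET adds quenching rates on top of each intrinsic rate, so a quenched
fraction `x_FRET` of donors decays with `k_i + k_j^FRET`.  Polarized
detection weights each channel with the rotational correlation decay,
`f_VV/VH(t) = f_iso(t)·(1 ± P·r0·e^(−t/ρ))`, and models are circularly
convolved with the measured instrument response (laser repetition period
handling included).  Fits minimize either a count-weighted reduced χ² or a
Poisson maximum-likelihood deviance.

The pattern fit keeps the donor and FRET lifetime patterns frozen at their
calibrated values and varies only `x_FRET`, one depolarization time and an
amplitude — this is what makes 1–2% fraction precision per 10⁶-photon cell
measurement possible.  The theoretical maximum `x_FRET,max = ξ·p_AD`
(cloud correction ξ = 0.465 times the donor–acceptor pairing probability)
converts fitted fractions into oligomer fractions.

## Worked example

```python
import numpy as np
from oligoquant import celfis, constants, synth

grid = synth.default_grid()                      # 256 bins over a 25 ns period
profiles = synth.gaussian_irf_profiles(grid)     # instrument response, both channels
library = celfis.PatternLibrary.default()        # calibrated donor/FRET/anisotropy patterns

vv, vh = synth.generate_tcspc_photons(
    library.donor, library.fret.with_x(0.15), library.aniso,
    profiles, grid, period=25.0, total_photons=10**6, rng=42,
)
fit = celfis.fit_xfret(vv, vh, library, profiles)
frac = celfis.oligomer_fraction(fit.x_fret, constants.X_FRET_MAX_EXPERIMENTAL["CD95"])
print(f"x_FRET = {fit.x_fret:.3f}  rho = {fit.rho_depol:.1f} ns  oligomer fraction = {frac:.2f}")
```

Output:

```
x_FRET = 0.153  rho = 48.1 ns  oligomer fraction = 0.42
```

The same pipeline is available from the shell:

```bash
oligoquant synth --out-dir demo --n-cells 5 --x-fret 0.15 --seed 7
oligoquant celfis fit --manifest demo/manifest.json --out demo/fits.tsv
```

Other entry points: `oligoquant pbsa detect|fit|stats`,
`oligoquant sted simulate|analyze|paircorr`, `oligoquant fcs simulate|fit`,
`oligoquant dynamics fit`.  Every subcommand documents itself via `--help`.

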