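# Methods and numerical choices

This document describes the models implemented in `oligoquant`, the
parameter conventions, the synthetic-data generators used for validation,
and the numerical decisions that shape the fits.

## 1. Polarized TCSPC decay models (`decay_models`)

### Ideal decays

The donor-only fluorescence decay is a normalized multi-exponential,

```
f_DO(t) = Σ_i p_i · exp(−k_i t),   Σ_i p_i = 1,  k_i = 1/τ_i.
```

FRET to a nearby acceptor adds quenching rate constants on top of each
intrinsic depopulation rate.  With a quenched donor fraction `x_FRET` and
a FRET-rate pattern `{k_j^FRET, a_j}`, the species fractions are
`p_0 = 1 − x_FRET` (unquenched) and `p_j = x_FRET·a_j`, giving

```
f_DA(t) = Σ_i Σ_j p_i · p_j · exp(−(k_i + k_j^FRET) t),
```

where `k_0^FRET = 0`.  `f_DA` is linear in `x_FRET` and reduces exactly to
`f_DO` at `x_FRET = 0`.

### Polarization

Vertically polarized excitation with parallel (VV) and perpendicular (VH)
detection resolves rotational depolarization:

```
f_VV(t) = f_iso(t) + 2·r(t)-weighted term,   f_VH(t) = f_iso(t) − r(t)-weighted term,
r(t) = r0 · Σ_l b_l · exp(−t/ρ_l),
```

i.e. channel weights `P_VV = +2`, `P_VH = −1`.  Because `P_VV + 2P_VH = 0`,
the magic-angle identity `f_VV + 2·G·f_VH = 3·f_VM` holds exactly; it is
enforced by a unit test.  The detection-efficiency ratio `G = g_VH/g_VV`
multiplies the VH model.  Defaults: `r0 = 0.37`, one depolarization time
`ρ ≈ 45 ns` (slow tumbling of a membrane receptor), `G = 1.087`.

### Instrument effects

Ideal models are circularly convolved with the measured instrument
response function (IRF) via FFT; a sub-bin IRF time shift is applied as a
frequency-domain phase factor.  The assembled per-channel model is

```
M(t) = a0 · (f ⊛ IRF)(t) + a_AF · (f_AF ⊛ IRF)(t) + a_sc · IRF(t − δ) + BG,
```

with autofluorescence decay `f_AF`, scattered excitation (VV only) and a
constant background, clipped at zero.  Convolving the autofluorescence
term with the IRF (rather than adding it unconvolved) is a deliberate
choice; the alternative changes results only within the IRF width.

### Goodness of fit

Two objectives are provided:

- `chi2_ls` — reduced least-squares χ² with Poisson weights `w = N(t)`
  (zero-count bins are excluded from the sum and the degrees of freedom);
  for composed VM = VV + 2G·VH histograms the propagated weights
  `w = VV + 4G²·VH` are used.
- `chi2_ml` — the Poisson deviance
  `2·[N_mod − N_exp + Σ n·ln(n/m)]`, valid down to zero counts.

Count-weighted least squares is biased at low counts (the Neyman effect:
downward-fluctuating bins get overweighted), which visibly biases joint
lifetime fits at 10⁶ photons across 256 bins.  Final parameter estimates
therefore always come from a `chi2_ml` refinement (see §2).

## 2. Pattern-fit pipeline (`celfis`)

The per-cell analysis follows a calibrate-then-freeze strategy:

1. **Donor calibration.**  `fit_donor_pattern` jointly fits donor-only
   cells: a Nelder–Mead search over `(τ1, τ2, p1)` (log/logit
   parameterized) with per-decay amplitudes profiled analytically, then a
   polarized `chi2_ml` refinement of `(τ1, τ2, p1, r0, ρ)` on VV/VH pairs
   with the amplitude profiled exactly as `N_exp/N_mod`.  Degenerate
   (effectively mono-exponential) solutions raise a warning.
   Calibrated default pattern: τ = {1.68 ns, 2.75 ns}, fractions
   {0.5, 0.5}.
2. **FRET pattern.**  Frozen two-rate pattern
   `k^FRET = {0.154, 1.346} ns⁻¹` with amplitudes `{0.75, 0.25}`.
3. **Per-cell fit.**  `fit_xfret` fits each cell's VV/VH pair with only
   three free parameters — `x_FRET`, one depolarization time and the
   amplitude — by L-BFGS-B on `chi2_ml(VV) + chi2_ml(VH)`, multistarted at
   `x ∈ {0.05, 0.2}`.  Pairs with fewer than 10⁵ photons are rejected.
4. **Conversion.**  `x_FRET,max = ξ·p_AD` with cloud-correction factor
   `ξ = 0.465` and pairing probability `p_AD` (0.71 for CD95/CD86, 0.78
   for CTLA4), giving 33% and 36%.  Where available, experimentally
   determined maxima (`0.36` CD95, `0.393` CTLA4) take precedence via
   `ConversionConstants.resolve_x_fret_max`.  `oligomer_fraction` divides
   by the maximum (1% x_FRET → 2.8% oligomers at the CD95 maximum) and
   clips values above 1 with a warning.
5. **Density and rate.**  Surface densities come from count rate /
   (power · molecular brightness), corrected for 80% fluorophore
   maturation and optionally a 60% membrane fraction; cells above
   1000 molecules/μm² are flagged for proximity FRET and excluded.
   `oligomerization_rate` is the linear slope (%/h) over a window anchored
   at the earliest time point (default 3 h).

Validated performance: 100 replicates at 10⁶ photons recover
`x_FRET = 0.15` with SD ≈ 0.005 and bias < 0.01 (the acceptance bound is
SD ≤ 0.02).

## 3. Photobleaching-step analysis (`pbsa`)

- **Spot selection**: Gaussian smoothing (σ = 1 px), local maxima above a
  photon threshold; any maximum with a neighbor closer than 450 nm is
  discarded together with its neighbor.
- **Minimum step size** (power-scaled): `50 · p485/1.36` counts per 5-ms
  bin; at the 1.36-μW reference this is 50 counts/bin = 10 kHz.
- **KV step fit**: greedy change-point addition, each addition accepted
  only if it lowers `SIC = (k+2)·ln N + N·ln σ̂²` (global variance around
  the piecewise-constant fit); afterwards adjacent levels closer than the
  minimum step are merged.  `n_steps` counts only downward transitions;
  upward transitions (blinking, late maturation) are reported separately.
  On Poisson bleaching traces with ≤ 64 bins and ≤ 2 steps the greedy fit
  is verified against exhaustive SIC minimization (same merge filter) —
  on pure-Gaussian noise the two can legitimately differ, because the
  greedy path and the exhaustive optimum may pick different spurious
  change points that the merge filter then removes differently.
- **Counts per step**: weighted orthogonal (Deming) regression through the
  per-`n_steps` mean integrated counts, verified against a numeric
  orthogonal-distance oracle.
- **Crowding**: with maturation `η`, an n-mer conditioned on being visible
  shows `nη/(1−(1−η)^n)` expected steps.  `k_crowd` is the mean of
  observed/expected ratios for the monomer and tandem-dimer controls; the
  reference controls (1.33 and 1.92 at η = 0.8) give 1.24.  A corrected
  fraction-without-crowding statistic is intentionally left `None`: its
  defining formula is not available (see §7).

## 4. STED spot simulation and analysis (`sted`)

The simulator stamps 25×25 px 2D Gaussians (σ = 2.5 px by default) at
uniform random positions: per fluorophore a normal amplitude with
σ = 0.3·⟨Q⟩, per-stamp Poisson noise, Poisson background over the full
frame, uint16 output, plus a ground-truth table.  Defaults (10,000
objects on 2500² px) match the standard simulation conditions; tests and
acceptance use smaller fields purely for runtime (the analysis cost is
~15–20 ms per spot).

`analyze_spots` thresholds at 1 photon, keeps 8-connected regions of ≥ 9
px, and refines each candidate with a bounded least-squares 2D Gaussian
fit in an 11×11 window (amplitude, center, axis SDs, offset); border
objects are excluded.  Monomer vs dimer populations separate by their
amplitude medians with a ratio ≈ 2.

`pair_correlation` implements the kernel-smoothed isotropic estimator

```
g(r) = Σ_{i<j} k_h(r − d_ij) / (π r ρ² γ̄(r)),
```

with an Epanechnikov kernel (5 nm bandwidth), 10 nm bins, and the
rotation-averaged set covariance of the rectangular window,
`γ̄(r) = ab − 2r(a+b)/π + r²/π`, as border correction.  Under complete
spatial randomness the estimate is flat at 1 (verified); fixed-distance
pairs produce a peak at their separation.

## 5. FCS (`fcs`)

Two-component correlation model,

```
G(t_c) = 1 + Σ_s ρ_s (1 + t_c/t_s)⁻¹ (1 + t_c/(κ² t_s))^(−1/2) + G_∞,
```

for a cytoplasmic and a membrane diffusion term; no triplet/bunching term
is fitted (omitting it stabilizes noisy live-cell fits without biasing the
diffusion times).  Curves are weighted by chunk standard errors; the
membrane diffusion time can be fixed to the globally calibrated 0.60 ms,
and diffusion times can be shared across curves in a global fit (lmfit
parameter expressions).  `D = ω₀²/(4 t_diff)` links times to diffusion
coefficients; Rhodamine 110 reference values (430/600 μm²/s at
22.5/37 °C) are tabulated for focal-volume calibration.

## 6. Apoptosis dynamics (`dynamics`)

The cumulative apoptotic fraction follows a Hill curve
`P(t) = P_max − (P_max − P_min)/(1 + (t/t_half)^n)`, fitted to the
binomially weighted empirical cumulative fraction (standard error floor at
√(1e-4/N) so boundary points keep finite weight).  `P_max` is
parameterized as `P_min + δ` with `δ ≥ 0` so the ordering constraint is
enforced natively.  The fit uses lmfit's `least_squares` (trust-region
reflective) driver: the Levenberg–Marquardt driver terminates prematurely
on its internal bound transform for this problem and stalls at the
starting Hill coefficient.

## 7. Synthetic generators

`synth.generate_tcspc_photons` draws exact multinomial photon counts from
the normalized VV/VH model curves (binomial channel split, then
per-channel multinomial over bins), so simulated histograms are true
Poissonian TCSPC realizations at any photon budget.  Generator defaults
(256 bins / 25 ns, Gaussian IRF of 0.3 ns FWHM centered at 2 ns,
calibrated pattern library) represent the standard measurement conditions
and are not tuned to any test.  Scope and limits:

- detector afterpulsing, dead time and differential nonlinearity are not
  simulated;
- the bleach-trace simulator uses per-bin geometric bleaching with
  optional Poisson shot noise — no blinking model;
- FCS curves are simulated as model + i.i.d. Gaussian chunk noise, not
  from particle trajectories;
- the STED simulator places objects at integer stamp positions and does
  not model STED-specific effects (depletion profiles, anti-bunching).

Test problem sizes (replicate counts, image sizes, trace lengths) are the
package's own validation choices, selected to keep the full suite within
minutes on one CPU while leaving comfortable statistical margins.

## 8. Open questions

- Whether the autofluorescence pattern should enter the model convolved
  with the IRF or as-is is ambiguous in the underlying method description;
  this implementation convolves it (§1) and documents the choice.
- The exact form of the linear-correction terms (`l1`, `l2`) for TCSPC
  pile-up/timing nonlinearity is instrument-specific; the model exposes
  hooks but defaults them to zero.
- The crowding-corrected "fraction without co-localization" statistic is
  reported as `None` because its defining formula is not available in the
  accessible sources; `k_crowd` itself is fully specified and tested.
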