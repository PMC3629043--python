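# Methods

`waveopt` implements wavelength-set optimization for quantitative diffuse
reflectance spectroscopy of tissue: given that a spectral imaging device can
only afford a handful of illumination wavelengths, which center wavelengths
(and how wide a source bandpass) preserve the accuracy of the tissue
parameters extracted from the full 450–600 nm spectrum?  The tissue
parameters are total hemoglobin [THb] (µM), β-carotene [βc] (µM), and the
band-averaged reduced scattering coefficient ⟨µs'⟩ (cm⁻¹) — the endpoints
whose contrast separates adipose, fibroglandular and malignant breast
tissue.

## Optical model

Absorption is a linear mixture of chromophores,

    µa(λ) = ln(10) · Σᵢ εᵢ(λ) · cᵢ ,

with decadic molar extinction εᵢ (cm⁻¹ M⁻¹) and concentrations in molar
units (the package's user-facing unit is µM).  Scattering follows either an
empirical power law µs'(λ) = a (λ/λ₀)^(−b) (λ₀ = 525 nm, the band midpoint)
or a monodisperse Mie model, µs' = ρ C_sca (1 − g), with C_sca and g from
the Bohren–Huffman series (logarithmic-derivative downward recurrence,
Wiscombe truncation).  ⟨µs'⟩ always denotes the arithmetic mean of µs'(λ)
over 450–600 nm sampled at 1 nm.

### Absorber basis

The packaged basis is **synthetic**: smooth Gaussian-band surrogates with
the qualitative features that drive the inverse problem — an oxyhemoglobin
α/β doublet at 542/577 nm on a Soret tail, a single deoxyhemoglobin band
near 555 nm, a broad β-carotene band below 520 nm, and a blue-shifted
crocin band (the carotenoid dye used as a β-carotene stand-in in liquid
phantoms).  Magnitudes are order-of-magnitude realistic (10⁴–10⁵ cm⁻¹ M⁻¹)
so µM concentrations give µa of a few cm⁻¹.  Any user-supplied extinction
table in the same CSV format (`absorber,wavelength_nm,extinction`) can be
substituted; all numerical claims in this repository are made with the
surrogate basis, which keeps the package fully self-contained.

## Forward models

Both forward models map (µa(λ), µs'(λ)) to calibrated diffuse reflectance
per unit detector area at a single source–detector separation (default
0.75 mm, configurable in `GeometryConfig`):

* **diffusion** — the closed-form steady-state extrapolated-boundary dipole
  for a semi-infinite medium.  Detection combines the fluence and
  normal-flux terms, R = φ/4 + F/2, which tracks transport solutions at
  sub-mm separations considerably better than the flux-only form.  The
  refractive-index mismatch enters through the extrapolated-boundary
  distance z_b = 2AD (Groenhuis/Egan–Hilgeman fit for A); the default
  geometry is index-matched (A = 1), matching the built-in photon
  simulation.
* **scaled_mc** — Beer–Lambert rescaling of a baseline absorption-free
  isotropic random walk (the "scaled Monte Carlo" idea): one simulation's
  exit weights w_j and path lengths L_j give
  R(λ) = (1/NA) Σ w_j exp(−µa L_j µs0/µs'(λ)).  Path-only rescaling is a
  local approximation — the exit-radius distribution is not rescaled — so
  the baseline µs (default 10 cm⁻¹) should sit near the µs' range of
  interest.  The two models agree within 15 % for µa/µs' < 0.1 at the
  default geometry (asserted in the tests against a 4×10⁵-photon baseline).

Higher modules are model-agnostic; the diffusion model is the default
everywhere because it is exact-by-construction for round-trip studies and
three orders of magnitude faster.

Bandpass degradation convolves a spectrum with a Gaussian kernel of the
source's FWHM (σ = FWHM/2√(2 ln 2)), discretized on the grid, truncated at
±3σ and renormalized per output sample so no out-of-band reflectance is
invented.  A caller-supplied kernel (e.g. an LED line shape) may replace
the Gaussian.

## Inverse model

Extraction is bound-constrained multi-start nonlinear least squares on the
reflectance residuals at the chosen wavelength subset.  Free parameters:
c_HbO₂, c_dHb, c_βc plus the power-law amplitude and exponent (five
unknowns; at least five center wavelengths are required, and a subset of
four raises an explicit under-determination error).  Bounds: concentrations
in [0, 3× the observed tissue maxima], a ∈ (0, 30] cm⁻¹, b ∈ [0.1, 3].
Five Latin-hypercube starting points (seeded) are refined with
trust-region-reflective least squares; the lowest residual wins, ties
broken by the lowest THb.  Comparisons between extractions always use the
derived summaries (THb, βc, ⟨µs'⟩), never the oxy/deoxy split, because an
equally good fit can redistribute hemoglobin between the two species.

Reduced-wavelength extractions are scored as signed percent error against
the full-spectrum extraction of the same spectrum,
100·(reduced − full)/full, positive = over-estimation.

## Genetic algorithm

A candidate is a set of k distinct wavelengths on an increment grid
(450–600 nm in 1, 5 or 10 nm steps).  Fitness is the RMS of the 45 absolute
percent errors (15 training spectra × 3 parameters) of the reduced-set
extraction versus the full-spectrum reference.  Defaults: population 50,
elite 15 copied unchanged, 35 offspring per generation from
roulette-selected parents (probability ∝ 1/fitness, floored at 1e−12), of
which round(0.20 × 35) = 7 are single-point crossovers and 28 are Gaussian
mutations of one wavelength (σ = 3 grid steps by default), duplicates
repaired by redrawing a fresh uniform grid wavelength.  Termination: best
fitness unchanged (relative tolerance 1e−9) for 10 generations, or 50
generations.  Elitism makes the best-of-generation fitness non-increasing;
fitness values are memoized per wavelength set, so elites cost nothing to
re-rank and the evolution trace is exactly reproducible from the seed.

The 15-sample training set mimics percentile sampling of a clinical
cohort: for each of THb, βc and ⟨µs'⟩, the samples at the nearest-rank
10/25/50/75/90th percentiles of the empirical cdf are chosen (ties resolve
to the first sample, so degenerate populations select one canonical index).
A packaged 15-row fixture spans THb 10.7–97.9 µM, βc 7.0–37.6 µM and
⟨µs'⟩ 3.7–11.9 cm⁻¹; its oxygen saturation is not part of the published
summaries and defaults to 0.7 (configurable) — tests compare THb only.

## Synthetic data

`generate_cohort` draws (THb, βc, ⟨µs'⟩) uniformly within the observed
tissue ranges, splits THb by saturation, calibrates the power-law amplitude
so the band-mean µs' is hit exactly, simulates spectra, and corrupts them
as

    R_noisy(λ) = R(λ) · g(λ) · (1 + ε_m) + ε_a ,

with per-sample multiplicative noise ε_m ~ N(0, 0.03²), additive noise
ε_a ~ N(0, (0.005·mean R)²), and a smooth multiplicative gain field
g(λ) = 1 + 0.02·z(λ) (standard-normal knots every 50 nm, linearly
interpolated).  The correlated gain term emulates calibration and
probe-contact variation, the dominant error source in measured reflectance;
it matters structurally because, unlike white noise, it does not average
away as wavelengths are added — without it, extraction error would keep
falling like 1/√k and the diminishing-returns knee past 8 wavelengths would
be an artifact of sample size rather than a property of the data.  Noise
magnitudes are package defaults chosen to put full-spectrum extraction
errors in the single-digit-percent regime; they are tuning knobs, not
measured values.  What the generator does **not** emulate: model mismatch
between tissue and the forward model (generation and inversion use the same
physics), probe-pressure artifacts, and spatial heterogeneity — so passing
closure tests demonstrates the correctness of the machinery, not clinical
accuracy.

`generate_phantom_set` realizes the 20-phantom factorial design (5 crocin
steps × 2 hemoglobin levels × 2 scattering levels at ⟨µs'⟩ = 9 and
12 cm⁻¹): each absorber concentration is calibrated so its band-averaged µa
matches the design value exactly (the band mean is linear in
concentration), and scattering is calibrated the same way.

`ToyUnmixingProblem` is a deliberately small selection problem — three
disjoint narrow absorber bands on a 10-point grid with fixed scattering —
whose C(10,3) = 120 subsets can be enumerated, providing an independent
global-optimum oracle for the GA; the informative optimum is the triple of
band centers.

## Validation statistics

Bland–Altman agreement reports bias = mean(reduced − full) and 95 % limits
of agreement ±1.96·SD (sample SD, n−1).  Margin maps of the βc/⟨µs'⟩ ratio
are compared by Pearson correlation over a shared validity mask and
classified positive when ≥ 98 % of valid pixels fall strictly below a ratio
of 6 (both thresholds configurable).  Group comparisons use the two-sided
Wilcoxon rank-sum test in its tie-corrected normal approximation; fully
tied data returns p = 1 by convention.

## Numerical choices and problem sizes

* Grid arithmetic uses integer index math scaled by the step, so 2.5 nm
  grids are exact (61 points over 450–600 nm).
* Basis interpolation is linear and never extrapolates beyond tabulated
  support.
* Subset wavelengths match spectrum samples by nearest-neighbour within
  half a grid step; anything farther raises.
* A failed extraction inside the GA contributes a 100 % penalty error per
  parameter rather than aborting the run.
* Default study sizes keep every analysis at desk scale: 100-draw cohorts
  for closure and the wavelength-count knee, the 15-sample fixture for the
  bandpass study (15 spectra × 7 FWHM levels = 105 degraded spectra), a
  4×10⁵-photon baseline for the transport cross-check, and 10⁵ draws for
  roulette-frequency calibration.

## Known limitations

* The inverse fit and the simulator share the same forward physics, so
  reported errors exclude model mismatch; against measured data, errors
  would be larger and wavelength rankings could shift.
* The scaled-MC model rescales path lengths only; far from its baseline µs
  it biases low, and it inherits Monte Carlo noise.
* The surrogate extinction curves are not literature data; absolute
  concentrations are only meaningful relative to the basis used.
* Hb/crocin unmixing is intrinsically ill-conditioned in 450–600 nm because
  the crocin band center lies below the window; noisy phantom recoveries
  show accordingly larger errors than tissue-like cohorts.
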