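# Methods

## Signal model and estimator

A C-scan is a complex reflectivity field C(z, x, y) sampled at δ = 4.48 µm
axially (in tissue, so no refractive rescaling is applied anywhere) and
12 µm laterally at full resolution.  When tissue moves axially by U between
two scans, each voxel's phase advances by 4πnU/λ_mean (λ_mean = 877.8 nm,
n = 1.375).  The estimator recovers this phase with the self-normalized,
amplitude-weighted windowed cross-correlation Ŵ (half-widths
w_z = w_x = 3 px, i.e. 7×7 windows), and the axial strain from a second
windowed correlation R between axially adjacent rows of Ŵ:
ε_zz = λ_mean·∠R/(4πnδ).

Choices that the formulas leave open:

* **Sign convention.** Correlations are ordered `later · conj(earlier)` (for
  W) and `deeper · conj(shallower)` (for R), so an imposed phase advance
  reads back with its own sign and axial expansion gives positive strain.
  Swelling is therefore positive throughout, shrinkage negative.
* **Window truncation.** Sums run over in-bounds pixels only (zero padding,
  no wrap-around).  Within ~2·w_z+1 rows of the tissue boundary the
  truncated, asymmetric windows bias the amplitude-weighted phase of a
  depth ramp; per-pixel checks therefore use `interior_tissue_mask`, which
  erodes by the combined support of both windows.  Regional band means that
  include boundary rows inherit a small low bias (≈2 % of the true value at
  native δ; larger when the band spans few rows, e.g. ≈10 % at 4× coarser
  axial sampling, since the ~7 biased rows are then a larger share of the
  band).
* **Zero modulus.** Where a windowed sum has negligible modulus the output
  is set to 0 and flagged invalid instead of normalized.
* **No phase unwrapping.** Per-pair displacement is unique within ±λ/(4n)
  (±160 nm) and strain within ±λ/(4nδ) (±3.6 %).  Typical swelling rates
  wrap the *displacement* map many times over a 1-minute interval at ~1 mm
  tissue thickness — exactly as in the real instrument — but the strain
  stays 1–2 orders of magnitude below its bound; beyond the bound strain
  aliases to the wrapped, sign-flipped value, which the validation suite
  asserts at ±0.99/1.01× the bound.  The phantom records a metadata warning
  when an imposed per-pair displacement exceeds the bound.
* **Quality masking.** A pixel is valid when the structural amplitude in
  both frames exceeds `amp_threshold` (default 0.1) × the median in-tissue
  amplitude *and* the windowed complex correlation coefficient
  γ = |ΣC₂C₁*|/√(Σ|C₁|²·Σ|C₂|²) exceeds `coherence_threshold` (default
  0.3).  The coherence term is what catches fluid-application artifacts:
  they destroy phase correlation while leaving amplitude intact, so an
  amplitude floor alone can never flag them.  A pair whose valid fraction
  inside the tissue drops below 0.5 is excluded from accumulation.

## Regional read-outs

Bands are anchored to the detected surfaces — the anterior band extends
`band_depth` (default 400 µm) down from the anterior surface, the posterior
band up from the posterior surface — so they follow corneal curvature.
Lateral windows are centered on the image (defaults 4 mm × 0.48 mm
half-extent for volumetric means; the central ~40 A-scans of the central
B-scan for depth–time maps and depth profiles).  Surface detection smooths
the amplitude axially and laterally (σ = 1 px; the lateral pooling fills
speckle nulls at the boundary), thresholds at 30 % of the column maximum,
median-filters the surfaces and interpolates failed columns; >50 % failures
raise an error.

Per scan pair the strain map is averaged over the region first, then the
regional increments are accumulated as a plain running sum expressed in
percent — increments are ≲4 ‰, so compounding corrections are second-order.
Invalid pairs contribute zero and are flagged rather than interpolated,
which is conservative: with k of N pairs lost, a constant-rate curve's
slope is underestimated by k/N.  Depth profiles resample each column onto
equal fractions of its local thickness (20 bins by default) before lateral
averaging.

## Statistics

Cumulative curves are segmented (defaults: minutes 1–20, 21–50, 51–80,
matching the pre-treatment / irradiation / post-treatment protocol), each
segment fitted by OLS on its valid points (≥3 required), and per-sample
slopes (%/min) compared with two-sided t-tests: Welch for between-group
contrasts (no equal-variance assumption; a pooled Student test is available
via `equal_var=True`), paired for within-sample segment contrasts.  Raw
p-values at α = 0.05, no multiple-testing correction.  The null calibration
of this procedure (identical slope distributions, n = 6 vs 6, 2000
replicates) is part of the validation battery.

## The phantom

Speckle is modeled as ~2 point scatterers per voxel with uniform phase,
binned to the grid, convolved with a Gaussian PSF (σ ≈ 0.7 px axial and
lateral) and clipped to the corneal band between two spherical (or flat)
surfaces — circular-Gaussian statistics with controllable decorrelation.
`scatterer_density = 0` requests a deterministic uniform-amplitude band
instead, used for exact closed-form checks: with speckle, the amplitude
weighting inside the windows adds zero-mean per-pixel noise proportional to
the phase-ramp slope (~3×10⁻⁴ strain at ε₀ = 10⁻³ even without additive
noise), so exactness is only meaningful on the uniform band, while
speckle accuracy is asserted on the in-tissue *mean* (within 10 % at
20 dB SNR; measured ≈0.1 %).

Deformation is imposed in phase space (`phase_only`): each voxel is
multiplied by exp(i·4πnU/λ) with U integrating the scenario's strain-rate
profile over time at the voxel's normalized stromal depth, anchored at the
posterior surface (swelling pushes the anterior surface toward the probe).
The returned ground truth satisfies diff(U)/δ = ε exactly on the strain
grid.  A `resample` mode additionally shifts the speckle pattern by U/δ
pixels (linear interpolation) for decorrelation-robustness experiments; it
is not used in accuracy claims.  Additive circular-Gaussian noise sets the
amplitude SNR (default 25–30 dB; 20 dB in stress tests); fresh per-frame
phase noise (σ = 0.02 rad default) models inter-frame decorrelation.
Dropout frames — emulating the periodic fluid applications that destroy
phase data — keep their amplitude but have their phase fully randomized,
which exercises the same masking path as the real column artifacts at
frame granularity.

### Scenarios

Rate magnitudes are descriptive defaults chosen as observed cumulative
strains divided by their durations; they define the simulated study
conditions, not claims about tissue:

| scenario | profile |
| --- | --- |
| `isotonic` | zero everywhere (null condition) |
| `hypotonic_swelling` | uniform in depth; 3.7 %/20 min, then 0.2 %/25 min after osmotic equilibrium |
| `hypertonic_deswelling` | linear in depth, −0.28 %/min at the anterior surface, zero at 55 % of thickness, posterior positive |
| `control_swelling` | uniform; 0.14 %/min (first 20 min) then 0.09 %/min, 80 min |
| `cxl` | control background; from minute 30 the anterior 200 µm flip to −0.07 %/min; dropout every 5 min during minutes 20–50 |

Two notes on the `cxl` defaults.  The onset (minute 30) is ten minutes
after irradiation begins at minute 20, when the shrinking layer has reached
its full 200 µm depth.  The shrink rate is set so the *anterior-400 µm band
mean* rate during irradiation is ≈0.01 %/min (half the band shrinking at
−0.07, half swelling at +0.09) — i.e. it reproduces the regional slope
dynamics; the per-‰ depth-map amplitudes this implies are a few-fold larger
than a strict reading of depth-resolved maps would give, a tension inherent
in reconciling band slopes with map color scales, resolved here in favor of
the slope statistics that the group comparison tests.  Note the band mean
over the anterior 400 µm of a depth-linear hypertonic profile is ~64 % of
its anterior-surface value (≈ −3.6 % at 20 min), which is what the pipeline
recovers.

Group simulations draw an eye-specific multiplicative rate factor
~N(1, 0.2²) (20 % between-eye variability — moderate biological spread,
below the ~40 % CV real slope tables show) and derive eye seeds from the
study seed plus the group name, so arms share no noise realizations.

## Problem sizes

Validation and analysis runs use reduced geometries chosen as the package's
own working sizes: 24–256 A-scans × 1–3 B-scans instead of 1000 × 100, and
for 80-minute group studies a 4× coarser axial pitch (17.92 µm) over a
1 mm cornea at one volume per minute.  The estimator parameters are never
scaled — only the field of view and sampling are — and the noisy-recovery
check runs at the native δ on 128×256×3 volumes.  Scenario endpoint
read-outs also run at native δ because the coarse grid's boundary-bias
share would otherwise dominate (see Window truncation above).

## Limitations

* Axial-only: no lateral displacement or shear strain; no elastic-modulus
  inversion; no wave-based elastography.
* No physical light propagation (no refraction at the liquid interface, no
  depth-dependent SNR, no absorption); speckle is statistically, not
  physically, realistic.
* Dropout is modeled per frame, not per column; real artifacts mask
  subsets of A-scans.
* Phase-only deformation does not decorrelate speckle the way large real
  deformations do; `resample` mode exists to probe that regime but is not
  part of the accuracy claims.
* Passing on the phantom demonstrates correctness of the estimator and
  statistics under the stated noise model, not performance on real corneal
  data with bulk motion, saturation artifacts, or layer-dependent optical
  properties.
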