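# Methods

## The integrity score

The score statistic quantifies how "structured" a fluorescence intensity
profile is. Profiles are sampled on parallel lines with unit-pixel steps
and bilinear interpolation. For a profile I(0..L−1):

* forward difference ΔI(x) = I(x+1) − I(x), length L−1;
* sliding window sum over k consecutive differences (stride 1), length
  L−k; the default k = 2 is the minimal window that cancels alternating
  single-pixel noise — for pure detector noise consecutive differences are
  anticorrelated and largely cancel, while the same-signed flank pair of a
  genuinely crossed filament adds up;
* S = c · SD(filtered differences) / max(I), population SD, with
  c = 100 fixed. SD/max of a non-negative signal is bounded by roughly
  0.7, so the factor 100 puts fully structured profiles in the 60–70 range
  and unstructured ones around 20–30, the conventional score scale
  (≈ 60 intact, ≈ 30 eliminated).

Two properties follow directly and are asserted in the test suite:
multiplying an image by any gain c > 0 leaves the score unchanged
(both SD and max scale), and adding a constant offset can only lower it
(the derivative SD is offset-free while the max grows).

The SD can alternatively be taken over the raw profile
(`score_signal="raw_intensity"` in `ScoringProtocol`); the derivative-based
signal is the default because it is the quantity the noise filter
produces. Reports record the mode in every output header; the calibration
anchors hold for the default mode only.

### Orientation and profile placement

Profiles must cross the microtubules to see them as peaks. The dominant
orientation of the linear structures is estimated from the structure
tensor (the summed outer product of the intensity gradient after light
Gaussian smoothing): the major eigenvector of that tensor is the dominant
gradient direction, and filaments run perpendicular to it. Second
*position* moments were considered and rejected: for an array that fills
the frame they are dominated by the frame geometry and carry no
orientation signal. `score_cell` then samples `n_profiles` = 5 lines
perpendicular to the estimated filament direction, spaced 8 px apart and
centred on the image midline. In an elongated cell with a transverse
cortical array this direction is the cell's elongation axis. Profiles with
more than 10 % saturated samples (at the bit-depth ceiling) are excluded
and the per-cell mean is taken over the rest; a constant image has no
defined orientation and is sampled along the rows, scoring zero.

## The synthetic image model

The generator emulates single spinning-disc confocal sections of
GFP-tubulin cells. No pixel size or optical model beyond a Gaussian PSF is
claimed; the image is 256 × 256 at 16 bit by default, intensities in
expected-photon units.

* **Filaments.** `n_filaments` = 76 straight lines with Gaussian
  cross-section (σ = 0.6 px, peak 160 photons), orientations
  N(90°, 1°), line centres a jittered regular grid (5 % jitter) along the
  perpendicular — a dense, quasi-regular transverse array. Real cortical
  arrays curve and branch; curvature adds nothing the score would see, so
  it is omitted.
* **Disintegration.** d ∈ [0, 1] scales the filament layer by (1−d) and
  adds d · mean(filament layer) to the uniform soluble background: the
  pre-noise photon budget of a void-free render is exactly independent of
  d. This is the model's definition of "elimination": fluorescence is
  exchanged, not lost.
* **Cytoplasmic granularity.** The soluble pool is modulated by a
  mean-one, bounded random texture (clipped Gaussian, relative SD 0.5,
  correlation ≈ 0.8 px): living cytoplasm is not optically flat, and this
  granularity — not detector noise — is what keeps the score of a fully
  eliminated cell near 30 rather than near zero. Detector noise alone
  cannot reproduce that floor without drowning the intact-state anchor;
  this was established numerically during calibration.
* **Organelle voids.** 600 small dark ellipses (semi-axes 4 × 2 px,
  transmission 0.08, edges blurred by 0.7 px) attenuate the *soluble*
  component only: filaments pass over them brightly. In the intact state
  the background is dark and the voids are invisible; after elimination
  they appear as dark "negative images" against the bright soluble pool,
  exactly the treated-cell phenotype. They contribute derivative variance
  without inflating the profile maximum, which keeps the score strictly
  decreasing in d up to the calibrated floor.
* **Speckles.** Bright Gaussian puncta (2× filament peak, σ 1.2 px) at a
  controllable density per 1000 px², emulating the scarce late-stage
  punctate state; off by default.
* **Noise.** Poisson shot noise on the expected image plus Gaussian read
  noise (SD 3), then rounding and clipping to the bit depth. `gaussian`
  and pure `poisson` models are selectable.

Every stochastic element draws from one `numpy` Generator seeded by the
`seed` field; identical parameters give bit-identical images. Batches give
image i the seed `seed + i`.

### Calibration

The score scale is defined only by its anchors, so the generator/protocol
defaults were tuned once — jointly over filament density, width, photon
budget, texture and noise — so that the default pipeline yields a mean
score of ≈ 62 at d = 0 and ≈ 26.5 at d = 1 over 30 cells, inside the
anchor bands (60 ± 6 and 30 ± 5, the published range for complete
elimination being 25–30), and then frozen. A genuine limitation surfaced
during calibration: near d = 1 the remnant filament peaks inflate the
profile maximum before they contribute variance, so the score of a mixture
necessarily dips slightly below the pure-texture endpoint. The frozen
calibration keeps the mean score strictly decreasing on the grid
d ∈ {0, 0.25, 0.5, 0.75, 1} with ≈ 1.3 score units of margin at the tail;
finer d grids near 1 may show a ≲ 1-unit inversion.

## Dose–response and group statistics

The dose → disintegration map is a Hill curve
d(x) = d_max · xʰ / (ec50ʰ + xʰ). The packaged aqueous sweep uses
d_max = 0.65, ec50 = 0.7 mg/mL, h = 3 on the grid
{0.1, 0.3, 1, 3, 10, 30, 100} mg/mL: the lowest dose is below detection,
the effect onset falls on 0.3 mg/mL and the response saturates in the low
thirties — the canonical shape of the bioassay this package analyses.

Groups (≥ 2 cells each) are compared with Duncan's multiple range test:
one-way ANOVA MSE, then ordered means compared stepwise against
R_p = q(1−(1−α)^(p−1); p, df) · √(MSE/n_h), with p the span of means
covered, q the studentized-range quantile (computed numerically from
`scipy.stats.studentized_range`, not from tables; the classical published
5 % tables serve as an independent oracle in the tests), and n_h the
harmonic mean group size (the standard treatment of unequal n, 10–32
cells per group being typical). The step-down protection rule applies:
pairs inside a span already found homogeneous are never declared
different, which makes the homogeneous sets intervals of the ordered
means; the compact letter display assigns one letter per maximal
homogeneous interval (so it is transitively consistent by construction),
letters ordered by ascending mean. With two groups the protection level
equals α and the decision reduces to Fisher's LSD. Zero MSE with tied
means degenerates to a single shared letter.

A dose–response table reports `lowest_significant_dose` (smallest dose
sharing no letter with the control) and `saturation_dose` (smallest dose,
at or above the onset, that every higher dose shares a letter with;
vacuously the top dose when every step separates; undefined when there is
no effect at all).

## Mortality coupling and regression

The Evans-blue assay is modelled per replicate as a binomial draw over
`n_cells_per_measurement` = 500 cells with success probability
clip(intercept + slope · (score − 60) + N(0, residual_sd), 0, 1), three
replicates per condition. The frozen defaults are intercept 0.05 (5 %
background mortality at full integrity), slope −0.059 per score unit and
residual_sd 0.04. The steep slope saturates the most potent conditions at
100 % mortality; that saturation is deliberate: it supplies a stable,
largely deterministic lack-of-fit to the *linear* regression of
condition-mean mortality (%) on condition-mean score, centring its R² at
≈ 0.73 over the default 12-condition grid with little run-to-run spread.
(A purely Gaussian condition residual calibrated to the same mean R² would
make a 12-point R² fluctuate by ± 0.12 between runs.) The regression
itself is unweighted OLS on condition-level means — matching the pooled
single-scatter analysis it reproduces — via statsmodels, with the
closed-form normal equations as the test oracle.

The default 12-condition grid crosses 3 tissues × 2 collection sites
× 2 doses (25 and 100 µg/mL of an alkaloid fraction); potency factors
(bark > leaf > root, Sanankoroba > Sikasso) scale the Hill midpoint so the
conditions spread over nearly the whole integrity range, and the
tissue × site heat maps reproduce the qualitative site ordering.

## Problem sizes and determinism

The packaged experiment sizes are 30 cells for the anchor estimates,
15 cells per condition for the 12-condition grid, and 20 cells per dose
for the 7-dose sweep — within the 10–30 cells per data point range such
assays use. One 256 × 256 cell renders and scores in ≈ 90 ms, so the full
12-condition experiment takes ≈ 20 s. All outputs carry the seed, the
protocol mode and the package version in their headers, and re-running
with the same configuration reproduces the CSVs byte for byte.

## What the synthetic tests do and do not show

The generator reproduces the *geometry and statistics* that the score
responds to (parallel bundles, soluble background, granularity, voids,
shot noise), not real optics: no curvature, no 3-D structure, no cell
boundary, no uneven illumination, no focus drift. Passing tests therefore
demonstrate that the implementation of score, statistics and couplings is
correct and internally calibrated — not that the score would achieve any
particular accuracy on real micrographs. The score itself is also purely
texture-based: any treatment that changes profile texture (fixation
artefacts, overexpression, bundling) moves it, microtubule-specific or
not.
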