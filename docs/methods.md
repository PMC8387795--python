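# Methods

This note documents the models and procedures implemented in `hhpbone`,
the assumptions behind the synthetic data, the defaults that matter, and
the numerical choices made where the design was genuinely open.

## 1. Apoptotic density mapping

### Pipeline

1. **Tile merging.** Micrograph tiles are composed row-major into a
   whole-sample image; overlap strips are blended by averaging
   (`merge_tiles`). The inverse, `cut_tiles`, exists for round-trip
   testing.
2. **Nucleus detection.** The DAPI channel is detrended by subtracting
   a large-sigma Gaussian blur (4× the maximum nucleus radius), which
   removes the broad DAPI-bright trabecular plateau while leaving
   nucleus-scale blobs. Nuclei are then scale-normalized
   Laplacian-of-Gaussian maxima (`skimage.feature.blob_log`) between
   `min_radius_px` (2) and `max_radius_px` (5) above `detect_threshold`
   (0.08 in normalized intensity units). This stands in for interactive
   cell-detection software; its parameters are explicit so runs are
   reproducible.
3. **TUNEL classification.** A detection is TUNEL-positive when the
   mean TUNEL intensity inside its nucleus disc exceeds
   `tunel_threshold`. The threshold is exposed because the right value
   depends on channel normalization; against the synthetic scenes,
   values in 0.15–0.25 give near-perfect labels.
4. **Spatial binning.** TUNEL-positive detections are counted into
   square bins (`bin_size_px`, default 64; the validation studies use
   16 px bins to give the radial zones enough bins). Bins are half-open
   in both axes, so totals are conserved exactly.
5. **Gaussian smoothing.** The count matrix is convolved with a
   unit-sum 2-D Gaussian (`sigma_bins`, default 2), truncated at 4σ,
   with a reflective boundary. Reflection folds kernel mass back into
   the grid, so the smoothed total equals the count total to floating-point
   precision — an invariant the tests assert at 1e-9 relative.
6. **Trabecular mask.** Bone matrix binds DAPI strongly, so trabeculae
   are the bright class of the DAPI histogram. `otsu_threshold` scans
   every candidate gray level for the maximum between-class variance
   (ties broken toward the lower level; integer images are scanned at
   integer levels, floats through a 256-bin histogram); the Boolean mask
   is `dapi > threshold`. An inversion flag handles inverted-contrast
   input.
7. **Density map.** The pixel mask is downsampled to the density grid
   by majority vote (a bin is trabecular when at least half its pixels
   are), and smoothed density is shown only on trabecular bins; other
   bins carry NaN.

### Boundary correction

Plain kernel smoothing underestimates density near the sample boundary:
part of every boundary bin's kernel mass falls outside the tissue, and
boundary bins are only partially covered by tissue in the first place.
`edge_corrected_density` applies the standard renormalization for kernel
density estimates near a support boundary — the smoothed counts are
divided by the identically smoothed support indicator. The support
(where tissue exists) is estimated from *all* detections, positive and
negative: bone sections are approximately round, so a circle at the
detection centroid with radius at the 99th percentile of
centroid-to-detection distances (2% margin) is fitted
(`estimate_sample_support`). The corrected density is a per-tissue-area
quantity and intentionally does not conserve raw counts; the pipeline
persists both the conserving smoothed matrix and the corrected map it
uses for the gradient statistic.

### Center/edge statistic

The center is the centroid of masked-in bins; radii are normalized by
the maximum centroid-to-masked-bin distance. `center_mean` averages bins
with normalized radius ≤ `inner_fraction` (default 0.15), `edge_mean`
those ≥ `outer_fraction` (default 0.92), and the ratio is their
quotient, with a binned radial profile alongside. The thin end zones are
deliberate: the statistic is a zone mean, and for a density varying
gradually between center and edge, wide zones would pull both means
toward the middle of the profile and shrink the ratio toward 1 (for a
linear profile with a true 4:1 gradient, 0.25/0.75 zones yield ≈ 2.6
while 0.15/0.92 zones yield ≈ 3.3). Zones with no masked-in bins raise
an error rather than returning a silent NaN.

Single-scene ratio estimates are noisy (tens of counts per zone), so the
reference study (`hhpbone.protocols.gradient_recovery_study`) pools
center and edge means across replicate scenes per condition before
taking the ratio — the analogue of averaging donors before comparing
groups.

## 2. Synthetic histology scenes

The generator emulates merged whole-sample TUNEL/DAPI images:

- **Sample geometry.** The tissue is a disc inscribed in the merged
  frame. The radial rate field of TUNEL-positive cells decreases
  linearly from `center_rate` to `edge_rate` in Euclidean distance
  normalized by the center-to-nearest-edge distance (clipped at 1), so
  the field's "edge" coincides with the disc boundary and with the
  statistic's radial normalization.
- **Point process.** TUNEL-positive cells are an inhomogeneous Poisson
  process over the rate-field bins (positions uniform within a bin),
  thinned to the disc; for a constant field, per-bin counts are Poisson
  with the configured mean, which a chi-square goodness-of-fit test
  asserts. TUNEL-negative nuclei are placed uniformly in the disc by
  dart throwing with a minimum separation of 2.5 nucleus radii, failing
  loudly when the requested count cannot be packed.
- **Rendering.** Nuclei are Gaussian spots (σ = nucleus radius; DAPI
  amplitude 0.45, TUNEL amplitude 1.0 for positives). Trabecular
  structure is a smoothed white-noise field thresholded at the quantile
  giving `trabecula_fraction` of the disc area (correlation length
  `texture_scale_px`, default 1/32 of the merged frame). The matrix is
  rendered *brighter than nuclei* (0.75 over a 0.05 background),
  reflecting the strong DAPI affinity of bone matrix, and with a
  diffuse edge (Gaussian softening over `matrix_edge_px`, default 3
  nucleus radii) — stained matrix has no pixel-sharp boundaries at this
  magnification. Channel noise is additive Gaussian with
  σ = peak/`snr`.
- **Determinism.** All randomness flows through one
  `numpy.random.Generator` seeded from `seed`; identical parameters
  give bit-identical scenes.

What the generator does *not* model: optical point-spread functions,
chromatic registration error, staining heterogeneity, autofluorescence
gradients, sectioning artifacts, and cell clustering beyond the Poisson
process. Passing the recovery tests therefore demonstrates that the
pipeline correctly inverts this generative model at realistic counts and
noise levels, not that it is robust to every artifact of real slides.

## 3. Gel densitometry

### Rendering model

Electrophoretic mobility follows the standard log-linear model for
agarose gels, `distance_px = a − b·log₁₀(size)`, with defaults
(a, b) = (720, 200) on a 400-row image, placing 100 bp–3 kb on the gel;
SDS-PAGE simulations reuse the same model in kD with a steeper slope.
Each mass quantum becomes a discrete Gaussian profile (σ = 2.5 px)
normalized to its mass in lane-profile units; smears are discretized
into 1024 quanta across their size range (uniform mass per bp). Bands
migrating off the image warn and are flagged clipped. Noise is additive
Gaussian on the image. Where a signal-to-noise ratio is quoted for a
gel, it is the ratio of the weakest lane's peak *densitogram* signal to
the densitogram noise σ — quantification happens on the densitogram,
and a gel whose weakest lane fell below that quality would be re-imaged
in practice.

### Quantification

- **Lane profile**: column mean over the lane's half-open column
  interval, on the bright-band image; polarity is auto-detected from the
  image median (dark-band images are flipped) with an override. An
  optional mass-conserving 1-D Gaussian smooth (pipeline default 1.5 px)
  suppresses pixel noise.
- **Baseline**: grey opening (rolling minimum then rolling maximum,
  window 251 px) subtracted and clipped at zero. Opening leaves monotone
  ramps in place and removes every structure narrower than the window,
  so the window must exceed the widest genuine feature — smears
  included. The input is padded by odd reflection so ramps are tracked
  to the profile ends, and on noisy profiles the baseline input is
  lightly presmoothed (2 px) so the opening does not ride the noise
  floor; the baseline is still subtracted from the unsmoothed signal.
- **Bands**: prominence-filtered peaks (`scipy.signal.find_peaks`) with
  subpixel centers by 3-point parabolic interpolation. The reported
  extent is the half-prominence region; the integration support runs
  between the peak bases, clipped at midpoints to neighbouring peaks and
  at 3× the half-prominence width. Peaks broader than
  `max_band_width_px` at half prominence are not bands (they are smear
  humps). With a local-base window set (pipeline default 51 px), bands
  are detected and integrated on the signal *above* a grey-opening local
  base, so a band riding on a smear carries only its own mass. The
  pipeline's prominence threshold is the larger of 5% of the lane
  maximum and 4× a robust noise σ (median absolute difference of the
  raw profile, scaled for the applied smoothing).
- **Smears**: runs of above-level signal (level: max of 5% of lane peak
  and 3× noise σ), measured on a 4-px-smoothed mask with noise gaps up
  to 5 rows closed, longer than 20 px. Band rows contribute the local
  base (the smear surface under the band), so band and smear volumes
  add up to the lane total without double counting — asserted to 1% on
  noiseless gels.
- **Ladder calibration**: bands and rung sizes are paired top-down
  (slowest band = largest rung; counts must match, pairing must be
  strictly monotone, at least 3 rungs) and fitted by least squares in
  (log₁₀ size, distance). The inverse map sizes every other band; a
  band midway between the 100 and 200 bp rungs reads the geometric mean
  √(100·200) ≈ 141 bp, a closed-form property of the log-linear model.
- **Categories**: `<200 bp`, `200–500 bp` (closed interval — sizes of
  exactly 200 or 500 fall here), `>500 bp`. Discrete bands contribute
  their volume at their center size. Smears are apportioned row by row
  through the calibration (default) or — in `compat` mode — assigned
  wholesale to the category of their largest-size reach, reproducing how
  a single-box smear volume behaves in interactive gel software; a
  high-molecular-weight smear then lands entirely in `>500 bp`.
  Relative quantification reports each treated category as a percentage
  of the control lane's volume, flagging categories with an empty
  control as undefined rather than dividing by zero.

## 4. Band-derived ratios

Relative expression is `treated_volume / control_volume` (1.0 = control
level); an absent treated band is "not detectable" and is carried as
missing data, never as zero, because non-detection on a gel bounds
nothing. A zero control volume is an error. The collagen ratio divides
the alpha-1 band volume by the alpha-2 band volume; intact collagen
type I (two α1 chains, one α2) predicts 2. The alpha pair is identified
geometrically as the unique adjacent close pair of discrete bands
(center gap ≤ 25 px), which excludes the lone high-molecular-weight
band; zero or multiple candidate pairs raise identification/ambiguity
errors instead of guessing. A molecular-weight calibration, when
supplied, only annotates apparent sizes.

## 5. Statistics

The factorial layout is pressure protocol × incubation time with donors
as replicates, analysed as a balanced fixed-effects two-way ANOVA in
closed form: SS_A, SS_B, SS_AB and SS_residual decompose SS_total
exactly (asserted to 1e-9 relative), F = MS_effect/MS_residual, p from
the F distribution. Degenerate inputs are handled explicitly: a
single-level factor reduces to the one-way analysis (zero SS/df for
that factor and the interaction); all-identical data give F = 0, p = 1;
a saturated design (one observation per cell) has no residual degrees of
freedom and errors; unbalanced tables error rather than silently
switching to a different sum-of-squares type. Post hoc comparisons are
pairwise t tests on the pooled within-group variance with Bonferroni
adjustment `min(1, m·p)` where m counts the comparisons actually
requested; significance is inclusive (p ≤ 0.05). Monte-Carlo tests
confirm per-effect type-I error calibration and family-wise error
control under the null.

## 6. Validation studies and problem sizes

The validation suite runs everything end to end at sizes chosen to give
stable statistics: the gradient-recovery study uses twenty 1280×1280
scenes of 2,000 cells (four each at center/edge ratios 1 and 2, twelve
at ratio 4, where the recovery band is checked), 16-px bins and
replicate-pooled zone means; gel category recovery uses three seeds per
fragment distribution at noiseless and SNR-10 conditions; ANOVA
calibration uses 1,000 null replicates. The collagen-stoichiometry
study rendered by `scripts/acceptance.py` is noiseless by design — the
planted quantity is a deterministic stoichiometry, and the measured
ratio isolates the densitometry chain's accuracy rather than photon
statistics.

## 7. Known limitations

- The cell detector assumes roughly circular nuclei of similar size;
  overlapping nuclei closer than about twice the blob scale merge into
  one detection, which attenuates density estimates in very crowded
  fields (visible as a mild shrink of recovered gradients toward 1).
- The trabecular mask inherits Otsu's bimodality assumption; tissues
  with strong intensity gradients would need local thresholding.
- The mobility model is log-linear over the calibrated range only;
  sizes extrapolated beyond the ladder are indicative.
- `compat` smear mode exists for comparability with single-box smear
  volumes; `apportion` is the physically sensible default, and the two
  disagree by construction for smears spanning category boundaries.
- The ANOVA layer is deliberately balanced-fixed-effects only; donors
  are replicates, not a blocking factor, and unbalanced designs are out
  of scope.
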