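# Methods

## Imaging quantification

The per-cell spGFP measurement assumes a two-channel confocal z-stack in
which mCherry marks mitochondria (matrix-targeted, fused to GFP1-10) and
GFP carries the reconstituted split-GFP signal.  The chain is:

1. **z-sum projection.** Both channels are summed along z in a widened
   accumulator (int64 for integer stacks), so a 12-plane uint16 stack
   cannot overflow.  All downstream quantities are on the summed scale;
   a per-plane intensity v appears as v × n_planes.
2. **Background segmentation.** A seeded random walker runs on the sum of
   both projected channels, rescaled to [0, 1].  Seeds: pixels at or below
   the 25th percentile of the combined image are background, at or above
   the 90th percentile foreground (both configurable).  *Assumption:* the
   percentile rule presumes cells cover more than ~10% of the field;
   default synthetic scenes use ~15% coverage, typical of mid-log yeast
   fields.  A constant image returns all-background with a warning; if the
   two seed thresholds collide (heavily quantized or noise-free images) the
   code falls back to a global Otsu threshold, again with a warning.
   The solver is the exact sparse ("bf") mode: confocal fields are small
   enough that iterative-solver tolerance noise is not worth the speed.
3. **Cell separation.** Marker-controlled watershed on the inverted
   Gaussian-smoothed (σ = 2 px) combined intensity, masked to the
   foreground.  Markers are local maxima of the Euclidean distance
   transform (itself smoothed at σ = 1 px to break plateau ties at disc
   centres), separated by at least the expected cell radius (default
   12 px; set it to the actual radius of your optics/magnification).
   Labels are renumbered contiguously.  The segmentation channel is the
   *sum* of both projections, a deliberate choice: mCherry alone marks only
   mitochondria, not the cell outline, and the brightfield channel used for
   visual delineation is not part of the quantification inputs.
4. **Mitochondrial mask.** Per cell, pixels with mCherry z-sum ≥ 5% of
   that cell's maximum ("for each cell" — the maximum is per-cell, not
   per-image).  The fractional threshold makes the mask exactly invariant
   to any positive gain on the channel.  An empty mask or zero maximum
   flags the cell NO_MITO; it is excluded from summaries rather than
   producing an infinite ratio.
5. **Per-cell readout.** Median GFP z-sum over the mask (numpy median:
   mean of the two central values for even counts), the analogous mCherry
   median, and their ratio.  QC flags: BORDER (touches the image edge,
   excluded by default), TOO_SMALL (< 100 px by default), NO_MITO.
6. **Population summaries.** Arithmetic means over QC-passing cells;
   normalized spGFP is the condition mean divided by a named reference
   condition's mean (reference = 1).

## Screen calling

Stage 1 uses population-mean spGFP per strain before/after heat shock
(30 min, 42 °C), background-subtracted with a single plate-level scalar
(a designated parental-control well; the measurement protocol for this
background is not specified upstream, so it is a config input).  A strain
is a candidate iff fold = HS/baseline < 1.1 — strictly, so fold = 1.1 is
not a candidate.  Strains whose baseline signal is ≤ 0 after subtraction
cannot display an increase and are candidates-by-default, annotated
LOW_SIGNAL.

Stage 2 tests per-cell imaging statistics.  The test behind the published
per-cell P values is not stated; since two-tailed t-tests are used
throughout the source experiments, the default is Welch's two-sided t-test
(config-switchable to Mann–Whitney).  The before/after-heat-shock
comparison is unpaired: the cells imaged at the two time points are
different individuals.  No multiple-testing correction is applied by
default, matching per-strain thresholding; Benjamini–Hochberg is available
as an option.  Degenerate inputs are resolved explicitly: identical
constant samples give p = 1 (no evidence), constant samples with different
values give p = 0.

## Gating

The positivity threshold is the (1 − f) empirical quantile of the control
spGFP sample with "higher" interpolation, and positivity is strict (>).
For a sorted control x(1..n) the threshold is x(k) with
k = ⌈(1−f)(n−1)⌉ + 1 (1-based), so at most f·n control events can exceed
it — the ≤ f guarantee holds for every finite sample, including all-equal
degenerate controls (0% positive).  The calibration is per-replicate (the
upstream protocol does not say whether the 1% rule pooled controls; the
per-replicate choice is an assumption).  The TMRM-negative gate for
depolarization fractions is calibrated the same way on an untreated
control's TMRM distribution and supplied by config.  All condition
comparisons (e.g. mean TMRM of positives vs negatives) are made on
biological-replicate summaries with two-sided paired or Welch t-tests —
never on pooled single cells.

## Nucleocytoplasmic ratio

Per cell: Otsu threshold of the nuclear-marker intensities within the cell,
keep the largest connected component → nucleoplasmic mask; dilate with a
disc of radius 3 px (config; the radius used by the original upstream
macro is not published) and subtract the nucleus → cytoplasmic ring, clipped to the
cell; ratio = mean reporter in nucleus / mean in ring.  The ratio is
exactly invariant to multiplicative intensity changes.  Cells with a
constant marker, an empty ring, or non-positive cytoplasmic mean are
flagged and excluded.  No background subtraction by default (none is
described for this assay); a constant offset is available in config.

## Synthetic data: what it emulates, what it does not

The generators state a world once and the tests measure against it; none
of their defaults were tuned against test outcomes.

* **Scenes.** Non-overlapping ellipses (rejection sampling, ≤ 1000
  attempts per cell, then an error) with ≥ 1 px background gaps;
  mitochondria as 2–5 dilated random walks filling ~30% of the cell area;
  12 z-planes with constant per-plane intensities, so the z-sum of a
  mitochondrial pixel is exactly true_spGFP × 12; additive Gaussian noise
  (σ = 2 a.u.) clipped at zero, stored uint16.  True per-cell spGFP values
  are integers so the zero-noise uint16 round-trip is lossless — that is
  what makes the exact end-to-end recovery test meaningful.  Not modelled:
  PSF blur, bleaching, depth attenuation, mitochondrial 3-D structure,
  overlapping cells.  A green recovery test therefore establishes the
  correctness of the measurement chain, not robustness to optical
  artefacts.
* **Screen plates.** Per-cell spGFP ~ Normal(50, 15), mCherry ~
  Normal(100, 10), clipped at zero.  Planted effects: Class 1 multiplies
  the baseline spGFP mean by 2; wild-type/null strains multiply it by 1.5
  after heat shock; Class 2 strains by 1.0 (fold change exactly 1 <
  1.1 by construction).  Cell count defaults to 200 per strain-condition.
* **Flow events.** spGFP is a two-component log-normal mixture, log-means
  4.0 (negative) and 7.0 (positive), log-sd 0.5 — a ~20-fold separation
  typical of a well-behaved reporter; TMRM is log-normal (log-mean 5.0,
  log-sd 0.4) plus a signed shift on positive events.  No spillover or
  instrument drift is modelled, so gating tests certify the calibration
  arithmetic, not compensation.
* **Nucleocytoplasmic images.** Discs with concentric nuclei; reporter
  cytoplasm 100 a.u., nucleus 100 × true ratio, float arrays so the
  noise-free ratio is exact.

## Numerical and design notes

* Gain/scale invariances are mathematically exact; the property tests
  exercise them with power-of-two gains, for which float multiplication is
  also bit-exact.  Arbitrary gains can flip pixels lying exactly on the 5%
  boundary by one ulp.
* The null-plate type-I suite pairs 5,000 iid null strains into 2,500
  independent KO/WT comparisons.  Comparing every strain to one shared
  wild-type sample — as a real plate does — makes all calls on the plate
  conditionally dependent on the wild-type draw, and the Class 1 count is
  then over-dispersed relative to binomial; the paired design measures the
  test's actual level, which is the property of interest.
* Determinism: every generator takes an explicit seed and builds its own
  `numpy.random.Generator`; there is no hidden global state.  Pipeline CSV
  outputs are written with a fixed float format so reruns are
  byte-identical.
* FCS file ingestion is not included (no FCS parser in the supported
  dependency set); flow events are read from CSV with columns
  spgfp/mcherry/tmrm/condition_id/replicate_id.

## Known limitations

* 2-D quantification only (on the z-sum), by design; no 3-D segmentation,
  deconvolution, or mitochondrial morphology metrics.
* The percentile-seeded background segmentation degrades on sparse fields
  (< ~10% cell coverage); adjust `bg_percentile`/`fg_percentile` for such
  data.
* Watershed marker separation assumes roughly convex, similar-sized
  cells; heavily elongated or budding cells may split.
* Replicate-level tests assume approximate normality of replicate means;
  with n = 3 replicates power is limited and only large effects reach
  significance, mirroring the experimental design the pipeline serves.
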