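# Methods

`synaptoscreen` implements an automated high-content synaptic phenotyping
pipeline end to end: synthetic multi-channel fluorescence plates with planted
ground truth, per-field image quantification, plating quality control,
screen-level normalization and hit calling, and effect-size/power utilities.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic validation does and does not demonstrate.

## The assay being modelled

A 96-well co-culture assay of human induced neurons (hN) with primary
astrocytes, stained for a nuclear dye (DAPI), a dendrite marker (MAP2) and a
presynaptic marker (SYNAPSIN1). Only the 60 inner wells carry cultures. Each
well is imaged as 12 fields; each field is a 3-channel z-stack of 5–8 slices.
The assay readout is the **presynaptic density**: the number of presynaptic
puncta colocalized with the dendrite mask, divided by the dendrite mask area.
Screens express every metric as an intra-plate Z-score against two columns of
vehicle (0.1% DMSO) control wells.

## Synthetic fields (`simulate`)

The generator emulates the *structure* of such fields, not their optics:

- **Neurites** — smoothed random-walk polylines rasterized and dilated to
  `neurite_width` px (default 4), with a Gaussian cross-section profile.
  The dilated binary mask is the ground-truth neurite mask.
- **Puncta** — 2-D Gaussian spots whose FWHM equals the requested equivalent
  diameter (default range 2–4 px). On-neurite puncta are sampled uniformly
  from the mask, off-neurite from its complement; each planted punctum is
  recorded with its position, diameter and on/off flag.
- **Nuclei** — filled ellipses of two classes: neuronal (round, bright,
  default diameter 16 px) and astrocytic (elongated 1.3:0.7, dimmer, default
  22 px). Each neuronal nucleus carries a dendrite-channel soma: a Gaussian
  radial profile attenuated ×0.25 inside the nucleus, reflecting the
  cytoplasmic localization of the dendrite marker. This nuclear "shadow"
  gives the nuclear and dendrite channels the sharp common edge that makes
  cross-channel registration well-posed, as it is in real data.
- **Bleed-through** — 8% of the nuclear signal leaks into the dendrite
  channel (`nuclear_bleedthrough`), emulating common spectral crosstalk; it
  travels with the dendrite acquisition and is therefore subject to the same
  channel shift.
- **z-structure** — every object is assigned one focal slice; other slices
  see it blurred by `defocus_per_slice × |Δz|` (default 1.2 px/slice), so
  maximum projection is meaningful.
- **Artifacts** — integer channel shifts applied to both non-reference
  channels, a multiplicative gain plane `a + b·y + c·x`, and an optional
  radial vignette.
- **Noise** — Poisson shot noise on the signal plus additive Gaussian read
  noise (default σ = 5 on a background of 100), the standard fluorescence
  camera model.

Defaults: 256×256 px fields at 0.6 µm/px (so a 0.4–1.6 µm² punctum footprint
is roughly 1–3 px), 5 slices, 60 on-neurite and 15 off-neurite puncta, 8
neuronal and 12 astrocytic nuclei per field. 60 on-neurite puncta over a
~6,000-px neurite mask gives a realistic moderate density at which puncta
rarely collide; much denser fields under-count because touching puncta merge,
exactly as in the real assay.

Determinism: a field is a pure function of `(FieldSpec, ArtifactSpec)`. Plate
generation derives each field's seed from the top-level seed and the (well,
field) position, so plates stream lazily and any field can be regenerated
independently. Per-well treatment effects multiply the planted on-neurite
count (density multiplier) and the nuclei counts (viability multiplier);
control wells must carry multiplier 1.

A separate table-level generator (`simulate_field_records`) emulates the
field *measurement table* directly — Normal neurite areas with a 4% rate of
gross outlier fields (0.2× or 2.5×), Poisson puncta and nuclei counts — for
exercising the screen-analytics layer at multi-plate scale, where rendering
hundreds of image fields per condition would add nothing to what is tested.

**What passing tests show** — that the measurement pipeline recovers planted
object counts, shifts and density gradients, and that the normalization
machinery has the stated identities. **What they do not show** — performance
on real optics (PSF structure, autofluorescence, staining variability,
out-of-focus wells); no claim is made that detection thresholds calibrated on
the simulator transfer to a microscope without re-tuning.

## Field quantification (`pipeline`)

Processing order: project → align → illumination-correct → rescale →
enhance/segment. Coordinates are 0-based (y, x); areas are in pixels; no
physical-unit conversion happens inside the pipeline.

1. **Maximum projection** per channel: `out[y,x] = max_z in[z,y,x]`.
2. **Alignment** — exhaustive integer-translation search (default ±10 px)
   maximizing the mutual information of the nuclear and dendrite projections;
   the winning translation is applied to the dendrite *and* presynaptic
   planes. MI is computed on 64-bin joint histograms over a fixed central
   crop (a shrinking-overlap MI is biased upward at large shifts), after
   Gaussian pre-smoothing with σ = 1 px to suppress pixel noise in the joint
   histogram. Ties break toward the smaller shift magnitude, then
   lexicographically; a constant plane yields offset (0, 0) with a warning
   flag.
3. **Illumination correction** — per channel, the per-pixel mean of all the
   plate's projected fields, smoothed with a large Gaussian filter (extent
   100 px; σ = extent/4 so ±2σ spans the declared size), normalized to mean
   1; correction is division by this surface.
4. **Rescale** — affine stretch of each plane to [0, 1]; constant planes map
   to zeros.
5. **Neurite segmentation** — tubeness enhancement (Sato Hessian ridge
   filter at scale σ = 2 px, followed by a white tophat to suppress residual
   background), then three-class Otsu thresholding on a 256-bin histogram;
   the mask is the union of the middle and upper classes by default
   (`neurite_foreground="upper"` keeps only the top class). Fewer than three
   distinct values falls back to two-class Otsu with a warning.
6. **Puncta detection** — white tophat *by reconstruction* with a disk of
   radius 4 px (just above the maximum valid punctum radius of 3 px):
   structures that can contain the disk are removed entirely, leaving no rim
   residues around large objects. Two-class Otsu binarizes the enhanced
   image, subject to a robust noise floor (median + 6·MAD·1.4826): after
   full-range rescaling a blank field would otherwise have its noise
   stretched to [0, 1] and Otsu would "find" speckle, so the floor is what
   makes the empty field yield zero puncta. Touching puncta are split by a
   watershed on the inverted intensity seeded at local maxima with ≥ 2 px
   separation (ties toward higher intensity, then smaller (y, x)). Objects
   with equivalent diameter 2·√(area/π) outside [1, 6] px are discarded.
7. **Colocalization** — a punctum is on-neurite iff its pixel set overlaps
   the neurite mask in ≥ 1 pixel (contained *or* partly touching). The
   on-neurite count is monotone in the mask by construction.
8. **Measurements** — per field: neurite area (px), on-neurite puncta count,
   nuclei count, and total area of all retained puncta. Written as one CSV
   row with the `AreaOccupied_…`/`Count_…` column names.

Whether illumination correction belongs before or after alignment is not
dictated by anything structural; the declared order (align first) was chosen
because the correction surfaces are built from unaligned projections either
way and division by a smooth surface barely perturbs the MI argmax.

## Plating QC (`plating`)

Nucleus detection approximates a proprietary diameter-gated detector with
standard components: Gaussian smoothing (σ = 2), two-class Otsu, and a
seeded watershed on the distance transform; objects with equivalent diameter
below 20 µm (converted via the pixel size) are discarded. Because only the
diameter criterion of the original detector is public, this detector is
judged by planted-truth recovery, not algorithmic identity.

Neuronal-vs-astrocytic classification is rule-based: a nucleus is neuronal
iff it passes all gates — mean intensity ≥ 0.33 and contrast ≥ 0.85 (both on
[0, 1]-rescaled planes; contrast is the relative excess over the sub-threshold
background median), area within 100–900 px, roundness (4πA/P², clipped to 1)
≥ 0.70, and a dendrite-positive soma: mean dendrite intensity ≥ 0.16 in a
3-px perinuclear annulus. Gate defaults were calibrated once on the
simulator's two nucleus classes; the soma and contrast gates carry most of
the separation.

Plate verdict: with per-well neuronal counts, covariance% = 100·SD/mean
(sample SD, n−1). A plate passes iff every well count lies inside
[4,000, 12,000] *and* covariance < 8%. The band strictness is configurable
(`band_fraction`, default 1.0 = every well) for screens that tolerate
isolated outlier wells. A zero mean is a degenerate failure. Note the
plating check images a different acquisition (fewer slices, more fields per
well) than the synapse assay; counts are reported per sampled area, and no
extrapolation to whole-well counts is attempted.

## Screen analytics (`analytics`)

Three QC filters, applied in order and equivalent to a single-pass
implementation of both rules (tested):

1. fields with neurite area outside mean ± SD of all fields in scope
   (batch-wide by default, per-plate optional; bounds inclusive) are removed;
2. wells with fewer than 5 surviving fields are excluded;
3. conditions with fewer than 2 surviving wells (of nominally 3) are flagged
   `qc_fail` but still reported.

Aggregation uses arithmetic means at both field→well and well→condition
levels; per-well density = mean count / mean area. Percent-of-control and
Z-scores are intra-plate: the control statistics are the mean and sample SD
(n−1) of the plate's surviving vehicle wells; control wells are scored too,
so their per-plate mean Z is identically 0. Plates with no usable controls,
zero control SD, or zero control mean are QC failures. Z-scores are invariant
under any per-plate affine rescaling x → a·x + b (a > 0) of a metric.

**Pattern correction** (off by default, an explicit approximation of
proprietary screening-software behaviour): the elementwise median across
vehicle-only observations — all wells of sentinel plates plus the control
wells of assay plates — is decomposed by NaN-tolerant two-way median polish
into additive row and column effects, which are subtracted from every well.
Because the pattern is estimated from vehicle wells only, a true single-well
treatment effect cannot enter it and survives correction.

**Hit calling** (condition level, configurable): `toxic` iff
z_density ≤ −3 AND z_map2 ≤ −2 — both conjuncts required, so a density drop
without neurite loss is not called toxic; `enhancer_candidate` iff
z_density ≥ +2 and z_map2 > −2. The enhancer threshold is this package's
declared default (+2): screens typically select positives from the ranked
Z-score distribution rather than a printed cutoff. `library_fractions`
reports per-class percentages of the library size, rounded to 2 decimals.

Open choices resolved here: the hit rule is evaluated at condition level
(a `min_wells_per_condition` switch allows well-level studies); control
statistics are plain in-sample (no leave-one-out when scoring control wells
themselves).

## Power (`power`)

Cohen's d uses the pooled SD,
s_p² = ((n_t−1)s_t² + (n_c−1)s_c²)/(n_t+n_c−2), direction treated − control.
Power uses the one-sample normal (z) approximation — the convention of the
standard `pwr.norm.test`-style routine, not a t-test:
power(greater) = Φ(√n·d − z₁₋α). The required-n solver inverts this in
closed form, n = ((z₁₋α + z_power)/d)², and reports both the continuous
solution (authoritative) and its nearest integer. At α = 0.05 one-sided and
95% power this gives 270.55 replicates at d = 0.2, 43.29 at d = 0.5 and
16.91 at d = 0.8. The Monte-Carlo agreement check (±0.01 at 20,000
replicates) is a test, not a feature.

## Problem sizes used in validation

The test suite runs scaled-down instances chosen to exercise every code
path: 192-px fields at 3 fields/well for the whole-plate recovery test
(Spearman ρ ≥ 0.9 against planted density), 50 fixed-seed trials for shift
recovery, and table-level screens of 8–11 plates for the normalization and
hit-calling properties. `scripts/acceptance.py` runs the full 60-well ×
12-field plate. Rank correlation is insensitive to the per-well field count
beyond ~3 fields because the planted multipliers span a 4× range.

## Known limitations

- No optical PSF model, no 3-D segmentation, no spectral unmixing; at most
  3 channels.
- The nucleus detector and neuronal classifier approximate proprietary
  tools; their gates are simulator-calibrated defaults, not transferable
  constants.
- Pattern correction reconstructs a named but unpublished algorithm as
  median polish; it is off by default and labelled an approximation.
- The z-approximation power model ignores variance estimation error (no
  t-correction) and multiple testing.
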