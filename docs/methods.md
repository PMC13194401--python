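# Methods

This note documents the models, parameters, and numerical choices behind
`organoidhci`: what the pipeline computes, what the synthetic plate
generator emulates, and where the declared defaults come from.

## The assay being quantified

Two high-content-imaging co-culture formats are covered:

* **Reconstituted co-culture** — patient-derived organoids embedded in a
  collagen/laminin hydrogel in 384-well plates together with immune effector
  cells (PBMCs, typically cell-tracker labeled, at a 5:1–10:1
  effector-to-target ratio), in quadruplicate technical replicates.
* ***Ex vivo* patient tissue (EVPT)** — minimally processed fresh tumor
  resections: a heterogeneous mix of 50–300 multicellular tumor clusters
  (tumoroids) >50 µm and <200 µm in diameter plus single cells, seeded per
  well with the autologous microenvironment, in octuplicate replicates.

Each well is imaged as one z-stack per fluorescence channel (nuclei, actin,
optional cell tracker) at low magnification: 20–80 sections, 20–50 µm
z-step. The readouts are tumoroid (total and per-object) volume, object
count, single-cell count, and immune-cell infiltration, normalized per
plate to control wells.

## Object definition and segmentation

The platform's operational object definition is: a **multicellular object**
is a connected actin-cytoskeleton structure containing nuclei. This package
operationalizes it as a fixed classical pipeline, every threshold exposed in
`RunConfig`:

1. Gaussian smoothing with a *physical* sigma (default 3.4 µm) divided by
   the per-axis voxel spacing — at 20–50 µm z-steps, isotropic voxel-space
   filtering would smear the axial dimension by an order of magnitude.
2. Global Otsu threshold on the smoothed actin channel. A contrast guard
   (foreground median must exceed background by 4 robust SD) keeps Otsu from
   splitting pure noise on empty wells.
3. Morphological closing (default radius 7 µm, anisotropic structuring
   element), per-slice hole filling, 26-connected 3D components.
4. Debris filter: components smaller than a 15 µm sphere are discarded.

Nuclei and tracker-labeled cells are detected as local maxima of the
smoothed channel above a global threshold, with a minimum separation of one
cell diameter (nuclei 10 µm; tracker 8 µm — tracker dyes mark small
lymphocytes, which pack tighter than epithelial nuclei). Two points closer
than the separation merge into one detection; this is the resolution limit
of the detector, and it matters for infiltration (below).

A component is **multicellular** iff its equivalent diameter is at least
30 µm *and* it contains ≥2 nucleus centroids. The platform restricts single
cells by a maximum object size; the actual cut-off value is not published,
so 30 µm is a declared default, not a reproduced one. A large component
with one nucleus is a single cell (the nucleus rule dominates). Every
nucleus is assigned exactly once: |single cells| + Σ(nuclei in
multicellular objects) = |nuclei| holds exactly by construction.

Touching tumoroids that merge after closing are reported as one object; no
watershed splitting is attempted (a documented limitation of the baseline).

## Morphometry

Reported object size is the cumulative segmented area through the stack:

    volume = Σ_z area(z) × z_step  (µm³),

which on a voxel grid equals voxel count × voxel volume. This makes the
0.01 mm³ control-window threshold dimensionally meaningful; per-slice areas
are retained for area-based reporting. The equivalent diameter is
(6V/π)^(1/3). Whether the original platform's "volume" is voxel-count or
area×z-step based is not published; both coincide here by construction.

**Infiltration** counts tracker-labeled cells whose detected centroid voxel
lies inside a multicellular object's mask (centroid-in-mask; cheap,
unambiguous, and matching the "present within a multicellular object"
definition). At labeled-cell densities where the within-object spacing
approaches the ~10 µm detection resolution (e.g. E:T 5–10 with high
infiltration), merged detections systematically *undercount* the infiltrated
fraction; ratios normalized between conditions remain comparable because
both sides are attenuated alike. Recovery tests therefore run at densities
the detector can resolve.

## Quality gates

* **Control window** (per control well, thresholds inclusive):
  object_count ≥ 50 AND total volume ≥ 0.01 mm³. A sample's verdict fails
  when more than half of its control wells fail (the published gate is
  stated per well and per sample; the aggregation fraction is a
  configurable choice).
* **Image quality** (actin channel): overgrowth/debris when the median
  intensity sits far above the darkest 5% of voxels or the foreground
  fraction exceeds 0.5; empty/low-label when the foreground fraction falls
  below 1e-4 or the foreground-to-background intensity ratio below 2; and a
  segmentation-coverage check (≥80% of bright voxels inside labels) so the
  segmentation "represents the input".
* **Exclusion fraction** counts wells lost to image-quality or analysis
  errors — the "well error" rate, expected <4% on a healthy plate.
  Control-window failures are an assay-window verdict driving per-sample
  decisions, not a well error, and are reported separately.
* **Replicate precision**: CV = sample SD (n−1) / mean, per replicate
  group. The published criterion (<0.35) describes the reconstituted
  format's quadruplicates.
* **Edge effect**: two-sided Wilcoxon rank-sum of edge vs interior control
  volumes; flagged only when p < 0.01 *and* the median ratio leaves
  [0.8, 1.25]. The published pipeline states the check but not the method;
  this test and its cutoffs are this package's choice, both configurable.

## Normalization and statistics

Per-well percent-of-control: poc = 100 × value / mean(passing control
wells of the same sample). The mean (not median) denominator makes the
control group's mean poc exactly 100; a median alternative is configurable.
Replicate summaries follow the per-readout convention: median for total
volume and object count (robust to a single bad well), mean for
single-cell count and infiltration. Volume reduction = 100 − poc is binned
into response categories with half-open bins:

    <10 non-responder | [10,31) "10-30" | [31,51) "31-50" | [51,71) "51-70" | ≥71 ">71"

The printed category labels leave (30,31) etc. undefined on continuous
values; half-open bins at 31/51/71 with a responder floor of 10 preserve
the labels while covering the whole real line.

Group comparisons are fixed-effects ANOVA on well-level poc (one-way, or
two-way with interaction via statsmodels), followed by all-pairs Tukey HSD
(studentized range) or many-to-one Dunnett against a named reference, with
significance stars at 0.05/0.01/0.005/0.0001. Dunnett's multivariate-t
integration is quasi-random; a fixed internal rng keeps repeated runs
byte-identical. No additional FDR layer is applied.

## Synthetic plate generator

The generator is first-class, tested code: it defines the study conditions
under which everything else is validated, standing in for patient material
that has no public deposition.

**Geometry** (all µm, resolution-independent): tumoroids are non-overlapping
spheres placed by rejection sampling (largest first, 20 µm minimum surface
gap) in a 2000×2000×750 µm field; diameters are log-normal truncated to the
seeding window — right-skewed sizes typical of organoid cultures. Resident
nuclei are placed at one cell per (18 µm)³ with approximate blue-noise
spacing; free single cells and labeled immune cells are uniform outside
tumoroid interiors.

* EVPT preset: per-well counts uniform on [50, 300], diameters in (50, 200),
  label-free (autologous immune cells carry no tracker dye).
* Reconstituted preset: Poisson counts (mean 150), diameters in (40, 150)
  (size-filtered organoids), tracker-labeled cells at a configurable E:T
  ratio. Poisson seeding is the physical model for robotic aliquoting from
  one suspension and is what gives quadruplicates their observed low CV; a
  uniform [50,300] per-well count would by itself impose a ~0.42 CV across
  technical replicates, contradicting the format's measured precision.

When a whole plate is simulated from the across-sample "uniform" window,
one seeding density per *sample* is drawn from the window and its wells
scatter around it with Poisson counting statistics — wells of one sample
are aliquots of one suspension; the 50–300 range expresses sample-to-sample
tissue richness, not well-to-well noise.

**Effects** act on ground truth: volumes scale by (1−f) (diameters by the
cube root), a Bernoulli subset of tumoroids is removed (nested across loss
fractions, so total volume is monotone in the fraction), labeled cells are
infiltrated with probability `infiltration_rate` (uniformly inside a
volume-weighted host), and the single-cell count grows by the fractional
`single_cell_growth_factor` (0 = identity). The labeled-cell count is fixed
by E:T × the *pre-effect* resident-cell estimate — the immune input is
pipetted before any killing happens. The all-zero effect reproduces the
control scene bit-for-bit at a fixed seed.

**Rendering**: nuclei/tracker channels deposit per-cell intensities at the
nearest voxel and apply one Gaussian blur (σ 4 µm lateral, 6 µm axial);
actin renders soft-edged filled spheres plus thin shells around free single
cells. Noise is the standard first-order camera model: constant background
(100 counts) + Poisson shot noise + Gaussian read noise (SD 5). The default
calibration is 3.4 µm/pixel, 25 µm z-step (the low-magnification pixel size
is not published; 3.4 µm is a plausible 4× binned value and keeps a well at
~588×588×30 voxels). All outputs are pure functions of (parameters, seed);
per-well seeds are CRC-derived from (master seed, well id).

**What the generator does not emulate**: optics (no PSF, no depth
attenuation), stroma/fibroblast channels, irregular tumoroid shapes, gel
meniscus artifacts, staining gradients. Passing recovery tests therefore
demonstrate correctness of the measurement chain on geometrically ideal
data, not robustness to every real-world artifact — which is exactly what
a ground-truth benchmark can and should show.

## Problem sizes

Plate-scale runs (the acceptance script, plate-level tests) use a coarser
"survey" calibration of the same physical field — 8 µm/pixel, 37.5 µm
z-step, 250×250×20 voxels per channel — chosen so a full 260-well plate
analyzes in minutes on one core while object counts stay within a few
percent of truth. Per-object precision tests use the default fine
calibration on smaller fields. The acceptance script simulates five
260-well EVPT plates (1300 wells) for the exclusion rate, twenty
independent reconstituted quadruplicate groups (80 wells) for replicate
CV, and 100 EVPT scenes for the generator's seeding window.

## Known limitations

* Fused tumoroids are counted once (no splitting); dense nucleus packings
  are undercounted by design — per-object nucleus counts are a lower bound.
* Infiltration saturates at high labeled-cell density (see above).
* Otsu thresholds assume a bimodal histogram; extremely sparse or
  saturated wells are handled by the QC gates rather than the segmenter.
* The EVPT single-cell fraction includes nuclei on tumoroid rims whose
  centroid voxel falls outside the actin mask; the partition identity still
  holds, but the single-cell count is a proxy, not a cell-type call.
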