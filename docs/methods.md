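# Methods

This note documents the models and procedures implemented in `ventra`,
the parameter defaults and why they were chosen, what the synthetic
data generator does and does not emulate, and the numerical conventions
that make results reproducible.

## Coordinate conventions

World space is RAS millimetres (+x right, +y anterior, +z superior).
Volumes read from disk are reoriented to canonical RAS axis order;
reorientation permutes and flips the voxel grid while updating the
affine, so world-space geometry is unchanged.  Voxel indices are
0-based and refer to voxel centres.  The stereotaxic template's origin
sits at the anterior-commissure-like centre of the synthetic template,
which anchors the anterior/posterior boundary plane at world
y = −12 mm.  A voxel is *anterior* iff its centre has y > −12 mm; the
plane itself belongs to the posterior part (a fixed, arbitrary
tie-break chosen for determinism).

## Intensity normalisation

Images are corrected for a smooth multiplicative bias field and
rescaled before any comparison across subjects:

1. A polynomial of degree ≤ 2 in normalised voxel coordinates is fit to
   log-intensities of head voxels (above 25% of the robust intensity
   range).  The fitted modulation (mean-removed) is divided out.  The
   correction is clamped to the range observed over the fitted voxels:
   an unclamped polynomial extrapolates without bound outside the head
   and would blow background noise into the rescaling percentiles.
2. Intensities are clamped at the 0.1 / 99.9 percentiles and mapped
   linearly to [0, 100], making downstream stages invariant to global
   intensity scaling.

Smooth anatomy (the grey/white radial structure) partially leaks into
the polynomial fit.  This flattens tissue contrast slightly but
identically for scans of the same anatomy, which is what the
segmentation and repeatability behaviour depend on.  Constant images
are rejected as degenerate.

## Affine registration

Registration maximises normalised cross-correlation (NCC) between the
template and the transformed moving image over a 6 (rigid), 9
(rigid + per-axis scale) or 12 (full affine) parameter transform;
default 12.  Numerical choices:

- Multiresolution pyramid, default 3 levels (smoothing + sampling
  factors 4, 2, 1); at full resolution the metric samples every second
  voxel.  Metric samples are restricted to the template head region
  dilated by 3 voxels — far-background voxels carry no alignment
  information, and including them measurably biases and flattens the
  metric (in development this was the difference between millimetre-
  and sub-decimillimetre recovery).
- Powell search in scaled coordinates (1 unit ≈ 1 mm of motion at the
  head radius: translations in mm, rotations/log-scales/shears scaled
  by 0.02), initialised by centre-of-mass alignment, with loose bounds
  and convergence tolerance 1e−5 on the metric; deterministic
  throughout.  Non-convergence at the finest level returns the
  best-found transform flagged `low_confidence`.
- Intensities are resampled trilinearly, labels by nearest neighbour.

On identical anatomy, known rigid+scale perturbations within the
generator's range are recovered to ~0.01 mm and ~0.2% volume scale.
When the subject's ventricles differ from the template's, the NCC
optimum legitimately absorbs a small part of that anatomy difference
into the affine (sub-millimetre, <1% scale at the default effect
sizes); this is inherent to affine stereotaxic normalisation, not an
optimiser artefact.

## Intracranial volume

Subject ICV = (template ICV mask volume) / |det| of the native→template
linear map.  This is exactly homogeneous in the transform scale and
requires no native-space skull stripping; ventricular volumes divided
by this ICV equal the corresponding native-space ratios.

## Patch-based label fusion

For each voxel x in the candidate region (union of library labels
dilated by a ball of radius 3 voxels):

1. collect library patches centred within the search window;
2. discard patches whose luminance-contrast structural similarity to
   the target patch is below 0.95 (SSIM luminance × contrast terms with
   the standard stabilising constants on the [0, 100] range);
3. weight survivors by w_i = exp(−d_i/h²), d_i the squared intensity
   distance, h² = min_i d_i + ε (ε = 1e−4) — the adaptive bandwidth
   makes the best-matching patch dominate;
4. fused vote v(x) = Σ w_i l_i / Σ w_i over the centre labels l_i;
   output label = [v(x) ≥ 0.5], ties counting foreground; v is returned
   as a confidence map.

If every patch at a voxel fails preselection, the vote falls back to
the unweighted mean of the (unfiltered) window centre labels.  Search
windows are clipped at the volume boundary — centres outside the
volume contribute no patch — while patches straddling the boundary
read zeros.  Defaults (3³ patches, 9³ windows, σ = 0.95) follow the
standard non-local label fusion design; all are exposed in
`FusionParams`.

The production implementation vectorises over voxels and skips patch
arithmetic wherever every window centre label of every entry agrees
(the convex vote of identical labels is that label, for any positive
weights, including the fallback path).  The test suite pins the
implementation voxel-for-voxel to an independent brute-force triple
loop on small instances.

Library images are passed through the same synthesis and resampling
chain as test subjects, mimicking a curated library whose scans were
preprocessed like the inputs; their labels are the generator's
template-space truth masks, standing in for expert manual
segmentations.

## Features and QC

Compartment volumes come from intersecting the segmentation with an
eight-compartment lobar atlas (frontal/parietal/temporal/occipital ×
left/right); segmentation voxels on atlas background are assigned to
the nearest coded compartment in world mm, so compartment volumes sum
exactly to the total.  The classifier features are
(ln APR, total/ICV, ln(L frontal / R frontal),
ln(L temporal / R temporal), age, sex[male=1]); ratios are
log-transformed, the normalised total volume is not.  Zero
denominators (posterior, right frontal, right temporal) raise an
undefined-feature error and the subject is reported as `QC_FAIL`.

Automated QC replaces visual rating with four explicit, configurable
checks: Dice against the template ventricle prior ≥ 0.3; total volume
in [5 000, 250 000] mm³; at most 4 six-connected components of ≥ 50
voxels; posterior, right-frontal and right-temporal compartments
non-empty.

## Classifier

A soft-margin linear SVM on z-scored features (squared hinge,
deterministic primal solver).  The penalty is applied per sample
(C/n), making the fitted boundary invariant under uniform duplication
of the dataset; C defaults to 1.  Inverse-frequency class weights are
on by default because realistic validation cohorts are heavily
imbalanced.  The decision is sign(w·z + b) with ties counting
positive.  Models serialise to a versioned, human-readable text format;
prediction is computed from the serialised numbers, so save/load
round-trips are bit-exact.  A seed-pinned reference model trained on a
synthetic cohort ships with the package as the default for `run`;
numerical parity with any externally trained ventricular-feature
classifier is out of scope.

## Evaluation

Confusion-matrix metrics follow the standard definitions;
LR+ = sens/(1−spec) is reported as ∞ (flagged, not an error) when there
are no false positives; Dice of two empty masks is defined as 1
(agreement on absence).  Group comparisons use Welch's unequal-variance
t-test by default (a pooled option exists) with Bonferroni adjustment
p_adj = min(1, m·p).  The misclassification report contrasts TP-vs-FN
and FP-vs-TN strata feature by feature, skipping strata with fewer than
two subjects in a cell.

## Synthetic data

The generator builds geometric head phantoms on a 96³ grid at 1 mm: an
ellipsoidal intracranial cavity (semi-axes 32 × 42 × 32 mm, ~180 cm³ —
a scaled-down head that keeps run times desk-sized) with a grey-matter
shell and white-matter core (means 50 / 70; CSF 10), and lateral
ventricles composed of a body plus frontal, temporal and occipital
horns per hemisphere, mirror-symmetric about x = 0.  The frontal-horn
size constant is calibrated once so the neutral phantom's APR is 1.00
(|ln APR| < 0.01 at 1 mm voxelisation).  Shape factors scale horn
volumes: `apr_factor` (anterior), `lr_frontal_factor`,
`lr_temporal_factor` (left hemisphere), `total_scale` (global).
Factors are clipped to ranges that keep the ventricles inside the
cavity; beyond them generation raises an error.

Acquisition effects: Gaussian noise (sd 2 on the [0, 100] scale), a
random degree-2 multiplicative bias (±15%), a grey/white contrast
multiplier (drawn U(0.85, 1.15) per subject) emulating scanner and
field-strength variation, and a random rigid+scale transform to
"native" space (±3 mm, ±4°, per-axis scale 0.95–1.05).  A rescan keeps
anatomy and native geometry and redraws contrast and noise.  Everything
is seeded and bit-reproducible.

Cohort defaults encode the group contrasts the tool is meant to
detect: bvFTD-like `apr_factor` ~ N(1.30, 0.15), `total_scale`
~ N(1.3, 0.1), age ~ N(63, 8); psychiatric-like N(1.00, 0.15),
N(1.0, 0.1), age ~ N(69, 10); sex ratio 0.5.  These echo the
feature-separation and age structure reported for real bvFTD versus
primary-psychiatric cohorts and give a Bayes error well below 0.15, so
a correctly implemented pipeline should reach sensitivity and
specificity ≥ 0.75 on held-out cohorts; they are configuration, not
claims of anatomical realism.

**What passing tests do and do not show.**  Phantoms are smooth
ellipsoid assemblies with a single bias/noise/contrast model; they
exercise the pipeline's mathematics — geometry, interpolation,
weighting, arithmetic, determinism — not its robustness to real MRI
(gyral anatomy, partial-volume mixtures at thin horns, motion,
pathology other than the modelled shape factors).  Dice ≈ 0.97 on
phantoms is an upper bound, not a clinical claim; the scan-rescan
experiment is a desk-scale analogue of multi-field-strength
repeatability, not a reproduction of it.

## Benchmark problem sizes

The packaged experiments use sizes chosen to keep a full run on one
CPU in the ten-minute range while leaving the conclusions stable across
seeds: 10 phantoms (plus 10 rescans) for segmentation quality and
repeatability; 200 subjects per group, with an independent
equally-sized test cohort, for classifier recovery (feature-level,
bypassing image synthesis, so the classifier is measured in isolation);
4 perturbation draws for registration recovery; a 3-subject cohort run
twice for the determinism check.

## Known limitations

- Affine-only normalisation: no deformable registration, and the ICV
  estimate inherits any scale absorbed from anatomy differences.
- The anterior/posterior plane and the atlas partition are fixed
  world-coordinate rules; on real data both would be inherited from a
  curated template and atlas.
- The temporal-horn left/right ratio is diluted by ventricle-body
  voxels that fall in temporal atlas territory; it tracks asymmetry
  directionally but attenuated.
- Binary classification only; no probability calibration, ROC analysis
  or confidence intervals.
- Single 3D T1-like contrast; no DICOM, 4D or multi-echo input.
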