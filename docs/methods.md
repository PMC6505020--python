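# Methods

## The quantification problem

Dopamine-transporter (DAT) SPECT with I-123-FP-CIT images the integrity of
the nigrostriatal pathway. Semi-quantification estimates the
non-displaceable binding potential BPnd = Cs/Cnd (specific over
non-displaceable tracer concentration at equilibrium) from a single static
scan. Two estimators are implemented:

* **SBR** (specific binding ratio): `SBR = (C − CR) / CR`, where `C` is the
  mean count concentration over an anatomical striatal ROI and `CR` the
  reference estimate of non-displaceable concentration. Because SPECT
  resolution (8–14 mm FWHM) is comparable to striatal dimensions, `C` is
  strongly reduced by partial-volume effects, and the reduction depends on
  camera resolution and striatum size.
* **SUSI** (specific uptake size index): `SUSI = (T − CR·V) / CR`, with `T`
  the total counts in a *large* ROI around the structure times the voxel
  volume and `V` the large-ROI volume. Since an activity-conserving
  reconstruction only displaces counts, a sufficiently large ROI collects
  them all and the SUSI is independent of resolution. The SUSI has units of
  volume (mL): on an ideal image, `SUSI = BPnd × Vs` with `Vs` the true
  structure volume, hence `SBR = SUSI / Vs`.

`CR` is the 75th percentile of voxel intensities in a reference region
(whole brain without striata, thalamus, brainstem). Percentiles interpolate
linearly between order statistics at fractional index `q·(n−1)`; this
convention is pinned because CR feeds every measure and must be bit-stable.
The relative IQR, `(P75 − P25)/P75` of the reference voxels, serves as an
uncertainty proxy for CR.

A consequence worth stating explicitly: a relative error ε in CR perturbs
the SUSI by roughly `ε · (SUSI + V)/SUSI`, which for `V ≈ 35 mL` per
structure is several times ε. The SUSI buys resolution independence at the
price of amplified sensitivity to reference-estimate errors — this
trade-off is what the reference-variability analyses probe.

## Digital striatal phantoms

No public image data is desk-usable for this design, so the package ships a
phantom generator with exact ground truth.

**Geometry.** Caudate and putamen are ellipsoids placed symmetrically about
the midline (putamen lateral and elongated anterior–posterior, caudate
superior-medial), each realized on the voxel grid by taking the `k` voxels
of smallest normalized ellipsoid radius, `k = round(V/voxel volume)` — so
realized volumes match targets within one voxel and masks of different
volumes are nested. The putamen is split into anterior/posterior halves by
the coronal plane through its centroid. The brain is an ellipsoidal
envelope (semi-axes 64 × 78 × 58 mm, ≈1.21 L); thalamus and brainstem are
box stand-ins used only to carve the reference region. Users with real
atlas masks can supply their own label volumes instead.

**Signal model.** Tissue concentration is piecewise constant: background
`Cnd` inside the brain, `(1 + BPnd)·Cnd` in each compartment, zero outside
the head. Voxel values are expected counts
(`concentration × voxel volume (mm³) × count_scale`); the default
`count_scale = 7.5` yields ≈60 counts per 2 mm voxel in the reference
region, giving a realistic relative IQR of ~0.15 from Poisson noise alone
before edge effects. Camera resolution is an isotropic Gaussian PSF applied
with a normalized truncated kernel (3.5 σ), so total counts are conserved
to better than 10⁻⁶ as long as the brain sits ≥3.5 σ inside the grid (the
default geometry guarantees this for FWHM ≤ 14 mm). Count noise is Poisson
per voxel, drawn after blurring; head misalignment is a rigid resampling
with trilinear interpolation. Reconstruction physics (projection,
attenuation, scatter) is out of scope: phantoms emulate *post-
reconstruction* images.

**ROI families.** Anatomical ROIs (for SBR) are the template-geometry
masks. Large ROIs (for SUSI) dilate each anatomical mask by a margin of
2 σ at the largest supported FWHM (≈12 mm, 6 voxels at 2 mm); contested
voxels go to the nearer structure so the large ROIs are disjoint. The large
putamen ROI is truncated at the putamen's anterior margin: the anatomical
putamen stays fully inside, but anterior spill-out falls to the large
caudate ROI, limiting caudate cross-talk in the putaminal SUSI (at 14 mm
FWHM this excludes a few percent of putaminal counts — the putaminal SUSI
is slightly resolution-dependent by construction, while the striatal union
captures everything). The margin width is a compromise measured during
design: a wider margin captures marginally more spill-out but consumes deep
brain tissue that the reference region needs — with too little deep
reference tissue the 75th percentile slides onto partially edge-dimmed
voxels and drifts with FWHM, which (amplified by the `(SUSI+V)/SUSI`
factor) destroys the SUSI's resolution independence.

**Cohorts.** Two settings are emulated. MONO: one camera, fixed 10 mm FWHM
(an 8 mm reconstruction postfilter plus intrinsic blur), native 3.9 mm
patient grid. MULTI: 24 sites, each drawing its FWHM once from
Uniform(8, 14) mm, subjects assigned round-robin, images on the standard
91×109×91, 2 mm template grid (multi-center studies distribute images
already normalized). Group distributions: controls have uniform striatal
BPnd ~ N(5.0, 0.6); disease subjects have a randomly-sided worse hemisphere
with posterior putamen BPnd ~ N(1.8, 0.7), anterior = 1.6 × posterior,
contralateral = 1.4 × the worse side, and caudate at 60% of the control
mean — the asymmetric, posterior-dominant pattern of nigrostriatal
degeneration. Volumes: putamen N(5.5, 0.7) mL/side, caudate
N(4.0, 0.5) mL/side, truncated at 0.5 mL. The disease effect size is a
calibration choice targeting hemisphere-minimum putaminal AUCs of
~0.95–0.98 at the emulated sample sizes (MONO 84/38, MULTI 438/207) —
the regime in which method differences are measurable; it was fixed once
during design and is exposed as configuration. An optional per-subject
global anatomy scale (SD 0, i.e. off, by default) makes head size vary so
that affine normalization has size variability to remove; it is used in the
patient-vs-template-space analyses.

Reproducibility: every subject's RNG stream is a child of the root seed
keyed by subject index (`SeedSequence(seed, spawn_key=(1, i))`), so cohorts
are bit-identical under a fixed config regardless of evaluation order.

## Stereotactical normalization

Transforms map template-space mm to patient-space mm; images are pushed to
template space with the inverse, masks pulled to patient space with the
forward transform (nearest-neighbour). Resampling interpolates
concentration trilinearly with *no Jacobian modulation* — concentration-
preserving normalization, which is what removes striatum-size variability
from the SUSI. Registration maximizes normalized cross-correlation
(intensity-scale invariant; the modality is the same on both sides) over a
rigid (6) or rigid+anisotropic-scale (9) parameterization, using Powell's
method on a smoothed multi-resolution pyramid (4× then 2× downsampling;
the full-resolution level is available but unnecessary — recovery accuracy
at the 2× level is ≈0.05 mm / 0.1°). All levels are smoothed at least
σ = 0.8 voxel: without this, Poisson noise biases the NCC optimum toward
half-voxel offsets (trilinear interpolation averages noise there), shifting
near-identity registrations by ~0.5 mm. The template is the voxelwise mean
of CR-scaled normal scans, so its own reference estimate is 1.

## Evaluation statistics

Orientation: reduced uptake is test-positive; subjects strictly below the
cutoff are positive, at-cutoff subjects negative. Scores are hemisphere
minima. AUC uses the Mann-Whitney rank formulation with ties counted ½;
CIs and paired comparisons use the DeLong structural-components
(co)variance; cutoffs maximize Youden's J with ties broken by accuracy,
then by classifying fewer subjects positive. The bootstrap of
`AUC_SUSI − AUC_SBR` resamples cases and controls separately (preserving
prevalence and within-subject pairing); the MULTI-vs-MONO comparison draws
10,000 independent pairs from the two bootstrap distributions and reports
the counted fraction with `diff_MULTI ≤ diff_MONO`, without continuity
correction. Group comparisons of the relative IQR use Welch's t test;
the 2×2 correctness analysis uses a two-way ANOVA with interaction
(Type-III sums of squares on effect coding, via statsmodels). No
multiple-testing adjustment is applied; p-values are reported unadjusted.
Youden cutoffs are fit in-sample, so accuracies carry the usual in-sample
optimism — deliberate, as the emulated design does the same.

The reference-variability study injects a spatially correlated
multiplicative field (Gaussian-smoothed, σ = 25 mm, per-subject amplitude
drawn from U(0.10, 0.40)) into the reference region of a random 30% subject
subset. Spatial correlation is essential: white voxel noise only *biases*
the 75th percentile (the reference averages ~10⁵ voxels, so the estimator
has negligible random error), the cohort cutoff adapts to a coherent bias,
and misclassification does not move. A correlated field reduces the
effective sample size to dozens of patches and gives CR a genuine,
amplitude-dependent random error — which is what raises misclassification
together with the relative IQR.

## Problem sizes and runtime choices

The replicate study of the primary hypothesis uses 20 MONO (84/38) + MULTI
(438/207, 24 sites) cohort pairs at the default grids, quantified in
template space without per-subject registration (the MULTI setting emulates
harmonized studies that distribute pre-normalized images; registration
accuracy is validated separately on 25 seeded misalignments). The cohort
renderer caches the blurred background per camera FWHM and blurs only the
striatal deltas on a padded crop (exact, by linearity of convolution), and
draws Poisson noise only on the support of positive expectation — a
Poisson with mean zero is deterministically zero, so this is
distributionally exact. DeLong CI calibration uses 500 null simulations at
n = 50/50; the reference-noise study 10 replicates of a 30/30 cohort.

## Numerical conventions

* World coordinates: mm, origin at the grid center, axes (x, y, z) =
  (right-left, posterior-anterior, inferior-superior); voxel indices
  0-based. NIfTI affines are diagonal with this origin.
* Percentiles: linear interpolation at `q·(n−1)` (see above).
* Interpolation: trilinear for intensities, nearest-neighbour for labels;
  out-of-field fill 0.
* Compartment voxel selection breaks radius ties by flat index order —
  deterministic, but left/right masks may differ by a thin boundary layer
  (<2% of voxels), so mirror symmetry holds to one voxel, not exactly.
* Volumes are float32; reductions (sums, means, percentiles) are float64.

## What the phantoms do and do not show

The generator reproduces the mechanisms the methodology depends on —
partial-volume loss and its camera dependence, spill-over between caudate
and putamen, reference contamination near the striata, Poisson counting
statistics, head misalignment, striatum-size variability — with exact
ground truth. It omits anatomical shape variability beyond global scale and
ellipsoid compartments, non-uniform background binding (white/grey matter
contrast), attenuation and scatter artifacts, reconstruction-specific noise
correlation, and patient motion during acquisition. Passing tests therefore
demonstrate correctness of the estimators and the claimed resolution/size/
reference trade-offs under the stated model, not clinical performance on
patient images; absolute AUCs are calibration-dependent by design.

## Known limitations

* The putaminal SUSI is deliberately not fully resolution-independent
  (anterior truncation); only the striatal union is.
* Registration is validated for same-modality template matching within
  ±10 mm / ±10°; larger misalignments may need a coarser pyramid level.
* The 2×2 ANOVA of relative IQR is frequently degenerate on clean cohorts
  (nobody misclassified in a cell); the pipeline reports `null` for it in
  that case rather than failing.
* `simulate` writes one NIfTI per subject; at paper-scale n this is
  gigabytes — `run_experiment` therefore defaults to metadata-only output
  (`write_volumes=False`).
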