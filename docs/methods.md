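# Methods

This note documents the measurement model, the statistical layer, the
synthetic generator and its calibration, and the numerical choices of
`face4d`. Every quantitative claim below is either a definition or is
verified by the test suite / acceptance script; nothing is asserted
from data the package does not compute.

## Measurement model

### Input contract

A recording is an ordered sequence of triangle meshes at a fixed frame
rate with *correspondence by index*: vertex `i` is the same material
point in every frame. All coordinates are millimetres. Five landmarks
are required as vertex indices: subnasale, cheilion right/left, labrale
superius/inferius. The upward normal of the horizontal anatomical
reference plane (Frankfort Horizontal) is supplied as recording
metadata, since it cannot be reconstructed from these five points.

### Clip trimming

All metrics are computed between the **last rest frame** and the
**first frame of maximum expression**. Both are located on the
activation trajectory a(t): the mean displacement of the expression's
two landmarks relative to frame 0, smoothed with a centred 3-frame
moving average.

Noise adaptivity: the noise SD of a(t) is estimated as
`1.4826 * median(|second differences|) / sqrt(6)` — on a smooth
trajectory, second differences are noise-dominated. The estimate is
taken on the pre-onset rest segment only (onset = first smoothed frame
at 5% of peak, minus two frames), because the motion ramp would inflate
a whole-trajectory estimate.

* **End rule**: the first frame whose smoothed activation reaches
  `peak_fraction * max − 3σ̂`, then advanced to the first local maximum
  of the raw activation. The default `peak_fraction = 0.995` was chosen
  (together with the local-maximum advance) so that smooth ramps with
  zero end-slope — e.g. the generator's cubic ease — are timed to the
  correct frame; a lower threshold such as 0.98 systematically fires
  ~2–3 frames early on such profiles, because a cubic ease crosses 98%
  of its range at ~89% of the ramp duration.
* **Start rule**: when the rest segment is exactly noise-free (σ̂ = 0
  and exactly-zero activation frames exist — almost surely impossible
  under continuous noise), the start is the last frame with zero
  activation. Otherwise the start is the last frame before the end
  whose smoothed frame-to-frame speed is at or below
  `max(rest_speed_threshold, 3σ̂_speed)` while the activation is still
  below half maximum, stepped back by one frame: the centred smoothing
  leaks the onset into the final rest frames, which biases the
  last-qualifying frame late by about one frame.

A sequence whose peak activation stays below 1 mm raises an error (no
expression present); a failed clip is excluded and reported, and the
cohort analysis proceeds complete-case.

Measured behaviour of the rule (reproduced by the test suite): without
noise, start and end are exact and magnitude/symmetry are recovered to
machine precision; with 0.15 mm tracking noise the time bias is below
1 ms and the magnitude bias ≈ +0.04 mm.

### The four parameters

With start frame S, end frame E, displacement `d_i = ||E_i − S_i||`:

* magnitude = (d_a + d_b)/2 over the two expression landmarks,
* symmetry = |d_a − d_b|,
* time = (end − start)/fps,
* shape change = full Procrustes distance between the lower-face
  configurations of S and E.

The lower face is every vertex with signed distance ≤ 1e-9 mm from the
plane through the subnasale oriented by the supplied normal (on-plane
vertices count as lower face — a deterministic tie-break). On the
packaged template this selects exactly 559 of 1178 vertices, and the
selection is invariant under rigid motions applied to mesh and normal
together. On noisy recordings the per-clip count jitters by a few
vertices, because the template's subnasale row sits only microns above
the plane; this has no visible effect on the Procrustes distance of a
~560-point configuration.

### Procrustes superimposition

Ordinary Procrustes analysis via SVD: the similarity transform
(translation, uniform scale, proper rotation) minimizing the summed
squared distances, with reflections disallowed (det R = +1 by
sign-correcting the smallest singular direction) — a face cannot mirror
between frames. `shape_change` first scales both configurations to unit
centroid size, giving a dimensionless, symmetric distance in [0, 1];
`shape_change_mm` is the raw residual in mm. The closed form is checked
against an independent numeric optimizer and a hand-derived example in
the tests.

## Statistical layer

* **Mixed model** per metric and expression:
  `metric ~ time * skeletal_class + (1 | subject)`, REML. EMMs average
  the four cell means with equal class weights. Wald CIs and tests use
  the split-plot t reference with `n_subjects − 2` denominator degrees
  of freedom, which is exact for the balanced 2×2 layout; the type-I
  error of the pooled time test is verified at 5% over 400 null
  replicates.
* **Wilcoxon signed-rank** (paired, two-sided) as a distribution-free
  sensitivity analysis: zero differences dropped and counted, exact
  null distribution for n ≤ 25 without ties (verified against full
  2^n enumeration), otherwise normal approximation with continuity
  correction.
* **Covariate model**: OLS of each subject's T1 − T0 magnitude change
  on the nine surgical movements plus skeletal class and intervention
  type; rank-deficient designs fail loudly, naming the collinear
  columns. Cohorts smaller than the parameter count skip this model
  with a warning instead of failing the whole report.
* **Method error**: two-way single-measure ICCs from the ANOVA mean
  squares — absolute agreement ICC(A,1) and consistency ICC(C,1) — with
  F-based 95% CIs (exact for consistency, Satterthwaite-type for
  agreement), verified against an independent ANOVA oracle and an
  external implementation.

No multiple-testing correction is applied; metrics are reported each on
their own.

## Synthetic generator

### Template and rigs

The template is a deterministic, bilaterally symmetric face-like
surface on a 31 × 38 vertex grid (95 × 125 mm, 32 mm anterior bulge)
with the five landmarks placed at plausible relative positions. Rows
rise laterally by up to 1.2 mm (a gentle jaw-line curve), which makes
the subnasale the only on-plane vertex of its row, so the lower-face
cut is exactly 558 strictly-below vertices plus the subnasale: 559.
Construction parameters violating any of these constraints raise an
error rather than producing a near-miss template.

Expression rigs are compact-support (Wendland C2) radial fields around
each of the two expression landmarks, with support radii (20 mm smile,
8 mm purse) strictly smaller than the landmark separation: the field of
one landmark is identically zero at the other, so a commanded amplitude
A with asymmetry s displaces the landmarks by exactly A + s/2 and
A − s/2. Animation: rest frames, a cubic-ease ramp over
`round(time_to_peak * fps)` frames, a short hold at peak; i.i.d.
isotropic Gaussian tracking noise per vertex and frame. Ground truth
(magnitude, symmetry, frame-quantized time, start/end indices) is exact
by construction.

The rigs are deliberately simple: they are not biomechanical, produce
no skin sliding, co-articulation, or head motion, and the noise is
white rather than spatially correlated as real tracking error would be.
The contract is ground-truth fidelity for pipeline validation, not
visual or physiological realism.

### Calibration fixture

Cohort-level parameters are encoded per expression and timepoint:

* T0 magnitude mean and between-subject SD, and the mean T1 − T0 shift
  (smile 15.24 mm, SD 5.63, +2.03; lip purse 9.34 mm, SD 2.37, −1.03);
* symmetry means per timepoint (smile 0.99 → 1.78 mm; purse
  1.27 → 1.06 mm), realized as signed half-normal draws whose mean
  magnitude matches (σ_signed = mean ÷ √(2/π));
* time means and shifts (smile 0.41 s → +0.02; purse 0.36 s → −0.04)
  with between-subject SDs back-solved the same way.

Between-subject SDs are back-solved from published 95% CIs of the
means: SD = √26 × half-width ÷ 1.96. Within-subject (T0→T1 residual)
SDs are *assumptions* — the source statistics identify only means and
between-subject spread — set to a fraction of the between-subject SD
(smile magnitude 1.4 mm, purse 0.6 mm, time 0.04 s) so that the paired
design has a realistic within-subject correlation. The nine surgical
covariates are drawn from their published means/SDs, translations
truncated at zero; 21 of 26 subjects are bimaxillary.

### Sampling modes

`sampling="stratified"` (default): subject-level latent scores are
permuted stratified normal quantiles, so every cohort reproduces the
fixture's means and SDs almost exactly and recovery error measures
pipeline bias rather than sampling luck. This is the right default for
calibrated-recovery validation: under i.i.d. draws the cohort mean of
smile magnitude alone has a sampling SD of ≈ 1.1 mm at n = 26, which
would swamp sub-half-millimetre recovery checks. `sampling="iid"` draws
ordinary i.i.d. normals and is used where sampling variability is the
object of study (type-I-error calibration of the mixed model).

All randomness flows from a single cohort seed through a documented
splitting scheme (subject draws; per-clip tracking noise keyed by
subject × expression × timepoint; method-error re-tracking noise), so
cohorts are reproducible and clips can be re-realized independently.

## Numerical choices

* PLY frames are stored as float32 (~1e-5 relative), so disk round
  trips reproduce in-memory metrics to ≈ 1e-3 mm.
* The ICC mean squares snap a sum of squares below 1e-12 of the total
  to zero: identical rating columns would otherwise leave an O(ε)
  residue that keeps a mathematically exact ICC of 1 just below 1.
* The run hash covers the analysis configuration but not the output
  directory, so identical analyses are byte-identical wherever written.
* Mixed-model EMM inference uses t(n − 2) rather than the normal
  approximation; with n = 26 this noticeably widens CIs and is what
  makes the null calibration exact in the balanced case.

## Limitations

* The generator validates the pipeline, not the biology: effect sizes
  and variances are encoded from published summary statistics, so
  cohort-level "recovery" demonstrates measurement fidelity, not
  clinical reproduction.
* Within-subject SDs and the covariate distributions' independence are
  assumptions (see above); the synthetic surgical covariates have no
  built-in relationship to the motion changes unless one is configured
  explicitly.
* The trimming rule assumes each recording starts at rest and contains
  a single expression ramp; repeated or hesitant expressions would need
  the explicit start/end overrides.
* Head-motion stabilization is off by default and available only as a
  rigid alignment on a user-chosen stable vertex set.
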