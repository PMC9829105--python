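# Methods

## The measurement problem

Two CBCT-derived surface models of the same rigid bone segment, taken at
different times (e.g. before and after orthognathic surgery), differ by a
rigid motion.  `centroidtrack` quantifies the *translational* part of that
motion along clinically meaningful axes — X sagittal, Y vertical, Z
transversal — without any manual landmark placement.  The method assumes
the segment does not change shape between time points; rotations are
invisible to it by construction (a centroid carries no orientation), and
rotational quantification is explicitly out of scope.

Two mesh grades enter per time point:

* an **accurate** model (segmentation-grade, faithful shape), and
* a coarse **spatial-reference** model whose geometry is poor but whose
  *position* is trustworthy because it comes from the software that
  defined the patient coordinate system.

The pipeline per time point: best-fit align the accurate model onto its
reference (rigid ICP), compute the area-weighted surface centroid of the
aligned accurate model, and express it in the clinical Cartesian frame.
The displacement is the final-minus-initial difference of those centroid
coordinates.

## Centroid definition

The centroid is the area-weighted mean of triangle barycenters,

    c = Σ_i A_i b_i / Σ_i A_i ,

with `A_i` the face area and `b_i` the face barycenter.  This is the
default because it is invariant under any re-triangulation that preserves
the surface pointwise (verified to 1e-9 mm under 1→4 midpoint
subdivision), which directly addresses the practical requirement that the
two time-point meshes be "even, with a similar number of triangles".  Two
alternatives are exposed for sensitivity analysis: `vertex_mean` (simple,
but biased by sampling density — subdivision moves it) and
`enclosed_volume` (divergence-theorem solid centroid; requires a
watertight mesh).  All three are exactly equivariant under rigid motion,
which is what makes "centroid displacement = segment translation" exact
for rigid, identically cropped surfaces.

A hard precondition, enforced rather than assumed: the ROI must be
cropped with the same boundaries at both time points.
`check_comparability` tests four reportable rules — face-count ratio and
total-area ratio within 10 %, per-axis bounding-box extents within 2 mm,
edge-length coefficient of variation ≤ 0.6 (the `strict` policy; a looser
`reference_grade` preset governs the accurate-vs-reference pair, which is
*expected* to differ in density).  Rule failures never raise inside the
checker; the tracking pipeline refuses a failing accurate pair and
attaches the report.

## Registration and the RMS gate

The best-fit alignment is point-to-point ICP with point-to-surface
correspondences: a fixed, area-uniform, seeded sample of points on the
moving mesh (default 5,000) is paired with exact closest points on the
reference *surface* (point-to-triangle, not vertex-to-vertex), and each
iteration re-solves the least-squares rigid motion in closed form via the
SVD of the cross-covariance (Kabsch).  Initialization translates the
moving mesh's centroid onto the reference's.  Iteration stops when the
RMS improvement falls below `tol_mm` (default 1e-6 mm) or at `max_iter`
(default 100).  If the RMS after initialization exceeds a gate (default
30 mm) the meshes are considered non-overlapping and a `diverged` report
is returned instead of an exception.

Closest-point queries use a k-d tree over triangle centroids proposing
`n_candidates` triangles per query, followed by exact vectorized
point-to-triangle distances (Ericson's region classification).  With the
default 16 candidates the queries are exact in practice (validated
against brute force over all triangles and against an independent
library implementation); the study configuration uses 6 candidates, where
the ~1e-3 mm worst-case approximation is far below the jitter noise floor.

Numerical behaviour worth knowing: point-to-point ICP converges linearly
and slides slowly near the optimum.  From a 15° initial rotation offset
on an exact copy, ~100 iterations still leave ~1° of residual; ~1000
iterations reach machine precision.  The property tests therefore give
the precision checks a deep iteration budget, while the study
configuration accepts the micro-metre-scale tail (tol 5e-5 mm, 60
iterations) that is irrelevant next to reference-model noise.  A run that
hits the iteration cap is *not* treated as divergence: the transform is
used and a warning is recorded.  On rotationally symmetric surfaces
(a sphere) the rotation component is unidentifiable; the alignment still
converges with near-zero RMS, and only the (well-identified) translation
matters for centroid tracking.

The RMS of unsigned closest-surface distances is a first-class output —
it is the superimposition-quality gate.  It is computed one-directionally
(accurate → reference), interpreted as the standard root of the
mean squared distance, and reported for both time points with a
configurable warning threshold (default 0.5 mm).

## The synthetic validation study

No patient data ships with the package; the study that validates the
pipeline is fully synthetic and fully seeded.

**Anatomy.** `generate_roi_mesh` builds watertight, rotationally
asymmetric surfaces at craniofacial scale (40–80 mm bounding box per
axis) from a deformed latitude–longitude sphere: a flattened dome with an
anterior ridge for the maxilla, a parabolically bent ellipsoid with a
chin-like prominence for the mandible, plus seeded smooth radial bumps
that guarantee no rotation maps the surface onto itself (verified:
surface RMS > 1 mm under 30° rotations about every axis).  What these
meshes do *not* emulate: thin bony walls, internal cavities, segmentation
topology errors, or scanner-specific artefacts.  Passing tests therefore
demonstrate the *method's* geometric correctness and its robustness to
mesh-quality degradation — not segmentation quality on real CBCT.

**Plans.** Surgical translations are drawn uniformly per axis within a
discrepancy envelope of ±15 mm (X), ±15 mm (Y), ±5 mm (Z), covering the
range of clinically plausible bimaxillary movements.  Plans are
translation-only by design: the centroid method cannot measure rotation,
so rotational plan components would only add unmeasurable confound.

**Degradation.** The gap between mesh grades is emulated by a seeded
pipeline: midpoint edge-collapse decimation to a face fraction, isotropic
Gaussian vertex jitter, and an optional random rigid pose offset.
Study defaults: the *reference* keeps 30 % of faces with 0.15 mm jitter
and exact position (it carries the truth); the *accurate* model keeps
full geometry but starts in a random pose up to 2 mm / 2° off, which the
alignment must recover.  At the default mesh density this calibration
places the alignment RMS near 0.2–0.3 mm — the scale reported for real
threshold-vs-segmentation superimpositions; coarser meshes raise it
(decimation chord error grows with element size).  It is a calibration
choice, not a claim about any particular software pair.

**Replicates.** Real reproducibility studies vary by manual operator
work; here, replicate runs reseed every stochastic stage (degradation,
poses, ICP sampling) while keeping anatomy and plans fixed.  Two
replicate *streams* of the same study are the in-silico analogue of two
examiners.  Seeds derive from the master seed via
`SeedSequence([master, stage, patient, roi, replicate, stream])`, so any
stage reproduces in isolation and adding patients never perturbs earlier
cases.

**Scale.** The study defaults are 10 patients × 2 ROIs × 20 replicates
with ~2,000-face meshes and 2,000 ICP sample points.  These sizes give
per-case runtimes well under a second and full-study runtimes of a few
minutes while leaving the headline statistics (mean |error| ~0.02–0.04
mm) an order of magnitude below the 0.1 mm acceptance bound; growing the
meshes or sample counts tightens the tail without changing conclusions.

## Statistics

* **Paired t-test** (two-sided, df = n−1) compares measured against
  planned translations; zero-variance degenerate inputs are flagged, not
  raised.  CIs use the exact t quantile.
* **Shapiro–Wilk** checks normality of the differences (3 ≤ n ≤ 5000).
* **ICC(A,1)** — two-way, absolute-agreement, single-measurement — is
  computed from the ANOVA mean squares
  `(MSR − MSE) / (MSR + (k−1)MSE + k(MSC − MSE)/n)` and clipped to
  [−1, 1].  Absolute agreement is the right form because the question is
  whether two examiners' measurements are interchangeable, not merely
  correlated.  Verified against a brute-force ANOVA oracle on all small
  table shapes and against an independent library implementation.
* **Bland–Altman** limits of agreement use the fixed 1.96 multiplier
  (95 %); the plot data (pairwise means vs differences) is exported
  rather than rendered.
* **Sample size** for the paired design is the smallest n whose exact
  noncentral-t power reaches the target; the normal approximation is
  only a lower bound at these small n.  With δ = 0.4 mm (one CBCT voxel)
  and difference SDs of 0.3–0.4 mm, the answer lands in the 9–16 patient
  range — which is why a ten-patient study design is reasonable — but no
  single "required n" is asserted because the underlying SD must come
  from pilot data.

## Design choices that were genuinely open

* **Which centroid** the original commercial tooling computes is not
  documented anywhere; the area-weighted surface centroid was chosen for
  its triangulation invariance, with the other two definitions kept as
  options.
* **Error sign convention**: measured − planned, everywhere.  Published
  per-patient error tables and their summary tables are not always
  internally sign-consistent, so the convention is fixed once and echoed
  in the reports.
* **Axis sign convention**: +X anterior, +Y superior, +Z toward the
  patient's right; recorded in every frame serialization because a
  displacement sign is meaningless without it.
* **One-directional RMS** (accurate → reference) mirrors the asymmetric
  role of the two mesh grades; "normalized" RMS is interpreted as the
  standard per-sample normalization.
* **No outlier trimming by default** — both meshes are the same anatomy;
  a worst-5 % trimming flag exists for robustness experiments.

## Known limitations

* Translations only; any true rotation of the segment leaves the centroid
  nearly unchanged and goes unmeasured.
* The centroid is only as meaningful as the crop: comparability checks
  catch gross boundary mismatches, not subtle ones along a coastline of
  identical extent.
* The decimation degrades geometry isotropically; real threshold-based
  segmentation errors are spatially structured (thin walls vanish first).
* Candidate-limited closest-point queries are approximate in adversarial
  geometry (long thin triangles far from their centroids); the default
  candidate count makes this unobservable on the meshes this package
  generates, and the brute-force oracle in the tests guards the bound.
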