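# Methods

This note documents the geometric model, the threshold-fitting
procedure, the synthetic-data generator, and the numerical and design
choices behind `spinemark`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Coordinate and sign conventions

Image coordinates are continuous pixels, x rightward, y downward. All
angle computations use ratios and orientations only, so results are
invariant to rigid motion and uniform scaling of a view; `pixel_spacing`
is therefore metadata. AP images are stored in standard radiographic
display orientation (patient's left at larger x) and landmark names
refer to the patient's side, so any mirroring must be resolved at
ingest — this removes the most likely silent sign error.

Line orientations are measured in (−90°, 90°]: 0 is vertical, positive
tilts toward +x at the top of the image. Angles between segments are
differences of orientations wrapped back into (−90°, 90°].

* **Sagittal sign**: positive = extension (segmental lordosis). This
  places flexion diagnoses below a low cutoff and extension above a
  high cutoff on one signed scale, matching how per-level flexion
  cutoffs (0.6–8.9°) sit below extension cutoffs (10.5–24.5°) in the
  reference table.
* **Axial sign**: positive β = rotation toward the patient's left
  (the right pedicle's offset X exceeds the left's Y).
* **Coronal**: magnitude only; the side ("left"/"right") is retained
  for tallies but never used by threshold fitting.

## Segmental angle model

A vertebra's **centerline** joins the midpoints of its superior and
inferior endplate lines. Sagittal and coronal angles are inter-centerline
angles against the next inferior level. For L5 the inferior reference is
the **normal** of the S1 superior line (lateral: `s1_ant–s1_post`; AP:
`d1–d2`), so a centerline perpendicular to the sacral plateau reads 0.
S1 is stated as the reference in the source protocol without a
construction; the normal is the only choice under which neutral
alignment is 0 on the same scale as the other levels.

**Rotation** uses the cylindrical pedicle model. Reading choices that
the protocol leaves open, fixed here:

* `R` is the cylinder **radius** — half the mean of the superior and
  inferior endplate widths. The projection equations require X ≤ R;
  pedicle offsets never exceed the half-width but always exceed
  nothing else, so the radius is the only reading under which the
  arcsines are well defined.
* `X`, `Y` are **perpendicular distances** from the medial pedicle
  points to the AP centerline, not raw horizontal differences; this
  decouples β from coronal tilt (a tilted but unrotated vertebra
  correctly reads β = 0).
* Ratios X/R or Y/R in (1, 1.02] are clamped to 1 (annotation jitter
  tolerance); larger ratios raise a geometry error naming the pedicle,
  since they indicate a mislabeled point.

**Sacral screen.** The inter-ala points G1, G2 are taken as the ala
markers `e1, e2` and H as the S2 spinous midpoint `f` (the screen's
points are not mapped to marker names in the source protocol; this is
the stated assumption, not a guess beyond it). r = |d1 − d2|/d1 with
d1 the half-span and d2 the distance from H's perpendicular foot to the
nearer ala point. The cohort fence is Q3 + 1.5·IQR with linearly
interpolated quartiles (the common scientific-software default; no
convention was stated). Cases pass iff r < fence; only passers receive
an L5 rotation angle, and L5 rotation is excluded from diagnosis
tallies entirely to keep a fixed denominator (4 levels × cases).
The screen needs ≥ 4 values; with fewer, every case fails and a warning
is logged.

## Threshold fitting

Classification rules: sagittal is three-class with an ordered pair
(flexion if a < t_flex, extension if a > t_ext, else neutral); coronal
and axial are binary on the magnitude with an inclusive boundary
(malposition iff m ≥ t). The sagittal task is fitted as one joint 2-D
search rather than two independent binary problems because the
reference analysis scores flexion/extension as a single task with a
neutral band between two per-level angles.

The score is support-weighted F1 over the task's classes, with a
class's F1 defined as 0 when its denominator is 0. As a function of a
scalar cutoff the score is piecewise constant, changing only where the
cutoff crosses an observed angle; the search space is therefore the
midpoints between consecutive distinct observed values plus sentinels
outside the range (union over raters for the global regime), which is
provably exhaustive. The test suite verifies this against a 0.001°
fine-grid scan on random instances. Ties break toward the smallest
cutoff (lexicographically smallest pair), making results deterministic;
output ordering is by (type, level, regime, rater).

Two regimes: **local** maximizes each rater's own F1_W; **global**
maximizes the *mean* over raters at a single shared cutoff. By
construction mean(local) ≥ mean(global). With a single rater the global
result is defined as that rater's local result.

The per-rater score table pools all levels within a rater into one
confusion matrix at that regime's per-level cutoffs (the per-level
table optimizes per level); the reference report does not state which
aggregation produced which of its tables, so both choices are fixed
here explicitly. Its footer reports the column mean and **population**
SD (ddof = 0), rounded half-up to 2 decimals — the convention that
reproduces the reference table's printed ±SD values. Ratios are
rounded half-up to 1 decimal. Computation never rounds internally.
An F1_W ≥ 0.7 is conventionally read as meaningful diagnostic accuracy;
the package reports scores and leaves that benchmark to the reader (it
is a convention, not a statistical test).

## Synthetic cohort generator

The generator emulates the study conditions of a hospital cohort read
by five raters on disjoint, round-robin-assigned case subsets (2000
cases → 400 per rater; inter-rater agreement is deliberately not
measurable, matching that design). Per case it draws per-level angles,
builds lateral and AP landmark stacks that realize them exactly under
the analysis constructions (rectangles for bodies; pedicle points at
perpendicular offsets R·sin(α ± β); the S2 spinous point placed so its
projection offset equals the drawn sacral asymmetry, giving r exactly),
then adds i.i.d. Gaussian jitter to every coordinate *last*, so noise
propagates through the true geometric pathway. Ground truth is recorded
pre-jitter.

Defaults (all configurable via `SpineGenParams`):

| parameter | default | rationale |
|---|---|---|
| sagittal means L1–L5 | 2, 4, 6, 9, 12° | segmental lordosis grows caudally |
| sagittal SD | 8° | spans the flexion and extension cutoff range at every level (the largest latent cutoff, 24.47° at L5, sits ~1.6 SD from the L5 mean, so recovery is identifiable by design) |
| coronal SD | 2.5° | bending cutoffs ≈ 2° sit near 0.8 SD |
| axial SD | 6° | rotation cutoffs 4.6–9.5° within ~1.6 SD |
| pedicle half-angle α | N(30°, 3°) | typical AP pedicle geometry; redraws keep α ± β inside (1°, 89°) |
| body width / height | U(100, 140) / U(70, 100) px | plausible lumbar proportions at ~0.35 mm/px |
| jitter SD | 0.5 px | sub-pixel annotation uncertainty; the true distribution is unknown (no repeat-labeling data), so this is a free parameter |
| sacral offset SD | 0.05 | half-normal r values with a realistic outlier tail for the fence |

Simulated raters threshold the *true* angles with latent per-level
cutoffs — defaulting to the published reference angles, which also
makes flexion calls dominate extension calls qualitatively — and then
each label is independently replaced by a uniformly chosen different
label with probability ε. L5 axial labels exist only for screen
passers.

What passing tests on this generator do **not** show about real data:
annotation error is modeled as isotropic Gaussian jitter (real raters
err anisotropically and systematically); vertebral bodies are
rectangles/cylinders without wedging, endplate curvature, or
degenerative morphology; rater disagreement is pure label noise rather
than criterion drift. The generator validates the *machinery*
(geometry inversion, search optimality, recovery behavior), not
clinical accuracy.

## Problem sizes and numerical notes

* The forward–inverse oracle runs on a 1000-case zero-jitter cohort
  (tolerance 1e-9°); rotation is additionally cross-checked against a
  root-finder inversion of the forward projection on 1000 random
  (α, β, R) triples.
* The recovery experiment uses 2000 cases × 5 raters: noiseless
  recovery must land inside the inter-observation gap around each
  latent cutoff with all F1_W = 1.0; with ε = 0.1 the *global* cutoffs
  (effective n = 2000/level) are required within 0.5° across 20 seeded
  replicates. Per-rater local cutoffs at ε = 0.1 are not held to that
  bound: near a low-density tail (e.g. L5 extension at ~1.6 SD,
  ≈ 6 observations per degree per rater) a 400-case local cutoff is
  not statistically identifiable to half a degree.
* Degenerate inputs: empty confusion matrices are representable but
  unscorable (error); single-class label sets yield a flagged
  degenerate result rather than an error; zero-length marker segments
  are validation violations that exclude the case with a log, never an
  abort.
* Angles are kept at full precision throughout; rounding (half-up)
  happens only at presentation.

## Known limitations

* The landmark file schema is this package's reconstruction of the
  protocol's named points; the original labeling program's export
  dialect is unpublished.
* The published headline scores and cutoff tables derive from 2000
  proprietary radiographs; the package reproduces the study's
  *self-contained arithmetic* exactly and validates the method by
  simulation, but cannot re-derive those clinical values. The
  reference sacral fence (0.0886) is likewise cohort-specific context.
* Cobb-style global curvature, 3-D reconstruction, and non-lumbar
  regions are out of scope.
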