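# Methods

`spinemetrics` implements a fully automatic measurement pipeline for
bi-planar (frontal + lateral) spine radiographs: region-of-interest
cropping from projected intensity histograms, per-ROI segmentation with
an inception U-Net, conversion of the binarized masks into named
anatomical landmarks, and computation of the coronal and sagittal
spinopelvic parameters, together with the evaluation statistics used to
judge each stage. Because clinical radiograph collections with
per-vertebra annotations are not publicly shareable, the package ships a
synthetic phantom generator that plays the role of the data: it emits
image pairs whose ground-truth landmarks and clinical parameters are
known exactly, so every stage of the pipeline is testable end to end.

## Coordinate and sign conventions

All landmarks live in image coordinates: origin top-left, x rightwards,
y downwards, units px, with `pixel_spacing_mm` converting to mm. In the
lateral view anterior is +x. Because image y points down, angle
primitives correct the sign so that clinically "up to the right"
(frontal) or "up anteriorly" (lateral) endplates are positive:

* **Endplate angle**: angle of the endplate line to the horizontal in
  (−90°, 90°], direction-free.
* **Cobb angle**: unsigned difference between the superior endplate
  angle of the upper end vertebra and the inferior endplate angle of the
  lower end vertebra; curves are reported most caudal first, at most
  three, and curves under 10° are kept but flagged sub-scoliotic (10° is
  the conventional scoliosis threshold).
* **THK** (thoracic kyphosis): T12 inferior minus T5 superior endplate
  angle, positive in kyphosis. The T5–T12 convention is fixed
  throughout.
* **LL** (lumbar lordosis): L1 superior endplate angle minus sacral
  endplate angle, positive in lordosis (L1–S1 convention).
* **SVA** (sagittal vertical axis): horizontal offset in mm from the
  vertical through the C7 body centroid to the posterior sacral endplate
  point, positive when the plumb line falls anterior.
* **SS** (sacral slope): inclination of the sacral endplate to the
  horizontal, unsigned, [0°, 90°).
* **PT** (pelvic tilt): angle to the vertical of the line from the
  hip-axis midpoint (midpoint of the femoral-head centers) to the
  sacral-endplate midpoint, positive for posterior tilt.
* **PI** (pelvic incidence): angle between the caudally directed sacral
  endplate normal at the endplate midpoint and the line to the hip-axis
  midpoint. PI = SS + PT is a geometric identity; the package computes
  PI independently and records the residual |PI − (SS+PT)|, which must
  stay below 0.01° on consistent landmark sets.

## Synthetic phantom

The phantom stacks 18 quadrilateral vertebral bodies (C7–L5, 20 mm
high, width tapering 25→35 mm cranio-caudally, 8 mm disk gaps) along a
curved centerline, adds a sacral endplate segment, two femoral-head
circles (11 mm radius), and a smooth soft-tissue background.

**Sagittal shape.** A per-level endplate tilt profile realizes the
requested parameters exactly: lumbar lordosis is distributed linearly
over L5→L1 ending at tilt SS − LL at L1; the thoracic tilt ramps
linearly from T12 (continuous with L1) to T5 with a total difference of
THK; above T5 the profile relaxes toward vertical so the
cervicothoracic junction looks physiologic. The sacral endplate is laid
down at exactly SS, and the hip axis is placed 70 mm from the sacral
midpoint along a line tilted PT from the vertical, so SS, PT and the
PI = SS + PT identity hold to machine precision. SVA is not dialed in
directly; it falls out of the sagittal profile and is recorded as truth.

**Coronal curves.** Each requested curve (apex level, target Cobb,
0–3 curves, alternating convexity, most caudal first) contributes a
smooth sine-shaped tilt lobe spanning apex ± 6 levels with extremes at
apex ± 3. Because adjacent lobes overlap and the downstream
end-vertebra search smooths the tilt profile, lobe amplitudes are
solved so that the signed tilt difference at the *search-identified*
end vertebrae equals the target, iterating solve → search → re-target
to a fixed point (it converges in one or two rounds). Truth records
therefore carry exactly the end vertebrae the measurement will find,
with the target angle realized there, and the truth apex is the most
laterally deviated vertebra of the realized curve. Configurations the
fixed point cannot realize (colliding apexes, curve combinations that
would need negative lobe amplitudes or make vertebrae overlap) raise an
explicit error rather than being silently clipped; the random-subject
helper rejection-samples past them.

**Rendering.** The background is three bright Gaussian bands (head,
shoulder girdle, pelvis) and two dark bands (neck, abdomen) over a
constant base, multiplied by a horizontal Gaussian torso profile; band
positions derive from the realized geometry (head above C7, shoulder at
T2, abdomen at L1, pelvis at the hip axis) so the structure the ROI
cropper exploits is present by construction. Bone content (vertebra
quadrilaterals, sacral disks, femoral circles) is painted brighter than
the background, and i.i.d. Gaussian noise (default sd 0.02 of the unit
intensity range — mild sensor noise) is added. Masks are rasterized per
class: the 18 filled vertebra quadrilaterals, C7 alone as the
neck-class target, 5 mm disks on the two sacral endplate points, and
one disk class per femoral head.

**Study conditions.** The random-subject generator draws SS from
U(25°, 50°), PT from U(5°, 25°), THK from U(15°, 45°) and LL = SS +
U(5°, 25°) — lumbar lordosis tracks sacral slope in standing adults,
and sampling the two independently produces sagittal columns no
patient exhibits (and spines that leave the detector frame). Cobb
targets are U(12°, 40°) for single curves; double curves pair a caudal
major (U(18°, 32°)) with a cranial minor at 0.55–0.9 of its magnitude,
apexes 6–7 levels apart. Images are 960×512 px at 1 mm/px.

**What the phantom does not model.** Rib, scapula and humerus
superimposition, X-ray physics (scatter, beam hardening), soft-tissue
texture, instrumentation, and out-of-plane rotation. Passing tests on
phantoms therefore demonstrate the correctness of the geometric and
statistical machinery and the trainability of the segmenter on
idealized content — not clinical segmentation performance, which is
dominated by exactly the superimposition effects the phantom omits.

## Preprocessing

Row sums (and column sums) of the image, normalized to max 1, form the
projected intensity profiles. Profiles are smoothed with a moving
average 2% of their length wide; local maxima with smoothed height
≥ 0.6 are accepted, and the minimum between consecutive accepted maxima
supplies the separating dark bands (a threshold cannot literally apply
to minima). The three tallest maxima are read as head, shoulder and
pelvis; the neck minimum lies between head and shoulder, the abdomen
minimum between shoulder and pelvis; the single vertical-profile peak
centers all windows left-right. Window extents are fixed fractions of
the inter-extremum spans (neck: around the neck minimum down to the
shoulder maximum; spine: neck minimum to 72% of the abdomen→pelvis
span; sacrum: 45%–130% of that span; femur: around the pelvis maximum),
padded by 5%, with per-ROI half-widths of 100–140 mm about the torso
peak. The exact extrema→window mapping is a package design choice; it
is validated by the containment criterion (a sample is correctly
preprocessed only if every ground-truth landmark of every ROI lies
strictly inside its window), which holds on ≥ 95% of rendered phantoms.

Each window records its crop box, resize scales and min-max
normalization constants, making the transform invertible: forward and
inverse mappings are exact affine algebra and round-trip well under
half a pixel.

## Segmentation

One network per ROI class maps the normalized crop to a per-pixel
probability map. The architecture is a U-Net whose encoder, bottleneck
and decoder blocks are inception modules — three parallel convolution
branches (1×1, 3×3, 5×5, each ReLU) concatenated along channels — with
2×2 max-pooling, nearest-neighbour upsampling, skip concatenation, and
a final 1×1 convolution. Training minimizes binary cross-entropy (on
logits, for stability) with Adam at an initial learning rate of 5e-4,
He-normal initialization, and an 85:15 train/validation split by seeded
shuffle; the best-validation weights are kept. The layers are
implemented directly in NumPy (im2col convolutions backed by BLAS
matmuls, explicit backward passes, verified against numerical gradients
to 1e-6 relative in float64), so training and inference are
deterministic given the seed, on any machine, with no framework
dependency.

Probability maps are binarized at 0.7, with values exactly at the
threshold kept (the boundary convention is documented and tested).

Desk-scale defaults — depth 3, 8 channels per branch, 20 epochs, batch
8, 64 spine ROIs at 64×32 px — train in about two minutes on one CPU
and reach training Dice ≈ 0.9 and validation Dice ≈ 0.9 on noiseless
phantoms. The full-scale clinical regime (500 epochs, batch 20, native
ROI resolutions, hundreds of radiographs) is reachable purely through
`NetworkConfig`; nothing in the code is desk-scale-specific.

## Postprocessing

In each view: the largest neck-ROI component is taken as C7, mapped
into the spine window, and replaces any spine-ROI content cranial to
it; components whose centroid lies caudal to the predicted sacral
endplate line are removed; the survivors are area-filtered (≥ 25% of
the median component area, with a 12 px absolute floor), sorted by
centroid height and labeled C7…L5 from the top. More than 18 survivors
are truncated caudally and flagged; fewer than 18 mark the sample
incomplete, and incomplete samples are excluded from parameter
prediction. A sample counts as a *reasonable segmentation* only when
every ROI produced a prediction and the spine yielded at least 18
bodies.

Corners are extracted per component from its minimum-area rotated
rectangle, refined by a total-least-squares refit of each edge to the
boundary pixels lying along it, each fitted edge pushed half a pixel
outward (boundary pixel centers sit half a pixel inside the true edge),
and corners taken as intersections of adjacent edges. The refit matters:
the raw minimum-area rectangle is determined by a handful of extreme
staircase pixels and its orientation jitters by 1–3°, which is
unacceptable for angles that must be good to fractions of a degree; the
refit brings landmark MAD on oracle masks to ≈ 0.25 px and endplate
angles to a few tenths of a degree. The long edges of the refined
rectangle are the endplates (vertebral bodies are wider than tall), the
higher one is superior. Corner extraction runs in full-image
coordinates (after inverting the window transform) so anisotropic ROI
resizing cannot bias the fit.

Sacral endplate points and femoral-head centers are mask-class
centroids; the sacral midpoint and hip-axis midpoint are exact averages
of their defining points. All failures surface as flags, not
exceptions, so cohort statistics can count them.

## Cobb end-vertebra search

Per-vertebra coronal inclination is the mean of the superior and
inferior endplate angles. The profile is smoothed with a ±2-level
moving average, local extrema above 0.25° in magnitude are kept
(suppressing numerical jitter on straight spines), each extremum is
refined to the most-tilted vertebra within one level on the raw profile
(the smoothed profile can tie exactly on two neighbouring levels at the
stack boundary, and the most-tilted vertebra is the clinical
end-vertebra definition), and consecutive opposite-sign extrema are
paired into curves. The curve angle uses the raw endplate angles of the
identified end vertebrae; the apex is the vertebra between them whose
centroid deviates farthest from the line joining the end-vertebra
centroids. The three largest curves are kept and ordered most caudal
first.

## Evaluation statistics

* **Dice/F1**: 2|A∩B|/(|A|+|B|); two empty masks score 1.0 by
  convention (flagged).
* **Landmark MAD**: Euclidean distances in mm between landmarks matched
  by name, with thoracic/lumbar/sacral/femoral region filters; SD is
  the sample standard deviation of the distances.
* **ICC**: two-way, single-measurement, absolute-agreement form
  ICC(A,1) = (MSR − MSE) / (MSR + (k−1)MSE + (k/n)(MSC − MSE)) from the
  two-way ANOVA mean squares, with the F-based 95% confidence interval
  of McGraw & Wong for this form. The implementation is written out
  explicitly (degenerate inputs — constant matrices, zero residual
  variance — need defined answers and flags) and is cross-checked in
  the tests against a brute-force sums-of-squares oracle (to 1e-8) and
  against `pingouin.intraclass_corr` (to machine precision).
  Reliability grades: excellent ≥ 0.9 > good ≥ 0.75 > moderate ≥ 0.5 >
  poor, boundaries taking the higher grade.
* **Success bookkeeping**: per-stage counts of correctly preprocessed
  samples (the strict landmark-containment rule), per-ROI window
  success, reasonable segmentations, and subjects with complete
  parameter predictions.

## Numerical choices and degenerate inputs

Binarization keeps values exactly at threshold. Equal-height plateau
maxima in profile extremum detection keep the earliest index. The
oracle-mask pipeline mode derives windows with resizing disabled
(window target = crop size) so it measures postprocessing fidelity
rather than resampling loss; the resized path is exercised separately.
Coincident points in angle primitives, all-zero images, degenerate
(line-like) components, thresholds outside (0,1) and malformed landmark
JSON all raise with the offending item named. Seeds propagate through
`numpy.random.Generator` everywhere; renders, masks, geometry, network
initialization and training are bit-reproducible under a fixed seed.

## Problem sizes

The shipped verification runs use cohorts of 100 phantoms for the
geometric and preprocessing properties (1000 for the PI identity),
64 spine ROIs at 64×32 px for the training run, and 100 random ratings
matrices (n ∈ [5,30], k ∈ [2,5]) for the ICC oracle — sizes chosen so
the whole suite completes in a few minutes on one CPU while keeping the
Monte-Carlo margins comfortable. The acceptance script scales a few of
these down (200 identity geometries, 50 recovery subjects, 30 oracle
round trips) without changing any condition.

## Known limitations

Phantom realism is deliberately minimal (see above). The Cobb search
assumes at most three curves with alternating convexity and shared or
separated junctions; exotic profiles (four curves, same-sign adjacent
curves) are out of scope. Vertebra labeling assumes the topmost
component after the neck merge is C7 and does not interpolate missing
mid-stack levels — a missing vertebra makes the sample incomplete, as
it should for a measurement that reports per-level angles. The
segmenter's clinical performance is not claimed: no result computed
here transfers to real radiographs beyond the correctness of the
geometry and statistics.
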