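# Methods

This note records the models, defaults and numerical choices behind
`zfinject`, and what the synthetic fixtures do and do not establish about
behaviour on real microscope imagery.

## Scope and architecture

The package reproduces the *decision* layer of a larva-microinjection
robot: recognition, targeting, descent monitoring, puncture detection,
droplet calibration and session bookkeeping. Everything that is hardware on
the instrument — stage and needle motors, the liquid lens, the pressure
channel, cameras — is replaced by seeded synthetic generators and a
simulated clock. Timestamps, throughput and success rates produced here
therefore describe the simulation, never a physical instrument.

Modules are layered in the order the procedure runs: `fixtures` →
`segmentation` → (`bloodflow`) → `targeting` → `focus` → `puncture` →
`droplet` → `session`, with `cli` as a thin shell layer. Learned components
(the plate/site segmentation network and the puncture classification
network of the production system) sit behind pluggable interfaces
(`Segmenter`, `PunctureModel`); the reference implementations used in tests
are a classical intensity-likelihood segmenter and a logistic model on
frame-difference features. This keeps every surrounding algorithm —
tiling, stitching, consensus, tracking, state machines — independently
verifiable without reproducing anyone's trained weights.

## Conventions

Pixel coordinates are 0-based, x rightward, y downward, intervals
half-open. Angles are degrees measured from +x toward +y (so direction
(0, 1) is 90°), normalized to [0, 360). Larva heading for needle
orientation is the direction from the eyes centroid to the swim-bladder
centroid. A single integer seed feeds one `numpy` generator per call; no
global state.

## Synthetic fixtures

The larva is a stylized 2-dpf template (`LarvaGeometry`): a 100×40 px
elliptical body carrying two eye disks near the head, a yolk disk, a
swim-bladder disk posterior, a small hindbrain disk, and two thin bands on
the yolk margin — duct of Cuvier dorsal, perivitelline space ventral —
each rendered at its own nominal gray level (`FIXTURE_LEVELS`, 8-bit,
neighbouring levels ≥ 25 apart) and rotated by the heading. Region masks
are pairwise disjoint by construction and all lie inside the body, so the
truth label map equals the priority-ordered overlay of the masks exactly.
Plates place a configurable number of larvae (default geometry supports
~20 on a 1200² plate, the practical batch size) by rejection sampling on
bounding circles with a 12-px margin; overcrowding raises a capacity error
after bounded retries. Noise is additive Gaussian (default sd 3), clipped
to the intensity range — the simplest controllable corruption.

Vessel videos draw dark particles (radius 1.6 px, 90 gray levels below
background) advancing 2 px/frame along the vessel, ordered by projection
onto the vessel's principal axis, evenly spaced with a seeded phase;
pixels outside the vessel are static up to sensor noise. Focal stacks blur
one seeded texture with Gaussian sigma proportional to the distance from
the peak index, making any reasonable focus measure exactly unimodal at
zero noise. Puncture sequences sample a smooth texture through a window
that drifts `drift_px` per frame (default 0.5) and snaps back by `jump_px`
(default 6) at the puncture frame — push, then rapid skin retraction.
Droplets are anti-aliased dark disks (analytic edge coverage) on a bright
oil background.

What the fixtures deliberately do **not** model: photorealistic larva
appearance, pigmentation variants, developmental stages other than an
idealized 2-dpf geometry, optical point-spread functions, needle shadows,
debris, or out-of-plane motion. Passing tests therefore establish the
correctness of the *algorithms* under known geometry and contrast, not
recognition performance on real bright-field plates — that is what the
pluggable network interface is for. Fixture appearance parameters (sizes
in pixels, contrast) are free knobs chosen for clear structure at typical
plate-camera scales, not calibrated to any instrument's optics.

## Segmentation machinery

Overlapping polygon annotations resolve per pixel to the most specific
covering class, priority order: eye > swim_bladder > yolk > duct_of_cuvier
> perivitelline_space > hindbrain > body > background. Painting regions in
reverse priority order makes resolution idempotent and independent of
annotation order.

Inference tiles default to 304 px with 50-px overlap; offsets advance at
stride 254 and the last tile per axis is clamped flush to the edge, so
coverage is exact for any image at least one tile wide. Smaller images are
reflect-padded to tile size and cropped after stitching. Stitching assigns
each pixel the scores of the covering tile whose center is nearest — a
hard nearest-center rule rather than averaging, chosen because the
motivation for overlap is distrust of predictions near the tile edge, and
nearest-center encodes exactly that. For any translation-consistent
segmenter this makes tiled inference pixel-identical to whole-image
inference, which the acceptance checks verify on plates up to 1024².

The consensus step uses six symmetries — identity, rotations by
90°/180°/270°, horizontal and vertical reflection (the fixed choice of six
among the eight square symmetries) — with a per-pixel majority vote over
the six back-transformed label rasters. Ties break by the annotation
priority order, then lowest class index. Non-square images are
reflect-padded to square for the rotations and cropped back.

## Targeting

The skewed frame is built from anatomy, not from the plate: origin at the
eyes centroid (union of both eyes), u to the yolk centroid, v to the
swim-bladder centroid. Which landmark anchors the origin is a design
choice; eyes-origin makes (1, 0) and (0, 1) the two remaining landmarks.
Frames with |cross(u,v)|/(|u||v|) < 1e-3 are rejected as degenerate.
The mapping and its 2×2-solve inverse are exact to numerical precision,
and the whole construction is equivariant under rigid motions of the
larva.

"Middle of the DoC" is realized as the geodesic center of the largest DoC
component — the pixel minimizing the maximal within-mask geodesic distance
(8-connected, √2 diagonals, computed with `scipy.sparse.csgraph`), with
tied centers averaged. Unlike thinning-based skeleton midpoints this is
exactly equivariant under grid rotations and reflections and robust to
band shape; masks beyond 20 000 px fall back to the centroid projection.
The "upper border" of the PVS is defined in the larva's own frame: among
boundary pixels of the PVS component, those on the positive-v side (by
median split of their b-coordinates), taking the one nearest the
configured entry coordinate; entry angles are validated against the
recommended 30–60° range, inclusive. Hindbrain poses consume a start and a
direction point; predicting those two points from edge segmentation is a
learned component on the instrument and is pluggable here, with a
geometric stand-in (start just beyond the hindbrain centroid on the
far side from the eyes).

## Blood flow

The activity map is the sum of absolute differences of subsequent frames,
divided by its maximum (an all-zero sum stays zero). Max-normalization is
the minimal reading of "normalize" that keeps the map in [0, 1]; no
pre-smoothing or percentile clipping is applied. Frames are cast to float
before differencing to avoid unsigned-integer wraparound. The map is
invariant to constant intensity offsets and to reversing the sequence. The
default video length is 10 frames. The overlay writes
`red = gray + weight·activity·(255 − gray)` with green/blue carrying the
gray value.

## Focus and touchdown

Sharpness is the variance of the discrete Laplacian — the canonical
classical focus measure — behind a swappable scoring function. The coarse
descent uses a streaming peak detector: track the running maximum; once a
score drops below peak × (1 − hysteresis) the peak index is emitted.
Hysteresis defaults to 0.05, enough that flat traces with small noise
never fire. The fine descent uses a touchdown detector: a rolling median
(window 5) of preceding scores is the baseline; the first score at least
3× the baseline (threshold configurable, must exceed 1) fires. The
detector requires at least 3 baseline samples before it may fire — a
median of one or two noisy samples is meaningless and caused early false
fires at 10%-of-jump noise. Both detectors are causal: an emitted event is
never revised. The two phases compose into a COARSE → FINE → TOUCHED state
machine mirroring the descent procedure. The instrument's actual threshold
and window values are not public; these defaults are configuration, not
claims.

## Puncture

Anchors (default 8) are seeded on Shi–Tomasi corner maxima above the 60th
percentile response within 30 px of the tip; a texture-poor scene raises an
error naming the found count. Tracking is normalized cross-correlation of
11×11 patches over a ±9 px search window (`skimage.feature.match_template`)
with quadratic sub-pixel refinement; the measured patch motion is applied
to the stored sub-pixel position (matching displacement against the
rounded template origin, not the float position, otherwise up to 0.5 px of
spurious displacement per frame accumulates). Points whose best match
falls below NCC 0.5 are flagged lost and excluded. The collective
statistic is the median displacement over surviving points — robust to
individually lost anchors. Puncture is the first frame (after 2 frames of
history) where the median displacement reaches max(k × median of prior
per-frame medians, 2 px), k = 4. The absolute floor is what keeps pure
drift and tracking noise from ever firing. The triplet-classification
route stacks frames t−2, t−1, t as channels; the toy logistic model uses
mean |Δ| of the two channel pairs and their log-ratio as features and is a
stand-in exercising the interface, not a reproduction of the production
classifier.

## Droplet calibration

Otsu's threshold separates the dark droplet from the bright oil; the
largest connected dark component is the candidate, a second component at
≥ 50% of its area makes the scene ambiguous (error listing areas), and
circularity 4πA/P² (Crofton perimeter) below 0.8 rejects elongated debris.
The reported diameter is the equivalent-area diameter — droplets in oil
are near-spherical, so max-Feret adds noise without information. Volume is
(π/6)d³ converted to nL; a 1 nL droplet is ~124 µm. The pressure update is
proportional: new = current × target/measured, clamped to a safe range
(default 10–1000). It is a first-order model — the true pulse physics,
cell sedimentation and clogging are out of scope; multi-pulse macros with
an operator checkpoint are the session-level answer to unrepresentative
droplet volumes when injecting cells.

## Session simulation

Macros are declarative YAML-serializable step lists; validation enforces
that a pulse can only follow an awaited puncture and that repeats are
positive. Shipped defaults: DoC (touchdown → advance → puncture → retract
→ single pulse), PVS (angled entry, two pulses, operator checkpoint),
hindbrain (double pulse). Detector `await_*` steps consume events from the
context; a missing event is a recorded per-larva failure (timeout), never
an exception, and the session continues with the next larva.

The simulated clock charges per-action costs chosen so an automated DoC
injection costs 42 s and a semi-automated run with one operator checkpoint
~82 s — mirroring the reported ratio that the automated mode is roughly
twice as fast as manual injection (~43 s vs ~84 s per larva). The batch
budget defaults to 7 simulated minutes, the bench guidance for how long
anesthetized larvae tolerate the open plate; larvae whose turn comes after
the budget are marked skipped. Success is defined purely as macro
completion with puncture confirmed — the visual, site-specific criteria an
experimenter applies are not operationalized here. Survival is explicitly
a placeholder: a seeded Bernoulli draw (default rate 0.8) per successful
injection, because survival is a biological outcome software cannot
compute. Summaries report success rate over injected (not skipped) larvae,
larvae/hour as 3600 over the mean simulated per-larva time, and
across-session aggregation as mean ± sample standard deviation (a single
session reports std 0 with a flag). Mode comparison is a one-tailed Welch
two-sample test (unequal variance) with Welch–Satterthwaite degrees of
freedom; two constant equal samples give p = 0.5 by convention, and the
implementation is checked against an independent computation to 1e-9.

## Problem sizes and determinism

The verification suite uses 20 plates up to 1024² for tiling equivalence,
100 random 32² rasters for consensus voting, 50 polygon sets for
annotation resolution, 1000 random frames plus 50 larvae for targeting
geometry, 20 ten-frame vessel videos, 200 noisy traces each for touchdown
and puncture (plus 100 pure-drift negatives), and a 20-larva plate for
session bookkeeping — sizes at which every property is measured in a few
seconds to a couple of minutes on one CPU. All randomness flows from
explicit integer seeds; the CLI pipeline run twice under one seed produces
byte-identical outputs, which the acceptance script verifies.

## Known limitations

- The fixture appearance model is stylized; recognition performance on
  real imagery depends entirely on the network plugged into `Segmenter`.
- The intensity segmenter assumes the fixture gray-level palette and is
  not meant for real images.
- Tracking assumes mostly-translational local motion; strong deformation
  or occlusion by the needle shadow is not modeled.
- The hindbrain start/direction predictor is a geometric stand-in for a
  learned regressor.
- Simulated times and rates are configuration-driven bookkeeping, suitable
  for comparing macro structures, not for claiming real-world throughput.
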