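# zfinject

Software decision stack of an automated microinjection robot for zebrafish
larvae, rebuilt as a hardware-free pipeline and exercised end-to-end on
synthetic imagery with exact ground truth.

Zebrafish xenograft assays need thousands of precise microinjections into
2-dpf larvae at sites such as the duct of Cuvier (DoC, intravenous), the
perivitelline space (PVS, subcutaneous-like) and the hindbrain ventricle
(orthotopic brain implantation). A robot that automates this must *decide*:
where each larva is and how it is oriented, where the injection site lies,
when the descending needle touches the skin, when it punctures, and how much
volume a pressure pulse delivers. `zfinject` implements those decisions as a
library plus CLI, with every hardware-facing input replaced by a seeded
synthetic generator that knows the ground truth, so each decision stage can
be verified quantitatively.

## What is implemented

- **Segmentation machinery** (`zfinject.segmentation`) — annotation overlap
  resolution (most specific class wins per pixel), per-pixel argmax over a
  W×H×N score map, tiling of large plates into 304-px tiles with 50-px
  overlap, stitching by nearest-tile-center assignment (a U-Net is least
  trustworthy near its input edge), and a six-transform test-time consensus
  (identity, rotations by 90°/180°/270°, horizontal/vertical reflection)
  with per-pixel majority vote. The segmenter itself is pluggable; a
  classical intensity-likelihood segmenter serves the synthetic imagery.
- **Targeting** (`zfinject.targeting`) — centroids of eyes/yolk/swim bladder,
  a skewed (non-orthogonal) larva-attached frame
  `p(a, b) = origin + a·u + b·v` with `origin` at the eyes,
  `u = yolk − eyes`, `v = swim bladder − eyes`, orientation-aware needle
  angle, and site selection: middle of the DoC (geodesic center of the
  band), any user-chosen DoC point, the upper PVS border at a 30–60° entry
  angle, and hindbrain start/direction poses.
- **Blood-flow mapping** (`zfinject.bloodflow`) —
  `activity = normalize(Σₜ |frameₜ₊₁ − frameₜ|)` over a short (default
  10-frame) video, colored red over the last frame, which makes the DoC
  visible to recognition.
- **Autofocus & touchdown** (`zfinject.focus`) — variance-of-Laplacian
  sharpness, a streaming local-maximum detector with hysteresis for the
  coarse descent, and a rolling-median jump detector for surface touchdown,
  wired as a COARSE → FINE → TOUCHED state machine.
- **Puncture detection** (`zfinject.puncture`) — anchor points seeded on
  corner-rich texture near the tip, tracked frame-to-frame by normalized
  cross-correlation with sub-pixel refinement; puncture is the first frame
  whose median displacement jumps k-fold (default 4×, 2-px floor) above the
  preceding drift. An alternative classifier route scores stacked
  3-frame triplets behind a pluggable model interface.
- **Droplet calibration** (`zfinject.droplet`) — segment the dark droplet in
  mineral oil, equivalent-area diameter, sphere volume
  `V = (π/6)·d³`, circularity gate against debris, and a proportional
  pressure update toward the target volume.
- **Session orchestration** (`zfinject.session`) — top-to-bottom plate scan,
  declarative injection macros (approach / descend / await_touchdown /
  advance / await_puncture / retract / pulse / repeat /
  operator_checkpoint), automated and semi-automated modes, a simulated
  clock with per-action costs, a 7-minute batch budget, per-larva outcome
  records, success-rate / larvae-per-hour summaries, and a one-tailed Welch
  test for comparing modes.
- **Synthetic fixtures** (`zfinject.fixtures`) — seeded, bit-reproducible
  generators for larva plates (stylized 2-dpf template with per-region
  ground-truth masks and landmarks), particle-flow vessel videos,
  unimodal-sharpness focal stacks, drift-then-jump puncture sequences,
  touchdown traces, and droplets in oil.

## Worked example

Simulate a 20-larva plate, run an automated DoC session, and calibrate a
droplet:

```sh
zfinject simulate-plate --n-larvae 20 --seed 11 --out demo
zfinject run-session --plate demo/plate.png --site doc_mid --seed 11 \
    --out demo/session.csv --summary demo/summary.json
```

prints

```json
{
  "larvae_per_hour": 85.71,
  "mean_seconds_per_larva": 42.0,
  "n_detected": 20,
  "n_injected": 10,
  "n_skipped": 10,
  "n_success": 10,
  "success_rate_pct": 100.0,
  "survival_rate_pct": 80.0
}
```

All 20 larvae were detected and ordered top-to-bottom; at the default
simulated cost of 42 s per automated DoC injection, 10 fit inside the
7-minute batch budget (anesthetized larvae dry out on the plate, so a batch
is capped) and the remaining 10 are recorded as skipped. Every injected
larva succeeded because the detector events here come from clean synthetic
fixtures; the survival number is a seeded placeholder outcome model, not
biology. `demo/session.csv` holds one row per larva with the pose, action
trace and timestamps.

```sh
zfinject calibrate-droplet --image demo/well.png --scale 2.0 \
    --target-nl 1.0 --pressure 200
# {"circularity": 1.0, "diameter_um": 99.91, "recommended_pressure": 383.0,
#  "volume_nl": 0.5222}
```

A 99.9-µm droplet is 0.52 nL, so reaching 1 nL needs roughly double the
pressure under the proportional first-order model.

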