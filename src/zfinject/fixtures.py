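"""Synthetic imagery with exact ground truth.

Every input the injection pipeline consumes — bright-field plates of
anesthetized larvae, particle-flow vessel videos, focal stacks, needle
drift/puncture sequences, droplets in mineral oil — is generated here as a
pure function of its parameters and a seed, together with the ground truth
the detectors are judged against.

The larva is a stylized 2-dpf template: an elliptical body carrying two
dark eye disks, a yolk disk, a swim-bladder disk, a hindbrain disk, and
thin duct-of-Cuvier / perivitelline-space bands on the yolk margin, each
rendered at its own nominal gray level and rotated by the larva's heading.
The pipeline needs geometry and contrast, not photorealism.

Conventions: pixel coordinates are 0-based, x rightward, y downward,
half-open intervals; angles are degrees measured from +x toward +y.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
import yaml
from PIL import Image
from scipy import ndimage

from .segmentation import CLASSES, LabelMap

# Nominal gray level of each anatomy class in fixture imagery (8-bit).
# Levels are separated well beyond the default sensor noise so a classical
# per-pixel segmenter can recover the truth.
FIXTURE_LEVELS: dict[str, float] = {
    "background": 230.0,
    "body": 185.0,
    "hindbrain": 155.0,
    "perivitelline_space": 130.0,
    "duct_of_cuvier": 105.0,
    "yolk": 80.0,
    "swim_bladder": 55.0,
    "eye": 25.0,
}

# Indexed-PNG palette for label maps (class index -> RGB).
PALETTE: dict[str, tuple[int, int, int]] = {
    "background": (0, 0, 0),
    "body": (180, 180, 180),
    "hindbrain": (255, 160, 0),
    "perivitelline_space": (0, 200, 200),
    "duct_of_cuvier": (220, 0, 0),
    "yolk": (240, 220, 0),
    "swim_bladder": (0, 120, 255),
    "eye": (255, 255, 255),
}


class CapacityError(RuntimeError):
    """Raised when larvae cannot be placed without contact."""


@dataclass(frozen=True)
class GroundTruthEvent:
    """Oracle record: at which frame/z-step an event truly occurs."""

    kind: str  # focus_peak | touchdown | puncture
    index: int


@dataclass
class FrameSequence:
    """Time- or z-ordered stack of equally sized grayscale frames."""

    frames: np.ndarray  # (T, H, W)

    def __post_init__(self) -> None:
        f = np.asarray(self.frames)
        if f.ndim != 3:
            raise ValueError("frames must be a (T, H, W) stack")
        self.frames = f

    def __len__(self) -> int:
        return self.frames.shape[0]

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]


@dataclass
class SyntheticLarva:
    """One placed larva: pose, per-class boolean masks, and landmarks."""

    position: tuple[float, float]  # body centroid (x, y) in plate pixels
    heading_deg: float  # 0 = facing +x
    region_masks: dict[str, np.ndarray]
    landmarks: dict[str, tuple[float, float]]


@dataclass
class SyntheticPlate:
    image: np.ndarray  # (H, W) uint8
    larvae: list[SyntheticLarva]
    truth: LabelMap
    seed: int


# ---------------------------------------------------------------------------
# Larva template geometry (local frame: x along heading, lengths in px)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LarvaGeometry:
    """Stylized 2-dpf larva template, idealized from ~3.7 x 0.6 mm."""

    body_a: float = 50.0  # body semi-axis along heading
    body_b: float = 20.0
    eye_centers: tuple[tuple[float, float], ...] = ((36.0, -7.0), (36.0, 7.0))
    eye_r: float = 4.0
    yolk_center: tuple[float, float] = (6.0, 2.0)
    yolk_r: float = 12.0
    ring_outer: float = 16.0  # DoC / PVS bands live on the yolk margin
    band_gap: float = 2.0  # dead band between dorsal DoC and ventral PVS
    sb_center: tuple[float, float] = (-20.0, -6.0)
    sb_r: float = 6.0
    hb_center: tuple[float, float] = (26.0, -9.0)
    hb_r: float = 3.0

    @property
    def bounding_radius(self) -> float:
        return self.body_a + 2.0

    def local_masks(self, lx: np.ndarray, ly: np.ndarray) -> dict[str, np.ndarray]:
        """Boolean membership of local coordinates in each region.

        Regions are made pairwise disjoint by construction: the thin bands
        sit strictly outside the yolk disk, and the dorsal (DoC) and
        ventral (PVS) bands are separated by ``band_gap``.
        """
        g = self
        body = (lx / g.body_a) ** 2 + (ly / g.body_b) ** 2 <= 1.0
        eye = np.zeros_like(body)
        for ex, ey in g.eye_centers:
            eye |= (lx - ex) ** 2 + (ly - ey) ** 2 <= g.eye_r**2
        yx, yy = g.yolk_center
        dyolk = np.hypot(lx - yx, ly - yy)
        yolk = dyolk <= g.yolk_r
        ring = (dyolk > g.yolk_r) & (dyolk <= g.ring_outer) & body
        doc = ring & (ly - yy <= -g.band_gap)
        pvs = ring & (ly - yy >= g.band_gap)
        sx, sy = g.sb_center
        sb = (lx - sx) ** 2 + (ly - sy) ** 2 <= g.sb_r**2
        hx, hy = g.hb_center
        hb = (lx - hx) ** 2 + (ly - hy) ** 2 <= g.hb_r**2
        masks = {
            "body": body,
            "eye": eye & body,
            "yolk": yolk & body,
            "duct_of_cuvier": doc,
            "perivitelline_space": pvs,
            "swim_bladder": sb & body,
            "hindbrain": hb & body,
        }
        return masks


def _rasterize_larva(
    shape: tuple[int, int],
    position: tuple[float, float],
    heading_deg: float,
    geometry: LarvaGeometry,
    scale: float,
) -> dict[str, np.ndarray]:
    """Full-image boolean masks for one rotated, scaled larva."""
    h, w = shape
    px, py = position
    rad = geometry.bounding_radius * scale
    x0, x1 = max(0, int(px - rad) - 1), min(w, int(px + rad) + 2)
    y0, y1 = max(0, int(py - rad) - 1), min(h, int(py + rad) + 2)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - px, yy - py
    th = math.radians(heading_deg)
    c, s = math.cos(th), math.sin(th)
    # inverse rotation into the larva's local frame
    lx = (c * dx + s * dy) / scale
    ly = (-s * dx + c * dy) / scale
    local = geometry.local_masks(lx, ly)
    out = {}
    for name, m in local.items():
        full = np.zeros(shape, dtype=bool)
        full[y0:y1, x0:x1] = m
        out[name] = full
    return out


def mask_centroid(mask: np.ndarray) -> tuple[float, float]:
    """Arithmetic centroid of a boolean mask as (x, y)."""
    ys, xs = np.nonzero(mask)
    if xs.size == 0:
        raise ValueError("empty mask has no centroid")
    return float(xs.mean()), float(ys.mean())


def generate_plate(
    n_larvae: int,
    image_size: tuple[int, int] = (1200, 1200),
    seed: int = 0,
    *,
    scale: float = 1.0,
    margin: float = 12.0,
    noise_sd: float = 3.0,
    geometry: LarvaGeometry = LarvaGeometry(),
    max_tries: int | None = None,
) -> SyntheticPlate:
    """Randomly place non-touching larvae on a bright-field-like plate.

    Mirrors the bench protocol of scattering ~20 anesthetized larvae on an
    agarose plate with no contact between them.  Placement is rejection
    sampling on bounding circles; an overcrowded plate raises
    :class:`CapacityError` after bounded retries.
    """
    if n_larvae < 1:
        raise ValueError("n_larvae must be >= 1")
    w, h = image_size
    rng = np.random.default_rng(seed)
    rad = geometry.bounding_radius * scale
    if w < 2 * rad + 4 or h < 2 * rad + 4:
        raise CapacityError(f"image {image_size} too small for one larva (r={rad:.0f})")

    centers: list[tuple[float, float]] = []
    headings: list[float] = []
    tries = max_tries if max_tries is not None else 500 * n_larvae
    while len(centers) < n_larvae:
        if tries <= 0:
            raise CapacityError(
                f"placed only {len(centers)}/{n_larvae} larvae without contact"
            )
        tries -= 1
        cx = rng.uniform(rad + 2, w - rad - 2)
        cy = rng.uniform(rad + 2, h - rad - 2)
        if all(math.hypot(cx - ox, cy - oy) >= 2 * rad + margin for ox, oy in centers):
            centers.append((cx, cy))
            headings.append(float(rng.uniform(0.0, 360.0)))

    truth = np.zeros((h, w), dtype=np.int64)  # background = 0
    image = np.full((h, w), FIXTURE_LEVELS["background"], dtype=np.float64)
    larvae = []
    paint_order = [  # least specific first so specific classes overwrite
        "body",
        "hindbrain",
        "perivitelline_space",
        "duct_of_cuvier",
        "yolk",
        "swim_bladder",
        "eye",
    ]
    for (cx, cy), hd in zip(centers, headings):
        masks = _rasterize_larva((h, w), (cx, cy), hd, geometry, scale)
        for name in paint_order:
            m = masks[name]
            truth[m] = CLASSES.index(name)
            image[m] = FIXTURE_LEVELS[name]
        landmarks = {n: mask_centroid(m) for n, m in masks.items() if m.any()}
        larvae.append(
            SyntheticLarva(
                position=mask_centroid(masks["body"]),
                heading_deg=hd,
                region_masks=masks,
                landmarks=landmarks,
            )
        )
    if noise_sd > 0:
        image = image + rng.normal(0.0, noise_sd, size=image.shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    return SyntheticPlate(
        image=image,
        larvae=larvae,
        truth=LabelMap(classes=CLASSES, raster=truth),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Blood-flow particle videos
# ---------------------------------------------------------------------------

def generate_bloodflow_sequence(
    vessel_mask: np.ndarray,
    n_frames: int = 10,
    particle_density: float = 0.08,
    seed: int = 0,
    *,
    noise_sd: float = 1.0,
    speed_px: float = 2.0,
    particle_r: float = 1.6,
    particle_drop: float = 90.0,
    background: float = 200.0,
) -> tuple[FrameSequence, np.ndarray]:
    """Dark blood cells streaming along a vessel over a static background.

    Particles are spaced evenly along the vessel (ordered by projection on
    its principal axis, a proxy for the flow direction) with a seeded phase
    and advance ``speed_px`` per frame, wrapping around.  Pixels outside the
    vessel mask are static up to the seeded sensor noise.
    """
    mask = np.asarray(vessel_mask, dtype=bool)
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    if not mask.any():
        raise ValueError("vessel mask is empty")
    rng = np.random.default_rng(seed)
    h, w = mask.shape
    ys, xs = np.nonzero(mask)
    pts = np.column_stack([xs, ys]).astype(float)
    centered = pts - pts.mean(axis=0)
    # principal axis of the vessel = dominant flow direction
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    proj = centered @ vt[0]
    order = np.argsort(proj, kind="stable")
    path = pts[order]
    n_px = path.shape[0]
    span = max(proj.max() - proj.min(), 1.0)
    idx_per_px = n_px / span  # ordered indices per pixel along the axis

    n_particles = int(round(particle_density * n_px))
    phase = rng.uniform(0.0, n_px)
    starts = (phase + np.arange(n_particles) * (n_px / max(n_particles, 1))) % n_px

    bg = background + rng.normal(0.0, 2.0, size=(h, w))  # static texture
    frames = np.empty((n_frames, h, w), dtype=np.float64)
    yy, xx = np.mgrid[0:h, 0:w]
    for t in range(n_frames):
        frame = bg.copy()
        for s0 in starts:
            i = int(s0 + t * speed_px * idx_per_px) % n_px
            cx, cy = path[i]
            x0, x1 = max(0, int(cx - 3)), min(w, int(cx + 4))
            y0, y1 = max(0, int(cy - 3)), min(h, int(cy + 4))
            d = np.hypot(xx[y0:y1, x0:x1] - cx, yy[y0:y1, x0:x1] - cy)
            stamp = (d <= particle_r) & mask[y0:y1, x0:x1]
            sub = frame[y0:y1, x0:x1]
            sub[stamp] = background - particle_drop
        if noise_sd > 0:
            frame = frame + rng.normal(0.0, noise_sd, size=(h, w))
        frames[t] = np.clip(frame, 0, 255)
    return FrameSequence(frames=np.rint(frames).astype(np.uint8)), mask


# ---------------------------------------------------------------------------
# Focal stacks and touchdown traces
# ---------------------------------------------------------------------------

def generate_focal_stack(
    peak_index: int,
    n_steps: int = 11,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    size: int = 96,
    sigma_scale: float = 1.0,
) -> tuple[FrameSequence, GroundTruthEvent]:
    """Unimodal-sharpness z-stack: a texture defocused away from the peak.

    Frame i is the base texture blurred with Gaussian sigma proportional to
    the distance |i - peak_index|, so any reasonable focus measure is
    unimodal with its maximum at ``peak_index`` when ``noise_sd`` is 0.
    """
    if n_steps < 3:
        raise ValueError("need at least 3 focal steps")
    if not 0 <= peak_index < n_steps:
        raise ValueError("peak_index out of range")
    rng = np.random.default_rng(seed)
    base = rng.uniform(40.0, 215.0, size=(size, size))
    frames = np.empty((n_steps, size, size), dtype=np.float64)
    for i in range(n_steps):
        sigma = sigma_scale * abs(i - peak_index)
        frame = ndimage.gaussian_filter(base, sigma) if sigma > 0 else base.copy()
        if noise_sd > 0:
            frame = frame + rng.normal(0.0, noise_sd, size=frame.shape)
        frames[i] = np.clip(frame, 0, 255)
    return (
        FrameSequence(frames=frames),
        GroundTruthEvent(kind="focus_peak", index=peak_index),
    )


def generate_touchdown_trace(
    touch_index: int,
    n_steps: int = 30,
    *,
    baseline: float = 1.0,
    jump_factor: float = 5.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, GroundTruthEvent]:
    """Sharpness trace for fine descent: low baseline, sudden jump at contact.

    With the focus set just below the needle tip, the image stays blurred
    until the tip reaches the surface, at which point sharpness jumps.
    """
    if not 1 <= touch_index < n_steps:
        raise ValueError("touch_index out of range")
    rng = np.random.default_rng(seed)
    trace = np.full(n_steps, baseline, dtype=np.float64)
    trace[touch_index:] = baseline * jump_factor
    if noise_sd > 0:
        trace = trace + rng.normal(0.0, noise_sd, size=n_steps)
    return np.maximum(trace, 0.0), GroundTruthEvent(kind="touchdown", index=touch_index)


# ---------------------------------------------------------------------------
# Needle-approach puncture sequences
# ---------------------------------------------------------------------------

def generate_puncture_sequence(
    puncture_frame: int = 17,
    drift_px: float = 0.5,
    jump_px: float = 6.0,
    seed: int = 0,
    *,
    n_frames: int = 24,
    size: int = 96,
    noise_sd: float = 0.0,
) -> tuple[FrameSequence, GroundTruthEvent]:
    """Drift-then-jump tissue motion around the advancing needle tip.

    As the needle pushes, the skin texture translates by ``drift_px`` per
    frame; at ``puncture_frame`` the skin retracts rapidly by ``jump_px``
    (opposite the push).  Motion is along +x; frames are windows into a
    larger smooth texture sampled with sub-pixel interpolation.
    """
    if not jump_px > drift_px >= 0:
        raise ValueError("require jump_px > drift_px >= 0")
    if puncture_frame < 2:
        raise ValueError("puncture_frame must be >= 2")
    if puncture_frame >= n_frames:
        raise ValueError("puncture_frame beyond sequence length")
    rng = np.random.default_rng(seed)
    margin = int(math.ceil(drift_px * n_frames + jump_px)) + 8
    base = ndimage.gaussian_filter(
        rng.uniform(0.0, 1.0, size=(size + 8, size + margin)), 1.5
    )
    lo, hi = base.min(), base.max()
    base = 50.0 + 150.0 * (base - lo) / (hi - lo)

    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    frames = np.empty((n_frames, size, size), dtype=np.float64)
    for t in range(n_frames):
        if t < puncture_frame:
            dx = drift_px * t
        else:
            dx = drift_px * puncture_frame - jump_px
        frame = ndimage.map_coordinates(
            base, [yy + 4.0, xx + 4.0 + dx], order=3, mode="nearest"
        )
        if noise_sd > 0:
            frame = frame + rng.normal(0.0, noise_sd, size=frame.shape)
        frames[t] = np.clip(frame, 0, 255)
    return (
        FrameSequence(frames=frames),
        GroundTruthEvent(kind="puncture", index=puncture_frame),
    )


# ---------------------------------------------------------------------------
# Droplets in mineral oil
# ---------------------------------------------------------------------------

def generate_droplet_image(
    diameter_um: float,
    scale_um_per_px: float = 2.0,
    seed: int = 0,
    *,
    size: int | None = None,
    background: float = 220.0,
    foreground: float = 45.0,
    noise_sd: float = 2.0,
) -> tuple[np.ndarray, float]:
    """Dark anti-aliased droplet disk on a bright oil background.

    Returns the image and the true diameter in micrometres.
    """
    if diameter_um <= 0 or scale_um_per_px <= 0:
        raise ValueError("diameter and scale must be positive")
    r = diameter_um / scale_um_per_px / 2.0
    if size is None:
        size = int(math.ceil(2 * r)) + 30
    if 2 * r + 4 > size:
        raise ValueError("droplet larger than image")
    rng = np.random.default_rng(seed)
    cx = size / 2.0 + rng.uniform(-2, 2)
    cy = size / 2.0 + rng.uniform(-2, 2)
    yy, xx = np.mgrid[0:size, 0:size]
    d = np.hypot(xx - cx, yy - cy)
    coverage = np.clip(r + 0.5 - d, 0.0, 1.0)  # anti-aliased edge
    img = background - (background - foreground) * coverage
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8), float(diameter_um)


# ---------------------------------------------------------------------------
# File I/O: PNG / TIFF rasters, YAML sidecars
# ---------------------------------------------------------------------------

def save_image(path: str | Path, image: np.ndarray) -> None:
    """8-bit grayscale PNG (or 16-bit TIFF when the suffix says so)."""
    path = Path(path)
    arr = np.asarray(image)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, arr.astype(np.uint16))
    else:
        Image.fromarray(arr.astype(np.uint8), mode="L").save(path)


def load_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        return tifffile.imread(path)
    return np.asarray(Image.open(path).convert("L"))


def save_labelmap(path: str | Path, labels: LabelMap) -> None:
    """Single-channel indexed PNG; palette follows :data:`PALETTE`."""
    im = Image.fromarray(labels.raster.astype(np.uint8), mode="P")
    pal = []
    for name in labels.classes:
        pal.extend(PALETTE.get(name, (128, 128, 128)))
    im.putpalette(pal + [0] * (768 - len(pal)))
    im.save(Path(path))


def load_labelmap(path: str | Path, classes: tuple[str, ...] = CLASSES) -> LabelMap:
    raster = np.asarray(Image.open(Path(path)), dtype=np.int64)
    return LabelMap(classes=classes, raster=raster)


def save_sequence(path: str | Path, seq: FrameSequence) -> None:
    """Multi-page TIFF (one page per frame)."""
    tifffile.imwrite(Path(path), np.asarray(seq.frames))


def load_sequence(path: str | Path) -> FrameSequence:
    return FrameSequence(frames=tifffile.imread(Path(path)))


def save_plate(plate: SyntheticPlate, outdir: str | Path) -> dict[str, Path]:
    """Write plate image, truth label PNG, and a YAML sidecar of landmarks."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": outdir / "plate.png",
        "truth": outdir / "truth.png",
        "sidecar": outdir / "plate.yaml",
    }
    save_image(paths["image"], plate.image)
    save_labelmap(paths["truth"], plate.truth)
    sidecar = {
        "seed": plate.seed,
        "classes": list(plate.truth.classes),
        "palette": {k: list(v) for k, v in PALETTE.items()},
        "larvae": [
            {
                "position": [round(float(v), 3) for v in lv.position],
                "heading_deg": round(float(lv.heading_deg), 3),
                "landmarks": {
                    k: [round(float(v), 3) for v in pt]
                    for k, pt in lv.landmarks.items()
                },
            }
            for lv in plate.larvae
        ],
    }
    paths["sidecar"].write_text(yaml.safe_dump(sidecar, sort_keys=True))
    return paths


def save_event(path: str | Path, event: GroundTruthEvent) -> None:
    Path(path).write_text(yaml.safe_dump({"kind": event.kind, "index": event.index}))


def load_event(path: str | Path) -> GroundTruthEvent:
    d = yaml.safe_load(Path(path).read_text())
    return GroundTruthEvent(kind=d["kind"], index=int(d["index"]))
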