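"""Skin-puncture detection during needle advance.

Two detection routes.  The reference route tracks anchor points seeded on
high-texture locations around the needle tip: as the needle pushes, the
points move collectively in small increments, but at puncture the skin
retracts rapidly and the per-frame displacement jumps.  The alternative
route stacks each triplet of subsequent grayscale frames into a 3-channel
image and asks a pluggable classifier for a per-triplet puncture score; the
trained network of the production system is not reproduced here — an
oracle stub and a toy logistic model on frame-difference features stand
behind the same interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Protocol

import numpy as np
from skimage.feature import corner_peaks, corner_shi_tomasi, match_template

from .fixtures import FrameSequence

#: Jump factor: puncture fires when the median displacement exceeds
#: k x the median of prior per-frame medians.
DEFAULT_JUMP_FACTOR = 4.0
#: Absolute displacement floor (px) so pure noise never fires.
DEFAULT_FLOOR_PX = 2.0
#: Patch half-size for NCC tracking.
PATCH_RADIUS = 5
#: Search half-size around the previous position.
SEARCH_RADIUS = 9
#: NCC score below which a point is declared lost.
MATCH_FLOOR = 0.5


class InsufficientTextureError(RuntimeError):
    def __init__(self, found: int, wanted: int) -> None:
        super().__init__(f"found only {found} textured anchor candidates, need {wanted}")
        self.found = found


@dataclass(frozen=True)
class PunctureEvent:
    frame_index: int
    statistic: float
    method: str  # anchor | classifier


@dataclass
class AnchorPointSet:
    """Tracked points near the needle tip plus their displacement history."""

    points: np.ndarray  # (N, 2) float (x, y)
    alive: np.ndarray  # (N,) bool
    history: list[np.ndarray] = field(default_factory=list)  # per-frame |disp|
    _prev_frame: np.ndarray | None = None

    @property
    def median_displacements(self) -> list[float]:
        """Per-frame median displacement over surviving points."""
        out = []
        for d in self.history:
            vals = d[np.isfinite(d)]
            out.append(float(np.median(vals)) if vals.size else 0.0)
        return out


def seed_anchors(
    image: np.ndarray,
    tip: tuple[float, float],
    n: int = 8,
    radius: float = 30.0,
) -> AnchorPointSet:
    """Choose n high-texture anchor points within ``radius`` of the tip.

    Candidates are Shi-Tomasi corner maxima; only locations whose response
    exceeds the 60th percentile of the response inside the search disk
    qualify, so a blank image raises rather than seeding untrackable points.
    """
    if n < 4:
        raise ValueError("need at least 4 anchor points")
    img = np.asarray(image, dtype=np.float64)
    h, w = img.shape
    tx, ty = tip
    if not (0 <= tx < w and 0 <= ty < h):
        raise ValueError("tip outside image")
    response = corner_shi_tomasi(img)
    yy, xx = np.mgrid[0:h, 0:w]
    disk = np.hypot(xx - tx, yy - ty) <= radius
    # keep clear of borders so tracking patches fit
    m = PATCH_RADIUS + 1
    disk[:m], disk[-m:], disk[:, :m], disk[:, -m:] = False, False, False, False
    if not disk.any():
        raise InsufficientTextureError(0, n)
    floor = np.percentile(response[disk], 60.0)
    masked = np.where(disk, response, -np.inf)
    peaks = corner_peaks(
        masked, min_distance=3, threshold_abs=max(floor, 1e-12), num_peaks=4 * n
    )
    if peaks.shape[0] < n:
        raise InsufficientTextureError(peaks.shape[0], n)
    # strongest n, deterministic order
    strengths = response[peaks[:, 0], peaks[:, 1]]
    order = np.argsort(-strengths, kind="stable")[:n]
    pts = peaks[order][:, ::-1].astype(np.float64)  # (x, y)
    return AnchorPointSet(
        points=pts, alive=np.ones(n, dtype=bool), _prev_frame=img
    )


def _ncc_match(
    prev: np.ndarray, cur: np.ndarray, pt: tuple[float, float]
) -> tuple[tuple[float, float], float]:
    """Track one point by normalized cross-correlation with sub-pixel fit."""
    h, w = prev.shape
    x0, y0 = int(round(pt[0])), int(round(pt[1]))
    p = PATCH_RADIUS
    tmpl = prev[y0 - p : y0 + p + 1, x0 - p : x0 + p + 1]
    s = SEARCH_RADIUS
    ya, yb = max(0, y0 - p - s), min(h, y0 + p + s + 1)
    xa, xb = max(0, x0 - p - s), min(w, x0 + p + s + 1)
    win = cur[ya:yb, xa:xb]
    if win.shape[0] < 2 * p + 1 or win.shape[1] < 2 * p + 1:
        return pt, -1.0

    if tmpl.std() == 0:
        return pt, -1.0
    scores = match_template(win, tmpl)  # normalized cross-correlation
    oh, ow = scores.shape
    iy, ix = np.unravel_index(np.argmax(scores), scores.shape)
    best = scores[iy, ix]

    def subpix(vals: np.ndarray, i: int, size: int) -> float:
        if 0 < i < size - 1:
            a, b, c = vals
            denom = a - 2 * b + c
            if denom < 0:
                return float(np.clip((a - c) / (2 * denom), -0.5, 0.5))
        return 0.0

    oy = subpix(scores[max(iy - 1, 0) : iy + 2, ix], iy, oh)
    ox = subpix(scores[iy, max(ix - 1, 0) : ix + 2], ix, ow)
    nx = xa + ix + p + ox
    ny = ya + iy + p + oy
    return (float(nx), float(ny)), float(best)


def track_anchors(anchors: AnchorPointSet, next_frame: np.ndarray) -> AnchorPointSet:
    """Advance all surviving anchors into the next frame by NCC matching.

    Each point's displacement magnitude is appended to the history; a point
    whose best match score falls below the floor is flagged lost and
    excluded from statistics from then on.
    """
    if anchors._prev_frame is None:
        raise ValueError("anchor set has no retained previous frame")
    cur = np.asarray(next_frame, dtype=np.float64)
    prev = anchors._prev_frame
    disp = np.full(anchors.points.shape[0], np.nan)
    new_pts = anchors.points.copy()
    for i, pt in enumerate(anchors.points):
        if not anchors.alive[i]:
            continue
        (nx, ny), score = _ncc_match(prev, cur, (pt[0], pt[1]))
        if score < MATCH_FLOOR:
            anchors.alive[i] = False
            continue
        # the template was extracted at the rounded position; its measured
        # motion is applied to the sub-pixel position to avoid re-rounding
        # the point every frame
        mx = nx - round(pt[0])
        my = ny - round(pt[1])
        disp[i] = float(np.hypot(mx, my))
        new_pts[i] = (pt[0] + mx, pt[1] + my)
    anchors.points = new_pts
    anchors.history.append(disp)
    anchors._prev_frame = cur
    return anchors


def detect_puncture_anchor(
    anchors: AnchorPointSet,
    k: float = DEFAULT_JUMP_FACTOR,
    floor_px: float = DEFAULT_FLOOR_PX,
) -> PunctureEvent | None:
    """First frame where the collective displacement jumps.

    Fires at the first frame t (with >= 2 frames of prior history) where
    the median displacement >= max(k x median of prior per-frame medians,
    ``floor_px``).  Steady drift stays below the floor and never fires.
    """
    if k <= 1:
        raise ValueError("jump factor k must exceed 1")
    medians = anchors.median_displacements
    for t in range(2, len(medians)):
        prior = np.median(medians[:t])
        thresh = max(k * prior, floor_px)
        if medians[t] >= thresh:
            # history index t is the displacement from frame t to t+1
            return PunctureEvent(
                frame_index=t + 1, statistic=medians[t], method="anchor"
            )
    return None


def run_anchor_detector(
    seq: FrameSequence,
    tip: tuple[float, float],
    n: int = 8,
    radius: float = 30.0,
    k: float = DEFAULT_JUMP_FACTOR,
    floor_px: float = DEFAULT_FLOOR_PX,
) -> tuple[PunctureEvent | None, AnchorPointSet]:
    """Seed on the first frame, track through the sequence, detect the jump."""
    anchors = seed_anchors(np.asarray(seq[0]), tip, n=n, radius=radius)
    event = None
    for t in range(1, len(seq)):
        track_anchors(anchors, np.asarray(seq[t]))
        if event is None:
            event = detect_puncture_anchor(anchors, k=k, floor_px=floor_px)
            if event is not None:
                break
    return event, anchors


# ---------------------------------------------------------------------------
# Frame-triplet classification route
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TripletImage:
    """Frames t-2, t-1, t stacked as channels; ``index`` = t."""

    channels: np.ndarray  # (H, W, 3)
    index: int

    def __post_init__(self) -> None:
        c = np.asarray(self.channels)
        if c.ndim != 3 or c.shape[2] != 3:
            raise ValueError("triplet must be (H, W, 3)")
        if self.index < 2:
            raise ValueError("triplet index must be >= 2")


def build_triplets(seq: FrameSequence) -> Iterator[TripletImage]:
    """Sliding 3-frame window: one triplet per frame t >= 2 (n - 2 total)."""
    frames = np.asarray(seq.frames)
    for t in range(2, frames.shape[0]):
        yield TripletImage(
            channels=np.stack([frames[t - 2], frames[t - 1], frames[t]], axis=-1),
            index=t,
        )


class PunctureModel(Protocol):
    """Anything that scores a triplet with a puncture probability."""

    def predict(self, triplet: TripletImage) -> float: ...


class OraclePunctureModel:
    """Stub that knows the ground-truth puncture frame (for tests/simulation)."""

    def __init__(self, puncture_frame: int) -> None:
        self.puncture_frame = puncture_frame

    def predict(self, triplet: TripletImage) -> float:
        return 1.0 if triplet.index == self.puncture_frame else 0.0


def triplet_features(triplet: TripletImage) -> np.ndarray:
    """Motion summary of a triplet: recent vs. preceding frame change.

    A puncture shows as a large t-1 -> t change after small t-2 -> t-1
    changes, so the mean absolute differences and their log-ratio separate
    puncture triplets from drift triplets.
    """
    c = triplet.channels.astype(np.float64)
    d01 = np.abs(c[..., 1] - c[..., 0]).mean()
    d12 = np.abs(c[..., 2] - c[..., 1]).mean()
    ratio = np.log((d12 + 1e-6) / (d01 + 1e-6))
    return np.array([d01, d12, ratio])


class ToyPunctureClassifier:
    """Logistic regression on :func:`triplet_features`.

    A deliberately small stand-in exercising the classification route
    end-to-end; the pluggable interface accepts any scoring model.
    """

    def __init__(self) -> None:
        from sklearn.linear_model import LogisticRegression

        self._clf = LogisticRegression(max_iter=1000)
        self.trained = False

    def fit(self, triplets: Iterable[TripletImage], labels: Iterable[int]) -> None:
        x = np.array([triplet_features(t) for t in triplets])
        y = np.asarray(list(labels))
        self._clf.fit(x, y)
        self.trained = True

    def predict(self, triplet: TripletImage) -> float:
        if not self.trained:
            raise RuntimeError("classifier not trained")
        return float(self._clf.predict_proba([triplet_features(triplet)])[0, 1])


def classify_puncture(
    model: PunctureModel, seq: FrameSequence, cutoff: float = 0.5
) -> PunctureEvent | None:
    """Session-level decision: first triplet whose score passes the cutoff."""
    for triplet in build_triplets(seq):
        score = model.predict(triplet)
        if score >= cutoff:
            return PunctureEvent(
                frame_index=triplet.index, statistic=score, method="classifier"
            )
    return None
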