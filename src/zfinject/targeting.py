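"""From a segmented larva to a needle target.

Larvae are scattered on the plate in arbitrary positions and orientations,
so injection sites are expressed in a larva-attached coordinate frame
rather than in plate pixels.  The frame is skewed (non-orthogonal): its
origin is the centroid of the eyes, and its two basis vectors run from the
eyes to the yolk centroid and from the eyes to the swim-bladder centroid.
Any user-chosen site coordinate (a, b) then maps affinely to plate pixels,
and the whole construction is equivariant under rigid motion of the larva.

Angles are degrees measured from +x toward +y (y down), normalized to
[0, 360).  The larva heading is the direction from the eyes centroid to the
swim-bladder centroid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .segmentation import ComponentResult, LabelMap, largest_component

#: |cross(u, v)| / (|u||v|) below this declares the frame degenerate.
COLLINEARITY_TOL = 1e-3


class MissingLandmarkError(ValueError):
    """A required anatomy class is absent from the label map."""


class SiteNotFoundError(ValueError):
    """The requested injection-site structure is absent."""


class DegenerateFrameError(ValueError):
    """Landmarks are (near-)collinear; no usable coordinate frame."""


@dataclass(frozen=True)
class LandmarkSet:
    """Anatomical centroids in plate pixels: eyes, yolk, swim bladder."""

    eyes: tuple[float, float]
    yolk: tuple[float, float]
    swim_bladder: tuple[float, float]

    def __post_init__(self) -> None:
        pts = [self.eyes, self.yolk, self.swim_bladder]
        if not all(np.isfinite(p).all() for p in map(np.asarray, pts)):
            raise ValueError("landmarks must be finite")
        for i in range(3):
            for j in range(i + 1, 3):
                if np.allclose(pts[i], pts[j]):
                    raise ValueError("landmarks must be pairwise distinct")


@dataclass(frozen=True)
class SkewedFrame:
    """origin + a*u + b*v: the larva-attached affine frame."""

    origin: tuple[float, float]
    u: tuple[float, float]
    v: tuple[float, float]

    def __post_init__(self) -> None:
        u, v = np.asarray(self.u), np.asarray(self.v)
        cross = abs(u[0] * v[1] - u[1] * v[0])
        norm = np.linalg.norm(u) * np.linalg.norm(v)
        if norm == 0 or cross / norm < COLLINEARITY_TOL:
            raise DegenerateFrameError("basis vectors are (near-)collinear")


@dataclass(frozen=True)
class NeedlePose:
    tip: tuple[float, float]
    angle_deg: float
    site: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "angle_deg", normalize_angle(self.angle_deg))


def normalize_angle(deg: float) -> float:
    return float(deg) % 360.0


# ---------------------------------------------------------------------------
# Landmarks and the skewed frame
# ---------------------------------------------------------------------------

def landmark_centroids(
    labels: LabelMap, swim_bladder_class: str = "swim_bladder"
) -> LandmarkSet:
    """Arithmetic centroids of the eyes (union of both), yolk, swim bladder.

    At stages or views where the swim bladder is not visible, the
    perivitelline space serves as the third landmark
    (``swim_bladder_class="perivitelline_space"``).
    """
    pts = {}
    for name in ("eye", "yolk", swim_bladder_class):
        mask = labels.mask(name)
        if not mask.any():
            raise MissingLandmarkError(f"class {name!r} absent from label map")
        ys, xs = np.nonzero(mask)
        pts[name] = (float(xs.mean()), float(ys.mean()))
    return LandmarkSet(
        eyes=pts["eye"], yolk=pts["yolk"], swim_bladder=pts[swim_bladder_class]
    )


def build_skewed_frame(lm: LandmarkSet) -> SkewedFrame:
    """Frame with origin at the eyes: u = yolk - eyes, v = swim_bladder - eyes."""
    ex, ey = lm.eyes
    return SkewedFrame(
        origin=lm.eyes,
        u=(lm.yolk[0] - ex, lm.yolk[1] - ey),
        v=(lm.swim_bladder[0] - ex, lm.swim_bladder[1] - ey),
    )


def to_plate(frame: SkewedFrame, ab: tuple[float, float]) -> tuple[float, float]:
    """Map site coordinates (a, b) to plate pixels: origin + a*u + b*v."""
    a, b = ab
    return (
        frame.origin[0] + a * frame.u[0] + b * frame.v[0],
        frame.origin[1] + a * frame.u[1] + b * frame.v[1],
    )


def from_plate(frame: SkewedFrame, xy: tuple[float, float]) -> tuple[float, float]:
    """Exact inverse of :func:`to_plate` (2x2 solve)."""
    m = np.array([[frame.u[0], frame.v[0]], [frame.u[1], frame.v[1]]])
    rhs = np.array([xy[0] - frame.origin[0], xy[1] - frame.origin[1]])
    a, b = np.linalg.solve(m, rhs)
    return float(a), float(b)


def orientation_and_angle(lm: LandmarkSet, configured_angle_deg: float) -> float:
    """Needle yaw for a larva in arbitrary orientation.

    The heading is the direction from the eyes centroid to the swim-bladder
    centroid; the configured offset (the angle the operator chose on a
    reference larva) is added and the result normalized to [0, 360).
    """
    dx = lm.swim_bladder[0] - lm.eyes[0]
    dy = lm.swim_bladder[1] - lm.eyes[1]
    if math.hypot(dx, dy) == 0:
        raise DegenerateFrameError("eyes and swim bladder coincide")
    heading = math.degrees(math.atan2(dy, dx))
    return normalize_angle(heading + configured_angle_deg)


# ---------------------------------------------------------------------------
# Site-specific targets
# ---------------------------------------------------------------------------

def _largest_mask(labels: LabelMap, cls: str) -> np.ndarray:
    comp: ComponentResult = largest_component(labels, cls)
    if not comp.present:
        raise SiteNotFoundError(f"no {cls!r} region found")
    return comp.mask


#: Masks above this size fall back to the centroid projection rather than
#: an all-pairs geodesic computation.
_GEODESIC_LIMIT = 20000


def _medial_axis_midpoint(mask: np.ndarray) -> tuple[float, float]:
    """Middle of a band-shaped mask: its geodesic center.

    The geodesic center — the mask pixel whose maximal within-mask geodesic
    distance to any other mask pixel is smallest — is the arc-length middle
    of an elongated band, and unlike thinning-based skeletons it is exactly
    equivariant under grid rotations and reflections.  Tied centers are
    averaged.  Oversized masks fall back to the pixel nearest the centroid.
    """
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import dijkstra

    ys, xs = np.nonzero(mask)
    n = xs.size
    if 3 <= n <= _GEODESIC_LIMIT:
        h, w = mask.shape
        idx = -np.ones((h, w), dtype=np.int64)
        idx[ys, xs] = np.arange(n)
        rows, cols, wts = [], [], []
        for dy, dx, cost in (
            (0, 1, 1.0), (1, 0, 1.0), (1, 1, math.sqrt(2)), (1, -1, math.sqrt(2)),
        ):
            ya, xa = ys + dy, xs + dx
            ok = (ya >= 0) & (ya < h) & (xa >= 0) & (xa < w)
            ok[ok] &= idx[ya[ok], xa[ok]] >= 0
            rows.append(idx[ys[ok], xs[ok]])
            cols.append(idx[ya[ok], xa[ok]])
            wts.append(np.full(ok.sum(), cost))
        graph = coo_matrix(
            (np.concatenate(wts), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        )
        dist = dijkstra(graph, directed=False)
        ecc = np.where(np.isfinite(dist), dist, 0.0).max(axis=1)
        best = ecc.min()
        sel = ecc <= best + 1e-9
        return float(xs[sel].mean()), float(ys[sel].mean())
    # fallback: mask pixel nearest the centroid
    cx, cy = xs.mean(), ys.mean()
    i = int(np.argmin((xs - cx) ** 2 + (ys - cy) ** 2))
    return float(xs[i]), float(ys[i])


def _nearest_mask_pixel(
    mask: np.ndarray, point: tuple[float, float]
) -> tuple[float, float]:
    ys, xs = np.nonzero(mask)
    i = int(np.argmin((xs - point[0]) ** 2 + (ys - point[1]) ** 2))
    return float(xs[i]), float(ys[i])


def _frame_heading(frame: SkewedFrame) -> float:
    """Larva heading from the frame itself: the direction of v (eyes -> swim bladder)."""
    return normalize_angle(math.degrees(math.atan2(frame.v[1], frame.v[0])))


def doc_target(
    flow_labels: LabelMap,
    frame: SkewedFrame,
    user_point: tuple[float, float] | None = None,
    angle_offset_deg: float = 0.0,
) -> NeedlePose:
    """Needle target on the duct of Cuvier.

    The default site is the middle of the DoC, realized as the medial-axis
    midpoint of the largest recognized DoC component.  With ``user_point``
    (in skewed coordinates) any point along the duct can be chosen: it is
    projected to the nearest DoC pixel.
    """
    mask = _largest_mask(flow_labels, "duct_of_cuvier")
    if user_point is not None:
        xy = to_plate(frame, user_point)
        xi, yi = int(round(xy[0])), int(round(xy[1]))
        h, w = mask.shape
        if 0 <= yi < h and 0 <= xi < w and mask[yi, xi]:
            tip = xy
        else:
            tip = _nearest_mask_pixel(mask, xy)
    else:
        tip = _medial_axis_midpoint(mask)
    angle = normalize_angle(_frame_heading(frame) + angle_offset_deg)
    return NeedlePose(tip=tip, angle_deg=angle, site="duct_of_cuvier")


def pvs_pose(
    labels: LabelMap,
    frame: SkewedFrame,
    angle_deg: float = 45.0,
    entry: tuple[float, float] | None = None,
) -> NeedlePose:
    """Needle tip on the upper border of the perivitelline space.

    The recommended entry angle is 30-60 degrees relative to the larva
    heading; values outside that range are rejected.  "Upper" is defined in
    the larva's own frame: among boundary pixels of the PVS component, those
    on the positive-b (v-axis) side; the tip is the one nearest the
    configured entry coordinate (default: center of the upper border).
    """
    if not 30.0 <= angle_deg <= 60.0:
        raise ValueError("PVS entry angle must lie in [30, 60] degrees")
    mask = _largest_mask(labels, "perivitelline_space")
    inner = np.zeros_like(mask)
    inner[1:-1, 1:-1] = (
        mask[1:-1, 1:-1]
        & mask[:-2, 1:-1]
        & mask[2:, 1:-1]
        & mask[1:-1, :-2]
        & mask[1:-1, 2:]
    )
    boundary = mask & ~inner
    ys, xs = np.nonzero(boundary)
    ab = np.array([from_plate(frame, (x, y)) for x, y in zip(xs, ys)])
    upper = ab[:, 1] >= np.median(ab[:, 1])
    cand = ab[upper]
    cand_xy = np.column_stack([xs[upper], ys[upper]])
    target_ab = np.asarray(entry if entry is not None else cand.mean(axis=0))
    i = int(np.argmin(((cand - target_ab) ** 2).sum(axis=1)))
    tip = (float(cand_xy[i, 0]), float(cand_xy[i, 1]))
    angle = normalize_angle(_frame_heading(frame) + angle_deg)
    return NeedlePose(tip=tip, angle_deg=angle, site="perivitelline_space")


def hindbrain_pose(
    start_point: tuple[float, float], direction_point: tuple[float, float]
) -> NeedlePose:
    """Pose from an annotated start point and direction point.

    The edge-based predictor that proposes the two points is pluggable;
    this consumes them: tip = start, yaw = direction of (direction - start).
    """
    dx = direction_point[0] - start_point[0]
    dy = direction_point[1] - start_point[1]
    if math.hypot(dx, dy) == 0:
        raise ValueError("start and direction points coincide")
    return NeedlePose(
        tip=(float(start_point[0]), float(start_point[1])),
        angle_deg=math.degrees(math.atan2(dy, dx)),
        site="hindbrain",
    )
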