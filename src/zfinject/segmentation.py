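"""Per-pixel anatomy segmentation machinery.

The robot's scene understanding is a semantic segmentation of the plate
image into anatomy classes (eyes, yolk, body, swim bladder, ...).  This
module implements everything around the network: resolution of overlapping
polygon annotations into a single label per pixel, the per-pixel argmax
decision, tiling of large images with overlap, stitching of tile
segmentations, and a six-transform test-time-augmentation consensus.  The
segmenter itself is a pluggable callable mapping an image to a probability
map, so a classical oracle, a toy model, or a real network can sit behind
the same interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np
from skimage.draw import polygon2mask
from skimage.measure import label as cc_label

# Canonical anatomy classes, index 0 = background.  The raster of a
# LabelMap stores indices into this (or a user-supplied) list.
CLASSES: tuple[str, ...] = (
    "background",
    "body",
    "hindbrain",
    "perivitelline_space",
    "duct_of_cuvier",
    "yolk",
    "swim_bladder",
    "eye",
)

# Annotation priority: more anatomically specific classes win when regions
# overlap (an eye pixel is also a body pixel; "eye" carries more
# information).  Most specific first.
PRIORITY: tuple[str, ...] = (
    "eye",
    "swim_bladder",
    "yolk",
    "duct_of_cuvier",
    "perivitelline_space",
    "hindbrain",
    "body",
    "background",
)


@dataclass(frozen=True)
class LabelMap:
    """Per-pixel class raster; the segmentation currency of the pipeline.

    ``raster`` is an (H, W) integer array of indices into ``classes``.
    """

    classes: tuple[str, ...]
    raster: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.raster)
        if r.ndim != 2:
            raise ValueError("label raster must be 2-D")
        n = len(self.classes)
        if r.size and (r.min() < 0 or r.max() >= n):
            raise ValueError(f"label indices must lie in [0, {n})")
        object.__setattr__(self, "raster", r.astype(np.int64, copy=False))

    @property
    def shape(self) -> tuple[int, int]:
        return self.raster.shape  # type: ignore[return-value]

    def index_of(self, name: str) -> int:
        return self.classes.index(name)

    def mask(self, name: str) -> np.ndarray:
        """Boolean mask of one class."""
        return self.raster == self.index_of(name)


@dataclass(frozen=True)
class ProbabilityMap:
    """(H, W, N) per-pixel class scores."""

    classes: tuple[str, ...]
    raster: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.raster, dtype=np.float64)
        if r.ndim != 3 or r.shape[2] != len(self.classes):
            raise ValueError("probability raster must be (H, W, N)")
        object.__setattr__(self, "raster", r)

    @property
    def shape(self) -> tuple[int, int]:
        return self.raster.shape[:2]  # type: ignore[return-value]


@dataclass
class AnnotationSet:
    """Polygon annotations with a class-priority total order.

    ``regions`` is a list of ``(polygon, class_name)`` where polygon is an
    (M, 2) array of (x, y) vertices.  ``priority`` orders classes most
    specific first; every annotated class must appear in it.
    """

    regions: list[tuple[np.ndarray, str]]
    priority: Sequence[str] = field(default_factory=lambda: PRIORITY)

    def __post_init__(self) -> None:
        for poly, name in self.regions:
            if np.asarray(poly).shape[0] < 3:
                raise ValueError(f"polygon for class {name!r} has < 3 vertices")
            if name not in self.priority:
                raise ValueError(f"class {name!r} missing from priority order")


@dataclass(frozen=True)
class TilingScheme:
    """Tile geometry for piecewise inference on large images."""

    tile_size: int = 304
    overlap: int = 50

    def __post_init__(self) -> None:
        if not 0 <= self.overlap < self.tile_size:
            raise ValueError("require 0 <= overlap < tile_size")

    @property
    def stride(self) -> int:
        return self.tile_size - self.overlap


class Tile(NamedTuple):
    data: np.ndarray
    offset: tuple[int, int]  # (x, y) of top-left corner in the image
    pad: tuple[int, int]  # (pad_x, pad_y) reflect-padding applied (small images)


#: A segmenter maps an (H, W) grayscale image to a ProbabilityMap of the
#: same spatial size.  Any callable with this signature plugs in.
Segmenter = Callable[[np.ndarray], ProbabilityMap]


# ---------------------------------------------------------------------------
# Annotation post-processing
# ---------------------------------------------------------------------------

def resolve_overlaps(annotations: AnnotationSet, image_size: tuple[int, int]) -> LabelMap:
    """Collapse overlapping polygon annotations into one class per pixel.

    Each pixel takes the highest-priority (most specific) class among the
    regions covering it; uncovered pixels are background.  Painting regions
    from least to most specific makes the result independent of the order
    in which regions were annotated.

    Parameters
    ----------
    image_size:
        (width, height) of the target raster.
    """
    w, h = image_size
    classes = tuple(reversed(annotations.priority))  # least specific first
    raster = np.zeros((h, w), dtype=np.int64)
    # class indices follow the canonical list when possible
    out_classes = _ordered_classes(annotations.priority)
    bg = out_classes.index("background") if "background" in out_classes else 0
    raster[:] = bg
    for name in classes:
        if name == "background":
            continue
        idx = out_classes.index(name)
        for poly, cname in annotations.regions:
            if cname != name:
                continue
            # polygon2mask takes (row, col) = (y, x) vertices
            pts = np.asarray(poly, dtype=float)[:, ::-1]
            mask = polygon2mask((h, w), pts)
            raster[mask] = idx
    return LabelMap(classes=out_classes, raster=raster)


def _ordered_classes(priority: Sequence[str]) -> tuple[str, ...]:
    """Class list for output label maps: canonical order where it applies."""
    if set(priority) <= set(CLASSES):
        return tuple(c for c in CLASSES if c in priority)
    # unknown classes: background first, then priority order
    rest = [c for c in priority if c != "background"]
    return ("background", *rest)


# ---------------------------------------------------------------------------
# Inference-side machinery
# ---------------------------------------------------------------------------

def argmax_classes(prob: ProbabilityMap) -> LabelMap:
    """Per-pixel class decision: index of the maximal score.

    Ties break toward the lowest class index (numpy argmax picks the first
    maximum).
    """
    r = prob.raster
    if not np.all(np.isfinite(r)):
        raise ValueError("probability map contains non-finite scores")
    return LabelMap(classes=prob.classes, raster=np.argmax(r, axis=2))


def tile_image(image: np.ndarray, scheme: TilingScheme = TilingScheme()) -> list[Tile]:
    """Cut an image into overlapping tiles for piecewise segmentation.

    Tiles are laid out at stride ``tile_size - overlap`` per axis; the last
    tile on each axis is clamped flush to the image edge so coverage is
    exact.  Images smaller than a tile are reflect-padded up to tile size
    (pad amounts recorded on the tile) and crop back after stitching.
    """
    img = np.asarray(image)
    h, w = img.shape[:2]
    t = scheme.tile_size
    pad_y = max(0, t - h)
    pad_x = max(0, t - w)
    if pad_x or pad_y:
        widths = [(0, pad_y), (0, pad_x)] + [(0, 0)] * (img.ndim - 2)
        img = np.pad(img, widths, mode="reflect")
        h, w = img.shape[:2]

    def offsets(size: int) -> list[int]:
        offs = list(range(0, size - t + 1, scheme.stride))
        if offs[-1] != size - t:
            offs.append(size - t)
        return offs

    tiles = []
    for oy in offsets(h):
        for ox in offsets(w):
            tiles.append(Tile(img[oy : oy + t, ox : ox + t], (ox, oy), (pad_x, pad_y)))
    return tiles


def stitch_segmentations(
    tiles: Sequence[tuple[ProbabilityMap, tuple[int, int]]],
    scheme: TilingScheme,
    image_size: tuple[int, int],
) -> ProbabilityMap:
    """Reassemble tile probability maps into a full-image map.

    Where tiles overlap, each pixel takes the scores from the tile whose
    center is nearest — a hard assignment that encodes distrust of
    predictions near tile edges, where a U-Net sees a truncated
    neighbourhood.
    """
    w, h = image_size
    if not tiles:
        raise ValueError("no tiles to stitch")
    classes = tiles[0][0].classes
    n = len(classes)
    t = scheme.tile_size

    yy, xx = np.mgrid[0:h, 0:w]
    best_d2 = np.full((h, w), np.inf)
    winner = np.full((h, w), -1, dtype=np.int64)
    for i, (_, (ox, oy)) in enumerate(tiles):
        cx, cy = ox + (t - 1) / 2.0, oy + (t - 1) / 2.0
        covered = (xx >= ox) & (xx < ox + t) & (yy >= oy) & (yy < oy + t)
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2
        take = covered & (d2 < best_d2)
        best_d2[take] = d2[take]
        winner[take] = i
    if (winner < 0).any():
        raise ValueError("tiles do not cover the image")

    out = np.empty((h, w, n), dtype=np.float64)
    for i, (pm, (ox, oy)) in enumerate(tiles):
        sel = winner == i
        if not sel.any():
            continue
        ys, xs = np.nonzero(sel)
        out[ys, xs] = pm.raster[ys - oy, xs - ox]
    return ProbabilityMap(classes=classes, raster=out)


def segment_tiled(
    image: np.ndarray,
    segmenter: Segmenter,
    scheme: TilingScheme = TilingScheme(),
) -> ProbabilityMap:
    """Tile → segment each tile → stitch; crops away any small-image padding."""
    img = np.asarray(image)
    h, w = img.shape[:2]
    tiles = tile_image(img, scheme)
    pad_x, pad_y = tiles[0].pad
    seg_tiles = [(segmenter(tl.data), tl.offset) for tl in tiles]
    stitched = stitch_segmentations(seg_tiles, scheme, (w + pad_x, h + pad_y))
    if pad_x or pad_y:
        stitched = ProbabilityMap(stitched.classes, stitched.raster[:h, :w])
    return stitched


# ---------------------------------------------------------------------------
# Test-time-augmentation consensus
# ---------------------------------------------------------------------------

# The six symmetries used for consensus: identity, the three non-trivial
# rotations, and the two axis reflections.  Each entry is
# (forward, inverse) acting on 2-D arrays.
TTA_TRANSFORMS: tuple[tuple[Callable, Callable], ...] = (
    (lambda a: a, lambda a: a),
    (lambda a: np.rot90(a, 1), lambda a: np.rot90(a, -1)),
    (lambda a: np.rot90(a, 2), lambda a: np.rot90(a, -2)),
    (lambda a: np.rot90(a, 3), lambda a: np.rot90(a, -3)),
    (np.fliplr, np.fliplr),
    (np.flipud, np.flipud),
)


def vote_consensus(
    votes: np.ndarray, classes: tuple[str, ...], priority: Sequence[str] = PRIORITY
) -> np.ndarray:
    """Per-pixel majority vote over a (K, H, W) stack of label rasters.

    Ties break by the annotation priority order (most specific class wins),
    then by lowest class index for classes outside the priority list.
    """
    k, h, w = votes.shape
    n = len(classes)
    counts = np.zeros((n, h, w), dtype=np.int32)
    for i in range(n):
        counts[i] = (votes == i).sum(axis=0)
    # evaluate candidates in tie-break order; argmax picks the first maximum
    order = _tiebreak_order(classes, priority)
    best = np.argmax(counts[order], axis=0)
    return np.asarray(order)[best]


def _tiebreak_order(classes: tuple[str, ...], priority: Sequence[str]) -> list[int]:
    ranked = [classes.index(c) for c in priority if c in classes]
    rest = [i for i in range(len(classes)) if i not in ranked]
    return ranked + rest


def tta_consensus(
    segmenter: Segmenter,
    image: np.ndarray,
    transforms: Sequence[tuple[Callable, Callable]] = TTA_TRANSFORMS,
    priority: Sequence[str] = PRIORITY,
) -> LabelMap:
    """Segment six symmetry-transformed copies and take a per-pixel vote.

    Non-square images are reflect-padded to square so the 90° rotations are
    well defined, and cropped back afterwards.
    """
    img = np.asarray(image)
    h, w = img.shape[:2]
    s = max(h, w)
    if h != w:
        img = np.pad(img, ((0, s - h), (0, s - w)), mode="reflect")

    votes = []
    classes = None
    for fwd, inv in transforms:
        pm = segmenter(fwd(img))
        if pm.shape != (s, s):
            raise ValueError(
                f"segmenter returned {pm.shape}, expected {(s, s)}"
            )
        classes = pm.classes
        labels = np.argmax(pm.raster, axis=2)
        votes.append(inv(labels))
    stack = np.stack(votes)
    raster = vote_consensus(stack, classes, priority)
    return LabelMap(classes=classes, raster=raster[:h, :w])


# ---------------------------------------------------------------------------
# Component selection and training augmentation
# ---------------------------------------------------------------------------

class ComponentResult(NamedTuple):
    mask: np.ndarray
    present: bool


def largest_component(labels: LabelMap, target_class: str) -> ComponentResult:
    """Largest 8-connected component of one class.

    The network can hallucinate several disjoint regions for a class; the
    one with the most pixels is kept.  An absent class yields an empty mask
    with ``present=False``.
    """
    mask = labels.mask(target_class)
    if not mask.any():
        return ComponentResult(np.zeros_like(mask), False)
    comp = cc_label(mask, connectivity=2)
    sizes = np.bincount(comp.ravel())
    sizes[0] = 0
    return ComponentResult(comp == np.argmax(sizes), True)


def augment(
    image: np.ndarray, labels: LabelMap, seed: int
) -> tuple[np.ndarray, LabelMap]:
    """Seeded training-time augmentation applied consistently to a pair.

    Geometric: random flip, 90°-rotation, integer shift. Photometric:
    brightness scale on the image only.  Labels undergo the identical
    geometric transform so the pairing is preserved.
    """
    rng = np.random.default_rng(seed)
    img = np.asarray(image).astype(np.float64)
    lab = labels.raster.copy()

    k = int(rng.integers(0, 4))
    img, lab = np.rot90(img, k), np.rot90(lab, k)
    if rng.random() < 0.5:
        img, lab = np.fliplr(img), np.fliplr(lab)
    if rng.random() < 0.5:
        img, lab = np.flipud(img), np.flipud(lab)
    dy, dx = (int(v) for v in rng.integers(-10, 11, size=2))
    img = np.roll(np.roll(img, dy, axis=0), dx, axis=1)
    lab = np.roll(np.roll(lab, dy, axis=0), dx, axis=1)
    img = np.clip(img * rng.uniform(0.8, 1.2), 0, 255)
    return img, LabelMap(classes=labels.classes, raster=np.ascontiguousarray(lab))


# ---------------------------------------------------------------------------
# Reference segmenters
# ---------------------------------------------------------------------------

class IntensitySegmenter:
    """Classical per-pixel segmenter for the stylized fixture imagery.

    Each anatomy region in the synthetic plates is rendered at a distinct
    nominal gray level; this segmenter scores each class with a Gaussian
    likelihood around its level.  Pixel-wise, hence exactly
    translation-consistent and equivariant under the TTA symmetries — the
    classical stand-in for a trained network on fixture images.
    """

    def __init__(
        self,
        levels: dict[str, float],
        classes: tuple[str, ...] = CLASSES,
        sigma: float = 6.0,
    ) -> None:
        self.classes = tuple(classes)
        self.levels = dict(levels)
        self.sigma = float(sigma)

    def __call__(self, image: np.ndarray) -> ProbabilityMap:
        img = np.asarray(image, dtype=np.float64)
        n = len(self.classes)
        scores = np.empty(img.shape + (n,), dtype=np.float64)
        for i, name in enumerate(self.classes):
            mu = self.levels[name]
            scores[..., i] = np.exp(-0.5 * ((img - mu) / self.sigma) ** 2)
        return ProbabilityMap(classes=self.classes, raster=scores)


def one_hot(labels: LabelMap) -> ProbabilityMap:
    """One-hot probability encoding of a label map."""
    n = len(labels.classes)
    raster = np.eye(n)[labels.raster]
    return ProbabilityMap(classes=labels.classes, raster=raster)
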