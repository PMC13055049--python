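"""Droplet calibration: measure the expelled droplet, recommend pressure.

Before a session the needle expels a droplet into mineral oil in a 6-well
plate; its size determines the injected volume.  The droplet appears as a
dark, near-circular blob on a bright background: the darkest blob is
segmented, its equivalent-area circle fitted, elongated blobs (debris) are
rejected by a circularity floor, and the diameter converts to volume via
the sphere formula V = (pi/6) d^3.  A proportional pressure update then
steers the volume toward the target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

#: Blobs less circular than this are debris, not droplets.
CIRCULARITY_FLOOR = 0.8
#: A second blob at least this fraction of the largest makes the scene ambiguous.
AMBIGUITY_RATIO = 0.5
#: Minimum blob area (px) considered at all.
MIN_AREA_PX = 9


class DropletNotFoundError(RuntimeError):
    pass


class AmbiguousDropletError(RuntimeError):
    def __init__(self, areas: list[int]) -> None:
        super().__init__(f"multiple similar dark blobs, areas {areas}")
        self.areas = areas


class NonCircularDropletError(RuntimeError):
    def __init__(self, circularity: float) -> None:
        super().__init__(f"blob circularity {circularity:.2f} below floor")
        self.circularity = circularity


@dataclass(frozen=True)
class DropletMeasurement:
    diameter_px: float
    diameter_um: float
    volume_nl: float
    circularity: float


def droplet_volume(diameter_um: float) -> float:
    """Sphere volume in nanoliters from a diameter in micrometres.

    (pi/6) d^3 in um^3; 1 nL = 1e6 um^3.
    """
    if diameter_um < 0:
        raise ValueError("diameter must be >= 0")
    return math.pi / 6.0 * diameter_um**3 / 1e6


def measure_droplet(
    image: np.ndarray,
    scale_um_per_px: float,
    circularity_floor: float = CIRCULARITY_FLOOR,
) -> DropletMeasurement:
    """Segment the dark droplet and report its equivalent-area diameter.

    Otsu's threshold separates the dark blob from the bright oil; the
    largest connected dark component is the candidate.  A comparably sized
    second blob raises an ambiguity error, and a blob failing the
    circularity floor (4 pi A / P^2, Crofton perimeter) is rejected as
    debris.
    """
    if scale_um_per_px <= 0:
        raise ValueError("scale must be positive")
    img = np.asarray(image, dtype=np.float64)
    if img.max() - img.min() < 10:
        raise DropletNotFoundError("no dark blob on bright background")
    mask = img < threshold_otsu(img)
    comp = cc_label(mask, connectivity=2)
    props = [p for p in regionprops(comp) if p.area >= MIN_AREA_PX]
    if not props:
        raise DropletNotFoundError("no dark blob of usable size")
    props.sort(key=lambda p: p.area, reverse=True)
    if len(props) > 1 and props[1].area >= AMBIGUITY_RATIO * props[0].area:
        raise AmbiguousDropletError([int(p.area) for p in props[:5]])
    blob = props[0]
    perim = blob.perimeter_crofton
    circ = min(1.0, 4.0 * math.pi * blob.area / perim**2) if perim > 0 else 0.0
    if circ < circularity_floor:
        raise NonCircularDropletError(circ)
    d_px = float(blob.equivalent_diameter_area)
    d_um = d_px * scale_um_per_px
    return DropletMeasurement(
        diameter_px=d_px,
        diameter_um=d_um,
        volume_nl=droplet_volume(d_um),
        circularity=circ,
    )


def recommend_pressure(
    measured_nl: float,
    target_nl: float,
    current_pressure: float,
    pressure_range: tuple[float, float] = (10.0, 1000.0),
) -> float:
    """Proportional pressure update toward the target volume.

    new = current * target / measured, clamped to the safe range.  Under
    multiplicative bounded measurement noise the iteration contracts toward
    the target.  A measured volume of zero signals a blocked needle and is
    an error, not a recommendation.
    """
    if measured_nl <= 0:
        raise ValueError("measured volume is zero — needle may be blocked")
    if target_nl <= 0 or current_pressure <= 0:
        raise ValueError("target volume and pressure must be positive")
    new = current_pressure * target_nl / measured_nl
    lo, hi = pressure_range
    return float(min(max(new, lo), hi))
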