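"""Blood-flow activity map from a short frame sequence.

A static bright-field image cannot show flowing blood; a short video can.
Summing absolute differences between subsequent frames highlights exactly
the pixels where blood cells moved, which is how the duct of Cuvier is made
visible to the recognition network: the activity map is colored red and
overlaid on the last frame of the set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fixtures import FrameSequence


@dataclass(frozen=True)
class BloodFlowMap:
    activity: np.ndarray  # (H, W) in [0, 1]
    n_frames_used: int

    def __post_init__(self) -> None:
        a = np.asarray(self.activity, dtype=np.float64)
        if a.ndim != 2 or not np.all(np.isfinite(a)):
            raise ValueError("activity must be a finite 2-D raster")
        if a.size and (a.min() < 0 or a.max() > 1):
            raise ValueError("activity must lie in [0, 1]")
        object.__setattr__(self, "activity", a)


def blood_flow_map(seq: FrameSequence | np.ndarray) -> BloodFlowMap:
    """Sum of absolute subsequent-frame differences, max-normalized.

    activity = normalize( sum_t |frame_{t+1} - frame_t| ).  Frames are cast
    to float before differencing (unsigned wraparound would corrupt the
    result).  Normalization divides by the maximum summed value; an all-zero
    sum (perfectly static video) stays all-zero.
    """
    frames = np.asarray(seq.frames if isinstance(seq, FrameSequence) else seq)
    if frames.ndim != 3:
        raise ValueError("need a (T, H, W) grayscale stack")
    if frames.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    f = frames.astype(np.float64)
    total = np.abs(np.diff(f, axis=0)).sum(axis=0)
    peak = total.max()
    if peak > 0:
        total = total / peak
    return BloodFlowMap(activity=total, n_frames_used=frames.shape[0])


def overlay_flow(
    flow: BloodFlowMap, last_frame: np.ndarray, weight: float = 1.0
) -> np.ndarray:
    """Color the activity red on top of the grayscale last frame.

    Returns an (H, W, 3) uint8 image: red channel is the gray value blended
    toward saturation by ``weight * activity``; green and blue carry the
    gray value unchanged.
    """
    gray = np.asarray(last_frame, dtype=np.float64)
    if gray.shape != flow.activity.shape:
        raise ValueError("last frame size does not match activity map")
    red = gray + weight * flow.activity * (255.0 - gray)
    rgb = np.stack([red, gray, gray], axis=-1)
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)
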