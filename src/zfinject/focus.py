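"""Autofocus and surface-touchdown detection for needle descent.

The descent is two-phase.  Coarse: the top camera focuses far below the
needle and the head moves down while the sharpness of the streamed images
is tracked; when sharpness passes a local maximum the larva's surface plane
has been found and the descent stops.  Fine: the focus is set just below
the needle tip, so the image stays blurred until the tip reaches the
surface — a sudden jump in sharpness relative to the rolling baseline marks
touchdown.

Detectors are causal stream processors: an event emitted at step i is never
revised by later samples.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import ndimage

#: Default fractional drop below the running maximum that confirms the
#: sharpness peak has been passed.
HYSTERESIS = 0.05
#: Rolling-median window for the touchdown baseline.
BASELINE_WINDOW = 5
#: Default sharpness-jump ratio that signals touchdown.
TOUCHDOWN_THRESHOLD = 3.0


@dataclass(frozen=True)
class DescentEvent:
    kind: str  # focus_peak | touchdown | none
    step_index: int = -1


@dataclass
class FocusTrace:
    """Ordered (z, sharpness) samples recorded during a descent."""

    steps: list[tuple[float, float]]

    def __post_init__(self) -> None:
        zs = [z for z, _ in self.steps]
        if any(b <= a for a, b in zip(zs, zs[1:])) and any(
            b >= a for a, b in zip(zs, zs[1:])
        ):
            raise ValueError("z positions must be strictly monotone")
        if any(not np.isfinite(s) or s < 0 for _, s in self.steps):
            raise ValueError("scores must be finite and >= 0")

    @property
    def scores(self) -> list[float]:
        return [s for _, s in self.steps]


def sharpness(image: np.ndarray) -> float:
    """Variance of the discrete Laplacian — the classical focus measure.

    Blur suppresses high spatial frequencies, so the Laplacian response
    collapses toward zero away from focus.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.size == 0:
        raise ValueError("empty image")
    return float(ndimage.laplace(img).var())


class PeakDetector:
    """Streaming local-maximum detector with hysteresis.

    Tracks the running maximum; once a score falls below
    ``peak * (1 - hysteresis)`` the peak is confirmed and its index
    reported.  The hysteresis band keeps sensor noise on a flat trace from
    triggering.
    """

    def __init__(self, hysteresis: float = HYSTERESIS) -> None:
        if not 0 < hysteresis < 1:
            raise ValueError("hysteresis must be in (0, 1)")
        self.hysteresis = hysteresis
        self._best = -np.inf
        self._best_index = -1
        self._i = -1
        self.fired = False

    def feed(self, score: float) -> DescentEvent | None:
        if self.fired:
            return None
        self._i += 1
        if score > self._best:
            self._best, self._best_index = score, self._i
        elif self._best > 0 and score < self._best * (1.0 - self.hysteresis):
            self.fired = True
            return DescentEvent(kind="focus_peak", step_index=self._best_index)
        return None


def find_focus_peak(
    scores: Iterable[float], hysteresis: float = HYSTERESIS
) -> DescentEvent:
    """Run the streaming peak detector over a whole trace."""
    det = PeakDetector(hysteresis)
    for s in scores:
        ev = det.feed(float(s))
        if ev is not None:
            return ev
    return DescentEvent(kind="none")


class TouchdownDetector:
    """Streaming sharpness-jump detector against a rolling-median baseline."""

    def __init__(
        self,
        threshold: float = TOUCHDOWN_THRESHOLD,
        window: int = BASELINE_WINDOW,
        min_baseline: int = 3,
    ) -> None:
        if threshold <= 1:
            raise ValueError("touchdown threshold must exceed 1")
        self.threshold = threshold
        self.min_baseline = min_baseline
        self._baseline: deque[float] = deque(maxlen=window)
        self._i = -1
        self.fired = False

    def feed(self, score: float) -> DescentEvent | None:
        if self.fired:
            return None
        self._i += 1
        # a one-sample "median" is noise; insist on a few baseline samples
        if len(self._baseline) >= self.min_baseline:
            base = float(np.median(self._baseline))
            if base > 0 and score >= self.threshold * base:
                self.fired = True
                return DescentEvent(kind="touchdown", step_index=self._i)
        self._baseline.append(float(score))
        return None


def detect_touchdown(
    scores: Iterable[float],
    threshold: float = TOUCHDOWN_THRESHOLD,
    window: int = BASELINE_WINDOW,
) -> DescentEvent:
    """Run the streaming touchdown detector over a whole trace."""
    det = TouchdownDetector(threshold, window)
    for s in scores:
        ev = det.feed(float(s))
        if ev is not None:
            return ev
    return DescentEvent(kind="none")


class DescentController:
    """Two-phase descent state machine: COARSE -> FINE -> TOUCHED.

    Coarse samples feed the peak detector; once the focus peak is found the
    controller switches to the fine phase, where samples feed the touchdown
    detector.  Emitted events are returned to the caller (the macro
    executor) as they happen.
    """

    COARSE, FINE, TOUCHED = "COARSE", "FINE", "TOUCHED"

    def __init__(
        self,
        hysteresis: float = HYSTERESIS,
        threshold: float = TOUCHDOWN_THRESHOLD,
        window: int = BASELINE_WINDOW,
    ) -> None:
        self.state = self.COARSE
        self._peak = PeakDetector(hysteresis)
        self._touch = TouchdownDetector(threshold, window)
        self.events: list[DescentEvent] = []

    def feed(self, score: float) -> DescentEvent | None:
        if self.state == self.COARSE:
            ev = self._peak.feed(score)
            if ev is not None:
                self.state = self.FINE
                self.events.append(ev)
                return ev
        elif self.state == self.FINE:
            ev = self._touch.feed(score)
            if ev is not None:
                self.state = self.TOUCHED
                self.events.append(ev)
                return ev
        return None
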