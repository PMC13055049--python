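"""Injection-session orchestration over a plate, against simulated hardware.

A session scans the plate top-to-bottom for larvae, targets each one, and
replays a declarative injection macro — an ordered list of primitive
needle/pressure actions — against a context that supplies detector events
(touchdown, puncture) and a pressure channel.  The context here is
simulated: detector events come from synthetic fixtures (or from oracles in
tests), and a simulated clock charges a configurable cost per primitive so
throughput can be modeled.  Timestamps and rates therefore describe the
simulation, never real hardware.

Bookkeeping mirrors the validation tables of injection campaigns: one row
per detected larva with site, mode, outcome and action trace; summaries
with success rate and larvae/hour; and a one-tailed Welch test for
comparing modes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Protocol, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import targeting
from .fixtures import generate_puncture_sequence, generate_touchdown_trace
from .focus import detect_touchdown, find_focus_peak
from .puncture import run_anchor_detector
from .segmentation import (
    LabelMap,
    Segmenter,
    TilingScheme,
    argmax_classes,
    segment_tiled,
)
from skimage.measure import label as cc_label
from skimage.measure import regionprops

SITES = ("doc_mid", "doc_choose", "pvs", "hindbrain")
MODES = ("automated", "semi_automated")

# Simulated seconds charged per primitive action.  Defaults are calibrated
# so the automated duct-of-Cuvier macro costs ~43 s per larva and a
# semi-automated run with one operator checkpoint ~84 s, the per-larva
# times reported for automated robotic vs. manual injection campaigns.
ACTION_COSTS: dict[str, float] = {
    "scan": 5.0,
    "approach": 12.0,
    "descend_coarse": 8.0,
    "descend_fine": 6.0,
    "await_touchdown": 3.0,
    "advance_along_axis": 1.5,
    "await_puncture": 4.0,
    "retract": 1.5,
    "pulse": 1.0,
    "operator_checkpoint": 40.0,
}

#: Batch time budget: anesthetized larvae dry out on the open plate, so a
#: batch should stay within 7 simulated minutes.
DEFAULT_BATCH_BUDGET_S = 7 * 60.0


class MacroError(ValueError):
    pass


@dataclass(frozen=True)
class InjectionMacro:
    """Ordered primitive actions replayed at each larva.

    Steps are dicts with an ``action`` key (approach, descend_coarse,
    descend_fine, await_touchdown, advance_along_axis, await_puncture,
    retract, pulse, repeat, operator_checkpoint).  ``repeat`` nests a
    ``steps`` list with ``times >= 1``.  A pulse may only occur after
    puncture has been awaited.
    """

    name: str
    steps: tuple[dict, ...]

    def __post_init__(self) -> None:
        def norm(step: dict) -> dict:
            step = dict(step)
            if "steps" in step:
                step["steps"] = tuple(norm(s) for s in step["steps"])
            return step

        object.__setattr__(self, "steps", tuple(norm(s) for s in self.steps))
        flat = list(self.flattened())
        seen_puncture = False
        for s in flat:
            a = s["action"]
            if a == "await_puncture":
                seen_puncture = True
            elif a == "pulse" and not seen_puncture:
                raise MacroError("pulse before await_puncture")

    def flattened(self) -> Iterable[dict]:
        def walk(steps: Sequence[dict]):
            for s in steps:
                if s["action"] == "repeat":
                    times = int(s.get("times", 0))
                    if times < 1:
                        raise MacroError("repeat times must be >= 1")
                    for _ in range(times):
                        yield from walk(s["steps"])
                else:
                    yield s

        yield from walk(self.steps)


DEFAULT_MACROS: dict[str, InjectionMacro] = {
    "doc": InjectionMacro(
        name="doc",
        steps=(
            {"action": "approach"},
            {"action": "descend_coarse"},
            {"action": "descend_fine"},
            {"action": "await_touchdown"},
            {"action": "advance_along_axis", "distance_um": 40},
            {"action": "await_puncture"},
            {"action": "retract", "distance_um": 15},
            {"action": "pulse", "pressure_hpa": 300, "duration_ms": 20},
        ),
    ),
    "pvs": InjectionMacro(
        name="pvs",
        steps=(
            {"action": "approach"},
            {"action": "descend_coarse"},
            {"action": "descend_fine"},
            {"action": "await_touchdown"},
            {"action": "advance_along_axis", "distance_um": 30},
            {"action": "await_puncture"},
            {"action": "retract", "distance_um": 20},
            {
                "action": "repeat",
                "times": 2,
                "steps": ({"action": "pulse", "pressure_hpa": 250, "duration_ms": 15},),
            },
            {"action": "operator_checkpoint"},
        ),
    ),
    "hindbrain": InjectionMacro(
        name="hindbrain",
        steps=(
            {"action": "approach"},
            {"action": "descend_coarse"},
            {"action": "descend_fine"},
            {"action": "await_touchdown"},
            {"action": "advance_along_axis", "distance_um": 25},
            {"action": "await_puncture"},
            {"action": "retract", "distance_um": 10},
            {
                "action": "repeat",
                "times": 2,
                "steps": ({"action": "pulse", "pressure_hpa": 280, "duration_ms": 15},),
            },
        ),
    ),
}


def save_macro(macro: InjectionMacro, path: str | Path) -> None:
    def listify(step: dict) -> dict:
        step = dict(step)
        if "steps" in step:
            step["steps"] = [listify(s) for s in step["steps"]]
        return step

    Path(path).write_text(
        yaml.safe_dump({"name": macro.name, "steps": [listify(s) for s in macro.steps]})
    )


def load_macro(path: str | Path) -> InjectionMacro:
    d = yaml.safe_load(Path(path).read_text())
    return InjectionMacro(name=d["name"], steps=tuple(d["steps"]))


@dataclass
class SessionSettings:
    """Injection-settings block (normally a YAML file)."""

    site: str = "doc_mid"
    mode: str = "automated"
    angle_offset_deg: float = 45.0
    pvs_angle_deg: float = 45.0
    user_point: tuple[float, float] | None = None
    stage: str = "2dpf"
    batch_budget_s: float = DEFAULT_BATCH_BUDGET_S
    survival_rate: float = 0.8  # placeholder outcome model, not biology
    needle_offset: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValueError(f"site must be one of {SITES}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SessionSettings":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "user_point" in d and d["user_point"] is not None:
            d["user_point"] = tuple(d["user_point"])
        if "needle_offset" in d:
            d["needle_offset"] = tuple(d["needle_offset"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Plate scanning
# ---------------------------------------------------------------------------

@dataclass
class LarvaDetection:
    larva_id: int
    centroid: tuple[float, float]  # (x, y)
    bbox: tuple[int, int, int, int]  # (x0, y0, x1, y1)
    labels: LabelMap  # crop
    mask: np.ndarray  # body component mask, crop-sized


def scan_plate(
    plate_image: np.ndarray,
    segmenter: Segmenter,
    scheme: TilingScheme = TilingScheme(),
    min_area_px: int = 400,
    pad: int = 4,
) -> list[LarvaDetection]:
    """Segment the plate and list larvae in scan order (top-down, then left).

    Each 8-connected non-background component above ``min_area_px`` is one
    larva; its detection carries a padded crop of the label map for
    targeting.
    """
    prob = segment_tiled(np.asarray(plate_image), segmenter, scheme)
    labels = argmax_classes(prob)
    bg = labels.classes.index("background")
    comp = cc_label(labels.raster != bg, connectivity=2)
    h, w = labels.raster.shape
    dets = []
    for p in regionprops(comp):
        if p.area < min_area_px:
            continue
        cy, cx = p.centroid
        y0, x0, y1, x1 = p.bbox
        x0, y0 = max(0, x0 - pad), max(0, y0 - pad)
        x1, y1 = min(w, x1 + pad), min(h, y1 + pad)
        crop = labels.raster[y0:y1, x0:x1].copy()
        # suppress other larvae leaking into the crop
        inside = comp[y0:y1, x0:x1] == p.label
        crop[~inside] = bg
        dets.append(
            LarvaDetection(
                larva_id=-1,
                centroid=(float(cx), float(cy)),
                bbox=(x0, y0, x1, y1),
                labels=LabelMap(classes=labels.classes, raster=crop),
                mask=inside,
            )
        )
    dets.sort(key=lambda d: (d.centroid[1], d.centroid[0]))
    for i, d in enumerate(dets):
        d.larva_id = i
    return dets


# ---------------------------------------------------------------------------
# Simulated hardware context and macro execution
# ---------------------------------------------------------------------------

@dataclass
class SimulatedClock:
    t: float = 0.0
    costs: dict[str, float] = field(default_factory=lambda: dict(ACTION_COSTS))

    def charge(self, action: str) -> None:
        self.t += self.costs.get(action, 0.0)


class InjectionContext(Protocol):
    """What a macro needs from the hardware: detector events and pressure."""

    def focus_peak(self) -> int | None: ...

    def touchdown(self) -> int | None: ...

    def puncture(self) -> int | None: ...

    def pulse(self, pressure_hpa: float, duration_ms: float) -> None: ...


class OracleContext:
    """Context whose detectors always report the scripted ground truth."""

    def __init__(
        self,
        focus_index: int = 5,
        touchdown_index: int = 8,
        puncture_index: int = 17,
    ) -> None:
        self._events = (focus_index, touchdown_index, puncture_index)
        self.pulses: list[tuple[float, float]] = []

    def focus_peak(self) -> int | None:
        return self._events[0]

    def touchdown(self) -> int | None:
        return self._events[1]

    def puncture(self) -> int | None:
        return self._events[2]

    def pulse(self, pressure_hpa: float, duration_ms: float) -> None:
        self.pulses.append((pressure_hpa, duration_ms))


class DetectorContext:
    """Context backed by synthetic descent/puncture fixtures and the real
    detectors: each query generates a seeded fixture and runs the
    corresponding detection algorithm on it."""

    def __init__(self, seed: int, noise_sd: float = 0.3) -> None:
        self._rng = np.random.default_rng(seed)
        self.noise_sd = noise_sd
        self.pulses: list[tuple[float, float]] = []

    def _seed(self) -> int:
        return int(self._rng.integers(0, 2**31 - 1))

    def focus_peak(self) -> int | None:
        from .fixtures import generate_focal_stack
        from .focus import sharpness

        peak = int(self._rng.integers(3, 9))
        stack, _ = generate_focal_stack(peak, n_steps=12, seed=self._seed(), size=48)
        ev = find_focus_peak(sharpness(f) for f in stack)
        return ev.step_index if ev.kind == "focus_peak" else None

    def touchdown(self) -> int | None:
        idx = int(self._rng.integers(5, 20))
        trace, _ = generate_touchdown_trace(
            idx, n_steps=25, noise_sd=self.noise_sd, seed=self._seed()
        )
        ev = detect_touchdown(trace)
        return ev.step_index if ev.kind == "touchdown" else None

    def puncture(self) -> int | None:
        idx = int(self._rng.integers(6, 16))
        seq, _ = generate_puncture_sequence(
            puncture_frame=idx,
            n_frames=idx + 4,
            seed=self._seed(),
            size=64,
            noise_sd=self.noise_sd,
        )
        event, _ = run_anchor_detector(seq, tip=(32.0, 32.0), radius=24.0)
        return event.frame_index if event is not None else None

    def pulse(self, pressure_hpa: float, duration_ms: float) -> None:
        self.pulses.append((pressure_hpa, duration_ms))


Operator = Callable[[int, int], str]  # (larva_id, step_index) -> continue|abort


@dataclass
class MacroResult:
    trace: list[str]
    outcome: str  # success | failure
    reason: str = ""
    n_pulses: int = 0


def execute_macro(
    macro: InjectionMacro,
    context: InjectionContext,
    clock: SimulatedClock | None = None,
    *,
    mode: str = "automated",
    operator: Operator | None = None,
    larva_id: int = 0,
) -> MacroResult:
    """Replay macro steps against the context, consuming detector events.

    An await step whose detector reports nothing is a recorded failure
    (timeout), never an exception; the remaining steps are not executed.
    Success means every await was satisfied and every pulse delivered.
    """
    clock = clock or SimulatedClock()
    trace: list[str] = []
    n_pulses = 0
    for i, step in enumerate(macro.flattened()):
        action = step["action"]
        clock.charge(action)
        if action == "await_touchdown":
            if context.touchdown() is None:
                trace.append("await_touchdown:timeout")
                return MacroResult(trace, "failure", "touchdown timeout", n_pulses)
            trace.append("await_touchdown")
        elif action == "await_puncture":
            if context.puncture() is None:
                trace.append("await_puncture:timeout")
                return MacroResult(trace, "failure", "puncture timeout", n_pulses)
            trace.append("await_puncture")
        elif action == "pulse":
            context.pulse(
                step.get("pressure_hpa", 300.0), step.get("duration_ms", 20.0)
            )
            n_pulses += 1
            trace.append("pulse")
        elif action == "operator_checkpoint":
            if mode == "semi_automated":
                verdict = operator(larva_id, i) if operator is not None else "continue"
                trace.append(f"operator_checkpoint:{verdict}")
                if verdict != "continue":
                    return MacroResult(trace, "failure", "operator abort", n_pulses)
            else:
                trace.append("operator_checkpoint:skipped")
        else:
            trace.append(action)
    return MacroResult(trace, "success", "", n_pulses)


# ---------------------------------------------------------------------------
# Targeting glue
# ---------------------------------------------------------------------------

def predict_hindbrain_points(
    labels: LabelMap,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Default start/direction proposal for hindbrain entry.

    The production predictor is learned from edge annotations and is
    pluggable; this stand-in starts outside the hindbrain on the far side
    from the eyes and points at the hindbrain centroid.
    """
    def centroid(cls: str) -> tuple[float, float]:
        m = labels.mask(cls)
        if not m.any():
            raise targeting.SiteNotFoundError(f"no {cls!r} region")
        ys, xs = np.nonzero(m)
        return float(xs.mean()), float(ys.mean())

    hx, hy = centroid("hindbrain")
    ex, ey = centroid("eye")
    dx, dy = hx - ex, hy - ey
    norm = math.hypot(dx, dy) or 1.0
    start = (hx + 12.0 * dx / norm, hy + 12.0 * dy / norm)
    return start, (hx, hy)


def target_for_site(
    detection: LarvaDetection, settings: SessionSettings
) -> targeting.NeedlePose:
    """Compute the needle pose for the configured site on one detection.

    Poses are computed in crop coordinates and shifted to plate pixels.
    """
    labels = detection.labels
    lm = targeting.landmark_centroids(labels)
    frame = targeting.build_skewed_frame(lm)
    if settings.site == "doc_mid":
        pose = targeting.doc_target(
            labels, frame, angle_offset_deg=settings.angle_offset_deg
        )
    elif settings.site == "doc_choose":
        pose = targeting.doc_target(
            labels,
            frame,
            user_point=settings.user_point,
            angle_offset_deg=settings.angle_offset_deg,
        )
    elif settings.site == "pvs":
        pose = targeting.pvs_pose(labels, frame, angle_deg=settings.pvs_angle_deg)
    else:  # hindbrain
        start, direction = predict_hindbrain_points(labels)
        pose = targeting.hindbrain_pose(start, direction)
    x0, y0 = detection.bbox[0], detection.bbox[1]
    ox, oy = settings.needle_offset
    return targeting.NeedlePose(
        tip=(pose.tip[0] + x0 + ox, pose.tip[1] + y0 + oy),
        angle_deg=pose.angle_deg,
        site=pose.site,
    )


# ---------------------------------------------------------------------------
# Session driver and bookkeeping
# ---------------------------------------------------------------------------

ContextFactory = Callable[[int], InjectionContext]

RECORD_COLUMNS = [
    "larva_id",
    "site",
    "mode",
    "outcome",
    "reason",
    "tip_x",
    "tip_y",
    "angle_deg",
    "n_pulses",
    "t_start",
    "t_end",
    "survived",
    "trace",
]


def run_session(
    detections: Sequence[LarvaDetection],
    settings: SessionSettings,
    macro: InjectionMacro,
    context_factory: ContextFactory,
    seed: int = 0,
    operator: Operator | None = None,
    clock: SimulatedClock | None = None,
) -> pd.DataFrame:
    """Iterate detections in scan order and replay the macro at each larva.

    Per-larva failures (targeting errors, detector timeouts, operator
    aborts) are recorded and the session continues.  Once the simulated
    clock exceeds the batch budget the remaining larvae are marked skipped:
    anesthetized larvae must not dry out on the plate.
    """
    rng = np.random.default_rng(seed)
    clock = clock or SimulatedClock()
    rows = []
    for det in detections:
        if clock.t >= settings.batch_budget_s:
            rows.append(
                {
                    "larva_id": det.larva_id,
                    "site": settings.site,
                    "mode": settings.mode,
                    "outcome": "skipped",
                    "reason": "batch time budget exhausted",
                    "tip_x": np.nan,
                    "tip_y": np.nan,
                    "angle_deg": np.nan,
                    "n_pulses": 0,
                    "t_start": clock.t,
                    "t_end": clock.t,
                    "survived": False,
                    "trace": "",
                }
            )
            continue
        t_start = clock.t
        clock.charge("scan")
        try:
            pose = target_for_site(det, settings)
        except ValueError as exc:  # missing landmark / absent site / degenerate frame
            rows.append(
                {
                    "larva_id": det.larva_id,
                    "site": settings.site,
                    "mode": settings.mode,
                    "outcome": "failure",
                    "reason": f"targeting: {exc}",
                    "tip_x": np.nan,
                    "tip_y": np.nan,
                    "angle_deg": np.nan,
                    "n_pulses": 0,
                    "t_start": t_start,
                    "t_end": clock.t,
                    "survived": False,
                    "trace": "",
                }
            )
            continue
        context = context_factory(det.larva_id)
        result = execute_macro(
            macro,
            context,
            clock,
            mode=settings.mode,
            operator=operator,
            larva_id=det.larva_id,
        )
        survived = bool(
            result.outcome == "success" and rng.random() < settings.survival_rate
        )
        rows.append(
            {
                "larva_id": det.larva_id,
                "site": settings.site,
                "mode": settings.mode,
                "outcome": result.outcome,
                "reason": result.reason,
                "tip_x": pose.tip[0],
                "tip_y": pose.tip[1],
                "angle_deg": pose.angle_deg,
                "n_pulses": result.n_pulses,
                "t_start": t_start,
                "t_end": clock.t,
                "survived": survived,
                "trace": ";".join(result.trace),
            }
        )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


@dataclass(frozen=True)
class SessionSummary:
    n_detected: int
    n_injected: int
    n_success: int
    n_skipped: int
    success_rate: float  # percent
    survival_rate: float  # percent, placeholder outcome model
    mean_seconds_per_larva: float
    larvae_per_hour: float


def summarize(records: pd.DataFrame) -> SessionSummary:
    """Session table -> headline numbers.

    success_rate = successes / injected x 100 (skipped larvae were never
    injected); larvae_per_hour = 3600 / mean simulated per-larva seconds.
    """
    if len(records) == 0:
        raise ValueError("no rows to summarize")
    injected = records[records["outcome"].isin(["success", "failure"])]
    n_injected = len(injected)
    if n_injected == 0:
        raise ValueError("zero injected larvae: rates undefined")
    n_success = int((injected["outcome"] == "success").sum())
    per_larva = (injected["t_end"] - injected["t_start"]).to_numpy(dtype=float)
    mean_s = float(per_larva.mean())
    survival = (
        100.0 * float(injected["survived"].sum()) / n_success if n_success else 0.0
    )
    return SessionSummary(
        n_detected=len(records),
        n_injected=n_injected,
        n_success=n_success,
        n_skipped=int((records["outcome"] == "skipped").sum()),
        success_rate=100.0 * n_success / n_injected,
        survival_rate=survival,
        mean_seconds_per_larva=mean_s,
        larvae_per_hour=3600.0 / mean_s if mean_s > 0 else float("inf"),
    )


def aggregate(values: Sequence[float]) -> dict:
    """mean +/- sample standard deviation across sessions.

    A single session reports std 0 with ``single=True``, matching the
    convention of quoting mean +/- STDEV in validation tables.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("no values")
    single = arr.size == 1
    return {
        "mean": float(arr.mean()),
        "std": 0.0 if single else float(arr.std(ddof=1)),
        "n": int(arr.size),
        "single": single,
    }


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p_one_tailed: float
    significant: bool


def compare_modes(
    sample_a: Sequence[float], sample_b: Sequence[float], alpha: float = 0.05
) -> WelchResult:
    """One-tailed Welch two-sample comparison (unequal variance).

    Tests whether sample_a exceeds sample_b: Welch t statistic with
    Welch-Satterthwaite degrees of freedom, one-tailed p.  Two constant,
    equal samples give p = 0.5 by convention (no evidence either way).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    diff = a.mean() - b.mean()
    if se2 == 0:
        if diff == 0:
            return WelchResult(0.0, float(na + nb - 2), 0.5, False)
        t_stat = math.inf if diff > 0 else -math.inf
        p = 0.0 if diff > 0 else 1.0
        return WelchResult(t_stat, float(na + nb - 2), p, p < alpha)
    t_stat = diff / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = float(stats.t.sf(t_stat, df))
    return WelchResult(float(t_stat), float(df), p, p < alpha)
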