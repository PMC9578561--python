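"""Continuous behavioral outcome measures from worm trajectory traces.

The phototaxis assay tracks each worm for 3 min of acclimation followed by a
5-min recording: 1 min red (1st dark cycle), 1 min green, 2 min red (2nd
dark cycle), 1 min blue.  Worms do not perceive red light, so the red phases
serve as dark baselines.  Mean speed is computed in every 30-s interval of
the recording (10 bins), and higher-level measures — resting fraction,
phototaxis response, wall preference, locomotor bursts — derive from the
frame speeds and positions.  Thermotaxis and noxious-heat metrics operate on
separately recorded traces/displacement series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RESTING_THRESHOLD = 0.2  # mm/s; resting is strictly below, moving strictly above


@dataclass(frozen=True)
class LightPhase:
    name: str
    color: str
    duration_s: float


@dataclass(frozen=True)
class LightSchedule:
    """Ordered light phases; the assay is everything after acclimation."""

    phases: tuple[LightPhase, ...]

    def __post_init__(self) -> None:
        if any(p.duration_s <= 0 for p in self.phases):
            raise ValueError("phase durations must be positive")

    @property
    def total_duration(self) -> float:
        return sum(p.duration_s for p in self.phases)

    @property
    def assay_start(self) -> float:
        return self.phases[0].duration_s if self.phases[0].name == "acclimation" else 0.0

    def phase_at(self, t: float) -> LightPhase | None:
        acc = 0.0
        for p in self.phases:
            acc += p.duration_s
            if t <= acc:
                return p
        return None

    def phase_name_at(self, t: float) -> str:
        p = self.phase_at(t)
        return p.name if p else "post"

    def bins(self, bin_s: float = 30.0) -> list[tuple[str, float, float]]:
        """(label, start, end) for each bin of the assay window.

        Bins never straddle a phase boundary; labels are phase name plus a
        1-based index within the phase (dark1-1, green1, dark2-3, ...).
        """
        out = []
        acc = 0.0
        for p in self.phases:
            if p.name == "acclimation":
                acc += p.duration_s
                continue
            nbins = int(round(p.duration_s / bin_s))
            for k in range(nbins):
                label = (f"{p.name}-{k + 1}" if p.name[-1:].isdigit()
                         else f"{p.name}{k + 1}")
                out.append((label, acc + k * bin_s, acc + (k + 1) * bin_s))
            acc += p.duration_s
        return out


DEFAULT_SCHEDULE = LightSchedule((
    LightPhase("acclimation", "red", 180.0),
    LightPhase("dark1", "red", 60.0),
    LightPhase("green", "green", 60.0),
    LightPhase("dark2", "red", 120.0),
    LightPhase("blue", "blue", 60.0),
))

# default 10 assay bins: dark1-1 dark1-2 green1 green2 dark2-1..4 blue1 blue2
DEFAULT_BINS = [b[0] for b in DEFAULT_SCHEDULE.bins()]
BLUE_BINS = ("blue1", "blue2")
DARK2_BINS = ("dark2-1", "dark2-2", "dark2-3", "dark2-4")
DARK2_SECOND_MINUTE = ("dark2-3", "dark2-4")


@dataclass
class TrajectoryTrace:
    """Time-stamped 2-D positions of one worm in a circular well."""

    data: pd.DataFrame  # t_s, x_mm, y_mm, tracked (bool); light_phase optional
    center: tuple[float, float] = (0.0, 0.0)
    radius_mm: float = 5.5
    schedule: LightSchedule = DEFAULT_SCHEDULE

    def __post_init__(self) -> None:
        t = self.data["t_s"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if "tracked" not in self.data:
            self.data = self.data.assign(tracked=True)

    def radial_distance(self) -> np.ndarray:
        cx, cy = self.center
        return np.hypot(self.data["x_mm"].to_numpy(float) - cx,
                        self.data["y_mm"].to_numpy(float) - cy)


@dataclass
class SpeedSeries:
    """Per-frame speeds plus 30-s bin means over the assay window.

    ``frames`` has columns t_s, speed_mm_s, bin (the bin label or NA).
    ``bin_means`` maps every schedule bin label to its mean speed over
    tracked samples; an empty bin is a missing value (NaN), never zero.
    """

    frames: pd.DataFrame
    bin_means: dict[str, float]
    schedule: LightSchedule = DEFAULT_SCHEDULE

    def mean_over(self, labels) -> float:
        vals = [self.bin_means[b] for b in labels if not math.isnan(self.bin_means.get(b, math.nan))]
        return float(np.mean(vals)) if vals else math.nan


def frame_speeds(trace: TrajectoryTrace, bin_s: float = 30.0) -> SpeedSeries:
    """Instantaneous speeds between consecutive tracked frames, binned.

    Speed is Euclidean displacement over elapsed time between consecutive
    *tracked* frames, assigned to the later timestamp; an untracked gap
    contributes no sample.  Bin means average tracked samples only.
    """
    df = trace.data
    tracked = df[df["tracked"].astype(bool)]
    if len(tracked) < 2:
        raise ValueError("need at least 2 tracked frames")
    t = tracked["t_s"].to_numpy(float)
    x = tracked["x_mm"].to_numpy(float)
    y = tracked["y_mm"].to_numpy(float)
    # consecutive in the original frame sequence: no untracked frame between
    idx = tracked.index.to_numpy()
    consecutive = np.diff(idx) == 1
    dt = np.diff(t)
    sp = np.hypot(np.diff(x), np.diff(y)) / dt
    keep = consecutive
    times = t[1:][keep]
    speeds = sp[keep]

    bins = trace.schedule.bins(bin_s)
    labels = np.full(times.shape, None, dtype=object)
    for label, lo, hi in bins:
        labels[(times > lo) & (times <= hi)] = label
    frames = pd.DataFrame({"t_s": times, "speed_mm_s": speeds, "bin": labels})
    means = {}
    for label, _, _ in bins:
        v = speeds[labels == label]
        means[label] = float(np.mean(v)) if v.size else math.nan
    return SpeedSeries(frames, means, trace.schedule)


def resting_fraction(speeds: SpeedSeries, window=DARK2_BINS,
                     threshold: float = RESTING_THRESHOLD) -> float:
    """Fraction of tracked samples in the window with speed below threshold."""
    sel = speeds.frames["bin"].isin(window)
    if not sel.any():
        return math.nan
    v = speeds.frames.loc[sel, "speed_mm_s"].to_numpy(float)
    return float(np.mean(v < threshold))


def phototaxis_response(speeds: SpeedSeries) -> float:
    """Mean blue-cycle speed minus mean speed in dark2's second minute."""
    return speeds.mean_over(BLUE_BINS) - speeds.mean_over(DARK2_SECOND_MINUTE)


def wall_preference(trace: TrajectoryTrace, window=DARK2_BINS,
                    rim_fraction: float = 0.25) -> float:
    """Fraction of tracked dark2 samples spent in the outer rim annulus.

    A sample counts as "at the wall" when its radial distance is at least
    ``(1 - rim_fraction) * radius``.  The default rim covers the outer 25%
    of the radius (~44% of the well area).
    """
    df = trace.data
    r = trace.radial_distance()
    t = df["t_s"].to_numpy(float)
    tracked = df["tracked"].to_numpy(bool)
    sel = np.zeros(len(df), dtype=bool)
    for label, lo, hi in trace.schedule.bins():
        if label in window:
            sel |= (t > lo) & (t <= hi)
    sel &= tracked
    if not sel.any():
        return math.nan
    return float(np.mean(r[sel] >= (1.0 - rim_fraction) * trace.radius_mm))


def locomotor_bursts(speeds: SpeedSeries, threshold: float = RESTING_THRESHOLD
                     ) -> dict[str, float]:
    """Count upward crossings of the resting threshold.

    A burst is a transition from resting (speed < threshold) to moving
    (speed > threshold) between consecutive samples; samples exactly at the
    threshold are neither resting nor moving and never trigger a burst.  A
    tracking gap (non-adjacent samples) resets the resting state.  Returns
    the total count over the assay and the blue/dark2 ratio (NaN when dark2
    has no bursts).
    """
    fr = speeds.frames
    v = fr["speed_mm_s"].to_numpy(float)
    t = fr["t_s"].to_numpy(float)
    labels = fr["bin"].to_numpy(object)
    if len(v) < 2:
        return {"total": 0, "ratio": math.nan}
    # consecutive samples: no gap larger than ~2x the modal frame interval
    dt = np.diff(t)
    step = np.median(dt)
    adjacent = dt <= 2.0 * step + 1e-9
    crossing = (v[:-1] < threshold) & (v[1:] > threshold) & adjacent
    total = int(np.sum(crossing))
    lab_after = labels[1:]
    blue = int(np.sum(crossing & np.isin(lab_after, BLUE_BINS)))
    dark2 = int(np.sum(crossing & np.isin(lab_after, DARK2_BINS)))
    ratio = blue / dark2 if dark2 > 0 else math.nan
    return {"total": total, "ratio": ratio, "blue": blue, "dark2": dark2}


def thermotaxis_fraction(trace: TrajectoryTrace, cold_zone) -> float:
    """Fraction of tracked samples inside the cold zone.

    ``cold_zone`` is a predicate ``f(x, y) -> bool array`` over positions
    relative to the well center (e.g. ``lambda x, y: x < 0`` for the cold
    half of a gradient along x).
    """
    df = trace.data
    tracked = df["tracked"].to_numpy(bool)
    if not tracked.any():
        return math.nan
    cx, cy = trace.center
    x = df["x_mm"].to_numpy(float) - cx
    y = df["y_mm"].to_numpy(float) - cy
    inside = np.asarray(cold_zone(x, y), dtype=bool)
    return float(np.mean(inside[tracked]))


def noxious_metrics(times_s, displacement_mm, terminal_fraction: float = 0.25
                    ) -> dict[str, float]:
    """Heat-response metrics from a displacement series.

    ``rate`` is the least-squares slope of displacement vs time over the
    whole heating window; ``strength`` is the median displacement over the
    terminal sub-window (the last ``terminal_fraction`` of the recording).
    """
    t = np.asarray(times_s, dtype=float)
    d = np.asarray(displacement_mm, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 samples")
    slope = float(np.polyfit(t, d, 1)[0])
    t0 = t[-1] - terminal_fraction * (t[-1] - t[0])
    tail = d[t >= t0]
    return {"rate": slope, "strength": float(np.median(tail))}
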