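"""Eye-tracking metrics from raw gaze samples and a dynamic brand AOI.

Nine metrics per ad: fixation count and mean duration over the whole
ad; fixation/visit statistics restricted to a time-varying rectangle
that follows the on-screen brand (the AOI); and two scan-style
summaries:

* ``Quad_sec`` — quadrant visits per second on a 4x4 screen grid.  A
  visit begins at the first valid sample and whenever the gaze's
  quadrant index changes; re-entries count again.  High values indicate
  ambient scanning, low values focal viewing.
* ``Brand_ratio`` — fixation time on the brand divided by the total
  time the brand was visible, in [0, 1].

Fixations are detected with a velocity-threshold (I-VT) classifier.
Screen coordinates are pixels, origin top-left, y down.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "GazeStream",
    "Fixation",
    "AOISegment",
    "AOITrack",
    "detect_fixations",
    "ad_metrics",
    "brand_metrics",
    "quad_sec",
    "brand_ratio",
    "extract_gaze_metrics",
    "GAZE_METRIC_NAMES",
]

GAZE_METRIC_NAMES = [
    "Fix_Count_Advert", "Fix_Dur_Advert",
    "Fix_Dur_Br", "Fix_Count_Br", "FFix_Dur_Br",
    "Visit_Count_Br", "Visit_Dur_Br",
    "Quad_sec", "Brand_ratio",
]


@dataclass
class GazeStream:
    """Gaze samples: times in ms, positions in px, validity flags."""

    t_ms: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    rate: float = 300.0
    screen: tuple[int, int] = (1920, 1080)

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.rate <= 0:
            raise ConfigurationError("sample rate must be positive")
        if np.any(np.diff(self.t_ms) <= 0):
            raise ConfigurationError("timestamps must strictly increase")


@dataclass
class Fixation:
    start_ms: float
    duration_ms: float
    cx: float
    cy: float

    @property
    def end_ms(self) -> float:
        return self.start_ms + self.duration_ms


@dataclass
class AOISegment:
    t_start_ms: float
    t_end_ms: float
    x0: float
    y0: float
    x1: float
    y1: float

    def contains(self, x: float, y: float) -> bool:
        # half-open so adjacent AOIs never double-claim a point
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1


@dataclass
class AOITrack:
    """Non-overlapping, time-ordered brand rectangles."""

    segments: list[AOISegment] = field(default_factory=list)

    def __post_init__(self) -> None:
        segs = sorted(self.segments, key=lambda s: s.t_start_ms)
        for a, b in zip(segs, segs[1:]):
            if b.t_start_ms < a.t_end_ms:
                raise ConfigurationError("AOI segments overlap in time")
        self.segments = segs

    def active_at(self, t_ms: float) -> AOISegment | None:
        for s in self.segments:
            if s.t_start_ms <= t_ms < s.t_end_ms:
                return s
        return None

    @property
    def total_visible_ms(self) -> float:
        return sum(s.t_end_ms - s.t_start_ms for s in self.segments)


def detect_fixations(g: GazeStream,
                     vel_thresh_px_per_s: float | None = None,
                     min_duration_ms: float = 60.0,
                     max_gap_ms: float = 75.0) -> list[Fixation]:
    """I-VT fixation classification.

    Consecutive valid samples whose point-to-point velocity stays below
    the threshold belong to one fixation; invalid gaps up to
    ``max_gap_ms`` are bridged; groups shorter than ``min_duration_ms``
    are discarded.  The default threshold is 30 px per inter-sample
    frame, expressed in px/s via the nominal rate.
    """
    if vel_thresh_px_per_s is None:
        vel_thresh_px_per_s = 30.0 * g.rate
    vi = np.flatnonzero(g.valid)
    if vi.size < 2:
        return []
    t, x, y = g.t_ms[vi], g.x[vi], g.y[vi]
    dt = np.diff(t)
    vel = np.hypot(np.diff(x), np.diff(y)) / (dt / 1000.0)
    # a pair of samples continues the current fixation when slow and the
    # (possibly invalid-sample) gap between them is bridgeable
    cont = (vel < vel_thresh_px_per_s) & (dt <= max_gap_ms)
    fixations: list[Fixation] = []
    start = 0
    for i in range(cont.size + 1):
        if i == cont.size or not cont[i]:
            members = slice(start, i + 1)
            dur = t[i] - t[start]
            if dur >= min_duration_ms:
                fixations.append(Fixation(
                    start_ms=float(t[start]),
                    duration_ms=float(dur),
                    cx=float(x[members].mean()),
                    cy=float(y[members].mean()),
                ))
            start = i + 1
    return fixations


def ad_metrics(fixes: list[Fixation],
               ad_duration_s: float) -> dict[str, float]:
    """Fixation count and mean fixation duration (s) over the ad."""
    count = len(fixes)
    mean_dur = (float(np.mean([f.duration_ms for f in fixes]) / 1000.0)
                if count else np.nan)
    return {"Fix_Count_Advert": count, "Fix_Dur_Advert": mean_dur}


def _aoi_fixations(fixes: list[Fixation],
                   aoi: AOITrack) -> list[tuple[Fixation, AOISegment]]:
    """Fixations whose centroid lies inside the AOI active at their start."""
    out = []
    for f in fixes:
        seg = aoi.active_at(f.start_ms)
        if seg is not None and seg.contains(f.cx, f.cy):
            out.append((f, seg))
    return out


def brand_metrics(fixes: list[Fixation], g: GazeStream,
                  aoi: AOITrack) -> dict[str, float]:
    """Brand-AOI fixation and visit metrics.

    A *visit* is a maximal run of consecutive valid samples inside the
    currently active AOI rectangle.  ``FFix_Dur_Br`` is the latency from
    a brand appearance to the first fixation on it, averaged over
    appearances that received at least one fixation.
    """
    if not aoi.segments:
        return {k: np.nan for k in ("Fix_Dur_Br", "Fix_Count_Br",
                                    "FFix_Dur_Br", "Visit_Count_Br",
                                    "Visit_Dur_Br")}
    hits = _aoi_fixations(fixes, aoi)
    fix_count = len(hits)
    fix_dur = (float(np.mean([f.duration_ms for f, _ in hits]) / 1000.0)
               if hits else np.nan)
    # time to first fixation, per appearance with a hit
    latencies = []
    for seg in aoi.segments:
        seg_hits = [f for f, s in hits if s is seg]
        if seg_hits:
            latencies.append(min(f.start_ms for f in seg_hits)
                             - seg.t_start_ms)
    ffix = float(np.mean(latencies) / 1000.0) if latencies else np.nan

    # visits from raw samples
    visits: list[float] = []
    run_start = None
    prev_t = None
    for t, x, y, v in zip(g.t_ms, g.x, g.y, g.valid):
        if not v:
            continue  # invalid samples neither open nor close a visit
        seg = aoi.active_at(t)
        inside = seg is not None and seg.contains(x, y)
        if inside and run_start is None:
            run_start = t
        elif not inside and run_start is not None:
            visits.append(prev_t - run_start + 1000.0 / g.rate)
            run_start = None
        prev_t = t
    if run_start is not None:
        visits.append(prev_t - run_start + 1000.0 / g.rate)
    return {
        "Fix_Dur_Br": fix_dur,
        "Fix_Count_Br": fix_count,
        "FFix_Dur_Br": ffix,
        "Visit_Count_Br": len(visits),
        "Visit_Dur_Br": float(np.mean(visits) / 1000.0) if visits else np.nan,
    }


def quadrant_index(x: np.ndarray, y: np.ndarray,
                   screen: tuple[int, int],
                   grid: tuple[int, int] = (4, 4)) -> np.ndarray:
    """Flat quadrant index of each point on a rows x cols screen grid."""
    rows, cols = grid
    w, h = screen
    cx = np.clip((np.asarray(x) / w * cols).astype(int), 0, cols - 1)
    cy = np.clip((np.asarray(y) / h * rows).astype(int), 0, rows - 1)
    return cy * cols + cx


def quad_sec(g: GazeStream, grid: tuple[int, int] = (4, 4),
             stim_duration_s: float | None = None) -> float:
    """Quadrant visits per second: N_q / t_s.

    A visit starts at the first valid sample and at every change of
    quadrant index between consecutive valid samples; re-entering a
    previously seen quadrant opens a new visit.
    """
    if stim_duration_s is None:
        stim_duration_s = (g.t_ms[-1] - g.t_ms[0]) / 1000.0 if g.t_ms.size else 0
    if stim_duration_s <= 0:
        raise ConfigurationError("stimulus duration must be positive")
    vi = np.flatnonzero(g.valid)
    if vi.size == 0:
        return 0.0
    q = quadrant_index(g.x[vi], g.y[vi], g.screen, grid)
    n_q = 1 + int(np.sum(q[1:] != q[:-1]))
    return n_q / stim_duration_s


def brand_ratio(g: GazeStream, aoi: AOITrack,
                fixes: list[Fixation] | None = None) -> float:
    """Fixation time on the visible brand over total brand-visible time.

    t_bf sums, for every fixation assigned to the AOI, the overlap of
    the fixation interval with the brand-visibility windows; t_b is the
    summed visibility duration.
    """
    t_b = aoi.total_visible_ms
    if t_b <= 0:
        return np.nan
    if fixes is None:
        fixes = detect_fixations(g)
    t_bf = 0.0
    for f, _seg in _aoi_fixations(fixes, aoi):
        for s in aoi.segments:
            lo = max(f.start_ms, s.t_start_ms)
            hi = min(f.end_ms, s.t_end_ms)
            if hi > lo:
                t_bf += hi - lo
    return min(t_bf / t_b, 1.0)


def extract_gaze_metrics(g: GazeStream, aoi: AOITrack,
                         ad_duration_s: float,
                         grid: tuple[int, int] = (4, 4),
                         **ivt_kwargs) -> dict[str, float]:
    """All nine gaze metrics for one subject x ad stream."""
    fixes = detect_fixations(g, **ivt_kwargs)
    out = ad_metrics(fixes, ad_duration_s)
    out.update(brand_metrics(fixes, g, aoi))
    out["Quad_sec"] = quad_sec(g, grid, ad_duration_s)
    out["Brand_ratio"] = brand_ratio(g, aoi, fixes)
    return out
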