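"""Synthetic subject x ad cohorts with planted, recoverable effects.

No public recording of the original study design is available, so this
module generates the full data structure the pipeline consumes — EEG,
RR-interval and gaze streams plus recall/liking/view-count labels — from
known ground-truth parameters, at the study's scale by default
(35 subjects x 8 thirty-second ads, 2-min neutral baseline, 256 Hz EEG,
300 Hz gaze).

Planted effects are deliberately simple and analytically recoverable:

* EEG: band-limited Gaussian noise per band; ad-period band amplitudes
  and a signed left/right frontal power offset (theta, alpha) are the
  planted parameters.
* RR: direct sinusoidal modulation of the interval series at one LF and
  one HF frequency, so the spectral peaks are known exactly.
* Gaze: fixation centres with within-fixation jitter and fast saccade
  transits; a per-appearance time budget plants the brand-attendance
  fraction; ambient vs focus mode controls how widely centres scatter.
* Labels: a latent score (ad-rank effect + noise) thresholds into
  recall and liking; view counts are drawn log-uniformly inside each
  rank bin, so separability is a single tunable effect size.

Identical spec (including seed) reproduces bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import signal as sps

from .ann import RANK_LABELS
from .eeg import DEFAULT_BANDS, EEGRecording
from .errors import ConfigurationError, GenerationError
from .gaze import GAZE_METRIC_NAMES, AOISegment, AOITrack, GazeStream
from .hrv import HRV_METRIC_NAMES, RRSeries
from .montage import DEFAULT_CHANNELS, FRONTAL_PAIRS

__all__ = [
    "EEGParams", "HRVParams", "GazeParams", "LabelModel",
    "SyntheticCohortSpec", "GroundTruth",
    "gen_eeg", "gen_rr", "gen_gaze", "gen_aoi",
    "gen_cohort", "gen_feature_table",
]

# view-count sampling ranges per rank bin (log-uniform)
_BIN_RANGES = [(1e4, 1e6), (1e6, 5e6), (5e6, 1e7), (1e7, 3e7)]

# metric columns that carry the planted rank signal in gen_feature_table;
# chosen to mirror the metrics that dominate variable-importance runs
_INFORMATIVE = ["PI_theta", "II_theta", "t_meanHR", "p_SD1",
                "Fix_Count_Advert", "Fix_Count_Br"]

EEG_METRIC_NAMES = ["z_delta", "z_theta", "z_alpha", "z_beta",
                    "z_beta_ext", "z_gamma",
                    "PI_theta", "PI_alpha", "II_theta", "II_beta"]
ALL_METRIC_NAMES = EEG_METRIC_NAMES + HRV_METRIC_NAMES + GAZE_METRIC_NAMES


@dataclass
class EEGParams:
    rate: float = 256.0
    channels: list[str] = field(default_factory=lambda: list(DEFAULT_CHANNELS))
    # per-band RMS amplitude (uV) during baseline and during the ad
    band_amplitudes_baseline: dict[str, float] = field(default_factory=lambda: {
        "delta": 8.0, "theta": 6.0, "alpha": 10.0, "beta": 4.0, "gamma": 2.0})
    band_amplitudes_ad: dict[str, float] = field(default_factory=lambda: {
        "delta": 8.0, "theta": 6.0, "alpha": 10.0, "beta": 4.0, "gamma": 2.0})
    frontal_asymmetry: float = 0.0   # signed left-minus-right power offset
    noise_sd: float = 1.0            # broadband floor, uV


@dataclass
class HRVParams:
    mean_rr_ms: float = 850.0
    lf_amp_ms: float = 30.0
    lf_freq_hz: float = 0.10
    hf_amp_ms: float = 20.0
    hf_freq_hz: float = 0.25
    jitter_sd_ms: float = 5.0


@dataclass
class GazeParams:
    rate: float = 300.0
    screen: tuple[int, int] = (1920, 1080)
    mode: str = "ambient"            # "ambient" | "focus"
    brand_attendance: float = 0.4    # fraction of visible time on brand
    jitter_sd_px: float = 4.0


@dataclass
class LabelModel:
    """Latent score = effect_size * rank-effect + N(0, noise_sd)."""

    effect_size: float = 1.0
    noise_sd: float = 1.0


@dataclass
class SyntheticCohortSpec:
    n_subjects: int = 35
    n_ads: int = 8
    ad_duration_s: float = 30.0
    baseline_duration_s: float = 120.0
    eeg: EEGParams = field(default_factory=EEGParams)
    hrv: HRVParams = field(default_factory=HRVParams)
    gaze: GazeParams = field(default_factory=GazeParams)
    labels: LabelModel = field(default_factory=LabelModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ad_duration_s <= 0 or self.baseline_duration_s <= 0:
            raise ConfigurationError("durations must be positive")
        if not 0.0 <= self.gaze.brand_attendance <= 1.0:
            raise ConfigurationError("brand_attendance must be in [0, 1]")
        if self.gaze.rate <= 0 or self.eeg.rate <= 0:
            raise ConfigurationError("sample rates must be positive")
        if not 300.0 < self.hrv.mean_rr_ms < 2000.0:
            raise ConfigurationError("mean RR must be in (300, 2000) ms")
        unknown = set(self.eeg.channels) - set(DEFAULT_CHANNELS)
        if unknown:
            raise ConfigurationError(f"unknown montage labels {sorted(unknown)}")


@dataclass
class GroundTruth:
    """Generating parameters of one stream (or one cohort record)."""

    params: dict

    def as_dict(self) -> dict:
        return self.params


def _band_noise(rng: np.random.Generator, n: int, rate: float,
                low: float, high: float) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to [low, high] Hz."""
    sos = sps.butter(4, [low, min(high, rate / 2 * 0.99)], btype="band",
                     fs=rate, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    rms = np.sqrt(np.mean(x * x))
    return x / rms if rms > 0 else x


def gen_eeg(spec: SyntheticCohortSpec, condition: str = "ad",
            rng: np.random.Generator | None = None,
            asymmetry: float | None = None,
            band_gain: dict[str, float] | None = None,
            brand_windows: list[tuple[float, float]] | None = None,
            ) -> tuple[EEGRecording, GroundTruth]:
    """One baseline+ad EEG recording with planted band powers.

    The recording covers the baseline period followed immediately by
    the ad period; events mark both windows and any brand appearances
    (times relative to recording start).  ``band_gain`` multiplies the
    ad-period amplitude per band; ``asymmetry`` overrides the spec's
    left-minus-right frontal power offset (applied in theta and alpha
    during the ad).
    """
    p = spec.eeg
    rng = rng or np.random.default_rng(spec.seed)
    a = p.frontal_asymmetry if asymmetry is None else asymmetry
    if not -1.0 < a < 1.0:
        raise ConfigurationError("asymmetry offset must be in (-1, 1)")
    rate = p.rate
    n_base = int(round(spec.baseline_duration_s * rate))
    n_ad = int(round(spec.ad_duration_s * rate))
    n = n_base + n_ad
    n_ch = len(p.channels)
    left = {l for l, _ in FRONTAL_PAIRS}
    right = {r for _, r in FRONTAL_PAIRS}

    data = p.noise_sd * rng.standard_normal((n_ch, n))
    gains = band_gain or {}
    for band, amp_base in p.band_amplitudes_baseline.items():
        low, high = DEFAULT_BANDS[band].low, DEFAULT_BANDS[band].high
        amp_ad = p.band_amplitudes_ad.get(band, amp_base) * gains.get(band, 1.0)
        for c, ch in enumerate(p.channels):
            comp = _band_noise(rng, n, rate, low, high)
            amp_profile = np.concatenate([
                np.full(n_base, amp_base), np.full(n_ad, amp_ad)])
            if band in ("theta", "alpha") and a != 0.0:
                if ch in left:
                    amp_profile[n_base:] *= np.sqrt(1.0 + a)
                elif ch in right:
                    amp_profile[n_base:] *= np.sqrt(1.0 - a)
            data[c] += amp_profile * comp

    t_base = spec.baseline_duration_s
    events: list[tuple[float, str]] = [
        (0.0, "baseline_start"), (t_base, "baseline_end"),
        (t_base, "ad_start"), (t_base + spec.ad_duration_s, "ad_end"),
    ]
    for w0, w1 in (brand_windows or []):
        events.append((t_base + w0, "brand_on"))
        events.append((t_base + w1, "brand_off"))
    rec = EEGRecording(data, rate, list(p.channels), events)
    gt = GroundTruth({
        "condition": condition,
        "band_amplitudes_ad": {b: p.band_amplitudes_ad.get(b, v) * gains.get(b, 1.0)
                               for b, v in p.band_amplitudes_baseline.items()},
        "asymmetry": a,
    })
    return rec, gt


def gen_rr(spec: SyntheticCohortSpec, condition: str = "ad",
           rng: np.random.Generator | None = None,
           duration_s: float | None = None,
           mean_rr_ms: float | None = None,
           ) -> tuple[RRSeries, GroundTruth]:
    """Beat series with RR(t) = mean + A_LF sin + A_HF sin + noise."""
    p = spec.hrv
    rng = rng or np.random.default_rng(spec.seed)
    duration_s = duration_s or spec.ad_duration_s
    mean_rr = mean_rr_ms or p.mean_rr_ms
    if mean_rr - p.lf_amp_ms - p.hf_amp_ms <= 0:
        raise GenerationError("modulation amplitudes exceed mean RR")
    t = 0.0
    times = [0.0]
    intervals = []
    while t < duration_s:
        rr = (mean_rr
              + p.lf_amp_ms * np.sin(2 * np.pi * p.lf_freq_hz * t)
              + p.hf_amp_ms * np.sin(2 * np.pi * p.hf_freq_hz * t)
              + (rng.normal(0.0, p.jitter_sd_ms) if p.jitter_sd_ms > 0 else 0.0))
        if rr <= 0:
            raise GenerationError("generated non-positive RR interval")
        intervals.append(rr)
        t += rr / 1000.0
        times.append(t)
    series = RRSeries(np.asarray(times), np.asarray(intervals))
    gt = GroundTruth({
        "condition": condition, "mean_rr_ms": mean_rr,
        "lf_freq_hz": p.lf_freq_hz, "hf_freq_hz": p.hf_freq_hz,
        "lf_amp_ms": p.lf_amp_ms, "hf_amp_ms": p.hf_amp_ms,
    })
    return series, gt


def gen_aoi(duration_s: float, n_appearances: int = 3,
            appearance_s: float = 4.0,
            screen: tuple[int, int] = (1920, 1080),
            rect_wh: tuple[int, int] = (400, 220),
            rng: np.random.Generator | None = None) -> AOITrack:
    """Evenly spaced brand appearances with randomly placed rectangles."""
    rng = rng or np.random.default_rng(0)
    w, h = screen
    rw, rh = rect_wh
    segs = []
    slot = duration_s / max(n_appearances, 1)
    appearance_s = min(appearance_s, 0.8 * slot)
    for i in range(n_appearances):
        t0 = (i * slot + (slot - appearance_s) / 2) * 1000.0
        x0 = float(rng.uniform(0, w - rw))
        y0 = float(rng.uniform(0, h - rh))
        segs.append(AOISegment(t0, t0 + appearance_s * 1000.0,
                               x0, y0, x0 + rw, y0 + rh))
    return AOITrack(segs)


def gen_gaze(spec: SyntheticCohortSpec, aoi: AOITrack,
             condition: str = "ad",
             rng: np.random.Generator | None = None,
             mode: str | None = None,
             attendance: float | None = None,
             ) -> tuple[GazeStream, GroundTruth]:
    """Fixation/saccade gaze stream with a planted brand-attendance
    fraction.

    Each brand appearance gets a fixation-time budget of
    ``attendance * appearance duration``; fixations started inside a
    visible AOI consume the budget (the closing fixation is truncated
    to it), everything else lands outside the rectangle.  Ambient mode
    scatters fixation centres across the whole screen with short
    dwells; focus mode keeps them near one cluster with long dwells.
    """
    p = spec.gaze
    rng = rng or np.random.default_rng(spec.seed)
    mode = mode or p.mode
    att = p.brand_attendance if attendance is None else attendance
    if not 0.0 <= att <= 1.0:
        raise ConfigurationError("attendance must be in [0, 1]")
    if mode not in ("ambient", "focus"):
        raise ConfigurationError(f"unknown gaze mode {mode!r}")
    w, h = p.screen
    dur_ms = spec.ad_duration_s * 1000.0
    dt = 1000.0 / p.rate
    budgets = {id(s): att * (s.t_end_ms - s.t_start_ms)
               for s in aoi.segments}
    focus_center = np.array([rng.uniform(w * .3, w * .7),
                             rng.uniform(h * .3, h * .7)])

    def away_from_gridlines(pt: np.ndarray,
                            grid: tuple[int, int] = (4, 4)) -> np.ndarray:
        # keep dwell centres clear of quadrant borders so sample jitter
        # does not alias into spurious quadrant visits
        cell = np.array([w / grid[1], h / grid[0]])
        rel = np.mod(pt, cell)
        pad = 4.0 * p.jitter_sd_px
        lo, hi = rel < pad, rel > cell - pad
        return pt + lo * (pad - rel) - hi * (rel - (cell - pad))

    def outside_point() -> np.ndarray:
        for _ in range(200):
            if mode == "ambient":
                pt = np.array([rng.uniform(20, w - 20),
                               rng.uniform(20, h - 20)])
            else:
                pt = focus_center + rng.normal(0, 60, size=2)
                pt = np.clip(pt, 20, [w - 20, h - 20])
            pt = away_from_gridlines(pt)
            seg = aoi.active_at(t)
            pad = 5.0 * p.jitter_sd_px
            if seg is None or not (seg.x0 - pad <= pt[0] < seg.x1 + pad
                                   and seg.y0 - pad <= pt[1] < seg.y1 + pad):
                return pt
        return pt

    def next_budgeted_onset(now: float) -> float | None:
        starts = [s.t_start_ms for s in aoi.segments
                  if s.t_start_ms > now and budgets[id(s)] >= 80.0]
        return min(starts) if starts else None

    ts, xs, ys = [], [], []
    t = 0.0
    prev_center = None
    n_fix = 0
    while t < dur_ms - dt:
        seg = aoi.active_at(t)
        inside = seg is not None and budgets[id(seg)] >= 80.0
        if inside:
            margin = 15.0
            center = np.array([
                rng.uniform(seg.x0 + margin, seg.x1 - margin),
                rng.uniform(seg.y0 + margin, seg.y1 - margin)])
            draw = rng.uniform(150.0, 350.0)
            fix_dur = min(draw, budgets[id(seg)], seg.t_end_ms - t)
            budgets[id(seg)] -= fix_dur
        else:
            center = outside_point()
            if prev_center is not None:
                tries = 0
                while np.hypot(*(center - prev_center)) < 50 and tries < 20:
                    center = outside_point()
                    tries += 1
            fix_dur = (rng.uniform(120.0, 280.0) if mode == "ambient"
                       else rng.uniform(350.0, 650.0))
            # do not let an off-brand dwell run over a pending appearance
            onset = next_budgeted_onset(t)
            if onset is not None:
                fix_dur = min(fix_dur, max(onset - t, 80.0))
        fix_dur = max(fix_dur, 80.0)
        n_fix += 1
        t_end = min(t + fix_dur, dur_ms)
        while t < t_end:
            jit = rng.normal(0.0, p.jitter_sd_px, size=2)
            ts.append(t)
            xs.append(center[0] + jit[0])
            ys.append(center[1] + jit[1])
            t += dt
        prev_center = center
        # while a visible appearance still has budget, jump straight to
        # the next in-brand dwell (the detector merges or splits on the
        # one fast inter-centre step; no fixation time is lost)
        if inside and budgets[id(seg)] >= 80.0 and t < seg.t_end_ms - dt:
            continue
        # saccade transit: a couple of fast intermediate samples
        n_sac = 2
        nxt = outside_point()
        for i in range(1, n_sac + 1):
            if t >= dur_ms:
                break
            frac = i / (n_sac + 1)
            px = center[0] + frac * (nxt[0] - center[0])
            py = center[1] + frac * (nxt[1] - center[1])
            seg_t = aoi.active_at(t)
            if seg_t is not None and seg_t.contains(px, py):
                t += dt  # transit would cross the visible brand: drop sample
                continue
            ts.append(t)
            xs.append(px)
            ys.append(py)
            t += dt
    valid = np.ones(len(ts), dtype=bool)
    stream = GazeStream(np.asarray(ts), np.asarray(xs), np.asarray(ys),
                        valid, rate=p.rate, screen=p.screen)
    gt = GroundTruth({
        "condition": condition, "mode": mode, "attendance": att,
        "n_fixations": n_fix,
    })
    return stream, gt


def _rank_effect(rank_idx: int) -> float:
    """Centred, unit-spaced effect of the four view-rank bins."""
    return rank_idx - 1.5


def _draw_ad_table(spec: SyntheticCohortSpec,
                   rng: np.random.Generator) -> list[dict]:
    """Per-ad views, rank and ACE score; ranks cycle over all four bins."""
    ads = []
    for a in range(spec.n_ads):
        rank_idx = a % 4
        lo, hi = _BIN_RANGES[rank_idx]
        views = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        ace = int(np.clip(530 + 120 * _rank_effect(rank_idx)
                          + rng.normal(0, 60), 1, 950))
        ads.append({"ad": a, "rank_idx": rank_idx,
                    "rank": RANK_LABELS[rank_idx],
                    "views": views, "ace": ace})
    return ads


def gen_feature_table(spec: SyntheticCohortSpec | None = None,
                      seed: int | None = None):
    """Metric-level cohort: the ~37-column feature table plus labels.

    Informative columns carry a per-rank mean shift of
    ``labels.effect_size`` standard deviations per rank step; all other
    metric columns are pure noise.  This is the fast path for testing
    the statistics and network stages at full cohort size without
    synthesising raw signals.

    Returns ``(table, GroundTruth)`` where table holds one row per
    subject x ad with all metric columns, gender and labels.
    """
    import pandas as pd

    spec = spec or SyntheticCohortSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    ads = _draw_ad_table(spec, rng)
    eff = spec.labels.effect_size
    rows = []
    genders = rng.integers(0, 2, size=spec.n_subjects)
    for s in range(spec.n_subjects):
        for ad in ads:
            q = _rank_effect(ad["rank_idx"])
            row = {"subject": s, "ad": ad["ad"], "views": ad["views"],
                   "rank": ad["rank"], "ace": ad["ace"],
                   "gender": int(genders[s])}
            for m in ALL_METRIC_NAMES:
                base = rng.standard_normal()
                if m in _INFORMATIVE:
                    base += eff * q
                row[m] = base
            latent = eff * q + rng.normal(0.0, spec.labels.noise_sd)
            row["recall"] = "RMB" if latent > 0 else "FRG"
            rating = int(np.clip(round(5.5 + 2.0 * latent), 1, 10))
            row["liking_rating"] = rating
            row["liking"] = "LIKE" if rating >= 5 else "DISLIKE"
            rows.append(row)
    table = pd.DataFrame(rows)
    gt = GroundTruth({
        "informative": list(_INFORMATIVE),
        "effect_size": eff,
        "ads": ads,
    })
    return table, gt


def gen_cohort(spec: SyntheticCohortSpec, outdir) -> dict:
    """Generate and write a full on-disk cohort.

    Layout: one ``sub{S}_ad{A}`` directory per stream triple holding
    eeg.csv + events.json, rr.txt, gaze.tsv and aoi.json; cohort-level
    labels.csv and ground_truth.json.  Returns the manifest dict.
    """
    from pathlib import Path

    from . import io as aio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root_ss = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(root_ss.spawn(1)[0])
    ads = _draw_ad_table(spec, rng)
    eff = spec.labels.effect_size
    genders = rng.integers(0, 2, size=spec.n_subjects)

    label_rows = []
    truth: dict[str, dict] = {"spec_seed": spec.seed, "streams": {}}
    for s in range(spec.n_subjects):
        for ad in ads:
            key = f"sub{s:02d}_ad{ad['ad']:02d}"
            d = outdir / key
            d.mkdir(exist_ok=True)
            ss = np.random.SeedSequence(
                entropy=spec.seed, spawn_key=(s, ad["ad"]))
            r_eeg, r_rr, r_gaze, r_lab = (
                np.random.default_rng(c) for c in ss.spawn(4))
            q = _rank_effect(ad["rank_idx"])

            aoi = gen_aoi(spec.ad_duration_s, screen=spec.gaze.screen,
                          rng=r_gaze)
            brand_windows = [(seg.t_start_ms / 1000.0, seg.t_end_ms / 1000.0)
                             for seg in aoi.segments]

            theta_gain = float(np.clip(1.0 + 0.25 * eff * q, 0.2, 4.0))
            asym = float(np.clip(0.2 * eff * q, -0.8, 0.8))
            rec, gt_eeg = gen_eeg(spec, rng=r_eeg, asymmetry=asym,
                                  band_gain={"theta": theta_gain},
                                  brand_windows=brand_windows)
            mean_rr = float(np.clip(
                spec.hrv.mean_rr_ms * (1.0 - 0.04 * eff * q), 400, 1800))
            rr, gt_rr = gen_rr(spec, rng=r_rr, mean_rr_ms=mean_rr)
            att = float(np.clip(0.45 + 0.10 * eff * q, 0.05, 0.95))
            gaze, gt_gaze = gen_gaze(spec, aoi, rng=r_gaze, attendance=att)

            aio.write_eeg_csv(d / "eeg.csv", rec)
            aio.write_events_json(d / "events.json", rec)
            aio.write_rr_txt(d / "rr.txt", rr)
            aio.write_gaze_tsv(d / "gaze.tsv", gaze)
            aio.write_aoi_json(d / "aoi.json", aoi)

            latent = eff * q + r_lab.normal(0.0, spec.labels.noise_sd)
            rating = int(np.clip(round(5.5 + 2.0 * latent), 1, 10))
            label_rows.append({
                "subject": s, "ad": ad["ad"],
                "recall": "RMB" if latent > 0 else "FRG",
                "liking_rating": rating,
                "liking": "LIKE" if rating >= 5 else "DISLIKE",
                "views": ad["views"], "rank": ad["rank"],
                "ace": ad["ace"], "gender": int(genders[s]),
            })
            truth["streams"][key] = {
                "eeg": gt_eeg.as_dict(), "rr": gt_rr.as_dict(),
                "gaze": gt_gaze.as_dict(), "latent": float(latent),
            }
    aio.write_labels_csv(outdir / "labels.csv", label_rows)
    aio.write_json(outdir / "ground_truth.json", truth)
    return {"n_streams": spec.n_subjects * spec.n_ads, "outdir": str(outdir),
            "spec": asdict(spec)}
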