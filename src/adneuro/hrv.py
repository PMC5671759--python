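"""Heart-rate-variability metrics from RR-interval series.

Seventeen metrics across three domains:

* time: t_meanHR, t_sdHR (bpm), t_RMSSD (ms), t_NN50 (count);
* frequency: Lomb-Scargle periodogram of the beat-timed interval
  series, integrated over the standard LF (0.04-0.15 Hz) and HF
  (0.15-0.40 Hz) bands — absolute, normalized and peak-frequency
  variants plus the LF/HF sympathovagal ratio;
* non-linear: Poincare SD1/SD2 and sample entropy at embedding
  lengths 1 and 2.

The Lomb-Scargle estimator is used because beat times are inherently
unevenly spaced; no resampling of the RR series is performed.  The
canonical input is an already-screened RR series; a simple energy-based
R-peak detector is provided for raw single-lead ECG.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import (
    DegenerateInputError,
    DetectionError,
    InsufficientDataError,
    QualityError,
)

__all__ = [
    "RRSeries",
    "FrequencyBands",
    "detect_rpeaks",
    "screen_ectopics",
    "time_domain",
    "lomb_spectrum",
    "poincare",
    "sample_entropy",
    "hrv_all",
    "HRV_METRIC_NAMES",
]

HRV_METRIC_NAMES = [
    "t_meanHR", "t_sdHR", "t_NN50", "t_RMSSD",
    "f_aLF_lomb", "f_aHF_lomb", "f_aTotal_lomb",
    "f_nLF_lomb", "f_nHF_lomb", "f_LFHF_lomb",
    "f_peakLF_lomb", "f_peakHF_lomb",
    "p_SD1", "p_SD2", "p_SD1vsSD2",
    "nl_sampen1", "nl_sampen2",
]


@dataclass
class FrequencyBands:
    """LF/HF band edges in Hz (Task-Force standard defaults)."""

    lf: tuple[float, float] = (0.04, 0.15)
    hf: tuple[float, float] = (0.15, 0.40)


@dataclass
class RRSeries:
    """Beat times (s, cumulative) and beat-to-beat intervals (ms).

    ``intervals[i]`` is the time from beat i to beat i+1, so there is
    one fewer interval than beat time.
    """

    beat_times: np.ndarray
    intervals: np.ndarray

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.intervals = np.asarray(self.intervals, dtype=float)
        if np.any(self.intervals <= 0):
            raise DegenerateInputError("non-positive RR interval")
        if np.any(np.diff(self.beat_times) <= 0):
            raise DegenerateInputError("beat times not strictly increasing")
        if self.beat_times.size != self.intervals.size + 1:
            raise DegenerateInputError(
                "need exactly one more beat time than intervals")

    @classmethod
    def from_intervals(cls, intervals_ms, t0: float = 0.0) -> "RRSeries":
        iv = np.asarray(intervals_ms, dtype=float)
        times = t0 + np.concatenate([[0.0], np.cumsum(iv) / 1000.0])
        return cls(times, iv)

    @property
    def n_beats(self) -> int:
        return self.beat_times.size

    @property
    def span_s(self) -> float:
        return float(self.beat_times[-1] - self.beat_times[0])


def detect_rpeaks(ecg: np.ndarray, rate: float,
                  refractory_s: float = 0.2) -> RRSeries:
    """Energy-based R-peak detection (derivative, square, integrate).

    The integrated energy must be spiky — a peak has to stand well above
    the series median — so broadband or sinusoidal inputs without QRS
    morphology yield a detection error rather than spurious beats.
    """
    x = np.asarray(ecg, dtype=float)
    if rate < 100:
        raise DetectionError("ECG sampling rate below 100 Hz")
    if x.size < 10 * rate:
        raise InsufficientDataError("need at least 10 s of ECG")
    d = np.diff(x)
    energy = d * d
    win = max(1, int(round(0.15 * rate)))
    integ = np.convolve(energy, np.ones(win) / win, mode="same")
    med = np.median(integ)
    height = max(0.25 * integ.max(), 4.0 * med)
    if integ.max() < 4.0 * max(med, 1e-30):
        raise DetectionError("no QRS-like spikes found")
    locs, _ = sps.find_peaks(integ, height=height,
                             distance=max(1, int(round(refractory_s * rate))))
    if locs.size < 2:
        raise DetectionError("fewer than two beats detected")
    # refine each peak to the local ECG maximum inside the window
    half = win
    peaks = []
    for p in locs:
        lo, hi = max(0, p - half), min(x.size, p + half)
        peaks.append(lo + int(np.argmax(x[lo:hi])))
    times = np.unique(np.asarray(peaks)) / rate
    return RRSeries(times, np.diff(times) * 1000.0)


def screen_ectopics(rr: RRSeries, tol: float = 0.2,
                    window: int = 5,
                    max_flag_frac: float = 0.2) -> tuple[RRSeries, np.ndarray]:
    """Flag intervals deviating more than ``tol`` from the local median.

    Flagged intervals (ectopic beats, missed detections) are replaced by
    the local-median value.  A series with more than ``max_flag_frac``
    flagged is rejected outright.
    """
    if rr.intervals.size < 3:
        raise InsufficientDataError("need at least 3 intervals to screen")
    iv = rr.intervals
    k = window if window % 2 == 1 else window + 1
    pad = k // 2
    padded = np.concatenate([iv[:pad][::-1], iv, iv[-pad:][::-1]])
    med = np.array([np.median(padded[i:i + k]) for i in range(iv.size)])
    with np.errstate(divide="ignore"):
        flags = np.abs(iv - med) / med > tol
    if flags.mean() > max_flag_frac:
        raise QualityError(
            f"{100 * flags.mean():.0f}% of intervals flagged as ectopic")
    if not flags.any():
        return rr, flags
    cleaned = np.where(flags, med, iv)
    return RRSeries.from_intervals(cleaned, t0=rr.beat_times[0]), flags


def time_domain(rr: RRSeries) -> dict[str, float]:
    """t_meanHR/t_sdHR in bpm, t_RMSSD in ms, t_NN50 count."""
    iv = rr.intervals
    if iv.size < 2:
        raise InsufficientDataError("need at least 2 intervals")
    hr = 60000.0 / iv
    d = np.diff(iv)
    return {
        "t_meanHR": float(hr.mean()),
        "t_sdHR": float(hr.std(ddof=1)),
        "t_RMSSD": float(np.sqrt(np.mean(d * d))),
        "t_NN50": int(np.sum(np.abs(d) > 50.0)),
    }


def lomb_grid(span_s: float, f_min: float = 0.003,
              f_max: float = 0.5) -> np.ndarray:
    """Frequency grid with resolution 1/(4 * series span)."""
    df = 1.0 / (4.0 * span_s)
    return np.arange(f_min, f_max + df / 2, df)


def lomb_spectrum(rr: RRSeries,
                  bands: FrequencyBands | None = None,
                  freqs: np.ndarray | None = None) -> dict[str, float]:
    """Lomb-Scargle band powers of the mean-centred RR series.

    Power is integrated trapezoidally over the LF and HF bands; total
    power is the LF+HF sum (VLF excluded), so f_nLF_lomb + f_nHF_lomb
    is exactly 1.  Peak frequencies are the within-band argmax of the
    periodogram.  Percent variants f_pLF/f_pHF (= 100 * normalized) are
    also returned.
    """
    bands = bands or FrequencyBands()
    if rr.intervals.size < 4:
        raise InsufficientDataError("too few beats for a spectrum")
    if freqs is None:
        freqs = lomb_grid(rr.span_s)
    # interval i is attributed to the time of the beat that closes it
    t = rr.beat_times[1:]
    y = rr.intervals - rr.intervals.mean()
    if not np.any(y):
        raise DegenerateInputError("constant RR series has zero power")
    power = sps.lombscargle(t, y, 2 * np.pi * freqs)
    power *= 2.0 / y.size  # per-Hz-ish scaling; units ms^2 x s

    def band_power(lo: float, hi: float) -> tuple[float, float]:
        m = (freqs >= lo) & (freqs <= hi)
        if m.sum() < 2:
            raise DegenerateInputError("frequency grid too coarse for band")
        p = float(np.trapezoid(power[m], freqs[m]))
        peak = float(freqs[m][np.argmax(power[m])])
        return p, peak

    a_lf, peak_lf = band_power(*bands.lf)
    a_hf, peak_hf = band_power(*bands.hf)
    a_total = a_lf + a_hf
    if a_total <= 0:
        raise DegenerateInputError("zero in-band spectral power")
    return {
        "f_aLF_lomb": a_lf,
        "f_aHF_lomb": a_hf,
        "f_aTotal_lomb": a_total,
        "f_nLF_lomb": a_lf / a_total,
        "f_nHF_lomb": a_hf / a_total,
        "f_pLF": 100.0 * a_lf / a_total,
        "f_pHF": 100.0 * a_hf / a_total,
        "f_LFHF_lomb": a_lf / a_hf if a_hf > 0 else np.inf,
        "f_peakLF_lomb": peak_lf,
        "f_peakHF_lomb": peak_hf,
    }


def poincare(rr: RRSeries) -> dict[str, float]:
    """Poincare plot dispersion SD1 (short-term) and SD2 (long-term).

    SD1 is the RMS perpendicular distance of the (RR_i, RR_i+1) points
    to the line of identity — the distance of a point to that line is
    |RR_i+1 - RR_i| / sqrt(2), so no mean is subtracted and the identity
    SD1 = RMSSD / sqrt(2) holds exactly.  SD2 is the sample SD of the
    projections along the identity line.
    """
    iv = rr.intervals
    if iv.size < 3:
        raise InsufficientDataError("need at least 3 intervals")
    d = np.diff(iv)
    s = (iv[:-1] + iv[1:]) / np.sqrt(2.0)
    sd1 = float(np.sqrt(np.mean(d * d) / 2.0))
    sd2 = float(s.std(ddof=1))
    ratio = sd1 / sd2 if sd2 > 0 else np.nan
    return {"p_SD1": sd1, "p_SD2": sd2, "p_SD1vsSD2": ratio}


def sample_entropy(x: np.ndarray, m: int = 2,
                   r_frac: float = 0.2) -> float:
    """Sample entropy: -ln(A/B) with tolerance r = r_frac * SD(x).

    B counts template pairs of length ``m`` (Chebyshev distance <= r,
    self-matches excluded), A the pairs still matching at length m+1;
    both counts run over the n-m templates that have an (m+1)-th
    element.  Zero for perfectly regular series; NaN when no m-match
    exists; +inf when m-matches exist but none extends.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < m + 2:
        raise InsufficientDataError("series shorter than m + 2")
    sd = x.std(ddof=1)
    if not sd > 0:
        return 0.0  # constant series: perfectly regular by convention
    r = r_frac * sd
    nt = n - m  # number of templates with an extension
    close = np.abs(x[:, None] - x[None, :]) <= r
    match_m = close[:nt, :nt].copy()
    for k in range(1, m):
        match_m &= close[k:k + nt, k:k + nt]
    match_m1 = match_m & close[m:m + nt, m:m + nt]
    iu = np.triu_indices(nt, k=1)
    b = int(match_m[iu].sum())
    a = int(match_m1[iu].sum())
    if b == 0:
        return np.nan
    if a == 0:
        return np.inf
    return float(-np.log(a / b))


def hrv_all(rr: RRSeries, bands: FrequencyBands | None = None,
            sampen_r: float = 0.2) -> dict[str, float]:
    """All seventeen HRV metrics in one pass.

    Sub-stage failures degrade to NaN for the affected metrics rather
    than aborting the whole row.
    """
    out: dict[str, float] = {k: np.nan for k in HRV_METRIC_NAMES}
    try:
        out.update(time_domain(rr))
    except (InsufficientDataError, DegenerateInputError):
        pass
    try:
        spec = lomb_spectrum(rr, bands)
        out.update({k: v for k, v in spec.items()
                    if k in HRV_METRIC_NAMES})
    except (InsufficientDataError, DegenerateInputError):
        pass
    try:
        out.update(poincare(rr))
    except (InsufficientDataError, DegenerateInputError):
        pass
    try:
        out["nl_sampen1"] = sample_entropy(rr.intervals, m=1, r_frac=sampen_r)
        out["nl_sampen2"] = sample_entropy(rr.intervals, m=2, r_frac=sampen_r)
    except InsufficientDataError:
        pass
    return out
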