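"""EEG brain-response metrics for ad viewing.

The metrics quantify band-specific cortical activation while a subject
watches a commercial, referenced to a neutral-documentary baseline:

* per-band z-scores of frontal Global Field Power (GFP) against the
  baseline period,
* a Pleasantness Index (PI): left-minus-right frontal GFP asymmetry in
  the theta and alpha bands (positive = left-dominant = approach/
  pleasant under the standard frontal-asymmetry reading),
* an Interest Index (II): the fraction of "relevant" band-GFP peaks
  that fall inside brand-exposure windows.

Processing stages: 1-s epoching with kurtosis-based artifact rejection,
zero-phase Butterworth band-pass filtering, spatial GFP, baseline
z-scoring.  Ocular/muscular component removal is not performed here; a
recording cleaned by any external method can be passed straight in.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .errors import (
    ConfigurationError,
    DegenerateInputError,
    EmptyResultError,
    InsufficientDataError,
)
from .montage import FRONTAL_CHANNELS, FRONTAL_PAIRS, POSITIONS_2D

__all__ = [
    "EEGRecording",
    "EpochSet",
    "BandDefinition",
    "DEFAULT_BANDS",
    "kurtosis",
    "reject_epochs",
    "interpolate_bad_channels",
    "band_filter",
    "gfp",
    "band_zscore",
    "pleasantness_index",
    "interest_index",
    "extract_eeg_metrics",
]

EVENT_KINDS = {
    "baseline_start", "baseline_end",
    "ad_start", "ad_end",
    "brand_on", "brand_off",
}


@dataclass
class BandDefinition:
    """A named frequency band in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ConfigurationError(f"invalid band {self.name}: "
                                     f"[{self.low}, {self.high}] Hz")


DEFAULT_BANDS: dict[str, BandDefinition] = {
    "delta": BandDefinition("delta", 1.0, 3.0),
    "theta": BandDefinition("theta", 4.0, 7.0),
    "alpha": BandDefinition("alpha", 8.0, 12.0),
    "beta": BandDefinition("beta", 13.0, 24.0),
    "beta_ext": BandDefinition("beta_ext", 13.0, 40.0),
    "gamma": BandDefinition("gamma", 25.0, 60.0),
}


@dataclass
class EEGRecording:
    """Multichannel EEG: ``data`` is channels x samples in microvolt.

    ``events`` is a list of ``(time_s, kind)`` markers; times are
    relative to the first sample.
    """

    data: np.ndarray
    rate: float
    channels: list[str]
    events: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ConfigurationError("data must be channels x samples")
        if self.rate <= 0:
            raise ConfigurationError("sampling rate must be positive")
        if len(self.channels) != self.data.shape[0]:
            raise ConfigurationError("one label per channel required")
        if len(set(self.channels)) != len(self.channels):
            raise ConfigurationError("channel labels must be unique")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def window(self, kind: str) -> tuple[float, float]:
        """Return the (start, end) times of a ``<kind>_start/_end`` pair."""
        starts = [t for t, k in self.events if k == f"{kind}_start"]
        ends = [t for t, k in self.events if k == f"{kind}_end"]
        if not starts or not ends:
            raise ConfigurationError(f"no {kind} window in events")
        return starts[0], ends[0]

    def windows(self, on: str, off: str) -> list[tuple[float, float]]:
        """Paired on/off event windows (e.g. brand appearances)."""
        ons = sorted(t for t, k in self.events if k == on)
        offs = sorted(t for t, k in self.events if k == off)
        return list(zip(ons, offs))

    def pick(self, labels: list[str]) -> np.ndarray:
        idx = []
        for lab in labels:
            if lab not in self.channels:
                raise ConfigurationError(f"unknown montage label {lab!r}")
            idx.append(self.channels.index(lab))
        return self.data[idx]


@dataclass
class EpochSet:
    """1-s epochs of a recording plus the kurtosis-based rejection mask."""

    epochs: np.ndarray          # n_epochs x channels x samples_per_epoch
    epoch_kurtosis: np.ndarray  # n_epochs x channels
    rejected: np.ndarray        # n_epochs bool
    start_time: float           # recording time of epoch 0

    @property
    def kept(self) -> np.ndarray:
        return self.epochs[~self.rejected]


def kurtosis(x: np.ndarray) -> float:
    """Fourth standardized moment K = E[(x-mu)^4] / E[(x-mu)^2]^2.

    Population moments; no excess-3 subtraction, so a normal sample
    gives values near 3.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise InsufficientDataError("kurtosis needs at least 4 samples")
    d = x - x.mean()
    m2 = np.mean(d * d)
    if m2 == 0:
        raise DegenerateInputError("zero-variance (flat) signal")
    return float(np.mean(d ** 4) / m2 ** 2)


def _epoch(rec: EEGRecording, t0: float, t1: float) -> tuple[np.ndarray, float]:
    """Cut non-overlapping 1-s epochs from [t0, t1); drop partial tail."""
    n = int(round(rec.rate))
    i0 = int(round(t0 * rec.rate))
    i1 = min(int(round(t1 * rec.rate)), rec.n_samples)
    n_ep = (i1 - i0) // n
    if n_ep < 1:
        raise InsufficientDataError("window shorter than one epoch")
    block = rec.data[:, i0:i0 + n_ep * n]
    eps = block.reshape(rec.data.shape[0], n_ep, n).transpose(1, 0, 2)
    return eps, i0 / rec.rate


def reject_epochs(rec: EEGRecording, z_thresh: float = 5.0,
                  window: tuple[float, float] | None = None) -> EpochSet:
    """Flag 1-s epochs whose within-channel kurtosis is an outlier.

    Each channel's epoch kurtosis values are standardized across epochs;
    an epoch is rejected when any channel exceeds ``|z| > z_thresh``.
    """
    if window is None:
        window = (0.0, rec.n_samples / rec.rate)
    eps, start = _epoch(rec, *window)
    n_ep, n_ch, _ = eps.shape
    kurt = np.empty((n_ep, n_ch))
    for e in range(n_ep):
        for c in range(n_ch):
            d = eps[e, c] - eps[e, c].mean()
            m2 = np.mean(d * d)
            kurt[e, c] = np.mean(d ** 4) / m2 ** 2 if m2 > 0 else np.nan
    # robust standardization of log-kurtosis (median / scaled MAD):
    # plain mean/SD z-scores are masked by the artifact epochs they
    # should flag, and raw kurtosis is right-skewed; the log symmetrizes
    with np.errstate(invalid="ignore", divide="ignore"):
        lk = np.log(kurt)
        med = np.nanmedian(lk, axis=0)
        mad = 1.4826 * np.nanmedian(np.abs(lk - med), axis=0)
        z = (lk - med) / np.where(mad > 0, mad, np.inf)
    rejected = np.nanmax(np.abs(z), axis=1) > z_thresh
    if rejected.all():
        raise EmptyResultError("all epochs rejected")
    return EpochSet(eps, kurt, rejected, start)


def interpolate_bad_channels(rec: EEGRecording, bad: set[str],
                             k: int = 4) -> EEGRecording:
    """Replace bad channels by an inverse-distance-weighted mean of the
    ``k`` nearest good electrodes in the projected 10-20 layout."""
    bad = set(bad)
    if not bad:
        return rec
    unknown = bad - set(rec.channels)
    if unknown:
        raise ConfigurationError(f"unknown montage labels {sorted(unknown)}")
    good = [c for c in rec.channels if c not in bad]
    if not good:
        raise DegenerateInputError("all channels marked bad")
    data = rec.data.copy()
    for ch in bad:
        dists = sorted(
            (np.hypot(POSITIONS_2D[ch][0] - POSITIONS_2D[g][0],
                      POSITIONS_2D[ch][1] - POSITIONS_2D[g][1]), g)
            for g in good if g in POSITIONS_2D
        )[:k]
        if not dists:
            raise ConfigurationError(f"no positioned neighbour for {ch!r}")
        w = np.array([1.0 / max(d, 1e-9) for d, _ in dists])
        w /= w.sum()
        neigh = rec.pick([g for _, g in dists])
        data[rec.channels.index(ch)] = w @ neigh
    return replace(rec, data=data)


def band_filter(rec: EEGRecording, band: BandDefinition,
                order: int = 4) -> EEGRecording:
    """Zero-phase band-pass: a Butterworth filter applied forward and
    backward, so the pass is effectively squared and phase cancels."""
    nyq = rec.rate / 2
    if not 0 < band.low < band.high < nyq:
        raise ConfigurationError(
            f"band [{band.low}, {band.high}] Hz outside (0, {nyq}) Hz")
    sos = sps.butter(order, [band.low, band.high], btype="band",
                     fs=rec.rate, output="sos")
    return replace(rec, data=sps.sosfiltfilt(sos, rec.data, axis=1))


def gfp(rec_or_data, electrodes: list[str] | None = None) -> np.ndarray:
    """Global field power: the spatial standard deviation (1/N) across
    the selected electrodes at every time sample."""
    if isinstance(rec_or_data, EEGRecording):
        data = (rec_or_data.pick(electrodes) if electrodes is not None
                else rec_or_data.data)
    else:
        data = np.asarray(rec_or_data, dtype=float)
    if data.shape[0] < 2:
        raise ConfigurationError("GFP needs at least 2 electrodes")
    return np.sqrt(np.mean((data - data.mean(axis=0)) ** 2, axis=0))


def band_zscore(ad_gfp: np.ndarray, baseline_gfp: np.ndarray) -> float:
    """z = (mean(ad GFP) - mean(baseline GFP)) / SD(baseline GFP)."""
    base = np.asarray(baseline_gfp, dtype=float)
    sd = base.std(ddof=1)
    if not sd > 0:
        raise DegenerateInputError("baseline GFP has zero variance")
    return float((np.mean(ad_gfp) - base.mean()) / sd)


def _side_z(series_ad: np.ndarray, series_base: np.ndarray) -> np.ndarray:
    sd = series_base.std(ddof=1)
    if not sd > 0:
        raise DegenerateInputError("baseline side GFP has zero variance")
    return (series_ad - series_base.mean()) / sd


def pleasantness_index(rec: EEGRecording, band: BandDefinition,
                       pairs: list[tuple[str, str]] | None = None,
                       keep_mask: np.ndarray | None = None) -> float:
    """Frontal-asymmetry pleasantness index in one band.

    GFP is computed separately over the left and the right electrodes of
    the homologous frontal pairs; each side is z-scored against its own
    baseline window; PI is the ad-period mean of (left - right).
    Positive = left-dominant.
    """
    if pairs is None:
        pairs = [p for p in FRONTAL_PAIRS
                 if p[0] in rec.channels and p[1] in rec.channels]
    if not pairs:
        raise ConfigurationError("no valid left/right frontal pair")
    for l, r in pairs:
        if l not in rec.channels or r not in rec.channels:
            raise ConfigurationError(f"missing pair electrode {l}/{r}")
    filt = band_filter(rec, band)
    left = gfp(filt, [l for l, _ in pairs])
    right = gfp(filt, [r for _, r in pairs])
    b0, b1 = rec.window("baseline")
    a0, a1 = rec.window("ad")
    sl = slice(int(round(b0 * rec.rate)), int(round(b1 * rec.rate)))
    sa = slice(int(round(a0 * rec.rate)), int(round(a1 * rec.rate)))
    zl = _side_z(left[sa], left[sl])
    zr = _side_z(right[sa], right[sl])
    diff = zl - zr
    if keep_mask is not None:
        diff = diff[keep_mask[: diff.size]]
    return float(diff.mean())


def interest_index(gfp_band: np.ndarray, rate: float,
                   brand_windows: list[tuple[float, float]],
                   c: float = 2.0, min_distance_s: float = 0.25,
                   t0: float = 0.0) -> tuple[int, int, float]:
    """Count relevant band-GFP peaks, total vs inside brand windows.

    A peak is a local maximum exceeding mean + ``c``*SD of the series,
    with at least ``min_distance_s`` between accepted peaks.  Returns
    ``(PN_total, PN_brand, II)`` with II = PN_brand / PN_total (0 when
    no peak at all).  ``t0`` is the recording time of the first sample,
    so window times and peak times share a clock.
    """
    x = np.asarray(gfp_band, dtype=float)
    thresh = x.mean() + c * x.std(ddof=1) if x.size > 1 else np.inf
    idx, _ = sps.find_peaks(x, height=thresh,
                            distance=max(1, int(round(min_distance_s * rate))))
    times = t0 + idx / rate
    pn_total = int(idx.size)
    pn_brand = int(sum(any(w0 <= t < w1 for w0, w1 in brand_windows)
                       for t in times))
    ii = pn_brand / pn_total if pn_total else 0.0
    return pn_total, pn_brand, ii


def _masked_mean_series(series: np.ndarray, i0: int, i1: int,
                        keep: np.ndarray | None, rate: float) -> np.ndarray:
    """Slice [i0,i1) of a series, dropping samples of rejected epochs."""
    seg = series[i0:i1]
    if keep is None:
        return seg
    n = int(round(rate))
    mask = np.ones(seg.size, dtype=bool)
    for e, k in enumerate(keep):
        if not k:
            mask[e * n:(e + 1) * n] = False
    return seg[mask]


def extract_eeg_metrics(rec: EEGRecording,
                        bands: dict[str, BandDefinition] | None = None,
                        frontal: list[str] | None = None,
                        pairs: list[tuple[str, str]] | None = None,
                        z_thresh: float = 5.0,
                        peak_c: float = 2.0) -> dict[str, float]:
    """Full per-ad EEG metric row.

    Returns z_<band> for the six bands, PI_theta, PI_alpha, II_theta and
    II_beta, using baseline/ad/brand windows from the recording events.
    Epochs rejected by the kurtosis rule are excluded from the ad and
    baseline averages.
    """
    bands = bands or DEFAULT_BANDS
    frontal = frontal or [c for c in FRONTAL_CHANNELS if c in rec.channels]
    b0, b1 = rec.window("baseline")
    a0, a1 = rec.window("ad")
    brand = rec.windows("brand_on", "brand_off")

    if z_thresh == np.inf:
        keep_ad = keep_base = None
    else:
        keep_ad = ~reject_epochs(rec, z_thresh, (a0, a1)).rejected
        keep_base = ~reject_epochs(rec, z_thresh, (b0, b1)).rejected

    ia0, ia1 = int(round(a0 * rec.rate)), int(round(a1 * rec.rate))
    ib0, ib1 = int(round(b0 * rec.rate)), int(round(b1 * rec.rate))

    out: dict[str, float] = {}
    for name, band in bands.items():
        g = gfp(band_filter(rec, band), frontal)
        g_ad = _masked_mean_series(g, ia0, ia1, keep_ad, rec.rate)
        g_base = _masked_mean_series(g, ib0, ib1, keep_base, rec.rate)
        out[f"z_{name}"] = band_zscore(g_ad, g_base)
        if name in ("theta", "beta"):
            _, _, ii = interest_index(g[ia0:ia1], rec.rate, brand,
                                      c=peak_c, t0=a0)
            out[f"II_{name}"] = ii
        if name in ("theta", "alpha"):
            out[f"PI_{name}"] = pleasantness_index(rec, band, pairs)
    return out
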