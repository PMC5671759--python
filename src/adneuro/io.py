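"""Plain-text readers and writers for the cohort on-disk layout.

Per subject x ad directory: ``eeg.csv`` (header row = montage labels,
one row per sample, microvolt), ``events.json`` (rate + timed event
markers), ``rr.txt`` (one RR interval in ms per line), ``gaze.tsv``
(timestamp_ms, x_px, y_px, validity) and ``aoi.json`` (time-stamped
brand rectangles).  Cohort level: ``labels.csv`` and
``ground_truth.json``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .eeg import EEGRecording
from .errors import ConfigurationError
from .gaze import AOISegment, AOITrack, GazeStream
from .hrv import RRSeries

__all__ = [
    "write_eeg_csv", "read_eeg_csv", "write_events_json",
    "write_rr_txt", "read_rr_txt",
    "write_gaze_tsv", "read_gaze_tsv",
    "write_aoi_json", "read_aoi_json",
    "write_labels_csv", "read_labels_csv",
    "write_json", "read_json",
    "read_stream_dir", "validate_inputs",
]


def write_eeg_csv(path, rec: EEGRecording) -> None:
    df = pd.DataFrame(rec.data.T, columns=rec.channels)
    df.to_csv(path, index=False, float_format="%.4f")


def write_events_json(path, rec: EEGRecording,
                      extra: dict | None = None) -> None:
    payload = {"rate": rec.rate,
               "events": [[float(t), k] for t, k in rec.events]}
    payload.update(extra or {})
    write_json(path, payload)


def read_eeg_csv(path, events_path=None) -> EEGRecording:
    df = pd.read_csv(path)
    rate, events = 256.0, []
    if events_path is not None and Path(events_path).exists():
        meta = read_json(events_path)
        rate = float(meta.get("rate", rate))
        events = [(float(t), str(k)) for t, k in meta.get("events", [])]
    return EEGRecording(df.to_numpy(dtype=float).T, rate,
                        list(df.columns), events)


def write_rr_txt(path, rr: RRSeries) -> None:
    np.savetxt(path, rr.intervals, fmt="%.3f")


def read_rr_txt(path) -> RRSeries:
    iv = np.loadtxt(path, ndmin=1)
    return RRSeries.from_intervals(iv)


def write_gaze_tsv(path, g: GazeStream) -> None:
    df = pd.DataFrame({
        "timestamp_ms": g.t_ms, "x_px": g.x, "y_px": g.y,
        "validity": g.valid.astype(int),
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.2f")


def read_gaze_tsv(path, rate: float = 300.0,
                  screen: tuple[int, int] = (1920, 1080)) -> GazeStream:
    df = pd.read_csv(path, sep="\t")
    required = {"timestamp_ms", "x_px", "y_px", "validity"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"gaze file missing columns {sorted(missing)}")
    return GazeStream(df["timestamp_ms"].to_numpy(float),
                      df["x_px"].to_numpy(float),
                      df["y_px"].to_numpy(float),
                      df["validity"].to_numpy() != 0,
                      rate=rate, screen=screen)


def write_aoi_json(path, aoi: AOITrack) -> None:
    write_json(path, [
        {"t_start_ms": s.t_start_ms, "t_end_ms": s.t_end_ms,
         "x0": s.x0, "y0": s.y0, "x1": s.x1, "y1": s.y1}
        for s in aoi.segments
    ])


def read_aoi_json(path) -> AOITrack:
    return AOITrack([AOISegment(**d) for d in read_json(path)])


def write_labels_csv(path, rows: list[dict]) -> None:
    pd.DataFrame(rows).to_csv(path, index=False)


def read_labels_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def read_stream_dir(d) -> dict:
    """Load the eeg/rr/gaze/aoi quadruple of one subject x ad directory."""
    d = Path(d)
    meta = read_json(d / "events.json") if (d / "events.json").exists() else {}
    return {
        "eeg": read_eeg_csv(d / "eeg.csv", d / "events.json"),
        "rr": read_rr_txt(d / "rr.txt"),
        "gaze": read_gaze_tsv(d / "gaze.tsv",
                              rate=float(meta.get("gaze_rate", 300.0)),
                              screen=tuple(meta.get("screen", (1920, 1080)))),
        "aoi": read_aoi_json(d / "aoi.json"),
    }


def validate_inputs(cohort_dir) -> list[dict]:
    """Schema check of a cohort directory; report-only, never raises.

    Returns one record per checked file with ``ok`` and a message
    naming the first offending line where applicable.
    """
    root = Path(cohort_dir)
    report: list[dict] = []

    def add(path, ok, msg=""):
        report.append({"file": str(path), "ok": bool(ok), "message": msg})

    labels = root / "labels.csv"
    if labels.exists():
        try:
            df = read_labels_csv(labels)
            ok, msg = True, ""
            if "liking_rating" in df.columns:
                bad = df.index[(df["liking_rating"] < 1)
                               | (df["liking_rating"] > 10)]
                if len(bad):
                    ok, msg = False, (f"liking_rating outside 1-10 at row "
                                      f"{int(bad[0]) + 2}")
            add(labels, ok, msg)
        except Exception as exc:  # noqa: BLE001 - report, don't raise
            add(labels, False, str(exc))
    else:
        add(labels, False, "missing")

    for d in sorted(p for p in root.iterdir() if p.is_dir()):
        for name, reader in (("eeg.csv", lambda p: read_eeg_csv(p)),
                             ("rr.txt", read_rr_txt),
                             ("aoi.json", read_aoi_json)):
            f = d / name
            if not f.exists():
                add(f, False, "missing")
                continue
            try:
                reader(f)
                add(f, True)
            except Exception as exc:  # noqa: BLE001
                add(f, False, str(exc))
        f = d / "gaze.tsv"
        if not f.exists():
            add(f, False, "missing")
        else:
            try:
                df = pd.read_csv(f, sep="\t")
                dt = np.diff(df["timestamp_ms"].to_numpy(float))
                bad = np.flatnonzero(dt <= 0)
                if bad.size:
                    add(f, False,
                        f"non-monotone timestamp at line {int(bad[0]) + 3}")
                else:
                    read_gaze_tsv(f)
                    add(f, True)
            except Exception as exc:  # noqa: BLE001
                add(f, False, str(exc))
    return report
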