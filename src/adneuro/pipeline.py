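"""Run orchestration: generate -> extract -> compare -> predict.

A run is driven by a serializable config dict (usually loaded from
YAML).  Stages are independent; each reads its inputs from disk and
writes CSV/JSON artifacts, so any stage can be re-run or skipped.  A
manifest with the config hash and per-artifact digests is written at
the end for reproducibility checks.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as aio
from .ann import MLPConfig, cross_validate, rank_bin
from .eeg import extract_eeg_metrics
from .errors import AdneuroError
from .gaze import extract_gaze_metrics
from .hrv import hrv_all, screen_ectopics
from .stats import compare_all, correlate_all
from .synthetic import SyntheticCohortSpec, gen_cohort

log = logging.getLogger("adneuro")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "cohort_dir": "cohort",
    "out_dir": "results",
    "generate": {"n_subjects": 4, "n_ads": 4,
                 "ad_duration_s": 12.0, "baseline_duration_s": 20.0,
                 "effect_size": 2.0},
    "eeg": {"z_thresh": 5.0, "peak_c": 2.0},
    "ann": {"k": 10, "hidden_units": None, "max_epochs": 400},
    "strict": False,
}


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def _child_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed so toggling one stage does not shift others."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def stage_generate(config: dict) -> Path:
    g = config.get("generate", {})
    spec = SyntheticCohortSpec(
        n_subjects=int(g.get("n_subjects", 4)),
        n_ads=int(g.get("n_ads", 4)),
        ad_duration_s=float(g.get("ad_duration_s", 12.0)),
        baseline_duration_s=float(g.get("baseline_duration_s", 20.0)),
        seed=_child_seed(config.get("seed", 0), "generate"),
    )
    spec.labels.effect_size = float(g.get("effect_size", 2.0))
    out = Path(config["cohort_dir"])
    gen_cohort(spec, out)
    log.info("generated cohort of %d x %d at %s",
             spec.n_subjects, spec.n_ads, out)
    return out


def extract_features(cohort_dir, eeg_kwargs: dict | None = None,
                     strict: bool = False) -> pd.DataFrame:
    """Per-stream metric extraction joined with the labels table.

    A failing stream is skipped with a logged warning unless
    ``strict``; partial metric rows keep NaN for the failed block.
    """
    root = Path(cohort_dir)
    labels = aio.read_labels_csv(root / "labels.csv")
    rows = []
    for d in sorted(p for p in root.iterdir() if p.is_dir()):
        try:
            streams = aio.read_stream_dir(d)
            rec = streams["eeg"]
            a0, a1 = rec.window("ad")
            row = {"stream": d.name}
            row.update(extract_eeg_metrics(rec, **(eeg_kwargs or {})))
            rr, _flags = screen_ectopics(streams["rr"])
            row.update(hrv_all(rr))
            row.update(extract_gaze_metrics(streams["gaze"], streams["aoi"],
                                            ad_duration_s=a1 - a0))
            rows.append(row)
        except AdneuroError as exc:
            msg = f"stream {d.name} failed: {exc}"
            if strict:
                raise
            log.warning("%s (skipped)", msg)
    feats = pd.DataFrame(rows)
    ids = feats["stream"].str.extract(r"sub(?P<subject>\d+)_ad(?P<ad>\d+)")
    feats["subject"] = ids["subject"].astype(int)
    feats["ad"] = ids["ad"].astype(int)
    return feats.merge(labels, on=["subject", "ad"], how="left")


def stage_extract(config: dict) -> Path:
    feats = extract_features(config["cohort_dir"],
                             eeg_kwargs=config.get("eeg"),
                             strict=config.get("strict", False))
    out = Path(config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    path = out / "features.csv"
    feats.to_csv(path, index=False)
    return path


def stage_compare(config: dict) -> tuple[Path, Path]:
    out = Path(config["out_dir"])
    table = pd.read_csv(out / "features.csv")
    comparisons = compare_all(table)
    correlations = correlate_all(table)
    p1, p2 = out / "comparisons.csv", out / "correlations.csv"
    comparisons.to_csv(p1, index=False)
    correlations.to_csv(p2, index=False)
    return p1, p2


def _feature_matrix(table: pd.DataFrame) -> pd.DataFrame:
    drop = {"stream", "subject", "ad", "views", "rank", "ace",
            "recall", "liking", "liking_rating"}
    X = table[[c for c in table.columns if c not in drop]].copy()
    X = X.select_dtypes(include=[np.number])
    X = X.replace([np.inf, -np.inf], np.nan)
    X = X.dropna(axis=1, how="all")
    return X.fillna(X.mean())


def stage_predict(config: dict) -> Path:
    out = Path(config["out_dir"])
    table = pd.read_csv(out / "features.csv")
    X = _feature_matrix(table)
    seed = _child_seed(config.get("seed", 0), "predict")
    a = config.get("ann", {})
    cfg = MLPConfig(hidden_units=a.get("hidden_units"),
                    max_epochs=int(a.get("max_epochs", 400)), seed=seed)
    k = int(a.get("k", 10))

    ranks = rank_bin(table["views"].to_numpy())
    clf = cross_validate(X, ranks, cfg, k=k, task="classify",
                         importance=True)
    reg = cross_validate(X, table["views"].to_numpy(float), cfg, k=k,
                         task="regress")
    aio.write_json(out / "cv_classification.json", {
        "k": clf.k, "seeds": clf.seeds,
        "mean_test_accuracy_pct": clf.mean_accuracy_pct,
        "averaged_confusion": clf.summary(),
    })
    aio.write_json(out / "cv_regression.json", {
        "k": reg.k, "relative_errors": reg.per_repeat,
        "mean_relative_error": reg.mean_relative_error,
    })
    clf.importance.sort_values(ascending=False).to_csv(
        out / "importance.csv", header=["importance_pct"])
    return out / "cv_classification.json"


STAGES = {
    "generate": stage_generate,
    "extract": stage_extract,
    "compare": stage_compare,
    "predict": stage_predict,
}


def run(config: dict,
        stages: tuple[str, ...] = ("generate", "extract",
                                   "compare", "predict")) -> dict:
    """Execute the enabled stages in dependency order; write a manifest."""
    config = {**DEFAULT_CONFIG, **config}
    out = Path(config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    for name in stages:
        log.info("stage %s", name)
        STAGES[name](config)
    digests = {}
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            digests[str(p.relative_to(out))] = hashlib.sha256(
                p.read_bytes()).hexdigest()
    manifest = {"config_hash": config_hash(config),
                "seed": config.get("seed", 0),
                "stages": list(stages), "artifacts": digests}
    aio.write_json(out / "manifest.json", manifest)
    return manifest
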