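"""MLP prediction of online ad views from neurophysiological metrics.

Two analyses share one architecture — a single hidden layer with tanh
activation on typified (zero-mean, unit-SD) covariates:

* a classifier of the four view-count rank bins (<1M, 1M-5M, 5M-10M,
  >10M; softmax output), summarised by averaged confusion matrices;
* a regressor of the raw view count (identity output, target typified
  and predictions mapped back), summarised by the relative error
  RSS / TSS of the test set.

Validation is repeated stratified 70/30 hold-out (k = 10 by default);
final figures are the element-wise average across repeats.  Variable
relevance is permutation importance normalized so the top feature
reads 100%.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier, MLPRegressor

from .errors import ConfigurationError, DegenerateInputError

__all__ = [
    "RANK_LABELS", "RANK_EDGES", "MLPConfig", "Standardizer",
    "rank_bin", "standardize", "train_classifier", "train_regressor",
    "cross_validate", "confusion_summary", "relative_error",
    "variable_importance", "CVResult",
]

RANK_LABELS = ["<1M", "1M-5M", "5M-10M", ">10M"]
RANK_EDGES = np.array([1e6, 5e6, 1e7])  # lower-closed bins


def rank_bin(views) -> np.ndarray | str:
    """Map view counts to rank labels: [0,1M) [1M,5M) [5M,10M) [10M,inf)."""
    arr = np.asarray(views)
    if np.any(arr < 0):
        raise ConfigurationError("view counts cannot be negative")
    idx = np.searchsorted(RANK_EDGES, arr, side="right")
    if arr.ndim == 0:
        return RANK_LABELS[int(idx)]
    return np.asarray(RANK_LABELS, dtype=object)[idx]


@dataclass
class Standardizer:
    """Column-wise typification with stored inverse transform."""

    mean: pd.Series
    sd: pd.Series
    dropped: list[str]

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        cols = self.mean.index
        return (df[cols] - self.mean) / self.sd

    def inverse(self, df: pd.DataFrame) -> pd.DataFrame:
        return df * self.sd[df.columns] + self.mean[df.columns]


def standardize(table: pd.DataFrame) -> tuple[pd.DataFrame, Standardizer]:
    """Typify every numeric column; constant columns are dropped."""
    num = table.select_dtypes(include=[np.number])
    if num.empty:
        raise DegenerateInputError("no numeric columns to standardize")
    sd = num.std(ddof=1)
    dropped = sd.index[~(sd > 0)].tolist()
    if dropped:
        warnings.warn(f"dropping zero-variance columns {dropped}",
                      stacklevel=2)
    keep = sd.index[sd > 0]
    tf = Standardizer(num[keep].mean(), sd[keep], dropped)
    return tf.transform(num), tf


@dataclass
class MLPConfig:
    """One-hidden-layer MLP settings.

    ``hidden_units`` defaults to ceil((n_inputs + n_outputs) / 2) at fit
    time.  Hidden activation is tanh; the output layer is softmax for
    classification and identity for regression (as provided by the
    underlying estimators).
    """

    hidden_units: int | None = None
    max_epochs: int = 400
    patience: int = 50
    learning_rate: float = 0.02
    l2_alpha: float = 1.0
    early_stopping: bool = True
    validation_fraction: float = 0.2
    seed: int = 0

    def resolve_units(self, n_in: int, n_out: int) -> int:
        return self.hidden_units or math.ceil((n_in + n_out) / 2)


def _fit(estimator_cls, X, y: np.ndarray, cfg: MLPConfig, n_out: int):
    units = cfg.resolve_units(X.shape[1], n_out)
    early = cfg.early_stopping
    if early:
        # the internal validation split needs >= 2 samples (and, for the
        # stratified classifier split, enough members of every class)
        n_val = int(len(y) * cfg.validation_fraction)
        if n_val < 2:
            early = False
        elif estimator_cls is MLPClassifier:
            counts = np.unique(y, return_counts=True)[1]
            if counts.min() < 4 or n_val < counts.size:
                early = False
    est = estimator_cls(
        hidden_layer_sizes=(units,), activation="tanh", solver="adam",
        learning_rate_init=cfg.learning_rate, alpha=cfg.l2_alpha,
        max_iter=cfg.max_epochs, early_stopping=early,
        validation_fraction=cfg.validation_fraction,
        n_iter_no_change=cfg.patience, random_state=cfg.seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X, y)
    return est


def train_classifier(X: pd.DataFrame | np.ndarray, y,
                     cfg: MLPConfig | None = None) -> MLPClassifier:
    cfg = cfg or MLPConfig()
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise DegenerateInputError("classification needs >= 2 classes")
    if not isinstance(X, pd.DataFrame):
        X = np.asarray(X, dtype=float)
    return _fit(MLPClassifier, X, y, cfg, classes.size)


def train_regressor(X: pd.DataFrame | np.ndarray, y,
                    cfg: MLPConfig | None = None) -> MLPRegressor:
    cfg = cfg or MLPConfig()
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise DegenerateInputError("regression target must be finite")
    if not isinstance(X, pd.DataFrame):
        X = np.asarray(X, dtype=float)
    return _fit(MLPRegressor, X, y, cfg, 1)


def relative_error(pred, obs) -> float:
    """RSS over TSS: 0 for perfect prediction, 1 for predicting the mean."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    tss = float(np.sum((obs - obs.mean()) ** 2))
    if obs.size < 2 or tss == 0:
        return np.nan
    return float(np.sum((obs - pred) ** 2) / tss)


def confusion_summary(counts: np.ndarray,
                      labels: list[str] | None = None) -> dict:
    """Percent summary of a confusion-count matrix.

    ``per_class_pct[i]`` = 100 * diagonal / row sum (success rate of true
    class i); ``overall_pct`` = 100 * trace / total; ``marginal_pct[j]``
    = 100 * column sum / total (share of predictions in class j).
    """
    m = np.asarray(counts, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ConfigurationError("confusion matrix must be square")
    if np.any(m < 0) or m.sum() <= 0:
        raise ConfigurationError("counts must be non-negative, total > 0")
    total = m.sum()
    row = m.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class = np.where(row > 0, 100.0 * np.diag(m) / row, np.nan)
    return {
        "labels": labels or RANK_LABELS[: m.shape[0]],
        "counts": m.astype(int).tolist(),
        "per_class_pct": per_class.tolist(),
        "overall_pct": float(100.0 * np.trace(m) / total),
        "marginal_pct": (100.0 * m.sum(axis=0) / total).tolist(),
    }


def variable_importance(model, X: pd.DataFrame, y,
                        n_repeats: int = 10,
                        seed: int = 0) -> pd.Series:
    """Permutation importance, normalized so the maximum is 100%.

    Importance of a column is the mean increase in model loss (log-loss
    for classifiers, squared error for regressors) when that column is
    shuffled, averaged over ``n_repeats`` permutations.
    """
    import zlib

    X = pd.DataFrame(X).reset_index(drop=True)
    if hasattr(model, "feature_names_in_"):
        X = X[list(model.feature_names_in_)]
    y = np.asarray(y)
    is_clf = hasattr(model, "predict_proba")

    def loss(Xv) -> float:
        if is_clf:
            proba = model.predict_proba(Xv)
            cls = list(model.classes_)
            idx = np.array([cls.index(v) for v in y])
            p = np.clip(proba[np.arange(y.size), idx], 1e-12, None)
            return float(-np.mean(np.log(p)))
        pred = model.predict(Xv)
        return float(np.mean((np.asarray(y, dtype=float) - pred) ** 2))

    base = loss(X)
    raw = {}
    for col in X.columns:
        # per-column stream keyed by name, so importances do not depend
        # on column order
        rng = np.random.default_rng([seed, zlib.crc32(str(col).encode())])
        deltas = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[col] = rng.permutation(Xp[col].to_numpy())
            deltas.append(loss(Xp) - base)
        raw[col] = float(np.mean(deltas))
    s = pd.Series(raw)
    top = s.max()
    if top <= 0:
        return s * 0.0
    return 100.0 * s.clip(lower=0.0) / top


@dataclass
class CVResult:
    """Averaged repeated hold-out summary."""

    task: str                          # "classify" | "regress"
    k: int
    seeds: list[int]
    per_repeat: list = field(default_factory=list)
    mean_confusion: np.ndarray | None = None
    mean_accuracy_pct: float | None = None
    mean_relative_error: float | None = None
    importance: pd.Series | None = None

    def summary(self) -> dict:
        if self.task == "classify":
            return confusion_summary(self.mean_confusion)
        return {"relative_error": self.mean_relative_error}


def cross_validate(X: pd.DataFrame, y, cfg: MLPConfig | None = None,
                   k: int = 10, test_size: float = 0.3,
                   task: str = "classify",
                   importance: bool = False,
                   max_redraws: int = 100) -> CVResult:
    """Repeated stratified 70/30 hold-out validation.

    Each of the ``k`` repeats draws an independent stratified split,
    trains a fresh network and evaluates the held-out 30%.  Results are
    element-wise averaged.  For regression the target is typified
    internally and predictions mapped back before scoring.
    """
    cfg = cfg or MLPConfig()
    X = pd.DataFrame(X).reset_index(drop=True)
    y = np.asarray(y)
    rng = np.random.default_rng(cfg.seed)
    seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=k)]
    res = CVResult(task=task, k=k, seeds=seeds)
    classes = np.unique(y) if task == "classify" else None
    mats, errs = [], []
    for rep_seed in seeds:
        strat = y if task == "classify" else None
        for attempt in range(max_redraws):
            Xtr, Xte, ytr, yte = train_test_split(
                X, y, test_size=test_size, stratify=strat,
                random_state=(rep_seed + attempt) % (2**31 - 1))
            if task != "classify" or \
                    np.unique(ytr).size == classes.size:
                break
        rcfg = MLPConfig(**{**cfg.__dict__, "seed": rep_seed})
        if task == "classify":
            model = train_classifier(Xtr, ytr, rcfg)
            pred = model.predict(Xte)
            mat = _sk_confusion(yte, pred, labels=classes)
            mats.append(mat)
            res.per_repeat.append(mat)
        else:
            mu, sd = ytr.mean(), ytr.std(ddof=1)
            if not sd > 0:
                sd = 1.0  # degenerate training draw: leave scale alone
            model = train_regressor(Xtr, (ytr - mu) / sd, rcfg)
            pred = model.predict(Xte) * sd + mu
            err = relative_error(pred, yte)
            errs.append(err)
            res.per_repeat.append(err)
    if task == "classify":
        res.mean_confusion = np.mean(mats, axis=0)
        res.mean_accuracy_pct = float(
            np.mean([100.0 * np.trace(m) / m.sum() for m in mats]))
    else:
        res.mean_relative_error = float(np.mean(errs))
    if importance:
        full_cfg = MLPConfig(**{**cfg.__dict__})
        if task == "classify":
            model = train_classifier(X, y, full_cfg)
            res.importance = variable_importance(model, X, y, seed=cfg.seed)
        else:
            mu, sd = y.mean(), y.std(ddof=1)
            model = train_regressor(X, (y - mu) / sd, full_cfg)
            res.importance = variable_importance(model, X, (y - mu) / sd,
                                                 seed=cfg.seed)
    return res
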