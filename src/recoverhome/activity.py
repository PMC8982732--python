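"""Posture/ambulation classification from 6-s acceleration windows.

A sliding window of 6 s with a 3-s step (150 samples at 25 Hz, 50%
overlap) is summarised into an 18-dimensional feature vector: per-axis
mean and standard deviation (6), mean and standard deviation of the
gravity-free signal (2) and a normalised 10-bin histogram of the
gravity-free signal over [−4, 4] g (10).  The gravity-free signal is
the L2 norm of the three axes minus the static 1 g offset, so a
motionless wrist centres on 0 — the symmetric histogram bins only make
sense for a zero-centred signal.

A random forest (100 trees, Gini splits, sqrt-features, bootstrap)
classifies windows into {lay down, sit, stair, stand, walk}; evaluation
uses stratified 5-fold cross-validation, and the forest seed is chosen
from a pool by highest training accuracy (an optimistic selection rule,
kept as-is and documented).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .core import ACTIVITY_CLASSES, SECONDS_PER_DAY, AnnotationTrack, SensorStream

__all__ = [
    "WINDOW_S",
    "STEP_S",
    "HIST_BINS",
    "HIST_RANGE",
    "sliding_windows",
    "gravity_free",
    "featurise_windows",
    "feature_names",
    "label_windows",
    "train_activity",
    "ActivityModel",
    "predict_windows",
    "predict_daily_activity",
]

WINDOW_S = 6.0
STEP_S = 3.0
HIST_BINS = 10
HIST_RANGE = (-4.0, 4.0)


def sliding_windows(stream: SensorStream, hz: float = 25.0
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Cut the accelerometer record into 6-s windows stepping by 3 s.

    Windows never span gaps: the record is segmented into contiguous
    runs (sample spacing ≤ 1.5 / hz) and each run of T seconds yields
    ``floor((T − 6) / 3) + 1`` windows; shorter runs yield none.

    Returns ``(windows, starts)`` — an (n, 150, 3) float array and the
    window start times in seconds.
    """
    acc = stream.accel
    if len(acc) == 0:
        return np.empty((0, int(WINDOW_S * hz), 3), np.float32), np.empty(0)
    t = acc["t"].to_numpy(float)
    xyz = acc[["x", "y", "z"]].to_numpy(np.float32)
    win = int(round(WINDOW_S * hz))
    step = int(round(STEP_S * hz))
    gaps = np.flatnonzero(np.diff(t) > 1.5 / hz)
    bounds = np.concatenate([[0], gaps + 1, [len(t)]])
    out, starts = [], []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a < win:
            continue
        view = sliding_window_view(xyz[a:b], win, axis=0)[::step]
        out.append(np.swapaxes(view, 1, 2))
        starts.append(t[a:b:step][: len(view)])
    if not out:
        return np.empty((0, win, 3), np.float32), np.empty(0)
    return np.concatenate(out), np.concatenate(starts)


def gravity_free(window: np.ndarray) -> np.ndarray:
    """Gravity-free signal: L2 norm of the axes minus the 1 g static
    offset.  Motionless samples map to ≈ 0; free fall maps to −1."""
    w = np.asarray(window, np.float64)
    return np.sqrt((w * w).sum(axis=-1)) - 1.0


def feature_names() -> list[str]:
    names = [f"{ax}_{s}" for ax in "xyz" for s in ("mean", "std")]
    names += ["gf_mean", "gf_std"]
    names += [f"hist_{i}" for i in range(HIST_BINS)]
    return names


def featurise_windows(windows: np.ndarray) -> np.ndarray:
    """18-dim feature matrix for a stack of (n, 150, 3) windows.

    Histogram counts are divided by the window's sample count;
    out-of-range samples (beyond ±4 g) are clipped into the edge bins,
    so each histogram block sums to 1.
    """
    w = np.asarray(windows, np.float64)
    if w.ndim == 2:
        w = w[None]
    if w.shape[1] < int(WINDOW_S * 25):
        raise ValueError("short window: need 150 samples (6 s at 25 Hz)")
    n, ns, _ = w.shape
    means = w.mean(axis=1)                       # (n, 3)
    stds = w.std(axis=1, ddof=0)                 # (n, 3)
    gf = np.sqrt((w * w).sum(axis=-1)) - 1.0     # (n, 150)
    gf_mean = gf.mean(axis=1)
    gf_std = gf.std(axis=1, ddof=0)
    lo, hi = HIST_RANGE
    width = (hi - lo) / HIST_BINS
    idx = np.clip(((gf - lo) / width).astype(np.int64), 0, HIST_BINS - 1)
    offsets = np.arange(n)[:, None] * HIST_BINS
    hist = np.bincount((idx + offsets).ravel(),
                       minlength=n * HIST_BINS).reshape(n, HIST_BINS) / ns
    feats = np.empty((n, 18))
    # x_mean, x_std, y_mean, y_std, z_mean, z_std
    feats[:, :6] = np.column_stack(
        [means[:, 0], stds[:, 0], means[:, 1], stds[:, 1], means[:, 2], stds[:, 2]])
    feats[:, 6] = gf_mean
    feats[:, 7] = gf_std
    feats[:, 8:] = hist
    return feats


def label_windows(starts: np.ndarray, annotations: AnnotationTrack,
                  hz: float = 25.0) -> np.ndarray:
    """Label each window start with the activity interval that fully
    contains the window (object array; None where uncovered)."""
    if annotations.kind != "activity":
        raise ValueError("annotations must be activity-kind")
    starts = np.asarray(starts, float)
    lab_start = annotations.label_at(starts)
    lab_end = annotations.label_at(starts + WINDOW_S - 1.0 / hz)
    same = np.array([a is not None and a == b
                     for a, b in zip(lab_start, lab_end)])
    out = np.full(starts.shape, None, dtype=object)
    out[same] = lab_start[same]
    return out


@dataclass
class ActivityModel:
    """Posture-activity random forest with its CV provenance."""

    forest: RandomForestClassifier
    classes: list[str]
    seed: int
    seed_record: list[dict] = field(default_factory=list)
    cv_accuracy: float = float("nan")
    confusion: pd.DataFrame | None = None

    def predict(self, features: np.ndarray) -> np.ndarray:
        return self.forest.predict(features)


def _forest(seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=100, criterion="gini", max_features="sqrt",
        bootstrap=True, min_samples_split=2, min_samples_leaf=1,
        random_state=seed, n_jobs=1)


def train_activity(features: np.ndarray, labels: np.ndarray,
                   seeds: list[int] | None = None,
                   n_folds: int = 5) -> ActivityModel:
    """Train and cross-validate the posture-activity forest.

    For each candidate seed a forest is fit on all data and scored on
    the training data; the seed with the highest training accuracy
    wins.  Stratified ``n_folds``-fold cross-validation with the
    winning seed pools out-of-fold predictions into the reported
    confusion matrix, and the returned forest is refit on all data.
    """
    y = np.asarray(labels, dtype=object).astype(str)
    X = np.asarray(features, float)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 activity classes")
    if counts.min() < n_folds:
        raise ValueError(
            f"class {classes[np.argmin(counts)]!r} has fewer examples than folds")

    seeds = list(seeds) if seeds is not None else list(range(10))
    record = []
    best_seed, best_score = seeds[0], -np.inf
    for s in seeds:
        f = _forest(s).fit(X, y)
        score = float(f.score(X, y))
        record.append({"seed": s, "train_accuracy": score})
        if score > best_score:
            best_seed, best_score = s, score

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=best_seed)
    y_pred = np.empty_like(y)
    for tr, te in skf.split(X, y):
        f = _forest(best_seed).fit(X[tr], y[tr])
        y_pred[te] = f.predict(X[te])
    order = [c for c in ACTIVITY_CLASSES if c in classes] + \
            [c for c in classes if c not in ACTIVITY_CLASSES]
    cm = pd.crosstab(pd.Series(y, name="true"), pd.Series(y_pred, name="pred"))
    cm = cm.reindex(index=order, columns=order, fill_value=0)
    acc = float((y_pred == y).mean())
    final = _forest(best_seed).fit(X, y)
    return ActivityModel(forest=final, classes=order, seed=best_seed,
                         seed_record=record, cv_accuracy=acc, confusion=cm)


def predict_windows(model: ActivityModel, stream: SensorStream,
                    hz: float = 25.0) -> pd.Series:
    """Predicted activity label per 6-s window of the stream, indexed by
    window start time (s)."""
    windows, starts = sliding_windows(stream, hz=hz)
    if len(windows) == 0:
        return pd.Series(dtype=object, name="activity")
    feats = featurise_windows(windows)
    return pd.Series(model.predict(feats), index=pd.Index(starts, name="t"),
                     name="activity")


def predict_daily_activity(model: ActivityModel, stream: SensorStream,
                           hz: float = 25.0) -> pd.DataFrame:
    """Percentage of classified windows per activity class per day;
    rows sum to 100 over the windows actually classified that day."""
    preds = predict_windows(model, stream, hz=hz)
    if len(preds) == 0:
        return pd.DataFrame(columns=model.classes)
    day = (preds.index.to_numpy(float) // SECONDS_PER_DAY).astype(int)
    counts = (pd.DataFrame({"day": day, "label": preds.to_numpy(object)})
              .groupby(["day", "label"]).size().unstack(fill_value=0))
    counts = counts.reindex(columns=model.classes, fill_value=0)
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    pct.index.name = "day"
    return pct
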