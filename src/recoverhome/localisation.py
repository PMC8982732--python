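"""RSSI-fingerprint indoor localisation.

A 1-s window of per-gateway RSSI readings is summarised into five
statistics per gateway (sum, mean, min, max, variance); gateways silent
within an otherwise covered window contribute a single synthetic reading
at the out-of-range constant (−100 dB), so their block is
(−100, −100, −100, −100, 0).  A multilayer perceptron with three hidden
layers of 10 nodes maps fingerprints to room labels; one model is
trained per home on technician walk-around annotations, shuffled and
split 60/40, with momentum, learning rate and solver tuned by grid
search on training-set score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import (
    confusion_matrix,
    precision_recall_fscore_support,
)
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .core import SECONDS_PER_DAY, UNKNOWN, AnnotationTrack, SensorStream

__all__ = [
    "STATS",
    "OUT_OF_RANGE_DB",
    "feature_columns",
    "featurise_rssi",
    "label_features",
    "train_localiser",
    "LocalisationModel",
    "predict_timeline",
    "daily_distribution",
    "gateway_health",
    "GatewayHealthReport",
]

STATS = ("sum", "mean", "min", "max", "var")
OUT_OF_RANGE_DB = -100.0

DEFAULT_GRID = {
    "solver": ["adam", "sgd"],
    "learning_rate_init": [1e-2, 1e-3, 1e-4],
    "momentum": [0.5, 0.9],
}


def feature_columns(roster: list[str]) -> list[str]:
    """Fingerprint column order: gateway-major, stats in STATS order."""
    return [f"{gw}:{s}" for gw in roster for s in STATS]


def featurise_rssi(stream: SensorStream, roster: list[str],
                   out_of_range_db: float = OUT_OF_RANGE_DB) -> pd.DataFrame:
    """Build one fingerprint per 1-s window with at least one in-range
    gateway.

    Windows are half-open ``[t, t+1)`` aligned on integer seconds.
    Windows where every gateway is silent produce no row at all; a
    silent gateway inside a covered window is treated as one synthetic
    reading at ``out_of_range_db`` (so its variance is 0).

    Returns a DataFrame indexed by window start (int seconds) with
    ``5 * len(roster)`` columns, plus per-gateway reading counts in
    ``attrs["reading_counts"]`` for auditing the cadence-dependent sum
    statistic.
    """
    if not roster:
        raise ValueError("empty gateway roster")
    df = stream.rssi
    if len(df) == 0:
        return pd.DataFrame(columns=feature_columns(roster))
    sec = np.floor(df["t"].to_numpy(float)).astype(np.int64)
    rssi = df["rssi"].to_numpy(float)
    work = pd.DataFrame({"sec": sec, "gateway": df["gateway"].to_numpy(),
                         "rssi": rssi, "sq": rssi * rssi})
    g = work.groupby(["sec", "gateway"], sort=True).agg(
        sum=("rssi", "sum"), count=("rssi", "size"),
        min=("rssi", "min"), max=("rssi", "max"), sq=("sq", "sum"))
    g["mean"] = g["sum"] / g["count"]
    g["var"] = g["sq"] / g["count"] - g["mean"] ** 2
    g["var"] = g["var"].clip(lower=0.0)   # numerical floor

    wide = g[["sum", "mean", "min", "max", "var", "count"]].unstack("gateway")
    secs = wide.index
    cols = {}
    counts = {}
    for gw in roster:
        present = ("count", gw) in wide.columns
        if present:
            cnt = wide[("count", gw)].fillna(0).astype(int)
        else:
            cnt = pd.Series(0, index=secs)
        counts[gw] = cnt
        for s in STATS:
            if present:
                v = wide[(s, gw)].copy()
            else:
                v = pd.Series(np.nan, index=secs)
            fill = 0.0 if s == "var" else out_of_range_db
            cols[f"{gw}:{s}"] = v.fillna(fill)
    feats = pd.DataFrame(cols, index=secs)[feature_columns(roster)]
    feats.index.name = "t"
    feats.attrs["roster"] = list(roster)
    feats.attrs["reading_counts"] = pd.DataFrame(counts, index=secs)
    return feats


def label_features(features: pd.DataFrame,
                   annotations: AnnotationTrack) -> tuple[pd.DataFrame, pd.Series]:
    """Attach room labels to fingerprints.

    A fingerprint takes the label of the annotation interval containing
    its window start; fingerprints outside every interval are dropped.
    Vectors from all walk-around repeats are pooled.
    """
    if annotations.kind != "location":
        raise ValueError("annotations must be location-kind")
    labels = annotations.label_at(features.index.to_numpy(float))
    keep = np.array([l is not None for l in labels])
    if not keep.any():
        raise ValueError("no overlap between fingerprints and annotations")
    X = features.loc[keep]
    y = pd.Series(labels[keep].astype(str), index=X.index, name="label")
    return X, y


@dataclass
class LocalisationModel:
    """A per-home room classifier with its provenance."""

    pipeline: Pipeline
    labels: list[str]
    roster: list[str]
    seed: int
    tuning: list[dict] = field(default_factory=list)
    chosen: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)
    confusion: pd.DataFrame | None = None

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        return self.pipeline.predict(features.to_numpy(float))


def _fit_mlp(X, y, seed, solver, lr, momentum):
    clf = MLPClassifier(
        hidden_layer_sizes=(10, 10, 10),
        solver=solver,
        learning_rate_init=lr,
        momentum=momentum,
        max_iter=600,
        random_state=seed,
    )
    pipe = Pipeline([("scale", StandardScaler()), ("mlp", clf)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        pipe.fit(X, y)
    return pipe


def train_localiser(features: pd.DataFrame, labels: pd.Series, seed: int,
                    tune: bool = True, test_size: float = 0.4,
                    grid: dict | None = None) -> LocalisationModel:
    """Train and evaluate the per-home MLP room classifier.

    The labelled fingerprints are shuffled and split 60/40 (stratified
    by room so rare rooms appear in both halves).  When ``tune`` is
    true, solver × learning rate × momentum are grid-searched with the
    winner chosen on *training-set* score; the held-out 40% yields the
    reported accuracy and support-weighted precision/recall/F1.
    """
    y = np.asarray(labels, dtype=object)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 room labels to train")
    if counts.min() < 10:
        raise ValueError("need at least 10 examples per room label")
    X = features.to_numpy(float)
    Xtr, Xte, ytr, yte = train_test_split(
        X, y, test_size=test_size, random_state=seed, shuffle=True, stratify=y)

    grid = dict(grid or DEFAULT_GRID)
    tuning: list[dict] = []
    best, best_score = None, -np.inf
    if tune:
        for solver in grid["solver"]:
            for lr in grid["learning_rate_init"]:
                moms = grid["momentum"] if solver == "sgd" else [grid["momentum"][0]]
                for mom in moms:
                    pipe = _fit_mlp(Xtr, ytr, seed, solver, lr, mom)
                    score = pipe.score(Xtr, ytr)
                    rec = dict(solver=solver, learning_rate_init=lr,
                               momentum=mom, train_score=float(score))
                    tuning.append(rec)
                    if score > best_score:
                        best, best_score = (pipe, rec), score
        pipe, chosen = best
    else:
        pipe = _fit_mlp(Xtr, ytr, seed, "adam", 1e-3, 0.9)
        chosen = dict(solver="adam", learning_rate_init=1e-3, momentum=0.9,
                      train_score=float(pipe.score(Xtr, ytr)))

    ypred = pipe.predict(Xte)
    acc = float((ypred == yte).mean())
    p, r, f1, _ = precision_recall_fscore_support(
        yte, ypred, average="weighted", zero_division=0)
    cm = pd.DataFrame(
        confusion_matrix(yte, ypred, labels=list(classes)),
        index=list(classes), columns=list(classes))
    metrics = dict(accuracy=acc, precision=float(p), recall=float(r),
                   f1=float(f1), support=int(len(yte)))
    return LocalisationModel(
        pipeline=pipe, labels=list(classes),
        roster=list(features.attrs.get("roster", [])) or
               sorted({c.split(":")[0] for c in features.columns}),
        seed=seed, tuning=tuning, chosen=chosen, metrics=metrics, confusion=cm)


def predict_timeline(model: LocalisationModel, stream: SensorStream,
                     span: tuple[float, float] | None = None) -> pd.Series:
    """Per-second room predictions over the stream (or a given span).

    Seconds with no in-range RSSI window are labelled ``unknown`` —
    interpreted as time outside the home.
    """
    feats = featurise_rssi(stream, model.roster)
    if span is None:
        if len(feats) == 0:
            raise ValueError("stream has no RSSI data and no span was given")
        t0 = int(feats.index.min())
        t1 = int(feats.index.max()) + 1
    else:
        t0, t1 = int(span[0]), int(span[1])
    secs = np.arange(t0, t1, dtype=np.int64)
    labels = pd.Series(UNKNOWN, index=secs, name="location", dtype=object)
    if len(feats):
        inside = feats.loc[(feats.index >= t0) & (feats.index < t1)]
        if len(inside):
            labels.loc[inside.index] = model.predict(inside)
    labels.index.name = "t"
    return labels


def daily_distribution(timeline: pd.Series) -> pd.DataFrame:
    """Percentage of each day spent per label (rooms ∪ unknown).

    Rows sum to 100.  Seconds missing from the timeline index within a
    day count as ``unknown``.
    """
    if len(timeline) == 0:
        raise ValueError("empty timeline")
    sec = timeline.index.to_numpy(np.int64)
    day = sec // SECONDS_PER_DAY
    df = pd.DataFrame({"day": day, "label": timeline.to_numpy(object)})
    counts = df.groupby(["day", "label"], sort=True).size().unstack(fill_value=0)
    if UNKNOWN not in counts.columns:
        counts[UNKNOWN] = 0
    # seconds of each calendar day absent from the index are unknown time
    present = counts.sum(axis=1)
    counts[UNKNOWN] += SECONDS_PER_DAY - present
    pct = counts * (100.0 / SECONDS_PER_DAY)
    pct.index.name = "day"
    return pct.sort_index(axis=1)


@dataclass
class GatewayHealthReport:
    """Daily message counts per gateway, with outage flags for days a
    gateway was silent while the rest of the network reported."""

    counts: pd.DataFrame                      # day × gateway message counts
    flags: list[tuple[str, int, int]]         # (gateway, first_day, last_day)


def gateway_health(stream: SensorStream, roster: list[str],
                   span_days: tuple[int, int] | None = None) -> GatewayHealthReport:
    """Count daily BLE messages per gateway and flag outages.

    A gateway is flagged on days where it reported nothing while total
    network traffic was non-zero; consecutive flagged days merge into
    one (gateway, first_day, last_day) range.
    """
    df = stream.rssi
    day = (df["t"].to_numpy(float) // SECONDS_PER_DAY).astype(int)
    tab = (pd.DataFrame({"day": day, "gateway": df["gateway"].to_numpy()})
           .groupby(["day", "gateway"]).size().unstack(fill_value=0))
    if span_days is None:
        if len(tab) == 0:
            return GatewayHealthReport(
                counts=pd.DataFrame(columns=roster, dtype=int), flags=[])
        d0, d1 = int(tab.index.min()), int(tab.index.max()) + 1
    else:
        d0, d1 = span_days
    tab = tab.reindex(index=range(d0, d1), columns=roster, fill_value=0)
    tab.index.name = "day"

    flags: list[tuple[str, int, int]] = []
    active = tab.sum(axis=1) > 0
    for gw in roster:
        silent = (tab[gw] == 0) & active
        run_start = None
        for d in tab.index:
            if silent.loc[d] and run_start is None:
                run_start = d
            elif not silent.loc[d] and run_start is not None:
                flags.append((gw, run_start, d - 1))
                run_start = None
        if run_start is not None:
            flags.append((gw, run_start, int(tab.index.max())))
    return GatewayHealthReport(counts=tab, flags=flags)
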