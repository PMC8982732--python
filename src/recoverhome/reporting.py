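"""Clinician-facing summaries: hourly modal grids, spiral-plot series,
PROM comparison tables, figures, and the end-to-end pipeline runner.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import actigraphy, activity, localisation, synthetic_home
from . import io as rio
from .actigraphy import ActigraphyProfile
from .core import SECONDS_PER_DAY, UNKNOWN, PromFixture

__all__ = [
    "HourlyModalGrid",
    "hourly_modal",
    "spiral_filter",
    "prom_report",
    "run_pipeline",
]

ACTIVE_ACTIVITIES = {"walk", "stair"}
TIMEPOINTS = ("BL", "FU1", "FU2", "FU3")


@dataclass
class HourlyModalGrid:
    """Day × hour grid of modal location and dominant activity, with the
    study-average L5/M10 windows highlighted."""

    grid: pd.DataFrame              # index (day, hour); columns below
    l5_hours: list[int]             # clock hours inside the L5 window
    m10_hours: list[int]


def _modal_per_hour(series: pd.Series, n_days: int, fill: str | None) -> pd.Series:
    """Plurality label per absolute hour; ties go to the label more
    frequent overall, then lexicographically first."""
    idx = pd.MultiIndex.from_product(
        [range(n_days), range(24)], names=["day", "hour"])
    if len(series) == 0:
        return pd.Series(fill, index=idx, dtype=object)
    t = series.index.to_numpy(float)
    day = (t // SECONDS_PER_DAY).astype(int)
    hour = ((t % SECONDS_PER_DAY) // 3600).astype(int)
    df = pd.DataFrame({"day": day, "hour": hour,
                       "label": series.to_numpy(object)})
    overall = df["label"].value_counts()
    counts = df.groupby(["day", "hour", "label"]).size().reset_index(name="n")
    counts["overall"] = counts["label"].map(overall)
    counts = counts.sort_values(
        ["day", "hour", "n", "overall", "label"],
        ascending=[True, True, False, False, True])
    top = counts.drop_duplicates(["day", "hour"]).set_index(["day", "hour"])["label"]
    return top.reindex(idx, fill_value=fill)


def _band_hours(onset_min: int, length_min: int) -> list[int]:
    h0 = onset_min // 60
    return sorted({(h0 + k) % 24 for k in range(int(np.ceil(length_min / 60)))})


def hourly_modal(timeline: pd.Series, activities: pd.Series,
                 profile: ActigraphyProfile,
                 n_days: int | None = None) -> HourlyModalGrid:
    """Build the at-a-glance hourly grid.

    Per hour: the modal predicted location (``unknown`` for empty
    hours), the dominant (plurality) activity among the hour's
    classified windows, and whether that dominant activity is an active
    one (walk/stair) or standing.  L5/M10 bands are taken from the
    rest–activity profile's onsets.
    """
    if n_days is None:
        t = timeline.index.to_numpy(float)
        n_days = int(t.max() // SECONDS_PER_DAY) + 1 if len(t) else 1
    loc = _modal_per_hour(timeline, n_days, fill=UNKNOWN)
    act = _modal_per_hour(activities, n_days, fill=None)
    grid = pd.DataFrame({"modal_location": loc, "dominant_activity": act})
    grid["active"] = grid["dominant_activity"].isin(ACTIVE_ACTIVITIES)
    grid["standing"] = grid["dominant_activity"] == "stand"
    return HourlyModalGrid(
        grid=grid,
        l5_hours=_band_hours(profile.l5_onset, actigraphy.L5_MINUTES),
        m10_hours=_band_hours(profile.m10_onset, actigraphy.M10_MINUTES),
    )


def spiral_filter(epochs: pd.DataFrame) -> pd.Series:
    """Per-minute magnitude std filtered to the 75th percentile.

    Values below the 75th percentile (linear-interpolation quantile) of
    all per-minute standard deviations are blanked to NaN; ties at the
    threshold are retained.  The result is what the clock-face spiral
    plot renders (angle = time of day, radius = study day)."""
    if len(epochs) == 0:
        raise ValueError("empty epoch table")
    std = epochs["std_g"].astype(float)
    thr = float(np.quantile(std.to_numpy(), 0.75))
    out = std.where(std >= thr)
    out.name = "std_g_p75"
    return out


def prom_report(fixtures: list[PromFixture],
                trends: dict[str, dict] | None = None) -> pd.DataFrame:
    """PROM scores per participant × instrument across BL/FU1/FU2/FU3,
    optionally joined with sensor-derived trend summaries (movement
    slope, bedroom-share slope, IV per period...).  Missing timepoints
    stay blank; an empty fixture list yields an empty table."""
    cols = list(TIMEPOINTS)
    if not fixtures:
        return pd.DataFrame(columns=cols)
    rows = pd.DataFrame([
        (f.participant, f.instrument, f.timepoint, f.score) for f in fixtures],
        columns=["participant", "instrument", "timepoint", "score"])
    table = rows.pivot_table(index=["participant", "instrument"],
                             columns="timepoint", values="score",
                             aggfunc="first")
    table = table.reindex(columns=cols)
    table.columns.name = None
    if trends:
        tr = pd.DataFrame.from_dict(trends, orient="index")
        tr.index.name = "participant"
        table = table.join(tr, on="participant")
    return table


# ---------------------------------------------------------------------------
# Figures
# ---------------------------------------------------------------------------

def _fig(path: Path, fig) -> None:
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_daily_distribution(dist: pd.DataFrame, path: Path, title: str) -> None:
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.stackplot(dist.index, [dist[c] for c in dist.columns],
                 labels=list(dist.columns))
    ax.set_xlabel("study day"); ax.set_ylabel("% of day"); ax.set_title(title)
    ax.legend(fontsize=6, ncol=3, loc="upper right")
    _fig(path, fig)


def plot_gateway_counts(counts: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(8, 3.5))
    ax.stackplot(counts.index, [counts[c] for c in counts.columns],
                 labels=list(counts.columns))
    ax.set_xlabel("study day"); ax.set_ylabel("messages/day")
    ax.set_title("BLE gateway message counts")
    ax.legend(fontsize=7)
    _fig(path, fig)


def plot_movement_trend(trend: pd.Series, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(trend.index, trend.to_numpy(), marker="o", ms=3)
    ax.set_xlabel("study day"); ax.set_ylabel("mean per-minute std (g)")
    ax.set_title("Daily movement intensity")
    _fig(path, fig)


def plot_modal_grid(grid: HourlyModalGrid, path: Path) -> None:
    g = grid.grid["modal_location"].unstack("hour")
    labels = sorted(set(g.to_numpy().ravel()))
    lut = {l: i for i, l in enumerate(labels)}
    img = g.apply(lambda col: col.map(lut)).to_numpy(float)
    fig, ax = plt.subplots(figsize=(8, max(2.5, 0.18 * len(g))))
    ax.imshow(img, aspect="auto", cmap="tab20", interpolation="nearest")
    for h in grid.l5_hours:
        ax.axvline(h, color="grey", alpha=0.6, lw=2)
    for h in grid.m10_hours:
        ax.axvline(h, color="gold", alpha=0.35, lw=2)
    ax.set_xlabel("hour of day"); ax.set_ylabel("study day")
    ax.set_title("Hourly modal location (grey = L5, yellow = M10)")
    _fig(path, fig)


def plot_spiral(series: pd.Series, path: Path) -> None:
    minute = series.index.to_numpy(np.int64)
    theta = (minute % 1440) / 1440.0 * 2 * np.pi
    radius = minute / 1440.0
    fig = plt.figure(figsize=(5, 5))
    ax = fig.add_subplot(projection="polar")
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)      # clockwise, inner = study start
    vals = series.to_numpy(float)
    ok = ~np.isnan(vals)
    ax.scatter(theta[ok], radius[ok], c=vals[ok], s=2, cmap="viridis")
    ax.set_yticklabels([]); ax.set_title("Movement ≥ 75th percentile")
    _fig(path, fig)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)]


def run_pipeline(config: dict | str | Path | None, out_dir: str | Path) -> dict:
    """Run simulate → train → localise → actigraphy → activity → report.

    ``config`` is a scenario dict or YAML path (see
    :func:`recoverhome.io.default_config`).  All artefacts (CSV/JSON
    tables and PNG figures plus ``report.html``) land in ``out_dir``;
    nothing outside it is touched.  Fully deterministic for a fixed
    config and seed.  Returns the summary dict.
    """
    cfg = rio.load_config(config) if not isinstance(config, dict) \
        else {**rio.default_config(), **config,
              "sim": {**rio.default_config()["sim"], **config.get("sim", {})}}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(int(cfg["seed"]), 6)
    days = int(cfg["days"])

    def stage(name):
        def wrap(fn, *a, **k):
            try:
                return fn(*a, **k)
            except Exception as e:  # pragma: no cover - error plumbing
                raise RuntimeError(f"pipeline stage '{name}' failed: {e}") from e
        return wrap

    # -- simulate -----------------------------------------------------------
    sim = stage("simulate")
    layout = sim(synthetic_home.generate_home, int(cfg["rooms"]),
                 int(cfg["gateways"]), seeds[0])
    routine = sim(synthetic_home.generate_routine, cfg["profile"], days, seeds[1])
    simcfg = rio.sim_config_from({**cfg, "seed": seeds[2]})
    stream = sim(synthetic_home.simulate_stream, layout, routine, simcfg)
    stream = sim(synthetic_home.inject_failures, stream, simcfg,
                 layout.gateway_ids)
    wa_cfg = rio.sim_config_from({**cfg, "seed": seeds[3], "failures": []})
    wa_stream, wa_track = sim(synthetic_home.simulate_walkaround, layout, wa_cfg, 2)
    if cfg.get("write_streams"):
        rio.write_stream(stream, out)
    rio.write_annotations(wa_track, out / "annotations.csv")

    # -- localisation -------------------------------------------------------
    loc = stage("localise")
    feats = loc(localisation.featurise_rssi, wa_stream, layout.gateway_ids)
    X, y = loc(localisation.label_features, feats, wa_track)
    model = loc(localisation.train_localiser, X, y, seeds[4])
    timeline = loc(localisation.predict_timeline, model, stream,
                   (0, days * SECONDS_PER_DAY))
    daily_loc = loc(localisation.daily_distribution, timeline)
    health = loc(localisation.gateway_health, stream, layout.gateway_ids,
                 (0, days))
    with open(out / "metrics.json", "w") as fh:
        json.dump({"localisation": model.metrics,
                   "tuning": model.chosen}, fh, indent=2)
    pd.DataFrame([{"participant": cfg["profile"],
                   "accuracy_pct": round(model.metrics["accuracy"] * 100),
                   "precision": round(model.metrics["precision"], 2),
                   "recall": round(model.metrics["recall"], 2),
                   "f1_score": round(model.metrics["f1"], 2),
                   "support": model.metrics["support"]}]) \
        .to_csv(out / "table1.csv", index=False)
    model.confusion.to_csv(out / "confusion_location.csv")
    daily_loc.to_csv(out / "daily_location.csv")
    health.counts.to_csv(out / "gateway_counts.csv")

    # -- actigraphy ---------------------------------------------------------
    act = stage("actigraphy")
    mag = act(actigraphy.magnitude, stream)
    epochs = act(actigraphy.epochise, mag, cfg.get("impute", "zero"),
                 (0, days * SECONDS_PER_DAY))
    trend = act(actigraphy.movement_trend, epochs)
    profile = None
    if days >= 2:
        profile = act(actigraphy.rest_activity_profile, epochs)
        with open(out / "profile.json", "w") as fh:
            json.dump(profile.as_dict(), fh, indent=2)
    epochs.to_csv(out / "epochs.csv")
    trend.to_csv(out / "movement_trend.csv")

    # -- activity -----------------------------------------------------------
    ac = stage("activity")
    n_exp = int(cfg.get("scripted_experiments", 10))
    exp_seeds = _child_seeds(seeds[5], n_exp)
    Xs, ys = [], []
    for s in exp_seeds:
        ecfg = rio.sim_config_from({**cfg, "seed": s, "failures": []})
        estream, etrack = ac(synthetic_home.simulate_scripted_experiment,
                             layout, ecfg, s)
        w, starts = ac(activity.sliding_windows, estream)
        labels = ac(activity.label_windows, starts, etrack)
        keep = np.array([l is not None for l in labels])
        Xs.append(ac(activity.featurise_windows, w[keep]))
        ys.append(labels[keep])
    amodel = ac(activity.train_activity, np.concatenate(Xs),
                np.concatenate(ys), seeds=exp_seeds[:10])
    daily_act = ac(activity.predict_daily_activity, amodel, stream)
    act_windows = ac(activity.predict_windows, amodel, stream)
    amodel.confusion.to_csv(out / "confusion_activity.csv")
    daily_act.to_csv(out / "daily_activity.csv")

    # -- report -------------------------------------------------------------
    rep = stage("report")
    synthetic_home.prom_table().to_csv(out / "proms.csv", index=False)
    proms = rep(prom_report, synthetic_home.load_prom_fixture())
    proms.to_csv(out / "prom_report.csv")
    spiral = rep(spiral_filter, epochs)
    figures = {}
    rep(plot_daily_distribution, daily_loc, out / "daily_location.png",
        "Location: % time per day")
    if len(daily_act):
        rep(plot_daily_distribution, daily_act, out / "daily_activity.png",
            "Activity: % classified windows per day")
    rep(plot_gateway_counts, health.counts, out / "gateway_counts.png")
    rep(plot_movement_trend, trend, out / "movement_trend.png")
    rep(plot_spiral, spiral, out / "spiral.png")
    if profile is not None:
        grid = rep(hourly_modal, timeline, act_windows, profile, days)
        grid.grid.to_csv(out / "hourly_modal.csv")
        rep(plot_modal_grid, grid, out / "modal_grid.png")
        figures["modal_grid"] = "modal_grid.png"

    summary = {
        "config": {k: v for k, v in cfg.items() if k != "sim"},
        "sim": cfg["sim"],
        "localisation": model.metrics,
        "gateway_outages": [list(f) for f in health.flags],
        "activity_cv_accuracy": amodel.cv_accuracy,
        "rest_activity": profile.as_dict() if profile is not None else None,
        "movement_trend_first_day": float(trend.iloc[0]) if len(trend) else None,
        "movement_trend_last_day": float(trend.iloc[-1]) if len(trend) else None,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)

    pngs = sorted(p.name for p in out.glob("*.png"))
    html = ["<html><head><title>recovery report</title></head><body>",
            f"<h1>Home-monitoring report — profile: {cfg['profile']}</h1>"]
    html += [f'<h2>{p}</h2><img src="{p}" width="700">' for p in pngs]
    html.append("</body></html>")
    (out / "report.html").write_text("\n".join(html))
    return summary
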