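"""Movement and non-parametric rest–activity analysis.

The tri-axial signal is reduced to its magnitude A = sqrt(x²+y²+z²),
summarised per second (mean/min/max/std) and then per 1-min epoch.
From zero-imputed epochs the classic non-parametric circadian metrics
are computed:

* **L5 / M10** — onset and mean level of the least-active 5 h and
  most-active 10 h windows of the average 24-h profile,
* **IS** — interdaily stability, the variance of the 24-h mean profile
  relative to total variance of hourly means (1 = perfectly repeated
  days),
* **IV** — intradaily variability, the normalised mean square of hourly
  first differences (≈ 2 for white noise, higher for fragmented
  rhythms),
* **RA** — relative amplitude, (M10 − L5) / (M10 + L5),
* **ΔT** — signed circular difference (minutes) between L5 onset and
  the self-reported sleep onset.

IS and IV follow the hourly-means convention of non-parametric
actigraphy analysis (as in the R nparACT package).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SECONDS_PER_DAY, SensorStream

__all__ = [
    "magnitude",
    "per_second_stats",
    "epochise",
    "full_day_epochs",
    "l5_m10",
    "interdaily_stability",
    "intradaily_variability",
    "relative_amplitude",
    "delta_t",
    "movement_trend",
    "ActigraphyProfile",
    "ACTIVITY_COL",
    "rest_activity_profile",
]

MINUTES_PER_DAY = 1440
L5_MINUTES = 5 * 60
M10_MINUTES = 10 * 60


def magnitude(stream: SensorStream) -> pd.Series:
    """Per-sample acceleration magnitude A = sqrt(x² + y² + z²), in g."""
    acc = stream.accel
    if len(acc) == 0:
        raise ValueError("stream has no accelerometer data")
    a = np.sqrt(
        acc["x"].to_numpy(np.float64) ** 2
        + acc["y"].to_numpy(np.float64) ** 2
        + acc["z"].to_numpy(np.float64) ** 2
    )
    return pd.Series(a, index=pd.Index(acc["t"].to_numpy(float), name="t"),
                     name="A")


def per_second_stats(mag: pd.Series) -> pd.DataFrame:
    """Mean/min/max/std of magnitude per 1-s window (std with ddof=0)."""
    t = mag.index.to_numpy(float)
    sec = np.floor(t).astype(np.int64)
    a = mag.to_numpy(float)
    order = np.argsort(sec, kind="stable")
    sec, a = sec[order], a[order]
    uniq, start = np.unique(sec, return_index=True)
    cnt = np.diff(np.append(start, len(a)))
    s = np.add.reduceat(a, start)
    sq = np.add.reduceat(a * a, start)
    mean = s / cnt
    var = np.maximum(sq / cnt - mean ** 2, 0.0)
    mn = np.minimum.reduceat(a, start)
    mx = np.maximum.reduceat(a, start)
    return pd.DataFrame(
        {"mean": mean, "min": mn, "max": mx, "std": np.sqrt(var)},
        index=pd.Index(uniq, name="t"))


def epochise(mag: pd.Series, impute: str = "zero",
             span: tuple[float, float] | None = None) -> pd.DataFrame:
    """Aggregate magnitude into contiguous 1-min epochs.

    Each epoch holds the mean magnitude (``mean_g``) and the mean of the
    per-second standard deviations within the minute (``std_g``).
    Minutes with no samples inside the covered span are filled according
    to ``impute`` ("zero" — the default, or "interpolate" for linear
    interpolation of both columns) and flagged ``imputed``.

    ``span`` (seconds) extends the epoch grid beyond the observed data,
    e.g. to whole days.
    """
    if impute not in ("zero", "interpolate"):
        raise ValueError(f"unknown imputation strategy {impute!r}")
    sec = per_second_stats(mag)
    minute = sec.index.to_numpy(np.int64) // 60
    df = pd.DataFrame({"minute": minute,
                       "mean_g": sec["mean"].to_numpy(),
                       "std_g": sec["std"].to_numpy()})
    ep = df.groupby("minute").mean()
    if span is None:
        m0, m1 = int(ep.index.min()), int(ep.index.max()) + 1
    else:
        m0, m1 = int(span[0] // 60), int(np.ceil(span[1] / 60))
    full = ep.reindex(range(m0, m1))
    full.index.name = "minute"
    full["imputed"] = full["mean_g"].isna()
    if impute == "zero":
        full[["mean_g", "std_g"]] = full[["mean_g", "std_g"]].fillna(0.0)
    else:
        full[["mean_g", "std_g"]] = (
            full[["mean_g", "std_g"]].interpolate(method="linear",
                                                  limit_direction="both"))
    return full


def full_day_epochs(epochs: pd.DataFrame) -> pd.DataFrame:
    """Restrict epochs to days (midnight-to-midnight) with all 1440
    minutes present; partial first/last days are excluded from rhythm
    metrics."""
    day = epochs.index.to_numpy(np.int64) // MINUTES_PER_DAY
    counts = pd.Series(1, index=day).groupby(level=0).size()
    keep_days = set(counts[counts == MINUTES_PER_DAY].index)
    return epochs.loc[[d in keep_days for d in day]]


#: Epoch column used as the circadian activity index.  Movement (the
#: per-minute mean of per-second magnitude std) rather than raw mean
#: magnitude: the raw mean includes the constant 1 g gravity offset, so
#: rest would not read as low activity and zero-imputed out-of-home
#: minutes would dominate the least-active window.
ACTIVITY_COL = "std_g"


def _mean_24h_profile(epochs: pd.DataFrame, col: str = ACTIVITY_COL) -> np.ndarray:
    """Average activity per clock minute across full days (1440 values)."""
    ep = full_day_epochs(epochs)
    if len(ep) == 0:
        raise ValueError("need at least one full day of epochs")
    cm = ep.index.to_numpy(np.int64) % MINUTES_PER_DAY
    prof = np.zeros(MINUTES_PER_DAY)
    cnt = np.zeros(MINUTES_PER_DAY)
    np.add.at(prof, cm, ep[col].to_numpy(float))
    np.add.at(cnt, cm, 1.0)
    return prof / cnt


def _window_means(profile: np.ndarray, width: int) -> np.ndarray:
    """Mean of every ``width``-minute window wrapping midnight; entry i
    is the window starting at clock minute i."""
    tiled = np.concatenate([profile, profile[: width - 1]])
    c = np.concatenate([[0.0], np.cumsum(tiled)])
    return (c[width:] - c[:-width])[:MINUTES_PER_DAY] / width


def l5_m10(epochs: pd.DataFrame,
           col: str = ACTIVITY_COL) -> tuple[int, float, int, float]:
    """Least-active 5-h and most-active 10-h windows of the average
    24-h profile.

    Returns ``(l5_onset, l5_mean, m10_onset, m10_mean)`` with onsets in
    clock minutes after midnight.  Windows wrap midnight; ties break to
    the first window start scanning clock time from 00:00.
    """
    prof = _mean_24h_profile(epochs, col)
    w5 = _window_means(prof, L5_MINUTES)
    w10 = _window_means(prof, M10_MINUTES)
    l5_onset = int(np.argmin(w5))
    m10_onset = int(np.argmax(w10))
    return l5_onset, float(w5[l5_onset]), m10_onset, float(w10[m10_onset])


def _hourly_means(epochs: pd.DataFrame, col: str = ACTIVITY_COL) -> pd.Series:
    ep = full_day_epochs(epochs)
    if len(ep) == 0:
        raise ValueError("need at least one full day of epochs")
    hour = ep.index.to_numpy(np.int64) // 60
    return ep[col].groupby(hour).mean()


def interdaily_stability(epochs: pd.DataFrame, col: str = ACTIVITY_COL) -> float:
    """IS = (n · Σ_h (x̄_h − x̄)²) / (p · Σ_i (x_i − x̄)²) on hourly means.

    x_i are the n hourly means across the whole span, x̄_h the 24 per
    clock-hour means (p = 24).  1 for perfectly repeated days, → 0 for
    structureless data.
    """
    x = _hourly_means(epochs, col)
    n = len(x)
    if n < 48:
        raise ValueError("IS needs at least 2 full days")
    xbar = x.mean()
    denom = ((x - xbar) ** 2).sum()
    if denom == 0:
        raise ValueError("IS undefined for a zero-variance series")
    clock_hour = x.index.to_numpy(np.int64) % 24
    xh = x.groupby(clock_hour).mean()
    num = n * ((xh - xbar) ** 2).sum()
    return float(num / (24 * denom))


def intradaily_variability(epochs: pd.DataFrame, col: str = ACTIVITY_COL) -> float:
    """IV = (n · Σ (x_i − x_{i−1})²) / ((n−1) · Σ (x_i − x̄)²) on hourly
    means.  ≈ 2 for white noise; undefined (ValueError) for a constant
    series."""
    x = _hourly_means(epochs, col).to_numpy(float)
    n = len(x)
    if n < 24:
        raise ValueError("IV needs at least 1 full day")
    denom = ((x - x.mean()) ** 2).sum()
    if denom == 0:
        raise ValueError("IV undefined for a constant series")
    num = n * (np.diff(x) ** 2).sum()
    return float(num / ((n - 1) * denom))


def relative_amplitude(l5_mean: float, m10_mean: float) -> float:
    """RA = (M10 − L5) / (M10 + L5); in [0, 1] for non-negative levels."""
    if l5_mean < 0 or m10_mean < 0:
        raise ValueError("activity levels must be non-negative")
    if l5_mean == 0 and m10_mean == 0:
        raise ValueError("RA undefined when both levels are zero")
    return (m10_mean - l5_mean) / (m10_mean + l5_mean)


def delta_t(l5_onset_minutes: float, reported_onset_minutes: float) -> float:
    """Signed circular difference (minutes, in (−720, 720]) between the
    L5 onset and the self-reported sleep onset; positive when L5 starts
    later than the participant reported."""
    d = (l5_onset_minutes - reported_onset_minutes) % MINUTES_PER_DAY
    if d > 720:
        d -= MINUTES_PER_DAY
    return float(d)


def movement_trend(epochs: pd.DataFrame) -> pd.Series:
    """Per-day mean of the per-minute magnitude standard deviation —
    the daily movement-intensity summary.  Imputed epochs are excluded
    (they carry no observed movement)."""
    obs = epochs.loc[~epochs["imputed"]]
    day = obs.index.to_numpy(np.int64) // MINUTES_PER_DAY
    s = obs["std_g"].groupby(day).mean()
    s.index.name = "day"
    s.name = "mean_std_g"
    return s


@dataclass
class ActigraphyProfile:
    """Bundle of the non-parametric rest–activity metrics for a span."""

    l5_onset: int          # clock minutes after midnight
    l5_mean: float
    m10_onset: int
    m10_mean: float
    IS: float
    IV: float
    RA: float
    epochs_per_day: int
    n_epochs: int

    def as_dict(self) -> dict:
        return {
            "l5_onset_min": self.l5_onset, "l5_mean_g": self.l5_mean,
            "m10_onset_min": self.m10_onset, "m10_mean_g": self.m10_mean,
            "IS": self.IS, "IV": self.IV, "RA": self.RA,
            "epochs_per_day": self.epochs_per_day, "n_epochs": self.n_epochs,
        }


def rest_activity_profile(epochs: pd.DataFrame,
                          col: str = ACTIVITY_COL) -> ActigraphyProfile:
    """Compute all rest–activity metrics from one epoch table."""
    l5o, l5m, m10o, m10m = l5_m10(epochs, col)
    return ActigraphyProfile(
        l5_onset=l5o, l5_mean=l5m, m10_onset=m10o, m10_mean=m10m,
        IS=interdaily_stability(epochs, col),
        IV=intradaily_variability(epochs, col),
        RA=relative_amplitude(l5m, m10m),
        epochs_per_day=MINUTES_PER_DAY,
        n_epochs=len(full_day_epochs(epochs)),
    )
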