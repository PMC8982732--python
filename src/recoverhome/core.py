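"""Shared domain types for the home-monitoring pipeline.

Time convention: all timestamps are seconds since the start of the
observation, with ``t = 0`` at local midnight on day 0, and day 0 a Monday
(weekday/weekend logic uses ``day % 7``, days 5 and 6 being the weekend).
The CSV serialisers in :mod:`recoverhome.io` anchor this axis at an ISO
epoch that falls on a Monday.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

SECONDS_PER_DAY = 86_400

#: Room label emitted while the participant is away from home.  The
#: wearable is out of BLE range, so no sensor data is produced at all.
OUT = "OUT"

#: The five posture/ambulation classes recognised by the activity model.
ACTIVITY_CLASSES = ("lay down", "sit", "stair", "stand", "walk")

#: Label assigned to seconds with no in-range RSSI data; interpreted as
#: time spent outside the home.
UNKNOWN = "unknown"


@dataclass(frozen=True)
class Room:
    label: str
    x: float
    y: float
    floor: int = 0

    @property
    def z(self) -> float:
        return 3.0 * self.floor


@dataclass(frozen=True)
class Gateway:
    gateway_id: str
    x: float
    y: float
    z: float = 0.0


@dataclass
class HomeLayout:
    """A multi-room home instrumented with fixed BLE gateways.

    ``adjacency`` holds unordered room-label pairs; the graph must be
    connected so a simulated resident can reach every room.
    """

    rooms: list[Room]
    gateways: list[Gateway]
    adjacency: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        labels = [r.label for r in self.rooms]
        if len(set(labels)) != len(labels):
            raise ValueError("room labels must be unique")
        if not self.gateways:
            raise ValueError("a home needs at least one gateway")
        if len(self.rooms) > 1 and not self._connected():
            raise ValueError("adjacency graph must connect every room")

    def _connected(self) -> bool:
        labels = self.room_labels
        idx = {l: i for i, l in enumerate(labels)}
        m = np.zeros((len(labels), len(labels)))
        for a, b in self.adjacency:
            m[idx[a], idx[b]] = m[idx[b], idx[a]] = 1
        n_comp, _ = connected_components(m, directed=False)
        return n_comp == 1

    @property
    def room_labels(self) -> list[str]:
        return [r.label for r in self.rooms]

    @property
    def gateway_ids(self) -> list[str]:
        return [g.gateway_id for g in self.gateways]

    def room(self, label: str) -> Room:
        for r in self.rooms:
            if r.label == label:
                return r
        raise KeyError(label)


@dataclass(frozen=True)
class Segment:
    """One interval of the daily routine: a room (or OUT) plus the posture
    activity performed there.  OUT segments carry no activity."""

    start: float
    end: float
    room: str
    activity: str | None = None

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class RoutineSchedule:
    """A participant's routine over ``day_count`` days.

    Segments are ordered, non-overlapping and cover the full span
    ``[0, day_count * 86400)``.  ``sleep_onsets`` records, per day, the
    clock time (seconds after midnight) the participant went to bed —
    the self-report used for the ΔT sleep comparison.
    """

    segments: list[Segment]
    day_count: int
    sleep_onsets: list[float]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("empty routine")
        t = 0.0
        for seg in self.segments:
            if not np.isclose(seg.start, t):
                raise ValueError(
                    f"segments must tile the span; gap/overlap at t={seg.start}"
                )
            if seg.end <= seg.start:
                raise ValueError("segment with non-positive duration")
            if seg.room == OUT:
                if seg.activity is not None:
                    raise ValueError("OUT segments carry no activity")
            elif seg.activity not in ACTIVITY_CLASSES:
                raise ValueError(f"unknown activity {seg.activity!r}")
            t = seg.end
        if not np.isclose(t, self.day_count * SECONDS_PER_DAY):
            raise ValueError("segments must cover the full day span")

    @property
    def rooms_used(self) -> set[str]:
        return {s.room for s in self.segments if s.room != OUT}

    def room_share(self, room: str, day_from: int, day_to: int) -> float:
        """Fraction of [day_from, day_to) spent in ``room``."""
        lo, hi = day_from * SECONDS_PER_DAY, day_to * SECONDS_PER_DAY
        tot = 0.0
        for s in self.segments:
            if s.room == room:
                tot += max(0.0, min(s.end, hi) - max(s.start, lo))
        return tot / (hi - lo)


@dataclass
class SimConfig:
    """Parameters of the sensor channel models.

    RSSI follows a log-distance path-loss law with i.i.d. Gaussian
    shadowing: ``rssi = ref_power_db - 10 * path_loss_exponent *
    log10(d) + N(0, shadowing_std_db)``.  Readings below
    ``out_of_range_db`` are dropped (out of BLE range).  Acceleration is
    expressed in g with gravity included, sampled at ``accel_hz``.
    """

    seed: int = 0
    ref_power_db: float = -40.0          # received power at 1 m, dBm
    path_loss_exponent: float = 2.5
    shadowing_std_db: float = 3.0
    out_of_range_db: float = -100.0
    accel_noise_std_g: float = 0.01      # sensor noise floor
    gait_hz: float = 1.8                 # step frequency while walking
    accel_hz: float = 25.0
    rssi_rate_hz: float = 1.0            # nominal emissions per gateway
    rssi_drop_prob: float = 0.1          # packet loss
    failure_windows: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.shadowing_std_db < 0:
            raise ValueError("shadowing std must be >= 0")


RSSI_COLUMNS = ["t", "gateway", "rssi"]
ACCEL_COLUMNS = ["t", "x", "y", "z"]


@dataclass
class SensorStream:
    """Wearable data for one participant: per-gateway RSSI readings and
    tri-axial acceleration.  Gaps are expected (time out of home, gateway
    failures)."""

    rssi: pd.DataFrame
    accel: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.rssi.columns) != RSSI_COLUMNS:
            raise ValueError(f"rssi columns must be {RSSI_COLUMNS}")
        if list(self.accel.columns) != ACCEL_COLUMNS:
            raise ValueError(f"accel columns must be {ACCEL_COLUMNS}")

    @staticmethod
    def empty() -> "SensorStream":
        return SensorStream(
            rssi=pd.DataFrame(columns=RSSI_COLUMNS),
            accel=pd.DataFrame(columns=ACCEL_COLUMNS),
        )


@dataclass
class AnnotationTrack:
    """Ground-truth label intervals: either room labels from a technician
    walk-around, or activity labels from a scripted experiment."""

    intervals: pd.DataFrame  # columns: start, end, label
    kind: str                # "location" | "activity"

    def __post_init__(self) -> None:
        if self.kind not in ("location", "activity"):
            raise ValueError("kind must be 'location' or 'activity'")
        iv = self.intervals.sort_values("start")
        if (iv["end"].to_numpy()[:-1] > iv["start"].to_numpy()[1:] + 1e-9).any():
            raise ValueError("annotation intervals overlap")

    def label_at(self, t: np.ndarray) -> np.ndarray:
        """Label for each time (object array; None outside all intervals)."""
        t = np.asarray(t, dtype=float)
        iv = self.intervals.sort_values("start")
        starts = iv["start"].to_numpy(float)
        ends = iv["end"].to_numpy(float)
        labels = iv["label"].to_numpy(object)
        idx = np.searchsorted(starts, t, side="right") - 1
        out = np.full(t.shape, None, dtype=object)
        ok = (idx >= 0) & (t < ends[np.clip(idx, 0, None)])
        out[ok] = labels[idx[ok]]
        return out


@dataclass(frozen=True)
class PromFixture:
    """One patient-reported outcome record.  Oxford Hip Score lies in
    [0, 48] (higher = fewer symptoms); the HOOS quality-of-life subscale
    is a percentage in [0, 100]."""

    participant: str
    instrument: str   # "OHS" | "HOOS-QOL"
    timepoint: str    # "BL" | "FU1" | "FU2" | "FU3"
    score: float

    def __post_init__(self) -> None:
        if self.instrument == "OHS" and not 0 <= self.score <= 48:
            raise ValueError("OHS out of range [0, 48]")
        if self.instrument == "HOOS-QOL" and not 0 <= self.score <= 100:
            raise ValueError("HOOS-QOL out of range [0, 100]")
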