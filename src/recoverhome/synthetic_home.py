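"""Synthetic smart-home data generator.

Emulates the data a BLE-instrumented home produces around one wearable:
per-gateway RSSI with log-distance path loss and Gaussian shadowing,
25 Hz tri-axial acceleration conditioned on posture activity, technician
walk-around and scripted-experiment annotation protocols, gateway outage
injection, and bundled patient-reported outcome (PROM) fixtures.

Everything is deterministic given a seed.  Acceleration is in g with
gravity included, so a motionless wrist reads ``|a| ≈ 1``.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .core import (
    ACTIVITY_CLASSES,
    OUT,
    SECONDS_PER_DAY,
    AnnotationTrack,
    Gateway,
    HomeLayout,
    PromFixture,
    Room,
    RoutineSchedule,
    Segment,
    SensorStream,
    SimConfig,
)

__all__ = [
    "generate_home",
    "generate_routine",
    "simulate_stream",
    "simulate_stream_days",
    "inject_failures",
    "simulate_walkaround",
    "simulate_scripted_experiment",
    "load_prom_fixture",
    "prom_table",
]

# ---------------------------------------------------------------------------
# Home layout
# ---------------------------------------------------------------------------

# Catalogue of room names and nominal centroids (x m, y m, floor).  The
# first four are the canonical rooms every home shares.  "laundry" and
# "stairs" are deliberately placed under 1.5 m from "kitchen" and "hall"
# respectively: physically adjoining spaces whose RSSI fingerprints
# overlap, the hard case for the localiser.
_ROOM_CATALOGUE = [
    ("bedroom", 0.0, 0.0, 1),
    ("kitchen", 0.0, 0.0, 0),
    ("bathroom", 4.0, 0.0, 1),
    ("living room", 4.0, 0.0, 0),
    ("hall", 8.0, 0.0, 0),
    ("study", 8.0, 0.0, 1),
    ("dining room", 0.0, 4.0, 0),
    ("stairs", 8.6, 0.5, 0),
    ("laundry", 0.6, 0.5, 0),
    ("porch", 8.0, 4.0, 0),
    ("bedroom 2", 0.0, 4.0, 1),
]


def generate_home(room_count: int, gateway_count: int, seed: int) -> HomeLayout:
    """Generate a deterministic multi-room home with BLE gateways.

    Homes with >= 4 rooms always contain the canonical bedroom, kitchen,
    bathroom and living room.  Homes with >= 11 rooms contain the two
    adjoining room pairs (kitchen/laundry, hall/stairs) placed < 1.5 m
    apart.  Gateways sit near a spread of room centroids.
    """
    if room_count < 1 or gateway_count < 1:
        raise ValueError("room_count and gateway_count must be positive")
    rng = np.random.default_rng(seed)

    rooms: list[Room] = []
    for i in range(room_count):
        if i < len(_ROOM_CATALOGUE):
            label, x, y, floor = _ROOM_CATALOGUE[i]
        else:
            k = i - len(_ROOM_CATALOGUE)
            label, x, y, floor = f"room {i + 1}", 4.0 * (k % 3), 8.0, k // 3
        jx, jy = rng.uniform(-0.15, 0.15, size=2)
        rooms.append(Room(label, x + jx, y + jy, floor))

    # gateways near evenly spread rooms, offset off the centroid
    pick = np.unique(np.round(np.linspace(0, room_count - 1, gateway_count)))
    pick = list(pick.astype(int))
    while len(pick) < gateway_count:  # more gateways than rooms
        pick.append(int(rng.integers(room_count)))
    gateways = []
    for j, ri in enumerate(sorted(pick)):
        r = rooms[ri]
        ox, oy = rng.uniform(0.3, 0.7, size=2)
        gateways.append(Gateway(f"gw{j + 1}", r.x + ox, r.y + oy, r.z))

    adjacency = _connect_rooms(rooms)
    return HomeLayout(rooms=rooms, gateways=gateways, adjacency=adjacency)


def _connect_rooms(rooms: list[Room]) -> set[tuple[str, str]]:
    """Adjacency = Euclidean MST plus any pair closer than 2 m."""
    from scipy.sparse.csgraph import minimum_spanning_tree
    from scipy.spatial.distance import squareform, pdist

    if len(rooms) == 1:
        return set()
    pts = np.array([[r.x, r.y, r.z] for r in rooms])
    d = squareform(pdist(pts))
    mst = minimum_spanning_tree(d).toarray()
    adj: set[tuple[str, str]] = set()
    for i in range(len(rooms)):
        for j in range(i + 1, len(rooms)):
            if mst[i, j] > 0 or mst[j, i] > 0 or d[i, j] < 2.0:
                adj.add((rooms[i].label, rooms[j].label))
    return adj


# ---------------------------------------------------------------------------
# Routines
# ---------------------------------------------------------------------------

_SLEEP_END = 7 * 3600          # 07:00 wake
_SLEEP_ONSET = 23 * 3600       # 23:00 nominal bedtime

# Relative daytime shares per (room-role, activity).  Actual segment
# durations are these weights normalised onto the awake span.
def _day_shares(profile: str, day: int, days: int, rng: np.random.Generator):
    f = day / max(days - 1, 1)          # 0 → 1 across the observation
    weekend = day % 7 >= 5
    if profile == "control":
        if weekend:
            w = {
                ("living room", "sit"): 0.36,
                ("kitchen", "stand"): 0.15,
                ("hall", "walk"): 0.16,
                ("hall", "stair"): 0.03,
                ("bathroom", "stand"): 0.04,
                ("bedroom", "lay down"): 0.12,
                ("bedroom", "sit"): 0.14,
            }
        else:
            w = {
                (OUT, None): 0.50,
                ("kitchen", "stand"): 0.10,
                ("living room", "sit"): 0.20,
                ("bedroom", "sit"): 0.04,
                ("bathroom", "stand"): 0.03,
                ("hall", "walk"): 0.09,
                ("hall", "stair"): 0.02,
                ("bedroom", "lay down"): 0.02,
            }
    elif profile == "recovering":
        # mobility and time out of home grow; daytime bedroom rest shrinks
        w = {
            (OUT, None): 0.02 + 0.28 * f,
            ("bedroom", "lay down"): 0.30 - 0.25 * f,
            ("bedroom", "sit"): 0.08,
            ("living room", "sit"): 0.32 - 0.10 * f,
            ("kitchen", "stand"): 0.08 + 0.04 * f,
            ("bathroom", "stand"): 0.03,
            ("hall", "walk"): 0.04 + 0.14 * f,
            ("hall", "stair"): 0.005 + 0.02 * f,
        }
    elif profile == "withdrawing":
        # withdraws to the bedroom, sits most of the day, moves less
        w = {
            (OUT, None): 0.05 * (1 - f),
            ("bedroom", "sit"): 0.15 + 0.35 * f,
            ("bedroom", "lay down"): 0.10 + 0.10 * f,
            ("living room", "sit"): 0.30 - 0.10 * f,
            ("kitchen", "stand"): 0.10 - 0.05 * f,
            ("bathroom", "stand"): 0.03,
            ("hall", "walk"): 0.10 - 0.08 * f,
            ("hall", "stair"): 0.01 * (1 - f) + 0.002,
        }
    else:
        raise ValueError(f"unknown profile {profile!r}")
    return w


def generate_routine(profile: str, days: int, seed: int) -> RoutineSchedule:
    """Generate a ``days``-long routine for one of three participant
    profiles.

    ``control``: stable 23:00–07:00 sleep, out of the home on weekdays
    but not weekends.  ``recovering``: time out of home and movement
    intensity ramp up over the span while daytime bedroom rest shrinks.
    ``withdrawing``: bedroom share grows, sitting dominates, movement
    declines.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    if profile not in ("control", "recovering", "withdrawing"):
        raise ValueError(f"unknown profile {profile!r}")
    rng = np.random.default_rng(seed)

    segments: list[Segment] = []
    sleep_onsets: list[float] = []
    t = 0.0
    for day in range(days):
        day0 = day * SECONDS_PER_DAY
        # asleep from last night until 07:00
        wake = day0 + _SLEEP_END
        segments.append(Segment(t, wake, "bedroom", "lay down"))
        if profile == "control":
            onset = float(_SLEEP_ONSET)
        else:
            onset = float(np.clip(_SLEEP_ONSET + rng.normal(0, 15 * 60),
                                  22 * 3600, 23.75 * 3600))
        sleep_onsets.append(onset)
        bed = day0 + onset

        # daytime blocks: weights → two interleaved chunks each
        w = _day_shares(profile, day, days, rng)
        keys = list(w)
        weights = np.array([w[k] for k in keys], float)
        weights = weights / weights.sum()
        durs = weights * (bed - wake)
        # at-home activities round-robin in 4 chunks each (so every
        # daytime hour mixes postures), with one contiguous mid-day OUT
        # block between rounds 2 and 3
        blocks: list[tuple[str, str | None, float]] = []
        home_keys = [i for i, k in enumerate(keys) if k[0] != OUT]
        out_keys = [i for i, k in enumerate(keys) if k[0] == OUT]
        rounds = 4
        for rnd in range(rounds):
            if rnd == rounds // 2:
                for i in out_keys:
                    blocks.append((*keys[i], durs[i]))
            for i in home_keys:
                blocks.append((*keys[i], durs[i] / rounds))
        t = wake
        for room, act, dur in blocks:
            if dur <= 1.0:
                continue    # sliver: absorbed by the evening fill block
            segments.append(Segment(t, t + dur, room, act))
            t += dur
        if t < bed - 1e-6:
            segments.append(Segment(t, bed, "living room", "sit"))
            t = bed
        # to sleep until midnight (next loop adds the pre-wake stretch)
        end = (day + 1) * SECONDS_PER_DAY
        segments.append(Segment(t, end, "bedroom", "lay down"))
        t = end

    segments = _merge_contiguous(segments)
    return RoutineSchedule(segments=segments, day_count=days, sleep_onsets=sleep_onsets)


def _merge_contiguous(segments: list[Segment]) -> list[Segment]:
    out: list[Segment] = []
    for s in segments:
        if out and out[-1].room == s.room and out[-1].activity == s.activity \
                and math.isclose(out[-1].end, s.start):
            out[-1] = Segment(out[-1].start, s.end, s.room, s.activity)
        else:
            out.append(s)
    return out


# ---------------------------------------------------------------------------
# Sensor channel models
# ---------------------------------------------------------------------------

# Per-activity motion model: isotropic jitter expressed as a multiple of
# cfg.accel_noise_std_g (so a zero-noise config yields exactly gravity),
# periodic amplitude (g) at (a multiple of) the gait frequency, and wrist
# orientation (gravity direction in device axes).  Jitter orders the
# gravity-free variance lay down < sit < stand < walk.
_MOTION = {
    "lay down": dict(jitter=1.0, amp=0.0, freq=0.0, grav=(1.0, 0.0, 0.0)),
    "sit": dict(jitter=1.5, amp=0.0, freq=0.0, grav=(0.0, 0.5, 0.866)),
    "stand": dict(jitter=3.0, amp=0.0, freq=0.0, grav=(0.0, 0.0, 1.0)),
    "walk": dict(jitter=3.0, amp=0.30, freq=1.0, grav=(0.0, 0.0, 1.0)),
    "stair": dict(jitter=4.0, amp=0.45, freq=0.85, grav=(0.0, 0.0, 1.0)),
}

# Walking comes in bouts: brief standing pauses interrupt it, and
# standing includes occasional shuffling steps.  This is what makes
# walk/stand the genuinely confusable class pair.
_WALK_PAUSE = dict(mean_bout=12.0, mean_pause=4.0)
_STAND_SHUFFLE = dict(prob=0.10, amp=0.15)


def _alternating_envelope(n: int, hz: float, mean_on: float, mean_off: float,
                          rng: np.random.Generator) -> np.ndarray:
    """0/1 envelope of exponentially-distributed on/off runs."""
    env = np.empty(n, dtype=np.float32)
    i = 0
    on = True
    while i < n:
        dur = rng.exponential(mean_on if on else mean_off)
        k = max(int(dur * hz), 1)
        env[i:i + k] = 1.0 if on else 0.0
        i += k
        on = not on
    return env


def _synth_accel_segment(seg: Segment, cfg: SimConfig,
                         rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """25 Hz tri-axial samples for one in-home segment."""
    hz = cfg.accel_hz
    n = int(round(seg.duration * hz))
    if n == 0:
        return np.empty(0), np.empty((0, 3), np.float32)
    t = seg.start + np.arange(n) / hz
    m = _MOTION[seg.activity]
    grav = np.array(m["grav"], np.float32)

    periodic = np.zeros(n, np.float32)
    if m["amp"] > 0:
        phase = rng.uniform(0, 2 * np.pi)
        periodic = (m["amp"] *
                    np.sin(2 * np.pi * cfg.gait_hz * m["freq"] * t + phase)
                    ).astype(np.float32)
        if seg.activity == "walk":
            env = _alternating_envelope(n, hz, _WALK_PAUSE["mean_bout"],
                                        _WALK_PAUSE["mean_pause"], rng)
            periodic *= env
    elif seg.activity == "stand":
        env = _alternating_envelope(n, hz, 2.0, 18.0, rng)
        if env.mean() > 0:
            phase = rng.uniform(0, 2 * np.pi)
            periodic = (_STAND_SHUFFLE["amp"] * env *
                        np.sin(2 * np.pi * cfg.gait_hz * t + phase)
                        ).astype(np.float32)

    noise_std = m["jitter"] * cfg.accel_noise_std_g
    xyz = grav[None, :] * (1.0 + periodic)[:, None]
    if noise_std > 0:
        xyz = xyz + rng.normal(0.0, noise_std, size=(n, 3)).astype(np.float32)
    return t, xyz.astype(np.float32, copy=False)


def _gateway_distances(layout: HomeLayout, room_label: str) -> np.ndarray:
    r = layout.room(room_label)
    pos = np.array([r.x, r.y, r.z])
    gws = np.array([[g.x, g.y, g.z] for g in layout.gateways])
    d = np.linalg.norm(gws - pos, axis=1)
    return np.maximum(d, 0.3)   # clamp: wearable never at the gateway itself


def _synth_rssi_segment(seg: Segment, layout: HomeLayout, cfg: SimConfig,
                        rng: np.random.Generator):
    """~1 Hz per-gateway RSSI readings for one in-home segment."""
    first = math.ceil(seg.start)
    secs = np.arange(first, seg.end, 1.0 / cfg.rssi_rate_hz)
    n = secs.size
    if n == 0:
        return None
    d = _gateway_distances(layout, seg.room)
    mean_rssi = cfg.ref_power_db - 10.0 * cfg.path_loss_exponent * np.log10(d)
    gw_ids = layout.gateway_ids
    ts, gws, vals = [], [], []
    for gi, gid in enumerate(gw_ids):
        keep = rng.random(n) >= cfg.rssi_drop_prob
        jitter = rng.uniform(0, 0.5, size=n)  # sub-second emission offset
        rssi = mean_rssi[gi] + rng.normal(0.0, cfg.shadowing_std_db, size=n)
        ok = keep & (rssi >= cfg.out_of_range_db)
        ts.append((secs + jitter)[ok])
        gws.append(np.full(ok.sum(), gid, dtype=object))
        vals.append(rssi[ok])
    return np.concatenate(ts), np.concatenate(gws), np.concatenate(vals)


def _simulate_segments(layout: HomeLayout, segments: list[Segment],
                       cfg: SimConfig, rng: np.random.Generator,
                       channels: str = "both") -> SensorStream:
    at, axyz, rt, rg, rv = [], [], [], [], []
    for seg in segments:
        if seg.room == OUT:
            continue    # out of BLE range: total silence
        if channels in ("both", "accel"):
            t, xyz = _synth_accel_segment(seg, cfg, rng)
            at.append(t)
            axyz.append(xyz)
        if channels in ("both", "rssi"):
            out = _synth_rssi_segment(seg, layout, cfg, rng)
            if out is not None:
                rt.append(out[0]); rg.append(out[1]); rv.append(out[2])
    accel = pd.DataFrame({
        "t": np.concatenate(at) if at else np.empty(0),
        "x": np.concatenate(axyz)[:, 0] if axyz else np.empty(0, np.float32),
        "y": np.concatenate(axyz)[:, 1] if axyz else np.empty(0, np.float32),
        "z": np.concatenate(axyz)[:, 2] if axyz else np.empty(0, np.float32),
    })
    if rt:
        order_t = np.concatenate(rt)
        order = np.argsort(order_t, kind="stable")
        rssi = pd.DataFrame({
            "t": order_t[order],
            "gateway": np.concatenate(rg)[order],
            "rssi": np.concatenate(rv)[order],
        })
    else:
        rssi = pd.DataFrame({"t": np.empty(0), "gateway": np.empty(0, object),
                             "rssi": np.empty(0)})
    return SensorStream(rssi=rssi, accel=accel)


def simulate_stream(layout: HomeLayout, routine: RoutineSchedule,
                    cfg: SimConfig, channels: str = "both") -> SensorStream:
    """Simulate the wearable's sensor stream for a routine.

    OUT segments emit nothing on either channel (the wearable is out of
    range of the home).  ``channels`` may restrict synthesis to
    ``"rssi"`` or ``"accel"`` for long runs where only one modality is
    analysed.
    """
    missing = routine.rooms_used - set(layout.room_labels)
    if missing:
        raise ValueError(f"routine uses rooms absent from layout: {missing}")
    rng = np.random.default_rng(cfg.seed)
    return _simulate_segments(layout, routine.segments, cfg, rng, channels)


def simulate_stream_days(layout: HomeLayout, routine: RoutineSchedule,
                         cfg: SimConfig, channels: str = "both"):
    """Yield ``(day, SensorStream)`` one day at a time.

    Long observations (25 Hz over months) do not fit in memory as one
    stream; this generator slices the routine at midnight boundaries and
    simulates each day independently, with a per-day RNG derived from
    ``cfg.seed`` so any day can be regenerated without the others.
    """
    missing = routine.rooms_used - set(layout.room_labels)
    if missing:
        raise ValueError(f"routine uses rooms absent from layout: {missing}")
    for day in range(routine.day_count):
        lo, hi = day * SECONDS_PER_DAY, (day + 1) * SECONDS_PER_DAY
        segs = [Segment(max(s.start, lo), min(s.end, hi), s.room, s.activity)
                for s in routine.segments if s.end > lo and s.start < hi]
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, day)))
        yield day, _simulate_segments(layout, segs, cfg, rng, channels)


def inject_failures(stream: SensorStream, cfg: SimConfig,
                    roster: list[str] | None = None) -> SensorStream:
    """Drop all RSSI records of the configured gateways inside their
    whole-day failure windows [start_day, end_day] (inclusive).  The
    accelerometer channel is untouched."""
    if not cfg.failure_windows:
        return stream
    known = set(roster) if roster is not None else set(stream.rssi["gateway"].unique())
    for gid, _, _ in cfg.failure_windows:
        if known and gid not in known:
            raise ValueError(f"unknown gateway {gid!r} in failure window")
    day = (stream.rssi["t"].to_numpy(float) // SECONDS_PER_DAY).astype(int)
    drop = np.zeros(len(stream.rssi), dtype=bool)
    gw = stream.rssi["gateway"].to_numpy()
    for gid, d0, d1 in cfg.failure_windows:
        drop |= (gw == gid) & (day >= d0) & (day <= d1)
    return SensorStream(rssi=stream.rssi.loc[~drop].reset_index(drop=True),
                        accel=stream.accel)


# ---------------------------------------------------------------------------
# Annotation protocols
# ---------------------------------------------------------------------------

def simulate_walkaround(layout: HomeLayout, cfg: SimConfig,
                        repeats: int = 2) -> tuple[SensorStream, AnnotationTrack]:
    """Simulate the technician walk-around annotation protocol.

    The technician carries the wearable into every room, dwelling about
    50 s per room, once per repeat; the deployment protocol uses two
    repeats (installation and removal).  Returns the sensor stream and
    the location-kind annotation intervals that label it.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    t = 0.0
    segs: list[Segment] = []
    rows = []
    for _ in range(repeats):
        for room in layout.room_labels:
            dwell = rng.uniform(45.0, 55.0)
            segs.append(Segment(t, t + dwell, room, "stand"))
            rows.append((t, t + dwell, room))
            t += dwell
    stream = _simulate_segments(layout, segs, cfg, rng, channels="both")
    track = AnnotationTrack(
        intervals=pd.DataFrame(rows, columns=["start", "end", "label"]),
        kind="location",
    )
    return stream, track


def simulate_scripted_experiment(layout: HomeLayout, cfg: SimConfig, seed: int,
                                 duration_s: float = 420.0
                                 ) -> tuple[SensorStream, AnnotationTrack]:
    """Simulate one scripted activity experiment (5–10 min in which the
    participant acts out their daily life), yielding acceleration data
    with activity-kind annotations for training the posture classifier."""
    rng = np.random.default_rng(seed)
    rooms = layout.room_labels
    t = 0.0
    segs: list[Segment] = []
    rows = []
    i = 0
    while t < duration_s:
        act = ACTIVITY_CLASSES[i % len(ACTIVITY_CLASSES)]
        dur = rng.uniform(30.0, 60.0)
        room = rooms[int(rng.integers(len(rooms)))]
        segs.append(Segment(t, t + dur, room, act))
        rows.append((t, t + dur, act))
        t += dur
        i += 1
    stream = _simulate_segments(layout, segs, cfg, rng, channels="accel")
    track = AnnotationTrack(
        intervals=pd.DataFrame(rows, columns=["start", "end", "label"]),
        kind="activity",
    )
    return stream, track


# ---------------------------------------------------------------------------
# PROM fixtures
# ---------------------------------------------------------------------------

# Published recovery-trajectory scores for the two post-operative
# participants: Oxford Hip Score (0–48) and HOOS quality-of-life
# subscale (%) at baseline and three follow-ups.
_PROM_ROWS = [
    ("B", "OHS", "BL", 18), ("B", "OHS", "FU1", 23),
    ("B", "OHS", "FU2", 35), ("B", "OHS", "FU3", 42),
    ("C", "OHS", "BL", 32), ("C", "OHS", "FU1", 33),
    ("C", "OHS", "FU2", 47), ("C", "OHS", "FU3", 47),
    ("B", "HOOS-QOL", "BL", 37.5), ("B", "HOOS-QOL", "FU1", 37.5),
    ("B", "HOOS-QOL", "FU2", 62.5), ("B", "HOOS-QOL", "FU3", 100.0),
    ("C", "HOOS-QOL", "BL", 68.75), ("C", "HOOS-QOL", "FU1", 62.5),
    ("C", "HOOS-QOL", "FU2", 75.0), ("C", "HOOS-QOL", "FU3", 75.0),
]


def load_prom_fixture() -> list[PromFixture]:
    """Return the bundled PROM records for participants B and C."""
    return [PromFixture(*row) for row in _PROM_ROWS]


def prom_table() -> pd.DataFrame:
    """PROM fixtures as a tidy DataFrame."""
    return pd.DataFrame(_PROM_ROWS,
                        columns=["participant", "instrument", "timepoint", "score"])
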