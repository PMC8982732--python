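"""CSV/YAML serialisation for streams, annotations and configs.

Internal timestamps are seconds since the observation start (day 0 =
Monday).  On disk, timestamps are ISO-8601 UTC anchored at
``EPOCH`` = 2018-01-01T00:00:00Z, which is a Monday, preserving the
weekday/weekend semantics.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import AnnotationTrack, SensorStream, SimConfig

EPOCH = pd.Timestamp("2018-01-01T00:00:00Z")

__all__ = ["EPOCH", "write_stream", "read_stream", "write_annotations",
           "read_annotations", "write_proms", "load_config", "default_config"]


def _to_iso(t: np.ndarray) -> pd.Series:
    return (EPOCH + pd.to_timedelta(np.asarray(t, float), unit="s")).strftime(
        "%Y-%m-%dT%H:%M:%S.%fZ")


def _from_iso(s: pd.Series) -> np.ndarray:
    ts = pd.to_datetime(s, utc=True, format="ISO8601")
    return (ts - EPOCH).dt.total_seconds().to_numpy()


def write_stream(stream: SensorStream, out_dir: str | Path) -> None:
    """Write ``rssi.csv`` (timestamp, gateway_id, rssi_db) and
    ``accel.csv`` (timestamp, x_g, y_g, z_g)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rssi = pd.DataFrame({
        "timestamp": _to_iso(stream.rssi["t"].to_numpy(float)),
        "gateway_id": stream.rssi["gateway"].to_numpy(),
        "rssi_db": stream.rssi["rssi"].to_numpy(float),
    })
    rssi.to_csv(out / "rssi.csv", index=False)
    accel = pd.DataFrame({
        "timestamp": _to_iso(stream.accel["t"].to_numpy(float)),
        "x_g": stream.accel["x"].to_numpy(float),
        "y_g": stream.accel["y"].to_numpy(float),
        "z_g": stream.accel["z"].to_numpy(float),
    })
    accel.to_csv(out / "accel.csv", index=False)


def read_stream(in_dir: str | Path) -> SensorStream:
    p = Path(in_dir)
    rssi = pd.read_csv(p / "rssi.csv")
    accel = pd.read_csv(p / "accel.csv")
    return SensorStream(
        rssi=pd.DataFrame({"t": _from_iso(rssi["timestamp"]),
                           "gateway": rssi["gateway_id"].to_numpy(object),
                           "rssi": rssi["rssi_db"].to_numpy(float)}),
        accel=pd.DataFrame({"t": _from_iso(accel["timestamp"]),
                            "x": accel["x_g"].to_numpy(np.float32),
                            "y": accel["y_g"].to_numpy(np.float32),
                            "z": accel["z_g"].to_numpy(np.float32)}),
    )


def write_annotations(track: AnnotationTrack, path: str | Path) -> None:
    df = pd.DataFrame({
        "start": _to_iso(track.intervals["start"].to_numpy(float)),
        "end": _to_iso(track.intervals["end"].to_numpy(float)),
        "label": track.intervals["label"],
        "kind": track.kind,
    })
    df.to_csv(path, index=False)


def read_annotations(path: str | Path) -> AnnotationTrack:
    df = pd.read_csv(path)
    kind = df["kind"].iloc[0]
    return AnnotationTrack(
        intervals=pd.DataFrame({"start": _from_iso(df["start"]),
                                "end": _from_iso(df["end"]),
                                "label": df["label"]}),
        kind=kind)


def write_proms(proms: pd.DataFrame, path: str | Path) -> None:
    proms.to_csv(path, index=False)


def default_config() -> dict:
    """Scenario defaults: a week of a control participant in a 7-room,
    5-gateway home at the study's channel parameters."""
    return {
        "seed": 0,
        "profile": "control",
        "days": 7,
        "rooms": 7,
        "gateways": 5,
        "sim": {
            "ref_power_db": -40.0,
            "path_loss_exponent": 2.5,
            "shadowing_std_db": 3.0,
            "out_of_range_db": -100.0,
            "accel_noise_std_g": 0.01,
            "gait_hz": 1.8,
            "rssi_rate_hz": 1.0,
            "rssi_drop_prob": 0.1,
        },
        "failures": [],          # [gateway_id, start_day, end_day]
        "impute": "zero",
        "scripted_experiments": 10,
        "write_streams": False,
    }


def load_config(path: str | Path | None) -> dict:
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        sim = {**cfg["sim"], **user.get("sim", {})}
        cfg.update(user)
        cfg["sim"] = sim
    return cfg


def sim_config_from(cfg: dict) -> SimConfig:
    return SimConfig(
        seed=int(cfg["seed"]),
        failure_windows=[tuple(f) for f in cfg.get("failures", [])],
        **cfg["sim"],
    )
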