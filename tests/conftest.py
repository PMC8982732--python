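"""Shared fixtures: small simulated homes, walk-around data, and a
trained localiser reused across tests (session-scoped — everything is
deterministic, so sharing is safe)."""

import numpy as np
import pandas as pd
import pytest

from recoverhome import SimConfig
from recoverhome import localisation as loc
from recoverhome import synthetic_home as sh
from recoverhome.core import SensorStream


@pytest.fixture(scope="session")
def home7():
    """The simple-home analogue: 7 rooms, 5 gateways."""
    return sh.generate_home(7, 5, seed=1)


@pytest.fixture(scope="session")
def home11():
    """The hard-home analogue: 11 rooms with two adjoining room pairs."""
    return sh.generate_home(11, 5, seed=1)


@pytest.fixture(scope="session")
def walkaround7(home7):
    cfg = SimConfig(seed=11)
    return sh.simulate_walkaround(home7, cfg, repeats=2)


@pytest.fixture(scope="session")
def labelled7(home7, walkaround7):
    stream, track = walkaround7
    feats = loc.featurise_rssi(stream, home7.gateway_ids)
    return loc.label_features(feats, track)


@pytest.fixture(scope="session")
def localiser7(labelled7):
    """Quick (untuned) room classifier for the simple home."""
    X, y = labelled7
    return loc.train_localiser(X, y, seed=0, tune=False)


def make_stream(rssi_rows=None, accel_rows=None):
    """Hand-build a SensorStream from row tuples."""
    rssi = pd.DataFrame(rssi_rows or [], columns=["t", "gateway", "rssi"])
    accel = pd.DataFrame(accel_rows or [], columns=["t", "x", "y", "z"])
    return SensorStream(rssi=rssi, accel=accel)


def accel_stream(t, xyz):
    """SensorStream with only an accelerometer channel."""
    xyz = np.asarray(xyz, float)
    return make_stream(accel_rows=list(zip(t, xyz[:, 0], xyz[:, 1], xyz[:, 2])))
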