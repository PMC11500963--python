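from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from foraytrack import AnalysisConfig, StationArray


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture
def line_array():
    """Home A at the origin, stations strung out to 400 m."""
    return StationArray(
        stations={
            "A": (0.0, 0.0),
            "B": (300.0, 0.0),
            "C": (200.0, 0.0),
            "D": (400.0, 0.0),
        },
        home_of={"tag1": "A"},
    )


def estimates_from_pattern(pattern, tag_id="tag1", step=5.0, start=0.0):
    """Build a dense estimate series from a compact pattern.

    Pattern tokens: 'H' known home (station A), '?' unknown, any other
    letter a known non-home station of that id.
    """
    rows = []
    for i, tok in enumerate(pattern):
        t = start + i * step
        if tok == "?":
            rows.append((tag_id, t, "unknown", None, np.nan, False))
        elif tok == "H":
            rows.append((tag_id, t, "known", "A", -5.0, True))
        else:
            rows.append((tag_id, t, "known", tok, -20.0, False))
    return pd.DataFrame(
        rows,
        columns=["tag_id", "epoch_start", "status", "station_id",
                 "mean_rssi", "is_home"],
    )


def random_log_instance(rng, *, max_logs=400, span=1200.0, n_stations=4,
                        integer_rssi=True):
    """Random single-tag detection logs; integer RSSI forces exact ties."""
    n = int(rng.integers(1, max_logs + 1))
    stations = [chr(ord("A") + i) for i in range(n_stations)]
    t = np.round(rng.uniform(0, span, size=n), 1)
    st = rng.choice(stations, size=n)
    if integer_rssi:
        rssi = rng.integers(-40, 0, size=n).astype(float)
    else:
        rssi = rng.uniform(-40, 0, size=n)
    return pd.DataFrame(
        {"tag_id": "tag1", "station_id": st, "time": t, "rssi": rssi}
    ).sort_values(["tag_id", "time", "station_id"], kind="mergesort").reset_index(drop=True)


def random_estimate_instance(rng, *, max_epochs=5000, stations=("B", "C", "D"),
                             p_home=0.45, p_unknown=0.25):
    """Random dense estimate series over the line_array stations."""
    n = int(rng.integers(2, max_epochs + 1))
    u = rng.random(n)
    pattern = []
    for x in u:
        if x < p_unknown:
            pattern.append("?")
        elif x < p_unknown + p_home:
            pattern.append("H")
        else:
            pattern.append(stations[int(rng.integers(len(stations)))])
    return estimates_from_pattern(pattern)
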