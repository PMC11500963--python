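"""Window-based RSSI localization over a receiver array.

A tag's detection-log stream is processed in moving windows (default 15 s
wide, stepped every 5 s). Each window yields a per-station mean RSSI, and a
decision tree turns that into a station-resolution "best estimate" location
for the 5-s epoch beginning at the window start:

1. no logs in the window → location *unknown*;
2. logs from exactly one station → that station;
3. logs from several stations, none of them the bird's home station → the
   station with the highest mean RSSI;
4. logs from several stations including home → home if the home station's
   window-mean RSSI is strictly above the home-override threshold
   (default −11.484, the calibrated mean signal strength at 50 m),
   otherwise the station with the highest mean RSSI (which may still be
   home).

Epochs partition time: each estimate stands for the ``step``-long interval
starting at its ``epoch_start``, and the epoch grid is anchored per tag at
the first log time rounded down to a multiple of ``step``.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .config import AnalysisConfig
from .io import StationArray

ESTIMATE_COLUMNS = (
    "tag_id",
    "epoch_start",
    "status",
    "station_id",
    "mean_rssi",
    "is_home",
)


def window_logs(
    logs: pd.DataFrame, config: AnalysisConfig | None = None
) -> list[tuple[float, dict[str, float]]]:
    """Per-window per-station mean RSSI for a single tag's sorted logs.

    Windows cover the half-open interval ``[epoch_start, epoch_start +
    window_width)`` and are stepped by ``config.step`` from the first log
    time rounded down to a multiple of the step, up to the last log time.

    Returns a list of ``(epoch_start, {station_id: mean_rssi})`` pairs, one
    per grid epoch (maps may be empty for log-free windows).
    """
    config = config or AnalysisConfig()
    if len(logs) == 0:
        return []
    if logs["tag_id"].nunique() > 1:
        raise ValueError("window_logs expects logs from a single tag")
    t = logs["time"].to_numpy(dtype=float)
    step, width = config.step, config.window_width
    anchor = np.floor(t.min() / step) * step
    last = np.floor(t.max() / step) * step
    epochs = np.arange(anchor, last + step / 2, step)
    out: list[tuple[float, dict[str, float]]] = []
    for e in epochs:
        in_win = (t >= e) & (t < e + width)
        means = logs.loc[in_win].groupby("station_id")["rssi"].mean().to_dict()
        out.append((float(e), {str(k): float(v) for k, v in means.items()}))
    return out


def assign_location(
    window: Mapping[str, float],
    home_station: str,
    config: AnalysisConfig | None = None,
    previous: Mapping | None = None,
) -> dict:
    """Apply the decision tree to one window's mean-RSSI map.

    ``previous`` (an earlier estimate dict) only matters for breaking exact
    ties in mean RSSI: the previously assigned station is preferred, then
    the lexicographically smallest id.
    """
    config = config or AnalysisConfig()
    if not window:
        return {"status": "unknown", "station_id": None, "mean_rssi": None,
                "is_home": False}
    if len(window) == 1:
        (station, rssi), = window.items()
    elif (
        home_station in window
        and window[home_station] > config.home_rssi_threshold
    ):
        station, rssi = home_station, window[home_station]
    else:
        best = max(window.values())
        tied = sorted(s for s, v in window.items() if v == best)
        if previous and previous.get("station_id") in tied:
            station = previous["station_id"]
        else:
            station = tied[0]
        rssi = window[station]
    return {
        "status": "known",
        "station_id": station,
        "mean_rssi": float(rssi),
        "is_home": station == home_station,
    }


class RssiLocalizer(BaseEstimator, TransformerMixin):
    """Transform detection logs into per-epoch best-estimate locations.

    A stateless transformer in the scikit-learn idiom: ``fit`` validates and
    stores the station array, ``transform`` maps a detection-log DataFrame
    (columns tag_id, station_id, time, rssi; one or many tags) to a dense
    estimate DataFrame with columns tag_id, epoch_start, status, station_id,
    mean_rssi, is_home.

    Parameters
    ----------
    array : StationArray
        Receiver coordinates and the tag → home-station map.
    config : AnalysisConfig, optional
        Window, step and home-override settings.
    """

    def __init__(self, array: StationArray | None = None,
                 config: AnalysisConfig | None = None):
        self.array = array
        self.config = config

    def fit(self, X=None, y=None) -> "RssiLocalizer":
        if self.array is None:
            raise ValueError("RssiLocalizer requires a station array")
        self.array_ = self.array
        self.config_ = self.config or AnalysisConfig()
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "array_"):
            self.fit()
        parts = []
        for tag_id, tag_logs in X.groupby("tag_id", sort=True):
            home = self.array_.home_station(str(tag_id))
            parts.append(
                _localize_single(tag_logs, str(tag_id), home, self.config_)
            )
        if not parts:
            return pd.DataFrame(columns=list(ESTIMATE_COLUMNS))
        return pd.concat(parts, ignore_index=True)


def _localize_single(
    logs: pd.DataFrame, tag_id: str, home: str, config: AnalysisConfig
) -> pd.DataFrame:
    """Vectorised localization of one tag's logs.

    Builds per-epoch per-station RSSI sums/counts with ``np.add.at`` (each
    log lands in every window covering it), then applies the decision tree
    on the resulting means matrix. Exact RSSI ties — a measure-zero event
    with noisy signals but common in constructed inputs — are resolved in a
    second, ordered pass that prefers the previously assigned station.
    """
    if len(logs) == 0:
        return pd.DataFrame(columns=list(ESTIMATE_COLUMNS))
    step, width = config.step, config.window_width
    t = logs["time"].to_numpy(dtype=float)
    rssi = logs["rssi"].to_numpy(dtype=float)
    stations = pd.Index(sorted(logs["station_id"].unique().astype(str)))
    st_idx = stations.get_indexer(logs["station_id"].astype(str))

    anchor = np.floor(t.min() / step) * step
    n_epochs = int(np.floor((t.max() - anchor) / step)) + 1
    n_st = len(stations)

    sums = np.zeros((n_epochs, n_st))
    counts = np.zeros((n_epochs, n_st), dtype=np.int64)
    # a log at time tt is inside window e iff e <= tt < e + width, e on grid
    n_back = int(np.ceil(width / step))
    base = np.floor((t - anchor) / step).astype(np.int64)
    for k in range(n_back):
        e = base - k
        ok = (e >= 0) & (t < anchor + e * step + width)
        flat = e[ok] * n_st + st_idx[ok]
        np.add.at(sums.ravel(), flat, rssi[ok])
        np.add.at(counts.ravel(), flat, 1)

    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    n_active = (counts > 0).sum(axis=1)

    home_col = stations.get_loc(home) if home in stations else -1
    home_mean = means[:, home_col] if home_col >= 0 else np.full(n_epochs, np.nan)

    masked = np.where(counts > 0, means, -np.inf)
    best_col = np.argmax(masked, axis=1)
    best_val = masked[np.arange(n_epochs), best_col]

    assigned = best_col.copy()
    # home override: several stations incl. home, home mean strictly above threshold
    override = (
        (n_active >= 2)
        & (home_col >= 0)
        & (counts[:, home_col] > 0 if home_col >= 0 else False)
        & (home_mean > config.home_rssi_threshold)
    )
    assigned[override] = home_col

    # tie resolution: epochs where >1 station attains the max and no override
    tie_rows = np.flatnonzero(
        (~override)
        & (n_active >= 2)
        & ((masked == best_val[:, None]).sum(axis=1) > 1)
    )
    if len(tie_rows):
        prev_station: int | None = None
        row_iter = iter(tie_rows)
        nxt = next(row_iter, None)
        for i in range(n_epochs):
            if i == nxt:
                tied = np.flatnonzero(masked[i] == best_val[i])
                if prev_station is not None and prev_station in tied:
                    assigned[i] = prev_station
                else:
                    assigned[i] = tied[0]  # stations sorted → lexicographic min
                nxt = next(row_iter, None)
            if n_active[i] > 0:
                prev_station = int(assigned[i])

    known = n_active > 0
    epoch_start = anchor + step * np.arange(n_epochs)
    station_ids = np.where(known, stations.values[assigned], None)
    mean_assigned = np.where(known, means[np.arange(n_epochs), assigned], np.nan)
    return pd.DataFrame(
        {
            "tag_id": tag_id,
            "epoch_start": epoch_start,
            "status": np.where(known, "known", "unknown"),
            "station_id": station_ids,
            "mean_rssi": mean_assigned,
            "is_home": known & (assigned == home_col) & (home_col >= 0),
        }
    )


def localize_tag(
    logs: pd.DataFrame,
    array: StationArray,
    tag_id: str,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Localize one tag: dense epoch series from first to last log time."""
    tag_logs = logs.loc[logs["tag_id"].astype(str) == str(tag_id)]
    loc = RssiLocalizer(array=array, config=config).fit()
    return loc.transform(tag_logs)


def localize_all(
    logs: pd.DataFrame, array: StationArray, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Localize every tag present in ``logs``."""
    return RssiLocalizer(array=array, config=config).fit().transform(logs)
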