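"""Tabular input/output: detection logs, station arrays, foray tables.

Detection logs are the raw product of a receiver ("base station") array:
one row per received tag pulse carrying the tag id, the receiving station,
the timestamp and the received signal strength indicator (RSSI). All tables
are plain delimited text with named header columns; column names are
remappable because field logger exports vary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LOG_COLUMNS = ("tag_id", "station_id", "time", "rssi")
FORAY_COLUMNS = (
    "tag_id",
    "start_time",
    "end_time",
    "duration_min",
    "max_distance_m",
    "round_trip_m",
    "n_known_epochs",
    "censored",
)


class SchemaError(ValueError):
    """A required column is missing or an identifier is duplicated."""


class ReferenceError_(KeyError):
    """A foreign reference (e.g. a home station) points nowhere."""


@dataclass
class StationArray:
    """Receiver coordinates plus the tag → home-station mapping.

    Coordinates are planar projected metres; distances are Euclidean.
    """

    stations: dict[str, tuple[float, float]]
    home_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tag, st in self.home_of.items():
            if st not in self.stations:
                raise ReferenceError_(
                    f"home station {st!r} of tag {tag!r} is not in the array"
                )
        for sid, (x, y) in self.stations.items():
            if not (np.isfinite(x) and np.isfinite(y)):
                raise ValueError(f"non-finite coordinates for station {sid!r}")

    @property
    def station_ids(self) -> list[str]:
        return list(self.stations)

    def coords(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s, x, y) for s, (x, y) in self.stations.items()],
            columns=["station_id", "x", "y"],
        )

    def distance(self, a: str, b: str) -> float:
        """Euclidean distance in metres between two stations."""
        xa, ya = self.stations[a]
        xb, yb = self.stations[b]
        return float(np.hypot(xa - xb, ya - yb))

    def distances_from(self, station_id: str) -> pd.Series:
        """Distances from one station to every station, indexed by id."""
        x0, y0 = self.stations[station_id]
        ids = self.station_ids
        xy = np.array([self.stations[s] for s in ids], dtype=float)
        d = np.hypot(xy[:, 0] - x0, xy[:, 1] - y0)
        return pd.Series(d, index=ids, name="distance_m")

    def mean_nearest_neighbour_distance(self) -> float:
        xy = np.array(list(self.stations.values()), dtype=float)
        if len(xy) < 2:
            raise ValueError("need at least 2 stations")
        d = np.hypot(
            xy[:, None, 0] - xy[None, :, 0], xy[:, None, 1] - xy[None, :, 1]
        )
        np.fill_diagonal(d, np.inf)
        return float(d.min(axis=1).mean())

    def home_station(self, tag_id: str) -> str:
        try:
            return self.home_of[tag_id]
        except KeyError:
            raise ReferenceError_(f"tag {tag_id!r} has no home station") from None


def _normalise_times(raw: pd.Series, epoch: str | None) -> pd.Series:
    """Accept numeric seconds or ISO-8601 strings; return float seconds."""
    numeric = pd.to_numeric(raw, errors="coerce")
    if numeric.notna().all():
        return numeric.astype(float)
    stamps = pd.to_datetime(raw, errors="coerce", utc=True, format="ISO8601")
    origin = pd.Timestamp(epoch or "1970-01-01", tz="UTC")
    seconds = (stamps - origin).dt.total_seconds()
    # mixed rows: numeric where parseable, ISO elsewhere
    return numeric.astype(float).fillna(seconds)


def read_logs(
    path: str | Path,
    schema: dict[str, str] | None = None,
    *,
    sep: str = ",",
    strict: bool = False,
    epoch: str | None = None,
) -> pd.DataFrame:
    """Read a detection-log table.

    Parameters
    ----------
    path : path
        Delimited-text file with a header row.
    schema : dict, optional
        Maps canonical names (``tag_id``, ``station_id``, ``time``,
        ``rssi``) to the column names actually present in the file.
    strict : bool
        If True, malformed rows raise; otherwise they are dropped and the
        drop count is logged and attached as ``df.attrs['n_bad_rows']``.
    epoch : str, optional
        Origin for ISO-8601 timestamps (ignored for numeric times).

    Returns
    -------
    DataFrame with columns tag_id, station_id, time (s), rssi, sorted
    deterministically by (tag_id, time, station_id).
    """
    schema = schema or {}
    colmap = {canon: schema.get(canon, canon) for canon in LOG_COLUMNS}
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [src for src in colmap.values() if src not in df.columns]
    if missing:
        raise SchemaError(f"missing columns in {path}: {missing}")
    df = df[[colmap[c] for c in LOG_COLUMNS]]
    df.columns = list(LOG_COLUMNS)

    time = _normalise_times(df["time"], epoch)
    rssi = pd.to_numeric(df["rssi"], errors="coerce")
    bad = time.isna() | rssi.isna() | (time < 0) | ~np.isfinite(rssi.fillna(np.nan))
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # header + 1-based
        if strict:
            raise ValueError(f"unparseable rows at lines {lines[:20]} in {path}")
        logger.warning("dropped %d malformed log rows (lines %s...)", bad.sum(), lines[:5])
    out = df.loc[~bad].assign(time=time[~bad], rssi=rssi[~bad])
    out = out.sort_values(["tag_id", "time", "station_id"], kind="mergesort")
    out = out.reset_index(drop=True)
    out.attrs["n_bad_rows"] = int(bad.sum())
    return out


def read_station_array(
    stations_path: str | Path,
    home_map_path: str | Path | None = None,
    *,
    sep: str = ",",
) -> StationArray:
    """Read station coordinates and (optionally) the tag → home map.

    The stations file needs columns station_id, x, y (metres); the home-map
    file needs tag_id, station_id.
    """
    st = pd.read_csv(stations_path, sep=sep)
    for col in ("station_id", "x", "y"):
        if col not in st.columns:
            raise SchemaError(f"stations file missing column {col!r}")
    if st["station_id"].duplicated().any():
        dupes = st.loc[st["station_id"].duplicated(), "station_id"].tolist()
        raise SchemaError(f"duplicate station ids: {dupes}")
    stations = {
        str(r.station_id): (float(r.x), float(r.y)) for r in st.itertuples()
    }
    home_of: dict[str, str] = {}
    if home_map_path is not None:
        hm = pd.read_csv(home_map_path, sep=sep)
        for col in ("tag_id", "station_id"):
            if col not in hm.columns:
                raise SchemaError(f"home-map file missing column {col!r}")
        home_of = {str(r.tag_id): str(r.station_id) for r in hm.itertuples()}
    return StationArray(stations=stations, home_of=home_of)


def write_station_array(array: StationArray, stations_path, home_map_path=None) -> None:
    array.coords().to_csv(stations_path, index=False)
    if home_map_path is not None:
        pd.DataFrame(
            [(t, s) for t, s in array.home_of.items()],
            columns=["tag_id", "station_id"],
        ).to_csv(home_map_path, index=False)


def write_forays(forays: pd.DataFrame, path: str | Path) -> None:
    """Write a foray table; round-trips bit-identically through read_forays."""
    out = forays.reindex(columns=list(FORAY_COLUMNS))
    out.to_csv(path, index=False, float_format="%.17g")


def read_forays(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FORAY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"foray table missing columns: {missing}")
    df["censored"] = df["censored"].astype(bool)
    return df


def write_estimates(estimates: pd.DataFrame, path: str | Path) -> None:
    estimates.to_csv(path, index=False, float_format="%.17g")


def read_estimates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["is_home"] = df["is_home"].astype(bool)
    df["station_id"] = df["station_id"].where(df["station_id"].notna(), None)
    return df
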