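"""Extra-territorial foray detection and rate aggregation.

A foray is a conservative, rule-based event on the best-estimate location
series: a run of known non-home locations, opened at the first known
non-home epoch after a known home epoch and closed at the next known home
epoch. Unknown epochs never break a run — a bird far outside the array can
be silent for long stretches mid-foray. The run qualifies as a foray iff

(a) its total known non-home time (epoch length × number of known non-home
    epochs) strictly exceeds ``min_nonhome_time`` (default 15 s), and
(b) the furthest assigned station lies strictly more than
    ``distance_threshold`` (default 250 m) from the home station.

Foray duration is the elapsed time between the first non-home estimate and
the first subsequent home estimate; foray distance is the straight-line
home-to-furthest-station distance, and the round trip is twice that. Runs
that are still open at the end of tracking, or that begin before the bird
was ever seen home, are emitted flagged ``censored`` and excluded from rate
summaries by default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .config import AnalysisConfig
from .io import FORAY_COLUMNS, StationArray


class ForayDetector(BaseEstimator, TransformerMixin):
    """Transform a best-estimate location series into a foray table.

    Parameters
    ----------
    array : StationArray
        Needed for home-to-station distances.
    config : AnalysisConfig, optional
        Distance / duration criteria and the epoch length.
    """

    def __init__(self, array: StationArray | None = None,
                 config: AnalysisConfig | None = None):
        self.array = array
        self.config = config

    def fit(self, X=None, y=None) -> "ForayDetector":
        if self.array is None:
            raise ValueError("ForayDetector requires a station array")
        self.array_ = self.array
        self.config_ = self.config or AnalysisConfig()
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "array_"):
            self.fit()
        parts = []
        for tag_id, est in X.groupby("tag_id", sort=True):
            home = self.array_.home_station(str(tag_id))
            parts.append(
                _detect_single(est, str(tag_id), home, self.array_, self.config_)
            )
        if not parts:
            return _empty_forays()
        return pd.concat(parts, ignore_index=True)


def _empty_forays() -> pd.DataFrame:
    return pd.DataFrame(columns=list(FORAY_COLUMNS)).astype(
        {"censored": bool, "n_known_epochs": np.int64}
    )


def _detect_single(
    est: pd.DataFrame,
    tag_id: str,
    home: str,
    array: StationArray,
    config: AnalysisConfig,
) -> pd.DataFrame:
    est = est.sort_values("epoch_start", kind="mergesort")
    t = est["epoch_start"].to_numpy(dtype=float)
    known = (est["status"] == "known").to_numpy()
    is_home = est["is_home"].to_numpy(dtype=bool) & known
    nonhome = known & ~is_home
    if not nonhome.any():
        return _empty_forays()

    dist_lookup = array.distances_from(home)
    station = est["station_id"].to_numpy(dtype=object)

    home_idx = np.flatnonzero(is_home)
    nh_idx = np.flatnonzero(nonhome)
    # index (into home_idx) of the closing home epoch for each non-home epoch
    closer = np.searchsorted(home_idx, nh_idx)

    rows = []
    for grp in np.split(nh_idx, np.flatnonzero(np.diff(closer)) + 1):
        c = int(np.searchsorted(home_idx, grp[0]))
        closed = c < len(home_idx)
        leading = c == 0  # never seen home before the run opened
        censored = (not closed) or leading
        start_time = t[grp[0]]
        end_time = t[home_idx[c]] if closed else np.nan
        dists = np.array([dist_lookup[s] for s in np.unique(station[grp])])
        max_distance = float(dists.max())
        n_epochs = len(grp)
        if not (config.step * n_epochs > config.min_nonhome_time):
            continue
        if not (max_distance > config.distance_threshold):
            continue
        rows.append(
            {
                "tag_id": tag_id,
                "start_time": start_time,
                "end_time": end_time,
                "duration_min": (end_time - start_time) / 60.0,
                "max_distance_m": max_distance,
                "round_trip_m": 2.0 * max_distance,
                "n_known_epochs": n_epochs,
                "censored": censored,
            }
        )
    if not rows:
        return _empty_forays()
    return pd.DataFrame(rows, columns=list(FORAY_COLUMNS))


def detect_forays(
    estimates: pd.DataFrame,
    array: StationArray,
    home_station: str | None = None,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Detect forays in a single tag's dense, time-ordered estimate series.

    ``home_station`` overrides the array's tag → home map when given (the
    estimates must still come from one tag only).
    """
    if estimates["tag_id"].nunique() > 1:
        raise ValueError("detect_forays expects estimates from a single tag")
    config = config or AnalysisConfig()
    if home_station is not None and len(estimates):
        tag = str(estimates["tag_id"].iloc[0])
        array = StationArray(
            stations=array.stations, home_of={**array.home_of, tag: home_station}
        )
    return ForayDetector(array=array, config=config).fit().transform(estimates)


def detect_all_forays(
    estimates: pd.DataFrame,
    array: StationArray,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    return ForayDetector(array=array, config=config).fit().transform(estimates)


def _local_day(time_s: np.ndarray, config: AnalysisConfig) -> np.ndarray:
    return np.floor(
        (np.asarray(time_s, dtype=float) + config.utc_offset_hours * 3600.0)
        / 86400.0
    ).astype(np.int64)


def _day_label(day_index: np.ndarray, config: AnalysisConfig) -> pd.Series:
    origin = pd.Timestamp(config.epoch)
    return pd.Series(origin + pd.to_timedelta(day_index, unit="D")).dt.date


def daily_rates(
    forays: pd.DataFrame,
    deployment: dict[str, tuple[float, float]],
    config: AnalysisConfig | None = None,
    *,
    include_censored: bool = False,
) -> pd.DataFrame:
    """Per-tag per-calendar-day foray counts over the deployment interval.

    A foray is counted on the local calendar day containing its start time.
    Censored runs are excluded unless ``include_censored``. Every day whose
    interval intersects the tag's deployment contributes one record, so
    foray-free days are explicit zeros.
    """
    config = config or AnalysisConfig()
    use = forays if include_censored else forays.loc[~forays["censored"].astype(bool)]
    records = []
    for tag, (dep_start, dep_end) in sorted(deployment.items()):
        if dep_end < dep_start:
            raise ValueError(f"deployment end before start for tag {tag!r}")
        # deployment is half-open: an end falling exactly on a local
        # midnight does not open a new tracked day
        d0 = _local_day(np.array([dep_start]), config)[0]
        d1 = int(np.floor(
            (dep_end + config.utc_offset_hours * 3600.0) / 86400.0 - 1e-12
        ))
        days = np.arange(d0, max(d0, d1) + 1)
        tf = use.loc[use["tag_id"].astype(str) == str(tag)]
        if len(tf):
            starts = tf["start_time"].to_numpy(dtype=float)
            if ((starts < dep_start) | (starts > dep_end)).any():
                raise ValueError(
                    f"foray outside deployment interval for tag {tag!r}"
                )
            fdays = _local_day(starts, config)
            counts = pd.Series(fdays).value_counts()
        else:
            counts = pd.Series(dtype=int)
        for d in days:
            records.append(
                {
                    "tag_id": str(tag),
                    "day_index": int(d),
                    "n_forays": int(counts.get(d, 0)),
                    "tracked": True,
                }
            )
    out = pd.DataFrame(
        records, columns=["tag_id", "day_index", "n_forays", "tracked"]
    )
    if len(out):
        out["date"] = _day_label(out["day_index"].to_numpy(), config)
    else:
        out["date"] = pd.Series(dtype=object)
    return out[["tag_id", "date", "day_index", "n_forays", "tracked"]]


def circadian_profile(
    forays: pd.DataFrame,
    deployment: dict[str, tuple[float, float]],
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Mean hourly foray rate per bird per tracked day, by hour of day.

    For each bird, forays starting within each local hour-of-day are divided
    by the bird's number of tracked days; the profile is the mean of those
    per-bird rates, hour by hour (24 values). Summing the profile over hours
    and multiplying by total tracked bird-days recovers the total foray
    count only when all birds are tracked equally long; the per-bird
    normalisation matches how hourly prospecting rates are usually plotted.
    """
    config = config or AnalysisConfig()
    rates = daily_rates(forays, deployment, config)
    tracked_days = rates.groupby("tag_id")["day_index"].size()
    use = forays.loc[~forays["censored"].astype(bool)]
    hours = np.floor(
        ((use["start_time"].to_numpy(dtype=float)
          + config.utc_offset_hours * 3600.0) % 86400.0) / 3600.0
    ).astype(int) if len(use) else np.array([], dtype=int)
    per_bird = np.zeros((len(tracked_days), 24))
    tags = list(tracked_days.index)
    tag_pos = {t: i for i, t in enumerate(tags)}
    for tag, h in zip(use["tag_id"].astype(str), hours):
        if tag in tag_pos:
            per_bird[tag_pos[tag], h] += 1
    per_bird /= tracked_days.to_numpy(dtype=float)[:, None]
    profile = per_bird.mean(axis=0) if len(tags) else np.zeros(24)
    return pd.DataFrame(
        {"hour": np.arange(24), "mean_rate_per_bird_per_day": profile}
    )


def threshold_sensitivity(
    estimates: pd.DataFrame,
    array: StationArray,
    config: AnalysisConfig,
    thresholds: list[float],
    deployment: dict[str, tuple[float, float]],
    sex_of: dict[str, str],
) -> pd.DataFrame:
    """Re-detect forays at each distance threshold and refit the sex effect.

    Returns one row per threshold with the total (non-censored) foray count
    and the male-vs-female log rate ratio (with SE) from a log-link count
    model on per-bird-day counts with bird-level clustering. The effect is
    reported absent (NaN) when either sex has fewer than two birds.
    """
    from .stats import _sex_effect_from_daily  # local import: avoids cycle

    rows = []
    for thr in thresholds:
        cfg = AnalysisConfig(**{**config.to_dict(), "distance_threshold": float(thr)})
        forays = detect_all_forays(estimates, array, cfg)
        daily = daily_rates(forays, deployment, cfg)
        total = int((~forays["censored"].astype(bool)).sum())
        effect, se = _sex_effect_from_daily(daily, sex_of)
        rows.append(
            {
                "threshold_m": float(thr),
                "total_forays": total,
                "sex_effect": effect,
                "sex_effect_se": se,
            }
        )
    return pd.DataFrame(rows)
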