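"""Brute-force reference implementations used to cross-check the pipeline.

These re-derive windowed localization and foray detection directly from
their rule statements, with no shared code with the package internals:
plain Python loops, per-window recomputation from scratch.
"""

from __future__ import annotations

import bisect
import math


def oracle_localize(rows, home, *, window_width=15.0, step=5.0,
                    home_rssi_threshold=-11.484):
    """Localize one tag's logs by direct per-window recomputation.

    ``rows``: list of (time, station_id, rssi) for a single tag.
    Returns list of dicts (epoch_start, status, station_id, mean_rssi,
    is_home), dense from floor(first/step)*step to the last log time.
    """
    if not rows:
        return []
    rows = sorted(rows, key=lambda r: (r[0], r[1]))
    times = [r[0] for r in rows]
    anchor = math.floor(times[0] / step) * step
    n_epochs = int(math.floor((times[-1] - anchor) / step)) + 1
    out = []
    prev_station = None
    for i in range(n_epochs):
        e = anchor + i * step
        lo = bisect.bisect_left(times, e)
        hi = bisect.bisect_left(times, e + window_width)
        sums, counts = {}, {}
        for t, s, r in rows[lo:hi]:
            sums[s] = sums.get(s, 0.0) + r
            counts[s] = counts.get(s, 0) + 1
        means = {s: sums[s] / counts[s] for s in sums}
        if not means:
            out.append({"epoch_start": e, "status": "unknown",
                        "station_id": None, "mean_rssi": None,
                        "is_home": False})
            continue
        if len(means) == 1:
            station = next(iter(means))
        elif home in means and means[home] > home_rssi_threshold:
            station = home
        else:
            best = max(means.values())
            tied = sorted(s for s, v in means.items() if v == best)
            station = prev_station if prev_station in tied else tied[0]
        prev_station = station
        out.append({"epoch_start": e, "status": "known",
                    "station_id": station, "mean_rssi": means[station],
                    "is_home": station == home})
    return out


def oracle_detect(estimates, dist_of, *, step=5.0, distance_threshold=250.0,
                  min_nonhome_time=15.0):
    """Foray detection by a direct sequential scan over the epoch series.

    ``estimates``: time-ordered list of dicts as from oracle_localize;
    ``dist_of``: mapping station_id → distance from home (m).
    Returns list of foray dicts.
    """
    forays = []
    run = None  # dict with start, stations, n, leading
    seen_home = False
    for est in estimates:
        if est["status"] != "known":
            continue
        if est["is_home"]:
            if run is not None:
                _close(run, est["epoch_start"], forays, step,
                       distance_threshold, min_nonhome_time, dist_of)
                run = None
            seen_home = True
        else:
            if run is None:
                run = {"start": est["epoch_start"], "stations": set(),
                       "n": 0, "leading": not seen_home}
            run["stations"].add(est["station_id"])
            run["n"] += 1
    if run is not None:
        _close(run, None, forays, step, distance_threshold,
               min_nonhome_time, dist_of)
    return forays


def _close(run, end_time, forays, step, distance_threshold,
           min_nonhome_time, dist_of):
    max_d = max(dist_of[s] for s in run["stations"])
    if not (step * run["n"] > min_nonhome_time):
        return
    if not (max_d > distance_threshold):
        return
    censored = run["leading"] or end_time is None
    forays.append({
        "start_time": run["start"],
        "end_time": end_time,
        "duration_min": None if end_time is None
        else (end_time - run["start"]) / 60.0,
        "max_distance_m": max_d,
        "round_trip_m": 2.0 * max_d,
        "n_known_epochs": run["n"],
        "censored": censored,
    })
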