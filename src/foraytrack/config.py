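"""Analysis configuration.

All tunables of the localization → foray-detection pipeline live in a single
:class:`AnalysisConfig` so that a run is fully described by one object that
can be materialized from YAML or JSON.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

#: Home-override RSSI threshold deployed in the original study: the fitted
#: mean signal strength at 50 m from a receiver. A home-station window mean
#: strictly above this value pins the bird to its home territory.
DEFAULT_HOME_RSSI_THRESHOLD = -11.484


@dataclass
class AnalysisConfig:
    """Parameters of the windowed localization and foray-detection rules.

    Parameters
    ----------
    window_width : float
        Width of the moving RSSI-averaging window, seconds.
    step : float
        Step between successive windows, seconds. Each location estimate
        stands for the ``step``-long epoch beginning at its ``epoch_start``.
    distance_threshold : float
        A run of non-home locations only counts as a foray if its furthest
        assigned station lies strictly more than this many metres from the
        bird's home station.
    min_nonhome_time : float
        Total known non-home time (``step`` × number of known non-home
        epochs) must strictly exceed this many seconds.
    home_rssi_threshold : float
        Home-override threshold: if the home station's window-mean RSSI is
        strictly greater, the bird is assigned home regardless of other
        stations.
    calibration_reference_distance : float
        Distance (m) at which the calibration module evaluates the fitted
        RSSI-distance curve to derive ``home_rssi_threshold``.
    utc_offset_hours : float
        Offset of local civil time from the time axis, used for calendar-day
        and hour-of-day binning.
    epoch : str
        ISO date that second 0 of the time axis refers to; only used to
        render calendar dates in outputs.
    """

    window_width: float = 15.0
    step: float = 5.0
    distance_threshold: float = 250.0
    min_nonhome_time: float = 15.0
    home_rssi_threshold: float = DEFAULT_HOME_RSSI_THRESHOLD
    calibration_reference_distance: float = 50.0
    utc_offset_hours: float = 0.0
    epoch: str = "2017-02-01"

    def __post_init__(self) -> None:
        if not (self.window_width >= self.step > 0):
            raise ValueError(
                f"require window_width >= step > 0, got "
                f"window_width={self.window_width}, step={self.step}"
            )
        if self.distance_threshold <= 0:
            raise ValueError("distance_threshold must be > 0")
        if self.min_nonhome_time < 0:
            raise ValueError("min_nonhome_time must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load from a YAML or JSON file (YAML is a superset, so one parser)."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_file(self, path: str | Path) -> None:
        p = Path(path)
        if p.suffix == ".json":
            p.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            p.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
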