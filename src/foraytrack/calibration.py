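"""RSSI–distance calibration from field transects.

Received signal strength falls off approximately linearly in log distance
(the standard log-distance path-loss model), so the calibration fit is an
ordinary least-squares regression of RSSI on log10(distance). The fitted
curve evaluated at a reference distance (default 50 m, about half the
spacing between neighbouring territory centres) gives the home-override
threshold used by the localizer: a home-station window mean above it is
taken as strong evidence that the bird is on its home territory.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.isotonic import IsotonicRegression


@dataclass
class RssiModel:
    """A fitted log-distance path-loss model.

    ``threshold_at_reference`` is the predicted mean RSSI at
    ``reference_distance`` — the quantity deployed as the localizer's
    home-override threshold.
    """

    intercept: float
    slope: float  # RSSI per decade of distance; negative for valid fits
    residual_sd: float
    threshold_at_reference: float
    reference_distance: float

    def predict(self, distance) -> np.ndarray:
        d = np.asarray(distance, dtype=float)
        return self.intercept + self.slope * np.log10(d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RssiModel":
        return cls(**json.loads(Path(path).read_text()))


class RssiDistanceCalibrator(BaseEstimator, RegressorMixin):
    """Least-squares fit of RSSI on log10(distance).

    Parameters
    ----------
    reference_distance : float
        Distance (m) at which the threshold RSSI is evaluated.
    mode : {"fit", "empirical-mean"}
        "fit" evaluates the regression line at the reference distance;
        "empirical-mean" instead averages the observed RSSI of calibration
        points lying within ``reference_tolerance`` of it (for protocols
        that read the threshold straight off the transect data).
    reference_tolerance : float
        Half-width (m) of the distance band used by "empirical-mean".

    Attributes
    ----------
    intercept_, slope_ : float
        Coefficients of ``rssi = intercept + slope * log10(d)``.
    residual_sd_ : float
        Standard deviation of fit residuals (ddof = 2).
    threshold_at_reference_ : float
        Threshold RSSI at the reference distance.
    model_ : RssiModel
        The same quantities bundled for serialisation.
    """

    def __init__(self, reference_distance: float = 50.0, mode: str = "fit",
                 reference_tolerance: float = 5.0):
        self.reference_distance = reference_distance
        self.mode = mode
        self.reference_tolerance = reference_tolerance

    def fit(self, X, y) -> "RssiDistanceCalibrator":
        d = np.asarray(X, dtype=float).reshape(-1)
        rssi = np.asarray(y, dtype=float).reshape(-1)
        if d.shape != rssi.shape:
            raise ValueError("distance and rssi must have equal length")
        if (d <= 0).any():
            raise ValueError("distances must be strictly positive")
        if len(np.unique(d)) < 2:
            raise np.linalg.LinAlgError(
                "all calibration distances equal: slope is unidentifiable"
            )
        logd = np.log10(d)
        A = np.column_stack([np.ones_like(logd), logd])
        coef, *_ = np.linalg.lstsq(A, rssi, rcond=None)
        self.intercept_, self.slope_ = float(coef[0]), float(coef[1])
        resid = rssi - A @ coef
        dof = max(len(d) - 2, 1)
        self.residual_sd_ = float(np.sqrt((resid**2).sum() / dof))
        if self.slope_ > -1e-9:  # flat or rising within numerical noise
            warnings.warn(
                "calibration slope is non-negative; RSSI should decay with "
                "distance — check the transect data",
                stacklevel=2,
            )
        if self.mode == "empirical-mean":
            band = np.abs(d - self.reference_distance) <= self.reference_tolerance
            if not band.any():
                raise ValueError(
                    f"no calibration points within {self.reference_tolerance} m "
                    f"of {self.reference_distance} m"
                )
            self.threshold_at_reference_ = float(rssi[band].mean())
        elif self.mode == "fit":
            self.threshold_at_reference_ = float(
                self.intercept_ + self.slope_ * np.log10(self.reference_distance)
            )
        else:
            raise ValueError(f"unknown mode {self.mode!r}")
        self.model_ = RssiModel(
            intercept=self.intercept_,
            slope=self.slope_,
            residual_sd=self.residual_sd_,
            threshold_at_reference=self.threshold_at_reference_,
            reference_distance=float(self.reference_distance),
        )
        return self

    def predict(self, X) -> np.ndarray:
        return self.model_.predict(np.asarray(X, dtype=float).reshape(-1))


def fit_rssi_distance(
    calibration: pd.DataFrame | list[tuple[float, float]],
    reference_distance: float = 50.0,
    mode: str = "fit",
) -> RssiModel:
    """Fit the RSSI–distance curve; input is (distance_m, rssi) pairs.

    Accepts a DataFrame with ``distance``/``rssi`` columns or a sequence of
    pairs. Requires at least three distinct positive distances.
    """
    if isinstance(calibration, pd.DataFrame):
        d = calibration["distance"].to_numpy(dtype=float)
        r = calibration["rssi"].to_numpy(dtype=float)
    else:
        arr = np.asarray(calibration, dtype=float)
        d, r = arr[:, 0], arr[:, 1]
    if len(np.unique(d)) < 3:
        raise ValueError("need >= 3 distinct calibration distances")
    cal = RssiDistanceCalibrator(
        reference_distance=reference_distance, mode=mode
    ).fit(d, r)
    return cal.model_


def detection_probability_curve(
    records: pd.DataFrame | list[tuple[float, int, int]],
    *,
    isotonic: bool = False,
) -> pd.DataFrame:
    """Empirical per-distance detection fraction from missed-pulse counts.

    ``records`` holds (distance_m, n_sent, n_received) per distance bin.
    With ``isotonic=True`` a monotone-decreasing isotonic regression is
    overlaid (column ``fraction_isotonic``), weighting bins by n_sent.
    """
    if isinstance(records, pd.DataFrame):
        df = records[["distance", "n_sent", "n_received"]].copy()
    else:
        df = pd.DataFrame(records, columns=["distance", "n_sent", "n_received"])
    if (df["n_sent"] <= 0).any():
        raise ValueError("n_sent must be positive in every bin")
    if (df["n_received"] > df["n_sent"]).any():
        raise ValueError("n_received exceeds n_sent in some bin")
    df = df.sort_values("distance").reset_index(drop=True)
    df["fraction"] = df["n_received"] / df["n_sent"]
    if isotonic:
        iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
        df["fraction_isotonic"] = iso.fit(
            df["distance"], df["fraction"], sample_weight=df["n_sent"]
        ).predict(df["distance"])
    return df
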