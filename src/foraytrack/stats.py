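"""Behavioural statistics on pipeline outputs.

Three pieces: the exact binomial test for a sex bias in directly observed
forays; construction of the trailing prospecting-rate covariate that pairs
each provisioning watch with the bird's foray rate over the preceding
days; and log-link count models of provisioning effort (feeds per watch,
watch duration as offset) used to estimate the prospecting–cooperation
trade-off and the sex effect on foray rates.

Count models are fitted as Poisson GEE with an exchangeable working
correlation over birds and cluster-robust standard errors; this targets
the same population-level log rate ratio as a random-intercept Poisson
GLMM while staying numerically robust at the small cluster counts typical
of these data.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

logger = logging.getLogger(__name__)


def exact_binomial_sex_test(
    k_male: int, n_total: int, p0: float = 0.5, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Exact binomial test of a sex bias in observed foray counts.

    Returns ``(proportion_male, p_value)``. The two-sided p-value is the
    minimum-likelihood sum: probabilities of all outcomes no more likely
    than the observed count.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= k_male <= n_total:
        raise ValueError("k_male must lie in [0, n_total]")
    res = sps.binomtest(k_male, n_total, p0, alternative=alternative)
    return k_male / n_total, float(res.pvalue)


def trailing_rate(
    forays: pd.DataFrame,
    bird_id: str,
    focal_day: int,
    window_days: int,
    deployment: dict[str, tuple[float, float]] | None = None,
    *,
    day_of=None,
) -> float:
    """Foray rate (per day) over the ``window_days`` days preceding
    ``focal_day``: the half-open day window [focal − w, focal).

    ``focal_day`` is a local day index; foray start times are converted
    with ``day_of`` (defaults to floor(start_time / 86400)). Raises if the
    window extends before the bird's deployment when one is given.
    """
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    if deployment is not None:
        t0 = deployment[bird_id][0]
        if (focal_day - window_days) < int(t0 // 86400.0):
            raise ValueError(
                f"trailing window before deployment start for {bird_id!r}"
            )
    f = forays.loc[
        (forays["tag_id"].astype(str) == str(bird_id))
        & (~forays["censored"].astype(bool))
    ]
    if day_of is None:
        day_of = lambda t: np.floor(np.asarray(t, float) / 86400.0).astype(int)
    days = day_of(f["start_time"].to_numpy(dtype=float)) if len(f) else np.array([], int)
    in_window = (days >= focal_day - window_days) & (days < focal_day)
    return float(in_window.sum()) / window_days


def build_tradeoff_table(
    forays: pd.DataFrame,
    provisioning_obs: pd.DataFrame,
    window_days: int = 3,
    deployment: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Pair each provisioning watch with the trailing prospecting rate.

    ``provisioning_obs`` needs columns bird_id, day_index, hours, feeds and
    optionally sex, brood_size, brood_age. Observations whose window falls
    before deployment start, or from birds without tracking data, are
    dropped (logged).
    """
    tracked = set(forays["tag_id"].astype(str))
    if deployment is not None:
        tracked |= set(map(str, deployment))
    rows, dropped = [], 0
    for r in provisioning_obs.itertuples():
        bird = str(r.bird_id)
        if bird not in tracked:
            dropped += 1
            continue
        try:
            rate = trailing_rate(forays, bird, int(r.day_index), window_days,
                                 deployment)
        except ValueError:
            dropped += 1
            continue
        rows.append({
            "bird_id": bird,
            "sex": getattr(r, "sex", None),
            "day_index": int(r.day_index),
            "provisioning_hours": float(r.hours),
            "feeds": int(r.feeds),
            "trailing_prospecting_rate": rate,
            "window_days": window_days,
            "brood_size": getattr(r, "brood_size", None),
            "brood_age": getattr(r, "brood_age", None),
        })
    if dropped:
        logger.info("dropped %d provisioning rows without usable windows", dropped)
    return pd.DataFrame(rows)


def _poisson_gee(
    df: pd.DataFrame, design: pd.DataFrame, y: str, groups: str,
    offset: np.ndarray | None = None,
) -> pd.DataFrame:
    """Poisson GEE (exchangeable over ``groups``) → (term, estimate, se)."""
    n_groups = df[groups].nunique()
    if n_groups < 2:
        warnings.warn(
            "only one cluster: falling back to a plain Poisson GLM",
            stacklevel=3,
        )
        model = sm.GLM(df[y], design, family=sm.families.Poisson(),
                       offset=offset)
        fit = model.fit()
        return pd.DataFrame(
            {"term": design.columns, "estimate": fit.params.to_numpy(),
             "se": fit.bse.to_numpy()}
        )
    model = sm.GEE(
        df[y], design, groups=df[groups],
        family=sm.families.Poisson(),
        cov_struct=sm.cov_struct.Exchangeable(),
        offset=offset,
    )
    fit = model.fit()
    return pd.DataFrame(
        {"term": design.columns, "estimate": fit.params.to_numpy(),
         "se": fit.bse.to_numpy()}
    )


def fit_tradeoff_model(table: pd.DataFrame) -> pd.DataFrame:
    """Fit the provisioning–prospecting trade-off count model.

    ``feeds ~ trailing rate + sex + brood age + brood size`` with
    ``log(provisioning_hours)`` as offset and birds as clusters. Returns a
    coefficient table (term, estimate, se); the trade-off slope is the
    ``trailing_prospecting_rate`` row, a log-scale effect per foray/day.
    """
    if len(table) == 0:
        raise ValueError("empty trade-off table")
    if table["trailing_prospecting_rate"].nunique() < 2:
        raise np.linalg.LinAlgError(
            "no variation in trailing prospecting rate: slope unidentifiable"
        )
    design = pd.DataFrame({"intercept": np.ones(len(table))},
                          index=table.index)
    design["trailing_prospecting_rate"] = table["trailing_prospecting_rate"]
    if "sex" in table and table["sex"].notna().any() and table["sex"].nunique() > 1:
        design["sex_male"] = (table["sex"] == "male").astype(float)
    for col in ("brood_age", "brood_size"):
        if col in table and table[col].notna().all() and table[col].nunique() > 1:
            design[col] = pd.to_numeric(table[col])
    offset = np.log(table["provisioning_hours"].to_numpy(dtype=float))
    return _poisson_gee(table, design, "feeds", "bird_id", offset)


def window_sensitivity(
    forays: pd.DataFrame,
    provisioning_obs: pd.DataFrame,
    windows: list[int],
    deployment: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Trade-off slope (and SE) refitted for each trailing-window length."""
    rows = []
    for w in windows:
        table = build_tradeoff_table(forays, provisioning_obs, w, deployment)
        coefs = fit_tradeoff_model(table)
        sl = coefs.set_index("term").loc["trailing_prospecting_rate"]
        rows.append({"window_days": int(w),
                     "tradeoff_estimate": float(sl["estimate"]),
                     "se": float(sl["se"])})
    return pd.DataFrame(rows)


def sex_rate_ratio(
    daily: pd.DataFrame, sex_of: dict[str, str]
) -> dict[str, float]:
    """Male:female foray-rate ratio from per-bird-day counts.

    Per-bird mean daily rates are averaged within sex; the log-ratio SE
    uses the bird-level (cluster) delta method, since per-bird rates — not
    individual days — are the independent replicates: home-territory
    geometry makes a bird's daily counts correlated.
    """
    df = daily.copy()
    df["sex"] = df["tag_id"].astype(str).map(sex_of)
    per_bird = (
        df.dropna(subset=["sex"])
        .groupby(["tag_id", "sex"], observed=True)["n_forays"]
        .mean()
        .reset_index()
    )
    g = per_bird.groupby("sex")["n_forays"]
    mean, var, n = g.mean(), g.var(), g.count()
    for s in ("male", "female"):
        if n.get(s, 0) < 2:
            raise ValueError(f"need >= 2 birds of sex {s!r}")
    rm, rf = float(mean["male"]), float(mean["female"])
    se_log = float(np.sqrt(
        var["male"] / (n["male"] * rm**2) + var["female"] / (n["female"] * rf**2)
    ))
    return {
        "rate_male": rm,
        "rate_female": rf,
        "ratio": rm / rf,
        "log_ratio": float(np.log(rm / rf)),
        "se_log": se_log,
    }


def _sex_effect_from_daily(
    daily: pd.DataFrame, sex_of: dict[str, str]
) -> tuple[float, float]:
    """Male-vs-female log rate ratio from per-bird-day foray counts.

    Log-link count model on daily counts with bird-level clustering;
    returns (estimate, se), or (nan, nan) with <2 birds per sex.
    """
    df = daily.copy()
    df["sex"] = df["tag_id"].astype(str).map(sex_of)
    df = df.dropna(subset=["sex"])
    per_sex = df.groupby("sex")["tag_id"].nunique()
    if per_sex.get("male", 0) < 2 or per_sex.get("female", 0) < 2:
        return float("nan"), float("nan")
    design = pd.DataFrame({
        "intercept": np.ones(len(df)),
        "sex_male": (df["sex"] == "male").astype(float),
    }, index=df.index)
    coefs = _poisson_gee(df, design, "n_forays", "tag_id")
    row = coefs.set_index("term").loc["sex_male"]
    return float(row["estimate"]), float(row["se"])
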