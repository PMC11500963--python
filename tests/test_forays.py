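import numpy as np
import pandas as pd
import pytest

from foraytrack import (
    AnalysisConfig,
    circadian_profile,
    daily_rates,
    detect_forays,
    threshold_sensitivity,
)

from conftest import estimates_from_pattern, random_estimate_instance
from oracles import oracle_detect


class TestDetectForays:
    def test_all_home_yields_no_forays(self, line_array):
        est = estimates_from_pattern("H" * 50)
        assert len(detect_forays(est, line_array)) == 0

    def test_hand_traced_single_foray(self, line_array):
        # H,H,B,B,B,B,B,H with B at 300 m and 5-s epochs
        est = estimates_from_pattern("HHBBBBBH")
        forays = detect_forays(est, line_array)
        assert len(forays) == 1
        f = forays.iloc[0]
        assert f["n_known_epochs"] == 5          # 25 s > 15 s
        assert f["max_distance_m"] == 300.0
        assert f["round_trip_m"] == 600.0
        assert f["start_time"] == 10.0
        assert f["end_time"] == 35.0
        assert f["duration_min"] == pytest.approx(25 / 60)
        assert not f["censored"]

    def test_distance_criterion_is_strict(self, line_array):
        # C sits at exactly 200 m: inside the 250 m threshold
        est = estimates_from_pattern("HHCCCCCH")
        assert len(detect_forays(est, line_array)) == 0
        cfg = AnalysisConfig(distance_threshold=199.0)
        assert len(detect_forays(est, line_array, config=cfg)) == 1
        cfg = AnalysisConfig(distance_threshold=200.0)  # 200 > 200 is false
        assert len(detect_forays(est, line_array, config=cfg)) == 0

    def test_duration_criterion_is_strict(self, line_array):
        # 3 non-home epochs = 15 s, not > 15 s
        assert len(detect_forays(estimates_from_pattern("HBBBH"), line_array)) == 0
        assert len(detect_forays(estimates_from_pattern("HBBBBH"), line_array)) == 1

    def test_unknown_epochs_do_not_break_a_run(self, line_array):
        # a bird silent far outside the array keeps its run open
        est = estimates_from_pattern("HBB" + "?" * 20 + "BBH")
        forays = detect_forays(est, line_array)
        assert len(forays) == 1
        f = forays.iloc[0]
        assert f["n_known_epochs"] == 4
        assert f["duration_min"] == pytest.approx((25 - 1) * 5 / 60)

    def test_short_known_time_around_gap_is_no_foray(self, line_array):
        # two known non-home epochs bracketing a gap total only 10 s
        est = estimates_from_pattern("HB" + "?" * 20 + "BH")
        assert len(detect_forays(est, line_array)) == 0

    def test_unknowns_alone_never_open_a_run(self, line_array):
        est = estimates_from_pattern("H" + "?" * 30 + "H")
        assert len(detect_forays(est, line_array)) == 0

    def test_open_run_at_data_end_is_censored(self, line_array):
        est = estimates_from_pattern("HHBBBBBB")
        forays = detect_forays(est, line_array)
        assert len(forays) == 1
        assert forays.iloc[0]["censored"]
        assert np.isnan(forays.iloc[0]["end_time"])

    def test_leading_nonhome_run_is_censored(self, line_array):
        est = estimates_from_pattern("BBBBBH")
        forays = detect_forays(est, line_array)
        assert len(forays) == 1
        assert forays.iloc[0]["censored"]
        # but its end is known, so the duration is reported
        assert forays.iloc[0]["end_time"] == 25.0

    def test_max_distance_over_all_assigned_stations(self, line_array):
        # run visits C (200 m) and D (400 m): max distance is D's
        est = estimates_from_pattern("HCCDDCH")
        forays = detect_forays(est, line_array)
        assert forays.iloc[0]["max_distance_m"] == 400.0

    def test_multiple_tags_rejected(self, line_array):
        a = estimates_from_pattern("HBBBBH", tag_id="tag1")
        b = estimates_from_pattern("HBBBBH", tag_id="tag2")
        with pytest.raises(ValueError, match="single tag"):
            detect_forays(pd.concat([a, b]), line_array)


@pytest.mark.parametrize("seed", range(30))
def test_detection_matches_brute_force(seed, line_array):
    """Vectorised run-splitting agrees with a sequential scan evaluating
    both criteria per candidate run."""
    rng = np.random.default_rng(100 + seed)
    est = random_estimate_instance(rng, max_epochs=2000)
    forays = detect_forays(est, line_array)
    dist_of = {s: line_array.distance("A", s) for s in line_array.station_ids}
    expected = oracle_detect(est.to_dict("records"), dist_of)
    assert len(forays) == len(expected)
    for got, want in zip(forays.itertuples(), expected):
        assert got.start_time == want["start_time"]
        assert got.n_known_epochs == want["n_known_epochs"]
        assert got.max_distance_m == pytest.approx(want["max_distance_m"])
        assert got.censored == want["censored"]
        if not np.isnan(got.end_time):
            assert got.end_time == want["end_time"]


def test_foray_invariants_on_random_instances(line_array, config):
    """Emitted forays satisfy their structural invariants."""
    rng = np.random.default_rng(42)
    for _ in range(20):
        est = random_estimate_instance(rng, max_epochs=1500)
        forays = detect_forays(est, line_array)
        if len(forays) == 0:
            continue
        open_f = forays.loc[~forays["censored"]]
        assert (open_f["end_time"] > open_f["start_time"]).all()
        assert (forays["max_distance_m"] > config.distance_threshold).all()
        assert (forays["round_trip_m"] == 2 * forays["max_distance_m"]).all()
        assert (config.step * forays["n_known_epochs"]
                > config.min_nonhome_time).all()
        starts = forays["start_time"].to_numpy()
        assert (np.diff(starts) > 0).all()  # disjoint, time-ordered


def test_foray_count_monotone_in_threshold_and_min_time(line_array):
    rng = np.random.default_rng(5)
    est = random_estimate_instance(rng, max_epochs=3000)
    counts = []
    for thr in [150, 200, 250, 300, 350, 401]:
        cfg = AnalysisConfig(distance_threshold=thr)
        counts.append(len(detect_forays(est, line_array, config=cfg)))
    assert counts == sorted(counts, reverse=True)
    tcounts = []
    for mt in [0, 15, 30, 60]:
        cfg = AnalysisConfig(min_nonhome_time=mt)
        tcounts.append(len(detect_forays(est, line_array, config=cfg)))
    assert tcounts == sorted(tcounts, reverse=True)


class TestDailyRates:
    def test_zero_forays_full_deployment(self, line_array):
        forays = detect_forays(estimates_from_pattern("H" * 10), line_array)
        daily = daily_rates(forays, {"tag1": (0.0, 10 * 86400.0 - 1)})
        assert len(daily) == 10
        assert (daily["n_forays"] == 0).all()
        assert daily["tracked"].all()

    def test_counts_per_day_and_mean(self, line_array):
        rows = []
        for day, n in [(0, 3), (1, 2), (2, 1)]:
            for k in range(n):
                start = day * 86400.0 + 3600.0 * (k + 1)
                rows.append({"tag_id": "tag1", "start_time": start,
                             "end_time": start + 300, "duration_min": 5.0,
                             "max_distance_m": 300.0, "round_trip_m": 600.0,
                             "n_known_epochs": 10, "censored": False})
        forays = pd.DataFrame(rows)
        daily = daily_rates(forays, {"tag1": (0.0, 3 * 86400.0 - 1)})
        assert daily["n_forays"].tolist() == [3, 2, 1]
        assert daily["n_forays"].mean() == pytest.approx(2.0)

    def test_foray_counted_on_start_day(self):
        # starts 23:59, ends next day: counted on the start day
        start = 86400.0 - 60.0
        forays = pd.DataFrame([{
            "tag_id": "tag1", "start_time": start, "end_time": start + 600,
            "duration_min": 10.0, "max_distance_m": 300.0,
            "round_trip_m": 600.0, "n_known_epochs": 10, "censored": False,
        }])
        daily = daily_rates(forays, {"tag1": (0.0, 2 * 86400.0 - 1)})
        assert daily["n_forays"].tolist() == [1, 0]

    def test_censored_excluded_by_default(self, line_array):
        est = estimates_from_pattern("HHBBBBBB")
        forays = detect_forays(est, line_array)
        daily = daily_rates(forays, {"tag1": (0.0, 86400.0 - 1)})
        assert daily["n_forays"].sum() == 0
        daily = daily_rates(forays, {"tag1": (0.0, 86400.0 - 1)},
                            include_censored=True)
        assert daily["n_forays"].sum() == 1

    def test_foray_outside_deployment_raises(self):
        forays = pd.DataFrame([{
            "tag_id": "tag1", "start_time": 1e6, "end_time": 1e6 + 60,
            "duration_min": 1.0, "max_distance_m": 300.0,
            "round_trip_m": 600.0, "n_known_epochs": 10, "censored": False,
        }])
        with pytest.raises(ValueError, match="outside deployment"):
            daily_rates(forays, {"tag1": (0.0, 86400.0)})


class TestCircadianProfile:
    def test_no_forays_gives_24_zeros(self):
        forays = pd.DataFrame(columns=[
            "tag_id", "start_time", "end_time", "duration_min",
            "max_distance_m", "round_trip_m", "n_known_epochs", "censored"])
        forays = forays.astype({"censored": bool})
        prof = circadian_profile(forays, {"tag1": (0.0, 2 * 86400.0 - 1)})
        assert len(prof) == 24
        assert (prof["mean_rate_per_bird_per_day"] == 0).all()

    def test_single_morning_foray_over_two_days(self):
        start = 7 * 3600.0 + 1800.0  # 07:30 on day 0
        forays = pd.DataFrame([{
            "tag_id": "tag1", "start_time": start, "end_time": start + 600,
            "duration_min": 10.0, "max_distance_m": 300.0,
            "round_trip_m": 600.0, "n_known_epochs": 10, "censored": False,
        }])
        prof = circadian_profile(forays, {"tag1": (0.0, 2 * 86400.0 - 1)})
        assert prof.loc[prof["hour"] == 7,
                        "mean_rate_per_bird_per_day"].item() == pytest.approx(0.5)
        assert prof["mean_rate_per_bird_per_day"].sum() == pytest.approx(0.5)

    def test_profile_conserves_total_count_for_equal_tracking(self):
        rng = np.random.default_rng(8)
        rows = []
        for tag in ["t1", "t2", "t3"]:
            for _ in range(rng.integers(2, 8)):
                start = float(rng.uniform(0, 4 * 86400.0))
                rows.append({"tag_id": tag, "start_time": start,
                             "end_time": start + 60, "duration_min": 1.0,
                             "max_distance_m": 300.0, "round_trip_m": 600.0,
                             "n_known_epochs": 10, "censored": False})
        forays = pd.DataFrame(rows)
        dep = {t: (0.0, 4 * 86400.0 - 1) for t in ["t1", "t2", "t3"]}
        prof = circadian_profile(forays, dep)
        total = prof["mean_rate_per_bird_per_day"].sum() * 4 * 3
        assert total == pytest.approx(len(forays))


def test_threshold_sensitivity_counts_and_consistency(line_array):
    rng = np.random.default_rng(17)
    ests = []
    sex_of, deployment = {}, {}
    for i in range(6):
        tag = f"tag{i}"
        pattern = "".join(
            rng.choice(list("HHH?BCD"), size=800)
        )
        e = estimates_from_pattern(pattern, tag_id=tag)
        ests.append(e)
        sex_of[tag] = "male" if i % 2 else "female"
        deployment[tag] = (0.0, 800 * 5.0)
        line_array.home_of[tag] = "A"
    est = pd.concat(ests, ignore_index=True)
    cfg = AnalysisConfig()
    table = threshold_sensitivity(est, line_array, cfg, [200, 250, 300],
                                  deployment, sex_of)
    counts = table["total_forays"].tolist()
    assert counts == sorted(counts, reverse=True)
    # single default threshold reproduces plain detection
    from foraytrack import detect_all_forays
    single = threshold_sensitivity(est, line_array, cfg, [250.0],
                                   deployment, sex_of)
    plain = detect_all_forays(est, line_array, cfg)
    assert single["total_forays"].iloc[0] == int((~plain["censored"]).sum())


def test_threshold_sensitivity_recovers_positive_male_effect(line_array):
    """Birds given a higher male foray propensity show a positive male
    log rate ratio at the default threshold."""
    rng = np.random.default_rng(99)
    ests, sex_of, deployment = [], {}, {}
    for i in range(10):
        tag = f"tag{i}"
        male = i % 2 == 0
        sex_of[tag] = "male" if male else "female"
        line_array.home_of[tag] = "A"
        # per-epoch chance of opening a 6-epoch excursion to B (300 m)
        p_foray = 0.004 if male else 0.001
        pattern = []
        n = 3000
        j = 0
        while len(pattern) < n:
            if rng.random() < p_foray:
                pattern += list("BBBBBB")
            else:
                pattern.append("H")
        ests.append(estimates_from_pattern(pattern[:n], tag_id=tag))
        deployment[tag] = (0.0, n * 5.0)
    est = pd.concat(ests, ignore_index=True)
    table = threshold_sensitivity(est, line_array, AnalysisConfig(), [250.0],
                                  deployment, sex_of)
    assert table["total_forays"].iloc[0] > 0
    assert table["sex_effect"].iloc[0] > 0
    assert np.isfinite(table["sex_effect_se"].iloc[0])


def test_threshold_sensitivity_effect_absent_with_one_sex(line_array):
    est = estimates_from_pattern("HHBBBBBH", tag_id="tag1")
    table = threshold_sensitivity(
        est, line_array, AnalysisConfig(), [250.0],
        {"tag1": (0.0, 86400.0)}, {"tag1": "male"},
    )
    assert np.isnan(table["sex_effect"].iloc[0])
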