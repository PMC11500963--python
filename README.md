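# foraytrack

Automated detection of extra-territorial prospecting forays from
receiver-array radio-telemetry logs.

In many cooperatively breeding birds, non-breeding subordinates make brief
excursions ("prospecting forays") out of their home territory, apparently
scouting dispersal opportunities. Direct observation badly undercounts
these events, so field studies increasingly deploy fixed arrays of radio
receivers ("base stations") at territory centres that log every pulse from
animal-borne transmit-only tags, with a timestamp and a received signal
strength indicator (RSSI). `foraytrack` turns those raw detection logs
into foray events and behavioural statistics, and ships a ground-truthed
deployment simulator so every stage of the pipeline can be validated
without field data.

## The method

**Localization.** Each tag's logs are processed in moving windows of width
*W* = 15 s stepped every Δ = 5 s. Each window yields a per-station mean
RSSI and a decision tree assigns a station-resolution "best estimate"
location to the Δ-long epoch at the window start: no logs → *unknown*; one
station → that station; several stations → the station with the highest
mean RSSI, except that the home station wins outright whenever its window
mean exceeds a calibrated home-override threshold (default −11.484, the
fitted mean RSSI at 50 m).

**Foray detection.** A candidate run opens at a known non-home epoch and
closes at the next known *home* epoch; unknown epochs never break a run
(a bird far outside the array can be silent for long stretches). The run
is a foray iff its known non-home time Δ·*k* strictly exceeds 15 s
(*k* = number of known non-home epochs) **and** its furthest assigned
station lies strictly more than 250 m from the home station. Duration is
first-out to first-back; the round-trip distance is twice the straight-line
home-to-furthest-station distance. Runs not closed by a return home are
flagged censored and excluded from rates by default.

**Calibration.** RSSI is regressed on log₁₀(distance) (log-distance
path loss); the fitted curve at a reference distance (50 m) gives the
home-override threshold.

**Statistics.** Exact binomial test for sex bias in observed forays;
per-bird-day foray rates and circadian profiles; a trailing
prospecting-rate covariate (forays/day over the *w* days preceding each
provisioning watch); and log-link count models (Poisson GEE with
bird-level clustering) for the sex effect on foray rate and for the
prospecting–provisioning trade-off (feeds per watch with a log-hours
offset).

## Worked example

Simulate a full deployment at the default study scale (35 stations ≈
93.7 m apart, 27 tagged birds — 13 males at 1.4 forays/day, 14 females at
0.8/day — tracked 37 days, tags pulsing every 5 s), then run the pipeline:

```python
import pandas as pd
from foraytrack import (SimConfig, simulate_deployment, localize_all,
                        detect_all_forays, daily_rates, sex_rate_ratio)

cfg = SimConfig()
sim = simulate_deployment(cfg, seed=1, with_provisioning=False)
est = localize_all(sim["logs"], sim["array"])
forays = detect_all_forays(est, sim["array"])
open_f = forays[~forays["censored"]]
daily = daily_rates(forays, sim["truth"].deployment)
print(len(open_f), round(daily["n_forays"].mean(), 3))
print(round(open_f["round_trip_m"].mean(), 1),
      round(open_f["round_trip_m"].min(), 1))
print(round(sex_rate_ratio(daily, cfg.sex_of())["ratio"], 3))
```

Output (seed 1):

```
487 0.487
723.0 500.4
1.421
```

487 forays pass the conservative criteria out of 1,041 generated — the
>250 m rule deliberately discards shorter excursions, so the detected
daily rate (0.49/day) undercounts the generating rates, exactly as the
station-resolution method is designed to behave. The mean round trip
(723.0 m) must exceed 2 × 250 m by construction (minimum here 500.4 m).
The detected male:female rate ratio (1.42) estimates the generating 1.75
with a bird-level cluster SE of about 0.13 on the log scale.

The same pipeline is scriptable from a shell (`foraytrack simulate`,
`localize`, `detect`, `rates`, `calibrate`, `sensitivity`, `tradeoff`,
`window-sensitivity`); see `foraytrack --help`.

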