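# Methods

This note documents the models and procedures implemented in `foraytrack`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Windowed RSSI localization

A tag's detection logs (one row per received pulse: tag, station, time,
RSSI) are reduced to a station-resolution location series. Windows of
width `window_width` (default 15 s) are stepped every `step` (default
5 s); each window covers the half-open interval `[e, e + W)` and yields a
per-station mean RSSI. The assignment rules are, in order: an empty
window is *unknown*; a single station is assigned directly; with several
stations the home station is assigned whenever its window mean strictly
exceeds `home_rssi_threshold`, otherwise the station with the highest
mean wins. Each estimate stands for the `step`-long epoch at its window
start, so epochs partition time even though windows overlap.

Numerical choices:

- **Window anchor.** The epoch grid is anchored per tag at the first log
  time rounded down to a multiple of `step`. Anchoring per tag keeps tags
  independent; any global anchor would couple them through an arbitrary
  origin.
- **Ties.** Exact ties in mean RSSI (measure-zero with noisy signals,
  routine with integer test data) are broken in favour of the previously
  assigned station, then the lexicographically smallest station id.
  Continuity-first is conservative against spurious movement.
- **Strictness.** The home override requires *strictly* greater than the
  threshold; a home mean exactly at the threshold falls through to the
  argmax rule.
- The production path is vectorised (per-epoch sum/count accumulation);
  ties are resolved in a second ordered pass over only the tied epochs.
  The test suite checks epoch-for-epoch equivalence against a brute-force
  per-window recomputation.

`home_rssi_threshold` defaults to −11.484, the calibrated mean signal
strength at 50 m from a receiver in the deployment this package's
defaults emulate. It can be refitted from transect data (below).

## Foray detection

On the dense estimate series, a candidate run opens at a known non-home
epoch and closes at the next known home epoch. Unknown epochs never break
a run: a prospecting bird beyond array coverage produces exactly this
signature. A run is a foray iff

1. `step × (known non-home epochs) > min_nonhome_time` (default 15 s;
   strict, so with 5-s epochs at least 4 known non-home epochs), and
2. `max over assigned stations of distance(home, station) >
   distance_threshold` (default 250 m; strict).

Duration is the time from the first non-home estimate to the first
subsequent home estimate; the round trip is twice the home-to-furthest-
station straight-line distance, a deliberate lower bound on the true path
length. Degenerate boundaries: runs still open at the end of tracking
have no defined end (duration is NaN), and runs that begin before the
bird was ever estimated home have no defined start context; both are
emitted flagged `censored` and excluded from rate summaries unless
requested. A foray is counted on the local calendar day containing its
start (days use a configurable UTC offset; deployment intervals are
half-open so an end falling exactly on midnight does not open a new
tracked day).

The distance criterion makes the detector intentionally conservative:
excursions that never register at a station more than `distance_threshold`
from home are discarded, so detected rates undercount true excursion
rates. This is a property of the method, not a defect; the sensitivity
analysis (`threshold_sensitivity`) quantifies how counts and the sex
effect respond to the threshold between 200 and 350 m.

## RSSI–distance calibration

`fit_rssi_distance` fits `rssi = a + b·log10(d)` by ordinary least
squares — the standard log-distance path-loss model — and evaluates the
fitted line at `reference_distance` (default 50 m) to produce the
home-override threshold. A non-negative fitted slope triggers a validity
warning (signal strength must decay with distance). Because the deployed
threshold could equally have been computed as a raw mean of observations
near the reference distance, an `empirical-mean` mode averages the RSSI
of calibration points within ±5 m of the reference instead. The
missed-pulse companion, `detection_probability_curve`, reports empirical
per-distance detection fractions with an optional decreasing isotonic
overlay.

## Count models

The sex effect on foray rate and the provisioning trade-off are both
log-link count models with repeated measures per bird. They are fitted as
Poisson GEE with an exchangeable working correlation over birds and
cluster-robust standard errors. A GEE targets the same population-level
log rate ratio as a random-intercept Poisson GLMM while remaining
numerically robust at the 10–30 clusters typical here; with a bird-level
random intercept the within-cluster correlation is exchangeable, which is
exactly the working structure used. With a single cluster the fit
collapses to a plain Poisson GLM with a warning. The trade-off model is
`feeds ~ trailing_rate + sex + brood_age + brood_size` with
`log(provisioning_hours)` as offset; constant covariates are dropped from
the design. The trailing prospecting rate for a watch on day *t* counts
forays starting in the half-open day window `[t − w, t)` divided by *w*
(default *w* = 3) — the focal day itself is excluded, and observations
whose window precedes deployment start are dropped.

The exact binomial sex test uses the minimum-likelihood two-sided
definition (the sum of probabilities of outcomes no more likely than the
observed count), the conventional exact-test convention; one-sided
alternatives are available.

## Synthetic deployments

`simulate_deployment` emulates the deployment the defaults describe:

- **Array**: a jittered grid of 35 stations, rescaled so the mean
  nearest-neighbour spacing is exactly 93.7 m; homes are assigned to
  birds with the sexes interleaved so territories are not spatially
  sex-segregated.
- **Movement**: 27 birds (13 male, 14 female) sit at their home station
  plus isotropic Gaussian jitter (SD 10 m) except during forays, drawn as
  a per-bird Poisson process with sex-specific daily rates (male 1.4,
  female 0.8 — ratio 1.75, population mean 1.09/day). Foray durations are
  log-normal (median 5.67 min, log-SD 1.54, giving mean ≈ 18.6 min);
  one-way distances are log-normal (median 324 m, log-SD 0.46, giving a
  round-trip spread matching a ≈ 720 m mean among detected forays).
  Start times fall between 06:00 and 19:00 local by default, reflecting
  the diurnal study species. Travel is straight-line at 5 m/s with a
  dwell at the target; overlapping draws are thinned keeping earlier
  starts, so truth intervals are disjoint.
- **Logs**: every 5-s pulse is received by each station independently
  with probability `logistic((midpoint − d)/scale)` (defaults 100 m and
  15 m), and received pulses log
  `rssi = 31.0 − 25.0·log10(d) + N(0, 4)`. The intercept is chosen so
  the model's 50-m mean equals the −11.484 default threshold; distances
  are clamped at 1 m.
- **Provisioning**: watch-level feed counts are Poisson with log-mean
  `log(baseline·hours) + β_tradeoff·trailing_rate + brood terms + bird
  intercept` (baseline 4 feeds/h, β_tradeoff −0.3, bird-intercept SD
  0.2 on the log scale).

Randomness derives from one seed split into per-stage, per-bird
substreams (`SeedSequence.spawn`), so identical seeds give bit-identical
outputs and stages can be re-run in isolation.

What the generator does **not** emulate: territorial interactions at
shared boundaries, terrain- or vegetation-dependent signal obstruction
(RSSI noise is i.i.d. Gaussian), anisotropic antennas, tag failure or
battery decay, heterogeneous per-territory detectability beyond what
array geometry induces, and dispersal (birds always return home). Passing
the end-to-end tests therefore demonstrates that the pipeline's rules are
implemented correctly and recover known generating parameters under the
stated movement and propagation model — not that the model captures every
feature of field RSSI data.

## Monte-Carlo error of the end-to-end sex-ratio check

The end-to-end validation compares the detected male:female rate ratio
with the generating 1.75. The correct Monte-Carlo SE treats *birds* as
the independent replicates (delta method on the log ratio using
between-bird variance within sex), not bird-days: a bird's daily counts
share its home-territory geometry, which modulates detectability — some
homes have more stations beyond 250 m within radio range than others —
so per-day Poisson SEs would be too small. This is the same reason the
sex-effect count models cluster by bird.

## Problem sizes used in validation

The end-to-end checks run one full deployment at the default scale
(27 birds × 37 days ≈ 17 M pulse epochs, ≈ 37 M log rows); oracle
equivalence uses 200 randomized instances of up to 5,000 epochs; the
trade-off power check uses 200 replicates of 200 observations each with
movement simulated at hourly pulse resolution (logs are not needed to
generate provisioning data). These sizes keep the whole suite at a few
minutes while leaving the Monte-Carlo checks well-powered.

## Known limitations

- Localization is station-resolution by design; no multilateration, so
  foray distances are lower bounds quantised to the array geometry.
- Censored runs carry no duration; studies wanting open-interval
  durations must opt in and treat them as right-censored.
- The GEE sex-effect/trade-off fits report population-averaged effects;
  subject-specific GLMM coefficients would differ under strong
  heterogeneity.
- The threshold-sensitivity contract reports the sex effect as absent
  with fewer than two birds per sex rather than extrapolating.
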