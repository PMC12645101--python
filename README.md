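# paircohesion

Analysis pipeline for studying **spatial pair cohesion** — how closely two
pair-bonded, territorial animals share space and coordinate movement — from
**grid-based automated radio telemetry**. The target setting is a field site
instrumented with ~100 fixed radio receivers ("nodes") spaced 100–150 m
apart, with tagged birds beaconing every 15 s; each beacon that reaches a
receiver is logged with its received signal strength (RSS, negative dB).

The package is aimed at movement ecologists working with node-grid telemetry
(e.g. CTT node networks) who want a tested, reproducible implementation of
the full chain from raw detections to dyadic cohesion statistics, plus a
synthetic-data generator to validate every stage against known ground truth.

## What it computes

1. **RSS–distance calibration** — OLS fit of the log-linear law
   `log10(d) = a + b·RSS`, so `d = 10^(a + b·RSS)`. The bundled reference
   curve `d = 10^(−1.27009 − 0.03302·RSS)` maps the −80 dB confidence cutoff
   to a 23.5 m detection radius. Elevation-effect metrics (detection rate,
   receivers per beacon, mean/max RSS per calibration test point) quantify
   how badly ground-level tags are detected.
2. **Localization** — detections are grouped into epoch-aligned 15-s windows;
   the *strongest-detection* method places the tag at the receiver with the
   strongest above-cutoff detection, and *multilateration* solves
   `min_p Σᵢ (‖p − rᵢ‖ − dᵢ)²` by nonlinear least squares over 100 distance
   resamples drawn around the calibration curve's residual spread, yielding a
   mean fix and a bivariate-normal error ellipse. Localization-rate and
   gap-length diagnostics cover the daylight tracking span.
3. **Array coverage** — detectable area per receiver (πr² = 1,735 m² at
   r = 23.5 m), summed and union areas over the array, minimum convex
   polygon use areas, and the expected localization fraction within each
   individual's MCP.
4. **Home-range overlap** — gridded utilization distributions (Gaussian
   kernel, Silverman bandwidth), 95% home-range areas per week × section of
   day, and the Bhattacharyya coefficient `BC = Σ √(p·q) ∈ [0, 1]` for every
   dyad, classified pair-bonded vs not.
5. **Cohesion** — per-window pair separation against a *day-shift null*
   (partner's track from the next day at the same time of day), movement
   events (changes of strongest receiver), following events (a partner
   repeating the focal bird's A→B relocation), a 90th-percentile lag
   threshold, following rates, and who-initiates attribution.
6. **Synthetic data** — jittered receiver grids, coupled leader–follower
   Ornstein–Uhlenbeck pair movement around territory centers, and a
   distance- and height-dependent beacon detection model with dB noise on
   the calibration curve.

## Worked example

```python
import numpy as np
from paircohesion import *
from paircohesion.homerange import common_grid

# a 6x6 receiver grid and one coupled pair sharing a territory
array = generate_receiver_array(6, 6, 115.0, jitter_sd=10.0, seed=1)
cfg = MovementConfig(centers={"F1": (290.0, 290.0), "M1": (290.0, 290.0)},
                     home_range_sd=40.0, coupling=0.8, follow_lag_mean=60.0)
female, male = simulate_pair_tracks(cfg, duration=4 * 3600.0, seed=1)
detections = emit_detections([female, male], array, EmissionConfig(), seed=2)

windows = window_detections(detections)
est = localize_windows(windows, array, method="strongest")
by_tag = {t: g.reset_index(drop=True) for t, g in est.groupby("tag_id")}

pts = {t: g[["x", "y"]].to_numpy(float) for t, g in by_tag.items()}
grid = common_grid(pts["F1"], pts["M1"], 30.0)
bc = bhattacharyya(estimate_ud(pts["F1"], bandwidth=30.0, grid=grid),
                   estimate_ud(pts["M1"], bandwidth=30.0, grid=grid))

config = CohesionConfig()
events = extract_movement_events(by_tag["F1"], config)
cands = extract_following_events(events, by_tag["M1"], config)
thr = lag_threshold(cands, config)
res = following_rate(events, cands, thr, by_tag["F1"], by_tag["M1"])
```

Output (printed by the snippet above with f-strings):

```
5323 detections from 36 receivers
240 strongest-detection fixes in 1905 windows
pair home-range overlap (BC): 0.99
median separation: 0.0 m over 28 matched windows
male followed 4/9 female relocations (rate 0.44, lag threshold 150 s)
```

Reading: over four simulated hours the pair's utilization distributions are
nearly identical (BC 0.99); whenever both birds are localized in the same
15-s window they are usually at the same receiver (median separation 0 m —
the strongest method quantizes positions to receiver coordinates); and the
male repeated 4 of the female's 9 observable relocations within the
150-second lag threshold.

## Command-line pipeline

```sh
paircohesion run-all --seed 42 --out runs/demo          # built-in demo scenario
paircohesion run-all --config my_scenario.yaml          # your own config
```

Stages (`simulate`, `calibrate`, `localize`, `coverage`, `homerange`,
`cohesion`) are also available as individual subcommands operating on the
same output directory. Every run writes a `manifest.json` with the seed,
config hash, and a SHA-256 per output file; rerunning an identical config
reproduces identical bytes.

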