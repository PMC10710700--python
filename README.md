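# soarflight

Analysis pipeline for studying how soaring raptors cross large water
barriers — built around the autumn Adriatic sea-crossings of GPS/GSM-tagged
Red Kites (*Milvus milvus*).  Over land, a migrating kite climbs in thermals
and glides between them; over the open sea thermals are scarce and weak, so
the question is which weather conditions let a bird keep soaring instead of
falling back on costly flapping flight, and which conditions trigger the
decision to set out over the water at all.

The package re-implements that analysis end to end as a tested library plus
numbered analysis drivers, exercised on a synthetic-trajectory generator
with known ground truth (no tracking-data download required):

1. **Sensor classification** (`soarflight.classify`) — duty-cycled 1 Hz
   bursts (5 min on, 10–15 min off) are sorted into flapping / gliding /
   soaring: a roost filter (speed < 1 km/h), an accelerometer z-channel
   split (passive flight is smooth within 800–1400 mG; flapping oscillates
   strongly), and a magnetometer x-channel split (circling makes mag_x
   oscillate once per turn; gliding is smooth).
2. **Pattern geometry** (`soarflight.geometry`) — soaring bursts are
   classed by turn geometry: *spiral* (full turns of fitted diameter
   < 10 m), *staircase* (diameter ≥ 10 m, circles separated by straight
   runs), *s-shape* (heading oscillation, no full 360° turn).
3. **Weather annotation** (`soarflight.weather`) — gridded hourly 0.25°
   reanalysis-style fields attached per fix (bilinear wind, nearest-
   neighbour thermal fields), then decomposed into wind support
   `|w|·cos α` (negative = headwind), |side wind| `|w|·|sin α|`, and
   ΔT = T_surface − T_air, the standard thermal-uplift proxy.
4. **Crossing analysis** (`soarflight.crossings`) — a crossing is the run
   between the first and last over-water fix; the departure dataset
   contrasts resting mornings (06:00–13:00 local, departed = 0) with the
   crossing morning up to 10 km offshore (departed = 1).
5. **Statistics** (`soarflight.stats`) — binomial GLMMs with a per-bird
   random intercept, fitted by Gauss–Hermite quadrature on the exact
   marginal likelihood: standardized predictors, a |r| ≥ 0.6 collinearity
   screen, 30 s thinning of 1 Hz series, all-subsets ranking by AIC/AICc
   with Akaike-weight averaging of models within Δ < 2, 10-fold predictive
   accuracy, and latent-scale (variance-partition) R²m/R²c.

The synthetic generator (`soarflight.synthetic`) emulates the logger
regime, the sensor signatures of all five flight modes, and logistic
decision structures with configurable standardized coefficients — so every
stage can be scored against known truth.

## Worked example

```python
from soarflight.synthetic import SimConfig, simulate_flight, simulate_soaring_dataset
from soarflight.classify import classify_track
from soarflight.stats import ModelSpec, dredge_average

fleet = simulate_flight(SimConfig(seed=1, n_birds=3, n_bursts_per_bird=10, burst_s=300))
segments = classify_track(fleet.track)
print(segments[0].behavior, segments[0].pattern, round(segments[0].climb_rate, 2))

table = simulate_soaring_dataset(SimConfig(seed=5), n_points=2000)
spec = ModelSpec("soaring", ["tailwind", "sidewind", "delta_T", "tailwind:delta_T"])
result = dredge_average(spec, table, kfold=10)
print(result.table.round(3))
```

prints (first line varies with the burst drawn; here a spiral-soaring burst
climbing at 0.81 m/s):

```
soaring spiral 0.81
                  estimate     se       z      p
(Intercept)         -0.138  0.165  -0.839  0.401
tailwind             1.681  0.101  16.711  0.000
sidewind             1.692  0.099  17.086  0.000
delta_T              2.149  0.118  18.207  0.000
tailwind:delta_T     1.739  0.123  14.085  0.000
```

i.e. the refit recovers the generating standardized coefficients
(1.51, 1.65, 1.97, 1.65) within two standard errors, with a 10-fold
predictive accuracy of 84%: both wind support and ΔT — and their
interaction — raise the odds of soaring over the sea.

The numbered drivers run the same stages as a narrative:

```
python analysis/01_simulate_fleet.py      # fleet + ground truth -> results/
python analysis/02_classify_behavior.py   # segments + confusion tables
python analysis/03_annotate_weather.py    # synthetic reanalysis grid + wind support/ΔT
python analysis/04_crossings.py           # crossing events + departure records
python analysis/05_fit_models.py          # GLMM families, averaged coefficients
```

A thin CLI mirrors the stages (`soarflight simulate|classify|annotate|crossings|fit`).

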