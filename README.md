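# newtflow

Ecohydrological flow-threshold modelling for Mediterranean headwater
catchments — built around the habitat question of the Montseny brook newt
(*Calotriton arnoldi*), a critically endangered amphibian confined to a few
forest headwater streams in NE Spain. The newt needs permanently flowing
water: prolonged low flows dry out its reaches, and sudden spates wash
larvae and adults downstream ("catastrophic drift"). `newtflow` provides
the full computational chain for asking how climate and vegetation-cover
change alter the frequency and duration of both kinds of events.

The package is aimed at catchment hydrologists and conservation ecologists
who want a transparent, fully scriptable version of this workflow:

1. **Bucket rainfall–runoff model** (`newtflow.buckets`) — a daily,
   semi-distributed conceptual model. Each landscape unit (holm oak,
   beech, heathland) is a quick → soil → groundwater reservoir cascade;
   catchment streamflow is the cover-fraction-weighted sum
   `Q(t) = Σ_u f_u · q_u(t)`. Degree-day PET with a soil-moisture power
   limitation `AET = PET · min(1, V_s/FC)^γ`, field-capacity overflow
   drainage, discrete linear-reservoir outflows, optional degree-day snow.
2. **Monte-Carlo calibration** (`newtflow.calibrate`) — uniform sampling in
   parameter ranges, iterated with ranges shrinking toward the running
   elite; candidates ranked by a composite of NS, log-NS, |RVD|,
   |1 − VAR| and "soft" ecological event-count penalties.
3. **Sensitivity analysis** (`newtflow.sensitivity`) — per-parameter
   one-sample Kolmogorov–Smirnov tests of the elite samples against the
   rectangular sampling distribution, Bonferroni-corrected.
4. **Flow-event statistics** (`newtflow.events`) — days and
   consecutive-day events below the low-flow threshold `Q_low`
   (0.33 L/s), single-day spates above the 99th-percentile day-over-day
   increases `Q_diff-all` / `Q_diff-dry` (97 / 42 L/s), flow-duration
   curves, seasonal breakdowns, threshold-robustness correlations, and the
   precipitation→streamflow lag.
5. **Scenario engine** (`newtflow.scenarios`) — the four vegetation
   storylines (as-present, beech-increased, heathland-protected, full holm
   oak) crossed with 2 future periods × 2 emission pathways, all run with
   the single calibrated parameter set and fixed reference thresholds.
6. **Variance partitioning** (`newtflow.anova`) — a main-effects three-way
   ANOVA expressing each factor's share as `SS_factor / SS_total`.
7. **Synthetic data** (`newtflow.synth`) — seeded Mediterranean weather
   generation, delta-change future forcings, and truth-model "observed"
   records with noise and gaps, so the whole pipeline runs without any
   external dataset.

## Worked example

Generate six years of synthetic weather for a 2 km² catchment, simulate,
and summarise the ecological flow events:

```python
import newtflow as nf

catchment = nf.montseny_reference_catchment()   # 52.2 / 15.1 / 32.7 % covers
forcing = nf.generate_weather(nf.WeatherConfig(), years=6, seed=7)
result = nf.simulate(forcing, catchment, nf.ParameterSet(), spinup_days=365)

print(f"balance closure {result.balance_closure():.2e} mm")
summary = nf.summarize_events(result.streamflow, nf.ThresholdSpec(area_km2=2.0))
print(f"annual flow {summary.annual_q:.0f} mm/yr")
print(f"{summary.days_below} days below 0.33 L/s in {summary.events_below} events")
print(f"{summary.events_above_all} spates above 97 L/s, "
      f"{summary.events_above_dry} dry-season spates above 42 L/s")
```

This prints:

```
balance closure 5.97e-12 mm
annual flow 306 mm/yr
207 days below 0.33 L/s in 4 events
2 spates above 97 L/s, 2 dry-season spates above 42 L/s
```

Water in equals water out to numerical precision; the synthetic catchment
yields ~300 mm/yr of runoff from ~1,000 mm/yr of rain (the rest is
evapotranspiration) and spends about 11 % of its days below the habitat
threshold in a handful of long dry spells — a flashy
subhumid-Mediterranean regime dominated by summer low flow.

The variance partition of the bundled published scenario table:

```python
from newtflow.anova import main_effects_anova
from newtflow.datasets import published_anova_input

print(main_effects_anova(published_anova_input("qlow_days")).rounded())
# {'period': 21, 'climate': 11, 'vegetation': 50, 'model': 82, 'residual': 18}
```

— vegetation-cover change explains half of the variation in future
low-flow days, more than period and climate pathway combined.

The same stages are available from a shell:

```sh
newtflow synth --mode weather --years 6 --seed 7 --out-dir wx/
newtflow simulate --forcing wx/weather_T.csv,wx/weather_P.csv \
    --params params.cfg --catchment catchment.cfg --out q.csv
newtflow events --q q.csv --thresholds thresholds.cfg --out-dir events/
```

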