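# birchphen

Evaluation machinery for birch-pollen forecasts: a degree-day flowering
phenology model with observation-fitted threshold maps, cumulative-percentage
pollen-season definition, station completeness quality control, seasonal
renormalisation, and categorical skill verification — plus a synthetic-data
generator that provides gridded meteorology and station observations with a
known ground truth, so every stage can be validated as a parameter-recovery
problem.

It is aimed at aerobiologists and air-quality modellers who need to fit
flowering-start thresholds from phenological or pollen-count networks and to
score pollen forecasts against daily station counts.

## The model

Flowering at a location starts when the temperature sum

```
S(d) = Σ_{t = 1 March}^{d} max(T̄_t − T_c, 0),      T_c = 3.5 °C
```

(daily-mean temperature `T̄` in °C, `S` in degree-days, dd) first reaches a
local threshold. Threshold maps are fitted three ways:

* **LU** — at each phenology station, the heat sum accumulated up to the
  reported leaf-unfolding date (a proxy for first flowering);
* **OBS** — at each pollen station, the heat sum at the season-start date,
  defined as the first day the cumulative pollen count reaches 2.5 % (or
  5 %) of the seasonal sum; the season end uses the 95 % criterion;
* **COMB** — LU in the north (where long-range transport contaminates early
  counts and biases OBS thresholds low), OBS elsewhere where available.

Station values are gridded by inverse-distance weighting. Forecast skill for
exceedance of the allergenic level (50 grains m⁻³) is scored from the
contingency table `N_xy` (model class x, observed class y; low/high):

```
MA  = (N_ll + N_hh) / N_total         HR  = N_hh / (N_hl + N_hh)
FAR = N_hl / (N_hl + N_hh)            POFD = N_hl / (N_hl + N_ll)
OR  = HR / POFD
```

Note `HR` here shares its denominator with `FAR` (so `HR + FAR = 1` whenever
the model predicts a high day); the conventional POD with the observed-high
denominator is reported separately as `pod_standard`.

## Worked example

```python
import numpy as np
import pandas as pd
import birchphen as bp
from birchphen.synthetic import snap_thresholds

grid = bp.GridSpec(50, 60, 10, 20, resolution=0.5)
scenario = bp.SimulationScenario(seed=1)        # spring trend + noise defaults
dates = pd.date_range("2006-03-01", "2006-06-30", freq="D")

temps = bp.gen_temperature(scenario, grid, dates)
truth = snap_thresholds(temps, bp.gen_truth_threshold(grid))
stations = bp.gen_station_locations(grid, 40, seed=2)
records = bp.gen_leaf_unfolding(temps, truth, stations, date_noise_sd=1.0, seed=3)
pollen = bp.gen_pollen_series(temps, truth, scenario, stations)

model = bp.FloweringModel(temps, leaf_unfolding=records, pollen=pollen)
res = model.fit("comb")
print(res.summary())
```

```
Flowering threshold fit
===============================================
method                                     COMB
stations fitted                              80
grid cells defined                          400
cut-off temperature (degC)                 3.50
threshold mean (dd)                      151.70
threshold sd (dd)                          4.33
threshold range (dd)              139.5 - 167.3
start-date bias (days)                    -4.10
start-date RMSE (days)                     4.24
stations compared                            40
===============================================
```

The fitted thresholds sit around 150 dd (the synthetic truth increases with
latitude); the negative bias says the predicted flowering start runs about
four days late on average against the observed proxies — here a consequence
of the ±2 °C day-to-day temperature noise and the 1-day date noise, not of a
model error. Scoring the noisy observations against the noise-free signal:

```python
obs = np.concatenate([s.conc for s in pollen])
clean = scenario.with_(obs_noise_sigma=0.0, missing_frac=0.0, lrt_spike_prob=0.0)
mod = np.concatenate(
    [s.conc for s in bp.gen_pollen_series(temps, truth, clean, stations)]
)
print(bp.skill_scores(bp.contingency(obs, mod)).to_dict())
# {'ma': 0.991, 'hr': 1.0, 'far': 0.0, 'pofd': 0.0,
#  'odds_ratio': inf, 'pod_standard': 0.957, 'n_total': 4668}
```

With the model equal to the generating signal, 99 % of the 4,668 valid
station-days fall on the contingency diagonal and no high day is falsely
alarmed; the lognormal observation noise alone accounts for the 4 % of
observed-high days the signal misses (`pod_standard`).

A `birchphen` console script exposes the same pipeline on files
(`fit-thresholds`, `season`, `qc`, `verify`); see `birchphen --help`.

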