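# Methods

## Degree-day phenology

The developmental clock is the classical temperature sum: starting 1 March,
each day contributes `max(T̄_d − T_c, 0)` degree-days, with `T̄_d` the daily
mean of the supplied timesteps (3-hourly fields are averaged per calendar
day first) and cut-off `T_c = 3.5 °C`. Flowering starts on the first day the
cumulative sum *reaches* the local threshold (a `≥` comparison: attaining the
threshold counts as crossing). Leap years are handled through calendar
dates, not fixed day-of-year indices. The daily-mean form is the standard
degree-day formulation; accumulating 3-hourly `(T − T_c)⁺` terms instead
would differ only for days straddling the cut-off, so the daily statistic is
kept as the single supported form with the cut-off and start date exposed as
parameters (`HeatSumParams`).

A structural property worth stating explicitly: a constant temperature bias
`b` applied to days already above the cut-off shifts the heat sum by exactly
`b` per day — `Δ S = b × (#days above cut-off)` — so a 0.5 °C bias sustained
over a 60–100-day accumulation period amounts to 30–50 dd, the same order as
the thresholds themselves. This is why the pipeline's verification stage
treats the temperature bias of the driving meteorology as the dominant error
source for flowering-start prediction, and it is the analytic anchor the
acceptance script recomputes.

## Threshold fitting and identifiability

The LU fit evaluates the heat sum at a station's grid cell (nearest cell
centre; no sub-cell interpolation of temperature, consistent with a
0.25°-class grid) up to the reported leaf-unfolding date. The OBS fit first
dates the season start with the cumulative 2.5 % criterion, then evaluates
the heat sum there. Station values are spread to the grid by
inverse-distance weighting with power 2 and a 5° search radius (Euclidean in
degrees); both are configuration knobs, not scientific claims — a cell
coinciding with a station reproduces the station value exactly, cells with
no station in radius stay undefined. The COMB map takes LU in cells labelled
"north" by the region mask (default: a latitude split at 60° N) and OBS
elsewhere where defined, falling back to LU.

Because accumulation is daily, a threshold is identifiable only up to the
heat-sum lattice: every value between two consecutive daily sums yields the
same crossing day, and fitting at the crossing day returns the attained sum,
which can exceed the nominal threshold by up to one daily increment (a few
per cent). The synthetic module therefore provides `snap_thresholds`, which
replaces each ground-truth value by the sum attained on its crossing day.
Recovery tests compare against the snapped truth — the quantity that is
actually identifiable — while `gen_truth_threshold` keeps the smooth linear
map for constructing scenarios.

## Season definition

Season start is the earliest day the cumulative count reaches the start
fraction (2.5 % default; 5 % available as a stricter filter against
long-range-transport spikes) of the window total, season end the 95 % day.
The "annual sum" is operationalised as the sum over the analysis window
(default 1 March – 30 June), which dominates the true annual total for
birch. Missing days contribute zero to cumulative sums — no gap-filling —
which is a known limitation: a station missing its peak days will date the
season late. Because the criteria are fractions, all season dates are
invariant under rescaling of the series. Stations whose 95 % date falls on
the window edge are flagged with a warning (the true end may be censored);
date statistics use bias = mean(observed − predicted), so positive bias
means the prediction runs too early.

## Station quality control

Four rules: (A) ≥ 45 observed days in April–May (≈75 % of the 61-day
period; days *observed*, not days with non-zero counts); (B) April
reporting at least as complete as March; (C) for every model run, an
observation on ≥ 80 % of the days that run predicts non-zero pollen at the
station; and a relaxation waiving C when any single run has at most one
predicted non-zero day without an observation. Rule B is implemented on
monthly completeness fractions (observed days over calendar days of the
month within the window) rather than raw counts: raw counts would fail a
station that reports every single day, because March is one day longer than
April, which cannot be the intent of a homogeneity requirement. A
"model-non-zero day" is one with predicted concentration at or above the
zero-class bound (1 grain m⁻³), which avoids float-noise sensitivity at
exactly zero. Failing stations list every violated rule. Note that adding
March observations can legitimately demote a station through rule B; the
monotonicity property (more data never hurts) holds only for additions from
April onwards.

## Verification

Five concentration classes (zero < 1, low 1–10, moderate 10–100, high
100–1,000, very high ≥ 1,000 grains m⁻³) with boundary values assigned
upward, consistent with "less than 1" defining the zero class. Exceedance
uses 50 grains m⁻³ — the centre of the classification — with "high"
implemented as ≥ 50 (a deterministic rule is needed where equality is left
open). Scores with an empty denominator are flagged `None` rather than
raised, so batch evaluation never aborts; the odds ratio is `inf` when
POFD = 0 with a positive hit rate. The hit rate deliberately uses the
model-high denominator, making HR + FAR ≡ 1; the conventional POD
(observed-high denominator) is exposed as `pod_standard` with no claim about
which convention any particular published figure used. The odds ratio is the
likelihood-style HR/POFD, not the cross-product `(N_hh·N_ll)/(N_hl·N_lh)`.
Coarse 3-class matrices (confusion vs observations including a no-data
column; setup-agreement between two model runs) are row-normalised.
Renormalisation computes one common factor — network-mean observed over
network-mean modelled cumulative count up to 31 May — and rescales all model
series, compensating for unmodelled inter-annual pollen production.

## The synthetic world

The generator emulates the statistical structure of the real inputs, not
their geography:

* **Temperature** — linear spring warming with a meridional gradient:
  `base_temp + warming_rate·(days since 1 March) + lat_gradient·(φ − φ_ref)
  + bias + N(0, noise_sd²)`. Defaults: 5 °C at 55° N on 1 March, 0.15 °C/day
  warming (≈9 °C over spring), −0.5 °C per degree latitude, 2 °C day-to-day
  noise — values a spring temperature climatology over a North-European
  domain would justify.
* **Truth thresholds** — linear in latitude, 100 dd at 45° N rising
  2 dd/degree northwards (floored at 1 dd), i.e. 120–130 dd over the default
  50–60° N domain, the order of magnitude of fitted birch heat sums at a
  3.5 °C cut-off.
* **Leaf unfolding** — the exact crossing day plus rounded Gaussian date
  noise, clamped inside the accumulation window; missing where the
  threshold is never reached.
* **Pollen** — zero before the local crossing, then a raised-cosine (Hann)
  pulse of `season_length` = 30 days peaking at 2,000 grains m⁻³ (sum
  exactly `peak·L/2`); pre-season days carry LRT spikes of 30 grains m⁻³
  with probability 0.1 per day, strictly before the local start;
  multiplicative lognormal observation noise (σ = 0.3) and i.i.d. Bernoulli
  missingness (5 %, with an optional March-only surcharge for exercising the
  QC homogeneity rule). The pulse shape is a smoothness choice, not an
  emission model; no transport between stations is simulated — LRT is a
  stochastic stand-in. The lognormal noise scale is a free parameter: the
  counting-uncertainty literature gives no distribution, and concentrations
  being positive with level-proportional error makes multiplicative
  lognormal the natural family.

Each noise source (temperature noise, date noise, spikes, observation noise,
missingness) draws from its own seeded sub-stream, so toggling one leaves
the others bit-identical — the property the QC and verification tests rely
on when they pair noisy observations with the noise-free signal.

What passing recovery tests shows — and what it does not: with noise off,
the pipeline inverts the generator exactly (thresholds to 1e-9 at station
cells, dates exactly, MA = 1/FAR = 0 for the perfect forecast), and with
2-day date noise the refit start-date RMSE matches the rounded-Gaussian
expectation (≈2.0 days). Real networks add everything the generator omits:
spatially correlated weather, non-Gaussian phenological error, transported
pollen that is not a simple pre-season spike, and reporting gaps that are
anything but independent. Recovery here validates the machinery, not the
model's skill on real data.

## Problem sizes and numerics

The default test domain is 20×20 cells at 0.5° with a 122-day daily window;
recovery suites use 100 stations (500 for the noisy-date experiment), sizes
at which every stage runs in seconds while keeping Monte-Carlo error well
inside the asserted bands. Date arithmetic is in whole days; cumulative
criteria and crossings use `≥`; IDW treats a distance below 1e-9° as
coincident. Degenerate inputs raise (`ValueError`) where a result would be
meaningless — all-zero pollen windows, empty networks, unreachable
accumulation windows — and are flagged values where batch processing must
continue (undefined skill scores, censored season ends, unreachable
thresholds in start maps).
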