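# Methods

## Model overview

`oaburden` estimates the lifetime quality-adjusted life-year (QALY) burden of
knee osteoarthritis (OA) in an adult population with a Monte Carlo
microsimulation in the osteoarthritis-policy-model tradition. The population
enters at baseline in 36 strata — nine 5-year age bands (40–44 … 80–84) ×
sex × ethnicity (Māori / non-Māori) — and each stratum is simulated as two
closed cohorts, one with prevalent knee OA and one without. Individuals pass
through annual cycles until death or the life-table closure age; each year
contributes one age- and pain-specific utility to the individual's QALY
total. Burden quantities are differences of cohort quality-adjusted life
expectancies (QALE), weighted and scaled by prevalence and population
counts. The model is a natural-history model: no treatment, no incident OA
in the comparator cohort, no structural/radiographic progression, and no
discounting (the target quantity is disease burden, not a cost-effectiveness
ratio).

## Pain and utilities

Knee pain is tracked on the WOMAC pain scale (0–100, 100 worst). OA cohorts
initialise WOMAC ~ Normal(30, 15) and add Normal(0.5, 5) each subsequent
year; draws are clamped to [0, 100] rather than resampled, so the nominal
mean/SD are preserved as parameters while scores stay valid (at these
parameters clamping shifts the initial mean by well under 0.05 points).
Scores collapse to three severity states — none (WOMAC < 1), moderate
([1, 70]), severe (> 70), both boundary values read as stated — and each
(5-year age band, state) maps to an EQ-5D utility (dead = 0, full health
= 1). The packaged utility table is VAS-valued; for every band the ordering
u(none) ≥ u(moderate) ≥ u(severe) is validated on construction. People
without knee OA are not pain-free: an age-specific share of them (a
configurable logistic-in-age curve, deliberately on the high side — about a
third of 40-year-olds rising to ~60% at 84) is in pain from other causes,
split 90/10 between moderate and severe by default. That level is drawn
once per 5-year band of occupancy, not annually: the data behind it are a
population distribution, and per-band persistence tracks age trends without
imposing artificial year-to-year churn.

An alternative value set approximates trade-off (standard-gamble-like)
valuations by the power transform u' = 1 − (1 − u)^α with α = 1.61 by
default and fully overridable from file. The transform is monotone
increasing and maps [0, 1] to itself, so the severity ordering is
preserved; for α > 1 it compresses utilities toward 1, which narrows the
utility gaps between typical OA and non-OA states and therefore shrinks the
attributable loss. (The none→moderate gap shrinks in every band; the
none→severe gap need not, because the transform's slope exceeds 1 at low
utilities — the loss reduction comes from the states that dominate the
comparison.) Ages beyond the last tabulated band (80–84) carry that row
forward, the minimal assumption for survivors past 84.

## Mortality

Mortality enters as 5-year death probabilities per (ethnicity, sex, age
band), annualised by the constant-hazard-within-band conversion
q₁ = 1 − (1 − q₅)^(1/5) — standard actuarial practice, and exactly
invertible, which the tests exploit. A person accrues the full year's
utility for each year begun; death is applied at year end (no half-cycle
correction). The life table extends past the entry bands to a closure age
(default 110) where death is certain: the year ending at the closure age is
the last possible one, so survival reaches exactly zero there and every
simulated lifetime is finite and bounded by closure − start.

## Synthetic inputs

National life tables, census counts and the background-pain curve are input
data the analysis consumes, not methods; the generators emulate their
structure so the full pipeline runs self-contained:

* **Life table** — Gompertz hazard h(t) = λ·e^{0.09 t} integrated over each
  band. Group-specific λ defaults (non-Māori male 4.5e-5, female 3.0e-5;
  Māori male 8.0e-5, female 5.5e-5) were chosen once to land remaining life
  expectancy at 40 near national values (≈ 39/43 years non-Māori male/
  female, ≈ 33/37 Māori), reproducing the orderings that drive the group
  differences in losses: female > male, non-Māori > Māori.
* **Population counts** — geometric thinning across age bands
  (decay 0.85/band), female share 0.51, Māori share 0.11, total 1.8 million
  (roughly the adult 40–84 population at the 2006 baseline). Fractional
  expected counts are rounded half-to-even for determinism.
* **Prevalence** — the packaged fixture is the published PPV-adjusted
  surface; a generator (base × slope^band, clipped to [0, 1]) supplies
  synthetic surfaces for property tests.

Generation is deterministic given parameters; `seed` arguments exist for
interface uniformity and future stochastic extensions. What the generators
do **not** emulate: cohort effects and period shocks in mortality, ethnic
differences in background pain, within-band age structure, and prevalence
measurement error. Tests passing on these inputs validate the *mechanics*
(accounting identities, monotonicities, convergence to analytic
expectations), not the absolute published magnitudes, which depend on
unpublished national inputs.

## Burden accounting

For each sex × ethnicity group, the age distribution of prevalent cases is
w(band) ∝ prevalence(band) × population(band). The counterfactual QALE of
the OA sub-population is the no-OA QALE weighted by w; per-person loss is
counterfactual minus OA QALE; population loss multiplies by the number of
prevalent cases. Group totals weight the OA and counterfactual QALE columns
by w and the no-OA column by the whole group population, so the identity
loss = counterfactual − OA QALE and loss × cases = population loss hold at
every aggregation level, and the grand total equals the sum of group
totals. Band-level per-person losses are independent of prevalence by
construction (prevalence only enters weights and case counts).

PPV adjustment for self-report bias is multiplicative: adjusted = raw ×
PPV, with PPV a scalar (default 0.9, near the middle of the published
false-positive range of 0–19.3%) or a per-group mapping. A consequence
worth stating: with a *uniform* PPV, switching to unadjusted prevalence
rescales every group's case counts by 1/PPV without moving the age weights,
so per-person losses are exactly unchanged and only population totals grow.
Reproducing a per-person shift under unadjusted prevalence requires PPVs
that vary across strata, which users can supply as a mapping.

## Randomness and common random numbers

All randomness derives from one master seed. Each cohort's generator is
keyed by (seed, stratum index, start age) and draws its arrays in a fixed
order — mortality uniforms, baseline WOMAC, annual increments, per-band
pain uniforms — *regardless* of OA status or pain-split parameters. Paired
OA/no-OA cohorts therefore share mortality histories, sensitivity re-runs
share all noise, and results are independent of the order strata are
simulated in. The background pain level is derived from its uniform by
cumulative thresholds ordered none < moderate < severe, so raising the
moderate share can only move individuals from severe to moderate — the
monotonicity the PSA relies on. Cohorts start at their band's midpoint age
(lower bound + 2), the representative age for a 5-year entry band.

## Sensitivity analysis

The PSA redraws the moderate-pain share from a uniform prior (default
U(0.80, 1.00)) and re-runs the burden pipeline per draw. Only the no-OA
cohorts depend on that parameter, so the OA cohorts are simulated once and
reused. Uncertainty intervals are central empirical quantiles of the
per-draw losses with linear interpolation of order statistics (numpy's
default, "type 7"). With common random numbers a degenerate prior
reproduces the base case exactly, and the interval from the default prior
brackets the base case. The PSA defaults to smaller cohorts
(`n_per_stratum` override) since parameter spread, not Monte Carlo
precision, is the object.

## Numerical choices and problem sizes

* Base-case cohort size 2,000 per stratum (Monte Carlo SE on group-level
  QALE ≈ 0.05 QALYs); analytic-oracle comparisons use 20,000; PSA uses 250
  per stratum × 200 draws. These sizes keep a full run in tens of seconds
  while leaving all assertions far from their noise floors.
* CSV round-trips write doubles with `%.17g` and parse them with Python's
  float parser, so write→read is bit-identical; outputs use LF endings and
  no timestamps, making same-seed runs byte-identical.
* Age-band labels are canonicalised to the en-dash form ("40–44"); readers
  accept hyphen and em-dash variants and UTF-8 BOM/CRLF dialects.
* Printed-table comparisons use ±0.01, the display precision of the
  published tables.

## Known limitations

* The comparator cohort never develops incident knee OA; the estimate is
  the burden of *prevalent* disease in a closed 2006-baseline population.
* BMI and other covariates are not modelled; the published model collects
  BMI but no effect pathway is specified here.
* The background-pain curve and the transform exponent are placeholders for
  appendix-level inputs; both are fully configurable and should be
  overridden when the source values are available.
* Pain affects utility but not mortality; any excess mortality associated
  with OA severity is outside the model.
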