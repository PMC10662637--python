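# Methods

## Model structure

`savm` is a deterministic, cohort-based, discrete-time (annual) simulation.
Each single-age, single-gender cohort is described by its occupancy shares
over tobacco/nicotine use states; cohorts are independent of one another.
Two scenarios are run on identical demographic inputs:

* the **counterfactual** (no vaping products): states *never smoker,
  current smoker, former smoker, former smoker (low risk)*; flows are
  smoking initiation (never → current) and net cessation (current →
  former), with cessation already discounted for relapse, so former states
  are absorbing;
* the **vaping scenario**: five additional states (*exclusive NVP user,
  NVP-using ex-smoker (low risk), former smoker who vapes, former NVP user,
  former NVP ex-smoker*) and five flows — smoking initiation, NVP
  initiation, smoking cessation, NVP cessation, and switching from smoking
  to exclusive NVP use. Dual users are treated as current smokers.

**Quit-before-35 rule.** A smoker who quits, or switches to vaping, with
attained age 34 or below enters a *low-risk* substate with never-smoker
baseline mortality; quitting or switching at 35+ retains the former-smoker
(or switcher) excess. At initialisation, former smokers younger than 35
necessarily quit before 35 and are therefore assigned to the low-risk
substate; the initial former pool at 35+ is assigned the full former-smoker
excess (a simplification — some of them will in fact have quit young, which
slightly overstates counterfactual mortality identically in both scenarios).

**Within-year order of operations.** (1) each state's share is multiplied
by its survival 1 − μ_s; (2) transition probabilities act on survivors;
(3) shares are renormalised to sum to one. Deaths are thereby attributed to
the state held at the start of the year, consistent with the
attributable-death formula, which uses start-of-year occupancy. The order
is a modeling choice (the alternative, transitions before survival, is not
exposed as an option; the renormalisation step is, see below).

**Shares evolve, counts come from the projection.** The population
projection already embodies total mortality, so the engine evolves the
*composition* (shares) and multiplies by projected headcounts, avoiding
double-counting deaths; differential mortality still reshapes composition
through the survival step. `renormalize=False` disables step (3), leaving
survival attrition in the shares, for users who prefer to evolve absolute
cohort sizes independently of the projection.

**New entrants.** Cohorts enter at the minimum modeled age (default 18)
each year with the base-year entry-age state distribution. In the vaping
scenario (from the introduction year on) the entry distribution is
re-weighted: the base-year current-smoker share at the entry age is treated
as the outcome of pre-entry initiation, so it is multiplied by the smoking
initiation multiplier, an NVP-user share of (NVP multiplier × that share)
is added, and never use absorbs the remainder. This is a documented
approximation for an 18+ model whose initiation largely happens before
entry; it errs toward applying the scenario's initiation contrast to
pre-entry behaviour as well.

## State mortality and attributable outcomes

With μ_n, μ_c, μ_f the never/current/former-smoker mortality rates and
exc_c = μ_c − μ_n, exc_f = μ_f − μ_n, the excess mortality per state is

| state                         | excess                      |
|-------------------------------|-----------------------------|
| never smoker                  | 0                           |
| current smoker (incl. dual)   | exc_c                       |
| former smoker                 | exc_f                       |
| former smoker, low risk       | 0                           |
| exclusive NVP user            | rr · exc_c                  |
| NVP-using ex-smoker, low risk | rr · exc_c                  |
| former smoker who vapes       | exc_f + rr · exc_c          |
| former NVP user               | rr · exc_f                  |
| former NVP ex-smoker          | exc_f + rr · exc_f          |

where *rr* is the NVP relative-risk multiplier (default 0.05). Each state's
mortality is μ_n plus its excess, used both for within-year survival and
for the outcome computation. The composition for former smokers who vape
(and their former-user counterpart) is genuinely open — evidence on
combined histories is lacking — so the additive choice above is a
configuration (`fsnvp_excess_mode="additive"`); `"nvp_only"` drops the
former-smoker term.

Attributable deaths are Σ_s excess_s × count_s per (age, gender, year);
life-years lost weight each death by a never smoker's remaining life
expectancy at that age. The net impact is the counterfactual-minus-vaping
difference; negative values (vaping harmful on net) are never clamped.
Reported prevalences are population-weighted over the modeled adult ages.

## Country adaptation

Reference (US-style) rates are rescaled to the target country:

* **initiation/cessation**: multiplied per gender by the country/reference
  base-year current-smoking prevalence ratio over ages 18–24 (initiation)
  and 25–64 (cessation), applied at all ages and years. Band prevalence is
  a population-weighted mean (the country's base-year population weights
  both series, since it is the only population in the inputs; an unweighted
  mean is available via `weighted_band_prevalence=False`). Scaled rates
  above 1 are clipped with a logged warning rather than erroring, since
  ratio scaling can overshoot for extreme countries.
* **mortality by smoking status**: multiplied cell-by-cell by the
  country/reference overall-mortality ratio. The ratio is applied to the
  full rate, not the excess; the common ratio preserves the ordering
  current ≥ former ≥ never, which is re-checked.
* **never-smoker life expectancy**: the reference schedule times the
  age/gender-specific country/reference overall life-expectancy ratio,
  computed once at the base year and held constant over the period.

**Grouped inputs.** Grouped mortality is expanded uniformly (each age in a
group takes the group value). Grouped survey prevalence is smoothed:
each group's value is anchored at its midpoint floor((lo+hi)/2) — which
gives 23 for an 18–29 group and 82 for 65–99 — with piecewise-linear
interpolation between midpoints and flat extension below the first and
above the last midpoint. Linear interpolation was chosen because it is
simple, monotone-preserving, and reproduces the stated boundary behaviour;
the smoothing function is a seam where users can substitute splines. The
flat extension beyond the outermost midpoints is a generalisation from the
known boundary instances, not a claim about any particular country.

## Vaping-scenario schedule

Smoking/NVP initiation in the vaping scenario are multiples (defaults
0.88 / 0.25) of the counterfactual smoking initiation rate; smoking/NVP
cessation are multiples (both 1.0) of the counterfactual cessation rate.
Switching comes from a pre-loaded grouped schedule (male 4.0%/yr under 25
down to 0.6% at 65+, female 2.5% down to 1.0%), scaled (default 0.50) and
decayed exponentially (factor 0.90/yr from 2018). The decay applies to
switching by default; every multiplier accepts an optional annual-change
factor through `ScenarioParams.annual_change` for users who want
time-varying initiation or cessation multipliers. Flows are annual
transition probabilities applied in a defined order, not competing hazards;
a feasibility check requires competing outflows of each state to sum to at
most 1. Before the NVP introduction year the NVP-specific flows are zero
and the smoking flows equal the counterfactual rates, so the scenario
coincides exactly with the counterfactual there.

Whether the pre-loaded switching values are quoted before or after the 50%
country adjustment is ambiguous in the source material; the schedule and
the scale are therefore independent configuration fields so either reading
is expressible.

## Synthetic inputs

The generator (`savm.synthetic`) produces a complete country + reference
bundle pair with no downloads, emulating the real inputs' qualitative
features: Gompertz baseline mortality (2.5·10⁻⁴ at age 18 doubling every
~8 years, female 28% below male), constant relative risks 2.5
(current/never) and 1.4 (former/never), initiation concentrated at young
adult ages (4.5%/yr at 18, e-folding width 5 years), cessation rising with
age from 2%/yr, smooth prevalence curves anchored at published 2012 German
(country) and US-like (reference) survey group values, and life
expectancies computed from the generated mortality by period life table so
all tables are internally consistent. The country sits 5% above the
reference in overall mortality so every rescaling operation is exercised
nontrivially. The population is a smooth pyramid (≈500,000 per single age
at entry) with a small seeded log-normal jitter; totals drift down 0.1%/yr.

What the fixture does **not** emulate: birth-cohort trends in initiation
and cessation, time-varying relative risks, migration, and the age-specific
irregularities of real survey data. Tests passing on these fixtures
demonstrate the correctness of the mechanics (scaling, bookkeeping,
monotonicities, conservation), not the realism of any projection; headline
synthetic numbers (e.g. ~268,000 deaths averted, 1.6% of counterfactual
deaths, under the default configuration at seed 1) characterise the
fixture, not Germany.

## Microsimulation oracle

`microsim_oracle` follows one single-age, single-gender cohort of
individual agents (≥1000; typically 10⁵–10⁶) through the identical
survival → transition rules with pseudo-random draws, for at most 15 years.
Initial states are allocated deterministically in proportion to the exact
initial distribution, so all Monte-Carlo noise comes from the dynamics
being checked. Because agents are i.i.d., the state distribution among
survivors is binomial around the cohort engine's renormalised shares, and
the engine is required to agree within three binomial standard errors at
every state and year; the acceptance checks run five random cohorts of 10⁶
agents over ten years.

## Numerical choices and degenerate inputs

* Shares must sum to 1 within 1e-9 at every index; counts match the
  projection to 1e-6 relative (exact by construction in the default mode).
* Renormalisation divides by the survivor total and leaves a cell at zero
  if the total is zero (only possible if every state's mortality is 1).
* A one-year horizon returns the initial occupancy only.
* Rates outside [0,1], violated share sums, negative excess mortality,
  uncovered ages/years, and infeasible competing flows raise typed errors
  (`DataError`, `CoverageError`, `SchemaError`, `FeasibilityError`).
* The equality checks on scenario coincidence are exact (bitwise): the
  null configuration (switch scale 0, NVP initiation 0, multipliers 1)
  takes code paths that multiply by 1.0 and add 0.0 only.

## Problem sizes in tests

Unit tests run on a reduced synthetic configuration (ages 18–70,
2012–2027); integration and acceptance-style checks run the full preset
(ages 18–99, 2012–2060, ≈8,000 age-gender-year cells per scenario) and the
full 10⁶-agent oracle comparisons. The complete suite and the acceptance
script each finish in seconds on one CPU.

## Known limitations

* No individual-level heterogeneity, smoking intensity, or years-since-quit
  strata beyond the two former-smoker substates; no morbidity, costs, or
  discounting; heated tobacco products are out of scope.
* The counterfactual assumes pre-base-year smoking trends would have
  continued unchanged; the model is forward-only and performs no
  statistical calibration to survey data (validation is by relative-change
  comparison only).
* New-entrant behaviour at the minimum age is an approximation (above).
* The published-values module stores printed summary totals of the original
  Germany application for arithmetic-identity checking; small (±1 unit or
  0.1 percentage point) inconsistencies among those printed numbers are
  inherent to their rounding and are noted in the tests where relevant.
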