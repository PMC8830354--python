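# miadm — decision modelling for small unruptured multiple intracranial aneurysms

`miadm` is a Markov cohort (state-transition) model for the management of a
patient harbouring **two small (<7 mm) unruptured intracranial aneurysms**
(the simplest case of multiple intracranial aneurysms, MIAs).  It is aimed
at health-economics and clinical-effectiveness researchers who want a
transparent, scriptable implementation of the classic decision problem:
*coil prophylactically, follow with imaging, or do nothing?*

Six strategies are compared for a 57-year-old patient followed in annual
cycles to age 99:

1. **treat_two** — prophylactic endovascular coiling of both aneurysms
2. **treat_one** — coiling of one aneurysm, the other left in place
3. **follow_up_1y / follow_up_2y / follow_up_5y** — MRA surveillance at a
   1-, 2- or 5-year interval; a growing aneurysm is coiled on detection
4. **natural_history** — no intervention

## Model

Nine health states: well with both MIAs, well with a growing MIA, well with
a single growing aneurysm, well with one treated aneurysm, well with both
treated, SAH (subarachnoid hemorrhage, a one-cycle transient state), mild
disability (mRS 2), moderate-to-severe disability (mRS 3–5), and death.
Effectiveness is measured in discounted quality-adjusted life-years:

```
EV = Σ_t (1+r)^(−t) Σ_s  occ(t,s) · u(s) · (1 − d·coil(t,s))
```

with discount rate `r = 0.03`/year, utilities `u` = 1 (well), 0.64 (SAH),
0.72 (mild), 0.41 (moderate-severe), 0 (death), and a temporary procedure
disutility `d = 0.05` in the cycle a coiling occurs.  Annual event
probabilities: aneurysm growth 0.026 and rupture 0.005 (small non-growing,
single aneurysm), rupture 0.063 once grown, de novo formation 0.003; for an
MIA patient these are scaled by risk ratios 3.47 (growth), 2.08 (rupture)
and 3.92 (de novo).  Coiling outcomes (full recovery / mild /
moderate-severe / death) are 0.937/0.016/0.047/0 for one aneurysm,
0.904/0.032/0.053/0.011 for both, and 0.41/0.15/0.09/0.35 after SAH.
Disabled patients die at 2.02× (mild) or 4.46× (moderate-severe) background
mortality.  Background mortality is a Gompertz fixture anchored at
q(57) = 0.005 and q(85) = 0.08, with the small SAH-attributable share
removed (cause deletion) so rupture deaths are not counted twice.  Any
life table can be substituted as a CSV (`age,q`).

Parameter uncertainty follows the published table: beta distributions for
probabilities and lognormal for risk ratios (both moment-matched from the
published mean and SD) and triangular for utilities.  On top of the base
case the package provides Monte Carlo probabilistic sensitivity analysis
(PSA), tornado-style one-way sweeps with bisection threshold search, and
two-way optimal-strategy maps — all running on a vectorised engine that
propagates thousands of parameter sets through the cohort at once.

## Worked example

```python
from miadm import (load_base_parameters, build_fixture_table,
                   evaluate_strategies, rank_strategies,
                   run_psa, optimal_frequencies, threshold_search)

params = load_base_parameters()          # bundled published inputs
table = build_fixture_table()            # Gompertz mortality fixture

for sid, qalys in rank_strategies(evaluate_strategies(params, table)):
    print(f"{sid:16s} {qalys:.2f} QALYs")

psa = run_psa(params, table, n_iterations=10_000, seed=1)
print(optimal_frequencies(psa))
print(threshold_search("mortality_after_two", params, table))
```

prints

```
treat_two        16.75 QALYs
follow_up_1y     16.55 QALYs
treat_one        16.50 QALYs
follow_up_2y     16.49 QALYs
follow_up_5y     16.30 QALYs
natural_history  15.61 QALYs
{'treat_two': 61.29, 'treat_one': 16.02, 'follow_up_1y': 18.44,
 'follow_up_2y': 0.0, 'follow_up_5y': 0.0, 'natural_history': 4.25}
ThresholdResult(parameter='mortality_after_two', threshold=0.0217...,
                strategy_below='treat_two', strategy_above='treat_one', ...)
```

Treating both aneurysms yields the highest expected QALYs; it stays optimal
in about 61% of PSA iterations and beats treating one aneurysm in about
71%, but loses its lead once its procedural mortality exceeds ≈0.022.
Absolute QALY totals scale with the background life table (see
`docs/methods.md`); the strategy comparisons are far less sensitive to it.

The same analyses are available from the command line:

```bash
miadm -v base-case --out out/base.csv
miadm psa --iterations 10000 --seed 1 --out out/psa.csv
miadm tornado --out out/tornado.csv
miadm threshold modsev_after_two --out out/threshold.json
miadm two-way modsev_after_one modsev_after_two --out out/map.csv
miadm make-fixtures --out-dir fixtures/
```

## Layout

| module                 | contents                                              |
|------------------------|-------------------------------------------------------|
| `miadm.parameters`     | parameter table, moment matching, sampling            |
| `miadm.life_table`     | mortality table, Gompertz fixture, adjustments        |
| `miadm.strategies`     | the six strategies and the screening schedule         |
| `miadm.markov_engine`  | nine-state cohort engine and QALY accumulation        |
| `miadm.sensitivity`    | PSA, tornado, threshold bisection, two-way maps       |
| `miadm.synthetic_data` | synthetic treatment cohorts and the proportion estimator |
| `miadm.cli`            | `miadm` command-line interface and report writers     |
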