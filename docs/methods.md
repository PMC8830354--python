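# Methods note

This note records the model structure, parameter handling, synthetic-data
scope and the numerical conventions used by `miadm`, including the choices
made where the underlying clinical problem admits more than one reasonable
formalisation.

## 1. Decision problem and model structure

The model evaluates the management of a 57-year-old patient with two small
(<7 mm) unruptured intracranial aneurysms (a multiple-intracranial-aneurysm,
MIA, patient) over a lifetime horizon (ages 57–99, 43 annual cycles).
Six strategies are compared by discounted quality-adjusted life-years
(QALYs): coil both aneurysms now (`treat_two`), coil one (`treat_one`),
imaging follow-up every 1, 2 or 5 years with coiling of any aneurysm seen
to grow (`follow_up_1y/2y/5y`), and no intervention (`natural_history`).

The cohort moves through nine health states:

| state | description |
|---|---|
| `WELL_MIA` | well, both untreated aneurysms small and stable |
| `WELL_GROWING_MIA` | well, at least one untreated aneurysm has grown |
| `WELL_SINGLE_GROWING` | well, one aneurysm treated, the remaining one has grown |
| `WELL_ONE_TREATED` | well, one aneurysm coiled, one small untreated |
| `WELL_BOTH_TREATED` | well, no untreated aneurysm at risk |
| `SAH` | subarachnoid hemorrhage this cycle (one-cycle transient state) |
| `MILD_DISABILITY` | mRS 2 after a procedure or SAH |
| `MOD_SEVERE_DISABILITY` | mRS 3–5 |
| `DEATH` | absorbing |

### Event ordering within a cycle

Competing annual risks are composed sequentially, each conditional on
surviving the previous one:

1. background (other-cause) mortality,
2. aneurysm rupture → `SAH`,
3. aneurysm growth, and — under a follow-up strategy — detection and
   treatment of a detected growing aneurysm,
4. de novo aneurysm formation in patients whose aneurysms are all treated.

This multiplicative composition keeps every row of the transition matrix a
probability distribution for any admissible inputs and matches the common
"check mortality first" convention of annual-cycle cohort models.

### Treatment, SAH and disability

Coiling sends the patient through an outcome branch
(full recovery / mild disability / moderate-severe disability / death);
one-stage treatment of both aneurysms uses the two-aneurysm branch, all
other procedures the one-aneurysm branch.  `SAH` is a tunnel state: the
entire SAH cohort resolves in the next cycle through the SAH outcome
branch (death 0.35, moderate-severe 0.09, mild 0.15, full recovery 0.41);
survivors who fully recover are assumed secured (`WELL_BOTH_TREATED`),
since a ruptured aneurysm is treated.  Background mortality is not applied
in the SAH cycle itself, so acute SAH deaths are not double-counted.
Disability states are chronic: patients remain until death, dying at
2.02× (mild) or 4.46× (moderate-severe) background mortality, capped at 1.

Design choices on points the clinical description leaves open:

- **Post-treatment surveillance.** A patient with one treated and one
  growing aneurysm (`WELL_SINGLE_GROWING`) is under clinical care and is
  assumed detected and treated at the next annual cycle regardless of the
  strategy's screening interval.
- **De novo aneurysms** in fully treated patients are detected and coiled
  (one-aneurysm branch); full recovery returns the patient to the prior
  well state.
- **Screening timing.** Under a k-yearly follow-up strategy, growth that
  occurred by the transition into cycle t is detected (and treated) when
  `t > 0 and t % k == 0`.
- **Risk-ratio scope.** The MIA rupture risk ratio (2.08) multiplies the
  small-aneurysm rupture rate while two untreated aneurysms are present.
  The growing-aneurysm rupture rate (0.063) is treated as an absolute
  rate for a growing lesion and is not additionally scaled; a settings
  toggle (`rr_on_growing`) exposes the alternative.  Risk ratios are
  applied multiplicatively with the product clamped to 1
  (`hazard_transform=True` switches to a hazard-scale transform).

## 2. Parameters

All inputs live in `src/miadm/data/default_parameters.csv` and are loaded
into `ParameterSpec` objects (name, mean, low, high, distribution family,
SD).  Units: all rates are annual probabilities; risk ratios are unitless;
utilities are on the 0–1 dead–healthy scale.

| name | mean (low–high) | family | role |
|---|---|---|---|
| growth_rate_small | 0.026 (0.019–0.035) | beta | annual growth, small single aneurysm |
| rr_growth_mia | 3.47 (1.18–10.2) | lognormal | MIA growth risk ratio |
| rupture_rate_nongrowing | 0.005 (0.003–0.009) | beta | annual rupture, small non-growing |
| rupture_rate_growing | 0.063 (0.018–0.2) | beta | annual rupture once grown |
| rr_rupture_mia | 2.08 (1.46–2.96) | lognormal | MIA rupture risk ratio |
| de_novo_rate | 0.003 (0.0007–0.009) | beta | annual de novo formation |
| rr_de_novo_mia | 3.92 (1.29–11.9) | lognormal | MIA de novo risk ratio |
| mild_after_one | 0.016 (0–0.05) | beta | coil one: mRS 2 |
| modsev_after_one | 0.047 (0.01–0.1) | beta | coil one: mRS 3–5 |
| mortality_after_one | 0 (0–0.01) | beta | coil one: death |
| mild_after_two | 0.032 (0.005–0.08) | beta | coil two: mRS 2 |
| modsev_after_two | 0.053 (0.015–0.11) | beta | coil two: mRS 3–5 |
| mortality_after_two | 0.011 (0.001–0.04) | beta | coil two: death |
| mild_after_sah | 0.15 (0.08–0.25) | beta | SAH: mRS 2 |
| modsev_after_sah | 0.09 (0.04–0.16) | beta | SAH: mRS 3–5 |
| mortality_after_sah | 0.35 (0.25–0.45) | beta | SAH: death |
| rr_death_mild | 2.02 (1.5–2.7) | lognormal | mortality multiplier, mRS 2 |
| rr_death_modsev | 4.46 (3.1–6.4) | lognormal | mortality multiplier, mRS 3–5 |
| utility_mild / modsev / sah | 0.72 / 0.41 / 0.64 | triangular | state utilities |
| utility_full_recovery | 1 | fixed | well-state utility |

Model settings (`ModelSettings`): start age 57, horizon age 99, discount
rate 0.03/year, procedure disutility 0.05 (one cycle), SAH share of
background mortality 0.003 (cause deletion).

### Distributions and moment matching

- **Beta**: shape parameters from the mean m and SD s via
  ν = m(1−m)/s² − 1, α = mν, β = (1−m)ν.  A zero-mean probability
  (procedural mortality after coiling one aneurysm) has no beta
  counterpart; it is sampled with a small-mean surrogate (mean 5·10⁻⁴)
  so PSA draws remain strictly non-negative and essentially zero.
- **Lognormal** (risk ratios): σ² = ln(1 + s²/m²), μ = ln m − σ²/2, which
  matches the arithmetic mean and SD exactly.
- **Triangular** (utilities): parameterised by (low, mode, high) with the
  published value as the mode.
- Draws are *not* truncated to the published low–high range; the range is
  used only for one-way/tornado/threshold sweeps.

PSA draws all parameters jointly and independently.  Draws that make a
treatment outcome branch sum above 1 are renormalised and counted
(`PSAResult.n_renormalized`); at the published SDs this is rare.

## 3. Background mortality

No machine-readable national life table is bundled; instead a Gompertz
fixture q(x) = a·exp(b·x) is anchored at q(57) = 0.005 and q(85) = 0.08
(a ≈ 1.77·10⁻⁵, b ≈ 0.0990), consistent with contemporary Chinese census
mortality at those ages.  The SAH-attributable fraction (0.003) is removed
before use.  Absolute QALY totals are sensitive to this choice — the
fixture implies a discounted all-well annuity of 18.03 from age 57,
whereas a heavier-tailed empirical table would give a smaller one, shifting
every strategy down by a similar amount — but strategy differences,
rankings under perturbation, PSA frequencies and switch thresholds are
driven by the event and outcome parameters and are much less sensitive.
Users comparing against a specific population should pass their own table
(`MortalityTable.from_csv`, CLI `--life-table`).

## 4. Markov engine and numerical conventions

- **Vectorisation.** Every parameter may be a scalar or an (n,) array;
  the engine builds (n, 9, 9) transition matrices per cycle and propagates
  the whole batch with `einsum`.  A 10,000-iteration PSA over all six
  strategies runs in a few seconds.
- **Reward accrual** is cycle-start: the cohort entering cycle t accrues
  u·(1.03)^(−t) with t = 0 at model entry, no half-cycle correction.  In
  the no-event, no-mortality limit this gives the 43-term annuity
  Σ 1.03^(−t) = 24.70, which the test suite pins as a closed-form oracle.
- **Procedure disutility** is applied to the cohort fraction *arriving*
  in a state via coiling that cycle, tracked by a parallel flag matrix,
  as 0.05 × utility for one cycle.
- **Entry cycle.** Immediate-treatment strategies apply their outcome
  branch at entry (cycle 0), so e.g. `treat_two` starts with 0.011 of the
  cohort dead and the survivors carrying the one-off procedure disutility.
- **Tie-breaking.** Whenever an optimal strategy is reported (PSA argmax,
  two-way maps, threshold search) ties are broken by the fixed order
  `treat_two, treat_one, follow_up_1y, follow_up_2y, follow_up_5y,
  natural_history`.
- **Threshold search** brackets the first change of optimum with a
  64-point coarse scan of the published range, then bisects to the
  requested tolerance (default 10⁻⁴ of the parameter scale); the test
  suite cross-checks it against a dense-grid oracle.  Parameters whose
  sweep never changes the optimum report `threshold=None`.

## 5. Synthetic data

`miadm.synthetic_data` generates patient-level treatment registries for
testing estimation pipelines, not for inference.  Each record has age
(normal, mean 56, SD 10, clipped to 18–90), sex (65.5% female), number of
aneurysms treated (1 or 2), follow-up months (normal, mean 31, SD 23,
non-negative) and a categorical procedural outcome drawn from the model's
treatment branch for that arm.  `estimate_outcome_proportions` inverts the
generator: per-arm outcome proportions p = k/n with binomial
SD = √(p(1−p)/n).  Round-trip recovery at large n, the zero-risk edge
case, and the consistency of binomial SDs at registry-scale branch sizes
(129 one-aneurysm, 95 two-aneurysm patients) with the published SDs are
all covered by tests.  Limits: outcomes are i.i.d. draws — no covariate
effects, no censoring, no operator or centre effects — so the generator
supports method validation only.

## 6. Limitations

- Costs are out of scope; the model is effectiveness-only (QALYs).
- The two-aneurysm case is the simplest MIA configuration; patients with
  three or more aneurysms, large or posterior-circulation lesions are not
  represented.
- Aneurysm growth and rupture rates are age-invariant; only background
  mortality ages.
- Clipping of treated/untreated aneurysm counts to the nine-state space
  means re-rupture after coiling and retreatment are not modelled.
- Absolute QALY levels depend on the background life-table fixture
  (section 3); cross-population comparisons should substitute a local
  table.
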