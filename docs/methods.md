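# Methods

## Model structure

The analysis is a two-strategy decision analysis over a three-state,
time-inhomogeneous Markov cohort model.  A closed cohort starts 100% in
*retained on ART* and transitions once per one-year cycle:

| from \ to        | retained           | not retained        | dead  |
|------------------|--------------------|---------------------|-------|
| retained on ART  | remainder          | dropout (time-dep.) | $m_R$ |
| not retained     | 0 (no re-entry)    | remainder           | $m_N$ |
| dead             | 0                  | 0                   | 1     |

No age-specific background mortality table is layered on top: the state
mortalities are taken as total annual death probabilities, and age enters
only through the horizon (below).

### Parameters

| parameter | default | units | note |
|---|---|---|---|
| horizon | 40 | cycles (years) | life-expectancy horizon of the 30-year-old reference patient |
| start age | 30 | years | shifts the horizon 1 cycle/year when swept |
| discount rate | 0.03 | 1/year | applied to costs and QALYs alike |
| $m_R$ | 0.094 | prob/year | mortality while retained on ART |
| $m_N$ | 0.375 | prob/year | mortality after disengagement |
| $u_R,u_N$ | 0.82, 0.53 | utility | dead = 0 (standard convention) |
| retention anchors | per arm | fraction | 1/2/3-year values are cohort-derived; 10–40-year values are long-term programme assumptions and live in the config so scenarios can replace them |
| annual cost | 246.45 / 250.13 | USD/patient/year | computed at run time from the facility cost table, not hard-coded |
| GDP per capita | 1408 | USD | WTP thresholds at 1× and 3× |

### Dropout from retention curves

Arm-level retention $R(t)$ is anchored at observed/assumed time points
with $R(0)=1$; the per-cycle conditional dropout probability is
$q_c = 1 - R(c)/R(c-1)$.  The anchors are interpreted as retention among
survivors: death while in care is a competing risk handled by the
transition matrix, not part of $R$.  Interpolation between anchors is
`linear` (default) or `constant_hazard` (log-linear); annual monitoring
data cannot distinguish them, so both are admissible calibration
switches.

### Discretionary conventions (calibration switches)

Four conventions are not determined by the published inputs:

1. **interpolation**: `linear` | `constant_hazard`;
2. **event ordering** within a cycle — annual data cannot say whether a
   patient who both disengaged and died left care first:
   `death_first` ($P_{R\to N} = q_c(1-m_R)$), `dropout_first`
   ($P_{R\to D} = m_R(1-q_c)$), or `independent` (both hazards applied,
   renormalized in the rare overflow case);
3. **half-cycle correction**: `initial_half_cycle` (half of the first
   cycle's reward credited undiscounted; the study's stated variant, and
   applied to costs and QALYs identically), `trapezoidal`, or `none`;
4. **cost accrual**: `retained_only` (the programme cost follows the
   patient in care) or `all_alive` (disengaged patients also accrue the
   arm's annual cost).

`artcea.calibrate` runs the full 2×3×3×2 grid, scores each combination
by the mean absolute relative residual over the nine published base-case
quantities (both arms' costs, QALYs and C/E ratios, ΔC, ΔE, ICER), and
the shipped default is the winner: **linear / independent /
initial_half_cycle / retained_only**.  The scoring rule was fixed before
inspecting per-quantity consequences and is not revisited.

### What the calibration cannot reach, and why

The discrepancy report (`discrepancy_report()`) computes two structural
facts rather than asserting them:

* **Annuity bound.**  Discounted QALYs cannot exceed
  $u_R\left(\tfrac12 + \sum_{c=1}^{40}\big(\tfrac{1-m_R}{1+r}\big)^c\right)
  \approx 6.37$, because every alive person-year is worth at most $u_R$
  and annual survival is at most $1-m_R$.  The published per-arm QALY
  totals (6.81 and 7.27) both exceed this bound (gaps ≈ 0.44 and 0.90),
  so no admissible switch combination — nor any three-state model with
  the printed mortality, utility and discount inputs — can reproduce
  them.  The grid's best QALY values are ≈ 5.0/5.25.
* **Additive-cost diagnostic.**  The published incremental cost
  (1341.86 USD) divided by the intervention arm's discounted retained
  person-years (≈ 5.35) is ≈ 250.7 USD/year — within 0.3% of the
  intervention's blended per-patient annual cost.  The published totals
  are therefore consistent with a comparison that charged the
  intervention arm its own annual cost *on top of* the comparator's
  (≈ 497 USD/year in the retained state), which would roughly double its
  lifetime cost, matching the published 2601.02 against the model's
  ≈ 1464.  We do not adopt that accrual as a default because it
  contradicts the printed statement that 250.13 USD *is* the
  intervention's total per-patient annual cost; the diagnostic documents
  the most plausible origin of the gap instead.

Downstream published sensitivity figures (scenario ICERs 1644.71/4365.34,
thresholds at utility 0.78 and mortality 39.3%, the CEAC indifference
point near 2800 USD) inherit the same cost structure and are likewise
out of reach; the acceptance tests assert them at printed precision and
fail honestly, with this note as the explanation.

## Costing

Facility costs are annual line items in 2011 Zambian Kwacha (capital
items already annualized), converted at 5000 ZMK/USD, divided by patient
volume (hospital 6000; 300 per rural health centre, the interpretation
under which the printed per-patient figure is exactly consistent), and
blended patient-weighted across one hospital + five centres for the
intervention arm.  `annualize_capital` provides the standard equivalent
annual cost $P / \big[(1-(1+r)^{-L})/r\big]$ for users supplying raw
purchase prices; the default useful lives (building 30y, furniture 10y,
vehicle 5y) are conventional assumptions, not observed values.  Money is
kept at double precision internally; rounding to 2 decimals happens only
in the reporting layer.

## Sensitivity analyses

* **Tornado**: ranges default to the published one-way table (mortality
  retained 4–17%, utility retained 0.62–0.98, age 20–50, mortality not
  retained 27–51%, discount 0–15%, costs halved/doubled).  The discount
  range is stated as 0–10% in one place and 0–15% in another; the
  shipped default is 0–15%, the range attached to the printed results.
  Entries are full re-runs of both arms (no caching) sorted by ICER
  swing.
* **Age sweep**: start age shifts the horizon one cycle per year
  (age 20 → 50 cycles), holding retention flat beyond its last anchor —
  a long-term plateau assumption needed because the curves are only
  anchored to 40 years.
* **Threshold search**: bisection (tolerance $10^{-4}$ of the parameter
  scale) on a signed decision margin — either ICER − WTP or the
  incremental net monetary benefit — after a 9-point monotonicity check;
  non-monotone responses fall back to a 201-point grid scan with a
  warning; no crossing returns `None`.
* **Scenarios**: both retention curves replaced by geometric annual
  reductions (best: 10%/yr comparator vs 3%/yr intervention; worst:
  reversed).
* **PSA**: the study reports an acceptability curve but no
  distributions, so these are implementation choices: beta for
  probabilities and utilities, gamma for costs, method-of-moments with
  the one-way range treated as a central 95% interval; 10,000
  iterations, seed 20110412.  Discount rate and reference age are policy
  settings and are not sampled.  CEAC ties are split equally so the two
  probabilities always sum to 1; the default WTP grid is 0–6000 USD in
  steps of 100, covering both GDP anchors.

## Synthetic cohort

The generator emulates the observational cohort behind the retention
anchors: ~32,428 patients enrolling uniformly over 2010–2011, monthly
clinic visits, administrative censoring (default 2012-12-31), LTFU
declared after >3 months without a visit.  It sub-cycles monthly
(annual hazard $h$ → $1-(1-h)^{1/12}$; monthly dropout from the
retention curve at monthly resolution) with death applied before dropout
within a month; ages are normal around a median of 33 (SD 10, floored at
15).  Deliberately *not* emulated: the paediatric/adult mix beyond the
age distribution, visit-level noise (visits are exactly monthly),
re-engagement after LTFU, and reporting of deaths occurring out of care
— so passing recovery tests show the estimators are consistent for this
generating process, not that real programme databases are this clean.

`estimate_retention` offers a simple proportion (default: among patients
with enough potential follow-up, excluding deaths in care before the
time point as the competing-risk convention requires; slightly
downward-biased because early dropouts stay in the denominator while
would-be-retained deaths leave it) and a Kaplan–Meier estimator with
dropout as the event and death/administrative end as censoring, which is
consistent and is what the parameter-recovery tests use.  Recovery of
the 36-month anchor needs ≥36 months of potential follow-up, so those
tests extend the (configurable) censor date.

## Numerical and testing choices

Transition rows are validated to sum to 1 within $10^{-12}$ and traces
to conserve mass within $10^{-10}$; the dropout-survival product
reproduces every anchor within $10^{-12}$.  An individual-level
microsimulation with the same per-cycle probabilities cross-checks the
deterministic trace (3 binomial SEs per cycle/state at $10^5$ patients;
mean discounted QALYs within 3 sample SEs — the per-seed SD of the mean
at that size is ≈ 0.012, so fixed absolute bounds tighter than that are
not meaningful).  Problem sizes in the test suite (PSA at $10^3$–$10^4$
iterations, microsimulation at $10^5$ patients, synthetic cohorts at
$5\times10^4$) were chosen so the whole suite runs in a few minutes on
one CPU while keeping Monte-Carlo error well inside the asserted bounds.

ICERs are computed on unrounded values; an exactly zero ΔE yields an
undefined-ICER sentinel (`None`), not an exception.  Negative ICERs are
routed to dominance logic rather than WTP classification.  Extended
dominance is pruned iteratively on the cost-sorted frontier.  A
south-west comparison (cheaper and less effective intervention) is
reported with raw increments and left unclassified.

## Known limitations

No CD4/WHO-stage structure, adherence, second-line ART, adverse events,
opportunistic infections or hospitalization costs — excluded by design
to stay a faithful re-implementation of the simple published model.  No
re-entry into care after LTFU.  Mortality out of care is a single
constant taken from natural-history data.  Programmatic costs
(training, supervision, M&E) are outside the costing scope.
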