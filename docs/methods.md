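# Methods

`screenburden` quantifies the economic burden that population-level cancer
screening shifts onto patients and a local insurance fund, using
insurance-claims records from the two arms of a cluster-randomized upper-G.I.
screening trial (screening arm offered one-time endoscopy; control arm none).
This note documents the model, the parameters that matter, the synthetic-data
generator, and the numerical conventions.

## The analysis model

**Case verification.** A participant's claims constitute a treated upper-G.I.
cancer case when either (a) some hospitalization's discharge diagnosis falls
in the ICD-10 blocks C15, C16, D00, or K22 (prefix match, so `C15.3` matches
`C15`), or (b) some expense line item belongs to a configured set of
cancer-directed therapy classifications (default: surgery, radiation,
chemotherapy medication). The rule is monotone in the episode set. Whether
precancerous-lesion blocks (D00, K22) qualify on their own is configurable;
the default treats them as qualifying, because endoscopically treated
early lesions generate the same kind of claims trajectory.

**Perfect Cohort.** In community cluster-randomized trials the arms enroll at
different times, so naive totals confound arm with follow-up length. The
harmonization takes the *minimum* follow-up time (end of follow-up minus
enrollment, in whole days) over all verified cases as a uniform cutoff `U`,
and retains only cases diagnosed within `U` days of their own enrollment.
The boundary is closed (diagnosis at exactly `U` days is included). The
minimum is taken over all verified treated cases; this is configurable. A
selection-bias table compares included vs excluded cases covariate by
covariate (uncorrected χ² for categorical, two-sided Wilcoxon rank-sum for
continuous; raw p-values, no multiplicity correction — the comparison is
descriptive).

**Standard observation window.** Each case is anchored at its first
hospitalization with an upper-G.I. discharge code in a secondary or tertiary
facility (ties on admission date break by discharge date, then input order).
The average-cost curve by month `m` since the anchor is

    average(m) = total cost admitted in month m / patients under observation in month m

with months defined as fixed 30-day bins `[30(m-1), 30m)` — not calendar
months, which would make bin membership depend on the anchor's day of month —
and a patient "under observation" in month `m` iff their follow-up extends
through the bin start. An episode's full cost belongs to the bin of its
admission date (no proration). The curve is L-shaped on claims data of this
kind; `select_window` returns the smallest `m` past which every later
month's average sits below a fraction (default 5%) of the month-1 average,
falling back to the last month with a warning. The headline pipeline fixes
the window at 12 months (360 days), mirroring the one-year convention; costs
are then collected from cancer-coded episodes admitted inside the window.

**Cost valuation.** All amounts enter as nominal CNY of their service year.
Each amount is (i) compounded to the base year at the annual discount rate on
whole-year differences, (ii) rescaled by the medical CPI ratio, and (iii)
divided by the PPP exchange rate:

    usd = cny × (1+r)^(Y_base − Y_service) × CPI[Y_base]/CPI[Y_service] / PPP

Time cost uses the human-capital approach with a caregiver:

    time_cost = OLS × (ANI / 365) × 2

where OLS is the case's total inpatient days over in-window episodes (each
episode valued in its own service year) and ANI the rural annual net income
per capita. Treatment cost ≡ hospitalization cost + time cost, an exact
identity carried through every report. Out-of-pocket cost sums the adjusted
unreimbursed expenses; it can never exceed the hospitalization cost.

**Catastrophic health expenditure (CHE).** A case is catastrophic when
out-of-pocket spending strictly exceeds 40% of the capacity to pay (WHO
operational rule, "exceeding" read as strict `>`), with capacity proxied by
local per-capita disposable income (default 10,906 CNY ≈ 3,072 USD at the
2018 PPP rate of ¥3.55/$). The comparison is made in USD after conversion.

**Reporting.** Costs are summarized as mean with lower/upper quartiles
(linear-interpolation quartiles; costs are heavy-tailed, so quartiles rather
than SDs). Strata are (arm × site group), with site groups *esophageal* and
*cardial + non-cardial gastric*; rare other sites (duodenal) report under
"other" and stay out of the two headline groups. Percentages round half away
from zero to integers. Arm totals divide screening by control per site group,
reported to two decimals. Accumulated-cost curves cumulate each stratum's
in-window episode costs (adjusted totals plus per-episode time cost) over
the 12 bins; the final point equals the stratum total exactly. The
classification breakdown divides each arm's adjusted line-item cost per
expense class by the arm's case count, so the class means sum to the arm's
mean hospitalization cost whenever line items partition episode totals.
Univariate logistic regressions of a binary cost outcome (default: CHE
status) on one covariate at a time give odds ratios with 95% Wald CIs;
perfect separation suppresses the estimate with a flag.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| discount rate | 0.03 | /year | standard health-economics annualization |
| base year | 2018 | — | end of claims coverage |
| PPP rate | 3.55 | CNY/USD | 2018 purchasing-power parity |
| ANI | 10,906 | CNY/year | **stand-in**: county per-capita disposable income, 2017; replace with provincial rural ANI per service year for real analyses |
| caregiver multiplier | 2 | — | patient plus one accompanying caregiver |
| CHE threshold | 0.40 | — | WHO catastrophic-expenditure rule |
| capacity to pay | 10,906 | CNY | county per-capita disposable income, 2017 |
| medical CPI | 2%/yr geometric, 2018 = 1 | — | stand-in series; a config input |
| window | 12 | 30-day months | where the monthly curve reaches ≈0 |

## The synthetic-data generator

Real claims are available only on request, so `synthetic_claims` emulates the
study conditions: 17,000 participants per arm aged 45–69, screening arm
enrolled 2012–2013, control arm 2013–2015 (staggered by design, so cohort
harmonization is non-trivially exercised), administrative censoring at
2018-12-31. Clinical incidence uses the target population's site rates
(esophageal 25.58/10⁵, cardial 5.0/10⁵, non-cardial gastric 7.45/10⁵,
duodenal 0.15/10⁵ person-years) times an enrichment factor of 2 for the
age-restricted high-risk cohort. Screening additionally detects prevalent
cases at enrollment with probability 0.0105 per screened participant
(≈ 180 screen-detected cases among ~17,000).

Screen-detected cases draw stages from an early-stage profile (67% 0–I) and
clinically diagnosed cases from a late-stage profile (81% III–IV), so the
screening arm's stage mixture shifts earlier — monotonically — as the
detection probability rises. Therapy follows stage through a conditional
table; hospitalization counts are 1 + Poisson(stage-dependent rate) and
per-episode lengths of stay lognormal, calibrated so per-case medians land
near 1 vs 2 episodes and 21 vs 39 days across the arms. Post-diagnosis
survival is exponential by stage with a 540-day floor: verified treated
cases are, by the construction of the claims-matching rule, patients who
survived the initial treatment course, and the shortest follow-up in such
cohorts is driven by late enrollment plus administrative censoring rather
than immediate deaths.

Episode costs are lognormal per therapy, split across the nine insurance
expense classifications with therapy-specific shares, and decay
geometrically with a 2.5-month half-life in 30-day months since the first
admission — so the monthly average curve is L-shaped and below 5% of its
month-1 level well before month 12. Therapy cost medians (13k–36k CNY per
episode) are calibrated so stratum per-case means land near the magnitudes
the method is designed for (≈$12k–20k per case) with advanced-stage therapy
the more expensive trajectory. Reimbursement rates are Beta-distributed per
episode around a mean of 0.50 (concentration 80), and out-of-pocket equals
total minus reimbursed to the cent.

What the generator does **not** emulate: village-level cluster effects,
screening test characteristics (sensitivity/specificity), background
mortality in non-cases, outpatient or travel costs, transfers between
hospitals (each episode is independent), and real ICD coding noise beyond a
10% admixture of non-G.I. codes in follow-up episodes. Passing tests on this
data therefore demonstrate the pipeline's arithmetic, invariants, and
qualitative behaviour (down-staging, L-shaped decay, arm asymmetry) — not
that real claims would produce any particular cost level.

The nine expense classifications are not publicly enumerated by the
insurance scheme; the shipped default
(bed, nursing, diagnostics, imaging, laboratory, surgery, radiation,
chemotherapy medication, other medication) is a documented stand-in and is
configurable.

## Numerical conventions and degenerate inputs

* Internal arithmetic in double precision; rounding (integer USD, integer
  percentages) only at the display layer.
* Money identities tolerate 0.01 CNY (claims are recorded to the cent).
* An empty episode list is "unverified", not an error; a verified case with
  no qualifying secondary/tertiary cancer-coded admission is flagged
  untreated and dropped from cost analysis with a warning.
* A month with an empty denominator reports average 0 with the denominator
  shown; an all-zero curve is an error for window selection.
* A zero control-arm total makes the ratio "undefined", not infinite.
* Single-level covariates are skipped (noted) in comparison tables; a
  constant outcome aborts the regression with a "degenerate outcome" error.

## Problem sizes

The default synthetic study (2 × 17,000 participants, ≈300 cases, ≈600
episodes) runs the full pipeline in a few seconds. The test suite uses a
compact study (2 × 2,500 participants with incidence enriched 8×, ≈350
cases) so every property is exercised on a populated two-arm cohort while
the whole suite stays fast.

## Known limitations

* The uniform follow-up emerging from the generator (≈550 days at default
  conditions) is shorter than in larger real cohorts; it depends on the
  survival floor and enrollment staggering, and downstream logic is
  insensitive to its exact value.
* With ~20 control-arm cohort cases at default conditions, control-arm
  stratum summaries are noisy across seeds, and the CHE outcome can be
  one-sided in a given run (the pipeline then skips the regression with a
  note rather than failing).
* ANI and the medical CPI series ship as documented stand-ins; conclusions
  about real data require the official statistics.
* Costs are inpatient-only plus hospitalization time cost; outpatient,
  travel, and broader productivity losses are out of scope.
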