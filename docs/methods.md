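# Methods

## Model structure and assumptions

The analysis is a one-year-horizon decision tree over a closed birth cohort.
Every newborn is screened exactly once by the first-line device; every
screen-positive newborn receives exactly one confirmatory BERA; screen
negatives are terminal (no follow-up, no downstream cost or detection). The
confirmatory test is modeled as a configurable `TestPerformance` defaulting
to perfect (sensitivity = specificity = 1), the usual gold-standard
idealization. Screen and confirmation outcomes are conditionally independent
given true hearing status — the implicit assumption of any cascade of this
form, and the one the Monte-Carlo simulator implements literally.

Expected branch counts are kept as real numbers throughout; integer views
are produced half-up only at report time, so conservation invariants
(branches sum to *N*, diseased branches to *D*) hold exactly in floating
point rather than "up to rounding".

### The two cascade parameterizations

`sens_spec` mode is the self-consistent tree driven by prevalence,
sensitivity and specificity. `observed` mode instead pins the referred and
confirmed counts (plus any known screen-missed cases) to field figures and
back-fills the branches: A = confirmed, C = referred − confirmed,
B = under-detected, D = *N* − referred − under-detected. Both are first-class
because field detection counts are generally not derivable from bench
accuracy — in the bundled 2019-20 parameter set, a specificity of 97% would
imply 2,985 false referrals while the observed figure is 238. In observed
mode the conservation invariants hold against the cascade-implied case load
(confirmed + under-detected); a mismatch with the configured prevalence is
reported in the discrepancy log rather than raised, since it reflects the
source data, not an invalid configuration. Inputs that would force a
negative branch count do raise.

## Costing

Micro-costing with six categories (human resources, medical and non-medical
consumables, medical and non-medical equipment, overheads), INR at 2019-20
prices, no currency conversion or inflation adjustment. Salaries are
apportioned by the fraction of working time spent on screening (derived from
daily hours at 22 working days and 176 monthly hours when not given
explicitly); lump-sum items such as post-service training are amortized
fully in the analysis year. Equipment is annualized straight-line over a
6-year lifespan with no discounting or salvage value, consistent with the
single-year horizon.

Throughput is ⌊effective hours × 60 / duration⌋ per day × 260 working days.
The effective screening day is 6 hours, not 8: with the stored durations of
15/10/90 minutes this yields the documented 24/36/4 screens per day, whereas
printed durations in (rounded) hours do not; both the durations-in-minutes
choice and the 6-hour day are therefore fixed as defaults and exposed as
configuration parameters. Unit cost per screen is total annual cost over
annual throughput; the unrounded value feeds all downstream accumulation and
the half-up integer is report-only.

## Health economics

QALYs are undiscounted: cohort QALYs = (unaffected + detected-and-treated) ×
0.95 + undetected × 0.77, times 69.2 years of life expectancy. The default
utilities are the pooled weights; unilateral (0.85) and bilateral (0.69)
weights are housed and selectable but unused by default. A discount-rate
parameter exists (annuity form) and defaults to 0 — the reference cohort
QALY total of 6,574,000.00 = 100,000 × 0.95 × 69.2 is only reproduced
undiscounted, which fixes that default.

Health-system cost = program screening cost (N × first-line unit cost +
referred × confirmatory unit cost) + confirmed cases × lifetime treatment
cost. Societal cost adds out-of-pocket expenditure: per visit, the
facility-mix-weighted mean transport cost (440/300/207/99 INR at medical
college / district / community / primary level) plus wage loss; one visit
per screened newborn and one extra per referral by default, since the
source's visit structure is unstated.

The ICER is ΔCost/ΔQALY with explicit flags: `equivalent` (both deltas
zero), `cost_minimization` (zero QALY difference), `dominant_a`/`dominant_b`
(cheaper and more effective). Reported ratios are rounded half-up to two
decimals; antisymmetry under strategy swap holds exactly because deltas are
plain subtractions.

### Derived defaults and the discrepancy log

Three families of published figures cannot be rebuilt from the published
inputs, and the package treats each the same way — compute from first
principles, report the computed value, and flag the printed one:

- **QALY difference.** The printed ΔQALY of 33.67 is not reconstructible
  (3 missed cases × 0.18 × 69.2 = 37.368). `delta_qaly_override` carries the
  printed value for reproduction runs; the model-derived value is computed
  and reported beside it in every table.
- **Treatment costs.** Lifetime cost per treated child is never itemized in
  the source; the fixture defaults (cochlear implant 1,229,552.89 INR,
  hearing aid 699,745.55 INR) were back-calculated once from the published
  scenario totals ((scenario total − screening total)/detected cases) and
  are tagged as derived, not authoritative.
- **OOPE composition.** The societal increments (~80.5M INR per strategy)
  are not decomposable from the printed per-visit transport means alone. The
  fixture uses an equal facility mix and a 540 INR wage loss per visit,
  which lands within 0.01% of the published increments; it is an approximate
  calibration, clearly labeled, with every component (mix, visits, wage
  loss) a free parameter.

The discrepancy log is a deliberate design element: the pipeline compares
each computed quantity against the `reference_values` section of the
configuration and records every mismatch (the OAE inventory sum, the BERA
direct-cost total, the per-case-detection quotients, the perspective
totals). A run on the bundled fixture must produce a non-empty log — tests
guard this so no future change silently "fixes" printed numbers.

## Monte-Carlo simulator

`simulate_cohort` draws hearing status Bernoulli(*p*), refer with
probability sensitivity (affected) or 1 − specificity (unaffected), and
confirmation analogously among referred infants, all through one
`numpy.random.Generator` with explicit seed — no global state, and fixed
seed ⇒ byte-identical cohorts. `simulate_observed_cohort` is the
observed-mode counterpart: a categorical draw calibrated so expected
referred/confirmed/missed counts equal the observed figures. OOPE is
deterministic per facility level unless a Gamma dispersion (by coefficient
of variation) is requested; the source gives no between-family cost
variance, so none is simulated by default.

What the simulator emulates is exactly the tree's statistical structure; it
does **not** model repeat-screen protocols, loss to follow-up, age-dependent
accuracy, unilateral/bilateral subtypes or visit-count heterogeneity.
Agreement between simulator and tree (asserted at 3 binomial standard errors
with N = 100,000, and parameter recovery of sensitivity/specificity over 50
replicates) therefore validates the implementation's internal consistency,
not the realism of the tree for field data.

## Numerical choices

- Reported INR and ratio values round half-up (`decimal`-based), never the
  banker's rounding of built-in `round`; all internal arithmetic is
  unrounded.
- Daily throughput uses floor division — a partial test does not fit in the
  working day.
- Undefined ratios (PPV with no referrals, unit cost at zero throughput,
  cost per case with zero detections) raise `UndefinedMetricError` in the
  core API; the replicate-level estimator returns `None` plus a flag
  instead, so simulation sweeps survive degenerate draws.
- One-way sensitivity sweeps force `sens_spec` mode: observed mode pins the
  counts, which would make accuracy and prevalence sweeps inert. Sweeps use
  the model-derived QALY difference, never the override.
- Problem sizes: the deterministic model is closed-form at any *N*; the
  simulator runs at the full cohort size of 100,000 (and 50 replicates for
  recovery checks), which completes in seconds vectorized.

## Known limitations

No probabilistic sensitivity analysis or acceptability curves; no
willingness-to-pay threshold judgment; no discounting of capital or
multi-year budget impact; no rescreening pathways. The observed-mode inputs
inherit whatever biases the underlying feasibility data carry, and the
derived treatment-cost and OOPE defaults should be replaced with primary
data before any use beyond reproducing the reference analysis.
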