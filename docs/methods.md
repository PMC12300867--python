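# Methods

## Model structure and assumptions

The engine is a deterministic (expected-value) Markov cohort model over
four mutually exclusive states — Healthy, Chronic T2D, Death from T2D,
Death from other causes — evaluated in annual cycles for each sex ×
age-band stratum independently. The cohort is closed: nobody enters,
nobody ages across bands, and population change over the horizon is
ignored, so results for a 10-year horizon describe the 2019 cohort only.
Chronic T2D is permanent (no remission), both death states are absorbing,
and Healthy individuals cannot die *of* T2D without first entering the
chronic state. Complications of T2D and inpatient care are outside the
model: the only costed event stream is outpatient care (including
dispensing) for the prevalent chronic pool.

Occupancy is propagated as `occupancy[t+1] = occupancy[t] @ M` with
fractional persons; per-cycle incident cases and T2D deaths are read off
start-of-cycle occupancy (`H_t * p(H→C)` and `C_t * p(C→D_t2d)`). All
transitions are evaluated simultaneously from start-of-cycle occupancy —
no intra-cycle event ordering and no half-cycle correction. Mass is
conserved to 1e-6 persons per cycle, which the test suite asserts on the
bundled strata and on 100 random synthetic strata.

## Transition probabilities

Published annual rates per 100,000 are used directly as per-cycle
probabilities (`rate / 1e5`), without the exponential rate→probability
conversion; at these magnitudes (≤2.6 % annual mortality) the difference
is below 0.2 % and the direct reading keeps the parameter tables exactly
reproducible from the published values. Three constructions matter:

* `p(H→C) = incidence/1e5 × RR` — the dose–response multiplier acts only
  on incidence;
* `p(→D_oth) = (all-cause − T2D mortality)/1e5` from both living states,
  so the all-cause rate is not double-counted against T2D deaths (this is
  why the parameter model requires T2D mortality ≤ all-cause mortality);
* `p(C→D_t2d) = T2D mortality/1e5` applied to the chronic pool. National
  T2D-mortality rates are general-population-denominated, so treating them
  as chronic-pool probabilities understates T2D deaths slightly; we keep
  the convention because the absolute flow is tiny (≈5,000 deaths against
  2.2 M incident cases over 10 years) and it matches how this class of
  analysis is usually parameterized.

Any row leaving [0, 1] (e.g. an RR multiplier pushing incidence past the
survival probability) raises a `ModelError` naming the offending row
rather than silently clipping.

## Dose–response risk model

The meta-analytic relative risk (0.93 per 50 g/day, 95 % CI 0.89–0.97) is
extrapolated as a power law: `RR(Δ) = 0.93^(Δ/50)`. This is the standard
log-linear reading of a "per-increment" dose–response slope; it makes the
multiplier multiplicative in Δ (asserted to 1e-12) and monotone
decreasing for protective RRs. Intake deltas are floored at zero — a
stratum already above the scenario target is not forced down, and negative
deltas (which would extrapolate to RR > 1) are rejected as outside the
modelled domain. The full effect applies from the first cycle, matching an
immediate, fully adhered-to intake change; no lag or adherence decay is
modelled. The same population-mean shift is applied to the whole stratum,
although real intake distributions are strongly right-skewed (median
intake in Japan is 0 g/day): the model is a cohort-mean approximation by
construction.

## Economics

The per-patient-year unit cost for each stratum is its published annual
outpatient expenditure divided by its baseline prevalent count (e.g. USD
≈598/patient-year for men 40–49, ≈939 for women 70–79). Costs accrue on
Chronic-T2D occupancy every cycle and are discounted at `(1+r)^-t` with
the first year undiscounted; the default rate is 2 %/year (0–4 % in
sensitivity), per Japanese economic-evaluation guidance.

Whether cycle *t* accrues cost on start-of-cycle or end-of-cycle occupancy
is a genuine freedom — decision-tree tools differ and rarely document it.
The accrual function exposes `timing={"start","end"}` and defaults to
**end**: someone diagnosed during a year plausibly incurs outpatient costs
in that same year, and end-of-cycle membership captures those incident
cases. The choice moves absolute 10-year expenditure by ≈1.5 % and ratio
outcomes by far less. The zero-discount, no-transition closed form
(`horizon × patients × unit cost`) holds exactly under both timings and is
asserted in the tests.

## Comparison conventions

Prevented incidence/deaths and saved expenditure are baseline minus
scenario, per stratum; sex-level and overall aggregates are summed
*before* percentages are taken, and percentages are computed from
unrounded aggregates (CSV output is unrounded; only the human-readable
summary rounds). Because stratum runs are independent, aggregated
prevented counts equal the sum over strata exactly. Per-stratum percent
reductions track the naive static prediction `100 × (1 − RR_s)` to within
two percentage points; the gap is the dynamic damping from the healthy
pool shrinking faster under the baseline than under the intervention.

## One-way sensitivity analysis

Each analysis perturbs one parameter family at a time — every stratum's
value replaced by its lower (then upper) 95 % CI bound simultaneously,
the dose–response RR by its CI bounds, or the discount rate set to 0 %
and 4 % — and re-runs both arms under the perturbed value (common-parameter
perturbation, standard DSA practice). Columns are ordered by *parameter*
bound, not by output size: for the protective RR the lower bound (0.89,
stronger protection) yields the *larger* savings, an inversion the test
suite asserts rather than hides. Tornado ordering is by |high − low|
descending with alphabetical tie-break, so collapsed-CI inputs sort
deterministically.

## Synthetic data and the microsimulation oracle

`SyntheticSpec` samples parameter sets with the same shape as the bundled
tables: uniform population, intake, rate and unit-cost draws inside
configurable ranges (defaults bracket the Japan-2019 values), CI bounds
log-symmetric around each rate, and costs back-computed from a
per-patient-year unit cost so validation passes by construction. The t2d
mortality range must sit strictly below the all-cause range — the
constructive guarantee that every sampled stratum satisfies the mortality
ordering invariant. Each stratum draws from `default_rng([seed, index])`,
so enlarging a set never reshuffles existing strata. The generator does
not emulate skewed individual-level intake; it produces stratum means,
which is all the deterministic engine consumes — so passing tests say
nothing about within-stratum heterogeneity.

The microsimulation oracle draws each of *n* individuals' annual paths
from the same transition matrix (initial state Bernoulli in prevalence,
then per-cycle categorical draws) and scales counts to the stratum
population. The marginal count of a state at a cycle is binomial, so the
deterministic trace should sit within a few binomial SEs of the
simulation. The per-stratum tests use a 3-SE band; the 20-stratum
acceptance property compares ~880 state × cycle cells at once, where the
*maximum* of that many near-normal deviations routinely touches 3 SE, so
it enforces 3 SE for 99 % of cells and a hard 4.5-SE band overall — a
multiplicity-aware reading of the same criterion, not a loosened one.

## Numerical choices and degenerate inputs

Row-stochasticity is checked to 1e-12 and conservation to 1e-6 persons.
Zero-rate strata produce an identity matrix and a constant trace; horizon
0 yields the initial split with zero flows; zero prevalence makes the
per-patient unit cost undefined (error) rather than infinite. Parameter
CSVs are written with pandas' shortest-repr floats, which round-trip
bit-exactly. Validation is report-based (all violations listed with their
stratum key) instead of fail-fast, so a bad hand-edited table surfaces
every problem at once.

## Known limitations

* Reproduction of the original published projections is close but not
  exact: ratio outcomes (percent reductions) match to a few tenths of a
  percentage point, while some absolute cumulative counts differ by up to
  ≈5 %. The published absolute figures are not jointly consistent with any
  conservative four-state cohort under the stated transition construction;
  they are best matched by an accounting in which the incidence
  probability is applied to the whole living cohort with an additional
  flat RR factor in every arm — behaviour this package deliberately does
  not replicate, because it is not mass-conserving and applies an
  intake-change risk ratio in the no-change arm. The acceptance suite
  therefore pins ratio claims tightly (0.5 %) and absolute counts/USD at
  2 %/5 %, and the affected absolute-count checks fail honestly rather
  than being tuned to pass.
* 10-year horizon only; longer horizons would accumulate larger death and
  cost effects but also stretch the closed-cohort assumption past
  usefulness.
* No QALYs, ICERs, intervention (yogurt purchase) costs, complication or
  inpatient costs; savings are gross outpatient savings.
* The intake variable aggregates fermented milk and probiotic beverages;
  it is an upper bound on yogurt-only intake.
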