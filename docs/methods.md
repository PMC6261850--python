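# Methods

This note documents the statistical model, the synthetic-data generator, the
numerical conventions, and the design decisions behind `worklife`, in the
order the pipeline runs them.

## State space and register conventions

The annual state space is employed, unemployed (receiving benefits),
inactive, retired, plus absorbing death; ages run 15–99 with certain death
during age 99. A person-year's state is the state occupying the most months
of the year. Ties are broken in favor of the economically more active state
(employed > unemployed > retired > inactive); the tie-break is a package
convention — month counts rarely tie in real registers, and the generator's
spell expansion never produces ties (the dominant state always gets at least
7 of 12 months). Unemployed or inactive person-years at ages 65+ are recoded
to retired (no unemployment-benefit entitlement at retirement ages) and
everyone at 80+ is retired. Absence from the register below 65 is read as
inactivity; ingestion fills unobserved years between a person's first
appearance and their death year (or the window end) accordingly. The
occupational category attached to a person-year is the highest ever attained
up to that year under the total order skilled non-manual > skilled manual >
unskilled non-manual > unskilled manual: skill dominates, then non-manual
over manual. Only the relative ranks of the two mixed categories are a
package convention; the endpoints follow the standard reading.

## Transition-probability estimation

Destination state at t+1 is modelled by multinomial logistic regression on:
origin-state indicators; a cubic B-spline in age with five interior knots at
the age quantiles of the subsample (unpenalised — a fixed modest basis
substitutes for a smoothing spline because each age band is narrow; knot
placement at quantiles keeps the basis stable under uneven age
distributions); calendar-year indicators with the first year as reference
(the final data year appears only as destination year and gets none); and,
optionally, occupational-category indicators plus occupation × year
interactions. The data are split into ten subsamples (sex × age bands
15–29, 30–54, 55–64, 65–79, 80–99) fitted independently, so age and sex
implicitly interact with everything and the age schedule may jump at band
edges — visible as small discontinuities at ages 30, 55, 65, 80 in the
predicted curves, which is intended. Optimisation uses an L2-regularised
maximum-likelihood fit (ridge 1e-6 per coefficient) as a separation guard;
log-likelihoods reported by `summary()` are the unpenalised values, computed
by the package. Destinations never observed in a subsample receive
structural zero probability with a logged warning. Predictions are
materialised on the full sex × occupation × year × age × origin grid; then
the boundary rules (retired-only at destination ages 80–98, certain death at
99) are enforced and rows renormalised — renormalisation is exact because
the transfer moves mass rather than deleting it. An occupation-free variant
(`include_occupation=False`) reproduces a total-population analysis with a
single stratum per sex.

A raw-frequency tabulation (`empirical_probability_set`) is kept as the
model-free oracle; cells without exposure are missing (NaN), never zero.

## Life-table computation

Occupancy is propagated forward from a start age under one period's
matrices (period / synthetic-cohort interpretation: the year-t schedule is
applied at every age). Year counting is left-endpoint: a person alive at
integer age x contributes one full year in that year's state, so
e_j(x0) = Σ π_j(x) and a chain that dies immediately after the start age
still yields a total expectancy of 1 year. This convention is forced by the
annual dominant-state labels, which carry no sub-annual information. The
default initial distribution is all-inactive at 15 (entry before any
labor-market contact) and all-retired for start ages 65+; data-driven runs
may pass the observed distribution. The fundamental-matrix backend builds
the (age × state) transient block U and solves (I − U)ᵀ v = init for the
expected visits; it agrees with forward propagation to ~1e-14 and exists
purely as an independent oracle. Age-band decompositions are band sums of
occupancy columns; change decompositions are their differences, additive by
construction.

## Mortality alignment

Register-implied mortality is aligned to an external HMD-style reference
life table per (sex, occupation, year) stratum: at each age the
state-specific death probabilities are scaled by a common factor so the
occupancy-weighted aggregate death probability equals the reference q_x,
with non-death destinations renormalised proportionally — conditional-on-
survival structure is untouched. Occupancy weights are recomputed from the
probabilities already adjusted at younger ages, so a single forward sweep
reaches the fixed point and the second iteration of the
occupancy → scale → occupancy loop (tolerance 1e-6, cap 50 iterations) only
confirms it. Factors that would push a death probability above 1 are capped
and the deficit reported per age in the adjustment report. The exact
alignment procedure is a package design: the minimal scheme that delivers
the one property required of it, namely that post-alignment total life
expectancy at 15 matches the reference table's (the package checks 0.05
years; the achieved gap is ~1e-13 when no capping occurs). Whether death
probabilities should be scaled per origin state rather than by a common
factor is an open modelling question; the common factor preserves relative
state-specific mortality.

`ReferenceLifeTable` carries two expectancy conventions: `full_year`
(Σ l_k / l_x), consistent with the chain's left-endpoint counting and used
for alignment checks, and `person_years` (Σ L_k / l_x), the classical form
that Sullivan's method rests on. External tables reconstruct missing l/L
columns from q_x with radix 100,000 and a_x = 0.5; tables derived from a
chain use L_x = l_x so that Sullivan and Markov quantities are compared
under one convention.

## Sullivan's method

Implemented as e_j(x) = (1/l_x) Σ_{k≥x} L_k d_j(k) — dividing by l_x, the
radix normalisation dimensional analysis requires. Prevalence d_j(k) comes
from person-year cross-sections; ages without exposure are linearly
interpolated per state from neighbouring observed ages (endpoint gaps carry
the nearest observed value) and renormalised. A model-implied prevalence
(`cohort_prevalence`) propagates each cross-sectional cohort from age 15
through the calendar years it actually lived (clamped to the covered
window), which is the deterministic limit of a simulated population and
reproduces the defining lag of prevalence behind incidence change. Under a
time-stationary regime with a matched life table, Sullivan and Markov
expectancies coincide exactly when the model prevalence is used, and within
sampling noise when estimated prevalence is used — the classical
equivalence, which the acceptance suite checks at every start age with a
0.1-year band.

The two-track segregated-market scenario frames the divergence: entrants
join an employment or unemployment track (probability `entry`), tracks
self-retain at `retention`, leavers re-enter the lottery, and everyone
retires at 65. When `entry` collapses in a shock year, only the youngest
prevalences move at first, so the Sullivan employment expectancy barely
reacts while the incidence-based expectancy drops immediately. The package
runs this comparison on the employed-state expectancy: with both tracks in
the labor force, the employed+unemployed aggregate (AWLE) is structurally
invariant to the shock, so the employment expectancy is the quantity on
which the two estimators can disagree. In the comparison the Markov series
is evaluated on the scenario's known transition probabilities (the large-n
limit of the incidence estimator) and the Sullivan series on prevalences
estimated from the simulated population, isolating the estimator contrast
from fitting noise. With `retention = 0` the chain is memoryless and the two
estimators coincide.

## Synthetic-data generator

The generator defines the study conditions; its parameters are not tuned to
test outcomes. Transition regimes are parameterised through additive
multinomial-logit utilities per destination: a quadratic age curve for
employment attraction peaking at 26 (width 16 years of age), a quadratic
unemployment-benefit curve fading by the early 60s, a saturating
(tanh) retirement attraction crossing its midpoint at 62, and a death
utility linear in age (Gompertz-type log-mortality, level 2e-5 at 15, slope
0.16 per year). Origin effects are additive shifts (employment retention
logit(0.90); job losers tilted toward unemployment over inactivity); sex and
occupation enter as additive shifts on the employment and death utilities
(women: less employment, lower mortality; a mild occupational gradient). A
crisis switch subtracts a fixed amount from the employment utility from the
shock year onward — exactly the year-indicator form the estimation model
uses. State-space rules are structural destination bars (no unemployment or
inactivity destinations from age 64, retirement-only from 79, death at 99,
no un-retirement), so probability rows sum to one by construction rather
than by renormalisation. Because every admissible log-odds is additive in
the model's covariates within each age band, parameter-recovery experiments
measure estimation quality, not structural misspecification; the one
deliberate exception is the retired-before-65 cells, whose mortality is
sharply elevated (a disability-pension-type selection), and which carry
little occupancy mass. The default regime yields total life expectancy at
15 of ~70 years (male) and ~72 (female), WLE ~38/35, and a crisis that
removes ~13 years of male WLE — magnitudes in the range register-based
studies report for a severe recession.

Trajectories are simulated annually (integer period ages: age a in year t,
a+1 in t+1) from entry until death or window end, under one shared seed;
identical configuration and seed give byte-identical output. Two population
designs exist: a closed entry cohort, and a "stationary" design in which
entry years and ages are uniform over the window and the initial state is
drawn from the regime's age-conditional occupancy, making every
cross-section stationary when the regime is. Each person-year is expanded
into 1–3 within-year spells: the annual state gets 7–12 of the 12 months and
the remainder is split among one or two other states — enough to exercise
the dominant-state ingestion rule (which it can never contradict, by the
7-month floor) without modelling real sub-annual dynamics. Occupation is
drawn once per person (a mobility switch exists to exercise the
highest-category rule) and masked at a configurable missing fraction;
deaths are reported in a separate person-level table because the spell
schema, like register extracts, has no death field. The generator emits
explicit inactive spells rather than register absence: this keeps the
ingestion round trip exact for every person-year, while the absence rules
are unit-tested on hand-built data. What passing tests on these data show is
that the pipeline's estimators are consistent and its identities exact under
a data-generating process of the assumed Markov form; they cannot show
robustness to features real registers have and the generator omits —
replacement sampling of the sample frame, outmigration masquerading as
inactivity, measurement error in spell durations, or true sub-annual
dynamics.

## Problem sizes and numerical tolerances

Validation experiments use sizes chosen for statistical adequacy at their
tolerances: 200,000 sampled transitions per subsample for parameter recovery
(mean absolute error of recovered probabilities ~0.003, checked against
0.01), one million Monte-Carlo paths for expectancy consistency (3 standard
errors), 400,000–600,000 simulated individuals for the Sullivan
stationarity check (0.1-year band), and 150,000 for the shock scenario,
where the effect (a ~36- vs ~2-year drop) dwarfs sampling noise. Exact
identities (row sums, additivity of expectancies and decompositions,
backend agreement) are asserted at 1e-9 to 1e-12. Probability rows are
validated to sum to 1 within 1e-10; the estimation grid renormalises after
boundary enforcement; the mortality adjuster scales alive mass by the row's
actual alive sum rather than 1 − q to avoid cancellation when q approaches
1. The adjustment convergence tolerance is 1e-6 on aggregate q_x.

## Known limitations

Expectancies are period quantities for hypothetical cohorts, not forecasts
for real ones. No confidence intervals are produced. Disability is merged
with inactivity/retirement; part-time and full-time work are not
distinguished. The inactivity-versus-outmigration problem of register data
is out of scope, as is replacement sampling of the register frame. The
published Spanish expectancy table embedded for worked-example arithmetic
contains three female rows whose printed components do not sum to their
printed totals within plausible rounding (gaps up to 0.7 years); the
package reproduces the identities that do hold and surfaces the others as
computed gaps rather than correcting the source values.
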