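# Methods

## Model structure and assumptions

`ckdscreen` is a discrete-time (annual-cycle), individual-based
microsimulation of CKD progression in a cohort framework: a starting
population reflecting the adult age/sex structure is followed until
death or censoring at age 90, with no new entrants. Disease progression
is strictly irreversible — the albuminuria category never regresses,
GFR never rises, and diabetes, renal replacement therapy (RRT), a
positive screening test and death are absorbing states. Individuals on
RRT remain in the model (accruing RRT costs and the RRT utility) and
are evaluated at the stage-G5 mortality relative risk.

Risk factors are carried as lifelong standard-deviation scores (SDS):
an individual's BMI and SBP z-scores are drawn once and the measured
values re-evaluated each year from the age/sex LMS reference curves, so
individuals track their percentile as the population distribution
shifts with age. The SBP pipeline mirrors its construction from a
published reference: a normal SDS draw (with a calibratable mean shift,
see below), conversion to mmHg, a linear BMI-dependent elevation
(`sbp_bmi_slope` mmHg per BMI unit above `sbp_bmi_ref` = 25), and
conversion back to the definitive lifelong SDS.

Risk-factor interactions use the baseline-risk decomposition: given a
marginal probability for an (age, sex) cell and relative risks for
exposed strata, the unexposed baseline is `r0 = marginal / Σ share·RR`,
so the stratum mixture reproduces the marginal exactly. Stratum shares
are taken from the current simulated population, not external
marginals. Probabilities that exceed 1 after RR multiplication are
capped, with a counter (`capped_prob_events`) surfaced in summaries.

Renal inputs (initial GFR distribution, albuminuria prevalence) are
only specified at age 30. Older starting ages are initialized from a
pre-simulated **renal age profile**: a cohort started at age 30 is
progressed (without screening) to age 90, and the surviving non-RRT
individuals supply per-(age, sex) GFR moments and albuminuria
prevalences. Ages 18–29 copy the age-30 row. Initial GFR is drawn from
a normal distribution truncated above the RRT threshold, so nobody
starts on RRT; lifetime RRT prevalence is measured from simulation
start. In small profile cohorts, empty old-age cells carry the previous
age's row forward.

## Screening and therapy

A testing occasion is two independent albumin-creatinine tests in the
same year; therapy starts only if both are positive (per-repeat
sensitivity 0.87, specificity 0.88, so P(detect | albuminuric) =
0.7569 and P(false positive | healthy) = 0.0144 per occasion). The two
repeats are treated as independent conditional on the true state; the
dependence structure is not otherwise specified by the test
characteristics. Positives — true and false — start lifelong ACEI and
are never re-tested. Adherence (91%) is drawn once per individual and
applies only to test-initiated therapy; ACEI/ARB allocated as
antihypertensive therapy is always clinically effective. Effects
(GFR-loss reduction `e_GFR`, micro→macro progression RR, death RR)
apply only while the individual is albuminuric and effectively treated;
medication costs accrue for everyone on test-initiated therapy,
adherent or not, false positive or not.

Screening precedes mortality within a cycle, so therapy initiated in a
cycle already lowers that cycle's death risk. The opposite ordering is
a one-line change in `progression.advance_year`.

## Outcomes and discounting

Only individuals alive at the end of a cycle accrue that year's
utility, medication and RRT costs; testing costs are charged to
everyone tested during the cycle (the occasion happened even if the
individual dies the same year). The discounting clock is shared —
years since simulation start, year 0 undiscounted — at 3.5%/year for
both costs and QALYs. The ACEI price (15 € / 100 days) is annualized to
15 € × 365.25/100 = 54.79 €/year for every year on therapy; the quoted
price is read as a price level, not a first-year-only cost. No
half-cycle correction is applied: the model is a plain annual-cycle
simulation. Confidence intervals are normal-approximation
(mean ± 1.959964·sd/√n, population sd; Wald for proportions).

If a scenario's QALY gain over base is not positive, the
cost-per-QALY ratios are reported as undefined (`None`) with a note,
never as a number.

## Common random numbers

Every stochastic decision is a pure function of
(master seed, event code, year, individual id), hashed to a uniform via
a splitmix64-style finalizer (`_rng.py`). Scenario arms therefore
receive identical randomness for identical decisions and diverge only
where screening differs; survival is exactly monotone across nested
scenarios (therapy only reduces risks, and the *presence* of
albuminuria is treatment-independent — only its micro/macro split is
affected). One consequence worth noting: per-individual testing *costs*
are not monotone across nested scenarios, because an early positive in
a broad scenario stops re-testing while a narrower scenario may keep
testing the same individual negative; the cost ordering holds in
population means, which is what the results table reports. A
counter-based scheme was chosen over stateful generators because no
vectorized keyed-stream primitive exists in numpy; the hash is not
cryptographic but passes the empirical uniformity/mean checks in the
test suite.

Normal draws use the inverse CDF of the hashed uniform. SDS draws are
truncated at |z| ≤ 3.5 so every draw stays inside the Box-Cox domain of
skewed LMS references; the truncation discards ~5·10⁻⁴ of the mass
symmetrically.

## LMS machinery

`value = M·(1 + L·S·z)^(1/L)` (L ≠ 0) and `M·exp(S·z)` (L = 0), with
|L| < 1e-7 routed to the L = 0 branch for continuity. Percentile curves
tabulated in 5-year age groups (SBP) are interpolated/extrapolated with
a least-squares cubic per percentile and refitted to LMS triplets per
integer age by least squares on the quantile function (exact for three
percentile points); references ending at age 79 (BMI) are extended to
90 the same way. Crossing percentiles after extrapolation raise an
error rather than being clamped. Percentile labels map to
standard-normal quantiles (P3 → −1.8808, P50 → 0, P97 → +1.8808); the
fixture tabulates P3/P10/P50/P90/P97.

## Calibration

* **SBP mean shift** — the BMI elevation right-shifts the SBP
  distribution; `calibrate_sbp_mean` bisects the mean of the raw SDS
  draw until the simulated median matches the unelevated reference
  median within 0.1 mmHg. The same draws are reused at every
  evaluation, making the objective deterministic and monotone.
* **Mortality factor** — CKD relative risks inflate overall mortality;
  `calibrate_mortality_factor` rescales the life-table probabilities by
  iterative proportional fitting until the base-case death rate matches
  the life-table expectation within 1%. The comparison uses the sum of
  individual death *probabilities* over person-years rather than
  realized deaths, which removes the binomial noise of the death draws;
  with unit relative risks the procedure returns exactly 1 on the first
  iteration.
* **GFR-loss scale** — the individual annual-loss multiplier (mean-1
  lognormal, σ = 0.45) is scaled by 0.75 at initialization, taken as a
  given calibrated input rather than re-derived.

## One-way sensitivity sweep

Five inputs (BMI medians, SBP percentile levels, diabetes
prevalence+incidence, albuminuria incidence, GFR loss) are scaled by
0.80…1.20 in 0.05 steps (9 levels, 45 cells), each cell a full
base-case rerun — including a re-derived renal profile — under a common
seed; multiplier 1.00 reproduces the unperturbed run bit-exactly.
Recorded outputs: lifetime RRT cost per individual, lifetime RRT
prevalence, RRT incidence per 1000 person-years.

## The fixture parameter set

The built-in fixture stands in for the external parameter tables so the
whole pipeline runs self-contained. Values printed in the source
literature are used verbatim (sensitivity 0.87, specificity 0.88,
adherence 0.91, 2-year interval, 140 mmHg hypertension threshold,
7 ml/min RRT threshold, 0.75 GFR-loss scale, 3.5% discount rate,
36.18 €/occasion, 63 000 €/RRT-year, 15 €/100 d ACEI, age cap 90).
Everything else is a documented placeholder chosen once to be
epidemiologically plausible for a western-European adult population: a
Gompertz–Makeham life table matching published German survival levels
(P(18→90) ≈ 0.39 women, 0.22 men), logistic age profiles for diabetes,
smooth LMS surfaces for BMI (M 22.5→28, right-skewed L < 0) and SBP
(M ≈ 112–135 mmHg, L = 0.6), and albuminuria onset/progression rates
with diabetes and high-SBP relative risks. Under these placeholders the
base case produces a lifetime RRT prevalence of ~2.2%, mean age at
death ~79, ~21% censored at 90, and ~30 undiscounted QALYs per
individual — the same order of magnitude as published results, which is
what makes the qualitative scenario comparison meaningful. Every
placeholder is flagged `placeholder` in the tables' `provenance`
column, so a real parameter set can be swapped in without code changes.

What passing tests on the fixture do **not** show: agreement with any
published headline numbers (those depend on the real parameter tables),
realistic correlation structure between risk factors beyond the modeled
pathways, or external validity of the placeholder utilities, relative
risks and GFR dynamics.

## Problem sizes

The package defaults to a 10⁶ renal-profile cohort (matching the scale
used to derive age profiles in comparable models). The test suite and
the acceptance script use scaled-down sizes chosen so Monte-Carlo error
is small relative to the effects under test: 10⁴–10⁵ individuals per
run, 2×10⁴ for calibration. The main published comparison uses 10⁷
individuals; at that scale the simulation is the same code, only slower
(runtime is linear in individuals × cycles).

## Known limitations

* No remission or transplant modelling; no competing-risk
  decomposition; no SBP feedback from antihypertensive therapy (drug
  choice is static once assigned).
* Treatment effects are applied prospectively only — baseline
  albuminuria prevalence at initialization is not reduced for
  individuals already on renin-angiotensin blockade.
* The two test repeats are conditionally independent; correlated
  repeats would lower the effective occasion sensitivity below 0.7569.
* QALY utilities depend on CKD stage only, not on diabetes or
  hypertension.
* False positives accrue medication costs but no harms (adverse
  effects, psychological costs and nonclinical costs are out of scope).
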