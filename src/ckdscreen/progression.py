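"""Annual disease-progression cycle.

One simulated year applies, in fixed order: anthropometrics (ageing along
fixed SDS percentiles), incident diabetes, albuminuria onset and
progression, GFR decline with treatment effects, renal-replacement
initiation, scenario-gated screening, mortality, and outcome accrual.
Progression is irreversible: the albuminuria category never regresses,
GFR never rises, and diabetes, RRT, a positive test and death are
absorbing.

Screening precedes mortality so that therapy initiated in a cycle
already affects that cycle's death risk; the opposite ordering is a
one-line change here.
"""

from __future__ import annotations

import numpy as np

from . import lms, outcomes, screening
from ._rng import CRNStream, Event
from .params import ParameterSet, ScenarioSpec
from .population import DRUG_ACEI, DRUG_ARB, DRUG_UNASSIGNED, PopulationState, draw_ht_drug

__all__ = [
    "stage_from_gfr",
    "utility_stage",
    "solve_baseline_risk",
    "scaled_probability_by_cell",
    "effectively_treated",
    "update_anthropometrics",
    "update_diabetes_incidence",
    "update_albuminuria",
    "update_gfr",
    "check_rrt",
    "apply_mortality",
    "advance_year",
]

# GFR band lower edges for CKD stages G1, G2, G3a, G3b, G4, G5
_STAGE_EDGES = np.array([90.0, 60.0, 45.0, 30.0, 15.0])
RRT_STAGE = 6  # utility index for renal replacement therapy


def stage_from_gfr(gfr: np.ndarray) -> np.ndarray:
    """CKD stage index 0..5 (G1, G2, G3a, G3b, G4, G5) from GFR in ml/min."""
    return np.searchsorted(-_STAGE_EDGES, -np.asarray(gfr, float), side="left").astype(np.int8)


def utility_stage(state: PopulationState) -> np.ndarray:
    """Stage index for utility lookup; RRT overrides the GFR band."""
    st = stage_from_gfr(state.gfr).astype(np.int64)
    st[state.on_rrt] = RRT_STAGE
    return st


def solve_baseline_risk(marginal: float, strata: list[tuple[float, float]]) -> float:
    """Baseline risk of the unexposed stratum given a population marginal.

    With strata ``(share_i, RR_i)`` the baseline ``r0`` satisfies
    ``sum(share_i * RR_i) * r0 = marginal``, so the stratum mixture
    reproduces the marginal exactly.
    """
    shares = np.array([s for s, _ in strata], dtype=float)
    rrs = np.array([r for _, r in strata], dtype=float)
    if np.any(shares < 0) or abs(shares.sum() - 1.0) > 1e-9:
        raise ValueError("stratum shares must be non-negative and sum to 1")
    if np.any(rrs < 0):
        raise ValueError("relative risks must be >= 0")
    denom = float((shares * rrs).sum())
    if denom == 0:
        if marginal > 0:
            raise ValueError("all stratum risk is zero but the marginal is positive")
        return 0.0
    return marginal / denom


def scaled_probability_by_cell(
    marginal_by_age_sex: np.ndarray,
    state: PopulationState,
    rr: np.ndarray,
    among: np.ndarray,
) -> tuple[np.ndarray, int]:
    """Vectorized baseline-risk decomposition per (age, sex) cell.

    Stratum shares are taken from the current simulated population (the
    individuals in ``among``), so within every age/sex cell the mixture
    of ``baseline * RR`` reproduces the marginal table value.  Returns
    per-individual probabilities (zero outside ``among``) and the count
    of probabilities capped at 1.
    """
    n_age = marginal_by_age_sex.shape[0]
    cell = state.age.astype(np.int64) * 2 + state.sex
    sums = np.bincount(cell[among], weights=rr[among], minlength=n_age * 2)
    counts = np.bincount(cell[among], minlength=n_age * 2)
    with np.errstate(invalid="ignore"):
        mean_rr = np.where(counts > 0, sums / np.maximum(counts, 1), 1.0)
    marg = marginal_by_age_sex.reshape(-1)
    with np.errstate(invalid="ignore"):
        r0 = np.where(mean_rr > 0, marg / mean_rr, 0.0)
    prob = np.zeros(state.n)
    prob[among] = r0[cell[among]] * rr[among]
    capped = int((prob > 1).sum())
    return np.clip(prob, 0.0, 1.0), capped


def effectively_treated(state: PopulationState) -> np.ndarray:
    """Individuals whose renin-angiotensin blockade is clinically effective.

    Hypertension-allocated ACEI/ARB always counts; test-initiated ACEI
    counts only for adherent individuals (adherence is modeled for the
    screening cascade only).
    """
    ht_raas = (state.ht_drug == DRUG_ACEI) | (state.ht_drug == DRUG_ARB)
    return ht_raas | (state.acei_from_test & state.adherent)


# ---------------------------------------------------------------------------
# cycle steps
# ---------------------------------------------------------------------------


def update_anthropometrics(state: PopulationState, p: ParameterSet, rng: CRNStream) -> PopulationState:
    """Age one year; re-evaluate BMI and SBP from the fixed SDS values."""
    c = p.compiled()
    act = state.active
    state.age[act] += 1
    a, s = state.age[act], state.sex[act]
    state.bmi[act] = lms.value_from_sds_arrays(
        c.bmi_L[a, s], c.bmi_M[a, s], c.bmi_S[a, s], state.bmi_sds[act], clip_domain=True
    )
    state.sbp[act] = lms.value_from_sds_arrays(
        c.sbp_L[a, s], c.sbp_M[a, s], c.sbp_S[a, s], state.sbp_sds[act], clip_domain=True
    )
    newly_ht = act & ~state.hypertensive & (state.sbp > p.sbp_hypertension_threshold)
    state.hypertensive |= newly_ht
    draw_ht_drug(state, newly_ht & (state.ht_drug == DRUG_UNASSIGNED), p, rng)
    return state


def update_diabetes_incidence(state: PopulationState, p: ParameterSet, rng: CRNStream) -> PopulationState:
    """Incident type-2 diabetes; absorbing, baseline-risk decomposed."""
    c = p.compiled()
    at_risk = state.active & ~state.diabetes
    if not at_risk.any():
        return state
    rr = np.where(state.bmi > p.bmi_obesity_threshold, p.rr_diabetes_obesity, 1.0) * np.where(
        state.hypertensive, p.rr_diabetes_hypertension, 1.0
    )
    prob, capped = scaled_probability_by_cell(c.diab_inc, state, rr, at_risk)
    state.capped_prob_events += capped
    u = rng.uniform(Event.DIABETES_INCIDENT, state.t, state.ids)
    state.diabetes |= at_risk & (u < prob)
    return state


def update_albuminuria(state: PopulationState, p: ParameterSet, rng: CRNStream) -> PopulationState:
    """Albuminuria onset (none->micro) and progression (micro->macro).

    Effective renin-angiotensin blockade multiplies the micro->macro
    probability by ``acei_rr_progression``; macroalbuminuria is
    absorbing and both transitions are evaluated on the start-of-cycle
    category, so nobody jumps two categories in one year.
    """
    c = p.compiled()
    act = state.active
    a, s = state.age.astype(int), state.sex.astype(int)
    dm = state.diabetes.astype(int)
    hi = (state.sbp >= p.sbp_hypertension_threshold).astype(int)

    was_none = act & (state.albuminuria == 0)
    was_micro = act & (state.albuminuria == 1)

    u_on = rng.uniform(Event.ALBUMINURIA_ONSET, state.t, state.ids)
    onset = was_none & (u_on < c.alb_inc[a, s, dm, hi])

    prog_p = c.alb_prog[a, s, dm, hi].copy()
    prog_p[effectively_treated(state)] *= p.acei_rr_progression
    u_pr = rng.uniform(Event.ALBUMINURIA_PROGRESSION, state.t, state.ids)
    progress = was_micro & (u_pr < prog_p)

    state.albuminuria[onset] = 1
    state.albuminuria[progress] = 2
    return state


def update_gfr(state: PopulationState, p: ParameterSet, rng: CRNStream) -> PopulationState:
    """Annual GFR decline; floored at zero.

    loss = (stratum base loss + age coefficient) * individual factor,
    reduced by ``acei_e_gfr`` for albuminuric individuals under effective
    blockade.  The individual factor already carries the 0.75
    calibration scale.
    """
    c = p.compiled()
    act = state.active
    s = state.sex.astype(int)
    dm = state.diabetes.astype(int)
    hi = (state.sbp >= p.sbp_hypertension_threshold).astype(int)
    alb = state.albuminuria.astype(int)
    base = c.gfr_base_loss[s, dm, hi, alb] + p.gfr_loss_age_coef * np.maximum(0, state.age - 30)
    loss = base * state.gfr_loss_factor
    treated_alb = effectively_treated(state) & (state.albuminuria > 0)
    loss[treated_alb] *= 1.0 - p.acei_e_gfr
    state.gfr[act] = np.maximum(0.0, state.gfr[act] - loss[act])
    return state


def check_rrt(state: PopulationState, p: ParameterSet) -> PopulationState:
    """Initiate renal replacement therapy when GFR drops strictly below threshold."""
    new = state.active & ~state.on_rrt & (state.gfr < p.gfr_rrt_threshold)
    state.on_rrt |= new
    state.age_at_rrt[new] = state.age[new]
    return state


def apply_mortality(
    state: PopulationState, p: ParameterSet, rng: CRNStream, q: np.ndarray | None = None
) -> PopulationState:
    """Annual death risk: life table x calibration x CKD stage/albuminuria RR.

    Effective blockade in albuminuric individuals multiplies the risk by
    ``acei_rr_death``; individuals on RRT are evaluated at the stage-G5
    relative risk (their GFR is below 15 by construction).
    """
    if q is None:
        q = death_probability(state, p)
    u = rng.uniform(Event.DEATH, state.t, state.ids)
    die = state.active & (u < q)
    state.alive &= ~die
    state.age_at_death[die] = state.age[die]
    return state


def death_probability(state: PopulationState, p: ParameterSet) -> np.ndarray:
    c = p.compiled()
    a, s = state.age.astype(int), state.sex.astype(int)
    st = stage_from_gfr(state.gfr).astype(int)
    q = c.life_q[a, s] * p.mortality_calibration_factor * c.rr_death[st, state.albuminuria.astype(int)]
    treated_alb = effectively_treated(state) & (state.albuminuria > 0)
    q[treated_alb] *= p.acei_rr_death
    over = q > 1
    if over.any():
        state.capped_prob_events += int(over.sum())
    return np.clip(q, 0.0, 1.0)


def advance_year(
    state: PopulationState,
    p: ParameterSet,
    scenario: ScenarioSpec,
    rng: CRNStream,
    stats: dict | None = None,
) -> PopulationState:
    """One full annual cycle, in the fixed documented order.

    anthropometrics -> diabetes incidence -> albuminuria -> GFR -> RRT
    check -> screening (scenario-gated) -> mortality -> accrual; then
    individuals at the age cap are censored and the year index advances.
    """
    update_anthropometrics(state, p, rng)
    update_diabetes_incidence(state, p, rng)
    update_albuminuria(state, p, rng)
    update_gfr(state, p, rng)
    check_rrt(state, p)

    test_cost = np.zeros(state.n)
    if scenario.eligibility != "none":
        mask = screening.select_eligible(state, scenario, state.t)
        out = screening.perform_test(state, mask, p, rng)
        screening.apply_positive_result(state, out, p, rng)
        test_cost = out.cost_incurred
        if stats is not None:
            stats["tests"] = stats.get("tests", 0) + int(mask.sum())

    if stats is not None:
        act = state.active
        c = p.compiled()
        q = death_probability(state, p)
        stats["person_years"] = stats.get("person_years", 0) + int(act.sum())
        stats["expected_deaths_lifetable"] = stats.get("expected_deaths_lifetable", 0.0) + float(
            c.life_q[state.age[act].astype(int), state.sex[act].astype(int)].sum()
        )
        # expectation of the model's own death risk on the same person-years;
        # lets calibration compare expectations instead of binomial draws
        stats["expected_deaths_model"] = stats.get("expected_deaths_model", 0.0) + float(q[act].sum())
        alive_before = int(state.alive.sum())
        apply_mortality(state, p, rng, q=q)
        stats["deaths"] = stats.get("deaths", 0) + (alive_before - int(state.alive.sum()))
    else:
        apply_mortality(state, p, rng)

    outcomes.accrue(state, p, test_cost)

    state.censored |= state.age >= int(p.age_cap)
    state.t += 1
    return state
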