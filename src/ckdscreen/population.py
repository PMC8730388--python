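"""Initial-cohort synthesis.

Builds the starting population: age and sex from the adult population
table, BMI as a lifelong standard-deviation score (SDS) mapped through
the age/sex LMS reference, systolic blood pressure as an adjusted-normal
SDS with a BMI-dependent elevation, hypertension status with a one-time
drug allocation, prevalent type-2 diabetes via the baseline-risk
decomposition, and the renal state (initial GFR, albuminuria category,
individual GFR-loss factor) drawn from pre-simulated age profiles.

Individuals keep their BMI and SBP SDS for life: as the reference curves
shift with age they remain at their initially assigned percentile.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from . import lms
from ._rng import CRNStream, Event
from .params import SEX_CODES, ParameterSet

__all__ = [
    "PopulationState",
    "RenalAgeProfile",
    "sample_age_sex",
    "assign_bmi",
    "assign_sbp",
    "assign_hypertension_therapy",
    "assign_diabetes_prevalent",
    "derive_renal_age_profiles",
    "initialize_renal_state",
    "build_initial_population",
]

#: SDS draws are truncated to this range so every draw stays inside the
#: Box-Cox domain of the skewed LMS references (|z| <= 3.5 covers all but
#: ~5e-4 of the mass and leaves the mean at zero by symmetry).
SDS_TRUNC = 3.5

# ht_drug codes
DRUG_ACEI, DRUG_ARB, DRUG_OTHER, DRUG_NONE, DRUG_UNASSIGNED = 0, 1, 2, 3, -1


@dataclass
class PopulationState:
    """Per-individual state matrix, advanced in annual cycles.

    All fields are aligned numpy arrays of length ``n``; ``t`` is the
    shared year index (0 = first simulated year).  Dead individuals are
    frozen; individuals reaching the age cap are censored.
    """

    ids: np.ndarray
    age: np.ndarray
    sex: np.ndarray
    bmi_sds: np.ndarray = None
    bmi: np.ndarray = None
    sbp_sds: np.ndarray = None
    sbp: np.ndarray = None
    hypertensive: np.ndarray = None
    ht_drug: np.ndarray = None
    diabetes: np.ndarray = None
    albuminuria: np.ndarray = None
    gfr: np.ndarray = None
    gfr_loss_factor: np.ndarray = None
    on_raas_blocker: np.ndarray = None
    tested_positive: np.ndarray = None
    false_positive: np.ndarray = None
    acei_from_test: np.ndarray = None
    adherent: np.ndarray = None
    on_rrt: np.ndarray = None
    alive: np.ndarray = None
    censored: np.ndarray = None
    age_at_rrt: np.ndarray = None
    age_at_death: np.ndarray = None
    years_stage3a5: np.ndarray = None
    qaly_undisc: np.ndarray = None
    qaly_disc: np.ndarray = None
    cost_test_undisc: np.ndarray = None
    cost_test_disc: np.ndarray = None
    cost_med_undisc: np.ndarray = None
    cost_med_disc: np.ndarray = None
    cost_rrt_undisc: np.ndarray = None
    cost_rrt_disc: np.ndarray = None
    t: int = 0
    capped_prob_events: int = field(default=0)  # probabilities truncated at 1

    def __post_init__(self):
        n = self.ids.size
        z = lambda dt: np.zeros(n, dtype=dt)
        defaults = {
            "bmi_sds": float, "bmi": float, "sbp_sds": float, "sbp": float,
            "gfr": float, "gfr_loss_factor": float,
            "years_stage3a5": float,
            "qaly_undisc": float, "qaly_disc": float,
            "cost_test_undisc": float, "cost_test_disc": float,
            "cost_med_undisc": float, "cost_med_disc": float,
            "cost_rrt_undisc": float, "cost_rrt_disc": float,
        }
        for name, dt in defaults.items():
            if getattr(self, name) is None:
                setattr(self, name, z(dt))
        for name in ("hypertensive", "diabetes", "on_raas_blocker", "tested_positive",
                     "false_positive", "acei_from_test", "adherent", "on_rrt", "censored"):
            if getattr(self, name) is None:
                setattr(self, name, z(bool))
        if self.alive is None:
            self.alive = np.ones(n, dtype=bool)
        if self.albuminuria is None:
            self.albuminuria = z(np.int8)
        if self.ht_drug is None:
            self.ht_drug = np.full(n, DRUG_UNASSIGNED, dtype=np.int8)
        for name in ("age_at_rrt", "age_at_death"):
            if getattr(self, name) is None:
                setattr(self, name, np.full(n, np.nan))

    @property
    def n(self) -> int:
        return self.ids.size

    @property
    def active(self) -> np.ndarray:
        """Alive and not yet censored at the age cap."""
        return self.alive & ~self.censored

    def clone(self) -> "PopulationState":
        kw = {}
        for f in fields(self):
            v = getattr(self, f.name)
            kw[f.name] = v.copy() if isinstance(v, np.ndarray) else v
        return PopulationState(**kw)


@dataclass
class RenalAgeProfile:
    """Per (attained age, sex): initial-GFR moments and albuminuria prevalence.

    Derived by pre-simulating an age-30 cohort forward; ages below 30
    copy the age-30 row.
    """

    table: pd.DataFrame  # columns: age, sex, gfr_mean, gfr_sd, p_micro, p_macro

    def __post_init__(self):
        cap = int(self.table["age"].max())
        self.gfr_mean = np.full((cap + 1, 2), np.nan)
        self.gfr_sd = np.full((cap + 1, 2), np.nan)
        self.p_micro = np.full((cap + 1, 2), np.nan)
        self.p_macro = np.full((cap + 1, 2), np.nan)
        idx = (self.table["age"].to_numpy(int), self.table["sex"].map(SEX_CODES).to_numpy(int))
        self.gfr_mean[idx] = self.table["gfr_mean"].to_numpy(float)
        self.gfr_sd[idx] = self.table["gfr_sd"].to_numpy(float)
        self.p_micro[idx] = self.table["p_micro"].to_numpy(float)
        self.p_macro[idx] = self.table["p_macro"].to_numpy(float)


# ---------------------------------------------------------------------------
# initialization steps
# ---------------------------------------------------------------------------


def sample_age_sex(n: int, p: ParameterSet, rng: CRNStream) -> PopulationState:
    """Draw ``n`` individuals from the age x sex population table."""
    if n < 1:
        raise ValueError("n must be >= 1")
    pop = p.population_age_sex
    shares = pop["share"].to_numpy(float)
    cum = np.cumsum(shares)
    cum[-1] = 1.0
    ids = np.arange(n, dtype=np.int64)
    u = rng.uniform(Event.AGE_SEX, 0, ids)
    rows = np.searchsorted(cum, u, side="right")
    age = pop["age"].to_numpy(int)[rows].astype(np.int16)
    sex = pop["sex"].map(SEX_CODES).to_numpy(np.int8)[rows]
    state = PopulationState(ids=ids, age=age, sex=sex)
    state.censored = age >= int(p.age_cap)
    return state


def assign_bmi(state: PopulationState, p: ParameterSet, rng: CRNStream) -> PopulationState:
    """Lifelong BMI SDS ~ N(0,1) (truncated), mapped through the LMS reference."""
    c = p.compiled()
    z = np.clip(rng.normal(Event.BMI_SDS, 0, state.ids), -SDS_TRUNC, SDS_TRUNC)
    state.bmi_sds = z
    a, s = state.age, state.sex
    state.bmi = lms.value_from_sds_arrays(c.bmi_L[a, s], c.bmi_M[a, s], c.bmi_S[a, s], z)
    return state


def assign_sbp(state: PopulationState, p: ParameterSet, rng: CRNStream) -> PopulationState:
    """SBP from an adjusted-normal SDS draw plus a BMI-dependent elevation.

    The raw SDS draw has mean ``sbp_mu_shift`` (a calibration scalar that
    compensates the population right-shift the BMI elevation would
    otherwise introduce).  The post-elevation value is converted back to
    the definitive, lifelong SDS.
    """
    c = p.compiled()
    z = p.sbp_mu_shift + np.clip(rng.normal(Event.SBP_Z, 0, state.ids), -SDS_TRUNC, SDS_TRUNC)
    a, s = state.age, state.sex
    L, M, S = c.sbp_L[a, s], c.sbp_M[a, s], c.sbp_S[a, s]
    raw = lms.value_from_sds_arrays(L, M, S, z, clip_domain=True)
    sbp = raw + p.sbp_bmi_slope * np.maximum(0.0, state.bmi - p.sbp_bmi_ref)
    state.sbp = sbp
    state.sbp_sds = lms.sds_from_value_arrays(L, M, S, sbp)
    return state


def draw_ht_drug(state: PopulationState, mask: np.ndarray, p: ParameterSet, rng: CRNStream) -> None:
    """One-time antihypertensive drug allocation for newly hypertensive individuals.

    The draw is keyed by individual id only, so an individual receives
    the same drug regardless of the year hypertension is reached.
    """
    if not mask.any():
        return
    c = p.compiled()
    u = rng.uniform(Event.HT_DRUG, 0, state.ids[mask])
    drug = np.searchsorted(c.ht_drug_cum, u, side="right").astype(np.int8)
    state.ht_drug[mask] = drug
    state.on_raas_blocker[mask] |= (drug == DRUG_ACEI) | (drug == DRUG_ARB)


def assign_hypertension_therapy(state: PopulationState, p: ParameterSet, rng: CRNStream) -> PopulationState:
    """Hypertension = SBP strictly above threshold; drug drawn once."""
    state.hypertensive = state.sbp > p.sbp_hypertension_threshold
    draw_ht_drug(state, state.hypertensive & (state.ht_drug == DRUG_UNASSIGNED), p, rng)
    return state


def assign_diabetes_prevalent(state: PopulationState, p: ParameterSet, rng: CRNStream) -> PopulationState:
    """Prevalent diabetes via the baseline-risk decomposition.

    The marginal age/sex prevalence is decomposed so that strata defined
    by obesity (BMI > 30) and hypertension carry their relative risks
    while the population mixture reproduces the marginal exactly.
    """
    from .progression import scaled_probability_by_cell  # local import, no cycle

    c = p.compiled()
    rr = np.where(state.bmi > p.bmi_obesity_threshold, p.rr_diabetes_obesity, 1.0) * np.where(
        state.hypertensive, p.rr_diabetes_hypertension, 1.0
    )
    prob, capped = scaled_probability_by_cell(c.diab_prev, state, rr, np.ones(state.n, dtype=bool))
    state.capped_prob_events += capped
    u = rng.uniform(Event.DIABETES_PREVALENT, 0, state.ids)
    state.diabetes = u < prob
    return state


# ---------------------------------------------------------------------------
# renal state
# ---------------------------------------------------------------------------


def _truncated_normal_above(mean, sd, lower, u):
    """Inverse-CDF sample of N(mean, sd) truncated to (lower, inf)."""
    a = ndtr((lower - mean) / sd)
    return mean + sd * ndtri(np.clip(a + u * (1.0 - a), 1e-12, 1 - 1e-12))


def _init_renal_age30(state: PopulationState, p: ParameterSet, rng: CRNStream) -> PopulationState:
    """Renal state at age 30 straight from the stratified input tables."""
    c = p.compiled()
    s = state.sex.astype(int)
    dm = state.diabetes.astype(int)
    hi = (state.sbp >= p.sbp_hypertension_threshold).astype(int)
    mean, sd = c.gfr_init_mean[s, dm, hi], c.gfr_init_sd[s, dm, hi]
    u = rng.uniform(Event.GFR_INIT, 0, state.ids)
    state.gfr = _truncated_normal_above(mean, sd, p.gfr_rrt_threshold, u)
    u2 = rng.uniform(Event.ALBUMINURIA_INIT, 0, state.ids)
    p_mac, p_mic = c.alb_prev30_macro[s, dm, hi], c.alb_prev30_micro[s, dm, hi]
    state.albuminuria = np.where(u2 < p_mac, 2, np.where(u2 < p_mac + p_mic, 1, 0)).astype(np.int8)
    _draw_loss_factor(state, p, rng)
    return state


def _draw_loss_factor(state: PopulationState, p: ParameterSet, rng: CRNStream) -> None:
    sigma = p.gfr_loss_factor_sigma
    z = rng.normal(Event.GFR_LOSS_FACTOR, 0, state.ids)
    factor = np.exp(sigma * z - 0.5 * sigma**2)  # mean-1 lognormal heterogeneity
    state.gfr_loss_factor = factor * p.gfr_loss_calibration_scale


def derive_renal_age_profiles(
    p: ParameterSet, cohort_size: int, rng: CRNStream, with_mortality: bool = True
) -> RenalAgeProfile:
    """Pre-simulate an age-30 cohort to tabulate renal state by attained age.

    The renal input tables are only valid at age 30, so a cohort of
    ``cohort_size`` individuals is started at 30 and progressed (no
    screening) to the age cap; surviving, non-RRT individuals supply the
    GFR moments and albuminuria prevalences used to initialize older
    starting ages.  Ages 18-29 copy the age-30 row.  Empty cells (thin
    old-age strata in small cohorts) carry the previous age forward.
    """
    from . import progression  # deferred: progression imports this module

    prng = rng.spawn(1)  # profile cohort owns an independent stream family
    ids = np.arange(cohort_size, dtype=np.int64)
    pop = p.population_age_sex
    sex_share_m = pop.loc[pop["sex"] == "M", "share"].sum()
    u = prng.uniform(Event.AGE_SEX, 0, ids)
    state = PopulationState(
        ids=ids,
        age=np.full(cohort_size, 30, dtype=np.int16),
        sex=(u < sex_share_m).astype(np.int8),
    )
    assign_bmi(state, p, prng)
    assign_sbp(state, p, prng)
    assign_hypertension_therapy(state, p, prng)
    assign_diabetes_prevalent(state, p, prng)
    _init_renal_age30(state, p, prng)

    cap = int(p.age_cap)
    rows = []

    def tabulate(age):
        for sex in (0, 1):
            m = state.active & ~state.on_rrt & (state.age == age) & (state.sex == sex)
            cnt = int(m.sum())
            if cnt >= 2:
                g = state.gfr[m]
                rows.append(
                    {"age": age, "sex": "F" if sex == 0 else "M",
                     "gfr_mean": g.mean(), "gfr_sd": max(g.std(), 1e-6),
                     "p_micro": float((state.albuminuria[m] == 1).mean()),
                     "p_macro": float((state.albuminuria[m] == 2).mean())}
                )
            elif rows:
                prev = next(r for r in reversed(rows) if r["sex"] == ("F" if sex == 0 else "M"))
                rows.append({**prev, "age": age})
            else:
                raise RuntimeError("profile cohort extinct at age 30")

    tabulate(30)
    for _ in range(30, cap):
        if not state.active.any():
            raise RuntimeError(f"profile cohort extinct before age {cap}")
        progression.update_anthropometrics(state, p, prng)
        progression.update_diabetes_incidence(state, p, prng)
        progression.update_albuminuria(state, p, prng)
        progression.update_gfr(state, p, prng)
        progression.check_rrt(state, p)
        if with_mortality:
            progression.apply_mortality(state, p, prng)
        tabulate(int(state.age.max()))
        state.censored |= state.age >= cap
        state.t += 1

    table = pd.DataFrame(rows)
    age30 = table[table["age"] == 30]
    young = pd.concat(
        [age30.assign(age=a) for a in range(18, 30)], ignore_index=True
    )
    table = pd.concat([young, table], ignore_index=True).sort_values(["age", "sex"]).reset_index(drop=True)
    return RenalAgeProfile(table=table)


def initialize_renal_state(
    state: PopulationState, profile: RenalAgeProfile, p: ParameterSet, rng: CRNStream
) -> PopulationState:
    """Draw GFR, albuminuria and the individual GFR-loss factor from the profile.

    The individual annual-loss multiplier is drawn from its lognormal
    distribution and scaled by ``gfr_loss_calibration_scale`` (0.75).
    """
    a, s = state.age.astype(int), state.sex.astype(int)
    mean, sd = profile.gfr_mean[a, s], profile.gfr_sd[a, s]
    if np.any(np.isnan(mean)):
        missing = sorted(set(state.age[np.isnan(mean)].tolist()))
        raise ValueError(f"renal age profile missing rows for ages {missing[:10]}")
    u = rng.uniform(Event.GFR_INIT, 0, state.ids)
    state.gfr = _truncated_normal_above(mean, sd, p.gfr_rrt_threshold, u)
    u2 = rng.uniform(Event.ALBUMINURIA_INIT, 0, state.ids)
    p_mac, p_mic = profile.p_macro[a, s], profile.p_micro[a, s]
    state.albuminuria = np.where(u2 < p_mac, 2, np.where(u2 < p_mac + p_mic, 1, 0)).astype(np.int8)
    _draw_loss_factor(state, p, rng)
    return state


def build_initial_population(
    n: int, p: ParameterSet, profile: RenalAgeProfile, rng: CRNStream
) -> PopulationState:
    """Full initialization pipeline for the shared starting cohort."""
    state = sample_age_sex(n, p, rng)
    assign_bmi(state, p, rng)
    assign_sbp(state, p, rng)
    assign_hypertension_therapy(state, p, rng)
    assign_diabetes_prevalent(state, p, rng)
    initialize_renal_state(state, profile, p, rng)
    return state
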