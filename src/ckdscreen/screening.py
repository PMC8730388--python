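"""Albuminuria screening cascade and therapy initiation.

A scenario selects who is tested (individuals with diabetes, with
diabetes or hypertension, or everyone), at a fixed interval, excluding
anyone already on a renin-angiotensin blocker and anyone who ever tested
positive.  A testing occasion is a two-times repeated urinary
albumin-creatinine test within the same annual follow-up: each repeat is
positive with probability = sensitivity (0.87) for albuminuric
individuals and 1 - specificity (0.12) otherwise, and therapy starts
only if both repeats are positive.  Every positive — including false
positives — starts lifelong ACEI with a one-time adherence draw; only
adherent, truly albuminuric individuals gain the clinical effects, but
everyone on therapy accrues medication costs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import CRNStream, Event
from .params import ParameterSet, ScenarioSpec
from .population import PopulationState

__all__ = ["TestOutcomes", "select_eligible", "perform_test", "apply_positive_result"]


@dataclass
class TestOutcomes:
    """Per-individual outcome of one testing occasion."""

    tested: np.ndarray
    positive: np.ndarray
    true_state: np.ndarray  # albuminuric (micro or macro) at test time
    cost_incurred: np.ndarray  # EUR, one occasion charge per tested individual


def select_eligible(state: PopulationState, scenario: ScenarioSpec, year_index: int) -> np.ndarray:
    """Eligibility mask for this cycle's testing occasion.

    Eligible = alive, not censored, matching the scenario rule, not on a
    renin-angiotensin blocker (if the scenario excludes them), never
    tested positive before, not on RRT, and the year index falls on the
    testing interval.
    """
    if scenario.eligibility == "none" or year_index % scenario.testing_interval_years != 0:
        return np.zeros(state.n, dtype=bool)
    if scenario.eligibility == "diabetes":
        rule = state.diabetes
    elif scenario.eligibility == "diabetes-or-hypertension":
        rule = state.diabetes | state.hypertensive
    else:  # "all"
        rule = np.ones(state.n, dtype=bool)
    mask = state.active & rule & ~state.tested_positive & ~state.on_rrt
    if scenario.exclude_if_on_raas_blocker:
        mask &= ~state.on_raas_blocker
    return mask


def perform_test(
    state: PopulationState, mask: np.ndarray, p: ParameterSet, rng: CRNStream
) -> TestOutcomes:
    """Run the repeated test on the masked individuals.

    Repeats are independent conditional on the true albuminuria state;
    the occasion is positive only if every repeat is positive.  One
    occasion cost is charged per tested individual.
    """
    albuminuric = state.albuminuria > 0
    p_pos = np.where(albuminuric, p.test_sensitivity, 1.0 - p.test_specificity)
    repeats = int(p.test_repeats)
    if repeats > 2:
        raise NotImplementedError("at most two test repeats are supported")
    positive = mask.copy()
    for event in (Event.TEST_1, Event.TEST_2)[:repeats]:
        u = rng.uniform(event, state.t, state.ids)
        positive &= u < p_pos
    cost = np.where(mask, p.c_test_occasion, 0.0)
    return TestOutcomes(tested=mask, positive=positive, true_state=albuminuric, cost_incurred=cost)


def apply_positive_result(
    state: PopulationState, outcomes: TestOutcomes, p: ParameterSet, rng: CRNStream
) -> PopulationState:
    """Start lifelong ACEI for every positive; adherence drawn once.

    ``tested_positive`` is sticky (positives are never re-tested);
    medication costs accrue from this cycle until death or the age cap
    regardless of adherence.
    """
    pos = outcomes.positive
    if not pos.any():
        return state
    state.tested_positive |= pos
    state.false_positive |= pos & ~outcomes.true_state
    state.acei_from_test |= pos
    state.on_raas_blocker |= pos
    u = rng.uniform(Event.ADHERENCE, 0, state.ids)
    state.adherent |= pos & (u < p.adherence_prob)
    return state
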