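"""Annual-cycle mechanics: baseline-risk solver, GFR decline, RRT, mortality."""

import numpy as np
import pytest

from ckdscreen import CRNStream, solve_baseline_risk, stage_from_gfr
from ckdscreen.params import ScenarioSpec
from ckdscreen.progression import (
    advance_year,
    apply_mortality,
    check_rrt,
    update_anthropometrics,
    update_gfr,
)

RNG = CRNStream(13)
BASE = ScenarioSpec("base", "none")


class TestBaselineRisk:
    @pytest.mark.parametrize(
        "marginal, strata, expected",
        [
            (0.10, [(0.5, 1.0), (0.5, 3.0)], 0.05),
            (0.13, [(0.7, 1.0), (0.3, 2.0)], 0.10),
            (0.10, [(1.0, 1.0)], 0.10),  # all RR=1 -> baseline is the marginal
        ],
    )
    def test_closed_forms(self, marginal, strata, expected):
        r0 = solve_baseline_risk(marginal, strata)
        assert r0 == pytest.approx(expected, abs=1e-12)
        # mixture identity is exact
        assert sum(s * rr * r0 for s, rr in strata) == pytest.approx(marginal, abs=1e-12)

    def test_zero_risk_with_positive_marginal_errors(self):
        with pytest.raises(ValueError):
            solve_baseline_risk(0.1, [(1.0, 0.0)])

    def test_exposed_probability_example(self):
        # marginal 0.10 over strata {(0.5, RR 3), (0.5, RR 1)}:
        # baseline 0.05, exposed group 0.15
        r0 = solve_baseline_risk(0.10, [(0.5, 3.0), (0.5, 1.0)])
        assert r0 * 3.0 == pytest.approx(0.15)


class TestStages:
    def test_gfr_band_edges(self):
        gfr = np.array([95.0, 90.0, 89.9, 60.0, 59.9, 45.0, 44.9, 30.0, 29.9, 15.0, 14.9, 5.0])
        expected = [0, 0, 1, 1, 2, 2, 3, 3, 4, 4, 5, 5]
        assert stage_from_gfr(gfr).tolist() == expected


class TestAnthropometrics:
    def test_aging_tracks_percentile(self, params, initial_pop):
        state = initial_pop.clone()
        c = params.compiled()
        before_sds = state.bmi_sds.copy()
        update_anthropometrics(state, params, RNG)
        np.testing.assert_array_equal(state.bmi_sds, before_sds)  # SDS is lifelong
        act = state.active
        a, s = state.age[act], state.sex[act]
        from ckdscreen import lms

        np.testing.assert_allclose(
            state.bmi[act],
            lms.value_from_sds_arrays(c.bmi_L[a, s], c.bmi_M[a, s], c.bmi_S[a, s],
                                      state.bmi_sds[act], clip_domain=True),
        )

    def test_dead_individuals_do_not_age(self, params, initial_pop):
        state = initial_pop.clone()
        state.alive[:100] = False
        ages = state.age[:100].copy()
        update_anthropometrics(state, params, RNG)
        np.testing.assert_array_equal(state.age[:100], ages)


class TestGfrDecline:
    def test_treatment_effect_closed_form(self, params, initial_pop):
        # base loss 2.0, factor 0.75, e_gfr 0.3 -> treated loss 1.05
        state = initial_pop.clone()
        i = 0
        state.albuminuria[i] = 1
        state.acei_from_test[i] = True
        state.adherent[i] = True
        state.gfr_loss_factor[i] = 0.75
        state.gfr[i] = 80.0
        gl = params.gfr_annual_loss.copy()
        gl["base_loss"] = 2.0
        p2 = params.replace(gfr_annual_loss=gl).with_scalars(gfr_loss_age_coef=0.0, acei_e_gfr=0.3)
        update_gfr(state, p2, RNG)
        assert state.gfr[i] == pytest.approx(80.0 - 2.0 * 0.75 * 0.7)

    def test_null_effect_leaves_treated_equal(self, params, initial_pop):
        a = initial_pop.clone()
        b = initial_pop.clone()
        b.acei_from_test[:] = True
        b.adherent[:] = True
        p2 = params.with_scalars(acei_e_gfr=0.0)
        update_gfr(a, p2, RNG)
        update_gfr(b, p2, RNG)
        np.testing.assert_array_equal(a.gfr, b.gfr)

    def test_gfr_floor_at_zero(self, params, initial_pop):
        state = initial_pop.clone()
        state.gfr[:] = 0.5
        state.gfr_loss_factor[:] = 10.0
        update_gfr(state, params, RNG)
        assert (state.gfr[state.active] == 0.0).all()


class TestRrt:
    def test_strict_threshold(self, params, initial_pop):
        state = initial_pop.clone()
        state.gfr[:3] = [6.9, 7.0, 7.1]
        check_rrt(state, params)
        assert state.on_rrt[:3].tolist() == [True, False, False]
        assert state.age_at_rrt[0] == state.age[0]

    def test_rrt_absorbing(self, params, initial_pop):
        state = initial_pop.clone()
        state.gfr[0] = 5.0
        check_rrt(state, params)
        age_first = state.age_at_rrt[0]
        state.age[0] += 1
        check_rrt(state, params)
        assert state.age_at_rrt[0] == age_first


class TestMortality:
    def test_risk_product(self, params):
        from ckdscreen.progression import death_probability
        from ckdscreen.population import sample_age_sex

        state = sample_age_sex(1, params, RNG)
        state.age[:] = 60
        state.sex[:] = 0
        state.gfr[:] = 50.0  # G3a
        state.albuminuria[:] = 0
        rr = params.rr_death_ckd.query("stage == 'G3a' and albuminuria == 'none'")["rr"].iloc[0]
        q_base = params.life_table.query("age == 60 and sex == 'F'")["q"].iloc[0]
        q = death_probability(state, params)
        assert q[0] == pytest.approx(q_base * rr)

    def test_probability_capped_at_one(self, params):
        from ckdscreen.progression import death_probability
        from ckdscreen.population import sample_age_sex

        p2 = params.with_scalars(mortality_calibration_factor=500.0)
        state = sample_age_sex(10, p2, RNG)
        state.gfr[:] = 50.0
        q = death_probability(state, p2)
        assert (q <= 1.0).all() and (q == 1.0).any()
        assert state.capped_prob_events > 0

    def test_life_table_reproduced_when_rrs_are_unit(self, params, profile):
        """With all CKD RRs at 1 and null therapy effects, realized deaths
        match the life-table expectation on the same person-years."""
        from ckdscreen.population import build_initial_population

        rr1 = params.rr_death_ckd.copy()
        rr1["rr"] = 1.0
        p2 = params.replace(rr_death_ckd=rr1).with_scalars(
            acei_rr_death=1.0, mortality_calibration_factor=1.0
        )
        state = build_initial_population(30_000, p2, profile, CRNStream(2))
        stats = {}
        for _ in range(30):
            advance_year(state, p2, BASE, CRNStream(2), stats=stats)
        expected = stats["expected_deaths_lifetable"]
        observed = stats["deaths"]
        assert abs(observed - expected) < 4 * np.sqrt(expected)


class TestInvariants:
    def test_monotone_and_absorbing_over_cycles(self, params, initial_pop):
        state = initial_pop.clone()
        rng = CRNStream(1)
        prev_gfr = state.gfr.copy()
        prev_alb = state.albuminuria.copy()
        prev_dm = state.diabetes.copy()
        prev_dead = ~state.alive
        prev_rrt = state.on_rrt.copy()
        for _ in range(25):
            advance_year(state, params, BASE, rng)
            assert (state.gfr <= prev_gfr + 1e-12).all()
            assert (state.albuminuria >= prev_alb).all()
            assert (state.diabetes | ~prev_dm).all()
            assert (state.alive | prev_dead | ~state.alive).all()  # death absorbing
            assert not (prev_dead & state.alive).any()
            assert (state.on_rrt | ~prev_rrt).all()
            prev_gfr = state.gfr.copy()
            prev_alb = state.albuminuria.copy()
            prev_dm = state.diabetes.copy()
            prev_dead = ~state.alive
            prev_rrt = state.on_rrt.copy()

    def test_cycle_deterministic(self, params, initial_pop):
        a, b = initial_pop.clone(), initial_pop.clone()
        for _ in range(5):
            advance_year(a, params, BASE, CRNStream(1))
            advance_year(b, params, BASE, CRNStream(1))
        np.testing.assert_array_equal(a.gfr, b.gfr)
        np.testing.assert_array_equal(a.alive, b.alive)
        np.testing.assert_array_equal(a.qaly_disc, b.qaly_disc)

    def test_all_dead_population_is_inert(self, params, initial_pop):
        state = initial_pop.clone()
        state.alive[:] = False
        snapshot = {k: getattr(state, k).copy() for k in
                    ("gfr", "albuminuria", "qaly_undisc", "cost_rrt_undisc", "age")}
        advance_year(state, params, BASE, CRNStream(1))
        for k, v in snapshot.items():
            np.testing.assert_array_equal(getattr(state, k), v)

    def test_stage_occupancy_accumulates(self, params, initial_pop):
        state = initial_pop.clone()
        rng = CRNStream(1)
        for _ in range(30):
            advance_year(state, params, BASE, rng)
        assert (state.years_stage3a5 >= 0).all()
        assert state.years_stage3a5.max() > 0  # someone spends time in CKD 3a-5
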