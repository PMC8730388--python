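"""Initial-cohort synthesis: sampling, SDS machinery, renal profiles."""

import numpy as np
import pytest

from ckdscreen import CRNStream, lms
from ckdscreen.population import (
    DRUG_ACEI,
    DRUG_ARB,
    assign_bmi,
    assign_diabetes_prevalent,
    assign_hypertension_therapy,
    assign_sbp,
    build_initial_population,
    derive_renal_age_profiles,
    initialize_renal_state,
    sample_age_sex,
)

RNG = CRNStream(7)


class TestSampleAgeSex:
    def test_frequencies_converge_to_table(self, params):
        n = 200_000
        state = sample_age_sex(n, params, RNG)
        pop = params.population_age_sex
        within = 0
        for _, row in pop.iterrows():
            share = row["share"]
            obs = np.mean((state.age == row["age"]) & (state.sex == (0 if row["sex"] == "F" else 1)))
            bound = 3 * np.sqrt(share * (1 - share) / n)
            within += abs(obs - share) <= bound
        assert within / len(pop) >= 0.97  # ~99% expected inside a 3-sigma band

    def test_single_individual_valid(self, params):
        state = sample_age_sex(1, params, RNG)
        assert 18 <= state.age[0] <= 90
        assert state.sex[0] in (0, 1)

    def test_degenerate_table(self, params):
        pop = params.population_age_sex.copy()
        pop["share"] = 0.0
        pop.loc[(pop["age"] == 40) & (pop["sex"] == "F"), "share"] = 1.0
        p2 = params.replace(population_age_sex=pop)
        state = sample_age_sex(500, p2, RNG)
        assert (state.age == 40).all() and (state.sex == 0).all()

    def test_rejects_empty_cohort(self, params):
        with pytest.raises(ValueError):
            sample_age_sex(0, params, RNG)


class TestBmiSbp:
    def test_bmi_sds_zero_gives_median(self, params):
        state = sample_age_sex(100, params, RNG)
        assign_bmi(state, params, RNG)
        state.bmi_sds[:] = 0.0
        c = params.compiled()
        state.bmi = lms.value_from_sds_arrays(
            c.bmi_L[state.age, state.sex], c.bmi_M[state.age, state.sex],
            c.bmi_S[state.age, state.sex], state.bmi_sds,
        )
        np.testing.assert_allclose(state.bmi, c.bmi_M[state.age, state.sex])

    def test_bmi_sds_mean_near_zero(self, params):
        state = sample_age_sex(100_000, params, RNG)
        assign_bmi(state, params, RNG)
        assert abs(state.bmi_sds.mean()) < 0.01 * np.sqrt(10)

    def test_sbp_sds_equals_draw_without_adjustment(self, params):
        p2 = params.with_scalars(sbp_bmi_slope=0.0, sbp_mu_shift=0.0)
        state = sample_age_sex(5000, p2, RNG)
        assign_bmi(state, p2, RNG)
        assign_sbp(state, p2, RNG)
        from ckdscreen._rng import Event
        from ckdscreen.population import SDS_TRUNC

        z = np.clip(RNG.normal(Event.SBP_Z, 0, state.ids), -SDS_TRUNC, SDS_TRUNC)
        np.testing.assert_allclose(state.sbp_sds, z, atol=1e-8)

    def test_bmi_elevation_raises_definitive_sds(self, params):
        state = sample_age_sex(20_000, params, RNG)
        assign_bmi(state, params, RNG)
        assign_sbp(state, params, RNG)
        from ckdscreen._rng import Event
        from ckdscreen.population import SDS_TRUNC

        z = params.sbp_mu_shift + np.clip(
            RNG.normal(Event.SBP_Z, 0, state.ids), -SDS_TRUNC, SDS_TRUNC
        )
        heavy = state.bmi > params.sbp_bmi_ref
        assert (state.sbp_sds[heavy] > z[heavy]).all()
        np.testing.assert_allclose(state.sbp_sds[~heavy], z[~heavy], atol=1e-8)


class TestHypertensionDiabetes:
    def _state(self, params, sbp_values):
        state = sample_age_sex(len(sbp_values), params, RNG)
        state.sbp = np.asarray(sbp_values, float)
        return state

    def test_threshold_is_strict(self, params):
        state = self._state(params, [141.0, 140.0, 139.0])
        assign_hypertension_therapy(state, params, RNG)
        assert state.hypertensive.tolist() == [True, False, False]

    def test_drug_assigned_once_and_raas_flag(self, params):
        state = sample_age_sex(50_000, params, RNG)
        assign_bmi(state, params, RNG)
        assign_sbp(state, params, RNG)
        assign_hypertension_therapy(state, params, RNG)
        ht = state.hypertensive
        assert (state.ht_drug[~ht] == -1).all()
        raas = (state.ht_drug == DRUG_ACEI) | (state.ht_drug == DRUG_ARB)
        assert (state.on_raas_blocker == raas).all()
        # allocated shares follow the drug distribution
        probs = params.compiled().ht_drug_probs
        for code, p_exp in enumerate(probs):
            obs = (state.ht_drug[ht] == code).mean()
            assert obs == pytest.approx(p_exp, abs=4 * np.sqrt(p_exp * (1 - p_exp) / ht.sum()))

    def test_diabetes_without_hypertension_gets_no_raas(self, params):
        state = sample_age_sex(20_000, params, RNG)
        assign_bmi(state, params, RNG)
        assign_sbp(state, params, RNG)
        assign_hypertension_therapy(state, params, RNG)
        assign_diabetes_prevalent(state, params, RNG)
        assert not state.on_raas_blocker[state.diabetes & ~state.hypertensive].any()

    def test_unit_relative_risks_reproduce_marginal(self, params):
        p2 = params.with_scalars(rr_diabetes_obesity=1.0, rr_diabetes_hypertension=1.0)
        state = sample_age_sex(100_000, p2, RNG)
        assign_bmi(state, p2, RNG)
        assign_sbp(state, p2, RNG)
        assign_hypertension_therapy(state, p2, RNG)
        assign_diabetes_prevalent(state, p2, RNG)
        c = p2.compiled()
        expected = c.diab_prev[state.age.astype(int), state.sex.astype(int)].mean()
        obs = state.diabetes.mean()
        assert obs == pytest.approx(expected, abs=4 * np.sqrt(expected * (1 - expected) / state.n))

    def test_zero_marginal_means_no_diabetes(self, params):
        zero = params.diabetes_prevalence.copy()
        zero["prob"] = 0.0
        p2 = params.replace(diabetes_prevalence=zero)
        state = sample_age_sex(5000, p2, RNG)
        assign_bmi(state, p2, RNG)
        assign_sbp(state, p2, RNG)
        assign_hypertension_therapy(state, p2, RNG)
        assign_diabetes_prevalent(state, p2, RNG)
        assert not state.diabetes.any()


class TestRenalProfiles:
    def test_young_ages_copy_age_30(self, profile):
        t = profile.table
        for sex in ("F", "M"):
            ref = t[(t["age"] == 30) & (t["sex"] == sex)].iloc[0]
            for age in range(18, 30):
                row = t[(t["age"] == age) & (t["sex"] == sex)].iloc[0]
                assert row["gfr_mean"] == ref["gfr_mean"]
                assert row["p_micro"] == ref["p_micro"]

    def test_profile_covers_all_ages(self, profile):
        assert set(profile.table["age"]) == set(range(18, 91))

    def test_albuminuria_monotone_without_mortality_or_loss(self, params):
        # freeze GFR decline so nobody leaves via RRT, and skip mortality:
        # with irreversible progression the prevalence must be non-decreasing
        p2 = params.with_scalars(gfr_loss_calibration_scale=0.0)
        prof = derive_renal_age_profiles(p2, 4000, CRNStream(3), with_mortality=False)
        t = prof.table[prof.table["age"] >= 30]
        for sex in ("F", "M"):
            prev = (t[t["sex"] == sex].sort_values("age")["p_micro"]
                    + t[t["sex"] == sex].sort_values("age")["p_macro"]).to_numpy()
            assert (np.diff(prev) >= -1e-12).all()

    def test_cohort_size_consistency(self, params, profile):
        small = derive_renal_age_profiles(params, 5000, CRNStream(11))
        for age in (40, 60):
            for sex in ("F", "M"):
                a = profile.table.query("age == @age and sex == @sex").iloc[0]
                b = small.table.query("age == @age and sex == @sex").iloc[0]
                # binomial-ish sampling agreement on prevalence and GFR mean
                assert abs(a["p_micro"] - b["p_micro"]) < 0.05
                assert abs(a["gfr_mean"] - b["gfr_mean"]) < 3.0


class TestInitializeRenal:
    def test_calibration_scale_applied(self, params, profile):
        state = sample_age_sex(5000, params, RNG)
        p_scaled = params.with_scalars(gfr_loss_factor_sigma=0.0)  # factor exactly 1
        initialize_renal_state(state, profile, p_scaled, RNG)
        np.testing.assert_allclose(state.gfr_loss_factor, 0.75)
        p_noscale = p_scaled.with_scalars(gfr_loss_calibration_scale=1.0)
        initialize_renal_state(state, profile, p_noscale, RNG)
        np.testing.assert_allclose(state.gfr_loss_factor, 1.0)

    def test_gfr_follows_profile_moments(self, params, profile):
        pop = params.population_age_sex.copy()
        pop["share"] = 0.0
        pop.loc[(pop["age"] == 50) & (pop["sex"] == "M"), "share"] = 1.0
        p2 = params.replace(population_age_sex=pop)
        state = sample_age_sex(50_000, p2, RNG)
        initialize_renal_state(state, profile, p2, RNG)
        row = profile.table.query("age == 50 and sex == 'M'").iloc[0]
        assert state.gfr.mean() == pytest.approx(row["gfr_mean"], abs=0.2)
        assert state.gfr.std() == pytest.approx(row["gfr_sd"], abs=0.3)
        assert (state.gfr > params.gfr_rrt_threshold).all()
        obs_micro = (state.albuminuria == 1).mean()
        assert obs_micro == pytest.approx(row["p_micro"], abs=0.01)


def test_same_seed_bit_identical_population(params, profile):
    a = build_initial_population(5000, params, profile, CRNStream(5))
    b = build_initial_population(5000, params, profile, CRNStream(5))
    for name in ("age", "sex", "bmi", "sbp", "gfr", "albuminuria", "diabetes", "gfr_loss_factor"):
        np.testing.assert_array_equal(getattr(a, name), getattr(b, name))
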