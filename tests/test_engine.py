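import dataclasses

import numpy as np
import pytest

from savm import ScenarioParams, UseState, run_scenario
from savm.engine import (
    N_STATES,
    CountryRates,
    init_no_nvp,
    step_no_nvp,
    step_nvp,
)
from savm.outcomes import build_excess_map
from savm.tables import AgeGenderYearTable


def cell(values_by_state):
    """(n_states, 1, 2) single-cell occupancy with equal genders."""
    occ = np.zeros((N_STATES, 1, 2))
    for state, v in values_by_state.items():
        occ[state] = v
    return occ


def flows(value):
    return np.full((1, 2), float(value))


def mu_cell(by_state, default=0.0):
    mu = np.full((N_STATES, 1, 2), float(default))
    for state, v in by_state.items():
        mu[state] = v
    return mu


class TestInitialOccupancy:
    def test_former_under_35_is_low_risk(self, small_bundles):
        country, _ = small_bundles
        occ = init_no_nvp(country)
        ages = country.ages
        young = ages < 35
        assert (occ[UseState.FORMER_SMOKER, young] == 0).all()
        assert (occ[UseState.FORMER_SMOKER_LOWRISK, ~young] == 0).all()
        former = country.smoking_prevalence_base["former"].values[:, :, 0]
        np.testing.assert_allclose(occ[UseState.FORMER_SMOKER_LOWRISK, young], former[young])
        np.testing.assert_allclose(occ[UseState.FORMER_SMOKER, ~young], former[~young])

    def test_shares_sum_to_one(self, small_bundles):
        occ = init_no_nvp(small_bundles[0])
        np.testing.assert_allclose(occ.sum(axis=0), 1.0, atol=1e-12)


class TestStepNoNvp:
    def test_no_flows_equal_mortality_is_identity(self):
        occ = cell({UseState.NEVER: 0.6, UseState.CURRENT_SMOKER: 0.3,
                    UseState.FORMER_SMOKER: 0.1})
        out = step_no_nvp(occ, flows(0.0), flows(0.0), mu_cell({}, 0.02),
                          lowrisk=np.array([False]))
        np.testing.assert_allclose(out, occ, atol=1e-15)

    def test_pure_initiation(self):
        occ = cell({UseState.NEVER: 1.0})
        out = step_no_nvp(occ, flows(0.1), flows(0.0), mu_cell({}, 0.01),
                          lowrisk=np.array([False]))
        assert out[UseState.NEVER, 0, 0] == pytest.approx(0.9)
        assert out[UseState.CURRENT_SMOKER, 0, 0] == pytest.approx(0.1)

    def test_single_step_matches_hand_calculation(self):
        # survivors: never .6*.99=.594, current .3*.97=.291, former .1*.98=.098
        # transitions: init .05 -> never .5643, current .2916; cess .1 -> former .1271
        # renormalize by the survivor total .983
        occ = cell({UseState.NEVER: 0.6, UseState.CURRENT_SMOKER: 0.3,
                    UseState.FORMER_SMOKER: 0.1})
        mu = mu_cell({UseState.NEVER: 0.01, UseState.CURRENT_SMOKER: 0.03,
                      UseState.FORMER_SMOKER: 0.02})
        out = step_no_nvp(occ, flows(0.05), flows(0.1), mu, lowrisk=np.array([False]))
        never_s, cur_s, form_s = 0.6 * 0.99, 0.3 * 0.97, 0.1 * 0.98
        never = never_s * 0.95
        current = cur_s * 0.9 + never_s * 0.05
        former = form_s + cur_s * 0.1
        total = never + current + former
        assert out[UseState.NEVER, 0, 0] == pytest.approx(never / total)
        assert out[UseState.CURRENT_SMOKER, 0, 0] == pytest.approx(current / total)
        assert out[UseState.FORMER_SMOKER, 0, 0] == pytest.approx(former / total)

    def test_quit_routing_follows_age35_rule(self):
        occ = cell({UseState.CURRENT_SMOKER: 1.0})
        young = step_no_nvp(occ, flows(0.0), flows(0.2), mu_cell({}),
                            lowrisk=np.array([True]))
        old = step_no_nvp(occ, flows(0.0), flows(0.2), mu_cell({}),
                          lowrisk=np.array([False]))
        assert young[UseState.FORMER_SMOKER_LOWRISK, 0, 0] == pytest.approx(0.2)
        assert young[UseState.FORMER_SMOKER, 0, 0] == 0
        assert old[UseState.FORMER_SMOKER, 0, 0] == pytest.approx(0.2)
        assert old[UseState.FORMER_SMOKER_LOWRISK, 0, 0] == 0


class TestStepNvp:
    def test_null_nvp_flows_match_no_nvp_bitwise(self, rng):
        occ = rng.dirichlet(np.ones(4), size=2).T.reshape(4, 1, 2)
        full = np.zeros((N_STATES, 1, 2))
        full[:4] = occ
        mu = mu_cell({UseState.CURRENT_SMOKER: 0.03, UseState.FORMER_SMOKER: 0.015})
        a = step_no_nvp(full, flows(0.04), flows(0.08), mu, np.array([False]))
        b = step_nvp(full, flows(0.04), flows(0.0), flows(0.08), flows(0.0),
                     flows(0.0), mu, np.array([False]))
        np.testing.assert_array_equal(a, b)

    def test_switching_routes_by_age(self):
        occ = cell({UseState.CURRENT_SMOKER: 1.0})
        out = step_nvp(occ, flows(0.0), flows(0.0), flows(0.1), flows(0.0),
                       flows(0.02), mu_cell({}), np.array([False]))
        assert out[UseState.CURRENT_SMOKER, 0, 0] == pytest.approx(0.88)
        assert out[UseState.FORMER_SMOKER, 0, 0] == pytest.approx(0.10)
        assert out[UseState.FS_NVP_USER, 0, 0] == pytest.approx(0.02)
        young = step_nvp(occ, flows(0.0), flows(0.0), flows(0.1), flows(0.0),
                         flows(0.02), mu_cell({}), np.array([True]))
        assert young[UseState.NVP_EXSMOKER_LOWRISK, 0, 0] == pytest.approx(0.02)

    def test_vaping_cessation_routes_to_former_states(self):
        occ = cell({UseState.NVP_USER: 0.3, UseState.NVP_EXSMOKER_LOWRISK: 0.3,
                    UseState.FS_NVP_USER: 0.4})
        out = step_nvp(occ, flows(0.0), flows(0.0), flows(0.0), flows(0.5),
                       flows(0.0), mu_cell({}), np.array([False]))
        assert out[UseState.FORMER_NVP_USER, 0, 0] == pytest.approx(0.3)
        assert out[UseState.FORMER_NVP_EXSMOKER, 0, 0] == pytest.approx(0.2)
        assert out[UseState.FS_NVP_USER, 0, 0] == pytest.approx(0.2)


class TestRunScenario:
    def test_share_conservation_everywhere(self, germany_results):
        for traj in (germany_results.trajectory_no_nvp, germany_results.trajectory_nvp):
            np.testing.assert_allclose(traj.share.sum(axis=1), 1.0, atol=1e-9)

    def test_counts_match_projection(self, germany_model, germany_results):
        traj = germany_results.trajectory_nvp
        pop = germany_model.country.population.values.transpose(2, 0, 1)
        np.testing.assert_allclose(traj.count.sum(axis=1), pop, rtol=1e-6)

    def test_null_nvp_trajectories_bitwise_identical(self, small_model, null_params):
        a = small_model.run_no_nvp(null_params)
        b = small_model.run_nvp(null_params)
        assert np.array_equal(a.share, b.share)

    def test_matrix_power_oracle_single_cohort(self, small_bundles):
        """Constant rates: a cohort's path equals the normalized matrix power."""
        country, _ = small_bundles
        ages, years = country.ages, country.years
        const = lambda v: AgeGenderYearTable.constant(v, ages, years)
        rates = CountryRates(
            init=const(0.04), cess=const(0.06),
            mort_never=const(0.01), mort_current=const(0.025), mort_former=const(0.015),
            le_never=const(30.0),
        )
        params = ScenarioParams(nvp_intro_year=country.base_year)
        from savm.schedule import TransitionSchedule

        sched = TransitionSchedule(
            smk_init=const(0.04 * 0.88), nvp_init=const(0.04 * 0.25),
            smk_cess=const(0.06), nvp_cess=const(0.06), switch=const(0.01),
        )
        # decay would make switching time-varying; this schedule is constant
        traj = run_scenario(country, rates, params, "nvp", sched)

        # independent operator: v_{k+1} proportional to T @ (surv * v_k);
        # start the cohort at age 40 (always above the age-35 threshold)
        excess = build_excess_map(rates, params.rr_nvp)[:, 0, 0, 0]
        surv = 1.0 - (0.01 + excess)
        T = np.zeros((N_STATES, N_STATES))
        T[UseState.NEVER, UseState.NEVER] = 1 - 0.04 * 0.88 - 0.04 * 0.25
        T[UseState.CURRENT_SMOKER, UseState.NEVER] = 0.04 * 0.88
        T[UseState.NVP_USER, UseState.NEVER] = 0.04 * 0.25
        T[UseState.CURRENT_SMOKER, UseState.CURRENT_SMOKER] = 1 - 0.06 - 0.01
        T[UseState.FORMER_SMOKER, UseState.CURRENT_SMOKER] = 0.06
        T[UseState.FS_NVP_USER, UseState.CURRENT_SMOKER] = 0.01
        T[UseState.FORMER_SMOKER, UseState.FORMER_SMOKER] = 1.0
        T[UseState.FORMER_SMOKER_LOWRISK, UseState.FORMER_SMOKER_LOWRISK] = 1.0
        T[UseState.NVP_USER, UseState.NVP_USER] = 1 - 0.06
        T[UseState.FORMER_NVP_USER, UseState.NVP_USER] = 0.06
        T[UseState.NVP_EXSMOKER_LOWRISK, UseState.NVP_EXSMOKER_LOWRISK] = 1 - 0.06
        T[UseState.FORMER_NVP_USER, UseState.NVP_EXSMOKER_LOWRISK] = 0.06
        T[UseState.FS_NVP_USER, UseState.FS_NVP_USER] = 1 - 0.06
        T[UseState.FORMER_NVP_EXSMOKER, UseState.FS_NVP_USER] = 0.06
        T[UseState.FORMER_NVP_USER, UseState.FORMER_NVP_USER] = 1.0
        T[UseState.FORMER_NVP_EXSMOKER, UseState.FORMER_NVP_EXSMOKER] = 1.0
        M = T @ np.diag(surv)

        a0 = 40 - country.min_age
        v = traj.share[0, :, a0, 0]
        for k in range(1, 11):
            w = np.linalg.matrix_power(M, k) @ v
            w = w / w.sum()
            np.testing.assert_allclose(traj.share[k, :, a0 + k, 0], w, atol=1e-12)

    def test_one_year_horizon_returns_initial_state_only(self, small_bundles):
        country, _ = small_bundles
        short = dataclasses.replace(
            country,
            end_year=country.base_year + 1,
            population=AgeGenderYearTable(
                country.population.values[:, :, :2], country.ages, country.years[:2]
            ),
            overall_mortality=AgeGenderYearTable(
                country.overall_mortality.values[:, :, :2], country.ages, country.years[:2]
            ),
        )
        _, reference = small_bundles

        from savm.model import adapt_country_rates

        rates = adapt_country_rates(country, reference)
        rates = CountryRates(
            **{
                f: AgeGenderYearTable(
                    getattr(rates, f).values[:, :, :2], country.ages, country.years[:2]
                )
                for f in ("init", "cess", "mort_never", "mort_current", "mort_former", "le_never")
            }
        )
        traj = run_scenario(short, rates, None, "no_nvp")
        np.testing.assert_allclose(traj.share[0], init_no_nvp(short))
        assert traj.share.shape[0] == 2

    def test_monotone_switching_reduces_smoking(self, small_model):
        base = small_model.fit()
        more = small_model.fit(params=small_model.params.perturb("switch_scale", 2.0))
        cur = UseState.CURRENT_SMOKER
        assert (
            more.trajectory_nvp.share[1:, cur] <= base.trajectory_nvp.share[1:, cur] + 1e-12
        ).all()
        vape_states = [UseState.NVP_USER, UseState.NVP_EXSMOKER_LOWRISK, UseState.FS_NVP_USER]
        assert (
            more.trajectory_nvp.share[1:, vape_states].sum(axis=1)
            >= base.trajectory_nvp.share[1:, vape_states].sum(axis=1) - 1e-12
        ).all()

    def test_smoking_prevalence_declines_when_cessation_dominates(self, germany_results):
        for out in (germany_results.outcomes_no_nvp, germany_results.outcomes_nvp):
            prev = out.smoking_prevalence
            assert prev.iloc[-1].max() < prev.iloc[0].min()
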