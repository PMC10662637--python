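"""Cohort engine: evolves use-state occupancy year by year for both scenarios.

The population is a set of single-age, single-gender cohorts. Within each
simulated year a cohort (1) survives with state-specific mortality, (2)
transitions between use states, and (3) is renormalized so the state shares
sum to one — the following year's absolute size comes from the population
projection, which already embodies total mortality; differential mortality
still reshapes the composition through the survival step.

States follow the quit-before-35 rule: smokers who quit (or switch to
vaping) with attained age 34 or below land in low-risk substates that carry
never-smoker baseline mortality. Dual users are treated as current smokers.
Former states are absorbing (cessation rates are net of relapse).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd

from .inputs import CountryBundle, DataError
from .params import ScenarioParams
from .schedule import FeasibilityError, TransitionSchedule
from .tables import GENDERS, AgeGenderYearTable


class UseState(IntEnum):
    """Smoking / vaping use states.

    The counterfactual (No-NVP) scenario uses only the first four. The
    low-risk substates mark people who quit smoking (or switched to vaping)
    before age 35 and therefore carry never-smoker baseline mortality.
    """

    NEVER = 0
    CURRENT_SMOKER = 1
    FORMER_SMOKER = 2
    FORMER_SMOKER_LOWRISK = 3
    NVP_USER = 4                  # initiated vaping never having smoked
    NVP_EXSMOKER_LOWRISK = 5      # switched from smoking before age 35
    FS_NVP_USER = 6               # former smoker (quit at 35+) who vapes
    FORMER_NVP_USER = 7
    FORMER_NVP_EXSMOKER = 8


N_STATES = len(UseState)
NO_NVP_STATES = (
    UseState.NEVER,
    UseState.CURRENT_SMOKER,
    UseState.FORMER_SMOKER,
    UseState.FORMER_SMOKER_LOWRISK,
)
#: states counted as exclusive NVP users in prevalence summaries
NVP_USER_STATES = (UseState.NVP_USER, UseState.NVP_EXSMOKER_LOWRISK)


@dataclass
class CountryRates:
    """Country-adapted counterfactual rates: the cohort engine's rate inputs."""

    init: AgeGenderYearTable
    cess: AgeGenderYearTable
    mort_never: AgeGenderYearTable
    mort_current: AgeGenderYearTable
    mort_former: AgeGenderYearTable
    le_never: AgeGenderYearTable


@dataclass
class StateTrajectory:
    """Occupancy shares and counts per (year, state, age, gender)."""

    share: np.ndarray  # (n_years, n_states, n_age, 2)
    count: np.ndarray
    ages: np.ndarray
    years: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: year, age, gender, state, share, count."""
        idx = pd.MultiIndex.from_product(
            [self.years, [s.name.lower() for s in UseState], self.ages, GENDERS],
            names=["year", "state", "age", "gender"],
        )
        df = pd.DataFrame(
            {"share": self.share.reshape(-1), "count": self.count.reshape(-1)}, index=idx
        ).reset_index()
        return df[["year", "age", "gender", "state", "share", "count"]]

    def prevalence(self, states, min_age: int | None = None) -> pd.DataFrame:
        """Population-weighted share of ``states``, by year and gender.

        Weights are the projected population; ages below ``min_age`` are
        excluded (default: all modeled ages).
        """
        states = [int(s) for s in np.atleast_1d(states)]
        sel = np.ones(len(self.ages), dtype=bool)
        if min_age is not None:
            sel = self.ages >= min_age
        pop = self.count.sum(axis=1)[:, sel, :]  # (Y, A', 2)
        num = self.count[:, states][:, :, sel, :].sum(axis=1)  # (Y, A', 2)
        prev = num.sum(axis=1) / pop.sum(axis=1)  # (Y, 2)
        return pd.DataFrame(prev, index=pd.Index(self.years, name="year"), columns=list(GENDERS))


# ----------------------------------------------------------------- initial state
def init_no_nvp(bundle: CountryBundle, age35_threshold: int = 35) -> np.ndarray:
    """Base-year occupancy (n_states, n_age, 2) from prevalence inputs.

    Former smokers younger than the age-35 threshold necessarily quit before
    35 and start in the low-risk substate; at 35+ the initial former pool is
    assigned the full former-smoker excess.
    """
    prev = bundle.smoking_prevalence_base
    ages = bundle.ages
    occ = np.zeros((N_STATES, len(ages), 2))
    occ[UseState.NEVER] = prev["never"].values[:, :, 0]
    occ[UseState.CURRENT_SMOKER] = prev["current"].values[:, :, 0]
    former = prev["former"].values[:, :, 0]
    young = ages < age35_threshold
    occ[UseState.FORMER_SMOKER_LOWRISK, young] = former[young]
    occ[UseState.FORMER_SMOKER, ~young] = former[~young]
    total = occ.sum(axis=0)
    if not np.allclose(total, 1.0, atol=1e-9):
        raise DataError("initial prevalence shares do not sum to 1")
    return occ


# ----------------------------------------------------------------- one-year step
def _step(
    shares: np.ndarray,      # (n_states, n_age, 2) at age a, year t
    mu_state: np.ndarray,    # (n_states, n_age, 2) mortality per state
    smk_init: np.ndarray,    # (n_age, 2) flows, all in [0,1]
    nvp_init: np.ndarray,
    smk_cess: np.ndarray,
    nvp_cess: np.ndarray,
    switch: np.ndarray,
    lowrisk: np.ndarray,     # (n_age,) True where attained age a+1 < 35
    renormalize: bool = True,
) -> np.ndarray:
    """Survival -> transitions -> renormalize; returns shares at (a+1, t+1).

    The caller shifts the age axis. Deaths are attributed to the state held
    at the start of the year; transitions act on survivors only.
    """
    if (mu_state > 1).any() or (mu_state < 0).any():
        raise DataError("state mortality outside [0,1]")
    if (smk_init + nvp_init > 1 + 1e-12).any() or (smk_cess + switch > 1 + 1e-12).any():
        raise FeasibilityError("competing outflows exceed 1")
    s = shares * (1.0 - mu_state)
    out = np.zeros_like(s)
    low = lowrisk[:, None]

    to_smk = s[UseState.NEVER] * smk_init
    to_nvp = s[UseState.NEVER] * nvp_init
    out[UseState.NEVER] = s[UseState.NEVER] - to_smk - to_nvp
    out[UseState.NVP_USER] = s[UseState.NVP_USER] + to_nvp

    quit = s[UseState.CURRENT_SMOKER] * smk_cess
    switched = s[UseState.CURRENT_SMOKER] * switch
    out[UseState.CURRENT_SMOKER] = s[UseState.CURRENT_SMOKER] - quit - switched + to_smk
    out[UseState.FORMER_SMOKER_LOWRISK] = s[UseState.FORMER_SMOKER_LOWRISK] + quit * low
    out[UseState.FORMER_SMOKER] = s[UseState.FORMER_SMOKER] + quit * (~low)
    out[UseState.NVP_EXSMOKER_LOWRISK] = s[UseState.NVP_EXSMOKER_LOWRISK] + switched * low
    out[UseState.FS_NVP_USER] = s[UseState.FS_NVP_USER] + switched * (~low)

    for vaping, former in (
        (UseState.NVP_USER, UseState.FORMER_NVP_USER),
        (UseState.NVP_EXSMOKER_LOWRISK, UseState.FORMER_NVP_USER),
        (UseState.FS_NVP_USER, UseState.FORMER_NVP_EXSMOKER),
    ):
        stop = s[vaping] * nvp_cess
        out[vaping] -= stop
        out[former] += stop
    out[UseState.FORMER_NVP_USER] += s[UseState.FORMER_NVP_USER]
    out[UseState.FORMER_NVP_EXSMOKER] += s[UseState.FORMER_NVP_EXSMOKER]

    if renormalize:
        total = out.sum(axis=0)
        out = np.divide(out, total, out=np.zeros_like(out), where=total > 0)
    return out


def step_no_nvp(
    shares: np.ndarray,
    init: np.ndarray,
    cess: np.ndarray,
    mu_state: np.ndarray,
    lowrisk: np.ndarray,
    renormalize: bool = True,
) -> np.ndarray:
    """Counterfactual one-year step: the generic step with all NVP flows zero."""
    zero = np.zeros_like(init)
    return _step(shares, mu_state, init, zero, cess, zero, zero, lowrisk, renormalize)


def step_nvp(
    shares: np.ndarray,
    smk_init: np.ndarray,
    nvp_init: np.ndarray,
    smk_cess: np.ndarray,
    nvp_cess: np.ndarray,
    switch: np.ndarray,
    mu_state: np.ndarray,
    lowrisk: np.ndarray,
    renormalize: bool = True,
) -> np.ndarray:
    """Vaping-scenario one-year step with the five flows active."""
    return _step(
        shares, mu_state, smk_init, nvp_init, smk_cess, nvp_cess, switch, lowrisk, renormalize
    )


# ----------------------------------------------------------------- full scenario
def state_mortality(
    rates: CountryRates, rr_nvp: float, year_index: int, fsnvp_excess_mode: str = "additive"
) -> np.ndarray:
    """Per-state mortality (n_states, n_age, 2) for one year: baseline + excess."""
    from .outcomes import build_excess_map  # local import; outcomes imports this module

    excess = build_excess_map(rates, rr_nvp, fsnvp_excess_mode)
    mu_never = rates.mort_never.values[:, :, year_index]
    return np.clip(mu_never[None, :, :] + excess[:, :, :, year_index], 0.0, 1.0)


def _entrant_distribution(
    base_occ_min_age: np.ndarray, params: ScenarioParams | None
) -> np.ndarray:
    """State distribution (n_states, 2) of new min-age entrants.

    The counterfactual uses the base-year distribution at the entry age. In
    the vaping scenario the smoked/vaped shares are re-weighted by the
    initiation multipliers, treating the base-year current-smoker share at
    the entry age as the outcome of pre-entry initiation; never use absorbs
    the remainder.
    """
    d = base_occ_min_age.copy()
    if params is None:
        return d
    cur = base_occ_min_age[UseState.CURRENT_SMOKER]
    new_cur = params.m_smk_init * cur
    new_nvp = params.m_nvp_init * cur
    # written so that multipliers (1, 0) leave the never share bitwise unchanged
    never = base_occ_min_age[UseState.NEVER] - cur * (params.m_smk_init - 1.0) - new_nvp
    if (never < -1e-12).any():
        raise DataError("entrant re-weighting drove the never-use share negative")
    d[UseState.NEVER] = np.maximum(never, 0.0)
    d[UseState.CURRENT_SMOKER] = new_cur
    d[UseState.NVP_USER] = new_nvp
    return d


def run_scenario(
    bundle: CountryBundle,
    rates: CountryRates,
    params: ScenarioParams | None = None,
    scenario: str = "no_nvp",
    schedule: TransitionSchedule | None = None,
    *,
    fsnvp_excess_mode: str = "additive",
    renormalize: bool = True,
) -> StateTrajectory:
    """Run one scenario over [base_year, end_year] x [min_age, max_age].

    New entrants appear at min_age each year with the base-year entry-age
    distribution (multiplier-adjusted in the vaping scenario from the NVP
    introduction year on); the top age class exits after its year. Counts
    are shares times the projected population throughout.
    """
    if scenario not in ("no_nvp", "nvp"):
        raise ValueError(f"unknown scenario {scenario!r}")
    if scenario == "nvp" and (schedule is None or params is None):
        raise ValueError("nvp scenario requires a schedule and params")
    ages, years = bundle.ages, bundle.years
    for tbl in (rates.init, rates.cess, rates.mort_never):
        if not (np.array_equal(tbl.ages, ages) and np.array_equal(tbl.years, years)):
            raise DataError("rates do not cover the modeling ages/years")

    threshold = params.age35_threshold if params is not None else 35
    rr = params.rr_nvp if (params is not None and scenario == "nvp") else 0.0
    lowrisk = (ages + 1) <= threshold - 1

    n_years = len(years)
    share = np.zeros((n_years, N_STATES, len(ages), 2))
    share[0] = init_no_nvp(bundle, threshold)
    entrant_base = share[0][:, 0, :].copy()

    from .outcomes import build_excess_map  # local import; outcomes imports this module

    excess = build_excess_map(rates, rr, fsnvp_excess_mode)  # (S, A, 2, Y)
    mu_all = np.clip(rates.mort_never.values[None, :, :, :] + excess, 0.0, 1.0)

    for k in range(n_years - 1):
        mu = mu_all[:, :, :, k]
        if scenario == "no_nvp":
            stepped = step_no_nvp(
                share[k], rates.init.values[:, :, k], rates.cess.values[:, :, k],
                mu, lowrisk, renormalize,
            )
        else:
            stepped = step_nvp(
                share[k],
                schedule.smk_init.values[:, :, k],
                schedule.nvp_init.values[:, :, k],
                schedule.smk_cess.values[:, :, k],
                schedule.nvp_cess.values[:, :, k],
                schedule.switch.values[:, :, k],
                mu, lowrisk, renormalize,
            )
        share[k + 1, :, 1:, :] = stepped[:, :-1, :]
        if scenario == "nvp" and years[k + 1] >= params.nvp_intro_year:
            share[k + 1, :, 0, :] = _entrant_distribution(entrant_base, params)
        else:
            share[k + 1, :, 0, :] = entrant_base

    pop = bundle.population.values.transpose(2, 0, 1)  # (Y, A, 2)
    count = share * pop[:, None, :, :]
    return StateTrajectory(share, count, ages, years)
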