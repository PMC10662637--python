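"""Attributable deaths, life-years lost, and the scenario net impact.

Smoking-attributable deaths (SADs) and smoking-and-vaping-attributable
deaths (SVADs) are the excess mortality of each use state times the number
of people in that state, using start-of-year counts. Life-years lost (LYLs)
weight each attributable death by the remaining life expectancy of a never
smoker at that age. The net public-health impact of vaping is the
difference (No-NVP minus NVP) in these quantities, yearly and cumulative.

Excess mortality per state (over never smokers), with rr the NVP relative
risk and exc_cur/exc_for the current/former smoker excess:

=========================  =======================================
state                      excess
=========================  =======================================
never                      0
current smoker             exc_cur
former smoker              exc_for
former smoker (low risk)   0 (quit before 35)
NVP user                   rr * exc_cur
NVP ex-smoker (low risk)   rr * exc_cur
FS-NVP user                exc_for + rr * exc_cur  (additive mode)
former NVP user            rr * exc_for
former NVP ex-smoker       exc_for + rr * exc_for  (additive mode)
=========================  =======================================

The composition for switchers at 35+ is a modeling choice; mode
``"nvp_only"`` drops the former-smoker term from the two ex-smoker rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import N_STATES, CountryRates, StateTrajectory, UseState
from .inputs import DataError
from .tables import GENDERS, AgeGenderYearTable, CoverageError, SchemaError


def build_excess_map(
    rates: CountryRates, rr_nvp: float, fsnvp_excess_mode: str = "additive"
) -> np.ndarray:
    """Excess mortality per state, shape (n_states, n_age, 2, n_year)."""
    if fsnvp_excess_mode not in ("additive", "nvp_only"):
        raise ValueError(f"unknown fsnvp_excess_mode {fsnvp_excess_mode!r}")
    exc_cur = rates.mort_current.values - rates.mort_never.values
    exc_for = rates.mort_former.values - rates.mort_never.values
    if (exc_cur < -1e-12).any() or (exc_for < -1e-12).any():
        raise DataError("negative smoking excess mortality")
    exc_cur = np.maximum(exc_cur, 0.0)
    exc_for = np.maximum(exc_for, 0.0)
    excess = np.zeros((N_STATES,) + exc_cur.shape)
    excess[UseState.CURRENT_SMOKER] = exc_cur
    excess[UseState.FORMER_SMOKER] = exc_for
    excess[UseState.NVP_USER] = rr_nvp * exc_cur
    excess[UseState.NVP_EXSMOKER_LOWRISK] = rr_nvp * exc_cur
    excess[UseState.FORMER_NVP_USER] = rr_nvp * exc_for
    smoking_part = exc_for if fsnvp_excess_mode == "additive" else 0.0
    excess[UseState.FS_NVP_USER] = smoking_part + rr_nvp * exc_cur
    excess[UseState.FORMER_NVP_EXSMOKER] = smoking_part + rr_nvp * exc_for
    return excess


def attributable_deaths(traj: StateTrajectory, excess: np.ndarray) -> np.ndarray:
    """Deaths (n_year, n_age, 2): sum over states of excess x start-of-year count."""
    if (excess < 0).any():
        raise DataError("excess mortality must be >= 0")
    # excess is (S, A, 2, Y); counts are (Y, S, A, 2)
    return np.einsum("ysag,sagy->yag", traj.count, excess)


def life_years_lost(deaths: np.ndarray, le_never: AgeGenderYearTable,
                    years: np.ndarray, ages: np.ndarray) -> np.ndarray:
    """LYLs (n_year, n_age, 2): deaths weighted by never-smoker life expectancy."""
    if not (np.array_equal(le_never.ages, ages) and np.array_equal(le_never.years, years)):
        raise CoverageError("life-expectancy table does not cover the deaths index")
    return deaths * le_never.values.transpose(2, 0, 1)


@dataclass
class OutcomeTable:
    """Per-scenario outputs: deaths and LYLs by gender/year plus prevalence summaries."""

    deaths: pd.DataFrame       # index year, columns male/female (deaths/yr)
    lyls: pd.DataFrame         # index year, columns male/female (years/yr)
    smoking_prevalence: pd.DataFrame  # index year, columns male/female (proportion)
    nvp_prevalence: pd.DataFrame
    fs_nvp_prevalence: pd.DataFrame

    @property
    def cumulative_deaths(self) -> pd.Series:
        out = self.deaths.sum(axis=0)
        out["both"] = out.sum()
        return out

    @property
    def cumulative_lyls(self) -> pd.Series:
        out = self.lyls.sum(axis=0)
        out["both"] = out.sum()
        return out


def summarize_outcomes(
    traj: StateTrajectory,
    rates: CountryRates,
    rr_nvp: float,
    *,
    fsnvp_excess_mode: str = "additive",
    prevalence_min_age: int = 18,
) -> OutcomeTable:
    """Compute an OutcomeTable for one scenario trajectory."""
    from .engine import NVP_USER_STATES

    excess = build_excess_map(rates, rr_nvp, fsnvp_excess_mode)
    deaths = attributable_deaths(traj, excess)
    lyls = life_years_lost(deaths, rates.le_never, traj.years, traj.ages)
    year_ix = pd.Index(traj.years, name="year")
    return OutcomeTable(
        deaths=pd.DataFrame(deaths.sum(axis=1), index=year_ix, columns=list(GENDERS)),
        lyls=pd.DataFrame(lyls.sum(axis=1), index=year_ix, columns=list(GENDERS)),
        smoking_prevalence=traj.prevalence(UseState.CURRENT_SMOKER, prevalence_min_age),
        nvp_prevalence=traj.prevalence(list(NVP_USER_STATES), prevalence_min_age),
        fs_nvp_prevalence=traj.prevalence(UseState.FS_NVP_USER, prevalence_min_age),
    )


@dataclass
class NetImpact:
    """No-NVP minus NVP differences: deaths and LYLs averted."""

    deaths_averted: pd.DataFrame  # index year, columns male/female/both
    lyls_averted: pd.DataFrame

    @property
    def cumulative_deaths_averted(self) -> pd.Series:
        return self.deaths_averted.sum(axis=0)

    @property
    def cumulative_lyls_averted(self) -> pd.Series:
        return self.lyls_averted.sum(axis=0)

    percent_deaths_averted: float = float("nan")  # vs No-NVP cumulative totals
    percent_lyls_averted: float = float("nan")


def net_impact(no_nvp: OutcomeTable, nvp: OutcomeTable) -> NetImpact:
    """Deaths/LYLs averted per year and gender, plus cumulative percentages.

    Averted values may be negative (the NVP scenario can be worse); nothing
    is clamped. Percentages are the cumulative both-gender averted totals
    over the No-NVP cumulative totals.
    """
    if not no_nvp.deaths.index.equals(nvp.deaths.index):
        raise SchemaError("outcome tables are not on identical year indices")
    d = no_nvp.deaths - nvp.deaths
    l = no_nvp.lyls - nvp.lyls
    d["both"] = d.sum(axis=1)
    l["both"] = l.sum(axis=1)
    return NetImpact(
        deaths_averted=d,
        lyls_averted=l,
        percent_deaths_averted=100.0 * d["both"].sum() / no_nvp.cumulative_deaths["both"],
        percent_lyls_averted=100.0 * l["both"].sum() / no_nvp.cumulative_lyls["both"],
    )


def relative_change(v0: float, v1: float) -> float:
    """(v1 - v0) / v0 — the relative change from v0 to v1."""
    if v0 == 0:
        raise ZeroDivisionError("relative change from a zero baseline")
    return (v1 - v0) / v0
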