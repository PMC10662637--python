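"""NVP-scenario transition schedule and the NVP mortality add-on.

The vaping scenario has five flows per (age, gender, year): smoking
initiation, NVP initiation, smoking cessation, NVP cessation, and switching
from smoking to exclusive NVP use. The first four are multiples of the
counterfactual (No-NVP) smoking initiation/cessation rates; switching comes
from a pre-loaded grouped schedule, scaled and decayed exponentially over
time. NVP excess mortality is a fixed fraction (rr) of the smoking excess.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inputs import DataError, expand_groups_uniform
from .params import ParameterError, ScenarioParams
from .tables import AgeGenderYearTable, GroupedTable


class FeasibilityError(ValueError):
    """Competing annual flows out of one state sum to more than 1."""


@dataclass
class TransitionSchedule:
    """The five NVP-scenario flows on a common (age, gender, year) index."""

    smk_init: AgeGenderYearTable
    nvp_init: AgeGenderYearTable
    smk_cess: AgeGenderYearTable
    nvp_cess: AgeGenderYearTable
    switch: AgeGenderYearTable

    def __post_init__(self) -> None:
        for name in ("smk_init", "nvp_init", "smk_cess", "nvp_cess", "switch"):
            v = getattr(self, name).values
            if ((v < 0) | (v > 1)).any():
                raise DataError(f"{name} outside [0,1]")
        if (self.smk_init.values + self.nvp_init.values > 1 + 1e-12).any():
            raise FeasibilityError("smoking + NVP initiation exceed 1 somewhere")
        if (self.smk_cess.values + self.switch.values > 1 + 1e-12).any():
            raise FeasibilityError("smoking cessation + switching exceed 1 somewhere")


def apply_decay(base: float, decay_factor: float, year: int, decay_start_year: int) -> float:
    """Exponential annual change: base * decay_factor**max(0, year - start)."""
    if decay_factor <= 0:
        raise ParameterError("decay_factor must be > 0")
    return base * decay_factor ** max(0, int(year) - int(decay_start_year))


def _decay_series(years: np.ndarray, factor: float, start_year: int) -> np.ndarray:
    if factor <= 0:
        raise ParameterError("decay_factor must be > 0")
    return factor ** np.maximum(0, years - start_year)


def build_schedule(
    no_nvp_init: AgeGenderYearTable,
    no_nvp_cess: AgeGenderYearTable,
    params: ScenarioParams,
    switch_schedule: GroupedTable,
) -> TransitionSchedule:
    """Assemble the five NVP-scenario flows from the counterfactual rates.

    smk_init/nvp_init are the counterfactual initiation rate times the
    respective multiplier; smk_cess/nvp_cess likewise from cessation.
    Switching expands the grouped schedule to single ages, applies
    switch_scale and the exponential decay from decay_start_year. Before
    nvp_intro_year the NVP-specific flows (NVP initiation, switching) are
    zero and the smoking flows equal the counterfactual rates, so the
    scenario reduces exactly to the counterfactual there. Optional
    per-parameter annual-change factors in params.annual_change decay the
    multipliers the same way.
    """
    no_nvp_init._check_aligned(no_nvp_cess)
    ages, years = no_nvp_init.ages, no_nvp_init.years
    active = years >= params.nvp_intro_year

    def _mult_series(name: str, mult: float) -> np.ndarray:
        series = np.full(len(years), float(mult))
        factor = params.annual_change.get(name)
        if factor is not None:
            series = series * _decay_series(years, float(factor), params.decay_start_year)
        return series

    def _smoking_flow(base: AgeGenderYearTable, name: str, mult: float) -> AgeGenderYearTable:
        series = np.where(active, _mult_series(name, mult), 1.0)
        return AgeGenderYearTable(base.values * series[None, None, :], ages, years)

    def _nvp_flow(base: AgeGenderYearTable, name: str, mult: float) -> AgeGenderYearTable:
        series = _mult_series(name, mult) * active
        return AgeGenderYearTable(base.values * series[None, None, :], ages, years)

    smk_init = _smoking_flow(no_nvp_init, "m_smk_init", params.m_smk_init)
    nvp_init = _nvp_flow(no_nvp_init, "m_nvp_init", params.m_nvp_init)
    smk_cess = _smoking_flow(no_nvp_cess, "m_smk_cess", params.m_smk_cess)
    nvp_cess = _nvp_flow(no_nvp_cess, "m_nvp_cess", params.m_nvp_cess)

    sw_by_age = expand_groups_uniform(switch_schedule, ages).values[:, :, 0]
    decay = _decay_series(years, params.decay_factor, params.decay_start_year)
    switch = AgeGenderYearTable(
        params.switch_scale * sw_by_age[:, :, None] * (decay * active)[None, None, :],
        ages,
        years,
    )
    return TransitionSchedule(smk_init, nvp_init, smk_cess, nvp_cess, switch)


def nvp_excess_mortality(
    mort_never: AgeGenderYearTable,
    mort_current: AgeGenderYearTable,
    mort_former: AgeGenderYearTable,
    rr_nvp: float,
) -> tuple:
    """NVP users' excess mortality as a fraction of the smoking excess.

    Returns (excess_nvp_current, excess_nvp_former): rr times the current-
    (former-) smoker excess over never smokers.
    """
    exc_cur = mort_current.values - mort_never.values
    exc_for = mort_former.values - mort_never.values
    if (exc_cur < -1e-12).any() or (exc_for < -1e-12).any():
        raise DataError("smoking excess mortality is negative somewhere")
    ages, years = mort_never.ages, mort_never.years
    return (
        AgeGenderYearTable(rr_nvp * np.maximum(exc_cur, 0.0), ages, years),
        AgeGenderYearTable(rr_nvp * np.maximum(exc_for, 0.0), ages, years),
    )


#: Pre-loaded smoker-to-vaper switching schedule (probability/yr) by age
#: group and gender, before any country scaling: male (female) 4% (2.5%)
#: for ages 24 and below, 2.5% (2.0%) for 25-34, 2.5% (1.6%) for 35-44,
#: 1.3% (1.4%) for 45-54, 1.2% (1.4%) for 55-64, 0.6% (1.0%) for 65+.
def default_switching_schedule(min_age: int = 18, max_age: int = 99) -> GroupedTable:
    import pandas as pd

    rows = []
    bands = [(0, 24), (25, 34), (35, 44), (45, 54), (55, 64), (65, 99)]
    male = [0.040, 0.025, 0.025, 0.013, 0.012, 0.006]
    female = [0.025, 0.020, 0.016, 0.014, 0.014, 0.010]
    for (lo, hi), m, f in zip(bands, male, female):
        lo, hi = max(lo, min_age), min(hi, max_age)
        if lo > hi:
            continue
        rows.append({"age_lo": lo, "age_hi": hi, "gender": "male", "value": m})
        rows.append({"age_lo": lo, "age_hi": hi, "gender": "female", "value": f})
    return GroupedTable(pd.DataFrame(rows))
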