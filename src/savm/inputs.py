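"""Country input handling: normalisation and country-adaptation of demographic data.

A country run needs four user-supplied quantities (population projections,
overall mortality, base-year overall life expectancy, base-year smoking
prevalence) plus reference rates estimated on a well-surveyed population
(US-style built-ins: initiation/cessation schedules, mortality by smoking
status, never-smoker life expectancy). This module expands grouped inputs to
single ages, smooths grouped survey prevalence, and rescales the reference
rates to the target country:

* never-smoker life expectancy is the reference schedule times the base-year
  country/reference overall life-expectancy ratio (constant over time);
* initiation (cessation) rates are scaled by the country/reference current
  smoking prevalence ratio over ages 18-24 (25-64);
* mortality by smoking status is scaled by the per-cell country/reference
  overall mortality ratio.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .tables import GENDERS, AgeGenderYearTable, CoverageError, GroupedTable, SchemaError

logger = logging.getLogger(__name__)

#: age bands whose prevalence ratios scale initiation / cessation rates
INITIATION_BAND = (18, 24)
CESSATION_BAND = (25, 64)


class DataError(ValueError):
    """Input values violate a domain invariant (shares, orderings, signs)."""


@dataclass
class CountryBundle:
    """Compulsory country inputs for one model run.

    population and overall_mortality cover [base_year, end_year]; the
    life-expectancy and prevalence tables are base-year only (single-year
    tables). Prevalence is a dict with keys never/current/former.
    """

    population: AgeGenderYearTable
    overall_mortality: AgeGenderYearTable
    le_overall_base: AgeGenderYearTable
    smoking_prevalence_base: dict
    base_year: int
    end_year: int
    min_age: int
    max_age: int

    def __post_init__(self) -> None:
        if not 0 <= self.min_age <= self.max_age <= 99:
            raise SchemaError("require 0 <= min_age <= max_age <= 99")
        if not 0 < self.end_year - self.base_year <= 88:
            raise SchemaError("modeling period must be 1..88 years")
        for key in ("never", "current", "former"):
            if key not in self.smoking_prevalence_base:
                raise SchemaError(f"smoking_prevalence_base missing {key!r}")
        total = sum(self.smoking_prevalence_base[k].values for k in ("never", "current", "former"))
        if not np.allclose(total, 1.0, atol=1e-9):
            raise DataError("never+current+former prevalence must sum to 1 at every age/gender")
        if (self.population.values < 0).any():
            raise DataError("population counts must be >= 0")
        mort = self.overall_mortality.values
        if ((mort < 0) | (mort > 1)).any():
            raise DataError("mortality rates must lie in [0,1]")

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.min_age, self.max_age + 1)

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.base_year, self.end_year + 1)


@dataclass
class ReferenceBundle:
    """Reference (built-in style) rates to be rescaled to the target country."""

    init: AgeGenderYearTable
    cess: AgeGenderYearTable
    mort_never: AgeGenderYearTable
    mort_current: AgeGenderYearTable
    mort_former: AgeGenderYearTable
    le_never: AgeGenderYearTable
    prev_base: dict
    le_overall_base: AgeGenderYearTable
    overall_mortality: AgeGenderYearTable

    def __post_init__(self) -> None:
        mc, mf, mn = self.mort_current.values, self.mort_former.values, self.mort_never.values
        if (mc < mf - 1e-12).any() or (mf < mn - 1e-12).any():
            warnings.warn(
                "mortality-by-status ordering current >= former >= never violated",
                stacklevel=2,
            )


# --------------------------------------------------------------------- expansion
def expand_groups_uniform(grouped: GroupedTable, ages, years=None) -> AgeGenderYearTable:
    """Expand a grouped table to single ages, constant within each group.

    Every age in [age_lo, age_hi] receives the group's value; an age covered
    by no group raises :class:`CoverageError`.
    """
    ages = np.asarray(ages, dtype=int)
    if years is None:
        if grouped.has_year:
            years = np.sort(grouped.data["year"].unique())
            if len(years) > 1 and not np.all(np.diff(years) == 1):
                raise SchemaError("grouped years must be contiguous")
        else:
            years = np.array([0])
    years = np.asarray(years, dtype=int)
    out = np.full((len(ages), 2, len(years)), np.nan)
    for gi, gender in enumerate(GENDERS):
        for yi, year in enumerate(years):
            sub = grouped.groups(gender, int(year) if grouped.has_year else None)
            for _, row in sub.iterrows():
                mask = (ages >= row["age_lo"]) & (ages <= row["age_hi"])
                out[mask, gi, yi] = row["value"]
    if np.isnan(out).any():
        age_ix, gi, _ = np.argwhere(np.isnan(out))[0]
        raise CoverageError(f"age {ages[age_ix]} ({GENDERS[gi]}) covered by no group")
    return AgeGenderYearTable(out, ages, years)


def group_midpoint(lo: int, hi: int) -> int:
    """Midpoint convention for survey groups: floor((lo+hi)/2)."""
    return (int(lo) + int(hi)) // 2


def smooth_group_prevalence(grouped: GroupedTable, ages) -> AgeGenderYearTable:
    """Convert grouped prevalence to single ages via midpoint interpolation.

    Each group's value is anchored at its midpoint; values between
    consecutive midpoints are piecewise-linear, and ages below the first
    (above the last) midpoint are held flat at the nearest midpoint value —
    e.g. with a first group (18, 29), ages 18-22 all take the value at the
    midpoint 23.
    """
    ages = np.asarray(ages, dtype=int)
    if grouped.has_year:
        raise SchemaError("prevalence smoothing expects a base-year (no year column) table")
    out = np.empty((len(ages), 2, 1))
    for gi, gender in enumerate(GENDERS):
        sub = grouped.groups(gender)
        mids = np.array([group_midpoint(lo, hi) for lo, hi in zip(sub["age_lo"], sub["age_hi"])])
        vals = sub["value"].to_numpy(dtype=float)
        # np.interp holds flat outside the anchor range, which is the rule here
        out[:, gi, 0] = np.interp(ages, mids, vals)
    return AgeGenderYearTable(out, ages, np.array([0]))


# --------------------------------------------------------------------- scaling
def scale_life_expectancy(
    le_never_ref: AgeGenderYearTable,
    le_overall_country_base: AgeGenderYearTable,
    le_overall_ref_base: AgeGenderYearTable,
) -> AgeGenderYearTable:
    """Rescale reference never-smoker life expectancy to the country.

    The age/gender-specific country/reference overall life-expectancy ratio
    is computed once at the base year and applied to every modeling year.
    """
    if (le_overall_ref_base.values <= 0).any():
        raise DataError("reference overall life expectancy must be > 0")
    ratio = le_overall_country_base.values[:, :, 0] / le_overall_ref_base.values[:, :, 0]
    return AgeGenderYearTable(
        le_never_ref.values * ratio[:, :, None], le_never_ref.ages, le_never_ref.years
    )


def _band_prevalence(prev: AgeGenderYearTable, population: AgeGenderYearTable,
                     band: tuple, weighted: bool = True) -> np.ndarray:
    """Population-weighted mean current-smoking prevalence over an age band.

    Returns a length-2 array (male, female). Weights are the base-year
    population; ``weighted=False`` uses a plain mean.
    """
    lo, hi = band
    sel = (prev.ages >= lo) & (prev.ages <= hi)
    p = prev.values[sel, :, 0]
    if weighted:
        psel = (population.ages >= lo) & (population.ages <= hi)
        w = population.values[psel, :, 0]
        return (p * w).sum(axis=0) / w.sum(axis=0)
    return p.mean(axis=0)


def scale_transition_rates(
    ref: ReferenceBundle,
    country_prev_base: dict,
    country_population: AgeGenderYearTable,
    *,
    weighted: bool = True,
) -> tuple:
    """Scale reference initiation/cessation rates by base-year prevalence ratios.

    Initiation is scaled per gender by the country/reference current-smoking
    prevalence ratio over ages 18-24, cessation by the ratio over ages 25-64,
    applied at all ages and years. Results above 1 are clipped with a logged
    warning.
    """
    pop_base = AgeGenderYearTable(
        country_population.values[:, :, :1], country_population.ages, country_population.years[:1]
    )
    ratios = {}
    for name, band in (("init", INITIATION_BAND), ("cess", CESSATION_BAND)):
        p_ref = _band_prevalence(ref.prev_base["current"], pop_base, band, weighted)
        if (p_ref <= 0).any():
            raise DataError(f"reference band prevalence for {name} scaling is zero")
        p_cty = _band_prevalence(country_prev_base["current"], pop_base, band, weighted)
        ratios[name] = p_cty / p_ref
        logger.info("%s scaling ratio (male, female): %s", name, ratios[name])

    def _apply(table: AgeGenderYearTable, ratio: np.ndarray, label: str) -> AgeGenderYearTable:
        scaled = table.values * ratio[None, :, None]
        if (scaled > 1).any():
            logger.warning("%s rates exceeded 1 after scaling; clipped", label)
        return AgeGenderYearTable(np.clip(scaled, 0.0, 1.0), table.ages, table.years)

    return _apply(ref.init, ratios["init"], "initiation"), _apply(ref.cess, ratios["cess"], "cessation")


def scale_mortality_by_status(
    ref: ReferenceBundle,
    overall_country: AgeGenderYearTable,
    overall_ref: AgeGenderYearTable,
) -> tuple:
    """Scale reference mortality-by-status by the overall mortality ratio.

    Each status rate is multiplied cell-by-cell by country/reference overall
    mortality; the same ratio preserves the current >= former >= never
    ordering, which is re-checked.
    """
    nonzero = overall_country.values > 0
    if (overall_ref.values[nonzero] <= 0).any():
        raise DataError("reference overall mortality is zero where country mortality is not")
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(nonzero, overall_country.values / np.where(
            overall_ref.values > 0, overall_ref.values, 1.0), 0.0)
    out = []
    for tbl in (ref.mort_never, ref.mort_current, ref.mort_former):
        out.append(AgeGenderYearTable(tbl.values * ratio, tbl.ages, tbl.years))
    mn, mc, mf = out
    if (mc.values < mf.values - 1e-12).any() or (mf.values < mn.values - 1e-12).any():
        warnings.warn("scaled mortality ordering current >= former >= never violated", stacklevel=2)
    return mn, mc, mf
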