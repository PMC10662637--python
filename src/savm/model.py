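"""Model and Results objects: the package's main user-facing surface.

``SmokingVapingModel`` is constructed from a country bundle and a reference
bundle; construction performs the country adaptation (prevalence smoothing
is assumed done upstream; rate/mortality/life-expectancy rescaling happens
here). ``fit()`` runs the deterministic two-scenario projection and returns
a ``SAVMResults`` holding both trajectories, per-scenario outcomes, the net
impact, and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import CountryRates, StateTrajectory, run_scenario
from .inputs import (
    CountryBundle,
    ReferenceBundle,
    scale_life_expectancy,
    scale_mortality_by_status,
    scale_transition_rates,
)
from .outcomes import NetImpact, OutcomeTable, net_impact, summarize_outcomes
from .params import ScenarioParams
from .schedule import TransitionSchedule, build_schedule, default_switching_schedule
from .tables import GroupedTable


def adapt_country_rates(
    country: CountryBundle, reference: ReferenceBundle, *, weighted: bool = True
) -> CountryRates:
    """Rescale the reference rates to the country (the preliminary steps)."""
    init, cess = scale_transition_rates(
        reference, country.smoking_prevalence_base, country.population, weighted=weighted
    )
    mn, mc, mf = scale_mortality_by_status(
        reference, country.overall_mortality, reference.overall_mortality
    )
    le_never = scale_life_expectancy(
        reference.le_never, country.le_overall_base, reference.le_overall_base
    )
    return CountryRates(init, cess, mn, mc, mf, le_never)


class SmokingVapingModel:
    """Two-scenario cohort projection of smoking and vaping for one country.

    Parameters
    ----------
    country, reference : CountryBundle, ReferenceBundle
        User inputs and reference (built-in style) rates; the reference
        rates are rescaled to the country at construction.
    params : ScenarioParams, optional
        Vaping-scenario knobs; defaults to the Germany-style configuration.
    switching : GroupedTable, optional
        Pre-loaded smoker-to-vaper switching schedule by age group and
        gender; defaults to the built-in schedule.
    weighted_band_prevalence : bool
        Population-weight the age-band prevalence ratios used for
        initiation/cessation scaling (plain mean if False).
    fsnvp_excess_mode : {"additive", "nvp_only"}
        Mortality composition for former smokers who vape (quit at 35+).
    renormalize : bool
        Renormalize state shares each year to the population projection
        (default); if False the shares carry survival attrition.
    """

    def __init__(
        self,
        country: CountryBundle,
        reference: ReferenceBundle,
        params: ScenarioParams | None = None,
        switching: GroupedTable | None = None,
        *,
        weighted_band_prevalence: bool = True,
        fsnvp_excess_mode: str = "additive",
        renormalize: bool = True,
    ) -> None:
        self.country = country
        self.reference = reference
        self.params = params if params is not None else ScenarioParams(
            nvp_intro_year=country.base_year
        )
        self.switching = (
            switching
            if switching is not None
            else default_switching_schedule(country.min_age, country.max_age)
        )
        self.fsnvp_excess_mode = fsnvp_excess_mode
        self.renormalize = renormalize
        self.rates = adapt_country_rates(country, reference, weighted=weighted_band_prevalence)
        self._no_nvp_cache: dict = {}

    @classmethod
    def from_synthetic(cls, seed: int = 0, config=None, **kwargs) -> "SmokingVapingModel":
        """Build a model from the synthetic Germany-like fixture bundles."""
        from .synthetic import generate_bundles, germany_like

        cfg = config if config is not None else germany_like(seed)
        country, reference = generate_bundles(cfg)
        return cls(country, reference, **kwargs)

    # ------------------------------------------------------------------ runs
    def schedule_for(self, params: ScenarioParams) -> TransitionSchedule:
        return build_schedule(self.rates.init, self.rates.cess, params, self.switching)

    def run_no_nvp(self, params: ScenarioParams | None = None) -> StateTrajectory:
        params = params if params is not None else self.params
        key = (params.age35_threshold, self.renormalize)
        if key not in self._no_nvp_cache:
            self._no_nvp_cache[key] = run_scenario(
                self.country, self.rates, params, "no_nvp",
                fsnvp_excess_mode=self.fsnvp_excess_mode, renormalize=self.renormalize,
            )
        return self._no_nvp_cache[key]

    def run_nvp(self, params: ScenarioParams | None = None) -> StateTrajectory:
        params = params if params is not None else self.params
        return run_scenario(
            self.country, self.rates, params, "nvp", self.schedule_for(params),
            fsnvp_excess_mode=self.fsnvp_excess_mode, renormalize=self.renormalize,
        )

    def fit(self, params: ScenarioParams | None = None) -> "SAVMResults":
        """Run both scenarios and assemble outcomes and net impact."""
        params = params if params is not None else self.params
        traj_no = self.run_no_nvp(params)
        traj_nvp = self.run_nvp(params)
        out_no = summarize_outcomes(
            traj_no, self.rates, 0.0,
            fsnvp_excess_mode=self.fsnvp_excess_mode, prevalence_min_age=self.country.min_age,
        )
        out_nvp = summarize_outcomes(
            traj_nvp, self.rates, params.rr_nvp,
            fsnvp_excess_mode=self.fsnvp_excess_mode, prevalence_min_age=self.country.min_age,
        )
        return SAVMResults(self, params, traj_no, traj_nvp, out_no, out_nvp,
                           net_impact(out_no, out_nvp))

    def sensitivity(self, spec=None) -> pd.DataFrame:
        from .sensitivity import SensitivitySpec, run_sensitivity

        return run_sensitivity(self, spec if spec is not None else SensitivitySpec())


@dataclass
class SAVMResults:
    """Fitted projection: trajectories, outcomes, and the scenario difference."""

    model: SmokingVapingModel
    params: ScenarioParams
    trajectory_no_nvp: StateTrajectory = field(repr=False)
    trajectory_nvp: StateTrajectory = field(repr=False)
    outcomes_no_nvp: OutcomeTable = field(repr=False)
    outcomes_nvp: OutcomeTable = field(repr=False)
    net: NetImpact = field(repr=False)

    @property
    def years(self) -> np.ndarray:
        return self.trajectory_no_nvp.years

    def _display_years(self) -> list:
        years = self.years
        picks = [years[0], years[0] + 5, years[0] + (years[-1] - years[0]) * 2 // 3, years[-1]]
        return sorted({int(min(max(y, years[0]), years[-1])) for y in picks})

    def summary_frame(self, precision: int = 1) -> pd.DataFrame:
        """Per-gender panel of prevalences, attributable deaths, and LYLs."""
        years = self._display_years()
        rows = []
        for gender in ("male", "female"):
            for label, out in (("no_nvp", self.outcomes_no_nvp), ("nvp", self.outcomes_nvp)):
                rows.append(
                    {
                        "gender": gender,
                        "scenario": label,
                        **{
                            f"smokers_{y}_pct": round(
                                100 * out.smoking_prevalence.loc[y, gender], precision
                            )
                            for y in years
                        },
                        "cumulative_deaths": round(out.cumulative_deaths[gender]),
                        "cumulative_lyls": round(out.cumulative_lyls[gender]),
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable report of the projection and its net impact."""
        years = self.years
        lines = [
            "Smoking and Vaping Model projection",
            f"  period {years[0]}-{years[-1]}, ages {self.model.country.min_age}-"
            f"{self.model.country.max_age}",
            f"  NVP relative risk {self.params.rr_nvp:.0%}, multipliers "
            f"smk_init {self.params.m_smk_init:.0%} / nvp_init {self.params.m_nvp_init:.0%} / "
            f"smk_cess {self.params.m_smk_cess:.0%} / nvp_cess {self.params.m_nvp_cess:.0%}, "
            f"switch scale {self.params.switch_scale:.0%}",
            "",
            self.summary_frame().to_string(index=False),
            "",
            "Net impact (No-NVP minus NVP, cumulative):",
            f"  deaths averted: {self.net.cumulative_deaths_averted['both']:,.0f} "
            f"({self.net.percent_deaths_averted:.1f}% of No-NVP deaths)",
            f"  life-years saved: {self.net.cumulative_lyls_averted['both']:,.0f} "
            f"({self.net.percent_lyls_averted:.1f}% of No-NVP LYLs)",
        ]
        return "\n".join(lines)

    # ------------------------------------------------------------------ plots
    def plot_prevalence(self, ax=None):
        """Smoking (both scenarios) and NVP-use prevalence over time."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for gender, style in (("male", "-"), ("female", "--")):
            ax.plot(self.years, 100 * self.outcomes_no_nvp.smoking_prevalence[gender],
                    style, color="C0", label=f"smoking, no-NVP ({gender})")
            ax.plot(self.years, 100 * self.outcomes_nvp.smoking_prevalence[gender],
                    style, color="C1", label=f"smoking, NVP ({gender})")
            ax.plot(self.years, 100 * self.outcomes_nvp.nvp_prevalence[gender],
                    style, color="C2", label=f"NVP use ({gender})")
        ax.set_xlabel("year")
        ax.set_ylabel("prevalence (%)")
        ax.legend(fontsize="small")
        return ax

    def plot_averted(self, ax=None):
        """Yearly deaths averted by gender."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for gender in ("male", "female", "both"):
            ax.plot(self.years, self.net.deaths_averted[gender], label=gender)
        ax.set_xlabel("year")
        ax.set_ylabel("attributable deaths averted / yr")
        ax.legend()
        return ax

    def validate(self, survey, period=None) -> pd.DataFrame:
        """Relative-change validation of the NVP-scenario smoking prevalence."""
        from .sensitivity import validate_against_survey

        return validate_against_survey(self.outcomes_nvp.smoking_prevalence, survey, period)
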