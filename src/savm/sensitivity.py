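"""One-at-a-time sensitivity grids and survey-based validation.

The sensitivity harness reruns the vaping scenario (the counterfactual is
unchanged) over a grid of NVP relative-risk values and single-parameter
perturbations of the transition multipliers, tabulating cumulative averted
deaths and life-years with relative differences versus the base estimate.
Validation compares model and survey smoking-prevalence series through
relative changes over a period, since absolute survey levels differ between
instruments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .outcomes import relative_change
from .params import ScenarioParams
from .tables import CoverageError


class ConfigError(ValueError):
    """A sensitivity or validation specification is malformed."""


@dataclass
class SensitivitySpec:
    """Grid definition: rr values plus (parameter, factor) perturbations."""

    rr_values: list = field(default_factory=lambda: [0.05, 0.15, 0.25, 0.40, 0.50])
    perturbations: list = field(
        default_factory=lambda: [
            (name, factor)
            for name in ("switch_scale", "m_smk_init", "m_nvp_init", "m_smk_cess", "m_nvp_cess")
            for factor in (0.5, 1.5)
        ]
    )
    factorial: bool = False

    def __post_init__(self) -> None:
        for name, factor in self.perturbations:
            if name not in ScenarioParams.MULTIPLIER_NAMES:
                raise ConfigError(f"unknown parameter in perturbation: {name!r}")
            if factor <= 0:
                raise ConfigError("perturbation factors must be > 0")


def run_sensitivity(model, spec: SensitivitySpec) -> pd.DataFrame:
    """One-at-a-time sensitivity grid for a fitted-or-unfitted model.

    For each rr value, reruns the vaping scenario at base parameters and at
    every single perturbation; in factorial mode every combination of the
    listed perturbations is run instead. Columns: rr, parameter, factor,
    averted deaths/LYLs (cumulative, both genders), relative difference vs
    the same-rr base row, and the cross-rr relative change of each row
    against the first rr value.
    """
    from .model import SmokingVapingModel  # circular-at-type-level only

    if not isinstance(model, SmokingVapingModel):
        raise TypeError("run_sensitivity expects a SmokingVapingModel")

    def _cases(rr: float) -> list:
        base = model.params.with_rr(rr)
        cases = [("base", 1.0, base)]
        if not spec.factorial:
            for name, factor in spec.perturbations:
                cases.append((name, factor, base.perturb(name, factor)))
            return cases
        from itertools import product

        by_param: dict = {}
        for name, factor in spec.perturbations:
            by_param.setdefault(name, [1.0]).append(factor)
        names = list(by_param)
        for combo in product(*(by_param[n] for n in names)):
            if all(f == 1.0 for f in combo):
                continue
            p = base
            for name, factor in zip(names, combo):
                if factor != 1.0:
                    p = p.perturb(name, factor)
            label = "*".join(f"{n}x{f}" for n, f in zip(names, combo) if f != 1.0)
            factor_label = combo[0] if sum(f != 1.0 for f in combo) == 1 else float("nan")
            cases.append((label, factor_label, p))
        return cases

    rows = []
    for rr in spec.rr_values:
        cases = _cases(rr)
        base_deaths = base_lyls = None
        for name, factor, params in cases:
            res = model.fit(params=params)
            deaths = res.net.cumulative_deaths_averted["both"]
            lyls = res.net.cumulative_lyls_averted["both"]
            if name == "base":
                base_deaths, base_lyls = deaths, lyls
            rows.append(
                {
                    "rr": rr,
                    "parameter": name,
                    "factor": factor,
                    "averted_deaths": deaths,
                    "averted_lyls": lyls,
                    "rel_diff_deaths": relative_change(base_deaths, deaths),
                    "rel_diff_lyls": relative_change(base_lyls, lyls),
                }
            )
    grid = pd.DataFrame(rows)
    # case sequence is identical for every rr, so the first-rr block aligns by position
    n_cases = len(grid) // len(spec.rr_values)
    for col, out in (
        ("averted_deaths", "rel_change_vs_first_rr_deaths"),
        ("averted_lyls", "rel_change_vs_first_rr_lyls"),
    ):
        first = grid[col].to_numpy()[:n_cases]
        grid[out] = [
            relative_change(first[i % n_cases], v) for i, v in enumerate(grid[col])
        ]
    return grid


@dataclass
class SurveySeries:
    """Observed prevalence points: columns year, gender, value (optionally age_group)."""

    data: pd.DataFrame
    source: str = "survey"

    def __post_init__(self) -> None:
        required = {"year", "gender", "value"}
        if required - set(self.data.columns):
            raise ConfigError(f"survey series needs columns {sorted(required)}")
        for _, sub in self.data.groupby("gender"):
            if sub["year"].duplicated().any():
                raise ConfigError("survey years must be strictly increasing per gender")


def validate_against_survey(
    model_prevalence: pd.DataFrame, survey: SurveySeries, period: tuple | None = None
) -> pd.DataFrame:
    """Compare model vs survey smoking prevalence through relative changes.

    model_prevalence: index year, columns per gender (as produced by the
    trajectory prevalence summaries). Returns one row per (gender, year) in
    the overlap with the per-year relative difference (model-survey)/survey,
    plus one ``endpoint`` row per gender holding the relative change of each
    series between the first and last overlapping year (or the given
    ``period`` endpoints).
    """
    rows = []
    for gender, sub in survey.data.groupby("gender"):
        sub = sub.sort_values("year")
        overlap = sub[sub["year"].isin(model_prevalence.index)]
        if len(overlap) == 0:
            raise CoverageError(f"no overlapping years for {gender}")
        y0, y1 = overlap["year"].iloc[0], overlap["year"].iloc[-1]
        if period is not None:
            y0, y1 = period
            if y0 not in overlap["year"].values or y1 not in overlap["year"].values:
                raise CoverageError(f"period endpoints {period} not in the overlap for {gender}")
        for _, r in overlap.iterrows():
            m = model_prevalence.loc[r["year"], gender]
            rows.append(
                {
                    "gender": gender,
                    "year": int(r["year"]),
                    "kind": "yearly",
                    "model": m,
                    "survey": r["value"],
                    "relative_difference": relative_change(r["value"], m),
                }
            )
        sv = overlap.set_index("year")["value"]
        rows.append(
            {
                "gender": gender,
                "year": int(y1),
                "kind": "endpoint_relative_change",
                "model": relative_change(
                    model_prevalence.loc[y0, gender], model_prevalence.loc[y1, gender]
                ),
                "survey": relative_change(sv.loc[y0], sv.loc[y1]),
                "relative_difference": np.nan,
            }
        )
    return pd.DataFrame(rows)
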