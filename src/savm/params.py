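"""Scenario parameters: the knobs of the NVP (vaping) scenario.

Defaults follow the Germany configuration: an NVP excess-mortality relative
risk of 5% of the smoking excess, smoking/NVP initiation multipliers of
88%/25% of the counterfactual smoking initiation rate, cessation multipliers
of 100%, the pre-loaded switching schedule halved, and a 10% annual decay of
switching from 2018 on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


class ParameterError(ValueError):
    """A scenario parameter is outside its admissible range."""


@dataclass(frozen=True)
class ScenarioParams:
    """All NVP-scenario knobs.

    Attributes
    ----------
    rr_nvp : float
        NVP users' excess mortality as a fraction of the smoking excess
        (current-smoker minus never-smoker mortality). In [0, 1].
    switch_scale : float
        Multiplier applied to the pre-loaded smoker-to-vaper switching
        schedule (0.50 for Germany).
    decay_factor : float
        Annual multiplicative decay of the switching rate (0.90 means a 10%
        reduction per year). In (0, 1].
    decay_start_year : int
        First calendar year the decay applies (exponent 0 before it).
    m_smk_init, m_nvp_init : float
        Smoking / NVP initiation multipliers relative to the counterfactual
        smoking initiation rate.
    m_smk_cess, m_nvp_cess : float
        Smoking / NVP cessation multipliers relative to the counterfactual
        smoking cessation rate.
    age35_threshold : int
        Quit-before-35 rule: smokers who quit (or switch to vaping) with
        attained age below this threshold carry never-smoker mortality.
    nvp_intro_year : int
        First year NVP flows are active; all NVP flows are zero before it.
    annual_change : dict
        Optional per-parameter annual change factors (name -> factor per
        year) applied as an exponential process from decay_start_year;
        switching decay is handled by decay_factor and need not appear here.
    """

    rr_nvp: float = 0.05
    switch_scale: float = 0.50
    decay_factor: float = 0.90
    decay_start_year: int = 2018
    m_smk_init: float = 0.88
    m_nvp_init: float = 0.25
    m_smk_cess: float = 1.00
    m_nvp_cess: float = 1.00
    age35_threshold: int = 35
    nvp_intro_year: int = 2012
    annual_change: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.rr_nvp <= 1.0:
            raise ParameterError(f"rr_nvp must be in [0,1], got {self.rr_nvp}")
        if not 0.0 < self.decay_factor <= 1.0:
            raise ParameterError(f"decay_factor must be in (0,1], got {self.decay_factor}")
        for name in ("switch_scale", "m_smk_init", "m_nvp_init", "m_smk_cess", "m_nvp_cess"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")

    MULTIPLIER_NAMES = ("switch_scale", "m_smk_init", "m_nvp_init", "m_smk_cess", "m_nvp_cess")

    def perturb(self, name: str, factor: float) -> "ScenarioParams":
        """Return a copy with one multiplier scaled by ``factor``."""
        if name not in self.MULTIPLIER_NAMES and name != "rr_nvp":
            raise ParameterError(f"unknown perturbable parameter: {name!r}")
        if factor <= 0:
            raise ParameterError("perturbation factor must be > 0")
        return replace(self, **{name: getattr(self, name) * factor})

    def with_rr(self, rr: float) -> "ScenarioParams":
        return replace(self, rr_nvp=rr)
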