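"""Synthetic input generation and a per-individual microsimulation oracle.

The generator builds a complete, internally consistent pair of input bundles
(country + reference) with no external data: Gompertz baseline mortality,
constant relative risks ordered current > former > never, initiation
concentrated at young adult ages, cessation rising with age, smooth grouped
prevalence curves, and life expectancies computed from the generated
mortality by period life table. Country tables differ from the reference
tables by configurable multiplicative offsets so every rescaling operation
is exercised nontrivially.

The microsimulation oracle follows one single-age, single-gender cohort of
individual agents through the identical survival -> transition rules with
pseudo-random draws, providing an independent check of the deterministic
cohort engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import N_STATES, CountryRates, UseState
from .inputs import CountryBundle, ReferenceBundle, smooth_group_prevalence
from .params import ScenarioParams
from .schedule import TransitionSchedule
from .tables import GENDERS, AgeGenderYearTable, GroupedTable

#: grouped current-smoking prevalence anchors, (age_lo, age_hi, value)
GERMANY_LIKE_GROUPS = [(18, 29, 0.347), (30, 44, 0.345), (45, 64, 0.304), (65, 99, 0.120)]
US_LIKE_GROUPS = [(18, 29, 0.213), (30, 44, 0.270), (45, 64, 0.221), (65, 99, 0.094)]


@dataclass
class FixtureConfig:
    """Knobs of the synthetic input generator.

    Defaults emulate a Germany-like setup: base year 2012, horizon 2060,
    adult ages 18-99, country smoking prevalence anchored at the published
    German survey group values with the reference anchored at US-like
    values, and the country about 5% above the reference in overall
    mortality.
    """

    seed: int = 0
    min_age: int = 18
    max_age: int = 99
    base_year: int = 2012
    end_year: int = 2060
    pop_scale: float = 500_000.0          # persons at the entry age
    pop_age_slope: float = -0.004         # log-linear pyramid slope per year of age
    pop_year_drift: float = 0.999         # total-population drift per calendar year
    gompertz_base: float = 2.5e-4         # never-smoker mortality at the entry age
    gompertz_rate: float = 0.085          # log-slope of mortality per year of age
    mort_improvement: float = 0.998       # mortality decline per calendar year
    rr_current: float = 2.5               # current/never mortality ratio
    rr_former: float = 1.4                # former/never mortality ratio
    init_peak: float = 0.045              # initiation rate at the entry age
    init_width: float = 5.0               # e-folding width of initiation decline
    cess_base: float = 0.02               # cessation rate at the entry age
    cess_slope: float = 0.0005            # cessation increase per year of age
    country_mort_offset: float = 1.05     # country/reference overall mortality ratio
    country_groups: list = field(default_factory=lambda: list(GERMANY_LIKE_GROUPS))
    reference_groups: list = field(default_factory=lambda: list(US_LIKE_GROUPS))
    gender_prev_scale: tuple = (1.17, 0.90)   # male/female scaling of the anchors
    former_base: float = 0.04             # former-smoker prevalence at the entry age
    former_slope: float = 0.004           # former-smoker increase per year of age
    noise_sd: float = 0.01               # lognormal jitter on the population pyramid

    def __post_init__(self) -> None:
        if not (self.min_age < self.max_age and self.base_year < self.end_year):
            raise ValueError("inconsistent age or year ranges")

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.min_age, self.max_age + 1)

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.base_year, self.end_year + 1)


def germany_like(seed: int = 0) -> FixtureConfig:
    """Germany-resembling preset (anchors from published 2012 survey groups).

    A resemblance for integration testing, not a reproduction of any
    official input set.
    """
    return FixtureConfig(seed=seed)


# --------------------------------------------------------------------- helpers
def _life_expectancy(mu_age: np.ndarray, ages: np.ndarray, gompertz_rate: float) -> np.ndarray:
    """Remaining life expectancy per age from a one-year mortality schedule.

    The schedule is extended beyond the top modeled age by continuing its
    log-linear (Gompertz) slope, capped at 1, so the tail of the life table
    closes properly.
    """
    ext_ages = np.arange(ages[0], 121)
    mu_ext = np.empty(len(ext_ages))
    mu_ext[: len(ages)] = mu_age
    tail = np.exp(gompertz_rate * (ext_ages[len(ages):] - ages[-1]))
    mu_ext[len(ages):] = np.minimum(mu_age[-1] * tail, 1.0)
    surv = np.concatenate([[1.0], np.cumprod(1.0 - mu_ext)])
    le = np.empty(len(ages))
    for i in range(len(ages)):
        l = surv[i: -1] / surv[i]
        # trapezoid within each year: deaths occur on average mid-year
        le[i] = np.sum((l[:-1] + l[1:]) / 2.0) if len(l) > 1 else 0.5
    return le


def _smooth_prev(groups: list, scale: tuple, ages: np.ndarray) -> np.ndarray:
    """(n_age, 2) smoothed current-smoking prevalence from grouped anchors."""
    rows = []
    for gi, gender in enumerate(GENDERS):
        for lo, hi, v in groups:
            rows.append({"age_lo": lo, "age_hi": hi, "gender": gender,
                         "value": min(v * scale[gi], 0.95)})
    return smooth_group_prevalence(GroupedTable(pd.DataFrame(rows)), ages).values[:, :, 0]


def _prevalence_dict(cur: np.ndarray, former: np.ndarray, ages: np.ndarray,
                     base_year: int) -> dict:
    never = 1.0 - cur - former
    if (never < 0).any():
        raise ValueError("generated prevalence exceeds 1")
    year = np.array([base_year])
    return {
        "never": AgeGenderYearTable(never[:, :, None], ages, year),
        "current": AgeGenderYearTable(cur[:, :, None], ages, year),
        "former": AgeGenderYearTable(former[:, :, None], ages, year),
    }


# --------------------------------------------------------------------- generator
def generate_bundles(cfg: FixtureConfig) -> tuple:
    """Deterministically generate a (CountryBundle, ReferenceBundle) pair."""
    rng = np.random.default_rng(cfg.seed)
    ages, years = cfg.ages, cfg.years
    A, Y = len(ages), len(years)
    rel_age = (ages - cfg.min_age).astype(float)

    # --- reference mortality by status (age x gender x year)
    gender_mult = np.array([1.0, 0.72])  # female baseline mortality below male
    mu_never = (
        cfg.gompertz_base
        * np.exp(cfg.gompertz_rate * rel_age)[:, None, None]
        * gender_mult[None, :, None]
        * (cfg.mort_improvement ** (years - cfg.base_year))[None, None, :]
    )
    mu_never = np.minimum(mu_never, 0.7)
    mu_curr = np.minimum(cfg.rr_current * mu_never, 0.95)
    mu_form = np.minimum(cfg.rr_former * mu_never, np.maximum(mu_curr, 0.95))
    mu_form = np.clip(mu_form, mu_never, mu_curr)

    def tbl(v):
        return AgeGenderYearTable(v, ages, years)

    # --- reference initiation / cessation
    init = cfg.init_peak * np.exp(-rel_age / cfg.init_width)
    init = np.repeat(init[:, None], 2, axis=1)
    init[:, 1] *= 0.9  # slightly lower female initiation
    cess = cfg.cess_base + cfg.cess_slope * rel_age
    cess = np.repeat(cess[:, None], 2, axis=1)
    init_tbl = tbl(np.repeat(init[:, :, None], Y, axis=2))
    cess_tbl = tbl(np.repeat(cess[:, :, None], Y, axis=2))

    # --- prevalence (base year)
    cur_ref = _smooth_prev(cfg.reference_groups, cfg.gender_prev_scale, ages)
    cur_cty = _smooth_prev(cfg.country_groups, cfg.gender_prev_scale, ages)
    former = np.minimum(cfg.former_base + cfg.former_slope * rel_age, 0.45)
    former = np.repeat(former[:, None], 2, axis=1)
    prev_ref = _prevalence_dict(cur_ref, former, ages, cfg.base_year)
    prev_cty = _prevalence_dict(cur_cty, former, ages, cfg.base_year)

    # --- overall mortality: prevalence-weighted mixture of the status rates
    def mixture(prev):
        w_n = prev["never"].values[:, :, 0][:, :, None]
        w_c = prev["current"].values[:, :, 0][:, :, None]
        w_f = prev["former"].values[:, :, 0][:, :, None]
        return w_n * mu_never + w_c * mu_curr + w_f * mu_form

    overall_ref = mixture(prev_ref)
    overall_cty = np.minimum(overall_ref * cfg.country_mort_offset, 1.0)

    # --- life expectancies from the generated mortality
    def le_table(mu):
        out = np.empty_like(mu)
        for gi in range(2):
            for yi in range(mu.shape[2]):
                out[:, gi, yi] = _life_expectancy(mu[:, gi, yi], ages, cfg.gompertz_rate)
        return out

    le_never_ref = le_table(mu_never)
    base_slice = slice(0, 1)
    le_overall_ref_base = AgeGenderYearTable(
        le_table(overall_ref[:, :, base_slice]), ages, years[:1]
    )
    le_overall_cty_base = AgeGenderYearTable(
        le_table(overall_cty[:, :, base_slice]), ages, years[:1]
    )

    # --- population projection with a mild seeded jitter on the pyramid
    pyramid = cfg.pop_scale * np.exp(cfg.pop_age_slope * rel_age)
    pyramid = pyramid[:, None] * np.array([[1.0, 1.02]])  # slight female surplus
    pyramid = pyramid * np.exp(rng.normal(0.0, cfg.noise_sd, size=pyramid.shape))
    drift = cfg.pop_year_drift ** (years - cfg.base_year)
    population = tbl(pyramid[:, :, None] * drift[None, None, :])

    country = CountryBundle(
        population=population,
        overall_mortality=tbl(overall_cty),
        le_overall_base=le_overall_cty_base,
        smoking_prevalence_base=prev_cty,
        base_year=cfg.base_year,
        end_year=cfg.end_year,
        min_age=cfg.min_age,
        max_age=cfg.max_age,
    )
    reference = ReferenceBundle(
        init=init_tbl,
        cess=cess_tbl,
        mort_never=tbl(mu_never),
        mort_current=tbl(mu_curr),
        mort_former=tbl(mu_form),
        le_never=tbl(le_never_ref),
        prev_base=prev_ref,
        le_overall_base=le_overall_ref_base,
        overall_mortality=tbl(overall_ref),
    )
    return country, reference


# --------------------------------------------------------------------- oracle
def microsim_oracle_cohort(
    init_dist: np.ndarray,   # (n_states,) initial shares of one cohort
    mu: np.ndarray,          # (n_years, n_states) state mortality per year
    smk_init: np.ndarray,    # (n_years,) per-year flow probabilities
    nvp_init: np.ndarray,
    smk_cess: np.ndarray,
    nvp_cess: np.ndarray,
    switch: np.ndarray,
    lowrisk: np.ndarray,     # (n_years,) attained age below the age-35 threshold
    n_agents: int,
    seed: int,
) -> tuple:
    """Agent-level Monte-Carlo of one cohort; returns (shares, se).

    shares[k] is the state distribution among survivors after k years;
    se[k] the binomial standard error sqrt(p(1-p)/n_alive). The initial
    states are allocated deterministically in proportion to ``init_dist``
    (each count within one agent of exact), so all Monte-Carlo noise comes
    from the survival and transition draws being checked. Refuses fewer
    than 1000 agents (too noisy to act as an oracle).
    """
    if n_agents < 1000:
        raise ValueError("n_agents must be >= 1000 for the oracle to be meaningful")
    if not np.isclose(init_dist.sum(), 1.0):
        raise ValueError("initial distribution must sum to 1")
    rng = np.random.default_rng(seed)
    n_years = mu.shape[0]
    bounds = np.round(np.cumsum(init_dist) / init_dist.sum() * n_agents).astype(int)
    counts = np.diff(np.concatenate([[0], bounds]))
    state = np.repeat(np.arange(N_STATES, dtype=np.int8), counts)
    alive = np.ones(n_agents, dtype=bool)

    shares = np.zeros((n_years + 1, N_STATES))
    se = np.zeros((n_years + 1, N_STATES))
    n_alive = np.zeros(n_years + 1, dtype=int)

    def record(k):
        n = int(alive.sum())
        counts = np.bincount(state[alive], minlength=N_STATES)
        p = counts / n
        shares[k] = p
        se[k] = np.sqrt(p * (1 - p) / n)
        n_alive[k] = n

    record(0)
    for k in range(n_years):
        u = rng.random(n_agents)
        dies = alive & (u < mu[k][state])
        alive &= ~dies

        u = rng.random(n_agents)
        s = state.copy()
        low = bool(lowrisk[k])

        is_never = alive & (s == UseState.NEVER)
        state[is_never & (u < smk_init[k])] = UseState.CURRENT_SMOKER
        state[is_never & (u >= smk_init[k]) & (u < smk_init[k] + nvp_init[k])] = UseState.NVP_USER

        is_cur = alive & (s == UseState.CURRENT_SMOKER)
        former_state = UseState.FORMER_SMOKER_LOWRISK if low else UseState.FORMER_SMOKER
        switch_state = UseState.NVP_EXSMOKER_LOWRISK if low else UseState.FS_NVP_USER
        state[is_cur & (u < smk_cess[k])] = former_state
        state[is_cur & (u >= smk_cess[k]) & (u < smk_cess[k] + switch[k])] = switch_state

        quit_nvp = alive & (u < nvp_cess[k])
        state[quit_nvp & np.isin(s, (UseState.NVP_USER, UseState.NVP_EXSMOKER_LOWRISK))] = (
            UseState.FORMER_NVP_USER
        )
        state[quit_nvp & (s == UseState.FS_NVP_USER)] = UseState.FORMER_NVP_EXSMOKER

        record(k + 1)
    return shares, se, n_alive


def microsim_oracle(
    bundle: CountryBundle,
    rates: CountryRates,
    params: ScenarioParams | None = None,
    schedule: TransitionSchedule | None = None,
    *,
    start_age: int,
    gender: str,
    n_years: int,
    n_agents: int = 100_000,
    seed: int = 0,
    fsnvp_excess_mode: str = "additive",
) -> tuple:
    """Monte-Carlo estimate of one cohort's state shares under either scenario.

    Follows the cohort entering at ``start_age`` in the base year for
    ``n_years`` years (ages start_age..start_age+n_years). Returns
    (shares, se, n_alive) with shares/se of shape (n_years+1, n_states).
    Horizons beyond 15 years are rejected: the oracle is a short-horizon
    checking device.
    """
    from .engine import init_no_nvp
    from .outcomes import build_excess_map

    if n_years > 15:
        raise ValueError("oracle horizon is limited to 15 years")
    gi = GENDERS.index(gender)
    ages = bundle.ages
    a0 = int(start_age) - bundle.min_age
    if a0 < 0 or a0 + n_years >= len(ages):
        raise ValueError("cohort would leave the modeled age range")
    threshold = params.age35_threshold if params is not None else 35
    rr = params.rr_nvp if (params is not None and schedule is not None) else 0.0

    excess = build_excess_map(rates, rr, fsnvp_excess_mode)
    mu_all = np.clip(rates.mort_never.values[None] + excess, 0.0, 1.0)

    ks = np.arange(n_years)
    diag_age = a0 + ks
    mu = mu_all[:, diag_age, gi, ks].T  # (n_years, n_states)
    zeros = np.zeros(n_years)
    if schedule is None:
        flows = dict(
            smk_init=rates.init.values[diag_age, gi, ks],
            nvp_init=zeros,
            smk_cess=rates.cess.values[diag_age, gi, ks],
            nvp_cess=zeros,
            switch=zeros,
        )
    else:
        flows = dict(
            smk_init=schedule.smk_init.values[diag_age, gi, ks],
            nvp_init=schedule.nvp_init.values[diag_age, gi, ks],
            smk_cess=schedule.smk_cess.values[diag_age, gi, ks],
            nvp_cess=schedule.nvp_cess.values[diag_age, gi, ks],
            switch=schedule.switch.values[diag_age, gi, ks],
        )
    lowrisk = (ages[diag_age] + 1) <= threshold - 1
    init_dist = init_no_nvp(bundle, threshold)[:, a0, gi]
    return microsim_oracle_cohort(
        init_dist, mu, flows["smk_init"], flows["nvp_init"], flows["smk_cess"],
        flows["nvp_cess"], flows["switch"], lowrisk, n_agents, seed,
    )
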