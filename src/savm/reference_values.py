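"""Published summary estimates from the original Germany application.

These are the printed headline results of the original Germany run of the
model (2012-2060, ages 18-99, NVP relative risk 5%): cumulative
attributable deaths and life-years lost per scenario and gender, prevalence
endpoints, the sensitivity grid of cumulative averted deaths/LYLs, and the
survey series used for relative-change validation. They are *inputs* for
arithmetic-identity checks of the net-impact, relative-change, and
sensitivity-report code — the package does not re-derive them, it recomputes
the derived quantities (differences, percentages, relative changes) from
them and they can be compared against the printed derived values.
"""

from __future__ import annotations

import pandas as pd

#: cumulative 2012-2060 totals by gender and scenario (deaths, life-years)
GERMANY_CUMULATIVE = {
    "male": {
        "sads_no_nvp": 4_956_100,
        "svads_nvp": 4_757_770,
        "lyls_no_nvp": 46_425_200,
        "lyls_nvp": 42_904_963,
    },
    "female": {
        "sads_no_nvp": 2_195_568,
        "svads_nvp": 2_101_907,
        "lyls_no_nvp": 18_462_657,
        "lyls_nvp": 17_247_469,
    },
}

#: both-gender No-NVP cumulative totals (the sensitivity tables' denominators)
GERMANY_TOTAL_SADS_NO_NVP = 7_151_668
GERMANY_TOTAL_LYLS_NO_NVP = 64_887_857

#: adult (18+) smoking prevalence endpoints, percent
GERMANY_PREVALENCE_2060 = {
    "male": {"no_nvp": 20.6, "nvp": 16.6},
    "female": {"no_nvp": 16.1, "nvp": 13.4},
}

#: cumulative averted deaths (SVADs) and LYLs by NVP relative risk and
#: one-at-a-time perturbation, as printed in the original sensitivity grids
GERMANY_SENSITIVITY_AVERTED = pd.DataFrame(
    [
        # scenario, rr, averted deaths, averted LYLs
        ("base", 0.05, 291_991, 4_735_424),
        ("base", 0.40, 167_127, 2_745_088),
        ("switching_x0.5", 0.05, 160_588, 2_737_897),
        ("switching_x0.5", 0.40, 89_496, 1_517_938),
        ("switching_x1.5", 0.05, 414_852, 6_589_927),
        ("switching_x1.5", 0.40, 239_723, 3_884_888),
        ("smk_init_x0.5", 0.05, 345_646, 6_282_285),
        ("smk_init_x0.5", 0.40, 222_726, 4_343_035),
        ("smk_init_x1.5", 0.05, 245_410, 3_412_112),
        ("smk_init_x1.5", 0.40, 118_780, 1_375_850),
        ("nvp_init_x0.5", 0.05, 290_608, 4_688_798),
        ("nvp_init_x0.5", 0.40, 172_263, 2_885_784),
        ("nvp_init_x1.5", 0.05, 293_338, 4_780_843),
        ("nvp_init_x1.5", 0.40, 162_200, 2_610_916),
        ("smk_cess_x0.5", 0.05, -769_218, -5_390_126),
        ("smk_cess_x0.5", 0.40, -906_453, -7_516_335),
        ("smk_cess_x1.5", 0.05, 972_300, 11_957_832),
        ("smk_cess_x1.5", 0.40, 857_132, 10_081_676),
        ("nvp_cess_x0.5", 0.05, 284_899, 4_658_618),
        ("nvp_cess_x0.5", 0.40, 116_621, 2_156_853),
        ("nvp_cess_x1.5", 0.05, 296_656, 4_791_564),
        ("nvp_cess_x1.5", 0.40, 200_873, 3_177_221),
    ],
    columns=["scenario", "rr", "averted_deaths", "averted_lyls"],
)

#: smoking-prevalence validation points, percent (model = NVP scenario, 15+)
GERMANY_VALIDATION_MODEL = pd.DataFrame(
    [
        ("male", 2014, 29.1), ("male", 2020, 24.7),
        ("female", 2014, 22.5), ("female", 2020, 19.6),
    ],
    columns=["gender", "year", "value"],
)
GERMANY_VALIDATION_EUROBAROMETER = pd.DataFrame(
    [
        ("male", 2014, 33.83), ("male", 2020, 27.6),
        ("female", 2014, 20.8), ("female", 2020, 18.8),
    ],
    columns=["gender", "year", "value"],
)
#: 2017 Microcensus comparison (18+, percent): model vs survey
GERMANY_MICROCENSUS_2017 = {
    "male": {"model": 27.4, "survey": 26.4},
    "female": {"model": 21.5, "survey": 18.6},
}
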