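"""Published New Zealand knee-OA burden estimates used as desk-check inputs.

These are the headline result tables of the NZ knee-osteoarthritis burden
study this package models: quality-adjusted life expectancies (QALE) and
QALY losses per ethnicity × sex group, and per 5-year age band.  They are
*inputs* for arithmetic cross-checks — the burden operations, fed the
published QALE columns, must reproduce the published loss columns — not
outputs of this package.

All QALE/loss values are in QALYs; ``proportion_with_oa`` is a proportion;
population losses are total QALYs for the 2006 NZ adult population.
"""

from __future__ import annotations

import pandas as pd

# Group-level summary: weighted QALE without / with knee OA, the
# counterfactual QALE (no-OA QALE weighted by the OA age distribution),
# per-person QALY loss, and population QALY loss.
SUMMARY_ROWS = [
    # (ethnicity, sex, qale_no_oa, qale_oa, qale_counterfactual, per_person_loss, population_loss)
    ("non_maori", "male", 19.73, 12.20, 15.54, 3.34, 166_023),
    ("non_maori", "female", 21.96, 12.22, 15.77, 3.55, 272_568),
    ("maori", "male", 17.57, 10.05, 12.64, 2.60, 11_562),
    ("maori", "female", 19.78, 12.17, 15.55, 3.38, 17_087),
    ("all", "all", 20.67, 12.14, 15.57, 3.44, 467_240),
]

# Band-level detail: proportion with knee OA, QALE without / with knee OA,
# per-person QALY loss and population QALY loss per stratum.
STRATA_ROWS = [
    # (ethnicity, sex, age_band, proportion_with_oa, qale_no_oa, qale_oa,
    #  per_person_loss, population_loss)
    ("non_maori", "male", "40–44", 0.012, 28.82, 22.34, 6.48, 10551.97),
    ("non_maori", "male", "45–49", 0.048, 25.39, 19.84, 5.55, 35422.91),
    ("non_maori", "male", "50–54", 0.048, 22.02, 17.29, 4.73, 26514.94),
    ("non_maori", "male", "55–59", 0.063, 18.77, 14.74, 4.03, 27745.57),
    ("non_maori", "male", "60–64", 0.063, 15.63, 12.31, 3.32, 17814.60),
    ("non_maori", "male", "65–69", 0.114, 12.69, 9.99, 2.70, 21586.74),
    ("non_maori", "male", "70–74", 0.114, 9.90, 7.81, 2.09, 12914.12),
    ("non_maori", "male", "75–79", 0.127, 7.41, 5.85, 1.57, 9131.25),
    ("non_maori", "male", "80–84", 0.128, 5.39, 4.24, 1.15, 4341.30),
    ("non_maori", "female", "40–44", 0.008, 31.33, 24.03, 7.30, 8426.69),
    ("non_maori", "female", "45–49", 0.045, 27.92, 21.52, 6.40, 39248.26),
    ("non_maori", "female", "50–54", 0.045, 24.53, 18.96, 5.57, 29815.42),
    ("non_maori", "female", "55–59", 0.105, 21.19, 16.37, 4.82, 56407.82),
    ("non_maori", "female", "60–64", 0.104, 17.92, 13.85, 4.06, 36980.56),
    ("non_maori", "female", "65–69", 0.170, 14.73, 11.43, 3.30, 41482.76),
    ("non_maori", "female", "70–74", 0.169, 11.61, 9.06, 2.55, 25454.77),
    ("non_maori", "female", "75–79", 0.216, 8.75, 6.84, 1.92, 22157.55),
    ("non_maori", "female", "80–84", 0.215, 6.32, 4.95, 1.37, 12593.97),
    ("maori", "male", "40–44", 0.009, 23.41, 18.49, 4.93, 814.83),
    ("maori", "male", "45–49", 0.029, 20.28, 16.12, 4.15, 2002.33),
    ("maori", "male", "50–54", 0.029, 17.27, 13.76, 3.51, 1303.93),
    ("maori", "male", "55–59", 0.097, 14.47, 11.52, 2.95, 2890.25),
    ("maori", "male", "60–64", 0.097, 11.97, 9.52, 2.45, 1610.46),
    ("maori", "male", "65–69", 0.144, 9.76, 7.74, 2.02, 1575.02),
    ("maori", "male", "70–74", 0.144, 7.68, 6.10, 1.58, 760.76),
    ("maori", "male", "75–79", 0.208, 5.82, 4.60, 1.22, 455.82),
    ("maori", "male", "80–84", 0.208, 4.33, 3.40, 0.93, 148.57),
    ("maori", "female", "40–44", 0.013, 26.14, 20.40, 5.74, 1578.25),
    ("maori", "female", "45–49", 0.048, 22.86, 17.92, 4.94, 4433.65),
    ("maori", "female", "50–54", 0.048, 19.72, 15.47, 4.24, 2858.42),
    ("maori", "female", "55–59", 0.070, 16.75, 13.10, 3.65, 2767.53),
    ("maori", "female", "60–64", 0.070, 13.98, 10.91, 3.07, 1577.79),
    ("maori", "female", "65–69", 0.131, 11.50, 8.97, 2.53, 1965.30),
    ("maori", "female", "70–74", 0.131, 9.16, 7.18, 1.98, 984.28),
    ("maori", "female", "75–79", 0.183, 7.04, 5.51, 1.53, 669.54),
    ("maori", "female", "80–84", 0.183, 5.22, 4.10, 1.12, 252.13),
]

#: Published headline values under the transformed (trade-off-style) value
#: set and the sensitivity analyses, for context in reports.
TRANSFORMED_PER_PERSON_LOSS = 1.65
TRANSFORMED_POPULATION_LOSS = 224_364
PSA_UI_MODERATE_SHARE = (1.42, 1.86)
PSA_UI_UNADJUSTED_PREVALENCE = (1.52, 1.94)
PROPORTION_LOST_RANGE = (0.20, 0.23)


def summary_frame() -> pd.DataFrame:
    return pd.DataFrame(
        SUMMARY_ROWS,
        columns=[
            "ethnicity", "sex", "qale_no_oa", "qale_oa", "qale_counterfactual",
            "per_person_loss", "population_loss",
        ],
    )


def strata_frame() -> pd.DataFrame:
    return pd.DataFrame(
        STRATA_ROWS,
        columns=[
            "ethnicity", "sex", "age_band", "proportion_with_oa",
            "qale_no_oa", "qale_oa", "per_person_loss", "population_loss",
        ],
    )
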