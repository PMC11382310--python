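"""Published summary statistics of the motivating cohort study.

The motivating single-center photon-vs-proton esophageal-cancer cohort
(734 patients; 506 after 1:1 propensity matching) is not publicly
deposited, but its published summary tables are. The 2x2 contingency
tables below (matched cohort, mediator = grade-4 radiation-induced
lymphopenia) are the inputs for validating the logistic fitter against the
published univariable odds ratios, and the headline figures calibrate the
synthetic generator. Counts are (mediator-negative, mediator-positive) per
level, reference level first.
"""

#: matched-cohort 2x2/2xk tables: level -> (n mediator=0, n mediator=1)
MATCHED_TABLES = {
    "modality": {"IMRT": (147, 106), "PBT": (195, 58)},
    "surgery": {"no": (146, 89), "yes": (196, 75)},
    "location": {"upper-middle": (56, 16), "lower": (286, 148)},
    "stage": {"I": (27, 5), "II": (109, 41), "III": (206, 118)},
    "ecog": {"1-2": (137, 52), "0": (205, 112)},
}

#: published univariable odds ratios for the same tables (2 dp)
PUBLISHED_OR = {
    "modality": 0.41,   # PBT vs IMRT
    "surgery": 0.63,    # yes vs no
    "location": 1.81,   # lower vs upper-middle
    "stage_iii": 3.09,  # III vs I
    "ecog": 1.44,       # 0 vs 1-2
}

#: full-cohort mediator counts by arm: (n mediator=0, n mediator=1)
FULL_COHORT_G4RIL = {"IMRT": (257, 212), "PBT": (205, 60)}

#: headline published figures used for generator calibration
HEADLINE = {
    "g4ril_prevalence_imrt": 0.452,
    "g4ril_prevalence_pbt_full": 0.226,
    "g4ril_incidence_pbt_matched_pct": 22.9,  # 58 / 253
    "median_os_imrt_months": 40.9,
    "mediator_death_hr": 1.49,
    "direct_modality_hr": 0.79,
    "nie_hr": 0.95,
    "exposure_prevalence": 265 / 734,
}


def expand_table(table: dict):
    """Long-format (y, level) rows from a level -> (n0, n1) table."""
    ys, levels = [], []
    for level, (n0, n1) in table.items():
        ys.extend([0] * n0 + [1] * n1)
        levels.extend([level] * (n0 + n1))
    return ys, levels
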