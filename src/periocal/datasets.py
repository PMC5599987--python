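"""Published reference estimates shipped as package inputs.

A nationwide Taiwanese periodontal survey (3,860 adults, 17,244 sextants,
twelve trained dentists in six regions, validated against a single
gold-standard periodontist) reported adjusted odds ratios for periodontal
disease risk factors before and after misclassification calibration,
together with the exposure prevalences used for attributable-proportion
arithmetic, under three outcome definitions.  Those printed point
estimates are reproduced here as input data: the raw survey records are
not publicly deposited, but the AR/PAR arithmetic (and the report cells
it produced) can be recomputed exactly from these numbers.

``ar/par_*_pct`` columns hold the published whole-percent report cells,
used only as an external cross-check of the effects module.
"""

from __future__ import annotations

import pandas as pd

_COLUMNS = [
    "outcome",
    "variable",
    "exposure",
    "or_uncal",
    "ar_uncal_pct",
    "par_uncal_pct",
    "or_cal",
    "ar_cal_pct",
    "par_cal_pct",
]

# outcome, variable, e, OR_uncal, AR%, PAR%, OR_cal, AR%, PAR%
_ROWS = [
    ("combined", "education", 0.40, 1.37, 27, 13, 1.75, 43, 23),
    ("combined", "bmi", 0.35, 1.02, 2, 1, 1.05, 5, 2),
    ("combined", "pre_dm", 0.16, 1.03, 3, 0, 1.31, 24, 5),
    ("combined", "dm", 0.06, 1.62, 38, 4, 2.96, 66, 11),
    ("combined", "smoking", 0.22, 2.00, 50, 18, 2.86, 65, 29),
    ("cpi", "education", 0.40, 1.27, 21, 10, 1.44, 31, 15),
    ("cpi", "bmi", 0.35, 1.10, 9, 3, 1.15, 13, 5),
    ("cpi", "pre_dm", 0.16, 0.99, -1, 0, 1.13, 12, 2),
    ("cpi", "dm", 0.06, 1.50, 33, 3, 2.26, 56, 7),
    ("cpi", "smoking", 0.22, 2.02, 50, 18, 2.75, 64, 28),
    ("la", "education", 0.40, 1.29, 22, 10, 2.14, 53, 31),
    ("la", "bmi", 0.35, 0.91, -10, -3, 0.86, -16, -5),
    ("la", "pre_dm", 0.16, 0.96, -4, -1, 1.51, 34, 8),
    ("la", "dm", 0.06, 1.49, 33, 3, 3.24, 69, 12),
    ("la", "smoking", 0.22, 1.93, 48, 17, 3.85, 74, 39),
]


def published_survey_effects() -> pd.DataFrame:
    """Adjusted ORs, exposure prevalences and published AR/PAR cells.

    ``outcome`` is the disease definition: ``combined`` (CPI >= 3 or
    LA >= 1), ``cpi`` (CPI >= 3) or ``la`` (LA >= 1).
    """
    return pd.DataFrame(_ROWS, columns=_COLUMNS)


#: overall sextant-level rater accuracy published for the same survey
PUBLISHED_OVERALL_ACCURACY = {
    "cpi": (0.73, 0.82),
    "la": (0.67, 0.73),
    "combined": (0.78, 0.69),
}
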