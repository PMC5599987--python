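"""Attributable and population-attributable proportions from odds ratios.

For an exposure with odds ratio OR and population exposure prevalence e:

    AR  = (OR - 1) / OR                       (attributable proportion)
    PAR = e (OR - 1) / (1 + e (OR - 1))       (population attributable
                                               proportion)

AR is the fraction of disease among the exposed attributable to the
exposure; PAR the fraction of disease in the whole population removable
by eliminating it.  Both are signed: a protective exposure (OR < 1)
yields negative values.  Report tables are rounded half-up to whole
percentages; full precision is kept internally.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import CalibratedFit

__all__ = [
    "attributable_proportion",
    "population_attributable_proportion",
    "percent_half_up",
    "effect_table_from_ors",
    "effect_table",
]


def attributable_proportion(odds_ratio: float) -> float:
    """AR = (OR - 1)/OR; signed, negative for protective exposures."""
    if not odds_ratio > 0:
        raise ValueError(f"odds ratio must be positive, got {odds_ratio}")
    return (odds_ratio - 1.0) / odds_ratio


def population_attributable_proportion(odds_ratio: float, exposure: float) -> float:
    """PAR = e(OR - 1) / (1 + e(OR - 1)) at exposure prevalence e."""
    if not odds_ratio > 0:
        raise ValueError(f"odds ratio must be positive, got {odds_ratio}")
    if not 0.0 <= exposure <= 1.0:
        raise ValueError(f"exposure prevalence must lie in [0,1], got {exposure}")
    denom = 1.0 + exposure * (odds_ratio - 1.0)
    if denom <= 0:
        raise ValueError(
            f"inadmissible combination OR={odds_ratio}, e={exposure}: "
            "1 + e(OR-1) <= 0"
        )
    return exposure * (odds_ratio - 1.0) / denom


def percent_half_up(x: float) -> int:
    """Round a signed proportion to a whole percentage, halves away from 0."""
    return int(
        Decimal(repr(100.0 * x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP)
    )


def effect_table_from_ors(estimates: pd.DataFrame, percent: bool = True) -> pd.DataFrame:
    """Compute AR/PAR columns from a table of odds ratios.

    ``estimates`` needs columns ``variable``, ``exposure``, ``or_uncal``,
    ``or_cal`` (extra columns pass through).  Adds raw ``ar_*``/``par_*``
    proportions and, when ``percent``, the half-up whole-percent report
    columns ``*_pct``.
    """
    required = {"variable", "exposure", "or_uncal", "or_cal"}
    missing = required - set(estimates.columns)
    if missing:
        raise ValueError(f"estimates table lacks columns {sorted(missing)}")
    out = estimates.copy()
    for mode in ("uncal", "cal"):
        ors = out[f"or_{mode}"].astype(float)
        out[f"ar_{mode}"] = [attributable_proportion(v) for v in ors]
        out[f"par_{mode}"] = [
            population_attributable_proportion(v, e)
            for v, e in zip(ors, out["exposure"].astype(float))
        ]
        if percent:
            out[f"ar_{mode}_pct"] = [percent_half_up(v) for v in out[f"ar_{mode}"]]
            out[f"par_{mode}_pct"] = [percent_half_up(v) for v in out[f"par_{mode}"]]
    return out


def effect_table(
    fit_uncal: CalibratedFit,
    fit_cal: CalibratedFit,
    exposures: Mapping[str, float],
    variables: Optional[Sequence[str]] = None,
    percent: bool = True,
) -> pd.DataFrame:
    """AR/PAR table comparing an uncalibrated and a calibrated fit.

    One row per binary exposure in ``exposures`` (continuous covariates
    like age, and variables without a prevalence, have no AR/PAR and are
    omitted).  Both fits must estimate every requested variable; the
    posterior-median ORs are used as point estimates.
    """
    have_u = set(fit_uncal.or_summary["covariate"])
    have_c = set(fit_cal.or_summary["covariate"])
    if variables is None:
        variables = [v for v in exposures if v in (have_u & have_c)]
    rows = []
    for v in variables:
        if v not in have_u or v not in have_c:
            raise ValueError(
                f"variable {v!r} is missing from the "
                f"{'uncalibrated' if v not in have_u else 'calibrated'} fit"
            )
        if v not in exposures:
            raise ValueError(f"no exposure prevalence supplied for {v!r}")
        rows.append(
            {
                "variable": v,
                "exposure": float(exposures[v]),
                "or_uncal": fit_uncal.odds_ratio(v)[0],
                "or_cal": fit_cal.odds_ratio(v)[0],
            }
        )
    return effect_table_from_ors(pd.DataFrame(rows), percent=percent)
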