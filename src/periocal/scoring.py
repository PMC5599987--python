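"""Sextant-level scoring of periodontal examination data.

Periodontal surveys score each of six probing sites per tooth with the
community periodontal index (CPI, ordinal 0-4: healthy, gingival bleeding,
calculus, 4-5 mm pockets, >=6 mm pockets) and a loss-of-attachment (LA)
score (ordinal >= 0).  The analysis unit is the *sextant*, one of six
segments of the dentition, represented by the highest site score within it.
Disease status is then a dichotomization of the sextant scores.

This module provides the site->sextant aggregation, the outcome
definitions (``cpi``: CPI >= c; ``la``: LA >= 1; ``combined``: either),
and schema-checked CSV readers/writers for the sextant table used by the
rest of the package.
"""

from __future__ import annotations

import logging
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CPI_LEVELS = (0, 1, 2, 3, 4)

#: outcome definitions supported throughout the package
OUTCOME_DEFINITIONS = ("cpi", "la", "combined")

#: canonical column order of the sextant-level survey table
SURVEY_COLUMNS = [
    "subject_id",
    "rater_id",
    "region_id",
    "sextant_index",
    "gender",
    "age",
    "education",
    "bmi",
    "pre_dm",
    "dm",
    "smoking",
    "alcohol",
    "cpi",
    "la",
    "y_obs",
]

#: binary covariates plus continuous age; dm status is encoded as the two
#: indicator contrasts pre_dm and dm versus normal
COVARIATES = [
    "gender",
    "age",
    "education",
    "bmi",
    "pre_dm",
    "dm",
    "smoking",
    "alcohol",
]


class SextantScore(NamedTuple):
    """Representative (CPI, LA) pair for one sextant."""

    cpi: int
    la: int


def aggregate_sextant(
    cpi_sites: Sequence[int], la_sites: Sequence[int]
) -> Optional[SextantScore]:
    """Aggregate site scores to the sextant representative (the site maxima).

    Parameters
    ----------
    cpi_sites, la_sites
        CPI and LA scores of the probed sites of one sextant.  The two
        sequences may have different lengths (a site can be unscorable for
        one index only); each must contain valid scores.

    Returns
    -------
    SextantScore or None
        Element-wise maxima, or ``None`` when *both* score lists are empty —
        the missing-sextant signal (an edentulous or unscorable sextant is
        missing, never "healthy").
    """
    cpi_sites = list(cpi_sites)
    la_sites = list(la_sites)
    if not cpi_sites and not la_sites:
        return None
    if not cpi_sites or not la_sites:
        raise ValueError(
            "sextant has sites scored for one index only; supply both CPI "
            "and LA site scores or neither"
        )
    for s in cpi_sites:
        if s not in CPI_LEVELS:
            raise ValueError(f"CPI site score {s!r} outside the 0-4 scale")
    for s in la_sites:
        if s < 0:
            raise ValueError(f"LA site score {s!r} is negative")
    return SextantScore(cpi=max(cpi_sites), la=max(la_sites))


def dichotomize(
    cpi: object, la: object, definition: str = "combined", cutoff: int = 3
) -> Optional[int]:
    """Dichotomize sextant scores into the binary disease outcome.

    ``definition`` is one of ``"cpi"`` (CPI >= cutoff), ``"la"`` (LA >= 1) or
    ``"combined"`` (either condition).  A missing score that the chosen
    definition needs yields ``None`` (missing outcome), never 0.
    """
    if definition not in OUTCOME_DEFINITIONS:
        raise ValueError(
            f"unknown outcome definition {definition!r}; "
            f"expected one of {OUTCOME_DEFINITIONS}"
        )
    cpi_missing = cpi is None or (isinstance(cpi, float) and np.isnan(cpi))
    la_missing = la is None or (isinstance(la, float) and np.isnan(la))
    if definition == "cpi":
        if cpi_missing:
            return None
        return int(cpi >= cutoff)
    if definition == "la":
        if la_missing:
            return None
        return int(la >= 1)
    if cpi_missing or la_missing:
        # "combined" can still resolve to 1 if the present score fires
        if not cpi_missing and cpi >= cutoff:
            return 1
        if not la_missing and la >= 1:
            return 1
        return None
    return int(cpi >= cutoff or la >= 1)


def apply_outcome(
    records: pd.DataFrame, definition: str = "combined", cutoff: int = 3
) -> pd.DataFrame:
    """Return a copy of ``records`` with the binary outcome column ``y``.

    Rows whose outcome is undeterminable get ``y = NaN`` and are counted in
    a log line; downstream model builders drop them explicitly.
    """
    out = records.copy()
    y = [
        dichotomize(c, l, definition=definition, cutoff=cutoff)
        for c, l in zip(out["cpi"], out["la"])
    ]
    out["y"] = pd.array(y, dtype="Int64").astype("float64")
    n_missing = int(out["y"].isna().sum())
    logger.info(
        "outcome %s (cutoff %d): %d records, %d with missing outcome",
        definition,
        cutoff,
        len(out),
        n_missing,
    )
    return out


def drop_empty_subjects(records: pd.DataFrame) -> pd.DataFrame:
    """Drop subjects with no scorable sextant at all, logging the count.

    Subjects contributing partial data (1-5 scorable sextants) are kept.
    """
    scorable = records["cpi"].notna() | records["la"].notna()
    keep_subjects = records.loc[scorable, "subject_id"].unique()
    dropped = records["subject_id"].nunique() - len(keep_subjects)
    if dropped:
        logger.info("dropped %d subjects with all sextants missing", dropped)
    return records[records["subject_id"].isin(keep_subjects)].copy()


_DTYPES = {
    "subject_id": "int64",
    "rater_id": "int64",
    "region_id": "int64",
    "sextant_index": "int64",
    "gender": "int64",
    "age": "float64",
    "education": "int64",
    "bmi": "int64",
    "pre_dm": "int64",
    "dm": "int64",
    "smoking": "int64",
    "alcohol": "int64",
    "cpi": "float64",  # float to admit NaN for missing sextants
    "la": "float64",
    "y_obs": "float64",
}


def read_survey_csv(path) -> pd.DataFrame:
    """Read a sextant-level survey table, enforcing the documented schema."""
    df = pd.read_csv(path)
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"survey file {path} lacks required columns {missing}")
    df = df[SURVEY_COLUMNS].astype(_DTYPES)
    bad = df["sextant_index"].dropna()
    if not bad.isin(range(1, 7)).all():
        raise ValueError("sextant_index outside the WHO 1-6 convention")
    logger.info("read %d sextant records from %s", len(df), path)
    return df


def write_survey_csv(records: pd.DataFrame, path) -> None:
    """Write a sextant-level survey table in canonical column order."""
    records[SURVEY_COLUMNS].to_csv(path, index=False)
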