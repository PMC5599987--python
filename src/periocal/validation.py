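"""Rater accuracy estimation from a paired validation substudy.

A validation study scores the same units (sextants) with both a
gold-standard examiner and the trained field raters.  From the paired
binary outcomes this module estimates sensitivity Se = TP/(TP+FN) and
specificity Sp = TN/(TN+FP) per stratum (rater, region, or pooled), with
exact Clopper-Pearson binomial confidence intervals, plus the positive
likelihood ratio LR+ = Se/(1-Sp) summarizing how informative a rater's
positive call is.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

logger = logging.getLogger(__name__)

STRATA = ("rater", "region", "overall")


@dataclass(frozen=True)
class AccuracyEstimate:
    """Se/Sp/LR+ of one stratum of validation pairs."""

    stratum: str
    tp: int
    fn: int
    fp: int
    tn: int
    se: Optional[float]
    sp: Optional[float]
    se_ci: Optional[Tuple[float, float]]
    sp_ci: Optional[Tuple[float, float]]
    lr_plus: Optional[float]

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def binomial_ci(
    successes: int, trials: int, level: float = 0.95
) -> Tuple[float, float]:
    """Exact (Clopper-Pearson) two-sided binomial confidence interval.

    The interval inverts the binomial tail probabilities, so at the
    boundaries the bounds are exact: 0 successes gives a lower bound of 0,
    ``trials`` successes an upper bound of 1.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in [0, trials]")
    if not 0 < level < 1:
        raise ValueError("level must be in (0,1)")
    lo, hi = proportion_confint(successes, trials, alpha=1 - level, method="beta")
    # statsmodels returns NaN rather than the exact bound at the edges
    lo = 0.0 if math.isnan(lo) else float(lo)
    hi = 1.0 if math.isnan(hi) else float(hi)
    return lo, hi


def lr_plus(se: float, sp: float) -> float:
    """Positive likelihood ratio se/(1-sp); +inf when sp == 1."""
    if not 0 <= se <= 1:
        raise ValueError("sensitivity outside [0,1]")
    if not 0 <= sp <= 1:
        raise ValueError("specificity outside [0,1]")
    if sp == 1:
        return math.inf
    return se / (1 - sp)


def _estimate_one(label: str, sub: pd.DataFrame, level: float) -> AccuracyEstimate:
    gold = sub["gold"].to_numpy(dtype=int)
    rated = sub["rated"].to_numpy(dtype=int)
    tp = int(np.sum((gold == 1) & (rated == 1)))
    fn = int(np.sum((gold == 1) & (rated == 0)))
    fp = int(np.sum((gold == 0) & (rated == 1)))
    tn = int(np.sum((gold == 0) & (rated == 0)))
    se = sp = se_ci = sp_ci = lrp = None
    if tp + fn > 0:
        se = tp / (tp + fn)
        se_ci = binomial_ci(tp, tp + fn, level)
    else:
        logger.warning("stratum %s has no gold-positive units; Se undefined", label)
    if tn + fp > 0:
        sp = tn / (tn + fp)
        sp_ci = binomial_ci(tn, tn + fp, level)
    else:
        logger.warning("stratum %s has no gold-negative units; Sp undefined", label)
    if se is not None and sp is not None:
        lrp = lr_plus(se, sp)
    return AccuracyEstimate(label, tp, fn, fp, tn, se, sp, se_ci, sp_ci, lrp)


def estimate_accuracy(
    pairs: pd.DataFrame, strata: str = "region", level: float = 0.95
) -> list[AccuracyEstimate]:
    """Estimate Se/Sp/LR+ per stratum plus the pooled "overall" stratum.

    Parameters
    ----------
    pairs
        Validation pairs with integer ``gold`` and ``rated`` columns and,
        for stratified estimates, ``rater_id`` / ``region_id``.
    strata
        ``"rater"``, ``"region"`` or ``"overall"``.

    Strata with no gold-positive (-negative) units get a missing Se (Sp)
    with a logged warning rather than a 0.
    """
    if strata not in STRATA:
        raise ValueError(f"strata must be one of {STRATA}")
    bad = set(np.unique(pairs[["gold", "rated"]])) - {0, 1}
    if bad:
        raise ValueError(f"gold/rated scores must be binary, found {sorted(bad)}")
    out: list[AccuracyEstimate] = []
    if strata != "overall":
        key = f"{strata}_id"
        for value, sub in pairs.groupby(key, sort=True):
            out.append(_estimate_one(f"{strata}={value}", sub, level))
    out.append(_estimate_one("overall", pairs, level))
    assert out[-1].n == len(pairs)
    return out


def accuracy_table(estimates: list[AccuracyEstimate]) -> pd.DataFrame:
    """Tidy DataFrame of accuracy estimates (one row per stratum)."""
    rows = []
    for e in estimates:
        rows.append(
            {
                "stratum": e.stratum,
                "n": e.n,
                "tp": e.tp,
                "fn": e.fn,
                "fp": e.fp,
                "tn": e.tn,
                "se": e.se,
                "se_lo": e.se_ci[0] if e.se_ci else None,
                "se_hi": e.se_ci[1] if e.se_ci else None,
                "sp": e.sp,
                "sp_lo": e.sp_ci[0] if e.sp_ci else None,
                "sp_hi": e.sp_ci[1] if e.sp_ci else None,
                "lr_plus": e.lr_plus,
            }
        )
    return pd.DataFrame(rows)


def rater_accuracy_map(
    pairs: pd.DataFrame, min_pairs: int = 20, level: float = 0.95
) -> dict[int, Tuple[float, float]]:
    """Per-rater (Se, Sp) point estimates for the calibrated model.

    Raters whose validation stratum is too sparse (< ``min_pairs`` pairs,
    or with an undefined Se or Sp) fall back to the pooled overall
    estimate, which must itself be defined.
    """
    per_rater = {
        e.stratum: e for e in estimate_accuracy(pairs, "rater", level)[:-1]
    }
    overall = estimate_accuracy(pairs, "overall", level)[0]
    if overall.se is None or overall.sp is None:
        raise ValueError("pooled validation data cannot identify Se and Sp")
    out: dict[int, Tuple[float, float]] = {}
    for rid in sorted(pairs["rater_id"].unique()):
        e = per_rater[f"rater={rid}"]
        if e.n < min_pairs or e.se is None or e.sp is None:
            out[int(rid)] = (overall.se, overall.sp)
        else:
            out[int(rid)] = (e.se, e.sp)
    return out
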