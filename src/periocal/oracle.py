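"""Brute-force grid posterior for two-parameter misclassified 2x2 fits.

An independent check of the MCMC machinery: for a 2x2 table (exposed /
unexposed, observed positives / totals) scored by a rater with fixed
sensitivity/specificity, the posterior over (b0, b1) — baseline log-odds
and log odds ratio — is evaluated by direct numerical integration on a
dense grid.  The likelihood is rebuilt here from first principles (no
shared code with the sampling path):

    p1 = expit(b0 + b1),  p0 = expit(b0),
    q  = Se * p + (1 - Sp) * (1 - p),
    L  = q1^s1 (1-q1)^(m1-s1) * q0^s0 (1-q0)^(m0-s0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
from scipy.special import expit, logit, logsumexp

from .model import rogan_gladen_correct


@dataclass
class GridPosterior:
    """Marginal posterior moments from grid integration."""

    mean: Dict[str, float]
    sd: Dict[str, float]
    median: Dict[str, float]
    q2_5: Dict[str, float]
    q97_5: Dict[str, float]
    mode: Dict[str, float]
    n_grid: int


def _marginal_stats(grid: np.ndarray, logpost: np.ndarray, axis: int):
    lw = logsumexp(logpost, axis=axis)
    w = np.exp(lw - logsumexp(lw))
    mean = float(np.sum(w * grid))
    sd = float(np.sqrt(np.sum(w * (grid - mean) ** 2)))
    cdf = np.cumsum(w)
    med, lo, hi = np.interp([0.5, 0.025, 0.975], cdf, grid)
    return mean, sd, float(med), float(lo), float(hi)


def grid_posterior_2x2(
    s_exposed: int,
    m_exposed: int,
    s_unexposed: int,
    m_unexposed: int,
    se: float = 1.0,
    sp: float = 1.0,
    coef_scale: float = 10.0,
    n_grid: int = 201,
    half_width: float = 1.5,
) -> GridPosterior:
    """Exact posterior over (b0, b1) for a misclassified 2x2 table.

    Parameters
    ----------
    s_exposed, m_exposed, s_unexposed, m_unexposed
        Observed positive counts and totals in the two exposure groups.
    se, sp
        Fixed rater sensitivity/specificity (1, 1 for a perfect rater).
    coef_scale
        SD of the Normal(0, coef_scale) prior on b0 and b1; ``inf`` for a
        flat prior.
    n_grid, half_width
        Grid resolution per axis and half-width (log-odds units) around a
        moment-based center.

    The grid is centred on the Rogan-Gladen-corrected sample log-odds,
    which for identifiable, interior tables is the maximum-likelihood
    point of the mixture model.
    """
    if min(m_exposed, m_unexposed) < 1:
        raise ValueError("both exposure groups need at least one unit")
    if se + sp <= 1:
        raise ValueError("se + sp <= 1 is not identifiable")

    def center(s, m):
        p_obs = np.clip(s / m, 0.02, 0.98)
        p_true = np.clip(rogan_gladen_correct(p_obs, se, sp).estimate, 0.02, 0.98)
        return float(logit(p_true))

    c0 = center(s_unexposed, m_unexposed)
    c1 = center(s_exposed, m_exposed) - c0
    b0 = np.linspace(c0 - half_width, c0 + half_width, n_grid)
    b1 = np.linspace(c1 - half_width, c1 + half_width, n_grid)
    B0 = b0[:, None]
    B1 = b1[None, :]

    def loglik(eta, s, m):
        p = expit(eta)
        q = np.clip(se * p + (1 - sp) * (1 - p), 1e-300, 1 - 1e-16)
        return s * np.log(q) + (m - s) * np.log1p(-q)

    logpost = loglik(B0 + B1, s_exposed, m_exposed) + loglik(
        B0 + np.zeros_like(B1), s_unexposed, m_unexposed
    )
    if np.isfinite(coef_scale):
        logpost = logpost - 0.5 * (B0**2 + B1**2) / coef_scale**2

    stats = {}
    for name, grid, axis in (("b0", b0, 1), ("b1", b1, 0)):
        stats[name] = _marginal_stats(grid, logpost, axis)
    i, j = np.unravel_index(np.argmax(logpost), logpost.shape)
    return GridPosterior(
        mean={k: v[0] for k, v in stats.items()},
        sd={k: v[1] for k, v in stats.items()},
        median={k: v[2] for k, v in stats.items()},
        q2_5={k: v[3] for k, v in stats.items()},
        q97_5={k: v[4] for k, v in stats.items()},
        mode={"b0": float(b0[i]), "b1": float(b1[j])},
        n_grid=n_grid,
    )


def rogan_gladen_or(
    s_exposed: int,
    m_exposed: int,
    s_unexposed: int,
    m_unexposed: int,
    se: float,
    sp: float,
) -> float:
    """Closed-form misclassification-corrected odds ratio of a 2x2 table.

    Applies the Rogan-Gladen inversion to each group's observed
    proportion and forms the odds ratio of the corrected proportions —
    the maximum-likelihood corrected OR when both corrections are
    interior.
    """
    p1 = rogan_gladen_correct(s_exposed / m_exposed, se, sp)
    p0 = rogan_gladen_correct(s_unexposed / m_unexposed, se, sp)
    if p1.clipped or p0.clipped:
        raise ValueError("corrected proportion clipped; OR undefined in closed form")
    if not 0 < p0.estimate < 1 or not 0 < p1.estimate < 1:
        raise ValueError("degenerate corrected proportion")
    odds1 = p1.estimate / (1 - p1.estimate)
    odds0 = p0.estimate / (1 - p0.estimate)
    return odds1 / odds0
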