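"""Forward simulation of a clustered periodontal survey with rater error.

The generator is the forward model of the analysis: subject-level
covariates, a subject random intercept u_j ~ Normal(0, sigma_u^2) on the
log-odds scale, a latent true sextant status
y* ~ Bernoulli(p), p = logit^-1(b0 + x'beta + u_j), and an observed status
drawn through the examining rater's sensitivity/specificity:
P(y = 1) = Se*p + (1 - Sp)*(1 - p).

Default study conditions emulate a nationwide periodontal survey in which
twelve trained dentists, two per each of six regions, examined roughly 4.5
scorable sextants per subject, with rater accuracy heterogeneous enough
that positive likelihood ratios span roughly 1.1-7.7, alongside a small
paired validation substudy against a single gold-standard periodontist.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .scoring import SURVEY_COLUMNS

__all__ = [
    "SimConfig",
    "SyntheticSurvey",
    "simulate_survey",
    "simulate_validation",
    "DEFAULT_RATER_ACCURACY",
    "DEFAULT_MARGINALS",
]

#: (sensitivity, specificity) per rater; raters 2r and 2r+1 belong to
#: region r.  Chosen so LR+ = se/(1-sp) spans ~1.1 to ~7.7 across raters,
#: the heterogeneity reported for trained raters in community surveys.
DEFAULT_RATER_ACCURACY: Tuple[Tuple[float, float], ...] = (
    (0.50, 0.55),
    (0.55, 0.58),
    (0.60, 0.62),
    (0.62, 0.65),
    (0.68, 0.70),
    (0.70, 0.75),
    (0.73, 0.82),
    (0.74, 0.80),
    (0.78, 0.85),
    (0.80, 0.86),
    (0.85, 0.89),
    (0.84, 0.88),
)

#: subject-level exposure prevalences (binary covariates; dm_status is the
#: three-level factor normal / pre-DM / DM)
DEFAULT_MARGINALS: Mapping[str, float] = {
    "gender": 0.42,  # male
    "education": 0.40,  # <= 9 years of schooling
    "bmi": 0.35,  # BMI >= 25 kg/m^2
    "pre_dm": 0.16,
    "dm": 0.06,
    "smoking": 0.22,
    "alcohol": 0.32,
}


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth configuration of a synthetic survey.

    Parameters
    ----------
    n_subjects
        Number of survey participants.
    sextants_per_subject
        Fixed count of scorable sextants per subject (1-6), or ``None`` to
        draw 1 + Binomial(5, 0.7) per subject (mean 4.5, emulating missing
        and edentulous sextants).
    beta
        Log odds ratios per covariate name; covariates absent from the
        mapping are still generated but carry effect 0.
    intercept
        Baseline log-odds of true sextant-level disease.
    sigma_u
        SD of the subject random intercept (log-odds units).
    se_by_rater, sp_by_rater
        Per-rater sensitivity/specificity; scalars broadcast to all raters.
    covariate_marginals
        Subject-level exposure prevalences; ``pre_dm`` and ``dm`` together
        define the three-level diabetes factor.
    age_mean, age_sd, age_min
        Age drawn Normal(age_mean, age_sd) truncated below at age_min.
    gold_prevalence
        True disease prevalence among validation units.
    seed
        Single RNG seed; identical configs produce byte-identical output.
    """

    n_subjects: int = 500
    sextants_per_subject: Optional[int] = None
    n_raters: int = 12
    n_regions: int = 6
    beta: Mapping[str, float] = field(default_factory=dict)
    intercept: float = float(logit(0.30))
    sigma_u: float = 0.8
    se_by_rater: object = None  # None -> DEFAULT_RATER_ACCURACY senses
    sp_by_rater: object = None
    covariate_marginals: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MARGINALS)
    )
    age_mean: float = 46.0
    age_sd: float = 16.0
    age_min: float = 18.0
    gold_prevalence: float = 0.4
    seed: int = 0

    def rater_accuracy(self) -> np.ndarray:
        """(n_raters, 2) array of (se, sp), validated for identifiability."""
        if self.se_by_rater is None and self.sp_by_rater is None:
            acc = np.array(DEFAULT_RATER_ACCURACY[: self.n_raters], dtype=float)
            if len(acc) < self.n_raters:
                raise ValueError(
                    "no default accuracy for more than "
                    f"{len(DEFAULT_RATER_ACCURACY)} raters; pass se/sp_by_rater"
                )
        else:
            se = np.broadcast_to(
                np.asarray(self.se_by_rater, dtype=float), (self.n_raters,)
            )
            sp = np.broadcast_to(
                np.asarray(self.sp_by_rater, dtype=float), (self.n_raters,)
            )
            acc = np.column_stack([se, sp])
        if np.any(acc <= 0) or np.any(acc > 1):
            raise ValueError("sensitivities/specificities must lie in (0, 1]")
        bad = np.where(acc.sum(axis=1) <= 1)[0]
        if bad.size:
            raise ValueError(
                f"rater(s) {bad.tolist()} have se + sp <= 1: the observed "
                "outcome carries no information about the true status and "
                "the calibrated model is not identifiable"
            )
        return acc

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.sextants_per_subject is not None and not (
            1 <= self.sextants_per_subject <= 6
        ):
            raise ValueError("sextants_per_subject must be in 1..6")
        if self.sigma_u < 0:
            raise ValueError("sigma_u must be >= 0")
        if self.n_raters % self.n_regions:
            raise ValueError("n_raters must be a multiple of n_regions")
        for name, p in self.covariate_marginals.items():
            if not 0 <= p <= 1:
                raise ValueError(f"marginal prevalence of {name} outside [0,1]")
        if not 0 < self.gold_prevalence < 1:
            raise ValueError("gold_prevalence must be in (0,1)")
        self.rater_accuracy()


@dataclass
class SyntheticSurvey:
    """Simulated survey records plus the ground truth that produced them."""

    records: pd.DataFrame  # SURVEY_COLUMNS schema
    truth: pd.DataFrame  # per-record y_true, u_j, p_true
    config: SimConfig

    def write(self, survey_path, truth_path=None) -> None:
        self.records[SURVEY_COLUMNS].to_csv(survey_path, index=False)
        if truth_path is not None:
            self.truth.to_csv(truth_path, index=False)


def _draw_subjects(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_subjects
    m = cfg.covariate_marginals
    # three-level diabetes factor drawn once, then encoded as two contrasts
    p_pre = m.get("pre_dm", 0.0)
    p_dm = m.get("dm", 0.0)
    dm_status = rng.choice(3, size=n, p=[1 - p_pre - p_dm, p_pre, p_dm])
    age = cfg.age_mean + cfg.age_sd * rng.standard_normal(n)
    age = np.clip(age, cfg.age_min, None)
    subjects = pd.DataFrame(
        {
            "subject_id": np.arange(n),
            "gender": rng.binomial(1, m.get("gender", 0.5), n),
            "age": np.round(age, 1),
            "education": rng.binomial(1, m.get("education", 0.5), n),
            "bmi": rng.binomial(1, m.get("bmi", 0.5), n),
            "pre_dm": (dm_status == 1).astype(int),
            "dm": (dm_status == 2).astype(int),
            "smoking": rng.binomial(1, m.get("smoking", 0.5), n),
            "alcohol": rng.binomial(1, m.get("alcohol", 0.5), n),
        }
    )
    # subjects partitioned across regions; each region's two raters
    # alternate over its subjects (raters nested in regions)
    region = np.arange(n) % cfg.n_regions
    per_region = cfg.n_raters // cfg.n_regions
    slot = (np.arange(n) // cfg.n_regions) % per_region
    subjects["region_id"] = region
    subjects["rater_id"] = region * per_region + slot
    return subjects


def _ordinal_scores_from_outcome(
    y_obs: np.ndarray, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Draw (cpi, la) ordinal scores consistent with the combined outcome.

    Diseased sextants are split between deep-pocket-only, pocket-plus-
    attachment-loss and attachment-loss-only presentations; healthy ones
    get CPI in 0..2 and LA 0.  ``dichotomize(cpi, la, "combined")``
    reproduces ``y_obs`` exactly.
    """
    n = y_obs.size
    cpi = rng.choice([0, 1, 2], size=n, p=[0.2, 0.3, 0.5])
    la = np.zeros(n, dtype=int)
    pos = np.where(y_obs == 1)[0]
    kind = rng.choice(3, size=pos.size, p=[0.45, 0.35, 0.20])
    cpi_pos = rng.choice([3, 4], size=pos.size, p=[0.7, 0.3])
    la_pos = rng.choice([1, 2], size=pos.size, p=[0.75, 0.25])
    cpi[pos] = np.where(kind <= 1, cpi_pos, cpi[pos])
    la[pos] = np.where(kind >= 1, la_pos, 0)
    return cpi, la


def simulate_survey(config: SimConfig) -> SyntheticSurvey:
    """Simulate a sextant-level survey under the hierarchical error model.

    All randomness flows from a single generator keyed by ``config.seed``,
    consumed in a fixed order (subjects, sextant counts, random
    intercepts, true statuses, observed statuses, ordinal scores), so a
    fixed config is bit-reproducible.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    acc = config.rater_accuracy()

    subjects = _draw_subjects(config, rng)
    n = config.n_subjects
    if config.sextants_per_subject is not None:
        counts = np.full(n, config.sextants_per_subject)
    else:
        counts = 1 + rng.binomial(5, 0.7, size=n)

    u = config.sigma_u * rng.standard_normal(n)
    beta = config.beta
    eta_subj = config.intercept + u
    for name, b in beta.items():
        if name not in subjects.columns:
            raise ValueError(f"beta refers to unknown covariate {name!r}")
        eta_subj = eta_subj + b * subjects[name].to_numpy()

    rec = subjects.loc[subjects.index.repeat(counts)].reset_index(drop=True)
    subj_row = np.repeat(np.arange(n), counts)
    # sextant indices: a random subset of the six WHO sextants per subject
    sextant_index = np.concatenate(
        [np.sort(rng.choice(6, size=c, replace=False)) + 1 for c in counts]
    )
    rec["sextant_index"] = sextant_index

    p_true = expit(eta_subj)[subj_row]
    y_true = rng.binomial(1, p_true)
    se = acc[rec["rater_id"].to_numpy(), 0]
    sp = acc[rec["rater_id"].to_numpy(), 1]
    q = se * y_true + (1 - sp) * (1 - y_true)
    y_obs = rng.binomial(1, q)
    cpi, la = _ordinal_scores_from_outcome(y_obs, rng)

    rec["cpi"] = cpi.astype(float)
    rec["la"] = la.astype(float)
    rec["y_obs"] = y_obs.astype(float)
    records = rec[SURVEY_COLUMNS].copy()

    truth = pd.DataFrame(
        {
            "subject_id": rec["subject_id"],
            "sextant_index": rec["sextant_index"],
            "u": u[subj_row],
            "p_true": p_true,
            "y_true": y_true,
        }
    )
    return SyntheticSurvey(records=records, truth=truth, config=config)


def simulate_validation(
    config: SimConfig, n_units: int, index: str = "combined"
) -> pd.DataFrame:
    """Simulate a paired validation substudy against the gold standard.

    Each unit (a sextant) carries a gold-standard status drawn at
    ``config.gold_prevalence`` and a trained-rater score drawn through that
    rater's Se/Sp; units are spread round-robin over all raters.

    Returns a DataFrame with columns unit_id, rater_id, region_id, gold,
    rated, index.
    """
    config.validate()
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    acc = config.rater_accuracy()
    rater = np.arange(n_units) % config.n_raters
    per_region = config.n_raters // config.n_regions
    region = rater // per_region
    gold = rng.binomial(1, config.gold_prevalence, n_units)
    se, sp = acc[rater, 0], acc[rater, 1]
    q = se * gold + (1 - sp) * (1 - gold)
    rated = rng.binomial(1, q)
    return pd.DataFrame(
        {
            "unit_id": np.arange(n_units),
            "rater_id": rater,
            "region_id": region,
            "gold": gold,
            "rated": rated,
            "index": index,
        }
    )


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Convenience: the same study conditions under a different seed."""
    return replace(config, seed=seed)
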