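"""Bayesian hierarchical logistic regression with outcome misclassification.

The model for sextant i of subject j examined by rater r is

    y*_ij ~ Bernoulli(p_ij),   logit(p_ij) = b0 + x_ij' beta + u_j,
    u_j   ~ Normal(0, sigma_u^2),
    y_ij  ~ Bernoulli(q_ij),   q_ij = Se_r * p_ij + (1 - Sp_r) * (1 - p_ij),

where y* is the latent true disease status and y the status recorded by an
imperfect rater with sensitivity Se_r and specificity Sp_r.  Setting
Se = Sp = 1 recovers the ordinary (uncalibrated) random-intercept
logistic model; with Se/Sp taken from a validation substudy the fit yields
*calibrated* odds ratios.  Non-differential misclassification (Se/Sp not
depending on exposure) attenuates odds ratios toward 1, so calibrated ORs
are generally farther from the null than uncalibrated ones.

The latent statuses never appear as sampled variables: the mixture q
marginalizes them analytically.  The subject random intercepts are
integrated out of the likelihood by Gauss-Hermite quadrature, leaving a
low-dimensional smooth posterior over (b0, beta, log sigma_u, ...) which
is sampled with the emcee affine-invariant ensemble sampler; walkers are
treated as chains for split-R-hat and effective-sample-size diagnostics.

Sensitivity/specificity can be fixed at validation point estimates
(default) or given independent Beta posteriors built from the validation
counts, propagating the validation uncertainty into the odds ratios.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Optional, Sequence, Tuple, Union

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit
from scipy.stats import beta as beta_dist
from scipy.stats import halfnorm, norm

logger = logging.getLogger(__name__)

_EPS = 1e-12


class ConvergenceError(RuntimeError):
    """Raised when a fit cannot produce a usable posterior."""


def mixture_prob(p, se, sp):
    """Observed-positive probability q = Se*p + (1-Sp)*(1-p).

    The canonical non-differential misclassification mixture: a truly
    diseased unit is called positive with probability Se, a truly healthy
    one with probability 1-Sp.
    """
    return se * np.asarray(p) + (1.0 - sp) * (1.0 - np.asarray(p))


class RoganGladenResult(NamedTuple):
    estimate: float
    clipped: bool


def rogan_gladen_correct(p_obs: float, se: float, sp: float) -> RoganGladenResult:
    """Invert the misclassification mixture for a single proportion.

    Returns (p_obs + sp - 1) / (se + sp - 1), clipped into [0, 1] with
    ``clipped=True`` when the raw inversion falls outside the unit
    interval (possible in small samples).  Requires se + sp > 1.
    """
    if se + sp <= 1:
        raise ValueError(
            f"se + sp = {se + sp:.3f} <= 1: the rater is uninformative and "
            "the true prevalence is not identifiable"
        )
    raw = (p_obs + sp - 1.0) / (se + sp - 1.0)
    clipped = not 0.0 <= raw <= 1.0
    return RoganGladenResult(float(np.clip(raw, 0.0, 1.0)), clipped)


# ---------------------------------------------------------------------------
# specification containers


@dataclass(frozen=True)
class Misclassification:
    """How the model treats rater error.

    mode "none"  -> Se = Sp = 1 (uncalibrated fit);
    mode "fixed" -> Se/Sp fixed at given values, globally or per rater;
    mode "beta"  -> Se/Sp sampled with Beta(tp+1, fn+1) / Beta(tn+1, fp+1)
                    priors built from validation counts (truncated to the
                    identifiable region se + sp > 1).
    """

    mode: str = "none"
    se: Union[None, float, Mapping[int, float]] = None
    sp: Union[None, float, Mapping[int, float]] = None
    counts: Optional[Tuple[int, int, int, int]] = None  # tp, fn, fp, tn

    @classmethod
    def none(cls) -> "Misclassification":
        return cls(mode="none")

    @classmethod
    def fixed(cls, se, sp) -> "Misclassification":
        return cls(mode="fixed", se=se, sp=sp)

    @classmethod
    def fixed_by_rater(
        cls, accuracy: Mapping[int, Tuple[float, float]]
    ) -> "Misclassification":
        se = {r: a[0] for r, a in accuracy.items()}
        sp = {r: a[1] for r, a in accuracy.items()}
        return cls(mode="fixed", se=se, sp=sp)

    @classmethod
    def beta_prior(cls, tp: int, fn: int, fp: int, tn: int) -> "Misclassification":
        return cls(mode="beta", counts=(tp, fn, fp, tn))

    def validate(self) -> None:
        if self.mode not in ("none", "fixed", "beta"):
            raise ValueError(f"unknown misclassification mode {self.mode!r}")
        if self.mode == "fixed":
            if isinstance(self.se, Mapping) != isinstance(self.sp, Mapping):
                raise ValueError("se and sp must both be scalar or both mappings")
            if isinstance(self.se, Mapping):
                pairs = [(self.se[r], self.sp[r]) for r in self.se]
            else:
                pairs = [(float(self.se), float(self.sp))]
            for se, sp in pairs:
                if not (0 < se <= 1 and 0 < sp <= 1):
                    raise ValueError("se and sp must lie in (0, 1]")
                if se + sp <= 1:
                    raise ValueError(
                        f"se + sp = {se + sp:.3f} <= 1 is not identifiable: "
                        "an uninformative rater admits no calibration"
                    )
        if self.mode == "beta":
            if self.counts is None or len(self.counts) != 4:
                raise ValueError("beta mode needs counts (tp, fn, fp, tn)")
            if any(c < 0 for c in self.counts):
                raise ValueError("validation counts must be non-negative")


@dataclass(frozen=True)
class Priors:
    """Weakly informative default priors on the log-odds scale.

    Coefficients (and the intercept) get Normal(0, coef_scale) with
    coef_scale = 10 by default — diffuse on the OR scale without the
    improper tails of a flat prior; ``coef_scale = inf`` gives a flat
    prior (used by the maximum-likelihood / grid-oracle checks).  The
    random-intercept SD gets Half-Normal(sigma_scale), default 2.
    """

    coef_scale: float = 10.0
    sigma_scale: float = 2.0


@dataclass(frozen=True)
class MCMCSettings:
    """Ensemble-sampler settings; walkers double as diagnostic chains."""

    n_walkers: int = 32
    n_steps: int = 1000  # kept draws per walker
    n_burn: int = 500
    seed: int = 0
    n_quad: int = 21  # Gauss-Hermite nodes for the random intercept
    dic_thin: int = 4  # thinning of kept draws for the DIC deviance mean
    rhat_max: float = 1.1
    ess_min: float = 400.0

    def validate(self) -> None:
        if self.n_walkers < 4:
            raise ValueError("need >= 4 walkers for split-chain diagnostics")
        if self.n_steps < 1 or self.n_burn < 0:
            raise ValueError("n_steps must be >= 1 and n_burn >= 0")
        if self.n_quad < 3:
            raise ValueError("n_quad must be >= 3")


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: covariates, cluster structure, misclassification mode.

    ``random_intercept`` keeps the mandatory subject-level intercept; it
    exists as a switch only so that closed-form and grid oracles can be
    checked on independent-data fits.  ``extra_level`` adds a second
    random intercept shared by all subjects of a rater or region.
    """

    covariates: Tuple[str, ...]
    misclassification: Misclassification = field(
        default_factory=Misclassification.none
    )
    random_intercept: bool = True
    extra_level: Optional[str] = None  # None, "rater" or "region"
    priors: Priors = field(default_factory=Priors)
    center_age: bool = True

    def validate(self) -> None:
        self.misclassification.validate()
        if self.extra_level not in (None, "rater", "region"):
            raise ValueError("extra_level must be None, 'rater' or 'region'")
        if len(set(self.covariates)) != len(self.covariates):
            raise ValueError("duplicate covariate in ModelSpec")


# ---------------------------------------------------------------------------
# likelihood construction


class CalibrationModel:
    """Compiled marginal log-posterior for one ModelSpec on one dataset.

    Records are collapsed to (subject, rater, covariate-pattern) groups
    carrying a positive count s and a size m, which makes every
    log-likelihood evaluation O(#groups x #quadrature nodes) rather than
    O(#sextants); with subject-level covariates #groups equals #subjects.
    """

    def __init__(self, spec: ModelSpec, data: pd.DataFrame, outcome_col: str = "y"):
        spec.validate()
        if len(data) == 0:
            raise ValueError("no records to fit")
        cols = ["subject_id", "rater_id", "region_id", *spec.covariates]
        missing = [c for c in cols + [outcome_col] if c not in data.columns]
        if missing:
            raise ValueError(f"data lacks columns {missing}")
        work = data[cols + [outcome_col]].rename(columns={outcome_col: "_y"})
        n0 = len(work)
        work = work.dropna()
        if len(work) < n0:
            logger.info(
                "dropped %d/%d records with missing outcome or covariates",
                n0 - len(work),
                n0,
            )
        if len(work) == 0:
            raise ValueError("all records dropped (missing outcome/covariates)")
        yv = work["_y"].to_numpy(dtype=float)
        if not np.isin(yv, (0.0, 1.0)).all():
            raise ValueError("outcome column must be binary 0/1")

        g = (
            work.groupby(cols, sort=True)["_y"]
            .agg(s="sum", m="size")
            .reset_index()
            .sort_values("subject_id", kind="stable")
            .reset_index(drop=True)
        )
        self.spec = spec
        self.n_records = len(work)
        self.s = g["s"].to_numpy(dtype=float)
        self.m = g["m"].to_numpy(dtype=float)
        X = g[list(spec.covariates)].to_numpy(dtype=float)
        self.age_center = 0.0
        if spec.center_age and "age" in spec.covariates:
            j = spec.covariates.index("age")
            self.age_center = float(np.average(X[:, j], weights=self.m))
            X[:, j] -= self.age_center
        self.X = X

        subj_codes, _ = pd.factorize(g["subject_id"], sort=False)
        self.n_subjects = int(subj_codes.max()) + 1
        # groups are sorted by subject: reduceat segment starts
        self.subj_starts = np.flatnonzero(np.r_[1, np.diff(subj_codes)])
        self._subj_codes = subj_codes

        if spec.extra_level is not None:
            lvl = g[f"{spec.extra_level}_id"].to_numpy()
            subj_lvl = np.empty(self.n_subjects, dtype=int)
            subj_lvl[subj_codes] = lvl
            self.cluster_codes, _ = pd.factorize(subj_lvl, sort=True)
            self.n_clusters = int(self.cluster_codes.max()) + 1
        else:
            self.cluster_codes = None
            self.n_clusters = 0

        self._setup_misclassification(g)
        self._setup_parameters()

    # -- misclassification plumbing

    def _setup_misclassification(self, g: pd.DataFrame) -> None:
        mis = self.spec.misclassification
        G = len(g)
        self.sample_sesp = mis.mode == "beta"
        if mis.mode == "none":
            self.se_g = np.ones(G)
            self.sp_g = np.ones(G)
        elif mis.mode == "fixed":
            if isinstance(mis.se, Mapping):
                raters = g["rater_id"].to_numpy()
                missing = sorted(set(raters) - set(mis.se))
                if missing:
                    raise ValueError(f"no fixed (se, sp) for rater(s) {missing}")
                self.se_g = np.array([mis.se[r] for r in raters], dtype=float)
                self.sp_g = np.array([mis.sp[r] for r in raters], dtype=float)
            else:
                self.se_g = np.full(G, float(mis.se))
                self.sp_g = np.full(G, float(mis.sp))
        else:  # beta: a single (se, sp) pair sampled with validation priors
            tp, fn, fp, tn = mis.counts
            self.se_prior = (tp + 1.0, fn + 1.0)
            self.sp_prior = (tn + 1.0, fp + 1.0)
            self.se_g = self.sp_g = None

    # -- parameter bookkeeping

    def _setup_parameters(self) -> None:
        spec = self.spec
        names = ["intercept", *spec.covariates]
        self.n_coef = len(names)
        self.idx_sigma_u = None
        self.idx_sigma_v = None
        self.idx_se = None
        self.idx_sp = None
        if spec.random_intercept:
            self.idx_sigma_u = len(names)
            names.append("log_sigma_u")
        if spec.extra_level is not None:
            self.idx_sigma_v = len(names)
            names.append(f"log_sigma_{spec.extra_level}")
        if self.sample_sesp:
            self.idx_se = len(names)
            names.append("logit_se")
            self.idx_sp = len(names)
            names.append("logit_sp")
        self.param_names = names
        self.n_params = len(names)

    # -- quadrature

    def set_quadrature(self, n_quad: int) -> None:
        z, w = np.polynomial.hermite_e.hermegauss(n_quad)
        self.quad_z = z
        self.quad_logw = np.log(w / np.sqrt(2.0 * np.pi))

    # -- likelihood and prior

    def _group_loglik(self, q: np.ndarray) -> np.ndarray:
        q = np.clip(q, _EPS, 1.0 - _EPS)
        if q.ndim == 1:
            return self.s * np.log(q) + (self.m - self.s) * np.log1p(-q)
        return self.s[:, None] * np.log(q) + (self.m - self.s)[:, None] * np.log1p(-q)

    def _subject_marginal(self, eta, sigma_u, se_g, sp_g) -> np.ndarray:
        """Per-subject marginal log-likelihood, intercept integrated out."""
        p = expit(eta[:, None] + sigma_u * self.quad_z[None, :])
        q = se_g[:, None] * p + (1.0 - sp_g[:, None]) * (1.0 - p)
        ll_gk = self._group_loglik(q)
        subj = np.add.reduceat(ll_gk, self.subj_starts, axis=0)
        a = subj + self.quad_logw[None, :]
        amax = a.max(axis=1, keepdims=True)
        return (amax + np.log(np.exp(a - amax).sum(axis=1, keepdims=True)))[:, 0]

    def log_likelihood(self, theta: np.ndarray) -> float:
        theta = np.asarray(theta, dtype=float)
        eta = theta[0] + self.X @ theta[1 : self.n_coef]
        if self.sample_sesp:
            se = expit(theta[self.idx_se])
            sp = expit(theta[self.idx_sp])
            if se + sp <= 1.0:
                return -np.inf
            se_g = np.full(len(self.s), se)
            sp_g = np.full(len(self.s), sp)
        else:
            se_g, sp_g = self.se_g, self.sp_g

        if not self.spec.random_intercept and self.spec.extra_level is None:
            q = se_g * expit(eta) + (1.0 - sp_g) * (1.0 - expit(eta))
            return float(self._group_loglik(q).sum())

        sigma_u = np.exp(theta[self.idx_sigma_u]) if self.idx_sigma_u is not None else 0.0

        if self.spec.extra_level is None:
            return float(self._subject_marginal(eta, sigma_u, se_g, sp_g).sum())

        # nested level: outer quadrature over the rater/region intercept
        sigma_v = np.exp(theta[self.idx_sigma_v])
        per_node = np.empty((self.n_clusters, len(self.quad_z)))
        for k, zk in enumerate(self.quad_z):
            subj_ll = self._subject_marginal(eta + sigma_v * zk, sigma_u, se_g, sp_g)
            per_node[:, k] = np.bincount(
                self.cluster_codes, weights=subj_ll, minlength=self.n_clusters
            )
        a = per_node + self.quad_logw[None, :]
        amax = a.max(axis=1)
        return float((amax + np.log(np.exp(a - amax[:, None]).sum(axis=1))).sum())

    def log_prior(self, theta: np.ndarray) -> float:
        pri = self.spec.priors
        lp = 0.0
        if np.isfinite(pri.coef_scale):
            lp += norm.logpdf(theta[: self.n_coef], scale=pri.coef_scale).sum()
        for idx in (self.idx_sigma_u, self.idx_sigma_v):
            if idx is not None:
                sigma = np.exp(theta[idx])
                lp += halfnorm.logpdf(sigma, scale=pri.sigma_scale) + theta[idx]
        if self.sample_sesp:
            se = expit(theta[self.idx_se])
            sp = expit(theta[self.idx_sp])
            if se + sp <= 1.0:
                return -np.inf
            lp += beta_dist.logpdf(se, *self.se_prior) + np.log(se * (1 - se))
            lp += beta_dist.logpdf(sp, *self.sp_prior) + np.log(sp * (1 - sp))
        return float(lp)

    def log_posterior(self, theta: np.ndarray) -> float:
        lp = self.log_prior(theta)
        if not np.isfinite(lp):
            return -np.inf
        ll = self.log_likelihood(theta)
        if np.isnan(ll):
            raise FloatingPointError(
                "log-likelihood is NaN at theta = "
                f"{np.array2string(np.asarray(theta), precision=3)}"
            )
        return lp + ll

    def initial_point(self) -> np.ndarray:
        x0 = np.zeros(self.n_params)
        obs_rate = self.s.sum() / self.m.sum()
        x0[0] = float(logit(np.clip(obs_rate, 0.05, 0.95)))
        if self.idx_sigma_u is not None:
            x0[self.idx_sigma_u] = np.log(0.5)
        if self.idx_sigma_v is not None:
            x0[self.idx_sigma_v] = np.log(0.3)
        if self.sample_sesp:
            a, b = self.se_prior
            x0[self.idx_se] = float(logit(np.clip(a / (a + b), 0.6, 0.95)))
            a, b = self.sp_prior
            x0[self.idx_sp] = float(logit(np.clip(a / (a + b), 0.6, 0.95)))
        return x0


def build_likelihood(
    spec: ModelSpec, data: pd.DataFrame, outcome_col: str = "y", n_quad: int = 21
) -> CalibrationModel:
    """Compile ``spec`` against sextant records into a CalibrationModel."""
    model = CalibrationModel(spec, data, outcome_col=outcome_col)
    model.set_quadrature(n_quad)
    return model


# ---------------------------------------------------------------------------
# fitting


@dataclass
class CalibratedFit:
    """Posterior summaries of one fit (calibrated or uncalibrated)."""

    summary: pd.DataFrame  # parameter, mean, median, sd, q2.5, q97.5, rhat, ess
    or_summary: pd.DataFrame  # covariate, or_median, or_q2.5, or_q97.5
    dic: float
    p_d: float
    mean_deviance: float
    calibrated: bool
    diagnostics: dict
    warnings: list
    draws: dict  # reported-scale flat draws per parameter
    map_estimate: dict
    settings: MCMCSettings

    @property
    def ok(self) -> bool:
        return not self.warnings

    def odds_ratio(self, covariate: str) -> Tuple[float, float, float]:
        row = self.or_summary.set_index("covariate").loc[covariate]
        return float(row["or_median"]), float(row["or_q2.5"]), float(row["or_q97.5"])


def _map_estimate(model: CalibrationModel) -> Tuple[np.ndarray, np.ndarray]:
    nlp = lambda t: -model.log_posterior(t)
    res = optimize.minimize(nlp, model.initial_point(), method="BFGS")
    if not np.isfinite(res.fun):
        raise ConvergenceError("posterior mode search failed (non-finite value)")
    scale = np.sqrt(np.clip(np.diag(res.hess_inv), 1e-6, 4.0))
    return res.x, scale


def fit(model: CalibrationModel, mcmc: MCMCSettings = MCMCSettings()) -> CalibratedFit:
    """Sample the posterior and summarize it.

    The sampler starts from a small ball around the posterior mode
    (found with BFGS) and runs ``n_burn + n_steps`` ensemble moves.
    Diagnostic failures (max split-R-hat > rhat_max, min bulk ESS <
    ess_min) are recorded in ``fit.warnings`` and emitted as Python
    warnings — loudly, but without discarding the fit.
    """
    mcmc.validate()
    model.set_quadrature(mcmc.n_quad)
    x_map, scale = _map_estimate(model)

    rng = np.random.default_rng(np.random.SeedSequence([mcmc.seed, 17]))
    nw, nd = mcmc.n_walkers, model.n_params
    p0 = x_map[None, :] + 0.2 * scale[None, :] * rng.standard_normal((nw, nd))

    # differential-evolution moves mix far better than the default stretch
    # move on the correlated (intercept, beta, log sigma) posterior
    sampler = emcee.EnsembleSampler(
        nw,
        nd,
        model.log_posterior,
        moves=[(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)],
    )
    sampler.random_state = np.random.RandomState(mcmc.seed % (2**31)).get_state()
    sampler.run_mcmc(p0, mcmc.n_burn + mcmc.n_steps, progress=False)
    chain = sampler.get_chain(discard=mcmc.n_burn)  # (steps, walkers, dim)
    if not np.isfinite(chain).all():
        raise ConvergenceError("non-finite parameter draws")

    # walkers -> arviz chains
    posterior = {
        name: np.swapaxes(chain[:, :, i], 0, 1)
        for i, name in enumerate(model.param_names)
    }
    ds = az.convert_to_dataset(posterior)
    rhat = az.rhat(ds)
    ess = az.ess(ds)

    flat = chain.reshape(-1, nd)
    msgs: list = []
    rows = []
    or_rows = []
    draws = {}
    qs = (2.5, 50.0, 97.5)
    for i, name in enumerate(model.param_names):
        x = flat[:, i]
        report = name
        if name.startswith("log_sigma"):
            report = name[len("log_") :]
            x = np.exp(x)
        elif name.startswith("logit_"):
            report = name[len("logit_") :]
            x = expit(x)
        lo, med, hi = np.percentile(x, qs)
        rows.append(
            {
                "parameter": report,
                "mean": float(np.mean(x)),
                "median": float(med),
                "sd": float(np.std(x, ddof=1)),
                "q2.5": float(lo),
                "q97.5": float(hi),
                "rhat": float(rhat[name]),
                "ess": float(ess[name]),
            }
        )
        draws[report] = x
        if name in model.spec.covariates:
            # OR summaries are exp of the log-OR quantiles (monotone map)
            or_rows.append(
                {
                    "covariate": name,
                    "or_median": float(np.exp(med)),
                    "or_q2.5": float(np.exp(lo)),
                    "or_q97.5": float(np.exp(hi)),
                }
            )
        if float(rhat[name]) > mcmc.rhat_max:
            msgs.append(f"R-hat {float(rhat[name]):.3f} > {mcmc.rhat_max} for {report}")
        if float(ess[name]) < mcmc.ess_min:
            msgs.append(f"ESS {float(ess[name]):.0f} < {mcmc.ess_min:.0f} for {report}")

    # DIC from the marginal deviance
    dev_draws = np.array(
        [-2.0 * model.log_likelihood(t) for t in flat[:: mcmc.dic_thin]]
    )
    mean_dev = float(dev_draws.mean())
    dev_at_mean = -2.0 * model.log_likelihood(flat.mean(axis=0))
    p_d = mean_dev - dev_at_mean
    dic_value = mean_dev + p_d

    for msg in msgs:
        warnings.warn(f"calibration fit did not converge cleanly: {msg}")

    return CalibratedFit(
        summary=pd.DataFrame(rows),
        or_summary=pd.DataFrame(
            or_rows, columns=["covariate", "or_median", "or_q2.5", "or_q97.5"]
        ),
        dic=float(dic_value),
        p_d=float(p_d),
        mean_deviance=mean_dev,
        calibrated=model.spec.misclassification.mode != "none",
        diagnostics={
            "max_rhat": float(max(float(rhat[n]) for n in model.param_names)),
            "min_ess": float(min(float(ess[n]) for n in model.param_names)),
            "acceptance_fraction": float(np.mean(sampler.acceptance_fraction)),
        },
        warnings=msgs,
        draws=draws,
        map_estimate=dict(zip(model.param_names, x_map)),
        settings=mcmc,
    )


def dic(fit_result: CalibratedFit) -> float:
    """Deviance information criterion of a fit: DIC = Dbar + pD."""
    return fit_result.dic
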