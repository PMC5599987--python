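import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from conftest import make_2x2_records
from periocal.model import (
    MCMCSettings,
    Misclassification,
    ModelSpec,
    Priors,
    build_likelihood,
    fit,
    mixture_prob,
    rogan_gladen_correct,
)
from periocal.scoring import apply_outcome
from periocal.simulate import SimConfig, simulate_survey

FAST = MCMCSettings(n_walkers=16, n_steps=400, n_burn=250, seed=3)


class TestMixture:
    def test_identity_at_perfect_accuracy(self):
        p = np.linspace(0, 1, 11)
        assert np.allclose(mixture_prob(p, 1.0, 1.0), p)

    def test_boundaries(self):
        assert mixture_prob(0.0, 0.73, 0.82) == pytest.approx(0.18)
        assert mixture_prob(1.0, 0.73, 0.82) == pytest.approx(0.73)

    def test_worked_value(self):
        assert mixture_prob(0.3, 0.73, 0.82) == pytest.approx(0.345)


class TestRoganGladen:
    def test_inverts_mixture(self):
        res = rogan_gladen_correct(0.345, 0.73, 0.82)
        assert res.estimate == pytest.approx(0.30)
        assert not res.clipped

    def test_identity_and_boundary(self):
        assert rogan_gladen_correct(0.4, 1.0, 1.0).estimate == pytest.approx(0.4)
        assert rogan_gladen_correct(0.18, 0.73, 0.82).estimate == pytest.approx(0.0)

    def test_clipping_flagged(self):
        res = rogan_gladen_correct(0.05, 0.73, 0.82)
        assert res.estimate == 0.0 and res.clipped

    def test_uninformative_rater_rejected(self):
        with pytest.raises(ValueError):
            rogan_gladen_correct(0.4, 0.5, 0.5)


class TestBuildLikelihood:
    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            build_likelihood(ModelSpec(("x",)), pd.DataFrame(columns=["y"]))

    def test_nonidentifiable_fixed_mode_rejected(self):
        with pytest.raises(ValueError, match="identifia"):
            Misclassification.fixed(0.4, 0.5).validate()

    def test_missing_covariate_rejected(self, small_survey):
        _, _, records = small_survey
        with pytest.raises(ValueError):
            build_likelihood(ModelSpec(("chewing",)), records)

    def test_missing_rows_dropped(self, small_survey):
        _, _, records = small_survey
        records = records.copy()
        records.loc[records.index[:10], "y"] = np.nan
        model = build_likelihood(ModelSpec(("smoking",)), records)
        assert model.n_records == len(records) - 10

    def test_groups_collapse_to_subjects(self, small_survey):
        _, _, records = small_survey
        model = build_likelihood(ModelSpec(("smoking",)), records)
        assert len(model.s) == records["subject_id"].nunique()


class TestFit:
    def test_identity_reduction_is_exact(self, small_survey):
        """Perfect-rater calibration and no calibration are the same model;
        with the same seed the posterior summaries coincide exactly."""
        _, _, records = small_survey
        f_unc = fit(build_likelihood(ModelSpec(("smoking",)), records), FAST)
        f_cal = fit(
            build_likelihood(
                ModelSpec(("smoking",), Misclassification.fixed(1.0, 1.0)), records
            ),
            FAST,
        )
        pd.testing.assert_frame_equal(f_unc.summary, f_cal.summary)
        assert f_unc.dic == pytest.approx(f_cal.dic)
        assert not f_unc.calibrated and f_cal.calibrated

    def test_parameter_recovery_no_clustering(self):
        """True OR 2 with perfect raters: the 95% interval covers the truth
        and the median lies inside the fit's own interval."""
        # replicated sextants identify sigma_u (with a single observation
        # per subject the intercept SD and the coefficients are confounded)
        cfg = SimConfig(
            n_subjects=1000,
            sextants_per_subject=5,
            beta={"smoking": float(np.log(2))},
            intercept=float(logit(0.3)),
            sigma_u=0.0,
            se_by_rater=1.0,
            sp_by_rater=1.0,
            seed=23,
        )
        records = apply_outcome(simulate_survey(cfg).records, "combined")
        f = fit(build_likelihood(ModelSpec(("smoking",)), records), FAST)
        med, lo, hi = f.odds_ratio("smoking")
        assert lo < med < hi
        assert lo < 2.0 < hi

    def test_or_interval_is_exp_of_beta_interval(self, small_survey):
        _, _, records = small_survey
        f = fit(build_likelihood(ModelSpec(("smoking",)), records), FAST)
        beta_row = f.summary.set_index("parameter").loc["smoking"]
        med, lo, hi = f.odds_ratio("smoking")
        assert med == pytest.approx(np.exp(beta_row["median"]), rel=1e-12)
        assert lo == pytest.approx(np.exp(beta_row["q2.5"]), rel=1e-12)
        assert hi == pytest.approx(np.exp(beta_row["q97.5"]), rel=1e-12)

    def test_deterministic_given_seed(self):
        records = make_2x2_records(120, 400, 80, 400)
        spec = ModelSpec(("x",), random_intercept=False)
        f1 = fit(build_likelihood(spec, records), FAST)
        f2 = fit(build_likelihood(spec, records), FAST)
        pd.testing.assert_frame_equal(f1.summary, f2.summary)
        assert f1.dic == f2.dic

    def test_beta_prior_mode_widens_or_interval(self):
        """Propagating validation uncertainty cannot sharpen the OR."""
        records = make_2x2_records(545, 1000, 400, 1000)
        slow = MCMCSettings(n_walkers=16, n_steps=800, n_burn=400, seed=6)
        fixed = fit(
            build_likelihood(
                ModelSpec(
                    ("x",), Misclassification.fixed(0.73, 0.82), random_intercept=False
                ),
                records,
            ),
            slow,
        )
        # counts whose point estimates are ~0.73/0.82
        beta = fit(
            build_likelihood(
                ModelSpec(
                    ("x",),
                    Misclassification.beta_prior(73, 27, 18, 82),
                    random_intercept=False,
                ),
                records,
            ),
            slow,
        )
        w_fixed = np.log(fixed.odds_ratio("x")[2]) - np.log(fixed.odds_ratio("x")[1])
        w_beta = np.log(beta.odds_ratio("x")[2]) - np.log(beta.odds_ratio("x")[1])
        assert w_beta > w_fixed
        assert {"se", "sp"} <= set(beta.summary["parameter"])

    def test_nested_second_level_runs(self, small_survey):
        _, _, records = small_survey
        spec = ModelSpec(("smoking",), extra_level="region")
        f = fit(
            build_likelihood(spec, records),
            MCMCSettings(n_walkers=16, n_steps=150, n_burn=100, seed=5, n_quad=9),
        )
        assert "sigma_region" in set(f.summary["parameter"])


class TestDIC:
    def test_saturated_intercept_model(self):
        """Intercept-only fit: D(theta_bar) ~ -2 * max Bernoulli loglik and
        pD ~ 1 effective parameter."""
        records = make_2x2_records(30, 100, 30, 100)[["subject_id", "rater_id", "region_id", "y"]]
        records["one"] = 0  # no covariates: intercept only via empty tuple
        spec = ModelSpec((), random_intercept=False, priors=Priors(coef_scale=np.inf))
        f = fit(build_likelihood(spec, records), FAST)
        p_hat = 60 / 200
        best = -2 * 200 * (
            p_hat * np.log(p_hat) + (1 - p_hat) * np.log(1 - p_hat)
        )
        assert f.mean_deviance - f.p_d == pytest.approx(best, abs=0.2)
        assert 0.4 < f.p_d < 2.0
        assert f.dic == pytest.approx(best + 2 * f.p_d, abs=0.3)

    def test_noise_covariate_changes_dic_little(self):
        rng = np.random.default_rng(8)
        records = make_2x2_records(300, 1000, 300, 1000)
        records["noise"] = rng.binomial(1, 0.5, len(records))
        base = fit(
            build_likelihood(ModelSpec(("x",), random_intercept=False), records), FAST
        )
        noisy = fit(
            build_likelihood(
                ModelSpec(("x", "noise"), random_intercept=False), records
            ),
            FAST,
        )
        assert abs(noisy.dic - base.dic) < 10
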