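import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import binom

from periocal.simulate import SimConfig, simulate_validation
from periocal.validation import (
    accuracy_table,
    binomial_ci,
    estimate_accuracy,
    lr_plus,
    rater_accuracy_map,
)


def pairs_from_counts(tp, fn, fp, tn, rater=0, region=0):
    gold = [1] * (tp + fn) + [0] * (fp + tn)
    rated = [1] * tp + [0] * fn + [1] * fp + [0] * tn
    return pd.DataFrame(
        {
            "unit_id": range(len(gold)),
            "rater_id": rater,
            "region_id": region,
            "gold": gold,
            "rated": rated,
        }
    )


class TestEstimateAccuracy:
    def test_overall_rates_from_counts(self):
        """73/27/18/82 confusion counts give Se 0.73, Sp 0.82, LR+ ~4.06."""
        est = estimate_accuracy(pairs_from_counts(73, 27, 18, 82), "overall")[0]
        assert est.se == pytest.approx(0.73)
        assert est.sp == pytest.approx(0.82)
        assert est.lr_plus == pytest.approx(4.0556, abs=1e-4)
        assert est.se_ci[0] < est.se < est.se_ci[1]
        assert est.sp_ci[0] < est.sp < est.sp_ci[1]

    def test_perfect_rater(self):
        est = estimate_accuracy(pairs_from_counts(10, 0, 0, 10), "overall")[0]
        assert est.se == 1.0 and est.sp == 1.0
        assert est.lr_plus == math.inf

    def test_all_gold_negative_stratum(self):
        est = estimate_accuracy(pairs_from_counts(0, 0, 3, 7), "overall")[0]
        assert est.se is None and est.se_ci is None
        assert est.sp == pytest.approx(0.7)

    def test_stratum_counts_sum_to_pooled(self):
        pairs = pd.concat(
            [
                pairs_from_counts(5, 2, 1, 9, rater=0, region=0),
                pairs_from_counts(7, 1, 3, 6, rater=1, region=1),
            ],
            ignore_index=True,
        )
        ests = estimate_accuracy(pairs, "rater")
        overall = ests[-1]
        for attr in ("tp", "fn", "fp", "tn"):
            assert getattr(overall, attr) == sum(
                getattr(e, attr) for e in ests[:-1]
            )
        assert overall.n == len(pairs)

    def test_nonbinary_scores_rejected(self):
        bad = pairs_from_counts(1, 1, 1, 1)
        bad.loc[0, "rated"] = 2
        with pytest.raises(ValueError):
            estimate_accuracy(bad, "overall")


class TestBinomialCI:
    def cp_oracle(self, k, n, level=0.95):
        """Invert exact binomial tails by bisection (independent of the
        beta-quantile route used by the implementation)."""
        alpha = (1 - level) / 2

        def solve(f, lo, hi):
            for _ in range(200):
                mid = (lo + hi) / 2
                if f(mid):
                    lo = mid
                else:
                    hi = mid
            return (lo + hi) / 2

        lower = 0.0 if k == 0 else solve(
            lambda p: binom.sf(k - 1, n, p) < alpha, 0.0, k / n
        )
        upper = 1.0 if k == n else solve(
            lambda p: binom.cdf(k, n, p) >= alpha, k / n, 1.0
        )
        return lower, upper

    @pytest.mark.parametrize("k,n", [(8, 10), (1, 12), (15, 40), (73, 100)])
    def test_matches_bisection_oracle(self, k, n):
        lo, hi = binomial_ci(k, n)
        olo, ohi = self.cp_oracle(k, n)
        assert lo == pytest.approx(olo, abs=5e-4)
        assert hi == pytest.approx(ohi, abs=5e-4)

    def test_eight_of_ten(self):
        lo, hi = binomial_ci(8, 10)
        assert (round(lo, 3), round(hi, 3)) == (0.444, 0.975)

    def test_boundaries_exact(self):
        assert binomial_ci(0, 10)[0] == 0.0
        assert binomial_ci(10, 10)[1] == 1.0

    def test_zero_trials_error(self):
        with pytest.raises(ValueError):
            binomial_ci(0, 0)

    def test_coverage_of_true_proportion(self):
        """Clopper-Pearson intervals cover the truth in >=90% of replicates
        (they are conservative, so empirical coverage should exceed 95%)."""
        rng = np.random.default_rng(11)
        p, n, cover = 0.67, 150, 0
        reps = 200
        for _ in range(reps):
            k = rng.binomial(n, p)
            lo, hi = binomial_ci(k, n)
            cover += lo <= p <= hi
        assert cover / reps >= 0.90


class TestLrPlus:
    def test_values(self):
        assert lr_plus(0.73, 0.82) == pytest.approx(4.0556, abs=1e-4)
        assert lr_plus(0.5, 0.5) == pytest.approx(1.0)
        assert lr_plus(1.0, 1.0) == math.inf

    @given(
        se=st.floats(0.05, 1.0),
        sp=st.floats(0.05, 0.99),
        d_se=st.floats(0.001, 0.05),
        d_sp=st.floats(0.001, 0.005),
    )
    def test_strictly_increasing(self, se, sp, d_se, d_sp):
        if se + d_se <= 1.0:
            assert lr_plus(se + d_se, sp) > lr_plus(se, sp)
        if sp + d_sp <= 0.999:
            assert lr_plus(se, sp + d_sp) > lr_plus(se, sp)


def test_simulated_accuracy_recovery():
    """Point estimates from simulated pairs recover the generating Se/Sp."""
    cfg = SimConfig(
        n_subjects=10, se_by_rater=0.8, sp_by_rater=0.85, gold_prevalence=0.5, seed=4
    )
    pairs = simulate_validation(cfg, 20_000)
    est = estimate_accuracy(pairs, "overall")[0]
    se_se = np.sqrt(0.8 * 0.2 / (est.tp + est.fn))
    se_sp = np.sqrt(0.85 * 0.15 / (est.tn + est.fp))
    assert abs(est.se - 0.8) < 3 * se_se
    assert abs(est.sp - 0.85) < 3 * se_sp


def test_rater_accuracy_map_sparse_fallback():
    pairs = pd.concat(
        [
            pairs_from_counts(40, 10, 10, 40, rater=0),
            pairs_from_counts(3, 1, 1, 3, rater=1),  # sparse: falls back
        ],
        ignore_index=True,
    )
    amap = rater_accuracy_map(pairs, min_pairs=20)
    assert amap[0] == (0.8, 0.8)
    overall = estimate_accuracy(pairs, "overall")[0]
    assert amap[1] == (overall.se, overall.sp)


def test_accuracy_table_shape():
    pairs = pairs_from_counts(5, 5, 5, 5)
    table = accuracy_table(estimate_accuracy(pairs, "region"))
    assert list(table["stratum"]) == ["region=0", "overall"]
    assert {"se", "sp", "lr_plus", "tp"} <= set(table.columns)
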