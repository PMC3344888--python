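"""Normalization, log transform, heteroscedastic ANOVA and BH FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fivedge.diffexpr import (
    bh_fdr,
    brown_forsythe_matrix,
    de_pipeline,
    log_transform,
    normalize_per_gene,
    welch_anova,
    welch_anova_matrix,
)


class TestNormalize:
    def test_known_profile(self):
        m = pd.DataFrame([[2, 4, 8, 16, 32, 64]], index=["g"], dtype=float)
        out, excluded = normalize_per_gene(m)
        assert excluded == []
        expected = [1 / 6, 1 / 3, 2 / 3, 4 / 3, 8 / 3, 16 / 3]
        assert np.allclose(out.loc["g"], expected)

    def test_constant_profile_becomes_ones(self):
        m = pd.DataFrame([[7.0] * 4], index=["g"])
        out, _ = normalize_per_gene(m)
        assert np.allclose(out.loc["g"], 1.0)

    def test_zero_median_gene_excluded(self):
        m = pd.DataFrame(
            [[0.0, 0.0, 0.0, 5.0], [1, 2, 3, 4]], index=["dead", "ok"], dtype=float
        )
        out, excluded = normalize_per_gene(m)
        assert excluded == ["dead"]
        assert list(out.index) == ["ok"]

    @given(c=st.floats(min_value=0.01, max_value=1e6))
    @settings(max_examples=50, derandomize=True)
    def test_scale_invariance(self, c):
        base = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["g"])
        a, _ = normalize_per_gene(base)
        b, _ = normalize_per_gene(base * c)
        assert np.allclose(a.to_numpy(), b.to_numpy(), rtol=1e-9)


class TestLogTransform:
    def test_values(self):
        m = pd.DataFrame([[1.0, 0.0]])
        out = log_transform(m, pseudo=0.0)
        assert out.iloc[0, 0] == 0.0 and np.isneginf(out.iloc[0, 1])
        out2 = log_transform(m, pseudo=0.01)
        assert out2.iloc[0, 1] == pytest.approx(np.log2(0.01))

    def test_monotone(self):
        x = pd.DataFrame([np.linspace(0, 10, 20)])
        y = log_transform(x, 0.01)
        assert (np.diff(y.to_numpy()[0]) > 0).all()

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log_transform(pd.DataFrame([[-1.0]]))


class TestWelch:
    def test_identical_groups_give_p_one(self):
        F, p = welch_anova([(1, 2, 3), (1, 2, 3)])
        assert F == 0.0 and p == 1.0

    def test_separated_groups_significant(self):
        F, p = welch_anova([(0, 0.1, -0.1), (10, 10.1, 9.9)])
        assert p < 1e-3

    def test_permutation_oracle_agrees_on_separated_groups(self):
        """The observed split is the most extreme of all relabelings.

        With 3+3 values there are only 20 ordered splits, so the permutation
        p-value bottoms out at 2/20 (the observed split and its mirror);
        the oracle confirms the observed Welch F is the maximum attainable.
        """
        rng = np.random.default_rng(0)
        a, b = np.array([0, 0.1, -0.1]), np.array([10, 10.1, 9.9])
        obs_F, _ = welch_anova([a, b])
        pool = np.concatenate([a, b])
        exceed = 0
        n_perm = 500
        for _ in range(n_perm):
            perm = rng.permutation(pool)
            F, _ = welch_anova([perm[:3], perm[3:]])
            assert F <= obs_F + 1e-9
            exceed += F >= obs_F - 1e-9
        assert exceed / n_perm == pytest.approx(2 / 20, abs=0.05)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 18))
        groups = [np.arange(t * 3, t * 3 + 3) for t in range(6)]
        F, p = welch_anova_matrix(X.copy(), groups)
        labels = np.repeat(np.arange(6), 3)
        for i in range(20):
            df = pd.DataFrame({"y": X[i], "g": labels})
            ref = pg.welch_anova(dv="y", between="g", data=df)
            assert F[i] == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
            assert p[i] == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-9)

    def test_zero_variance_group_with_real_difference(self):
        F, p = welch_anova([(5.0, 5.0, 5.0), (9.0, 9.1, 8.9)])
        assert p < 1e-3


class TestBrownForsythe:
    def test_matches_statsmodels(self):
        """Statistic and denominator df agree with statsmodels' BF variant.

        statsmodels additionally applies a numerator-df correction, so only
        F and df2 are directly comparable; our p uses the original k-1
        numerator degrees of freedom.
        """
        from statsmodels.stats.oneway import anova_oneway

        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 18))
        groups = [np.arange(t * 3, t * 3 + 3) for t in range(6)]
        F, p, df2 = brown_forsythe_matrix(X.copy(), groups, return_df2=True)
        labels = np.repeat(np.arange(6), 3)
        from scipy import stats as sps

        for i in range(10):
            ref = anova_oneway(X[i], labels, use_var="bf", welch_correction=False)
            assert F[i] == pytest.approx(float(ref.statistic), rel=1e-9)
            assert df2[i] == pytest.approx(float(ref.df[1]), rel=1e-9)
            assert p[i] == pytest.approx(float(sps.f.sf(F[i], 5, df2[i])), rel=1e-12)

    def test_calibration_better_than_welch_at_three_replicates(self):
        """Welch inflates the null rejection rate at n=3; BF does not."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20_000, 18))
        groups = [np.arange(t * 3, t * 3 + 3) for t in range(6)]
        _, p_w = welch_anova_matrix(X.copy(), groups)
        _, p_bf = brown_forsythe_matrix(X.copy(), groups)
        assert (p_w < 0.05).mean() > 0.06      # anti-conservative
        assert (p_bf < 0.05).mean() <= 0.05    # conservative


class TestBH:
    def test_step_up_by_hand(self):
        """p=(.01,.02,.03,.04), m=4: p(i) <= 0.05*i/4 holds for all i."""
        q, reject = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert reject.all()

    def test_all_ones_no_rejections(self):
        q, reject = bh_fdr([1.0] * 10)
        assert not reject.any()

    def test_single_p_004_rejected(self):
        q, reject = bh_fdr([0.04])
        assert reject[0] and q[0] == pytest.approx(0.04)

    def test_q_at_least_p(self):
        rng = np.random.default_rng(4)
        p = rng.random(100)
        q, _ = bh_fdr(p)
        assert (q >= p - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestPipeline:
    def test_output_contract(self):
        import fivedge as f

        tpm, truth, times = f.simulate_expression_matrix(n_genes=300, seed=5)
        res = de_pipeline(tpm, times)
        t = res.table
        assert ((t["p"] >= 0) & (t["p"] <= 1)).all()
        assert (t["q"] >= t["p"] - 1e-12).all()
        assert (t["significant"] == (t["q"] <= 0.05)).all()

    def test_missing_sample_time_rejected(self):
        m = pd.DataFrame(np.ones((3, 4)), columns=list("abcd"))
        with pytest.raises(ValueError, match="without a time point"):
            de_pipeline(m, {"a": "t0", "b": "t0", "c": "t1"})

    def test_strong_effects_detected_nulls_mostly_not(self):
        import fivedge as f

        tpm, truth, times = f.simulate_expression_matrix(
            n_genes=1_000, fraction_de=0.1, effect_fold=8.0, seed=6
        )
        res = de_pipeline(tpm, times)
        sig = res.table["significant"]
        de = truth.loc[res.table.index, "de"]
        assert (sig & de).sum() / de.sum() > 0.9
        assert (sig & ~de).sum() <= 0.03 * sig.sum() + 2
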