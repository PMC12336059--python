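import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cvrquant.cohortstats import (
    fit_lme,
    independent_test,
    normality_check,
    paired_test,
    percent_change,
    records_to_long,
)
from cvrquant.errors import ParameterError, ShapeError
from cvrquant.synthgen import CohortSpec, generate_cohort


class TestPercentChange:
    def test_reported_reduction_convention(self):
        assert percent_change(4.5, 3.0) == pytest.approx(33.3, abs=0.05)

    def test_no_change(self):
        assert percent_change(5.0, 5.0) == 0.0

    def test_increase_is_negative(self):
        assert percent_change(50.0, 60.0) == pytest.approx(-20.0)

    def test_zero_pre_rejected(self):
        with pytest.raises(ParameterError):
            percent_change(0.0, 1.0)


class TestPairedTest:
    def test_identical_vectors_t_zero_p_one(self):
        res = paired_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_hand_computed_four_point_example(self):
        # differences {2, 3, 1, 2}: t = dbar / (s_d / sqrt(n)) = 4.90
        post = np.array([10.0, 10.0, 10.0, 10.0])
        pre = post + np.array([2.0, 3.0, 1.0, 2.0])
        res = paired_test(pre, post)
        assert res.statistic == pytest.approx(4.8990, abs=1e-3)
        assert res.df == 3
        # agrees with the library implementation
        ref = sps.ttest_rel(pre, post)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-12)

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        pre, post = rng.normal(5, 1, 8), rng.normal(4, 1, 8)
        a = paired_test(pre, post)
        b = paired_test(post, pre)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_power_at_reported_effect_size(self):
        # naive-group CVR drop (4.5 -> 3.0, SD 0.9, r = 0.7), n = 8:
        # rejection rate should be high, consistent with p < 0.001
        rng = np.random.default_rng(1)
        cov = 0.9**2 * np.array([[1.0, 0.7], [0.7, 1.0]])
        rejections = 0
        for _ in range(500):
            draws = rng.multivariate_normal([4.5, 3.0], cov, size=8)
            res = paired_test(draws[:, 0], draws[:, 1])
            rejections += res.p_value < 0.05
        assert rejections / 500 > 0.9

    def test_length_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            paired_test([1.0, 2.0], [1.0, 2.0, 3.0])


class TestNormalityCheck:
    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(2)
        pvals = [normality_check(rng.normal(0, 1, 8)).p_value for _ in range(200)]
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_skewed_sample_rejected_with_high_power(self):
        rng = np.random.default_rng(3)
        rejections = sum(
            normality_check(rng.exponential(1.0, 100)).p_value < 0.05
            for _ in range(100)
        )
        assert rejections / 100 > 0.9

    def test_sample_size_bounds(self):
        with pytest.raises(ParameterError):
            normality_check([1.0, 2.0])


class TestIndependentTest:
    def test_identical_groups(self):
        res = independent_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0

    def test_pooled_hand_value(self):
        res = independent_test([1.0, 2.0, 3.0], [4.0, 5.0, 6.0], equal_var=True)
        assert res.statistic == pytest.approx(-3.674, abs=1e-3)

    def test_power_for_group_contrast_of_reductions(self):
        # percent-reduction contrast 31.2 +- 14.1 vs 16.7 +- 5.0, n = 8/8:
        # moderate power, consistent with a borderline p = 0.04
        rng = np.random.default_rng(4)
        rejections = 0
        for _ in range(500):
            a = rng.normal(31.2, 14.1, 8)
            b = rng.normal(16.7, 5.0, 8)
            rejections += independent_test(a, b).p_value < 0.05
        assert rejections / 500 > 0.5

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ParameterError):
            independent_test([1.0, 1.0, 1.0], [2.0, 2.0])


class TestMixedModel:
    def _balanced_table(self, cells, n=4, subject_sd=0.0, noise_sd=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for g in ("naive", "habituated"):
            for i in range(n):
                offset = rng.normal(0, subject_sd) if subject_sd else 0.0
                for s in ("pre", "post"):
                    y = cells[(g, s)] + offset
                    if noise_sd:
                        y += rng.normal(0, noise_sd)
                    rows.append(
                        dict(subject_id=f"{g}{i}", group=g, sex="F",
                             age=30.0, state=s, outcome=y)
                    )
        return pd.DataFrame(rows)

    def test_saturated_balanced_model_recovers_cell_contrasts(self):
        cells = {
            ("naive", "pre"): 4.5, ("naive", "post"): 3.0,
            ("habituated", "pre"): 5.1, ("habituated", "post"): 3.7,
        }
        import warnings

        df = self._balanced_table(cells)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_lme(df, "outcome", covariates=())
        assert res.coef("Intercept") == pytest.approx(4.5, abs=1e-8)
        assert res.coef("caffeine") == pytest.approx(-1.5, abs=1e-8)
        assert res.coef("group_code") == pytest.approx(0.6, abs=1e-8)
        assert res.coef("interaction") == pytest.approx(0.1, abs=1e-8)
        assert res.singular

    def test_zero_random_variance_matches_ols(self):
        import statsmodels.formula.api as smf
        import warnings

        cells = {
            ("naive", "pre"): 5.0, ("naive", "post"): 4.0,
            ("habituated", "pre"): 5.5, ("habituated", "post"): 5.0,
        }
        df = self._balanced_table(cells, n=8, subject_sd=0.0, noise_sd=0.5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_lme(df, "outcome", covariates=())
        long = records_to_long(df, "outcome")
        ols = smf.ols("outcome ~ caffeine * group_code", long).fit()
        for term, ols_term in [
            ("Intercept", "Intercept"), ("caffeine", "caffeine"),
            ("group_code", "group_code"),
            ("interaction", "caffeine:group_code"),
        ]:
            assert res.coef(term) == pytest.approx(
                ols.params[ols_term], abs=1e-6
            )

    def test_null_caffeine_coefficient_ci_coverage(self):
        rng = np.random.default_rng(5)
        covered = 0
        n_rep = 300
        import warnings

        for _ in range(n_rep):
            rows = []
            for g in ("naive", "habituated"):
                for i in range(8):
                    offset = rng.normal(0, 1.0)
                    for s in ("pre", "post"):
                        rows.append(
                            dict(subject_id=f"{g}{i}", group=g, sex="F",
                                 age=30.0, state=s,
                                 outcome=10.0 + offset + rng.normal(0, 0.7))
                        )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = fit_lme(pd.DataFrame(rows), "outcome", covariates=())
            row = res.fixed_effects.loc["caffeine"]
            covered += row["ci_low"] <= 0.0 <= row["ci_high"]
        assert 0.90 <= covered / n_rep <= 0.99

    def test_interaction_sign_on_group_differential_effect(self):
        # basal CBF drops more in the naive group; with habituated coded 1
        # the caffeine x group interaction must come out positive
        spec = CohortSpec(n_per_group=8)
        frames = []
        import warnings

        for seed in range(10):
            cohort = generate_cohort(spec, seed=seed)
            df = cohort.truth.rename(columns={"cbf": "outcome"})
            df["subject_id"] = df["subject_id"] + f"_r{seed}"
            frames.append(df)
        table = pd.concat(frames, ignore_index=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_lme(table, "outcome")
        assert res.coef("interaction") > 0

    def test_type_one_error_of_paired_test_under_null(self):
        rng = np.random.default_rng(6)
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            base = rng.normal(5.0, 1.0, 8)
            pre = base + rng.normal(0, 0.5, 8)
            post = base + rng.normal(0, 0.5, 8)
            rejections += paired_test(pre, post).p_value < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07
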