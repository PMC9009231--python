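import numpy as np
import pandas as pd
import pytest
from scipy import stats

import kinflux as kf
from kinflux.signatures import (
    ModelFit,
    SignatureResult,
    _calls,
    benjamini_hochberg,
    call_signature,
    fit_model1,
    fit_model2,
)


def _statsmodels_fit(y, X):
    import statsmodels.api as sm

    return sm.OLS(y, X).fit()


class TestOLSBackend:
    def test_model1_matches_statsmodels(self, cohort, rng):
        matrix, design, _, _ = cohort
        fit = fit_model1(matrix, design)
        sel = design.index[design["group"].isin(["CEN", "F1SP"])]
        case = (design.loc[sel, "group"] == "CEN").to_numpy(float)
        male = (design.loc[sel, "sex"] == "male").to_numpy(float)
        X = np.column_stack([np.ones(len(sel)), case, male])
        for feat in rng.choice(matrix.index, size=10, replace=False):
            ref = _statsmodels_fit(matrix.loc[feat, sel].to_numpy(), X)
            assert fit.beta[feat] == pytest.approx(ref.params[1], abs=1e-10)
            assert fit.p[feat] == pytest.approx(ref.pvalues[1], abs=1e-10)

    def test_model2_matches_statsmodels(self, cohort, rng):
        matrix, design, _, _ = cohort
        fit = fit_model2(matrix, design)
        sel = design.index[design["group"] == "F1SP"]
        age = design.loc[sel, "age"].to_numpy(float)
        male = (design.loc[sel, "sex"] == "male").to_numpy(float)
        X = np.column_stack([np.ones(len(sel)), age, male])
        for feat in rng.choice(matrix.index, size=10, replace=False):
            ref = _statsmodels_fit(matrix.loc[feat, sel].to_numpy(), X)
            assert fit.beta[feat] == pytest.approx(ref.params[1], abs=1e-10)
            assert fit.p[feat] == pytest.approx(ref.pvalues[1], abs=1e-10)

    def test_constant_feature_excluded(self, cohort):
        matrix, design, _, _ = cohort
        matrix = matrix.copy()
        matrix.loc["feat_flat"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            fit = fit_model1(matrix, design)
        assert "feat_flat" in fit.excluded
        assert "feat_flat" not in fit.table.index

    def test_model2_needs_age_spread(self, cohort):
        matrix, design, _, _ = cohort
        design = design.copy()
        design["age"] = 60.0
        with pytest.raises(ValueError, match="distinct ages"):
            fit_model2(matrix, design)


class TestSensitivityAndTypeI:
    def test_planted_shift_detected(self, rng):
        """A +2 sigma mean shift in the case group should reach p < 0.05
        in nearly all of 20 replicate features (power ~ 1 at n=40+40)."""
        n = 40
        hits = 0
        design = pd.DataFrame({
            "group": ["CEN"] * n + ["F1SP"] * n,
            "age": np.r_[rng.uniform(98, 108, n), rng.uniform(45, 75, n)],
            "sex": rng.choice(["male", "female"], 2 * n),
        }, index=[f"s{i}" for i in range(2 * n)])
        for _ in range(20):
            y = rng.normal(0, 1, 2 * n)
            y[:n] += 2.0
            matrix = pd.DataFrame([y], index=["f"], columns=design.index)
            fit = fit_model1(matrix, design)
            if fit.p["f"] < 0.05 and fit.beta["f"] > 0:
                hits += 1
        assert hits >= 18

    def test_null_features_hit_alpha_rate(self, rng):
        """With no group effect, ~5% of features should reach p < 0.05."""
        n = 40
        design = pd.DataFrame({
            "group": ["CEN"] * n + ["F1SP"] * n,
            "age": np.r_[rng.uniform(98, 108, n), rng.uniform(45, 75, n)],
            "sex": rng.choice(["male", "female"], 2 * n),
        }, index=[f"s{i}" for i in range(2 * n)])
        matrix = pd.DataFrame(
            rng.normal(0, 1, (400, 2 * n)),
            index=[f"f{i}" for i in range(400)],
            columns=design.index,
        )
        fit = fit_model1(matrix, design)
        rate = float((fit.p < 0.05).mean())
        assert 0.02 <= rate <= 0.09


class TestCallRule:
    @pytest.mark.parametrize(
        "b1, p1, b2, p2, expected",
        [
            (1.0, 0.01, 0.0, 0.9, "up"),     # significant up, no aging
            (1.0, 0.01, 1.0, 0.01, "none"),  # masked by positive aging effect
            (-1.0, 0.01, 1.0, 0.01, "down"), # down call unaffected by aging-up
            (1.0, 0.20, 0.0, 0.9, "none"),   # not significant
            (-1.0, 0.01, -1.0, 0.01, "none"),# down masked by aging-down
        ],
    )
    def test_worked_examples(self, b1, p1, b2, p2, expected):
        out = _calls(
            np.array([b1]), np.array([p1]), np.array([b2]), np.array([p2]), 0.05
        )
        assert out[0] == expected

    def test_counts_partition(self, cohort):
        matrix, design, _, _ = cohort
        sig = call_signature(fit_model1(matrix, design), fit_model2(matrix, design))
        counts = sig.counts()
        assert sum(counts.values()) == len(sig.table)


class TestDAScore:
    def _signature(self, calls):
        table = pd.DataFrame({
            "beta1": 0.0, "p1": 1.0, "beta2": 0.0, "p2": 1.0,
            "call": pd.Series(calls),
        })
        return SignatureResult(table)

    def test_worked_values(self):
        calls = {f"f{i}": c for i, c in enumerate(
            ["up"] * 4 + ["down"] * 1 + ["none"] * 5   # SS_A: (4-1)/10 = 0.3
            + ["up"] * 3                               # SS_B: 3/3 = 1.0
            + ["none"] * 2                             # SS_C: 0.0
        )}
        grouping = pd.Series(
            ["SS_A"] * 10 + ["SS_B"] * 3 + ["SS_C"] * 2,
            index=list(calls),
        )
        da = kf.da_score(self._signature(calls), grouping)
        assert da["SS_A"] == pytest.approx(0.3)
        assert da["SS_B"] == pytest.approx(1.0)
        assert da["SS_C"] == pytest.approx(0.0)

    def test_bounded_in_unit_interval(self, cohort):
        matrix, design, grouping, _ = cohort
        sig = call_signature(fit_model1(matrix, design), fit_model2(matrix, design))
        da = kf.da_score(sig, grouping)
        assert ((da >= -1.0) & (da <= 1.0)).all()


class TestBootstrap:
    def test_planted_subsystem_recovered(self, cohort):
        matrix, design, grouping, truth = cohort
        res = kf.da_bootstrap(matrix, design, grouping, B=200, seed=0)
        planted = truth["spec"].planted_subsystem
        assert res.table.loc[planted, "da"] > 0.5
        assert res.table.loc[planted, "fdr"] < 0.05

    def test_deterministic_given_seed(self, cohort):
        matrix, design, grouping, _ = cohort
        a = kf.da_bootstrap(matrix, design, grouping, B=50, seed=3)
        b = kf.da_bootstrap(matrix, design, grouping, B=50, seed=3)
        assert a.table.equals(b.table)

    def test_zero_da_gets_p_one(self, cohort):
        matrix, design, grouping, _ = cohort
        res = kf.da_bootstrap(matrix, design, grouping, B=50, seed=0)
        zeros = res.table.index[res.table["da"] == 0.0]
        assert (res.table.loc[zeros, "p"] == 1.0).all()

    def test_benjamini_hochberg_known_values(self):
        # classic worked example: p = (.01, .02, .03, .04), m = 4
        adj = benjamini_hochberg(np.array([0.01, 0.04, 0.03, 0.02]))
        assert adj == pytest.approx([0.04, 0.04, 0.04, 0.04])
        adj2 = benjamini_hochberg(np.array([0.005, 0.5]))
        assert adj2 == pytest.approx([0.01, 0.5])


class TestSummaryStatistics:
    def test_welch_matches_full_data_oracle(self, rng):
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.5, 2, 25)
        t, df, p = kf.welch_t_from_summary(
            x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y)
        )
        ref = stats.ttest_ind(x, y, equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_welch_cohort_blood_pressure_values(self):
        # blood pressure, centenarians vs controls and vs offspring:
        # both rounds to 0.03; blood glucose rounds to a non-significant 0.14
        _, _, p_ctrl = kf.welch_t_from_summary(146.0, 20.1, 76, 137.9, 18.0, 41)
        _, _, p_off = kf.welch_t_from_summary(146.0, 20.1, 76, 138.3, 19.2, 54)
        _, _, p_glc = kf.welch_t_from_summary(5.98, 1.26, 76, 6.70, 2.96, 41)
        assert p_ctrl == pytest.approx(0.0284, abs=5e-4)
        assert p_off == pytest.approx(0.0291, abs=5e-4)
        assert p_glc == pytest.approx(0.1437, abs=5e-4)

    def test_fisher_cohort_sex_composition(self):
        # 58 F / 18 M centenarians vs 40 F / 1 M controls
        p = kf.fisher_exact_2x2([[58, 18], [40, 1]])
        assert p == pytest.approx(0.00292, abs=5e-5)

    def test_welch_rejects_bad_sd(self):
        with pytest.raises(ValueError):
            kf.welch_t_from_summary(1, 0, 10, 2, 1, 10)

    def test_fisher_worked_values(self):
        assert kf.fisher_exact_2x2([[2, 0], [0, 2]]) == pytest.approx(1 / 3)
        assert kf.fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_fisher_zero_margin_warns(self):
        with pytest.warns(UserWarning, match="margin"):
            assert kf.fisher_exact_2x2([[0, 0], [3, 4]]) == 1.0

    def test_fisher_rejects_bad_shape(self):
        with pytest.raises(ValueError):
            kf.fisher_exact_2x2([[1, 2, 3], [4, 5, 6]])


class TestCompareSignatures:
    def test_perfect_correlation(self):
        idx = [f"f{i}" for i in range(5)]
        a = ModelFit(pd.DataFrame({"beta": [1, 2, 3, 4, 5], "p": 0.5}, index=idx), "model1")
        b = ModelFit(pd.DataFrame({"beta": [2, 4, 6, 8, 10], "p": 0.5}, index=idx), "model1")
        r, _ = kf.compare_signatures(a, b)
        assert r == pytest.approx(1.0)
        neg = ModelFit(pd.DataFrame({"beta": [-1, -2, -3, -4, -5], "p": 0.5}, index=idx), "model1")
        r, _ = kf.compare_signatures(a, neg)
        assert r == pytest.approx(-1.0)

    def test_matches_scipy_pearson(self, rng):
        idx = [f"f{i}" for i in range(50)]
        x, y = rng.normal(size=50), rng.normal(size=50)
        a = ModelFit(pd.DataFrame({"beta": x, "p": 0.5}, index=idx), "model1")
        b = ModelFit(pd.DataFrame({"beta": y, "p": 0.5}, index=idx), "model1")
        r, p = kf.compare_signatures(a, b)
        ref = stats.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_too_few_shared_features_errors(self):
        a = ModelFit(pd.DataFrame({"beta": [1.0], "p": 0.5}, index=["f0"]), "model1")
        with pytest.raises(ValueError, match="3"):
            kf.compare_signatures(a, a)


class TestSignatureModelInterface:
    def test_fit_returns_results_with_summary(self, cohort):
        matrix, design, grouping, truth = cohort
        model = kf.SignatureModel(matrix, design, grouping)
        results = model.fit(B=50, seed=0)
        text = results.summary()
        assert "Signature analysis" in text
        assert "CEN" in text
        assert results.da is not None
        planted = truth["spec"].planted_subsystem
        assert results.da.table.loc[planted, "da"] > 0.5

    def test_fit_without_bootstrap(self, cohort):
        matrix, design, grouping, _ = cohort
        results = kf.SignatureModel(matrix, design, grouping).fit()
        # without shuffles the DA table carries point scores but no p-values
        assert results.da.table["p"].isna().all()
        assert results.da.n_shuffles == 0
        assert len(results.signature.table) > 0

    def test_log2_transform_applied(self, cohort):
        matrix, design, _, _ = cohort
        m = kf.SignatureModel(matrix, design, log2=True)
        assert np.allclose(m.matrix.to_numpy(), np.log2(matrix.to_numpy()))
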