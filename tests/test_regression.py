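"""Design coding, IRLS logistic fit, Wald inference, HL test, VIF."""

import math

import numpy as np
import pandas as pd
import pytest

from chesurvey.errors import (
    HosmerLemeshowError,
    RankDeficiencyError,
    SeparationError,
    ValidationError,
)
from chesurvey.regression import (
    build_design_matrix,
    default_design_spec,
    fit_logistic,
    hosmer_lemeshow,
    odds_ratios,
    vif,
    vif_by_term,
)


def reference_records(n=3):
    """Households entirely at reference levels (URRBMI, single-person, ...)."""
    return pd.DataFrame(
        {
            "household_id": [f"H{i}" for i in range(n)],
            "age": [60.0] * n,
            "region": ["East"] * n,
            "economic_level": [1] * n,
            "size_class": ["1"] * n,
            "labour": ["No"] * n,
            "member_65": ["No"] * n,
            "disabled": ["No"] * n,
            "outpatient": ["No"] * n,
            "inpatient": ["No"] * n,
            "heart_disease": ["No"] * n,
            "stroke": ["No"] * n,
            "malignant_tumour": ["No"] * n,
            "chronic_lung_disease": ["No"] * n,
            "diabetes": ["No"] * n,
            "insurance": ["URRBMI"] * n,
        }
    )


class TestDesignMatrix:
    def test_reference_household_is_all_zero_dummies(self):
        records = reference_records()
        y, X, names = build_design_matrix(records, np.zeros(3), default_design_spec())
        # intercept 1, age passes through, every dummy 0
        assert names[0] == "const"
        np.testing.assert_array_equal(X[:, 0], 1.0)
        age_col = names.index("age")
        np.testing.assert_array_equal(X[:, age_col], 60.0)
        dummy_cols = [j for j, n_ in enumerate(names) if n_ not in ("const", "age")]
        assert np.all(X[:, dummy_cols] == 0.0)
        assert all(not n_.startswith("insurance[URRBMI") for n_ in names)
        assert all(not n_.startswith("size_class[1]") for n_ in names)

    def test_column_count_by_enumeration(self):
        # 1 intercept + 1 numeric + sum(levels-1) over categorical terms
        spec = default_design_spec()
        expected = 1 + 1 + sum(
            len(t.levels) - 1 for t in spec.terms if t.kind == "categorical"
        )
        _, X, names = build_design_matrix(reference_records(), np.zeros(3), spec)
        assert X.shape[1] == len(names) == expected == 24

    def test_unseen_category_named(self):
        records = reference_records()
        records.loc[1, "insurance"] = "Commercial"
        with pytest.raises(ValidationError, match="H1.*Commercial|Commercial.*H1"):
            build_design_matrix(records, np.zeros(3), default_design_spec())


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.array([1.0] * 25 + [0.0] * 75)
        fit = fit_logistic(y, np.ones((100, 1)), columns=["const"])
        assert fit.beta[0] == pytest.approx(math.log(0.25 / 0.75), abs=1e-8)
        assert fit.converged

    def test_fitted_probabilities_sum_to_event_count(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(500), rng.normal(size=500), rng.integers(0, 2, 500)])
        eta = -0.5 + 0.8 * X[:, 1] + 0.5 * X[:, 2]
        y = (rng.uniform(size=500) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = fit_logistic(y, X)
        assert fit.fitted.sum() == pytest.approx(y.sum(), abs=1e-6)
        assert np.all((fit.fitted > 0) & (fit.fitted < 1))

    def test_matches_grid_search_mle(self):
        # brute-force MLE on a 2-parameter toy problem
        rng = np.random.default_rng(4)
        x = rng.normal(size=120)
        y = (rng.uniform(size=120) < 1 / (1 + np.exp(-(0.3 + 0.9 * x)))).astype(float)
        X = np.column_stack([np.ones(120), x])
        fit = fit_logistic(y, X)

        def nll(b0, b1):
            eta = b0 + b1 * x
            return -np.sum(y * eta - np.logaddexp(0, eta))

        grid = np.linspace(-2, 2, 401)
        best = min(((nll(b0, b1), b0, b1) for b0 in grid for b1 in grid))
        # grid spacing 0.01: the IRLS optimum must sit within one cell
        assert fit.beta[0] == pytest.approx(best[1], abs=1.5e-2)
        assert fit.beta[1] == pytest.approx(best[2], abs=1.5e-2)
        assert nll(*fit.beta) <= best[0] + 1e-9

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(9)
        X = np.column_stack([np.ones(400), rng.normal(size=400), rng.integers(0, 2, 400)])
        eta = -1.0 + 0.7 * X[:, 1] - 0.4 * X[:, 2]
        y = (rng.uniform(size=400) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = fit_logistic(y, X)
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(fit.beta, ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.se, ref.bse, rtol=1e-4)

    def test_perfect_separation_raises(self):
        x = np.concatenate([np.full(20, -1.0), np.full(20, 1.0)])
        y = (x > 0).astype(float)
        with pytest.raises(SeparationError):
            fit_logistic(y, np.column_stack([np.ones(40), x]))

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        X = np.column_stack([np.ones(50), x, x])
        y = rng.integers(0, 2, 50).astype(float)
        with pytest.raises(RankDeficiencyError) as err:
            fit_logistic(y, X, columns=["const", "a", "a_copy"])
        assert "a_copy" in err.value.columns


class TestOddsRatios:
    def make_fit(self, beta, se):
        from chesurvey.regression import LogisticFit

        k = len(beta)
        return LogisticFit(
            columns=[f"b{i}" for i in range(k)],
            beta=np.array(beta),
            se=np.array(se),
            cov=np.diag(np.array(se) ** 2),
            converged=True,
            n_iter=1,
            log_likelihood=0.0,
            fitted=np.array([0.5]),
            outcome=np.array([1.0]),
            design=np.ones((1, k)),
        )

    def test_null_coefficient(self):
        out = odds_ratios(self.make_fit([0.0], [0.2]))
        assert out["or"].iloc[0] == pytest.approx(1.0)
        assert out["ci_lower"].iloc[0] * out["ci_upper"].iloc[0] == pytest.approx(1.0)

    def test_wald_formula_by_hand(self):
        out = odds_ratios(self.make_fit([math.log(2.0)], [0.1]))
        z = 1.959963984540054
        assert out["or"].iloc[0] == pytest.approx(2.0)
        assert out["ci_lower"].iloc[0] == pytest.approx(math.exp(0.6931471805599453 - z * 0.1), rel=1e-9)
        assert out["ci_upper"].iloc[0] == pytest.approx(math.exp(0.6931471805599453 + z * 0.1), rel=1e-9)
        assert out["ci_lower"].iloc[0] == pytest.approx(1.644, abs=5e-4)
        assert out["ci_upper"].iloc[0] == pytest.approx(2.433, abs=5e-4)

    def test_ci_width_shrinks_with_se(self):
        widths = [
            (lambda o: o["ci_upper"].iloc[0] - o["ci_lower"].iloc[0])(
                odds_ratios(self.make_fit([0.5], [s]))
            )
            for s in (0.4, 0.2, 0.1, 0.05)
        ]
        assert widths == sorted(widths, reverse=True)


class TestHosmerLemeshow:
    def test_perfect_calibration_is_zero(self):
        # five blocks of 20 with distinct probabilities and observed counts
        # exactly equal to expected in every block
        p = np.repeat([0.1, 0.2, 0.3, 0.4, 0.5], 20)
        y = np.concatenate(
            [np.r_[np.ones(int(20 * q)), np.zeros(20 - int(20 * q))] for q in (0.1, 0.2, 0.3, 0.4, 0.5)]
        )
        stat, df, pval = hosmer_lemeshow(y, p, groups=5)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert df == 3
        assert pval == pytest.approx(1.0)

    def test_ten_groups_give_df_8(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.05, 0.95, 500)
        y = (rng.uniform(size=500) < p).astype(float)
        _, df, _ = hosmer_lemeshow(y, p, groups=10)
        assert df == 8

    def test_order_invariance(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0.05, 0.95, 300)
        y = (rng.uniform(size=300) < p).astype(float)
        stat1, *_ = hosmer_lemeshow(y, p)
        perm = rng.permutation(300)
        stat2, *_ = hosmer_lemeshow(y[perm], p[perm])
        assert stat1 == pytest.approx(stat2, rel=1e-12)

    def test_degenerate_group_advises_fewer_groups(self):
        y = np.array([0.0] * 50)
        p = np.full(50, 1e-9)
        with pytest.raises((HosmerLemeshowError, ValidationError)):
            hosmer_lemeshow(y, p, groups=5)


class TestVif:
    def test_orthogonal_predictors(self):
        X = np.column_stack(
            [np.ones(4), [1, 1, -1, -1], [1, -1, 1, -1], [1, -1, -1, 1]]
        )
        out = vif(X, ["const", "a", "b", "c"])
        np.testing.assert_allclose(out.to_numpy(), 1.0, atol=1e-12)

    def test_known_r2_half(self):
        # x2 = a + z with a, z orthogonal: R^2 = 0.5 each way -> VIF 2
        a = np.array([1.0, 1.0, -1.0, -1.0])
        z = np.array([1.0, -1.0, 1.0, -1.0])
        X = np.column_stack([np.ones(4), a, a + z])
        out = vif(X, ["const", "a", "a_plus_z"])
        np.testing.assert_allclose(out.to_numpy(), 2.0, rtol=1e-12)

    def test_duplicate_column_is_infinite(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        X = np.column_stack([np.ones(30), x, x, rng.normal(size=30)])
        out = vif(X, ["const", "a", "a_copy", "b"])
        assert np.isinf(out["a"]) and np.isinf(out["a_copy"])
        assert np.isfinite(out["b"])

    def test_matches_statsmodels(self):
        smo = pytest.importorskip("statsmodels.stats.outliers_influence")
        rng = np.random.default_rng(6)
        base = rng.normal(size=(200, 3))
        X = np.column_stack([np.ones(200), base[:, 0], base[:, 1], base[:, 0] + 0.5 * base[:, 2]])
        ours = vif(X, ["const", "a", "b", "c"])
        theirs = [smo.variance_inflation_factor(X, j) for j in (1, 2, 3)]
        np.testing.assert_allclose(ours.to_numpy(), theirs, rtol=1e-8)

    def test_term_aggregation_takes_max(self):
        rng = np.random.default_rng(7)
        x1 = rng.normal(size=100)
        x2 = x1 + 0.2 * rng.normal(size=100)
        x3 = rng.normal(size=100)
        X = np.column_stack([np.ones(100), x1, x2, x3])
        per_col = vif(X, ["const", "ins[A]", "ins[B]", "age"])
        by_term = vif_by_term(X, ["const", "ins[A]", "ins[B]", "age"])
        assert by_term["ins"] == pytest.approx(max(per_col["ins[A]"], per_col["ins[B]"]))
        assert set(by_term.index) == {"ins", "age"}
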