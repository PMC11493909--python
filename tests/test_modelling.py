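"""Multinomial fitting, contrasts, selection and collinearity diagnostics."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from dogchange import modelling as mdl


def _simulate_multinomial(n, beta_improving, beta_declining, rng, intercepts=(0.0, 0.0)):
    """Outcome data from a known softmax model with one predictor x."""
    x = rng.standard_normal(n)
    lin_d = intercepts[0] + beta_declining * x
    lin_i = intercepts[1] + beta_improving * x
    logits = np.column_stack([np.zeros(n), lin_d, lin_i])
    p = np.exp(logits - logits.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random(n)
    codes = (u[:, None] > p.cumsum(axis=1)).sum(axis=1)
    cats = np.array(["stable", "declining", "improving"])[codes]
    return pd.DataFrame({"category": cats, "x": x})


class TestInterventionCoding:
    def test_combined_counts_as_both(self):
        c = mdl.intervention_coding("combined")
        assert c["any_physical"] == "yes" and c["any_cognitive"] == "yes"
        assert c["any_intervention"] == "yes"

    def test_control_is_no_on_all(self):
        c = mdl.intervention_coding("control")
        assert (c["any_physical"], c["any_cognitive"], c["any_intervention"]) == (
            "no", "no", "no",
        )

    def test_cognitive_only(self):
        c = mdl.intervention_coding("cognitive")
        assert c["any_physical"] == "no" and c["any_cognitive"] == "yes"

    def test_unknown_label_errors(self):
        with pytest.raises(ValueError):
            mdl.intervention_coding("placebo")

    def test_spec_rejects_two_codings(self):
        with pytest.raises(ValueError):
            mdl.ModelSpec("c", ("any_physical", "any_cognitive"))


class TestFitMultinomial:
    def test_intercept_only_closed_form(self, rng):
        data = _simulate_multinomial(90, 0.8, -0.5, rng)
        fit = mdl.fit_multinomial(data, mdl.ModelSpec("category"))
        counts = data["category"].value_counts()
        n = len(data)
        # logLik = sum_k n_k ln(n_k / N)
        expected_llf = sum(c * np.log(c / n) for c in counts)
        assert fit.llf == pytest.approx(expected_llf, abs=1e-8)
        # fitted intercepts reproduce the observed proportions
        for cat in ("declining", "improving"):
            expected_b = np.log(counts[cat] / counts["stable"])
            assert fit.params.loc["const", cat] == pytest.approx(expected_b, abs=1e-6)
        assert fit.aic == pytest.approx(-2 * expected_llf + 2 * 2, abs=1e-6)

    def test_two_observed_categories_match_logistic_oracle(self, rng):
        data = _simulate_multinomial(300, 1.0, 0.0, rng)
        data = data[data["category"] != "declining"]
        fit = mdl.fit_multinomial(data, mdl.ModelSpec("category", ("x",)))
        y = (data["category"] == "improving").astype(float)
        X = sm.add_constant(data["x"].to_numpy())
        oracle = sm.Logit(y, X).fit(disp=0, method="newton", tol=1e-10)
        assert fit.params["improving"].to_numpy() == pytest.approx(
            oracle.params, abs=1e-6
        )

    def test_binary_predictor_matches_crossproduct_ratios(self, rng):
        # each category-vs-reference slope equals the log cross-product
        # ratio of the corresponding 2x2 subtable
        g = rng.integers(0, 2, 400)
        cats = np.where(
            rng.random(400) < 0.3 + 0.2 * g, "improving",
            np.where(rng.random(400) < 0.5, "stable", "declining"),
        )
        data = pd.DataFrame({"category": cats, "g": g.astype(float)})
        fit = mdl.fit_multinomial(data, mdl.ModelSpec("category", ("g",)))
        tab = pd.crosstab(data["g"], data["category"])
        for cat in ("declining", "improving"):
            lor = np.log(
                tab.loc[1, cat] * tab.loc[0, "stable"]
                / (tab.loc[0, cat] * tab.loc[1, "stable"])
            )
            assert fit.params.loc["g", cat] == pytest.approx(lor, abs=1e-6)

    def test_rank_deficient_design_errors(self, rng):
        data = _simulate_multinomial(100, 0.5, 0.5, rng)
        data["x2"] = 2.0 * data["x"]
        with pytest.raises(ValueError, match="rank"):
            mdl.fit_multinomial(data, mdl.ModelSpec("category", ("x", "x2")))

    def test_row_permutation_invariance(self, rng):
        data = _simulate_multinomial(150, 0.7, -0.3, rng)
        fit1 = mdl.fit_multinomial(data, mdl.ModelSpec("category", ("x",)))
        fit2 = mdl.fit_multinomial(
            data.sample(frac=1.0, random_state=4), mdl.ModelSpec("category", ("x",))
        )
        assert np.allclose(fit1.params, fit2.params, atol=1e-8)


class TestContrasts:
    def test_zero_beta_gives_unit_or(self):
        or_, lo, hi = mdl.wald_odds_ratio(0.0, 0.2)
        assert or_ == 1.0 and lo < 1.0 < hi

    def test_printed_or_arithmetic(self):
        # beta 0.17 +- 0.05 -> OR 1.19, CI [1.07, 1.31] at 2 decimals
        or_, lo, hi = mdl.wald_odds_ratio(0.17, 0.05)
        assert round(or_, 2) == 1.19
        assert (round(lo, 2), round(hi, 2)) == (1.07, 1.31)
        assert round(mdl.wald_odds_ratio(0.39, 0.11)[0], 2) == 1.48

    def test_delta_method_third_contrast(self, rng):
        data = _simulate_multinomial(400, 0.9, -0.4, rng)
        fit = mdl.fit_multinomial(data, mdl.ModelSpec("category", ("x",)))
        contrasts = {c.contrast: c for c in mdl.pairwise_contrasts(fit)}
        direct = contrasts["improving vs stable"]
        assert direct.beta == pytest.approx(fit.params.loc["x", "improving"])
        diff = contrasts["improving vs declining"]
        assert diff.beta == pytest.approx(
            fit.params.loc["x", "improving"] - fit.params.loc["x", "declining"]
        )
        # oracle: refit with declining as the reference category
        refit = mdl.fit_multinomial(
            data, mdl.ModelSpec("category", ("x",), reference="declining")
        )
        assert diff.beta == pytest.approx(
            refit.params.loc["x", "improving"], abs=1e-5
        )
        assert diff.se == pytest.approx(
            refit.bse.loc["x", "improving"], rel=1e-3
        )
        assert diff.ci_low < diff.odds_ratio < diff.ci_high


class TestLRT:
    def test_identical_models_give_zero(self, rng):
        data = _simulate_multinomial(100, 0.5, 0.2, rng)
        fit = mdl.fit_multinomial(data, mdl.ModelSpec("category", ("x",)))
        stat, df, p = mdl.lrt(fit, fit)
        assert (stat, df, p) == (0.0, 0, 1.0)

    def test_aic_algebraic_identity(self, rng):
        data = _simulate_multinomial(200, 0.8, -0.2, rng)
        nested = mdl.fit_multinomial(data, mdl.ModelSpec("category"))
        full = mdl.fit_multinomial(data, mdl.ModelSpec("category", ("x",)))
        stat, df, _ = mdl.lrt(nested, full)
        assert stat == pytest.approx(
            -(full.aic - nested.aic) + 2 * (full.n_params - nested.n_params), abs=1e-8
        )

    def test_non_nested_errors(self, rng):
        data = _simulate_multinomial(100, 0.5, 0.2, rng)
        data["z"] = rng.standard_normal(100)
        f1 = mdl.fit_multinomial(data, mdl.ModelSpec("category", ("x",)))
        f2 = mdl.fit_multinomial(data, mdl.ModelSpec("category", ("z",)))
        with pytest.raises(ValueError):
            mdl.lrt(f1, f2)

    def test_null_predictor_p_uniform(self, rng):
        # under H0 the LRT p-value is Uniform(0,1); KS test over replicates
        from scipy.stats import kstest

        ps = []
        for _ in range(120):
            data = _simulate_multinomial(120, 0.0, 0.0, rng)
            nested = mdl.fit_multinomial(data, mdl.ModelSpec("category"))
            full = mdl.fit_multinomial(data, mdl.ModelSpec("category", ("x",)))
            ps.append(mdl.lrt(nested, full)[2])
        assert kstest(ps, "uniform").pvalue > 0.01


class TestForwardSelection:
    def test_deterministic_given_data_and_order(self, rng):
        data = _simulate_multinomial(84, 1.0, -1.0, rng)
        data["noise"] = rng.standard_normal(len(data))
        r1 = mdl.forward_aic_select(data, "category", ["x", "noise"])
        r2 = mdl.forward_aic_select(data, "category", ["x", "noise"])
        assert r1.spec.predictors == r2.spec.predictors
        assert r1.fit.aic == pytest.approx(r2.fit.aic)

    def test_at_most_one_intervention_coding(self, rng):
        n = 84
        group = rng.choice(["physical", "cognitive", "combined", "control"], n)
        df = pd.DataFrame({"exposure": group})
        df = mdl.add_intervention_codings(df)
        treated = (df["any_intervention"] == "yes").to_numpy()
        # strong any-intervention effect: both codings would qualify alone
        cats = np.where(
            rng.random(n) < np.where(treated, 0.7, 0.15), "improving",
            np.where(rng.random(n) < 0.5, "stable", "declining"),
        )
        df["category"] = cats
        res = mdl.forward_aic_select(
            df, "category",
            ["any_intervention", "any_physical", "any_cognitive", "group4"],
        )
        codings = [p for p in res.spec.predictors if p in mdl.INTERVENTION_CODINGS]
        assert len(codings) <= 1

    def test_returns_intercept_only_when_nothing_qualifies(self, rng):
        data = _simulate_multinomial(84, 0.0, 0.0, rng)
        res = mdl.forward_aic_select(data, "category", ["x"])
        assert res.spec.predictors == ()
        assert res.history == []


class TestVIF:
    def test_orthogonal_predictors_near_one(self, rng):
        n = 3000
        data = pd.DataFrame(
            {
                "x1": rng.standard_normal(n),
                "x2": rng.standard_normal(n),
                "category": rng.choice(["stable", "declining", "improving"], n),
            }
        )
        diag = mdl.vif_binomial(data, mdl.ModelSpec("category", ("x1", "x2")))
        assert np.allclose(diag.vif.to_numpy(), 1.0, atol=0.05)
        assert diag.max_vif >= 1.0 - 1e-9

    def test_correlated_pair_matches_identity(self, rng):
        # for two predictors with correlation r, VIF ~ 1/(1-r^2)
        n, r = 4000, 0.7
        x1 = rng.standard_normal(n)
        x2 = r * x1 + np.sqrt(1 - r**2) * rng.standard_normal(n)
        data = pd.DataFrame(
            {
                "x1": x1, "x2": x2,
                "category": rng.choice(["stable", "declining", "improving"], n),
            }
        )
        diag = mdl.vif_binomial(data, mdl.ModelSpec("category", ("x1", "x2")))
        emp_r2 = np.corrcoef(x1, x2)[0, 1] ** 2
        assert diag.vif.loc["x1"].to_numpy() == pytest.approx(
            1 / (1 - emp_r2), rel=0.05
        )

    def test_duplicated_predictor_raises_aliasing_error(self, rng):
        n = 200
        x = rng.standard_normal(n)
        data = pd.DataFrame(
            {
                "x1": x, "x2": x,
                "category": rng.choice(["stable", "declining", "improving"], n),
            }
        )
        with pytest.raises(ValueError, match="alias"):
            mdl.vif_binomial(data, mdl.ModelSpec("category", ("x1", "x2")))

    def test_single_predictor_errors(self, rng):
        data = _simulate_multinomial(100, 0.5, 0.2, rng)
        with pytest.raises(ValueError):
            mdl.vif_binomial(data, mdl.ModelSpec("category", ("x",)))
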