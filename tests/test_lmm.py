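import numpy as np
import pandas as pd
import pytest

from meld.formula import ModelFormula, parse_formula
from meld.lmm import LmerEngine, fit_components, fit_lmer


def crossed_dataset(seed=7, ns=6, ni=10, slope=0.8):
    """Crossed subject x item layout with a two-level condition."""
    rng = np.random.default_rng(seed)
    u_int = rng.normal(0, 0.5, ns)
    u_sl = rng.normal(0, 0.3, ns)
    w = rng.normal(0, 1.0, ni)
    beh = np.array(["A"] * (ni // 2) + ["B"] * (ni // 2))
    xj = np.where(beh == "A", -0.5, 0.5)
    rows, ys = [], []
    for i in range(ns):
        for j in range(ni):
            mu = 1.0 + (slope + u_sl[i]) * xj[j] + u_int[i] + w[j]
            ys.append(mu + rng.normal(0, 1))
            rows.append((f"s{i}", f"i{j}", beh[j]))
    design = pd.DataFrame(rows, columns=["subject", "item", "beh"])
    return design, np.array(ys)


class TestAgainstIndependentReferences:
    def test_no_random_terms_equals_ols_exactly(self):
        design, y = crossed_dataset()
        fit = fit_lmer(y, design, parse_formula("y~beh"))
        X = np.column_stack([np.ones(len(y)), np.where(design.beh == "A", -0.5, 0.5)])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ beta
        sigma2 = resid @ resid / (len(y) - 2)
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
        np.testing.assert_allclose(fit.beta, beta, atol=1e-10)
        np.testing.assert_allclose(fit.se, se, atol=1e-10)
        assert fit.status == "converged"

    def test_balanced_one_way_matches_anova_closed_form(self):
        # balanced one-way random-intercept layout: REML variance estimates
        # equal the ANOVA estimators MSW and (MSB - MSW)/m
        rng = np.random.default_rng(42)
        g, m = 8, 6
        b = rng.normal(0, 1.3, g)
        y = 1.5 + np.repeat(b, m) + rng.normal(0, 0.9, g * m)
        design = pd.DataFrame({"grp": np.repeat([f"g{i}" for i in range(g)], m)})
        # intercept-only fixed part, constructed directly (the formula
        # grammar itself requires a slope term for the pipeline)
        formula = ModelFormula("y", (), ((("1",), "grp"),))
        fit = fit_lmer(y, design, formula)
        ybar_g = y.reshape(g, m).mean(axis=1)
        msb = m * np.sum((ybar_g - y.mean()) ** 2) / (g - 1)
        msw = np.sum((y.reshape(g, m) - ybar_g[:, None]) ** 2) / (g * (m - 1))
        assert abs(fit.sigma2 - msw) < 1e-6
        assert abs(fit.vcomp["grp"][0, 0] - (msb - msw) / m) < 1e-6
        assert abs(fit.beta[0] - y.mean()) < 1e-8

    def test_matches_frozen_reference_reml_fit(self):
        # reference values from an independent REML implementation on this
        # exact (seeded) dataset: fixed effects, SEs, t, variances, criterion
        design, y = crossed_dataset(seed=7, ns=6, ni=10, slope=0.8)
        fit = fit_lmer(y, design, parse_formula("y~beh+(beh|subject)+(1|item)"))
        np.testing.assert_allclose(
            fit.beta, [-0.02275166253, 0.09012130785], rtol=1e-6
        )
        np.testing.assert_allclose(fit.se, [0.2731682266, 0.5455638033], rtol=1e-4)
        np.testing.assert_allclose(fit.t, [-0.08328809983, 0.16518930931], rtol=1e-4)
        assert abs(fit.sigma2 - 0.7570761885) < 1e-5
        assert abs(fit.reml_criterion - 169.594778397) < 1e-6
        assert abs(fit.vcomp["item"][0, 0] - 0.617053886495) < 1e-4

    def test_parameter_recovery_over_simulations(self):
        # mean of the fixed-effect estimate over replicates approaches the
        # generative contrast (sign per the -0.5/+0.5 coding of A/B)
        slopes = []
        for seed in range(60):
            design, y = crossed_dataset(seed=seed, ns=6, ni=10, slope=0.8)
            fit = fit_lmer(y, design, parse_formula("y~beh+(beh|subject)+(1|item)"))
            slopes.append(fit.beta[1])
        mean = np.mean(slopes)
        mc_se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(mean - 0.8) < 3.5 * mc_se


class TestInvariances:
    def test_t_invariant_to_affine_rescaling_of_response(self):
        design, y = crossed_dataset(seed=3)
        f = parse_formula("y~beh+(beh|subject)+(1|item)")
        t1 = fit_lmer(y, design, f).t
        t2 = fit_lmer(5.0 * y + 11.0, design, f).t
        np.testing.assert_allclose(t1[1:], t2[1:], rtol=1e-4)

    def test_crossed_factors_fit_without_aliasing(self):
        design, y = crossed_dataset(seed=9)
        fit = fit_lmer(y, design, parse_formula("y~beh+(1|subject)+(1|item)"))
        assert fit.status == "converged"
        # each item appears under every subject (fully crossed)
        counts = design.groupby(["subject", "item"]).size()
        assert (counts == 1).all()

    def test_singular_fixed_design_rejected(self):
        design, y = crossed_dataset()
        design["beh2"] = design["beh"]
        with pytest.raises(ValueError, match="singular"):
            fit_lmer(y, design, parse_formula("y~beh+beh2+(1|subject)"))


class TestFitComponents:
    def test_component_matrix_shape_and_order(self):
        design, y = crossed_dataset(seed=5)
        rng = np.random.default_rng(0)
        Y_w = np.column_stack([y, rng.standard_normal(len(y)), y])
        out = fit_components(Y_w, design, parse_formula("y~beh+(1|item)"))
        assert out.T_s.shape == (3, 1)
        # duplicated column gives identical rows (deterministic fits)
        np.testing.assert_allclose(out.T_s[0], out.T_s[2], rtol=1e-6)

    def test_null_noise_components_have_small_t(self):
        design, _ = crossed_dataset(seed=1)
        rng = np.random.default_rng(123)
        Y_w = rng.standard_normal((len(design), 8))
        out = fit_components(Y_w, design, parse_formula("y~beh+(1|subject)"))
        assert np.abs(out.T_s).max() < 4.0
        assert abs(np.mean(out.T_s)) < 1.0

    def test_two_fixed_terms_give_two_columns(self):
        design, y = crossed_dataset(seed=2)
        rng = np.random.default_rng(4)
        design["cont"] = rng.standard_normal(len(design))
        out = fit_components(
            y[:, None], design, parse_formula("y~beh+cont+(1|subject)")
        )
        assert out.T_s.shape == (1, 2)
        assert out.term_names == ["beh", "cont"]

    def test_non_finite_scores_rejected(self):
        design, y = crossed_dataset()
        bad = np.full((len(y), 1), np.nan)
        with pytest.raises(ValueError):
            fit_components(bad, design, parse_formula("y~beh+(1|subject)"))
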