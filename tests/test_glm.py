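"""IRLS logistic regression, joint Wald tests, chi-square tails, LRT screening."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from varzea import (
    DEFINITIONS,
    LogisticFit,
    ValidationError,
    chi_square_upper_tail,
    encode_design,
    fit_logistic_irls,
    interaction_check,
    predict_probability_grid,
    wald_factor_test,
    with_interaction,
)
from varzea.rarity import StatusAssignment
from varzea.simulate import simulate_status_table


def make_fit(params: dict, cov: np.ndarray, converged=True) -> LogisticFit:
    names = list(params)
    return LogisticFit(
        params=pd.Series(params),
        cov=pd.DataFrame(cov, index=names, columns=names),
        loglik=0.0,
        n_iter=1,
        converged=converged,
        separation_flag=False,
        n_obs=10,
    )


# --------------------------------------------------------------------------
# design encoding
# --------------------------------------------------------------------------

def _toy_assignment(statuses):
    ids = pd.Index([f"s{i}" for i in range(len(statuses))], name="species")
    return StatusAssignment(definition=DEFINITIONS["i"], status=pd.Series(statuses, index=ids))


def test_encode_design_dummy_coding():
    asg = _toy_assignment(["rare_locally", "rare_throughout", "rare_locally"])
    traits = pd.DataFrame({"mean_wet_weight_g": [10.0, 1.0, 100.0]}, index=asg.status.index)
    profiles = pd.DataFrame(
        {"n_lakes": [1, 1, 1], "n_seasons": [2, 1, 4]}, index=asg.status.index
    )
    design = encode_design(asg, traits, profiles, factor="seasons")
    # log10 of 10 g is exactly 1.0
    assert design.X.at["s0", "log10_weight"] == 1.0
    assert list(design.X.columns) == ["intercept", "log10_weight", "seasons[2]", "seasons[4]"]
    assert design.X.at["s0", "seasons[2]"] == 1.0 and design.X.at["s0", "seasons[4]"] == 0.0
    assert design.X.loc["s1", ["seasons[2]", "seasons[4]"]].tolist() == [0.0, 0.0]
    assert design.y.tolist() == [0.0, 1.0, 0.0]
    assert design.reference_level == 1


def test_encode_design_four_levels_three_dummies():
    n = 8
    ids = pd.Index([f"s{i}" for i in range(n)], name="species")
    asg = StatusAssignment(
        definition=DEFINITIONS["i"],
        status=pd.Series(["rare_locally", "rare_throughout"] * 4, index=ids),
    )
    traits = pd.DataFrame({"mean_wet_weight_g": np.ones(n)}, index=ids)
    profiles = pd.DataFrame({"n_lakes": [1, 2, 3, 4, 1, 2, 3, 4], "n_seasons": 1}, index=ids)
    design = encode_design(asg, traits, profiles, factor="lakes")
    assert design.dummy_names == ("lakes[2]", "lakes[3]", "lakes[4]")


def test_encode_design_errors():
    asg = _toy_assignment(["rare_locally", "rare_locally"])
    traits = pd.DataFrame({"mean_wet_weight_g": [1.0, 1.0]}, index=asg.status.index)
    profiles = pd.DataFrame({"n_lakes": [1, 2], "n_seasons": [1, 1]}, index=asg.status.index)
    with pytest.raises(ValidationError, match="constant"):
        encode_design(asg, traits, profiles, factor="lakes")
    asg2 = _toy_assignment(["rare_locally", "rare_throughout"])
    bad_prof = pd.DataFrame({"n_lakes": [1, 9], "n_seasons": [1, 1]}, index=asg2.status.index)
    with pytest.raises(ValidationError, match="outside 1..5"):
        encode_design(asg2, traits, bad_prof, factor="lakes")


# --------------------------------------------------------------------------
# IRLS
# --------------------------------------------------------------------------

def test_intercept_only_logit_of_observed_proportion():
    X = pd.DataFrame({"intercept": np.ones(10)})
    y = pd.Series([1] * 5 + [0] * 5, dtype=float)
    fit = fit_logistic_irls(X, y)
    assert fit.converged
    assert fit.params["intercept"] == pytest.approx(0.0, abs=1e-10)


def test_two_by_two_table_closed_form():
    """Saturated 2x2 logit: coefficients and SE have closed forms."""
    x = np.repeat([0.0, 1.0], 10)
    y = np.concatenate([np.repeat([1.0, 0.0], [2, 8]), np.repeat([1.0, 0.0], [8, 2])])
    X = pd.DataFrame({"intercept": np.ones(20), "x": x})
    fit = fit_logistic_irls(X, pd.Series(y))
    assert fit.converged
    assert fit.params["intercept"] == pytest.approx(np.log(0.25), abs=1e-6)
    assert fit.params["x"] == pytest.approx(np.log(16.0), abs=1e-6)
    # SE of the log odds ratio: sqrt(1/2 + 1/8 + 1/8 + 1/2)
    assert fit.bse["x"] == pytest.approx(np.sqrt(1.25), abs=1e-6)


def test_irls_matches_statsmodels(rng):
    sm = pytest.importorskip("statsmodels.api")
    n = 300
    X = pd.DataFrame(
        {
            "intercept": np.ones(n),
            "x1": rng.normal(size=n),
            "x2": rng.binomial(1, 0.4, size=n).astype(float),
        }
    )
    eta = 0.3 - 0.8 * X["x1"] + 1.1 * X["x2"]
    y = pd.Series((rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float))
    ours = fit_logistic_irls(X, y)
    theirs = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    np.testing.assert_allclose(ours.params, theirs.params, atol=1e-6)
    np.testing.assert_allclose(ours.bse, theirs.bse, atol=1e-6)
    assert ours.loglik == pytest.approx(theirs.llf, abs=1e-6)


def test_score_norm_small_at_optimum(rng):
    n = 200
    X = pd.DataFrame({"intercept": np.ones(n), "x": rng.normal(size=n)})
    y = pd.Series(rng.binomial(1, 0.3, n).astype(float))
    fit = fit_logistic_irls(X, y)
    mu = 1 / (1 + np.exp(-(X.to_numpy() @ fit.params.to_numpy())))
    score = X.to_numpy().T @ (y.to_numpy() - mu)
    assert np.max(np.abs(score)) < 1e-6


def test_perfect_separation_flagged():
    x = np.concatenate([np.linspace(-3, -1, 10), np.linspace(1, 3, 10)])
    y = pd.Series((x > 0).astype(float))
    X = pd.DataFrame({"intercept": np.ones(20), "x": x})
    fit = fit_logistic_irls(X, y)
    assert fit.separation_flag
    assert not fit.converged


def test_rank_deficient_design_rejected():
    X = pd.DataFrame({"a": np.ones(10), "b": np.ones(10)})
    with pytest.raises(ValidationError, match="rank"):
        fit_logistic_irls(X, pd.Series([0, 1] * 5, dtype=float))


# --------------------------------------------------------------------------
# Wald and chi-square tails
# --------------------------------------------------------------------------

def test_wald_single_coefficient_cases():
    fit = make_fit({"b": 0.0}, np.array([[1.0]]))
    res = wald_factor_test(fit, ["b"])
    assert res.statistic == 0.0 and res.p == 1.0
    fit = make_fit({"b": 2.0}, np.array([[1.0]]))
    res = wald_factor_test(fit, ["b"])
    assert res.statistic == pytest.approx(4.0)
    # equals the squared z-test: p = 2 * normal upper tail at |z| = 2
    assert res.p == pytest.approx(2 * stats.norm.sf(2.0), abs=1e-10)


def test_wald_equals_squared_z_over_se(rng):
    for _ in range(5):
        b = rng.normal()
        v = rng.uniform(0.1, 2.0)
        fit = make_fit({"b": b}, np.array([[v]]))
        res = wald_factor_test(fit, ["b"])
        assert res.statistic == pytest.approx((b / np.sqrt(v)) ** 2, abs=1e-10)


def test_wald_block_closed_form_df2():
    fit = make_fit({"a": 1.0, "b": 1.0}, np.eye(2))
    res = wald_factor_test(fit, ["a", "b"])
    assert res.statistic == pytest.approx(2.0)
    assert res.df == 2
    assert res.p == pytest.approx(np.exp(-1.0), abs=1e-12)


def test_wald_singular_block_errors():
    fit = make_fit({"a": 1.0, "b": 1.0}, np.ones((2, 2)))
    with pytest.raises(ValidationError, match="singular"):
        wald_factor_test(fit, ["a", "b"])


def test_chi_square_upper_tail_values_and_errors():
    assert chi_square_upper_tail(0.0, 7) == pytest.approx(1.0)
    assert chi_square_upper_tail(2.0, 2) == pytest.approx(np.exp(-1.0), abs=1e-12)
    # the printed-table convention: chi2 = 12.3 on 4 df gives p = 0.015
    assert round(chi_square_upper_tail(12.3, 4), 3) == 0.015
    with pytest.raises(ValueError):
        chi_square_upper_tail(-1.0, 2)
    with pytest.raises(ValueError):
        chi_square_upper_tail(1.0, 0)


def test_chi_square_tail_matches_quadrature():
    for df in (1, 3, 4, 5):
        for x in (0.5, 2.0, 7.3, 15.0):
            num, _ = integrate.quad(lambda t: stats.chi2.pdf(t, df), x, x + 300.0, limit=200)
            assert chi_square_upper_tail(x, df) == pytest.approx(num, abs=1e-8)


# --------------------------------------------------------------------------
# prediction surfaces and interaction screen
# --------------------------------------------------------------------------

def _fitted_design(n=300, seed=1):
    asg, traits, profiles = simulate_status_table(n=n, seed=seed)
    design = encode_design(asg, traits, profiles, factor="seasons")
    return design, fit_logistic_irls(design.X, design.y)


def test_predict_grid_pointwise_oracle():
    design, fit = _fitted_design()
    grid = predict_probability_grid(fit, design, weights_log10=[-1.0, 0.0, 1.0])
    for row in grid.itertuples():
        eta = fit.params["intercept"] + fit.params["log10_weight"] * row.log10_weight
        name = f"seasons[{row.level}]"
        if name in fit.params.index:
            eta += fit.params[name]
        assert row.probability == pytest.approx(1 / (1 + np.exp(-eta)), abs=1e-12)
        assert 0.0 < row.probability < 1.0


def test_predict_grid_zero_coefficients_give_half():
    design, fit = _fitted_design()
    flat = LogisticFit(
        params=fit.params * 0.0,
        cov=fit.cov,
        loglik=0.0,
        n_iter=1,
        converged=True,
        separation_flag=False,
        n_obs=fit.n_obs,
    )
    grid = predict_probability_grid(flat, design, weights_log10=[-2.0, 0.0, 2.0])
    assert (grid["probability"] == 0.5).all()


def test_predict_grid_monotone_in_weight():
    design, fit = _fitted_design()
    sign = np.sign(fit.params["log10_weight"])
    grid = predict_probability_grid(fit, design, weights_log10=np.linspace(-1, 1, 9), levels=[1])
    diffs = np.diff(grid["probability"])
    assert (np.sign(diffs) == sign).all()


def test_interaction_identical_designs_is_null():
    design, _ = _fitted_design()
    res = interaction_check(design.X, design.X.copy(), design.y)
    assert res.statistic == 0.0 and res.p == 1.0 and res.df == 0


def test_interaction_non_nested_rejected():
    design, _ = _fitted_design()
    X_other = design.X.drop(columns=["log10_weight"]).assign(z=1.0)
    with pytest.raises(ValueError, match="nested"):
        interaction_check(design.X, X_other, design.y)


def test_interaction_type_one_error_rate():
    """With no interaction in truth, the LRT rejects at roughly its nominal 5%."""
    rejections = 0
    used = 0
    for rep in range(200):
        asg, traits, profiles = simulate_status_table(n=500, seed=10_000 + rep)
        design = encode_design(asg, traits, profiles, factor="seasons")
        res = interaction_check(design.X, with_interaction(design), design.y)
        if not res.converged:
            continue
        used += 1
        rejections += res.p < 0.05
    assert used > 150
    rate = rejections / used
    assert 0.015 <= rate <= 0.10, rate


def test_interaction_statistic_grows_with_n_under_true_interaction():
    coefs = dict(
        intercept=0.4, log10_weight=-0.8, **{"seasons[2]": -0.6, "seasons[3]": -1.1, "seasons[4]": -1.6}
    )

    def stat_at(n, seed):
        asg, traits, profiles = simulate_status_table(n=n, coefs=coefs, seed=seed)
        design = encode_design(asg, traits, profiles, factor="seasons")
        X_full = with_interaction(design)
        # inject a strong interaction by flipping responses where weight and
        # level are jointly large
        eta = X_full.to_numpy() @ np.concatenate([list(coefs.values()), [1.5, 1.5, 1.5]])
        y = pd.Series(
            (np.random.default_rng(seed).random(n) < 1 / (1 + np.exp(-eta))).astype(float),
            index=design.y.index,
        )
        return interaction_check(design.X, X_full, y).statistic

    small = np.mean([stat_at(300, s) for s in range(3)])
    large = np.mean([stat_at(3000, s) for s in range(3)])
    assert large > small
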