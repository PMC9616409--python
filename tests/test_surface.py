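import numpy as np
import pandas as pd
import pytest

from fermopt import (ExperimentTable, ModelSpec, ResponseSurfaceRegressor,
                     adjusted_r2, anova, build_model_matrix, fit_least_squares,
                     generate_central_composite, generate_plackett_burman,
                     predicted_r2_constant_leverage, screen_effects)
from fermopt.datasets import (load_pbd_screen, published_quadratic_coefficients,
                              published_screen_coefficients)
from fermopt.errors import InsufficientRunsError, SingularDesignError

QUAD_TERMS = ModelSpec.quadratic(4)


def _published_surface(coeffs: dict, names) -> ResponseSurfaceRegressor:
    spec = ModelSpec.quadratic(len(names)) if len(coeffs) > len(names) + 1 \
        else ModelSpec.first_order(len(names))
    ordered = [coeffs[t] for t in spec.term_names(names)]
    return ResponseSurfaceRegressor.from_coefficients(spec, ordered, names)


# ---------------------------------------------------------------------------
# model matrix
# ---------------------------------------------------------------------------

def test_model_matrix_shapes_and_columns():
    d = generate_plackett_burman(4, 12)
    M1 = build_model_matrix(d, ModelSpec.first_order(4))
    assert M1.shape == (12, 5)
    assert (M1.iloc[:, 0] == 1).all()
    M2 = build_model_matrix(generate_central_composite(4, 2.0, 6), QUAD_TERMS)
    assert M2.shape == (30, 15)  # 1 + 4 linear + 6 interaction + 4 quadratic
    # quadratic column equals 1 on the +/-1 factorial block
    assert (M2.iloc[:16, 11:] == 1).all().all()
    # interaction column is the elementwise product
    X = generate_central_composite(4, 2.0, 6).to_array()
    assert np.allclose(M2["X1:X2"], X[:, 0] * X[:, 1])


def test_model_matrix_out_of_range_index():
    d = generate_plackett_burman(3, 12)
    with pytest.raises(IndexError):
        build_model_matrix(d, ModelSpec.quadratic(5))


def test_model_spec_validation():
    with pytest.raises(ValueError):
        ModelSpec((("intercept",), ("linear", 0), ("linear", 0)))
    with pytest.raises(ValueError):
        ModelSpec((("linear", 0),))
    with pytest.raises(ValueError):
        ModelSpec((("intercept",), ("interaction", 1, 0)))


# ---------------------------------------------------------------------------
# least-squares fit on the published response-surface experiment
# ---------------------------------------------------------------------------

def test_quadratic_fit_recovers_published_equation(rsm_fit, published_quadratic):
    """OLS on the 30-run experiment reproduces every published coefficient
    of the quadratic yield model to the printed 2-decimal precision."""
    for term, published in published_quadratic.items():
        assert rsm_fit.coefficients_[term] == pytest.approx(published, abs=0.01), term


def test_quadratic_fit_r2_family(rsm_fit):
    assert rsm_fit.r2_ == pytest.approx(0.9270, abs=1e-4)
    assert rsm_fit.r2_adjusted_ == pytest.approx(0.8588, abs=1e-4)
    assert rsm_fit.r2_predicted_ == pytest.approx(0.6600, abs=1e-3)


def test_fitted_surface_invariants(rsm_fit):
    """Residuals orthogonal to every model column; leverages sum to p and
    lie in (0,1); PRESS >= SSE hence predicted R^2 <= R^2."""
    M = build_model_matrix(rsm_fit._X, rsm_fit.spec_).to_numpy()
    scale = np.abs(rsm_fit._y).max()
    assert np.abs(M.T @ rsm_fit.residuals_).max() <= 1e-6 * scale
    assert rsm_fit.leverages_.sum() == pytest.approx(rsm_fit.p_)
    assert ((rsm_fit.leverages_ > 0) & (rsm_fit.leverages_ < 1)).all()
    assert rsm_fit.press_ >= rsm_fit.sse_
    assert rsm_fit.r2_predicted_ <= rsm_fit.r2_
    assert rsm_fit.r2_adjusted_ <= rsm_fit.r2_


def test_prediction_matches_published_columns(rsm_data, rsm_fit, pbd_printed):
    """The fitted quadratic reproduces all 30 published predicted yields to
    +/-0.02; the published first-order screening equation reproduces the
    12 published screen predictions to +/-0.01."""
    _, predicted = rsm_data
    assert np.abs(rsm_fit.fitted_ - predicted.to_numpy()).max() < 0.02
    assert rsm_fit.predict(np.array([-2.0, 0, 0, 0])) == pytest.approx(239.28, abs=0.01)

    screen_tab, screen_pred = pbd_printed
    names = screen_tab.design.factor_names
    coeffs = published_screen_coefficients()
    surf = _published_surface(
        {**{n: 0.0 for n in names}, **coeffs},
        names)
    pred = surf.predict(screen_tab.design.to_array())
    assert np.abs(pred - screen_pred.to_numpy()).max() <= 0.01 + 1e-9
    assert pred[0] == pytest.approx(407.92, abs=0.01)
    assert pred[7] == pytest.approx(24.93, abs=0.01)


def test_predict_at_origin_is_intercept(rsm_fit):
    assert rsm_fit.predict(np.zeros(4)) == pytest.approx(rsm_fit.intercept_)
    with pytest.raises(ValueError):
        rsm_fit.predict(np.zeros(3))


def test_noiseless_interpolation_recovers_truth(rng):
    """A response generated exactly from the model span is recovered to 1e-8."""
    design = generate_central_composite(4, 2.0, 6)
    truth = rng.normal(0, 50, size=15)
    y = build_model_matrix(design, QUAD_TERMS).to_numpy() @ truth
    fit = ResponseSurfaceRegressor(terms=QUAD_TERMS).fit(design, y)
    assert np.abs(fit.params_ - truth).max() <= 1e-8


def test_orthogonal_contrast_oracle(pbd_reconciled):
    """On an orthogonal two-level design each linear coefficient equals
    sum(column * response) / sum(column^2) -- checked against the solver."""
    table, _ = pbd_reconciled
    X, y = table.design.to_array(), table.response.to_numpy()
    fit = fit_least_squares(table, "first-order")
    oracle = X.T @ y / (X ** 2).sum(axis=0)
    assert np.allclose(fit.coef_, oracle, atol=1e-10)
    assert fit.intercept_ == pytest.approx(y.mean())


def test_press_equals_brute_force_loo(rsm_data):
    """PRESS from leverages equals explicit leave-one-out refitting."""
    table, _ = rsm_data
    fit = fit_least_squares(table, "quadratic")
    M = build_model_matrix(table.design, QUAD_TERMS).to_numpy()
    y = table.response.to_numpy()
    press = 0.0
    for i in range(len(y)):
        keep = np.arange(len(y)) != i
        beta, *_ = np.linalg.lstsq(M[keep], y[keep], rcond=None)
        press += (y[i] - M[i] @ beta) ** 2
    assert fit.press_ == pytest.approx(press, rel=1e-6)


def test_errors_rank_deficiency_and_capacity():
    d = generate_plackett_burman(2, 12)
    X = np.column_stack([d.to_array(), d.to_array()[:, 0]])  # duplicated factor
    with pytest.raises(SingularDesignError) as err:
        ResponseSurfaceRegressor(model="first-order").fit(X, np.arange(12.0))
    assert err.value.collinear_terms  # names the collinear columns
    with pytest.raises(InsufficientRunsError):
        ResponseSurfaceRegressor(model="quadratic").fit(np.eye(3), np.arange(3.0))


# ---------------------------------------------------------------------------
# R^2 helpers
# ---------------------------------------------------------------------------

def test_r2_helpers_published_values():
    """From the published screen R^2 = 0.9778 with n=12, p=5: adjusted
    0.9651 and constant-leverage predicted 0.9347."""
    assert adjusted_r2(0.9778, 12, 5) == pytest.approx(0.9651, abs=1e-4)
    assert predicted_r2_constant_leverage(0.9778, 12, 5) == pytest.approx(0.9347, abs=1e-4)
    assert adjusted_r2(1.0, 20, 6) == 1.0
    with pytest.raises(ValueError):
        adjusted_r2(0.9, 5, 5)
    with pytest.raises(ValueError):
        predicted_r2_constant_leverage(1.2, 12, 5)


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

def test_anova_whole_model_significant(rsm_fit):
    table = anova(rsm_fit)
    assert table.loc["Model", "p_value"] < 1e-4
    assert table.loc["Model", "df"] == 14


def test_anova_zero_coefficient_term_has_zero_f(rng):
    d = generate_plackett_burman(4, 12)
    X = d.to_array()
    # noise projected onto the orthocomplement of the model span, so the
    # X2..X4 coefficients are exactly zero while the residual MS is not
    M = np.column_stack([np.ones(12), X])
    v = rng.normal(size=12)
    e = v - M @ np.linalg.lstsq(M, v, rcond=None)[0]
    y = 3.0 * X[:, 0] + 10.0 + e
    fit = ResponseSurfaceRegressor(model="first-order").fit(X, y)
    tab = anova(fit)
    zero_terms = [t for t, c in fit.coefficients_.items()
                  if t != "Intercept" and abs(c) < 1e-10]
    assert zero_terms
    for t in zero_terms:
        assert tab.loc[t, "F"] == pytest.approx(0.0, abs=1e-18)
        assert tab.loc[t, "p_value"] == pytest.approx(1.0)


def test_anova_requires_residual_df(pbd_reconciled):
    table, _ = pbd_reconciled
    saturated = fit_least_squares(table, "first-order")  # 12 params, 12 runs
    with pytest.raises(InsufficientRunsError):
        anova(saturated)


# ---------------------------------------------------------------------------
# effect screening
# ---------------------------------------------------------------------------

def test_screen_recovers_published_significant_factors(pbd_reconciled):
    """Backward elimination at alpha=0.05 retains exactly the four factors
    of the published screening equation."""
    table, _ = pbd_reconciled
    fit = fit_least_squares(table, "first-order")
    eff = screen_effects(fit, 0.05)
    assert set(eff.index[eff["keep"]]) == {"peptone", "temperature",
                                           "agitation", "inoculum_size"}
    # ranked by |coefficient|, temperature (largest effect) first and negative
    assert eff.index[0] == "temperature"
    assert eff.loc["temperature", "sign"] == -1
    assert eff.loc["peptone", "sign"] == 1


def test_screen_matches_best_subset_oracle(pbd_reconciled):
    """Independent oracle: exhaustive SSE comparison of all 4-factor
    submodels picks the same set the screen retains."""
    from itertools import combinations
    table, _ = pbd_reconciled
    X, y = table.design.to_array(), table.response.to_numpy()
    names = table.design.factor_names
    best = min(
        combinations(range(11), 4),
        key=lambda idx: np.linalg.lstsq(
            np.column_stack([np.ones(12)] + [X[:, i] for i in idx]),
            y, rcond=None)[1][0])
    assert {names[i] for i in best} == {"peptone", "temperature",
                                        "agitation", "inoculum_size"}


def test_screen_drops_uncorrelated_factor():
    d = generate_plackett_burman(5, 12)
    X = d.to_array()
    y = 20.0 + 8.0 * X[:, 0] - 5.0 * X[:, 1]  # X3..X5 carry nothing
    fit = ResponseSurfaceRegressor(model="first-order").fit(X, y)
    eff = screen_effects(fit, 0.05)
    assert set(eff.index[eff["keep"]]) == {"X1", "X2"}


def test_screen_all_zero_response_retains_nothing():
    d = generate_plackett_burman(5, 12)
    fit = ResponseSurfaceRegressor(model="first-order").fit(d.to_array(), np.zeros(12))
    eff = screen_effects(fit, 0.05)
    assert not eff["keep"].any()


def test_screen_rejects_quadratic_model(rsm_fit):
    with pytest.raises(ValueError):
        screen_effects(rsm_fit, 0.05)


# ---------------------------------------------------------------------------
# documented irreproducibility of the published screen observations
# ---------------------------------------------------------------------------

def test_printed_screen_data_inconsistent_with_published_fit(pbd_printed,
                                                             pbd_reconciled):
    """Finding: no least-squares fit of the observations as published can
    yield the published screening equation -- the orthogonal-contrast
    intercept is the response mean, 194.95, not the published 186.62.
    Reconciling run 12 (158.900 -> 58.952) restores the published
    coefficients and the full R^2 family."""
    printed, _ = pbd_printed
    assert printed.response.mean() == pytest.approx(194.949, abs=1e-3)
    assert abs(printed.response.mean() - 186.62) > 5

    rec, _ = pbd_reconciled
    fit = fit_least_squares(
        rec, ModelSpec((("intercept",), ("linear", 0), ("linear", 7),
                        ("linear", 8), ("linear", 9))))
    assert fit.intercept_ == pytest.approx(186.62, abs=0.01)
    assert fit.coefficients_["peptone"] == pytest.approx(29.81, abs=0.01)
    assert fit.coefficients_["temperature"] == pytest.approx(-85.54, abs=0.01)
    assert fit.coefficients_["agitation"] == pytest.approx(68.92, abs=0.01)
    assert fit.coefficients_["inoculum_size"] == pytest.approx(37.03, abs=0.01)
    assert fit.r2_ == pytest.approx(0.9778, abs=1e-4)
    assert fit.r2_adjusted_ == pytest.approx(0.9651, abs=1e-4)
    assert fit.r2_predicted_ == pytest.approx(0.9347, abs=1e-4)
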