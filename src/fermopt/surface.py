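"""Least-squares response-surface models on coded designs.

The workhorse is :class:`ResponseSurfaceRegressor`, a scikit-learn style
estimator fitting either a first-order model (intercept + one linear term
per factor, the screening model) or a full quadratic model (adds all
pairwise interactions and pure quadratic terms, the response-surface
model) by ordinary least squares on coded factor levels.

Diagnostics follow standard regression theory.  With model matrix X
(n runs x p terms), hat matrix H = X (X'X)^-1 X' and leverages h_i = H_ii:

* R^2            = 1 - SSE/SST
* adjusted R^2   = 1 - (1 - R^2) (n - 1)/(n - p)
* PRESS          = sum_i (e_i / (1 - h_i))^2   (leave-one-out identity)
* predicted R^2  = 1 - PRESS/SST

On an orthogonal two-level design every leverage equals p/n, which
collapses predicted R^2 to the closed form implemented by
:func:`predicted_r2_constant_leverage`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .designs import DesignMatrix
from .errors import InsufficientRunsError, SingularDesignError

__all__ = [
    "Term",
    "ModelSpec",
    "ExperimentTable",
    "ResponseSurfaceRegressor",
    "build_model_matrix",
    "fit_least_squares",
    "predict",
    "adjusted_r2",
    "predicted_r2_constant_leverage",
    "anova",
    "screen_effects",
]

# A model term: ("intercept",) | ("linear", i) | ("interaction", i, j) | ("quadratic", i)
Term = tuple


def _term_name(term: Term, names: Sequence[str]) -> str:
    kind = term[0]
    if kind == "intercept":
        return "Intercept"
    if kind == "linear":
        return names[term[1]]
    if kind == "interaction":
        return f"{names[term[1]]}:{names[term[2]]}"
    if kind == "quadratic":
        return f"{names[term[1]]}^2"
    raise ValueError(f"unknown term kind {kind!r}")


@dataclass(frozen=True)
class ModelSpec:
    """Ordered list of polynomial terms over K coded factors."""

    terms: tuple[Term, ...]

    def __post_init__(self) -> None:
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("duplicate terms in model spec")
        if sum(1 for t in self.terms if t[0] == "intercept") != 1:
            raise ValueError("model spec must contain the intercept exactly once")
        for t in self.terms:
            if t[0] == "interaction" and not t[1] < t[2]:
                raise ValueError(f"interaction indices must satisfy i < j: {t}")

    @classmethod
    def first_order(cls, k: int) -> "ModelSpec":
        return cls((("intercept",),) + tuple(("linear", i) for i in range(k)))

    @classmethod
    def quadratic(cls, k: int) -> "ModelSpec":
        terms: list[Term] = [("intercept",)]
        terms += [("linear", i) for i in range(k)]
        terms += [("interaction", i, j) for i in range(k) for j in range(i + 1, k)]
        terms += [("quadratic", i) for i in range(k)]
        return cls(tuple(terms))

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def max_factor_index(self) -> int:
        idx = [-1]
        for t in self.terms:
            idx.extend(t[1:])
        return max(idx)

    def term_names(self, factor_names: Sequence[str]) -> list[str]:
        return [_term_name(t, factor_names) for t in self.terms]


@dataclass
class ExperimentTable:
    """A coded design joined with its observed response (one value per run)."""

    design: DesignMatrix
    response: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        y = np.asarray(self.response, dtype=float)
        if len(y) != self.design.n_runs:
            raise ValueError("response length must equal the number of runs")
        if not np.isfinite(y).all():
            raise ValueError("responses must be finite")
        if (y < 0).any():
            raise ValueError("responses are concentrations and must be >= 0")
        self.response = pd.Series(y, index=self.design.rows.index, name="response")

    def to_frame(self) -> pd.DataFrame:
        df = self.design.rows.copy()
        df["response"] = self.response
        return df


def _coded_array(design, spec: ModelSpec) -> np.ndarray:
    X = design.to_array() if isinstance(design, DesignMatrix) else np.asarray(design, float)
    if X.ndim == 1:
        X = X[None, :]
    if spec.max_factor_index() >= X.shape[1]:
        raise IndexError(
            f"model spec references factor index {spec.max_factor_index()} "
            f"but the design has only {X.shape[1]} factors")
    return X


def build_model_matrix(design, spec: ModelSpec) -> pd.DataFrame:
    """Expand coded factor levels into the runs x terms regression matrix."""
    X = _coded_array(design, spec)
    n = X.shape[0]
    cols = {}
    names = (design.factor_names if isinstance(design, DesignMatrix)
             else [f"X{i + 1}" for i in range(X.shape[1])])
    for term in spec.terms:
        kind = term[0]
        if kind == "intercept":
            col = np.ones(n)
        elif kind == "linear":
            col = X[:, term[1]]
        elif kind == "interaction":
            col = X[:, term[1]] * X[:, term[2]]
        else:
            col = X[:, term[1]] ** 2
        cols[_term_name(term, names)] = col
    return pd.DataFrame(cols)


class ResponseSurfaceRegressor(RegressorMixin, BaseEstimator):
    """Ordinary least-squares polynomial response surface on coded factors.

    Parameters
    ----------
    model : {"quadratic", "first-order"}, default "quadratic"
        Which canonical term set to use; ignored when *terms* is given.
    terms : ModelSpec or None
        Explicit term list overriding *model*.
    rank_rtol : float
        Relative singular-value tolerance for rank-deficiency detection.

    Attributes (after :meth:`fit`)
    ------------------------------
    spec_ : ModelSpec of the fitted terms.
    coefficients_ : dict mapping term name -> estimate.
    intercept_, coef_ : scikit-learn style views of the same estimates.
    fitted_, residuals_, leverages_ : per-run arrays.
    sse_, sst_, press_, r2_, r2_adjusted_, r2_predicted_ : scalars.
    n_, p_ : runs and parameter count.
    """

    def __init__(self, model: str = "quadratic", terms: ModelSpec | None = None,
                 rank_rtol: float = 1e-10):
        self.model = model
        self.terms = terms
        self.rank_rtol = rank_rtol

    # -- construction helpers -------------------------------------------
    def _resolve_spec(self, k: int) -> ModelSpec:
        if self.terms is not None:
            return self.terms
        if self.model == "quadratic":
            return ModelSpec.quadratic(k)
        if self.model in ("first-order", "first_order", "linear"):
            return ModelSpec.first_order(k)
        raise ValueError(f"unknown model {self.model!r}")

    @classmethod
    def from_coefficients(cls, spec: ModelSpec, coefficients: Iterable[float],
                          factor_names: Sequence[str] | None = None
                          ) -> "ResponseSurfaceRegressor":
        """Build a predict-only surface from known (e.g. published) coefficients."""
        est = cls(terms=spec)
        beta = np.asarray(list(coefficients), dtype=float)
        if len(beta) != spec.n_terms:
            raise ValueError("coefficient count must match the term count")
        k = spec.max_factor_index() + 1
        est.spec_ = spec
        est.params_ = beta
        est.factor_names_ = (list(factor_names) if factor_names
                             else [f"X{i + 1}" for i in range(k)])
        est.n_features_in_ = k
        est.coefficients_ = dict(zip(spec.term_names(est.factor_names_), beta))
        return est

    # -- scikit-learn API -------------------------------------------------
    def fit(self, X, y, factor_names: Sequence[str] | None = None):
        """Fit by least squares; X holds coded levels (n_runs x k), y the response."""
        if isinstance(X, DesignMatrix):
            factor_names = factor_names or X.factor_names
            X = X.to_array()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional (runs x factors)")
        n, k = X.shape
        if len(y) != n:
            raise ValueError("X and y have inconsistent lengths")
        spec = self._resolve_spec(k)
        names = list(factor_names) if factor_names else [f"X{i + 1}" for i in range(k)]
        M = build_model_matrix(X, spec).to_numpy()
        term_names = spec.term_names(names)
        p = M.shape[1]
        if n < p:
            raise InsufficientRunsError(
                f"{p} parameters cannot be estimated from {n} runs")
        sv = np.linalg.svd(M, compute_uv=False)
        if sv[-1] <= self.rank_rtol * sv[0]:
            _, _, vt = np.linalg.svd(M)
            null = np.abs(vt[-1])
            bad = [term_names[i] for i in np.nonzero(null > 0.1 * null.max())[0]]
            raise SingularDesignError(
                f"model matrix is rank deficient; collinear terms: {bad}", bad)

        res = sm.OLS(y, M).fit()
        self.spec_ = spec
        self.factor_names_ = names
        self.n_features_in_ = k
        self.params_ = np.asarray(res.params, dtype=float)
        self.coefficients_ = dict(zip(term_names, self.params_))
        self.fitted_ = np.asarray(res.fittedvalues, dtype=float)
        self.residuals_ = y - self.fitted_
        self.leverages_ = res.get_influence().hat_matrix_diag
        self.n_ = n
        self.p_ = p
        self.sse_ = float(self.residuals_ @ self.residuals_)
        self.sst_ = float(((y - y.mean()) ** 2).sum())
        # PRESS is undefined for a saturated fit (every leverage is 1)
        if n > p and (self.leverages_ < 1.0 - 1e-12).all():
            self.press_ = float(((self.residuals_ / (1.0 - self.leverages_)) ** 2).sum())
        else:
            self.press_ = np.nan
        self.r2_ = 1.0 - self.sse_ / self.sst_ if self.sst_ > 0 else 1.0
        self.r2_adjusted_ = (adjusted_r2(self.r2_, n, p) if n > p else np.nan)
        self.r2_predicted_ = (1.0 - self.press_ / self.sst_
                              if self.sst_ > 0 and np.isfinite(self.press_) else np.nan)
        self._sm_results = res
        self._X = X
        self._y = y
        return self

    @property
    def intercept_(self) -> float:
        check_is_fitted(self, "params_")
        return float(self.params_[self.spec_.terms.index(("intercept",))])

    @property
    def coef_(self) -> np.ndarray:
        check_is_fitted(self, "params_")
        i0 = self.spec_.terms.index(("intercept",))
        return np.delete(self.params_, i0)

    def predict(self, X) -> np.ndarray:
        """Evaluate the polynomial at coded points (n x k, or a single k-vector)."""
        check_is_fitted(self, "params_")
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        if single:
            if len(X) != self.n_features_in_:
                raise ValueError(
                    f"point has {len(X)} coordinates, expected {self.n_features_in_}")
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} factors, expected {self.n_features_in_}")
        M = build_model_matrix(X, self.spec_).to_numpy()
        out = M @ self.params_
        return out[0] if single else out

    # -- reporting ---------------------------------------------------------
    def summary_frame(self) -> pd.DataFrame:
        check_is_fitted(self, "fitted_")
        return pd.DataFrame({
            "observed": self._y,
            "fitted": self.fitted_,
            "residual": self.residuals_,
            "leverage": self.leverages_,
        })


# ---------------------------------------------------------------------------
# module-level wrappers
# ---------------------------------------------------------------------------

def fit_least_squares(table: ExperimentTable, spec: ModelSpec | str = "quadratic"
                      ) -> ResponseSurfaceRegressor:
    """Fit *spec* (a ModelSpec or "quadratic"/"first-order") to an experiment table."""
    if isinstance(spec, str):
        est = ResponseSurfaceRegressor(model=spec)
    else:
        est = ResponseSurfaceRegressor(terms=spec)
    return est.fit(table.design, table.response.to_numpy())


def predict(model: ResponseSurfaceRegressor, coded_point) -> float | np.ndarray:
    """Predicted response of *model* at a coded point (or points)."""
    return model.predict(coded_point)


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Degrees-of-freedom adjusted R^2: 1 - (1 - R^2)(n - 1)/(n - p)."""
    if n <= p:
        raise ValueError("adjusted R^2 requires n > p")
    if not 0.0 <= r2 <= 1.0:
        raise ValueError("r2 must lie in [0, 1]")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p)


def predicted_r2_constant_leverage(r2: float, n: int, p: int) -> float:
    """Leave-one-out R^2 under equal leverages h_i = p/n.

    On an orthogonal two-level design every leverage equals p/n, so
    PRESS = SSE (n/(n-p))^2 and predicted R^2 = 1 - (1 - R^2)(n/(n-p))^2.
    """
    if n <= p:
        raise ValueError("predicted R^2 requires n > p")
    if not 0.0 <= r2 <= 1.0:
        raise ValueError("r2 must lie in [0, 1]")
    return 1.0 - (1.0 - r2) * (n / (n - p)) ** 2


def anova(model: ResponseSurfaceRegressor) -> pd.DataFrame:
    """Whole-model and per-term F statistics with upper-tail probabilities.

    Per-term rows use partial (drop-one) sums of squares, F = t^2 on one
    degree of freedom; on orthogonal designs this coincides with the
    sequential decomposition.  The returned frame has one row per
    non-intercept term plus a leading "Model" row.
    """
    check_is_fitted(model, "fitted_")
    n, p = model.n_, model.p_
    if n == p:
        raise InsufficientRunsError("saturated model: no residual degrees of freedom")
    mse = model.sse_ / (n - p)
    res = model._sm_results
    names = model.spec_.term_names(model.factor_names_)
    rows = []
    ssr = model.sst_ - model.sse_
    f_model = (ssr / (p - 1)) / mse if p > 1 else np.nan
    rows.append({"term": "Model", "ss": ssr, "df": p - 1, "F": f_model,
                 "p_value": float(stats.f.sf(f_model, p - 1, n - p))})
    for i, term in enumerate(model.spec_.terms):
        if term == ("intercept",):
            continue
        t = float(res.tvalues[i])
        F = t * t
        rows.append({"term": names[i], "ss": F * mse, "df": 1, "F": F,
                     "p_value": float(stats.f.sf(F, 1, n - p))})
    return pd.DataFrame(rows).set_index("term")


def _term_pvalues(X: np.ndarray, y: np.ndarray, idx: list[int]) -> np.ndarray:
    """p-values of the linear terms *idx* in an intercept + linear fit.

    A zero residual mean square (interpolating fit) degenerates the t test;
    terms with numerically nonzero coefficients are then reported as p=0 and
    exact-zero coefficients as p=1.
    """
    M = np.column_stack([np.ones(len(y))] + [X[:, j] for j in idx])
    beta, _, _, _ = np.linalg.lstsq(M, y, rcond=None)
    resid = y - M @ beta
    n, p = M.shape
    df = n - p
    sse = float(resid @ resid)
    scale = max(float(np.abs(y).max()), 1.0)
    if sse <= (1e-10 * scale) ** 2 * n:
        return np.where(np.abs(beta[1:]) > 1e-8 * scale, 0.0, 1.0)
    mse = sse / df
    XtX_inv = np.linalg.inv(M.T @ M)
    se = np.sqrt(mse * np.diag(XtX_inv)[1:])
    tvals = beta[1:] / se
    return 2.0 * stats.t.sf(np.abs(tvals), df)


def screen_effects(model: ResponseSurfaceRegressor, significance_level: float = 0.05,
                   drop: str = "all") -> pd.DataFrame:
    """Rank first-order screening effects and flag which factors to keep.

    Factors are ranked by absolute coefficient.  Selection proceeds by
    backward elimination: a saturated model is first reduced by dropping
    the smallest-magnitude effects until a residual degree of freedom
    exists, then each round refits and drops the non-significant terms
    (every term with p > *significance_level* when ``drop="all"``, the
    single worst when ``drop="one"``) until all retained terms pass.
    """
    check_is_fitted(model, "fitted_")
    if any(t[0] not in ("intercept", "linear") for t in model.spec_.terms):
        raise ValueError("screening requires a first-order model")
    X, y = model._X, model._y
    k = model.n_features_in_
    coefs = {i: model.coefficients_[model.factor_names_[i]] for i in range(k)}
    ranked = sorted(range(k), key=lambda i: -abs(coefs[i]))

    # saturated start: keep the largest effects so that n > p (one residual df)
    max_terms = len(y) - 2
    current = sorted(ranked[:max_terms]) if len(ranked) > max_terms else list(range(k))
    while current:
        pvals = _term_pvalues(X, y, current)
        failing = [(pv, j) for pv, j in zip(pvals, current) if pv > significance_level]
        if not failing:
            break
        if drop == "one":
            current.remove(max(failing)[1])
        else:
            for _, j in failing:
                current.remove(j)
    kept = set(current)
    out = pd.DataFrame({
        "factor": [model.factor_names_[i] for i in ranked],
        "coefficient": [coefs[i] for i in ranked],
        "sign": [int(np.sign(coefs[i])) for i in ranked],
        "rank": np.arange(1, k + 1),
        "keep": [i in kept for i in ranked],
    }).set_index("factor")
    return out
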