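"""Association stage: factor analysis of fitted parameters and covariate regression.

Fitted parameters from both model families enter in transformed
(fitting) space and are standardized.  Factor extraction defaults to
principal-axis factoring with varimax rotation and three retained
factors; method, rotation and factor count are configurable (maximum-
likelihood extraction via scikit-learn is also available).  Factor
scores use the Thurstone regression estimator.

Regression of a target (a parameter or a factor score) on the covariate
is ordinary least squares with an intercept and, optionally, a quadratic
term; the plain Pearson correlation is reported alongside the purely
linear model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "factor_parameters",
    "varimax",
    "regress_covariate",
    "FactorResult",
    "RegressionResult",
    "AssociationResult",
    "associate",
]


def varimax(loadings: np.ndarray, max_iter: int = 100, tol: float = 1e-8) -> np.ndarray:
    """Orthogonal varimax rotation of a loadings matrix."""
    L = loadings.copy()
    n, k = L.shape
    if k < 2:
        return L
    R = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (Lr**3 - (Lr * np.mean(Lr**2, axis=0)))
        )
        R = u @ vt
        var_new = s.sum()
        if var_new < var_old * (1 + tol):
            break
        var_old = var_new
    return L @ R


def _principal_axis(corr: np.ndarray, n_factors: int, max_iter: int = 200, tol: float = 1e-6):
    """Iterated principal-axis factoring on a correlation matrix."""
    k = corr.shape[0]
    # initial communalities: squared multiple correlations
    try:
        inv = np.linalg.inv(corr)
        with np.errstate(divide="ignore"):
            h2 = 1.0 - 1.0 / np.diag(inv)
        h2 = np.where(np.isfinite(h2), h2, 0.995)
    except np.linalg.LinAlgError:
        h2 = np.full(k, 0.5)
    h2 = np.clip(h2, 0.05, 0.995)
    for _ in range(max_iter):
        reduced = corr.copy()
        np.fill_diagonal(reduced, h2)
        w, V = np.linalg.eigh(reduced)
        idx = np.argsort(w)[::-1][:n_factors]
        lam = np.clip(w[idx], 0.0, None)
        loadings = V[:, idx] * np.sqrt(lam)
        h2_new = np.clip(np.sum(loadings**2, axis=1), 0.0, 0.995)
        if np.max(np.abs(h2_new - h2)) < tol:
            h2 = h2_new
            break
        h2 = h2_new
    return loadings


@dataclass
class FactorResult:
    loadings: pd.DataFrame  # parameters x factors
    scores: pd.DataFrame  # subjects x factors
    method: str
    rotation: str | None


def factor_parameters(
    params: pd.DataFrame,
    n_factors: int = 3,
    method: str = "principal_axis",
    rotation: str | None = "varimax",
) -> FactorResult:
    """Factor-analyze a (subjects x parameters) table of transformed estimates."""
    if params.shape[1] < 2:
        raise ValueError("need at least 2 parameters")
    if params.shape[0] <= n_factors:
        raise ValueError("need more subjects than factors")
    X = params.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant parameter column; matrix is singular")
    Z = (X - X.mean(axis=0)) / sd
    corr = np.corrcoef(Z, rowvar=False)
    if method == "principal_axis":
        loadings = _principal_axis(corr, n_factors)
    elif method == "ml":
        from sklearn.decomposition import FactorAnalysis

        fa = FactorAnalysis(n_components=n_factors, rotation=None)
        fa.fit(Z)
        loadings = fa.components_.T
    else:
        raise ValueError(f"unknown extraction method {method!r}")
    if rotation == "varimax":
        loadings = varimax(loadings)
    elif rotation is not None:
        raise ValueError(f"unknown rotation {rotation!r}")
    # orient each factor so its largest loading is positive
    for j in range(loadings.shape[1]):
        if loadings[np.argmax(np.abs(loadings[:, j])), j] < 0:
            loadings[:, j] = -loadings[:, j]
    factor_names = [f"factor{j + 1}" for j in range(n_factors)]
    # Thurstone regression scores: Z R^-1 Lambda
    scores = Z @ np.linalg.solve(corr, loadings)
    return FactorResult(
        loadings=pd.DataFrame(loadings, index=params.columns, columns=factor_names),
        scores=pd.DataFrame(scores, index=params.index, columns=factor_names),
        method=method,
        rotation=rotation,
    )


@dataclass
class RegressionResult:
    target: str
    coefficients: pd.DataFrame  # term, coef, se, t, p  (df = n - p)
    r_squared: float
    pearson_r: float | None = None  # only for the purely linear model
    pearson_p: float | None = None


def regress_covariate(
    target: np.ndarray | pd.Series,
    covariate: np.ndarray | pd.Series,
    include_quadratic: bool = False,
    name: str = "target",
) -> RegressionResult:
    """OLS of a target on the covariate (+ covariate^2), with intercept."""
    y = np.asarray(target, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if y.shape != x.shape:
        raise ValueError("target and covariate must have equal length")
    if y.size < 4:
        raise ValueError("need at least 4 observations")
    cols = {"intercept": np.ones_like(x), "linear": x}
    if include_quadratic:
        cols["quadratic"] = x**2
    X = np.column_stack(list(cols.values()))
    fit = sm.OLS(y, X).fit()
    coef = pd.DataFrame(
        {
            "term": list(cols),
            "coef": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    )
    pearson_r = pearson_p = None
    if not include_quadratic:
        r, p = stats.pearsonr(x, y)
        pearson_r, pearson_p = float(r), float(p)
    return RegressionResult(
        target=name,
        coefficients=coef,
        r_squared=float(fit.rsquared),
        pearson_r=pearson_r,
        pearson_p=pearson_p,
    )


@dataclass
class AssociationResult:
    factors: FactorResult
    regressions: list[RegressionResult] = field(default_factory=list)

    def regression_table(self) -> pd.DataFrame:
        rows = []
        for reg in self.regressions:
            for _, row in reg.coefficients.iterrows():
                rows.append({"target": reg.target, **row.to_dict()})
        return pd.DataFrame(rows)


def associate(
    params: pd.DataFrame,
    covariate: np.ndarray | pd.Series,
    n_factors: int = 3,
    method: str = "principal_axis",
    rotation: str | None = "varimax",
    include_quadratic: bool = True,
    targets: list[str] | None = None,
) -> AssociationResult:
    """Factor the parameter table and regress scores (and any named
    parameter columns) on the covariate."""
    fr = factor_parameters(params, n_factors=n_factors, method=method, rotation=rotation)
    regs = []
    for col in fr.scores.columns:
        regs.append(
            regress_covariate(
                fr.scores[col], covariate, include_quadratic=include_quadratic, name=col
            )
        )
    for col in targets or []:
        regs.append(
            regress_covariate(
                params[col], covariate, include_quadratic=include_quadratic, name=col
            )
        )
    return AssociationResult(factors=fr, regressions=regs)
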