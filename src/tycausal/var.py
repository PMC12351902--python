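"""Equation-by-equation OLS estimation of VAR systems.

Everything downstream — the lag-augmented Wald causality test, lag
selection, and the recursive-residual stability machinery — consumes the
objects defined here.  A VAR(k) with m variables is estimated equation by
equation on the common design matrix [1, y_{t-1}, ..., y_{t-k}] (all
variables at every lag), which for identical regressors coincides with the
system GLS estimate.  Coefficient covariances use the homoskedastic OLS
form s^2 (X'X)^{-1} with s^2 = RSS / (T_eff - n_coef).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import AnnualPanel

__all__ = [
    "VarFit",
    "LagSelection",
    "VarError",
    "build_lag_design",
    "fit_var",
    "select_lag",
    "vif_pair",
    "recursive_residuals",
]


class VarError(ValueError):
    """Estimation failures: rank deficiency, too few observations."""


@dataclass(frozen=True)
class VarFit:
    """An estimated VAR(k): per-equation OLS results on a shared design.

    ``coefs[i]`` stacks equation i's parameters as ``[intercept,
    var1.L1, ..., varm.L1, var1.L2, ...]``; ``cov_params[i]`` is the
    matching ``s^2 (X'X)^{-1}``.
    """

    variables: tuple[str, ...]
    lag_order: int
    nobs: int  # effective sample size (rows of the design)
    coefs: np.ndarray  # (m, n_coef)
    cov_params: np.ndarray  # (m, n_coef, n_coef)
    residuals: np.ndarray  # (m, nobs)
    sigma_u: np.ndarray  # (m, m) residual covariance, df-adjusted
    design: np.ndarray = field(repr=False, compare=False, default=None)
    targets: np.ndarray = field(repr=False, compare=False, default=None)

    @property
    def n_coef(self) -> int:
        return self.coefs.shape[1]

    def coef_index(self, variable: str, lag: int) -> int:
        """Column index of ``variable`` at ``lag`` in the design/coefs."""
        if not 1 <= lag <= self.lag_order:
            raise IndexError(f"lag {lag} outside 1..{self.lag_order}")
        return 1 + (lag - 1) * len(self.variables) + self.variables.index(variable)

    def equation(self, variable: str) -> int:
        return self.variables.index(variable)


@dataclass(frozen=True)
class LagSelection:
    """AIC values over candidate lag orders and the (possibly capped) choice."""

    criterion: str
    values: dict[int, float]
    argmin: int
    chosen: int
    cap: int
    cap_applied: bool


def build_lag_design(Y: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Design and target matrices for a VAR(k) on data ``Y`` (m x n).

    Returns ``(X, Z)`` with X of shape ``(n-k, 1 + k m)`` (intercept first,
    then all variables at lag 1, then lag 2, ...) and Z of shape
    ``(m, n-k)`` holding the left-hand sides.
    """
    m, n = Y.shape
    if n - k < 1:
        raise VarError("too few observations for requested lag order")
    rows = n - k
    X = np.empty((rows, 1 + k * m))
    X[:, 0] = 1.0
    for lag in range(1, k + 1):
        X[:, 1 + (lag - 1) * m : 1 + lag * m] = Y[:, k - lag : n - lag].T
    Z = Y[:, k:]
    return X, Z


def fit_var(panel: AnnualPanel, lag_order: int, include_intercept: bool = True) -> VarFit:
    """Estimate a VAR(``lag_order``) on all panel variables by OLS.

    Raises :class:`VarError` when the effective sample cannot support the
    parameter count or the design is rank deficient.
    """
    if lag_order < 1:
        raise VarError("lag_order must be >= 1")
    Y = panel.values
    m, n = Y.shape
    X, Z = build_lag_design(Y, lag_order)
    if not include_intercept:
        X = X[:, 1:]
    rows, ncoef = X.shape
    if rows < ncoef + 1:
        raise VarError(
            f"too few observations: {rows} rows for {ncoef} parameters per equation"
        )
    gram = X.T @ X
    rank = np.linalg.matrix_rank(gram)
    if rank < ncoef:
        raise VarError("collinear regressors: design matrix is rank deficient")
    gram_inv = np.linalg.inv(gram)
    B = gram_inv @ (X.T @ Z.T)  # (ncoef, m)
    resid = Z - (X @ B).T  # (m, rows)
    dof = rows - ncoef
    s2 = np.einsum("ij,ij->i", resid, resid) / dof
    cov = s2[:, None, None] * gram_inv[None, :, :]
    sigma_u = (resid @ resid.T) / dof
    return VarFit(
        variables=panel.variables,
        lag_order=lag_order,
        nobs=rows,
        coefs=B.T.copy(),
        cov_params=cov,
        residuals=resid,
        sigma_u=sigma_u,
        design=X,
        targets=Z,
    )


def _aic(panel: AnnualPanel, p: int, offset: int) -> float:
    """Gaussian VAR AIC on the common estimation sample.

    ``offset`` drops the first ``offset - p`` extra observations so every
    candidate order is scored on the same rows and criteria are comparable.
    """
    Y = panel.values[:, offset - p :]
    m = Y.shape[0]
    X, Z = build_lag_design(Y, p)
    rows = X.shape[0]
    if rows < X.shape[1] + 1:
        raise VarError("too few observations")
    B, _, rank, _ = np.linalg.lstsq(X, Z.T, rcond=None)
    if rank < X.shape[1]:
        raise VarError("collinear regressors")
    resid = Z.T - X @ B
    sigma = (resid.T @ resid) / rows  # MLE scale for the criterion
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        raise VarError("singular residual covariance")
    n_params = m * X.shape[1]
    return float(logdet + 2.0 * n_params / rows)


def select_lag(
    panel: AnnualPanel, max_p: int, cap: int | None = None, criterion: str = "AIC"
) -> LagSelection:
    """AIC lag-order selection over ``1..max_p`` with an optional hard cap.

    All candidates are scored on the common sample trimmed for ``max_p``
    lags.  When the AIC argmin exceeds ``cap`` the chosen order is ``cap``
    and ``cap_applied`` is set — the small-sample rule used when short
    annual series cannot support the AIC-preferred order.
    """
    if criterion != "AIC":
        raise ValueError("only AIC selection is supported")
    if max_p < 1:
        raise ValueError("max_p must be >= 1")
    values: dict[int, float] = {}
    for p in range(1, max_p + 1):
        try:
            values[p] = _aic(panel, p, offset=max_p)
        except VarError:
            continue  # candidate infeasible on this sample; exclude
    if not values:
        raise VarError("no feasible lag order in 1..max_p")
    argmin = min(values, key=lambda p: (values[p], p))
    cap = max_p if cap is None else cap
    cap_applied = argmin > cap
    return LagSelection(
        criterion="AIC",
        values=values,
        argmin=argmin,
        chosen=cap if cap_applied else argmin,
        cap=cap,
        cap_applied=cap_applied,
    )


def vif_pair(x, y) -> float:
    """Variance inflation factor 1/(1-R^2) between two level series.

    R^2 comes from regressing one series on the other with intercept; for
    two variables this is symmetric (R^2 equals the squared correlation).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("series must have equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate series: constant input")
    r = np.corrcoef(x, y)[0, 1]
    r2 = min(float(r * r), 1.0 - 1e-15)
    return 1.0 / (1.0 - r2)


def recursive_residuals(y, X) -> np.ndarray:
    """Standardized one-step-ahead recursive residuals of ``y`` on ``X``.

    Starting from the first ``rank(X)`` observations, each subsequent
    observation is predicted from the coefficients estimated on all earlier
    ones; the prediction error is scaled by its conditional standard
    deviation sqrt(1 + x' (X'X)^{-1} x), so under a stable correct model the
    output is i.i.d. with mean 0 and the innovation variance (unit variance
    for standard Gaussian errors).  Length is ``n - rank(X)``.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    n, k = X.shape
    if n <= k:
        raise VarError("too few observations for recursive residuals")
    if np.linalg.matrix_rank(X) < k:
        raise VarError("collinear regressors: design matrix is rank deficient")
    X0 = X[:k]
    if np.linalg.matrix_rank(X0) < k:
        # slide the startup window forward until it is full rank
        start = k
        while start < n and np.linalg.matrix_rank(X[:start]) < k:
            start += 1
        X0 = X[:start]
    else:
        start = k
    gram_inv = np.linalg.pinv(X0.T @ X0)
    beta = gram_inv @ (X0.T @ y[:start])
    w = np.empty(n - start)
    for t in range(start, n):
        x_t = X[t]
        f_t = 1.0 + x_t @ gram_inv @ x_t
        w[t - start] = (y[t] - x_t @ beta) / np.sqrt(f_t)
        # rank-1 update of (X'X)^{-1} and beta with the new observation
        gx = gram_inv @ x_t
        gram_inv = gram_inv - np.outer(gx, gx) / f_t
        beta = beta + gram_inv @ x_t * (y[t] - x_t @ beta)
    return w
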