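"""Unit-root testing and integration-order determination.

The lag-augmented causality test needs, for every model, the highest order
of integration (``dmax``) among its variables.  Orders are determined by
repeated augmented Dickey-Fuller (ADF) tests on successively differenced
series: the order of a variable is the smallest number of differences after
which the ADF test rejects a unit root at level ``alpha``.  The KPSS test
(null of stationarity, i.e. the opposite null) is available as a
complementary check for short series where the ADF has little power.

ADF lag length is chosen by AIC over ``0..max_lag`` with the Schwert rule
``max_lag = floor(12 (n/100)^0.25)``, shrunk when the series is short.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.tsa.stattools import adfuller, kpss

__all__ = [
    "UnitRootResult",
    "IntegrationProfile",
    "adf_test",
    "kpss_test",
    "integration_order",
    "integration_profile",
    "schwert_max_lag",
]

_DET = {"constant": "c", "constant+trend": "ct"}


@dataclass(frozen=True)
class UnitRootResult:
    """Outcome of one unit-root test on a (possibly differenced) series."""

    variable: str
    test: str  # "ADF" or "KPSS"
    differencing: int
    deterministic: str
    statistic: float
    p_value: float
    lags_used: int
    stationary: bool
    alpha: float


@dataclass(frozen=True)
class IntegrationProfile:
    """Per-variable integration orders and the model-level maximum."""

    orders: dict[str, int]
    dmax: int
    flagged: tuple[str, ...] = ()  # variables still nonstationary at d_cap


def schwert_max_lag(n: int) -> int:
    """Schwert's rule of thumb for the ADF lag bound."""
    return int(np.floor(12.0 * (n / 100.0) ** 0.25))


def _check_series(series: np.ndarray, min_n: int) -> np.ndarray:
    x = np.asarray(series, dtype=float).ravel()
    if x.size and np.ptp(x) == 0:
        raise ValueError("degenerate series: constant input")
    if x.size < min_n:
        raise ValueError(f"insufficient observations: n={x.size} < {min_n}")
    return x


def adf_test(
    series,
    deterministic: str = "constant",
    max_lag: int | None = None,
    alpha: float = 0.05,
    variable: str = "",
    differencing: int = 0,
) -> UnitRootResult:
    """Augmented Dickey-Fuller test (null: unit root).

    The statistic is the t-ratio on the lagged level in the augmented
    regression; the p-value comes from MacKinnon's response-surface
    approximation of the Dickey-Fuller distribution.  ``stationary`` is
    ``p < alpha`` (unit root rejected).
    """
    x = _check_series(series, 10)
    if max_lag is None:
        max_lag = min(schwert_max_lag(x.size), max(x.size - 10, 0))
    if x.size < max_lag + 10:
        raise ValueError(f"insufficient observations: n={x.size} < max_lag+10")
    stat, pvalue, usedlag, _, _, _ = adfuller(
        x, maxlag=max_lag, regression=_DET[deterministic], autolag="AIC"
    )
    return UnitRootResult(
        variable=variable,
        test="ADF",
        differencing=differencing,
        deterministic=deterministic,
        statistic=float(stat),
        p_value=float(pvalue),
        lags_used=int(usedlag),
        stationary=bool(pvalue < alpha),
        alpha=alpha,
    )


def kpss_test(
    series,
    deterministic: str = "constant",
    alpha: float = 0.05,
    variable: str = "",
    differencing: int = 0,
    nlags: int | None = None,
) -> UnitRootResult:
    """KPSS test (null: stationarity) — decision sense inverted vs. ADF.

    ``stationary`` is ``p >= alpha`` (stationarity not rejected).  The
    p-value is interpolated from the standard KPSS table and clipped to
    [0.01, 0.10] outside its range.  The long-run variance bandwidth
    defaults to the short rule ``floor(4 (n/100)^0.25)`` (KPSS's "l4"),
    which keeps power against random walks on moderate samples.
    """
    x = _check_series(series, 10)
    if nlags is None:
        nlags = int(np.floor(4.0 * (x.size / 100.0) ** 0.25))
    with warnings.catch_warnings():
        # p-value outside the lookup table is expected for clearly (non)stationary input
        warnings.simplefilter("ignore")
        stat, pvalue, lags, _ = kpss(x, regression=_DET[deterministic], nlags=nlags)
    return UnitRootResult(
        variable=variable,
        test="KPSS",
        differencing=differencing,
        deterministic=deterministic,
        statistic=float(stat),
        p_value=float(pvalue),
        lags_used=int(lags),
        stationary=bool(pvalue >= alpha),
        alpha=alpha,
    )


def integration_order(
    series,
    d_cap: int = 2,
    alpha: float = 0.05,
    deterministic: str = "constant",
    max_lag: int | None = None,
) -> tuple[int, bool]:
    """Smallest ``d`` whose d-th difference is ADF-stationary at ``alpha``.

    Returns ``(d, flagged)``; ``flagged`` is true when even the ``d_cap``-th
    difference fails to reject a unit root, in which case ``d = d_cap``.
    """
    x = np.asarray(series, dtype=float).ravel()
    for d in range(d_cap + 1):
        res = adf_test(
            np.diff(x, n=d), deterministic=deterministic, max_lag=max_lag,
            alpha=alpha, differencing=d,
        )
        if res.stationary:
            return d, False
    return d_cap, True


def integration_profile(
    panel,
    variables=None,
    d_cap: int = 2,
    alpha: float = 0.05,
    deterministic: str = "constant",
) -> IntegrationProfile:
    """Integration orders for a set of panel variables and their maximum."""
    names = tuple(variables) if variables is not None else panel.variables
    orders: dict[str, int] = {}
    flagged = []
    for name in names:
        d, flag = integration_order(
            panel.series(name), d_cap=d_cap, alpha=alpha, deterministic=deterministic
        )
        orders[name] = d
        if flag:
            flagged.append(name)
    return IntegrationProfile(orders=orders, dmax=max(orders.values()), flagged=tuple(flagged))
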