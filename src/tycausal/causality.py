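"""Toda-Yamamoto lag-augmented causality tests.

A Granger-type causality hypothesis "X (does not) cause Y" is tested on a
VAR estimated in *levels* with ``p + dmax`` lags, where ``p`` is the
information-criterion lag order and ``dmax`` the highest integration order
among the model's variables.  The Wald restriction covers only the
coefficients of lags ``1..p`` of the restricted (causal) variables in the
outcome equation; the ``dmax`` augmentation lags are never restricted.
This keeps the Wald statistic asymptotically chi-square even when the
series are integrated or cointegrated, so no differencing or cointegration
pre-testing is needed.

Joint hypotheses place several causal blocks in the same equation; the
joint test restricts all their lag blocks at once (df = p x #variables),
while submodels restrict one block at a time on the *same* fitted VAR —
the comparison of joint and submodel outcomes is what separates mediated
from synergistic structures downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .panel import AnnualPanel
from .stationarity import integration_profile
from .var import VarError, VarFit, fit_var, select_lag

__all__ = [
    "TYSpec",
    "TYResult",
    "ty_test",
    "ty_joint_with_submodels",
    "run_hypothesis_battery",
    "wald_restriction",
]


@dataclass(frozen=True)
class TYSpec:
    """One causality hypothesis: ``cause_blocks -> outcome``.

    ``cause_blocks`` is an ordered list of variable groups; a singleton list
    gives a simple test, several groups give a joint test.  ``p`` and
    ``dmax`` may be left ``None`` to be resolved from the data (AIC lag
    selection with cap, ADF integration orders).
    """

    outcome: str
    cause_blocks: tuple[tuple[str, ...], ...]
    p: int | None = None
    dmax: int | None = None
    alpha: float = 0.05
    name: str = ""

    def __post_init__(self) -> None:
        blocks = tuple(tuple(b) if not isinstance(b, str) else (b,) for b in self.cause_blocks)
        object.__setattr__(self, "cause_blocks", blocks)
        causes = [v for b in blocks for v in b]
        if not causes:
            raise ValueError("at least one causal variable required")
        if len(set(causes)) != len(causes):
            raise ValueError("causal variables must be distinct")
        if self.outcome in causes:
            raise ValueError("outcome must not appear in any cause block")
        if self.p is not None and self.p < 1:
            raise ValueError("p must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @property
    def causes(self) -> tuple[str, ...]:
        return tuple(v for b in self.cause_blocks for v in b)

    @property
    def variables(self) -> tuple[str, ...]:
        return (self.outcome, *self.causes)


@dataclass(frozen=True)
class TYResult:
    """Wald outcome of one causality hypothesis."""

    spec: TYSpec
    chi2: float
    df: int
    p_value: float
    reject: bool
    p_used: int
    dmax_used: int
    restricted: tuple[str, ...]
    lag_selection: object = field(default=None, compare=False)
    fit: VarFit = field(default=None, repr=False, compare=False)
    error: str | None = None


def wald_restriction(fit: VarFit, outcome: str, restricted: tuple[str, ...], p: int):
    """Assemble (R beta, R V R') for zero restrictions on lags 1..p.

    Returns ``(rb, rvr, df)`` where ``rb`` stacks the restricted
    coefficients of the outcome equation and ``rvr`` their covariance
    block.  Augmentation lags ``p+1..k`` are deliberately excluded.
    """
    eq = fit.equation(outcome)
    idx = [fit.coef_index(v, lag) for v in restricted for lag in range(1, p + 1)]
    beta = fit.coefs[eq]
    V = fit.cov_params[eq]
    rb = beta[idx]
    rvr = V[np.ix_(idx, idx)]
    return rb, rvr, len(idx)


def _wald(fit: VarFit, outcome: str, restricted: tuple[str, ...], p: int, alpha: float):
    rb, rvr, df = wald_restriction(fit, outcome, restricted, p)
    try:
        sol = np.linalg.solve(rvr, rb)
    except np.linalg.LinAlgError as exc:
        raise VarError("ill-conditioned Wald: singular restricted covariance") from exc
    cond = np.linalg.cond(rvr)
    if not np.isfinite(cond) or cond > 1e12:
        raise VarError("ill-conditioned Wald: singular restricted covariance")
    chi2 = float(rb @ sol)
    p_value = float(stats.chi2.sf(chi2, df))
    return chi2, df, p_value, bool(p_value < alpha)


def _resolve(panel: AnnualPanel, spec: TYSpec, max_p: int, cap: int, d_cap: int):
    """Fill in per-model p (AIC with cap) and dmax (ADF orders) if absent."""
    sub = panel.subset(spec.variables)
    selection = None
    p = spec.p
    if p is None:
        selection = select_lag(sub, max_p=max_p, cap=cap)
        p = selection.chosen
    dmax = spec.dmax
    if dmax is None:
        dmax = integration_profile(sub, d_cap=d_cap, alpha=spec.alpha).dmax
    return sub, p, dmax, selection


def ty_test(
    panel: AnnualPanel,
    spec: TYSpec,
    max_p: int = 5,
    cap: int = 3,
    d_cap: int = 2,
) -> TYResult:
    """Toda-Yamamoto causality test for one hypothesis.

    Fits a VAR(p + dmax) in levels on the model's variables and applies the
    Wald restriction to lags ``1..p`` of every causal variable jointly.
    """
    sub, p, dmax, selection = _resolve(panel, spec, max_p, cap, d_cap)
    fit = fit_var(sub, lag_order=p + dmax)
    chi2, df, p_value, reject = _wald(fit, spec.outcome, spec.causes, p, spec.alpha)
    return TYResult(
        spec=spec, chi2=chi2, df=df, p_value=p_value, reject=reject,
        p_used=p, dmax_used=dmax, restricted=spec.causes,
        lag_selection=selection, fit=fit,
    )


def ty_joint_with_submodels(
    panel: AnnualPanel,
    outcome: str,
    causes,
    p: int | None = None,
    dmax: int | None = None,
    alpha: float = 0.05,
    max_p: int = 5,
    cap: int = 3,
    d_cap: int = 2,
    name: str = "",
) -> dict[str, TYResult]:
    """Joint test plus one submodel per causal variable, on one fitted VAR.

    All restrictions are evaluated on the *same* VAR(p + dmax) containing
    the outcome and every cause: the joint test restricts all lag blocks
    (df = p x #causes), each submodel restricts a single block (df = p).
    With a single cause the joint test degenerates to the simple test.
    """
    causes = tuple(causes)
    spec = TYSpec(
        outcome=outcome, cause_blocks=tuple((c,) for c in causes),
        p=p, dmax=dmax, alpha=alpha, name=name,
    )
    sub, p_res, dmax_res, selection = _resolve(panel, spec, max_p, cap, d_cap)
    fit = fit_var(sub, lag_order=p_res + dmax_res)

    def result(restricted: tuple[str, ...], label: str) -> TYResult:
        chi2, df, p_value, reject = _wald(fit, outcome, restricted, p_res, alpha)
        return TYResult(
            spec=replace(spec, name=label or spec.name), chi2=chi2, df=df,
            p_value=p_value, reject=reject, p_used=p_res, dmax_used=dmax_res,
            restricted=restricted, lag_selection=selection, fit=fit,
        )

    out = {"joint": result(causes, name)}
    for c in causes:
        out[f"sub_{c}"] = result((c,), f"{name}:{c}" if name else c)
    return out


def run_hypothesis_battery(
    panel: AnnualPanel,
    registry,
    max_p: int = 5,
    cap: int = 3,
    d_cap: int = 2,
) -> list[TYResult]:
    """Run every :class:`TYSpec` in ``registry`` and collect results.

    Per-spec failures are recorded in the result's ``error`` field (with
    NaN statistics) and the battery continues; an empty registry is an
    error.  Output order follows the registry.
    """
    registry = list(registry)
    if not registry:
        raise ValueError("empty hypothesis registry")
    results: list[TYResult] = []
    for spec in registry:
        try:
            results.append(ty_test(panel, spec, max_p=max_p, cap=cap, d_cap=d_cap))
        except (VarError, ValueError, KeyError) as exc:
            results.append(
                TYResult(
                    spec=spec, chi2=float("nan"), df=0, p_value=float("nan"),
                    reject=False, p_used=0, dmax_used=0, restricted=spec.causes,
                    error=str(exc),
                )
            )
    return results
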