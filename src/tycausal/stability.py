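"""Structural-stability testing of single-equation regressions.

Two complementary tools, applied to the outcome equation of each causality
model:

* :func:`bai_perron` — multiple unknown coefficient breaks, located by
  exact dynamic-programming minimization of the segmented sum of squared
  residuals; the number of breaks is chosen by the sequential sup-F(l+1|l)
  test at a (deliberately liberal) 10% default level.
* :func:`cusum_test` — recursive CUSUM (mean shifts) and CUSUM of squares
  (variance shifts) of the standardized recursive residuals against their
  classical confidence boundaries.

P-values for the sup-F and recursive-CUSUM statistics are interpolated
from Monte Carlo quantile tables of the asymptotic limit distributions
(see :mod:`tycausal._critical_values`); the CUSUM-of-squares p-value uses
the Kolmogorov distribution of the maximum Brownian-bridge deviation.
These are documented approximations and may differ from other software in
the third decimal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from ._critical_values import CUSUM_QUANTILES, PROBS, SUPF_QUANTILES
from .var import VarError, recursive_residuals

__all__ = ["BreakReport", "CusumReport", "bai_perron", "cusum_test"]


@dataclass(frozen=True)
class BreakReport:
    """Breakpoints, sequential sup-F statistics, and the chosen partition."""

    n_breaks: int
    break_indices: tuple[int, ...]  # last observation of each pre-break regime
    break_years: tuple[int, ...]  # same positions mapped through `years`
    supf: dict[int, float]  # tested break count l+1 -> supF(l+1|l)
    supf_p: dict[int, float]
    p_value: float  # p of the test that fixed n_breaks
    ssr: float  # SSR of the chosen partition
    trim: float


@dataclass(frozen=True)
class CusumReport:
    """A cumulative-statistic path, its boundaries, and the crossing verdict."""

    variant: str  # "CUSUM" | "CUSUM-SQ"
    path: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    crossed: bool
    statistic: float
    p_value: float
    level: float


def _segment_ssr_table(y: np.ndarray, X: np.ndarray, h: int) -> np.ndarray:
    """SSR of OLS on every admissible segment [i, j] (inclusive, 0-based).

    Uses prefix Gram matrices so each segment costs one small solve;
    returns an (n, n) table with NaN for segments shorter than ``h``.
    """
    n, q = X.shape
    xx = np.concatenate([np.zeros((1, q, q)), np.cumsum(X[:, :, None] * X[:, None, :], axis=0)])
    xy = np.concatenate([np.zeros((1, q)), np.cumsum(X * y[:, None], axis=0)])
    yy = np.concatenate([[0.0], np.cumsum(y * y)])
    ssr = np.full((n, n), np.nan)
    for i in range(n - h + 1):
        js = np.arange(i + h - 1, n)
        G = xx[js + 1] - xx[i]
        b = xy[js + 1] - xy[i]
        # pinv-based solve tolerates within-segment collinearity
        for idx, j in enumerate(js):
            coef, res, rank, _ = np.linalg.lstsq(G[idx], b[idx], rcond=None)
            ssr[i, j] = max(yy[j + 1] - yy[i] - b[idx] @ coef, 0.0)
    return ssr


def _optimal_partition(ssr: np.ndarray, n_breaks: int, h: int) -> tuple[float, list[int]]:
    """Global SSR-minimizing partition with ``n_breaks`` breaks (DP)."""
    n = ssr.shape[0]
    # cost[j, t]: min SSR of first t+1 obs split into j+1 segments
    cost = np.full((n_breaks + 1, n), np.inf)
    arg = np.zeros((n_breaks + 1, n), dtype=int)
    cost[0] = ssr[0]
    for j in range(1, n_breaks + 1):
        for t in range((j + 1) * h - 1, n):
            # previous segment ends at s, current is [s+1, t]
            s_lo, s_hi = j * h - 1, t - h
            cand = cost[j - 1, s_lo : s_hi + 1] + ssr[s_lo + 1 : s_hi + 2, t]
            k = int(np.argmin(cand))
            cost[j, t] = cand[k]
            arg[j, t] = s_lo + k
    if not np.isfinite(cost[n_breaks, n - 1]):
        raise VarError("infeasible trimming for requested break count")
    breaks = []
    t = n - 1
    for j in range(n_breaks, 0, -1):
        s = arg[j, t]
        breaks.append(int(s))
        t = s
    return float(cost[n_breaks, n - 1]), sorted(breaks)


def _supf_p(F: float, q: int, n_segments: int) -> float:
    """P-value of sup-F(l+1|l) from the frozen limit-quantile table.

    The sequential statistic is the max over ``n_segments`` independent
    copies of the one-break limit, so p = 1 - G(F)^n_segments.
    """
    table = SUPF_QUANTILES[min(q, max(SUPF_QUANTILES))]
    G = float(np.interp(F, table, PROBS, left=0.0, right=PROBS[-1]))
    return float(np.clip(1.0 - G**n_segments, 1e-4, 1.0))


def bai_perron(
    y,
    X,
    max_breaks: int = 5,
    trim: float = 0.15,
    alpha: float = 0.10,
    years=None,
) -> BreakReport:
    """Bai-Perron multiple-breakpoint test for a linear regression.

    All coefficients are allowed to shift (pure structural change).  The
    number of breaks is chosen sequentially: starting from the stable
    model, sup-F(l+1|l) — the largest F-statistic for one additional break
    within any current regime — is compared with its asymptotic
    distribution; breaks are added while p < ``alpha`` (default 0.10, the
    conventional liberal level for break screening) up to ``max_breaks``.
    Break dates are then the global SSR-minimizing partition.

    ``break_indices`` hold the last observation of each pre-break regime;
    ``break_years`` map them through ``years`` when given.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    n, q = X.shape
    h = max(int(np.ceil(trim * n)), q + 1)
    if (max_breaks + 1) * h > n:
        raise VarError(
            f"infeasible trimming: {max_breaks} breaks need {(max_breaks + 1) * h} obs, have {n}"
        )
    ssr_table = _segment_ssr_table(y, X, h)
    ssr0 = float(ssr_table[0, n - 1])
    scale = float(y @ y) + 1.0

    supf: dict[int, float] = {}
    supf_p: dict[int, float] = {}
    n_breaks = 0
    partition: list[int] = []
    ssr_current = ssr0
    p_value = 1.0
    while n_breaks < max_breaks:
        # best additional break inside any current regime
        bounds = [-1] + partition + [n - 1]
        best_F = 0.0
        found = False
        for a, b in zip(bounds[:-1], bounds[1:]):
            i, j = a + 1, b
            seg_n = j - i + 1
            if seg_n < 2 * h:
                continue
            ssr_seg = ssr_table[i, j]
            splits = np.arange(i + h - 1, j - h + 1)
            split_ssr = ssr_table[i, splits] + ssr_table[splits + 1, j]
            best = float(np.min(split_ssr))
            if ssr_seg <= 1e-12 * scale:  # exact fit: nothing to improve
                continue
            denom = best / max(seg_n - 2 * q, 1)
            F = ((ssr_seg - best) / q) / denom if denom > 0 else np.inf
            best_F = max(best_F, F)
            found = True
        l = n_breaks
        if not found:
            if l == 0:
                supf[1], supf_p[1] = 0.0, 1.0
                p_value = 1.0
            break
        p_seq = _supf_p(best_F, q, l + 1)
        supf[l + 1] = best_F
        supf_p[l + 1] = p_seq
        if p_seq >= alpha:
            if l == 0:
                p_value = p_seq
            break
        n_breaks += 1
        p_value = p_seq
        ssr_current, partition = _optimal_partition(ssr_table, n_breaks, h)

    if n_breaks == 0:
        partition, ssr_current = [], ssr0
    years = list(years) if years is not None else None
    break_years = tuple(int(years[b]) for b in partition) if years else tuple(partition)
    return BreakReport(
        n_breaks=n_breaks,
        break_indices=tuple(partition),
        break_years=break_years,
        supf=supf,
        supf_p=supf_p,
        p_value=float(p_value),
        ssr=float(ssr_current),
        trim=trim,
    )


def _cusum_boundary_a(level: float) -> float:
    """Boundary slope parameter a with crossing probability ``level``."""
    return float(np.interp(1.0 - level, PROBS, CUSUM_QUANTILES))


def cusum_test(y, X, variant: str = "CUSUM", level: float = 0.05) -> CusumReport:
    """Recursive CUSUM / CUSUM-of-squares parameter-stability test.

    CUSUM tracks the scaled cumulative sum of standardized recursive
    residuals against the linear boundaries ±a(sqrt(m) + 2 t / sqrt(m));
    it reacts to shifts in the residual mean (coefficient drift).
    CUSUM-SQ tracks the cumulative share of squared residuals against
    parallel bands around its diagonal expectation; it reacts to variance
    changes.  ``p_value`` is the approximate probability, under stability,
    of a deviation at least as large as the observed maximum.
    """
    w = recursive_residuals(y, X)
    m = w.size
    t = np.arange(1, m + 1)
    y_scale = float(np.max(np.abs(np.asarray(y, float)))) or 1.0
    if np.max(np.abs(w)) <= 1e-10 * y_scale:
        w = np.zeros(m)  # numerically exact fit: the path sits at its null expectation
    if variant == "CUSUM":
        sd = float(np.std(w, ddof=1))
        path = np.cumsum(w) / sd if sd > 0 else np.zeros(m)
        shape = np.sqrt(m) + 2.0 * t / np.sqrt(m)
        a = _cusum_boundary_a(level)
        lower, upper = -a * shape, a * shape
        stat = float(np.max(np.abs(path) / shape))
        p = float(np.clip(1.0 - np.interp(stat, CUSUM_QUANTILES, PROBS, left=0.0), 1e-4, 1.0))
        crossed = bool(stat > a)
    elif variant == "CUSUM-SQ":
        total = float(np.sum(w**2))
        expected = t / m
        path = np.cumsum(w**2) / total if total > 0 else expected.copy()
        stat = float(np.max(np.abs(path - expected)))
        # sqrt(m/2) (s_t - t/m) converges to a Brownian bridge
        z = stat * np.sqrt(m / 2.0)
        p = float(np.clip(special.kolmogorov(z), 0.0, 1.0)) if z > 0 else 1.0
        c0 = float(special.kolmogi(level)) * np.sqrt(2.0 / m)
        lower, upper = expected - c0, expected + c0
        crossed = bool(stat > c0)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return CusumReport(
        variant=variant, path=path, lower=lower, upper=upper,
        crossed=crossed, statistic=stat, p_value=p, level=level,
    )
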