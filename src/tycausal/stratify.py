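"""Income-group stratification and cross-group comparison of test results.

Countries are clustered on (standardized) per-capita GDP at purchasing
power parity and per-capita health expenditure with K-means (best of 25
random initializations, Euclidean distance).  The cluster count is chosen
from the within-cluster sum of squares (elbow) and mean silhouette
profiles.  Group labels are assigned post hoc by center ordering on the
first feature (higher center = "high_income"), since raw K-means labels
are arbitrary.

Causality results estimated separately per group are compared by mapping
each chi-square statistic to an approximately standard-normal deviate via
the Wilson-Hilferty cube-root transform and contrasting the two deviates:
z = (z_low - z_high) / sqrt(2), two-sided p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .panel import CountryCrossSection

__all__ = [
    "ClusterResult",
    "GroupComparison",
    "standardize",
    "kmeans_cluster",
    "choose_k",
    "compare_groups",
    "wilson_hilferty",
]


@dataclass(frozen=True)
class ClusterResult:
    """K-means assignments plus the diagnostics used to pick k."""

    assignments: dict[str, int]  # country -> 1..k
    centers: np.ndarray  # (k, n_features), ordered by first feature desc
    wss: float
    wss_by_k: dict[int, float]
    silhouette_by_k: dict[int, float | None]
    chosen_k: int
    n_init: int
    seed: int
    group_names: tuple[str, ...] = ()


@dataclass(frozen=True)
class GroupComparison:
    """Cross-group contrast of one model's chi-square outcomes."""

    model: str
    chi2_low: float
    df_low: int
    p_low: float
    chi2_high: float
    df_high: int
    p_high: float
    z: float
    p_value: float
    df_mismatch: bool


def standardize(features: np.ndarray) -> np.ndarray:
    """Column z-scores (population sd); constant columns become zeros."""
    x = np.asarray(features, dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mu) / sd


def _fit_kmeans(x: np.ndarray, k: int, n_init: int, seed: int) -> KMeans:
    return KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(x)


def kmeans_cluster(
    data: CountryCrossSection,
    k: int,
    n_init: int = 25,
    seed: int = 0,
    scale: bool = True,
) -> ClusterResult:
    """Best-of-``n_init`` K-means on a country cross-section.

    Clusters are relabelled so cluster 1 has the highest center on the
    first feature; with k = 2 the groups are named ``high_income`` /
    ``low_income``.  ``scale=False`` clusters on raw feature values.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    n = len(data.country_ids)
    if k >= n:
        raise ValueError("k must be smaller than the number of countries")
    x = standardize(data.features) if scale else np.asarray(data.features, float)
    if np.unique(x, axis=0).shape[0] < k:
        raise ValueError("degenerate data: fewer distinct points than clusters")
    km = _fit_kmeans(x, k, n_init, seed)
    order = np.argsort(-km.cluster_centers_[:, 0])  # descending on first feature
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    labels = relabel[km.labels_]
    sil = None
    if k >= 2:
        sil = float(silhouette_score(x, km.labels_))
    names = ("high_income", "low_income") if k == 2 else tuple(f"cluster_{i}" for i in range(1, k + 1))
    return ClusterResult(
        assignments={c: int(g) for c, g in zip(data.country_ids, labels)},
        centers=km.cluster_centers_[order],
        wss=float(km.inertia_),
        wss_by_k={k: float(km.inertia_)},
        silhouette_by_k={k: sil},
        chosen_k=k,
        n_init=n_init,
        seed=seed,
        group_names=names,
    )


def choose_k(
    data: CountryCrossSection,
    k_range=range(1, 7),
    n_init: int = 25,
    seed: int = 0,
    scale: bool = True,
    silhouette_threshold: float = 0.5,
) -> ClusterResult:
    """Scan ``k_range``, record WSS and silhouette, and pick k.

    The rule: among k >= 2 whose silhouette clears ``silhouette_threshold``,
    take the one with the largest relative WSS drop from k-1 (the elbow);
    if none clears the threshold the structure is weak and the k with the
    best silhouette is returned with ``chosen_k`` still set, so callers can
    inspect ``silhouette_by_k`` before trusting the split.  k = 1 has no
    silhouette (reported as ``None``) and WSS equal to the total sum of
    squares.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k range")
    x = standardize(data.features) if scale else np.asarray(data.features, float)
    wss_by_k: dict[int, float] = {}
    sil_by_k: dict[int, float | None] = {}
    for k in ks:
        if k == 1:
            wss_by_k[1] = float(((x - x.mean(axis=0)) ** 2).sum())
            sil_by_k[1] = None
            continue
        km = _fit_kmeans(x, k, n_init, seed)
        wss_by_k[k] = float(km.inertia_)
        sil_by_k[k] = float(silhouette_score(x, km.labels_))
    candidates = [k for k in ks if k >= 2 and sil_by_k.get(k) is not None]
    eligible = [k for k in candidates if sil_by_k[k] >= silhouette_threshold]
    pool = eligible or candidates
    if pool:
        def drop(k: int) -> float:
            prev = wss_by_k.get(k - 1)
            if prev is None or prev <= 0:
                return 0.0
            return (prev - wss_by_k[k]) / prev
        chosen = max(pool, key=drop) if eligible else max(pool, key=lambda k: sil_by_k[k])
    else:
        chosen = ks[0]
    if chosen == 1:
        raise ValueError("k_range must include a feasible k >= 2 to cluster")
    result = kmeans_cluster(data, chosen, n_init=n_init, seed=seed, scale=scale)
    return ClusterResult(
        assignments=result.assignments,
        centers=result.centers,
        wss=result.wss,
        wss_by_k=wss_by_k,
        silhouette_by_k=sil_by_k,
        chosen_k=chosen,
        n_init=n_init,
        seed=seed,
        group_names=result.group_names,
    )


def wilson_hilferty(chi2: float, df: int) -> float:
    """Map a chi-square variate to an approximately N(0,1) deviate."""
    if df <= 0:
        raise ValueError("df must be positive")
    c = 2.0 / (9.0 * df)
    return ((chi2 / df) ** (1.0 / 3.0) - (1.0 - c)) / np.sqrt(c)


def compare_groups(result_low, result_high, model: str = "") -> GroupComparison:
    """Contrast one hypothesis's chi-square outcome across income groups.

    Both statistics are Wilson-Hilferty-transformed to normal deviates and
    differenced: z = (z_low - z_high)/sqrt(2) (positive z = stronger
    evidence in the low-income group), two-sided p.  A df mismatch is
    flagged but the comparison is still computed.
    """
    z_low = wilson_hilferty(result_low.chi2, result_low.df)
    z_high = wilson_hilferty(result_high.chi2, result_high.df)
    z = (z_low - z_high) / np.sqrt(2.0)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return GroupComparison(
        model=model or getattr(result_low.spec, "name", ""),
        chi2_low=float(result_low.chi2),
        df_low=int(result_low.df),
        p_low=float(result_low.p_value),
        chi2_high=float(result_high.chi2),
        df_high=int(result_high.df),
        p_high=float(result_high.p_value),
        z=float(z),
        p_value=p,
        df_mismatch=bool(result_low.df != result_high.df),
    )
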