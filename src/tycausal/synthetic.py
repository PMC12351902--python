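"""Synthetic panels and cross-sections with declared ground truth.

Every statistical stage of the pipeline is exercised on data whose causal
structure is known.  The generators emulate the features of the macro
panels the analysis is designed for: short annual series (n ~ 23-33),
mixed integration orders I(0)/I(1), lagged causal links with 1-6 period
delays, mediated chains X -> M -> Y, coefficient breaks at known dates,
and two-cluster country cross-sections.  Each generated dataset carries a
:class:`SyntheticTruth` record so recovery can be scored.

All randomness flows through ``numpy.random.default_rng(seed)``; the same
seed and truth always reproduce bit-identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import AnnualPanel, CountryCrossSection

__all__ = [
    "SyntheticTruth",
    "gen_var_panel",
    "gen_mediation_chain",
    "gen_break_regression",
    "gen_country_cross_section",
    "PRESET_SPANS",
]

# named sample sizes mirroring the study's spans: the global food-insecurity
# series (23 annual points), the food-price series (33), and the
# country-level consumer-price window (11)
PRESET_SPANS = {"fi_global": 23, "fpi_global": 33, "country": 11}


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth attached to a generated dataset.

    ``edges`` are directed lagged links ``(source, target, lag, coef)``;
    ``ar`` gives each variable's own-lag coefficient; ``integration``
    flags variables to be cumulated after simulation (I(1) or I(2)).
    """

    variables: tuple[str, ...]
    edges: tuple[tuple[str, str, int, float], ...] = ()
    ar: dict[str, float] = field(default_factory=dict)
    integration: dict[str, int] = field(default_factory=dict)
    break_spec: tuple[int, float] | None = None
    noise_sd: dict[str, float] = field(default_factory=dict)
    n: int = 0
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def max_lag(self) -> int:
        own = 1 if self.ar else 0
        return max([own] + [lag for _, _, lag, _ in self.edges])

    def companion_spectral_radius(self) -> float:
        """Spectral radius of the companion matrix of the stationary core."""
        m = len(self.variables)
        k = max(self.max_lag(), 1)
        A = np.zeros((k, m, m))
        idx = {v: i for i, v in enumerate(self.variables)}
        for v, a in self.ar.items():
            A[0, idx[v], idx[v]] = a
        for src, dst, lag, coef in self.edges:
            A[lag - 1, idx[dst], idx[src]] += coef
        top = np.hstack(list(A))
        comp = np.vstack([top, np.hstack([np.eye(m * (k - 1)), np.zeros((m * (k - 1), m))])])
        return float(np.max(np.abs(np.linalg.eigvals(comp)))) if comp.size else 0.0

    def validate(self) -> None:
        names = set(self.variables)
        for src, dst, lag, coef in self.edges:
            if src not in names or dst not in names:
                raise ValueError(f"edge references unknown variable: {(src, dst)}")
            if lag < 1:
                raise ValueError("contemporaneous (lag-0) edges are not allowed")
            if not np.isfinite(coef):
                raise ValueError("non-finite edge coefficient")
        rho = self.companion_spectral_radius()
        if rho >= 0.99:
            raise ValueError(
                f"explosive or near-unit stationary core (spectral radius {rho:.3f}); "
                "declare the variable I(1) instead"
            )


def gen_var_panel(
    truth: SyntheticTruth,
    burn_in: int = 100,
    start_year: int = 1990,
    rng: np.random.Generator | None = None,
) -> AnnualPanel:
    """Simulate the VAR described by ``truth`` with Gaussian innovations.

    The stationary core is simulated with ``burn_in`` discarded start-up
    periods; variables flagged I(d) are then cumulated d times (so the
    *differenced* output reproduces the stationary draw exactly).  Years
    run from ``start_year``.
    """
    truth.validate()
    rng = rng if rng is not None else np.random.default_rng(truth.seed)
    m = len(truth.variables)
    idx = {v: i for i, v in enumerate(truth.variables)}
    k = max(truth.max_lag(), 1)
    total = truth.n + burn_in + k
    sd = np.array([truth.noise_sd.get(v, 1.0) for v in truth.variables])
    eps = rng.standard_normal((m, total)) * sd[:, None]
    Y = np.zeros((m, total))
    for t in range(k, total):
        acc = eps[:, t].copy()
        for v, a in truth.ar.items():
            acc[idx[v]] += a * Y[idx[v], t - 1]
        for src, dst, lag, coef in truth.edges:
            acc[idx[dst]] += coef * Y[idx[src], t - lag]
        Y[:, t] = acc
    out = Y[:, total - truth.n :].copy()
    for v, d in truth.integration.items():
        for _ in range(int(d)):
            out[idx[v]] = np.cumsum(out[idx[v]])
    years = tuple(range(start_year, start_year + truth.n))
    return AnnualPanel(years, truth.variables, out, {"synthetic": True, "seed": truth.seed})


def gen_mediation_chain(
    beta_xm: float,
    beta_my: float,
    beta_xy: float = 0.0,
    lag_xm: int = 1,
    lag_my: int = 1,
    n: int = 150,
    seed: int = 0,
    phi: float = 0.5,
    noise_sd: float = 1.0,
) -> tuple[AnnualPanel, SyntheticTruth]:
    """Three-variable chain X -> M -> Y with an optional direct X -> Y path.

    X is an exogenous AR(1) with coefficient ``phi``; M picks up X at lag
    ``lag_xm``; Y picks up M at lag ``lag_my`` and, when ``beta_xy != 0``,
    X at lag 1.  The truth records whether the direct path exists, which
    the mediation classifier is scored against.
    """
    edges = [("X", "M", lag_xm, beta_xm), ("M", "Y", lag_my, beta_my)]
    if beta_xy != 0.0:
        edges.append(("X", "Y", 1, beta_xy))
    truth = SyntheticTruth(
        variables=("X", "M", "Y"),
        edges=tuple(edges),
        ar={"X": phi, "M": phi, "Y": phi},
        noise_sd={v: noise_sd for v in ("X", "M", "Y")},
        n=n,
        seed=seed,
        extra={"direct_path": beta_xy != 0.0, "chain": beta_xm != 0.0 and beta_my != 0.0},
    )
    return gen_var_panel(truth), truth


def gen_break_regression(
    n: int,
    break_at: int,
    shift: float,
    seed: int = 0,
    slope: float = 1.0,
    intercept: float = 0.0,
    noise_sd: float = 1.0,
    trim: float = 0.15,
) -> tuple[np.ndarray, np.ndarray, SyntheticTruth]:
    """Linear regression whose slope shifts by ``shift`` at ``break_at``.

    Returns ``(y, X)`` with X = [1, x] and the truth record.  ``break_at``
    is the first observation of the new regime (0-based);  infeasible
    placements under ``trim`` raise ``ValueError``.
    """
    h = int(np.ceil(trim * n))
    if not h <= break_at <= n - h:
        raise ValueError(
            f"break at {break_at} infeasible for n={n} with trim {trim} (need >= {h} per regime)"
        )
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    b = np.where(np.arange(n) >= break_at, slope + shift, slope)
    y = intercept + b * x + noise_sd * rng.standard_normal(n)
    X = np.column_stack([np.ones(n), x])
    truth = SyntheticTruth(
        variables=("y",),
        break_spec=(break_at, shift),
        noise_sd={"y": noise_sd},
        n=n,
        seed=seed,
        extra={"slope": slope, "intercept": intercept},
    )
    return y, X, truth


def gen_country_cross_section(
    n_countries: int = 99,
    n_clusters: int = 2,
    separation: float = 6.0,
    seed: int = 0,
    n_features: int = 2,
    feature_names: tuple[str, ...] = ("GDP_PPP", "HE"),
    year: int = 2022,
    cluster_sizes=None,
) -> tuple[CountryCrossSection, np.ndarray]:
    """Gaussian country clouds with centers ``separation`` sigmas apart.

    Returns the cross-section and the true cluster labels (1-based,
    ordered so cluster 1 has the highest first-feature center).  With
    ``separation=0`` all countries come from one cloud and the labels
    carry no recoverable signal.
    """
    if n_clusters < 1 or n_clusters > n_countries:
        raise ValueError("need 1 <= n_clusters <= n_countries")
    rng = np.random.default_rng(seed)
    if cluster_sizes is None:
        base = n_countries // n_clusters
        cluster_sizes = [base + (1 if i < n_countries % n_clusters else 0) for i in range(n_clusters)]
    if sum(cluster_sizes) != n_countries:
        raise ValueError("cluster sizes must sum to n_countries")
    centers = np.zeros((n_clusters, n_features))
    for i in range(n_clusters):
        centers[i, :] = i * separation  # spread along the diagonal
    feats = []
    labels = []
    for i, size in enumerate(cluster_sizes):
        feats.append(centers[i] + rng.standard_normal((size, n_features)))
        labels.extend([i] * size)
    features = np.vstack(feats)
    labels = np.asarray(labels)
    # label 1 = highest first-feature center, matching the clustering module
    order = np.argsort(-centers[:, 0])
    relabel = np.empty(n_clusters, dtype=int)
    relabel[order] = np.arange(1, n_clusters + 1)
    labels = relabel[labels]
    ids = tuple(f"C{i:03d}" for i in range(n_countries))
    names = tuple(feature_names[:n_features]) if len(feature_names) >= n_features else tuple(
        f"f{j}" for j in range(n_features)
    )
    return CountryCrossSection(ids, names, features, year), labels
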