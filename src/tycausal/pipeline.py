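"""Full study workflow: registry, batteries, stability, report, diagram.

The study battery mirrors the twelve-model design of the multicausality
analysis the package implements: nine single-cause models, three joint
models with their submodels, two mediation triples, structural-stability
checks per model, and an optional income-stratified re-run with
cross-group Wald comparisons.  All stages are driven by a
:class:`StudyConfig` and produce a :class:`StudyReport` whose tables are
plain rows ready for CSV/JSON export.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .causality import TYResult, TYSpec, run_hypothesis_battery, ty_joint_with_submodels, ty_test
from .mediation import MediationVerdict, scan_triples
from .panel import AnnualPanel, read_panel, write_results
from .stability import BreakReport, CusumReport, bai_perron, cusum_test
from .stationarity import adf_test, integration_order
from .stratify import GroupComparison, compare_groups
from .var import VarError, vif_pair

__all__ = [
    "StudyConfig",
    "StudyReport",
    "STUDY_MODELS",
    "MEDIATION_TRIPLES",
    "run_battery",
    "run_study",
    "render_causality_graph",
    "ty_table",
    "stationarity_table",
]

# (model id, cause or causes, outcome); tuples of causes are joint models
# with submodels.  Models 11-12 are the reverse-causality checks.
STUDY_MODELS: tuple[tuple[str, tuple[str, ...] | str, str], ...] = (
    ("1", "GINI", "FPI"),
    ("2", "GDP_PPP", "FPI"),
    ("3", "GINI", "FI"),
    ("4", "GDP_PPP", "FI"),
    ("5", ("GINI", "FPI"), "FI"),
    ("6", ("GDP_PPP", "FPI"), "FI"),
    ("7", "FPI", "FI"),
    ("8", "FPI", "HE"),
    ("9", "FI", "HE"),
    ("10", ("FPI", "FI"), "HE"),
    ("11", "FPI", "GINI"),
    ("12", "FI", "FPI"),
)

# (X, M, Y): does M mediate the X -> Y relation?
MEDIATION_TRIPLES = (("FPI", "GINI", "FI"), ("FPI", "FI", "HE"))


@dataclass
class StudyConfig:
    """Everything needed to run the study end to end.

    ``variable_map`` renames the canonical roles (GINI, GDP_PPP, FPI, FI,
    HE) to the columns actually present — the income-stratified re-run
    substitutes CPI for FPI and FS for FI through exactly this map.
    """

    panel_path: str | None = None
    layout: str = "wide"
    year_column: str = "year"
    variable_map: dict[str, str] = field(
        default_factory=lambda: {v: v for v in ("GINI", "GDP_PPP", "FPI", "FI", "HE")}
    )
    alpha: float = 0.05
    max_p: int = 5
    lag_cap: int = 3
    d_cap: int = 2
    deterministic: str = "constant"
    stability_max_breaks: int = 5
    stability_trim: float = 0.15
    break_alpha: float = 0.10
    seed: int = 0
    out_dir: str | None = None

    def validate(self, panel: AnnualPanel) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        missing = [v for v in self.variable_map.values() if v not in panel.variables]
        if missing:
            raise ValueError(f"config references missing variable(s): {missing}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class StudyReport:
    """All stage outputs plus run metadata."""

    stationarity: list[dict]
    lag_table: list[dict]
    vif: dict[str, float]
    causality: list[dict]
    mediation: list[MediationVerdict]
    stability: dict[str, dict]
    comparisons: list[GroupComparison]
    failures: dict[str, str]
    meta: dict
    battery: dict[str, TYResult] = field(default_factory=dict, repr=False)


def _model_key(causes: tuple[str, ...], outcome: str) -> str:
    return f"{'+'.join(causes)}->{outcome}"


def run_battery(
    panel: AnnualPanel,
    variable_map: dict[str, str],
    alpha: float = 0.05,
    max_p: int = 5,
    cap: int = 3,
    d_cap: int = 2,
) -> tuple[dict[str, TYResult], dict[str, str]]:
    """Run the twelve-model battery; returns (results, failures).

    Keys are ``"X->Y"`` for simple models, ``"X+Z->Y"`` for joint models
    and ``"X+Z->Y:X"`` for submodels; joint keys are registered under both
    cause orderings so mediation scans can look them up either way.
    """
    results: dict[str, TYResult] = {}
    failures: dict[str, str] = {}
    vm = variable_map
    for model_id, causes, outcome in STUDY_MODELS:
        joint = not isinstance(causes, str)
        cause_names = tuple(vm[c] for c in (causes if joint else (causes,)))
        out_name = vm[outcome]
        key = _model_key(cause_names, out_name)
        try:
            if joint:
                trio = ty_joint_with_submodels(
                    panel, out_name, cause_names, alpha=alpha,
                    max_p=max_p, cap=cap, d_cap=d_cap, name=f"model {model_id}",
                )
                results[key] = trio["joint"]
                alias = _model_key(cause_names[::-1], out_name)
                results[alias] = trio["joint"]
                for c in cause_names:
                    results[f"{key}:{c}"] = trio[f"sub_{c}"]
                    results[f"{alias}:{c}"] = trio[f"sub_{c}"]
            else:
                spec = TYSpec(
                    outcome=out_name, cause_blocks=(cause_names,),
                    alpha=alpha, name=f"model {model_id}",
                )
                results[key] = ty_test(panel, spec, max_p=max_p, cap=cap, d_cap=d_cap)
        except (VarError, ValueError, KeyError) as exc:
            failures[key] = str(exc)
    return results, failures


def ty_table(battery: dict[str, TYResult]) -> list[dict]:
    """Flatten battery results into table rows (model, chi2, df, p, decision)."""
    rows = []
    seen = set()
    for key, res in battery.items():
        if id(res) in seen:
            continue  # skip alias entries
        seen.add(id(res))
        rows.append(
            {
                "model": key,
                "hypothesis": res.spec.name,
                "chi2": round(res.chi2, 4),
                "df": res.df,
                "p": round(res.p_value, 4),
                "p_lags": res.p_used,
                "dmax": res.dmax_used,
                "decision": "H0 rejected" if res.reject else "H0 not rejected",
            }
        )
    return rows


def stationarity_table(
    panel: AnnualPanel, variables, alpha: float = 0.05, d_cap: int = 2,
    deterministic: str = "constant",
) -> list[dict]:
    """ADF results at each differencing level up to the integration order."""
    rows = []
    for name in variables:
        d, flagged = integration_order(
            panel.series(name), d_cap=d_cap, alpha=alpha, deterministic=deterministic
        )
        x = np.asarray(panel.series(name), float)
        for dd in range(d + 1):
            res = adf_test(
                np.diff(x, n=dd), deterministic=deterministic, alpha=alpha,
                variable=name, differencing=dd,
            )
            rows.append(
                {
                    "variable": name + " (Δ)" * dd,
                    "d": dd,
                    "statistic": round(res.statistic, 4),
                    "p": round(res.p_value, 4),
                    "result": "S" if res.stationary else "NS",
                    "order": d,
                    "flagged": flagged,
                }
            )
    return rows


def _stability_stage(battery: dict[str, TYResult], config: StudyConfig) -> dict[str, dict]:
    """Per-model stability: Bai-Perron for single-cause outcome equations,
    CUSUM / CUSUM-SQ for multi-cause models, on the fitted design."""
    out: dict[str, dict] = {}
    seen = set()
    for key, res in battery.items():
        if res.fit is None or id(res) in seen or ":" in key:
            continue
        seen.add(id(res))
        fit = res.fit
        y = fit.targets[fit.equation(res.spec.outcome)]
        X = fit.design
        entry: dict = {}
        if len(res.restricted) == 1:
            h = max(int(len(y) * config.stability_trim + 0.999), X.shape[1] + 1)
            feasible = len(y) // h - 1
            max_breaks = max(min(config.stability_max_breaks, feasible), 0)
            if max_breaks >= 1:
                try:
                    br: BreakReport = bai_perron(
                        y, X, max_breaks=max_breaks, trim=config.stability_trim,
                        alpha=config.break_alpha,
                    )
                    entry["bai_perron"] = {
                        "n_breaks": br.n_breaks,
                        "break_indices": list(br.break_indices),
                        "p": round(br.p_value, 4),
                        "supf": {k: round(v, 3) for k, v in br.supf.items()},
                    }
                except VarError as exc:
                    entry["bai_perron"] = {"error": str(exc)}
            else:
                entry["bai_perron"] = {"error": "infeasible trimming for any break"}
        try:
            for variant in ("CUSUM", "CUSUM-SQ"):
                cr: CusumReport = cusum_test(y, X, variant=variant, level=config.alpha)
                entry[variant] = {
                    "crossed": cr.crossed,
                    "statistic": round(cr.statistic, 4),
                    "p": round(cr.p_value, 4),
                }
        except VarError as exc:
            entry["cusum_error"] = str(exc)
        out[key] = entry
    return out


def run_study(
    config: StudyConfig,
    panel: AnnualPanel | None = None,
    group_panels: dict[str, AnnualPanel] | None = None,
    group_variable_map: dict[str, str] | None = None,
) -> StudyReport:
    """Execute the full pipeline.

    Stages: read -> stationarity/dmax -> per-model lag selection with cap
    -> VIF screen -> causality battery -> mediation scan -> stability ->
    optional stratified battery with cross-group comparisons.  ``panel``
    may be passed directly (e.g. a synthetic panel); otherwise it is read
    from ``config.panel_path``.  ``group_panels`` maps group names (e.g.
    ``low_income`` / ``high_income``) to per-group panels for the
    stratified re-run, using ``group_variable_map`` for the variable
    substitutions (CPI for FPI, FS for FI).
    """
    if panel is None:
        if config.panel_path is None:
            raise ValueError("either a panel or config.panel_path is required")
        panel = read_panel(config.panel_path, layout=config.layout, year_column=config.year_column)
    config.validate(panel)
    vm = config.variable_map

    stat_rows = stationarity_table(
        panel, [vm[v] for v in ("GINI", "GDP_PPP", "FPI", "FI", "HE") if v in vm],
        alpha=config.alpha, d_cap=config.d_cap, deterministic=config.deterministic,
    )

    battery, failures = run_battery(
        panel, vm, alpha=config.alpha, max_p=config.max_p,
        cap=config.lag_cap, d_cap=config.d_cap,
    )

    lag_rows = [
        {
            "model": key, "chosen_p": res.p_used, "dmax": res.dmax_used,
            "cap_applied": bool(res.lag_selection and res.lag_selection.cap_applied),
        }
        for key, res in battery.items()
        if ":" not in key and res.lag_selection is not None
    ]

    vif: dict[str, float] = {}
    for model_id, causes, outcome in STUDY_MODELS:
        if isinstance(causes, str):
            continue
        a, b = (vm[c] for c in causes)
        try:
            vif[f"{a},{b}"] = round(vif_pair(panel.series(a), panel.series(b)), 2)
        except ValueError as exc:
            failures[f"vif:{a},{b}"] = str(exc)

    triples = [tuple(vm[r] for r in triple) for triple in MEDIATION_TRIPLES]
    try:
        verdicts = scan_triples(battery, triples, alpha=config.alpha)
    except KeyError as exc:
        verdicts = []
        failures["mediation"] = str(exc)

    stability = _stability_stage(battery, config)

    comparisons: list[GroupComparison] = []
    if group_panels:
        gvm = group_variable_map or vm
        group_results = {}
        for gname, gpanel in group_panels.items():
            gbattery, gfail = run_battery(
                gpanel, gvm, alpha=config.alpha, max_p=config.max_p,
                cap=config.lag_cap, d_cap=config.d_cap,
            )
            group_results[gname] = gbattery
            failures.update({f"{gname}:{k}": v for k, v in gfail.items()})
        names = sorted(group_panels)
        if len(names) == 2:
            low = next((n for n in names if "low" in n), names[0])
            high = next((n for n in names if n != low), names[1])
            seen_pairs: set[tuple[int, int]] = set()
            for key in group_results[low]:
                if key not in group_results[high]:
                    continue
                pair = (id(group_results[low][key]), id(group_results[high][key]))
                if pair in seen_pairs:
                    continue  # alias key (same joint model under both cause orders)
                seen_pairs.add(pair)
                comparisons.append(
                    compare_groups(group_results[low][key], group_results[high][key], model=key)
                )

    report = StudyReport(
        stationarity=stat_rows,
        lag_table=lag_rows,
        vif=vif,
        causality=ty_table(battery),
        mediation=verdicts,
        stability=stability,
        comparisons=comparisons,
        failures=failures,
        meta={
            "seed": config.seed,
            "alpha": config.alpha,
            "lag_cap": config.lag_cap,
            "config_hash": config.config_hash(),
            "n_years": panel.n_years,
            "span": [panel.years[0], panel.years[-1]],
        },
        battery=battery,
    )
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_results(report.stationarity, out / "stationarity.csv", format="csv")
        write_results(report.causality, out / "causality.csv", format="csv")
        write_results(report.mediation, out / "mediation.json", format="json")
        write_results(report.stability, out / "stability.json", format="json")
        write_results([asdict(c) for c in report.comparisons], out / "comparisons.csv", format="csv")
        write_results(report.meta | {"vif": report.vif, "failures": report.failures},
                      out / "run_meta.json", format="json")
        (out / "causality_graph.dot").write_text(render_causality_graph(report))
    return report


def render_causality_graph(report: StudyReport, alpha: float | None = None) -> str:
    """DOT causality diagram: solid edges = significant direct causality
    (annotated with the tested lag), dashed edges = mediated paths."""
    lines = ["digraph causality {", "  rankdir=LR;", "  node [shape=box];"]
    nodes: set[str] = set()
    for key, res in report.battery.items():
        if ":" in key or len(res.restricted) != 1 or not res.reject:
            continue
        src, dst = res.restricted[0], res.spec.outcome
        nodes.update((src, dst))
        lines.append(f'  "{src}" -> "{dst}" [label="lag {res.p_used}"];')
    for v in report.mediation:
        if v.label in ("full_mediation", "partial_mediation"):
            nodes.update((v.x, v.m, v.y))
            lines.append(
                f'  "{v.x}" -> "{v.y}" [style=dashed, label="via {v.m}"];'
            )
    # ensure all battery variables appear even in an edgeless graph
    for res in report.battery.values():
        nodes.update(res.spec.variables)
    for n in sorted(nodes):
        lines.append(f'  "{n}";')
    lines.append("}")
    return "\n".join(lines) + "\n"
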