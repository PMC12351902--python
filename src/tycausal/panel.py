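"""Annual panel and country cross-section containers plus CSV/JSON plumbing.

The whole pipeline operates on two containers:

* :class:`AnnualPanel` — a small year-indexed multivariate time series
  (e.g. global GINI, GDP_PPP, FPI, FI, HE).  Years are strictly contiguous
  and the value block is complete: reading trims to the maximal contiguous
  span on which every requested variable is observed, and never interpolates.
* :class:`CountryCrossSection` — a single-year country × feature matrix used
  for income-group clustering.

Reports produced by the statistical stages are plain dataclasses; they are
serialized through :func:`write_results` (JSON, or flat CSV).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, is_dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AnnualPanel",
    "CountryCrossSection",
    "PanelError",
    "read_panel",
    "write_results",
]


class PanelError(ValueError):
    """Raised for malformed panel inputs (gaps, duplicates, empty spans)."""


@dataclass(frozen=True)
class AnnualPanel:
    """Year-indexed multivariate annual series.

    Parameters
    ----------
    years
        Strictly increasing consecutive calendar years.
    variables
        Unique variable names, one per row of ``values``.
    values
        ``(n_variables, n_years)`` float matrix with no missing cells.
    meta
        Free-form provenance map (source, units, trimming notes).
    """

    years: tuple[int, ...]
    variables: tuple[str, ...]
    values: np.ndarray
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        years = tuple(int(y) for y in self.years)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "variables", tuple(self.variables))
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if len(set(self.variables)) != len(self.variables):
            raise PanelError("duplicate variable names")
        if vals.shape != (len(self.variables), len(years)):
            raise PanelError(
                f"values shape {vals.shape} does not match "
                f"{len(self.variables)} variables x {len(years)} years"
            )
        if len(years) == 0:
            raise PanelError("empty year span")
        if any(b - a != 1 for a, b in zip(years, years[1:])):
            raise PanelError("years must be consecutive")
        if not np.all(np.isfinite(vals)):
            raise PanelError("missing or non-finite values inside the panel span")

    @property
    def n_years(self) -> int:
        return len(self.years)

    def series(self, name: str) -> np.ndarray:
        """Return one variable as a 1-d array ordered by year."""
        try:
            i = self.variables.index(name)
        except ValueError:
            raise KeyError(f"variable {name!r} not in panel") from None
        return self.values[i]

    def subset(self, names: Sequence[str]) -> "AnnualPanel":
        """Panel restricted to ``names``, preserving the given order."""
        rows = [self.series(n) for n in names]
        return AnnualPanel(self.years, tuple(names), np.vstack(rows), dict(self.meta))

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame: index = year, one column per variable."""
        return pd.DataFrame(
            self.values.T, index=pd.Index(self.years, name="year"), columns=list(self.variables)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, meta: Mapping | None = None) -> "AnnualPanel":
        return cls(
            tuple(int(y) for y in frame.index),
            tuple(map(str, frame.columns)),
            frame.to_numpy().T,
            dict(meta or {}),
        )


@dataclass(frozen=True)
class CountryCrossSection:
    """Country × feature matrix for a single reference year."""

    country_ids: tuple[str, ...]
    feature_names: tuple[str, ...]
    features: np.ndarray
    year: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "country_ids", tuple(map(str, self.country_ids)))
        object.__setattr__(self, "feature_names", tuple(map(str, self.feature_names)))
        feats = np.asarray(self.features, dtype=float)
        object.__setattr__(self, "features", feats)
        if feats.ndim != 2 or feats.shape != (len(self.country_ids), len(self.feature_names)):
            raise PanelError("features must be (country x feature)")
        if len(self.country_ids) < 2:
            raise PanelError("need at least 2 countries")
        if feats.shape[1] < 1:
            raise PanelError("need at least 1 feature")
        if not np.all(np.isfinite(feats)):
            raise PanelError("missing cells in cross-section")


def _trim_contiguous(frame: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Maximal contiguous run of years with all variables present.

    Returns the trimmed frame and the number of years dropped.
    """
    complete = frame.dropna()
    if complete.empty:
        raise PanelError("empty intersection span: no year has all variables")
    years = complete.index.to_numpy()
    # split into runs of consecutive years, keep the longest (latest on ties)
    breaks = np.flatnonzero(np.diff(years) != 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(years) - 1]])
    lengths = ends - starts + 1
    best = np.flatnonzero(lengths == lengths.max())[-1]
    run = complete.iloc[starts[best] : ends[best] + 1]
    return run, len(frame.index) - len(run)


def read_panel(
    path: str | Path,
    layout: str = "wide",
    year_column: str = "year",
    variables: Sequence[str] | None = None,
) -> AnnualPanel:
    """Read an annual panel from CSV.

    ``layout="wide"`` expects one column per variable plus a year column;
    ``layout="long"`` expects columns ``(variable, year, value)``.  The result
    is trimmed to the maximal contiguous span where all requested variables
    are present; the dropped-year count is recorded in ``meta``.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if layout == "long":
        required = {"variable", year_column, "value"}
        if not required.issubset(df.columns):
            raise PanelError(f"long layout requires columns {sorted(required)}")
        dup = df.duplicated(subset=["variable", year_column])
        if dup.any():
            bad = df.loc[dup, ["variable", year_column]].iloc[0]
            raise PanelError(f"duplicate cell ({bad['variable']}, {bad[year_column]})")
        wide = df.pivot(index=year_column, columns="variable", values="value")
    elif layout == "wide":
        if year_column not in df.columns:
            raise PanelError(f"wide layout requires a {year_column!r} column")
        if df[year_column].duplicated().any():
            y = df.loc[df[year_column].duplicated(), year_column].iloc[0]
            raise PanelError(f"duplicate cell (year {y})")
        wide = df.set_index(year_column)
    else:
        raise PanelError(f"unknown layout {layout!r}")

    try:
        wide.index = wide.index.astype(int)
    except (TypeError, ValueError) as exc:
        raise PanelError(f"unparseable years in column {year_column!r}") from exc
    wide = wide.sort_index()
    if variables is not None:
        missing = set(variables) - set(wide.columns)
        if missing:
            raise PanelError(f"variables not in file: {sorted(missing)}")
        wide = wide[list(variables)]
    wide = wide.astype(float)

    trimmed, dropped = _trim_contiguous(wide)
    meta = {"source": str(path), "dropped_years": dropped}
    return AnnualPanel.from_frame(trimmed, meta)


def write_panel(panel: AnnualPanel, path: str | Path) -> None:
    """Write a panel as wide CSV (inverse of :func:`read_panel`)."""
    panel.to_frame().to_csv(path, index=True, float_format="%.12g")


def _to_jsonable(obj: Any) -> Any:
    if is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (bool, int, float, str)) or obj is None:
        return obj
    return str(obj)


def _flatten(obj: Any, prefix: str = "") -> dict[str, Any]:
    out: dict[str, Any] = {}
    if isinstance(obj, dict):
        for k, v in obj.items():
            key = f"{prefix}.{k}" if prefix else str(k)
            out.update(_flatten(v, key))
    elif isinstance(obj, list):
        out[prefix] = json.dumps(obj)
    else:
        out[prefix] = obj
    return out


def write_results(results: Any, path: str | Path, format: str = "json") -> None:
    """Serialize a stage report (dataclass, dict, or a list of them).

    JSON preserves nesting losslessly; CSV flattens each record into one row
    (nested fields become dotted column names, lists become JSON strings).
    """
    path = Path(path)
    payload = _to_jsonable(results)
    if format == "json":
        path.write_text(json.dumps(payload, indent=2, allow_nan=True) + "\n")
    elif format == "csv":
        records = payload if isinstance(payload, list) else [payload]
        rows = [_flatten(r) for r in records]
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_results(path: str | Path) -> Any:
    """Read back a JSON report written by :func:`write_results`."""
    return json.loads(Path(path).read_text())
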