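"""File ingestion, validation and configuration.

All tabular I/O is UTF-8 comma-separated text with a header row.  Judgment
matrices are wide CSV (first row and column carry item names) and accept
fractional entries written as strings like ``1/3``.  The hierarchy is a
YAML/JSON config listing domains and criteria in display order.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .ahp import ExpertProfile, PairwiseComparisonMatrix
from .econ import CoverageSurvey, DosingRegimen
from .hierarchy import CriteriaHierarchy
from .scoring import ScorePanel
from .sensitivity import WeightScenario
from .utils import ValidationError


def parse_ratio(text) -> float:
    """Parse a judgment entry: a plain number or a fraction like '1/3'."""
    if isinstance(text, (int, float)):
        return float(text)
    s = str(text).strip()
    if "/" in s:
        num, den = s.split("/", 1)
        return float(num) / float(den)
    return float(s)


def read_matrix_csv(path, node: str = "", **kwargs) -> PairwiseComparisonMatrix:
    """Read a judgment matrix from wide CSV (names in first row/column)."""
    df = pd.read_csv(path, index_col=0)
    labels = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != labels:
        raise ValidationError(
            f"{path}: row and column names differ ({list(df.index)} vs {labels})"
        )
    values = np.array([[parse_ratio(v) for v in row] for row in df.to_numpy()])
    return PairwiseComparisonMatrix(values, labels, node or Path(str(path)).stem, **kwargs)


def write_matrix_csv(matrix: PairwiseComparisonMatrix, path) -> None:
    pd.DataFrame(matrix.values, index=matrix.labels, columns=matrix.labels).to_csv(path)


def read_hierarchy(path) -> CriteriaHierarchy:
    """Read a hierarchy definition from YAML/JSON:

    .. code-block:: yaml

        domains:
          - name: safety
            weight: 0.3855
            criteria:
              - {name: A1, weight: 0.5141}
              - {name: A2, weight: 0.2322}
    """
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "domains" not in cfg:
        raise ValidationError(f"{path}: expected a mapping with a 'domains' list")
    dom_w = {}
    crit_w: dict[str, dict[str, float]] = {}
    for d in cfg["domains"]:
        dom_w[d["name"]] = float(d["weight"])
        crit_w[d["name"]] = {
            c["name"]: float(c["weight"]) for c in d.get("criteria", [])
        }
    return CriteriaHierarchy.from_local(dom_w, crit_w)


def read_global_weights_csv(path, *, normalize: bool = True) -> CriteriaHierarchy:
    """Read a hierarchy from CSV columns domain, criterion, global_weight."""
    return CriteriaHierarchy.from_global(pd.read_csv(path), normalize=normalize)


def read_panel_csv(path) -> ScorePanel:
    return ScorePanel.from_csv(path)


def read_scenarios_csv(path) -> list[WeightScenario]:
    """Scenarios CSV: column scenario_id plus one column per domain (percent)."""
    df = pd.read_csv(path)
    if "scenario_id" not in df.columns:
        raise ValidationError(f"{path}: missing scenario_id column")
    domains = [c for c in df.columns if c != "scenario_id"]
    return [
        WeightScenario(str(r["scenario_id"]), {d: float(r[d]) for d in domains})
        for _, r in df.iterrows()
    ]


def write_scenarios_csv(scenarios, path) -> None:
    rows = []
    for sc in scenarios:
        row = {"scenario_id": sc.scenario_id}
        row.update(sc.weights)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_reports_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"report_id", "drug", "event"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_aggregated_signals_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"event", "a", "b", "c", "d"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_survey_csv(path) -> CoverageSurvey:
    """Survey CSV: columns institution_type, stocked, total."""
    df = pd.read_csv(path)
    missing = {"institution_type", "stocked", "total"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return CoverageSurvey(
        {
            str(r["institution_type"]): (int(r["stocked"]), int(r["total"]))
            for _, r in df.iterrows()
        }
    )


def read_roster_csv(path) -> list[ExpertProfile]:
    """Expert roster CSV: columns expert_id, ca, cs."""
    df = pd.read_csv(path)
    missing = {"expert_id", "ca", "cs"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return [
        ExpertProfile(str(r["expert_id"]), float(r["ca"]), float(r["cs"]))
        for _, r in df.iterrows()
    ]


# -- run configuration ----------------------------------------------------


@dataclass
class SignalThresholds:
    prr: float = 2.0
    chi2: float = 4.0
    min_cases: int = 3
    ci_level: float = 0.95
    yates: bool = True

    def __post_init__(self) -> None:
        if min(self.prr, self.chi2, self.min_cases) <= 0 or not 0 < self.ci_level < 1:
            raise ValidationError("signal thresholds must be positive, CI level in (0,1)")


@dataclass
class EconomicsConfig:
    regimens: dict[str, DosingRegimen] = field(default_factory=dict)
    incomes: dict[str, float] = field(default_factory=dict)
    household_size: float = 2.62


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (paths relative to the config
    file's directory)."""

    hierarchy: Path | None = None
    weights_csv: Path | None = None
    normalize_weights: bool = True
    panel: Path | None = None
    scenarios: Path | None = None
    reports: Path | None = None
    target_drug: str | None = None
    survey: Path | None = None
    economics: EconomicsConfig | None = None
    thresholds: SignalThresholds = field(default_factory=SignalThresholds)
    output_dir: Path = Path("mcda_out")
    seed: int = 0
    verbosity: int = 1


def load_config(path) -> RunConfig:
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    base = path.parent

    def _p(key):
        return (base / raw[key]).resolve() if raw.get(key) else None

    econ = None
    if "economics" in raw:
        e = raw["economics"]
        econ = EconomicsConfig(
            regimens={
                arm: DosingRegimen(
                    float(r["price_per_vial"]),
                    int(r["vials_per_administration"]),
                    int(r["administrations_per_year"]),
                )
                for arm, r in e.get("regimens", {}).items()
            },
            incomes={k: float(v) for k, v in e.get("incomes", {}).items()},
            household_size=float(e.get("household_size", 2.62)),
        )
    thresholds = SignalThresholds(**raw.get("thresholds", {}))
    return RunConfig(
        hierarchy=_p("hierarchy"),
        weights_csv=_p("weights_csv"),
        normalize_weights=bool(raw.get("normalize_weights", True)),
        panel=_p("panel"),
        scenarios=_p("scenarios"),
        reports=_p("reports"),
        target_drug=raw.get("target_drug"),
        survey=_p("survey"),
        economics=econ,
        thresholds=thresholds,
        output_dir=(base / raw.get("output_dir", "mcda_out")).resolve(),
        seed=int(raw.get("seed", 0)),
        verbosity=int(raw.get("verbosity", 1)),
    )


# -- validation -----------------------------------------------------------


@dataclass
class ValidationIssue:
    path: str
    kind: str
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue]

    @property
    def ok(self) -> bool:
        return not self.issues

    def __str__(self) -> str:
        if self.ok:
            return "all inputs valid"
        return "\n".join(f"{i.path}: [{i.kind}] {i.message}" for i in self.issues)


_READERS = {
    "matrix": read_matrix_csv,
    "hierarchy": read_hierarchy,
    "weights": read_global_weights_csv,
    "panel": read_panel_csv,
    "scenarios": read_scenarios_csv,
    "reports": read_reports_csv,
    "aggregated": read_aggregated_signals_csv,
    "survey": read_survey_csv,
    "roster": read_roster_csv,
}


def validate_inputs(paths: Mapping[str, Any]) -> ValidationReport:
    """Check every input file against its schema, collecting all violations
    (not fail-fast).  ``paths`` maps a schema kind (see keys of the reader
    registry: matrix, hierarchy, weights, panel, scenarios, reports,
    aggregated, survey, roster) to one path or a list of paths."""
    issues: list[ValidationIssue] = []
    for kind, entry in paths.items():
        if kind not in _READERS:
            issues.append(ValidationIssue(str(entry), "config", f"unknown input kind '{kind}'"))
            continue
        entries = entry if isinstance(entry, (list, tuple)) else [entry]
        for p in entries:
            try:
                _READERS[kind](p)
            except ValidationError as exc:
                issues.append(ValidationIssue(str(p), "schema", str(exc)))
            except FileNotFoundError:
                issues.append(ValidationIssue(str(p), "io", "file not found"))
            except OSError as exc:
                issues.append(ValidationIssue(str(p), "io", str(exc)))
            except Exception as exc:  # malformed CSV/YAML etc.
                issues.append(ValidationIssue(str(p), "parse", str(exc)))
    return ValidationReport(issues)


def dataclass_to_jsonable(obj):
    """Recursively convert dataclasses / paths / pandas objects for JSON."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: dataclass_to_jsonable(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="split"))
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, dict):
        return {k: dataclass_to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [dataclass_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
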