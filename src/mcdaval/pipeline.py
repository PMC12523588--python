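"""End-to-end pipeline: weights -> scores -> sensitivity -> signals -> economics.

``run_pipeline`` executes whichever stages the configuration covers, writes
per-table CSV outputs plus one JSON bundle and a run manifest (input hashes,
package version, seed), and removes partial outputs if any stage fails.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .econ import economics_summary
from .io import RunConfig, dataclass_to_jsonable, read_global_weights_csv, read_hierarchy, read_panel_csv, read_reports_csv, read_scenarios_csv, read_survey_csv
from .model import MCDAModel
from .signals import DisproportionalityModel
from .utils import ValidationError

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class _StageTimer:
    def __init__(self, stage: str, verbosity: int) -> None:
        self.stage = stage
        self.verbosity = verbosity

    def __enter__(self):
        self.t0 = time.perf_counter()
        if self.verbosity:
            print(f"[{self.stage}] ...", file=sys.stderr)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if self.verbosity:
            status = "done" if exc_type is None else "FAILED"
            print(f"[{self.stage}] {status} in {dt:.2f}s", file=sys.stderr)
        return False


def run_pipeline(config: RunConfig) -> dict:
    """Run all configured stages; returns the result objects keyed by stage.

    Outputs written to ``config.output_dir``: value_report.csv,
    sensitivity.csv, signals.csv, economics CSVs, bundle.json, manifest.json.
    Any stage failure aborts with a stage-named error and removes files
    already written for this run.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    results: dict = {}
    bundle: dict = {}

    def _write_csv(df: pd.DataFrame, name: str, **kwargs) -> None:
        p = out / name
        df.to_csv(p, **kwargs)
        written.append(p)

    try:
        hierarchy = None
        if config.weights_csv:
            with _StageTimer("weights", config.verbosity):
                hierarchy = read_global_weights_csv(
                    config.weights_csv, normalize=config.normalize_weights
                )
        elif config.hierarchy:
            with _StageTimer("weights", config.verbosity):
                hierarchy = read_hierarchy(config.hierarchy)

        if hierarchy is not None and config.panel:
            with _StageTimer("score", config.verbosity):
                panel = read_panel_csv(config.panel)
                fit = MCDAModel(hierarchy, panel).fit()
                results["value"] = fit
                _write_csv(fit.report.criterion_scores, "value_report.csv", index=False)
                bundle["value"] = json.loads(fit.report.to_json())

            if config.scenarios:
                with _StageTimer("sensitivity", config.verbosity):
                    scenarios = read_scenarios_csv(config.scenarios)
                    stab = fit.sensitivity(scenarios)
                    results["sensitivity"] = stab
                    _write_csv(stab.scenario_overall, "sensitivity.csv")
                    bundle["sensitivity"] = {
                        "baseline": stab.baseline_overall.to_dict(),
                        "scenarios": dataclass_to_jsonable(stab.scenario_overall),
                        "margins": stab.margins.to_dict(),
                        "stable": bool(stab.stable),
                    }

        if config.reports and config.target_drug:
            with _StageTimer("signal", config.verbosity):
                reports = read_reports_csv(config.reports)
                screen = DisproportionalityModel(
                    reports,
                    config.target_drug,
                    prr_threshold=config.thresholds.prr,
                    chi2_threshold=config.thresholds.chi2,
                    min_cases=config.thresholds.min_cases,
                    ci_level=config.thresholds.ci_level,
                    yates=config.thresholds.yates,
                ).fit()
                results["signals"] = screen
                _write_csv(screen.frame, "signals.csv", index=False)
                bundle["signals"] = dataclass_to_jsonable(screen.frame)

        if config.economics:
            with _StageTimer("afford", config.verbosity):
                survey = read_survey_csv(config.survey) if config.survey else None
                econ = economics_summary(
                    config.economics.regimens,
                    config.economics.incomes,
                    config.economics.household_size,
                    survey,
                )
                results["economics"] = econ
                _write_csv(econ["costs"], "economics_costs.csv")
                _write_csv(econ["affordability"], "economics_affordability.csv")
                if "coverage" in econ:
                    _write_csv(econ["coverage"].to_frame(), "economics_coverage.csv")
                bundle["economics"] = dataclass_to_jsonable(econ)

        if not results:
            raise ValidationError("configuration enables no pipeline stage")

        bundle_path = out / "bundle.json"
        bundle_path.write_text(json.dumps(bundle, indent=2, sort_keys=True))
        written.append(bundle_path)

        inputs = {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in {
                "hierarchy": config.hierarchy,
                "weights_csv": config.weights_csv,
                "panel": config.panel,
                "scenarios": config.scenarios,
                "reports": config.reports,
                "survey": config.survey,
            }.items()
            if p
        }
        manifest = {
            "package": "mcdaval",
            "version": __version__,
            "seed": config.seed,
            "inputs": inputs,
            "outputs": [str(p) for p in written],
        }
        manifest_path = out / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        results["manifest"] = manifest
        return results
    except Exception:
        # a failed stage must not leave partial outputs behind
        for p in written:
            p.unlink(missing_ok=True)
        raise
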