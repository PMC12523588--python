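"""Pharmacovigilance disproportionality analysis for spontaneous reports.

For a target drug and adverse event the report database collapses to a 2x2
table (a = drug & event, b = drug & other events, c = other drugs & event,
d = other drugs & other events).  Signal statistics:

* PRR = (a/(a+b)) / (c/(c+d)), flagged positive when PRR > 2 together with a
  Pearson chi-squared >= 4 (Yates-corrected by default),
* ROR = ad/bc with a Woolf (log-normal) confidence interval, flagged
  positive when the case count a >= 3 and the CI lower bound exceeds 1.

A drug-event pair counts as a signal only when *both* rules fire.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .utils import ValidationError

DEFAULT_PRR_THRESHOLD = 2.0
DEFAULT_CHI2_THRESHOLD = 4.0
DEFAULT_MIN_CASES = 3


@dataclass(frozen=True)
class ContingencyTable:
    """Drug/event report counts: a, b, c, d (all nonnegative integers)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValidationError(f"cell {name} = {v} must be a nonnegative integer")
            object.__setattr__(self, name, int(v))

    @property
    def n_case(self) -> int:
        """Number of co-occurrence reports (the N of the ROR rule)."""
        return self.a

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def corrected(self) -> "_CorrectedTable":
        """Haldane-Anscombe continuity correction: +0.5 on all four cells."""
        return _CorrectedTable(self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)

    def swapped(self) -> "ContingencyTable":
        """Exchange the drug rows: (a,b) <-> (c,d)."""
        return ContingencyTable(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class _CorrectedTable:
    a: float
    b: float
    c: float
    d: float

    @property
    def n_case(self) -> float:
        return self.a


def _cells(table, correction: bool):
    t = table.corrected() if correction else table
    return t.a, t.b, t.c, t.d


def prr(table: ContingencyTable, *, correction: bool = False) -> float:
    """Proportional reporting ratio (a/(a+b)) / (c/(c+d)).

    Requires a+b > 0, c+d > 0 and c > 0; with ``correction`` the
    Haldane-Anscombe +0.5 adjustment makes zero cells admissible.
    """
    a, b, c, d = _cells(table, correction)
    if a + b == 0 or c + d == 0 or c == 0 or a == 0:
        raise ValidationError(
            f"PRR undefined for cells a={table.a}, b={table.b}, c={table.c}, "
            f"d={table.d}; enable the continuity correction for zero cells"
        )
    return (a / (a + b)) / (c / (c + d))


def ror_with_ci(
    table: ContingencyTable,
    level: float = 0.95,
    *,
    correction: bool = False,
) -> tuple[float, float, float]:
    """Reporting odds ratio ad/bc with a Woolf confidence interval.

    CI = exp(ln ROR +- z * sqrt(1/a + 1/b + 1/c + 1/d)) at the requested
    level.  All four cells must be positive unless ``correction`` is set.
    """
    if not 0.0 < level < 1.0:
        raise ValidationError(f"confidence level {level} outside (0, 1)")
    a, b, c, d = _cells(table, correction)
    if min(a, b, c, d) == 0:
        raise ValidationError(
            f"ROR undefined with a zero cell (a={table.a}, b={table.b}, "
            f"c={table.c}, d={table.d}); enable the continuity correction"
        )
    ror = (a * d) / (b * c)
    z = stats.norm.ppf(0.5 + level / 2.0)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = float(np.exp(np.log(ror) - z * se))
    hi = float(np.exp(np.log(ror) + z * se))
    return float(ror), lo, hi


def chi2(table: ContingencyTable, *, yates: bool = True) -> float:
    """Pearson chi-squared statistic of the 2x2 table (Yates continuity
    correction on by default).  Zero margins are rejected."""
    obs = np.array([[table.a, table.b], [table.c, table.d]], dtype=float)
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValidationError(
            f"chi-squared undefined: zero margin in table a={table.a}, "
            f"b={table.b}, c={table.c}, d={table.d}"
        )
    stat, _, _, _ = stats.chi2_contingency(obs, correction=yates)
    return float(stat)


@dataclass(frozen=True)
class SignalResult:
    """Disproportionality statistics and the dual-rule verdict for one
    drug-event pair."""

    event: str
    n_case: int
    prr: float
    chi2: float
    ror: float
    ror_ci_low: float
    ror_ci_high: float
    prr_positive: bool
    ror_positive: bool
    signal: bool


def apply_signal_rule(
    prr_value: float,
    chi2_value: float,
    n_case: int,
    ci_low: float,
    *,
    prr_threshold: float = DEFAULT_PRR_THRESHOLD,
    chi2_threshold: float = DEFAULT_CHI2_THRESHOLD,
    min_cases: int = DEFAULT_MIN_CASES,
) -> tuple[bool, bool, bool]:
    """Dual positivity rule on already-computed statistics.

    PRR-positive iff PRR > 2 (strict) and chi2 >= 4; ROR-positive iff
    N >= 3 and the CI lower bound > 1 (strict).  Signal iff both.
    """
    prr_pos = (prr_value > prr_threshold) and (chi2_value >= chi2_threshold)
    ror_pos = (n_case >= min_cases) and (ci_low > 1.0)
    return prr_pos, ror_pos, prr_pos and ror_pos


def flag_signal(
    table: ContingencyTable,
    *,
    event: str = "",
    prr_threshold: float = DEFAULT_PRR_THRESHOLD,
    chi2_threshold: float = DEFAULT_CHI2_THRESHOLD,
    min_cases: int = DEFAULT_MIN_CASES,
    ci_level: float = 0.95,
    yates: bool = True,
    correction: bool = False,
) -> SignalResult:
    """Compute PRR, chi-squared, ROR with CI, and the dual-rule verdict."""
    p = prr(table, correction=correction)
    x2 = chi2(table, yates=yates)
    r, lo, hi = ror_with_ci(table, ci_level, correction=correction)
    prr_pos, ror_pos, sig = apply_signal_rule(
        p,
        x2,
        table.n_case,
        lo,
        prr_threshold=prr_threshold,
        chi2_threshold=chi2_threshold,
        min_cases=min_cases,
    )
    return SignalResult(
        event=event,
        n_case=table.n_case,
        prr=p,
        chi2=x2,
        ror=r,
        ror_ci_low=lo,
        ror_ci_high=hi,
        prr_positive=prr_pos,
        ror_positive=ror_pos,
        signal=sig,
    )


def _norm_name(x: str) -> str:
    return str(x).strip().casefold()


def tabulate_events(
    reports: pd.DataFrame, target_drug: str
) -> dict[str, ContingencyTable]:
    """Collapse case-level (report_id, drug, event) rows into one 2x2 table
    per event for the target drug.

    Drug and event names are normalized by case-folding and whitespace
    trimming only.  Rows are assumed deduplicated (one row per report).
    """
    required = {"report_id", "drug", "event"}
    if not required.issubset(reports.columns):
        raise ValidationError(f"report table needs columns {sorted(required)}")
    if len(reports) == 0:
        raise ValidationError("empty report table")
    df = reports.copy()
    df["drug"] = df["drug"].map(_norm_name)
    df["event"] = df["event"].map(_norm_name)
    target = _norm_name(target_drug)
    is_target = df["drug"] == target
    n_target = int(is_target.sum())
    n_other = int((~is_target).sum())
    tables: dict[str, ContingencyTable] = {}
    target_counts = df.loc[is_target, "event"].value_counts()
    other_counts = df.loc[~is_target, "event"].value_counts()
    for event in sorted(set(df["event"])):
        a = int(target_counts.get(event, 0))
        c = int(other_counts.get(event, 0))
        tables[event] = ContingencyTable(a, n_target - a, c, n_other - c)
    return tables


def screen_events(
    reports: pd.DataFrame,
    target_drug: str,
    *,
    min_cases: int = DEFAULT_MIN_CASES,
    correction: bool = True,
    **rule_kwargs,
) -> list[SignalResult]:
    """Disproportionality screen of every event reported with the target
    drug, sorted by case count (descending), then PRR (descending), then
    event name.

    Events never co-reported with the target drug (a = 0) are reported with
    NaN statistics and no signal; the Haldane-Anscombe correction (on by
    default here, where arbitrary sparse tables occur) handles other zero
    cells.
    """
    tables = tabulate_events(reports, target_drug)
    results = []
    for event, t in tables.items():
        try:
            if t.a == 0:
                raise ValidationError("no co-occurrence reports")
            results.append(
                flag_signal(
                    t, event=event, min_cases=min_cases, correction=correction,
                    **rule_kwargs,
                )
            )
        except ValidationError:
            # degenerate table (no co-reports, zero margin): not a signal
            results.append(
                SignalResult(event, t.a, np.nan, np.nan, np.nan, np.nan, np.nan,
                             False, False, False)
            )
    results.sort(key=lambda r: (-r.n_case, -(r.prr if np.isfinite(r.prr) else -np.inf), r.event))
    return results


def results_frame(results: Iterable[SignalResult]) -> pd.DataFrame:
    """Tabular view of screen results mirroring a published signal table:
    event, frequency, PRR, chi2, ROR and its CI bounds, plus verdict flags."""
    return pd.DataFrame(
        [
            {
                "event": r.event,
                "frequency": r.n_case,
                "prr": r.prr,
                "chi2": r.chi2,
                "ror": r.ror,
                "ci_low": r.ror_ci_low,
                "ci_high": r.ror_ci_high,
                "prr_positive": r.prr_positive,
                "ror_positive": r.ror_positive,
                "signal": r.signal,
            }
            for r in results
        ]
    )


class DisproportionalityModel:
    """Model object for a disproportionality screen of a report database.

    Parameters
    ----------
    reports
        Case-level frame with columns report_id, drug, event (one row per
        drug-event mention, deduplicated).
    target_drug
        Drug whose event profile is screened against the background.
    thresholds
        Optional overrides of the signal rule (prr_threshold,
        chi2_threshold, min_cases, ci_level, yates).
    """

    def __init__(self, reports: pd.DataFrame, target_drug: str, **thresholds) -> None:
        self.reports = reports
        self.target_drug = target_drug
        self.thresholds = thresholds

    def fit(self) -> "SignalScreenResults":
        results = screen_events(self.reports, self.target_drug, **self.thresholds)
        return SignalScreenResults(self, results)


class SignalScreenResults:
    """Results of a disproportionality screen."""

    def __init__(self, model: DisproportionalityModel, results: list[SignalResult]):
        self.model = model
        self.results = results
        self.frame = results_frame(results)

    @property
    def signals(self) -> list[SignalResult]:
        return [r for r in self.results if r.signal]

    def summary(self) -> str:
        df = self.frame.copy()
        for col in ("prr", "chi2", "ror", "ci_low", "ci_high"):
            df[col] = df[col].map(lambda v: f"{v:.2f}" if np.isfinite(v) else "-")
        lines = [
            f"Disproportionality screen: drug '{self.model.target_drug}', "
            f"{len(self.results)} events, {len(self.signals)} signals",
            "",
            df.to_string(index=False),
        ]
        return "\n".join(lines)
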