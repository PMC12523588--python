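"""Economic and accessibility calculators.

Annual treatment cost from a dosing regimen, daily cost, affordability as the
share of annual household disposable income (per-capita income times household
size), and formulary coverage rates across surveyed institutions.  All money
arithmetic is plain floating point with two-decimal half-up rounding at
presentation only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .utils import ValidationError, round_half_up

#: Days per year used for daily-cost conversion (calendar convention of the
#: published tables: annual / 365).
DAYS_PER_YEAR = 365

#: Default household size (persons) multiplying per-capita income into
#: household income.  Calibrated by :func:`calibrate_household_size` against
#: the published affordability table; see docs/methods.md.
DEFAULT_HOUSEHOLD_SIZE = 2.62


@dataclass(frozen=True)
class DosingRegimen:
    """A fixed dosing schedule priced per vial."""

    price_per_vial: float
    vials_per_administration: int
    administrations_per_year: int

    def __post_init__(self) -> None:
        if self.price_per_vial <= 0:
            raise ValidationError(f"price {self.price_per_vial} must be positive")
        for name in ("vials_per_administration", "administrations_per_year"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValidationError(f"{name} = {v} must be a nonnegative integer")


@dataclass(frozen=True)
class AffordabilityContext:
    """Income context: per-capita disposable income and household size."""

    per_capita_income: float
    household_size: float = DEFAULT_HOUSEHOLD_SIZE

    def __post_init__(self) -> None:
        if self.per_capita_income <= 0:
            raise ValidationError("per-capita income must be positive")
        if self.household_size <= 0:
            raise ValidationError("household size must be positive")


@dataclass(frozen=True)
class CoverageSurvey:
    """Stocking counts per institution type: {type: (stocked, total)}."""

    counts: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        for t, (s, n) in self.counts.items():
            if not (0 <= s <= n):
                raise ValidationError(
                    f"institution type '{t}': stocked {s} outside [0, total={n}]"
                )
            if n == 0:
                raise ValidationError(f"institution type '{t}': zero institutions")


def annual_cost(regimen: DosingRegimen, *, permissive: bool = False) -> float:
    """Annual treatment cost = price x vials per administration x
    administrations per year.  Zero-vial regimens cost 0 only under the
    permissive flag."""
    if regimen.vials_per_administration == 0 and not permissive:
        raise ValidationError("zero vials per administration (pass permissive=True)")
    return (
        regimen.price_per_vial
        * regimen.vials_per_administration
        * regimen.administrations_per_year
    )


def daily_cost(annual: float) -> float:
    """Average daily cost: annual / 365."""
    if annual < 0:
        raise ValidationError(f"annual cost {annual} must be nonnegative")
    return annual / DAYS_PER_YEAR


def affordability(annual: float, context: AffordabilityContext) -> float:
    """Annual treatment cost as a percent of annual household disposable
    income (per-capita income x household size)."""
    if annual < 0:
        raise ValidationError(f"annual cost {annual} must be nonnegative")
    return 100.0 * annual / (context.per_capita_income * context.household_size)


def coverage_rate(survey: CoverageSurvey) -> pd.Series:
    """Percent of institutions stocking the drug per type plus 'overall'
    (summed counts)."""
    out = {}
    tot_s = tot_n = 0
    for t, (s, n) in survey.counts.items():
        out[t] = 100.0 * s / n
        tot_s += s
        tot_n += n
    out["overall"] = 100.0 * tot_s / tot_n
    return pd.Series(out, name="coverage_pct")


def affordability_table(
    annual_costs: Mapping[str, float],
    incomes: Mapping[str, float],
    household_size: float = DEFAULT_HOUSEHOLD_SIZE,
) -> pd.DataFrame:
    """Affordability grid: income group (rows) x cost arm (columns), percent."""
    rows = {}
    for group, income in incomes.items():
        ctx = AffordabilityContext(income, household_size)
        rows[group] = {
            arm: affordability(cost, ctx) for arm, cost in annual_costs.items()
        }
    return pd.DataFrame(rows).T


def calibrate_household_size(
    annual_costs: Sequence[float],
    incomes: Sequence[float],
    printed_percent: np.ndarray | Sequence[Sequence[float]],
    *,
    grid: tuple[float, float, float] = (1.0, 4.0, 0.01),
) -> float:
    """Brute-force fit of the household-size multiplier.

    Scans h over the grid (lo, hi, step) and returns the value minimizing the
    maximum absolute deviation between computed affordability percentages
    (cost i, income j) and the printed table.  Used to recover an unstated
    household size from a published affordability table.
    """
    costs = np.asarray(annual_costs, dtype=float)
    inc = np.asarray(incomes, dtype=float)
    target = np.asarray(printed_percent, dtype=float)
    if target.shape != (len(costs), len(inc)):
        raise ValidationError(
            f"printed table shape {target.shape} != ({len(costs)}, {len(inc)})"
        )
    lo, hi, step = grid
    hs = np.arange(lo, hi + step / 2, step)
    best_h, best_dev = hs[0], np.inf
    for h in hs:
        computed = 100.0 * costs[:, None] / (inc[None, :] * h)
        dev = np.max(np.abs(computed - target))
        if dev < best_dev:
            best_dev, best_h = dev, h
    return float(round_half_up(best_h, 2))


def economics_summary(
    regimens: Mapping[str, DosingRegimen],
    incomes: Mapping[str, float],
    household_size: float = DEFAULT_HOUSEHOLD_SIZE,
    survey: CoverageSurvey | None = None,
) -> dict[str, pd.DataFrame | pd.Series]:
    """Assemble the cost / affordability / coverage block in one call.

    Returns a dict with 'costs' (annual and daily per arm), 'affordability'
    (income group x arm, percent) and, if a survey is given, 'coverage'."""
    costs = pd.DataFrame(
        {
            arm: {"annual": annual_cost(r), "daily": daily_cost(annual_cost(r))}
            for arm, r in regimens.items()
        }
    ).T
    out: dict[str, pd.DataFrame | pd.Series] = {
        "costs": costs,
        "affordability": affordability_table(
            {arm: float(costs.loc[arm, "annual"]) for arm in costs.index},
            incomes,
            household_size,
        ),
    }
    if survey is not None:
        out["coverage"] = coverage_rate(survey)
    return out
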