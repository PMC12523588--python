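"""Weight-scenario sensitivity analysis.

Overall strategy values are recomputed under alternative domain-weight
allocations and the resulting rankings compared with the baseline.  A
strategy's score under a scenario is the scenario-weighted sum of its
*domain effective scores* — the local-weight-weighted mean expert score
within each domain, which equals the domain's comprehensive-score total
divided by the domain weight on unrounded inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .scoring import ValueReport, _rank
from .utils import ValidationError, fmt2

_PCT_TOL = 1e-6


@dataclass(frozen=True)
class WeightScenario:
    """One alternative domain-weight allocation, in percent (sums to 100)."""

    scenario_id: str
    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        w = dict(self.weights)
        if not w:
            raise ValidationError(f"scenario {self.scenario_id}: no weights")
        if any(v <= 0 for v in w.values()):
            raise ValidationError(
                f"scenario {self.scenario_id}: weights must be positive"
            )
        total = sum(w.values())
        if abs(total - 100.0) > _PCT_TOL:
            raise ValidationError(
                f"scenario {self.scenario_id}: weights sum to {total}, expected 100"
            )
        object.__setattr__(self, "weights", w)

    def order_preserved(self, baseline_order: Sequence[str], *, top_only: bool = False) -> bool:
        """Whether the scenario keeps the baseline domain ordering (weakly).

        With ``top_only`` the check is relaxed to leading-domain dominance:
        the first domain outweighs (>=) the second, and the second outweighs
        every remaining domain — the sense in which published scenario sets
        that bump one minor domain still 'preserve hierarchical order'.
        """
        w = [self.weights[d] for d in baseline_order]
        if top_only:
            return w[0] >= w[1] and all(w[1] >= v for v in w[2:])
        return all(a >= b for a, b in zip(w, w[1:]))


def make_scenarios(
    rows: Mapping[str, Mapping[str, float]],
    baseline_order: Sequence[str] | None = None,
    *,
    allow_reorder: bool = False,
    top_only: bool = True,
) -> list[WeightScenario]:
    """Build scenarios, refusing weight sets that upset the baseline
    hierarchical order unless ``allow_reorder`` is set."""
    scenarios = []
    for sid, weights in rows.items():
        sc = WeightScenario(sid, weights)
        if baseline_order is not None and not allow_reorder:
            if not sc.order_preserved(baseline_order, top_only=top_only):
                raise ValidationError(
                    f"scenario {sid} violates the baseline hierarchical order "
                    f"{list(baseline_order)}; pass allow_reorder=True to admit it"
                )
        scenarios.append(sc)
    return scenarios


def domain_effective_scores(
    report: ValueReport | None = None,
    *,
    domain_totals: pd.DataFrame | None = None,
    domain_weights: Mapping[str, float] | pd.Series | None = None,
) -> pd.DataFrame:
    """Per-domain effective score (domain x strategy).

    Preferred route (unrounded): from a :class:`ValueReport`, as
    sum(local_weight x ESc) over the domain's criteria.  Fixture route: from
    a table of domain comprehensive-score totals and the domain weights, as
    total / weight — identical on unrounded inputs, approximate when the
    totals come from rounded published tables.
    """
    if report is not None:
        cs = report.criterion_scores.copy()
        # local weight = global weight / domain weight, per domain
        dom_w = (
            cs[cs["strategy"] == cs["strategy"].iloc[0]]
            .groupby("domain", sort=False)["weight"]
            .sum()
        )
        if (dom_w <= 0).any():
            bad = dom_w[dom_w <= 0].index.tolist()
            raise ValidationError(f"zero-weight domains: {bad}")
        cs["local"] = cs.apply(lambda r: r["weight"] / dom_w[r["domain"]], axis=1)
        cs["contrib"] = cs["local"] * cs["esc_mean"]
        out = cs.pivot_table(
            index="domain", columns="strategy", values="contrib", aggfunc="sum",
            sort=False,
        ).reindex(dom_w.index)
        out.columns.name = None
        return out
    if domain_totals is None or domain_weights is None:
        raise ValidationError(
            "provide either a ValueReport or domain_totals + domain_weights"
        )
    dw = pd.Series(dict(domain_weights), dtype=float)
    if (dw <= 0).any():
        raise ValidationError(f"zero-weight domains: {dw[dw <= 0].index.tolist()}")
    dt = pd.DataFrame(domain_totals).astype(float)
    missing = set(dt.index) - set(dw.index)
    if missing:
        raise ValidationError(f"no weight for domains: {sorted(missing)}")
    return dt.div(dw.reindex(dt.index), axis=0)


def apply_scenario(
    scenario: WeightScenario, domain_scores: pd.DataFrame
) -> pd.Series:
    """Overall score per strategy under one scenario:
    sum over domains of (scenario weight / 100) x domain effective score."""
    missing = set(domain_scores.index) - set(scenario.weights)
    if missing:
        raise ValidationError(
            f"scenario {scenario.scenario_id} missing domains: {sorted(missing)}"
        )
    w = pd.Series(scenario.weights, dtype=float).reindex(domain_scores.index) / 100.0
    out = domain_scores.mul(w, axis=0).sum(axis=0)
    out.name = scenario.scenario_id
    return out


@dataclass
class StabilityResult:
    """Rank stability of strategies across weight scenarios."""

    baseline_overall: pd.Series
    baseline_ranking: list[tuple[int, str, float]]
    scenario_overall: pd.DataFrame  # scenario x strategy
    scenario_rankings: dict[str, list[tuple[int, str, float]]]
    margins: pd.Series = field(default_factory=pd.Series)  # top-two CS gap
    stable: bool = False

    def summary(self) -> str:
        lines = ["Weight-scenario sensitivity analysis", ""]
        header = ["scenario"] + [str(s) for s in self.scenario_overall.columns]
        lines.append("  ".join(f"{h:>12}" for h in header))
        base = ["baseline"] + [fmt2(v) for v in self.baseline_overall]
        lines.append("  ".join(f"{b:>12}" for b in base))
        for sid, row in self.scenario_overall.iterrows():
            vals = [str(sid)] + [fmt2(v) for v in row]
            lines.append("  ".join(f"{v:>12}" for v in vals))
        lines.append("")
        lines.append(f"margins (top-two gap): "
                     + ", ".join(f"{k}={v:.4f}" for k, v in self.margins.items()))
        lines.append(f"ranking stable across scenarios: {self.stable}")
        return "\n".join(lines)


def _order(ranking: list[tuple[int, str, float]]) -> list[str]:
    return [s for _, s, _ in ranking]


def check_rank_stability(
    domain_scores: pd.DataFrame,
    baseline_weights: Mapping[str, float] | pd.Series,
    scenarios: Sequence[WeightScenario],
) -> StabilityResult:
    """Score every scenario and compare its strategy ranking to baseline.

    ``baseline_weights`` are fractions (summing to ~1).  The result carries
    per-scenario overalls, rankings, the top-two margin per scenario (4+
    decimals retained so near-ties stay visible) and the overall stability
    verdict: stable iff every scenario ranking equals the baseline ranking.
    """
    if not scenarios:
        raise ValidationError("at least one scenario is required")
    bw = pd.Series(dict(baseline_weights), dtype=float)
    baseline = domain_scores.mul(
        bw.reindex(domain_scores.index), axis=0
    ).sum(axis=0)
    baseline.name = "baseline"
    baseline_ranking = _rank(baseline)
    rows = {}
    rankings = {}
    margins = {}
    for sc in scenarios:
        overall = apply_scenario(sc, domain_scores)
        rows[sc.scenario_id] = overall
        rankings[sc.scenario_id] = _rank(overall)
        ordered = sorted(overall, reverse=True)
        margins[sc.scenario_id] = (
            ordered[0] - ordered[1] if len(ordered) > 1 else float("nan")
        )
    scenario_overall = pd.DataFrame(rows).T
    stable = all(
        _order(r) == _order(baseline_ranking) for r in rankings.values()
    )
    return StabilityResult(
        baseline_overall=baseline,
        baseline_ranking=baseline_ranking,
        scenario_overall=scenario_overall,
        scenario_rankings=rankings,
        margins=pd.Series(margins),
        stable=stable,
    )
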