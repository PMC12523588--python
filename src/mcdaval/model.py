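"""Model / Results objects tying the stages together.

`AHPModel` fits criterion weights from multi-expert pairwise judgments;
`MCDAModel` fits the weighted-sum value model from a criteria hierarchy and
an expert score panel (or precomputed score summaries).  Results objects
carry the estimates, diagnostics, a ``summary()`` table, and sensitivity /
plotting entry points.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from . import ahp as _ahp
from .ahp import ConsistencyReport, ExpertProfile, PairwiseComparisonMatrix
from .hierarchy import CriteriaHierarchy
from .scoring import (
    ScorePanel,
    ValueReport,
    overall_from_means,
    overall_score,
    summarize_panel,
)
from .sensitivity import (
    StabilityResult,
    WeightScenario,
    check_rank_stability,
    domain_effective_scores,
)
from .utils import ValidationError, fmt2


class AHPModel:
    """Group AHP weighting model.

    Parameters
    ----------
    judgments
        Mapping node -> list of one judgment matrix per expert.  The node
        ``"domains"`` holds comparisons among domains; any node named after a
        domain holds comparisons among that domain's criteria.  A domain with
        a single criterion needs no matrix.
    experts
        Optional expert profiles; with ``cr_weighted=True`` the aggregation
        weights each expert's judgments by their authority coefficient Cr.
    """

    def __init__(
        self,
        judgments: Mapping[str, Sequence[PairwiseComparisonMatrix]],
        experts: Sequence[ExpertProfile] | None = None,
        *,
        cr_weighted: bool = False,
    ) -> None:
        if not judgments:
            raise ValidationError("no judgment matrices supplied")
        if cr_weighted and experts is None:
            raise ValidationError("cr_weighted aggregation needs expert profiles")
        self.judgments = {k: list(v) for k, v in judgments.items()}
        self.experts = list(experts) if experts is not None else None
        self.cr_weighted = cr_weighted

    def fit(self, *, cr_threshold: float = _ahp.DEFAULT_CR_THRESHOLD) -> "AHPResults":
        expert_weights = None
        if self.cr_weighted and self.experts:
            expert_weights = [e.authority for e in self.experts]
        weights: dict[str, pd.Series] = {}
        reports: dict[str, ConsistencyReport] = {}
        for node, mats in self.judgments.items():
            agg = _ahp.aggregate_judgments(mats, expert_weights)
            w, _ = _ahp.principal_weights(agg)
            weights[node] = pd.Series(w, index=agg.labels, name=node)
            reports[node] = _ahp.consistency(agg, threshold=cr_threshold)
        hierarchy = None
        if "domains" in weights:
            dom = weights["domains"]
            local: dict[str, dict[str, float]] = {}
            complete = True
            for d in dom.index:
                if d in weights:
                    local[d] = weights[d].to_dict()
                else:
                    complete = False
            if complete:
                hierarchy = CriteriaHierarchy.from_local(dom.to_dict(), local)
        return AHPResults(self, weights, reports, hierarchy)


class AHPResults:
    """Fitted AHP weights with consistency diagnostics."""

    def __init__(
        self,
        model: AHPModel,
        weights: dict[str, pd.Series],
        consistency: dict[str, ConsistencyReport],
        hierarchy: CriteriaHierarchy | None,
    ) -> None:
        self.model = model
        self.weights = weights
        self.consistency = consistency
        self.hierarchy = hierarchy

    @property
    def panel_authoritative(self) -> bool | None:
        if self.model.experts is None:
            return None
        return _ahp.panel_authoritative(self.model.experts)

    def summary(self) -> str:
        lines = ["Group AHP weighting", ""]
        for node, w in self.weights.items():
            rep = self.consistency[node]
            lines.append(
                f"node '{node}' (n={rep.n}): lambda_max={rep.lambda_max:.4f}, "
                f"CR={rep.consistency_ratio:.4f} "
                f"({'acceptable' if rep.acceptable else 'NOT acceptable'})"
            )
            for name, v in w.items():
                lines.append(f"    {name:<40s} {v:.4f}")
        if self.hierarchy is not None:
            lines.append("")
            lines.append("global criterion weights:")
            for name, v in self.hierarchy.global_weights.items():
                lines.append(f"    {name:<40s} {v:.4f}")
        if self.panel_authoritative is not None:
            lines.append("")
            lines.append(f"expert panel authoritative (all Cr > 0.8): "
                         f"{self.panel_authoritative}")
        return "\n".join(lines)


class MCDAModel:
    """Weighted-sum multicriteria value model.

    Built from a :class:`CriteriaHierarchy` (criterion weights Wc) and either
    a raw expert :class:`ScorePanel` or a table of mean scores per criterion
    and strategy.  ``fit()`` computes per-criterion comprehensive scores
    CS = Wc x ESc, domain subtotals, overall strategy values and the ranking.
    """

    def __init__(
        self,
        hierarchy: CriteriaHierarchy,
        panel: ScorePanel | None = None,
        *,
        summaries: pd.DataFrame | None = None,
    ) -> None:
        if (panel is None) == (summaries is None):
            raise ValidationError("supply exactly one of panel or summaries")
        self.hierarchy = hierarchy
        self.panel = panel
        self._summaries = summaries

    @classmethod
    def from_summaries(
        cls,
        hierarchy: CriteriaHierarchy,
        means: pd.DataFrame | Mapping[str, Mapping[str, float]],
        sds: pd.DataFrame | Mapping[str, Mapping[str, float]] | None = None,
    ) -> "MCDAModel":
        """Build from a criterion x strategy table of mean scores."""
        means_df = pd.DataFrame(means)
        sds_df = pd.DataFrame(sds) if sds is not None else None
        rows = []
        for c in means_df.index:
            for s in means_df.columns:
                rows.append(
                    {
                        "criterion": c,
                        "strategy": s,
                        "mean": float(means_df.loc[c, s]),
                        "sd": float(sds_df.loc[c, s]) if sds_df is not None else float("nan"),
                    }
                )
        summaries = pd.DataFrame(rows).set_index(["criterion", "strategy"])
        return cls(hierarchy, summaries=summaries)

    def fit(self) -> "MCDAResults":
        if self.panel is not None:
            summaries = summarize_panel(self.panel)
        else:
            summaries = self._summaries
        report = overall_score(self.hierarchy, summaries)
        return MCDAResults(self, summaries, report)


class MCDAResults:
    """Fitted comprehensive-value results."""

    def __init__(
        self, model: MCDAModel, summaries: pd.DataFrame, report: ValueReport
    ) -> None:
        self.model = model
        self.summaries = summaries
        self.report = report

    @property
    def overall(self) -> pd.Series:
        return self.report.overall

    @property
    def ranking(self) -> list[tuple[int, str, float]]:
        return self.report.ranking

    @property
    def domain_totals(self) -> pd.DataFrame:
        return self.report.domain_totals

    def domain_scores(self) -> pd.DataFrame:
        """Per-domain effective scores (local-weight-weighted mean ESc)."""
        return domain_effective_scores(self.report)

    def sensitivity(self, scenarios: Sequence[WeightScenario]) -> StabilityResult:
        """Re-score every strategy under alternative domain-weight scenarios
        (computed from the fitted, unrounded domain effective scores)."""
        dw = self.model.hierarchy.domain_weights
        return check_rank_stability(self.domain_scores(), dw, scenarios)

    def summary(self) -> str:
        lines = [
            "Weighted-sum MCDA value model",
            f"{len(self.model.hierarchy.domains)} domains, "
            f"{len(self.model.hierarchy)} criteria, "
            f"strategies: {', '.join(self.overall.index)}",
            "",
            self.report.to_table().to_string(index=False),
            "",
            "ranking: "
            + "; ".join(f"{r}. {s} ({fmt2(v)})" for r, s, v in self.ranking)
            + ("  [ties present]" if self.report.has_ties else ""),
        ]
        return "\n".join(lines)

    def plot_contributions(self, ax=None):
        """Stacked-bar plot of domain comprehensive-score contributions per
        strategy (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        bottom = None
        dt = self.domain_totals
        for domain in dt.index:
            vals = dt.loc[domain]
            ax.bar(dt.columns, vals, bottom=bottom, label=domain)
            bottom = vals if bottom is None else bottom + vals
        ax.set_ylabel("comprehensive score (points)")
        ax.legend(fontsize="small")
        return ax
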