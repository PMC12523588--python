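"""Evidence-matrix scoring.

Experts score each criterion for each strategy on a 1-10 scale against the
assembled evidence.  Per criterion and strategy the panel is summarized as the
mean expert score ESc (+- sample SD); a criterion's comprehensive score is
CS = Wc x ESc (global criterion weight times mean score), and a strategy's
overall value is the sum of CS over all criteria.  All arithmetic is done on
unrounded values; two-decimal half-up rounding is presentation only.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hierarchy import CriteriaHierarchy
from .utils import ValidationError, fmt2, round_half_up

#: Qualitative bands on the 1-10 score scale.
BANDS = {"poor": (1, 3), "moderate": (4, 7), "excellent": (8, 10)}


def band_of(mean_score: float) -> str:
    """Band of a (possibly fractional) mean score: the band of its nearest
    integer (half-up)."""
    k = int(round_half_up(mean_score, 0))
    for name, (lo, hi) in BANDS.items():
        if lo <= k <= hi:
            return name
    raise ValidationError(f"score {mean_score} outside the 1-10 scale")


class ScorePanel:
    """Expert x criterion x strategy integer scores in [1, 10].

    Stored long-form with columns ``expert_id, strategy, criterion, score``.
    A missing (expert, criterion, strategy) row is an explicitly missing
    score; duplicated cells are rejected.
    """

    COLUMNS = ["expert_id", "strategy", "criterion", "score"]

    def __init__(self, data: pd.DataFrame) -> None:
        missing = set(self.COLUMNS) - set(data.columns)
        if missing:
            raise ValidationError(f"score panel missing columns {sorted(missing)}")
        df = data[self.COLUMNS].copy()
        if len(df) == 0:
            raise ValidationError("empty score panel")
        scores = df["score"].to_numpy()
        as_int = np.asarray(scores, dtype=float)
        if not np.all(np.isfinite(as_int)) or np.any(as_int != np.round(as_int)):
            raise ValidationError("scores must be integers")
        df["score"] = as_int.astype(int)
        bad = df[(df["score"] < 1) | (df["score"] > 10)]
        if len(bad):
            r = bad.iloc[0]
            raise ValidationError(
                f"score {r['score']} by expert {r['expert_id']} for "
                f"({r['criterion']}, {r['strategy']}) outside [1, 10]"
            )
        if df.duplicated(["expert_id", "strategy", "criterion"]).any():
            raise ValidationError("duplicate (expert, strategy, criterion) cells")
        self.data = df.reset_index(drop=True)

    @property
    def experts(self) -> list[str]:
        return sorted(self.data["expert_id"].astype(str).unique())

    @property
    def strategies(self) -> list[str]:
        return list(dict.fromkeys(self.data["strategy"]))

    @property
    def criteria(self) -> list[str]:
        return list(dict.fromkeys(self.data["criterion"]))

    @property
    def n_experts(self) -> int:
        return self.data["expert_id"].nunique()

    @classmethod
    def from_csv(cls, path) -> "ScorePanel":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def summarize_panel(panel: ScorePanel) -> pd.DataFrame:
    """Mean +- sample SD of expert scores per (criterion, strategy).

    Returns a frame indexed by (criterion, strategy) with columns
    ``mean, sd, n, n_missing, band``.  Missing cells are excluded pairwise;
    the count of missing experts is reported.  The SD uses the n-1
    denominator and is 0 for a single score.
    """
    g = panel.data.groupby(["criterion", "strategy"], sort=False)["score"]
    out = g.agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count").reset_index()
    out["sd"] = out["sd"].fillna(0.0)
    out["n_missing"] = panel.n_experts - out["n"]
    out["band"] = out["mean"].map(band_of)
    full = len(panel.criteria) * len(panel.strategies)
    if len(out) < full:
        have = set(zip(out["criterion"], out["strategy"]))
        absent = [
            (c, s)
            for c in panel.criteria
            for s in panel.strategies
            if (c, s) not in have
        ]
        raise ValidationError(f"no scores at all for cells: {absent}")
    return out.set_index(["criterion", "strategy"])


def comprehensive_score(wc: float, esc: float) -> float:
    """Comprehensive score of a criterion: CS = Wc x ESc.

    Wc is the criterion's global weight in [0, 1] and ESc the mean expert
    score in [1, 10] (0 weight is allowed and yields 0)."""
    if not 0.0 <= wc <= 1.0:
        raise ValidationError(f"weight Wc = {wc} outside [0, 1]")
    if wc > 0 and not 1.0 <= esc <= 10.0:
        raise ValidationError(f"mean score ESc = {esc} outside [1, 10]")
    return wc * esc


@dataclass
class ValueReport:
    """Comprehensive-score breakdown for every strategy.

    Attributes
    ----------
    criterion_scores
        Frame with one row per (domain, criterion) and, per strategy, the
        mean score, SD and comprehensive score (columns ``esc_<s>``,
        ``sd_<s>``, ``cs_<s>`` are avoided in favor of a tidy layout:
        columns = domain, criterion, weight, strategy, esc_mean, esc_sd, cs).
    domain_totals
        Frame domain x strategy of summed comprehensive scores.
    overall
        Series strategy -> overall comprehensive score.
    ranking
        List of (rank, strategy, overall) with competition ranking; ties
        share a rank.
    """

    criterion_scores: pd.DataFrame
    domain_totals: pd.DataFrame
    overall: pd.Series
    ranking: list[tuple[int, str, float]]

    @property
    def has_ties(self) -> bool:
        ranks = [r for r, _, _ in self.ranking]
        return len(ranks) != len(set(ranks))

    def to_table(self) -> pd.DataFrame:
        """Wide presentation table mirroring the published layout: per
        strategy an ``ESc`` column (mean +- SD at 2 decimals) and a ``CS``
        column, with domain subtotal and overall rows appended."""
        strategies = list(self.overall.index)
        rows = []
        cs = self.criterion_scores
        for (domain, criterion), grp in cs.groupby(
            ["domain", "criterion"], sort=False
        ):
            row = {"domain": domain, "criterion": criterion}
            for s in strategies:
                g = grp[grp["strategy"] == s].iloc[0]
                row[f"ESc {s}"] = f"{fmt2(g['esc_mean'])} ± {fmt2(g['esc_sd'])}"
                row[f"CS {s}"] = fmt2(g["cs"])
            rows.append(row)
        for domain in self.domain_totals.index:
            row = {"domain": domain, "criterion": "Total"}
            for s in strategies:
                row[f"ESc {s}"] = "-"
                row[f"CS {s}"] = fmt2(self.domain_totals.loc[domain, s])
            rows.append(row)
        row = {"domain": "Overall", "criterion": ""}
        for s in strategies:
            row[f"ESc {s}"] = "-"
            row[f"CS {s}"] = fmt2(self.overall[s])
        rows.append(row)
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        payload = {
            "criterion_scores": self.criterion_scores.to_dict(orient="records"),
            "domain_totals": {
                s: self.domain_totals[s].to_dict() for s in self.domain_totals
            },
            "overall": self.overall.to_dict(),
            "ranking": [
                {"rank": r, "strategy": s, "overall": v} for r, s, v in self.ranking
            ],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ValueReport":
        payload = json.loads(text)
        cs = pd.DataFrame(payload["criterion_scores"])
        dt = pd.DataFrame(payload["domain_totals"])
        dt.index.name = "domain"
        overall = pd.Series(payload["overall"], name="overall")
        ranking = [
            (r["rank"], r["strategy"], r["overall"]) for r in payload["ranking"]
        ]
        return cls(cs, dt, overall, ranking)

    def to_csv(self, path) -> None:
        self.criterion_scores.to_csv(path, index=False)

    def __str__(self) -> str:
        buf = io.StringIO()
        buf.write(self.to_table().to_string(index=False))
        return buf.getvalue()


def _rank(overall: pd.Series) -> list[tuple[int, str, float]]:
    ordered = overall.sort_values(ascending=False, kind="stable")
    ranking: list[tuple[int, str, float]] = []
    prev_val: float | None = None
    rank = 0
    for i, (s, v) in enumerate(ordered.items(), start=1):
        if prev_val is None or v < prev_val - 1e-12:
            rank = i
        ranking.append((rank, str(s), float(v)))
        prev_val = v
    return ranking


def overall_score(
    hierarchy: CriteriaHierarchy,
    summaries: pd.DataFrame,
    strategies: Sequence[str] | None = None,
) -> ValueReport:
    """Aggregate criterion summaries into a :class:`ValueReport`.

    ``summaries`` is indexed by (criterion, strategy) with at least a
    ``mean`` column (``sd`` optional), as produced by
    :func:`summarize_panel`.  Every hierarchy criterion must have a summary
    for every strategy; the error lists any missing criteria.
    """
    if strategies is None:
        strategies = list(dict.fromkeys(summaries.index.get_level_values(1)))
    strategies = list(strategies)
    if not strategies:
        raise ValidationError("no strategies to score")
    weights = hierarchy.global_weights
    missing = [
        (c, s)
        for c in hierarchy.criteria
        for s in strategies
        if (c, s) not in summaries.index
    ]
    if missing:
        raise ValidationError(f"missing criterion summaries for: {missing}")
    rows = []
    for _, hrow in hierarchy.table.iterrows():
        c = hrow["criterion"]
        for s in strategies:
            srow = summaries.loc[(c, s)]
            esc = float(srow["mean"])
            rows.append(
                {
                    "domain": hrow["domain"],
                    "criterion": c,
                    "strategy": s,
                    "weight": float(weights[c]),
                    "esc_mean": esc,
                    "esc_sd": float(srow.get("sd", np.nan)),
                    "cs": comprehensive_score(float(weights[c]), esc),
                }
            )
    cs = pd.DataFrame(rows)
    domain_totals = (
        cs.pivot_table(
            index="domain", columns="strategy", values="cs", aggfunc="sum", sort=False
        )
        .reindex(hierarchy.domains)[strategies]
    )
    domain_totals.columns.name = None
    overall = domain_totals.sum(axis=0)
    overall.name = "overall"
    return ValueReport(cs, domain_totals, overall, _rank(overall))


def overall_from_means(
    hierarchy: CriteriaHierarchy,
    means: Mapping[str, Mapping[str, float]] | pd.DataFrame,
    sds: Mapping[str, Mapping[str, float]] | pd.DataFrame | None = None,
) -> ValueReport:
    """Convenience wrapper: build summaries from a criterion x strategy table
    of mean scores (and optional SDs) and aggregate them."""
    means_df = pd.DataFrame(means)
    rows = []
    for c in means_df.index:
        for s in means_df.columns:
            sd = np.nan
            if sds is not None:
                sd = pd.DataFrame(sds).loc[c, s]
            rows.append(
                {"criterion": c, "strategy": s, "mean": means_df.loc[c, s], "sd": sd}
            )
    summaries = pd.DataFrame(rows).set_index(["criterion", "strategy"])
    return overall_score(hierarchy, summaries, list(means_df.columns))
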