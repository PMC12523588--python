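"""Synthetic-data generators with controlled ground truth.

Three generators emulate the pipeline's inputs:

* expert judgment matrices around a true weight vector with multiplicative
  log-normal noise (optionally snapped to the admissible Saaty values),
* integer expert score panels whose realized means converge to specified
  targets (the latent normal mean is calibrated so discretization and
  clipping to [1, 10] do not bias the mean),
* case-level spontaneous-report tables with a background event distribution
  and implanted drug-event signals of chosen strength.

Every generator draws from its own pseudo-random stream derived from the
master seed by a fixed offset, so adding a generator never shifts existing
draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .ahp import SAATY_LEVELS, PairwiseComparisonMatrix
from .scoring import ScorePanel
from .utils import ValidationError, round_half_up

# Fixed stream offsets per generator (SeedSequence spawn keys).
_STREAM_JUDGMENTS = 1
_STREAM_SCORES = 2
_STREAM_REPORTS = 3

_LOG_LEVELS = np.log(np.array(SAATY_LEVELS))


def _rng(seed: int, offset: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(offset,)))


def snap_to_saaty(value: float) -> float:
    """Nearest admissible Saaty judgment value, nearest in log space."""
    if value <= 0:
        raise ValidationError(f"judgment ratio {value} must be positive")
    idx = int(np.argmin(np.abs(np.log(value) - _LOG_LEVELS)))
    return float(SAATY_LEVELS[idx])


@dataclass(frozen=True)
class PanelSimulationSpec:
    """Ground truth and noise model for one expert-elicitation simulation.

    ``domain_weights`` and per-domain ``criterion_weights`` are the true
    hierarchy; ``score_means``/``score_sds`` map (criterion, strategy) to the
    target mean and dispersion of the 1-10 integer scores.  ``sigma`` is the
    log-scale SD of the multiplicative judgment noise; ``snap`` maps noisy
    ratios to the nearest Saaty value.
    """

    domain_weights: Mapping[str, float]
    criterion_weights: Mapping[str, Mapping[str, float]]
    score_means: Mapping[tuple[str, str], float]
    score_sds: Mapping[tuple[str, str], float]
    n_experts: int = 17
    sigma: float = 0.1
    snap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_experts < 1:
            raise ValidationError("need at least one expert")
        if self.sigma < 0:
            raise ValidationError("sigma must be nonnegative")
        for (c, s), m in self.score_means.items():
            if not 1.0 <= m <= 10.0:
                raise ValidationError(f"target mean {m} for ({c}, {s}) outside [1, 10]")
        for (c, s), sd in self.score_sds.items():
            if sd < 0:
                raise ValidationError(f"dispersion {sd} for ({c}, {s}) negative")


def _noisy_matrix(
    weights: Sequence[float],
    labels: Sequence[str],
    node: str,
    sigma: float,
    snap: bool,
    rng: np.random.Generator,
) -> PairwiseComparisonMatrix:
    w = np.asarray(weights, dtype=float)
    n = len(w)
    a = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            ratio = w[i] / w[j]
            if sigma > 0:
                ratio *= float(np.exp(rng.normal(0.0, sigma)))
            if snap:
                ratio = snap_to_saaty(ratio)
            a[i, j] = ratio
            a[j, i] = 1.0 / ratio
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return PairwiseComparisonMatrix(a, labels, node, permissive_scale=True)


def simulate_judgments(
    spec: PanelSimulationSpec,
) -> dict[str, list[PairwiseComparisonMatrix]]:
    """Per-expert judgment matrices for the root node (``"domains"``) and for
    every domain with at least two criteria.

    Entry ij is (w_i / w_j) * exp(eps), eps ~ Normal(0, sigma^2), mirrored to
    keep reciprocity exact, optionally snapped to the Saaty scale.
    """
    rng = _rng(spec.seed, _STREAM_JUDGMENTS)
    nodes: dict[str, list[PairwiseComparisonMatrix]] = {"domains": []}
    multi = {
        d: w for d, w in spec.criterion_weights.items() if len(w) >= 2
    }
    for d in multi:
        nodes[d] = []
    dom_labels = list(spec.domain_weights)
    dom_w = [spec.domain_weights[d] for d in dom_labels]
    for _ in range(spec.n_experts):
        nodes["domains"].append(
            _noisy_matrix(dom_w, dom_labels, "domains", spec.sigma, spec.snap, rng)
        )
        for d, cw in multi.items():
            labels = list(cw)
            nodes[d].append(
                _noisy_matrix(
                    [cw[c] for c in labels], labels, d, spec.sigma, spec.snap, rng
                )
            )
    return nodes


# -- integer score panels -------------------------------------------------


def _discrete_pmf(mu: float, sd: float) -> np.ndarray:
    """PMF over scores 1..10 of a Normal(mu, sd) discretized to the nearest
    integer with the tails clipped into 1 and 10."""
    edges = np.arange(1.5, 10.0, 1.0)  # 1.5 .. 9.5
    cdf = stats.norm.cdf(edges, loc=mu, scale=sd)
    p = np.diff(np.concatenate([[0.0], cdf, [1.0]]))
    return p


def _calibrated_mu(target_mean: float, sd: float) -> float:
    """Latent normal mean whose discretized/clipped score mean equals the
    target.  Solved by bisection; the discretized mean is strictly
    increasing in mu with open range (1, 10)."""
    scores = np.arange(1, 11)

    def realized(mu: float) -> float:
        return float(_discrete_pmf(mu, sd) @ scores)

    lo, hi = -40.0, 50.0
    if not realized(lo) < target_mean < realized(hi):
        raise ValidationError(
            f"target mean {target_mean} unattainable on the 1-10 scale with sd {sd}"
        )
    return float(optimize.brentq(lambda m: realized(m) - target_mean, lo, hi, xtol=1e-10))


def simulate_scores(spec: PanelSimulationSpec) -> ScorePanel:
    """Integer score panel drawn from discretized clipped normals.

    With dispersion 0 every expert emits round(mean).  Otherwise the latent
    mean is calibrated so that the expected integer score equals the target
    mean exactly, making the empirical panel mean converge to the specified
    ground truth as the panel grows.
    """
    rng = _rng(spec.seed, _STREAM_SCORES)
    scores_axis = np.arange(1, 11)
    rows = []
    experts = [f"expert_{k + 1:02d}" for k in range(spec.n_experts)]
    for (criterion, strategy), mean in spec.score_means.items():
        sd = spec.score_sds.get((criterion, strategy), 0.0)
        if sd == 0:
            vals = np.full(spec.n_experts, int(round_half_up(mean, 0)))
        else:
            pmf = _discrete_pmf(_calibrated_mu(mean, sd), sd)
            vals = rng.choice(scores_axis, size=spec.n_experts, p=pmf)
        for e, v in zip(experts, vals):
            rows.append(
                {
                    "expert_id": e,
                    "strategy": strategy,
                    "criterion": criterion,
                    "score": int(v),
                }
            )
    return ScorePanel(pd.DataFrame(rows))


# -- spontaneous reports --------------------------------------------------


@dataclass(frozen=True)
class ReportSimulationSpec:
    """Generator settings for a synthetic spontaneous-report database.

    Each of ``n_reports`` reports mentions one drug (the target with
    probability ``target_share``, otherwise a background drug) and one event
    from ``background_probs``.  For the target drug the probability of each
    implanted signal event is multiplied by its reporting-rate ratio lambda
    and the event distribution renormalized.
    """

    n_reports: int = 50_000
    target_drug: str = "targetdrug"
    target_share: float = 0.05
    background_probs: Mapping[str, float] = field(default_factory=dict)
    signals: Mapping[str, float] = field(default_factory=dict)
    n_background_drugs: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports < 1:
            raise ValidationError("n_reports must be positive")
        if not 0.0 <= self.target_share <= 1.0:
            raise ValidationError("target share must lie in [0, 1]")
        probs = dict(self.background_probs) or default_event_vocabulary()
        total = sum(probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"background probabilities sum to {total}, not 1")
        if any(p <= 0 for p in probs.values()):
            raise ValidationError("background probabilities must be positive")
        for ev, lam in self.signals.items():
            if lam <= 0:
                raise ValidationError(f"signal strength for '{ev}' must be positive")
            if ev not in probs:
                raise ValidationError(f"signal event '{ev}' not in the vocabulary")
        object.__setattr__(self, "background_probs", probs)


def default_event_vocabulary(n_events: int = 20) -> dict[str, float]:
    """Zipf-like background event distribution (rank r gets mass 1/r,
    normalized) over generic event names."""
    ranks = np.arange(1, n_events + 1, dtype=float)
    p = (1.0 / ranks) / (1.0 / ranks).sum()
    return {f"event_{k:02d}": float(v) for k, v in zip(range(1, n_events + 1), p)}


def simulate_reports(spec: ReportSimulationSpec) -> pd.DataFrame:
    """Case-level report table with columns report_id, drug, event."""
    rng = _rng(spec.seed, _STREAM_REPORTS)
    events = list(spec.background_probs)
    bg = np.array([spec.background_probs[e] for e in events])
    tgt = bg.copy()
    for ev, lam in spec.signals.items():
        tgt[events.index(ev)] *= lam
    tgt = tgt / tgt.sum()
    is_target = rng.random(spec.n_reports) < spec.target_share
    drug_ids = rng.integers(1, spec.n_background_drugs + 1, size=spec.n_reports)
    drugs = np.where(
        is_target,
        spec.target_drug,
        np.char.add("drug_", drug_ids.astype(str)),
    )
    ev_idx = np.empty(spec.n_reports, dtype=int)
    n_t = int(is_target.sum())
    if n_t:
        ev_idx[is_target] = rng.choice(len(events), size=n_t, p=tgt)
    if spec.n_reports - n_t:
        ev_idx[~is_target] = rng.choice(
            len(events), size=spec.n_reports - n_t, p=bg
        )
    return pd.DataFrame(
        {
            "report_id": [f"r{k + 1:07d}" for k in range(spec.n_reports)],
            "drug": drugs,
            "event": [events[i] for i in ev_idx],
        }
    )
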