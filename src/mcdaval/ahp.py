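"""Analytic hierarchy process primitives.

Pairwise-comparison (judgment) matrices on the Saaty 1-9 ratio scale, priority
weight extraction by the principal right eigenvector (power iteration, with the
row-geometric-mean method as a cross-check), Saaty consistency diagnostics
(CI, RI, CR), group aggregation of multiple experts' judgments by element-wise
(optionally authority-weighted) geometric mean, and expert authority
coefficients Cr = (Ca + Cs) / 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .utils import ConfigurationError, NonConvergenceError, ValidationError

#: Admissible Saaty judgment values {1/9, ..., 1/2, 1, 2, ..., 9}.
SAATY_LEVELS: tuple[float, ...] = tuple(1.0 / k for k in range(9, 1, -1)) + tuple(
    float(k) for k in range(1, 10)
)

SAATY_MIN = 1.0 / 9.0
SAATY_MAX = 9.0

#: Saaty's random consistency index by matrix order n = 1..15.  The CR of a
#: judgment matrix is CI divided by this order-specific expectation of CI for
#: random reciprocal matrices.
RANDOM_INDEX: dict[int, float] = {
    1: 0.0,
    2: 0.0,
    3: 0.58,
    4: 0.90,
    5: 1.12,
    6: 1.24,
    7: 1.32,
    8: 1.41,
    9: 1.45,
    10: 1.49,
    11: 1.51,
    12: 1.48,
    13: 1.56,
    14: 1.57,
    15: 1.59,
}

#: Default Saaty acceptability threshold on the consistency ratio.
DEFAULT_CR_THRESHOLD = 0.1


class PairwiseComparisonMatrix:
    """A reciprocal judgment matrix for one node of the criteria hierarchy.

    Parameters
    ----------
    values
        Square array of positive ratios; ``values[i, j]`` states how much more
        important item *i* is than item *j* on the 1-9 ratio scale.
    labels
        Item names, in order.  Defaults to ``item_1 .. item_n``.
    node
        Identifier of the hierarchy node the comparisons refer to (e.g. the
        root ``"domains"`` or a domain name).
    permissive_scale
        If True, entries outside ``[1/9, 9]`` are admitted with a warning
        instead of rejected.
    rtol
        Relative tolerance for the reciprocity check ``a_ij * a_ji == 1``.
    """

    def __init__(
        self,
        values,
        labels: Sequence[str] | None = None,
        node: str = "",
        *,
        permissive_scale: bool = False,
        rtol: float = 1e-6,
    ) -> None:
        a = np.asarray(values, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValidationError(f"judgment matrix must be square, got shape {a.shape}")
        n = a.shape[0]
        if n < 2:
            raise ValidationError("judgment matrix needs at least 2 items")
        if not np.all(np.isfinite(a)) or np.any(a <= 0):
            bad = np.argwhere(~np.isfinite(a) | (a <= 0))[0]
            raise ValidationError(
                f"entry ({bad[0]}, {bad[1]}) of node '{node}' is not a positive number"
            )
        if not np.allclose(np.diag(a), 1.0, atol=rtol):
            i = int(np.argmax(np.abs(np.diag(a) - 1.0)))
            raise ValidationError(f"diagonal entry ({i}, {i}) of node '{node}' must be 1")
        prod = a * a.T
        if not np.allclose(prod, 1.0, rtol=rtol):
            i, j = np.unravel_index(np.argmax(np.abs(prod - 1.0)), prod.shape)
            raise ValidationError(
                f"reciprocity violated at cells ({i}, {j}) and ({j}, {i}) of node "
                f"'{node}': {a[i, j]:g} * {a[j, i]:g} != 1"
            )
        off = ~np.eye(n, dtype=bool)
        out_of_scale = (a[off] < SAATY_MIN * (1 - 1e-9)) | (a[off] > SAATY_MAX * (1 + 1e-9))
        if np.any(out_of_scale):
            if permissive_scale:
                warnings.warn(
                    f"node '{node}': {int(out_of_scale.sum())} entries outside the "
                    f"Saaty scale [1/9, 9] admitted permissively",
                    stacklevel=2,
                )
            else:
                idx = np.argwhere(off)[out_of_scale][0]
                raise ValidationError(
                    f"entry ({idx[0]}, {idx[1]}) = {a[idx[0], idx[1]]:g} of node "
                    f"'{node}' outside the Saaty scale [1/9, 9]"
                )
        if labels is None:
            labels = [f"item_{k + 1}" for k in range(n)]
        if len(labels) != n:
            raise ValidationError(f"{len(labels)} labels for a {n}x{n} matrix")
        if len(set(labels)) != n:
            raise ValidationError("item labels must be unique")
        self.values = a
        self.labels = list(labels)
        self.node = node

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @classmethod
    def from_upper(
        cls,
        upper: Mapping[tuple[int, int], float],
        n: int,
        labels: Sequence[str] | None = None,
        node: str = "",
        **kwargs,
    ) -> "PairwiseComparisonMatrix":
        """Build from upper-triangle entries; the lower triangle is filled
        with exact reciprocals."""
        a = np.eye(n)
        for (i, j), v in upper.items():
            if not (0 <= i < j < n):
                raise ValidationError(f"({i}, {j}) is not an upper-triangle cell")
            a[i, j] = v
            a[j, i] = 1.0 / v
        missing = [
            (i, j) for i in range(n) for j in range(i + 1, n) if (i, j) not in upper
        ]
        if missing:
            raise ValidationError(f"upper-triangle cells missing: {missing}")
        return cls(a, labels, node, **kwargs)

    @classmethod
    def consistent_from_weights(
        cls,
        weights: Sequence[float],
        labels: Sequence[str] | None = None,
        node: str = "",
    ) -> "PairwiseComparisonMatrix":
        """Perfectly consistent matrix ``a_ij = w_i / w_j`` from a positive
        weight vector (entries may leave the Saaty scale; admitted)."""
        w = np.asarray(weights, dtype=float)
        if np.any(w <= 0):
            raise ValidationError("weights must be positive")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return cls(np.outer(w, 1.0 / w), labels, node, permissive_scale=True)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PairwiseComparisonMatrix(node={self.node!r}, n={self.n})"


@dataclass(frozen=True)
class ConsistencyReport:
    """Saaty consistency diagnostics for one judgment matrix."""

    node: str
    n: int
    lambda_max: float
    consistency_index: float
    random_index: float
    consistency_ratio: float
    threshold: float
    acceptable: bool


@dataclass(frozen=True)
class ExpertProfile:
    """An expert's authority: influence Ca, familiarity Cs, Cr = (Ca+Cs)/2."""

    expert_id: str
    influence: float
    familiarity: float

    def __post_init__(self) -> None:
        for name, v in (("influence", self.influence), ("familiarity", self.familiarity)):
            if not 0.0 <= v <= 1.0:
                raise ValidationError(
                    f"expert {self.expert_id}: {name} = {v} outside [0, 1]"
                )

    @property
    def authority(self) -> float:
        return authority_coefficient(self.influence, self.familiarity)


def authority_coefficient(ca: float, cs: float) -> float:
    """Authority coefficient Cr = (Ca + Cs) / 2.

    Ca is the expert's influence on the judgment (basis of judgment) and Cs
    their familiarity with the problem, both as fractions in [0, 1].
    """
    if not (0.0 <= ca <= 1.0 and 0.0 <= cs <= 1.0):
        raise ValidationError(f"Ca = {ca}, Cs = {cs} must both lie in [0, 1]")
    return (ca + cs) / 2.0


def panel_authoritative(
    experts: Iterable[ExpertProfile], threshold: float = 0.8
) -> bool:
    """True when every expert's Cr strictly exceeds the acceptability
    threshold (default 0.8), i.e. the panel as a whole counts as
    authoritative."""
    experts = list(experts)
    if not experts:
        raise ValidationError("empty expert panel")
    return all(e.authority > threshold for e in experts)


def principal_weights(
    matrix: PairwiseComparisonMatrix,
    *,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> tuple[np.ndarray, float]:
    """Priority weights as the normalized principal right eigenvector.

    Uses power iteration on the positive matrix (Perron-Frobenius guarantees
    a unique dominant eigenvalue with a positive eigenvector).  Returns the
    weight vector (sums to 1) and the dominant eigenvalue lambda_max.
    """
    a = matrix.values
    n = matrix.n
    w = np.full(n, 1.0 / n)
    lam = float(n)
    for _ in range(max_iter):
        aw = a @ w
        lam = float(aw.sum())  # w sums to 1, so at a fixpoint sum(Aw) = lambda
        w_new = aw / lam
        if np.abs(w_new - w).sum() < tol:
            return w_new, lam
        w = w_new
    raise NonConvergenceError(
        f"power iteration did not converge in {max_iter} iterations on node "
        f"'{matrix.node}'"
    )


def row_geometric_mean_weights(matrix: PairwiseComparisonMatrix) -> np.ndarray:
    """Row-geometric-mean priority weights (identical to the eigenvector
    method on perfectly consistent matrices; used as a cross-check)."""
    g = np.exp(np.log(matrix.values).mean(axis=1))
    return g / g.sum()


def consistency(
    matrix: PairwiseComparisonMatrix,
    *,
    threshold: float = DEFAULT_CR_THRESHOLD,
) -> ConsistencyReport:
    """Saaty consistency diagnostics: CI = (lambda_max - n)/(n - 1), CR = CI/RI.

    A reciprocal 2x2 matrix is always consistent, so CR is defined as 0 there.
    Orders outside the tabulated random-index range (2..15) raise a
    configuration error.
    """
    n = matrix.n
    if n not in RANDOM_INDEX:
        raise ConfigurationError(
            f"no random index tabulated for matrix order n = {n} (supported: 2..15)"
        )
    _, lam = principal_weights(matrix)
    if n == 2:
        ci = 0.0
        cr = 0.0
    else:
        ci = (lam - n) / (n - 1)
        cr = ci / RANDOM_INDEX[n]
    return ConsistencyReport(
        node=matrix.node,
        n=n,
        lambda_max=lam,
        consistency_index=ci,
        random_index=RANDOM_INDEX[n],
        consistency_ratio=cr,
        threshold=threshold,
        acceptable=cr < threshold,
    )


def aggregate_judgments(
    matrices: Sequence[PairwiseComparisonMatrix],
    expert_weights: Sequence[float] | None = None,
) -> PairwiseComparisonMatrix:
    """Combine several experts' judgment matrices for the same node by the
    element-wise geometric mean, optionally weighted by authority
    coefficients Cr.

    Output entry ij is ``(prod_k a_ij^u_k)^(1/sum_k u_k)``; reciprocity is
    enforced exactly by aggregating the upper triangle and mirroring.
    """
    if not matrices:
        raise ValidationError("no judgment matrices to aggregate")
    first = matrices[0]
    n = first.n
    for m in matrices[1:]:
        if m.n != n:
            raise ValidationError(
                f"matrix orders differ: {n} vs {m.n} (node '{first.node}')"
            )
        if m.node != first.node:
            raise ValidationError(f"nodes differ: '{first.node}' vs '{m.node}'")
    if expert_weights is None:
        u = np.ones(len(matrices))
    else:
        u = np.asarray(expert_weights, dtype=float)
        if len(u) != len(matrices):
            raise ValidationError("one expert weight per matrix required")
        if np.any(u <= 0):
            raise ValidationError("expert weights must be positive")
    logs = np.stack([np.log(m.values) for m in matrices])
    mean_log = np.tensordot(u, logs, axes=1) / u.sum()
    agg = np.eye(n)
    iu = np.triu_indices(n, k=1)
    agg[iu] = np.exp(mean_log[iu])
    agg[(iu[1], iu[0])] = 1.0 / agg[iu]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return PairwiseComparisonMatrix(
            agg, first.labels, first.node, permissive_scale=True
        )
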