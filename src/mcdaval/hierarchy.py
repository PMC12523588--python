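"""Two-level criteria hierarchy: domains and their criteria, with local and
global weights (global = domain weight x local weight within the domain)."""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .utils import ValidationError

_SUM_TOL = 1e-6


def _normalize(weights: Mapping[str, float], what: str) -> dict[str, float]:
    names = list(weights)
    if len(set(names)) != len(names):
        raise ValidationError(f"duplicate names in {what}")
    vals = np.array([float(weights[k]) for k in names])
    if np.any(vals <= 0):
        raise ValidationError(f"{what}: weights must be positive")
    s = vals.sum()
    if abs(s - 1.0) > _SUM_TOL:
        warnings.warn(
            f"{what}: weights sum to {s:.6f}, renormalizing to 1", stacklevel=3
        )
    return dict(zip(names, vals / s))


class CriteriaHierarchy:
    """Ordered two-level tree of evaluation domains and criteria.

    The canonical constructor is :meth:`from_local` (domain weights plus,
    per domain, local criterion weights).  :meth:`from_global` accepts global
    criterion weights directly; with ``normalize=False`` it preserves them
    verbatim even when they do not sum exactly to 1, which is needed when the
    weights come from rounded published tables.
    """

    def __init__(self, table: pd.DataFrame, *, validate: bool = True) -> None:
        required = {"domain", "criterion", "local_weight", "global_weight"}
        if not required.issubset(table.columns):
            raise ValidationError(f"hierarchy table needs columns {sorted(required)}")
        if table["criterion"].duplicated().any():
            dup = table.loc[table["criterion"].duplicated(), "criterion"].tolist()
            raise ValidationError(f"duplicate criterion names: {dup}")
        self.table = table.reset_index(drop=True)
        if validate:
            tot = self.table["global_weight"].sum()
            if abs(tot - 1.0) > 1e-9:
                raise ValidationError(f"global weights sum to {tot}, expected 1")

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_local(
        cls,
        domain_weights: Mapping[str, float],
        criterion_weights: Mapping[str, Mapping[str, float]],
    ) -> "CriteriaHierarchy":
        """Compose from domain weights and per-domain local criterion weights.

        Each weight vector is renormalized (with a warning when off by more
        than 1e-6); global weight = domain weight x local weight.
        """
        dw = _normalize(domain_weights, "domain weights")
        if set(criterion_weights) != set(dw):
            raise ValidationError(
                "criterion weights must cover exactly the declared domains"
            )
        rows = []
        for d in dw:  # preserves insertion order
            local = _normalize(criterion_weights[d], f"criteria of domain '{d}'")
            for c, lw in local.items():
                rows.append(
                    {
                        "domain": d,
                        "criterion": c,
                        "local_weight": lw,
                        "global_weight": dw[d] * lw,
                    }
                )
        return cls(pd.DataFrame(rows))

    @classmethod
    def from_global(
        cls,
        table: pd.DataFrame,
        *,
        normalize: bool = True,
    ) -> "CriteriaHierarchy":
        """Build from a table with columns domain, criterion, global_weight.

        Domain weights are the within-domain sums.  With ``normalize=False``
        the stated weights are kept verbatim (sum-to-one is not enforced);
        local weights are still exact fractions of their domain total.
        """
        t = table.copy()
        if not {"domain", "criterion", "global_weight"}.issubset(t.columns):
            raise ValidationError(
                "need columns domain, criterion, global_weight"
            )
        if np.any(t["global_weight"].to_numpy(dtype=float) <= 0):
            raise ValidationError("global weights must be positive")
        total = t["global_weight"].sum()
        if normalize:
            if abs(total - 1.0) > _SUM_TOL:
                warnings.warn(
                    f"global weights sum to {total:.6f}, renormalizing",
                    stacklevel=2,
                )
            t["global_weight"] = t["global_weight"] / total
        dom_tot = t.groupby("domain", sort=False)["global_weight"].transform("sum")
        t["local_weight"] = t["global_weight"] / dom_tot
        return cls(
            t[["domain", "criterion", "local_weight", "global_weight"]],
            validate=normalize,
        )

    # -- views ------------------------------------------------------------

    @property
    def domains(self) -> list[str]:
        return list(dict.fromkeys(self.table["domain"]))

    @property
    def criteria(self) -> list[str]:
        return self.table["criterion"].tolist()

    @property
    def domain_weights(self) -> pd.Series:
        return self.table.groupby("domain", sort=False)["global_weight"].sum()

    @property
    def global_weights(self) -> pd.Series:
        return self.table.set_index("criterion")["global_weight"]

    @property
    def local_weights(self) -> pd.Series:
        return self.table.set_index("criterion")["local_weight"]

    @property
    def domain_of(self) -> dict[str, str]:
        return dict(zip(self.table["criterion"], self.table["domain"]))

    def criteria_in(self, domain: str) -> list[str]:
        if domain not in self.domains:
            raise KeyError(domain)
        sel = self.table["domain"] == domain
        return self.table.loc[sel, "criterion"].tolist()

    def __len__(self) -> int:
        return len(self.table)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"CriteriaHierarchy({len(self.domains)} domains, "
            f"{len(self)} criteria)"
        )


def compose_hierarchy(
    domain_weights: Mapping[str, float],
    criterion_weights: Mapping[str, Mapping[str, float]],
) -> CriteriaHierarchy:
    """Functional alias for :meth:`CriteriaHierarchy.from_local`."""
    return CriteriaHierarchy.from_local(domain_weights, criterion_weights)
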