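"""Bundled reference inputs: the omalizumab pediatric-asthma case study.

A published MCDA of omalizumab plus standard of care (SOC) versus SOC alone
for moderate-to-severe pediatric allergic asthma in China.  Bundled here are
the study's reported quantities as fixture inputs: the six-domain / 15-
criterion hierarchy with its elicited weights, the expert panel's mean
scores (+- SD) per criterion and strategy, the printed per-domain
comprehensive-score totals, the six sensitivity weight scenarios, the
economic parameters, the formulary survey counts, and the top pediatric
adverse-event disproportionality statistics.

The elicited weights are inputs, not outputs: the raw expert judgment
matrices behind them were never published, so they cannot be recomputed from
first principles.  Note the criterion weights below reproduce the published
per-criterion comprehensive scores; because the published effectiveness
figures are internally inconsistent at the printed precision (the guideline-
recommendations weight implied by its comprehensive score differs from the
separately printed percentage), the bundled global weights sum to 0.9906
rather than 1 and are deliberately not renormalized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .econ import CoverageSurvey, DosingRegimen
from .hierarchy import CriteriaHierarchy
from .sensitivity import WeightScenario

STRATEGY_OMZ = "OMZ+SOC"
STRATEGY_SOC = "SOC"

#: Elicited domain weights (fractions) in display order.
DOMAIN_WEIGHTS: dict[str, float] = {
    "safety": 0.3855,
    "effectiveness": 0.2885,
    "economics": 0.0965,
    "innovation": 0.0824,
    "applicability": 0.0688,
    "accessibility": 0.0784,
}

#: Hierarchical order of domains by elicited weight (descending).
DOMAIN_ORDER = [
    "safety",
    "effectiveness",
    "economics",
    "innovation",
    "accessibility",
    "applicability",
]

# (domain, criterion, global weight).  Weights reproduce the published
# per-criterion comprehensive scores (CS / ESc), constrained to the printed
# domain sums; see the module docstring for the effectiveness caveat.
_CRITERIA: list[tuple[str, str, float]] = [
    ("safety", "A1 Pre-market safety", 0.1982),
    ("safety", "A2 Adverse drug reactions/events", 0.0895),
    ("safety", "A3 Drug safety warnings", 0.0978),
    ("effectiveness", "B1 Guideline recommendations", 0.1439),
    ("effectiveness", "B2 Clinical efficacy", 0.1351),
    ("economics", "C1 Economic reports", 0.0276),
    ("economics", "C2 Medicine costs", 0.0360),
    ("economics", "C3 Incremental analysis", 0.0329),
    ("innovation", "D1 Medicine technology characteristics", 0.0228),
    ("innovation", "D2 Addressing unmet clinical needs", 0.0450),
    ("innovation", "D3 Industry information", 0.0146),
    ("applicability", "E1 Technical applicability", 0.0262),
    ("applicability", "E2 Usage applicability", 0.0426),
    ("accessibility", "F1 Accessibility", 0.0386),
    ("accessibility", "F2 Affordability", 0.0398),
]

# criterion -> (mean OMZ+SOC, sd OMZ+SOC, mean SOC, sd SOC)
_ESC: dict[str, tuple[float, float, float, float]] = {
    "A1 Pre-market safety": (7.71, 1.02, 7.24, 1.96),
    "A2 Adverse drug reactions/events": (7.71, 1.52, 7.00, 2.22),
    "A3 Drug safety warnings": (6.06, 1.95, 7.82, 1.50),
    "B1 Guideline recommendations": (8.06, 1.68, 7.19, 1.18),
    "B2 Clinical efficacy": (8.76, 0.64, 6.71, 1.67),
    "C1 Economic reports": (7.24, 1.11, 7.00, 1.33),
    "C2 Medicine costs": (5.00, 1.50, 7.76, 1.39),
    "C3 Incremental analysis": (5.53, 1.58, 7.41, 1.72),
    "D1 Medicine technology characteristics": (7.88, 1.23, 6.71, 1.27),
    "D2 Addressing unmet clinical needs": (8.88, 1.23, 5.88, 2.42),
    "D3 Industry information": (8.29, 1.49, 6.29, 1.99),
    "E1 Technical applicability": (6.88, 1.41, 7.76, 0.94),
    "E2 Usage applicability": (6.94, 1.35, 7.88, 1.08),
    "F1 Accessibility": (7.00, 1.19, 8.35, 1.64),
    "F2 Affordability": (5.82, 1.42, 8.47, 0.98),
}

#: Published per-domain comprehensive-score totals (rounded, as printed).
DOMAIN_CS_PRINTED = pd.DataFrame(
    {
        STRATEGY_OMZ: [2.81, 2.35, 0.56, 0.70, 0.48, 0.50],
        STRATEGY_SOC: [2.83, 1.94, 0.72, 0.51, 0.54, 0.66],
    },
    index=pd.Index(
        ["safety", "effectiveness", "economics", "innovation", "applicability",
         "accessibility"],
        name="domain",
    ),
)

#: Published overall scores (points).
OVERALL_PRINTED = {STRATEGY_OMZ: 7.40, STRATEGY_SOC: 7.19}

# Six sensitivity scenarios: assigned domain weights in percent.
_SCENARIOS: dict[str, dict[str, float]] = {
    "1": {"safety": 45, "effectiveness": 25, "economics": 10, "innovation": 8,
          "applicability": 5, "accessibility": 7},
    "2": {"safety": 35, "effectiveness": 35, "economics": 10, "innovation": 8,
          "applicability": 5, "accessibility": 7},
    "3": {"safety": 35, "effectiveness": 30, "economics": 15, "innovation": 8,
          "applicability": 5, "accessibility": 7},
    "4": {"safety": 35, "effectiveness": 30, "economics": 10, "innovation": 13,
          "applicability": 5, "accessibility": 7},
    "5": {"safety": 35, "effectiveness": 30, "economics": 10, "innovation": 8,
          "applicability": 10, "accessibility": 7},
    "6": {"safety": 35, "effectiveness": 30, "economics": 10, "innovation": 8,
          "applicability": 5, "accessibility": 12},
}

# Economics (Chinese yuan).  150 mg/vial; 300 mg (2 vials) per administration,
# 12 administrations per 12-month course; incomes are 2024 per-capita annual
# disposable incomes.
PRICE_PER_VIAL_LIST = 1319.39
PRICE_PER_VIAL_REIMBURSED = 400.0
INCOMES = {"all": 41314.0, "urban": 54188.0, "rural": 23119.0}
HOUSEHOLD_SIZE = 2.62

#: Published affordability table (percent), rows = (pre, post) reimbursement,
#: columns = income groups in INCOMES order.
AFFORDABILITY_PRINTED = pd.DataFrame(
    {"all": [29.25, 8.87], "urban": [22.30, 6.76], "rural": [52.28, 15.85]},
    index=["pre", "post"],
)

_SURVEY = {
    "pediatric": (12, 20),
    "general": (20, 26),
    "maternal_child": (2, 14),
}

#: Top pediatric adverse-event disproportionality statistics for the target
#: drug (event, co-report count N, PRR, chi-squared, ROR, 95% CI bounds).
AE_SIGNAL_STATS = pd.DataFrame(
    [
        ("urticaria", 223, 11.60, 2069.63, 13.24, 11.46, 15.29),
        ("allergic reaction", 159, 20.57, 2708.34, 22.63, 19.09, 26.83),
        ("difficulty breathing", 155, 5.71, 592.17, 6.19, 5.24, 7.32),
        ("headache", 120, 2.61, 119.35, 2.73, 2.27, 3.29),
        ("lethargy", 119, 6.28, 514.79, 6.69, 5.54, 8.08),
        ("cough", 115, 6.03, 470.77, 6.41, 5.29, 7.76),
        ("wheezing", 107, 22.76, 2007.95, 24.25, 19.76, 29.76),
        ("itching", 103, 5.34, 354.89, 5.63, 4.60, 6.88),
        ("hypotension", 97, 23.70, 1892.48, 25.10, 20.24, 31.12),
        ("weight gain", 86, 4.69, 243.80, 4.89, 3.93, 6.09),
    ],
    columns=["event", "n", "prr", "chi2", "ror", "ci_low", "ci_high"],
)


@dataclass(frozen=True)
class CaseStudy:
    """All reference inputs for the bundled case study."""

    strategies: tuple[str, str]
    hierarchy: CriteriaHierarchy
    domain_weights: Mapping[str, float]
    domain_order: list[str]
    esc_means: pd.DataFrame  # criterion x strategy
    esc_sds: pd.DataFrame
    domain_cs_printed: pd.DataFrame
    overall_printed: Mapping[str, float]
    scenarios: list[WeightScenario]
    regimens: Mapping[str, DosingRegimen]
    incomes: Mapping[str, float]
    household_size: float
    affordability_printed: pd.DataFrame
    survey: CoverageSurvey
    ae_signal_stats: pd.DataFrame


def omalizumab_case_study() -> CaseStudy:
    """Load the bundled omalizumab pediatric-asthma case study."""
    hier = CriteriaHierarchy.from_global(
        pd.DataFrame(_CRITERIA, columns=["domain", "criterion", "global_weight"]),
        normalize=False,
    )
    criteria = [c for _, c, _ in _CRITERIA]
    esc_means = pd.DataFrame(
        {
            STRATEGY_OMZ: [_ESC[c][0] for c in criteria],
            STRATEGY_SOC: [_ESC[c][2] for c in criteria],
        },
        index=pd.Index(criteria, name="criterion"),
    )
    esc_sds = pd.DataFrame(
        {
            STRATEGY_OMZ: [_ESC[c][1] for c in criteria],
            STRATEGY_SOC: [_ESC[c][3] for c in criteria],
        },
        index=pd.Index(criteria, name="criterion"),
    )
    scenarios = [WeightScenario(sid, w) for sid, w in _SCENARIOS.items()]
    regimens = {
        "pre": DosingRegimen(PRICE_PER_VIAL_LIST, 2, 12),
        "post": DosingRegimen(PRICE_PER_VIAL_REIMBURSED, 2, 12),
    }
    return CaseStudy(
        strategies=(STRATEGY_OMZ, STRATEGY_SOC),
        hierarchy=hier,
        domain_weights=dict(DOMAIN_WEIGHTS),
        domain_order=list(DOMAIN_ORDER),
        esc_means=esc_means,
        esc_sds=esc_sds,
        domain_cs_printed=DOMAIN_CS_PRINTED.copy(),
        overall_printed=dict(OVERALL_PRINTED),
        scenarios=scenarios,
        regimens=regimens,
        incomes=dict(INCOMES),
        household_size=HOUSEHOLD_SIZE,
        affordability_printed=AFFORDABILITY_PRINTED.copy(),
        survey=CoverageSurvey(dict(_SURVEY)),
        ae_signal_stats=AE_SIGNAL_STATS.copy(),
    )
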