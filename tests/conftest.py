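import numpy as np
import pytest

import mcdaval as m


@pytest.fixture(scope="session")
def case_study():
    return m.omalizumab_case_study()


@pytest.fixture(scope="session")
def case_fit(case_study):
    """Fitted value model on the bundled case-study summaries."""
    model = m.MCDAModel.from_summaries(
        case_study.hierarchy, case_study.esc_means, case_study.esc_sds
    )
    return model.fit()


@pytest.fixture(scope="session")
def panel_spec(case_study):
    """Simulation spec whose ground truth is the bundled case study."""
    hier = case_study.hierarchy
    local = {
        d: {c: float(hier.local_weights[c]) for c in hier.criteria_in(d)}
        for d in hier.domains
    }
    means = {
        (c, s): float(case_study.esc_means.loc[c, s])
        for c in case_study.esc_means.index
        for s in case_study.esc_means.columns
    }
    sds = {
        (c, s): float(case_study.esc_sds.loc[c, s])
        for c in case_study.esc_sds.index
        for s in case_study.esc_sds.columns
    }
    def make(**overrides):
        kw = dict(
            domain_weights=dict(case_study.domain_weights),
            criterion_weights=local,
            score_means=means,
            score_sds=sds,
            n_experts=17,
            sigma=0.1,
            seed=0,
        )
        kw.update(overrides)
        return m.PanelSimulationSpec(**kw)
    return make


def random_reciprocal_matrix(rng: np.random.Generator, n: int) -> m.PairwiseComparisonMatrix:
    """Random reciprocal Saaty-scale matrix (helper shared across tests)."""
    from mcdaval.ahp import SAATY_LEVELS

    a = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            v = float(rng.choice(SAATY_LEVELS))
            a[i, j] = v
            a[j, i] = 1.0 / v
    return m.PairwiseComparisonMatrix(a)
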