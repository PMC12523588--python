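"""Disproportionality statistics and the dual signal rule."""

import numpy as np
import pandas as pd
import pytest

import mcdaval as m
from mcdaval.signals import (
    ContingencyTable,
    apply_signal_rule,
    chi2,
    flag_signal,
    prr,
    ror_with_ci,
    screen_events,
    tabulate_events,
)


def brute_force_stats(a, b, c, d):
    """Independent oracle: PRR, ROR and uncorrected Pearson chi-squared from
    first-principles margins arithmetic."""
    prr_v = (a / (a + b)) / (c / (c + d))
    ror_v = (a * d) / (b * c)
    n = a + b + c + d
    chi = 0.0
    obs = [[a, b], [c, d]]
    rows = [a + b, c + d]
    cols = [a + c, b + d]
    for i in range(2):
        for j in range(2):
            exp = rows[i] * cols[j] / n
            chi += (obs[i][j] - exp) ** 2 / exp
    return prr_v, ror_v, chi


class TestPRR:
    def test_identical_proportions(self):
        assert prr(ContingencyTable(10, 90, 10, 90)) == pytest.approx(1.0)

    def test_threefold_rate(self):
        assert prr(ContingencyTable(30, 70, 100, 900)) == pytest.approx(3.0)

    def test_zero_cell_rejected_without_correction(self):
        with pytest.raises(m.ValidationError, match="continuity"):
            prr(ContingencyTable(0, 100, 10, 90))

    def test_zero_cell_with_correction(self):
        v = prr(ContingencyTable(0, 100, 10, 90), correction=True)
        assert v == pytest.approx((0.5 / 101) / (10.5 / 101), abs=1e-12)


class TestROR:
    def test_unit_table_symmetric_ci(self):
        ror, lo, hi = ror_with_ci(ContingencyTable(25, 25, 25, 25))
        assert ror == pytest.approx(1.0)
        assert np.log(lo) == pytest.approx(-np.log(hi), abs=1e-12)

    def test_hand_computed_table(self):
        ror, lo, hi = ror_with_ci(ContingencyTable(30, 70, 100, 900))
        assert ror == pytest.approx(27000 / 7000, abs=1e-12)
        z = 1.959963984540054
        se = np.sqrt(1 / 30 + 1 / 70 + 1 / 100 + 1 / 900)
        assert lo == pytest.approx(np.exp(np.log(ror) - z * se), abs=1e-10)
        assert hi == pytest.approx(np.exp(np.log(ror) + z * se), abs=1e-10)

    def test_cross_product(self):
        ror, _, _ = ror_with_ci(ContingencyTable(3, 1, 1, 3))
        assert ror == pytest.approx(9.0)

    def test_against_statsmodels(self):
        from statsmodels.stats.contingency_tables import Table2x2

        t = ContingencyTable(42, 958, 517, 93_483)
        ror, lo, hi = ror_with_ci(t)
        sm = Table2x2(np.array([[t.a, t.b], [t.c, t.d]]))
        assert ror == pytest.approx(sm.oddsratio, rel=1e-12)
        sm_lo, sm_hi = sm.oddsratio_confint(0.05)
        assert lo == pytest.approx(sm_lo, rel=1e-9)
        assert hi == pytest.approx(sm_hi, rel=1e-9)


class TestChi2:
    def test_independence_gives_zero(self):
        assert chi2(ContingencyTable(10, 90, 10, 90), yates=False) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_uncorrected_matches_margins_oracle(self):
        t = ContingencyTable(30, 70, 100, 900)
        _, _, chi_oracle = brute_force_stats(30, 70, 100, 900)
        assert chi2(t, yates=False) == pytest.approx(chi_oracle, abs=1e-10)

    def test_yates_never_exceeds_uncorrected(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            a, b, c, d = rng.integers(1, 200, 4)
            t = ContingencyTable(int(a), int(b), int(c), int(d))
            assert chi2(t, yates=True) <= chi2(t, yates=False) + 1e-12

    def test_zero_margin_rejected(self):
        with pytest.raises(m.ValidationError, match="margin"):
            chi2(ContingencyTable(0, 0, 10, 90))


class TestOracleEquivalence:
    def test_thousand_random_tables_match_brute_force(self):
        rng = np.random.default_rng(12345)
        for _ in range(1000):
            a, b, c, d = (int(v) for v in rng.integers(1, 500, 4))
            t = ContingencyTable(a, b, c, d)
            prr_o, ror_o, chi_o = brute_force_stats(a, b, c, d)
            assert prr(t) == pytest.approx(prr_o, abs=1e-10)
            ror_v, _, _ = ror_with_ci(t)
            assert ror_v == pytest.approx(ror_o, abs=1e-10 * max(1, ror_o))
            assert chi2(t, yates=False) == pytest.approx(chi_o, abs=1e-8)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            a, b, c, d = (int(v) for v in rng.integers(1, 300, 4))
            t = ContingencyTable(a, b, c, d)
            s = t.swapped()
            assert prr(s) == pytest.approx(1.0 / prr(t), rel=1e-12)
            assert ror_with_ci(s)[0] == pytest.approx(1.0 / ror_with_ci(t)[0], rel=1e-12)


class TestSignalRule:
    def test_urticaria_statistics_flag_positive(self, case_study):
        row = case_study.ae_signal_stats.set_index("event").loc["urticaria"]
        prr_pos, ror_pos, signal = apply_signal_rule(
            row["prr"], row["chi2"], int(row["n"]), row["ci_low"]
        )
        assert prr_pos and ror_pos and signal

    def test_all_published_events_flag_positive(self, case_study):
        for _, row in case_study.ae_signal_stats.iterrows():
            _, _, signal = apply_signal_rule(
                row["prr"], row["chi2"], int(row["n"]), row["ci_low"]
            )
            assert signal, row["event"]

    def test_null_table_not_a_signal(self):
        res = flag_signal(ContingencyTable(10, 90, 10, 90))
        assert not res.signal

    def test_low_case_count_blocks_ror_rule(self):
        prr_pos, ror_pos, signal = apply_signal_rule(5.0, 10.0, 2, 1.5)
        assert prr_pos and not ror_pos and not signal

    def test_strictness_of_inequalities(self):
        assert not apply_signal_rule(2.0, 10.0, 5, 1.5)[0]  # PRR must exceed 2
        assert apply_signal_rule(2.01, 4.0, 5, 1.5)[0]  # chi2 >= 4 inclusive
        assert apply_signal_rule(3.0, 5.0, 3, 1.0)[1] is False  # CI low must exceed 1
        assert apply_signal_rule(3.0, 5.0, 3, 1.001)[1] is True  # N >= 3 inclusive

    def test_ci_ordering_invariant(self):
        res = flag_signal(ContingencyTable(30, 70, 100, 900))
        assert res.ror_ci_low <= res.ror <= res.ror_ci_high


class TestScreening:
    def test_implanted_signal_detected(self):
        spec = m.ReportSimulationSpec(
            n_reports=50_000, signals={"event_05": 10.0}, seed=1
        )
        reports = m.simulate_reports(spec)
        results = screen_events(reports, "targetdrug")
        by_event = {r.event: r for r in results}
        assert by_event["event_05"].signal

    def test_null_profile_dual_rule_conservative(self):
        # with no implanted signal, the dual rule fires at most as often as
        # the PRR rule alone (the conjunction can only reduce positives)
        spec = m.ReportSimulationSpec(n_reports=20_000, seed=11)
        results = screen_events(m.simulate_reports(spec), "targetdrug")
        n_dual = sum(r.signal for r in results)
        n_prr = sum(r.prr_positive for r in results)
        assert n_dual <= n_prr
        assert n_dual <= 2  # essentially no false signals under the null

    def test_single_report_dataset_no_signals(self):
        df = pd.DataFrame(
            {"report_id": ["r1"], "drug": ["targetdrug"], "event": ["nausea"]}
        )
        results = screen_events(df, "targetdrug")
        assert all(not r.signal for r in results)

    def test_no_target_reports_no_signals(self):
        df = pd.DataFrame(
            {"report_id": ["r1", "r2"], "drug": ["x", "y"], "event": ["e1", "e2"]}
        )
        results = screen_events(df, "targetdrug")
        assert all(not r.signal for r in results)

    def test_tabulate_counts_and_normalization(self):
        df = pd.DataFrame(
            {
                "report_id": ["r1", "r2", "r3", "r4"],
                "drug": ["TargetDrug ", "targetdrug", "other", "other"],
                "event": ["Rash", "rash", "rash", "fever"],
            }
        )
        tables = tabulate_events(df, "targetdrug")
        t = tables["rash"]
        assert (t.a, t.b, t.c, t.d) == (2, 0, 1, 1)

    def test_sorted_by_frequency_then_prr(self):
        spec = m.ReportSimulationSpec(n_reports=30_000, signals={"event_03": 5.0}, seed=4)
        results = screen_events(m.simulate_reports(spec), "targetdrug")
        freqs = [r.n_case for r in results]
        assert freqs == sorted(freqs, reverse=True)

    def test_empty_table_rejected(self):
        with pytest.raises(m.ValidationError, match="empty"):
            tabulate_events(pd.DataFrame(columns=["report_id", "drug", "event"]), "x")


def test_ci_empirical_coverage():
    """Woolf 95% CI covers the true odds ratio in ~95% of simulated tables."""
    rng = np.random.default_rng(2024)
    n1 = n2 = 200
    p1, p2, reps = 0.3, 0.15, 10_000
    a = rng.binomial(n1, p1, reps).astype(float)
    c = rng.binomial(n2, p2, reps).astype(float)
    b, d = n1 - a, n2 - c
    true_or = (p1 / (1 - p1)) / (p2 / (1 - p2))
    z = 1.959963984540054
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = np.log(a * d / (b * c))
    cover = np.mean(
        (np.exp(log_or - z * se) < true_or) & (true_or < np.exp(log_or + z * se))
    )
    assert cover == pytest.approx(0.95, abs=0.02)
    # spot-check the vectorized formula against the package implementation
    t = ContingencyTable(int(a[0]), int(b[0]), int(c[0]), int(d[0]))
    ror_v, lo, hi = ror_with_ci(t)
    assert lo == pytest.approx(np.exp(log_or[0] - z * se[0]), rel=1e-9)
    assert hi == pytest.approx(np.exp(log_or[0] + z * se[0]), rel=1e-9)


def test_model_results_surface():
    spec = m.ReportSimulationSpec(n_reports=30_000, signals={"event_04": 8.0}, seed=2)
    fit = m.DisproportionalityModel(m.simulate_reports(spec), "targetdrug").fit()
    assert any(r.event == "event_04" for r in fit.signals)
    assert {"event", "frequency", "prr", "chi2", "ror", "ci_low", "ci_high"}.issubset(
        fit.frame.columns
    )
    assert "signals" in fit.summary()
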