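"""Exact tests, odds ratios, penalized logistic fits and rank statistics.

Oracles: closed-form hypergeometric probabilities (scipy), hand-computed
rank statistics, and parameter recovery on data simulated from known
coefficients.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from osteomargin.stats import (
    ContingencyTable,
    LogisticFit,
    fisher_exact,
    kruskal_wallis,
    logistic_fit,
    odds_ratio_cc,
    sdcf_posthoc,
)

TABLE1_YES = (17, 8, 1, 0)
TABLE1_NO = (65, 77, 83, 84)


class TestContingencyTable:
    def test_rejects_negative_and_fractional_counts(self):
        with pytest.raises(ValueError):
            ContingencyTable(np.array([[1, -1], [2, 3]]))
        with pytest.raises(ValueError):
            ContingencyTable(np.array([[1.5, 1.0], [2.0, 3.0]]))

    def test_rejects_one_column(self):
        with pytest.raises(ValueError):
            ContingencyTable(np.array([[1], [2]]))


class TestFisherExact:
    def test_balanced_table_p_one(self):
        assert fisher_exact(ContingencyTable(np.array([[5, 5], [5, 5]]))) == 1.0

    def test_diagonal_table_closed_form(self):
        p = fisher_exact(ContingencyTable(np.array([[10, 0], [0, 10]])))
        assert p == pytest.approx(2.0 / 184756.0, rel=1e-9)

    def test_study_counts_highly_significant(self):
        table = ContingencyTable(np.array([TABLE1_YES, TABLE1_NO]))
        assert fisher_exact(table) < 1e-4

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fisher_exact(ContingencyTable(np.array([[0, 0], [3, 4]])))

    def test_enumeration_matches_hypergeometric_all_small_tables(self):
        # Exhaustive: every 2x2 table with N <= 30, against the closed-form
        # two-sided hypergeometric p computed independently with scipy.
        checked = 0
        for n in range(2, 31):
            for r in range(1, n):  # row-1 total
                for c in range(1, n):  # col-1 total
                    rv = sps.hypergeom(n, r, c)
                    support = np.arange(max(0, r + c - n), min(r, c) + 1)
                    pmf = rv.pmf(support)
                    for a in support:
                        table = np.array([[a, r - a], [c - a, n - r - c + a]])
                        if table.min() < 0:
                            continue
                        ours = fisher_exact(ContingencyTable(table))
                        p_obs = rv.pmf(a)
                        oracle = pmf[pmf <= p_obs * (1 + 1e-9)].sum()
                        assert ours == pytest.approx(min(oracle, 1.0), rel=1e-7), table
                        checked += 1
        assert checked > 10_000

    def test_two_by_four_matches_scipy_on_22_collapse(self):
        # Collapsing the 2x4 to 2x2 must agree with scipy's Fisher test.
        table = np.array([[7, 2], [3, 9]])
        ours = fisher_exact(ContingencyTable(table))
        _, scipy_p = sps.fisher_exact(table)
        assert ours == pytest.approx(scipy_p, rel=1e-9)


class TestOddsRatioCC:
    @pytest.mark.parametrize(
        "exposed,reference,expected",
        [
            ((17, 65), (8, 77), 2.44),  # unguided vs AR
            ((1, 83), (8, 77), 0.16),  # IN vs AR
            ((0, 84), (8, 77), 0.05),  # AR+IN vs AR (zero-cell case)
        ],
    )
    def test_reproduces_study_univariate_estimates(self, exposed, reference, expected):
        assert round(odds_ratio_cc(exposed, reference).estimate, 2) == expected

    def test_identical_groups_give_unity(self):
        assert odds_ratio_cc((8, 77), (8, 77)).estimate == pytest.approx(1.0)

    def test_large_count_limit_matches_crossproduct(self):
        res = odds_ratio_cc((600, 900), (500, 1000))
        raw = (600 * 1000) / (900 * 500)
        assert abs(res.estimate - raw) / raw < 0.01

    def test_ci_brackets_estimate(self):
        res = odds_ratio_cc((17, 65), (8, 77))
        assert res.ci_low < res.estimate < res.ci_high

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio_cc((0, 0), (0, 0))


def simulate_logistic(n, seed, cond_logors):
    """Factorial outcome data with known condition log-odds-ratios vs AR."""
    rng = np.random.default_rng(seed)
    conditions = np.array(["AR", "Unguided", "IN", "AR+IN"])
    cond = rng.choice(conditions, n)
    tumor = rng.integers(1, 5, n).astype(str)
    surgeon = rng.integers(1, 6, n).astype(str)
    intercept = np.log(0.094 / (1 - 0.094))  # AR baseline event rate
    eta = np.full(n, intercept)
    for name, b in cond_logors.items():
        eta[cond == name] += b
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    return y, pd.DataFrame({"condition": cond, "tumor": tumor, "surgeon": surgeon})


class TestLogisticFit:
    def test_null_recovery_on_balanced_data(self):
        y, design = simulate_logistic(2000, 0, {"Unguided": 0.0, "IN": 0.0, "AR+IN": 0.0})
        fit = logistic_fit(y, design, reference_levels={"condition": "AR"})
        for name in ("condition[Unguided]", "condition[IN]", "condition[AR+IN]"):
            assert abs(fit.params[name]) <= 3 * fit.bse[name]

    def test_recovers_planted_log_odds_ratios(self):
        truth = {"Unguided": np.log(2.5), "IN": np.log(0.16), "AR+IN": np.log(0.06)}
        y, design = simulate_logistic(4000, 1, truth)
        fit = logistic_fit(y, design, reference_levels={"condition": "AR"})
        for name, b in truth.items():
            key = f"condition[{name}]"
            assert abs(fit.params[key] - b) <= 3 * fit.bse[key], key

    def test_zero_event_group_engages_firth_with_finite_estimates(self):
        rng = np.random.default_rng(2)
        cond = np.repeat(["AR", "AR+IN"], 84)
        y = np.zeros(168, int)
        y[rng.choice(84, 8, replace=False)] = 1  # events only in AR
        fit = logistic_fit(y, pd.DataFrame({"condition": cond}),
                           reference_levels={"condition": "AR"})
        assert fit.method == "firth"
        assert np.isfinite(fit.params).all()
        assert abs(fit.params["condition[AR+IN]"]) < 10

    def test_firth_matches_penalized_likelihood_grid_on_toy(self):
        # Two-parameter toy: intercept + one binary predictor with a
        # zero-event cell; the Firth estimate must sit at the maximum of
        # the Jeffreys-penalized likelihood computed by brute-force grid.
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        x01 = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1])
        design = pd.DataFrame({"g": x01.astype(str)})
        fit = logistic_fit(y, design, firth=True)
        xmat = np.column_stack([np.ones(10), x01])

        def penalized(beta):
            eta = xmat @ beta
            mu = 1.0 / (1.0 + np.exp(-eta))
            ll = np.sum(y * eta - np.log1p(np.exp(eta)))
            info = (xmat.T * (mu * (1 - mu))) @ xmat
            return ll + 0.5 * np.log(np.linalg.det(info))

        b0 = np.linspace(-4, 3, 141)
        b1 = np.linspace(-8, 4, 241)
        grid = np.array([[penalized(np.array([a, b])) for b in b1] for a in b0])
        i, j = np.unravel_index(np.argmax(grid), grid.shape)
        assert fit.params["intercept"] == pytest.approx(b0[i], abs=0.06)
        assert fit.params["g[1]"] == pytest.approx(b1[j], abs=0.06)

    def test_plain_mle_diverges_where_firth_converges(self):
        cond = np.repeat(["a", "b"], 40)
        y = np.concatenate([np.ones(40), np.zeros(40)]).astype(int)  # separated
        design = pd.DataFrame({"condition": cond})
        with pytest.raises(RuntimeError, match="converge"):
            logistic_fit(y, design, firth=False, max_iter=25)
        fit = logistic_fit(y, design)  # auto-detects and penalizes
        assert fit.method == "firth" and np.isfinite(fit.params).all()


class TestKruskalWallis:
    def test_hand_computed_example(self):
        h, _ = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert h == pytest.approx(7.2)

    def test_identical_groups_null(self):
        h, p = kruskal_wallis([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]])
        assert h == 0.0 and p == 1.0

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(deadline=None, max_examples=20)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        groups = [rng.normal(size=12), rng.normal(1.0, 2.0, size=15), rng.normal(size=9)]
        h0, _ = kruskal_wallis(groups)
        h1, _ = kruskal_wallis([np.exp(g) for g in groups])
        assert h1 == pytest.approx(h0, rel=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0], []])


class TestSDCF:
    def test_obvious_separation_detected(self):
        groups = [np.arange(20.0), np.arange(100.0, 120.0), np.arange(200.0, 220.0)]
        res = sdcf_posthoc(groups)
        assert (res["p_value"] < 0.01).all()

    def test_identical_groups_not_flagged(self):
        rng = np.random.default_rng(0)
        g = rng.normal(size=20)
        res = sdcf_posthoc([g, g.copy()])
        assert (res["p_value"] > 0.9).all()

    def test_family_wise_error_calibrated(self):
        # 4 iid groups of 20; the chance any pairwise comparison is called
        # significant at 0.05 should itself be near 0.05.
        k, n, reps = 4, 20, 2000
        crit = sps.studentized_range.ppf(0.95, k, np.inf)
        rng = np.random.default_rng(12345)
        false_alarms = 0
        for _ in range(reps):
            groups = [rng.normal(size=n) for _ in range(k)]
            res = sdcf_posthoc(groups, compute_p=False)
            false_alarms += (res["statistic"] > crit).any()
        rate = false_alarms / reps
        assert 0.035 < rate < 0.065

    def test_statistic_matches_p_value_direction(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(size=15), rng.normal(0.8, 1.0, 15), rng.normal(size=15)]
        res = sdcf_posthoc(groups)
        order_by_q = res.sort_values("statistic")["p_value"].to_numpy()
        assert np.all(np.diff(order_by_q) <= 1e-12)
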