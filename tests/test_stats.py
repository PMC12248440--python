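"""Contingency inference: odds ratios, exact tests, logistic models."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from her2ith import (
    ContingencyTable,
    build_table2,
    chi_square,
    fisher_exact,
    multivariate_logistic,
    odds_ratio_woolf,
    pcr_rate,
)

# printed 2x2 tables (exposure row first): pCR+, pCR- per row
ER_TABLE = ContingencyTable(21, 31, 35, 10)
PGR_TABLE = ContingencyTable(9, 19, 47, 22)
HET_TABLE = ContingencyTable(5, 13, 51, 28)


def exact_fisher_oracle(t: ContingencyTable) -> float:
    """Brute-force two-sided Fisher p with exact rational arithmetic."""
    row1, row2 = t.a + t.b, t.c + t.d
    col1, n = t.a + t.c, t.n

    def pmf(a: int) -> Fraction:
        return Fraction(
            math.comb(row1, a) * math.comb(row2, col1 - a), math.comb(n, col1)
        )

    a_min, a_max = max(0, col1 - row2), min(row1, col1)
    p_obs = pmf(t.a)
    return float(sum(pmf(a) for a in range(a_min, a_max + 1) if pmf(a) <= p_obs))


class TestPCRRate:
    @pytest.mark.parametrize(
        "n_pcr, n_total, rounded",
        [(5, 18, 28), (51, 79, 65), (56, 97, 58), (0, 10, 0)],
    )
    def test_printed_rates(self, n_pcr, n_total, rounded):
        rate = pcr_rate(n_pcr, n_total)
        assert rate.rounded == rounded
        assert rate.percent == pytest.approx(100 * n_pcr / n_total)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            pcr_rate(1, 0)
        with pytest.raises(ValueError):
            pcr_rate(5, 4)


class TestWoolfOddsRatio:
    @pytest.mark.parametrize(
        "table, expected",
        [
            (ER_TABLE, (0.194, 0.0791, 0.474)),
            (PGR_TABLE, (0.222, 0.0865, 0.568)),
            (HET_TABLE, (0.211, 0.0682, 0.654)),
        ],
        ids=["ER", "PgR", "heterogeneity"],
    )
    def test_reproduces_printed_rows_at_3_sig_figs(self, table, expected):
        assert odds_ratio_woolf(table).rounded(3) == expected

    def test_equal_odds_table(self):
        r = odds_ratio_woolf(ContingencyTable(10, 10, 10, 10))
        assert r.or_point == pytest.approx(1.0)
        assert r.ci_low * r.ci_high == pytest.approx(1.0)  # log-symmetric

    def test_zero_cell_gets_haldane_correction(self):
        r = odds_ratio_woolf(ContingencyTable(0, 10, 5, 5))
        assert r.corrected
        assert 0 < r.or_point < 1

    def test_swap_both_invariance_and_single_swap_inversion(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b, c, d = rng.integers(1, 40, size=4)
            t = ContingencyTable(int(a), int(b), int(c), int(d))
            base = odds_ratio_woolf(t).or_point
            both = odds_ratio_woolf(t.swap_rows().swap_cols()).or_point
            rows = odds_ratio_woolf(t.swap_rows()).or_point
            assert both == pytest.approx(base, rel=1e-12)
            assert rows == pytest.approx(1 / base, rel=1e-12)


class TestFisherExact:
    def test_heterogeneity_table_small_p(self):
        p = fisher_exact(HET_TABLE)
        assert p == pytest.approx(exact_fisher_oracle(HET_TABLE), abs=1e-12)
        assert p < 0.01

    def test_degenerate_margin_gives_one(self):
        assert fisher_exact(ContingencyTable(0, 0, 7, 3)) == 1.0

    def test_matches_rational_enumeration_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(60):
            a, b, c, d = (int(v) for v in rng.integers(0, 50, size=4))
            if a + b + c + d == 0:
                continue
            t = ContingencyTable(a, b, c, d)
            assert fisher_exact(t) == pytest.approx(
                exact_fisher_oracle(t), abs=1e-10)

    def test_matches_scipy_two_sided(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            a, b, c, d = (int(v) for v in rng.integers(0, 60, size=4))
            if a + b + c + d == 0:
                continue
            t = ContingencyTable(a, b, c, d)
            assert fisher_exact(t) == pytest.approx(
                sps.fisher_exact(t.as_array())[1], abs=1e-9)


class TestChiSquare:
    def test_closed_form_heterogeneity(self):
        stat, p = chi_square(HET_TABLE)
        assert stat == pytest.approx(8.1265, abs=1e-3)
        assert p < 0.01

    def test_er_table_highly_significant(self):
        _, p = chi_square(ER_TABLE)
        assert p < 0.001

    def test_proportional_table_is_null(self):
        stat, p = chi_square(ContingencyTable(10, 20, 20, 40))
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_scipy_with_and_without_yates(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            a, b, c, d = (int(v) for v in rng.integers(1, 60, size=4))
            t = ContingencyTable(a, b, c, d)
            for yates in (False, True):
                stat, p = chi_square(t, yates=yates)
                s_stat, s_p, _, _ = sps.chi2_contingency(
                    t.as_array(), correction=yates)
                assert stat == pytest.approx(s_stat, rel=1e-10)
                assert p == pytest.approx(s_p, rel=1e-8)

    def test_zero_expected_cell_rejected(self):
        with pytest.raises(ValueError):
            chi_square(ContingencyTable(0, 0, 7, 3))


class TestLogistic:
    def test_single_covariate_fit_equals_closed_form_or(self):
        # saturated model on the heterogeneity 2x2
        rows = []
        for x, y, n in [(1, 1, 5), (1, 0, 13), (0, 1, 51), (0, 0, 28)]:
            rows += [{"hh": x, "pcr": y}] * n
        data = pd.DataFrame(rows)
        res = multivariate_logistic(data, "pcr", ["hh"])["hh"]
        assert res.or_point == pytest.approx(
            odds_ratio_woolf(HET_TABLE).or_point, abs=1e-6)

    def test_coefficient_recovery_on_synthetic_cohort(self):
        rng = np.random.default_rng(10)
        n = 2000
        x1 = rng.integers(0, 2, n)
        x2 = rng.integers(0, 2, n)
        beta = {"x1": -1.2, "x2": 0.7}
        logit = -0.3 + beta["x1"] * x1 + beta["x2"] * x2
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        data = pd.DataFrame({"x1": x1, "x2": x2, "y": y})
        res = multivariate_logistic(data, "y", ["x1", "x2"])
        for name, true_b in beta.items():
            est = math.log(res[name].or_point)
            se = (math.log(res[name].ci_high) - math.log(res[name].or_point)) / 1.96
            assert abs(est - true_b) < 2 * se

    def test_null_covariate_ci_coverage(self):
        # covariate independent of outcome: 95% Wald CI covers OR=1 in
        # >= 93% of 100 seeded replicates
        covered = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = 250
            x = rng.integers(0, 2, n)
            y = rng.integers(0, 2, n)
            data = pd.DataFrame({"x": x, "y": y})
            r = multivariate_logistic(data, "y", ["x"])["x"]
            covered += r.ci_low <= 1.0 <= r.ci_high
        assert covered >= 93

    def test_separation_flagged_with_profile_ci(self):
        data = pd.DataFrame({"x": [0] * 10 + [1] * 10,
                             "y": [0] * 10 + [1] * 10})
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = multivariate_logistic(data, "y", ["x"])["x"]
        assert res.corrected
        assert res.or_point > 1


class TestTable2Report:
    def test_paper97_univariate_rows(self, paper97_cohort):
        labeled = paper97_cohort.table.assign(
            ith_label=paper97_cohort.table.planted_label)
        report = build_table2(labeled)
        uni = report.univariate.set_index("characteristic")
        got = {
            "ER": uni.loc["ER (positive vs negative)", "or"],
            "PgR": uni.loc["PgR (positive vs negative)", "or"],
            "het": uni.loc["HER2 heterogeneity (high vs low)", "or"],
        }
        assert got["ER"] == pytest.approx(0.194, abs=5e-4)
        assert got["PgR"] == pytest.approx(0.222, abs=5e-4)
        assert got["het"] == pytest.approx(0.211, abs=5e-4)
        # grade row: cross-product from the printed counts, not the
        # unreproducible printed 1.79
        assert uni.loc["Histological grade (3 vs 1-2)", "or"] == pytest.approx(
            2.409, abs=2e-3)
        assert report.total_pcr_rate.rounded == 58
        assert len(report.multivariate) == 4

    def test_no_hh_cohort_flags_degenerate_row(self, paper97_cohort):
        labeled = paper97_cohort.table.assign(ith_label="LH")
        report = build_table2(labeled)
        assert any("heterogeneity" in f.lower() and "degenerate" in f
                   for f in report.flags)
        uni = report.univariate.set_index("characteristic")
        assert bool(uni.loc["HER2 heterogeneity (high vs low)",
                            "haldane_corrected"])

    def test_shuffled_outcomes_give_null_or(self, paper97_cohort):
        # permutation null: mean log-OR across shuffles ~ 0
        labeled = paper97_cohort.table.assign(
            ith_label=paper97_cohort.table.planted_label)
        rng = np.random.default_rng(4)
        logors = []
        for _ in range(60):
            shuffled = labeled.assign(
                pcr=rng.permutation(labeled["pcr"].to_numpy()))
            report = build_table2(shuffled)
            uni = report.univariate.set_index("characteristic")
            logors.append(math.log(
                uni.loc["HER2 heterogeneity (high vs low)", "or"]))
        assert abs(np.mean(logors)) < 0.25

    def test_missing_covariate_column_skipped_with_flag(self, paper97_cohort):
        labeled = paper97_cohort.table.assign(
            ith_label=paper97_cohort.table.planted_label).drop(columns=["pgr"])
        report = build_table2(labeled)
        assert any("pgr" in f for f in report.flags)
        assert "PgR (positive vs negative)" not in set(
            report.univariate["characteristic"])

    def test_summary_and_json(self, paper97_cohort):
        labeled = paper97_cohort.table.assign(
            ith_label=paper97_cohort.table.planted_label)
        report = build_table2(labeled)
        assert "pCR association analysis" in report.summary()
        import json

        payload = json.loads(report.to_json())
        assert payload["total"]["n"] == 97
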