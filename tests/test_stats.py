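import math

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from nvcoupling.stats import (bh_fdr, group_ttest, partial_pearson,
                              pearson_with_behavior, round_half_up,
                              summarize_cohort)


def _long_table(values_by_subject, metric="m"):
    rows = []
    for sid, vals in values_by_subject.items():
        for region, v in enumerate(vals, start=1):
            rows.append({"subject_id": sid, "region": region, metric: v})
    return pd.DataFrame(rows)


def _records(groups, **extra):
    df = pd.DataFrame({"subject_id": list(groups), "group": list(groups.values())})
    for k, v in extra.items():
        df[k] = v
    return df


def welch_oracle(a, b):
    """Textbook Welch t-test, written from the formulas."""
    ma, mb = sum(a) / len(a), sum(b) / len(b)
    va = sum((x - ma) ** 2 for x in a) / (len(a) - 1)
    vb = sum((x - mb) ** 2 for x in b) / (len(b) - 1)
    se2 = va / len(a) + vb / len(b)
    t = (ma - mb) / math.sqrt(se2)
    df = se2 ** 2 / ((va / len(a)) ** 2 / (len(a) - 1)
                     + (vb / len(b)) ** 2 / (len(b) - 1))
    return t, df


class TestGroupTtest:
    def test_identical_groups_null(self):
        table = _long_table({"a": [1.0], "b": [2.0], "c": [1.0], "d": [2.0]})
        rec = _records({"a": "patient", "b": "patient", "c": "control",
                        "d": "control"})
        row = group_ttest(table, rec, "m").iloc[0]
        assert row["estimate"] == pytest.approx(0.0)
        assert row["p_uncorrected"] == pytest.approx(1.0)

    def test_matches_welch_oracle(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        table = _long_table({f"p{i}": [v] for i, v in enumerate(a)}
                            | {f"c{i}": [v] for i, v in enumerate(b)})
        rec = _records({f"p{i}": "patient" for i in range(3)}
                       | {f"c{i}": "control" for i in range(3)})
        row = group_ttest(table, rec, "m").iloc[0]
        t, df = welch_oracle(a, b)
        assert row["estimate"] == pytest.approx(t, abs=1e-10)
        assert row["df"] == pytest.approx(df, abs=1e-10)
        assert row["direction"] == "patient<control"

    def test_injected_difference_detected(self, rng):
        n = 30
        n_regions = 20
        rows = {}
        groups = {}
        for i in range(n):
            sid = f"p{i}"
            vals = rng.normal(size=n_regions)
            vals[0] += 2.0  # large effect in region 1 only
            rows[sid] = vals
            groups[sid] = "patient"
        for i in range(n):
            sid = f"c{i}"
            rows[sid] = rng.normal(size=n_regions)
            groups[sid] = "control"
        res = group_ttest(_long_table(rows), _records(groups), "m")
        assert res[res["region"] == 1]["p_uncorrected"].iloc[0] < 0.001
        null_p = res[res["region"] != 1]["p_uncorrected"]
        assert (null_p < 0.05).mean() <= 0.25  # no more than a handful of 19

    def test_missing_group_yields_missing_row(self):
        table = _long_table({"a": [1.0], "b": [2.0]})
        rec = _records({"a": "patient", "b": "patient"})
        row = group_ttest(table, rec, "m").iloc[0]
        assert np.isnan(row["estimate"])
        assert row["n_control"] == 0

    def test_type_i_error_within_binomial_bounds(self, rng):
        # >= 200 null simulations; each draws 12/12 subjects x 5 regions
        n_sims, n_regions, n = 240, 5, 12
        total = rejected = 0
        for _ in range(n_sims):
            rows, groups = {}, {}
            for i in range(n):
                rows[f"p{i}"] = rng.normal(size=n_regions)
                groups[f"p{i}"] = "patient"
                rows[f"c{i}"] = rng.normal(size=n_regions)
                groups[f"c{i}"] = "control"
            res = group_ttest(_long_table(rows), _records(groups), "m")
            rejected += (res["p_uncorrected"] < 0.05).sum()
            total += len(res)
        rate = rejected / total
        se = math.sqrt(0.05 * 0.95 / total)
        assert abs(rate - 0.05) < 2.576 * se + 1e-12


class TestPearson:
    def test_perfect_linear_relation(self):
        table = _long_table({f"s{i}": [float(i)] for i in range(6)})
        rec = _records({f"s{i}": "patient" for i in range(6)},
                       score=[2.0 * i + 1 for i in range(6)])
        row = pearson_with_behavior(table, rec, "m", "score").iloc[0]
        assert row["estimate"] == pytest.approx(1.0)

    def test_matches_bruteforce_covariance(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        table = _long_table({f"s{i}": [x[i]] for i in range(12)})
        rec = _records({f"s{i}": "patient" for i in range(12)}, score=y)
        row = pearson_with_behavior(table, rec, "m", "score").iloc[0]
        mx, my = x.mean(), y.mean()
        oracle = (((x - mx) * (y - my)).sum()
                  / math.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum()))
        assert row["estimate"] == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_flagged(self):
        table = _long_table({f"s{i}": [1.0] for i in range(5)})
        rec = _records({f"s{i}": "patient" for i in range(5)},
                       score=[1.0, 2.0, 3.0, 4.0, 5.0])
        row = pearson_with_behavior(table, rec, "m", "score").iloc[0]
        assert np.isnan(row["estimate"])
        assert row["reason"] == "zero-variance"

    def test_target_correlation_recovered_at_n37(self, rng):
        n, rho = 37, -0.5
        z = rng.normal(size=n)
        score = rho * z + math.sqrt(1 - rho ** 2) * rng.normal(size=n)
        table = _long_table({f"s{i}": [z[i]] for i in range(n)})
        rec = _records({f"s{i}": "patient" for i in range(n)}, score=score)
        r = pearson_with_behavior(table, rec, "m", "score").iloc[0]["estimate"]
        # 95% CI around rho via Fisher z at n = 37
        zr, half = np.arctanh(rho), 1.96 / math.sqrt(n - 3)
        assert np.tanh(zr - half) < r < np.tanh(zr + half)


class TestPartialPearson:
    @staticmethod
    def _tables(x, y, z):
        n = len(x)
        table = _long_table({f"s{i}": [x[i]] for i in range(n)})
        rec = _records({f"s{i}": "patient" for i in range(n)}, score=y, age=z)
        return table, rec

    def test_matches_closed_form(self, rng):
        x = rng.normal(size=20)
        z = rng.normal(size=20)
        y = 0.5 * z + rng.normal(size=20)
        x = x + 0.3 * z
        table, rec = self._tables(x, y, z)
        row = partial_pearson(table, rec, "m", "score", "age").iloc[0]
        rxy = np.corrcoef(x, y)[0, 1]
        rxz = np.corrcoef(x, z)[0, 1]
        ryz = np.corrcoef(y, z)[0, 1]
        closed = (rxy - rxz * ryz) / math.sqrt((1 - rxz ** 2) * (1 - ryz ** 2))
        assert row["estimate"] == pytest.approx(closed, abs=1e-10)

    def test_independent_covariate_leaves_r_unchanged(self, rng):
        n = 500
        x = rng.normal(size=n)
        y = 0.6 * x + rng.normal(size=n)
        z = rng.normal(size=n)  # independent of both
        table, rec = self._tables(x, y, z)
        r0 = pearson_with_behavior(table, rec, "m", "score").iloc[0]["estimate"]
        rp = partial_pearson(table, rec, "m", "score", "age").iloc[0]["estimate"]
        assert abs(rp - r0) < 0.05

    def test_score_equal_to_covariate_degenerates(self, rng):
        x = rng.normal(size=10)
        z = rng.normal(size=10)
        table, rec = self._tables(x, z.copy(), z)
        row = partial_pearson(table, rec, "m", "score", "age").iloc[0]
        assert np.isnan(row["estimate"])
        assert row["reason"] == "zero-variance"


class TestBhFdr:
    def test_single_p(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_quartet(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_never_decreases_p(self, rng):
        p = rng.random(50)
        assert np.all(bh_fdr(p) >= p - 1e-12)

    def test_matches_statsmodels_oracle(self, rng):
        p = rng.random(200)
        q = bh_fdr(p)
        _, q_sm, *_ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, q_sm, atol=1e-12)

    def test_rejections_match_stepup_rule(self, rng):
        p = rng.random(80) ** 2
        alpha = 0.1
        q = bh_fdr(p)
        # classic step-up oracle: largest k with p_(k) <= k/m * alpha
        order = np.argsort(p)
        ps = p[order]
        m = len(p)
        k = 0
        for i in range(m, 0, -1):
            if ps[i - 1] <= i / m * alpha:
                k = i
                break
        expected = np.zeros(m, dtype=bool)
        expected[order[:k]] = True
        np.testing.assert_array_equal(q <= alpha, expected)

    def test_second_application_never_shrinks_q(self, rng):
        # BH is NOT idempotent in its rejection set: e.g. p = (0.03, 0.066,
        # 0.9) gives q = (0.09, 0.099, 0.9) but re-adjusting yields
        # (0.1485, 0.1485, 0.9), changing the decisions at alpha = 0.1.
        # What does hold: a second application can only inflate q.
        q1 = bh_fdr([0.03, 0.066, 0.9])
        q2 = bh_fdr(q1)
        np.testing.assert_allclose(q1, [0.09, 0.099, 0.9])
        np.testing.assert_allclose(q2, [0.1485, 0.1485, 0.9])
        p = rng.random(60) ** 3
        q1 = bh_fdr(p)
        assert np.all(bh_fdr(q1) >= q1 - 1e-12)

    def test_invalid_p_errors(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_fdr([-0.1])

    def test_nan_passthrough(self):
        q = bh_fdr([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2]], bh_fdr([0.01, 0.04]))


class TestSummarizeCohort:
    @staticmethod
    def _patients(n=37, n_above_cesd=8, n_above_stai=18, n_men=30):
        return pd.DataFrame({
            "subject_id": [f"p{i}" for i in range(n)],
            "group": "patient",
            "sex": ["M"] * n_men + ["F"] * (n - n_men),
            "CESD": [30.0] * n_above_cesd + [10.0] * (n - n_above_cesd),
            "STAI_B": [60.0] * n_above_stai + [40.0] * (n - n_above_stai),
        })

    def test_cesd_cutoff_percentage(self):
        df = summarize_cohort(self._patients(), cutoffs={"CESD": 22})
        row = df[df["variable"] == "CESD>22"].iloc[0]
        assert row["count"] == 8
        assert row["pct"] == 21.6

    def test_stai_cutoff_percentage(self):
        df = summarize_cohort(self._patients(), cutoffs={"STAI_B": 49})
        row = df[df["variable"] == "STAI_B>49"].iloc[0]
        assert row["count"] == 18
        assert row["pct"] == 48.6

    def test_sex_percentage(self):
        df = summarize_cohort(self._patients())
        row = df[df["variable"] == "sex=M"].iloc[0]
        assert row["count"] == 30
        assert row["pct"] == 81.1

    def test_zero_above_cutoff(self):
        df = summarize_cohort(self._patients(n_above_cesd=0),
                              cutoffs={"CESD": 22})
        row = df[df["variable"] == "CESD>22"].iloc[0]
        assert row["count"] == 0 and row["pct"] == 0.0

    def test_descriptives(self):
        rec = pd.DataFrame({"subject_id": ["a", "b", "c"], "group": "patient",
                            "age": [20.0, 30.0, 40.0]})
        row = summarize_cohort(rec)[lambda d: d["variable"] == "age"].iloc[0]
        assert row["n"] == 3
        assert row["mean"] == pytest.approx(30.0)
        assert row["sd"] == pytest.approx(10.0)
        assert (row["min"], row["max"]) == (20.0, 40.0)

    def test_empty_records_error(self):
        with pytest.raises(ValueError):
            summarize_cohort(pd.DataFrame())

    def test_round_half_up(self):
        assert round_half_up(48.65) == 48.7
        assert round_half_up(21.62162) == 21.6
        assert round_half_up(81.08108) == 81.1
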