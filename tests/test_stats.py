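"""Association, survival and drug statistics against enumeration oracles."""

import numpy as np
import pandas as pd
import pytest

from brafsig.stats import (
    cox_univariate,
    dichotomize_by_median,
    drug_correlations,
    fisher_exact_2x2,
    km_logrank,
    response_logistic,
    response_rate_by_group,
    roc_auc,
    wilcoxon_one_sided,
)
from brafsig.types import DegenerateInputError, ParameterError
from conftest import (
    oracle_fisher_two_sided,
    oracle_logrank,
    oracle_wilcoxon_greater,
)


class TestDichotomize:
    def test_even_split(self):
        g = dichotomize_by_median(pd.Series([1, 2, 3, 4],
                                            index=list("abcd")))
        assert g.tolist() == ["low", "low", "high", "high"]

    def test_odd_n_median_goes_low(self):
        g = dichotomize_by_median(pd.Series([1, 2, 3]))
        assert g.tolist() == ["low", "low", "high"]

    def test_identical_values_rejected(self):
        with pytest.raises(DegenerateInputError):
            dichotomize_by_median([5, 5, 5])

    def test_group_imbalance_bounded_by_median_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            v = rng.integers(0, 10, size=rng.integers(4, 30)).astype(float)
            if np.ptp(v) == 0:
                continue
            g = dichotomize_by_median(v)
            n_ties = int((v == np.median(v)).sum())
            # counting bound: #<med and #>med are each at most n/2, so the
            # split is balanced up to the values sitting exactly at the median
            assert abs((g == "high").sum() - (g == "low").sum()) <= 2 * n_ties


class TestWilcoxon:
    def test_worked_example(self):
        res = wilcoxon_one_sided([3, 4, 5], [1, 2])
        assert res.p_value == pytest.approx(0.1)
        assert "exact" in res.test_name

    def test_identical_groups_not_significant(self):
        res = wilcoxon_one_sided([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value >= 0.5

    def test_empty_group_rejected(self):
        with pytest.raises(ParameterError):
            wilcoxon_one_sided([], [1.0])

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            n_a = int(rng.integers(1, 6))
            n_b = int(rng.integers(1, 6))
            pooled = rng.permutation(np.arange(1.0, n_a + n_b + 1))
            a, b = pooled[:n_a], pooled[n_a:]
            res = wilcoxon_one_sided(a, b)
            assert res.p_value == pytest.approx(
                oracle_wilcoxon_greater(a, b), abs=1e-12
            )

    def test_ties_switch_to_corrected_approximation(self):
        res = wilcoxon_one_sided([1.0, 2.0, 2.0], [2.0, 3.0])
        assert "asymptotic" in res.test_name
        assert 0 < res.p_value <= 1


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]).auc == 1.0

    def test_worked_three_quarters(self):
        assert roc_auc([1, 2, 3, 4], [0, 1, 0, 1]).auc == pytest.approx(0.75)

    def test_all_tied_scores_give_half(self):
        assert roc_auc([5, 5, 5, 5], [0, 1, 0, 1]).auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            roc_auc([1, 2], [1, 1])

    def test_equals_normalized_mann_whitney_u(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(2)
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, 60)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        u = mannwhitneyu(scores[labels == 1], scores[labels == 0],
                         alternative="two-sided").statistic
        expected = u / ((labels == 1).sum() * (labels == 0).sum())
        assert roc_auc(scores, labels).auc == pytest.approx(expected)


def _clinical(times, events, ids=None):
    ids = ids or [f"s{i}" for i in range(len(times))]
    return pd.DataFrame({
        "sample_id": ids, "os_time": times, "os_event": events,
        "age": 60.0, "sex": 0,
    })


class TestKmLogrank:
    def test_identical_groups_give_null_statistic(self):
        times = [5, 10, 15, 20, 25, 30]
        events = [1, 1, 0, 1, 1, 0]
        clin = _clinical(times + times, events + events)
        groups = pd.Series(["a"] * 6 + ["b"] * 6,
                           index=clin["sample_id"])
        res = km_logrank(clin, groups)
        assert res.logrank_statistic == pytest.approx(0.0, abs=1e-10)
        assert res.logrank_p == pytest.approx(1.0, abs=1e-10)

    def test_matches_hand_logrank_oracle(self):
        times = [3.0, 5.0, 7.0, 11.0, 13.0, 17.0]
        events = [1, 1, 1, 1, 1, 1]
        group = [0, 1, 0, 1, 0, 1]
        clin = _clinical(times, events)
        groups = pd.Series(["g0" if g == 0 else "g1" for g in group],
                           index=clin["sample_id"])
        res = km_logrank(clin, groups)
        assert res.logrank_statistic == pytest.approx(
            oracle_logrank(times, events, group), abs=1e-10
        )

    def test_invariant_under_time_scaling(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(100, 40)
        events = rng.integers(0, 2, 40)
        events[0] = 1
        clin1 = _clinical(times, events)
        clin2 = _clinical(times * 10, events)
        groups = pd.Series(["a"] * 20 + ["b"] * 20, index=clin1["sample_id"])
        r1 = km_logrank(clin1, groups)
        r2 = km_logrank(clin2, groups)
        assert r1.logrank_statistic == pytest.approx(r2.logrank_statistic)
        assert r1.logrank_p == pytest.approx(r2.logrank_p)

    def test_km_curves_non_increasing_from_one(self):
        rng = np.random.default_rng(4)
        clin = _clinical(rng.exponential(50, 30), rng.integers(0, 2, 30))
        clin.loc[0, "os_event"] = 1
        groups = pd.Series(["a"] * 15 + ["b"] * 15, index=clin["sample_id"])
        res = km_logrank(clin, groups)
        for curve in res.km_curves.values():
            s = curve["survival"].to_numpy()
            assert (np.diff(s) <= 1e-12).all()
            assert s[0] <= 1.0 + 1e-12

    def test_zero_events_rejected(self):
        clin = _clinical([1.0, 2.0], [0, 0])
        groups = pd.Series(["a", "b"], index=clin["sample_id"])
        with pytest.raises(DegenerateInputError):
            km_logrank(clin, groups)


class TestCoxUnivariate:
    def test_identical_survival_gives_unit_hazard_ratio(self):
        times = [5.0, 8.0, 12.0, 20.0, 33.0]
        events = [1, 1, 0, 1, 1]
        clin = _clinical(times + times, events + events)
        cov = pd.Series([0.0] * 5 + [1.0] * 5, index=clin["sample_id"])
        res = cox_univariate(clin, cov)
        assert res.hazard_ratio == pytest.approx(1.0, abs=1e-6)
        assert res.ci_low <= res.hazard_ratio <= res.ci_high

    def test_label_flip_inverts_hazard_ratio(self):
        rng = np.random.default_rng(5)
        times = rng.exponential(10, 60)
        cov = (np.arange(60) < 30).astype(float)
        times[cov == 1] *= 2
        clin = _clinical(times, [1] * 60)
        c1 = cox_univariate(clin, pd.Series(cov, index=clin["sample_id"]))
        c2 = cox_univariate(clin, pd.Series(1 - cov, index=clin["sample_id"]))
        assert c1.hazard_ratio == pytest.approx(1 / c2.hazard_ratio, rel=1e-6)

    def test_constant_covariate_rejected(self):
        clin = _clinical([1.0, 2.0], [1, 1])
        with pytest.raises(ParameterError):
            cox_univariate(clin, pd.Series([1.0, 1.0],
                                           index=clin["sample_id"]))


class TestDrugCorrelations:
    def _table(self, scores, ic50, drug="D1"):
        return pd.DataFrame({
            "cell_line_id": list(scores.index),
            "drug_name": drug,
            "ic50": ic50,
        })

    def test_noise_free_linear_negative_relation(self):
        scores = pd.Series([1.0, 2.0, 3.0, 4.0],
                           index=["c1", "c2", "c3", "c4"])
        out = drug_correlations(scores, self._table(scores, -scores.to_numpy()))
        assert out["pearson_rho"].iloc[0] == pytest.approx(-1.0)

    def test_matches_covariance_formula_oracle(self):
        rng = np.random.default_rng(6)
        scores = pd.Series(rng.normal(size=50),
                           index=[f"c{i}" for i in range(50)])
        y = rng.normal(size=50)
        out = drug_correlations(scores, self._table(scores, y))
        x = scores.to_numpy()
        rho = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert out["pearson_rho"].iloc[0] == pytest.approx(rho, abs=1e-12)

    def test_constant_ic50_flagged_undefined(self):
        scores = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        out = drug_correlations(scores, self._table(scores, [7.0, 7.0, 7.0]))
        assert not out["defined"].iloc[0]
        assert np.isnan(out["pearson_rho"].iloc[0])

    def test_too_few_shared_lines_rejected(self):
        scores = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ParameterError, match=">= 3"):
            drug_correlations(scores, self._table(scores, [1.0, 2.0]))


class TestFisherExact:
    def test_matches_enumeration_oracle(self):
        for table in ([[5, 1], [1, 5]], [[2, 3], [3, 0]], [[4, 0], [0, 4]],
                      [[1, 2], [2, 1]]):
            res = fisher_exact_2x2(table)
            assert res.p_value == pytest.approx(
                oracle_fisher_two_sided(table), abs=1e-12
            )

    def test_proportional_rows_give_p_one(self):
        assert fisher_exact_2x2([[2, 4], [3, 6]]).p_value == pytest.approx(1.0)

    def test_transpose_invariance(self):
        t = np.array([[7, 2], [3, 9]])
        assert fisher_exact_2x2(t).p_value == pytest.approx(
            fisher_exact_2x2(t.T).p_value
        )

    def test_negative_entries_rejected(self):
        with pytest.raises(ParameterError):
            fisher_exact_2x2([[1, -1], [2, 3]])


class TestResponseLogistic:
    def test_recovers_planted_direction(self):
        rng = np.random.default_rng(7)
        score = rng.normal(size=200)
        p = 1 / (1 + np.exp(1.5 * score))  # high score -> resistant
        resp = (rng.uniform(size=200) < p).astype(int)
        tbl = response_logistic(resp, score)
        row = tbl.set_index("term").loc["score"]
        assert row["estimate"] < 0
        assert row["p_value"] < 0.01

    def test_null_covariate_type_i_error(self):
        rng = np.random.default_rng(8)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            resp = rng.integers(0, 2, 80)
            if resp.min() == resp.max():
                resp[0] = 1 - resp[0]
            noise = rng.normal(size=80)
            tbl = response_logistic(resp, noise)
            p = tbl.set_index("term").loc["score", "p_value"]
            rejections += p < 0.05
        assert 0.01 <= rejections / n_rep <= 0.11

    def test_covariates_added_when_supplied(self):
        rng = np.random.default_rng(9)
        resp = rng.integers(0, 2, 100)
        resp[:2] = [0, 1]
        tbl = response_logistic(
            resp, rng.normal(size=100), age=rng.uniform(30, 85, 100),
            sex=rng.integers(0, 2, 100),
            other_therapy=rng.integers(0, 2, 100),
        )
        assert set(tbl["term"]) == {"intercept", "score", "age", "sex",
                                    "other_therapy"}

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            response_logistic(np.ones(10), np.arange(10.0))


class TestResponseRates:
    def test_worked_rates(self):
        resp = [1] * 6 + [0] * 4 + [1] * 2 + [0] * 8
        groups = ["low"] * 10 + ["high"] * 10
        table, rates = response_rate_by_group(resp, groups)
        assert rates["low"] == pytest.approx(0.6)
        assert rates["high"] == pytest.approx(0.2)
        assert table.loc["low"].tolist() == [6, 4]

    def test_marginals_conserved(self):
        rng = np.random.default_rng(10)
        resp = rng.integers(0, 2, 50)
        groups = np.where(rng.uniform(size=50) < 0.5, "low", "high")
        table, _ = response_rate_by_group(resp, groups)
        assert table.to_numpy().sum() == 50
        for lv in ("low", "high"):
            assert table.loc[lv].sum() == (groups == lv).sum()

    def test_declared_empty_group_rejected(self):
        with pytest.raises(DegenerateInputError):
            response_rate_by_group([1, 0], ["low", "low"],
                                   levels=["low", "high"])

    def test_feeds_fisher(self):
        table, _ = response_rate_by_group(
            [1] * 6 + [0] * 4 + [1] * 2 + [0] * 8,
            ["low"] * 10 + ["high"] * 10,
        )
        res = fisher_exact_2x2(table.to_numpy())
        assert 0 < res.p_value <= 1
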