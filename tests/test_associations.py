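"""Validation batteries: KM/log-rank, chi-square, rank-sum, Spearman and
clinical Cox regressions."""

import numpy as np
import pandas as pd
import pytest

from irlncpair.associations import (
    bh_within,
    chisq_clinical_association,
    cox_clinical,
    km_logrank,
    ranksum_by_group,
    spearman_with_score,
)
from irlncpair.cox import _derivatives, _prepare

from conftest import survival_cohort


def scores_frame(time, event, score=None, group=None, index=None):
    n = len(time)
    if index is None:
        index = [f"S{i}" for i in range(n)]
    return pd.DataFrame({
        "score": score if score is not None else np.zeros(n),
        "group": group if group is not None else ["low"] * n,
        "time": time, "event": event,
    }, index=pd.Index(index, name="sample"))


class TestKMLogrank:
    def test_hand_product_limit(self):
        """Textbook fixture: the curves equal running products computed by
        hand."""
        # group A: 1 (censored), 2 (event), 3 (event), 4 (censored)
        # group B: 2 (event), 3 (censored), 5 (event)
        scores = scores_frame(
            time=[1, 2, 3, 4, 2, 3, 5],
            event=[0, 1, 1, 0, 1, 0, 1],
            group=["high"] * 4 + ["low"] * 3,
        )
        curves, record = km_logrank(scores)
        a = curves[curves["group"] == "high"].set_index("time")["survival"]
        # A: at t=2, 3 at risk, 1 event -> 2/3; at t=3, 2 at risk, 1 event -> 2/3*1/2
        assert a.loc[2.0] == pytest.approx(2 / 3, abs=1e-12)
        assert a.loc[3.0] == pytest.approx(2 / 3 * 1 / 2, abs=1e-12)
        b = curves[curves["group"] == "low"].set_index("time")["survival"]
        # B: at t=2, 3 at risk, 1 event -> 2/3; at t=5, 1 at risk, 1 event -> 0
        assert b.loc[2.0] == pytest.approx(2 / 3, abs=1e-12)
        assert b.loc[5.0] == pytest.approx(0.0, abs=1e-12)
        assert 0 <= record["p"] <= 1

    def test_identical_groups_null(self):
        time = [1.0, 2.0, 3.0, 4.0]
        event = [1, 0, 1, 1]
        scores = scores_frame(time + time, event + event,
                              group=["high"] * 4 + ["low"] * 4)
        _, record = km_logrank(scores)
        assert record["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert record["p"] == pytest.approx(1.0, abs=1e-12)

    def test_separated_groups_detected(self):
        rng = np.random.default_rng(1)
        x = rng.binomial(1, 0.5, (400, 1)).astype(float)
        time, event = survival_cohort(rng, x, [np.log(2.5)])
        scores = scores_frame(time, event,
                              group=np.where(x[:, 0] == 1, "high", "low"))
        _, record = km_logrank(scores)
        assert record["p"] < 0.001

    def test_single_group_is_na(self):
        scores = scores_frame([1.0, 2.0], [1, 1], group=["high", "high"])
        curves, record = km_logrank(scores)
        assert np.isnan(record["p"])
        assert not curves.empty

    def test_matches_cox_score_test(self):
        """On tie-free data the two-sample log-rank statistic equals the
        Cox score test (gradient^2 / information at beta = 0)."""
        rng = np.random.default_rng(2)
        x = rng.binomial(1, 0.5, (200, 1)).astype(float)
        time, event = survival_cohort(rng, x, [0.7])
        scores = scores_frame(time, event, group=np.where(x[:, 0] == 1, "high", "low"))
        _, record = km_logrank(scores)
        t, d, Xs = _prepare(time, event, x)
        _, grad, hess = _derivatives(t, d, Xs, np.zeros(1), 0.0)
        score_stat = float(grad[0] ** 2 / -hess[0, 0])
        assert record["statistic"] == pytest.approx(score_stat, rel=1e-6)

    def test_time_unit_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.binomial(1, 0.5, (100, 1)).astype(float)
        time, event = survival_cohort(rng, x, [1.0])
        g = np.where(x[:, 0] == 1, "high", "low")
        _, rec_days = km_logrank(scores_frame(time * 365.25, event, group=g))
        _, rec_years = km_logrank(scores_frame(time, event, group=g))
        assert rec_days["p"] == pytest.approx(rec_years["p"], abs=1e-12)


class TestChiSquare:
    def build(self, counts):
        """counts[(group, category)] -> long clinical/score frames."""
        rows_g, rows_f, idx = [], [], []
        i = 0
        for (g, f), k in counts.items():
            for _ in range(k):
                idx.append(f"S{i}")
                rows_g.append(g)
                rows_f.append(f)
                i += 1
        scores = scores_frame([1.0] * i, [0] * i, group=rows_g, index=idx)
        clinical = pd.DataFrame({"stage": rows_f}, index=pd.Index(idx, name="sample"))
        return scores, clinical

    def test_printed_fixture(self):
        """2x2 table [[20,10],[10,20]] gives chi2 = 20/3 by the O/E formula."""
        scores, clinical = self.build({("high", "I"): 20, ("high", "II"): 10,
                                       ("low", "I"): 10, ("low", "II"): 20})
        rec = chisq_clinical_association(scores, clinical, "stage")
        # independent O/E arithmetic: all expected counts are 15
        expect = 4 * (5.0 ** 2 / 15.0)
        assert rec["statistic"] == pytest.approx(expect, abs=1e-10)
        assert rec["p"] == pytest.approx(0.00982, abs=2e-4)

    def test_independent_table_zero(self):
        scores, clinical = self.build({("high", "I"): 20, ("high", "II"): 10,
                                       ("low", "I"): 40, ("low", "II"): 20})
        rec = chisq_clinical_association(scores, clinical, "stage")
        assert rec["statistic"] == pytest.approx(0.0, abs=1e-10)

    def test_degenerate_table_na(self):
        scores, clinical = self.build({("high", "I"): 5, ("low", "I"): 5})
        rec = chisq_clinical_association(scores, clinical, "stage")
        assert np.isnan(rec["p"])
        assert "degenerate" in rec["effect"]

    def test_low_expected_flagged(self):
        scores, clinical = self.build({("high", "I"): 2, ("high", "II"): 30,
                                       ("low", "I"): 3, ("low", "II"): 28})
        rec = chisq_clinical_association(scores, clinical, "stage")
        assert rec["low_expected"] is True


class TestRankSum:
    def test_exact_small_sample(self):
        """{1,2,3} vs {4,5,6}: U = 0, exact two-sided p = 2/20."""
        vals = pd.Series([1, 2, 3, 4, 5, 6], dtype=float)
        grp = pd.Series(["a", "a", "a", "b", "b", "b"])
        rec = ranksum_by_group(vals, grp, "demo")
        assert min(rec["statistic"], 9 - rec["statistic"]) == 0
        assert rec["p"] == pytest.approx(0.1, abs=1e-12)

    def test_identical_values_flagged(self):
        rec = ranksum_by_group(pd.Series([2.0] * 6), pd.Series(["a"] * 3 + ["b"] * 3), "x")
        assert rec["p"] == 1.0
        assert "identical" in rec["effect"]

    def test_null_permutations_uniform(self):
        """Label permutations on a fixed sample give approximately uniform
        p-values."""
        rng = np.random.default_rng(4)
        vals = pd.Series(rng.normal(size=40))
        ps = []
        for _ in range(200):
            grp = pd.Series(rng.permutation(["a"] * 20 + ["b"] * 20))
            ps.append(ranksum_by_group(vals, grp, "x")["p"])
        ps = np.asarray(ps)
        assert (ps < 0.05).mean() <= 0.08
        assert ps.mean() == pytest.approx(0.5, abs=0.1)


class TestSpearman:
    def test_identity_and_antitone(self):
        s = pd.Series(np.arange(10, dtype=float), index=[f"S{i}" for i in range(10)])
        assert spearman_with_score(s, s, "x")["statistic"] == pytest.approx(1.0)
        assert spearman_with_score(s, -s, "x")["statistic"] == pytest.approx(-1.0)

    def test_matches_rank_difference_formula(self):
        """No-ties fixture agrees with 1 - 6*sum(d^2)/(n(n^2-1))."""
        rng = np.random.default_rng(5)
        idx = [f"S{i}" for i in range(10)]
        a = pd.Series(rng.permutation(10).astype(float), index=idx)
        b = pd.Series(rng.permutation(10).astype(float), index=idx)
        d = a.rank() - b.rank()
        expect = 1 - 6 * (d ** 2).sum() / (10 * 99)
        assert spearman_with_score(a, b, "x")["statistic"] == pytest.approx(expect, abs=1e-12)

    def test_constant_vector_na(self):
        s = pd.Series([1.0, 2.0, 3.0])
        rec = spearman_with_score(s, pd.Series([5.0, 5.0, 5.0]), "x")
        assert np.isnan(rec["p"])


class TestCoxClinical:
    def make(self, n=300, seed=6, with_clinical=True):
        rng = np.random.default_rng(seed)
        score = rng.normal(size=n)
        time, event = survival_cohort(rng, score[:, None], [1.0])
        idx = [f"S{i}" for i in range(n)]
        scores = scores_frame(time, event, score=score, index=idx)
        cols = {}
        if with_clinical:
            cols = {
                "age": rng.integers(40, 85, n),
                "stage": rng.choice(["I", "II", "III", "IV"], n),
                "T": rng.choice(["T1", "T2", "T3", "T4"], n),
                "N": rng.choice(["N0", "N1", "N2"], n),
                "M": rng.choice(["M0", "M1"], n),
            }
        clinical = pd.DataFrame(cols, index=pd.Index(idx, name="sample"))
        return scores, clinical

    def test_true_predictor_significant(self):
        scores, clinical = self.make(n=400)
        uni = cox_clinical(scores, clinical, mode="uni").set_index("feature")
        assert uni.loc["score", "hr"] > 1
        assert uni.loc["score", "p"] < 0.001

    def test_multi_single_covariate_equals_uni(self):
        scores, clinical = self.make(with_clinical=False)
        uni = cox_clinical(scores, clinical, mode="uni").set_index("feature")
        multi = cox_clinical(scores, clinical, mode="multi").set_index("feature")
        assert multi.loc["score", "hr"] == pytest.approx(uni.loc["score", "hr"], abs=1e-10)

    def test_collinear_covariate_dropped(self):
        scores, clinical = self.make()
        clinical = clinical.copy()
        clinical["age"] = 2.0  # constant -> dropped before the rank check
        multi = cox_clinical(scores, clinical, mode="multi").set_index("feature")
        assert "NA" in str(multi.loc["age", "effect"]) or np.isnan(multi.loc["age", "p"])

    def test_null_covariate_ci_coverage(self):
        """A covariate independent of survival: the 95% CI covers HR = 1 at
        roughly the nominal rate."""
        cover = 0
        n_rep = 40
        for seed in range(n_rep):
            rng = np.random.default_rng(1000 + seed)
            time, event = survival_cohort(rng, rng.normal(size=(150, 1)), [0.0])
            idx = [f"S{i}" for i in range(150)]
            scores = scores_frame(time, event, score=rng.normal(size=150), index=idx)
            uni = cox_clinical(scores, pd.DataFrame(index=pd.Index(idx, name="sample")),
                               mode="uni").set_index("feature")
            if uni.loc["score", "ci_low"] <= 1.0 <= uni.loc["score", "ci_high"]:
                cover += 1
        assert cover / n_rep >= 0.85


def test_bh_within_q_at_least_p():
    recs = [{"feature": f"f{i}", "test": "t", "statistic": 0.0,
             "p": p, "effect": ""} for i, p in enumerate([0.001, 0.02, 0.4, 0.9])]
    out = bh_within(recs)
    assert (out["q"] >= out["p"] - 1e-15).all()
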