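"""Risk scores, IPCW time-dependent ROC and the optimal-cutpoint search."""

import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter

from irlncpair.datatypes import CoxSignature, CutoffResult, ROCCurve
from irlncpair.risk import (
    assign_groups,
    censoring_survival,
    compute_risk_scores,
    select_cutoff,
    time_dependent_roc,
)

from conftest import indicator_cohort, survival_cohort


def mann_whitney_auc(case_scores, control_scores):
    """Exhaustive pair counting with ties at one half (the oracle)."""
    wins = 0.0
    for s in case_scores:
        for c in control_scores:
            wins += 1.0 if s > c else (0.5 if s == c else 0.0)
    return wins / (len(case_scores) * len(control_scores))


class TestRiskScores:
    def test_zero_coefficients_zero_scores(self):
        pm, _, planted = indicator_cohort(seed=1, n=30, p=3)
        sig = CoxSignature(pairs=list(planted), coef=np.zeros(3), loglik=0.0)
        scores = compute_risk_scores(sig, pm.values)
        assert (scores["score"] == 0).all()

    def test_single_binary_pair_two_values(self):
        pm, _, planted = indicator_cohort(seed=2, n=30, p=1)
        sig = CoxSignature(pairs=[planted[0]], coef=[1.3], loglik=0.0)
        scores = compute_risk_scores(sig, pm.values)
        assert set(scores["score"].unique()) <= {0.0, 1.3}

    def test_matches_independent_dot_product(self):
        pm, _, planted = indicator_cohort(seed=3, n=50, p=3)
        coef = np.array([0.7, -1.1, 0.4])
        sig = CoxSignature(pairs=list(planted), coef=coef, loglik=0.0)
        scores = compute_risk_scores(sig, pm.values)
        for s in pm.samples:
            manual = sum(c * pm.values.loc[p, s] for p, c in zip(planted, coef))
            assert scores.loc[s, "score"] == manual

    def test_missing_pair_aborts(self):
        pm, _, _ = indicator_cohort(seed=4, n=20, p=2)
        sig = CoxSignature(pairs=["NOPE|PAIR"], coef=[1.0], loglik=0.0)
        with pytest.raises(KeyError, match="NOPE"):
            compute_risk_scores(sig, pm.values)


class TestCensoringKM:
    def test_matches_lifelines_flipped_events(self):
        rng = np.random.default_rng(5)
        time, event = survival_cohort(rng, rng.normal(size=(80, 1)), [0.5])
        G = censoring_survival(time, event)
        kmf = KaplanMeierFitter().fit(time, 1 - event)
        for t in np.quantile(time, [0.1, 0.4, 0.7, 0.95]):
            expect = float(kmf.survival_function_at_times(t).iloc[0])
            assert G(t)[0] == pytest.approx(expect, abs=1e-10)

    def test_left_limit_precedes_drop(self):
        time = np.array([1.0, 2.0, 3.0])
        event = np.array([1, 0, 1])  # censoring at t=2
        G = censoring_survival(time, event)
        assert G(2.0, left=True)[0] == 1.0
        assert G(2.0)[0] < 1.0


class TestTimeDependentROC:
    def test_reduces_to_mann_whitney_without_censoring(self):
        rng = np.random.default_rng(7)
        time = rng.uniform(0.2, 6.0, 20)
        event = np.ones(20, dtype=int)
        score = rng.normal(size=20).round(1)  # rounding forces some ties
        roc = time_dependent_roc(score, time, event, horizon=3.0)
        cases = score[(time <= 3.0)]
        controls = score[time > 3.0]
        assert roc.auc == pytest.approx(mann_whitney_auc(cases, controls), abs=1e-12)

    def test_constant_scores_give_half(self):
        time = np.array([1.0, 2.0, 4.0, 5.0])
        event = np.array([1, 1, 1, 0])
        roc = time_dependent_roc(np.ones(4), time, event, horizon=3.0)
        assert roc.auc == 0.5

    def test_invariant_to_monotone_score_transform(self):
        rng = np.random.default_rng(8)
        time, event = survival_cohort(rng, rng.normal(size=(100, 1)), [1.0])
        score = rng.normal(size=100)
        a = time_dependent_roc(score, time, event, horizon=3.0).auc
        b = time_dependent_roc(np.exp(2 * score) + 5, time, event, horizon=3.0).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_ipcw_approaches_uncensored_auc_as_censoring_vanishes(self):
        """Shrinking the censoring window toward late times drives the IPCW
        AUC to the uncensored Mann-Whitney value."""
        rng = np.random.default_rng(9)
        n = 600
        x = rng.normal(size=(n, 1))
        lp = 1.2 * x[:, 0]
        t_event = rng.exponential(1.0 / (0.3 * np.exp(lp)))
        score = lp
        target = mann_whitney_auc(score[t_event <= 2.0], score[t_event > 2.0])
        gaps = []
        for lo in (0.5, 4.0, 25.0):
            t_cens = rng.uniform(lo, lo + 5.0, n)
            time = np.minimum(t_event, t_cens)
            event = (t_event <= t_cens).astype(int)
            auc = time_dependent_roc(score, time, event, horizon=2.0).auc
            gaps.append(abs(auc - target))
        assert gaps[-1] < 0.01
        assert gaps[-1] <= gaps[0] + 0.02

    def test_strong_effect_discriminates(self):
        rng = np.random.default_rng(10)
        x = rng.binomial(1, 0.5, (400, 1)).astype(float)
        time, event = survival_cohort(rng, x, [2.0], baseline_hazard=0.15)
        roc = time_dependent_roc(x[:, 0], time, event, horizon=3.0)
        assert roc.auc > 0.7

    def test_requires_cases_and_controls(self):
        with pytest.raises(ValueError):
            time_dependent_roc([1.0, 2.0], [0.5, 0.6], [1, 1], horizon=3.0)


class TestCutoff:
    def roc_from_points(self, thresholds, sens, spec):
        tab = pd.DataFrame({"threshold": thresholds, "sensitivity": sens,
                            "specificity": spec})
        return ROCCurve(horizon=3.0, table=tab, auc=0.5)

    def test_youden_picks_best_point(self):
        roc = self.roc_from_points([4.0, 3.0, 2.0, 1.0],
                                   [1.0, 0.9, 0.4, 0.0],
                                   [0.0, 0.8, 0.95, 1.0])
        cut = select_cutoff(roc, criterion="youden")
        assert cut.threshold == 3.0
        assert cut.value == pytest.approx(0.7)

    def test_matches_exhaustive_search(self):
        """The chosen cutoff attains the maximum of Youden's J over every
        observed score, recomputed by brute force."""
        rng = np.random.default_rng(11)
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            time, event = survival_cohort(rng, rng.normal(size=(60, 1)), [1.0])
            score = rng.normal(size=60).round(1)
            roc = time_dependent_roc(score, time, event, horizon=3.0)
            cut = select_cutoff(roc)
            best_j, best_thr = -np.inf, None
            for c in sorted(np.unique(score), reverse=True):
                row = roc.table[roc.table["threshold"] == c].iloc[0]
                j = row["sensitivity"] + row["specificity"] - 1
                if j > best_j + 1e-12 or (abs(j - best_j) <= 1e-12 and c < best_thr):
                    best_j, best_thr = j, c
            assert cut.threshold == best_thr
            assert cut.value == pytest.approx(best_j, abs=1e-12)

    def test_perfect_separation_j_one(self):
        time = np.array([1.0, 1.5, 6.0, 7.0])
        event = np.array([1, 1, 0, 0])
        score = np.array([5.0, 4.0, 1.0, 0.5])
        roc = time_dependent_roc(score, time, event, horizon=3.0)
        cut = select_cutoff(roc)
        assert cut.value == pytest.approx(1.0)

    def test_closest_criterion_available(self):
        roc = self.roc_from_points([3.0, 2.0, 1.0], [1.0, 0.8, 0.0],
                                   [0.1, 0.9, 1.0])
        cut = select_cutoff(roc, criterion="closest")
        assert cut.threshold == 2.0


class TestGroups:
    def make_scores(self, values):
        return pd.DataFrame({"score": values},
                            index=[f"S{i}" for i in range(len(values))])

    def cut(self, thr):
        return CutoffResult(threshold=thr, criterion="youden", value=0.0,
                            table=pd.DataFrame())

    def test_threshold_below_min_all_high(self):
        scores = assign_groups(self.make_scores([1.0, 2.0, 3.0]), self.cut(0.5))
        assert (scores["group"] == "high").all()

    def test_strict_rule_at_median(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0]
        scores = assign_groups(self.make_scores(vals), self.cut(3.0))
        assert (scores["group"] == "high").sum() == 2
        assert (scores["group"] == "low").sum() == 3

    def test_groups_recover_latent_split(self):
        rng = np.random.default_rng(12)
        latent = rng.binomial(1, 0.5, 300)
        score = latent * 2.0 + rng.normal(scale=0.2, size=300)
        scores = self.make_scores(score)
        groups = assign_groups(scores, self.cut(1.0))
        agree = ((groups["group"] == "high") == (latent == 1)).mean()
        assert agree >= 0.9
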