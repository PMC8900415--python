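"""Risk scores, time-dependent ROC curves and the high/low-risk cutoff.

The risk score is the Cox linear predictor ``sum_i Coef_i * x_i`` over the
signature's 0/1 pair indicators — no standardisation, so with binary
covariates the score takes at most 2^n distinct values.

The ROC at horizon t uses the cumulative/dynamic definition with inverse
probability of censoring weights (IPCW): cases are subjects with an event
by t, weighted by 1/G(T_i-) where G is the Kaplan-Meier estimate of the
censoring survival function; controls are subjects still at risk after t.
With no censoring G = 1 and the AUC reduces exactly to the Mann-Whitney
statistic of the binary outcome "event by t" against the score; score ties
count one half.

The cutoff that splits patients into high and low risk maximises a
standard optimal-cutpoint criterion on the 3-year curve — Youden's
J = sensitivity + specificity - 1 by default, or the closest-to-(0,1)
distance — with ties broken toward the smaller threshold (more patients
called high-risk).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import CoxSignature, CutoffResult, ROCCurve

__all__ = [
    "DAYS_PER_YEAR",
    "compute_risk_scores",
    "censoring_survival",
    "time_dependent_roc",
    "select_cutoff",
    "assign_groups",
]

DAYS_PER_YEAR = 365.25

log = logging.getLogger(__name__)


def compute_risk_scores(sig: CoxSignature, pair_values: pd.DataFrame) -> pd.DataFrame:
    """Per-sample risk score from the signature's coefficients.

    ``pair_values`` is the pairs x samples indicator frame; every signature
    pair must be present.  Returns a frame indexed by sample with a single
    ``score`` column.
    """
    missing = [p for p in sig.pairs if p not in pair_values.index]
    if missing:
        raise KeyError(f"signature pairs absent from the pair matrix: {missing}")
    if sig.n == 0:
        scores = np.zeros(pair_values.shape[1])
    else:
        X = pair_values.loc[sig.pairs].to_numpy(dtype=float).T
        scores = X @ sig.coef
    return pd.DataFrame({"score": scores},
                        index=pd.Index(pair_values.columns, name="sample"))


def censoring_survival(time, event):
    """Kaplan-Meier estimate of the censoring survival function G.

    Events and censorings swap roles: a "death" here is a censoring.
    Returns a step function ``G(t, left=False)``; ``left=True`` evaluates
    the left limit G(t-), the weight denominator for cases.
    """
    time = np.asarray(time, dtype=float)
    cens = 1 - np.asarray(event, dtype=int)
    order = np.argsort(time, kind="stable")
    t, c = time[order], cens[order]
    uniq = np.unique(t)
    surv = []
    g = 1.0
    at_risk = len(t)
    for u in uniq:
        mask = t == u
        d = int(c[mask].sum())           # censorings at u are "events" of G
        if at_risk > 0 and d > 0:
            g *= 1.0 - d / at_risk
        surv.append(g)
        at_risk -= int(mask.sum())
    uniq = np.asarray(uniq)
    surv = np.asarray(surv)

    def G(x, left: bool = False) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        side = "left" if left else "right"
        idx = np.searchsorted(uniq, x, side=side) - 1
        out = np.where(idx >= 0, surv[np.clip(idx, 0, None)], 1.0)
        return out

    return G


def time_dependent_roc(
    score, time, event, horizon: float, weight_cap: float = 20.0
) -> ROCCurve:
    """Cumulative/dynamic IPCW ROC curve at the given horizon.

    ``time`` must be on the same scale as ``horizon``.  Cases are subjects
    with an observed event at or before the horizon, controls those still
    under observation beyond it.  Case weights 1/G(T-) are truncated at
    ``weight_cap`` with a warning when the censoring KM reaches zero.
    """
    score = np.asarray(score, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    cases = (time <= horizon) & (event == 1)
    controls = time > horizon
    if cases.sum() < 1 or controls.sum() < 1:
        raise ValueError(
            f"ROC at t={horizon} needs >= 1 event by the horizon and >= 1 subject beyond it"
        )
    G = censoring_survival(time, event)
    g_case = G(time[cases], left=True)
    if np.any(g_case <= 0):
        log.warning("censoring KM hit zero for %d cases; weights capped at %g",
                    int((g_case <= 0).sum()), weight_cap)
    with np.errstate(divide="ignore"):
        w = np.where(g_case > 0, 1.0 / np.maximum(g_case, 1.0 / weight_cap), weight_cap)
    w = np.minimum(w, weight_cap)

    s_case = score[cases]
    s_ctrl = score[controls]
    thresholds = np.unique(score)[::-1]  # strictly decreasing
    w_total = w.sum()
    n_ctrl = s_ctrl.size
    sens = np.array([(w * (s_case > c)).sum() / w_total for c in thresholds])
    spec = np.array([(s_ctrl <= c).sum() / n_ctrl for c in thresholds])

    # weighted Mann-Whitney over case-control pairs, ties at half weight
    gt = (s_case[:, None] > s_ctrl[None, :]).astype(float)
    eq = (s_case[:, None] == s_ctrl[None, :]).astype(float)
    auc = float((w[:, None] * (gt + 0.5 * eq)).sum() / (w_total * n_ctrl))

    table = pd.DataFrame({"threshold": thresholds, "sensitivity": sens, "specificity": spec})
    return ROCCurve(horizon=float(horizon), table=table, auc=auc)


def select_cutoff(roc: ROCCurve, criterion: str = "youden") -> CutoffResult:
    """Optimal cutpoint on a ROC curve.

    ``"youden"`` maximises J = sensitivity + specificity - 1;
    ``"closest"`` minimises the squared distance to the perfect corner
    (1-sens)^2 + (1-spec)^2.  Ties go to the smaller threshold, which calls
    more patients high-risk.  The per-threshold criterion table is part of
    the result for inspection.
    """
    tab = roc.table.copy()
    if len(tab) < 2:
        raise ValueError("cutoff search needs a ROC curve with >= 2 thresholds")
    if criterion == "youden":
        tab["criterion"] = tab["sensitivity"] + tab["specificity"] - 1.0
        best_val = tab["criterion"].max()
    elif criterion == "closest":
        tab["criterion"] = -((1 - tab["sensitivity"]) ** 2 + (1 - tab["specificity"]) ** 2)
        best_val = tab["criterion"].max()
    else:
        raise ValueError(f"unknown cutoff criterion {criterion!r}")
    ties = tab[np.isclose(tab["criterion"], best_val, rtol=0, atol=1e-12)]
    threshold = float(ties["threshold"].min())
    return CutoffResult(threshold=threshold, criterion=criterion,
                        value=float(best_val), table=tab)


def assign_groups(scores: pd.DataFrame, cut: CutoffResult) -> pd.DataFrame:
    """Add a high/low risk ``group`` column: high iff score > threshold."""
    out = scores.copy()
    out["group"] = np.where(out["score"] > cut.threshold, "high", "low")
    n_high = int((out["group"] == "high").sum())
    n_low = len(out) - n_high
    log.info("risk groups: %d high / %d low at threshold %g", n_high, n_low, cut.threshold)
    if n_high == 0 or n_low == 0:
        log.warning("one risk group is empty; downstream group tests will be NA")
    return out
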