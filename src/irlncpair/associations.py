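"""Validation batteries run after risk stratification.

Kaplan-Meier / log-rank survival comparison of the risk groups, chi-square
association of the groups with clinicopathological categories, unpaired
rank-sum (Mann-Whitney) comparison of continuous values between groups,
Spearman correlation of immune-cell abundances with the risk score, and
uni/multivariate Cox regressions of the clinical covariates plus the
score.  Each battery applies Benjamini-Hochberg correction within itself.

Stage, T, N and M enter the chi-square tests as categoricals and the Cox
fits as numeric ordinals (stage I..IV -> 1..4, and so on); unknown codes
("TX", blank) are treated as missing and dropped per-analysis.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cox import fit_cox
from .simulate import STAGE_LEVELS, T_LEVELS, N_LEVELS, M_LEVELS

__all__ = [
    "km_logrank",
    "chisq_clinical_association",
    "ranksum_by_group",
    "spearman_with_score",
    "cox_clinical",
    "abundance_battery",
    "ic50_battery",
    "checkpoint_gene_battery",
    "bh_within",
]

log = logging.getLogger(__name__)

ORDINAL_CODES = {
    "stage": {lvl: i + 1 for i, lvl in enumerate(STAGE_LEVELS)},
    "T": {lvl: i + 1 for i, lvl in enumerate(T_LEVELS)},
    "N": {lvl: i + 1 for i, lvl in enumerate(N_LEVELS)},
    "M": {lvl: i + 1 for i, lvl in enumerate(M_LEVELS)},
}


def _ordinal(series: pd.Series, feature: str) -> pd.Series:
    codes = ORDINAL_CODES.get(feature)
    if codes is None:
        return pd.to_numeric(series, errors="coerce")
    return series.map(codes)


def bh_within(records: list[dict]) -> pd.DataFrame:
    """Assemble AssociationRecords and add BH q-values within the battery."""
    df = pd.DataFrame(records)
    if df.empty:
        return df
    ok = df["p"].notna()
    q = np.full(len(df), np.nan)
    if ok.any():
        q[ok.values] = multipletests(df.loc[ok, "p"].values, method="fdr_bh")[1]
    df["q"] = q
    return df


def km_logrank(scores: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Kaplan-Meier curves per risk group and the two-sample log-rank test.

    ``scores`` needs columns score/group/time/event.  Returns the stacked
    step-function table and an AssociationRecord dict; with a single
    non-empty group the curves are still computed and the test is NA.
    """
    curves = []
    groups = [g for g in ("high", "low") if (scores["group"] == g).any()]
    for g in groups:
        sub = scores[scores["group"] == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=g)
        tab = kmf.survival_function_.reset_index()
        tab.columns = ["time", "survival"]
        tab.insert(0, "group", g)
        curves.append(tab)
    curves = pd.concat(curves, ignore_index=True)

    record = {"feature": "risk_group", "test": "logrank",
              "statistic": np.nan, "p": np.nan, "effect": ""}
    if len(groups) == 2 and scores["event"].sum() >= 1:
        res = multivariate_logrank_test(scores["time"], scores["group"], scores["event"])
        record["statistic"] = float(res.test_statistic)
        record["p"] = float(res.p_value)
        med = scores.groupby("group")["time"].median()
        record["effect"] = f"median time high={med.get('high', np.nan):g} low={med.get('low', np.nan):g}"
    else:
        record["effect"] = "NA: single risk group"
    return curves, record


def chisq_clinical_association(
    scores: pd.DataFrame, clinical: pd.DataFrame, feature: str
) -> dict:
    """Pearson chi-square of risk group against one clinical category."""
    merged = scores.join(clinical[[feature]], how="inner").dropna(subset=[feature])
    merged = merged[merged[feature].astype(str).str.len() > 0]
    record = {"feature": feature, "test": "chisq", "statistic": np.nan,
              "p": np.nan, "effect": "", "low_expected": False}
    table = pd.crosstab(merged["group"], merged[feature])
    table = table.loc[:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        record["effect"] = "NA: degenerate contingency table"
        return record
    chi2, p, dof, expected = stats.chi2_contingency(table.values, correction=False)
    record.update(statistic=float(chi2), p=float(p),
                  effect=f"df={dof}", low_expected=bool((expected < 5).any()))
    return record


def ranksum_by_group(values: pd.Series, groups: pd.Series, feature: str) -> dict:
    """Unpaired two-sample rank-sum (Mann-Whitney) comparison.

    Exact enumeration when both groups have at most 8 untied observations,
    otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    df = pd.DataFrame({"v": values, "g": groups}).dropna()
    labels = df["g"].unique()
    record = {"feature": feature, "test": "ranksum", "statistic": np.nan,
              "p": np.nan, "effect": ""}
    if len(labels) != 2:
        record["effect"] = f"NA: expected two groups, found {len(labels)}"
        return record
    a = df.loc[df["g"] == labels[0], "v"].to_numpy(dtype=float)
    b = df.loc[df["g"] == labels[1], "v"].to_numpy(dtype=float)
    if a.size < 1 or b.size < 1:
        record["effect"] = "NA: empty group"
        return record
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        record.update(statistic=float(a.size * b.size / 2), p=1.0,
                      effect="flag: all values identical")
        return record
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    record.update(
        statistic=float(res.statistic), p=float(res.pvalue),
        effect=f"median {labels[0]}={np.median(a):g} {labels[1]}={np.median(b):g} ({method})",
    )
    return record


def spearman_with_score(score: pd.Series, values: pd.Series, feature: str) -> dict:
    """Spearman rank correlation of a per-sample value with the risk score."""
    df = pd.DataFrame({"s": score, "v": values}).dropna()
    record = {"feature": feature, "test": "spearman", "statistic": np.nan,
              "p": np.nan, "effect": ""}
    if len(df) < 3:
        record["effect"] = "NA: fewer than 3 paired observations"
        return record
    if df["v"].nunique() == 1 or df["s"].nunique() == 1:
        record["effect"] = "NA: constant vector"
        return record
    rho, p = stats.spearmanr(df["s"], df["v"])
    record.update(statistic=float(rho), p=float(p),
                  effect=f"rho={rho:.3f}", significant=bool(p < 0.05))
    return record


def abundance_battery(scores: pd.DataFrame, abundance: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation of each (method, cell type) column with the score,
    BH-corrected within each method label, plus group rank-sum tests."""
    records = []
    for method, sub in abundance.groupby("method", sort=True):
        for cell, cc in sub.groupby("cell_type", sort=True):
            vals = cc.set_index("sample")["abundance"]
            common = scores.index.intersection(vals.index)
            rec = spearman_with_score(scores.loc[common, "score"], vals.loc[common],
                                      feature=f"{method}:{cell}")
            rec["battery"] = f"abundance_spearman:{method}"
            records.append(rec)
            rs = ranksum_by_group(vals.loc[common], scores.loc[common, "group"],
                                  feature=f"{method}:{cell}")
            rs["battery"] = f"abundance_ranksum:{method}"
            records.append(rs)
    out = pd.DataFrame(records)
    parts = [bh_within(sub.to_dict("records"))
             for _, sub in out.groupby("battery", sort=True)]
    return pd.concat(parts, ignore_index=True)


def ic50_battery(scores: pd.DataFrame, ic50: pd.DataFrame) -> pd.DataFrame:
    """Rank-sum comparison of predicted drug IC50 between risk groups."""
    records = []
    for drug, sub in ic50.groupby("drug", sort=True):
        vals = sub.set_index("sample")["ic50"]
        common = scores.index.intersection(vals.index)
        rec = ranksum_by_group(vals.loc[common], scores.loc[common, "group"], feature=drug)
        rec["battery"] = "ic50_ranksum"
        records.append(rec)
    return bh_within(records)


def checkpoint_gene_battery(
    scores: pd.DataFrame, expr_values: pd.DataFrame, genes: list[str]
) -> pd.DataFrame:
    """Rank-sum comparison of configured gene expression between risk groups."""
    records = []
    for g in genes:
        if g not in expr_values.index:
            records.append({"feature": g, "test": "ranksum", "statistic": np.nan,
                            "p": np.nan, "effect": "NA: gene absent",
                            "battery": "checkpoint_ranksum"})
            continue
        vals = np.log2(expr_values.loc[g] + 1.0)
        common = scores.index.intersection(vals.index)
        rec = ranksum_by_group(vals.loc[common], scores.loc[common, "group"], feature=g)
        rec["battery"] = "checkpoint_ranksum"
        records.append(rec)
    return bh_within(records)


def cox_clinical(
    scores: pd.DataFrame, clinical: pd.DataFrame, mode: str = "uni"
) -> pd.DataFrame:
    """Cox regressions of survival on clinical covariates plus the score.

    ``mode="uni"`` fits one model per covariate; ``mode="multi"`` one joint
    model.  Ordinals are numeric-coded; collinear covariates are dropped
    from the joint fit with a warning.  Returns a forest-style table.
    """
    feats = ["age", "stage", "T", "N", "M", "score"]
    df = scores[["score", "time", "event"]].join(
        clinical[[c for c in ("age", "stage", "T", "N", "M") if c in clinical.columns]],
        how="inner",
    )
    for f in ("stage", "T", "N", "M"):
        if f in df.columns:
            df[f] = _ordinal(df[f], f)
    feats = [f for f in feats if f in df.columns]
    n_events = int(df["event"].sum())
    if mode == "multi" and n_events < 10:
        log.warning("multivariate Cox with only %d events; estimates may be unstable", n_events)

    records = []
    if mode == "uni":
        for f in feats:
            sub = df[["time", "event", f]].dropna()
            if sub[f].nunique() < 2:
                records.append({"feature": f, "test": "cox_uni", "statistic": np.nan,
                                "p": np.nan, "effect": "NA: constant covariate"})
                continue
            fit = fit_cox(sub["time"], sub["event"], sub[[f]].to_numpy(), names=[f])
            records.append(_cox_record(fit, 0, "cox_uni"))
    elif mode == "multi":
        sub = df[["time", "event"] + feats].dropna()
        use, const = [], []
        for f in feats:
            if sub[f].nunique() < 2:
                log.warning("covariate %s is constant; dropped from the joint fit", f)
                const.append(f)
                continue
            use.append(f)
        for f in const:
            records.append({"feature": f, "test": "cox_multi", "statistic": np.nan,
                            "p": np.nan, "effect": "NA: constant, dropped"})
        X = sub[use].to_numpy(dtype=float)
        # drop collinear columns via rank-revealing QR on the centered matrix
        Xc = X - X.mean(axis=0)
        keep, dropped = [], []
        for j in range(X.shape[1]):
            trial = keep + [j]
            if np.linalg.matrix_rank(Xc[:, trial]) == len(trial):
                keep.append(j)
            else:
                dropped.append(use[j])
        if dropped:
            log.warning("collinear covariates dropped: %s", dropped)
        use = [use[j] for j in keep]
        fit = fit_cox(sub["time"], sub["event"], X[:, keep], names=use)
        for i, f in enumerate(use):
            records.append(_cox_record(fit, i, "cox_multi"))
        for f in dropped:
            records.append({"feature": f, "test": "cox_multi", "statistic": np.nan,
                            "p": np.nan, "effect": "NA: collinear, dropped"})
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return bh_within(records)


def _cox_record(fit, i: int, test: str) -> dict:
    ci = fit.confint()
    return {
        "feature": fit.names[i],
        "test": test,
        "statistic": float(fit.coef[i] / fit.se[i]) if fit.se[i] > 0 else np.nan,
        "p": float(fit.wald_p()[i]),
        "effect": f"HR={np.exp(fit.coef[i]):.4g} CI=[{ci[i, 0]:.4g}, {ci[i, 1]:.4g}]",
        "hr": float(np.exp(fit.coef[i])),
        "ci_low": float(ci[i, 0]),
        "ci_high": float(ci[i, 1]),
    }
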