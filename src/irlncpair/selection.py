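"""From valid pairs to a Cox signature.

The selection chain has four stages:

1. univariate screen — one Breslow Cox fit per pair indicator, keeping
   pairs with Wald p below a threshold;
2. repeated lasso — R seeded cycles, each drawing a patient resample,
   fitting an L1-penalised Cox path and choosing the penalty by k-fold
   cross-validated partial likelihood (Verweij-van Houwelingen); the
   number of cycles in which each pair has a nonzero coefficient is its
   selection frequency, and pairs reaching ``min_freq`` are kept;
3. stepwise Cox — bidirectional AIC search over the selected pairs;
4. AUC zenith — over nested candidate models grown in descending lasso
   frequency, the smallest model attaining the maximum horizon AUC wins.

The path fits use scikit-survival's coxnet; every likelihood evaluated for
cross-validation, AIC or reporting is the package's own Breslow logPL so
numbers are comparable across stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .cox import breslow_loglik, fit_cox, fit_univariate_cox
from .datatypes import CoxSignature, PairIndicatorMatrix, PipelineHalt, EmptyResult
from .risk import compute_risk_scores, time_dependent_roc, DAYS_PER_YEAR

__all__ = [
    "univariate_cox_screen",
    "repeated_lasso_selection",
    "stepwise_cox",
    "build_nested_candidates",
    "auc_zenith_selection",
]

log = logging.getLogger(__name__)


def _aligned(pm: PairIndicatorMatrix | pd.DataFrame, clinical: pd.DataFrame):
    values = pm.values if isinstance(pm, PairIndicatorMatrix) else pm
    samples = [s for s in values.columns if s in clinical.index]
    if len(samples) < len(values.columns):
        log.warning("%d pair-matrix samples lack clinical data and were dropped",
                    len(values.columns) - len(samples))
    X = values[samples].to_numpy(dtype=float).T
    time = clinical.loc[samples, "time"].to_numpy(dtype=float)
    event = clinical.loc[samples, "event"].to_numpy(dtype=int)
    return list(values.index), X, time, event, samples


def univariate_cox_screen(
    pm: PairIndicatorMatrix, clinical: pd.DataFrame, p_max: float = 0.05
) -> pd.DataFrame:
    """Single-pair Cox fits; survivors have Wald p < p_max.

    Constant indicators (impossible after the validity filter) and fits
    with monotone likelihood are skipped with a warning.  Returns a frame
    indexed by pair with coef, hr, p and 95% CI, sorted by p.
    """
    pairs, X, time, event, _ = _aligned(pm, clinical)
    if event.sum() < 1:
        raise PipelineHalt("selection", "univariate screen needs at least one event")
    rows = []
    for j, pair in enumerate(pairs):
        x = X[:, j]
        if np.ptp(x) == 0:
            log.warning("pair %s has a constant indicator; skipped", pair)
            continue
        fit = fit_univariate_cox(time, event, x, name=pair)
        if not fit.converged:
            log.warning("pair %s: Cox fit did not converge (monotone likelihood?); excluded", pair)
            continue
        (lo, hi), = fit.confint()
        rows.append({"pair": pair, "coef": fit.coef[0], "hr": fit.hazard_ratios[0],
                     "p": fit.wald_p()[0], "ci_low": lo, "ci_high": hi})
    table = pd.DataFrame(rows, columns=["pair", "coef", "hr", "p", "ci_low", "ci_high"])
    table = table.set_index("pair")
    survivors = table[table["p"] < p_max].sort_values("p")
    log.info("univariate screen: %d of %d pairs at p < %g", len(survivors), len(table), p_max)
    if survivors.empty:
        raise EmptyResult("selection", "no pair passes the univariate Cox screen")
    return survivors


def _cv_partial_likelihood(X, time, event, alphas, k, rng) -> np.ndarray:
    """Per-alpha cross-validated partial likelihood (V&VH difference form)."""
    n = X.shape[0]
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    y_all = Surv.from_arrays(event=event.astype(bool), time=time)
    score = np.zeros(len(alphas))
    used = 0
    for fold in folds:
        train = np.setdiff1d(perm, fold, assume_unique=False)
        if event[train].sum() < 2 or event.sum() - event[train].sum() < 1:
            continue
        model = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas, fit_baseline_model=False)
        try:
            model.fit(X[train], y_all[train])
        except (ValueError, ArithmeticError):
            continue
        coefs = model.coef_  # (p, n_alphas_fit)
        fitted = list(model.alphas_)
        for ai, alpha in enumerate(alphas):
            if alpha not in fitted:
                continue
            b = coefs[:, fitted.index(alpha)]
            ll_full = breslow_loglik(time, event, X, b)
            ll_train = breslow_loglik(time[train], event[train], X[train], b)
            score[ai] += ll_full - ll_train
        used += 1
    if used == 0:
        raise ValueError("no usable cross-validation fold")
    return score


def repeated_lasso_selection(
    pm: PairIndicatorMatrix | pd.DataFrame,
    clinical: pd.DataFrame,
    R: int = 1000,
    min_freq: int = 2,
    seed: int = 0,
    k_folds: int = 10,
    n_alphas: int = 30,
    resample: str = "bootstrap",
    max_redraws: int = 20,
) -> tuple[pd.Series, list[str]]:
    """Frequency-recorded lasso-Cox over R resampling cycles.

    Each cycle draws a patient resample (bootstrap with replacement by
    default; ``resample="subsample"`` draws 63.2% without replacement),
    fits the L1 path, picks the penalty by ``k_folds``-fold cross-validated
    partial likelihood and records the pairs with nonzero coefficients.
    Returns the pair -> count table (descending) and the pairs whose count
    reaches ``min_freq``.  Fully deterministic given ``seed``.
    """
    pairs, X, time, event, _ = _aligned(pm, clinical)
    if len(pairs) < 2:
        raise PipelineHalt("selection", "repeated lasso needs >= 2 screened pairs")
    if event.sum() < 10:
        raise PipelineHalt("selection", "repeated lasso needs >= 10 events")
    n = X.shape[0]
    counts = pd.Series(0, index=pd.Index(pairs, name="pair"), dtype=int)
    streams = np.random.SeedSequence(seed).spawn(R)
    n_failed = 0
    for cyc in range(R):
        rng = np.random.default_rng(streams[cyc])
        selected = None
        for attempt in range(max_redraws):
            if resample == "bootstrap":
                idx = rng.integers(0, n, size=n)
            elif resample == "subsample":
                idx = rng.choice(n, size=max(2, int(round(0.632 * n))), replace=False)
            else:
                raise ValueError(f"unknown resample mode {resample!r}")
            if event[idx].sum() < 2:
                log.info("cycle %d: resample with < 2 events redrawn", cyc)
                continue
            Xc, tc, ec = X[idx], time[idx], event[idx]
            keep_cols = np.ptp(Xc, axis=0) > 0
            if keep_cols.sum() == 0:
                continue
            try:
                path = CoxnetSurvivalAnalysis(
                    l1_ratio=1.0, n_alphas=n_alphas, fit_baseline_model=False
                )
                path.fit(Xc[:, keep_cols], Surv.from_arrays(event=ec.astype(bool), time=tc))
                alphas = list(path.alphas_)
                cv = _cv_partial_likelihood(Xc[:, keep_cols], tc, ec, alphas, k_folds, rng)
                best = int(np.argmax(cv))
                beta = path.coef_[:, best]
            except (ValueError, ArithmeticError) as exc:
                log.info("cycle %d attempt %d failed (%s); redrawn", cyc, attempt, exc)
                continue
            cols = np.flatnonzero(keep_cols)
            selected = [pairs[cols[j]] for j in np.flatnonzero(beta != 0)]
            break
        if selected is None:
            n_failed += 1
            continue
        counts[selected] += 1
    if n_failed == R:
        raise PipelineHalt("selection", "every lasso cycle failed")
    if n_failed:
        log.warning("%d of %d lasso cycles failed and were skipped", n_failed, R)
    counts = counts.sort_values(ascending=False, kind="stable")
    chosen = counts.index[counts >= min_freq].tolist()
    log.info("repeated lasso: %d pairs reach frequency >= %d over %d cycles",
             len(chosen), min_freq, R)
    if not chosen:
        raise EmptyResult("selection", f"no pair reaches lasso frequency {min_freq} in {R} cycles")
    return counts, chosen


def _fit_subset(pairs_subset, pairs, X, time, event) -> "tuple[object, float]":
    if not pairs_subset:
        ll = breslow_loglik(time, event, np.zeros((len(time), 1)), [0.0])
        return None, -2.0 * ll
    cols = [pairs.index(p) for p in pairs_subset]
    fit = fit_cox(time, event, X[:, cols], names=list(pairs_subset))
    if not fit.converged:
        fit = fit_cox(time, event, X[:, cols], names=list(pairs_subset), ridge=1e-6)
        log.warning("stepwise sub-model %s needed a ridge-stabilised fit", pairs_subset)
    return fit, fit.aic


def stepwise_cox(
    pm: PairIndicatorMatrix | pd.DataFrame, clinical: pd.DataFrame
) -> CoxSignature:
    """Bidirectional stepwise AIC search starting from the full model.

    Each step evaluates all single-term drops (in lexicographic pair
    order) then all re-adds, and applies the move with the lowest AIC;
    the search stops when no move improves AIC.  The empty model is a
    legal outcome.
    """
    pairs, X, time, event, _ = _aligned(pm, clinical)
    if len(pairs) < 1:
        raise PipelineHalt("selection", "stepwise search needs at least one pair")
    current = sorted(pairs)
    fit, aic = _fit_subset(current, pairs, X, time, event)
    while True:
        best = (aic, None, fit)
        removed = sorted(set(pairs) - set(current))
        moves = [("drop", p) for p in current] + [("add", p) for p in removed]
        for kind, p in moves:
            trial = [q for q in current if q != p] if kind == "drop" else sorted(current + [p])
            f, a = _fit_subset(trial, pairs, X, time, event)
            if a < best[0] - 1e-10:
                best = (a, trial, f)
        if best[1] is None:
            break
        aic, current, fit = best[0], best[1], best[2]
    if fit is None:
        ll = breslow_loglik(time, event, np.zeros((len(time), 1)), [0.0])
        log.info("stepwise search returned the empty model")
        return CoxSignature(pairs=[], coef=np.empty(0), loglik=ll, se=np.empty(0))
    return CoxSignature(pairs=list(fit.names), coef=fit.coef, loglik=fit.loglik, se=fit.se)


def build_nested_candidates(
    ordered_pairs: list[str],
    pm: PairIndicatorMatrix | pd.DataFrame,
    clinical: pd.DataFrame,
) -> list[CoxSignature]:
    """Fit the nested models over growing prefixes of ``ordered_pairs``."""
    pairs, X, time, event, _ = _aligned(pm, clinical)
    out = []
    for k in range(1, len(ordered_pairs) + 1):
        subset = ordered_pairs[:k]
        fit, _ = _fit_subset(subset, pairs, X, time, event)
        out.append(CoxSignature(pairs=list(fit.names), coef=fit.coef,
                                loglik=fit.loglik, se=fit.se))
    return out


def auc_zenith_selection(
    candidates: list[CoxSignature],
    pm: PairIndicatorMatrix | pd.DataFrame,
    clinical: pd.DataFrame,
    horizon: float = 3.0,
    days_per_year: float = DAYS_PER_YEAR,
) -> tuple[CoxSignature, pd.DataFrame]:
    """First candidate attaining the maximum horizon AUC, plus the trace.

    ``candidates`` must be ordered by increasing size (nested models grown
    in descending lasso frequency).  The returned trace has one row per
    candidate with its size and AUC, for inspection or plotting.
    """
    if not candidates:
        raise PipelineHalt("selection", "no candidate models to choose from")
    values = pm.values if isinstance(pm, PairIndicatorMatrix) else pm
    aucs = []
    for sig in candidates:
        scores = compute_risk_scores(sig, values)
        merged = scores.join(clinical[["time", "event"]])
        try:
            roc = time_dependent_roc(
                merged["score"], merged["time"] / days_per_year, merged["event"], horizon
            )
            aucs.append(roc.auc)
        except ValueError:
            aucs.append(np.nan)
    aucs = np.asarray(aucs, dtype=float)
    if np.all(np.isnan(aucs)):
        raise PipelineHalt("selection", f"AUC undefined for every candidate at {horizon} years")
    best = int(np.nanargmax(aucs))
    trace = pd.DataFrame({
        "size": [sig.n for sig in candidates],
        "auc": aucs,
    })
    return candidates[best], trace
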