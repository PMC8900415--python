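"""End-to-end orchestration: screening -> pairing -> selection -> risk ->
validation, with per-stage counts collected in a run log.

The stages run in the flow-chart order and every intermediate table is
written to the output directory, so a run is fully inspectable.  Two halt
modes are distinguished:

* :class:`~irlncpair.datatypes.EmptyResult` — a screen legitimately found
  nothing (e.g. no differentially expressed immune lncRNA).  The run stops
  cleanly, records the stage in the run log and reports an empty
  signature; this is the correct outcome on a cohort without signal.
* :class:`~irlncpair.datatypes.PipelineHalt` — invalid input or a
  degenerate cohort.  The exception propagates and the CLI exits nonzero
  with the stage named.

With ``split="half"`` the cohort is divided 50/50 (seeded; odd n gives the
extra sample to training): every data-dependent choice — the DE gene list,
the valid-pair list, the lasso selection, the signature and the cutoff —
is made on the training half only and then applied frozen to the test
half, so the test-half stratification is leakage-free.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import associations as assoc
from . import io as pio
from . import preprocess, pairing, selection, risk
from .datatypes import (
    CoxSignature, CutoffResult, EmptyResult, ExpressionMatrix, GeneAnnotation,
    PipelineHalt,
)
from .simulate import SimulatedStudy

__all__ = ["PipelineParams", "StudyInputs", "RunLog", "split_cohort", "run_pipeline", "run_study"]

log = logging.getLogger(__name__)

# binary regroupings used for the score-by-clinical rank-sum strip charts
_BINARY_SPLITS = {
    "stage": ({"I", "II"}, "I-II", "III-IV"),
    "T": ({"T1", "T2"}, "T1-2", "T3-4"),
    "N": ({"N0"}, "N0", "N1+"),
    "M": ({"M0"}, "M0", "M1"),
}


@dataclass
class PipelineParams:
    """Every tunable threshold of the analysis, with the defaults used
    throughout: coexpression |r| > 0.4 at p < 0.001, |log2FC| > 2 at
    FDR < 0.05, valid-pair band (0.2, 0.8), univariate p < 0.05, 1000
    lasso cycles at minimum frequency 2, horizons 1/2/3 years and a Youden
    cutoff on the 3-year curve."""

    r_min: float = 0.4
    coexpr_p_max: float = 0.001
    coexpr_method: str = "pearson"
    coexpr_samples: str = "all"
    lfc_min: float = 2.0
    fdr_max: float = 0.05
    pair_lo: float = 0.2
    pair_hi: float = 0.8
    uni_p_max: float = 0.05
    lasso_cycles: int = 1000
    min_freq: int = 2
    k_folds: int = 10
    n_alphas: int = 30
    resample: str = "bootstrap"
    horizons: tuple[float, ...] = (1.0, 2.0, 3.0)
    cutoff_horizon: float = 3.0
    cutoff_criterion: str = "youden"
    split: str = "none"              # none | half
    seed: int = 0
    days_per_year: float = 365.25
    checkpoint_genes: tuple[str, ...] = ()
    record_timestamps: bool = False

    def validate(self) -> None:
        if not (0 <= self.pair_lo < self.pair_hi <= 1):
            raise ValueError("pair validity band must satisfy 0 <= lo < hi <= 1")
        for name in ("coexpr_p_max", "fdr_max", "uni_p_max"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.split not in ("none", "half"):
            raise ValueError("split must be 'none' or 'half'")
        if self.lasso_cycles < 1:
            raise ValueError("lasso_cycles must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineParams":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("horizons", "checkpoint_genes"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        params = cls(**raw)
        params.validate()
        return params


@dataclass
class StudyInputs:
    """In-memory bundle of everything one run consumes."""

    expression: ExpressionMatrix
    annotation: GeneAnnotation
    immune_genes: list[str]
    clinical: pd.DataFrame
    abundance: pd.DataFrame | None = None
    ic50: pd.DataFrame | None = None

    @classmethod
    def from_study(cls, study: SimulatedStudy) -> "StudyInputs":
        return cls(
            expression=study.expression,
            annotation=study.annotation,
            immune_genes=study.immune_genes,
            clinical=study.clinical,
            abundance=study.abundance,
            ic50=study.ic50,
        )

    @classmethod
    def from_dir(cls, indir: str | Path) -> "StudyInputs":
        indir = Path(indir)
        labels = indir / "sample_labels.tsv"
        expr = pio.read_expression(
            indir / "expression.tsv", labels if labels.exists() else None
        )
        ann_gtf = indir / "annotation.gtf"
        ann = pio.read_annotation(ann_gtf if ann_gtf.exists() else indir / "annotation.tsv")
        ab = indir / "abundance.tsv"
        ic = indir / "ic50.tsv"
        return cls(
            expression=expr,
            annotation=ann,
            immune_genes=pio.read_immune_genes(indir / "immune_genes.txt"),
            clinical=pio.read_clinical(indir / "clinical.tsv"),
            abundance=pio.read_abundance(ab) if ab.exists() else None,
            ic50=pio.read_ic50(ic) if ic.exists() else None,
        )


@dataclass
class RunLog:
    """Per-stage counts, parameters and outcome of one run."""

    params: dict
    seed: int
    counts: dict = field(default_factory=dict)
    status: str = "ok"
    message: str = ""
    started: str | None = None
    finished: str | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n"


def split_cohort(clinical: pd.DataFrame, mode: str = "half", seed: int = 0):
    """Seeded 50/50 split of the tumor cohort (odd n: train gets one more)."""
    ids = list(clinical.index)
    if mode == "none":
        return ids, []
    if mode != "half":
        raise ValueError(f"unknown split mode {mode!r}")
    if len(ids) < 4:
        raise PipelineHalt("cli_io", "cohort split needs >= 4 tumor samples")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = (len(ids) + 1) // 2
    train = sorted(ids[i] for i in perm[:n_train])
    test = sorted(ids[i] for i in perm[n_train:])
    return train, test


@dataclass
class _FittedModel:
    """Everything the training cohort determines, frozen for test scoring."""

    deirlnc_genes: list[str]
    valid_pairs: list[str]
    signature: CoxSignature
    stepwise: CoxSignature
    cutoff: CutoffResult


def _years(days: pd.Series, params: PipelineParams) -> pd.Series:
    return days / params.days_per_year


def _write_signature(sig: CoxSignature, path: Path) -> None:
    pio.write_table(sig.as_frame(), path)


def _downstream(inputs, params, scores, outdir, counts):
    """Validation batteries on a scored, grouped cohort."""
    clinical = inputs.clinical.loc[scores.index]
    curves, km_record = assoc.km_logrank(scores)
    pio.write_table(curves, outdir / "km_curves.tsv", index=False)
    records = [dict(km_record, battery="km_logrank", q=km_record["p"])]

    chi_records = [
        assoc.chisq_clinical_association(scores, clinical, f)
        for f in ("stage", "T", "N", "M") if f in clinical.columns
    ]
    for r in chi_records:
        r["battery"] = "clinical_chisq"
    records.extend(assoc.bh_within(chi_records).to_dict("records"))

    strip_records = []
    for feat, (low_set, low_name, high_name) in _BINARY_SPLITS.items():
        if feat not in clinical.columns:
            continue
        cat = clinical[feat].dropna().astype(str)
        grouping = cat.map(lambda v: low_name if v in low_set else high_name)
        rec = assoc.ranksum_by_group(scores["score"], grouping, feature=f"score_by_{feat}")
        rec["battery"] = "score_ranksum"
        strip_records.append(rec)
    rec = assoc.ranksum_by_group(scores["score"], scores["group"], feature="score_by_group")
    rec["battery"] = "score_ranksum"
    strip_records.append(rec)
    records.extend(assoc.bh_within(strip_records).to_dict("records"))

    for mode in ("uni", "multi"):
        forest = assoc.cox_clinical(scores, clinical, mode=mode)
        records.extend(forest.to_dict("records"))
        pio.write_table(forest, outdir / f"cox_forest_{mode}.tsv", index=False)

    if inputs.abundance is not None and len(inputs.abundance):
        ab = inputs.abundance[inputs.abundance["sample"].isin(scores.index)]
        if len(ab):
            records.extend(assoc.abundance_battery(scores, ab).to_dict("records"))
    if inputs.ic50 is not None and len(inputs.ic50):
        ic = inputs.ic50[inputs.ic50["sample"].isin(scores.index)]
        if len(ic):
            records.extend(assoc.ic50_battery(scores, ic).to_dict("records"))
    if params.checkpoint_genes:
        records.extend(
            assoc.checkpoint_gene_battery(
                scores, inputs.expression.values, list(params.checkpoint_genes)
            ).to_dict("records")
        )

    table = pd.DataFrame(records)
    front = [c for c in ("battery", "feature", "test", "statistic", "p", "q", "effect") if c in table.columns]
    table = table[front + [c for c in table.columns if c not in front]]
    pio.write_table(table, outdir / "associations.tsv", index=False)
    counts["n_association_tests"] = int(len(table))


def _score_and_validate(inputs, params, pm_values, fitted, samples, outdir, counts):
    """Score a cohort with a frozen model, derive ROC tables and run the
    validation batteries."""
    scores = risk.compute_risk_scores(fitted.signature, pm_values[samples])
    clin = inputs.clinical.loc[samples]
    scores = scores.join(clin[["time", "event"]])
    for t in params.horizons:
        try:
            roc = risk.time_dependent_roc(
                scores["score"], _years(scores["time"], params), scores["event"], t
            )
            pio.write_table(roc.table, outdir / f"roc_{t:g}y.tsv", index=False)
            counts[f"auc_{t:g}y"] = round(float(roc.auc), 6)
        except ValueError as exc:
            log.warning("ROC at %gy unavailable: %s", t, exc)
            counts[f"auc_{t:g}y"] = None
    scores = risk.assign_groups(scores, fitted.cutoff)
    pio.write_table(scores, outdir / "risk_scores.tsv")
    counts["n_high"] = int((scores["group"] == "high").sum())
    counts["n_low"] = int((scores["group"] == "low").sum())
    _downstream(inputs, params, scores, outdir, counts)
    return scores


def _fit_cohort(inputs: StudyInputs, params: PipelineParams, samples: list[str], outdir: Path,
                counts: dict) -> tuple[_FittedModel, pd.DataFrame]:
    """Run every model-fitting stage on one cohort of tumor samples.

    All screens (coexpression, DE) see only this cohort's tumor samples
    plus the normal samples, so under a train/test split nothing leaks
    from the held-out half.
    """
    expr = inputs.expression.subset_samples(
        list(samples) + inputs.expression.normal_samples
    )
    counts["n_genes"] = len(expr.genes)
    counts["n_tumor"] = len(samples)
    counts["n_normal"] = len(expr.normal_samples)

    lnc, mrna = preprocess.split_by_biotype(expr, inputs.annotation)
    counts["n_lnc"] = len(lnc.genes)
    counts["n_mrna"] = len(mrna.genes)

    irlnc = preprocess.immune_coexpression_filter(
        lnc, mrna, inputs.immune_genes,
        r_min=params.r_min, p_max=params.coexpr_p_max,
        method=params.coexpr_method, samples=params.coexpr_samples,
    )
    counts["n_irlnc"] = len(irlnc)
    pio.write_table(irlnc, outdir / "irlncrna.tsv")
    if irlnc.empty:
        raise EmptyResult("preprocess", "no immune-related lncRNA passes the coexpression screen")

    de = preprocess.moderated_de_test(lnc.subset_genes(irlnc.index))
    pio.write_table(de, outdir / "de_irlncrna.tsv")
    deir = preprocess.select_deirlncrnas(de, lfc_min=params.lfc_min, fdr_max=params.fdr_max)
    counts["n_deirlnc"] = len(deir)
    counts["n_deirlnc_up"] = int((deir["log2fc"] > 0).sum())
    counts["n_deirlnc_down"] = int((deir["log2fc"] < 0).sum())
    pio.write_table(deir, outdir / "deirlncrna.tsv")

    de_expr = expr.subset_genes(deir.index).subset_samples(
        [s for s in samples if s in expr.samples]
    )
    # all retained samples are tumor samples already; build over them
    pm_all = pairing.build_pair_matrix(de_expr, tumor_only=True)
    counts["n_candidate_pairs"] = len(pm_all.pairs)
    counts["n_tied_comparisons"] = pm_all.n_ties
    pm = pairing.filter_valid_pairs(pm_all, lo=params.pair_lo, hi=params.pair_hi)
    counts["n_valid_pairs"] = len(pm.pairs)
    pairs_out = pd.DataFrame({
        "one_fraction": pm_all.one_fraction(),
        "valid": pm_all.pairs.isin(pm.pairs),
    })
    pairs_out.index.name = "pair"
    pio.write_table(pairs_out, outdir / "pairs.tsv")

    clin = inputs.clinical.loc[[s for s in samples if s in inputs.clinical.index]]
    uni = selection.univariate_cox_screen(pm, clin, p_max=params.uni_p_max)
    counts["n_screened_pairs"] = len(uni)
    pio.write_table(uni, outdir / "univariate_cox.tsv")

    freq, chosen = selection.repeated_lasso_selection(
        pm.subset_pairs(uni.index), clin,
        R=params.lasso_cycles, min_freq=params.min_freq, seed=params.seed,
        k_folds=params.k_folds, n_alphas=params.n_alphas, resample=params.resample,
    )
    counts["n_selected_pairs"] = len(chosen)
    freq_out = freq.rename("count").to_frame()
    freq_out["selected"] = freq_out.index.isin(chosen)
    pio.write_table(freq_out, outdir / "lasso_freq.tsv")

    sel_pm = pm.subset_pairs(chosen)
    stepwise_sig = selection.stepwise_cox(sel_pm, clin)
    counts["stepwise_size"] = stepwise_sig.n
    _write_signature(stepwise_sig, outdir / "stepwise_signature.tsv")

    # nested candidates in descending lasso frequency, univariate p tie-break
    order = sorted(chosen, key=lambda p: (-freq[p], uni.loc[p, "p"], p))
    candidates = selection.build_nested_candidates(order, sel_pm, clin)
    signature, trace = selection.auc_zenith_selection(
        candidates, sel_pm, clin,
        horizon=params.cutoff_horizon, days_per_year=params.days_per_year,
    )
    counts["signature_size"] = signature.n
    pio.write_table(trace, outdir / "auc_trace.tsv", index=False)
    _write_signature(signature, outdir / "signature.tsv")

    scores = risk.compute_risk_scores(signature, pm.values)
    scores = scores.join(clin[["time", "event"]])
    roc3 = risk.time_dependent_roc(
        scores["score"], _years(scores["time"], params), scores["event"],
        params.cutoff_horizon,
    )
    cutoff = risk.select_cutoff(roc3, criterion=params.cutoff_criterion)
    pio.write_table(cutoff.table, outdir / "cutoff.tsv", index=False)
    counts["cutoff_threshold"] = round(float(cutoff.threshold), 10)

    fitted = _FittedModel(
        deirlnc_genes=list(deir.index),
        valid_pairs=list(pm.pairs),
        signature=signature,
        stepwise=stepwise_sig,
        cutoff=cutoff,
    )
    return fitted, pm.values


def _empty_signature_outputs(outdir: Path) -> None:
    empty = pd.DataFrame(columns=["pair", "coef", "hr"]).set_index("pair")
    pio.write_table(empty, outdir / "signature.tsv")


def run_study(inputs: StudyInputs, params: PipelineParams, outdir: str | Path) -> RunLog:
    """Execute the full pipeline on in-memory inputs; write all artifacts."""
    params.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    runlog = RunLog(params=dataclasses.asdict(params), seed=params.seed)
    if params.record_timestamps:
        runlog.started = _time.strftime("%Y-%m-%dT%H:%M:%S")

    tumor = [s for s in inputs.expression.tumor_samples if s in inputs.clinical.index]
    if not tumor:
        raise PipelineHalt("cli_io", "no tumor samples with clinical data")
    if inputs.clinical.loc[tumor, "event"].sum() == 0:
        raise PipelineHalt("cli_io", "cohort has no observed events; survival modeling impossible")

    try:
        if params.split == "none":
            fitted, pm_values = _fit_cohort(inputs, params, tumor, outdir, runlog.counts)
            _score_and_validate(inputs, params, pm_values, fitted, tumor, outdir, runlog.counts)
        else:
            train, test = split_cohort(inputs.clinical.loc[tumor], "half", params.seed)
            runlog.counts["n_train"] = len(train)
            runlog.counts["n_test"] = len(test)
            tdir = outdir / "train"
            tdir.mkdir(exist_ok=True)
            tcounts: dict = {}
            fitted, pm_train = _fit_cohort(inputs, params, train, tdir, tcounts)
            _score_and_validate(inputs, params, pm_train, fitted, train, tdir, tcounts)
            runlog.counts["train"] = tcounts

            # frozen application to the held-out half
            sdir = outdir / "test"
            sdir.mkdir(exist_ok=True)
            scounts: dict = {}
            test_expr = inputs.expression.subset_genes(fitted.deirlnc_genes).subset_samples(test)
            pm_test = pairing.build_pair_matrix(test_expr, tumor_only=True)
            pm_test = pm_test.subset_pairs(
                [p for p in fitted.valid_pairs if p in pm_test.pairs]
            )
            _score_and_validate(inputs, params, pm_test.values, fitted, test, sdir, scounts)
            runlog.counts["test"] = scounts
            manifest = {
                "frozen_pairs": fitted.valid_pairs,
                "signature": {p: float(c) for p, c in zip(fitted.signature.pairs,
                                                          fitted.signature.coef)},
                "cutoff": float(fitted.cutoff.threshold),
            }
            (outdir / "frozen_model.json").write_text(
                json.dumps(manifest, indent=2, sort_keys=True) + "\n"
            )
    except EmptyResult as exc:
        runlog.status = f"halted:{exc.stage}"
        runlog.message = str(exc)
        runlog.counts["signature_size"] = 0
        _empty_signature_outputs(outdir)
        log.info("pipeline stopped cleanly: %s", exc)

    if params.record_timestamps:
        runlog.finished = _time.strftime("%Y-%m-%dT%H:%M:%S")
    (outdir / "runlog.json").write_text(runlog.to_json())
    return runlog


def run_pipeline(indir: str | Path, params: PipelineParams, outdir: str | Path) -> RunLog:
    """Load a study directory (expression/annotation/immune/clinical TSVs)
    and run :func:`run_study` on it."""
    inputs = StudyInputs.from_dir(indir)
    return run_study(inputs, params, outdir)
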