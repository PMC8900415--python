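"""Seeded synthetic tumor cohorts with the structure the pipeline assumes.

The generator emulates a TCGA-style study: an FPKM expression matrix over
lncRNAs and mRNAs for tumor and normal samples, an immune-gene subset, a
clinical table with overall survival and staging, and auxiliary
immune-cell-abundance / drug-IC50 tables.  Each screening step of the
analysis maps to one generative knob:

* a latent immune factor shared by the immune genes and a chosen subset of
  lncRNAs makes the coexpression screen recoverable (the factor loading is
  set so the population |Pearson r| on the log scale exceeds 0.5);
* a log2 shift on tumor columns of chosen lncRNAs makes the differential
  expression screen recoverable;
* survival follows a proportional-hazards model whose linear predictor is a
  sum of planted rank-pair indicators, so the selection chain has a ground
  truth to find;
* stage/T/N/M are drawn with probabilities monotone in the linear-predictor
  quartile, and abundance/IC50 columns are noisy linear functions of the
  standardized predictor with mixed signs.

Expression is generated on the log2 scale as
``baseline + loading * factor + DE shift + Normal(0, noise_sd)`` and mapped
to FPKM by ``max(2^x - 1, 0)``.  One integer seed drives every draw through
spawned ``numpy`` generator streams, so identical configs reproduce
byte-identical exports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GeneAnnotation, TUMOR, NORMAL, pair_id

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "default_config",
    "simulate_expression",
    "simulate_survival",
    "simulate_auxiliary_tables",
    "simulate_study",
    "write_study",
]

ABUNDANCE_METHODS = ["TIMER", "CIBERSORT", "CIBERSORT-ABS", "XCELL", "MCPCOUNTER", "EPIC"]
CELL_TYPES = ["CD4_T_cell", "CD8_T_cell", "NK_cell", "monocyte", "neutrophil", "hematopoietic_stem_cell"]
DRUGS = ["oxaliplatin", "MG132", "NVP-TAE684", "fluorouracil", "irinotecan"]

STAGE_LEVELS = ["I", "II", "III", "IV"]
T_LEVELS = ["T1", "T2", "T3", "T4"]
N_LEVELS = ["N0", "N1", "N2"]
M_LEVELS = ["M0", "M1"]

# category probabilities at the lowest / highest risk quartile; intermediate
# quartiles interpolate linearly, scaled by ``clinical_effect``
_CLINICAL_PROFILES = {
    "stage": (STAGE_LEVELS, [0.50, 0.28, 0.16, 0.06], [0.18, 0.27, 0.31, 0.24]),
    "T": (T_LEVELS, [0.25, 0.35, 0.30, 0.10], [0.08, 0.22, 0.40, 0.30]),
    "N": (N_LEVELS, [0.65, 0.25, 0.10], [0.35, 0.35, 0.30]),
    "M": (M_LEVELS, [0.92, 0.08], [0.70, 0.30]),
}

DAYS_PER_YEAR = 365.25


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; defaults mirror a TCGA-scale colon
    cohort (373 tumor / 41 normal) with a three-pair planted signature."""

    n_tumor: int = 373
    n_normal: int = 41
    n_lnc: int = 120
    n_mrna: int = 400
    n_immune: int = 120              # immune genes are a subset of the mRNAs
    n_coexpressed_lnc: int = 40      # lncRNAs tied to immune genes via the factor
    n_de_lnc: int = 30               # lncRNAs shifted in tumor vs normal
    de_log2fc: float = 3.0
    planted_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    baseline_hazard: float = 0.10    # events per year at linear predictor 0
    censor_window: tuple[float, float] = (1.0, 10.0)   # years
    noise_sd: float = 0.5            # log2-scale expression noise
    clinical_effect: float = 1.0     # 0 = stage/T/N/M independent of risk
    seed: int = 0

    def lnc_ids(self) -> list[str]:
        return [f"LNC{i + 1:04d}" for i in range(self.n_lnc)]

    def mrna_ids(self) -> list[str]:
        return [f"MRNA{i + 1:04d}" for i in range(self.n_mrna)]

    def validate(self) -> None:
        if self.n_lnc < 2:
            raise ValueError("n_lnc must be >= 2 (no pairs possible otherwise)")
        if self.n_immune > self.n_mrna:
            raise ValueError("n_immune must not exceed n_mrna")
        if self.n_coexpressed_lnc > self.n_lnc:
            raise ValueError("n_coexpressed_lnc must not exceed n_lnc")
        if self.n_de_lnc > self.n_lnc:
            raise ValueError("n_de_lnc must not exceed n_lnc")
        known = set(self.lnc_ids())
        seen = set()
        for a, b, _ in self.planted_pairs:
            if a == b:
                raise ValueError(f"planted pair ({a}, {b}) names the same gene twice")
            if a not in known or b not in known:
                raise ValueError(f"planted pair ({a}, {b}) references unknown lncRNAs")
            key = frozenset((a, b))
            if key in seen:
                raise ValueError(f"planted pair ({a}, {b}) duplicated")
            seen.add(key)


def default_config(**overrides) -> SimulationConfig:
    """A config with three planted pairs drawn from the coexpressed+DE set."""
    cfg = SimulationConfig(**overrides)
    if not cfg.planted_pairs and "planted_pairs" not in overrides:
        ids = cfg.lnc_ids()
        k = min(cfg.n_coexpressed_lnc, cfg.n_de_lnc, 6)
        betas = [0.9, -0.85, 1.0]
        pairs = []
        for j in range(k // 2):
            pairs.append((ids[2 * j], ids[2 * j + 1], betas[j % len(betas)]))
        cfg.planted_pairs = pairs[:3]
    cfg.validate()
    return cfg


@dataclass
class SimulatedStudy:
    """Everything one synthetic study produces, plus its ground truth."""

    config: SimulationConfig
    expression: ExpressionMatrix
    annotation: GeneAnnotation
    immune_genes: list[str]
    clinical: pd.DataFrame           # index tumor sample; time(days), event, age, stage, T, N, M
    abundance: pd.DataFrame          # long: sample, cell_type, method, abundance
    ic50: pd.DataFrame               # long: sample, drug, ic50
    truth: dict


def _streams(seed: int) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    names = ["expression", "survival", "auxiliary"]
    return {n: np.random.default_rng(s) for n, s in zip(names, ss.spawn(len(names)))}


def simulate_expression(config: SimulationConfig, rng: np.random.Generator | None = None):
    """Draw the FPKM matrix, annotation, immune-gene list and truth record.

    Planted-pair members are given identical baselines and factor loadings,
    so their within-sample ordering is driven by noise alone and the pair
    indicator splits the cohort near 50/50.
    """
    config.validate()
    if rng is None:
        rng = _streams(config.seed)["expression"]

    lnc = config.lnc_ids()
    mrna = config.mrna_ids()
    genes = lnc + mrna
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene ids in simulated gene universe")

    n = config.n_tumor + config.n_normal
    tumor = [f"SAMP{i + 1:04d}-01" for i in range(config.n_tumor)]
    normal = [f"SAMP{i + 1:04d}-11" for i in range(config.n_normal)]
    samples = tumor + normal

    immune = mrna[: config.n_immune]
    coexpressed = lnc[: config.n_coexpressed_lnc]
    de_genes = lnc[: config.n_de_lnc]

    baseline = pd.Series(rng.uniform(2.0, 8.0, size=len(genes)), index=genes)
    # loading 2*sigma gives population r = 4/5 on the log scale
    load_mag = 2.0 * config.noise_sd if config.noise_sd > 0 else 1.0
    loading = pd.Series(0.0, index=genes)
    for k, g in enumerate(immune):
        loading[g] = load_mag * (1 if k % 2 == 0 else -1)
    for k, g in enumerate(coexpressed):
        loading[g] = load_mag * (1 if k % 2 == 0 else -1)

    # planted pairs: equalise baseline and loading, keep both in the DE set
    de_set = set(de_genes)
    for a, b, _ in config.planted_pairs:
        baseline[b] = baseline[a]
        loading[b] = loading[a]
        if (a in de_set) != (b in de_set):
            de_set.update((a, b))
    de_genes = [g for g in lnc if g in de_set]

    factor = rng.normal(size=n) if config.n_coexpressed_lnc > 0 else np.zeros(n)
    x = baseline.values[:, None] + np.outer(loading.values, factor)
    if config.n_de_lnc > 0 or de_genes:
        de_rows = np.array([g in de_set for g in genes])
        x[np.ix_(de_rows, np.arange(config.n_tumor))] += config.de_log2fc
    if config.noise_sd > 0:
        x = x + rng.normal(scale=config.noise_sd, size=x.shape)

    fpkm = np.maximum(np.exp2(x) - 1.0, 0.0)
    values = pd.DataFrame(fpkm, index=genes, columns=samples)
    labels = pd.Series([TUMOR] * len(tumor) + [NORMAL] * len(normal), index=samples)
    expr = ExpressionMatrix(values, labels)

    biotype = pd.Series(
        ["lncRNA"] * len(lnc) + ["protein_coding"] * len(mrna), index=genes
    )
    ann = GeneAnnotation(biotype=biotype, symbol=pd.Series(genes, index=genes))

    truth = {
        "planted_pairs": [
            {"pair": pair_id(*sorted((a, b))), "a": a, "b": b, "beta": beta}
            for a, b, beta in config.planted_pairs
        ],
        "de_genes": de_genes,
        "coexpressed_lnc": coexpressed,
        "immune_genes": immune,
    }
    return expr, ann, immune, truth


def _planted_indicators(expr: ExpressionMatrix, config: SimulationConfig) -> pd.DataFrame:
    """Planted-pair 0/1 indicators over tumor samples, by the canonical rule."""
    from .pairing import pair_indicator_values

    tumor = expr.tumor_samples
    rows = {}
    for a, b, _ in config.planted_pairs:
        aa, bb = sorted((a, b))
        rows[pair_id(aa, bb)] = pair_indicator_values(expr.values, aa, bb)[tumor]
    if not rows:
        return pd.DataFrame(index=pd.Index([], name="pair"), columns=tumor)
    return pd.DataFrame(rows).T


def simulate_survival(
    pair_indicators: pd.DataFrame,
    config: SimulationConfig,
    tumor_samples: list[str] | None = None,
    rng: np.random.Generator | None = None,
):
    """Draw the clinical table from a proportional-hazards model.

    Event times are exponential with rate
    ``baseline_hazard * exp(sum_k beta_k * indicator_k)``; administrative
    censoring is uniform over ``censor_window``.  Returns the clinical
    DataFrame (times in days) and the true per-sample linear predictor.
    """
    if rng is None:
        rng = _streams(config.seed)["survival"]
    if tumor_samples is None:
        tumor_samples = list(pair_indicators.columns)
    n = len(tumor_samples)

    betas = {}
    for a, b, beta in config.planted_pairs:
        betas[pair_id(*sorted((a, b)))] = beta
    lp = np.zeros(n)
    for pid, beta in betas.items():
        lp += beta * pair_indicators.loc[pid, tumor_samples].values.astype(float)
    lp = pd.Series(lp, index=tumor_samples, name="linear_predictor")

    rate = config.baseline_hazard * np.exp(lp.values)
    t_event = rng.exponential(1.0 / np.maximum(rate, 1e-12))
    lo, hi = config.censor_window
    t_cens = rng.uniform(lo, hi, size=n) if hi > lo else np.full(n, float(lo))
    observed = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    age = np.clip(np.round(rng.normal(65.0, 10.0, size=n)), 30, 90).astype(int)

    if n >= 4 and np.ptp(lp.values) > 0:
        cuts = np.quantile(lp.values, [0.25, 0.5, 0.75])
        quart = np.searchsorted(cuts, lp.values, side="left")
    else:
        quart = np.zeros(n, dtype=int)

    cols = {}
    for name, (levels, p_lo, p_hi) in _CLINICAL_PROFILES.items():
        p_lo, p_hi = np.asarray(p_lo), np.asarray(p_hi)
        drawn = []
        for q in quart:
            w = np.clip(config.clinical_effect, 0.0, 1.0) * (q / 3.0)
            p = (1.0 - w) * p_lo + w * p_hi
            drawn.append(rng.choice(levels, p=p / p.sum()))
        cols[name] = drawn

    clinical = pd.DataFrame(
        {
            "time": np.round(observed * DAYS_PER_YEAR).astype(int),
            "event": event,
            "age": age,
            "stage": cols["stage"],
            "T": cols["T"],
            "N": cols["N"],
            "M": cols["M"],
        },
        index=pd.Index(tumor_samples, name="sample"),
    )
    return clinical, lp


def simulate_auxiliary_tables(
    lp: pd.Series, config: SimulationConfig, rng: np.random.Generator | None = None
):
    """Immune-cell abundance and drug-IC50 tables tied to the true risk.

    Each column is ``a * z + Normal(0, 1)`` with ``z`` the standardized
    linear predictor; coefficient signs alternate so both positive and
    negative associations exist, matching the mixed correlations seen in
    deconvolution and chemosensitivity panels.
    """
    if rng is None:
        rng = _streams(config.seed)["auxiliary"]
    samples = list(lp.index)
    n = len(samples)
    if n == 0:
        abundance = pd.DataFrame(columns=["sample", "cell_type", "method", "abundance"])
        ic50 = pd.DataFrame(columns=["sample", "drug", "ic50"])
        return abundance, ic50

    sd = lp.values.std()
    z = (lp.values - lp.values.mean()) / sd if sd > 0 else np.zeros(n)

    coefs = [2.0, -2.0, 1.0, -1.0, 0.5, -0.5]
    ab_rows = []
    for mi, method in enumerate(ABUNDANCE_METHODS):
        for ci, cell in enumerate(CELL_TYPES):
            a = coefs[(mi + ci) % len(coefs)]
            vals = a * z + rng.normal(size=n)
            ab_rows.append(
                pd.DataFrame(
                    {"sample": samples, "cell_type": cell, "method": method, "abundance": vals}
                )
            )
    abundance = pd.concat(ab_rows, ignore_index=True)

    drug_coefs = {"oxaliplatin": -2.0, "MG132": 2.0, "NVP-TAE684": 1.5, "fluorouracil": -1.0, "irinotecan": 0.8}
    ic_rows = []
    for drug in DRUGS:
        vals = drug_coefs[drug] * z + rng.normal(size=n)
        ic_rows.append(pd.DataFrame({"sample": samples, "drug": drug, "ic50": vals}))
    ic50 = pd.concat(ic_rows, ignore_index=True)
    return abundance, ic50


def simulate_study(config: SimulationConfig | None = None) -> SimulatedStudy:
    """Generate a full study: expression, clinical and auxiliary tables."""
    if config is None:
        config = default_config()
    config.validate()
    streams = _streams(config.seed)
    expr, ann, immune, truth = simulate_expression(config, streams["expression"])
    indicators = _planted_indicators(expr, config)
    clinical, lp = simulate_survival(
        indicators, config, tumor_samples=expr.tumor_samples, rng=streams["survival"]
    )
    abundance, ic50 = simulate_auxiliary_tables(lp, config, rng=streams["auxiliary"])
    truth = dict(truth)
    truth["linear_predictor"] = {s: float(v) for s, v in lp.items()}
    return SimulatedStudy(
        config=config,
        expression=expr,
        annotation=ann,
        immune_genes=immune,
        clinical=clinical,
        abundance=abundance,
        ic50=ic50,
        truth=truth,
    )


def write_study(study: SimulatedStudy, outdir: str | Path) -> Path:
    """Export the study as the TSV/JSON bundle every reader accepts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ff = "%.10g"
    expr = study.expression.values.copy()
    expr.index.name = "gene_id"
    expr.to_csv(outdir / "expression.tsv", sep="\t", float_format=ff)
    labels = study.expression.labels.rename("label").to_frame()
    labels.index.name = "sample"
    labels.to_csv(outdir / "sample_labels.tsv", sep="\t")
    ann = study.annotation.biotype.rename("biotype").to_frame()
    ann.index.name = "gene_id"
    ann.to_csv(outdir / "annotation.tsv", sep="\t")
    (outdir / "immune_genes.txt").write_text("\n".join(study.immune_genes) + "\n")
    study.clinical.to_csv(outdir / "clinical.tsv", sep="\t", float_format=ff)
    study.abundance.to_csv(outdir / "abundance.tsv", sep="\t", index=False, float_format=ff)
    study.ic50.to_csv(outdir / "ic50.tsv", sep="\t", index=False, float_format=ff)
    cfg = asdict(study.config)
    cfg["planted_pairs"] = [list(p) for p in cfg["planted_pairs"]]
    cfg["censor_window"] = list(cfg["censor_window"])
    payload = {"config": cfg, "truth": study.truth}
    (outdir / "truth.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return outdir
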