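"""Screening chain from raw FPKM to differentially expressed immune lncRNAs.

Three filters applied in order:

1. biotype split — the annotation partitions genes into lncRNAs and mRNAs;
   unannotated genes are dropped with a logged count;
2. immune coexpression — an lncRNA is immune-related (irlncRNA) when its
   log-scale Pearson correlation with some immune gene exceeds ``r_min``
   in absolute value at raw p below ``p_max`` (strict inequalities, p from
   the two-sided t transform of r);
3. differential expression — a moderated t-test (empirical-Bayes variance
   shrinkage) between tumor and normal log2(FPKM+1), keeping genes with
   |log2FC| > ``lfc_min`` and Benjamini-Hochberg FDR < ``fdr_max``.

The moderated test shrinks each gene's pooled variance toward a prior
fitted by method of moments on the log residual variances: with residual
df d_g and prior (d0, s0^2), the posterior variance is
s~^2 = (d0*s0^2 + d_g*s_g^2) / (d0 + d_g) and the statistic is referred to
a t distribution with d0 + d_g degrees of freedom.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix, GeneAnnotation, PipelineHalt, EmptyResult

__all__ = [
    "split_by_biotype",
    "immune_coexpression_filter",
    "moderated_de_test",
    "select_deirlncrnas",
]

log = logging.getLogger(__name__)


def split_by_biotype(
    expr: ExpressionMatrix, ann: GeneAnnotation
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Partition annotated genes into (lncRNA, protein-coding) matrices."""
    annotated = [g for g in expr.genes if g in ann.biotype.index]
    dropped = len(expr.genes) - len(annotated)
    if dropped:
        log.warning("%d genes absent from the annotation were dropped", dropped)
    bio = ann.biotype.loc[annotated]
    lnc_genes = [g for g in annotated if bio[g] == "lncRNA"]
    mrna_genes = [g for g in annotated if bio[g] == "protein_coding"]
    if not lnc_genes:
        raise PipelineHalt("preprocess", "no lncRNAs after the biotype split")
    if not mrna_genes:
        raise PipelineHalt("preprocess", "no protein-coding genes after the biotype split")
    return expr.subset_genes(lnc_genes), expr.subset_genes(mrna_genes)


def _pearson_with_p(L: np.ndarray, M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-vs-row Pearson r and two-sided p for (l x n) against (m x n)."""
    n = L.shape[1]
    Ls = L - L.mean(axis=1, keepdims=True)
    Ms = M - M.mean(axis=1, keepdims=True)
    Lsd = np.sqrt((Ls**2).sum(axis=1))
    Msd = np.sqrt((Ms**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Ls @ Ms.T) / np.outer(Lsd, Msd)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    # constant rows have undefined correlation: mark as no evidence
    const = np.isnan(r)
    r = np.where(const, np.nan, r)
    p = np.where(const, 1.0, p)
    return r, p


def immune_coexpression_filter(
    lnc: ExpressionMatrix,
    mrna: ExpressionMatrix,
    immune_genes,
    r_min: float = 0.4,
    p_max: float = 0.001,
    method: str = "pearson",
    samples: str = "all",
) -> pd.DataFrame:
    """Immune-related lncRNAs: |r| > r_min and p < p_max for some immune gene.

    Correlation is computed on log2(FPKM+1) across all samples by default
    (``samples="tumor"`` restricts to the tumor cohort); ``method`` may be
    ``"pearson"`` or ``"spearman"``.  Returns one row per retained lncRNA
    with its best-correlated immune gene.
    """
    immune_in = [g for g in immune_genes if g in mrna.genes]
    if not immune_in:
        raise PipelineHalt("preprocess", "immune gene set does not intersect the mRNA matrix")
    cols = lnc.tumor_samples if samples == "tumor" else list(lnc.samples)
    if len(cols) < 3:
        raise PipelineHalt("preprocess", "coexpression screen needs >= 3 samples")

    L = lnc.log2()[cols].to_numpy()
    M = mrna.log2().loc[immune_in, cols].to_numpy()
    if method == "spearman":
        L = np.apply_along_axis(stats.rankdata, 1, L)
        M = np.apply_along_axis(stats.rankdata, 1, M)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    r, p = _pearson_with_p(L, M)

    n_const = int(np.isnan(r).any(axis=1).sum())
    if n_const:
        log.warning("%d lncRNA rows had constant-gene comparisons skipped", n_const)

    hit = (np.abs(r) > r_min) & (p < p_max)
    rows = []
    for i, g in enumerate(lnc.genes):
        if not hit[i].any():
            continue
        with np.errstate(invalid="ignore"):
            absr = np.where(hit[i], np.abs(r[i]), -np.inf)
        j = int(np.argmax(absr))
        rows.append({"gene": g, "best_immune_gene": immune_in[j],
                     "r": float(r[i, j]), "p": float(p[i, j])})
    out = pd.DataFrame(rows, columns=["gene", "best_immune_gene", "r", "p"])
    log.info("coexpression screen: %d of %d lncRNAs retained", len(out), len(lnc.genes))
    return out.set_index("gene")


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square variance prior.

    Matches the first two moments of log(s_g^2) to the theoretical
    log-F(d_g, d0) distribution using digamma/trigamma identities; returns
    (d0, s0^2) with d0 = inf when the observed spread is no larger than
    sampling noise alone.
    """
    ok = s2 > 0
    z = np.log(s2[ok])
    G = z.size
    if G < 2:
        return np.inf, float(np.exp(z.mean())) if G else 1.0
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    ebar = e.mean()
    evar = e.var(ddof=1)
    target = evar - special.polygamma(1, df / 2.0)
    if target <= 0:
        d0 = np.inf
        s0sq = float(np.exp(ebar))
        return d0, s0sq
    # invert trigamma(d0/2) = target by Newton on x = d0/2
    x = 0.5 + 1.0 / target
    for _ in range(50):
        tri = special.polygamma(1, x)
        step = tri * (1.0 - tri / target) / special.polygamma(2, x)
        x = x + step
        if abs(step) < 1e-10 * x:
            break
    d0 = 2.0 * x
    s0sq = float(np.exp(ebar + special.digamma(x) - np.log(x)))
    return float(d0), s0sq


def moderated_de_test(
    lnc: ExpressionMatrix, d0_override: float | None = None
) -> pd.DataFrame:
    """Tumor-vs-normal moderated t-test on log2(FPKM+1), per gene.

    Returns a frame indexed by gene with ``log2fc`` (tumor - normal), raw
    ``p``, BH-adjusted ``fdr`` and ``direction``.  ``d0_override`` forces
    the prior df (``inf`` recovers an ordinary pooled t with the prior
    variance), a hook for checking the shrinkage limit.
    """
    tumor = lnc.tumor_samples
    normal = lnc.normal_samples
    n_t, n_n = len(tumor), len(normal)
    if n_t < 2 or n_n < 2:
        raise PipelineHalt("preprocess", "DE test needs >= 2 tumor and >= 2 normal samples")

    X = lnc.log2()
    T = X[tumor].to_numpy()
    N = X[normal].to_numpy()
    mean_t = T.mean(axis=1)
    mean_n = N.mean(axis=1)
    lfc = mean_t - mean_n
    df_resid = n_t + n_n - 2
    ss = ((T - mean_t[:, None]) ** 2).sum(axis=1) + ((N - mean_n[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_resid
    scale = 1.0 / n_t + 1.0 / n_n

    if np.all(s2 == 0) and d0_override is None:
        log.warning("all residual variances are zero; falling back to Welch t")
        tstat, p = stats.ttest_ind(T, N, axis=1, equal_var=False)
        p = np.where(np.isnan(p), np.where(lfc == 0, 1.0, 0.0), p)
    else:
        if d0_override is not None:
            d0 = float(d0_override)
            s0sq = float(np.exp(np.log(s2[s2 > 0]).mean())) if (s2 > 0).any() else 1.0
        else:
            d0, s0sq = _fit_variance_prior(s2, df_resid)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0sq)
            df_total = np.inf
        else:
            s2_post = (d0 * s0sq + df_resid * s2) / (d0 + df_resid)
            df_total = d0 + df_resid
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = lfc / np.sqrt(s2_post * scale)
        tstat = np.where(np.isnan(tstat), 0.0, tstat)
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(tstat))
        else:
            p = 2.0 * stats.t.sf(np.abs(tstat), df=df_total)
        p = np.where(np.isinf(tstat), 0.0, p)

    fdr = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "log2fc": lfc,
            "p": p,
            "fdr": fdr,
            "direction": np.where(lfc > 0, "up", np.where(lfc < 0, "down", "none")),
        },
        index=lnc.genes,
    )
    return out


def select_deirlncrnas(
    de: pd.DataFrame, lfc_min: float = 2.0, fdr_max: float = 0.05
) -> pd.DataFrame:
    """Apply the strict |log2FC| > lfc_min and FDR < fdr_max thresholds.

    Raises :class:`EmptyResult` when no gene survives, so the pipeline can
    stop cleanly with an empty signature instead of cascading errors.
    """
    if de.empty:
        raise PipelineHalt("preprocess", "DE result table is empty")
    keep = de[(de["log2fc"].abs() > lfc_min) & (de["fdr"] < fdr_max)]
    n_up = int((keep["log2fc"] > 0).sum())
    n_down = int((keep["log2fc"] < 0).sum())
    log.info("DEirlncRNAs: %d (%d up, %d down)", len(keep), n_up, n_down)
    if keep.empty:
        raise EmptyResult("preprocess", "no DEirlncRNAs pass the fold-change/FDR thresholds")
    return keep
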