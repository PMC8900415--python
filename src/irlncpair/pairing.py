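"""Rank-based 0/1 pairing of differentially expressed immune lncRNAs.

For an ordered gene pair (A, B) and a sample s the indicator is

    C(A, B, s) = 0 if expr(A, s) < expr(B, s), else 1,

a within-sample comparison: no normalisation or fixed expression scale is
needed, and the matrix is invariant under any strictly increasing
per-sample transform of expression.  Ties take the "otherwise" branch,
C = 1; tie counts are recorded so tie-heavy data can be spotted.

A pair is *valid* (informative) when its fraction of ones across the
modeling cohort lies strictly between ``lo`` and ``hi`` (default 20%-80%):
a pair whose orientation is nearly constant cannot split the cohort.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, PairIndicatorMatrix, PipelineHalt, pair_id

__all__ = ["build_pair_matrix", "filter_valid_pairs", "pair_indicator_values"]

log = logging.getLogger(__name__)


def pair_indicator_values(values: pd.DataFrame, a: str, b: str) -> pd.Series:
    """Indicator C(a, b, .) over all columns of a genes x samples frame."""
    return (values.loc[a] >= values.loc[b]).astype(np.uint8)


def build_pair_matrix(expr: ExpressionMatrix, tumor_only: bool = True) -> PairIndicatorMatrix:
    """All m(m-1)/2 canonical pair indicators over the modeling samples.

    Genes are ordered lexicographically and each unordered pair emitted
    once with A < B.  By default only tumor samples enter the matrix, since
    risk modeling concerns the tumor cohort.
    """
    samples = expr.tumor_samples if tumor_only else list(expr.samples)
    genes = sorted(expr.genes)
    m = len(genes)
    if m < 2:
        log.warning("fewer than 2 genes: pair matrix is empty")
        return PairIndicatorMatrix(
            pd.DataFrame(np.empty((0, len(samples)), dtype=np.uint8),
                         index=pd.Index([], name="pair"), columns=samples)
        )
    if len(samples) < 1:
        raise PipelineHalt("pairing", "no samples available for the pair matrix")

    vals = expr.values.loc[genes, samples].to_numpy(dtype=float)
    ia, ib = np.triu_indices(m, k=1)
    a_vals = vals[ia]
    b_vals = vals[ib]
    c = (a_vals >= b_vals).astype(np.uint8)
    n_ties = int((a_vals == b_vals).sum())
    if n_ties:
        log.info("pair matrix contains %d tied comparisons (assigned C=1)", n_ties)
    index = pd.Index([pair_id(genes[i], genes[j]) for i, j in zip(ia, ib)], name="pair")
    return PairIndicatorMatrix(pd.DataFrame(c, index=index, columns=samples), n_ties=n_ties)


def filter_valid_pairs(
    pm: PairIndicatorMatrix, lo: float = 0.2, hi: float = 0.8
) -> PairIndicatorMatrix:
    """Keep pairs whose one-fraction f satisfies lo < f < hi (strict).

    Raises :class:`PipelineHalt` when nothing survives — a cohort with no
    informative pair cannot be modeled.
    """
    if len(pm.pairs) == 0:
        raise PipelineHalt("pairing", "pair matrix is empty; nothing to filter")
    f = pm.one_fraction()
    keep = f.index[(f > lo) & (f < hi)]
    log.info("valid pairs: %d of %d (lo=%g, hi=%g)", len(keep), len(f), lo, hi)
    if len(keep) == 0:
        raise PipelineHalt("pairing", "no pair has a one-fraction strictly inside "
                           f"({lo}, {hi}); cohort cannot be split informatively")
    return pm.subset_pairs(keep)
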