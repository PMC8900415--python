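"""Lightweight containers shared across pipeline stages.

All tabular payloads are plain pandas objects; the dataclasses here only
bundle them with the metadata each stage needs (sample labels, pair
composition, fitted coefficients) and enforce the invariants the pipeline
relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneAnnotation",
    "PairIndicatorMatrix",
    "CoxSignature",
    "ROCCurve",
    "CutoffResult",
    "PipelineHalt",
    "EmptyResult",
]

TUMOR = "tumor"
NORMAL = "normal"


class PipelineHalt(RuntimeError):
    """A stage aborted on invalid input; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


class EmptyResult(RuntimeError):
    """A screening stage legitimately found nothing; the run stops cleanly."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class ExpressionMatrix:
    """Genes x samples FPKM matrix with tumor/normal sample labels."""

    values: pd.DataFrame            # index: gene ids, columns: sample ids
    labels: pd.Series               # sample id -> "tumor" | "normal"

    def __post_init__(self):
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        missing = [s for s in self.values.columns if s not in self.labels.index]
        if missing:
            raise ValueError(f"samples without a tumor/normal label: {missing}")
        self.labels = self.labels.loc[self.values.columns]
        bad = set(self.labels.unique()) - {TUMOR, NORMAL}
        if bad:
            raise ValueError(f"unknown sample labels: {sorted(bad)}")
        if (self.values.values < 0).any():
            raise ValueError("FPKM values must be non-negative")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def tumor_samples(self) -> list[str]:
        return [s for s in self.samples if self.labels[s] == TUMOR]

    @property
    def normal_samples(self) -> list[str]:
        return [s for s in self.samples if self.labels[s] == NORMAL]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.labels)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        samples = list(samples)
        return ExpressionMatrix(self.values[samples], self.labels.loc[samples])

    def log2(self) -> pd.DataFrame:
        """log2(FPKM + 1), the scale used for correlation and DE testing."""
        return np.log2(self.values + 1.0)


@dataclass
class GeneAnnotation:
    """gene id -> biotype map; unknown biotypes are preserved as 'other'."""

    biotype: pd.Series              # gene id -> lncRNA | protein_coding | other
    symbol: pd.Series | None = None

    def __post_init__(self):
        if self.biotype.index.duplicated().any():
            raise ValueError("duplicate gene ids in annotation")

    def of(self, biotype: str) -> list[str]:
        return self.biotype.index[self.biotype == biotype].tolist()


def pair_id(a: str, b: str) -> str:
    return f"{a}|{b}"


@dataclass
class PairIndicatorMatrix:
    """0/1 rank-pair indicators: rows = canonical pairs 'A|B', cols = samples.

    Entry C(A,B,s) is 1 when gene A's expression in sample s is not lower
    than gene B's, else 0 — a within-sample comparison that needs no
    normalisation.
    """

    values: pd.DataFrame            # uint8, index "A|B", columns sample ids
    n_ties: int = 0                 # count of exactly-equal comparisons

    def __post_init__(self):
        arr = self.values.values
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise ValueError("pair indicators must be exactly 0 or 1")

    @property
    def pairs(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def one_fraction(self) -> pd.Series:
        """Per-pair fraction of samples with indicator 1."""
        return self.values.mean(axis=1)

    def subset_pairs(self, pairs) -> "PairIndicatorMatrix":
        return PairIndicatorMatrix(self.values.loc[list(pairs)], self.n_ties)

    def subset_samples(self, samples) -> "PairIndicatorMatrix":
        return PairIndicatorMatrix(self.values[list(samples)], self.n_ties)


@dataclass
class CoxSignature:
    """Selected pairs and their Cox coefficients; defines the risk score."""

    pairs: list[str]
    coef: np.ndarray
    loglik: float
    se: np.ndarray | None = None

    def __post_init__(self):
        self.coef = np.asarray(self.coef, dtype=float)
        if len(self.pairs) != len(self.coef):
            raise ValueError("pairs and coefficients must align")

    @property
    def n(self) -> int:
        return len(self.pairs)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n

    def as_frame(self) -> pd.DataFrame:
        from scipy import stats
        df = pd.DataFrame({"pair": self.pairs, "coef": self.coef})
        df["hr"] = np.exp(df["coef"])
        if self.se is not None:
            z = np.where(self.se > 0, self.coef / self.se, np.inf)
            df["se"] = self.se
            df["wald_p"] = 2.0 * stats.norm.sf(np.abs(z))
        return df.set_index("pair")


@dataclass
class ROCCurve:
    """Time-horizon ROC: thresholds (strictly decreasing) with sens/spec."""

    horizon: float                  # years
    table: pd.DataFrame             # columns: threshold, sensitivity, specificity
    auc: float

    def __post_init__(self):
        thr = self.table["threshold"].values
        if len(thr) > 1 and not (np.diff(thr) < 0).all():
            raise ValueError("ROC thresholds must be strictly decreasing")


@dataclass
class CutoffResult:
    """Optimal-cutpoint search result on a ROC curve."""

    threshold: float
    criterion: str
    value: float
    table: pd.DataFrame             # per-threshold criterion values
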