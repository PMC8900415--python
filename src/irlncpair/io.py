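"""Readers and writers for the TSV/GTF/JSON formats the pipeline consumes.

Expression matrices are genes x samples TSV with the gene id in the first
column.  Tumor/normal labels come from an explicit sidecar table when one
is given, otherwise from a TCGA-style barcode suffix (sample-type code 01
= tumor, 11 = normal); the explicit file wins.  Annotation is either a GTF
(``gene`` features with ``gene_id`` and ``gene_type``/``gene_biotype``
attributes, ``gene_type`` taking precedence) or a two-column TSV.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GeneAnnotation, TUMOR, NORMAL

__all__ = [
    "read_expression",
    "read_annotation",
    "read_immune_genes",
    "read_clinical",
    "read_abundance",
    "read_ic50",
    "labels_from_barcodes",
    "write_table",
]

log = logging.getLogger(__name__)

_BARCODE_SUFFIX = re.compile(r"[-.](0[0-9]|1[0-9])[A-Z]?$")


def labels_from_barcodes(samples) -> pd.Series:
    """Tumor/normal labels from TCGA-style sample-type suffixes (01/11)."""
    labels = {}
    for s in samples:
        m = _BARCODE_SUFFIX.search(s)
        if not m:
            raise ValueError(f"sample {s!r} has no recognisable sample-type suffix; "
                             "provide an explicit label file")
        code = int(m.group(1))
        labels[s] = TUMOR if code < 10 else NORMAL
    return pd.Series(labels)


def read_expression(path: str | Path, labels_path: str | Path | None = None) -> ExpressionMatrix:
    """Read a genes x samples FPKM TSV; labels from a sidecar or barcodes."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate gene ids in {path}: {dup}")
    values = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad.values][0]
            raise ValueError(f"non-numeric expression value at gene {gene!r}, sample {col!r}")
        values[col] = parsed
    if (values.values < 0).any():
        r, c = np.argwhere(values.values < 0)[0]
        raise ValueError(f"negative FPKM at gene {values.index[r]!r}, sample {values.columns[c]!r}")
    if labels_path is not None:
        lab = pd.read_csv(labels_path, sep="\t", index_col=0).iloc[:, 0].astype(str)
    else:
        lab = labels_from_barcodes(values.columns)
    return ExpressionMatrix(values, lab)


_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _read_gtf(path: Path) -> GeneAnnotation:
    biotypes, symbols = {}, {}
    n_features = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = dict(_ATTR.findall(parts[8]))
            gid = attrs.get("gene_id")
            if gid is None:
                continue
            n_features += 1
            # gene_type wins over gene_biotype when both are present
            biotypes[gid] = attrs.get("gene_type", attrs.get("gene_biotype", "other"))
            symbols[gid] = attrs.get("gene_name", gid)
    if n_features == 0:
        raise ValueError(f"no gene features parsed from GTF {path}")
    bio = pd.Series(biotypes)
    bio = bio.where(bio.isin(["lncRNA", "protein_coding"]), "other")
    return GeneAnnotation(biotype=bio, symbol=pd.Series(symbols))


def read_annotation(path: str | Path) -> GeneAnnotation:
    """Read a GTF or 2-column (gene_id, biotype) TSV into a biotype map."""
    path = Path(path)
    if path.suffix.lower() in (".gtf", ".gff"):
        return _read_gtf(path)
    with open(path) as fh:
        first = fh.readline()
    if "\t" in first and len(first.split("\t")) >= 9:
        return _read_gtf(path)
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"annotation TSV {path} needs gene_id and biotype columns")
    bio = pd.Series(df.iloc[:, 1].astype(str).values, index=df.iloc[:, 0].astype(str).values)
    bio = bio.where(bio.isin(["lncRNA", "protein_coding"]), "other")
    return GeneAnnotation(biotype=bio)


def read_immune_genes(path: str | Path) -> list[str]:
    """Plain-text immune gene list, one symbol per line."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    if not out:
        raise ValueError(f"immune gene list {path} is empty")
    return out


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Clinical TSV: sample, time (days), event, age, stage, T, N, M.

    Unknown ordinal codes (``TX``, ``NX``, blanks) become missing values.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    for col in ("time", "event", "age"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if (df["time"] < 0).any():
        raise ValueError("clinical times must be non-negative")
    if not df["event"].dropna().isin([0, 1]).all():
        raise ValueError("event indicator must be 0/1")
    for col in ("stage", "T", "N", "M"):
        if col in df.columns:
            s = df[col].astype(str).str.strip()
            s = s.where(~s.str.upper().str.endswith("X"), other=pd.NA)
            s = s.replace({"": pd.NA, "nan": pd.NA, "NA": pd.NA})
            df[col] = s
    return df


def read_abundance(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"sample", "cell_type", "method", "abundance"}
    if not need.issubset(df.columns):
        raise ValueError(f"abundance table needs columns {sorted(need)}")
    if df.duplicated(["sample", "cell_type", "method"]).any():
        raise ValueError("duplicate (sample, cell_type, method) rows in abundance table")
    return df


def read_ic50(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"sample", "drug", "ic50"}
    if not need.issubset(df.columns):
        raise ValueError(f"IC50 table needs columns {sorted(need)}")
    if df.duplicated(["sample", "drug"]).any():
        raise ValueError("duplicate (sample, drug) rows in IC50 table")
    return df


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> Path:
    """Deterministic TSV export (fixed float format, no timestamps)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")
    return path
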