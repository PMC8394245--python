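"""Expression handling and pathway activation level (PAL) scoring.

The scoring chain is: raw counts -> median-of-ratios normalization ->
case-to-normal ratios (CNR) against an averaged-sample control -> PAL.

CNR_n for gene n in a sample is its normalized expression divided by the
control level, where the control is the dataset's averaged tumor sample
(geometric mean by default, so that log CNR is mean-zero per gene). PAL for
pathway p in a sample is

    PAL_p = 100 * sum_n ARR_np * log10(CNR_n) / sum_n |ARR_np|

over the pathway's genes measured in the matrix; ARR is the per-gene
activator/repressor weight in {-1, -0.5, 0, 0.5, 1}. A positive PAL means
net pathway up-regulation relative to the averaged sample.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LAYERS = ("raw", "normalized", "cnr")


class ExpressionError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix with a layer tag (raw | normalized | cnr).

    ``values`` is a pandas DataFrame indexed by upper-cased gene symbols with
    sample ids as columns. Raw layers are integer counts >= 0; CNR layers are
    strictly positive ratios.
    """

    values: pd.DataFrame
    layer: str = "raw"

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ExpressionError(f"unknown layer {self.layer!r}")
        if (self.values.values < 0).any():
            raise ExpressionError("negative expression values")
        if self.layer == "cnr" and (self.values.values <= 0).any():
            raise ExpressionError("CNR layer must be strictly positive")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def read_counts(path: str | os.PathLike) -> ExpressionMatrix:
    """Read a TSV count matrix (first column gene symbols, header sample ids).

    Gene symbols are upper-cased; duplicate gene rows are summed with a
    warning. Non-numeric, negative or non-integer cells raise
    :class:`ExpressionError` naming the offending coordinates.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.upper()
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            gene = df.index[bad.values.argmax()]
            raise ExpressionError(f"{path}: non-numeric count at gene {gene!r}, sample {col!r}")
    values = df.astype(float)
    if (values.values < 0).any():
        gene, sample = np.argwhere(values.values < 0)[0]
        raise ExpressionError(
            f"{path}: negative count at gene {values.index[gene]!r}, "
            f"sample {values.columns[sample]!r}"
        )
    if not np.allclose(values.values, np.round(values.values)):
        raise ExpressionError(f"{path}: raw counts must be integers")
    if values.index.duplicated().any():
        dups = sorted(set(values.index[values.index.duplicated()]))
        logger.warning("%s: %d duplicated gene row(s) summed (e.g. %s)", path, len(dups), dups[:3])
        values = values.groupby(level=0, sort=False).sum()
    return ExpressionMatrix(values=values, layer="raw")


def write_counts(m: ExpressionMatrix, path: str | os.PathLike) -> None:
    out = m.values
    if m.layer == "raw":
        out = out.astype(int)
    out.to_csv(path, sep="\t", index_label="gene")


def normalize_median_of_ratios(m: ExpressionMatrix) -> ExpressionMatrix:
    """Median-of-ratios (size factor) normalization of raw counts.

    For each sample, the size factor is the median over genes — restricted to
    genes with positive counts in every sample — of count / geometric mean of
    that gene across samples. Counts are divided by the sample's factor.
    This is the classical RNA-seq library-size correction; it assumes most
    genes are not differentially expressed.
    """
    if m.layer != "raw":
        raise ExpressionError("normalization expects the raw layer")
    if m.values.shape[1] < 2:
        raise ExpressionError("normalization needs >= 2 samples")
    counts = m.values.values.astype(float)
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        raise ExpressionError("no gene has positive counts in all samples")
    ref = counts[all_positive]
    log_geo_mean = np.log(ref).mean(axis=1, keepdims=True)
    ratios = np.exp(np.log(ref) - log_geo_mean)
    size_factors = np.median(ratios, axis=0)
    normalized = pd.DataFrame(
        counts / size_factors, index=m.values.index, columns=m.values.columns
    )
    return ExpressionMatrix(values=normalized, layer="normalized")


def compute_cnr(
    m: ExpressionMatrix, pseudocount: float = 1.0, control: str = "geometric"
) -> ExpressionMatrix:
    """Case-to-normal ratios against the averaged-sample control.

    The control value for each gene is the geometric mean (default) or the
    arithmetic mean across all samples of (value + pseudocount); CNR is
    (value + pseudocount) / control, strictly positive. With the geometric
    control, the per-gene geometric mean of CNR across samples is exactly 1,
    so PALs are mean-zero over the cohort.
    """
    if m.layer != "normalized":
        raise ExpressionError("CNR expects the normalized layer")
    if m.values.empty:
        raise ExpressionError("empty expression matrix")
    shifted = m.values.values + pseudocount
    if control == "geometric":
        ctrl = np.exp(np.log(shifted).mean(axis=1, keepdims=True))
    elif control == "arithmetic":
        ctrl = shifted.mean(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown control type {control!r}")
    cnr = pd.DataFrame(shifted / ctrl, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(values=cnr, layer="cnr")


def compute_pal(cnr: ExpressionMatrix, pathway, log_base: float = 10.0) -> pd.DataFrame:
    """Score PAL for one pathway in every sample.

    ``pathway`` is any object with ``name`` and ``arr`` (gene -> weight);
    genes absent from the matrix are skipped (their count is reported in the
    ``n_genes_used`` column). Raises :class:`ExpressionError` when no pathway
    gene is measured or all weights are zero.

    Returns a tidy DataFrame with columns sample_id, pathway, pal,
    n_genes_used.
    """
    if cnr.layer != "cnr":
        raise ExpressionError("PAL expects the CNR layer")
    name = pathway.name
    arr = {g.upper(): float(v) for g, v in pathway.arr.items()}
    present = [g for g in arr if g in cnr.values.index]
    skipped = len(arr) - len(present)
    if skipped:
        logger.info("pathway %s: %d gene(s) absent from the matrix, skipped", name, skipped)
    if not present:
        raise ExpressionError(f"pathway {name!r}: no pathway gene is present in the matrix")
    weights = np.array([arr[g] for g in present])
    denom = np.abs(weights).sum()
    if denom == 0:
        raise ExpressionError(f"pathway {name!r}: all ARR weights are zero")
    logs = np.log(cnr.values.loc[present].values) / np.log(log_base)
    pal = 100.0 * (weights @ logs) / denom
    return pd.DataFrame(
        {
            "sample_id": cnr.samples,
            "pathway": name,
            "pal": pal,
            "n_genes_used": len(present),
        }
    )


def seed_expression_score(
    normalized: ExpressionMatrix, gene: str, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Per-sample log2 expression of a single gene (the gene-level biomarker).

    Monotone in the normalized expression, so median splits and ROC analyses
    are unaffected by the log transform.
    """
    gene = gene.upper()
    if gene not in normalized.values.index:
        raise ExpressionError(f"gene {gene!r} absent from the matrix")
    vals = np.log2(normalized.values.loc[gene].values + pseudocount)
    return pd.DataFrame(
        {"sample_id": normalized.samples, "biomarker": f"{gene}_expr", "value": vals}
    )
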