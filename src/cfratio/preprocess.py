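"""Expression-matrix ingest and normalization ahead of scoring.

An expression matrix is a pandas DataFrame with gene symbols as the row
index and sample ids as columns; values are non-negative abundances
(FPKM, TPM, or normalized array intensity).  Rank-based scoring is
invariant to monotone per-sample transforms, so the TPM conversion and
log transform exist for interface parity and interpretability rather than
because the downstream enrichment scores require them.

Multi-batch inputs must be batch-corrected upstream; no correction is
applied here.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def validate_expression(m: pd.DataFrame, *, allow_duplicate_genes: bool = True) -> pd.DataFrame:
    """Check matrix invariants: unique samples, finite non-negative values."""
    if m.columns.duplicated().any():
        dups = m.columns[m.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dups}")
    if not allow_duplicate_genes and m.index.duplicated().any():
        dups = m.index[m.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dups}")
    vals = m.to_numpy(dtype=float)
    if not np.isfinite(vals[~np.isnan(vals)]).all():
        raise ValueError("expression values must be finite")
    if np.nanmin(vals) < 0:
        raise ValueError("expression values must be >= 0 (is the matrix in log space?)")
    return m


def fpkm_to_tpm(m: pd.DataFrame) -> pd.DataFrame:
    """Rescale each sample so its values sum to 1e6 (FPKM -> TPM).

    out[i, j] = in[i, j] / sum_i in[i, j] * 1e6.  Idempotent, and
    invariant to per-column scaling.  A sample with no positive value has
    no defined composition and is an error.
    """
    colsums = m.sum(axis=0)
    zero = colsums[colsums <= 0]
    if len(zero):
        raise ValueError(f"all-zero expression column(s): {zero.index.tolist()}")
    return m.div(colsums, axis=1) * 1e6


def collapse_duplicate_genes(m: pd.DataFrame, method: str = "max-mean") -> pd.DataFrame:
    """Resolve duplicate gene rows to one row per symbol.

    ``max-mean`` keeps the duplicate row with the highest row mean (ties:
    first occurrence, with a warning); ``first`` keeps the first
    occurrence.  Duplicate-free input is returned unchanged.
    """
    if not m.index.duplicated().any():
        return m
    if method == "first":
        return m[~m.index.duplicated(keep="first")]
    if method != "max-mean":
        raise ValueError(f"unknown collapse method {method!r}")
    means = m.mean(axis=1).to_numpy()
    keep = np.zeros(len(m), dtype=bool)
    for gene, grp in pd.Series(range(len(m)), index=m.index).groupby(level=0):
        idx = grp.to_numpy()
        best = idx[np.argmax(means[idx])]  # argmax keeps the first on ties
        if len(idx) > 1 and (means[idx] == means[best]).sum() > 1:
            logger.warning("collapse_duplicate_genes: tie on mean for %r; keeping first occurrence", gene)
        keep[best] = True
    out = m[keep]
    return out.loc[m.index.unique()]  # preserve first-occurrence gene order


def log2_transform(m: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(x + pseudocount); pseudocount must be positive."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return np.log2(m + pseudocount)


# ---------------------------------------------------------------- I/O

def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples matrix from TSV or GCT 1.2 (by content)."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#1.2"):
        return read_gct(path)
    m = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    m.index = m.index.astype(str)
    return validate_expression(m)


def read_gct(path) -> pd.DataFrame:
    """Read GCT 1.2: version line, dims line, then Name/Description header."""
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ValueError(f"{path}: not a GCT 1.2 file (first line {version!r})")
        dims = fh.readline().split()
        n_genes, n_samples = int(dims[0]), int(dims[1])
        m = pd.read_csv(fh, sep="\t", index_col=0)
    m = m.drop(columns=m.columns[0])  # Description column
    if m.shape != (n_genes, n_samples):
        raise ValueError(f"{path}: header declares {n_genes}x{n_samples}, found {m.shape}")
    m.index = m.index.astype(str)
    m.index.name = "gene"
    return validate_expression(m)


def write_expression(m: pd.DataFrame, path) -> None:
    """Write TSV: header row of sample ids, first column of gene ids."""
    m.to_csv(path, sep="\t", index_label="gene")


def write_gct(m: pd.DataFrame, path) -> None:
    """Write GCT 1.2 with an empty Description column."""
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{m.shape[0]}\t{m.shape[1]}\n")
        body = m.copy()
        body.insert(0, "Description", "na")
        body.to_csv(fh, sep="\t", index_label="Name")
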