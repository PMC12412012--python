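"""Readers, writers and cohort-preprocessing rules.

Formats
-------
* Expression matrices: TSV, genes (or probes) in rows, first column the
  gene/probe id, header row of sample ids, UTF-8, "." decimal — the
  shape of GEO series-matrix-derived exports.
* Sample labels, survival records, IHC records: CSV.
* Single-cell data: MatrixMarket triplet (``matrix.mtx`` genes x cells,
  ``genes.tsv``, ``barcodes.tsv``) plus ``cells.csv`` annotations
  (barcode, cell_type, tissue, patient_id, patient_msi).
* Signatures / manifests / summaries: JSON.

Preprocessing rules
-------------------
* :func:`collapse_probes` — where a gene is measured by several probes,
  keep the probe with the highest across-sample mean (ties broken by
  lexicographically smallest probe id).
* :func:`harmonize_msi_labels` — MSI-high and dMMR map to MSI; MSI-low,
  MSS and pMMR map to MSS; anything else becomes "unknown" and is
  excluded downstream with a logged count.
"""

from __future__ import annotations

import logging
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

log = logging.getLogger("glycomsi")

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_labels_csv",
    "write_labels_csv",
    "read_gene_list",
    "write_gene_list",
    "read_single_cell",
    "write_single_cell",
    "collapse_probes",
    "harmonize_msi_labels",
    "DEFAULT_MSI_SYNONYMS",
]


def read_expression_tsv(path) -> pd.DataFrame:
    """Read a genes-x-samples TSV (first column = gene/probe id)."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    return df


def write_expression_tsv(matrix: pd.DataFrame, path) -> None:
    # %.17g round-trips IEEE doubles exactly
    matrix.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


def read_labels_csv(path, label_col: str | None = None) -> pd.Series:
    """Read per-sample labels from a CSV with a ``sample_id`` column; by
    default the second column holds the label."""
    df = pd.read_csv(path)
    df = df.set_index("sample_id")
    col = label_col or df.columns[0]
    return df[col].astype(str)


def write_labels_csv(labels: pd.Series, path) -> None:
    labels.rename_axis("sample_id").to_frame().to_csv(path)


def read_gene_list(path) -> list[str]:
    """One gene id per line; blank lines ignored."""
    return [
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    ]


def write_gene_list(genes, path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


def write_single_cell(adata: ad.AnnData, directory) -> None:
    """Write an AnnData as MTX triplet + cell-annotation CSV."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    X = adata.X
    X = X if sparse.issparse(X) else sparse.csr_matrix(np.asarray(X))
    spio.mmwrite(d / "matrix.mtx", X.T.tocoo())  # genes x cells on disk
    write_gene_list(adata.var_names, d / "genes.tsv")
    write_gene_list(adata.obs_names, d / "barcodes.tsv")
    adata.obs.rename_axis("barcode").to_csv(d / "cells.csv")


def read_single_cell(directory) -> ad.AnnData:
    """Read an MTX triplet + cells.csv back into an AnnData (cells x genes)."""
    d = Path(directory)
    X = spio.mmread(d / "matrix.mtx").tocsr().T  # back to cells x genes
    genes = read_gene_list(d / "genes.tsv")
    barcodes = read_gene_list(d / "barcodes.tsv")
    obs = pd.read_csv(d / "cells.csv", index_col="barcode")
    obs.index = obs.index.astype(str)
    obs = obs.reindex(barcodes)
    return ad.AnnData(
        X=np.asarray(X.todense(), dtype=np.float64),
        obs=obs,
        var=pd.DataFrame(index=genes),
    )


def collapse_probes(matrix: pd.DataFrame, probe_to_gene: dict) -> pd.DataFrame:
    """Collapse a probe-level matrix to gene level.

    For each gene represented by multiple probes, only the probe with
    the highest across-sample mean expression is kept; exact mean ties
    break to the lexicographically smallest probe id. Probes absent from
    the map are dropped (count logged).
    """
    if matrix.empty:
        raise ValueError("empty matrix")
    mapped = [p for p in matrix.index if p in probe_to_gene]
    n_dropped = len(matrix.index) - len(mapped)
    if n_dropped:
        log.info("collapse_probes: dropping %d unmapped probes", n_dropped)
    sub = matrix.loc[mapped]
    order = pd.DataFrame(
        {"gene": [probe_to_gene[p] for p in sub.index], "mean": sub.mean(axis=1)},
        index=sub.index,
    )
    # best probe per gene first: mean descending, probe id ascending on ties
    idx = np.lexsort((order.index.to_numpy().astype(str), -order["mean"].to_numpy()))
    order = order.iloc[idx]
    keep = order[~order["gene"].duplicated(keep="first")]
    out = sub.loc[keep.index]
    out.index = [probe_to_gene[p] for p in out.index]
    out.index.name = "gene_id"
    return out.sort_index()


#: Default synonym table for MSI/MMR label harmonization (lower-cased keys).
DEFAULT_MSI_SYNONYMS = {
    "msi": "MSI",
    "msi-h": "MSI",
    "msi-high": "MSI",
    "msi_high": "MSI",
    "dmmr": "MSI",
    "msi-l": "MSS",
    "msi-low": "MSS",
    "msi_low": "MSS",
    "mss": "MSS",
    "pmmr": "MSS",
}


def harmonize_msi_labels(raw_labels, synonyms: dict | None = None) -> pd.Series:
    """Map raw MSI/MMR labels onto {MSI, MSS, unknown}.

    MSI-high (and dMMR) become MSI; MSI-low is merged with MSS (and
    pMMR) into MSS. Matching is case-insensitive via a configurable
    synonym table; unrecognized labels become "unknown" (logged), to be
    excluded downstream — they are data, not errors.
    """
    table = dict(DEFAULT_MSI_SYNONYMS)
    if synonyms:
        table.update({k.lower(): v for k, v in synonyms.items()})
    s = pd.Series(raw_labels).astype(str)
    out = s.str.strip().str.lower().map(table).fillna("unknown")
    n_unknown = int((out == "unknown").sum())
    if n_unknown:
        log.info("harmonize_msi_labels: %d unrecognized labels -> unknown", n_unknown)
    out.name = "msi_status"
    return out
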