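"""Tri-modal concordant differential-expression screen.

Identifies genes separating MSI from MSS colorectal cancer concordantly
across three expression modalities — bulk tissue, cell lines, and single
tumor-epithelial cells. A gene is selected when

* it is detected (non-zero counts) in at least ``prevalence_threshold``
  (default 5%) of tumor-epithelial cells,
* its absolute log2 fold change (MSI minus MSS) strictly exceeds
  ``fc_threshold`` (default 0.4) in *all three* modalities, and
* the three fold changes share one sign (consistent up- or
  down-regulation), unless sign concordance is disabled.

Fold changes are differences of group means of log2-scale values (for
single cells, of log2(count+1)), not log-ratios of linear means, since
the inputs are distributed log-transformed.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd

from .signature import GeneSignature

__all__ = [
    "ScreenThresholds",
    "log2_fold_change",
    "fraction_expressing",
    "sc_log2_fold_change",
    "screen_signature",
    "screen_cohorts",
]


@dataclass(frozen=True)
class ScreenThresholds:
    """Selection thresholds for the concordance screen."""

    fc_threshold: float = 0.4
    prevalence_threshold: float = 0.05
    require_sign_concordance: bool = True

    def __post_init__(self) -> None:
        if self.fc_threshold <= 0:
            raise ValueError("fc_threshold must be > 0")
        if not (0.0 < self.prevalence_threshold < 1.0):
            raise ValueError("prevalence_threshold must be in (0, 1)")


def _check_classes(labels: pd.Series, class_a: str, class_b: str) -> None:
    counts = labels.value_counts()
    for cls in (class_a, class_b):
        if counts.get(cls, 0) < 2:
            raise ValueError(
                f"class {cls!r} has {counts.get(cls, 0)} samples; need >= 2"
            )


def log2_fold_change(
    matrix: pd.DataFrame,
    labels: pd.Series,
    class_a: str = "MSI",
    class_b: str = "MSS",
) -> pd.Series:
    """Per-gene difference of group means of log2-scale expression.

    Parameters
    ----------
    matrix
        Genes x samples, values already on a log2 scale.
    labels
        Per-sample class label, indexed by sample id.
    class_a, class_b
        ``mean(class_a) - mean(class_b)`` is returned (MSI minus MSS by
        convention, so positive means up in MSI).
    """
    labels = labels.reindex(matrix.columns)
    if labels.isna().any():
        missing = matrix.columns[labels.isna()].tolist()
        raise ValueError(f"samples without labels: {missing[:5]}")
    _check_classes(labels, class_a, class_b)
    vals = matrix.to_numpy()
    if not np.all(np.isfinite(vals)):
        raise ValueError("expression matrix contains non-finite values")
    a = vals[:, (labels == class_a).to_numpy()].mean(axis=1)
    b = vals[:, (labels == class_b).to_numpy()].mean(axis=1)
    return pd.Series(a - b, index=matrix.index, name="log2fc")


def fraction_expressing(sc: ad.AnnData, cell_mask=None) -> pd.Series:
    """Per-gene fraction of (masked) cells with a non-zero count.

    ``cell_mask`` is a boolean array over ``sc.obs`` rows; by default all
    tumor-epithelial cells are used, matching the screen's prevalence
    rule ("detected in at least 5% of cells of that cell type").
    """
    if cell_mask is None:
        cell_mask = (sc.obs["cell_type"] == "tumor_epithelial").to_numpy()
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if cell_mask.sum() == 0:
        raise ValueError("cell mask selects no cells")
    X = sc.X[cell_mask]
    X = X.toarray() if hasattr(X, "toarray") else np.asarray(X)
    frac = (X > 0).mean(axis=0)
    return pd.Series(np.asarray(frac).ravel(), index=sc.var_names, name="frac_expressing")


def sc_log2_fold_change(sc: ad.AnnData) -> pd.Series:
    """Per-gene MSI-minus-MSS difference in mean log2(count+1) over
    tumor-epithelial cells, pooled across patients."""
    obs = sc.obs
    tumor = (obs["cell_type"] == "tumor_epithelial").to_numpy()
    msi = tumor & (obs["patient_msi"] == "MSI").to_numpy()
    mss = tumor & (obs["patient_msi"] == "MSS").to_numpy()
    if msi.sum() == 0 or mss.sum() == 0:
        raise ValueError("need tumor-epithelial cells from both MSI and MSS patients")
    X = sc.X.toarray() if hasattr(sc.X, "toarray") else np.asarray(sc.X)
    logX = np.log2(X + 1.0)
    fc = logX[msi].mean(axis=0) - logX[mss].mean(axis=0)
    return pd.Series(fc, index=sc.var_names, name="log2fc_sc")


def screen_signature(
    bulk_fc: pd.Series,
    cellline_fc: pd.Series,
    sc_fc: pd.Series,
    frac_sc: pd.Series,
    thresholds: ScreenThresholds = ScreenThresholds(),
    name: str = "screened_signature",
) -> tuple[pd.DataFrame, GeneSignature | None]:
    """Apply the concordance rules and assemble the resulting signature.

    All four per-gene vectors must cover the same gene universe (order
    free). Returns the per-gene screen table (sorted by gene id) and the
    :class:`~glycomsi.signature.GeneSignature` built from the selected
    genes, with direction taken from the shared fold-change sign.
    """
    universe = set(bulk_fc.index)
    for v, label in ((cellline_fc, "cell line"), (sc_fc, "single cell"), (frac_sc, "prevalence")):
        if set(v.index) != universe:
            raise ValueError(f"{label} vector covers a different gene universe")
    genes = sorted(universe)
    tbl = pd.DataFrame(
        {
            "log2fc_bulk": bulk_fc.reindex(genes),
            "log2fc_cellline": cellline_fc.reindex(genes),
            "log2fc_sc": sc_fc.reindex(genes),
            "frac_expressing_sc": frac_sc.reindex(genes),
        },
        index=pd.Index(genes, name="gene"),
    )
    fcs = tbl[["log2fc_bulk", "log2fc_cellline", "log2fc_sc"]].to_numpy()
    prevalent = tbl["frac_expressing_sc"].to_numpy() >= thresholds.prevalence_threshold
    big = np.all(np.abs(fcs) > thresholds.fc_threshold, axis=1)
    all_pos = np.all(fcs > 0, axis=1)
    all_neg = np.all(fcs < 0, axis=1)
    if thresholds.require_sign_concordance:
        selected = prevalent & big & (all_pos | all_neg)
    else:
        selected = prevalent & big
    direction = np.where(
        selected & all_pos, "up", np.where(selected & all_neg, "down", "none")
    )
    # without concordance a selected gene's direction follows the bulk sign
    if not thresholds.require_sign_concordance:
        mixed = selected & ~(all_pos | all_neg)
        direction = np.where(
            mixed, np.where(tbl["log2fc_bulk"] > 0, "up", "down"), direction
        )
    tbl["selected"] = selected
    tbl["direction"] = direction
    if selected.any():
        sig = GeneSignature(
            up_genes=tuple(tbl.index[tbl["direction"] == "up"]),
            down_genes=tuple(tbl.index[tbl["direction"] == "down"]),
            name=name,
        )
    else:
        sig = None
    return tbl, sig


def screen_cohorts(
    bulk: tuple[pd.DataFrame, pd.Series],
    cellline: tuple[pd.DataFrame, pd.Series],
    sc: ad.AnnData,
    thresholds: ScreenThresholds = ScreenThresholds(),
    name: str = "screened_signature",
) -> tuple[pd.DataFrame, GeneSignature | None]:
    """Convenience wrapper: compute all four per-gene vectors from the
    three cohorts (restricted to their common gene universe) and screen.

    Genes absent from any modality cannot satisfy the all-three rule and
    are excluded before screening.
    """
    b_mat, b_lab = bulk
    c_mat, c_lab = cellline
    common = sorted(
        set(b_mat.index) & set(c_mat.index) & set(sc.var_names)
    )
    if not common:
        raise ValueError("no genes shared by all three modalities")
    sc_sub = sc[:, common]
    return screen_signature(
        log2_fold_change(b_mat.loc[common], b_lab),
        log2_fold_change(c_mat.loc[common], c_lab),
        sc_log2_fold_change(sc_sub),
        fraction_expressing(sc_sub),
        thresholds,
        name=name,
    )
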