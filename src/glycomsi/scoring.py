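"""Glyco-MSI signature scoring and discrimination metrics.

The Glyco-MSI score of a sample is the mean log-scale expression of the
signature's up genes minus the mean of its down genes — no z-scoring or
re-normalization. Discrimination of MSI from MSS is quantified with the
tie-corrected rank AUC (the Mann-Whitney U statistic divided by
n_pos * n_neg), i.e. the probability that a random MSI sample scores
above a random MSS sample, ties counted half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .signature import GeneSignature

__all__ = [
    "ScoreResult",
    "ROCResult",
    "glyco_msi_score",
    "signature_average",
    "roc_auc",
    "pearson_correlation",
    "evaluate_cohorts",
]


@dataclass(frozen=True)
class ScoreResult:
    """Per-sample scores plus bookkeeping on which signature genes were used."""

    scores: pd.Series
    signature_name: str
    n_up_used: int
    n_down_used: int


@dataclass(frozen=True)
class ROCResult:
    auc: float
    n_pos: int
    n_neg: int
    u_statistic: float


def glyco_msi_score(matrix: pd.DataFrame, signature: GeneSignature) -> ScoreResult:
    """Score each sample: mean over up genes minus mean over down genes.

    Signature genes absent from the matrix are dropped (and counted in
    ``n_up_used`` / ``n_down_used``); an entirely absent arm is an error
    because the score is then no longer a contrast.
    """
    up = [g for g in signature.up_genes if g in matrix.index]
    down = [g for g in signature.down_genes if g in matrix.index]
    if signature.up_genes and not up:
        raise ValueError(f"no up-arm gene of {signature.name!r} present in matrix")
    if signature.down_genes and not down:
        raise ValueError(f"no down-arm gene of {signature.name!r} present in matrix")
    up_mean = matrix.loc[up].mean(axis=0) if up else 0.0
    down_mean = matrix.loc[down].mean(axis=0) if down else 0.0
    scores = up_mean - down_mean
    scores.name = signature.name
    return ScoreResult(scores, signature.name, len(up), len(down))


def signature_average(matrix: pd.DataFrame, gene_set) -> pd.Series:
    """Per-sample mean of the present genes of ``gene_set``.

    Used e.g. as a one-number immune-infiltration surrogate: the mean
    log-scale expression of an immune gene signature.
    """
    present = [g for g in gene_set if g in matrix.index]
    if not present:
        raise ValueError("no gene of the set present in the matrix")
    return matrix.loc[present].mean(axis=0)


def roc_auc(scores, labels, positive="MSI") -> ROCResult:
    """Tie-corrected AUC via midranks: U / (n_pos * n_neg).

    Equals the pairwise concordance probability
    P(score_pos > score_neg) + 0.5 * P(equal).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite scores")
    pos = labels == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(f"need both classes; got {n_pos} positive, {n_neg} negative")
    ranks = stats.rankdata(scores)  # midranks
    u = float(ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0)
    return ROCResult(auc=u / (n_pos * n_neg), n_pos=n_pos, n_neg=n_neg, u_statistic=u)


def pearson_correlation(x, y) -> float:
    """Product-moment correlation coefficient of two paired vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    return float(stats.pearsonr(x, y).statistic)


def evaluate_cohorts(cohorts, signature: GeneSignature) -> pd.DataFrame:
    """Evaluate score discrimination per cohort.

    Parameters
    ----------
    cohorts
        Mapping or iterable of ``(name, matrix, labels)``; mapping values
        are ``(matrix, labels)`` pairs.
    signature
        Signature scored in every cohort.

    Returns one row per cohort: auc, n_msi, n_mss, n_up_used,
    n_down_used, and an ``error`` column — a failing cohort is reported
    in its row without aborting the rest.
    """
    if hasattr(cohorts, "items"):
        items = [(k, m, l) for k, (m, l) in cohorts.items()]
    else:
        items = list(cohorts)
    if not items:
        raise ValueError("no cohorts supplied")
    rows = []
    for name, matrix, labels in items:
        row = {"cohort": name, "auc": np.nan, "n_msi": 0, "n_mss": 0,
               "n_up_used": 0, "n_down_used": 0, "error": ""}
        try:
            res = glyco_msi_score(matrix, signature)
            lab = pd.Series(labels).reindex(res.scores.index) if not isinstance(
                labels, pd.Series) else labels.reindex(res.scores.index)
            roc = roc_auc(res.scores.to_numpy(), lab.to_numpy())
            row.update(
                auc=roc.auc, n_msi=roc.n_pos, n_mss=roc.n_neg,
                n_up_used=res.n_up_used, n_down_used=res.n_down_used,
            )
        except ValueError as exc:
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows).set_index("cohort")
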