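"""IHC H-score quantification and association statistics.

GALNT7 staining of tumor epithelium is quantified as an H-score: the
product of staining intensity (0 negative, 1 weak, 2 moderate, 3
strong) and a positivity category binning the percentage of positive
cells (1: 0-25%, 2: 26-50%, 3: 51-75%, 4: 76-100%). The product ranges
0-12 and takes exactly nine values {0,1,2,3,4,6,8,9,12}. Tumors with
H-score >= 8 are GALNT7-High, below GALNT7-Low (the printed Low bin is
0-7 even though 7 itself is not a product of any intensity x category
pair; using the >= 8 cut keeps every integer 0-12 classifiable, e.g.
when observers' scores are averaged).

Association statistics are the field's standard ones: Fisher's exact
test (two-sided by the minimum-likelihood rule), Pearson's chi-square
without continuity correction by default, and the Mann-Whitney U test
with the tie-corrected normal approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import floor

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "positivity_category",
    "h_score",
    "classify_galnt7",
    "fisher_exact",
    "chi_square_test",
    "mann_whitney",
    "summarize_ihc_cohort",
    "ACHIEVABLE_H_SCORES",
]

#: All H-scores reachable as intensity (0-3) x positivity category (1-4).
ACHIEVABLE_H_SCORES = frozenset(
    i * c for i in range(4) for c in range(1, 5)
)


def positivity_category(pct) -> int:
    """Bin a percentage of positive cells into categories 1-4.

    0-25% -> 1, 26-50% -> 2, 51-75% -> 3, 76-100% -> 4. Non-integer
    percentages are floored before binning (scores are whole-percent
    estimates).
    """
    p = floor(float(pct))
    if not (0 <= p <= 100):
        raise ValueError(f"percentage {pct} outside 0-100")
    if p <= 25:
        return 1
    if p <= 50:
        return 2
    if p <= 75:
        return 3
    return 4


def h_score(intensity: int, positivity_cat: int) -> int:
    """Intensity (0-3) times positivity category (1-4); range 0-12."""
    i, c = int(intensity), int(positivity_cat)
    if i not in (0, 1, 2, 3):
        raise ValueError(f"intensity {intensity} outside 0-3")
    if c not in (1, 2, 3, 4):
        raise ValueError(f"positivity category {positivity_cat} outside 1-4")
    return i * c


def classify_galnt7(h) -> str:
    """H-score >= 8 -> "High", 0-7 -> "Low"."""
    h = int(h)
    if not (0 <= h <= 12):
        raise ValueError(f"H-score {h} outside 0-12")
    return "High" if h >= 8 else "Low"


def fisher_exact(table) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table.

    Returns (odds ratio, two-sided p). The odds ratio is the sample
    (a*d)/(b*c), reported as inf or 0 at zero cells; the two-sided p
    sums hypergeometric probabilities of all tables with the same
    margins whose probability does not exceed the observed table's.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a 2x2 table of non-negative counts")
    if t.sum() == 0:
        raise ValueError("all-zero table")
    res = stats.fisher_exact(t, alternative="two-sided")
    a, b, c, d = t.ravel()
    if b * c == 0:
        odds = np.nan if a * d == 0 else np.inf  # nan: 0/0, margin degenerate
    else:
        odds = (a * d) / (b * c)
    return float(odds), float(res.pvalue)


def chi_square_test(table, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square test of independence on an r x c table.

    No Yates continuity correction by default (pass ``correction=True``
    to enable it). Requires all expected counts > 0.
    """
    t = np.asarray(table, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative counts")
    res = stats.chi2_contingency(t, correction=correction)
    if np.any(res.expected_freq <= 0):
        raise ValueError("zero expected count")
    return float(res.statistic), float(res.pvalue)


def mann_whitney(x, y) -> tuple[float, float]:
    """Mann-Whitney U test, tie-corrected normal approximation.

    Returns (U for x, two-sided p); U/(n_x*n_y) equals the rank AUC of x
    over y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic", use_continuity=False)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class IHCSummary:
    """Stratified summary of an IHC cohort."""

    strata: pd.DataFrame          # per MMR stratum: n, n_high, prop_high
    pdl1_tables: dict             # stratum -> 2x2 DataFrame (class x PD-L1)
    pdl1_tests: pd.DataFrame      # stratum: pdl1_prop_high/low, OR, fisher p, status
    marker_tests: pd.DataFrame    # stratum x marker: medians by class, U, p, status


_MARKERS = ["tn_h_score", "cd8", "cd4", "foxp3", "cd163"]


def summarize_ihc_cohort(records: pd.DataFrame) -> IHCSummary:
    """Stratified GALNT7-High proportions and association tests.

    Per MMR stratum: the GALNT7-High proportion; the GALNT7 class x
    PD-L1 2x2 table with Fisher's exact p; and Mann-Whitney comparisons
    of Tn H-score and TIL densities between GALNT7-High and -Low tumors.
    A stratum or comparison without enough data is reported with status
    "insufficient data" instead of raising.
    """
    if len(records) == 0:
        raise ValueError("empty cohort")
    rec = records.copy()
    if "galnt7_class" not in rec.columns:
        rec["galnt7_class"] = rec["h_score"].map(classify_galnt7)

    strata_rows, pdl1_rows, marker_rows = [], [], []
    pdl1_tables = {}
    for stratum, grp in rec.groupby("mmr_status", sort=True):
        n = len(grp)
        n_high = int((grp["galnt7_class"] == "High").sum())
        strata_rows.append(
            {"mmr_status": stratum, "n": n, "n_high": n_high, "prop_high": n_high / n}
        )
        high = grp[grp["galnt7_class"] == "High"]
        low = grp[grp["galnt7_class"] == "Low"]

        if "pdl1_tumor" in grp.columns and grp["pdl1_tumor"].notna().any():
            tab = pd.crosstab(grp["galnt7_class"], grp["pdl1_tumor"]).reindex(
                index=["High", "Low"], columns=[1, 0], fill_value=0
            )
            pdl1_tables[stratum] = tab
            row = {
                "mmr_status": stratum,
                "pdl1_prop_high": tab.loc["High", 1] / max(1, tab.loc["High"].sum()),
                "pdl1_prop_low": tab.loc["Low", 1] / max(1, tab.loc["Low"].sum()),
                "odds_ratio": np.nan,
                "fisher_p": np.nan,
                "status": "ok",
            }
            if len(high) >= 1 and len(low) >= 1 and n >= 2:
                try:
                    odds, p = fisher_exact(tab.to_numpy())
                    row["odds_ratio"], row["fisher_p"] = odds, p
                except ValueError as exc:
                    row["status"] = str(exc)
            else:
                row["status"] = "insufficient data"
            pdl1_rows.append(row)

        for marker in _MARKERS:
            if marker not in grp.columns or grp[marker].isna().all():
                continue
            row = {
                "mmr_status": stratum,
                "marker": marker,
                "median_high": float(high[marker].median()) if len(high) else np.nan,
                "median_low": float(low[marker].median()) if len(low) else np.nan,
                "u_statistic": np.nan,
                "p_value": np.nan,
                "status": "ok",
            }
            if len(high) >= 1 and len(low) >= 1 and n >= 3:
                try:
                    u, p = mann_whitney(high[marker].dropna(), low[marker].dropna())
                    row["u_statistic"], row["p_value"] = u, p
                except ValueError as exc:
                    row["status"] = str(exc)
            else:
                row["status"] = "insufficient data"
            marker_rows.append(row)

    return IHCSummary(
        strata=pd.DataFrame(strata_rows).set_index("mmr_status"),
        pdl1_tables=pdl1_tables,
        pdl1_tests=pd.DataFrame(
            pdl1_rows,
            columns=["mmr_status", "pdl1_prop_high", "pdl1_prop_low",
                     "odds_ratio", "fisher_p", "status"],
        ).set_index("mmr_status") if pdl1_rows else pd.DataFrame(),
        marker_tests=pd.DataFrame(
            marker_rows,
            columns=["mmr_status", "marker", "median_high", "median_low",
                     "u_statistic", "p_value", "status"],
        ),
    )
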