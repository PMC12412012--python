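"""Median-split survival analysis on a score-linked synthetic cohort.

Samples above the median Glyco-MSI score form the "high" group; their
event hazard is simulated at half the baseline (true HR 0.5). The
analysis recovers this with a Kaplan-Meier comparison, the log-rank
test, and a univariable Cox model with a 95% Wald interval.
"""

import numpy as np

from glycomsi import GLYCO_MSI_V1, dichotomize_at_median, glyco_msi_score, stratify_by_value
from glycomsi.synthetic import SurvivalSimSpec, default_bulk_spec, generate_bulk_cohort, generate_survival

matrix, _ = generate_bulk_cohort(default_bulk_spec(seed=1))
score = glyco_msi_score(matrix, GLYCO_MSI_V1).scores
groups = (dichotomize_at_median(score) == "high").astype(int).to_numpy()

records = generate_survival(
    groups,
    SurvivalSimSpec(n=len(groups), log_hr=np.log(0.5), censoring_rate=0.3, seed=8),
)
records["sample_id"] = score.index.to_numpy()

comp = stratify_by_value(records, score)
lo, hi = comp.cox.summary["ci_low"].iloc[0], comp.cox.summary["ci_high"].iloc[0]
print(f"n = {comp.cox.n}, events = {comp.cox.n_events}, "
      f"groups = {comp.group_sizes}")
print(f"log-rank chi2 = {comp.logrank.statistic:.2f}, "
      f"p = {comp.logrank.p_value:.2e}")
print(f"HR (high vs low) = {comp.cox.hr():.3f}  "
      f"[95% CI {lo:.3f}-{hi:.3f}]")
for g, curve in comp.curves.items():
    print(f"  Kaplan-Meier S(5), group {g}: {curve.survival_at(5.0):.3f}")
print(
    "\nHR < 1 with a CI excluding 1 means high scorers have significantly"
    "\nlower hazard — the analysis recovers the simulated HR of 0.5."
)
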