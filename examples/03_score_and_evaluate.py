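"""Score cohorts with the Glyco-MSI signature and measure discrimination.

The Glyco-MSI score of a sample is the mean log2 expression of the up
genes (GALNT7, GALNT1, HPSE) minus the mean of the down genes (GALNT6,
ST6GAL1). Discrimination of MSI from MSS is the rank AUC: the
probability that a random MSI sample scores above a random MSS sample.
"""

from glycomsi import GLYCO_MSI_V1, evaluate_cohorts, glyco_msi_score
from glycomsi.synthetic import (
    default_bulk_spec,
    default_cellline_spec,
    generate_bulk_cohort,
)

bulk_m, bulk_l = generate_bulk_cohort(default_bulk_spec(seed=1))
cl_m, cl_l = generate_bulk_cohort(default_cellline_spec(seed=2))

scores = glyco_msi_score(bulk_m, GLYCO_MSI_V1).scores
print("first five bulk-sample scores:")
print(scores.head().round(3).to_string())

table = evaluate_cohorts(
    [("bulk_tissue", bulk_m, bulk_l), ("cell_lines", cl_m, cl_l)], GLYCO_MSI_V1
)
print("\nper-cohort discrimination:")
print(table[["auc", "n_msi", "n_mss"]].round(3).to_string())
print(
    "\nAUC near 1 means the five-gene score almost perfectly separates MSI"
    "\nfrom MSS samples; 0.5 would be chance. With the planted 0.8 log2FC"
    "\neffect both synthetic cohorts sit near 0.99."
)
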