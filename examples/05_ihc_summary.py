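"""H-score classification and MMR-stratified IHC association analysis.

Each tumor's GALNT7 staining is an H-score (intensity 0-3 times
positivity category 1-4, range 0-12); H >= 8 is GALNT7-High. The
summary reports the High proportion per MMR stratum, the GALNT7 class x
PD-L1 contingency with Fisher's exact test, and Mann-Whitney
comparisons of Tn antigen and TIL markers between classes.
"""

from glycomsi import classify_galnt7, h_score, positivity_category, summarize_ihc_cohort
from glycomsi.synthetic import IHCSimSpec, generate_ihc_cohort

# the scheme on one tumor: moderate staining in 60% of cells
cat = positivity_category(60)
h = h_score(2, cat)
print(f"intensity 2, 60% positive cells -> category {cat}, "
      f"H-score {h}, class {classify_galnt7(h)}\n")

records = generate_ihc_cohort(IHCSimSpec(n=2000, seed=4))
summary = summarize_ihc_cohort(records)

print("GALNT7-High proportion by MMR stratum:")
print(summary.strata.round(3).to_string())
print("\nPD-L1 positivity by GALNT7 class (Fisher exact):")
print(summary.pdl1_tests.round(4).to_string())
print("\nmarker comparisons (Mann-Whitney, High vs Low):")
print(summary.marker_tests.round(3).to_string(index=False))
print(
    "\ndMMR/MSI tumors are mostly GALNT7-High (~65%) while pMMR/MSS tumors"
    "\nare mostly Low (~21% High); within dMMR/MSI, PD-L1 positivity is"
    "\ndepleted in the GALNT7-High subset — the two molecular subtypes the"
    "\nclassification is designed to expose."
)
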