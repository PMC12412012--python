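# Methods

This note documents the statistical procedures `glycomsi` implements,
the synthetic data model its tests rest on, and the numerical choices
made where the design was genuinely open. Nothing here states a result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The concordance screen

The screen asks which of 188 glycosyltransferase genes separate MSI
from MSS colorectal cancer *consistently* across three measurement
modalities: bulk tumor RNA-seq, cancer cell lines, and single
tumor-epithelial cells. For each modality the effect measure is the
difference of group means on the log₂ scale,

    log2FC(g) = mean_MSI(x_g) − mean_MSS(x_g),

not the log of the ratio of linear-scale means — public expression
matrices are distributed log-transformed and the difference-of-means is
the convention for such data. Single-cell values enter as
log₂(count + 1) (pseudocount 1, bounded at zero), pooled over all
tumor-epithelial cells rather than patient-level pseudobulk; the
detection (prevalence) filter likewise pools cells: a gene must have a
non-zero count in at least 5% of tumor-epithelial cells. This guards
against the zero-inflation of droplet data promoting genes that are
only sporadically captured.

Selection requires, jointly: prevalence ≥ 0.05 (inclusive, "at least
5%"), |log2FC| strictly > 0.4 in *all three* modalities, and — because
the target is consistent up- or down-regulation — one shared sign
across the three fold changes. Sign concordance can be disabled
(`require_sign_concordance=False`), in which case direction follows the
bulk sign. Genes absent from any modality cannot satisfy the all-three
rule and are excluded before screening. Selection is monotone in both
thresholds and invariant to gene/sample order (property-tested).

There are no p-values here by design: the rule is purely
threshold-based, and the null behavior of the whole screen is
characterized by simulation instead (with no planted effect, the mean
number of selected genes per replicate is ≈ 0).

## The Glyco-MSI score and its evaluation

For a signature with up-arm *U* and down-arm *D*, a sample's score is
mean over present *U* genes minus mean over present *D* genes, computed
on the log-scale values exactly as provided — no z-scoring or
re-normalization, since the score definition contains none. Missing
signature genes are dropped and counted (`n_up_used`, `n_down_used`);
an entirely missing arm is an error because the score would stop being
a contrast. The score is therefore invariant to adding a constant to
the whole matrix, and swapping the arms negates it (both tested).

Discrimination is quantified by the rank AUC via midranks:
AUC = U / (n₊ n₋), the tie-corrected concordance probability
P(score_MSI > score_MSS) + ½ P(equal). The U-statistic route is exact
and deterministic, unlike trapezoidal ROC integration, and makes the
identity with the Mann–Whitney U (used on the IHC side) exact to
machine precision. `evaluate_cohorts` applies score + AUC per cohort
and isolates per-cohort failures into the result row rather than
aborting the table.

Immune infiltration is summarized by `signature_average`: the plain
mean of an immune gene set's log-scale values. This is deliberately not
a rank-based ssGSEA enrichment score; the package uses the quantity
only for correlation direction, and the operation accepts any gene
list, so a full immune signature can be supplied where available.

## Survival analysis

Expression or score values are dichotomized at the sample median with
ties assigned to "low" (strictly greater than the median → "high").
The tie rule is a deliberate choice: it is deterministic and keeps the
high group at most half the cohort.

The two groups are compared by: the Kaplan–Meier product-limit
estimator (censored-only times reduce the risk set but add no factor);
the standard two-group log-rank test with hypergeometric variance at
each distinct event time (p from χ²₁); and a Cox proportional-hazards
model maximizing the Breslow partial likelihood, with hazard ratios
reported as exp(β) and 95% Wald intervals exp(β ± 1.96·se). Breslow tie
handling was chosen over Efron because it is the simplest standard
method with a tractable brute-force oracle — the tests check the fitted
β against a golden-section maximizer of the Breslow partial likelihood
written independently, and check the log-rank statistic against the
Cox score statistic at β = 0, an exact identity when no event times are
tied. Censored records at time t remain at risk for the event at t
(standard convention). Monotone likelihood (complete separation) is
reported via `converged=False` — detected by diverging |β| or standard
error, since the score gradient itself vanishes at the asymptote — and
never raised.

Results computed with other software may differ in the third decimal on
real data with heavy ties (Efron vs Breslow) or with profile-likelihood
rather than Wald intervals; both alternatives are out of scope.

## The IHC H-score model

GALNT7 staining is quantified per tumor as intensity (0 negative … 3
strong) times positivity category (1: 0–25%, 2: 26–50%, 3: 51–75%,
4: 76–100% of cells positive), giving the 9 achievable values
{0,1,2,3,4,6,8,9,12} with range 0–12. Tumors with H ≥ 8 are
GALNT7-High. Note that 7 is not a product of any valid pair, yet the
Low bin is conventionally printed as "0–7"; the classifier uses the
≥ 8 cut so that any integer 0–12 — e.g. an average of two observers'
scores — remains classifiable. Non-integer positivity percentages are
floored before binning (scores are whole-percent estimates).

Association tests are the field's standard ones: Fisher's exact test
with the two-sided p summing hypergeometric probabilities of all
same-margin tables no more probable than the observed one (the
convention of common statistical software; verified against full
enumeration for every 2×2 table with total ≤ 40); Pearson's χ² without
Yates correction by default (a flag toggles it); and the Mann–Whitney
U test with the tie-corrected normal approximation, whose
U / (n_x n_y) equals the rank AUC to 1e−12. `summarize_ihc_cohort`
reports, per MMR stratum, the GALNT7-High proportion, the GALNT7 ×
PD-L1 2×2 table with Fisher p, and Mann–Whitney comparisons of Tn
antigen H-score and TIL densities; strata or comparisons without
enough data are flagged "insufficient data" rather than raised.

## Synthetic data model

The generators define the study conditions the tests and the
acceptance script run under. All are pure functions of their spec
(including the seed); randomness comes from named substreams of one
root seed (CRC-keyed `SeedSequence` children) so stages cannot
contaminate each other.

**Bulk and cell lines.** Log₂ expression is Gaussian: baseline mean 8.0
(a typical log₂ microarray intensity), per-gene noise SD 0.5 (a
realistic between-sample SD for an expressed gene), with the planted
effect ±0.8 added to MSI samples' means for the five signature genes.
Defaults mirror the cohort structure the analysis targets: 76 MSI /
450 MSS bulk samples and 20 / 34 cell lines. Count-level realism is
intentionally absent — the screen consumes log-scale values, so
library-size and batch structure would add machinery without exercising
any additional code path.

**Single cell.** Counts are Poisson with a base rate of 5 per gene,
then zeroed by independent Bernoulli dropout at rate 0.5, giving a
detection fraction of ≈ 0.5 for expressed genes. Dropout attenuates a
naive rate shift: a rate multiplier 2^0.8 would yield an observed mean
log₂(count+1) difference well below 0.8 once half the entries are
zeroed. The generator therefore calibrates the MSI-cell rate for
planted genes by bisection so that the *observed* expectation
(1 − d)·E[log₂(Poisson(λ)+1)] differs from baseline by exactly the
requested effect. Under extreme dropout the target can be unattainable
(the required rate grows like 2^(δ/(1−d))); the rate then saturates at
10⁴ and the planted effect is smaller than requested. Patients default
to 23 with a 4/23 MSI fraction; cells are assigned to patients
uniformly. The model reproduces zero-inflation — the feature that
motivates the 5% prevalence rule — but not ambient RNA, doublets,
per-cell library-size variation, or patient-level expression shifts, so
passing tests demonstrate correctness of the screen's arithmetic and
thresholds, not robustness to those artifacts.

**Survival.** Event times are exponential with hazard
h·exp(β·group); independent exponential censoring has its rate solved
by bisection so the expected censored fraction hits the target (≈ 30%
by default, with optional administrative truncation). This yields exact
seeded determinism and known truth for parameter-recovery tests
(e.g. true log-HR log 0.25 recovered within ±0.1 with ~95% CI coverage
over 50 replicates).

**IHC.** MMR status, GALNT7 class, and PD-L1 are drawn from explicit
conditionals; the (intensity, positivity) pair is then drawn uniformly
from the pairs consistent with the class, so `h_score ≥ 8 ⇔ High` holds
by construction. Defaults follow the observed cohort structure: ~8.4%
dMMR, High in 65.4% of dMMR and 21.3% of pMMR tumors, PD-L1 in 23.8% /
58.8% of High/Low dMMR tumors and 10% of MSS tumors. Tn H-score gets a
+3 mean shift in High tumors; TIL densities are gamma with heavier CD8
infiltration in dMMR. These auxiliary fields exist to exercise the
summary statistics, not to model staining biology.

## Numerical choices and problem sizes

- Fold-change threshold strictly > 0.4; prevalence ≥ 0.05; both per
  the stated selection rule's wording.
- Probe collapse keeps the probe with the highest across-sample mean;
  exact ties break to the lexicographically smallest probe id
  (deterministic).
- Label harmonization: MSI-high/dMMR → MSI; MSI-low/MSS/pMMR → MSS;
  anything else → "unknown", excluded downstream with a logged count.
- Expression TSVs are written with 17 significant digits and read with
  round-trip float parsing, so write∘read is the identity on doubles.
- Test and acceptance problem sizes (screen replicates of 80/400 +
  20/34 + 2,000 cells; 50-replicate recovery runs; Fisher enumeration
  to total 40) were chosen so the full suite runs in about a minute on
  one CPU while keeping Monte-Carlo standard errors well inside the
  asserted tolerances.

## Known limitations

- Real-cohort numbers depend on each dataset's upstream normalization;
  the loaders accept any log-scale matrix and make no attempt to
  reproduce cohort-specific preprocessing.
- Efron tie handling, stratified/multivariable model selection,
  time-varying covariates, and proportional-hazards diagnostics are not
  implemented.
- The immune score is a signature average, not ssGSEA; CMS, BRAF and
  TMB are carried as opaque labels if present, never computed.
- Whether single-cell fold changes should be pooled or pseudobulked,
  and whether scores should be z-scored per cohort, are open questions
  in the source methodology; the pooled/plain-average readings are
  implemented and documented above.
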