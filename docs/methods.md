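# Methods

## Specificity model

For each feature *g* (gene or peak) and cell type *c*, the reference
pipeline computes a pseudobulk mean activity E_gc over control cells and
converts it to a specificity score S_gc = E_gc / Σ_c' E_gc'. The score is a
proper distribution over cell types per feature (rows sum to 1, or to 0 for
features with no activity anywhere, which are flagged and never selected).
Because the score is a ratio within feature, it is invariant to any global
rescaling of the means; it is *not* invariant to per-type depth differences,
which is why cell-level normalization precedes averaging.

Choices that the score definition leaves open, fixed here:

- **RNA normalization** is counts-per-10,000 per cell *without* a log
  transform, then the arithmetic mean per type. A log transform would change
  the ratio that defines the score; the count scale keeps S_gc a share of
  total expression.
- **ATAC normalization** is the standard LSI form of TF-IDF:
  value = log(1 + 10⁴ · TF · IDF), TF the within-cell peak share, IDF =
  n_cells / n_cells-with-peak. Peaks absent everywhere get IDF 0 by
  convention (columns stay zero). Both the scale and the variant are
  configurable arguments. Any negative activity values produced by upstream
  transforms are clipped to 0 before averaging so A_pc, hence S_pc, stays in
  [0, 1].
- **Expression filter** (RNA only): a gene is kept if detected (count > 0)
  in at least 10 % of cells of at least one type, inclusive at the boundary.
- **Control cells** are a configurable conjunction of predicates rather than
  a hard-coded rule, because RNA references (donor pathology: Braak ≤ 2,
  no/possible neuritic plaques, no cognitive impairment, MMSE > 23) and ATAC
  references (pathological-control flag plus TSS enrichment strictly > 1)
  gate on different fields.
- **Selection count** is floor(q · |universe|) exactly, per type, with
  selection independent across types (sets may overlap). Ranking ties break
  by descending specificity, then descending mean activity, then feature id
  — deterministic and platform-independent.
- **Neuron subtypes** use a two-stage rule: top q_parent (default 20 %) of
  the full universe by parent-type specificity, then specificity recomputed
  *among the subtypes only* on that subset and the top q_subtype (20 %)
  taken per subtype. The same activity transform is used in both stages.

## SNP masks

All internal intervals are 0-based half-open (BED); variant positions are
1-based (VCF); the single conversion `pos − 1` lives in `snps_in_ranges`.
Masks are stored merged and sorted; abutting intervals merge because a mask
is a set of positions and abutment cannot change membership. The three
strategies:

- gene windows: gene **body** ± flank (30 kb default), symmetric, strand
  ignored, clamped at 0 (no upper clamp without a chromosome-sizes input);
- peak ranges: spans verbatim;
- multi-omic: subtype peak intervals kept when the base-pair gap to the
  nearest neuron-specific gene span is ≤ 300 kb (overlap counts as 0,
  boundary inclusive).

The APOE exclusion subtracts gene-body ± 1 Mb, with the APOE span looked up
in the supplied annotation rather than hard-coded, so any genome build
works. By default the exclusion applies to cell-type masks but not the
genome-wide score (a flag flips this). Membership for indels is tested on
POS only. An optional mask can empty out entirely; that is valid and
warned, not fatal.

## Summary statistics

HWE uses the 1-df chi-square goodness-of-fit test (monomorphic → p = 1);
an exact test would be a reasonable extension but the chi-square is
deterministic, fast, and matches the usual thresholding (p < 1e−6). QC
exclusion is strict on the stated side, so boundary values (MAC = 5,
p = 1e−6, missingness = 10 %) are kept. In the imputation filter, MAF
exactly at the 0.01 split falls under the lenient common-variant rule
(R² ≥ 0.4); a missing R² is treated as a directly typed variant (R² = 1)
with a warning.

Per-cohort association is a plain maximum-likelihood logistic regression of
case status on dosage plus covariates (five PCs by default at this stage;
three in the endophenotype battery, matching the two analysis contexts).
Mixed-model machinery is out of scope; for the independent synthetic
cohorts generated here plain logistic regression is the correct model.
Separation or non-convergence drops the variant with a warning — never a
silent NA. Cohorts need ≥ 5 cases and ≥ 5 controls. Meta-analysis is
fixed-effects inverse-variance on beta/SE (weights 1/SE²), with alleles
harmonized to the first cohort carrying each variant, sign and EAF flipped
for swapped reports, and unresolvable allele pairs dropped. Cochran's Q is
reported informationally; no genomic control or heterogeneity filtering is
applied.

## Scoring and association

Weights are consumed, not estimated: any six-column (CHR, ID, POS, A1, A2,
WEIGHT) table works, from raw meta-analysis betas to shrinkage-tool
posteriors. Harmonization matches by id, then by (chrom, pos), checks the
allele pair in both orientations, and records a flip flag (effective dosage
2 − d) rather than rewriting the matrix. Missing dosages are mean-imputed
per variant (2 × in-sample EAF). Raw scores are standardized to z-scores
with the sample SD (n − 1); a degenerate (constant) score distribution is
an error. No p-value thresholding of weights is applied by default.

Every association model shares one covariate scheme (age at death, sex,
PC1–3, APOE ε2/ε4 dosages; education added exactly when the outcome is
MMSE), casewise deletion, and n reported per model. The design matrix is
checked for rank deficiency by pivoted QR on unit-normalized columns and
collinearity is an error naming the offending columns, never a silent
estimate. The battery's "FDR" is the multiplicative adjustment min(1, p·m)
— deliberately not Benjamini–Hochberg, which is available separately under
its own name. Binary pathology outcomes are coded from NIA-Reagan stages
{2,3} → 1, {0,1} → 0. Per-SNP follow-up reports a study-wide line of
0.05/|set| derived from the actual set size; the locus scan is inclusive at
|Δpos| ≤ window and tests all available variants, not just mask members.
The single-cell eQTL test regresses donor-level pseudobulk counts-per-10k
expression (no log, consistent with the specificity normalization) on
dosage with the same covariates, requiring ≥ 20 donors.

## Synthetic data

The toy genome is two 10 Mb chromosomes — small enough that brute-force
interval scans remain feasible as oracles. Features are laid out on an even
stride (genome length / feature count); nominal spans are 10 kb genes and
500 bp peaks, shrunk automatically when a dense layout leaves less room.
The default end-to-end study uses 280 genes, giving a 71.4 kb stride so
that 30 kb windows of *different* genes never overlap and each cell type's
mask is private to its markers.

Counts are negative-binomial with background mean 0.2 and dispersion 0.5
(variance m + 0.5 m²), chosen to give realistic single-cell sparsity;
planted markers multiply the mean by `fold` (default 4) in their own type
only, and subtype markers get an extra fold within their subtype. Genotypes
are Binomial(2, MAF) with MAF ~ Uniform(0.05, 0.5), independent across
variants — the selection logic is position-based, so LD-free variants
exercise it fully (no LD simulation is attempted). Phenotypes set the
genetic value G = Σ effect × dosage and add Gaussian noise scaled so
var(G)/var(outcome) equals the target h² (default 0.3); the binary
diagnosis thresholds an independent liability copy at the target prevalence
(0.35). Covariates are generated independently of G.

The default recovery experiment plants 20 markers per type (fold 4), 10
variants inside each type's marker gene bodies plus 60 background variants,
n = 2,000 samples, h² = 0.3, and estimates weights from an independent
discovery cohort of the same size via the logistic GWAS. Problem sizes were
chosen so a 50-replicate experiment completes in well under a minute while
leaving each replicate's signal comfortably detectable.

What passing these tests shows — and does not show: the generators have no
LD, no batch or ambient-RNA structure, no population stratification, no
doublets, and outcome noise is Gaussian and independent across outcomes.
Recovery under these conditions validates the selection/scoring/association
logic, not robustness to the confounders of real cohort data.

## Numerical and degenerate-input conventions

- Ties in any ranking break deterministically (specificity, then mean
  activity, then feature id); reruns on identical input are byte-identical.
- Zero-activity features get specificity 0, not NaN, and are excluded from
  selection.
- An all-zero cell is an error naming the cell ids (it cannot be
  normalized), as is an empty cell-type group.
- Interval normalization (merge + sort) is idempotent; subtraction
  conserves covered length against the intersection.
- Logistic fits use Newton iterations capped at 100–200 with convergence
  checked; unstable SEs (> 10³) are treated as failures.

## Limitations

Distance-based SNP selection ignores LD, so variants tagging a causal site
from outside a mask are missed. Cell-type labels and subtype annotations
are inputs; no clustering, label transfer, doublet removal or batch
correction is performed. Bayesian effect-size shrinkage is an upstream
dependency, not reimplemented. The multiplicative FDR is conservative
relative to BH and is kept because it defines the battery's significance
arithmetic; both are exposed.
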