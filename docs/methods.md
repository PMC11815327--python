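# Methods

This note documents the models, algorithms, parameter choices and
limitations behind `comethnet`. It is written for users who need to know
what the package actually computes, not just which buttons to press.

## Scope and data model

The pipeline starts from a *normalized* beta matrix (CpG × sample,
values in [0, 1]); array-level QC and normalization (IDAT import,
detection-p filtering, dye-bias/quantile normalization, sex checks,
reference-based cell-proportion estimation) are upstream of this package.
Genomic coordinates are 1-based inclusive throughout (Illumina-manifest /
VCF convention); BED input/output is converted at the file boundary.
Genotypes are alt-allele dosages {0, 1, 2} with NaN for missing calls.

## Phenotype harmonization

Clinical labels follow fixed rules: dementia iff MMSE < 24 or last
CDR ≥ 1 (a missing score contributes false; both missing is an error); AD
iff dementia with CERAD ≥ 2 and Braak NFT stage ≥ III, or Braak ≥ V when
CERAD is unavailable. Psychosis status is harmonized across two rating
instruments by symptom *frequency* over the past month: recurrent means
≥ 3 times/month on the CERAD Behavioral Rating Scale or "about once a
week" and above (ordinal level ≥ 2) on the Neuropsychiatric Inventory; NPI
severity is ignored so the instruments match. AD+P requires a recurrent
delusion or hallucination rating at any assessment; AD−P requires zeros on
both symptoms at *all* assessments. Donors who are symptomatic but never
recurrent fall in neither defined group; they are labeled `indeterminate`
and excluded from group contrasts rather than forced into either class.

## Preprocessing

Confounders (age, sex, Braak stage, cell proportions, plate) are removed
from every CpG by per-CpG OLS on the beta scale (the scale the network is
built on); categorical covariates are one-hot encoded with a dropped
reference level, and compositional cell proportions should enter as
all-but-one columns. Residual rows are mean-zero and orthogonal to every
design column; residualization is idempotent. A rank-deficient design is
an error naming the collinear columns.

The variability filter ranks CpGs by unscaled median absolute deviation
(the 1.4826 consistency constant is omitted — ranking is scale-invariant,
so the choice is inert and documented only for reproducibility) and keeps
the top fraction (default 50%), breaking ties by CpG id.

The sample-outlier screen builds average-linkage trees under Euclidean and
under 1 − Pearson distance and flags a sample only when it is a singleton
branch whose merge height exceeds median + 3·IQR of all merge heights in
*both* trees. It never drops samples automatically — the main study
finding of "no consistent outliers" is a report, not an action.

## Unsigned network and module detection

Adjacency is `a_ij = |cor(x_i, x_j)|^β` with soft-threshold power β = 3 by
default; unsigned, so hyper- and hypomethylated CpGs moving together form
one module. Similarity is the topological overlap matrix
`TOM_ij = (ℓ_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)` with
`ℓ_ij = Σ_{u≠i,j} a_iu a_uj`, and clustering runs on 1 − TOM with average
linkage. `pick_soft_threshold` reports the standard scale-free fit index
(signed R² of the log-log connectivity histogram regression, 10 bins, on a
≤ 2,000-CpG subsample) per candidate power.

Module extraction is a re-implementation of the *spirit* of the hybrid
dynamic tree cut, not a branch-for-branch clone; the contract is
planted-module recovery. The recursive branch decomposition:

1. **Shaving** — leaves that join a branch far later than its core (the
   largest gap in sorted leaf-join heights, searched beyond a
   minimum-module-size core, exceeding 10% of the join-height span) are
   stragglers — typically noise CpGs chained onto a module — and are sent
   to grey while the core is revisited.
2. **Splitting** — a static cut at 99% of the branch root height produces
   sub-branches; every sub-branch of at least the minimum module size is
   descended into. Oversplitting a homogeneous module is deliberately
   tolerated here because the later eigengene-merge and kME-sweep stages
   repair it, whereas an undersplit (two modules fused) cannot be repaired
   downstream. A single dense sub-branch surrounded by many unclustered
   leaves is also descended into.
3. **Tightness** — an atomic branch becomes a module only if its mean
   within-branch |correlation| exceeds 2.5× the chance level for the
   sample count (median |r| of an uncorrelated pair, ≈ 0.6745/√(n−1)).
   This keeps all-noise data fully unassigned regardless of how the tree
   happens to fragment. Without sample-count information the fallback
   requires the mean within-branch TOM dissimilarity to sit below 90% of
   the matrix-wide background.

Blockwise runs split CpGs into balanced blocks (k-means on the top-8
principal-component loadings, capacity-constrained) and cut each block
separately. Two reconciliation stages make blockwise and single-block runs
agree: **eigengene merging** joins modules with 1 − |cor(ME)| below 0.15
(closest pair first, eigengenes recomputed after every merge), and a final
**kME membership sweep** assigns every CpG to its argmax-|kME| module when
that correlation is significant (default p < 1e-3, two-sided t test on
df = n − 2) and to grey otherwise, dropping modules that fall below the
minimum size. Merging uses the *absolute* eigengene correlation: in an
unsigned network a module mixes anti-correlated CpGs, which makes the ME
sign convention (mean member correlation ≥ 0) arbitrary — two blockwise
halves of one module can anticorrelate perfectly and would never merge
under signed correlation. Signed merging remains available
(`use_abs=False`) for signed networks.

Module eigengenes are unit-length first right singular vectors of the
CpG-standardized module submatrix, sign-aligned to non-negative mean
member correlation. Module membership (kME) is the Pearson correlation of
each CpG with each ME (p from the t transform, df = n − 2); probe
significance is the point-biserial correlation with the 0/1 trait; the
module–trait test is Welch's t on the ME between groups (the pooled-variance
test is a special case; group imbalance is expected in case-heavy cohorts);
the MM–PS correlation is Pearson on |MM| vs |PS| within the module
(absolute values — the standard tutorial convention; with signed values
the random loading directions of an unsigned module would cancel).
Candidate modules require trait p < 0.05, MM–PS p < 0.05 and MM–PS r > 0.
Hub CpGs are the intersection of the top quartile by |MM| and the top
quartile by |PS| within a module (ceiling counts, ties by CpG id); under
independent rankings this leaves ≈ 1/16 of the module, consistent with
published hub fractions.

## Module preservation

Preservation of reference modules in a test cohort uses three density
statistics (mean within-module adjacency, proportion of variance explained
by the test-cohort ME, mean |kME|) and three connectivity statistics
(cross-cohort correlations of intramodular connectivity, of kME, and of
the vectorized upper-triangle correlation matrices). The permutation null
draws uniform random CpG sets of the module's size from the shared CpGs
and treats each set as the module in *both* cohorts (label permutation),
which keeps the cross-cohort statistics well defined. Z(stat) =
(observed − null mean)/null SD; Z-density and Z-connectivity are medians
of their three component Zs (zero-variance statistics are excluded with a
log notice); Z-summary is their mean. Bands: > 10 highly preserved, 5–10
moderately preserved (both boundaries land in "moderate"), < 5 not
preserved. The default is 1,000 permutations; the bundled contract tests
use 200 to keep the suite fast, which changes Z-summary by well under the
stability tolerance on the fixtures. A module replicates when it is highly
preserved *and* shows a significant MM–PS correlation *and* a significant
module–trait test in the test cohort, computed with the reference labels.

## mQTL mapping

Genotype QC applies, in order: drop samples with > 5% missing calls, drop
SNPs with > 1% missingness, drop SNPs with MAF < 0.05 (exactly 0.05 is
kept), drop SNPs with Hardy–Weinberg exact-test p < 1e-5. The HWE test is
the exact conditional test on the heterozygote count given allele counts,
two-sided by point-probability ordering (the PLINK convention), computed
by direct enumeration with log-gamma factorials. Relatedness is screened
with a GRM-based kinship estimate (φ ≈ GRM/2 from standardized,
mean-imputed dosages) — a simpler estimator than KING, adequate for the
duplicate/unrelated discrimination it is asked to make; of each pair above
0.25 the member with higher mean kinship is removed (ties by sample id).
Ancestry adjustment uses the first three PCs of the standardized dosage
matrix with a deterministic sign convention.

The association model per SNP–CpG pair is OLS of residualized methylation
on [intercept, dosage, PC1–3]; methylation enters already residualized for
the epidemiological confounders, so only genotype PCs are added here. The
mass scan computes the dosage t statistic through the partialled-out
correlation (Frisch–Waugh), which is algebraically identical to the full
fit and is verified against a normal-equations oracle to 1e-8; SNPs with
missing dosages fall back to per-SNP complete-case fits. Only
same-chromosome pairs are tested: cis means |SNP − CpG| ≤ 1 Mb (boundary
inclusive), trans means > 1 Mb on the same chromosome — trans here
deliberately does *not* include other chromosomes. Records below p = 1e-5
are reported, sorted by p.

## Colocalization

Per-SNP evidence is the Wakefield asymptotic Bayes factor
`log ABF = ½ log(se²/(se² + W²)) + ½ z² W²/(se² + W²)` with prior effect
SD W = 0.15·sd(Y) for quantitative traits (sd(Y) = 1 on the residual
scale) and W = 0.2 for case-control log odds ratios. When a GWAS provides
p + MAF + n instead of beta/se, `var(beta) ≈ 1/(2·n·maf·(1−maf))` on the
standardized scale recovers se, and |z| from p recovers |beta| (the ABF
depends only on z²). SNPs are matched across traits by chromosome:position
only; allele harmonization/strand flips are out of scope and logged.

Under the one-causal-variant-per-trait assumption the hypothesis sums are
S1 = Σ ABF1, S2 = Σ ABF2, S4 = Σ ABF1·ABF2, S3 = S1·S2 − S4, combined
with the default priors p1 = p2 = 1e-4, p12 = 1e-5 and normalized to
PP0–PP4 in log space (log-sum-exp; the S3 cancellation at a single shared
SNP is handled exactly). The implementation is verified against exhaustive
enumeration over all causal configurations to 1e-12.

Candidate regions around GWAS lead SNPs span the furthest SNPs with
dosage r² > 0.6 within ±250 kb of the lead (lead-only when none qualify).
Regions with PP3+PP4 > 0.9 earn a permutation p-value: `n_random` random
lead SNPs are drawn uniformly from the QC'd panel, each LD-expanded and
resized symmetrically to the candidate's exact bp length; within each
random region the GWAS statistics are paired with the module CpG holding
the most significant mQTL records there (the candidate's own CpG when no
CpG has a record); draws sharing fewer than `min_snps` (default 10) SNPs
are redrawn, with a 10×n_random attempt cap. perm_p is the fraction of
random regions whose PP3+PP4 also exceeds 0.9, and a colocalization is
called only when PP3+PP4 > 0.9 *and* perm_p < 0.05. This guards against
candidates whose "colocalization" reflects pervasive genome-wide sharing
rather than a specific locus: in such genomes random regions pass as often
as the candidate and perm_p stays large.

## Enrichment

Set enrichment is a one-sided (greater) Fisher exact test of module CpGs
against a target CpG list on an explicit background (for cross-array
comparisons, the CpGs shared between arrays); the odds ratio is the sample
(a·d)/(b·c) with Haldane 0.5 correction at zero cells. Region enrichment
tests module CpGs and hub CpGs separately against each genomic region
(membership by position, regions merged when overlapping), Bonferroni
correcting across regions within each family. CpG→gene annotation takes
genes within 1 kb of a probe (inclusive boundary). Cell-type enrichment
follows the expression-weighted bootstrap scheme: the statistic per cell
type is the mean specificity of the gene list, the null is `n_boot`
same-size uniform gene samples from the matrix's universe,
p = (1 + #{null ≥ observed})/(1 + n_boot) (the +1 keeps p positive, the
standard permutation estimator), fold = observed/null mean, and
Benjamini–Hochberg adjusts across cell types (the convention of the
reference bootstrap method; Bonferroni is used for regions because that is
how region counts are reported).

## Synthetic cohorts

The generator works on the M-value scale, `M = log2(beta/(1−beta))`, where
array noise is approximately homoscedastic, and maps to beta through the
logistic transform. Each planted module is a one-factor model: member
CpGs load on a shared per-sample eigengene with graded |loadings| drawn
uniformly from ±0.2 around the module mean (a hub-to-periphery gradient,
as in real modules — and necessary for connectivity-based preservation
statistics to carry signal) and random signs (hyper-/hypomethylated
members). Trait-associated modules shift the eigengene by a standardized
difference between trait groups before normalization. Every CpG gets its
own baseline level ~N(0, 2) on the M scale, per-CpG covariate responses
(age, sex, Braak, neuronal proportion, plate), and N(0, noise_sd²) noise;
defaults emulate a ~120-donor brain cohort at 70% case prevalence with
five planted modules of 150–400 CpGs, mean loading 0.7 and unit noise.

Genotypes are latent Gaussians with AR(1) autocorrelation 0.98 within
20-SNP blocks, thresholded at Hardy–Weinberg genotype frequencies for
block-level MAFs (shared within a block with small jitter, as in real
haplotype blocks — without this, MAF heterogeneity caps attainable dosage
r² below the 0.6 region-expansion threshold). At the default 5 kb SNP
spacing this yields adjacent dosage r² ≈ 0.8 and r² > 0.6 spans of tens of
kb, comparable to imputed-panel LD. Planted mQTLs solve for the effect
size b such that `cor(beta(M + b·dosage), dosage)²` equals the requested
variance explained *in the realized sample and on the beta scale the
pipeline analyzes* (Brent root find; the logistic map compresses M-shifts
near the [0,1] boundaries, so calibrating on the M scale would
under-deliver). GWAS summary statistics come from an explicit independent
panel drawn from the same LD process (not analytic draws), so LD is
consistent between panels by construction; phenotypes add √h² per
standardized causal dosage. Specificity matrices are Dirichlet rows,
concentrated (α = 20 vs 1) on the planted cell type for planted genes.

What the generator does *not* emulate: probe-design artifacts and type
I/II chemistry differences, batch effects beyond a plate offset,
genome-realistic coordinates or LD structure (fixed spacing, block-AR(1)),
imputation uncertainty, and cell-type-specific methylation. Passing tests
therefore demonstrate that the algorithms recover the statistical
structure they assume, not that any particular biological dataset will
behave as cleanly.

## Numerical and design choices

* Correlation p-values use the exact t transform `t = r√((n−2)/(1−r²))`.
* TOM is computed with one matrix product (`ℓ = A² − 2A` exploits the unit
  diagonal) and clipped to [0, 1]; degenerate denominators map to 0.
* Zero-variance CpGs are an error in network construction (they admit no
  correlation), a degenerate-flag case in MM–PS correlation (r = 0,
  p = 1), and rank-deficiency is an error naming the collinear columns.
* Tie-breaks are deterministic everywhere (CpG/sample id order), and all
  stochastic stages take explicit seeds; the pipeline driver derives
  per-stage child seeds from the global seed by stable hashing, so stages
  are independently reproducible.
* Band boundaries: preservation Z-summary exactly 10 is "moderate";
  MAF exactly 0.05 is kept; cis distance exactly 1 Mb is cis; a gene at
  exactly 1 kb is annotated.
* The problem sizes in the bundled test suite and the acceptance script
  (5,000-CpG networks, 1,000–2,000-SNP panels, 200 preservation
  permutations, 200 random regions per colocalization candidate) are the
  package's chosen verification scale: large enough that every contract is
  exercised at realistic signal-to-noise, small enough to run routinely.

## Known limitations

* The tree cut matches the reference dynamic hybrid algorithm in behavior
  (planted-partition recovery, noise robustness) but not branch-for-branch;
  module counts on real data may differ from runs of the original
  implementation with particular deepSplit/PAM settings.
* The kinship estimator is GRM/2, not KING; it discriminates duplicates
  and close relatives from unrelated samples but is not robust to strong
  ancestry structure.
* Colocalization assumes at most one causal variant per trait per region;
  multi-causal fine-mapping is out of scope.
* Different-chromosome SNP–CpG pairs are never tested, by definition of
  the trans window used here.
* Missing dosages use pairwise complete-case regression, which assumes
  missingness unrelated to methylation.
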