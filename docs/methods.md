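# Methods

This note documents the statistical models implemented in `postgwas`, the
design choices behind the synthetic-data generator, and the numerical
conventions that affect results.

## Disease model and cohort simulation

Case-control cohorts are generated from an additive logistic model on
genotype dosage: for individual j with dosages g_jk,

    logit P(case) = β₀ + Σ_k β_k g_jk.

The intercept β₀ is not a free parameter; it is solved (Brent root-finding
on a 200,000-draw Monte-Carlo genotype sample) so that the population mean
case probability equals the assumed lifetime risk K, default **0.5%** — the
baseline risk for testicular germ cell tumors averaged over the
contributing countries. Case/control samples are drawn by rejection from
this population model rather than by a liability-threshold construction, so
the generative model matches the logistic association model exactly and
odds-ratio recovery is unbiased by design. During rejection only causal
dosages are materialised, which keeps sampling at K = 0.005 cheap; full
genotype rows are built for accepted samples only.

Haplotypes come from a block-stationary Markov copy chain: within an LD
block a haplotype copies the previous variant's allele with probability ρ
(`within_block_rho`) and otherwise draws Bernoulli(f_j) at the variant's
base frequency. Blocks are independent. With equal frequencies inside a
block the adjacent-variant correlation equals ρ exactly, and in general r²
decays geometrically with distance — a deliberately simple stand-in for
reference-panel LD that gives tunable, monotone decay. Because copying
pulls marginal frequencies toward their block neighbours, the generator
reports the chain's theoretical marginals (p_j = ρ p_{j−1} + (1−ρ) f_j) as
the panel truth; conservation tests compare cohort control frequencies to
the *realised* panel frequencies, since cohorts resample the panel itself.

Genotypes are the sum of two independently drawn haplotypes
(Hardy-Weinberg by construction). An X-linked mode draws one haplotype per
(male) sample and codes dosage {0, 2}, keeping the per-allele effect scale
identical to autosomes. Missingness, when requested, is injected uniformly
at random. All randomness flows from a single master seed through spawned
per-study substreams, so adding a study never perturbs earlier ones and
identical seeds give bit-identical cohorts.

Default study conditions mirror the target study class: odds ratios in the
1.1–1.6 range, risk-allele frequencies 0.1–0.8, prevalence 0.5%,
several studies of equal size (per-study case:control ratios are uniform
because the multi-site design does not pin them down).

## Quality control

Variant filters run in a fixed order — call rate (< 0.99), differential
missingness by case status (two-sided Fisher, P < 10⁻⁵), Hardy-Weinberg
exact test (P < 10⁻⁵), minor allele frequency (< 0.01), duplicate physical
position — and each dropped variant carries the *first* failing reason, so
reports are deterministic. The HWE exact test conditions on allele counts
and sums the probabilities of all heterozygote configurations no more
probable than the observed one; it is evaluated in controls only, the
standard practice that avoids discarding variants whose case-group
departure from equilibrium is the association signal itself. Sample
filters: call rate (< 0.98), heterozygosity beyond 3 SD of the mean, and an
ancestry filter measuring Euclidean distance from the PC1/PC2 centroid with
a 6 SD cut. The original k-means clustering step degenerates on
single-population synthetic data, so the filter uses a single centroid;
with one cluster the two procedures coincide.

PCA standardizes dosages by √(2f(1−f)) after mean-imputation, uses a
truncated SVD with a fixed deterministic start vector when few components
are requested, and fixes component signs by making the largest-magnitude
loading positive.

## Association and meta-analysis

Per-variant association is additive logistic regression (intercept, dosage,
then principal components and study-center covariates), with a two-sided
Wald test on the dosage coefficient. The fitter is a compact IRLS/Newton
routine (max 50 iterations, log-likelihood tolerance 10⁻⁸) so genome-wide
scans of thousands of variants stay fast on one core; the test suite
cross-checks coefficients and standard errors against statsmodels to 10⁻⁶.
Separation and non-convergence produce flagged records with missing
estimates, never extrapolated numbers. P-values are computed in log space
(`norm.logsf`), so associations at the 10⁻¹⁵⁰ scale are representable as
−log₁₀P even where the float P underflows.

Meta-analysis is fixed-effects inverse-variance weighting. Effect alleles
are aligned to the first study; swapped records flip β and map f → 1−f,
strand flips resolve through base complements, variants absent from any
study and multiallelic records are dropped. Strand-ambiguous A/T and C/G
variants are dropped under the default strict policy; a permissive mode
orients them by frequency and requires the oriented frequencies to agree
within 0.2 — the standard compromise when strand information is absent.
Heterogeneity is controlled *before* significance: variants with Cochran
Q-test P < 0.001 are flagged and excluded from the significant set; I² > 50
is reported but never used as a filter. Genome-wide significance is
P ≤ 5×10⁻⁸. The genomic inflation factor is the median association χ²
divided by 0.4549364, the exact median of χ²₁. A single study is an exact
identity case: β and SE pass through unchanged and Q ≡ 0.

## Credible risk variants and conditional analysis

A locus's CRV set contains every reference-panel variant with r² ≥ 0.80 to
the lead within ±1 Mb (the same window as the cis-colocalization analyses;
the source methods give no explicit window). The ≥ boundary follows the
methods wording where the descriptive text is inconsistent ("≥ 0.80" vs
"> 0.80"); both the threshold and the window are configurable. The span of
the CRV set demarcates the gene region; genes overlap by ≥ 1 bp on 1-based
inclusive coordinates (BED I/O converts at the boundary), and a singleton
CRV set degenerates the region to the lead position.

Joint effects are approximated from summary statistics: marginal per-allele
βs are standardized by √(2f(1−f)), premultiplied by the inverse LD
correlation matrix, and standard errors taken from diag(R⁻¹) scaled by each
marginal sampling variance. This linear approximation, the one used by
summary-statistic conditional analysis of binary traits, is exact for
orthogonal variants (verified to 10⁻¹⁰) and agrees with direct two-variant
logistic fits within 15% relative error (coefficient-vector norm; a
per-coefficient ratio is unstable when the conditional effect of a
non-causal proxy is near zero) for |β| ≤ 0.3 at n = 20,000 across
r ∈ {0, 0.3, 0.5, 0.7}. Candidate pairs at r² ≥ 0.9 or matrices with
condition number above 10⁸ are rejected as collinear. Stepwise selection
starts from the smallest marginal P and adds the smallest conditional P
while it stays at or below 5×10⁻⁸, with deterministic (P, position, id)
tie-breaking; the selected set is invariant to input row order.

## Heritability and risk

Per-SNP heritability explained is h = β²·2f(1−f)/ln(λ²) with natural
logarithm — the base is fixed by requiring the packaged 22-locus table to
reproduce its published totals (7.0% at λ = 4, 4.7% at λ = 8), which it
does only under ln. X-chromosome loci enter the father-to-son (λ = 4)
aggregate exactly like autosomal ones; this mirrors the source computation
even though X is not father-to-son transmitted — fidelity over genetic
realism, and required to reproduce the printed totals. Lifetime risk uses
the rare-disease approximation OR ≈ RR, risk = RR·K capped at 1.

PRS weights always come from an external table (never re-fit on scored
samples). Scores are weighted allele counts with missing dosages replaced
by their expectation 2f; more than 20% absent model variants is a hard
failure. Percentile bins use edges 0, 5, …, 100 on the combined
case+control distribution with the 45–55th percentile stratum as the
reference (OR ≡ 1 by construction); per-bin ORs use Woolf log-OR 95%
intervals with Haldane-Anscombe 0.5 correction on zero cells. AUC is the
concordance probability (midranks, ties count ½), identical to the
normalized Mann-Whitney statistic. With fixed external weights
leave-one-out cross-validation re-estimates nothing, so the LOOCV AUC
equals the plain AUC; an optional mode re-fits a univariate logistic
calibration per left-out sample, which is mildly pessimistic at small n and
converges to the plain AUC — both interpretations are exposed.

## Gene adjudication

Component scores: region (2 = one gene, 1 = two or more, 0 = none),
location (1 = exonic/intronic/±10 kb inclusive), eQTL colocalization
(0/0.5/1 for none/one/two-plus significant non-testis tissues, +1 for a
significant testis colocalization; ceiling 2, giving a total ceiling of 7),
fetal germ-cell expression tertile (0/0.5/1; the published integer cutoffs
698/2348 ship as a replication fixture, low ≤ 698 < medium ≤ 2348 < high),
and promoter contacts (0/0.5/1 for none/one/two-plus cell lines). The
colocalization rule is strict on both inequalities: PP3+PP4 > 0.8 *and*
PP4/(PP3+PP4) > 0.9, with an empty denominator failing. Categories: total
≥ 3.0 highly likely, 2.0 or 2.5 moderately likely, below 2.0 unlikely —
the explicit enumeration resolves the boundary where a "≤ 2.0" phrasing
would overlap it. Missing evidence components contribute 0 and are flagged,
mirroring the reduced scheme used where a data type (X-chromosome eQTLs) is
unavailable; when a gene is scored at multiple signals the highest category
is reported.

A chromatin *connection* in a cell line requires a proxy SNP (default proxy
threshold r² ≥ 0.4, deliberately distinct from the 0.8 CRV threshold)
inside an open-chromatin peak, the SNP inside a loop's distal fragment, and
the contacted gene's promoter (TSS ± 1 kb) overlapping a peak — loops come
from the single Capture-C cell line, openness is evaluated per cell line.
Testis specificity: *enriched* = ≥ 1 TPM and ≥ 5× the maximum of other
tissues; *enhanced* = not enriched, ≥ 1 TPM and ≥ 5× the mean of the
others; checked in that order so the classes partition. Gene-set
enrichment is the hypergeometric upper tail including the observed count.

## Evidence generator

`simulate_evidence` assigns each gene a target category, picks a component
combination realising it, and lays out raw tables — annotation, signal
regions, colocalization posteriors, expression values, ATAC peaks,
promoter loops, TPM profiles — in disjoint 1 Mb tiles so signals cannot
interfere. Expression values are placed relative to the configured cutoffs
(the scoring pipeline receives the same cutoffs), because tertiles computed
from an arbitrary mixture of target classes would not respect per-gene
targets. The construction is exact rather than noisy: the round-trip
property (generated evidence re-scored to its assigned category) holds for
100% of genes, comfortably above the 95% requirement. What this does *not*
emulate: correlated evidence across tissues, shared regions between genes,
annotation errors, or partial data — conclusions about those belong to real
data, not to these tests.

## Problem sizes and determinism

The validation suite runs the full chain at reduced but non-trivial sizes
chosen to keep a complete run on one core in minutes: null calibration uses
20 seeds of 3 studies × 2,000 samples × 2,000 variants (λ_GC is assessed as
the mean over seeds, since the median-based estimator from 2,000 variants
has a per-seed sampling SD of ~0.05); effect recovery uses 20 seeds at a
combined n of 20,000. The demo pipeline run is fully deterministic:
identical config and seed give bit-identical reports and TSV artifacts.
When too few loci reach significance for percentile strata to be
well-defined (a handful of discrete score values), the pipeline's PRS stage
records the skip instead of failing the run.

## Known limitations

- The LD model has no recombination-map realism, no demographic structure,
  and no imputation-error model; relatedness is assumed pre-filtered.
- The joint-effect approximation inherits the usual summary-statistic
  caveats: it degrades as |β| grows, as case:control balance departs from
  the LD reference, and near collinearity.
- Colocalization posteriors are consumed, not computed; the Bayes-factor
  machinery that produces PP0–PP4 is out of scope.
- Heritability shares assume independent loci (no LD between lead SNPs) and
  the rare-disease OR ≈ RR approximation.
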