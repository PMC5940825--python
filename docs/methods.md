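# Methods

## The summary gene association statistic

The model underlying everything here is a pair of linear regressions on a
cohort of n individuals: per SNP, Y = α₁ + X_l β_l + η (the GWAS), and per
gene, Y = α₂ + T_g γ_g + ε, where T_g = Σ_l w_lg X_l is the genetically
regulated expression imputed from cis-SNP dosages with externally trained
weights. Writing sample moments with the n−1 convention, the least-squares
estimates are γ̂_g = Cov(T_g, Y)/Var(T_g) and β̂_l = Cov(X_l, Y)/Var(X_l),
with se²(γ̂_g) = σ̂_Y²(1−R_g²)/(n σ̂_g²) and the analogous expression per
SNP. Substituting and cancelling gives the Wald Z-score

    Z_g = Σ_l w_lg (σ̂_l/σ̂_g) Z_l · √((1−R_l²)/(1−R_g²)),

where σ̂_g² = W_g′ Γ_g W_g and Γ_g is the SNP covariance. Everything on the
right is available from summary data and a reference panel except the last
factor, which requires σ̂_Y² and n. By default the factor is set to 1
(`compute_zscore`); `compute_zscore_exact` restores it, using R_l² =
β̂_l² σ̂_l²/σ̂_Y² per SNP and R_g² = γ̂_g² σ̂_g²/σ̂_Y² with γ̂_g =
Σ_l w_lg β̂_l σ̂_l²/σ̂_g². On synthetic cohorts where the study set is its
own reference, the exact form reproduces the individual-level Z to
~1e-14, so any discrepancy of the default form is attributable to the
dropped factor alone; under a null phenotype at n = 500 the per-gene
difference stays near 0.01 in |Z| and the squared correlation across genes
exceeds 0.99999.

Numerical choices: σ_g² ≤ 1e-12 is reported as `zero_variance` rather than
divided by; when model SNPs are missing from the GWAS the statistic is
computed on the intersection with σ_g recomputed on that same subset, and
`n_snps_used`/`n_snps_in_model` is reported so users can filter poorly
covered genes. For a single-SNP model the ratio w σ_l/√(w²σ_l²) is
evaluated in closed form as sign(w), making the reduction of the gene
chi-square to the GWAS chi-square exact in floating point. P-values are
two-sided standard normal; no genomic control is applied. A helper
computes the Bonferroni threshold 0.05/(number of gene-tissue results).

## Conventions

All sample variances and covariances use n−1, including the reference
covariance Γ_g. This keeps the numerator and denominator of Z_g on one
convention; the choice is invisible to the Z-score at any realistic panel
size but matters for exact-identity tests. Missing panel dosages are
mean-imputed per SNP. Positions are 1-based; the cis window is
tss − 1 Mb ≤ pos ≤ tes + 1 Mb with inclusive boundaries.

Allele harmonization flips the effect sign and maps frequency f → 1−f when
the GWAS alleles are swapped relative to the model frame, removes
strand-ambiguous pairs (A/T, C/G and reverses) — ambiguity is checked
before frame matching, so an A/T record counts as ambiguous rather than
mismatched — and drops non-matching allele sets. The Z-score precedence
when parsing is: β/se if both present, else a provided Z, else
sign(effect) · Φ⁻¹(1−p/2) from a p-value with a sign source; p-value-only
records carry no sign and are dropped with a report entry. Odds ratios are
converted as β = ln(OR).

## Expression model training

Per gene, cis SNPs are filtered to MAF > 0.01 and resolvable strand,
expression is residualized on the supplied covariate matrix (covariate
estimation, e.g. expression factor analysis, is upstream of this package),
and an elastic net with mixing parameter α = 0.5 is fit on standardized
dosages, with coefficients mapped back to the dosage scale. The penalty is
selected over 10 CV folds by the one-standard-error rule: the strongest
penalty whose mean CV error is within one SE of the minimum. Both that
rule and selection at the minimum (`penalty_rule="min"`) are standard; we
default to the 1-SE rule because the minimum-error penalty systematically
over-selects — on the reference recovery setting (3 causal SNPs of 100,
h² = 0.5, n = 300) it yields median support precision ≈ 0.18 against ≈ 1.0
for the 1-SE rule at independent SNPs, while both recover every causal
sign correctly. Model performance is the squared correlation between
cross-validated predictions and observed expression with a one-sided
p-value for positive correlation (a negative predictive correlation is
failure, not signal). Models are retained at q < 0.05, with q-values from
Storey's π₀ (estimated on a λ-grid of 0.05…0.95 with cubic-spline
smoothing) times the Benjamini–Hochberg adjustment; fewer than 20
p-values, or an unstable π₀ outside (0, 1], falls back to π₀ = 1 (plain BH).

## SMR statistic and its null

T_SMR = Z²_eQTL Z²_GWAS/(Z²_eQTL + Z²_GWAS) is computed per gene from the
top eQTL; it is symmetric in its arguments, bounded by min(Z²_eQTL,
Z²_GWAS), and zero when either Z is zero. First-order expansions in either
dominance regime are provided: T ≈ Z²_GWAS (1 − Z²_GWAS/Z²_eQTL) when the
eQTL dominates, and the mirrored form otherwise; the expansion error falls
below 1% once one |Z| exceeds the other tenfold. The null-calibration
simulation draws, per repeat, 10⁵ pairs with Z²_GWAS ~ χ²₁ and Z²_eQTL ~
non-central χ²₁(λ = 29), retains pairs whose eQTL passes two-sided
p < 5×10⁻⁸ (Z² > 29.717), and records the mean T_SMR; with 1000 repeats
the grand mean lands near 0.93, quantifying the statistic's deflation
relative to the nominal χ²₁ mean of 1. Filtering is applied per repeat.
The whole 10⁸-pair simulation is vectorized and runs in seconds.

## Colocalization and the staged filter

For each gene region the per-SNP Wakefield log approximate Bayes factors
are ½[log(1−r) + r z²] with r = W/(W+V), V = se², and prior effect
variance W = (0.15·sdY)² for quantitative traits (sdY estimated by
regressing 2nf(1−f) on 1/V through the origin, defaulting to 1 when
frequencies or n are unavailable) or 0.2² for case-control. The five
configuration sums use per-SNP priors p1 = p2 = 1×10⁻⁴, p12 = 1×10⁻⁵
(exposed in `ColocPriors`), are accumulated in log space, and are
normalized to posteriors P0–P4. A region pair sharing a single SNP cannot
support the independent-signals configuration; it is flagged degenerate
with P3 = 0. Classification uses strict thresholds: colocalized if
P4 > 0.5, independent if P3 > 0.5, otherwise undetermined, with
1−P3−P4 reported as the aggregate limited-power probability.

The staged filter computes its thresholds from realized set sizes:
step 1 keeps gene associations at p < 0.05/n_tested; step 2 keeps
prediction-performance p-values < 0.05/n_step1; step 3 drops likely LD
contamination (keeps P3 < 0.5); step 4 optionally demands explicit
colocalization (P4 > 0.5). Stages are nested by construction. Survivors
with no colocalization result are dropped at step 3 by default
(`keep_missing_coloc` reverses this, with a count reported either way).

## Synthetic data

The generator is the package's test bed and defines its study conditions.
Genotypes are HWE draws with block LD via a Gaussian copula: per gene
block, each haplotype's SNPs share a latent equicorrelated normal
(correlation `ld_rho`, default 0.5) thresholded at the allele frequency
(uniform in `maf_range`, default 0.05–0.5), and the two haplotypes sum to
a dosage. This gives controllable within-block correlation without
coalescent machinery; the realized dosage correlation is somewhat below
the latent ρ. Genes are spaced 3 Mb apart so cis windows never overlap.
Expression is X·w over `n_causal_snps` SNPs (weights uniform ±[0.2, 1.0])
plus Gaussian noise scaled so the genetic variance share equals `h2_expr`
exactly at h² ∈ {0, 1} and in expectation otherwise. Phenotypes are null
(standard normal), mediated (γ per standardized genetic component, default
γ = 0.25, summed over the mediated genes, then standardized), or
LD-contaminated: decoy genes contribute through a block SNP drawn from the
reserved tail of the block (25% of SNPs never receive model weights), so
the phenotype-causal SNP is correlated with — but absent from — the
model. The decoy fixture uses a per-SNP effect of 0.5 sd so that decoys
actually reach association significance; a decoy that never becomes
significant would not exercise the LD-contamination filter. All draws
flow from one mandatory seed through `numpy.random.default_rng`, and a
scenario serializes to JSON.

What the generator does not emulate: realistic human LD maps, population
structure, binary-trait liability, allele-frequency spectra, or trans
effects. Passing tests therefore demonstrate internal consistency of the
statistical machinery under its stated model, not robustness to the full
complexity of real cohorts — in particular, reference/study LD mismatch is
not stressed beyond what the concordance experiment covers.

## Problem sizes

The shipped experiments use desk-scale sizes chosen to make the targeted
quantities stable: concordance on n = 500 individuals × 200 genes × 20
SNPs; null calibration on 1000 genes; the SMR null at its full 1000 × 10⁵
specification (the test suite uses 100 repeats, which already pins the
grand mean to ±0.01); training recovery on 50 genes × 100 SNPs × n = 300;
and the pipeline fixture on 20 seeds of 32 genes × n = 1500.

## Known limitations

- The exact-factor correction needs per-SNP betas plus σ_Y² and n; it is
  estimable but deliberately not the default, matching practice.
- Colocalization assumes one causal variant per trait per region; with
  multiple causal eQTLs posterior mass can shift toward "independent".
- The individual-level oracle is linear-model only; binary phenotypes
  enter as GWAS summaries upstream, not through the oracle.
- Storey's π₀ estimate is crude for small model sets; the BH fallback is
  conservative there.
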