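# Methods

This note documents the statistical models implemented in `pqtlkit`, the
defaults they ship with, what the synthetic-data generator does and does
not emulate, and the numerical choices that a maintainer would otherwise
have to reverse-engineer from the code.

## Synthetic cohorts (`pqtlkit.simulate`)

**Genotypes.** The LD model is blockwise haplotype copying. Each block
carries `n_ancestral` (default 12) independent ancestral haplotypes with
site frequencies drawn from a Beta spectrum (default Beta(0.4, 2), which
puts substantial mass below MAF 1%); every pool haplotype is a mosaic of
these with a per-site template-switch probability (`switch_rate`,
default 0.01). Adjacent common variants then show population r² of order
1/`n_ancestral`, decaying with distance, and cross-block r² is zero in
expectation. Sites whose target frequency falls below `rare_cut`
(default 0.08) model young alleles and are assigned directly by
Bernoulli draws: a small template set cannot produce frequencies below
1/`n_ancestral`, and recent rare alleles being essentially unlinked
(high D′, low r²) is also what real data show. Positions are 1-based
with fully closed intervals throughout.

**Cohorts.** Sampling a cohort recombines the pool haplotypes again;
`n_families` families contribute one full-sib pair each (children copy
whole parental blocks, giving expected GRM-scale relatedness 0.5, which
is recorded in `kinship_truth`). Isolate drift applies a Balding–Nichols
Beta perturbation to the pool frequencies — Var(p′ − p) = F·p(1−p) — and
moves each site to its drifted frequency by minimal random toggling of
haplotype entries, which preserves the haplotype background and hence
most LD. Missing genotypes are injected independently at a configured
rate. Age, sex, plate and season covariates are drawn per sample; plates
follow collection order, so plate and season are strongly (not
perfectly) correlated.

**Proteins.** Each protein is baseline + covariate effects + per-allele
variant effects + rare-burden effects + polygenic term + Gaussian noise,
on a natural-log (NPX-like) scale. Effect sizes are per allele in
phenotype-SD units, so a variant explains β²·Var(dosage). The polygenic
term uses the infinitesimal model — many small effects on common
(MAF ≥ 1%) markers scaled to `h2_poly` — whose conditional covariance is
`h2_poly` times the realized marker GRM (pedigree kinship in
expectation). A pedigree-only multivariate-normal term was rejected:
against a marker GRM it is not recoverable by REML at desk scale,
whereas marker-driven phenotypes match the mixed model the scan assumes.
Unless set explicitly, the noise standard deviation fills the remaining
unit variance budget; a budget above 1 is an error. The per-protein LOD
is the `lod_quantile` empirical quantile of the generated values.

**What the generator does not emulate:** realistic human LD maps and
recombination hotspots, demographic history, genotyping error and
likelihood-based calls, phasing, X-chromosome dosage, vendor-specific
panel normalization internals. Passing tests therefore demonstrate
correctness of the statistical machinery under the stated model, not
performance claims about any particular real cohort.

## Phenotype preparation (`pqtlkit.phenotypes`)

NPX values strictly below the per-protein LOD are set to missing (and
flagged); proteins with missing-or-censored proportion strictly greater
than 40% are dropped; remaining proteins are adjusted by OLS for age,
age², sex, plate indicators, season and per-sample mean NPX, and the
residuals are inverse-normal transformed with quantile offset
(r − 0.5)/n and average ranks for ties. The per-sample mean NPX is
computed after censoring and before protein exclusion. Rank-deficient
designs (for example season perfectly confounded with plate) drop the
redundant columns with a warning. Samples with missing age are excluded.
A panel with a single protein skips the mean-NPX covariate, which would
otherwise be the phenotype itself.

## Mixed-model scan (`pqtlkit.lmm`)

The GRM uses LD-pruned (r² ≤ 0.2 within 1 Mb) variants with MAF > 1%
passing the two-sided exact Hardy–Weinberg test at p ≥ 1e-5, with
columns centred at 2f and scaled by √(2f(1−f)). REML profiles the
restricted likelihood over λ = σ²_g/σ²_e through the eigendecomposition
of K, bracketing on a decade grid over log₁₀λ ∈ [−5, 5] before bounded
Brent refinement; λ at the lower bound is reported as σ²_g = 0, and an
identity GRM is flagged as non-identifiable. The scan mean-imputes
missing dosages per variant, filters MAC < 10 and missingness > 1%,
and reports the χ²₁ score statistic (upper tail) with effect and
standard error from the equivalent GLS fit under the fitted components.
λ_GC uses the fixed reference median 0.4549 and gates traits outside
[0.97, 1.05].

At desk scale a marker-estimated GRM has m comparable to n, and its
Marchenko–Pastur eigenvalue noise alone miscalibrates any mixed model —
an artefact of small m, absent at study scale (millions of markers).
Calibration experiments (type-I error, λ_GC contrasts with a naive
unadjusted scan) therefore use the simulation-truth kinship as K; all
parameter-recovery experiments use the estimated GRM.

## Signals, clumping and joint selection (`pqtlkit.peaks`)

Peak extraction visits significant variants by ascending p (ties broken
by position), removes everything at r² > 0.2 with the current variant,
then chains retained variants within 2 Mb (transitively, exposed as a
`--merge-adjacent` distance) into signals indexed by their lowest-p
member. Clumping is the same greedy pass at r² > 0.1 within 1 Mb.
Approximate joint selection rebuilds the normal equations from summary
statistics: X′X ≈ D^½ R D^½ with D_j = 2f_j(1−f_j)n_j and in-sample LD R
(the discovery cohort is its own LD reference), X′y_j = D_j β_j, and the
phenotypic sum of squares from the median of D_j β_j² + D_j se_j²(n_j−1).
Forward steps add the best conditional variant below the threshold,
skipping candidates at r² > 0.9 with the selected set; backward steps
drop selected variants whose joint p rises above it; iteration stops at
a fixed point (an explicit non-convergence error carries the partial
model). Conditional scans fit each remaining variant jointly with the
conditioning set; proxies at r² > 0.99 with that set are reported as
fully explained (β = 0, p = 1).

## Rare-variant burdens (`pqtlkit.burden`, `pqtlkit.quadform`)

Masks per gene (MAF < 5%, missingness < 1%): consequences strictly more
severe than missense with unit weights (`--include-missense` relaxes the
reading); all coding variants weighted by CADD phred; coding plus
gene-linked regulatory variants weighted by Eigen phred; regulatory-only
with Eigen. Weights are the raw phred scores — no additional MAF-based
weighting — so p-values are invariant to weight rescaling. Severity
comes from a packaged consequence rank table; regulatory-to-gene links
emulate eQTL-based linking.

The test decorrelates phenotype and genotypes with Σ^{-1/2} from the
fitted components, projects out covariates, and forms
Q_ρ = (1−ρ)Σw²_jS²_j + ρ(Σw_jS_j)² on the grid
ρ ∈ {0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1}. Per-ρ p-values invert the
characteristic function of the weighted chi-square mixture (Imhof), with
Liu-style moment matching as fallback. For the omnibus p the null of the
score vector is exactly N(0, Z′Z), so the null distribution of the
statistic T = min_ρ p_ρ is sampled directly (default 100,000 draws,
fixed internal seed, marginals uniformised by their own ranks so only
the copula matters); this matches permutation oracles within Monte Carlo
error. Beyond Monte Carlo resolution (fewer than 50 null exceedances)
the implementation falls back to the one-dimensional SKAT-O integration,
which measures ~2–3× conservative at small m with heterogeneous weights
— acceptable where p is orders of magnitude below any threshold; the
route used is recorded in the result. Single-variant masks and
single-point grids reduce exactly to the corresponding score tests.
Conditional re-testing moves the top single-point member into the fixed
effects; the end-to-end pipeline calls a burden "supported by at least
two distinct variants" when the conditional p stays below 1e-3.
Cross-cohort meta-analysis is Stouffer's method on one-sided
Z-equivalents weighted by √n (the combination rule is this package's
choice); genes present in one cohort keep their single-cohort p with a
flag.

## Calibration and replication (`pqtlkit.calibration`)

M_eff = M(1 − (M−1)V_λ/M²) with V_λ the population variance of the
correlation-matrix eigenvalues (the eigenvalue-variance form; the
equivalent trace expression is not used). Study-wide thresholds are
α/(M_eff · n_eff,variants) with the variant-side effective count
supplied by the user or by the null simulation. That simulation draws
standard-normal null phenotypes (default 200 replicates over a cohort of
500 samples, ~20,000 variants, 100 genes × 4 masks), records the minimum
p over single-point, burden and combined analyses, and estimates
effective test counts as α divided by the empirical α-quantile of the
minimum p — with 200 replicates this estimator carries roughly 30%
Monte Carlo noise, which the qualitative conclusion (the combined ratio
stays far below one order of magnitude) easily absorbs. The one-sided
proportion test uses the normal approximation without continuity
correction, which reproduces the printed two-digit p for 53/80 (the
exact binomial gives ~0.003). BH-FDR is the standard step-up.
Replication requires presence (or an r² > 0.8 proxy; best r², ties by
distance) in the replication summary statistics, p below α/N (strict)
and, by default, direction consistency through the LD sign; variants
monomorphic in replication are unassessable. Allele-frequency divergence
uses the two-proportion z-test on allele counts with a >5-fold flag.

## Mendelian randomization (`pqtlkit.mr`)

Instruments are the conditionally independent variants per protein,
excluding configured pleiotropic regions. Harmonization flips outcome
effects on allele swaps, drops mismatched allele pairs, and (by default)
drops palindromic variants with MAF > 0.42. Tags are carried through the
sign of the LD correlation between alt-allele dosages. The Wald ratio
uses the first-order standard error se_out/|β_exp| (second-order terms
are not applied); instruments with |β_exp|/se < 2 raise a weak-instrument
warning. IVW is fixed-effect only — with so few instruments per protein,
heterogeneity-robust estimators (Egger and relatives) are deliberately
out of scope. Screening applies BH-FDR at 0.05 across pairs and flags
pairs whose positive causal estimate implies that genetically lowered
protein levels track lower disease risk.

## Polygenic scores (`pqtlkit.pgs`)

Scores follow clumping (r² 0.1, 1 Mb) + thresholding over a log-spaced
p-value grid from 1e-4 down to study-wide significance (a linear grid
with a 1e-10 step is degenerate near 1e-4; the log spacing is this
package's interpretation) crossed with three frequency rules (MAF ≥
0.05, ≥ 0.01, MAC ≥ 10). Missing dosages impute from discovery
frequencies; empty models at stringent thresholds are valid results.
Validation r² is the squared Pearson correlation with the prepared
phenotype in an independent cohort; repeated k-fold cross-validation
(default 3 × 5-fold with a 20% holdout) picks the best threshold/rule on
training folds and is byte-reproducible given a seed. Disease screens
fit logistic regressions per (protein score, phenotype) with covariates,
flagging Wald p below α/(n_proteins × n_eff,phenotypes) — the effective
phenotype count is an input, not recomputed — and excluding separated
fits. Model comparison uses the likelihood-ratio test on nested designs
plus DeLong's paired test with midrank (half-credit) tie handling.
Elastic-net selection standardizes scores, tunes λ per α by k-fold
cross-validated log-loss, takes the strongest λ within one standard
error of the minimum, and reports nonzero-coefficient scores and holdout
AUC per α; covariates enter the penalized design (the implementation
does not support unpenalized columns, which matters little once scores
are standardized).

## Problem sizes

Default experiment scales, chosen to exercise every code path with
stable statistics: cohorts of 250–1300 samples, pools of 300–2400
variants (the multiple-testing simulation uses ~20,000), panels of
8–25 proteins, 100k-draw SKAT-O null tables, 100-seed Monte Carlo
summaries. The acceptance script (`scripts/acceptance.py`) re-runs all
of them from scratch in a few minutes on one CPU.

## Known limitations

Single chromosome coordinate system (positions span block gaps rather
than true genetic maps); in-sample LD only (no external reference panel
option); fixed-effect IVW only; elastic-net penalizes covariates; the
combined-test simulation reuses one cohort realization per call; deep
SKAT-O tails rely on a conservative integration; the pedigree supports
full-sib pairs only (no extended families).
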