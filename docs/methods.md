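# Methods

This note documents the statistical models the package implements, the
defaults and why they were chosen, what the synthetic-data generators do and
do not emulate, and the numerical choices that affect results.

## Data model and conventions

All genomic spans are 1-based inclusive internally; BED input is converted
on read. Summary statistics carry per-SNP effect (β), SE, z, p, N and MAF;
z is derived from β/SE when absent and the two are cross-checked when both
are present. The LD reference is block-diagonal: correlation across blocks
is zero by construction, and a ridge of 10⁻³ is applied to block diagonals
before any inversion. The MHC exclusion interval defaults to
chr6:25,000,000–35,000,000 (configurable) — the region's extreme LD breaks
the approximations below.

Gene-body extension is strand-aware: "upstream" means 5′ of the coding
strand, so a minus-strand gene extends its high coordinate. The
conservative construct adds 5 kb upstream / 1.5 kb downstream; the liberal
one 35 kb / 10 kb. Boundaries are asymmetric because promoter-proximal
regulatory variation concentrates upstream. Extended intervals are closed.

The package is a library: the importable modules plus the narrative scripts
in `examples/` are its interface; no shell entry point is installed.

## LD-score regression

Per-variant LD scores ℓⱼ = Σₖ r²ⱼₖ within block. Heritability is the slope
of χ²ⱼ on N·ℓⱼ/M with a free intercept (absorbing uncontrolled inflation)
and heteroskedasticity weights 1/ℓⱼ, estimated in a single step. The
bivariate slope of z₁z₂ on √(N₁N₂)·ℓ/M is the genetic covariance, and
r_g = gcov/√(h²₁h²₂). Standard errors are delete-a-block jackknives over
200 contiguous blocks (the jackknife recomputes the full r_g ratio per
deletion). The full two-step iterative weighting of production LDSC
implementations is deliberately omitted: at the package's problem sizes the
single-step estimator recovers h² = 0.3 within ±0.05 and r_g = 0.5 within
±0.07 (mean over 50 replicates, M = 20,000, N = 50,000), which is the
validation standard used throughout. r_g of a trait with itself is exactly
1 by construction (identical regressions cancel). Estimates are clipped to
±1.25 with a flag, keeping estimator noise visible rather than silently
saturating at ±1.

A note on identifiability: with a free intercept the regression needs
spread in ℓⱼ. Panels whose blocks all share one AR(1) parameter have nearly
constant LD scores and produce unusable slope estimates; the synthetic
panel therefore draws each block's AR(1) strength from a range (default
U(0, 0.9) in the validation settings), mirroring the heterogeneity of real
genomes.

## Latent causal variable model

Two correlated traits are modelled as loading on a shared latent factor:
α̃₁ = q₁π + γ₁, α̃₂ = q₂π + γ₂ with Var(π) = 1 and excess kurtosis κ > 0.
Then E[α̃₁³α̃₂] − 3ρ = κρq₁² and E[α̃₁α̃₂³] − 3ρ = κρq₂², so the ratio R of
the excess moments gives GCP = −ln R/(2 ln |ρ|) with κ cancelling — the
estimator never needs the architecture's kurtosis, only that it is
non-Gaussian. A Gaussian architecture (κ = 0) is unidentifiable by
construction; the synthetic generator uses a spike-and-slab latent factor
precisely to supply κ > 0, and Gaussian-architecture simulations are a
designed failure case.

Estimation is by method of moments on observed z-scores. Independent-cohort
noise is removed exactly at third order (E[z₁³z₂] − 3E[z₁z₂] = E[a₁³a₂] for
unit-variance Gaussian noise) and at second order by subtracting 1 from
E[z²]. Per-SNP LD-score weighting of the fourth moments is not applied — a
deliberate simplification; recovery behaviour is the validation. The log of
the moment ratio is evaluated term-by-term so that swapping the traits
negates the estimate exactly in floating point. Guards: |ρ| < 0.05 or both
excess moments within 10⁻³ of zero raise an "unidentifiable" error; when
sampling noise flips one excess moment's sign (R ≤ 0), the estimate is set
to the ±1 boundary implied by the dominant moment. Standard errors are
100-block jackknives; GCP = 0 is tested two-sided against t(blocks − 1).
|GCP| > 0.6 flags partial causality; heritability Z < 7 on either trait
flags a potentially biased estimate.

## Mendelian randomisation

Instrument selection: greedy LD clumping at p < 5×10⁻⁸ and r² < 0.001
(window 250 kb — the clumping window is not a sensitive choice at this r²
threshold and is exposed as a parameter), palindromic (A/T, C/G) variants
removed, outcome effects harmonized to the exposure's effect alleles.

* **IVW**: weighted regression through the origin, weights 1/SE_y²;
  multiplicative random effects scale the SE by max(1, √(Q/(k−1))) — floored
  at 1 so the SE never drops below the fixed-effect value. Q is Cochran's
  heterogeneity statistic with k−1 df.
* **Weighted median**: Wald ratios with delta-method variances, cumulative
  standardized weights with midpoint interpolation at 0.5; SE by seeded
  parametric bootstrap (default 1000 draws) on (bx, by).
* **MR-Egger**: instruments oriented so bx > 0, WLS with intercept; t
  inference on k−2 df; residual SD floored at 1 (same random-effects
  convention as IVW).
* **Steiger**: per-instrument variance explained approximated as
  r² ≈ z²/(z² + n) (no allele frequencies needed — documented
  approximation), summed per trait; the difference of Fisher-transformed
  aggregate correlations gives the p-value.
* **Global pleiotropy test**: observed RSS uses leave-one-out slopes (each
  instrument compared with a fit excluding it); the null distribution
  simulates outcome effects under the full-sample fitted IVW slope with the
  reported SE_y noise (default 1000 simulations, add-one p). Simulating
  under the full fit rather than the leave-one-out means was chosen for
  calibration: the alternative showed mild anti-conservatism in
  Kolmogorov–Smirnov checks across master seeds. Only the global test is
  implemented; the outlier-correction (distortion) stage is out of scope.

Pre-harmonized instrument tables load through `IvSet.from_table`, so
published per-SNP effect tables can be re-analysed directly.

## Gene and gene-set association

Gene statistics combine the p-values of a gene's SNPs (only SNPs with
p < P_T enter; P_T = 1 is the all-SNPs model and keeps p = 1 rows) as
T = Σ −2 ln pⱼ with E[T] = 2k and Var[T] = 4k + 2Σᵢ<ⱼ cov(−2 ln pᵢ, −2 ln pⱼ),
matched to a scaled chi-square (c = Var/2E, f = 2E²/Var). The covariance
term uses the Kost–McDermott cubic **evaluated on r²**:
cov ≈ 3.263r² + 0.710r⁴ + 0.027r⁶. The classic cubic on |r| applies to
one-sided p-values; GWAS p-values are two-sided (functions of |z|), which
makes the covariance an even function of r close to 4r². Monte-Carlo
measurement (bivariate normal z, 4×10⁵ draws): at r = 0.7 the empirical
covariance is 1.94 against 2.64 from the |r| cubic and 1.77 from the r²
cubic; the r² form holds the 5% type-I error at 0.055 under an AR(1)
r = 0.7 null where the |r| form is conservative at 0.037. SNPs absent from
the LD panel are treated as independent with a warning.

Competitive gene-set association regresses probit gene Z-scores on set
membership with gene size, genic minor-allele count (Σ 2·N·MAF over the
gene's included SNPs) and their logs as confounders, one-sided for
enrichment. Exactly collinear confounder columns are dropped (tiny scans
can degenerate); membership is always retained. The multi-threshold scan
tests every (set, P_T, boundary) combination, applies Benjamini–Hochberg to
the pooled table (BH rather than Bonferroni because the same sets recur
across thresholds), and retains each set's most significant row; candidates
are q < 0.05.

## Pathway polygenic scores

A score definition restricts the summary statistics to common variants
(MAF > 0.01) inside the set's extended gene bodies with p below the set's
retained P_T, then LD-clumps (default r² < 0.1 within 250 kb, the
convention of standard PGS software; the same operation with no gene-body
restriction yields the genome-wide PGS). Scoring: raw_i = Σⱼ β̂ⱼGᵢⱼ over
non-missing dosages, divided by the per-individual count of non-missing
scored SNPs ("SNPs carried" is read as non-missing genotyped SNPs), then
standardized cohort-wide — standardization happens before any modelling.
Dosages coded on the other allele are flipped (d → 2−d), making scores
invariant to allele recoding up to an additive constant that
standardization removes.

Phenotypes for association are OLS residuals on covariates (sex, age, age²,
height, height², smoking and similar; the per-row maximum over repeated
spirometry attempts is supported) passed through the Blom inverse-rank
normal transform Φ⁻¹((rank − 3/8)/(n + ¼)) with average ranks for ties.
Association is OLS of the transformed phenotype on the score plus
covariates (plus the genome-wide PGS when adjusting), reporting ΔR²
against the same model without the score; a score collinear with the
adjustment PGS raises rather than silently double-counting. The
decile-depletion model is logistic regression of bottom-score-decile
membership (stable-sorted, ⌊n/10⌋ individuals) on the standardized
phenotype, reporting OR per phenotype SD; complete separation falls back to
an L2-penalised fit, flagged in the output. Drug-target
overrepresentation is an upper-tail hypergeometric per drug within a gene
universe (default: all scored genes), BH-corrected, reported only at
overlap ≥ 3.

## TWAS fine-mapping

The gene-level association statistic is Z = wᵀz/√(wᵀRw) for SNP weights w,
GWAS z-scores z and SNP LD R (ridge-regularised, renormalised to unit
diagonal). Fine-mapping enumerates causal configurations c with |c| ≤ 3
(guarded at 10⁶ configurations) over the locus's predicted-expression
correlation Ω: likelihood N(z; 0, Ω + nσ_c²·Ω[:,c]Ω[c,:]) — causal effects
propagate through the expression correlation — with an independent
Bernoulli(p) prior per causal indicator (defaults p = 10⁻³, nσ_c² = 40,
alternate conservative p = 10⁻⁵ under which every PIP weakly decreases).
The enumerated posterior is normalised to 1; PIPs are marginal sums, and
the null (empty) configuration carries its own posterior. This covariance
form is a documented choice validated by the Ω = I closed form
(PIP = pB/(pB + 1 − p), B the Gaussian Bayes factor), exact agreement with
brute-force 2^m enumeration for m ≤ 4, and coverage calibration.

The ρ-credible set (default ρ = 0.9) normalises gene PIPs together with the
null posterior, sorts descending (ties broken by gene order), and
accumulates until ≥ ρ. The genes accumulated are always listed; the null
model entering the set raises the `locus_excluded` flag, the signal that a
reporting pipeline should drop the locus. The set is not emptied when the
null ranks first: exclusion is a downstream filtering decision, and
emptying the set destroys the frequentist coverage of the credible sets
(measured 0.68 instead of 0.91 under the calibration design below).

Coverage calibration: 2000 loci of m = 10 genes, one causal gene with
effect variance 40, fine-mapped with the matched prior p = 1/m (Bayesian
coverage is only guaranteed when the analysis prior matches the generative
design; the 10⁻³ default encodes the much sparser expectation of a
transcriptome-wide screen, not of a locus pre-selected to contain a
signal). The causal gene falls in the 90% set in 91–92% of loci.
Per-tissue Bonferroni significance filtering and the confounder-trait
set-difference (e.g. removing genes also associated with smoking) are
provided as reporting utilities.

## Synthetic data

LD panels are AR(1) blocks (scalar or per-block-range correlation
strength); variants get synthetic rsIDs, positions 5 kb apart with 500 kb
between blocks, and a per-block MAF drawn from U(0.1, 0.5). MAF is shared
within a block deliberately: two SNPs in strong LD cannot hold discrepant
allele frequencies (the Fréchet bound caps the attainable dosage
correlation), and tight LD with matched frequencies is also the realistic
regime. Genotypes are two Gaussian-copula haplotypes thresholded at the
allele-frequency quantile; the latent correlation is calibrated per SNP
pair (tetrachoric inversion, cached) so the realized **dosage** correlation
matches the panel's r — realized correlations agree with targets within
0.05 at n = 5000.

Summary statistics are simulated at the z level — z = √N·Rβ + MVN(0, R)
per block, so E[χ²ⱼ] = N·h²·ℓⱼ/M + 1 — rather than via individual-level
GWAS, for speed; β is in per-standardized-genotype units and SE = 1/√N on
that scale. The trait-pair generator draws a shared spike-and-slab latent
factor (default 5% causal fraction) with loadings q₁ = |r_g|^((1−GCP)/2),
q₂ = |r_g|^((1+GCP)/2), making GCP the analytic ground truth
(q₁q₂ = |r_g| is asserted); GCP = 1 yields a fully causal exposure →
outcome pair whose genome-wide-significant instruments make a working MR
test bed at N = 200,000. Cohorts plant an exact phenotypic-variance
fraction inside a designated gene-set's gene bodies (default 1% — the scale
of pathway-score effects reported for spirometry), with optional polygenic
background, sex/age/height covariate effects (~10% of variance) and
Gaussian noise. TWAS loci draw causal effects λ ~ N(0, nσ_c²) and
z ~ MVN(Ωλ, Ω). Every generator is a pure function of (params, seed).

What the generators do **not** emulate: realistic allele-frequency spectra,
genome-scale M, population stratification, sample overlap between cohorts
(the LCV noise correction assumes independent cohorts), assortative mating,
or binary phenotypes. Passing recovery tests therefore demonstrates
estimator correctness under the stated models, not robustness to those
real-data complications.

## Problem sizes and determinism

Validation runs use M = 20,000 SNPs (400 blocks × 50) for LDSC/GCP, ~50
instruments for MR, 5-SNP genes at AR(1) r = 0.7 for the Brown oracle
(20,000 Monte-Carlo draws), 1000-gene scans for competitive calibration,
n = 5000 cohorts for pathway scores, and 1000–2000 loci for credible-set
coverage — sizes at which every stated tolerance is met while the whole
suite stays desk-scale. All stochastic components take explicit seeds;
`scripts/acceptance.py` derives every stream from a single `--seed` via
`numpy.random.SeedSequence`.

## Known limitations

* The LDSC estimator is single-step with 1/ℓ weights; intercepts are free
  but sample-overlap cross-trait intercept modelling is not implemented.
* The GCP estimator is a moment surrogate for the full latent-causal
  posterior machinery; its SEs are jackknife, not posterior, quantities.
* MR assumes a pre-harmonized two-sample design; multivariable MR and
  phenome-wide instrument lookups are out of scope.
* Brown's method uses a single aggregate statistic per gene (no top-SNP or
  mean-χ² hybrid components).
* Expression-weight training for TWAS is out of scope; loci enter as
  (Z, Ω) pairs.
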