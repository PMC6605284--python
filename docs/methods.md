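# Methods

This note documents the statistical models behind `pathprs`, the
parameters that matter, the synthetic-data generator's assumptions, and
the numerical choices made where the design was genuinely open.

## Summary-on-summary score association

Given discovery GWAS weights and target GWAS effects for the same SNPs,
the association of the weighted allele score with the target trait is
estimated without individual-level data. After harmonization every row
carries `(w, b, s)`: the discovery beta oriented so `w ≥ 0` (flipping
`w`, `b` and the allele frequency together when the discovery effect is
negative, so `w` is always the risk-allele weight), the target beta on
the same allele, and its SE. Over SNPs passing the discovery threshold:

    â = Σ w b / s²  ÷  Σ w² / s² ,   se = (Σ w² / s²)^(-1/2) ,   z = â/se

This is exactly weighted least squares of `b` on `w` through the origin
with weights `1/s²` and known unit dispersion; the tests verify
equality with a generic WLS solver to 1e-10. Its validity assumes the
scored SNPs are close to independent, which is why scoring always
follows clumping. Pseudo variance explained is defined through the
regression identity `R² = z²/(n − 2 + z²)` with `n` the target GWAS
sample size; `z²/n` is the familiar small-effect approximation. Field
reports of this quantity rarely state a formula, so the identity-based
definition is this package's choice. P-values are two-sided normal
throughout.

Harmonization details: inner join on SNP id; swapped or
reverse-complement allele pairs resolve with a sign flip;
strand-ambiguous palindromic SNPs (A/T, C/G) are dropped by default
because strand cannot be inferred from summary data — an optional
frequency-based rescue accepts them when both cohorts' frequencies are
at least 0.08 from 0.5 and orients by frequency concordance. Datasets
with different genome-build tags are a hard error (no liftover).

## Clumping

Greedy P-value-ordered clumping with the parameter set used for
stringent AD score construction (`p1 = p2 = 0.5`, 300 kb window,
`r² ≥ 0.05`), LD measured as squared Pearson correlation of additive
dosages in the reference panel. Ties in the discovery p-value break by
`(chrom, pos, snp_id)` so results are order-independent. The window is
index-to-candidate distance (|Δpos| ≤ 300 kb), the conventional
definition. SNPs absent from the panel are excluded from scoring
entirely: LD with their neighbours is unknown, so their independence
cannot be certified. A brute-force pairwise oracle reproduces the index
sets exactly in the tests.

## Region masks and filters

The MHC (chr6: 26.0–34.0 Mb) and the APOE region (chr19: 44.4–46.5 Mb)
are masked by default, as closed 1-based intervals — the sources quote
kb ranges only, so the boundary convention is ours and configurable.
MAF filtering keeps `min(eaf, 1−eaf) > 0.01` by default (common
variants only).

## Bilateral averaging

Left/right hemisphere GWAS of the same subjects are combined per SNP as
`β = (βL + βR)/2` with `se = sqrt(sL² + sR² + 2 ρ sL sR)/2`; ignoring ρ
would understate the noise because the two GWAS share subjects. ρ
defaults to the correlation of left/right Z-scores among SNPs null in
both hemispheres (p > 0.1), an estimate of the phenotypic correlation,
and can be overridden.

## Meta-analysis

Study-level estimates combine by inverse-variance fixed effects
(default, appropriate for two cohorts measuring the same quantity);
DerSimonian–Laird random effects is available since the upstream
tooling this mirrors defaults to a random-effects fit. SNP-level
meta-analysis before the gene stage first rescales each cohort to
standardized-trait units, `b* = z / sqrt(2f(1−f)(n + z²))`,
`s* = 1/sqrt(2f(1−f)(n + z²))` — cohorts publish in arbitrary units
(mm³ vs standardized volumes), and inverse-variance pooling of raw
mixed-unit betas is not meaningful.

## Competitive permutation null

The pathway score's R² is compared with scores from random SNP sets
drawn from the clumped, thresholded pool, matched on set size and on
discovery significance: the pool is cut into `match_bins = 10` quantile
strata of the discovery p-value and each draw reproduces the observed
set's stratum profile exactly, sampling without replacement within a
draw. The matching scheme is our operationalization of
"size- and significance-matched" sampling; the binning is a package choice.
"Surpass" counts null R² ≥ observed (ties count against enrichment).
Both the plug-in `k/B` (which can be 0, not a valid p-value) and the add-one estimator
`(k+1)/(B+1)` are always reported; calibration tests use the latter.
`B = 1000` by default. The full null vector is written out and is
reproducible from the seed.

## Gene and gene-set statistics

Per gene (SNPs mapped with a strand-aware 35 kb upstream / 10 kb
downstream window; protein-coding genes only), the statistic is
`T = Σ χ²₁(pᵢ)` — the SNP-wise mean model up to the constant `1/m`,
which leaves p-values unchanged. Under the null `T ~ Σ λⱼ χ²₁` with λ
the eigenvalues of the SNP dosage correlation matrix (signed r) from
the panel. Tail probabilities come from Imhof's characteristic-function
inversion, evaluated on a composite Gauss–Legendre grid with panels at
most half an oscillation wide and truncation chosen from the
alternating-tail bound; absolute accuracy is ~1e-6, verified against
adaptive quadrature and Monte Carlo. Equal spectra (single SNPs,
identity correlation) reduce analytically to a scaled central χ²; when
inversion leaves the reliable range (p below ~1e-6, or degenerate
grids) the Satterthwaite moment match (scale `Σλ²/Σλ`, df `(Σλ)²/Σλ²`)
takes over and is flagged per gene. Rank-deficient correlation matrices
(long genes, finite panels) are handled by flooring eigenvalues at 1e-6
of the leading one and rescaling the spectrum to restore the exact
trace m. Genes with no usable SNP are excluded and reported, mirroring
published exclusions for missing SNP data.

The competitive gene-set test regresses `z_gene = Φ⁻¹(1 − p_gene)` on
the 0/1 set-membership indicator with intercept and nuisance covariates
{SNP count, log SNP count, gene length kb, log length} — the exact
transform set behind "corrected for gene size and SNP density" is
not standardized across tools, so both raw and log terms are included
and configurable.
The reported p is the two-sided t-test on the membership coefficient.

## Synthetic studies

The generator emulates the statistical structure of the motivating
analysis: a large discovery GWAS (effective n = 50,000 for a
case/control study approximated as a continuous-liability GWAS — the
pipeline consumes betas and SEs identically), two target cohorts of
13,163 and 9,707, and a 56-gene set among 1,000 genes.

* Genotypes: SNPs in 200 equicorrelated blocks of 100 (latent Gaussian
  correlation 0.8 within a block, independence across), dosage = two
  thresholded haplotype draws at each SNP's MAF ~ U(0.05, 0.5); panel
  of 500 individuals (1000-Genomes-phase-3-like). Blocks are laid
  round-robin over 22 chromosomes at 3 kb SNP spacing.
* Genes tile the blocks (≈5 per block, lengths U(10, 100) kb, random
  strand); set genes are sampled uniformly.
* Effects: 5% of SNPs causal; per-SNP (β_disc, β_targ) bivariate normal
  with variances `h²/(m_causal · 2f(1−f))` (h² = 0.3 per trait) and
  correlation 0.1 outside the set, `min(1, 0.1 × enrichment_factor)`
  inside (default factor 5).
* Summary statistics: marginal effects are LD-smeared through the
  realized block correlation (`Rβ`), with independent sampling noise of
  SE `1/sqrt(n · 2f(1−f))` scaled by the cohort's trait units; a
  fraction of rows is emitted on the opposite allele to exercise
  harmonization.

What this does **not** emulate: realistic LD decay (blocks are
exchangeable inside, so clumping collapses each block to about one
index SNP), allele-frequency spectra, population stratification, sample
overlap, or binary-trait ascertainment. Consequences worth knowing
when reading the test results: (i) a 20,000-SNP genome holds only ~200
independent loci after clumping, so pathway scores contain ~10–15 SNPs
and the permutation test has limited power even at five-fold covariance
enrichment — the calibration (type-I error) results are the informative
ones at this scale; (ii) because enrichment scales only the cross-trait
*correlation* while target effect variances are equal inside and
outside the set, the target GWAS alone carries no per-gene signal
difference, so the gene-set regression is expected to be null-behaved
on these simulations — its correctness is established by its exactness
against a generic least-squares oracle and its type-I calibration, not
by sign recovery. Passing tests therefore demonstrate estimator
correctness and calibration, not field-realistic power.

## Problem sizes used in the tests

Unit tests run on 1,000–2,000-SNP genomes with 100–250 panel samples.
The calibration experiments use 500 replicates of a 1,000-SNP study
(permutation type-I, with the observed set itself drawn by the matched
sampler — the exchangeable null), 500 replicates of a 500-gene
regression, and one 20,000-SNP null GWAS for p-value uniformity. The
enrichment-recovery experiment runs the full pipeline 50 times per
condition at the default (20,000 SNP) configuration. The acceptance
script performs one complete default-scale analysis per seed.

## Known limitations

* LD is genotype (dosage) r² from an unphased panel; no haplotype r²,
  no covariance shrinkage.
* The quadratic-form inversion is absolute-accuracy limited (~1e-6);
  extreme gene p-values are moment-matched approximations.
* No liftover, no imputation of missing summary statistics, no
  individual-level scoring.
* The permutation null draws independent sets; it does not implement a
  circular genomic rotation variant.
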