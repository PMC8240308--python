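# Methods

## Scope and model

The package evaluates shared genetic aetiology between two binary traits
from two directions: (i) a polygenic-score gradient — does a weighted sum
of trait-1 risk alleles predict trait-2 case status? — and (ii) two-sample
Mendelian randomization — do trait-1's strongest individual variants shift
trait-2 risk in proportion to their trait-1 effects, as a causal effect of
liability would require? A positive PRS association with a null MR suite
is the signature of diffuse shared polygenic influences rather than a
causal liability-to-disease pathway, and the synthetic-data generator can
produce exactly that configuration (many small correlated effects, no
causal coupling between traits).

## Polygenic scoring

Discovery summary statistics are filtered at each inclusion threshold of
the fixed 11-point ladder (1e-6, 5e-6, 1e-5, 5e-5, 1e-4, 5e-4, 1e-3,
5e-3, 1e-2, 5e-2, 1e-1), then LD-clumped: candidates are visited in
ascending p-value (ties broken by chromosome, position, SNP id for
determinism); each surviving candidate becomes an index SNP and absorbs
all not-yet-absorbed SNPs on the same chromosome within ±250 kb
(inclusive) whose squared dosage correlation in the reference panel is
≥ 0.1. Thresholding precedes clumping for each score (the alternative
order is available behind a flag); SNPs absent from the reference panel
are excluded rather than kept unclumped, trading a little power for no
double-counted LD. r² uses pairwise-complete observations and returns 0
for monomorphic vectors.

The raw score is the dosage-weighted sum of clumped betas, with weight
alleles oriented to the genotype panel's counted allele (strand
complements resolved; palindromic weights dropped, since dosage panels
carry no frequency to disambiguate strand). Missing dosages are imputed
as 2·eaf when the weight table carries a frequency, otherwise the SNP is
dropped. Scores are standardized with the sample SD (n−1) over the full
analysis sample, so association effects are per 1 SD of score. Dosage
centering is deliberately omitted from the raw score: it is absorbed by
standardization (verified by an affine-invariance test).

## Association and meta-analysis

Logistic regression is fit by iteratively reweighted least squares with
step-halving on likelihood decrease, convergence at max |Δcoef| < 1e-8
(≤ 100 iterations), standard errors from the inverse observed
information. The fit is authored in-package — it is part of the surface
under test — and is cross-checked in the suite against both a long-double
gradient-ascent oracle and an established implementation. Perfect
separation is detected heuristically (coefficient infinity-norm > 50 on
standardized inputs) and raised as an error naming the offending column;
this is adequate at the sample sizes targeted and documented as a
limitation. Continuous outcomes (e.g. alcohol units/week, smoking
pack-years) use OLS with homoskedastic standard errors. Subtype analyses
restrict cases to one subtype while reusing the full control set.

Cohorts are pooled by fixed-effects inverse-variance meta-analysis on the
log-odds scale. When only a printed OR (95% CI) is available, the standard
error is reconstructed as (ln U − ln L)/(2·z₀.₉₇₅) with the normal
quantile computed, not hard-coded, so arbitrary levels work. Pooling the
printed per-cohort estimates 1.09 (1.04, 1.13) and 1.02 (0.95, 1.10)
yields 1.07 (1.03, 1.11) at two-decimal rounding; the pooled p-value is
not targeted because printed inputs are already rounded.

## Mendelian randomization

All estimators operate on Wald ratios β_Yj/β_Xj with first-order standard
errors σ_Yj/|β_Xj| (NOME: exposure uncertainty neglected, defensible for
genome-wide-significant instruments and stated as an assumption). IVW is
the fixed-effect weighted mean — algebraically the WLS slope through the
origin with weights σ_Y⁻², an identity asserted to 1e-10 in tests. A
multiplicative-overdispersion variant exists behind the Egger machinery
but fixed-effect IVW is primary, matching the few-instrument setting.
MR-Egger adds an intercept after orienting exposure betas non-negative;
its standard errors carry max(1, √(RSS_w/(J−2))) and p-values use
t(J−2). The weighted median interpolates the inverse-variance-weighted
cumulative distribution of ratios at 0.5 (midpoint convention, so equal
weights with odd J reduce to the plain median); the weighted mode
maximizes a weighted Gaussian-kernel density with Silverman-style
bandwidth φ·0.9·min(SD, IQR/1.349)·J^(−1/5), grid search plus
golden-section refinement, φ defaulting to 1. Median and mode standard
errors come from a parametric bootstrap (default 1,000 draws, seed
mandatory in the CLI). Cochran's Q uses first-order weights with a
χ²(J−1) reference. Harmonization aligns outcome records to the exposure's
effect allele — swap ⇒ sign flip, strand complement resolved first;
palindromic SNPs are oriented by allele frequency when both minor-allele
frequencies are below 0.42 (the conventional informativeness cutoff) and
dropped otherwise, or dropped wholesale under the `drop_all` policy.

## Synthetic data

Genotypes: haplotype alleles within a block follow a Gaussian copula with
exchangeable latent correlation `ld_rho`, thresholded at Φ⁻¹(p_j), so
marginal frequencies are exact by construction and block LD is tunable;
blocks are independent. This was chosen over coalescent simulation for
closed-form control and speed; it does not reproduce recombination-map
realism, allele-frequency/LD coupling, or population structure beyond an
optional covariate-confounding weight, so passing tests demonstrate
statistical correctness of the pipeline, not robustness to those
real-data features.

Effects: a shared causal subset (fraction `causal_fraction`) receives
bivariate-normal effect pairs with correlation ρ_g and per-SNP variance
h²/(n_causal·2p_j(1−p_j)) on the allele-count scale, then a per-trait
rescaling makes Σ b_j²·2p_j(1−p_j) equal h² exactly (LD between causal
SNPs is ignored at this step, standard practice in forward simulators).
Liability is the centered genetic value plus a Gaussian residual whose
variance is set from a Monte-Carlo estimate of the genetic variance on a
population batch of 4,000, so realized heritability is respected even
under LD. Cases exceed Φ⁻¹(1−K); quotas are filled by rejection sampling
(exact, affordable at desk scale; prevalences implying acceptance below
1e-6 are refused). Discovery summary statistics add sampling noise with
the standard GWAS standard error 1/√(2·n_eff·p_j(1−p_j)).

A note on the calibration null: with ρ_g = 0 but both traits heritable,
the two finite effect vectors overlap by chance (correlation of order
1/√n_causal), which induces genuine per-replicate score-outcome
associations and inflates the marginal rejection rate well above α at
desk-scale polygenicity (measured at roughly 0.1-0.3 with 100 causal
SNPs). Type-I-error calibration therefore uses the exact
no-shared-genetics null h²_trait2 = 0; the ρ_g = 0 heritable
configuration remains available for studying that chance-overlap
phenomenon itself.

## Frozen study conditions in the test suite

Power/calibration tests and the acceptance script use: M = 200 SNPs in
blocks of 10 with `ld_rho` 0.3, causal fraction 0.5, h² = 0.5 per trait,
ρ_g = 0.7 (shared arm) or h²_trait2 = 0 (null arm), trait-2 prevalence
0.25, discovery n_eff = 20,000, target 400 cases / 400 controls,
reference panel 300, 25-60 replicates per arm; MR recovery uses J = 6
instruments at n_eff = 50,000 with a true ratio of 0.3, and robustness
uses 10 instruments with 3 carrying large directional pleiotropy. These
sizes give high power for the effects simulated while keeping each suite
run to seconds; larger replications only tighten the same comparisons.
All randomness flows from one integer seed through NumPy `SeedSequence`
spawning.

## Numerical and edge-case conventions

Positions are 1-based (VCF convention) throughout. Summary-statistic
loading drops rows whose p-value disagrees with the two-sided normal test
of β/σ by more than 10% relative tolerance (disable for files with
rounded p-values). Degenerate cases are errors, not silent results: zero
score variance, zero instrument exposure effect (named SNP), fewer than 3
instruments for Egger, non-positive standard errors, CI bounds out of
order. Zero-variance dosage vectors give r² = 0; identical Wald ratios
give Q = 0 and a zero-bandwidth mode that returns the common ratio.
Display TSVs round half-even at two decimals; `.full.tsv` twins retain
full precision.

## Known limitations

No genome-build liftover, no imputation uncertainty, no X chromosome, no
relatedness or mixed models, no Firth correction, no random-effects
meta-analysis, no bidirectional MR, no MR-PRESSO/Steiger variants. The
separation heuristic can miss quasi-separation on unstandardized
covariates. The copula LD model understates long-range LD; clumping
results on real panels will differ accordingly.
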