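# Methods

## Model and data structures

The package works entirely at the summary level. A study is a pair of GWAS
summary-statistic tables: an exposure table (systolic blood pressure, SBP)
and one or more outcome tables (binary disease outcomes on the log-odds
scale, or a linear-scale table plus case/control counts). For SNP *i*,
γ̂ᵢ ± se(γ̂ᵢ) is the per-allele exposure effect and Γ̂ᵢ ± se(Γ̂ᵢ) the
per-allele outcome effect; the instrumental-variable assumptions make the
Wald ratio Γᵢ/γᵢ identify the causal effect θ of the exposure on the
outcome. Drug-target MR restricts instruments to variants near the genes
encoding a drug class's protein targets, so θ is interpreted as the effect
of pharmacological modulation of that target, expressed per unit SBP
*reduction* in reports.

Exposure effects are kept in the units of a variance-standardized trait:
the generator's sampling SE for a quantitative trait is
se = 1/√(2·maf·(1−maf)·n), which is exact for a unit-variance phenotype.
One unit therefore corresponds to one phenotypic SD of SBP (≈ 19 mmHg in
adult populations); per-mmHg effects are this package's per-SD effects
divided by that SD. All coordinates are 1-based inclusive; alleles are
single nucleotides (indels are rejected at parse time with a named error).

## Instrument selection

Selection order is fixed: gene window → significance → LD clumping →
F filter → proxy resolution. Choices worth noting:

- The ±100 kb window is anchored on gene boundaries (not the TSS); the
  window width is a parameter (`window_bp`).
- The genome-wide threshold is strict (p < 5×10⁻⁸; equality drops).
- Clumping is greedy on ascending p-value (ties broken by genomic
  position, making selection deterministic and row-order invariant) and
  removes candidates against **all** kept SNPs, so survivors are mutually
  independent at r² < 0.1 — stricter than index-variant-only clumping.
  A pair absent from the LD table is treated as r² = 0 and logged, since
  real LD references are sparse.
- F is computed as the squared Wald z, (β/se)²; it requires no
  variance-explained or sample-size assumptions. The alternative
  F = (n−2)R²/(1−R²) is available behind `use_r2_form`.
- A proxy (r² > 0.8, highest r² first) substitutes an instrument missing
  from the outcome study only when the LD table carries a correlated-allele
  map covering the instrument's alleles; phase is never guessed. The
  exposure association is carried over to the proxy's identifier and
  alleles. Every input SNP receives exactly one terminal fate in the
  selection log.

## Harmonization

Outcome records are rewritten onto the exposure's effect-allele convention:
same pair/same orientation (aligned); same pair swapped (negate Γ̂, flip
EAF); complementary-strand pair for non-palindromic SNPs (complement, then
align). Palindromic SNPs (A/T, C/G) have no strand information in their
alleles: if min(EAF, 1−EAF) > 0.42 in **either** study (conservative
both-study rule; the convention fixes only the threshold) — or if either
frequency is missing — the SNP is dropped; otherwise alignment is inferred
from whether the two frequencies fall on the same side of 0.5. Drop
decisions depend only on alleles and frequencies, never on effect sizes.

## Estimators

- **IVW.** Ratio form with first-order delta SEs, algebraically identical
  to WLS of Γ̂ on γ̂ through the origin with weights 1/se(Γ̂)² (both forms
  implemented; cross-checked to 1e-10 in tests). A second-order delta SE is
  available behind a flag. Cochran's Q = Σwᵢ(rᵢ−θ̂)², I² = max(0,(Q−df)/Q).
  Multiplicative random effects scale the SE by max(1, √(Q/(k−1))) —
  underdispersion never shrinks an SE. `model="auto"` selects random
  effects exactly when Q's p < 0.05. Normal inference.
- **MR-Egger.** SNPs are oriented to γ̂ᵢ ≥ 0 first (the fit is otherwise
  not invariant to allele coding). Weighted regression with intercept;
  SEs use the same dispersion floor (max(1, √(residual MSE))) applied to
  the fixed-effect covariance; t(k−2) inference for slope and intercept.
- **Weighted median.** Ordered ratios interpolated at standardized
  cumulative weight 0.5 (scale-invariant in the weights); SE from a
  parametric bootstrap (ratios re-drawn at their own SEs, weights fixed,
  1000 draws, mandatory seed).
- **MR-PRESSO.** Residuals are taken about leave-one-out IVW slopes;
  the observed weighted RSS is compared with its simulated null
  (outcome betas re-drawn about the LOO fits; exposure betas also re-drawn
  by default, flag-controlled). Per-SNP simulation p-values are
  Bonferroni-flagged at α/k; the distortion test compares the
  outlier-driven shift in θ̂ against removing random non-outlier subsets of
  the same size. All simulation p-values use add-one smoothing, so none
  can be exactly 0. Inputs are canonicalized (γ̂ ≥ 0, SNPs sorted by id)
  before simulation so the p-values are exactly invariant to row order and
  joint allele flips. Agreement with the reference algorithm is
  statistical, not bitwise.
- **Reporting.** Estimation runs per unit SBP increase; reporting negates
  exactly once: OR per reduction = exp(−θ̂) with 95% CI
  exp(−θ̂ ± 1.96·se). The 1.96 quantile is used verbatim — it reproduces
  published drug-target MR confidence bounds to the printed precision.
  The Bonferroni tier divides α = 0.05 by the number of drug classes
  (9 by default, not class × cohort pairs): significant below 0.0056,
  suggestive below 0.05, strict boundaries.

## Pipeline conventions

The positive-control gate requires a protective effect in the SBP-lowering
direction on CAD (θ per increase > 0 and p < 0.05 after harmonization
against the control table). Because published analyses state the gate as an
exclusion rule but in practice retain a failing class with a caveat, the
default `gate_policy="warn"` retains failing classes prominently flagged;
`"exclude"` drops them — these are the only two behaviors. A class whose
instruments vanish during selection is reported `not_estimable` and the
study run continues. Per-class random streams derive from the master seed
plus a CRC32 hash of the class/cohort name, so adding a class never
perturbs another's results; a fixed config and seed reproduce reports
byte-identically.

The cis-eQTL secondary analysis reuses the same harmonization and IVW
machinery with expression as the exposure: stage 1 confirms each gene's
eQTLs shift SBP in the expected direction (positive expression→SBP
estimate ⇒ reduced expression lowers SBP); stage 2 estimates the outcome
effect per unit *lower* expression. The synthetic eQTL layer is
tissue-agnostic.

## The synthetic generator

`synthetic.simulate_exposure/simulate_outcome` emulate the statistical
structure of the real inputs without any genotype data: per-SNP true
effects γᵢ ~ N(γ̄, σ_γ²) inside each gene window (null decoys outside),
observed with the closed-form sampling SE above; outcome effects
Γᵢ = θγᵢ + αᵢ + outlier shift, with αᵢ ~ N(pleiotropy mean, sd²) and
case-control SE 1/√(2·maf(1−maf)·n·μ(1−μ)). Exposure and outcome noise are
independent (two-sample, non-overlapping cohorts). Default sample sizes
mirror the real study: exposure n = 757,601; a biobank-style caries cohort
(2,110/359,084, generated on the linear scale and converted through the
μ(1−μ) transform — the standard conversion for linear-model binary-trait
GWAS, adopted here as the natural reading of "standardized
transformation"); a registry-style cohort (4,170/195,395); a CAD-scale
control (122,733/424,528). The default causal effect θ = 1.3 per SD
(≈ 0.07 per mmHg) and γ̄ = 0.015 ± 0.006 produce per-class instrument
counts (≈ 8–27) and F statistics (tens to a few hundred) in the ranges a
real drug-target SBP analysis reports, with the same qualitative power
profile (multi-gene classes significant in the registry cohort, weaker in
the low-prevalence biobank cohort).

LD is block-constant: blocks of consecutive within-region SNPs share one
pairwise r² (default 0.3 > the 0.1 clumping threshold, so clumping keeps
one SNP per block); there is no distance decay, which is sufficient to
exercise clumping and proxy logic but does not emulate realistic haplotype
structure. Reporting-convention perturbations (allele swaps, strand flips,
near-0.5 palindromic SNPs, proxy-only outcome SNPs) are planted with
recorded truth so harmonization can be scored exactly. The generator does
not model realistic MAF spectra, imputation quality, sample overlap, or
genome builds — so passing tests demonstrate correctness of the statistical
machinery under the stated model, not robustness to those real-data
features.

All randomness flows from one mandatory seed through
`numpy.random.SeedSequence`; each cohort derives its stream from a stable
hash of its name.

## Calibration studies

`calibration.py` measures operating characteristics over independent
replicate studies. The standard conditions are k = 50 strong instruments
with γ ~ N(0.05, 0.015²): the γ spread is ~70× the exposure sampling
variance, so F sits in the hundreds and neither regression dilution nor
weak-instrument bias contaminates the measurements — bias and coverage
then isolate the estimator itself. (With γ spread comparable to the
exposure noise, the Egger intercept absorbs slope dilution of order
θ·γ̄·se_exp²/Var(γ), which is a property of the design, not the
estimator.) Under these conditions the suite verifies: IVW bias below
0.1·|θ| with 95% CI coverage in [0.93, 0.97]; type-I error 0.05 ± 0.02
with Q matching χ²(k−1) (KS); Egger intercept centred on the simulated
directional pleiotropy with >50% power and ~5% type-I under balanced
pleiotropy (mafs drawn from a narrow band so the weighted regression is
correctly specified); and ≥95% MR-PRESSO detection of a single 10-SE
outlier among 20 SNPs. The replicate counts (500/1000/200/100) keep the
whole suite to about a minute on one core while holding Monte-Carlo error
comfortably below the acceptance margins.

## Known limitations

- First-order Wald SEs understate uncertainty for weak instruments; the
  F ≥ 10 filter is the guard, and the second-order option exists for
  sensitivity checks.
- The MR-PRESSO distortion test's null resamples observed non-outlier
  SNPs, so with very few SNPs its p-value is coarse.
- The weighted-median bootstrap resamples ratios (not the underlying
  betas), which is accurate for strong instruments.
- No multivariable MR, mode-based estimators, Steiger filtering, or
  sample-overlap correction; no genotype-level processing; LD handling is
  restricted to the supplied pairwise table.
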