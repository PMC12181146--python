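# Methods

## The interaction model

For each variant with additive effect-allele dosage g ∈ [0, 2] and each
continuous trait y, the package fits by ordinary least squares

y = β₀ + β_G·g + β_age·age + β_int·(g·age) + β_sex·sex + Σₖ γₖ·PCₖ + ε,

with age in years (uncentered by default, so β_int is in trait units
per allele per year), sex coded 0 = male / 1 = female, and ten
principal-component covariates to absorb population stratification.
β_int is tested two-sided with a Wald statistic against a t reference
with residual degrees of freedom — indistinguishable from the normal
reference at biobank n, exact at the small n used in tests. The
marginal (conventional GWAS) model drops the product term and tests
β_G. All five risk factors are treated as Gaussian; triglycerides are
analysed on the natural-log scale, so β is a log fold-change per allele
and exp(β) a multiplicative effect.

Standard errors are model-based by default; a heteroscedasticity-robust
HC0 sandwich is available behind `se_type="robust"`. Which flavour a
given published scan used is often unreported, so both are provided and
the choice is recorded in output headers.

The interaction coefficient, its SE and p-value are invariant to
replacing age by age − c for any constant c; this is asserted in tests
for c ∈ {0, 58}.

### Fast path

The scan fits thousands of variants against a shared covariate block
C = [1, age, sex, PC₁..PC₁₀]. C is QR-factorised once; for each variant
the two columns (g, g·age) are residualised against C and a 2×2 system
is solved (Frisch–Waugh–Lovell). The full-model coefficient and
standard error of the age term are recovered through the
partitioned-inverse identities, so the fast path is *algebraically
identical* to the per-variant solve — equality to relative 1e-10 is a
tested contract against both the per-variant path and an independent
dense normal-equation solve. Monomorphic variants are flagged per row
rather than aborting a block. Missing dosages are mean-imputed per
variant (standard for imputed genotype data; a drop option exists);
missing trait values are handled by per-trait complete-case
restriction in the scan.

## Phenotype preprocessing

Stage order (configurable, default as listed):

1. average duplicate SBP readings;
2. medication corrections — statin users' measured LDL-C is divided by
   0.7, and 10 mmHg is added to treated individuals' mean SBP; ApoB and
   TG are deliberately left uncorrected in statin users;
3. natural-log transform of TG;
4. winsorization at k = 6 SDs per trait on the analysis scale: mean and
   SD are computed once on all non-missing values, and values outside
   m ± 6s are set exactly to the nearer bound (one pass, so re-clipping
   against the original bounds is a no-op);
5. complete-case filter on the five analysis traits.

Correction-before-winsorization is the default so that the +10 mmHg
shift cannot carry values past a clip bound computed on the uncorrected
distribution; whether published cohorts winsorized before or after
correcting is generally unstated, so the reverse order is supported via
`PrepConfig(winsorize_before_correction=True)`. Likewise the 6-SD rule
is applied to log-TG (the analysis scale) by default. Quantiles in
cohort summaries use linear interpolation between order statistics.
Age-group bins are [40, 50), [50, 60) and [60, 70] — the top bin is
closed so age 70 has a defined home.

A double application of the medication correction is a state error, not
a silent bias: tables carry a raw/preprocessed marker.

## Multiple testing and lead selection

The per-trait genome-wide interaction threshold is α/n_traits
(5×10⁻⁸/5 = 10⁻⁸). Variants with minor-allele frequency strictly below
0.001 are removed before fitting; the boundary value is kept, reading
the rule as "below the cutoff". LD clumping is greedy: rows significant
at the seeding threshold are ranked by ascending p (ties: larger |β|,
then position), the best remaining row becomes a lead and absorbs every
remaining row with r² ≥ 0.1 against it; retained leads are therefore
mutually below r² 0.1, which is asserted on every run. r² is the
squared Pearson correlation of dosage vectors, computed in-sample by
default (an external panel can be supplied as a precomputed matrix; a
variant absent from the LD source is treated as independent with a
logged warning). No physical-distance window limits clump membership by
default. Positional gene mapping annotates every gene within 10 kb,
inclusive at exactly 10 kb; BED input (0-based half-open) is converted
at the boundary to the internal 1-based inclusive convention.

The look-up stage clumps the *marginal* scan at p < 5×10⁻⁸, then tests
each trait's leads for interaction at 0.05 divided by that trait's lead
count — thresholds are monotone decreasing in the number of leads by
construction.

## Stratified estimation

Within each age bin, the trait is regressed on genotype — additive
dosage, or two indicator contrasts (heterozygote and effect-allele
homozygote vs the non-effect homozygote) — adjusting for sex (omitted
in sex-stratified fits) and the ten PCs. Genotype contrasts require
hard calls; fractional dosages are rounded at 0.5 with the rounded
count logged. CIs are Wald with the normal quantile; for log-scale
traits the contrast is also reported as exp(β) with a two-decimal
"x.xx-fold (95% CI a.aa, b.bb)" rendering, and the implicit reference
category's fold change is exactly 1. An empty genotype category marks
only that contrast unavailable. Under a purely additive truth the
homozygote contrast is twice the heterozygote contrast; with β_G > 0
and β_int < 0 the per-bin contrast β_G + β_int·(mean bin age − c)
decreases strictly across bins — both are regression tests.

## The synthetic cohort generator

The generator is the package's substitute for access-controlled biobank
data, and its defaults are fixed study conditions, not tuning knobs.

* **Genotypes.** Hard calls {0, 1, 2} drawn from Hardy–Weinberg
  proportions (1−p)², 2p(1−p), p² by thresholding a latent standard
  normal at the HWE cumulative cut points. Within an LD block, adjacent
  latents follow a first-order Gaussian-copula chain with parameter
  ρ ∈ [0, 1): the simplest structure with exact HWE marginals and a
  tunable, monotone r² decay (tested over ρ ∈ {0, 0.3, 0.6, 0.9}).
  `maf = 0` is rejected — a monomorphic "variant" is a degenerate spec.
  An optional beta-distributed dosage perturbation emulates imputation
  uncertainty.
* **Phenotypes.** trait = intercept + age_slope·age + sex_effect·male
  + Σ_v (β_G,v + β_int,v·(age − c))·g_v + PC effects + N(0, σ²), with TG
  built on the log scale then exponentiated. The centering constant c
  defaults to 0 (β_G defined at age 0) with an option to centre at the
  cohort mean; β_int is invariant to c, and c is recorded in the truth
  table so recovery tests are well posed. Intercepts, slopes and SDs
  default to values giving cohort margins typical of a middle-aged
  European biobank (overall means near ApoB 1.03 g/L, LDL-C 3.6 mmol/L,
  TG median ≈ 1.5 mmol/L, SBP 138 mmHg, BMI 27 kg/m²; ages uniform on
  40–70; 54.2% female).
* **Medication.** Assignment is logistic in age and the *untreated*
  trait value, reproducing the steep age gradient of treated fractions
  (a few percent of statin users in the forties rising to roughly a
  quarter in the sixties) without copying any cohort's exact numbers —
  the true joint distribution of treatment and phenotype is not
  publicly characterised, so this is a stand-in, not an estimate.
  Statin users' *measured* LDL-C is the untreated value × 0.7;
  treated SBP is the untreated value − 10 mmHg. These are the exact
  inverses of the preprocessing corrections, so the round trip
  (simulate → correct) restores untreated values to machine precision —
  a tested invariant. Missingness is applied last.
* **What it does not emulate.** Realistic human LD maps, relatedness,
  genuine population structure (PCs are simulated standard-normal
  columns, not computed from genotypes), non-Gaussian trait noise,
  assortative mating, or selection. Passing tests therefore demonstrate
  the correctness and calibration of the statistical machinery under
  the stated generative model, not robustness to every feature of real
  cohort data.

All randomness flows through one seeded generator (phenotype noise uses
a child stream so it cannot rewind genotype draws); identical specs
give byte-identical outputs, and the full pipeline is tested to be
byte-deterministic given a seed.

## Validation summary

The test suite checks, among others: HWE goodness of fit across 1,000
simulated variants; exact coefficient recovery on noise-free data;
equality of the engine with independent normal-equation and statsmodels
fits (model-based and HC0); uniformity of null marginal p-values (KS);
type-I error of the interaction test within [0.04, 0.06] at nominal
0.05 across 5,000 null variants at n = 2,000; 95% CI coverage within
[0.92, 0.98] and no detectable bias across 200 causal variants with
β_int ∈ [−0.002, 0.002] at n = 20,000 (the magnitude range of reported
biobank interaction effects); greedy clumping against an exhaustive
pairwise-constraint oracle on simulated 200-variant LD blocks; and the
age-attenuation signature in stratified contrasts. Problem sizes are
desk scale by design — the scan is correct and streaming-structured at
thousands of variants rather than engineered for the ~10⁸ of a real
genome-wide run.

## Known limitations

* Continuous traits only (OLS); no binary-trait GLMs, mixed models or
  relatedness correction.
* In-sample LD rather than an external reference panel by default.
* Medication corrections are the standard global constants; dose- and
  type-specific corrections are out of scope.
* The robust-SE option uses the per-variant path; the block fast path
  is model-based.
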