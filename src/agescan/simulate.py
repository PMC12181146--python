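"""Synthetic biobank cohort generator with known genetic architecture.

Emulates a cohort of unrelated middle-aged adults (default ages 40-70)
carrying five cardiometabolic risk factors — ApoB (g/L), LDL-C (mmol/L),
TG (mmol/L), SBP (mmHg) and BMI (kg/m²) — with:

* Hardy–Weinberg hard-call genotypes, optionally correlated within LD
  blocks through a first-order Gaussian-copula chain;
* per-variant genetic main effects and SNP-by-age interaction effects;
* linear age and sex effects plus Gaussian noise per trait, TG generated
  on the natural-log scale and exponentiated to mmol/L;
* medication use that masks the measured phenotype: statin users' measured
  LDL-C is the untreated value times a multiplicative effect, and
  antihypertensive users' measured SBP is the untreated value minus an
  additive effect — the exact inverses of the downstream preprocessing
  corrections;
* optional per-trait missingness, applied last.

The generator returns a :class:`TruthTable` holding every variant's true
per-trait main effect and interaction effect together with the age-centering
constant of the generative model, so parameter-recovery tests are well
posed.  All randomness flows through one ``numpy`` generator seeded from
``SimulationSpec.seed``; identical specs give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .containers import LOG_TRAITS, PC_COLUMNS, TRAITS, GenotypeBlock, PhenotypeTable
from .exceptions import DimensionError, InvalidSpecError

__all__ = [
    "VariantSpec",
    "MedicationModel",
    "SimulationSpec",
    "TruthTable",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_cohort",
]


@dataclass
class VariantSpec:
    """One simulated variant: position, alleles, frequency and true effects.

    ``beta_g`` maps trait name -> main effect (trait units per effect
    allele, at the generative centering age); ``beta_gxage`` maps trait
    name -> interaction effect (trait units per allele per year). Traits
    absent from either map have a zero effect.  For TG both effects are on
    the natural-log scale.
    """

    id: str
    chrom: str
    pos: int
    effect_allele: str = "A"
    non_effect_allele: str = "G"
    maf: float = 0.25
    beta_g: dict = field(default_factory=dict)
    beta_gxage: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise InvalidSpecError(
                f"variant {self.id}: maf must lie in (0, 0.5], got {self.maf}"
            )
        if self.pos < 1:
            raise InvalidSpecError(f"variant {self.id}: pos must be >= 1")
        for m in (self.beta_g, self.beta_gxage):
            for t in m:
                if t not in TRAITS:
                    raise InvalidSpecError(f"unknown trait {t!r} in effects of {self.id}")


@dataclass
class MedicationModel:
    """Logistic medication assignment and its masking of measured values.

    Assignment probabilities are logistic in age and the *untreated* trait
    value, reproducing the steep age gradient in medication use seen in
    biobank cohorts (statin use rising from a few percent in the forties
    to roughly a quarter in the sixties) without matching any particular
    cohort's numbers.  ``statin_ldl_effect`` multiplies a statin user's
    measured LDL-C (default 0.7, the inverse of the standard /0.7
    correction); ``bp_med_sbp_effect`` is subtracted from an
    antihypertensive user's measured SBP (default 10 mmHg).
    """

    statin_intercept: float = -10.0
    statin_age_slope: float = 0.11  # per year
    statin_ldl_slope: float = 0.6  # per mmol/L untreated LDL-C
    statin_ldl_effect: float = 0.7
    bp_med_intercept: float = -13.0
    bp_med_age_slope: float = 0.12  # per year
    bp_med_sbp_slope: float = 0.03  # per mmHg untreated SBP
    bp_med_sbp_effect: float = 10.0  # mmHg

    def validate(self) -> None:
        if not (0.0 < self.statin_ldl_effect <= 1.0):
            raise InvalidSpecError("statin_ldl_effect must lie in (0, 1]")
        if self.bp_med_sbp_effect < 0:
            raise InvalidSpecError("bp_med_sbp_effect must be >= 0")


# Trait-level generative defaults: value at age 0 (intercept), linear age
# slope per year, additive male effect (sex coded 0=male, 1=female: the
# female effect is 0, males get +sex_effect), and residual SD.  TG entries
# are on the natural-log scale.  Chosen to give cohort margins typical of a
# middle-aged European biobank population (overall means near ApoB 1.03 g/L,
# LDL-C 3.6 mmol/L, TG median ~1.5 mmol/L, SBP 138 mmHg, BMI 27 kg/m²).
DEFAULT_TRAIT_MEANS = {"apob": 0.916, "ldl": 3.285, "tg": -0.056, "sbp": 98.0, "bmi": 25.6}
DEFAULT_AGE_SLOPES = {"apob": 0.002, "ldl": 0.005, "tg": 0.008, "sbp": 0.7, "bmi": 0.03}
DEFAULT_SEX_EFFECTS = {"apob": 0.03, "ldl": 0.05, "tg": 0.15, "sbp": 4.0, "bmi": 0.3}
DEFAULT_NOISE_SD = {"apob": 0.22, "ldl": 0.80, "tg": 0.50, "sbp": 16.0, "bmi": 4.5}


@dataclass
class SimulationSpec:
    """Full description of a synthetic cohort.

    ``ld_blocks`` is a list of ``(start, stop, rho)`` tuples giving
    half-open variant-index ranges within which adjacent variants share a
    latent copula correlation ``rho`` in [0, 1).  ``age_center`` is the
    constant c of the generative model
    ``trait += (beta_g + beta_gxage * (age - c)) * dosage``; the
    interaction coefficient is invariant to c, and c is recorded in the
    truth table.  ``dosage_noise`` > 0 replaces hard calls with noisy
    dosages (beta-distributed perturbation clipped to [0, 2]) to emulate
    imputation.  ``seed`` is mandatory.
    """

    n_individuals: int
    seed: int
    variants: list = field(default_factory=list)
    ld_blocks: list = field(default_factory=list)
    age_range: tuple = (40, 70)
    sex_fraction: float = 0.542  # proportion female
    trait_means: dict = field(default_factory=lambda: dict(DEFAULT_TRAIT_MEANS))
    age_slopes: dict = field(default_factory=lambda: dict(DEFAULT_AGE_SLOPES))
    sex_effects: dict = field(default_factory=lambda: dict(DEFAULT_SEX_EFFECTS))
    noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    pc_effects: dict = field(default_factory=dict)  # trait -> length-10 vector
    medication: MedicationModel = field(default_factory=MedicationModel)
    missingness: dict = field(default_factory=dict)  # trait -> rate in [0,1]
    age_center: float = 0.0
    center_age_at_mean: bool = False
    dosage_noise: float = 0.0

    def validate(self) -> None:
        if self.n_individuals <= 0:
            raise InvalidSpecError("n_individuals must be > 0")
        lo, hi = self.age_range
        if not (0 < lo < hi < 120):
            raise InvalidSpecError(f"age_range must lie within (0, 120), got {self.age_range}")
        if not (0.0 <= self.sex_fraction <= 1.0):
            raise InvalidSpecError("sex_fraction must lie in [0, 1]")
        if self.seed is None:
            raise InvalidSpecError("a seed is mandatory for simulation")
        for v in self.variants:
            v.validate()
        self.medication.validate()
        for t, r in self.missingness.items():
            if not (0.0 <= r <= 1.0):
                raise InvalidSpecError(f"missingness rate for {t} must lie in [0, 1]")
        if self.dosage_noise < 0:
            raise InvalidSpecError("dosage_noise must be >= 0")
        spans = []
        for start, stop, rho in self.ld_blocks:
            if not (0.0 <= rho < 1.0):
                raise InvalidSpecError(f"LD rho must lie in [0, 1), got {rho}")
            if not (0 <= start < stop <= len(self.variants)):
                raise InvalidSpecError(f"LD block range ({start}, {stop}) out of bounds")
            spans.append((start, stop))
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise InvalidSpecError("overlapping LD blocks")


@dataclass
class TruthTable:
    """Ground truth of a simulated cohort: one row per variant-trait pair
    with the true beta_g, beta_gxage and the generative age-centering
    constant."""

    df: pd.DataFrame  # columns: variant_id, trait, beta_g, beta_gxage, age_center

    def effects_for(self, variant_id: str, trait: str) -> tuple[float, float]:
        row = self.df[(self.df.variant_id == variant_id) & (self.df.trait == trait)]
        if row.empty:
            raise KeyError(f"no truth row for ({variant_id}, {trait})")
        return float(row.beta_g.iloc[0]), float(row.beta_gxage.iloc[0])


def _latent_chain(rng: np.random.Generator, n_variants: int, n: int, ld_blocks) -> np.ndarray:
    """Latent standard-normal matrix with a first-order correlation chain.

    Variant j correlates rho with variant j-1 when both fall inside the
    same LD block; across block boundaries (and outside blocks) latents
    are independent.  Marginals are exactly N(0, 1).
    """
    rho_prev = np.zeros(n_variants)
    for start, stop, rho in ld_blocks:
        rho_prev[start + 1 : stop] = rho
    z = np.empty((n_variants, n))
    innov = rng.standard_normal((n_variants, n))
    z[0] = innov[0]
    for j in range(1, n_variants):
        r = rho_prev[j]
        z[j] = r * z[j - 1] + math.sqrt(1.0 - r * r) * innov[j]
    return z


def simulate_genotypes(spec: SimulationSpec) -> GenotypeBlock:
    """Draw a dosage matrix from Hardy–Weinberg proportions.

    Hard calls {0, 1, 2} are drawn per variant with probabilities
    (1-p)², 2p(1-p), p² at effect-allele frequency p = maf, by thresholding
    a latent Gaussian at the HWE cumulative cut points; within an LD block
    adjacent latents are correlated via the copula chain, which preserves
    the HWE marginals exactly.  With ``spec.dosage_noise`` > 0 the hard
    calls are perturbed into fractional dosages in [0, 2].
    Deterministic given ``spec.seed``.
    """
    spec.validate()
    if not spec.variants:
        raise InvalidSpecError("spec contains no variants")
    rng = np.random.default_rng(spec.seed)
    m, n = len(spec.variants), spec.n_individuals
    z = _latent_chain(rng, m, n, spec.ld_blocks)
    u = norm.cdf(z)
    p = np.array([v.maf for v in spec.variants])[:, None]
    c0 = (1.0 - p) ** 2  # P(G = 0)
    c1 = c0 + 2.0 * p * (1.0 - p)  # P(G <= 1)
    geno = np.where(u < c0, 0.0, np.where(u < c1, 1.0, 2.0))
    if spec.dosage_noise > 0:
        # beta(2,2)-distributed perturbation, centred, clipped to [0, 2]
        eps = spec.dosage_noise * 2.0 * (rng.beta(2.0, 2.0, size=geno.shape) - 0.5)
        geno = np.clip(geno + eps, 0.0, 2.0)
    variants = pd.DataFrame(
        {
            "id": [v.id for v in spec.variants],
            "chrom": [v.chrom for v in spec.variants],
            "pos": [v.pos for v in spec.variants],
            "non_effect_allele": [v.non_effect_allele for v in spec.variants],
            "effect_allele": [v.effect_allele for v in spec.variants],
        }
    )
    samples = [f"S{i + 1:06d}" for i in range(n)]
    return GenotypeBlock(dosages=geno, variants=variants, samples=samples)


def simulate_phenotypes(
    genotypes: GenotypeBlock, spec: SimulationSpec
) -> tuple[PhenotypeTable, TruthTable]:
    """Generate measured phenotypes on top of a genotype matrix.

    For each trait:
    ``value = intercept + age_slope*age + sex_effect*(sex==male)
    + sum_v (beta_g_v + beta_gxage_v*(age - c)) * dosage_v
    + PC effects + N(0, noise_sd)``, with TG built on the natural-log
    scale and exponentiated to mmol/L.  Medication masks the measured
    values (statins multiply LDL-C by ``statin_ldl_effect``;
    antihypertensives subtract ``bp_med_sbp_effect`` mmHg from SBP) and
    missingness is applied last.
    """
    spec.validate()
    if genotypes.n_samples != spec.n_individuals:
        raise DimensionError(
            f"genotype block has {genotypes.n_samples} samples but spec "
            f"declares {spec.n_individuals}"
        )
    if genotypes.n_variants != len(spec.variants):
        raise DimensionError(
            f"genotype block has {genotypes.n_variants} variants but spec "
            f"declares {len(spec.variants)}"
        )
    # an independent stream so phenotype noise never rewinds genotype draws
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    n = spec.n_individuals
    lo, hi = spec.age_range
    age = rng.integers(lo, hi + 1, size=n).astype(float)
    sex = (rng.random(n) < spec.sex_fraction).astype(float)  # 1 = female
    male = 1.0 - sex
    pcs = rng.standard_normal((n, 10))
    c = float(np.mean(age)) if spec.center_age_at_mean else spec.age_center

    dos = np.nan_to_num(genotypes.dosages, nan=0.0)
    values: dict[str, np.ndarray] = {}
    untreated: dict[str, np.ndarray] = {}
    for trait in TRAITS:
        y = (
            spec.trait_means[trait]
            + spec.age_slopes[trait] * age
            + spec.sex_effects[trait] * male
        )
        if trait in spec.pc_effects:
            y = y + pcs @ np.asarray(spec.pc_effects[trait], dtype=float)
        for j, v in enumerate(spec.variants):
            bg = v.beta_g.get(trait, 0.0)
            bi = v.beta_gxage.get(trait, 0.0)
            if bg != 0.0 or bi != 0.0:
                y = y + (bg + bi * (age - c)) * dos[j]
        sd = spec.noise_sd[trait]
        if sd > 0:
            y = y + sd * rng.standard_normal(n)
        if trait in LOG_TRAITS:
            y = np.exp(y)
        untreated[trait] = y.copy()
        values[trait] = y

    med = spec.medication
    logit_statin = (
        med.statin_intercept
        + med.statin_age_slope * age
        + med.statin_ldl_slope * untreated["ldl"]
    )
    statin = (rng.random(n) < 1.0 / (1.0 + np.exp(-logit_statin))).astype(int)
    logit_bp = (
        med.bp_med_intercept
        + med.bp_med_age_slope * age
        + med.bp_med_sbp_slope * untreated["sbp"]
    )
    bp_med = (rng.random(n) < 1.0 / (1.0 + np.exp(-logit_bp))).astype(int)

    values["ldl"] = np.where(statin == 1, untreated["ldl"] * med.statin_ldl_effect, untreated["ldl"])
    values["sbp"] = np.where(bp_med == 1, untreated["sbp"] - med.bp_med_sbp_effect, untreated["sbp"])

    for trait, rate in spec.missingness.items():
        if rate > 0:
            mask = rng.random(n) < rate
            values[trait] = np.where(mask, np.nan, values[trait])

    df = pd.DataFrame({"sample_id": genotypes.samples, "age": age, "sex": sex})
    for trait in TRAITS:
        df[trait] = values[trait]
    df["statin"] = statin
    df["bp_med"] = bp_med
    for i, col in enumerate(PC_COLUMNS):
        df[col] = pcs[:, i]

    truth_rows = [
        {
            "variant_id": v.id,
            "trait": t,
            "beta_g": v.beta_g.get(t, 0.0),
            "beta_gxage": v.beta_gxage.get(t, 0.0),
            "age_center": c,
        }
        for v in spec.variants
        for t in TRAITS
    ]
    truth = TruthTable(pd.DataFrame(truth_rows))
    return PhenotypeTable(df=df, state="raw", tg_scale="raw"), truth


def simulate_cohort(spec: SimulationSpec) -> tuple[GenotypeBlock, PhenotypeTable, TruthTable]:
    """Convenience wrapper: genotypes then phenotypes from one spec."""
    geno = simulate_genotypes(spec)
    pheno, truth = simulate_phenotypes(geno, spec)
    return geno, pheno, truth
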