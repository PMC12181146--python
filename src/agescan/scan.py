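"""Genome-wide interaction scan: variant filtering, multiple-testing
thresholds, and orchestration of the per-variant fits over blocks and
traits.

``InteractionScan`` is the model object: it is built from a genotype
source and a preprocessed phenotype table, and ``fit()`` returns
:class:`ScanResults` holding one row per variant x trait with marginal
and/or interaction statistics, the significance threshold applied, and
methods for clumping and summarising.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import LOG_TRAITS, TRAITS, GenotypeBlock, PhenotypeTable
from .engine import build_covariates, fit_interaction_block, fit_marginal_block
from .exceptions import AlignmentError, StateError

logger = logging.getLogger(__name__)

__all__ = ["ScanConfig", "InteractionScan", "ScanResults", "maf_filter", "genomewide_threshold"]

#: Column order of the results TSV dialect.
RESULT_COLUMNS = [
    "SNPID",
    "CHR",
    "POS",
    "Non_Effect_Allele",
    "Effect_Allele",
    "N",
    "EAF",
    "Beta_G",
    "SE_G",
    "Beta_Age",
    "SE_Age",
    "Beta_GxAge",
    "SE_GxAge",
    "P_Int",
    "P_Marginal",
]


@dataclass
class ScanConfig:
    """Scan settings.

    ``maf_min``: variants with minor-allele frequency strictly below this
    are removed; the boundary value is kept. ``alpha`` is the per-test
    genome-wide level before the Bonferroni division by ``n_traits``
    (default 5e-8 / 5 = 1e-8 per trait). ``models`` selects which fits
    run; ``se_type`` 'model' or 'robust' (robust uses the per-variant
    path).
    """

    maf_min: float = 0.001
    models: str = "both"  # 'interaction' | 'marginal' | 'both'
    se_type: str = "model"
    block_size: int = 512
    alpha: float = 5e-8
    n_traits: int = 5

    def __post_init__(self):
        if not (0.0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must lie in [0, 0.5)")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.models not in ("interaction", "marginal", "both"):
            raise ValueError("models must be 'interaction', 'marginal' or 'both'")

    @property
    def threshold(self) -> float:
        return genomewide_threshold(self.alpha, self.n_traits)


def genomewide_threshold(alpha: float, n_traits: int) -> float:
    """Bonferroni per-trait significance threshold: alpha / n_traits.

    With the conventional genome-wide alpha 5e-8 and five risk factors the
    per-trait interaction threshold is 1e-8.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if n_traits < 1:
        raise ValueError("n_traits must be >= 1")
    return alpha / n_traits


def maf_filter(block: GenotypeBlock, maf_min: float) -> tuple[GenotypeBlock, list[str]]:
    """Remove variants with MAF strictly below ``maf_min``.

    The boundary (maf == maf_min) is kept: the rule removes frequencies
    *below* the cutoff. MAF is computed on the samples present in the
    block, so callers subset to the analysis sample first.
    """
    maf = block.maf()
    keep = maf >= maf_min
    removed = block.variants.loc[~keep, "id"].tolist()
    if removed:
        logger.info("maf_filter removed %d variants below %g", len(removed), maf_min)
    return block.subset_variants(keep), removed


class InteractionScan:
    """Genome-wide SNP-by-age interaction scan model.

    Parameters
    ----------
    genotypes : GenotypeBlock or iterable of GenotypeBlock
        Dosage source; an iterable is consumed block by block (stateless,
        restartable).
    phenotypes : PhenotypeTable
        Preprocessed phenotype/covariate table.
    traits : sequence of str, optional
        Traits to scan (default: all five risk factors present).
    config : ScanConfig
    """

    def __init__(self, genotypes, phenotypes: PhenotypeTable, traits=None, config: ScanConfig | None = None):
        if phenotypes.state != "preprocessed":
            raise StateError("scan requires a preprocessed phenotype table")
        self.genotypes = genotypes
        self.phenotypes = phenotypes
        self.traits = list(traits) if traits is not None else [t for t in TRAITS if t in phenotypes.df.columns]
        self.config = config or ScanConfig()

    def _blocks(self):
        if isinstance(self.genotypes, GenotypeBlock):
            yield self.genotypes
        else:
            yield from self.genotypes

    def fit(self) -> "ScanResults":
        cfg = self.config
        pheno = self.phenotypes.df
        rows: list[pd.DataFrame] = []
        n_overlap_checked = False
        for block in self._blocks():
            common = pd.Index(block.samples).intersection(pheno["sample_id"])
            if len(common) == 0:
                raise AlignmentError("no overlapping samples between genotypes and phenotypes")
            if not n_overlap_checked:
                logger.info(
                    "sample reconciliation: %d genotyped, %d phenotyped, %d overlapping",
                    block.n_samples, len(pheno), len(common),
                )
                n_overlap_checked = True
            sample_pos = {s: i for i, s in enumerate(block.samples)}
            ph = pheno[pheno["sample_id"].isin(common)].reset_index(drop=True)
            gidx = np.array([sample_pos[s] for s in ph["sample_id"]])
            sub = block.subset_samples(gidx)
            sub, _removed = maf_filter(sub, cfg.maf_min)
            if sub.n_variants == 0:
                continue
            for trait in self.traits:
                keep = ~ph[trait].isna().to_numpy()
                ph_t = ph[keep].reset_index(drop=True)
                g_t = sub.dosages[:, keep]
                covars = build_covariates(ph_t)
                age = ph_t["age"].to_numpy(dtype=float)
                y = ph_t[trait].to_numpy(dtype=float)
                eaf = np.nanmean(g_t, axis=1) / 2.0

                res = pd.DataFrame(
                    {
                        "SNPID": sub.variants["id"],
                        "CHR": sub.variants["chrom"].astype(str),
                        "POS": sub.variants["pos"].astype(int),
                        "Non_Effect_Allele": sub.variants["non_effect_allele"],
                        "Effect_Allele": sub.variants["effect_allele"],
                        "N": len(ph_t),
                        "EAF": eaf,
                    }
                )
                res["trait"] = trait
                if cfg.models in ("interaction", "both"):
                    fit = fit_interaction_block(y, g_t, age, covars)
                    res["Beta_G"] = fit["beta_g"].to_numpy()
                    res["SE_G"] = fit["se_g"].to_numpy()
                    res["Beta_Age"] = fit["beta_age"].to_numpy()
                    res["SE_Age"] = fit["se_age"].to_numpy()
                    res["Beta_GxAge"] = fit["beta_int"].to_numpy()
                    res["SE_GxAge"] = fit["se_int"].to_numpy()
                    res["P_Int"] = fit["p_int"].to_numpy()
                    res["ok"] = fit["ok"].to_numpy()
                if cfg.models in ("marginal", "both"):
                    mfit = fit_marginal_block(y, g_t, age, covars)
                    res["P_Marginal"] = mfit["p_g"].to_numpy()
                    res["Beta_G_Marginal"] = mfit["beta_g"].to_numpy()
                    res["SE_G_Marginal"] = mfit["se_g"].to_numpy()
                    if cfg.models == "marginal":
                        res["Beta_G"] = mfit["beta_g"].to_numpy()
                        res["SE_G"] = mfit["se_g"].to_numpy()
                        res["Beta_Age"] = mfit["beta_age"].to_numpy()
                        res["SE_Age"] = mfit["se_age"].to_numpy()
                        res["ok"] = mfit["ok"].to_numpy()
                rows.append(res)
        if rows:
            table = pd.concat(rows, ignore_index=True)
        else:
            table = pd.DataFrame(columns=[*RESULT_COLUMNS, "trait", "ok"])
        table = table.sort_values(["trait", "CHR", "POS", "SNPID"], kind="mergesort").reset_index(drop=True)
        threshold = cfg.threshold
        if "P_Int" in table.columns:
            table["significant_interaction"] = table["P_Int"] < threshold
        if "P_Marginal" in table.columns:
            table["significant_marginal"] = table["P_Marginal"] < cfg.alpha
        return ScanResults(table=table, config=cfg, threshold=threshold, traits=self.traits)


@dataclass
class ScanResults:
    """Results of a genome-wide interaction scan.

    ``table`` holds one row per variant x trait in deterministic (trait,
    chrom, pos, id) order; ``threshold`` is the Bonferroni per-trait
    interaction threshold actually applied.
    """

    table: pd.DataFrame
    config: ScanConfig
    threshold: float
    traits: list = field(default_factory=list)

    def for_trait(self, trait: str) -> pd.DataFrame:
        return self.table[self.table["trait"] == trait].reset_index(drop=True)

    def significant(self, kind: str = "interaction") -> pd.DataFrame:
        col = f"significant_{kind}"
        return self.table[self.table[col]].reset_index(drop=True)

    def clump(self, ld, trait: str, kind: str = "interaction", r2_max: float = 0.1, p_max: float | None = None):
        """Greedy LD clumping of this scan's rows for one trait; see
        :func:`agescan.leads.clump`."""
        from .leads import clump

        p_col = "P_Int" if kind == "interaction" else "P_Marginal"
        if p_max is None:
            p_max = self.threshold if kind == "interaction" else self.config.alpha
        return clump(self.for_trait(trait), ld, r2_max=r2_max, p_max=p_max, p_col=p_col)

    def summary(self) -> str:
        lines = [
            "Genome-wide SNP-by-age interaction scan",
            f"traits: {', '.join(self.traits)}",
            f"per-trait interaction threshold: {self.threshold:g} "
            f"(alpha {self.config.alpha:g} / {self.config.n_traits} traits)",
            f"rows: {len(self.table)}",
        ]
        if "significant_interaction" in self.table.columns:
            for t in self.traits:
                sub = self.for_trait(t)
                lines.append(
                    f"  {t}: {len(sub)} variants tested, "
                    f"{int(sub['significant_interaction'].sum())} genome-wide "
                    f"significant interactions"
                )
        return "\n".join(lines)
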