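"""Core in-memory containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import DimensionError, StateError

#: The five cardiometabolic risk factors analysed by the pipeline, in the
#: canonical column order of the phenotype TSV dialect.
TRAITS = ("apob", "ldl", "tg", "sbp", "bmi")

#: Traits analysed on the natural-log scale after preprocessing.
LOG_TRAITS = ("tg",)

PC_COLUMNS = tuple(f"pc{i}" for i in range(1, 11))

PHENO_COLUMNS = ("sample_id", "age", "sex", *TRAITS, "statin", "bp_med", *PC_COLUMNS)


@dataclass
class GenotypeBlock:
    """A variants x individuals dosage matrix with variant metadata.

    ``dosages`` holds additive effect-allele dosages in [0, 2]; hard calls
    are the integers {0, 1, 2}. ``variants`` carries one row per variant
    with columns ``id, chrom, pos, non_effect_allele, effect_allele``
    (positions 1-based, VCF convention). Missing dosages are NaN.
    """

    dosages: np.ndarray  # shape (n_variants, n_samples), float
    variants: pd.DataFrame
    samples: list[str]

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise DimensionError("dosage matrix must be 2-D (variants x samples)")
        if self.dosages.shape[0] != len(self.variants):
            raise DimensionError(
                f"{self.dosages.shape[0]} dosage rows but "
                f"{len(self.variants)} variant records"
            )
        if self.dosages.shape[1] != len(self.samples):
            raise DimensionError(
                f"{self.dosages.shape[1]} dosage columns but "
                f"{len(self.samples)} sample ids"
            )

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[1]

    def eaf(self) -> np.ndarray:
        """Effect-allele frequency per variant (mean dosage / 2, NaN-aware)."""
        return np.nanmean(self.dosages, axis=1) / 2.0

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per variant: min(EAF, 1 - EAF)."""
        p = self.eaf()
        return np.minimum(p, 1.0 - p)

    def subset_variants(self, mask_or_index) -> "GenotypeBlock":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeBlock(
            dosages=self.dosages[idx],
            variants=self.variants.iloc[idx].reset_index(drop=True),
            samples=list(self.samples),
        )

    def subset_samples(self, mask_or_index) -> "GenotypeBlock":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeBlock(
            dosages=self.dosages[:, idx],
            variants=self.variants.copy(),
            samples=[self.samples[i] for i in idx],
        )

    def dosage_for(self, variant_id: str) -> np.ndarray:
        rows = np.flatnonzero((self.variants["id"] == variant_id).to_numpy())
        if len(rows) == 0:
            raise KeyError(f"variant {variant_id!r} not in block")
        return self.dosages[rows[0]]


@dataclass
class PhenotypeTable:
    """Per-individual trait values, age, sex, medication flags and PCs.

    ``state`` is 'raw' or 'preprocessed'; the only legal transition is
    raw -> preprocessed (enforced by the preprocessing stages).
    ``tg_scale`` records whether the tg column is on mmol/L ('raw') or
    natural-log ('log') scale. ``sex`` is coded 0 = male, 1 = female.
    """

    df: pd.DataFrame
    state: str = "raw"
    tg_scale: str = "raw"
    stage_log: list = field(default_factory=list)

    def __post_init__(self):
        if self.state not in ("raw", "preprocessed"):
            raise ValueError(f"unknown state {self.state!r}")
        if "sample_id" not in self.df.columns:
            raise DimensionError("phenotype table requires a sample_id column")

    def require_raw(self, op: str) -> None:
        if self.state != "raw":
            raise StateError(
                f"{op} requires a raw-state table (double application forbidden)"
            )

    def evolve(self, df: pd.DataFrame, note: str, **changes) -> "PhenotypeTable":
        new = replace(self, df=df, **changes)
        new.stage_log = self.stage_log + [note]
        return new

    @property
    def n(self) -> int:
        return len(self.df)
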