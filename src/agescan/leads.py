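"""Lead-variant identification: greedy LD clumping, positional gene
mapping, and the two-stage look-up analysis.

Clumping selects independent lead variants: rows are ranked by ascending
p-value and the best remaining row repeatedly becomes a lead, absorbing
every remaining variant whose LD r² with it reaches the threshold
(default r² >= 0.1 joins the clump, so retained leads are mutually below
r² 0.1). The look-up analysis takes each trait's marginal (main-effect)
leads at genome-wide significance and tests their interaction p-values
against a per-trait Bonferroni threshold of 0.05 divided by that trait's
number of marginal leads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeBlock

logger = logging.getLogger(__name__)

__all__ = [
    "LDSource",
    "LeadVariant",
    "GeneInterval",
    "clump",
    "map_genes",
    "lookup_interactions",
    "read_bed",
]


class LDSource:
    """Pairwise LD r² between variants.

    Backed either by a dosage matrix (r² is the squared Pearson
    correlation of the dosage vectors, computed in-sample) or by a
    precomputed symmetric matrix, e.g. from an external reference panel.
    Variants unknown to the source are treated as independent of
    everything (r² = 0) with a logged warning, matching how a reference
    panel that lacks a variant behaves.
    """

    def __init__(self, ids: list[str], dosages: np.ndarray | None = None, r2_matrix: np.ndarray | None = None):
        if (dosages is None) == (r2_matrix is None):
            raise ValueError("provide exactly one of dosages or r2_matrix")
        self._index = {v: i for i, v in enumerate(ids)}
        self._dos = None if dosages is None else np.asarray(dosages, dtype=float)
        self._r2 = None if r2_matrix is None else np.asarray(r2_matrix, dtype=float)
        if self._r2 is not None:
            if self._r2.shape != (len(ids), len(ids)):
                raise ValueError("r2_matrix shape must be (n_variants, n_variants)")
        self._warned: set[str] = set()

    @classmethod
    def from_genotypes(cls, block: GenotypeBlock) -> "LDSource":
        return cls(list(block.variants["id"]), dosages=block.dosages)

    @classmethod
    def from_matrix(cls, ids: list[str], r2_matrix: np.ndarray) -> "LDSource":
        return cls(ids, r2_matrix=r2_matrix)

    def _missing(self, vid: str) -> bool:
        if vid in self._index:
            return False
        if vid not in self._warned:
            logger.warning("variant %s absent from LD source; treated as independent", vid)
            self._warned.add(vid)
        return True

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        if self._missing(a) or self._missing(b):
            return 0.0
        i, j = self._index[a], self._index[b]
        if self._r2 is not None:
            return float(self._r2[i, j])
        x, y = self._dos[i], self._dos[j]
        ok = ~(np.isnan(x) | np.isnan(y))
        x, y = x[ok], y[ok]
        sx, sy = x.std(), y.std()
        if sx == 0.0 or sy == 0.0:
            return 0.0
        r = float(np.corrcoef(x, y)[0, 1])
        return r * r

    def r2_with(self, a: str, others: list[str]) -> np.ndarray:
        """Vector of r² between one variant and a list of variants."""
        if self._missing(a) or self._dos is None:
            return np.array([self.r2(a, b) for b in others])
        i = self._index[a]
        x = self._dos[i]
        out = np.empty(len(others))
        for k, b in enumerate(others):
            out[k] = self.r2(a, b) if (b == a or self._missing(b)) else self._pair(x, self._index[b])
        return out

    def _pair(self, x: np.ndarray, j: int) -> float:
        y = self._dos[j]
        ok = ~(np.isnan(x) | np.isnan(y))
        xv, yv = x[ok], y[ok]
        if xv.std() == 0.0 or yv.std() == 0.0:
            return 0.0
        r = float(np.corrcoef(xv, yv)[0, 1])
        return r * r


@dataclass
class LeadVariant:
    """A clump representative: the lowest-p row, its absorbed members and
    any positionally mapped genes."""

    row: pd.Series
    members: list = field(default_factory=list)  # variant ids clumped away
    genes: list = field(default_factory=list)  # (gene name, distance bp)

    @property
    def id(self) -> str:
        return str(self.row["SNPID"])

    @property
    def chrom(self) -> str:
        return str(self.row["CHR"])

    @property
    def pos(self) -> int:
        return int(self.row["POS"])


@dataclass
class GeneInterval:
    """A gene span, 1-based inclusive coordinates."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"gene {self.name}: start > end")

    def distance_to(self, chrom: str, pos: int) -> float:
        if str(chrom) != str(self.chrom):
            return np.inf
        if self.start <= pos <= self.end:
            return 0
        return self.start - pos if pos < self.start else pos - self.end


def clump(
    rows: pd.DataFrame,
    ld: LDSource,
    r2_max: float = 0.1,
    p_max: float = 5e-8,
    p_col: str = "P_Int",
) -> list[LeadVariant]:
    """Greedy LD clumping of one trait's scan rows.

    Rows with p < ``p_max`` seed clumps in order of ascending p (ties
    broken by larger \\|beta\\|, then chrom/pos); each new lead absorbs every
    remaining significant row whose r² with it is >= ``r2_max``. All
    retained leads therefore have pairwise r² < ``r2_max``, and every
    significant row ends up as a lead or a member of exactly one clump.
    The result is invariant to the input row order.
    """
    if not (0.0 < r2_max <= 1.0):
        raise ValueError("r2_max must lie in (0, 1]")
    sig = rows[rows[p_col] < p_max].copy()
    if sig.empty:
        return []
    beta_col = "Beta_GxAge" if p_col == "P_Int" and "Beta_GxAge" in sig.columns else "Beta_G"
    sig["_absbeta"] = sig[beta_col].abs() if beta_col in sig.columns else 0.0
    sig = sig.sort_values(
        [p_col, "_absbeta", "CHR", "POS", "SNPID"],
        ascending=[True, False, True, True, True],
        kind="mergesort",
    ).drop(columns="_absbeta")
    remaining = list(sig.index)
    leads: list[LeadVariant] = []
    by_idx = {i: sig.loc[i] for i in remaining}
    while remaining:
        head = remaining.pop(0)
        lead_row = by_idx[head]
        lead = LeadVariant(row=lead_row.drop(labels=[c for c in ("significant_interaction", "significant_marginal") if c in lead_row.index]))
        still = []
        for i in remaining:
            if ld.r2(str(lead_row["SNPID"]), str(by_idx[i]["SNPID"])) >= r2_max:
                lead.members.append(str(by_idx[i]["SNPID"]))
            else:
                still.append(i)
        remaining = still
        leads.append(lead)
    return leads


def map_genes(
    leads: list[LeadVariant],
    genes: list[GeneInterval],
    max_dist: int = 10_000,
) -> list[LeadVariant]:
    """Positional gene mapping: annotate each lead with every gene whose
    interval lies within ``max_dist`` bp (default 10 kb) of the variant
    position. The boundary is inclusive: a gene exactly ``max_dist`` away
    is mapped; distance is 0 for a variant inside the gene.
    """
    for lead in leads:
        hits = []
        for g in genes:
            d = g.distance_to(lead.chrom, lead.pos)
            if d <= max_dist:
                hits.append((g.name, int(d)))
        hits.sort(key=lambda t: (t[1], t[0]))
        lead.genes = hits
    return leads


def lookup_interactions(
    marginal_leads: dict[str, list[LeadVariant]],
    gwis_table: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-stage look-up: test marginal GWAS leads for age interaction.

    For each trait the significance threshold is ``alpha`` divided by the
    number of that trait's marginal leads (e.g. 0.05/145 when 145 leads
    were extracted). Interaction statistics are pulled from ``gwis_table``
    (a scan results table containing P_Int) by (trait, SNPID). Returns one
    row per marginal lead with its interaction beta, SE, p, the per-trait
    threshold and a significance flag; traits with zero leads simply
    contribute no rows.
    """
    records = []
    for trait, leads in marginal_leads.items():
        if not leads:
            continue
        threshold = alpha / len(leads)
        sub = gwis_table[gwis_table["trait"] == trait].set_index("SNPID")
        for lead in leads:
            vid = lead.id
            if vid not in sub.index:
                logger.warning("look-up: %s has no interaction row for trait %s", vid, trait)
                continue
            row = sub.loc[vid]
            records.append(
                {
                    "RSID": vid,
                    "CHR": row["CHR"],
                    "POS": int(row["POS"]),
                    "Non_effect_allele": row["Non_Effect_Allele"],
                    "Effect_allele": row["Effect_Allele"],
                    "N": int(row["N"]),
                    "EAF": float(row["EAF"]),
                    "Beta_GxAge": float(row["Beta_GxAge"]),
                    "SE_GxAge": float(row["SE_GxAge"]),
                    "P_Int": float(row["P_Int"]),
                    "trait": trait,
                    "n_marginal_leads": len(leads),
                    "threshold": threshold,
                    "significant": bool(row["P_Int"] < threshold),
                    "genes": ";".join(g for g, _ in lead.genes) if lead.genes else "",
                }
            )
    cols = [
        "RSID", "CHR", "POS", "Non_effect_allele", "Effect_allele", "N", "EAF",
        "Beta_GxAge", "SE_GxAge", "P_Int", "trait", "n_marginal_leads",
        "threshold", "significant", "genes",
    ]
    return pd.DataFrame(records, columns=cols)


def read_bed(path) -> list[GeneInterval]:
    """Read gene intervals from a BED file (0-based half-open) and convert
    to the internal 1-based inclusive convention: start+1, end unchanged."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
            genes.append(GeneInterval(name=name, chrom=chrom, start=start + 1, end=end))
    return genes
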