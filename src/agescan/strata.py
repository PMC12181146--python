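"""Age-group and sex-stratified effect estimation for lead variants.

Within each age group (default 40–49, 50–59 and 60–70, with age 70
assigned to the top bin) the trait is regressed on the variant's genotype
— either an additive per-allele dosage or two indicator contrasts
(heterozygote and effect-allele homozygote against the non-effect
homozygote reference) — adjusting for sex (omitted when sex-stratified)
and the ten principal components. For natural-log-transformed traits the
contrast is also reported as a fold change, exp(beta), with its Wald CI;
the reference category's fold change is exactly 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular

from .containers import LOG_TRAITS, PC_COLUMNS, PhenotypeTable
from .engine import _qr_checked, fit_interaction
from .exceptions import EmptyStratumError
from .phenoprep import DEFAULT_AGE_BINS

logger = logging.getLogger(__name__)

__all__ = [
    "StratumEstimate",
    "stratified_fit",
    "genotype_frequencies",
    "interaction_by_sex",
    "harden_dosages",
    "plot_strata",
]

GENOTYPE_LABELS = {0: "ref_hom", 1: "het", 2: "alt_hom"}


@dataclass
class StratumEstimate:
    """One genotype contrast within one age bin (and sex scope)."""

    variant_id: str
    trait: str
    age_bin: str
    sex_scope: str  # 'all' | 'women' | 'men'
    contrast: str  # 'additive' | 'het' | 'alt_hom'
    beta: float
    se: float
    ci_low: float
    ci_high: float
    n: int
    fold_change: float | None = None
    fc_low: float | None = None
    fc_high: float | None = None
    available: bool = True

    def fold_change_str(self) -> str:
        """Two-decimal rendering, e.g. '1.11-fold (95% CI 1.08, 1.14)'."""
        if self.fold_change is None:
            return "NA"
        return (
            f"{self.fold_change:.2f}-fold "
            f"(95% CI {self.fc_low:.2f}, {self.fc_high:.2f})"
        )


def harden_dosages(g: np.ndarray) -> tuple[np.ndarray, int]:
    """Round fractional dosages to hard calls {0, 1, 2} (threshold 0.5,
    ties to even per IEEE rounding); returns (hard calls, count rounded)."""
    g = np.asarray(g, dtype=float)
    hard = np.clip(np.rint(g), 0, 2)
    n_rounded = int(np.sum(~np.isnan(g) & (g != hard)))
    if n_rounded:
        logger.info("hardened %d fractional dosages to genotype calls", n_rounded)
    return hard, n_rounded


def _ols(y: np.ndarray, X: np.ndarray, names: list[str]):
    Q, R = _qr_checked(X, names)
    beta = solve_triangular(R, Q.T @ y)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = float(resid @ resid) / df
    Rinv = solve_triangular(R, np.eye(X.shape[1]))
    se = np.sqrt(sigma2 * np.sum(Rinv * Rinv, axis=1))
    return beta, se, df


def _bin_mask(age: np.ndarray, lo: int, hi: int) -> np.ndarray:
    return (age >= lo) & (age < hi)


def _sex_mask(df: pd.DataFrame, sex_scope: str) -> np.ndarray:
    if sex_scope == "all":
        return np.ones(len(df), dtype=bool)
    if sex_scope == "women":
        return df["sex"].to_numpy() == 1
    if sex_scope == "men":
        return df["sex"].to_numpy() == 0
    raise ValueError("sex_scope must be 'all', 'women' or 'men'")


def stratified_fit(
    pheno: PhenotypeTable,
    dosage: np.ndarray,
    variant_id: str,
    trait: str,
    age_bins=DEFAULT_AGE_BINS,
    coding: str = "genotype",
    sex_scope: str = "all",
) -> list[StratumEstimate]:
    """Per-age-bin regression of a trait on one variant's genotype.

    ``coding='genotype'`` fits the two indicator contrasts against the
    non-effect homozygote reference (dosages are hardened first);
    ``coding='additive'`` fits the per-allele slope. An empty genotype
    category within a bin marks that contrast unavailable without
    aborting the others. CIs are Wald with the normal quantile.
    """
    df = pheno.df
    g = np.asarray(dosage, dtype=float)
    if len(g) != len(df):
        raise ValueError("dosage vector must align with the phenotype table")
    if coding == "genotype":
        g, _ = harden_dosages(g)
    elif coding != "additive":
        raise ValueError("coding must be 'genotype' or 'additive'")
    log_scale = trait in LOG_TRAITS and pheno.tg_scale == "log"
    z = stats.norm.ppf(0.975)
    out: list[StratumEstimate] = []
    smask = _sex_mask(df, sex_scope)
    for lo, hi in age_bins:
        label = f"{lo}–{hi - 1}"
        mask = _bin_mask(df["age"].to_numpy(dtype=float), lo, hi) & smask
        mask &= ~np.isnan(g) & ~df[trait].isna().to_numpy()
        sub = df[mask]
        gb = g[mask]
        n = len(sub)
        if n == 0:
            raise EmptyStratumError(f"age bin {label} ({sex_scope}) has no samples")
        y = sub[trait].to_numpy(dtype=float)
        pcs = sub[list(PC_COLUMNS)].to_numpy(dtype=float)
        base_cols = [np.ones(n)]
        base_names = ["const"]
        if sex_scope == "all":
            base_cols.append(sub["sex"].to_numpy(dtype=float))
            base_names.append("sex")

        def emit(contrast, beta, se):
            est = StratumEstimate(
                variant_id=variant_id, trait=trait, age_bin=label,
                sex_scope=sex_scope, contrast=contrast,
                beta=float(beta), se=float(se),
                ci_low=float(beta - z * se), ci_high=float(beta + z * se), n=n,
            )
            if log_scale:
                est.fold_change = float(np.exp(beta))
                est.fc_low = float(np.exp(est.ci_low))
                est.fc_high = float(np.exp(est.ci_high))
            out.append(est)

        if coding == "additive":
            X = np.column_stack([*base_cols, gb, pcs])
            names = [*base_names, "g", *PC_COLUMNS]
            beta, se, _ = _ols(y, X, names)
            emit("additive", beta[len(base_cols)], se[len(base_cols)])
        else:
            het = (gb == 1).astype(float)
            hom = (gb == 2).astype(float)
            missing = [c for c, v in (("het", het), ("alt_hom", hom)) if v.sum() == 0]
            cols, names = list(base_cols), list(base_names)
            keep_contrasts = []
            for cname, v in (("het", het), ("alt_hom", hom)):
                if cname not in missing:
                    cols.append(v)
                    names.append(cname)
                    keep_contrasts.append(cname)
            X = np.column_stack([*cols, pcs])
            beta, se, _ = _ols(y, X, [*names, *PC_COLUMNS])
            for cname in keep_contrasts:
                i = names.index(cname)
                emit(cname, beta[i], se[i])
            for cname in missing:
                out.append(
                    StratumEstimate(
                        variant_id=variant_id, trait=trait, age_bin=label,
                        sex_scope=sex_scope, contrast=cname,
                        beta=np.nan, se=np.nan, ci_low=np.nan, ci_high=np.nan,
                        n=n, available=False,
                    )
                )
    return out


def genotype_frequencies(
    dosage: np.ndarray,
    age: np.ndarray,
    age_bins=DEFAULT_AGE_BINS,
    variant_id: str = "",
) -> pd.DataFrame:
    """Genotype category frequencies (%) per age bin, two-decimal
    rendering; per-bin percentages sum to 100 within rounding."""
    g, _ = harden_dosages(np.asarray(dosage, dtype=float))
    age = np.asarray(age, dtype=float)
    rows = []
    for lo, hi in age_bins:
        label = f"{lo}–{hi - 1}"
        mask = _bin_mask(age, lo, hi) & ~np.isnan(g)
        gb = g[mask]
        n = len(gb)
        row = {"variant_id": variant_id, "age_bin": label, "n": n}
        for code, name in GENOTYPE_LABELS.items():
            row[name] = round(100.0 * float(np.mean(gb == code)), 2) if n else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def plot_strata(estimates: list[StratumEstimate], ax=None):
    """Forest-style plot of stratified genotype contrasts: one point ±
    95% CI per (age bin, contrast), fold-change scale for log traits."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.6 * max(4, len(estimates))))
    avail = [e for e in estimates if e.available]
    log_scale = all(e.fold_change is not None for e in avail) and avail
    ys = np.arange(len(avail))[::-1]
    for y, e in zip(ys, avail):
        if log_scale:
            x, lo, hi = e.fold_change, e.fc_low, e.fc_high
        else:
            x, lo, hi = e.beta, e.ci_low, e.ci_high
        ax.errorbar(x, y, xerr=[[x - lo], [hi - x]], fmt="o", color="C0", capsize=3)
    ax.axvline(1.0 if log_scale else 0.0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(ys)
    ax.set_yticklabels([f"{e.age_bin} {e.contrast}" for e in avail])
    ax.set_xlabel("fold change (95% CI)" if log_scale else "effect (95% CI)")
    if avail:
        ax.set_title(f"{avail[0].variant_id} on {avail[0].trait} ({avail[0].sex_scope})")
    return ax


def interaction_by_sex(pheno: PhenotypeTable, dosage: np.ndarray, trait: str):
    """Fit the SNP-by-age interaction model in women and men separately,
    dropping the sex covariate. Returns {'women': results, 'men': results}."""
    df = pheno.df
    g = np.asarray(dosage, dtype=float)
    out = {}
    for scope in ("women", "men"):
        mask = _sex_mask(df, scope) & ~np.isnan(g) & ~df[trait].isna().to_numpy()
        if mask.sum() == 0:
            raise EmptyStratumError(f"no {scope} in the dataset")
        sub = df[mask]
        covars = sub[list(PC_COLUMNS)].astype(float)
        out[scope] = fit_interaction(
            sub[trait].to_numpy(dtype=float), g[mask],
            sub["age"].to_numpy(dtype=float), covars,
        )
    return out
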