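"""Phenotype preprocessing: medication corrections, TG log transform,
winsorization, complete-case filtering and cohort summaries.

The corrections undo the masking of measured values by treatment: a statin
user's measured LDL-C is divided by 0.7 to approximate the untreated level,
and 10 mmHg is added to the mean measured SBP of antihypertensive users.
ApoB and TG are left untouched in statin users. TG is natural-log
transformed. Values beyond k standard deviations from the trait mean
(default k = 6) are set exactly to the boundary. Individuals missing any
of the five analysis traits are excluded.

The default stage order is: average SBP readings -> medication corrections
-> TG log transform -> winsorization (per trait, on the analysis scale)
-> complete-case filter. Correction before winsorization is chosen so the
+10 mmHg shift cannot push values past a clip bound computed on the
uncorrected distribution; the order is configurable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import LOG_TRAITS, TRAITS, PhenotypeTable
from .exceptions import EmptyCohortError

logger = logging.getLogger(__name__)

__all__ = [
    "PrepConfig",
    "CohortSummary",
    "average_sbp_readings",
    "correct_medications",
    "transform_tg",
    "winsorize",
    "winsorize_traits",
    "complete_case_filter",
    "preprocess",
    "summarize_cohort",
    "DEFAULT_AGE_BINS",
]

#: Closed-open bins [40,50), [50,60) and the top bin closed at 70.
DEFAULT_AGE_BINS = ((40, 50), (50, 60), (60, 71))


def age_bin_labels(bins=DEFAULT_AGE_BINS) -> list[str]:
    return [f"{lo}–{hi - 1}" for lo, hi in bins]


@dataclass
class PrepConfig:
    """Constants of the preprocessing stage.

    ``statin_ldl_divisor``: measured LDL-C of statin users is divided by
    this (default 0.7). ``bp_med_sbp_addition``: mmHg added to the mean
    measured SBP of antihypertensive users (default 10). ``winsor_k``:
    clip bound in SD units (default 6). ``winsorize_before_correction``
    flips the default correction-first order.
    """

    statin_ldl_divisor: float = 0.7
    bp_med_sbp_addition: float = 10.0
    winsor_k: float = 6.0
    tg_log: bool = True
    complete_case_traits: tuple = TRAITS
    winsorize_before_correction: bool = False

    def __post_init__(self):
        if not (0.0 < self.statin_ldl_divisor <= 1.0):
            raise ValueError("statin_ldl_divisor must lie in (0, 1]")
        if self.bp_med_sbp_addition < 0:
            raise ValueError("bp_med_sbp_addition must be >= 0")
        if self.winsor_k <= 0:
            raise ValueError("winsor_k must be > 0")
        unknown = set(self.complete_case_traits) - set(TRAITS)
        if unknown:
            raise ValueError(f"unknown traits in complete_case_traits: {sorted(unknown)}")


def average_sbp_readings(table: PhenotypeTable) -> PhenotypeTable:
    """Replace two SBP readings (columns sbp_1, sbp_2) by their mean.

    No-op when the table already carries a single ``sbp`` column.
    """
    df = table.df
    if "sbp_1" in df.columns and "sbp_2" in df.columns:
        df = df.copy()
        df["sbp"] = (df["sbp_1"] + df["sbp_2"]) / 2.0
        df = df.drop(columns=["sbp_1", "sbp_2"])
        return table.evolve(df, "averaged two SBP readings")
    return table


def correct_medications(table: PhenotypeTable, cfg: PrepConfig | None = None) -> PhenotypeTable:
    """Undo treatment masking: LDL-C of statin users divided by the
    divisor; SBP of antihypertensive users increased by the addition.
    ApoB and TG are untouched; non-users are unchanged.

    Raises :class:`StateError` on an already-preprocessed table, because a
    double correction would silently bias the traits.
    """
    cfg = cfg or PrepConfig()
    table.require_raw("correct_medications")
    df = table.df.copy()
    statin = df["statin"].astype(bool)
    df.loc[statin, "ldl"] = df.loc[statin, "ldl"] / cfg.statin_ldl_divisor
    bp = df["bp_med"].astype(bool)
    df.loc[bp, "sbp"] = df.loc[bp, "sbp"] + cfg.bp_med_sbp_addition
    note = (
        f"medication corrections: LDL-C /{cfg.statin_ldl_divisor} for "
        f"{int(statin.sum())} statin users; SBP +{cfg.bp_med_sbp_addition} mmHg "
        f"for {int(bp.sum())} treated"
    )
    logger.info(note)
    return table.evolve(df, note)


def transform_tg(table: PhenotypeTable) -> PhenotypeTable:
    """Natural-log transform TG (mmol/L -> log mmol/L)."""
    if table.tg_scale == "log":
        raise ValueError("tg already on log scale")
    df = table.df.copy()
    tg = df["tg"].to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isnan(tg) & (tg <= 0))
    if bad.size:
        offender = df["sample_id"].iloc[bad[0]]
        raise ValueError(
            f"tg must be strictly positive for log transform; sample "
            f"{offender!r} has tg = {tg[bad[0]]}"
        )
    df["tg"] = np.log(tg)
    return table.evolve(df, "TG natural-log transformed", tg_scale="log")


def winsorize(values, k: float) -> np.ndarray:
    """Clip values beyond k SDs from the mean to exactly the boundary.

    Mean and SD are computed once on the non-missing input entries; every
    value outside [m - k*s, m + k*s] is set to the nearer bound. Missing
    entries pass through. Zero SD (all values equal) is a warned no-op.
    A second application with the same data is an exact no-op because the
    clipped output lies within the original bounds.
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    x = np.asarray(values, dtype=float).copy()
    finite = ~np.isnan(x)
    if finite.sum() < 2:
        raise ValueError("winsorize needs at least 2 non-missing values")
    m = x[finite].mean()
    s = x[finite].std(ddof=1)
    if s == 0.0:
        warnings.warn("zero SD: winsorization is a no-op", stacklevel=2)
        return x
    lo, hi = m - k * s, m + k * s
    x[finite] = np.clip(x[finite], lo, hi)
    return x


def winsorize_traits(table: PhenotypeTable, k: float, traits=TRAITS) -> PhenotypeTable:
    df = table.df.copy()
    n_clipped = 0
    for t in traits:
        before = df[t].to_numpy(dtype=float)
        if (~np.isnan(before)).sum() < 2:
            warnings.warn(f"trait {t}: fewer than 2 non-missing values; winsorization skipped")
            continue
        after = winsorize(before, k)
        with np.errstate(invalid="ignore"):
            n_clipped += int(np.nansum(before != after))
        df[t] = after
    return table.evolve(df, f"winsorized at {k} SD ({n_clipped} values clipped)")


def complete_case_filter(table: PhenotypeTable, traits=TRAITS) -> PhenotypeTable:
    """Drop rows missing any of the listed traits; log the removal count."""
    df = table.df
    keep = ~df[list(traits)].isna().any(axis=1)
    removed = int((~keep).sum())
    logger.info("complete-case filter removed %d of %d rows", removed, len(df))
    if keep.sum() == 0:
        raise EmptyCohortError("complete-case filter removed every individual")
    return table.evolve(
        df[keep].reset_index(drop=True),
        f"complete-case filter on {list(traits)}: removed {removed} rows",
    )


def preprocess(table: PhenotypeTable, cfg: PrepConfig | None = None) -> PhenotypeTable:
    """Run the full staged preprocessing pipeline on a raw table.

    Default order: average SBP readings, medication corrections, TG log
    transform, winsorization on the analysis scale, complete-case filter.
    The result is in the 'preprocessed' state.
    """
    cfg = cfg or PrepConfig()
    table.require_raw("preprocess")
    t = average_sbp_readings(table)
    if cfg.winsorize_before_correction:
        if cfg.tg_log:
            t = transform_tg(t)
        t = winsorize_traits(t, cfg.winsor_k)
        t = correct_medications(t, cfg)
    else:
        t = correct_medications(t, cfg)
        if cfg.tg_log:
            t = transform_tg(t)
        t = winsorize_traits(t, cfg.winsor_k)
    t = complete_case_filter(t, cfg.complete_case_traits)
    t.state = "preprocessed"
    return t


@dataclass
class CohortSummary:
    """Table-1-style descriptive summary: one row per age bin plus overall."""

    table: pd.DataFrame

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.table.to_string(index=False)


def _median_iqr(x: pd.Series) -> str:
    x = x.dropna()
    if x.empty:
        return "NA"
    # linear interpolation between order statistics
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])
    return f"{med:.2f} [{q1:.2f}, {q3:.2f}]"


def _mean_sd(x: pd.Series) -> str:
    x = x.dropna()
    if x.empty:
        return "NA"
    return f"{x.mean():.2f} ({x.std(ddof=1):.2f})"


def summarize_cohort(table: PhenotypeTable, age_bins=DEFAULT_AGE_BINS) -> CohortSummary:
    """Descriptive cohort summary per age bin and overall.

    Mean (SD) for ApoB, LDL-C, SBP and BMI; median [IQR] (linear
    interpolation between order statistics) for age and TG — TG reported
    on the raw mmol/L scale, back-transformed if the table is on the log
    scale. Empty bins yield an n = 0 row with statistics marked NA.
    """
    df = table.df
    groups: list[tuple[str, pd.DataFrame]] = [("overall", df)]
    for lo, hi in age_bins:
        sub = df[(df["age"] >= lo) & (df["age"] < hi)]
        groups.append((f"{lo}–{hi - 1}", sub))
    rows = []
    for label, sub in groups:
        n = len(sub)
        if n == 0:
            rows.append({"group": label, "n": 0})
            continue
        tg = np.exp(sub["tg"]) if table.tg_scale == "log" else sub["tg"]
        rows.append(
            {
                "group": label,
                "n": n,
                "pct_female": round(100.0 * sub["sex"].mean(), 1),
                "age_median_iqr": _median_iqr(sub["age"]),
                "apob_mean_sd": _mean_sd(sub["apob"]),
                "ldl_mean_sd": _mean_sd(sub["ldl"]),
                "tg_median_iqr": _median_iqr(tg),
                "sbp_mean_sd": _mean_sd(sub["sbp"]),
                "bmi_mean_sd": _mean_sd(sub["bmi"]),
                "statin_n": int(sub["statin"].sum()),
                "statin_pct": round(100.0 * sub["statin"].mean(), 1),
                "bp_med_n": int(sub["bp_med"].sum()),
                "bp_med_pct": round(100.0 * sub["bp_med"].mean(), 1),
            }
        )
    return CohortSummary(pd.DataFrame(rows))
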