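"""Per-variant linear models: the SNP-by-age interaction model and the
marginal (main-effect) model, with Wald tests.

The interaction model regresses a continuous trait on
``[1, g, age, g*age, sex, pc1..pc10]`` by ordinary least squares; the
coefficient of the product term ``g*age`` (trait units per effect allele
per year) is the gene-age interaction effect and is tested two-sided
against a t reference with residual degrees of freedom. The marginal model
drops the product term and tests the main genetic effect. Standard errors
are model-based by default with a heteroscedasticity-robust (HC0 sandwich)
option.

Two computational routes give mathematically identical estimates:

* :class:`SnpAgeInteractionModel` / :class:`MarginalModel` — one explicit
  design matrix per variant, solved by QR; and
* :func:`fit_interaction_block` / :func:`fit_marginal_block` — a
  Frisch–Waugh–Lovell fast path for scans, which factorises the shared
  covariate block once and solves a small per-variant system, recovering
  the full-model coefficients, standard errors and p-values exactly via
  the partitioned-inverse identities.

Equality of the two routes is a tested contract, not an approximation.
Missing dosages are mean-imputed per variant by default (configurable to
drop); missing trait or covariate values must be removed by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular

from .containers import PC_COLUMNS
from .exceptions import CollinearityError, DimensionError, MonomorphicVariantError

__all__ = [
    "SnpAgeInteractionModel",
    "MarginalModel",
    "InteractionResults",
    "build_covariates",
    "fit_interaction",
    "fit_marginal",
    "fit_interaction_block",
    "fit_marginal_block",
    "mean_impute",
]

_RCOND = 1e-10  # relative tolerance on QR diagonal for rank checks


def build_covariates(pheno_df: pd.DataFrame, include_sex: bool = True) -> pd.DataFrame:
    """Assemble the standard covariate block (sex indicator + 10 PCs)."""
    cols = (["sex"] if include_sex else []) + list(PC_COLUMNS)
    return pheno_df[cols].astype(float)


def mean_impute(g: np.ndarray) -> tuple[np.ndarray, int]:
    """Replace missing dosages by the variant mean; returns (g, n_imputed)."""
    g = np.asarray(g, dtype=float)
    miss = np.isnan(g)
    k = int(miss.sum())
    if k:
        if k == g.size:
            raise MonomorphicVariantError("all dosages missing")
        g = g.copy()
        g[miss] = g[~miss].mean()
    return g, k


def _qr_checked(X: np.ndarray, names: list[str]):
    Q, R = np.linalg.qr(X)
    d = np.abs(np.diag(R))
    tol = _RCOND * max(X.shape) * (d.max() if d.size else 0.0)
    bad = np.flatnonzero(d <= tol)
    if bad.size:
        raise CollinearityError(names[bad[0]])
    return Q, R


@dataclass
class InteractionResults:
    """OLS estimates for one variant-trait fit.

    Attributes mirror statsmodels results: ``params``, ``bse``,
    ``tvalues``, ``pvalues`` are Series indexed by term name; ``n``,
    ``df_resid``, ``sigma2`` describe the fit. Convenience accessors
    expose the terms of interest (``beta_int``/``p_int`` exist only for
    the interaction model, ``p_g_marginal`` only for the marginal model).
    """

    params: pd.Series
    bse: pd.Series
    n: int
    df_resid: int
    sigma2: float
    se_type: str
    model: str  # 'interaction' or 'marginal'

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2.0 * stats.t.sf(np.abs(self.tvalues), self.df_resid),
            index=self.params.index,
        )

    # -- named accessors -------------------------------------------------
    beta_g = property(lambda self: float(self.params["g"]))
    se_g = property(lambda self: float(self.bse["g"]))
    beta_age = property(lambda self: float(self.params["age"]))
    se_age = property(lambda self: float(self.bse["age"]))

    @property
    def beta_int(self) -> float:
        return float(self.params["g_x_age"])

    @property
    def se_int(self) -> float:
        return float(self.bse["g_x_age"])

    @property
    def t_int(self) -> float:
        return float(self.tvalues["g_x_age"])

    @property
    def p_int(self) -> float:
        return float(self.pvalues["g_x_age"])

    @property
    def p_g_marginal(self) -> float:
        if self.model != "marginal":
            raise AttributeError("p_g_marginal is defined on the marginal model")
        return float(self.pvalues["g"])

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        q = stats.t.ppf(1.0 - alpha / 2.0, self.df_resid)
        return pd.DataFrame(
            {"lower": self.params - q * self.bse, "upper": self.params + q * self.bse}
        )

    def summary(self) -> str:
        head = (
            f"{'SNP-age interaction model' if self.model == 'interaction' else 'Marginal model'}"
            f"  (OLS, {self.se_type} SEs)\n"
            f"n = {self.n}, residual df = {self.df_resid}, "
            f"residual variance = {self.sigma2:.6g}\n"
        )
        tab = pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "t": self.tvalues,
                "P>|t|": self.pvalues,
            }
        )
        ci = self.conf_int()
        tab["[0.025"] = ci["lower"]
        tab["0.975]"] = ci["upper"]
        return head + tab.to_string(float_format=lambda v: f"{v: .6g}")


class _LinearVariantModel:
    """Shared machinery for the two per-variant designs."""

    _model_name = ""

    def __init__(self, y, g, age, covars, *, missing_dosage: str = "mean"):
        y = np.asarray(y, dtype=float)
        age = np.asarray(age, dtype=float)
        g = np.asarray(g, dtype=float)
        if not (len(y) == len(g) == len(age)):
            raise DimensionError("y, g and age must have equal length")
        if covars is not None:
            self._covar_names = (
                list(covars.columns)
                if isinstance(covars, pd.DataFrame)
                else [f"x{i}" for i in range(np.asarray(covars).shape[1])]
            )
            covars = np.asarray(covars, dtype=float)
            if covars.shape[0] != len(y):
                raise DimensionError("covariate rows must match phenotype rows")
        else:
            self._covar_names = []
        if np.isnan(y).any() or np.isnan(age).any():
            raise ValueError("y and age must be free of missing values")
        if missing_dosage == "mean":
            g, self.n_imputed = mean_impute(g)
        elif missing_dosage == "drop":
            keep = ~np.isnan(g)
            y, g, age = y[keep], g[keep], age[keep]
            covars = covars[keep] if covars is not None else None
            self.n_imputed = 0
        else:
            raise ValueError("missing_dosage must be 'mean' or 'drop'")
        if np.ptp(g) == 0.0:
            raise MonomorphicVariantError(
                f"dosage vector is constant ({g[0]:.3g}); variant is monomorphic "
                "in the analysis sample"
            )
        self.y, self.g, self.age, self.covars = y, g, age, covars

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, trait: str, dosage: str = "g", **kw):
        """Build the model from a phenotype-style DataFrame holding the
        trait, a dosage column, age, sex and pc1..pc10."""
        covars = build_covariates(df)
        return cls(df[trait].to_numpy(), df[dosage].to_numpy(), df["age"].to_numpy(), covars, **kw)

    def _design(self) -> tuple[np.ndarray, list[str]]:
        raise NotImplementedError

    def fit(self, se_type: str = "model") -> InteractionResults:
        """OLS fit via QR; ``se_type`` is 'model' or 'robust' (HC0)."""
        X, names = self._design()
        n, p = X.shape
        if n <= p:
            raise DimensionError(f"n = {n} samples but {p} design columns")
        Q, R = _qr_checked(X, names)
        beta = solve_triangular(R, Q.T @ self.y)
        resid = self.y - X @ beta
        df_resid = n - p
        sigma2 = float(resid @ resid) / df_resid
        Rinv = solve_triangular(R, np.eye(p))
        xtx_inv = Rinv @ Rinv.T
        if se_type == "model":
            cov = sigma2 * xtx_inv
        elif se_type == "robust":
            meat = X.T @ (resid[:, None] ** 2 * X)
            cov = xtx_inv @ meat @ xtx_inv
        else:
            raise ValueError("se_type must be 'model' or 'robust'")
        return InteractionResults(
            params=pd.Series(beta, index=names),
            bse=pd.Series(np.sqrt(np.diag(cov)), index=names),
            n=n,
            df_resid=df_resid,
            sigma2=sigma2,
            se_type=se_type,
            model=self._model_name,
        )


class SnpAgeInteractionModel(_LinearVariantModel):
    """Trait ~ 1 + g + age + g*age + covariates, the interaction scan model."""

    _model_name = "interaction"

    def _design(self):
        cols = [np.ones_like(self.y), self.g, self.age, self.g * self.age]
        names = ["const", "g", "age", "g_x_age"]
        if self.covars is not None:
            cols.extend(self.covars.T)
            names.extend(self._covar_names)
        return np.column_stack(cols), names


class MarginalModel(_LinearVariantModel):
    """Trait ~ 1 + g + age + covariates, the conventional GWAS model."""

    _model_name = "marginal"

    def _design(self):
        cols = [np.ones_like(self.y), self.g, self.age]
        names = ["const", "g", "age"]
        if self.covars is not None:
            cols.extend(self.covars.T)
            names.extend(self._covar_names)
        return np.column_stack(cols), names


def fit_interaction(y, g, age, covars, se_type: str = "model", **kw) -> InteractionResults:
    """Functional wrapper over :class:`SnpAgeInteractionModel`."""
    return SnpAgeInteractionModel(y, g, age, covars, **kw).fit(se_type=se_type)


def fit_marginal(y, g, age, covars, se_type: str = "model", **kw) -> InteractionResults:
    """Functional wrapper over :class:`MarginalModel`."""
    return MarginalModel(y, g, age, covars, **kw).fit(se_type=se_type)


# ---------------------------------------------------------------------------
# Frisch–Waugh–Lovell fast path for block scans
# ---------------------------------------------------------------------------


class _SharedCovariateBasis:
    """QR factorisation of the covariate block [1, age, sex, pcs] shared by
    every variant of a scan, with the pieces needed to reconstruct full-model
    coefficients and standard errors for the age column."""

    def __init__(self, age: np.ndarray, covars, names_extra: list[str]):
        n = len(age)
        cols = [np.ones(n), np.asarray(age, dtype=float)]
        names = ["const", "age"]
        if covars is not None:
            cols.extend(np.asarray(covars, dtype=float).T)
            names.extend(names_extra)
        C = np.column_stack(cols)
        self.C, self.names = C, names
        self.k = C.shape[1]
        self.Q, self.R = _qr_checked(C, names)
        Rinv = solve_triangular(self.R, np.eye(self.k))
        self.ctc_inv = Rinv @ Rinv.T
        self.age_idx = 1

    def project_out(self, M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (residual of M on C, coefficient matrix (C'C)^-1 C'M)."""
        A = self.Q.T @ M
        B = solve_triangular(self.R, A)
        return M - self.Q @ A, B


def _prepare_block(y, G, age, covars):
    y = np.asarray(y, dtype=float)
    G = np.asarray(G, dtype=float)
    age = np.asarray(age, dtype=float)
    if G.ndim != 2 or G.shape[1] != len(y) or len(age) != len(y):
        raise DimensionError("G must be (variants x samples) aligned with y and age")
    names_extra = (
        list(covars.columns) if isinstance(covars, pd.DataFrame) else
        ([] if covars is None else [f"x{i}" for i in range(np.asarray(covars).shape[1])])
    )
    basis = _SharedCovariateBasis(age, covars, names_extra)
    # per-variant mean imputation of missing dosages
    Gt = G.T.copy()  # samples x variants
    miss = np.isnan(Gt)
    if miss.any():
        col_mean = np.nanmean(Gt, axis=0)
        idx = np.where(miss)
        Gt[idx] = col_mean[idx[1]]
    mono = np.ptp(Gt, axis=0) == 0.0
    return y, Gt, age, basis, mono


def fit_interaction_block(y, G, age, covars, return_age_terms: bool = True) -> pd.DataFrame:
    """Fit the interaction model for every variant row of ``G`` at once.

    Mathematically identical to looping :func:`fit_interaction` over
    variants (model-based SEs): the shared covariate block ``[1, age, sex,
    pcs]`` is factorised once, the two variant columns ``(g, g*age)`` are
    residualised against it, and the full-model coefficients and the age
    term's standard error are recovered through the partitioned-inverse
    identities. Monomorphic variants are flagged (``ok = False``) with NaN
    statistics rather than aborting the block.

    Returns a DataFrame with columns ``beta_g, se_g, beta_age, se_age,
    beta_int, se_int, t_int, p_int, n, df_resid, sigma2, n_imputed, ok``.
    """
    y, Gt, age, basis, mono = _prepare_block(y, G, age, covars)
    n, m = Gt.shape
    k = basis.k
    df_resid = n - (k + 2)
    if df_resid <= 0:
        raise DimensionError("not enough samples for the interaction design")
    GA = Gt * age[:, None]
    Gr, B1 = basis.project_out(Gt)
    Ar, B2 = basis.project_out(GA)
    yr, b0 = basis.project_out(y[:, None])
    yr = yr[:, 0]
    b0 = b0[:, 0]

    s11 = np.einsum("ij,ij->j", Gr, Gr)
    s12 = np.einsum("ij,ij->j", Gr, Ar)
    s22 = np.einsum("ij,ij->j", Ar, Ar)
    t1 = Gr.T @ yr
    t2 = Ar.T @ yr
    det = s11 * s22 - s12 * s12
    with np.errstate(divide="ignore", invalid="ignore"):
        beta_g = (s22 * t1 - s12 * t2) / det
        beta_int = (s11 * t2 - s12 * t1) / det
        rss = float(yr @ yr) - beta_g * t1 - beta_int * t2
        sigma2 = np.maximum(rss, 0.0) / df_resid
        se_g = np.sqrt(sigma2 * s22 / det)
        se_int = np.sqrt(sigma2 * s11 / det)
        if return_age_terms:
            a = basis.age_idx
            beta_age = b0[a] - B1[a] * beta_g - B2[a] * beta_int
            w1, w2 = B1[a], B2[a]
            quad = (w1 * w1 * s22 - 2.0 * w1 * w2 * s12 + w2 * w2 * s11) / det
            se_age = np.sqrt(sigma2 * (basis.ctc_inv[a, a] + quad))
        else:
            beta_age = np.full(m, np.nan)
            se_age = np.full(m, np.nan)
        t_int = beta_int / se_int
    p_int = 2.0 * stats.t.sf(np.abs(t_int), df_resid)
    out = pd.DataFrame(
        {
            "beta_g": beta_g,
            "se_g": se_g,
            "beta_age": beta_age,
            "se_age": se_age,
            "beta_int": beta_int,
            "se_int": se_int,
            "t_int": t_int,
            "p_int": p_int,
        }
    )
    out["n"] = n
    out["df_resid"] = df_resid
    out["sigma2"] = sigma2
    out["ok"] = ~mono
    out.loc[mono, ["beta_g", "se_g", "beta_age", "se_age", "beta_int", "se_int", "t_int", "p_int", "sigma2"]] = np.nan
    return out


def fit_marginal_block(y, G, age, covars, return_age_terms: bool = True) -> pd.DataFrame:
    """Fit the marginal model for every variant row of ``G`` at once;
    exact per-variant equivalence as in :func:`fit_interaction_block`.

    Returns columns ``beta_g, se_g, beta_age, se_age, p_g, n, df_resid,
    sigma2, ok``.
    """
    y, Gt, age, basis, mono = _prepare_block(y, G, age, covars)
    n, m = Gt.shape
    k = basis.k
    df_resid = n - (k + 1)
    if df_resid <= 0:
        raise DimensionError("not enough samples for the marginal design")
    Gr, B1 = basis.project_out(Gt)
    yr, b0 = basis.project_out(y[:, None])
    yr = yr[:, 0]
    b0 = b0[:, 0]
    s11 = np.einsum("ij,ij->j", Gr, Gr)
    t1 = Gr.T @ yr
    with np.errstate(divide="ignore", invalid="ignore"):
        beta_g = t1 / s11
        rss = float(yr @ yr) - beta_g * t1
        sigma2 = np.maximum(rss, 0.0) / df_resid
        se_g = np.sqrt(sigma2 / s11)
        if return_age_terms:
            a = basis.age_idx
            beta_age = b0[a] - B1[a] * beta_g
            se_age = np.sqrt(sigma2 * (basis.ctc_inv[a, a] + B1[a] ** 2 / s11))
        else:
            beta_age = np.full(m, np.nan)
            se_age = np.full(m, np.nan)
        t_g = beta_g / se_g
    p_g = 2.0 * stats.t.sf(np.abs(t_g), df_resid)
    out = pd.DataFrame(
        {
            "beta_g": beta_g,
            "se_g": se_g,
            "beta_age": beta_age,
            "se_age": se_age,
            "p_g": p_g,
        }
    )
    out["n"] = n
    out["df_resid"] = df_resid
    out["sigma2"] = sigma2
    out["ok"] = ~mono
    out.loc[mono, ["beta_g", "se_g", "beta_age", "se_age", "p_g", "sigma2"]] = np.nan
    return out
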