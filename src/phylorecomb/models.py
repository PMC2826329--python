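"""Regression of log recombination rate on heterozygosity and life-form.

Three models mirror the comparative analysis: an uncorrected Gaussian GLM
(ordinary least squares), and two phylogeny-corrected fits in which the
species correlation matrix derived from the tree enters a generalized
estimating equation.  For a Gaussian identity-link model with a *fixed*
correlation matrix the GEE estimating equations collapse to generalized
least squares, so the corrected fits are computed in one GLS step:

    beta_hat = (X' R^-1 X)^-1 X' R^-1 y

with standard errors from sigma^2 (X' R^-1 X)^-1 and two-sided t
p-values on n - p degrees of freedom.  The second corrected model splits
"tree" into angiosperm and conifer trees via an extra dummy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

__all__ = [
    "ModelFit",
    "build_design",
    "fit_gaussian",
    "fitted_group_means",
    "kruskal_wallis",
]

# column order: intercept, He, herb, shrub, (conifer tree)
BASELINE = "tree"


@dataclass
class ModelFit:
    """Coefficients, standard errors and p-values from one model."""

    params: pd.Series
    se: pd.Series
    p_values: pd.Series
    cov_params: pd.DataFrame
    sigma2: float
    df_resid: int
    method: str  # "uncorrected" | "phylo_gee"
    n_obs: int
    corr_fingerprint: Optional[float] = None  # mean off-diagonal of R

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "estimate": self.params,
            "se": self.se,
            "p_value": self.p_values,
        })


def build_design(table: pd.DataFrame, conifer_separate: bool = False):
    """Response vector and design matrix for the rate ~ He + life-form model.

    Baseline life-form is (angiosperm) tree; herbs and shrubs get 0/1
    dummies.  With ``conifer_separate`` an extra "conifer tree" dummy
    splits conifer trees from the angiosperm-tree baseline.  Factor
    levels absent from the data are dropped with a warning.
    """
    if table.empty:
        raise ValueError("empty rate table")
    y = table["log_rate"].to_numpy(dtype=float)
    cols = {"intercept": np.ones(len(table)), "he": table["he"].to_numpy(dtype=float)}
    lf = table["life_form"].to_numpy()
    tg = table["taxon_group"].to_numpy()
    dummies = {
        "herb": (lf == "herb").astype(float),
        "shrub": (lf == "shrub").astype(float),
    }
    if conifer_separate:
        dummies["conifer_tree"] = ((lf == "tree") & (tg == "conifer")).astype(float)
    for name, col in dummies.items():
        if col.sum() == 0:
            warnings.warn(f"factor level {name!r} absent from data; column dropped")
            continue
        cols[name] = col
    X = pd.DataFrame(cols, index=table.index)
    return y, X


def fit_gaussian(
    y: np.ndarray,
    X: pd.DataFrame,
    R: Optional[np.ndarray] = None,
) -> ModelFit:
    """Gaussian GLS fit of y on X with correlation matrix R.

    ``R = None`` (or the identity) gives ordinary least squares; any
    symmetric positive-definite R gives the phylogeny-corrected fit.
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"x{i}" for i in range(np.asarray(X).shape[1])]
    Xm = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = Xm.shape
    if n <= p:
        raise ValueError("more parameters than observations")
    method = "uncorrected"
    fingerprint = None
    if R is None:
        Xw, yw = Xm, y
    else:
        R = np.asarray(R, dtype=float)
        if R.shape != (n, n):
            raise ValueError("correlation matrix dimension mismatch")
        if not np.allclose(R, R.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        try:
            L = linalg.cholesky(R, lower=True)
        except linalg.LinAlgError as exc:
            raise ValueError("correlation matrix not positive definite") from exc
        Xw = linalg.solve_triangular(L, Xm, lower=True)
        yw = linalg.solve_triangular(L, y, lower=True)
        if not np.allclose(R, np.eye(n)):
            method = "phylo_gee"
            off = R[~np.eye(n, dtype=bool)]
            fingerprint = float(off.mean()) if off.size else 0.0

    XtX = Xw.T @ Xw
    if np.linalg.matrix_rank(XtX) < p:
        raise ValueError("design matrix is rank deficient")
    XtX_inv = linalg.inv(XtX)
    beta = XtX_inv @ (Xw.T @ yw)
    resid = yw - Xw @ beta
    df = n - p
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * XtX_inv
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    idx = pd.Index(names)
    return ModelFit(
        params=pd.Series(beta, index=idx),
        se=pd.Series(se, index=idx),
        p_values=pd.Series(pvals, index=idx),
        cov_params=pd.DataFrame(cov, index=idx, columns=idx),
        sigma2=sigma2,
        df_resid=df,
        method=method,
        n_obs=n,
        corr_fingerprint=fingerprint,
    )


def fitted_group_means(fit: ModelFit, at_he: Optional[float] = None) -> pd.DataFrame:
    """Fitted log rate per life-form, with delta-method standard errors.

    The baseline (tree) mean is the intercept; each other level adds its
    coefficient.  With ``at_he`` given the He term is evaluated there;
    by default means are reported at the intercept scale (He absorbed).
    """
    levels = {"tree": []}
    for name in fit.params.index:
        if name in ("intercept", "he"):
            continue
        levels[name] = [name]
    rows = []
    for level, extra in levels.items():
        c = pd.Series(0.0, index=fit.params.index)
        c["intercept"] = 1.0
        if at_he is not None and "he" in c.index:
            c["he"] = at_he
        for name in extra:
            c[name] = 1.0
        mean = float(c @ fit.params)
        var = float(c @ fit.cov_params @ c)
        rows.append({"life_form": level, "fitted_log_rate": mean,
                     "se": np.sqrt(var)})
    return pd.DataFrame(rows)


def kruskal_wallis(groups: Sequence[Sequence[float]]):
    """Kruskal-Wallis rank test across groups (tie-corrected H).

    Returns a dict with H, degrees of freedom (k - 1) and the chi-square
    p-value.  All-identical values across groups make the statistic
    degenerate (H = 0, p = 1).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    pooled = np.concatenate(groups)
    if len(np.unique(pooled)) < 2:
        return {"H": 0.0, "df": len(groups) - 1, "p_value": 1.0}
    H, p = stats.kruskal(*groups)
    return {"H": float(H), "df": len(groups) - 1, "p_value": float(p)}
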