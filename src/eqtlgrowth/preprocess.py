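"""Phenotype preprocessing: covariate correction and standardization.

Expression is corrected per gene by ordinary least squares on the
measurement batch (a factor) and the culture density at RNA extraction
(OD600, numeric); the residuals carry forward. Growth is not
covariate-corrected, but a per-condition correction for growth on the base
medium (YNB or YPD) is available. Both matrices are finally standardized
column-wise to mean 0 and standard deviation 1 over non-missing entries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import PhenotypeMatrix, ValidationError


@dataclass
class RegressionFit:
    """Coefficients and residuals of a single OLS covariate fit."""

    coefficients: pd.Series
    residuals: np.ndarray


def _design_matrix(covariates: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Intercept + batch factor contrasts + numeric od600."""
    n = len(covariates)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    if "batch" in covariates.columns:
        levels = pd.unique(covariates["batch"])
        counts = covariates["batch"].value_counts()
        lonely = counts[counts == 1]
        if len(lonely):
            warnings.warn(
                f"batch level(s) {list(lonely.index)} have a single segregant; "
                "the fit is still valid but the level is absorbed exactly"
            )
        for lev in levels[1:]:  # first level is the reference
            cols.append((covariates["batch"] == lev).to_numpy(float))
            names.append(f"batch[{lev}]")
    if "od600" in covariates.columns:
        cols.append(covariates["od600"].to_numpy(float))
        names.append("od600")
    return np.column_stack(cols), names


def ols_residuals(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares residuals of each column of Y on the design X."""
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - X @ beta, beta


def correct_expression(expr: PhenotypeMatrix) -> tuple[PhenotypeMatrix, list[RegressionFit]]:
    """Regress batch and OD600 out of every gene's expression.

    Returns the residual matrix (same labels, covariates dropped) together
    with the per-gene fits.
    """
    if expr.covariates is None:
        raise ValidationError("expression covariates (batch / od600) are required")
    if not {"batch", "od600"} & set(expr.covariates.columns):
        raise ValidationError("covariates must include 'batch' and/or 'od600'")
    X, names = _design_matrix(expr.covariates)
    resid, beta = ols_residuals(expr.values, X)
    fits = [
        RegressionFit(pd.Series(beta[:, j], index=names), resid[:, j])
        for j in range(expr.n_traits)
    ]
    out = PhenotypeMatrix(
        resid, list(expr.trait_ids), list(expr.segregant_ids), None, expr.kind
    )
    return out, fits


def standardize(pheno: PhenotypeMatrix) -> PhenotypeMatrix:
    """Column-wise z-score over non-missing entries; SD uses n-1.

    Constant columns are left as all-zero (flagged via ``constant_traits``
    attribute on the returned object).
    """
    V = pheno.values.copy()
    constant: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(V, axis=0)
        sd = np.nanstd(V, axis=0, ddof=1)
    for j in range(V.shape[1]):
        if not np.isfinite(sd[j]) or sd[j] == 0:
            V[:, j] = np.where(np.isnan(V[:, j]), np.nan, 0.0)
            constant.append(pheno.trait_ids[j])
        else:
            V[:, j] = (V[:, j] - mean[j]) / sd[j]
    out = PhenotypeMatrix(
        V, list(pheno.trait_ids), list(pheno.segregant_ids), pheno.covariates, pheno.kind
    )
    out.constant_traits = constant  # type: ignore[attr-defined]
    return out


def correct_base_medium(
    growth_cond: np.ndarray, growth_base: np.ndarray, min_pairs: int = 3
) -> np.ndarray:
    """Residualize growth in a condition on growth in its base medium.

    Fits ``G_i = alpha * G_b + intercept`` on pairwise-complete segregants
    and returns residuals (NaN where either input is missing).
    """
    gc = np.asarray(growth_cond, float)
    gb = np.asarray(growth_base, float)
    if gc.shape != gb.shape:
        raise ValidationError("condition and base growth must share segregants")
    ok = ~np.isnan(gc) & ~np.isnan(gb)
    if ok.sum() < min_pairs:
        raise ValidationError(
            f"only {int(ok.sum())} complete pairs; need at least {min_pairs}"
        )
    X = np.column_stack([np.ones(ok.sum()), gb[ok]])
    beta, *_ = np.linalg.lstsq(X, gc[ok], rcond=None)
    out = np.full_like(gc, np.nan)
    out[ok] = gc[ok] - X @ beta
    return out
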