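"""Univariable additive-allelic association scans.

Each variant's alternate-allele dosage is regressed on the (normalised)
trait by ordinary least squares with nuisance covariates — donor-clinic
dummies and the leading genotype principal components — projected out
once via Frisch-Waugh-Lovell, which makes the per-variant fits exact
and fast.  OLS stands in for the mixed model the field uses at biobank
scale; on unrelated samples the two coincide.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2
from scipy.stats import t as t_dist

from .synthdata import GenotypeMatrix

#: null median of a 1-df chi-squared variable
CHI2_NULL_MEDIAN = float(chi2.ppf(0.5, df=1))


def variant_filters(
    variants: pd.DataFrame, maf_min: float = 0.0004, info_min: float = 0.4
) -> pd.DataFrame:
    """Quality-control filter: keep variants with MAF > 0.04% and INFO > 0.4."""
    keep = (variants["maf"] > maf_min) & (variants["info"] > info_min)
    return variants.loc[keep]


def genotype_pcs(dosages: np.ndarray, k: int = 10) -> np.ndarray:
    """Leading principal-component score vectors of the dosage matrix."""
    x = dosages - dosages.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    x = x / sd
    k = min(k, min(x.shape) - 1)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    return u[:, :k] * s[:k]


def build_covariates(cov: pd.DataFrame | None, pcs: np.ndarray | None) -> np.ndarray:
    """Assemble the nuisance design: intercept + clinic dummies + PC scores."""
    n = len(cov) if cov is not None else (pcs.shape[0] if pcs is not None else 0)
    cols = [np.ones((n, 1))]
    if cov is not None and "clinic" in cov:
        clin = cov["clinic"].astype(str).to_numpy()
        levels = sorted(np.unique(clin))[1:]
        for lev in levels:
            cols.append((clin == lev).astype(float).reshape(-1, 1))
    if pcs is not None:
        cols.append(pcs)
    return np.concatenate(cols, axis=1)


def residualize(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Project out the covariate space (least-squares residual)."""
    beta, *_ = np.linalg.lstsq(covariates, y, rcond=None)
    return y - covariates @ beta


def _orthonormal_basis(covariates: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the covariate column space (rank-safe QR)."""
    q, r = np.linalg.qr(covariates)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r[0, 0]))
    return q[:, keep]


def run_univariable(
    trait: np.ndarray,
    g: GenotypeMatrix,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-variant OLS of trait on dosage plus covariates (Wald test).

    Missing dosages are mean-imputed per variant.  Monomorphic variants
    are flagged not-testable (``testable`` False, NaN statistics).
    Returns a summary-statistics frame with columns
    (id, chrom, pos, ref, alt, beta, se, p, n, maf, info, testable).
    """
    y = np.asarray(trait, dtype=float)
    n = len(y)
    if covariates is None:
        covariates = np.ones((n, 1))
    q = _orthonormal_basis(covariates)
    k = q.shape[1]
    y_r = y - q @ (q.T @ y)

    dos = g.dosages
    if np.isnan(dos).any():
        dos = dos.copy()
        means = np.nanmean(dos, axis=0)
        nan_r, nan_c = np.where(np.isnan(dos))
        dos[nan_r, nan_c] = means[nan_c]

    # moment computations avoid materialising the residualised dosage
    # matrix: sxy = x'y_r (y_r already orthogonal to the covariates) and
    # sxx = x'x - ||q'x||^2 columnwise
    qx = q.T @ dos
    sxx = np.einsum("ij,ij->j", dos, dos) - np.einsum("ij,ij->j", qx, qx)
    sxy = dos.T @ y_r

    testable = sxx > 1e-12
    df = n - k - 1
    beta = np.full(dos.shape[1], np.nan)
    se = np.full(dos.shape[1], np.nan)
    p = np.full(dos.shape[1], np.nan)

    with np.errstate(invalid="ignore", divide="ignore"):
        b = sxy / sxx
        rss = np.sum(y_r**2) - b * sxy
        s2 = rss / df
        se_all = np.sqrt(s2 / sxx)
        tstat = b / se_all
    beta[testable] = b[testable]
    se[testable] = se_all[testable]
    p[testable] = 2 * t_dist.sf(np.abs(tstat[testable]), df=df)

    out = g.variants[["id", "chrom", "pos", "ref", "alt", "maf", "info"]].copy()
    out["beta"] = beta
    out["se"] = se
    out["p"] = p
    out["n"] = n
    out["testable"] = testable
    return out


def gc_lambda(pvals: np.ndarray) -> float:
    """Genomic-control inflation factor.

    The p-values are mapped back to 1-df chi-squared statistics and the
    median statistic is divided by the null median (about 0.455).
    """
    p = np.asarray(pvals, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("gc_lambda needs at least one p-value")
    stats = chi2.isf(p, df=1)
    return float(np.median(stats) / CHI2_NULL_MEDIAN)
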