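"""Kinship, heritability and mixed-model GWAS for accession phenotypes.

Phenotypes are accession-level summaries of the microbiome (richness
BLUPs, BLUP-PCA scores, the bacteria-vs-fungi preference).  Relatedness
is the standardized genomic relationship matrix (GRM) K = Z Z' / m over
MAF-filtered SNPs.  Narrow-sense SNP heritability comes from REML on the
one-random-effect model y = mu + g + e, g ~ N(0, sg2 K), solved by a
single spectral decomposition of K and one-dimensional Brent search over
the heritability ratio.  GWAS uses the same machinery: variance
components are estimated once on the null model and every SNP is tested
by generalized least squares under V = sg2 K + se2 I (the EMMAX
approximation), with a genomic-control lambda reported.  Genome-wide
significance is calibrated by phenotype permutations in the whitened
space of the fitted covariance (Cholesky transform), which preserves the
relatedness structure under the null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .datamodel import GenotypeMatrix
from .glmm import PoissonGLMMResult

logger = logging.getLogger(__name__)

__all__ = ["KinshipMatrix", "HeritabilityEstimate", "BroadSenseEstimate",
           "GwasResult", "kinship", "reml_h2", "broad_sense_h2", "gwas_scan",
           "cholesky_perm_threshold", "window_summary", "overlap_scatter"]

CHI2_MEDIAN_1DF = stats.chi2.ppf(0.5, 1)  # ~0.4549


@dataclass
class KinshipMatrix:
    values: np.ndarray
    accessions: list[str]
    method: str = "standardized-GRM"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.accessions)
        if self.values.shape != (n, n):
            raise ValueError("kinship shape must match accession list")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship must be symmetric")

    def check_psd(self, tol: float = 1e-8) -> None:
        w = np.linalg.eigvalsh(self.values)
        if w.min() < -tol * max(1.0, w.max()):
            raise ValueError(f"kinship not PSD: min eigenvalue {w.min():.3g}")


def kinship(geno: GenotypeMatrix) -> KinshipMatrix:
    """Standardized GRM: K = Z Z' / m with per-SNP mean-0, variance-1
    columns.  Monomorphic SNPs are dropped; tiny negative eigenvalues
    from roundoff are clipped to keep K positive semi-definite."""
    X = geno.imputed()
    sd = X.std(axis=0)
    poly = sd > 0
    if not poly.all():
        logger.warning("kinship: dropping %d monomorphic SNP(s)",
                       int((~poly).sum()))
    X = X[:, poly]
    if X.shape[1] == 0:
        raise ValueError("no polymorphic SNPs for kinship")
    Z = (X - X.mean(axis=0)) / X.std(axis=0)
    K = Z @ Z.T / Z.shape[1]
    K = (K + K.T) / 2.0
    w, U = np.linalg.eigh(K)
    if w.min() < -1e-8:
        K = (U * np.clip(w, 0.0, None)) @ U.T
        K = (K + K.T) / 2.0
    return KinshipMatrix(values=K, accessions=list(geno.accession_ids))


@dataclass
class HeritabilityEstimate:
    sigma2_g: float
    sigma2_e: float
    h2: float
    loglik: float
    method: str = "REML-spectral"
    boundary: bool = False


def _reml_spectral(y: np.ndarray, X: np.ndarray, lam: np.ndarray,
                   Ut: np.ndarray, tol: float = 1e-8
                   ) -> HeritabilityEstimate:
    """REML over h2 for y = X b + g + e with eigendecomposed K."""
    n, p = X.shape
    yt = Ut @ y
    Xt = Ut @ X

    def negll(h2: float) -> float:
        return -_reml_loglik(h2, yt, Xt, lam, n, p)[0]

    res = minimize_scalar(negll, bounds=(1e-9, 1.0 - 1e-9), method="bounded",
                          options={"xatol": tol})
    h2 = float(res.x)
    ll, s2_total = _reml_loglik(h2, yt, Xt, lam, n, p)
    boundary = h2 < 1e-6 or h2 > 1.0 - 1e-6
    if h2 < 1e-6:
        h2 = 0.0
    elif h2 > 1.0 - 1e-6:
        h2 = 1.0
    return HeritabilityEstimate(
        sigma2_g=h2 * s2_total, sigma2_e=(1.0 - h2) * s2_total, h2=h2,
        loglik=float(ll), boundary=boundary,
    )


def _reml_loglik(h2, yt, Xt, lam, n, p) -> tuple[float, float]:
    w = h2 * lam + (1.0 - h2)
    w = np.maximum(w, 1e-12)
    wi = 1.0 / w
    XtWX = (Xt * wi[:, None]).T @ Xt
    XtWy = (Xt * wi[:, None]).T @ yt
    try:
        beta = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError:
        beta = np.linalg.lstsq(XtWX, XtWy, rcond=None)[0]
    r = yt - Xt @ beta
    quad = float(np.sum(r * r * wi))
    s2 = quad / (n - p)
    sign, logdet_xwx = np.linalg.slogdet(XtWX)
    ll = -0.5 * (
        (n - p) * np.log(2.0 * np.pi * s2) + (n - p)
        + np.sum(np.log(w)) + logdet_xwx
    )
    return float(ll), float(s2)


def reml_h2(y, K: KinshipMatrix, X: np.ndarray | None = None
            ) -> HeritabilityEstimate:
    """SNP heritability of an accession-level phenotype by spectral REML.

    ``y`` may be a Series indexed by accession (aligned to K) or an
    array in K's accession order.  ``X`` defaults to the intercept.
    """
    if isinstance(y, pd.Series):
        y = y.reindex(K.accessions).to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) != len(K.accessions):
        raise ValueError("phenotype length must match kinship accessions")
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype contains non-finite values")
    K.check_psd()
    if X is None:
        X = np.ones((len(y), 1))
    lam, U = np.linalg.eigh(K.values)
    lam = np.clip(lam, 0.0, None)
    return _reml_spectral(y, X, lam, U.T)


@dataclass
class BroadSenseEstimate:
    sigma2_accession: float
    sigma2_other_random: float
    sigma2_fixed: float
    sigma2_dist: float
    H2: float


def broad_sense_h2(fit: PoissonGLMMResult) -> BroadSenseEstimate:
    """Broad-sense heritability from a fitted Poisson richness/abundance GLMM.

    The accession share of the latent (log) scale variance:

        H2 = s2_accession / (s2_fixed + s2_accession + s2_dist),

    with s2_fixed the variance of the fixed-effect linear predictor and
    s2_dist = ln(1 + 1/rate) the log-link distribution-specific variance
    at the model's geometric-mean rate — the conditional-minus-marginal
    R2 attributable to the accession random effect.
    """
    s2_fixed = fit.var_fixed()
    rate = fit.mean_rate()
    s2_dist = float(np.log1p(1.0 / rate))
    s2_acc = fit.sigma2_group
    total = s2_fixed + s2_acc + s2_dist
    return BroadSenseEstimate(
        sigma2_accession=s2_acc,
        sigma2_other_random=0.0,
        sigma2_fixed=s2_fixed,
        sigma2_dist=s2_dist,
        H2=s2_acc / total if total > 0 else 0.0,
    )


@dataclass
class GwasResult:
    table: pd.DataFrame          # chrom, pos, beta, se, stat, p
    lambda_gc: float
    sigma2_g: float
    sigma2_e: float
    threshold: float | None = None

    @property
    def p(self) -> np.ndarray:
        return self.table["p"].to_numpy()


def _gwas_core(yt: np.ndarray, st: np.ndarray, it: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP GLS in the whitened space.

    ``yt``: whitened phenotype; ``st``: whitened SNP columns (n x m);
    ``it``: whitened intercept.  Returns (beta, se, t-stat); zero-variance
    (collinear) SNPs give NaN.
    """
    n = len(yt)
    ii = float(it @ it)
    # residualize y and every SNP on the whitened intercept
    yr = yt - it * (it @ yt) / ii
    proj = (it @ st) / ii
    sr = st - np.outer(it, proj)
    ss = np.einsum("ij,ij->j", sr, sr)
    sy = sr.T @ yr
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sy / ss
        rss = float(yr @ yr) - beta * sy
        dof = n - 2
        se = np.sqrt(np.maximum(rss, 0.0) / dof / ss)
        tstat = beta / se
    bad = ss <= 1e-12 * n
    beta[bad] = np.nan
    se[bad] = np.nan
    tstat[bad] = np.nan
    return beta, se, tstat


def gwas_scan(y, geno: GenotypeMatrix, K: KinshipMatrix,
              vc: HeritabilityEstimate | None = None) -> GwasResult:
    """Mixed-model association scan (EMMAX-style).

    Variance components are estimated once on the null model (unless
    supplied), the phenotype/genotypes are rotated into the eigenbasis of
    K and scaled by the fitted variances, and each SNP is tested by GLS
    with a t-test on n - 2 degrees of freedom.
    """
    if isinstance(y, pd.Series):
        y = y.reindex(K.accessions).to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    if list(geno.accession_ids) != list(K.accessions):
        raise ValueError("genotype and kinship accession order disagree")
    if vc is None:
        vc = reml_h2(y, K)
    lam, U = np.linalg.eigh(K.values)
    lam = np.clip(lam, 0.0, None)
    w = vc.sigma2_g * lam + vc.sigma2_e
    w = np.maximum(w, 1e-12 * w.max())
    scale = 1.0 / np.sqrt(w)
    Ut = U.T
    yt = scale * (Ut @ y)
    it = scale * (Ut @ np.ones(len(y)))
    st = scale[:, None] * (Ut @ geno.imputed())
    beta, se, tstat = _gwas_core(yt, st, it)
    dof = len(y) - 2
    p = 2.0 * stats.t.sf(np.abs(tstat), df=dof)
    ok = np.isfinite(p)
    chi2 = stats.chi2.isf(np.clip(p[ok], 1e-300, 1.0), 1)
    lambda_gc = float(np.median(chi2) / CHI2_MEDIAN_1DF) if ok.any() else np.nan
    table = pd.DataFrame({
        "chrom": geno.chrom, "pos": geno.pos, "beta": beta, "se": se,
        "stat": tstat, "p": p,
    })
    return GwasResult(table=table, lambda_gc=lambda_gc,
                      sigma2_g=vc.sigma2_g, sigma2_e=vc.sigma2_e)


def ols_scan(y, geno: GenotypeMatrix) -> GwasResult:
    """Naive per-SNP OLS scan (no relatedness correction); the
    structured-confounding comparator for the mixed model."""
    if isinstance(y, pd.Series):
        y = y.reindex(geno.accession_ids).to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    beta, se, tstat = _gwas_core(y, geno.imputed(), np.ones(n))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    ok = np.isfinite(p)
    chi2 = stats.chi2.isf(np.clip(p[ok], 1e-300, 1.0), 1)
    table = pd.DataFrame({
        "chrom": geno.chrom, "pos": geno.pos, "beta": beta, "se": se,
        "stat": tstat, "p": p,
    })
    return GwasResult(table=table,
                      lambda_gc=float(np.median(chi2) / CHI2_MEDIAN_1DF),
                      sigma2_g=0.0, sigma2_e=float(np.var(y)))


def cholesky_perm_threshold(
    y, geno: GenotypeMatrix, K: KinshipMatrix,
    n_perm: int = 100, alpha: float = 0.05, seed: int | None = None,
) -> float:
    """Genome-wide p-value threshold by structure-preserving permutation.

    The phenotype is whitened with the Cholesky factor of the fitted
    phenotypic covariance (y* = L^-1 y, so y* has covariance sg2 I under
    the null); each permutation shuffles y*, back-transforms
    y_perm = L P y*, rescans the genome, and records the minimum
    p-value.  The threshold is the empirical alpha-quantile of those
    minima.
    """
    if n_perm < 20:
        raise ValueError("n_perm < 20 gives an unstable quantile; refuse")
    if isinstance(y, pd.Series):
        y = y.reindex(K.accessions).to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    vc = reml_h2(y, K)
    V = vc.sigma2_g * K.values + vc.sigma2_e * np.eye(len(y))
    L = np.linalg.cholesky(V + 1e-10 * np.trace(V) / len(y) * np.eye(len(y)))
    y_white = np.linalg.solve(L, y)
    rng = np.random.default_rng(seed)
    minima = np.empty(n_perm)
    for b in range(n_perm):
        y_perm = L @ y_white[rng.permutation(len(y))]
        res = gwas_scan(y_perm, geno, K, vc=vc)
        minima[b] = np.nanmin(res.p)
    return float(np.quantile(minima, alpha))


def window_summary(res: GwasResult, window_bp: int = 10_000) -> pd.DataFrame:
    """Minimum p-value per half-open genomic window [k*w, (k+1)*w).

    Windows are 0-based: a SNP at 1-based position ``pos`` falls in
    window (pos - 1) // window_bp.  Windows without SNPs are absent.
    """
    tab = res.table.dropna(subset=["p"]).copy()
    tab["window"] = (tab["pos"] - 1) // window_bp
    out = (
        tab.groupby(["chrom", "window"], sort=True)["p"].min()
        .reset_index().rename(columns={"p": "min_p"})
    )
    out["window_start"] = out["window"] * window_bp + 1  # 1-based
    return out


def overlap_scatter(res1: GwasResult, res2: GwasResult,
                    window_bp: int = 10_000) -> pd.DataFrame:
    """Join per-window minimum p-values of two scans on window id."""
    w1 = window_summary(res1, window_bp).rename(columns={"min_p": "min_p_1"})
    w2 = window_summary(res2, window_bp).rename(columns={"min_p": "min_p_2"})
    return w1.merge(w2[["chrom", "window", "min_p_2"]],
                    on=["chrom", "window"], how="outer")
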