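"""Accelerated linear mixed-model association scan (EMMA/EMMAX style).

Model: y = mu + x*beta + g + e with g ~ N(0, sg2*K) and e ~ N(0, se2*I),
where K is an identity-by-state kinship computed from homozygous calls
(heterozygous calls are excluded throughout, since in this application they
are the artifact under study, not genotypes).

The acceleration is the standard EMMAX approximation: the variance ratio
delta = se2/sg2 is fitted once by REML under the null (no SNP term) using
the eigendecomposition of K, then every SNP is tested by generalized least
squares in the rotated, whitened coordinate system, which costs O(n) per
SNP. Binary 0/1 phenotypes are treated as Gaussian.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import eigh
from scipy.optimize import minimize_scalar

from .io_formats import GenotypeMatrix, HET, HOM_ALT, HOM_REF

log = logging.getLogger(__name__)

LOGP_CAP = 300.0  # p-values below 1e-300 are reported as -log10 p = 300
_LOG_DELTA_RANGE = (-10.0, 10.0)


@dataclass
class KinshipMatrix:
    K: np.ndarray
    method: str = "ibs"

    def validate(self, tol: float = 1e-8) -> None:
        K = self.K
        if not np.allclose(K, K.T, atol=1e-12):
            raise ValueError("kinship not symmetric")
        if (K.max(axis=1) > K.diagonal() + 1e-12).any():
            raise ValueError("kinship diagonal not maximal per row")
        if eigh(K, eigvals_only=True, subset_by_index=[0, 0])[0] < -tol:
            raise ValueError("kinship not positive semidefinite")


@dataclass
class VarianceComponents:
    delta: float  # se2 / sg2
    sigma_g2: float
    sigma_e2: float
    eigenvalues: np.ndarray  # of K
    rotation: np.ndarray  # eigenvectors U (columns)

    @property
    def heritability(self) -> float:
        return 1.0 / (1.0 + self.delta)


def compute_kinship(gm: GenotypeMatrix, method: str = "ibs",
                    psd_repair: bool = True) -> KinshipMatrix:
    """Identity-by-state kinship over homozygous, non-missing calls.

    K[i, j] = fraction of co-typed SNPs at which i and j carry the same
    homozygous genotype; het and missing calls are ignored. ``method=
    "vanraden"`` gives the centered-genotype alternative instead.

    Because each pair has its own co-typing denominator, the raw IBS ratio
    matrix can carry small negative eigenvalues; ``psd_repair`` clips them
    at zero (eigendecomposition + reconstruction), which perturbs entries
    by at most the clipped magnitude and makes K a valid random-effect
    covariance. Disable to inspect the raw ratios.
    """
    if gm.n_accessions < 2:
        raise ValueError("need >= 2 accessions")
    c = gm.calls
    A0 = (c == HOM_REF).astype(np.float64)
    A2 = (c == HOM_ALT).astype(np.float64)
    valid = A0 + A2
    den = valid.T @ valid
    if (den == 0).any():
        i, j = np.argwhere(den == 0)[0]
        raise ValueError(f"accessions {gm.accessions[i]}/{gm.accessions[j]} "
                         "share no co-typed homozygous SNP")
    if method == "ibs":
        num = A0.T @ A0 + A2.T @ A2
        K = num / den
        np.fill_diagonal(K, 1.0)
    elif method == "vanraden":
        x = np.where(valid > 0, A2, np.nan)
        p = np.nanmean(x, axis=1)
        z = np.where(valid > 0, A2 - p[:, None], 0.0)
        norm = 2 * np.sum(p * (1 - p))
        K = (z.T @ z) / max(norm, 1e-12)
    else:
        raise ValueError(f"unknown kinship method {method}")
    K = (K + K.T) / 2
    if psd_repair:
        lam, U = eigh(K)
        if lam[0] < 0:
            K = (U * np.clip(lam, 0.0, None)) @ U.T
            K = (K + K.T) / 2
    return KinshipMatrix(K, method)


def _reml_criterion(log_delta, lam, yt, xt):
    """Profiled restricted log-likelihood (up to a constant) at log delta."""
    delta = np.exp(log_delta)
    w = 1.0 / (lam + delta)
    xtwx = np.sum(w * xt * xt)
    beta = np.sum(w * xt * yt) / xtwx
    r = yt - xt * beta
    rss = np.sum(w * r * r)
    n, q = len(yt), 1
    return -0.5 * ((n - q) * np.log(rss) + np.sum(np.log(lam + delta))
                   + np.log(xtwx))


def fit_null(y: np.ndarray, kinship: KinshipMatrix,
             grid_points: int = 64, tol: float = 1e-6) -> VarianceComponents:
    """One-time REML fit of the variance ratio delta under the null model.

    Maximizes the restricted likelihood over log-delta in [-10, 10] by a
    grid pre-scan plus bounded Brent refinement. A criterion that is flat
    in delta (e.g. K = I) is non-identifiable; by convention the fit then
    returns the upper delta bound, i.e. heritability 0.
    """
    y = np.asarray(y, dtype=np.float64)
    if np.ptp(y) == 0:
        raise ValueError("phenotype invariant")
    lam, U = eigh(kinship.K)
    lam = np.clip(lam, 0.0, None)
    yt = U.T @ y
    xt = U.T @ np.ones_like(y)

    grid = np.linspace(*_LOG_DELTA_RANGE, grid_points)
    vals = np.array([_reml_criterion(g, lam, yt, xt) for g in grid])
    if np.ptp(vals) < 1e-9:  # flat likelihood: non-identifiable
        best_ld = _LOG_DELTA_RANGE[1]
    else:
        i = int(np.argmax(vals))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, grid_points - 1)]
        res = minimize_scalar(lambda g: -_reml_criterion(g, lam, yt, xt),
                              bounds=(lo, hi), method="bounded",
                              options={"xatol": tol})
        best_ld = float(res.x)
        if vals[i] > -res.fun:
            best_ld = float(grid[i])
    delta = float(np.exp(best_ld))

    w = 1.0 / (lam + delta)
    xtwx = np.sum(w * xt * xt)
    beta = np.sum(w * xt * yt) / xtwx
    r = yt - xt * beta
    sigma_g2 = float(np.sum(w * r * r) / (len(y) - 1))
    return VarianceComponents(delta, sigma_g2, delta * sigma_g2, lam, U)


def _dosage(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP 0/1 dosage with het and missing as NaN, plus hom MAF."""
    c = gm.calls.astype(np.float64)
    x = np.where(c == HOM_REF, 0.0, np.where(c == HOM_ALT, 1.0, np.nan))
    n_valid = (~np.isnan(x)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.nansum(np.nan_to_num(x), axis=1) / n_valid
    maf = np.where(n_valid > 0, np.minimum(f, 1 - f), np.nan)
    return x, maf


def scan(y: np.ndarray, gm: GenotypeMatrix, kinship: KinshipMatrix,
         vc: VarianceComponents | None = None,
         refit_per_snp: bool = False) -> pd.DataFrame:
    """EMMAX generalized-least-squares test of every SNP against y.

    Het calls are excluded from the genotype coding (0/2 -> 0/1 dosage,
    het/missing -> NaN, then per-SNP mean imputation). Returns a DataFrame
    with snp_id, chrom, pos, maf, beta, minus_log10_p; SNPs with zero
    dosage variance after imputation are skipped. ``refit_per_snp`` re-fits
    delta for each SNP model by exact REML (slow; for oracle checking).
    """
    y = np.asarray(y, dtype=np.float64)
    if vc is None:
        vc = fit_null(y, kinship)
    x, maf = _dosage(gm)
    # per-SNP mean imputation of het/missing dosages
    valid = ~np.isnan(x)
    means = np.nansum(np.nan_to_num(x), axis=1) / np.maximum(valid.sum(axis=1), 1)
    x = np.where(valid, x, means[:, None])

    keep = np.nanstd(x, axis=1) > 0
    n_skip = int((~keep).sum())
    if n_skip:
        log.info("scan: skipped %d zero-variance SNPs", n_skip)

    if refit_per_snp:
        logp, beta = _scan_exact(y, x, kinship, keep)
    else:
        logp, beta = _scan_emmax(y, x, vc, keep)

    df = pd.DataFrame(dict(snp_id=gm.snp_ids, chrom=gm.chrom, pos=gm.pos,
                           maf=maf, beta=beta, minus_log10_p=logp))
    return df[keep].reset_index(drop=True)


def _scan_emmax(y, x, vc, keep):
    n = len(y)
    U, lam, delta = vc.rotation, vc.eigenvalues, vc.delta
    w = 1.0 / (lam + delta)
    yt = U.T @ y
    ot = U.T @ np.ones(n)
    Xt = x @ U  # row s = rotated dosage of SNP s

    a = np.sum(w * ot * ot)
    p = np.sum(w * ot * yt)
    yy = np.sum(w * yt * yt)
    b = Xt @ (w * ot)
    q = Xt @ (w * yt)
    cc = np.sum(w * Xt * Xt, axis=1)
    det = a * cc - b * b

    with np.errstate(divide="ignore", invalid="ignore"):
        beta1 = (a * q - b * p) / det
        beta0 = (cc * p - b * q) / det
        rss = np.maximum(yy - beta0 * p - beta1 * q, 0.0)
        sigma2 = rss / (n - 2)
        var_beta = sigma2 * a / det
        tstat = beta1 / np.sqrt(var_beta)
    pval = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
    pval = np.where(np.isfinite(tstat), pval, 0.0)
    logp = -np.log10(np.maximum(pval, 1e-300))
    logp = np.minimum(logp, LOGP_CAP)
    logp[~keep] = np.nan
    return logp, beta1


def _scan_exact(y, x, kinship, keep):
    """Per-SNP exact REML refit (two-covariate model); oracle-grade, slow."""
    n = len(y)
    lam, U = eigh(kinship.K)
    lam = np.clip(lam, 0.0, None)
    yt = U.T @ y
    logp = np.full(x.shape[0], np.nan)
    beta = np.full(x.shape[0], np.nan)
    for s in np.flatnonzero(keep):
        Xs = np.column_stack([np.ones(n), x[s]])
        Xt = U.T @ Xs

        def crit(ld):
            w = 1.0 / (lam + np.exp(ld))
            XtW = Xt * w[:, None]
            G = Xt.T @ XtW
            bh = np.linalg.solve(G, XtW.T @ yt)
            r = yt - Xt @ bh
            rss = np.sum(w * r * r)
            return -0.5 * ((n - 2) * np.log(rss) + np.sum(np.log(lam + np.exp(ld)))
                           + np.linalg.slogdet(G)[1])

        grid = np.linspace(*_LOG_DELTA_RANGE, 32)
        vals = [crit(g) for g in grid]
        ld = float(grid[int(np.argmax(vals))])
        res = minimize_scalar(lambda g: -crit(g), bounds=(ld - 0.7, ld + 0.7),
                              method="bounded", options={"xatol": 1e-6})
        w = 1.0 / (lam + np.exp(res.x))
        XtW = Xt * w[:, None]
        G = Xt.T @ XtW
        bh = np.linalg.solve(G, XtW.T @ yt)
        r = yt - Xt @ bh
        sigma2 = np.sum(w * r * r) / (n - 2)
        vb = sigma2 * np.linalg.inv(G)[1, 1]
        t = bh[1] / np.sqrt(vb)
        pv = 2 * stats.t.sf(abs(t), df=n - 2)
        logp[s] = min(-np.log10(max(pv, 1e-300)), LOGP_CAP)
        beta[s] = bh[1]
    return logp, beta


def filter_scan(scan_df: pd.DataFrame, maf_min: float = 0.05,
                logp_min: float = 4.0) -> pd.DataFrame:
    """Raw-output filter: keep SNPs with maf >= maf_min and -log10 p >= logp_min."""
    keep = (scan_df["maf"] >= maf_min) & (scan_df["minus_log10_p"] >= logp_min)
    return scan_df[keep].reset_index(drop=True)


def genomic_control_lambda(minus_log10_p: np.ndarray) -> float:
    """Median chi-square inflation factor of a scan's p-values."""
    p = np.power(10.0, -np.asarray(minus_log10_p, dtype=np.float64))
    chi2 = stats.chi2.isf(np.clip(p, 1e-300, 1), df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))
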