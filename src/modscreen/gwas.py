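"""Mixed-model genome-wide association across inbred lines.

The association model for strain-mean phenotype y (length n) and marker
dosage x is

    y = alpha + x beta + u + eps,
    u ~ MVN(0, lambda * tau_inv * K),   eps ~ MVN(0, tau_inv * I_n),

where K is the centered marker-based genetic relatedness matrix, lambda
the ratio of the polygenic to residual variance components and tau_inv
the residual variance.  The spectral decomposition K = U D U^T turns the
covariance into a diagonal (lambda d_i + 1) in the rotated basis, so
variance-component estimation is a one-dimensional optimization in
lambda and each per-variant fit is a weighted two-column regression.

Two scan modes are offered: ``null_lambda_reused`` (the null-model
lambda-hat is fixed for every variant — the EMMAX approximation, the
default) and ``per_variant_lambda`` (lambda re-optimized per variant —
exact, slower).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import GenotypeMatrix, KinshipMatrix

__all__ = [
    "filter_variants",
    "compute_centered_grm",
    "fit_null_lmm",
    "lmm_association",
    "top_variants",
    "LMMModel",
    "FilterReport",
]

_LOG_LAMBDA_BOUNDS = (-5.0, 5.0)  # lambda grid spans [1e-5, 1e5]
_N_GRID = 61


@dataclass
class FilterReport:
    """Counts of variants removed by each filtering rule."""

    n_input: int
    n_nonbiallelic: int
    n_excluded_chrom: int
    n_monomorphic: int
    n_low_maf: int
    n_kept: int


def filter_variants(G: GenotypeMatrix, min_maf: float | None = None,
                    exclude_chromosomes: set[str] | None = None,
                    ) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the screen's variant filters in order.

    Removes non-biallelic records (ref/alt with multiple alleles),
    variants on excluded chromosomes (e.g. the X, whose variants the
    F1 males inherit from the donor strain), monomorphic variants, and —
    only when ``min_maf`` is given — variants with MAF < min_maf.  The
    screen's own default leaves ``min_maf`` unset: rare alleles are kept
    deliberately.
    """
    exclude_chromosomes = exclude_chromosomes or set()
    keep = np.ones(G.n_variants, dtype=bool)

    single = G.variants["ref"].str.len().eq(1) & G.variants["alt"].str.len().eq(1)
    biallelic = single & ~G.variants["alt"].str.contains(",", regex=False)
    n_nonbi = int((~biallelic & keep).sum())
    keep &= biallelic.to_numpy()

    on_excluded = G.variants["chrom"].isin(exclude_chromosomes).to_numpy()
    n_chrom = int((on_excluded & keep).sum())
    keep &= ~on_excluded

    maf = G.maf()
    mono = ~(maf > 0.0)  # includes all-missing columns (NaN maf)
    n_mono = int((mono & keep).sum())
    keep &= ~mono

    n_maf = 0
    if min_maf is not None:
        low = maf < min_maf
        n_maf = int((low & keep).sum())
        keep &= ~low

    kept_idx = np.flatnonzero(keep)
    report = FilterReport(
        n_input=G.n_variants, n_nonbiallelic=n_nonbi, n_excluded_chrom=n_chrom,
        n_monomorphic=n_mono, n_low_maf=n_maf, n_kept=len(kept_idx),
    )
    if len(kept_idx) == 0:
        import warnings

        warnings.warn("all variants removed by filtering", stacklevel=2)
    return G.take_variants(kept_idx), report


def compute_centered_grm(G: GenotypeMatrix) -> KinshipMatrix:
    """Centered GRM: K = (1/m) sum_k (x_k - xbar_k)(x_k - xbar_k)^T.

    Missing dosages are mean-imputed per variant first, which makes the
    imputed entries identical to the column mean and hence contribute
    zeros after centering.  K is symmetric and PSD with zero row sums.
    """
    if G.n_lines < 2:
        raise ValueError("need >= 2 lines for a relatedness matrix")
    if G.n_variants < 1:
        raise ValueError("no variants left to build the relatedness matrix")
    X = G.imputed_dosages()
    Xc = X - X.mean(axis=0, keepdims=True)
    K = (Xc @ Xc.T) / G.n_variants
    K = (K + K.T) / 2.0
    return KinshipMatrix(line_ids=list(G.line_ids), values=K)


@dataclass
class LMMModel:
    """Fitted null (or per-variant) mixed model in the eigenbasis of K."""

    line_ids: list[str]
    lambda_hat: float
    tau_inv: float           # residual variance T^-1
    alpha: float             # intercept, phenotype units
    log_likelihood: float
    method: str              # "reml" | "ml"
    eigenvalues: np.ndarray  # D, clipped at 0
    eigenvectors: np.ndarray  # U, orthonormal columns
    beta: float | None = None  # set when fitted with a marker column


def _eigendecompose(K: KinshipMatrix, psd_tol: float = 1e-6) -> tuple[np.ndarray, np.ndarray]:
    d, U = np.linalg.eigh(K.values)
    scale = max(1.0, float(d.max(initial=0.0)))
    if d.min() < -psd_tol * scale:
        raise ValueError(f"K is not PSD: min eigenvalue {d.min():.3g}")
    return np.clip(d, 0.0, None), U


def _profiled_loglik(log_lam: float, yr: np.ndarray, Xr: np.ndarray, d: np.ndarray,
                     method: str) -> tuple[float, np.ndarray, float]:
    """Profile log-likelihood in lambda after rotating by U.

    Returns (loglik, GLS coefficients, tau_inv-hat).  ``yr`` and ``Xr``
    are U^T y and U^T X; the rotated covariance is diag(lambda d_i + 1)
    times tau_inv, so GLS reduces to weighted least squares.
    """
    lam = 10.0 ** log_lam
    n, p = Xr.shape
    h = lam * d + 1.0
    w = 1.0 / h
    XtWX = (Xr * w[:, None]).T @ Xr
    XtWy = (Xr * w[:, None]).T @ yr
    try:
        b = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError:
        return -np.inf, np.full(p, np.nan), np.nan
    resid = yr - Xr @ b
    rss = float(np.sum(w * resid**2))
    if rss <= 0.0:
        return -np.inf, b, 0.0
    logdet_h = float(np.sum(np.log(h)))
    if method == "ml":
        tau_inv = rss / n
        ll = -0.5 * (n * np.log(2 * np.pi * tau_inv) + logdet_h + n)
    else:  # REML
        tau_inv = rss / (n - p)
        sign, logdet_xwx = np.linalg.slogdet(XtWX)
        _, logdet_xx = np.linalg.slogdet(Xr.T @ Xr)
        if sign <= 0:
            return -np.inf, b, tau_inv
        ll = -0.5 * ((n - p) * np.log(2 * np.pi * tau_inv) + logdet_h
                     + logdet_xwx - logdet_xx + (n - p))
    return float(ll), b, float(tau_inv)


def _optimize_lambda(yr: np.ndarray, Xr: np.ndarray, d: np.ndarray,
                     method: str) -> tuple[float, float, np.ndarray, float]:
    """Log-grid search over lambda followed by bounded scalar refinement."""
    lo, hi = _LOG_LAMBDA_BOUNDS
    grid = np.linspace(lo, hi, _N_GRID)
    lls = np.array([_profiled_loglik(g, yr, Xr, d, method)[0] for g in grid])
    i = int(np.argmax(lls))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda g: -_profiled_loglik(g, yr, Xr, d, method)[0],
        bounds=(a, b), method="bounded",
        options={"xatol": 1e-6},
    )
    best_log_lam = float(res.x) if -res.fun >= lls[i] else float(grid[i])
    ll, coef, tau_inv = _profiled_loglik(best_log_lam, yr, Xr, d, method)
    return 10.0 ** best_log_lam, ll, coef, tau_inv


def fit_null_lmm(y: pd.Series, K: KinshipMatrix, method: str = "reml") -> LMMModel:
    """Estimate lambda, tau_inv and the intercept under the null (no marker).

    ``y`` is the strain-mean phenotype Series indexed by line ID; its
    index must match ``K.line_ids`` as a set (it is reordered to K's
    order).  The restricted likelihood is the default objective.
    """
    if method not in ("reml", "ml"):
        raise ValueError("method must be 'reml' or 'ml'")
    if set(y.index) != set(K.line_ids):
        raise ValueError("phenotype strains do not match kinship line IDs")
    yv = y.loc[K.line_ids].to_numpy(dtype=float)
    n = len(yv)
    if n < 10:
        raise ValueError("need >= 10 lines to estimate variance components")
    if not np.all(np.isfinite(yv)):
        raise ValueError("phenotype vector contains non-finite values")
    d, U = _eigendecompose(K)
    yr = U.T @ yv
    Xr = U.T @ np.ones((n, 1))
    lam, ll, coef, tau_inv = _optimize_lambda(yr, Xr, d, method)
    return LMMModel(
        line_ids=list(K.line_ids), lambda_hat=lam, tau_inv=tau_inv,
        alpha=float(coef[0]), log_likelihood=ll, method=method,
        eigenvalues=d, eigenvectors=U,
    )


def _wald_scan_fixed_lambda(yr: np.ndarray, ones_r: np.ndarray, Xr: np.ndarray,
                            lam: float, d: np.ndarray) -> tuple[np.ndarray, ...]:
    """Vectorized weighted 2-column regressions at a fixed lambda.

    All variants share the weight vector w = 1/(lambda d + 1), so each
    per-variant fit is a closed-form 2x2 solve done array-wise.
    """
    n, m = Xr.shape
    w = 1.0 / (lam * d + 1.0)
    sw = np.sqrt(w)
    yt = sw * yr
    ot = sw * ones_r
    Xt = Xr * sw[:, None]

    s00 = float(ot @ ot)
    s01 = ot @ Xt                    # (m,)
    s11 = np.einsum("ij,ij->j", Xt, Xt)
    sy0 = float(ot @ yt)
    sy1 = yt @ Xt
    yty = float(yt @ yt)

    det = s00 * s11 - s01**2
    scale = s00 * np.maximum(s11, 1e-300)
    ok = det > 1e-12 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (s00 * sy1 - s01 * sy0) / det
        alpha = (s11 * sy0 - s01 * sy1) / det
        rss = yty - (alpha * sy0 + beta * sy1)
    dfe = n - 2
    rss = np.maximum(rss, 0.0)
    sigma2 = rss / dfe
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2 * s00 / det)
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), dfe)
    beta[~ok] = np.nan
    se[~ok] = np.nan
    tstat[~ok] = np.nan
    p[~ok] = np.nan
    return beta, se, tstat, p


def lmm_association(y: pd.Series, G: GenotypeMatrix, K: KinshipMatrix,
                    mode: str = "null_lambda_reused", method: str = "reml",
                    lambda_override: float | None = None,
                    add_bh: bool = False) -> pd.DataFrame:
    """Scan every variant with the mixed model; Wald test, t with n-2 df.

    Returns a DataFrame with one row per variant: chrom, pos, ref, alt,
    af, maf, beta, se, stat, p, n_used.  Variants that are constant after
    mean imputation get NA statistics rather than raising.  With
    ``lambda_override=0`` the scan reduces exactly to ordinary
    least-squares simple regression.
    """
    if mode not in ("null_lambda_reused", "per_variant_lambda"):
        raise ValueError(f"unknown mode {mode!r}")
    if list(G.line_ids) != list(K.line_ids):
        raise ValueError("genotype and kinship line IDs are not aligned")
    if set(y.index) != set(K.line_ids):
        raise ValueError("phenotype strains do not match kinship line IDs")
    yv = y.loc[K.line_ids].to_numpy(dtype=float)
    n = len(yv)
    d, U = _eigendecompose(K)
    X = G.imputed_dosages()
    n_used = np.sum(~np.isnan(G.dosages), axis=0)

    yr = U.T @ yv
    ones_r = U.T @ np.ones(n)
    Xr = U.T @ X

    if mode == "null_lambda_reused":
        if lambda_override is not None:
            lam = float(lambda_override)
        else:
            lam = fit_null_lmm(y, K, method=method).lambda_hat
        beta, se, tstat, p = _wald_scan_fixed_lambda(yr, ones_r, Xr, lam, d)
    else:
        beta = np.empty(G.n_variants)
        se = np.empty(G.n_variants)
        tstat = np.empty(G.n_variants)
        p = np.empty(G.n_variants)
        for k in range(G.n_variants):
            xk = Xr[:, k]
            if np.ptp(X[:, k]) == 0.0:
                beta[k] = se[k] = tstat[k] = p[k] = np.nan
                continue
            Xmat = np.column_stack([ones_r, xk])
            if lambda_override is not None:
                lam_k = float(lambda_override)
            else:
                lam_k, _, _, _ = _optimize_lambda(yr, Xmat, d, method)
            b_k, s_k, t_k, p_k = _wald_scan_fixed_lambda(yr, ones_r, xk[:, None], lam_k, d)
            beta[k], se[k], tstat[k], p[k] = b_k[0], s_k[0], t_k[0], p_k[0]

    af = G.alt_frequency()
    res = pd.DataFrame({
        "chrom": G.variants["chrom"].to_numpy(),
        "pos": G.variants["pos"].to_numpy(),
        "ref": G.variants["ref"].to_numpy(),
        "alt": G.variants["alt"].to_numpy(),
        "af": af,
        "maf": np.minimum(af, 1 - af),
        "beta": beta,
        "se": se,
        "stat": tstat,
        "p": p,
        "n_used": n_used,
    })
    if add_bh:
        res["p_bh"] = _benjamini_hochberg(res["p"].to_numpy())
    return res


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values; NaNs propagate."""
    out = np.full_like(p, np.nan, dtype=float)
    ok = np.isfinite(p)
    pv = p[ok]
    m = len(pv)
    if m == 0:
        return out
    order = np.argsort(pv)
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    vals = np.empty(m)
    vals[order] = np.minimum(adj, 1.0)
    out[ok] = vals
    return out


def top_variants(res: pd.DataFrame, threshold: float = 1e-4) -> pd.DataFrame:
    """Variants with p < threshold, ascending by p; ties by (chrom, pos)."""
    hits = res[res["p"] < threshold].copy()
    return hits.sort_values(["p", "chrom", "pos"], kind="mergesort").reset_index(drop=True)
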