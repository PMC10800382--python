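"""LD score regression: univariate, bivariate and stratified fits.

Model
-----
Under a polygenic additive model with LD scores ``l_j``,

    E[z_j^2]      = N * (h2 / M) * l_j + intercept,
    E[z_1j z_2j]  = sqrt(N1 N2) * (gcov / M) * l_j + cross-intercept,

so the slope of a weighted regression of chi-square (or z-score products)
on LD scores estimates heritability (or genetic covariance), while
confounding inflation loads on the intercept.  Genetic correlation is
``rg = gcov / sqrt(h2_1 h2_2)``.  The stratified fit regresses z^2 on
per-category LD scores jointly, giving per-SNP variance coefficients
``tau_c`` and category enrichments.

Uncertainty comes from a delete-one block jackknife over contiguous SNP
blocks (default 200), including full re-estimation of every ratio term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .gwas_io import LdInfo, SummaryStats, category_ld_scores

__all__ = [
    "H2Fit",
    "RgFit",
    "PartitionedFit",
    "EstimationError",
    "fit_h2",
    "fit_rg",
    "fit_partitioned",
    "jackknife",
]


class EstimationError(RuntimeError):
    """Raised when a regression estimate is undefined or a resample fails."""


@dataclass
class H2Fit:
    h2: float
    h2_se: float
    intercept: float
    intercept_se: float
    mean_chi2: float
    n_snps_used: int


@dataclass
class RgFit:
    rg: float
    rg_se: float
    p: float
    gcov: float
    gcov_intercept: float
    h2_1: H2Fit
    h2_2: H2Fit


@dataclass
class PartitionedFit:
    categories: list[str]
    tau: np.ndarray
    tau_se: np.ndarray
    coeff_z: np.ndarray
    enrichment: np.ndarray
    enrichment_se: np.ndarray
    p: np.ndarray
    h2: float
    h2_per_category: np.ndarray
    prop_snps: np.ndarray


# ---------------------------------------------------------------------------
# jackknife
# ---------------------------------------------------------------------------

def jackknife(blocks: list, estimator) -> tuple[np.ndarray, np.ndarray]:
    """Delete-one block jackknife.

    ``estimator`` maps a list of per-block inputs to a scalar or vector
    statistic.  Returns the full-sample estimate and the jackknife SE
    ``se^2 = (B-1)/B * sum_b (theta_(-b) - mean)^2``.
    """
    n_blocks = len(blocks)
    if n_blocks < 2:
        raise ValueError("jackknife needs at least 2 blocks")
    full = np.atleast_1d(np.asarray(estimator(blocks), dtype=float))
    loo = np.empty((n_blocks, full.size))
    for b in range(n_blocks):
        try:
            loo[b] = np.atleast_1d(estimator(blocks[:b] + blocks[b + 1:]))
        except Exception as exc:  # noqa: BLE001 - re-raise with block context
            raise EstimationError(f"estimator failed on leave-one-out block {b}: {exc}") from exc
    mean = loo.mean(axis=0)
    se = np.sqrt((n_blocks - 1) / n_blocks * ((loo - mean) ** 2).sum(axis=0))
    if full.size == 1:
        return float(full[0]), float(se[0])
    return full, se


# ---------------------------------------------------------------------------
# weighted-regression plumbing
# ---------------------------------------------------------------------------

def _block_bounds(n: int, n_blocks: int) -> list[tuple[int, int]]:
    edges = np.linspace(0, n, n_blocks + 1).astype(int)
    return [(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


def _wls_block_stats(x: np.ndarray, y: np.ndarray, w: np.ndarray,
                     bounds: list[tuple[int, int]]):
    """Per-block normal-equation pieces (X'WX, X'Wy) for a design x (n, k)."""
    k = x.shape[1]
    a = np.empty((len(bounds), k, k))
    c = np.empty((len(bounds), k))
    xw = x * w[:, None]
    for i, (lo, hi) in enumerate(bounds):
        a[i] = xw[lo:hi].T @ x[lo:hi]
        c[i] = xw[lo:hi].T @ y[lo:hi]
    return a, c


def _solve(a: np.ndarray, c: np.ndarray, ridge: float = 0.0) -> np.ndarray:
    # scale-normalize so conditioning (and any ridge) is unit-free
    d = np.sqrt(np.maximum(np.diag(a), np.finfo(float).tiny))
    an = a / np.outer(d, d)
    if ridge > 0:
        an = an + ridge * np.eye(an.shape[0])
    return np.linalg.solve(an, c / d) / d


def _is_collinear(a: np.ndarray, tol: float = 1e10) -> bool:
    d = np.sqrt(np.maximum(np.diag(a), np.finfo(float).tiny))
    return np.linalg.cond(a / np.outer(d, d)) > tol


def _jackknife_from_stats(a: np.ndarray, c: np.ndarray, ridge: float = 0.0):
    """Full estimate and leave-one-block coefficient paths from block stats."""
    a_tot, c_tot = a.sum(axis=0), c.sum(axis=0)
    full = _solve(a_tot, c_tot, ridge)
    n_blocks = a.shape[0]
    loo = np.empty((n_blocks, full.size))
    for b in range(n_blocks):
        loo[b] = _solve(a_tot - a[b], c_tot - c[b], ridge)
    mean = loo.mean(axis=0)
    se = np.sqrt((n_blocks - 1) / n_blocks * ((loo - mean) ** 2).sum(axis=0))
    return full, se, loo


def _two_step_weights(ell: np.ndarray, pred: np.ndarray) -> np.ndarray:
    base = np.maximum(ell, 1.0)
    return 1.0 / (base * np.maximum(pred, 0.1) ** 2)


def _prepare(stats_: SummaryStats, ld: LdInfo):
    z = stats_.table["Z"].to_numpy(dtype=float)
    n = stats_.table["N"].to_numpy(dtype=float)
    good = np.isfinite(z)
    return z, n, good


# ---------------------------------------------------------------------------
# fits
# ---------------------------------------------------------------------------

def fit_h2(
    stats_: SummaryStats,
    ld: LdInfo,
    n_blocks: int = 200,
    weight_iterations: int = 2,
    max_chisq: float | None = None,
) -> H2Fit:
    """Univariate LD score regression for SNP heritability.

    Two-step WLS of z^2 on LD scores: initial weights ``1/max(l, 1)``, then
    ``1/[max(l, 1) * (intercept + N h2 l / M)^2]``.  SEs from a delete-one
    jackknife over ``n_blocks`` contiguous SNP blocks.  ``max_chisq``
    optionally drops SNPs above a chi-square cap (off by default).
    """
    z, n, good = _prepare(stats_, ld)
    ell = np.asarray(ld.ld_scores, dtype=float)
    if len(ell) != len(z):
        raise ValueError("LD scores do not match summary statistics")
    y = z ** 2
    if max_chisq is not None:
        good &= y <= max_chisq
    y, ell, n = y[good], ell[good], n[good]
    m = len(y)
    if m <= n_blocks:
        raise EstimationError(f"{m} usable SNPs for {n_blocks} jackknife blocks")
    m_total = ld.n_snps

    x = np.column_stack([n * ell / m_total, np.ones(m)])
    w = 1.0 / np.maximum(ell, 1.0)
    coef = None
    for _ in range(max(weight_iterations, 1)):
        if coef is not None:
            pred = x @ coef
            w = _two_step_weights(ell, pred)
        bounds = _block_bounds(m, n_blocks)
        a, c = _wls_block_stats(x, y, w, bounds)
        coef = _solve(a.sum(axis=0), c.sum(axis=0))
    full, se, _ = _jackknife_from_stats(a, c)
    return H2Fit(
        h2=float(full[0]), h2_se=float(se[0]),
        intercept=float(full[1]), intercept_se=float(se[1]),
        mean_chi2=float(y.mean()), n_snps_used=m,
    )


def fit_rg(
    stats1: SummaryStats,
    stats2: SummaryStats,
    ld: LdInfo,
    n_blocks: int = 200,
    weight_iterations: int = 2,
) -> RgFit:
    """Bivariate LD score regression for genetic correlation.

    Regresses z1*z2 on LD scores for the genetic covariance, divides by the
    univariate heritabilities, and jackknifes the full ratio (numerator and
    both denominators re-estimated per left-out block).  Raises
    :class:`EstimationError` when either heritability is non-positive.
    """
    if len(stats1.table) != len(stats2.table):
        raise ValueError("traits must share a harmonized SNP universe")
    fit1 = fit_h2(stats1, ld, n_blocks, weight_iterations)
    fit2 = fit_h2(stats2, ld, n_blocks, weight_iterations)
    if fit1.h2 <= 0 or fit2.h2 <= 0:
        raise EstimationError("genetic correlation undefined: non-positive heritability")

    z1, n1, g1 = _prepare(stats1, ld)
    z2, n2, g2 = _prepare(stats2, ld)
    good = g1 & g2
    ell = np.asarray(ld.ld_scores, dtype=float)[good]
    z1, z2, n1, n2 = z1[good], z2[good], n1[good], n2[good]
    m = len(z1)
    if m <= n_blocks:
        raise EstimationError(f"{m} usable SNPs for {n_blocks} jackknife blocks")
    m_total = ld.n_snps

    y12 = z1 * z2
    y1, y2 = z1 ** 2, z2 ** 2
    x1 = np.column_stack([n1 * ell / m_total, np.ones(m)])
    x2 = np.column_stack([n2 * ell / m_total, np.ones(m)])
    x12 = np.column_stack([np.sqrt(n1 * n2) * ell / m_total, np.ones(m)])
    bounds = _block_bounds(m, n_blocks)

    def _fit_stats(x, y, weights=None):
        """Two-step WLS; returns block stats, final coef and step-1 coef."""
        w = 1.0 / np.maximum(ell, 1.0)
        a, c = _wls_block_stats(x, y, w, bounds)
        coef_step1 = _solve(a.sum(axis=0), c.sum(axis=0))
        if weights is None:
            w = _two_step_weights(ell, x @ coef_step1)
        else:
            w = weights
        a, c = _wls_block_stats(x, y, w, bounds)
        return a, c, _solve(a.sum(axis=0), c.sum(axis=0)), coef_step1

    a1, c1, coef1, coef1a = _fit_stats(x1, y1)
    a2, c2, coef2, coef2a = _fit_stats(x2, y2)
    # cross-regression heteroskedasticity weights from the step-1 fits:
    # var(z1 z2) ~ (E z1^2)(E z2^2) + (E z1 z2)^2, so a trait paired with
    # itself gets weights proportional to the univariate ones (rg = 1 exactly)
    w0 = 1.0 / np.maximum(ell, 1.0)
    a12, c12 = _wls_block_stats(x12, y12, w0, bounds)
    coef12a = _solve(a12.sum(axis=0), c12.sum(axis=0))
    s1, s2, cr = x1 @ coef1a, x2 @ coef2a, x12 @ coef12a
    w12 = 1.0 / (np.maximum(ell, 1.0) * np.maximum(s1 * s2 + cr ** 2, 0.1))
    a12, c12, coef12, _ = _fit_stats(x12, y12, weights=w12)

    def _rg_from(idx: np.ndarray) -> float:
        g = _solve(a12[idx].sum(axis=0), c12[idx].sum(axis=0))[0]
        h1 = _solve(a1[idx].sum(axis=0), c1[idx].sum(axis=0))[0]
        h2_ = _solve(a2[idx].sum(axis=0), c2[idx].sum(axis=0))[0]
        if h1 <= 0 or h2_ <= 0:
            raise EstimationError("non-positive heritability in jackknife resample")
        return g / np.sqrt(h1 * h2_)

    all_idx = np.arange(n_blocks)
    rg = _rg_from(all_idx)
    loo = np.empty(n_blocks)
    for b in range(n_blocks):
        loo[b] = _rg_from(np.delete(all_idx, b))
    rg_se = float(np.sqrt((n_blocks - 1) / n_blocks * ((loo - loo.mean()) ** 2).sum()))
    zstat = rg / rg_se if rg_se > 0 else np.inf
    p = float(min(max(2.0 * stats.norm.sf(abs(zstat)), np.finfo(float).tiny), 1.0))
    return RgFit(rg=float(rg), rg_se=rg_se, p=p, gcov=float(coef12[0]),
                 gcov_intercept=float(coef12[1]), h2_1=fit1, h2_2=fit2)


def fit_partitioned(
    stats_: SummaryStats,
    annot: np.ndarray,
    ld: LdInfo,
    n_blocks: int = 200,
    category_names: list[str] | None = None,
    weight_iterations: int = 2,
    ridge: float = 1e-8,
) -> PartitionedFit:
    """Stratified LD score regression with category enrichments.

    ``annot`` is a binary (n_snps, n_categories) matrix; a baseline
    all-SNPs category is appended unless the constant vector already lies
    in the annotation column space (an explicit all-ones column or an exact
    partition), which would make the design singular.  The fit
    regresses z^2 on {N * l(j, c)} jointly; ``h2_c`` sums the fitted
    per-SNP variance over category members and ``enrichment_c =
    (h2_c / h2) / (M_c / M)``.  Collinear categories trigger a ridge
    fallback (weight ``ridge`` x mean diagonal) with a warning.  Coefficient
    p-values are one-sided upper on the jackknife z-score.
    """
    a_mat = np.asarray(annot, dtype=float)
    if a_mat.ndim == 1:
        a_mat = a_mat[:, None]
    names = list(category_names) if category_names else [f"cat{i+1}" for i in range(a_mat.shape[1])]
    ones = np.ones(len(a_mat))
    sol = np.linalg.lstsq(a_mat, ones, rcond=None)[0]
    spans_base = float(np.abs(ones - a_mat @ sol).max()) < 1e-6
    if not spans_base:
        a_mat = np.column_stack([a_mat, ones])
        names = names + ["base"]

    z, n, good = _prepare(stats_, ld)
    ell_c = category_ld_scores(ld, a_mat)
    y = z[good] ** 2
    n = n[good]
    ell_c = ell_c[good]
    a_good = a_mat[good]
    m = len(y)
    if m <= n_blocks:
        raise EstimationError(f"{m} usable SNPs for {n_blocks} jackknife blocks")
    ell_tot = np.asarray(ld.ld_scores, dtype=float)[good]

    n_cat = a_mat.shape[1]
    x = np.column_stack([n[:, None] * ell_c, np.ones(m)])
    bounds = _block_bounds(m, n_blocks)

    w = 1.0 / np.maximum(ell_tot, 1.0)
    coef = None
    use_ridge = 0.0
    for _ in range(max(weight_iterations, 1)):
        if coef is not None:
            w = _two_step_weights(ell_tot, x @ coef)
        a_s, c_s = _wls_block_stats(x, y, w, bounds)
        a_tot = a_s.sum(axis=0)
        if _is_collinear(a_tot):
            warnings.warn("collinear annotation categories; ridge fallback applied",
                          RuntimeWarning, stacklevel=2)
            use_ridge = ridge
        coef = _solve(a_tot, c_s.sum(axis=0), use_ridge)

    tau_full, tau_se, loo = _jackknife_from_stats(a_s, c_s, use_ridge)
    tau = tau_full[:n_cat]
    tau_se_ = tau_se[:n_cat]

    m_total = len(a_mat)
    m_c = a_mat.sum(axis=0)

    def _enrich(tau_vec: np.ndarray):
        per_snp = a_mat @ tau_vec
        h2_tot = float(per_snp.sum())
        h2_c = a_mat.T @ per_snp
        with np.errstate(divide="ignore", invalid="ignore"):
            enr = (h2_c / h2_tot) / (m_c / m_total)
        return h2_tot, h2_c, enr

    h2_tot, h2_c, enr = _enrich(tau)
    enr_loo = np.array([_enrich(loo[b][:n_cat])[2] for b in range(n_blocks)])
    enr_mean = enr_loo.mean(axis=0)
    enr_se = np.sqrt((n_blocks - 1) / n_blocks * ((enr_loo - enr_mean) ** 2).sum(axis=0))

    with np.errstate(divide="ignore", invalid="ignore"):
        coeff_z = np.where(tau_se_ > 0, tau / tau_se_, np.inf)
    p = stats.norm.sf(coeff_z)
    return PartitionedFit(
        categories=names, tau=tau, tau_se=tau_se_, coeff_z=coeff_z,
        enrichment=enr, enrichment_se=enr_se, p=p, h2=h2_tot,
        h2_per_category=h2_c, prop_snps=m_c / m_total,
    )
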