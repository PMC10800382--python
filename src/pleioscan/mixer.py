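"""Bivariate causal-mixture model of polygenic overlap.

The per-SNP effect pair follows the four-component mixture of
:mod:`pleioscan.simulate`.  Marginally each z-score is a sum over LD
neighbours of mixture-distributed effects plus Gaussian noise, so its
characteristic function factorises over neighbours.  With neighbour
r-squared values binned into a histogram, the log characteristic function
of (z1, z2) at a SNP is

    log cf(t1, t2) = sum_bins count_b * log[ pi0 + pi1 g1(r2_b)
                     + pi2 g2(r2_b) + pi12 g12(r2_b) ]  + noise term,

where g1 = exp(-N1 s1^2 r2 t1^2 / 2), g2 likewise in t2, and g12 carries
the rho12 cross term.  Densities come from discrete Fourier inversion of
the cf on a regular grid; the likelihood interpolates them at the observed
z-scores.

Fitting is sequential: univariate margins (pi_u, sigma_u^2, sigma0^2) per
trait first, then the overlap parameters (pi12, rho12, rho0) with the
margins held fixed.  Standard errors come from a parametric bootstrap of
the bivariate stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .gwas_io import LdInfo, SummaryStats
from .simulate import MixtureParams, SimConfig, draw_effects, expected_rg, simulate_zscores

__all__ = [
    "UnivariateMixtureFit",
    "BivariateMixtureFit",
    "OverlapSummary",
    "ConditionalQQ",
    "GridSpec",
    "GridError",
    "mixture_density",
    "fit_univariate",
    "fit_bivariate",
    "polygenicity_n90",
    "overlap_summary",
    "conditional_qq",
]


class GridError(ValueError):
    """Raised when the Fourier grid is too coarse or too narrow."""


@dataclass(frozen=True)
class GridSpec:
    """Fourier inversion grid: n points spanning [-z_max, z_max)."""

    n: int = 256
    z_max: float = 15.0

    def axes(self):
        dz = 2.0 * self.z_max / self.n
        z = (np.arange(self.n) - self.n // 2) * dz
        t = 2.0 * np.pi * np.fft.fftfreq(self.n, d=dz)
        return z, t, dz


@dataclass
class UnivariateMixtureFit:
    pi_u: float
    sigma_u_sq: float
    sigma0_sq: float
    loglik: float
    n_snps: int = 0

    @property
    def implied_h2(self) -> float:
        """M pi sigma^2 per SNP-count unit; multiply by M externally."""
        return self.pi_u * self.sigma_u_sq


@dataclass
class BivariateMixtureFit:
    params: MixtureParams
    rho0: float
    loglik: float
    boundary_pi12: bool
    se: dict = field(default_factory=dict)
    bootstrap_params: list = field(default_factory=list)
    sigma0_sq: tuple[float, float] = (1.0, 1.0)


@dataclass
class OverlapSummary:
    n_causal_1: float
    n_causal_2: float
    n_shared: float
    n_unique_1: float
    n_unique_2: float
    se: dict
    rg_mixer: float
    n_shared_raw: float  # pi12 * M without the 90%-of-h2 convention

    def __post_init__(self) -> None:
        if self.n_shared > min(self.n_causal_1, self.n_causal_2) + 1e-9:
            raise ValueError("shared count exceeds a margin")


@dataclass
class ConditionalQQ:
    thresholds: tuple
    strata: dict  # threshold -> (expected -log10 p, observed -log10 p)
    stratum_sizes: dict
    shift: float  # median -log10 p difference, strictest vs full stratum


# ---------------------------------------------------------------------------
# density machinery
# ---------------------------------------------------------------------------

def _hist_groups(ld: LdInfo, idx: np.ndarray):
    """Unique r2-histogram rows among selected SNPs and the group index."""
    hists = ld.r2_hist[idx]
    uniq, inverse = np.unique(hists, axis=0, return_inverse=True)
    return uniq, inverse


def _invert_1d(phi: np.ndarray, n: int, dz: float) -> np.ndarray:
    sign = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
    return np.fft.fft(phi * sign, axis=-1).real / (n * dz)


def _invert_2d(phi: np.ndarray, n: int, dz: float) -> np.ndarray:
    sign = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
    s2 = np.outer(sign, sign)
    return np.fft.fft2(phi * s2, axes=(-2, -1)).real / (n * dz) ** 2


def _uni_group_pdfs(
    pi_u: float, sigma_u_sq: float, sigma0_sq: float, n_eff: float,
    uniq_hists: np.ndarray, mids: np.ndarray, grid: GridSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Densities (n_groups, n) on the z grid for each unique LD histogram."""
    z, t, dz = grid.axes()
    r2_vals = np.concatenate([[1.0], mids])  # self neighbour first
    w_self = np.ones((len(uniq_hists), 1))
    weights = np.concatenate([w_self, uniq_hists], axis=1)  # (G, n_bins + 1)
    ex = np.exp(-0.5 * n_eff * sigma_u_sq * np.outer(r2_vals, t ** 2))
    f = np.maximum((1.0 - pi_u) + pi_u * ex, 1e-300)
    log_phi = weights @ np.log(f) - 0.5 * sigma0_sq * t ** 2
    pdf = _invert_1d(np.exp(log_phi), grid.n, dz)
    return z, pdf


class _BivDensityEngine:
    """Caches the parameter-independent pieces of the bivariate cf.

    With the margins (sigma1^2, sigma2^2, sigma0^2, N1, N2) fixed, only
    pi's, rho12 and rho0 vary during optimization.  The per-component
    Gaussian cf exponents are precomputed on the t-grid for every LD
    r-squared bin actually populated; each likelihood evaluation then costs
    one exp/log pass plus one FFT per histogram group.
    """

    def __init__(self, sigma1_sq, sigma2_sq, sigma0_sq, n1, n2,
                 uniq_hists, mids, grid: GridSpec):
        self.grid = grid
        z, t, dz = grid.axes()
        self.z, self.dz = z, dz
        t1sq = (t ** 2)[:, None]
        t2sq = (t ** 2)[None, :]
        t12 = t[:, None] * t[None, :]
        weights = np.concatenate([np.ones((len(uniq_hists), 1)), uniq_hists], axis=1)
        r2_all = np.concatenate([[1.0], mids])
        used = weights.sum(axis=0) > 0
        self.weights = weights[:, used]
        r2 = r2_all[used]
        # log-scale Gaussian cf exponents per used r2 value (all <= 0)
        self.a1 = -0.5 * n1 * sigma1_sq * r2[:, None, None] * t1sq[None]
        self.a2 = -0.5 * n2 * sigma2_sq * r2[:, None, None] * t2sq[None]
        self.l12 = -np.sqrt(n1 * n2 * sigma1_sq * sigma2_sq) * r2[:, None, None] * t12[None]
        self.e1 = np.exp(self.a1)
        self.e2 = np.exp(self.a2)
        s01, s02 = sigma0_sq
        self.noise_base = -0.5 * (s01 * t1sq + s02 * t2sq)
        self.noise_cross = -np.sqrt(s01 * s02) * t12

    def phis(self, params: MixtureParams, rho0: float) -> np.ndarray:
        """cf values (n_groups, n, n) in fft order."""
        e12 = np.exp(np.minimum(self.a1 + self.a2 + params.rho12 * self.l12, 0.0))
        f = params.pi0 + params.pi1 * self.e1 + params.pi2 * self.e2 + params.pi12 * e12
        log_f = np.log(np.maximum(f, 1e-300))
        log_phi = np.tensordot(self.weights, log_f, axes=(1, 0))
        log_phi += np.minimum(self.noise_base + rho0 * self.noise_cross, 0.0)[None]
        return np.exp(log_phi)

    def pdfs(self, params: MixtureParams, rho0: float) -> np.ndarray:
        return _invert_2d(self.phis(params, rho0), self.grid.n, self.dz)


def _bi_group_phis(
    params: MixtureParams, rho0: float, sigma0_sq: tuple[float, float],
    n1: float, n2: float, uniq_hists: np.ndarray, mids: np.ndarray, grid: GridSpec,
) -> np.ndarray:
    eng = _BivDensityEngine(params.sigma1_sq, params.sigma2_sq, sigma0_sq,
                            n1, n2, uniq_hists, mids, grid)
    return eng.phis(params, rho0)


def mixture_density(
    params: MixtureParams,
    rho0: float,
    sigma0_sq: tuple[float, float],
    ld: LdInfo,
    n1: float,
    n2: float,
    snp_indices: np.ndarray | None = None,
    grid: GridSpec = GridSpec(),
    check: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Bivariate z-score density per LD-histogram group by Fourier inversion.

    Returns ``(z_grid, densities, group_index, clip_mass)`` where
    ``densities[g]`` is the (n, n) density for group ``g`` and
    ``group_index`` maps each selected SNP to its group.  Negative
    inversion ripple is clipped at 0 and reported as ``clip_mass``.  With
    ``check=True`` an estimated wrap-around/aliasing mass above 1e-3 raises
    :class:`GridError` advising a larger grid.
    """
    idx = np.arange(ld.n_snps) if snp_indices is None else snp_indices
    uniq, inverse = _hist_groups(ld, idx)
    z, _, dz = grid.axes()
    phi = _bi_group_phis(params, rho0, sigma0_sq, n1, n2, uniq, ld.r2_bin_mids(), grid)
    pdf = _invert_2d(phi, grid.n, dz)
    clip_mass = float(np.maximum(-pdf, 0.0).sum() * dz * dz / max(len(uniq), 1))
    if check:
        edge = np.concatenate([pdf[:, 0, :], pdf[:, -1, :], pdf[:, :, 0], pdf[:, :, -1]],
                              axis=-1)
        alias = float(np.abs(edge).sum() * dz * dz * grid.n / (4 * max(len(uniq), 1)))
        if alias > 1e-3 or clip_mass > 1e-3:
            raise GridError(
                f"Fourier grid too coarse/narrow (edge mass ~{alias:.2e}, "
                f"clip mass ~{clip_mass:.2e}); increase n or z_max")
    pdf = np.maximum(pdf, 0.0)
    return z, pdf, inverse, clip_mass


def _interp_1d(zq: np.ndarray, zg: np.ndarray, pdf: np.ndarray) -> np.ndarray:
    return np.interp(zq, zg, pdf, left=pdf[0], right=pdf[-1])


def _interp_2d(z1q, z2q, zg, pdf):
    dz = zg[1] - zg[0]
    f1 = np.clip((z1q - zg[0]) / dz, 0, len(zg) - 1 - 1e-9)
    f2 = np.clip((z2q - zg[0]) / dz, 0, len(zg) - 1 - 1e-9)
    i1, i2 = f1.astype(int), f2.astype(int)
    a1, a2 = f1 - i1, f2 - i2
    return ((1 - a1) * (1 - a2) * pdf[i1, i2] + a1 * (1 - a2) * pdf[i1 + 1, i2]
            + (1 - a1) * a2 * pdf[i1, i2 + 1] + a1 * a2 * pdf[i1 + 1, i2 + 1])


def _auto_grid(zmax_obs: float, base: GridSpec | None) -> GridSpec:
    if base is not None:
        return base
    z_max = max(15.0, 1.1 * zmax_obs)
    return GridSpec(n=256, z_max=z_max)


# ---------------------------------------------------------------------------
# univariate fit
# ---------------------------------------------------------------------------

_UNI_STARTS = ((1e-4, 0.2), (1e-3, 0.2), (1e-2, 0.2))  # (pi_u, implied h2) starts


def _likelihood_snps(ld: LdInfo, subsample: int | None, rng: np.random.Generator,
                     prune_blocks: bool) -> np.ndarray:
    """SNP indices for the composite likelihood.

    The per-SNP likelihood treats SNPs as independent, which within an LD
    block they are not; evaluating on one randomly chosen SNP per block
    keeps the composite log-likelihood calibrated (block draws are
    independent).  Without block structure, a plain random subsample is
    used.
    """
    m = ld.n_snps
    if prune_blocks and ld.blocks is not None and len(ld.blocks) > 1:
        idx = np.array([int(rng.integers(lo, hi)) for lo, hi in ld.blocks])
    else:
        idx = np.arange(m)
    if subsample is not None and subsample < len(idx):
        idx = rng.choice(idx, size=subsample, replace=False)
    return np.sort(idx)


def fit_univariate(
    stats_: SummaryStats,
    ld: LdInfo,
    subsample: int | None = None,
    seed: int = 0,
    grid: GridSpec | None = None,
    maxiter: int = 400,
    prune_blocks: bool = True,
) -> UnivariateMixtureFit:
    """Maximum-likelihood univariate mixture fit (pi_u, sigma_u^2, sigma0^2).

    Nelder-Mead on log/logit-transformed coordinates from a documented
    3-point multistart; deterministic under ``seed`` (which governs only the
    SNP subsample).  The likelihood is evaluated on one SNP per LD block
    (see :func:`_likelihood_snps`) unless ``prune_blocks`` is off.
    """
    z_all = stats_.table["Z"].to_numpy(dtype=float)
    n_eff = float(np.median(stats_.table["N"]))
    m = ld.n_snps
    rng = np.random.default_rng(seed)
    idx = _likelihood_snps(ld, subsample, rng, prune_blocks)
    size = len(idx)
    z = z_all[idx]
    uniq, inverse = _hist_groups(ld, idx)
    mids = ld.r2_bin_mids()
    gspec = _auto_grid(np.abs(z).max(), grid)

    def unpack(x):
        pi_u = 0.5 * special.expit(x[0])
        sig_u = np.exp(x[1])
        sig0 = 1.0 + np.exp(x[2])
        return pi_u, sig_u, sig0

    def negloglik(x):
        pi_u, sig_u, sig0 = unpack(x)
        if not np.isfinite(sig_u) or sig_u > 1.0:
            return 1e12
        zg, pdf = _uni_group_pdfs(pi_u, sig_u, sig0, n_eff, uniq, mids, gspec)
        pdf = np.maximum(pdf, 1e-300)
        ll = 0.0
        for g in range(len(uniq)):
            sel = inverse == g
            ll += np.log(_interp_1d(z[sel], zg, pdf[g])).sum()
        return -ll

    best = None
    for pi0_, h2_ in _UNI_STARTS:
        x0 = np.array([special.logit(min(pi0_ / 0.5, 0.99)),
                       np.log(h2_ / (m * pi0_)), np.log(0.05)])
        res = optimize.minimize(negloglik, x0, method="Nelder-Mead",
                                options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-6})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("univariate mixture fit failed to converge")
    pi_u, sig_u, sig0 = unpack(best.x)
    return UnivariateMixtureFit(float(pi_u), float(sig_u), float(sig0),
                                loglik=-float(best.fun), n_snps=size)


# ---------------------------------------------------------------------------
# bivariate fit
# ---------------------------------------------------------------------------

_BI_STARTS = ((0.5, 0.0, 0.0), (0.1, 0.7, 0.0), (0.9, -0.7, 0.0))  # (pi12/pmin, rho12, rho0)


def fit_bivariate(
    stats1: SummaryStats,
    stats2: SummaryStats,
    ld: LdInfo,
    fit_u1: UnivariateMixtureFit,
    fit_u2: UnivariateMixtureFit,
    subsample: int | None = None,
    seed: int = 0,
    n_boot: int = 20,
    grid: GridSpec | None = None,
    maxiter: int = 150,
    prune_blocks: bool = True,
) -> BivariateMixtureFit:
    """Fit the overlap parameters (pi12, rho12, rho0) with margins fixed.

    The univariate fits pin pi1 + pi12 = pi_u1 (and symmetrically), the
    per-trait effect variances and the noise variances; only the shared
    fraction, its effect correlation and the noise correlation are free,
    with pi12 in [0, min(pi_u1, pi_u2)].  A boundary solution pi12 ~ 0 is
    flagged, not raised.  SEs come from ``n_boot`` parametric-bootstrap
    refits of this stage.
    """
    z1_all = stats1.table["Z"].to_numpy(dtype=float)
    z2_all = stats2.table["Z"].to_numpy(dtype=float)
    n1 = float(np.median(stats1.table["N"]))
    n2 = float(np.median(stats2.table["N"]))
    m = ld.n_snps
    rng = np.random.default_rng(seed)
    idx = _likelihood_snps(ld, subsample, rng, prune_blocks)
    z1, z2 = z1_all[idx], z2_all[idx]
    uniq, inverse = _hist_groups(ld, idx)
    mids = ld.r2_bin_mids()
    gspec = _auto_grid(max(np.abs(z1).max(), np.abs(z2).max()), grid)
    zg = gspec.axes()[0]

    pmin = min(fit_u1.pi_u, fit_u2.pi_u)
    sig0 = (fit_u1.sigma0_sq, fit_u2.sigma0_sq)
    engine = _BivDensityEngine(fit_u1.sigma_u_sq, fit_u2.sigma_u_sq, sig0,
                               n1, n2, uniq, mids, gspec)
    group_sel = [inverse == g for g in range(len(uniq))]

    def make_params(pi12, rho12):
        pi1 = max(fit_u1.pi_u - pi12, 0.0)
        pi2 = max(fit_u2.pi_u - pi12, 0.0)
        pi0 = max(1.0 - pi1 - pi2 - pi12, 0.0)
        total = pi0 + pi1 + pi2 + pi12
        return MixtureParams(pi0 / total, pi1 / total, pi2 / total, pi12 / total,
                             fit_u1.sigma_u_sq, fit_u2.sigma_u_sq, rho12)

    def loglik_at(pi12, rho12, rho0, zz1, zz2):
        params = make_params(pi12, rho12)
        pdf = np.maximum(engine.pdfs(params, rho0), 1e-300)
        ll = 0.0
        for g, sel in enumerate(group_sel):
            ll += np.log(_interp_2d(zz1[sel], zz2[sel], zg, pdf[g])).sum()
        return ll

    def fit_stage(zz1, zz2):
        def neg(x):
            pi12 = pmin * special.expit(x[0])
            rho12 = np.tanh(x[1])
            rho0 = np.tanh(x[2])
            return -loglik_at(pi12, rho12, rho0, zz1, zz2)

        best = None
        for frac, r12, r0 in _BI_STARTS:
            x0 = np.array([special.logit(frac), np.arctanh(r12), np.arctanh(r0)])
            res = optimize.minimize(neg, x0, method="Nelder-Mead",
                                    options={"maxiter": maxiter, "xatol": 2e-3,
                                             "fatol": 1e-3})
            if best is None or res.fun < best.fun:
                best = res
        pi12 = pmin * special.expit(best.x[0])
        rho12, rho0 = float(np.tanh(best.x[1])), float(np.tanh(best.x[2]))
        ll_best = -float(best.fun)
        # boundary model selection: the overlap model adds 2 parameters
        # (pi12, rho12) that are unidentified at pi12 = 0, so an AIC margin
        # of 2 log-likelihood units decides interior vs boundary; this also
        # snaps optimizer stalls on the flat ridge near pi12 = 0
        ll0 = loglik_at(0.0, 0.0, rho0, zz1, zz2)
        if ll_best - ll0 < 2.0:
            return 0.0, 0.0, rho0, float(ll0)
        return float(pi12), rho12, rho0, ll_best

    pi12, rho12, rho0, ll = fit_stage(z1, z2)
    boundary = pi12 < 0.01 * pmin
    params = make_params(pi12, rho12)

    boot_params: list[tuple[float, float, float]] = []
    if n_boot > 0:
        a1 = max(fit_u1.sigma0_sq - 1.0, 0.0) / n1
        a2 = max(fit_u2.sigma0_sq - 1.0, 0.0) / n2
        for b in range(n_boot):
            bseed = int(rng.integers(2 ** 31))
            truth = draw_effects(params, m, bseed)
            cfg = SimConfig(n_snps=m, sample_sizes=(n1, n2), inflation=(a1, a2),
                            cross_trait_noise=rho0, seed=bseed)
            sims = simulate_zscores(truth, ld, cfg)
            bz1 = sims[0].table["Z"].to_numpy()[idx]
            bz2 = sims[1].table["Z"].to_numpy()[idx]
            bp12, br12, br0, _ = fit_stage(bz1, bz2)
            boot_params.append((bp12, br12, br0))
    se = {}
    if boot_params:
        arr = np.asarray(boot_params)
        se = {"pi12": float(arr[:, 0].std(ddof=1)),
              "rho12": float(arr[:, 1].std(ddof=1)),
              "rho0": float(arr[:, 2].std(ddof=1))}
    return BivariateMixtureFit(params=params, rho0=rho0, loglik=ll,
                               boundary_pi12=boundary, se=se,
                               bootstrap_params=boot_params, sigma0_sq=sig0)


def bivariate_loglik(
    stats1: SummaryStats,
    stats2: SummaryStats,
    ld: LdInfo,
    params: MixtureParams,
    rho0: float,
    sigma0_sq: tuple[float, float],
    subsample: int | None = None,
    seed: int = 0,
    grid: GridSpec | None = None,
    prune_blocks: bool = True,
) -> float:
    """Composite log-likelihood of a parameter point (diagnostic surface)."""
    z1_all = stats1.table["Z"].to_numpy(dtype=float)
    z2_all = stats2.table["Z"].to_numpy(dtype=float)
    n1 = float(np.median(stats1.table["N"]))
    n2 = float(np.median(stats2.table["N"]))
    rng = np.random.default_rng(seed)
    idx = _likelihood_snps(ld, subsample, rng, prune_blocks)
    z1, z2 = z1_all[idx], z2_all[idx]
    uniq, inverse = _hist_groups(ld, idx)
    gspec = _auto_grid(max(np.abs(z1).max(), np.abs(z2).max()), grid)
    zg = gspec.axes()[0]
    eng = _BivDensityEngine(params.sigma1_sq, params.sigma2_sq, sigma0_sq,
                            n1, n2, uniq, ld.r2_bin_mids(), gspec)
    pdf = np.maximum(eng.pdfs(params, rho0), 1e-300)
    ll = 0.0
    for g in range(len(uniq)):
        sel = inverse == g
        ll += np.log(_interp_2d(z1[sel], z2[sel], zg, pdf[g])).sum()
    return float(ll)


# ---------------------------------------------------------------------------
# polygenicity and overlap summaries
# ---------------------------------------------------------------------------

def polygenicity_n90(pi_c: float, sigma_sq: float, n_snps: int,
                     point_mass: bool = False) -> float:
    """Effective causal variants explaining 90% of heritability.

    Causal squared effects follow sigma^2 * chi2(1).  The threshold t with
    E[X 1(X > t)] / E[X] = 0.9 is found by root-finding (the partial
    expectation of a chi2(1) variable equals the chi2(3) upper tail), and
    n90 = pi_c * M * P(X > t) — independent of sigma^2.  The degenerate
    equal-effects option returns 0.9 * pi_c * M.
    """
    if not 0.0 < pi_c <= 1.0:
        raise ValueError("pi_c must be in (0, 1]")
    if sigma_sq <= 0:
        raise ValueError("sigma_sq must be positive")
    if point_mass:
        return 0.9 * pi_c * n_snps
    t = optimize.brentq(lambda u: stats.chi2.sf(u, df=3) - 0.9, 1e-12, 50.0)
    q_star = stats.chi2.sf(t, df=1)
    return float(pi_c * n_snps * q_star)


def overlap_summary(fit: BivariateMixtureFit, n_snps: int) -> OverlapSummary:
    """Venn quantities (counts of effective variants) from a bivariate fit."""
    p = fit.params

    def venn(pi1, pi2, pi12):
        f = lambda pi, sq: polygenicity_n90(pi, sq, n_snps) if pi > 0 else 0.0
        c1 = f(pi1 + pi12, p.sigma1_sq)
        c2 = f(pi2 + pi12, p.sigma2_sq)
        sh = f(pi12, p.sigma1_sq)
        return c1, c2, sh

    c1, c2, sh = venn(p.pi1, p.pi2, p.pi12)
    se = {}
    if fit.bootstrap_params:
        boots = []
        for bp12, _, _ in fit.bootstrap_params:
            pi1b = max(p.pi1 + p.pi12 - bp12, 0.0)
            pi2b = max(p.pi2 + p.pi12 - bp12, 0.0)
            boots.append(venn(pi1b, pi2b, bp12))
        arr = np.asarray(boots)
        sd = arr.std(axis=0, ddof=1)
        se = {"n_causal_1": float(sd[0]), "n_causal_2": float(sd[1]),
              "n_shared": float(sd[2])}
    return OverlapSummary(
        n_causal_1=c1, n_causal_2=c2, n_shared=sh,
        n_unique_1=c1 - sh, n_unique_2=c2 - sh, se=se,
        rg_mixer=expected_rg(p), n_shared_raw=p.pi12 * n_snps,
    )


def conditional_qq(
    primary: SummaryStats,
    conditioning: SummaryStats,
    thresholds: tuple = (1.0, 0.1, 0.01, 0.001),
) -> ConditionalQQ:
    """Conditional Q-Q curves: primary-trait p-values stratified by the
    conditioning trait.

    Emits, per threshold tau, sorted observed -log10 p of the primary trait
    in the stratum {p_conditioning <= tau} against expected uniform
    quantiles, plus a scalar enrichment shift (median -log10 p in the
    strictest nonempty stratum minus the full stratum).  Empty strata are
    omitted with a warning.
    """
    merged = primary.table.merge(conditioning.table, on="SNP", suffixes=("_p", "_c"))
    if merged.empty:
        raise ValueError("no shared SNPs between traits")
    p_pri = merged["P_p"].to_numpy(dtype=float)
    p_con = merged["P_c"].to_numpy(dtype=float)

    strata, sizes, medians = {}, {}, {}
    for tau in sorted(thresholds, reverse=True):
        sel = p_con <= tau
        k = int(sel.sum())
        if k == 0:
            warnings.warn(f"empty conditional stratum at threshold {tau}", RuntimeWarning,
                          stacklevel=2)
            continue
        obs = np.sort(-np.log10(np.maximum(p_pri[sel], 1e-300)))[::-1]
        exp = -np.log10((np.arange(1, k + 1) - 0.5) / k)
        strata[tau] = (exp, obs)
        sizes[tau] = k
        medians[tau] = float(np.median(obs))
    if not strata:
        raise ValueError("all conditional strata are empty")
    taus = sorted(strata)
    shift = medians[taus[0]] - medians[taus[-1]]
    return ConditionalQQ(tuple(taus), strata, sizes, float(shift))
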