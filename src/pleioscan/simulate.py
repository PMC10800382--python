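"""Synthetic multi-trait GWAS summary statistics with known ground truth.

Generative model
----------------
Genotypes are standardized, so per-SNP effects live on the unit-variance
scale and a trait's SNP heritability is ``h2_t = sum_j beta_tj^2``.  For a
pair of traits, per-SNP effects follow the four-component causal mixture

    (b1j, b2j) ~ pi0 * N(0, 0) + pi1 * N(0, S1) + pi2 * N(0, S2)
                 + pi12 * N(0, S12)

with S1 = diag(s1^2, 0), S2 = diag(0, s2^2) and S12 the full covariance
with correlation rho12.  Given LD correlation R, z-scores are

    z_t = sqrt(N_t) * R @ beta_t + eta_t,
    Cov(eta_t) = (1 + N_t * a_t) * R,

where ``a_t`` injects confounding inflation (LDSC intercept target
1 + N_t * a_t) and noise at each SNP is correlated across traits with
coefficient ``r0`` (sample overlap).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gwas_io import LdInfo, SummaryStats

__all__ = [
    "MixtureParams",
    "SimConfig",
    "TruthRecord",
    "draw_effects",
    "draw_effects_multi",
    "simulate_zscores",
    "simulate_annotated",
    "expected_rg",
]

COMPONENT_LABELS = ("null", "unique-1", "unique-2", "shared")


@dataclass(frozen=True)
class MixtureParams:
    """Four-component bivariate causal mixture parameters."""

    pi0: float
    pi1: float
    pi2: float
    pi12: float
    sigma1_sq: float
    sigma2_sq: float
    rho12: float = 0.0

    def __post_init__(self) -> None:
        total = self.pi0 + self.pi1 + self.pi2 + self.pi12
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"mixture weights sum to {total}, not 1")
        if min(self.pi0, self.pi1, self.pi2, self.pi12) < 0:
            raise ValueError("mixture weights must be nonnegative")
        if self.sigma1_sq <= 0 or self.sigma2_sq <= 0:
            raise ValueError("effect variances must be positive")
        if not -1.0 <= self.rho12 <= 1.0:
            raise ValueError("rho12 must be in [-1, 1]")

    @property
    def sigma12(self) -> np.ndarray:
        s1, s2 = np.sqrt(self.sigma1_sq), np.sqrt(self.sigma2_sq)
        return np.array([[self.sigma1_sq, self.rho12 * s1 * s2],
                         [self.rho12 * s1 * s2, self.sigma2_sq]])


@dataclass
class SimConfig:
    """Study conditions for a summary-statistics simulation."""

    n_snps: int
    sample_sizes: tuple[float, ...]  # N_t per trait
    inflation: tuple[float, ...] | None = None  # a_t, defaults to 0
    cross_trait_noise: float = 0.0  # r0 in (-1, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("need at least one SNP")
        if any(n <= 0 for n in self.sample_sizes):
            raise ValueError("sample sizes must be positive")
        if self.inflation is None:
            self.inflation = tuple(0.0 for _ in self.sample_sizes)
        if len(self.inflation) != len(self.sample_sizes):
            raise ValueError("inflation must match sample_sizes length")
        if not -1.0 < self.cross_trait_noise < 1.0:
            raise ValueError("cross_trait_noise must be in (-1, 1)")

    @property
    def n_traits(self) -> int:
        return len(self.sample_sizes)


@dataclass
class TruthRecord:
    """Ground truth of one simulation: labels, effects, realized h2."""

    components: np.ndarray | None  # (M,) int index into COMPONENT_LABELS (pairwise runs)
    beta: np.ndarray  # (M, T) standardized-scale effects
    h2: np.ndarray = field(init=False)  # (T,) realized sum of beta^2

    def __post_init__(self) -> None:
        self.h2 = (self.beta ** 2).sum(axis=0)
        if self.components is not None:
            lab = self.components
            nz = self.beta != 0.0
            # null rows carry zero effects; unique rows zero in the other trait
            if nz[lab == 0].any():
                raise ValueError("null-labelled SNPs carry nonzero effects")
            if self.beta.shape[1] >= 2:
                if nz[lab == 1, 1].any() or nz[lab == 2, 0].any():
                    raise ValueError("unique-labelled SNPs leak into the other trait")


def draw_effects(params: MixtureParams, n_snps: int, seed: int) -> TruthRecord:
    """Draw per-SNP bivariate effects from the four-component mixture."""
    rng = np.random.default_rng(seed)
    probs = [params.pi0, params.pi1, params.pi2, params.pi12]
    comp = rng.choice(4, size=n_snps, p=probs)
    beta = np.zeros((n_snps, 2))
    i1 = comp == 1
    beta[i1, 0] = rng.normal(0.0, np.sqrt(params.sigma1_sq), i1.sum())
    i2 = comp == 2
    beta[i2, 1] = rng.normal(0.0, np.sqrt(params.sigma2_sq), i2.sum())
    i12 = comp == 3
    if i12.any():
        cov = params.sigma12
        beta[i12] = rng.multivariate_normal([0.0, 0.0], cov, i12.sum(),
                                            method="cholesky" if params.rho12 ** 2 < 1 else "svd")
    return TruthRecord(comp, beta)


def draw_effects_multi(
    n_traits: int,
    n_snps: int,
    pair_specs: dict[tuple[int, int], MixtureParams],
    seed: int,
    background: tuple[float, float] | None = None,
) -> TruthRecord:
    """Multi-trait effects from declared pairwise mixtures on disjoint SNP pools.

    The SNP axis is split evenly across the declared pairs; each pool
    receives a bivariate mixture draw for its pair.  ``background``
    optionally adds independent trait-specific effects (pi, sigma_sq) on
    all SNPs for every trait.
    """
    rng = np.random.default_rng(seed)
    beta = np.zeros((n_snps, n_traits))
    pairs = list(pair_specs.items())
    bounds = np.linspace(0, n_snps, len(pairs) + 1).astype(int)
    for ((t1, t2), params), lo, hi in zip(pairs, bounds[:-1], bounds[1:]):
        if not (0 <= t1 < n_traits and 0 <= t2 < n_traits and t1 != t2):
            raise ValueError(f"invalid trait pair ({t1}, {t2})")
        sub = draw_effects(params, hi - lo, int(rng.integers(2 ** 31)))
        beta[lo:hi, t1] += sub.beta[:, 0]
        beta[lo:hi, t2] += sub.beta[:, 1]
    if background is not None:
        pi_b, sig_b = background
        for t in range(n_traits):
            mask = rng.random(n_snps) < pi_b
            beta[mask, t] += rng.normal(0.0, np.sqrt(sig_b), mask.sum())
    return TruthRecord(None, beta)


def _block_chol(ld: LdInfo) -> list[tuple[int, int, np.ndarray]]:
    """Cholesky factors of each LD block (cached per call, jittered PSD)."""
    blocks = ld.blocks if ld.blocks is not None else [(0, ld.n_snps)]
    out = []
    cache: dict[tuple, np.ndarray] = {}
    for lo, hi in blocks:
        sub = ld.submatrix(np.arange(lo, hi))
        # equicorrelated blocks repeat across the genome; reuse their factors
        rho = float(sub[0, 1]) if hi - lo > 1 else 0.0
        is_equi = np.array_equal(sub, _equi(hi - lo, rho))
        key = (hi - lo, rho) if is_equi else None
        L = cache.get(key) if key is not None else None
        if L is None:
            try:
                L = np.linalg.cholesky(sub)
            except np.linalg.LinAlgError:
                w, v = np.linalg.eigh(sub)
                L = v @ np.diag(np.sqrt(np.maximum(w, 1e-10)))
            if key is not None:
                cache[key] = L
        out.append((lo, hi, L))
    return out


def _equi(n: int, rho: float) -> np.ndarray:
    m = np.full((n, n), rho)
    np.fill_diagonal(m, 1.0)
    return m


def simulate_zscores(
    truth: TruthRecord,
    ld: LdInfo,
    config: SimConfig,
    trait_ids: list[str] | None = None,
) -> list[SummaryStats]:
    """Simulate per-trait summary statistics from effects and LD.

    z_t = sqrt(N_t) R beta_t + eta_t with Cov(eta_t) = (1 + N_t a_t) R and
    cross-trait noise correlation ``r0`` at each SNP.  Two-sided normal
    p-values are attached.  Reproducible under ``config.seed``.
    """
    m, n_traits = truth.beta.shape
    if m != ld.n_snps:
        raise ValueError(f"truth has {m} SNPs but LD has {ld.n_snps}")
    if n_traits != config.n_traits:
        raise ValueError("truth trait count does not match config")
    rng = np.random.default_rng(config.seed)

    r0 = config.cross_trait_noise
    c_trait = _equi(n_traits, r0)
    l_trait = np.linalg.cholesky(c_trait)

    eps = rng.standard_normal((m, n_traits)) @ l_trait.T
    z = np.empty((m, n_traits))
    chols = _block_chol(ld)
    for lo, hi, L in chols:
        sub_r = L @ L.T
        z[lo:hi] = sub_r @ truth.beta[lo:hi]  # R beta, exact per block
        eps[lo:hi] = L @ eps[lo:hi]  # LD-correlated noise
    scale_n = np.sqrt(np.asarray(config.sample_sizes))
    scale_noise = np.sqrt(1.0 + np.asarray(config.sample_sizes) * np.asarray(config.inflation))
    z = z * scale_n + eps * scale_noise

    ids = trait_ids or [f"trait{t+1}" for t in range(n_traits)]
    out = []
    for t, tid in enumerate(ids):
        table = pd.DataFrame({
            "SNP": ld.snp_ids,
            "CHR": "1",
            "BP": np.arange(1, m + 1) * 1000,
            "A1": "A",
            "A2": "G",
            "Z": z[:, t],
            "N": float(config.sample_sizes[t]),
            "P": 2.0 * stats.norm.sf(np.abs(z[:, t])),
        })
        out.append(SummaryStats(tid, table))
    return out


def simulate_annotated(
    config: SimConfig,
    ld: LdInfo,
    categories: np.ndarray,
    tau: np.ndarray,
    trait_id: str = "trait1",
) -> tuple[SummaryStats, TruthRecord]:
    """Univariate simulation with annotation-structured per-SNP variance.

    beta_j ~ N(0, sum_c tau_c * a_jc); z simulated as in
    :func:`simulate_zscores` with the first declared trait.
    """
    a = np.asarray(categories, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    tau = np.asarray(tau, dtype=float)
    var = a @ tau
    if (var < 0).any():
        raise ValueError("negative per-SNP effect variance")
    rng = np.random.default_rng(config.seed)
    beta = rng.normal(0.0, 1.0, config.n_snps) * np.sqrt(var)
    truth = TruthRecord(None, beta[:, None])
    uni = SimConfig(n_snps=config.n_snps, sample_sizes=(config.sample_sizes[0],),
                    inflation=(config.inflation[0],), seed=int(rng.integers(2 ** 31)))
    ss = simulate_zscores(truth, ld, uni, trait_ids=[trait_id])[0]
    return ss, truth


def expected_rg(params: MixtureParams) -> float:
    """Genetic correlation implied by the mixture parameters.

    rg = pi12 rho12 s1 s2 / sqrt((pi1 + pi12) s1^2 (pi2 + pi12) s2^2);
    0 when pi12 = 0.
    """
    f1 = params.pi1 + params.pi12
    f2 = params.pi2 + params.pi12
    if f1 <= 0 and f2 <= 0:
        raise ValueError("genetic correlation undefined: no causal SNPs in either trait")
    if params.pi12 == 0:
        return 0.0
    s1, s2 = np.sqrt(params.sigma1_sq), np.sqrt(params.sigma2_sq)
    num = params.pi12 * params.rho12 * s1 * s2
    den = np.sqrt(f1 * params.sigma1_sq * f2 * params.sigma2_sq)
    return float(num / den)
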