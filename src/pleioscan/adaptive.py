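"""Gene-based adaptive sum-of-powered-score tests from summary statistics.

For a gene with d SNPs and m traits, the observed traits x SNPs z-matrix Z
is compared against a matrix-normal null with among-SNP covariance R (from
a reference panel) and among-trait covariance V (from genome-wide pruned,
signal-capped z-score correlations).  Test statistics:

    SPUs(g1; Z(h))        = (sum_j |Z_hj|^g1)^(1/g1)     (g1 = inf: max |z|)
    MTSPUsSet(g1, g2; Z)  = sum_h SPUs(g1; Z(h))^g2

The adaptive versions take the minimum Monte-Carlo p-value over the power
grid (default {1, 2, 4, 8} for both), with the min-p itself calibrated on
the same null bank (each null draw is ranked against the other B - 1), so
all reported p-values are valid and lie in [1/(B+1), 1].  A staged schedule
escalates B only for genes that look significant, mirroring how very small
p-values (down to 1/(B+1) at the final stage) are obtained cheaply.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .gwas_io import LdInfo

__all__ = [
    "GeneZMatrix",
    "GammaGrid",
    "GeneTestResult",
    "spus",
    "mtspusset",
    "estimate_trait_correlation",
    "simulate_null_bank",
    "aspus",
    "mtaspusset",
    "staged_p",
    "gene_scan",
    "DEFAULT_SCHEDULE",
]

DEFAULT_SCHEDULE = (1_000, 10_000, 100_000, 1_000_000)


def _psd_factor(mat: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Lower-triangular-like factor L with L L^T = mat (eigenvalue-floored)."""
    mat = np.asarray(mat, dtype=float)
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError("correlation matrix is not symmetric")
    try:
        return np.linalg.cholesky(mat)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(mat)
        if w.min() < -1e-4:
            raise ValueError(f"matrix far from PSD (min eigenvalue {w.min():.3g})")
        return v * np.sqrt(np.maximum(w, floor))


def _sym_sqrt(mat: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Symmetric PSD square root with eigenvalue flooring."""
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError("correlation matrix is not symmetric")
    w, v = np.linalg.eigh(mat)
    if w.min() < -1e-4:
        raise ValueError(f"matrix far from PSD (min eigenvalue {w.min():.3g})")
    return (v * np.sqrt(np.maximum(w, floor))) @ v.T


@dataclass(frozen=True)
class GammaGrid:
    """Power grids for SNPs (gamma1) and traits (gamma2); np.inf allowed."""

    gamma1_set: tuple = (1.0, 2.0, 4.0, 8.0)
    gamma2_set: tuple = (1.0, 2.0, 4.0, 8.0)

    def __post_init__(self) -> None:
        if not self.gamma1_set or not self.gamma2_set:
            raise ValueError("power grids must be nonempty")
        if min(self.gamma1_set) < 1 or min(self.gamma2_set) < 1:
            raise ValueError("powers must be >= 1")


@dataclass
class GeneZMatrix:
    """One gene's traits x SNPs z-matrix with SNP (R) and trait (V) correlations."""

    gene_id: str
    z: np.ndarray  # (m, d)
    r: np.ndarray  # (d, d)
    v: np.ndarray  # (m, m)

    def __post_init__(self) -> None:
        self.z = np.atleast_2d(np.asarray(self.z, dtype=float))
        m, d = self.z.shape
        if self.r.shape != (d, d) or self.v.shape != (m, m):
            raise ValueError(f"gene {self.gene_id}: R/V dimensions inconsistent with Z")
        if not (np.allclose(np.diag(self.r), 1.0) and np.allclose(np.diag(self.v), 1.0)):
            raise ValueError("R and V must have unit diagonal")

    @property
    def n_traits(self) -> int:
        return self.z.shape[0]

    @property
    def n_snps(self) -> int:
        return self.z.shape[1]


@dataclass
class GeneTestResult:
    gene_id: str
    p_mtaspusset: float
    p_aspus: np.ndarray  # per-trait adaptive p
    argmin_gamma: tuple  # (gamma1, gamma2) of the best cell
    argmin_gamma_aspus: tuple  # per-trait best gamma1
    b_used: int
    p_per_cell: dict = field(default_factory=dict)

    @property
    def min_attainable_p(self) -> float:
        return 1.0 / (self.b_used + 1)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def spus(z_row: np.ndarray, gamma1: float, signed: bool = False) -> float:
    """Sum of powered scores for one trait's SNP z-vector.

    Default reading: the gamma1-norm of absolute z-scores,
    ``(sum |z|^g)^(1/g)``; ``gamma1 = inf`` gives ``max |z|``.  The
    ``signed`` compatibility mode returns the raw signed power sum
    ``sum z^g`` (no absolute values, no outer root).
    """
    z = np.asarray(z_row, dtype=float)
    if z.ndim != 1 or z.size < 1:
        raise ValueError("z_row must be a nonempty vector")
    if signed:
        if np.isinf(gamma1):
            return float(np.max(np.abs(z)))
        return float((z ** gamma1).sum())
    if np.isinf(gamma1):
        return float(np.max(np.abs(z)))
    if gamma1 < 1:
        raise ValueError("gamma1 must be >= 1")
    return float((np.abs(z) ** gamma1).sum() ** (1.0 / gamma1))


def mtspusset(z: np.ndarray, gamma1: float, gamma2: float, signed: bool = False) -> float:
    """Multi-trait statistic: sum over traits of SPUs(gamma1)^gamma2."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    s = np.array([spus(row, gamma1, signed) for row in z])
    if signed:
        s = np.abs(s)
    return float((s ** gamma2).sum())


def _row_spus(bank: np.ndarray, gamma1_set: Sequence[float]) -> np.ndarray:
    """SPUs per draw/trait for each gamma1: (B, m, d) -> (B, m, n_g1)."""
    a = np.abs(bank)
    out = np.empty(bank.shape[:2] + (len(gamma1_set),))
    for i, g in enumerate(gamma1_set):
        if np.isinf(g):
            out[..., i] = a.max(axis=-1)
        else:
            out[..., i] = (a ** g).sum(axis=-1) ** (1.0 / g)
    return out


def _mt_cells(row_stats: np.ndarray, gamma2_set: Sequence[float]) -> np.ndarray:
    """(B, m, n_g1) SPUs -> (B, n_g1 * n_g2) MTSPUsSet cell statistics."""
    pieces = []
    for g2 in gamma2_set:
        if np.isinf(g2):
            pieces.append(row_stats.max(axis=1))
        else:
            pieces.append((row_stats ** g2).sum(axis=1))
    return np.concatenate(pieces, axis=-1)  # cells ordered g2-major, g1-minor


# ---------------------------------------------------------------------------
# null machinery
# ---------------------------------------------------------------------------

def simulate_null_bank(
    r: np.ndarray, v: np.ndarray, n_draws: int, seed: int,
    chunk: int = 100_000, floor: float = 1e-8,
) -> Iterator[np.ndarray]:
    """Stream matrix-normal null z-matrices Z_b = L_V X L_R^T in chunks.

    The vectorized covariance is kron(V, R); both factors are
    eigenvalue-floored before factorization.  V uses its symmetric square
    root so the null law is equivariant under trait relabelling.
    Reproducible under ``seed``.
    """
    l_r = _psd_factor(np.asarray(r, dtype=float), floor)
    l_v = _sym_sqrt(np.asarray(v, dtype=float), floor)
    m, d = l_v.shape[0], l_r.shape[0]
    rng = np.random.default_rng(seed)
    done = 0
    while done < n_draws:
        c = min(chunk, n_draws - done)
        x = rng.standard_normal((c, m, d))
        yield l_v @ x @ l_r.T
        done += c


def _mc_pvalues(t_obs: np.ndarray, t_bank: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell Monte-Carlo p for the observation and for each null draw.

    p_obs(c) = (1 + #{b : T_b >= T_obs}) / (B + 1); p_b(c) ranks T_b against
    the other B - 1 draws with the same +1 correction.
    """
    n_draws = t_bank.shape[0]
    p_obs = np.empty(t_obs.shape)
    p_bank = np.empty(t_bank.shape)
    for c in range(t_bank.shape[1]):
        col = t_bank[:, c]
        srt = np.sort(col)
        p_obs[c] = (1.0 + n_draws - np.searchsorted(srt, t_obs[c], side="left")) / (n_draws + 1)
        cnt_ge = n_draws - np.searchsorted(srt, col, side="left")  # includes self
        p_bank[:, c] = cnt_ge / n_draws
    return p_obs, p_bank


def _adaptive_p(p_obs: np.ndarray, p_bank: np.ndarray) -> float:
    n_draws = p_bank.shape[0]
    min_obs = p_obs.min()
    min_bank = p_bank.min(axis=1)
    return float((1.0 + (min_bank <= min_obs).sum()) / (n_draws + 1))


def estimate_trait_correlation(
    z_matrix: np.ndarray,
    prune_idx: np.ndarray | None = None,
    z_cap: float = 2.0,
    min_snps: int = 500,
    floor: float = 1e-8,
) -> np.ndarray:
    """Trait z-score correlation V from pruned, signal-capped SNPs.

    Uses genome-wide columns of the (traits x SNPs) z-matrix restricted to
    ``prune_idx`` and to SNPs with max |z| < ``z_cap`` across traits
    (excluding true-signal SNPs so V reflects only correlated noise).
    Truncating each margin at +-z_cap attenuates the correlation of the
    surviving null z's by the truncated-normal variance factor
    ``v = 1 - 2 c phi(c) / (2 Phi(c) - 1)`` (first order in rho); the
    estimate is divided by that factor.  The result has unit diagonal and
    is PSD-floored.
    """
    z = np.asarray(z_matrix, dtype=float)
    if prune_idx is not None:
        z = z[:, prune_idx]
    keep = np.abs(z).max(axis=0) < z_cap
    if keep.sum() < min_snps:
        raise ValueError(f"only {int(keep.sum())} capped SNPs; need >= {min_snps}")
    v = np.atleast_2d(np.corrcoef(z[:, keep]))
    from scipy import stats as _stats
    c = float(z_cap)
    atten = 1.0 - 2.0 * c * _stats.norm.pdf(c) / (2.0 * _stats.norm.cdf(c) - 1.0)
    off = ~np.eye(v.shape[0], dtype=bool)
    v[off] = np.clip(v[off] / atten, -0.99, 0.99)
    w, vecs = np.linalg.eigh(v)
    v = (vecs * np.maximum(w, floor)) @ vecs.T
    dd = np.sqrt(np.diag(v))
    v = v / np.outer(dd, dd)
    np.fill_diagonal(v, 1.0)
    return v


# ---------------------------------------------------------------------------
# adaptive tests
# ---------------------------------------------------------------------------

def aspus(
    z_row: np.ndarray,
    r: np.ndarray,
    gamma1_set: Sequence[float] = (1.0, 2.0, 4.0, 8.0),
    n_draws: int = 1000,
    seed: int = 0,
    chunk: int = 100_000,
) -> tuple[float, dict, float]:
    """Single-trait adaptive SPUs p-value via one shared null bank.

    Returns (adaptive p, per-gamma observed p, argmin gamma).
    """
    z = np.asarray(z_row, dtype=float)[None, None, :]
    t_obs = _row_spus(z, gamma1_set)[0, 0]
    banks = []
    for zb in simulate_null_bank(r, np.eye(1), n_draws, seed, chunk):
        banks.append(_row_spus(zb, gamma1_set)[:, 0, :])
    t_bank = np.concatenate(banks, axis=0)
    p_obs, p_bank = _mc_pvalues(t_obs, t_bank)
    p_ad = _adaptive_p(p_obs, p_bank)
    per_gamma = {g: float(p) for g, p in zip(gamma1_set, p_obs)}
    best = gamma1_set[int(np.argmin(p_obs))]
    return p_ad, per_gamma, best


def mtaspusset(
    gz: GeneZMatrix,
    grid: GammaGrid = GammaGrid(),
    n_draws: int = 1000,
    seed: int = 0,
    chunk: int = 100_000,
) -> GeneTestResult:
    """Multi-trait adaptive test plus per-trait aSPUs from one null bank.

    The double Monte Carlo reuses a single matrix-normal bank: per-cell
    observed p-values use the bank directly, and the adaptive minimum-p is
    ranked against each draw's own minimum over the grid.
    """
    g1s, g2s = grid.gamma1_set, grid.gamma2_set
    t_obs_rows = _row_spus(gz.z[None], g1s)  # (1, m, n_g1)
    t_obs_mt = _mt_cells(t_obs_rows, g2s)[0]

    rows_list = []
    for zb in simulate_null_bank(gz.r, gz.v, n_draws, seed, chunk):
        rows_list.append(_row_spus(zb, g1s))
    rows = np.concatenate(rows_list, axis=0)  # (B, m, n_g1)
    t_bank_mt = _mt_cells(rows, g2s)

    p_obs_mt, p_bank_mt = _mc_pvalues(t_obs_mt, t_bank_mt)
    p_mt = _adaptive_p(p_obs_mt, p_bank_mt)
    cell_idx = int(np.argmin(p_obs_mt))
    argmin = (g1s[cell_idx % len(g1s)], g2s[cell_idx // len(g1s)])

    m = gz.n_traits
    p_tr = np.empty(m)
    best_g1 = []
    for h in range(m):
        p_obs_h, p_bank_h = _mc_pvalues(t_obs_rows[0, h], rows[:, h, :])
        p_tr[h] = _adaptive_p(p_obs_h, p_bank_h)
        best_g1.append(g1s[int(np.argmin(p_obs_h))])

    per_cell = {(g1s[i % len(g1s)], g2s[i // len(g1s)]): float(p)
                for i, p in enumerate(p_obs_mt)}
    return GeneTestResult(
        gene_id=gz.gene_id, p_mtaspusset=p_mt, p_aspus=p_tr,
        argmin_gamma=argmin, argmin_gamma_aspus=tuple(best_g1),
        b_used=rows.shape[0], p_per_cell=per_cell,
    )


def staged_p(
    gz: GeneZMatrix,
    grid: GammaGrid = GammaGrid(),
    schedule: Sequence[int] = DEFAULT_SCHEDULE,
    escalate_factor: float = 5.0,
    seed: int = 0,
    chunk: int = 100_000,
) -> GeneTestResult:
    """Run the adaptive test with Monte-Carlo size escalation.

    Stages run in increasing order of B; the scan stops as soon as both the
    multi-trait p and every per-trait p exceed ``escalate_factor / B`` (the
    estimate is then resolved well above the Monte-Carlo floor), otherwise
    the next stage re-runs at larger B with a fresh stream.
    """
    if list(schedule) != sorted(schedule):
        raise ValueError("schedule must be increasing")
    res = None
    for stage, b in enumerate(schedule):
        res = mtaspusset(gz, grid, int(b), seed=(seed + stage) % (2 ** 31), chunk=chunk)
        thr = escalate_factor / b
        if res.p_mtaspusset >= thr and (res.p_aspus >= thr).all():
            break
    return res


def _gene_seed(master_seed: int, gene_id: str) -> int:
    return (int(master_seed) + zlib.crc32(gene_id.encode())) % (2 ** 31)


def classify_pleiotropic(
    p_mtaspusset: float,
    p_aspus: np.ndarray,
    threshold: float,
    known_traits: set | None = None,
) -> tuple[bool, bool]:
    """(pleiotropic, novel) flags for one gene.

    Pleiotropic: significant in the multi-trait test AND in at least one
    single-trait adaptive test at the gene-level Bonferroni threshold.
    Novel: pleiotropic and absent from the known-association lookup.
    """
    pleio = bool(p_mtaspusset < threshold and (np.asarray(p_aspus) < threshold).any())
    return pleio, bool(pleio and not known_traits)


def gene_scan(
    z_matrix: np.ndarray,
    gene_map: dict[str, np.ndarray],
    ld: LdInfo,
    v: np.ndarray,
    trait_ids: Sequence[str] | None = None,
    grid: GammaGrid = GammaGrid(),
    schedule: Sequence[int] = DEFAULT_SCHEDULE,
    alpha: float = 0.05,
    seed: int = 0,
    known_associations: dict[str, set] | None = None,
    d_cap: int = 500,
) -> tuple[pd.DataFrame, list[str]]:
    """Genome scan: per-gene multi-trait and per-trait adaptive p-values.

    Each gene is tested at the Bonferroni threshold ``alpha / G`` where G is
    the number of genes tested.  A gene is flagged pleiotropic when its
    multi-trait p and at least one per-trait p are both significant, and
    novel when additionally absent from ``known_associations``.  Per-gene
    seeds derive from the master seed plus a gene-id hash, so results do not
    depend on scan order.
    """
    m = z_matrix.shape[0]
    ids = list(trait_ids) if trait_ids else [f"trait{t+1}" for t in range(m)]
    genes = [g for g, idx in gene_map.items() if len(idx) > 0]
    audit: list[str] = []
    n_genes = len(genes)
    if n_genes == 0:
        raise ValueError("no genes with SNPs to test")
    threshold = alpha / n_genes

    records = []
    for gene in genes:
        idx = np.asarray(gene_map[gene])
        if len(idx) > d_cap:
            audit.append(f"{gene}: {len(idx)} SNPs capped to {d_cap}")
            idx = idx[:d_cap]
        r = ld.submatrix(idx)
        gz = GeneZMatrix(gene, z_matrix[:, idx], r, v)
        res = staged_p(gz, grid, schedule, seed=_gene_seed(seed, gene))
        known = known_associations.get(gene) if known_associations else None
        pleio, novel = classify_pleiotropic(res.p_mtaspusset, res.p_aspus, threshold, known)
        rec = {"gene": gene, "n_snps": len(idx), "p_mtaspusset": res.p_mtaspusset}
        for tid, p in zip(ids, res.p_aspus):
            rec[f"p_aspus_{tid}"] = p
        rec.update({
            "b_used": res.b_used,
            "significant_mt": bool(res.p_mtaspusset < threshold),
            "pleiotropic": pleio,
            "novel": novel,
            "known_traits": ",".join(sorted(known)) if known else "",
        })
        records.append(rec)
    table = pd.DataFrame(records).sort_values("p_mtaspusset", kind="mergesort")
    return table.reset_index(drop=True), audit
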