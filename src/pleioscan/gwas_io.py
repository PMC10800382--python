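"""Summary-statistics, reference-panel and gene-model I/O plus LD utilities.

Conventions
-----------
* Genomic coordinates are 1-based inclusive throughout.  BED input
  (0-based, half-open) is converted at read time via a flag.
* Summary statistics are whitespace/tab delimited with a header; the
  canonical column order on write is ``SNP CHR BP A1 A2 Z N P``.
* LD windows and pruning windows are counted in SNPs, not kb.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats

__all__ = [
    "SummaryStats",
    "GenotypePanel",
    "LdInfo",
    "GeneModel",
    "SumstatsError",
    "read_sumstats",
    "write_sumstats",
    "read_panel",
    "read_gene_models",
    "read_annotations",
    "harmonize",
    "compute_ld",
    "block_ld_info",
    "category_ld_scores",
    "ld_prune",
    "map_snps_to_genes",
]

CANONICAL_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "Z", "N", "P"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class SumstatsError(ValueError):
    """Raised on malformed or unusable summary-statistics input."""


@dataclass
class SummaryStats:
    """One trait's per-SNP z-scores with alleles and sample size.

    ``table`` holds the canonical columns SNP CHR BP A1 A2 Z N P, sorted by
    (CHR, BP) with unique SNP ids.
    """

    trait_id: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.table.columns]
        if missing:
            raise SumstatsError(f"summary statistics missing columns: {missing}")
        if self.table["SNP"].duplicated().any():
            raise SumstatsError("duplicate SNP ids in summary statistics")
        self.table = self.table.sort_values(["CHR", "BP"], kind="mergesort").reset_index(drop=True)

    @property
    def n_snps(self) -> int:
        return len(self.table)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class GenotypePanel:
    """Reference genotypes: samples x SNPs allele counts in {0,1,2}.

    Missing dosages are NaN.  Monomorphic SNPs (zero variance after
    missing-value removal) are rejected at construction.
    """

    snp_meta: pd.DataFrame  # columns SNP CHR BP A1 A2
    dosages: np.ndarray  # (n_samples, n_snps) float, NaN = missing

    def __post_init__(self) -> None:
        if self.dosages.ndim != 2 or self.dosages.shape[1] != len(self.snp_meta):
            raise ValueError("dosage matrix does not match SNP metadata")
        with np.errstate(invalid="ignore"):
            var = np.nanvar(self.dosages, axis=0)
        bad = ~(var > 0)
        if bad.any():
            ids = self.snp_meta["SNP"].to_numpy()[bad]
            raise ValueError(f"monomorphic panel SNPs rejected: {list(ids[:5])}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]


@dataclass
class LdInfo:
    """SNP-SNP correlation structure: banded r, LD scores, r2 histograms.

    ``r`` is stored sparse (CSR); ``r2_hist`` counts neighbour (self
    excluded) r-squared values per SNP over fixed ``r2_bin_edges``.
    ``blocks`` optionally records independent index ranges [(start, stop)),
    used by simulators to draw LD-correlated noise blockwise.
    """

    snp_ids: np.ndarray
    r: sparse.csr_matrix
    ld_scores: np.ndarray
    r2_hist: np.ndarray  # (n_snps, n_bins) counts
    r2_bin_edges: np.ndarray
    blocks: list[tuple[int, int]] | None = None

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def r2_bin_mids(self) -> np.ndarray:
        e = self.r2_bin_edges
        return 0.5 * (e[:-1] + e[1:])

    def submatrix(self, idx: np.ndarray) -> np.ndarray:
        """Dense correlation matrix for a subset of SNP indices."""
        sub = self.r[np.ix_(idx, idx)].toarray()
        np.fill_diagonal(sub, 1.0)
        return sub


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_DEFAULT_DIALECT: Mapping[str, str] = {
    "SNP": "SNP", "CHR": "CHR", "BP": "BP", "A1": "A1", "A2": "A2",
    "Z": "Z", "N": "N", "P": "P", "BETA": "BETA", "SE": "SE",
}


def read_sumstats(
    path,
    trait_id: str | None = None,
    dialect: Mapping[str, str] | None = None,
    p_tolerance: float = 1e-4,
) -> tuple[SummaryStats, pd.DataFrame]:
    """Read one trait's summary statistics from a delimited text file.

    ``dialect`` maps canonical names (SNP, CHR, BP, A1, A2, Z or BETA+SE,
    N, P) to the file's column names.  Z is taken directly or computed as
    BETA/SE.  Rows violating the record invariants (non-finite z, a1 == a2,
    or a stated p inconsistent with the two-sided normal tail of |z| beyond
    ``p_tolerance``) are dropped and itemised in the returned audit frame.

    Returns ``(SummaryStats, audit)``; raises :class:`SumstatsError` when a
    mandatory column is absent or no valid row remains.
    """
    dia = dict(_DEFAULT_DIALECT)
    if dialect:
        dia.update(dialect)
    raw = pd.read_csv(path, sep=r"\s+", dtype={dia["SNP"]: str})

    def col(name: str, required: bool = True):
        src = dia[name]
        if src not in raw.columns:
            if required:
                raise SumstatsError(f"missing mandatory column '{src}' (for {name})")
            return None
        return raw[src]

    snp = col("SNP")
    chrom = col("CHR").astype(str)
    bp = pd.to_numeric(col("BP"), errors="coerce")
    a1 = col("A1").astype(str).str.upper()
    a2 = col("A2").astype(str).str.upper()
    n = pd.to_numeric(col("N"), errors="coerce")

    zc = col("Z", required=False)
    if zc is not None:
        z = pd.to_numeric(zc, errors="coerce")
    else:
        beta, se = col("BETA", required=False), col("SE", required=False)
        if beta is None or se is None:
            raise SumstatsError("need a Z column or both BETA and SE columns")
        z = pd.to_numeric(beta, errors="coerce") / pd.to_numeric(se, errors="coerce")

    pc = col("P", required=False)
    p = pd.to_numeric(pc, errors="coerce") if pc is not None else pd.Series(np.nan, index=raw.index)

    reasons = pd.Series("", index=raw.index)
    bad = ~np.isfinite(z)
    reasons[bad & (reasons == "")] = "non-finite z"
    same = (a1 == a2)
    reasons[same & (reasons == "")] = "a1 == a2"
    badn = ~(n > 0)
    reasons[badn & (reasons == "")] = "non-positive N"
    p_implied = 2.0 * stats.norm.sf(np.abs(z.fillna(0.0)))
    p_bad = p.notna() & np.isfinite(z) & (np.abs(p - p_implied) > p_tolerance)
    reasons[p_bad & (reasons == "")] = "p inconsistent with z"

    keep = reasons == ""
    audit = pd.DataFrame({"SNP": snp[~keep], "reason": reasons[~keep]}).reset_index(drop=True)
    if not keep.any():
        raise SumstatsError("no valid rows after validation")

    out = pd.DataFrame({
        "SNP": snp[keep].astype(str),
        "CHR": chrom[keep],
        "BP": bp[keep].astype(np.int64),
        "A1": a1[keep],
        "A2": a2[keep],
        "Z": z[keep].astype(float),
        "N": n[keep].astype(float),
        "P": np.where(p[keep].notna(), p[keep], 2.0 * stats.norm.sf(np.abs(z[keep]))),
    })
    tid = trait_id if trait_id is not None else str(path)
    return SummaryStats(tid, out), audit


def write_sumstats(ss: SummaryStats, path) -> None:
    ss.table[CANONICAL_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_panel(dosage_path, meta_path, missing: str = "NA") -> GenotypePanel:
    """Read a delimited dosage matrix with a sidecar SNP metadata table."""
    meta = pd.read_csv(meta_path, sep=r"\s+", dtype={"SNP": str})
    dos = pd.read_csv(dosage_path, sep=r"\s+", header=None, na_values=[missing])
    return GenotypePanel(meta, dos.to_numpy(dtype=float))


def read_gene_models(path, bed: bool = False) -> list[GeneModel]:
    """Read gene intervals.

    Default: 1-based inclusive 4+ column table (gene chrom start end
    [strand]) with a header.  With ``bed=True``: headerless BED
    (chrom start end name [score strand]), 0-based half-open, converted to
    1-based inclusive.
    """
    genes: list[GeneModel] = []
    if bed:
        tab = pd.read_csv(path, sep=r"\s+", header=None)
        for row in tab.itertuples(index=False):
            strand = str(row[5]) if len(row) > 5 else "unknown"
            genes.append(GeneModel(str(row[3]), str(row[0]), int(row[1]) + 1, int(row[2]), strand))
    else:
        tab = pd.read_csv(path, sep=r"\s+")
        cols = list(tab.columns)
        for row in tab.itertuples(index=False):
            strand = str(row[4]) if len(cols) > 4 else "unknown"
            genes.append(GeneModel(str(row[0]), str(row[1]), int(row[2]), int(row[3]), strand))
    return genes


def read_annotations(path) -> pd.DataFrame:
    """Read a binary SNP x category annotation matrix (header, SNP column)."""
    tab = pd.read_csv(path, sep=r"\s+", dtype={"SNP": str})
    return tab.set_index("SNP")


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

def _is_palindromic(a1: str, a2: str) -> bool:
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


def harmonize(
    traits: Sequence[SummaryStats], panel_meta: pd.DataFrame
) -> tuple[np.ndarray, pd.DataFrame, pd.DataFrame]:
    """Align alleles of several traits to a reference panel.

    Keeps SNPs present in every trait and the panel; flips the z sign where
    a trait's effect/other alleles are swapped relative to the panel
    (allowing strand complements); removes strand-ambiguous palindromic
    (A/T, C/G) SNPs and SNPs with irreconcilable alleles.

    Parameters
    ----------
    panel_meta : DataFrame with columns SNP CHR BP A1 A2 (e.g.
        ``GenotypePanel.snp_meta``).

    Returns
    -------
    z_matrix : (n_traits, n_snps) array of harmonized z-scores.
    universe : panel-ordered metadata of retained SNPs (SNP CHR BP A1 A2
        plus per-trait N columns).
    audit : per-SNP disposition for every excluded SNP.
    """
    if not traits:
        raise ValueError("need at least one trait")
    if len(panel_meta) == 0:
        raise ValueError("empty panel")

    panel = panel_meta.reset_index(drop=True)
    pal = np.array([_is_palindromic(a.upper(), b.upper())
                    for a, b in zip(panel["A1"], panel["A2"])])
    disposition = np.full(len(panel), "kept", dtype=object)
    disposition[pal] = "palindromic"

    trait_maps = []
    for ss in traits:
        t = ss.table.set_index("SNP")
        trait_maps.append(t)
        missing = ~panel["SNP"].isin(t.index).to_numpy()
        disposition[missing & (disposition == "kept")] = "absent from trait"

    kept_idx = np.flatnonzero(disposition == "kept")
    z_rows, n_rows = [], []
    for ss, t in zip(traits, trait_maps):
        sub = t.loc[panel["SNP"].to_numpy()[kept_idx]]
        z = sub["Z"].to_numpy(dtype=float).copy()
        pa1 = panel["A1"].to_numpy()[kept_idx]
        pa2 = panel["A2"].to_numpy()[kept_idx]
        ta1 = sub["A1"].to_numpy()
        ta2 = sub["A2"].to_numpy()
        ca1 = np.array([_COMPLEMENT.get(a, "?") for a in ta1])
        ca2 = np.array([_COMPLEMENT.get(a, "?") for a in ta2])
        match = ((ta1 == pa1) & (ta2 == pa2)) | ((ca1 == pa1) & (ca2 == pa2))
        swapped = ((ta1 == pa2) & (ta2 == pa1)) | ((ca1 == pa2) & (ca2 == pa1))
        bad = ~(match | swapped)
        z[swapped & ~match] *= -1.0
        if bad.any():
            disposition[kept_idx[bad]] = "irreconcilable alleles"
        z_rows.append(z)
        n_rows.append(sub["N"].to_numpy(dtype=float))

    final = disposition[kept_idx] == "kept"
    kept_idx = kept_idx[final]
    if kept_idx.size == 0:
        raise ValueError("no SNPs shared by all traits and the panel after harmonization")
    z_matrix = np.vstack([z[final] for z in z_rows])

    universe = panel.iloc[kept_idx].reset_index(drop=True).copy()
    for ss, nvec in zip(traits, n_rows):
        universe[f"N_{ss.trait_id}"] = nvec[final]
    audit = pd.DataFrame({"SNP": panel["SNP"], "disposition": disposition})
    audit = audit[audit["disposition"] != "kept"].reset_index(drop=True)
    return z_matrix, universe, audit


# ---------------------------------------------------------------------------
# LD computation, pruning, gene mapping
# ---------------------------------------------------------------------------

DEFAULT_R2_BIN_EDGES = np.linspace(0.0, 1.0, 21)


def compute_ld(
    panel: GenotypePanel,
    window_snps: int = 100,
    bias_correct: bool = False,
    r2_bin_edges: np.ndarray | None = None,
) -> LdInfo:
    """Windowed Pearson LD from a reference panel.

    Missing dosages are mean-imputed per SNP.  ``ld_score_j = 1 +
    sum_{k != j, |k-j| <= window} r2_jk``; with ``bias_correct`` each
    off-diagonal r2 is first replaced by ``r2 - (1 - r2)/(n - 2)`` floored
    at 0 (the standard finite-sample adjustment).
    """
    if window_snps < 1:
        raise ValueError("window_snps must be >= 1")
    n, m = panel.dosages.shape
    if bias_correct and n < 3:
        raise ValueError("bias correction needs at least 3 samples")
    edges = DEFAULT_R2_BIN_EDGES if r2_bin_edges is None else np.asarray(r2_bin_edges)

    x = panel.dosages.copy()
    mu = np.nanmean(x, axis=0)
    ix = np.where(np.isnan(x))
    x[ix] = np.take(mu, ix[1])
    x -= x.mean(axis=0)
    x /= np.sqrt((x ** 2).sum(axis=0))

    rows, cols, vals = [], [], []
    ld = np.ones(m)
    hist = np.zeros((m, len(edges) - 1))
    for j in range(m):
        lo, hi = max(0, j - window_snps), min(m, j + window_snps + 1)
        r = x[:, lo:hi].T @ x[:, j]
        k = np.arange(lo, hi)
        off = k != j
        r2 = r ** 2
        r2_adj = r2.copy()
        if bias_correct:
            r2_adj[off] = np.maximum(r2[off] - (1.0 - r2[off]) / (n - 2), 0.0)
        ld[j] = 1.0 + r2_adj[off].sum()
        hist[j] = np.histogram(np.clip(r2[off], 0.0, 1.0), bins=edges)[0]
        rows.extend([j] * len(k))
        cols.extend(k.tolist())
        vals.extend(r.tolist())
    rmat = sparse.csr_matrix((vals, (rows, cols)), shape=(m, m))
    return LdInfo(panel.snp_meta["SNP"].to_numpy(), rmat, ld, hist, edges,
                  blocks=[(0, m)])


def block_ld_info(
    n_snps: int,
    block_size: int | Sequence[int],
    rho: float | tuple[float, float],
    seed: int | None = None,
    snp_ids: Sequence[str] | None = None,
    r2_bin_edges: np.ndarray | None = None,
) -> LdInfo:
    """Exact block-equicorrelated LdInfo (no panel needed).

    Consecutive blocks of ``block_size`` SNPs (an int, or a sequence
    sampled from) share pairwise correlation ``rho`` — a constant, a
    2-tuple (lo, hi) uniform range sampled per block, or a list/array of
    discrete values sampled per block.  Used by the simulator as the known
    LD ground truth.
    """
    rng = np.random.default_rng(seed)
    edges = DEFAULT_R2_BIN_EDGES if r2_bin_edges is None else np.asarray(r2_bin_edges)

    sizes: list[int] = []
    total = 0
    while total < n_snps:
        if np.isscalar(block_size):
            s = int(block_size)
        else:
            s = int(rng.choice(np.asarray(block_size)))
        s = min(s, n_snps - total)
        sizes.append(s)
        total += s

    rows_l, cols_l, vals_l = [], [], []
    ld = np.empty(n_snps)
    hist = np.zeros((n_snps, len(edges) - 1))
    blocks: list[tuple[int, int]] = []
    start = 0
    for s in sizes:
        if np.isscalar(rho):
            rho_b = float(rho)
        elif isinstance(rho, tuple) and len(rho) == 2:
            rho_b = float(rng.uniform(rho[0], rho[1]))
        else:
            rho_b = float(rng.choice(np.asarray(rho)))
        stop = start + s
        blocks.append((start, stop))
        idx = np.arange(start, stop)
        block = np.full((s, s), rho_b)
        np.fill_diagonal(block, 1.0)
        rows_l.append(np.repeat(idx, s))
        cols_l.append(np.tile(idx, s))
        vals_l.append(block.ravel())
        ld[start:stop] = 1.0 + (s - 1) * rho_b ** 2
        b = np.clip(np.searchsorted(edges, rho_b ** 2, side="right") - 1, 0, len(edges) - 2)
        hist[start:stop, b] = s - 1
        start = stop
    ids = np.array([f"rs{i+1}" for i in range(n_snps)]) if snp_ids is None else np.asarray(snp_ids)
    rmat = sparse.csr_matrix(
        (np.concatenate(vals_l), (np.concatenate(rows_l), np.concatenate(cols_l))),
        shape=(n_snps, n_snps))
    return LdInfo(ids, rmat, ld, hist, edges, blocks=blocks)


def category_ld_scores(ld: LdInfo, annot: np.ndarray) -> np.ndarray:
    """Per-category LD scores l(j, c) = sum_k r2_jk * a_kc (self included)."""
    a = np.asarray(annot, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    r2 = ld.r.copy()
    r2.data = r2.data ** 2
    return np.asarray(r2 @ a)


def ld_prune(
    ld: LdInfo,
    window_snps: int = 50,
    step_snps: int = 5,
    r2_threshold: float = 0.1,
) -> np.ndarray:
    """Greedy windowed LD pruning (PLINK indep-pairwise style, SNP-count units).

    Windows of ``window_snps`` SNPs are scanned left to right, advancing by
    ``step_snps``.  Within a window, for every surviving pair with
    r2 > ``r2_threshold`` the later-position SNP is dropped.  Deterministic;
    returns the kept SNP ids in position order.
    """
    if window_snps < 1 or step_snps < 1:
        raise ValueError("window and step must be positive")
    if not (0.0 < r2_threshold <= 1.0):
        raise ValueError("r2_threshold must be in (0, 1]")
    m = ld.n_snps
    keep = np.ones(m, dtype=bool)
    r = ld.r.tocsr()
    start = 0
    while True:
        stop = min(start + window_snps, m)
        idx = np.arange(start, stop)
        for a_pos in range(len(idx)):
            j = idx[a_pos]
            if not keep[j]:
                continue
            row = r.getrow(j)
            for k, rv in zip(row.indices, row.data):
                if k <= j or k >= stop or k < start or not keep[k]:
                    continue
                if rv ** 2 > r2_threshold:
                    keep[k] = False
        if stop >= m:
            break
        start += step_snps
    return ld.snp_ids[keep]


def map_snps_to_genes(
    universe: pd.DataFrame,
    genes: Iterable[GeneModel],
    flank_bp: int = 0,
) -> dict[str, np.ndarray]:
    """Assign SNPs (rows of a harmonized universe with CHR/BP) to genes.

    A SNP belongs to every gene with ``start - flank <= pos <= end + flank``
    (1-based inclusive); genes with zero SNPs are omitted.  Returns
    gene_id -> sorted array of row indices into ``universe``.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    chrom = universe["CHR"].astype(str).to_numpy()
    pos = universe["BP"].to_numpy()
    out: dict[str, np.ndarray] = {}
    for g in genes:
        mask = (chrom == str(g.chrom)) & (pos >= g.start - flank_bp) & (pos <= g.end + flank_bp)
        idx = np.flatnonzero(mask)
        if idx.size:
            out[g.gene_id] = idx[np.argsort(pos[idx], kind="mergesort")]
    return out
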