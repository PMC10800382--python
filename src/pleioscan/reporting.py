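"""Multiple-testing thresholds, gene-set enrichment and table emitters."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bonferroni_threshold",
    "EnrichmentResult",
    "hypergeometric_enrichment",
    "read_gene_sets",
    "format_thousands",
    "rg_lower_triangle",
    "emit_table",
]


def round_sig(x: float, sig_figs: int) -> float:
    """Round to ``sig_figs`` significant figures."""
    if sig_figs < 1:
        raise ValueError("sig_figs must be >= 1")
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig_figs - 1))


def bonferroni_threshold(alpha: float, m_tests: int, sig_figs: int = 3) -> float:
    """Family-wise significance threshold alpha / m, rounded to significant figures."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    return round_sig(alpha / m_tests, sig_figs)


@dataclass
class EnrichmentResult:
    set_id: str
    overlap_genes: list[str]
    k_overlap: int
    k_set: int
    n_query: int
    n_background: int
    p: float
    p_adjusted: float = float("nan")

    def __post_init__(self) -> None:
        if self.k_overlap > min(self.k_set, self.n_query):
            raise ValueError("overlap exceeds set or query size")


def hypergeometric_enrichment(
    query: list[str],
    sets: dict[str, list[str]],
    background: list[str],
    adjust: str = "BH",
) -> list[EnrichmentResult]:
    """Over-representation of a gene list in named gene sets.

    Upper hypergeometric tail P(X >= k) with population = background,
    successes = set members in background, draws = query size.  Query genes
    must lie in the background; each set is intersected with the background
    before testing.  ``adjust`` is BH (default) or bonferroni, applied
    across the tested sets.  Results are sorted by raw p.
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    q = set(query)
    if not q <= bg:
        raise ValueError("query genes must be a subset of the background")
    results = []
    for set_id, members in sets.items():
        s = set(members) & bg
        overlap = sorted(q & s)
        k, big_k, n, big_n = len(overlap), len(s), len(q), len(bg)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        results.append(EnrichmentResult(set_id, overlap, k, big_k, n, big_n, min(p, 1.0)))
    if results:
        raw = [r.p for r in results]
        method = {"BH": "fdr_bh", "bonferroni": "bonferroni"}[adjust]
        adj = multipletests(raw, method=method)[1]
        for r, pa in zip(results, adj):
            r.p_adjusted = float(max(pa, r.p))
    return sorted(results, key=lambda r: (r.p, r.set_id))


def read_gene_sets(path) -> dict[str, list[str]]:
    """Two-column long format: set-name <tab> gene."""
    tab = pd.read_csv(path, sep=r"\s+", header=None, names=["set", "gene"])
    return {name: grp["gene"].tolist() for name, grp in tab.groupby("set", sort=True)}


def format_thousands(count: float) -> str:
    """Variant counts on the K scale with two decimals: 210 -> '0.21K'."""
    return f"{count / 1000.0:.2f}K"


def rg_lower_triangle(trait_ids: list[str], rg_fits: dict) -> pd.DataFrame:
    """Lower-triangle genetic-correlation table over all trait pairs.

    ``rg_fits`` maps unordered pairs (tuple of two trait ids) to RgFit-like
    objects with rg / rg_se / p attributes; exactly C(T, 2) rows emerge.
    """
    rows = []
    for i, t1 in enumerate(trait_ids):
        for t2 in trait_ids[:i]:
            fit = rg_fits.get((t1, t2), rg_fits.get((t2, t1)))
            if fit is None:
                raise KeyError(f"missing rg fit for pair ({t1}, {t2})")
            rows.append({"trait1": t1, "trait2": t2, "rg": fit.rg,
                         "rg_se": fit.rg_se, "p": fit.p})
    return pd.DataFrame(rows)


def emit_table(frame: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    """Deterministic delimited output (stable row order left to the caller)."""
    frame.to_csv(path, sep="\t", index=False, float_format=float_format)
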