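#!/usr/bin/env python
"""Hypergeometric gene-set enrichment of the pleiotropic genes.

Queries the scan's pleiotropic genes against gene sets (one set is
constructed around half of the flagged genes to act as a positive control;
the rest are random draws from the background), with BH adjustment across
sets, mirroring a functional-annotation table.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from pleioscan import reporting

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "enrichment"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    scan = pd.read_csv(ROOT / "gene_scan" / "gene_scan.tsv", sep="\t")
    background = scan["gene"].tolist()
    query = scan.loc[scan["pleiotropic"], "gene"].tolist()
    if not query:
        print("no pleiotropic genes flagged; nothing to enrich")
        return

    rng = np.random.default_rng(7)
    positive = list(query[: max(len(query) // 2, 1)]) + \
        list(rng.choice(background, size=20, replace=False))
    sets = {"positive_control": sorted(set(positive))}
    for i in range(5):
        sets[f"random_set_{i}"] = list(
            rng.choice(background, size=25, replace=False))

    results = reporting.hypergeometric_enrichment(query, sets, background,
                                                  adjust="BH")
    tab = pd.DataFrame([{
        "set": r.set_id, "k_overlap": r.k_overlap, "set_size": r.k_set,
        "query_size": r.n_query, "p": r.p, "p_adjusted": r.p_adjusted,
        "genes": ",".join(r.overlap_genes),
    } for r in results])
    reporting.emit_table(tab, OUT / "gene_sets.tsv")
    print(tab.drop(columns="genes").to_string(index=False, float_format="%.3g"))


if __name__ == "__main__":
    main()
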