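"""Gene-set over-representation analysis of DEG lists.

Over-representation of a gene list in each gene set is tested with the
hypergeometric upper tail P(X >= k) on the overlap k, against a finite
gene universe (by default all genes tested for differential expression).
Sets passing p < 0.05 and BH q < 0.1 are ranked by descending -log2(q)
and the top 10 reported.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .dge import bh_adjust

__all__ = ["hypergeom_ora", "enrichment_table", "top_sets"]


def hypergeom_ora(gene_list, gene_set, universe) -> tuple[int, float]:
    """Overlap size and hypergeometric upper-tail p of a list vs a set.

    ``p = P(X >= k)`` where X ~ Hypergeom(N=|universe|, m=|set|,
    n=|list|). Both list and set must be subsets of the universe.
    """
    uni = set(universe)
    lst = set(gene_list)
    st = set(gene_set)
    outside = sorted((lst | st) - uni)
    if outside:
        raise ValueError(f"genes outside the universe: {outside[:10]}")
    n_uni, m, n = len(uni), len(st), len(lst)
    k = len(lst & st)
    p = float(hypergeom.sf(k - 1, n_uni, m, n))
    return k, min(p, 1.0)


def enrichment_table(gene_list, gene_sets: dict, universe) -> pd.DataFrame:
    """ORA of one gene list against a collection of sets.

    Returns a table with per-set overlap, raw p, BH q, -log2(q) and rank
    (1 = most enriched); ties in q break by smaller raw p, then name.
    """
    if not gene_sets:
        raise ValueError("no gene sets supplied")
    uni = set(universe)
    rows = []
    for name, genes in gene_sets.items():
        genes_in = [g for g in dict.fromkeys(genes) if g in uni]
        k, p = hypergeom_ora(gene_list, genes_in, uni)
        rows.append({"set": name, "set_size": len(genes_in), "overlap": k, "pvalue": p})
    table = pd.DataFrame(rows).set_index("set")
    table["universe"] = len(uni)
    table["list_size"] = len(set(gene_list))
    table["qvalue"] = bh_adjust(table["pvalue"])
    with np.errstate(divide="ignore"):
        table["neg_log2_q"] = -np.log2(table["qvalue"])
    order = table.sort_values(
        by=["neg_log2_q", "pvalue", "set"], ascending=[False, True, True]
    ).index
    table["rank"] = pd.Series(np.arange(1, len(order) + 1), index=order)
    return table.loc[order]


def top_sets(
    table: pd.DataFrame,
    n: int = 10,
    p_max: float = 0.05,
    q_max: float = 0.1,
) -> pd.DataFrame:
    """The top-``n`` sets by -log2(q) among those meeting the
    significance criteria (p < p_max and q < q_max); may be shorter."""
    passing = table[(table["pvalue"] < p_max) & (table["qvalue"] < q_max)].copy()
    passing["_name"] = passing.index
    ordered = passing.sort_values(
        by=["neg_log2_q", "pvalue", "_name"], ascending=[False, True, True]
    ).drop(columns="_name")
    return ordered.head(n)
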