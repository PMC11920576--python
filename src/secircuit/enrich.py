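"""Over-representation analysis (ORA) of a query gene set against a GMT
collection: one-sided hypergeometric upper-tail p per set with
Benjamini-Hochberg adjustment."""

from __future__ import annotations

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection


def ora_test(query_genes, gene_sets: GeneSetCollection, universe,
             alpha: float = 0.05) -> pd.DataFrame:
    """Hypergeometric over-representation test for each gene set.

    With universe size N, set size K (after intersecting the set with the
    universe), query size n and overlap k, p = P[X >= k] for
    X ~ Hypergeom(N, K, n).  Rows are BH-adjusted across tested sets,
    flagged significant at raw p <= alpha, and sorted by (p, name).
    """
    universe = frozenset(universe)
    query = frozenset(query_genes)
    if not universe:
        raise ValueError("empty universe")
    if not query:
        raise ValueError("empty query")
    if not query <= universe:
        raise ValueError(f"query genes outside universe: "
                         f"{sorted(query - universe)[:5]}")
    rows = []
    n = len(query)
    N = len(universe)
    for name in sorted(gene_sets.sets):
        members = gene_sets.sets[name] & universe
        if not members:
            continue
        K = len(members)
        k = len(members & query)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, K, n, N, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["set_name", "overlap", "set_size",
                                     "query_size", "universe_size", "pvalue"])
    if len(df):
        df["qvalue"] = multipletests(df["pvalue"], method="fdr_bh")[1]
        df["significant"] = df["pvalue"] <= alpha
        df = df.sort_values(["pvalue", "set_name"], kind="mergesort")
        df = df.reset_index(drop=True)
    else:
        df["qvalue"] = []
        df["significant"] = []
    return df
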