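"""Hypergeometric over-representation analysis against GMT gene sets.

For a query of n genes drawn from a measured universe of N genes and an
annotation set covering K universe genes of which k are in the query, the
one-sided enrichment p-value is the upper hypergeometric tail
P(X >= k); BH correction runs across all tested sets.
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy import stats

from .diffexpr import bh_fdr
from .iolib import GeneSetCollection

logger = logging.getLogger("dynprognet")


def hypergeom_enrich(query: set[str], sets: GeneSetCollection,
                     universe: set[str], alpha: float = 0.05) -> pd.DataFrame:
    """One-sided over-representation of each gene set in the query.

    Query genes outside the universe are dropped (logged); sets with no
    universe overlap are skipped.  Returns one row per tested set with
    k (query hits), K (set size in universe), n (query size), N (universe
    size), p, BH q, a significance flag at ``alpha`` on q, and the hit list.
    """
    if not universe:
        raise ValueError("universe is empty")
    universe = set(universe)
    dropped = query - universe
    if dropped:
        logger.info("hypergeom_enrich: %d query genes outside universe dropped",
                    len(dropped))
    query = query & universe
    if not query:
        raise ValueError("query is empty after intersecting with universe")
    n, N = len(query), len(universe)
    rows = []
    for name, members in sets.sets.items():
        in_universe = members & universe
        K = len(in_universe)
        if K == 0:
            continue
        hits = sorted(query & in_universe)
        k = len(hits)
        # upper tail: P(X >= k) with X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        p = min(max(p, 0.0), 1.0)
        rows.append((name, k, K, n, N, p, ",".join(hits)))
    if not rows:
        return pd.DataFrame(columns=["set_name", "k", "K", "n", "N",
                                     "p_value", "q_value", "significant",
                                     "gene_hits"])
    out = pd.DataFrame(rows, columns=["set_name", "k", "K", "n", "N",
                                      "p_value", "gene_hits"])
    out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    out["significant"] = out["q_value"] < alpha
    out = out[["set_name", "k", "K", "n", "N", "p_value", "q_value",
               "significant", "gene_hits"]]
    return out.sort_values(["p_value", "set_name"]).reset_index(drop=True)
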