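"""Hypergeometric gene-set over-representation with BH correction.

The standard upper-tail hypergeometric test: for a query of n genes
drawn from a universe of N, a term covering K universe genes, and k
query hits, p = P(X >= k) with X ~ Hypergeom(N, K, n).  This is the
package's deliberate stand-in for web-service enrichment engines; it is
exact, dependency-light, and auditable.
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy import stats

from .expression import benjamini_hochberg

log = logging.getLogger("regcascade")


def hypergeom_enrich(query, universe, collection: dict[str, list[str]],
                     ) -> pd.DataFrame:
    """Upper-tail hypergeometric p per term, BH across terms, sorted by p.

    ``query`` must be a subset of ``universe``; each collection set is
    intersected with the universe before testing.
    """
    query = set(query)
    universe = set(universe)
    if not query:
        raise ValueError("hypergeom_enrich: empty query")
    stray = query - universe
    if stray:
        raise ValueError(f"hypergeom_enrich: query genes outside the universe: "
                         f"{sorted(stray)[:5]}...")
    N, n = len(universe), len(query)
    rows = []
    for term in sorted(collection):
        members = set(collection[term]) & universe
        K = len(members)
        if K == 0:
            continue
        k = len(members & query)
        # P(X >= k); sf(k-1) is the exact upper tail
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N,
                     "pvalue": min(p, 1.0)})
    table = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "pvalue"])
    if len(table):
        table["fdr"] = benjamini_hochberg(table["pvalue"].to_numpy())
        table = (table.sort_values(["pvalue", "term"], kind="stable")
                 .reset_index(drop=True))
    else:
        table["fdr"] = []
    log.info("hypergeom_enrich: %d terms tested, query n=%d, universe N=%d",
             len(table), n, N)
    return table
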