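"""Hypergeometric over-representation of gene lists against GO/KEGG-style sets.

For a query of n genes drawn from a universe of N genes, a set with K members
in the universe and k members in the query is scored by the upper-tail
hypergeometric probability P(X >= k).  P-values are BH-adjusted across all
sets tested within a namespace, and each retained term gets an enrichment
score ES = -log10(adjusted p).

The universe defaults, in the pipeline, to the orthologs present in all
species after mapping — the background actually tested.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from xsci.diffexpr import benjamini_hochberg
from xsci.io import GeneSetCollection

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "term_id", "term_name", "namespace", "k", "K", "n", "N",
    "p", "p_adj", "es", "overlap_genes",
]


def enrichment_score(p_adj: float) -> float:
    """-log10 of an adjusted p-value; p_adj = 0 is clamped to the smallest
    positive float (logged)."""
    if p_adj < 0 or p_adj > 1:
        raise ValueError("p_adj must lie in [0, 1]")
    if p_adj == 0:
        p_adj = float(np.nextafter(0.0, 1.0))
        logger.info("enrichment_score: p_adj = 0 clamped to %.3g", p_adj)
    return -math.log10(p_adj) + 0.0  # avoid -0.0 at p_adj = 1


def hypergeom_enrich(
    query: Iterable[str],
    sets: GeneSetCollection,
    universe: Iterable[str],
    p_adj_max: float | None = 0.05,
) -> pd.DataFrame:
    """Over-representation of *query* against every set in *sets*.

    Each set is intersected with the universe before testing; empty
    intersections are skipped (logged).  BH adjustment runs across all tested
    sets in the collection (one namespace).  With the default
    ``p_adj_max = 0.05`` only significant terms are returned; pass None for
    the full table.  Rows are sorted by (p_adj, p, term_id).
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    query_set = set(query)
    offenders = sorted(query_set - universe_set)
    if offenders:
        raise ValueError(f"query genes absent from the universe: {offenders}")
    N = len(universe_set)
    n = len(query_set)

    rows = []
    n_skipped = 0
    for term_id, (term_name, members) in sets.sets.items():
        in_universe = frozenset(members) & universe_set
        K = len(in_universe)
        if K == 0:
            n_skipped += 1
            continue
        overlap = sorted(in_universe & query_set)
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        p = min(max(p, 0.0), 1.0)
        rows.append(
            {
                "term_id": term_id, "term_name": term_name,
                "namespace": sets.namespace,
                "k": k, "K": K, "n": n, "N": N, "p": p,
                "overlap_genes": ",".join(overlap),
            }
        )
    if n_skipped:
        logger.info(
            "enrichment: skipped %d set(s) with no members in the universe",
            n_skipped,
        )
    if not rows:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    df = pd.DataFrame(rows)
    df["p_adj"] = benjamini_hochberg(df["p"].to_numpy())
    if p_adj_max is not None:
        df = df[df["p_adj"] <= p_adj_max]
    df["es"] = [enrichment_score(v) for v in df["p_adj"]]
    df = df.sort_values(["p_adj", "p", "term_id"], kind="mergesort", ignore_index=True)
    return df[RESULT_COLUMNS]


def top_k_by_namespace(
    results: pd.DataFrame,
    k: int = 5,
    query: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Top-k most enriched terms per namespace.

    Terms are ranked by smallest ``p_adj``; ties broken by larger overlap
    ``k`` then lexicographic ``term_id``.  When ``query`` is given, each row
    also reports how many and what percentage of the query genes fall into at
    least one set of that namespace (columns ``n_query_in_namespace``,
    ``pct_query_in_namespace``).
    """
    if results.empty:
        return results.copy()
    ranked = results.sort_values(
        ["namespace", "p_adj", "k", "term_id"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    top = ranked.groupby("namespace", group_keys=False).head(k).reset_index(drop=True)
    if query is not None:
        query_set = set(query)
        cover: dict[str, int] = {}
        for ns, grp in results.groupby("namespace"):
            hit: set[str] = set()
            for genes in grp["overlap_genes"]:
                if genes:
                    hit.update(genes.split(","))
            cover[ns] = len(hit & query_set)
        top["n_query_in_namespace"] = top["namespace"].map(cover)
        top["pct_query_in_namespace"] = (
            100.0 * top["n_query_in_namespace"] / max(len(query_set), 1)
        )
    return top
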