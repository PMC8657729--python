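"""Confidence filtering and degree ordering of protein-interaction networks.

Mirrors the STRING/Cytoscape workflow: keep edges at or above a confidence
cut-off (0.4, STRING's "medium confidence", by default), restrict to the query
gene list, drop singletons, and order the remaining nodes by descending degree
(the "degree sorted circle layout" ordering), ties lexicographic.
"""

from __future__ import annotations

import logging
from typing import Iterable

import networkx as nx
import pandas as pd

from xsci.io import normalize_edges

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 0.4


def filter_network(
    edges: pd.DataFrame,
    cutoff: float = DEFAULT_CUTOFF,
    query_nodes: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Filter an undirected, confidence-scored edge list.

    Parameters
    ----------
    edges : DataFrame with columns node_a, node_b, confidence
        Self-loops and duplicate undirected edges are normalized away first.
    cutoff : float in [0, 1]
        Edges with confidence >= cutoff are kept.
    query_nodes : optional
        When given, both endpoints must belong to this set.

    Returns
    -------
    (filtered, order) : the surviving edges (sorted by node pair) and the
        node ordering by descending degree, ties broken lexicographically.
        Nodes of degree 0 (singletons) do not appear.  An empty result is
        allowed (logged).
    """
    if not (0.0 <= cutoff <= 1.0):
        raise ValueError("cutoff must lie in [0, 1]")
    df = normalize_edges(edges)
    df = df[df["confidence"] >= cutoff]
    if query_nodes is not None:
        allowed = set(query_nodes)
        df = df[df["node_a"].isin(allowed) & df["node_b"].isin(allowed)]
    df = df.reset_index(drop=True)
    if df.empty:
        logger.info("network filter: no edges survive cutoff %.3g", cutoff)
        return df, []

    g = nx.Graph()
    g.add_edges_from(zip(df["node_a"], df["node_b"]))
    order = sorted(g.nodes, key=lambda v: (-g.degree[v], v))
    return df, order


def degree_table(edges: pd.DataFrame) -> pd.Series:
    """Node degrees of an edge list, descending, ties lexicographic."""
    g = nx.Graph()
    g.add_edges_from(zip(edges["node_a"], edges["node_b"]))
    deg = pd.Series(dict(g.degree), name="degree", dtype=int)
    return deg.sort_index().sort_values(ascending=False, kind="mergesort")
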