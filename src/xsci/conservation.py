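"""Amino-acid conservation: identity, Poisson distances, NJ trees, orderings.

Distances are in expected substitutions per site.  The Poisson correction
d = -ln(1 - p) converts the observed proportion of differing sites p into a
multiple-hit-corrected distance; comparable sites are counted per pair with
pairwise deletion (columns holding a gap or an 'X' in either member of the
pair are excluded for that pair only).

Trees are built by the classic Saitou-Nei neighbor-joining agglomeration and
returned as ``skbio.TreeNode`` objects (Newick in/out, Robinson-Foulds
comparisons).  Ties in the Q-criterion are broken by the lexicographically
smallest taxon pair so runs are deterministic; negative branch lengths are
clamped to zero with the deficit logged.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from skbio import DistanceMatrix, TreeNode

from xsci.io import AlignedSequenceSet

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# identity and distances
# ---------------------------------------------------------------------------


def percent_identity(aln: AlignedSequenceSet, reference: str) -> pd.Series:
    """Percent identity of every taxon against *reference*.

    identity = identical columns / columns where neither sequence has a gap,
    times 100; terminal and internal gap columns are both excluded from the
    denominator.
    """
    if reference not in aln.taxa:
        raise ValueError(f"reference taxon {reference!r} not in alignment")
    ref = np.frombuffer(aln.row(reference).encode(), dtype="S1")
    out = {}
    for taxon in aln.taxa:
        row = np.frombuffer(aln.row(taxon).encode(), dtype="S1")
        comparable = (ref != b"-") & (row != b"-")
        n_comp = int(comparable.sum())
        if n_comp == 0:
            raise ValueError(
                f"no comparable (gap-free) columns between {taxon!r} and "
                f"{reference!r}"
            )
        n_same = int((ref[comparable] == row[comparable]).sum())
        out[taxon] = 100.0 * n_same / n_comp
    return pd.Series(out, name=f"pct_identity_vs_{reference}")


def poisson_distance(aln: AlignedSequenceSet) -> DistanceMatrix:
    """Poisson-corrected pairwise distances with pairwise deletion.

    For each pair, columns with a gap or ambiguity 'X' in either sequence are
    removed; p = differing / comparable columns and d = -ln(1 - p).  A pair
    with p >= 1 (or no comparable columns) has no defined distance and raises.
    """
    n = len(aln.taxa)
    arr = np.array([np.frombuffer(r.encode(), dtype="S1") for r in aln.rows])
    usable = (arr != b"-") & (arr != b"X")
    d = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            comparable = usable[i] & usable[j]
            n_comp = int(comparable.sum())
            if n_comp == 0:
                raise ValueError(
                    f"no comparable columns between {aln.taxa[i]!r} and "
                    f"{aln.taxa[j]!r} after pairwise deletion"
                )
            p = float((arr[i, comparable] != arr[j, comparable]).sum()) / n_comp
            if p >= 1.0:
                raise ValueError(
                    f"pair ({aln.taxa[i]!r}, {aln.taxa[j]!r}) differs at every "
                    "comparable site; Poisson distance undefined"
                )
            d[i, j] = d[j, i] = -np.log1p(-p)
    return DistanceMatrix(d, ids=list(aln.taxa))


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; returns an unrooted tree (trifurcating root).

    At each step the pair (i, j) minimizing
    Q(i, j) = (r - 2) d(i, j) - R_i - R_j  (R_i = sum_k d(i, k))
    is joined; ties are broken by the lexicographically smallest (sorted)
    taxon-name pair, internal nodes being represented by their smallest leaf
    name.  Branch lengths use the standard formulas; negative lengths are
    clamped to 0 and the deficit logged.  Exact on additive matrices.
    """
    d = np.asarray(dm.data, dtype=float)
    ids = list(dm.ids)
    if len(ids) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite distances")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix is not symmetric")

    def clamp(length: float, context: str) -> float:
        if length < 0:
            logger.info("NJ: clamped negative branch length %.4g at %s", length, context)
            return 0.0
        return float(length)

    # active clusters: (sort key = smallest leaf name, TreeNode)
    nodes: list[TreeNode] = [TreeNode(name=t) for t in ids]
    keys: list[str] = list(ids)
    dist = d.copy()

    while len(nodes) > 3:
        r = len(nodes)
        row_sums = dist.sum(axis=1)
        best: tuple[float, str, str] | None = None
        best_pair = (-1, -1)
        for i in range(r):
            for j in range(i + 1, r):
                q = (r - 2) * dist[i, j] - row_sums[i] - row_sums[j]
                name_pair = tuple(sorted((keys[i], keys[j])))
                cand = (q, *name_pair)
                if best is None or cand < best:
                    best = cand
                    best_pair = (i, j)
        i, j = best_pair
        li = 0.5 * dist[i, j] + (row_sums[i] - row_sums[j]) / (2.0 * (r - 2))
        lj = dist[i, j] - li
        pair_ctx = f"({keys[i]},{keys[j]})"
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = clamp(li, pair_ctx)
        child_j.length = clamp(lj, pair_ctx)
        new_node = TreeNode(children=[child_i, child_j])
        new_key = min(keys[i], keys[j])

        new_d = 0.5 * (dist[i, :] + dist[j, :] - dist[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        nd = np.zeros((r - 1, r - 1))
        nd[: r - 2, : r - 2] = dist[np.ix_(keep, keep)]
        nd[r - 2, : r - 2] = nd[: r - 2, r - 2] = new_d[keep]
        dist = nd
        nodes = [nodes[k] for k in keep] + [new_node]
        keys = [keys[k] for k in keep] + [new_key]

    # resolve the last three clusters by the three-point formulas
    (a, b, c) = range(3)
    la = 0.5 * (dist[a, b] + dist[a, c] - dist[b, c])
    lb = 0.5 * (dist[a, b] + dist[b, c] - dist[a, c])
    lc = 0.5 * (dist[a, c] + dist[b, c] - dist[a, b])
    ctx = f"root ({keys[a]},{keys[b]},{keys[c]})"
    for node, length in zip(nodes, (la, lb, lc)):
        node.length = clamp(length, ctx)
    # deterministic child order by cluster key
    order = sorted(range(3), key=lambda k: keys[k])
    root = TreeNode(children=[nodes[k] for k in order])
    return root


# ---------------------------------------------------------------------------
# heatmap orderings: cosine hierarchical clustering + spherical k-means
# ---------------------------------------------------------------------------


def _spherical_kmeans(
    x: np.ndarray, k: int, rng: np.random.Generator,
    n_restarts: int = 10, max_iter: int = 100,
) -> tuple[np.ndarray, float]:
    """K-means under 1 - cosine dissimilarity on L2-normalized rows.

    Centroids are the normalized means of their members; inertia is the sum of
    (1 - cosine similarity to the assigned centroid).  The best of
    ``n_restarts`` seeded restarts is kept.
    """
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    xn = x / norms
    n = xn.shape[0]
    best_labels = None
    best_inertia = np.inf
    for _ in range(n_restarts):
        centroids = xn[rng.choice(n, size=k, replace=False)]
        labels = np.full(n, -1, dtype=int)
        for _iteration in range(max_iter):
            sims = xn @ centroids.T
            new_labels = np.argmax(sims, axis=1)
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for c in range(k):
                members = xn[labels == c]
                if len(members) == 0:
                    # re-seed an empty cluster at the worst-fit row
                    worst = int(np.argmin(np.max(sims, axis=1)))
                    centroids[c] = xn[worst]
                else:
                    m = members.mean(axis=0)
                    nm = np.linalg.norm(m)
                    centroids[c] = m / nm if nm > 0 else centroids[c]
        sims = xn @ centroids.T
        inertia = float(np.sum(1.0 - sims[np.arange(n), labels]))
        if inertia < best_inertia:
            best_inertia = inertia
            best_labels = labels.copy()
    return best_labels, best_inertia


def order_for_heatmap(
    values: pd.DataFrame,
    n_gene_clusters: int = 4,
    seed: int = 0,
) -> tuple[list[str], pd.Series]:
    """Heatmap ordering: species columns by cosine average-linkage, gene rows
    by spherical k-means.

    Parameters
    ----------
    values : DataFrame
        Genes (rows) by species (columns).
    n_gene_clusters : int
        k for the gene k-means (default 4).
    seed : int
        Seeds the k-means restarts.

    Returns
    -------
    (species_order, gene_labels) : leaf order of the species dendrogram
        (average linkage on 1 - cosine) and a per-gene cluster label Series.
        All-zero gene rows have no direction under cosine and get the sentinel
        label -1 (logged).  All-zero species columns are an error.
    """
    x = values.to_numpy(dtype=float)
    col_norm = np.linalg.norm(x, axis=0)
    if np.any(col_norm == 0):
        zero_cols = [c for c, nz in zip(values.columns, col_norm) if nz == 0]
        raise ValueError(f"all-zero species column(s): {zero_cols}")

    # species: average-linkage hierarchical clustering on 1 - cosine
    if values.shape[1] < 2:
        species_order = list(values.columns)
    else:
        link = hierarchy.linkage(pdist(x.T, metric="cosine"), method="average")
        leaves = hierarchy.leaves_list(link)
        species_order = [values.columns[i] for i in leaves]

    row_norm = np.linalg.norm(x, axis=1)
    zero_rows = row_norm == 0
    if zero_rows.any():
        logger.info(
            "heatmap ordering: %d all-zero gene row(s) assigned sentinel "
            "cluster -1", int(zero_rows.sum()),
        )
    usable = x[~zero_rows]
    if n_gene_clusters > usable.shape[0]:
        raise ValueError(
            f"k = {n_gene_clusters} exceeds the {usable.shape[0]} usable genes"
        )
    rng = np.random.default_rng(seed)
    labels_usable, _ = _spherical_kmeans(usable, n_gene_clusters, rng)
    labels = np.full(len(values), -1, dtype=int)
    labels[~zero_rows] = labels_usable
    return species_order, pd.Series(labels, index=values.index, name="gene_cluster")


# ---------------------------------------------------------------------------
# isoform selection helper
# ---------------------------------------------------------------------------


def select_longest_isoforms(
    sequences: dict[str, str], gene_of: dict[str, str]
) -> dict[str, tuple[str, str]]:
    """Keep the longest record per gene (ties by lexicographically smallest id).

    ``sequences`` maps record id -> sequence, ``gene_of`` record id -> gene.
    Returns gene -> (record id, sequence).
    """
    best: dict[str, tuple[str, str]] = {}
    for rec_id in sorted(sequences):
        gene = gene_of.get(rec_id)
        if gene is None:
            continue
        seq = sequences[rec_id]
        ungapped = seq.replace("-", "")
        if gene not in best or len(ungapped) > len(best[gene][1].replace("-", "")):
            best[gene] = (rec_id, seq)
    return best
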