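"""Hierarchical clustering, interaction-network filtering, pathway overlap.

The clustering reproduces the heatmap settings used for the panel data:
Euclidean distance and complete (maximum) linkage, with genes below the
detection threshold set to 0 before distances are taken.  The network
utilities post-process packaged gene-gene interaction edge lists by
confidence threshold (0.700 "high confidence", 0.900 "highest
confidence" in the STRING convention) and intersect gene sets with
pathway membership tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

EDGE_COLUMNS = ("gene_a", "gene_b", "confidence")

HIGH_CONFIDENCE = 0.700
HIGHEST_CONFIDENCE = 0.900


def zero_fill(matrix) -> pd.DataFrame:
    """Replace MISSING (NaN) entries by 0, leaving the rest unchanged.

    Accepts a DataFrame or any labelled matrix exposing ``values_frame``
    (masked counts, ranks or quantile scores).
    """
    frame = getattr(matrix, "values_frame", matrix)
    return pd.DataFrame(frame).fillna(0.0)


def euclidean_distances(matrix, axis: str = "genes") -> pd.DataFrame:
    """Pairwise Euclidean distances between rows (genes) or columns (samples)."""
    frame = pd.DataFrame(getattr(matrix, "values_frame", matrix))
    if axis == "samples":
        frame = frame.T
    elif axis != "genes":
        raise ValueError("axis must be 'genes' or 'samples'")
    if len(frame) < 2:
        raise ValueError("need at least 2 items to compute distances")
    d = squareform(pdist(frame.to_numpy(dtype=float), metric="euclidean"))
    return pd.DataFrame(d, index=frame.index, columns=frame.index)


@dataclass
class Dendrogram:
    """Agglomerative merge history over ``labels``.

    ``merges`` lists (cluster_a, cluster_b, height, new_size) with leaves
    numbered 0..n-1 and each merge creating cluster n+i, the convention
    used by scipy linkage matrices.
    """

    merges: list = field(default_factory=list)
    labels: list = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def to_linkage_matrix(self) -> np.ndarray:
        """scipy-style (n-1) x 4 linkage matrix."""
        return np.array(
            [[a, b, h, s] for a, b, h, s in self.merges], dtype=float
        )

    def heights(self) -> list:
        return [h for _, _, h, _ in self.merges]

    def _children(self) -> dict:
        return {
            self.n_leaves + i: (a, b) for i, (a, b, _, _) in enumerate(self.merges)
        }

    def _node_heights(self) -> dict:
        heights = {i: 0.0 for i in range(self.n_leaves)}
        for i, (_, _, h, _) in enumerate(self.merges):
            heights[self.n_leaves + i] = h
        return heights

    def leaf_order(self) -> list:
        """Leaf labels in dendrogram (left-to-right) order."""
        children = self._children()

        def walk(node):
            if node < self.n_leaves:
                return [node]
            a, b = children[node]
            return walk(a) + walk(b)

        root = self.n_leaves + len(self.merges) - 1
        return [self.labels[i] for i in walk(root)]

    def to_newick(self) -> str:
        """Newick string with branch lengths = height differences."""
        children = self._children()
        heights = self._node_heights()

        def render(node, parent_height):
            length = parent_height - heights[node]
            if node < self.n_leaves:
                label = str(self.labels[node]).replace(" ", "_")
                return f"{label}:{length:.10g}"
            a, b = children[node]
            h = heights[node]
            return f"({render(a, h)},{render(b, h)}):{length:.10g}"

        root = self.n_leaves + len(self.merges) - 1
        h = heights[root]
        return f"({render(children[root][0], h)},{render(children[root][1], h)});"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.merges, columns=["cluster_a", "cluster_b", "height", "new_size"]
        )


def _validate_distance(d: pd.DataFrame) -> np.ndarray:
    arr = np.asarray(d, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(arr, arr.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(arr < 0):
        raise ValueError("distances must be nonnegative")
    if not np.allclose(np.diag(arr), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    return arr


def complete_linkage(d) -> Dendrogram:
    """Agglomerative clustering with complete (maximum) linkage.

    At each step the pair of active clusters at minimum inter-cluster
    distance is merged, where inter-cluster distance is the maximum
    pairwise distance between members.  Ties are broken by the smallest
    (lexicographic) pair of cluster indices, so the output is fully
    deterministic.  Complete linkage is monotone, so merge heights never
    decrease; this is verified on every run.
    """
    if isinstance(d, pd.DataFrame):
        labels = [str(x) for x in d.index]
    else:
        labels = [str(i) for i in range(np.asarray(d).shape[0])]
    arr = _validate_distance(d)
    n = arr.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items to cluster")

    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(arr[i, j])
    sizes = {i: 1 for i in range(n)}
    active = set(range(n))
    merges = []
    next_id = n
    last_height = -np.inf
    for _ in range(n - 1):
        best = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        (a, b), height = best
        if height < last_height - 1e-9:
            raise RuntimeError("complete-linkage heights decreased (internal error)")
        last_height = max(last_height, height)
        new_size = sizes[a] + sizes[b]
        merges.append((a, b, height, new_size))
        active -= {a, b}
        for k in active:
            dist[_pair(next_id, k)] = max(
                dist.pop(_pair(a, k)), dist.pop(_pair(b, k))
            )
        del dist[(a, b)]
        sizes[next_id] = new_size
        active.add(next_id)
        next_id += 1
    return Dendrogram(merges=merges, labels=labels)


def _pair(i: int, j: int) -> tuple:
    return (i, j) if i < j else (j, i)


def cluster_matrix(matrix, axis: str = "genes") -> Dendrogram:
    """Euclidean/complete-linkage clustering of a (zero-filled) matrix."""
    return complete_linkage(euclidean_distances(zero_fill(matrix), axis=axis))


def _validate_edges(edges: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in EDGE_COLUMNS if c not in edges.columns]
    if missing:
        raise ValueError(f"edge list missing columns: {missing}")
    conf = np.asarray(edges["confidence"], dtype=float)
    if np.any((conf < 0) | (conf > 1)):
        raise ValueError("confidences must lie in [0, 1]")
    if (edges["gene_a"] == edges["gene_b"]).any():
        raise ValueError("self-loops are not allowed")
    key = edges.apply(
        lambda r: tuple(sorted((str(r["gene_a"]), str(r["gene_b"])))), axis=1
    )
    if key.duplicated().any():
        raise ValueError("duplicate edges for the same unordered gene pair")
    return edges


def filter_edges(edges: pd.DataFrame, min_conf: float) -> pd.DataFrame:
    """Retain edges with confidence >= ``min_conf`` (boundary inclusive)."""
    if not 0.0 <= min_conf <= 1.0:
        raise ValueError("min_conf must lie in [0, 1]")
    edges = _validate_edges(edges)
    kept = edges[edges["confidence"] >= min_conf]
    return kept.reset_index(drop=True)


def connected_components(
    edges: pd.DataFrame, universe: Iterable | None = None
) -> list:
    """Partition of ``universe`` (plus edge endpoints) into components.

    Genes with no retained edge are singletons.  Components are returned
    as frozensets sorted by decreasing size then smallest member.
    """
    edges = _validate_edges(edges) if len(edges) else edges
    graph = nx.Graph()
    if universe is not None:
        graph.add_nodes_from(str(g) for g in universe)
    for _, row in edges.iterrows():
        graph.add_edge(str(row["gene_a"]), str(row["gene_b"]))
    comps = [frozenset(c) for c in nx.connected_components(graph)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def pathways_from_frame(frame: pd.DataFrame) -> dict:
    """Long-format (pathway_id, gene_id) table -> {pathway_id: gene set}."""
    for col in ("pathway_id", "gene_id"):
        if col not in frame.columns:
            raise ValueError(f"pathway table missing column {col!r}")
    return {
        str(p): set(sub["gene_id"].astype(str))
        for p, sub in frame.groupby("pathway_id")
    }


def pathway_overlap(genes: Iterable, pathways: Mapping[str, Iterable]) -> pd.DataFrame:
    """Exact set intersection of a gene set with each pathway.

    Identifiers are case-sensitive.  Returns one row per pathway with the
    overlap count and the sorted overlapping members.
    """
    gene_set = {str(g) for g in genes}
    rows = []
    for pid in sorted(pathways):
        members = {str(g) for g in pathways[pid]}
        inter = sorted(gene_set & members)
        rows.append(
            {
                "pathway_id": pid,
                "n_members": len(members),
                "overlap": len(inter),
                "overlap_genes": ",".join(inter),
            }
        )
    return pd.DataFrame(rows, columns=["pathway_id", "n_members", "overlap", "overlap_genes"])


def heatmap_figure(matrix, axis: str = "genes", cmap: str = "viridis"):
    """Optional heatmap export: matrix reordered by the dendrogram.

    Returns a matplotlib Figure with the zero-filled matrix reordered on
    the clustered axis.  Rendering is a thin convenience; the tested
    surface is the merge structure itself.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    frame = zero_fill(matrix)
    tree = cluster_matrix(frame, axis=axis)
    order = tree.leaf_order()
    ordered = frame.loc[order] if axis == "genes" else frame[order]
    fig, ax = plt.subplots(figsize=(6, 6))
    im = ax.imshow(ordered.to_numpy(dtype=float), aspect="auto", cmap=cmap)
    ax.set_yticks(range(len(ordered.index)))
    ax.set_yticklabels(ordered.index, fontsize=6)
    ax.set_xticks(range(len(ordered.columns)))
    ax.set_xticklabels(ordered.columns, rotation=90, fontsize=6)
    fig.colorbar(im, ax=ax, label="value")
    fig.tight_layout()
    return fig
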