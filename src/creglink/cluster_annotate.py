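"""Joint RNA+ATAC clustering and correlation-based cell-type annotation.

The joint graph is a shared-nearest-neighbor (SNN) graph over the
per-component-standardized concatenation of the PCA and LSI embeddings
(a deliberate, documented substitute for weighted-nearest-neighbor
integration).  Clustering is Louvain at a configurable resolution;
annotation assigns each cluster pseudobulk the reference label with the
highest Spearman correlation over the top variable genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from scipy.stats import spearmanr
from sklearn.neighbors import NearestNeighbors

from .matrices import Pseudobulk, ReducedMatrix

__all__ = [
    "ClusterAssignment",
    "ReferencePseudobulks",
    "joint_neighbor_graph",
    "louvain_cluster",
    "annotate_clusters",
    "fallback_annotation",
    "read_reference_pseudobulks",
    "write_reference_pseudobulks",
]


@dataclass
class ClusterAssignment:
    assignments: Dict[str, int]  # barcode -> cluster id
    resolution: float

    def cluster_ids(self) -> List[int]:
        return sorted(set(self.assignments.values()))


@dataclass
class ReferencePseudobulks:
    """Reference label -> log-normalized mean expression vector."""

    feature_ids: list
    profiles: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for label, vec in self.profiles.items():
            if len(vec) != len(self.feature_ids):
                raise ValueError(f"profile {label!r} length mismatch")


def read_reference_pseudobulks(path) -> ReferencePseudobulks:
    """TSV with a ``feature`` column and one column per reference label."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    if "feature" not in df.columns:
        raise ValueError("reference pseudobulk TSV needs a 'feature' column")
    features = df["feature"].astype(str).tolist()
    profiles = {
        str(col): df[col].to_numpy(dtype=float)
        for col in df.columns
        if col != "feature"
    }
    return ReferencePseudobulks(features, profiles)


def write_reference_pseudobulks(ref: ReferencePseudobulks, path) -> None:
    import pandas as pd

    df = pd.DataFrame({"feature": ref.feature_ids})
    for label, vec in ref.profiles.items():
        df[label] = vec
    df.to_csv(path, sep="\t", index=False)


def _standardize(emb: np.ndarray) -> np.ndarray:
    sd = emb.std(axis=0)
    sd[sd == 0] = 1.0
    return (emb - emb.mean(axis=0)) / sd


def joint_neighbor_graph(
    rna: ReducedMatrix,
    atac: ReducedMatrix,
    barcodes: Sequence[str],
    k: int = 20,
) -> nx.Graph:
    """SNN graph over standardized, concatenated RNA/ATAC embeddings.

    Each cell's neighbor set is itself plus its k nearest cells by
    Euclidean distance; an edge between two cells in each other's kNN
    carries the Jaccard overlap of their neighbor sets.
    """
    n = len(barcodes)
    if rna.used.shape[0] != n or atac.used.shape[0] != n:
        raise ValueError("embeddings and barcode list disagree on cell count")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    joint = np.hstack([_standardize(rna.used), _standardize(atac.used)])
    nn = NearestNeighbors(n_neighbors=k + 1).fit(joint)
    _, idx = nn.kneighbors(joint)  # includes self at distance 0
    neighbor_sets = [set(row) | {i} for i, row in enumerate(idx)]

    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in idx[i]:
            j = int(j)
            if j <= i:
                continue
            inter = len(neighbor_sets[i] & neighbor_sets[j])
            union = len(neighbor_sets[i] | neighbor_sets[j])
            w = inter / union
            if w > 0:
                g.add_edge(i, j, weight=w)
    nx.set_node_attributes(g, {i: bc for i, bc in enumerate(barcodes)}, "barcode")
    return g


def louvain_cluster(
    graph: nx.Graph, resolution: float = 1.0, seed: int = 0
) -> ClusterAssignment:
    """Louvain modularity clustering; deterministic for a fixed seed.

    Community ids are renumbered by the smallest member node so labels do
    not depend on traversal order.
    """
    communities = nx.community.louvain_communities(
        graph, weight="weight", resolution=resolution, seed=seed
    )
    communities = sorted(communities, key=min)
    barcode = nx.get_node_attributes(graph, "barcode")
    assignments = {}
    for cid, nodes in enumerate(communities):
        for node in nodes:
            assignments[barcode.get(node, node)] = cid
    return ClusterAssignment(assignments, resolution)


def _reference_variable_genes(
    reference: ReferencePseudobulks, shared: List[str], n_var: int
) -> List[str]:
    pos = {f: i for i, f in enumerate(reference.feature_ids)}
    idx = [pos[f] for f in shared]
    mat = np.vstack([reference.profiles[l][idx] for l in reference.profiles])
    var = mat.var(axis=0)
    order = np.argsort(-var, kind="stable")
    return [shared[i] for i in order[: min(n_var, len(shared))]]


def annotate_clusters(
    query: Sequence[Pseudobulk],
    reference: ReferencePseudobulks,
    n_var: int = 3000,
) -> Dict[str, Tuple[str, float]]:
    """Assign each query pseudobulk the best-correlated reference label.

    Features are restricted to the query/reference intersection; the top
    ``n_var`` variable genes are selected on the reference side.  Returns
    ``{query group id: (label, Spearman rho)}``; ties go to the earlier
    reference label.
    """
    if not query:
        return {}
    ref_labels = list(reference.profiles)
    shared = [f for f in query[0].feature_ids if f in set(reference.feature_ids)]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared features; need >= 3")
    genes = _reference_variable_genes(reference, shared, n_var)

    ref_pos = {f: i for i, f in enumerate(reference.feature_ids)}
    ref_idx = [ref_pos[f] for f in genes]
    ref_mat = np.vstack([reference.profiles[l][ref_idx] for l in ref_labels])

    out: Dict[str, Tuple[str, float]] = {}
    for pb in query:
        q_pos = {f: i for i, f in enumerate(pb.feature_ids)}
        q = pb.values[[q_pos[f] for f in genes]]
        rhos = np.array([spearmanr(q, ref_mat[i]).statistic for i in range(len(ref_labels))])
        best = int(np.argmax(rhos))  # argmax keeps the first label on ties
        out[pb.group_id] = (ref_labels[best], float(rhos[best]))
    return out


def fallback_annotation(
    cluster_ids: Sequence[int], source_name: str
) -> Dict[int, str]:
    """Label every cluster with the sample's source name (no reference case)."""
    if not source_name:
        raise ValueError("source name must be non-empty for fallback annotation")
    return {cid: source_name for cid in cluster_ids}
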