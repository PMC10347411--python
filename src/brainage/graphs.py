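"""Graph construction from connectivity matrices.

Each parcellation region is a vertex; vertex i's feature vector is row i of
the FC matrix (its connectivity profile, including the self-correlation 1).
Directed edges (i, j) and (j, i) are kept wherever the correlation passes the
threshold, carrying the signed r_ij as a scalar edge feature. A threshold of
0 yields the complete graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .connectivity import ConnectivityMatrix

__all__ = ["BrainGraph", "build_graph", "stack_graphs"]


@dataclass
class BrainGraph:
    subject_id: str
    vertex_features: np.ndarray  # (R, R): row i = FC profile of region i
    edges: np.ndarray  # (n_edges, 2) directed pairs
    edge_features: np.ndarray  # (n_edges,) signed r_ij
    label: float  # chronological age in years
    region_labels: list[str] = field(default_factory=list)

    @property
    def n_vertices(self) -> int:
        return self.vertex_features.shape[0]

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency_mask(self) -> np.ndarray:
        """Dense {0,1} adjacency, mask[i, j] = 1 iff directed edge (i, j)."""
        R = self.n_vertices
        mask = np.zeros((R, R))
        if len(self.edges):
            mask[self.edges[:, 0], self.edges[:, 1]] = 1.0
        return mask

    def dense_edge_features(self) -> np.ndarray:
        """(R, R) matrix of edge features, 0 where no edge."""
        R = self.n_vertices
        E = np.zeros((R, R))
        if len(self.edges):
            E[self.edges[:, 0], self.edges[:, 1]] = self.edge_features
        return E


def build_graph(
    fc: ConnectivityMatrix,
    threshold: float = 0.0,
    age: float = np.nan,
    signed: bool = False,
) -> BrainGraph:
    """Threshold an FC matrix into a directed brain graph.

    By default the criterion is |r_ij| >= threshold, so strong negative
    correlations are kept; with ``signed=True`` the criterion is
    r_ij >= threshold instead.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    fc.validate()
    R = fc.n_regions
    vals = fc.values
    crit = vals >= threshold if signed else np.abs(vals) >= threshold
    np.fill_diagonal(crit, False)
    src, dst = np.nonzero(crit)
    edges = np.column_stack([src, dst]).astype(int)
    edge_features = vals[src, dst]

    degree = crit.sum(axis=1)
    isolated = np.flatnonzero(degree == 0)
    if isolated.size:
        names = [fc.region_labels[i] for i in isolated]
        warnings.warn(
            f"subject {fc.subject_id}: threshold {threshold} isolates "
            f"{isolated.size} vertex(es): {', '.join(names[:10])}",
            stacklevel=2,
        )
    return BrainGraph(
        subject_id=fc.subject_id,
        vertex_features=vals.copy(),
        edges=edges,
        edge_features=edge_features,
        label=float(age),
        region_labels=list(fc.region_labels),
    )


def stack_graphs(graphs: list[BrainGraph]):
    """Stack same-R graphs into dense batched arrays (X, E, mask, ages).

    X: (N, R, R) vertex features; E: (N, R, R) edge features (0 off-graph);
    mask: (N, R, R) adjacency; ages: (N,).
    """
    if not graphs:
        raise ValueError("no graphs to stack")
    R = graphs[0].n_vertices
    for g in graphs:
        if g.n_vertices != R:
            raise ValueError("all graphs must share the same vertex count")
    X = np.stack([g.vertex_features for g in graphs])
    E = np.stack([g.dense_edge_features() for g in graphs])
    mask = np.stack([g.adjacency_mask() for g in graphs])
    ages = np.array([g.label for g in graphs], dtype=float)
    return X, E, mask, ages
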