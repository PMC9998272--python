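"""Core containers: circles, tissue scaffolds, spatial parameters, labeled tissues.

A tissue is modeled as a planar graph: packed circles are cells, touching
circles are adjacent cells joined by an edge.  Cell-type information lives on
the nodes; all spatial statistics in this package are functions of the graph
and its labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .errors import InvalidParameterError

__all__ = [
    "Circle",
    "TissueScaffold",
    "SpatialParameters",
    "LabeledTissue",
    "induced_tissue",
]


@dataclass(frozen=True)
class Circle:
    """A packed circle (one cell) in abstract pixel units."""

    x: float
    y: float
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise InvalidParameterError(f"circle radius must be > 0, got {self.radius}")


class TissueScaffold:
    """A blank tissue: packed circles plus their planar adjacency graph.

    Nodes are integer circle indices ``0..n-1``.  The graph is simple and
    undirected; an edge means the two cells are adjacent (their circles come
    within ``r_min`` of touching).
    """

    def __init__(
        self,
        xy: np.ndarray,
        radii: np.ndarray,
        graph: nx.Graph,
        region_bounds: tuple[float, float],
        r_min: float,
    ):
        self.xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        self.radii = np.asarray(radii, dtype=float).ravel()
        self.graph = graph
        self.region_bounds = (float(region_bounds[0]), float(region_bounds[1]))
        self.r_min = float(r_min)
        if self.xy.shape[0] != self.radii.shape[0]:
            raise InvalidParameterError("xy and radii length mismatch")
        if graph.number_of_nodes() != self.xy.shape[0]:
            raise InvalidParameterError("graph node count must equal circle count")
        self._adj_cache: sp.csr_matrix | None = None

    @property
    def n_cells(self) -> int:
        return self.xy.shape[0]

    @property
    def circles(self) -> list[Circle]:
        return [Circle(x, y, r) for (x, y), r in zip(self.xy, self.radii)]

    def adjacency_matrix(self) -> sp.csr_matrix:
        """Sparse symmetric adjacency matrix A over circle indices."""
        if self._adj_cache is None:
            self._adj_cache = nx.to_scipy_sparse_array(
                self.graph, nodelist=range(self.n_cells), format="csr"
            ).astype(float)
        return self._adj_cache

    def degrees(self) -> np.ndarray:
        """Node degrees, i.e. diag(AA^T) for the 0/1 adjacency matrix."""
        a = self.adjacency_matrix()
        return np.asarray(a.sum(axis=1)).ravel()

    def __repr__(self) -> str:  # pragma: no cover
        w, h = self.region_bounds
        return (
            f"TissueScaffold(n_cells={self.n_cells}, "
            f"edges={self.graph.number_of_edges()}, bounds=({w:g}, {h:g}))"
        )


@dataclass
class SpatialParameters:
    """Cell-type proportions p and neighborhood probability matrix H.

    ``p[k]`` is the probability a cell is of type ``k``; ``H[i, j]`` is the
    probability that a neighbor of a type-``i`` cell is of type ``j``.  Each
    row of H sums to one.
    """

    p: np.ndarray
    H: np.ndarray
    type_names: list[str] | None = None

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float).ravel()
        self.H = np.asarray(self.H, dtype=float)
        k = self.p.shape[0]
        if k == 0:
            raise InvalidParameterError("need at least one cell type (K >= 1)")
        if self.H.shape != (k, k):
            raise InvalidParameterError(
                f"H must be {k}x{k} to match p, got {self.H.shape}"
            )
        if np.any(self.p < 0) or np.any(self.H < 0):
            raise InvalidParameterError("p and H must be non-negative")
        if abs(self.p.sum() - 1.0) > 1e-9:
            raise InvalidParameterError(f"p must sum to 1, got {self.p.sum()!r}")
        row_sums = self.H.sum(axis=1)
        if np.any(np.abs(row_sums - 1.0) > 1e-9):
            raise InvalidParameterError("every row of H must sum to 1")
        if self.type_names is not None and len(self.type_names) != k:
            raise InvalidParameterError("type_names length must equal K")

    @property
    def K(self) -> int:
        return self.p.shape[0]

    @staticmethod
    def uniform_neighbors(p: np.ndarray) -> "SpatialParameters":
        """Unstructured (null) parameters: every row of H equals p."""
        p = np.asarray(p, dtype=float)
        return SpatialParameters(p=p, H=np.tile(p, (p.shape[0], 1)))


@dataclass
class LabeledTissue:
    """An in silico tissue: a scaffold plus a per-node cell-type label.

    ``labels[v]`` is an integer type index in ``[0, K)``.  ``region`` is an
    optional per-node annotation of gross morphology (e.g. tile zone).
    """

    scaffold: TissueScaffold
    labels: np.ndarray
    K: int
    region: np.ndarray | None = None
    type_names: list[str] | None = field(default=None)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int).ravel()
        if self.labels.shape[0] != self.scaffold.n_cells:
            raise InvalidParameterError("labels length must equal cell count")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.K):
            raise InvalidParameterError("label indices must lie in [0, K)")
        if self.region is not None:
            self.region = np.asarray(self.region)
            if self.region.shape[0] != self.scaffold.n_cells:
                raise InvalidParameterError("region length must equal cell count")

    @property
    def n_cells(self) -> int:
        return self.scaffold.n_cells

    def type_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.K)

    def with_labels(self, labels: np.ndarray) -> "LabeledTissue":
        """Copy of this tissue with a different labeling on the same scaffold."""
        return LabeledTissue(
            scaffold=self.scaffold,
            labels=np.asarray(labels, dtype=int),
            K=self.K,
            region=self.region,
            type_names=self.type_names,
        )


def induced_tissue(tissue: LabeledTissue, nodes: np.ndarray) -> LabeledTissue:
    """Sub-tissue induced by ``nodes``: subgraph, labels and coordinates.

    Node ids are compacted to ``0..m-1`` in the order given.
    """
    nodes = np.asarray(nodes, dtype=int)
    sub = tissue.scaffold.graph.subgraph(nodes.tolist())
    mapping = {int(v): i for i, v in enumerate(nodes)}
    g = nx.relabel_nodes(nx.Graph(sub), mapping, copy=True)
    g.add_nodes_from(range(len(nodes)))  # keep isolated nodes
    xy = tissue.scaffold.xy[nodes]
    scaffold = TissueScaffold(
        xy=xy,
        radii=tissue.scaffold.radii[nodes],
        graph=g,
        region_bounds=tissue.scaffold.region_bounds,
        r_min=tissue.scaffold.r_min,
    )
    return LabeledTissue(
        scaffold=scaffold,
        labels=tissue.labels[nodes],
        K=tissue.K,
        region=None if tissue.region is None else tissue.region[nodes],
        type_names=tissue.type_names,
    )
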