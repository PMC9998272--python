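"""Cell-table and graph I/O, adjacency builders for real data, run configs.

The canonical cell-table dialect is comma-separated text with a header
``id,x,y,type[,region]``; tab-separated files are accepted by sniffing.
Scaffolds and labeled tissues round-trip through a JSON node-link format.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, fields

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .core import LabeledTissue, TissueScaffold
from .errors import InvalidParameterError, SchemaError

__all__ = [
    "CellTable",
    "RunConfig",
    "read_cell_table",
    "write_cell_table",
    "cell_table_from_tissue",
    "graph_from_points",
    "export_graphml",
    "tissue_from_cell_table",
    "save_scaffold",
    "load_scaffold",
    "save_tissue",
    "load_tissue",
]

REQUIRED_COLUMNS = ("x", "y", "type")


@dataclass
class CellTable:
    """Validated per-cell table: id, x, y, type and optional region."""

    data: pd.DataFrame
    units: str = "px"

    def __post_init__(self):
        df = self.data
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"cell table is missing required column {col!r}")
        if "id" not in df.columns:
            df = df.copy()
            df.insert(0, "id", np.arange(len(df)))
        if df["id"].duplicated().any():
            raise SchemaError("cell ids must be unique")
        for col in ("x", "y"):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = np.flatnonzero(coerced.isna() & df[col].notna()) if len(df) else []
            if df[col].isna().any():
                row = int(np.flatnonzero(df[col].isna())[0])
                raise SchemaError(f"missing {col} coordinate at data row {row + 2}")
            if len(bad):
                # +2: one for the header line, one for 1-based numbering
                raise SchemaError(
                    f"non-numeric {col} coordinate at data row {int(bad[0]) + 2}"
                )
            df = df.assign(**{col: coerced})
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def types(self) -> list:
        return sorted(self.data["type"].unique().tolist())


def read_cell_table(path, dialect: str | None = None) -> CellTable:
    """Read a delimited cell table; the delimiter is sniffed unless given.

    ``dialect`` may be ``"csv"`` or ``"tsv"``.
    """
    if dialect is None:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    elif dialect == "csv":
        sep = ","
    elif dialect == "tsv":
        sep = "\t"
    else:
        raise InvalidParameterError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep=sep, dtype={"type": str})
    return CellTable(data=df)


def write_cell_table(table: CellTable, path) -> None:
    table.data.to_csv(path, index=False)


def cell_table_from_tissue(tissue: LabeledTissue) -> CellTable:
    """Export a labeled tissue as a cell table."""
    if tissue.type_names is not None:
        types = [tissue.type_names[k] for k in tissue.labels]
    else:
        types = tissue.labels.astype(str)
    df = pd.DataFrame(
        {
            "id": np.arange(tissue.n_cells),
            "x": tissue.scaffold.xy[:, 0],
            "y": tissue.scaffold.xy[:, 1],
            "type": types,
        }
    )
    if tissue.region is not None:
        df["region"] = tissue.region
    return CellTable(data=df)


def graph_from_points(
    table: CellTable, method: str = "delaunay_pruned", cutoff: float = 30.0
) -> TissueScaffold:
    """Build an adjacency graph for measured cell positions.

    ``delaunay_pruned`` keeps Delaunay edges no longer than ``cutoff``;
    ``radius`` connects all pairs within ``cutoff``.  Degenerate geometry
    (collinear or too few points) falls back to the radius method with a
    warning.  The returned scaffold has zero-radius circles (real data
    carries no packing radii).
    """
    xy = table.data[["x", "y"]].to_numpy(dtype=float)
    n = xy.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))

    def radius_edges():
        from scipy.spatial import cKDTree

        tree = cKDTree(xy)
        return tree.query_pairs(cutoff)

    if method == "radius":
        pairs = radius_edges()
    elif method == "delaunay_pruned":
        try:
            from scipy.spatial import Delaunay, QhullError

            if n < 3:
                raise QhullError("fewer than 3 points")
            tri = Delaunay(xy)
            pairs = set()
            for simplex in tri.simplices:
                for i in range(3):
                    u, v = int(simplex[i]), int(simplex[(i + 1) % 3])
                    d = float(np.hypot(*(xy[u] - xy[v])))
                    if d <= cutoff:
                        pairs.add((min(u, v), max(u, v)))
        except Exception as exc:  # degenerate geometry
            warnings.warn(
                f"Delaunay triangulation failed ({exc}); "
                "falling back to the radius method",
                stacklevel=2,
            )
            pairs = radius_edges()
    else:
        raise InvalidParameterError(f"unknown method {method!r}")

    g.add_edges_from(pairs)
    bounds = (
        float(xy[:, 0].max()) if n else 0.0,
        float(xy[:, 1].max()) if n else 0.0,
    )
    return TissueScaffold(
        xy=xy, radii=np.zeros(n), graph=g, region_bounds=bounds, r_min=0.0
    )


def tissue_from_cell_table(
    table: CellTable, method: str = "delaunay_pruned", cutoff: float = 30.0
) -> LabeledTissue:
    """Cell table -> labeled tissue, with type labels indexed alphabetically."""
    scaffold = graph_from_points(table, method=method, cutoff=cutoff)
    names = table.types
    index = {t: i for i, t in enumerate(names)}
    labels = table.data["type"].map(index).to_numpy()
    region = (
        table.data["region"].to_numpy() if "region" in table.data.columns else None
    )
    return LabeledTissue(
        scaffold=scaffold,
        labels=labels,
        K=len(names),
        region=region,
        type_names=[str(t) for t in names],
    )


def save_scaffold(scaffold: TissueScaffold, path) -> None:
    """Serialize a scaffold as JSON node-link data (id, x, y, radius, edges)."""
    payload = {
        "region_bounds": list(scaffold.region_bounds),
        "r_min": scaffold.r_min,
        "graph": nx.node_link_data(scaffold.graph, edges="edges"),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_scaffold(path) -> TissueScaffold:
    with open(path) as fh:
        payload = json.load(fh)
    g = nx.node_link_graph(payload["graph"], edges="edges")
    n = g.number_of_nodes()
    xy = np.array([[g.nodes[i]["x"], g.nodes[i]["y"]] for i in range(n)])
    radii = np.array([g.nodes[i]["radius"] for i in range(n)])
    return TissueScaffold(
        xy=xy.reshape(n, 2),
        radii=radii,
        graph=g,
        region_bounds=tuple(payload["region_bounds"]),
        r_min=payload["r_min"],
    )


def export_graphml(scaffold: TissueScaffold, path) -> None:
    """Export the scaffold graph (with x, y, radius attributes) as GraphML."""
    nx.write_graphml(scaffold.graph, path)


def save_tissue(tissue: LabeledTissue, graph_path, table_path) -> None:
    """Serialize a labeled tissue: graph JSON plus a cell table."""
    save_scaffold(tissue.scaffold, graph_path)
    write_cell_table(cell_table_from_tissue(tissue), table_path)


def load_tissue(graph_path, table_path) -> LabeledTissue:
    scaffold = load_scaffold(graph_path)
    table = read_cell_table(table_path)
    names = table.types
    index = {t: i for i, t in enumerate(names)}
    labels = table.data["type"].map(index).to_numpy()
    region = (
        table.data["region"].to_numpy() if "region" in table.data.columns else None
    )
    return LabeledTissue(
        scaffold=scaffold,
        labels=labels,
        K=len(names),
        region=region,
        type_names=[str(t) for t in names],
    )


@dataclass
class RunConfig:
    """Every tunable default of the toolkit, round-trippable through YAML."""

    width: float = 500.0
    height: float = 500.0
    r_min: float = 2.9
    r_max: float = 6.0
    max_consecutive_failures: int = 500
    grid_size: float = 50.0
    shift: float = 25.0
    epsilon: int = 1
    correction_iters: int = 500
    correction_tol: float = 0.02
    l1: float = 1.0
    l2: float = 1.0
    learning_rate: float = 0.01
    iterations: int = 2000
    fov_fraction: float = 0.05
    n_fov: int = 50
    n_trials: int = 1000
    alpha: float = 0.01
    spot_spacing: float = 100.0
    spot_radius: float = 27.5
    spot_threshold: float = 0.10
    voronoi_max_cells: int = 20000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def child_seed(self, stage: str) -> int:
        """Per-stage child seed derived from the global seed.

        Stages are identified by name; the split is a SeedSequence spawn
        keyed on the stable hash of the stage name, so any stage's seed is
        reproducible independently of the others.
        """
        key = int.from_bytes(stage.encode(), "little") % (2**31)
        ss = np.random.SeedSequence([self.seed, key])
        return int(ss.generate_state(1)[0] % (2**31))
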