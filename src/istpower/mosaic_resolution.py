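"""Whole-slide mosaic ISTs and spatial-resolution degradation.

Large tissues with gross morphological regions are emulated by a tile map:
the annotated tissue is partitioned into a square grid, each tile takes the
modal ("dominant") region label of its cells, and spatial parameters are
estimated per region.  One shared blank scaffold sized to the mean cells
per tile is relabeled independently for every tile with that tile's region
parameters and the tiles are stitched into a composite coordinate frame
(tiles are graph-disjoint: cross-tile adjacencies are not modeled).

Resolution degradation bins single-cell data onto a triangular lattice of
"spots" (Visium-like): spot centers a fixed pitch apart, cells within a
capture radius assigned, all other cells discarded.  A spot whose member
composition exceeds a threshold for a type of interest is a "spot of
interest"; the FOV power pipeline then runs on spots of interest instead of
single cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .core import LabeledTissue, TissueScaffold, induced_tissue
from .errors import InvalidParameterError, UnattainableError
from .scaffold import scaffold_for_count

__all__ = [
    "TileMap",
    "SpotTissue",
    "build_tilemap",
    "generate_mosaic",
    "shuffle_tiles",
    "bin_to_spots",
    "spot_of_interest",
    "spot_level_power",
]


@dataclass
class TileMap:
    """Grid of tiles, each dominated by one morphological region."""

    shape: tuple[int, int]  # (rows, cols)
    zones: np.ndarray  # (rows, cols) array of region labels
    region_params: dict  # region label -> SpatialParameters
    mean_cells_per_tile: float
    grid_size: float

    def zone_counts(self) -> dict:
        vals, counts = np.unique(self.zones, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


@dataclass
class SpotTissue:
    """Visium-like binning of a tissue onto triangular-lattice spots."""

    centers: np.ndarray  # (n_spots, 2) spot centers
    spacing: float
    radius: float
    members: list = field(repr=False)  # per-spot arrays of cell ids
    type_counts: np.ndarray = field(repr=False)  # (n_spots, K)
    n_discarded: int = 0
    bounds: tuple[float, float] = (0.0, 0.0)
    K: int = 0

    @property
    def n_spots(self) -> int:
        return self.centers.shape[0]

    def spot_totals(self) -> np.ndarray:
        return self.type_counts.sum(axis=1)

    def spots_of_interest(self, type_index: int, threshold: float = 0.10) -> np.ndarray:
        """Boolean mask: spots whose composition strictly exceeds threshold."""
        totals = self.spot_totals()
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(totals > 0, self.type_counts[:, type_index] / totals, 0.0)
        return frac > threshold

    def to_table(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "spot": np.arange(self.n_spots),
                "x": self.centers[:, 0],
                "y": self.centers[:, 1],
            }
        )
        for k in range(self.type_counts.shape[1]):
            df[f"type_{k}"] = self.type_counts[:, k]
        return df


def build_tilemap(tissue: LabeledTissue, grid_size: float) -> TileMap:
    """Partition an annotated tissue into tiles with dominant-region labels.

    Each tile's zone is the modal region label of its member cells; empty
    tiles inherit the zone of the nearest (Chebyshev-distance) non-empty
    tile, ties resolved toward the lowest zone label.  Per-region spatial
    parameters are estimated from the subgraph induced by each region.
    """
    if tissue.region is None:
        raise InvalidParameterError("tissue has no region annotation")
    if grid_size <= 0:
        raise InvalidParameterError("grid_size must be positive")
    from .adjacency_stats import estimate_parameters

    width, height = tissue.scaffold.region_bounds
    cols = max(1, math.ceil(width / grid_size))
    rows = max(1, math.ceil(height / grid_size))
    xy = tissue.scaffold.xy
    col_idx = np.clip((xy[:, 0] // grid_size).astype(int), 0, cols - 1)
    row_idx = np.clip((xy[:, 1] // grid_size).astype(int), 0, rows - 1)

    region_labels = np.unique(tissue.region)
    zones = np.empty((rows, cols), dtype=object)
    for r in range(rows):
        for c in range(cols):
            members = np.flatnonzero((row_idx == r) & (col_idx == c))
            if members.size:
                vals, counts = np.unique(tissue.region[members], return_counts=True)
                # modal label; ties -> lowest label
                zones[r, c] = sorted(vals[counts == counts.max()].tolist())[0]
            else:
                zones[r, c] = None

    # empty tiles inherit the nearest non-empty tile's zone (Chebyshev)
    filled = [(r, c) for r in range(rows) for c in range(cols) if zones[r, c] is not None]
    if not filled:
        raise InvalidParameterError("tissue has no cells; cannot build a tile map")
    for r in range(rows):
        for c in range(cols):
            if zones[r, c] is None:
                dists = [max(abs(r - rr), abs(c - cc)) for rr, cc in filled]
                dmin = min(dists)
                cands = sorted(
                    zones[rr, cc]
                    for (rr, cc), d in zip(filled, dists)
                    if d == dmin
                )
                zones[r, c] = cands[0]

    params = {}
    for label in region_labels:
        nodes = np.flatnonzero(tissue.region == label)
        params[label] = estimate_parameters(induced_tissue(tissue, nodes))

    return TileMap(
        shape=(rows, cols),
        zones=zones,
        region_params=params,
        mean_cells_per_tile=tissue.n_cells / (rows * cols),
        grid_size=float(grid_size),
    )


def generate_mosaic(
    tilemap: TileMap,
    seed: int | None = None,
    scaffold: TissueScaffold | None = None,
    correction_iters: int = 500,
) -> LabeledTissue:
    """Stitch a whole-slide IST from a tile map.

    A single blank scaffold sized to the mean cells per tile is generated
    once and independently relabeled for each tile using that tile's region
    parameters (heuristic engine + swap correction), then translated into
    the composite frame.  Tiles are disjoint components of the composite
    graph.
    """
    from .labeling_heuristic import generate_ist

    rows, cols = tilemap.shape
    ss = np.random.SeedSequence(seed)
    scaffold_seed, *tile_seeds = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(rows * cols + 1)
    ]
    if scaffold is None:
        n_target = max(1, round(tilemap.mean_cells_per_tile))
        scaffold = scaffold_for_count(
            n_target, tilemap.grid_size, tilemap.grid_size, seed=scaffold_seed
        )

    # consistent type universe across regions
    any_params = next(iter(tilemap.region_params.values()))
    K = any_params.K

    xy_parts, radii_parts, label_parts, region_parts = [], [], [], []
    graphs = []
    for r in range(rows):
        for c in range(cols):
            zone = tilemap.zones[r, c]
            params = tilemap.region_params.get(zone)
            if params is None:
                raise InvalidParameterError(
                    f"no estimable parameters for region {zone!r}"
                )
            tile_seed = tile_seeds[r * cols + c]
            labeled = generate_ist(
                scaffold, params, correction_iters=correction_iters, seed=tile_seed
            )
            offset = np.array([c * tilemap.grid_size, r * tilemap.grid_size])
            xy_parts.append(scaffold.xy + offset)
            radii_parts.append(scaffold.radii)
            label_parts.append(labeled.labels)
            region_parts.append(np.repeat(zone, scaffold.n_cells))
            graphs.append(scaffold.graph)

    composite = nx.disjoint_union_all([nx.Graph(g) for g in graphs])
    xy = np.vstack(xy_parts)
    combined = TissueScaffold(
        xy=xy,
        radii=np.concatenate(radii_parts),
        graph=composite,
        region_bounds=(cols * tilemap.grid_size, rows * tilemap.grid_size),
        r_min=scaffold.r_min,
    )
    return LabeledTissue(
        scaffold=combined,
        labels=np.concatenate(label_parts),
        K=K,
        region=np.concatenate(region_parts),
        type_names=any_params.type_names,
    )


def shuffle_tiles(tilemap: TileMap, seed: int | None = None) -> TileMap:
    """Randomize tile positions while preserving per-zone tile counts."""
    rng = np.random.default_rng(seed)
    flat = tilemap.zones.ravel().copy()
    rng.shuffle(flat)
    return TileMap(
        shape=tilemap.shape,
        zones=flat.reshape(tilemap.shape),
        region_params=tilemap.region_params,
        mean_cells_per_tile=tilemap.mean_cells_per_tile,
        grid_size=tilemap.grid_size,
    )


def _triangular_lattice(bounds: tuple[float, float], spacing: float) -> np.ndarray:
    """Triangular lattice covering the bounding box (origin at the corner).

    Rows run along x; odd rows are offset by half the pitch; the row pitch
    is ``spacing * sqrt(3)/2``.  One extra row/column beyond each edge is
    included so boundary cells can still fall within a capture radius.
    """
    width, height = bounds
    dy = spacing * math.sqrt(3.0) / 2.0
    n_rows = int(math.ceil(height / dy)) + 2
    n_cols = int(math.ceil(width / spacing)) + 2
    pts = []
    for i in range(-1, n_rows):
        y = i * dy
        x0 = (spacing / 2.0) if (i % 2) else 0.0
        for j in range(-1, n_cols):
            pts.append((x0 + j * spacing, y))
    return np.asarray(pts)


def bin_to_spots(
    tissue: LabeledTissue, spacing: float = 100.0, radius: float = 27.5
) -> SpotTissue:
    """Bin cells to triangular-lattice spots; out-of-radius cells are discarded.

    ``radius`` must be below ``spacing / 2`` so every cell has at most one
    capturing spot.  Units follow the tissue coordinates (the canonical
    Visium-like geometry is a 100 um pitch with a 27.5 um capture radius).
    """
    if spacing <= 0:
        raise InvalidParameterError("spacing must be positive")
    if not radius < spacing / 2.0:
        raise InvalidParameterError(
            "radius must be < spacing/2 (otherwise spot assignment is ambiguous)"
        )
    from scipy.spatial import cKDTree

    centers = _triangular_lattice(tissue.scaffold.region_bounds, spacing)
    tree = cKDTree(centers)
    dist, idx = tree.query(tissue.scaffold.xy, k=1)
    assigned = dist <= radius
    members = [
        np.flatnonzero(assigned & (idx == s)) for s in range(centers.shape[0])
    ]
    type_counts = np.zeros((centers.shape[0], tissue.K), dtype=int)
    for s, mem in enumerate(members):
        if mem.size:
            type_counts[s] = np.bincount(tissue.labels[mem], minlength=tissue.K)
    return SpotTissue(
        centers=centers,
        spacing=float(spacing),
        radius=float(radius),
        members=members,
        type_counts=type_counts,
        n_discarded=int(np.sum(~assigned)),
        bounds=tissue.scaffold.region_bounds,
        K=tissue.K,
    )


def spot_of_interest(
    spot_tissue: SpotTissue, spot_index: int, type_index: int, threshold: float = 0.10
) -> bool:
    """True iff strictly more than ``threshold`` of the spot's cells are the type.

    Empty spots are never of interest.
    """
    total = int(spot_tissue.type_counts[spot_index].sum())
    if total == 0:
        return False
    return bool(spot_tissue.type_counts[spot_index, type_index] / total > threshold)


def spot_level_power(
    spot_tissue: SpotTissue,
    type_index: int,
    fraction: float,
    target: float,
    seed: int | None = None,
    n_fov: int = 50,
    threshold: float = 0.10,
) -> int:
    """FOVs required to observe at least one spot of interest.

    Runs the gamma-Poisson FOV pipeline with spots of interest standing in
    for cells of interest: random FOVs are drawn over the tissue bounds,
    qualifying spot centers are counted per FOV, the count distribution is
    fitted by the zero term method and the requirement for the target
    detection probability returned.
    """
    from .sampling_models import _fov_side, fit_nbd_ztm, fovs_required

    mask = spot_tissue.spots_of_interest(type_index, threshold)
    if not mask.any():
        raise UnattainableError("no spot of interest anywhere in the tissue")
    pts = spot_tissue.centers[mask]
    rng = np.random.default_rng(seed)
    side = _fov_side(spot_tissue.bounds, fraction)
    w, h = spot_tissue.bounds
    counts = np.empty(n_fov, dtype=int)
    for t in range(n_fov):
        ox = rng.uniform(0.0, w - side) if w > side else 0.0
        oy = rng.uniform(0.0, h - side) if h > side else 0.0
        counts[t] = int(
            np.sum(
                (pts[:, 0] >= ox)
                & (pts[:, 0] < ox + side)
                & (pts[:, 1] >= oy)
                & (pts[:, 1] < oy + side)
            )
        )
    if np.all(counts > 0):
        # the zero-anchored estimate of a blank FOV is 0: one FOV suffices
        return 1
    model = fit_nbd_ztm(counts)
    return fovs_required(model, target)
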