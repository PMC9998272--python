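"""Tissue rendering: Voronoi tessellation for small tissues, scatter fallback.

Each cell's Voronoi region is filled with its type color, which gives a
tissue-section-like image.  Voronoi construction is slow for very large
tissues, so above a configurable cell-count threshold a colored scatter
plot is drawn instead.
"""

from __future__ import annotations

import logging

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .core import LabeledTissue
from .errors import InvalidParameterError

logger = logging.getLogger(__name__)

__all__ = ["render_voronoi", "render_scatter"]

VORONOI_MAX_CELLS = 20000


def _colors(K: int):
    cmap = plt.get_cmap("tab20" if K > 10 else "tab10")
    return [cmap(k % cmap.N) for k in range(K)]


def render_scatter(tissue: LabeledTissue, path, dpi: int = 150) -> None:
    """Scatter rendering colored by cell type."""
    colors = _colors(tissue.K)
    fig, ax = plt.subplots(figsize=(6, 6))
    for k in range(tissue.K):
        mask = tissue.labels == k
        name = tissue.type_names[k] if tissue.type_names else str(k)
        ax.scatter(
            tissue.scaffold.xy[mask, 0],
            tissue.scaffold.xy[mask, 1],
            s=4,
            color=colors[k],
            label=name,
        )
    ax.set_aspect("equal")
    ax.legend(markerscale=3, fontsize=7)
    fig.savefig(path, dpi=dpi)
    plt.close(fig)


def render_voronoi(
    tissue: LabeledTissue,
    path,
    max_voronoi: int = VORONOI_MAX_CELLS,
    dpi: int = 150,
) -> None:
    """Render a tissue as a type-colored Voronoi diagram.

    Falls back to scatter rendering (logged) above ``max_voronoi`` cells,
    where the tessellation becomes slow.
    """
    if tissue.n_cells < 4:
        raise InvalidParameterError("Voronoi rendering needs at least 4 cells")
    if tissue.n_cells > max_voronoi:
        logger.info(
            "tissue has %d cells (> %d); using scatter rendering",
            tissue.n_cells,
            max_voronoi,
        )
        render_scatter(tissue, path, dpi=dpi)
        return

    from scipy.spatial import Voronoi

    vor = Voronoi(tissue.scaffold.xy)
    colors = _colors(tissue.K)
    w, h = tissue.scaffold.region_bounds
    fig, ax = plt.subplots(figsize=(6, 6))
    for point_idx, region_idx in enumerate(vor.point_region):
        region = vor.regions[region_idx]
        if not region or -1 in region:
            continue
        polygon = vor.vertices[region]
        ax.fill(*zip(*polygon), color=colors[tissue.labels[point_idx]], lw=0.1)
    ax.set_xlim(0, w)
    ax.set_ylim(0, h)
    ax.set_aspect("equal")
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
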