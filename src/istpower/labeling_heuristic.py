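"""Heuristic cell-type assignment on a tissue scaffold.

The scaffold region is partitioned into a square grid.  Within each grid
partition a random start node is drawn, its type is sampled from the
proportion vector ``p``, and the nodes within geodesic distance ``epsilon``
of it are labeled by sampling the corresponding row of the neighborhood
matrix ``H``.  The grid is then shifted by half a partition and the process
repeated on still-unlabeled nodes; any stragglers are labeled the same way.

A swap-based correction pass then compares the observed neighborhood matrix
to the target and exchanges labels between node pairs whenever the exchange
reduces the L1 deviation, which monotonically improves the fit.
"""

from __future__ import annotations

import numpy as np

from ._graphops import observed_H
from .core import LabeledTissue, SpatialParameters, TissueScaffold
from .errors import InvalidParameterError

__all__ = ["heuristic_assign", "swap_correction", "generate_ist"]


def _epsilon_ball(graph, start: int, epsilon: int) -> list[int]:
    """Nodes within geodesic distance epsilon of start (excluding start)."""
    if epsilon == 1:
        return list(graph.neighbors(start))
    seen = {start: 0}
    frontier = [start]
    out = []
    for d in range(1, epsilon + 1):
        nxt = []
        for v in frontier:
            for u in graph.neighbors(v):
                if u not in seen:
                    seen[u] = d
                    nxt.append(u)
                    out.append(u)
        frontier = nxt
    return out


def heuristic_assign(
    scaffold: TissueScaffold,
    params: SpatialParameters,
    grid_size: float = 50.0,
    shift: float = 25.0,
    epsilon: int = 1,
    seed: int | None = None,
) -> LabeledTissue:
    """Label a scaffold by grid-partitioned multinomial neighborhood sampling.

    Nodes labeled in an earlier pass are never relabeled.  Deterministic for
    a fixed seed.
    """
    if scaffold.n_cells == 0:
        raise InvalidParameterError("scaffold must contain at least one cell")
    if grid_size <= 0:
        raise InvalidParameterError("grid_size must be positive")
    rng = np.random.default_rng(seed)
    n = scaffold.n_cells
    K = params.K
    labels = np.full(n, -1, dtype=int)
    graph = scaffold.graph
    xy = scaffold.xy

    def one_pass(offset: float) -> None:
        cols = np.floor((xy[:, 0] - offset) / grid_size).astype(int)
        rows = np.floor((xy[:, 1] - offset) / grid_size).astype(int)
        partitions: dict[tuple[int, int], list[int]] = {}
        for v in range(n):
            partitions.setdefault((rows[v], cols[v]), []).append(v)
        for key in sorted(partitions):
            members = partitions[key]
            unlabeled = [v for v in members if labels[v] < 0]
            if not unlabeled:
                continue
            start = unlabeled[rng.integers(len(unlabeled))]
            k = int(rng.choice(K, p=params.p))
            labels[start] = k
            ball = [u for u in _epsilon_ball(graph, start, epsilon) if labels[u] < 0]
            if ball:
                labels[ball] = rng.choice(K, size=len(ball), p=params.H[k])

    one_pass(0.0)
    one_pass(float(shift))

    # stragglers: same process, seeded from random remaining nodes
    remaining = np.flatnonzero(labels < 0)
    while remaining.size:
        start = int(remaining[rng.integers(remaining.size)])
        k = int(rng.choice(K, p=params.p))
        labels[start] = k
        ball = [u for u in _epsilon_ball(graph, start, epsilon) if labels[u] < 0]
        if ball:
            labels[ball] = rng.choice(K, size=len(ball), p=params.H[k])
        remaining = np.flatnonzero(labels < 0)

    return LabeledTissue(scaffold=scaffold, labels=labels, K=K,
                         type_names=params.type_names)


def swap_correction(
    tissue: LabeledTissue,
    params: SpatialParameters,
    max_iters: int = 500,
    tol: float = 0.02,
    seed: int | None = None,
) -> LabeledTissue:
    """Improve the fit of the observed neighborhood matrix by label swaps.

    Per iteration a random pair of differently-labeled nodes is proposed for
    a label exchange; the swap is accepted only if it strictly decreases
    ``||H_obs - H||_1`` (summed over defined entries), so the deviation is
    non-increasing.  Stops once every defined entry of the deviation is
    within ``tol``, or after ``max_iters`` iterations.  Swaps preserve the
    graph and the label multiset exactly.
    """
    if max_iters < 0:
        raise InvalidParameterError("max_iters must be >= 0")
    rng = np.random.default_rng(seed)
    A = tissue.scaffold.adjacency_matrix()
    K = tissue.K
    labels = tissue.labels.copy()
    target = params.H

    def deviation(lab):
        h = observed_H(A, lab, K)
        d = np.abs(h - target)
        return np.nansum(d), np.nanmax(d) if np.any(np.isfinite(d)) else 0.0

    cur_l1, cur_max = deviation(labels)
    n = labels.shape[0]
    for _ in range(max_iters):
        if cur_max <= tol:
            break
        u = int(rng.integers(n))
        w = int(rng.integers(n))
        if labels[u] == labels[w]:
            continue
        labels[u], labels[w] = labels[w], labels[u]
        new_l1, new_max = deviation(labels)
        if new_l1 < cur_l1:
            cur_l1, cur_max = new_l1, new_max
        else:
            labels[u], labels[w] = labels[w], labels[u]

    return tissue.with_labels(labels)


def generate_ist(
    scaffold: TissueScaffold,
    params: SpatialParameters,
    grid_size: float = 50.0,
    shift: float = 25.0,
    epsilon: int = 1,
    correction_iters: int = 500,
    tol: float = 0.02,
    seed: int | None = None,
) -> LabeledTissue:
    """Heuristic assignment followed by swap correction (the full IST recipe)."""
    ss = np.random.SeedSequence(seed)
    s1, s2 = ss.spawn(2)
    tissue = heuristic_assign(
        scaffold, params, grid_size=grid_size, shift=shift, epsilon=epsilon,
        seed=s1.generate_state(1)[0],
    )
    if correction_iters > 0:
        tissue = swap_correction(
            tissue, params, max_iters=correction_iters, tol=tol,
            seed=s2.generate_state(1)[0],
        )
    return tissue
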