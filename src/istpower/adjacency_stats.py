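"""Adjacency statistics: parameter estimation, permutation testing, the
adjacency enrichment statistic (AES), clustering of significance profiles,
and the adjacency-reduction tissue edit.

The permutation test shuffles the label vector while keeping the graph
fixed, recomputes the observed neighborhood matrix at each shuffle, and
scores each type pair one-sidedly:

    P = (n_trials - #{shuffles more extreme} + 1) / (n_trials + 1)

with strict inequalities, so ties favor the null and the smallest
attainable p-value is 1 / (n_trials + 1).

The AES for a type pair (A, B) compares the observed number of A-B edges to
the proportion-based expectation:

    Sigma = 2 f_A f_B |E| ,      AES = N_AB / Sigma - 1 ,

computed for all pairs at once via C = B^T A B (off-diagonal entries count
cross-type edges; the diagonal is halved).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from ._graphops import observed_H, pair_edge_counts
from .core import LabeledTissue, SpatialParameters, induced_tissue
from .errors import (
    DegenerateComparisonError,
    InvalidParameterError,
    UnattainableError,
)
from .sampling_models import draw_fovs

__all__ = [
    "PermutationResult",
    "AESResult",
    "AESMatrix",
    "AESDistribution",
    "estimate_parameters",
    "permutation_test",
    "aes_matrix",
    "aes_distribution",
    "aes_z_test",
    "welch_z_test",
    "adjacency_clustering",
    "reduce_adjacency",
]


@dataclass
class PermutationResult:
    """One-sided permutation p-values for every type pair.

    ``p_enrich[i, j]`` tests whether type-j neighbors of type-i cells are
    more frequent than under random labeling; ``p_avoid`` tests the opposite
    direction.
    """

    n_trials: int
    p_enrich: np.ndarray
    p_avoid: np.ndarray
    observed_H: np.ndarray


@dataclass(frozen=True)
class AESResult:
    """AES for one type pair: observed vs expected edge count."""

    pair: tuple[int, int]
    n_edges: float
    expected: float
    aes: float


@dataclass
class AESMatrix:
    """AES for all type pairs of a tissue."""

    n_edges: np.ndarray  # K x K observed pair edge counts
    expected: np.ndarray  # K x K expectation Sigma = 2 f_A f_B |E|
    aes: np.ndarray  # K x K; NaN marks undefined pairs (f_A f_B = 0)

    def pair(self, a: int, b: int) -> AESResult:
        return AESResult(
            pair=(a, b),
            n_edges=float(self.n_edges[a, b]),
            expected=float(self.expected[a, b]),
            aes=float(self.aes[a, b]),
        )


@dataclass
class AESDistribution:
    """Per-FOV AES samples with a Gaussian maximum-likelihood fit."""

    samples: np.ndarray
    mean: float
    sd: float  # MLE (1/n) standard deviation
    n: int
    n_excluded: int = 0
    pair: tuple[int, int] | None = None


def estimate_parameters(tissue: LabeledTissue) -> SpatialParameters:
    """Estimate (p, H) from a labeled tissue.

    ``p`` is the label frequency vector; ``H`` the observed neighborhood
    matrix (per-node neighbor-type fractions averaged within type).
    """
    labels = tissue.labels
    if np.any(labels < 0):
        raise InvalidParameterError("tissue contains unlabeled nodes")
    counts = tissue.type_counts().astype(float)
    p = counts / counts.sum()
    H = observed_H(tissue.scaffold.adjacency_matrix(), labels, tissue.K)
    return SpatialParameters(p=p, H=_renormalize_rows(H), type_names=tissue.type_names)


def _renormalize_rows(H: np.ndarray) -> np.ndarray:
    """Normalize defined rows of an observed H so each sums to one.

    Rows can sum to slightly less than one when some nodes of the type are
    isolated (their neighbor row is all zero); absent types give NaN rows,
    which are replaced by a uniform row so the result is a valid stochastic
    matrix.
    """
    H = H.copy()
    K = H.shape[0]
    for i in range(K):
        row = H[i]
        if np.any(~np.isfinite(row)) or row.sum() <= 0:
            H[i] = 1.0 / K
        else:
            H[i] = row / row.sum()
    return H


def permutation_test(
    tissue: LabeledTissue, n_trials: int = 1000, seed: int | None = None
) -> PermutationResult:
    """Label-shuffling permutation test of neighborhood enrichment/avoidance.

    Every shuffle permutes the label vector (preserving the label multiset)
    on the fixed graph.  Entries of H undefined in a given shuffle or in the
    observed tissue (absent type) are skipped for that comparison.
    """
    if n_trials < 1:
        raise InvalidParameterError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    A = tissue.scaffold.adjacency_matrix()
    K = tissue.K
    labels = tissue.labels
    H_obs = observed_H(A, labels, K)

    more = np.zeros((K, K))  # shuffled H > observed (strict)
    less = np.zeros((K, K))
    for _ in range(n_trials):
        perm = rng.permutation(labels)
        H_perm = observed_H(A, perm, K)
        with np.errstate(invalid="ignore"):
            more += (H_perm > H_obs).astype(float)
            less += (H_perm < H_obs).astype(float)

    p_enrich = (n_trials - less + 1.0) / (n_trials + 1.0)
    p_avoid = (n_trials - more + 1.0) / (n_trials + 1.0)
    return PermutationResult(
        n_trials=n_trials, p_enrich=p_enrich, p_avoid=p_avoid, observed_H=H_obs
    )


def aes_matrix(tissue: LabeledTissue) -> AESMatrix:
    """AES for all type pairs via the one-shot matrix computation."""
    A = tissue.scaffold.adjacency_matrix()
    n_edges_total = tissue.scaffold.graph.number_of_edges()
    if n_edges_total == 0:
        raise InvalidParameterError("tissue graph has no edges; AES undefined")
    counts = pair_edge_counts(A, tissue.labels, tissue.K)
    f = tissue.type_counts() / tissue.n_cells
    sigma = 2.0 * np.outer(f, f) * n_edges_total
    with np.errstate(divide="ignore", invalid="ignore"):
        aes = np.where(sigma > 0, counts / sigma - 1.0, np.nan)
    return AESMatrix(n_edges=counts, expected=sigma, aes=aes)


def aes_distribution(
    tissue: LabeledTissue,
    pair: tuple[int, int],
    fraction: float,
    n_fov: int = 100,
    seed: int | None = None,
) -> AESDistribution:
    """Distribution of the AES for one pair over random FOVs.

    The AES is evaluated on each FOV-induced subgraph (edges with both
    endpoints inside the FOV).  FOVs in which either type is absent or the
    subgraph has no edges leave the statistic undefined and are excluded;
    the exclusion count is reported.  The Gaussian fit is by maximum
    likelihood (sample mean; variance with 1/n).
    """
    a, b = pair
    if not (np.any(tissue.labels == a) and np.any(tissue.labels == b)):
        raise InvalidParameterError(f"pair {pair} not defined in this tissue")
    fovs = draw_fovs(tissue, fraction, n_fov, seed=seed)
    samples = []
    excluded = 0
    for fov in fovs:
        if fov.n_cells == 0:
            excluded += 1
            continue
        sub = induced_tissue(tissue, fov.members)
        if sub.scaffold.graph.number_of_edges() == 0:
            excluded += 1
            continue
        counts = sub.type_counts()
        if counts[a] == 0 or counts[b] == 0:
            excluded += 1
            continue
        mat = aes_matrix(sub)
        samples.append(mat.aes[a, b])
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise UnattainableError(
            "every FOV left the AES undefined; increase the FOV size or count"
        )
    return AESDistribution(
        samples=samples,
        mean=float(samples.mean()),
        sd=float(samples.std(ddof=0)),
        n=int(samples.size),
        n_excluded=excluded,
        pair=(a, b),
    )


def aes_z_test(d1: AESDistribution, d2: AESDistribution) -> tuple[float, float]:
    """Test of difference between two AES distributions:

        z = (mean1 - mean2) / sqrt(sd1 / sqrt(n1) + sd2 / sqrt(n2))

    with the one-sided p-value from the standard Gaussian survival
    function.  (For the conventional two-sample statistic see
    :func:`welch_z_test`.)
    """
    if d1.n < 2 or d2.n < 2:
        raise InvalidParameterError("both distributions need n >= 2")
    denom = _sqrt(d1.sd / _sqrt(d1.n) + d2.sd / _sqrt(d2.n))
    if denom == 0.0:
        raise DegenerateComparisonError("zero spread in both AES distributions")
    z = (d1.mean - d2.mean) / denom
    return float(z), float(stats.norm.sf(z))


def welch_z_test(d1: AESDistribution, d2: AESDistribution) -> tuple[float, float]:
    """Standard two-sample z statistic (variances over n under the root)."""
    if d1.n < 2 or d2.n < 2:
        raise InvalidParameterError("both distributions need n >= 2")
    denom = _sqrt(d1.sd**2 / d1.n + d2.sd**2 / d2.n)
    if denom == 0.0:
        raise DegenerateComparisonError("zero spread in both AES distributions")
    z = (d1.mean - d2.mean) / denom
    return float(z), float(stats.norm.sf(z))


def _sqrt(x: float) -> float:
    if x < 0:
        raise DegenerateComparisonError(f"negative value under square root: {x}")
    return float(np.sqrt(x))


def adjacency_clustering(
    pvalue_profiles, n_clusters: int | None = None
) -> tuple[np.ndarray, np.ndarray | None]:
    """UPGMA (average-linkage) clustering of per-tissue p-value profiles.

    Profiles are flattened p-value vectors of equal length, one per tissue.
    Returns the scipy linkage matrix and, when ``n_clusters`` is given, flat
    cluster labels.  Deterministic.
    """
    try:
        profiles = np.asarray(pvalue_profiles, dtype=float)
    except ValueError as exc:
        raise InvalidParameterError(f"profiles must be rectangular: {exc}") from exc
    if profiles.ndim != 2 or profiles.shape[0] < 2:
        raise InvalidParameterError(
            "need >= 2 equal-length profiles (a 2-D array of p-values)"
        )
    Z = linkage(profiles, method="average", metric="euclidean")
    labels = None
    if n_clusters is not None:
        labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    return Z, labels


def _pair_edge_count(tissue: LabeledTissue, labels: np.ndarray, a: int, b: int) -> int:
    A = tissue.scaffold.adjacency_matrix()
    mask_a = labels == a
    mask_b = labels == b
    if a == b:
        sub = A[mask_a][:, mask_a]
        return int(sub.sum() // 2)
    return int(A[mask_a][:, mask_b].sum())


def reduce_adjacency(
    tissue: LabeledTissue,
    pair: tuple[int, int],
    reduction: float,
    seed: int | None = None,
    tol: float = 0.02,
    max_steps: int | None = None,
) -> LabeledTissue:
    """Reduce the number of A-B adjacencies by label swaps.

    Labels are exchanged between an endpoint of an A-B edge and another
    node carrying a different label, which preserves the type histogram and
    the graph exactly.  Swaps are accepted greedily while they move the A-B
    edge count toward ``(1 - reduction)`` of its original value; the edit
    stops within ``tol * original`` edges of the target.  If no sequence of
    swaps reaches the tolerance an error reports the best reduction found.
    """
    a, b = pair
    if not 0.0 < reduction < 1.0:
        raise InvalidParameterError("reduction must lie strictly in (0, 1)")
    labels = tissue.labels.copy()
    orig = _pair_edge_count(tissue, labels, a, b)
    if orig == 0:
        raise InvalidParameterError(f"pair {pair} has no adjacencies to reduce")
    target = (1.0 - reduction) * orig
    tol_edges = max(tol * orig, 0.5)
    rng = np.random.default_rng(seed)
    graph = tissue.scaffold.graph
    n = labels.shape[0]
    if max_steps is None:
        max_steps = 50 * orig

    def local_pair_edges(lab, nodes) -> int:
        """A-B edges incident to the given nodes (each edge once)."""
        seen = set()
        total = 0
        for u in nodes:
            for v in graph.neighbors(u):
                e = (u, v) if u < v else (v, u)
                if e in seen:
                    continue
                seen.add(e)
                lu, lv = lab[e[0]], lab[e[1]]
                if (lu == a and lv == b) or (lu == b and lv == a):
                    total += 1
        return total

    current = orig
    best = current
    best_labels = labels.copy()
    steps = 0
    stall = 0
    # keep swapping until within half an edge of the target (or stalled);
    # tol_edges only decides whether the final state is acceptable
    while abs(current - target) > 0.5 and steps < max_steps and stall < 2000:
        steps += 1
        # endpoint of a current A-B edge
        u = int(rng.integers(n))
        if labels[u] != a and labels[u] != b:
            stall += 1
            continue
        w = int(rng.integers(n))
        if labels[w] == labels[u]:
            stall += 1
            continue
        nodes = (u, w)
        before = local_pair_edges(labels, nodes)
        labels[u], labels[w] = labels[w], labels[u]
        after = local_pair_edges(labels, nodes)
        new = current - before + after
        if abs(new - target) < abs(current - target):
            current = new
            stall = 0
            if abs(new - target) < abs(best - target):
                best = new
                best_labels = labels.copy()
        else:
            labels[u], labels[w] = labels[w], labels[u]
            stall += 1

    if abs(best - target) > tol_edges:
        raise UnattainableError(
            f"requested reduction {reduction:.0%} not reached: best achieved "
            f"{1 - best / orig:.1%} ({best}/{orig} edges remain)"
        )
    return tissue.with_labels(best_labels)
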