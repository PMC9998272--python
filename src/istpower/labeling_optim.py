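"""Optimization-based cell-type assignment.

Instead of sampling labels, a continuous assignment matrix ``B`` (n x K,
rows ~ per-cell type probabilities) is optimized so that the induced
neighborhood probability matrix

    H(B) = diag(B^T B)^-1  B^T  diag(A A^T)^-1  A B

matches a target ``H*``.  The relaxed objective is

    argmin_B  -Trace(H(B)^T H*)  +  l1 ||B 1_K - 1_n||_2
                                 +  l2 ||colsum(B)/n - p||_2

(the trace term rewards alignment with the target neighborhood structure,
the l1 term pushes rows toward the probability simplex, and the l2 term
matches the marginal cell-type proportions; per-type weights ``w_k`` turn
the l2 term into a weighted sum of squared proportion residuals so rare
types can be up-weighted).  Minimization is plain gradient descent with an
analytic gradient and projection of ``B`` onto the box [0, 1].

The discrete labeling is obtained afterwards by rounding each row (argmax,
ties to the lowest type index) or by sampling each row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import LabeledTissue, SpatialParameters, TissueScaffold
from .errors import (
    DegenerateTypeError,
    InvalidParameterError,
    OptimizationFailureError,
)

__all__ = [
    "AssignmentMatrix",
    "OptimizerConfig",
    "neighborhood_matrix",
    "assignment_objective",
    "optimize_assignment",
    "discretize_assignment",
]

_EPS = 1e-12


@dataclass
class AssignmentMatrix:
    """n x K type-assignment matrix; probabilistic or one-hot."""

    B: np.ndarray
    mode: str = "probabilistic"
    loss_trace: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.B = np.asarray(self.B, dtype=float)
        if self.B.ndim != 2:
            raise InvalidParameterError("B must be a 2-D matrix")
        if self.mode not in ("probabilistic", "one-hot"):
            raise InvalidParameterError(f"unknown mode {self.mode!r}")
        rows = self.B.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-6):
            raise InvalidParameterError("every row of B must sum to 1")
        if self.mode == "one-hot":
            if not np.all((self.B == 0) | (self.B == 1)):
                raise InvalidParameterError("one-hot B must contain only 0/1")
        elif np.any(self.B < -1e-12) or np.any(self.B > 1 + 1e-12):
            raise InvalidParameterError("probabilistic B entries must lie in [0,1]")

    @property
    def n(self) -> int:
        return self.B.shape[0]

    @property
    def K(self) -> int:
        return self.B.shape[1]

    def labels(self) -> np.ndarray:
        if self.mode != "one-hot":
            raise InvalidParameterError("labels() requires a one-hot matrix")
        return np.argmax(self.B, axis=1)


@dataclass
class OptimizerConfig:
    """Tunables for :func:`optimize_assignment`."""

    l1: float = 1.0
    l2: float = 1.0
    w: np.ndarray | None = None
    learning_rate: float = 0.01
    iterations: int = 2000
    seed: int | None = None
    extreme_values_only: bool = False

    def __post_init__(self):
        if self.l1 <= 0 or self.l2 <= 0:
            raise InvalidParameterError("l1 and l2 must be positive")
        if self.learning_rate <= 0:
            raise InvalidParameterError("learning_rate must be positive")
        if self.iterations < 1:
            raise InvalidParameterError("iterations must be >= 1")
        if self.w is not None:
            self.w = np.asarray(self.w, dtype=float).ravel()
            if np.any(self.w < 0):
                raise InvalidParameterError("weights w must be non-negative")


def neighborhood_matrix(
    B: AssignmentMatrix | np.ndarray, scaffold: TissueScaffold
) -> np.ndarray:
    """Evaluate H(B) on a scaffold.

    For one-hot ``B`` on a graph without isolated nodes every row sums to 1.
    Zero node degrees are replaced by 1 (such nodes contribute a zero
    neighbor row); a type with zero total assignment mass has an undefined
    row and raises :class:`DegenerateTypeError`.
    """
    mat = B.B if isinstance(B, AssignmentMatrix) else np.asarray(B, dtype=float)
    if mat.shape[0] != scaffold.n_cells:
        raise InvalidParameterError("B row count must equal scaffold cell count")
    A = scaffold.adjacency_matrix()
    deg = scaffold.degrees()
    safe_deg = np.where(deg > 0, deg, 1.0)
    s = np.einsum("ik,ik->k", mat, mat)  # diag(B^T B)
    dead = np.flatnonzero(s <= _EPS)
    if dead.size:
        raise DegenerateTypeError(
            f"type(s) {dead.tolist()} have zero assigned mass; H row undefined"
        )
    M = (A @ mat) / safe_deg[:, None]
    return (mat.T @ M) / s[:, None]


def _objective_and_grad(
    Bm: np.ndarray,
    A,
    deg: np.ndarray,
    target: np.ndarray,
    p: np.ndarray,
    cfg: OptimizerConfig,
    p_mask: np.ndarray,
):
    """Loss and analytic gradient of the relaxed assignment objective."""
    n, K = Bm.shape
    safe_deg = np.where(deg > 0, deg, 1.0)
    s_raw = np.einsum("ik,ik->k", Bm, Bm)
    # floor the per-type mass at one cell: without it the trace term is
    # unbounded below (a vanishing column makes H(B) blow up) and gradient
    # descent chases that degenerate direction instead of the labeling
    floored = s_raw < 1.0
    s = np.where(floored, 1.0, s_raw)
    MB = (A @ Bm) / safe_deg[:, None]  # diag(AA^T)^-1 A B
    BtMB = Bm.T @ MB
    H = BtMB / s[:, None]

    loss_trace = -np.sum(H * target)

    # gradient of the trace term:
    #   -M B T^T S^-1 - M^T B S^-1 T + 2 B diag(c),   M = diag(AA^T)^-1 A
    c = np.einsum("kj,kj->k", H, target) / s  # diag(S^-1 B^T M B T^T S^-1)
    c = np.where(floored, 0.0, c)  # ds/dB = 0 where the floor is active
    MtB = A @ (Bm / safe_deg[:, None])  # M^T B, using A = A^T
    grad = -(MB @ target.T) / s[None, :] - MtB @ (target / s[:, None])
    grad += 2.0 * Bm * c[None, :]

    # row-sum penalty l1 ||B 1 - 1||_2
    g_row = Bm.sum(axis=1) - 1.0
    row_norm = np.linalg.norm(g_row)
    loss_row = cfg.l1 * row_norm
    if row_norm > _EPS:
        grad += cfg.l1 * (g_row / row_norm)[:, None]

    # proportion penalty on column sums (per-cell proportions)
    r = Bm.sum(axis=0) / n - p
    r = np.where(p_mask, r, 0.0)
    if cfg.w is not None:
        loss_col = cfg.l2 * float(np.sum(cfg.w * r * r))
        grad += (2.0 * cfg.l2 / n) * (cfg.w * r)[None, :]
    else:
        col_norm = np.linalg.norm(r)
        loss_col = cfg.l2 * col_norm
        if col_norm > _EPS:
            grad += (cfg.l2 / n) * (r / col_norm)[None, :]

    return loss_trace + loss_row + loss_col, grad


def assignment_objective(
    B: AssignmentMatrix | np.ndarray,
    scaffold: TissueScaffold,
    params: SpatialParameters,
    config: OptimizerConfig | None = None,
) -> float:
    """Evaluate the relaxed objective for any assignment matrix."""
    cfg = config or OptimizerConfig()
    mat = B.B if isinstance(B, AssignmentMatrix) else np.asarray(B, dtype=float)
    K = params.K
    if cfg.extreme_values_only:
        sd = np.std(params.p, ddof=1) if K > 1 else 0.0
        p_mask = np.abs(params.p - params.p.mean()) > sd
        if not p_mask.any():
            p_mask = np.ones(K, dtype=bool)
    else:
        p_mask = np.ones(K, dtype=bool)
    loss, _ = _objective_and_grad(
        mat, scaffold.adjacency_matrix(), scaffold.degrees(),
        params.H, params.p, cfg, p_mask,
    )
    return float(loss)


def optimize_assignment(
    scaffold: TissueScaffold,
    params: SpatialParameters,
    config: OptimizerConfig | None = None,
) -> AssignmentMatrix:
    """Gradient-descent minimization of the relaxed assignment objective.

    Returns the best iterate (lowest recorded loss) as a probabilistic
    assignment matrix with the loss trace attached.  Deterministic for a
    fixed ``config.seed``.
    """
    cfg = config or OptimizerConfig()
    n, K = scaffold.n_cells, params.K
    if cfg.w is not None and cfg.w.shape[0] != K:
        raise InvalidParameterError("w must have one weight per type")
    rng = np.random.default_rng(cfg.seed)

    if K == 1:
        B = np.ones((n, 1))
        return AssignmentMatrix(B=B, mode="probabilistic",
                                loss_trace=np.zeros(1))

    if cfg.extreme_values_only:
        sd = np.std(params.p, ddof=1) if K > 1 else 0.0
        p_mask = np.abs(params.p - params.p.mean()) > sd
        if not p_mask.any():
            p_mask = np.ones(K, dtype=bool)
    else:
        p_mask = np.ones(K, dtype=bool)

    A = scaffold.adjacency_matrix()
    deg = scaffold.degrees()

    # strictly interior start: row-softmax of iid standard Gaussians
    Z = rng.standard_normal((n, K))
    B = np.exp(Z - Z.max(axis=1, keepdims=True))
    B /= B.sum(axis=1, keepdims=True)

    best_B = B.copy()
    best_loss = np.inf
    trace = np.empty(cfg.iterations)
    for it in range(cfg.iterations):
        loss, grad = _objective_and_grad(B, A, deg, params.H, params.p, cfg, p_mask)
        if not np.isfinite(loss):
            raise OptimizationFailureError(
                f"non-finite loss at iteration {it}; reduce the learning rate",
                iteration=it,
            )
        trace[it] = loss
        if loss < best_loss:
            best_loss = loss
            best_B = B.copy()
        B = np.clip(B - cfg.learning_rate * grad, 0.0, 1.0)

    # renormalize rows so the result is a valid probabilistic assignment
    rows = best_B.sum(axis=1, keepdims=True)
    rows = np.where(rows > _EPS, rows, 1.0)
    best_B = best_B / rows
    return AssignmentMatrix(B=best_B, mode="probabilistic", loss_trace=trace)


def discretize_assignment(
    B: AssignmentMatrix,
    params: SpatialParameters | None = None,
    strategy: str = "argmax",
    seed: int | None = None,
) -> AssignmentMatrix:
    """Round a probabilistic assignment to one-hot.

    ``argmax`` breaks ties toward the lowest type index; ``sample`` draws
    each row from its (renormalized) probabilities, reproducibly for a fixed
    seed.
    """
    if B.mode != "probabilistic":
        raise InvalidParameterError("discretize_assignment expects probabilistic B")
    mat = B.B
    n, K = mat.shape
    if strategy == "argmax":
        idx = np.argmax(mat, axis=1)  # numpy argmax returns the first maximum
    elif strategy == "sample":
        rng = np.random.default_rng(seed)
        probs = mat / mat.sum(axis=1, keepdims=True)
        u = rng.random((n, 1))
        idx = (probs.cumsum(axis=1) < u).sum(axis=1)
        idx = np.minimum(idx, K - 1)
    else:
        raise InvalidParameterError(f"unknown strategy {strategy!r}")
    out = np.zeros_like(mat)
    out[np.arange(n), idx] = 1.0
    return AssignmentMatrix(B=out, mode="one-hot")


def labeled_tissue_from_assignment(
    scaffold: TissueScaffold, B: AssignmentMatrix, params: SpatialParameters
) -> LabeledTissue:
    """Wrap a one-hot assignment as a labeled tissue."""
    return LabeledTissue(
        scaffold=scaffold, labels=B.labels(), K=params.K,
        type_names=params.type_names,
    )
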