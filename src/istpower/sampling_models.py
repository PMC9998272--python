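"""Detection-power models for three spatial sampling strategies.

* **single-cell sampling** — cells drawn at random with no spatial context;
  detection of at least ``n_min`` cells of a type of abundance ``p`` among
  ``n`` profiled cells is binomial.
* **spatial (FOV) sampling** — whole square fields of view are assayed; the
  per-FOV count of a cell type is overdispersed by tissue structure and is
  modeled as gamma-Poisson (negative binomial, NBD), fitted by the zero
  term method (ZTM).  The chance of seeing the type in at least one of
  ``n_fov`` independent FOVs is ``1 - P(X=0)^n_fov``.
* **regional sampling** — FOVs are drawn, dissociated and a number of cells
  profiled; overdispersion of the per-FOV composition is captured by a
  beta-binomial model fitted by moments from per-FOV proportions.

Also provides FOV drawing, cohort-size calculators, retrospective power
analysis on sub-samples, and multi-tissue FOV requirements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import LabeledTissue, induced_tissue
from .errors import (
    EstimationError,
    InvalidParameterError,
    UnattainableError,
    UnfittableError,
)

__all__ = [
    "FOV",
    "NBDModel",
    "BetaBinomialModel",
    "binomial_detection",
    "cells_required",
    "draw_fovs",
    "fov_counts",
    "nbd_pmf",
    "fit_nbd_ztm",
    "fov_power",
    "fovs_required",
    "beta_binomial_from_moments",
    "fit_beta_binomial",
    "regional_detection",
    "tissues_required",
    "retrospective_power",
    "multi_sample_requirement",
]

_K_MAX = 1e6  # shape cap; the NBD degenerates to Poisson as k -> inf


@dataclass(frozen=True)
class FOV:
    """A square field of view, fully contained in the tissue bounds."""

    origin: tuple[float, float]
    side: float
    members: np.ndarray = field(repr=False)

    @property
    def n_cells(self) -> int:
        return int(self.members.shape[0])


@dataclass
class NBDModel:
    """Gamma-Poisson (negative binomial) model of per-FOV counts.

    ``m`` is the mean, ``k`` the shape (k -> inf is the Poisson limit);
    ``n0`` and ``N`` record the zero count and sample size used in fitting,
    ``method`` the estimator that produced ``k``.
    """

    m: float
    k: float
    n0: int = 0
    N: int = 0
    method: str = "ztm"

    def __post_init__(self):
        if not (np.isfinite(self.m) and self.m > 0):
            raise InvalidParameterError(f"mean m must be finite and > 0, got {self.m}")
        if not (np.isfinite(self.k) and self.k > 0):
            raise InvalidParameterError(f"shape k must be finite and > 0, got {self.k}")

    def p_zero(self) -> float:
        return float((1.0 + self.m / self.k) ** (-self.k))


@dataclass
class BetaBinomialModel:
    """Beta-binomial model of the per-FOV proportion of a cell type."""

    alpha: float
    beta: float
    mu: float
    sigma: float  # sample variance of per-FOV proportions

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise InvalidParameterError("alpha and beta must be positive")


def binomial_detection(
    p_type: float, n_cells: int, n_min: int = 1, fdr: float = 0.0
) -> float:
    """P(at least n_min cells of the type among n_cells), X ~ Binomial.

    ``fdr`` optionally discounts the abundance by a cell-type miscalling
    rate: the effective abundance is ``p_type * (1 - fdr)``.
    """
    if not 0.0 < p_type < 1.0:
        raise InvalidParameterError("p_type must lie strictly in (0, 1)")
    if not 0.0 <= fdr < 1.0:
        raise InvalidParameterError("fdr must lie in [0, 1)")
    if n_cells < 0 or n_min < 0:
        raise InvalidParameterError("counts must be non-negative")
    p_eff = p_type * (1.0 - fdr)
    return float(stats.binom.sf(n_min - 1, n_cells, p_eff))


def cells_required(
    p_type: float, target: float, n_min: int = 1, fdr: float = 0.0
) -> int:
    """Smallest number of profiled cells with binomial detection >= target."""
    if not 0.0 < target < 1.0:
        raise InvalidParameterError("target must lie strictly in (0, 1)")
    p_eff = p_type * (1.0 - fdr)
    if n_min == 1:
        n = max(1, math.ceil(math.log(1.0 - target) / math.log(1.0 - p_eff)))
    else:
        n = n_min
    while binomial_detection(p_type, n, n_min, fdr) < target:
        n += 1
    while n > n_min and binomial_detection(p_type, n - 1, n_min, fdr) >= target:
        n -= 1
    return n


def _fov_side(bounds: tuple[float, float], fraction: float) -> float:
    width, height = bounds
    side = math.sqrt(fraction * width * height)
    if side > min(width, height) + 1e-9:
        raise InvalidParameterError(
            f"a square FOV of {fraction:.0%} tissue area does not fit in the bounds"
        )
    return min(side, min(width, height))


def draw_fovs(
    tissue: LabeledTissue,
    fraction: float,
    n_fov: int,
    seed: int | None = None,
) -> list[FOV]:
    """Draw ``n_fov`` independent random square FOVs of the given area fraction.

    FOVs are placed uniformly at random, fully inside the tissue bounds;
    overlap between draws is permitted (draws are independent).
    """
    if not 0.0 < fraction <= 1.0:
        raise InvalidParameterError("fraction must lie in (0, 1]")
    if n_fov < 0:
        raise InvalidParameterError("n_fov must be non-negative")
    rng = np.random.default_rng(seed)
    bounds = tissue.scaffold.region_bounds
    side = _fov_side(bounds, fraction)
    xy = tissue.scaffold.xy
    out = []
    for _ in range(n_fov):
        ox = rng.uniform(0.0, bounds[0] - side) if bounds[0] > side else 0.0
        oy = rng.uniform(0.0, bounds[1] - side) if bounds[1] > side else 0.0
        inside = (
            (xy[:, 0] >= ox)
            & (xy[:, 0] < ox + side)
            & (xy[:, 1] >= oy)
            & (xy[:, 1] < oy + side)
        )
        out.append(FOV(origin=(ox, oy), side=side, members=np.flatnonzero(inside)))
    return out


def fov_counts(tissue: LabeledTissue, fovs: list[FOV], type_index: int) -> np.ndarray:
    """Per-FOV counts of cells of one type."""
    return np.array(
        [int(np.sum(tissue.labels[f.members] == type_index)) for f in fovs]
    )


def nbd_pmf(x, model: NBDModel):
    """NBD probability mass, parameterized by mean m and shape k:

        P(X = x) = Gamma(k+x) / (x! Gamma(k)) (1 + m/k)^-k (m/(m+k))^x
    """
    x = np.asarray(x)
    if np.any(x < 0):
        raise InvalidParameterError("x must be non-negative")
    # identical to scipy's nbinom with n = k, p = k / (k + m)
    return stats.nbinom.pmf(x, model.k, model.k / (model.k + model.m))


def fit_nbd_ztm(counts) -> NBDModel:
    """Fit the NBD by the zero term method.

    The mean is the sample mean; the shape solves

        n0 / N = (m/k + 1)^-k

    numerically (the left side is the observed zero fraction).  When the
    observed zero fraction is at or below the Poisson floor ``exp(-m)``
    (including the no-zeros case) the equation has no root and the moments
    estimator ``k = m^2 / (s^2 - m)`` is used instead; an under-dispersed
    sample caps the shape at the Poisson limit.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise UnfittableError("no counts provided")
    if np.any(counts < 0):
        raise InvalidParameterError("counts must be non-negative")
    m = float(counts.mean())
    if m == 0.0:
        raise UnfittableError("all counts are zero; the NBD mean is unidentifiable")
    N = counts.size
    n0 = int(np.sum(counts == 0))

    def moments() -> NBDModel:
        s2 = float(counts.var(ddof=1)) if N > 1 else 0.0
        if s2 > m:
            k = min(m * m / (s2 - m), _K_MAX)
        else:
            k = _K_MAX
        return NBDModel(m=m, k=k, n0=n0, N=N, method="moments")

    p0 = n0 / N
    if n0 == 0 or p0 <= math.exp(-m):
        return moments()

    def f(k):
        return (1.0 + m / k) ** (-k) - p0

    lo, hi = 1e-3, _K_MAX
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        if fhi > 0:  # zero fraction still above the k->inf limit numerically
            return moments()
        raise EstimationError(
            "zero-term equation has no root in the search bracket",
            diagnostics={"m": m, "p0": p0, "f_lo": flo, "f_hi": fhi},
        )
    try:
        k = optimize.brentq(f, lo, hi, xtol=1e-10, rtol=1e-12, maxiter=200)
    except RuntimeError as exc:  # pragma: no cover - brentq rarely fails
        raise EstimationError(
            f"root finding did not converge: {exc}",
            diagnostics={"m": m, "p0": p0},
        ) from exc
    return NBDModel(m=m, k=float(k), n0=n0, N=N, method="ztm")


def fov_power(model: NBDModel, n_fov: int) -> float:
    """P(type observed in at least one of ``n_fov`` independent FOVs)."""
    if n_fov < 0:
        raise InvalidParameterError("n_fov must be non-negative")
    return float(1.0 - model.p_zero() ** n_fov)


def fovs_required(model: NBDModel, target: float) -> int:
    """Smallest number of FOVs whose joint detection probability >= target."""
    if not 0.0 < target < 1.0:
        raise InvalidParameterError("target must lie strictly in (0, 1)")
    p0 = model.p_zero()
    if p0 <= 0.0:
        return 1
    if p0 >= 1.0:
        raise UnattainableError("zero detection probability per FOV")
    n = max(1, math.ceil(math.log(1.0 - target) / math.log(p0)))
    while fov_power(model, n) < target:
        n += 1
    while n > 1 and fov_power(model, n - 1) >= target:
        n -= 1
    return n


def beta_binomial_from_moments(mu: float, sigma: float) -> BetaBinomialModel:
    """Moment fit of the beta distribution of per-FOV proportions:

        alpha = mu   (mu (1 - mu) / sigma - 1)
        beta  = (1 - mu) (mu (1 - mu) / sigma - 1)

    where ``mu``/``sigma`` are the sample mean and variance of the per-FOV
    proportions.  Requires ``0 < sigma < mu (1 - mu)``.
    """
    if not 0.0 < mu < 1.0:
        raise EstimationError(f"mean proportion must lie in (0,1), got {mu}")
    if sigma <= 0.0:
        raise EstimationError(
            "zero variance across FOVs; the beta-binomial is degenerate"
        )
    if sigma >= mu * (1.0 - mu):
        raise EstimationError(
            "variance exceeds the mu(1-mu) bound (under-dispersion); "
            "use the binomial model instead",
            diagnostics={"mu": mu, "sigma": sigma},
        )
    nu = mu * (1.0 - mu) / sigma - 1.0
    return BetaBinomialModel(alpha=mu * nu, beta=(1.0 - mu) * nu, mu=mu, sigma=sigma)


def fit_beta_binomial(
    tissue: LabeledTissue,
    type_index: int,
    fraction: float = 0.05,
    n_fov: int = 50,
    seed: int | None = None,
) -> BetaBinomialModel:
    """Fit the regional-sampling model from randomly placed FOVs.

    Draws ``n_fov`` FOVs of the given area fraction, computes the per-FOV
    proportion of the type of interest (empty FOVs are skipped), and fits
    (alpha, beta) by moments.
    """
    if not np.any(tissue.labels == type_index):
        raise InvalidParameterError(f"type {type_index} not present in the tissue")
    fovs = draw_fovs(tissue, fraction, n_fov, seed=seed)
    props = [
        np.mean(tissue.labels[f.members] == type_index)
        for f in fovs
        if f.n_cells > 0
    ]
    if len(props) < 2:
        raise EstimationError("fewer than two non-empty FOVs; cannot fit moments")
    props = np.asarray(props, dtype=float)
    return beta_binomial_from_moments(float(props.mean()), float(props.var(ddof=1)))


def regional_detection(
    model: BetaBinomialModel, n_cells: int, n_min: int = 1
) -> float:
    """P(at least n_min cells of the type among n_cells profiled from FOVs).

    Beta-binomial survival function evaluated at ``n_min - 1``.
    """
    if n_cells < 0 or n_min < 0:
        raise InvalidParameterError("counts must be non-negative")
    if n_min == 0:
        return 1.0
    return float(
        stats.betabinom.sf(n_min - 1, n_cells, model.alpha, model.beta)
    )


def tissues_required(q: float, target: float) -> int:
    """Smallest cohort size n with 1 - (1 - q)^n >= target.

    ``q`` is the per-tissue probability of observing the feature (e.g. the
    fraction of replicate ISTs in which an adjacency was significant).
    """
    if q == 0.0:
        raise UnattainableError("feature never observed (q = 0); no cohort suffices")
    if not 0.0 < q <= 1.0:
        raise InvalidParameterError("q must lie in (0, 1]")
    if not 0.0 < target < 1.0:
        raise InvalidParameterError("target must lie strictly in (0, 1)")
    if q == 1.0:
        return 1
    n = max(1, math.ceil(math.log(1.0 - target) / math.log(1.0 - q)))
    while 1.0 - (1.0 - q) ** n < target:
        n += 1
    while n > 1 and 1.0 - (1.0 - q) ** (n - 1) >= target:
        n -= 1
    return n


def retrospective_power(
    tissue: LabeledTissue,
    fractions,
    trials: int = 100,
    alpha: float = 0.01,
    seed: int | None = None,
    n_perm: int = 300,
) -> pd.DataFrame:
    """Recovery of ground-truth adjacency calls from contiguous sub-samples.

    The ground truth is the set of significant adjacencies and avoidances
    (one-sided permutation test at level ``alpha``) on the full tissue.  For
    each area fraction, ``trials`` square sub-samples are drawn and the same
    test is run on each sub-sample; reported per fraction are the mean
    proportion of ground-truth calls recovered and the mean proportion of
    null hypotheses falsely called.  The permutation seed is shared between
    the full-tissue and sub-sample tests, so a sub-sample covering the whole
    tissue reproduces the ground truth exactly.
    """
    from .adjacency_stats import permutation_test  # local import to avoid cycle

    ss = np.random.SeedSequence(seed)
    perm_seed = int(ss.generate_state(1)[0] % (2**31))
    fov_ss = ss.spawn(1)[0]

    def calls(t: LabeledTissue) -> set[tuple[int, int, str]]:
        res = permutation_test(t, n_trials=n_perm, seed=perm_seed)
        out = set()
        K = t.K
        for i in range(K):
            for j in range(K):
                if res.p_enrich[i, j] < alpha:
                    out.add((i, j, "enrich"))
                if res.p_avoid[i, j] < alpha:
                    out.add((i, j, "avoid"))
        return out

    truth = calls(tissue)
    n_hyp = 2 * tissue.K * tissue.K
    rows = []
    for fraction in fractions:
        rec, fc = [], []
        fov_seeds = fov_ss.spawn(trials)
        for t_idx in range(trials):
            fov = draw_fovs(
                tissue, fraction, 1,
                seed=int(fov_seeds[t_idx].generate_state(1)[0] % (2**31)),
            )[0]
            if fov.n_cells == 0:
                continue
            sub = induced_tissue(tissue, fov.members)
            found = calls(sub)
            if truth:
                rec.append(len(found & truth) / len(truth))
            denom = n_hyp - len(truth)
            fc.append(len(found - truth) / denom if denom else 0.0)
        rows.append(
            {
                "fraction": fraction,
                "recovery": float(np.mean(rec)) if rec else float("nan"),
                "false_calls": float(np.mean(fc)) if fc else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def multi_sample_requirement(
    tissues: list[LabeledTissue],
    fraction: float,
    type_index: int,
    target: float,
    seed: int | None = None,
    n_fov: int = 50,
) -> pd.DataFrame:
    """Mean FOV requirement when FOVs are spread over 1..n tissue samples.

    For each subset size, every combination of tissues is sampled with
    ``n_fov`` FOVs allocated round-robin across the subset; the pooled
    per-FOV counts are fitted (ZTM) and the FOV requirement for the target
    detection probability computed, then averaged over combinations.
    """
    if not tissues:
        raise InvalidParameterError("need at least one tissue")
    ss = np.random.SeedSequence(seed)
    rows = []
    for size in range(1, len(tissues) + 1):
        reqs = []
        for combo in combinations(range(len(tissues)), size):
            counts = []
            child = ss.spawn(1)[0]
            per_tissue = [n_fov // size + (1 if r < n_fov % size else 0)
                          for r in range(size)]
            for t_pos, t_idx in enumerate(combo):
                t = tissues[t_idx]
                fovs = draw_fovs(
                    t, fraction, per_tissue[t_pos],
                    seed=int(child.generate_state(1)[0] % (2**31)) + t_pos,
                )
                counts.extend(fov_counts(t, fovs, type_index).tolist())
            model = fit_nbd_ztm(np.asarray(counts))
            reqs.append(fovs_required(model, target))
        rows.append({"n_tissues": size, "mean_fovs_required": float(np.mean(reqs))})
    return pd.DataFrame(rows)
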