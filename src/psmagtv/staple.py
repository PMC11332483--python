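"""Binary STAPLE consensus of multiple manual delineations.

STAPLE (simultaneous truth and performance level estimation) treats the
unknown true segmentation as a latent voxelwise label and each rater j as a
noisy channel with sensitivity p_j and specificity q_j, and estimates both
by expectation-maximization. The E-step computes the posterior weight W_i
that voxel i is truly foreground,

    W_i = g * prod_j a_ij / (g * prod_j a_ij + (1 - g) * prod_j b_ij),
    a_ij = p_j^D_ij (1 - p_j)^(1 - D_ij),
    b_ij = (1 - q_j)^D_ij q_j^(1 - D_ij),

with D_ij the rater decisions and g a fixed prior foreground probability;
the M-step re-estimates p_j, q_j from the weights. The consensus mask is
the posterior thresholded at 0.5 (ties included).

Specificity estimates are diluted by vast empty background, so by default
the EM runs over the bounding box of the union of rater masks dilated by 5
voxels; the full grid is available via ``region="full"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import BinaryMask

__all__ = ["StapleResult", "staple", "interobserver_dsc", "mean_pairwise_dsc"]

_EPS = 1e-300


@dataclass
class StapleResult:
    posterior: np.ndarray          # full-grid voxelwise P(true label = 1)
    p_hat: np.ndarray              # per-rater sensitivity estimates
    q_hat: np.ndarray              # per-rater specificity estimates
    consensus: BinaryMask          # posterior >= 0.5
    n_iterations: int
    converged: bool
    log_likelihood: list           # observed-data log-likelihood per iteration
    prior: float
    region_slices: tuple           # evaluation region within the grid


def _evaluation_slices(union: np.ndarray, dilate_voxels: int = 5) -> tuple:
    idx = np.argwhere(union)
    lo = np.maximum(idx.min(axis=0) - dilate_voxels, 0)
    hi = np.minimum(idx.max(axis=0) + dilate_voxels, np.asarray(union.shape) - 1)
    return tuple(slice(int(a), int(b) + 1) for a, b in zip(lo, hi))


def staple(
    raters: list,
    prior: float | None = None,
    init_pq: float = 0.99999,
    tol: float = 1e-7,
    max_iter: int = 100,
    region: str = "union-bbox",
) -> StapleResult:
    """Fuse rater masks into a consensus by binary STAPLE.

    Parameters
    ----------
    raters:
        One or more :class:`BinaryMask` on a common grid.
    prior:
        Fixed prior foreground probability g. By default the mean foreground
        fraction across raters over the evaluation region.
    init_pq:
        Initial value of every p_j and q_j.
    tol:
        Convergence threshold on ``max_j (|dp_j| + |dq_j|)``.
    region:
        ``"union-bbox"`` (default) evaluates over the bounding box of the
        union of rater masks dilated by 5 voxels; ``"full"`` uses the grid.
    """
    if len(raters) == 0:
        raise ValueError("at least one rater is required")
    grid = raters[0].grid
    for r in raters[1:]:
        grid.require_compatible(r.grid)

    union = np.zeros(grid.shape, dtype=bool)
    for r in raters:
        union |= r.voxels
    if not union.any():
        raise ValueError("all rater masks are empty; STAPLE prior is degenerate")

    if region == "union-bbox":
        slices = _evaluation_slices(union)
    elif region == "full":
        slices = tuple(slice(0, n) for n in grid.shape)
    else:
        raise ValueError(f"unknown region mode {region!r}")

    # decisions matrix over the evaluation region: (n_voxels, n_raters)
    D = np.stack([r.voxels[slices].reshape(-1) for r in raters], axis=1)
    J = D.shape[1]

    g = float(prior) if prior is not None else float(D.mean())
    if not (0 < g < 1):
        raise ValueError(f"prior foreground probability must lie in (0, 1), got {g}")

    p = np.full(J, float(init_pq))
    q = np.full(J, float(init_pq))

    ll_history = []
    converged = False
    n_iter = 0
    W = np.empty(D.shape[0])
    for n_iter in range(1, max_iter + 1):
        # E-step
        a = np.prod(np.where(D, p, 1.0 - p), axis=1)
        b = np.prod(np.where(D, 1.0 - q, q), axis=1)
        num = g * a
        den = num + (1.0 - g) * b
        W = num / np.maximum(den, _EPS)
        ll_history.append(float(np.sum(np.log(np.maximum(den, _EPS)))))

        # M-step
        sw = W.sum()
        swc = (1.0 - W).sum()
        p_new = (W[:, None] * D).sum(axis=0) / max(sw, _EPS)
        q_new = ((1.0 - W)[:, None] * (~D)).sum(axis=0) / max(swc, _EPS)
        delta = float(np.max(np.abs(p_new - p) + np.abs(q_new - q)))
        p, q = p_new, q_new
        if delta < tol:
            converged = True
            break

    # final posterior at the converged parameters
    a = np.prod(np.where(D, p, 1.0 - p), axis=1)
    b = np.prod(np.where(D, 1.0 - q, q), axis=1)
    den = g * a + (1.0 - g) * b
    W = g * a / np.maximum(den, _EPS)

    posterior = np.zeros(grid.shape, dtype=np.float64)
    posterior[slices] = W.reshape([s.stop - s.start for s in slices])
    consensus = BinaryMask(grid, posterior >= 0.5)
    return StapleResult(
        posterior=posterior,
        p_hat=p,
        q_hat=q,
        consensus=consensus,
        n_iterations=n_iter,
        converged=converged,
        log_likelihood=ll_history,
        prior=g,
        region_slices=slices,
    )


def interobserver_dsc(raters: list) -> float:
    """Pooled pairwise Dice agreement of two or more raters.

    ``2 * sum_{j<k} |A_j & A_k| / sum_{j<k} (|A_j| + |A_k|)`` — intersections
    and sizes pooled over all unordered pairs before dividing.
    """
    if len(raters) < 2:
        raise ValueError("interobserver agreement needs at least 2 raters")
    grid = raters[0].grid
    for r in raters[1:]:
        grid.require_compatible(r.grid)
    inter = 0
    sizes = 0
    for j in range(len(raters)):
        for k in range(j + 1, len(raters)):
            inter += int(np.sum(raters[j].voxels & raters[k].voxels))
            sizes += raters[j].n_true + raters[k].n_true
    if sizes == 0:
        return 0.0
    return 2.0 * inter / sizes


def mean_pairwise_dsc(raters: list) -> float:
    """Mean of the pairwise Dice coefficients (alternative agreement summary)."""
    if len(raters) < 2:
        raise ValueError("interobserver agreement needs at least 2 raters")
    vals = []
    for j in range(len(raters)):
        for k in range(j + 1, len(raters)):
            inter = int(np.sum(raters[j].voxels & raters[k].voxels))
            denom = raters[j].n_true + raters[k].n_true
            vals.append(2.0 * inter / denom if denom else 0.0)
    return float(np.mean(vals))
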