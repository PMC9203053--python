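"""Robust spline-like smoothing of gridded data via a DCT penalized fit.

The smoother minimizes ``‖W^(1/2)(z − y)‖² + s·‖Δz‖²`` over the grid, where
Δ is the discrete Laplacian and W holds per-cell weights (observation counts;
zero for empty cells).  Diagonalizing the penalty in the type-II discrete
cosine basis gives the per-frequency shrinkage Γ = 1/(1 + s·λ²); with
non-uniform weights the solution is obtained by fixed-point iteration

    z ← IDCT( Γ ⊙ DCT( W ⊙ (y − z) + z ) ),

which handles arbitrary missing-data patterns.  An optional robust stage
downweights outlying residuals with bisquare weights.

The user-facing bandwidth is ``s_frac``, the smoother's approximate
half-width as a fraction of each axis span.  Linearizing the penalty at low
frequency, the −3 dB cutoff satisfies s·λ(ω_c)² = 1 with
λ(ω) ≈ (πω/n)², giving a spatial half-width ≈ (π/2)·s^(1/4) cells; the
default mapping inverts this, s = (2·n·s_frac/π)⁴.  The raw parameter ``s``
may be passed directly instead.
"""

from __future__ import annotations

import numpy as np
from scipy.fft import dctn, idctn

__all__ = ["smooth_grid", "s_from_frac", "bin_scattered"]


def s_from_frac(s_frac: float, n_cells: int) -> float:
    """Map a half-width fraction of the axis span to the penalty weight s."""
    if s_frac <= 0:
        raise ValueError("s_frac must be positive")
    return float((2.0 * n_cells * s_frac / np.pi) ** 4)


def _gamma(shape: tuple[int, ...], s: float) -> np.ndarray:
    """Per-frequency shrinkage factors 1/(1 + s λ²) on the DCT grid."""
    lam = np.zeros(shape)
    for axis, n in enumerate(shape):
        idx = [None] * len(shape)
        idx[axis] = slice(None)
        lam = lam + (2.0 - 2.0 * np.cos(np.pi * np.arange(n) / n))[tuple(idx)]
    return 1.0 / (1.0 + s * lam**2)


def _solve(
    y: np.ndarray,
    w: np.ndarray,
    gamma: np.ndarray,
    z0: np.ndarray,
    tol: float,
    max_iter: int,
) -> np.ndarray:
    """Fixed-point iteration for the weighted penalized fit.

    ``y`` may carry leading batch dimensions; ``w``/``gamma`` are broadcast.
    NaNs in y (empty cells) must have zero weight and are treated as 0.
    """
    y = np.where(w > 0, y, 0.0)
    relax = 1.75  # over-relaxation accelerates the weighted iteration

    squeeze = y.ndim == 2
    yb = y[None] if squeeze else y
    wb = np.broadcast_to(w, yb.shape)
    zb = (z0[None] if squeeze else z0).copy()
    out = np.empty_like(zb)
    # compact the batch as members converge so finished members cost nothing
    index = np.arange(zb.shape[0])
    for _ in range(max_iter):
        rhs = wb * (yb - zb) + zb
        z_hat = idctn(
            gamma * dctn(rhs, axes=(-2, -1), norm="ortho"),
            axes=(-2, -1), norm="ortho",
        )
        z_new = relax * z_hat + (1.0 - relax) * zb
        delta = np.abs(z_new - zb).max(axis=(-2, -1))
        scale = np.maximum(np.abs(z_new).max(axis=(-2, -1)), 1e-12)
        zb = z_new
        done = delta / scale < tol
        if done.any():
            out[index[done]] = zb[done]
            if done.all():
                index = index[:0]
                break
            keep = ~done
            index, zb = index[keep], zb[keep]
            yb, wb = yb[keep], wb[keep]
    if index.size:
        out[index] = zb
    return out[0] if squeeze else out


def smooth_grid(
    y: np.ndarray,
    weights: np.ndarray | None = None,
    s: float | None = None,
    s_frac: float = 0.40,
    robust_iters: int = 0,
    tol: float = 1e-5,
    max_iter: int = 400,
) -> np.ndarray:
    """Smooth one grid or a batch of grids sharing a weight pattern.

    Parameters
    ----------
    y
        Grid of values, shape ``(..., ny, nx)``; leading dimensions are a
        batch smoothed jointly (same weights and bandwidth).  NaN marks
        empty cells (their weight must be 0).
    weights
        Non-negative per-cell weights, shape ``(ny, nx)``; typically the
        observation counts from :func:`bin_scattered`.  ``None`` means all 1.
        Weights are scaled so their maximum is 1 (the iteration's contraction
        requires weights in [0, 1]).
    s, s_frac
        Penalty weight; if ``s`` is None it is derived from ``s_frac`` via
        :func:`s_from_frac` using the mean axis length.
    robust_iters
        Number of bisquare reweighting passes applied after the initial fit
        (0 disables robustness; the smoother is then linear in ``y``).
    """
    y = np.asarray(y, dtype=float)
    grid_shape = y.shape[-2:]
    if weights is None:
        w = np.ones(grid_shape)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != grid_shape:
            raise ValueError(f"weights shape {w.shape} != grid shape {grid_shape}")
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        if w.max() <= 0:
            raise ValueError("all weights are zero")
        w = w / w.max()
    if np.isnan(y[..., w > 0]).any():
        raise ValueError("NaN values at cells with positive weight")
    if s is None:
        s = s_from_frac(s_frac, int(np.mean(grid_shape)))

    gamma = _gamma(grid_shape, s)
    support = w > 0
    # initial guess: weighted mean everywhere (stable for strong smoothing)
    mean0 = (
        np.sum(np.where(support, y, 0.0) * w, axis=(-2, -1), keepdims=True)
        / w.sum()
    )
    z0 = np.broadcast_to(mean0, y.shape).copy()
    z = _solve(y, w, gamma, z0, tol, max_iter)

    for _ in range(robust_iters):
        resid = np.where(support, y - z, 0.0)
        mad = np.median(np.abs(resid[..., support]), axis=-1)
        scale = 1.4826 * np.maximum(mad, 1e-12)
        u = resid / (6.0 * scale[..., None, None] if np.ndim(scale) else 6.0 * scale)
        bisq = np.clip(1.0 - u**2, 0.0, None) ** 2
        wr = w * bisq
        flat_max = wr.reshape(*wr.shape[:-2], -1).max(axis=-1)
        if np.ndim(flat_max):
            wr = wr / np.maximum(flat_max, 1e-12)[..., None, None]
        else:
            wr = wr / max(flat_max, 1e-12)
        # _solve broadcasts per-member robust weights across the batch
        z = _solve(y, wr, gamma, z, tol, max_iter)
    return z


def bin_scattered(
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    x_edges: np.ndarray,
    y_edges: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Bin scattered (x, y, z) points onto a grid.

    Returns ``(values, counts)`` with shape ``(len(y_edges)−1,
    len(x_edges)−1)``; a cell's value is the mean z of the points falling in
    it (NaN where empty) and its count is the number of points (the
    smoother's weight).  Points on the outer edges are included.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    ny, nx = len(y_edges) - 1, len(x_edges) - 1
    ix = np.clip(np.digitize(x, x_edges) - 1, 0, nx - 1)
    iy = np.clip(np.digitize(y, y_edges) - 1, 0, ny - 1)
    counts = np.zeros((ny, nx))
    sums = np.zeros((ny, nx))
    np.add.at(counts, (iy, ix), 1.0)
    np.add.at(sums, (iy, ix), z)
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return values, counts
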