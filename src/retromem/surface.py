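"""Smoothed Osgood surfaces and cluster-based permutation inference.

Per-pair retroactive effects ΔM = M_condition − M_control live at scattered
(target relatedness, cue relatedness) coordinates.  They are binned to a
grid, smoothed (:mod:`retromem.smoothing`), and tested for regions that
exceed chance: condition labels are scrambled within each pair (a sign flip
of its ΔM), the permuted data are re-smoothed identically, per-cell tail
quantiles of the permuted surfaces give pointwise significance thresholds,
and the sizes of connected suprathreshold clusters in the true surface are
referred to the permutation distribution of maximum cluster sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .smoothing import bin_scattered, s_from_frac, smooth_grid

__all__ = ["SurfaceConfig", "SurfaceGrid", "Cluster", "ClusterResult",
           "smooth_scattered", "cluster_permutation"]


@dataclass
class SurfaceConfig:
    grid_size: int = 64  # cells per axis
    s_frac: float = 0.10  # smoother half-width as fraction of axis span
    s: float | None = None  # raw penalty weight; overrides s_frac
    robust_iters: int = 2
    pointwise_alpha: float = 0.01  # each one-sided tail
    n_permutations: int = 1000
    seed: int = 0
    margin: float = 0.02  # grid margin as fraction of each axis span
    connectivity: int = 4  # 4- or 8-neighbor cluster connectivity
    threshold_mode: str = "smooth_first"  # or "threshold_then_smooth"
    permutation_scheme: str = "scramble"  # or "sign_flip"
    plus_one_correction: bool = True  # (b+1)/(m+1): valid finite-sample p
    allow_few_permutations: bool = False

    def __post_init__(self):
        if self.s_frac <= 0:
            raise ValueError("s_frac must be positive")
        if not 0.0 < self.pointwise_alpha < 0.5:
            raise ValueError("pointwise_alpha must lie in (0, 0.5)")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.threshold_mode not in ("smooth_first", "threshold_then_smooth"):
            raise ValueError(f"unknown threshold mode {self.threshold_mode!r}")
        if self.permutation_scheme not in ("scramble", "sign_flip"):
            raise ValueError(f"unknown permutation scheme {self.permutation_scheme!r}")

    def penalty(self) -> float:
        return self.s if self.s is not None else s_from_frac(self.s_frac, self.grid_size)


@dataclass
class SurfaceGrid:
    x: np.ndarray  # cell-center coordinates, target-relatedness axis
    y: np.ndarray  # cell-center coordinates, cue-relatedness axis
    z: np.ndarray  # smoothed surface, shape (len(y), len(x))
    support: np.ndarray  # boolean mask of cells containing data
    upper: np.ndarray | None = None  # pointwise upper threshold
    lower: np.ndarray | None = None  # pointwise lower threshold

    def to_frame(self):
        import pandas as pd

        yy, xx = np.meshgrid(self.y, self.x, indexing="ij")
        out = {
            "x": xx.ravel(),
            "y": yy.ravel(),
            "z": self.z.ravel(),
            "support": self.support.ravel(),
        }
        if self.upper is not None:
            out["upper"] = self.upper.ravel()
            out["lower"] = self.lower.ravel()
        return pd.DataFrame(out)


@dataclass
class Cluster:
    polarity: str  # "above" or "below"
    cells: np.ndarray  # boolean member mask
    size: int
    p_value: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    null_max_sizes: np.ndarray
    n_permutations: int
    cluster_map: np.ndarray = field(default=None)  # int labels, 0 = none

    @property
    def min_p(self) -> float:
        return min((c.p_value for c in self.clusters), default=1.0)


def _grid_edges(v: np.ndarray, n: int, margin: float) -> np.ndarray:
    lo, hi = float(np.min(v)), float(np.max(v))
    span = hi - lo
    if span <= 0:
        raise ValueError("degenerate axis span")
    return np.linspace(lo - margin * span, hi + margin * span, n + 1)


def smooth_scattered(points, config: SurfaceConfig) -> SurfaceGrid:
    """Smooth scattered (x, y, z) triples onto a regular grid.

    ``points`` is an (n, 3) array-like.  Bin counts serve as smoothing
    weights, so the penalized fit bridges empty cells while honoring
    multiply-observed ones.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array of (x, y, z)")
    if len(pts) < 5:
        raise ValueError("need at least 5 points to fit a surface")
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    x_edges = _grid_edges(x, config.grid_size, config.margin)
    y_edges = _grid_edges(y, config.grid_size, config.margin)
    values, counts = bin_scattered(x, y, z, x_edges, y_edges)
    zs = smooth_grid(
        values,
        weights=counts,
        s=config.penalty(),
        robust_iters=config.robust_iters,
    )
    return SurfaceGrid(
        x=0.5 * (x_edges[:-1] + x_edges[1:]),
        y=0.5 * (y_edges[:-1] + y_edges[1:]),
        z=zs,
        support=counts > 0,
    )


def _label_clusters(mask: np.ndarray, connectivity: int) -> tuple[np.ndarray, int]:
    structure = (
        np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        if connectivity == 4
        else np.ones((3, 3))
    )
    return ndimage.label(mask, structure=structure)


def _max_cluster_size(mask: np.ndarray, connectivity: int) -> int:
    labels, n = _label_clusters(mask, connectivity)
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def cluster_permutation(delta_points, config: SurfaceConfig):
    """Cluster-level permutation test of a retroactive-effect surface.

    ``delta_points`` is an (n, 4) array-like of per-pair
    ``(x, y, M_condition, M_control)``.  The observed surface smooths
    ΔM = M_condition − M_control.  Each permutation swaps the two condition
    labels independently per pair with probability ½ (equivalently flips the
    sign of its ΔM) and re-smooths with identical settings; per-cell tail
    quantiles of the permuted surfaces give the pointwise thresholds (with
    ``threshold_then_smooth``, quantiles of the *unsmoothed* binned permuted
    values are taken first and the threshold grids are then smoothed).  The
    p-value of each suprathreshold cluster in the true surface is the
    fraction of permutations whose own maximum suprathreshold cluster is at
    least as large.

    Returns ``(SurfaceGrid, ClusterResult)``.
    """
    pts = np.asarray(delta_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 4:
        raise ValueError("delta_points must be (n, 4): x, y, M_cond, M_control")
    if config.n_permutations < 100 and not config.allow_few_permutations:
        raise ValueError(
            "fewer than 100 permutations is unreliable; "
            "set allow_few_permutations=True to proceed"
        )
    rng = np.random.default_rng(config.seed)
    x, y = pts[:, 0], pts[:, 1]
    dm = pts[:, 2] - pts[:, 3]
    n_pairs, n_perm = len(pts), config.n_permutations

    x_edges = _grid_edges(x, config.grid_size, config.margin)
    y_edges = _grid_edges(y, config.grid_size, config.margin)
    _, counts = bin_scattered(x, y, dm, x_edges, y_edges)
    support = counts > 0

    # permuted ΔM draws (coordinates and counts stay fixed):
    # "scramble" pools the 2n memorability values and randomly reassigns
    # which fall in the condition vs the control group, so each permuted
    # pair difference is a difference of two randomly relabeled values;
    # "sign_flip" swaps the two condition labels within each pair.
    if config.permutation_scheme == "scramble":
        pool = np.concatenate([pts[:, 2], pts[:, 3]])
        idx = np.argsort(rng.random((n_perm, 2 * n_pairs)), axis=1)
        shuffled = pool[idx]
        perm_dm = shuffled[:, :n_pairs] - shuffled[:, n_pairs:]
    else:
        signs = np.where(rng.random((n_perm, n_pairs)) < 0.5, -1.0, 1.0)
        perm_dm = signs * dm

    # bin observed + permuted values in one pass (counts are shared)
    ny, nx = config.grid_size, config.grid_size
    ix = np.clip(np.digitize(x, x_edges) - 1, 0, nx - 1)
    iy = np.clip(np.digitize(y, y_edges) - 1, 0, ny - 1)
    flat = iy * nx + ix
    all_dm = np.vstack([dm[None, :], perm_dm])  # (n_perm+1, n_pairs)
    sums = np.zeros((n_perm + 1, ny * nx))
    np.add.at(sums.T, flat, all_dm.T)
    with np.errstate(invalid="ignore"):
        binned = np.where(
            counts.ravel() > 0, sums / np.maximum(counts.ravel(), 1), np.nan
        ).reshape(n_perm + 1, ny, nx)

    smoothed = smooth_grid(
        binned,
        weights=counts,
        s=config.penalty(),
        robust_iters=config.robust_iters,
    )
    z_true, z_perm = smoothed[0], smoothed[1:]

    # thresholds are taken over observed + permuted surfaces together: the
    # observed surface is one member of the exchangeable family, and leaving
    # it out would let it exceed thresholds the permutations helped set,
    # inflating the false-positive rate
    a = config.pointwise_alpha
    if config.threshold_mode == "smooth_first":
        upper = np.quantile(smoothed, 1.0 - a, axis=0)
        lower = np.quantile(smoothed, a, axis=0)
    else:
        # literal order: per-cell quantiles of raw binned values where data
        # exist, then smooth the threshold grids themselves
        upper_raw = np.full(z_true.shape, np.nan)
        lower_raw = np.full(z_true.shape, np.nan)
        upper_raw[support] = np.quantile(binned[:, support], 1.0 - a, axis=0)
        lower_raw[support] = np.quantile(binned[:, support], a, axis=0)
        thr = smooth_grid(
            np.stack([upper_raw, lower_raw]),
            weights=counts,
            s=config.penalty(),
            robust_iters=0,
        )
        upper, lower = thr[0], thr[1]

    exceed_true = {"above": z_true > upper, "below": z_true < lower}
    exceed_perm = (z_perm > upper) | (z_perm < lower)
    null_max = np.array(
        [_max_cluster_size(m, config.connectivity) for m in exceed_perm]
    )

    add = 1 if config.plus_one_correction else 0
    clusters: list[Cluster] = []
    cluster_map = np.zeros(z_true.shape, dtype=int)
    next_id = 1
    for polarity, mask in exceed_true.items():
        labels, n = _label_clusters(mask, config.connectivity)
        for lab in range(1, n + 1):
            members = labels == lab
            size = int(members.sum())
            p = (np.sum(null_max >= size) + add) / (len(null_max) + add)
            clusters.append(
                Cluster(polarity=polarity, cells=members, size=size, p_value=float(p))
            )
            cluster_map[members] = next_id
            next_id += 1
    clusters.sort(key=lambda c: c.p_value)

    grid = SurfaceGrid(
        x=0.5 * (x_edges[:-1] + x_edges[1:]),
        y=0.5 * (y_edges[:-1] + y_edges[1:]),
        z=z_true,
        support=support,
        upper=upper,
        lower=lower,
    )
    result = ClusterResult(
        clusters=clusters,
        null_max_sizes=null_max,
        n_permutations=n_perm,
        cluster_map=cluster_map,
    )
    return grid, result
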