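"""Shared-gene preprocessing and spatial-graph construction.

Both slices of a pair are reduced to one ordered panel of shared highly
variable genes (HVGs), then normalised per spot, log-transformed and
(optionally) scaled per gene. The spatial side turns coordinates into a
symmetric kNN graph, its degree-normalised adjacency Ã = D^{-1/2} A D^{-1/2}
and the pairwise squared-distance matrix used by the structure-preservation
loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist

from .io import SliceData

__all__ = [
    "PreprocessConfig",
    "SpatialGraph",
    "preprocess_pair",
    "build_knn_graph",
    "normalize_adjacency",
    "pairwise_sqdist",
    "build_spatial_graph",
]


@dataclass
class PreprocessConfig:
    """Preprocessing switches.

    ``scale_unit_variance`` defaults to off: the decoder ends in a ReLU, so
    reconstructions are nonnegative and the targets should be kept on the
    nonnegative log-normalised scale.
    """

    n_hvg: int = 1500
    normalize_total: bool = True
    target_sum: float = 1e4
    log1p: bool = True
    scale_unit_variance: bool = False
    sqdist_mean_normalize: bool = True

    def __post_init__(self):
        if self.n_hvg < 2:
            raise ValueError("n_hvg must be at least 2")


@dataclass
class SpatialGraph:
    """Adjacency, normalised adjacency, squared distances and neighbor sets."""

    adj: np.ndarray
    norm_adj: np.ndarray
    sqdist: np.ndarray
    neighbor_sets: list = field(default_factory=list)


def _dispersion(expr: np.ndarray) -> np.ndarray:
    """Per-gene dispersion (variance over mean) on total-normalised counts."""
    totals = expr.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    norm = expr / totals * np.median(totals)
    mean = norm.mean(axis=0)
    var = norm.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
    return disp


def _shared_hvg_panel(a: SliceData, b: SliceData, n_hvg: int) -> list[str]:
    shared = [g for g in a.gene_ids if g in set(b.gene_ids)]
    if len(shared) < 2:
        raise ValueError("slices share fewer than 2 genes")
    target = min(n_hvg, len(shared))
    ia = {g: i for i, g in enumerate(a.gene_ids)}
    ib = {g: i for i, g in enumerate(b.gene_ids)}
    disp_a = _dispersion(a.expr)[[ia[g] for g in shared]]
    disp_b = _dispersion(b.expr)[[ib[g] for g in shared]]
    # per-slice dispersion rank (0 = most variable), grow the per-slice top
    # lists until their intersection is large enough, then truncate by the
    # combined rank
    rank_a = np.empty(len(shared), dtype=np.intp)
    rank_a[np.argsort(-disp_a, kind="stable")] = np.arange(len(shared))
    rank_b = np.empty(len(shared), dtype=np.intp)
    rank_b[np.argsort(-disp_b, kind="stable")] = np.arange(len(shared))
    m = target
    while True:
        keep = np.flatnonzero((rank_a < m) & (rank_b < m))
        if len(keep) >= target or m >= len(shared):
            break
        m = min(len(shared), m + max(1, (target - len(keep))))
    combined = rank_a[keep] + rank_b[keep]
    order = keep[np.argsort(combined, kind="stable")][:target]
    return [shared[i] for i in sorted(order)]


def _apply_normalisation(expr: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    out = expr.astype(np.float64, copy=True)
    if cfg.normalize_total:
        totals = out.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        out = out / totals * cfg.target_sum
    if cfg.log1p:
        out = np.log1p(out)
    if cfg.scale_unit_variance:
        sd = out.std(axis=0)
        sd[sd == 0] = 1.0
        out = (out - out.mean(axis=0)) / sd
    return out


def preprocess_pair(a: SliceData, b: SliceData,
                    cfg: Optional[PreprocessConfig] = None) -> tuple[SliceData, SliceData]:
    """Restrict both slices to a shared ordered HVG panel and normalise.

    Order of operations: panel restriction, per-spot total normalisation,
    log1p, per-gene unit-variance scaling (each step only when enabled).
    """
    cfg = cfg or PreprocessConfig()
    panel = _shared_hvg_panel(a, b, cfg.n_hvg)
    out = []
    for sl in (a, b):
        idx = {g: i for i, g in enumerate(sl.gene_ids)}
        cols = [idx[g] for g in panel]
        out.append(
            SliceData(
                coords=sl.coords.copy(),
                expr=_apply_normalisation(sl.expr[:, cols], cfg),
                gene_ids=list(panel),
                spot_ids=list(sl.spot_ids),
                labels=None if sl.labels is None else sl.labels.copy(),
            )
        )
    return out[0], out[1]


def build_knn_graph(coords: np.ndarray, k: int = 6) -> np.ndarray:
    """Symmetric kNN adjacency: edge i–j iff j is among i's k nearest or vice versa.

    Distance ties are broken by spot index (brute-force exact neighbors).
    The diagonal is zero.
    """
    coords = np.asarray(coords, dtype=np.float64)
    n = coords.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"k ({k}) must be smaller than the spot count ({n})")
    d = cdist(coords, coords, metric="sqeuclidean")
    np.fill_diagonal(d, np.inf)  # never self-neighbor
    order = np.argsort(d, axis=1, kind="stable")  # ties -> lowest index
    adj = np.zeros((n, n), dtype=np.float64)
    rows = np.repeat(np.arange(n), k)
    adj[rows, order[:, :k].ravel()] = 1.0
    adj = np.maximum(adj, adj.T)
    np.fill_diagonal(adj, 0.0)
    return adj


def normalize_adjacency(adj: np.ndarray, add_self_loops: bool = True) -> np.ndarray:
    """Return D^{-1/2} A D^{-1/2}, optionally with A replaced by A + I."""
    a = np.asarray(adj, dtype=np.float64)
    if add_self_loops:
        a = a + np.eye(a.shape[0])
    deg = a.sum(axis=1)
    if np.any(deg <= 0):
        raise ValueError(
            "isolated node with zero degree; enable add_self_loops or fix the graph"
        )
    dinv = 1.0 / np.sqrt(deg)
    return a * dinv[:, None] * dinv[None, :]


def pairwise_sqdist(coords: np.ndarray, mean_normalize: bool = True) -> np.ndarray:
    """Pairwise squared Euclidean distances, optionally scaled so that the
    mean off-diagonal entry is 1 (making the structure loss scale-free)."""
    coords = np.asarray(coords, dtype=np.float64)
    d = cdist(coords, coords, metric="sqeuclidean")
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    n = d.shape[0]
    if mean_normalize and n > 1:
        off_mean = d.sum() / (n * (n - 1))
        if off_mean > 0:
            d = d / off_mean
    return d


def build_spatial_graph(coords: np.ndarray, k: int = 6, add_self_loops: bool = True,
                        mean_normalize_sqdist: bool = True) -> SpatialGraph:
    """Bundle adjacency, Ã, squared distances and neighbor sets for one slice."""
    adj = build_knn_graph(coords, k)
    norm_adj = normalize_adjacency(adj, add_self_loops=add_self_loops)
    sqd = pairwise_sqdist(coords, mean_normalize=mean_normalize_sqdist)
    neighbor_sets = [np.flatnonzero(adj[i]) for i in range(adj.shape[0])]
    return SpatialGraph(adj=adj, norm_adj=norm_adj, sqdist=sqd,
                        neighbor_sets=neighbor_sets)
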