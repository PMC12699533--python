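"""Coarse-to-fine hyperspot acceleration.

The cross-attention step is the quadratic bottleneck of the method: it
touches every pair of spots. To scale, each slice's spots are grouped by
k-means on their coordinates into m ≪ n "hyperspots"; during training the
attention map, Sinkhorn plan and the structure/alignment losses are computed
between hyperspot-mean embeddings and centroid distance matrices. After
training, the learned projection is reused once at full resolution to
recover a spot-level plan — no retraining.

The degenerate partition m = n (every spot its own hyperspot) is handled by
an explicit identity shortcut so that the coarse computation is literally
the full-resolution one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from ._tensor import Tensor, astensor
from .alignment import (
    TransportPlan,
    attention_cost,
    sinkhorn_normalize,
    t_align_loss,
    t_maintain_loss,
    t_marginal_penalty,
)

__all__ = [
    "HyperspotPartition",
    "build_hyperspots",
    "aggregate_embeddings",
    "aggregation_matrix",
    "coarse_losses",
    "full_resolution_plan",
]

DEFAULT_FRACTION = 0.15  # within the 10-20% coarsening range


@dataclass
class HyperspotPartition:
    """Assignment of n spots to m spatial clusters."""

    assignment: np.ndarray
    m: int
    centroid_coords: np.ndarray
    member_counts: np.ndarray

    def __post_init__(self):
        self.assignment = np.asarray(self.assignment, dtype=np.intp)
        if self.assignment.min() < 0 or self.assignment.max() >= self.m:
            raise ValueError("assignments must lie in [0, m)")
        if (self.member_counts <= 0).any():
            raise ValueError("every hyperspot must be nonempty")
        if int(self.member_counts.sum()) != self.assignment.shape[0]:
            raise ValueError("member counts must sum to the spot count")

    @property
    def n(self) -> int:
        return self.assignment.shape[0]

    @property
    def is_identity(self) -> bool:
        return self.m == self.n and bool(
            (self.assignment == np.arange(self.n)).all()
        )


def build_hyperspots(coords: np.ndarray, fraction: float = DEFAULT_FRACTION,
                     seed: int = 0) -> HyperspotPartition:
    """k-means on coordinates with m = round(fraction · n) centers.

    ``fraction = 1`` yields the degenerate identity partition (one spot per
    hyperspot), which makes the coarse pipeline coincide exactly with the
    full-resolution one.
    """
    coords = np.asarray(coords, dtype=np.float64)
    n = coords.shape[0]
    if not (0.0 < fraction <= 1.0):
        raise ValueError("hyperspot fraction must be in (0, 1]")
    m = int(round(fraction * n))
    if m < 2:
        raise ValueError(f"round(fraction*n) = {m} hyperspots; need at least 2")
    if m > n:
        raise ValueError("more hyperspots than spots")
    if m == n:
        return HyperspotPartition(
            assignment=np.arange(n),
            m=n,
            centroid_coords=coords.copy(),
            member_counts=np.ones(n, dtype=np.intp),
        )
    km = KMeans(n_clusters=m, random_state=int(seed) % (2**32), n_init=10)
    labels = km.fit_predict(coords)
    counts = np.bincount(labels, minlength=m)
    # sklearn's k-means does not leave clusters empty, but repair defensively:
    # reassign the farthest member of the largest cluster to any empty one.
    while (counts == 0).any():
        empty = int(np.flatnonzero(counts == 0)[0])
        big = int(counts.argmax())
        members = np.flatnonzero(labels == big)
        far = members[
            np.argmax(((coords[members] - km.cluster_centers_[big]) ** 2).sum(axis=1))
        ]
        labels[far] = empty
        counts = np.bincount(labels, minlength=m)
    centroids = np.vstack(
        [coords[labels == g].mean(axis=0) for g in range(m)]
    )
    return HyperspotPartition(
        assignment=labels, m=m, centroid_coords=centroids,
        member_counts=counts.astype(np.intp),
    )


def aggregation_matrix(part: HyperspotPartition) -> np.ndarray:
    """m×n averaging matrix P with P[g, i] = 1/|g| for spot i in hyperspot g."""
    p = np.zeros((part.m, part.n), dtype=np.float64)
    p[part.assignment, np.arange(part.n)] = 1.0 / part.member_counts[part.assignment]
    return p


def t_aggregate(h: Tensor, part: HyperspotPartition,
                agg: np.ndarray | None = None) -> Tensor:
    """Differentiable hyperspot averaging; identity partitions pass through."""
    if part.is_identity:
        return h
    if agg is None:
        agg = aggregation_matrix(part)
    return astensor(agg) @ h


def aggregate_embeddings(h: np.ndarray, part: HyperspotPartition) -> np.ndarray:
    """Row g = mean embedding over the spots assigned to hyperspot g."""
    h = np.asarray(h, dtype=np.float64)
    if h.shape[0] != part.n:
        raise ValueError("embedding rows do not match the partition size")
    if part.is_identity:
        return h.copy()
    return aggregation_matrix(part) @ h


def coarse_losses(h1_hyper: np.ndarray, h2_hyper: np.ndarray,
                  centroid_sqdist1: np.ndarray, centroid_sqdist2: np.ndarray,
                  attn_proj: np.ndarray, sinkhorn_iters: int = 200,
                  sinkhorn_tol: float = 1e-6, negative_logits: bool = False):
    """Hyperspot-level maintain/align/marginal losses and the coarse plan.

    Identical formulas to the full-resolution ones with (n1, n2) replaced by
    (m1, m2), embeddings by hyperspot means and distances by centroid
    distances.
    """
    c = attention_cost(h1_hyper, h2_hyper, attn_proj,
                       negative_logits=negative_logits)
    plan = sinkhorn_normalize(c, max_iters=sinkhorn_iters, tol=sinkhorn_tol)
    pi = astensor(plan.pi)
    maintain = float(t_maintain_loss(pi, astensor(centroid_sqdist1),
                                     astensor(centroid_sqdist2)).value)
    align = float(t_align_loss(pi, astensor(h1_hyper), astensor(h2_hyper)).value)
    marginal = float(t_marginal_penalty(pi).value)
    return maintain, align, marginal, plan


def full_resolution_plan(h1: np.ndarray, h2: np.ndarray, attn_proj: np.ndarray,
                         max_iters: int = 200, tol: float = 1e-6,
                         scale_sqrt_d: bool = False,
                         negative_logits: bool = False) -> TransportPlan:
    """Spot-level plan from a (coarsely) trained projection: full-resolution
    attention followed by Sinkhorn to uniform marginals."""
    c = attention_cost(h1, h2, attn_proj, scale_sqrt_d=scale_sqrt_d,
                       negative_logits=negative_logits)
    return sinkhorn_normalize(c, max_iters=max_iters, tol=tol)
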