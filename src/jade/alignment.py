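"""Attention-parameterised transport plans and the alignment-side losses.

The cross-slice similarity is a learned bilinear form: with projection M,
logits L = (H1 M)(H2 M)ᵀ / d and C = row-softmax(L), a row-stochastic
attention map (a ``negative_logits`` switch provides the negated, cost-style
orientation of the same form). Sinkhorn-Knopp rescaling then balances C into a transport
plan Π with uniform marginals (rows 1/n1, columns 1/n2). Three losses act on
the plan:

* ``marginal_penalty`` — KL divergence of the column sums from uniform,
  compensating for a truncated Sinkhorn during training;
* ``maintain_loss`` — a fused-Gromov-Wasserstein-style discrepancy between
  each slice's squared-distance matrix and its transported counterpart;
* ``align_loss`` — discrepancy between each slice's embeddings and the
  plan-transported embeddings of the other slice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tensor import Tensor, astensor

__all__ = [
    "AttentionMap",
    "TransportPlan",
    "attention_cost",
    "sinkhorn_normalize",
    "marginal_penalty",
    "maintain_loss",
    "align_loss",
]

MASS_FLOOR = 1e-30  # entries clamped here before any division


@dataclass
class AttentionMap:
    """Row-stochastic similarity matrix C ∈ [0,1]^{n1×n2}."""

    c: np.ndarray

    def __post_init__(self):
        self.c = np.asarray(self.c, dtype=np.float64)
        if not np.isfinite(self.c).all():
            raise ValueError("non-finite attention values")
        rows = self.c.sum(axis=1)
        if np.abs(rows - 1.0).max() > 1e-6:
            raise ValueError("attention rows must sum to 1")


@dataclass
class TransportPlan:
    """Balanced plan Π with total mass 1; rows target 1/n1, columns 1/n2."""

    pi: np.ndarray
    converged: bool = True
    marginal_err: float = 0.0

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=np.float64)

    @property
    def n1(self) -> int:
        return self.pi.shape[0]

    @property
    def n2(self) -> int:
        return self.pi.shape[1]


# -- differentiable cores ----------------------------------------------------

def t_attention_logits(h1: Tensor, h2: Tensor, attn_proj: Tensor,
                       scale_sqrt_d: bool = False,
                       negative_logits: bool = False) -> Tensor:
    # Similarity logits (H1 M)(H2 M)ᵀ / d: high attention between embeddings
    # that agree under the learned projection. ``negative_logits`` negates
    # them, turning the bilinear form into a transport cost; with a PSD form
    # MMᵀ that variant cannot place its row maxima on mutually similar pairs
    # (see the methods note), so the similarity orientation is the default.
    d = h1.shape[1]
    scale = float(np.sqrt(d)) if scale_sqrt_d else float(d)
    logits = ((h1 @ attn_proj) @ (h2 @ attn_proj).T) / scale
    return -logits if negative_logits else logits


def t_attention_map(h1: Tensor, h2: Tensor, attn_proj: Tensor,
                    scale_sqrt_d: bool = False,
                    negative_logits: bool = False) -> Tensor:
    return t_attention_logits(h1, h2, attn_proj, scale_sqrt_d,
                              negative_logits).softmax_rows()


def t_sinkhorn(c: Tensor, n_iters: int) -> Tensor:
    """Fixed-iteration Sinkhorn (row target 1/n1, column target 1/n2).

    A fixed iteration count keeps the operation smooth in C so gradients flow
    to the attention projection during training.
    """
    n1, n2 = c.shape
    pi = c / float(n1)  # rows of C sum to 1 -> rows now sum to 1/n1
    for _ in range(n_iters):
        col = pi.sum(axis=0, keepdims=True).clip(MASS_FLOOR, np.inf)
        pi = pi / col / float(n2)
        row = pi.sum(axis=1, keepdims=True).clip(MASS_FLOOR, np.inf)
        pi = pi / row / float(n1)
    return pi


def t_marginal_penalty(pi: Tensor) -> Tensor:
    n2 = pi.shape[1]
    col = pi.sum(axis=0).clip(MASS_FLOOR, np.inf)
    return (col * (col * float(n2)).log()).sum()


def t_maintain_loss(pi: Tensor, d1: Tensor, d2: Tensor) -> Tensor:
    n1, n2 = pi.shape
    t1 = d1 - float(n2) ** 2 * ((pi @ d2) @ pi.T)
    t2 = d2 - float(n1) ** 2 * ((pi.T @ d1) @ pi)
    return t1.frobenius() / float(n1) + t2.frobenius() / float(n2)


def t_align_loss(pi: Tensor, h1: Tensor, h2: Tensor) -> Tensor:
    n1, n2 = pi.shape
    t1 = h1 - float(n2) * (pi @ h2)
    t2 = h2 - float(n1) * (pi.T @ h1)
    return t1.frobenius() / float(n1) + t2.frobenius() / float(n2)


# -- public numpy-facing operations -----------------------------------------

def attention_cost(h1: np.ndarray, h2: np.ndarray, attn_proj: np.ndarray,
                   scale_sqrt_d: bool = False,
                   negative_logits: bool = False) -> AttentionMap:
    """Row-softmax of (H1 M)(H2 M)ᵀ/d (or /√d with ``scale_sqrt_d``).

    ``negative_logits=True`` negates the bilinear form before the softmax
    (the cost-matrix orientation).
    """
    h1, h2, m = map(lambda a: np.asarray(a, dtype=np.float64), (h1, h2, attn_proj))
    if h1.shape[1] != h2.shape[1] or m.shape != (h1.shape[1], h1.shape[1]):
        raise ValueError("latent dimensions of h1, h2 and attn_proj must agree")
    if not (np.isfinite(h1).all() and np.isfinite(h2).all() and np.isfinite(m).all()):
        raise ValueError("non-finite inputs to attention_cost")
    return AttentionMap(
        t_attention_map(astensor(h1), astensor(h2), astensor(m), scale_sqrt_d,
                        negative_logits).value
    )


def sinkhorn_normalize(c: AttentionMap | np.ndarray, max_iters: int = 200,
                       tol: float = 1e-6) -> TransportPlan:
    """Alternate row/column rescaling until the marginals are uniform.

    Stops when the maximum absolute deviation of row sums from 1/n1 and
    column sums from 1/n2 drops below ``tol``, or after ``max_iters`` sweeps.
    """
    mat = np.asarray(getattr(c, "c", c), dtype=np.float64)
    if (mat <= 0).any():
        raise ValueError("Sinkhorn requires strictly positive input entries")
    n1, n2 = mat.shape
    pi = mat / mat.sum()
    err = np.inf
    converged = False
    for _ in range(max_iters):
        rows = np.maximum(pi.sum(axis=1, keepdims=True), MASS_FLOOR)
        pi = pi / rows / n1
        cols = np.maximum(pi.sum(axis=0, keepdims=True), MASS_FLOOR)
        pi = pi / cols / n2
        err = max(
            np.abs(pi.sum(axis=1) - 1.0 / n1).max(),
            np.abs(pi.sum(axis=0) - 1.0 / n2).max(),
        )
        if err < tol:
            converged = True
            break
    return TransportPlan(pi=pi, converged=converged, marginal_err=float(err))


def marginal_penalty(plan: TransportPlan | np.ndarray) -> float:
    """KL(column sums ‖ uniform 1/n2), with 0·log 0 = 0."""
    pi = np.asarray(getattr(plan, "pi", plan), dtype=np.float64)
    col = pi.sum(axis=0)
    if (col < -1e-12).any():
        raise ValueError("negative column sum in transport plan")
    n2 = pi.shape[1]
    pos = col > 0
    return float(np.sum(col[pos] * np.log(col[pos] * n2)))


def maintain_loss(plan: TransportPlan | np.ndarray, sqdist1: np.ndarray,
                  sqdist2: np.ndarray) -> float:
    """(1/n1)‖D1 − n2²·Π D2 Πᵀ‖_F + (1/n2)‖D2 − n1²·Πᵀ D1 Π‖_F."""
    pi = np.asarray(getattr(plan, "pi", plan), dtype=np.float64)
    d1 = np.asarray(sqdist1, dtype=np.float64)
    d2 = np.asarray(sqdist2, dtype=np.float64)
    if d1.shape != (pi.shape[0],) * 2 or d2.shape != (pi.shape[1],) * 2:
        raise ValueError("distance matrix shapes do not match the plan")
    return float(t_maintain_loss(astensor(pi), astensor(d1), astensor(d2)).value)


def align_loss(plan: TransportPlan | np.ndarray, h1: np.ndarray,
               h2: np.ndarray) -> float:
    """(1/n1)‖H1 − n2·Π H2‖_F + (1/n2)‖H2 − n1·Πᵀ H1‖_F."""
    pi = np.asarray(getattr(plan, "pi", plan), dtype=np.float64)
    h1 = np.asarray(h1, dtype=np.float64)
    h2 = np.asarray(h2, dtype=np.float64)
    if h1.shape[0] != pi.shape[0] or h2.shape[0] != pi.shape[1] or h1.shape[1] != h2.shape[1]:
        raise ValueError("embedding shapes do not match the plan")
    return float(t_align_loss(astensor(pi), astensor(h1), astensor(h2)).value)
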