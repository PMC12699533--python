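"""Trainable networks: GCN encoder/decoder pairs and the contrastive objective.

Each slice has its own one-layer graph-convolutional encoder
H = ReLU(Ã X W_e + b_e) and decoder X̂ = ReLU(Ã H W_d + b_d). Embeddings are
additionally shaped by a Deep-Graph-Infomax-style contrastive loss: for each
spot the mean embedding of its graph neighbors is a positive "local proxy",
a row-shuffled copy of the embedding matrix provides negatives, and a
bilinear sigmoid discriminator Φ(h, r) = σ(hᵀ W_Φ r) is trained to tell the
two apart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tensor import Tensor, astensor

__all__ = [
    "EmbeddingPair",
    "ModelParams",
    "init_params",
    "gcn_encode",
    "gcn_decode",
    "reconstruction_loss",
    "neighborhood_proxy",
    "neighbor_mean_matrix",
    "shuffle_negatives",
    "contrastive_loss",
]

SCORE_EPS = 1e-7  # discriminator probabilities clamped to (eps, 1-eps)


@dataclass
class EmbeddingPair:
    """Final latent embeddings of the two slices (n1×d and n2×d)."""

    h1: np.ndarray
    h2: np.ndarray

    def __post_init__(self):
        self.h1 = np.asarray(self.h1, dtype=np.float64)
        self.h2 = np.asarray(self.h2, dtype=np.float64)
        if self.h1.shape[1] != self.h2.shape[1]:
            raise ValueError("embeddings must share the latent dimension")
        if not (np.isfinite(self.h1).all() and np.isfinite(self.h2).all()):
            raise ValueError("non-finite embeddings")

    @property
    def d(self) -> int:
        return self.h1.shape[1]


@dataclass
class ModelParams:
    """All trainable arrays for a slice pair.

    Encoder weights are p×d, decoder weights d×p; ``attn_proj`` is the d×d
    attention projection shared by both slices and ``disc_weight`` the d×d
    bilinear discriminator.
    """

    enc_weight_1: np.ndarray
    enc_bias_1: np.ndarray
    enc_weight_2: np.ndarray
    enc_bias_2: np.ndarray
    dec_weight_1: np.ndarray
    dec_bias_1: np.ndarray
    dec_weight_2: np.ndarray
    dec_bias_2: np.ndarray
    attn_proj: np.ndarray
    disc_weight: np.ndarray

    @property
    def d(self) -> int:
        return self.enc_weight_1.shape[1]

    @property
    def p(self) -> int:
        return self.enc_weight_1.shape[0]


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


def init_params(p: int, d: int, rng: np.random.Generator,
                share_decoder: bool = True) -> ModelParams:
    """Glorot-uniform weights, zero biases, identity-plus-noise attention.

    The two per-slice encoders receive the *same* initial draw (they are
    trained separately afterwards): starting from a common latent gauge lets
    the reconstruction and alignment losses keep the two latent spaces
    comparable instead of having to bridge two unrelated random bases.
    ``share_decoder=True`` (default) ties slice 2's decoder to slice 1's, so
    both slices must occupy one latent space to reconstruct well — this is
    the cross-slice coupling that makes batch mixing possible.
    """
    w_e = _glorot(rng, p, d)
    w1d = _glorot(rng, d, p)
    w2d = w1d if share_decoder else _glorot(rng, d, p)
    attn = np.eye(d) + 0.01 * rng.standard_normal((d, d))
    disc = _glorot(rng, d, d)
    return ModelParams(
        enc_weight_1=w_e, enc_bias_1=np.zeros(d),
        enc_weight_2=w_e.copy(), enc_bias_2=np.zeros(d),
        dec_weight_1=w1d, dec_bias_1=np.zeros(p),
        dec_weight_2=w2d.copy() if share_decoder else w2d, dec_bias_2=np.zeros(p),
        attn_proj=attn, disc_weight=disc,
    )


# -- differentiable cores (Tensor in, Tensor out) ---------------------------

def t_gcn_layer(x: Tensor, norm_adj: Tensor, w: Tensor, b: Tensor) -> Tensor:
    return ((norm_adj @ x) @ w + b).relu()


def t_reconstruction_loss(x1: Tensor, xhat1: Tensor, x2: Tensor, xhat2: Tensor) -> Tensor:
    r1 = x1 - xhat1
    r2 = x2 - xhat2
    n1, n2 = x1.shape[0], x2.shape[0]
    return (r1 * r1).sum() / float(n1) + (r2 * r2).sum() / float(n2)


def t_contrastive_loss(h: Tensor, proxies: Tensor, h_neg: Tensor,
                       proxies_neg: Tensor, disc_weight: Tensor) -> Tensor:
    pos = ((h @ disc_weight) * proxies).sum(axis=1).sigmoid().clip(SCORE_EPS, 1 - SCORE_EPS)
    neg = ((h_neg @ disc_weight) * proxies_neg).sum(axis=1).sigmoid().clip(SCORE_EPS, 1 - SCORE_EPS)
    return -(pos.log() + (1.0 - neg).log()).mean()


# -- public numpy-facing operations -----------------------------------------

def gcn_encode(x: np.ndarray, norm_adj: np.ndarray, w: np.ndarray,
               b: np.ndarray) -> np.ndarray:
    """One GCN layer: ReLU(Ã X W + b)."""
    for name, arr in (("x", x), ("norm_adj", norm_adj), ("w", w), ("b", b)):
        if not np.isfinite(np.asarray(arr)).all():
            raise ValueError(f"non-finite values in {name}")
    return t_gcn_layer(astensor(x), astensor(norm_adj), astensor(w), astensor(b)).value


def gcn_decode(h: np.ndarray, norm_adj: np.ndarray, w: np.ndarray,
               b: np.ndarray) -> np.ndarray:
    """Decoder layer, same form as the encoder: ReLU(Ã H W + b)."""
    return gcn_encode(h, norm_adj, w, b)


def reconstruction_loss(x1, xhat1, x2, xhat2) -> float:
    """(1/n1)‖X1 − X̂1‖_F² + (1/n2)‖X2 − X̂2‖_F²."""
    x1, xhat1, x2, xhat2 = map(np.asarray, (x1, xhat1, x2, xhat2))
    if x1.shape != xhat1.shape or x2.shape != xhat2.shape:
        raise ValueError("reconstruction shapes do not match originals")
    return float(
        t_reconstruction_loss(*map(astensor, (x1, xhat1, x2, xhat2))).value
    )


def neighbor_mean_matrix(neighbor_sets: list, n: int) -> np.ndarray:
    """Row-stochastic averaging matrix P with P[i, j] = 1/|N(i)| for j ∈ N(i).

    The local proxy of the contrastive loss is then r = P H; i itself is
    excluded from N(i).
    """
    p = np.zeros((n, n), dtype=np.float64)
    for i, nbrs in enumerate(neighbor_sets):
        nbrs = np.asarray(nbrs)
        if nbrs.size == 0:
            raise ValueError(f"spot {i} has no graph neighbors")
        p[i, nbrs] = 1.0 / nbrs.size
    return p


def neighborhood_proxy(h: np.ndarray, neighbor_sets: list) -> np.ndarray:
    """Row i = mean of h over the graph neighbors of spot i."""
    h = np.asarray(h, dtype=np.float64)
    return neighbor_mean_matrix(neighbor_sets, h.shape[0]) @ h


def shuffle_negatives(h: np.ndarray, rng_seed: int) -> np.ndarray:
    """Row-permuted copy of h (uniform permutation, deterministic per seed)."""
    h = np.asarray(h)
    if h.shape[0] < 2:
        raise ValueError("need at least 2 rows to shuffle")
    perm = np.random.default_rng(rng_seed).permutation(h.shape[0])
    return h[perm]


def contrastive_loss(h, proxies, h_neg, proxies_neg, disc_weight) -> float:
    """Per-slice Graph-Infomax BCE loss.

    −(1/n) Σ_i [log σ(h_iᵀ W_Φ r_i) + log(1 − σ(h'_iᵀ W_Φ r'_i))], with
    probabilities clamped away from 0 and 1.
    """
    return float(
        t_contrastive_loss(*map(astensor, (h, proxies, h_neg, proxies_neg, disc_weight))).value
    )
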