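"""The roundtrip optimisation loop.

Each epoch alternates two phases over the full pair of slices:

* **Phase E (embedding refinement)** — with the transport plan held fixed,
  the encoders, decoders and contrastive discriminator are updated on
  L_SCL + λ2·L_recon + λ4·L_align.
* **Phase A (alignment refinement)** — with the embeddings held fixed, the
  attention map and a truncated Sinkhorn plan are recomputed and the
  attention projection M is updated on λ3·L_maintain + λ4·L_align +
  λ5·L_marginal.

The weight λ3 of the structure-preservation loss can be selected from the
data: slices whose pseudo-bulk expression profiles correlate strongly get a
larger λ3 (more information sharing), dissimilar slices a smaller one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from ._tensor import Adam, Tensor, astensor
from .alignment import (
    TransportPlan,
    t_align_loss,
    t_attention_map,
    t_maintain_loss,
    t_marginal_penalty,
    t_sinkhorn,
)
from .fast import (
    DEFAULT_FRACTION,
    HyperspotPartition,
    build_hyperspots,
    full_resolution_plan,
    t_aggregate,
)
from .io import SliceData
from .model import (
    EmbeddingPair,
    ModelParams,
    init_params,
    neighbor_mean_matrix,
    t_contrastive_loss,
    t_gcn_layer,
    t_reconstruction_loss,
)
from .preprocess import build_spatial_graph, pairwise_sqdist

__all__ = [
    "LossWeights",
    "TrainConfig",
    "JadeResult",
    "select_lambda3",
    "total_loss",
    "train_jade",
]

LOSS_NAMES = ("scl", "recon", "maintain", "align", "marginal")


@dataclass
class LossWeights:
    """Weights of the five-term objective; the contrastive term is fixed at 1."""

    lambda2: float = 10.0
    lambda3: float = 1.0
    lambda4: float = 0.1
    lambda5: float = 1.0

    def __post_init__(self):
        for name in ("lambda2", "lambda3", "lambda4", "lambda5"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class TrainConfig:
    epochs: int = 500
    learning_rate: float = 1e-3
    seed: int = 0
    sinkhorn_train_iters: int = 5
    sinkhorn_eval_iters: int = 200
    sinkhorn_tol: float = 1e-6
    k_neighbors: int = 6
    latent_dim: int = 32
    fast: bool = False
    hyperspot_fraction: float = DEFAULT_FRACTION
    early_stop_patience: int = 50
    early_stop_tol: float = 1e-9
    joint_backprop: bool = False
    share_decoder: bool = True
    scale_sqrt_d: bool = False
    negative_logits: bool = False
    sqdist_mean_normalize: bool = True
    device: str = "cpu"  # informational; the implementation is CPU numpy

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class JadeResult:
    """Everything a run produces: embeddings, plan, history and parameters."""

    embeddings: EmbeddingPair
    plan: TransportPlan
    loss_history: pd.DataFrame
    weights: LossWeights
    seed: int
    params: ModelParams
    partitions: Optional[tuple[HyperspotPartition, HyperspotPartition]] = None


def select_lambda3(x1: np.ndarray, x2: np.ndarray) -> float:
    """Data-driven λ3 ∈ [0.2, 2.0] from inter-slice similarity.

    Similarity is the Pearson correlation ρ of the two slices' gene-wise
    mean-expression (pseudo-bulk) vectors; λ3 = 0.2 + 1.8·max(ρ, 0), so
    identical slices get the full weight 2.0 and unrelated slices the floor
    0.2 (guarding against negative transfer).
    """
    x1 = np.asarray(x1, dtype=np.float64)
    x2 = np.asarray(x2, dtype=np.float64)
    if x1.shape[1] != x2.shape[1]:
        raise ValueError("slices must share a gene panel")
    b1 = x1.mean(axis=0)
    b2 = x2.mean(axis=0)
    if b1.std() == 0 or b2.std() == 0:
        warnings.warn("zero-variance pseudo-bulk; falling back to lambda3 = 0.2")
        return 0.2
    rho = float(np.corrcoef(b1, b2)[0, 1])
    return 0.2 + 1.8 * max(rho, 0.0)


def total_loss(scl: float, recon: float, maintain: float, align: float,
               marginal: float, w: LossWeights) -> float:
    """L_SCL + λ2·L_recon + λ3·L_maintain + λ4·L_align + λ5·L_marginal."""
    comps = dict(zip(LOSS_NAMES, (scl, recon, maintain, align, marginal)))
    for name, val in comps.items():
        if not np.isfinite(val):
            raise FloatingPointError(f"non-finite loss component: {name} = {val}")
    return (
        comps["scl"]
        + w.lambda2 * comps["recon"]
        + w.lambda3 * comps["maintain"]
        + w.lambda4 * comps["align"]
        + w.lambda5 * comps["marginal"]
    )


def _np_gcn(x: np.ndarray, norm_adj: np.ndarray, w: np.ndarray,
            b: np.ndarray) -> np.ndarray:
    return np.maximum(norm_adj @ x @ w + b, 0.0)


class _TrainState:
    """Parameter tensors plus the fixed per-slice constants of a run."""

    def __init__(self, a: SliceData, b: SliceData, cfg: TrainConfig,
                 rng_init: np.random.Generator, hyper_seeds):
        self.x1 = astensor(a.expr)
        self.x2 = astensor(b.expr)
        g1 = build_spatial_graph(a.coords, cfg.k_neighbors,
                                 mean_normalize_sqdist=cfg.sqdist_mean_normalize)
        g2 = build_spatial_graph(b.coords, cfg.k_neighbors,
                                 mean_normalize_sqdist=cfg.sqdist_mean_normalize)
        self.a1 = astensor(g1.norm_adj)
        self.a2 = astensor(g2.norm_adj)
        self.p1 = astensor(neighbor_mean_matrix(g1.neighbor_sets, a.n))
        self.p2 = astensor(neighbor_mean_matrix(g2.neighbor_sets, b.n))
        init = init_params(a.p, cfg.latent_dim, rng_init,
                           share_decoder=cfg.share_decoder)
        self.t = {
            name: Tensor(getattr(init, name), requires_grad=True)
            for name in (
                "enc_weight_1", "enc_bias_1", "enc_weight_2", "enc_bias_2",
                "dec_weight_1", "dec_bias_1", "dec_weight_2", "dec_bias_2",
                "attn_proj", "disc_weight",
            )
        }
        if cfg.share_decoder:
            self.t["dec_weight_2"] = self.t["dec_weight_1"]
            self.t["dec_bias_2"] = self.t["dec_bias_1"]
        if cfg.fast:
            self.part1 = build_hyperspots(a.coords, cfg.hyperspot_fraction,
                                          seed=hyper_seeds[0])
            self.part2 = build_hyperspots(b.coords, cfg.hyperspot_fraction,
                                          seed=hyper_seeds[1])
            # with identity partitions, reuse the spot-level matrices so the
            # coarse path is bitwise the full-resolution one
            self.d1 = astensor(
                g1.sqdist if self.part1.is_identity else pairwise_sqdist(
                    self.part1.centroid_coords, cfg.sqdist_mean_normalize)
            )
            self.d2 = astensor(
                g2.sqdist if self.part2.is_identity else pairwise_sqdist(
                    self.part2.centroid_coords, cfg.sqdist_mean_normalize)
            )
        else:
            self.part1 = self.part2 = None
            self.d1 = astensor(g1.sqdist)
            self.d2 = astensor(g2.sqdist)

    def embed_params(self) -> list[Tensor]:
        names = ["enc_weight_1", "enc_bias_1", "enc_weight_2", "enc_bias_2",
                 "dec_weight_1", "dec_bias_1", "disc_weight"]
        if self.t["dec_weight_2"] is not self.t["dec_weight_1"]:
            names += ["dec_weight_2", "dec_bias_2"]
        return [self.t[n] for n in names]

    def final_params(self) -> ModelParams:
        return ModelParams(**{name: t.value.copy() for name, t in self.t.items()})

    def encode(self, as_tensor: bool = True):
        h1 = t_gcn_layer(self.x1, self.a1, self.t["enc_weight_1"], self.t["enc_bias_1"])
        h2 = t_gcn_layer(self.x2, self.a2, self.t["enc_weight_2"], self.t["enc_bias_2"])
        return (h1, h2) if as_tensor else (h1.value, h2.value)


def _phase_losses(state: _TrainState, cfg: TrainConfig, h1: Tensor, h2: Tensor,
                  perm1: np.ndarray, perm2: np.ndarray, plan_fixed: np.ndarray):
    """Embedding-side losses (contrastive, reconstruction, align-to-plan)."""
    xhat1 = t_gcn_layer(h1, state.a1, state.t["dec_weight_1"], state.t["dec_bias_1"])
    xhat2 = t_gcn_layer(h2, state.a2, state.t["dec_weight_2"], state.t["dec_bias_2"])
    recon = t_reconstruction_loss(state.x1, xhat1, state.x2, xhat2)

    scl = Tensor(0.0)
    for h, pmat, perm in ((h1, state.p1, perm1), (h2, state.p2, perm2)):
        prox = pmat @ h
        h_neg = h.gather_rows(perm)
        prox_neg = pmat @ h_neg
        scl = scl + t_contrastive_loss(h, prox, h_neg, prox_neg,
                                       state.t["disc_weight"])

    h1a = t_aggregate(h1, state.part1) if cfg.fast else h1
    h2a = t_aggregate(h2, state.part2) if cfg.fast else h2
    align = t_align_loss(astensor(plan_fixed), h1a, h2a)
    return scl, recon, align, (h1a, h2a)


def _alignment_losses(state: _TrainState, cfg: TrainConfig, h1a: Tensor, h2a: Tensor):
    """Plan-side losses through a truncated, differentiable Sinkhorn."""
    c = t_attention_map(h1a, h2a, state.t["attn_proj"],
                        scale_sqrt_d=cfg.scale_sqrt_d,
                        negative_logits=cfg.negative_logits)
    pi = t_sinkhorn(c, cfg.sinkhorn_train_iters)
    maintain = t_maintain_loss(pi, state.d1, state.d2)
    align = t_align_loss(pi, h1a, h2a)
    marginal = t_marginal_penalty(pi)
    return maintain, align, marginal, pi


def train_jade(a: SliceData, b: SliceData, cfg: Optional[TrainConfig] = None,
               weights: Union[LossWeights, str, None] = "auto") -> JadeResult:
    """Run the roundtrip loop on a preprocessed slice pair.

    ``weights='auto'`` uses the default λ2/λ4/λ5 and the data-driven λ3.
    Everything is deterministic given ``cfg.seed``. Raises
    ``FloatingPointError`` (with the epoch and component values) if the
    objective diverges.
    """
    cfg = cfg or TrainConfig()
    if a.p != b.p or a.gene_ids != b.gene_ids:
        raise ValueError("slices must be preprocessed to a shared gene panel")
    if weights is None or (isinstance(weights, str) and weights == "auto"):
        weights = LossWeights(lambda3=select_lambda3(a.expr, b.expr))
    elif isinstance(weights, str):
        raise ValueError(f"unknown weights spec: {weights!r}")

    ss = np.random.SeedSequence(cfg.seed)
    s_init, s_perm, s_h1, s_h2 = ss.spawn(4)
    rng_init = np.random.default_rng(s_init)
    rng_perm = np.random.default_rng(s_perm)
    hyper_seeds = (
        int(s_h1.generate_state(1)[0] % (2**31)),
        int(s_h2.generate_state(1)[0] % (2**31)),
    )

    state = _TrainState(a, b, cfg, rng_init, hyper_seeds)
    m1 = state.part1.m if cfg.fast else a.n
    m2 = state.part2.m if cfg.fast else b.n
    plan_fixed = np.full((m1, m2), 1.0 / (m1 * m2))

    opt_embed = Adam(state.embed_params(), lr=cfg.learning_rate)
    opt_attn = Adam([state.t["attn_proj"]], lr=cfg.learning_rate)
    opt_joint = Adam(state.embed_params() + [state.t["attn_proj"]],
                     lr=cfg.learning_rate) if cfg.joint_backprop else None

    history = []
    best = np.inf
    stale = 0
    for epoch in range(cfg.epochs):
        perm1 = rng_perm.permutation(a.n)
        perm2 = rng_perm.permutation(b.n)

        if cfg.joint_backprop:
            h1, h2 = state.encode()
            scl, recon, _, (h1a, h2a) = _phase_losses(
                state, cfg, h1, h2, perm1, perm2, plan_fixed)
            maintain, align, marginal, pi = _alignment_losses(state, cfg, h1a, h2a)
            loss = (scl + weights.lambda2 * recon + weights.lambda3 * maintain
                    + weights.lambda4 * align + weights.lambda5 * marginal)
            opt_joint.zero_grad()
            loss.backward()
            opt_joint.step()
            plan_fixed = pi.value.copy()
            # the marginal KL is >= 0 mathematically; clamp float round-off
            row = (scl.item(), recon.item(), maintain.item(), align.item(),
                   max(marginal.item(), 0.0))
        else:
            # phase E: refine embeddings against the fixed plan
            h1, h2 = state.encode()
            scl, recon, align_e, _ = _phase_losses(
                state, cfg, h1, h2, perm1, perm2, plan_fixed)
            loss_e = scl + weights.lambda2 * recon + weights.lambda4 * align_e
            opt_embed.zero_grad()
            loss_e.backward()
            opt_embed.step()

            # phase A: refine the plan with embeddings frozen
            h1v, h2v = state.encode(as_tensor=False)
            if cfg.fast:
                h1v = t_aggregate(astensor(h1v), state.part1).value
                h2v = t_aggregate(astensor(h2v), state.part2).value
            maintain, align_a, marginal, pi = _alignment_losses(
                state, cfg, astensor(h1v), astensor(h2v))
            loss_a = (weights.lambda3 * maintain + weights.lambda4 * align_a
                      + weights.lambda5 * marginal)
            opt_attn.zero_grad()
            loss_a.backward()
            opt_attn.step()
            plan_fixed = pi.value.copy()
            row = (scl.item(), recon.item(), maintain.item(), align_a.item(),
                   max(marginal.item(), 0.0))

        tot = total_loss(*row, weights)
        if not np.isfinite(tot):  # pragma: no cover - total_loss raises first
            raise FloatingPointError(f"diverged at epoch {epoch}: {row}")
        history.append((epoch, *row, tot))

        if tot < best - cfg.early_stop_tol:
            best = tot
            stale = 0
        else:
            stale += 1
            if stale >= cfg.early_stop_patience:
                break

    h1_final, h2_final = state.encode(as_tensor=False)
    plan = full_resolution_plan(
        h1_final, h2_final, state.t["attn_proj"].value,
        max_iters=cfg.sinkhorn_eval_iters, tol=cfg.sinkhorn_tol,
        scale_sqrt_d=cfg.scale_sqrt_d, negative_logits=cfg.negative_logits,
    )
    loss_history = pd.DataFrame(
        history, columns=["epoch", *LOSS_NAMES, "total"]
    )
    return JadeResult(
        embeddings=EmbeddingPair(h1=h1_final, h2=h2_final),
        plan=plan,
        loss_history=loss_history,
        weights=weights,
        seed=cfg.seed,
        params=state.final_params(),
        partitions=(state.part1, state.part2) if cfg.fast else None,
    )
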