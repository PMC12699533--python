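"""Evaluation and interpretation of embeddings and transport plans.

Covers the standard read-outs of a slice-pair integration: model-based
clustering of the embeddings into spatial domains, adjusted Rand index
against annotations, the integrated local inverse Simpson's index (iLISI)
for cross-slice mixing, argmax alignment accuracy of a transport plan, and
one-vs-rest marker-gene testing per detected domain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import adjusted_rand_score
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "DomainAssignment",
    "cluster_embeddings",
    "adjusted_rand_index",
    "ilisi_score",
    "alignment_accuracy",
    "marker_gene_test",
]


@dataclass
class DomainAssignment:
    labels: np.ndarray
    k: int
    responsibilities: Optional[np.ndarray] = None


def cluster_embeddings(h: np.ndarray, k: int, seed: int = 0,
                       covariance_type: str = "tied",
                       init_params: str = "kmeans") -> DomainAssignment:
    """Model-based clustering of L2-normalised embeddings.

    Rows of ``h`` are scaled to unit norm, then fit with a Gaussian mixture
    sharing one full covariance across components (the mclust "EEE" model;
    other sklearn covariance models selectable), k-means initialised. Hard
    labels are the maximum-responsibility components.
    """
    h = np.asarray(h, dtype=np.float64)
    n = h.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if n <= k:
        raise ValueError("need more points than clusters")
    norms = np.linalg.norm(h, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    u = h / norms
    for attempt in range(2):
        gm = GaussianMixture(
            n_components=k,
            covariance_type=covariance_type,
            init_params=init_params,
            n_init=3,
            reg_covar=1e-6,
            random_state=(int(seed) + attempt) % (2**32),
        )
        labels = gm.fit_predict(u)
        counts = np.bincount(labels, minlength=k)
        if (counts >= 2).all():
            return DomainAssignment(labels=labels, k=k,
                                    responsibilities=gm.predict_proba(u))
    raise RuntimeError("a mixture component collapsed to fewer than 2 points")


def adjusted_rand_index(a, b) -> float:
    """Chance-corrected partition agreement (permutation-model ARI)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape[0] != b.shape[0]:
        raise ValueError("label vectors must have equal length")
    return float(adjusted_rand_score(a, b))


def _perplexity_weights(dist: np.ndarray, perplexity: float,
                        n_steps: int = 64) -> np.ndarray:
    """Exponential kernel weights whose entropy is calibrated to
    log(perplexity) by a binary search over the bandwidth.

    As in the LISI reference implementations, the kernel acts on the plain
    (unsquared) neighbor distances.
    """
    target = np.log(perplexity)
    d0 = dist - dist.min()  # shift for numerical stability
    beta, beta_lo, beta_hi = 1.0, -np.inf, np.inf
    p = np.full(d0.shape, 1.0 / d0.size)
    for _ in range(n_steps):
        w = np.exp(-d0 * beta)
        p = w / w.sum()
        pos = p > 0
        ent = -(p[pos] * np.log(p[pos])).sum()
        diff = ent - target
        if abs(diff) < 1e-5:
            break
        if diff > 0:  # distribution too flat: sharpen
            beta_lo = beta
            beta = beta * 2 if np.isinf(beta_hi) else (beta + beta_hi) / 2
        else:
            beta_hi = beta
            beta = beta / 2 if np.isinf(beta_lo) else (beta + beta_lo) / 2
    return p


def ilisi_score(embeddings: np.ndarray, slice_ids, perplexity: float = 30.0) -> float:
    """Integrated local inverse Simpson's index of slice mixing.

    For each spot, its neighbors are weighted by a distance kernel calibrated
    to the given perplexity; the (bias-corrected) inverse Simpson's index of
    the slice-identity proportions is averaged over spots. For two slices the
    score lies in [1, 2]: 1 means fully separated, 2 perfectly mixed.
    """
    x = np.asarray(embeddings, dtype=np.float64)
    ids = np.asarray(slice_ids)
    n = x.shape[0]
    if ids.shape[0] != n:
        raise ValueError("slice_ids length must match embeddings")
    if np.unique(ids).size < 2:
        raise ValueError("need at least two slice identities")
    if n <= perplexity:
        raise ValueError("need more spots than the perplexity")
    k = int(min(n - 1, 3 * perplexity))
    nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
    dist, idx = nn.kneighbors(x)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self
    cats, codes = np.unique(ids, return_inverse=True)
    n_cats = cats.size
    scores = np.empty(n)
    for i in range(n):
        p = _perplexity_weights(dist[i], perplexity)
        props = np.bincount(codes[idx[i]], weights=p, minlength=n_cats)
        # bias-corrected Simpson index of the weighted neighbor sample: the
        # raw plug-in Σ props² overestimates concentration by the weight mass
        # Σ p² (a finite-effective-sample effect), so perfectly mixed data
        # would plateau below the nominal maximum; the corrected estimator
        # targets the population index exactly.
        w2 = float(np.sum(p**2))
        lam = (float(np.sum(props**2)) - w2) / (1.0 - w2)
        scores[i] = 1.0 / min(max(lam, 1.0 / n_cats), 1.0)
    return float(scores.mean())


def alignment_accuracy(plan, labels1, labels2, unaligned_threshold: float = 1.0,
                       unaligned_mode: str = "wrong"):
    """Fraction of spots whose argmax partner carries the same domain label.

    A slice-1 spot is "aligned" when its row-max mass is at least
    ``unaligned_threshold / (n1·n2)`` (i.e. the threshold is expressed in
    units of the uniform-plan mass). Unaligned spots either count as
    incorrect (``unaligned_mode='wrong'``, default) or are dropped from the
    denominator (``'exclude'``). Returns ``(accuracy, per_domain_table)``;
    the table lists correct/incorrect/unaligned counts and matched index
    lists per slice-1 domain.
    """
    pi = np.asarray(getattr(plan, "pi", plan), dtype=np.float64)
    l1 = np.asarray(labels1)
    l2 = np.asarray(labels2)
    n1, n2 = pi.shape
    if l1.shape[0] != n1 or l2.shape[0] != n2:
        raise ValueError("label vectors do not cover the plan dimensions")
    if unaligned_mode not in ("wrong", "exclude"):
        raise ValueError("unaligned_mode must be 'wrong' or 'exclude'")
    cutoff = unaligned_threshold / (n1 * n2)
    j_star = pi.argmax(axis=1)
    row_max = pi[np.arange(n1), j_star]
    aligned = row_max >= cutoff
    correct = aligned & (l1 == l2[j_star])

    rows = []
    for dom in pd.unique(l1):
        sel = l1 == dom
        rows.append(
            {
                "domain": dom,
                "n_spots": int(sel.sum()),
                "n_correct": int((correct & sel).sum()),
                "n_incorrect": int((aligned & ~correct & sel).sum()),
                "n_unaligned": int((~aligned & sel).sum()),
                "correct_pairs": [(int(i), int(j_star[i]))
                                  for i in np.flatnonzero(correct & sel)],
                "incorrect_pairs": [(int(i), int(j_star[i]))
                                    for i in np.flatnonzero(aligned & ~correct & sel)],
            }
        )
    table = pd.DataFrame(rows)
    if unaligned_mode == "exclude":
        denom = int(aligned.sum())
        acc = float(correct.sum() / denom) if denom else 0.0
    else:
        acc = float(correct.sum() / n1)
    return acc, table


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(pvals, method="fdr_bh")[1]


def marker_gene_test(expr: np.ndarray, labels, fdr: float = 0.05,
                     gene_ids: Optional[list] = None) -> dict[str, pd.DataFrame]:
    """One-vs-rest Wilcoxon rank-sum marker test per domain.

    For every domain and gene a two-sided rank-sum test compares in-domain
    against out-of-domain expression; p-values are BH-adjusted across genes
    within each domain. Returns, per domain, the genes passing ``fdr``
    ranked by effect size (difference of means). Constant genes get p = 1
    and are flagged in the full table.
    """
    x = np.asarray(expr, dtype=np.float64)
    labels = np.asarray(labels)
    n, p = x.shape
    if labels.shape[0] != n:
        raise ValueError("labels must cover all spots")
    doms, counts = np.unique(labels, return_counts=True)
    if doms.size < 2:
        raise ValueError("need at least 2 domains")
    if (counts < 3).any():
        raise ValueError("every domain needs at least 3 spots")
    gene_ids = gene_ids or [f"gene_{j}" for j in range(p)]

    # rank-based z-tests computed vectorised over genes (normal approximation
    # with tie correction; equivalent to scipy's default for these sizes)
    from scipy.stats import norm

    ranks = np.apply_along_axis(rankdata, 0, x)
    tie_term = np.empty(p)
    for j in range(p):
        _, tc = np.unique(x[:, j], return_counts=True)
        tie_term[j] = (tc**3 - tc).sum()

    out = {}
    for dom in doms:
        sel = labels == dom
        n1 = int(sel.sum())
        n2 = n - n1
        r1 = ranks[sel].sum(axis=0)
        u = r1 - n1 * (n1 + 1) / 2.0
        mu = n1 * n2 / 2.0
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        constant = sigma2 <= 0
        z = np.zeros(p)
        z[~constant] = (u[~constant] - mu) / np.sqrt(sigma2[~constant])
        pvals = np.where(constant, 1.0, 2 * norm.sf(np.abs(z)))
        padj = _bh_adjust(pvals)
        effect = x[sel].mean(axis=0) - x[~sel].mean(axis=0)
        table = pd.DataFrame(
            {
                "gene": gene_ids,
                "effect": effect,
                "pval": pvals,
                "padj": padj,
                "constant": constant,
            }
        )
        sig = table[(table.padj < fdr) & (table.effect > 0)].sort_values(
            "effect", ascending=False
        )
        out[str(dom)] = sig.reset_index(drop=True)
    return out
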