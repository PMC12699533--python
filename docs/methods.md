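# Methods

## Problem and model

A pair of SRT slices is modelled as two attributed spatial graphs. Spots are
nodes; edges connect each spot to its k nearest coordinate neighbors
(symmetrized, default k = 6 — the neighbor count of a hexagonal Visium
lattice). Expression enters after restriction to a shared panel of highly
variable genes, per-spot total normalisation (target 10⁴) and log1p. Unit
variance scaling is available but off by default: the decoder ends in a
ReLU, so reconstruction targets must stay nonnegative.

The method couples three ingredients.

**Graph autoencoder.** One-layer GCN encoders per slice,
H = ReLU(Ã X Wᵉ + bᵉ) with Ã = D^{-1/2}(A+I)D^{-1/2}, and a GCN decoder
ReLU(Ã H Wᵈ + bᵈ) whose weights are *shared between the two slices*
(`share_decoder=True`). Sharing the decoder is deliberate: it is the only
term of the objective strong enough (weight λ₂ = 10) to force the two
slices' embeddings into one latent space. With separate decoders each slice
settles into its own latent gauge and the clouds never mix — measured on
the synthetic pair, joint-cluster ARI drops from ≈0.93 to ≈0.17 and iLISI
collapses to 1.0. Self-loops are added before degree normalisation so
isolated spots are not annihilated; the literal no-self-loop formula is
available via `add_self_loops=False`.

Both encoders receive the same initial Glorot draw (they are trained
separately afterwards). Starting from a common gauge is what allows the
embedding spaces to remain comparable within a few hundred epochs; with
independent draws, the alignment loss — whose unsquared Frobenius norm has
a bounded gradient — cannot bridge two unrelated random bases in that time.

**Attention-based optimal transport.** Alignment logits are the learned
bilinear similarity (H₁M)(H₂M)ᵀ/d. A row-softmax gives the attention map C,
and Sinkhorn–Knopp rescaling balances it to a transport plan Π with uniform
marginals (row sums 1/n₁, column sums 1/n₂). During training Sinkhorn runs a
fixed small number of sweeps (default 5) so the plan stays smooth in M and
gradients flow through it; the marginal KL penalty compensates for the
truncation. At inference Sinkhorn runs to tolerance (200 sweeps, 1e-6).

A note on the sign of the logits. A negated variant
(`negative_logits=True`), which treats the bilinear form as a transport
cost, is provided but not the default, for a structural reason: Sinkhorn is
invariant to rank-1 row/column rescalings, so the negated kernel
exp(−uᵢ·vⱼ) is equivalent to exp(−‖uᵢ+vⱼ‖²/2) — it matches each projected
embedding uᵢ = Mᵀh₁ᵢ to the *negation* of vⱼ = Mᵀh₂ⱼ. Whenever matched
spots have similar embeddings (which every other loss encourages), a
positive-semidefinite bilinear cost can then never place the plan's row
maxima on the true matches (if G is a Gram matrix, G_kk < G_kl for all l
cannot hold for every k). Empirically the negated kernel converges either
to a mirror-image correspondence or to slice-separated latent spaces. The
positive orientation is the standard attention similarity and has no such
obstruction.

**Contrastive regularisation.** Per slice, a Deep-Graph-Infomax objective:
positive pairs (hᵢ, rᵢ) with rᵢ the mean embedding over graph neighbors
N(i) (excluding i), negatives from a uniformly drawn row permutation of H,
and a bilinear sigmoid discriminator σ(hᵀWᶲr). With a zero discriminator
the loss is exactly 2·log 2 per slice (chance level), a useful analytic
anchor for tests.

**Objective and roundtrip.** Total loss
L_SCL + λ₂L_recon + λ₃L_maintain + λ₄L_align + λ₅L_marginal with λ₂ = 10,
λ₄ = 0.1, λ₅ = 1. λ₃ is selected from the data: ρ = Pearson correlation of
the two pseudo-bulk (gene-wise mean) vectors, λ₃ = 0.2 + 1.8·max(ρ, 0) —
similar slices share more structural information, dissimilar slices are
protected from negative transfer. Each epoch alternates phase E (encoders,
decoder, discriminator updated on L_SCL + λ₂L_recon + λ₄L_align with Π
fixed) and phase A (M updated on λ₃L_maintain + λ₄L_align + λ₅L_marginal
through the truncated Sinkhorn). A single-backprop joint mode exists
(`joint_backprop=True`). Optimisation is full-batch Adam, lr 1e-3, default
500 epochs with early stop after a 50-epoch plateau of the total loss.
Everything — initialisation, negative-sampling permutations, k-means —
derives from one run seed, and runs are bitwise reproducible.

The maintain and align losses use unsquared Frobenius norms and the
scalings n₂²·ΠD₂Πᵀ (resp. n₁²·ΠᵀD₁Π) and n₂·ΠH₂ (resp. n₁·ΠᵀH₁), which
put the transported matrices on the scale of the originals under uniform
marginals. Squared distance matrices are normalised so their mean
off-diagonal entry is 1, making λ₃ platform- and unit-independent.

## Fast variant

K-means on spatial coordinates (coordinates only; including expression is
optional and off by default) groups each slice into m = round(fraction·n)
hyperspots, fraction default 0.15. Hyperspot embeddings are recomputed from
the current spot embeddings every forward pass, so encoder gradients flow
through the averaging. Attention, Sinkhorn and the maintain/align losses
run at m₁×m₂ during training; centroid distance matrices replace the spot
ones (same mean normalisation). After training, the learned M is applied
once at full resolution and Sinkhorn produces the spot-level plan. The
degenerate fraction 1.0 takes an explicit identity-partition shortcut, so
the coarse computation is literally the full-resolution one and the two
code paths agree bitwise — a strong regression anchor.

## Evaluation utilities

*Clustering* mimics the mclust-EEE protocol: embeddings are L2-normalised
row-wise, then fit with a Gaussian mixture sharing one full covariance
across components (k-means initialised, seeded).

*iLISI* measures cross-slice mixing: per spot, neighbors (3× perplexity,
default perplexity 30) are weighted by an exponential kernel whose entropy
is calibrated to log(perplexity); the inverse Simpson's index of the
slice-identity proportions is averaged over spots. The plug-in weighted
Simpson estimator is biased by the finite effective sample — for perfectly
mixed data it plateaus at 2(1−Σw²) ≈ 1.89 rather than 2 — so the standard
bias-corrected estimator λ̂ = (Σp̂² − Σw²)/(1 − Σw²) is used, clamped so
per-spot scores stay in [1, B]. Its expectation is the population index: 1
for separated slices, 2 for perfect two-slice mixing.

*Alignment accuracy* takes each slice-1 spot's argmax partner in Π;
correct means same domain label. Spots whose row maximum falls below
`threshold/(n₁n₂)` (default threshold 1, i.e. the uniform-plan mass) count
as unaligned; by default unaligned spots count as incorrect, and an
"exclude" mode drops them from the denominator instead. A per-domain table
with matched index pairs supports line-plot style visual QC.

*Markers* are one-vs-rest Wilcoxon rank-sum tests per gene and domain
(normal approximation with tie correction), BH-adjusted across genes within
a domain, ranked by difference of means among genes passing the FDR.

## Synthetic data

The generator emulates an adjacent-section pair. Slice 1: spots on a
jittered grid over a *tapered* (trapezoidal) footprint, partitioned into
domains (horizontal layers by default, also radial rings or random blobs);
expression counts are negative-binomial (gamma-Poisson, inverse size =
`noise`) around domain programs — a lognormal gene baseline times
exp(signal_strength) on a disjoint marker block per domain — thinned by
dropout. Slice 2: a `match_fraction` subsample of slice-1 spots, rotated
about the centroid plus a sinusoidal warp (per-axis displacement ≤ the warp
amplitude), expression redrawn from the same programs, multiplied by
per-gene lognormal batch factors (SD `batch_sd`), dropout applied, and
rounded back to integers. The correspondence and all deformation/batch
parameters are recorded as ground truth.

The taper matters: a mirror-symmetric footprint admits a reflection that is
an exact isometry of the distance matrices but reverses the layer order, so
no geometry-aware criterion can identify the true correspondence (measured:
the structure loss of the reflected coupling equals the true one on a
square, 0.70 vs 0.18 on the tapered footprint). Real sections are
irregular, so the asymmetric footprint is also the more realistic choice.

The "easy" preset (signal 2.0, dispersion 0.1, warp 0.05, batch SD 0.2,
dropout 0.05) is verified to be genuinely easy — nearest-centroid
classification on raw log-normalised counts recovers domains with
ARI > 0.9. The "hard" preset (signal 0.8, dispersion 0.6, warp 0.15, batch
SD 0.8, dropout 0.3, match fraction 0.8) exists for robustness testing.
What the generator does not emulate: platform-specific artifacts (tissue
tears, fiducials), spatially varying capture efficiency, partial overlaps
with non-rigid topology changes, or >2 slices. Passing tests on these data
show the estimator recovers planted structure under count noise, batch
effects and smooth deformation; they do not certify performance on real
tissue.

## Numerical choices

* Autodiff: a small reverse-mode tape over numpy (`jade._tensor`);
  gradients of every primitive and of the composed losses are checked
  against central finite differences in the test suite.
* Sinkhorn entries are clamped at 1e-30 before division; attention softmax
  is computed shifted; discriminator probabilities are clamped to
  (1e-7, 1−1e-7) before the logs.
* Frobenius norms use a guarded square-root subgradient at zero.
* kNN distance ties break by spot index (exact brute-force neighbors), so
  duplicate coordinates are legal and runs are deterministic.
* The recorded marginal KL is floored at 0 (it is nonnegative analytically;
  float round-off can produce −1e-18).
* Problem sizes: the shipped study conditions use 300 spots and 200 genes
  per slice and 300 epochs, which one CPU core trains in well under a
  minute; the hyperspot path has been exercised at fraction 0.10 of that
  size and scales as m₁·m₂ in the attention step.

## Known limitations

* Pairwise only; multi-slice joint alignment is out of scope.
* The λ₃ similarity rule (pseudo-bulk correlation) is a simple stand-in and
  is isolated in one function (`select_lambda3`) for easy replacement.
* The mclust-EEE analogue is a shared-covariance Gaussian mixture, not
  mclust proper; covariance model and initialisation are exposed knobs.
* Embedding mixing depends on slices sharing expression programs; strongly
  divergent biology (low pseudo-bulk correlation) reduces both λ₃ and the
  achievable iLISI by design.
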