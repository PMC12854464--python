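# Methods

## Model

snapdyn models a population of cells measured by destructive snapshots as an
interacting diffusion.  Each cell's latent expression state `x_t ∈ R^d`
follows a McKean–Vlasov SDE

    dx_t = f(x_t, ρ_t) dt + σ dW_t,          x_{t0} ~ ρ̂_{t0},

where `ρ_t` is the population law at time `t` and `σ ≥ 0` a constant
isotropic diffusion.  The drift decomposes into a non-interacting and an
interacting part,

    f(x, ρ) = f_intra(x) + f_inter(x, ρ),

with `f_intra` a two-layer MLP (d → 256 → d, leaky-rectifier activation)
acting on each cell independently, and `f_inter` a masked multi-head
cell-wise self-attention block in which every cell of the current batch is a
token.  Per head `h`, with `Q = X W_h^Q`, `K = X W_h^K`, `V = X W_h^V`,

    A_h = softmax( Q K^T / sqrt(d_k)  with the diagonal masked ),
    head_h = A_h V,

heads are concatenated and mixed by `W^O`, added to the input through a
residual connection, layer-normalized, and passed through a two-layer
feed-forward readout:

    f_inter(X) = FFN( LN( X + Concat(head_1 … head_H) W^O ) ).

`W^Q` and `W^K` are independent, so `A` is generally asymmetric: `A[i, j]`
is the directed influence of source cell `j` (key) on target cell `i`
(query).  The diagonal mask (applied pre-softmax, so rows renormalize over
peers; a post-softmax variant is config-exposed) removes self-influence from
the interaction term entirely — self-effects live in `f_intra` by
construction.  The empirical batch stands in for `ρ_t`, which is exact in
the mean-field sense as the batch grows.

Two deliberate architectural choices:

* **No second residual/LayerNorm after the FFN.**  A full post-norm encoder
  layer outputs `LN(Z + FFN(Z))`, which is O(1) even with all weights at
  zero.  We require instead that zeroing the FFN output layer makes
  `f_inter ≡ 0` exactly, so the model reduces *bitwise* to an ordinary
  single-particle Itô SDE — a testable contract that also gives a clean
  zero-drift initialization.
* **Zero-initialized output layers.**  Both `f_intra`'s and the FFN's final
  affine maps start at zero, so training starts from the identity flow and
  the action cost starts at exactly zero.

## Training objective

Parameters are fitted to snapshot marginals by a least-action principle
relaxed with entropic optimal transport:

    min_θ  E ∫ ||f_θ(x_t, ρ_t)||² dt  +  λ Σ_{l≥1} W2( ρ̂_{t_l}, ρ_{t_l} )²,

simulated with Euler–Maruyama (default 10 substeps per unit interval;
observed time labels are integer-coded so intervals have length 1).  Per
iteration a fresh batch of B = 512 cells is drawn from the first snapshot,
carried through all training times in one unrolled pass, and penalized at
each later training time against a fresh B-subsample of that snapshot with
a **debiased Sinkhorn divergence** (quadratic cost; blur 0.1 in state-space
distance units; ε annealed from the squared cloud diameter down to blur² by
the scaling ratio 0.7; uniform weights; log-domain iterations).  The action
term is the Riemann sum `Σ_steps mean_cells ||f||² dt`.  Gradients flow
through the unrolled solver and the unrolled Sinkhorn iterations
(discretize-then-optimize); optimization is Adam (lr 1e-3, β 0.9/0.999)
with global gradient-norm clipping at 0.1.  Dropout 0.1 on attention
probabilities and FFN activations is active during training only; every
recorded attention matrix is dropout-free.

λ defaults to 1 (both terms active at comparable scale on the synthetic
systems); it is the primary user-tunable knob and is recorded with every
checkpoint.  All numerics are float64 on a small reverse-mode automatic
differentiation engine written for this package; its gradients are verified
against central finite differences (≥ 99% of parameters within 1e-3
relative on the full objective) in the test suite.

## Preprocessing

Raw counts → top-2000 highly variable genes → library-size normalization to
10⁴ per cell → log1p → PCA to r = 50 components.  Every data-dependent
transform (HVG set, PCA means/components) is fitted **only on training time
points** and then applied identically to held-out snapshots; the tests
verify bit-identity of the basis under perturbation of held-out data.  The
HVG statistic is the mean-binned normalized dispersion (var/mean of
linear-scale normalized expression, z-scored within 20 equal-occupancy bins
of the gene mean), ties broken by gene index; genes with zero raw variance
are excluded outright.  PCA centers but does not whiten.  Cells with zero
library size raise an error rather than being dropped silently.

## Evaluation

Held-out tasks remove middle time points (interpolation), terminal time
points (extrapolation), or both; the first two times always remain in
training.  Presets reproduce the 12-point and 19-point benchmark layouts.
Prediction initializes cells from the first training snapshot and solves
the fitted SDE forward jointly; interpolation and extrapolation use the
same continuous-time solve.  Scoring uses **exact** 1- and 2-Wasserstein
distances in the r-dimensional latent space — linear assignment for
equal-size clouds, a transportation LP otherwise, with seeded subsampling
to 1000 points per side above 10⁶ cost entries.  The entropic Sinkhorn
approximation is reserved for the training loss, so the reported metric
satisfies the metric axioms (`W1 ≤ W2` always).  Velocities are the drift
field evaluated at observed states with the population as context (noise
excluded).

## Interaction readout

Attention is recorded dropout-free, head-averaged, rows = targets (queries),
columns = sources (keys); rows are row-stochastic with an exactly zero
diagonal.  Type-level networks average `A[i, j]` over all (target type a,
source type b) pairs with `i ≠ j`.  The asymmetry index
`||M − M^T||_F / (2 ||M||_F)` is 0 for symmetric matrices and grows toward
1 for maximally anti-symmetric ones; it is reported per time point.
Concordance with an external directed type-pair score table (e.g. an
aggregated ligand–receptor communication score) retains distinct-type pairs
passing both thresholds (defaults 0.005 external / 0.001 attention) and
reports the Spearman rank correlation, flagged unreliable below 3 pairs.

## Synthetic test systems

The generators emulate the snapshot structure of temporal scRNA-seq:
**independent cohorts per time point** (fresh particles simulated from t0
to each observation time with fine step dt = 0.01, one RNG substream per
cohort), so no cell identity survives across — or within — snapshots.

* `mean_attraction`: `dx_i = [−γ(x_i − μ) + κ(x̄ − x_i)]dt + σ dW_i`.
  The interaction cancels in the cohort mean, so the mean follows
  `μ + (m₀ − μ)e^{−γt}` and relaxes at rate γ, while centered deviations
  are an OU process at rate γ + κ with stationary variance σ²/(2(γ+κ)).
  Both closed forms — including the correct Monte-Carlo variance of the
  cohort mean, which relaxes at γ only and therefore fluctuates more than
  deviations/N — serve as test oracles.  Defaults: d = 2, γ = 0.5, κ = 1,
  σ = 0.3, 500 cells, integer times 0–6, initial mean 2 and stationary
  initial spread (so the variance law holds at every time).
* `leader_follower`: the asymmetry test bed.  Leaders (a wide cloud,
  spread 1) advect at constant velocity and ignore followers; followers
  relax at rate κ toward a Gaussian-kernel-weighted local average of leader
  positions (bandwidth h = 0.75).  Influence is strictly one-directional.
  The *local* coupling is deliberate: with plain centroid tracking the
  follower dynamics can be fitted from each cell's own state plus a global
  population statistic, and attention has no reason to point at leaders —
  direction recovery was at chance in probes.  With local coupling,
  different followers must read different nearby leaders, which is exactly
  the query-dependent computation attention provides; direction recovery
  is then consistent across seeds.  For a Gaussian leader cloud of spread
  s the kernel pull is exactly centroid attraction at rate
  κ h²/(s² + h²), so the follower centroid lags by velocity/rate — a
  closed-form oracle (h → ∞ recovers the plain centroid case).  Leader and
  follower noise use separate RNG substreams, so leader trajectories are
  bitwise invariant to everything about the followers.
* `none`: independent OU particles (κ = 0), the non-interacting null.
* `to_counts` embeds latent states through a fixed random linear map into
  Poisson rates `rate_scale · max(0, XA + baseline)` with lognormal
  per-cell library factors — enough to exercise HVG selection,
  normalization, and PCA end-to-end.  It makes no attempt at dropout or
  overdispersion beyond Poisson, so passing preprocessing tests says
  nothing about robustness to those artifacts.

What the synthetic systems do *not* emulate: branching fates, growth and
death (mass is conserved, matching the balanced-OT objective), batch
effects, and realistic count noise.  Benchmarks passing on these systems
demonstrate that the machinery (solver, loss, gradients, attention readout)
works as specified, not that the model resolves real developmental biology.

## Problem sizes and defaults used in the shipped checks

Training-based checks run 2-D systems with 7 unit-spaced snapshots of 500
cells, batches of 96, 5 substeps per interval, 200–250 Adam iterations, and
a 64-unit intra MLP / 64-unit FFN — small enough to run on one CPU core in
a few minutes per fit while leaving the contracts (held-out recovery vs a
persistence baseline, one-directional attention recovery vs a reciprocal
control, determinism) fully exercised.  The architecture defaults
(256-unit MLPs, H = 2 heads, dropout 0.1, σ = 0.1, B = 512, lr 1e-3,
clip 0.1, blur 0.1, scaling 0.7, r = 50, 2000 HVGs) are the standard
configuration for real data.

## Known limitations

* Balanced OT: proliferation/apoptosis bias the fitted drift when the
  population grows or shrinks.
* Constant σ: no state-dependent noise.
* The attention readout is an associational interpretability artifact; on
  systems where the marginals can be fitted without using the interaction
  term, attention weights need not reflect the causal influence graph (see
  the leader–follower design notes above).
* The Sinkhorn penalty at blur 0.1 has an entropic floor; evaluation
  therefore uses exact OT, and training comparisons across configurations
  should compare like with like.
* Backpropagation through the unrolled solver stores the whole graph;
  memory grows linearly in (time points × substeps × B²) attention blocks.
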