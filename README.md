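# snapdyn

Interacting mean-field SDE models of collective cell dynamics from
time-series snapshots.

Temporal single-cell RNA-seq measures a population destructively: at each
time point you get an independent sample of cells with no identity shared
within or across snapshots.  Most trajectory-inference methods treat each
cell as an independent particle whose fate depends only on its own state,
ignoring the cell–cell interactions that drive collective behavior.
snapdyn instead fits a **McKean–Vlasov SDE**, in which every cell's drift
depends on the empirical distribution of the whole population:

    dx_t = [ f_intra(x_t) + f_inter(x_t, ρ_t) ] dt + σ dW_t,   ρ_t = Law(x_t)

`f_intra` is a small MLP (the cell-autonomous part); `f_inter` is
parameterized by **masked multi-head cell-wise self-attention** — each
cell's expression vector is a token, the diagonal is masked so a cell never
attends to itself, and because the query and key projections are independent
the attention matrix `A` is directional: `A[i, j]` quantifies the influence
of source cell `j` on target cell `i`.

Training matches the model to the observed snapshot marginals with a
least-action objective relaxed by entropic optimal transport,

    min_θ  E ∫ ||f_θ||² dt + λ Σ_l W2(ρ̂_{t_l}, ρ_{t_l})²,

backpropagated through an unrolled Euler–Maruyama solve and a debiased
log-domain Sinkhorn divergence (blur 0.1, ε-scaling 0.7), with Adam
(lr 1e-3, batch 512, gradient clipping at norm 0.1).  The fitted model

* predicts gene-expression distributions at held-out time points
  (interpolation and extrapolation), scored with exact W1/W2 distances,
* infers per-cell velocities (the drift field at observed states), and
* yields directed, possibly **asymmetric cell–cell interaction networks**
  by aggregating attention over annotated cell types, with an asymmetry
  index and a Spearman-concordance comparison against external
  ligand–receptor score tables.

Intended users: computational biologists analyzing temporal scRNA-seq who
want population-level dynamics *with* interactions, and methods developers
who need a fully-testable reference implementation with synthetic systems
and closed-form oracles (see `docs/methods.md`).

## Worked example

Fit the model to a synthetic interacting diffusion (7 snapshots of 500
cells whose drift pulls every cell toward the population mean), holding out
t = 3, then predict the held-out snapshot:

```python
import numpy as np
from snapdyn import (SyntheticConfig, simulate_interacting_ou, MeanFieldSDE,
                     ArchConfig, TrainConfig, make_task, wasserstein_distance)

cfg = SyntheticConfig(d=2, n_cells=500, times=(0, 1, 2, 3, 4, 5, 6), seed=42)
series, truth = simulate_interacting_ou(cfg)

task = make_task(series.times, "custom", held_out=[3.0])
model = MeanFieldSDE.from_series(
    series, train_times=task.train_times,
    arch=ArchConfig(d=2, intra_hidden=64, d_ff=64),
    config=TrainConfig(batch_size=96, n_iterations=200, substeps=5))
result = model.fit(seed=0)
print(result.summary())

pred = result.predict([3.0], seed=0)[3.0]
print(wasserstein_distance(pred, series.snapshots[3.0], p=2))
```

which prints

```
Interacting mean-field SDE — fit summary
==============================================
observed times        : [0.0, 1.0, 2.0, 4.0, 5.0, 6.0]
cells per snapshot    : [500, 500, 500, 500, 500, 500]
state dimension d     : 2
intra MLP             : 2 -> 64 -> 2
attention heads H     : 2 (d_k=1)
FFN width             : 64
diffusion sigma       : 0.1
parameters            : 672
iterations            : 200 (batch 96, lr 0.001, clip 0.1)
Sinkhorn blur/scaling : 0.1/0.7, lambda 1.0
loss (total)          : 24.3341 -> 1.7985
loss (action)         : 0.0000 -> 1.5506
W2^2 penalty @ t=1   : 1.2259 -> 0.0647
W2^2 penalty @ t=2   : 3.2571 -> 0.0885
W2^2 penalty @ t=4   : 5.9480 -> 0.0504
W2^2 penalty @ t=5   : 6.7136 -> 0.0299
W2^2 penalty @ t=6   : 7.1894 -> 0.0144
```

The Sinkhorn penalties at every training time drop by one to two orders of
magnitude while the action settles at the cost of the transport actually
needed.  The held-out prediction scores `W2 = 0.288` against the true
t = 3 snapshot, well below the persistence baseline
`W2(truth at t=2, truth at t=3) = 0.424` — the model interpolates the
distribution rather than copying the nearest snapshot.
`result.attention(time=...)`, `result.interaction_network(time=...)` and
`result.asymmetry()` expose the interaction readout; on this reciprocal
system the asymmetry index decays toward zero as the population reaches its
stationary cloud (0.34 at t = 0 down to 0.02 at t = 6).

The same pipeline is available from the shell:

```sh
snapdyn simulate   --outdir sim --seed 5 --n-cells 500 --kernel leader_follower
snapdyn preprocess --indir sim --outdir proc --n-hvg 2000 --r 50
snapdyn train      --indir proc --outdir run --task custom --held-out 3 --seed 5
snapdyn evaluate   --indir proc --checkpoint run/checkpoint --outdir eval --held-out 3
snapdyn attention  --indir proc --checkpoint run/checkpoint --outdir att
```

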