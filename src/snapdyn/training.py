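"""Fitting the interacting SDE to snapshot marginals.

The objective is a least-action principle relaxed by entropic optimal
transport: simulate a mini-batch of cells from the first snapshot through
all training times and minimize

    E \\int ||f_theta(x_t, rho_t)||^2 dt  +  lambda * sum_l W2(rho_hat_l, rho_l)^2

where the marginal penalty at each observed training time is a debiased
Sinkhorn approximation of the squared 2-Wasserstein distance between the
simulated batch and a fresh subsample of the observed snapshot.  Gradients
flow through the unrolled Euler–Maruyama solve and the unrolled Sinkhorn
iterations (discretize-then-optimize); optimization is Adam with global
gradient-norm clipping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .drift import ArchConfig, DriftModel, total_drift_t
from .sde import TimeGrid

__all__ = [
    "TrainConfig", "LossBreakdown", "TrainingDiverged", "action_cost",
    "sinkhorn_w2", "sinkhorn_w2_sq_t", "sample_batch", "compute_loss",
    "Adam", "training_step", "fit",
]


@dataclass
class TrainConfig:
    """Training hyperparameters.

    Defaults: batch size 512 cells, Adam at learning rate 1e-3, gradient
    clipping at global norm 0.1, Sinkhorn blur 0.1 (entropic radius, in
    state-space distance units) with epsilon-annealing ratio 0.7, diffusion
    sigma 0.1, marginal-penalty weight lambda_w 1, and 10 Euler substeps per
    unit observed interval.
    """

    batch_size: int = 512
    learning_rate: float = 1e-3
    grad_clip_max_norm: float = 0.1
    sinkhorn_blur: float = 0.1
    sinkhorn_scaling: float = 0.7
    lambda_w: float = 1.0
    n_iterations: int = 1000
    substeps: int = 10
    sigma: float = 0.1
    divergence_threshold: float = 1e6

    def __post_init__(self):
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (attention needs peers)")
        for name in ("learning_rate", "grad_clip_max_norm", "sinkhorn_blur"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 < self.sinkhorn_scaling < 1):
            raise ValueError("sinkhorn_scaling must lie in (0, 1)")
        if self.lambda_w < 0:
            raise ValueError("lambda_w must be >= 0")


@dataclass
class LossBreakdown:
    """One iteration's objective, split into its terms."""

    action: float
    marginal_penalties: dict[float, float]
    lambda_w: float
    grad_norm: float | None = None

    @property
    def total(self) -> float:
        return self.action + self.lambda_w * sum(self.marginal_penalties.values())


class TrainingDiverged(RuntimeError):
    def __init__(self, message, history=None):
        super().__init__(message)
        self.history = history or []


# ---------------------------------------------------------------------
# loss terms
# ---------------------------------------------------------------------

def action_cost(drifts: np.ndarray, dt) -> float:
    """Riemann discretization of E int ||f||^2 dt.

    ``drifts`` is (n_steps, N, d); ``dt`` a scalar or per-step vector.
    Each step contributes mean-over-cells squared drift norm times dt.
    """
    drifts = np.asarray(drifts, dtype=np.float64)
    if drifts.ndim != 3 or drifts.shape[0] < 1:
        raise ValueError("need at least one integration step of drift values")
    dt = np.broadcast_to(np.asarray(dt, dtype=np.float64), (drifts.shape[0],))
    per_step = (drifts ** 2).sum(axis=2).mean(axis=1)
    return float(np.sum(per_step * dt))


def _eps_schedule(diameter2: float, blur: float, scaling: float,
                  extra: int = 5) -> list[float]:
    """Annealed entropic radii: diameter^2 down to blur^2 by factor scaling^2."""
    eps_final = blur * blur
    eps = max(diameter2, eps_final)
    out = []
    while eps > eps_final:
        out.append(eps)
        eps *= scaling * scaling
    out.extend([eps_final] * max(extra, 1))
    return out


def _ot_eps_t(C: Tensor, eps_list: list[float]) -> Tensor:
    """Entropic OT value <a,f>+<b,g> for uniform weights, log-domain."""
    n, m = C.shape
    loga, logb = -np.log(n), -np.log(m)
    f = ad.constant(np.zeros(n))
    g = ad.constant(np.zeros(m))
    for eps in eps_list:
        # g_j = -eps lse_i[(f_i - C_ij)/eps + log a_i]
        M = ad.scale(ad.sub(f, ad.transpose(C)), 1.0 / eps)
        g = ad.scale(ad.logsumexp(ad.add(M, loga), axis=1), -eps)
        # f_i = -eps lse_j[(g_j - C_ij)/eps + log b_j]
        M2 = ad.scale(ad.sub(g, C), 1.0 / eps)
        f = ad.scale(ad.logsumexp(ad.add(M2, logb), axis=1), -eps)
    return ad.add(ad.mean_(f), ad.mean_(g))


def _sym_ot_eps_t(C: Tensor, eps_list: list[float]) -> Tensor:
    """Self term OT_eps(x, x) via the symmetric fixed-point iteration."""
    n = C.shape[0]
    logw = -np.log(n)
    p = ad.constant(np.zeros(n))
    for eps in eps_list:
        M = ad.scale(ad.sub(p, ad.transpose(C)), 1.0 / eps)
        q = ad.scale(ad.logsumexp(ad.add(M, logw), axis=1), -eps)
        p = ad.scale(ad.add(p, q), 0.5)
    return ad.scale(ad.mean_(p), 2.0)


def sinkhorn_w2_sq_t(x, y, blur: float = 0.1, scaling: float = 0.7) -> Tensor:
    """Debiased entropic approximation of the squared W2 distance.

    S(x, y) = OT_eps(x, y) - (OT_eps(x, x) + OT_eps(y, y)) / 2 with the
    quadratic cost, epsilon annealed from the squared point-cloud diameter
    down to blur^2 by the given scaling ratio.  Differentiable in both
    point clouds through the unrolled iterations.
    """
    xt, yt = ad.constant(x), ad.constant(y)
    if xt.data.shape[0] < 1 or yt.data.shape[0] < 1:
        raise ValueError("point sets must be non-empty")
    if xt.data.shape[1] != yt.data.shape[1]:
        raise ValueError("point sets must share the state dimension")
    Cxy = ad.pairwise_sqdist(xt, yt)
    diam2 = float(np.max(Cxy.data)) if Cxy.data.size else 1.0
    eps_list = _eps_schedule(max(diam2, 1e-12), blur, scaling)
    val = _ot_eps_t(Cxy, eps_list)
    cx = _sym_ot_eps_t(ad.pairwise_sqdist(xt, xt), eps_list)
    cy = _sym_ot_eps_t(ad.pairwise_sqdist(yt, yt), eps_list)
    return ad.sub(val, ad.scale(ad.add(cx, cy), 0.5))


def sinkhorn_w2(x: np.ndarray, y: np.ndarray,
                blur: float = 0.1, scaling: float = 0.7) -> float:
    """Entropic (debiased, symmetric, >= 0 up to tolerance) W2 estimate."""
    a = sinkhorn_w2_sq_t(np.asarray(x, float), np.asarray(y, float),
                         blur, scaling).item()
    b = sinkhorn_w2_sq_t(np.asarray(y, float), np.asarray(x, float),
                         blur, scaling).item()
    return float(np.sqrt(max(0.5 * (a + b), 0.0)))


def sample_batch(snapshot: np.ndarray, batch_size: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Uniform batch of cells: without replacement when it fits, with
    replacement when the batch exceeds the snapshot."""
    snapshot = np.asarray(snapshot)
    n = snapshot.shape[0]
    if n < 1:
        raise ValueError("snapshot is empty")
    if batch_size < 2:
        raise ValueError("batch_size must be >= 2 (attention needs peers)")
    idx = rng.choice(n, size=batch_size, replace=batch_size > n)
    return snapshot[idx]


# ---------------------------------------------------------------------
# objective over the unrolled solve
# ---------------------------------------------------------------------

def compute_loss(params_t: dict[str, Tensor],
                 arch: ArchConfig,
                 x0: np.ndarray,
                 observed: dict[float, np.ndarray],
                 times: np.ndarray,
                 noise_steps: list[np.ndarray] | None,
                 config: TrainConfig,
                 dropout_rng: np.random.Generator | None = None,
                 ) -> tuple[Tensor, LossBreakdown]:
    """Unrolled action + lambda * Sinkhorn penalties, as a graph tensor.

    ``observed`` maps each training time beyond the first to the snapshot
    batch it is penalized against; ``noise_steps`` holds one pre-drawn
    (B, d) standard-normal array per integration step (None for a
    noise-free solve).  Deterministic given its inputs, which makes it
    directly checkable by finite differences.
    """
    grid = TimeGrid(observed_times=np.asarray(times, float),
                    substeps=config.substeps)
    X = ad.constant(np.asarray(x0, dtype=np.float64))
    action = ad.constant(np.zeros(()))
    penalties: dict[float, Tensor] = {}
    b = X.shape[0]
    obs_index = {int(i) for i in grid.observed_indices[1:]}
    for k, dt in enumerate(grid.dts):
        f, _ = total_drift_t(X, params_t, arch, training=dropout_rng is not None,
                             dropout_rng=dropout_rng)
        action = ad.add(action, ad.scale(ad.sumsq(f), dt / b))
        X = ad.add(X, ad.scale(f, dt))
        if noise_steps is not None and config.sigma > 0:
            X = ad.add(X, ad.constant(config.sigma * np.sqrt(dt) * noise_steps[k]))
        if (k + 1) in obs_index:
            t = float(grid.times[k + 1])
            target = observed[t]
            penalties[t] = sinkhorn_w2_sq_t(
                X, target, blur=config.sinkhorn_blur,
                scaling=config.sinkhorn_scaling)
    total = action
    for p in penalties.values():
        total = ad.add(total, ad.scale(p, config.lambda_w))
    breakdown = LossBreakdown(
        action=float(action.data),
        marginal_penalties={t: float(p.data) for t, p in penalties.items()},
        lambda_w=config.lambda_w)
    if not np.isfinite(total.data):
        bad = [t for t, p in penalties.items() if not np.isfinite(p.data)]
        term = f"marginal penalty at t={bad}" if bad else "action term"
        raise TrainingDiverged(f"non-finite loss ({term})")
    return total, breakdown


# ---------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------

class Adam:
    """Adam with conventional moment defaults (0.9 / 0.999, eps 1e-8)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / b1c
            vhat = self.v[k] / b2c
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def clip_grads(grads: dict[str, np.ndarray], max_norm: float) -> float:
    """Scale all gradients so their global l2 norm is at most ``max_norm``.

    Returns the post-clip global norm.
    """
    total = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
    if total > max_norm and total > 0:
        factor = max_norm / total
        for k in grads:
            grads[k] = grads[k] * factor
        return max_norm
    return total


# ---------------------------------------------------------------------
# the training loop
# ---------------------------------------------------------------------

def _grid_steps(times, substeps):
    return (len(times) - 1) * substeps


def training_step(model: DriftModel,
                  snapshots: dict[float, np.ndarray],
                  times: np.ndarray,
                  config: TrainConfig,
                  optimizer: Adam,
                  batch_rng: np.random.Generator,
                  noise_rng: np.random.Generator,
                  dropout_rng: np.random.Generator | None = None,
                  ) -> LossBreakdown:
    """One mini-batch update of the drift parameters.

    A fresh batch is drawn from the first snapshot, carried through all
    training times in one unrolled pass, and penalized at each later time
    against a fresh batch of that snapshot; one clipped Adam step follows.
    """
    times = np.asarray(times, dtype=np.float64)
    b = config.batch_size
    x0 = sample_batch(snapshots[float(times[0])], b, batch_rng)
    observed = {float(t): sample_batch(snapshots[float(t)], b, batch_rng)
                for t in times[1:]}
    d = x0.shape[1]
    n_steps = _grid_steps(times, config.substeps)
    noise = [noise_rng.standard_normal((b, d)) for _ in range(n_steps)] \
        if config.sigma > 0 else None
    params_t = {k: Tensor(v) for k, v in model.params.items()}
    loss, breakdown = compute_loss(params_t, model.arch, x0, observed, times,
                                   noise, config, dropout_rng=dropout_rng)
    loss.backward()
    grads = {k: (t.grad if t.grad is not None else np.zeros_like(t.data))
             for k, t in params_t.items()}
    breakdown.grad_norm = clip_grads(grads, config.grad_clip_max_norm)
    optimizer.step(grads)
    return breakdown


def fit(snapshots: dict[float, np.ndarray],
        times,
        arch: ArchConfig,
        config: TrainConfig,
        seed: int = 0,
        callback=None) -> tuple[DriftModel, list[LossBreakdown]]:
    """Fit drift parameters to a series of snapshot marginals.

    Fully reproducible given ``seed``: parameter initialization, batching,
    solver noise, and dropout each draw from a named child stream of the
    seed.  Aborts with :class:`TrainingDiverged` (history attached) if the
    loss becomes non-finite or exceeds the divergence threshold.
    """
    times = np.asarray(sorted(float(t) for t in np.asarray(times).ravel()))
    if times.size < 2:
        raise ValueError("need at least two training time points")
    ss = np.random.SeedSequence(seed)
    init_s, batch_s, noise_s, drop_s = ss.spawn(4)
    model = DriftModel.initialize(
        arch, sigma=config.sigma, seed=np.random.default_rng(init_s))
    optimizer = Adam(model.params, lr=config.learning_rate)
    batch_rng = np.random.default_rng(batch_s)
    noise_rng = np.random.default_rng(noise_s)
    dropout_rng = np.random.default_rng(drop_s) if arch.dropout > 0 else None
    history: list[LossBreakdown] = []
    for it in range(config.n_iterations):
        bd = training_step(model, snapshots, times, config, optimizer,
                           batch_rng, noise_rng, dropout_rng)
        history.append(bd)
        if not np.isfinite(bd.total) or bd.total > config.divergence_threshold:
            raise TrainingDiverged(
                f"loss diverged at iteration {it}: total={bd.total:.3g}",
                history=history)
        if callback is not None:
            callback(it, bd)
    return model, history
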