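"""Model / Results surface tying the pieces together.

:class:`MeanFieldSDE` holds the snapshot data and configuration;
``fit()`` trains the drift network and returns a
:class:`MeanFieldSDEResults` carrying the fitted parameters, the loss
history, and the downstream analyses (prediction, velocities, attention,
interaction networks, summary).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .drift import ArchConfig, AttentionRecord, DriftModel
from .evaluation import infer_velocity, wasserstein_distance
from .interactions import (InteractionNetwork, aggregate_by_type,
                           asymmetry_index, attention_snapshot)
from .preprocess import ProcessedSeries
from .training import LossBreakdown, TrainConfig, fit
from .synthetic import SnapshotSeries

__all__ = ["MeanFieldSDE", "MeanFieldSDEResults"]


class MeanFieldSDE:
    """An interacting mean-field SDE model of snapshot time-series.

    Parameters
    ----------
    snapshots : mapping of observed time -> (N_t, d) latent state matrix.
        No cell correspondence across times is assumed.
    cell_types : optional mapping of time -> per-cell type labels.
    arch : drift-network architecture; defaults to the standard
        configuration (256-unit intra MLP, 2 attention heads, dropout 0.1)
        at the data's dimension.
    config : training hyperparameters (:class:`TrainConfig`).
    """

    def __init__(self, snapshots: dict[float, np.ndarray],
                 cell_types: dict[float, np.ndarray] | None = None,
                 arch: ArchConfig | None = None,
                 config: TrainConfig | None = None):
        self.snapshots = {float(t): np.asarray(x, dtype=np.float64)
                          for t, x in snapshots.items()}
        self.times = np.asarray(sorted(self.snapshots), dtype=np.float64)
        if self.times.size < 2:
            raise ValueError("need snapshots at >= 2 time points")
        dims = {x.shape[1] for x in self.snapshots.values()}
        if len(dims) != 1:
            raise ValueError(f"inconsistent state dimensions {sorted(dims)}")
        self.d = dims.pop()
        self.cell_types = None if cell_types is None else \
            {float(t): np.asarray(v) for t, v in cell_types.items()}
        self.arch = arch or ArchConfig(d=self.d)
        if self.arch.d != self.d:
            raise ValueError(
                f"architecture is for d={self.arch.d}, data has d={self.d}")
        self.config = config or TrainConfig()

    @classmethod
    def from_processed(cls, series: ProcessedSeries, train_times=None,
                       **kwargs) -> "MeanFieldSDE":
        """Build from a preprocessed latent series, optionally restricted
        to a training subset of its times."""
        if train_times is not None:
            series = series.subset(train_times)
        return cls({float(t): series.latents[float(t)] for t in series.times},
                   cell_types=series.cell_types, **kwargs)

    @classmethod
    def from_series(cls, series: SnapshotSeries, train_times=None,
                    **kwargs) -> "MeanFieldSDE":
        """Build from a synthetic :class:`SnapshotSeries`."""
        times = series.times if train_times is None else \
            np.asarray(train_times, dtype=np.float64)
        snaps = {float(t): series.snapshots[float(t)] for t in times}
        types = None if series.cell_types is None else \
            {float(t): series.cell_types[float(t)] for t in times}
        return cls(snaps, cell_types=types, **kwargs)

    def fit(self, seed: int = 0, callback=None) -> "MeanFieldSDEResults":
        """Train the drift network; reproducible given ``seed``."""
        drift_model, history = fit(self.snapshots, self.times, self.arch,
                                   self.config, seed=seed, callback=callback)
        return MeanFieldSDEResults(model=self, drift=drift_model,
                                   history=history, seed=seed)


@dataclass
class MeanFieldSDEResults:
    """Fitted interacting SDE: estimates, diagnostics, and analyses."""

    model: MeanFieldSDE
    drift: DriftModel
    history: list[LossBreakdown]
    seed: int

    # -- diagnostics --------------------------------------------------
    @property
    def loss_history(self) -> pd.DataFrame:
        rows = []
        for i, bd in enumerate(self.history):
            row = {"iteration": i, "action": bd.action, "total": bd.total,
                   "grad_norm": bd.grad_norm}
            for t, v in bd.marginal_penalties.items():
                row[f"penalty_t{t:g}"] = v
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        n_params = sum(v.size for v in self.drift.params.values())
        first, last = self.history[0], self.history[-1]
        arch = self.drift.arch
        cfg = self.model.config
        lines = [
            "Interacting mean-field SDE — fit summary",
            "=" * 46,
            f"observed times        : {self.model.times.tolist()}",
            f"cells per snapshot    : "
            f"{[self.model.snapshots[float(t)].shape[0] for t in self.model.times]}",
            f"state dimension d     : {self.model.d}",
            f"intra MLP             : {arch.d} -> {arch.intra_hidden} -> {arch.d}",
            f"attention heads H     : {arch.n_heads} (d_k={arch.d_k})",
            f"FFN width             : {arch.d_ff}",
            f"diffusion sigma       : {self.drift.sigma}",
            f"parameters            : {n_params}",
            f"iterations            : {len(self.history)} "
            f"(batch {cfg.batch_size}, lr {cfg.learning_rate}, "
            f"clip {cfg.grad_clip_max_norm})",
            f"Sinkhorn blur/scaling : {cfg.sinkhorn_blur}/{cfg.sinkhorn_scaling}"
            f", lambda {cfg.lambda_w}",
            f"loss (total)          : {first.total:.4f} -> {last.total:.4f}",
            f"loss (action)         : {first.action:.4f} -> {last.action:.4f}",
        ]
        for t in sorted(last.marginal_penalties):
            lines.append(
                f"W2^2 penalty @ t={t:g}   : "
                f"{first.marginal_penalties[t]:.4f} -> "
                f"{last.marginal_penalties[t]:.4f}")
        return "\n".join(lines)

    # -- prediction ---------------------------------------------------
    def predict(self, times, n_cells: int | None = None,
                seed: int = 0) -> dict[float, np.ndarray]:
        """Simulated snapshots at the requested times (>= first observed)."""
        requested = np.asarray(times, dtype=np.float64)
        from .sde import simulate_to_times

        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=seed, spawn_key=(1,)))
        pool = self.model.snapshots[float(self.model.times[0])]
        n = n_cells or pool.shape[0]
        x0 = pool[rng.choice(pool.shape[0], size=n, replace=n > pool.shape[0])]
        sim_rng = np.random.default_rng(np.random.SeedSequence(
            entropy=seed, spawn_key=(2,)))
        return simulate_to_times(x0, self.drift, self.model.times, requested,
                                 substeps=self.model.config.substeps,
                                 seed=sim_rng)

    def score(self, truth: dict[float, np.ndarray],
              seed: int = 0) -> pd.DataFrame:
        """Exact W1/W2 between predictions and given true snapshots."""
        preds = self.predict(sorted(truth), seed=seed)
        rows = []
        for t in sorted(truth):
            rows.append({"time": float(t),
                         "W1": wasserstein_distance(preds[float(t)],
                                                    truth[t], p=1),
                         "W2": wasserstein_distance(preds[float(t)],
                                                    truth[t], p=2)})
        return pd.DataFrame(rows)

    # -- velocities / attention --------------------------------------
    def velocities(self, X: np.ndarray,
                   context: np.ndarray | None = None) -> np.ndarray:
        """Drift field at the given states (noise excluded)."""
        return infer_velocity(self.drift, X, context)

    def attention(self, time: float | None = None,
                  X: np.ndarray | None = None,
                  cell_types: np.ndarray | None = None,
                  max_cells: int = 500, seed: int = 0,
                  order_by_type: bool = False) -> AttentionRecord:
        """Attention record at an observed time (or an explicit batch)."""
        if X is None:
            if time is None:
                raise ValueError("give either a time or an explicit batch")
            X = self.model.snapshots[float(time)]
            if cell_types is None and self.model.cell_types is not None:
                cell_types = self.model.cell_types[float(time)]
        return attention_snapshot(self.drift, X, cell_types,
                                  max_cells=max_cells, seed=seed,
                                  order_by_type=order_by_type, time=time)

    def interaction_network(self, time: float,
                            max_cells: int = 500,
                            seed: int = 0) -> InteractionNetwork:
        """Type-aggregated directed network at one observed time."""
        if self.model.cell_types is None:
            raise ValueError("interaction networks require cell-type labels")
        rec = self.attention(time=time, max_cells=max_cells, seed=seed)
        types = self.model.cell_types[float(time)][rec.cell_index]
        return aggregate_by_type(rec, types, time=time)

    def asymmetry(self, max_cells: int = 500, seed: int = 0) -> pd.DataFrame:
        """Asymmetry index of the cell-wise attention at every time."""
        rows = []
        for t in self.model.times:
            rec = self.attention(time=float(t), max_cells=max_cells, seed=seed)
            rows.append({"time": float(t),
                         "asymmetry_index": asymmetry_index(rec.head_average)})
        return pd.DataFrame(rows)

    # -- persistence --------------------------------------------------
    def save(self, path) -> None:
        self.drift.save(path)

    @staticmethod
    def load_drift(path) -> DriftModel:
        return DriftModel.load(path)
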