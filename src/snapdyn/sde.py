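"""Euler–Maruyama integration of the interacting cell SDE.

Because the drift depends on the empirical distribution of the batch, all
cells advance jointly: one drift evaluation per step sees the whole batch.
Observed snapshot times sit exactly on the integration grid, with a fixed
number of equal substeps between consecutive observed times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .drift import AttentionRecord, DriftModel


@dataclass
class TimeGrid:
    """Uniform refinement of the observed time axis.

    Each interval between consecutive observed times is split into
    ``substeps`` equal Euler steps; every observed time lies exactly on the
    grid.
    """

    observed_times: np.ndarray
    substeps: int = 10
    times: np.ndarray = field(init=False)
    observed_indices: np.ndarray = field(init=False)

    def __post_init__(self):
        obs = np.asarray(self.observed_times, dtype=np.float64)
        if obs.ndim != 1 or obs.size < 1:
            raise ValueError("observed_times must be a non-empty 1-D sequence")
        if obs.size > 1 and np.any(np.diff(obs) <= 0):
            raise ValueError("observed_times must be strictly increasing")
        if self.substeps < 1:
            raise ValueError(f"substeps must be >= 1, got {self.substeps}")
        self.observed_times = obs
        pts = [obs[0]]
        idx = [0]
        for a, b in zip(obs[:-1], obs[1:]):
            seg = a + (b - a) * np.arange(1, self.substeps + 1) / self.substeps
            seg[-1] = b  # land exactly on the observed time
            pts.extend(seg.tolist())
            idx.append(len(pts) - 1)
        self.times = np.asarray(pts)
        self.observed_indices = np.asarray(idx, dtype=int)

    @property
    def dts(self) -> np.ndarray:
        return np.diff(self.times)

    @property
    def n_steps(self) -> int:
        return len(self.times) - 1


@dataclass
class TrajectoryEnsemble:
    """Jointly simulated cell states on the integration grid.

    ``states`` has shape (n_grid_points, N, d) with ``states[0]`` the
    initial batch; ``drifts`` holds the drift evaluated at the start of each
    of the ``n_steps`` integration steps (the action integrand).
    """

    grid: TimeGrid
    states: np.ndarray
    drifts: np.ndarray
    seed: int | None = None
    attention_records: dict[float, AttentionRecord] = field(default_factory=dict)

    def at_time(self, t: float) -> np.ndarray:
        i = np.flatnonzero(np.isclose(self.grid.times, t))
        if i.size == 0:
            raise KeyError(f"time {t} is not on the integration grid")
        return self.states[i[0]]

    @property
    def observed_states(self) -> dict[float, np.ndarray]:
        return {float(t): self.states[i] for t, i in
                zip(self.grid.observed_times, self.grid.observed_indices)}

    def save(self, path) -> None:
        """npz container (grid + state/drift tensors) plus one delimited
        state matrix per observed time."""
        from pathlib import Path

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(path / "trajectory.npz", times=self.grid.times,
                 states=self.states, drifts=self.drifts)
        for t, X in self.observed_states.items():
            np.savetxt(path / f"state_t{t:g}.tsv", X, delimiter="\t")


def euler_maruyama(X0: np.ndarray,
                   drift,
                   grid: TimeGrid,
                   sigma: float | None = None,
                   seed: int | np.random.Generator = 0,
                   noise: bool = True,
                   interacting: bool = True,
                   record_attention: bool = False) -> TrajectoryEnsemble:
    """Simulate X_{k+1} = X_k + f(X_k) dt + sigma sqrt(dt) xi_k.

    Parameters
    ----------
    drift : a :class:`~snapdyn.drift.DriftModel` (its ``sigma`` is used
        unless overridden) or any callable ``f(X) -> (N, d) array``.
    noise : with ``False`` (or sigma 0) the flow is deterministic.
    interacting : with ``False`` a DriftModel's interaction term is skipped
        entirely — a single-particle (Itô) run with the same noise stream.
    record_attention : capture the AttentionRecord at every observed time.

    Noise increments are independent standard normals per cell and
    dimension, drawn in grid order, so two runs with the same seed are
    bitwise identical.
    """
    X = np.asarray(X0, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("X0 must be an (N, d) matrix with N >= 1")
    if not np.all(np.isfinite(X)):
        raise ValueError("X0 contains non-finite entries")

    is_model = isinstance(drift, DriftModel)
    if sigma is None:
        sigma = drift.sigma if is_model else 0.0
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)

    n_pts = len(grid.times)
    states = np.empty((n_pts, *X.shape))
    drifts = np.empty((n_pts - 1, *X.shape))
    states[0] = X
    records: dict[float, AttentionRecord] = {}
    obs_idx = set(grid.observed_indices.tolist())

    def eval_drift(Xk, k):
        if is_model:
            f, rec = drift.total_drift(Xk, interacting=interacting)
            if record_attention and rec is not None and k in obs_idx:
                rec.time = float(grid.times[k])
                records[float(grid.times[k])] = rec
            return f
        return np.asarray(drift(Xk), dtype=np.float64)

    for k, dt in enumerate(grid.dts):
        f = eval_drift(states[k], k)
        Xn = states[k] + f * dt
        if noise and sigma > 0:
            Xn = Xn + sigma * np.sqrt(dt) * rng.standard_normal(X.shape)
        if not np.all(np.isfinite(Xn)):
            raise FloatingPointError(
                f"state blew up at step {k} (t={grid.times[k]:.4g}): "
                f"max |x| = {np.nanmax(np.abs(Xn)):.3g}")
        drifts[k] = f
        states[k + 1] = Xn
    if record_attention and is_model:
        # attention at the final observed time (state after the last step)
        k = n_pts - 1
        if k in obs_idx and interacting:
            _, rec = drift.total_drift(states[k])
            if rec is not None:
                rec.time = float(grid.times[k])
                records[float(grid.times[k])] = rec

    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    return TrajectoryEnsemble(grid=grid, states=states, drifts=drifts,
                              seed=seed_val, attention_records=records)


def simulate_to_times(X0: np.ndarray,
                      drift,
                      observed_times,
                      requested_times,
                      substeps: int = 10,
                      sigma: float | None = None,
                      seed: int | np.random.Generator = 0,
                      noise: bool = True) -> dict[float, np.ndarray]:
    """Snapshots of a joint simulation at the requested times.

    The grid is built over the union of observed and requested times (so
    extrapolation beyond the last observed time simply extends the grid);
    requesting a time before the first observed time is an error — the
    solver does not run backwards.
    """
    req = np.asarray(requested_times, dtype=np.float64)
    obs = np.asarray(observed_times, dtype=np.float64)
    t0 = obs.min()
    if np.any(req < t0):
        raise ValueError(
            f"requested times {req[req < t0].tolist()} precede the initial "
            f"time {t0}; backward simulation is unsupported")
    all_t = np.unique(np.concatenate([obs, req]))
    grid = TimeGrid(observed_times=all_t, substeps=substeps)
    traj = euler_maruyama(X0, drift, grid, sigma=sigma, seed=seed, noise=noise)
    return {float(t): traj.at_time(float(t)) for t in req}
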