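"""Snapshot series from known interacting diffusions.

These generators emulate the structure of time-series single-cell data:
independent cohorts of cells at each observed time (no cell identity shared
within or across snapshots, mimicking destructive measurement), produced by
an interacting particle system with a known intra-cellular drift, a known
pairwise interaction kernel, and a known diffusion constant.  Linear cases
carry closed-form moment oracles so downstream modules can be tested
without external data.

Kernels
-------
mean_attraction
    dx_i = [-gamma (x_i - mu_type) + kappa (xbar - x_i)] dt + sigma dW_i —
    every cell is pulled toward the population mean; the interaction is
    reciprocal.  For a single type the population mean obeys
    dm/dt = -gamma (m - mu) (the interaction cancels) and centered
    deviations are an OU process with rate gamma + kappa, giving the
    stationary variance sigma^2 / (2 (gamma + kappa)).
leader_follower
    Leaders advect with the moving target (constant velocity), ignoring
    followers; followers relax (rate kappa) toward a Gaussian-kernel
    weighted local average of leader positions (bandwidth
    ``interaction_range``; infinite bandwidth reduces to plain centroid
    tracking).  For a Gaussian leader cloud of spread s the kernel
    attraction is exactly centroid attraction at the effective rate
    kappa h^2 / (s^2 + h^2), giving a closed-form centroid lag.  The
    influence graph is strictly one-directional, the ground truth for
    attention-asymmetry recovery; the local (query-dependent) coupling is
    what makes the direction identifiable from snapshots.
none
    Independent OU particles (kappa = 0): the non-interacting null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "SyntheticConfig", "GroundTruth", "SnapshotSeries",
    "simulate_interacting_ou", "simulate_leader_follower",
    "simulate_noninteracting", "to_counts",
]

_KERNELS = ("mean_attraction", "leader_follower", "none")


@dataclass
class SyntheticConfig:
    """Ground-truth system parameters.

    Defaults describe the standard test system used throughout the package:
    a 2-D mean-attraction diffusion with relaxation rate gamma 0.5,
    interaction strength kappa 1, diffusion 0.3, 500 cells per snapshot at
    integer times 0..6, started at stationary spread around mean 2.
    """

    d: int = 2
    n_cells: int = 500
    times: tuple = (0, 1, 2, 3, 4, 5, 6)
    gamma: float = 0.5
    kappa: float = 1.0
    sigma_true: float = 0.3
    kernel: str = "mean_attraction"
    init_mean: float | np.ndarray = 2.0
    init_std: float | None = None  # default: stationary deviation scale
    type_means: np.ndarray | None = None  # (n_types, d); None -> origin
    leader_velocity: float | np.ndarray = 0.5
    leader_fraction: float = 0.5
    interaction_range: float = 0.75  # kernel bandwidth h of the follower pull
    follower_offset: tuple = (0.0, -2.0)
    sim_dt: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.kernel not in _KERNELS:
            raise ValueError(f"kernel must be one of {_KERNELS}")
        if self.n_cells < 2:
            raise ValueError("n_cells must be >= 2")
        if min(self.gamma, self.kappa, self.sigma_true) < 0:
            raise ValueError("gamma, kappa, sigma_true must be >= 0")
        if len(self.times) < 1 or np.any(np.diff(np.asarray(self.times)) <= 0):
            raise ValueError("times must be non-empty and strictly increasing")

    @property
    def deviation_rate(self) -> float:
        """Relaxation rate of centered deviations (gamma + kappa)."""
        return self.gamma + (self.kappa if self.kernel == "mean_attraction" else 0.0)

    @property
    def stationary_variance(self) -> float:
        """Per-coordinate stationary variance of centered deviations."""
        rate = self.deviation_rate
        if rate == 0:
            return np.inf
        return self.sigma_true ** 2 / (2.0 * rate)

    def resolved_init_std(self) -> float:
        if self.init_std is not None:
            return self.init_std
        v = self.stationary_variance
        return float(np.sqrt(v)) if np.isfinite(v) else 1.0


@dataclass
class SnapshotSeries:
    """Ordered snapshots with no cross-time cell correspondence."""

    times: np.ndarray
    snapshots: dict[float, np.ndarray]
    cell_types: dict[float, np.ndarray] | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64)

    def n_cells(self, t: float) -> int:
        return self.snapshots[float(t)].shape[0]

    @property
    def d(self) -> int:
        return next(iter(self.snapshots.values())).shape[1]


@dataclass
class GroundTruth:
    """Closed-form oracles for the generated system."""

    config: SyntheticConfig
    mean_fn: Callable[[float], np.ndarray] | None = None
    variance_fn: Callable[[float], float] | None = None
    drift_fn: Callable[[np.ndarray], np.ndarray] | None = None
    influence: dict[tuple[str, str], float] = field(default_factory=dict)
    lag_rate: float | None = None  # effective follower tracking rate
    mean_variance_fn: Callable[[float], float] | None = None

    def mean(self, t: float) -> np.ndarray:
        if self.mean_fn is None:
            raise ValueError("no closed-form mean for this kernel")
        return self.mean_fn(float(t))

    def variance(self, t: float) -> float:
        if self.variance_fn is None:
            raise ValueError("no closed-form variance for this kernel")
        return self.variance_fn(float(t))

    def mean_se(self, t: float, n: int) -> float:
        """Monte-Carlo standard error of the cohort mean per coordinate.

        The cohort mean relaxes at rate gamma only (the interaction term
        cancels in the mean), so its variance is v0 e^{-2 gamma t} / n +
        sigma^2 (1 - e^{-2 gamma t}) / (2 gamma n) — larger than the
        naive (deviation variance)/n whenever kappa > 0.
        """
        if self.mean_variance_fn is None:
            raise ValueError("no closed-form mean variance for this kernel")
        return float(np.sqrt(self.mean_variance_fn(float(t)) / n))


def _cohort_rng(seed: int, snapshot_index: int) -> np.random.Generator:
    # one independent substream per snapshot: perturbing one cohort's
    # stream cannot touch any other snapshot
    return np.random.default_rng(np.random.SeedSequence(
        entropy=seed, spawn_key=(snapshot_index,)))


def _em_cohort(x0: np.ndarray, drift: Callable, t_end: float, dt: float,
               sigma: float, rng: np.random.Generator,
               t_start: float = 0.0) -> np.ndarray:
    """Fine-step Euler–Maruyama of one cohort from t_start to t_end."""
    x = x0.copy()
    t = t_start
    while t < t_end - 1e-12:
        step = min(dt, t_end - t)
        x = x + drift(x, t) * step
        if sigma > 0:
            x = x + sigma * np.sqrt(step) * rng.standard_normal(x.shape)
        t += step
    return x


def simulate_interacting_ou(config: SyntheticConfig
                            ) -> tuple[SnapshotSeries, GroundTruth]:
    """Mean-attraction interacting OU cohorts with moment oracles.

    Each snapshot is an independent cohort simulated from time 0 to its
    observation time with step ``sim_dt`` — fresh particles per time point,
    so no correspondence survives across snapshots.
    """
    if config.kernel != "mean_attraction":
        raise ValueError("simulate_interacting_ou requires kernel='mean_attraction'")
    return _simulate_ou_like(config)


def simulate_noninteracting(config: SyntheticConfig
                            ) -> tuple[SnapshotSeries, GroundTruth]:
    """Independent OU particles: the null for interaction detection."""
    if config.kernel != "none":
        raise ValueError("simulate_noninteracting requires kernel='none'")
    return _simulate_ou_like(config)


def _simulate_ou_like(config: SyntheticConfig
                      ) -> tuple[SnapshotSeries, GroundTruth]:
    d = config.d
    mu = np.zeros(d) if config.type_means is None \
        else np.asarray(config.type_means, float).reshape(-1)[:d]
    kappa = config.kappa if config.kernel == "mean_attraction" else 0.0
    gamma = config.gamma
    m0 = np.broadcast_to(np.asarray(config.init_mean, float), (d,)).astype(float)
    v0 = config.resolved_init_std() ** 2
    rate = gamma + kappa
    v_inf = config.stationary_variance

    def drift(x, t):
        pull = -gamma * (x - mu)
        if kappa > 0:
            pull = pull + kappa * (x.mean(axis=0, keepdims=True) - x)
        return pull

    def mean_fn(t):
        return mu + (m0 - mu) * np.exp(-gamma * t)

    def variance_fn(t):
        if rate == 0:
            return v0 + config.sigma_true ** 2 * t
        decay = np.exp(-2.0 * rate * t)
        return v0 * decay + v_inf * (1.0 - decay)

    def mean_variance_fn(t):
        # the mean is an OU process with rate gamma and noise sigma/sqrt(N);
        # this is its variance times N (per-cohort, per-coordinate)
        if gamma == 0:
            return v0 + config.sigma_true ** 2 * t
        decay = np.exp(-2.0 * gamma * t)
        return v0 * decay + \
            config.sigma_true ** 2 / (2.0 * gamma) * (1.0 - decay)

    snapshots = {}
    for l, t in enumerate(config.times):
        rng = _cohort_rng(config.seed, l)
        x0 = m0 + config.resolved_init_std() * rng.standard_normal(
            (config.n_cells, d))
        snapshots[float(t)] = _em_cohort(x0, drift, float(t), config.sim_dt,
                                         config.sigma_true, rng)
    series = SnapshotSeries(times=np.asarray(config.times, float),
                            snapshots=snapshots)
    truth = GroundTruth(config=config, mean_fn=mean_fn,
                        variance_fn=variance_fn,
                        mean_variance_fn=mean_variance_fn,
                        drift_fn=lambda X: drift(X, 0.0))
    return series, truth


def _follower_drift(followers: np.ndarray, leaders: np.ndarray,
                    kappa: float, h: float) -> np.ndarray:
    """Pull toward the kernel-weighted local average of leader positions."""
    if not np.isfinite(h):
        target = np.broadcast_to(leaders.mean(axis=0), followers.shape)
        return kappa * (target - followers)
    d2 = ((followers[:, None, :] - leaders[None, :, :]) ** 2).sum(-1)
    w = np.exp(-d2 / (2.0 * h * h))
    w = w / w.sum(axis=1, keepdims=True)
    return kappa * (w @ leaders - followers)


def simulate_leader_follower(config: SyntheticConfig
                             ) -> tuple[SnapshotSeries, GroundTruth]:
    """Two-type system with strictly one-directional influence.

    Leaders (a wide cloud, spread ``init_std`` defaulting to 1) advect at
    ``leader_velocity`` along the first coordinate, ignoring followers.
    Followers start displaced by ``follower_offset`` and relax at rate
    ``kappa`` toward the kernel-weighted local average of leader positions
    (bandwidth ``interaction_range``); with ``kappa = 0`` they reduce to
    pure diffusion around their start.  Leader and follower noise come
    from separate substreams, so leader trajectories are bitwise invariant
    to anything about the followers.
    """
    if config.kernel != "leader_follower":
        raise ValueError("simulate_leader_follower requires kernel='leader_follower'")
    d = config.d
    n_lead = int(round(config.n_cells * config.leader_fraction))
    n_follow = config.n_cells - n_lead
    if n_lead < 2 or n_follow < 2:
        raise ValueError(
            f"need >= 2 cells of each type, got {n_lead} leaders / "
            f"{n_follow} followers")
    vel = np.zeros(d)
    vel[0] = np.asarray(config.leader_velocity, float).reshape(-1)[0]
    offset = np.zeros(d)
    off = np.asarray(config.follower_offset, float).ravel()
    offset[: min(d, off.size)] = off[: min(d, off.size)]
    spread = config.init_std if config.init_std is not None else 1.0
    h = config.interaction_range
    snapshots, types = {}, {}
    labels = np.array(["leader"] * n_lead + ["follower"] * n_follow)
    for l, t in enumerate(config.times):
        rng_l = _cohort_rng(config.seed, 2 * l)
        rng_f = _cohort_rng(config.seed, 2 * l + 1)
        lead = spread * rng_l.standard_normal((n_lead, d))
        foll = offset + spread * rng_f.standard_normal((n_follow, d))
        tt, dt = 0.0, config.sim_dt
        while tt < float(t) - 1e-12:
            step = min(dt, float(t) - tt)
            foll = foll + _follower_drift(foll, lead, config.kappa, h) * step
            lead = lead + vel * step
            if config.sigma_true > 0:
                root = np.sqrt(step) * config.sigma_true
                lead = lead + root * rng_l.standard_normal(lead.shape)
                foll = foll + root * rng_f.standard_normal(foll.shape)
            tt += step
        snapshots[float(t)] = np.vstack([lead, foll])
        types[float(t)] = labels.copy()
    series = SnapshotSeries(times=np.asarray(config.times, float),
                            snapshots=snapshots, cell_types=types)
    # for a Gaussian leader cloud of spread s, kernel attraction is exactly
    # centroid attraction at rate kappa h^2 / (s^2 + h^2)
    s2 = spread * spread
    lag_rate = config.kappa if not np.isfinite(h) else \
        config.kappa * h * h / (s2 + h * h)

    def drift_fn(X, n_lead=n_lead):
        out = np.empty_like(X)
        out[:n_lead] = vel
        out[n_lead:] = _follower_drift(X[n_lead:], X[:n_lead],
                                       config.kappa, h)
        return out

    truth = GroundTruth(config=config, drift_fn=drift_fn,
                        influence={("leader", "follower"): config.kappa,
                                   ("follower", "leader"): 0.0},
                        lag_rate=lag_rate)
    return series, truth


def expected_rates(X: np.ndarray, loadings: np.ndarray,
                   baseline: float) -> np.ndarray:
    """Poisson rate matrix for latent states under the count model."""
    return np.maximum(X @ loadings + baseline, 0.0)


def count_loadings(d: int, n_genes: int, basis_seed: int = 0) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=basis_seed, spawn_key=(10_000,)))
    return rng.standard_normal((d, n_genes)) / np.sqrt(d)


def to_counts(series: SnapshotSeries, n_genes: int,
              basis_seed: int = 0,
              baseline: float = 5.0,
              library_sigma: float = 0.2,
              rate_scale: float = 1.0):
    """Embed latent snapshots into Poisson count matrices.

    Latent states map through a fixed random linear layer into non-negative
    rates rate_scale * max(0, X A + baseline), scaled per cell by a
    lognormal library factor, and counts are Poisson draws (``rate_scale``
    sets sequencing depth, hence the Poisson noise floor).  With a zero
    latent state and zero baseline every rate — hence every count — is
    zero.  Returns a :class:`~snapdyn.preprocess.RawSnapshotSeries`.
    """
    from .preprocess import RawSnapshotSeries

    d = series.d
    if n_genes < d:
        raise ValueError(f"n_genes ({n_genes}) must be >= latent dim ({d})")
    A = count_loadings(d, n_genes, basis_seed)
    counts = {}
    gene_ids = [f"g{j:05d}" for j in range(n_genes)]
    cell_ids = {}
    for l, t in enumerate(series.times):
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=basis_seed, spawn_key=(20_000 + l,)))
        X = series.snapshots[float(t)]
        rates = rate_scale * expected_rates(X, A, baseline)
        lib = np.exp(library_sigma * rng.standard_normal((X.shape[0], 1)))
        counts[float(t)] = rng.poisson(rates * lib).astype(np.int64)
        cell_ids[float(t)] = np.array(
            [f"c_t{t:g}_{i}" for i in range(X.shape[0])])
    return RawSnapshotSeries(times=series.times.copy(), counts=counts,
                             gene_ids=gene_ids,
                             cell_types=series.cell_types,
                             cell_ids=cell_ids)
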