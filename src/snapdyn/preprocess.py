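"""Raw count snapshots -> the r-dimensional latent series the model uses.

Pipeline (every data-dependent transform is fitted on training time points
only, so held-out snapshots can never leak into the basis):

1. select the top highly variable genes on the pooled training cells,
2. library-size normalize each cell to a fixed total and log1p-transform,
3. fit PCA on the pooled normalized training cells,
4. project every snapshot (train and held-out alike) into the r-dim basis.

HVG selection uses the mean-binned normalized-dispersion convention common
in single-cell analysis, computed on log-normalized training expression,
with ties broken deterministically by gene index.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "RawSnapshotSeries", "LatentBasis", "ProcessedSeries",
    "select_hvgs", "normalize_log", "fit_pca", "transform",
    "inverse_transform", "preprocess_series", "load_raw_series",
]

DEFAULT_N_HVG = 2000
DEFAULT_SCALE = 1e4
DEFAULT_R = 50


@dataclass
class RawSnapshotSeries:
    """Count snapshots sharing one gene axis, no cell correspondence."""

    times: np.ndarray
    counts: dict[float, np.ndarray]
    gene_ids: list[str]
    cell_types: dict[float, np.ndarray] | None = None
    cell_ids: dict[float, np.ndarray] | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.times.size < 1 or (self.times.size > 1
                                   and np.any(np.diff(self.times) <= 0)):
            raise ValueError("times must be non-empty and strictly increasing")
        n_genes = len(self.gene_ids)
        for t in self.times:
            c = self.counts[float(t)]
            if c.shape[0] < 1:
                raise ValueError(f"snapshot at t={t} has no cells")
            if c.shape[1] != n_genes:
                raise ValueError(
                    f"snapshot at t={t} has {c.shape[1]} genes, "
                    f"expected {n_genes}")
            if np.any(c < 0):
                raise ValueError(f"negative counts at t={t}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class LatentBasis:
    """Fitted HVG + PCA transform (training-time provenance)."""

    hvg_index: np.ndarray
    library_scale: float
    pca_means: np.ndarray
    pca_components: np.ndarray  # (r, n_hvg), rows orthonormal
    r: int

    def __post_init__(self):
        self.hvg_index = np.asarray(self.hvg_index, dtype=int)
        if self.r > self.hvg_index.size:
            raise ValueError("r cannot exceed the number of selected genes")
        G = self.pca_components @ self.pca_components.T
        if np.max(np.abs(G - np.eye(self.r))) > 1e-6:
            raise ValueError("pca_components rows must be orthonormal")

    def checksum(self) -> str:
        h = hashlib.sha256()
        h.update(self.hvg_index.tobytes())
        h.update(np.asarray(self.pca_means).tobytes())
        h.update(np.asarray(self.pca_components).tobytes())
        return h.hexdigest()[:16]

    def save(self, path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), hvg_index=self.hvg_index,
                 pca_means=self.pca_means, pca_components=self.pca_components)
        meta = {"r": self.r, "library_scale": self.library_scale,
                "n_hvg": int(self.hvg_index.size),
                "checksum": self.checksum()}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path) -> "LatentBasis":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        with np.load(path.with_suffix(".npz")) as z:
            return cls(hvg_index=z["hvg_index"], pca_means=z["pca_means"],
                       pca_components=z["pca_components"], r=meta["r"],
                       library_scale=meta["library_scale"])


@dataclass
class ProcessedSeries:
    """Latent snapshots plus the basis that produced them."""

    times: np.ndarray
    latents: dict[float, np.ndarray]
    cell_types: dict[float, np.ndarray] | None = None
    basis: LatentBasis | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64)
        dims = {self.latents[float(t)].shape[1] for t in self.times}
        if len(dims) > 1:
            raise ValueError(f"inconsistent latent dimensions: {sorted(dims)}")

    @property
    def d(self) -> int:
        return next(iter(self.latents.values())).shape[1]

    def subset(self, times) -> "ProcessedSeries":
        times = np.asarray(times, dtype=np.float64)
        return ProcessedSeries(
            times=times,
            latents={float(t): self.latents[float(t)] for t in times},
            cell_types=None if self.cell_types is None else
            {float(t): self.cell_types[float(t)] for t in times},
            basis=self.basis)

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = {"times": self.times.tolist(), "d": self.d, "files": {}}
        for t in self.times:
            name = f"latent_t{t:g}.tsv"
            np.savetxt(outdir / name, self.latents[float(t)], delimiter="\t")
            manifest["files"][f"{t:g}"] = name
            if self.cell_types is not None:
                tname = f"types_t{t:g}.txt"
                np.savetxt(outdir / tname, self.cell_types[float(t)], fmt="%s")
                manifest.setdefault("type_files", {})[f"{t:g}"] = tname
        if self.basis is not None:
            self.basis.save(outdir / "basis")
            manifest["basis_checksum"] = self.basis.checksum()
            manifest["r"] = self.basis.r
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, outdir) -> "ProcessedSeries":
        outdir = Path(outdir)
        manifest = json.loads((outdir / "manifest.json").read_text())
        times = np.asarray(manifest["times"], dtype=np.float64)
        latents = {}
        types = {}
        for t in times:
            arr = np.loadtxt(outdir / manifest["files"][f"{t:g}"],
                             delimiter="\t", ndmin=2)
            latents[float(t)] = arr
            tfile = manifest.get("type_files", {}).get(f"{t:g}")
            if tfile:
                types[float(t)] = np.loadtxt(outdir / tfile, dtype=str, ndmin=1)
        basis = None
        if (outdir / "basis.json").exists():
            basis = LatentBasis.load(outdir / "basis")
        return cls(times=times, latents=latents,
                   cell_types=types or None, basis=basis)


# ---------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------

def normalize_log(counts: np.ndarray, scale: float = DEFAULT_SCALE) -> np.ndarray:
    """Library-size scale each cell to ``scale`` total, then log1p."""
    counts = np.asarray(counts, dtype=np.float64)
    totals = counts.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"cells with zero total count cannot be normalized: "
            f"rows {zero.tolist()[:20]}")
    return np.log1p(counts * (scale / totals[:, None]))


def _dispersion_stats(Y: np.ndarray, n_bins: int = 20):
    """Mean-binned normalized dispersion of each gene (column) of Y.

    ``Y`` is library-size-normalized (linear-scale) expression; dispersion
    is var/mean, z-scored within equal-occupancy bins of the gene mean —
    the usual highly-variable-gene convention.
    """
    mean = Y.mean(axis=0)
    var = Y.var(axis=0, ddof=1) if Y.shape[0] > 1 else np.zeros(Y.shape[1])
    disp = np.where(mean > 1e-12, var / np.maximum(mean, 1e-12), 0.0)
    # equal-occupancy bins over the mean ranking: deterministic, no edge cases
    order = np.argsort(mean, kind="stable")
    n_genes = Y.shape[1]
    bins = np.empty(n_genes, dtype=int)
    bins[order] = np.minimum(
        (np.arange(n_genes) * n_bins) // max(n_genes, 1), n_bins - 1)
    z = np.zeros(n_genes)
    for b in range(n_bins):
        sel = bins == b
        if not np.any(sel):
            continue
        mu_b = disp[sel].mean()
        sd_b = disp[sel].std(ddof=1) if sel.sum() > 1 else 0.0
        z[sel] = (disp[sel] - mu_b) / sd_b if sd_b > 0 else 0.0
    return z, disp, mean


def select_hvgs(counts_train: list[np.ndarray], n_hvg: int = DEFAULT_N_HVG,
                scale: float = DEFAULT_SCALE) -> np.ndarray:
    """Top ``n_hvg`` genes by normalized dispersion on pooled training cells.

    Deterministic: ties in the dispersion statistic break by gene index.
    """
    mats = [np.asarray(c) for c in counts_train]
    n_genes = mats[0].shape[1]
    if any(m.shape[1] != n_genes for m in mats):
        raise ValueError("training snapshots disagree on the gene axis")
    if n_genes < n_hvg:
        raise ValueError(
            f"cannot select {n_hvg} highly variable genes from only "
            f"{n_genes} genes")
    pooled = np.vstack(mats).astype(np.float64)
    totals = pooled.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError(
            f"cells with zero total count: rows "
            f"{np.flatnonzero(totals == 0).tolist()[:20]}")
    Y = pooled * (scale / totals[:, None])  # linear normalized expression
    z, _, _ = _dispersion_stats(Y)
    # a gene with zero raw variance can never be highly variable, even if
    # library-size normalization lends it apparent variation
    raw_var = pooled.astype(np.float64).var(axis=0)
    z = np.where(raw_var > 0, z, -np.inf)
    # sort by (-z, gene index): stable and fully deterministic
    order = np.lexsort((np.arange(n_genes), -z))
    return np.sort(order[:n_hvg])


def fit_pca(train_normalized: list[np.ndarray], r: int = DEFAULT_R,
            random_state: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA (centering only, no whitening) on pooled normalized training rows.

    Returns (means, components (r, n_genes), explained_variances).
    """
    pooled = np.vstack([np.asarray(m, dtype=np.float64)
                        for m in train_normalized])
    max_rank = min(pooled.shape)
    if r > max_rank:
        raise ValueError(
            f"r={r} exceeds the feasible rank {max_rank} of the pooled "
            f"training matrix {pooled.shape}")
    solver = "full" if max(pooled.shape) < 600 else "randomized"
    pca = PCA(n_components=r, svd_solver=solver, random_state=random_state)
    pca.fit(pooled)
    return pca.mean_, pca.components_, pca.explained_variance_


def transform(matrix: np.ndarray, basis: LatentBasis) -> np.ndarray:
    """Center by the training means and project onto the r components.

    ``matrix`` must already be restricted to the HVG gene order.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.shape[1] != basis.pca_means.size:
        raise ValueError(
            f"gene axis mismatch: matrix has {matrix.shape[1]} columns, "
            f"basis expects {basis.pca_means.size}")
    return (matrix - basis.pca_means) @ basis.pca_components.T


def inverse_transform(latent: np.ndarray, basis: LatentBasis) -> np.ndarray:
    """Map latent coordinates back to (centered-at-means) HVG space."""
    latent = np.asarray(latent, dtype=np.float64)
    if latent.shape[1] != basis.r:
        raise ValueError(
            f"latent has {latent.shape[1]} columns, basis r={basis.r}")
    return latent @ basis.pca_components + basis.pca_means


def preprocess_series(raw: RawSnapshotSeries,
                      train_times,
                      n_hvg: int = DEFAULT_N_HVG,
                      r: int = DEFAULT_R,
                      scale: float = DEFAULT_SCALE) -> ProcessedSeries:
    """Full pipeline; the basis is fitted on ``train_times`` only."""
    train_times = [float(t) for t in train_times]
    missing = [t for t in train_times if t not in
               {float(x) for x in raw.times}]
    if missing:
        raise ValueError(f"train times {missing} absent from the series")
    counts_train = [raw.counts[t] for t in train_times]
    hvg = select_hvgs(counts_train, n_hvg=n_hvg, scale=scale)
    norm_train = [normalize_log(c, scale)[:, hvg] for c in counts_train]
    means, components, _ = fit_pca(norm_train, r=r)
    basis = LatentBasis(hvg_index=hvg, library_scale=scale,
                        pca_means=means, pca_components=components, r=r)
    latents = {}
    for t in raw.times:
        Y = normalize_log(raw.counts[float(t)], scale)[:, hvg]
        latents[float(t)] = transform(Y, basis)
    return ProcessedSeries(times=raw.times.copy(), latents=latents,
                           cell_types=raw.cell_types, basis=basis)


# ---------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------

def load_raw_series(matrix_path, metadata_path, genes_path=None
                    ) -> RawSnapshotSeries:
    """Read counts (MTX sparse or dense delimited) + per-cell metadata.

    The metadata TSV needs columns ``cell_id`` and ``time`` (optionally
    ``cell_type``), one row per matrix row, in matrix order.  For MTX input
    a gene list (one id per line) is required; dense input takes gene ids
    from its header row.
    """
    matrix_path = Path(matrix_path)
    meta = pd.read_csv(metadata_path, sep="\t")
    for col in ("cell_id", "time"):
        if col not in meta.columns:
            raise ValueError(f"metadata is missing required column {col!r}")
    if matrix_path.suffix == ".mtx":
        from scipy.io import mmread
        mat = np.asarray(mmread(matrix_path).todense())
        if genes_path is None:
            raise ValueError("MTX input requires a gene-id file")
        gene_ids = Path(genes_path).read_text().split()
    else:
        df = pd.read_csv(matrix_path, sep="\t")
        gene_ids = list(df.columns)
        mat = df.to_numpy()
    if mat.shape[0] != len(meta):
        raise ValueError(
            f"matrix has {mat.shape[0]} rows but metadata {len(meta)}")
    times = np.asarray(sorted(meta["time"].unique()), dtype=np.float64)
    counts, types, ids = {}, {}, {}
    has_types = "cell_type" in meta.columns
    for t in times:
        sel = (meta["time"].to_numpy() == t)
        counts[float(t)] = np.asarray(mat[sel], dtype=np.int64)
        ids[float(t)] = meta.loc[sel, "cell_id"].to_numpy()
        if has_types:
            types[float(t)] = meta.loc[sel, "cell_type"].to_numpy()
    return RawSnapshotSeries(times=times, counts=counts, gene_ids=gene_ids,
                             cell_types=types if has_types else None,
                             cell_ids=ids)
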