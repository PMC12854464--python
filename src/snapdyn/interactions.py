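"""Interpretable artifacts from recorded attention.

The row-stochastic, zero-diagonal attention matrices produced by the drift
model quantify the directed influence of source cells (columns/keys) on
target cells (rows/queries).  This module turns them into display and
analysis artifacts: per-time cell-wise matrices ordered by cell type,
cell-type-aggregated directed networks, an asymmetry index, and rank
concordance against an externally produced ligand–receptor score table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .drift import AttentionRecord, DriftModel

__all__ = [
    "InteractionNetwork", "ConcordanceResult", "attention_snapshot",
    "aggregate_by_type", "asymmetry_index", "concordance_with_external",
    "export_network", "import_network_tsv",
]


@dataclass
class InteractionNetwork:
    """Directed type-level network: weights[a, b] = mean attention paid by
    targets of type a to sources of type b (influence b -> a)."""

    types: list[str]
    weights: np.ndarray  # (K, K), >= 0; diagonal = within-type (i != j)
    time: float | None = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        k = len(self.types)
        if self.weights.shape != (k, k):
            raise ValueError("weights must be K x K for K types")
        if np.any(self.weights < 0):
            raise ValueError("attention-derived weights must be >= 0")

    def weight(self, source: str, target: str) -> float:
        """Mean attention for the directed influence source -> target."""
        a = self.types.index(target)
        b = self.types.index(source)
        return float(self.weights[a, b])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a, tgt in enumerate(self.types):
            for b, src in enumerate(self.types):
                rows.append({"source_type": src, "target_type": tgt,
                             "weight": float(self.weights[a, b]),
                             "time": self.time})
        return pd.DataFrame(rows)


@dataclass
class ConcordanceResult:
    """Spearman agreement between attention and external interaction scores."""

    pairs: pd.DataFrame  # retained (source_type, target_type, attention, external)
    spearman_rho: float
    n_pairs: int
    min_external: float
    min_attention: float

    @property
    def reliable(self) -> bool:
        return self.n_pairs >= 3


def attention_snapshot(model: DriftModel, snapshot: np.ndarray,
                       cell_types: np.ndarray | None = None,
                       max_cells: int = 500, seed: int = 0,
                       order_by_type: bool = False,
                       time: float | None = None) -> AttentionRecord:
    """Dropout-free attention record at one snapshot.

    Snapshots larger than ``max_cells`` are uniformly subsampled (seeded)
    since the N x N matrix is a display/aggregation artifact.  With
    ``order_by_type`` cells are sorted by their type label so heatmap
    blocks line up; the permutation is recorded in ``cell_index``.
    """
    X = np.asarray(snapshot, dtype=np.float64)
    n = X.shape[0]
    if n < 2:
        raise ValueError("attention needs at least two cells")
    idx = np.arange(n)
    if n > max_cells:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(n, size=max_cells, replace=False))
    types = None if cell_types is None else np.asarray(cell_types)[idx]
    if order_by_type:
        if types is None:
            raise ValueError("ordering by type requires cell-type labels")
        order = np.argsort(types, kind="stable")
        idx = idx[order]
        types = types[order]
    _, record = model.total_drift(X[idx])
    record.time = time
    record.cell_index = idx
    return record


def aggregate_by_type(record: AttentionRecord,
                      cell_types: np.ndarray,
                      time: float | None = None) -> InteractionNetwork:
    """Mean attention over (target type, source type) cell pairs.

    weights[a, b] averages A[i, j] over targets i of type a and sources j
    of type b with i != j (the mask already removes self-pairs; within-type
    blocks keep all distinct-cell pairs).  Types present in the labels but
    with no cells contributing to a block are reported as NaN-free by
    construction — every labelled type has at least one cell.
    """
    A = record.head_average
    cell_types = np.asarray(cell_types)
    if cell_types.size != A.shape[0]:
        raise ValueError(
            f"{cell_types.size} labels for {A.shape[0]} cells")
    types = sorted(set(cell_types.tolist()))
    k = len(types)
    weights = np.zeros((k, k))
    masks = {ty: cell_types == ty for ty in types}
    offdiag = ~np.eye(A.shape[0], dtype=bool)
    for a, ta in enumerate(types):
        for b, tb in enumerate(types):
            block_mask = np.outer(masks[ta], masks[tb]) & offdiag
            n_pairs = block_mask.sum()
            weights[a, b] = A[block_mask].mean() if n_pairs else 0.0
    return InteractionNetwork(types=types, weights=weights,
                              time=record.time if time is None else time)


def asymmetry_index(M: np.ndarray) -> float:
    """Directionality of a square interaction matrix, in [0, 1].

    ||M - M^T||_F / (||M||_F + ||M^T||_F): zero for symmetric M, rising
    toward one as the structure becomes maximally anti-symmetric.  Reported
    per time point, it exposes e.g. in-vivo vs in-vitro contrasts in how
    reciprocal the inferred communication is.
    """
    M = np.asarray(M, dtype=np.float64)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"asymmetry index needs a square matrix, got {M.shape}")
    denom = 2.0 * np.linalg.norm(M)
    if denom == 0:
        return 0.0
    return float(np.linalg.norm(M - M.T) / denom)


def concordance_with_external(network: InteractionNetwork,
                              external_scores: pd.DataFrame,
                              min_external: float = 0.005,
                              min_attention: float = 0.001
                              ) -> ConcordanceResult:
    """Spearman rank agreement with an external interaction score table.

    ``external_scores`` must have columns source_type, target_type, score
    (e.g. aggregated ligand–receptor communication strengths).  Only
    directed pairs of *distinct* types passing both thresholds are
    retained; fewer than 3 retained pairs is flagged unreliable (rho NaN
    when fewer than 2).
    """
    for col in ("source_type", "target_type", "score"):
        if col not in external_scores.columns:
            raise ValueError(f"external table is missing column {col!r}")
    att = network.to_frame()
    att = att[att["source_type"] != att["target_type"]]
    merged = att.merge(external_scores, on=["source_type", "target_type"],
                       how="inner", suffixes=("_attention", "_external"))
    if merged.empty:
        return ConcordanceResult(pairs=merged, spearman_rho=float("nan"),
                                 n_pairs=0, min_external=min_external,
                                 min_attention=min_attention)
    keep = (merged["score"] >= min_external) & \
           (merged["weight"] >= min_attention)
    retained = merged[keep].reset_index(drop=True)
    if len(retained) < 2:
        rho = float("nan")
    else:
        rho = float(spearmanr(retained["weight"], retained["score"]).statistic)
    return ConcordanceResult(pairs=retained, spearman_rho=rho,
                             n_pairs=len(retained),
                             min_external=min_external,
                             min_attention=min_attention)


def export_network(network: InteractionNetwork, path, fmt: str = "tsv") -> None:
    """Write the directed weighted network as a TSV edge list or GraphML."""
    path = Path(path)
    if fmt == "tsv":
        network.to_frame().to_csv(path, sep="\t", index=False)
    elif fmt == "graphml":
        import networkx as nx

        g = nx.DiGraph()
        for ty in network.types:
            g.add_node(ty)
        for _, row in network.to_frame().iterrows():
            g.add_edge(row["source_type"], row["target_type"],
                       weight=float(row["weight"]))
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def import_network_tsv(path) -> InteractionNetwork:
    df = pd.read_csv(path, sep="\t")
    types = sorted(set(df["source_type"]) | set(df["target_type"]))
    k = len(types)
    weights = np.zeros((k, k))
    for _, row in df.iterrows():
        a = types.index(row["target_type"])
        b = types.index(row["source_type"])
        weights[a, b] = row["weight"]
    time = df["time"].iloc[0] if "time" in df.columns and len(df) else None
    time = None if pd.isna(time) else time
    return InteractionNetwork(types=types, weights=weights, time=time)
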