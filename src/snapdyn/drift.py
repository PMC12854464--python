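"""Distribution-dependent drift of the interacting cell SDE.

The drift of every cell decomposes as

    f(x, rho) = f_intra(x) + f_inter(x, rho)

where ``f_intra`` is a small two-layer MLP acting on each cell's own state
and ``f_inter`` couples a cell to the empirical population ``rho`` — here
represented by the batch of cells itself — through masked multi-head
cell-wise self-attention.  Each cell's expression vector is a token; the
attention score A[i, j] quantifies the influence of source cell j (key) on
target cell i (query).  The diagonal is masked so a cell never attends to
itself, keeping self-influence entirely inside ``f_intra``.

The interaction head is a single attention layer followed by a residual
connection, layer normalization, and a two-layer feed-forward readout:

    f_inter(X) = FFN(LN(X + MultiHead(X)))

With the feed-forward output layer at zero the interaction drift is exactly
zero, so the model reduces bitwise to an ordinary (Itô) single-particle SDE
— a property the tests pin down.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor


@dataclass
class ArchConfig:
    """Architecture of the drift network.

    Parameters
    ----------
    d : state (latent) dimension.
    intra_hidden : width of the intra-cellular MLP hidden layer.
    n_heads : number of attention heads H (distinct interaction channels).
    d_k : query/key dimension per head; defaults to max(1, d // n_heads).
    d_ff : width of the feed-forward readout of the interaction block.
    dropout : dropout rate on attention probabilities and FFN activations
        (training only; recorded attention is always dropout-free).
    leaky_slope : negative slope of the leaky rectifier activations.
    mask_mode : "pre_softmax" masks the diagonal before the row softmax
        (rows renormalize over peers); "post_softmax" zeroes the diagonal
        after an unmasked softmax and renormalizes the rows.
    """

    d: int
    intra_hidden: int = 256
    n_heads: int = 2
    d_k: int | None = None
    d_ff: int = 256
    dropout: float = 0.1
    leaky_slope: float = 0.01
    mask_mode: str = "pre_softmax"

    def __post_init__(self):
        if self.d < 1:
            raise ValueError(f"state dimension must be >= 1, got {self.d}")
        if self.n_heads < 1:
            raise ValueError(f"need >= 1 attention head, got {self.n_heads}")
        if self.d_k is None:
            self.d_k = max(1, self.d // self.n_heads)
        if self.d_k < 1:
            raise ValueError(f"d_k must be >= 1, got {self.d_k}")
        if self.mask_mode not in ("pre_softmax", "post_softmax"):
            raise ValueError(f"unknown mask_mode {self.mask_mode!r}")


@dataclass
class AttentionRecord:
    """Per-head N x N attention scores at one time point.

    Rows are targets (queries), columns sources (keys).  Every diagonal
    entry is exactly zero and, for N >= 2, every row sums to one.
    """

    heads: list[np.ndarray]
    time: float | None = None
    cell_index: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return self.heads[0].shape[0]

    @property
    def head_average(self) -> np.ndarray:
        return np.mean(self.heads, axis=0)

    def validate(self, atol: float = 1e-6) -> None:
        for a in self.heads:
            if a.shape[0] != a.shape[1]:
                raise ValueError("attention matrix must be square")
            if np.any(np.diagonal(a) != 0.0):
                raise ValueError("attention diagonal must be exactly zero")
            if np.any(a < 0) or np.any(a > 1):
                raise ValueError("attention entries must lie in [0, 1]")
            if a.shape[0] >= 2:
                rows = a.sum(axis=1)
                if np.max(np.abs(rows - 1.0)) > atol:
                    raise ValueError("attention rows must sum to 1")


def init_params(arch: ArchConfig, rng: np.random.Generator,
                zero_final: bool = True) -> dict[str, np.ndarray]:
    """Glorot-initialized parameter arrays for the drift network.

    With ``zero_final`` the output layers of both the intra MLP and the
    interaction FFN start at zero, so the initial drift field is identically
    zero and training starts from the identity flow.
    """
    d, h = arch.d, arch.intra_hidden

    def glorot(n_in, n_out):
        s = np.sqrt(6.0 / (n_in + n_out))
        return rng.uniform(-s, s, size=(n_in, n_out))

    p = {
        "intra.W1": glorot(d, h),
        "intra.b1": np.zeros(h),
        "intra.W2": np.zeros((h, d)) if zero_final else glorot(h, d),
        "intra.b2": np.zeros(d),
        "attn.Wo": glorot(arch.n_heads * d, d),
        "ln.gamma": np.ones(d),
        "ln.beta": np.zeros(d),
        "ffn.W1": glorot(d, arch.d_ff),
        "ffn.b1": np.zeros(arch.d_ff),
        "ffn.W2": np.zeros((arch.d_ff, d)) if zero_final else glorot(arch.d_ff, d),
        "ffn.b2": np.zeros(d),
    }
    for hh in range(arch.n_heads):
        p[f"head{hh}.Wq"] = glorot(d, arch.d_k)
        p[f"head{hh}.Wk"] = glorot(d, arch.d_k)
        p[f"head{hh}.Wv"] = glorot(d, d)
    return p


INTER_KEYS_PREFIXES = ("head", "attn.", "ln.", "ffn.")
INTRA_KEYS_PREFIXES = ("intra.",)


def zero_inter(params: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Copy of ``params`` with every interaction parameter zeroed."""
    out = {}
    for k, v in params.items():
        out[k] = np.zeros_like(v) if k.startswith(INTER_KEYS_PREFIXES) else v.copy()
    return out


def zero_intra(params: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Copy of ``params`` with the intra-cellular MLP zeroed."""
    out = {}
    for k, v in params.items():
        out[k] = np.zeros_like(v) if k.startswith(INTRA_KEYS_PREFIXES) else v.copy()
    return out


def _check_finite(X: np.ndarray, stage: str) -> None:
    if not np.all(np.isfinite(X)):
        raise FloatingPointError(f"non-finite values encountered in {stage}")


# ---------------------------------------------------------------------
# forward passes (autodiff tensors; pass plain arrays for inference)
# ---------------------------------------------------------------------

def intra_drift_t(X, params: dict, arch: ArchConfig) -> Tensor:
    """Intra-cellular drift: row-wise two-layer MLP with leaky rectifier."""
    h = ad.leaky_relu(ad.linear(X, params["intra.W1"], params["intra.b1"]),
                      arch.leaky_slope)
    return ad.linear(h, params["intra.W2"], params["intra.b2"])


def masked_attention_t(X, Wq, Wk, Wv, d_k: int,
                       mask_mode: str = "pre_softmax") -> tuple[Tensor, Tensor]:
    """One attention head over cells with the diagonal masked out.

    Returns the row-stochastic score matrix A (zero diagonal) and the
    head output Y = A V.  For a single cell there are no peers: A is the
    1 x 1 zero matrix and the output is zero.
    """
    n = X.shape[0] if isinstance(X, Tensor) else np.asarray(X).shape[0]
    if n == 1:
        z = ad.constant(np.zeros((1, 1)))
        d = Wv.shape[1] if isinstance(Wv, Tensor) else np.asarray(Wv).shape[1]
        return z, ad.constant(np.zeros((1, d)))
    Q = ad.matmul(X, Wq)
    K = ad.matmul(X, Wk)
    V = ad.matmul(X, Wv)
    logits = ad.scale(ad.matmul(Q, ad.transpose(K)), 1.0 / np.sqrt(d_k))
    offdiag = 1.0 - np.eye(n)
    if mask_mode == "pre_softmax":
        A = ad.masked_softmax(logits, offdiag)
    else:  # post_softmax: unmasked softmax, zero the diagonal, renormalize
        P = ad.masked_softmax(logits, np.ones((n, n)))
        P = ad.mul(P, ad.constant(offdiag))
        rows = ad.sum_(P, axis=1, keepdims=True)
        A = ad.mul(P, ad.exp(ad.scale(ad.log(rows), -1.0)))
    return A, ad.matmul(A, V)


def inter_drift_t(X, params: dict, arch: ArchConfig,
                  training: bool = False,
                  dropout_rng: np.random.Generator | None = None,
                  ) -> tuple[Tensor, AttentionRecord]:
    """Interaction drift from masked multi-head attention + FFN readout.

    Dropout (on attention probabilities and FFN activations) is applied only
    when ``training`` is set; the returned :class:`AttentionRecord` always
    holds the dropout-free scores.
    """
    Xt = ad.constant(X)
    heads_out = []
    record_heads = []
    p_drop = arch.dropout if training else 0.0
    for hh in range(arch.n_heads):
        A, Y = masked_attention_t(Xt, params[f"head{hh}.Wq"],
                                  params[f"head{hh}.Wk"],
                                  params[f"head{hh}.Wv"],
                                  arch.d_k, arch.mask_mode)
        record_heads.append(A.data.copy())
        if p_drop > 0.0 and dropout_rng is not None and A.shape[0] > 1:
            keep = (dropout_rng.random(A.shape) >= p_drop) / (1.0 - p_drop)
            Adrop = ad.mul(A, ad.constant(keep))
            Wv = params[f"head{hh}.Wv"]
            Y = ad.matmul(Adrop, ad.matmul(Xt, Wv))
        heads_out.append(Y)
    concat = heads_out[0] if arch.n_heads == 1 else ad.concat(heads_out, axis=1)
    mixed = ad.matmul(concat, params["attn.Wo"])
    Z = ad.layer_norm(ad.add(Xt, mixed), params["ln.gamma"], params["ln.beta"])
    Hact = ad.leaky_relu(ad.linear(Z, params["ffn.W1"], params["ffn.b1"]),
                         arch.leaky_slope)
    if p_drop > 0.0 and dropout_rng is not None:
        keep = (dropout_rng.random(Hact.shape) >= p_drop) / (1.0 - p_drop)
        Hact = ad.mul(Hact, ad.constant(keep))
    out = ad.linear(Hact, params["ffn.W2"], params["ffn.b2"])
    _check_finite(out.data, "inter_drift output")
    record = AttentionRecord(heads=record_heads)
    return out, record


def total_drift_t(X, params: dict, arch: ArchConfig,
                  training: bool = False,
                  dropout_rng: np.random.Generator | None = None,
                  interacting: bool = True,
                  ) -> tuple[Tensor, AttentionRecord | None]:
    """f = f_intra + f_inter; the batch rows stand in for the law rho_t."""
    Xt = ad.constant(X)
    intra = intra_drift_t(Xt, params, arch)
    if not interacting:
        return intra, None
    inter, record = inter_drift_t(Xt, params, arch, training, dropout_rng)
    return ad.add(intra, inter), record


# ---------------------------------------------------------------------
# numpy-facing wrappers (inference surface)
# ---------------------------------------------------------------------

@dataclass
class DriftModel:
    """Drift network plus diffusion constant: the full SDE specification.

    ``sigma`` is the constant isotropic diffusion strength; ``sigma = 0``
    gives a deterministic flow.
    """

    arch: ArchConfig
    sigma: float = 0.1
    params: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")

    @classmethod
    def initialize(cls, arch: ArchConfig, sigma: float = 0.1,
                   seed: int | np.random.Generator = 0,
                   zero_final: bool = True) -> "DriftModel":
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        return cls(arch=arch, sigma=sigma,
                   params=init_params(arch, rng, zero_final=zero_final))

    def _tensor_params(self) -> dict[str, Tensor]:
        return {k: ad.Tensor(v) for k, v in self.params.items()}

    def intra_drift(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        _check_finite(X, "intra_drift input")
        return intra_drift_t(ad.constant(X), self.params, self.arch).data

    def inter_drift(self, X: np.ndarray,
                    training: bool = False,
                    dropout_rng: np.random.Generator | None = None,
                    ) -> tuple[np.ndarray, AttentionRecord]:
        X = np.asarray(X, dtype=np.float64)
        _check_finite(X, "inter_drift input")
        out, rec = inter_drift_t(X, self.params, self.arch, training, dropout_rng)
        return out.data, rec

    def total_drift(self, X: np.ndarray,
                    interacting: bool = True,
                    ) -> tuple[np.ndarray, AttentionRecord | None]:
        X = np.asarray(X, dtype=np.float64)
        _check_finite(X, "total_drift input")
        out, rec = total_drift_t(X, self.params, self.arch,
                                 interacting=interacting)
        return out.data, rec

    def masked_attention(self, X: np.ndarray, head: int = 0) -> np.ndarray:
        """Score matrix of one head (inference; dropout-free)."""
        X = np.asarray(X, dtype=np.float64)
        A, _ = masked_attention_t(ad.constant(X),
                                  ad.constant(self.params[f"head{head}.Wq"]),
                                  ad.constant(self.params[f"head{head}.Wk"]),
                                  ad.constant(self.params[f"head{head}.Wv"]),
                                  self.arch.d_k, self.arch.mask_mode)
        return A.data

    # -- persistence --------------------------------------------------
    def save(self, path) -> None:
        """Checkpoint: npz of parameter arrays + JSON sidecar of shapes."""
        import json
        from pathlib import Path

        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.params)
        meta = {
            "d": self.arch.d, "intra_hidden": self.arch.intra_hidden,
            "n_heads": self.arch.n_heads, "d_k": self.arch.d_k,
            "d_ff": self.arch.d_ff, "dropout": self.arch.dropout,
            "leaky_slope": self.arch.leaky_slope,
            "mask_mode": self.arch.mask_mode, "sigma": self.sigma,
            "param_shapes": {k: list(v.shape) for k, v in self.params.items()},
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path) -> "DriftModel":
        import json
        from pathlib import Path

        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        arch = ArchConfig(d=meta["d"], intra_hidden=meta["intra_hidden"],
                          n_heads=meta["n_heads"], d_k=meta["d_k"],
                          d_ff=meta["d_ff"], dropout=meta["dropout"],
                          leaky_slope=meta["leaky_slope"],
                          mask_mode=meta["mask_mode"])
        with np.load(path.with_suffix(".npz")) as z:
            params = {k: z[k] for k in z.files}
        return cls(arch=arch, sigma=meta["sigma"], params=params)
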