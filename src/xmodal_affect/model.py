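"""Dual-branch representation learner with bidirectional multi-head cross attention.

Two identical convolutional streams turn the EEG and peripheral feature
sequences into high-level temporal representations (Conv1D -> activation
-> max-pool -> batch norm -> dropout, cascaded three times).  The two
streams are then fused bidirectionally: one attention module uses the
peripheral sequence as queries against EEG keys/values, the other uses
the EEG sequence as queries against peripheral keys/values, and the two
outputs are concatenated along the feature axis.  A temporal mean-pool
and a small fully connected head produce class probabilities.

Everything is implemented directly on NumPy arrays with hand-derived
backward passes, so analytic gradients can be verified against central
differences and training is reproducible bit-for-bit from a seed.
Sequences are batched as ``[batch, time, features]``; the spec-level
functional operations accept single ``[time, features]`` matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConvBlockSpec",
    "AttentionSpec",
    "ModelConfig",
    "FusedRepresentation",
    "default_model_config",
    "scaled_dot_attention",
    "softmax",
    "init_attention_params",
    "identity_attention_params",
    "multi_head",
    "conv_block",
    "branch_forward",
    "cross_attention_fuse",
    "classify",
    "CrossAttentionClassifier",
]

BN_EPS = 1e-5


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConvBlockSpec:
    """One convolutional block: Conv1D -> activation -> max-pool -> BN -> dropout."""

    n_filters: int = 64
    kernel_size: int = 3
    pool_size: int = 2
    dropout_rate: float = 0.3
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.kernel_size < 1 or self.pool_size < 1 or self.n_filters < 1:
            raise ValueError("n_filters, kernel_size and pool_size must be >= 1")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.activation not in ("relu", "linear"):
            raise ValueError(f"unsupported activation {self.activation!r}")


@dataclass(frozen=True)
class AttentionSpec:
    """Multi-head attention geometry: h heads over key/value subspaces."""

    n_heads: int = 4
    model_dim: int = 64
    key_dim: int = 64
    value_dim: int = 64

    def __post_init__(self) -> None:
        if self.n_heads < 1:
            raise ValueError("n_heads must be >= 1")
        if self.key_dim % self.n_heads or self.value_dim % self.n_heads:
            raise ValueError(
                f"key_dim ({self.key_dim}) and value_dim ({self.value_dim}) "
                f"must be divisible by n_heads ({self.n_heads})"
            )

    @property
    def head_key_dim(self) -> int:
        return self.key_dim // self.n_heads

    @property
    def head_value_dim(self) -> int:
        return self.value_dim // self.n_heads


@dataclass(frozen=True)
class ModelConfig:
    """Full architecture: three conv blocks per branch, attention, classifier head."""

    eeg_branch: tuple[ConvBlockSpec, ...]
    peri_branch: tuple[ConvBlockSpec, ...]
    attention: AttentionSpec
    n_classes: int = 2
    fc_hidden: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        for name, branch in (("eeg_branch", self.eeg_branch), ("peri_branch", self.peri_branch)):
            if len(branch) != 3:
                raise ValueError(f"{name} must have exactly 3 conv blocks, got {len(branch)}")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.fc_hidden < 1:
            raise ValueError("fc_hidden must be >= 1")


def default_model_config(n_classes: int = 2, seed: int = 0, *,
                         dropout_rate: float = 0.3,
                         n_heads: int = 4, model_dim: int = 64,
                         fc_hidden: int = 64) -> ModelConfig:
    """Conventional small-model defaults: filters (64, 128, 128), kernel 3, pool 2."""
    blocks = tuple(
        ConvBlockSpec(n_filters=f, kernel_size=3, pool_size=2, dropout_rate=dropout_rate)
        for f in (64, 128, 128)
    )
    att = AttentionSpec(n_heads=n_heads, model_dim=model_dim,
                        key_dim=model_dim, value_dim=model_dim)
    return ModelConfig(eeg_branch=blocks, peri_branch=blocks, attention=att,
                       n_classes=n_classes, fc_hidden=fc_hidden, seed=seed)


@dataclass
class FusedRepresentation:
    """Concatenated bidirectional cross-attention outputs ([windows x 2*model_dim])."""

    values: np.ndarray
    attention_eeg: np.ndarray
    attention_peri: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("fused representation contains NaN/Inf")
        if self.values.shape[-1] != self.attention_eeg.shape[-1] + self.attention_peri.shape[-1]:
            raise ValueError("fused width must be the sum of the two attention widths")


# ---------------------------------------------------------------------------
# Primitive forward/backward ops (batched [B, T, C])
# ---------------------------------------------------------------------------

def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def _uniform_fan_in(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(max(1, fan_in))
    return rng.uniform(-bound, bound, size=shape)


def _conv1d_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Same-padded 1-D convolution over time. x [B,T,Cin], W [k,Cin,Cout]."""
    B, T, _ = x.shape
    k = W.shape[0]
    pl, pr = (k - 1) // 2, k // 2
    xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
    y = np.zeros((B, T, W.shape[2]))
    for j in range(k):
        y += xp[:, j : j + T, :] @ W[j]
    return y + b, (xp, W, x.shape)


def _conv1d_backward(dy: np.ndarray, cache):
    xp, W, x_shape = cache
    B, T, _ = x_shape
    k = W.shape[0]
    pl = (k - 1) // 2
    db = dy.sum(axis=(0, 1))
    dW = np.zeros_like(W)
    dxp = np.zeros_like(xp)
    for j in range(k):
        dW[j] = np.einsum("btc,btf->cf", xp[:, j : j + T, :], dy)
        dxp[:, j : j + T, :] += dy @ W[j].T
    dx = dxp[:, pl : pl + T, :]
    return dx, dW, db


def _relu_forward(x: np.ndarray):
    mask = x > 0
    return x * mask, mask


def _maxpool_forward(x: np.ndarray, pool: int):
    """Non-overlapping temporal max-pool with trailing-sample discard."""
    B, T, C = x.shape
    Tt = T // pool
    if Tt < 1:
        raise ValueError(f"sequence length {T} shorter than pool size {pool}")
    xt = x[:, : Tt * pool, :].reshape(B, Tt, pool, C)
    idx = np.argmax(xt, axis=2)
    y = np.take_along_axis(xt, idx[:, :, None, :], axis=2)[:, :, 0, :]
    return y, (idx, x.shape, pool)


def _maxpool_backward(dy: np.ndarray, cache):
    idx, x_shape, pool = cache
    B, T, C = x_shape
    Tt = T // pool
    dxt = np.zeros((B, Tt, pool, C))
    np.put_along_axis(dxt, idx[:, :, None, :], dy[:, :, None, :], axis=2)
    dx = np.zeros(x_shape)
    dx[:, : Tt * pool, :] = dxt.reshape(B, Tt * pool, C)
    return dx


def _batchnorm_forward(x: np.ndarray, gamma: np.ndarray, beta: np.ndarray,
                       state: dict, mode: str, update_stats: bool, momentum: float = 0.1):
    """Per-channel normalization over the batch and time axes."""
    if mode == "train":
        mu = x.mean(axis=(0, 1))
        var = x.var(axis=(0, 1))
        if update_stats:
            state["mean"] = (1 - momentum) * state["mean"] + momentum * mu
            state["var"] = (1 - momentum) * state["var"] + momentum * var
    else:
        mu, var = state["mean"], state["var"]
    ivar = 1.0 / np.sqrt(var + BN_EPS)
    xhat = (x - mu) * ivar
    return gamma * xhat + beta, (xhat, ivar, gamma, mode)


def _batchnorm_backward(dy: np.ndarray, cache):
    xhat, ivar, gamma, mode = cache
    dgamma = np.sum(dy * xhat, axis=(0, 1))
    dbeta = np.sum(dy, axis=(0, 1))
    dxhat = dy * gamma
    if mode == "train":
        N = dy.shape[0] * dy.shape[1]
        dx = (ivar / N) * (
            N * dxhat
            - np.sum(dxhat, axis=(0, 1))
            - xhat * np.sum(dxhat * xhat, axis=(0, 1))
        )
    else:
        dx = dxhat * ivar
    return dx, dgamma, dbeta


def _dropout_forward(x: np.ndarray, rate: float, mode: str, rng: np.random.Generator | None):
    if mode != "train" or rate == 0.0:
        return x, None
    if rng is None:
        raise ValueError("dropout in train mode requires an RNG")
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * mask, mask


# ---------------------------------------------------------------------------
# Attention
# ---------------------------------------------------------------------------

def scaled_dot_attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray,
                         return_weights: bool = False):
    """softmax(Q K^T / sqrt(d_k)) V on single matrices.

    ``d_k`` is the shared column dimension of Q and K; each output row is
    a convex combination of the rows of V.
    """
    Q, K, V = (np.asarray(a, dtype=float) for a in (Q, K, V))
    if Q.shape[1] != K.shape[1]:
        raise ValueError(f"Q width {Q.shape[1]} != K width {K.shape[1]}")
    if K.shape[0] != V.shape[0]:
        raise ValueError(f"K rows {K.shape[0]} != V rows {V.shape[0]}")
    scores = (Q @ K.T) / np.sqrt(Q.shape[1])
    weights = softmax(scores, axis=-1)
    out = weights @ V
    return (out, weights) if return_weights else out


def init_attention_params(spec: AttentionSpec, d_query_in: int, d_kv_in: int,
                          rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Seeded uniform fan-in initialization of the per-head projections."""
    h, dk, dv = spec.n_heads, spec.head_key_dim, spec.head_value_dim
    return {
        "Wq": _uniform_fan_in(rng, (h, d_query_in, dk), d_query_in),
        "Wk": _uniform_fan_in(rng, (h, d_kv_in, dk), d_kv_in),
        "Wv": _uniform_fan_in(rng, (h, d_kv_in, dv), d_kv_in),
        "Wo": _uniform_fan_in(rng, (spec.value_dim, spec.model_dim), spec.value_dim),
    }


def identity_attention_params(spec: AttentionSpec, dim: int) -> dict[str, np.ndarray]:
    """Identity projections (single-head reduction case); requires matching dims."""
    if spec.n_heads != 1 or spec.head_key_dim != dim or spec.head_value_dim != dim \
            or spec.model_dim != dim:
        raise ValueError("identity projections need h=1 and all dims equal to `dim`")
    eye = np.eye(dim)
    return {"Wq": eye[None], "Wk": eye[None], "Wv": eye[None], "Wo": eye.copy()}


def _multi_head_forward(Q: np.ndarray, K: np.ndarray, V: np.ndarray,
                        params: dict[str, np.ndarray]):
    """Batched multi-head attention. Q [B,m,Dq], K/V [B,n,Dkv]."""
    Wq, Wk, Wv, Wo = params["Wq"], params["Wk"], params["Wv"], params["Wo"]
    dh = Wq.shape[2]
    Qh = np.einsum("bmd,hdk->bhmk", Q, Wq)
    Kh = np.einsum("bnd,hdk->bhnk", K, Wk)
    Vh = np.einsum("bnd,hdv->bhnv", V, Wv)
    S = np.einsum("bhmk,bhnk->bhmn", Qh, Kh) / np.sqrt(dh)
    A = softmax(S, axis=-1)
    Oh = np.einsum("bhmn,bhnv->bhmv", A, Vh)
    B, h, m, dv = Oh.shape
    concat = Oh.transpose(0, 2, 1, 3).reshape(B, m, h * dv)
    out = concat @ Wo
    cache = (Q, K, V, Qh, Kh, Vh, A, concat, params)
    return out, cache


def _multi_head_backward(dout: np.ndarray, cache):
    Q, K, V, Qh, Kh, Vh, A, concat, params = cache
    Wq, Wk, Wv, Wo = params["Wq"], params["Wk"], params["Wv"], params["Wo"]
    dh = Wq.shape[2]
    B, h, m, dv = A.shape[0], Wq.shape[0], Q.shape[1], Wv.shape[2]

    dWo = np.einsum("bmd,bme->de", concat, dout)
    dconcat = dout @ Wo.T
    dOh = dconcat.reshape(B, m, h, dv).transpose(0, 2, 1, 3)

    dA = np.einsum("bhmv,bhnv->bhmn", dOh, Vh)
    dVh = np.einsum("bhmn,bhmv->bhnv", A, dOh)
    dS = A * (dA - np.sum(dA * A, axis=-1, keepdims=True))
    dS /= np.sqrt(dh)
    dQh = np.einsum("bhmn,bhnk->bhmk", dS, Kh)
    dKh = np.einsum("bhmn,bhmk->bhnk", dS, Qh)

    dQ = np.einsum("bhmk,hdk->bmd", dQh, Wq)
    dK = np.einsum("bhnk,hdk->bnd", dKh, Wk)
    dV = np.einsum("bhnv,hdv->bnd", dVh, Wv)
    grads = {
        "Wq": np.einsum("bmd,bhmk->hdk", Q, dQh),
        "Wk": np.einsum("bnd,bhnk->hdk", K, dKh),
        "Wv": np.einsum("bnd,bhnv->hdv", V, dVh),
        "Wo": dWo,
    }
    return dQ, dK, dV, grads


def multi_head(Q: np.ndarray, K: np.ndarray, V: np.ndarray, spec: AttentionSpec,
               params: dict[str, np.ndarray], return_weights: bool = False):
    """Multi-head attention on single matrices (spec-level surface).

    Projects Q, K, V into ``n_heads`` subspaces, runs scaled dot-product
    attention in parallel, concatenates the heads and applies the output
    projection.
    """
    Q, K, V = (np.asarray(a, dtype=float) for a in (Q, K, V))
    out, cache = _multi_head_forward(Q[None], K[None], V[None], params)
    if return_weights:
        A = cache[6][0]  # [h, m, n]
        return out[0], A
    return out[0]


# ---------------------------------------------------------------------------
# Spec-level functional blocks (single [T x F] matrices)
# ---------------------------------------------------------------------------

def _init_conv_block_params(spec: ConvBlockSpec, n_in: int,
                            rng: np.random.Generator) -> dict[str, np.ndarray]:
    fan_in = spec.kernel_size * n_in
    return {
        "W": _uniform_fan_in(rng, (spec.kernel_size, n_in, spec.n_filters), fan_in),
        "b": np.zeros(spec.n_filters),
        "gamma": np.ones(spec.n_filters),
        "beta": np.zeros(spec.n_filters),
    }


def _conv_block_forward(x: np.ndarray, spec: ConvBlockSpec, params: dict,
                        state: dict | None, mode: str, update_stats: bool,
                        rng: np.random.Generator | None):
    """Batched conv block; returns output and the caches for backward."""
    if x.shape[1] < spec.kernel_size:
        raise ValueError(
            f"sequence length {x.shape[1]} shorter than kernel size {spec.kernel_size}"
        )
    y, conv_cache = _conv1d_forward(x, params["W"], params["b"])
    if spec.activation == "relu":
        y, act_cache = _relu_forward(y)
    else:
        act_cache = None
    y, pool_cache = _maxpool_forward(y, spec.pool_size)
    if "gamma" in params:
        if state is None:
            state = {"mean": np.zeros(spec.n_filters), "var": np.ones(spec.n_filters)}
        y, bn_cache = _batchnorm_forward(y, params["gamma"], params["beta"],
                                         state, mode, update_stats)
    else:
        bn_cache = None
    y, drop_mask = _dropout_forward(y, spec.dropout_rate, mode, rng)
    return y, (conv_cache, act_cache, pool_cache, bn_cache, drop_mask)


def _conv_block_backward(dy: np.ndarray, cache):
    conv_cache, act_cache, pool_cache, bn_cache, drop_mask = cache
    grads: dict[str, np.ndarray] = {}
    if drop_mask is not None:
        dy = dy * drop_mask
    if bn_cache is not None:
        dy, grads["gamma"], grads["beta"] = _batchnorm_backward(dy, bn_cache)
    dy = _maxpool_backward(dy, pool_cache)
    if act_cache is not None:
        dy = dy * act_cache
    dx, grads["W"], grads["b"] = _conv1d_backward(dy, conv_cache)
    return dx, grads


def conv_block(seq: np.ndarray, spec: ConvBlockSpec, mode: str = "eval",
               params: dict | None = None, state: dict | None = None,
               rng: np.random.Generator | None = None,
               seed: int = 0) -> np.ndarray:
    """One convolutional block on a single [T x F] sequence.

    If ``params`` omits the batch-norm scale/shift the normalization
    stage is skipped (identity), which lets hand-set weights be checked
    against direct computation.
    """
    x = np.asarray(seq, dtype=float)[None]
    if params is None:
        params = _init_conv_block_params(spec, x.shape[2], np.random.default_rng(seed))
    y, _ = _conv_block_forward(x, spec, params, state, mode, False, rng)
    return y[0]


def branch_forward(seq: np.ndarray, blocks, mode: str = "eval",
                   params: list[dict] | None = None,
                   states: list[dict] | None = None,
                   rng: np.random.Generator | None = None,
                   seed: int = 0) -> np.ndarray:
    """Cascade of conv blocks on a single [T x F] sequence.

    The temporal length is floored by each block's pool size in turn; a
    sequence too short for some block raises an error naming it.
    """
    x = np.asarray(seq, dtype=float)
    init_rng = np.random.default_rng(seed)
    for i, spec in enumerate(blocks):
        p = params[i] if params is not None else _init_conv_block_params(spec, x.shape[1], init_rng)
        s = states[i] if states is not None else None
        try:
            x = conv_block(x, spec, mode=mode, params=p, state=s, rng=rng)
        except ValueError as err:
            raise ValueError(f"branch block {i}: {err}") from err
    return x


def cross_attention_fuse(eeg_seq: np.ndarray, peri_seq: np.ndarray, spec: AttentionSpec,
                         params_eeg: dict | None = None, params_peri: dict | None = None,
                         seed: int = 0) -> FusedRepresentation:
    """Bidirectional cross attention on single sequences.

    ``Attention_EEG`` attends EEG keys/values with peripheral queries,
    ``Attention_PERI`` attends peripheral keys/values with EEG queries;
    the fusion is a feature-axis concatenation of the two outputs.
    """
    eeg = np.asarray(eeg_seq, dtype=float)
    peri = np.asarray(peri_seq, dtype=float)
    if eeg.shape[0] == 0 or peri.shape[0] == 0:
        raise ValueError("both sequences must be non-empty")
    rng = np.random.default_rng(seed)
    if params_eeg is None:
        params_eeg = init_attention_params(spec, peri.shape[1], eeg.shape[1], rng)
    if params_peri is None:
        params_peri = init_attention_params(spec, eeg.shape[1], peri.shape[1], rng)
    att_eeg = multi_head(peri, eeg, eeg, spec, params_eeg)
    att_peri = multi_head(eeg, peri, peri, spec, params_peri)
    if att_eeg.shape[0] != att_peri.shape[0]:
        raise ValueError("cross-attention outputs must share the window count to concatenate")
    fused = np.concatenate([att_eeg, att_peri], axis=1)
    return FusedRepresentation(fused, att_eeg, att_peri)


def classify(fused: FusedRepresentation | np.ndarray, n_classes: int,
             params: dict | None = None, fc_hidden: int = 64,
             seed: int = 0) -> np.ndarray:
    """Temporal mean-pool -> hidden layer -> softmax class probabilities."""
    values = fused.values if isinstance(fused, FusedRepresentation) else np.asarray(fused, float)
    pooled = values.mean(axis=0)
    if params is None:
        rng = np.random.default_rng(seed)
        params = {
            "W1": _uniform_fan_in(rng, (len(pooled), fc_hidden), len(pooled)),
            "b1": np.zeros(fc_hidden),
            "W2": _uniform_fan_in(rng, (fc_hidden, n_classes), fc_hidden),
            "b2": np.zeros(n_classes),
        }
    h = np.maximum(pooled @ params["W1"] + params["b1"], 0.0)
    logits = h @ params["W2"] + params["b2"]
    return softmax(logits)


# ---------------------------------------------------------------------------
# Full model
# ---------------------------------------------------------------------------

class CrossAttentionClassifier:
    """End-to-end trainable model over paired EEG/peripheral feature sequences.

    Parameters live in ``self.params`` (name -> array); batch-norm running
    statistics in ``self.state``.  ``forward`` returns probabilities and a
    cache; ``backward`` consumes the cache and produces the gradient of
    mean cross-entropy + L2 with respect to every parameter.
    """

    def __init__(self, config: ModelConfig, n_eeg_features: int, n_peri_features: int):
        self.config = config
        self.n_eeg_features = n_eeg_features
        self.n_peri_features = n_peri_features
        rng = np.random.default_rng(config.seed)
        self.params: dict[str, np.ndarray] = {}
        self.state: dict[str, dict[str, np.ndarray]] = {}
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(1,)))

        widths = {}
        for branch, blocks, n_in in (("eeg", config.eeg_branch, n_eeg_features),
                                     ("peri", config.peri_branch, n_peri_features)):
            width = n_in
            for i, spec in enumerate(blocks):
                p = _init_conv_block_params(spec, width, rng)
                for key, val in p.items():
                    self.params[f"{branch}_block{i}_{key}"] = val
                self.state[f"{branch}_block{i}"] = {
                    "mean": np.zeros(spec.n_filters),
                    "var": np.ones(spec.n_filters),
                }
                width = spec.n_filters
            widths[branch] = width

        att = config.attention
        for name, (dq, dkv) in (("att_eeg", (widths["peri"], widths["eeg"])),
                                ("att_peri", (widths["eeg"], widths["peri"]))):
            for key, val in init_attention_params(att, dq, dkv, rng).items():
                self.params[f"{name}_{key}"] = val

        fused_dim = 2 * att.model_dim
        self.params["fc1_W"] = _uniform_fan_in(rng, (fused_dim, config.fc_hidden), fused_dim)
        self.params["fc1_b"] = np.zeros(config.fc_hidden)
        self.params["fc2_W"] = _uniform_fan_in(rng, (config.fc_hidden, config.n_classes),
                                               config.fc_hidden)
        self.params["fc2_b"] = np.zeros(config.n_classes)

        self.l2_param_names = [
            name for name in self.params
            if name.endswith(("_W", "_Wq", "_Wk", "_Wv", "_Wo"))
        ]

    # -- forward -----------------------------------------------------------

    def _branch(self, x: np.ndarray, branch: str, mode: str, update_stats: bool,
                rng: np.random.Generator | None):
        blocks = getattr(self.config, f"{branch}_branch")
        caches = []
        for i, spec in enumerate(blocks):
            p = {k: self.params[f"{branch}_block{i}_{k}"] for k in ("W", "b", "gamma", "beta")}
            if x.shape[1] < max(spec.kernel_size, spec.pool_size):
                raise ValueError(
                    f"{branch} branch block {i}: sequence length {x.shape[1]} too short"
                )
            x, cache = _conv_block_forward(x, spec, p, self.state[f"{branch}_block{i}"],
                                           mode, update_stats, rng)
            caches.append(cache)
        return x, caches

    def forward(self, X_eeg: np.ndarray, X_peri: np.ndarray, mode: str = "eval",
                update_stats: bool = False, rng: np.random.Generator | None = None):
        """Probabilities [B x n_classes] plus the cache needed for ``backward``."""
        X_eeg = np.asarray(X_eeg, dtype=float)
        X_peri = np.asarray(X_peri, dtype=float)
        eeg_out, eeg_caches = self._branch(X_eeg, "eeg", mode, update_stats, rng)
        peri_out, peri_caches = self._branch(X_peri, "peri", mode, update_stats, rng)

        p_att_eeg = {k: self.params[f"att_eeg_{k}"] for k in ("Wq", "Wk", "Wv", "Wo")}
        p_att_peri = {k: self.params[f"att_peri_{k}"] for k in ("Wq", "Wk", "Wv", "Wo")}
        att_eeg, cache_eeg = _multi_head_forward(peri_out, eeg_out, eeg_out, p_att_eeg)
        att_peri, cache_peri = _multi_head_forward(eeg_out, peri_out, peri_out, p_att_peri)
        fused = np.concatenate([att_eeg, att_peri], axis=2)

        pooled = fused.mean(axis=1)
        z1 = pooled @ self.params["fc1_W"] + self.params["fc1_b"]
        h1 = np.maximum(z1, 0.0)
        logits = h1 @ self.params["fc2_W"] + self.params["fc2_b"]
        probs = softmax(logits, axis=-1)
        cache = {
            "eeg_caches": eeg_caches, "peri_caches": peri_caches,
            "att_cache_eeg": cache_eeg, "att_cache_peri": cache_peri,
            "fused_shape": fused.shape, "pooled": pooled,
            "z1": z1, "h1": h1, "probs": probs,
        }
        return probs, cache

    # -- backward ----------------------------------------------------------

    def backward(self, cache: dict, y_true: np.ndarray, l2_lambda: float = 0.0):
        """Gradient of mean CE + l2_lambda * sum of squared weights."""
        probs = cache["probs"]
        B, n_classes = probs.shape
        dlogits = probs.copy()
        dlogits[np.arange(B), y_true] -= 1.0
        dlogits /= B

        grads: dict[str, np.ndarray] = {}
        grads["fc2_W"] = cache["h1"].T @ dlogits
        grads["fc2_b"] = dlogits.sum(axis=0)
        dh1 = dlogits @ self.params["fc2_W"].T
        dz1 = dh1 * (cache["z1"] > 0)
        grads["fc1_W"] = cache["pooled"].T @ dz1
        grads["fc1_b"] = dz1.sum(axis=0)
        dpooled = dz1 @ self.params["fc1_W"].T

        _, T, fused_dim = cache["fused_shape"]
        dfused = np.repeat(dpooled[:, None, :] / T, T, axis=1)
        half = fused_dim // 2
        datt_eeg, datt_peri = dfused[:, :, :half], dfused[:, :, half:]

        dQ_e, dK_e, dV_e, g_eeg = _multi_head_backward(datt_eeg, cache["att_cache_eeg"])
        dQ_p, dK_p, dV_p, g_peri = _multi_head_backward(datt_peri, cache["att_cache_peri"])
        for key, val in g_eeg.items():
            grads[f"att_eeg_{key}"] = val
        for key, val in g_peri.items():
            grads[f"att_peri_{key}"] = val
        # att_eeg used (Q=peri, K=V=eeg); att_peri used (Q=eeg, K=V=peri)
        deeg_out = dK_e + dV_e + dQ_p
        dperi_out = dQ_e + dK_p + dV_p

        for branch, dout in (("eeg", deeg_out), ("peri", dperi_out)):
            caches = cache[f"{branch}_caches"]
            for i in reversed(range(len(caches))):
                dout, block_grads = _conv_block_backward(dout, caches[i])
                for key, val in block_grads.items():
                    grads[f"{branch}_block{i}_{key}"] = val

        if l2_lambda:
            for name in self.l2_param_names:
                grads[name] = grads[name] + 2.0 * l2_lambda * self.params[name]
        return grads

    # -- convenience -------------------------------------------------------

    def loss(self, probs: np.ndarray, y_true: np.ndarray, l2_lambda: float = 0.0) -> float:
        p = np.clip(probs[np.arange(len(y_true)), y_true], 1e-12, None)
        ce = -float(np.mean(np.log(p)))
        l2 = sum(float(np.sum(self.params[n] ** 2)) for n in self.l2_param_names)
        return ce + l2_lambda * l2

    def predict_proba(self, X_eeg: np.ndarray, X_peri: np.ndarray) -> np.ndarray:
        probs, _ = self.forward(X_eeg, X_peri, mode="eval")
        return probs

    def predict(self, X_eeg: np.ndarray, X_peri: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(X_eeg, X_peri), axis=1)
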