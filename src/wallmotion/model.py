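"""CNN-LSTM regression network with temporal attention for point-level
wall-status scoring.

Architecture ("cnn_lstm_attention", the proposed model): two 1-D
convolution blocks (ReLU, stride 1, same padding) capture short-term
dynamics, an LSTM over the conv features captures long-term dynamics, and
additive (Bahdanau-style) temporal attention layers pool each conv block's
output and the LSTM sequence output into context vectors.  The contexts are
concatenated and passed through the dense_1 embedding layer (ReLU) — the
feature space on which the auxiliary loss terms operate — and a sigmoid unit
emits a scalar score in [0, 1]: 0 means thin-walled (TW), 1 hyperplastic
remodeling (HR).

A plain "lstm_baseline" variant (LSTM + two dense layers, no convolution,
no attention) is provided for ablation.

All weights use Glorot uniform initialization, all biases start at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor, concat, conv1d_same, softmax
from .exceptions import ConfigError, DataError

ARCHITECTURES = ("cnn_lstm_attention", "lstm_baseline")


@dataclass
class ModelConfig:
    n_channels: int = 5
    conv_blocks: int = 2
    conv_filters: int = 64
    kernel_size: int = 3
    lstm_units: int = 64
    attention_dim: int = 32
    embedding_dim: int = 32       # width of the dense_1 feature layer
    architecture: str = "cnn_lstm_attention"
    seed: int = 0

    def __post_init__(self):
        for name in ("n_channels", "conv_blocks", "conv_filters", "kernel_size",
                     "lstm_units", "attention_dim", "embedding_dim"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.kernel_size % 2 == 0:
            raise ConfigError("kernel_size must be odd (same padding)")
        if self.architecture not in ARCHITECTURES:
            raise ConfigError(f"unknown architecture {self.architecture!r}")


@dataclass
class TrainedModel:
    """Parameters plus the normalization statistics frozen at training time."""

    config: ModelConfig
    params: dict                  # name -> Tensor
    norm_stats: dict | None = None

    def parameters(self) -> list:
        return list(self.params.values())

    def copy(self) -> "TrainedModel":
        return TrainedModel(
            config=self.config,
            params={k: Tensor(v.data.copy()) for k, v in self.params.items()},
            norm_stats=None if self.norm_stats is None else {
                k: np.array(v, copy=True) for k, v in self.norm_stats.items()
            },
        )


def save_model(model: TrainedModel, path) -> None:
    """Write a checkpoint: one .npz holding the config (JSON string), every
    parameter array, and the normalization statistics."""
    import json

    payload = {f"param/{k}": v.data for k, v in model.params.items()}
    if model.norm_stats is not None:
        payload["norm/mean"] = model.norm_stats["mean"]
        payload["norm/sd"] = model.norm_stats["sd"]
    payload["config"] = np.array(json.dumps(asdict(model.config)))
    np.savez(path, **payload)


def load_model(path) -> TrainedModel:
    import json

    with np.load(path, allow_pickle=False) as data:
        config = ModelConfig(**json.loads(str(data["config"])))
        params = {
            k.removeprefix("param/"): Tensor(data[k])
            for k in data.files
            if k.startswith("param/")
        }
        norm = None
        if "norm/mean" in data.files:
            norm = {"mean": data["norm/mean"], "sd": data["norm/sd"]}
    return TrainedModel(config=config, params=params, norm_stats=norm)


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape))


def init_model(config: ModelConfig) -> TrainedModel:
    """Create a model with Glorot-uniform weights and zero biases,
    deterministically from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    C, F, K = config.n_channels, config.conv_filters, config.kernel_size
    H, A, E = config.lstm_units, config.attention_dim, config.embedding_dim
    p: dict = {}

    def dense(name, n_in, n_out):
        p[f"{name}_W"] = glorot_uniform(rng, (n_in, n_out), n_in, n_out)
        p[f"{name}_b"] = Tensor(np.zeros(n_out))

    def attention(name, n_in):
        dense(f"{name}_proj", n_in, A)
        dense(f"{name}_score", A, 1)

    def lstm(name, n_in):
        p[f"{name}_Wx"] = glorot_uniform(rng, (n_in, 4 * H), n_in, 4 * H)
        p[f"{name}_Wh"] = glorot_uniform(rng, (H, 4 * H), H, 4 * H)
        p[f"{name}_b"] = Tensor(np.zeros(4 * H))

    if config.architecture == "cnn_lstm_attention":
        c_in = C
        for i in range(config.conv_blocks):
            p[f"conv{i}_W"] = glorot_uniform(rng, (K, c_in, F), K * c_in, K * F)
            p[f"conv{i}_b"] = Tensor(np.zeros(F))
            attention(f"attn_conv{i}", F)
            c_in = F
        lstm("lstm", F)
        attention("attn_lstm", H)
        dense("dense1", config.conv_blocks * F + H, E)
    else:  # lstm_baseline: LSTM + two dense layers
        lstm("lstm", C)
        dense("dense1", H, E)
    dense("out", E, 1)
    return TrainedModel(config=config, params=p)


# ---------------------------------------------------------------------------
# Forward graph
# ---------------------------------------------------------------------------

def _lstm_scan(p: dict, name: str, x: Tensor, hidden: int) -> list:
    """Run an LSTM over x (B, T, C); return the list of hidden states."""
    B, T, _ = x.data.shape
    Wx, Wh, b = p[f"{name}_Wx"], p[f"{name}_Wh"], p[f"{name}_b"]
    xproj = x @ Wx + b  # (B, T, 4H): all input projections in one matmul
    h = Tensor(np.zeros((B, hidden)))
    c = Tensor(np.zeros((B, hidden)))
    states = []
    for t in range(T):
        z = xproj[:, t, :] + h @ Wh
        i = z[:, 0 * hidden : 1 * hidden].sigmoid()
        f = z[:, 1 * hidden : 2 * hidden].sigmoid()
        g = z[:, 2 * hidden : 3 * hidden].tanh()
        o = z[:, 3 * hidden : 4 * hidden].sigmoid()
        c = f * c + i * g
        h = o * c.tanh()
        states.append(h)
    return states


def _attend(p: dict, name: str, seq: Tensor) -> tuple[Tensor, Tensor]:
    """Additive temporal attention over seq (B, T, D).

    Returns (context (B, D), weights (B, T)); weights are a softmax over
    time, so they are non-negative and sum to one per sequence.
    """
    scores = (
        (seq @ p[f"{name}_proj_W"] + p[f"{name}_proj_b"]).tanh()
        @ p[f"{name}_score_W"] + p[f"{name}_score_b"]
    )  # (B, T, 1)
    B, T, _ = scores.data.shape
    alpha = softmax(scores.reshape(B, T), axis=1)      # (B, T)
    context = (seq * alpha.reshape(B, T, 1)).sum(axis=1)
    return context, alpha


def forward_graph(model: TrainedModel, X: np.ndarray) -> tuple[Tensor, Tensor, list]:
    """Differentiable forward pass.

    X: (B, 5, L) raw feature matrix; normalization stats (if present) are
    applied first.  Returns (scores (B,), embeddings (B, E), attention
    weight Tensors, one (B, T) per attention layer).
    """
    cfg = model.config
    X = np.asarray(X, dtype=float)
    if X.ndim != 3 or X.shape[1] != cfg.n_channels:
        raise DataError(f"expected batch of (n_channels={cfg.n_channels}, L), got {X.shape}")
    if model.norm_stats is not None:
        X = (X - model.norm_stats["mean"][None, :, None]) / model.norm_stats["sd"][None, :, None]
    p = model.params
    x = Tensor(np.transpose(X, (0, 2, 1)))  # (B, L, C)

    attn_weights: list = []
    if cfg.architecture == "cnn_lstm_attention":
        contexts = []
        h = x
        for i in range(cfg.conv_blocks):
            h = conv1d_same(h, p[f"conv{i}_W"], p[f"conv{i}_b"]).relu()
            ctx, alpha = _attend(p, f"attn_conv{i}", h)
            contexts.append(ctx)
            attn_weights.append(alpha)
        states = _lstm_scan(p, "lstm", h, cfg.lstm_units)
        from .autodiff import stack as _stack

        seq = _stack(states, axis=1)  # (B, T, H)
        ctx, alpha = _attend(p, "attn_lstm", seq)
        contexts.append(ctx)
        attn_weights.append(alpha)
        pooled = concat(contexts, axis=1)
    else:
        states = _lstm_scan(p, "lstm", x, cfg.lstm_units)
        pooled = states[-1]

    emb = (pooled @ p["dense1_W"] + p["dense1_b"]).relu()
    B = emb.data.shape[0]
    score = (emb @ p["out_W"] + p["out_b"]).sigmoid().reshape(B)
    return score, emb, attn_weights


def forward(model: TrainedModel, X: np.ndarray):
    """Inference forward pass (numpy outputs).

    Returns (scores in [0, 1], embeddings, attention weights as a list of
    (B, T) arrays; empty for the baseline architecture).
    """
    score, emb, attns = forward_graph(model, X)
    return score.data.copy(), emb.data.copy(), [a.data.copy() for a in attns]


def attention_map(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Average the attention layers' weights per time step -> (B, L).

    All attention layers share the sequence length L (same-padded convs and
    a sequence-output LSTM preserve it), so the average is well defined and
    still sums to one per sequence.
    """
    _, _, attns = forward(model, X)
    if not attns:
        raise DataError("architecture has no attention layers")
    return np.mean(attns, axis=0)
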