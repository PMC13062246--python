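"""Transformer bag aggregator in plain numpy, with explicit backpropagation.

Each patch embedding (768-d) is linearly projected to the model width
(512-d) with a ReLU; a learnable CLS token is prepended and the sequence is
passed through two pre-norm transformer encoder layers (multi-head
self-attention with 4 heads of 128 dimensions, a feed-forward block, layer
normalization and residual connections). The final CLS state, after a last
layer norm, is the 512-d slide embedding. No positional encodings are used,
so the slide embedding is invariant to patch order — the natural contract
for a bag of tiles.

Training attaches a temporary logistic head to the CLS token, minimizes
binary cross-entropy with Adam, and discards the head; the gradients flow
through the whole encoder. Training arithmetic runs in float32 for speed,
inference in float64; both are deterministic for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..containers import PatchBag, SlideEmbedding

__all__ = [
    "AggregatorConfig",
    "AggregatorWeights",
    "init_aggregator",
    "aggregate_slide",
    "aggregate_slides",
    "train_aggregator",
    "save_weights",
    "load_weights",
]

_LN_EPS = 1e-5


@dataclass
class AggregatorConfig:
    """Architecture hyperparameters of the bag aggregator.

    Defaults follow the slide-embedding design: 768-d patches projected to a
    512-d model width, two layers, four 128-d attention heads, feed-forward
    width 4x the model width. ``dropout`` is kept for interface parity but
    the numpy trainer runs deterministically with dropout 0.
    """

    input_dim: int = 768
    model_dim: int = 512
    n_layers: int = 2
    n_heads: int = 4
    head_dim: int = 128
    ffn_dim: int | None = None
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ffn_dim is None:
            self.ffn_dim = 4 * self.model_dim
        if self.n_heads * self.head_dim != self.model_dim:
            raise ValueError(
                f"n_heads * head_dim must equal model_dim "
                f"({self.n_heads}*{self.head_dim} != {self.model_dim})"
            )
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")


@dataclass
class AggregatorWeights:
    """Fitted (or seeded-random) parameters plus their configuration."""

    config: AggregatorConfig
    params: dict[str, np.ndarray]
    loss_history: list[float] = field(default_factory=list)


def save_weights(weights: AggregatorWeights, path) -> None:
    """Serialize parameters to a single .npz checkpoint with config metadata."""
    import json

    meta = json.dumps(
        {
            "config": {
                k: getattr(weights.config, k)
                for k in (
                    "input_dim", "model_dim", "n_layers", "n_heads",
                    "head_dim", "ffn_dim", "dropout", "seed",
                )
            },
            "loss_history": weights.loss_history,
        }
    )
    np.savez(path, __meta__=np.array(meta), **weights.params)


def load_weights(path) -> AggregatorWeights:
    """Inverse of :func:`save_weights`."""
    import json

    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        params = {k: data[k] for k in data.files if k != "__meta__"}
    return AggregatorWeights(
        config=AggregatorConfig(**meta["config"]),
        params=params,
        loss_history=list(meta["loss_history"]),
    )


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    std = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.standard_normal((fan_in, fan_out)) * std


def init_aggregator(cfg: AggregatorConfig | None = None) -> AggregatorWeights:
    """Seeded random initialization of all encoder parameters."""
    cfg = cfg or AggregatorConfig()
    rng = np.random.default_rng(cfg.seed)
    m, f = cfg.model_dim, cfg.ffn_dim
    p: dict[str, np.ndarray] = {
        "W_in": _xavier(rng, cfg.input_dim, m),
        "b_in": np.zeros(m),
        "cls": rng.standard_normal(m) * 0.02,
        "lnf_g": np.ones(m),
        "lnf_b": np.zeros(m),
    }
    for l in range(cfg.n_layers):
        pre = f"l{l}_"
        for name in ("Wq", "Wk", "Wv", "Wo"):
            p[pre + name] = _xavier(rng, m, m)
        for name in ("bq", "bk", "bv", "bo"):
            p[pre + name] = np.zeros(m)
        p[pre + "ln1_g"] = np.ones(m)
        p[pre + "ln1_b"] = np.zeros(m)
        p[pre + "ln2_g"] = np.ones(m)
        p[pre + "ln2_b"] = np.zeros(m)
        p[pre + "W1"] = _xavier(rng, m, f)
        p[pre + "c1"] = np.zeros(f)
        p[pre + "W2"] = _xavier(rng, f, m)
        p[pre + "c2"] = np.zeros(m)
    return AggregatorWeights(config=cfg, params=p)


# ---------------------------------------------------------------------------
# forward / backward primitives
# ---------------------------------------------------------------------------

def _layernorm_fwd(x, g, b):
    mu = x.mean(axis=1, keepdims=True)
    var = x.var(axis=1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (x - mu) * inv
    return xhat * g + b, (xhat, inv, g)


def _layernorm_bwd(dy, cache):
    xhat, inv, g = cache
    dxhat = dy * g
    dg = (dy * xhat).sum(axis=0)
    db = dy.sum(axis=0)
    dx = inv * (
        dxhat
        - dxhat.mean(axis=1, keepdims=True)
        - xhat * (dxhat * xhat).mean(axis=1, keepdims=True)
    )
    return dx, dg, db


def _split_heads(x, n_heads, head_dim):
    n = x.shape[0]
    return x.reshape(n, n_heads, head_dim).transpose(1, 0, 2)  # (h, n, d)


def _merge_heads(x):
    h, n, d = x.shape
    return x.transpose(1, 0, 2).reshape(n, h * d)


def _forward(params, cfg: AggregatorConfig, x: np.ndarray):
    """Encoder forward pass; returns (cls_vector, caches for backprop)."""
    dtype = params["W_in"].dtype
    x = np.asarray(x, dtype=dtype)
    if x.ndim != 2 or x.shape[1] != cfg.input_dim:
        raise ValueError(
            f"expected patch matrix (n, {cfg.input_dim}); got {x.shape}"
        )
    caches: dict = {"x": x}
    pre_in = x @ params["W_in"] + params["b_in"]
    h0 = np.maximum(pre_in, 0.0)
    caches["pre_in"] = pre_in
    s = np.vstack([params["cls"][None, :].astype(dtype), h0])
    scale = float(cfg.head_dim) ** -0.5
    layer_caches = []
    for l in range(cfg.n_layers):
        pre = f"l{l}_"
        lc: dict = {"s_in": s}
        a, lc["ln1"] = _layernorm_fwd(s, params[pre + "ln1_g"], params[pre + "ln1_b"])
        lc["a"] = a
        q = _split_heads(a @ params[pre + "Wq"] + params[pre + "bq"], cfg.n_heads, cfg.head_dim)
        k = _split_heads(a @ params[pre + "Wk"] + params[pre + "bk"], cfg.n_heads, cfg.head_dim)
        v = _split_heads(a @ params[pre + "Wv"] + params[pre + "bv"], cfg.n_heads, cfg.head_dim)
        scores = np.einsum("hid,hjd->hij", q, k) * scale
        scores -= scores.max(axis=2, keepdims=True)
        expd = np.exp(scores)
        attn_p = expd / expd.sum(axis=2, keepdims=True)
        o = np.einsum("hij,hjd->hid", attn_p, v)
        oc = _merge_heads(o)
        attn_out = oc @ params[pre + "Wo"] + params[pre + "bo"]
        lc.update(q=q, k=k, v=v, attn_p=attn_p, oc=oc)
        s = s + attn_out
        lc["s_mid"] = s
        a2, lc["ln2"] = _layernorm_fwd(s, params[pre + "ln2_g"], params[pre + "ln2_b"])
        lc["a2"] = a2
        pre_f = a2 @ params[pre + "W1"] + params[pre + "c1"]
        f1 = np.maximum(pre_f, 0.0)
        f2 = f1 @ params[pre + "W2"] + params[pre + "c2"]
        lc.update(pre_f=pre_f, f1=f1)
        s = s + f2
        layer_caches.append(lc)
    z, caches["lnf"] = _layernorm_fwd(s, params["lnf_g"], params["lnf_b"])
    caches["layers"] = layer_caches
    return z[0].copy(), caches


def _backward(params, cfg: AggregatorConfig, caches, dcls: np.ndarray):
    """Backpropagate a gradient on the CLS output through the encoder."""
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    n1 = caches["layers"][0]["s_in"].shape[0]
    dz = np.zeros((n1, cfg.model_dim), dtype=caches["x"].dtype)
    dz[0] = dcls
    ds, grads["lnf_g"], grads["lnf_b"] = _layernorm_bwd(dz, caches["lnf"])
    scale = float(cfg.head_dim) ** -0.5
    for l in reversed(range(cfg.n_layers)):
        pre = f"l{l}_"
        lc = caches["layers"][l]
        # feed-forward block
        df2 = ds
        grads[pre + "W2"] = lc["f1"].T @ df2
        grads[pre + "c2"] = df2.sum(axis=0)
        df1 = df2 @ params[pre + "W2"].T
        dpre_f = df1 * (lc["pre_f"] > 0)
        grads[pre + "W1"] = lc["a2"].T @ dpre_f
        grads[pre + "c1"] = dpre_f.sum(axis=0)
        da2 = dpre_f @ params[pre + "W1"].T
        ds_ln2, grads[pre + "ln2_g"], grads[pre + "ln2_b"] = _layernorm_bwd(
            da2, lc["ln2"]
        )
        ds = ds + ds_ln2
        # attention block
        dattn = ds
        grads[pre + "Wo"] = lc["oc"].T @ dattn
        grads[pre + "bo"] = dattn.sum(axis=0)
        do = _split_heads(dattn @ params[pre + "Wo"].T, cfg.n_heads, cfg.head_dim)
        dp = np.einsum("hid,hjd->hij", do, lc["v"])
        dv = np.einsum("hij,hid->hjd", lc["attn_p"], do)
        p_attn = lc["attn_p"]
        dscores = p_attn * (dp - (dp * p_attn).sum(axis=2, keepdims=True))
        dq = np.einsum("hij,hjd->hid", dscores, lc["k"]) * scale
        dk = np.einsum("hij,hid->hjd", dscores, lc["q"]) * scale
        dqf, dkf, dvf = (_merge_heads(g) for g in (dq, dk, dv))
        a = lc["a"]
        grads[pre + "Wq"] = a.T @ dqf
        grads[pre + "bq"] = dqf.sum(axis=0)
        grads[pre + "Wk"] = a.T @ dkf
        grads[pre + "bk"] = dkf.sum(axis=0)
        grads[pre + "Wv"] = a.T @ dvf
        grads[pre + "bv"] = dvf.sum(axis=0)
        da = dqf @ params[pre + "Wq"].T + dkf @ params[pre + "Wk"].T + dvf @ params[pre + "Wv"].T
        ds_ln1, grads[pre + "ln1_g"], grads[pre + "ln1_b"] = _layernorm_bwd(
            da, lc["ln1"]
        )
        ds = ds + ds_ln1
    grads["cls"] = ds[0].copy()
    dh0 = ds[1:]
    dpre_in = dh0 * (caches["pre_in"] > 0)
    grads["W_in"] = caches["x"].T @ dpre_in
    grads["b_in"] = dpre_in.sum(axis=0)
    return grads


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def aggregate_slide(bag: PatchBag, weights: AggregatorWeights) -> SlideEmbedding:
    """Encode one bag of patch embeddings into its 512-d CLS slide vector."""
    if bag.embeddings is None:
        raise ValueError(f"bag {bag.slide_id!r} has no embeddings; featurize first")
    cls_vec, _ = _forward(weights.params, weights.config, bag.embeddings)
    return SlideEmbedding(slide_id=bag.slide_id, vector=cls_vec)


def aggregate_slides(
    bags: list[PatchBag], weights: AggregatorWeights
) -> tuple[np.ndarray, list[str]]:
    """Stack CLS vectors for many bags; returns (m x 512 matrix, slide ids)."""
    embs = [aggregate_slide(b, weights) for b in bags]
    return np.stack([e.vector for e in embs]), [e.slide_id for e in embs]


def train_aggregator(
    bags: list[PatchBag],
    cfg: AggregatorConfig | None = None,
    epochs: int = 8,
    lr: float = 1e-3,
    seed: int = 0,
    clip_norm: float = 5.0,
) -> AggregatorWeights:
    """Train the encoder on labeled bags with a temporary logistic CLS head.

    Binary cross-entropy is minimized by Adam, one bag per step, gradients
    flowing through the full encoder; the head is discarded from the
    returned weights. Requires at least two labeled bags per class.
    ``loss_history`` on the result holds the mean training loss per epoch.
    """
    cfg = cfg or AggregatorConfig(seed=seed)
    labeled = [b for b in bags if b.label is not None]
    labels = np.array([b.label for b in labeled])
    if len(labeled) < 4 or len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 labeled bags in each class")
    for cls_label in (0, 1):
        if np.count_nonzero(labels == cls_label) < 2:
            raise ValueError("need at least 2 labeled bags in each class")

    weights = init_aggregator(cfg)
    # float32 working copies: halves the cost of the matrix products
    params = {k: v.astype(np.float32) for k, v in weights.params.items()}
    rng = np.random.default_rng(seed)
    head_w = (rng.standard_normal(cfg.model_dim) * 0.02).astype(np.float32)
    head_b = 0.0

    # Adam state over encoder params + head
    m_state = {k: np.zeros_like(v) for k, v in params.items()}
    v_state = {k: np.zeros_like(v) for k, v in params.items()}
    m_hw = np.zeros_like(head_w)
    v_hw = np.zeros_like(head_w)
    m_hb = v_hb = 0.0
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    history: list[float] = []

    for _ in range(epochs):
        order = rng.permutation(len(labeled))
        losses = []
        for idx in order:
            bag = labeled[idx]
            t = float(bag.label)
            cls_vec, caches = _forward(params, cfg, bag.embeddings)
            z = float(cls_vec @ head_w + head_b)
            p = 1.0 / (1.0 + np.exp(-z))
            p_c = min(max(p, 1e-12), 1 - 1e-12)
            losses.append(-(t * np.log(p_c) + (1 - t) * np.log(1 - p_c)))
            dz = np.float32(p - t)
            dcls = dz * head_w
            grads = _backward(params, cfg, caches, dcls)
            g_hw = dz * cls_vec
            g_hb = dz

            # global gradient-norm clipping for stability
            total = np.sqrt(
                sum(float((g ** 2).sum()) for g in grads.values())
                + float((g_hw ** 2).sum())
                + g_hb ** 2
            )
            factor = min(1.0, clip_norm / (total + 1e-12))

            step += 1
            bc1 = 1 - beta1 ** step
            bc2 = 1 - beta2 ** step
            for k2, g in grads.items():
                g = g * factor
                m_state[k2] = beta1 * m_state[k2] + (1 - beta1) * g
                v_state[k2] = beta2 * v_state[k2] + (1 - beta2) * g * g
                params[k2] -= lr * (m_state[k2] / bc1) / (
                    np.sqrt(v_state[k2] / bc2) + eps
                )
            g_hw *= factor
            g_hb *= factor
            m_hw = beta1 * m_hw + (1 - beta1) * g_hw
            v_hw = beta2 * v_hw + (1 - beta2) * g_hw * g_hw
            head_w -= lr * (m_hw / bc1) / (np.sqrt(v_hw / bc2) + eps)
            m_hb = beta1 * m_hb + (1 - beta1) * g_hb
            v_hb = beta2 * v_hb + (1 - beta2) * g_hb * g_hb
            head_b -= lr * (m_hb / bc1) / (np.sqrt(v_hb / bc2) + eps)
        history.append(float(np.mean(losses)))

    weights.params = {k: v.astype(np.float64) for k, v in params.items()}
    weights.loss_history = history
    return weights
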