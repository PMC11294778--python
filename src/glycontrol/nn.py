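"""Numerical core of the attention model: forward passes, gradients, Adam.

The architecture is a standard pre-norm transformer, specialised for weekly
lab-value grids:

* encoder — masked multi-head self-attention over week positions, with a
  key-padding mask (missing weeks get attention weight exactly 0) and a
  causal mask (a week attends only to itself and earlier weeks);
* decoder — a single learned classification query token that cross-attends
  over the encoder states through ``decoder_layers`` blocks, ending in a
  linear layer and a sigmoid;
* a linear regression head over encoder states for the self-supervised
  next-value task.

Everything is plain numpy.  Each ``*_fwd`` function returns a cache that
its ``*_bwd`` twin consumes; gradients are verified against central
differences in the test suite.  Parameters live in a flat ``{name: array}``
dict, which makes freezing the encoder during the supervised stage a key
filter rather than a code path.

Missing weeks are handled by construction: their embedding rows are forced
to exactly zero (so the stored sentinel value can never leak in), their
columns carry zero attention weight everywhere, and neither loss reads
them.  Rows whose attention has no valid key (an unobserved week before the
first observation, under the causal mask) get an all-zero weight row rather
than NaN; such rows are themselves masked and never read downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ArchConfig", "init_params", "param_count", "Adam"]


@dataclass
class ArchConfig:
    """Architecture shape; the defaults are overridden by the estimator."""

    d_model: int = 128
    n_heads: int = 4
    d_ff: int = 512
    encoder_layers: int = 4
    decoder_layers: int = 4
    dropout: float = 0.0
    causal: bool = True
    dtype: str = "float32"

    def validate(self) -> None:
        if self.d_model % self.n_heads != 0:
            raise ValueError("hidden size must be divisible by the number of heads")
        for name in ("d_model", "n_heads", "d_ff", "encoder_layers", "decoder_layers"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)


# ---------------------------------------------------------------------------
# primitives


def sinusoidal_encoding(n_positions: int, dim: int, dtype=np.float32) -> np.ndarray:
    """Non-learned sin/cos positional code over week indices (so the model
    size is independent of the grid width)."""
    pos = np.arange(n_positions, dtype=np.float64)[:, None]
    i = np.arange(dim // 2, dtype=np.float64)[None, :]
    angles = pos / np.power(10000.0, 2.0 * i / dim)
    enc = np.zeros((n_positions, dim))
    enc[:, 0::2] = np.sin(angles)
    enc[:, 1::2] = np.cos(angles)
    return enc.astype(dtype)


def softmax_masked(scores: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Softmax over the last axis restricted to ``valid`` entries.

    Invalid entries get weight exactly 0.0; rows with no valid entry get an
    all-zero row (never NaN).
    """
    neg = np.where(valid, scores, -np.inf)
    m = neg.max(axis=-1, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    e = np.exp(neg - m, where=valid, out=np.zeros_like(scores, dtype=scores.dtype))
    s = e.sum(axis=-1, keepdims=True)
    return e / np.where(s == 0.0, 1.0, s)


def softmax_masked_bwd(dw: np.ndarray, w: np.ndarray) -> np.ndarray:
    return w * (dw - (dw * w).sum(axis=-1, keepdims=True))


def _layer_norm_fwd(x, g, b, eps=1e-5):
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    istd = 1.0 / np.sqrt(var + eps)
    xhat = xc * istd
    return xhat * g + b, (xhat, istd, g)


def _layer_norm_bwd(dy, cache):
    xhat, istd, g = cache
    dxhat = dy * g
    dx = istd * (
        dxhat
        - dxhat.mean(axis=-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
    )
    axes = tuple(range(dy.ndim - 1))
    return dx, (dy * xhat).sum(axis=axes), dy.sum(axis=axes)


def _linear_fwd(x, W, b):
    return x @ W + b, x


def _linear_bwd(dy, x, W):
    din, dout = W.shape
    dW = x.reshape(-1, din).T @ dy.reshape(-1, dout)
    db = dy.reshape(-1, dout).sum(axis=0)
    return dy @ W.T, dW, db


def _split_heads(x, n_heads):
    b, t, d = x.shape
    return x.reshape(b, t, n_heads, d // n_heads).transpose(0, 2, 1, 3)


def _merge_heads(x):
    b, h, t, dh = x.shape
    return x.transpose(0, 2, 1, 3).reshape(b, t, h * dh)


def _mha_fwd(p, prefix, xq, xkv, valid, n_heads):
    """Multi-head attention; ``valid`` is (B, Tq, Tk) boolean."""
    q, _ = _linear_fwd(xq, p[prefix + "Wq"], p[prefix + "bq"])
    k, _ = _linear_fwd(xkv, p[prefix + "Wk"], p[prefix + "bk"])
    v, _ = _linear_fwd(xkv, p[prefix + "Wv"], p[prefix + "bv"])
    qh, kh, vh = (_split_heads(z, n_heads) for z in (q, k, v))
    dh = qh.shape[-1]
    scale = 1.0 / np.sqrt(dh)
    scores = (qh @ kh.transpose(0, 1, 3, 2)) * np.asarray(scale, dtype=xq.dtype)
    w = softmax_masked(scores, valid[:, None, :, :])
    ctx = w @ vh
    merged = _merge_heads(ctx)
    out, _ = _linear_fwd(merged, p[prefix + "Wo"], p[prefix + "bo"])
    cache = (xq, xkv, qh, kh, vh, w, merged, valid, scale)
    return out, w, cache


def _mha_bwd(dout, cache, p, prefix, grads):
    xq, xkv, qh, kh, vh, w, merged, valid, scale = cache
    n_heads = qh.shape[1]
    dmerged, dWo, dbo = _linear_bwd(dout, merged, p[prefix + "Wo"])
    grads[prefix + "Wo"] = grads.get(prefix + "Wo", 0) + dWo
    grads[prefix + "bo"] = grads.get(prefix + "bo", 0) + dbo
    dctx = _split_heads(dmerged, n_heads)
    dw = dctx @ vh.transpose(0, 1, 3, 2)
    dvh = w.transpose(0, 1, 3, 2) @ dctx
    dscores = softmax_masked_bwd(dw, w) * np.asarray(scale, dtype=dout.dtype)
    dqh = dscores @ kh
    dkh = dscores.transpose(0, 1, 3, 2) @ qh
    dq, dk, dv = (_merge_heads(z) for z in (dqh, dkh, dvh))
    dxq, dWq, dbq = _linear_bwd(dq, xq, p[prefix + "Wq"])
    dxk, dWk, dbk = _linear_bwd(dk, xkv, p[prefix + "Wk"])
    dxv, dWv, dbv = _linear_bwd(dv, xkv, p[prefix + "Wv"])
    for name, g in (("Wq", dWq), ("bq", dbq), ("Wk", dWk), ("bk", dbk), ("Wv", dWv), ("bv", dbv)):
        grads[prefix + name] = grads.get(prefix + name, 0) + g
    return dxq, dxk + dxv


def _ffn_fwd(p, prefix, x):
    h, _ = _linear_fwd(x, p[prefix + "W1"], p[prefix + "b1"])
    a = np.maximum(h, 0)
    y, _ = _linear_fwd(a, p[prefix + "W2"], p[prefix + "b2"])
    return y, (x, h > 0, a)


def _ffn_bwd(dy, cache, p, prefix, grads):
    x, relu_mask, a = cache
    da, dW2, db2 = _linear_bwd(dy, a, p[prefix + "W2"])
    dh = da * relu_mask
    dx, dW1, db1 = _linear_bwd(dh, x, p[prefix + "W1"])
    for name, g in (("W1", dW1), ("b1", db1), ("W2", dW2), ("b2", db2)):
        grads[prefix + name] = grads.get(prefix + name, 0) + g
    return dx


def _dropout_fwd(x, rate, train, rng):
    if not train or rate <= 0.0:
        return x, None
    keep = (rng.random(x.shape) >= rate).astype(x.dtype) / (1.0 - rate)
    return x * keep, keep


def _dropout_bwd(dy, keep):
    return dy if keep is None else dy * keep


# ---------------------------------------------------------------------------
# parameters


def init_params(arch: ArchConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    arch.validate()
    d, f = arch.d_model, arch.d_ff
    dt = arch.np_dtype
    std = 0.02
    p: dict[str, np.ndarray] = {}

    def norm(*shape):
        return (std * rng.standard_normal(shape)).astype(dt)

    p["embed.w"] = norm(d)
    p["embed.b"] = np.zeros(d, dtype=dt)

    def block(prefix):
        p[prefix + "ln1.g"] = np.ones(d, dtype=dt)
        p[prefix + "ln1.b"] = np.zeros(d, dtype=dt)
        for nm in ("Wq", "Wk", "Wv", "Wo"):
            p[prefix + "attn." + nm] = norm(d, d)
        for nm in ("bq", "bk", "bv", "bo"):
            p[prefix + "attn." + nm] = np.zeros(d, dtype=dt)
        p[prefix + "ln2.g"] = np.ones(d, dtype=dt)
        p[prefix + "ln2.b"] = np.zeros(d, dtype=dt)
        p[prefix + "ffn.W1"] = norm(d, f)
        p[prefix + "ffn.b1"] = np.zeros(f, dtype=dt)
        p[prefix + "ffn.W2"] = norm(f, d)
        p[prefix + "ffn.b2"] = np.zeros(d, dtype=dt)

    for l in range(arch.encoder_layers):
        block(f"enc{l}.")
    p["enc_lnf.g"] = np.ones(d, dtype=dt)
    p["enc_lnf.b"] = np.zeros(d, dtype=dt)
    p["reg.W"] = norm(d, 1)
    p["reg.b"] = np.zeros(1, dtype=dt)
    p["query"] = norm(d)
    for l in range(arch.decoder_layers):
        block(f"dec{l}.")
    p["dec_lnf.g"] = np.ones(d, dtype=dt)
    p["dec_lnf.b"] = np.zeros(d, dtype=dt)
    p["cls.W"] = norm(d, 1)
    p["cls.b"] = np.zeros(1, dtype=dt)
    return p


ENCODER_PREFIXES = ("embed.", "enc", "reg.")
DECODER_PREFIXES = ("query", "dec", "cls.")


def encoder_param_names(params) -> list[str]:
    return [k for k in params if k.startswith(ENCODER_PREFIXES)]

def decoder_param_names(params) -> list[str]:
    return [k for k in params if k.startswith(DECODER_PREFIXES)]


def param_count(params: dict[str, np.ndarray]) -> int:
    return int(sum(v.size for v in params.values()))


# ---------------------------------------------------------------------------
# encoder


def embed_values(params, arch, values, obs_mask):
    """(B, W) values -> (B, W, d) tokens; missing rows are exactly zero."""
    dt = arch.np_dtype
    v = np.asarray(values, dtype=dt)
    mask = np.asarray(obs_mask, dtype=bool)
    w = v.shape[-1]
    pos = sinusoidal_encoding(w, arch.d_model, dt)
    e = v[..., None] * params["embed.w"] + params["embed.b"] + pos
    return e * mask[..., None].astype(dt)


def attention_validity(obs_mask: np.ndarray, causal: bool) -> np.ndarray:
    """(B, W, W) boolean: query t may attend to key s iff s is observed and,
    under causal masking, s <= t."""
    mask = np.asarray(obs_mask, dtype=bool)
    valid = np.repeat(mask[:, None, :], mask.shape[1], axis=1)
    if causal:
        w = mask.shape[1]
        valid = valid & np.tril(np.ones((w, w), dtype=bool))
    return valid


def encoder_apply(params, arch, values, obs_mask, causal=True, train=False, rng=None,
                  collect_attention=False):
    """Run the encoder stack.

    Returns ``(hidden, caches, attention)`` where hidden is (B, W, d) and
    attention (if collected) is a list over layers of (B, H, W, W)
    row-stochastic-over-valid-keys maps.
    """
    mask = np.asarray(obs_mask, dtype=bool)
    if not mask.any(axis=-1).all():
        raise ValueError("no observed values: at least one slot per series must be observed")
    e = embed_values(params, arch, values, obs_mask)
    valid = attention_validity(mask, causal)
    h = e
    caches = {"layers": [], "valid": valid, "mask": mask,
              "values": np.asarray(values, dtype=arch.np_dtype)}
    attn_maps = []
    for l in range(arch.encoder_layers):
        pre = f"enc{l}."
        a, c_ln1 = _layer_norm_fwd(h, params[pre + "ln1.g"], params[pre + "ln1.b"])
        attn, w_attn, c_attn = _mha_fwd(params, pre + "attn.", a, a, valid, arch.n_heads)
        attn, keep1 = _dropout_fwd(attn, arch.dropout, train, rng)
        h1 = h + attn
        f, c_ln2 = _layer_norm_fwd(h1, params[pre + "ln2.g"], params[pre + "ln2.b"])
        ff, c_ffn = _ffn_fwd(params, pre + "ffn.", f)
        ff, keep2 = _dropout_fwd(ff, arch.dropout, train, rng)
        h = h1 + ff
        caches["layers"].append((c_ln1, c_attn, keep1, c_ln2, c_ffn, keep2))
        if collect_attention:
            attn_maps.append(w_attn)
    henc, c_lnf = _layer_norm_fwd(h, params["enc_lnf.g"], params["enc_lnf.b"])
    caches["lnf"] = c_lnf
    return henc, caches, attn_maps


def encoder_backward(dhenc, caches, params, arch, grads=None):
    """Backpropagate through the encoder; returns the grads dict (and the
    gradient wrt the embedded tokens, unused by training but handy for
    checks)."""
    if grads is None:
        grads = {}
    dh, dg, db = _layer_norm_bwd(dhenc, caches["lnf"])
    grads["enc_lnf.g"] = grads.get("enc_lnf.g", 0) + dg
    grads["enc_lnf.b"] = grads.get("enc_lnf.b", 0) + db
    for l in range(arch.encoder_layers - 1, -1, -1):
        pre = f"enc{l}."
        c_ln1, c_attn, keep1, c_ln2, c_ffn, keep2 = caches["layers"][l]
        dff = _dropout_bwd(dh, keep2)
        df = _ffn_bwd(dff, c_ffn, params, pre + "ffn.", grads)
        dh1, dg, db = _layer_norm_bwd(df, c_ln2)
        grads[pre + "ln2.g"] = grads.get(pre + "ln2.g", 0) + dg
        grads[pre + "ln2.b"] = grads.get(pre + "ln2.b", 0) + db
        dh1 = dh1 + dh
        dattn = _dropout_bwd(dh1, keep1)
        dxq, dxkv = _mha_bwd(dattn, c_attn, params, pre + "attn.", grads)
        da = dxq + dxkv
        dh0, dg, db = _layer_norm_bwd(da, c_ln1)
        grads[pre + "ln1.g"] = grads.get(pre + "ln1.g", 0) + dg
        grads[pre + "ln1.b"] = grads.get(pre + "ln1.b", 0) + db
        dh = dh0 + dh1
    # embedding: e = (v * w + b + pos) * mask
    mask = caches["mask"][..., None].astype(dh.dtype)
    de = dh * mask
    grads["embed.b"] = grads.get("embed.b", 0) + de.reshape(-1, de.shape[-1]).sum(axis=0)
    v = (caches["values"] * caches["mask"])[..., None].astype(dh.dtype)
    grads["embed.w"] = grads.get("embed.w", 0) + (de * v).reshape(-1, de.shape[-1]).sum(axis=0)
    return grads, de


def regression_apply(params, henc):
    """Next-value head: (B, W, d) encoder states -> (B, W) predictions."""
    return (henc @ params["reg.W"] + params["reg.b"])[..., 0]


def regression_backward(dyhat, henc, params, grads):
    dy = dyhat[..., None]
    d = henc.shape[-1]
    grads["reg.W"] = grads.get("reg.W", 0) + henc.reshape(-1, d).T @ dy.reshape(-1, 1)
    grads["reg.b"] = grads.get("reg.b", 0) + dy.sum()
    return dy @ params["reg.W"].T


# ---------------------------------------------------------------------------
# decoder


def decoder_apply(params, arch, henc, obs_mask, train=False, rng=None, collect_attention=False):
    """Classification query token cross-attends over encoder states.

    Returns ``(probability (B,), logit (B,), caches, cross_maps)`` with
    cross_maps a list over layers of (B, H, W) weight vectors.
    """
    mask = np.asarray(obs_mask, dtype=bool)
    b, w, d = henc.shape
    q = np.broadcast_to(params["query"], (b, 1, d)).astype(henc.dtype).copy()
    valid = mask[:, None, :]
    caches = {"layers": [], "henc": henc, "mask": mask}
    cross_maps = []
    for l in range(arch.decoder_layers):
        pre = f"dec{l}."
        a, c_ln1 = _layer_norm_fwd(q, params[pre + "ln1.g"], params[pre + "ln1.b"])
        cross, w_attn, c_attn = _mha_fwd(params, pre + "attn.", a, henc, valid, arch.n_heads)
        cross, keep1 = _dropout_fwd(cross, arch.dropout, train, rng)
        q1 = q + cross
        f, c_ln2 = _layer_norm_fwd(q1, params[pre + "ln2.g"], params[pre + "ln2.b"])
        ff, c_ffn = _ffn_fwd(params, pre + "ffn.", f)
        ff, keep2 = _dropout_fwd(ff, arch.dropout, train, rng)
        q = q1 + ff
        caches["layers"].append((c_ln1, c_attn, keep1, c_ln2, c_ffn, keep2))
        if collect_attention:
            cross_maps.append(w_attn[:, :, 0, :])
    z, c_lnf = _layer_norm_fwd(q, params["dec_lnf.g"], params["dec_lnf.b"])
    caches["lnf"] = c_lnf
    logit = (z[:, 0, :] @ params["cls.W"] + params["cls.b"])[:, 0]
    caches["z"] = z
    p = 1.0 / (1.0 + np.exp(-logit))
    return p, logit, caches, cross_maps


def decoder_backward(dlogit, caches, params, arch, grads=None):
    """Returns (grads, dhenc); dhenc feeds encoder_backward when fine-tuning."""
    if grads is None:
        grads = {}
    z = caches["z"]
    dz = np.zeros_like(z)
    dz[:, 0, :] = dlogit[:, None] * params["cls.W"][:, 0]
    grads["cls.W"] = grads.get("cls.W", 0) + z[:, 0, :].T @ dlogit[:, None]
    grads["cls.b"] = grads.get("cls.b", 0) + dlogit.sum(keepdims=True)
    dq, dg, db = _layer_norm_bwd(dz, caches["lnf"])
    grads["dec_lnf.g"] = grads.get("dec_lnf.g", 0) + dg
    grads["dec_lnf.b"] = grads.get("dec_lnf.b", 0) + db
    dhenc = np.zeros_like(caches["henc"])
    for l in range(arch.decoder_layers - 1, -1, -1):
        pre = f"dec{l}."
        c_ln1, c_attn, keep1, c_ln2, c_ffn, keep2 = caches["layers"][l]
        dff = _dropout_bwd(dq, keep2)
        df = _ffn_bwd(dff, c_ffn, params, pre + "ffn.", grads)
        dq1, dg, db = _layer_norm_bwd(df, c_ln2)
        grads[pre + "ln2.g"] = grads.get(pre + "ln2.g", 0) + dg
        grads[pre + "ln2.b"] = grads.get(pre + "ln2.b", 0) + db
        dq1 = dq1 + dq
        dcross = _dropout_bwd(dq1, keep1)
        dxq, dxkv = _mha_bwd(dcross, c_attn, params, pre + "attn.", grads)
        dhenc += dxkv
        da, dg, db = _layer_norm_bwd(dxq, c_ln1)
        grads[pre + "ln1.g"] = grads.get(pre + "ln1.g", 0) + dg
        grads[pre + "ln1.b"] = grads.get(pre + "ln1.b", 0) + db
        dq = da + dq1
    grads["query"] = grads.get("query", 0) + dq.sum(axis=(0, 1))
    return grads, dhenc


# ---------------------------------------------------------------------------
# losses

_EPS = 1e-7


def focal_loss_terms(p, y, gamma, alpha):
    """Per-example focal loss -alpha * (1 - p_t)^gamma * log(p_t)."""
    p = np.clip(p, _EPS, 1.0 - _EPS)
    pt = np.where(y == 1, p, 1.0 - p)
    return -alpha * (1.0 - pt) ** gamma * np.log(pt)


def focal_loss_dlogit(p, y, gamma, alpha):
    """d(focal)/d(logit) for p = sigmoid(logit)."""
    p = np.clip(p, _EPS, 1.0 - _EPS)
    pos = alpha * (1.0 - p) ** gamma * (gamma * p * np.log(p) - (1.0 - p))
    neg = alpha * p**gamma * (p - gamma * (1.0 - p) * np.log(1.0 - p))
    return np.where(y == 1, pos, neg)


def masked_mse(pred, target, target_mask):
    """Mean squared error over target positions only."""
    n = target_mask.sum()
    if n == 0:
        raise ValueError("no target positions for the regression loss")
    diff = np.where(target_mask, pred - np.where(target_mask, target, 0.0), 0.0)
    loss = float((diff * diff).sum() / n)
    return loss, (2.0 / n) * diff


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    def __init__(self, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params, grads, keys=None):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for k in keys if keys is not None else grads:
            g = np.asarray(grads[k], dtype=params[k].dtype).reshape(params[k].shape)
            if k not in self.m:
                self.m[k] = np.zeros_like(params[k])
                self.v[k] = np.zeros_like(params[k])
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            params[k] -= self.lr * (self.m[k] / bias1) / (np.sqrt(self.v[k] / bias2) + self.eps)
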