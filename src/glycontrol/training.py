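"""Two-stage training: self-supervised encoder pretraining, supervised
decoder training, and F1-maximizing threshold selection.

The self-supervised task asks the encoder (through the regression head) to
predict, at every observed week that has a later observation, the value of
that next observation; the squared-error loss is taken over exactly those
target positions, so sentinel values at missing weeks contribute nothing.
The supervised stage then optimizes the cross-attention decoder under focal
loss, with the encoder frozen by default (self-attention weights come from
self-supervision, cross-attention weights from supervision; a flag enables
joint fine-tuning).

Both stages run a fixed iteration budget with no early stopping, sampling
minibatches uniformly with replacement from a seeded generator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn

__all__ = [
    "TrainState",
    "DecisionThreshold",
    "ssl_targets",
    "pretrain_self_supervised",
    "train_supervised",
    "select_threshold",
]


@dataclass
class TrainState:
    stage: str
    iterations: int
    seed: int
    losses: list = field(default_factory=list)  # (iteration, loss) pairs
    frozen: tuple = ()

    def log(self, iteration: int, loss: float) -> None:
        self.losses.append((int(iteration), float(loss)))


@dataclass
class DecisionThreshold:
    value: float
    f1_at_threshold: float
    selected_on: str = "train"


def ssl_targets(values: np.ndarray, mask: np.ndarray, target: str = "next_observed"):
    """Targets of the self-supervised task.

    ``next_observed`` (default): position t is a target iff week t is
    observed and some later week is observed; the target value is the next
    observed one.  ``next_week``: position t is a target iff weeks t and
    t+1 are both observed; the target is week t+1's value.
    """
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    targets = np.zeros_like(values)
    tmask = np.zeros_like(mask)
    if target == "next_week":
        both = mask[:, :-1] & mask[:, 1:]
        tmask[:, :-1] = both
        targets[:, :-1] = np.where(both, values[:, 1:], 0.0)
    elif target == "next_observed":
        for i in range(len(values)):
            idx = np.flatnonzero(mask[i])
            if idx.size >= 2:
                tmask[i, idx[:-1]] = True
                targets[i, idx[:-1]] = values[i, idx[1:]]
    else:
        raise ValueError(f"unknown ssl target {target!r}")
    return targets, tmask


def pretrain_self_supervised(
    values,
    mask,
    arch: nn.ArchConfig,
    params=None,
    learning_rate: float = 1e-4,
    batch_size: int = 512,
    iterations: int = 20_000,
    seed: int = 0,
    ssl_target: str = "next_observed",
    log_every: int = 50,
):
    """Minimize next-value MSE over the encoder + regression head."""
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    targets, tmask = ssl_targets(values, mask, ssl_target)
    usable = tmask.any(axis=1)
    if not usable.any():
        raise ValueError("self-supervised pretraining needs at least one instance with >= 2 observed values")
    values, mask = values[usable], mask[usable]
    targets, tmask = targets[usable], tmask[usable]

    rng = np.random.default_rng(seed)
    if params is None:
        params = nn.init_params(arch, rng)
    opt = nn.Adam(lr=learning_rate)
    keys = nn.encoder_param_names(params)
    state = TrainState("pretrain", iterations, seed, frozen=("decoder",))
    n = len(values)
    for it in range(iterations):
        idx = rng.integers(0, n, size=min(batch_size, n))
        h, caches, _ = nn.encoder_apply(
            params, arch, values[idx], mask[idx], train=True, rng=rng
        )
        pred = nn.regression_apply(params, h)
        loss, dpred = nn.masked_mse(pred, targets[idx], tmask[idx])
        grads: dict = {}
        dh = nn.regression_backward(dpred.astype(h.dtype), h, params, grads)
        nn.encoder_backward(dh, caches, params, arch, grads)
        opt.step(params, grads, keys=keys)
        if it % log_every == 0 or it == iterations - 1:
            state.log(it, loss)
    return params, state


def train_supervised(
    values,
    mask,
    y,
    params,
    arch: nn.ArchConfig,
    learning_rate: float = 1e-4,
    batch_size: int = 512,
    iterations: int = 20_000,
    seed: int = 0,
    gamma: float = 2.0,
    alpha: float = 0.25,
    freeze_encoder: bool = True,
    log_every: int = 50,
):
    """Minimize focal loss over the decoder (and encoder iff not frozen).

    With the encoder frozen, its states are computed once per instance and
    reused every iteration, which is what makes the supervised stage cheap.
    """
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    y = np.asarray(y).astype(int).ravel()
    if not (y == 1).any():
        raise ValueError("supervised training needs positive instances; none present")
    if not (y == 0).any():
        raise ValueError("supervised training needs negative instances; none present")

    rng = np.random.default_rng(seed)
    opt = nn.Adam(lr=learning_rate)
    dec_keys = nn.decoder_param_names(params)
    state = TrainState(
        "supervised", iterations, seed, frozen=("encoder",) if freeze_encoder else ()
    )
    n = len(values)

    henc_all = None
    if freeze_encoder:
        henc_all = np.empty((n, values.shape[1], arch.d_model), dtype=arch.np_dtype)
        for i in range(0, n, 512):
            h, _, _ = nn.encoder_apply(params, arch, values[i : i + 512], mask[i : i + 512])
            henc_all[i : i + 512] = h

    for it in range(iterations):
        idx = rng.integers(0, n, size=min(batch_size, n))
        grads: dict = {}
        if freeze_encoder:
            h = henc_all[idx]
            p, _, caches, _ = nn.decoder_apply(params, arch, h, mask[idx], train=True, rng=rng)
            loss = float(np.mean(nn.focal_loss_terms(p, y[idx], gamma, alpha)))
            dlogit = (nn.focal_loss_dlogit(p, y[idx], gamma, alpha) / len(idx)).astype(h.dtype)
            nn.decoder_backward(dlogit, caches, params, arch, grads)
            opt.step(params, grads, keys=dec_keys)
        else:
            h, enc_caches, _ = nn.encoder_apply(
                params, arch, values[idx], mask[idx], train=True, rng=rng
            )
            p, _, caches, _ = nn.decoder_apply(params, arch, h, mask[idx], train=True, rng=rng)
            loss = float(np.mean(nn.focal_loss_terms(p, y[idx], gamma, alpha)))
            dlogit = (nn.focal_loss_dlogit(p, y[idx], gamma, alpha) / len(idx)).astype(h.dtype)
            _, dhenc = nn.decoder_backward(dlogit, caches, params, arch, grads)
            nn.encoder_backward(dhenc, enc_caches, params, arch, grads)
            opt.step(params, grads, keys=[k for k in params if k in grads])
        if it % log_every == 0 or it == iterations - 1:
            state.log(it, loss)
    return params, state


def select_threshold(scores, labels) -> DecisionThreshold:
    """Decision threshold maximizing F1 on the given scores.

    The decision rule is ``score >= threshold``.  All distinct score values
    plus 0 and 1 are scanned exhaustively; ties are broken toward the
    higher threshold (fewer predicted positives).
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).astype(int).ravel()
    if len(scores) != len(labels):
        raise ValueError("scores and labels have different lengths")
    if not (labels == 1).any():
        raise ValueError("threshold selection needs positive labels; none present")
    if not (labels == 0).any():
        raise ValueError("threshold selection needs negative labels; none present")

    candidates = np.unique(np.concatenate([scores, [0.0, 1.0]]))
    n_pos = int(labels.sum())
    best_f1, best_thr = -1.0, None
    for thr in candidates:  # ascending scan; >= keeps the later (higher) tie
        pred = scores >= thr
        tp = int((pred & (labels == 1)).sum())
        denom = int(pred.sum()) + n_pos
        f1 = 2.0 * tp / denom if denom else 0.0
        if f1 >= best_f1:
            best_f1, best_thr = f1, float(thr)
    if np.unique(scores).size == 1:
        warnings.warn("all scores identical; threshold degenerate", stacklevel=2)
        best_thr = float(scores[0])
        pred = scores >= best_thr
        tp = int((pred & (labels == 1)).sum())
        best_f1 = 2.0 * tp / (int(pred.sum()) + n_pos)
    return DecisionThreshold(best_thr, best_f1)
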