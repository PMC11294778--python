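"""The interpretable attention classifier for poor glycemic control.

``HbA1cTransformer`` is a scikit-learn style estimator.  ``X`` is an
``(n_instances, n_weeks)`` array of weekly-quantized HbA1c values with NaN
at missing weeks; ``y`` is the binary poor-control outcome (HbA1c >= 8%
within the year after the reference date).  Fitting runs two stages:

1. self-supervised pretraining of the encoder (predict the next observed
   HbA1c value, squared error at observed target positions only), then
2. supervised training of the cross-attention decoder under focal loss,
   with the encoder frozen by default,

followed by selection of the decision threshold that maximizes F1 on the
training scores.  Inference is deterministic (dropout off).

The default hyperparameters are the full-scale configuration (4 encoder
and 4 decoder layers, 4 heads, hidden size 128, feed-forward 512, Adam at
1e-4, batch 512, 20,000 iterations per stage, no early stopping);
``HbA1cTransformer.desk()`` returns a scaled-down profile (2+2 layers,
hidden 64, batch 64, 2,000 iterations) suitable for laptop-scale runs and
continuous testing.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .preprocess import WeeklySeries

__all__ = [
    "ModelConfig",
    "TokenSequence",
    "AttentionRecord",
    "HbA1cTransformer",
    "masked_softmax",
    "embed_series",
    "encoder_forward",
    "decoder_forward",
    "regression_head",
    "focal_loss",
]


@dataclass
class ModelConfig:
    """Full model configuration (architecture and optimization)."""

    encoder_layers: int = 4
    decoder_layers: int = 4
    heads: int = 4
    hidden_size: int = 128
    ffn_hidden: int = 512
    optimizer: str = "adam"
    learning_rate: float = 1e-4
    batch_size: int = 512
    iterations: int = 20_000
    pretrain_iterations: int = 20_000
    loss: str = "focal"
    focal_gamma: float = 2.0
    focal_alpha: float = 0.25
    positional_encoding: str = "sinusoidal"
    dropout: float = 0.0

    def validate(self) -> None:
        self.arch().validate()
        if self.focal_gamma < 0:
            raise ValueError("focal_gamma must be >= 0")
        if not 0.0 < self.focal_alpha <= 1.0:
            raise ValueError("focal_alpha must lie in (0, 1]")
        for name in ("learning_rate", "batch_size", "iterations", "pretrain_iterations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def arch(self, dtype: str = "float32") -> nn.ArchConfig:
        return nn.ArchConfig(
            d_model=self.hidden_size,
            n_heads=self.heads,
            d_ff=self.ffn_hidden,
            encoder_layers=self.encoder_layers,
            decoder_layers=self.decoder_layers,
            dropout=self.dropout,
            causal=True,
            dtype=dtype,
        )


#: scaled-down profile for interactive use and CI.  The training budget is
#: ~80x smaller than the full-scale configuration (batch 64 x 2,000 vs
#: 512 x 20,000), so the step size is raised to keep both stages converged.
DESK_PROFILE = ModelConfig(
    encoder_layers=2,
    decoder_layers=2,
    heads=4,
    hidden_size=64,
    ffn_hidden=256,
    learning_rate=1e-3,
    batch_size=64,
    iterations=2_000,
    pretrain_iterations=2_000,
)


@dataclass
class TokenSequence:
    """Embedded weekly grid: (W, hidden) rows plus a key-padding mask
    (True = missing / ignored)."""

    embeddings: np.ndarray
    key_padding_mask: np.ndarray


@dataclass
class AttentionRecord:
    """Per-instance attention maps.

    ``self_attention`` is (layers, heads, W, W), each row stochastic over
    unmasked keys at or before the query week and exactly 0 elsewhere.
    ``cross_attention`` is (layers, heads, W).  The aggregates average heads
    within a layer and then layers: ``self_salience[s]`` is the mean
    attention key week s receives over observed query rows;
    ``cross_mean`` is a probability vector over observed weeks.
    """

    self_attention: np.ndarray
    cross_attention: np.ndarray
    observed_mask: np.ndarray
    self_salience: np.ndarray
    cross_mean: np.ndarray
    probability: float


# ---------------------------------------------------------------------------
# spec-level operations (thin wrappers over the numerical core)


def masked_softmax(scores, mask) -> np.ndarray:
    """Softmax over unmasked entries; masked entries get weight exactly 0.

    ``mask`` follows the observation convention: True = participate.
    """
    scores = np.asarray(scores, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any(axis=-1).all():
        raise ValueError("all entries masked: softmax undefined")
    return nn.softmax_masked(scores, mask)


def _params_for(config: ModelConfig, params=None, seed: int = 0, dtype="float32"):
    if params is not None:
        return params
    return nn.init_params(config.arch(dtype), np.random.default_rng(seed))


def embed_series(series: WeeklySeries, config: ModelConfig, params=None, seed: int = 0) -> TokenSequence:
    """Embed a weekly series: value projection + sinusoidal week-position code.

    Missing slots produce exactly-zero rows and are flagged in the
    key-padding mask, so their stored sentinel can never reach the model.
    """
    if not series.observed_mask.any():
        raise ValueError("no observed values")
    params = _params_for(config, params, seed)
    arch = config.arch()
    vals = np.nan_to_num(series.values, nan=0.0)[None, :]
    emb = nn.embed_values(params, arch, vals, series.observed_mask[None, :])[0]
    return TokenSequence(embeddings=emb, key_padding_mask=~series.observed_mask)


def encoder_forward(values, observed_mask, config: ModelConfig, params=None, causal=True, seed=0):
    """Encoder pass for one series: returns (W, hidden) states and the
    (layers, heads, W, W) self-attention maps."""
    params = _params_for(config, params, seed)
    arch = config.arch()
    h, _, maps = nn.encoder_apply(
        params, arch, np.asarray(values, float)[None, :], np.asarray(observed_mask, bool)[None, :],
        causal=causal, collect_attention=True,
    )
    return h[0], np.stack([m[0] for m in maps])


def decoder_forward(encoder_states, key_padding_mask, config: ModelConfig, params=None, seed=0):
    """Decoder pass: poor-control probability plus (layers, heads, W)
    cross-attention maps.  ``key_padding_mask`` is True at missing weeks."""
    params = _params_for(config, params, seed)
    arch = config.arch()
    observed = ~np.asarray(key_padding_mask, bool)
    p, _, _, maps = nn.decoder_apply(
        params, arch, encoder_states[None, ...], observed[None, :], collect_attention=True
    )
    return float(p[0]), np.stack([m[0] for m in maps])


def regression_head(encoder_states, config: ModelConfig = None, params=None, seed=0):
    """Next-value predictions, one per week position, from encoder states."""
    params = _params_for(config or ModelConfig(hidden_size=encoder_states.shape[-1]), params, seed)
    return nn.regression_apply(params, encoder_states[None, ...])[0]


def focal_loss(p, y, gamma: float = 2.0, alpha: float = 0.25) -> float:
    """Mean focal loss -alpha * (1 - p_t)^gamma * ln(p_t) over a batch.

    ``p_t`` is p for positive labels and 1-p otherwise; probabilities are
    clamped to [1e-7, 1 - 1e-7].
    """
    p = np.atleast_1d(np.asarray(p, dtype=float))
    y = np.atleast_1d(np.asarray(y))
    return float(np.mean(nn.focal_loss_terms(p, y, gamma, alpha)))


# ---------------------------------------------------------------------------
# estimator


class HbA1cTransformer(ClassifierMixin, BaseEstimator):
    """Attention-based classifier of future poor glycemic control.

    Parameters mirror :class:`ModelConfig`; see the module docstring for
    the training protocol.  ``X`` rows are weekly HbA1c grids with NaN at
    missing weeks.
    """

    def __init__(
        self,
        encoder_layers: int = 4,
        decoder_layers: int = 4,
        heads: int = 4,
        hidden_size: int = 128,
        ffn_hidden: int = 512,
        learning_rate: float = 1e-4,
        batch_size: int = 512,
        iterations: int = 20_000,
        pretrain_iterations: int = 20_000,
        focal_gamma: float = 2.0,
        focal_alpha: float = 0.25,
        dropout: float = 0.0,
        freeze_encoder: bool = True,
        ssl_target: str = "next_observed",
        random_state: int | None = None,
    ):
        self.encoder_layers = encoder_layers
        self.decoder_layers = decoder_layers
        self.heads = heads
        self.hidden_size = hidden_size
        self.ffn_hidden = ffn_hidden
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.iterations = iterations
        self.pretrain_iterations = pretrain_iterations
        self.focal_gamma = focal_gamma
        self.focal_alpha = focal_alpha
        self.dropout = dropout
        self.freeze_encoder = freeze_encoder
        self.ssl_target = ssl_target
        self.random_state = random_state

    # -- profiles ---------------------------------------------------------

    @classmethod
    def desk(cls, **overrides) -> "HbA1cTransformer":
        """Scaled-down profile (2+2 layers, hidden 64, batch 64, 2,000
        iterations per stage)."""
        kw = dict(
            encoder_layers=DESK_PROFILE.encoder_layers,
            decoder_layers=DESK_PROFILE.decoder_layers,
            heads=DESK_PROFILE.heads,
            hidden_size=DESK_PROFILE.hidden_size,
            ffn_hidden=DESK_PROFILE.ffn_hidden,
            learning_rate=DESK_PROFILE.learning_rate,
            batch_size=DESK_PROFILE.batch_size,
            iterations=DESK_PROFILE.iterations,
            pretrain_iterations=DESK_PROFILE.pretrain_iterations,
        )
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def from_config(cls, config: ModelConfig, **overrides) -> "HbA1cTransformer":
        kw = dict(
            encoder_layers=config.encoder_layers,
            decoder_layers=config.decoder_layers,
            heads=config.heads,
            hidden_size=config.hidden_size,
            ffn_hidden=config.ffn_hidden,
            learning_rate=config.learning_rate,
            batch_size=config.batch_size,
            iterations=config.iterations,
            pretrain_iterations=config.pretrain_iterations,
            focal_gamma=config.focal_gamma,
            focal_alpha=config.focal_alpha,
            dropout=config.dropout,
        )
        kw.update(overrides)
        return cls(**kw)

    def config(self) -> ModelConfig:
        return ModelConfig(
            encoder_layers=self.encoder_layers,
            decoder_layers=self.decoder_layers,
            heads=self.heads,
            hidden_size=self.hidden_size,
            ffn_hidden=self.ffn_hidden,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            iterations=self.iterations,
            pretrain_iterations=self.pretrain_iterations,
            focal_gamma=self.focal_gamma,
            focal_alpha=self.focal_alpha,
            dropout=self.dropout,
        )

    # -- helpers ----------------------------------------------------------

    @staticmethod
    def _split_input(X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional (instances x weeks)")
        mask = ~np.isnan(X)
        return np.nan_to_num(X, nan=0.0), mask

    # -- fitting ----------------------------------------------------------

    def fit(self, X, y):
        from . import training  # local import to avoid a cycle

        cfg = self.config()
        cfg.validate()
        values, mask = self._split_input(X)
        y = np.asarray(y).astype(int).ravel()
        if len(y) != len(values):
            raise ValueError("X and y have different lengths")
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = values.shape[1]

        seed = 0 if self.random_state is None else int(self.random_state)
        ss = np.random.SeedSequence(seed)
        init_seed, pre_seed, sup_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3))

        arch = cfg.arch()
        params = nn.init_params(arch, np.random.default_rng(init_seed))
        params, self.pretrain_state_ = training.pretrain_self_supervised(
            values, mask, arch, params=params,
            learning_rate=self.learning_rate, batch_size=self.batch_size,
            iterations=self.pretrain_iterations, seed=pre_seed, ssl_target=self.ssl_target,
        )
        params, self.supervised_state_ = training.train_supervised(
            values, mask, y, params, arch,
            learning_rate=self.learning_rate, batch_size=self.batch_size,
            iterations=self.iterations, seed=sup_seed,
            gamma=self.focal_gamma, alpha=self.focal_alpha,
            freeze_encoder=self.freeze_encoder,
        )
        self.params_ = params
        self.arch_ = arch
        scores = self._scores(values, mask)
        self.threshold_ = training.select_threshold(scores, y)
        return self

    # -- inference --------------------------------------------------------

    def _scores(self, values, mask, batch: int = 256) -> np.ndarray:
        out = np.empty(len(values))
        for i in range(0, len(values), batch):
            h, _, _ = nn.encoder_apply(self.params_, self.arch_, values[i : i + batch], mask[i : i + batch])
            p, _, _, _ = nn.decoder_apply(self.params_, self.arch_, h, mask[i : i + batch])
            out[i : i + batch] = p
        return out

    def encode(self, X, batch: int = 256) -> tuple[np.ndarray, np.ndarray]:
        """Encoder states for each instance (deterministic, dropout off)."""
        values, mask = self._split_input(X)
        states = np.empty((len(values), values.shape[1], self.arch_.d_model), dtype=self.arch_.np_dtype)
        for i in range(0, len(values), batch):
            h, _, _ = nn.encoder_apply(self.params_, self.arch_, values[i : i + batch], mask[i : i + batch])
            states[i : i + batch] = h
        return states, mask

    def predict_proba(self, X) -> np.ndarray:
        values, mask = self._split_input(X)
        p = self._scores(values, mask)
        return np.column_stack([1.0 - p, p])

    def decision_function(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        p = self.predict_proba(X)[:, 1]
        return (p >= self.threshold_.value).astype(int)

    def attention_records(self, X) -> list[AttentionRecord]:
        """Self- and cross-attention maps for each instance (see
        :class:`AttentionRecord`)."""
        values, mask = self._split_input(X)
        records = []
        for i in range(len(values)):
            h, _, smaps = nn.encoder_apply(
                self.params_, self.arch_, values[i : i + 1], mask[i : i + 1], collect_attention=True
            )
            p, _, _, cmaps = nn.decoder_apply(
                self.params_, self.arch_, h, mask[i : i + 1], collect_attention=True
            )
            self_attn = np.stack([m[0] for m in smaps])  # (L, H, W, W)
            cross = np.stack([m[0] for m in cmaps])  # (L, H, W)
            agg_self = self_attn.mean(axis=1).mean(axis=0)  # heads, then layers
            obs = mask[i]
            salience = agg_self[obs].mean(axis=0)
            cross_mean = cross.mean(axis=1).mean(axis=0)
            records.append(
                AttentionRecord(
                    self_attention=self_attn,
                    cross_attention=cross,
                    observed_mask=obs,
                    self_salience=salience,
                    cross_mean=cross_mean,
                    probability=float(p[0]),
                )
            )
        return records

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        meta = {
            "config": dataclasses.asdict(self.config()),
            "params": {
                "freeze_encoder": self.freeze_encoder,
                "ssl_target": self.ssl_target,
                "random_state": self.random_state,
            },
            "threshold": {
                "value": self.threshold_.value,
                "f1_at_threshold": self.threshold_.f1_at_threshold,
                "selected_on": self.threshold_.selected_on,
            },
            "n_features_in": int(self.n_features_in_),
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **self.params_)

    @classmethod
    def load(cls, path) -> "HbA1cTransformer":
        from .training import DecisionThreshold

        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            params = {k: data[k] for k in data.files if k != "__meta__"}
        cfg = ModelConfig(**meta["config"])
        est = cls.from_config(cfg, **meta["params"])
        est.params_ = params
        est.arch_ = cfg.arch()
        est.classes_ = np.array([0, 1])
        est.n_features_in_ = meta["n_features_in"]
        est.threshold_ = DecisionThreshold(**meta["threshold"])
        return est
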