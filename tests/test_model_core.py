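"""Attention masking contracts, focal loss closed forms, gradient checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import glycontrol as g
from glycontrol import nn
from glycontrol.model import ModelConfig, embed_series, focal_loss, masked_softmax
from glycontrol.preprocess import WeeklySeries


class TestMaskedSoftmax:
    def test_single_unmasked_key_gets_weight_one(self):
        w = masked_softmax([3.0, -1.0, 5.0], [False, True, False])
        np.testing.assert_array_equal(w, [0.0, 1.0, 0.0])

    def test_equal_scores_split_evenly(self):
        w = masked_softmax(np.zeros(5), [True, True, False, True, True])
        np.testing.assert_allclose(w[[0, 1, 3, 4]], 0.25)
        assert w[2] == 0.0

    def test_known_softmax_value(self):
        w = masked_softmax([0.0, np.log(3.0)], [True, True])
        np.testing.assert_allclose(w, [0.25, 0.75], atol=1e-12)

    def test_all_masked_raises_not_nan(self):
        with pytest.raises(ValueError, match="masked"):
            masked_softmax([1.0, 2.0], [False, False])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-30, 30), min_size=2, max_size=12), st.data())
    def test_row_stochastic_with_exact_zeros(self, scores, data):
        mask = data.draw(
            st.lists(st.booleans(), min_size=len(scores), max_size=len(scores)).filter(any)
        )
        w = masked_softmax(scores, mask)
        assert (w >= 0).all()
        assert w[~np.asarray(mask)].sum() == 0.0  # exactly zero, not small
        assert w.sum() == pytest.approx(1.0, abs=1e-6)


class TestEmbedding:
    def _series(self, values, mask):
        vals = np.where(mask, values, np.nan)
        return WeeklySeries(__import__("datetime").date(2013, 6, 15), 1, vals, np.asarray(mask))

    def test_shape_matches_hidden_size(self):
        rng = np.random.default_rng(0)
        mask = np.ones(53, bool)
        tok = embed_series(self._series(rng.normal(7, 1, 53), mask), ModelConfig())
        assert tok.embeddings.shape == (53, 128)
        assert not tok.key_padding_mask.any()

    def test_masked_slot_sentinel_cannot_leak(self):
        rng = np.random.default_rng(1)
        mask = rng.random(53) < 0.2
        mask[10] = True
        vals = rng.normal(7, 1, 53)
        a = embed_series(self._series(vals, mask), ModelConfig(), seed=7)
        # same series, masked entries never even reach embed_series (NaN there)
        b = embed_series(self._series(vals, mask), ModelConfig(), seed=7)
        np.testing.assert_array_equal(a.embeddings, b.embeddings)
        assert (a.embeddings[~mask] == 0.0).all()

    def test_all_masked_rejected(self):
        with pytest.raises(ValueError, match="no observed values"):
            embed_series(self._series(np.zeros(53), np.zeros(53, bool)), ModelConfig())


class TestEncoderContracts:
    def test_causal_cone(self, tiny_arch, tiny_params, random_series):
        """Perturbing week t changes hidden states only at weeks >= t."""
        values, mask = random_series
        h0, _, _ = nn.encoder_apply(tiny_params, tiny_arch, values, mask)
        row = 0
        t = int(np.flatnonzero(mask[row])[1])
        values2 = values.copy()
        values2[row, t] += 1.0
        h1, _, _ = nn.encoder_apply(tiny_params, tiny_arch, values2, mask)
        np.testing.assert_array_equal(h0[row, :t], h1[row, :t])
        assert np.abs(h0[row, t:] - h1[row, t:]).max() > 0

    def test_masked_slot_perturbation_changes_nothing(self, tiny_arch, tiny_params, random_series):
        values, mask = random_series
        h0, _, _ = nn.encoder_apply(tiny_params, tiny_arch, values, mask)
        values2 = values.copy()
        values2[~mask] = 1e6  # arbitrary finite sentinel
        h1, _, _ = nn.encoder_apply(tiny_params, tiny_arch, values2, mask)
        np.testing.assert_array_equal(h0, h1)

    def test_attention_maps_shape_and_invariants(self, tiny_arch, tiny_params, random_series):
        values, mask = random_series
        _, _, maps = nn.encoder_apply(tiny_params, tiny_arch, values, mask, collect_attention=True)
        assert len(maps) == tiny_arch.encoder_layers
        w = values.shape[1]
        upper = ~np.tril(np.ones((w, w), bool))
        for m in maps:
            assert m.shape == (len(values), tiny_arch.n_heads, w, w)
            for b in range(len(values)):
                # masked keys receive exactly zero attention everywhere
                assert m[b, :, :, ~mask[b]].sum() == 0.0
            # causal zeros: key week > query week
            assert m[:, :, upper].sum() == 0.0
            # rows of observed queries are stochastic over valid keys
            rowsums = m.mean(axis=1).sum(axis=-1)
            assert np.allclose(rowsums[mask], 1.0, atol=1e-5)

    def test_full_scale_map_count(self):
        cfg = ModelConfig()
        rng = np.random.default_rng(0)
        values = rng.normal(7, 1, (1, 53))
        mask = np.ones((1, 53), bool)
        h, smaps = g.model.encoder_forward(values[0], mask[0], cfg)
        assert smaps.shape == (4, 4, 53, 53)
        assert h.shape == (53, 128)


class TestDecoderContracts:
    def test_probability_in_unit_interval_and_cross_rows_stochastic(
        self, tiny_arch, tiny_params, random_series
    ):
        values, mask = random_series
        h, _, _ = nn.encoder_apply(tiny_params, tiny_arch, values, mask)
        p, _, _, maps = nn.decoder_apply(tiny_params, tiny_arch, h, mask, collect_attention=True)
        assert ((p >= 0) & (p <= 1)).all()
        for m in maps:  # (B, H, W)
            np.testing.assert_allclose(m.sum(axis=-1), 1.0, atol=1e-5)
            assert m[~np.repeat(mask[:, None, :], tiny_arch.n_heads, 1)].sum() == 0.0

    def test_deterministic_inference(self, tiny_arch, tiny_params, random_series):
        values, mask = random_series
        h, _, _ = nn.encoder_apply(tiny_params, tiny_arch, values, mask)
        p1, _, _, _ = nn.decoder_apply(tiny_params, tiny_arch, h, mask)
        p2, _, _, _ = nn.decoder_apply(tiny_params, tiny_arch, h, mask)
        np.testing.assert_array_equal(p1, p2)


class TestRegressionHead:
    def test_output_length_and_causality(self, tiny_arch, tiny_params, random_series):
        values, mask = random_series
        h, _, _ = nn.encoder_apply(tiny_params, tiny_arch, values, mask)
        pred = nn.regression_apply(tiny_params, h)
        assert pred.shape == values.shape
        t = int(np.flatnonzero(mask[0])[-1])
        values2 = values.copy()
        values2[0, t] += 2.0  # last observed week: predictions before t unchanged
        h2, _, _ = nn.encoder_apply(tiny_params, tiny_arch, values2, mask)
        pred2 = nn.regression_apply(tiny_params, h2)
        np.testing.assert_array_equal(pred[0, :t], pred2[0, :t])


class TestFocalLoss:
    def test_gamma_zero_alpha_one_is_cross_entropy(self):
        assert focal_loss(0.5, 1, gamma=0.0, alpha=1.0) == pytest.approx(np.log(2), abs=1e-12)
        rng = np.random.default_rng(0)
        p = rng.uniform(0.01, 0.99, 100)
        y = rng.integers(0, 2, 100)
        ce = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert focal_loss(p, y, gamma=0.0, alpha=1.0) == pytest.approx(ce, abs=1e-9)

    def test_tabulated_value(self):
        assert focal_loss(0.9, 1, gamma=2.0, alpha=1.0) == pytest.approx(
            0.01 * -np.log(0.9), abs=1e-9
        )

    def test_perfect_prediction_near_zero(self):
        assert focal_loss(1.0 - 1e-9, 1, gamma=2.0, alpha=0.25) < 1e-8

    def test_out_of_range_probability_clamped_finite(self):
        assert np.isfinite(focal_loss(0.0, 1, gamma=2.0, alpha=0.25))
        assert np.isfinite(focal_loss(1.0, 0, gamma=2.0, alpha=0.25))


def test_parameter_count_independent_of_grid_width(tiny_arch, tiny_params):
    """Positional encoding is non-learned, so one model serves N=1..5."""
    n0 = nn.param_count(tiny_params)
    rng = np.random.default_rng(0)
    for w in (53, 105, 261):
        values = rng.normal(7, 1, (2, w))
        mask = np.ones((2, w), bool)
        h, _, _ = nn.encoder_apply(tiny_params, tiny_arch, values, mask)
        assert h.shape == (2, w, tiny_arch.d_model)
    assert nn.param_count(tiny_params) == n0


class TestGradients:
    """Central-difference verification of the hand-written backward passes."""

    def _setup(self):
        rng = np.random.default_rng(3)
        arch = nn.ArchConfig(d_model=8, n_heads=2, d_ff=16, encoder_layers=1,
                             decoder_layers=1, dtype="float64")
        params = nn.init_params(arch, rng)
        values = rng.normal(7, 1, (2, 6))
        mask = np.array([[True, False, True, True, False, True]] * 2)
        return arch, params, values, mask, rng

    def _check(self, params, grads, loss_fn, keys, tol=1e-6):
        rng = np.random.default_rng(9)
        for k in keys:
            flat = params[k].reshape(-1)
            ga = np.asarray(grads[k]).reshape(-1)
            for idx in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                eps = 1e-6
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = loss_fn()
                flat[idx] = orig - eps
                lm = loss_fn()
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert abs(num - ga[idx]) / max(1.0, abs(num)) < tol, k

    def test_ssl_loss_gradients(self):
        arch, params, values, mask, rng = self._setup()
        targets = rng.normal(7, 1, values.shape)
        tmask = mask.copy()

        def loss_fn():
            h, _, _ = nn.encoder_apply(params, arch, values, mask)
            return nn.masked_mse(nn.regression_apply(params, h), targets, tmask)[0]

        h, caches, _ = nn.encoder_apply(params, arch, values, mask)
        loss, dpred = nn.masked_mse(nn.regression_apply(params, h), targets, tmask)
        grads = {}
        dh = nn.regression_backward(dpred, h, params, grads)
        nn.encoder_backward(dh, caches, params, arch, grads)
        self._check(params, grads, loss_fn, nn.encoder_param_names(params))

    def test_focal_loss_gradients_through_decoder_and_encoder(self):
        arch, params, values, mask, rng = self._setup()
        y = np.array([1, 0])

        def loss_fn():
            h, _, _ = nn.encoder_apply(params, arch, values, mask)
            p, _, _, _ = nn.decoder_apply(params, arch, h, mask)
            return float(np.mean(nn.focal_loss_terms(p, y, 2.0, 0.25)))

        h, ecaches, _ = nn.encoder_apply(params, arch, values, mask)
        p, _, dcaches, _ = nn.decoder_apply(params, arch, h, mask)
        grads = {}
        dlogit = nn.focal_loss_dlogit(p, y, 2.0, 0.25) / len(y)
        _, dhenc = nn.decoder_backward(dlogit, dcaches, params, arch, grads)
        nn.encoder_backward(dhenc, ecaches, params, arch, grads)
        self._check(params, grads, loss_fn, list(grads))
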