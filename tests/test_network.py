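"""Network-layer correctness: scalar-loop oracles, receptive field,
padding invariance, decoder contracts and causality."""

import numpy as np
import pytest

from seqsite import autodiff as ad
from seqsite.autodiff import Tensor
from seqsite.features import dummy_feature_row
from seqsite.network import (
    NetworkConfig,
    encoder_conv_layers,
    encoder_forward,
    en_decoder_forward,
    forward_logits,
    init_weights,
    extend_to_en,
    pad_batch,
    predict,
    receptive_field,
    softmax_probabilities,
    std_decoder_forward,
    LN_EPS,
)
from seqsite.features import FeatureMap


# ---------------------------------------------------------------------------
# independent scalar-loop oracles
# ---------------------------------------------------------------------------

def glu_oracle(x: np.ndarray) -> np.ndarray:
    m, _, ch = x.shape
    half = ch // 2
    out = np.zeros((m, 1, half))
    for i in range(m):
        for j in range(half):
            a = x[i, 0, j]
            b = x[i, 0, half + j]
            out[i, 0, j] = a * (1.0 / (1.0 + np.exp(-b)))
    return out


def layer_norm_oracle(x: np.ndarray, gain, offset, eps=LN_EPS) -> np.ndarray:
    out = np.zeros_like(x)
    for i in range(x.shape[0]):
        row = x[i, 0]
        mu = sum(row) / len(row)
        var = sum((v - mu) ** 2 for v in row) / len(row)
        for j in range(len(row)):
            out[i, 0, j] = (row[j] - mu) / np.sqrt(var + eps) * gain[j] + offset[j]
    return out


def conv_oracle(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Width-k convolution, zero-padded (k-1)/2 per side, via nested loops."""
    m, _, cin = x.shape
    k, _, cout = w.shape
    r = (k - 1) // 2
    out = np.zeros((m, 1, cout))
    for i in range(m):
        for o in range(cout):
            acc = b[o]
            for t in range(k):
                src = i + t - r
                if 0 <= src < m:
                    for ci in range(cin):
                        acc += x[src, 0, ci] * w[t, ci, o]
            out[i, 0, o] = acc
    return out


def basic_block_oracle(x, ln_g, ln_b, w, b, residual=True):
    z = layer_norm_oracle(x, ln_g, ln_b)
    z = glu_oracle(z)
    z = conv_oracle(z, w, b)
    return z + x if residual else z


class TestLayerOracles:
    """Fused vectorized layers agree with naive scalar loops to 1e-5."""

    def setup_method(self):
        self.rng = np.random.default_rng(7)

    def test_glu_matches_loop_oracle(self):
        x = self.rng.normal(size=(9, 1, 8))
        got = ad.glu(Tensor(x[None, :, 0, :])).data[0][:, None, :]
        np.testing.assert_allclose(got, glu_oracle(x), atol=1e-6)

    def test_glu_basic_values_and_saturation(self):
        out = ad.glu(Tensor(np.array([[[1.0, -2.0, 0.0, 0.0]]])))
        np.testing.assert_allclose(out.data, [[[0.5, -1.0]]])
        sat = ad.glu(Tensor(np.array([[[3.0, -1.5, 50.0, 50.0]]])))
        np.testing.assert_allclose(sat.data, [[[3.0, -1.5]]], atol=1e-9)

    def test_glu_rejects_odd_channels(self):
        with pytest.raises(ValueError):
            ad.glu(Tensor(np.zeros((1, 2, 3))))

    def test_layer_norm_matches_loop_oracle(self):
        x = self.rng.normal(size=(7, 1, 6))
        gain = self.rng.normal(size=6)
        offset = self.rng.normal(size=6)
        got = ad.layer_norm(Tensor(x[None, :, 0, :]), Tensor(gain), Tensor(offset)).data
        np.testing.assert_allclose(got[0][:, None, :], layer_norm_oracle(x, gain, offset), atol=1e-6)

    def test_conv_matches_loop_oracle(self):
        x = self.rng.normal(size=(8, 1, 3))
        w = self.rng.normal(size=(5, 3, 4))
        b = self.rng.normal(size=4)
        got = ad.conv1d(Tensor(x[None, :, 0, :]), Tensor(w), Tensor(b)).data
        np.testing.assert_allclose(got[0][:, None, :], conv_oracle(x, w, b), atol=1e-6)

    def test_basic_block_matches_composed_oracle(self):
        m, c, k = 7, 2, 3
        cfg = NetworkConfig(k=k, blocks_per_stage=1, c=c, d=4, dropout=0.0)
        weights = init_weights(cfg, self.rng)
        x = self.rng.normal(size=(m, 1, 2 * c))
        from seqsite.network import _basic_block

        mask = np.ones((1, m), dtype=bool)
        got = _basic_block(Tensor(x[None, :, 0, :]), weights, "enc.s1.b0", mask, residual=True)
        expected = basic_block_oracle(
            x,
            weights["enc.s1.b0.ln.g"].data, weights["enc.s1.b0.ln.b"].data,
            weights["enc.s1.b0.conv.W"].data, weights["enc.s1.b0.conv.b"].data,
        )
        np.testing.assert_allclose(got.data[0][:, None, :], expected, atol=1e-5)

    def test_zero_conv_weights_give_pure_residual(self):
        cfg = NetworkConfig(k=3, blocks_per_stage=1, c=3, d=4, dropout=0.0)
        weights = init_weights(cfg, self.rng)
        weights["enc.s1.b0.conv.W"].data[:] = 0.0
        weights["enc.s1.b0.conv.b"].data[:] = 0.0
        from seqsite.network import _basic_block

        x = self.rng.normal(size=(1, 6, 6))
        mask = np.ones((1, 6), dtype=bool)
        out = _basic_block(Tensor(x), weights, "enc.s1.b0", mask, residual=True)
        np.testing.assert_allclose(out.data, x)


# ---------------------------------------------------------------------------
# receptive field
# ---------------------------------------------------------------------------

class TestReceptiveField:
    @pytest.mark.parametrize("n, k, expected", [(1, 1, 1), (10, 3, 21), (20, 5, 81), (0, 5, 1)])
    def test_formula(self, n, k, expected):
        assert receptive_field(n, k) == expected

    @staticmethod
    def _empirical_radius(forward, m, d, probe_pos):
        """Largest |j - probe_pos| at which perturbing input row j changes
        the output at probe_pos."""
        rng = np.random.default_rng(0)
        base = rng.normal(size=(1, m, d))
        mask = np.ones((1, m), dtype=bool)
        ref = forward(base, mask)[0, probe_pos]
        radius = 0
        for j in range(m):
            x = base.copy()
            # perturb one channel only: a uniform row shift is LN-invariant
            x[0, j, 0] += 1.0
            if np.max(np.abs(forward(x, mask)[0, probe_pos] - ref)) > 1e-9:
                radius = max(radius, abs(j - probe_pos))
        return radius

    @pytest.mark.parametrize("n_blocks, k", [(2, 3), (2, 5), (4, 3), (4, 5)])
    def test_block_stack_field_matches_law(self, n_blocks, k):
        """A free-standing stack of n BasicBlocks has input field 1 + n(k-1)."""
        c = 3
        cfg = NetworkConfig(k=k, blocks_per_stage=n_blocks, c=c, d=2 * c, dropout=0.0)
        weights = init_weights(cfg, np.random.default_rng(5))
        from seqsite.network import _basic_block

        def forward(x, mask):
            h = Tensor(x)
            for j in range(n_blocks):
                h = _basic_block(h, weights, f"enc.s1.b{j}", mask, residual=(j > 0))
            return h.data

        field = receptive_field(n_blocks, k)
        m = field + 8
        radius = self._empirical_radius(forward, m, 2 * c, probe_pos=m // 2)
        assert 2 * radius + 1 == field

    @pytest.mark.parametrize("blocks_per_stage, k", [(1, 3), (1, 5), (2, 3)])
    def test_full_encoder_field_matches_law(self, blocks_per_stage, k):
        cfg = NetworkConfig(k=k, blocks_per_stage=blocks_per_stage, c=3, d=6, dropout=0.0)
        weights = init_weights(cfg, np.random.default_rng(6))

        def forward(x, mask):
            return encoder_forward(x, mask, weights).data

        n = encoder_conv_layers(cfg)
        assert n == 2 * blocks_per_stage + 1
        field = receptive_field(n, k)
        m = field + 8
        radius = self._empirical_radius(forward, m, cfg.d, probe_pos=m // 2)
        assert 2 * radius + 1 == field


# ---------------------------------------------------------------------------
# padding / batching invariance
# ---------------------------------------------------------------------------

def _random_maps(rng, lengths):
    maps = []
    for i, L in enumerate(lengths):
        vals = rng.uniform(0, 1, size=(L, 30))
        maps.append(FeatureMap(vals, protein_id=f"p{i}"))
    return maps


class TestPaddingInvariance:
    def test_encoder_rows_independent_of_padding(self):
        rng = np.random.default_rng(3)
        cfg = NetworkConfig(k=3, blocks_per_stage=2, c=4, dropout=0.0)
        weights = init_weights(cfg, rng)
        maps = _random_maps(rng, [11, 7, 19])
        solo = encoder_forward(pad_batch([maps[1]]).features,
                               pad_batch([maps[1]]).mask, weights).data[0, :7]
        batch = pad_batch(maps)
        together = encoder_forward(batch.features, batch.mask, weights).data[1, :7]
        np.testing.assert_allclose(together, solo, atol=1e-12)
        # extra explicit padding changes nothing either
        padded = pad_batch([maps[1]], pad_to=40)
        alone_padded = encoder_forward(padded.features, padded.mask, weights).data[0, :7]
        np.testing.assert_allclose(alone_padded, solo, atol=1e-12)

    @pytest.mark.parametrize("mode", ["std", "en"])
    def test_predictions_independent_of_batch_composition(self, mode):
        rng = np.random.default_rng(4)
        cfg = NetworkConfig(k=3, blocks_per_stage=1, c=4, dropout=0.0, mode=mode)
        weights = init_weights(cfg, rng)
        if mode == "en":
            for n in ("ctxl", "ctxr"):
                weights[f"{n}.ln.g"].data[:] = 0.7  # activate context path
        maps = _random_maps(rng, [9, 14, 5])
        solo = {m.protein_id: predict(weights, m)[0] for m in maps}
        batched = predict(weights, maps)
        for r in batched:
            np.testing.assert_allclose(
                r.probabilities, solo[r.protein_id].probabilities, atol=1e-12)
            assert np.array_equal(r.labels, solo[r.protein_id].labels)


# ---------------------------------------------------------------------------
# decoders
# ---------------------------------------------------------------------------

class TestStdDecoder:
    def test_probability_rows_sum_to_one_and_masked_rows_removed(self):
        rng = np.random.default_rng(5)
        cfg = NetworkConfig(k=3, blocks_per_stage=1, c=4, dropout=0.5)
        weights = init_weights(cfg, rng)
        maps = _random_maps(rng, [6, 10])
        results = predict(weights, maps)
        assert [len(r.probabilities) for r in results] == [6, 10]
        for r in results:
            np.testing.assert_allclose(r.probabilities.sum(axis=1), 1.0, atol=1e-9)

    def test_inference_is_deterministic_despite_dropout_config(self):
        rng = np.random.default_rng(6)
        cfg = NetworkConfig(k=3, blocks_per_stage=1, c=4, dropout=0.5)
        weights = init_weights(cfg, rng)
        fm = _random_maps(rng, [12])[0]
        a = predict(weights, fm)[0].probabilities
        b = predict(weights, fm)[0].probabilities
        np.testing.assert_array_equal(a, b)

    def test_threshold_extremes(self):
        rng = np.random.default_rng(7)
        cfg = NetworkConfig(k=3, blocks_per_stage=1, c=4, dropout=0.0)
        weights = init_weights(cfg, rng)
        fm = _random_maps(rng, [15])[0]
        assert predict(weights, fm, threshold=1.0 + 1e-9)[0].labels.sum() == 0
        assert predict(weights, fm, threshold=1e-12)[0].labels.sum() == 15


class TestEnDecoder:
    def _setup(self, seed=8, m=14):
        rng = np.random.default_rng(seed)
        cfg = NetworkConfig(k=3, blocks_per_stage=1, context_blocks=2, c=4,
                            dropout=0.0, mode="en")
        weights = init_weights(cfg, rng)
        for n in ("ctxl", "ctxr"):
            weights[f"{n}.ln.g"].data[:] = rng.normal(size=2 * cfg.c)
            weights[f"{n}.ln.b"].data[:] = rng.normal(size=2 * cfg.c)
        fm = _random_maps(rng, [m])[0]
        batch = pad_batch([fm])
        enc = encoder_forward(batch.features, batch.mask, weights)
        return rng, weights, batch, enc

    def test_zero_context_is_well_defined(self):
        _, weights, batch, enc = self._setup()
        ctx = np.zeros(batch.mask.shape + (2,))
        logits = en_decoder_forward(enc, ctx, batch.mask, weights)
        probs = softmax_probabilities(logits.data, batch.mask)
        np.testing.assert_allclose(probs[batch.mask].sum(axis=-1), 1.0, atol=1e-9)

    def test_context_branch_causality(self):
        """Perturbing context at position i never changes outputs that the
        causal branches must not see: the left branch is blind to positions
        >= i, the right branch to positions <= i."""
        rng, weights, batch, enc = self._setup()
        from seqsite.network import _context_branch

        m = batch.features.shape[1]
        base = rng.uniform(0, 1, size=(1, m, 2))
        for side, blind in (("ctxl", "ge"), ("ctxr", "le")):
            ref = _context_branch(Tensor(base), batch.mask, weights, side).data
            for i in range(m):
                pert = base.copy()
                pert[0, i] += 1.3
                out = _context_branch(Tensor(pert), batch.mask, weights, side).data
                diff = np.max(np.abs(out - ref), axis=-1)[0]
                if blind == "ge":
                    assert np.all(diff[: i + 1] < 1e-12)
                else:
                    assert np.all(diff[i:] < 1e-12)

    def test_context_length_mismatch_rejected(self):
        _, weights, batch, enc = self._setup()
        bad = np.zeros((1, batch.features.shape[1] + 2, 2))
        with pytest.raises(ValueError):
            en_decoder_forward(enc, bad, batch.mask, weights)

    def test_fresh_context_branch_contributes_zero(self):
        """With zero-initialized stage-top LN, an untrained en network makes
        exactly the std network's predictions."""
        rng = np.random.default_rng(9)
        cfg = NetworkConfig(k=3, blocks_per_stage=1, c=4, dropout=0.0)
        std_w = init_weights(cfg, rng)
        en_w = extend_to_en(std_w, rng)
        fm = _random_maps(rng, [13])[0]
        np.testing.assert_allclose(
            predict(en_w, fm)[0].probabilities,
            predict(std_w, fm)[0].probabilities, atol=1e-12)

    def test_teacher_forced_context_matches_training_graph(self):
        """predict() with an explicit label context equals the teacher-forced
        forward pass used during training."""
        rng = np.random.default_rng(10)
        cfg = NetworkConfig(k=3, blocks_per_stage=1, context_blocks=1, c=4,
                            dropout=0.0, mode="en")
        weights = init_weights(cfg, rng)
        for n in ("ctxl", "ctxr"):
            weights[f"{n}.ln.g"].data[:] = 0.5
        fm = _random_maps(rng, [11])[0]
        batch = pad_batch([fm], labels=[rng.integers(0, 2, size=11)])
        from seqsite.training import _one_hot_context

        ctx = _one_hot_context(batch)
        train_logits = forward_logits(batch, weights, context=ctx, training=False)
        train_probs = softmax_probabilities(train_logits.data, batch.mask)[0, :11]
        infer = predict(weights, fm, context=ctx)[0]
        np.testing.assert_allclose(infer.probabilities, train_probs, atol=1e-12)


class TestWeightsContainer:
    def test_state_dict_round_trip_is_bit_exact(self):
        cfg = NetworkConfig(k=3, blocks_per_stage=1, c=4, mode="en")
        w = init_weights(cfg, np.random.default_rng(11))
        state = w.state_dict()
        w2 = init_weights(cfg, np.random.default_rng(99))
        w2.load_state_dict(state)
        for n in w.names():
            np.testing.assert_array_equal(w[n].data, w2[n].data)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            NetworkConfig(k=4)  # even kernel width
        with pytest.raises(ValueError):
            NetworkConfig(blocks_per_stage=0)
        with pytest.raises(ValueError):
            NetworkConfig(mode="fancy")

    def test_shape_mismatch_rejected(self):
        cfg = NetworkConfig(k=3, blocks_per_stage=1, c=4)
        w = init_weights(cfg, np.random.default_rng(0))
        state = w.state_dict()
        state["dec.fc2.W"] = np.zeros((3, 3))
        with pytest.raises(ValueError):
            w.load_state_dict(state)
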