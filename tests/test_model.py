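import numpy as np
import pytest

from oracles import fusion_forward_oracle
from pfnet.nn.layers import Conv2D, Dense, LocallyConnected2D, softmax
from pfnet.nn.model import VARIANTS, FusionNetwork


def small_net(variant="full", seed=0, loss_mode="per_head"):
    rng = np.random.default_rng(seed)
    return FusionNetwork(
        variant, raw_shape=(6, 4), dwpt_shape=(8, 8), num_classes=5,
        maps=3, fc_feature=10, fc_knowledge=12, fc_fusion=7,
        dropout_rate=0.5, rng=rng, loss_mode=loss_mode,
    )


def small_inputs(seed=1, B=3):
    rng = np.random.default_rng(seed)
    return rng.standard_normal((B, 6, 4)), rng.standard_normal((B, 8, 8))


class TestForwardContract:
    def test_full_forward_matches_straight_line_oracle(self):
        """y1, y2 and their sum must equal the hand-composed 3-stage
        fusion computed layer-by-layer from the raw parameter arrays."""
        net = small_net()
        xf, xd = small_inputs()
        out = net.forward(xf, xd, training=False)
        y1, y2, y_final = fusion_forward_oracle(net, xf, xd)
        np.testing.assert_allclose(out["y1"], y1, atol=1e-6)
        np.testing.assert_allclose(out["y2"], y2, atol=1e-6)
        np.testing.assert_allclose(out["scores"], y_final, atol=1e-6)

    def test_softmax_heads_are_normalized(self):
        net = small_net()
        xf, xd = small_inputs()
        out = net.forward(xf, xd)
        for head in ("y1", "y2"):
            assert np.all(out[head] >= 0)
            np.testing.assert_allclose(out[head].sum(axis=1), 1.0)

    def test_fused_scores_sum_to_two(self):
        net = small_net()
        xf, xd = small_inputs()
        out = net.forward(xf, xd)
        np.testing.assert_allclose(out["scores"].sum(axis=1), 2.0)

    def test_shared_peak_survives_summation(self):
        y1 = softmax(np.array([[10.0, 0, 0, 0, 0]]))
        y2 = softmax(np.array([[8.0, 1, 0, 0, 0]]))
        assert np.argmax(y1 + y2) == 0

    def test_uniform_second_head_preserves_first_head_argmax(self):
        """Zeroing H2's output layer makes y2 uniform, so the fused
        decision must coincide with stage-1 alone."""
        net = small_net()
        final_dense = net._modules["h2"].layers[-1]
        final_dense.W[...] = 0.0
        final_dense.b[...] = 0.0
        xf, xd = small_inputs(seed=5, B=8)
        out = net.forward(xf, xd)
        np.testing.assert_allclose(out["y2"], 1.0 / 5, atol=1e-12)
        np.testing.assert_array_equal(
            np.argmax(out["scores"], axis=1), np.argmax(out["y1"], axis=1)
        )

    def test_all_variants_produce_width_num_classes(self):
        xf, xd = small_inputs()
        for variant in VARIANTS:
            out = small_net(variant).forward(xf, xd)
            assert out["scores"].shape == (3, 5), variant

    def test_decision_fusion_scores_are_sum_of_stream_heads(self):
        net = small_net("decision_fusion")
        xf, xd = small_inputs()
        out = net.forward(xf, xd)
        np.testing.assert_allclose(out["scores"], out["y1"] + out["y2"], atol=1e-12)
        np.testing.assert_allclose(out["scores"].sum(axis=1), 2.0)

    def test_variant_head_counts(self):
        xf, xd = small_inputs()
        assert set(small_net("full").forward(xf, xd)) == {"y1", "y2", "scores"}
        assert set(small_net("stage1_only").forward(xf, xd)) == {"y1", "scores"}
        assert set(small_net("stage2_only").forward(xf, xd)) == {"y2", "scores"}

    def test_flonly_ignores_coefficient_stream(self):
        rng = np.random.default_rng(0)
        net = FusionNetwork("FLonly", (6, 4), None, 5, maps=3,
                            fc_feature=10, fc_knowledge=12, fc_fusion=7, rng=rng)
        xf, xd = small_inputs()
        out1 = net.forward(xf, None)
        out2 = net.forward(xf, np.random.default_rng(9).standard_normal((3, 8, 8)))
        np.testing.assert_array_equal(out1["scores"], out2["scores"])

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            small_net("bogus")


class TestLocallyConnected:
    def test_position_unsharing(self, rng):
        """Swapping two spatial positions of the input commutes with a
        1x1 convolution (tied weights) but not with a locally connected
        layer (per-position weights)."""
        x = rng.standard_normal((2, 4, 3, 2))
        x_swapped = x.copy()
        x_swapped[:, [0, 2]] = x_swapped[:, [2, 0]]

        conv = Conv2D(2, 3, (1, 1), rng)
        out = conv.forward(x)
        out_sw = conv.forward(x_swapped)
        ref = out.copy()
        ref[:, [0, 2]] = ref[:, [2, 0]]
        np.testing.assert_allclose(out_sw, ref, atol=1e-12)

        lc = LocallyConnected2D(4, 3, 2, 3, rng)
        out = lc.forward(x)
        out_sw = lc.forward(x_swapped)
        ref = out.copy()
        ref[:, [0, 2]] = ref[:, [2, 0]]
        assert not np.allclose(out_sw, ref)

    def test_parameter_count_exceeds_tied_conv(self, rng):
        H, W, ci, co = 5, 4, 3, 6
        lc = LocallyConnected2D(H, W, ci, co, rng)
        conv = Conv2D(ci, co, (1, 1), rng)
        lc_params = sum(p.size for p in lc.params)
        conv_params = sum(p.size for p in conv.params)
        assert lc_params == H * W * (ci * co + co)
        assert lc_params > conv_params == ci * co + co


class TestGradients:
    @pytest.mark.parametrize("variant", ["full", "FLonly", "decision_fusion"])
    def test_backprop_matches_finite_differences(self, variant):
        """Analytic gradients of the training loss agree with central
        finite differences on a sample of weights from every layer."""
        rng = np.random.default_rng(3)
        net = FusionNetwork(
            variant, raw_shape=(5, 4), dwpt_shape=(6, 6), num_classes=3,
            maps=2, fc_feature=6, fc_knowledge=6, fc_fusion=5,
            dropout_rate=0.0, rng=rng,
        )
        xf = rng.standard_normal((4, 5, 4))
        xd = rng.standard_normal((4, 6, 6))
        t = np.eye(3)[rng.integers(0, 3, size=4)]

        def loss():
            out = net.forward(xf, xd, training=True)
            return net._head_grads(out, t)[0]

        out = net.forward(xf, xd, training=True)
        net.zero_grad()
        net.backward(out, t)
        check = rng
        eps = 1e-6
        for p, g in zip(net.params, net.grads):
            flat_idx = check.integers(0, p.size, size=min(3, p.size))
            for i in flat_idx:
                orig = p.flat[i]
                p.flat[i] = orig + eps
                lp = loss()
                p.flat[i] = orig - eps
                lm = loss()
                p.flat[i] = orig
                num = (lp - lm) / (2 * eps)
                assert abs(num - g.flat[i]) < 1e-5 * max(1.0, abs(num)), (
                    f"gradient mismatch: analytic {g.flat[i]}, numeric {num}"
                )

    def test_final_score_loss_mode_gradients(self):
        rng = np.random.default_rng(4)
        net = FusionNetwork(
            "full", raw_shape=(5, 4), dwpt_shape=(6, 6), num_classes=3,
            maps=2, fc_feature=6, fc_knowledge=6, fc_fusion=5,
            dropout_rate=0.0, rng=rng, loss_mode="final",
        )
        xf = rng.standard_normal((3, 5, 4))
        xd = rng.standard_normal((3, 6, 6))
        t = np.eye(3)[[0, 2, 1]]
        out = net.forward(xf, xd, training=True)
        net.zero_grad()
        net.backward(out, t)
        p = net.params[0]
        g = net.grads[0]
        eps = 1e-6
        i = 1
        orig = p.flat[i]
        for sign in (+1, -1):
            p.flat[i] = orig + sign * eps
            o = net.forward(xf, xd, training=True)
            val = net._head_grads(o, t)[0]
            if sign > 0:
                lp = val
            else:
                lm = val
        p.flat[i] = orig
        assert abs((lp - lm) / (2 * eps) - g.flat[i]) < 1e-5


class TestInputValidation:
    def test_conv_smaller_than_filter_rejected(self, rng):
        conv = Conv2D(1, 2, (2, 2), rng, padding="valid")
        with pytest.raises(ValueError, match="smaller"):
            conv.forward(rng.standard_normal((1, 1, 1, 1)))

    def test_lc_shape_mismatch_rejected(self, rng):
        lc = LocallyConnected2D(4, 3, 2, 3, rng)
        with pytest.raises(ValueError, match="spatial"):
            lc.forward(rng.standard_normal((1, 5, 3, 2)))

    def test_dk_variant_requires_image_shape(self):
        with pytest.raises(ValueError, match="coefficient-image"):
            FusionNetwork("full", (6, 4), None, 5, rng=np.random.default_rng(0))
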