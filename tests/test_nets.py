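"""Architecture contracts: SE gating, SEC fusion pipeline, U-shape wiring,
pyramid structure, auto-context cascade, and label prediction — each checked
against independent loop-level oracles where values matter."""

import numpy as np
import pytest

from secpnet import (
    CascadeNet,
    NetworkConfig,
    SEBlock,
    SECFuse,
    SECPNet,
    UNetBackbone,
    predict_labels,
)
from secpnet.autodiff import Tensor
from secpnet.layers import parameter_hash
from secpnet.nets import (
    gradient_flow_audit,
    load_checkpoint,
    parameter_count,
    save_checkpoint,
)
from secpnet.training import cross_entropy_loss


# ---------------------------------------------------------------------------
# oracles: independent scalar-loop implementations
# ---------------------------------------------------------------------------


def conv3x3_oracle(x, w, b):
    """Same-padding correlation, one pixel at a time."""
    B, C, H, W = x.shape
    O = w.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    y = np.zeros((B, O, H, W))
    for bb in range(B):
        for o in range(O):
            for h in range(H):
                for c in range(W):
                    y[bb, o, h, c] = (xp[bb, :, h : h + 3, c : c + 3] * w[o]).sum()
                    y[bb, o, h, c] += b[o]
    return y


def upsample2x_oracle(x):
    """Bilinear 2x with half-pixel centres, scalar loops."""
    B, C, H, W = x.shape
    out = np.zeros((B, C, 2 * H, 2 * W))
    for i in range(2 * H):
        sy = min(max((i + 0.5) / 2 - 0.5, 0), H - 1)
        y0, ty = int(np.floor(sy)), None
        ty = sy - y0
        y1 = min(y0 + 1, H - 1)
        for j in range(2 * W):
            sx = min(max((j + 0.5) / 2 - 0.5, 0), W - 1)
            x0 = int(np.floor(sx))
            tx = sx - x0
            x1 = min(x0 + 1, W - 1)
            out[:, :, i, j] = (
                (1 - ty) * (1 - tx) * x[:, :, y0, x0]
                + (1 - ty) * tx * x[:, :, y0, x1]
                + ty * (1 - tx) * x[:, :, y1, x0]
                + ty * tx * x[:, :, y1, x1]
            )
    return out


def se_oracle(x, w1, b1, w2, b2):
    """GAP -> affine -> ReLU -> affine -> sigmoid -> channel scaling."""
    B, C = x.shape[:2]
    out = np.zeros_like(x)
    gates = np.zeros((B, C))
    for bb in range(B):
        gap = np.array([x[bb, c].mean() for c in range(C)])
        hidden = np.maximum(w1 @ gap + b1, 0.0)
        gates[bb] = 1.0 / (1.0 + np.exp(-(w2 @ hidden + b2)))
        for c in range(C):
            out[bb, c] = gates[bb, c] * x[bb, c]
    return out, gates


# ---------------------------------------------------------------------------
# SE block
# ---------------------------------------------------------------------------


class TestSEBlock:
    def test_zero_weights_gate_half(self, rng):
        se = SEBlock(channels=4, reduction=2, rng=rng)
        for p in se.parameters():
            p.data[...] = 0.0
        x = rng.normal(size=(2, 4, 8, 8))
        out = se(x)
        np.testing.assert_allclose(out.data, 0.5 * x, atol=1e-12)

    def test_zero_input_maps_to_zero(self, rng):
        se = SEBlock(channels=3, reduction=2, rng=rng)
        se.fc1.b.data[...] = 0.0
        se.fc2.b.data[...] = 0.0
        out = se(np.zeros((1, 3, 4, 4)))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_matches_loop_oracle(self, rng):
        se = SEBlock(channels=4, reduction=2, rng=rng)
        x = rng.normal(size=(2, 4, 8, 8))
        want, gates = se_oracle(
            x, se.fc1.w.data, se.fc1.b.data, se.fc2.w.data, se.fc2.b.data
        )
        np.testing.assert_allclose(se(x).data, want, atol=1e-6)
        assert np.all(gates > 0) and np.all(gates < 1)

    def test_output_never_exceeds_input_magnitude(self, rng):
        se = SEBlock(channels=5, reduction=4, rng=rng)
        x = rng.normal(size=(3, 5, 6, 6))
        assert np.all(np.abs(se(x).data) <= np.abs(x) + 1e-15)

    def test_rejects_nonfinite_input(self, rng):
        se = SEBlock(channels=2, reduction=1, rng=rng)
        x = np.zeros((1, 2, 4, 4))
        x[0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            se(x)

    def test_hidden_width_clamped_to_one(self, rng):
        se = SEBlock(channels=3, reduction=16, rng=rng)
        assert se.fc1.w.shape == (1, 3)


# ---------------------------------------------------------------------------
# SEC fusion
# ---------------------------------------------------------------------------


class TestSECFuse:
    def test_output_shape_contract(self, rng):
        sec = SECFuse(shallow_channels=8, deep_channels=16, reduction=2, rng=rng)
        out = sec(rng.normal(size=(2, 8, 32, 32)), rng.normal(size=(2, 16, 16, 16)))
        assert out.shape == (2, 8, 32, 32)

    def test_zero_weights_propagate_zero(self, rng):
        sec = SECFuse(4, 8, 2, rng)
        for p in sec.conv_deep.parameters():
            p.data[...] = 0.0
        for p in sec.conv_fuse.parameters():
            p.data[...] = 0.0
        out = sec(rng.normal(size=(1, 4, 8, 8)), rng.normal(size=(1, 8, 4, 4)))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_matches_five_step_oracle(self, rng):
        sec = SECFuse(shallow_channels=2, deep_channels=4, reduction=2, rng=rng)
        level1 = rng.normal(size=(2, 2, 4, 4))
        level2 = rng.normal(size=(2, 4, 2, 2))
        step1 = conv3x3_oracle(level2, sec.conv_deep.w.data, sec.conv_deep.b.data)
        step2 = upsample2x_oracle(step1)
        step3 = np.concatenate([level1, step2], axis=1)
        step4 = conv3x3_oracle(step3, sec.conv_fuse.w.data, sec.conv_fuse.b.data)
        want, _ = se_oracle(
            step4,
            sec.se.fc1.w.data, sec.se.fc1.b.data,
            sec.se.fc2.w.data, sec.se.fc2.b.data,
        )
        np.testing.assert_allclose(sec(level1, level2).data, want, atol=1e-5)

    def test_spatial_mismatch_reports_both_shapes(self, rng):
        sec = SECFuse(4, 8, 2, rng)
        with pytest.raises(ValueError, match=r"(?s)1, 4, 8, 8.*1, 8, 3, 3"):
            sec(rng.normal(size=(1, 4, 8, 8)), rng.normal(size=(1, 8, 3, 3)))


# ---------------------------------------------------------------------------
# backbone / primary / cascade
# ---------------------------------------------------------------------------


class TestBackbone:
    def test_logit_shape(self, rng, preset_cfg):
        net = UNetBackbone(preset_cfg, rng)
        out = net(rng.normal(size=(2, 1, 64, 64)))
        assert out.shape == (2, 5, 64, 64)

    def test_indivisible_size_names_axis(self, rng, preset_cfg):
        net = UNetBackbone(preset_cfg, rng)
        with pytest.raises(ValueError, match="height 65"):
            net(rng.normal(size=(1, 1, 65, 64)))
        with pytest.raises(ValueError, match="width 68"):
            net(rng.normal(size=(1, 1, 64, 68)))

    def test_batch_independence(self, rng, small_cfg):
        net = UNetBackbone(small_cfg, rng).eval()
        x = rng.normal(size=(1, 1, 8, 8))
        both = np.concatenate([x, x], axis=0)
        out = net(both).data
        np.testing.assert_allclose(out[0], out[1], atol=1e-6)

    def test_forward_is_deterministic(self, rng, small_cfg):
        net = UNetBackbone(small_cfg, rng).eval()
        x = rng.normal(size=(2, 1, 8, 8))
        np.testing.assert_array_equal(net(x).data, net(x).data)


class TestPrimary:
    def test_shapes_and_probability_normalisation(self, rng, preset_cfg):
        net = SECPNet(preset_cfg, rng)
        logits, probs = net(rng.normal(size=(2, 1, 64, 64)))
        assert logits.shape == (2, 5, 64, 64)
        np.testing.assert_allclose(probs.data.sum(axis=1), 1.0, atol=1e-5)
        assert np.all(probs.data >= 0)

    def test_pyramid_structure_audit(self, rng, preset_cfg):
        """One SEC per level 1..depth-1 plus a single bottom SE block."""
        net = SECPNet(preset_cfg, rng)
        assert len(net.secs) == preset_cfg.depth - 1
        assert isinstance(net.se_bottom, SEBlock)
        sec_names = {
            n.split(".")[0] for n, _ in net.named_parameters() if n.startswith("secs")
        }
        assert sec_names == {f"secs{i}" for i in range(preset_cfg.depth - 1)}

    def test_primary_has_more_parameters_than_backbone(self, rng, preset_cfg):
        primary = SECPNet(preset_cfg, rng)
        backbone = UNetBackbone(preset_cfg, rng)
        assert parameter_count(primary) > parameter_count(backbone)
        # the difference is exactly the SE/SEC additions
        extra = sum(
            p.data.size
            for n, p in primary.named_parameters()
            if n.startswith(("secs", "se_bottom"))
        )
        assert parameter_count(primary) == parameter_count(backbone) + extra

    def test_every_parameter_receives_gradient(self, rng, preset_cfg):
        net = SECPNet(preset_cfg, rng)
        x = Tensor(rng.normal(size=(2, 1, 64, 64)))
        target = rng.integers(0, 5, (2, 64, 64))
        _, probs = net(x)
        flow = gradient_flow_audit(net, cross_entropy_loss(probs, target))
        dead = [name for name, alive in flow.items() if not alive]
        assert dead == []


class TestCascade:
    def test_secondary_input_channel_arithmetic(self, rng):
        cfg = NetworkConfig(
            num_classes=14, in_channels=1, depth=2, stage_channels=(4, 6, 8),
            se_reduction=2,
        )
        cascade = CascadeNet(cfg, rng)
        assert cascade.secondary.cfg.in_channels == 15

    def test_mismatched_secondary_rejected(self, rng, small_cfg):
        bad = NetworkConfig(
            num_classes=4, in_channels=3, depth=2, stage_channels=(4, 6, 8),
            se_reduction=2,
        )
        with pytest.raises(ValueError, match="auto-context"):
            CascadeNet(small_cfg, rng, secondary_cfg=bad)

    def test_final_probabilities_normalised(self, rng, small_cfg):
        cascade = CascadeNet(small_cfg, rng)
        _, _, final = cascade(rng.normal(size=(2, 1, 8, 8)))
        np.testing.assert_allclose(final.data.sum(axis=1), 1.0, atol=1e-5)

    def test_secondary_perturbation_isolated_from_primary(self, rng, small_cfg):
        cascade = CascadeNet(small_cfg, rng).eval()
        x = rng.normal(size=(1, 1, 8, 8))
        primary_before, final_before, _ = (o.data for o in cascade(x))
        for p in cascade.secondary.parameters():
            p.data += 0.1
        primary_after, final_after, _ = (o.data for o in cascade(x))
        np.testing.assert_array_equal(primary_before, primary_after)
        assert not np.allclose(final_before, final_after)


# ---------------------------------------------------------------------------
# label prediction, checkpoints
# ---------------------------------------------------------------------------


class TestPredictLabels:
    def test_uniform_tie_breaks_to_class_zero(self):
        probs = np.full((1, 4, 3, 3), 0.25)
        np.testing.assert_array_equal(predict_labels(probs), 0)

    def test_one_hot_recovers_hot_index(self, rng):
        labels = rng.integers(0, 4, (2, 5, 5))
        probs = np.eye(4)[labels].transpose(0, 3, 1, 2)
        np.testing.assert_array_equal(predict_labels(probs), labels)

    def test_matches_per_pixel_scan_oracle(self, rng):
        probs = rng.random((1, 3, 4, 4))
        got = predict_labels(probs)
        for h in range(4):
            for w in range(4):
                best, best_v = 0, probs[0, 0, h, w]
                for c in range(1, 3):
                    if probs[0, c, h, w] > best_v:
                        best, best_v = c, probs[0, c, h, w]
                assert got[0, h, w] == best


def test_checkpoint_roundtrip(tmp_path, rng, small_cfg):
    net = SECPNet(small_cfg, rng)
    x = rng.normal(size=(1, 1, 8, 8))
    want = net.eval()(x)[0].data
    path = save_checkpoint(net, tmp_path / "primary")
    restored = load_checkpoint(path).eval()
    assert parameter_hash(restored) == parameter_hash(net)
    np.testing.assert_array_equal(restored(x)[0].data, want)


def test_cascade_checkpoint_roundtrip(tmp_path, rng, small_cfg):
    cascade = CascadeNet(small_cfg, rng).eval()
    x = rng.normal(size=(1, 1, 8, 8))
    want = cascade(x)[2].data
    save_checkpoint(cascade, tmp_path / "cascade")
    restored = load_checkpoint(tmp_path / "cascade").eval()
    np.testing.assert_array_equal(restored(x)[2].data, want)


def test_config_validation_errors():
    with pytest.raises(ValueError, match="depth"):
        NetworkConfig(num_classes=3, depth=3, stage_channels=(4, 8))
    with pytest.raises(ValueError, match="num_classes"):
        NetworkConfig(num_classes=1, depth=1, stage_channels=(4, 8))
    cfg = NetworkConfig(num_classes=3, depth=2, stage_channels=(2, 4, 8))
    with pytest.raises(ValueError, match="multiple"):
        cfg.check_spatial(10, 8)
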