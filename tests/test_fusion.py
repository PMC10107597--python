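"""Fusion head and end-to-end model graph."""

import numpy as np
import pytest

from tsdnet import autograd as ag
from tsdnet.config import ConfigurationError, ModelConfig, ThresholdConfig
from tsdnet.fusion import FusionHead, TSDNet, build_model, small_config


def tiny_cfg(**overrides):
    base = dict(image_size=16, backbone_widths=(4, 8), d_fuse=16, n_classes=3, seed=7)
    base.update(overrides)
    return ModelConfig(**base)


@pytest.fixture
def head(rng):
    # m=2 spatial, c=3 channels, shallow-screened map has c channels
    cfg = ModelConfig(image_size=16, backbone_widths=(3,), d_fuse=8, n_classes=2, seed=0)
    return FusionHead(np.random.default_rng(0), cfg, m=2, c=3, c_cg=3)


def _zero_params(layer):
    for p in layer.params:
        p.data[...] = 0.0


class TestFuseMid:
    def test_zero_inputs_zero_bias_gives_zero(self, head):
        f1 = ag.constant(np.zeros((2, 2, 2, 9)))
        f3 = ag.constant(np.zeros((2, 2, 2, 9)))
        f_cg = ag.constant(np.zeros((2, 2, 2, 3)))
        out = head.fuse_mid(f1, f3, f_cg)
        np.testing.assert_array_equal(out.data, 0.0)

    def test_output_length_is_d_fuse(self, head, rng):
        out = head.fuse_mid(
            ag.constant(rng.normal(size=(4, 2, 2, 9))),
            ag.constant(rng.normal(size=(4, 2, 2, 9))),
            ag.constant(rng.normal(size=(4, 2, 2, 3))),
        )
        assert out.shape == (4, 8)

    def test_matches_affine_loop_oracle(self, head, rng):
        f1 = rng.normal(size=(1, 2, 2, 9))
        f3 = rng.normal(size=(1, 2, 2, 9))
        f_cg = rng.normal(size=(1, 2, 2, 3))
        out = head.fuse_mid(ag.constant(f1), ag.constant(f3), ag.constant(f_cg)).data[0]
        # independent re-computation with plain loops
        conv = ag.conv2d(ag.constant(f1), head.conv_f1.w, head.conv_f1.b).data
        conv = np.maximum(conv, 0.0)
        expected = np.zeros(8)
        for j in range(8):
            acc = head.dense_f3.b.data[j] + head.dense_f1.b.data[j] + head.dense_cg_mid.b.data[j]
            for i, v in enumerate(f3.ravel()):
                acc += v * head.dense_f3.w.data[i, j]
            for i, v in enumerate(conv.ravel()):
                acc += v * head.dense_f1.w.data[i, j]
            for i, v in enumerate(f_cg.ravel()):
                acc += v * head.dense_cg_mid.w.data[i, j]
            expected[j] = acc
        np.testing.assert_allclose(out, expected, atol=1e-10)


class TestFuseDeep:
    def test_sequence_length_is_sum_of_parts(self, head, rng):
        f_cg = ag.constant(rng.normal(size=(2, 2, 2, 3)))
        f_m = ag.constant(rng.normal(size=(2, 8)))
        f_deep = ag.constant(rng.normal(size=(2, 2, 2, 3)))
        out = head.fuse_deep(f_cg, f_m, f_deep)
        assert out.shape == (2, 8 + 8 + 12, 1)

    def test_zero_inputs_zero_bias_gives_zero(self, head):
        _zero_params(head.conv_fm)
        f_cg = ag.constant(np.zeros((1, 2, 2, 3)))
        f_m = ag.constant(np.zeros((1, 8)))
        f_deep = ag.constant(np.zeros((1, 2, 2, 3)))
        np.testing.assert_array_equal(head.fuse_deep(f_cg, f_m, f_deep).data, 0.0)


class TestClassify:
    def test_softmax_contract(self, head, rng):
        f_i = ag.constant(rng.normal(size=(3, 28, 1)))
        logits = head.classify(f_i)
        probs = ag.softmax(logits, axis=1).data
        assert probs.shape == (3, 2)
        assert probs.min() >= 0.0
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_softmax_shift_invariance(self, rng):
        logits = rng.normal(size=(2, 4))
        a = ag.softmax(ag.constant(logits), axis=1).data
        b = ag.softmax(ag.constant(logits + 3.7), axis=1).data
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_two_logit_closed_form(self):
        probs = ag.softmax(ag.constant(np.array([[0.0, np.log(3.0)]])), axis=1).data
        np.testing.assert_allclose(probs, [[0.25, 0.75]], atol=1e-12)


class TestBuildModel:
    def test_same_cfg_same_parameter_count(self):
        assert build_model(tiny_cfg()).n_parameters() == build_model(tiny_cfg()).n_parameters()

    def test_forward_on_zero_image(self):
        model = build_model(tiny_cfg())
        probs, _ = model.forward(np.zeros((1, 16, 16, 3)))
        assert probs.data.shape == (1, 3)
        np.testing.assert_allclose(probs.data.sum(), 1.0, atol=1e-6)

    def test_forward_determinism(self, rng):
        x = rng.uniform(size=(2, 16, 16, 3))
        p1, _ = build_model(tiny_cfg()).forward(x)
        p2, _ = build_model(tiny_cfg()).forward(x)
        np.testing.assert_array_equal(p1.data, p2.data)

    def test_batch_order_invariance(self, rng):
        x = rng.uniform(size=(3, 16, 16, 3))
        model = build_model(tiny_cfg())
        p, _ = model.forward(x)
        p_rev, _ = model.forward(x[::-1])
        np.testing.assert_allclose(p.data[::-1], p_rev.data, atol=1e-12)

    def test_invalid_threshold_ordering_rejected(self):
        with pytest.raises(ConfigurationError):
            tiny_cfg(thresholds=ThresholdConfig(t1=0.3, t2=0.5))

    def test_wrong_input_shape_raises(self):
        model = build_model(tiny_cfg())
        with pytest.raises(ConfigurationError):
            model.forward(np.zeros((1, 8, 8, 3)))

    def test_gradient_finite_difference_spot_check(self, rng):
        model = build_model(tiny_cfg())
        # nudge every parameter off the zero-bias init so no ReLU sits
        # exactly at its kink (one-sided derivatives break the check there)
        for p in model.params:
            p.data += rng.normal(0.0, 0.01, size=p.data.shape)
        x = rng.uniform(size=(2, 16, 16, 3))
        y = np.array([0, 2])

        def loss_value():
            _, det = model.forward(x)
            return float(ag.softmax_cross_entropy(det["logits"], y).data)

        _, det = model.forward(x)
        loss = ag.softmax_cross_entropy(det["logits"], y)
        for p in model.params:
            p.grad = None
        loss.backward()
        eps = 1e-5
        param_rng = np.random.default_rng(0)
        checked = 0
        for p in param_rng.choice(len(model.params), size=5, replace=False):
            param = model.params[p]
            idx = tuple(param_rng.integers(0, s) for s in param.data.shape)
            orig = param.data[idx]
            param.data[idx] = orig + eps
            hi = loss_value()
            param.data[idx] = orig - eps
            lo = loss_value()
            param.data[idx] = orig
            num = (hi - lo) / (2 * eps)
            ana = 0.0 if param.grad is None else param.grad[idx]
            assert np.isfinite(num) and np.isfinite(ana)
            assert ana == pytest.approx(num, rel=1e-3, abs=1e-6)
            checked += 1
        assert checked == 5


class TestKnockoutsAndGating:
    def test_unknown_knockout_raises(self, rng):
        model = build_model(tiny_cfg())
        with pytest.raises(ConfigurationError):
            model.forward(rng.uniform(size=(1, 16, 16, 3)), knockout={"f_9"})

    def test_all_branches_knockout_rejected(self, rng):
        model = build_model(tiny_cfg())
        with pytest.raises(ConfigurationError):
            model.forward(rng.uniform(size=(1, 16, 16, 3)),
                          knockout={"f_cg", "f_1", "f_2", "f_3"})

    @pytest.mark.parametrize("branch", ["f_cg", "f_1", "f_2", "f_3"])
    def test_knockout_zeroes_branch(self, rng, branch):
        model = build_model(tiny_cfg())
        _, det = model.forward(rng.uniform(size=(2, 16, 16, 3)), knockout={branch})
        np.testing.assert_array_equal(det[branch].data, 0.0)

    def test_masked_positions_contribute_exactly_zero(self, rng):
        model = build_model(tiny_cfg(per_pixel_masks=False))
        x = rng.uniform(size=(1, 16, 16, 3))
        _, det = model.forward(x)
        masks = det["masks"]
        for b in ("HV", "HD", "VD"):
            triple = masks[b].as_tuple()
        # level features are exactly zero wherever their mask eliminated
        for level, k in (("f_1", 0), ("f_2", 1), ("f_3", 2)):
            arr = det[level].data
            c = arr.shape[-1] // 3
            for bi, b in enumerate(("HV", "HD", "VD")):
                m = masks[b].as_tuple()[k].astype(bool)
                chunk = arr[..., bi * c : (bi + 1) * c]
                assert np.all(chunk[~m] == 0.0)

    def test_masks_stop_gradient_into_attention(self, rng):
        model = build_model(tiny_cfg())
        x = rng.uniform(size=(2, 16, 16, 3))
        _, det = model.forward(x)
        loss = ag.softmax_cross_entropy(det["logits"], np.array([0, 1]))
        for p in model.params:
            p.grad = None
        before = {k: v.copy() for k, v in model.attention.state().items()}
        loss.backward()
        after = model.attention.state()
        for k in before:
            np.testing.assert_array_equal(before[k], after[k])


class TestSerialization:
    def test_checkpoint_roundtrip(self, tmp_path, rng):
        model = build_model(tiny_cfg())
        x = rng.uniform(size=(2, 16, 16, 3))
        p_before, _ = model.forward(x)
        path = tmp_path / "ckpt.npz"
        model.save(path)
        restored = TSDNet.load(path, tiny_cfg(seed=99))
        p_after, _ = restored.forward(x)
        np.testing.assert_array_equal(p_before.data, p_after.data)

    def test_shape_mismatch_on_load(self, tmp_path):
        model = build_model(tiny_cfg())
        path = tmp_path / "ckpt.npz"
        model.save(path)
        with pytest.raises(ConfigurationError):
            TSDNet.load(path, tiny_cfg(backbone_widths=(4, 16)))

    def test_summary_rows_cover_all_params(self):
        model = build_model(tiny_cfg())
        total = sum(n for _, _, n in model.summary_rows())
        assert total == model.n_parameters()


def test_small_config_matches_reduced_recipe():
    cfg = small_config(n_classes=3, seed=1)
    assert cfg.image_size == 64
    assert cfg.backbone_widths == (8, 16, 32)
    assert cfg.d_fuse == 64
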