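import numpy as np
import pytest

from ribseg.network import (CamFuse, Hddc, ModelConfig, build_model, cam_fuse,
                            directional_pool, hddc_forward, model_forward,
                            receptive_field, receptive_field_of)
from ribseg.nn import Tensor
from ribseg.objective_metrics import LossConfig, compound_loss


class TestModelConfig:
    def test_defaults_are_resnet34_like(self):
        cfg = ModelConfig()
        assert cfg.encoder == (64, 64, 128, 256, 512)
        assert cfg.blocks == (3, 4, 6, 3)

    def test_reduction_too_aggressive_rejected(self):
        with pytest.raises(ValueError, match="cam_reduction_r"):
            ModelConfig(encoder=(8, 8, 16, 32, 64), cam_reduction_r=16)

    def test_nonpositive_rates_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(hddc_rates=(1, 0, 5))

    def test_json_round_trip(self):
        cfg = ModelConfig.tiny(use_cam=False)
        assert ModelConfig.from_json(cfg.to_json()) == cfg


class TestDirectionalPool:
    def test_worked_2x2_example(self):
        x = np.array([[[1.0, 3.0], [5.0, 7.0]]])  # (C=1, 2, 2)
        z_h, z_w = directional_pool(x)
        np.testing.assert_allclose(z_h[0], [2.0, 6.0])   # row means
        np.testing.assert_allclose(z_w[0], [3.0, 5.0])   # column means

    def test_constant_map(self):
        x = np.full((3, 4, 5), 2.5)
        z_h, z_w = directional_pool(x)
        assert (z_h == 2.5).all() and (z_w == 2.5).all()

    def test_profile_means_equal_global_mean(self, rng):
        x = rng.normal(0, 1, (2, 6, 9))
        z_h, z_w = directional_pool(x)
        assert z_h.mean() == pytest.approx(x.mean(), rel=1e-6)
        assert z_w.mean() == pytest.approx(x.mean(), rel=1e-6)

    def test_tensor_input_gives_tensor_output(self, rng):
        x = Tensor(rng.normal(0, 1, (1, 2, 4, 5)))
        z_h, z_w = directional_pool(x)
        assert z_h.shape == (1, 2, 4) and z_w.shape == (1, 2, 5)


class TestCamFuse:
    @pytest.mark.parametrize("shape", [(1, 4, 8, 8), (2, 8, 4, 12),
                                       (1, 16, 6, 6)])
    def test_shape_preserved(self, rng, shape):
        x_l = Tensor(rng.normal(0, 1, shape))
        x_t = Tensor(rng.normal(0, 1, shape))
        out = cam_fuse(x_l, x_t, r=4, rng=rng)
        assert out.shape == shape

    def test_zero_low_level_passes_high_level_through(self, rng):
        x_t = rng.normal(0, 1, (1, 4, 6, 6)).astype(np.float32)
        out = cam_fuse(np.zeros((1, 4, 6, 6)), x_t, r=2, rng=rng)
        np.testing.assert_allclose(out.data, x_t, atol=1e-6)

    def test_frozen_zero_parameters_give_quarter_mix(self, rng):
        mod = CamFuse(4, 2, rng)
        for p in mod.parameters():
            p.data[:] = 0.0
        mod.bn.weight.data[:] = 1.0  # BN still normalizes, gates stay at 0
        x_l = Tensor(rng.normal(0, 1, (2, 4, 5, 7)).astype(np.float32))
        x_t = Tensor(rng.normal(0, 1, (2, 4, 5, 7)).astype(np.float32))
        out = mod(x_l, x_t)
        np.testing.assert_allclose(out.data, 0.25 * x_l.data + x_t.data,
                                   atol=1e-6)

    def test_residual_is_gated_low_level(self, rng):
        # x_o - x_t = x_l ⊙ (f_h ⊗ f_w), every factor strictly in (0,1)
        mod = CamFuse(8, 4, rng)
        mod.eval()
        x_l = Tensor(rng.normal(0, 1, (1, 8, 6, 9)).astype(np.float32))
        x_t = Tensor(rng.normal(0, 1, (1, 8, 6, 9)).astype(np.float32))
        out = mod(x_l, x_t)
        f_h, f_w = mod.attention_weights(x_l, x_t)
        assert ((0 < f_h) & (f_h < 1)).all()
        assert ((0 < f_w) & (f_w < 1)).all()
        expected = x_l.data * f_h[:, :, :, None] * f_w[:, :, None, :] + x_t.data
        np.testing.assert_allclose(out.data, expected, atol=1e-5)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            cam_fuse(np.zeros((1, 4, 8, 8)), np.zeros((1, 4, 8, 9)), rng=rng)

    def test_over_reduction_rejected(self, rng):
        with pytest.raises(ValueError):
            CamFuse(4, 8, rng)


class TestHddc:
    @pytest.mark.parametrize("rates", [(1, 3, 5), (1, 2), (2,)])
    @pytest.mark.parametrize("merge", ["sum", "concat"])
    def test_shape_preserved(self, rng, rates, merge):
        x = Tensor(rng.normal(0, 1, (1, 6, 8, 8)))
        mod = Hddc(6, rates, rng, merge=merge)
        assert mod(x).shape == (1, 6, 8, 8)

    def test_invalid_rate_rejected(self, rng):
        with pytest.raises(ValueError, match="rates"):
            Hddc(4, (1, 0), rng)
        with pytest.raises(ValueError):
            hddc_forward(np.zeros((1, 4, 8, 8)), rates=(-1,), rng=rng)

    def test_functional_wrapper(self, rng):
        out = hddc_forward(rng.normal(0, 1, (1, 4, 6, 6)), rates=(1, 2),
                           rng=rng)
        assert out.shape == (1, 4, 6, 6)


def brute_force_receptive_field(layers, size=201):
    """Oracle: propagate a dependency footprint through dilated kernels."""
    support = np.zeros(size, dtype=bool)
    support[size // 2] = True
    for kernel, stride, dilation in layers:
        assert stride == 1  # oracle covers the bottleneck (stride-1) case
        new = np.zeros(size, dtype=bool)
        half = (kernel - 1) // 2 * dilation
        for i in np.nonzero(support)[0]:
            for o in range(-half, half + 1, dilation):
                if 0 <= i + o < size:
                    new[i + o] = True
        support = new
    # extent = span between extreme contributing inputs (holes included)
    nz = np.nonzero(support)[0]
    return int(nz.max() - nz.min() + 1)


class TestReceptiveField:
    @pytest.mark.parametrize("layers,expected", [
        ([(3, 1, 1)], 3),
        ([(3, 1, 1), (3, 1, 1)], 5),
        ([(3, 1, 5)], 11),
        ([(3, 1, 1), (3, 1, 3), (3, 1, 5)], 19),
    ])
    def test_analytic_values_match_brute_force(self, layers, expected):
        assert receptive_field_of(layers) == expected
        assert brute_force_receptive_field(layers) == expected

    def test_config_level(self):
        assert receptive_field(ModelConfig(hddc_rates=(1, 3, 5))) == 19
        assert receptive_field(ModelConfig(use_hddc=False)) == 1

    def test_monotone_in_added_layers(self, rng):
        layers = []
        prev = 1
        for _ in range(6):
            layers.append((3, 1, int(rng.integers(1, 6))))
            cur = receptive_field_of(layers)
            assert cur >= prev
            prev = cur


class TestModelForward:
    def test_output_shape_and_range(self, rng):
        model = build_model(ModelConfig.tiny(), seed=0)
        img = rng.uniform(0, 1, (64, 64)).astype(np.float32)
        out = model.predict(img)
        assert out.shape == (64, 64)
        assert (out > 0).all() and (out < 1).all()

    def test_deterministic(self, rng):
        img = rng.uniform(0, 1, (64, 64)).astype(np.float32)
        a = build_model(ModelConfig.tiny(), seed=4).predict(img)
        b = build_model(ModelConfig.tiny(), seed=4).predict(img)
        np.testing.assert_array_equal(a, b)

    def test_indivisible_size_errors_by_default(self, rng):
        model = build_model(ModelConfig.tiny(), seed=0)
        with pytest.raises(ValueError, match="not divisible"):
            model.predict(rng.uniform(0, 1, (60, 64)).astype(np.float32))

    def test_pad_mode_crops_back(self, rng):
        model = build_model(ModelConfig.tiny(pad_mode="pad"), seed=0)
        out = model.predict(rng.uniform(0, 1, (60, 70)).astype(np.float32))
        assert out.shape == (60, 70)

    def test_missing_parameters_rejected(self, rng):
        with pytest.raises(ValueError, match="parameters"):
            model_forward(rng.uniform(0, 1, (64, 64)), ModelConfig.tiny(), None)

    def test_functional_equals_method(self, rng):
        model = build_model(ModelConfig.tiny(), seed=1)
        img = rng.uniform(0, 1, (64, 64)).astype(np.float32)
        out = model_forward(img, model.config, model.state_dict())
        np.testing.assert_allclose(out, model.predict(img), atol=1e-6)

    def test_gradients_finite_everywhere(self, rng):
        model = build_model(ModelConfig.tiny(), seed=0)
        img = rng.uniform(0, 1, (2, 1, 32, 32)).astype(np.float32)
        mask = (rng.uniform(0, 1, (2, 1, 32, 32)) < 0.05).astype(np.float32)
        loss = compound_loss(model(Tensor(img)), mask, LossConfig())
        loss.backward()
        for name, p in model.named_parameters():
            assert p.grad is not None, f"no grad for {name}"
            assert np.isfinite(p.grad).all(), f"non-finite grad in {name}"


class TestAblationNesting:
    def test_parameter_sets_strictly_nested(self):
        def names(**kw):
            return {n for n, _ in
                    build_model(ModelConfig.tiny(**kw)).named_parameters()}

        base = names(use_hddc=False, use_cam=False)
        hddc = names(use_hddc=True, use_cam=False)
        full = names(use_hddc=True, use_cam=True)
        assert base < hddc < full

    def test_baseline_reduces_to_plain_residual_unet(self, rng):
        model = build_model(ModelConfig.tiny(use_hddc=False, use_cam=False),
                            seed=0)
        assert model.hddc is None
        assert model.dec4.cam is None
        img = rng.uniform(0, 1, (64, 64)).astype(np.float32)
        assert model.predict(img).shape == (64, 64)
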