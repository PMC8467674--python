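import numpy as np
import pytest

import _oracles as orc
import rcunet.nn.layers as L
from rcunet.architectures import (BackboneConfig, DenseUnitSpec, ResPathSpec,
                                  UNetModel, build_dense_unit, build_rcunet,
                                  build_res_path, build_unet, build_variant,
                                  default_dense_spec, default_respath_specs,
                                  predict_mask, predict_proba)
from rcunet.nn import init_weights
from rcunet.nn.init import ConfigurationError
from rcunet.nn.losses import batch_loss_grad


class TestShapeTraces:
    def test_encoder_extents_halve_and_decoder_restores(self):
        cfg = BackboneConfig(input_extent=(64, 64),
                             encoder_filters=(4, 8, 16, 32, 64))
        model = build_unet(cfg)
        trace = {r["stage"]: r for r in model.summary()}
        for i in range(5):
            assert trace[f"encoder{i + 1}"]["extent"] == (64 // 2 ** i,) * 2
        for i in range(4):
            assert trace[f"decoder{i + 1}"]["extent"] == (64 // 2 ** i,) * 2

    def test_default_channel_trace_matches_published_widths(self):
        model = build_rcunet()
        trace = {r["stage"]: r for r in model.summary()}
        enc_widths = [trace[f"encoder{i}"]["channels"] for i in range(1, 6)]
        assert enc_widths == [64, 128, 256, 512, 1024]
        assert trace["dense_unit"]["channels"] == 128
        assert trace["decoder1"]["channels"] == 128  # last decoder stage
        units = [trace[f"shortcut{i}"]["res_units"] for i in range(1, 5)]
        assert units == [4, 3, 2, 1]

    def test_bottleneck_is_1024_channels_at_16x16(self):
        model = build_unet()
        trace = {r["stage"]: r for r in model.summary()}
        assert trace["encoder5"]["channels"] == 1024
        assert trace["encoder5"]["extent"] == (16, 16)

    def test_forward_pass_restores_input_extent(self, rng):
        cfg = BackboneConfig(input_extent=(32, 32),
                             encoder_filters=(4, 8, 16, 32, 64))
        model = build_rcunet(cfg)
        init_weights(model, seed=0)
        model.eval()
        out = model(rng.random((2, 1, 32, 32)))
        assert out.shape == (2, 1, 32, 32)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_extent_not_divisible_by_16_rejected(self):
        with pytest.raises(ConfigurationError):
            build_unet(BackboneConfig(input_extent=(100, 100)))


class TestParameterCounts:
    def test_plain_unet_count_matches_analytic_formula(self):
        filters = (8, 16, 32, 64, 128)
        model = build_unet(BackboneConfig(input_extent=(16, 16),
                                          encoder_filters=filters))
        assert model.parameter_count() == orc.oracle_unet_param_count(filters)

    def test_halving_filters_quarters_the_count(self):
        full = build_unet(BackboneConfig(input_extent=(16, 16),
                                         encoder_filters=(16, 32, 64, 128, 256)))
        half = build_unet(BackboneConfig(input_extent=(16, 16),
                                         encoder_filters=(8, 16, 32, 64, 128)))
        ratio = full.parameter_count() / half.parameter_count()
        assert 3.6 <= ratio <= 4.1

    def test_rcunet_strictly_larger_than_unet(self):
        cfg = BackboneConfig(input_extent=(16, 16),
                             encoder_filters=(8, 16, 32, 64, 128))
        assert build_rcunet(cfg).parameter_count() > \
            build_unet(cfg).parameter_count()


class TestResPath:
    def test_default_level1_path_has_4_units_of_64_channels(self):
        path = build_res_path(ResPathSpec(level=1, n_units=4,
                                          unit_channels=64))
        assert len(path.units.layers) == 4
        for unit in path.units.layers:
            assert unit.body.layers[0].out_channels == 64

    def test_zeroed_residual_transform_is_identity(self, rng):
        path = build_res_path(ResPathSpec(level=1, n_units=3,
                                          unit_channels=8), in_channels=8)
        init_weights(path, seed=0)
        path.eval()
        for unit in path.units.layers:
            unit.body.layers[-1].gamma.data[...] = 0.0  # H_l == 0
        x = rng.random((2, 8, 6, 6)).astype(np.float32)  # non-negative input
        np.testing.assert_array_equal(path(x), x)

    def test_single_unit_matches_hand_computed_conv_plus_add(self):
        L.set_default_dtype(np.float64)
        try:
            path = build_res_path(ResPathSpec(level=1, n_units=1,
                                              unit_channels=1),
                                  in_channels=1)
            unit = path.units.layers[0]
            conv1, bn1, _, conv2, bn2 = unit.body.layers
            conv1.weight.data[...] = 0.0
            conv1.weight.data[0, 0, 1, 1] = 2.0   # center tap only
            conv2.weight.data[...] = 0.0
            conv2.weight.data[0, 0, 1, 1] = -0.5
            for bn in (bn1, bn2):
                bn.gamma.data[...] = 1.0
                bn.beta.data[...] = 0.0
            path.eval()  # BN uses running stats mean 0 / var 1
            x = np.full((1, 1, 1, 1), 0.8)
            # hand arithmetic: s = 1/sqrt(1 + 1e-5) per BN pass
            s = 1.0 / np.sqrt(1.0 + 1e-5)
            h = max(0.8 * 2.0 * s, 0.0) * (-0.5) * s
            expected = max(h + 0.8, 0.0)
            assert path(x)[0, 0, 0, 0] == pytest.approx(expected, rel=1e-12)
        finally:
            L.set_default_dtype(np.float32)

    def test_rejects_empty_path(self):
        with pytest.raises(ConfigurationError):
            build_res_path(ResPathSpec(level=1, n_units=0, unit_channels=8))


class TestDenseUnit:
    def test_published_growth_arithmetic(self):
        spec = DenseUnitSpec(base_filters=64, growth_rate=16, stages=4)
        assert spec.output_channels == 128
        assert spec.input_channels_at(3) == 96
        unit = build_dense_unit(spec)
        # layer 3's convolution consumes F + 2k = 96 channels
        assert unit.dense_layers.layers[2].layers[-1].in_channels == 96

    def test_output_width_after_forward(self, rng):
        unit = build_dense_unit(DenseUnitSpec(8, 2, 4))
        init_weights(unit, seed=0)
        unit.eval()
        out = unit(rng.random((1, 1, 12, 12)))
        assert out.shape == (1, 16, 12, 12)

    def test_zero_growth_keeps_constant_width(self, rng):
        unit = build_dense_unit(DenseUnitSpec(base_filters=6, growth_rate=0,
                                              stages=4))
        init_weights(unit, seed=0)
        unit.eval()
        out = unit(rng.random((1, 1, 8, 8)))
        assert out.shape[1] == 6


class TestRCUNetAssembly:
    def test_dense_width_mismatch_rejected(self):
        cfg = BackboneConfig(input_extent=(16, 16),
                             encoder_filters=(4, 8, 16, 32, 64))
        bad_dense = DenseUnitSpec(base_filters=4, growth_rate=2, stages=4)
        with pytest.raises(ConfigurationError):
            build_rcunet(cfg, default_respath_specs(cfg), bad_dense)

    def test_ablated_graph_reproduces_plain_unet_bit_for_bit(self, rng):
        cfg = BackboneConfig(input_extent=(16, 16),
                             encoder_filters=(4, 8, 16, 32, 64))
        reference = build_unet(cfg)
        init_weights(reference, seed=3)
        ablated = UNetModel(cfg, respath_specs=None, dense_spec=None)
        ablated.load_state_dict(reference.state_dict())
        x = rng.random((2, 1, 16, 16))
        reference.eval()
        ablated.eval()
        np.testing.assert_array_equal(reference(x), ablated(x))

    def test_gradient_reaches_every_parameter_group(self, tiny_rcunet, rng):
        """One training step must produce nonzero gradients in every Res
        Path unit, every dense layer and every backbone block (guards
        against disconnected subgraphs)."""
        model = tiny_rcunet
        init_weights(model, seed=1)
        model.train()
        x = rng.random((2, 1, 16, 16))
        y = np.zeros((2, 1, 16, 16))
        y[:, :, 4:10, 5:11] = 1.0
        pred = model(x)
        model.zero_grad()
        model.backward(batch_loss_grad(y, pred))
        for name, p in model.named_parameters():
            assert np.abs(p.grad).max() > 0, f"no gradient reached {name}"

    def test_variant_dispatch(self):
        cfg = BackboneConfig(input_extent=(16, 16),
                             encoder_filters=(2, 4, 8, 16, 32))
        assert build_variant("unet", cfg).variant == "unet"
        assert build_variant("unet_respath", cfg).variant == "unet_respath"
        assert build_variant("rcunet", cfg).variant == "rcunet"
        with pytest.raises(ConfigurationError):
            build_variant("segnet", cfg)


class TestPredictMask:
    @pytest.fixture
    def small_model(self):
        cfg = BackboneConfig(input_extent=(16, 16),
                             encoder_filters=(2, 4, 8, 16, 32))
        model = build_unet(cfg)
        init_weights(model, seed=0)
        return model

    def test_threshold_zero_gives_all_foreground(self, small_model, rng):
        img = rng.random((16, 16))
        assert predict_mask(small_model, img, threshold=0.0).all()

    def test_threshold_above_one_gives_empty_mask(self, small_model, rng):
        img = rng.random((16, 16))
        assert not predict_mask(small_model, img, threshold=1.01).any()

    def test_deterministic_at_inference(self, small_model, rng):
        img = rng.random((16, 16))
        a = predict_mask(small_model, img)
        b = predict_mask(small_model, img)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (16, 16)

    def test_extent_mismatch_rejected(self, small_model, rng):
        with pytest.raises(ValueError):
            predict_proba(small_model, rng.random((8, 8)))
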