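"""Architecture: parameter arithmetic, ECA behaviour, blocks, fusion, reports."""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seedqc import nn
from seedqc.arch import (
    ConvSpec,
    DinceptionResNetBlock,
    ECAConfig,
    ModelConfig,
    ModuleConfig,
    ParamReport,
    apply_eca,
    build_dinception_module,
    build_model,
    count_separable_params,
    count_standard_params,
    eca_kernel_size,
    load_checkpoint,
    param_ratio,
    param_report,
    save_checkpoint,
    zero_conv_weights,
)


class TestParamArithmetic:
    def test_worked_example(self):
        spec = ConvSpec(3, 3, 64, 128)
        assert count_separable_params(spec) == 3 * 3 * 64 + 64 * 128 == 8768
        assert count_standard_params(spec) == 73728
        assert param_ratio(spec) == Fraction(1, 128) + Fraction(1, 9)

    def test_one_by_one_limit(self):
        assert count_separable_params(ConvSpec(1, 1, 32, 16)) == 32 + 32 * 16

    def test_separable_exceeds_standard_for_pointwise_single_output(self):
        """1x1 with N=1: the factorisation costs more (ratio 2), reported as-is."""
        assert param_ratio(ConvSpec(1, 1, 77, 1)) == 2

    @given(
        h=st.sampled_from([1, 3, 5, 7]),
        w=st.sampled_from([1, 3, 5, 7]),
        c=st.integers(1, 200),
        n=st.integers(1, 200),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_ratio_closed_form(self, h, w, c, n):
        """separable/standard == 1/N + 1/(H*W) exactly, independent of C."""
        assert param_ratio(ConvSpec(h, w, c, n)) == Fraction(1, n) + Fraction(1, h * w)

    def test_ratio_limits_to_inverse_kernel_area(self):
        for k in range(1, 12):
            n = 2**k
            r = param_ratio(ConvSpec(3, 3, 16, n))
            assert abs(float(r) - 1 / 9) <= 1 / n

    def test_counts_match_enumerated_layer_weights(self):
        for h, w, c, n in [(3, 3, 64, 128), (1, 7, 4, 9), (5, 5, 3, 16)]:
            layer = nn.separable_conv(c, n, kernel=(h, w))
            enumerated = sum(
                p.size for l in layer.layers for p in l.params() if p.trainable
            )
            assert enumerated == count_separable_params(ConvSpec(h, w, c, n))

    def test_report_fields_consistent(self):
        rep = ParamReport.from_spec(ConvSpec(3, 3, 8, 8))
        assert rep.ratio == Fraction(rep.separable_params, rep.standard_params)


class TestEcaKernelSize:
    @pytest.mark.parametrize(
        "channels,expected",
        [(1, 1), (2, 1), (16, 3), (64, 3), (128, 3), (256, 5), (1024, 5)],
    )
    def test_known_channel_counts(self, channels, expected):
        assert eca_kernel_size(channels) == expected

    def test_matches_formula_enumeration(self):
        """Oracle: nearest odd to |log2 C / gamma + b / gamma|, ties down."""
        for k in range(11):
            C = 2**k
            t = abs(math.log2(C) / 2 + 0.5)
            odds = np.arange(1, 21, 2)
            best = odds[np.lexsort((odds, np.abs(odds - t)))][0]
            assert eca_kernel_size(C) == best

    def test_always_odd_and_positive(self):
        for C in range(1, 600, 7):
            k = eca_kernel_size(C)
            assert k >= 1 and k % 2 == 1


class TestEcaGate:
    def test_zero_input_zero_output(self):
        out = apply_eca(np.zeros((6, 6, 8), dtype=np.float32), ECAConfig(channels=8))
        assert np.all(out == 0)

    def test_zero_weights_halve_input(self):
        x = np.random.default_rng(0).normal(size=(5, 5, 16)).astype(np.float32)
        cfg = ECAConfig(channels=16)
        out = apply_eca(x, cfg, weights=np.zeros(cfg.resolved_kernel_size))
        assert np.allclose(out, 0.5 * x, atol=1e-6)

    def test_per_channel_proportional_gating(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(2, 16, 6, 6)).astype(np.float32)
        cfg = ECAConfig(channels=16)
        out = apply_eca(x, cfg)
        for n in range(2):
            for c in range(16):
                nz = x[n, c] != 0
                ratios = out[n, c][nz] / x[n, c][nz]
                assert ratios.std() < 1e-5
                assert 0.0 < ratios.mean() < 1.0

    def test_shape_preserved_and_magnitude_bounded(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(3, 32, 4, 4)).astype(np.float32)
        out = apply_eca(x, ECAConfig(channels=32))
        assert out.shape == x.shape
        assert np.all(np.abs(out) <= np.abs(x) + 1e-7)

    def test_channel_permutation_equivariance(self):
        """With the pointwise (delta-kernel) initialisation the gate of each
        channel depends on that channel alone, so permuting input channels
        permutes the output identically."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=(2, 16, 5, 5)).astype(np.float32)
        cfg = ECAConfig(channels=16)
        perm = rng.permutation(16)
        assert np.allclose(apply_eca(x[:, perm], cfg), apply_eca(x, cfg)[:, perm], atol=1e-6)

    def test_channel_mismatch_rejected(self):
        with pytest.raises(ValueError):
            apply_eca(np.zeros((4, 4, 8), dtype=np.float32), ECAConfig(channels=16))


class TestDinceptionBlock:
    def test_residual_identity_with_zeroed_branches(self):
        block = build_dinception_module(ModuleConfig.default(16), rng_seed=0)
        zero_conv_weights(block)
        x = np.abs(np.random.default_rng(0).normal(size=(2, 16, 8, 8))).astype(np.float32)
        out = block.forward(x)
        assert np.allclose(out, x, atol=1e-6)

    def test_shape_conservation(self):
        block = build_dinception_module(ModuleConfig.default(64), rng_seed=1)
        x = np.random.default_rng(1).normal(size=(2, 64, 32, 32)).astype(np.float32)
        assert block.forward(x).shape == (2, 64, 32, 32)

    def test_mismatched_widths_require_projection(self):
        with pytest.raises(ValueError):
            ModuleConfig(in_channels=16, branch1=4, branch2=(4, 4), branch3=(4, 4), branch_pool=8)
        cfg = ModuleConfig(
            in_channels=16,
            branch1=4,
            branch2=(4, 4),
            branch3=(4, 4),
            branch_pool=8,
            residual_projection=True,
        )
        block = build_dinception_module(cfg, rng_seed=0)
        x = np.random.default_rng(0).normal(size=(1, 16, 6, 6)).astype(np.float32)
        assert block.forward(x).shape == (1, 20, 6, 6)

    def test_block_params_sum_of_conv_counts(self):
        """Block weight count reconciles with the closed-form conv arithmetic."""
        width = 16
        q = width // 4
        block = build_dinception_module(ModuleConfig.default(width), rng_seed=0)
        conv_weights = (
            width * q  # branch1 pointwise
            + (width * q + count_separable_params(ConvSpec(3, 3, q, q)))  # branch2
            + (width * q + 2 * count_separable_params(ConvSpec(3, 3, q, q)))  # branch3
            + width * q  # pool branch pointwise
        )
        bn_channels = q * 7  # 7 BN layers (1 + 2 + 3 + 1 across the branches)
        enumerated = sum(p.size for p in block.params() if p.trainable)
        assert enumerated == conv_weights + 2 * bn_channels


class TestModel:
    def test_fused_vector_length(self):
        model = build_model(ModelConfig(input_size=64, stages=((1, 32), (1, 64), (1, 128))))
        assert model.fused_width == 32 + 64 + 128 == 224

    def test_softmax_normalised(self, tiny_model_config):
        model = build_model(tiny_model_config)
        x = np.random.default_rng(0).uniform(size=(4, 3, 64, 64)).astype(np.float32)
        proba = model.predict_proba(x)
        assert proba.shape == (4, 2)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_fusion_toggle_changes_only_head(self):
        kwargs = dict(input_size=64, stages=((1, 16), (1, 32), (1, 64)), rng_seed=0)
        fused = build_model(ModelConfig(fusion_enabled=True, **kwargs))
        tail = build_model(ModelConfig(fusion_enabled=False, **kwargs))
        body = lambda m: sum(
            p.size
            for name, child in m.named_children()
            if name != "head"
            for p in child.params()
            if p.trainable
        )
        assert body(fused) == body(tail)
        assert fused.head.weight.size == 2 * (16 + 32 + 64)
        assert tail.head.weight.size == 2 * 64

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(input_size=8)

    def test_fusion_needs_three_stages(self):
        with pytest.raises(ValueError):
            ModelConfig(stages=((1, 16), (1, 32)), fusion_enabled=True)


class TestParamReport:
    def test_total_row_matches_framework_totals(self, tiny_model_config):
        model = build_model(tiny_model_config)
        rep = param_report(model)
        total = rep[rep["layer"] == "total"].iloc[0]
        assert total["actual_params"] == sum(p.size for p in model.params() if p.trainable)
        assert total["non_trainable_params"] == sum(
            p.size for p in model.params() if not p.trainable
        )
        body = rep[rep["layer"] != "total"]
        assert body["actual_params"].sum() == total["actual_params"]

    def test_separable_rows_show_reduction(self, tiny_model_config):
        rep = param_report(build_model(tiny_model_config))
        sep = rep[rep["kind"] == "separable_conv"]
        assert len(sep) > 0
        assert (sep["actual_params"] < sep["standard_equiv_params"]).all()

    def test_no_normalisation_means_no_frozen_params(self):
        rep = param_report(nn.Sequential(nn.Conv2d(3, 8), nn.ReLU(), nn.Dense(8, 2)))
        assert rep["non_trainable_params"].sum() == 0

    def test_single_separable_layer_worked_example(self):
        rep = param_report(nn.separable_conv(64, 128, kernel=3))
        row = rep[rep["kind"] == "separable_conv"].iloc[0]
        assert row["actual_params"] == 8768
        assert row["standard_equiv_params"] == 73728


class TestCheckpoint:
    def test_roundtrip_preserves_outputs(self, tmp_path, tiny_model_config):
        model = build_model(tiny_model_config)
        x = np.random.default_rng(1).uniform(size=(2, 3, 64, 64)).astype(np.float32)
        before = model.predict_proba(x)
        save_checkpoint(model, tmp_path / "ckpt")
        loaded, meta = load_checkpoint(tmp_path / "ckpt")
        assert np.allclose(loaded.predict_proba(x), before, atol=1e-7)
        assert meta["classes"] == ["good", "defective"]
        assert (tmp_path / "ckpt_params.csv").exists()
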