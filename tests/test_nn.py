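"""Autodiff engine and layer tests: gradients against finite differences,
convolution against an independent reference, hash encoding against dense
interpolation, LoRA algebra, and optimizer/module plumbing."""

import numpy as np
import pytest
from scipy.signal import correlate2d

from qmtrecon.nn import (
    Adam,
    Conv2d,
    HashEncoding,
    HashEncodingConfig,
    InstanceNorm2d,
    Linear,
    LoRAConv2d,
    MLP,
    Tensor,
    UNet,
    avg_pool2d,
    concat,
    conv2d,
    stack,
    upsample_nearest2d,
)


def numeric_grad(build_loss, tensor, n_checks=6, eps=1e-6, rng=None):
    rng = rng or np.random.default_rng(0)
    tensor.grad = None
    build_loss().backward()
    analytic = tensor.grad.copy()
    tensor.grad = None
    flat = tensor.data.ravel()
    errs = []
    for i in rng.choice(flat.size, size=min(n_checks, flat.size), replace=False):
        orig = flat[i]
        flat[i] = orig + eps
        lp = build_loss().item()
        flat[i] = orig - eps
        lm = build_loss().item()
        flat[i] = orig
        fd = (lp - lm) / (2 * eps)
        errs.append(abs(fd - analytic.ravel()[i]) / max(abs(fd), 1e-8))
    return max(errs)


class TestAutodiffOps:
    @pytest.mark.parametrize(
        "fn",
        [
            lambda x: (x * x + 2.0 * x - 1.0).sum(),
            lambda x: (x.exp() + (x * x + 1.0).log()).sum(),
            lambda x: (x.sigmoid() * x.tanh()).sum(),
            lambda x: ((x * x + 0.5).sqrt() / (x * x + 2.0)).sum(),
            lambda x: x.softplus().sum(),
            lambda x: (x.relu() + x.abs()).mean(),
            lambda x: (x.sin() * x.cos()).sum(),
            lambda x: (x.reshape(6, 4).T @ x.reshape(6, 4)).sum(),
            lambda x: x.reshape(2, 3, 4).sum(axis=(0, 2)).mean(),
            lambda x: (x.reshape(2, 3, 4)[1, :, 1:3] ** 3).sum(),
            lambda x: x.clip(-0.5, 0.5).sum(),
            lambda x: (1.0 / (x * x + 1.0)).sum(),
        ],
    )
    def test_gradients_match_finite_differences(self, fn):
        rng = np.random.default_rng(42)
        x = Tensor(rng.normal(size=24), requires_grad=True)
        assert numeric_grad(lambda: fn(x), x, rng=rng) < 1e-4

    def test_broadcasting_backward(self):
        rng = np.random.default_rng(0)
        a = Tensor(rng.normal(size=(5, 1)), requires_grad=True)
        b = Tensor(rng.normal(size=(1, 7)), requires_grad=True)
        loss = ((a * b + a - b) ** 2).sum()
        loss.backward()
        assert a.grad.shape == (5, 1) and b.grad.shape == (1, 7)
        assert numeric_grad(lambda: ((a * b + a - b) ** 2).sum(), a, rng=rng) < 1e-5

    def test_concat_stack_roundtrip_gradients(self):
        rng = np.random.default_rng(3)
        xs = [Tensor(rng.normal(size=(3, 2)), requires_grad=True) for _ in range(3)]
        loss = (concat(xs, axis=1) * stack(xs, axis=0).reshape(3, 6)).sum()
        loss.backward()
        for x in xs:
            assert x.grad is not None and x.grad.shape == (3, 2)

    def test_scalar_ops_preserve_float32(self):
        x = Tensor(np.ones(4, np.float32), requires_grad=True)
        y = ((x * 2.0 + 1.0) / 3.0 - 0.5) ** 2
        assert y.dtype == np.float32
        y.sum().backward()
        assert x.grad.dtype == np.float32

    def test_multiuse_accumulation(self):
        x = Tensor(np.array([2.0]), requires_grad=True)
        y = x * x + x * 3.0  # x used three times
        y.backward(np.array([1.0]))
        assert x.grad[0] == pytest.approx(2 * 2.0 + 3.0)


class TestConv:
    def test_matches_scipy_correlate(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, 9, 7, 3))
        w = rng.normal(size=(4, 3, 3, 3))
        out = conv2d(Tensor(x), Tensor(w), None, pad=1).data
        for b in range(2):
            for o in range(4):
                ref = sum(
                    correlate2d(x[b, :, :, c], w[o, c], mode="same") for c in range(3)
                )
                assert np.allclose(out[b, :, :, o], ref, atol=1e-10)

    def test_weight_and_input_gradients(self):
        rng = np.random.default_rng(1)
        x = Tensor(rng.normal(size=(1, 6, 6, 2)), requires_grad=True)
        conv = Conv2d(2, 3, rng)
        for p in conv.parameters():
            p.data = p.data.astype(np.float64)
        assert numeric_grad(lambda: (conv(x) ** 2).sum(), conv.weight, rng=rng) < 1e-5
        assert numeric_grad(lambda: (conv(x) ** 2).sum(), x, rng=rng) < 1e-5

    def test_pool_upsample_inverse_on_constant(self):
        x = Tensor(np.ones((1, 4, 4, 2)))
        assert np.allclose(upsample_nearest2d(avg_pool2d(x)).data, 1.0)

    def test_instance_norm_statistics(self):
        rng = np.random.default_rng(2)
        x = Tensor(rng.normal(2.0, 3.0, size=(2, 8, 8, 3)))
        out = InstanceNorm2d(3)(x).data
        assert np.abs(out.mean(axis=(1, 2))).max() < 1e-6
        assert np.abs(out.std(axis=(1, 2)) - 1.0).max() < 1e-3


class TestUNet:
    def test_output_shape_matches_input(self):
        rng = np.random.default_rng(0)
        un = UNet(4, 4, base=8, depth=3, rng=rng)
        x = Tensor(rng.normal(size=(2, 16, 16, 4)).astype(np.float32))
        assert un(x).shape == (2, 16, 16, 4)

    def test_batch_elements_independent(self):
        rng = np.random.default_rng(0)
        un = UNet(2, 2, base=4, depth=2, rng=rng)
        a = rng.normal(size=(1, 8, 8, 2)).astype(np.float32)
        b = rng.normal(size=(1, 8, 8, 2)).astype(np.float32)
        joint = un(Tensor(np.concatenate([a, b], axis=0))).data
        sep = np.concatenate([un(Tensor(a)).data, un(Tensor(b)).data], axis=0)
        assert np.allclose(joint, sep, atol=1e-5)

    def test_four_stage_variant_parameter_count(self):
        # the full-size configuration (4 pooling stages, widths 32..512)
        un = UNet(4, 4, base=32, depth=5, rng=np.random.default_rng(0))
        assert 7_500_000 < un.n_parameters() < 8_200_000


class TestHashEncoding:
    def test_collision_free_matches_dense_interpolation(self):
        rng = np.random.default_rng(0)
        cfg = HashEncodingConfig(
            n_levels=1,
            features_per_level=1,
            table_size_log2=10,
            base_resolution=4,
            growth_factor=1.5,
            dimensionality=1,
        )
        enc = HashEncoding(cfg, rng)
        table = rng.normal(size=(5, 1))
        enc.tables[0].table.data = table.astype(np.float32)
        coords = rng.uniform(0, 1, size=(50, 1))
        out = enc(enc.build_interpolator(coords)).data.ravel()
        oracle = np.interp(coords.ravel() * 4, np.arange(5), table.ravel())
        assert np.allclose(out, oracle, atol=1e-6)

    def test_deterministic_and_continuous(self):
        rng = np.random.default_rng(1)
        cfg = HashEncodingConfig(
            n_levels=4, features_per_level=2, table_size_log2=8, base_resolution=4,
            growth_factor=2.0, dimensionality=3,
        )
        enc = HashEncoding(cfg, rng)
        for h in enc.tables:
            h.table.data = rng.normal(size=h.table.shape).astype(np.float32)
        coords = rng.uniform(0.05, 0.95, size=(20, 3))
        out1 = enc(enc.build_interpolator(coords)).data
        out2 = enc(enc.build_interpolator(coords)).data
        assert np.array_equal(out1, out2)
        # Lipschitz bound: features interpolate table values linearly, so a
        # small coordinate step moves features at most range * resolution * eps
        eps = 1e-4
        out_shift = enc(enc.build_interpolator(coords + eps)).data
        max_res = cfg.level_resolution(cfg.n_levels - 1)
        val_range = max(np.ptp(h.table.data) for h in enc.tables)
        bound = 3 * val_range * max_res * eps * 1.01
        assert np.abs(out_shift - out1).max() <= bound

    def test_out_of_range_coordinates_clamped_with_warning(self):
        enc = HashEncoding(HashEncodingConfig(n_levels=1, dimensionality=1), np.random.default_rng(0))
        with pytest.warns(UserWarning, match="clamp"):
            enc.build_interpolator(np.array([[1.5]]))
        with pytest.raises(ValueError):
            enc.build_interpolator(np.array([[1.5]]), strict=True)

    def test_table_gradient_flows(self):
        rng = np.random.default_rng(2)
        cfg = HashEncodingConfig(n_levels=2, dimensionality=3, table_size_log2=6,
                                 base_resolution=2, growth_factor=2.0)
        enc = HashEncoding(cfg, rng)
        for h in enc.tables:
            h.table.data = h.table.data.astype(np.float64)
        interp = enc.build_interpolator(rng.uniform(0, 1, size=(13, 3)))
        err = numeric_grad(
            lambda: (enc(interp) ** 2).sum(), enc.tables[0].table, rng=rng
        )
        assert err < 1e-5


class TestLoRA:
    def test_identity_at_initialization(self):
        rng = np.random.default_rng(0)
        base = Conv2d(3, 4, rng)
        x = Tensor(rng.normal(size=(1, 6, 6, 3)).astype(np.float32))
        before = base(x).data.copy()
        wrapped = LoRAConv2d(base, rank=2, beta=1.0, rng=rng)
        assert np.array_equal(wrapped(x).data, before)

    def test_trainable_parameter_arithmetic(self):
        rng = np.random.default_rng(0)
        base = Conv2d(32, 32, rng)
        wrapped = LoRAConv2d(base, rank=8, beta=1.0, rng=rng)
        lora_params = int(wrapped.lora_a.size + wrapped.lora_b.size)
        assert lora_params == 32 * 8 + 8 * 288 == 2560
        assert base.weight.size == 9216
        assert wrapped.n_trainable() == lora_params  # base + bias frozen

    def test_beta_scales_update_linearly(self):
        rng = np.random.default_rng(1)
        base = Conv2d(2, 2, rng)
        x = Tensor(rng.normal(size=(1, 5, 5, 2)).astype(np.float32))
        y0 = base(x).data.copy()
        w = LoRAConv2d(base, rank=1, beta=1.0, rng=rng)
        w.lora_b.data = rng.normal(size=w.lora_b.shape).astype(np.float32)
        d1 = w(x).data - y0
        w.beta = 2.0
        d2 = w(x).data - y0
        assert np.allclose(d2, 2 * d1, atol=1e-6)

    def test_excessive_rank_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            LoRAConv2d(Conv2d(2, 2, rng), rank=2, beta=1.0, rng=rng)


class TestModuleAndOptim:
    def test_freeze_excludes_from_trainable(self):
        rng = np.random.default_rng(0)
        mlp = MLP(4, [8], 2, rng)
        total = mlp.n_parameters()
        mlp.freeze()
        assert mlp.n_trainable() == 0
        mlp.unfreeze()
        assert mlp.n_trainable() == total

    def test_state_dict_roundtrip(self):
        rng = np.random.default_rng(0)
        a, b = MLP(3, [5], 2, rng), MLP(3, [5], 2, rng)
        b.load_state_dict(a.state_dict())
        x = Tensor(rng.normal(size=(4, 3)).astype(np.float32))
        assert np.allclose(a(x).data, b(x).data)

    def test_adam_matches_reference_update(self):
        p = Tensor(np.array([1.0, -2.0]), requires_grad=True)
        opt = Adam([p], lr=0.1)
        g = np.array([0.5, -1.5])
        p.grad = g.copy()
        opt.step()
        m = 0.1 * g
        v = 0.001 * g * g
        ref = np.array([1.0, -2.0]) - 0.1 * (m / 0.1) / (np.sqrt(v / 0.001) + 1e-8)
        assert np.allclose(p.data, ref, atol=1e-12)

    def test_adam_descends_quadratic(self):
        target = np.array([3.0, -1.0, 0.5])
        p = Tensor(np.zeros(3), requires_grad=True)
        opt = Adam([p], lr=0.1)
        for _ in range(200):
            opt.zero_grad()
            loss = ((p - target) ** 2).sum()
            loss.backward()
            opt.step()
        assert np.allclose(p.data, target, atol=1e-2)
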