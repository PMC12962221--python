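"""Acquisition-operator tests: masks, adjointness, zero-filling, and the
data-consistency functional and gradient (both computation routes)."""

import numpy as np
import pytest

from qmtrecon.encoding import (
    CoilSensitivities,
    InvalidMaskConfigError,
    SamplingMask,
    adjoint_encode,
    data_consistency_grad,
    data_consistency_value,
    forward_encode,
    make_vd_gaussian_mask,
    model_images,
    zero_fill_recon,
)
from qmtrecon.inr import signal_tensor
from qmtrecon.nn import Tensor, stack
from qmtrecon.signal import QMapVolume, measurement_constants
from qmtrecon.unroll import dc_backprojection


class TestMaskGeneration:
    def test_full_sampling_at_af1(self):
        m = make_vd_gaussian_mask((16, 16), 1, 4, seed=0)
        assert m.grid.all()

    @pytest.mark.parametrize(
        "shape,af,cal,expected_pct",
        [((176, 48), 4, 24, 25.0), ((176, 48), 5, 24, 20.0)],
    )
    def test_budget_exact(self, shape, af, cal, expected_pct):
        m = make_vd_gaussian_mask(shape, af, cal, seed=0)
        n = shape[0] * shape[1]
        assert m.n_sampled == round(n / af)
        assert 100 * m.sampled_fraction == pytest.approx(expected_pct, abs=0.05)

    def test_calibration_block_fully_sampled(self):
        m = make_vd_gaussian_mask((64, 64), 4, 16, seed=7)
        x0 = (64 - 16) // 2
        assert m.grid[x0 : x0 + 16, x0 : x0 + 16].all()

    def test_seed_determinism_and_variation(self):
        a = make_vd_gaussian_mask((48, 32), 3, 8, seed=5)
        b = make_vd_gaussian_mask((48, 32), 3, 8, seed=5)
        c = make_vd_gaussian_mask((48, 32), 3, 8, seed=6)
        assert np.array_equal(a.grid, b.grid)
        assert not np.array_equal(a.grid, c.grid)
        assert a.n_sampled == c.n_sampled

    def test_1d_mask_samples_full_lines(self):
        m = make_vd_gaussian_mask((64, 48), 4, 12, seed=0, dim=1, axis=0)
        line_sums = m.grid.sum(axis=1)
        assert set(line_sums.tolist()) <= {0, 48}
        assert (line_sums > 0).sum() == round(64 / 4)

    def test_oversized_calibration_rejected(self):
        with pytest.raises(InvalidMaskConfigError):
            make_vd_gaussian_mask((32, 32), 8, 24, seed=0)


class TestOperator:
    def test_zero_images_give_zero_kspace(self, small_operator):
        C, mask, shape = small_operator
        assert np.allclose(forward_encode(np.zeros(shape), C, mask), 0)

    def test_parseval_full_mask_single_coil(self, rng):
        nx, ny, nz, nm = 16, 16, 1, 3
        C = CoilSensitivities(np.ones((1, nx, ny, nz), complex), np.ones((nx, ny, nz), bool))
        full = SamplingMask(np.ones((nx, ny), np.uint8), (nx, ny), 1.0, 0)
        W = rng.normal(size=(nm, nx, ny, nz)) + 1j * rng.normal(size=(nm, nx, ny, nz))
        d = forward_encode(W, C, full)
        assert np.linalg.norm(d) == pytest.approx(np.linalg.norm(W), rel=1e-10)
        back = adjoint_encode(d, C, full)
        assert np.allclose(back, W, atol=1e-10)

    def test_adjoint_dot_product_ten_trials(self, small_operator):
        C, mask, shape = small_operator
        rng = np.random.default_rng(0)
        nm, nx, ny, nz = shape
        nc = C.n_coils
        for _ in range(10):
            x = rng.normal(size=shape) + 1j * rng.normal(size=shape)
            y = rng.normal(size=(nm, nc, nx, ny, nz)) + 1j * rng.normal(
                size=(nm, nc, nx, ny, nz)
            )
            lhs = np.vdot(y, forward_encode(x, C, mask))
            rhs = np.vdot(adjoint_encode(y, C, mask), x)
            assert abs(lhs - rhs) / abs(lhs) < 1e-10

    def test_shape_mismatch_reported(self, small_operator):
        C, mask, shape = small_operator
        with pytest.raises(ValueError, match="shape"):
            forward_encode(np.zeros((2, 4, 4, 1)), C, mask)


class TestZeroFill:
    def test_fully_sampled_recovery(self, rng):
        nx, ny, nz = 12, 12, 1
        maps = rng.normal(size=(4, nx, ny, nz)) + 1j * rng.normal(size=(4, nx, ny, nz))
        maps /= np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
        C = CoilSensitivities(maps, np.ones((nx, ny, nz), bool))
        full = SamplingMask(np.ones((nx, ny), np.uint8), (nx, ny), 1.0, 0)
        W = rng.normal(size=(2, nx, ny, nz)) + 1j * rng.normal(size=(2, nx, ny, nz))
        rec = zero_fill_recon(forward_encode(W, C, full), C, full)
        assert np.allclose(rec, W, atol=1e-8)

    def test_zero_data_zero_images(self, small_operator):
        C, mask, shape = small_operator
        nm, nx, ny, nz = shape
        d = np.zeros((nm, C.n_coils, nx, ny, nz), complex)
        assert np.allclose(zero_fill_recon(d, C, mask), 0)

    def test_undersampled_energy_not_amplified(self, rng):
        nx, ny, nz = 32, 32, 1
        C = CoilSensitivities(np.ones((1, nx, ny, nz), complex), np.ones((nx, ny, nz), bool))
        mask = make_vd_gaussian_mask((nx, ny), 4, 8, seed=0)
        W = np.zeros((1, nx, ny, nz), complex)
        W[0, 16, 16, 0] = 1.0  # point object
        rec = zero_fill_recon(forward_encode(W, C, mask), C, mask)
        assert np.linalg.norm(rec) <= np.linalg.norm(W) * (1 + 1e-9)


@pytest.fixture
def dc_problem(protocol, consts, rng):
    shape = (8, 8, 1)
    Q = QMapVolume(
        i0=np.full(shape, 1.0),
        t1f=np.full(shape, 1.2) + 0.1 * rng.random(shape),
        f=np.full(shape, 0.1) + 0.05 * rng.random(shape),
        kf=np.full(shape, 2.0) + rng.random(shape),
    )
    C = CoilSensitivities(np.ones((1,) + shape, complex), np.ones(shape, bool))
    mask = make_vd_gaussian_mask((8, 8), 2, 2, seed=0)
    mc = measurement_constants(protocol, consts)
    W = model_images(Q, mc)
    noise = 0.05 * (
        rng.normal(size=(protocol.n_measurements, 1) + shape)
        + 1j * rng.normal(size=(protocol.n_measurements, 1) + shape)
    )
    d = forward_encode(W, C, mask) + noise * mask.grid[None, None, :, :, None]
    return Q, d, C, mask


class TestDataConsistency:
    def test_zero_at_noiseless_truth(self, protocol, consts):
        shape = (6, 6, 1)
        Q = QMapVolume(*(np.full(shape, v) for v in (1.0, 1.2, 0.1, 2.0)))
        C = CoilSensitivities(np.ones((1,) + shape, complex), np.ones(shape, bool))
        mask = make_vd_gaussian_mask((6, 6), 2, 2, seed=0)
        mc = measurement_constants(protocol, consts)
        d = forward_encode(model_images(Q, mc), C, mask)
        val = data_consistency_value(Q, d, C, mask, protocol, consts)
        assert val <= 1e-16 * np.sum(np.abs(d) ** 2)

    def test_quadratic_in_residual(self, dc_problem, protocol, consts):
        Q, d, C, mask = dc_problem
        mc = measurement_constants(protocol, consts)
        W = model_images(Q, mc)
        pred = forward_encode(W, C, mask)
        g1 = data_consistency_value(Q, d, C, mask, protocol, consts)
        d2 = pred + 2.0 * (d - pred)  # doubled residual
        g2 = data_consistency_value(Q, d2, C, mask, protocol, consts)
        assert g2 == pytest.approx(4.0 * g1, rel=1e-10)

    def test_matches_elementwise_brute_force(self, protocol, consts, rng):
        shape = (4, 4, 1)
        Q = QMapVolume(*(np.full(shape, v) for v in (1.0, 1.0, 0.12, 2.5)))
        C = CoilSensitivities(np.ones((1,) + shape, complex), np.ones(shape, bool))
        mask = make_vd_gaussian_mask((4, 4), 2, 2, seed=1)
        mc = measurement_constants(protocol, consts)
        d = rng.normal(size=(protocol.n_measurements, 1) + shape) * mask.grid[None, None, :, :, None]
        val = data_consistency_value(Q, d, C, mask, protocol, consts)
        r = forward_encode(model_images(Q, mc), C, mask) - d
        brute = 0.5 * sum(abs(x) ** 2 for x in r.ravel())
        assert val == pytest.approx(brute, rel=1e-12)

    def test_gradient_matches_finite_differences(self, dc_problem, protocol, consts):
        Q, d, C, mask = dc_problem
        g = data_consistency_grad(Q, d, C, mask, protocol, consts)
        st = Q.stack()
        rng = np.random.default_rng(2)
        for _ in range(8):
            i = rng.integers(0, 4)
            x, y = rng.integers(0, 8, size=2)
            h = 1e-6 * max(abs(st[i, x, y, 0]), 1e-3)
            hi, lo = st.copy(), st.copy()
            hi[i, x, y, 0] += h
            lo[i, x, y, 0] -= h
            fd = (
                data_consistency_value(QMapVolume.from_stack(hi), d, C, mask, protocol, consts)
                - data_consistency_value(QMapVolume.from_stack(lo), d, C, mask, protocol, consts)
            ) / (2 * h)
            assert g[i, x, y, 0] == pytest.approx(fd, rel=1e-4, abs=1e-10)

    def test_gradient_zero_at_noiseless_truth(self, protocol, consts):
        shape = (6, 6, 1)
        Q = QMapVolume(*(np.full(shape, v) for v in (1.0, 1.2, 0.1, 2.0)))
        C = CoilSensitivities(np.ones((1,) + shape, complex), np.ones(shape, bool))
        mask = make_vd_gaussian_mask((6, 6), 2, 2, seed=0)
        mc = measurement_constants(protocol, consts)
        d = forward_encode(model_images(Q, mc), C, mask)
        g = data_consistency_grad(Q, d, C, mask, protocol, consts)
        assert np.abs(g).max() < 1e-8

    def test_reverse_mode_route_agrees_with_jacobian_chain(
        self, dc_problem, protocol, consts
    ):
        """∇g via backprop through the composed graph must match the
        explicit adjoint-plus-Jacobian contraction to 1e-6 relative."""
        Q, d, C, mask = dc_problem
        g_explicit = data_consistency_grad(Q, d, C, mask, protocol, consts)
        mc = measurement_constants(protocol, consts)
        maps = {
            "i0": Tensor(Q.i0, requires_grad=True),
            "t1f": Tensor(Q.t1f, requires_grad=True),
            "f": Tensor(Q.f, requires_grad=True),
            "kf": Tensor(Q.kf, requires_grad=True),
        }
        from qmtrecon.inr import sense_data_term

        sre, sim = signal_tensor(maps, mc)
        loss = sense_data_term(sre, sim, d, C, mask) * 0.5  # = g(Q)
        loss.backward()
        for i, k in enumerate(("i0", "t1f", "f", "kf")):
            num = maps[k].grad
            denom = max(np.abs(g_explicit[i]).max(), 1e-12)
            assert np.abs(num - g_explicit[i]).max() / denom < 1e-6


class TestPerMeasurementMasks:
    def test_adjoint_holds_with_distinct_patterns(self, rng):
        from qmtrecon.encoding import stack_measurement_masks

        nx, ny, nz, nc, nm = 12, 10, 1, 2, 3
        maps = rng.normal(size=(nc, nx, ny, nz)) + 1j * rng.normal(size=(nc, nx, ny, nz))
        maps /= np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
        C = CoilSensitivities(maps, np.ones((nx, ny, nz), bool))
        mask = stack_measurement_masks(
            make_vd_gaussian_mask((nx, ny), 2, 2, seed=s) for s in range(nm)
        )
        assert mask.per_measurement
        # patterns genuinely differ between measurements
        assert not np.array_equal(mask.grid[0], mask.grid[1])
        x = rng.normal(size=(nm, nx, ny, nz)) + 1j * rng.normal(size=(nm, nx, ny, nz))
        y = rng.normal(size=(nm, nc, nx, ny, nz)) + 1j * rng.normal(
            size=(nm, nc, nx, ny, nz)
        )
        lhs = np.vdot(y, forward_encode(x, C, mask))
        rhs = np.vdot(adjoint_encode(y, C, mask), x)
        assert abs(lhs - rhs) / abs(lhs) < 1e-10
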