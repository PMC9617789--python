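"""SSDU partitioning, the self-supervised loss, the unrolled solver, and
training-loop behaviour (determinism, gradients, leakage)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import siimrecon as sr
from siimrecon.classic import cg_least_squares
from siimrecon.datamodel import ValidationError
from siimrecon.encoding import EncodingOperator
from siimrecon.unrolled import (
    TrainConfig,
    UnrolledModel,
    _training_step,
    _unrolled_backward,
    build_training_samples,
    enumerate_training_frames,
    reconstruct_with_model,
    restore_intensity,
    ssdu_loss,
    ssdu_partition,
    train_model,
    unrolled_forward,
)


@pytest.fixture(scope="module")
def tiny_setup():
    protocol = sr.AcquisitionProtocol(
        matrix_size=(32, 32), n_coils=4, sms_factor=2, n_groups=1, n_frames=6,
        in_plane_R=2, partial_fourier=1, fov_shift_fraction="1/2", calib_size=(12, 12),
    )
    phantom = sr.generate_phantom(
        sr.PhantomConfig(matrix_size=(32, 32), n_slices=2, n_frames=6, n_coils=4,
                         noise_sigma=0.02)
    )
    kspace, _ = sr.simulate_acquisition(phantom, protocol, seed=5)
    caipi = sr.make_caipi_schedule(protocol, kspace.pattern_ref)
    op = EncodingOperator(phantom.maps, kspace.pattern_ref, caipi)
    return protocol, phantom, kspace, op


@pytest.fixture(scope="module")
def protocol_split():
    protocol = sr.AcquisitionProtocol()  # full-size mask, SMS=3, R=4, pf=6/8
    pattern = sr.make_sampling_pattern(protocol)
    return pattern, ssdu_partition(pattern, rho=0.4, n_masks=6, seed=2)


class TestSsduPartition:
    def test_partition_invariants(self, protocol_split):
        pattern, split = protocol_split
        omega = pattern.mask
        for k in range(split.n_masks):
            assert not np.any(split.theta[k] & split.lam[k])
            np.testing.assert_array_equal(split.theta[k] | split.lam[k], omega)
            ratio = split.lam[k].sum() / omega.sum()
            assert abs(ratio - 0.4) <= 2 / np.sqrt(omega.sum())

    def test_determinism_and_mask_diversity(self, protocol_split):
        pattern, split = protocol_split
        again = ssdu_partition(pattern, rho=0.4, n_masks=6, seed=2)
        np.testing.assert_array_equal(split.lam, again.lam)
        for k in range(1, split.n_masks):
            assert np.any(split.lam[0] != split.lam[k])

    def test_center_protected(self, protocol_split):
        pattern, split = protocol_split
        nx, ny = pattern.mask.shape
        c = (slice(nx // 2 - 3, nx // 2 + 4), slice(ny // 2 - 3, ny // 2 + 4))
        for k in range(split.n_masks):
            assert not split.lam[k][c].any()

    def test_coverage_over_many_masks(self):
        pattern = sr.make_sampling_pattern(sr.AcquisitionProtocol())
        split = ssdu_partition(pattern, rho=0.4, n_masks=10, seed=0)
        nx, ny = pattern.mask.shape
        protect = np.zeros_like(pattern.mask)
        protect[nx // 2 - 3 : nx // 2 + 4, ny // 2 - 3 : ny // 2 + 4] = True
        eligible = pattern.mask & ~protect
        union = split.lam.any(axis=0)
        assert union[eligible].mean() > 0.95

    def test_bad_rho(self, protocol_split):
        pattern, _ = protocol_split
        with pytest.raises(ValueError):
            ssdu_partition(pattern, rho=0.0)
        with pytest.raises(ValueError):
            ssdu_partition(pattern, rho=0.999)  # larger than unprotected set


class TestSsduLoss:
    def test_zero_for_exact_prediction(self, rng):
        y = rng.normal(size=(3, 8)) + 1j * rng.normal(size=(3, 8))
        assert ssdu_loss(y, y) == 0.0

    @settings(max_examples=25, deadline=None)
    @given(
        re=st.floats(-5, 5), im=st.floats(-5, 5)
    )
    def test_scale_invariance(self, re, im):
        alpha = complex(re, im)
        if abs(alpha) < 1e-3:
            return
        rng = np.random.default_rng(0)
        y = rng.normal(size=16) + 1j * rng.normal(size=16)
        p = rng.normal(size=16) + 1j * rng.normal(size=16)
        a = ssdu_loss(p, y)
        b = ssdu_loss(alpha * p, alpha * y)
        assert b == pytest.approx(a, rel=1e-9)

    def test_three_point_hand_example(self):
        y = np.array([1.0, 0.0, 2.0], dtype=complex)
        p = np.array([0.0, 0.0, 2.0], dtype=complex)
        # e = (1, 0, 0): l2 term = 1/sqrt(5); l1 term = 1/3
        expected = 1 / np.sqrt(5) + 1 / 3
        assert ssdu_loss(p, y) == pytest.approx(expected, rel=1e-12)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            ssdu_loss(np.zeros(0, complex), np.zeros(0, complex))


class TestUnrolledForward:
    def test_zero_unrolls_returns_adjoint(self, tiny_setup):
        _, _, kspace, op = tiny_setup
        model = UnrolledModel.init(n_unrolls=0, cg_iters=5, n_blocks=1, n_channels=4)
        x = unrolled_forward(kspace.data[0, 0], op, model)
        np.testing.assert_array_equal(x, op.adjoint(kspace.data[0, 0]))

    def test_identity_reg_small_mu_approaches_cg(self, tiny_setup):
        _, _, kspace, op = tiny_setup
        y = kspace.data[1, 0]
        model = UnrolledModel.init(
            n_unrolls=2, cg_iters=400, n_blocks=1, n_channels=4, identity=True
        )
        model.mu_raw = -18.0  # mu ~ 1.5e-8
        x = unrolled_forward(y, op, model, cg_tol=1e-12)
        x_cg, _ = cg_least_squares(op, y, tol=1e-12, max_iter=600)
        assert np.linalg.norm(x - x_cg) / np.linalg.norm(x_cg) < 1e-4

    def test_deterministic(self, tiny_setup):
        _, _, kspace, op = tiny_setup
        model = UnrolledModel.init(n_unrolls=2, cg_iters=5, n_blocks=2, n_channels=6, seed=4)
        a = unrolled_forward(kspace.data[0, 0], op, model)
        b = unrolled_forward(kspace.data[0, 0], op, model)
        np.testing.assert_array_equal(a, b)


class TestGradients:
    def test_full_chain_gradient_check(self, tiny_setup):
        """Central-difference check of the SSDU training loss w.r.t. a
        regularizer weight and the penalty parameter."""
        _, _, kspace, op = tiny_setup
        split = ssdu_partition(op.pattern, rho=0.4, n_masks=2, seed=1, center_protect=2)
        model = UnrolledModel.init(n_unrolls=2, cg_iters=300, n_blocks=2, n_channels=6, seed=0)
        rng = np.random.default_rng(7)
        model.weights.tensors = [
            t + rng.normal(scale=0.02, size=t.shape) for t in model.weights.tensors
        ]
        sample = {"op": op, "y": kspace.data[1, 0], "pattern": op.pattern}
        loss, w_grads, g_mu = _training_step(sample, split, 0, model)
        eps = 1e-6

        def loss_at(m):
            return _training_step(sample, split, 0, m)[0]

        for ti, idx in [(0, (0, 0, 1, 1)), (3, (2, 1, 0, 2))]:
            m = UnrolledModel(model.weights.copy(), model.mu_raw, 2, 300, "conventional")
            m.weights.tensors[ti][idx] += eps
            lp = loss_at(m)
            m.weights.tensors[ti][idx] -= 2 * eps
            lm = loss_at(m)
            fd = (lp - lm) / (2 * eps)
            assert abs(fd - w_grads[ti][idx]) / max(abs(fd), 1e-10) < 1e-3

        m = UnrolledModel(model.weights.copy(), model.mu_raw + eps, 2, 300, "conventional")
        lp = loss_at(m)
        m.mu_raw -= 2 * eps
        lm = loss_at(m)
        fd = (lp - lm) / (2 * eps)
        assert abs(fd - g_mu) / max(abs(fd), 1e-10) < 1e-3

    def test_siim_gradient_check(self, tiny_setup):
        _, phantom, kspace, op = tiny_setup
        L = np.abs(phantom.truth.data[:, 1]) + 0.5
        op_h = EncodingOperator(op.maps, op.pattern, op.caipi, L)
        split = ssdu_partition(op.pattern, rho=0.4, n_masks=1, seed=3, center_protect=2)
        model = UnrolledModel.init(
            "siim", n_unrolls=1, cg_iters=300, n_blocks=1, n_channels=4, seed=2
        )
        rng = np.random.default_rng(8)
        model.weights.tensors = [
            t + rng.normal(scale=0.02, size=t.shape) for t in model.weights.tensors
        ]
        sample = {"op": op_h, "y": kspace.data[1, 0], "pattern": op.pattern}
        loss, w_grads, g_mu = _training_step(sample, split, 0, model)
        eps = 1e-6
        ti, idx = (1, (1, 2, 2, 0))
        m = UnrolledModel(model.weights.copy(), model.mu_raw, 1, 300, "siim")
        m.weights.tensors[ti][idx] += eps
        lp = _training_step(sample, split, 0, m)[0]
        m.weights.tensors[ti][idx] -= 2 * eps
        lm = _training_step(sample, split, 0, m)[0]
        fd = (lp - lm) / (2 * eps)
        assert abs(fd - w_grads[ti][idx]) / max(abs(fd), 1e-10) < 1e-3


class TestTraining:
    def test_enumeration_rule(self):
        assert list(enumerate_training_frames(40, 35)) == list(range(5, 40))
        assert len(enumerate_training_frames(40, 35)) == 35

    def test_420_samples(self):
        """4 subjects x 3 SMS groups x last 35 of 40 frames = 420."""
        protocol = sr.AcquisitionProtocol(
            matrix_size=(16, 16), n_coils=2, sms_factor=3, n_groups=3, n_frames=40,
            in_plane_R=4, fov_shift_fraction="1/3", calib_size=(8, 8),
        )
        pattern = sr.make_sampling_pattern(protocol)
        caipi = sr.make_caipi_schedule(protocol, pattern)
        subjects = []
        for _ in range(4):
            subjects.append(
                {
                    "protocol": protocol,
                    "kspace": np.zeros(protocol.kspace_shape, complex),
                    "maps": np.ones((9, 2, 16, 16), complex),
                    "pattern": pattern,
                    "caipi": caipi,
                    "intensity": None,
                }
            )
        samples = build_training_samples(subjects, "conventional", n_last_frames=35)
        assert len(samples) == 420
        frames = {s["frame"] for s in samples}
        assert frames == set(range(5, 40))

    def test_missing_intensity_for_siim(self):
        protocol = sr.AcquisitionProtocol(
            matrix_size=(16, 16), n_coils=2, sms_factor=1, n_groups=1, n_frames=4,
            in_plane_R=1, partial_fourier=1, fov_shift_fraction=0, calib_size=(8, 8),
        )
        pattern = sr.make_sampling_pattern(protocol)
        sub = {
            "protocol": protocol,
            "kspace": np.zeros(protocol.kspace_shape, complex),
            "maps": np.ones((1, 2, 16, 16), complex),
            "pattern": pattern,
            "caipi": None,
            "intensity": None,
        }
        with pytest.raises(ValueError, match="intensity"):
            build_training_samples([sub], "siim", 2)

    def test_deterministic_loss_trace(self, tiny_setup):
        protocol, phantom, kspace, op = tiny_setup
        sub = {
            "protocol": protocol,
            "kspace": kspace.data,
            "maps": phantom.maps,
            "pattern": op.pattern,
            "caipi": op.caipi,
            "intensity": None,
        }
        cfg = TrainConfig(
            n_unrolls=1, cg_iters=4, n_blocks=1, n_channels=4, n_steps=4,
            n_last_frames=4, center_protect=2,
        )
        samples = build_training_samples([sub], "conventional", 4)
        _, t1 = train_model(samples, "conventional", cfg, seed=9)
        _, t2 = train_model(samples, "conventional", cfg, seed=9)
        assert t1 == t2

    def test_smoke_training_loss_decreases(self, tiny_setup):
        protocol, phantom, kspace, op = tiny_setup
        sub = {
            "protocol": protocol,
            "kspace": kspace.data,
            "maps": phantom.maps,
            "pattern": op.pattern,
            "caipi": op.caipi,
            "intensity": None,
        }
        cfg = TrainConfig(
            n_unrolls=3, cg_iters=5, n_blocks=2, n_channels=8, n_steps=50,
            lr=2e-3, n_last_frames=5, center_protect=2,
        )
        samples = build_training_samples([sub], "conventional", 5)
        model, trace = train_model(samples, "conventional", cfg, seed=0)
        assert len(trace) == 50
        # the per-step trace is noisy across (sample, mask) draws; compare
        # the mean objective over a fixed evaluation set before/after
        splits = [
            ssdu_partition(s["pattern"], rho=cfg.rho, n_masks=2, seed=50 + i,
                           center_protect=2)
            for i, s in enumerate(samples)
        ]
        init = UnrolledModel.init(
            "conventional", cfg.n_unrolls, cfg.cg_iters, cfg.n_blocks,
            cfg.n_channels, seed=0,
        )
        def mean_loss(m):
            return np.mean(
                [_training_step(s, sp, 0, m)[0] for s, sp in zip(samples, splits)]
            )
        assert mean_loss(model) < mean_loss(init)

    def test_df_blind_to_lambda(self, tiny_setup):
        """Information-leakage check: zeroing the measured data on Lambda
        changes the network-domain reconstruction used for DF by exactly 0."""
        _, _, kspace, op = tiny_setup
        split = ssdu_partition(op.pattern, rho=0.4, n_masks=1, seed=6, center_protect=2)
        model = UnrolledModel.init(n_unrolls=2, cg_iters=5, n_blocks=2, n_channels=6, seed=1)
        y = kspace.data[2, 0]
        theta_op = op.with_mask(split.theta[0])
        x_a = unrolled_forward(y * split.theta[0], theta_op, model)
        y_zeroed = y.copy()
        y_zeroed[:, split.lam[0]] = 0.0
        x_b = unrolled_forward(y_zeroed * split.theta[0], theta_op, model)
        np.testing.assert_array_equal(x_a, x_b)


class TestReconstructRestore:
    def test_kind_mismatch_rejected(self, tiny_setup):
        _, _, kspace, op = tiny_setup
        model = UnrolledModel.init("siim", n_unrolls=1, cg_iters=2, n_blocks=1, n_channels=4)
        with pytest.raises(ValidationError):
            reconstruct_with_model(kspace.data[0, 0], op, model)

    def test_identity_regularizer_full_sampling_recovers(self):
        protocol = sr.AcquisitionProtocol(
            matrix_size=(32, 32), n_coils=4, sms_factor=1, n_groups=1, n_frames=2,
            in_plane_R=1, partial_fourier=1, fov_shift_fraction=0, calib_size=(12, 12),
        )
        phantom = sr.generate_phantom(
            sr.PhantomConfig(matrix_size=(32, 32), n_slices=1, n_frames=2, n_coils=4)
        )
        kspace, _ = sr.simulate_acquisition(phantom, protocol, seed=0)
        op = EncodingOperator(phantom.maps[0], kspace.pattern_ref)
        model = UnrolledModel.init(
            n_unrolls=2, cg_iters=50, n_blocks=1, n_channels=4, identity=True
        )
        x = reconstruct_with_model(kspace.data[0, 0], op, model)
        tru = phantom.truth.data[0, 0]
        assert np.linalg.norm(x[0] - tru) / np.linalg.norm(tru) < 1e-6

    def test_restore_identity_and_scaling(self, rng):
        x = rng.normal(size=(2, 8, 8)) + 1j * rng.normal(size=(2, 8, 8))
        L = np.abs(rng.normal(size=(2, 8, 8))) + 0.2
        np.testing.assert_array_equal(restore_intensity(x, np.ones_like(L)), x)
        np.testing.assert_allclose(
            restore_intensity(x, 2.0 * L), 2.0 * restore_intensity(x, L), atol=1e-12
        )

    def test_restore_rejects_unfloored(self, rng):
        x = rng.normal(size=(1, 4, 4)) + 0j
        L = np.zeros((1, 4, 4))
        with pytest.raises(ValidationError):
            restore_intensity(x, L)

    def test_restore_matches_conventional_solve(self, wellposed_setup):
        """Inverse-chain: restoring the intensity-informed solve reproduces
        the conventional least-squares solution."""
        _, phantom, kspace, _, pattern, caipi = wellposed_setup
        op_e = EncodingOperator(phantom.maps, pattern, caipi)
        L = np.abs(phantom.truth.data[:, 1]) + 1.0
        op_h = EncodingOperator(phantom.maps, pattern, caipi, L)
        y = kspace.data[1, 0]
        x_reg, _ = cg_least_squares(op_e, y, tol=1e-11, max_iter=3000)
        x_siim, _ = cg_least_squares(op_h, y, tol=1e-11, max_iter=3000)
        restored = restore_intensity(x_siim, L)
        assert np.linalg.norm(restored - x_reg) / np.linalg.norm(x_reg) < 1e-6
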