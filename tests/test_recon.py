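"""Reconstruction tests: preprocessing, operator correctness (adjoint and
subspace-domain equivalence), the LLR proximal operator, and solver
behaviour on the phantom acquisition."""

import numpy as np
import pytest

import subangio as sa
from subangio.recon import (
    BinnedOperator,
    SubspaceOperator,
    _llr_value,
    data_to_flat,
    flat_to_data,
    tag_control_difference,
)
from subangio.subspace import expand


class TestScaleKspace:
    def test_constant_magnitude(self):
        data = np.full((2, 10), 3.0 + 4.0j)
        scaled, factor = sa.scale_kspace(data)
        assert factor == pytest.approx(5.0)
        assert np.allclose(np.abs(scaled), 1.0)

    def test_undo_round_trip(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal(500) + 1j * rng.standard_normal(500)
        scaled, factor = sa.scale_kspace(data)
        assert np.allclose(scaled * factor, data)
        rescaled, f2 = sa.scale_kspace(scaled * factor)
        assert f2 == pytest.approx(factor)

    def test_percentile_against_sort_oracle(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal(1000) + 1j * rng.standard_normal(1000)
        _, factor = sa.scale_kspace(data)
        mags = np.sort(np.abs(data))
        # linear-interpolation percentile on the sorted magnitudes
        pos = 0.95 * (len(mags) - 1)
        lo, hi = int(np.floor(pos)), int(np.ceil(pos))
        expected = mags[lo] + (pos - lo) * (mags[hi] - mags[lo])
        assert factor == pytest.approx(expected, rel=1e-12)

    def test_zero_data_rejected(self):
        with pytest.raises(ValueError):
            sa.scale_kspace(np.zeros(10, complex))


def test_tag_control_difference():
    tag = np.ones(5, complex)
    control = np.full(5, 3.0 + 0j)
    assert np.allclose(tag_control_difference(tag, control), 2.0)
    with pytest.raises(ValueError):
        tag_control_difference(np.ones(4), np.ones(5))


class TestCoilCompression:
    def test_lossless_when_keeping_all(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((4, 300)) + 1j * rng.standard_normal((4, 300))
        comp, mixing, retained = sa.compress_coils(data, 4)
        assert retained == pytest.approx(1.0, abs=1e-12)
        # unitary mixing preserves total energy
        assert np.sum(np.abs(comp) ** 2) == pytest.approx(
            np.sum(np.abs(data) ** 2), rel=1e-10)

    def test_rank_one_coils(self):
        rng = np.random.default_rng(3)
        signal = rng.standard_normal(200) + 1j * rng.standard_normal(200)
        weights = np.array([1.0, 0.5j, -0.3, 2.0])
        data = weights[:, None] * signal[None, :]
        _, _, retained = sa.compress_coils(data, 1)
        assert retained == pytest.approx(1.0, abs=1e-10)

    def test_retained_energy_monotone(self):
        rng = np.random.default_rng(4)
        data = rng.standard_normal((6, 400)) + 1j * rng.standard_normal((6, 400))
        fracs = [sa.compress_coils(data, k)[2] for k in range(1, 7)]
        assert np.all(np.diff(fracs) >= -1e-12)


class TestSensitivities:
    def test_single_coil_uniform(self, seq):
        sampling = sa.build_sampling(seq, n_repeats=2, matrix_size=8,
                                     samples_per_spoke=16)
        data = np.ones((1, 144, 2, 16), complex)
        sens = sa.estimate_sensitivities(data, sampling)
        assert np.allclose(sens, 1.0)

    def test_identical_coils_equal_magnitude(self, seq):
        n = 8
        sampling = sa.build_sampling(seq, n_repeats=4, matrix_size=n,
                                     samples_per_spoke=16)
        nufft = sa.Nufft3(sampling.coords_flat(), (n, n, n))
        static = np.repeat(np.ones((n, n, n), complex)[None], 144, axis=0)
        one = sa.simulate_kspace(static, sampling, nufft=nufft)
        data = np.concatenate([one, one], axis=0)
        sens = sa.estimate_sensitivities(data, sampling, nufft=nufft)
        assert np.allclose(np.abs(sens[0]), np.abs(sens[1]), atol=1e-8)
        rss = np.sqrt((np.abs(sens) ** 2).sum(axis=0))
        assert rss.max() <= 1.0 + 1e-6

    def test_smooth_maps_recovered(self, seq):
        """Walsh-combined maps align with the simulated ground truth
        (normalized inner product per coil, first-coil phase reference)."""
        n = 8
        x, y, z = np.meshgrid(*[np.linspace(-1, 1, n)] * 3, indexing="ij")
        truth = np.stack([
            (1.0 + 0.5 * x + 0.3 * y) * np.exp(1j * 0.7 * z),
            (1.0 - 0.4 * x + 0.2 * z) * np.exp(-1j * 0.5 * y),
            (0.8 + 0.3 * y - 0.2 * z) * np.exp(1j * 0.3 * x),
        ]).astype(complex)
        truth /= np.sqrt((np.abs(truth) ** 2).sum(0))
        ref = truth * np.conj(truth[0] / np.abs(truth[0]))[None]
        sampling = sa.build_sampling(seq, n_repeats=8, matrix_size=n,
                                     samples_per_spoke=16)
        nufft = sa.Nufft3(sampling.coords_flat(), (n, n, n))
        static = np.repeat(np.ones((n, n, n), complex)[None], 144, axis=0)
        data = sa.simulate_kspace(static, sampling, sensitivities=truth,
                                  nufft=nufft)
        est = sa.estimate_sensitivities(data, sampling, nufft=nufft)
        for c in range(3):
            align = abs(np.vdot(est[c], ref[c])) / (
                np.linalg.norm(est[c]) * np.linalg.norm(ref[c]))
            assert align >= 0.99


@pytest.fixture(scope="module")
def tiny_problem(seq):
    """8^3 acquisition plus a 12-component subspace for operator tests."""
    n = 8
    sampling = sa.build_sampling(seq, n_repeats=4, matrix_size=n,
                                 samples_per_spoke=16)
    nufft = sa.Nufft3(sampling.coords_flat(), (n, n, n))
    dictionary = sa.build_dictionary(sa.parameter_grid(n_per_axis=8), seq)
    subspace = sa.extract_subspace(dictionary, 12)
    return sampling, nufft, subspace


class TestOperators:
    def test_subspace_adjoint_identity(self, tiny_problem):
        sampling, nufft, subspace = tiny_problem
        op = SubspaceOperator(sampling, subspace, nufft=nufft)
        rng = np.random.default_rng(8)
        x = rng.standard_normal(op.x_shape) + 1j * rng.standard_normal(op.x_shape)
        y = rng.standard_normal(op.y_shape) + 1j * rng.standard_normal(op.y_shape)
        lhs = np.vdot(y, op.forward(x))
        rhs = np.vdot(op.adjoint(y), x)
        scale = np.linalg.norm(op.forward(x)) * np.linalg.norm(y)
        assert abs(lhs - rhs) / scale <= 1e-6

    def test_binned_adjoint_identity(self, tiny_problem):
        sampling, nufft, _ = tiny_problem
        op = BinnedOperator(sampling, bin_size=12, nufft=nufft)
        rng = np.random.default_rng(9)
        x = rng.standard_normal(op.x_shape) + 1j * rng.standard_normal(op.x_shape)
        y = rng.standard_normal(op.y_shape) + 1j * rng.standard_normal(op.y_shape)
        lhs = np.vdot(y, op.forward(x))
        rhs = np.vdot(op.adjoint(y), x)
        scale = np.linalg.norm(op.forward(x)) * np.linalg.norm(y)
        assert abs(lhs - rhs) / scale <= 1e-6

    def test_subspace_domain_equals_expand_then_sample(self, tiny_problem):
        """Eq.-level equivalence: per-sample basis weighting of component
        k-space equals expanding to all frames then sampling frame-wise."""
        sampling, nufft, subspace = tiny_problem
        op = SubspaceOperator(sampling, subspace, nufft=nufft)
        rng = np.random.default_rng(10)
        coeffs = rng.standard_normal(op.x_shape) \
            + 1j * rng.standard_normal(op.x_shape)
        direct = op.forward(coeffs)
        frames = expand(coeffs, subspace)
        naive = data_to_flat(
            sa.simulate_kspace(frames, sampling, nufft=nufft), sampling)
        assert np.linalg.norm(direct - naive) / np.linalg.norm(naive) <= 1e-8

    def test_zero_data_zero_maps(self, tiny_problem):
        sampling, nufft, subspace = tiny_problem
        op = SubspaceOperator(sampling, subspace, nufft=nufft)
        assert np.all(op.adjoint(np.zeros(op.y_shape, complex)) == 0)

    def test_gram_matches_explicit_normal_operator(self, tiny_problem):
        sampling, nufft, subspace = tiny_problem
        op = SubspaceOperator(sampling, subspace, nufft=nufft)
        rng = np.random.default_rng(11)
        x = rng.standard_normal(op.x_shape) + 1j * rng.standard_normal(op.x_shape)
        ref = op.adjoint(op.forward(x))
        fast = op.gram().apply(x)
        assert np.linalg.norm(fast - ref) / np.linalg.norm(ref) <= 1e-4

    def test_flat_layout_round_trip(self, tiny_problem):
        sampling, _, _ = tiny_problem
        rng = np.random.default_rng(12)
        shape = (2, sampling.n_timepoints, sampling.n_repeats,
                 sampling.samples_per_spoke)
        data = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        assert np.array_equal(flat_to_data(data_to_flat(data, sampling),
                                           sampling), data)


class TestLlrProx:
    def test_zero_threshold_identity(self):
        rng = np.random.default_rng(13)
        maps = rng.standard_normal((3, 8, 8, 8)) \
            + 1j * rng.standard_normal((3, 8, 8, 8))
        assert np.array_equal(sa.llr_prox(maps, 0.0, 4), maps)

    def test_large_threshold_annihilates(self):
        rng = np.random.default_rng(14)
        maps = rng.standard_normal((3, 8, 8, 8)) + 0j
        out = sa.llr_prox(maps, 1e6, 4)
        assert np.abs(out).max() <= 1e-12

    def test_rank_one_patch_soft_threshold(self):
        """A rank-1 patch with singular value 2 thresholded by 0.5 shrinks
        by exactly 25%."""
        u = np.zeros((4, 4, 4))
        u[1, 2, 3] = 1.0
        v = np.array([2.0, 0.0, 0.0])
        maps = v[:, None, None, None] * u[None]     # sigma = 2, rank 1
        out = sa.llr_prox(maps + 0j, 0.5, 4)
        assert np.allclose(out, 0.75 * maps, atol=1e-12)

    def test_shift_round_trip_preserves_shape(self):
        rng = np.random.default_rng(15)
        maps = rng.standard_normal((2, 10, 10, 10)) + 0j   # pads to 12
        out = sa.llr_prox(maps, 1e-3, 4, shift=2)
        assert out.shape == maps.shape


class TestSolver:
    def test_unregularized_residual_reaches_noise_floor(
            self, recon_unregularized):
        """Noiseless consistent data: lam = 0 least squares drives the
        relative k-space residual to the numerical floor."""
        assert recon_unregularized["relative_residual"] <= 1e-4

    def test_unregularized_recovers_projected_truth(
            self, phantom_run, recon_unregularized):
        """Expanded timecourses match the recoverable (subspace-projected,
        band-limited) phantom on vessel voxels to well under 2% NRMSE."""
        vi = phantom_run["phantom"].vessel_indices
        rec = np.abs(recon_unregularized["series"][(slice(None),) + vi])
        truth = np.abs(recon_unregularized["truth"][(slice(None),) + vi])
        nrmse = (np.linalg.norm(rec - truth, axis=0)
                 / np.linalg.norm(truth, axis=0))
        assert nrmse.max() <= 0.02

    def test_objective_traces_non_increasing(self, recon_subspace,
                                             recon_binned,
                                             recon_unregularized):
        for trace in (recon_subspace["trace"], recon_binned["trace"],
                      recon_unregularized["trace"]):
            diffs = np.diff(trace)
            assert np.all(diffs <= np.abs(trace[:-1]) * 1e-6 + 1e-12)

    def test_zero_data_zero_solution(self, tiny_problem):
        sampling, nufft, subspace = tiny_problem
        shape = (1, sampling.n_timepoints, sampling.n_repeats,
                 sampling.samples_per_spoke)
        cfg = sa.ReconConfig(lam=1e-3, n_iterations=5, patch_size=4)
        coeffs, _ = sa.reconstruct_subspace(np.zeros(shape, complex),
                                            sampling, subspace, config=cfg,
                                            nufft=nufft)
        assert np.abs(coeffs).max() <= 1e-12

    def test_deterministic_repeat(self, tiny_problem, seq):
        sampling, nufft, subspace = tiny_problem
        phantom = sa.make_vessel_phantom(8)
        series = sa.phantom_series(phantom, seq).astype(complex)
        data, _ = sa.scale_kspace(
            sa.simulate_kspace(series, sampling, nufft=nufft))
        cfg = sa.ReconConfig(lam=1e-3, n_iterations=10, patch_size=4)
        op = sa.SubspaceOperator(sampling, subspace, nufft=nufft)
        a, _ = sa.reconstruct_subspace(data, sampling, subspace, config=cfg,
                                       nufft=nufft, operator=op)
        b, _ = sa.reconstruct_subspace(data, sampling, subspace, config=cfg,
                                       nufft=nufft, operator=op)
        assert np.array_equal(a, b)

    def test_regularizer_value_monotone_in_lambda(self, tiny_problem, seq):
        """Stronger LLR weighting never increases the solution's summed
        patch nuclear norm (spot check at three weights)."""
        sampling, nufft, subspace = tiny_problem
        phantom = sa.make_vessel_phantom(8)
        series = sa.phantom_series(phantom, seq).astype(complex)
        data, _ = sa.scale_kspace(
            sa.simulate_kspace(series, sampling, nufft=nufft))
        op = sa.SubspaceOperator(sampling, subspace, nufft=nufft)
        values = []
        for lam in (1e-4, 1e-3, 1e-2):
            cfg = sa.ReconConfig(lam=lam, n_iterations=60, patch_size=4)
            coeffs, _ = sa.reconstruct_subspace(data, sampling, subspace,
                                                config=cfg, nufft=nufft,
                                                operator=op)
            values.append(_llr_value(coeffs, 4, 0))
        assert np.all(np.diff(values) <= 1e-9)


class TestBinnedRecon:
    def test_twelve_bins_give_twelve_frames(self, recon_binned):
        assert recon_binned["frames"].shape[0] == 12

    def test_degenerate_single_bin_static(self, tiny_problem, seq):
        sampling, nufft, _ = tiny_problem
        phantom = sa.make_vessel_phantom(8)
        series = sa.phantom_series(phantom, seq).astype(complex)
        data, _ = sa.scale_kspace(
            sa.simulate_kspace(series, sampling, nufft=nufft))
        cfg = sa.ReconConfig(lam=1e-1, n_iterations=10, patch_size=4,
                             bin_size=144)
        frames, trace = sa.reconstruct_binned(data, sampling, config=cfg,
                                              nufft=nufft)
        assert frames.shape == (1, 8, 8, 8)
        assert np.all(np.diff(trace) <= np.abs(trace[:-1]) * 1e-6 + 1e-12)
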