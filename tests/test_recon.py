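"""SLAM/SLIM operators, FT-MRS reconstruction and coil combination."""

import numpy as np
import pytest

from cmrsi.encoding import PhaseEncodeScheme, make_aw_scheme, make_central_scheme
from cmrsi.grids import GridSpec, ravel_map
from cmrsi.phantom import (
    KSpaceData,
    Phantom,
    PhantomConfig,
    ResonanceParams,
    forward_encode,
    make_cardiac_phantom,
    refine_phantom,
)
from cmrsi.recon import (
    CompartmentMask,
    build_g_matrix,
    build_pe_matrix,
    compartment_noise_sd,
    compress_compartments,
    ft_mrs_reconstruct,
    slam_reconstruct,
    slim_reconstruct,
    wsvd_combine,
)

from .conftest import DWELL, compartment_ground_truth

FOV = (240.0, 240.0, 200.0)


def scheme_1d(kx_values, repeats, matrix=(8, 1, 1)):
    k = np.array([[float(kx), 0.0, 0.0] for kx in kx_values])
    return PhaseEncodeScheme(k, np.asarray(repeats, dtype=int), FOV, matrix)


class TestPeMatrix:
    def test_k0_row_is_all_ones(self):
        s = scheme_1d([0], [1])
        pe = build_pe_matrix(s, GridSpec((8, 1, 1), FOV))
        np.testing.assert_allclose(pe, np.ones((1, 8)), atol=1e-15)

    def test_repeat_weighting_doubles_rows(self):
        s1 = scheme_1d([0, 1], [1, 1])
        s2 = scheme_1d([0, 1], [1, 2])
        g = GridSpec((8, 1, 1), FOV)
        pe1, pe2 = build_pe_matrix(s1, g), build_pe_matrix(s2, g)
        np.testing.assert_allclose(pe2[1], 2 * pe1[1], rtol=1e-15)
        np.testing.assert_allclose(pe2[0], pe1[0], rtol=1e-15)

    def test_full_uniform_matrix_columns_are_orthogonal(self):
        s = make_aw_scheme((4, 4, 2), 1, "uniform", FOV)
        pe = build_pe_matrix(s, GridSpec((4, 4, 2), FOV))
        gram = pe.conj().T @ pe
        np.testing.assert_allclose(gram, 32 * np.eye(32), atol=1e-10)


class TestCompress:
    def test_single_compartment_k0_scalar_is_repeat_count(self):
        labels = np.zeros((8, 1, 1), dtype=int)
        mask = CompartmentMask(labels, [0], FOV)
        s = scheme_1d([0], [3])
        op = compress_compartments(build_pe_matrix(s, mask.grid), mask, scheme=s)
        assert op.encoding_matrix.shape == (1, 1)
        assert op.encoding_matrix[0, 0] == pytest.approx(3.0)

    def test_two_half_fov_compartments_match_brute_force(self):
        labels = np.zeros((8, 1, 1), dtype=int)
        labels[4:, 0, 0] = 1
        mask = CompartmentMask(labels, [0, 1], FOV)
        s = scheme_1d([0, 1], [1, 1])
        pe = build_pe_matrix(s, mask.grid)
        op = compress_compartments(pe, mask, scheme=s)
        # brute force: mean of exp(-2 pi i k x_j) over each half
        x = (np.arange(8) - 4) / 8
        expected = np.empty((2, 2), dtype=complex)
        for m, k in enumerate([0, 1]):
            expected[m, 0] = np.mean(np.exp(-2j * np.pi * k * x[:4]))
            expected[m, 1] = np.mean(np.exp(-2j * np.pi * k * x[4:]))
        np.testing.assert_allclose(op.encoding_matrix, expected, atol=1e-14)

    def test_empty_compartment_is_named_in_error(self, phantom, central_scheme):
        labels = phantom.label_map.copy()
        labels[labels == 2] = 0
        with pytest.raises(ValueError, match="2"):
            mask = CompartmentMask(phantom.label_map, [0, 1, 2], FOV)
            pe = build_pe_matrix(central_scheme, mask.grid)
            bad_mask = CompartmentMask.__new__(CompartmentMask)
            object.__setattr__(bad_mask, "label_map", labels)
            object.__setattr__(bad_mask, "compartment_ids", [0, 1, 2])
            object.__setattr__(bad_mask, "fov_mm", FOV)
            compress_compartments(pe, bad_mask, scheme=central_scheme)

    def test_pseudoinverse_identity(self, phantom, mask, aw_scheme, central_scheme):
        for s in (aw_scheme, central_scheme):
            op = compress_compartments(build_pe_matrix(s, mask.grid), mask, scheme=s)
            np.testing.assert_allclose(
                op.pseudoinverse @ op.encoding_matrix, np.eye(3), atol=1e-8
            )
            opg = build_g_matrix(s, mask)
            np.testing.assert_allclose(
                opg.pseudoinverse @ opg.encoding_matrix, np.eye(3), atol=1e-8
            )


class TestSlam:
    def test_noiseless_recovery_is_exact(self, phantom, mask, aw_scheme):
        kd = forward_encode(phantom, aw_scheme, n_time=32, dwell_s=DWELL)
        op = compress_compartments(build_pe_matrix(aw_scheme, mask.grid), mask, scheme=aw_scheme)
        spectra = slam_reconstruct(kd, op)
        for i, c in enumerate(mask.compartment_ids):
            gt = compartment_ground_truth(phantom, c, 32)
            err = np.linalg.norm(spectra.time_signals[i] - gt) / np.linalg.norm(gt)
            assert err < 1e-8

    def test_randomized_phantoms_recover_exactly(self, mask):
        # homogeneous compartments with randomized spectra and schemes
        rng = np.random.default_rng(11)
        ph0 = make_cardiac_phantom()
        for trial in range(3):
            lines = {
                c: [
                    ResonanceParams(
                        f"r{j}", rng.uniform(0.2, 3.0), rng.uniform(-800, 800), rng.uniform(15, 70)
                    )
                    for j in range(rng.integers(1, 4))
                ]
                for c in (0, 1, 2)
            }
            ph = Phantom(ph0.grid, ph0.label_map, lines, ph0.delta_f_map,
                         ph0.phase_map, ph0.b1_tx_map, ph0.density_map)
            n_k = int(rng.integers(8, 30))
            kset = set()
            while len(kset) < n_k:
                kset.add(tuple(rng.integers(-3, 4, size=3).tolist()))
            s = PhaseEncodeScheme(
                np.array(sorted(kset), dtype=float),
                rng.integers(1, 5, size=n_k), FOV, (8, 16, 8),
            )
            kd = forward_encode(ph, s, n_time=16, dwell_s=DWELL)
            op = compress_compartments(build_pe_matrix(s, mask.grid), mask, scheme=s)
            spectra = slam_reconstruct(kd, op)
            for i, c in enumerate(mask.compartment_ids):
                gt = compartment_ground_truth(ph, c, 16)
                assert np.linalg.norm(spectra.time_signals[i] - gt) < 1e-8 * np.linalg.norm(gt)

    def test_zero_data_zero_spectra(self, mask, central_scheme):
        op = compress_compartments(
            build_pe_matrix(central_scheme, mask.grid), mask, scheme=central_scheme
        )
        kd = KSpaceData(central_scheme, np.zeros((1, 64, 8), dtype=complex), DWELL)
        assert np.all(slam_reconstruct(kd, op).spectra == 0)

    def test_repeat_doubling_cancels_in_reconstruction(self, phantom, mask, central_scheme):
        doubled = PhaseEncodeScheme(
            central_scheme.k_coords, 2 * central_scheme.repeats,
            central_scheme.fov_mm, central_scheme.matrix_shape,
        )
        out = []
        for s in (central_scheme, doubled):
            kd = forward_encode(phantom, s, n_time=16, dwell_s=DWELL)
            op = compress_compartments(build_pe_matrix(s, mask.grid), mask, scheme=s)
            out.append(slam_reconstruct(kd, op).time_signals)
        np.testing.assert_allclose(out[0], out[1], rtol=1e-10)

    def test_scheme_mismatch_rejected(self, phantom, mask, aw_scheme, central_scheme):
        kd = forward_encode(phantom, central_scheme, n_time=8, dwell_s=DWELL)
        op = compress_compartments(build_pe_matrix(aw_scheme, mask.grid), mask, scheme=aw_scheme)
        with pytest.raises(ValueError):
            slam_reconstruct(kd, op)

    def test_noise_sd_matches_closed_form(self, phantom, mask, central_scheme):
        # Monte-Carlo over noise-only acquisitions vs sigma*||row(H_eff W)||
        ph = Phantom(phantom.grid, phantom.label_map, phantom.resonances,
                     phantom.delta_f_map, phantom.phase_map, phantom.b1_tx_map,
                     np.zeros(phantom.grid.shape))
        op = compress_compartments(
            build_pe_matrix(central_scheme, mask.grid), mask, scheme=central_scheme
        )
        pred = compartment_noise_sd(op, 0.5)
        draws = []
        for i in range(200):
            kd = forward_encode(ph, central_scheme, noise_sd=0.5, seed=900 + i,
                                n_time=8, dwell_s=DWELL)
            draws.append(slam_reconstruct(kd, op).time_signals)
        emp = np.sqrt(np.mean(np.abs(np.asarray(draws)) ** 2, axis=(0, 2)))
        np.testing.assert_allclose(emp, pred, rtol=0.05)


class TestGMatrix:
    def test_k0_column_is_unity_after_volume_normalization(self, mask, central_scheme):
        op = build_g_matrix(central_scheme, mask)
        m0 = int(np.flatnonzero((central_scheme.k_coords == 0).all(axis=1))[0])
        np.testing.assert_allclose(
            op.encoding_matrix[m0], central_scheme.repeats[m0] * np.ones(3), atol=1e-12
        )

    def test_single_voxel_compartment_closed_form(self):
        labels = np.full((8, 1, 1), -1)
        labels[2, 0, 0] = 0
        mask = CompartmentMask(labels, [0], FOV)
        r = 3
        s = scheme_1d([1], [r])
        op = build_g_matrix(s, mask)
        x_center = (2 - 4) / 8
        expected = r * np.sinc(1 / 8) * np.exp(-2j * np.pi * 1 * x_center)
        assert op.encoding_matrix[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_full_period_integral_vanishes(self):
        # compartment spanning the full FOV along x: integer-k integral = 0
        labels = np.zeros((8, 1, 1), dtype=int)
        mask = CompartmentMask(labels, [0], FOV)
        s = scheme_1d([0, 1, 2], [1, 1, 1])
        op = build_g_matrix(s, mask)
        assert op.encoding_matrix[0, 0] == pytest.approx(1.0)
        np.testing.assert_allclose(op.encoding_matrix[1:, 0], 0.0, atol=1e-12)


class TestSlim:
    def test_refined_simulation_recovery_and_convergence(self, phantom, mask, central_scheme):
        op = build_g_matrix(central_scheme, mask)
        errs = []
        for q in (1, 3):
            fine = refine_phantom(phantom, q)
            kd = forward_encode(fine, central_scheme, n_time=16, dwell_s=DWELL)
            kd = KSpaceData(central_scheme, kd.data / q**3, DWELL)
            spectra = slim_reconstruct(kd, op)
            err = max(
                np.linalg.norm(spectra.time_signals[i] - compartment_ground_truth(phantom, c, 16))
                / np.linalg.norm(compartment_ground_truth(phantom, c, 16))
                for i, c in enumerate(mask.compartment_ids)
            )
            errs.append(err)
        assert errs[0] < 0.1  # acquisition-grid point sampling: few-percent mismatch
        assert errs[1] < 1e-2  # box-consistent refinement converges
        assert errs[1] < errs[0] / 3

    def test_zero_data_zero_spectra(self, mask, central_scheme):
        op = build_g_matrix(central_scheme, mask)
        kd = KSpaceData(central_scheme, np.zeros((1, 64, 8), dtype=complex), DWELL)
        assert np.all(slim_reconstruct(kd, op).spectra == 0)

    def test_whole_fov_k0_solution_is_mean_voxel_fid(self, phantom):
        labels = np.where(phantom.label_map >= 0, 0, 0)  # single compartment everywhere
        mask1 = CompartmentMask(labels, [0], FOV)
        s = scheme_1d([0], [1], matrix=(8, 16, 8))
        kd = forward_encode(phantom, s, n_time=16, dwell_s=DWELL)
        op = build_g_matrix(s, mask1)
        spectra = slim_reconstruct(kd, op)
        from cmrsi.phantom import all_voxel_fids

        mean_fid = all_voxel_fids(phantom, 16, DWELL).mean(axis=0)
        np.testing.assert_allclose(spectra.time_signals[0], mean_fid, rtol=1e-10, atol=1e-12)

    def test_slam_and_slim_agree_for_vanishing_voxel_width(self):
        # 1D refinement: voxel width 1/128 along the encoded axis
        ph = make_cardiac_phantom(PhantomConfig(grid_shape=(128, 4, 4)))
        mask = CompartmentMask.from_phantom(ph)
        s = make_central_scheme((8, 1, 1), (4, 1, 1), 1)
        kd = forward_encode(ph, s, n_time=16, dwell_s=DWELL)
        op_a = compress_compartments(build_pe_matrix(s, ph.grid), mask, scheme=s)
        op_g = build_g_matrix(s, mask)
        xa = slam_reconstruct(kd, op_a).time_signals
        xg = slim_reconstruct(kd, op_g).time_signals
        assert np.linalg.norm(xa - xg) / np.linalg.norm(xa) < 1e-3


class TestFtMrs:
    def _delta_phantom(self, j0=(4, 8, 4)):
        grid = GridSpec((8, 16, 8), FOV)
        dens = np.zeros(grid.shape)
        dens[j0] = 1.0
        z = np.zeros(grid.shape)
        return Phantom(grid, np.zeros(grid.shape, dtype=int),
                       {0: [ResonanceParams("PCr", 1.0, 0.0, 30.0)]},
                       z, z, np.ones(grid.shape), dens)

    def test_delta_phantom_concentrates_at_source_voxel(self):
        ph = self._delta_phantom()
        s = make_aw_scheme((8, 16, 8), 1, "uniform")
        voxels = ft_mrs_reconstruct(forward_encode(ph, s, n_time=8, dwell_s=DWELL))
        mag = np.abs(voxels.fids[..., 0])
        assert np.unravel_index(mag.argmax(), mag.shape) == (4, 8, 4)
        others = np.sort(mag.ravel())[:-1]
        assert others.max() < 1e-10 * mag.max()

    def test_aw_scheme_produces_window_psf_sidelobes(self):
        ph = self._delta_phantom()
        s = make_aw_scheme((8, 16, 8), 4, "hamming")
        voxels = ft_mrs_reconstruct(forward_encode(ph, s, n_time=4, dwell_s=DWELL))
        mag = np.abs(voxels.fids[..., 0])
        assert np.unravel_index(mag.argmax(), mag.shape) == (4, 8, 4)
        # oracle: the image of a delta source is the inverse DFT of the
        # repeat table (the window PSF), up to a constant
        reps = np.zeros((8, 16, 8))
        for k, r in zip(s.k_coords.astype(int), s.repeats):
            reps[k[0] + 4, k[1] + 8, k[2] + 4] = r
        psf = np.abs(np.fft.ifftn(np.fft.ifftshift(reps)))
        psf = np.fft.fftshift(psf)
        np.testing.assert_allclose(mag / mag.max(), psf / psf.max(), atol=1e-10)
        sidelobes = np.delete(mag.ravel(), mag.argmax())
        assert sidelobes.max() > 1e-6 * mag.max()  # nonzero sidelobes exist

    def test_voxel_sum_equals_k0_sample(self, phantom):
        s = make_aw_scheme((8, 16, 8), 4, "hamming")
        kd = forward_encode(phantom, s, n_time=8, dwell_s=DWELL)
        voxels = ft_mrs_reconstruct(kd)
        m0 = int(np.flatnonzero((s.k_coords == 0).all(axis=1))[0])
        total = voxels.fids.reshape(-1, 8, order="F").sum(axis=0)
        np.testing.assert_allclose(total, kd.data[0, m0], rtol=1e-10)

    def test_fractional_k_rejected(self, phantom):
        s = PhaseEncodeScheme(np.array([[0.5, 0.0, 0.0]]), np.array([1]), FOV, (8, 16, 8))
        kd = forward_encode(phantom, s, n_time=4, dwell_s=DWELL)
        with pytest.raises(ValueError, match="integer"):
            ft_mrs_reconstruct(kd)


class TestWsvd:
    def test_single_channel_pass_through(self, phantom, central_scheme):
        kd = forward_encode(phantom, central_scheme, n_time=8, dwell_s=DWELL)
        assert wsvd_combine(kd) is kd

    def test_zero_second_channel_recovers_first(self, phantom, central_scheme):
        kd = forward_encode(phantom, central_scheme, n_time=8, dwell_s=DWELL)
        stacked = KSpaceData(
            central_scheme,
            np.concatenate([kd.data, np.zeros_like(kd.data)]),
            DWELL,
        )
        comb = wsvd_combine(stacked, noise_cov=np.eye(2))
        np.testing.assert_allclose(comb.data[0], kd.data[0], rtol=1e-10)

    def test_identical_channels_gain_sqrt2_snr(self, phantom, central_scheme):
        rng = np.random.default_rng(5)
        kd = forward_encode(phantom, central_scheme, n_time=32, dwell_s=DWELL)
        signal = kd.data[0]
        gains = []
        for _ in range(60):
            noise = lambda: (rng.standard_normal(signal.shape) + 1j * rng.standard_normal(signal.shape)) * 2.0
            two = KSpaceData(central_scheme, np.stack([signal + noise(), signal + noise()]), DWELL)
            comb = wsvd_combine(two, noise_cov=np.eye(2))
            # project onto the known signal to split signal/noise
            s_hat = np.vdot(signal, comb.data[0]) / np.vdot(signal, signal)
            resid = comb.data[0] - s_hat * signal
            snr = np.abs(s_hat) * np.linalg.norm(signal) / np.linalg.norm(resid)
            one = KSpaceData(central_scheme, (signal + noise())[None], DWELL)
            s1 = np.vdot(signal, one.data[0]) / np.vdot(signal, signal)
            r1 = one.data[0] - s1 * signal
            gains.append(snr / (np.abs(s1) * np.linalg.norm(signal) / np.linalg.norm(r1)))
        assert np.mean(gains) == pytest.approx(np.sqrt(2), rel=0.05)

    def test_non_positive_definite_covariance_rejected(self, phantom, central_scheme):
        kd = forward_encode(phantom, central_scheme, n_time=8, dwell_s=DWELL)
        stacked = KSpaceData(central_scheme, np.concatenate([kd.data, kd.data]), DWELL)
        with pytest.raises(ValueError):
            wsvd_combine(stacked, noise_cov=np.array([[1.0, 2.0], [2.0, 1.0]]))
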