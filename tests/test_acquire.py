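"""K-space acquisition: excitation profile, phase models, encoding."""

import warnings

import numpy as np
import pytest

import dpgre
from dpgre.acquire import encode_partition, load_acquisition, save_acquisition
from dpgre.errors import ConfigurationError
from dpgre.fourier import cfft2, icfft2
from dpgre.recon import hamming_apodize, nav_to_image


class TestReducedFovProfile:
    def test_full_fov_is_all_ones(self):
        np.testing.assert_array_equal(dpgre.reduced_fov_profile(64, 1.0, "ideal"), 1.0)

    def test_quarter_fov_is_sixteen_centred_ones(self):
        p = dpgre.reduced_fov_profile(64, 0.25, "ideal")
        assert p.sum() == 16
        assert np.all(p[24:40] == 1.0) and p[23] == 0.0 and p[40] == 0.0

    @pytest.mark.parametrize("frac", [0.0, 1.5, -0.2])
    def test_invalid_fraction_rejected(self, frac):
        with pytest.raises(ValueError):
            dpgre.reduced_fov_profile(64, frac)

    def test_sinc_profile_matches_small_tip_bloch_integration(self):
        """The Fourier-transform profile of the Hamming-windowed sinc pulse
        agrees with a hard-pulse Bloch integration at small flip, and has a
        flat passband with a suppressed stopband."""
        ny, frac = 128, 0.4
        profile = dpgre.reduced_fov_profile(ny, frac, "sinc")

        tbw, nt, flip = 12.0, 400, np.deg2rad(5.0)
        tau = (np.arange(nt) + 0.5) / nt - 0.5
        b1 = np.hamming(nt) * np.sinc(tbw * tau)
        alphas = flip * b1 / b1.sum()          # per-sample nutation
        width = frac * ny
        u = (np.arange(ny) - ny // 2) / width  # slab-normalized position
        oracle = np.empty(ny)
        for i, ui in enumerate(u):
            dpsi = 2.0 * np.pi * tbw * ui / nt  # off-resonance per sample
            m = np.array([0.0, 0.0, 1.0])
            for a in alphas:
                ca, sa = np.cos(a), np.sin(a)
                m = np.array([m[0], ca * m[1] + sa * m[2], -sa * m[1] + ca * m[2]])
                cp, sp = np.cos(dpsi), np.sin(dpsi)
                m = np.array([cp * m[0] - sp * m[1], sp * m[0] + cp * m[1], m[2]])
            oracle[i] = np.hypot(m[0], m[1])
        oracle /= oracle[ny // 2]

        np.testing.assert_allclose(profile, oracle, atol=5e-3)
        passband = np.abs(u) <= 0.35
        stopband = np.abs(u) >= 0.75
        assert abs(profile[passband].mean() - 1.0) < 0.01
        assert profile[stopband].mean() < 0.05


class TestCoilSensitivities:
    def test_single_coil_is_identity(self):
        np.testing.assert_array_equal(dpgre.make_coil_sens(1, (8, 8)), 1.0)

    def test_sum_of_squares_positive_everywhere(self):
        sens = dpgre.make_coil_sens(6, (32, 24), seed=2)
        assert np.all(np.sum(np.abs(sens) ** 2, axis=0) > 0)

    def test_deterministic_from_seed(self):
        a = dpgre.make_coil_sens(4, (16, 16), seed=9)
        b = dpgre.make_coil_sens(4, (16, 16), seed=9)
        np.testing.assert_array_equal(a, b)
        c = dpgre.make_coil_sens(4, (16, 16), seed=10)
        assert not np.array_equal(a, c)


class TestPhaseErrorModel:
    def test_reproducible_per_shot_key(self):
        pm = dpgre.PhaseErrorModel(kind="smooth", seed=4)
        a = pm.phase_map((0, 0, 3), (32, 32), nav_band_ky=7.0)
        b = pm.phase_map((0, 0, 3), (32, 32), nav_band_ky=7.0)
        c = pm.phase_map((0, 0, 4), (32, 32), nav_band_ky=7.0)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_smooth_field_is_band_limited(self):
        pm = dpgre.PhaseErrorModel(kind="smooth", smooth_cutoff_frac=0.5, seed=4)
        fld = pm.phase_map((0, 0, 0), (32, 32), nav_band_ky=7.0)
        spec = cfft2(fld)
        fy = np.abs(np.arange(32) - 16)
        out_of_band = spec[:, fy > 3.5]
        assert np.abs(out_of_band).max() < 1e-10 * np.abs(spec).max()
        assert fld.std() == pytest.approx(0.3, rel=1e-9)

    def test_linear_field_has_constant_and_gradient(self):
        pm = dpgre.PhaseErrorModel(kind="linear", seed=4)
        fld = pm.phase_map((0, 0, 0), (16, 16))
        gx = np.diff(fld, axis=0)
        assert np.allclose(gx, gx[0, 0])  # constant gradient
        assert np.abs(fld).max() <= np.pi + np.pi / 2  # offset + ramps bound

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigurationError):
            dpgre.PhaseErrorModel(kind="quadratic")


class TestSimulateAcquisition:
    def test_dc_sample_matches_brute_force_dft(self, small_volume, small_cfg):
        sens = dpgre.make_coil_sens(2, (16, 16), seed=3)
        acq = dpgre.simulate_acquisition(small_volume, small_cfg, coil_sens=sens, seed=0)
        sig0 = dpgre.forward_signal(small_volume, small_cfg, 0.0)
        nz = small_volume.grid_shape[2]
        for shot in (acq.shots_for(0.0)[0], acq.shots_for(0.0)[nz - 1]):
            kappa = shot.kz - nz // 2
            wz = np.exp(-2j * np.pi * kappa * (np.arange(nz) - nz // 2) / nz)
            for c in range(2):
                expected = np.sum(sens[c][..., None] * sig0 * wz)
                got = shot.kspace[c, small_cfg.lines_per_shot // 2, 16 // 2]
                assert got == pytest.approx(expected, rel=1e-10)

    def test_clean_navigator_phase_is_common_to_all_shots(self, small_volume, small_cfg):
        """Without intershot errors the navigator carries only a common-mode
        phase (object/coil phase plus the linear-order train-decay ramp),
        identical for every shot — so the conjugate correction cancels it
        and introduces no shot-to-shot inconsistency."""
        acq = dpgre.simulate_acquisition(small_volume, small_cfg, seed=0)
        navs = [
            nav_to_image(hamming_apodize(s.nav_kspace), (16, 16)).data
            for s in acq.shots_for(0.0)
        ]
        for nav in navs[1:]:
            np.testing.assert_array_equal(nav, navs[0])

    def test_pure_encoding_navigator_phase_is_zero_in_object(self):
        """With flat line weights (encoding only) and symmetric apodization
        (odd extents, window peak on the DC sample), the navigator of a
        real smooth object has vanishing phase inside the object."""
        nx, ny = 33, 32
        X = np.arange(nx) - nx // 2
        Y = np.arange(ny) - ny // 2
        obj = np.exp(-(X[:, None] ** 2 + Y[None, :] ** 2) / (2 * 5.0**2))
        F = cfft2(obj)
        nav_lines = 13
        rows = ny // 2 + (np.arange(nav_lines) - nav_lines // 2)
        nav_k = np.transpose(F[:, rows])[None]  # (1, nav_lines, nx)
        nav = nav_to_image(hamming_apodize(nav_k), (nx, ny)).data[0]
        mag = np.abs(nav)
        inside = mag > 0.3 * mag.max()
        assert np.abs(np.angle(nav[inside])).max() < 1e-8

    def test_constant_phase_error_passes_through_to_navigator(self, small_volume, small_cfg):
        pm = dpgre.PhaseErrorModel(kind="constant", seed=11)
        clean = dpgre.simulate_acquisition(small_volume, small_cfg, seed=0)
        err = dpgre.simulate_acquisition(small_volume, small_cfg, phase_model=pm, seed=0)
        s_c, s_e = clean.shots_for(0.0)[1], err.shots_for(0.0)[1]
        c = s_e.true_phase[0, 0]
        nav_c = nav_to_image(hamming_apodize(s_c.nav_kspace), (16, 16)).data[0]
        nav_e = nav_to_image(hamming_apodize(s_e.nav_kspace), (16, 16)).data[0]
        inside = np.abs(nav_c) > 0.5 * np.abs(nav_c).max()
        # image phase of the shot is -theta by the package's sign convention
        delta = np.angle(nav_e[inside] * np.conj(nav_c[inside]))
        np.testing.assert_allclose(delta, -c, atol=1e-6)

    def test_linearity_in_proton_density(self, small_volume, small_cfg):
        doubled = dpgre.TissueVolume(
            small_volume.grid_shape, small_volume.voxel_size_mm,
            2.0 * small_volume.pd, small_volume.t1_ms, small_volume.t2_ms,
            small_volume.adc_mm2_per_s, small_volume.labels,
        )
        a = dpgre.simulate_acquisition(small_volume, small_cfg, seed=0)
        b = dpgre.simulate_acquisition(doubled, small_cfg, seed=0)
        np.testing.assert_allclose(
            b.shots[0].kspace, 2.0 * a.shots[0].kspace, rtol=1e-12, atol=1e-14
        )

    def test_shot_order_does_not_change_kspace(self, small_volume, small_cfg):
        pm = dpgre.PhaseErrorModel(kind="smooth", seed=7)
        rng = np.random.default_rng(1)
        n_shots = sum(small_cfg.averages) * small_cfg.n_partitions
        perm = rng.permutation(n_shots)
        a = dpgre.simulate_acquisition(
            small_volume, small_cfg, phase_model=pm, noise_sigma=1e-4, seed=3
        )
        b = dpgre.simulate_acquisition(
            small_volume, small_cfg, phase_model=pm, noise_sigma=1e-4, seed=3,
            shot_order=perm,
        )
        for sa, sb in zip(a.shots, b.shots):
            np.testing.assert_array_equal(sa.kspace, sb.kspace)
            np.testing.assert_array_equal(sa.nav_kspace, sb.nav_kspace)

    def test_noise_scale_is_relative_to_dc(self, small_volume, small_cfg):
        sigma = 1e-3
        clean = dpgre.simulate_acquisition(small_volume, small_cfg, seed=2)
        noisy = dpgre.simulate_acquisition(small_volume, small_cfg,
                                           noise_sigma=sigma, seed=2)
        # use the DC partition: its peak sample is the b0 DC reference
        nz = small_volume.grid_shape[2]
        s_c = clean.shots_for(0.0)[nz // 2]
        s_n = noisy.shots_for(0.0)[nz // 2]
        assert s_c.kz == nz // 2
        dc = np.abs(s_c.kspace).max()
        resid = s_n.kspace - s_c.kspace
        measured = resid.real.std()
        assert measured == pytest.approx(sigma * dc, rel=0.2)

    def test_grid_mismatch_rejected(self, small_volume):
        cfg = dpgre.SequenceConfig(lines_per_shot=12, n_partitions=4, nav_lines=6)
        with pytest.raises(ConfigurationError):
            dpgre.simulate_acquisition(small_volume, cfg)

    def test_wrap_warning_when_object_exceeds_reduced_fov(self, six_vial_adcs):
        vol = dpgre.make_vial_phantom(6, six_vial_adcs, grid_shape=(32, 32, 4))
        cfg = dpgre.SequenceConfig(lines_per_shot=16, n_partitions=4, nav_lines=6,
                                   averages=(1, 1))
        with pytest.warns(UserWarning, match="alias"):
            dpgre.simulate_acquisition(vol, cfg, fov_phase_fraction=1.0, seed=0)


class TestEncodingProperties:
    """Pure-encoding invariants, checked with unit line weights so the
    sequence's train decay does not enter."""

    @staticmethod
    def _confined_object(nx=16, ny=16, nz=4, inner=8, seed=0):
        rng = np.random.default_rng(seed)
        obj = np.zeros((nx, ny, nz), complex)
        lo = ny // 2 - inner // 2
        obj[:, lo : lo + inner, :] = rng.standard_normal((nx, inner, nz)) \
            + 1j * rng.standard_normal((nx, inner, nz))
        return obj

    def test_parseval_per_partition(self):
        obj = self._confined_object()
        plane = encode_partition(obj, kz_row=1)
        F = cfft2(plane)
        energy_k = (np.abs(F) ** 2).sum()
        energy_img = (np.abs(plane) ** 2).sum() * plane.size
        assert energy_k == pytest.approx(energy_img, rel=1e-12)

    def test_reduced_matrix_sampling_is_alias_free_for_confined_object(self):
        """Sampling every 2nd ky line of an object confined to the inner
        half FOV reconstructs exactly the central crop of the full-FOV
        image."""
        nx, ny, nz, ny_red = 16, 16, 4, 8
        obj = self._confined_object(nx, ny, nz, inner=ny_red)
        plane = encode_partition(obj, kz_row=2)
        F = cfft2(plane)
        cols = ny // 2 + 2 * (np.arange(ny_red) - ny_red // 2)
        img_red = icfft2(F[:, cols])
        crop = plane[:, ny // 2 - ny_red // 2 : ny // 2 + ny_red // 2]
        assert np.abs(img_red - crop).max() < 1e-6 * np.abs(crop).max()

    def test_partition_dc_row_is_slab_projection(self):
        obj = self._confined_object()
        np.testing.assert_allclose(
            encode_partition(obj, kz_row=obj.shape[2] // 2), obj.sum(axis=-1),
            atol=1e-12,
        )


class TestHdf5RoundTrip:
    def test_acquisition_survives_save_load(self, small_volume, small_cfg, tmp_path):
        pm = dpgre.PhaseErrorModel(kind="linear", seed=5)
        acq = dpgre.simulate_acquisition(
            small_volume, small_cfg,
            coil_sens=dpgre.make_coil_sens(2, (16, 16), seed=1),
            phase_model=pm, noise_sigma=1e-4, seed=6,
        )
        path = tmp_path / "acq.h5"
        save_acquisition(acq, path)
        back = load_acquisition(path)
        assert back.cfg == acq.cfg
        assert back.noise_sigma == acq.noise_sigma
        assert len(back.shots) == len(acq.shots)
        np.testing.assert_array_equal(back.coil_sens, acq.coil_sens)
        for sa, sb in zip(acq.shots, back.shots):
            assert (sa.kz, sa.b_value, sa.average_index) == (sb.kz, sb.b_value, sb.average_index)
            np.testing.assert_array_equal(sa.kspace, sb.kspace)
            np.testing.assert_array_equal(sa.nav_kspace, sb.nav_kspace)
            np.testing.assert_array_equal(sa.true_phase, sb.true_phase)
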