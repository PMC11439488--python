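"""Beamforming: apodizations, ESC, DAS point-spread, NSI null inversion."""

import numpy as np
import pytest
from scipy.signal import hilbert, resample_poly

import nsidoppler as nd
from conftest import WAVELENGTH, peak_cross_section


class TestApodizations:
    def test_four_element_triplet_construction(self):
        t = nd.make_apodizations(4, 0.1)
        np.testing.assert_allclose(t.w_zm, [1, 1, -1, -1])
        np.testing.assert_allclose(t.w_dc1, [1.1, 1.1, -0.9, -0.9])
        np.testing.assert_allclose(t.w_dc2, [-0.9, -0.9, 1.1, 1.1])

    def test_zero_offset_degenerates_to_signed_zm(self):
        t = nd.make_apodizations(8, 0.0)
        np.testing.assert_allclose(t.w_dc1, t.w_zm)
        np.testing.assert_allclose(t.w_dc2, -t.w_zm)

    @pytest.mark.parametrize("n,eps", [(4, 0.1), (10, 0.5), (64, 0.01)])
    def test_dc_sums_equal_n_times_offset(self, n, eps):
        t = nd.make_apodizations(n, eps)
        assert t.w_zm.sum() == pytest.approx(0.0, abs=1e-12)
        assert t.w_dc1.sum() == pytest.approx(n * eps)
        assert t.w_dc2.sum() == pytest.approx(n * eps)

    def test_odd_aperture_drops_center_and_stays_zero_mean(self):
        t = nd.make_apodizations(5, 0.1)
        assert t.w_zm[2] == 0.0 and t.w_dc1[2] == 0.0
        assert t.w_zm.sum() == pytest.approx(0.0, abs=1e-12)

    def test_negative_offset_rejected(self):
        with pytest.raises(ValueError):
            nd.make_apodizations(4, -0.1)


class TestESC:
    def test_unit_profile_is_identity(self, point_acq):
        prof = nd.SensitivityProfile(s_d=np.ones(128), s_s=np.ones(128))
        out = nd.esc_correct(point_acq, prof)
        np.testing.assert_array_equal(out.rf, point_acq.rf)
        assert out.esc_applied

    def test_constant_profile_scales(self, point_acq):
        prof = nd.SensitivityProfile(s_d=np.full(128, 4.0), s_s=np.full(128, 2.0))
        out = nd.esc_correct(point_acq, prof)
        np.testing.assert_allclose(out.rf, point_acq.rf / 2.0, rtol=1e-6)

    def test_wrong_length_profile_rejected(self, point_acq):
        prof = nd.SensitivityProfile(s_d=np.ones(64), s_s=np.ones(64))
        with pytest.raises(ValueError, match="elements"):
            nd.esc_correct(point_acq, prof)

    def test_recovery_equalizes_channel_peaks_within_2pct(self):
        """Measured profile correction removes simulated {0.8, 1.0, 1.2}
        receive gains: broadside point-target envelope peaks equalize."""
        gains = np.tile([0.8, 1.0, 1.2], 43)[:128]
        geom = nd.ArrayGeometry(true_sensitivity=gains)
        params = nd.AcquisitionParams(n_frames=1, angles_deg=[0.0])
        scene = nd.make_scene("bubble_trace", n_frames=1, z0=5e-3, velocity=0.0)
        acq = nd.simulate_channel_data(scene, geom, params)
        prof = nd.simulate_element_measurement(geom)
        corr = nd.esc_correct(acq, prof)
        up = resample_poly(corr.rf[:, :, 0, 0].astype(float), 8, 1, axis=0)
        peaks = np.abs(hilbert(up, axis=0)).max(axis=0)[32:96]
        assert (peaks.max() - peaks.min()) / peaks.mean() <= 0.02


class TestDAS:
    def test_zero_rf_gives_zero_iq(self, point_acq, point_grid):
        zero = nd.PlaneWaveAcquisition(
            rf=np.zeros_like(point_acq.rf),
            geometry=point_acq.geometry,
            params=point_acq.params,
        )
        stack = nd.das_beamform(zero, point_grid)
        assert np.all(stack.iq == 0)

    def test_point_localized_within_one_pixel(self, das_point_stack, point_grid):
        env = np.abs(das_point_stack.iq[:, :, 0])
        iz, ix = np.unravel_index(env.argmax(), env.shape)
        assert abs(point_grid.x_coords[ix] - 0.0) <= np.diff(point_grid.x_coords)[0]
        assert abs(point_grid.z_coords[iz] - 5e-3) <= np.diff(point_grid.z_coords)[0]

    def test_lateral_fwhm_matches_diffraction_limit(self, das_point_stack):
        """Amplitude PSF width ~= 1.21 lambda F# for a rect aperture at F#=1
        (the PD/intensity width is narrower by sqrt-of-square)."""
        pd = nd.power_doppler(das_point_stack, "das")
        pos, amps = peak_cross_section(pd)
        width = nd.fwhm(amps, pos[1] - pos[0])
        assert width == pytest.approx(0.886 * WAVELENGTH * 1e6, rel=0.15)

    def test_beamforming_is_linear(self, point_acq, point_grid):
        a = point_acq
        rf2 = 2.0 * a.rf[:, :, :, :2]
        acq2 = nd.PlaneWaveAcquisition(rf=rf2, geometry=a.geometry, params=_clip(a, 2))
        acq1 = nd.PlaneWaveAcquisition(
            rf=a.rf[:, :, :, :2], geometry=a.geometry, params=_clip(a, 2)
        )
        s1 = nd.das_beamform(acq1, point_grid)
        s2 = nd.das_beamform(acq2, point_grid)
        np.testing.assert_allclose(s2.iq, 2.0 * s1.iq, rtol=1e-4, atol=1e-5)

    def test_output_invariant_to_lateral_interp_at_shared_pixels(self, point_acq):
        g2 = nd.BeamGrid.for_region(
            (-0.4e-3, 0.4e-3), (4.8e-3, 5.2e-3), point_acq.geometry.pitch,
            lateral_interp_factor=2, axial_pixel=WAVELENGTH / 8,
        )
        g4 = nd.BeamGrid.for_region(
            (-0.4e-3, 0.4e-3), (4.8e-3, 5.2e-3), point_acq.geometry.pitch,
            lateral_interp_factor=4, axial_pixel=WAVELENGTH / 8,
        )
        s2 = nd.das_beamform(point_acq, g2)
        s4 = nd.das_beamform(point_acq, g4)
        shared = np.isin(np.round(g4.x_coords * 1e9), np.round(g2.x_coords * 1e9))
        np.testing.assert_allclose(s4.iq[:, shared], s2.iq, rtol=1e-5, atol=1e-6)


def _clip(acq, n):
    p = acq.params
    return nd.AcquisitionParams(
        sampling_rate=p.sampling_rate, sound_speed=p.sound_speed,
        angles_deg=p.angles_deg, prf=p.prf, n_frames=n,
        transmit_frequency=p.transmit_frequency, n_samples=acq.n_samples,
    )


class TestNSI:
    def test_zm_null_at_least_20db_below_dc1_peak(self, nsi_point_stacks, point_grid):
        zm, dc1, _ = nsi_point_stacks
        e_zm = np.abs(zm.iq[:, :, 0])
        e_dc1 = np.abs(dc1.iq[:, :, 0])
        iz = e_dc1.max(axis=1).argmax()
        ix0 = np.argmin(np.abs(point_grid.x_coords))
        null_db = 20 * np.log10(e_zm[iz, ix0] / e_dc1[iz].max())
        assert null_db <= -20.0

    def test_zm_stack_independent_of_offset(self, point_acq, point_grid, nsi_point_stacks):
        zm2, _, _ = nd.nsi_beamform(point_acq, point_grid, dc_offset=0.2)
        np.testing.assert_array_equal(zm2.iq, nsi_point_stacks[0].iq)

    def test_unit_offset_dc1_is_uniform_plus_zm(self, point_acq):
        """At eps=1 the DC1 weighting is ZM + uniform, so the beams add.

        Checked on a single-row grid (no axial analytic transform coupling
        rows) at pixels whose dynamic aperture holds an even element count;
        odd apertures drop the center element in the NSI weightings only."""
        geom = point_acq.geometry
        grid = nd.BeamGrid(
            x_coords=np.arange(-0.8e-3, 0.81e-3, geom.pitch / 4),
            z_coords=np.array([5e-3]),
        )
        zm, dc1, _ = nd.nsi_beamform(point_acq, grid, dc_offset=1.0)
        uni = nd.das_beamform(point_acq, grid, "uniform")
        half = grid.z_coords[0] / (2.0 * grid.f_number)
        e_lo = np.maximum(
            np.ceil((grid.x_coords - half - geom.element_x[0]) / geom.pitch - 1e-9), 0
        )
        e_hi = np.minimum(
            np.floor((grid.x_coords + half - geom.element_x[0]) / geom.pitch + 1e-9),
            geom.n_elements - 1,
        )
        even = (e_hi - e_lo + 1) % 2 == 0
        expected = (uni.iq + zm.iq)[0, even]
        scale = np.abs(expected).max()
        np.testing.assert_allclose(dc1.iq[0, even], expected, atol=1e-4 * scale)

    def test_no_esc_under_inhomogeneity_degrades_null(
        self, inhomogeneous_geometry, point_grid
    ):
        """+-20% gain spread fills the ZM null unless ESC restores it."""
        params = nd.AcquisitionParams(n_frames=1)
        scene = nd.make_scene("bubble_trace", n_frames=1, z0=5e-3, velocity=0.0)
        acq = nd.simulate_channel_data(scene, inhomogeneous_geometry, params)
        prof = nd.simulate_element_measurement(inhomogeneous_geometry)

        def null_db(a):
            zm, dc1, _ = nd.nsi_beamform(a, point_grid, dc_offset=0.1)
            e_zm = np.abs(zm.iq[:, :, 0])
            e_dc1 = np.abs(dc1.iq[:, :, 0])
            iz = e_dc1.max(axis=1).argmax()
            ix0 = np.argmin(np.abs(point_grid.x_coords))
            return 20 * np.log10(e_zm[iz, ix0] / e_dc1[iz].max())

        assert null_db(acq) - null_db(nd.esc_correct(acq, prof)) >= 10.0


class TestNSICombine:
    def test_formula(self):
        out = nd.nsi_combine(np.ones((2, 2)), 3 * np.ones((2, 2)), 3 * np.ones((2, 2)))
        np.testing.assert_allclose(out, 2.0)

    def test_clips_to_zero_when_zm_dominates(self):
        out = nd.nsi_combine(np.full((3, 3), 5.0), np.ones((3, 3)), np.ones((3, 3)))
        np.testing.assert_array_equal(out, 0.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            nd.nsi_combine(np.ones((2, 2)), np.ones((2, 3)), np.ones((2, 2)))

    def test_normalization_by_twice_offset(self):
        out = nd.nsi_combine(
            np.zeros((2, 2)), np.ones((2, 2)), np.ones((2, 2)),
            dc_offset=0.1, normalize=True,
        )
        np.testing.assert_allclose(out, 5.0)


class TestResolutionVsOffset:
    def test_smaller_offset_gives_narrower_combined_psf(
        self, point_acq, point_grid, nsi_point_stacks
    ):
        def combined_fwhm(stacks):
            pd = nd.power_doppler(stacks, "nsi")
            pos, amps = peak_cross_section(pd)
            return nd.fwhm(amps, pos[1] - pos[0])

        wide = combined_fwhm(nd.nsi_beamform(point_acq, point_grid, dc_offset=1.0))
        narrow = combined_fwhm(nsi_point_stacks)  # eps = 0.1
        assert narrow < wide

    def test_nsi_psf_at_most_half_of_das(self, nsi_point_stacks, das_point_stack):
        pd_nsi = nd.power_doppler(nsi_point_stacks, "nsi")
        pd_das = nd.power_doppler(das_point_stack, "das")
        pos_n, amps_n = peak_cross_section(pd_nsi)
        pos_d, amps_d = peak_cross_section(pd_das)
        w_nsi = nd.fwhm(amps_n, pos_n[1] - pos_n[0])
        w_das = nd.fwhm(amps_d, pos_d[1] - pos_d[0])
        assert w_nsi <= 0.5 * w_das
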