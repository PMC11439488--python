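"""SVD clutter filtering: Casorati constructions, banding, blockwise blending."""

import numpy as np
import pytest

import nsidoppler as nd


def _stack(n_z=10, n_x=5, n_f=7, label="uniform", seed=0):
    rng = np.random.default_rng(seed)
    grid = nd.BeamGrid(
        x_coords=np.arange(n_x) * 25e-6,
        z_coords=np.arange(n_z) * 12.5e-6 + 4e-3,
    )
    iq = rng.normal(size=(n_z, n_x, n_f)) + 1j * rng.normal(size=(n_z, n_x, n_f))
    return nd.IQStack(iq=iq, apodization_label=label, grid=grid)


class TestCasorati:
    def test_postbf_das_dimensions(self):
        m = nd.build_casorati(_stack(10, 5, 7), "postbf_das")
        assert m.data.shape == (50, 7)

    def test_postbf_nsi_is_three_times_taller(self):
        stacks = tuple(_stack(10, 5, 7, lbl, seed=i) for i, lbl in enumerate(["ZM", "DC1", "DC2"]))
        m = nd.build_casorati(stacks, "postbf_nsi")
        assert m.data.shape == (150, 7)

    def test_round_trip_bit_identical(self):
        stacks = tuple(_stack(6, 4, 5, lbl, seed=i) for i, lbl in enumerate(["ZM", "DC1", "DC2"]))
        out = nd.invert_casorati(nd.build_casorati(stacks, "postbf_nsi"))
        for a, b in zip(stacks, out):
            np.testing.assert_array_equal(a.iq, b.iq)
            assert a.apodization_label == b.apodization_label

    def test_prebf_round_trip(self):
        rf = np.random.default_rng(1).normal(size=(30, 8, 6))
        m = nd.build_casorati(rf, "prebf_angle", angle_index=3)
        assert m.data.shape == (240, 6)
        np.testing.assert_array_equal(nd.invert_casorati(m), rf)

    def test_inconsistent_stack_shapes_rejected(self):
        stacks = (_stack(6, 4, 5, "ZM"), _stack(6, 4, 5, "DC1"), _stack(7, 4, 5, "DC2"))
        with pytest.raises(ValueError, match="shape"):
            nd.build_casorati(stacks, "postbf_nsi")


class TestSVDFilter:
    def test_full_band_is_identity(self):
        m = nd.build_casorati(_stack(12, 6, 8), "postbf_das")
        out = nd.svd_filter(m, nd.FilterBand(1, 8))
        np.testing.assert_allclose(out.data, m.data, rtol=0, atol=1e-6 * np.abs(m.data).max())

    def test_rank1_static_clutter_suppressed_40db(self):
        """Static clutter 40 dB above a moving component: removing the first
        singular component leaves residual static energy <= -40 dB."""
        rng = np.random.default_rng(2)
        n_space, n_f = 400, 16
        u = rng.normal(size=n_space)
        u /= np.linalg.norm(u)
        clutter = 100.0 * np.outer(u, np.ones(n_f))  # 40 dB amplitude ratio
        flow = np.zeros((n_space, n_f))
        for j in range(n_f):  # moving bump
            flow[(20 + 10 * j) % n_space : (20 + 10 * j) % n_space + 8, j] = 1.0
        m = nd.CasoratiMatrix(data=clutter + flow, mode="postbf_das")
        out = nd.svd_filter(m, nd.FilterBand(2, n_f))
        residual_static = u @ out.data  # projection on the clutter direction
        ratio_db = 10 * np.log10(
            np.sum(residual_static**2) / np.sum((u @ clutter) ** 2)
        )
        assert ratio_db <= -40.0

    def test_parseval_energy_of_retained_band(self):
        m = nd.build_casorati(_stack(15, 5, 10, seed=4), "postbf_das")
        sv = np.linalg.svd(m.data, compute_uv=False)
        out = nd.svd_filter(m, nd.FilterBand(3, 7))
        assert np.linalg.norm(out.data) ** 2 == pytest.approx(
            np.sum(sv[2:7] ** 2), rel=1e-9
        )

    def test_identical_stacks_stay_identical_through_nsi_filter(self):
        s = _stack(8, 4, 6, "ZM", seed=5)
        stacks = tuple(
            nd.IQStack(iq=s.iq.copy(), apodization_label=l, grid=s.grid)
            for l in ["ZM", "DC1", "DC2"]
        )
        m = nd.build_casorati(stacks, "postbf_nsi")
        out = nd.invert_casorati(nd.svd_filter(m, nd.FilterBand(2, 4)))
        np.testing.assert_allclose(out[0].iq, out[1].iq, atol=1e-12)
        np.testing.assert_allclose(out[0].iq, out[2].iq, atol=1e-12)

    def test_nonfinite_input_rejected(self):
        data = np.ones((10, 4))
        data[3, 2] = np.nan
        m = nd.CasoratiMatrix(data=data, mode="postbf_das")
        with pytest.raises(ValueError, match="finite"):
            nd.svd_filter(m, nd.FilterBand(1, 4))


class TestAdaptiveBand:
    def test_constructed_knee_found_within_one(self):
        """Two log-linear decay segments joined at index 5 put the knee there."""
        idx = np.arange(1, 21)
        logs = np.where(idx <= 5, 6.0 - 1.0 * idx, 1.5 - 0.1 * idx)
        band = nd.adaptive_band(10.0**logs)
        assert abs(band.low_cut - 5) <= 1

    def test_plateau_onset_sets_high_cut(self):
        sv = np.concatenate([10.0 ** np.linspace(4, 1, 10), np.full(10, 10.0)])
        band = nd.adaptive_band(np.sort(sv)[::-1])
        assert 9 <= band.high_cut <= 12

    def test_all_equal_values_fall_back_to_default(self):
        band = nd.adaptive_band(np.ones(10), default_band=nd.FilterBand(2, 6))
        assert (band.low_cut, band.high_cut) == (2, 6)

    def test_explicit_overrides_win(self):
        idx = np.arange(1, 21)
        sv = 10.0 ** np.where(idx <= 5, 6.0 - idx, 1.5 - 0.1 * idx)
        band = nd.adaptive_band(sv, low_cut=3, high_cut=11)
        assert (band.low_cut, band.high_cut) == (3, 11)

    def test_too_few_values_rejected_without_fallback(self):
        with pytest.raises(ValueError, match="at least 4"):
            nd.adaptive_band([3.0, 2.0, 1.0])

    def test_increasing_values_rejected(self):
        with pytest.raises(ValueError, match="non-increasing"):
            nd.adaptive_band([1.0, 2.0, 3.0, 4.0, 5.0])


@pytest.fixture(scope="module")
def static_acq(geometry):
    params = nd.AcquisitionParams(n_frames=6, angles_deg=[-2.0, 0.0, 2.0])
    scene = nd.make_scene(
        "clutter_phantom", seed=3, n_frames=6, clutter_density=0.5,
        clutter_amplitude=1.0, x_limits=(-2e-3, 2e-3), z_limits=(4e-3, 6e-3),
    )
    return nd.simulate_channel_data(scene, geometry, params)


class TestPreBF:
    def test_static_scene_energy_removed(self, static_acq):
        out = nd.prebf_filter(static_acq, nd.FilterBand(2, 6))
        assert np.sum(out.rf.astype(float) ** 2) <= 0.01 * np.sum(
            static_acq.rf.astype(float) ** 2
        )

    def test_full_band_is_identity(self, static_acq):
        out = nd.prebf_filter(static_acq, nd.FilterBand(1, 6))
        np.testing.assert_allclose(
            out.rf, static_acq.rf, atol=1e-5 * np.abs(static_acq.rf).max()
        )

    def test_commutes_with_channel_scaling(self, static_acq):
        scaled = nd.PlaneWaveAcquisition(
            rf=3.0 * static_acq.rf, geometry=static_acq.geometry, params=static_acq.params
        )
        a = nd.prebf_filter(scaled, nd.FilterBand(2, 5))
        b = nd.prebf_filter(static_acq, nd.FilterBand(2, 5))
        np.testing.assert_allclose(
            a.rf, 3.0 * b.rf, rtol=0, atol=1e-6 * np.abs(scaled.rf).max()
        )


class TestBlockwise:
    def test_step_arithmetic_100px_90pct_overlap(self):
        from nsidoppler.clutter import _block_starts

        starts = _block_starts(300, 100, 10)
        assert starts[1] - starts[0] == 10
        assert starts[0] == 0 and starts[-1] == 200

    def test_single_block_equals_global_filter(self):
        s = _stack(20, 6, 8, seed=6)
        global_out = nd.invert_casorati(
            nd.svd_filter(nd.build_casorati(s, "postbf_das"), nd.FilterBand(2, 6))
        )
        block_out = nd.blockwise_filter(s, block_px=20, overlap=0.0, band=nd.FilterBand(2, 6))
        np.testing.assert_allclose(block_out.iq, global_out.iq, atol=1e-10)

    def test_full_band_blockwise_is_identity(self):
        """Overlapping full-band (identity) blocks must blend back to the
        input exactly -- the blend weights form a partition of unity."""
        s = _stack(50, 4, 5, seed=7)
        out = nd.blockwise_filter(s, block_px=16, overlap=0.75, band=nd.FilterBand(1, 5))
        np.testing.assert_allclose(out.iq, s.iq, atol=1e-9)

    def test_oversized_block_clamped_to_image(self):
        s = _stack(12, 4, 5, seed=8)
        out = nd.blockwise_filter(s, block_px=100, overlap=0.9, band=nd.FilterBand(1, 5))
        np.testing.assert_allclose(out.iq, s.iq, atol=1e-9)


class TestStandardSceneSuppression:
    """On the clutter scene (static field 40 dB above two bubbles + noise)
    every filter construction leaves the bubble traces as the PD maxima."""

    def _max_on_trace(self, pd_img, grid):
        iz, ix = np.unravel_index(pd_img.power.argmax(), pd_img.power.shape)
        x, z = grid.x_coords[ix], grid.z_coords[iz]
        travel = 2e-3 * 63 / 1000.0
        return abs(abs(x) - 50e-6) < 40e-6 and (5e-3 - travel - 1e-4) < z < (5e-3 + travel + 1e-4)

    def test_postbf_das(self, clutter_das_stack, clutter_grid):
        m = nd.build_casorati(clutter_das_stack, "postbf_das")
        out = nd.invert_casorati(nd.svd_filter(m, "auto"))
        assert self._max_on_trace(nd.power_doppler(out, "das"), clutter_grid)

    def test_blockwise_das(self, clutter_das_stack, clutter_grid):
        out = nd.blockwise_filter(clutter_das_stack, block_px=40, overlap=0.75, band="auto")
        assert self._max_on_trace(nd.power_doppler(out, "das"), clutter_grid)

    def test_prebf_das(self, clutter_acq, clutter_grid):
        filtered = nd.prebf_filter(clutter_acq, "auto")
        stack = nd.das_beamform(filtered, clutter_grid, "uniform")
        assert self._max_on_trace(nd.power_doppler(stack, "das"), clutter_grid)

    def test_postbf_nsi(self, clutter_acq, clutter_grid):
        stacks = nd.nsi_beamform(clutter_acq, clutter_grid, dc_offset=0.1)
        m = nd.build_casorati(stacks, "postbf_nsi")
        out = nd.invert_casorati(nd.svd_filter(m, "auto"))
        assert self._max_on_trace(nd.power_doppler(out, "nsi", 0.1), clutter_grid)
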