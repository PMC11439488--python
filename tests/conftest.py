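"""Shared fixtures: small in-silico acquisitions reused across the suite.

Beamforming is the expensive step, so the point-target and clutter-scene
acquisitions and their beamformed stacks are session-scoped.
"""

import numpy as np
import pytest

import nsidoppler as nd

WAVELENGTH = 1540.0 / 15.625e6  # imaging wavelength, ~98.6 um


@pytest.fixture(scope="session")
def geometry():
    return nd.ArrayGeometry()


@pytest.fixture(scope="session")
def point_acq(geometry):
    """Static point scatterer at (0, 5 mm), 9 angles, 8 frames, noiseless."""
    params = nd.AcquisitionParams(n_frames=8)
    scene = nd.make_scene("bubble_trace", n_frames=8, z0=5e-3, velocity=0.0)
    return nd.simulate_channel_data(scene, geometry, params)


@pytest.fixture(scope="session")
def point_grid(geometry):
    return nd.BeamGrid.for_region(
        (-0.8e-3, 0.8e-3),
        (4.55e-3, 5.45e-3),
        geometry.pitch,
        lateral_interp_factor=10,
        axial_pixel=WAVELENGTH / 8,
    )


@pytest.fixture(scope="session")
def das_point_stack(point_acq, point_grid):
    return nd.das_beamform(point_acq, point_grid, "uniform")


@pytest.fixture(scope="session")
def nsi_point_stacks(point_acq, point_grid):
    return nd.nsi_beamform(point_acq, point_grid, dc_offset=0.1)


@pytest.fixture(scope="session")
def inhomogeneous_geometry():
    """+-20% peak-to-peak receive-gain inhomogeneity (seeded)."""
    rng = np.random.default_rng(5)
    gains = 1.0 + 0.2 * (rng.random(128) - 0.5)
    return nd.ArrayGeometry(true_sensitivity=gains)


@pytest.fixture(scope="session")
def clutter_acq(geometry):
    """Standard clutter scene: two moving bubbles + static clutter 40 dB
    above them + channel noise."""
    params = nd.AcquisitionParams(n_frames=64, snr_db=60.0)
    scene = nd.make_scene(
        "trace_pair",
        seed=7,
        n_frames=64,
        z0=5e-3,
        separation=100e-6,
        velocity=2e-3,
        clutter_density=1.0,
        clutter_amplitude=100.0,
        x_limits=(-2e-3, 2e-3),
        z_limits=(4e-3, 6e-3),
    )
    return nd.simulate_channel_data(scene, geometry, params)


@pytest.fixture(scope="session")
def clutter_grid(geometry):
    return nd.BeamGrid.for_region(
        (-1e-3, 1e-3),
        (4.6e-3, 5.4e-3),
        geometry.pitch,
        lateral_interp_factor=4,
        axial_pixel=WAVELENGTH / 8,
    )


@pytest.fixture(scope="session")
def clutter_das_stack(clutter_acq, clutter_grid):
    return nd.das_beamform(clutter_acq, clutter_grid, "uniform")


def peak_cross_section(pd_image, n_points=801):
    """Lateral cross-section through the power maximum."""
    grid = pd_image.grid
    iz, _ = np.unravel_index(pd_image.power.argmax(), pd_image.power.shape)
    z = grid.z_coords[iz]
    pos, amps = nd.cross_section(
        pd_image, ((grid.x_coords[0], z), (grid.x_coords[-1], z)), n_points
    )
    return pos, amps
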