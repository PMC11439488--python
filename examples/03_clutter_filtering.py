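"""SVD clutter filtering on a tissue-mimicking scene.

Two moving microbubbles are buried under a static scatterer field 40 dB
stronger (tissue clutter) plus channel noise.  The adaptive singular-value
band removes the clutter subspace; the rendered power-Doppler image then
peaks on the bubble traces.
"""

import numpy as np

import nsidoppler as nd

geometry = nd.ArrayGeometry()
params = nd.AcquisitionParams(n_frames=64, snr_db=60.0)
scene = nd.make_scene(
    "trace_pair", seed=7, n_frames=64, z0=5e-3, separation=100e-6,
    velocity=2e-3, clutter_density=1.0, clutter_amplitude=100.0,
    x_limits=(-2e-3, 2e-3), z_limits=(4e-3, 6e-3),
)
acq = nd.simulate_channel_data(scene, geometry, params)

wavelength = params.sound_speed / params.transmit_frequency
grid = nd.BeamGrid.for_region(
    (-1e-3, 1e-3), (4.6e-3, 5.4e-3), geometry.pitch,
    lateral_interp_factor=4, axial_pixel=wavelength / 8,
)

config = nd.PipelineConfig(beamformer="das", filter="postbf", esc=False)
result = nd.run_pipeline(config, acq, grid)

iz, ix = np.unravel_index(result.pd.power.argmax(), result.pd.power.shape)
print(f"clutter level: 40 dB above the bubbles, {len(scene.static_scatterers)} static scatterers")
print(f"PD maximum at x = {grid.x_coords[ix] * 1e6:+.0f} um, "
      f"z = {grid.z_coords[iz] * 1e3:.2f} mm (bubbles at x = +/-50 um)")
print(f"adaptive dynamic range: {result.display.dr:.1f} dB "
      f"(sigma = {result.display.sigma_pixel:.1f}, mu = {result.display.mu_pixel:.1f})")
print()
print("Without the filter the static field would dominate the image by 40 dB;")
print("after removing the clutter singular components the moving bubbles are")
print("the brightest structures.")
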