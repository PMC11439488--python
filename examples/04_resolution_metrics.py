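"""Global resolution metrics: iso-frequency curves and the cutoff ratio.

Builds the 25-um trace-pair images for NSI and DAS, radially averages their
2-D Fourier magnitudes, fits decaying exponentials, and reads the
matched-amplitude spatial-frequency cutoff ratio at the half-wavelength
reference frequency.
"""

import nsidoppler as nd

geometry = nd.ArrayGeometry()
params = nd.AcquisitionParams(n_frames=64)
wavelength = params.sound_speed / params.transmit_frequency
scene = nd.make_scene("trace_pair", seed=1, n_frames=64, z0=5e-3,
                      separation=25e-6, velocity=2e-3)
acq = nd.simulate_channel_data(scene, geometry, params)
grid = nd.BeamGrid.for_region(
    (-0.4e-3, 0.4e-3), (4.87e-3, 5.23e-3), geometry.pitch,
    lateral_interp_factor=10, axial_pixel=wavelength / 8,
)

pd_nsi = nd.power_doppler(nd.nsi_beamform(acq, grid, 0.1), "nsi")
pd_das = nd.power_doppler(nd.das_beamform(acq, grid), "das")

curve_nsi = nd.iso_frequency_curve(pd_nsi)
curve_das = nd.iso_frequency_curve(pd_das)

f_half_wavelength = 1.0 / (wavelength / 2 * 1e3)  # 1/mm
ratio = nd.resolution_ratio(curve_das, curve_nsi, f_half_wavelength)

print(f"DAS iso-curve fit:  A = {curve_das.fit_amplitude:.3g}, "
      f"decay = {curve_das.fit_decay:.2f} mm")
print(f"NSI iso-curve fit:  A = {curve_nsi.fit_amplitude:.3g}, "
      f"decay = {curve_nsi.fit_decay:.2f} mm")
print(f"reference frequency (half wavelength): {f_half_wavelength:.1f} 1/mm")
print(f"matched-amplitude cutoff ratio NSI/DAS: {ratio.ratio:.2f}"
      + ("  (extrapolated)" if ratio.extrapolated else ""))
print()
print("A ratio above 1 means the NSI spectrum holds its amplitude out to")
print("higher spatial frequencies, i.e. finer structure survives in the image.")
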