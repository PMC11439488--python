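# Methods

This note documents the models, parameter choices and numerical decisions
behind `nsidoppler`, and what the in-silico validation does and does not
show about real acquisitions.

## Forward model (simulate)

The simulator implements a linear point-scatterer pulse-echo model for a
uniform linear array insonified by steered plane waves.  For a scatterer at
(x, z), steering angle θ and element at x_e, the echo arrives at

    τ = (z·cosθ + x·sinθ)/c + √((x − x_e)² + z²)/c

as a Gaussian-windowed sinusoid at the transmit frequency (a full-cycle
imaging pulse; −6 dB fractional bandwidth 0.6 by default, a config
parameter).  Defaults emulate a 128-element, 100-µm-pitch high-frequency
array (18.5 MHz element center frequency) driven at 15.625 MHz, sampled at
62.5 MHz, with nine plane waves at −4°…+4° in 1° steps and a 1000 Hz
post-compounding frame rate.  Sound speed defaults to 1540 m/s for imaging
scenes; 1480 m/s is the default for the water-tank sensitivity measurement
and selectable everywhere (the water-tank value for the trace experiment is
not pinned down, so it is a config key, not a constant).

Deliberate simplifications:

- **Receive-only inhomogeneity.**  Per-element gain inhomogeneity is
  applied on receive only; plane-wave transmits fire all elements jointly
  and are not element-weighted.  This makes the receive-path correction
  exactly recoverable and is the controlled condition the ESC tests need.
- **Linear scatterers.**  Microbubbles are linear point targets with
  prescribed trajectories; nonlinear oscillation, radiation-force dynamics,
  attenuation, element directivity and multiple scattering are out of
  scope.
- **Noise.**  White Gaussian, i.i.d. per sample/channel, with variance set
  by `snr_db` against the mean echo power of the central frame (unit power
  for an empty scene).  All randomness is seeded; identical parameters give
  bit-identical tensors.

### Scenes

`trace_pair` places the two descending bubbles at the requested lateral
separation with an axial stagger (default: half the travel distance).  Two
scatterers co-located in depth and separated laterally by a fraction of a
wavelength are coherently inseparable in a single frame by any receive
beamformer — their echoes differ by a negligible phase gradient.  What the
water-tank experiment actually exploits is that real bubbles pass a given
depth at different instants; the stagger reproduces exactly that: the
traces overlap in a common depth band, but the scatterers are never
coincident in time, so each frame contributes one well-isolated point image
per trace.  Cross-sections for resolvability tests are taken inside the
common band.

`clutter_phantom` (and the `clutter_density`/`clutter_amplitude` options of
every scene) adds a static uniformly distributed scatterer field; the
standard validation scene uses clutter 40 dB above the bubbles, which is
the regime where the clutter filter, not the beamformer, determines whether
flow is visible.

### Element sensitivity measurement

Each element individually transmits onto a planar reflector parallel to the
array and receives its own echo; the envelope peak is the two-way
sensitivity `s_d ∝ gain²`.  Under the stated assumption that transmit and
receive paths are identical, the single-path profile used for correction is
`s_s = √s_d`, normalized to mean 1.  (Taking the two-way amplitude itself
as the single-path sensitivity would over-correct receive-only data by the
gain squared; the square root is what makes the correction exact under the
equal-paths assumption, and the recovery tests confirm it to < 2 %.)

## Beamforming

Delay-and-sum with coherent compounding: per pixel and angle, the dynamic
receive aperture has half-width z/(2·F#) (F# = 1 by default, so the
aperture is as wide as the pixel is deep), truncated at the array edge with
the apodization regenerated at the truncated length.  Delays are evaluated
by linear interpolation on RF axially interpolated by a factor of 4
(polyphase resampling), which sets the delay accuracy.  The lateral pixel
pitch is the element pitch divided by the lateral interpolation factor
(1–10; small-structure studies use 10, i.e. 10 µm pixels); output is
invariant to this factor at shared pixel locations.  The analytic signal is
taken along the axial image dimension (Hilbert transform) after angle
compounding; the default axial pixel of λ/8 keeps the axial oscillation
well below Nyquist for the envelope.

NSI specifics:

- The subaperture carrying the ZM/DC1/DC2 weights **is** the dynamic
  F-number-limited aperture (consistent with the fixed F# = 1), not a fixed
  split of the full array.
- Odd aperture element counts drop the center element (weight 0 in all
  three weightings) so the ZM weighting stays exactly zero-mean; an exact
  null is worth half an element of aperture.
- All requested apodizations are accumulated in a single kernel pass
  (numba-compiled), so the three NSI stacks share every delay computation;
  plain DAS is the same kernel with a uniform weight.
- The combination clips negatives to zero (envelope semantics).  An
  optional normalization by 2ε puts sweeps over the offset on a common
  amplitude scale; it is off by default since the display is
  scale-invariant.

## Clutter filtering

Columns of the spatiotemporal (Casorati) matrix are vectorized slow-time
frames.  Tissue, flow and noise separate along the singular spectrum;
filtering keeps a 1-based index band [low_cut, high_cut] of the economy
SVD.  The NSI-aware construction concatenates the three apodization stacks
per frame into one column (3× the rows), filtering all three coherently
before the phase-destroying envelope combination.  Pre-beamforming
filtering operates on the real RF of each steering angle independently (no
analytic conversion first).  Slow-time mean removal is *not* applied; the
clutter subspace is left entirely to the band selection.

The adaptive band is a documented stand-in for decay-based threshold
selection (the cited art's exact formula is not restated here): low_cut at
the largest-curvature knee of the log singular-value decay, high_cut at the
noise-plateau onset (first local log-slope below 0.02 per index), both
overridable by explicit configuration, with a configurable default band for
degenerate spectra.  On clutter-free synthetic scenes the adaptive knee
would land inside the signal subspace, so such studies pass an explicit
full band — the filter stays in the chain, the cutoffs are configured.

The blockwise variant slides axial blocks (default 100 pixel rows, 90 %
overlap ⇒ 10-row step) spanning the full lateral width — clutter statistics
vary mainly with depth — and blends overlapping reconstructions with
triangular weights normalized to a partition of unity (strictly positive at
block edges so border pixels keep full weight).  A block covering the whole
image reduces exactly to the global filter.

## Power Doppler, equalization, display

DAS PD sums |IQ|² over frames; NSI PD combines the three envelopes per
frame, squares the combined envelope and sums — keeping both methods on the
same power-integration semantics.  Noise equalization divides the PD power
by the squared depth profile of the smallest-singular-component
reconstruction of the post-beamforming spatiotemporal matrix (lateral-and-
frame mean envelope, 32-pixel axial moving average, floored at machine
epsilon, min-normalized to 1).  The same post-beamforming reference is used
in every chain, including the pre-beamforming one — one extra economy SVD
buys a uniform, well-defined noise field.  Equalizing the accumulated power
by the squared profile is algebraically identical to equalizing each
frame's envelope before squaring, so the stage order (PD, then
equalization) matches the per-frame formulation.

Display: `db = 10·log10(power) − max` (intensity convention; power is a
squared quantity), zero pixels floored 120 dB below the maximum, and the
adaptive dynamic range `DR = α·σ_pixel + |µ_pixel|` computed over the dB
pixels (α = 1 for contrast-enhanced, 0.5 for contrast-free imaging); the
display clamps dB to [−DR, 0].

## Resolution metrics

FWHM uses the half-maximum crossings nearest the global peak with
sub-sample linear interpolation; a profile that never falls below half
maximum on one side is reported as *unresolved* (excluded and counted in
statistics, never silently numbered).  Multi-modal profiles are segmented
at inter-peak minima and measured per peak.  Two-trace resolvability is
operationalized as the inter-peak dip falling below half of the lower peak.

Iso-frequency curves radially bin the 2-D Fourier magnitude (bin width =
one spectral sample) and fit a single decaying exponential A·exp(−b·f) over
the band from the first bin above DC to where the curve first falls below
1 % of its maximum (stabilizing the fit away from the noise floor; a single
exponential without offset is used, the simplest model that matches the
observed decay).  By default the transform is taken of the linear power
image (config flag for the dB image), peak-normalized to unit maximum so
fitted amplitudes of different methods are on a common scale — the
matched-amplitude cutoff comparison is only meaningful between comparably
scaled images.  The cutoff ratio reads the reference fit's amplitude at the
reference frequency (half a wavelength for bubble-trace studies, one
wavelength for tissue studies) and solves the test fit for the frequency
reaching that amplitude; results outside the test fit's band are flagged as
extrapolated.

## Problem sizes

The validation suite runs at desk scale by design: 64–128 slow-time frames
(vs. thousands in a live acquisition), fields of view of one to a few
millimetres, and grids of order 10²×10² pixels.  These sizes keep every
study reproducible in minutes on one CPU while preserving the regimes that
matter (clutter 40 dB above flow, quarter-wavelength separations, ±20 %
element-gain spread).  Full acquisition-scale values (thousands of frames,
full-aperture fields of view) remain reachable through configuration.

## What passing tests do and do not show

The in-silico experiments validate the *processing chain*: that the null
inversion resolves quarter-wavelength structure when the effective
weighting is truly zero-mean, that ESC restores that condition under
realistic gain spread, that the three SVD constructions remove static
clutter 40 dB above flow, and that the metrics recover known analytic
widths.  They do not validate performance under tissue motion, nonlinear
bubble responses, reverberation clutter, aberration, or depth-dependent
attenuation — none of which the forward model contains.  In particular the
resolvability results assume scatterers that are sparse in time at any
given depth; dense, simultaneously flowing scatterers within a resolution
cell remain coherently mixed for NSI exactly as for DAS.

## Known limitations

- The adaptive band rule and the noise-equalization profile are documented
  stand-ins for cited art whose exact formulas are not restated here; both
  are fully overridable.
- NSI output amplitude depends on ε and is not calibrated to DAS amplitude;
  comparisons go through max-subtracted dB displays or normalized spectra.
- The Hilbert-based envelope assumes the axial pixel pitch resolves the RF
  oscillation (λ/8 default); very coarse axial grids would alias it.
- `PDImage.db`/`display` are filled in place by `render`; re-rendering with
  a different α overwrites them.
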