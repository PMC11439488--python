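"""Plane-wave RF channel-data simulation for microvessel power-Doppler studies.

The simulator produces raw channel data for a linear array insonifying point
scatterers with steered plane waves.  It is an in-silico analog of the
descending microbubble-trace water-tank experiment: a small number of
prescribed moving point targets (microbubbles pushed away from the
transducer), optionally embedded in a static high-amplitude scatterer field
(tissue-like clutter), with per-element receive-sensitivity inhomogeneity and
additive white channel noise.

The forward model is deliberately simple and exactly invertible where the
processing chain needs it to be:

* each scatterer at ``(x, z)`` insonified at steering angle ``theta``
  produces on element ``e`` an echo at delay
  ``tau = (z cos(theta) + x sin(theta))/c + sqrt((x - x_e)^2 + z^2)/c``;
* the echo waveform is a Gaussian-windowed sinusoid at the transmit
  frequency (a full-cycle imaging pulse);
* receive-path inhomogeneity multiplies each channel by the element's true
  sensitivity; the transmit side is NOT weighted (all elements fire jointly
  in a plane-wave transmit), so element sensitivity correction on receive is
  exactly recoverable;
* white Gaussian noise is added at a configured SNR relative to the mean
  echo power of the central frame.

Element directivity, attenuation, multiple scattering and nonlinear bubble
oscillation are outside the model; microbubbles are linear point scatterers
with prescribed trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import hilbert

__all__ = [
    "ArrayGeometry",
    "AcquisitionParams",
    "Scene",
    "PlaneWaveAcquisition",
    "SensitivityProfile",
    "make_scene",
    "simulate_channel_data",
    "simulate_element_measurement",
    "gaussian_pulse_sigma",
]


def gaussian_pulse_sigma(frequency: float, bandwidth_fraction: float) -> float:
    """Temporal std-dev (s) of a Gaussian envelope with the given -6 dB
    fractional bandwidth around ``frequency``."""
    if frequency <= 0 or bandwidth_fraction <= 0:
        raise ValueError("frequency and bandwidth_fraction must be positive")
    df = bandwidth_fraction * frequency
    return np.sqrt(2.0 * np.log(2.0)) / (np.pi * df)


@dataclass
class ArrayGeometry:
    """Linear-array geometry and per-element ground-truth receive gain.

    Defaults emulate a 128-element high-frequency linear array (100 um pitch,
    18.5 MHz element center frequency) driven below its center frequency.
    """

    n_elements: int = 128
    pitch: float = 100e-6
    center_frequency: float = 18.5e6
    bandwidth_fraction: float = 0.6
    true_sensitivity: np.ndarray | None = None
    element_x: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.n_elements < 2:
            raise ValueError("n_elements must be >= 2")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")
        self.element_x = (
            np.arange(self.n_elements) - (self.n_elements - 1) / 2.0
        ) * self.pitch
        if self.true_sensitivity is None:
            self.true_sensitivity = np.ones(self.n_elements)
        else:
            self.true_sensitivity = np.asarray(self.true_sensitivity, dtype=float)
            if self.true_sensitivity.shape != (self.n_elements,):
                raise ValueError("true_sensitivity must have one gain per element")
            if np.any(self.true_sensitivity <= 0):
                raise ValueError("true_sensitivity must be positive everywhere")

    @property
    def aperture_width(self) -> float:
        return self.n_elements * self.pitch


@dataclass
class AcquisitionParams:
    """Plane-wave acquisition parameters.

    ``prf`` is the post-compounding frame rate (one frame = one full sweep of
    all steering angles).  ``snr_db=None`` means a noiseless acquisition.
    """

    sampling_rate: float = 62.5e6
    sound_speed: float = 1540.0
    angles_deg: Sequence[float] = tuple(range(-4, 5))
    prf: float = 1000.0
    n_frames: int = 128
    transmit_frequency: float = 15.625e6
    snr_db: float | None = None
    n_samples: int | None = None

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if not np.all(np.isfinite(self.angles_deg)):
            raise ValueError("steering angles must be finite")
        if self.sampling_rate < 4.0 * self.transmit_frequency:
            raise ValueError(
                "sampling_rate must be at least 4x the transmit frequency "
                f"({self.sampling_rate:.3g} < 4*{self.transmit_frequency:.3g})"
            )
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.sound_speed <= 0 or self.prf <= 0:
            raise ValueError("sound_speed and prf must be positive")

    @property
    def n_angles(self) -> int:
        return len(self.angles_deg)

    @property
    def angles_rad(self) -> np.ndarray:
        return np.deg2rad(self.angles_deg)


@dataclass
class Scene:
    """Prescribed point-scatterer scene.

    ``scatterers`` holds moving targets as ``(trajectory, amplitude)`` pairs,
    where ``trajectory`` is an ``(n_frames, 2)`` array of ``(x, z)`` metres.
    ``static_scatterers`` is an ``(n, 3)`` array of ``(x, z, amplitude)`` for
    the static clutter field (empty when no clutter was requested); the echo
    of a static scatterer is identical in every frame.
    """

    scatterers: list[tuple[np.ndarray, float]]
    static_scatterers: np.ndarray
    seed: int
    kind: str
    x_limits: tuple[float, float]
    z_limits: tuple[float, float]
    clutter_spec: dict | None = None

    @property
    def n_frames(self) -> int:
        if not self.scatterers:
            return 0
        return int(self.scatterers[0][0].shape[0])


@dataclass
class PlaneWaveAcquisition:
    """Raw (or sensitivity-corrected) RF channel data plus metadata.

    ``rf`` has shape ``(n_samples, n_elements, n_angles, n_frames)``.
    """

    rf: np.ndarray
    geometry: ArrayGeometry
    params: AcquisitionParams
    esc_applied: bool = False

    def __post_init__(self) -> None:
        expected = (self.geometry.n_elements, self.params.n_angles, self.params.n_frames)
        if self.rf.ndim != 4 or self.rf.shape[1:] != expected:
            raise ValueError(
                f"rf tensor shape {self.rf.shape} inconsistent with geometry/params "
                f"(expected (n_samples, {expected[0]}, {expected[1]}, {expected[2]}))"
            )
        if not np.all(np.isfinite(self.rf)):
            raise ValueError("rf tensor contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.rf.shape[0]


@dataclass
class SensitivityProfile:
    """Measured per-element sensitivity.

    ``s_d`` is the two-way (pulse-echo, same element transmits and receives)
    envelope-peak amplitude; ``s_s`` the derived single-path sensitivity used
    for receive-channel correction, normalized to mean 1.
    """

    s_d: np.ndarray
    s_s: np.ndarray
    transmit_voltage_tag: str = ""

    def __post_init__(self) -> None:
        self.s_d = np.asarray(self.s_d, dtype=float)
        self.s_s = np.asarray(self.s_s, dtype=float)
        if self.s_d.shape != self.s_s.shape:
            raise ValueError("s_d and s_s must have the same length")
        if np.any(self.s_s <= 0):
            raise ValueError("single-path sensitivity must be positive everywhere")


# ---------------------------------------------------------------------------
# Scene construction


def _check_inside(traj: np.ndarray, x_limits, z_limits, label: str) -> None:
    x, z = traj[:, 0], traj[:, 1]
    if x.min() < x_limits[0] or x.max() > x_limits[1] or z.min() < z_limits[0] or z.max() > z_limits[1]:
        raise ValueError(
            f"{label} leaves the imaging field: x in [{x.min():.2e}, {x.max():.2e}] m, "
            f"z in [{z.min():.2e}, {z.max():.2e}] m, allowed x in "
            f"[{x_limits[0]:.2e}, {x_limits[1]:.2e}], z in [{z_limits[0]:.2e}, {z_limits[1]:.2e}]"
        )


def make_scene(
    kind: str,
    *,
    seed: int = 0,
    n_frames: int = 128,
    prf: float = 1000.0,
    x0: float = 0.0,
    z0: float = 5e-3,
    amplitude: float = 1.0,
    velocity: float = 1e-3,
    separation: float = 25e-6,
    z_stagger: float | None = None,
    axial_separation: float = 200e-6,
    lateral_speed: float = 5e-3,
    clutter_density: float | None = None,
    clutter_amplitude: float = 1.0,
    x_limits: tuple[float, float] = (-6.4e-3, 6.4e-3),
    z_limits: tuple[float, float] = (0.5e-3, 10e-3),
) -> Scene:
    """Build a deterministic point-scatterer scene.

    Kinds
    -----
    ``bubble_trace``
        One microbubble descending away from the transducer at ``velocity``
        (m/s), starting at ``(x0, z0)``.
    ``trace_pair``
        Two parallel descending microbubbles laterally ``separation`` metres
        apart, centered on ``x0``.  The second bubble is offset axially by
        ``z_stagger`` (default: half the travel distance, placed above), as
        real bubbles detach at different instants: the traces overlap in
        depth but the scatterers are never coincident in time, so each
        paints its own trace without coherent interference from the other.
    ``vessel_pair``
        Two scatterers translating laterally at ``lateral_speed`` at depths
        ``z0 -/+ axial_separation/2`` (two parallel vessels seen in cross
        flow).
    ``clutter_phantom``
        No moving targets; only the static clutter field.

    Any kind accepts ``clutter_density`` (scatterers per mm^2, drawn uniformly
    over the field) and ``clutter_amplitude`` (linear amplitude per clutter
    scatterer, e.g. 100 for clutter 40 dB above a unit-amplitude bubble).
    The same seed always reproduces the identical scene.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if amplitude <= 0 or clutter_amplitude <= 0:
        raise ValueError("amplitudes must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) / prf
    scatterers: list[tuple[np.ndarray, float]] = []

    if kind == "bubble_trace":
        traj = np.column_stack([np.full(n_frames, x0), z0 + velocity * t])
        scatterers.append((traj, amplitude))
    elif kind == "trace_pair":
        if separation <= 0:
            raise ValueError("separation must be positive")
        if z_stagger is None:
            z_stagger = velocity * (n_frames - 1) / prf / 2.0
        for sgn, dz in ((-0.5, 0.0), (+0.5, -z_stagger)):
            traj = np.column_stack(
                [np.full(n_frames, x0 + sgn * separation), z0 + dz + velocity * t]
            )
            scatterers.append((traj, amplitude))
    elif kind == "vessel_pair":
        if axial_separation <= 0:
            raise ValueError("axial_separation must be positive")
        span = lateral_speed * t
        x_start = x0 - span[-1] / 2.0
        for sgn in (-0.5, +0.5):
            traj = np.column_stack(
                [x_start + span, np.full(n_frames, z0 + sgn * axial_separation)]
            )
            scatterers.append((traj, amplitude))
    elif kind == "clutter_phantom":
        if clutter_density is None:
            clutter_density = 2.0
    else:
        raise ValueError(f"unknown scene kind {kind!r}")

    for traj, _amp in scatterers:
        _check_inside(traj, x_limits, z_limits, f"{kind} trajectory")

    if clutter_density is not None:
        area_mm2 = (
            (x_limits[1] - x_limits[0]) * 1e3 * (z_limits[1] - z_limits[0]) * 1e3
        )
        n_clutter = max(1, int(round(clutter_density * area_mm2)))
        cx = rng.uniform(x_limits[0], x_limits[1], n_clutter)
        cz = rng.uniform(z_limits[0], z_limits[1], n_clutter)
        static = np.column_stack([cx, cz, np.full(n_clutter, clutter_amplitude)])
        clutter_spec = {"density_per_mm2": clutter_density, "amplitude": clutter_amplitude}
    else:
        static = np.empty((0, 3))
        clutter_spec = None

    return Scene(
        scatterers=scatterers,
        static_scatterers=static,
        seed=seed,
        kind=kind,
        x_limits=x_limits,
        z_limits=z_limits,
        clutter_spec=clutter_spec,
    )


# ---------------------------------------------------------------------------
# RF simulation


def _echo_delays(
    x: np.ndarray, z: np.ndarray, theta: float, element_x: np.ndarray, c: float
) -> np.ndarray:
    """Two-way delay (s) for scatterers at (x, z) -> every element, one angle.

    Returns shape (n_scatterers, n_elements)."""
    tx = (z * np.cos(theta) + x * np.sin(theta)) / c
    rx = np.sqrt((x[:, None] - element_x[None, :]) ** 2 + z[:, None] ** 2) / c
    return tx[:, None] + rx


def _add_echoes(
    rf_frame: np.ndarray,
    delays: np.ndarray,
    amps: np.ndarray,
    gains: np.ndarray,
    fs: float,
    f0: float,
    sigma: float,
    half_win: int,
) -> None:
    """Accumulate Gaussian-windowed sinusoid echoes into one (samples, elements)
    RF frame.  ``delays`` is (n_scat, n_elem), ``amps`` (n_scat,)."""
    n_samples, n_elem = rf_frame.shape
    win = np.arange(2 * half_win + 1)
    cols = np.arange(n_elem)[None, :]
    for s in range(delays.shape[0]):
        i0 = np.round(delays[s] * fs).astype(np.int64) - half_win  # (n_elem,)
        idx = i0[None, :] + win[:, None]  # (W, n_elem)
        t_rel = idx / fs - delays[s][None, :]
        vals = amps[s] * gains[None, :] * np.sin(2 * np.pi * f0 * t_rel) * np.exp(
            -(t_rel**2) / (2 * sigma**2)
        )
        # unique (sample, element) pairs within one scatterer: direct fancy add
        rf_frame[idx, cols] += vals


def _required_samples(scene: Scene, geometry: ArrayGeometry, params: AcquisitionParams) -> int:
    pts = [traj for traj, _ in scene.scatterers]
    if scene.static_scatterers.size:
        pts.append(scene.static_scatterers[:, :2])
    if not pts:
        # empty scene: window covering the field depth
        z_max = scene.z_limits[1]
        tau_max = 2.2 * z_max / params.sound_speed
    else:
        allpts = np.concatenate(pts, axis=0)
        tau_max = 0.0
        for th in params.angles_rad:
            d = _echo_delays(
                allpts[:, 0], allpts[:, 1], th, geometry.element_x, params.sound_speed
            )
            tau_max = max(tau_max, float(d.max()))
    sigma = gaussian_pulse_sigma(params.transmit_frequency, geometry.bandwidth_fraction)
    return int(np.ceil((tau_max + 4 * sigma) * params.sampling_rate)) + 4


def simulate_channel_data(
    scene: Scene, geometry: ArrayGeometry, params: AcquisitionParams
) -> PlaneWaveAcquisition:
    """Simulate plane-wave RF channel data for a scene.

    Static clutter echoes are computed once per angle and broadcast across
    frames (static means static).  Receive gains ``geometry.true_sensitivity``
    multiply each channel; plane-wave transmits are not element-weighted.
    Noise, when ``params.snr_db`` is set, is white Gaussian i.i.d. per
    channel/sample, with variance set against the mean echo power of the
    central frame (or unit power for an empty scene), seeded from the scene
    seed so identical inputs give bit-identical tensors.
    """
    if scene.scatterers and scene.n_frames < params.n_frames:
        raise ValueError(
            f"scene provides {scene.n_frames} trajectory frames but the "
            f"acquisition requests {params.n_frames}"
        )
    fs = params.sampling_rate
    f0 = params.transmit_frequency
    c = params.sound_speed
    sigma = gaussian_pulse_sigma(f0, geometry.bandwidth_fraction)
    half_win = int(np.ceil(4 * sigma * fs))

    n_needed = _required_samples(scene, geometry, params)
    n_samples = params.n_samples if params.n_samples is not None else n_needed
    if n_samples < n_needed:
        raise ValueError(
            f"n_samples={n_samples} cannot hold the farthest echo; "
            f"at least {n_needed} samples required"
        )

    gains = np.asarray(geometry.true_sensitivity, dtype=float)
    rf = np.zeros(
        (n_samples, geometry.n_elements, params.n_angles, params.n_frames),
        dtype=np.float64,
    )

    for k, th in enumerate(params.angles_rad):
        if scene.static_scatterers.size:
            frame = np.zeros((n_samples, geometry.n_elements))
            d = _echo_delays(
                scene.static_scatterers[:, 0],
                scene.static_scatterers[:, 1],
                th,
                geometry.element_x,
                c,
            )
            _add_echoes(
                frame, d, scene.static_scatterers[:, 2], gains, fs, f0, sigma, half_win
            )
            rf[:, :, k, :] += frame[:, :, None]
        for traj, amp in scene.scatterers:
            for j in range(params.n_frames):
                d = _echo_delays(
                    traj[j : j + 1, 0], traj[j : j + 1, 1], th, geometry.element_x, c
                )
                _add_echoes(
                    rf[:, :, k, j], d, np.array([amp]), gains, fs, f0, sigma, half_win
                )

    if params.snr_db is not None:
        mid = params.n_frames // 2
        p_sig = float(np.mean(rf[:, :, :, mid] ** 2))
        if p_sig == 0.0:
            p_sig = 1.0  # empty scene: SNR referenced to unit power
        noise_var = p_sig * 10.0 ** (-params.snr_db / 10.0)
        noise_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=scene.seed, spawn_key=(0xD0,))
        )
        rf += noise_rng.normal(0.0, np.sqrt(noise_var), size=rf.shape)

    return PlaneWaveAcquisition(
        rf=rf.astype(np.float32), geometry=geometry, params=params, esc_applied=False
    )


# ---------------------------------------------------------------------------
# Element sensitivity measurement (planar-reflector pulse-echo)


def simulate_element_measurement(
    geometry: ArrayGeometry,
    reflector_depth: float = 10e-3,
    noise_db: float | None = None,
    *,
    sound_speed: float = 1480.0,
    sampling_rate: float = 62.5e6,
    transmit_frequency: float = 15.625e6,
    seed: int = 0,
    transmit_voltage_tag: str = "",
) -> SensitivityProfile:
    """In-silico analog of the planar-reflector sensitivity measurement.

    Each element is excited individually and receives its own echo from a
    planar reflector parallel to the array at ``reflector_depth`` (default
    water-tank sound speed 1480 m/s).  The pulse-echo amplitude of element
    ``e`` scales as ``true_sensitivity[e]**2`` (the same element transmits
    and receives), and the round-trip geometric delay ``2 d / c`` is
    identical for all elements by construction.

    ``s_d`` is the envelope peak of each echo; the single-path profile is
    ``s_s = sqrt(s_d)`` normalized to mean 1 (transmit and receive paths
    assumed identical).  ``noise_db`` adds white noise at the given level
    below the mean echo peak.
    """
    if reflector_depth <= 0:
        raise ValueError("reflector_depth must be positive")
    sigma = gaussian_pulse_sigma(transmit_frequency, geometry.bandwidth_fraction)
    tau = 2.0 * reflector_depth / sound_speed
    n_samples = int(np.ceil((tau + 5 * sigma) * sampling_rate)) + 4
    t = np.arange(n_samples) / sampling_rate
    g = np.asarray(geometry.true_sensitivity, dtype=float)
    echoes = (
        g[None, :] ** 2
        * np.sin(2 * np.pi * transmit_frequency * (t[:, None] - tau))
        * np.exp(-((t[:, None] - tau) ** 2) / (2 * sigma**2))
    )
    if noise_db is not None:
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0xE5,)))
        scale = float(np.mean(np.abs(echoes).max(axis=0))) * 10.0 ** (-noise_db / 20.0)
        echoes = echoes + rng.normal(0.0, scale, size=echoes.shape)
    env = np.abs(hilbert(echoes, axis=0))
    s_d = env.max(axis=0)
    if np.any(s_d <= 0):
        raise ValueError("degenerate measurement: zero envelope peak")
    s_s = np.sqrt(s_d)
    s_s = s_s / s_s.mean()
    return SensitivityProfile(s_d=s_d, s_s=s_s, transmit_voltage_tag=transmit_voltage_tag)
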