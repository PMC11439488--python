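"""Delay-and-sum plane-wave beamforming, coherent compounding, and NSI.

Null subtraction imaging (NSI) beamforms the same channel data three times
with different receive apodizations over the dynamic (F-number-limited)
subaperture:

* ``ZM`` — zero-mean Heaviside weighting, +1 on the proximal half of the
  subaperture and -1 on the distal half, which places a sharp null at the
  beam axis;
* ``DC1`` — the same weighting plus a small DC offset ``eps``;
* ``DC2`` — the spatially flipped version of DC1.

The combination ``(|DC1| + |DC2|)/2 - |ZM|`` of the three envelopes inverts
the null into a mainlobe far narrower than the diffraction limit for small
``eps``; element sensitivity correction (ESC) keeps the ZM weighting truly
zero-mean in the presence of per-channel gain inhomogeneity, which is what
lets small offsets keep improving resolution.

Delays follow the standard plane-wave round trip
``tau = (z cos(theta) + x sin(theta))/c + sqrt((x - x_e)^2 + z^2)/c``,
evaluated by linear interpolation on RF axially interpolated by a factor of
4.  One numba kernel computes every requested apodization in a single pass,
so the three NSI stacks share all delay computation.  The analytic (complex)
signal is taken along the axial image dimension after angle compounding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.signal import hilbert, resample_poly

from .simulate import PlaneWaveAcquisition, SensitivityProfile

__all__ = [
    "BeamGrid",
    "ApodizationTriplet",
    "IQStack",
    "esc_correct",
    "make_apodizations",
    "das_beamform",
    "nsi_beamform",
    "nsi_combine",
]


@dataclass
class BeamGrid:
    """Rectangular pixel grid for beamformed images.

    ``x_coords``/``z_coords`` are pixel centers in metres (x = 0 at the array
    center, z positive away from the array).  The lateral pixel pitch is the
    element pitch divided by ``lateral_interp_factor``; ``f_number`` sets the
    dynamic receive aperture half-width ``z / (2 F#)``.
    """

    x_coords: np.ndarray
    z_coords: np.ndarray
    f_number: float = 1.0
    axial_interp_factor: int = 4
    lateral_interp_factor: int = 4

    def __post_init__(self) -> None:
        self.x_coords = np.asarray(self.x_coords, dtype=float)
        self.z_coords = np.asarray(self.z_coords, dtype=float)
        for name, c in (("x_coords", self.x_coords), ("z_coords", self.z_coords)):
            if c.ndim != 1 or len(c) < 1:
                raise ValueError(f"{name} must be a non-empty 1-D array")
            if len(c) > 1 and np.any(np.diff(c) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
        if self.f_number <= 0:
            raise ValueError("f_number must be positive")
        if self.axial_interp_factor < 1 or self.lateral_interp_factor < 1:
            raise ValueError("interpolation factors must be >= 1")

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.z_coords), len(self.x_coords))

    @classmethod
    def for_region(
        cls,
        x_span: tuple[float, float],
        z_span: tuple[float, float],
        pitch: float,
        *,
        lateral_interp_factor: int = 4,
        axial_pixel: float = 12.5e-6,
        f_number: float = 1.0,
        axial_interp_factor: int = 4,
    ) -> "BeamGrid":
        """Grid covering a region, with the lateral pixel pitch locked to
        ``pitch / lateral_interp_factor`` so that grids with different
        lateral interpolation factors share pixel locations (x = 0 is on the
        grid whenever the span contains it)."""
        dx = pitch / lateral_interp_factor
        x = dx * np.arange(np.ceil(x_span[0] / dx - 1e-9), np.floor(x_span[1] / dx + 1e-9) + 1)
        z = axial_pixel * np.arange(
            np.ceil(z_span[0] / axial_pixel - 1e-9),
            np.floor(z_span[1] / axial_pixel + 1e-9) + 1,
        )
        return cls(
            x_coords=x,
            z_coords=z,
            f_number=f_number,
            axial_interp_factor=axial_interp_factor,
            lateral_interp_factor=lateral_interp_factor,
        )


@dataclass
class ApodizationTriplet:
    """The three NSI receive weight vectors for one subaperture length."""

    w_zm: np.ndarray
    w_dc1: np.ndarray
    w_dc2: np.ndarray
    dc_offset: float

    def __post_init__(self) -> None:
        self.w_zm = np.asarray(self.w_zm, dtype=float)
        self.w_dc1 = np.asarray(self.w_dc1, dtype=float)
        self.w_dc2 = np.asarray(self.w_dc2, dtype=float)
        n = len(self.w_zm)
        if len(self.w_dc1) != n or len(self.w_dc2) != n:
            raise ValueError("all three apodizations must have the same length")
        if abs(self.w_zm.sum()) > 1e-12 * max(1, n):
            raise ValueError("ZM apodization must sum to zero")


@dataclass
class IQStack:
    """Beamformed complex frames on a pixel grid (one stack per apodization)."""

    iq: np.ndarray  # (N_z, N_x, N_f) complex
    apodization_label: str
    grid: BeamGrid

    def __post_init__(self) -> None:
        if self.iq.ndim != 3 or self.iq.shape[:2] != self.grid.shape:
            raise ValueError(
                f"iq shape {self.iq.shape} does not match grid {self.grid.shape} + frames"
            )
        if not np.all(np.isfinite(self.iq)):
            raise ValueError("iq contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.iq.shape[2]

    def envelope(self) -> np.ndarray:
        return np.abs(self.iq)


# ---------------------------------------------------------------------------
# ESC


def esc_correct(
    acq: PlaneWaveAcquisition, profile: SensitivityProfile
) -> PlaneWaveAcquisition:
    """Divide every receive channel by its single-path sensitivity.

    ``R_esc[n] = R_raw[n] / s_s[n]`` applied across all samples, angles and
    frames; this restores a uniform effective receive gain so the ZM
    apodization forms a true null.
    """
    s_s = np.asarray(profile.s_s, dtype=float)
    if len(s_s) != acq.geometry.n_elements:
        raise ValueError(
            f"sensitivity profile has {len(s_s)} entries for "
            f"{acq.geometry.n_elements} elements"
        )
    if np.any(s_s <= 0):
        raise ValueError("single-path sensitivity must be positive")
    rf = acq.rf / s_s[None, :, None, None].astype(acq.rf.dtype)
    return PlaneWaveAcquisition(
        rf=rf.astype(acq.rf.dtype), geometry=acq.geometry, params=acq.params, esc_applied=True
    )


# ---------------------------------------------------------------------------
# Apodizations


def make_apodizations(n_active: int, dc_offset: float) -> ApodizationTriplet:
    """Build the NSI weight triplet for a subaperture of ``n_active`` elements.

    ``w_zm`` is +1 on the first half and -1 on the second half; ``w_dc1``
    adds the DC offset to every active weight; ``w_dc2`` is the spatial
    reversal of ``w_dc1``.  For odd ``n_active`` the center element is
    dropped (weight 0 in all three) so the ZM weighting stays exactly
    zero-mean.
    """
    if n_active < 2:
        raise ValueError("subaperture must contain at least 2 elements")
    if dc_offset < 0:
        raise ValueError("dc_offset must be non-negative")
    half = n_active // 2
    w_zm = np.zeros(n_active)
    w_zm[:half] = 1.0
    w_zm[n_active - half :] = -1.0
    active = w_zm != 0.0
    w_dc1 = np.where(active, w_zm + dc_offset, 0.0)
    w_dc2 = w_dc1[::-1].copy()
    return ApodizationTriplet(w_zm=w_zm, w_dc1=w_dc1, w_dc2=w_dc2, dc_offset=dc_offset)


# ---------------------------------------------------------------------------
# Delay-and-sum kernel


@njit(cache=True, fastmath=True)
def _das_accumulate(
    rf,  # (ns_up, n_elem, n_frames) float32, axially interpolated, one angle
    fs_up,
    x_coords,
    z_coords,
    elem_x,
    pitch,
    theta,
    c,
    f_number,
    dc_offset,
    nsi_mode,  # 0: uniform only; 1: ZM/DC1/DC2
    out,  # (n_apod, N_z, N_x, n_frames) float32
):
    ns_up, n_elem, n_frames = rf.shape
    ex0 = elem_x[0]
    sin_t = np.sin(theta)
    cos_t = np.cos(theta)
    for iz in range(z_coords.shape[0]):
        z = z_coords[iz]
        half_ap = z / (2.0 * f_number)
        tx = z * cos_t / c
        for ix in range(x_coords.shape[0]):
            x = x_coords[ix]
            tx_full = tx + x * sin_t / c
            e_lo = int(np.ceil((x - half_ap - ex0) / pitch - 1e-9))
            e_hi = int(np.floor((x + half_ap - ex0) / pitch + 1e-9))
            if e_lo < 0:
                e_lo = 0
            if e_hi > n_elem - 1:
                e_hi = n_elem - 1
            n_act = e_hi - e_lo + 1
            if n_act < 1:
                continue
            half_n = n_act // 2
            odd = n_act % 2 == 1
            for e in range(e_lo, e_hi + 1):
                j = e - e_lo
                if nsi_mode == 1:
                    if odd and j == half_n:
                        continue  # dropped center element keeps ZM zero-mean
                    zm = 1.0 if j < half_n else -1.0
                    w0 = zm
                    w1 = zm + dc_offset
                    w2 = -zm + dc_offset  # flipped DC1
                else:
                    w0 = 1.0
                    w1 = 0.0
                    w2 = 0.0
                dx = x - elem_x[e]
                tau = tx_full + np.sqrt(dx * dx + z * z) / c
                si = tau * fs_up
                i0 = int(si)
                if si < 0.0 or i0 + 1 >= ns_up:
                    continue
                fr = si - i0
                if nsi_mode == 1:
                    for f in range(n_frames):
                        v = rf[i0, e, f] * (1.0 - fr) + rf[i0 + 1, e, f] * fr
                        out[0, iz, ix, f] += w0 * v
                        out[1, iz, ix, f] += w1 * v
                        out[2, iz, ix, f] += w2 * v
                else:
                    for f in range(n_frames):
                        v = rf[i0, e, f] * (1.0 - fr) + rf[i0 + 1, e, f] * fr
                        out[0, iz, ix, f] += w0 * v


def _beamform_multi(
    acq: PlaneWaveAcquisition, grid: BeamGrid, nsi_mode: int, dc_offset: float
) -> np.ndarray:
    """Run the kernel over all angles; return real beamformed data of shape
    (n_apod, N_z, N_x, N_f) after coherent angle compounding."""
    params = acq.params
    geometry = acq.geometry
    n_apod = 3 if nsi_mode == 1 else 1
    n_z, n_x = grid.shape
    out = np.zeros((n_apod, n_z, n_x, params.n_frames), dtype=np.float32)
    fs_up = params.sampling_rate * grid.axial_interp_factor

    # empty-aperture check (vectorized, mirrors the kernel's truncation rule)
    half_ap = grid.z_coords[:, None] / (2.0 * grid.f_number)
    e_lo = np.ceil((grid.x_coords[None, :] - half_ap - geometry.element_x[0]) / geometry.pitch - 1e-9)
    e_hi = np.floor((grid.x_coords[None, :] + half_ap - geometry.element_x[0]) / geometry.pitch + 1e-9)
    n_act = np.minimum(e_hi, geometry.n_elements - 1) - np.maximum(e_lo, 0) + 1
    if np.any(n_act < 1):
        warnings.warn(
            f"{int(np.sum(n_act < 1))} pixels have an empty receive aperture and "
            "are set to zero",
            stacklevel=3,
        )

    for k, theta in enumerate(params.angles_rad):
        rf_angle = np.ascontiguousarray(acq.rf[:, :, k, :], dtype=np.float32)
        if grid.axial_interp_factor > 1:
            rf_up = resample_poly(
                rf_angle.astype(np.float64), grid.axial_interp_factor, 1, axis=0
            ).astype(np.float32)
        else:
            rf_up = rf_angle
        _das_accumulate(
            rf_up,
            fs_up,
            grid.x_coords,
            grid.z_coords,
            geometry.element_x,
            geometry.pitch,
            float(theta),
            params.sound_speed,
            grid.f_number,
            float(dc_offset),
            nsi_mode,
            out,
        )
    return out


def _to_analytic(bf: np.ndarray) -> np.ndarray:
    """Analytic signal along the axial image dimension, per apodization/frame."""
    if bf.shape[1] < 2:
        return bf.astype(np.complex64)
    return hilbert(bf.astype(np.float64), axis=1).astype(np.complex64)


def das_beamform(
    acq: PlaneWaveAcquisition,
    grid: BeamGrid,
    apodization: str = "uniform",
    dc_offset: float = 0.1,
) -> IQStack:
    """Delay-and-sum beamform with coherent compounding over all angles.

    ``apodization`` is ``uniform`` (plain DAS) or one of the NSI weight rules
    ``zm`` / ``dc1`` / ``dc2`` (regenerated per pixel at the truncated
    dynamic-aperture length).  Returns complex frames on the grid.
    """
    if apodization == "uniform":
        bf = _beamform_multi(acq, grid, nsi_mode=0, dc_offset=0.0)
        iq = _to_analytic(bf)[0]
        return IQStack(iq=iq, apodization_label="uniform", grid=grid)
    labels = {"zm": 0, "dc1": 1, "dc2": 2}
    if apodization not in labels:
        raise ValueError(f"unknown apodization rule {apodization!r}")
    if apodization != "zm" and dc_offset <= 0:
        raise ValueError("dc_offset must be positive for DC apodizations")
    bf = _beamform_multi(acq, grid, nsi_mode=1, dc_offset=dc_offset)
    iq = _to_analytic(bf)[labels[apodization]]
    return IQStack(iq=iq, apodization_label=apodization.upper(), grid=grid)


def nsi_beamform(
    acq: PlaneWaveAcquisition, grid: BeamGrid, dc_offset: float = 0.1
) -> tuple[IQStack, IQStack, IQStack]:
    """Beamform the three NSI stacks (ZM, DC1, DC2) in one delay pass."""
    if dc_offset <= 0:
        raise ValueError("dc_offset must be positive")
    bf = _beamform_multi(acq, grid, nsi_mode=1, dc_offset=dc_offset)
    iq = _to_analytic(bf)
    return (
        IQStack(iq=iq[0], apodization_label="ZM", grid=grid),
        IQStack(iq=iq[1], apodization_label="DC1", grid=grid),
        IQStack(iq=iq[2], apodization_label="DC2", grid=grid),
    )


def nsi_combine(
    env_zm: np.ndarray,
    env_dc1: np.ndarray,
    env_dc2: np.ndarray,
    dc_offset: float | None = None,
    normalize: bool = False,
) -> np.ndarray:
    """Combine the three NSI envelopes into the null-inverted image.

    ``out = max(0, (env_dc1 + env_dc2)/2 - env_zm)`` pixel-wise.  Negative
    values are clipped: the result has envelope semantics.  With
    ``normalize=True`` the output is divided by ``2 * dc_offset`` so sweeps
    over the offset compare on a common amplitude scale.
    """
    env_zm = np.asarray(env_zm)
    env_dc1 = np.asarray(env_dc1)
    env_dc2 = np.asarray(env_dc2)
    if not (env_zm.shape == env_dc1.shape == env_dc2.shape):
        raise ValueError("envelope shapes differ")
    if min(env_zm.min(), env_dc1.min(), env_dc2.min()) < 0:
        raise ValueError("envelopes must be non-negative")
    out = np.maximum(0.0, 0.5 * (env_dc1 + env_dc2) - env_zm)
    if normalize:
        if not dc_offset or dc_offset <= 0:
            raise ValueError("normalize=True requires a positive dc_offset")
        out = out / (2.0 * dc_offset)
    return out
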