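"""Power-Doppler accumulation, noise equalization, and adaptive display.

Power Doppler integrates the clutter-filtered slow-time signal energy per
pixel.  The DAS path sums |IQ|^2 over frames; the NSI path combines the
three apodization envelopes per frame (null inversion), squares the combined
envelope, and sums.  Depth-dependent noise amplification by the dynamic
receive aperture is equalized with a profile derived from the
smallest-singular-component reconstruction of the same acquisition.  Display
uses log compression with the maximum subtracted and an adaptive dynamic
range DR = alpha * sigma_pixel + |mu_pixel| computed from the dB-pixel
statistics, so images from different beamformer/filter combinations render
at comparable vessel-to-background contrast.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np

from .beamform import BeamGrid, IQStack, nsi_combine

__all__ = ["PDImage", "DisplayParams", "power_doppler", "noise_equalize", "render"]

DB_FLOOR = 1e-12  # relative power floor for log compression (-120 dB)


@dataclass
class DisplayParams:
    """Adaptive dynamic-range display parameters (all dB except alpha)."""

    alpha: float
    sigma_pixel: float
    mu_pixel: float
    dr: float

    def __post_init__(self) -> None:
        expected = self.alpha * self.sigma_pixel + abs(self.mu_pixel)
        if not np.isclose(self.dr, expected, rtol=1e-9, atol=1e-9):
            raise ValueError(
                f"dr={self.dr} violates dr = alpha*sigma + |mu| = {expected}"
            )


@dataclass
class PDImage:
    """Accumulated power-Doppler image.

    ``power`` is the linear power map; ``db`` the log-compressed
    (max-subtracted) image and ``display`` its adaptive-DR parameters, both
    filled by :func:`render`.
    """

    power: np.ndarray
    method_tag: str
    grid: BeamGrid | None = None
    db: np.ndarray | None = None
    display: DisplayParams | None = None

    def __post_init__(self) -> None:
        if self.power.ndim != 2:
            raise ValueError("power must be a 2-D image")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")


def power_doppler(
    filtered,
    method: str = "das",
    dc_offset: float | None = None,
    normalize: bool = False,
    method_tag: str | None = None,
) -> PDImage:
    """Accumulate the power-Doppler image from clutter-filtered IQ frames.

    ``method='das'`` takes one stack and sums |IQ|^2 over frames.
    ``method='nsi'`` takes the (ZM, DC1, DC2) triple; per frame the three
    envelopes are combined by null inversion and the combined envelope is
    squared before summation, keeping DAS and NSI on the same power
    integration semantics.
    """
    if method == "das":
        if not isinstance(filtered, IQStack):
            raise ValueError("das power Doppler expects a single IQStack")
        power = np.sum(np.abs(filtered.iq.astype(np.complex128)) ** 2, axis=2)
        grid = filtered.grid
    elif method == "nsi":
        try:
            zm, dc1, dc2 = filtered
        except (TypeError, ValueError) as exc:
            raise ValueError("nsi power Doppler expects the (ZM, DC1, DC2) triple") from exc
        frames = {s.n_frames for s in (zm, dc1, dc2)}
        if len(frames) != 1:
            raise ValueError(f"frame-count mismatch among NSI stacks: {sorted(frames)}")
        combined = nsi_combine(
            np.abs(zm.iq), np.abs(dc1.iq), np.abs(dc2.iq),
            dc_offset=dc_offset, normalize=normalize,
        )
        power = np.sum(combined.astype(np.float64) ** 2, axis=2)
        grid = zm.grid
    else:
        raise ValueError(f"unknown power-Doppler method {method!r}")
    return PDImage(power=power, method_tag=method_tag or method, grid=grid)


def _depth_profile(noise_env: np.ndarray, window: int) -> np.ndarray:
    profile = noise_env.mean(axis=tuple(range(1, noise_env.ndim)))
    if window > 1:
        w = min(window, len(profile))
        kernel = np.ones(w) / w
        # same-mode moving average with edge renormalization
        num = np.convolve(profile, kernel, mode="same")
        den = np.convolve(np.ones_like(profile), kernel, mode="same")
        profile = num / den
    profile = np.maximum(profile, np.finfo(float).eps)
    return profile / profile.min()


def noise_equalize(
    pd: PDImage, noise_reference, window: int = 32
) -> PDImage:
    """Equalize the depth-dependent noise floor of a PD image.

    ``noise_reference`` is the envelope stack (or (ZM, DC1, DC2) envelope
    stacks) reconstructed from the smallest retained-out singular component
    of the same acquisition.  Its lateral-and-frame mean gives a depth
    profile, smoothed axially with a moving average (default 32-pixel
    window), floored at machine epsilon and normalized to a minimum of 1;
    the PD power is divided by the squared profile across depth.
    """
    if isinstance(noise_reference, (list, tuple)):
        env = np.concatenate([np.abs(np.asarray(s.iq if isinstance(s, IQStack) else s))
                              for s in noise_reference], axis=-1)
    elif isinstance(noise_reference, IQStack):
        env = np.abs(noise_reference.iq)
    else:
        env = np.abs(np.asarray(noise_reference))
    if env.shape[0] != pd.power.shape[0]:
        raise ValueError("noise reference depth dimension does not match the PD image")
    if not np.any(env):
        warnings.warn("all-zero noise reference; returning the image unchanged")
        return PDImage(power=pd.power.copy(), method_tag=pd.method_tag, grid=pd.grid)
    profile = _depth_profile(env, window)
    power = pd.power / profile[:, None] ** 2
    return PDImage(power=power, method_tag=pd.method_tag, grid=pd.grid)


def render(pd: PDImage, alpha: float = 1.0) -> tuple[np.ndarray, DisplayParams]:
    """Log-compress and display with adaptive dynamic range.

    ``db = 10 log10(power) - max``; the dynamic range is
    ``DR = alpha * sigma_pixel + |mu_pixel|`` over the dB pixels (alpha = 1
    for contrast-enhanced imaging, 0.5 for contrast-free), and the returned
    display image clamps dB to [-DR, 0].  Fills ``pd.db`` and ``pd.display``.
    """
    p_max = float(pd.power.max())
    if p_max <= 0:
        raise ValueError("power image has no positive pixel")
    db = 10.0 * np.log10(np.maximum(pd.power, p_max * DB_FLOOR))
    db -= db.max()
    sigma = float(db.std())
    mu = float(db.mean())
    dr = alpha * sigma + abs(mu)
    params = DisplayParams(alpha=alpha, sigma_pixel=sigma, mu_pixel=mu, dr=dr)
    pd.db = db
    pd.display = params
    return np.clip(db, -dr, 0.0), params
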