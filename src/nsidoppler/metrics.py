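"""Resolution metrics for power-Doppler images.

Local resolution is measured as the full width at half maximum (FWHM) of
cross-section profiles through vessels or microbubble traces, with
sub-sample linear interpolation at the half-maximum crossings.  Global
resolution is measured in the Fourier domain: the mean 2-D spectral
magnitude at each radial spatial frequency (the iso-frequency curve) is
fitted with a decaying exponential, and two images are compared by the ratio
of spatial frequencies at which their fitted curves reach the same
amplitude — the matched-amplitude cutoff read at a reference frequency of
the reference image (half a wavelength or one wavelength).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.optimize import curve_fit

from .beamform import BeamGrid, nsi_beamform
from .doppler import PDImage, power_doppler, noise_equalize
from .clutter import build_casorati, invert_casorati, svd_filter

__all__ = [
    "ResolutionReport",
    "IsoCurve",
    "FwhmStats",
    "RatioResult",
    "cross_section",
    "fwhm",
    "fwhm_peaks",
    "fwhm_stats",
    "is_resolved",
    "dc_sweep",
    "iso_frequency_curve",
    "resolution_ratio",
]


class FwhmStats(NamedTuple):
    mean: float
    std: float
    per_section: list[float]
    n_unresolved: int


@dataclass
class IsoCurve:
    """Radially averaged spectral magnitude with its exponential fit."""

    frequencies: np.ndarray  # 1/mm
    amplitudes: np.ndarray
    fit_amplitude: float  # A in A*exp(-b f)
    fit_decay: float  # b in mm
    fit_band: tuple[float, float]  # frequency range used for the fit


class RatioResult(NamedTuple):
    ratio: float
    test_frequency: float
    reference_frequency: float
    extrapolated: bool


@dataclass
class ResolutionReport:
    """Aggregated resolution quantification for one PD image (all um)."""

    fwhm_mean: float | None = None
    fwhm_std: float | None = None
    per_section_fwhm: list[float] = field(default_factory=list)
    n_unresolved: int = 0
    dc_offset_sweep: dict = field(default_factory=dict)
    iso_curve: IsoCurve | None = None
    cutoff_ratio: RatioResult | None = None


# ---------------------------------------------------------------------------
# Cross sections and FWHM


def cross_section(
    pd: PDImage,
    line: tuple[tuple[float, float], tuple[float, float]],
    n_points: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample ``pd.power`` along a line by bilinear interpolation.

    ``line`` is ``((x0, z0), (x1, z1))`` in metres on the image grid.
    Returns positions along the line (um, starting at 0) and amplitudes.
    """
    if pd.grid is None:
        raise ValueError("PD image carries no grid; cannot map metres to pixels")
    (x0, z0), (x1, z1) = line
    length = float(np.hypot(x1 - x0, z1 - z0))
    if length == 0:
        raise ValueError("cross-section line has zero length")
    gx, gz = pd.grid.x_coords, pd.grid.z_coords
    for x, z in ((x0, z0), (x1, z1)):
        if not (gx[0] - 1e-12 <= x <= gx[-1] + 1e-12 and gz[0] - 1e-12 <= z <= gz[-1] + 1e-12):
            raise ValueError(
                f"endpoint ({x:.3e}, {z:.3e}) m outside image bounds "
                f"x:[{gx[0]:.3e}, {gx[-1]:.3e}], z:[{gz[0]:.3e}, {gz[-1]:.3e}]"
            )
    t = np.linspace(0.0, 1.0, n_points)
    xs = x0 + t * (x1 - x0)
    zs = z0 + t * (z1 - z0)
    dx = gx[1] - gx[0] if len(gx) > 1 else 1.0
    dz = gz[1] - gz[0] if len(gz) > 1 else 1.0
    cols = (xs - gx[0]) / dx
    rows = (zs - gz[0]) / dz
    amps = map_coordinates(pd.power, np.vstack([rows, cols]), order=1, mode="nearest")
    return t * length * 1e6, amps


def _half_crossing(profile: np.ndarray, peak: int, half: float, direction: int) -> float | None:
    """Sub-sample index of the half-max crossing nearest the peak, or None."""
    i = peak
    while 0 <= i + direction < len(profile):
        j = i + direction
        if profile[j] < half:
            frac = (profile[i] - half) / (profile[i] - profile[j])
            return i + direction * frac
        i = j
    return None


def fwhm(profile: np.ndarray, spacing: float) -> float | None:
    """Full width at half maximum of a profile (``spacing`` in um per sample).

    Uses the half-maximum crossings nearest the global peak with linear
    sub-sample interpolation.  Returns ``None`` (explicitly unresolved) when
    the profile never falls below half maximum on either side.
    """
    profile = np.asarray(profile, dtype=float)
    if len(profile) < 3:
        raise ValueError("profile too short")
    peak = int(np.argmax(profile))
    half = profile[peak] / 2.0
    left = _half_crossing(profile, peak, half, -1)
    right = _half_crossing(profile, peak, half, +1)
    if left is None or right is None:
        return None
    return float((right - left) * spacing)


def fwhm_peaks(profile: np.ndarray, spacing: float) -> list[tuple[float, float | None]]:
    """Per-peak FWHM for multi-modal profiles.

    Local maxima are separated at the minima between them and each peak's
    width is measured on its own segment.  Returns ``(position_um, width)``
    pairs (width ``None`` when that peak never drops to half max within its
    segment).
    """
    from scipy.signal import find_peaks

    profile = np.asarray(profile, dtype=float)
    peaks, _ = find_peaks(profile)
    if len(peaks) == 0:
        peaks = np.array([int(np.argmax(profile))])
    bounds = [0]
    for a, b in zip(peaks[:-1], peaks[1:]):
        bounds.append(a + int(np.argmin(profile[a:b])))
    bounds.append(len(profile))
    out = []
    for i, p in enumerate(peaks):
        seg = profile[bounds[i] : bounds[i + 1]]
        w = fwhm(seg, spacing) if len(seg) >= 3 else None
        out.append((float(p * spacing), w))
    return out


def is_resolved(profile: np.ndarray, min_rel_height: float = 0.25) -> bool:
    """Dip-below-half-maximum two-peak resolvability criterion.

    The two highest local maxima (above ``min_rel_height`` of the global
    maximum, to ignore noise ripple) count as resolved when the profile
    between them dips below half of the lower peak.
    """
    from scipy.signal import find_peaks

    profile = np.asarray(profile, dtype=float)
    peaks, _ = find_peaks(profile, height=min_rel_height * profile.max())
    if len(peaks) < 2:
        return False
    lo, hi = sorted(sorted(peaks, key=lambda i: profile[i])[-2:])
    dip = profile[lo : hi + 1].min()
    return bool(dip < 0.5 * min(profile[lo], profile[hi]))


def fwhm_stats(
    pd: PDImage,
    lines: Sequence[tuple[tuple[float, float], tuple[float, float]]],
    n_points: int = 200,
) -> FwhmStats:
    """Mean/std FWHM over a set of cross-section lines.

    Unresolved sections are excluded from the statistics and counted.
    """
    if not lines:
        raise ValueError("at least one cross-section line is required")
    widths: list[float] = []
    n_unresolved = 0
    for line in lines:
        pos, amps = cross_section(pd, line, n_points=n_points)
        spacing = pos[1] - pos[0]
        w = fwhm(amps, spacing)
        if w is None:
            n_unresolved += 1
        else:
            widths.append(w)
    if not widths:
        raise ValueError("all cross-sections are unresolved")
    return FwhmStats(
        mean=float(np.mean(widths)),
        std=float(np.std(widths)),
        per_section=widths,
        n_unresolved=n_unresolved,
    )


# ---------------------------------------------------------------------------
# DC offset sweep


def dc_sweep(
    acq,
    grid: BeamGrid,
    dc_offsets: Sequence[float],
    lines: Sequence[tuple[tuple[float, float], tuple[float, float]]],
    band=None,
    equalize: bool = False,
    n_points: int = 200,
) -> dict[float, FwhmStats | Exception]:
    """Run the NSI pipeline at each DC offset and collect FWHM statistics.

    ``band=None`` skips clutter filtering (appropriate for clutter-free
    scenes); otherwise the concatenated post-beamforming SVD filter is
    applied with the given band rule.  Per-offset failures are recorded in
    the result instead of aborting the sweep.
    """
    results: dict[float, FwhmStats | Exception] = {}
    for eps in dc_offsets:
        try:
            stacks = nsi_beamform(acq, grid, dc_offset=float(eps))
            if band is not None:
                m = build_casorati(stacks, "postbf_nsi")
                stacks = invert_casorati(svd_filter(m, band))
            pd = power_doppler(stacks, method="nsi", dc_offset=float(eps))
            if equalize:
                m = build_casorati(stacks, "postbf_nsi")
                from .clutter import smallest_component

                noise = invert_casorati(smallest_component(m))
                pd = noise_equalize(pd, noise)
            results[float(eps)] = fwhm_stats(pd, lines, n_points=n_points)
        except Exception as exc:  # propagate per-offset failures in the map
            results[float(eps)] = exc
    return results


# ---------------------------------------------------------------------------
# Iso-frequency curves


def iso_frequency_curve(
    pd: PDImage,
    domain: str = "power",
    fit_floor: float = 0.01,
) -> IsoCurve:
    """Radially averaged 2-D Fourier magnitude with an exponential fit.

    The image (linear power by default, or the dB image with
    ``domain='db'``) is Fourier transformed; spectral magnitudes are binned
    by radial spatial-frequency magnitude (bin width = one spectral sample)
    and averaged.  ``A * exp(-b f)`` is least-squares fitted over the band
    from the first bin above DC down to where the curve first falls below
    ``fit_floor`` of its maximum.

    Power images are normalized to unit maximum before the transform so
    fitted amplitudes of different method combinations are on a common
    scale and matched-amplitude cutoffs (:func:`resolution_ratio`) are
    meaningful; dB images are already max-subtracted and used as-is.
    """
    if pd.grid is None:
        raise ValueError("PD image carries no grid; pixel pitch unknown")
    if domain == "power":
        img = pd.power
        if img.max() > 0:
            img = img / img.max()
    elif domain == "db":
        if pd.db is None:
            raise ValueError("dB image not rendered yet")
        img = pd.db
    else:
        raise ValueError(f"unknown Fourier domain {domain!r}")
    n_z, n_x = img.shape
    if n_z < 8 or n_x < 8:
        raise ValueError("image smaller than 8x8 pixels")
    dx_mm = (pd.grid.x_coords[1] - pd.grid.x_coords[0]) * 1e3
    dz_mm = (pd.grid.z_coords[1] - pd.grid.z_coords[0]) * 1e3
    mag = np.abs(np.fft.fftshift(np.fft.fft2(img)))
    fx = np.fft.fftshift(np.fft.fftfreq(n_x, d=dx_mm))
    fz = np.fft.fftshift(np.fft.fftfreq(n_z, d=dz_mm))
    fr = np.hypot(fz[:, None], fx[None, :])
    df = max(1.0 / (n_x * dx_mm), 1.0 / (n_z * dz_mm))
    bins = np.round(fr / df).astype(int)
    n_bins = bins.max() + 1
    sums = np.bincount(bins.ravel(), weights=mag.ravel(), minlength=n_bins)
    counts = np.bincount(bins.ravel(), minlength=n_bins)
    amps = sums / np.maximum(counts, 1)
    freqs = np.arange(n_bins) * df

    # fit band: skip DC, stop where the curve first drops below the floor
    start = 1
    rest = amps[start:]
    below = np.nonzero(rest < fit_floor * rest.max())[0]
    stop = start + (int(below[0]) if len(below) else len(rest))
    if stop - start < 3:
        stop = min(start + 3, n_bins)
    f_fit = freqs[start:stop]
    a_fit = amps[start:stop]
    # log-linear seed, then nonlinear least squares on the curve itself
    slope, intercept = np.polyfit(f_fit, np.log(np.maximum(a_fit, 1e-300)), 1)
    p0 = (float(np.exp(intercept)), float(-slope))
    try:
        popt, _ = curve_fit(
            lambda f, a, b: a * np.exp(-b * f), f_fit, a_fit, p0=p0, maxfev=10000
        )
        amp0, decay = float(popt[0]), float(popt[1])
    except RuntimeError:
        amp0, decay = p0
    return IsoCurve(
        frequencies=freqs,
        amplitudes=amps,
        fit_amplitude=amp0,
        fit_decay=decay,
        fit_band=(float(f_fit[0]), float(f_fit[-1])),
    )


def resolution_ratio(
    curve_ref: IsoCurve, curve_test: IsoCurve, reference_frequency: float
) -> RatioResult:
    """Matched-amplitude cutoff ratio between two fitted iso-curves.

    The reference curve's fitted amplitude at ``reference_frequency`` (1/mm)
    is located on the test curve's fit; the ratio is the test frequency over
    the reference frequency (> 1 means finer resolution).  If the matched
    frequency falls outside the band the test curve was fitted on, the
    result is flagged as extrapolated.
    """
    if reference_frequency <= 0:
        raise ValueError("reference_frequency must be positive")
    if curve_test.fit_decay <= 0 or curve_ref.fit_decay <= 0:
        raise ValueError("fitted decay rates must be positive")
    amp = curve_ref.fit_amplitude * np.exp(-curve_ref.fit_decay * reference_frequency)
    f_test = float(np.log(curve_test.fit_amplitude / amp) / curve_test.fit_decay)
    lo, hi = curve_test.fit_band
    extrapolated = not (lo <= f_test <= hi)
    return RatioResult(
        ratio=f_test / reference_frequency,
        test_frequency=f_test,
        reference_frequency=reference_frequency,
        extrapolated=extrapolated,
    )
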