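"""Spatiotemporal SVD clutter filtering.

Tissue clutter, blood/bubble signal, and noise separate along the singular
spectrum of the Casorati (spatiotemporal) matrix whose columns are the
vectorized slow-time frames: slowly varying high-energy clutter occupies the
largest singular components, flow the middle band, and noise the tail.
Three matrix constructions are supported:

* ``postbf_das`` — the conventional construction: one beamformed IQ stack,
  each frame reshaped to a column (N_z*N_x rows).
* ``postbf_nsi`` — the NSI-aware construction: the three apodization stacks
  (ZM, DC1, DC2) of each frame are concatenated into a single column, giving
  a matrix three times taller, so one SVD filters all three stacks
  coherently (the nonlinear NSI envelope combination destroys phase, so the
  filter must run before it).
* ``prebf_angle`` — filtering the raw RF channel data of one steering angle
  (n_samples*n_elements rows) before any beamforming.

A blockwise variant runs an independently banded SVD on sliding axial blocks
(default 100 pixel rows, 90% overlap) and blends the overlapping
reconstructions, adapting the filter to depth-dependent clutter statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .beamform import IQStack
from .simulate import PlaneWaveAcquisition

__all__ = [
    "CasoratiMatrix",
    "FilterBand",
    "build_casorati",
    "invert_casorati",
    "svd_filter",
    "smallest_component",
    "adaptive_band",
    "prebf_filter",
    "blockwise_filter",
]

BandRule = "FilterBand | str | Callable[[np.ndarray], 'FilterBand']"


@dataclass
class FilterBand:
    """Retained singular-component band, 1-based inclusive indices."""

    low_cut: int
    high_cut: int

    def __post_init__(self) -> None:
        if self.low_cut < 1 or self.high_cut < self.low_cut:
            raise ValueError(
                f"invalid band [{self.low_cut}, {self.high_cut}]: need "
                "1 <= low_cut <= high_cut"
            )


@dataclass
class CasoratiMatrix:
    """2-D spatiotemporal matrix (space x slow-time) with reshape metadata."""

    data: np.ndarray
    mode: str  # postbf_das | postbf_nsi | prebf_angle
    shape_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise ValueError("Casorati data must be 2-D")
        if self.mode not in ("postbf_das", "postbf_nsi", "prebf_angle"):
            raise ValueError(f"unknown Casorati mode {self.mode!r}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]


def build_casorati(stacks, mode: str, angle_index: int | None = None) -> CasoratiMatrix:
    """Form the spatiotemporal matrix for one of the three constructions.

    ``stacks`` is an :class:`IQStack` for ``postbf_das``, a (ZM, DC1, DC2)
    triple for ``postbf_nsi``, or a real RF array of shape
    ``(n_samples, n_elements, n_frames)`` for ``prebf_angle`` (pass
    ``angle_index`` for bookkeeping).  Column ``j`` is frame ``j``
    vectorized; for ``postbf_nsi`` the three apodization blocks are stacked
    in fixed ZM, DC1, DC2 order.  The recorded metadata makes
    :func:`invert_casorati` an exact inverse.
    """
    if mode == "postbf_das":
        if not isinstance(stacks, IQStack):
            raise ValueError("postbf_das expects a single IQStack")
        n_z, n_x = stacks.grid.shape
        data = stacks.iq.reshape(n_z * n_x, stacks.n_frames)
        meta = {
            "n_z": n_z,
            "n_x": n_x,
            "n_frames": stacks.n_frames,
            "grid": stacks.grid,
            "labels": (stacks.apodization_label,),
        }
    elif mode == "postbf_nsi":
        try:
            zm, dc1, dc2 = stacks
        except (TypeError, ValueError) as exc:
            raise ValueError("postbf_nsi expects the (ZM, DC1, DC2) stack triple") from exc
        shapes = {s.iq.shape for s in (zm, dc1, dc2)}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent stack shapes: {sorted(shapes)}")
        n_z, n_x = zm.grid.shape
        n_f = zm.n_frames
        data = np.concatenate([s.iq.reshape(n_z * n_x, n_f) for s in (zm, dc1, dc2)], axis=0)
        meta = {
            "n_z": n_z,
            "n_x": n_x,
            "n_frames": n_f,
            "grid": zm.grid,
            "labels": (zm.apodization_label, dc1.apodization_label, dc2.apodization_label),
        }
    elif mode == "prebf_angle":
        rf = np.asarray(stacks)
        if rf.ndim != 3:
            raise ValueError(
                "prebf_angle expects RF of shape (n_samples, n_elements, n_frames)"
            )
        n_s, n_e, n_f = rf.shape
        data = rf.reshape(n_s * n_e, n_f)
        meta = {
            "n_samples": n_s,
            "n_elements": n_e,
            "n_frames": n_f,
            "angle_index": angle_index,
        }
    else:
        raise ValueError(f"unknown Casorati mode {mode!r}")
    return CasoratiMatrix(data=data, mode=mode, shape_meta=meta)


def invert_casorati(m: CasoratiMatrix):
    """Invert :func:`build_casorati` exactly (lossless reshape round-trip)."""
    meta = m.shape_meta
    if m.mode == "postbf_das":
        iq = m.data.reshape(meta["n_z"], meta["n_x"], meta["n_frames"])
        return IQStack(iq=iq, apodization_label=meta["labels"][0], grid=meta["grid"])
    if m.mode == "postbf_nsi":
        n_px = meta["n_z"] * meta["n_x"]
        out = []
        for i, label in enumerate(meta["labels"]):
            block = m.data[i * n_px : (i + 1) * n_px]
            out.append(
                IQStack(
                    iq=block.reshape(meta["n_z"], meta["n_x"], meta["n_frames"]),
                    apodization_label=label,
                    grid=meta["grid"],
                )
            )
        return tuple(out)
    return m.data.reshape(meta["n_samples"], meta["n_elements"], meta["n_frames"])


# ---------------------------------------------------------------------------
# SVD


def _economy_svd(m: CasoratiMatrix):
    if not np.all(np.isfinite(m.data)):
        raise ValueError("Casorati matrix contains non-finite values")
    return np.linalg.svd(m.data, full_matrices=False)


def _resolve_band(band, singular_values: np.ndarray, **auto_kwargs) -> FilterBand:
    if isinstance(band, FilterBand):
        return band
    if band == "auto":
        return adaptive_band(singular_values, **auto_kwargs)
    if callable(band):
        return band(singular_values)
    raise ValueError(f"cannot interpret band rule {band!r}")


def svd_filter(m: CasoratiMatrix, band) -> CasoratiMatrix:
    """Keep singular components with 1-based index in [low_cut, high_cut].

    ``band`` is a :class:`FilterBand`, the string ``"auto"`` (adaptive band
    from the singular spectrum), or a callable mapping singular values to a
    band.  Economy decomposition; mode and reshape metadata are preserved.
    """
    u, s, vh = _economy_svd(m)
    band = _resolve_band(band, s)
    if band.low_cut > len(s):
        raise ValueError(
            f"band low_cut={band.low_cut} exceeds the {len(s)} singular "
            "components of the matrix"
        )
    lo = band.low_cut - 1
    hi = min(band.high_cut, len(s))
    filtered = (u[:, lo:hi] * s[lo:hi]) @ vh[lo:hi]
    return CasoratiMatrix(data=filtered, mode=m.mode, shape_meta=dict(m.shape_meta))


def smallest_component(m: CasoratiMatrix) -> CasoratiMatrix:
    """Reconstruction from the single smallest singular component (the noise
    reference used for depth-dependent noise equalization)."""
    u, s, vh = _economy_svd(m)
    r = len(s)
    data = (u[:, r - 1 : r] * s[r - 1 : r]) @ vh[r - 1 : r]
    return CasoratiMatrix(data=data, mode=m.mode, shape_meta=dict(m.shape_meta))


def adaptive_band(
    singular_values: Sequence[float],
    strategy: str = "knee_plateau",
    low_cut: int | None = None,
    high_cut: int | None = None,
    default_band: FilterBand | None = None,
    plateau_slope: float = 0.02,
) -> FilterBand:
    """Choose the retained band from the singular-value decay.

    The tissue/flow boundary (``low_cut``) is placed at the knee — the
    largest-curvature point of the log singular-value decay.  The flow/noise
    boundary (``high_cut``) is the noise-plateau onset: the first index past
    the knee where the local slope of the log values flattens below
    ``plateau_slope`` (log10 per index); if the spectrum never flattens the
    full tail is retained.  Explicit ``low_cut``/``high_cut`` overrides
    always win.  Degenerate spectra (all equal) fall back to
    ``default_band`` (or the full band when none is configured).
    """
    if strategy != "knee_plateau":
        raise ValueError(f"unknown strategy {strategy!r}")
    sv = np.asarray(singular_values, dtype=float)
    n = len(sv)
    if low_cut is not None and high_cut is not None:
        return FilterBand(low_cut, high_cut)
    if np.any(np.diff(sv) > 1e-12 * max(sv.max(initial=0.0), 1.0)):
        raise ValueError("singular values must be non-increasing")
    if n < 4:
        if default_band is not None:
            return default_band
        raise ValueError(
            "need at least 4 singular values for adaptive banding; "
            "provide explicit cutoffs or a default band"
        )
    if sv[0] <= 0 or np.allclose(sv, sv[0]):
        band = default_band if default_band is not None else FilterBand(1, n)
    else:
        logs = np.log10(np.maximum(sv, sv[0] * 1e-12))
        curv = logs[:-2] - 2 * logs[1:-1] + logs[2:]  # centered at index i+1
        knee = int(np.argmax(curv)) + 2  # 1-based index of max curvature
        slopes = np.abs(np.diff(logs))  # slope between i and i+1 (0-based)
        flat = np.nonzero(slopes[knee - 1 :] < plateau_slope)[0]
        plateau = knee + int(flat[0]) if len(flat) else n
        band = FilterBand(knee, max(plateau, knee))
    lo = low_cut if low_cut is not None else band.low_cut
    hi = high_cut if high_cut is not None else band.high_cut
    return FilterBand(lo, max(hi, lo))


# ---------------------------------------------------------------------------
# Pre-beamforming filter


def prebf_filter(acq: PlaneWaveAcquisition, band="auto") -> PlaneWaveAcquisition:
    """SVD-filter the raw RF channel data, one steering angle at a time.

    Each angle's real RF forms its own Casorati matrix (samples*elements
    rows) and is filtered independently with its own band.
    """
    rf_out = np.empty_like(acq.rf)
    for k in range(acq.params.n_angles):
        m = build_casorati(acq.rf[:, :, k, :].astype(np.float64), "prebf_angle", angle_index=k)
        filt = svd_filter(m, band)
        rf_out[:, :, k, :] = invert_casorati(filt).astype(acq.rf.dtype)
    return PlaneWaveAcquisition(
        rf=rf_out, geometry=acq.geometry, params=acq.params, esc_applied=acq.esc_applied
    )


# ---------------------------------------------------------------------------
# Blockwise filter


def _block_starts(n_rows: int, block: int, step: int) -> list[int]:
    starts = list(range(0, max(n_rows - block, 0) + 1, step))
    if starts[-1] + block < n_rows:
        starts.append(n_rows - block)
    return starts


def blockwise_filter(stacks, block_px: int = 100, overlap: float = 0.9, band="auto"):
    """Blockwise adaptive SVD filtering on sliding axial blocks.

    Blocks of ``block_px`` pixel rows (spanning the full lateral width) slide
    with step ``block_px * (1 - overlap)`` (100 px / 90% overlap -> 10-row
    step); each block is filtered with its own adaptively chosen band, and
    overlapping reconstructions are blended with triangular weights that
    normalize to a partition of unity at every pixel.  Accepts one IQ stack
    (DAS) or the (ZM, DC1, DC2) triple (NSI, filtered through the
    concatenated construction per block).  A block covering the whole image
    reduces exactly to the global post-beamforming filter.
    """
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    single = isinstance(stacks, IQStack)
    ref = stacks if single else stacks[0]
    n_z, n_x = ref.grid.shape
    block = min(block_px, n_z)
    step = max(1, int(round(block * (1.0 - overlap))))
    starts = _block_starts(n_z, block, step)

    stack_list = [stacks] if single else list(stacks)
    acc = [np.zeros_like(s.iq) for s in stack_list]
    wsum = np.zeros(n_z)
    # triangular weight, strictly positive at block edges so edge pixels
    # covered by a single block keep full weight after normalization
    ramp = 1.0 - np.abs(np.arange(block) - (block - 1) / 2.0) / ((block + 1) / 2.0)

    for s0 in starts:
        sl = slice(s0, s0 + block)
        sub = [
            IQStack(iq=s.iq[sl], apodization_label=s.apodization_label, grid=_subgrid(s.grid, sl))
            for s in stack_list
        ]
        if single:
            m = build_casorati(sub[0], "postbf_das")
        else:
            m = build_casorati(tuple(sub), "postbf_nsi")
        filt = invert_casorati(svd_filter(m, band))
        filt_list = [filt] if single else list(filt)
        for a, f in zip(acc, filt_list):
            a[sl] += ramp[:, None, None] * f.iq
        wsum[sl] += ramp

    out = []
    for s, a in zip(stack_list, acc):
        out.append(
            IQStack(
                iq=a / wsum[:, None, None],
                apodization_label=s.apodization_label,
                grid=s.grid,
            )
        )
    return out[0] if single else tuple(out)


def _subgrid(grid, sl: slice):
    from .beamform import BeamGrid

    return BeamGrid(
        x_coords=grid.x_coords,
        z_coords=grid.z_coords[sl],
        f_number=grid.f_number,
        axial_interp_factor=grid.axial_interp_factor,
        lateral_interp_factor=grid.lateral_interp_factor,
    )
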