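"""Pipeline orchestration: the six beamformer x clutter-filter combinations.

The processing chain runs, in order: element sensitivity correction
(optional) -> pre-beamforming SVD filter (if selected) -> beamforming (DAS
or NSI) -> post-beamforming global or blockwise SVD filter (if selected) ->
noise equalization -> power-Doppler accumulation -> log compression with
adaptive dynamic range -> resolution metrics.  Two beamformers (das, nsi)
crossed with three filters (prebf, postbf, blockwise) give the six standard
method combinations; `filter='none'` is additionally allowed for clutter-free
in-silico studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .simulate import PlaneWaveAcquisition, SensitivityProfile
from .beamform import BeamGrid, IQStack, das_beamform, nsi_beamform, esc_correct
from .clutter import (
    FilterBand,
    build_casorati,
    invert_casorati,
    svd_filter,
    smallest_component,
    prebf_filter,
    blockwise_filter,
)
from .doppler import PDImage, DisplayParams, power_doppler, noise_equalize, render
from .metrics import ResolutionReport, fwhm_stats, iso_frequency_curve

logger = logging.getLogger("nsidoppler")

BEAMFORMERS = ("das", "nsi")
FILTERS = ("prebf", "postbf", "blockwise", "none")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Full parameterization of one pipeline run.

    ``low_cut``/``high_cut`` accept explicit 1-based singular indices or
    ``"auto"`` for the adaptive knee/plateau rule.  A single global ``seed``
    fans out deterministically to per-module seeds.
    """

    beamformer: str = "das"
    filter: str = "postbf"
    dc_offset: float = 0.1
    alpha: float = 1.0
    esc: bool = True
    low_cut: int | str = "auto"
    high_cut: int | str = "auto"
    block_px: int = 100
    overlap: float = 0.9
    equalize: bool = True
    normalize_nsi: bool = False
    f_number: float = 1.0
    axial_interp_factor: int = 4
    lateral_interp_factor: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beamformer not in BEAMFORMERS:
            raise ValueError(f"beamformer must be one of {BEAMFORMERS}")
        if self.filter not in FILTERS:
            raise ValueError(f"filter must be one of {FILTERS}")
        if self.beamformer == "nsi" and self.dc_offset <= 0:
            raise ValueError("NSI requires a positive dc_offset")
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must be in [0, 1)")

    @property
    def band_rule(self):
        if self.low_cut == "auto" and self.high_cut == "auto":
            return "auto"
        from .clutter import adaptive_band

        lo = None if self.low_cut == "auto" else int(self.low_cut)
        hi = None if self.high_cut == "auto" else int(self.high_cut)
        return lambda sv: adaptive_band(sv, low_cut=lo, high_cut=hi)

    def module_seed(self, module: str) -> int:
        """Deterministic per-module seed fanned out from the global seed."""
        ss = np.random.SeedSequence(
            entropy=self.seed, spawn_key=(sum(map(ord, module)) % 251,)
        )
        return int(ss.generate_state(1)[0] % (2**31))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class PipelineResult:
    pd: PDImage
    display_image: np.ndarray
    display: DisplayParams
    stacks: IQStack | tuple | None = None
    report: ResolutionReport | None = None
    config: PipelineConfig | None = None


def _stage(name: str, config: PipelineConfig, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage '{name}' failed with config {config.to_dict()}"
        ) from exc


def run_pipeline(
    config: PipelineConfig,
    acq: PlaneWaveAcquisition,
    grid: BeamGrid,
    profile: SensitivityProfile | None = None,
    lines: Sequence | None = None,
    keep_stacks: bool = False,
) -> PipelineResult:
    """Execute the full processing chain for one method combination.

    ``profile`` is required when ``config.esc`` is set and the acquisition is
    not already corrected.  ``lines`` (cross-section endpoints in metres)
    enable FWHM statistics in the returned report; the iso-frequency curve
    is always computed when the image is at least 8x8 pixels.
    """
    grid = BeamGrid(
        x_coords=grid.x_coords,
        z_coords=grid.z_coords,
        f_number=config.f_number,
        axial_interp_factor=config.axial_interp_factor,
        lateral_interp_factor=grid.lateral_interp_factor,
    )
    band = config.band_rule

    if config.esc and not acq.esc_applied:
        if profile is None:
            raise ValueError("config.esc is set but no sensitivity profile was given")
        acq = _stage("esc", config, esc_correct, acq, profile)
        logger.info("ESC applied")

    if config.filter == "prebf":
        acq = _stage("prebf_filter", config, prebf_filter, acq, band)
        logger.info("pre-beamforming SVD filter applied")

    if config.beamformer == "das":
        stacks = _stage("beamform", config, das_beamform, acq, grid, "uniform")
    else:
        stacks = _stage("beamform", config, nsi_beamform, acq, grid, config.dc_offset)
    logger.info("beamformed with %s", config.beamformer)

    casorati_mode = "postbf_das" if config.beamformer == "das" else "postbf_nsi"
    if config.filter == "postbf":
        m = _stage("postbf_filter", config, build_casorati, stacks, casorati_mode)
        stacks = _stage("postbf_filter", config, lambda: invert_casorati(svd_filter(m, band)))
    elif config.filter == "blockwise":
        stacks = _stage(
            "blockwise_filter",
            config,
            blockwise_filter,
            stacks,
            config.block_px,
            config.overlap,
            band,
        )
    if config.filter != "none":
        logger.info("clutter filter: %s", config.filter)

    method_tag = f"{config.beamformer}|{config.filter}"
    pd = _stage(
        "power_doppler",
        config,
        power_doppler,
        stacks,
        config.beamformer,
        config.dc_offset if config.beamformer == "nsi" else None,
        config.normalize_nsi,
        method_tag,
    )

    if config.equalize:
        m = build_casorati(stacks, casorati_mode)
        noise = invert_casorati(smallest_component(m))
        pd = _stage("noise_equalize", config, noise_equalize, pd, noise)
        logger.info("noise equalization applied")

    display_image, display = _stage("render", config, render, pd, config.alpha)

    report = ResolutionReport()
    if lines:
        stats = _stage("metrics", config, fwhm_stats, pd, lines)
        report.fwhm_mean = stats.mean
        report.fwhm_std = stats.std
        report.per_section_fwhm = stats.per_section
        report.n_unresolved = stats.n_unresolved
    if pd.power.shape[0] >= 8 and pd.power.shape[1] >= 8:
        report.iso_curve = _stage("metrics", config, iso_frequency_curve, pd)

    return PipelineResult(
        pd=pd,
        display_image=display_image,
        display=display,
        stacks=stacks if keep_stacks else None,
        report=report,
        config=config,
    )
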