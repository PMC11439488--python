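"""HDF5 container I/O for acquisitions, sensitivity profiles, IQ stacks and
PD images.

Layout (schema version 1):

* acquisition files — ``/rf`` (float32, samples x elements x angles x
  frames), ``/geometry/element_x``, optional ``/geometry/true_sensitivity``
  (test-only ground truth), root attributes ``sampling_rate``,
  ``sound_speed``, ``angles_deg``, ``prf``, ``transmit_frequency`` plus
  geometry/flag metadata;
* sensitivity files — ``/sensitivity/s_d``, ``/sensitivity/s_s``;
* IQ files — ``/iq/<label>`` complex64 stacks with the grid under
  ``/grid``;
* PD files — ``/pd/power`` and (when rendered) ``/pd/db`` with the display
  parameters as attributes.

All round trips are lossless for every dataset and attribute defined here;
missing datasets and unknown schema versions raise :class:`SchemaError`
naming the problem — no silent fallback.
"""

from __future__ import annotations

import numpy as np
import h5py

from .simulate import ArrayGeometry, AcquisitionParams, PlaneWaveAcquisition, SensitivityProfile
from .beamform import BeamGrid, IQStack
from .doppler import PDImage, DisplayParams

SCHEMA_VERSION = 1

__all__ = [
    "SchemaError",
    "write_acquisition",
    "read_acquisition",
    "write_sensitivity",
    "read_sensitivity",
    "write_iq_stacks",
    "read_iq_stacks",
    "write_pd",
    "read_pd",
    "export_pd_images",
]


class SchemaError(ValueError):
    """A container is missing required data or has an unsupported schema."""


def _check_schema(f: h5py.File, path: str) -> None:
    version = f.attrs.get("schema_version")
    if version is None:
        raise SchemaError(f"{path}: missing 'schema_version' attribute")
    if int(version) != SCHEMA_VERSION:
        raise SchemaError(
            f"{path}: unsupported schema version {version} (supported: {SCHEMA_VERSION})"
        )


def _require(f: h5py.File, name: str, path: str):
    if name not in f:
        raise SchemaError(f"{path}: missing dataset '{name}'")
    return f[name]


def _require_attr(obj, name: str, path: str):
    if name not in obj.attrs:
        raise SchemaError(f"{path}: missing attribute '{name}'")
    return obj.attrs[name]


# ---------------------------------------------------------------------------
# Acquisitions


def write_acquisition(path, acq: PlaneWaveAcquisition, include_truth: bool = False) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.create_dataset("/rf", data=acq.rf.astype(np.float32))
        f.create_dataset("/geometry/element_x", data=acq.geometry.element_x)
        if include_truth:
            f.create_dataset(
                "/geometry/true_sensitivity", data=acq.geometry.true_sensitivity
            )
        f.attrs["sampling_rate"] = acq.params.sampling_rate
        f.attrs["sound_speed"] = acq.params.sound_speed
        f.attrs["angles_deg"] = np.asarray(acq.params.angles_deg)
        f.attrs["prf"] = acq.params.prf
        f.attrs["transmit_frequency"] = acq.params.transmit_frequency
        f.attrs["pitch"] = acq.geometry.pitch
        f.attrs["center_frequency"] = acq.geometry.center_frequency
        f.attrs["bandwidth_fraction"] = acq.geometry.bandwidth_fraction
        f.attrs["esc_applied"] = bool(acq.esc_applied)
        f.attrs["snr_db"] = np.nan if acq.params.snr_db is None else acq.params.snr_db


def read_acquisition(path) -> PlaneWaveAcquisition:
    with h5py.File(path, "r") as f:
        _check_schema(f, str(path))
        rf = _require(f, "/rf", str(path))[()]
        element_x = _require(f, "/geometry/element_x", str(path))[()]
        pitch = float(_require_attr(f, "pitch", str(path)))
        geometry = ArrayGeometry(
            n_elements=len(element_x),
            pitch=pitch,
            center_frequency=float(_require_attr(f, "center_frequency", str(path))),
            bandwidth_fraction=float(_require_attr(f, "bandwidth_fraction", str(path))),
            true_sensitivity=(
                f["/geometry/true_sensitivity"][()]
                if "/geometry/true_sensitivity" in f
                else None
            ),
        )
        snr = float(_require_attr(f, "snr_db", str(path)))
        params = AcquisitionParams(
            sampling_rate=float(_require_attr(f, "sampling_rate", str(path))),
            sound_speed=float(_require_attr(f, "sound_speed", str(path))),
            angles_deg=np.asarray(_require_attr(f, "angles_deg", str(path))),
            prf=float(_require_attr(f, "prf", str(path))),
            n_frames=rf.shape[3],
            transmit_frequency=float(_require_attr(f, "transmit_frequency", str(path))),
            snr_db=None if np.isnan(snr) else snr,
            n_samples=rf.shape[0],
        )
        return PlaneWaveAcquisition(
            rf=rf,
            geometry=geometry,
            params=params,
            esc_applied=bool(_require_attr(f, "esc_applied", str(path))),
        )


# ---------------------------------------------------------------------------
# Sensitivity profiles


def write_sensitivity(path, profile: SensitivityProfile) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.create_dataset("/sensitivity/s_d", data=profile.s_d)
        f.create_dataset("/sensitivity/s_s", data=profile.s_s)
        f["/sensitivity"].attrs["transmit_voltage_tag"] = profile.transmit_voltage_tag


def read_sensitivity(path) -> SensitivityProfile:
    with h5py.File(path, "r") as f:
        _check_schema(f, str(path))
        s_d = _require(f, "/sensitivity/s_d", str(path))[()]
        s_s = _require(f, "/sensitivity/s_s", str(path))[()]
        tag = str(f["/sensitivity"].attrs.get("transmit_voltage_tag", ""))
        return SensitivityProfile(s_d=s_d, s_s=s_s, transmit_voltage_tag=tag)


# ---------------------------------------------------------------------------
# IQ stacks


def _write_grid(f: h5py.File, grid: BeamGrid) -> None:
    g = f.create_group("/grid")
    g.create_dataset("x_coords", data=grid.x_coords)
    g.create_dataset("z_coords", data=grid.z_coords)
    g.attrs["f_number"] = grid.f_number
    g.attrs["axial_interp_factor"] = grid.axial_interp_factor
    g.attrs["lateral_interp_factor"] = grid.lateral_interp_factor


def _read_grid(f: h5py.File, path: str) -> BeamGrid:
    g = _require(f, "/grid", path)
    return BeamGrid(
        x_coords=_require(f, "/grid/x_coords", path)[()],
        z_coords=_require(f, "/grid/z_coords", path)[()],
        f_number=float(_require_attr(g, "f_number", path)),
        axial_interp_factor=int(_require_attr(g, "axial_interp_factor", path)),
        lateral_interp_factor=int(_require_attr(g, "lateral_interp_factor", path)),
    )


def write_iq_stacks(path, stacks) -> None:
    if isinstance(stacks, IQStack):
        stacks = [stacks]
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        _write_grid(f, stacks[0].grid)
        for s in stacks:
            f.create_dataset(f"/iq/{s.apodization_label}", data=s.iq.astype(np.complex64))


def read_iq_stacks(path):
    with h5py.File(path, "r") as f:
        _check_schema(f, str(path))
        grid = _read_grid(f, str(path))
        group = _require(f, "/iq", str(path))
        stacks = [
            IQStack(iq=group[label][()], apodization_label=label, grid=grid)
            for label in group
        ]
    if not stacks:
        raise SchemaError(f"{path}: '/iq' group holds no stacks")
    return stacks[0] if len(stacks) == 1 else tuple(stacks)


# ---------------------------------------------------------------------------
# PD images


def write_pd(path, pd: PDImage) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.create_dataset("/pd/power", data=pd.power)
        f["/pd"].attrs["method_tag"] = pd.method_tag
        if pd.grid is not None:
            _write_grid(f, pd.grid)
        if pd.db is not None:
            f.create_dataset("/pd/db", data=pd.db)
        if pd.display is not None:
            for k in ("alpha", "sigma_pixel", "mu_pixel", "dr"):
                f["/pd"].attrs[k] = getattr(pd.display, k)


def read_pd(path) -> PDImage:
    with h5py.File(path, "r") as f:
        _check_schema(f, str(path))
        power = _require(f, "/pd/power", str(path))[()]
        attrs = f["/pd"].attrs
        display = None
        if "dr" in attrs:
            display = DisplayParams(
                alpha=float(attrs["alpha"]),
                sigma_pixel=float(attrs["sigma_pixel"]),
                mu_pixel=float(attrs["mu_pixel"]),
                dr=float(attrs["dr"]),
            )
        return PDImage(
            power=power,
            method_tag=str(attrs.get("method_tag", "")),
            grid=_read_grid(f, str(path)) if "/grid" in f else None,
            db=f["/pd/db"][()] if "/pd/db" in f else None,
            display=display,
        )


def export_pd_images(pd: PDImage, tiff_path=None, png_path=None) -> None:
    """Export the rendered display image as 16-bit TIFF and/or PNG."""
    if pd.db is None or pd.display is None:
        raise ValueError("render the PD image before exporting")
    dr = pd.display.dr
    img = np.clip(pd.db, -dr, 0.0)
    scaled = ((img + dr) / dr * 65535.0).astype(np.uint16)
    if tiff_path is not None:
        import tifffile

        tifffile.imwrite(tiff_path, scaled)
    if png_path is not None:
        from PIL import Image

        Image.fromarray((scaled / 257).astype(np.uint8)).save(png_path)
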