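"""File dialects: raw float32 channel data + JSON sidecars, TIFF/PNG images.

Channel data are stored as little-endian float32, axial-major, next to a
JSON sidecar carrying the acquisition geometry, depth, and provenance
(seed, frame index).  An equivalent single-file HDF5 container uses the
same field names.  Beamformed images are written as 32-bit float TIFF and
display images as 8-bit PNG (linear map of [-DR, 0] dB to [0, 255]), each
with a JSON sidecar holding the pixel spacings and beamforming parameters.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np
import tifffile

from .beamform import BeamformedImage, DisplayImage
from .simulate import ArrayGeometry, ChannelData

__all__ = [
    "write_channel_data",
    "read_channel_data",
    "write_channel_data_hdf5",
    "read_channel_data_hdf5",
    "write_image",
    "read_image",
    "write_display_png",
]


def _geometry_dict(g: ArrayGeometry) -> dict:
    return {
        "num_elements": g.num_elements,
        "pitch_mm": g.pitch_mm,
        "sampling_frequency_mhz": g.sampling_frequency_mhz,
        "sound_speed_m_s": g.sound_speed_m_s,
        "center_frequency_mhz": g.center_frequency_mhz,
        "fractional_bandwidth": g.fractional_bandwidth,
    }


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_channel_data(
    path: str | Path, frame: ChannelData, seed: int | None = None
) -> Path:
    """Raw little-endian float32 (axial-major) plus a JSON sidecar."""
    path = Path(path)
    np.ascontiguousarray(frame.samples, dtype="<f4").tofile(path)
    meta = {
        "format": "raw-float32-le",
        "shape": list(frame.samples.shape),
        "order": "axial-major",
        "depth_mm": frame.depth_mm,
        "frame_index": frame.frame_index,
        "seed": seed,
        "geometry": _geometry_dict(frame.geometry),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_channel_data(path: str | Path) -> ChannelData:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    samples = np.fromfile(path, dtype="<f4").reshape(meta["shape"])
    return ChannelData(
        samples=samples.astype(np.float64),
        geometry=ArrayGeometry(**meta["geometry"]),
        depth_mm=meta["depth_mm"],
        frame_index=meta.get("frame_index", 0),
    )


def write_channel_data_hdf5(
    path: str | Path, frame: ChannelData, seed: int | None = None
) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=frame.samples.astype("<f4"))
        f.attrs["depth_mm"] = frame.depth_mm
        f.attrs["frame_index"] = frame.frame_index
        if seed is not None:
            f.attrs["seed"] = seed
        for key, val in _geometry_dict(frame.geometry).items():
            f.attrs[key] = val
    return path


def read_channel_data_hdf5(path: str | Path) -> ChannelData:
    with h5py.File(path, "r") as f:
        samples = f["samples"][...]
        geometry = ArrayGeometry(
            num_elements=int(f.attrs["num_elements"]),
            pitch_mm=float(f.attrs["pitch_mm"]),
            sampling_frequency_mhz=float(f.attrs["sampling_frequency_mhz"]),
            sound_speed_m_s=float(f.attrs["sound_speed_m_s"]),
            center_frequency_mhz=float(f.attrs["center_frequency_mhz"]),
            fractional_bandwidth=float(f.attrs["fractional_bandwidth"]),
        )
        return ChannelData(
            samples=samples.astype(np.float64),
            geometry=geometry,
            depth_mm=float(f.attrs["depth_mm"]),
            frame_index=int(f.attrs["frame_index"]),
        )


def write_image(
    path: str | Path,
    img: BeamformedImage,
    method: str | None = None,
    cumulative_lag: int | None = None,
    axial_kernel: int | None = None,
) -> Path:
    """32-bit float TIFF of the pre-log values plus a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, img.values.astype(np.float32))
    meta = {
        "lateral_positions_mm": list(map(float, img.lateral_positions_mm)),
        "axial_spacing_mm": img.axial_spacing_mm,
        "normalized": img.normalized,
        "method": method or img.method,
        "M": cumulative_lag,
        "k": axial_kernel,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_image(path: str | Path) -> BeamformedImage:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    values = tifffile.imread(path).astype(np.float64)
    return BeamformedImage(
        values=values,
        lateral_positions_mm=np.asarray(meta["lateral_positions_mm"]),
        axial_spacing_mm=meta["axial_spacing_mm"],
        normalized=meta["normalized"],
        method=meta.get("method", ""),
    )


def write_display_png(path: str | Path, disp: DisplayImage) -> Path:
    """8-bit PNG: linear map of [-DR, 0] dB to [0, 255] (axial vertical)."""
    path = Path(path)
    scaled = (disp.values_db + disp.dynamic_range_db) / disp.dynamic_range_db
    img8 = np.round(255 * np.clip(scaled, 0, 1)).astype(np.uint8)
    iio.imwrite(path, img8.T)  # rows = axial samples, columns = scanlines
    meta = {
        "dynamic_range_db": disp.dynamic_range_db,
        "lateral_positions_mm": list(map(float, disp.lateral_positions_mm)),
        "axial_spacing_mm": disp.axial_spacing_mm,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path
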