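"""File I/O: HDF5 as the canonical intermediate format, TIFF for
interoperability, YAML for configuration.

Every dataset written carries its voxel/pixel size and unit string as
HDF5 attributes, plus a free-form provenance dict echoing the stage
parameters, so figure-like outputs remain traceable.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml

__all__ = [
    "save_volume",
    "load_volume",
    "save_tiff_stack",
    "load_tiff_stack",
    "load_config",
    "save_frames",
    "load_frames",
]


def save_volume(path, data: np.ndarray, pixel_um: float, units: str, **provenance) -> None:
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        save_tiff_stack(path, data)
        return
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("data", data=np.asarray(data))
        ds.attrs["pixel_um"] = pixel_um
        ds.attrs["units"] = units
        if provenance:
            ds.attrs["provenance"] = json.dumps(provenance, default=str)


def load_volume(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        return load_tiff_stack(path), {}
    with h5py.File(path, "r") as f:
        ds = f["data"]
        attrs = {k: ds.attrs[k] for k in ds.attrs}
        return ds[()], attrs


def save_tiff_stack(path, data: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(data, dtype=np.float32))


def load_tiff_stack(path) -> np.ndarray:
    return tifffile.imread(str(path))


def load_config(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)


def save_frames(path, angles_rad, frame_sets, geometry) -> None:
    """Write a simulated scan: /reference/p<i> once (reference frames
    are angle-independent) and /sample/a<j>/p<i> per angle."""
    with h5py.File(path, "w") as f:
        f.attrs["geometry"] = json.dumps(
            {
                "energy_kev": geometry.energy_kev,
                "source_to_modulator_m": geometry.source_to_modulator_m,
                "modulator_to_sample_m": geometry.modulator_to_sample_m,
                "sample_to_detector_m": geometry.sample_to_detector_m,
                "detector_pixel_um": geometry.detector_pixel_um,
                "magnification": geometry.magnification,
            }
        )
        f.create_dataset("angles_rad", data=np.asarray(angles_rad))
        first = frame_sets[0]
        for i in range(first.n_positions):
            f.create_dataset(f"reference/p{i}", data=first.reference[i])
        for j, fs in enumerate(frame_sets):
            for i in range(fs.n_positions):
                f.create_dataset(f"sample/a{j}/p{i}", data=fs.sample[i])


def load_frames(path):
    """Inverse of :func:`save_frames`; returns (angles, frame_sets, geometry)."""
    from .geometry import ScanGeometry
    from .retrieval import ModulatedFrameSet

    with h5py.File(path, "r") as f:
        geom = ScanGeometry(**json.loads(f.attrs["geometry"]))
        angles = f["angles_rad"][()]
        n_pos = len(f["reference"])
        reference = np.stack([f[f"reference/p{i}"][()] for i in range(n_pos)])
        frame_sets = []
        for j in range(len(angles)):
            sample = np.stack([f[f"sample/a{j}/p{i}"][()] for i in range(n_pos)])
            frame_sets.append(
                ModulatedFrameSet(sample=sample, reference=reference.copy(), geometry=geom)
            )
    return angles, frame_sets, geom
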