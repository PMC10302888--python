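"""TIFF / YAML / JSON persistence for stacks, volumes and configs.

Image stacks travel as multi-page 32-bit float TIFF; grid metadata
(z positions, pixel size, normalization) lives in a YAML sidecar named
``<stem>.meta.yaml`` next to the TIFF.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .forward import Volume
from .optics import OpticalConfig, PSFStack

__all__ = [
    "load_optical_config", "save_optical_config",
    "save_psf_stack", "load_psf_stack",
    "save_volume", "load_volume",
    "read_frame_tiff", "write_frame_tiff",
    "write_json",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.yaml") \
        if path.suffix.lower() not in (".tif", ".tiff") \
        else path.with_name(path.stem + ".meta.yaml")


def load_optical_config(path: str | Path) -> OpticalConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    fields = {f.name for f in dataclasses.fields(OpticalConfig)}
    kwargs = {}
    for k, v in raw.items():
        if k not in fields:
            raise KeyError(f"unknown OpticalConfig field {k!r}")
        kwargs[k] = tuple(v) if isinstance(v, list) else v
    return OpticalConfig(**kwargs)


def save_optical_config(cfg: OpticalConfig, path: str | Path) -> None:
    d = dataclasses.asdict(cfg)
    d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def save_psf_stack(psf: PSFStack, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path, psf.data.astype(np.float32), photometric="minisblack")
    meta = {
        "z_positions_um": [float(z) for z in psf.z_positions_um],
        "pixel_um": float(psf.pixel_um),
        "normalization": psf.normalization,
        "lenslet_boxes": [list(map(int, b)) for b in psf.lenslet_boxes]
        if psf.lenslet_boxes else None,
    }
    with open(_sidecar(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def load_psf_stack(path: str | Path) -> PSFStack:
    path = Path(path)
    data = np.asarray(tifffile.imread(path), dtype=np.float64)
    with open(_sidecar(path)) as fh:
        meta = yaml.safe_load(fh)
    boxes = meta.get("lenslet_boxes")
    return PSFStack(data=data,
                    z_positions_um=np.asarray(meta["z_positions_um"]),
                    pixel_um=meta["pixel_um"],
                    normalization=meta.get("normalization", "per-slice-sum-one"),
                    lenslet_boxes=[tuple(b) for b in boxes] if boxes else None)


def save_volume(vol: Volume, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path, vol.data.astype(np.float32), photometric="minisblack")
    meta = {
        "voxel_size_um": [float(v) for v in vol.voxel_size_um],
        "z_positions_um": [float(z) for z in vol.z_positions_um],
    }
    with open(_sidecar(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def load_volume(path: str | Path) -> Volume:
    path = Path(path)
    data = np.asarray(tifffile.imread(path), dtype=np.float64)
    with open(_sidecar(path)) as fh:
        meta = yaml.safe_load(fh)
    return Volume(data=data,
                  voxel_size_um=tuple(meta["voxel_size_um"]),
                  z_positions_um=np.asarray(meta["z_positions_um"]))


def read_frame_tiff(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=np.float64)


def write_frame_tiff(data: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(Path(path), np.asarray(data, dtype=np.float32),
                     photometric="minisblack")


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
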