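"""NIfTI / sidecar I/O helpers."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Tuple

import nibabel as nib
import numpy as np

from .parametric import DynamicImage, FrameSchedule, ParametricImage

__all__ = ["load_dynamic", "load_mask", "load_volume", "save_volume", "load_schedule"]


def load_schedule(path) -> FrameSchedule:
    with open(path) as fh:
        return FrameSchedule.from_dict(json.load(fh))


def _voxel_size(img) -> Tuple[float, float, float]:
    return tuple(float(z) for z in img.header.get_zooms()[:3])


def load_dynamic(image_path, schedule_path) -> DynamicImage:
    """4D NIfTI + JSON timing sidecar ({frame_starts_min, frame_ends_min})."""
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{image_path} is not a 4D volume")
    return DynamicImage(
        data=data,
        voxel_size=_voxel_size(img),
        schedule=load_schedule(schedule_path),
    )


def load_mask(path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.dataobj) > 0


def load_volume(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), _voxel_size(img)


def save_volume(data: np.ndarray, voxel_size, path) -> None:
    affine = np.diag(list(voxel_size) + [1.0])
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def save_parametric(image: ParametricImage, path) -> None:
    dtype = np.int16 if image.kind == "TTP" else np.float32
    save_volume(image.data.astype(dtype), image.voxel_size, path)
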