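"""Image loading for the pipeline: grayscale PNG rasters and NIfTI slices.

Coordinate convention: arrays are row-major with 0-based indices; for a
NIfTI volume the sagittal direction is taken to be the first voxel axis of
the stored array, and ``slice_index`` counts from 0 along it.
"""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np

log = logging.getLogger(__name__)

__all__ = ["load_image"]

# ITU-R BT.601 luminance weights for the RGB fallback
_LUMA = np.array([0.299, 0.587, 0.114])

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def load_image(
    path, slice_index: int | None = None, rgb_mode: str = "luminance"
) -> np.ndarray:
    """Load a 2D float image from a PNG (8/16-bit) or a NIfTI volume.

    PNG intensities are scaled to [0, 1] by the dtype maximum.  RGB input is
    converted to luminance when ``rgb_mode="luminance"`` (default) and
    rejected when ``rgb_mode="error"``.  A 3D NIfTI requires
    ``slice_index``: the returned grid is ``volume[slice_index]`` (sagittal
    slice, first axis).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    name = path.name.lower()
    if any(name.endswith(s) for s in _NIFTI_SUFFIXES):
        return _load_nifti_slice(path, slice_index)
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        if rgb_mode == "error":
            raise ValueError(f"{path}: color image rejected (rgb_mode='error')")
        if rgb_mode != "luminance":
            raise ValueError(f"unknown rgb_mode {rgb_mode!r}")
        arr = arr[..., :3].astype(float) @ _LUMA
        log.info("%s: RGB converted to luminance", path)
    elif arr.ndim != 2:
        raise ValueError(f"{path}: unsupported image dimensionality {arr.ndim}")
    scale = float(np.iinfo(arr.dtype).max) if arr.dtype.kind in "ui" else 1.0
    return arr.astype(float) / scale


def _load_nifti_slice(path: Path, slice_index: int | None) -> np.ndarray:
    import nibabel as nib

    vol = np.asanyarray(nib.load(str(path)).dataobj).astype(float)
    vol = np.squeeze(vol)
    if vol.ndim == 2:
        return vol
    if vol.ndim != 3:
        raise ValueError(f"{path}: expected a 2D/3D NIfTI, got {vol.ndim}D")
    if slice_index is None:
        raise ValueError(
            f"{path}: a 3D volume needs slice_index (sagittal, first axis, 0-based)"
        )
    if not 0 <= slice_index < vol.shape[0]:
        raise ValueError(
            f"{path}: slice_index {slice_index} out of range [0, {vol.shape[0]})"
        )
    log.info("%s: extracted sagittal slice %d (first voxel axis)", path, slice_index)
    return vol[slice_index]
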