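"""NIfTI-1 input/output helpers.

Volumes come and go through nibabel; the masked grid carries the NIfTI
affine so peak coordinates can be reported in world millimetres (MNI when
the mask is MNI-registered).
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .grid import MaskedGrid

__all__ = [
    "load_mask",
    "load_prob_maps",
    "extract_timecourses",
    "save_voxel_map",
]


def _voxel_sizes(img) -> tuple[float, ...]:
    return tuple(float(z) for z in img.header.get_zooms()[:3])


def load_mask(path) -> MaskedGrid:
    """Load a binary mask volume as a MaskedGrid (nonzero = inside)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"mask {path} must be 3-D, got {data.ndim}-D")
    return MaskedGrid(data != 0, voxel_size_mm=_voxel_sizes(img),
                      affine=img.affine)


def load_prob_maps(paths) -> tuple[list[np.ndarray], tuple, np.ndarray]:
    """Load probabilistic maps, checking that all share one grid."""
    maps, zooms, affine = [], None, None
    for p in paths:
        img = nib.load(str(p))
        data = np.asanyarray(img.dataobj).astype(float)
        if maps and data.shape != maps[0].shape:
            raise ValueError(
                f"{p} grid {data.shape} differs from {maps[0].shape}"
            )
        if affine is not None and not np.allclose(img.affine, affine):
            raise ValueError(f"{p} affine differs from the first map's")
        maps.append(data)
        zooms, affine = _voxel_sizes(img), img.affine
    if not maps:
        raise ValueError("no probability maps given")
    return maps, zooms, affine


def extract_timecourses(path, grid: MaskedGrid) -> np.ndarray:
    """Masked (N, T) timecourses from a 4-D volume."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{path} must be 4-D, got {data.ndim}-D")
    if data.shape[:3] != grid.shape:
        raise ValueError(
            f"{path} spatial shape {data.shape[:3]} does not match the "
            f"mask {grid.shape}"
        )
    return data[grid.mask].astype(float)


def save_voxel_map(values: np.ndarray, grid: MaskedGrid, path) -> None:
    """Write a per-voxel array back into image space as a NIfTI volume."""
    vol = grid.embed(np.asarray(values)).astype(np.float32)
    if vol.ndim == 2:  # single-slice analyses are stored as thin 3-D volumes
        vol = vol[..., None]
    affine = grid.affine
    if affine is None or affine.shape != (4, 4):
        zooms = list(grid.voxel_size_mm) + [1.0] * (3 - grid.ndim)
        affine = np.diag(zooms + [1.0])
    nib.save(nib.Nifti1Image(vol, affine), str(path))
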