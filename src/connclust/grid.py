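"""Masked voxel grids and spatial adjacency.

The voxel universe for a connectome analysis is a binary mask over a 2-D or
3-D grid.  Masked voxels are enumerated in a fixed C-scan (row-major) order,
giving every voxel a flat index ``0..N-1``; connectivity matrices, link-count
arrays and cluster member lists all refer to this ordering, so matrices built
on the same grid are directly comparable across scans and subjects.

Spatial cluster adjacency follows the face-or-edge convention: 18-connectivity
on 3-D grids, 8-connectivity (including diagonals) on 2-D grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["MaskedGrid", "connectivity_structure", "neighborhood_size"]


def connectivity_structure(ndim: int) -> np.ndarray:
    """Binary structuring element defining spatial cluster adjacency.

    Voxels belong to the same cluster when they share a face or an edge:
    18-connectivity in 3-D.  On 2-D grids the analogue used is 8-connectivity
    (all in-plane neighbours including diagonals).

    Parameters
    ----------
    ndim : int
        Grid dimensionality, 2 or 3.

    Returns
    -------
    numpy.ndarray
        Boolean structuring element of shape ``(3,) * ndim`` suitable for
        :func:`scipy.ndimage.label`.
    """
    if ndim == 2:
        return ndimage.generate_binary_structure(2, 2)
    if ndim == 3:
        return ndimage.generate_binary_structure(3, 2)
    raise ValueError(f"grids must be 2-D or 3-D, got ndim={ndim}")


def neighborhood_size(ndim: int) -> int:
    """Number of voxels in the adjacency neighbourhood including the centre.

    For 3-D face-or-edge adjacency this is 19 — a voxel plus its 18
    neighbours — the natural smallest cluster that still spans a voxel and
    everything it shares substantial signal with under typical smoothing.
    """
    return int(connectivity_structure(ndim).sum())


@dataclass
class MaskedGrid:
    """A binary mask over a regular grid with flat-index bookkeeping.

    Parameters
    ----------
    mask : numpy.ndarray
        Boolean array, 2-D or 3-D.  True cells are the analysis voxels.
    voxel_size_mm : tuple of float
        Physical edge length of a voxel along each axis, in millimetres.
    affine : numpy.ndarray, optional
        ``(ndim+1, ndim+1)`` voxel-to-world transform (NIfTI convention).
        When absent, world coordinates are voxel index times voxel size.
    """

    mask: np.ndarray
    voxel_size_mm: tuple[float, ...] = (1.0,)
    affine: np.ndarray | None = None
    _coords: np.ndarray = field(init=False, repr=False)
    _index_vol: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim not in (2, 3):
            raise ValueError(f"mask must be 2-D or 3-D, got {self.mask.ndim}-D")
        if len(self.voxel_size_mm) == 1:
            self.voxel_size_mm = tuple(self.voxel_size_mm) * self.mask.ndim
        if len(self.voxel_size_mm) != self.mask.ndim:
            raise ValueError("voxel_size_mm length must match mask dimensionality")
        self._coords = np.argwhere(self.mask)  # C-scan order
        if self.n_voxels < 2:
            raise ValueError(
                f"mask must contain at least two voxels, got {self.n_voxels}"
            )
        self._index_vol = np.full(self.mask.shape, -1, dtype=np.int64)
        self._index_vol[self.mask] = np.arange(self.n_voxels)

    # -- basic geometry -------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.mask.shape

    @property
    def ndim(self) -> int:
        return self.mask.ndim

    @property
    def n_voxels(self) -> int:
        """Number of voxels inside the mask (N)."""
        return len(self._coords)

    @property
    def coords(self) -> np.ndarray:
        """``(N, ndim)`` grid coordinates of mask voxels in flat-index order."""
        return self._coords

    def index_of(self, coord) -> int:
        """Flat voxel index of a grid coordinate inside the mask."""
        idx = int(self._index_vol[tuple(coord)])
        if idx < 0:
            raise KeyError(f"coordinate {tuple(coord)} is outside the mask")
        return idx

    def coord_of(self, index: int) -> tuple[int, ...]:
        """Grid coordinate of a flat voxel index."""
        return tuple(int(c) for c in self._coords[index])

    def world_coords(self, coords: np.ndarray) -> np.ndarray:
        """Map grid coordinates to world mm via the affine (or voxel size)."""
        coords = np.atleast_2d(coords).astype(float)
        if self.affine is not None:
            homo = np.c_[coords, np.ones(len(coords))]
            return (homo @ self.affine.T)[:, : self.ndim]
        return coords * np.asarray(self.voxel_size_mm)

    # -- embedding ------------------------------------------------------

    def embed(self, values: np.ndarray, fill=0) -> np.ndarray:
        """Place a length-N array of per-voxel values into a full volume."""
        values = np.asarray(values)
        if values.shape[0] != self.n_voxels:
            raise ValueError(
                f"expected {self.n_voxels} values, got {values.shape[0]}"
            )
        vol = np.full(self.mask.shape + values.shape[1:], fill, dtype=values.dtype)
        vol[self.mask] = values
        return vol

    def extract(self, volume: np.ndarray) -> np.ndarray:
        """Read per-voxel values out of a full volume, in flat-index order."""
        if volume.shape[: self.ndim] != self.shape:
            raise ValueError("volume shape does not match grid shape")
        return volume[self.mask]

    @property
    def structure(self) -> np.ndarray:
        """Cluster adjacency structuring element for this grid's ndim."""
        return connectivity_structure(self.ndim)

    def mask_hash(self) -> str:
        """Short stable hash of the mask contents, for provenance sidecars."""
        import hashlib

        h = hashlib.sha256()
        h.update(np.asarray(self.shape, dtype=np.int64).tobytes())
        h.update(np.packbits(self.mask.ravel()).tobytes())
        return h.hexdigest()[:16]
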