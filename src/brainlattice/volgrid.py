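"""Voxel grid over a brain mask.

Everything downstream works on flattened in-mask vectors: a :class:`Grid`
fixes the affine, the mask and a stable linear ordering of in-mask voxels,
and converts between mm coordinates, 3D volumes and flat vectors. Reported
activation peaks (points in MNI mm space) are turned into binary voxel
activations by stamping a hard sphere of configurable radius around each
peak — a voxel is "active" for a study if its center lies within the radius
of any of the study's peaks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

#: Default radius (mm) of the sphere stamped around each reported peak.
DEFAULT_SPHERE_RADIUS = 10.0


class GridError(ValueError):
    """Shape/affine mismatch or invalid grid construction."""


@dataclass
class Grid:
    """A voxel grid: 4x4 mm<->voxel affine plus a boolean brain mask.

    In-mask voxels get linear indices ``0..n_voxels-1`` in C (row-major)
    scan order of the mask array; that ordering is the coordinate system of
    every flattened map in the package.
    """

    affine: np.ndarray
    mask: np.ndarray
    _ijk: np.ndarray = field(init=False, repr=False)
    _centers: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise GridError(f"affine must be 4x4, got {self.affine.shape}")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise GridError("affine is not invertible")
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise GridError(f"mask must be 3D, got {self.mask.ndim}D")
        self._ijk = np.argwhere(self.mask)
        self._centers = self._ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    # -- basic geometry -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def n_voxels(self) -> int:
        """Count of in-mask voxels."""
        return len(self._ijk)

    @property
    def voxel_centers(self) -> np.ndarray:
        """(n_voxels, 3) mm coordinates of in-mask voxel centers."""
        return self._centers

    def mm_to_voxel(self, xyz) -> np.ndarray:
        """Map mm coordinates to the nearest voxel index (may be out of bounds)."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        ijk = xyz @ inv[:3, :3].T + inv[:3, 3]
        return np.rint(ijk).astype(int)

    def contains_mm(self, xyz) -> np.ndarray:
        """True where the mm point falls on an in-mask voxel."""
        ijk = self.mm_to_voxel(xyz)
        ok = np.all((ijk >= 0) & (ijk < np.array(self.shape)), axis=1)
        out = np.zeros(len(ijk), dtype=bool)
        if ok.any():
            sub = ijk[ok]
            out[ok] = self.mask[sub[:, 0], sub[:, 1], sub[:, 2]]
        return out

    def nearest_voxel_index(self, xyz) -> int:
        """Linear in-mask index of the voxel center nearest to ``xyz`` (mm)."""
        xyz = np.asarray(xyz, dtype=float)
        d2 = ((self._centers - xyz) ** 2).sum(axis=1)
        return int(np.argmin(d2))

    # -- flatten / unflatten --------------------------------------------

    def vectorize(self, volume: np.ndarray) -> np.ndarray:
        """Extract the in-mask values of a 3D volume as a flat vector."""
        volume = np.asarray(volume)
        if volume.shape != self.shape:
            raise GridError(
                f"volume shape {volume.shape} does not match grid {self.shape}"
            )
        return volume[self.mask]

    def unvectorize(self, vector: np.ndarray) -> np.ndarray:
        """Scatter a flat in-mask vector back into a 3D volume (0 outside mask)."""
        vector = np.asarray(vector)
        if vector.shape != (self.n_voxels,):
            raise GridError(
                f"vector length {vector.shape} does not match n_voxels {self.n_voxels}"
            )
        out = np.zeros(self.shape, dtype=vector.dtype)
        out[self.mask] = vector
        return out

    # -- I/O -------------------------------------------------------------

    def to_image(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.mask.astype(np.uint8), self.affine)

    @classmethod
    def from_image(cls, img: nib.Nifti1Image, threshold: float = 0.5) -> "Grid":
        data = np.asanyarray(img.dataobj)
        return cls(affine=np.asarray(img.affine), mask=data > threshold)

    @classmethod
    def ellipsoid(
        cls,
        resolution: float = 8.0,
        semiaxes: tuple[float, float, float] = (64.0, 80.0, 64.0),
    ) -> "Grid":
        """Synthetic brain-shaped mask: an axis-aligned ellipsoid centered at
        the mm origin, sampled at isotropic ``resolution``.

        Semiaxes default to roughly brain-sized extents so MNI-plausible
        coordinates fall inside. Test suites use this at coarse resolution.
        """
        semiaxes = np.asarray(semiaxes, dtype=float)
        if resolution <= 0 or np.any(semiaxes <= 0):
            raise GridError("resolution and semiaxes must be positive")
        shape = (2 * np.ceil(semiaxes / resolution) + 3).astype(int)
        center = (shape - 1) / 2.0
        affine = np.diag([resolution] * 3 + [1.0])
        affine[:3, 3] = -resolution * center
        idx = np.indices(shape)
        mm = (idx - center.reshape(3, 1, 1, 1)) * resolution
        inside = ((mm / semiaxes.reshape(3, 1, 1, 1)) ** 2).sum(axis=0) <= 1.0
        return cls(affine=affine, mask=inside)


@dataclass
class ActivationMatrix:
    """Binary studies x in-mask-voxels matrix: 1 where a study reports
    activation at (within the stamping radius of) that voxel."""

    studies: list[str]
    values: np.ndarray  # (n_studies, n_voxels) uint8

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.studies):
            raise GridError("activation matrix shape does not match study list")
        if not np.isin(self.values, (0, 1)).all():
            raise GridError("activation matrix must be binary")
        self.values = self.values.astype(np.uint8)

    @property
    def n_studies(self) -> int:
        return len(self.studies)

    def row(self, study_id: str) -> np.ndarray:
        return self.values[self.studies.index(study_id)]


def stamp_spheres(peaks, grid: Grid, radius: float = DEFAULT_SPHERE_RADIUS) -> np.ndarray:
    """Binary in-mask vector: 1 at every voxel whose center lies within
    ``radius`` mm of any peak.

    A peak whose sphere misses the mask entirely contributes nothing and
    triggers a warning (it is usually a sign of a bad coordinate).
    """
    if radius < 0:
        raise GridError("radius must be >= 0")
    peaks = np.atleast_2d(np.asarray(peaks, dtype=float))
    out = np.zeros(grid.n_voxels, dtype=np.uint8)
    if peaks.size == 0:
        return out
    r2 = radius**2
    for peak in peaks:
        d2 = ((grid.voxel_centers - peak) ** 2).sum(axis=1)
        hit = d2 <= r2
        if not hit.any():
            warnings.warn(
                f"peak {tuple(np.round(peak, 1))} contributes no in-mask voxel "
                f"at radius {radius}",
                stacklevel=2,
            )
        out[hit] = 1
    return out


def activation_matrix(tables, grid: Grid, radius: float = DEFAULT_SPHERE_RADIUS) -> ActivationMatrix:
    """One row per study: the union of stamped spheres of its peaks.

    Studies are ordered by sorted study_id so the row order is reproducible
    regardless of input row order.
    """
    coords = tables.coordinates
    if len(coords) == 0:
        raise GridError("coordinates table is empty")
    studies = sorted(coords["study_id"].unique())
    values = np.zeros((len(studies), grid.n_voxels), dtype=np.uint8)
    grouped = coords.groupby("study_id")
    for i, sid in enumerate(studies):
        peaks = grouped.get_group(sid)[["x", "y", "z"]].to_numpy(dtype=float)
        row = stamp_spheres(peaks, grid, radius)
        if row.sum() == 0:
            logger.warning("study %s: no peak stamped any in-mask voxel", sid)
        values[i] = row
    return ActivationMatrix(studies=studies, values=values)


def read_volume(path, grid: Grid | None = None) -> np.ndarray:
    """Read a NIfTI volume; if a grid is given, enforce matching shape/affine."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if grid is not None:
        if data.shape != grid.shape:
            raise GridError(
                f"volume shape {data.shape} does not match grid {grid.shape}"
            )
        if not np.allclose(img.affine, grid.affine, atol=1e-4):
            raise GridError("volume affine does not match grid affine")
    return data


def write_volume(volume: np.ndarray, grid: Grid, path) -> None:
    """Write a 3D volume (or flat in-mask vector, which is unvectorized first)."""
    volume = np.asarray(volume)
    if volume.ndim == 1:
        volume = grid.unvectorize(volume)
    if volume.shape != grid.shape:
        raise GridError(
            f"volume shape {volume.shape} does not match grid {grid.shape}"
        )
    nib.save(nib.Nifti1Image(volume.astype(np.float32), grid.affine), str(path))
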