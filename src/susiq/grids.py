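"""Voxel grids and intensity volumes.

World coordinates are millimetres with the origin at the *center* of the
grid (center of the central voxel for odd shapes), axes ordered (x, y, z) =
(right-left, posterior-anterior, inferior-superior). Voxel indices are
0-based. These conventions are fixed so that NIfTI affines written by this
package are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["VoxelGrid", "Volume", "TEMPLATE_GRID", "PATIENT_GRID"]


@dataclasses.dataclass(frozen=True)
class VoxelGrid:
    """Regular 3D voxel lattice with isotropic-or-not spacing in mm."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        vsize = tuple(float(v) for v in self.voxel_size)
        if len(shape) != 3 or len(vsize) != 3:
            raise ValueError("grid must be three-dimensional")
        if any(s < 8 for s in shape):
            raise ValueError(f"all grid dimensions must be >= 8 voxels, got {shape}")
        if any(v <= 0 for v in vsize):
            raise ValueError(f"voxel sizes must be positive, got {vsize}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size", vsize)

    @property
    def voxel_volume_mm3(self) -> float:
        vx, vy, vz = self.voxel_size
        return vx * vy * vz

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    @property
    def origin(self) -> np.ndarray:
        """World mm coordinate of the center of voxel (0, 0, 0)."""
        return -(np.asarray(self.shape, float) - 1.0) / 2.0 * np.asarray(self.voxel_size)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        return np.asarray(ijk, float) * np.asarray(self.voxel_size) + self.origin

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        return (np.asarray(xyz, float) - self.origin) / np.asarray(self.voxel_size)

    def coordinate_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World mm coordinates per axis, broadcastable to ``shape``."""
        o = self.origin
        xs = o[0] + np.arange(self.shape[0]) * self.voxel_size[0]
        ys = o[1] + np.arange(self.shape[1]) * self.voxel_size[1]
        zs = o[2] + np.arange(self.shape[2]) * self.voxel_size[2]
        return xs[:, None, None], ys[None, :, None], zs[None, None, :]

    def nifti_affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size)
        aff[:3, 3] = self.origin
        return aff

    @classmethod
    def from_nifti_affine(cls, shape, affine) -> "VoxelGrid":
        vsize = tuple(round(float(v), 6) for v in np.diag(affine)[:3])
        grid = cls(tuple(shape), vsize)
        # NIfTI stores the affine in float32; compare at that precision
        if not np.allclose(affine, grid.nifti_affine(), atol=1e-3):
            raise ValueError("NIfTI affine is not an origin-centered diagonal affine")
        return grid


#: Template-space grid: 91 x 109 x 91 cubic voxels of 2 mm edge length.
TEMPLATE_GRID = VoxelGrid((91, 109, 91), (2.0, 2.0, 2.0))

#: Native patient-space grid with 3.9 mm cubic voxels (clinical mono-camera style).
PATIENT_GRID = VoxelGrid((47, 56, 47), (3.9, 3.9, 3.9))


@dataclasses.dataclass
class Volume:
    """A 3D intensity image (counts per voxel) on a :class:`VoxelGrid`.

    ``meta`` carries provenance (applied rigid transform, field-of-view
    warnings, per-subject truth) without affecting numeric identity.
    """

    grid: VoxelGrid
    data: np.ndarray
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if tuple(self.data.shape) != self.grid.shape:
            raise ValueError(
                f"data shape {self.data.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")

    @property
    def total_counts(self) -> float:
        return float(self.data.sum(dtype=np.float64))

    def copy(self) -> "Volume":
        return Volume(self.grid, self.data.copy(), dict(self.meta))

    def save(self, path: str | Path) -> None:
        img = nib.Nifti1Image(np.asarray(self.data, np.float32), self.grid.nifti_affine())
        nib.save(img, str(path))

    @classmethod
    def load(cls, path: str | Path) -> "Volume":
        img = nib.load(str(path))
        grid = VoxelGrid.from_nifti_affine(img.shape, img.affine)
        return cls(grid, np.asarray(img.dataobj, np.float32))


def save_labels(labels: np.ndarray, grid: VoxelGrid, path: str | Path,
                label_map: dict[str, int] | None = None) -> None:
    """Write an integer label volume as NIfTI plus an optional JSON label map."""
    img = nib.Nifti1Image(np.asarray(labels, np.int16), grid.nifti_affine())
    nib.save(img, str(path))
    if label_map is not None:
        p = Path(str(path).removesuffix(".gz").removesuffix(".nii") + "_labels.json")
        p.write_text(json.dumps(label_map, indent=2, sort_keys=True))


def load_labels(path: str | Path) -> tuple[np.ndarray, VoxelGrid]:
    img = nib.load(str(path))
    grid = VoxelGrid.from_nifti_affine(img.shape, img.affine)
    return np.asarray(img.dataobj, np.int16), grid
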