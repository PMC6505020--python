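"""Parametric striatal anatomy and ROI construction.

The package does not ship an anatomical atlas. Instead, caudate and putamen
are modelled as ellipsoids placed symmetrically about the midline, the brain
as a large ellipsoidal envelope, and thalamus/brainstem as box stand-ins
that are only used to carve the reference region. Users with real atlas
masks can bypass this module entirely and supply their own label volumes.

Three ROI families are produced:

* anatomical ROIs (caudate, anterior/posterior putamen, their unions) used
  for the specific binding ratio (SBR),
* large ROIs (anatomical masks dilated by a spill-out margin, mutually
  disjoint, with the putamen's large ROI truncated at the putamen's
  anterior margin to limit caudate cross-talk) used for the specific
  uptake size index (SUSI),
* the reference region (brain envelope minus the large-ROI margin around
  the striata, minus thalamus and brainstem stand-ins) whose 75th intensity
  percentile estimates non-displaceable binding.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import ndimage

from .grids import VoxelGrid

__all__ = [
    "StriatalGeometry",
    "RoiSet",
    "make_roi_set",
    "COMPARTMENTS",
    "GeometryError",
]

#: Canonical compartment names (one entry per unilateral structure).
COMPARTMENTS = (
    "caudate_L",
    "caudate_R",
    "putamen_ant_L",
    "putamen_ant_R",
    "putamen_post_L",
    "putamen_post_R",
)

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


class GeometryError(ValueError):
    """Raised when the requested geometry cannot be realized on the grid."""


@dataclasses.dataclass(frozen=True)
class StriatalGeometry:
    """All lengths in mm, volumes in mL; left hemisphere is x > 0.

    ``large_margin_mm`` defaults to twice the Gaussian sigma of the largest
    supported point-spread FWHM: wide enough that spill-out loss from the
    large ROIs stays around one percent at the worst supported resolution,
    while leaving enough deep brain tissue for a stable reference estimate.
    """

    brain_semi: tuple[float, float, float] = (64.0, 78.0, 58.0)
    caudate_center: tuple[float, float, float] = (13.0, 14.0, 8.0)
    caudate_semi: tuple[float, float, float] = (6.0, 16.0, 10.0)
    putamen_center: tuple[float, float, float] = (28.0, -2.0, 2.0)
    putamen_semi: tuple[float, float, float] = (7.5, 20.0, 8.5)
    caudate_volume_ml: float = 4.0
    putamen_volume_ml: float = 5.5
    thalamus_box: tuple[tuple[float, float], ...] = ((-18.0, 18.0), (-28.0, -6.0), (-2.0, 14.0))
    brainstem_box: tuple[tuple[float, float], ...] = ((-13.0, 13.0), (-40.0, -16.0), (-58.0, -6.0))
    max_fwhm_mm: float = 14.0
    #: The large putamen ROI is truncated at the coronal plane lying this
    #: fraction of the putamen's anterior-posterior extent behind its
    #: anterior margin. At the default 0.0 the plane sits exactly at the
    #: anterior margin: the anatomical putamen stays fully inside its large
    #: ROI, but anterior spill-out is excluded (falling to the large caudate
    #: ROI), which limits caudate cross-talk in the putaminal SUSI.
    anterior_trunc_fraction: float = 0.0
    candidate_radius: float = 1.45  # max linear scale of compartment ellipsoids

    @property
    def large_margin_mm(self) -> float:
        return 2.0 * self.max_fwhm_mm * FWHM_TO_SIGMA

    def scaled(self, factor: float) -> "StriatalGeometry":
        """Uniformly scaled geometry (lengths x factor, volumes x factor^3)."""
        s = float(factor)

        def v3(t):
            return tuple(x * s for x in t)

        def box(b):
            return tuple((lo * s, hi * s) for lo, hi in b)

        return dataclasses.replace(
            self,
            brain_semi=v3(self.brain_semi),
            caudate_center=v3(self.caudate_center),
            caudate_semi=v3(self.caudate_semi),
            putamen_center=v3(self.putamen_center),
            putamen_semi=v3(self.putamen_semi),
            caudate_volume_ml=self.caudate_volume_ml * s**3,
            putamen_volume_ml=self.putamen_volume_ml * s**3,
            thalamus_box=box(self.thalamus_box),
            brainstem_box=box(self.brainstem_box),
            max_fwhm_mm=self.max_fwhm_mm * s,
        )


@dataclasses.dataclass
class RoiSet:
    """Named boolean masks on a grid, plus compartment voxel orderings.

    ``candidates`` maps each compartment name to a flat-index array of voxels
    sorted by increasing normalized ellipsoid radius; a phantom compartment
    of true volume ``V`` is realized as the first ``round(V / voxel_volume)``
    entries, so realized volume matches the target within one voxel.
    Mapped ROI sets (patient space) carry masks only.
    """

    grid: VoxelGrid
    masks: dict[str, np.ndarray]
    geometry: StriatalGeometry | None = None
    candidates: dict[str, np.ndarray] | None = None
    mapped_volumes_ml: dict[str, float] | None = None

    @property
    def anterior_fraction(self) -> float:
        """Fraction of the template putamen anterior to the split plane."""
        return self.volume_ml("putamen_ant_L") / self.volume_ml("putamen_L")

    def mask(self, name: str) -> np.ndarray:
        if name not in self.masks:
            raise KeyError(f"ROI set has no mask named {name!r}")
        return self.masks[name]

    def volume_ml(self, name: str) -> float:
        return float(self.mask(name).sum()) * self.grid.voxel_volume_ml

    def to_labels(self, names: list[str]) -> tuple[np.ndarray, dict[str, int]]:
        """Pack non-overlapping masks into one integer label volume."""
        labels = np.zeros(self.grid.shape, np.int16)
        label_map: dict[str, int] = {}
        for i, name in enumerate(names, start=1):
            m = self.mask(name)
            if np.any(labels[m]):
                raise ValueError(f"mask {name!r} overlaps a previously packed mask")
            labels[m] = i
            label_map[name] = i
        return labels, label_map

    @classmethod
    def from_labels(cls, labels: np.ndarray, grid: VoxelGrid,
                    label_map: dict[str, int]) -> "RoiSet":
        masks = {name: labels == value for name, value in label_map.items()}
        return cls(grid=grid, masks=masks)


def _ellipsoid_radius2(grid: VoxelGrid, center, semi) -> np.ndarray:
    xs, ys, zs = grid.coordinate_arrays()
    return (
        ((xs - center[0]) / semi[0]) ** 2
        + ((ys - center[1]) / semi[1]) ** 2
        + ((zs - center[2]) / semi[2]) ** 2
    )


def _box_mask(grid: VoxelGrid, box) -> np.ndarray:
    xs, ys, zs = grid.coordinate_arrays()
    (x0, x1), (y0, y1), (z0, z1) = box
    return (
        (xs >= x0) & (xs <= x1) & (ys >= y0) & (ys <= y1) & (zs >= z0) & (zs <= z1)
    )


def _select_k(r2: np.ndarray, restrict: np.ndarray | None, k: int,
              cap2: float) -> np.ndarray:
    """Flat indices of the k voxels with smallest ellipsoid radius."""
    ok = r2 <= cap2
    if restrict is not None:
        ok &= restrict
    idx = np.flatnonzero(ok)
    if k > idx.size:
        raise GeometryError(
            f"compartment needs {k} voxels but only {idx.size} candidates exist"
        )
    order = np.argsort(r2.flat[idx], kind="stable")
    return idx[order[:k]]


def make_roi_set(grid: VoxelGrid, geometry: StriatalGeometry | None = None) -> RoiSet:
    """Build anatomical, large (SUSI) and reference masks on ``grid``.

    Raises :class:`GeometryError`, naming the offending compartment, if a
    large ROI would collide with the brain envelope (spill-out would then be
    irrecoverably lost to zero-intensity voxels outside the head).
    """
    geom = geometry or StriatalGeometry()
    vox_ml = grid.voxel_volume_ml
    xs, ys, zs = grid.coordinate_arrays()
    brain = _ellipsoid_radius2(grid, (0.0, 0.0, 0.0), geom.brain_semi) <= 1.0
    if not brain.any():
        raise GeometryError("brain envelope does not intersect the grid")

    cap2 = geom.candidate_radius**2
    masks: dict[str, np.ndarray] = {"brain": brain}
    candidates: dict[str, np.ndarray] = {}
    anat: dict[str, np.ndarray] = {}

    for side, sign in (("L", 1.0), ("R", -1.0)):
        cc = (sign * geom.caudate_center[0], geom.caudate_center[1], geom.caudate_center[2])
        pc = (sign * geom.putamen_center[0], geom.putamen_center[1], geom.putamen_center[2])
        r2_cau = _ellipsoid_radius2(grid, cc, geom.caudate_semi)
        r2_put = _ellipsoid_radius2(grid, pc, geom.putamen_semi)
        anterior = (ys >= pc[1]) & np.ones(grid.shape, bool)
        k_cau = int(round(geom.caudate_volume_ml / vox_ml))
        k_put = int(round(geom.putamen_volume_ml / vox_ml))
        if min(k_cau, k_put) < 1:
            raise GeometryError("compartment volume smaller than one voxel")

        cau_idx = _select_k(r2_cau, None, k_cau, cap2)
        put_idx = _select_k(r2_put, None, k_put, cap2)
        cau = np.zeros(grid.shape, bool)
        cau.flat[cau_idx] = True
        put = np.zeros(grid.shape, bool)
        put.flat[put_idx] = True
        overlap = cau & put
        if overlap.any():
            # contested voxels go to the nearer compartment (normalized radius)
            to_put = overlap & (r2_put < r2_cau)
            cau &= ~to_put
            put &= ~(overlap & ~to_put)

        anat[f"caudate_{side}"] = cau
        anat[f"putamen_{side}"] = put
        anat[f"putamen_ant_{side}"] = put & anterior
        anat[f"putamen_post_{side}"] = put & ~anterior
        candidates[f"caudate_{side}"] = _select_k(
            r2_cau, None, int((r2_cau <= cap2).sum()), cap2
        )
        candidates[f"putamen_ant_{side}"] = _select_k(
            r2_put, anterior, int(((r2_put <= cap2) & anterior).sum()), cap2
        )
        candidates[f"putamen_post_{side}"] = _select_k(
            r2_put, ~anterior, int(((r2_put <= cap2) & ~anterior).sum()), cap2
        )

    masks.update(anat)
    for side in ("L", "R"):
        masks[f"striatum_{side}"] = masks[f"caudate_{side}"] | masks[f"putamen_{side}"]

    # --- large ROIs: margin dilation, disjoint by nearest structure ---------
    margin = geom.large_margin_mm
    structures = ["caudate_L", "caudate_R", "putamen_L", "putamen_R"]
    dist = np.stack(
        [
            ndimage.distance_transform_edt(~masks[s], sampling=grid.voxel_size)
            for s in structures
        ]
    )
    in_margin = dist.min(axis=0) <= margin
    nearest = np.argmin(dist, axis=0)

    outside = in_margin & ~brain
    if outside.any():
        bad = structures[int(np.bincount(nearest[outside]).argmax())]
        raise GeometryError(
            f"large ROI of {bad} collides with the brain boundary; "
            "shrink the margin or enlarge the brain envelope"
        )

    large: dict[str, np.ndarray] = {
        s: in_margin & (nearest == i) for i, s in enumerate(structures)
    }
    # truncate the large putamen anterior to the putamen's anterior quarter
    for i, side in ((2, "L"), (3, "R")):
        put = masks[f"putamen_{side}"]
        yvals = np.broadcast_to(ys, grid.shape)[put]
        y_cut = yvals.max() - geom.anterior_trunc_fraction * (yvals.max() - yvals.min())
        drop = large[f"putamen_{side}"] & (np.broadcast_to(ys, grid.shape) > y_cut)
        large[f"putamen_{side}"] &= ~drop
        # truncated voxels fall back to the nearer large caudate ROI, so the
        # striatal union (caudate + putamen large ROI) still captures all
        # striatal counts
        to_left = drop & (dist[0] <= dist[1])
        large["caudate_L"] |= to_left
        large["caudate_R"] |= drop & ~to_left

    for side in ("L", "R"):
        masks[f"large_caudate_{side}"] = large[f"caudate_{side}"]
        masks[f"large_putamen_{side}"] = large[f"putamen_{side}"]
        masks[f"large_striatum_{side}"] = large[f"caudate_{side}"] | large[f"putamen_{side}"]

    reference = (
        brain
        & ~in_margin
        & ~_box_mask(grid, geom.thalamus_box)
        & ~_box_mask(grid, geom.brainstem_box)
    )
    if not reference.any():
        raise GeometryError("reference region is empty under this geometry")
    masks["reference"] = reference

    return RoiSet(grid=grid, masks=masks, geometry=geom, candidates=candidates)


#: Geometry preset small enough for a 32 voxel cube at 2 mm (smoke tests).
TINY_GEOMETRY = StriatalGeometry().scaled(0.32)
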