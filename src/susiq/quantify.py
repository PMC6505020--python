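"""SBR and SUSI semi-quantification of a single subject.

Two semi-quantitative measures of specific striatal tracer binding:

* SBR = (C - CR) / CR, with C the mean count concentration over an
  anatomical ROI. Resolution-dependent through partial-volume effects.
* SUSI = (T - CR * V) / CR, with T the total counts in a large ROI times
  the voxel volume and V the large-ROI volume. SUSI has units of mL
  (SUSI = BPnd * Vs for an ideal count-conserving image) and is independent
  of spatial resolution as long as the large ROI captures all spill-out.

CR is the 75th percentile of voxel intensities in the reference region
(whole brain without striata, thalamus and brainstem). Percentiles use
linear interpolation between order statistics at fractional index
``q * (n - 1)``; this convention is fixed so CR is bit-stable.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .anatomy import RoiSet
from .grids import Volume

__all__ = [
    "ReferenceEstimate",
    "QuantComponents",
    "SubjectQuant",
    "estimate_reference",
    "compute_sbr",
    "compute_susi",
    "quantify_subject",
    "quantify_cohort",
    "SBR_REGIONS",
    "SUSI_REGIONS",
]

#: regions quantified by SBR (anatomical masks), per hemisphere
SBR_REGIONS = ("caudate", "putamen", "putamen_ant", "putamen_post", "striatum")
#: regions quantified by SUSI (large masks), per hemisphere
SUSI_REGIONS = ("caudate", "putamen", "striatum")


@dataclasses.dataclass(frozen=True)
class ReferenceEstimate:
    """Reference-region summary: CR (P75), P25, and relative IQR."""

    cr: float
    p25: float

    def __post_init__(self) -> None:
        if self.cr <= 0:
            raise ValueError("reference estimate CR must be positive (degenerate image)")
        if self.p25 > self.cr:
            raise ValueError("p25 cannot exceed the 75th percentile")

    @property
    def rel_iqr(self) -> float:
        return (self.cr - self.p25) / self.cr


@dataclasses.dataclass(frozen=True)
class QuantComponents:
    """Raw ingredients of one measure: C (mean counts/voxel), T, V."""

    c: float
    t: float
    v: float


def estimate_reference(vol: Volume, ref_mask: np.ndarray) -> ReferenceEstimate:
    vals = vol.data[ref_mask]
    if vals.size == 0:
        raise ValueError("reference mask is empty")
    p25, p75 = np.percentile(vals.astype(np.float64), [25.0, 75.0])
    return ReferenceEstimate(cr=float(p75), p25=float(p25))


def compute_sbr(vol: Volume, anat_mask: np.ndarray, ref: ReferenceEstimate) -> float:
    vals = vol.data[anat_mask]
    if vals.size == 0:
        raise ValueError("anatomical mask is empty")
    c = float(vals.mean(dtype=np.float64))
    return (c - ref.cr) / ref.cr


def compute_susi(vol: Volume, large_mask: np.ndarray, ref: ReferenceEstimate,
                 voxel_volume_ml: float) -> float:
    vals = vol.data[large_mask]
    if vals.size == 0:
        raise ValueError("large mask is empty")
    t = float(vals.sum(dtype=np.float64)) * voxel_volume_ml
    v = vals.size * voxel_volume_ml
    return (t - ref.cr * v) / ref.cr


@dataclasses.dataclass
class SubjectQuant:
    """All per-region measures of one subject (SBR, SUSI in mL, reference)."""

    sbr: dict[str, float]              # e.g. {"putamen_L": ...}
    susi: dict[str, float]
    reference: ReferenceEstimate
    space: str = "template"
    mapped_putamen_volume_ml: float | None = None

    def hemisphere_min(self, method: str, region: str) -> float:
        table = self.sbr if method == "sbr" else self.susi
        return min(table[f"{region}_L"], table[f"{region}_R"])

    def to_row(self) -> dict[str, float | str]:
        row: dict[str, float | str] = {"space": self.space}
        for name, val in self.sbr.items():
            row[f"sbr_{name}"] = val
        for name, val in self.susi.items():
            row[f"susi_{name}"] = val
        for region in SBR_REGIONS:
            row[f"sbr_{region}_min"] = self.hemisphere_min("sbr", region)
        for region in SUSI_REGIONS:
            row[f"susi_{region}_min"] = self.hemisphere_min("susi", region)
        row["cr"] = self.reference.cr
        row["rel_iqr"] = self.reference.rel_iqr
        if self.mapped_putamen_volume_ml is not None:
            row["mapped_putamen_volume_ml"] = self.mapped_putamen_volume_ml
        return row


def quantify_subject(vol: Volume, rois: RoiSet, space: str = "template") -> SubjectQuant:
    """SBR and SUSI for every region and hemisphere, plus hemisphere minima.

    Striatal SUSI is the sum of caudate and putamen SUSI (their large ROIs
    are disjoint and their union is the striatal large ROI). Patient-space
    ROI sets carry mapped region volumes; the mean bilateral mapped putamen
    volume is recorded as the individual putamen-size measure.
    """
    for needed in ["reference"] + [
        f"{r}_{s}" for r in SBR_REGIONS for s in ("L", "R")
    ] + [f"large_{r}_{s}" for r in ("caudate", "putamen") for s in ("L", "R")]:
        if needed not in rois.masks:
            raise ValueError(f"ROI set is missing mask {needed!r}")
    ref = estimate_reference(vol, rois.mask("reference"))
    vox_ml = vol.grid.voxel_volume_ml

    sbr = {
        f"{region}_{side}": compute_sbr(vol, rois.mask(f"{region}_{side}"), ref)
        for region in SBR_REGIONS
        for side in ("L", "R")
    }
    susi: dict[str, float] = {}
    for side in ("L", "R"):
        for region in ("caudate", "putamen"):
            susi[f"{region}_{side}"] = compute_susi(
                vol, rois.mask(f"large_{region}_{side}"), ref, vox_ml
            )
        susi[f"striatum_{side}"] = susi[f"caudate_{side}"] + susi[f"putamen_{side}"]

    mapped_vol = None
    if space == "patient" and rois.mapped_volumes_ml is not None:
        mapped_vol = 0.5 * (
            rois.mapped_volumes_ml["putamen_L"] + rois.mapped_volumes_ml["putamen_R"]
        )
    return SubjectQuant(sbr=sbr, susi=susi, reference=ref, space=space,
                        mapped_putamen_volume_ml=mapped_vol)


def quantify_cohort(subjects, rois: RoiSet, space: str = "template") -> pd.DataFrame:
    """Quantify a list of :class:`~susiq.phantom.SimulatedSubject` objects."""
    rows = []
    for s in subjects:
        q = quantify_subject(s.volume, rois, space=space)
        row = {"subject_id": s.subject_id, "label": s.label, "site": s.site,
               "fwhm_mm": s.fwhm_mm}
        row.update(q.to_row())
        rows.append(row)
    return pd.DataFrame(rows)
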