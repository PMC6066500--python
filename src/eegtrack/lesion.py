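"""Infarct–ROI overlap arithmetic and the lesion-exclusion flags.

Masks are binary 3-D volumes assumed already co-registered to a common
space; a ``space_tag`` equality check guards against comparing masks from
different spaces.  Overlap of a lesion with a region of interest is the
percent of ROI voxels falling inside the lesion.  A subject is excluded
from the lesion-restricted secondary analysis when any critical ROI (by
default the precentral gyrus and the superior and inferior parietal
lobules) shows nonzero overlap, with an optional minimum-percent override.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VolumeMask",
    "InjuryProfile",
    "overlap_percent",
    "infarct_volume",
    "injury_profile",
    "exclusion_flags",
    "DEFAULT_CRITICAL_ROIS",
]

DEFAULT_CRITICAL_ROIS = ("precentral_gyrus", "superior_parietal", "inferior_parietal")


@dataclass
class VolumeMask:
    """Binary 3-D mask with voxel size (mm per axis) and a space tag."""

    grid: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    space_tag: str = "unknown"

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 3:
            raise ValueError("mask grid must be 3-D")
        uniq = np.unique(grid)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask must be binary")
        self.grid = grid.astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())

    # ---- NIfTI I/O -----------------------------------------------------
    @classmethod
    def from_nifti(cls, path, space_tag: str = "unknown") -> "VolumeMask":
        import nibabel as nib

        img = nib.load(str(path))
        grid = np.asarray(img.get_fdata()) > 0.5
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(grid=grid, voxel_size_mm=zooms, space_tag=space_tag)

    def to_nifti(self, path) -> None:
        import nibabel as nib

        affine = np.diag([*self.voxel_size_mm, 1.0])
        img = nib.Nifti1Image(self.grid.astype(np.uint8), affine)
        img.header.set_zooms(self.voxel_size_mm)
        nib.save(img, str(path))


def _check_compatible(a: VolumeMask, b: VolumeMask) -> None:
    if a.grid.shape != b.grid.shape:
        raise ValueError(f"mask shapes differ: {a.grid.shape} vs {b.grid.shape}")
    if not np.allclose(a.voxel_size_mm, b.voxel_size_mm):
        raise ValueError("mask voxel sizes differ")
    if a.space_tag != b.space_tag:
        raise ValueError(f"masks in different spaces: {a.space_tag!r} vs {b.space_tag!r}")


def overlap_percent(lesion: VolumeMask, roi: VolumeMask) -> float:
    """Percent of ROI voxels inside the lesion: 100 * |lesion ∧ roi| / |roi|."""
    _check_compatible(lesion, roi)
    n_roi = roi.n_voxels
    if n_roi == 0:
        raise ValueError("ROI mask is empty")
    return 100.0 * int((lesion.grid & roi.grid).sum()) / n_roi


def infarct_volume(lesion: VolumeMask) -> float:
    """Lesion volume in cubic centimetres."""
    vx_mm3 = float(np.prod(lesion.voxel_size_mm))
    return lesion.n_voxels * vx_mm3 / 1000.0


@dataclass
class InjuryProfile:
    """Per-subject lesion load against the critical ROIs."""

    subject_id: str
    overlap_pct: dict[str, float]
    infarct_volume_cc: float
    excluded: bool


def injury_profile(
    subject_id: str,
    lesion: VolumeMask,
    roi_masks: dict[str, VolumeMask],
    critical_rois=DEFAULT_CRITICAL_ROIS,
    min_percent: float = 0.0,
) -> InjuryProfile:
    """Compute overlaps and the exclusion flag for one subject."""
    overlaps = {name: overlap_percent(lesion, m) for name, m in roi_masks.items()}
    missing = [r for r in critical_rois if r not in overlaps]
    if missing:
        raise KeyError(f"missing overlap entries for critical ROIs: {missing}")
    excluded = any(overlaps[r] > min_percent for r in critical_rois)
    return InjuryProfile(
        subject_id=subject_id, overlap_pct=overlaps,
        infarct_volume_cc=infarct_volume(lesion), excluded=excluded,
    )


def exclusion_flags(
    profiles: list[InjuryProfile],
    critical_rois=DEFAULT_CRITICAL_ROIS,
    min_percent: float = 0.0,
) -> dict[str, bool]:
    """Exclusion flag per subject: any critical-ROI overlap above threshold."""
    flags = {}
    for p in profiles:
        missing = [r for r in critical_rois if r not in p.overlap_pct]
        if missing:
            raise KeyError(f"{p.subject_id}: missing overlaps for {missing}")
        flags[p.subject_id] = any(p.overlap_pct[r] > min_percent for r in critical_rois)
    return flags


def profiles_frame(profiles: list[InjuryProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for roi, pct in sorted(p.overlap_pct.items()):
            rows.append(
                {
                    "subject_id": p.subject_id, "roi": roi, "overlap_pct": pct,
                    "infarct_cc": p.infarct_volume_cc, "excluded": p.excluded,
                }
            )
    return pd.DataFrame(rows)
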