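"""Labeled 3-D volumes and the label dictionaries used throughout the pipeline.

A :class:`LabelVolume` is the carrier for both the tissue *segmentation*
(cortical gray matter, white matter, deep gray matter, cerebellum, brainstem,
hippocampus, ventricles) and the anatomical *parcellation* (ten regions per
hemisphere).  World coordinates are voxel index times voxel spacing, with no
rotational affine: phantoms are generated in the same frame, so geometric
oracles stay exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .errors import ValidationError

# -- segmentation (tissue) labels --------------------------------------------
SEGMENTATION_LABELS: dict[str, int] = {
    "background": 0,
    "cgm": 1,
    "wm": 2,
    "dgm": 3,
    "cerebellum": 4,
    "brainstem": 5,
    "hippocampus": 6,
    "ventricles": 7,
}

#: the six tissues reported as volumes (ventricles are segmented but not
#: reported as a tissue volume)
TISSUES: tuple[str, ...] = (
    "cgm",
    "wm",
    "dgm",
    "cerebellum",
    "brainstem",
    "hippocampus",
)

# -- parcellation regions ------------------------------------------------------
#: ten anatomical regions; left-hemisphere labels are 1..10 in this order,
#: right-hemisphere labels are 11..20.
REGIONS: tuple[str, ...] = (
    "frontal",
    "parietal",
    "temporal",
    "occipital",
    "anterior_cingulate",
    "posterior_cingulate",
    "insula",
    "corpus_callosum",
    "dgm",
    "ventricles",
)

#: the four lobes on which cortical folding is reported
LOBES: tuple[str, ...] = ("frontal", "parietal", "temporal", "occipital")

HEMISPHERES: tuple[str, ...] = ("left", "right")


def region_label(region: str, hemisphere: str) -> int:
    """Integer parcellation label for ``region`` in ``hemisphere``."""
    if region not in REGIONS:
        raise ValidationError(f"unknown region {region!r}")
    if hemisphere not in HEMISPHERES:
        raise ValidationError(f"unknown hemisphere {hemisphere!r}")
    offset = 0 if hemisphere == "left" else len(REGIONS)
    return REGIONS.index(region) + 1 + offset


def label_region(label: int) -> tuple[str, str]:
    """Inverse of :func:`region_label`: ``(region, hemisphere)`` for a label."""
    if not 1 <= label <= 2 * len(REGIONS):
        raise ValidationError(f"label {label} is not a parcellation label")
    idx = (label - 1) % len(REGIONS)
    hemi = "left" if label <= len(REGIONS) else "right"
    return REGIONS[idx], hemi


@dataclass
class LabelVolume:
    """Integer label grid with voxel spacing in millimetres.

    Parameters
    ----------
    data:
        3-D integer array of labels.
    spacing:
        Voxel edge lengths ``(sx, sy, sz)`` in mm; all strictly positive.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = field(default=(1.0, 1.0, 1.0))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError("label volume must be 3-D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValidationError("label volume must hold integer labels")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError("spacing must be three positive lengths (mm)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def mid_sagittal_x(self) -> float:
        """World x-coordinate of the mid-sagittal plane (grid centre)."""
        return (self.data.shape[0] - 1) / 2.0 * self.spacing[0]

    def hemisphere_mask(self, hemisphere: str) -> np.ndarray:
        """Boolean voxel mask for one hemisphere.

        Voxels whose centre lies exactly on the mid-sagittal plane are
        assigned to the left hemisphere by convention.
        """
        if hemisphere not in HEMISPHERES:
            raise ValidationError(f"unknown hemisphere {hemisphere!r}")
        x = np.arange(self.data.shape[0]) * self.spacing[0]
        left = x <= self.mid_sagittal_x()
        mask = left if hemisphere == "left" else ~left
        return np.broadcast_to(mask[:, None, None], self.data.shape)

    # -- NIfTI round trip -----------------------------------------------------
    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.diag((*self.spacing, 1.0))
        return nib.Nifti1Image(self.data.astype(np.int16), affine)

    def save(self, path: str) -> None:
        nib.save(self.to_nifti(), path)

    @classmethod
    def load(cls, path: str) -> "LabelVolume":
        img = nib.load(path)
        zooms = img.header.get_zooms()[:3]
        if any(z <= 0 for z in zooms):
            raise ValidationError(f"{path}: missing or invalid voxel spacing")
        data = np.asarray(img.dataobj)
        if not np.allclose(data, np.round(data)):
            raise ValidationError(f"{path}: volume does not contain integer labels")
        return cls(data=np.round(data).astype(np.int16), spacing=tuple(zooms))
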