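"""Voxel-count tissue volumetry and acquisition-geometry helpers.

Volumes are pure label counts times the voxel volume — no partial-volume
correction — computed in mm^3 internally and reported in cm^3, optionally
split by hemisphere about the grid's mid-sagittal plane.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .volume import SEGMENTATION_LABELS, TISSUES, LabelVolume

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class VolumeGeometry:
    """Acquisition geometry: voxel spacing, field of view and matrix size."""

    spacing: tuple[float, float, float]
    fov_mm: float
    matrix: int

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing) or self.fov_mm <= 0 or self.matrix <= 0:
            raise ValidationError("geometry values must be positive")


def in_plane_resolution(fov_mm: float, matrix: int) -> float:
    """In-plane resolution (mm) = field of view / acquisition matrix.

    E.g. a 320 mm field of view over a 256 matrix gives 1.25 mm.
    """
    if fov_mm <= 0 or matrix <= 0:
        raise ValidationError("fov and matrix must be positive")
    return fov_mm / matrix


def voxel_volume(spacing: tuple[float, float, float]) -> float:
    """Voxel volume in mm^3 as the product of the three spacings."""
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValidationError("spacing must be three positive lengths (mm)")
    sx, sy, sz = spacing
    return float(sx) * float(sy) * float(sz)


@dataclass
class TissueVolumes:
    """Per-tissue volumes in cm^3, optionally one entry per hemisphere."""

    volumes_cm3: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.volumes_cm3.items():
            if v < 0:
                raise ValidationError(f"negative volume for {k!r}")

    def __getitem__(self, tissue: str) -> float:
        return self.volumes_cm3[tissue]

    def items(self):
        return self.volumes_cm3.items()


def tissue_volumes(
    seg: LabelVolume,
    hemisphere: str | None = None,
    mask: np.ndarray | None = None,
) -> TissueVolumes:
    """Count-based tissue volumes in cm^3.

    Parameters
    ----------
    seg:
        Segmentation label volume (labels from the tissue dictionary; any
        other labels present are ignored with a warning).
    hemisphere:
        ``"left"`` or ``"right"`` to restrict to one hemisphere about the
        mid-sagittal plane; ``None`` for the whole volume.
    mask:
        Optional boolean voxel mask applied on top of the hemisphere choice.
    """
    data = seg.data
    if mask is not None:
        if mask.shape != data.shape:
            raise ValidationError("mask shape does not match the label volume")
        sel = mask
    else:
        sel = np.ones(data.shape, dtype=bool)
    if hemisphere is not None:
        sel = sel & seg.hemisphere_mask(hemisphere)

    vv = seg.voxel_volume_mm3
    labels = data[sel]
    counts = np.bincount(labels.ravel(), minlength=max(SEGMENTATION_LABELS.values()) + 1)
    known = set(SEGMENTATION_LABELS.values())
    unknown = [int(l) for l in np.nonzero(counts)[0] if int(l) not in known]
    if unknown:
        log.warning("ignoring unknown labels %s in segmentation", unknown)

    out = {
        tissue: counts[SEGMENTATION_LABELS[tissue]] * vv / 1000.0
        for tissue in TISSUES
    }
    return TissueVolumes(out)
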