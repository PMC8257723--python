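"""Labelled voxel volumes for knee-joint segmentations.

The segmentation input to the whole pipeline is a 3D integer label grid with
physical voxel spacing.  Axes follow a fixed anatomical convention:

* axis 0 (rows): anterior → posterior,
* axis 1 (cols): medial → lateral for a *right* knee,
* axis 2 (slices): superior → inferior (the joint's long axis; the femur
  occupies low slice indices, the tibia high ones).

Left knees are mirror images along axis 1; :func:`kneequant.geometry.align_volume`
mirrors them into this canonical right-knee frame before quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "BACKGROUND",
    "FEMUR_BONE",
    "FEMORAL_CARTILAGE",
    "TIBIA_BONE",
    "TIBIAL_CARTILAGE",
    "LABEL_LEGEND",
    "BONE_LABELS",
    "CARTILAGE_LABELS",
    "AlignmentRecord",
    "LabelVolume",
]

BACKGROUND = 0
FEMUR_BONE = 1
FEMORAL_CARTILAGE = 2
TIBIA_BONE = 3
TIBIAL_CARTILAGE = 4

LABEL_LEGEND = {
    BACKGROUND: "background",
    FEMUR_BONE: "femur_bone",
    FEMORAL_CARTILAGE: "femoral_cartilage",
    TIBIA_BONE: "tibia_bone",
    TIBIAL_CARTILAGE: "tibial_cartilage",
}

#: bone label and its articular cartilage label, keyed by bone name
BONE_LABELS = {"femur": FEMUR_BONE, "tibia": TIBIA_BONE}
CARTILAGE_LABELS = {"femur": FEMORAL_CARTILAGE, "tibia": TIBIAL_CARTILAGE}


@dataclass(frozen=True)
class AlignmentRecord:
    """Provenance of the alignment applied to a volume for one bone.

    Angles are in degrees.  ``posterior_line`` stores the (row, col) pixel
    endpoints of the posterior condylar chord in the aligned projection,
    which should be horizontal within ``kneequant.geometry.ANGLE_TOL_DEG``.
    """

    bone: str
    mirrored: bool
    long_axis_rotation_deg: float
    inplane_rotation_deg: float
    posterior_line: tuple[tuple[int, int], tuple[int, int]]


@dataclass
class LabelVolume:
    """A 3D integer-labelled voxel grid with physical spacing.

    Parameters
    ----------
    data
        Integer array of shape (rows, cols, slices) with labels drawn from
        :data:`LABEL_LEGEND`.
    spacing_mm
        Voxel spacing (row, col, slice) in millimetres; all positive.
    knee_side
        ``"left"`` or ``"right"``.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    knee_side: str = "right"
    #: set by align_volume; keyed by bone name
    alignment: dict[str, AlignmentRecord] = field(default_factory=dict)
    #: True once mirrored into the canonical right-knee frame
    canonical: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"label volume must be 3D, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError(f"label volume must hold integers, got dtype {self.data.dtype}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be three positive reals, got {self.spacing_mm}")
        if self.knee_side not in ("left", "right"):
            raise ValueError(f"knee_side must be 'left' or 'right', got {self.knee_side!r}")
        unknown = set(np.unique(self.data)) - set(LABEL_LEGEND)
        if unknown:
            raise ValueError(f"unknown labels in volume: {sorted(unknown)}")

    # -- convenience ------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def mask(self, label: int) -> np.ndarray:
        return self.data == label

    def count(self, label: int) -> int:
        return int(np.count_nonzero(self.data == label))

    def mirrored(self) -> "LabelVolume":
        """Mirror along the medial–lateral axis, flipping the knee side."""
        side = "left" if self.knee_side == "right" else "right"
        return LabelVolume(
            data=self.data[:, ::-1, :].copy(),
            spacing_mm=self.spacing_mm,
            knee_side=side,
        )

    def copy(self, **changes) -> "LabelVolume":
        out = replace(self, data=self.data.copy(), **changes)
        out.alignment = dict(self.alignment)
        return out


def require_bone(volume: LabelVolume, bone: str) -> tuple[int, int]:
    """Return (bone_label, cartilage_label) or raise if either is empty."""
    if bone not in BONE_LABELS:
        raise ValueError(f"bone must be 'femur' or 'tibia', got {bone!r}")
    bl, cl = BONE_LABELS[bone], CARTILAGE_LABELS[bone]
    if volume.count(bl) == 0:
        raise ValueError(f"{bone} bone label ({bl}) is empty in volume")
    if volume.count(cl) == 0:
        raise ValueError(f"{bone} cartilage label ({cl}) is empty in volume")
    return bl, cl
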