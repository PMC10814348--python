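"""Oriented imaging-prescription volumes, Dice overlap, and ROI fractions.

The imaging prescription is an oriented box (center, rotation, extents)
derived from an atlas-anchored template.  Serial-coverage consistency is
quantified by the Dice coefficient between rasterized prescription
volumes; per-voxel ROI fractions on the coarse metabolic grid support
partial-volume thresholds such as the >30% NAWM rule.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "PrescriptionVolume",
    "GridGeometry",
    "voxelize",
    "dice",
    "roi_fraction",
    "serial_prescription_dice",
]


@dataclass
class GridGeometry:
    """Axis-aligned sampling grid in mm: shape plus voxel size and origin."""

    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def voxel_centers(self) -> np.ndarray:
        """Voxel-center coordinates, shape ``shape + (3,)``, in mm."""
        axes = [
            self.origin_mm[i] + (np.arange(self.shape[i]) + 0.5) * self.voxel_size_mm[i]
            for i in range(3)
        ]
        grid = np.meshgrid(*axes, indexing="ij")
        return np.stack(grid, axis=-1)


@dataclass
class PrescriptionVolume:
    """Oriented-box imaging prescription: center, rotation, extents (mm)."""

    center: np.ndarray  # (3,), mm
    rotation: np.ndarray  # (3, 3) orthonormal, columns = box axes in world frame
    extents: np.ndarray  # (3,), full edge lengths, mm

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.extents = np.asarray(self.extents, dtype=float).reshape(3)
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal (R^T R = I)")
        if np.any(self.extents <= 0):
            raise ValueError("extents must be > 0")

    def to_json(self) -> str:
        return json.dumps(
            {
                "center_mm": self.center.tolist(),
                "rotation_rowmajor": self.rotation.ravel().tolist(),
                "extents_mm": self.extents.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PrescriptionVolume":
        d = json.loads(text)
        for key in ("center_mm", "rotation_rowmajor", "extents_mm"):
            if key not in d:
                raise ValueError(f"prescription JSON missing field {key!r}")
        return cls(
            center=np.array(d["center_mm"]),
            rotation=np.array(d["rotation_rowmajor"]).reshape(3, 3),
            extents=np.array(d["extents_mm"]),
        )


def voxelize(volume: PrescriptionVolume, grid: GridGeometry) -> np.ndarray:
    """Rasterize an oriented box: voxel in iff its center lies in the box.

    Inclusion is half-open on the max faces (``-e/2 <= x < e/2`` along
    each box axis) so that abutting boxes tile without double counting.
    Emits a warning when the box is thinner than a voxel along any axis.
    """
    if np.any(volume.extents < np.min(grid.voxel_size_mm)):
        warnings.warn(
            "prescription box is thinner than a voxel; rasterization is coarse",
            stacklevel=2,
        )
    centers = grid.voxel_centers().reshape(-1, 3)
    local = (centers - volume.center) @ volume.rotation  # world -> box frame
    half = volume.extents / 2.0
    inside = np.all((local >= -half) & (local < half), axis=1)
    return inside.reshape(grid.shape)


def dice(v1: np.ndarray, v2: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) between two binary volumes."""
    v1 = np.asarray(v1, dtype=bool)
    v2 = np.asarray(v2, dtype=bool)
    if v1.shape != v2.shape:
        raise ValueError("volumes must share one grid")
    n1, n2 = int(v1.sum()), int(v2.sum())
    if n1 + n2 == 0:
        raise ValueError("Dice undefined: both volumes are empty")
    inter = int(np.count_nonzero(v1 & v2))
    return 2.0 * inter / (n1 + n2)


def roi_fraction(roi_mask: np.ndarray, coarse_shape: tuple[int, int, int]) -> np.ndarray:
    """Per-coarse-voxel occupied fraction of a fine binary ROI mask.

    The fine grid must nest integrally into the coarse grid (each coarse
    dimension divides the corresponding fine dimension).  Returns values
    in [0, 1]: the fraction of fine voxels inside each coarse voxel that
    belong to the ROI.
    """
    roi = np.asarray(roi_mask, dtype=bool)
    if roi.ndim != 3 or len(coarse_shape) != 3:
        raise ValueError("expected 3-D mask and 3-D coarse shape")
    factors = []
    for fine, coarse in zip(roi.shape, coarse_shape):
        if coarse < 1 or fine % coarse != 0:
            raise ValueError(
                f"fine grid {roi.shape} does not nest into coarse {coarse_shape}"
            )
        factors.append(fine // coarse)
    fz, fr, fc = factors
    cz, cr, cc = coarse_shape
    blocks = roi.reshape(cz, fz, cr, fr, cc, fc)
    return blocks.mean(axis=(1, 3, 5))


def serial_prescription_dice(
    anatomy_box: PrescriptionVolume,
    head_rotation_deg: float,
    grid: GridGeometry,
    axis: str = "z",
) -> tuple[float, float]:
    """Compare atlas-anchored vs fixed-axis prescriptions under head rotation.

    Models two serial exams whose only difference is a rigid head
    rotation about the box center.  An atlas-anchored prescription
    follows the anatomy, so in the anatomy-fixed frame both exams image
    the same box; a fixed scanner-axis prescription keeps its original
    world orientation, so in the anatomy frame the second exam's box
    appears counter-rotated.  Returns ``(dice_atlas, dice_fixed)``
    computed on ``grid``.
    """
    base = voxelize(anatomy_box, grid)
    # atlas-anchored: identical anatomy-frame box in both exams
    dice_atlas = dice(base, voxelize(anatomy_box, grid))
    rot = Rotation.from_euler(axis, -head_rotation_deg, degrees=True).as_matrix()
    fixed_second = PrescriptionVolume(
        center=anatomy_box.center,
        rotation=rot @ anatomy_box.rotation,
        extents=anatomy_box.extents,
    )
    dice_fixed = dice(base, voxelize(fixed_second, grid))
    return dice_atlas, dice_fixed
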