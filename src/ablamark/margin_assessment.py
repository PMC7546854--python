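"""Ablative-margin quantification on registered tumor / ablation-zone masks.

The ablative margin (AM) is the shortest distance from the tumor boundary to
the ablation-zone boundary after treatment.  The pre-ablation tumor outline
is warped into post-ablation space with the estimated displacement field,
then every tumor boundary voxel gets a signed Euclidean distance (mm, via
the voxel spacing) to the nearest ablation-boundary voxel centre — positive
where the tumor boundary lies inside the ablation zone, negative where the
tumor protrudes.  The minimal AM is floored at 0 mm (a breached margin is
reported as 0, the signed map keeps the negatives for visualization), and
lesions are graded group A (AM <= 5 mm) / group B (AM > 5 mm).

Boundary voxels are foreground voxels with at least one face-adjacent
(6-connected) background neighbour; the volume border counts as background.
Distances are measured between voxel centres, so the discretization error is
at most half a voxel diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imaging_core import (
    DisplacementField,
    GeometryError,
    Mask,
    ValidationError,
    identity_grid,
    sample_trilinear,
)

__all__ = [
    "MarginResult",
    "warp_mask",
    "minimal_margin",
    "classify_margin",
    "theoretical_margin_contour",
    "margin_sufficiency",
]

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclass
class MarginResult:
    """Minimal ablative margin plus the per-surface-voxel signed distances."""

    min_margin_mm: float
    surface_distances_mm: np.ndarray
    group: str
    covered: bool

    def summary(self) -> dict:
        d = self.surface_distances_mm
        return {
            "min_margin_mm": self.min_margin_mm,
            "group": self.group,
            "covered": bool(self.covered),
            "surface_distance_percentiles_mm": {
                str(p): float(np.percentile(d, p)) for p in (0, 5, 25, 50, 75, 95, 100)
            },
        }


def boundary_voxels(mask_data: np.ndarray) -> np.ndarray:
    """Foreground voxels with a face-adjacent background neighbour."""
    fg = mask_data.astype(bool)
    eroded = ndimage.binary_erosion(fg, structure=_FACE_STRUCT, border_value=0)
    return fg & ~eroded


def classify_margin(min_margin_mm: float, threshold_mm: float = 5.0) -> str:
    """Group ``"A"`` iff the margin is <= the threshold (inclusive), else ``"B"``."""
    if min_margin_mm < 0:
        raise ValidationError(f"min margin must be >= 0 mm, got {min_margin_mm}")
    return "A" if min_margin_mm <= threshold_mm else "B"


def minimal_margin(tumor: Mask, ablation: Mask, spacing=None, threshold_mm: float = 5.0) -> MarginResult:
    """Signed surface distances and the minimal AM between two masks.

    ``spacing`` defaults to the tumor mask's own (z, y, x) mm spacing.
    """
    if tumor.shape != ablation.shape:
        raise GeometryError(f"mask shapes differ: {tumor.shape} vs {ablation.shape}")
    if spacing is None:
        spacing = tumor.spacing
    if not np.allclose(tumor.spacing, ablation.spacing):
        raise GeometryError(f"mask spacings differ: {tumor.spacing} vs {ablation.spacing}")
    t = tumor.data.astype(bool)
    a = ablation.data.astype(bool)
    if not t.any():
        raise ValidationError("tumor mask is empty")
    if not a.any():
        raise ValidationError("ablation mask is empty")

    t_bnd = boundary_voxels(t)
    a_bnd = boundary_voxels(a)
    # distance from every voxel to the nearest ablation-boundary voxel centre
    dist_to_abl = ndimage.distance_transform_edt(~a_bnd, sampling=spacing)
    signed = np.where(a, 1.0, -1.0)[t_bnd] * dist_to_abl[t_bnd]
    min_signed = float(signed.min())
    min_margin = max(0.0, min_signed)
    covered = bool(np.all(signed >= 0.0))
    return MarginResult(
        min_margin_mm=min_margin,
        surface_distances_mm=signed,
        group=classify_margin(min_margin, threshold_mm),
        covered=covered,
    )


def warp_mask(mask: Mask, field: DisplacementField) -> Mask:
    """Resample a mask through a displacement field (linear, thresholded at 0.5).

    The identity field returns the input mask exactly (integer-coordinate
    sampling is exact for the tent kernel).
    """
    dense = field.materialize(mask.shape)
    grid = identity_grid(mask.shape, mode="3d")
    x = grid.points[..., 0] + dense[..., 2]
    y = grid.points[..., 1] + dense[..., 1]
    z = grid.points[..., 2] + dense[..., 0]
    soft = sample_trilinear(mask.data.astype(np.float64), x, y, z)
    return Mask((soft >= 0.5).astype(np.uint8), mask.spacing, mask.origin)


def theoretical_margin_contour(tumor: Mask, margin_mm: float = 5.0) -> Mask:
    """Spacing-aware dilation of the tumor by a ball of radius ``margin_mm``.

    This is the automatically constructed "theoretical margin": the set of
    voxels whose centre lies within ``margin_mm`` of the tumor.
    """
    if margin_mm <= 0:
        raise ValidationError(f"margin must be > 0 mm, got {margin_mm}")
    t = tumor.data.astype(bool)
    if not t.any():
        raise ValidationError("tumor mask is empty")
    dist_to_tumor = ndimage.distance_transform_edt(~t, sampling=tumor.spacing)
    out = t | (dist_to_tumor <= margin_mm)
    return Mask(out.astype(np.uint8), tumor.spacing, tumor.origin)


def margin_sufficiency(
    tumor: Mask,
    ablation: Mask,
    field: DisplacementField | None = None,
    margin_mm: float = 5.0,
) -> tuple[MarginResult, bool]:
    """Warp the tumor, measure the minimal AM, and grade the safe margin.

    ``achieved`` is true iff the lesion lands in group B (AM > ``margin_mm``)
    — the ablation zone covers the tumor with the requested safety margin.
    """
    if field is not None:
        tumor = warp_mask(tumor, field)
    result = minimal_margin(tumor, ablation, threshold_mm=margin_mm)
    return result, result.group == "B"
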