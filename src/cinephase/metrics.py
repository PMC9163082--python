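"""Segmentation post-processing and per-phase cycle metrics.

Covers the path from a probabilistic segmentation to the scalar metrics that
describe the cardiac cycle: cavity volume (uL), area of the most
cycle-variant short-axis slice (mm^2), and marching-cubes surface area
(mm^2), plus the Sorensen-Dice score and foreground/background imbalance
used for benchmarking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from scipy import ndimage
from skimage import measure

from .core import CineSeries, MaskStack, ProbabilityMap

__all__ = ["PostprocessSpec", "CycleCurve", "postprocess", "lv_volume",
           "dice_score", "select_variance_slice", "surface_area",
           "class_imbalance", "cycle_curve"]

Metric = Literal["volume", "surface_area", "slice_area"]


@dataclass
class PostprocessSpec:
    """Thresholding + morphology applied to a probability map.

    Hole filling (2D, per short-axis slice) runs before the opening so a
    cavity pinhole cannot seed the erosion; the opening then shaves thin
    protrusions with a radius-``opening_radius_vox`` Chebyshev ball (a full
    box), which leaves compact blocky bodies untouched.
    """

    threshold: float = 0.5
    opening_radius_vox: int = 1
    fill_holes: bool = True
    keep_largest_per_slice: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")
        if self.opening_radius_vox < 0:
            raise ValueError("opening radius must be >= 0")


@dataclass
class CycleCurve:
    """One scalar metric per cardiac phase."""

    metric: Metric
    phase_indices: np.ndarray
    values: np.ndarray
    selected_slice_index: Optional[int] = None

    def __post_init__(self) -> None:
        self.phase_indices = np.asarray(self.phase_indices, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.phase_indices.shape != self.values.shape:
            raise ValueError("phase_indices and values must have the same length")
        if (self.values < 0).any():
            raise ValueError("metric values must be non-negative")


def postprocess(prob: ProbabilityMap, spec: PostprocessSpec | None = None) -> MaskStack:
    """Binarise a probability map and clean it up morphologically."""
    spec = spec or PostprocessSpec()
    m = prob.values >= spec.threshold
    if spec.fill_holes:
        for z in range(m.shape[0]):
            m[z] = ndimage.binary_fill_holes(m[z])
    if spec.opening_radius_vox > 0:
        r = spec.opening_radius_vox
        selem = np.ones((2 * r + 1,) * 3, dtype=bool)
        # erode with out-of-volume treated as foreground so a full-array
        # solid survives; dilate normally
        eroded = ndimage.binary_erosion(m, structure=selem, border_value=1)
        m = ndimage.binary_dilation(eroded, structure=selem, border_value=0)
    if spec.keep_largest_per_slice:
        for z in range(m.shape[0]):
            lab, n = ndimage.label(m[z])
            if n > 1:
                sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=range(1, n + 1))
                m[z] = lab == (int(np.argmax(sizes)) + 1)
    if not m.any():
        warnings.warn("post-processing produced an empty mask")
    return MaskStack(m.astype(np.uint8), prob.spacing_mm, prob.label)


def lv_volume(mask: MaskStack) -> float:
    """Cavity volume in uL: foreground voxel count x voxel volume (mm^3)."""
    return float(mask.voxels.sum()) * mask.voxel_volume_ul


def dice_score(a: MaskStack, b: MaskStack) -> float:
    """Sorensen-Dice overlap 2|A∩B|/(|A|+|B|); 1.0 when both masks are empty."""
    if a.voxels.shape != b.voxels.shape:
        raise ValueError(f"shape mismatch {a.voxels.shape} vs {b.voxels.shape}")
    na, nb = int(a.voxels.sum()), int(b.voxels.sum())
    if na + nb == 0:
        return 1.0
    inter = int(np.logical_and(a.voxels, b.voxels).sum())
    return 2.0 * inter / (na + nb)


def select_variance_slice(series: CineSeries) -> tuple[int, np.ndarray]:
    """Pick the short-axis slice whose area varies most over the cycle.

    Returns the slice index and that slice's per-phase area series (mm^2).
    Ties on the variance are broken by the smallest slice index (warned).
    """
    masks = series.masks()
    if len(masks) < 2:
        raise ValueError("need at least 2 phases")
    dz, dy, dx = series.spacing_mm
    counts = np.stack([m.voxels.sum(axis=(1, 2)) for m in masks], axis=1)  # (z, phase)
    if counts.sum() == 0:
        raise ValueError("all masks are empty")
    areas = counts * (dy * dx)
    var = areas.var(axis=1)
    best = int(np.argmax(var))
    if (var == var[best]).sum() > 1:
        warnings.warn("variance tie across slices; returning the smallest index")
        best = int(np.flatnonzero(var == var[best])[0])
    return best, areas[best].astype(float)


def surface_area(mask: MaskStack) -> float:
    """Total area (mm^2) of the iso-surface mesh of a binary mask.

    The surface is extracted at level 0.5 with the Lewiner marching cubes
    algorithm using the physical voxel spacing; the volume is zero-padded so
    masks touching the grid boundary still yield a closed surface.  The
    binary field is first smoothed with a 0.8-voxel Gaussian to suppress the
    staircase-artefact area inflation (roughly +8% on a raw binary sphere);
    structures too small to survive the smoothing fall back to the raw
    binary field.
    """
    if mask.voxels.sum() == 0:
        raise ValueError("empty mask has no surface")
    padded = np.pad(mask.voxels.astype(float), 1)
    smoothed = ndimage.gaussian_filter(padded, sigma=0.8)
    field = smoothed if smoothed.max() > 0.5 else padded
    verts, faces, _, _ = measure.marching_cubes(field, level=0.5,
                                                spacing=mask.spacing_mm,
                                                method="lewiner")
    return float(measure.mesh_surface_area(verts, faces))


def class_imbalance(mask: MaskStack) -> float:
    """Foreground-to-background voxel-count ratio."""
    fg = int(mask.voxels.sum())
    bg = mask.voxels.size - fg
    if bg == 0:
        raise ValueError("background is empty")
    return fg / bg


def cycle_curve(series: CineSeries, metric: Metric) -> CycleCurve:
    """Compute one cycle metric for every phase of a series."""
    idx = np.asarray(series.phase_indices)
    if metric == "volume":
        vals = [lv_volume(m) for m in series.masks()]
        return CycleCurve("volume", idx, vals)
    if metric == "surface_area":
        vals = [surface_area(m) for m in series.masks()]
        return CycleCurve("surface_area", idx, vals)
    if metric == "slice_area":
        z, areas = select_variance_slice(series)
        return CycleCurve("slice_area", idx, areas, selected_slice_index=z)
    raise ValueError(f"unknown metric {metric!r}")
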