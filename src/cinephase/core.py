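"""Core data containers, NIfTI I/O and pre-processing for short-axis cine MRI.

Arrays are indexed ``(z, y, x)`` (slice, row, column) and voxel spacing is the
matching ``(dz, dy, dx)`` tuple in millimetres.  The phase (time) axis of a 4D
cine acquisition is the leading axis once loaded.  The study grid is
12 slices of 86x98 voxels at 0.5x0.5 mm in-plane and 1.5 mm through-plane.
"""

from __future__ import annotations

import glob
import os
import re
import warnings
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import nibabel as nib
import numpy as np
from skimage.transform import resize as _sk_resize

DEFAULT_SPACING_MM: tuple[float, float, float] = (1.5, 0.5, 0.5)
DEFAULT_SHAPE: tuple[int, int, int] = (12, 86, 98)

__all__ = [
    "MaskStack",
    "ProbabilityMap",
    "CineSeries",
    "PreprocessSpec",
    "read_cine_nifti",
    "write_cine_nifti",
    "resize_normalise",
    "resize_mask",
    "DEFAULT_SPACING_MM",
    "DEFAULT_SHAPE",
]


@dataclass
class MaskStack:
    """A single 3D binary left-ventricle mask with physical voxel spacing.

    Parameters
    ----------
    voxels : ndarray of shape (z, y, x)
        Binary occupancy; stored as uint8 in {0, 1}.
    spacing_mm : tuple of float
        Voxel spacing ``(dz, dy, dx)`` in millimetres.
    label : str
        Free-text identifier (animal/timepoint/phase).
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING_MM
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3 or min(v.shape) < 1:
            raise ValueError(f"mask must be 3D with all dims >= 1, got shape {v.shape}")
        uniq = np.unique(v)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("mask voxels must be binary (0/1)")
        self.voxels = v.astype(np.uint8)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be three positive components")

    @property
    def voxel_volume_ul(self) -> float:
        """Volume of one voxel in microlitres (1 mm^3 == 1 uL)."""
        dz, dy, dx = self.spacing_mm
        return dz * dy * dx

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class ProbabilityMap:
    """Per-voxel foreground probability in [0, 1], same geometry as MaskStack."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING_MM
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise ValueError(f"probability map must be 3D, got shape {v.shape}")
        if not np.isfinite(v).all():
            raise ValueError("probability map contains non-finite values")
        if v.min() < 0.0 or v.max() > 1.0:
            raise ValueError("probability values must lie within [0, 1]")
        self.values = v
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)


@dataclass
class Phase:
    """One cardiac phase: optional intensity image, mask and probability map."""

    phase_index: int
    image: Optional[np.ndarray] = None
    mask: Optional[MaskStack] = None
    prob: Optional[ProbabilityMap] = None


@dataclass
class CineSeries:
    """Temporally ordered cardiac phases for one animal/timepoint.

    Phases are 8 ms apart in the study protocol; 11-13 phases cover one
    cardiac cycle of the rat heart.
    """

    phases: list[Phase]
    temporal_resolution_ms: float = 8.0
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING_MM
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.phases) < 2:
            raise ValueError("a cine series needs at least 2 phases")
        idx = [p.phase_index for p in self.phases]
        if idx != list(range(len(idx))):
            raise ValueError("phase_index must strictly increase from 0")
        shapes = set()
        for p in self.phases:
            for vol in (p.image, None if p.mask is None else p.mask.voxels,
                        None if p.prob is None else p.prob.values):
                if vol is not None:
                    shapes.add(np.asarray(vol).shape)
        if len(shapes) > 1:
            raise ValueError(f"all member volumes must share one shape, got {shapes}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)

    def __len__(self) -> int:
        return len(self.phases)

    @property
    def phase_indices(self) -> list[int]:
        return [p.phase_index for p in self.phases]

    def masks(self) -> list[MaskStack]:
        out = []
        for p in self.phases:
            if p.mask is None:
                raise ValueError(f"phase {p.phase_index} carries no mask")
            out.append(p.mask)
        return out


@dataclass
class PreprocessSpec:
    """Standardisation target: resize to a fixed grid, then normalise."""

    target_shape: tuple[int, int, int] = DEFAULT_SHAPE
    normalisation: Literal["minmax", "zscore"] = "minmax"

    def __post_init__(self) -> None:
        if len(self.target_shape) != 3 or any(int(d) < 1 for d in self.target_shape):
            raise ValueError("target dims must all be >= 1")
        self.target_shape = tuple(int(d) for d in self.target_shape)
        if self.normalisation not in ("minmax", "zscore"):
            raise ValueError(f"unknown normalisation {self.normalisation!r}")


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

_NUM_RE = re.compile(r"(\d+)")


def _natural_key(name: str):
    return [int(t) if t.isdigit() else t for t in _NUM_RE.split(os.path.basename(name))]


def _vol_from_nifti(img: nib.Nifti1Image) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Return a (z, y, x) array and (dz, dy, dx) spacing from a 3D NIfTI."""
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]  # (dx, dy, dz) in on-disk order
    # nibabel data is (x, y, z); transpose to (z, y, x)
    return np.transpose(data, (2, 1, 0)), (float(zooms[2]), float(zooms[1]), float(zooms[0]))


def read_cine_nifti(path: str, *, is_mask: bool = False,
                    temporal_resolution_ms: float = 8.0,
                    label: str = "") -> CineSeries:
    """Read a cine series from a 4D NIfTI file or a directory of 3D files.

    A 4D file is interpreted with nibabel's on-disk ``(x, y, z, t)`` layout;
    the result is reordered to phase-major ``(t, z, y, x)``.  A directory is
    read as per-phase 3D volumes ordered by the numeric index in their names.

    Parameters
    ----------
    path : str
        ``.nii``/``.nii.gz`` file or directory of such files.
    is_mask : bool
        If True, volumes are binarised (``> 0.5``) and stored as masks;
        otherwise stored as intensity images.
    """
    if os.path.isdir(path):
        files = sorted(
            glob.glob(os.path.join(path, "*.nii")) + glob.glob(os.path.join(path, "*.nii.gz")),
            key=_natural_key,
        )
        if not files:
            raise FileNotFoundError(f"no NIfTI files in directory {path}")
        vols, spacings = [], []
        for f in files:
            v, sp = _vol_from_nifti(nib.load(f))
            if v.ndim != 3:
                raise ValueError(f"{f}: expected 3D volume, got {v.ndim}D")
            vols.append(v)
            spacings.append(sp)
        if len({v.shape for v in vols}) != 1:
            raise ValueError("inconsistent shapes across phase files")
        spacing = spacings[0]
    elif os.path.exists(path):
        img = nib.load(path)
        data = np.asanyarray(img.dataobj)
        if data.ndim != 4:
            raise ValueError(f"expected 4D NIfTI, got {data.ndim}D; "
                             "pass a directory for per-phase 3D files")
        zooms = img.header.get_zooms()[:3]
        spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
        # (x, y, z, t) -> (t, z, y, x)
        vols = [np.transpose(data[..., k], (2, 1, 0)) for k in range(data.shape[3])]
    else:
        raise FileNotFoundError(path)

    phases = []
    for k, v in enumerate(vols):
        if not np.isfinite(v).all():
            raise ValueError(f"phase {k} contains non-finite voxels")
        if is_mask:
            phases.append(Phase(k, mask=MaskStack((v > 0.5).astype(np.uint8), spacing,
                                                  label=f"{label}/phase{k}")))
        else:
            phases.append(Phase(k, image=np.asarray(v, dtype=float)))
    return CineSeries(phases, temporal_resolution_ms=temporal_resolution_ms,
                      spacing_mm=spacing, label=label)


def write_cine_nifti(series: CineSeries, path: str, *, what: str = "image") -> None:
    """Write a cine series as a single 4D NIfTI file (on-disk ``(x, y, z, t)``).

    ``what`` selects the component: ``"image"``, ``"mask"`` or ``"prob"``.
    """
    vols = []
    for p in series.phases:
        v = {"image": p.image,
             "mask": None if p.mask is None else p.mask.voxels,
             "prob": None if p.prob is None else p.prob.values}[what]
        if v is None:
            raise ValueError(f"phase {p.phase_index} has no {what!r} component")
        vols.append(np.transpose(v, (2, 1, 0)))  # (z,y,x) -> (x,y,z)
    data = np.stack(vols, axis=-1)
    dz, dy, dx = series.spacing_mm
    affine = np.diag([dx, dy, dz, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((dx, dy, dz, series.temporal_resolution_ms / 1000.0))
    nib.save(img, path)


# ---------------------------------------------------------------------------
# Pre-processing
# ---------------------------------------------------------------------------

def resize_normalise(stack: np.ndarray, spec: PreprocessSpec) -> np.ndarray:
    """Resize an intensity volume to ``spec.target_shape`` and normalise.

    Resizing is trilinear; ``minmax`` maps the observed range onto [0, 1]
    and ``zscore`` standardises to zero mean, unit variance.  A constant
    volume is returned as all zeros with a warning (its range/variance is
    degenerate).
    """
    arr = np.asarray(stack, dtype=float)
    if arr.size == 0:
        raise ValueError("empty input")
    if not np.isfinite(arr).all():
        raise ValueError("input contains non-finite values")
    if arr.shape != spec.target_shape:
        arr = _sk_resize(arr, spec.target_shape, order=1, mode="edge",
                         anti_aliasing=False, preserve_range=True)
    lo, hi = arr.min(), arr.max()
    if spec.normalisation == "minmax":
        if hi == lo:
            warnings.warn("constant image under minmax normalisation; returning zeros")
            return np.zeros_like(arr)
        return (arr - lo) / (hi - lo)
    sd = arr.std()
    if sd == 0:
        warnings.warn("constant image under zscore normalisation; returning zeros")
        return np.zeros_like(arr)
    return (arr - arr.mean()) / sd


def resize_mask(mask: MaskStack, target_shape: Sequence[int]) -> MaskStack:
    """Resize a binary mask with nearest-neighbour interpolation (stays binary)."""
    target_shape = tuple(int(d) for d in target_shape)
    if mask.voxels.shape == target_shape:
        return MaskStack(mask.voxels.copy(), mask.spacing_mm, mask.label)
    out = _sk_resize(mask.voxels.astype(float), target_shape, order=0, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    scale = [o / t for o, t in zip(mask.voxels.shape, target_shape)]
    new_spacing = tuple(s * f for s, f in zip(mask.spacing_mm, scale))
    return MaskStack((out > 0.5).astype(np.uint8), new_spacing, mask.label)
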