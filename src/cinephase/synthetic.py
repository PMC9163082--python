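"""Synthetic short-axis cine generator with known ground-truth EF.

Emulates the study's data regime: one cardiac cycle sampled at 11-13 phases,
a left-ventricular cavity modelled as a z-truncated ellipsoid inside a
myocardial shell, on the standard 12x86x98 grid at (1.5, 0.5, 0.5) mm
spacing.  The cavity volume follows a smooth one-cycle curve with a
configurable ejection fraction in the study's 41-67% range.

Ground truth (EDV, ESV, EF, extreme phases) is measured on the *voxelised*
masks, not the analytic ellipsoid, so a pipeline fed the ground-truth masks
can recover the EF exactly.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .core import CineSeries, MaskStack, Phase, write_cine_nifti, DEFAULT_SHAPE, DEFAULT_SPACING_MM

__all__ = ["SyntheticCineSpec", "SyntheticCineResult", "generate_cycle_volumes",
           "rasterise_phase", "generate"]


@dataclass
class SyntheticCineSpec:
    """Parameters of a synthetic cine series.

    Defaults follow the study regime: 13 phases, 12x86x98 grid at
    (1.5, 0.5, 0.5) mm, end-diastolic volume 500 uL, EF 55% (mid-range of
    the 41-67% cohort), systole at 35% of the acquisition window.
    """

    n_phases: int = 13
    shape: tuple[int, int, int] = DEFAULT_SHAPE
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING_MM
    edv_ul: float = 500.0
    ef_pct: float = 55.0
    systole_phase_frac: float = 0.35
    wall_thickness_mm: float = 2.0
    intensity_levels: tuple[float, float, float] = (50.0, 300.0, 180.0)  # bg, cavity, myo
    cycle_shape: Literal["cosine", "skewed"] = "cosine"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.ef_pct < 100.0):
            raise ValueError("ef_pct must lie in (0, 100)")
        if self.edv_ul <= 0:
            raise ValueError("edv_ul must be positive")
        if self.n_phases < 5:
            raise ValueError("need at least 5 phases")
        if not (0.0 < self.systole_phase_frac < 1.0):
            raise ValueError("systole_phase_frac must lie in (0, 1)")
        if any(v < 0 for v in self.intensity_levels):
            raise ValueError("intensity levels must be non-negative")
        if self.cycle_shape not in ("cosine", "skewed"):
            raise ValueError(f"unknown cycle_shape {self.cycle_shape!r}")


@dataclass
class SyntheticCineResult:
    """Generated series plus voxel-grid ground truth."""

    series: CineSeries
    edv_ul: float
    esv_ul: float
    ef_pct: float
    diastole_phase: int
    systole_phase: int

    def __post_init__(self) -> None:
        ef = 100.0 * (self.edv_ul - self.esv_ul) / self.edv_ul
        assert abs(ef - self.ef_pct) < 1e-9


def generate_cycle_volumes(spec: SyntheticCineSpec) -> list[float]:
    """Target cavity volume (uL) per phase along one cardiac cycle.

    The curve peaks at ``edv_ul`` at the diastolic phase (phase 0) and dips
    to ``esv_ul = edv_ul * (1 - ef/100)`` at the systolic phase.  The
    ``cosine`` shape is a smooth dip-and-recover whose end-of-window value
    recovers 93% of the EDV-ESV span (keeping the maximum unique and
    resolvable on the voxel grid); ``skewed`` drops fast off the phase-0
    peak (4%, so the maximum stays resolvable after voxelisation) into a
    gently tilted diastolic plateau broken by a sharp systolic dip.
    """
    n = spec.n_phases
    esv = spec.edv_ul * (1.0 - spec.ef_pct / 100.0)
    u = np.arange(n) / (n - 1)
    us = spec.systole_phase_frac
    s_phase = int(round(us * (n - 1)))
    s_phase = min(max(s_phase, 1), n - 2)  # keep the dip interior
    us = s_phase / (n - 1)

    if spec.cycle_shape == "cosine":
        down = u <= us
        v = np.empty(n)
        # half-cosine descent EDV -> ESV, then ascent recovering 93% of span
        v[down] = esv + (spec.edv_ul - esv) * 0.5 * (1 + np.cos(np.pi * u[down] / us))
        top = esv + 0.93 * (spec.edv_ul - esv)
        v[~down] = esv + (top - esv) * 0.5 * (1 - np.cos(np.pi * (u[~down] - us) / (1 - us)))
    else:
        # skewed: fast early decline off the end-diastolic maximum (so the
        # phase-0 peak stays resolvable after voxelisation), gently tilted
        # plateau, then a narrow raised-cosine systolic dip
        plateau = spec.edv_ul * (1.0 - 0.04 * (1.0 - np.exp(-u / 0.08)) - 0.02 * u)
        width = max(0.18, 1.5 / (n - 1))  # half-width of the dip in cycle fraction
        g = np.where(np.abs(u - us) < width,
                     np.cos(np.pi * (u - us) / (2 * width)) ** 2, 0.0)
        amp = spec.edv_ul * (1.0 - 0.04 * (1.0 - np.exp(-us / 0.08)) - 0.02 * us) - esv
        v = plateau - amp * g
    return [float(x) for x in v]


def _max_cavity_volume_ul(spec: SyntheticCineSpec) -> float:
    """Analytic volume of the largest cavity ellipsoid that fits the grid."""
    dz, dy, dx = spec.spacing_mm
    D, H, W = spec.shape
    wall = spec.wall_thickness_mm
    az = (D * dz) / 2 - dz          # leave one slice margin axially
    ay = (H * dy) / 2 - wall - 2 * dy
    ax = (W * dx) / 2 - wall - 2 * dx
    return 4.0 / 3.0 * np.pi * az * ay * ax


def rasterise_phase(volume_target: float, spec: SyntheticCineSpec, phase: int,
                    ) -> tuple[np.ndarray, MaskStack]:
    """Voxelise one phase: cavity ellipsoid + myocardial shell on the grid.

    The cavity is a prolate-ish ellipsoid (long axis along z, truncated by
    the slab so apical/basal slices carry smaller areas than mid slices)
    whose long axis is fixed per series; the in-plane radius is scaled
    (radial contraction) until the voxelised volume matches
    ``volume_target`` within 5%.  The image paints background/cavity/myocardium at the spec's
    intensity levels.  Deterministic given ``spec.seed`` (the seed only
    perturbs the in-plane cavity centre, identically for all phases).
    """
    dz, dy, dx = spec.spacing_mm
    D, H, W = spec.shape
    vox_ul = dz * dy * dx
    if volume_target < vox_ul:
        raise ValueError(
            f"target volume {volume_target:.3g} uL is below one voxel ({vox_ul:.3g} uL)")
    vmax = _max_cavity_volume_ul(spec)
    if volume_target > vmax:
        raise ValueError(
            f"target volume {volume_target:.1f} uL exceeds the maximum achievable "
            f"volume {vmax:.1f} uL on this grid")

    rng = np.random.default_rng(spec.seed)
    # per-series jitter of the in-plane centre; same for every phase
    cy_off = rng.uniform(-2.0, 2.0)  # mm
    cx_off = rng.uniform(-2.0, 2.0)

    z = (np.arange(D) + 0.5) * dz
    y = (np.arange(H) + 0.5) * dy
    x = (np.arange(W) + 0.5) * dx
    # slight axial offset breaks base/apex symmetry (no exact mirrored slices)
    cz, cy, cx = D * dz / 2 + 0.37 * dz, H * dy / 2 + cy_off, W * dx / 2 + cx_off
    Z = ((z - cz) ** 2)[:, None, None]
    Y = ((y - cy) ** 2)[None, :, None]
    X = ((x - cx) ** 2)[None, None, :]

    # long axis fixed per series from the end-diastolic volume (1.5x the
    # EDV in-plane radius, spanning ~9 of 12 slices so apical/basal slices
    # stay partial); contraction is purely radial, as in short-axis cine —
    # every covered slice then shares the same relative area swing and the
    # largest (mid) slices carry the largest absolute variance
    r_edv = (max(spec.edv_ul, volume_target) * 3.0 / (4.0 * np.pi * 1.5)) ** (1.0 / 3.0)
    az = min(1.5 * r_edv, (D * dz) / 2 - 0.5 * dz)
    r0 = np.sqrt(volume_target * 3.0 / (4.0 * np.pi * az))

    def voxelise(s: float) -> np.ndarray:
        ay, ax = s * r0, s * r0
        return (Z / az**2 + Y / ay**2 + X / ax**2 <= 1.0)

    # in-plane rescaling until the voxelised volume tracks the target
    # closely (0.2% ~ a few voxels, so smooth target curves stay smooth
    # after voxelisation); volume scales as s^2 at fixed long axis
    s = 1.0
    cavity = voxelise(s)
    for _ in range(25):
        got = cavity.sum() * vox_ul
        if got > 0 and abs(got - volume_target) / volume_target <= 0.002:
            break
        ratio = volume_target / max(got, vox_ul)
        s *= ratio ** (1.0 / 2.0)
        cavity = voxelise(s)
    got = cavity.sum() * vox_ul
    if abs(got - volume_target) / volume_target > 0.05:
        raise ValueError(
            f"could not match target volume {volume_target:.1f} uL on this grid "
            f"(achieved {got:.1f} uL)")

    wall = spec.wall_thickness_mm
    ay, ax = s * r0, s * r0
    outer = (Z / (az + wall) ** 2 + Y / (ay + wall) ** 2 + X / (ax + wall) ** 2 <= 1.0)
    myo = outer & ~cavity

    bg_i, cav_i, myo_i = spec.intensity_levels
    image = np.full(spec.shape, bg_i, dtype=float)
    image[myo] = myo_i
    image[cavity] = cav_i
    mask = MaskStack(cavity.astype(np.uint8), spec.spacing_mm, label=f"phase{phase}")
    return image, mask


def generate(spec: SyntheticCineSpec) -> SyntheticCineResult:
    """Generate a full synthetic cine series with voxel-grid ground truth."""
    targets = generate_cycle_volumes(spec)
    phases = []
    vols = []
    for k, tgt in enumerate(targets):
        image, mask = rasterise_phase(tgt, spec, k)
        phases.append(Phase(k, image=image, mask=mask))
        vols.append(mask.voxels.sum() * mask.voxel_volume_ul)
    vols = np.asarray(vols)
    dia = int(np.argmax(vols))
    sys_ = int(np.argmin(vols))
    edv, esv = float(vols[dia]), float(vols[sys_])
    series = CineSeries(phases, spacing_mm=spec.spacing_mm,
                        label=f"synth-ef{spec.ef_pct:g}-seed{spec.seed}")
    return SyntheticCineResult(series=series, edv_ul=edv, esv_ul=esv,
                               ef_pct=100.0 * (edv - esv) / edv,
                               diastole_phase=dia, systole_phase=sys_)


def write_synthetic(result: SyntheticCineResult, out_dir: str) -> None:
    """Write images.nii.gz, masks.nii.gz and truth.json into ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)
    write_cine_nifti(result.series, os.path.join(out_dir, "images.nii.gz"), what="image")
    write_cine_nifti(result.series, os.path.join(out_dir, "masks.nii.gz"), what="mask")
    truth = {"edv_ul": result.edv_ul, "esv_ul": result.esv_ul,
             "ef_pct": result.ef_pct, "diastole_phase": result.diastole_phase,
             "systole_phase": result.systole_phase}
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=2)
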