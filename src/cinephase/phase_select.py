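"""Automated end-systole/end-diastole selection and EF estimation.

The cardiac cycle curve (one metric value per phase) is fitted either with a
fourth-degree polynomial or with Gaussian-process regression (constant x RBF
kernel, hyperparameters by marginal-likelihood maximisation).  Diastole is
the global maximum and systole the global minimum of the fitted curve on a
dense grid; each extremum is snapped to the nearest acquired phase, and the
ejection fraction is always computed from the segmentation-derived volumes
at those phases — never from the fitted curve's ordinate.

The fitting core follows the model/results idiom: build a
:class:`CycleCurveModel` from a :class:`~cinephase.metrics.CycleCurve`, call
``fit()`` and read phases, diagnostics and ``summary()`` off the returned
:class:`PhaseSelectionResult`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel

from .core import CineSeries
from .metrics import CycleCurve, Metric, cycle_curve, lv_volume

__all__ = ["FitSpec", "PhaseSelection", "EFEstimate", "CycleCurveModel",
           "PhaseSelectionResult", "fit_curve", "select_phases", "estimate_ef",
           "auto_ef"]


@dataclass
class FitSpec:
    """Configuration of the cycle-curve fit.

    ``gp_jitter`` is the observation-noise term added to the kernel diagonal,
    expressed as a fraction of the (standardised) value variance.
    """

    method: Literal["poly4", "gp"] = "gp"
    gp_restarts: int = 5
    gp_jitter: float = 1e-6
    dense_grid_points: int = 501
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("poly4", "gp"):
            raise ValueError(f"unknown fit method {self.method!r}")
        if self.gp_restarts < 0:
            raise ValueError("gp_restarts must be >= 0")
        if self.dense_grid_points < 10:
            raise ValueError("dense grid too coarse")


@dataclass
class PhaseSelection:
    """Selected extreme phases plus the dense fitted curve."""

    systole_phase: int
    diastole_phase: int
    fitted_x: np.ndarray
    fitted_y: np.ndarray
    method: str
    metric: str
    warnings: list[str] = field(default_factory=list)


@dataclass
class EFEstimate:
    """End-diastolic/-systolic volumes (uL) and ejection fraction (%)."""

    edv_ul: float
    esv_ul: float
    ef_pct: float
    source_phases: tuple[int, int]  # (diastole, systole)

    def __post_init__(self) -> None:
        assert abs(self.ef_pct - 100.0 * (self.edv_ul - self.esv_ul) / self.edv_ul) < 1e-9


class CycleCurveModel:
    """Fit a smooth model to a cardiac cycle curve and locate its extremes.

    Parameters
    ----------
    curve : CycleCurve
        Per-phase metric values (volume, slice area or surface area).
    spec : FitSpec, optional
        Fit method and hyperparameters; defaults to the GP.
    """

    def __init__(self, curve: CycleCurve, spec: FitSpec | None = None):
        self.curve = curve
        self.spec = spec or FitSpec()
        y = curve.values
        if not np.isfinite(y).all():
            raise ValueError("non-finite metric values")
        n = len(y)
        if self.spec.method == "poly4" and n < 5:
            raise ValueError("degree-4 polynomial needs at least 5 phases")
        if self.spec.method == "gp" and n < 3:
            raise ValueError("GP fit needs at least 3 phases")
        if self.spec.dense_grid_points < 10 * n:
            # keep the dense grid fine enough to resolve between-phase extrema
            import dataclasses
            self.spec = dataclasses.replace(self.spec, dense_grid_points=10 * n)

    # -- fitting -----------------------------------------------------------

    def _dense_x(self) -> np.ndarray:
        x = self.curve.phase_indices
        return np.linspace(x.min(), x.max(), self.spec.dense_grid_points)

    def _fit_poly4(self):
        x, y = self.curve.phase_indices.astype(float), self.curve.values
        poly = np.polynomial.Polynomial.fit(x, y, deg=4)
        xs = self._dense_x()
        return xs, poly(xs), {"model": poly, "residuals": y - poly(x)}

    def _fit_gp(self):
        x = self.curve.phase_indices.astype(float)[:, None]
        y = self.curve.values
        mu, sd = y.mean(), y.std()
        xs = self._dense_x()
        if sd == 0:
            return xs, np.full_like(xs, mu), {"model": None, "residuals": np.zeros_like(y)}
        z = (y - mu) / sd
        kernel = ConstantKernel(1.0, (1e-3, 1e3)) * RBF(length_scale=1.0,
                                                        length_scale_bounds=(0.1, 100.0))
        gp = GaussianProcessRegressor(kernel=kernel, alpha=self.spec.gp_jitter,
                                      n_restarts_optimizer=self.spec.gp_restarts,
                                      normalize_y=False,
                                      random_state=self.spec.seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence chatter on tiny n
            gp.fit(x, z)
        zs = gp.predict(xs[:, None])
        return xs, zs * sd + mu, {"model": gp, "residuals": (z - gp.predict(x)) * sd}

    def fit(self) -> "PhaseSelectionResult":
        """Fit the curve and package the results (phases selected lazily)."""
        if self.spec.method == "poly4":
            xs, ys, diag = self._fit_poly4()
        else:
            xs, ys, diag = self._fit_gp()
        return PhaseSelectionResult(self, xs, ys, diag)


class PhaseSelectionResult:
    """Results of a cycle-curve fit: selected phases, diagnostics, summary."""

    def __init__(self, model: CycleCurveModel, fitted_x: np.ndarray,
                 fitted_y: np.ndarray, diagnostics: dict):
        self.model = model
        self.fitted_x = fitted_x
        self.fitted_y = fitted_y
        self.diagnostics = diagnostics
        self._selection: PhaseSelection | None = None

    @property
    def selection(self) -> PhaseSelection:
        """Diastole/systole selected from the fitted curve (computed on demand).

        Raises ``ValueError`` for a degenerate cycle where both extremes snap
        to the same phase (e.g. a constant curve).
        """
        if self._selection is not None:
            return self._selection
        xs, ys = self.fitted_x, self.fitted_y
        curve, spec = self.model.curve, self.model.spec
        notes: list[str] = []
        x_obs, y_obs = curve.phase_indices, curve.values
        dy = np.diff(ys)
        monotone = (dy >= 0).all() or (dy <= 0).all()
        if monotone:
            notes.append("fitted curve is monotone; falling back to raw-data extrema")
            dia = int(x_obs[int(np.argmax(y_obs))])
            sys_ = int(x_obs[int(np.argmin(y_obs))])
        else:
            dia = int(x_obs[np.argmin(np.abs(x_obs - xs[int(np.argmax(ys))]))])
            sys_ = int(x_obs[np.argmin(np.abs(x_obs - xs[int(np.argmin(ys))]))])
        if dia == sys_:
            raise ValueError("degenerate cycle: systole and diastole snap to the same phase")
        self._selection = PhaseSelection(systole_phase=sys_, diastole_phase=dia,
                                         fitted_x=xs, fitted_y=ys,
                                         method=spec.method, metric=curve.metric,
                                         warnings=notes)
        return self._selection

    @property
    def systole_phase(self) -> int:
        return self.selection.systole_phase

    @property
    def diastole_phase(self) -> int:
        return self.selection.diastole_phase

    @property
    def rmse(self) -> float:
        r = np.asarray(self.diagnostics["residuals"], dtype=float)
        return float(np.sqrt(np.mean(r ** 2)))

    def summary(self) -> str:
        c, s = self.model.curve, self.selection
        lines = [
            "Cardiac cycle phase selection",
            "=" * 33,
            f"metric:           {c.metric}",
            f"fit method:       {s.method}",
            f"phases observed:  {len(c.values)}",
            f"diastole phase:   {s.diastole_phase} "
            f"(value {c.values[list(c.phase_indices).index(s.diastole_phase)]:.2f})",
            f"systole phase:    {s.systole_phase} "
            f"(value {c.values[list(c.phase_indices).index(s.systole_phase)]:.2f})",
            f"fit RMSE:         {self.rmse:.4g}",
        ]
        for w in s.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot observations, the fitted curve and the selected phases."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c, s = self.model.curve, self.selection
        ax.plot(c.phase_indices, c.values, "ko", label="observed")
        ax.plot(s.fitted_x, s.fitted_y, "-", label=f"{s.method} fit")
        for ph, lbl, col in ((s.diastole_phase, "diastole", "tab:blue"),
                             (s.systole_phase, "systole", "tab:red")):
            ax.axvline(ph, color=col, ls="--", lw=1, label=lbl)
        ax.set_xlabel("cycle phase")
        ax.set_ylabel(f"{c.metric}")
        ax.legend()
        return ax


# -- functional wrappers ----------------------------------------------------

def fit_curve(curve: CycleCurve, spec: FitSpec | None = None
              ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Fit a cycle curve; returns (dense x, fitted y, diagnostics)."""
    res = CycleCurveModel(curve, spec).fit()
    return res.fitted_x, res.fitted_y, res.diagnostics


def select_phases(curve: CycleCurve, spec: FitSpec | None = None) -> PhaseSelection:
    """Fit a cycle curve and return the selected systole/diastole phases."""
    return CycleCurveModel(curve, spec).fit().selection


def estimate_ef(series: CineSeries, selection: PhaseSelection) -> EFEstimate:
    """EF from cavity volumes at the selected phases.

    EDV/ESV always come from the masks at the diastolic/systolic phase,
    whatever metric drove the selection.  A mis-selection with ESV > EDV
    yields a negative EF with a warning — it is reported, not clamped.
    """
    by_idx = {p.phase_index: p for p in series.phases}
    for ph in (selection.diastole_phase, selection.systole_phase):
        if ph not in by_idx or by_idx[ph].mask is None:
            raise ValueError(f"no mask available at selected phase {ph}")
    edv = lv_volume(by_idx[selection.diastole_phase].mask)
    esv = lv_volume(by_idx[selection.systole_phase].mask)
    if edv == 0:
        raise ValueError("end-diastolic volume is zero")
    ef = 100.0 * (edv - esv) / edv
    if ef < 0:
        warnings.warn("ESV exceeds EDV at the selected phases; EF is negative")
    return EFEstimate(edv_ul=edv, esv_ul=esv, ef_pct=ef,
                      source_phases=(selection.diastole_phase, selection.systole_phase))


def auto_ef(series: CineSeries, metric: Metric = "slice_area",
            spec: FitSpec | None = None,
            ) -> tuple[EFEstimate, PhaseSelection, CycleCurve]:
    """Fully automated pipeline: metric curve -> fit -> phase pick -> EF."""
    curve = cycle_curve(series, metric)
    selection = select_phases(curve, spec)
    ef = estimate_ef(series, selection)
    return ef, selection, curve
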