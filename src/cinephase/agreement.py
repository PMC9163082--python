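"""Agreement statistics for paired ejection-fraction estimates.

Mean absolute difference (MD), Bland-Altman bias and 1.96-sd limits of
agreement with classical 95% confidence intervals, a proportional-bias
regression check, and a paired TOST equivalence test with a 2% EF margin
(a paired simplification of a mixed-model equivalence contrast; the output
is labelled accordingly).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PairedEF", "AgreementReport", "mean_abs_diff", "bland_altman",
           "tost_equivalence", "bland_altman_plot"]


@dataclass
class PairedEF:
    """Paired EF estimates (%) for a set of subjects."""

    ids: list[str]
    ef_estimated: np.ndarray
    ef_reference: np.ndarray

    def __post_init__(self) -> None:
        self.ef_estimated = np.asarray(self.ef_estimated, dtype=float)
        self.ef_reference = np.asarray(self.ef_reference, dtype=float)
        if not (len(self.ids) == len(self.ef_estimated) == len(self.ef_reference)):
            raise ValueError("columns must have equal length")
        if not (np.isfinite(self.ef_estimated).all() and np.isfinite(self.ef_reference).all()):
            raise ValueError("EF values must be finite")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PairedEF":
        return cls(list(df["id"].astype(str)),
                   df["ef_estimated"].to_numpy(), df["ef_reference"].to_numpy())

    @classmethod
    def from_csv(cls, path: str) -> "PairedEF":
        return cls.from_dataframe(pd.read_csv(path))

    @property
    def diffs(self) -> np.ndarray:
        return self.ef_estimated - self.ef_reference

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class AgreementReport:
    """Bland-Altman + MD summary for one paired comparison."""

    n: int
    md: float
    md_sd: float
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    ci_bias: tuple[float, float]
    ci_loa_lower: tuple[float, float]
    ci_loa_upper: tuple[float, float]
    slope_p: float
    bias_significant: bool

    def to_dict(self) -> dict:
        return asdict(self)

    def summary(self) -> str:
        return "\n".join([
            f"n = {self.n}",
            f"MD (mean |dEF|):  {self.md:.3f} ± {self.md_sd:.3f}",
            f"bias:             {self.bias:.3f} "
            f"[{self.ci_bias[0]:.3f}, {self.ci_bias[1]:.3f}]"
            f"{'  (significant)' if self.bias_significant else ''}",
            f"LoA lower:        {self.loa_lower:.3f} "
            f"[{self.ci_loa_lower[0]:.3f}, {self.ci_loa_lower[1]:.3f}]",
            f"LoA upper:        {self.loa_upper:.3f} "
            f"[{self.ci_loa_upper[0]:.3f}, {self.ci_loa_upper[1]:.3f}]",
            f"proportional-bias slope p: {self.slope_p:.4f}",
        ])


def mean_abs_diff(pairs: PairedEF) -> tuple[float, float]:
    """MD = mean |EF_estimated − EF_reference| and the sample sd of |dEF|.

    With a single pair the sd is undefined and reported as 0 with a warning.
    """
    if len(pairs) < 1:
        raise ValueError("empty input")
    a = np.abs(pairs.diffs)
    if len(a) == 1:
        warnings.warn("sd undefined for a single pair; reporting 0")
        return float(a[0]), 0.0
    return float(a.mean()), float(a.std(ddof=1))


def bland_altman(pairs: PairedEF) -> AgreementReport:
    """Bland-Altman bias and 1.96-sd limits of agreement with 95% CIs.

    CI of the bias uses t * sd/sqrt(n); each limit's CI uses the classical
    t * sd * sqrt(3/n) approximation.  Proportional bias is screened by
    regressing the differences on the pair means.
    """
    n = len(pairs)
    if n < 3:
        raise ValueError("Bland-Altman needs at least 3 pairs")
    d = pairs.diffs
    means = (pairs.ef_estimated + pairs.ef_reference) / 2.0
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_lo, loa_hi = bias - 1.96 * sd, bias + 1.96 * sd
    tcrit = float(stats.t.ppf(0.975, n - 1))
    half_bias = tcrit * sd / np.sqrt(n)
    half_loa = tcrit * sd * np.sqrt(3.0 / n)
    if np.ptp(means) == 0 or sd == 0:
        slope_p = 1.0
    else:
        slope_p = float(stats.linregress(means, d).pvalue)
    md, md_sd = mean_abs_diff(pairs)
    return AgreementReport(
        n=n, md=md, md_sd=md_sd, bias=bias, sd_diff=sd,
        loa_lower=loa_lo, loa_upper=loa_hi,
        ci_bias=(bias - half_bias, bias + half_bias),
        ci_loa_lower=(loa_lo - half_loa, loa_lo + half_loa),
        ci_loa_upper=(loa_hi - half_loa, loa_hi + half_loa),
        slope_p=slope_p,
        bias_significant=not (bias - half_bias <= 0.0 <= bias + half_bias),
    )


def tost_equivalence(pairs: PairedEF, margin: float = 2.0,
                     alpha: float = 0.05) -> tuple[float, bool]:
    """Paired two-one-sided-tests equivalence of the two EF columns.

    Tests whether the mean paired difference lies within ±``margin`` EF
    points; p-value is the larger of the two one-sided t-test p-values.
    With zero variance the decision is exact on |bias| vs the margin.
    """
    if margin <= 0:
        raise ValueError("margin must be positive")
    n = len(pairs)
    if n < 3:
        raise ValueError("TOST needs at least 3 pairs")
    d = pairs.diffs
    mean, sd = float(d.mean()), float(d.std(ddof=1))
    if sd == 0:
        p = 0.0 if abs(mean) < margin else 1.0
        return p, p < alpha
    se = sd / np.sqrt(n)
    t_lo = (mean + margin) / se    # H0: mean <= -margin
    t_hi = (mean - margin) / se    # H0: mean >= +margin
    p_lo = float(stats.t.sf(t_lo, n - 1))
    p_hi = float(stats.t.cdf(t_hi, n - 1))
    p = max(p_lo, p_hi)
    return p, p < alpha


def bland_altman_plot(pairs: PairedEF, report: Optional[AgreementReport] = None, ax=None):
    """Bland-Altman plot: scatter, bias line, LoA lines and shaded 95% CIs."""
    import matplotlib.pyplot as plt

    report = report or bland_altman(pairs)
    if ax is None:
        _, ax = plt.subplots()
    means = (pairs.ef_estimated + pairs.ef_reference) / 2.0
    ax.scatter(means, pairs.diffs, s=18, color="k", zorder=3)
    x0, x1 = means.min(), means.max()
    for y, ci, col in ((report.bias, report.ci_bias, "tab:blue"),
                       (report.loa_lower, report.ci_loa_lower, "tab:red"),
                       (report.loa_upper, report.ci_loa_upper, "tab:red")):
        ax.axhline(y, color=col, lw=1.2)
        ax.fill_between([x0, x1], ci[0], ci[1], color=col, alpha=0.15)
    ax.set_xlabel("mean EF (%)")
    ax.set_ylabel("difference in EF (%)")
    return ax
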