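"""Exposure metrics (AUC_inf, Cmax) and the 0.5-2-fold acceptance comparison.

AUC_inf is the trapezoidal integral of the predicted curve plus the
terminal extrapolation C_last / lambda_z, with the terminal slope taken
from the best log-linear fit over the final 3-5 points (highest
adjusted R^2). Medians across simulated individuals are compared as
fold-change ratios against a reference population; a ratio inside the
inclusive 0.5-2.0 band passes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .human import SimulationResult
from .structural import ConcentrationProfile, ValidationError

__all__ = [
    "ExposureSummary",
    "FoldChangeReport",
    "auc_inf",
    "cmax",
    "terminal_slope",
    "summarize",
    "compare",
]


@dataclass(frozen=True)
class ExposureSummary:
    """Median exposure across a simulated population."""

    median_auc_inf: float  # ug/mL*h
    median_cmax: float     # ng/mL
    sd_auc_inf: float
    sd_cmax: float
    n: int

    def __post_init__(self):
        if self.median_auc_inf < 0 or self.median_cmax < 0:
            raise ValidationError("exposure medians must be >= 0")


@dataclass(frozen=True)
class FoldChangeReport:
    """Test/reference median ratio for one metric, with the 0.5-2 pass flag."""

    metric: str  # "auc_inf" | "cmax"
    ratio: float
    passes: bool

    @property
    def ratio_1dp(self) -> float:
        """Presentation rounding to one decimal; full precision kept in `ratio`."""
        return round(self.ratio, 1)


def terminal_slope(profile: ConcentrationProfile, n_points=(3, 4, 5)):
    """Terminal elimination rate lambda_z (1/h) by log-linear regression.

    Fits the last 3-5 positive-concentration points and keeps the fit
    with the highest adjusted R^2. A non-positive terminal slope (no
    apparent terminal decline) is an error naming the grid end.
    """
    t = profile.time_grid
    c = profile.concentrations
    pos = c > 0
    t, c = t[pos], c[pos]
    if t.size < 3:
        raise ValidationError("terminal slope needs >= 3 positive concentrations")
    best = None
    for n in n_points:
        if n > t.size:
            continue
        tt, lc = t[-n:], np.log(c[-n:])
        slope, intercept = np.polyfit(tt, lc, 1)
        resid = lc - (slope * tt + intercept)
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((lc - lc.mean()) ** 2))
        if ss_tot == 0:
            r2adj = -np.inf if slope == 0 else 1.0
        else:
            r2 = 1.0 - ss_res / ss_tot
            r2adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        if best is None or r2adj > best[0]:
            best = (r2adj, slope)
    lam = -best[1]
    if lam <= 0:
        raise ValidationError(
            f"non-positive terminal slope at grid end t={profile.time_grid[-1]} h; "
            "extend the simulation into the terminal phase"
        )
    return lam


def auc_inf(profile: ConcentrationProfile) -> float:
    """Area under the curve to infinity, in ug/mL*h.

    Trapezoidal integral over the grid (ng/mL * h) plus C_last/lambda_z,
    converted to ug/mL*h. An all-zero profile has zero exposure.
    """
    c = profile.concentrations
    if np.all(c == 0):
        return 0.0
    auc_grid = float(np.trapezoid(c, profile.time_grid))
    lam = terminal_slope(profile)
    c_last = float(c[c > 0][-1])
    return (auc_grid + c_last / lam) / 1000.0


def cmax(profile: ConcentrationProfile) -> float:
    """Maximum gridded concentration (ng/mL)."""
    if profile.concentrations.size == 0:
        raise ValidationError("empty profile")
    return float(np.max(profile.concentrations))


def summarize(result: SimulationResult) -> ExposureSummary:
    """Per-individual AUC_inf and Cmax, summarized as median with sd spread."""
    if result.n_rows < 1:
        raise ValidationError("summarize needs at least one simulated individual")
    aucs = np.array([auc_inf(p) for p in result.profiles()])
    cmaxes = np.array([cmax(p) for p in result.profiles()])
    return ExposureSummary(
        median_auc_inf=float(np.median(aucs)),
        median_cmax=float(np.median(cmaxes)),
        sd_auc_inf=float(np.std(aucs, ddof=1)) if aucs.size > 1 else 0.0,
        sd_cmax=float(np.std(cmaxes, ddof=1)) if cmaxes.size > 1 else 0.0,
        n=int(aucs.size),
    )


def compare(test: ExposureSummary, reference: ExposureSummary):
    """Fold-change of test vs reference medians, with the 0.5-2 criterion.

    Endpoints are inclusive: ratios of exactly 0.5 or 2.0 pass. Rounding
    to one decimal is applied only at presentation (``ratio_1dp``).
    """
    reports = []
    for metric, tv, rv in (
        ("auc_inf", test.median_auc_inf, reference.median_auc_inf),
        ("cmax", test.median_cmax, reference.median_cmax),
    ):
        if rv == 0:
            raise ValidationError(f"reference median {metric} is zero")
        ratio = tv / rv
        reports.append(
            FoldChangeReport(metric=metric, ratio=float(ratio),
                             passes=bool(0.5 <= ratio <= 2.0))
        )
    return reports
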