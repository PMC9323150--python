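"""Ordinary-least-squares trend fits over the element-statistics table.

Four regressions summarize how an element's chemical breadth
(#-mineral-elements) relates to its mineral record and crustal abundance:

1. breadth vs log10(number of mineral species),
2. breadth vs log10(summed locality count),
3. log10(crustal weight percent) vs breadth,
4. atomic number vs breadth.

Elements lying far from a fitted trend are flagged from externally
studentized residuals; the default threshold of 2.0 operationalizes
"forms minerals with more/fewer elements than expected in the trend".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.diagnostic import het_breuschpagan

__all__ = [
    "RegressionResult",
    "OutlierCall",
    "DiagnosticReport",
    "DEFAULT_OUTLIER_THRESHOLD",
    "PAPER_FIT_NAMES",
    "fit_linear_trend",
    "run_paper_regressions",
    "flag_outliers",
    "regression_diagnostics",
]

Transform = Literal["none", "log10_x", "log10_y"]

DEFAULT_OUTLIER_THRESHOLD: float = 2.0

#: canonical names of the four standard fits, in order
PAPER_FIT_NAMES = (
    "breadth_vs_log_species",
    "breadth_vs_log_localities",
    "log_abundance_vs_breadth",
    "atomic_number_vs_breadth",
)


@dataclass
class RegressionResult:
    """A simple-OLS fit with per-point residual bookkeeping."""

    x_name: str
    y_name: str
    transform: Transform
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    residuals: dict[str, float]
    studentized_residuals: dict[str, float]
    slope_stderr: float
    intercept_stderr: float
    #: transformed design arrays retained for diagnostics
    x: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)

    def summary(self) -> str:
        return (
            f"OLS {self.y_name} ~ {self.x_name} (transform={self.transform}, n={self.n})\n"
            f"  slope     {self.slope:.6g} (SE {self.slope_stderr:.3g})\n"
            f"  intercept {self.intercept:.6g} (SE {self.intercept_stderr:.3g})\n"
            f"  R^2       {self.r_squared:.4f}\n"
            f"  p(slope)  {self.p_value:.3g}"
        )


@dataclass(frozen=True)
class OutlierCall:
    """An element well above (+) or below (−) a fitted trend."""

    symbol: str
    direction: Literal["positive", "negative"]
    studentized_residual: float


@dataclass(frozen=True)
class DiagnosticReport:
    """Minimal residual diagnostics for one fit."""

    normality_stat: float
    normality_p: float
    heteroscedasticity_stat: float
    heteroscedasticity_p: float
    heteroscedastic: bool
    recommend_log_transform: bool
    small_sample: bool


def _apply_transform(
    labels: list[str], x: np.ndarray, y: np.ndarray, transform: Transform
) -> tuple[np.ndarray, np.ndarray]:
    if transform == "log10_x":
        bad = [lab for lab, v in zip(labels, x) if v <= 0]
        if bad:
            raise ValueError(f"log10_x transform requires positive x; offending: {bad}")
        x = np.log10(x)
    elif transform == "log10_y":
        bad = [lab for lab, v in zip(labels, y) if v <= 0]
        if bad:
            raise ValueError(f"log10_y transform requires positive y; offending: {bad}")
        y = np.log10(y)
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite values after transform")
    return x, y


def fit_linear_trend(
    points: Mapping[str, tuple[float, float]],
    transform: Transform = "none",
    x_name: str = "x",
    y_name: str = "y",
) -> RegressionResult:
    """OLS fit of per-element (x, y) pairs, with optional log10 transform.

    The p-value is the two-sided t-test of zero slope.  Externally
    studentized residuals are recorded per element; on an exact fit (zero
    residual variance) they are defined as 0.
    """
    labels = list(points)
    if len(labels) < 3:
        raise ValueError(f"need at least 3 points, got {len(labels)}")
    x = np.asarray([points[k][0] for k in labels], dtype=float)
    y = np.asarray([points[k][1] for k in labels], dtype=float)
    x, y = _apply_transform(labels, x, y, transform)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x; slope is undefined")

    model = sm.OLS(y, sm.add_constant(x))
    fit = model.fit()
    resid = np.asarray(fit.resid)
    if np.allclose(resid, 0, atol=1e-10 * max(1.0, float(np.abs(y).max()))):
        student = np.zeros_like(resid)
        r2 = 1.0 if np.ptp(y) > 0 else 0.0
    else:
        student = np.asarray(fit.get_influence().resid_studentized_external)
        student = np.nan_to_num(student, nan=0.0)
        r2 = float(fit.rsquared) if np.ptp(y) > 0 else 0.0
    p_value = float(fit.pvalues[1])
    if math.isnan(p_value):  # exact fit: slope SE is 0
        p_value = 0.0 if fit.params[1] != 0 else 1.0
    return RegressionResult(
        x_name=x_name,
        y_name=y_name,
        transform=transform,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=r2,
        p_value=min(max(p_value, np.nextafter(0, 1)), 1.0),
        n=len(labels),
        residuals=dict(zip(labels, resid.tolist())),
        studentized_residuals=dict(zip(labels, student.tolist())),
        slope_stderr=float(fit.bse[1]),
        intercept_stderr=float(fit.bse[0]),
        x=x,
        y=y,
    )


def run_paper_regressions(records: pd.DataFrame) -> dict[str, RegressionResult]:
    """Run the four standard fits over an (exclusion-filtered) element table.

    Fit 3 drops elements without a crustal abundance value (C, H and N are
    absent from the bulk continental-crust compilation); the dropped
    symbols are recoverable as the difference in ``n`` between fits.
    """
    recs = records.set_index("symbol")

    def pairs(xcol: str, ycol: str, sub: pd.DataFrame) -> dict[str, tuple[float, float]]:
        return {s: (float(r[xcol]), float(r[ycol])) for s, r in sub.iterrows()}

    results: dict[str, RegressionResult] = {}
    results["breadth_vs_log_species"] = fit_linear_trend(
        pairs("n_minerals", "n_mineral_elements", recs),
        transform="log10_x",
        x_name="n_minerals",
        y_name="n_mineral_elements",
    )
    results["breadth_vs_log_localities"] = fit_linear_trend(
        pairs("n_localities", "n_mineral_elements", recs),
        transform="log10_x",
        x_name="n_localities",
        y_name="n_mineral_elements",
    )
    with_crust = recs.loc[recs["crustal_wt_pct"].notna()]
    results["log_abundance_vs_breadth"] = fit_linear_trend(
        pairs("crustal_wt_pct", "n_mineral_elements", with_crust),
        transform="log10_x",
        x_name="crustal_wt_pct",
        y_name="n_mineral_elements",
    )
    results["atomic_number_vs_breadth"] = fit_linear_trend(
        pairs("atomic_number", "n_mineral_elements", recs),
        transform="none",
        x_name="atomic_number",
        y_name="n_mineral_elements",
    )
    return results


def flag_outliers(
    result: RegressionResult, threshold: float = DEFAULT_OUTLIER_THRESHOLD
) -> list[OutlierCall]:
    """Elements whose externally studentized residual exceeds ±threshold,
    sorted by descending magnitude."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if result.n < 4:
        raise ValueError("outlier flagging needs at least 4 points")
    calls = [
        OutlierCall(sym, "positive" if t >= threshold else "negative", t)
        for sym, t in result.studentized_residuals.items()
        if abs(t) >= threshold
    ]
    return sorted(calls, key=lambda c: abs(c.studentized_residual), reverse=True)


def regression_diagnostics(result: RegressionResult) -> DiagnosticReport:
    """Residual normality (Shapiro–Wilk) and Breusch–Pagan heteroscedasticity.

    A normality p below 0.05 yields a "consider log transform"
    recommendation; n below 8 sets a small-sample caveat flag.
    """
    resid = np.asarray([result.residuals[k] for k in result.residuals])
    small = result.n < 8
    if np.allclose(resid, 0):
        return DiagnosticReport(0.0, 1.0, 0.0, 1.0, False, False, small)
    w, norm_p = sps.shapiro(resid)
    lm, lm_p, _, _ = het_breuschpagan(resid, sm.add_constant(result.x))
    return DiagnosticReport(
        normality_stat=float(w),
        normality_p=float(norm_p),
        heteroscedasticity_stat=float(lm),
        heteroscedasticity_p=float(lm_p),
        heteroscedastic=bool(lm_p < 0.05),
        recommend_log_transform=bool(norm_p < 0.05),
        small_sample=small,
    )
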