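"""Per-peak univariate calibration and ICH-style validation summaries.

Each retained chromatographic peak gets an ordinary-least-squares model
``area = B0 + B1 * concentration`` fitted over the calibration levels.
The module provides inverse prediction with a 95% confidence interval,
the R^2 > threshold model-selection filter, detection and quantitation
limits (LOD = 3.3 * Sy.x / B1, LOQ = 10 * Sy.x / B1 with Sy.x the standard
error of the estimate), and accuracy/precision summaries in the ICH Q2(R1)
style (%E accuracy, %RSD repeatability / intermediate precision /
stability / robustness).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LinearCalibration",
    "InversePrediction",
    "fit_linear",
    "select_calibrated_peaks",
    "inverse_predict",
    "lod_loq",
    "validation_summary",
    "pct_rsd",
]


@dataclass(frozen=True)
class LinearCalibration:
    """OLS calibration line for one peak: response = B0 + B1 * level."""

    peak_name: str
    B0: float
    B1: float
    se_B0: float
    se_B1: float
    R2: float
    Syx: float
    n: int
    x_mean: float
    Sxx: float

    def predict(self, level: float) -> float:
        return self.B0 + self.B1 * level


@dataclass(frozen=True)
class InversePrediction:
    """Interpolated concentration with its 95% confidence bounds."""

    estimate: float
    lower: float
    upper: float
    m: int = 1


def fit_linear(
    levels: Sequence[float], responses: Sequence[float], peak_name: str = ""
) -> LinearCalibration:
    """Fit response = B0 + B1 * level by OLS with coefficient SEs."""
    x = np.asarray(levels, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.size != y.size:
        raise ValueError("levels and responses must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 calibration points")
    if np.unique(x).size < 2:
        raise ValueError("all levels identical; cannot calibrate")
    res = stats.linregress(x, y)
    yhat = res.intercept + res.slope * x
    ssr = float(np.sum((y - yhat) ** 2))
    sstot = float(np.sum((y - y.mean()) ** 2))
    syx = float(np.sqrt(ssr / (x.size - 2)))
    r2 = 1.0 - ssr / sstot if sstot > 0 else 1.0
    return LinearCalibration(
        peak_name=peak_name,
        B0=float(res.intercept),
        B1=float(res.slope),
        se_B0=float(res.intercept_stderr),
        se_B1=float(res.stderr),
        R2=float(r2),
        Syx=syx,
        n=int(x.size),
        x_mean=float(x.mean()),
        Sxx=float(np.sum((x - x.mean()) ** 2)),
    )


def select_calibrated_peaks(
    models: Sequence[LinearCalibration], threshold: float = 0.99
) -> List[str]:
    """Names of models with R^2 strictly greater than the threshold."""
    if not models:
        raise ValueError("no models to select from")
    return [m.peak_name for m in models if m.R2 > threshold]


def inverse_predict(
    model: LinearCalibration, response: float, m: int = 1
) -> InversePrediction:
    """Interpolate a concentration from a measured response.

    The 95% interval uses the standard inverse-prediction half-width
    t * (Syx/|B1|) * sqrt(1/m + 1/n + (x0 - x_mean)^2 / Sxx) with m the
    number of replicate measurements averaged into ``response``.
    """
    if abs(model.B1) < 1e-14 * max(1.0, abs(model.B0)):
        raise ValueError("slope is numerically zero; cannot invert")
    x0 = (response - model.B0) / model.B1
    tcrit = stats.t.ppf(0.975, model.n - 2)
    half = (
        tcrit
        * (model.Syx / abs(model.B1))
        * np.sqrt(1.0 / m + 1.0 / model.n + (x0 - model.x_mean) ** 2 / model.Sxx)
    )
    return InversePrediction(float(x0), float(x0 - half), float(x0 + half), m)


def lod_loq(model: LinearCalibration) -> tuple:
    """Detection and quantitation limits (3.3 and 10 x Sy.x / slope)."""
    if not model.B1 > 0:
        raise ValueError("LOD/LOQ require a positive slope")
    return 3.3 * model.Syx / model.B1, 10.0 * model.Syx / model.B1


def pct_rsd(values: np.ndarray) -> float:
    """Percent relative standard deviation, sample (n-1) convention."""
    values = np.asarray(values, dtype=float)
    return float(100.0 * values.std(ddof=1) / values.mean())


def validation_summary(predictions: pd.DataFrame) -> pd.DataFrame:
    """Summarize interpolated concentrations into an ICH-style report.

    ``predictions`` is tidy with columns ``level`` (nominal, ug/mL),
    ``day``, ``run``, ``condition`` and ``value`` (interpolated ug/mL).
    Conditions: ``standard`` rows feed accuracy (%E of the grand mean vs
    nominal), repeatability (within-run %RSD, averaged over runs of day 1)
    and intermediate precision (%RSD pooled over all days); ``stability``
    rows give the timed re-injection %RSD and ``robustness`` rows the
    perturbed-condition %RSD.  Cells with fewer than 2 values are reported
    as missing (NaN), never as zero.
    """
    required = {"level", "day", "run", "condition", "value"}
    missing = required - set(predictions.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    rows = []
    for level, grp in predictions.groupby("level"):
        std = grp[grp.condition == "standard"]
        rec = {"level": level}
        rec["accuracy_pctE"] = (
            100.0 * (std.value.mean() - level) / level if len(std) else np.nan
        )
        day1 = std[std.day == std.day.min()] if len(std) else std
        within = [
            pct_rsd(g.value.to_numpy())
            for _, g in day1.groupby("run")
            if len(g) >= 2
        ]
        rec["repeatability_pctRSD"] = float(np.mean(within)) if within else np.nan
        rec["intermediate_precision_pctRSD"] = (
            pct_rsd(std.value.to_numpy()) if len(std) >= 2 and std.day.nunique() > 1 else np.nan
        )
        stab = grp[grp.condition == "stability"]
        rec["stability_pctRSD"] = pct_rsd(stab.value.to_numpy()) if len(stab) >= 2 else np.nan
        rob = grp[grp.condition == "robustness"]
        rec["robustness_pctRSD"] = pct_rsd(rob.value.to_numpy()) if len(rob) >= 2 else np.nan
        rows.append(rec)
    return pd.DataFrame(rows).set_index("level")
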