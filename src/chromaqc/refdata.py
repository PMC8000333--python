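"""Published worked-example data for the colistimethate UPLC-UV assay.

Two small tables ship with the package: the per-peak linear-calibration
coefficients of the 23 retained CMS peaks (intercept B0, slope B1, their
standard errors, R^2 and the standard error of the estimate Sy.x, all in
AU*min and ug/mL units) and the PLS-interpolated total-CMS concentrations
of the seven commercial batches assayed at a nominal 160 ug/mL.  They
serve as worked-example inputs for the LOD/LOQ and %error arithmetic.
"""

from __future__ import annotations

from importlib import resources
from typing import List

import pandas as pd

from .calibration import LinearCalibration, lod_loq

__all__ = [
    "load_reference_calibration",
    "reference_calibration_models",
    "load_pls_batch_estimates",
    "lod_loq_ranges",
    "PLS_NOMINAL_LEVEL",
]

PLS_NOMINAL_LEVEL = 160.0


def _data(name: str) -> pd.DataFrame:
    with resources.files("chromaqc.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_reference_calibration() -> pd.DataFrame:
    """The 23 published per-peak calibration coefficients."""
    return _data("cms_reference_calibration.csv")


def reference_calibration_models(n: int = 5) -> List[LinearCalibration]:
    """Wrap the published coefficients as LinearCalibration objects.

    The published table does not restate the calibration design, which was
    n = 5 levels at 100-220 ug/mL; x_mean and Sxx are reconstructed from
    those levels for inverse-prediction use.
    """
    levels = pd.Series([100.0, 130.0, 160.0, 190.0, 220.0])
    df = load_reference_calibration()
    models = []
    for _, row in df.iterrows():
        models.append(
            LinearCalibration(
                peak_name=row.peak_name,
                B0=row.B0,
                B1=row.B1,
                se_B0=row.se_B0,
                se_B1=row.se_B1,
                R2=row.R2,
                Syx=row.Syx,
                n=n,
                x_mean=float(levels.mean()),
                Sxx=float(((levels - levels.mean()) ** 2).sum()),
            )
        )
    return models


def load_pls_batch_estimates() -> pd.DataFrame:
    """PLS-interpolated total concentrations of the assayed batches."""
    return _data("cms_pls_batch_estimates.csv").set_index("batch")


def lod_loq_ranges() -> dict:
    """Min/max LOD and LOQ (ug/mL) over the 23 published calibrations."""
    pairs = [lod_loq(m) for m in reference_calibration_models()]
    lods = [p[0] for p in pairs]
    loqs = [p[1] for p in pairs]
    return {
        "lod_min": min(lods),
        "lod_max": max(lods),
        "loq_min": min(loqs),
        "loq_max": max(loqs),
    }
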