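"""Seeded end-to-end evaluation helpers.

These wrap the pipeline into small, reproducible experiments used by the
test suite and the acceptance script: a single-seed recovery trial
(calibration series plus one unknown at the nominal concentration,
assayed through baseline correction, deconvolution, calibration and
inverse prediction) and a multi-seed recovery-rate summary.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .calibration import fit_linear, inverse_predict, select_calibrated_peaks
from .peaks import match_peaks
from .pipeline import RunConfig, process_chromatograms
from .synthetic import default_profile, make_calibration_series, make_chromatogram

__all__ = ["recovery_trial", "recovery_rate"]


def recovery_trial(seed: int, config: Optional[RunConfig] = None) -> dict:
    """Assay one synthetic unknown at the nominal level through the pipeline.

    Generates the 5-level calibration series plus a conforming sample at
    the nominal concentration, runs baseline correction, deconvolution
    (residual-driven on the top standard, warm-started elsewhere),
    per-peak calibration with the R^2 filter, and returns the retained
    model count and the median inverse-predicted concentration of the
    unknown over the retained peaks.
    """
    config = config or RunConfig(seed=seed)
    profile = default_profile()
    cal_chroms, _ = make_calibration_series(profile, config.levels, seed=seed)
    test_chrom, truth = make_chromatogram(
        profile, config.nominal, seed + 500_000, sample_id="unknown", role="batch"
    )
    chroms = cal_chroms + [test_chrom]
    sets = process_chromatograms(chroms, config)
    table = match_peaks(
        sets,
        config.rt_tolerance,
        sample_ids=[c.sample_id for c in chroms],
        reference_index=len(cal_chroms) - 1,
    )
    n_cal = len(cal_chroms)
    levels = np.array([c.level for c in cal_chroms], dtype=float)
    models = [
        fit_linear(levels, table.areas[:n_cal, j], table.peak_names[j])
        for j in range(table.n_peaks)
    ]
    retained = select_calibrated_peaks(models, config.r2_threshold)
    by_name = {m.peak_name: m for m in models}
    row = table.areas[n_cal]
    estimates = [
        inverse_predict(by_name[p], row[table.peak_names.index(p)]).estimate
        for p in retained
    ]
    estimate = float(np.median(estimates))
    retained_centers = [float(p.split("_")[1]) for p in retained]
    return {
        "n_models": len(models),
        "n_retained": len(retained),
        "retained_centers": retained_centers,
        "estimate": estimate,
        "pct_error": 100.0 * (estimate - config.nominal) / config.nominal,
    }


def recovery_rate(
    n_seeds: int = 50, tolerance_pct: float = 3.0, base_seed: int = 1
) -> dict:
    """Fraction of seeds whose nominal-level estimate lands within tolerance."""
    errors = []
    for k in range(n_seeds):
        res = recovery_trial(base_seed + k)
        errors.append(res["pct_error"])
    errors = np.array(errors)
    return {
        "n_seeds": n_seeds,
        "rate_within_tol": float(np.mean(np.abs(errors) <= tolerance_pct)),
        "median_abs_pct_error": float(np.median(np.abs(errors))),
        "max_abs_pct_error": float(np.max(np.abs(errors))),
    }
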