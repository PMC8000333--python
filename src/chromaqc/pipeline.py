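"""End-to-end QC runs: baseline -> peaks -> calibration -> PLS/PCA -> conformity.

`run_qc` executes the whole pipeline from a single configuration and
returns a report bundle of six tables (calibration models, per-peak batch
interpolations, PLS predictions, validation summary, similarity battery,
SSIM scores).  Inputs are either synthetic (generated on the fly with
ground truth, the default) or chromatogram files listed in the config.
All randomness is seeded; identical configs give identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .baseline import BaselineParams, subtract_baseline
from .calibration import (
    LinearCalibration,
    fit_linear,
    inverse_predict,
    lod_loq,
    select_calibrated_peaks,
    validation_summary,
)
from .conformity import SSIMParams, conformity_report
from .io import Chromatogram, PeakTable, read_chromatogram, write_report_tables
from .multivariate import fit_with_loo, pls_predict
from .peaks import FittedPeakSet, GaussianPeak, auto_add_peaks, fit_peaks, match_peaks
from .synthetic import (
    BatchProfile,
    default_batch_profiles,
    default_profile,
    make_batches,
    make_calibration_series,
    make_chromatogram,
)

log = logging.getLogger("chromaqc")

__all__ = ["RunConfig", "RunResult", "run_qc", "version_info", "process_chromatograms"]


@dataclass
class RunConfig:
    """Configuration of a QC run (defaults follow the assay conditions)."""

    seed: int = 1
    levels: Sequence[float] = (100.0, 130.0, 160.0, 190.0, 220.0)
    nominal: float = 160.0
    r2_threshold: float = 0.99
    baseline: BaselineParams = field(default_factory=BaselineParams)
    max_peaks: int = 40
    min_height: float = 1.2e-3
    max_hwhm: float = 0.3
    init_hwhm: float = 0.06
    rt_tolerance: float = 0.15
    max_components: int = 4
    fit_points: int = 3000  # decimation target for the deconvolution stage
    ssim: SSIMParams = field(default_factory=SSIMParams)
    ssim_threshold: float = 0.97
    reference_peak: Optional[str] = None  # default: retained peak with max R^2
    validate: bool = False
    validation_days: int = 2
    validation_replicates: int = 2
    outdir: Optional[str] = None
    # file-input mode (synthetic when empty)
    calibration_files: Sequence[str] = ()
    calibration_levels: Sequence[float] = ()
    batch_files: Sequence[str] = ()
    reference_batch: Optional[str] = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key, val in raw.items():
            if key == "baseline":
                kwargs["baseline"] = BaselineParams(**val)
            elif key == "ssim":
                kwargs["ssim"] = SSIMParams(**val)
            else:
                kwargs[key] = val
        return cls(**kwargs)


@dataclass
class RunResult:
    """Report bundle of one QC run."""

    tables: Dict[str, pd.DataFrame]
    models: List[LinearCalibration]
    retained_peaks: List[str]
    peak_table: PeakTable
    pls_model: object
    reference_peak: str
    log_records: List[str] = field(default_factory=list)


def _scaled_template(template: FittedPeakSet, scale: float) -> FittedPeakSet:
    peaks = [GaussianPeak(p.height * scale, p.center, p.hwhm) for p in template.peaks]
    return FittedPeakSet(peaks)


def process_chromatograms(
    chroms: Sequence[Chromatogram],
    config: RunConfig,
    reference_index: Optional[int] = None,
    template: Optional[FittedPeakSet] = None,
    template_level: Optional[float] = None,
) -> List[FittedPeakSet]:
    """Baseline-correct and deconvolve a set of traces.

    The reference trace (default: the calibration sample at the highest
    level, else the first trace) is deconvolved from scratch by
    residual-driven peak addition; every other trace starts from the
    reference peak set with heights rescaled by the level ratio, which
    keeps the same peaks integrated in all runs.  When an already fitted
    ``template`` (with its level) is supplied, every trace is warm-fitted
    from it instead.
    """
    corrected = [subtract_baseline(c, config.baseline) for c in chroms]
    # baseline runs at full resolution; the nonlinear fit does not need it
    step = max(1, len(chroms[0]) // config.fit_points)
    if step > 1:
        corrected = [
            Chromatogram(c.sample_id, c.time[::step], c.intensity[::step],
                         level=c.level, role=c.role)
            for c in corrected
        ]
    sets: List[Optional[FittedPeakSet]] = [None] * len(chroms)
    if template is None:
        if reference_index is None:
            cal = [i for i, c in enumerate(chroms) if c.role == "calibration" and c.level]
            reference_index = max(cal, key=lambda i: chroms[i].level) if cal else 0
        template_level = chroms[reference_index].level or config.nominal
        template = auto_add_peaks(
            corrected[reference_index],
            max_peaks=config.max_peaks,
            min_height=config.min_height,
            init_hwhm=config.init_hwhm,
            max_hwhm=config.max_hwhm,
        )
        log.info("reference trace: %d peaks found", len(template))
        sets[reference_index] = template
    elif template_level is None:
        template_level = config.nominal
    for i, chrom in enumerate(chroms):
        if sets[i] is not None:
            continue
        scale = (chrom.level or config.nominal) / template_level
        sets[i] = fit_peaks(
            corrected[i], _scaled_template(template, scale), max_hwhm=config.max_hwhm
        )
    return sets


def _calibration_table(models: Sequence[LinearCalibration]) -> pd.DataFrame:
    rows = []
    for m in models:
        lod, loq = lod_loq(m) if m.B1 > 0 else (np.nan, np.nan)
        rows.append(
            {
                "peak_name": m.peak_name,
                "B0": m.B0,
                "B1": m.B1,
                "se_B0": m.se_B0,
                "se_B1": m.se_B1,
                "R2": m.R2,
                "Syx": m.Syx,
                "LOD": lod,
                "LOQ": loq,
            }
        )
    return pd.DataFrame(rows).set_index("peak_name")


def _simulate_validation(
    profile, config: RunConfig, models, retained, template, template_level
) -> pd.DataFrame:
    """Generate and assay validation samples (accuracy/precision/stability/
    robustness), then summarize worst-case metrics across the retained models."""
    rng = np.random.default_rng(config.seed + 900)
    jobs = []  # (level, day, run, replicate, condition, global_scale)
    for level in (130.0, 160.0, 190.0):
        for day in range(1, config.validation_days + 1):
            for rep in range(1, config.validation_replicates + 1):
                jobs.append((level, day, 1, rep, "standard", 1.0))
    for rep in range(1, 4):
        jobs.append((160.0, 1, 1, rep, "stability", 1.0))
    for rep in range(1, 4):
        jobs.append((160.0, 1, 1, rep, "robustness", float(rng.uniform(0.98, 1.02))))
    chroms = []
    meta = []
    for level, day, run, rep, cond, scale in jobs:
        pert = BatchProfile(
            f"v_{cond}", {n: scale for n in profile.peak_names}, "conforming"
        )
        chrom, _ = make_chromatogram(
            profile,
            level,
            int(rng.integers(0, 2**31 - 1)),
            sample_id=f"val_{cond}_{level:g}_{day}_{rep}",
            role="batch",
            perturbation=pert if scale != 1.0 else None,
        )
        chroms.append(chrom)
        meta.append((level, day, run, cond))
    sets = process_chromatograms(
        chroms, config, template=template, template_level=template_level
    )
    # prepend the template so its centers define the peak names
    table = match_peaks(
        [template] + sets,
        config.rt_tolerance,
        ["template"] + [c.sample_id for c in chroms],
    )
    table = PeakTable(
        table.sample_ids[1:], table.peak_names, table.areas[1:], None
    )
    by_name = {m.peak_name: m for m in models}
    frames = []
    for peak in retained:
        if peak not in table.peak_names:
            continue
        col = table.areas[:, table.peak_names.index(peak)]
        recs = []
        for (level, day, run, cond), area in zip(meta, col):
            est = inverse_predict(by_name[peak], area).estimate
            recs.append(
                {"level": level, "day": day, "run": run, "condition": cond, "value": est}
            )
        rep_table = validation_summary(pd.DataFrame(recs))
        rep_table["peak"] = peak
        frames.append(rep_table)
    full = pd.concat(frames)
    worst = full.drop(columns="peak").abs().groupby(level=0).max()
    worst.columns = ["max_abs_" + c for c in worst.columns]
    return worst


def run_qc(config: RunConfig) -> RunResult:
    """Execute the full QC pipeline and assemble the report bundle."""
    records: List[str] = []

    def note(msg, *args):
        log.info(msg, *args)
        records.append(msg % args if args else msg)

    note("chromaqc %s, seed=%d", __version__, config.seed)
    if config.calibration_files:
        if len(config.calibration_files) != len(config.calibration_levels):
            raise ValueError("calibration_files and calibration_levels differ in length")
        if not config.batch_files:
            raise ValueError("batch files required in file mode")
        if config.reference_batch is None:
            raise ValueError("reference required")
        cal_chroms = [
            read_chromatogram(p, level=l, role="calibration")
            for p, l in zip(config.calibration_files, config.calibration_levels)
        ]
        batch_chroms = [read_chromatogram(p, role="batch") for p in config.batch_files]
        reference_id = config.reference_batch
        profile = None
        labels = None
    else:
        profile = default_profile()
        cal_chroms, _ = make_calibration_series(
            profile, config.levels, replicates=1, seed=config.seed
        )
        batch_profiles = [BatchProfile("reference", {}, "conforming")]
        batch_profiles += default_batch_profiles(profile, seed=config.seed)
        batch_chroms, labels = make_batches(
            profile, batch_profiles, concentration=config.nominal, seed=config.seed
        )
        reference_id = "reference"
    note("inputs: %d calibration + %d batch traces", len(cal_chroms), len(batch_chroms))

    chroms = list(cal_chroms) + list(batch_chroms)
    sets = process_chromatograms(chroms, config)
    table = match_peaks(
        sets,
        config.rt_tolerance,
        sample_ids=[c.sample_id for c in chroms],
        reference_index=len(cal_chroms) - 1,  # highest-level calibration trace
        levels=[c.level if c.role == "calibration" else np.nan for c in chroms],
    )
    note("peak table: %d samples x %d peaks", table.n_samples, table.n_peaks)

    n_cal = len(cal_chroms)
    cal_levels = np.array([c.level for c in cal_chroms], dtype=float)
    models = [
        fit_linear(cal_levels, table.areas[:n_cal, j], table.peak_names[j])
        for j in range(table.n_peaks)
    ]
    retained = select_calibrated_peaks(models, config.r2_threshold)
    note("calibration: %d models, %d retained at R2 > %.2f",
         len(models), len(retained), config.r2_threshold)
    models_table = _calibration_table(models)
    models_table["retained"] = [m.peak_name in retained for m in models]

    by_name = {m.peak_name: m for m in models}
    batch_ids = [c.sample_id for c in batch_chroms]
    interp = pd.DataFrame(index=retained, columns=batch_ids, dtype=float)
    for sid in batch_ids:
        row = table.row(sid)
        for peak in retained:
            area = row[table.peak_names.index(peak)]
            interp.loc[peak, sid] = inverse_predict(by_name[peak], area).estimate
    interp.index.name = "peak_name"

    X_cal = table.areas[:n_cal]
    pls = fit_with_loo(
        X_cal,
        cal_levels,
        max_components=min(config.max_components, n_cal - 2),
        peak_names=table.peak_names,
    )
    note("PLS: %d component(s) selected, fitted R2=%.4f",
         pls.n_components, pls.r2_fitted[pls.n_components - 1])
    pls_table = pls_predict(pls, table.areas[n_cal:], nominal=config.nominal)
    pls_table.index = batch_ids

    if config.validate:
        if profile is None:
            raise ValueError("validation requires synthetic mode")
        validation = _simulate_validation(
            profile, config, models, retained,
            template=sets[n_cal - 1], template_level=cal_levels[-1],
        )
    else:
        validation = pd.DataFrame(
            columns=[
                "max_abs_accuracy_pctE",
                "max_abs_repeatability_pctRSD",
                "max_abs_intermediate_precision_pctRSD",
                "max_abs_stability_pctRSD",
                "max_abs_robustness_pctRSD",
            ]
        )

    ref_peak = config.reference_peak
    if ref_peak is None:
        ref_peak = max(
            (m for m in models if m.peak_name in retained), key=lambda m: m.R2
        ).peak_name
    note("conformity reference peak: %s", ref_peak)
    batch_table = PeakTable(
        batch_ids, table.peak_names, table.areas[n_cal:], None
    ).subset(retained)
    conf = conformity_report(
        batch_table,
        reference_id=reference_id,
        reference_peak=ref_peak,
        ssim_params=config.ssim,
        ssim_threshold=config.ssim_threshold,
    )
    similarity = conf.drop(columns=["ssim", "pca_score_distance", "flag"]).T
    ssim_table = conf[["ssim", "pca_score_distance", "flag"]]
    if labels is not None:
        ssim_table = ssim_table.join(labels["label"], how="left")

    tables = {
        "calibration_models": models_table,
        "batch_interpolations": interp,
        "pls_predictions": pls_table,
        "validation": validation,
        "similarity": similarity,
        "ssim": ssim_table,
    }
    if config.outdir:
        written = write_report_tables(tables, config.outdir, decimals=4)
        note("wrote %d tables to %s", len(written), config.outdir)
    return RunResult(
        tables=tables,
        models=models,
        retained_peaks=retained,
        peak_table=table,
        pls_model=pls,
        reference_peak=ref_peak,
        log_records=records,
    )


def version_info() -> str:
    """Tool version and the parameter defaults of a run."""
    cfg = RunConfig()
    return (
        f"chromaqc {__version__}\n"
        f"baseline: lambda_exponent={cfg.baseline.lambda_exponent}, "
        f"hwi={cfg.baseline.hwi}, iterations={cfg.baseline.iterations}, "
        f"buckets={cfg.baseline.buckets}\n"
        f"peaks: max_peaks={cfg.max_peaks}, min_height={cfg.min_height}, "
        f"rt_tolerance={cfg.rt_tolerance}\n"
        f"calibration: levels={tuple(cfg.levels)}, R2 threshold={cfg.r2_threshold}\n"
        f"ssim: K1={cfg.ssim.K1}, K2={cfg.ssim.K2}, window={cfg.ssim.window}"
    )
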