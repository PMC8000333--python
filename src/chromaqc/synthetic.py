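"""Synthetic chromatogram generator with exact ground truth.

No raw traces are deposited for the colistimethate UPLC-UV assay, so the
pipeline is exercised on synthetic data that emulate its statistical
structure: a 29-peak Gaussian profile over a 0-34 min gradient window,
23 peaks with strictly linear detector response (response factors spanning
~1e-6 to ~4e-5 AU*min per ug/mL, matching the published calibration
slopes) and 6 peaks with a deliberately curved (quadratic) response plus
inflated area noise, so that the downstream R^2 > 0.99 filter retains
exactly the 23 designed-linear peaks.  Traces ride on a smooth drifting
baseline with additive i.i.d. Gaussian detector noise.  Batch samples
apply multiplicative per-peak perturbations: conforming batches stay
within +/-3%, moderately deviating batches move a peak subset by ~15%,
and an "expired-like" batch raises most peaks by ~35% while dropping a
small subset by ~20% (the degradation pattern seen in aged lots).

Every dataset is reproducible from (profile, seed), and the truth records
carry the analytic Gaussian areas actually synthesized — no numerical
integration is involved on the truth side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import Chromatogram, peak_name
from .peaks import _AREA_FACTOR, gaussian_profile

__all__ = [
    "SyntheticProfile",
    "BatchProfile",
    "default_profile",
    "default_batch_profiles",
    "true_areas",
    "make_chromatogram",
    "make_calibration_series",
    "make_batches",
    "CALIBRATION_LEVELS",
]

CALIBRATION_LEVELS = (100.0, 130.0, 160.0, 190.0, 220.0)

# retention times (min) and linear response factors (AU*min per ug/mL) of
# the 23 linear-response peaks
_LINEAR_PEAKS: List[Tuple[float, float]] = [
    (7.28, 1.73e-6),
    (8.73, 4.88e-6),
    (9.02, 1.73e-6),
    (9.30, 8.27e-6),
    (9.80, 1.32e-6),
    (10.43, 2.96e-5),
    (11.99, 3.62e-5),
    (12.53, 3.0e-6),
    (12.76, 7.74e-6),
    (13.18, 1.61e-5),
    (14.35, 1.54e-5),
    (17.18, 1.59e-6),
    (18.95, 1.18e-6),
    (19.33, 1.07e-5),
    (20.27, 4.29e-6),
    (20.87, 1.29e-6),
    (21.33, 8.46e-6),
    (21.75, 4.77e-6),
    (22.12, 3.82e-6),
    (22.70, 1.13e-5),
    (23.13, 1.24e-5),
    (23.65, 1.08e-5),
    (24.20, 3.72e-6),
]

# the 6 curved-response peaks sit away from the named ones (>0.3 min gaps)
_NONLINEAR_PEAKS: List[Tuple[float, float]] = [
    (8.20, 5.5e-6),
    (10.90, 9.0e-6),
    (15.60, 4.0e-6),
    (16.40, 7.0e-6),
    (18.20, 6.0e-6),
    (19.90, 8.0e-6),
]


@dataclass(frozen=True)
class SyntheticProfile:
    """Ground-truth chromatographic profile for the generator."""

    centers: np.ndarray
    response_factors: np.ndarray
    hwhm: np.ndarray
    linear: np.ndarray  # bool mask; False = curved response, 3x area noise
    t_start: float = 0.0
    t_end: float = 34.0
    dt: float = 0.001
    drift_offset: float = 0.02
    drift_slope: float = 0.0006  # AU per min
    drift_sine_amp: float = 0.008
    noise_sd: float = 2e-5  # AU, additive on the trace
    area_rel_noise: float = 0.004  # relative area jitter, linear peaks
    nonlinear_noise_mult: float = 3.0

    def __post_init__(self) -> None:
        c = np.asarray(self.centers, dtype=float)
        if not np.all(np.diff(c) > 0):
            raise ValueError("peak centers must be strictly increasing")
        if np.any(np.asarray(self.response_factors) <= 0):
            raise ValueError("response factors must be positive")

    @property
    def n_peaks(self) -> int:
        return len(self.centers)

    @property
    def peak_names(self) -> List[str]:
        return [peak_name(c) for c in self.centers]

    @property
    def linear_peak_names(self) -> List[str]:
        return [n for n, lin in zip(self.peak_names, self.linear) if lin]

    def time_grid(self) -> np.ndarray:
        n = int(round((self.t_end - self.t_start) / self.dt)) + 1
        return self.t_start + self.dt * np.arange(n)

    def drift(self, t: np.ndarray) -> np.ndarray:
        span = self.t_end - self.t_start
        return (
            self.drift_offset
            + self.drift_slope * (t - self.t_start)
            + self.drift_sine_amp * np.sin(np.pi * (t - self.t_start) / span)
        )


def default_profile(**overrides) -> SyntheticProfile:
    """The 29-peak profile the pipeline is validated on."""
    entries = sorted(
        [(c, rf, True) for c, rf in _LINEAR_PEAKS]
        + [(c, rf, False) for c, rf in _NONLINEAR_PEAKS]
    )
    centers = np.array([e[0] for e in entries])
    rfs = np.array([e[1] for e in entries])
    linear = np.array([e[2] for e in entries])
    # deterministic narrow widths in [0.05, 0.08] min
    hwhm = 0.05 + 0.03 * ((np.arange(len(centers)) * 7) % 11) / 10.0
    return SyntheticProfile(
        centers=centers, response_factors=rfs, hwhm=hwhm, linear=linear, **overrides
    )


@dataclass(frozen=True)
class BatchProfile:
    """Per-peak multiplicative perturbation pattern of one batch."""

    name: str
    perturbation: Dict[str, float]
    label: str = "conforming"

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.perturbation.values()):
            raise ValueError("perturbations must be positive")
        if self.label not in ("conforming", "moderate_deviation", "expired_like"):
            raise ValueError(f"unknown label {self.label!r}")

    def factor(self, name: str) -> float:
        return self.perturbation.get(name, 1.0)


def default_batch_profiles(
    profile: SyntheticProfile, seed: int = 0
) -> List[BatchProfile]:
    """A batch panel mirroring a typical QC campaign.

    One moderately deviating batch (b1), three conforming batches
    (b2-b4) and one expired-like batch (b5) whose degradation pattern
    drops four peaks by ~20% while the rest rise by ~35%.
    """
    rng = np.random.default_rng(seed)
    names = profile.peak_names
    out = []
    mod = {n: 1.0 for n in names}
    moved = rng.choice(len(names), size=8, replace=False)
    for i in moved:
        mod[names[i]] = 1.0 + rng.choice([-0.15, 0.15]) * rng.uniform(0.8, 1.0)
    out.append(BatchProfile("b1", mod, "moderate_deviation"))
    for bname in ("b2", "b3", "b4"):
        pert = {n: float(rng.uniform(0.97, 1.03)) for n in names}
        out.append(BatchProfile(bname, pert, "conforming"))
    lowered = {"peak_8.73", "peak_10.43", "peak_23.13", "peak_23.65"}
    exp = {}
    for n in names:
        if n in lowered:
            exp[n] = float(0.80 * rng.uniform(0.98, 1.02))
        else:
            exp[n] = float(1.35 * rng.uniform(0.98, 1.02))
    out.append(BatchProfile("b5", exp, "expired_like"))
    return out


def true_areas(profile: SyntheticProfile, concentration: float) -> np.ndarray:
    """Noise-free design areas at a concentration (AU*min).

    Linear peaks respond as rf * x; the curved peaks follow the quadratic
    rf * (2 x^2 / 160 - x), which coincides with the linear response at
    x = 160 ug/mL but bends strongly enough across 100-220 ug/mL that an
    OLS line cannot reach R^2 > 0.99.
    """
    x = float(concentration)
    rf = profile.response_factors
    lin = rf * x
    quad = rf * (2.0 * x * x / 160.0 - x)
    return np.where(profile.linear, lin, quad)


def make_chromatogram(
    profile: SyntheticProfile,
    concentration: float,
    seed: int,
    sample_id: str = "sample",
    role: str = "unknown",
    perturbation: Optional[BatchProfile] = None,
) -> Tuple[Chromatogram, dict]:
    """Synthesize one trace; returns (chromatogram, truth record).

    The truth record holds the exact analytic area, height and width of
    every generated Gaussian (after area jitter and any batch
    perturbation) plus the baseline array that was added.
    """
    if not concentration > 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    t = profile.time_grid()
    areas = true_areas(profile, concentration).copy()
    if perturbation is not None:
        factors = np.array([perturbation.factor(n) for n in profile.peak_names])
        areas = areas * factors
    rel_sd = np.where(
        profile.linear,
        profile.area_rel_noise,
        profile.area_rel_noise * profile.nonlinear_noise_mult,
    )
    areas = areas * (1.0 + rel_sd * rng.standard_normal(profile.n_peaks))
    areas = np.abs(areas)
    heights = areas / (profile.hwhm * _AREA_FACTOR)
    y = np.zeros_like(t)
    for h, c, w in zip(heights, profile.centers, profile.hwhm):
        y += gaussian_profile(t, h, c, w)
    baseline = profile.drift(t)
    y = y + baseline + profile.noise_sd * rng.standard_normal(t.size)
    chrom = Chromatogram(sample_id, t, y, level=concentration, role=role)
    truth = {
        "sample_id": sample_id,
        "level": concentration,
        "peak_names": profile.peak_names,
        "areas": dict(zip(profile.peak_names, areas)),
        "heights": dict(zip(profile.peak_names, heights)),
        "hwhm": dict(zip(profile.peak_names, profile.hwhm)),
        "baseline": baseline,
    }
    return chrom, truth


def make_calibration_series(
    profile: SyntheticProfile,
    levels: Sequence[float] = CALIBRATION_LEVELS,
    replicates: int = 1,
    seed: int = 0,
) -> Tuple[List[Chromatogram], pd.DataFrame]:
    """One chromatogram per level x replicate, plus a tidy truth table."""
    if np.any(np.asarray(levels) <= 0):
        raise ValueError("levels must be positive")
    ss = np.random.SeedSequence(seed)
    child = ss.generate_state(len(levels) * replicates, dtype=np.uint32)
    chroms, rows = [], []
    k = 0
    for rep in range(replicates):
        for lev in levels:
            sid = f"cal_{lev:g}" if replicates == 1 else f"cal_{lev:g}_r{rep+1}"
            chrom, truth = make_chromatogram(
                profile, lev, int(child[k]), sample_id=sid, role="calibration"
            )
            chroms.append(chrom)
            for name, area in truth["areas"].items():
                rows.append(
                    {"sample_id": sid, "level": lev, "replicate": rep + 1,
                     "peak": name, "true_area": area}
                )
            k += 1
    return chroms, pd.DataFrame(rows)


def make_batches(
    profile: SyntheticProfile,
    batch_profiles: Optional[Sequence[BatchProfile]] = None,
    concentration: float = 160.0,
    seed: int = 0,
) -> Tuple[List[Chromatogram], pd.DataFrame]:
    """Batch samples at the nominal assay concentration, plus truth labels."""
    if batch_profiles is None:
        batch_profiles = default_batch_profiles(profile, seed)
    if not batch_profiles:
        raise ValueError("batch_profiles must be non-empty")
    ss = np.random.SeedSequence(seed + 1)
    child = ss.generate_state(len(batch_profiles), dtype=np.uint32)
    chroms, rows = [], []
    for i, bp in enumerate(batch_profiles):
        chrom, truth = make_chromatogram(
            profile, concentration, int(child[i]), sample_id=bp.name, role="batch",
            perturbation=bp,
        )
        chroms.append(chrom)
        rows.append({"sample_id": bp.name, "label": bp.label,
                     "level": concentration})
    return chroms, pd.DataFrame(rows).set_index("sample_id")
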