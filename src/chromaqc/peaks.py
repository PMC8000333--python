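"""Gaussian peak deconvolution, integration and cross-run matching.

A baseline-corrected chromatogram is modelled as a sum of Gaussian peaks
parameterized by (height, center, hwhm), profile
``h * exp(-ln2 * ((t - c) / w)**2)``, whose analytic area is
``h * w * sqrt(pi / ln 2)``.  Peaks are refined jointly by damped nonlinear
least squares, new peaks are seeded at the residual maximum until the
residual falls below a threshold, and peak sets from different runs are
matched by retention time against a reference run to build a peak table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .io import Chromatogram, PeakTable, peak_name

__all__ = [
    "GaussianPeak",
    "FittedPeakSet",
    "gaussian_area",
    "gaussian_profile",
    "fit_peaks",
    "auto_add_peaks",
    "match_peaks",
    "doe_responses",
]

_LN2 = np.log(2.0)
_AREA_FACTOR = np.sqrt(np.pi / _LN2)  # area = h * w * sqrt(pi/ln2)


@dataclass(frozen=True)
class GaussianPeak:
    """One Gaussian peak: height (AU), center (min), hwhm (min)."""

    height: float
    center: float
    hwhm: float

    def __post_init__(self) -> None:
        if not (self.height > 0 and self.hwhm > 0):
            raise ValueError("height and hwhm must be positive")

    @property
    def fwhm(self) -> float:
        return 2.0 * self.hwhm

    @property
    def area(self) -> float:
        return gaussian_area(self)


def gaussian_profile(t: np.ndarray, height: float, center: float, hwhm: float) -> np.ndarray:
    return height * np.exp(-_LN2 * ((t - center) / hwhm) ** 2)


def gaussian_area(peak: GaussianPeak) -> float:
    """Analytic area under a Gaussian peak, AU*min."""
    return peak.height * peak.hwhm * _AREA_FACTOR


@dataclass
class FittedPeakSet:
    """A fitted sum-of-Gaussians model of one chromatogram."""

    peaks: List[GaussianPeak]
    sum_squared_residuals: float = np.nan
    n_points: int = 0
    converged: bool = False
    excluded: List[GaussianPeak] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: p.center)

    def __len__(self) -> int:
        return len(self.peaks)

    def model(self, t: np.ndarray) -> np.ndarray:
        y = np.zeros_like(np.asarray(t, dtype=float))
        for p in self.peaks:
            y += gaussian_profile(t, p.height, p.center, p.hwhm)
        return y

    def areas(self) -> np.ndarray:
        return np.array([gaussian_area(p) for p in self.peaks])


def _pack(peaks: Sequence[GaussianPeak]) -> np.ndarray:
    return np.array([[p.height, p.center, p.hwhm] for p in peaks]).ravel()


def _unpack(theta: np.ndarray) -> List[GaussianPeak]:
    theta = theta.reshape(-1, 3)
    return [GaussianPeak(h, c, max(w, 1e-12)) for h, c, w in theta]


def _model_and_jac(theta: np.ndarray, t: np.ndarray):
    p = theta.reshape(-1, 3)
    h, c, w = p[:, 0:1], p[:, 1:2], p[:, 2:3]
    u = (t[None, :] - c) / w
    g = np.exp(-_LN2 * u**2)  # (k, n)
    model = (h * g).sum(axis=0)
    dh = g
    dc = h * g * (2.0 * _LN2 * u / w)
    dw = h * g * (2.0 * _LN2 * u**2 / w)
    jac = np.empty((t.size, theta.size))
    jac[:, 0::3] = dh.T
    jac[:, 1::3] = dc.T
    jac[:, 2::3] = dw.T
    return model, jac


def fit_peaks(
    chrom: Chromatogram,
    initial: FittedPeakSet,
    rel_tol: float = 1e-10,
    max_nfev: int = 200,
    max_hwhm: Optional[float] = None,
) -> FittedPeakSet:
    """Refine all peak parameters by damped nonlinear least squares.

    The cost never increases relative to the initial parameter vector.  On
    failure to converge within the iteration budget the best point found is
    returned with ``converged=False``; degenerate peaks (hwhm below one
    sampling interval) are excluded and reported on ``excluded``.
    """
    t, y = chrom.time, chrom.intensity
    k = len(initial.peaks)
    if k == 0:
        return FittedPeakSet([], float(np.sum(y**2)), len(chrom), True)
    if len(chrom) < 3 * k:
        raise ValueError(f"{len(chrom)} points cannot constrain {k} peaks")
    dt = float(np.median(np.diff(t)))
    theta0 = _pack(initial.peaks)
    w_max = max_hwhm if max_hwhm is not None else (t[-1] - t[0])
    lo = np.tile([1e-12, t[0] - 1.0, dt / 10.0], k)
    hi = np.tile([np.inf, t[-1] + 1.0, w_max], k)
    theta0 = np.clip(theta0, lo, hi)

    def resid(theta):
        model, _ = _model_and_jac(theta, t)
        return model - y

    def jac(theta):
        _, J = _model_and_jac(theta, t)
        return J

    res = least_squares(
        resid,
        theta0,
        jac=jac,
        bounds=(lo, hi),
        method="trf",
        x_scale="jac",
        ftol=rel_tol,
        xtol=1e-12,
        gtol=1e-12,
        max_nfev=max_nfev,
    )
    peaks = _unpack(res.x)
    kept, excluded = [], []
    for p in peaks:
        (kept if p.hwhm >= dt else excluded).append(p)
    if excluded:
        warnings.warn(f"{len(excluded)} degenerate peak(s) excluded (hwhm < {dt:.4g} min)")
    ssr = float(2.0 * res.cost)
    return FittedPeakSet(kept, ssr, len(chrom), bool(res.status > 0), excluded)


def auto_add_peaks(
    chrom: Chromatogram,
    current: Optional[FittedPeakSet] = None,
    max_peaks: int = 40,
    min_height: float = 1.2e-3,
    init_hwhm: float = 0.06,
    max_nfev: int = 60,
    max_hwhm: float = 0.3,
) -> FittedPeakSet:
    """Residual-driven peak addition.

    Repeatedly seeds a Gaussian at the residual maximum (height = residual
    value there, hwhm = ``init_hwhm``), refits all peaks, and stops when the
    residual maximum drops below ``min_height`` or ``max_peaks`` is reached.
    Peak widths are bounded by ``max_hwhm``: real chromatographic peaks at
    this scale are seconds wide, so components that run into the width
    bound (or end below ``min_height``) are absorbing residual background,
    not peaks, and are pruned before the final tight refit.
    """
    t, y = chrom.time, chrom.intensity
    if current is None:
        current = FittedPeakSet([], float(np.sum(y**2)), len(chrom), True)
    best = current
    while len(best) < max_peaks:
        resid = y - best.model(t)
        imax = int(np.argmax(resid))
        if resid[imax] < min_height:
            break
        seed = GaussianPeak(float(resid[imax]), float(t[imax]), init_hwhm)
        candidate = FittedPeakSet(best.peaks + [seed])
        best = fit_peaks(chrom, candidate, max_nfev=max_nfev, max_hwhm=max_hwhm)
    pruned = [
        p for p in best.peaks
        if p.height >= min_height and p.hwhm < 0.99 * max_hwhm
    ]
    if len(pruned) > 0 and (len(pruned) < len(best) or best is not current):
        best = fit_peaks(
            chrom, FittedPeakSet(pruned), max_nfev=max_nfev * 3, max_hwhm=max_hwhm
        )
    return best


def match_peaks(
    sets: Sequence[FittedPeakSet],
    rt_tolerance: float = 0.15,
    sample_ids: Optional[Sequence[str]] = None,
    reference_index: int = 0,
    levels: Optional[Sequence[float]] = None,
) -> PeakTable:
    """Match fitted peaks across runs by retention time.

    Peak names come from the reference set's centers; for every other run
    each reference peak is matched greedily to the nearest unclaimed center
    within ``rt_tolerance`` minutes.  Unmatched reference peaks get area 0
    with a warning.
    """
    if not sets:
        raise ValueError("need at least one peak set")
    if sample_ids is None:
        sample_ids = [f"sample_{i}" for i in range(len(sets))]
    ref = sets[reference_index]
    ref_centers = np.array([p.center for p in ref.peaks])
    names = [peak_name(c) for c in ref_centers]
    areas = np.zeros((len(sets), len(names)))
    for si, pset in enumerate(sets):
        centers = np.array([p.center for p in pset.peaks])
        peak_areas = pset.areas()
        claimed = np.zeros(centers.size, dtype=bool)
        # visit reference peaks in order of best available match
        order = sorted(
            range(ref_centers.size),
            key=lambda j: np.min(np.abs(centers - ref_centers[j])) if centers.size else np.inf,
        )
        for j in order:
            if centers.size == 0:
                break
            d = np.abs(centers - ref_centers[j])
            d[claimed] = np.inf
            i = int(np.argmin(d))
            if d[i] <= rt_tolerance:
                areas[si, j] = peak_areas[i]
                claimed[i] = True
        missing = [names[j] for j in range(len(names)) if areas[si, j] == 0.0]
        if missing:
            warnings.warn(
                f"{sample_ids[si]}: unmatched reference peak(s) {missing}; area set to 0"
            )
    return PeakTable(list(sample_ids), names, areas, levels)


def doe_responses(pset: FittedPeakSet) -> tuple:
    """The two chromatographic response factors used for method optimization.

    Returns (sum of half-height resolutions over adjacent peak pairs,
    sum of analytic peak areas).  Rs = 1.18 * (c2 - c1) / (fwhm1 + fwhm2).
    """
    peaks = pset.peaks
    sum_area = float(sum(gaussian_area(p) for p in peaks))
    if len(peaks) < 2:
        return 0.0, sum_area
    rs = 0.0
    for a, b in zip(peaks[:-1], peaks[1:]):
        rs += 1.18 * (b.center - a.center) / (a.fwhm + b.fwhm)
    return float(rs), sum_area
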