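"""Baseline estimation by iterative mean suppression ("peak filling").

UV chromatograms acquired near the solvent cut-off ride on a large, slowly
varying baseline.  The estimator here follows the iterative mean-suppression
family: the trace is first smoothed with a discrete second-difference
penalized (Whittaker) smoother, aggregated into a coarse grid of contiguous
buckets, and the bucket values are then repeatedly replaced by the minimum
of their current value and the chord through the two window endpoints (the
mean of the values at distance +/-w), with the window half-width shrinking
geometrically across passes and each pass updating in place so that filled
values propagate across wide peak clusters.  Peaks, which rise above their
surroundings, are thereby "filled" from above while the smooth baseline is
preserved.  The bucket values are finally interpolated back to the full
time grid and lightly re-smoothed.

Parameters (defaults follow the values selected for the colistimethate
UPLC-UV traces): ``lambda_exponent`` = 6 (log10 of the Whittaker penalty),
``hwi`` = 30 buckets, ``iterations`` = 10, ``buckets`` = 2000.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .io import Chromatogram

__all__ = [
    "BaselineParams",
    "whittaker_smooth",
    "estimate_baseline",
    "subtract_baseline",
]


@dataclass(frozen=True)
class BaselineParams:
    """Parameters of the peak-filling baseline estimator."""

    lambda_exponent: float = 6.0
    hwi: int = 30
    iterations: int = 10
    buckets: int = 2000

    def validate(self, n_points: int) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.buckets < 4:
            raise ValueError("buckets must be >= 4")
        if self.hwi < 1:
            raise ValueError("hwi must be >= 1")
        if self.buckets > n_points:
            raise ValueError(
                f"buckets ({self.buckets}) exceeds signal length ({n_points})"
            )


def whittaker_smooth(y: np.ndarray, log10_penalty: float) -> np.ndarray:
    """Second-difference penalized smoother.

    Returns the minimizer z of  sum (y_i - z_i)^2 + 10^log10_penalty *
    sum (delta^2 z)^2 , i.e. the solution of (I + lam * D'D) z = y with D
    the second-difference operator.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise ValueError("y must be a 1-D vector of length >= 3")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in input")
    n = y.size
    lam = 10.0 ** float(log10_penalty)
    D = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n), format="csc")
    A = sparse.identity(n, format="csc") + lam * (D.T @ D)
    return spsolve(A, y)


def _bucket_slices(n: int, buckets: int) -> list:
    """Contiguous near-equal-count segments (sizes differ by at most one)."""
    bounds = np.linspace(0, n, buckets + 1).round().astype(int)
    return [slice(bounds[i], bounds[i + 1]) for i in range(buckets)]


def _window_schedule(hwi: int, iterations: int) -> np.ndarray:
    """Half-widths shrinking geometrically from hwi to 1 over the passes."""
    if iterations == 1:
        return np.array([max(1, hwi)], dtype=int)
    j = np.arange(iterations)
    w = np.rint(hwi ** (1.0 - j / (iterations - 1.0))).astype(int)
    return np.maximum(w, 1)


def _suppress_pass(v: np.ndarray, w: int) -> np.ndarray:
    """One peak-filling pass: min(current, mean of left/right window means).

    The update runs in place from left to right so that already suppressed
    values feed into the windows of later buckets; this lets the fill
    propagate across wide peak clusters instead of only shaving each peak
    once per pass.
    """
    v = v.copy()
    m = v.size
    # edge buckets with a truncated window are left untouched: a clamped
    # endpoint would drag a sloping baseline down at the trace ends
    for i in range(w, m - w):
        chord = 0.5 * (v[i - w] + v[i + w])
        if chord < v[i]:
            v[i] = chord
    return v


def _fill_passes(values: np.ndarray, widths: np.ndarray) -> tuple:
    """Run all suppression passes; returns (final values, per-pass history)."""
    v = values.copy()
    history = [v.copy()]
    for w in widths:
        v = _suppress_pass(v, int(w))
        history.append(v.copy())
    return v, history


def estimate_baseline(
    chrom: Chromatogram, params: BaselineParams = BaselineParams()
) -> np.ndarray:
    """Estimate the baseline of a trace; same length as the signal."""
    params.validate(len(chrom))
    t, y = chrom.time, chrom.intensity
    smooth = whittaker_smooth(y, params.lambda_exponent)
    slices = _bucket_slices(y.size, params.buckets)
    bucket_vals = np.array([smooth[s].mean() for s in slices])
    bucket_t = np.array([t[s].mean() for s in slices])
    widths = _window_schedule(params.hwi, params.iterations)
    filled, _ = _fill_passes(bucket_vals, widths)
    base = np.interp(t, bucket_t, filled)
    # linear extrapolation over the half-bucket overhang at each end
    # (np.interp clamps, which would kink the baseline there)
    lo = t < bucket_t[0]
    hi = t > bucket_t[-1]
    if bucket_t.size >= 2:
        s0 = (filled[1] - filled[0]) / (bucket_t[1] - bucket_t[0])
        s1 = (filled[-1] - filled[-2]) / (bucket_t[-1] - bucket_t[-2])
        base[lo] = filled[0] + s0 * (t[lo] - bucket_t[0])
        base[hi] = filled[-1] + s1 * (t[hi] - bucket_t[-1])
    # light final smooth to iron out the piecewise-linear interpolation
    return whittaker_smooth(base, max(params.lambda_exponent - 2.0, 0.0))


def subtract_baseline(
    chrom: Chromatogram, params: BaselineParams = BaselineParams()
) -> Chromatogram:
    """Return the trace with its estimated baseline removed."""
    base = estimate_baseline(chrom, params)
    return chrom.with_intensity(chrom.intensity - base)
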