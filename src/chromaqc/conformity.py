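"""Batch-conformity scoring from peak-area ratios.

Because no certified standard exists for the analyte mixture, a batch is
compared to an arbitrarily chosen reference batch through scale-invariant
peak-area ratios: (i) a ratio *vector* (every retained peak divided by a
designated reference peak) scored by a battery of 19 similarity and
distance measures, and (ii) an all-by-all ratio *matrix* (every peak
divided by every peak) rendered as a heatmap and scored against the
reference matrix by the structural similarity index (SSIM).  Distances d
are reported on a similarity-like scale via s = 1 / (1 + d).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter
from scipy.spatial import distance as ssd

from .io import PeakTable
from .multivariate import pca

__all__ = [
    "RatioVector",
    "RatioMatrix",
    "SSIMParams",
    "reference_ratio_vector",
    "similarity_battery",
    "ratio_matrix",
    "ssim_score",
    "heatmap_export",
    "conformity_report",
    "BATTERY_MEASURES",
]

SIMILARITY_MEASURES = ("ejaccard", "cosine", "edice", "correlation", "gower")
DISTANCE_MEASURES = (
    "bray",
    "canberra",
    "chord",
    "divergence",
    "euclidean",
    "geodesic",
    "hellinger",
    "kullback",
    "manhattan",
    "podani",
    "soergel",
    "supremum",
    "whittaker",
    "bhjattacharyya",
)
BATTERY_MEASURES = SIMILARITY_MEASURES + DISTANCE_MEASURES


@dataclass(frozen=True)
class RatioVector:
    """Per-sample peak areas divided by one designated reference peak."""

    sample_id: str
    ratios: np.ndarray
    peak_names: tuple
    reference_peak: str

    def __post_init__(self) -> None:
        r = np.asarray(self.ratios, dtype=float)
        object.__setattr__(self, "ratios", r)
        object.__setattr__(self, "peak_names", tuple(self.peak_names))
        if not np.all(np.isfinite(r)) or np.any(r <= 0):
            raise ValueError("ratio vector entries must be finite and positive")


@dataclass(frozen=True)
class RatioMatrix:
    """All-by-all peak-area ratio matrix for one sample, M[i,j] = a_i / a_j."""

    sample_id: str
    M: np.ndarray
    peak_names: tuple

    def __post_init__(self) -> None:
        M = np.asarray(self.M, dtype=float)
        object.__setattr__(self, "M", M)
        object.__setattr__(self, "peak_names", tuple(self.peak_names))
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError("ratio matrix must be square")
        if np.any(M <= 0) or not np.all(np.isfinite(M)):
            raise ValueError("ratio matrix entries must be finite and positive")


@dataclass(frozen=True)
class SSIMParams:
    """SSIM stabilization constants and windowing mode.

    K1/K2 are the universal defaults; ``window`` None means the global
    single-statistic mode, an odd integer w means the mean of the local
    statistic over sliding w x w windows.
    """

    K1: float = 0.01
    K2: float = 0.03
    window: Optional[int] = None

    def __post_init__(self) -> None:
        if not (self.K1 > 0 and self.K2 > 0):
            raise ValueError("K1 and K2 must be positive")
        if self.window is not None and (self.window < 2 or self.window % 2 == 0):
            raise ValueError("window must be an odd integer >= 3")


def reference_ratio_vector(
    areas: np.ndarray,
    peak_names: Sequence[str],
    reference_peak: str,
    sample_id: str = "",
) -> RatioVector:
    """Divide every peak area by the reference peak's area."""
    areas = np.asarray(areas, dtype=float)
    names = list(peak_names)
    if reference_peak not in names:
        raise ValueError(f"reference peak {reference_peak!r} not in table")
    ref = areas[names.index(reference_peak)]
    if not ref > 0:
        raise ValueError(f"reference peak {reference_peak!r} has non-positive area")
    return RatioVector(sample_id, areas / ref, names, reference_peak)


def _as_vectors(x, y):
    xv = x.ratios if isinstance(x, RatioVector) else np.asarray(x, dtype=float)
    yv = y.ratios if isinstance(y, RatioVector) else np.asarray(y, dtype=float)
    if xv.size != yv.size:
        raise ValueError("vectors have different lengths")
    if np.any(xv <= 0) or np.any(yv <= 0):
        raise ValueError("battery measures require positive entries")
    return xv, yv


def _gower(x: np.ndarray, y: np.ndarray, ranges: Optional[np.ndarray]) -> float:
    if ranges is None:
        # per-pair fallback: range = max of the two (positive) values, which
        # keeps every term in [0, 1]; pooled ranges are preferred when a
        # whole sample set is available
        ranges = np.maximum(x, y)
    ranges = np.asarray(ranges, dtype=float)
    terms = np.empty_like(x)
    for i in range(x.size):
        if ranges[i] == 0:
            if x[i] == y[i]:
                terms[i] = 1.0
            else:
                raise ValueError(f"zero Gower range at variable {i} with unequal values")
        else:
            terms[i] = 1.0 - abs(x[i] - y[i]) / ranges[i]
    return float(terms.mean())


def _podani_discordance(x: np.ndarray, y: np.ndarray) -> float:
    """Ordinal discordance: fraction of component pairs ranked oppositely."""
    n = x.size
    if n < 2:
        return 0.0
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(n, k=1)
    discordant = (dx[iu] * dy[iu]) < 0
    return float(discordant.mean())


def similarity_battery(
    x,
    y,
    gower_ranges: Optional[np.ndarray] = None,
) -> pd.Series:
    """Evaluate the 19-measure similarity/distance battery.

    Similarity measures are reported as-is; distance measures d are
    converted to s = 1/(1+d) so that every entry lives on a 0-1
    similarity-like scale and identical vectors score 1 everywhere.
    """
    xv, yv = _as_vectors(x, y)
    out = {}
    cos = 1.0 - ssd.cosine(xv, yv)
    sxy = float(xv @ yv)
    sxx, syy = float(xv @ xv), float(yv @ yv)
    out["ejaccard"] = sxy / (sxx + syy - sxy)
    out["cosine"] = cos
    out["edice"] = 2.0 * sxy / (sxx + syy)
    # Pearson; a constant vector has no defined correlation, so score 1
    # when both are constant (identical shape) and 0 otherwise
    xc, yc = xv - xv.mean(), yv - yv.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        out["correlation"] = 1.0 if (xc @ xc) == (yc @ yc) else 0.0
    else:
        out["correlation"] = float(xc @ yc / denom)
    out["gower"] = _gower(xv, yv, gower_ranges)

    p = xv / xv.sum()
    q = yv / yv.sum()
    d = {
        "bray": ssd.braycurtis(xv, yv),
        "canberra": ssd.canberra(xv, yv),
        "chord": np.sqrt(max(2.0 * (1.0 - cos), 0.0)),
        "divergence": float(np.sum((xv - yv) ** 2 / (xv + yv) ** 2)),
        "euclidean": ssd.euclidean(xv, yv),
        "geodesic": float(np.arccos(np.clip(cos, -1.0, 1.0))),
        "hellinger": float(np.sqrt(np.sum((np.sqrt(p) - np.sqrt(q)) ** 2))),
        "kullback": float(np.sum((p - q) * np.log(p / q))),
        "manhattan": ssd.cityblock(xv, yv),
        "podani": _podani_discordance(xv, yv),
        "soergel": float(np.sum(np.abs(xv - yv)) / np.sum(np.maximum(xv, yv))),
        "supremum": ssd.chebyshev(xv, yv),
        "whittaker": 0.5 * float(np.sum(np.abs(p - q))),
        "bhjattacharyya": float(np.sqrt(np.sum((np.sqrt(xv) - np.sqrt(yv)) ** 2))),
    }
    for name in DISTANCE_MEASURES:
        out[name] = 1.0 / (1.0 + d[name])
    return pd.Series(out, index=list(BATTERY_MEASURES), dtype=float)


def ratio_matrix(
    areas: np.ndarray, peak_names: Sequence[str], sample_id: str = ""
) -> RatioMatrix:
    """Build the all-by-all ratio matrix in the given fixed peak order."""
    a = np.asarray(areas, dtype=float)
    if np.any(a <= 0):
        bad = [peak_names[i] for i in np.where(a <= 0)[0]]
        raise ValueError(f"non-positive area(s) for peak(s) {bad}")
    return RatioMatrix(sample_id, a[:, None] / a[None, :], tuple(peak_names))


def _scale_pair(A: np.ndarray, B: np.ndarray):
    lo = min(A.min(), B.min())
    hi = max(A.max(), B.max())
    if hi == lo:
        return np.zeros_like(A), np.zeros_like(B)
    return (A - lo) / (hi - lo), (B - lo) / (hi - lo)


def _ssim_stat(mx, my, vx, vy, cxy, C1, C2):
    return ((2 * mx * my + C1) * (2 * cxy + C2)) / (
        (mx**2 + my**2 + C1) * (vx + vy + C2)
    )


def ssim_score(
    M_ref: RatioMatrix | np.ndarray,
    M_test: RatioMatrix | np.ndarray,
    params: SSIMParams = SSIMParams(),
) -> float:
    """Structural similarity index between two ratio matrices.

    Both matrices are min-max scaled to [0, 1] using their pooled range
    (dynamic range L = 1 afterwards).  Global mode computes the SSIM
    statistic once over all entries; windowed mode averages it over sliding
    w x w windows (uniform filter, sample covariance, borders cropped as in
    the standard image-quality implementation).
    """
    A = M_ref.M if isinstance(M_ref, RatioMatrix) else np.asarray(M_ref, dtype=float)
    B = M_test.M if isinstance(M_test, RatioMatrix) else np.asarray(M_test, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch {A.shape} vs {B.shape}")
    if (
        isinstance(M_ref, RatioMatrix)
        and isinstance(M_test, RatioMatrix)
        and M_ref.peak_names != M_test.peak_names
    ):
        raise ValueError("peak orderings differ")
    X, Y = _scale_pair(A, B)
    L = 1.0
    C1, C2 = (params.K1 * L) ** 2, (params.K2 * L) ** 2
    if params.window is None:
        ns = X.size
        mx, my = X.mean(), Y.mean()
        vx = X.var(ddof=1) if ns > 1 else 0.0
        vy = Y.var(ddof=1) if ns > 1 else 0.0
        cxy = float(((X - mx) * (Y - my)).sum() / (ns - 1)) if ns > 1 else 0.0
        return float(_ssim_stat(mx, my, vx, vy, cxy, C1, C2))
    w = params.window
    if w > min(X.shape):
        raise ValueError("window larger than matrix")
    ns = w * w
    cov_norm = ns / (ns - 1.0)
    ux = uniform_filter(X, size=w)
    uy = uniform_filter(Y, size=w)
    uxx = uniform_filter(X * X, size=w)
    uyy = uniform_filter(Y * Y, size=w)
    uxy = uniform_filter(X * Y, size=w)
    vx = cov_norm * (uxx - ux * ux)
    vy = cov_norm * (uyy - uy * uy)
    cxy = cov_norm * (uxy - ux * uy)
    S = _ssim_stat(ux, uy, vx, vy, cxy, C1, C2)
    pad = (w - 1) // 2
    return float(S[pad:-pad or None, pad:-pad or None].mean())


def heatmap_export(
    M: RatioMatrix,
    path: os.PathLike | str,
    text_path: Optional[os.PathLike | str] = None,
    decimals: int = 3,
    cmap: str = "RdBu",
) -> None:
    """Render the ratio matrix as a heatmap plus a text twin for diffing.

    The peak order is fixed (no dendrogram reordering) and the colour map
    is diverging and symmetric about the matrix midpoint, so low and high
    extremes are dark while middle values stay light.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    path = str(path)
    arr = M.M
    mid = (arr.min() + arr.max()) / 2.0
    half = max(arr.max() - mid, mid - arr.min()) or 1.0
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(arr, cmap=cmap, vmin=mid - half, vmax=mid + half)
    ax.set_xticks(range(len(M.peak_names)))
    ax.set_yticks(range(len(M.peak_names)))
    ax.set_xticklabels(M.peak_names, rotation=90, fontsize=5)
    ax.set_yticklabels(M.peak_names, fontsize=5)
    fig.colorbar(im, ax=ax, label="area ratio")
    ax.set_title(M.sample_id)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    if text_path is None:
        text_path = os.path.splitext(path)[0] + ".txt"
    pd.DataFrame(arr, index=list(M.peak_names), columns=list(M.peak_names)).to_csv(
        text_path, float_format=f"%.{decimals}f"
    )


def conformity_report(
    table: PeakTable,
    reference_id: str,
    reference_peak: str,
    peaks: Optional[Sequence[str]] = None,
    ssim_params: SSIMParams = SSIMParams(),
    ssim_threshold: float = 0.95,
    n_score_components: int = 2,
) -> pd.DataFrame:
    """Score every batch in the table against the reference batch.

    Per batch: the 19-measure battery on reference-peak ratio vectors
    (Gower ranges pooled over all samples), the SSIM of the all-by-all
    ratio matrices, and the Euclidean distance to the reference in the
    first ``n_score_components`` PCA score dimensions of the ratio
    vectors.  The batch with the minimum SSIM is flagged non-conforming
    when that SSIM falls below ``ssim_threshold``.
    """
    if reference_id not in table.sample_ids:
        raise ValueError(f"reference sample {reference_id!r} not in table")
    if peaks is not None:
        table = table.subset(peaks)
    names = table.peak_names
    vectors = {
        sid: reference_ratio_vector(table.row(sid), names, reference_peak, sid)
        for sid in table.sample_ids
    }
    all_ratios = np.vstack([vectors[s].ratios for s in table.sample_ids])
    ranges = all_ratios.max(axis=0) - all_ratios.min(axis=0)
    matrices = {
        sid: ratio_matrix(table.row(sid), names, sid) for sid in table.sample_ids
    }
    pc = pca(all_ratios, center=True, scale=False)
    k = min(n_score_components, pc.scores.shape[1])
    scores = pc.scores[:, :k]
    ref_idx = table.sample_ids.index(reference_id)
    rows = []
    batch_ids = [s for s in table.sample_ids if s != reference_id]
    for sid in batch_ids:
        rec = similarity_battery(
            vectors[reference_id], vectors[sid], gower_ranges=ranges
        ).to_dict()
        rec["ssim"] = ssim_score(matrices[reference_id], matrices[sid], ssim_params)
        i = table.sample_ids.index(sid)
        rec["pca_score_distance"] = float(
            np.linalg.norm(scores[i] - scores[ref_idx])
        )
        rows.append(pd.Series(rec, name=sid))
    report = pd.DataFrame(rows)
    min_ssim = report["ssim"].min()
    report["flag"] = [
        "non-conforming" if (s == min_ssim and s < ssim_threshold) else "conforming"
        for s in report["ssim"]
    ]
    return report
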