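"""SIMPLS partial least squares and principal component analysis.

The PLS regressor follows the SIMPLS construction (direct deflation of the
cross-covariance matrix), with leave-one-out cross-validation producing an
MSEP/RMSEP table per component count and per-fold coefficient sets that
feed Tukey jack-knife prediction intervals.  PCA is SVD-based with
explained-variance percentages and a row-resampling bootstrap summary of
the eigenvalue spectrum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PLSModel",
    "PCAResult",
    "simpls_fit",
    "loo_cv",
    "select_n_components",
    "fit_with_loo",
    "pls_predict",
    "pca",
    "bootstrap_eigenvalues",
]


def _simpls_core(X0: np.ndarray, y0: np.ndarray, A: int):
    """SIMPLS for a single response; X0, y0 already centered.

    Returns (R weights, P x-loadings, q y-loadings, T scores), each with A
    columns (q is length A).
    """
    n, p = X0.shape
    R = np.zeros((p, A))
    P = np.zeros((p, A))
    V = np.zeros((p, A))
    T = np.zeros((n, A))
    q = np.zeros(A)
    s = X0.T @ y0
    for a in range(A):
        r = s.copy()
        t = X0 @ r
        t -= t.mean()
        normt = np.linalg.norm(t)
        if normt < 1e-12:
            raise np.linalg.LinAlgError("rank deficient")
        t /= normt
        r /= normt
        p_a = X0.T @ t
        q_a = float(y0 @ t)
        v = p_a.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ p_a)
        v /= np.linalg.norm(v)
        s = s - v * (v @ s)
        R[:, a], P[:, a], V[:, a], T[:, a], q[a] = r, p_a, v, t, q_a
    return R, P, q, T


@dataclass
class PLSModel:
    """A fitted SIMPLS regression of one response on a peak-area matrix."""

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray      # R, (p, A): X0 @ R = scores
    x_loadings: np.ndarray   # P
    y_loadings: np.ndarray   # q
    scores: np.ndarray       # T, orthonormal columns
    coefficients: List[np.ndarray]  # per component count a=1..A
    r2_fitted: List[float]
    peak_names: Optional[List[str]] = None
    cv_table: Optional[pd.DataFrame] = None
    loo_coefficient_sets: Optional[list] = None  # (x_mean_i, y_mean_i, beta_i)

    def coef(self, a: Optional[int] = None) -> np.ndarray:
        a = self.n_components if a is None else a
        return self.coefficients[a - 1]

    def predict(self, X_new: np.ndarray, a: Optional[int] = None) -> np.ndarray:
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        return self.y_mean + (X_new - self.x_mean) @ self.coef(a)


def simpls_fit(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    peak_names: Optional[Sequence[str]] = None,
) -> PLSModel:
    """Fit a SIMPLS model with up to ``n_components`` latent factors.

    If the data rank cannot support the requested number of components the
    fit is truncated with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y sample counts differ")
    A = int(n_components)
    if A > min(n - 1, p):
        warnings.warn(
            f"n_components={A} exceeds min(n-1, p)={min(n - 1, p)}; truncating"
        )
        A = min(n - 1, p)
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    X0, y0 = X - x_mean, y - y_mean
    try:
        R, P, q, T = _simpls_core(X0, y0, A)
    except np.linalg.LinAlgError:
        for A_try in range(A - 1, 0, -1):
            try:
                R, P, q, T = _simpls_core(X0, y0, A_try)
                warnings.warn(f"rank deficiency: truncated to {A_try} component(s)")
                A = A_try
                break
            except np.linalg.LinAlgError:
                continue
        else:
            raise
    sstot = float(np.sum(y0**2))
    coefficients, r2 = [], []
    for a in range(1, A + 1):
        beta = R[:, :a] @ q[:a]
        coefficients.append(beta)
        resid = y0 - X0 @ beta
        r2.append(1.0 - float(np.sum(resid**2)) / sstot if sstot > 0 else 1.0)
    return PLSModel(
        n_components=A,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=R,
        x_loadings=P,
        y_loadings=q,
        scores=T,
        coefficients=coefficients,
        r2_fitted=r2,
        peak_names=list(peak_names) if peak_names is not None else None,
    )


def loo_cv(X: np.ndarray, y: np.ndarray, max_components: int) -> pd.DataFrame:
    """Leave-one-out cross-validation table (MSEP, RMSEP, R2 per a)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 3:
        raise ValueError("LOO CV needs at least 3 samples")
    A = int(max_components)
    if A > min(n - 2, X.shape[1]):
        warnings.warn("max_components too large for LOO; truncating")
        A = min(n - 2, X.shape[1])
    press = np.zeros(A)
    for i in range(n):
        mask = np.arange(n) != i
        sub = simpls_fit(X[mask], y[mask], A)
        for a in range(1, sub.n_components + 1):
            press[a - 1] += (sub.predict(X[i], a)[0] - y[i]) ** 2
        # rank-truncated folds reuse the largest available component count
        for a in range(sub.n_components + 1, A + 1):
            press[a - 1] += (sub.predict(X[i], sub.n_components)[0] - y[i]) ** 2
    msep = press / n
    sstot = float(np.sum((y - y.mean()) ** 2))
    return pd.DataFrame(
        {
            "n_components": np.arange(1, A + 1),
            "MSEP": msep,
            "RMSEP": np.sqrt(msep),
            "R2_cv": 1.0 - press / sstot if sstot > 0 else np.nan,
        }
    ).set_index("n_components")


def select_n_components(cv_table: pd.DataFrame, rel_slack: float = 0.05) -> int:
    """Smallest component count with RMSEP within ``rel_slack`` of the minimum."""
    rmsep = cv_table["RMSEP"].to_numpy()
    best = rmsep.min()
    ok = np.where(rmsep <= best * (1.0 + rel_slack))[0]
    return int(cv_table.index[ok[0]])


def fit_with_loo(
    X: np.ndarray,
    y: np.ndarray,
    max_components: int = 4,
    n_components: Optional[int] = None,
    peak_names: Optional[Sequence[str]] = None,
) -> PLSModel:
    """Fit SIMPLS, attach the LOO CV table and per-fold coefficient sets."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    cv = loo_cv(X, y, max_components)
    a_sel = n_components if n_components is not None else select_n_components(cv)
    model = simpls_fit(X, y, a_sel, peak_names=peak_names)
    model.cv_table = cv
    folds = []
    n = X.shape[0]
    for i in range(n):
        mask = np.arange(n) != i
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sub = simpls_fit(X[mask], y[mask], model.n_components)
        folds.append((sub.x_mean, sub.y_mean, sub.coef()))
    model.loo_coefficient_sets = folds
    return model


def pls_predict(
    model: PLSModel, X_new: np.ndarray, nominal: Optional[float] = 160.0
) -> pd.DataFrame:
    """Predict new samples with Tukey jack-knife 95% intervals.

    The point estimate uses the full-data coefficients; the interval comes
    from the spread of the leave-one-out coefficient sets via Tukey
    pseudo-values with a t(n-1) quantile.  ``%error`` is reported against
    the nominal concentration when one is given.
    """
    if model.loo_coefficient_sets is None:
        raise ValueError("model has no LOO coefficient sets; use fit_with_loo")
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.x_mean.size:
        raise ValueError(
            f"expected {model.x_mean.size} peak columns, got {X_new.shape[1]}"
        )
    n = len(model.loo_coefficient_sets)
    est = model.predict(X_new)
    fold_preds = np.stack(
        [ym + (X_new - xm) @ b for xm, ym, b in model.loo_coefficient_sets]
    )  # (n_folds, n_new)
    pseudo = n * est[None, :] - (n - 1) * fold_preds
    se = pseudo.std(axis=0, ddof=1) / np.sqrt(n)
    tcrit = stats.t.ppf(0.975, n - 1)
    out = pd.DataFrame(
        {
            "estimate": est,
            "lower": est - tcrit * se,
            "upper": est + tcrit * se,
        }
    )
    if nominal is not None:
        out["pct_error"] = 100.0 * (est - nominal) / nominal
    return out


@dataclass
class PCAResult:
    """SVD-based principal components of a data matrix."""

    scores: np.ndarray
    loadings: np.ndarray
    eigenvalues: np.ndarray
    explained_pct: np.ndarray
    centered: bool
    scaled: bool
    mean_: np.ndarray = field(default=None, repr=False)
    scale_: np.ndarray = field(default=None, repr=False)


def pca(X: np.ndarray, center: bool = True, scale: bool = False) -> PCAResult:
    """Principal component analysis via singular value decomposition."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("X must be 2-D with >= 2 samples and >= 1 variable")
    mean = X.mean(axis=0) if center else np.zeros(X.shape[1])
    Z = X - mean
    if scale:
        sd = Z.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = np.where(sd == 0)[0]
            raise ValueError(f"zero-variance variable(s) at index {bad.tolist()}")
        Z = Z / sd
    else:
        sd = np.ones(X.shape[1])
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    eig = s**2 / (X.shape[0] - 1)
    total = eig.sum()
    explained = 100.0 * eig / total if total > 0 else np.zeros_like(eig)
    return PCAResult(
        scores=U * s,
        loadings=Vt.T,
        eigenvalues=eig,
        explained_pct=explained,
        centered=center,
        scaled=scale,
        mean_=mean,
        scale_=sd,
    )


def bootstrap_eigenvalues(
    X: np.ndarray,
    n_boot: int = 7,
    seed: Optional[int] = None,
    center: bool = True,
    scale: bool = False,
) -> pd.DataFrame:
    """Bootstrap (row resampling) summary of the explained-variance spectrum.

    Returns per-component mean and 2.5/97.5 percentile of the explained
    percentage over ``n_boot`` resamples.  Degenerate resamples (all rows
    identical) are skipped with a warning.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    k = min(n - 1, X.shape[1])
    draws = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        Xb = X[idx]
        if np.allclose(Xb, Xb[0]):
            warnings.warn("degenerate bootstrap resample skipped")
            continue
        pct = pca(Xb, center=center, scale=scale).explained_pct
        draws.append(pct[:k] if pct.size >= k else np.pad(pct, (0, k - pct.size)))
    if not draws:
        raise ValueError("all bootstrap resamples degenerate")
    arr = np.vstack(draws)
    return pd.DataFrame(
        {
            "component": np.arange(1, k + 1),
            "mean_explained_pct": arr.mean(axis=0),
            "p2.5": np.percentile(arr, 2.5, axis=0),
            "p97.5": np.percentile(arr, 97.5, axis=0),
        }
    ).set_index("component")
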