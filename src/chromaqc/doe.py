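"""Box-Behnken design, response-surface fitting and desirability optimization.

The chromatographic method was optimized over three factors (ammonium
formate concentration, detection wavelength, column temperature) with a
three-level Box-Behnken design: all +/-1 combinations on each factor pair
with the remaining factor at its center, plus replicated center runs.
Responses (sum of adjacent-peak resolutions, sum of peak areas) are fitted
with reduced response-surface polynomials chosen by backward elimination
from the estimable cubic candidate set, with lack-of-fit ANOVA from the
center replicates, and jointly optimized with Derringer-Suich desirability.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

__all__ = [
    "BoxBehnkenDesign",
    "ResponseSurfaceFit",
    "DesirabilityGoal",
    "box_behnken",
    "decode",
    "fit_response_surface",
    "desirability_optimize",
    "DEFAULT_FACTOR_MAPPING",
]

# factor levels used for the colistimethate UPLC-UV method
DEFAULT_FACTOR_MAPPING: Dict[str, Tuple[float, float, float]] = {
    "ammonium_formate_M": (1e-3, 2e-3, 3e-3),
    "wavelength_nm": (214.0, 217.0, 220.0),
    "temperature_C": (29.0, 34.5, 40.0),
}


@dataclass
class BoxBehnkenDesign:
    """Coded three-level design: runs x factors over {-1, 0, +1}."""

    coded: np.ndarray
    n_center: int
    factor_names: List[str]
    mapping: Optional[Dict[str, Tuple[float, float, float]]] = None

    @property
    def n_runs(self) -> int:
        return self.coded.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.coded, columns=self.factor_names)


def box_behnken(
    n_factors: int = 3,
    n_center: int = 5,
    factor_names: Optional[Sequence[str]] = None,
    mapping: Optional[Dict[str, Tuple[float, float, float]]] = None,
) -> BoxBehnkenDesign:
    """Construct a Box-Behnken design (3 factors: 12 edge runs + centers)."""
    if n_factors != 3:
        raise ValueError("only the 3-factor Box-Behnken design is supported")
    if factor_names is None:
        factor_names = (
            list(mapping) if mapping is not None else [f"X{i+1}" for i in range(n_factors)]
        )
    rows = []
    for i, j in itertools.combinations(range(n_factors), 2):
        for a, b in itertools.product((-1.0, 1.0), repeat=2):
            row = np.zeros(n_factors)
            row[i], row[j] = a, b
            rows.append(row)
    rows.extend(np.zeros(n_factors) for _ in range(n_center))
    return BoxBehnkenDesign(np.array(rows), n_center, list(factor_names), mapping)


def decode(design: BoxBehnkenDesign) -> pd.DataFrame:
    """Map coded -1/0/+1 levels to actual factor units."""
    if design.mapping is None:
        raise ValueError("design has no factor mapping")
    cols = {}
    for k, name in enumerate(design.factor_names):
        if name not in design.mapping:
            raise ValueError(f"no mapping for factor {name!r}")
        low, mid, high = design.mapping[name]
        lut = {-1.0: low, 0.0: mid, 1.0: high}
        cols[name] = [lut[v] for v in design.coded[:, k]]
    return pd.DataFrame(cols)


def _term_column(coded: np.ndarray, term: Tuple[int, ...]) -> np.ndarray:
    col = np.ones(coded.shape[0])
    for k in term:
        col = col * coded[:, k]
    return col


def _term_name(term: Tuple[int, ...], names: Sequence[str]) -> str:
    if not term:
        return "Intercept"
    parts = []
    for k in sorted(set(term)):
        power = term.count(k)
        parts.append(names[k] if power == 1 else f"{names[k]}^{power}")
    return "*".join(parts)


def _candidate_terms(n_factors: int) -> List[Tuple[int, ...]]:
    """Intercept, linear, two-way interactions, squares, mixed cubic terms."""
    terms: List[Tuple[int, ...]] = [()]
    terms += [(i,) for i in range(n_factors)]
    terms += [t for t in itertools.combinations(range(n_factors), 2)]
    terms += [(i, i) for i in range(n_factors)]
    for i, j in itertools.permutations(range(n_factors), 2):
        terms.append(tuple(sorted((i, i, j))))
    return terms


def _hierarchy_parents(term: Tuple[int, ...]) -> List[Tuple[int, ...]]:
    """Lower-order terms a retained term forces to stay (strict subsets)."""
    parents = set()
    for r in range(1, len(term)):
        for comb in itertools.combinations(term, r):
            parents.add(tuple(sorted(comb)))
    return list(parents)


@dataclass
class ResponseSurfaceFit:
    """A reduced polynomial response-surface model with its ANOVA."""

    response_name: str
    factor_names: List[str]
    terms: List[Tuple[int, ...]]
    term_names: List[str]
    coef: np.ndarray
    coef_p: np.ndarray
    R2: float
    anova: Dict[str, float]

    def predict(self, coded: np.ndarray) -> np.ndarray:
        coded = np.atleast_2d(np.asarray(coded, dtype=float))
        Xc = np.column_stack([_term_column(coded, t) for t in self.terms])
        return Xc @ self.coef

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.coef, "p_value": self.coef_p}, index=self.term_names
        )


def _ols(X: np.ndarray, y: np.ndarray):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = X.shape[0] - X.shape[1]
    s2 = float(resid @ resid) / df if df > 0 else np.nan
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.maximum(np.diag(XtX_inv) * s2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df) if df > 0 else np.full_like(beta, np.nan)
    return beta, se, pvals, resid


def fit_response_surface(
    design: BoxBehnkenDesign,
    y: Sequence[float],
    candidate_terms: Optional[List[Tuple[int, ...]]] = None,
    alpha_keep: float = 0.05,
    response_name: str = "response",
) -> ResponseSurfaceFit:
    """Fit a reduced polynomial model on the coded factors.

    Starts from the estimable cubic-type candidate set, drops aliased
    (rank-deficient) columns, then backward-eliminates terms with
    p > ``alpha_keep`` while preserving model hierarchy.  The residual is
    partitioned into lack-of-fit and pure error using the replicated
    center runs; with no replicates the lack-of-fit entries are NaN.
    """
    y = np.asarray(y, dtype=float)
    coded = design.coded
    n = coded.shape[0]
    if y.size != n:
        raise ValueError("response length does not match run count")
    if candidate_terms is None:
        candidate_terms = _candidate_terms(coded.shape[1])
    # drop aliased terms (columns not increasing the rank)
    terms: List[Tuple[int, ...]] = []
    cols: List[np.ndarray] = []
    for t in candidate_terms:
        trial = cols + [_term_column(coded, t)]
        if np.linalg.matrix_rank(np.column_stack(trial)) == len(trial) and len(trial) < n:
            terms.append(t)
            cols.append(trial[-1])
    # backward elimination with hierarchy preservation
    while True:
        X = np.column_stack([_term_column(coded, t) for t in terms])
        beta, se, pvals, resid = _ols(X, y)
        required = set()
        for t in terms:
            for parent in _hierarchy_parents(t):
                required.add(parent)
        removable = [
            i
            for i, t in enumerate(terms)
            if t and t not in required and pvals[i] > alpha_keep
        ]
        if not removable:
            break
        worst = max(removable, key=lambda i: pvals[i])
        del terms[worst]
    X = np.column_stack([_term_column(coded, t) for t in terms])
    beta, se, pvals, resid = _ols(X, y)
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_model = ss_tot - ss_res
    df_model = len(terms) - 1
    df_res = n - len(terms)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    anova: Dict[str, float] = {
        "ss_model": ss_model,
        "ss_residual": ss_res,
        "ss_total": ss_tot,
        "df_model": df_model,
        "df_residual": df_res,
    }
    if df_model > 0 and df_res > 0 and ss_res > 0:
        F = (ss_model / df_model) / (ss_res / df_res)
        anova["model_F"] = F
        anova["model_p"] = float(stats.f.sf(F, df_model, df_res))
    else:
        anova["model_F"] = np.nan
        anova["model_p"] = np.nan
    # pure error from replicated center runs
    center_mask = np.all(coded == 0.0, axis=1)
    n_center = int(center_mask.sum())
    if n_center >= 2:
        yc = y[center_mask]
        ss_pe = float(np.sum((yc - yc.mean()) ** 2))
        df_pe = n_center - 1
        ss_lof = ss_res - ss_pe
        df_lof = df_res - df_pe
        anova.update(ss_pure_error=ss_pe, df_pure_error=df_pe,
                     ss_lack_of_fit=ss_lof, df_lack_of_fit=df_lof)
        if df_lof > 0 and ss_pe > 0:
            F_lof = (ss_lof / df_lof) / (ss_pe / df_pe)
            anova["lack_of_fit_F"] = F_lof
            anova["lack_of_fit_p"] = float(stats.f.sf(F_lof, df_lof, df_pe))
        else:
            anova["lack_of_fit_F"] = np.nan
            anova["lack_of_fit_p"] = np.nan
    else:
        for k in ("ss_pure_error", "df_pure_error", "ss_lack_of_fit",
                  "df_lack_of_fit", "lack_of_fit_F", "lack_of_fit_p"):
            anova[k] = np.nan
    names = design.factor_names
    return ResponseSurfaceFit(
        response_name=response_name,
        factor_names=list(names),
        terms=terms,
        term_names=[_term_name(t, names) for t in terms],
        coef=beta,
        coef_p=pvals,
        R2=r2,
        anova=anova,
    )


@dataclass(frozen=True)
class DesirabilityGoal:
    """Derringer-Suich goal for one response (maximize between L and U)."""

    response_name: str
    low: float
    high: float
    weight: float = 1.0
    goal: str = "maximize"

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError("low anchor must be below high anchor")
        if not self.weight > 0:
            raise ValueError("weight must be positive")
        if self.goal != "maximize":
            raise ValueError("only maximize goals are supported")

    def desirability(self, yhat: np.ndarray) -> np.ndarray:
        d = (np.asarray(yhat, dtype=float) - self.low) / (self.high - self.low)
        return np.clip(d, 0.0, 1.0) ** self.weight


def desirability_optimize(
    fits: Sequence[ResponseSurfaceFit],
    goals: Sequence[DesirabilityGoal],
    grid: int = 21,
    mapping: Optional[Dict[str, Tuple[float, float, float]]] = None,
) -> dict:
    """Maximize the geometric-mean desirability over the coded cube.

    A deterministic grid search (``grid`` points per axis over [-1, 1])
    is refined by Nelder-Mead; ties on the grid break in first-found
    (row-major) order.  Returns the coded optimum, its decoded settings
    (when a mapping is available) and the composite desirability D.
    """
    if not goals:
        raise ValueError("at least one goal is required")
    if len(fits) != len(goals):
        raise ValueError("one goal per fitted response is required")
    by_name = {f.response_name: f for f in fits}
    for g in goals:
        if g.response_name not in by_name:
            raise ValueError(f"no fit for response {g.response_name!r}")
    k = len(fits[0].factor_names)

    def D(point: np.ndarray) -> float:
        point = np.clip(point, -1.0, 1.0)
        ds = []
        for g in goals:
            yhat = by_name[g.response_name].predict(point)[0]
            ds.append(g.desirability(yhat))
        ds = np.asarray(ds, dtype=float)
        if np.any(ds <= 0.0):
            return 0.0
        return float(np.exp(np.mean(np.log(ds))))

    axes = [np.linspace(-1.0, 1.0, grid)] * k
    best_point, best_D = None, -1.0
    for point in itertools.product(*axes):
        val = D(np.array(point))
        if val > best_D + 1e-15:
            best_D, best_point = val, np.array(point)
    res = minimize(
        lambda p: -D(p), best_point, method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 2000},
    )
    if -res.fun > best_D:
        best_D, best_point = -res.fun, np.clip(res.x, -1.0, 1.0)
    out = {
        "coded": best_point,
        "D": best_D,
        "factor_names": list(fits[0].factor_names),
    }
    mapping = mapping or getattr(fits[0], "mapping", None)
    if mapping:
        actual = {}
        for k_i, name in enumerate(fits[0].factor_names):
            low, mid, high = mapping[name]
            c = best_point[k_i]
            actual[name] = mid + c * (high - mid) if c >= 0 else mid + c * (mid - low)
        out["actual"] = actual
    return out
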