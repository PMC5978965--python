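"""Least-squares machinery with influence and over-fitting diagnostics.

The model-commissioning workflow leans on three classical quantities:

* Cook's distance ``D_i = r_i^2 h_ii / (p s^2 (1 - h_ii)^2)`` — how much the
  fitted surface moves when case *i* is omitted; cases with large ``D_i``
  are *influential* and can distort the model for the majority of plans.
* Studentized residuals — "far from the regression line" on scatter plots.
* A parameter-average chi-squared, defined here as the leave-one-out
  predictive sum of squares over the fit sum of squares, rescaled so a
  correctly specified model sits near 1:  ``chi2 = (PRESS/SSE) * (n-p)/n``.
  Over-parameterized fits predict much worse than they fit, pushing the
  statistic above 1; the commissioning threshold for "severe over-fitting"
  is 1.3.

Everything is computed from one QR factorization; PRESS uses the hat
diagonal identity ``e_(i) = r_i / (1 - h_ii)`` so no refits are needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

CHI2_EXACT_FIT = 1.0  # PRESS/SSE is 0/0 on an exact fit; defined as 1


@dataclass
class LinearFit:
    """An ordinary-least-squares fit with diagnostics.

    ``terms`` names the predictor columns (intercept excluded from the name
    list but always fitted first); ``p`` counts all fitted parameters
    including the intercept.
    """

    terms: list[str]
    coef: np.ndarray          # (p,), intercept first
    fitted: np.ndarray        # (n,)
    residuals: np.ndarray     # (n,)
    hat_diag: np.ndarray      # (n,)
    s2: float                 # residual variance SSE/(n-p)
    sse: float
    sst: float
    n: int
    p: int
    xtx_inv: np.ndarray = field(repr=False)  # (p,p) of the design incl. intercept
    flagged_terms: list[str] = field(default_factory=list)

    @property
    def r_squared(self) -> float:
        if self.sst <= 0:
            return 0.0
        return 1.0 - self.sse / self.sst


def fit_ols(y: np.ndarray, X: np.ndarray, terms: list[str]) -> LinearFit:
    """Fit y on [1, X] by QR and collect residual/hat diagnostics."""
    y = np.asarray(y, dtype=float)
    n = y.size
    if X is None or X.size == 0:
        A = np.ones((n, 1))
        terms = []
    else:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != n:
            X = X.T
        A = np.column_stack([np.ones(n), X])
    p = A.shape[1]
    Q, R = np.linalg.qr(A)
    diag = np.abs(np.diag(R))
    if diag.min() < 1e-10 * max(diag.max(), 1.0):
        raise np.linalg.LinAlgError("rank-deficient design")
    coef = np.linalg.solve(R, Q.T @ y)
    fitted = A @ coef
    resid = y - fitted
    hat = np.sum(Q * Q, axis=1)
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    s2 = sse / (n - p) if n > p else np.nan
    xtx_inv = np.linalg.inv(R.T @ R)
    return LinearFit(terms=list(terms), coef=coef, fitted=fitted, residuals=resid,
                     hat_diag=hat, s2=s2, sse=sse, sst=sst, n=n, p=p,
                     xtx_inv=xtx_inv)


def cooks_distance(fit: LinearFit) -> np.ndarray:
    """Cook's distance per case; infinite where the hat diagonal is 1."""
    h = fit.hat_diag
    r = fit.residuals
    out = np.full(fit.n, np.inf)
    ok = h < 1.0 - 1e-12
    if fit.s2 == 0 or not np.isfinite(fit.s2):
        # exact fit: zero residuals everywhere -> zero influence
        return np.where(np.abs(r) < 1e-12, 0.0, out)
    out[ok] = (r[ok] ** 2 / (fit.p * fit.s2)) * (h[ok] / (1.0 - h[ok]) ** 2)
    return out


def studentized_residuals(fit: LinearFit) -> np.ndarray:
    """Internally studentized residuals r_i / (s * sqrt(1 - h_ii))."""
    h = np.clip(fit.hat_diag, 0.0, 1.0 - 1e-12)
    s = np.sqrt(fit.s2) if fit.s2 > 0 else 0.0
    if s == 0:
        return np.zeros(fit.n)
    return fit.residuals / (s * np.sqrt(1.0 - h))


def externally_studentized_residuals(fit: LinearFit) -> np.ndarray:
    """Deletion (externally studentized) residuals r_i / (s_(i) sqrt(1-h_ii)).

    The residual scale s_(i) excludes case i, so a gross outlier does not
    mask itself; this is the standard form for outlier testing.
    """
    h = np.clip(fit.hat_diag, 0.0, 1.0 - 1e-12)
    r = fit.residuals
    df = fit.n - fit.p - 1
    if df <= 0 or fit.sse <= 0:
        return np.zeros(fit.n)
    s2_i = (fit.sse - r ** 2 / (1.0 - h)) / df
    s2_i = np.maximum(s2_i, 1e-300)
    return r / np.sqrt(s2_i * (1.0 - h))


def press_statistic(fit: LinearFit) -> float:
    """Leave-one-out predictive sum of squares via the hat identity."""
    h = np.clip(fit.hat_diag, 0.0, 1.0 - 1e-12)
    loo = fit.residuals / (1.0 - h)
    return float(loo @ loo)


def chi_squared_overfit(fit: LinearFit) -> float:
    """Over-fitting monitor: (PRESS / SSE) * (n - p) / n.

    Near 1 for a correctly specified model; grows with over-parameterization
    because PRESS degrades much faster than SSE.  An exact (zero-residual)
    fit is defined as 1.
    """
    if fit.n <= fit.p + 1:
        raise ValueError("need n > p + 1 for the over-fitting statistic")
    if fit.sse <= 1e-300 or fit.sse <= 1e-12 * max(fit.sst, 1.0):
        return CHI2_EXACT_FIT
    return press_statistic(fit) / fit.sse * (fit.n - fit.p) / fit.n


def prediction_se(fit: LinearFit, x_row: np.ndarray) -> float:
    """Standard error of a new-case prediction at predictor row ``x_row``."""
    a = np.concatenate([[1.0], np.asarray(x_row, dtype=float)])
    lev = float(a @ fit.xtx_inv @ a)
    return float(np.sqrt(max(fit.s2, 0.0) * (1.0 + lev)))


def forward_stepwise(y: np.ndarray, candidates: np.ndarray,
                     candidate_names: list[str], alpha_in: float = 0.05,
                     allow_interactions: bool = False) -> LinearFit:
    """Forward variable selection by partial F-test.

    At each step the candidate with the largest partial F enters if its
    p-value is below ``alpha_in``.  Ties are broken by candidate order.
    Product (interaction) terms of the base candidates are offered only
    when ``allow_interactions`` and are flagged in the result, since such
    terms have no physical interpretation for DVH prediction.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    C = np.atleast_2d(np.asarray(candidates, dtype=float))
    if C.shape[0] != n:
        C = C.T
    names = list(candidate_names)
    flagged: list[str] = []
    if allow_interactions:
        base_k = C.shape[1]
        inter_cols = []
        for i in range(base_k):
            for j in range(i + 1, base_k):
                inter_cols.append(C[:, i] * C[:, j])
                nm = f"{names[i]}*{names[j]}"
                names.append(nm)
                flagged.append(nm)
        if inter_cols:
            C = np.column_stack([C] + [np.column_stack(inter_cols)])

    selected: list[int] = []
    current = fit_ols(y, None, [])
    if current.sst <= 0:
        current.flagged_terms = []
        return current  # constant response: intercept-only, R^2 = 0

    while len(selected) < C.shape[1] and current.p + 1 < n:
        best = None
        for j in range(C.shape[1]):
            if j in selected:
                continue
            cols = selected + [j]
            try:
                trial = fit_ols(y, C[:, cols], [names[c] for c in cols])
            except np.linalg.LinAlgError:
                continue  # constant or collinear candidate

            df2 = n - trial.p
            if df2 <= 0:
                continue
            denom = trial.sse / df2
            if denom <= 1e-300:
                f_stat = np.inf
            else:
                f_stat = max(current.sse - trial.sse, 0.0) / denom
            if best is None or f_stat > best[0] + 1e-12:
                best = (f_stat, j, trial)
        if best is None:
            break
        f_stat, j, trial = best
        p_val = 0.0 if np.isinf(f_stat) else float(stats.f.sf(f_stat, 1, n - trial.p))
        if p_val >= alpha_in:
            break
        selected.append(j)
        current = trial
        if current.sse <= 1e-12 * current.sst:
            break  # exact fit; further F-tests are 0/0

    current.flagged_terms = [t for t in current.terms if t in flagged]
    return current
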