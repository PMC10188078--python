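"""Broken-line (plateau) dose-response models and requirement estimation.

Two classical forms are supported, both parameterized by a plateau ``L``, a
rate constant ``U`` and a break point ``R`` (the estimated requirement):

* **LBL** — linear broken-line: ``Y = L + U·(R − X)·I``
* **QBL** — quadratic broken-line: ``Y = L + U·(R − X)²·I``

with the indicator ``I = 1`` when ``X < R`` and ``0`` otherwise, so the
prediction is exactly ``L`` on and beyond the break.  Both curves are
continuous at ``X = R``; the QBL joins with zero slope (smooth plateau
entry).  ``U`` is signed: negative when the trait rises to a maximum plateau
(egg production), positive when the sub-requirement limb lies above the
plateau (feed conversion ratio).

Fitting profiles the break point: for each candidate ``R`` the model is
linear in ``(L, U)`` and solved in closed form, giving an exact SSE profile
``SSE(R)``; the profile minimum is then refined by Brent search.  When the
profile is flat at its minimum (the break is not identified by the data —
typically because too few doses lie below it), the fitter reports the upper
edge of the minimizing set, i.e. the largest dose consistent with a still
-responding trait, and flags the fit as non-identifiable rather than
returning an arbitrary interior point.

Fit quality follows the usual least-squares summaries with a small-sample
parameter count ``P = k + 1`` (``k = 3`` regression parameters for either
form):

``R² = (SST − SSE)/SST``, ``RMSE = √(SSE/N)``, ``AIC = N·ln(SSE/N) + 2P``,
and the residual-df adjusted ``adj R² = 1 − (1 − R²)(N − 1)/(N − P)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cmp_to_key
from typing import Literal, Sequence

import numpy as np
from scipy import optimize

from .errors import ComparisonError, IdentifiabilityError

Form = Literal["LBL", "QBL"]

#: Profile grid step over the dose axis, mg/kg.
GRID_STEP = 0.1
#: Relative tolerance used to detect SSE ties on the profile (relative to
#: the corrected total sum of squares, i.e. the natural SSE scale).
TIE_RTOL = 1e-12


@dataclass(frozen=True)
class BrokenLineParams:
    """Parameters of a broken-line model."""

    form: Form
    L: float   # plateau, trait units
    U: float   # rate constant, trait units per mg/kg (LBL) or per (mg/kg)² (QBL)
    R: float   # break point (requirement), mg/kg

    def __post_init__(self):
        if self.form not in ("LBL", "QBL"):
            raise ValueError(f"unknown broken-line form {self.form!r}")


def _limb_basis(form: Form, R: float, X: np.ndarray) -> np.ndarray:
    d = np.where(X < R, R - X, 0.0)
    return d if form == "LBL" else d * d


def predict(params: BrokenLineParams, X) -> np.ndarray | float:
    """Evaluate the broken-line model at dose(s) ``X``.

    Returns ``L`` exactly for every ``X ≥ R`` (including the break itself).
    """
    x = np.asarray(X, dtype=float)
    y = params.L + params.U * _limb_basis(params.form, params.R, x)
    return float(y) if np.isscalar(X) or x.ndim == 0 else y


@dataclass(frozen=True)
class FitQuality:
    """Least-squares fit summaries for model comparison."""

    n_obs: int
    k: int            # regression parameters
    sse: float
    sst: float        # corrected total sum of squares
    r2: float
    adj_r2: float
    rmse: float
    aic: float
    perfect: bool = False   # SSE == 0; AIC is a -inf sentinel

    @property
    def p(self) -> int:
        """Small-sample parameter count P = k + 1 used in the AIC."""
        return self.k + 1


def fit_quality(y, predictions, k: int) -> FitQuality:
    """Compute SSE/SST, R², adjusted R², RMSE and AIC for a fitted model.

    ``AIC = N·ln(SSE/N) + 2P`` with ``P = k + 1``.  A perfect fit
    (SSE = 0) gets an ``aic = -inf`` sentinel and ``perfect=True`` so model
    selection still ranks it first without a log-of-zero error.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(predictions, dtype=float)
    n = y.size
    if n <= k:
        raise IdentifiabilityError(f"need more than k={k} observations, got {n}")
    sse = float(np.sum((y - yhat) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if sst == 0 else (sst - sse) / sst
    p = k + 1
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p) if n > p else float("nan")
    rmse = math.sqrt(sse / n)
    if sse == 0.0:
        return FitQuality(n, k, sse, sst, r2, adj, rmse, float("-inf"), perfect=True)
    aic = n * math.log(sse / n) + 2 * p
    return FitQuality(n, k, sse, sst, r2, adj, rmse, aic)


@dataclass(frozen=True)
class BrokenLineFit:
    """A fitted broken-line model with uncertainty and diagnostics."""

    params: BrokenLineParams
    se: dict                     # standard errors for L, U, R (delta method)
    quality: FitQuality
    converged: bool = True
    boundary: bool = False       # R̂ within one grid step of the dose range edge
    identifiable: bool = True    # False when the SSE profile is flat at its minimum
    flat_interval: tuple | None = None   # (lo, hi) of the SSE-minimizing R set
    degenerate: bool = False     # constant-response fallback (U = 0, R undefined)
    data_key: tuple = field(default=(), repr=False)  # fingerprint for select_model

    @property
    def requirement(self) -> float:
        return self.params.R


def _profile_sse(form: Form, X: np.ndarray, Y: np.ndarray, grid: np.ndarray):
    """Closed-form conditional (L, U) least squares at every grid break.

    Vectorized over the grid: for fixed R the model is ``Y = L + U·z(R)``
    with ``z`` the limb basis, an ordinary simple regression.
    """
    d = grid[:, None] - X[None, :]
    z = np.where(d > 0, d, 0.0)
    if form == "QBL":
        z = z * z
    zbar = z.mean(axis=1)
    ybar = Y.mean()
    zc = z - zbar[:, None]
    szz = np.einsum("ij,ij->i", zc, zc)
    szy = zc @ (Y - ybar)
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(szz > 0, szy / np.where(szz > 0, szz, 1.0), 0.0)
    L = ybar - u * zbar
    resid = Y[None, :] - L[:, None] - u[:, None] * z
    sse = np.einsum("ij,ij->i", resid, resid)
    return sse, L, u


def _solve_at(form: Form, X: np.ndarray, Y: np.ndarray, R: float):
    z = _limb_basis(form, R, X)
    zbar, ybar = z.mean(), Y.mean()
    szz = float(np.sum((z - zbar) ** 2))
    if szz <= 0:
        u = 0.0
    else:
        u = float(np.sum((z - zbar) * (Y - ybar)) / szz)
    L = float(ybar - u * zbar)
    sse = float(np.sum((Y - L - u * z) ** 2))
    return sse, L, u


def _gauss_newton_se(form: Form, X, Y, L, U, R, sse):
    """Delta-method SEs from the Gauss-Newton (JᵀJ) approximation."""
    n = X.size
    dof = n - 3
    if dof <= 0 or sse < 0:
        return {"L": float("nan"), "U": float("nan"), "R": float("nan")}
    below = X < R
    d = np.where(below, R - X, 0.0)
    if form == "LBL":
        jU, jR = d, np.where(below, U, 0.0)
    else:
        jU, jR = d * d, np.where(below, 2 * U * d, 0.0)
    J = np.column_stack([np.ones(n), jU, jR])
    s2 = sse / dof
    JtJ = J.T @ J
    try:
        cov = s2 * np.linalg.inv(JtJ)
        ses = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        ses = np.full(3, np.nan)
    return {"L": float(ses[0]), "U": float(ses[1]), "R": float(ses[2])}


def fit(X, Y, form: Form, grid_step: float = GRID_STEP) -> BrokenLineFit:
    """Fit a broken-line model by profiled least squares.

    Parameters
    ----------
    X, Y : array-like
        Doses (mg/kg total dietary Mn) and trait observations.  Replicate
        -level data (repeated doses) and treatment means are both accepted.
    form : {"LBL", "QBL"}
        Limb shape.
    grid_step : float
        Break-point profile grid step; the candidate range is
        ``[min(X) + step, max(X) − step]``.

    Raises
    ------
    IdentifiabilityError
        Fewer than 4 observations or fewer than 3 distinct doses.
    """
    X = np.asarray(X, dtype=float).ravel()
    Y = np.asarray(Y, dtype=float).ravel()
    if X.size != Y.size:
        raise ValueError("X and Y must have equal length")
    if X.size < 4:
        raise IdentifiabilityError("broken-line fit needs at least 4 observations")
    if np.unique(X).size < 3:
        raise IdentifiabilityError("broken-line fit needs at least 3 distinct doses")
    key = _data_key(X, Y)

    if np.ptp(Y) == 0.0:
        # Constant response: plateau only, break point undefined.
        params = BrokenLineParams(form=form, L=float(Y[0]), U=0.0, R=float("nan"))
        q = fit_quality(Y, np.full_like(Y, Y[0]), k=3)
        return BrokenLineFit(params=params, se={"L": 0.0, "U": 0.0, "R": float("nan")},
                             quality=q, degenerate=True, identifiable=False,
                             data_key=key)

    lo, hi = X.min() + grid_step, X.max() - grid_step
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    sse_prof, _, _ = _profile_sse(form, X, Y, grid)
    sse_min = float(sse_prof.min())
    # Ties must be detected only for *structural* flatness (identical SSE up
    # to float roundoff), never for a merely shallow noisy profile; the
    # tolerance sits ~10× above accumulated roundoff and far below any real
    # profile variation.
    scale = max(1.0, float(np.sum((Y - Y.mean()) ** 2)))
    tie_tol = TIE_RTOL * (scale + sse_min)
    ties = np.flatnonzero(sse_prof <= sse_min + tie_tol)

    identifiable = True
    flat_interval = None
    if ties.size > 1 and (grid[ties[-1]] - grid[ties[0]]) > 1.5 * grid_step:
        # Flat SSE valley: the break is not pinned down by the data.  Report
        # the largest R still attaining the minimum (upper edge, refined by
        # bisection) — the highest dose at which the trait could still be
        # responding — and flag it.
        identifiable = False
        r_hat = _upper_edge(form, X, Y, grid[ties[-1]],
                            min(grid[ties[-1]] + grid_step, hi),
                            sse_min, tie_tol)
        flat_interval = (float(grid[ties[0]]), float(r_hat))
    else:
        i = int(np.argmin(sse_prof))
        a = grid[max(i - 1, 0)]
        b = grid[min(i + 1, grid.size - 1)]
        if b > a:
            res = optimize.minimize_scalar(
                lambda r: _solve_at(form, X, Y, r)[0],
                bounds=(a, b), method="bounded",
                options={"xatol": 1e-8},
            )
            r_hat = float(res.x)
            if _solve_at(form, X, Y, r_hat)[0] > sse_prof[i]:
                r_hat = float(grid[i])
        else:
            r_hat = float(grid[i])

    sse, L, U = _solve_at(form, X, Y, r_hat)
    params = BrokenLineParams(form=form, L=L, U=U, R=r_hat)
    q = fit_quality(Y, predict(params, X), k=3)
    se = _gauss_newton_se(form, X, Y, L, U, r_hat, sse)
    if q.perfect:
        se = {k_: 0.0 for k_ in se}
    boundary = (r_hat - lo) < grid_step or (hi - r_hat) < grid_step
    return BrokenLineFit(params=params, se=se, quality=q, boundary=boundary,
                         identifiable=identifiable, flat_interval=flat_interval,
                         data_key=key)


def _upper_edge(form, X, Y, inside, outside, sse_min, tol):
    """Largest R with SSE(R) ≤ min + tol, by bisection on the profile."""
    if _solve_at(form, X, Y, outside)[0] <= sse_min + tol:
        return float(outside)
    lo, hi = float(inside), float(outside)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _solve_at(form, X, Y, mid)[0] <= sse_min + tol:
            lo = mid
        else:
            hi = mid
    return lo


def _data_key(X: np.ndarray, Y: np.ndarray) -> tuple:
    return (X.size, float(X.sum()), float(Y.sum()),
            float(np.dot(X, X)), float(np.dot(Y, Y)))


def select_model(fits: Sequence[BrokenLineFit]) -> list[BrokenLineFit]:
    """Rank candidate fits of the same data.

    Primary key: lowest AIC.  When two fits are within 2 AIC units (the
    usual indistinguishability band), the lower RMSE wins, then the higher
    adjusted R²; fully tied fits keep their input order.

    Raises
    ------
    ComparisonError
        If the fits were not computed on identical data.
    """
    fits = list(fits)
    if len(fits) >= 2:
        k0 = fits[0].data_key
        for f in fits[1:]:
            if f.data_key != k0:
                raise ComparisonError("cannot rank fits computed on different data")

    def cmp(a: BrokenLineFit, b: BrokenLineFit) -> int:
        qa, qb = a.quality, b.quality
        da = qa.aic - qb.aic
        if math.isinf(qa.aic) or math.isinf(qb.aic):
            if qa.aic != qb.aic:
                return -1 if qa.aic < qb.aic else 1
        elif abs(da) >= 2.0:
            return -1 if da < 0 else 1
        if qa.rmse != qb.rmse:
            return -1 if qa.rmse < qb.rmse else 1
        if qa.adj_r2 != qb.adj_r2:
            return -1 if qa.adj_r2 > qb.adj_r2 else 1
        return 0

    return sorted(fits, key=cmp_to_key(cmp))
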