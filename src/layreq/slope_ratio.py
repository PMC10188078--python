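"""Slope-ratio bioassay: relative bio-efficacy (RBE) of nutrient sources.

The slope-ratio model regresses a response on per-source dose columns with a
*common* intercept:

    Y = a + b₁X₁ + b₂X₂ + b₃X₃

where ``a`` is the response on the unsupplemented basal diet and ``Xₛ`` is
the supplemental dose for source ``s`` (zero on every row not fed that
source, so the control anchors all arms at a shared origin).  The relative
bio-efficacy of source ``i`` against a reference source is then

    RBE_i = 100 · b_i / b_ref  (percent),

invariant to any common rescaling of the dose columns.  Confidence limits
for the slope ratio are computed by Fieller's theorem (exact under
normality of the coefficient estimates), with the simpler delta-method
interval reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .design import TrialDesign
from .errors import IdentifiabilityError, InvalidDesignError, LayreqError

#: A reference slope smaller than this (in absolute value) makes the ratio
#: numerically meaningless.
SLOPE_TOL = 1e-12


def encode_doses(design: TrialDesign,
                 dose_scale: str = "supplemental_nominal") -> pd.DataFrame:
    """Per-treatment one-hot-by-source dose columns.

    ``dose_scale="supplemental_nominal"`` uses the nominal added Mn
    (0/30/60/90 in the reference trial); ``"supplemental_analyzed"`` uses
    analyzed total Mn minus the control's analyzed total.  The control row
    is all-zero on either scale.
    """
    if dose_scale not in ("supplemental_nominal", "supplemental_analyzed"):
        raise ValueError(f"unknown dose_scale {dose_scale!r}")
    sources = design.sources
    if not sources:
        raise InvalidDesignError("design has no supplemented sources")
    control = design.control  # raises if absent
    if dose_scale == "supplemental_analyzed":
        if control.analyzed_total_mn is None:
            raise InvalidDesignError("analyzed dose scale needs an analyzed control")
        base = control.analyzed_total_mn
    rows = []
    for t in design.treatments:
        x = {f"X_{s}": 0.0 for s in sources}
        if t.source != "none":
            if t.source not in sources:
                raise InvalidDesignError(f"treatment {t.id} has unknown source")
            if dose_scale == "supplemental_nominal":
                x[f"X_{t.source}"] = t.nominal_added_mn
            else:
                if t.analyzed_total_mn is None:
                    raise InvalidDesignError(
                        f"treatment {t.id} lacks an analyzed Mn concentration"
                    )
                x[f"X_{t.source}"] = t.analyzed_total_mn - base
        rows.append({"treatment": t.id, **x})
    return pd.DataFrame(rows)


@dataclass
class SlopeRatioFit:
    """OLS fit of the common-intercept slope-ratio model."""

    intercept: float
    slopes: dict                  # source -> b
    cov: pd.DataFrame             # coefficient covariance (const + X cols)
    r2: float
    p_value: float                # overall model F-test
    df_resid: int
    dose_scale: str
    n_obs: int


def fit_slope_ratio(y: Sequence[float], X: pd.DataFrame,
                    dose_scale: str = "supplemental_nominal") -> SlopeRatioFit:
    """Ordinary least squares for the common-intercept multi-source model.

    ``X`` holds one ``X_<source>`` column per source (as produced by
    :func:`encode_doses`, repeated per replicate for replicate-level fits);
    ``y`` is the matching response.  With equal replication the fit on
    replicate data and on treatment means give identical coefficients.
    """
    cols = [c for c in X.columns if c.startswith("X_")]
    if not cols:
        raise ValueError("X must contain X_<source> dose columns")
    M = sm.add_constant(X[cols].to_numpy(dtype=float), has_constant="add")
    if np.linalg.matrix_rank(M) < M.shape[1]:
        bad = _deficient_columns(M, ["const"] + cols)
        raise IdentifiabilityError(
            f"design matrix is rank deficient (columns: {', '.join(bad)})"
        )
    res = sm.OLS(np.asarray(y, dtype=float), M).fit()
    names = ["const"] + cols
    cov = pd.DataFrame(res.cov_params(), index=names, columns=names)
    slopes = {c.removeprefix("X_"): float(b) for c, b in zip(cols, res.params[1:])}
    return SlopeRatioFit(
        intercept=float(res.params[0]),
        slopes=slopes,
        cov=cov,
        r2=float(res.rsquared),
        p_value=float(res.f_pvalue),
        df_resid=int(res.df_resid),
        dose_scale=dose_scale,
        n_obs=int(res.nobs),
    )


def _deficient_columns(M: np.ndarray, names: list[str]) -> list[str]:
    bad = []
    for j in range(M.shape[1]):
        others = np.delete(M, j, axis=1)
        if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(M):
            bad.append(names[j])
    return bad or names


@dataclass
class RBEResult:
    """Relative bio-efficacy of each source against the reference."""

    reference: str
    rbe: dict                     # source -> percent (full precision)
    rbe_rounded: dict             # source -> integer percent for reporting
    ci_fieller: dict = field(default_factory=dict)   # source -> (lo, hi) percent
    ci_delta: dict = field(default_factory=dict)
    alpha: float = 0.05


def rbe_from_slopes(slopes: Mapping[str, float], reference: str) -> RBEResult:
    """RBE percentages from bare slope estimates (no uncertainty).

    Useful for desk calculations from a published coefficient table.
    """
    if reference not in slopes:
        raise LayreqError(f"reference source {reference!r} not among slopes")
    b_ref = slopes[reference]
    if abs(b_ref) < SLOPE_TOL:
        raise LayreqError("reference slope is (numerically) zero; RBE undefined")
    vals = {s: 100.0 * b / b_ref for s, b in slopes.items()}
    return RBEResult(reference=reference, rbe=vals,
                     rbe_rounded={s: round(v) for s, v in vals.items()})


def rbe(fit: SlopeRatioFit, reference: str = "organic",
        alpha: float = 0.05) -> RBEResult:
    """RBE with Fieller and delta-method confidence limits.

    Fieller's interval for ρ = b_i/b_ref uses the joint normality of the two
    slope estimates; when the reference slope is not significantly nonzero
    (g = t²·v_rr/b_ref² ≥ 1) the interval is unbounded and (nan, nan) is
    reported for that source.
    """
    if reference not in fit.slopes:
        raise LayreqError(f"reference source {reference!r} not in fit")
    b_ref = fit.slopes[reference]
    if abs(b_ref) < SLOPE_TOL:
        raise LayreqError("reference slope is (numerically) zero; RBE undefined")
    res = rbe_from_slopes(fit.slopes, reference)
    res.alpha = alpha
    tcrit = stats.t.ppf(1 - alpha / 2, fit.df_resid)
    ref_col = f"X_{reference}"
    v_rr = float(fit.cov.loc[ref_col, ref_col])
    for s, b_i in fit.slopes.items():
        if s == reference:
            res.ci_fieller[s] = (100.0, 100.0)
            res.ci_delta[s] = (100.0, 100.0)
            continue
        col = f"X_{s}"
        v_ii = float(fit.cov.loc[col, col])
        v_ir = float(fit.cov.loc[col, ref_col])
        rho = b_i / b_ref
        # Delta method on the ratio.
        var_rho = (v_ii - 2 * rho * v_ir + rho * rho * v_rr) / (b_ref * b_ref)
        half = tcrit * np.sqrt(max(var_rho, 0.0))
        res.ci_delta[s] = (100 * (rho - half), 100 * (rho + half))
        # Fieller.
        g = tcrit * tcrit * v_rr / (b_ref * b_ref)
        if g >= 1:
            res.ci_fieller[s] = (float("nan"), float("nan"))
            continue
        disc = (v_ii - 2 * rho * v_ir + rho * rho * v_rr
                - g * (v_ii - v_ir * v_ir / v_rr))
        root = (tcrit / abs(b_ref)) * np.sqrt(max(disc, 0.0))
        centre = rho - g * v_ir / v_rr
        lo = (centre - root) / (1 - g)
        hi = (centre + root) / (1 - g)
        res.ci_fieller[s] = (100 * lo, 100 * hi)
    return res


def rbe_table(fit: SlopeRatioFit, result: RBEResult) -> pd.DataFrame:
    """CSV-ready summary mirroring a published slope/RBE table row set."""
    rows = []
    for s, b in fit.slopes.items():
        rows.append({
            "source": s,
            "slope": b,
            "rbe_percent": result.rbe[s],
            "rbe_rounded": result.rbe_rounded[s],
            "fieller_lo": result.ci_fieller.get(s, (np.nan, np.nan))[0],
            "fieller_hi": result.ci_fieller.get(s, (np.nan, np.nan))[1],
            "delta_lo": result.ci_delta.get(s, (np.nan, np.nan))[0],
            "delta_hi": result.ci_delta.get(s, (np.nan, np.nan))[1],
        })
    df = pd.DataFrame(rows)
    df.attrs.update(intercept=fit.intercept, r2=fit.r2, p_value=fit.p_value,
                    reference=result.reference)
    return df
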