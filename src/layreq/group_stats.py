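"""Treatment comparisons: one-way ANOVA, Tukey letters, dose contrasts.

The experimental unit is the replicate (cage group); a trait analyzed for
one period (or the pooled "overall" row) gives one observation per replicate
and a classical completely-randomized one-way layout.  The module provides

* a fixed-effects one-way ANOVA with pooled MSE and the treatment-mean
  standard error SEM = √(MSE/r);
* Tukey's HSD multiple comparison rendered as a compact letter display
  (treatments sharing a letter do not differ at the chosen α), with the
  Tukey–Kramer correction when replication is unbalanced;
* linear and quadratic orthogonal polynomial dose contrasts within each
  supplemented source arm (control + its levels), built for the *actual*
  dose values so unequal spacing is handled exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.formula.api import ols

from .design import TrialDesign
from .errors import LayreqError


@dataclass
class AnovaResult:
    """One-way ANOVA summary for one trait."""

    trait: str
    means: "pd.Series"            # per-treatment least-squares means
    n_per_group: "pd.Series"
    mse: float
    df_resid: int
    f_stat: float
    p_value: float
    sem: float                    # √(MSE/r) for common replication r
    balanced: bool
    letters: dict | None = None
    contrasts: dict = field(default_factory=dict)  # source -> {"linear": p, "quadratic": p}


def one_way_anova(data: pd.DataFrame, trait: str,
                  group: str = "treatment") -> AnovaResult:
    """Fixed-effects one-way ANOVA of ``trait`` by ``group``.

    Uses an OLS cell-means fit; the F statistic is the classical
    between/within mean-square ratio.  A degenerate table in which every
    observation is identical returns F = 0, p = 1.  With unbalanced groups
    the common-r SEM is replaced by √(MSE/harmonic-mean r) and a warning is
    issued (per-treatment SEMs remain derivable from ``mse`` and
    ``n_per_group``).
    """
    df = data[[group, trait]].dropna().rename(columns={group: "g", trait: "y"})
    counts = df.groupby("g", sort=True)["y"].count()
    if len(counts) < 2 or (counts < 2).any():
        raise LayreqError("ANOVA needs >= 2 groups with >= 2 observations each")
    if np.ptp(df["y"].to_numpy()) == 0:
        means = df.groupby("g", sort=True)["y"].mean()
        return AnovaResult(trait=trait, means=means, n_per_group=counts,
                           mse=0.0, df_resid=int(len(df) - len(counts)),
                           f_stat=0.0, p_value=1.0, sem=0.0,
                           balanced=counts.nunique() == 1)
    model = ols("y ~ C(g)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=1)
    ss_t, ss_e = table["sum_sq"].iloc[0], table["sum_sq"].iloc[1]
    df_t, df_e = int(table["df"].iloc[0]), int(table["df"].iloc[1])
    mse = ss_e / df_e
    if ss_t + ss_e == 0:
        f, p = 0.0, 1.0
    else:
        f = float(table["F"].iloc[0])
        p = float(table["PR(>F)"].iloc[0])
        if np.isnan(f):  # zero within-group variance with real between-group SS
            f, p = np.inf, 0.0
    means = df.groupby("g", sort=True)["y"].mean()
    balanced = counts.nunique() == 1
    if balanced:
        r = float(counts.iloc[0])
    else:
        r = stats.hmean(counts)
        warnings.warn(
            f"unbalanced replication for {trait}; SEM uses harmonic-mean r={r:.2f}",
            stacklevel=2,
        )
    sem = float(np.sqrt(mse / r)) if mse > 0 else 0.0
    return AnovaResult(trait=trait, means=means, n_per_group=counts, mse=float(mse),
                       df_resid=df_e, f_stat=float(f), p_value=float(p), sem=sem,
                       balanced=balanced)


def tukey_cld(means: Mapping, mse: float, df: int, r,
              alpha: float = 0.05) -> dict:
    """Compact letter display from Tukey's studentized-range test.

    Parameters
    ----------
    means : mapping group -> mean
    mse, df : pooled error mean square and its degrees of freedom
    r : common replication (scalar) or mapping group -> n; a mapping
        triggers the Tukey–Kramer allowance for each pair.
    alpha : family-wise significance level.

    Returns mapping group -> letter string (e.g. ``"ab"``); any two groups
    whose means differ by more than the HSD share no letter.  Letters are
    ordered so that ``"a"`` contains the largest mean.  Group order (for tie
    -breaking) follows the input mapping order.
    """
    if df <= 0:
        raise LayreqError("Tukey test needs positive residual df")
    groups = list(means.keys())
    k = len(groups)
    if k == 1:
        return {groups[0]: "a"}
    q = stats.studentized_range.ppf(1 - alpha, k, df)

    def hsd(g1, g2) -> float:
        if isinstance(r, Mapping):
            return q * np.sqrt(mse / 2 * (1 / r[g1] + 1 / r[g2]))
        return q * np.sqrt(mse / r)

    # Insert-and-absorb: start with one letter covering everything; for each
    # significantly different pair split any letter containing both, then
    # drop letters that became subsets of others.
    cols: list[set] = [set(groups)]
    order = sorted(groups, key=lambda g: -means[g])
    for i, g1 in enumerate(order):
        for g2 in order[i + 1:]:
            if abs(means[g1] - means[g2]) > hsd(g1, g2):
                new_cols = []
                for col in cols:
                    if g1 in col and g2 in col:
                        new_cols.extend([col - {g1}, col - {g2}])
                    else:
                        new_cols.append(col)
                cols = _absorb(new_cols)
    # Stable letter order: by descending best mean within each column.
    cols.sort(key=lambda col: -max(means[g] for g in col))
    letters = {g: "" for g in groups}
    for letter_idx, col in enumerate(cols):
        ch = chr(ord("a") + letter_idx)
        for g in groups:
            if g in col:
                letters[g] += ch
    return letters


def _absorb(cols: list[set]) -> list[set]:
    out: list[set] = []
    for col in cols:
        if not col:
            continue
        if any(col < other or col == other for other in out):
            continue
        out = [o for o in out if not (o < col)]
        out.append(col)
    return out


def orthogonal_poly_coefs(doses: Sequence[float], degree: int = 2) -> np.ndarray:
    """Orthogonal polynomial contrast coefficients for arbitrary dose spacing.

    Gram–Schmidt orthogonalization of (x, x², …) against the constant vector
    and each other, normalized to unit length.  Row ``i`` (0-based) is the
    degree-(i+1) contrast; each row sums to zero and rows are mutually
    orthogonal whatever the spacing.
    """
    x = np.asarray(doses, dtype=float)
    n = x.size
    if np.unique(x).size <= degree:
        raise LayreqError(
            f"degree-{degree} contrast needs more than {degree} distinct doses"
        )
    basis = [np.ones(n) / np.sqrt(n)]
    rows = []
    for d in range(1, degree + 1):
        v = x ** d
        for b in basis:
            v = v - (v @ b) * b
        norm = np.linalg.norm(v)
        if norm < 1e-12:
            raise LayreqError("dose values are collinear; contrast undefined")
        v = v / norm
        basis.append(v)
        rows.append(v)
    return np.vstack(rows)


def poly_dose_contrasts(arm_means: Sequence[float], doses: Sequence[float],
                        mse: float, df: int, r: float) -> dict:
    """Linear/quadratic dose-trend tests within one source arm.

    ``arm_means`` are the treatment means at the given dose values (control
    included).  Each contrast L = Σcᵢmᵢ is tested with
    t = L / √(MSE·Σcᵢ²/r) against the pooled residual df of the full ANOVA.
    With fewer than 3 distinct doses the quadratic entry is omitted with a
    warning.

    Returns ``{"linear": {"estimate", "se", "t", "p"}, "quadratic": {...}}``.
    """
    m = np.asarray(arm_means, dtype=float)
    x = np.asarray(doses, dtype=float)
    if m.size != x.size:
        raise LayreqError("means and doses length mismatch")
    degree = 2
    if np.unique(x).size < 3:
        warnings.warn("fewer than 3 distinct doses: quadratic contrast omitted",
                      stacklevel=2)
        degree = 1
    coefs = orthogonal_poly_coefs(x, degree=degree)
    out = {}
    for name, c in zip(("linear", "quadratic"), coefs):
        est = float(c @ m)
        se = float(np.sqrt(mse * np.sum(c ** 2) / r))
        if se == 0:
            t = np.inf if est != 0 else 0.0
            p = 0.0 if est != 0 else 1.0
        else:
            t = est / se
            p = 2 * stats.t.sf(abs(t), df)
        out[name] = {"estimate": est, "se": se, "t": float(t), "p": float(p),
                     "coefs": c.tolist()}
    return out


def treatment_analysis(traits: pd.DataFrame, trait: str, design: TrialDesign,
                       alpha: float = 0.05,
                       dose_scale: str = "analyzed") -> AnovaResult:
    """Full per-trait analysis: ANOVA, Tukey letters, per-source L/Q trends.

    ``traits`` must hold one row per (treatment, replicate) for the analyzed
    period; dose contrasts use each source arm's total-Mn doses on the
    requested scale (analyzed concentrations by default; the shared control
    anchors every arm).
    """
    res = one_way_anova(traits, trait)
    r = res.n_per_group
    res.letters = tukey_cld(res.means.to_dict(), res.mse, res.df_resid,
                            r.to_dict() if not res.balanced else float(r.iloc[0]),
                            alpha=alpha)
    for source in design.sources:
        arm = design.arm(source)
        ids = [t.id for t in arm]
        if any(i not in res.means.index for i in ids):
            continue
        doses = design.doses(arm, scale=dose_scale)
        means = [res.means[i] for i in ids]
        rr = float(r.loc[ids].mean())
        res.contrasts[source] = poly_dose_contrasts(means, doses, res.mse,
                                                    res.df_resid, rr)
    return res


def anova_report(res: AnovaResult) -> pd.DataFrame:
    """Tidy CSV-ready table: treatment means with letters, then footer rows
    (SEM, F, p, and per-source linear/quadratic trend p-values)."""
    rows = [{"row": f"treatment_{g}", "value": res.means[g],
             "letter": res.letters.get(g, "") if res.letters else ""}
            for g in res.means.index]
    rows.append({"row": "SEM", "value": res.sem, "letter": ""})
    rows.append({"row": "F", "value": res.f_stat, "letter": ""})
    rows.append({"row": "p", "value": res.p_value, "letter": ""})
    for source, c in res.contrasts.items():
        rows.append({"row": f"p_linear_{source}", "value": c["linear"]["p"],
                     "letter": ""})
        if "quadratic" in c:
            rows.append({"row": f"p_quadratic_{source}",
                         "value": c["quadratic"]["p"], "letter": ""})
    return pd.DataFrame(rows)
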