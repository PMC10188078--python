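"""Performance and egg-quality trait computation from raw laying records.

Performance traits are computed per (treatment, replicate, period) on a
hen-day basis — every rate divides by the realized bird-days of the
replicate, so mortality adjustment is automatic:

* ``EP``  — hen-day egg production, % = 100 × eggs / hen-days
* ``EW``  — mean egg weight, g = total egg weight / eggs
* ``EM``  — egg mass, g/bird/day = total egg weight / hen-days
            (identically EP/100 × EW)
* ``FI``  — feed intake, g/bird/day = (offered − residual) / hen-days
* ``FCR`` — feed conversion ratio = total feed intake / total egg mass,
            a ratio of totals, *not* a mean of per-period ratios

Egg-quality traits come from individually measured eggs:

* shape index, % = 100 × width / length
* Haugh unit = 100 · log10(h + 7.57 − 1.7·W^0.37), h = albumen height (mm),
  W = egg weight (g)
* relative eggshell weight (RESW), g shell per 100 g egg
* mean shell thickness, μm, averaged over the top/middle/bottom sites
* albumen weight, g = egg − yolk − shell (bookkeeping identity)

"Overall" rows aggregate the periods of each replicate; by default they are
recomputed from summed counts and masses (hen-day weighted), with a
``simple`` switch for unweighted period means.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .errors import DataIntegrityError, UndefinedTraitError

#: Constant of the Haugh albumen-quality formula.
HAUGH_OFFSET = 7.57
HAUGH_COEF = 1.7
HAUGH_EXP = 0.37


def hen_day_ep(eggs_laid, hen_days) -> float:
    """Hen-day egg production, % of bird-days on which an egg was laid."""
    if hen_days <= 0:
        raise UndefinedTraitError("hen_days must be positive")
    if eggs_laid < 0:
        raise DataIntegrityError("eggs_laid cannot be negative")
    if eggs_laid > hen_days:
        raise DataIntegrityError(
            f"eggs_laid ({eggs_laid}) exceeds hen_days ({hen_days})"
        )
    return 100.0 * eggs_laid / hen_days


def feed_intake(feed_offered, feed_residual, hen_days) -> float:
    """Feed intake, g per bird-day, from offered minus residual feed."""
    if hen_days <= 0:
        raise UndefinedTraitError("hen_days must be positive")
    if feed_offered < 0 or feed_residual < 0:
        raise DataIntegrityError("feed masses cannot be negative")
    if feed_residual > feed_offered:
        raise DataIntegrityError("residual feed exceeds feed offered")
    return (feed_offered - feed_residual) / hen_days


def fcr(total_feed_intake, total_egg_mass) -> float:
    """Feed conversion ratio: total feed intake / total egg mass (g/g).

    Computed on totals; summing periods first and dividing is *not* the
    same as averaging per-period ratios when egg mass varies.
    """
    if total_egg_mass <= 0:
        raise UndefinedTraitError("total egg mass must be positive")
    if total_feed_intake < 0:
        raise DataIntegrityError("feed intake cannot be negative")
    return total_feed_intake / total_egg_mass


def shape_index(width, length) -> float:
    """Egg shape index, % = 100 × maximum width / maximum length."""
    if width <= 0 or length <= 0:
        raise DataIntegrityError("egg dimensions must be positive")
    if width > length:
        raise DataIntegrityError(f"width ({width}) exceeds length ({length})")
    return 100.0 * width / length


def haugh_unit(albumen_height, egg_weight) -> float:
    """Haugh unit: 100 · log10(h + 7.57 − 1.7·W^0.37)."""
    if albumen_height <= 0 or egg_weight <= 0:
        raise DataIntegrityError("albumen height and egg weight must be positive")
    arg = albumen_height + HAUGH_OFFSET - HAUGH_COEF * egg_weight ** HAUGH_EXP
    if arg <= 0:
        raise UndefinedTraitError(
            f"Haugh log argument non-positive ({arg:.4f}) for "
            f"h={albumen_height}, W={egg_weight}"
        )
    return 100.0 * math.log10(arg)


def relative_shell_weight(shell, egg) -> float:
    """Relative eggshell weight, g of shell per 100 g of whole egg."""
    if shell <= 0 or egg <= 0:
        raise DataIntegrityError("shell and egg weights must be positive")
    if shell >= egg:
        raise DataIntegrityError(f"shell weight ({shell}) not below egg weight ({egg})")
    return 100.0 * shell / egg


def mean_shell_thickness(top, middle, bottom) -> float:
    """Mean shell thickness (μm) over the three measurement sites."""
    if min(top, middle, bottom) <= 0:
        raise DataIntegrityError("shell thicknesses must be positive")
    return (top + middle + bottom) / 3.0


# ---------------------------------------------------------------------------
# table-level computation

PERFORMANCE_TRAITS = ("egg_production", "egg_weight", "egg_mass",
                      "feed_intake", "fcr")
EGG_TRAITS = ("resw", "shell_thickness", "shape_index", "haugh_unit",
              "yolk_weight", "albumen_weight")

#: Decimals used when formatting report tables (full precision kept internally).
REPORT_DECIMALS = {"fcr": 3, "default": 2}


def _performance_row(g: pd.DataFrame) -> pd.Series:
    hd = float(g["hen_days"].sum())
    eggs = float(g["eggs_laid"].sum())
    egg_wt = float(g["total_egg_weight_g"].sum())
    feed = float((g["feed_offered_g"] - g["feed_residual_g"]).sum())
    ep = hen_day_ep(eggs, hd)
    ew = egg_wt / eggs if eggs > 0 else float("nan")
    em = egg_wt / hd
    fi = feed / hd
    ratio = fcr(feed, egg_wt)
    return pd.Series({
        "hen_days": hd,
        "egg_production": ep,
        "egg_weight": ew,
        "egg_mass": em,
        "feed_intake": fi,
        "fcr": ratio,
    })


def _egg_row(g: pd.DataFrame) -> pd.Series:
    resw = [relative_shell_weight(s, w)
            for s, w in zip(g["shell_g"], g["egg_weight_g"])]
    thick = [mean_shell_thickness(t, m, b)
             for t, m, b in zip(g["thick_top_um"], g["thick_mid_um"], g["thick_bot_um"])]
    shape = [shape_index(w, l) for w, l in zip(g["width_mm"], g["length_mm"])]
    hu = [haugh_unit(h, w) for h, w in zip(g["albumen_height_mm"], g["egg_weight_g"])]
    albumen = g["egg_weight_g"] - g["yolk_g"] - g["shell_g"]
    if (albumen < 0).any():
        raise DataIntegrityError("yolk + shell weight exceeds whole-egg weight")
    return pd.Series({
        "resw": float(np.mean(resw)),
        "shell_thickness": float(np.mean(thick)),
        "shape_index": float(np.mean(shape)),
        "haugh_unit": float(np.mean(hu)),
        "yolk_weight": float(g["yolk_g"].mean()),
        "albumen_weight": float(albumen.mean()),
    })


def compute_traits(replicates: pd.DataFrame,
                   eggs: pd.DataFrame | None = None,
                   overall: str = "hen_day_weighted") -> pd.DataFrame:
    """Derive the trait table from replicate and (optionally) egg records.

    Parameters
    ----------
    replicates : DataFrame
        Columns treatment, replicate, period, hen_days, eggs_laid,
        total_egg_weight_g, feed_offered_g, feed_residual_g, mortality.
    eggs : DataFrame, optional
        Egg-level quality records; when given, egg-quality traits are merged
        in (period means over the sampled eggs of each replicate).
    overall : {"hen_day_weighted", "simple"}
        How the per-replicate "overall" row pools periods: recompute from
        summed counts/masses (default) or average the period trait values.

    Returns
    -------
    DataFrame keyed by (treatment, replicate, period) with ``period`` also
    taking the value ``"overall"``.
    """
    if overall not in ("hen_day_weighted", "simple"):
        raise ValueError(f"unknown overall mode {overall!r}")
    keys = ["treatment", "replicate", "period"]
    per = (replicates.groupby(keys, sort=True)
           .apply(_performance_row, include_groups=False)
           .reset_index())

    if overall == "hen_day_weighted":
        ov = (replicates.groupby(["treatment", "replicate"], sort=True)
              .apply(_performance_row, include_groups=False)
              .reset_index())
    else:
        ov = (per.groupby(["treatment", "replicate"], sort=True)
              [list(PERFORMANCE_TRAITS) + ["hen_days"]]
              .mean().reset_index())
    ov["period"] = "overall"

    out = pd.concat([per.astype({"period": object}), ov], ignore_index=True)

    if eggs is not None:
        ekeys = ["treatment", "replicate", "period"]
        eg = (eggs.groupby(ekeys, sort=True)
              .apply(_egg_row, include_groups=False)
              .reset_index())
        eg_ov = (eggs.groupby(["treatment", "replicate"], sort=True)
                 .apply(_egg_row, include_groups=False)
                 .reset_index())
        eg_ov["period"] = "overall"
        eg_all = pd.concat([eg.astype({"period": object}), eg_ov],
                           ignore_index=True)
        out = out.merge(eg_all, on=keys, how="left")

    return out.sort_values(keys, key=_period_sort).reset_index(drop=True)


def _period_sort(col: pd.Series) -> pd.Series:
    if col.name == "period":
        return col.map(lambda p: math.inf if p == "overall" else float(p))
    return col


def round_for_report(traits: pd.DataFrame) -> pd.DataFrame:
    """Report-precision copy: 3 decimals for FCR, 2 for other traits."""
    out = traits.copy()
    for c in out.columns:
        if c in ("treatment", "replicate", "period", "hen_days"):
            continue
        if pd.api.types.is_numeric_dtype(out[c]):
            out[c] = out[c].round(REPORT_DECIMALS.get(c, REPORT_DECIMALS["default"]))
    return out
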