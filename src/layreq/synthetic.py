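"""Synthetic trial generator with known dose-response truth.

Every downstream stage of the pipeline (traits → ANOVA → broken-line →
slope-ratio) is testable against data whose generating model is known.  The
generator emulates the reference trial's layout — 10 treatments (control +
3 sources × 3 added Mn levels), 6 replicate cages of 12 hens, three 4-week
periods — and produces the same raw record schema a real trial would yield.

Generative model
----------------
Each trait has a :class:`SyntheticTruth`: per-source broken-line curves
evaluated at the treatment's total dietary Mn, plus replicate-level Gaussian
noise.  The control diet belongs to no source arm; its generative value is
the mean of the source curves evaluated at the basal concentration (a single
shared diet must have a single truth).  Noise is drawn once per replicate
and shared across that replicate's periods — the replicate is the
experimental unit, and the noise sd is calibrated as SEM × √6 from the
reference trial's treatment-mean standard errors (6 replicates/treatment);
an optional independent per-period jitter can be added on top.

Raw-record bookkeeping is internally consistent, so the traits module
recovers the generative egg production, egg weight, egg mass, feed intake
and FCR exactly when noise is zero.  By default egg counts are kept
fractional (``egg_count_mode="exact"``) so this round trip is exact to
machine precision; ``"integer"`` mode rounds daily cumulative lay counts
(remainders carried forward), which quantizes hen-day production by
~0.3 percentage points per period.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .broken_line import BrokenLineParams, predict
from .design import TrialDesign, Treatment
from .errors import InvalidParameterError
from . import trial

log = logging.getLogger(__name__)

#: Default generator seed.
DEFAULT_SEED = 20230315

#: Fraction of offered feed left in the feeders (bookkeeping only).
RESIDUAL_FRACTION = 0.02

#: Maximum rejection-sampling attempts per simulated egg.
MAX_EGG_ATTEMPTS = 1000

REPLICATE_COLUMNS = ["treatment", "replicate", "period", "hen_days",
                     "eggs_laid", "total_egg_weight_g", "feed_offered_g",
                     "feed_residual_g", "mortality"]
EGG_COLUMNS = ["treatment", "replicate", "period", "egg_id", "egg_weight_g",
               "width_mm", "length_mm", "albumen_height_mm", "yolk_g",
               "shell_g", "thick_top_um", "thick_mid_um", "thick_bot_um"]


def constant_truth(mean: float) -> BrokenLineParams:
    """A flat (dose-independent) truth as a degenerate broken line."""
    return BrokenLineParams(form="LBL", L=mean, U=0.0, R=0.0)


@dataclass(frozen=True)
class SyntheticTruth:
    """Generative model of one trait across the trial.

    ``models`` maps each supplemented source to its broken-line curve over
    total dietary Mn; ``noise_sd`` is the replicate-level Gaussian sd in
    trait units.  ``control`` overrides the control diet's generative value
    (default: mean of the source curves at the basal dose).
    """

    models: Mapping[str, BrokenLineParams]
    noise_sd: float = 0.0
    control: float | None = None

    def __post_init__(self):
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")

    def evaluate(self, treatment: Treatment, design: TrialDesign) -> float:
        x = treatment.total_mn(design.basal_mn, scale="analyzed")
        if treatment.source == "none":
            if self.control is not None:
                return self.control
            vals = [predict(m, x) for m in self.models.values()]
            return float(np.mean(vals))
        try:
            model = self.models[treatment.source]
        except KeyError:
            raise InvalidParameterError(
                f"no truth model for source {treatment.source!r}"
            ) from None
        return predict(model, x)


def default_truths(noise: bool = True) -> dict[str, SyntheticTruth]:
    """Truths emulating the reference trial.

    Dose-responsive egg production plus flat egg weight and feed intake
    (neither showed a dose response in the reference trial); egg mass and
    FCR then inherit their dose response through the bookkeeping identities.
    Noise sds are SEM × √6.
    """
    s = trial.SQRT6 if noise else 0.0
    flat = trial.FLAT_TRAIT_MEANS
    return {
        "egg_production": SyntheticTruth(
            models=trial.FITTED_MODELS["egg_production"],
            noise_sd=trial.OVERALL_SEM["egg_production"] * s),
        "egg_weight": SyntheticTruth(
            models={src: constant_truth(flat["egg_weight"])
                    for src in ("oxide", "sulphate", "organic")},
            noise_sd=trial.OVERALL_SEM["egg_weight"] * s),
        "feed_intake": SyntheticTruth(
            models={src: constant_truth(flat["feed_intake"])
                    for src in ("oxide", "sulphate", "organic")},
            noise_sd=trial.OVERALL_SEM["feed_intake"] * s),
    }


def simulate_replicates(design: TrialDesign,
                        truths: Mapping[str, SyntheticTruth],
                        seed: int = DEFAULT_SEED,
                        egg_count_mode: str = "exact",
                        period_jitter_sd: float = 0.0) -> pd.DataFrame:
    """Simulate the replicate-period performance records of a trial.

    Parameters
    ----------
    design : TrialDesign
    truths : mapping trait -> SyntheticTruth
        ``"egg_production"`` is required; ``"egg_weight"`` and
        ``"feed_intake"`` default to the reference trial's flat means with
        zero noise when omitted.
    seed : int
        Seed for the generator; identical (design, truths, seed) give
        byte-identical tables.
    egg_count_mode : {"exact", "integer"}
        Fractional egg counts (exact trait round trip) or daily cumulative
        rounding to whole eggs.
    period_jitter_sd : float
        Optional extra per-period noise sd applied on top of the shared
        replicate-level draw, in trait units (same for every trait, scaled
        by each trait's ``noise_sd`` relative to egg production is *not*
        attempted — the jitter is absolute per trait only when nonzero).
    """
    if "egg_production" not in truths:
        raise InvalidParameterError("truths must define 'egg_production'")
    if egg_count_mode not in ("exact", "integer"):
        raise ValueError(f"unknown egg_count_mode {egg_count_mode!r}")
    truths = dict(truths)
    flat = trial.FLAT_TRAIT_MEANS
    truths.setdefault("egg_weight", SyntheticTruth(
        models={s: constant_truth(flat["egg_weight"]) for s in design.sources}))
    truths.setdefault("feed_intake", SyntheticTruth(
        models={s: constant_truth(flat["feed_intake"]) for s in design.sources}))

    rng = np.random.default_rng(seed)
    n_clipped = 0
    rows = []
    for t in design.treatments:
        mu = {name: tr.evaluate(t, design) for name, tr in truths.items()}
        for rep in range(1, design.n_replicates + 1):
            eff = {name: rng.normal(0.0, tr.noise_sd) if tr.noise_sd > 0 else 0.0
                   for name, tr in truths.items()}
            for per in range(1, design.n_periods + 1):
                jit = (rng.normal(0.0, period_jitter_sd)
                       if period_jitter_sd > 0 else 0.0)
                ep = mu["egg_production"] + eff["egg_production"] + jit
                if ep < 0.0 or ep > 100.0:
                    n_clipped += 1
                    ep = float(np.clip(ep, 0.0, 100.0))
                ew = max(mu["egg_weight"] + eff["egg_weight"], 1e-6)
                fi = max(mu["feed_intake"] + eff["feed_intake"], 0.0)
                hen_days = design.birds_per_replicate * design.period_days
                if egg_count_mode == "exact":
                    eggs = hen_days * ep / 100.0
                else:
                    eggs = _integer_eggs(design.birds_per_replicate,
                                         design.period_days, ep)
                consumed = fi * hen_days
                offered = consumed / (1.0 - RESIDUAL_FRACTION)
                rows.append({
                    "treatment": t.id,
                    "replicate": rep,
                    "period": per,
                    "hen_days": hen_days,
                    "eggs_laid": eggs,
                    "total_egg_weight_g": eggs * ew,
                    "feed_offered_g": offered,
                    "feed_residual_g": offered - consumed,
                    "mortality": 0,
                })
    if n_clipped:
        log.warning("clipped %d egg-production draws to [0, 100]", n_clipped)
    df = pd.DataFrame(rows, columns=REPLICATE_COLUMNS)
    df.attrs["n_clipped"] = n_clipped
    return df


def _integer_eggs(birds: int, days: int, ep: float) -> int:
    """Whole-egg count via daily cumulative rounding (remainder carried)."""
    total = 0
    cum = 0.0
    prev = 0
    for _ in range(days):
        cum += birds * ep / 100.0
        laid_to_date = round(cum)
        total += laid_to_date - prev
        prev = laid_to_date
    return total


def default_egg_params(design: TrialDesign) -> dict[int, dict[str, float]]:
    """Per-treatment egg-quality means emulating the reference trial.

    All fields share common means except shell weight, which tracks the
    relative-eggshell-weight dose response (slope model on supplemental Mn).
    """
    params = {}
    for t in design.treatments:
        means = dict(trial.EGG_QUALITY_MEANS)
        resw = trial.resw_mean(t, design)
        means["shell_g"] = resw / 100.0 * means["egg_weight_g"]
        params[t.id] = means
    return params


def default_egg_sds(noise: bool = True) -> dict[str, float]:
    scale = 1.0 if noise else 0.0
    sds = {k: v * scale for k, v in trial.EGG_QUALITY_SDS.items()}
    sds["shell_g"] = trial.OVERALL_SEM["resw"] * trial.SQRT6 / 100.0 \
        * trial.EGG_QUALITY_MEANS["egg_weight_g"] * scale
    return sds


def _validate_egg_means(tid: int, means: Mapping[str, float]) -> None:
    missing = [c for c in EGG_COLUMNS[4:] if c not in means]
    if missing:
        raise InvalidParameterError(
            f"treatment {tid}: egg parameter means missing {missing}"
        )
    if any(means[c] <= 0 for c in EGG_COLUMNS[4:]):
        raise InvalidParameterError(f"treatment {tid}: egg means must be positive")
    if means["width_mm"] > means["length_mm"]:
        raise InvalidParameterError(
            f"treatment {tid}: mean width exceeds mean length"
        )
    if means["shell_g"] + means["yolk_g"] >= means["egg_weight_g"]:
        raise InvalidParameterError(
            f"treatment {tid}: shell + yolk means not below egg weight"
        )


def simulate_eggs(design: TrialDesign,
                  egg_params: Mapping[int, Mapping[str, float]] | None = None,
                  sds: Mapping[str, float] | None = None,
                  seed: int = DEFAULT_SEED,
                  eggs_per_replicate: int = 6) -> pd.DataFrame:
    """Simulate individually measured eggs (quality subsample).

    ``eggs_per_replicate`` eggs per replicate per period are drawn with
    Gaussian noise around the treatment means; physically impossible draws
    (width > length, shell + yolk > egg, non-positive values) are rejected
    and redrawn, with a bounded retry loop so inconsistent parameter sets
    raise instead of spinning.  Zero noise reproduces the means exactly.
    """
    egg_params = egg_params if egg_params is not None else default_egg_params(design)
    sds = dict(sds) if sds is not None else default_egg_sds()
    fields = EGG_COLUMNS[4:]
    for t in design.treatments:
        if t.id not in egg_params:
            raise InvalidParameterError(f"no egg parameters for treatment {t.id}")
        _validate_egg_means(t.id, egg_params[t.id])

    rng = np.random.default_rng(seed + 1)  # decouple from replicate stream
    rows = []
    for t in design.treatments:
        means = egg_params[t.id]
        for rep in range(1, design.n_replicates + 1):
            for per in range(1, design.n_periods + 1):
                for egg_id in range(1, eggs_per_replicate + 1):
                    egg = _draw_egg(rng, means, sds, fields)
                    rows.append({"treatment": t.id, "replicate": rep,
                                 "period": per, "egg_id": egg_id, **egg})
    return pd.DataFrame(rows, columns=EGG_COLUMNS)


def _draw_egg(rng, means, sds, fields) -> dict[str, float]:
    for _ in range(MAX_EGG_ATTEMPTS):
        egg = {f: rng.normal(means[f], sds.get(f, 0.0)) for f in fields}
        if any(v <= 0 for v in egg.values()):
            continue
        if egg["width_mm"] > egg["length_mm"]:
            continue
        if egg["shell_g"] + egg["yolk_g"] > egg["egg_weight_g"]:
            continue
        return egg
    raise InvalidParameterError(
        "egg rejection sampling failed: means/sds admit no valid egg "
        f"within {MAX_EGG_ATTEMPTS} attempts"
    )


def simulate_trait_observations(model: BrokenLineParams, doses,
                                n_per_dose: int, noise_sd: float,
                                seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Flat (X, Y) arrays of replicate observations on one truth curve.

    The low-level primitive behind break-point recovery studies: ``n_per_dose``
    independent Gaussian draws around the curve at each dose.
    """
    rng = np.random.default_rng(seed)
    x = np.repeat(np.asarray(doses, dtype=float), n_per_dose)
    y = predict(model, x) + rng.normal(0.0, noise_sd, size=x.size)
    return x, np.asarray(y, dtype=float)


def write_csvs(replicates: pd.DataFrame, eggs: pd.DataFrame | None,
               design: TrialDesign, outdir) -> None:
    """Write replicates.csv / eggs.csv / design.json (UTF-8, '.' decimals)."""
    from pathlib import Path
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    replicates.to_csv(out / "replicates.csv", index=False)
    if eggs is not None:
        eggs.to_csv(out / "eggs.csv", index=False)
    design.to_json(out / "design.json")
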