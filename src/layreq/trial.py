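"""Built-in constants of the reference layer-hen manganese trial.

These describe a 12-week completely randomized trial in 83-week-old
Hy-Line W-36 layers: one unsupplemented control (10.4 mg/kg analyzed dietary
Mn) plus three added levels (nominally 30/60/90 mg/kg Mn) of each of three
sources — Mn-oxide (Mn2O3, 69.62 % Mn), Mn-sulphate (MnSO4·H2O, 36.4 % Mn)
and an organic Mn-amino-acid complex (10 % Mn) — with 6 replicate cages of
12 hens followed over three 4-week periods.

The module also carries the trial's reported dose-response summaries, used as
generative truths by the synthetic-data module and as worked-example inputs:
per-source broken-line models for egg production, egg mass and feed
conversion; the common-intercept slope-ratio coefficients; and treatment-mean
standard errors used to calibrate replicate-level noise.
"""

from __future__ import annotations

from .broken_line import BrokenLineParams
from .design import TrialDesign, make_design

#: Trial layout: (source, additive rate mg/kg, Mn fraction, nominal added Mn,
#: analyzed total Mn mg/kg).
DESIGN_CONFIG: dict = {
    "basal_mn": 10.3,
    "n_replicates": 6,
    "birds_per_replicate": 12,
    "n_periods": 3,
    "period_days": 28,
    "treatments": [
        {"source": "none", "supplement_rate": 0.0, "analyzed_total_mn": 10.4},
        {"source": "oxide", "supplement_rate": 43, "mn_fraction": 0.6962,
         "nominal_added_mn": 30, "analyzed_total_mn": 40.20},
        {"source": "oxide", "supplement_rate": 86, "mn_fraction": 0.6962,
         "nominal_added_mn": 60, "analyzed_total_mn": 70.75},
        {"source": "oxide", "supplement_rate": 130, "mn_fraction": 0.6962,
         "nominal_added_mn": 90, "analyzed_total_mn": 100.60},
        {"source": "sulphate", "supplement_rate": 82, "mn_fraction": 0.364,
         "nominal_added_mn": 30, "analyzed_total_mn": 40.25},
        {"source": "sulphate", "supplement_rate": 164, "mn_fraction": 0.364,
         "nominal_added_mn": 60, "analyzed_total_mn": 70.70},
        {"source": "sulphate", "supplement_rate": 247, "mn_fraction": 0.364,
         "nominal_added_mn": 90, "analyzed_total_mn": 100.25},
        {"source": "organic", "supplement_rate": 300, "mn_fraction": 0.10,
         "nominal_added_mn": 30, "analyzed_total_mn": 40.60},
        {"source": "organic", "supplement_rate": 600, "mn_fraction": 0.10,
         "nominal_added_mn": 60, "analyzed_total_mn": 70.20},
        {"source": "organic", "supplement_rate": 900, "mn_fraction": 0.10,
         "nominal_added_mn": 90, "analyzed_total_mn": 100.70},
    ],
}


def reference_design() -> TrialDesign:
    """The 10-treatment reference trial as a validated :class:`TrialDesign`."""
    return make_design(DESIGN_CONFIG)


#: Reported per-source broken-line models of whole-trial (overall) traits
#: against total dietary Mn (mg/kg, as-fed).  U is signed: negative for
#: traits maximized at the plateau, positive for FCR whose sub-plateau limb
#: rises as Mn falls.
FITTED_MODELS: dict[str, dict[str, BrokenLineParams]] = {
    "egg_production": {
        "oxide": BrokenLineParams(form="LBL", L=75.77, U=-0.07, R=82.0),
        "sulphate": BrokenLineParams(form="QBL", L=78.17, U=-0.009, R=40.0),
        "organic": BrokenLineParams(form="QBL", L=77.84, U=-0.014, R=33.0),
    },
    "egg_mass": {
        "oxide": BrokenLineParams(form="LBL", L=47.51, U=-0.029, R=92.0),
        "sulphate": BrokenLineParams(form="QBL", L=49.21, U=-0.005, R=39.0),
        # The printed plateau for this arm (90.13) is inconsistent with the
        # trait's scale (~49 g/b/d); the arm's observed plateau is used.
        "organic": BrokenLineParams(form="QBL", L=49.0, U=-0.006, R=36.0),
    },
    "fcr": {
        "oxide": BrokenLineParams(form="LBL", L=2.437, U=0.002, R=89.0),
        "sulphate": BrokenLineParams(form="QBL", L=2.36, U=-0.0003, R=38.0),
        "organic": BrokenLineParams(form="QBL", L=2.33, U=-0.0003, R=39.0),
    },
}

#: Reported common-intercept slope-ratio coefficients (per mg/kg supplemental
#: Mn) for each response, keyed trait -> {"intercept", "oxide", "sulphate",
#: "organic"}.
SLOPE_RATIO_COEFS: dict[str, dict[str, float]] = {
    "egg_production": {"intercept": 72.52, "oxide": 0.0353,
                       "sulphate": 0.0684, "organic": 0.0786},
    "egg_mass": {"intercept": 46.18, "oxide": 0.0122,
                 "sulphate": 0.0380, "organic": 0.0406},
    "fcr": {"intercept": 2.520, "oxide": -0.0009,
            "sulphate": -0.0025, "organic": -0.0025},
    "resw": {"intercept": 9.09, "oxide": 0.0023,
             "sulphate": 0.0047, "organic": 0.0062},
}

#: Whole-trial treatment-mean standard errors (6 replicates each).  The
#: replicate-level noise sd used in simulation is SEM × √6.
OVERALL_SEM: dict[str, float] = {
    "egg_production": 1.67,
    "egg_weight": 0.57,
    "egg_mass": 1.06,
    "feed_intake": 1.57,
    "fcr": 0.06,
    "resw": 0.17,
    "shell_thickness": 6.66,
    "haugh_unit": 2.33,
}

SQRT6 = 6 ** 0.5

#: Whole-trial grand means for traits with no dose response (flat truths).
FLAT_TRAIT_MEANS: dict[str, float] = {
    "egg_weight": 62.9,    # g/egg
    "feed_intake": 115.2,  # g/bird/day
}

#: Default per-egg quality means shared across treatments, except shell
#: weight which follows the relative-eggshell-weight slope model.
EGG_QUALITY_MEANS: dict[str, float] = {
    "egg_weight_g": 62.9,
    "width_mm": 44.0,
    "length_mm": 58.7,
    "albumen_height_mm": 8.4,
    "yolk_g": 16.5,
    "thick_top_um": 383.0,
    "thick_mid_um": 383.0,
    "thick_bot_um": 383.0,
}

#: Per-egg measurement noise sds for the same fields (shell noise handled by
#: the resw truth's replicate noise).
EGG_QUALITY_SDS: dict[str, float] = {
    "egg_weight_g": 2.5,
    "width_mm": 0.8,
    "length_mm": 1.0,
    "albumen_height_mm": 0.9,
    "yolk_g": 0.8,
    "thick_top_um": 18.0,
    "thick_mid_um": 18.0,
    "thick_bot_um": 18.0,
}


def reported_slopes(trait: str) -> dict[str, float]:
    """Per-source slope coefficients of one response row (intercept dropped)."""
    row = SLOPE_RATIO_COEFS[trait]
    return {s: b for s, b in row.items() if s != "intercept"}


def resw_mean(treatment, design: TrialDesign | None = None) -> float:
    """Generative relative-eggshell-weight mean (g/100 g) for a treatment.

    Linear in supplemental nominal Mn with the reported common-intercept
    slopes; the control sits at the intercept.
    """
    c = SLOPE_RATIO_COEFS["resw"]
    if treatment.source == "none":
        return c["intercept"]
    return c["intercept"] + c[treatment.source] * treatment.nominal_added_mn
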