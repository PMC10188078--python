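"""End-to-end pipeline: raw or simulated records → report bundle.

``run(config, outdir)`` drives the full chain — trait computation, per-trait
treatment ANOVA with Tukey letters and dose trends, per-source broken-line
requirement fits with model selection, and the slope-ratio RBE table — and
writes every table as machine-readable CSV/JSON plus a manifest recording
versions, the seed and input checksums so a run can be reproduced
byte-for-byte.

Config schema (JSON-compatible dict)::

    {
      "design": {...} | "design_path": "design.json",
      # exactly one of:
      "inputs": {"replicates": "replicates.csv", "eggs": "eggs.csv"},
      "simulate": {"noise": true, "egg_records": true},
      "traits": ["egg_production", "egg_mass", "fcr", "resw"],
      "alpha": 0.05,
      "anova_dose_scale": "analyzed",          # or "nominal"
      "broken_line_forms": ["LBL", "QBL"],
      "rbe_dose_scale": "supplemental_nominal",
      "reference_source": "organic",
      "seed": 20230315
    }
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, broken_line, group_stats, slope_ratio, synthetic, trial
from .design import TrialDesign, load_design, make_design
from .errors import ConfigError, LayreqError
from .traits import EGG_TRAITS, compute_traits

DEFAULT_TRAITS = ["egg_production", "egg_mass", "fcr", "resw"]


def validate_config(config: dict) -> dict:
    cfg = dict(config)
    has_inputs = "inputs" in cfg
    has_sim = "simulate" in cfg
    if has_inputs == has_sim:
        raise ConfigError("config must contain exactly one of 'inputs' | 'simulate'")
    alpha = cfg.setdefault("alpha", 0.05)
    if not (0 < alpha < 1):
        raise ConfigError(f"alpha must lie in (0, 1), got {alpha}")
    cfg.setdefault("traits", list(DEFAULT_TRAITS))
    cfg.setdefault("anova_dose_scale", "analyzed")
    cfg.setdefault("broken_line_forms", ["LBL", "QBL"])
    cfg.setdefault("rbe_dose_scale", "supplemental_nominal")
    cfg.setdefault("reference_source", "organic")
    cfg.setdefault("seed", synthetic.DEFAULT_SEED)
    if "design" not in cfg and "design_path" not in cfg and has_sim:
        cfg["design"] = dict(trial.DESIGN_CONFIG)
    return cfg


def _load_data(cfg: dict, design: TrialDesign):
    if "inputs" in cfg:
        paths = cfg["inputs"]
        replicates = pd.read_csv(paths["replicates"])
        eggs = pd.read_csv(paths["eggs"]) if paths.get("eggs") else None
        checksums = {k: _sha256(v) for k, v in paths.items() if v}
        return replicates, eggs, checksums
    sim = cfg["simulate"]
    noise = bool(sim.get("noise", True))
    truths = synthetic.default_truths(noise=noise)
    replicates = synthetic.simulate_replicates(design, truths, seed=cfg["seed"])
    eggs = None
    if sim.get("egg_records", True):
        eggs = synthetic.simulate_eggs(
            design, sds=synthetic.default_egg_sds(noise=noise), seed=cfg["seed"])
    return replicates, eggs, {}


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run(config: dict, outdir) -> dict:
    """Execute the pipeline; returns the manifest dict.

    Raises :class:`ConfigError` on validation failures (the CLI maps these
    to a nonzero exit with a single-line reason).
    """
    cfg = validate_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    if "design_path" in cfg:
        design = load_design(cfg["design_path"])
    else:
        design = make_design(cfg["design"])

    replicates, eggs, checksums = _load_data(cfg, design)
    egg_traits_requested = [t for t in cfg["traits"] if t in EGG_TRAITS]
    if egg_traits_requested and eggs is None:
        raise ConfigError(
            "egg records required for trait(s): " + ", ".join(egg_traits_requested)
        )

    traits_df = compute_traits(replicates, eggs)
    traits_df.to_csv(out / "traits.csv", index=False)
    overall = traits_df[traits_df["period"] == "overall"]

    # --- treatment ANOVA per trait -------------------------------------
    dose_scale = "analyzed" if cfg["anova_dose_scale"] == "analyzed" else "nominal"
    for tr_name in cfg["traits"]:
        if tr_name not in overall.columns:
            raise ConfigError(f"trait {tr_name!r} not present in trait table")
        res = group_stats.treatment_analysis(overall, tr_name, design,
                                             alpha=cfg["alpha"],
                                             dose_scale=dose_scale)
        group_stats.anova_report(res).to_csv(out / f"anova_{tr_name}.csv",
                                             index=False)

    # --- broken-line requirement fits per source arm --------------------
    selection_rows = []
    for tr_name in [t for t in cfg["traits"] if t not in EGG_TRAITS]:
        for source in design.sources:
            arm = design.arm(source)
            ids = [t.id for t in arm]
            sub = overall[overall["treatment"].isin(ids)]
            dose_by_id = {t.id: t.total_mn(design.basal_mn, "analyzed")
                          for t in arm}
            x = sub["treatment"].map(dose_by_id).to_numpy()
            y = sub[tr_name].to_numpy()
            fits = [broken_line.fit(x, y, form) for form in cfg["broken_line_forms"]]
            ranked = broken_line.select_model(fits)
            best = ranked[0]
            payload = {
                "trait": tr_name, "source": source,
                "selected_form": best.params.form,
                "candidates": [_fit_dict(f) for f in ranked],
            }
            with open(out / f"fit_{tr_name}_{source}.json", "w",
                      encoding="utf-8") as fh:
                json.dump(payload, fh, indent=2, default=_jsonable)
            selection_rows.append({
                "trait": tr_name, "source": source,
                "form": best.params.form,
                "requirement_mg_kg": best.params.R,
                "requirement_se": best.se["R"],
                "plateau": best.params.L,
                "identifiable": best.identifiable,
                "boundary": best.boundary,
            })
    pd.DataFrame(selection_rows).to_csv(out / "requirements.csv", index=False)

    # --- slope-ratio RBE -------------------------------------------------
    X = slope_ratio.encode_doses(design, dose_scale=cfg["rbe_dose_scale"])
    rbe_frames = []
    for tr_name in cfg["traits"]:
        merged = overall.merge(X, on="treatment")
        fit = slope_ratio.fit_slope_ratio(merged[tr_name], merged,
                                          dose_scale=cfg["rbe_dose_scale"])
        result = slope_ratio.rbe(fit, reference=cfg["reference_source"],
                                 alpha=cfg["alpha"])
        tab = slope_ratio.rbe_table(fit, result)
        tab.insert(0, "trait", tr_name)
        tab.insert(2, "intercept", fit.intercept)
        rbe_frames.append(tab)
    pd.concat(rbe_frames, ignore_index=True).to_csv(out / "rbe.csv", index=False)

    manifest = {
        "layreq_version": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": cfg["seed"],
        "config": {k: v for k, v in cfg.items() if k != "design"},
        "input_checksums": checksums,
        "n_clipped_ep": int(replicates.attrs.get("n_clipped", 0)),
        "outputs": sorted({p.name for p in out.iterdir()} | {"manifest.json"}),
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _fit_dict(f: broken_line.BrokenLineFit) -> dict:
    return {
        "form": f.params.form,
        "L": f.params.L, "U": f.params.U, "R": f.params.R,
        "se": f.se,
        "quality": asdict(f.quality),
        "identifiable": f.identifiable,
        "boundary": f.boundary,
        "flat_interval": f.flat_interval,
        "degenerate": f.degenerate,
    }


def _jsonable(o):
    if isinstance(o, (np.floating, np.integer, np.bool_)):
        return o.item()
    if isinstance(o, float) and not np.isfinite(o):
        return str(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
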