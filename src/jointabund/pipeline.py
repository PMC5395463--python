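"""End-to-end orchestration: synthesize -> assemble -> reduce -> model set
-> effects, driven by a single config, with a machine-readable manifest.

The three analyses (main additive/interaction set on 1974-2013, pesticide
three-way set on 1990-2013, single-variable crop comparison on 1986-1989
plus 2002-2009) each build their own restricted dataset with its own
standardization, as the study design requires, and regional re-analyses
rerun the main machinery per region with county-only random intercepts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assembly, effects, modelset, synth
from .errors import PipelineError
from .mixedmodel import ModelSpec, fit_lmm
from .terms import all_components, canonical

DEFAULT_GROUPS = {
    "land_use": [
        "harvested_cropland_pct:year",
        "unharvested_cropland_pct:year",
        "cropland_pasture_pct",
        "crp_pct",
    ],
    "climate": list(synth.CLIMATE_COVARIATES),
    "avian": list(synth.AVIAN_COVARIATES),
}

DEFAULT_THREE_WAYS = [
    "harvested_cropland_pct:pesticide_total:year",
    "unharvested_cropland_pct:pesticide_total:year",
]

# Latent effects the default synthetic world carries: a positive cropland
# association that decays through time, a mild climate effect, corvid
# pressure, a pesticide modification of the cropland effect, and a handful
# of crop-type effects of both signs.
DEFAULT_BETA = {
    "harvested_cropland_pct": 0.020,
    "harvested_cropland_pct:year": -0.0008,
    "unharvested_cropland_pct": 0.030,
    "unharvested_cropland_pct:year": -0.0008,
    "tmin_breeding": 0.05,
    "corvid": -0.005,
    "harvested_cropland_pct:pesticide_total:year": -0.0003,
    "barley": 0.05,
    "sugar_beets": 0.06,
    "nut_trees": -0.05,
    "rice": -0.02,
}


@dataclass
class RunConfig:
    """Everything one run needs; serializable to/from YAML."""

    seed: int = 1
    design: synth.SurveyDesign = field(
        default_factory=lambda: synth.SurveyDesign(n_regions=4, counties_per_region=6)
    )
    truth: synth.SimTruth = field(
        default_factory=lambda: synth.SimTruth(beta_true=dict(DEFAULT_BETA))
    )
    transform: str = "log1p"
    correlation_threshold: float = 0.65
    max_effects: int = 4
    max_fixed_params: int = 8
    support_margin: float = 2.0
    groups: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_GROUPS.items()})
    main_year_range: tuple = (1974, 2013)
    pesticide_year_range: tuple = (1990, 2013)
    crop_year_range: tuple = ((1986, 1989), (2002, 2009))
    pesticide_candidates: list = field(default_factory=lambda: list(DEFAULT_THREE_WAYS))
    pesticide_era_split: int = 2001
    pesticide_quantiles: tuple = (0.10, 0.90)
    crop_terms: list = field(default_factory=lambda: list(synth.CROP_COVARIATES))
    regional: bool = True

    def __post_init__(self):
        if self.correlation_threshold <= 0 or self.max_effects <= 0:
            raise ValueError("thresholds must be positive")
        if self.support_margin <= 0:
            raise ValueError("support_margin must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["design"] = dataclasses.asdict(self.design)
        d["truth"] = dataclasses.asdict(self.truth)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "design" in d:
            dd = dict(d["design"])
            if "year_span" in dd:
                dd["year_span"] = {k: tuple(v) for k, v in dd["year_span"].items()}
            d["design"] = synth.SurveyDesign(**dd)
        if "truth" in d:
            d["truth"] = synth.SimTruth(**d["truth"])
        for key in ("main_year_range", "pesticide_year_range"):
            if key in d:
                d[key] = tuple(d[key])
        if "crop_year_range" in d:
            d["crop_year_range"] = tuple(tuple(w) for w in d["crop_year_range"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(self.to_dict()), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(_plain(self.to_dict()), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _plain(obj):
    """YAML/JSON-friendly copy (tuples -> lists, numpy scalars -> python)."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise PipelineError(name, exc) from exc
        return wrapped
    return deco


def synthesize(config: RunConfig, out: Path) -> tuple:
    """Generate and persist the synthetic surveys + covariate panel."""
    panel = synth.generate_covariate_panel(config.design, config.seed)
    truth = config.truth.replace(seed=int(config.seed))
    latent = synth.generate_latent_abundance(panel, truth)
    records = synth.generate_surveys(latent, truth, config.design)
    out.mkdir(parents=True, exist_ok=True)
    records.to_csv(out / "surveys.csv", index=False)
    panel.to_csv(out / "covariates.csv", index=False)
    with open(out / "truth.yaml", "w") as fh:
        yaml.safe_dump(_plain(dataclasses.asdict(truth)), fh, sort_keys=True)
    return records, panel


def _screened_specs(table, candidates, config, random_spec="county_in_region",
                    max_fixed_params="config"):
    covs = sorted(all_components(candidates) - {"year"}) + ["year"]
    present = [c for c in covs if c in table.columns or c == "year"]
    forbidden = assembly.correlation_screen(
        table, present, config.correlation_threshold
    )
    cap = config.max_fixed_params if max_fixed_params == "config" else max_fixed_params
    return modelset.enumerate_models(
        candidates,
        max_effects=config.max_effects,
        forbidden_pairs=forbidden,
        max_fixed_params=cap,
        random_spec=random_spec,
    ), forbidden


def _importance_csv(summary, path):
    imp = modelset.adjusted_importance(summary)
    out = imp.copy()
    out["adj_er"] = [modelset.format_er(v) for v in imp["adj_er"]]
    out["adj_probability"] = [f"{p:.2f}" for p in imp["adj_probability"]]
    out.to_csv(path, index=False)
    return imp


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run all stages; returns the manifest (also written as JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": config.config_hash(),
        "seed": int(config.seed),
        "stages": {},
    }

    records, panel = _stage("synthesize")(synthesize)(config, out)
    manifest["stages"]["synthesize"] = {
        "n_survey_records": int(len(records)),
        "n_panel_rows": int(len(panel)),
    }

    reduction = _stage("variable_reduction")(modelset.variable_reduction)(
        records,
        panel,
        config.groups,
        transform=config.transform,
        support_margin=config.support_margin,
    )
    for name, df in reduction["groups"].items():
        df.to_csv(out / f"reduction_{name}.csv", index=False)
    carried = reduction["carried_forward"]
    (out / "carried_forward.txt").write_text("\n".join(carried) + "\n")
    manifest["stages"]["variable_reduction"] = {"carried_forward": carried}

    @_stage("model_set_main")
    def _main():
        if not carried:
            raise ValueError(
                "no candidate terms for enumeration: variable reduction "
                "carried nothing forward (check groups/config)"
            )
        cands = carried
        covs = sorted(all_components(cands) - {"year"})
        table = assembly.build_joint_table(
            records, panel, covs, year_range=config.main_year_range,
            transform=config.transform,
        )
        specs, forbidden = _screened_specs(table, cands, config)
        summary = modelset.fit_model_set(table, specs, candidates=cands)
        summary.models.to_csv(out / "models_main.csv", index=False)
        imp = _importance_csv(summary, out / "importance_main.csv")
        return table, cands, summary, imp, forbidden

    table_main, main_cands, summary_main, imp_main, forbidden_main = _main()
    manifest["stages"]["model_set_main"] = {
        "n_rows": int(len(table_main)),
        "n_models": int(len(summary_main.models)),
        "n_forbidden_pairs": len(forbidden_main),
        "sum_weights": float(summary_main.models["weight"].sum()),
        "top_model": list(summary_main.top.spec.effect_terms),
        "top_r2c": float(summary_main.top.r2c),
    }

    @_stage("effect_surface")
    def _surface():
        top = summary_main.top
        for x_term in ("harvested_cropland_pct", "unharvested_cropland_pct"):
            inter = canonical(f"{x_term}:year")
            if inter in top.spec.effect_terms:
                xg = np.linspace(
                    float(table_main[x_term].quantile(0.05)),
                    float(table_main[x_term].quantile(0.95)),
                    12,
                )
                yg = np.linspace(
                    float(table_main["year"].min()), float(table_main["year"].max()), 9
                )
                surf = effects.predict_surface(top, x_term, "year", xg, yg)
                surf.grid.to_csv(out / "surface_main.csv", index=False)
                return x_term
        return None

    manifest["stages"]["effect_surface"] = {"x_term": _surface()}

    if config.regional:
        regional = {}
        for region in sorted(records["region_id"].unique()):
            @_stage(f"model_set_region_{region}")
            def _region(region=region):
                recs = records[records["region_id"] == region]
                cands = main_cands
                covs = sorted(all_components(cands) - {"year"})
                tbl = assembly.build_joint_table(
                    recs, panel[panel["region_id"] == region], covs,
                    year_range=config.main_year_range, transform=config.transform,
                )
                specs, _ = _screened_specs(tbl, cands, config, random_spec="county")
                summary = modelset.fit_model_set(tbl, specs, candidates=cands)
                _importance_csv(summary, out / f"importance_region_{region}.csv")
                return {"n_rows": int(len(tbl)), "n_models": int(len(summary.models))}

            regional[region] = _region()
        manifest["stages"]["regional"] = regional

    @_stage("model_set_pesticide")
    def _pesticide():
        land_covs = set(synth.LAND_USE_COVARIATES) | {"pesticide_total"}
        extra = [
            c for c in carried
            if not (all_components([c]) - {"year"}) & land_covs
        ]
        cands = list(config.pesticide_candidates) + extra
        covs = sorted(all_components(cands) - {"year"})
        table = assembly.build_joint_table(
            records, panel, covs, year_range=config.pesticide_year_range,
            transform=config.transform,
        )
        # the three-way set needs more than 8 fixed parameters by construction
        specs, _ = _screened_specs(table, cands, config, max_fixed_params=None)
        summary = modelset.fit_model_set(table, specs, candidates=cands)
        summary.models.to_csv(out / "models_pesticide.csv", index=False)
        _importance_csv(summary, out / "importance_pesticide.csv")
        classes = effects.pesticide_classes(
            panel,
            low_q=config.pesticide_quantiles[0],
            high_q=config.pesticide_quantiles[1],
            era_split=config.pesticide_era_split,
        )
        top = summary.top
        slices_info = None
        for crop in ("harvested_cropland_pct", "unharvested_cropland_pct"):
            three = canonical(f"{crop}:pesticide_total:year")
            if three in top.spec.effect_terms:
                grid = np.linspace(
                    float(table[crop].quantile(0.05)),
                    float(table[crop].quantile(0.95)),
                    12,
                )
                sl = effects.three_way_slices(top, crop, classes, grid)
                sl.to_csv(out / "pesticide_slices.csv", index=False)
                slices_info = crop
                break
        return summary, classes, slices_info, len(table)

    summary_pest, classes, slices_info, n_pest = _pesticide()
    manifest["stages"]["model_set_pesticide"] = {
        "n_rows": int(n_pest),
        "n_models": int(len(summary_pest.models)),
        "low_threshold": classes.low_threshold,
        "high_threshold": classes.high_threshold,
        "slices_for": slices_info,
        "top_model": list(summary_pest.top.spec.effect_terms),
    }

    @_stage("crop_posthoc")
    def _crops():
        table = assembly.build_joint_table(
            records, panel, list(config.crop_terms),
            year_range=list(config.crop_year_range), transform=config.transform,
        )
        res = effects.crop_posthoc(table, config.crop_terms)
        res.to_csv(out / "crops.csv", index=False)
        return res, len(table)

    crops, n_crop = _crops()
    manifest["stages"]["crop_posthoc"] = {
        "n_rows": int(n_crop),
        "n_crops": int(len(crops)),
        "n_supported": int(crops["supported"].sum()),
    }

    with open(out / "manifest.json", "w") as fh:
        json.dump(_plain(manifest), fh, indent=2, sort_keys=True)
    config.to_yaml(out / "config.yaml")
    return manifest


REPORT_REQUIRED = ["manifest.json", "importance_main.csv", "crops.csv"]


def write_report(run_dir) -> str:
    """Render a human-readable summary from a completed run directory.

    Pure function of the on-disk artifacts: regenerating it yields the
    identical text. Probabilities print with 2 decimals and evidence
    ratios with 2 decimals or ">100".
    """
    run = Path(run_dir)
    missing = [f for f in REPORT_REQUIRED if not (run / f).exists()]
    if missing:
        raise FileNotFoundError(f"run directory incomplete; missing: {missing}")
    with open(run / "manifest.json") as fh:
        manifest = json.load(fh)
    lines = []
    lines.append("Joint abundance-index analysis report")
    lines.append("=" * 38)
    lines.append(f"config hash : {manifest['config_hash']}")
    lines.append(f"seed        : {manifest['seed']}")
    lines.append("")

    def importance_section(title, path):
        if not path.exists():
            return
        df = pd.read_csv(path, dtype={"adj_probability": str, "adj_er": str})
        lines.append(title)
        lines.append("-" * len(title))
        lines.append(f"{'Rank':>4}  {'Covariate':<48} {'Adj. prob.':>10} {'Adj. ER':>8}")
        for _, r in df.iterrows():
            lines.append(
                f"{int(r['rank']):>4}  {r['covariate']:<48} "
                f"{r['adj_probability']:>10} {r['adj_er']:>8}"
            )
        lines.append("")

    importance_section("Covariate importance (main analysis)", run / "importance_main.csv")
    for p in sorted(run.glob("importance_region_*.csv")):
        region = p.stem.replace("importance_region_", "")
        importance_section(f"Covariate importance (region {region})", p)
    importance_section(
        "Covariate importance (pesticide analysis)", run / "importance_pesticide.csv"
    )

    crops = pd.read_csv(run / "crops.csv")
    lines.append("Crop-type effects (percent change per 1% crop increase)")
    lines.append("-" * 55)
    lines.append(f"{'Crop':<16} {'Estimate':>9} {'95% CI':>22} {'Support':>8}")
    for _, r in crops.iterrows():
        ci = f"({r['lower95_pct']:.1f} to {r['upper95_pct']:.1f})"
        flag = "yes" if bool(r["supported"]) else "no"
        lines.append(f"{r['crop']:<16} {r['estimate_pct']:>8.1f}% {ci:>22} {flag:>8}")
    lines.append("")
    text = "\n".join(lines) + "\n"
    (run / "report.txt").write_text(text)
    return text
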