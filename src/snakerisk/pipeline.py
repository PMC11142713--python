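"""End-to-end orchestration: simulate -> prepare -> dataset -> five fits ->
evaluation -> consensus -> incidence -> case summaries, with a manifest of
every artefact.

Each stage reads its inputs from the run directory and writes text artefacts
(ASCII grids, CSV tables, JSON reports), so the CLI subcommands can re-run any
stage independently. All randomness derives from seeds in the config; a rerun
under the same config reproduces every artefact byte for byte, which the
manifest checksums make checkable.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from snakerisk import cases as case_epi
from snakerisk import evaluate as ev
from snakerisk import incidence as inc
from snakerisk import models as mdl
from snakerisk import occurrence as occ
from snakerisk import prep
from snakerisk import simulate as sim
from snakerisk.raster import StudyArea, read_ascii_grid, write_ascii_grid
from snakerisk.stack import PredictorStack

__all__ = ["RunConfig", "run_all", "STAGES"]

DEFAULT_CONFIG: dict = {
    "output_dir": "runs/demo",
    "seed": 1,
    "grid": {
        "shape": [60, 60],
        "cell_size": 0.00833333,
        "origin_x": 91.0,
        "origin_y": 24.0,
        "length_scale": 5.0,
        "layers": ["bio1", "bio2", "bio3", "bio12", "bio13", "bio15", "bio16", "elevation"],
        "means": {"bio1": 25.0, "bio2": 10.0, "bio3": 60.0, "bio12": 2800.0,
                  "bio13": 600.0, "bio15": 70.0, "bio16": 1600.0, "elevation": 150.0},
        "sds": {"bio1": 1.5, "bio2": 1.0, "bio3": 5.0, "bio12": 350.0,
                "bio13": 120.0, "bio15": 8.0, "bio16": 300.0, "elevation": 180.0},
        # wettest-month vs wettest-quarter precipitation are near-duplicates
        # by construction, exercising the collinearity pruning rule
        "correlations": [["bio16", "bio13", 0.95]],
    },
    "population": {"mean": 850.0, "sd": 300.0, "length_scale": 8.0},
    "study_area": {"inset_fraction": 0.05},
    "truth": {
        "beta0": -1.0,
        "beta": {"bio1": 1.2, "bio12": -0.8, "bio15": 0.9, "elevation": -1.2},
        "n_presence": 998,
        "standardized": True,
    },
    "scenario": {
        "label_current": "current",
        "label_future": "future_2070",
        "mean_shifts": {"bio1": 2.0, "bio12": -150.0},
        "population_growth": 1.02,
    },
    "cases": {},
    # priority = scientific interest: the wettest-quarter precipitation (bio16)
    # outranks the near-duplicate wettest-month layer (bio13), so the pruning
    # step keeps the quarter-scale layer
    "prune": {"threshold": 0.9, "priority": ["bio1", "bio2", "bio3", "bio12", "bio16",
                                             "bio15", "elevation", "bio13"]},
    "background": {"n": 1000},
    "split": {"train_fraction": 0.8, "stratified": True},
    "models": {
        "list": ["envelope", "glm_binomial", "glm_gaussian", "random_forest", "maxent_like"],
        "n_trees": 100,
        "mtry": None,
        "penalty": 1.0,
    },
    "consensus": {"scheme": "auc_excess", "histogram_bins": 10, "threshold_cutoff": 0.5},
    "regression": {"family": "gaussian_identity", "alpha": 0.05,
                   "include_population": True, "risk_cutoff": 0.5},
}


# dict-valued leaves that are *data*, not nested config sections: a user
# override replaces them wholesale instead of merging key-by-key
_ATOMIC_KEYS = {"beta", "means", "sds", "correlations", "priority", "list", "mean_shifts"}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict) and k not in _ATOMIC_KEYS:
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


@dataclass
class RunConfig:
    """Validated run configuration (user file merged over defaults)."""

    raw: dict

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        return cls(raw=_deep_merge(DEFAULT_CONFIG, user))

    @classmethod
    def defaults(cls, **overrides) -> "RunConfig":
        return cls(raw=_deep_merge(DEFAULT_CONFIG, overrides))

    def __post_init__(self) -> None:
        if "seed" not in self.raw or self.raw["seed"] is None:
            raise ValueError("config must set an explicit seed")
        fam = self.raw["regression"]["family"]
        if fam not in inc.FAMILIES:
            raise ValueError(f"unknown regression family {fam!r}")
        scheme = self.raw["consensus"]["scheme"]
        if scheme not in ("auc_excess", "equal"):
            raise ValueError(f"unknown consensus scheme {scheme!r}")
        unknown = set(self.raw["models"]["list"]) - {
            "envelope", "glm_binomial", "glm_gaussian", "random_forest", "maxent_like"
        }
        if unknown:
            raise ValueError(f"unknown models in config: {sorted(unknown)}")

    def __getitem__(self, key):
        return self.raw[key]

    @property
    def out_dir(self) -> Path:
        return Path(self.raw["output_dir"])

    def seed_for(self, stage: str) -> int:
        """Derive a stable per-stage seed from the master seed."""
        h = hashlib.sha256(f"{self.raw['seed']}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31 - 1)

    def hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_json(obj, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=float)
        fh.write("\n")


def _require(path: Path, stage: str, hint: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"stage {stage!r}: missing input {path} — run {hint!r} first")
    return path


# -- stages -------------------------------------------------------------------


def _field_spec(cfg: RunConfig, extra_layer=None, mean_shifts=None) -> sim.FieldSpec:
    g = cfg["grid"]
    means = dict(g["means"])
    for k, v in (mean_shifts or {}).items():
        means[k] = means.get(k, 0.0) + v
    return sim.FieldSpec(
        shape=tuple(g["shape"]),
        cell_size=g["cell_size"],
        origin_x=g["origin_x"],
        origin_y=g["origin_y"],
        layer_names=tuple(g["layers"]),
        length_scale=g["length_scale"],
        means=means,
        sds=dict(g["sds"]),
        correlations=tuple((a, b, r) for a, b, r in g.get("correlations") or ()),
        seed=cfg.seed_for("fields"),
    )


def _population_spec(cfg: RunConfig, growth: float = 1.0) -> sim.FieldSpec:
    g, pcfg = cfg["grid"], cfg["population"]
    return sim.FieldSpec(
        shape=tuple(g["shape"]),
        cell_size=g["cell_size"],
        origin_x=g["origin_x"],
        origin_y=g["origin_y"],
        layer_names=("human_population",),
        length_scale=pcfg["length_scale"],
        means={"human_population": pcfg["mean"] * growth},
        sds={"human_population": pcfg["sd"] * growth},
        seed=cfg.seed_for("population"),
    )


def _study_area(cfg: RunConfig) -> StudyArea:
    g = cfg["grid"]
    f = cfg["study_area"]["inset_fraction"]
    nrows, ncols = g["shape"]
    cs = g["cell_size"]
    x0, y0 = g["origin_x"], g["origin_y"]
    w, h = ncols * cs, nrows * cs
    ring = [
        (x0 + f * w, y0 - f * h),
        (x0 + (1 - f) * w, y0 - f * h),
        (x0 + (1 - f) * w, y0 - (1 - f) * h),
        (x0 + f * w, y0 - (1 - f) * h),
        (x0 + f * w, y0 - f * h),
    ]
    return StudyArea.from_vertices(ring)


def _truth_spec(cfg: RunConfig, stack: PredictorStack) -> sim.OccurrenceProcessSpec:
    t = cfg["truth"]
    beta = dict(t["beta"])
    if t.get("standardized", True):
        # coefficients are stated on the standardized scale; convert to the
        # raw scale of the generated layers
        g = cfg["grid"]
        beta0 = t["beta0"]
        raw_beta = {}
        for name, b in beta.items():
            sd = g["sds"].get(name, 1.0)
            mean = g["means"].get(name, 0.0)
            raw_beta[name] = b / sd
            beta0 -= b * mean / sd
        beta = raw_beta
    else:
        beta0 = t["beta0"]
    return sim.OccurrenceProcessSpec(
        beta=beta, beta0=beta0, n_presence=t["n_presence"], seed=cfg.seed_for("occurrences")
    )


def stage_simulate(cfg: RunConfig) -> dict:
    """Generate predictor stacks (current + future), population rasters, the
    study area, presence points, and the hospital-style case table."""
    out = cfg.out_dir / "inputs"
    out.mkdir(parents=True, exist_ok=True)
    scen = cfg["scenario"]

    area = _study_area(cfg)
    stack = sim.gen_predictor_stack(_field_spec(cfg))
    future = sim.gen_predictor_stack(_field_spec(cfg, mean_shifts=scen["mean_shifts"]))
    pop = sim.gen_predictor_stack(_population_spec(cfg))["human_population"]
    pop = pop.with_values(np.clip(pop.values, 0.0, None))
    pop_future = sim.gen_predictor_stack(
        _population_spec(cfg, growth=scen["population_growth"])
    )["human_population"]
    pop_future = pop_future.with_values(np.clip(pop_future.values, 0.0, None))

    cur_dir = out / "stack_current"
    fut_dir = out / "stack_future"
    stack.write_dir(cur_dir)
    future.write_dir(fut_dir)
    write_ascii_grid(pop, out / "population_current.asc")
    write_ascii_grid(pop_future, out / "population_future.asc")

    import shapely

    with open(out / "study_area.geojson", "w") as fh:
        json.dump(json.loads(shapely.to_geojson(area.polygon)), fh)

    truth = _truth_spec(cfg, stack)
    presences = sim.gen_occurrences(stack, truth)
    pd.DataFrame(presences, columns=["x", "y"]).to_csv(out / "presences.csv", index=False)
    _write_json(
        {"beta": truth.beta, "beta0": truth.beta0, "n_presence": truth.n_presence,
         "stated_beta": cfg["truth"]["beta"], "stated_beta0": cfg["truth"]["beta0"]},
        out / "truth.json",
    )

    case_spec = sim.CaseTableSpec(seed=cfg.seed_for("cases"), **cfg["cases"])
    table = sim.gen_case_table(case_spec, stack, truth)
    case_epi.write_cases(table, out / "cases.csv")
    return {"n_presence": len(presences), "n_cases": len(table)}


def _load_inputs(cfg: RunConfig, stage: str):
    out = cfg.out_dir / "inputs"
    _require(out / "stack_current", stage, "simulate")
    layers = list(cfg["grid"]["layers"])
    stack = PredictorStack.read_dir(out / "stack_current", names=layers)
    future = PredictorStack.read_dir(out / "stack_future", names=layers)
    area = StudyArea.from_geojson(out / "study_area.geojson")
    return stack, future, area


def stage_prep(cfg: RunConfig) -> dict:
    """Crop to the study area, prune collinear layers, standardize with
    training-period parameters (reused for the future stack), summarize by PCA."""
    from snakerisk.raster import crop_to_area

    stack, future, area = _load_inputs(cfg, "prep")
    stack = stack.map_layers(lambda _n, g: crop_to_area(g, area))
    future = future.map_layers(lambda _n, g: crop_to_area(g, area))

    priority = cfg["prune"]["priority"]
    if priority is not None:
        # unlisted layers rank after the listed ones, in stack order
        priority = [n for n in priority if n in stack] + [
            n for n in stack.names if n not in priority
        ]
    pruned, dropped = prep.prune_correlated(
        stack, threshold=cfg["prune"]["threshold"], priority=priority
    )
    future = future.subset(pruned.names)
    std, params = prep.standardize_stack(pruned)
    std_future = prep.apply_standardization(future, params)
    pca = prep.pca_summary(std)

    out = cfg.out_dir / "prepared"
    std.write_dir(out / "stack_current")
    std_future.write_dir(out / "stack_future")
    _write_json({"means": params.means, "sds": params.sds}, out / "standardization.json")
    pd.DataFrame(dropped, columns=["kept", "dropped", "r"]).to_csv(
        out / "pruned_pairs.csv", index=False
    )
    prep.pca_report_frame(pca).to_csv(out / "pca.csv", index=False)
    _write_json({"layers": std.names}, out / "layers.json")

    pop = read_ascii_grid(cfg.out_dir / "inputs" / "population_current.asc")
    pop_f = read_ascii_grid(cfg.out_dir / "inputs" / "population_future.asc")
    pop = crop_to_area(pop, area)
    pop_f = crop_to_area(pop_f, area)
    pm, ps = float(pop.valid_values().mean()), float(pop.valid_values().std(ddof=1))
    _write_json({"mean": pm, "sd": ps}, out / "population_standardization.json")
    write_ascii_grid(pop, out / "population_current.asc")
    write_ascii_grid(pop_f, out / "population_future.asc")
    return {"n_layers": len(std.names), "dropped": [d[1] for d in dropped],
            "pc_fractions": pca.fractions[:2].tolist()}


def _load_prepared(cfg: RunConfig, stage: str):
    out = cfg.out_dir / "prepared"
    _require(out / "layers.json", stage, "prep")
    with open(out / "layers.json") as fh:
        layers = json.load(fh)["layers"]
    std = PredictorStack.read_dir(out / "stack_current", names=layers)
    std_future = PredictorStack.read_dir(out / "stack_future", names=layers)
    return std, std_future


def stage_dataset(cfg: RunConfig) -> dict:
    """Background sampling, feature extraction, and the stratified 80/20 split."""
    std, _ = _load_prepared(cfg, "dataset")
    inputs = cfg.out_dir / "inputs"
    _require(inputs / "presences.csv", "dataset", "simulate")
    presences = pd.read_csv(inputs / "presences.csv")[["x", "y"]].to_numpy()
    area = StudyArea.from_geojson(inputs / "study_area.geojson")
    bg = occ.sample_background(area, std, n=cfg["background"]["n"],
                               seed=cfg.seed_for("background"))
    ds = occ.build_dataset(presences, bg, std)
    ds = occ.split_train_test(ds, train_fraction=cfg["split"]["train_fraction"],
                              seed=cfg.seed_for("split"))
    out = cfg.out_dir / "dataset"
    out.mkdir(parents=True, exist_ok=True)
    ds.to_frame().to_csv(out / "dataset.csv", index=False)
    counts = occ.cases_per_cell(presences, std.template)
    write_ascii_grid(counts, out / "case_counts.asc")
    return {"n_points": len(ds.points), "n_excluded": ds.n_excluded}


def _load_dataset(cfg: RunConfig, stage: str) -> occ.OccurrenceDataset:
    path = _require(cfg.out_dir / "dataset" / "dataset.csv", stage, "dataset")
    std, _ = _load_prepared(cfg, stage)
    return occ.OccurrenceDataset.from_frame(pd.read_csv(path), std.names)


def stage_fit(cfg: RunConfig, only: str | None = None) -> dict:
    """Fit the configured occurrence models on the training split."""
    std, _ = _load_prepared(cfg, "fit")
    ds = _load_dataset(cfg, "fit")
    counts_grid = read_ascii_grid(cfg.out_dir / "dataset" / "case_counts.asc")
    Xtr, ytr = ds.rows(split="train")
    mcfg = cfg["models"]
    wanted = [only] if only else mcfg["list"]
    out = cfg.out_dir / "models"
    out.mkdir(parents=True, exist_ok=True)
    fitted = []
    for kind in wanted:
        if kind == "envelope":
            model = mdl.envelope_fit(Xtr[ytr == 1], std.names)
        elif kind == "glm_binomial":
            model = mdl.glm_binomial_fit(Xtr, ytr, layer_names=std.names)
        elif kind == "glm_gaussian":
            # response: per-cell case count at each point's cell
            pts = ds.points[["x", "y"]].to_numpy()[ds.points["split"] == "train"]
            rows, cols, _ = counts_grid.cell_of(pts[:, 0], pts[:, 1])
            counts = counts_grid.values[rows, cols]
            model = mdl.glm_gaussian_fit(Xtr, counts, layer_names=std.names)
        elif kind == "random_forest":
            model = mdl.forest_fit(Xtr, ytr, n_trees=mcfg["n_trees"], mtry=mcfg["mtry"],
                                   seed=cfg.seed_for("forest"), layer_names=std.names)
        elif kind == "maxent_like":
            model = mdl.maxent_like_fit(Xtr[ytr == 1], Xtr[ytr == 0],
                                        penalty=mcfg["penalty"], layer_names=std.names)
        else:
            raise ValueError(f"unknown model kind {kind!r}")
        mdl.save_model(model, out / f"{kind}.json")
        fitted.append(kind)
    return {"fitted": fitted}


def stage_evaluate(cfg: RunConfig) -> dict:
    """Score each fitted model on the held-out test points (AUC, point-biserial
    r, p-value) and write the evaluation table."""
    ds = _load_dataset(cfg, "evaluate")
    out = cfg.out_dir / "eval"
    out.mkdir(parents=True, exist_ok=True)
    Xte, yte = ds.rows(split="test")
    rows = []
    for kind in cfg["models"]["list"]:
        path = _require(cfg.out_dir / "models" / f"{kind}.json", "evaluate", "fit")
        model = mdl.load_model(path)
        res = ev.evaluate_scores(kind, model.predict(Xte), yte)
        rows.append(res.__dict__)
    pd.DataFrame(rows).to_csv(out / "evaluation.csv", index=False)
    return {"auc": {r["model"]: r["auc"] for r in rows}}


def stage_consensus(cfg: RunConfig) -> dict:
    """Predict each model over both scenario stacks and combine them into
    AUC-weighted consensus maps with probability histograms."""
    std, std_future = _load_prepared(cfg, "consensus")
    eval_path = _require(cfg.out_dir / "eval" / "evaluation.csv", "consensus", "evaluate")
    evals = pd.read_csv(eval_path).set_index("model")["auc"].to_dict()
    scen = cfg["scenario"]
    out = cfg.out_dir / "consensus"
    out.mkdir(parents=True, exist_ok=True)
    results = {}
    for label, stack in ((scen["label_current"], std), (scen["label_future"], std_future)):
        maps = {}
        for kind in cfg["models"]["list"]:
            model = mdl.load_model(cfg.out_dir / "models" / f"{kind}.json")
            maps[kind] = model.predict_map(stack)
        cons = ev.consensus(maps, {k: evals[k] for k in maps}, scheme=cfg["consensus"]["scheme"])
        write_ascii_grid(cons.grid, out / f"consensus_{label}.asc")
        write_ascii_grid(
            ev.threshold_map(cons.grid, cutoff=cfg["consensus"]["threshold_cutoff"]),
            out / f"suitable_{label}.asc",
        )
        hist = ev.probability_histogram(cons.grid, n_bins=cfg["consensus"]["histogram_bins"])
        nb = cfg["consensus"]["histogram_bins"]
        pd.DataFrame({
            "bin_low": np.arange(nb) / nb, "bin_high": (np.arange(nb) + 1) / nb,
            "count": hist,
        }).to_csv(out / f"histogram_{label}.csv", index=False)
        results[label] = {"weights": cons.weights, "n_valid": cons.grid.n_valid}
    _write_json(results, out / "consensus_report.json")
    return results


def stage_incidence(cfg: RunConfig) -> dict:
    """Backward-selected occurrence regression (predictors + human population)
    applied to both scenarios and scaled by population into incidence totals."""
    std, std_future = _load_prepared(cfg, "incidence")
    ds = _load_dataset(cfg, "incidence")
    rcfg = cfg["regression"]
    prep_dir = cfg.out_dir / "prepared"
    pop = read_ascii_grid(_require(prep_dir / "population_current.asc", "incidence", "prep"))
    pop_f = read_ascii_grid(prep_dir / "population_future.asc")
    with open(prep_dir / "population_standardization.json") as fh:
        pstd = json.load(fh)

    features = pd.DataFrame(ds.features, columns=ds.layer_names)
    reg_stack_layers = dict(std.items())
    reg_stack_future_layers = dict(std_future.items())
    if rcfg["include_population"]:
        pop_std = pop.with_values((pop.values - pstd["mean"]) / pstd["sd"])
        pop_std_f = pop_f.with_values((pop_f.values - pstd["mean"]) / pstd["sd"])
        pts = ds.points[["x", "y"]].to_numpy()
        rows, cols, _ = pop_std.cell_of(pts[:, 0], pts[:, 1])
        features["human_population"] = pop_std.values[rows, cols]
        reg_stack_layers["human_population"] = pop_std
        reg_stack_future_layers["human_population"] = pop_std_f
        keep = features["human_population"].notna()
        features = features[keep]
        response = ds.points["label"].to_numpy()[keep.to_numpy()]
    else:
        response = ds.points["label"].to_numpy()

    fit = inc.backward_select(features, response, family=rcfg["family"], alpha=rcfg["alpha"])
    out = cfg.out_dir / "incidence"
    out.mkdir(parents=True, exist_ok=True)
    report = fit.report_frame()
    report.to_csv(out / "regression.csv", index=False)
    _write_json(
        {"family": fit.family, "r2_adjusted": fit.r2_adjusted,
         "trace": [{"term": t, "p_value": p} for t, p in fit.trace]},
        out / "regression_meta.json",
    )

    scenarios = {
        cfg["scenario"]["label_current"]: (PredictorStack(reg_stack_layers), pop),
        cfg["scenario"]["label_future"]: (PredictorStack(reg_stack_future_layers), pop_f),
    }
    comp = inc.compare_scenarios(fit, scenarios)
    for label in scenarios:
        write_ascii_grid(comp["risk"][label], out / f"risk_{label}.asc")
        write_ascii_grid(comp["incidence"][label], out / f"incidence_{label}.asc")
    for label, grid in comp["risk_change"].items():
        write_ascii_grid(grid, out / f"risk_change_{label}.asc")
    pops = {cfg["scenario"]["label_current"]: pop, cfg["scenario"]["label_future"]: pop_f}
    at_risk = {
        label: inc.population_at_risk(comp["risk"][label], pops[label],
                                      cutoff=rcfg["risk_cutoff"])
        for label in scenarios
    }
    _write_json(
        {"totals": comp["totals"], "difference_vs_baseline": comp["difference_vs_baseline"],
         "population_at_risk": at_risk, "risk_cutoff": rcfg["risk_cutoff"],
         "retained_terms": fit.terms, "r2_adjusted": fit.r2_adjusted},
        out / "totals.json",
    )
    return {"totals": comp["totals"], "retained": fit.terms}


def stage_epi(cfg: RunConfig) -> dict:
    """Demography, seasonality, and bite-type summaries of the case table."""
    path = _require(cfg.out_dir / "inputs" / "cases.csv", "epi", "simulate")
    df = case_epi.load_cases(path)
    out = cfg.out_dir / "epi"
    out.mkdir(parents=True, exist_ok=True)

    sexed, audit_sex = case_epi.subdataset(df, ["sex"])
    demo = case_epi.demography(sexed)
    demo["pyramid"].to_csv(out / "age_pyramid.csv")
    seas = case_epi.seasonal_summary(df, by_bite_type=True)
    seas["by_bite_type"].to_csv(out / "season_by_type.csv")
    pd.DataFrame({
        "season": list(seas["counts"]),
        "count": list(seas["counts"].values()),
        "share": [seas["shares"][s] for s in seas["counts"]],
    }).to_csv(out / "seasonal.csv", index=False)
    shares = case_epi.bite_type_shares(df, denominator="all_records")
    pd.DataFrame({"bite_type": list(shares), "mean_yearly_share": list(shares.values())}
                 ).to_csv(out / "bite_types.csv", index=False)
    case_epi.admin_counts(df, "district").to_csv(out / "district_counts.csv", index=False)
    summary = {
        "n_records": len(df),
        "n_with_sex": audit_sex["n_kept"],
        "sex_counts": demo["counts"],
        "sex_shares": demo["shares"],
        "season_shares": seas["shares"],
        "bite_type_mean_yearly_share": shares,
    }
    _write_json(summary, out / "summary.json")
    return summary


STAGES = {
    "simulate": stage_simulate,
    "prep": stage_prep,
    "dataset": stage_dataset,
    "fit": stage_fit,
    "evaluate": stage_evaluate,
    "consensus": stage_consensus,
    "incidence": stage_incidence,
    "epi": stage_epi,
}


def _manifest(cfg: RunConfig) -> dict:
    entries = {}
    root = cfg.out_dir
    for path in sorted(root.rglob("*")):
        if path.is_file() and path.name not in ("manifest.json", "run_report.json"):
            entries[str(path.relative_to(root))] = hashlib.sha256(
                path.read_bytes()
            ).hexdigest()
    return {"config_hash": cfg.hash(), "artifacts": entries}


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage in order and write the checksum manifest.

    Any stage failure aborts with the stage name attached; the manifest of
    artefacts produced so far is still written.
    """
    report: dict = {"config_hash": cfg.hash(), "stages": {}}
    try:
        for name, fn in STAGES.items():
            report["stages"][name] = fn(cfg)
    except Exception as exc:
        _write_json(_manifest(cfg), cfg.out_dir / "manifest.json")
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    manifest = _manifest(cfg)
    _write_json(manifest, cfg.out_dir / "manifest.json")
    _write_json(report, cfg.out_dir / "run_report.json")
    return report
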