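"""End-to-end pipeline: simulate -> communication battery -> behavior
prediction -> structure-function coupling -> combined ranking.

Driven by a flat, schema-validated configuration (one nesting level per
stage); every stochastic stage draws from an explicit seed recorded in the
run manifest, so reruns with an identical config are bitwise-identical."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import io
from .behavior import (
    family_aware_folds,
    impute_masked,
    lasso_predict_cv,
    nbs_predict_cv,
    preprocess_behavior,
    vectorize_features,
)
from .comm import MODELS, SCHEMES, communication_battery
from .coupling import coupling_battery, predictor_matrices
from .ranking import combined_ranking, rank_by_median
from .synth import (
    GroundTruth,
    generate_connectome_template,
    generate_geometry,
    generate_subject_ensemble,
    generate_synthetic_fc,
    generate_synthetic_behavior,
    plant_connected_support,
)

log = logging.getLogger("connectocomm")


class SimulateConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_regions: int = 68
    n_subjects: int = 50
    target_density: float = 0.25
    decay_mm: float = 30.0
    edge_noise: float = 0.2
    rewire_frac: float = 0.0
    fc_model: str = "SPE"
    fc_scheme: str = "wei"
    fc_coupling: float = 0.6
    distance_weight: float = 0.2
    n_dimensions: int = 2
    behavior_support_size: int = 10
    target_r2: float = 0.3
    seed: int = 0


class PredictConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k: int = 5
    n_repetitions: int = 2
    seed: int = 7
    methods: list = ["lasso", "nbs"]
    dimension: str = "dim1"
    t_threshold: float = 3.0
    n_permutations: int = 200
    require_significance: bool = True
    inner_k: int = 5


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    simulate: SimulateConfig = SimulateConfig()
    predict: PredictConfig = PredictConfig()
    density: float | None = None  # battery-level thresholding
    ranking_weights: list | None = None


def simulate_ensemble(cfg: SimulateConfig):
    """Build the full synthetic study: geometry, template, subjects, FC and
    behavioral dimensions (planted on the configured communication model)."""
    coords = generate_geometry(cfg.n_regions, cfg.seed)
    template = generate_connectome_template(coords, cfg.target_density,
                                            cfg.decay_mm, cfg.seed + 1)
    ens = generate_subject_ensemble(template, cfg.n_subjects,
                                    edge_noise=cfg.edge_noise,
                                    rewire_frac=cfg.rewire_frac,
                                    seed=cfg.seed + 2, coords=coords)
    truth = GroundTruth(generating_model=(cfg.fc_model, cfg.fc_scheme),
                        fc_coupling=cfg.fc_coupling,
                        distance_weight=cfg.distance_weight,
                        target_r2=cfg.target_r2)
    feats = []
    for i, subj in enumerate(ens.subjects):
        bat = communication_battery(subj.sc, coords, density=None,
                                    models=(cfg.fc_model,))
        cmat = bat[(cfg.fc_model, cfg.fc_scheme)]
        subj.fc = generate_synthetic_fc(subj.sc, coords, truth,
                                        seed=cfg.seed + 1000 + i,
                                        comm_values=cmat)
        feats.append(vectorize_features(np.nan_to_num(cmat, nan=0.0)))
    X = np.vstack(feats)
    # behavior is planted on region pairs regardless of direct connections:
    # communication features are defined for polysynaptic pairs too
    n = cfg.n_regions
    support_mask = np.ones((n, n)) - np.eye(n)
    ages = [s.age for s in ens.subjects]
    sexes = [s.sex for s in ens.subjects]
    for b in range(cfg.n_dimensions):
        t_b = GroundTruth(generating_model=truth.generating_model,
                          fc_coupling=cfg.fc_coupling,
                          distance_weight=cfg.distance_weight,
                          target_r2=cfg.target_r2)
        t_b.behavior_support = plant_connected_support(
            support_mask, cfg.behavior_support_size, seed=cfg.seed + 500 + b)
        y, t_b = generate_synthetic_behavior(X, ages, sexes, t_b,
                                             seed=cfg.seed + 600 + b)
        for i, subj in enumerate(ens.subjects):
            vec = np.zeros(cfg.n_dimensions) if subj.behavior is None \
                else np.asarray(subj.behavior)
            if vec.size < cfg.n_dimensions:
                vec = np.resize(vec, cfg.n_dimensions)
            vec[b] = y[i]
            subj.behavior = vec
    ens.generation_manifest.update(cfg.model_dump())
    return ens, truth


def predict_stage(ens, cfg: PredictConfig, density=None):
    """Run the configured prediction methods for every predictor tag."""
    coords = ens.coords
    pheno = ens.phenotypes()
    y = preprocess_behavior(pheno[cfg.dimension], pheno["age"], pheno["sex"])
    fold_plan = family_aware_folds(pheno["family_id"], k=cfg.k,
                                   n_repetitions=cfg.n_repetitions,
                                   seed=cfg.seed)
    # feature blocks per predictor
    blocks = {}
    cache_sc, cache_bat = None, None
    for subj in ens.subjects:
        if cache_sc is None or not np.array_equal(subj.sc, cache_sc):
            cache_sc = subj.sc
            cache_bat = communication_battery(subj.sc, coords, density)
        mats = predictor_matrices(cache_bat)
        mats["FC"] = subj.fc
        for tag, M in mats.items():
            if tag == "dist":
                continue  # distance is an FC benchmark, not a behavior predictor
            blocks.setdefault(tag, []).append(vectorize_features(M))
    n_regions = ens.subjects[0].sc.shape[0]
    results = {}
    for tag, rows in blocks.items():
        X = np.vstack(rows)
        X = impute_masked(X, kind="si" if tag.startswith("SI") else "efficiency")
        per_method = {}
        if "lasso" in cfg.methods:
            per_method["lasso"] = lasso_predict_cv(X, y, fold_plan,
                                                   inner_k=cfg.inner_k)
        if "nbs" in cfg.methods:
            per_method["nbs"] = nbs_predict_cv(
                X, y, fold_plan, n_regions=n_regions,
                t_threshold=cfg.t_threshold,
                n_permutations=cfg.n_permutations, seed=cfg.seed,
                require_significance=cfg.require_significance)
        results[tag] = per_method
        log.info("predicted %s: %s", tag,
                 {m: round(float(df["r"].mean()), 3)
                  for m, df in per_method.items()})
    return results, fold_plan


def run_pipeline(config: dict | RunConfig, out_dir) -> Path:
    """Execute all stages and write per-stage outputs plus ``manifest.json``."""
    cfg = config if isinstance(config, RunConfig) else RunConfig(**config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest = {"config": cfg.model_dump(), "outputs": [], "stages": {}}

    def _mark(stage):
        manifest["stages"][stage] = round(time.time() - t0, 2)
        log.info("stage %s done (%.1fs)", stage, time.time() - t0)

    ens, truth = simulate_ensemble(cfg.simulate)
    io.save_coords(out / "coords.tsv", ens.coords)
    io.save_phenotypes(out / "phenotypes.tsv", ens.phenotypes())
    manifest["outputs"] += ["coords.tsv", "phenotypes.tsv"]
    _mark("simulate")

    results, _ = predict_stage(ens, cfg.predict, density=cfg.density)
    acc_rows = []
    for tag, per_method in results.items():
        for method, df in per_method.items():
            for _, r in df.iterrows():
                acc_rows.append({"predictor": tag, "method": method,
                                 "repetition": r["repetition"],
                                 "fold": r["fold"], "r": r["r"],
                                 "mse": r["mse"]})
    acc = pd.DataFrame(acc_rows)
    acc.to_csv(out / "behavior_accuracy.tsv", sep="\t", index=False)
    manifest["outputs"].append("behavior_accuracy.tsv")
    _mark("predict")

    ctab = coupling_battery(ens, density=cfg.density)
    ctab.to_csv(out / "coupling.tsv", sep="\t", index=False)
    manifest["outputs"].append("coupling.tsv")
    _mark("couple")

    # ranking: combined over 16 structural predictors (FC excluded),
    # FC kept as a benchmark column in the behavioral table
    struct = [f"{m}_{s}" for m in MODELS for s in SCHEMES] + ["SC"]
    beh_ranks = []
    for method in cfg.predict.methods:
        per_rep = (acc[acc["method"] == method]
                   .groupby(["predictor", "repetition"])["r"].mean()
                   .unstack(level=0))
        beh_ranks.append(rank_by_median(per_rep[struct]))
    med = (ctab[(ctab["unit"] != "GROUP") & (ctab["stratum"] == "all")]
           .groupby("predictor")["rho"].median())
    fun_rank = rank_by_median(pd.DataFrame([med[struct]] * 2))
    weights = cfg.ranking_weights
    table = combined_ranking(beh_ranks if len(beh_ranks) > 1 else beh_ranks[0],
                             fun_rank, weights)
    table.to_csv(out / "ranking.tsv", sep="\t")
    manifest["outputs"].append("ranking.tsv")
    _mark("rank")

    blob = json.dumps(manifest["config"], sort_keys=True).encode()
    manifest["config_hash"] = hashlib.sha256(blob).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out
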