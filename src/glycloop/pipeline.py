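"""End-to-end orchestration of the prediction and dosing pipeline.

Stages: simulate -> featurize -> cluster -> train -> evaluate -> explain ->
closed-loop. Each stage writes plain-text artifacts into the run directory
and registers them in ``run.json`` (config hash, package version, stage
seeds, artifact paths). Re-running with the same config reproduces every
artifact bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bolus import closed_loop_evaluate
from .cohort import generate_cohort, save_manifest
from .config import RunConfig, stage_seed
from .core_io import save_patient_records
from .ensemble import (
    predict_instance, predict_matrix, run_protocol, train_system,
)
from .errors import GlycloopError
from .explain import (
    aggregate_lime_ranks, aggregate_shap, lime_explain, shapley_interactions,
)
from .features import FEATURE_NAMES, MealInstance, build_dataset, dataset_to_arrays
from .profiling import build_profile_index
from .report import tir_report

logger = logging.getLogger(__name__)


def instances_to_frame(instances: list[MealInstance]) -> pd.DataFrame:
    X, y1, y2 = dataset_to_arrays(instances)
    df = pd.DataFrame(X, columns=FEATURE_NAMES)
    df.insert(0, "patient_id", [i.patient_id for i in instances])
    df["label_hypo"], df["label_hyper"] = y1, y2
    df["cluster_id_s1"] = [i.cluster_id_s1 for i in instances]
    df["cluster_id_s2"] = [i.cluster_id_s2 for i in instances]
    df["meal_time"] = [str(i.meal_time) for i in instances]
    return df


def frame_to_instances(df: pd.DataFrame) -> list[MealInstance]:
    from .features import FeatureVector

    out = []
    for _, row in df.iterrows():
        fv = FeatureVector(
            cgm_at_meal=row["cgm_at_meal"],
            hourly_means=tuple(row[f] for f in FEATURE_NAMES[1:7]),
            lbgi_6h=row["lbgi_6h"], hbgi_6h=row["hbgi_6h"],
            excursion_60=row["excursion_60min"], cho=row["cho_g"],
            meal_hour=int(row["meal_hour"]), mib=row["bolus_u"],
        )
        inst = MealInstance(
            patient_id=str(row["patient_id"]), features=fv,
            label_hypo=int(row["label_hypo"]), label_hyper=int(row["label_hyper"]),
        )
        for col in ("cluster_id_s1", "cluster_id_s2"):
            v = row.get(col)
            if v is not None and not pd.isna(v):
                setattr(inst, col, int(v))
        out.append(inst)
    return out


class PipelineRun:
    """A run directory with its manifest."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        cfg_json = json.dumps(config.to_dict(), sort_keys=True, default=str)
        self.manifest = {
            "config": config.to_dict(),
            "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "version": __version__,
            "stages": {},
        }

    def register(self, stage: str, seed: int | None, artifacts: dict[str, Path]):
        for name, p in artifacts.items():
            if not Path(p).exists() or Path(p).stat().st_size == 0:
                raise GlycloopError(f"stage {stage}: artifact {p} missing or empty")
        self.manifest["stages"][stage] = {
            "seed": seed,
            "artifacts": {k: str(v) for k, v in artifacts.items()},
        }
        self.write_manifest()

    def write_manifest(self):
        (self.out / "run.json").write_text(
            json.dumps(self.manifest, indent=1, default=str))


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage; returns the run directory."""
    run = PipelineRun(config)
    out = run.out

    # -- simulate -----------------------------------------------------------
    seed = stage_seed(config.master_seed, "simulate")
    scenario = config.scenario
    scenario.seed = seed
    records, manifest = generate_cohort(scenario)
    records_csv = out / "records.csv"
    save_patient_records(records, records_csv)
    save_manifest(manifest, out / "manifest.json")
    tir_rows = []
    for rec in records:
        rep = tir_report(rec.trace)
        tir_rows.append({"patient_id": rec.patient_id, **rep.as_dict()})
    pd.DataFrame(tir_rows).to_csv(out / "cohort_tir.csv", index=False)
    run.register("simulate", seed, {
        "records": records_csv, "manifest": out / "manifest.json",
        "cohort_tir": out / "cohort_tir.csv"})

    # -- featurize -----------------------------------------------------------
    instances = build_dataset(records)
    inst_csv = out / "instances.csv"
    instances_to_frame(instances).to_csv(inst_csv, index=False)
    run.register("featurize", None, {"instances": inst_csv})

    # -- cluster (diagnostic store over the full dataset) --------------------
    seed = stage_seed(config.master_seed, "cluster")
    store = build_profile_index(
        instances, seed=seed, k=config.profiling.k,
        som_epochs=config.profiling.som_epochs,
        include_hour=config.profiling.include_hour)
    store_json = out / "store.json"
    store_json.write_text(json.dumps(store.to_dict(), indent=1))
    instances_to_frame(instances).to_csv(inst_csv, index=False)  # now with ids
    run.register("cluster", seed, {"store": store_json})

    # -- train (final models on the full dataset) ----------------------------
    seed = stage_seed(config.master_seed, "train")
    s1 = train_system(instances, "S1", store, seed=seed,
                      search=config.protocol.search,
                      negatives=config.protocol.negatives)
    s2 = train_system(instances, "S2", store, seed=seed + 1,
                      search=config.protocol.search,
                      negatives=config.protocol.negatives)
    summary = {
        sysname: {str(k): rec for k, rec in system.search_records.items()}
        for sysname, system in (("S1", s1), ("S2", s2))
    }
    train_json = out / "training_summary.json"
    train_json.write_text(json.dumps(summary, indent=1, default=str))
    run.register("train", seed, {"training_summary": train_json})

    # -- evaluate (repeated-split protocol) -----------------------------------
    seed = stage_seed(config.master_seed, "evaluate")
    result = run_protocol(
        instances, n_iter=config.protocol.n_iter,
        test_frac=config.protocol.test_frac, seed=seed,
        search=config.protocol.search, som_epochs=config.profiling.som_epochs,
        k=config.profiling.k, negatives=config.protocol.negatives)
    result.table.to_csv(out / "protocol_metrics.csv", index=False)
    result.medians().to_csv(out / "protocol_medians.csv")
    run.register("evaluate", seed, {
        "metrics": out / "protocol_metrics.csv",
        "medians": out / "protocol_medians.csv"})

    # -- explain ---------------------------------------------------------------
    seed = stage_seed(config.master_seed, "explain")
    rng = np.random.default_rng(seed)
    X, _, _ = dataset_to_arrays(instances)
    bg_idx = rng.choice(len(X), size=min(config.explain.n_background, len(X)),
                        replace=False)
    background = X[bg_idx]
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd < 1e-9, 1.0, sd)
    cho_i = FEATURE_NAMES.index("cho_g")
    mib_i = FEATURE_NAMES.index("bolus_u")
    shap_records, lime_records, inter_rows = [], [], []
    pick = rng.choice(len(X), size=min(config.explain.n_instances, len(X)),
                      replace=False)
    for sysname, system in (("S1", s1), ("S2", s2)):
        def fused(M, _system=system):
            return predict_matrix(_system, store, M)[1]
        for idx in pick:
            inter = shapley_interactions(fused, X[idx], background)
            shap_records.append(dict(model=sysname, iteration=0,
                                     phi=inter.attribution.values))
            inter_rows.append(dict(
                model=sysname, instance=int(idx),
                cho_mib_interaction=inter.pair(cho_i, mib_i),
                cho_phi=float(inter.attribution.values[cho_i]),
                mib_phi=float(inter.attribution.values[mib_i])))
            sur = lime_explain(fused, X[idx], training_sd=sd,
                               n_samples=config.explain.lime_samples,
                               seed=int(rng.integers(2**31 - 1)))
            cluster = (instances[idx].cluster_id_s1 if sysname == "S1"
                       else instances[idx].cluster_id_s2)
            lime_records.append(dict(cluster=f"{sysname}:{cluster}", surrogate=sur))
    aggregate_shap(shap_records, FEATURE_NAMES).to_csv(
        out / "shap_means.csv", index=False)
    pd.DataFrame(inter_rows).to_csv(out / "cho_mib_interactions.csv", index=False)
    aggregate_lime_ranks(lime_records, FEATURE_NAMES).to_csv(
        out / "lime_ranks.csv", index=False)
    run.register("explain", seed, {
        "shap_means": out / "shap_means.csv",
        "cho_mib_interactions": out / "cho_mib_interactions.csv",
        "lime_ranks": out / "lime_ranks.csv"})

    # -- closed loop -------------------------------------------------------------
    seed = stage_seed(config.master_seed, "closed_loop")
    cl_scenario = type(scenario)(
        n_patients=config.closed_loop.n_patients,
        n_days=config.closed_loop.n_days, seed=seed)

    def predictor(v):
        return (predict_instance(s1, store, v).fused_vote,
                predict_instance(s2, store, v).fused_vote)

    cl = closed_loop_evaluate(cl_scenario, predictor,
                              config.closed_loop.bolus, seed=seed)
    cl.summary_table().to_csv(out / "closed_loop.csv", index=False)
    run.register("closed_loop", seed, {"closed_loop": out / "closed_loop.csv"})

    logger.info("pipeline complete: %s", out)
    return out


__all__ = ["run_pipeline", "PipelineRun", "instances_to_frame", "frame_to_instances"]
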