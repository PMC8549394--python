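"""End-to-end orchestration: ingest -> featurize -> split -> train -> evaluate -> screen.

Each stage writes its artifacts into the working directory and the next
stage reads them back, so a run is resumable per stage and every
intermediate is inspectable.  All randomness flows from the single seed
in the run configuration; rerunning with an identical configuration
reproduces identical reports.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import ann_model, metrics, reporting, screening, synthetic_data
from .chem_io import read_component_table, read_selectivity_table, write_selectivity_table
from .descriptors import featurize_dataset, il_descriptor_vectors
from .preprocess import BoundingBoxAD, RangeScaler
from .splitting import SplitPlan, build_split_plan

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "cv_fraction": 0.2,
    "opt_fraction": 0.10,
    "grid": "desk",
    "epochs": 100,
    "batch_size": 2000,
    "tasks": ["regression", "bigidac"],
    "synthetic": {},
    "screen": {
        "solute": "SOL1",
        "raffinate": "RAF1",
        "temperature": 298.15,
        "explored_fraction": 0.048,
    },
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _merge(base: Mapping, override: Mapping) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), Mapping):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def resolve_config(config: Mapping | None = None) -> dict:
    return _merge(DEFAULT_CONFIG, config or {})


def _grid_from_config(spec) -> list[ann_model.HyperParams]:
    if spec == "desk":
        return ann_model.desk_grid()
    if spec == "full":
        return ann_model.full_grid()
    return [ann_model.HyperParams(**entry) for entry in spec]


def run_pipeline(config: Mapping | None, workdir, resume: bool = True) -> dict[str, Path]:
    """Run every stage; returns the artifact paths keyed by name."""
    cfg = resolve_config(config)
    work = Path(workdir)
    work.mkdir(parents=True, exist_ok=True)
    with open(work / "resolved_config.json", "w") as fh:
        json.dump(cfg, fh, indent=2, default=str)
    artifacts: dict[str, Path] = {}

    # --- fixtures / inputs ------------------------------------------------
    try:
        if "components" in cfg and "data" in cfg:
            components_path = Path(cfg["components"])
            data_path = Path(cfg["data"])
            combos_path = Path(cfg["combos"]) if "combos" in cfg else None
        else:
            fixture_dir = work / "fixtures"
            if not resume or not (fixture_dir / "selectivity.csv").exists():
                spec = synthetic_data.SyntheticSpec(seed=cfg["seed"], **cfg["synthetic"])
                synthetic_data.write_fixture_dir(
                    spec, fixture_dir, cfg["screen"].get("explored_fraction", 0.048)
                )
            components_path = fixture_dir / "components.csv"
            data_path = fixture_dir / "selectivity.csv"
            combos_path = fixture_dir / "combos.txt"
        artifacts["components"] = components_path
        artifacts["data"] = data_path
    except Exception as exc:
        raise StageError("fixtures", exc) from exc

    # --- ingest -----------------------------------------------------------
    try:
        components = read_component_table(components_path)
        points = read_selectivity_table(data_path, components)
        dataset_path = work / "dataset.csv"
        write_selectivity_table(points, dataset_path)
        artifacts["dataset"] = dataset_path
    except Exception as exc:
        raise StageError("ingest", exc) from exc

    # --- featurize --------------------------------------------------------
    try:
        features, kept, dropped = featurize_dataset(points, components)
        meta = pd.DataFrame(
            {
                "il_code": [p.il.il_code for p in kept],
                "temperature_K": [p.temperature for p in kept],
                "log10_S": [p.log_selectivity for p in kept],
                "big_idac": [p.big_idac for p in kept],
            }
        )
        features.to_csv(work / "features.csv", index=False)
        meta.to_csv(work / "meta.csv", index=False)
        artifacts["features"] = work / "features.csv"
        artifacts["meta"] = work / "meta.csv"
        artifacts["n_dropped"] = dropped
    except Exception as exc:
        raise StageError("featurize", exc) from exc

    # --- split ------------------------------------------------------------
    try:
        plan_path = work / "splitplan.json"
        if resume and plan_path.exists():
            plan = SplitPlan.from_json(plan_path)
        else:
            vectors = il_descriptor_vectors(kept, components)
            plan = build_split_plan(
                vectors,
                meta["il_code"].tolist(),
                cfg["cv_fraction"],
                cfg["seed"],
                cfg["opt_fraction"],
            )
            plan.to_json(plan_path)
        artifacts["splitplan"] = plan_path
    except Exception as exc:
        raise StageError("split", exc) from exc

    # --- train ------------------------------------------------------------
    x = features.to_numpy(dtype=float)
    train_mask = meta["il_code"].isin(plan.training_ils).to_numpy()
    opt_mask = meta["il_code"].isin(plan.optimization_ils).to_numpy()
    train_rows = np.flatnonzero(train_mask)
    pos = {int(g): i for i, g in enumerate(train_rows)}
    folds_local = [
        (np.array([pos[int(g)] for g in fit]), np.array([pos[int(g)] for g in val]))
        for fit, val in plan.folds
    ]
    try:
        scaler = RangeScaler.fit(x[train_rows], features.columns)
        ad = BoundingBoxAD.fit(x[train_rows], features.columns)
        scaler.to_json(work / "scaler.json")
        ad.to_json(work / "ad.json")
        artifacts["scaler"] = work / "scaler.json"
        artifacts["ad"] = work / "ad.json"
        x_train = scaler.transform(x[train_rows])
        x_opt = scaler.transform(x[opt_mask])
        grid = _grid_from_config(cfg["grid"])
        ensembles: dict[str, ann_model.FoldEnsemble] = {}
        for task in cfg["tasks"]:
            tcfg = ann_model.TrainingConfig(
                task=task,
                batch_size=cfg["batch_size"],
                epochs=cfg["epochs"],
                seed=cfg["seed"],
            )
            targets = (
                meta["log10_S"].to_numpy()[train_rows]
                if task == "regression"
                else meta["big_idac"].to_numpy()[train_rows].astype(float)
            )
            opt_targets = (
                meta["log10_S"].to_numpy()[opt_mask]
                if task == "regression"
                else meta["big_idac"].to_numpy()[opt_mask]
            )
            best_hp, ens, report = ann_model.grid_search(
                x_train,
                targets,
                folds_local,
                x_opt,
                opt_targets,
                meta["il_code"].to_numpy()[opt_mask],
                tcfg,
                grid,
                opt_temperatures=meta["temperature_K"].to_numpy()[opt_mask],
            )
            model_dir = work / f"model_{task}"
            ann_model.save_ensemble(ens, model_dir)
            report.to_csv(model_dir / "grid_report.csv", index=False)
            ensembles[task] = ens
            artifacts[f"model_{task}"] = model_dir
    except StageError:
        raise
    except Exception as exc:
        raise StageError("train", exc) from exc

    # --- evaluate ---------------------------------------------------------
    try:
        split_pct = int(round(cfg["cv_fraction"] * 100))
        evaluation: dict[str, Any] = {"split_pct": split_pct}
        opt_in_ad = ad.contains(x[opt_mask])
        evaluation["opt_in_ad_fraction"] = float(np.mean(opt_in_ad)) if opt_in_ad.size else 1.0
        if "regression" in ensembles:
            pred = ensembles["regression"].predict(x_opt)
            m = metrics.RegressionMetrics.evaluate(
                meta["log10_S"].to_numpy()[opt_mask],
                pred,
                meta["temperature_K"].to_numpy()[opt_mask],
                meta["il_code"].to_numpy()[opt_mask],
            )
            reporting.write_report(
                reporting.regression_table({split_pct: m}), work / "report_regression"
            )
            cat = metrics.categorize_regression(meta["log10_S"].to_numpy()[opt_mask], pred)
            evaluation["regression"] = vars(m)
            evaluation["regression_categorical"] = vars(cat)
            artifacts["report_regression"] = work / "report_regression.csv"
        if "bigidac" in ensembles:
            _, flags = ensembles["bigidac"].predict(x_opt)
            m = metrics.ClassificationMetrics.evaluate(
                meta["big_idac"].to_numpy()[opt_mask],
                flags,
                meta["il_code"].to_numpy()[opt_mask],
            )
            reporting.write_report(
                reporting.classification_table({split_pct: m}), work / "report_classification"
            )
            evaluation["classification"] = vars(m)
            artifacts["report_classification"] = work / "report_classification.csv"
        with open(work / "evaluation.json", "w") as fh:
            json.dump(evaluation, fh, indent=2)
        artifacts["evaluation"] = work / "evaluation.json"
    except Exception as exc:
        raise StageError("evaluate", exc) from exc

    # --- screen -----------------------------------------------------------
    if cfg.get("screen") and combos_path is not None and Path(combos_path).exists():
        try:
            matrix = screening.read_matrix(combos_path)
            records = screening.screen(
                matrix.candidates(),
                cfg["screen"]["solute"],
                cfg["screen"]["raffinate"],
                cfg["screen"]["temperature"],
                ensembles.get("regression"),
                ensembles.get("bigidac"),
                scaler,
                ad,
                components,
            )
            screening.records_to_frame(records).to_csv(work / "ranking.csv", index=False)
            artifacts["ranking"] = work / "ranking.csv"
        except Exception as exc:
            raise StageError("screen", exc) from exc

    return artifacts
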