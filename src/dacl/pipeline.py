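"""End-to-end orchestration: generate -> impute -> select -> tune -> train ->
evaluate, with one YAML config, derived per-stage seeds, and JSON artifacts.

Each stage consumes the previous stage's serialized artifact and writes its
own, so stages can also be run individually from the CLI.  Per-stage seeds
are derived from the global seed by hashing the stage name, so toggling one
stage never shifts another stage's randomness.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .colbgan import ColBGaNClassifier, ColBGaNConfig, augment_minority
from .daem import DAEMConfig, DAEMImputer, impute
from .gfs import FeatureSelectionProblem, GFSConfig, select_features
from .metrics import classification_metrics, confusion, roc_auc
from .schema import (ColumnSpec, DataTable, FeatureSchema, encode_table,
                     load_table, stratified_split, write_table)
from .synthetic import CohortConfig, generate_cohort, stroke_schema
from .wdo import IWDConfig, tune_loss_parameter

logger = logging.getLogger("dacl")

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "stage_seed",
           "schema_from_dict", "schema_to_dict", "config_from_yaml",
           "default_config"]

STAGES = ("generate", "impute", "select", "tune", "train", "evaluate")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31: CRC32 mix of seed and name."""
    return zlib.crc32(f"{global_seed}:{stage}".encode()) % (2**31)


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(
        default_factory=lambda: CohortConfig(missing_rate=0.1))
    daem: DAEMConfig = field(default_factory=DAEMConfig)
    # wrapper selection and GAN training sized for minutes-scale runs; raise
    # iterations/epochs for production-quality sweeps
    gfs: GFSConfig = field(
        default_factory=lambda: GFSConfig(population_size=20, iterations=100))
    colbgan: ColBGaNConfig = field(
        default_factory=lambda: ColBGaNConfig(epochs=120))
    wdo: IWDConfig = field(
        default_factory=lambda: IWDConfig(n_drops=5, max_iterations=8))
    delta_grid: tuple[float, ...] = (0.0, 0.01, 0.1, 0.5, 1.0, 2.0)
    tune_epochs: int = 25
    accuracy_weight: float = 0.9
    cv_folds: int = 3
    test_fraction: float = 0.25
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    global_seed: int = 0
    output_dir: str = "dacl_output"
    input_csv: str | None = None   # skip generation and load this instead

    def enabled(self, stage: str) -> bool:
        return bool(self.stages.get(stage, True))


@dataclass
class PipelineReport:
    artifacts: dict = field(default_factory=dict)
    selected_features: list[str] | None = None
    tuned_delta: float | None = None
    metrics: dict | None = None
    seeds: dict = field(default_factory=dict)
    runtime_s: dict = field(default_factory=dict)
    stage_status: dict = field(default_factory=dict)
    ground_truth: dict | None = None

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2, sort_keys=True))


def schema_from_dict(d: dict) -> FeatureSchema:
    cols = tuple(ColumnSpec(c["name"], c["kind"], tuple(c.get("levels", ())))
                 for c in d["columns"])
    return FeatureSchema(cols, d["label_column"], d.get("id_column"))


def schema_to_dict(schema: FeatureSchema) -> dict:
    return {
        "columns": [{"name": c.name, "kind": c.kind,
                     **({"levels": list(c.levels)} if c.levels else {})}
                    for c in schema.columns],
        "label_column": schema.label_column,
        "id_column": schema.id_column,
    }


def config_from_yaml(path_or_dict) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file or an already-parsed dict."""
    if isinstance(path_or_dict, dict):
        raw = path_or_dict
    else:
        raw = yaml.safe_load(Path(path_or_dict).read_text()) or {}
    schema = schema_from_dict(raw["schema"]) if "schema" in raw else stroke_schema()
    cohort_kwargs = dict(raw.get("cohort", {}))
    for key in ("informative_features", "coefficients"):
        if key in cohort_kwargs:
            cohort_kwargs[key] = tuple(cohort_kwargs[key])
    cohort = CohortConfig(schema=schema, **cohort_kwargs)
    kwargs = dict(
        cohort=cohort,
        daem=DAEMConfig(**raw.get("daem", {})),
        gfs=GFSConfig(**raw.get("gfs", {})),
        colbgan=ColBGaNConfig(**{k: tuple(v) if isinstance(v, list) else v
                                 for k, v in raw.get("colbgan", {}).items()}),
        wdo=IWDConfig(**raw.get("wdo", {})),
    )
    for key in ("delta_grid", "tune_epochs", "accuracy_weight", "cv_folds",
                "test_fraction", "stages", "global_seed", "output_dir", "input_csv"):
        if key in raw:
            val = raw[key]
            kwargs[key] = tuple(val) if key == "delta_grid" else val
    return PipelineConfig(**kwargs)


def default_config(**overrides) -> PipelineConfig:
    cfg = PipelineConfig()
    return dataclasses.replace(cfg, **overrides) if overrides else cfg


def _select_columns(enc_matrix: np.ndarray, encoding_map: dict,
                    feature_names: list[str]) -> np.ndarray:
    idx = [i for name in feature_names for i in encoding_map[name]["indices"]]
    return enc_matrix[:, idx]


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the enabled stages in order and return the report.

    A stage failure marks the stage failed in the report and skips everything
    downstream.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = PipelineReport()
    report.seeds = {s: stage_seed(config.global_seed, s) for s in STAGES}

    state: dict = {}
    for stage in STAGES:
        if not config.enabled(stage):
            report.stage_status[stage] = "disabled"
            continue
        t0 = time.perf_counter()
        try:
            _STAGE_FUNCS[stage](config, state, report, out)
            report.stage_status[stage] = "ok"
        except Exception as exc:  # stage isolation: fail, skip downstream
            logger.error("stage %s failed: %s", stage, exc)
            report.stage_status[stage] = f"failed: {exc}"
            report.runtime_s[stage] = round(time.perf_counter() - t0, 3)
            for rest in STAGES[STAGES.index(stage) + 1:]:
                if config.enabled(rest):
                    report.stage_status[rest] = "skipped"
            break
        report.runtime_s[stage] = round(time.perf_counter() - t0, 3)
    report.write(out / "report.json")
    return report


def _stage_generate(config: PipelineConfig, state: dict,
                    report: PipelineReport, out: Path) -> None:
    seed = stage_seed(config.global_seed, "generate")
    if config.input_csv:
        table = load_table(config.input_csv, config.cohort.schema)
        truth = None
    else:
        cohort = dataclasses.replace(config.cohort, seed=seed)
        table, truth = generate_cohort(cohort)
        report.ground_truth = {
            "informative_features": list(truth.informative_features),
            "coefficients": list(truth.coefficients),
            "intercept": truth.intercept,
            "achieved_prevalence": truth.achieved_prevalence,
            "bayes_accuracy_estimate": truth.bayes_accuracy_estimate,
        }
        (out / "ground_truth.json").write_text(json.dumps(report.ground_truth, indent=2))
    path = out / "cohort.csv"
    write_table(table, path)
    report.artifacts["cohort"] = str(path)
    state["table"] = table
    logger.info("generate: %d rows, %d masked cells", table.n_rows,
                int(table.missing_mask.sum()))


def _stage_impute(config: PipelineConfig, state: dict,
                  report: PipelineReport, out: Path) -> None:
    table: DataTable = state["table"]
    if table.missing_mask.any():
        daem = dataclasses.replace(config.daem,
                                   seed=stage_seed(config.global_seed, "impute"))
        results = DAEMImputer.from_table(table, daem).fit()
        table = impute(table, results)
        logger.info("impute: final loss %.5f", results.loss_history[-1])
    path = out / "imputed.csv"
    write_table(table, path)
    report.artifacts["imputed"] = str(path)
    state["table"] = table


def _split(config: PipelineConfig, state: dict) -> None:
    if "train_idx" in state:
        return
    table: DataTable = state["table"]
    tr, te = stratified_split(table, config.test_fraction,
                              stage_seed(config.global_seed, "split"))
    state["train_idx"], state["test_idx"] = tr, te
    state["enc_all"] = encode_table(table)


def _stage_select(config: PipelineConfig, state: dict,
                  report: PipelineReport, out: Path) -> None:
    _split(config, state)
    enc = state["enc_all"]
    tr = state["train_idx"]
    seed = stage_seed(config.global_seed, "select")
    problem = FeatureSelectionProblem(
        X=enc.matrix[tr], y=np.asarray(enc.label_vector, dtype=int)[tr],
        accuracy_weight=config.accuracy_weight, cv_folds=config.cv_folds,
        cv_seed=seed % 10_000)
    gfs = dataclasses.replace(config.gfs, seed=seed)
    mask, fitness, _ = select_features(problem, gfs)
    # map encoded-column mask back to source feature names
    names = []
    for name, rec in enc.encoding_map.items():
        if any(mask[i] for i in rec["indices"]):
            names.append(name)
    report.selected_features = names
    path = out / "selected_features.json"
    path.write_text(json.dumps({"features": names, "fitness": fitness}, indent=2))
    report.artifacts["selected_features"] = str(path)
    state["feature_names"] = names
    logger.info("select: %d features %s", len(names), names)


def _feature_matrix(config: PipelineConfig, state: dict, rows: np.ndarray) -> np.ndarray:
    enc = state["enc_all"]
    names = state.get("feature_names")
    if names is None:  # selection disabled: use every encoded feature column
        return enc.matrix[rows]
    return _select_columns(enc.matrix, enc.encoding_map, names)[rows]


def _encoded_subset(config: PipelineConfig, state: dict, rows: np.ndarray):
    from .schema import EncodedMatrix
    enc = state["enc_all"]
    X = _feature_matrix(config, state, rows)
    y = np.asarray(enc.label_vector, dtype=int)[rows]
    emap = {"all": {"kind": "numeric", "indices": list(range(X.shape[1])),
                    "min": 0.0, "max": 1.0}}
    sub = EncodedMatrix(X, np.zeros_like(X, dtype=bool), emap, y)
    # mark every column continuous only if it came from a numeric source;
    # simplest faithful choice: treat all as continuous for GAN geometry
    return sub


def _stage_tune(config: PipelineConfig, state: dict,
                report: PipelineReport, out: Path) -> None:
    _split(config, state)
    seed = stage_seed(config.global_seed, "tune")
    tr = state["train_idx"]
    sub = _encoded_subset(config, state, tr)
    # short-run validation: hold out a quarter of the training rows
    rng = np.random.default_rng(seed)
    n = len(sub.label_vector)
    order = rng.permutation(n)
    val, fit_idx = order[: n // 4], order[n // 4:]

    def evaluate(cand: dict) -> float:
        from .schema import EncodedMatrix
        cfg = dataclasses.replace(
            config.colbgan, delta=float(cand["delta"]),
            epochs=config.tune_epochs, seed=seed)
        enc_fit = EncodedMatrix(sub.matrix[fit_idx],
                                np.zeros_like(sub.matrix[fit_idx], dtype=bool),
                                sub.encoding_map, sub.label_vector[fit_idx])
        res = ColBGaNClassifier(enc_fit, cfg).fit()
        _, probs = res.predict(sub.matrix[val])
        yv = sub.label_vector[val]
        p = np.clip(probs[np.arange(len(yv)), yv], 1e-12, None)
        return float(np.mean(np.log(p)))  # maximize validation log-likelihood

    wdo = dataclasses.replace(config.wdo, seed=seed)
    best, score = tune_loss_parameter({"delta": list(config.delta_grid)},
                                      evaluate, wdo)
    report.tuned_delta = float(best["delta"])
    path = out / "tuned.json"
    path.write_text(json.dumps({"delta": report.tuned_delta,
                                "validation_score": score}, indent=2))
    report.artifacts["tuned"] = str(path)
    logger.info("tune: delta* = %s", report.tuned_delta)


def _stage_train(config: PipelineConfig, state: dict,
                 report: PipelineReport, out: Path) -> None:
    _split(config, state)
    seed = stage_seed(config.global_seed, "train")
    tr = state["train_idx"]
    sub = _encoded_subset(config, state, tr)
    delta = report.tuned_delta if report.tuned_delta is not None \
        else config.colbgan.delta
    cfg = dataclasses.replace(config.colbgan, delta=float(delta), seed=seed)
    results = ColBGaNClassifier(sub, cfg).fit()
    if cfg.augment_to_balance:
        augmented, flags = augment_minority(sub, results.model, seed=seed)
        if flags.any():
            from .colbgan import refit_classifier
            refit_classifier(results.model, augmented,
                             epochs=max(10, cfg.epochs // 4),
                             lr=cfg.lr_clf, seed=seed)
            logger.info("train: appended %d synthetic minority rows",
                        int(flags.sum()))
    state["results"] = results
    path = out / "training_log.json"
    path.write_text(json.dumps({
        "discriminator_value": results.log.discriminator_value,
        "generator_loss": results.log.generator_loss,
        "classifier_loss": results.log.classifier_loss,
    }, indent=2))
    report.artifacts["training_log"] = str(path)


def _stage_evaluate(config: PipelineConfig, state: dict,
                    report: PipelineReport, out: Path) -> None:
    _split(config, state)
    te = state["test_idx"]
    results = state["results"]
    X_test = _feature_matrix(config, state, te)
    y_test = np.asarray(state["enc_all"].label_vector, dtype=int)[te]
    y_pred, probs = results.predict(X_test)
    rep = classification_metrics(confusion(y_test, y_pred))
    try:
        _, auc = roc_auc(y_test, probs[:, 1])
        rep.auc = auc
    except ValueError:
        rep.auc = None
    report.metrics = rep.as_dict()
    path = out / "metrics.json"
    path.write_text(json.dumps(report.metrics, indent=2, sort_keys=True))
    report.artifacts["metrics"] = str(path)
    logger.info("evaluate: accuracy %.4f", rep.accuracy)


_STAGE_FUNCS = {
    "generate": _stage_generate,
    "impute": _stage_impute,
    "select": _stage_select,
    "tune": _stage_tune,
    "train": _stage_train,
    "evaluate": _stage_evaluate,
}
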