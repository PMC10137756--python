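"""End-to-end experimental protocol: stratified CV + external validation.

The protocol mirrors a two-institution study: the training cohort is split
by event-stratified k-fold sampling; each fold's best model (lowest
full-risk-set validation loss) is evaluated on the fold's held-out split
and on an external cohort that never touches preprocessing fitting,
training or model selection.  External metrics are the average of the k
per-fold-model evaluations.  Feature groups follow treatment stage:
pretreatment covariates only, or pretreatment plus the on-treatment
Deauville score.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import SurvivalDataset, load_dataset, stratified_kfold
from .embedding import EncoderConfig
from .metrics import EvaluationReport
from .model import (LinearCoxModel, SurvivalResults, TrainingConfig, TTSurvModel)
from .schema import FeatureSchema, ON_TREATMENT, PRETREATMENT

__all__ = ["ExperimentConfig", "run_cross_validation", "compare_stages",
           "predict_patients"]

_MODELS = {"ttsurv": TTSurvModel, "linear": LinearCoxModel}


@dataclass(frozen=True)
class ExperimentConfig:
    """Paths, feature stage, folds and hyperparameters for one run."""

    train_cohort: str | None = None
    external_cohort: str | None = None
    schema_path: str | None = None
    stage: str = PRETREATMENT
    k: int = 5
    seed: int = 0
    model: str = "ttsurv"
    hidden: int = 32
    encoder: dict = field(default_factory=dict)
    training: dict = field(default_factory=dict)
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be at least 2")
        if self.stage not in (PRETREATMENT, ON_TREATMENT):
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.model not in _MODELS:
            raise ValueError(f"unknown model {self.model!r}")

    def training_config(self, seed: int | None = None) -> TrainingConfig:
        kw = dict(self.training)
        kw["seed"] = self.seed if seed is None else seed
        return TrainingConfig(**kw)

    def encoder_config(self) -> EncoderConfig | None:
        return EncoderConfig(**self.encoder) if self.encoder else None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _load_cohorts(config: ExperimentConfig,
                  train_data: SurvivalDataset | None,
                  external_data: SurvivalDataset | None):
    if train_data is None:
        schema = FeatureSchema.from_yaml(config.schema_path)
        train_data = load_dataset(config.train_cohort, schema)
        if config.external_cohort:
            external_data = load_dataset(config.external_cohort, schema)
    return train_data, external_data


def run_cross_validation(config: ExperimentConfig,
                         train_data: SurvivalDataset | None = None,
                         external_data: SurvivalDataset | None = None) -> dict:
    """Stratified k-fold CV plus external evaluation of each fold's model.

    Returns a dict with the tidy per-fold/mean ``report`` dataframe, the
    per-fold :class:`SurvivalResults`, and the fold index arrays.  Fully
    deterministic given the config (per-fold training seeds derive from
    ``config.seed``).
    """
    train_data, external_data = _load_cohorts(config, train_data, external_data)
    # fold assignment uses the full cohort before stage restriction: the
    # event indicator is stage-independent, so both arms share folds
    folds = stratified_kfold(train_data, config.k, config.seed)
    staged = train_data.restrict_to_stage(config.stage)
    external = (None if external_data is None
                else external_data.restrict_to_stage(config.stage))
    model_cls = _MODELS[config.model]
    rows = []
    results: list[SurvivalResults] = []
    for f, (tr_idx, va_idx) in enumerate(folds):
        raw_tr, raw_va = staged.subset(tr_idx), staged.subset(va_idx)
        kwargs = ({"encoder": config.encoder_config(), "hidden": config.hidden}
                  if config.model == "ttsurv" else {})
        model = model_cls(raw_tr, **kwargs)
        res = model.fit(config.training_config(seed=config.seed + f),
                        valid=raw_va)
        results.append(res)
        rows.append({"fold": f, "cohort": "internal",
                     "c_index": res.c_index(raw_va), "mae_days": res.mae(raw_va),
                     "n_events": raw_va.n_events})
        if external is not None:
            rows.append({"fold": f, "cohort": "external",
                         "c_index": res.c_index(external),
                         "mae_days": res.mae(external),
                         "n_events": external.n_events})
    report = pd.DataFrame(rows)
    means = (report.groupby("cohort", as_index=False)[["c_index", "mae_days"]]
             .mean())
    means.insert(0, "fold", "mean")
    means["n_events"] = np.nan
    report = pd.concat([report, means], ignore_index=True)
    evaluation = {}
    for cohort in ("internal", "external"):
        sub = report[(report["cohort"] == cohort) & (report["fold"] != "mean")]
        if len(sub):
            evaluation[cohort] = EvaluationReport(
                fold_c_index=sub["c_index"].tolist(),
                fold_mae_days=sub["mae_days"].tolist(),
                fold_n_events=sub["n_events"].astype(int).tolist())
    out = {"report": report, "results": results, "folds": folds,
           "config": config, "evaluation": evaluation}
    if config.out_dir:
        _write_run(out, train_data)
    return out


def _write_run(out: dict, train_data: SurvivalDataset) -> None:
    config: ExperimentConfig = out["config"]
    d = Path(config.out_dir)
    d.mkdir(parents=True, exist_ok=True)
    out["report"].to_csv(d / "report.csv", index=False)
    assign = pd.DataFrame({
        "id": train_data.ids,
        "fold": _fold_of(out["folds"], train_data.n),
    })
    assign.to_csv(d / "folds.csv", index=False)
    from . import __version__
    manifest = {k: getattr(config, k) for k in config.__dataclass_fields__}
    manifest["ttsurv_version"] = __version__
    (d / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    for f, res in enumerate(out["results"]):
        res.save(d / f"model_fold{f}.npz")


def _fold_of(folds, n: int) -> np.ndarray:
    assign = np.full(n, -1)
    for f, (_, va) in enumerate(folds):
        assign[va] = f
    return assign


def compare_stages(config: ExperimentConfig,
                   train_data: SurvivalDataset | None = None,
                   external_data: SurvivalDataset | None = None) -> dict:
    """Run the CV protocol for both feature stages on identical folds.

    Emits a paired report with pretreatment and on-treatment C-index / MAE
    side by side and their differences (on-treatment minus pretreatment).
    """
    train_data, external_data = _load_cohorts(config, train_data, external_data)
    arms = {}
    for stage in (PRETREATMENT, ON_TREATMENT):
        cfg = replace(config, stage=stage,
                      out_dir=(str(Path(config.out_dir) / stage.replace("-", "_"))
                               if config.out_dir else None))
        arms[stage] = run_cross_validation(cfg, train_data, external_data)
    pre, on = arms[PRETREATMENT]["report"], arms[ON_TREATMENT]["report"]
    paired = pre.merge(on, on=["fold", "cohort"],
                       suffixes=("_pre", "_on"))
    paired["c_index_diff"] = paired["c_index_on"] - paired["c_index_pre"]
    paired["mae_days_diff"] = paired["mae_days_on"] - paired["mae_days_pre"]
    paired = paired.drop(columns=[c for c in paired.columns
                                  if c.startswith("n_events")])
    if config.out_dir:
        Path(config.out_dir).mkdir(parents=True, exist_ok=True)
        paired.to_csv(Path(config.out_dir) / "stage_comparison.csv", index=False)
    return {"paired": paired, "pretreatment": arms[PRETREATMENT],
            "on_treatment": arms[ON_TREATMENT]}


def predict_patients(model_path: str | Path,
                     cohort: SurvivalDataset | str | Path,
                     schema: FeatureSchema | None = None,
                     out_dir: str | Path | None = None) -> dict:
    """Per-patient median life table + survival curves from saved artifacts."""
    res = SurvivalResults.load(model_path)
    if not isinstance(cohort, SurvivalDataset):
        cohort = load_dataset(cohort, schema or res.model.schema)
    cohort = cohort.restrict_to_stage(
        ON_TREATMENT if any(f.stage == ON_TREATMENT
                            for f in res.model.schema.features)
        else PRETREATMENT)
    if cohort.schema.to_dict() != res.model.schema.to_dict():
        raise ValueError("cohort schema does not match the saved model")
    days, crossed = res.predict_median(cohort)
    table = pd.DataFrame({"id": cohort.ids, "median_life_days": days,
                          "crossed": crossed})
    curves = res.predict_survival(cohort)
    if out_dir is not None:
        d = Path(out_dir)
        d.mkdir(parents=True, exist_ok=True)
        table.to_csv(d / "predictions.csv", index=False)
        for pid, curve in zip(cohort.ids, curves):
            curve.to_frame().to_csv(d / f"curve_{pid}.csv", index=False)
    return {"table": table, "curves": curves}
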