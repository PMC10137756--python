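"""Survival dataset container, delimited-text I/O, preprocessing, folds."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import FeatureSchema

__all__ = [
    "SurvivalDataset",
    "load_dataset",
    "write_dataset",
    "dataset_from_dataframe",
    "Preprocessor",
    "fit_preprocessor",
    "apply_preprocessor",
    "stratified_kfold",
]


@dataclass
class SurvivalDataset:
    """Covariate matrices + observed time (days) + event indicator.

    ``x_cont`` is n x p_cont real; ``x_cat`` is n x N integer level codes in
    schema level order; ``t`` strictly positive durations; ``d`` in {0, 1}
    (1 = event observed, 0 = censored).
    """

    schema: FeatureSchema
    x_cont: np.ndarray
    x_cat: np.ndarray
    t: np.ndarray
    d: np.ndarray
    ids: np.ndarray
    true_risk: np.ndarray | None = None  # simulator oracle only

    def __post_init__(self) -> None:
        self.x_cont = np.asarray(self.x_cont, dtype=np.float64).reshape(len(self.t), -1)
        self.x_cat = np.asarray(self.x_cat, dtype=np.int64).reshape(len(self.t), -1)
        self.t = np.asarray(self.t, dtype=np.float64)
        self.d = np.asarray(self.d, dtype=np.int64)
        self.ids = np.asarray(self.ids)
        if np.any(self.t <= 0):
            raise ValueError("all durations must be strictly positive")
        if not np.isin(self.d, (0, 1)).all():
            raise ValueError("event indicator must be 0 or 1")
        for i, c in enumerate(self.schema.cardinalities):
            col = self.x_cat[:, i]
            if col.size and (col.min() < 0 or col.max() >= c):
                name = self.schema.categorical[i].name
                raise ValueError(f"categorical codes out of range for {name!r}")

    @property
    def n(self) -> int:
        return len(self.t)

    @property
    def n_events(self) -> int:
        return int(self.d.sum())

    def subset(self, idx: np.ndarray) -> "SurvivalDataset":
        idx = np.asarray(idx)
        return SurvivalDataset(
            self.schema, self.x_cont[idx], self.x_cat[idx], self.t[idx],
            self.d[idx], self.ids[idx],
            None if self.true_risk is None else self.true_risk[idx])

    def restrict_to_stage(self, stage: str) -> "SurvivalDataset":
        sub = self.schema.restrict_to_stage(stage)
        keep_cont = [i for i, f in enumerate(self.schema.continuous) if f.name in
                     {g.name for g in sub.continuous}]
        keep_cat = [i for i, f in enumerate(self.schema.categorical) if f.name in
                    {g.name for g in sub.categorical}]
        return SurvivalDataset(sub, self.x_cont[:, keep_cont], self.x_cat[:, keep_cat],
                               self.t, self.d, self.ids, self.true_risk)

    def to_dataframe(self) -> pd.DataFrame:
        cols: dict[str, object] = {"id": self.ids}
        for j, f in enumerate(self.schema.continuous):
            cols[f.name] = self.x_cont[:, j]
        for j, f in enumerate(self.schema.categorical):
            cols[f.name] = [f.levels[c] for c in self.x_cat[:, j]]
        cols[self.schema.duration_column] = self.t
        cols[self.schema.event_column] = self.d
        if self.true_risk is not None:
            cols["true_risk"] = self.true_risk
        return pd.DataFrame(cols)


def dataset_from_dataframe(df: pd.DataFrame, schema: FeatureSchema,
                           with_true_risk: bool = False) -> SurvivalDataset:
    """Build a :class:`SurvivalDataset` from a dataframe, validating labels."""
    required = ([f.name for f in schema.features]
                + [schema.duration_column, schema.event_column])
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    for col in required:
        if df[col].isna().any():
            row = int(df.index[df[col].isna()][0])
            raise ValueError(f"missing value in column {col!r} at row {row}")

    n = len(df)
    ids = (df["id"].to_numpy() if "id" in df.columns
           else np.array([f"P{i:05d}" for i in range(n)]))

    t = pd.to_numeric(df[schema.duration_column], errors="raise").to_numpy(float)
    if np.any(~np.isfinite(t)) or np.any(t <= 0):
        row = int(np.flatnonzero(~np.isfinite(t) | (t <= 0))[0])
        raise ValueError(
            f"non-positive duration at row {row}: {t[row]!r} "
            f"(column {schema.duration_column!r})")
    d = pd.to_numeric(df[schema.event_column], errors="raise").to_numpy()
    if not np.isin(d, (0, 1)).all():
        row = int(np.flatnonzero(~np.isin(d, (0, 1)))[0])
        raise ValueError(f"event value outside {{0,1}} at row {row}: {d[row]!r}")

    x_cont = np.column_stack(
        [pd.to_numeric(df[f.name], errors="raise").to_numpy(float)
         for f in schema.continuous]) if schema.continuous else np.empty((n, 0))

    cat_cols = []
    for f in schema.categorical:
        codes = np.empty(n, dtype=np.int64)
        for i, label in enumerate(df[f.name].astype(str)):
            try:
                codes[i] = f.code_of(label)
            except KeyError:
                raise ValueError(
                    f"unknown level {label!r} for feature {f.name!r} at row {i}"
                ) from None
        cat_cols.append(codes)
    x_cat = np.column_stack(cat_cols) if cat_cols else np.empty((n, 0), dtype=np.int64)

    true_risk = None
    if with_true_risk and "true_risk" in df.columns:
        true_risk = df["true_risk"].to_numpy(float)
    return SurvivalDataset(schema, x_cont, x_cat, t, d.astype(np.int64), ids, true_risk)


def load_dataset(path: str | Path, schema: FeatureSchema,
                 with_true_risk: bool = False) -> SurvivalDataset:
    """Read a comma-separated file with header into a :class:`SurvivalDataset`.

    Categorical labels are mapped to codes via the schema's level order; an
    unknown label, a non-positive duration, an event value outside {0, 1} or
    any missing value is an error (no silent imputation of clinical data).
    """
    df = pd.read_csv(path, dtype=str).replace("", np.nan)
    return dataset_from_dataframe(df, schema, with_true_risk=with_true_risk)


def write_dataset(data: SurvivalDataset, path: str | Path) -> None:
    data.to_dataframe().to_csv(path, index=False)


@dataclass
class Preprocessor:
    """Per-continuous-feature standardisation fitted on training data only.

    Location is the training mean, scale the population (uncorrected)
    standard deviation; categorical codes pass through untouched.
    """

    schema: FeatureSchema
    location: np.ndarray
    scale: np.ndarray


def fit_preprocessor(train: SurvivalDataset, schema: FeatureSchema) -> Preprocessor:
    if train.schema.to_dict() != schema.to_dict():
        raise ValueError("dataset schema does not match supplied schema")
    if train.n < 2:
        raise ValueError("need at least 2 rows to fit the preprocessor")
    loc = train.x_cont.mean(axis=0) if train.x_cont.size else np.empty(0)
    scale = train.x_cont.std(axis=0, ddof=0) if train.x_cont.size else np.empty(0)
    for j, s in enumerate(scale):
        if s <= 0:
            raise ValueError(
                f"continuous feature {schema.continuous[j].name!r} is constant "
                "on the training data")
    return Preprocessor(schema, np.asarray(loc), np.asarray(scale))


def apply_preprocessor(pre: Preprocessor, data: SurvivalDataset) -> SurvivalDataset:
    if data.schema.to_dict() != pre.schema.to_dict():
        raise ValueError("preprocessor schema does not match dataset schema")
    x = data.x_cont
    if x.size:
        x = (x - pre.location) / pre.scale
    return SurvivalDataset(data.schema, x, data.x_cat.copy(), data.t, data.d,
                           data.ids, data.true_risk)


def stratified_kfold(data: SurvivalDataset, k: int,
                     seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Event-stratified k-fold split: deterministic given seed.

    Both strata (events, censored) are shuffled and dealt round-robin into k
    folds, so per-fold event counts differ by at most one.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for value in (1, 0):
        stratum = np.flatnonzero(data.d == value)
        if len(stratum) < k:
            kind = "event" if value else "censored"
            raise ValueError(
                f"{kind} stratum has {len(stratum)} members; needs >= k={k}")
        rng.shuffle(stratum)
        for pos, idx in enumerate(stratum):
            folds[pos % k].append(int(idx))
    out = []
    all_idx = np.arange(data.n)
    for f in folds:
        valid = np.sort(np.array(f, dtype=np.intp))
        train = np.setdiff1d(all_idx, valid)
        out.append((train, valid))
    return out
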