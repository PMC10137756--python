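"""Feature schema for tabular censored survival data.

The schema is authoritative: it declares each covariate's role (continuous
vs categorical), the ordered category levels, and at which treatment stage
the covariate becomes available (pretreatment vs on-treatment, e.g. the
Deauville score from interim PET is on-treatment only).  No type inference
is done from the data file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["Feature", "FeatureSchema", "PRETREATMENT", "ON_TREATMENT"]

PRETREATMENT = "pretreatment"
ON_TREATMENT = "on-treatment"
_ROLES = ("continuous", "categorical")
_STAGES = (PRETREATMENT, ON_TREATMENT)


@dataclass(frozen=True)
class Feature:
    """One covariate: name, role, ordered levels (categorical only), stage."""

    name: str
    role: str
    levels: tuple[str, ...] = ()
    stage: str = PRETREATMENT

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValueError(f"feature {self.name!r}: unknown role {self.role!r}")
        if self.stage not in _STAGES:
            raise ValueError(f"feature {self.name!r}: unknown stage {self.stage!r}")
        if self.role == "categorical":
            if not self.levels:
                raise ValueError(f"categorical feature {self.name!r} has no levels")
            if len(set(self.levels)) != len(self.levels):
                raise ValueError(f"feature {self.name!r} has duplicate levels")
        elif self.levels:
            raise ValueError(f"continuous feature {self.name!r} must not list levels")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def code_of(self, label: str) -> int:
        try:
            return self.levels.index(str(label))
        except ValueError:
            raise KeyError(label) from None


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered covariate declarations plus duration/event column names."""

    features: tuple[Feature, ...]
    duration_column: str = "duration_days"
    event_column: str = "event"

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in schema")
        for col in (self.duration_column, self.event_column):
            if col in names:
                raise ValueError(f"{col!r} cannot be both outcome and feature")
        if self.duration_column == self.event_column:
            raise ValueError("duration and event columns must differ")
        if not any(f.role == "categorical" for f in self.features):
            raise ValueError("schema needs at least one categorical feature")

    # -- views ----------------------------------------------------------------
    @property
    def continuous(self) -> tuple[Feature, ...]:
        return tuple(f for f in self.features if f.role == "continuous")

    @property
    def categorical(self) -> tuple[Feature, ...]:
        return tuple(f for f in self.features if f.role == "categorical")

    @property
    def cardinalities(self) -> tuple[int, ...]:
        return tuple(f.n_levels for f in self.categorical)

    def __getitem__(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def restrict_to_stage(self, stage: str) -> "FeatureSchema":
        """Keep pretreatment features, plus on-treatment ones if requested.

        The on-treatment view is a superset of the pretreatment view: on
        treatment, everything known before treatment is still known.
        """
        if stage not in _STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        if stage == ON_TREATMENT:
            kept = self.features
        else:
            kept = tuple(f for f in self.features if f.stage == PRETREATMENT)
        return FeatureSchema(kept, self.duration_column, self.event_column)

    # -- serialisation ---------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "duration_column": self.duration_column,
            "event_column": self.event_column,
            "features": [
                {
                    "name": f.name,
                    "role": f.role,
                    "stage": f.stage,
                    **({"levels": list(f.levels)} if f.role == "categorical" else {}),
                }
                for f in self.features
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSchema":
        feats = tuple(
            Feature(
                name=item["name"],
                role=item["role"],
                levels=tuple(str(x) for x in item.get("levels", ())),
                stage=item.get("stage", PRETREATMENT),
            )
            for item in d["features"]
        )
        return cls(feats, d["duration_column"], d["event_column"])

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FeatureSchema":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
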