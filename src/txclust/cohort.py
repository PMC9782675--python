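"""Cohort containers: variable schema, cohort table, and distance matrix.

A cohort is one row per transplant recipient.  Every analysis variable is
declared in a schema as continuous, binary, categorical, or ordinal; columns
outside the schema (subject IDs, inclusion-criterion fields such as KDPI,
outcome columns) ride along in the table but never enter the clustering.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

VARIABLE_KINDS = ("continuous", "binary", "categorical", "ordinal")

#: analysis variables must stay below this missing fraction after inclusion
#: filtering; violations warn rather than fail.
MISSING_FRACTION_WARN = 0.05

ID_COLUMN = "subject_id"


class CohortError(ValueError):
    """Raised when a cohort, schema, or configuration is invalid."""


@dataclass
class VariableSpec:
    """Declaration of one analysis variable.

    ``levels`` is required for binary/categorical/ordinal variables; for
    ordinal variables the order of ``levels`` is the ordinal order.  The
    generative fields (``means``/``sds`` for continuous, ``probs`` as a
    per-cluster list of level-probability vectors otherwise) are only used
    by the synthetic-registry generator and may be ``None`` for schemas
    describing observed data.
    """

    name: str
    kind: str
    levels: list | None = None
    means: list[float] | None = None
    sds: list[float] | None = None
    probs: list[list[float]] | None = None

    def __post_init__(self) -> None:
        if self.kind not in VARIABLE_KINDS:
            raise CohortError(
                f"variable {self.name!r}: kind must be one of {VARIABLE_KINDS}, "
                f"got {self.kind!r}"
            )
        if self.kind != "continuous" and not self.levels:
            raise CohortError(f"variable {self.name!r}: {self.kind} requires levels")
        if self.kind == "binary" and self.levels is not None and len(self.levels) != 2:
            raise CohortError(f"variable {self.name!r}: binary requires 2 levels")

    def validate_generative(self, n_clusters: int) -> None:
        """Check per-cluster generative parameters against ``n_clusters``."""
        if self.kind == "continuous":
            if self.means is None or self.sds is None:
                raise CohortError(f"variable {self.name!r}: means/sds required")
            if len(self.means) != n_clusters or len(self.sds) != n_clusters:
                raise CohortError(
                    f"variable {self.name!r}: need {n_clusters} per-cluster means/sds"
                )
            if any(s <= 0 for s in self.sds):
                raise CohortError(f"variable {self.name!r}: sd must be > 0")
        else:
            if self.probs is None or len(self.probs) != n_clusters:
                raise CohortError(
                    f"variable {self.name!r}: need {n_clusters} probability vectors"
                )
            for c, p in enumerate(self.probs):
                p = np.asarray(p, dtype=float)
                if len(p) != len(self.levels) or (p < 0).any():
                    raise CohortError(
                        f"variable {self.name!r}: cluster {c + 1} probabilities "
                        f"must be non-negative with one entry per level"
                    )
                if abs(p.sum() - 1.0) > 1e-9:
                    raise CohortError(
                        f"variable {self.name!r}: cluster {c + 1} probabilities "
                        f"sum to {p.sum():.12g}, not 1"
                    )


Schema = dict[str, VariableSpec]


def schema_to_json(schema: Schema, path: str | Path) -> None:
    payload = {
        name: {"kind": spec.kind, "levels": spec.levels}
        for name, spec in schema.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=str))


def schema_from_json(path: str | Path) -> Schema:
    payload = json.loads(Path(path).read_text())
    return {
        name: VariableSpec(name=name, kind=d["kind"], levels=d.get("levels"))
        for name, d in payload.items()
    }


@dataclass
class CohortTable:
    """Subjects x variables table with schema and missingness mask.

    ``data`` holds a ``subject_id`` column, every schema column, and any
    auxiliary columns.  ``missing_mask`` is boolean over the schema columns
    only and records which cells were originally missing — it survives
    imputation so imputed cells remain auditable.
    """

    data: pd.DataFrame
    schema: Schema
    missing_mask: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.missing_mask is None:
            self.missing_mask = self.data[self.variables].isna()
        self.validate()

    @property
    def variables(self) -> list[str]:
        return list(self.schema)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def subject_ids(self) -> pd.Series:
        return self.data[ID_COLUMN]

    def validate(self) -> None:
        if ID_COLUMN not in self.data.columns:
            raise CohortError(f"cohort lacks {ID_COLUMN!r} column")
        if self.data[ID_COLUMN].duplicated().any():
            raise CohortError("subject_id values are not unique")
        for name, spec in self.schema.items():
            if name not in self.data.columns:
                raise CohortError(f"schema variable {name!r} missing from table")
            if spec.kind != "continuous":
                observed = self.data[name].dropna()
                bad = ~observed.isin(spec.levels)
                if bad.any():
                    raise CohortError(
                        f"variable {name!r}: values outside declared levels: "
                        f"{sorted(observed[bad].unique())[:5]}"
                    )
        if list(self.missing_mask.columns) != self.variables or len(
            self.missing_mask
        ) != len(self.data):
            raise CohortError("missing_mask shape does not match schema columns")
        frac = self.data[self.variables].isna().mean()
        high = frac[frac >= MISSING_FRACTION_WARN]
        if len(high):
            warnings.warn(
                "missing fraction >= "
                f"{MISSING_FRACTION_WARN:.0%} in: "
                + ", ".join(f"{v} ({f:.1%})" for v, f in high.items()),
                stacklevel=2,
            )

    def copy(self) -> "CohortTable":
        return CohortTable(
            data=self.data.copy(),
            schema=dict(self.schema),
            missing_mask=self.missing_mask.copy(),
        )

    def is_complete(self) -> bool:
        return not self.data[self.variables].isna().any().any()

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, schema: Schema) -> "CohortTable":
        data = pd.read_csv(path)
        for name, spec in schema.items():
            if spec.kind != "continuous" and name in data.columns:
                # CSV round-trips integer-coded levels as int64; align dtype
                # with the declared levels.
                lvl_type = type(spec.levels[0])
                data[name] = data[name].map(
                    lambda v: lvl_type(v) if pd.notna(v) else v
                )
        return cls(data=data, schema=schema)


@dataclass
class DistanceMatrix:
    """Dense pairwise dissimilarities in [0, 1] with subject ordering."""

    values: np.ndarray
    subject_ids: Sequence

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise CohortError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise CohortError("distance matrix must be symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) > 1e-12:
            raise CohortError("distance matrix diagonal must be zero")
        if v.min(initial=0.0) < -1e-12 or v.max(initial=0.0) > 1 + 1e-12:
            raise CohortError("distances must lie in [0, 1]")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            self.values, index=self.subject_ids, columns=self.subject_ids
        ).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(values=df.to_numpy(dtype=float), subject_ids=list(df.columns))
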