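"""Schema-validated single-table clinical datasets.

A dataset is a plain CSV table plus a JSON *schema sidecar* that declares,
for every column, whether it is categorical or numeric, which column is the
binary outcome (target), and zero or more *logical rules* of the form

    if trigger_column == trigger_value then dependent_column == required_value

e.g. ``smoker == "no"  =>  pack_years == 0``.  Rules describe deterministic
main-attribute/subattribute relationships whose violation produces clinically
impossible records ("drinking: no" together with a positive weekly amount).

Records with missing values are refused at load time: the modelling pipeline
assumes a complete table (incomplete records are expected to be excluded
upstream, as is usual for registry-derived study populations), and silently
imputing would fabricate clinical facts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CATEGORICAL = "categorical"
NUMERIC = "numeric"

#: Absolute tolerance for numeric equality in rule checking.
RULE_NUMERIC_TOL = 1e-9


class SchemaError(ValueError):
    """Raised when a schema sidecar is internally inconsistent."""


class DatasetError(ValueError):
    """Raised when table values violate their declared schema."""


# ---------------------------------------------------------------------------
# schema
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColumnSchema:
    """Declaration of a single column.

    Parameters
    ----------
    name
        Column identifier, unique within the schema.
    kind
        ``"categorical"`` or ``"numeric"``.
    categories
        Ordered, duplicate-free category labels; required for categorical
        columns and forbidden for numeric ones.
    role
        ``"feature"`` or ``"target"``.  The target must be categorical with
        exactly two categories.
    """

    name: str
    kind: str
    categories: tuple[str, ...] | None = None
    role: str = "feature"

    def __post_init__(self) -> None:
        if self.kind not in (CATEGORICAL, NUMERIC):
            raise SchemaError(f"column {self.name!r}: unknown kind {self.kind!r}")
        if self.role not in ("feature", "target"):
            raise SchemaError(f"column {self.name!r}: unknown role {self.role!r}")
        if self.kind == CATEGORICAL:
            if not self.categories:
                raise SchemaError(f"categorical column {self.name!r} needs categories")
            object.__setattr__(self, "categories", tuple(str(c) for c in self.categories))
            if len(set(self.categories)) != len(self.categories):
                raise SchemaError(f"column {self.name!r}: duplicate categories")
        elif self.categories is not None:
            raise SchemaError(f"numeric column {self.name!r} must not list categories")

    @property
    def is_categorical(self) -> bool:
        return self.kind == CATEGORICAL


@dataclass(frozen=True)
class LogicalRule:
    """Deterministic constraint: trigger value forces the dependent value.

    ``trigger_column`` must be categorical; ``required_value`` is a category
    label when the dependent column is categorical and a finite number when
    it is numeric.
    """

    trigger_column: str
    trigger_value: str
    dependent_column: str
    required_value: Any

    def __post_init__(self) -> None:
        if self.trigger_column == self.dependent_column:
            raise SchemaError(
                f"rule on {self.trigger_column!r}: trigger and dependent coincide"
            )

    def to_json(self) -> dict[str, Any]:
        return {
            "trigger_column": self.trigger_column,
            "trigger_value": self.trigger_value,
            "dependent_column": self.dependent_column,
            "required_value": self.required_value,
        }


@dataclass(frozen=True)
class TableSchema:
    """Full sidecar: column declarations, the binary target, logical rules."""

    columns: tuple[ColumnSchema, ...]
    target: str
    rules: tuple[LogicalRule, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "columns", tuple(self.columns))
        object.__setattr__(self, "rules", tuple(self.rules))
        names = [c.name for c in self.columns]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate column names in schema")
        by_name = {c.name: c for c in self.columns}
        if self.target not in by_name:
            raise SchemaError(f"target column {self.target!r} not declared")
        tgt = by_name[self.target]
        if not tgt.is_categorical or len(tgt.categories) != 2:
            raise SchemaError("target must be categorical with exactly 2 categories")
        if tgt.role != "target":
            raise SchemaError(f"target column {self.target!r} must have role 'target'")
        for c in self.columns:
            if c.role == "target" and c.name != self.target:
                raise SchemaError(f"column {c.name!r} has role target but is not the target")
        for rule in self.rules:
            for col in (rule.trigger_column, rule.dependent_column):
                if col not in by_name:
                    raise SchemaError(f"rule references unknown column {col!r}")
            trig = by_name[rule.trigger_column]
            if not trig.is_categorical:
                raise SchemaError(f"rule trigger {trig.name!r} must be categorical")
            if str(rule.trigger_value) not in trig.categories:
                raise SchemaError(
                    f"rule trigger value {rule.trigger_value!r} not a category of {trig.name!r}"
                )
            dep = by_name[rule.dependent_column]
            if dep.is_categorical:
                if str(rule.required_value) not in dep.categories:
                    raise SchemaError(
                        f"rule required value {rule.required_value!r} "
                        f"not a category of {dep.name!r}"
                    )
            else:
                try:
                    v = float(rule.required_value)
                except (TypeError, ValueError):
                    raise SchemaError(
                        f"rule required value {rule.required_value!r} is not numeric"
                    ) from None
                if not math.isfinite(v):
                    raise SchemaError("rule required value must be finite")

    # -- lookups ------------------------------------------------------------

    def column(self, name: str) -> ColumnSchema:
        for c in self.columns:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.columns)

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.columns if c.name != self.target)

    @property
    def numeric_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.columns if not c.is_categorical)

    @property
    def categorical_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.columns if c.is_categorical)

    @property
    def target_categories(self) -> tuple[str, str]:
        return self.column(self.target).categories  # type: ignore[return-value]

    @property
    def positive_class(self) -> str:
        """Event class: by convention the second listed target category."""
        return self.target_categories[1]

    @property
    def negative_class(self) -> str:
        return self.target_categories[0]

    # -- serialization ------------------------------------------------------

    def to_json(self) -> dict[str, Any]:
        cols = []
        for c in self.columns:
            entry: dict[str, Any] = {"name": c.name, "kind": c.kind, "role": c.role}
            if c.categories is not None:
                entry["categories"] = list(c.categories)
            cols.append(entry)
        return {
            "columns": cols,
            "target": self.target,
            "rules": [r.to_json() for r in self.rules],
        }

    @classmethod
    def from_json(cls, doc: Mapping[str, Any]) -> "TableSchema":
        try:
            cols = tuple(
                ColumnSchema(
                    name=c["name"],
                    kind=c["kind"],
                    categories=tuple(c["categories"]) if "categories" in c else None,
                    role=c.get("role", "feature"),
                )
                for c in doc["columns"]
            )
            rules = tuple(
                LogicalRule(
                    trigger_column=r["trigger_column"],
                    trigger_value=r["trigger_value"],
                    dependent_column=r["dependent_column"],
                    required_value=r["required_value"],
                )
                for r in doc.get("rules", [])
            )
            target = doc["target"]
        except KeyError as exc:
            raise SchemaError(f"schema sidecar missing key {exc}") from None
        return cls(columns=cols, target=target, rules=rules)


def read_schema(path: str | Path) -> TableSchema:
    with open(path, encoding="utf-8") as fh:
        return TableSchema.from_json(json.load(fh))


def write_schema(schema: TableSchema, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(schema.to_json(), fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# dataset
# ---------------------------------------------------------------------------

class TabularDataset:
    """A validated table bound to its :class:`TableSchema`.

    Categorical values are stored as python strings, numeric values as
    float64.  Construction validates every cell; instances are treated as
    immutable (mutating the underlying frame is a programming error).
    """

    def __init__(self, schema: TableSchema, frame: pd.DataFrame, *, validate: bool = True):
        self.schema = schema
        frame = frame.reset_index(drop=True)
        if validate:
            frame = _validate_frame(schema, frame)
        self.frame = frame

    # -- basics -------------------------------------------------------------

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    def __len__(self) -> int:
        return self.n_rows

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TabularDataset):
            return NotImplemented
        if self.schema != other.schema or self.n_rows != other.n_rows:
            return False
        return self.frame[list(self.schema.names)].equals(
            other.frame[list(other.schema.names)]
        )

    def __repr__(self) -> str:
        return f"TabularDataset(n_rows={self.n_rows}, columns={list(self.schema.names)})"

    # -- row selection ------------------------------------------------------

    def select(self, mask: Sequence[bool] | np.ndarray) -> "TabularDataset":
        sub = self.frame.loc[np.asarray(mask, dtype=bool)].reset_index(drop=True)
        return TabularDataset(self.schema, sub, validate=False)

    def take(self, indices: Sequence[int] | np.ndarray) -> "TabularDataset":
        sub = self.frame.iloc[np.asarray(indices, dtype=int)].reset_index(drop=True)
        return TabularDataset(self.schema, sub, validate=False)

    def column_values(self, name: str) -> np.ndarray:
        self.schema.column(name)  # raise KeyError on unknown
        return self.frame[name].to_numpy()

    @property
    def target_values(self) -> np.ndarray:
        return self.frame[self.schema.target].to_numpy()


def concat_datasets(datasets: Sequence[TabularDataset]) -> TabularDataset:
    """Concatenate row-wise; all parts must share one schema."""
    if not datasets:
        raise DatasetError("cannot concatenate an empty list of datasets")
    schema = datasets[0].schema
    for d in datasets[1:]:
        if d.schema != schema:
            raise DatasetError("schema mismatch between concatenated datasets")
    frame = pd.concat([d.frame for d in datasets], ignore_index=True)
    return TabularDataset(schema, frame, validate=False)


def _validate_frame(schema: TableSchema, frame: pd.DataFrame) -> pd.DataFrame:
    missing_cols = set(schema.names) - set(frame.columns)
    if missing_cols:
        raise DatasetError(f"table is missing declared columns: {sorted(missing_cols)}")
    extra = set(frame.columns) - set(schema.names)
    if extra:
        raise DatasetError(f"table has undeclared columns: {sorted(extra)}")
    out: dict[str, Any] = {}
    for col in schema.columns:
        series = frame[col.name]
        na = series.isna()
        if na.any():
            row = int(np.flatnonzero(na.to_numpy())[0])
            raise DatasetError(f"missing value at row {row}, column {col.name!r}")
        if col.is_categorical:
            values = series.astype(str).to_numpy()
            if (values == "").any():
                row = int(np.flatnonzero(values == "")[0])
                raise DatasetError(f"missing value at row {row}, column {col.name!r}")
            allowed = set(col.categories)
            bad = ~np.isin(values, list(allowed))
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise DatasetError(
                    f"row {row}, column {col.name!r}: value {values[row]!r} "
                    f"not among categories {list(col.categories)}"
                )
            out[col.name] = values
        else:
            if series.dtype == object:
                stripped = series.astype(str).str.strip()
                if (stripped == "").any():
                    row = int(np.flatnonzero((stripped == "").to_numpy())[0])
                    raise DatasetError(f"missing value at row {row}, column {col.name!r}")
            if series.dtype == object:
                # python's float() is correctly rounded, so repr-written
                # values re-read to the identical double
                try:
                    values = np.array([float(v) for v in series], dtype=float)
                except (ValueError, TypeError) as exc:
                    raise DatasetError(
                        f"column {col.name!r}: numeric parse failure ({exc})"
                    ) from None
            else:
                values = series.astype(float).to_numpy()
            if not np.isfinite(values).all():
                row = int(np.flatnonzero(~np.isfinite(values))[0])
                raise DatasetError(
                    f"row {row}, column {col.name!r}: non-finite numeric value"
                )
            out[col.name] = values
    return pd.DataFrame(out, columns=list(schema.names))


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_dataset(csv_path: str | Path, schema_path: str | Path) -> TabularDataset:
    """Load and validate a CSV table against its schema sidecar.

    Empty cells, categories not declared in the sidecar and unparseable
    numerics are all load errors naming the offending row/column.
    """
    schema = read_schema(schema_path)
    frame = pd.read_csv(
        csv_path, dtype=str, keep_default_na=False, na_values=[""], skip_blank_lines=False
    )
    return TabularDataset(schema, frame)


def write_dataset(dataset: TabularDataset, csv_path: str | Path) -> None:
    """Write the table as UTF-8 CSV with a header row.

    Numerics are rendered with python's shortest round-trip ``repr`` so a
    re-read reproduces the exact float values (read/write round-trip
    identity).
    """
    frame = dataset.frame.copy()
    for name in dataset.schema.numeric_names:
        frame[name] = [repr(float(v)) for v in frame[name]]
    frame.to_csv(csv_path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# rule checking (shared by the consistency checker and rejection sampling)
# ---------------------------------------------------------------------------

def rule_violation_mask(dataset: TabularDataset, rule: LogicalRule) -> np.ndarray:
    """Boolean mask of rows violating ``rule``.

    A row violates the rule iff the trigger matches and the dependent value
    differs from the required constant (numeric equality within
    ``RULE_NUMERIC_TOL``).
    """
    schema = dataset.schema
    for col in (rule.trigger_column, rule.dependent_column):
        if col not in schema.names:
            raise DatasetError(f"rule references unknown column {col!r}")
    triggered = dataset.column_values(rule.trigger_column) == str(rule.trigger_value)
    dep = schema.column(rule.dependent_column)
    values = dataset.column_values(rule.dependent_column)
    if dep.is_categorical:
        ok = values == str(rule.required_value)
    else:
        ok = np.abs(values.astype(float) - float(rule.required_value)) <= RULE_NUMERIC_TOL
    return triggered & ~ok
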