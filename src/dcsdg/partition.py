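"""The "divide" step: class-specific split, then splits on division features.

The original table is first split by the binary outcome (the class-specific
criterion: the survival and death groups get their own generators), then each
class branch is split on the *division features* derived from perfect-
association (V = 1) column pairs — e.g. smoker/non-smoker.  With one division
feature this yields the four subsets death-smoker, death-nonsmoker,
survival-smoker, survival-nonsmoker.

Over-division starves the per-subset generators of training rows, so rule
splits that would produce a subset below ``min_subset_size`` are dropped for
the affected class branch (the class split itself always survives).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_model import TabularDataset

logger = logging.getLogger(__name__)

DEFAULT_MIN_SUBSET_SIZE = 50


class PartitionError(ValueError):
    pass


@dataclass(frozen=True)
class DivisionCriteria:
    """Ordered division plan: the target class split plus division features.

    ``division_features`` holds ``(feature, pair)`` entries where ``pair`` is
    the V = 1 column pair the feature was derived from.
    """

    target_column: str
    division_features: tuple[tuple[str, tuple[str, str]], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "division_features", tuple(self.division_features)
        )
        for feat, _ in self.division_features:
            if feat == self.target_column:
                raise PartitionError("a division feature cannot be the target")
        feats = [f for f, _ in self.division_features]
        if len(set(feats)) != len(feats):
            raise PartitionError("duplicate division features")


@dataclass(frozen=True)
class PartitionSubset:
    label: dict[str, str]
    data: TabularDataset

    @property
    def key(self) -> str:
        return "|".join(f"{k}={v}" for k, v in self.label.items())

    @property
    def n_rows(self) -> int:
        return self.data.n_rows


@dataclass(frozen=True)
class Partition:
    """Disjoint labelled subsets whose union is the input table."""

    subsets: tuple[PartitionSubset, ...]
    target_column: str

    def __post_init__(self) -> None:
        keys = [s.key for s in self.subsets]
        if len(set(keys)) != len(keys):
            raise PartitionError("partition labels are not unique")

    def __len__(self) -> int:
        return len(self.subsets)

    def by_class(self, cls: str) -> list[PartitionSubset]:
        return [s for s in self.subsets if s.label[self.target_column] == cls]


def derive_division_feature(data: TabularDataset, pair: tuple[str, str]) -> str:
    """Pick the *main attribute* of a V = 1 pair.

    The member with fewer observed distinct values wins (smoking status beats
    raw pack-years); ties go to the natively categorical member, then to the
    lexicographically first.
    """
    a, b = pair
    counts = {name: len(np.unique(data.column_values(name))) for name in (a, b)}
    if counts[a] != counts[b]:
        return a if counts[a] < counts[b] else b
    cat = {name: data.schema.column(name).is_categorical for name in (a, b)}
    if cat[a] != cat[b]:
        return a if cat[a] else b
    return min(a, b)


def build_partition(
    data: TabularDataset,
    criteria: DivisionCriteria,
    min_subset_size: int = DEFAULT_MIN_SUBSET_SIZE,
) -> Partition:
    """Cross-partition by target class, then by each division feature.

    Within a class branch, a division feature whose application would leave
    any subset smaller than ``min_subset_size`` is skipped (and logged); the
    class split itself is never dropped.  The subsets are pairwise disjoint
    and their multiset union equals the input.
    """
    if min_subset_size < 1:
        raise PartitionError("min_subset_size must be >= 1")
    target = criteria.target_column
    if target != data.schema.target:
        raise PartitionError(
            f"criteria target {target!r} does not match schema target"
        )
    classes = data.schema.target_categories
    tvals = data.target_values
    subsets: list[PartitionSubset] = []
    for cls in classes:
        branch_data = data.select(tvals == cls)
        if branch_data.n_rows == 0:
            raise PartitionError(f"target class {cls!r} has zero rows; cannot class-split")
        branch = [PartitionSubset(label={target: cls}, data=branch_data)]
        for feat, pair in criteria.division_features:
            tentative: list[PartitionSubset] = []
            for sub in branch:
                values = sub.data.column_values(feat)
                for val in _observed_values(values):
                    piece = sub.data.select(values == val)
                    label = dict(sub.label)
                    label[feat] = str(val)
                    tentative.append(PartitionSubset(label=label, data=piece))
            if any(t.n_rows < min_subset_size for t in tentative):
                logger.warning(
                    "class %r: dropping division feature %r (derived from pair %s): "
                    "smallest subset %d < min_subset_size %d",
                    cls, feat, pair,
                    min(t.n_rows for t in tentative), min_subset_size,
                )
                continue
            branch = tentative
        subsets.extend(branch)
    part = Partition(subsets=tuple(subsets), target_column=target)
    logger.info(
        "partition: %d subsets, sizes %s",
        len(part), {s.key: s.n_rows for s in part.subsets},
    )
    return part


def _observed_values(values: np.ndarray) -> list:
    seen: list = []
    for v in values:
        if v not in seen:
            seen.append(v)
    return sorted(seen, key=str)
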