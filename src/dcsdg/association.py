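"""Chi-square / Cramér V association analysis over column pairs.

Cramér's V measures the association between two categorical variables in a
contingency table:

    V = sqrt( chi2 / (N * min(r - 1, c - 1)) )

where ``chi2`` is the Pearson chi-square statistic of the table, ``N`` the
number of observations and ``r``, ``c`` the table dimensions.  V ranges from
0 (independence) to 1 (complete association).  Pairs reaching V = 1 reveal a
deterministic main-attribute/subattribute relationship (e.g. smoking status
vs. pack-years, which is 0 exactly for non-smokers) and are the division
criteria of the divide-and-conquer generation strategy.

Numeric columns take part after conversion to categorical.  The binning here
is equal-frequency with a *point-mass carve-out*: any single value occupying
at least 1/n_bins of the rows (a structural zero, typically) gets a dedicated
bin.  Without the carve-out a structural zero is smeared across quantile bins
and the deterministic pair no longer scores V = 1.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import TabularDataset

logger = logging.getLogger(__name__)

#: Absolute tolerance used when testing V against the division threshold.
V_TOLERANCE = 1e-9

DEFAULT_N_BINS = 10


class AssociationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# contingency tables and Cramér V
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable:
    """Cross-tabulation of two categorical variables.

    Zero-marginal categories are dropped before the dimensions are fixed, so
    every row and column sums to a positive count.
    """

    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    @property
    def N(self) -> int:
        return int(self.counts.sum())

    @property
    def r(self) -> int:
        return self.counts.shape[0]

    @property
    def c(self) -> int:
        return self.counts.shape[1]

    @property
    def chi2(self) -> float:
        return chi_square_statistic(self)


def crosstab(values_a: Sequence, values_b: Sequence) -> ContingencyTable:
    """Build a contingency table from two aligned label sequences.

    Only observed categories appear, so there are no zero marginals.
    """
    a = np.asarray(values_a, dtype=object)
    b = np.asarray(values_b, dtype=object)
    if a.shape != b.shape or a.ndim != 1:
        raise AssociationError("inputs must be equal-length 1-d sequences")
    if len(a) == 0:
        raise AssociationError("cannot tabulate an empty sample")
    table = pd.crosstab(pd.Series(a), pd.Series(b))
    return ContingencyTable(
        counts=table.to_numpy(dtype=np.int64),
        row_labels=tuple(str(x) for x in table.index),
        col_labels=tuple(str(x) for x in table.columns),
    )


def contingency_table(
    data: TabularDataset, col_a: str, col_b: str
) -> ContingencyTable:
    """Cross-tabulate two *categorical* dataset columns.

    Numeric columns must be discretized first (see :func:`discretize_numeric`).
    """
    for name in (col_a, col_b):
        if not data.schema.column(name).is_categorical:
            raise AssociationError(
                f"column {name!r} is numeric; discretize it before tabulating"
            )
    return crosstab(data.column_values(col_a), data.column_values(col_b))


def chi_square_statistic(table: ContingencyTable) -> float:
    """Pearson chi-square, sum (observed - expected)^2 / expected.

    No continuity correction.  Expected counts come from the product of the
    marginals; a zero marginal is an error (drop empty categories first).
    """
    counts = np.asarray(table.counts, dtype=float)
    n = counts.sum()
    if n <= 0:
        raise AssociationError("contingency table has no observations")
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise AssociationError("zero marginal in contingency table; drop empty categories")
    expected = np.outer(rows, cols) / n
    return float(((counts - expected) ** 2 / expected).sum())


def cramers_v(table: ContingencyTable) -> float:
    """Cramér V of a contingency table, clamped to [0, 1].

    Defined as 0 when either dimension has a single category (no association
    is measurable against a constant).
    """
    if table.r < 2 or table.c < 2:
        return 0.0
    chi2 = chi_square_statistic(table)
    v = np.sqrt(chi2 / (table.N * min(table.r - 1, table.c - 1)))
    return float(min(1.0, max(0.0, v)))


# ---------------------------------------------------------------------------
# numeric -> categorical conversion
# ---------------------------------------------------------------------------

def _format_value(v: float) -> str:
    return f"{v:g}"


@dataclass(frozen=True)
class NumericBinner:
    """Equal-frequency binner with dedicated point-mass bins.

    Fitted on one (real) column and reusable on another (synthetic) column so
    both sides of a comparison share bin edges.  Values outside the fitted
    range fall into the first/last quantile bin.
    """

    point_masses: tuple[float, ...]
    edges: tuple[float, ...]          # interior edges of the quantile bins
    interval_labels: tuple[str, ...]  # len(edges) + 1 labels, possibly 0

    @classmethod
    def fit(cls, values: Sequence[float], n_bins: int = DEFAULT_N_BINS) -> "NumericBinner":
        if n_bins < 2:
            raise AssociationError("n_bins must be >= 2")
        x = np.asarray(values, dtype=float)
        if len(x) == 0:
            raise AssociationError("cannot bin an empty column")
        uniq, counts = np.unique(x, return_counts=True)
        # point mass: a single value filling at least 1/n_bins of the rows
        mass = counts * n_bins >= len(x)
        point_masses = tuple(float(v) for v in uniq[mass])
        rest = x[~np.isin(x, uniq[mass])]
        if len(rest) == 0:
            if not point_masses:
                raise AssociationError("no values to bin")  # pragma: no cover
            if len(point_masses) == 1:
                logger.info("constant (single point-mass) column collapsed to one bin")
            return cls(point_masses=point_masses, edges=(), interval_labels=())
        qs = np.quantile(rest, np.linspace(0, 1, n_bins + 1))
        interior = np.unique(qs[1:-1])
        # drop interior edges equal to the extremes (heavy ties)
        interior = interior[(interior > rest.min()) & (interior < rest.max())]
        edges = tuple(float(e) for e in interior)
        bounds = [float(rest.min())] + list(edges) + [float(rest.max())]
        labels = []
        for i in range(len(bounds) - 1):
            left = "[" if i == 0 else "("
            labels.append(f"{left}{_format_value(bounds[i])}, {_format_value(bounds[i + 1])}]")
        return cls(point_masses=point_masses, edges=edges, interval_labels=tuple(labels))

    def transform(self, values: Sequence[float]) -> np.ndarray:
        x = np.asarray(values, dtype=float)
        out = np.empty(len(x), dtype=object)
        remaining = np.ones(len(x), dtype=bool)
        for pm in self.point_masses:
            hit = remaining & (x == pm)
            out[hit] = _format_value(pm)
            remaining &= ~hit
        if remaining.any():
            if not self.interval_labels:
                # fitted column had only point masses; spill into nearest one
                idx = np.flatnonzero(remaining)
                pms = np.asarray(self.point_masses)
                for i in idx:
                    out[i] = _format_value(pms[np.argmin(np.abs(pms - x[i]))])
            else:
                bins = np.searchsorted(np.asarray(self.edges), x[remaining], side="left")
                bins = np.clip(bins, 0, len(self.interval_labels) - 1)
                lab = np.asarray(self.interval_labels, dtype=object)
                out[remaining] = lab[bins]
        return out

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(_format_value(pm) for pm in self.point_masses) + self.interval_labels


def discretize_numeric(values: Sequence[float], n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    """Equal-frequency binning with point-mass carve-out; returns bin labels."""
    return NumericBinner.fit(values, n_bins).transform(values)


# ---------------------------------------------------------------------------
# association matrix and division pairs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssociationMatrix:
    """Symmetric Cramér V matrix over all dataset columns (diagonal = 1)."""

    columns: tuple[str, ...]
    values: np.ndarray
    target: str

    def get(self, col_a: str, col_b: str) -> float:
        i = self.columns.index(col_a)
        j = self.columns.index(col_b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.columns, columns=self.columns)


def cramers_v_matrix(
    data: TabularDataset, n_bins: int = DEFAULT_N_BINS
) -> AssociationMatrix:
    """Pairwise Cramér V over all columns, numerics discretized first."""
    cols = list(data.schema.names)
    converted: dict[str, np.ndarray] = {}
    for name in cols:
        if data.schema.column(name).is_categorical:
            converted[name] = data.column_values(name)
        else:
            converted[name] = discretize_numeric(data.column_values(name), n_bins)
    k = len(cols)
    out = np.eye(k)
    for i, j in itertools.combinations(range(k), 2):
        table = crosstab(converted[cols[i]], converted[cols[j]])
        v = cramers_v(table)  # 1-category columns give r or c == 1 -> 0
        out[i, j] = out[j, i] = v
    return AssociationMatrix(columns=tuple(cols), values=out, target=data.schema.target)


def find_division_pairs(
    matrix: AssociationMatrix,
    threshold: float = 1.0,
    tolerance: float = V_TOLERANCE,
) -> list[tuple[str, str]]:
    """Column pairs whose V reaches the division threshold.

    The target column is excluded (the class-specific split handles it).
    Pairs are sorted by descending V, then lexicographically; an empty list
    means no perfect-association pair exists.
    """
    if not (0.0 < threshold <= 1.0):
        raise AssociationError("threshold must lie in (0, 1]")
    feats = [c for c in matrix.columns if c != matrix.target]
    hits = []
    for a, b in itertools.combinations(feats, 2):
        v = matrix.get(a, b)
        if v >= threshold - tolerance:
            hits.append((v, tuple(sorted((a, b)))))
    hits.sort(key=lambda t: (-t[0], t[1]))
    pairs = [pair for _, pair in hits]
    if pairs:
        logger.info("division-candidate pairs at V >= %g: %s", threshold, pairs)
    else:
        logger.info("no column pair reaches the division threshold V >= %g", threshold)
    return pairs
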