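"""Fidelity metrics: column shapes, pair trends and rule violations.

Similarity between an original table (OD) and a synthetic table (STD) is
scored per column and per column pair, each on [0, 1] with 1 = identical:

* numeric column:      1 - KSS, the Kolmogorov-Smirnov sup-distance between
                       the two empirical CDFs;
* categorical column:  1 - TVD, the total variation distance (half the L1
                       distance between the probability mass functions);
* numeric pair:        1 - |rho_OD - rho_STD| / 2 (Pearson correlation);
* any other pair:      1 - half-L1 distance between the joint cell
                       proportions of the two contingency tables, numeric
                       members discretized with bins fitted on the OD.

The *shape* score is the mean of the column scores, the *pair trend* score
the mean of the pair scores, and the *overall* score the mean of the two
aggregates.  Reports are on [0, 1]; the command line prints them x100.

The logical-consistency checker counts rows that break a declared
trigger => dependent rule (clinically impossible records such as a
non-smoker with positive pack-years).
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .association import DEFAULT_N_BINS, NumericBinner
from .data_model import LogicalRule, TabularDataset, rule_violation_mask


class FidelityError(ValueError):
    pass


# ---------------------------------------------------------------------------
# column metrics
# ---------------------------------------------------------------------------

def kss(real: Sequence[float], synthetic: Sequence[float]) -> float:
    """Kolmogorov-Smirnov statistic between two numeric samples.

    Sup-distance between the empirical CDFs, computed by evaluating both
    step functions over the pooled sample values.
    """
    x = np.sort(np.asarray(real, dtype=float))
    y = np.sort(np.asarray(synthetic, dtype=float))
    if len(x) == 0 or len(y) == 0:
        raise FidelityError("kss requires non-empty samples")
    pooled = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, pooled, side="right") / len(x)
    cdf_y = np.searchsorted(y, pooled, side="right") / len(y)
    return float(np.abs(cdf_x - cdf_y).max())


def _pmf(values: Sequence, support: Sequence) -> np.ndarray:
    counts = pd.Series(np.asarray(values, dtype=object)).value_counts()
    return np.array([counts.get(s, 0) for s in support], dtype=float) / len(values)


def tvd(real: Sequence, synthetic: Sequence) -> float:
    """Total variation distance between two categorical samples.

    Half the L1 distance between probability mass functions, taken over the
    union of observed categories.
    """
    r = np.asarray(real, dtype=object)
    s = np.asarray(synthetic, dtype=object)
    if len(r) == 0 or len(s) == 0:
        raise FidelityError("tvd requires non-empty samples")
    support = sorted(set(r) | set(s), key=str)
    return float(0.5 * np.abs(_pmf(r, support) - _pmf(s, support)).sum())


# ---------------------------------------------------------------------------
# pair metrics
# ---------------------------------------------------------------------------

def correlation_similarity(
    real_x: Sequence[float],
    real_y: Sequence[float],
    syn_x: Sequence[float],
    syn_y: Sequence[float],
) -> float:
    """1 - |Pearson rho(OD pair) - Pearson rho(STD pair)| / 2, in [0, 1]."""
    rho_r = _pearson(real_x, real_y)
    rho_s = _pearson(syn_x, syn_y)
    return float(1.0 - abs(rho_r - rho_s) / 2.0)


def _pearson(x: Sequence[float], y: Sequence[float]) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise FidelityError("correlation undefined for a constant column")
    return float(np.corrcoef(x, y)[0, 1])


def contingency_similarity(
    real_x: Sequence,
    real_y: Sequence,
    syn_x: Sequence,
    syn_y: Sequence,
) -> float:
    """1 - half-L1 distance between joint cell proportions, in [0, 1].

    Cells range over the union of category combinations observed in either
    table; proportions (not counts) are compared, so sample sizes may differ.
    """
    rx = np.asarray(real_x, dtype=object)
    ry = np.asarray(real_y, dtype=object)
    sx = np.asarray(syn_x, dtype=object)
    sy = np.asarray(syn_y, dtype=object)
    if len(rx) == 0 or len(sx) == 0:
        raise FidelityError("contingency similarity requires non-empty samples")
    real_cells = Counter(zip(rx, ry))
    syn_cells = Counter(zip(sx, sy))
    support = sorted(real_cells.keys() | syn_cells.keys(), key=str)
    p = np.array([real_cells[c] for c in support], dtype=float) / len(rx)
    q = np.array([syn_cells[c] for c in support], dtype=float) / len(sx)
    return float(1.0 - 0.5 * np.abs(p - q).sum())


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FidelityReport:
    """Per-column and per-pair similarities with their aggregates (0-1)."""

    column_scores: dict[str, float]
    pair_scores: dict[tuple[str, str], float]
    shape: float
    pair_trend: float
    overall: float

    @classmethod
    def from_scores(
        cls,
        column_scores: Mapping[str, float],
        pair_scores: Mapping[tuple[str, str], float],
    ) -> "FidelityReport":
        shape = float(np.mean(list(column_scores.values())))
        pair_trend = float(np.mean(list(pair_scores.values()))) if pair_scores else 1.0
        return cls(
            column_scores=dict(column_scores),
            pair_scores=dict(pair_scores),
            shape=shape,
            pair_trend=pair_trend,
            overall=(shape + pair_trend) / 2.0,
        )

    def to_json(self) -> dict:
        return {
            "column_scores": self.column_scores,
            "pair_scores": {f"{a}|{b}": v for (a, b), v in self.pair_scores.items()},
            "shape": self.shape,
            "pair_trend": self.pair_trend,
            "overall": self.overall,
        }


def quality_report(
    real: TabularDataset,
    synthetic: TabularDataset,
    n_bins: int = DEFAULT_N_BINS,
) -> FidelityReport:
    """Full shape / pair-trend report between an OD and an STD table.

    Numeric-numeric pairs use correlation similarity unless a member is
    constant in either table (correlation undefined), in which case — like
    every pair involving a categorical column — the numeric members are
    discretized with bins fitted on the real data and the pair is scored by
    contingency similarity.
    """
    if real.schema != synthetic.schema:
        raise FidelityError("real and synthetic datasets must share a schema")
    schema = real.schema
    binned: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name in schema.numeric_names:
        binner = NumericBinner.fit(real.column_values(name), n_bins)
        binned[name] = (
            binner.transform(real.column_values(name)),
            binner.transform(synthetic.column_values(name)),
        )

    column_scores: dict[str, float] = {}
    for name in schema.names:
        if schema.column(name).is_categorical:
            column_scores[name] = 1.0 - tvd(
                real.column_values(name), synthetic.column_values(name)
            )
        else:
            column_scores[name] = 1.0 - kss(
                real.column_values(name), synthetic.column_values(name)
            )

    pair_scores: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(schema.names, 2):
        numeric_pair = (
            not schema.column(a).is_categorical
            and not schema.column(b).is_categorical
        )
        if numeric_pair:
            try:
                score = correlation_similarity(
                    real.column_values(a), real.column_values(b),
                    synthetic.column_values(a), synthetic.column_values(b),
                )
                pair_scores[(a, b)] = score
                continue
            except FidelityError:
                pass  # constant member: fall back to the contingency path
        ra = binned[a][0] if a in binned else real.column_values(a)
        sa = binned[a][1] if a in binned else synthetic.column_values(a)
        rb = binned[b][0] if b in binned else real.column_values(b)
        sb = binned[b][1] if b in binned else synthetic.column_values(b)
        pair_scores[(a, b)] = contingency_similarity(ra, rb, sa, sb)

    return FidelityReport.from_scores(column_scores, pair_scores)


# ---------------------------------------------------------------------------
# logical consistency
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ViolationReport:
    """Rule-violation counts over a table."""

    n_rows: int
    violations_per_rule: dict[LogicalRule, int]
    violation_rate: float  # fraction of rows breaking at least one rule

    def to_json(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "violations_per_rule": [
                {**r.to_json(), "count": c} for r, c in self.violations_per_rule.items()
            ],
            "violation_rate": self.violation_rate,
        }


def violation_report(
    data: TabularDataset, rules: Sequence[LogicalRule]
) -> ViolationReport:
    """Count rows breaking each rule and the fraction breaking any."""
    per_rule: dict[LogicalRule, int] = {}
    any_bad = np.zeros(data.n_rows, dtype=bool)
    for rule in rules:
        mask = rule_violation_mask(data, rule)
        per_rule[rule] = int(mask.sum())
        any_bad |= mask
    rate = float(any_bad.mean()) if data.n_rows else 0.0
    return ViolationReport(
        n_rows=data.n_rows, violations_per_rule=per_rule, violation_rate=rate
    )
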