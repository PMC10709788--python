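"""Clinical-like study tables with planted structure.

Emulates the statistical shape the divide-and-conquer method assumes, so the
whole pipeline can be exercised and validated without access to any registry
data: a binary adverse-event outcome with configurable prevalence,
class-dependent smoking status, a pack-years subattribute that is exactly 0
for non-smokers (the planted logical rule and the perfect-association pair),
class-shifted Gaussian clinical features (age and lung-function analogues)
and independent noise columns.

The returned *truth record* carries the planted parameters together with the
Bayes-optimal AUC of the class signal, computed in closed form: the
log-likelihood-ratio of the Gaussian block is normal with shift
``delta^2 = sum(d_i^2)`` (effects ``d_i`` in SD units), and the smoking
status adds a discrete log-likelihood offset, so the optimal AUC is a finite
mixture of normal CDF terms over (smoker-status-of-case, of-control) pairs.
Pack-years itself adds no signal beyond smoking status because its
distribution given smoking status is class-independent.

Default effect sizes are chosen so the Bayes AUC is about 0.85, comparable
to what strong tree ensembles reach on real registry mortality tables, which
keeps train-on-synthetic comparisons meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ColumnSchema, LogicalRule, TableSchema, TabularDataset

logger = logging.getLogger(__name__)


class FixtureError(ValueError):
    pass


#: Base (mean, SD) of the clinical feature analogues; effects shift the event
#: class by ``effect * SD``.
_BASE_FEATURES: dict[str, tuple[float, float]] = {
    "age": (65.0, 8.0),
    "fvc": (3.2, 0.7),
    "dlco": (80.0, 15.0),
}

#: Within-class correlation of the standardized clinical features, in
#: _BASE_FEATURES order (age, fvc, dlco).  Lung-function measures correlate
#: with each other and decline with age in real cohorts; this within-class
#: dependence is what pair-trend-preserving generation must reproduce.
_BASE_CORRELATION = np.array(
    [
        [1.0, -0.4, -0.4],
        [-0.4, 1.0, 0.6],
        [-0.4, 0.6, 1.0],
    ]
)

_NOISE_CATEGORIES = ("a", "b", "c")


@dataclass(frozen=True)
class FixtureParams:
    """Knobs of the planted-structure generator.

    ``smoker_rate_by_class`` is (P(smoker | no event), P(smoker | event));
    ``numeric_effects`` maps feature name to the event-class mean shift in SD
    units; ``pack_years_location/scale`` parameterize the log-normal draw for
    smokers (strictly positive, so the planted rule pair is exact).
    """

    n: int = 2304
    event_prevalence: float = 0.5
    smoker_rate_by_class: tuple[float, float] = (0.35, 0.65)
    pack_years_location: float = 3.2   # log-scale median ~ exp(3.2) ~ 24.5 pack-years
    pack_years_scale: float = 0.5
    numeric_effects: Mapping[str, float] = field(
        default_factory=lambda: {"age": 1.0, "fvc": -1.1, "dlco": -1.1}
    )
    n_noise_numeric: int = 2
    n_noise_categorical: int = 2
    seed: int = 0
    max_retries: int = 100

    def __post_init__(self) -> None:
        if self.n < 4:
            raise FixtureError("n must be at least 4 (one row per class x smoker cell)")
        for p in (self.event_prevalence, *self.smoker_rate_by_class):
            if not (0.0 < p < 1.0):
                raise FixtureError("probabilities must lie strictly in (0, 1)")
        unknown = set(self.numeric_effects) - set(_BASE_FEATURES)
        if unknown:
            raise FixtureError(f"unknown feature(s) in numeric_effects: {sorted(unknown)}")


def bayes_auc(params: FixtureParams) -> float:
    """Closed-form optimal AUC of the planted class signal.

    The Gaussian block contributes a Mahalanobis separation
    ``delta^2 = d' R^-1 d`` (effects ``d`` in SD units, within-class
    correlation ``R``); smoking status adds discrete log-likelihood offsets.
    """
    effects = np.array([params.numeric_effects.get(k, 0.0) for k in _BASE_FEATURES])
    delta_sq = float(effects @ np.linalg.solve(_BASE_CORRELATION, effects))
    p1, p0 = params.smoker_rate_by_class[1], params.smoker_rate_by_class[0]
    lam = {  # smoking-status log-likelihood-ratio offsets
        "yes": np.log(p1 / p0),
        "no": np.log((1 - p1) / (1 - p0)),
    }
    prob1 = {"yes": p1, "no": 1 - p1}
    prob0 = {"yes": p0, "no": 1 - p0}
    total = 0.0
    for s_case in ("yes", "no"):
        for s_ctrl in ("yes", "no"):
            w = prob1[s_case] * prob0[s_ctrl]
            shift = delta_sq + lam[s_case] - lam[s_ctrl]
            if delta_sq > 0:
                term = stats.norm.cdf(shift / np.sqrt(2 * delta_sq))
            else:
                term = 1.0 if shift > 0 else (0.5 if shift == 0 else 0.0)
            total += w * term
    return float(total)


def fixture_schema(params: FixtureParams) -> TableSchema:
    cols = [
        ColumnSchema("age", "numeric"),
        ColumnSchema("fvc", "numeric"),
        ColumnSchema("dlco", "numeric"),
        ColumnSchema("smoker", "categorical", categories=("no", "yes")),
        ColumnSchema("pack_years", "numeric"),
    ]
    for i in range(params.n_noise_numeric):
        cols.append(ColumnSchema(f"noise_num_{i + 1}", "numeric"))
    for i in range(params.n_noise_categorical):
        cols.append(
            ColumnSchema(f"noise_cat_{i + 1}", "categorical", categories=_NOISE_CATEGORIES)
        )
    cols.append(
        ColumnSchema("adverse_event", "categorical", categories=("no", "yes"), role="target")
    )
    rules = (
        LogicalRule(
            trigger_column="smoker",
            trigger_value="no",
            dependent_column="pack_years",
            required_value=0.0,
        ),
    )
    return TableSchema(columns=tuple(cols), target="adverse_event", rules=rules)


def generate_fixture(
    params: FixtureParams,
) -> tuple[TabularDataset, tuple[LogicalRule, ...], dict]:
    """Draw one study table; returns (dataset, planted rules, truth record).

    Redraws (up to ``max_retries``) until every class x smoker cell is
    non-empty, so the four-subset division always exists.
    """
    schema = fixture_schema(params)
    rng = np.random.default_rng(params.seed)
    for attempt in range(params.max_retries):
        frame = _draw(params, rng)
        cells = pd.crosstab(frame["adverse_event"], frame["smoker"])
        if cells.shape == (2, 2) and (cells.to_numpy() > 0).all():
            if attempt:
                logger.info("fixture: %d redraw(s) to fill all class x smoker cells", attempt)
            break
    else:
        raise FixtureError(
            f"could not populate all class x smoker cells in {params.max_retries} draws"
        )
    truth = {
        "event_prevalence": params.event_prevalence,
        "smoker_rate_by_class": params.smoker_rate_by_class,
        "numeric_effects": dict(params.numeric_effects),
        "bayes_auc": bayes_auc(params),
    }
    return TabularDataset(schema, frame), schema.rules, truth


def _draw(params: FixtureParams, rng: np.random.Generator) -> pd.DataFrame:
    n = params.n
    event = rng.random(n) < params.event_prevalence
    smoker_p = np.where(event, *params.smoker_rate_by_class[::-1])
    smoker = rng.random(n) < smoker_p
    pack_years = np.where(
        smoker,
        rng.lognormal(params.pack_years_location, params.pack_years_scale, n),
        0.0,
    )
    out: dict[str, np.ndarray] = {}
    z = rng.standard_normal((n, len(_BASE_FEATURES))) @ np.linalg.cholesky(
        _BASE_CORRELATION
    ).T
    for j, (name, (mean, sd)) in enumerate(_BASE_FEATURES.items()):
        shift = params.numeric_effects.get(name, 0.0) * sd
        out[name] = mean + np.where(event, shift, 0.0) + sd * z[:, j]
    out["smoker"] = np.where(smoker, "yes", "no")
    out["pack_years"] = pack_years
    for i in range(params.n_noise_numeric):
        out[f"noise_num_{i + 1}"] = rng.normal(0.0, 1.0, n)
    for i in range(params.n_noise_categorical):
        out[f"noise_cat_{i + 1}"] = rng.choice(_NOISE_CATEGORIES, size=n)
    out["adverse_event"] = np.where(event, "yes", "no")
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def fixture_presets() -> dict[str, FixtureParams]:
    """Named parameter sets for the standard experiment scales."""
    return {
        # registry-like cohort size, meant to be split 70/30
        "nsclc-like": FixtureParams(n=2304),
        "small": FixtureParams(n=400),
        "imbalanced-od": FixtureParams(n=2304, event_prevalence=0.1),
    }


def fixture_preset(name: str, seed: int | None = None) -> FixtureParams:
    presets = fixture_presets()
    try:
        params = presets[name]
    except KeyError:
        raise FixtureError(
            f"unknown preset {name!r}; available: {sorted(presets)}"
        ) from None
    return replace(params, seed=seed) if seed is not None else params
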