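"""Generator backends, the conquer step and end-to-end synthesis.

The reference backend is a Gaussian copula: each column is reduced to its
empirical marginal (sorted training values for numerics; category frequency
intervals on [0, 1] for categoricals), the dependence between columns is a
correlation matrix estimated on normal scores, and sampling draws a
multivariate normal, pushes each coordinate through the standard normal CDF
and inverts the marginals.  Numeric inversion interpolates between sorted
training values and therefore stays inside the training range — this is the
mechanism by which a subset whose dependent column is constant (pack-years 0
for non-smokers) reproduces that constant *exactly*, and hence why the
divide-and-conquer pipeline emits no logically impossible rows.

Three strategies are provided:

``dc``    divide (class split + V = 1 pairs), fit one backend per subset,
          sample per-subset volumes, recombine (conquer).
``cs``    conditional sampling: one backend on the whole table, rejection
          sampling against the logical rules.
``none``  one backend on the whole table, plain sampling.

Neural tabular GANs (CTGAN, CopulaGAN) attach through the same fit/sample
backend contract with a declared hyperparameter grid; their training
internals are out of scope here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Any, Mapping, Protocol, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import DEFAULT_N_BINS, V_TOLERANCE, cramers_v_matrix, find_division_pairs
from .data_model import (
    DatasetError,
    LogicalRule,
    TableSchema,
    TabularDataset,
    concat_datasets,
    rule_violation_mask,
)
from .partition import (
    DEFAULT_MIN_SUBSET_SIZE,
    DivisionCriteria,
    Partition,
    build_partition,
    derive_division_feature,
)

logger = logging.getLogger(__name__)

_SEED_MOD = 2**31


class GenerationError(RuntimeError):
    pass


class RejectionError(GenerationError):
    """Raised when rejection sampling cannot collect enough valid rows."""

    def __init__(self, message: str, acceptance_rate: float):
        super().__init__(message)
        self.acceptance_rate = acceptance_rate


# ---------------------------------------------------------------------------
# marginals and the fitted copula state
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NumericMarginal:
    """Empirical CDF support: sorted training values on a mid-rank grid."""

    sorted_values: np.ndarray

    @property
    def grid(self) -> np.ndarray:
        n = len(self.sorted_values)
        return (np.arange(n) + 0.5) / n

    def inverse(self, u: np.ndarray) -> np.ndarray:
        # linear interpolation between order statistics; clamped to the
        # training min/max by np.interp's end handling
        return np.interp(u, self.grid, self.sorted_values)


@dataclass(frozen=True)
class CategoricalMarginal:
    """Category frequencies as contiguous sub-intervals of [0, 1]."""

    categories: tuple[str, ...]
    probs: np.ndarray  # aligned with categories, sums to 1

    @property
    def cum(self) -> np.ndarray:
        return np.cumsum(self.probs)

    def midpoints(self) -> np.ndarray:
        cum = self.cum
        lo = np.concatenate([[0.0], cum[:-1]])
        return (lo + cum) / 2.0

    def inverse(self, u: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.cum, u, side="left")
        idx = np.clip(idx, 0, len(self.categories) - 1)
        return np.asarray(self.categories, dtype=object)[idx]


@dataclass(frozen=True)
class GeneratorModel:
    """Fitted per-subset generative state (fit/sample contract)."""

    schema: TableSchema
    marginals: dict[str, NumericMarginal | CategoricalMarginal]
    dependence: np.ndarray  # PSD correlation matrix on normal scores
    n_train: int

    @property
    def columns(self) -> tuple[str, ...]:
        return self.schema.names


def _nearest_psd_correlation(matrix: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Clip negative eigenvalues and renormalize to unit diagonal."""
    sym = (matrix + matrix.T) / 2.0
    w, v = np.linalg.eigh(sym)
    if w.min() >= eps:
        return sym
    w = np.clip(w, eps, None)
    repaired = (v * w) @ v.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


def _normal_scores(data: TabularDataset) -> tuple[np.ndarray, dict]:
    """Per-column normal scores and the fitted marginals."""
    n = data.n_rows
    marginals: dict[str, NumericMarginal | CategoricalMarginal] = {}
    scores = np.empty((n, len(data.schema.names)))
    for j, name in enumerate(data.schema.names):
        col = data.schema.column(name)
        values = data.column_values(name)
        if col.is_categorical:
            counts = pd.Series(values).value_counts()
            probs = np.array(
                [counts.get(c, 0) for c in col.categories], dtype=float
            )
            probs /= probs.sum()
            marg = CategoricalMarginal(categories=col.categories, probs=probs)
            mids = dict(zip(col.categories, marg.midpoints()))
            u = np.array([mids[v] for v in values])
        else:
            marg = NumericMarginal(sorted_values=np.sort(values.astype(float)))
            ranks = stats.rankdata(values, method="average")
            u = (ranks - 0.5) / n
        marginals[name] = marg
        scores[:, j] = stats.norm.ppf(np.clip(u, 1e-12, 1 - 1e-12))
    return scores, marginals


def fit_copula(subset: TabularDataset) -> GeneratorModel:
    """Fit the Gaussian-copula reference backend on one subset.

    A single-row subset degenerates to row replication (identity dependence,
    point-mass marginals); this is logged because such a generator carries no
    variability.
    """
    if subset.n_rows == 0:
        raise GenerationError("cannot fit a generator on an empty subset")
    if subset.n_rows == 1:
        logger.warning("1-row subset: generator degenerates to row replication")
    scores, marginals = _normal_scores(subset)
    k = scores.shape[1]
    if subset.n_rows < 2:
        dependence = np.eye(k)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(scores, rowvar=False)
        corr = np.atleast_2d(corr)
        corr[~np.isfinite(corr)] = 0.0  # constant columns: no dependence
        np.fill_diagonal(corr, 1.0)
        dependence = _nearest_psd_correlation(corr)
    return GeneratorModel(
        schema=subset.schema,
        marginals=marginals,
        dependence=dependence,
        n_train=subset.n_rows,
    )


def fit_independent(subset: TabularDataset) -> GeneratorModel:
    """Marginals-only ablation: identity dependence (destroys pair trends)."""
    model = fit_copula(subset)
    return replace(model, dependence=np.eye(len(model.columns)))


def _sample_model(model: GeneratorModel, n: int, rng: np.random.Generator) -> TabularDataset:
    cols = model.columns
    k = len(cols)
    if n == 0:
        frame = pd.DataFrame({c: [] for c in cols})
        for name in model.schema.numeric_names:
            frame[name] = frame[name].astype(float)
        return TabularDataset(model.schema, frame, validate=False)
    chol = np.linalg.cholesky(_nearest_psd_correlation(model.dependence))
    z = rng.standard_normal((n, k)) @ chol.T
    u = stats.norm.cdf(z)
    out: dict[str, Any] = {}
    for j, name in enumerate(cols):
        out[name] = model.marginals[name].inverse(u[:, j])
    frame = pd.DataFrame(out, columns=list(cols))
    return TabularDataset(model.schema, frame, validate=False)


def sample_copula(model: GeneratorModel, n: int, seed: int) -> TabularDataset:
    """Draw ``n`` rows; deterministic for a given seed."""
    if n < 0:
        raise GenerationError("n must be >= 0")
    return _sample_model(model, n, np.random.default_rng(seed))


#: The independent backend samples exactly like the copula backend; only the
#: fitted dependence differs.
sample_independent = sample_copula


# ---------------------------------------------------------------------------
# backend contract
# ---------------------------------------------------------------------------

class GeneratorBackend(Protocol):
    """fit/sample contract every backend (incl. neural adapters) satisfies."""

    name: str
    hyperparameter_grid: Mapping[str, Sequence[Any]]

    def fit(self, subset: TabularDataset) -> Any: ...

    def sample(self, model: Any, n: int, seed: int) -> TabularDataset: ...


class GaussianCopulaBackend:
    name = "copula"
    hyperparameter_grid: Mapping[str, Sequence[Any]] = {}

    def __init__(self, **params: Any):
        self.params = params

    def fit(self, subset: TabularDataset) -> GeneratorModel:
        return fit_copula(subset)

    def sample(self, model: GeneratorModel, n: int, seed: int) -> TabularDataset:
        return sample_copula(model, n, seed)


class IndependentBackend:
    name = "independent"
    hyperparameter_grid: Mapping[str, Sequence[Any]] = {}

    def __init__(self, **params: Any):
        self.params = params

    def fit(self, subset: TabularDataset) -> GeneratorModel:
        return fit_independent(subset)

    def sample(self, model: GeneratorModel, n: int, seed: int) -> TabularDataset:
        return sample_copula(model, n, seed)


_BACKENDS: dict[str, type] = {
    GaussianCopulaBackend.name: GaussianCopulaBackend,
    IndependentBackend.name: IndependentBackend,
}


def register_backend(name: str, factory: type) -> None:
    """Register an adapter backend (e.g. a neural tabular GAN wrapper)."""
    _BACKENDS[name] = factory


def get_backend(name: str, **params: Any) -> GeneratorBackend:
    try:
        factory = _BACKENDS[name]
    except KeyError:
        raise GenerationError(
            f"unknown backend {name!r}; registered: {sorted(_BACKENDS)}"
        ) from None
    return factory(**params)


# ---------------------------------------------------------------------------
# conditional sampling (rejection) baseline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RejectionStats:
    n_proposed: int
    n_accepted: int

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / self.n_proposed if self.n_proposed else 1.0


def rejection_sample(
    model: GeneratorModel,
    rules: Sequence[LogicalRule],
    n: int,
    seed: int,
    max_batches: int = 100,
    return_stats: bool = False,
) -> TabularDataset | tuple[TabularDataset, RejectionStats]:
    """Sample rows and discard any violating a logical rule, until n remain.

    Batches of size ``n`` are drawn repeatedly.  If ``max_batches`` batches
    do not yield ``n`` valid rows the conditions are over-constrained for the
    fitted model and a :class:`RejectionError` reporting the acceptance rate
    is raised — the information-loss failure mode of filtering approaches.
    """
    if n < 0:
        raise GenerationError("n must be >= 0")
    if max_batches < 1:
        raise GenerationError("max_batches must be >= 1")
    rng = np.random.default_rng(seed)
    kept: list[TabularDataset] = []
    n_kept = 0
    n_proposed = 0
    batch_size = max(n, 1)
    for _ in range(max_batches):
        if n_kept >= n:
            break
        batch = _sample_model(model, batch_size, rng)
        n_proposed += batch.n_rows
        bad = np.zeros(batch.n_rows, dtype=bool)
        for rule in rules:
            bad |= rule_violation_mask(batch, rule)
        good = batch.select(~bad)
        kept.append(good)
        n_kept += good.n_rows
    stats_ = RejectionStats(n_proposed=n_proposed, n_accepted=n_kept)
    if n_kept < n:
        raise RejectionError(
            f"rejection sampling collected {n_kept}/{n} valid rows after "
            f"{max_batches} batches (acceptance rate "
            f"{stats_.acceptance_rate:.4f}); conditions over-constrain the model",
            acceptance_rate=stats_.acceptance_rate,
        )
    data = concat_datasets(kept).take(np.arange(n)) if kept else _sample_model(
        model, 0, rng
    )
    if n == 0:
        data = _sample_model(model, 0, rng)
    if return_stats:
        return data, stats_
    return data


# ---------------------------------------------------------------------------
# conquer: volume allocation and recombination
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VolumePlan:
    """How many synthetic rows each subset contributes."""

    total: int
    per_subset: dict[str, int]  # partition subset key -> count
    class_ratio: tuple[float, float]


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment proportional to ``weights`` summing to total."""
    if total == 0:
        return np.zeros(len(weights), dtype=int)
    quotas = weights / weights.sum() * total
    base = np.floor(quotas).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(quotas - base), kind="stable")
    base[order[:rem]] += 1
    return base


def allocate_volumes(
    partition: Partition,
    total: int,
    class_ratio: tuple[float, float] = (1.0, 1.0),
) -> VolumePlan:
    """Split the requested volume across classes, then across subsets.

    ``class_ratio`` is a pair of weights aligned with the target categories
    (negative class first, positive/event class second).  The minority class
    gets ``round(total * w_min / (w_min + w_max))`` rows — e.g. a 1:100 event
    ratio at total 5000 gives round(5000/101) = 50 event rows — and the
    majority the remainder.  Within a class, counts follow the subsets'
    original-data sizes with largest-remainder rounding, so the plan always
    sums exactly to ``total``.
    """
    if total < 2:
        raise GenerationError("total must cover both classes")
    w = np.asarray(class_ratio, dtype=float)
    if len(w) != 2 or (w <= 0).any():
        raise GenerationError("class_ratio must be a pair of positive weights")
    classes = list(zip_target_classes(partition))
    minority_idx = int(np.argmin(w)) if w[0] != w[1] else 1
    n_min = int(round(total * w[minority_idx] / w.sum()))
    class_totals = [0, 0]
    class_totals[minority_idx] = n_min
    class_totals[1 - minority_idx] = total - n_min
    per_subset: dict[str, int] = {}
    for (cls, subs), cls_total in zip(classes, class_totals):
        if not subs:
            raise GenerationError(f"class {cls!r} has no subsets in the partition")
        sizes = np.array([s.n_rows for s in subs], dtype=float)
        counts = _largest_remainder(sizes, cls_total)
        for s, c in zip(subs, counts):
            per_subset[s.key] = int(c)
    logger.info("volume plan: total=%d per-subset=%s", total, per_subset)
    return VolumePlan(total=total, per_subset=per_subset, class_ratio=(float(w[0]), float(w[1])))


def zip_target_classes(partition: Partition):
    """(class, subsets) pairs in schema target-category order."""
    schema = partition.subsets[0].data.schema
    for cls in schema.target_categories:
        yield cls, partition.by_class(cls)


def conquer(
    subset_samples: Sequence[tuple[str, TabularDataset]], seed: int
) -> TabularDataset:
    """Recombine per-subset synthetic tables into one shuffled table."""
    if not subset_samples:
        raise GenerationError("conquer needs at least one subset sample")
    datasets = [d for _, d in subset_samples]
    combined = concat_datasets(datasets)  # raises on schema mismatch
    rng = np.random.default_rng(seed)
    return combined.take(rng.permutation(combined.n_rows))


# ---------------------------------------------------------------------------
# end-to-end generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenerationConfig:
    """Settings of one synthesis run."""

    strategy: str = "dc"          # dc | cs | none
    backend: str = "copula"       # registered backend name
    total: int = 5000
    class_ratio: tuple[float, float] = (1.0, 1.0)
    seed: int = 0
    n_bins: int = DEFAULT_N_BINS
    v_threshold: float = 1.0
    v_tolerance: float = V_TOLERANCE
    min_subset_size: int = DEFAULT_MIN_SUBSET_SIZE
    max_batches: int = 100
    backend_params: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strategy not in ("dc", "cs", "none"):
            raise GenerationError(f"unknown strategy {self.strategy!r}")


def _subset_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % _SEED_MOD) for child in ss.spawn(n)]


def generate_std(
    data: TabularDataset,
    rules: Sequence[LogicalRule] | None = None,
    config: GenerationConfig = GenerationConfig(),
) -> TabularDataset:
    """Generate synthetic tabular data from ``data`` per ``config``.

    ``rules`` defaults to the schema's logical rules; they are consumed only
    by the ``cs`` strategy (the ``dc`` strategy preserves them structurally,
    ``none`` ignores them).
    """
    if rules is None:
        rules = data.schema.rules
    backend = get_backend(config.backend, **dict(config.backend_params))
    if config.strategy == "dc":
        return _generate_dc(data, config, backend)
    model = backend.fit(data)
    if config.strategy == "cs":
        result = rejection_sample(
            model, rules, config.total, config.seed, config.max_batches
        )
        assert isinstance(result, TabularDataset)
        return result
    return backend.sample(model, config.total, config.seed)


def _generate_dc(
    data: TabularDataset, config: GenerationConfig, backend: GeneratorBackend
) -> TabularDataset:
    matrix = cramers_v_matrix(data, config.n_bins)
    pairs = find_division_pairs(matrix, config.v_threshold, config.v_tolerance)
    features: list[tuple[str, tuple[str, str]]] = []
    for pair in pairs:
        feat = derive_division_feature(data, pair)
        if feat not in [f for f, _ in features]:
            features.append((feat, pair))
    criteria = DivisionCriteria(
        target_column=data.schema.target, division_features=tuple(features)
    )
    part = build_partition(data, criteria, config.min_subset_size)
    plan = allocate_volumes(part, config.total, config.class_ratio)
    seeds = _subset_seeds(config.seed, len(part.subsets))
    samples: list[tuple[str, TabularDataset]] = []
    for subset, sub_seed in zip(part.subsets, seeds):
        model = backend.fit(subset.data)
        n = plan.per_subset[subset.key]
        samples.append((subset.key, backend.sample(model, n, sub_seed)))
    return conquer(samples, config.seed)
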