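"""Train-on-synthetic / test-on-real (TSTR) utility evaluation.

Synthetic data is only useful if a classifier trained on it predicts the
real held-out outcome about as well as one trained on the real development
data.  The protocol: stratified 70/30 split of the original table, generate
synthetic data from the development part, fit a classifier on the synthetic
rows (one-hot categoricals, numeric passthrough), score the real validation
rows, and report AUC and macro-F1 as mean (SD) over repeated seeds.

AUC uses the Mann-Whitney formulation — the fraction of (positive, negative)
pairs ranked concordantly, ties counted 1/2 — which equals the trapezoidal
area under the ROC curve.  F1 is macro-averaged over the two classes
(per-class F1 = 2PR/(P+R), undefined-as-0), with positive-class averaging
available.

Classifiers are consumed through an opaque fit/predict_proba contract;
adapters for decision tree, random forest, XGBoost and LightGBM are
provided with fixed small hyperparameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Protocol, Sequence

import numpy as np
from scipy import stats as _sps

from .data_model import TabularDataset

logger = logging.getLogger(__name__)


class UtilityError(ValueError):
    pass


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def stratified_split(
    data: TabularDataset, train_fraction: float, seed: int
) -> tuple[TabularDataset, TabularDataset]:
    """Per-class random split; train size per class = round(fraction * n_class)."""
    if not (0.0 < train_fraction < 1.0):
        raise UtilityError("train_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    tvals = data.target_values
    train_idx: list[np.ndarray] = []
    val_idx: list[np.ndarray] = []
    for cls in data.schema.target_categories:
        idx = np.flatnonzero(tvals == cls)
        if len(idx) < 2:
            raise UtilityError(f"class {cls!r} has fewer than 2 rows; cannot split")
        perm = rng.permutation(idx)
        n_train = int(round(train_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)  # keep both sides non-empty
        train_idx.append(perm[:n_train])
        val_idx.append(perm[n_train:])
    train = data.take(np.sort(np.concatenate(train_idx)))
    val = data.take(np.sort(np.concatenate(val_idx)))
    return train, val


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) statistic."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise UtilityError("labels and scores must have equal length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UtilityError("AUC requires both classes present")
    ranks = _sps.rankdata(s, method="average")
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _binary_f1(tp: int, fp: int, fn: int) -> float:
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def f1(
    labels: Sequence[int], predictions: Sequence[int], average: str = "macro"
) -> float:
    """F1 score; macro-averaged over both classes by default.

    ``average="positive"`` returns the event-class F1 only.  A class with no
    true or predicted members scores 0 (undefined-as-0 convention).
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predictions, dtype=int)
    if y.shape != p.shape:
        raise UtilityError("labels and predictions must have equal length")
    tp = int(((y == 1) & (p == 1)).sum())
    fp = int(((y == 0) & (p == 1)).sum())
    fn = int(((y == 1) & (p == 0)).sum())
    tn = int(((y == 0) & (p == 0)).sum())
    f1_pos = _binary_f1(tp, fp, fn)
    if average == "positive":
        return f1_pos
    if average != "macro":
        raise UtilityError(f"unknown averaging {average!r}")
    f1_neg = _binary_f1(tn, fn, fp)  # negative class: swap roles
    return (f1_pos + f1_neg) / 2.0


# ---------------------------------------------------------------------------
# feature encoding and the classifier contract
# ---------------------------------------------------------------------------

def encode_features(dataset: TabularDataset) -> np.ndarray:
    """One-hot categoricals over the *schema* categories, numerics as-is.

    Encoding is schema-driven, so any two datasets sharing a schema encode
    to aligned design matrices regardless of which categories they realize.
    """
    blocks: list[np.ndarray] = []
    for name in dataset.schema.feature_names:
        col = dataset.schema.column(name)
        values = dataset.column_values(name)
        if col.is_categorical:
            for cat in col.categories:
                blocks.append((values == cat).astype(float))
        else:
            blocks.append(values.astype(float))
    return np.column_stack(blocks) if blocks else np.empty((dataset.n_rows, 0))


def encode_labels(dataset: TabularDataset) -> np.ndarray:
    """0/1 labels; 1 = the schema's positive (event) class."""
    return (dataset.target_values == dataset.schema.positive_class).astype(int)


class Classifier(Protocol):
    def fit(self, X: np.ndarray, y: np.ndarray) -> "Classifier": ...

    def predict_proba(self, X: np.ndarray) -> np.ndarray: ...


#: Fixed small hyperparameters for the four classifier families.
CLASSIFIER_NAMES = ("dt", "rf", "xgb", "lgbm")


def make_classifier(name: str, seed: int) -> Classifier:
    """Instantiate a classifier adapter by family name."""
    if name == "dt":
        from sklearn.tree import DecisionTreeClassifier

        return DecisionTreeClassifier(max_depth=6, random_state=seed)
    if name == "rf":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    if name == "xgb":
        from xgboost import XGBClassifier

        return XGBClassifier(
            n_estimators=100,
            max_depth=4,
            learning_rate=0.1,
            random_state=seed,
            n_jobs=1,
            verbosity=0,
            eval_metric="logloss",
        )
    if name == "lgbm":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(
            n_estimators=100, random_state=seed, n_jobs=1, verbose=-1
        )
    raise UtilityError(f"unknown classifier {name!r}; choose from {CLASSIFIER_NAMES}")


# ---------------------------------------------------------------------------
# TSTR protocol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UtilityResult:
    """Per-seed AUC/F1 with population mean/SD over the repeats."""

    per_seed: tuple[tuple[int, float, float], ...]  # (seed, auc, f1)

    @property
    def mean_auc(self) -> float:
        return float(np.mean([a for _, a, _ in self.per_seed]))

    @property
    def sd_auc(self) -> float:
        return float(np.std([a for _, a, _ in self.per_seed]))  # ddof=0

    @property
    def mean_f1(self) -> float:
        return float(np.mean([f for _, _, f in self.per_seed]))

    @property
    def sd_f1(self) -> float:
        return float(np.std([f for _, _, f in self.per_seed]))

    def to_json(self) -> dict:
        return {
            "per_seed": [
                {"seed": s, "auc": a, "f1": f} for s, a, f in self.per_seed
            ],
            "mean_auc": self.mean_auc,
            "sd_auc": self.sd_auc,
            "mean_f1": self.mean_f1,
            "sd_f1": self.sd_f1,
        }


def evaluate_once(
    train: TabularDataset,
    validation: TabularDataset,
    classifier: Classifier,
    f1_average: str = "macro",
) -> tuple[float, float]:
    """Fit on train, score validation; returns (AUC, F1 at threshold 0.5)."""
    X_train, y_train = encode_features(train), encode_labels(train)
    X_val, y_val = encode_features(validation), encode_labels(validation)
    classifier.fit(X_train, y_train)
    proba = np.asarray(classifier.predict_proba(X_val))
    if proba.ndim == 2:
        classes = getattr(classifier, "classes_", np.array([0, 1]))
        pos_col = int(np.flatnonzero(np.asarray(classes) == 1)[0])
        scores = proba[:, pos_col]
    else:
        scores = proba
    preds = (scores >= 0.5).astype(int)
    return auc(y_val, scores), f1(y_val, preds, average=f1_average)


def tstr_evaluate(
    train: TabularDataset,
    validation: TabularDataset,
    classifier: str | Callable[[int], Classifier],
    seeds: Sequence[int],
    f1_average: str = "macro",
) -> UtilityResult:
    """Repeat fit/score over seeds and aggregate mean (SD).

    ``classifier`` is a family name (``dt``/``rf``/``xgb``/``lgbm``) or a
    factory mapping a seed to a fitted-contract object.
    """
    if train.schema != validation.schema:
        raise UtilityError("train and validation must share a schema")
    factory = (
        (lambda s: make_classifier(classifier, s))
        if isinstance(classifier, str)
        else classifier
    )
    rows = []
    for seed in seeds:
        try:
            a, f = evaluate_once(train, validation, factory(seed), f1_average)
        except Exception as exc:
            raise UtilityError(f"classifier failed at seed {seed}: {exc}") from exc
        rows.append((int(seed), a, f))
    return UtilityResult(per_seed=tuple(rows))


# ---------------------------------------------------------------------------
# full experiment grid (strategies x backends x balances x classifiers)
# ---------------------------------------------------------------------------

def experiment_grid(
    data: TabularDataset,
    rules=None,
    strategies: Sequence[str] = ("dc", "cs", "none"),
    backends: Sequence[str] = ("copula",),
    balances: Sequence[tuple[float, float]] = ((1.0, 1.0), (100.0, 1.0)),
    classifiers: Sequence[str] = CLASSIFIER_NAMES,
    seeds: Sequence[int] = (1, 2, 3, 4, 5),
    total: int = 5000,
    train_fraction: float = 0.7,
    split_seed: int = 0,
    f1_average: str = "macro",
    min_subset_size: int = 50,
):
    """Cross every setting; per cell, mean (SD) utility plus fidelity/violations.

    The original table is split once (stratified, ``train_fraction``); each
    cell generates one synthetic table per seed from the development part,
    trains each classifier on it and scores the real validation part.
    Returns a pandas DataFrame with one row per
    (strategy, backend, balance, classifier).
    """
    import pandas as pd

    from .fidelity import quality_report, violation_report
    from .generate import GenerationConfig, generate_std

    if rules is None:
        rules = data.schema.rules
    dev, val = stratified_split(data, train_fraction, split_seed)
    records = []
    for strategy in strategies:
        for backend in backends:
            for balance in balances:
                stds = []
                for seed in seeds:
                    cfg = GenerationConfig(
                        strategy=strategy,
                        backend=backend,
                        total=total,
                        class_ratio=balance,
                        seed=int(seed),
                        min_subset_size=min_subset_size,
                    )
                    stds.append(generate_std(dev, rules, cfg))
                fidelity_scores = [quality_report(dev, s).overall for s in stds]
                violation_rates = [
                    violation_report(s, rules).violation_rate for s in stds
                ]
                for clf in classifiers:
                    rows = []
                    for seed, std in zip(seeds, stds):
                        a, f = evaluate_once(
                            std, val, make_classifier(clf, int(seed)), f1_average
                        )
                        rows.append((int(seed), a, f))
                    result = UtilityResult(per_seed=tuple(rows))
                    records.append(
                        {
                            "strategy": strategy,
                            "backend": backend,
                            "balance": f"{balance[0]:g}:{balance[1]:g}",
                            "classifier": clf,
                            "mean_auc": result.mean_auc,
                            "sd_auc": result.sd_auc,
                            "mean_f1": result.mean_f1,
                            "sd_f1": result.sd_f1,
                            "mean_overall_fidelity": float(np.mean(fidelity_scores)),
                            "mean_violation_rate": float(np.mean(violation_rates)),
                        }
                    )
    return pd.DataFrame.from_records(records)
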