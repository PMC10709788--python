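import numpy as np
import pandas as pd
import pytest

from dcsdg.data_model import ColumnSchema, LogicalRule, TableSchema, TabularDataset
from dcsdg.fixture import FixtureParams, generate_fixture


def make_dataset(columns, rows, target, rules=()):
    """Build a small validated dataset from literal column specs and rows.

    ``columns``: list of (name, kind, categories-or-None[, role]) tuples;
    ``rows``: list of per-row value tuples in column order.
    """
    schemas = []
    for spec in columns:
        name, kind, cats = spec[:3]
        role = spec[3] if len(spec) > 3 else ("target" if name == target else "feature")
        schemas.append(
            ColumnSchema(name, kind, tuple(cats) if cats else None, role=role)
        )
    schema = TableSchema(tuple(schemas), target=target, rules=tuple(rules))
    frame = pd.DataFrame(rows, columns=[c.name for c in schemas])
    return TabularDataset(schema, frame)


@pytest.fixture(scope="session")
def small_fixture():
    """Planted-structure table, n=400, plus its rules and truth record."""
    return generate_fixture(FixtureParams(n=400, seed=11))


@pytest.fixture(scope="session")
def medium_fixture():
    """Planted-structure table at the registry development-group scale."""
    return generate_fixture(FixtureParams(n=1616, seed=11))


@pytest.fixture(scope="session")
def toy_conditional():
    """Uniform 4-cell table: smoker x categorical pack-years, no dependence.

    The rule smoker == "no" => pack_years == "0" rejects exactly one of the
    four equiprobable cells, so rejection sampling accepts with probability
    3/4.
    """
    rule = LogicalRule("smoker", "no", "pack_years", "0")
    data = make_dataset(
        [
            ("smoker", "categorical", ("no", "yes")),
            ("pack_years", "categorical", ("0", "10")),
            ("outcome", "categorical", ("a", "b")),
        ],
        [
            ("no", "0", "a"),
            ("no", "10", "b"),
            ("yes", "0", "a"),
            ("yes", "10", "b"),
        ],
        target="outcome",
    )
    return data, rule
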