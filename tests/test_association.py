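import itertools

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from dcsdg.association import (
    AssociationError,
    ContingencyTable,
    NumericBinner,
    chi_square_statistic,
    contingency_table,
    cramers_v,
    cramers_v_matrix,
    crosstab,
    discretize_numeric,
    find_division_pairs,
)

from .conftest import make_dataset


def table(counts):
    counts = np.asarray(counts, dtype=np.int64)
    return ContingencyTable(
        counts=counts,
        row_labels=tuple(f"r{i}" for i in range(counts.shape[0])),
        col_labels=tuple(f"c{j}" for j in range(counts.shape[1])),
    )


def brute_force_cramers_v(counts):
    """Independent oracle: expected counts cell by cell, then the V formula."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    chi2 = 0.0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            expected = counts[i].sum() * counts[:, j].sum() / n
            chi2 += (counts[i, j] - expected) ** 2 / expected
    r, c = counts.shape
    if r < 2 or c < 2:
        return 0.0
    return min(1.0, np.sqrt(chi2 / (n * min(r - 1, c - 1))))


def random_tables(n_tables, max_dim=6, seed=0):
    rng = np.random.default_rng(seed)
    for _ in range(n_tables):
        r = rng.integers(2, max_dim + 1)
        c = rng.integers(2, max_dim + 1)
        # +1 guarantees positive marginals
        yield rng.integers(0, 40, size=(r, c)) + 1


class TestChiSquare:
    def test_perfect_independence_is_zero(self):
        assert chi_square_statistic(table([[5, 5], [5, 5]])) == pytest.approx(0.0)

    def test_perfect_association_2x2_equals_n(self):
        assert chi_square_statistic(table([[10, 0], [0, 10]])) == pytest.approx(20.0)

    def test_2x2_closed_form(self):
        # N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) = 50 * 375^2 / 390625 = 18
        assert chi_square_statistic(table([[20, 5], [5, 20]])) == pytest.approx(18.0)

    def test_matches_scipy_without_correction(self):
        for counts in random_tables(50, seed=1):
            expected = chi2_contingency(counts, correction=False).statistic
            assert chi_square_statistic(table(counts)) == pytest.approx(
                expected, abs=1e-9
            )

    def test_zero_marginal_is_an_error(self):
        with pytest.raises(AssociationError):
            chi_square_statistic(table([[5, 0], [5, 0]]))


class TestCramersV:
    def test_complete_association_is_one(self):
        assert cramers_v(table([[10, 0], [0, 10]])) == pytest.approx(1.0)

    def test_no_association_is_zero(self):
        assert cramers_v(table([[5, 5], [5, 5]])) == pytest.approx(0.0)

    def test_worked_2x2_value(self):
        # sqrt(18 / (50 * min(1, 1))) = 0.6
        assert cramers_v(table([[20, 5], [5, 20]])) == pytest.approx(0.6, abs=1e-12)

    def test_matches_brute_force_oracle(self):
        for counts in random_tables(200, seed=2):
            assert cramers_v(table(counts)) == pytest.approx(
                brute_force_cramers_v(counts), abs=1e-12
            )

    def test_single_category_dimension_defined_as_zero(self):
        assert cramers_v(table([[3, 7]])) == 0.0

    def test_invariant_under_permutation(self):
        rng = np.random.default_rng(3)
        for counts in random_tables(30, seed=4):
            v = cramers_v(table(counts))
            permuted = counts[rng.permutation(counts.shape[0])][
                :, rng.permutation(counts.shape[1])
            ]
            assert cramers_v(table(permuted)) == pytest.approx(v, abs=1e-12)

    def test_invariant_under_duplication(self):
        for counts in random_tables(30, seed=5):
            v = cramers_v(table(counts))
            assert cramers_v(table(counts * 2)) == pytest.approx(v, abs=1e-12)

    def test_bounded_and_one_iff_single_nonzero_per_row(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            r = rng.integers(2, 5)
            c = rng.integers(r, 7)  # r <= c
            counts = np.zeros((r, c), dtype=np.int64)
            for i in range(r):  # one nonzero cell per row
                counts[i, rng.integers(0, c)] += rng.integers(1, 30)
            # drop all-zero columns before tabulating
            counts = counts[:, counts.sum(axis=0) > 0]
            if counts.shape[1] < 2:
                continue
            assert cramers_v(table(counts)) == pytest.approx(1.0, abs=1e-12)
        for counts in random_tables(50, seed=7):
            v = cramers_v(table(counts))
            assert 0.0 <= v <= 1.0
            per_row_nonzero = (counts > 0).sum(axis=1)
            if (per_row_nonzero > 1).any():
                assert v < 1.0


class TestContingencyTable:
    def test_count_bookkeeping(self):
        rows = [("y" if i < 10 else "n", "a" if i % 2 else "b", "alive")
                for i in range(20)]
        data = make_dataset(
            [("u", "categorical", ("y", "n")), ("v", "categorical", ("a", "b")),
             ("outcome", "categorical", ("alive", "dead"))],
            rows, target="outcome",
        )
        t = contingency_table(data, "u", "v")
        assert t.counts.sum() == 20
        assert t.counts.shape == (2, 2)

    def test_single_observed_category_gives_one_row(self):
        data = make_dataset(
            [("u", "categorical", ("y", "n")), ("v", "categorical", ("a", "b")),
             ("outcome", "categorical", ("alive", "dead"))],
            [("y", "a", "alive"), ("y", "b", "alive")], target="outcome",
        )
        t = contingency_table(data, "u", "v")
        assert t.r == 1 and t.c == 2

    def test_numeric_column_rejected(self, small_fixture):
        data, _, _ = small_fixture
        with pytest.raises(AssociationError):
            contingency_table(data, "smoker", "pack_years")

    def test_planted_rule_yields_block_structure(self, small_fixture):
        data, _, _ = small_fixture
        binned = discretize_numeric(data.column_values("pack_years"), 10)
        t = crosstab(data.column_values("smoker"), binned)
        # direct counting oracle: the zero bin holds exactly the non-smokers
        n_nonsmoker = (data.column_values("smoker") == "no").sum()
        zero_col = t.col_labels.index("0")
        assert t.counts[:, zero_col].sum() == n_nonsmoker
        # every column is pure: no bin mixes smokers and non-smokers
        assert (np.count_nonzero(t.counts, axis=0) == 1).all()


class TestDiscretize:
    def test_point_mass_gets_dedicated_bin(self):
        values = [0, 0, 0, 0, 12, 30, 45, 60]
        labels = discretize_numeric(values, n_bins=4)
        assert set(labels[:4]) == {"0"}
        assert "0" not in set(labels[4:])
        assert len(set(labels[4:])) == 4  # positives quantile-binned

    def test_equal_frequency_on_distinct_values(self):
        values = np.arange(100, dtype=float)
        labels = discretize_numeric(values, n_bins=4)
        _, counts = np.unique(labels, return_counts=True)
        assert sorted(counts.tolist()) == [25, 25, 25, 25]

    def test_constant_column_is_single_bin(self):
        labels = discretize_numeric([7.0] * 10, n_bins=4)
        assert set(labels) == {"7"}

    def test_binner_reusable_on_new_values(self):
        binner = NumericBinner.fit([0, 0, 0, 0, 10, 20, 30, 40], n_bins=4)
        out = binner.transform([0, 15, 1000])
        assert out[0] == "0"
        assert out[2] == binner.interval_labels[-1]  # clamped into last bin


class TestMatrixAndDivisionPairs:
    def test_planted_pair_scores_one(self, medium_fixture):
        data, _, _ = medium_fixture
        matrix = cramers_v_matrix(data)
        assert matrix.get("smoker", "pack_years") == pytest.approx(1.0, abs=1e-9)

    def test_matrix_symmetric_with_unit_diagonal(self, small_fixture):
        data, _, _ = small_fixture
        matrix = cramers_v_matrix(data)
        assert np.allclose(matrix.values, matrix.values.T)
        assert np.allclose(np.diag(matrix.values), 1.0)
        assert (matrix.values >= 0).all() and (matrix.values <= 1).all()

    def test_independent_columns_score_near_zero(self):
        rng = np.random.default_rng(8)
        n = 5000
        rows = list(zip(
            rng.choice(["a", "b", "c"], n),
            rng.normal(size=n),
            rng.choice(["alive", "dead"], n),
        ))
        data = make_dataset(
            [("u", "categorical", ("a", "b", "c")), ("x", "numeric", None),
             ("outcome", "categorical", ("alive", "dead"))],
            rows, target="outcome",
        )
        matrix = cramers_v_matrix(data)
        off = matrix.values[~np.eye(3, dtype=bool)]
        assert (off < 0.1).all()
        assert find_division_pairs(matrix) == []

    def test_fixture_division_pair_found(self, medium_fixture):
        data, _, _ = medium_fixture
        pairs = find_division_pairs(cramers_v_matrix(data))
        assert pairs == [("pack_years", "smoker")]

    def test_threshold_domain_checked(self, small_fixture):
        data, _, _ = small_fixture
        matrix = cramers_v_matrix(data)
        with pytest.raises(AssociationError):
            find_division_pairs(matrix, threshold=0.0)
        with pytest.raises(AssociationError):
            find_division_pairs(matrix, threshold=1.5)
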