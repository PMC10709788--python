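from collections import Counter

import numpy as np
import pytest
from scipy import stats

from dcsdg.data_model import LogicalRule
from dcsdg.fidelity import violation_report
from dcsdg.generate import (
    GenerationConfig,
    GenerationError,
    RejectionError,
    allocate_volumes,
    conquer,
    fit_copula,
    fit_independent,
    generate_std,
    rejection_sample,
    sample_copula,
    sample_independent,
)
from dcsdg.partition import DivisionCriteria, build_partition

from .conftest import make_dataset


def bivariate_dataset(rho, n=5000, seed=0):
    """Two numerics with Gaussian-copula dependence rho, plus a target."""
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal([0, 0], cov, size=n)
    rows = [
        (float(z[i, 0]), float(np.exp(z[i, 1])), "n" if i % 2 else "y")
        for i in range(n)
    ]
    return make_dataset(
        [("x", "numeric", None), ("y", "numeric", None),
         ("outcome", "categorical", ("n", "y"))],
        rows, target="outcome",
    )


class TestCopulaFit:
    def test_categorical_intervals_match_frequencies(self):
        rows = [("yes", "n")] * 7 + [("no", "y")] * 3
        data = make_dataset(
            [("smoker", "categorical", ("yes", "no")),
             ("outcome", "categorical", ("n", "y"))],
            rows, target="outcome",
        )
        model = fit_copula(data)
        marg = model.marginals["smoker"]
        assert marg.probs == pytest.approx([0.7, 0.3])
        assert marg.cum == pytest.approx([0.7, 1.0])

    def test_dependence_close_to_rank_correlation(self):
        data = bivariate_dataset(rho=0.9)
        model = fit_copula(data)
        spearman = stats.spearmanr(
            data.column_values("x"), data.column_values("y")
        ).statistic
        i = model.columns.index("x")
        j = model.columns.index("y")
        assert model.dependence[i, j] == pytest.approx(spearman, abs=0.05)

    def test_empty_subset_rejected(self, small_fixture):
        data, _, _ = small_fixture
        with pytest.raises(GenerationError):
            fit_copula(data.select(np.zeros(data.n_rows, dtype=bool)))

    def test_single_row_degenerates_to_replication(self):
        data = make_dataset(
            [("x", "numeric", None), ("outcome", "categorical", ("n", "y"))],
            [(3.5, "y")], target="outcome",
        )
        sample = sample_copula(fit_copula(data), 10, seed=0)
        assert (sample.column_values("x") == 3.5).all()
        assert (sample.column_values("outcome") == "y").all()


class TestCopulaSampling:
    def test_constant_column_propagates_exactly(self, small_fixture):
        data, _, _ = small_fixture
        criteria = DivisionCriteria(
            "adverse_event", (("smoker", ("pack_years", "smoker")),)
        )
        part = build_partition(data, criteria, 1)
        nonsmoker = next(
            s for s in part.subsets
            if s.label == {"adverse_event": "no", "smoker": "no"}
        )
        sample = sample_copula(fit_copula(nonsmoker.data), 500, seed=1)
        assert (sample.column_values("smoker") == "no").all()
        assert (sample.column_values("pack_years") == 0.0).all()

    def test_sampling_is_deterministic_per_seed(self, small_fixture):
        data, _, _ = small_fixture
        model = fit_copula(data)
        a = sample_copula(model, 200, seed=42)
        b = sample_copula(model, 200, seed=42)
        c = sample_copula(model, 200, seed=43)
        assert a == b
        assert a != c

    def test_zero_rows_requested(self, small_fixture):
        data, _, _ = small_fixture
        sample = sample_copula(fit_copula(data), 0, seed=0)
        assert sample.n_rows == 0
        assert sample.schema == data.schema

    def test_numeric_samples_confined_to_training_range(self, small_fixture):
        data, _, _ = small_fixture
        sample = sample_copula(fit_copula(data), 2000, seed=2)
        for name in data.schema.numeric_names:
            train = data.column_values(name)
            assert sample.column_values(name).min() >= train.min()
            assert sample.column_values(name).max() <= train.max()

    def test_marginal_recovery_at_n5000(self, medium_fixture):
        data, _, _ = medium_fixture
        sample = sample_copula(fit_copula(data), 5000, seed=3)
        from dcsdg.fidelity import kss, tvd

        for name in data.schema.numeric_names:
            assert kss(data.column_values(name), sample.column_values(name)) <= 0.05
        for name in data.schema.categorical_names:
            assert tvd(data.column_values(name), sample.column_values(name)) <= 0.05

    def test_dependence_recovery_at_n5000(self):
        data = bivariate_dataset(rho=0.85, seed=4)
        sample = sample_copula(fit_copula(data), 5000, seed=5)
        s_train = stats.spearmanr(
            data.column_values("x"), data.column_values("y")
        ).statistic
        s_sample = stats.spearmanr(
            sample.column_values("x"), sample.column_values("y")
        ).statistic
        assert s_sample == pytest.approx(s_train, abs=0.05)


class TestIndependentBaseline:
    def test_destroys_correlation(self):
        data = bivariate_dataset(rho=0.95, seed=6)
        sample = sample_independent(fit_independent(data), 5000, seed=7)
        rho = np.corrcoef(
            sample.column_values("x"), sample.column_values("y")
        )[0, 1]
        assert abs(rho) < 0.05

    def test_preserves_marginal_frequencies(self):
        rows = [("a", "n")] * 600 + [("b", "n")] * 300 + [("c", "y")] * 100
        data = make_dataset(
            [("g", "categorical", ("a", "b", "c")),
             ("outcome", "categorical", ("n", "y"))],
            rows, target="outcome",
        )
        sample = sample_independent(fit_independent(data), 5000, seed=8)
        observed = Counter(sample.column_values("g"))
        expected = {"a": 3000, "b": 1500, "c": 500}
        chi2 = sum(
            (observed[k] - expected[k]) ** 2 / expected[k] for k in expected
        )
        # df=2; 13.8 is the 0.1% point — fails only under gross distortion
        assert chi2 < 13.8


class TestRejectionSampling:
    def test_four_cell_acceptance_rate(self, toy_conditional):
        data, rule = toy_conditional
        model = fit_independent(data)
        out, info = rejection_sample(
            model, [rule], 20000, seed=5, max_batches=50, return_stats=True
        )
        assert out.n_rows == 20000
        assert violation_report(out, [rule]).violation_rate == 0.0
        assert info.acceptance_rate == pytest.approx(0.75, abs=0.02)

    def test_no_rules_is_plain_sampling(self, toy_conditional):
        data, _ = toy_conditional
        model = fit_independent(data)
        out, info = rejection_sample(
            model, [], 100, seed=6, return_stats=True
        )
        assert out.n_rows == 100
        assert info.acceptance_rate == 1.0

    def test_unsatisfiable_rule_raises_with_acceptance_rate(self, toy_conditional):
        data, _ = toy_conditional
        model = fit_independent(data)
        impossible = LogicalRule("smoker", "yes", "pack_years", "0")
        also = LogicalRule("smoker", "no", "pack_years", "10")
        strict = [
            impossible, also,
            LogicalRule("smoker", "yes", "pack_years", "10"),
            LogicalRule("smoker", "no", "pack_years", "0"),
        ]
        with pytest.raises(RejectionError) as err:
            rejection_sample(model, strict, 100, seed=7, max_batches=3)
        assert err.value.acceptance_rate == 0.0


class TestVolumeAllocation:
    def _partition(self, small_fixture):
        data, _, _ = small_fixture
        criteria = DivisionCriteria(
            "adverse_event", (("smoker", ("pack_years", "smoker")),)
        )
        return build_partition(data, criteria, 1)

    def test_balanced_totals(self, small_fixture):
        plan = allocate_volumes(self._partition(small_fixture), 5000, (1.0, 1.0))
        by_class = {"no": 0, "yes": 0}
        for key, n in plan.per_subset.items():
            by_class[key.split("|")[0].split("=")[1]] += n
        assert by_class == {"no": 2500, "yes": 2500}

    def test_imbalanced_minority_rounding(self, small_fixture):
        plan = allocate_volumes(self._partition(small_fixture), 5000, (100.0, 1.0))
        by_class = {"no": 0, "yes": 0}
        for key, n in plan.per_subset.items():
            by_class[key.split("|")[0].split("=")[1]] += n
        assert by_class["yes"] == 50  # round(5000 / 101)
        assert by_class["no"] == 4950

    def test_proportional_within_class(self):
        rows = [("a", "n")] * 300 + [("b", "n")] * 100 + [("a", "y")] * 10
        data = make_dataset(
            [("g", "categorical", ("a", "b")),
             ("outcome", "categorical", ("n", "y"))],
            rows, target="outcome",
        )
        part = build_partition(
            data, DivisionCriteria("outcome", (("g", ("g", "x")),)), 1
        )
        plan = allocate_volumes(part, 2000, (1.0, 1.0))
        assert plan.per_subset["outcome=n|g=a"] == 750
        assert plan.per_subset["outcome=n|g=b"] == 250

    def test_total_conserved_for_any_inputs(self, small_fixture):
        part = self._partition(small_fixture)
        rng = np.random.default_rng(10)
        for _ in range(50):
            total = int(rng.integers(2, 9999))
            w = (float(rng.integers(1, 200)), float(rng.integers(1, 200)))
            plan = allocate_volumes(part, total, w)
            assert sum(plan.per_subset.values()) == total


class TestConquer:
    def test_sizes_add_up_and_rows_are_shuffled(self, small_fixture):
        data, _, _ = small_fixture
        model = fit_copula(data)
        a = sample_copula(model, 2500, seed=1)
        b = sample_copula(model, 2500, seed=2)
        combined = conquer([("a", a), ("b", b)], seed=3)
        assert combined.n_rows == 5000

    def test_single_part_is_permutation(self, small_fixture):
        data, _, _ = small_fixture
        out = conquer([("all", data)], seed=4)
        assert Counter(map(tuple, out.frame.itertuples(index=False))) == Counter(
            map(tuple, data.frame.itertuples(index=False))
        )
        assert not out.frame.equals(data.frame)  # order actually changed

    def test_empty_list_rejected(self):
        with pytest.raises(GenerationError):
            conquer([], seed=0)

    def test_schema_mismatch_rejected(self, small_fixture, toy_conditional):
        data, _, _ = small_fixture
        toy, _ = toy_conditional
        with pytest.raises(Exception, match="schema"):
            conquer([("a", data), ("b", toy)], seed=0)


class TestEndToEnd:
    def test_dc_balanced_run(self, medium_fixture):
        data, rules, _ = medium_fixture
        std = generate_std(
            data, rules, GenerationConfig(strategy="dc", total=5000, seed=1)
        )
        assert std.n_rows == 5000
        assert violation_report(std, rules).violation_rate == 0.0
        assert Counter(std.target_values) == {"no": 2500, "yes": 2500}

    def test_unconstrained_whole_table_fit_violates_rules(self, medium_fixture):
        data, rules, _ = medium_fixture
        std = generate_std(
            data, rules, GenerationConfig(strategy="none", total=5000, seed=1)
        )
        assert violation_report(std, rules).violation_rate > 0.0

    def test_conditional_sampling_satisfies_rules(self, medium_fixture):
        data, rules, _ = medium_fixture
        std = generate_std(
            data, rules, GenerationConfig(strategy="cs", total=2000, seed=1)
        )
        assert std.n_rows == 2000
        assert violation_report(std, rules).violation_rate == 0.0

    def test_identical_seeds_identical_outputs(self, small_fixture):
        data, rules, _ = small_fixture
        cfg = GenerationConfig(strategy="dc", total=500, seed=9)
        assert generate_std(data, rules, cfg) == generate_std(data, rules, cfg)
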