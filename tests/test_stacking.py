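import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grnstack.diagnostics import complementary_oracle_table
from grnstack.exceptions import (
    ConfigError,
    ContractError,
    DegenerateTrainingError,
    SplitError,
)
from grnstack.level1 import EdgeScoreTable
from grnstack.stacking import (
    FeatureTable,
    GaussianNaiveBayes,
    assemble_features,
    average_rank_baseline,
    fit_level2,
    kurtosis_filter,
    predict_level2,
    rank_normalize,
    tf_disjoint_split,
    tune_hyperparameters,
)

from conftest import universe_for


def table_from_columns(universe, **columns):
    names = list(columns.keys())
    return EdgeScoreTable(
        universe=universe,
        method_names=names,
        scores=np.column_stack([np.asarray(columns[n], dtype=float) for n in names]),
    )


class TestSplit:
    def test_counts_six_regulators(self):
        split = tf_disjoint_split([f"r{i}" for i in range(6)], seed=0)
        assert len(split.train_tfs) == 4 and len(split.test_tfs) == 2
        assert not split.train_tfs & split.test_tfs

    def test_counts_twenty_nine_regulators(self):
        split = tf_disjoint_split([f"r{i}" for i in range(29)], seed=1)
        assert len(split.train_tfs) == 19 and len(split.test_tfs) == 10

    def test_deterministic_and_covering(self):
        regs = [f"r{i}" for i in range(7)]
        assert tf_disjoint_split(regs, seed=5) == tf_disjoint_split(regs, seed=5)
        seen_in_test = set()
        for seed in range(50):
            seen_in_test |= tf_disjoint_split(regs, seed=seed).test_tfs
        assert seen_in_test == set(regs)

    def test_too_few_regulators(self):
        with pytest.raises(SplitError):
            tf_disjoint_split(["only"], seed=0)

    def test_bad_ratio(self):
        with pytest.raises(ConfigError):
            tf_disjoint_split(["a", "b", "c"], ratio=1.5, seed=0)


class TestKurtosisFilter:
    def test_uniform_dropped_laplace_retained(self):
        rng = np.random.default_rng(0)
        n = 20_000
        uni = universe_for([f"t{i}" for i in range(n // 2)], ["r1", "r2"])
        assert uni.n_edges == n
        table = table_from_columns(
            uni,
            flat=rng.uniform(0, 1, n),
            heavy=rng.laplace(0, 1, n),
        )
        retained, kurt = kurtosis_filter(table)
        assert retained == ["heavy"]
        assert kurt["flat"] == pytest.approx(-1.2, abs=0.1)
        assert kurt["heavy"] == pytest.approx(3.0, abs=0.3)

    def test_constant_column_dropped_with_warning(self, caplog):
        rng = np.random.default_rng(1)
        uni = universe_for([f"t{i}" for i in range(50)], ["r1"])
        table = table_from_columns(
            uni, const=np.full(uni.n_edges, 0.5), heavy=rng.laplace(size=uni.n_edges)
        )
        with caplog.at_level("WARNING"):
            retained, kurt = kurtosis_filter(table)
        assert retained == ["heavy"]
        assert math.isnan(kurt["const"])
        assert "zero variance" in caplog.text

    def test_fallback_retains_all_when_none_positive(self, caplog):
        rng = np.random.default_rng(2)
        uni = universe_for([f"t{i}" for i in range(500)], ["r1"])
        table = table_from_columns(
            uni,
            flat1=rng.uniform(size=uni.n_edges),
            flat2=rng.uniform(size=uni.n_edges),
        )
        with caplog.at_level("WARNING"):
            retained, _ = kurtosis_filter(table)
        assert retained == ["flat1", "flat2"]
        assert "retaining all" in caplog.text

    def test_filter_ignores_labels(self):
        """Kurtosis decisions depend only on score distributions (no leakage)."""
        rng = np.random.default_rng(3)
        uni1 = universe_for([f"t{i}" for i in range(300)], ["r1"])
        col = rng.laplace(size=uni1.n_edges)
        import dataclasses

        uni2 = dataclasses.replace(uni1, labels=1 - uni1.labels)
        r1, k1 = kurtosis_filter(table_from_columns(uni1, m=col))
        r2, k2 = kurtosis_filter(table_from_columns(uni2, m=col))
        assert r1 == r2 and k1 == k2


class TestAssembleFeatures:
    @pytest.fixture()
    def six_edge_setup(self):
        uni = universe_for(["t1", "t2", "t3"], ["rA", "rB"],
                           gold_edges=[("rA", "t1"), ("rB", "t2")])
        return uni

    def test_rank_normalization_values(self, six_edge_setup):
        uni = six_edge_setup
        table = table_from_columns(uni, m=[3, 1, 2, 6, 5, 4])
        split = tf_disjoint_split(["rA", "rB"], ratio=0.5, seed=0)
        ft_train = assemble_features(table, ["m"], uni, split, "train")
        ft_test = assemble_features(table, ["m"], uni, split, "test")
        all_vals = np.concatenate([ft_train.X[:, 0], ft_test.X[:, 0]])
        assert sorted(all_vals) == pytest.approx(
            [1 / 6, 2 / 6, 3 / 6, 4 / 6, 5 / 6, 1.0]
        )

    def test_tied_scores_get_average_ranks(self):
        assert rank_normalize(np.array([5.0, 5.0, 1.0])) == pytest.approx(
            [5 / 6, 5 / 6, 1 / 3]
        )
        assert rank_normalize(np.array([3.0, 1.0, 2.0])) == pytest.approx(
            [1.0, 1 / 3, 2 / 3]
        )

    def test_rows_restricted_to_split_side(self, six_edge_setup):
        uni = six_edge_setup
        table = table_from_columns(uni, m=np.arange(uni.n_edges))
        split = tf_disjoint_split(["rA", "rB"], ratio=0.5, seed=0)
        ft = assemble_features(table, ["m"], uni, split, "train")
        assert {r for r, _ in ft.edges} == set(split.train_tfs)
        assert ft.labels is not None and len(ft.labels) == ft.n_rows
        ft_test = assemble_features(table, ["m"], uni, split, "test")
        assert ft_test.labels is None

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(-1000, 1000), min_size=3, max_size=40)
    )
    def test_rank_normalize_invariant_to_monotone_transform(self, raw):
        col = np.asarray(raw, dtype=float)
        assert rank_normalize(np.exp(col / 500)) == pytest.approx(
            rank_normalize(col), abs=1e-12
        )


class TestGaussianNaiveBayes:
    def bayes_oracle(self, x, mu, var, priors):
        """Closed-form two-class posterior from explicit Gaussian densities."""

        def pdf(x, m, v):
            return math.exp(-((x - m) ** 2) / (2 * v)) / math.sqrt(2 * math.pi * v)

        like = [priors[c] * pdf(x, mu[c], var[c]) for c in (0, 1)]
        return like[1] / (like[0] + like[1])

    def test_posterior_matches_closed_form(self):
        X = np.array([[0.1], [0.2], [0.8], [0.9]])
        y = np.array([0, 0, 1, 1])
        model = GaussianNaiveBayes().fit(X, y)
        # population-variance fits: mean 0.15/0.85, var 0.0025 each
        assert model.means_[:, 0] == pytest.approx([0.15, 0.85], abs=1e-12)
        assert model.variances_[:, 0] == pytest.approx([0.0025, 0.0025], abs=1e-11)
        got = model.predict_proba(np.array([[0.85]]))[0, 1]
        want = self.bayes_oracle(0.85, {0: 0.15, 1: 0.85},
                                 {0: 0.0025, 1: 0.0025}, {0: 0.5, 1: 0.5})
        assert got == pytest.approx(want, abs=1e-9)
        assert got > 0.5

    def test_identical_class_conditionals_give_prior(self):
        X = np.array([[0.2], [0.8], [0.2], [0.8], [0.2], [0.8]])
        y = np.array([0, 0, 0, 0, 1, 1])
        model = GaussianNaiveBayes().fit(X, y)
        post = model.predict_proba(np.array([[0.1], [0.5], [0.9]]))[:, 1]
        assert post == pytest.approx([1 / 3, 1 / 3, 1 / 3], abs=1e-12)

    def test_agrees_with_sklearn_reference(self):
        """Independent cross-check against sklearn's Gaussian NB."""
        from sklearn.naive_bayes import GaussianNB

        rng = np.random.default_rng(4)
        X = rng.uniform(size=(200, 3))
        y = (X[:, 0] + 0.3 * rng.normal(size=200) > 0.5).astype(int)
        ours = GaussianNaiveBayes().fit(X, y).predict_proba(X)[:, 1]
        ref = GaussianNB(var_smoothing=1e-12).fit(X, y).predict_proba(X)[:, 1]
        assert ours == pytest.approx(ref, abs=1e-6)

    def test_single_class_raises(self):
        with pytest.raises(DegenerateTrainingError):
            GaussianNaiveBayes().fit(np.array([[0.1], [0.2]]), np.array([1, 1]))


class TestLevel2ModelZoo:
    @pytest.fixture()
    def train_test(self):
        table = complementary_oracle_table(n_tfs=20, n_targets=15, seed=3)
        uni = table.universe
        split = tf_disjoint_split(sorted(uni.regulators), seed=0)
        train = assemble_features(table, table.method_names, uni, split, "train")
        test = assemble_features(table, table.method_names, uni, split, "test")
        return train, test

    @pytest.mark.parametrize(
        "kind",
        ["voting", "logistic", "logistic_sgd", "naive_bayes", "svm", "knn",
         "random_forest", "adaboost", "gradient_boost"],
    )
    def test_all_kinds_emit_unit_interval_confidences(self, kind, train_test):
        train, test = train_test
        model = fit_level2(kind, train, seed=0)
        scores = predict_level2(model, test)
        assert scores.shape == (test.n_rows,)
        assert np.all((scores >= 0) & (scores <= 1))

    def test_voting_needs_no_fit_and_is_monotone_in_votes(self):
        uni = universe_for([f"t{i}" for i in range(10)], ["r"])
        X = np.tile(np.linspace(0.05, 0.95, uni.n_edges - 1), (3, 1)).T
        # edge 0: top decile by 2 of 3 methods; edge 1: by 1 method
        two_votes = np.array([0.95, 0.95, 0.1])
        one_vote = np.array([0.95, 0.5, 0.1])
        ft = FeatureTable(
            edges=uni.edges[:2],
            X=np.vstack([two_votes, one_vote]),
            method_names=["m1", "m2", "m3"],
        )
        model = fit_level2("voting", ft)
        assert model.estimator is None
        s = predict_level2(model, ft)
        assert s[0] > s[1]
        assert s == pytest.approx([2 / 3, 1 / 3])

    def test_prediction_permutes_with_row_order(self, train_test):
        train, test = train_test
        model = fit_level2("naive_bayes", train)
        scores = predict_level2(model, test)
        perm = np.random.default_rng(0).permutation(test.n_rows)
        test_perm = FeatureTable(
            edges=tuple(test.edges[i] for i in perm),
            X=test.X[perm],
            method_names=test.method_names,
        )
        assert predict_level2(model, test_perm) == pytest.approx(scores[perm])

    def test_column_mismatch_is_contract_error(self, train_test):
        train, test = train_test
        model = fit_level2("logistic", train)
        bad = FeatureTable(
            edges=test.edges, X=test.X, method_names=["oracle_a", "other"]
        )
        with pytest.raises(ContractError, match="missing"):
            predict_level2(model, bad)

    def test_single_class_training_raises_except_voting(self, train_test):
        train, _ = train_test
        degenerate = FeatureTable(
            edges=train.edges,
            X=train.X,
            method_names=train.method_names,
            labels=np.zeros(train.n_rows, dtype=np.int8),
        )
        with pytest.raises(DegenerateTrainingError):
            fit_level2("logistic", degenerate)
        assert fit_level2("voting", degenerate).kind == "voting"

    def test_stacking_beats_both_oracle_columns(self):
        """Complementary-oracle property: every trained kind combines two
        half-informative columns into a strictly better test ranking."""
        from grnstack.evaluation import auprc

        table = complementary_oracle_table(seed=7)
        uni = table.universe
        split = tf_disjoint_split(sorted(uni.regulators), seed=11)
        edge_regs = np.array([r for r, _ in uni.edges])
        mask = np.isin(edge_regs, list(split.test_tfs))
        y = uni.labels[mask]
        single_best = max(
            auprc(table.column(m)[mask], y) for m in table.method_names
        )
        train = assemble_features(table, table.method_names, uni, split, "train")
        test = assemble_features(table, table.method_names, uni, split, "test")
        for kind in ["logistic", "logistic_sgd", "naive_bayes", "svm", "knn",
                     "random_forest", "adaboost", "gradient_boost"]:
            model = fit_level2(kind, train, seed=1)
            assert auprc(predict_level2(model, test), y) > single_best, kind


class TestAverageRank:
    def test_identical_rankings_preserved(self):
        uni = universe_for([f"t{i}" for i in range(5)], ["r"])
        raw = np.array([0.9, 0.1, 0.5, 0.3, 0.7])
        table = table_from_columns(uni, a=raw, b=raw * 10)
        out = average_rank_baseline(table, ["a", "b"])
        assert np.argsort(-out).tolist() == np.argsort(-raw).tolist()

    def test_reversed_rankings_tie_everything(self):
        uni = universe_for(["t1", "t2", "t3"], ["r"])
        table = table_from_columns(uni, a=[3.0, 2.0, 1.0], b=[1.0, 2.0, 3.0])
        out = average_rank_baseline(table, ["a", "b"])
        assert np.ptp(out) == pytest.approx(0.0, abs=1e-12)

    def test_majority_ranking_wins_against_adversary(self):
        """Brute-force check on 5 edges: two agreeing methods outvote one
        reversed method in the average rank."""
        uni = universe_for([f"t{i}" for i in range(5)], ["r"])
        agree = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        table = table_from_columns(
            uni, a=agree, b=agree * 2, c=agree[::-1].copy()
        )
        out = average_rank_baseline(table, ["a", "b", "c"])
        # independent brute-force average of per-method ranks
        ranks = np.column_stack(
            [rank_normalize(agree), rank_normalize(agree * 2),
             rank_normalize(agree[::-1].copy())]
        ).mean(axis=1)
        assert out == pytest.approx(ranks, abs=1e-12)
        assert np.argsort(-out).tolist() == [0, 1, 2, 3, 4]


class TestTuning:
    def make_table(self, n_tfs=8, n_targets=5, seed=0):
        table = complementary_oracle_table(n_tfs=n_tfs, n_targets=n_targets, seed=seed)
        uni = table.universe
        return FeatureTable(
            edges=uni.edges,
            X=np.column_stack(
                [rank_normalize(table.column(m)) for m in table.method_names]
            ),
            method_names=table.method_names,
            labels=uni.labels,
        )

    def test_empty_grid_returns_empty_mapping(self):
        assert tune_hyperparameters("naive_bayes", self.make_table(), {}) == {}

    def test_infeasible_knn_k_skipped(self, caplog):
        ft = self.make_table(n_tfs=8, n_targets=5)  # 40 rows
        with caplog.at_level("WARNING"):
            best = tune_hyperparameters(
                "knn", ft, {"n_neighbors": [1, 51]}, k_folds=2, seed=0
            )
        assert best == {"n_neighbors": 1}
        assert "infeasible" in caplog.text

    def test_single_combination_returned(self):
        best = tune_hyperparameters(
            "logistic", self.make_table(), {"C": [0.5]}, k_folds=2, seed=0
        )
        assert best == {"C": 0.5}

    def test_folds_are_tf_disjoint_and_deterministic(self):
        ft = self.make_table(n_tfs=12, n_targets=6, seed=2)
        grid = {"C": [0.1, 1.0]}
        a = tune_hyperparameters("logistic", ft, grid, k_folds=3, seed=9)
        b = tune_hyperparameters("logistic", ft, grid, k_folds=3, seed=9)
        assert a == b
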