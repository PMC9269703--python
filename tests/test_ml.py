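"""Classifier benchmark, grid search, protocol determinism, and SFS."""

import numpy as np
import pandas as pd
import pytest

from bendreturn import (
    ClassifierSpec,
    EvalProtocol,
    FeatureTable,
    default_specs,
    evaluate_classifiers,
    grid_search,
    reduced_specs,
    sfs_rank,
)
from bendreturn.ml import ALGORITHMS, _folds, make_estimator


def toy_table(n=40, n_features=6, sep=3.0, seed=0, subjects=None):
    """Two-class table: feature 0 carries the separation, rest is noise."""
    rng = np.random.default_rng(seed)
    y = np.array(["NLBP"] * (n // 2) + ["CLBP"] * (n - n // 2))
    X = rng.standard_normal((n, n_features))
    X[:, 0] += np.where(y == "NLBP", sep / 2, -sep / 2)
    cols = [f"f{i}" for i in range(n_features)]
    subj = subjects if subjects is not None else [f"s{i}" for i in range(n)]
    return FeatureTable(
        pd.DataFrame(X, columns=cols), pd.Series(y), pd.Series(subj)
    )


class TestSpecs:
    def test_selected_values_live_inside_their_grids(self):
        for spec in default_specs() + reduced_specs():
            for name, value in spec.selected.items():
                assert value in spec.grid[name]

    def test_every_algorithm_instantiates(self):
        for spec in default_specs():
            est = make_estimator(spec, random_state=0)
            assert est is not None
        assert len(default_specs()) == len(ALGORITHMS) == 7

    def test_selected_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="not among candidates"):
            ClassifierSpec("Linear SVM", grid={"C": [1, 10]}, selected={"C": 5})


class TestGridSearch:
    def test_single_candidate_grid_returns_it(self):
        spec = ClassifierSpec(
            "GaussianNB", grid={"var_smoothing": [0.5]},
            selected={"var_smoothing": 0.5},
        )
        sel = grid_search(spec, toy_table(), EvalProtocol(seed=1))
        assert sel == {"var_smoothing": 0.5}

    def test_separable_data_ties_break_to_first_candidate(self):
        # Every C separates the clusters perfectly, so the first-listed
        # candidate must win the tie.
        spec = next(s for s in default_specs() if s.algorithm == "Linear SVM")
        table = toy_table(sep=10.0, n_features=2)
        sel = grid_search(spec, table, EvalProtocol(seed=1))
        assert sel["C"] == spec.grid["C"][0] == 0.001

    def test_rf_max_features_candidates_clipped_to_table(self):
        spec = next(s for s in default_specs() if s.algorithm == "RF")
        spec.grid = {k: list(v) for k, v in spec.grid.items()}
        spec.grid["n_estimators"] = [5]
        spec.grid["max_depth"] = [5]
        spec.selected = {"max_depth": 5, "n_estimators": 5, "max_features": 1}
        sel = grid_search(spec, toy_table(n_features=3), EvalProtocol(seed=0))
        assert sel["max_features"] in (1, 3)

    def test_single_class_labels_rejected(self):
        table = toy_table()
        table.labels[:] = "NLBP"
        with pytest.raises(ValueError, match="single class"):
            grid_search(default_specs()[0], table, EvalProtocol())


class TestEvaluate:
    def test_separable_clusters_reach_perfect_scores(self):
        # Every feature carries the cluster separation; in the separable
        # limit all seven algorithms approach perfect scores.
        table = toy_table(sep=12.0)
        shift = np.where(table.y == "NLBP", 6.0, -6.0)
        for col in table.data.columns[1:]:
            table.data[col] += shift
        res = evaluate_classifiers(
            table, EvalProtocol(repetitions=3, seed=0), default_specs()
        )
        for alg, s in res.scores.items():
            assert s["accuracy_mean"] > 0.95, alg
            assert s["auc_mean"] > 0.97, alg

    def test_random_labels_stay_near_chance(self):
        table = toy_table(sep=0.0, seed=3)
        gnb = [s for s in default_specs() if s.algorithm == "GaussianNB"]
        res = evaluate_classifiers(table, EvalProtocol(repetitions=20, seed=0), gnb)
        assert 0.3 <= res.scores["GaussianNB"]["accuracy_mean"] <= 0.7

    def test_same_seed_reproduces_bit_identical_results(self):
        table = toy_table(sep=1.0, seed=5)
        specs = [s for s in default_specs() if s.algorithm in ("RF", "AdaBoost")]
        proto = EvalProtocol(repetitions=3, seed=9)
        a = evaluate_classifiers(table, proto, specs)
        b = evaluate_classifiers(table, proto, specs)
        assert a.scores == b.scores

    def test_scaling_is_required_and_applied(self):
        # Feature 0 separates but lives at a 1e-4 scale next to a 1e4-scale
        # noise feature: distance-based KNN only works if standardisation
        # happens (inside the folds).
        table = toy_table(sep=8.0, n_features=2, seed=6)
        table.data["f0"] *= 1e-4
        table.data["f1"] *= 1e4
        knn = [s for s in default_specs() if s.algorithm == "BF KNN"]
        res = evaluate_classifiers(table, EvalProtocol(repetitions=3, seed=0), knn)
        assert res.scores["BF KNN"]["accuracy_mean"] > 0.9

    def test_missing_values_raise_a_clear_error(self):
        table = toy_table()
        table.data.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing values"):
            evaluate_classifiers(table, EvalProtocol(repetitions=1), default_specs()[:1])

    def test_report_formats_mean_pm_sd(self):
        table = toy_table(sep=5.0)
        res = evaluate_classifiers(
            table, EvalProtocol(repetitions=2, seed=0),
            [s for s in default_specs() if s.algorithm == "GaussianNB"],
        )
        rep = res.report()
        assert "±" in rep.loc["GaussianNB", "Accuracy"]


class TestFolds:
    def test_subject_grouping_never_splits_a_subject(self):
        # 10 subjects x 4 cycles each
        subjects = [f"s{i // 4}" for i in range(40)]
        table = toy_table(subjects=subjects)
        proto = EvalProtocol(grouping="subject", n_folds=5)
        folds = _folds(table.y, table.groups.to_numpy(), proto, rep_seed=0)
        groups = np.asarray(subjects)
        for tr, te in folds:
            assert not set(groups[tr]) & set(groups[te])

    def test_row_grouping_partitions_all_rows(self):
        table = toy_table()
        folds = _folds(table.y, table.groups.to_numpy(), EvalProtocol(), 1)
        seen = np.concatenate([te for _, te in folds])
        assert sorted(seen) == list(range(40))


class TestSFS:
    def test_duplicated_informative_features_split_first_place(self):
        rng = np.random.default_rng(8)
        y = np.array(["NLBP"] * 20 + ["CLBP"] * 20)
        informative = np.where(y == "NLBP", 2.0, -2.0) + 0.3 * rng.standard_normal(40)
        X = rng.standard_normal((40, 4))
        X[:, 1] = informative
        X[:, 2] = informative  # exact duplicate
        table = FeatureTable(
            pd.DataFrame(X, columns=["a", "dup1", "dup2", "b"]),
            pd.Series(y), pd.Series([f"s{i}" for i in range(40)]),
        )
        gnb = [s for s in reduced_specs() if s.algorithm == "GaussianNB"]
        rank = sfs_rank(table, gnb, EvalProtocol(repetitions=20, seed=0), "forward")
        assert rank.total_runs == 20
        assert sum(rank.counts_first.values()) == 20
        assert set(rank.counts_first) <= {"dup1", "dup2"}

    def test_backward_elimination_keeps_the_informative_feature(self):
        table = toy_table(sep=6.0, n_features=5, seed=10)
        gnb = [s for s in reduced_specs() if s.algorithm == "GaussianNB"]
        rank = sfs_rank(table, gnb, EvalProtocol(repetitions=10, seed=0), "backward")
        assert rank.counts_first.most_common(1)[0][0] == "f0"

    def test_seven_algorithms_times_reps_runs(self):
        table = toy_table(sep=4.0, n_features=3)
        rank = sfs_rank(
            table, reduced_specs(), EvalProtocol(repetitions=2, seed=0), "forward"
        )
        assert rank.total_runs == 14

    def test_bad_direction_rejected(self):
        with pytest.raises(ValueError, match="direction"):
            sfs_rank(toy_table(), reduced_specs(), EvalProtocol(), "sideways")
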