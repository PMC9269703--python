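"""Classifier benchmark, grid search, and sequential feature ranking.

The benchmark pits seven supervised algorithms — brute-force KNN, linear SVM,
RBF SVM, decision tree, random forest, AdaBoost and Gaussian naive Bayes —
against a binary clinical-group feature table.  The evaluation protocol is a
stratified n-fold cross-validation (default 5-fold) with per-feature
standardisation fitted on the training folds only, repeated (default 100
times) with a fresh random row ordering each repetition; accuracy and ROC AUC
are pooled over the folds of each repetition and reported as mean ± SD over
repetitions.  With the same base seed the whole benchmark is bit-identical.

Feature importance is ranked with a greedy sequential feature selector run
once per (algorithm, repetition) — 7 x 100 = 700 runs by default — tallying
which feature is ranked first and second in each run.  Forward selection adds
the single best feature, then the best partner; backward elimination drops
the weakest feature until one survives (the survivor is ranked first, the
last-dropped feature second).

In cycle mode the rows are individual movement cycles that share a subject;
the protocol's ``grouping="subject"`` keeps all cycles of a subject on one
side of every split (leakage-safe), while ``grouping="row"`` treats cycles as
independent rows.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.model_selection import (
    GridSearchCV,
    StratifiedGroupKFold,
    StratifiedKFold,
)
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureTable

__all__ = [
    "ALGORITHMS",
    "ClassifierSpec",
    "EvalProtocol",
    "BenchmarkResult",
    "SFSRanking",
    "default_specs",
    "reduced_specs",
    "make_estimator",
    "grid_search",
    "evaluate_classifiers",
    "sfs_rank",
]

ALGORITHMS = (
    "BF KNN",
    "Linear SVM",
    "SVM RBF",
    "DT",
    "RF",
    "AdaBoost",
    "GaussianNB",
)


@dataclass
class ClassifierSpec:
    """One algorithm with its hyperparameter grid and chosen values."""

    algorithm: str
    grid: dict[str, list]
    selected: dict[str, object]

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        for name, value in self.selected.items():
            if name not in self.grid:
                raise ValueError(f"{self.algorithm}: {name!r} not in grid")
            if value not in self.grid[name]:
                raise ValueError(
                    f"{self.algorithm}: selected {name}={value!r} "
                    f"not among candidates {self.grid[name]}"
                )


def default_specs() -> list[ClassifierSpec]:
    """The seven benchmark algorithms with their full candidate grids.

    The ``selected`` values are the grid-search winners used as defaults.
    """
    return [
        ClassifierSpec(
            "BF KNN",
            grid={
                "n_neighbors": [3, 5, 8, 10],
                "weights": ["uniform", "distance"],
                "algorithm": ["brute", "kd_tree", "auto", "ball_tree"],
            },
            selected={"n_neighbors": 3, "weights": "distance", "algorithm": "brute"},
        ),
        ClassifierSpec(
            "Linear SVM",
            grid={"C": [0.001, 0.01, 0.1, 1, 10, 100, 1000]},
            selected={"C": 0.001},
        ),
        ClassifierSpec(
            "SVM RBF",
            grid={
                "C": [0.001, 0.01, 0.1, 1, 10, 100],
                "gamma": [0.001, 0.01, 0.1, 1, 10, 100],
            },
            selected={"C": 1, "gamma": 0.001},
        ),
        ClassifierSpec(
            "DT",
            grid={
                "max_depth": [1, 5, 10, 100],
                "criterion": ["gini", "entropy"],
                "splitter": ["best", "random"],
            },
            selected={"max_depth": 10, "criterion": "gini", "splitter": "best"},
        ),
        ClassifierSpec(
            "RF",
            grid={
                "max_depth": [1, 5, 10, 100],
                "n_estimators": [1, 5, 10, 100],
                "max_features": [1, 5, 10, 100],
            },
            selected={"max_depth": 10, "n_estimators": 100, "max_features": 1},
        ),
        ClassifierSpec(
            "AdaBoost",
            grid={
                "n_estimators": [5, 10, 50, 100, 500],
                "learning_rate": [0.000001, 0.001, 0.1, 1, 5, 10, 100],
            },
            selected={"n_estimators": 50, "learning_rate": 1},
        ),
        ClassifierSpec(
            "GaussianNB",
            grid={"var_smoothing": [0.0000001, 0.01, 1, 10, 100]},
            selected={"var_smoothing": 0.0000001},
        ),
    ]


def reduced_specs() -> list[ClassifierSpec]:
    """Lightweight hyperparameter choices for the many-run SFS studies.

    Ensemble sizes are cut (RF 10 trees, AdaBoost 10 estimators) so that the
    700-run selector tallies stay cheap; the other algorithms keep their
    default selections.
    """
    specs = []
    for spec in default_specs():
        if spec.algorithm == "RF":
            spec = replace(spec, selected={**spec.selected, "n_estimators": 10})
        elif spec.algorithm == "AdaBoost":
            spec = replace(spec, selected={**spec.selected, "n_estimators": 10})
        specs.append(spec)
    return specs


def make_estimator(spec: ClassifierSpec, random_state: int | None = None):
    """Instantiate the bare sklearn estimator for *spec* (no scaler)."""
    sel = dict(spec.selected)
    alg = spec.algorithm
    if alg == "BF KNN":
        return KNeighborsClassifier(**sel)
    if alg == "Linear SVM":
        return SVC(kernel="linear", random_state=random_state, **sel)
    if alg == "SVM RBF":
        return SVC(kernel="rbf", random_state=random_state, **sel)
    if alg == "DT":
        return DecisionTreeClassifier(random_state=random_state, **sel)
    if alg == "RF":
        return RandomForestClassifier(random_state=random_state, **sel)
    if alg == "AdaBoost":
        return AdaBoostClassifier(random_state=random_state, **sel)
    if alg == "GaussianNB":
        return GaussianNB(**sel)
    raise ValueError(f"unknown algorithm {alg!r}")  # pragma: no cover


def _scaled(est) -> Pipeline:
    return Pipeline([("scale", StandardScaler()), ("clf", est)])


@dataclass(frozen=True)
class EvalProtocol:
    """Cross-validation protocol shared by benchmark, grid search and SFS."""

    n_folds: int = 5
    repetitions: int = 100
    seed: int = 0
    grouping: str = "row"  # "row" or "subject"

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError(f"n_folds must be >= 2, got {self.n_folds}")
        if self.repetitions < 1:
            raise ValueError(
                f"repetitions must be >= 1, got {self.repetitions}"
            )
        if self.grouping not in ("row", "subject"):
            raise ValueError(f"grouping must be 'row' or 'subject', got {self.grouping!r}")


def _validate_table(table: FeatureTable) -> tuple[np.ndarray, np.ndarray]:
    X = table.X
    if np.isnan(X).any():
        bad = [c for c, has in zip(table.feature_names,
                                   np.isnan(X).any(axis=0)) if has]
        raise ValueError(
            f"feature table contains missing values (undefined SampEn?) in "
            f"{bad}; drop or restrict those columns before evaluation"
        )
    y = table.y
    if len(np.unique(y)) < 2:
        raise ValueError("feature table has a single class label")
    return X, y


def _folds(
    y: np.ndarray,
    groups: np.ndarray,
    protocol: EvalProtocol,
    rep_seed: int,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified fold index pairs for one repetition.

    Row grouping: random row ordering, then stratified folds.  Subject
    grouping: stratified group folds so no subject straddles a split.
    """
    if protocol.grouping == "subject":
        cv = StratifiedGroupKFold(
            n_splits=protocol.n_folds, shuffle=True, random_state=rep_seed
        )
        return [(tr, te) for tr, te in cv.split(np.zeros_like(y), y, groups)]
    rng = np.random.default_rng(rep_seed)
    order = rng.permutation(len(y))
    cv = StratifiedKFold(n_splits=protocol.n_folds, shuffle=False)
    return [
        (order[tr], order[te]) for tr, te in cv.split(order, y[order])
    ]


def grid_search(
    spec: ClassifierSpec,
    table: FeatureTable,
    protocol: EvalProtocol | None = None,
) -> dict[str, object]:
    """Exhaustively search *spec*'s grid by cross-validated accuracy.

    Performed once on the full table (a single winning setting per
    algorithm); ties resolve to the first-listed candidate.  Candidate
    values that are structurally impossible for the table (e.g. more
    ``max_features`` than columns) are dropped before the search.  The
    winning values are stored back into ``spec.selected``.
    """
    protocol = protocol or EvalProtocol()
    X, y = _validate_table(table)
    grid = {k: list(v) for k, v in spec.grid.items()}
    if spec.algorithm == "RF":
        nf = X.shape[1]
        grid["max_features"] = [v for v in grid["max_features"]
                                if not isinstance(v, int) or v <= nf]
    pipe = _scaled(make_estimator(spec, random_state=protocol.seed))
    search = GridSearchCV(
        pipe,
        {f"clf__{k}": v for k, v in grid.items()},
        scoring="accuracy",
        cv=StratifiedKFold(
            n_splits=protocol.n_folds, shuffle=True, random_state=protocol.seed
        ),
        n_jobs=1,
    )
    search.fit(X, y)
    selected = {k[len("clf__"):]: v for k, v in search.best_params_.items()}
    spec.selected = {**spec.selected, **selected}
    return selected


def _scores_for_auc(est, X_test: np.ndarray) -> np.ndarray:
    """Continuous scores oriented toward ``est.classes_[1]``."""
    if hasattr(est, "predict_proba"):
        return est.predict_proba(X_test)[:, 1]
    return est.decision_function(X_test)


@dataclass
class BenchmarkResult:
    """Accuracy/AUC mean ± SD over repetitions, per algorithm."""

    scores: dict[str, dict[str, float]]  # algorithm -> metric summaries
    protocol: EvalProtocol
    feature_set: str = "raw"

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame.from_dict(self.scores, orient="index")
        df.index.name = "algorithm"
        return df

    def report(self) -> pd.DataFrame:
        """Human-readable 'mean ± SD' table alongside the raw floats."""
        df = self.to_dataframe()
        out = pd.DataFrame(index=df.index)
        out["Accuracy"] = [
            f"{r.accuracy_mean:.2f} ± {r.accuracy_sd:.2f}"
            for r in df.itertuples()
        ]
        out["AUC"] = [
            f"{r.auc_mean:.2f} ± {r.auc_sd:.2f}" for r in df.itertuples()
        ]
        return pd.concat([out, df], axis=1)


def evaluate_classifiers(
    table: FeatureTable,
    protocol: EvalProtocol | None = None,
    specs: list[ClassifierSpec] | None = None,
    *,
    feature_set: str = "raw",
) -> BenchmarkResult:
    """Repeated stratified CV benchmark of the given algorithms.

    For each repetition the rows are re-ordered with a repetition-specific
    seed, split into stratified folds, and each algorithm is fitted per fold
    inside a pipeline whose scaler sees only the training rows.  Accuracy
    and AUC are pooled over the repetition's folds; the summary is their
    mean and SD over repetitions.
    """
    from sklearn.metrics import roc_auc_score

    protocol = protocol or EvalProtocol()
    specs = specs if specs is not None else default_specs()
    X, y = _validate_table(table)
    if len(y) < protocol.n_folds:
        raise ValueError(
            f"{len(y)} rows cannot fill {protocol.n_folds} folds"
        )
    groups = table.groups.to_numpy()
    classes = np.unique(y)

    acc = {s.algorithm: np.empty(protocol.repetitions) for s in specs}
    auc = {s.algorithm: np.empty(protocol.repetitions) for s in specs}
    for rep in range(protocol.repetitions):
        rep_seed = protocol.seed + rep
        folds = _folds(y, groups, protocol, rep_seed)
        for spec in specs:
            correct = 0
            total = 0
            pooled_scores = []
            pooled_truth = []
            for tr, te in folds:
                if len(np.unique(y[te])) < 2:
                    warnings.warn(
                        f"{spec.algorithm}: single-class test fold skipped for AUC",
                        stacklevel=2,
                    )
                est = _scaled(make_estimator(spec, random_state=rep_seed))
                est.fit(X[tr], y[tr])
                pred = est.predict(X[te])
                correct += int((pred == y[te]).sum())
                total += len(te)
                if len(np.unique(y[te])) == 2:
                    pooled_scores.append(_scores_for_auc(est, X[te]))
                    pooled_truth.append(y[te] == classes[1])
            acc[spec.algorithm][rep] = correct / total
            if pooled_truth:
                truth = np.concatenate(pooled_truth)
                scores = np.concatenate(pooled_scores)
                auc[spec.algorithm][rep] = roc_auc_score(truth, scores)
            else:  # every fold degenerate; AUC undefined this repetition
                auc[spec.algorithm][rep] = np.nan

    summary = {
        s.algorithm: {
            "accuracy_mean": float(acc[s.algorithm].mean()),
            "accuracy_sd": float(acc[s.algorithm].std(ddof=1))
            if protocol.repetitions > 1 else 0.0,
            "auc_mean": float(auc[s.algorithm].mean()),
            "auc_sd": float(auc[s.algorithm].std(ddof=1))
            if protocol.repetitions > 1 else 0.0,
        }
        for s in specs
    }
    return BenchmarkResult(scores=summary, protocol=protocol, feature_set=feature_set)


# ---------------------------------------------------------------------------
# Sequential feature selection
# ---------------------------------------------------------------------------


def _cv_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    cols: list[int],
    est_proto,
    folds: list[tuple[np.ndarray, np.ndarray]],
) -> float:
    """Mean fold accuracy on the column subset, scaler fit on train only.

    Standardisation is done with plain numpy (train mean/SD) to keep the
    inner SFS loop cheap; zero-variance columns scale to zero.
    """
    correct = 0
    total = 0
    sub = X[:, cols]
    for tr, te in folds:
        mu = sub[tr].mean(axis=0)
        sd = sub[tr].std(axis=0)
        sd[sd == 0] = 1.0
        est = clone(est_proto)
        est.fit((sub[tr] - mu) / sd, y[tr])
        pred = est.predict((sub[te] - mu) / sd)
        correct += int((pred == y[te]).sum())
        total += len(te)
    return correct / total


@dataclass
class SFSRanking:
    """First/second-place tallies of a repeated sequential feature selector."""

    direction: str
    counts_first: Counter
    counts_second: Counter
    total_runs: int

    def __post_init__(self) -> None:
        if sum(self.counts_first.values()) != self.total_runs:
            raise ValueError("first-place counts must sum to total_runs")

    def report(self, top: int = 5) -> pd.DataFrame:
        rows = []
        firsts = self.counts_first.most_common(top)
        seconds = self.counts_second.most_common(top)
        for k in range(max(len(firsts), len(seconds))):
            f = firsts[k] if k < len(firsts) else ("", "")
            s = seconds[k] if k < len(seconds) else ("", "")
            rows.append({"Feature": f[0], "First": f[1],
                         "Feature ": s[0], "Second": s[1]})
        return pd.DataFrame(rows)


def _forward_first_two(X, y, est_proto, folds) -> tuple[int, int]:
    nf = X.shape[1]
    best1, best1_score = 0, -1.0
    for j in range(nf):
        score = _cv_accuracy(X, y, [j], est_proto, folds)
        if score > best1_score:
            best1, best1_score = j, score
    best2, best2_score = -1, -1.0
    for j in range(nf):
        if j == best1:
            continue
        score = _cv_accuracy(X, y, [best1, j], est_proto, folds)
        if score > best2_score:
            best2, best2_score = j, score
    return best1, best2


def _backward_first_two(X, y, est_proto, folds) -> tuple[int, int]:
    remaining = list(range(X.shape[1]))
    last_removed = -1
    while len(remaining) > 1:
        worst, worst_score = None, -1.0
        for j in remaining:
            rest = [k for k in remaining if k != j]
            score = _cv_accuracy(X, y, rest, est_proto, folds)
            if score > worst_score:  # removing j hurts least
                worst, worst_score = j, score
        remaining.remove(worst)
        last_removed = worst
    return remaining[0], last_removed


def sfs_rank(
    table: FeatureTable,
    specs: list[ClassifierSpec] | None = None,
    protocol: EvalProtocol | None = None,
    direction: str = "forward",
) -> SFSRanking:
    """Tally which features a greedy selector ranks first and second.

    One selector run per (algorithm, repetition): 7 algorithms x 100
    repetitions = 700 runs with the defaults.  Folds are repetition-specific
    and shared across algorithms; greedy ties resolve to the lowest column
    index.
    """
    if direction not in ("forward", "backward"):
        raise ValueError(f"direction must be 'forward' or 'backward', got {direction!r}")
    protocol = protocol or EvalProtocol()
    specs = specs if specs is not None else reduced_specs()
    X, y = _validate_table(table)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features to rank")
    groups = table.groups.to_numpy()
    names = table.feature_names

    counts_first: Counter = Counter()
    counts_second: Counter = Counter()
    runs = 0
    for rep in range(protocol.repetitions):
        rep_seed = protocol.seed + rep
        folds = _folds(y, groups, protocol, rep_seed)
        for spec in specs:
            est_proto = make_estimator(spec, random_state=rep_seed)
            if direction == "forward":
                first, second = _forward_first_two(X, y, est_proto, folds)
            else:
                first, second = _backward_first_two(X, y, est_proto, folds)
            counts_first[names[first]] += 1
            counts_second[names[second]] += 1
            runs += 1
    return SFSRanking(
        direction=direction,
        counts_first=counts_first,
        counts_second=counts_second,
        total_runs=runs,
    )
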