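"""Ordinal wellness-state prediction with a weighted-voting classifier ensemble.

Each wellness attribute (stress, happiness, positive attitude, self-assessed
health) is predicted as a K-class problem from participant-week feature
vectors under three feature sets:

* ``baseline``      — gender + the 12 weekly behavioral features (13 columns);
* ``network_only``  — the 10 structural features (5 metrics x 2 networks);
* ``full``          — gender + behavior + structure (23 columns).

Five standard base learners (KNN, CART, SVM, LR, RF) are tuned by grid search
with stratified 5-fold cross-validation on the 75% training split; the three
with the highest CV accuracy form the ensemble.  The ensemble prediction is

    y_vote = argmax_j  sum_{i=1..3} w_ij * p_ij

where ``p_ij`` is classifier *i*'s predicted probability of class *j* and the
weights ``w`` are selected on held-out training folds from a step-0.1 grid —
by default one scalar weight per classifier on the 3-simplex (66 points); a
per-class mode searches the K-simplex per classifier row (286 rows at K=4),
exhaustively or by coordinate ascent.  Ties always break toward the lowest
class index, making every prediction deterministic.

Performance is reported as per-class F1 and their unweighted (macro) mean,
against a uniform-random baseline whose per-class F1 has the closed form
2p/(Kp+1) for a class of prevalence p.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .behavior_features import BEHAVIOR_FEATURES
from .correlation_analysis import STRUCTURE_COLUMNS
from .data_model import ORDINAL_RANGES

logger = logging.getLogger("netwell")

# SVC(probability=True) is the probability construction used here on purpose;
# newer scikit-learn warns it will move to CalibratedClassifierCV.
warnings.filterwarnings(
    "ignore", message="The `probability` parameter was deprecated", category=FutureWarning
)

#: Fixed classifier order; also the tie-break order everywhere.
CLASSIFIER_ORDER = ("KNN", "CART", "SVM", "LR", "RF")

FEATURE_SETS = {
    "baseline": ("gender",) + BEHAVIOR_FEATURES,
    "network_only": STRUCTURE_COLUMNS,
    "full": ("gender",) + BEHAVIOR_FEATURES + STRUCTURE_COLUMNS,
}

#: Gender indicator used in the model matrix.
GENDER_CODES = {"male": 0, "female": 1}

RF_DEFAULT_TREES = 35  # fixed default; the tuning grid spans 10..100 step 5


def _estimators(seed: int) -> dict[str, Pipeline]:
    """Unfitted scaler+classifier pipelines; scaling therefore always uses
    training-fold statistics only."""
    return {
        "KNN": Pipeline([("scale", StandardScaler()), ("clf", KNeighborsClassifier())]),
        "CART": Pipeline(
            [("scale", StandardScaler()), ("clf", DecisionTreeClassifier(random_state=seed))]
        ),
        "SVM": Pipeline(
            [("scale", StandardScaler()), ("clf", SVC(probability=True, random_state=seed))]
        ),
        "LR": Pipeline(
            [("scale", StandardScaler()), ("clf", LogisticRegression(max_iter=2000))]
        ),
        "RF": Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", RandomForestClassifier(n_estimators=RF_DEFAULT_TREES, random_state=seed)),
            ]
        ),
    }


PARAM_GRIDS: dict[str, dict[str, list[dict]]] = {
    "full": {
        "KNN": [{"clf__n_neighbors": [3, 5, 7, 9, 11, 15, 21]}],
        "CART": [{"clf__min_samples_leaf": [1, 2, 5, 10, 20, 50]}],
        "SVM": [
            {"clf__kernel": ["linear", "rbf"], "clf__C": [0.1, 1.0, 10.0]},
            {"clf__kernel": ["poly"], "clf__degree": [2, 3], "clf__C": [1.0]},
        ],
        "LR": [{"clf__C": [0.01, 0.1, 1.0, 10.0]}],
        "RF": [{"clf__n_estimators": list(range(10, 101, 5))}],
    },
    "small": {
        "KNN": [{"clf__n_neighbors": [5, 11]}],
        "CART": [{"clf__min_samples_leaf": [5, 20]}],
        "SVM": [{"clf__kernel": ["linear", "rbf"], "clf__C": [1.0]}],
        "LR": [{"clf__C": [1.0]}],
        "RF": [{"clf__n_estimators": [RF_DEFAULT_TREES]}],
    },
}


@dataclasses.dataclass
class TunedClassifier:
    name: str
    estimator: Pipeline  # fitted on the full training split
    cv_accuracy: float
    best_params: dict


@dataclasses.dataclass
class F1Report:
    overall: float  # macro F1
    per_level: dict  # class -> F1
    support: dict  # class -> count in y_true
    weighted: float

    def as_row(self) -> dict:
        row = {"F1": self.overall}
        row.update({f"Level{k}": v for k, v in self.per_level.items()})
        return row


@dataclasses.dataclass
class EnsembleModel:
    attribute: str
    feature_set: str
    classifiers: list  # the three TunedClassifier, in selection order
    weights: np.ndarray  # (3, K)
    classes: np.ndarray  # 1..K


# ---------------------------------------------------------------------------
# dataset assembly and splitting
# ---------------------------------------------------------------------------

def assemble_dataset(
    feature_table: pd.DataFrame, attribute: str, feature_set: str
) -> pd.DataFrame:
    """One modelling instance per participant-week with complete features and
    a label for ``attribute``; columns restricted to the feature set (plus
    participant / week / label bookkeeping columns).

    Rows with a missing label, unreported gender or any missing feature are
    excluded (logged).  Feature scaling happens inside the model pipelines,
    never here, so test data cannot leak into training statistics.
    """
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {feature_set!r}")
    if attribute not in ORDINAL_RANGES:
        raise ValueError(f"unknown wellness attribute {attribute!r}")
    df = feature_table.copy()
    if "gender" in df.columns and df["gender"].dtype == object:
        df["gender"] = df["gender"].map(GENDER_CODES)
    cols = list(FEATURE_SETS[feature_set])
    keep = ["participant", "week", *cols, attribute]
    missing_cols = [c for c in keep if c not in df.columns]
    if missing_cols:
        raise ValueError(f"feature table lacks column(s) {missing_cols}")
    n_before = len(df)
    df = df[keep].dropna()
    if df.empty:
        raise ValueError("no complete instances after dropping missing rows")
    if len(df) < n_before:
        logger.info("assemble_dataset(%s, %s): dropped %d incomplete row(s)",
                    attribute, feature_set, n_before - len(df))
    df = df.rename(columns={attribute: "label"})
    df["label"] = df["label"].astype(int)
    return df.reset_index(drop=True)


def split_train_test(
    instances: pd.DataFrame,
    frac: float = 0.75,
    unit: str = "participant",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """75/25 split, by default grouped at the participant level.

    ``unit='participant'`` keeps all of a participant's weeks on one side
    (no identity leakage), allocating participants per label stratum;
    ``unit='row'`` is a stratified row split (floor rule on the train size).
    """
    if not 0 < frac < 1:
        raise ValueError("frac must be in (0, 1): an empty split is not usable")
    if unit == "row":
        train, test = train_test_split(
            instances, train_size=frac, stratify=instances["label"], random_state=seed
        )
        return train.reset_index(drop=True), test.reset_index(drop=True)
    if unit != "participant":
        raise ValueError(f"unknown split unit {unit!r}")

    rng = np.random.default_rng(seed)
    per_participant = instances.groupby("participant")["label"].agg(
        lambda s: s.mode().iloc[0]
    )
    if len(per_participant) < 2:
        raise ValueError("participant-level split needs >= 2 participants")
    train_ids: list[str] = []
    test_ids: list[str] = []
    for _, grp in per_participant.groupby(per_participant):
        ids = list(grp.index)
        rng.shuffle(ids)
        n_train = int(round(frac * len(ids)))
        n_train = min(max(n_train, 1 if len(ids) > 1 else len(ids)), len(ids))
        train_ids += ids[:n_train]
        test_ids += ids[n_train:]
    if not test_ids:  # tiny strata can round everything into train
        test_ids.append(train_ids.pop())
    train = instances[instances["participant"].isin(train_ids)]
    test = instances[instances["participant"].isin(test_ids)]
    train_classes = set(train["label"])
    if not set(test["label"]) <= train_classes:
        logger.warning("split_train_test: test contains class(es) absent from train")
    return train.reset_index(drop=True), test.reset_index(drop=True)


def _xy(instances: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    X = instances.drop(columns=["participant", "week", "label"]).to_numpy(dtype=float)
    y = instances["label"].to_numpy(dtype=int)
    return X, y


def _cv(y: np.ndarray, n_folds: int, seed: int) -> StratifiedKFold:
    counts = np.bincount(y)
    smallest = int(counts[counts > 0].min())
    k = max(2, min(n_folds, smallest))
    if k < n_folds:
        logger.warning("reducing CV folds to %d (smallest class has %d member(s))",
                       k, smallest)
    return StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)


# ---------------------------------------------------------------------------
# base classifiers
# ---------------------------------------------------------------------------

def tune_base_classifiers(
    train: pd.DataFrame,
    grid: str = "full",
    seed: int = 0,
    n_folds: int = 5,
) -> dict[str, TunedClassifier]:
    """Grid-search the five base classifiers with stratified CV.

    ``grid='full'`` is the complete search (e.g. 19 tree counts for the
    random forest); ``'small'`` is a trimmed grid; ``'none'`` skips the search
    and scores the fixed defaults (35 trees for RF) with the same CV.
    Returns each classifier refit on the whole training split together with
    its mean CV accuracy.
    """
    X, y = _xy(train)
    cv = _cv(y, n_folds, seed)
    out: dict[str, TunedClassifier] = {}
    for name, est in _estimators(seed).items():
        if grid == "none":
            scores = []
            for tr, va in cv.split(X, y):
                m = clone(est).fit(X[tr], y[tr])
                scores.append(float(np.mean(m.predict(X[va]) == y[va])))
            fitted = clone(est).fit(X, y)
            out[name] = TunedClassifier(name, fitted, float(np.mean(scores)), {})
        else:
            search = GridSearchCV(est, PARAM_GRIDS[grid][name], scoring="accuracy", cv=cv)
            search.fit(X, y)
            out[name] = TunedClassifier(
                name, search.best_estimator_, float(search.best_score_), dict(search.best_params_)
            )
    return out


def select_top3(tuned: dict[str, TunedClassifier]) -> list[str]:
    """The three classifiers with highest mean CV accuracy; ties break by the
    fixed classifier-name order."""
    if len(tuned) < 3:
        raise ValueError("need >= 3 tuned classifiers")
    order = {name: i for i, name in enumerate(CLASSIFIER_ORDER)}
    ranked = sorted(tuned.values(), key=lambda t: (-t.cv_accuracy, order[t.name]))
    return [t.name for t in ranked[:3]]


def predict_proba_matrix(
    estimators: Sequence, X: np.ndarray, classes: np.ndarray
) -> np.ndarray:
    """Stacked class-probability tensor P[n, i, j] over the full 1..K class
    set (classes a classifier never saw get probability 0)."""
    n, m, K = X.shape[0], len(estimators), len(classes)
    P = np.zeros((n, m, K))
    class_pos = {int(c): j for j, c in enumerate(classes)}
    for i, est in enumerate(estimators):
        proba = est.predict_proba(X)
        for col, c in enumerate(est.classes_):
            P[:, i, class_pos[int(c)]] = proba[:, col]
    return P


# ---------------------------------------------------------------------------
# weighted voting
# ---------------------------------------------------------------------------

def simplex_grid(dim: int, step: float = 0.1) -> np.ndarray:
    """All points of the ``dim``-simplex on a step grid (stars and bars)."""
    units = round(1.0 / step)
    if not 0 < step <= 1 or abs(units * step - 1.0) > 1e-9:
        raise ValueError("step must divide 1 evenly and lie in (0, 1]")
    points = []
    for combo in itertools.combinations(range(units + dim - 1), dim - 1):
        prev = -1
        parts = []
        for c in combo:
            parts.append(c - prev - 1)
            prev = c
        parts.append(units + dim - 2 - prev)
        points.append(parts)
    return np.asarray(points, dtype=float) * step


def enumerate_weight_grid(
    mode: str = "scalar",
    n_classes: int = 4,
    n_classifiers: int = 3,
    step: float = 0.1,
) -> np.ndarray | Iterable[np.ndarray]:
    """Candidate weight matrices w[i, j] on a step grid.

    ``scalar`` — one weight per classifier, summing to 1 over classifiers
    (66 matrices for 3 classifiers at step 0.1), broadcast over classes.
    ``per_class`` — every classifier row lives on the K-class simplex (286
    rows at K=4, step 0.1); the cartesian product over classifiers is
    combinatorially large, so it is yielded lazily.
    """
    if mode == "scalar":
        v = simplex_grid(n_classifiers, step)  # (G, m)
        return np.repeat(v[:, :, None], n_classes, axis=2)
    if mode == "per_class":
        rows = simplex_grid(n_classes, step)  # (M, K)
        return (
            np.stack(combo)
            for combo in itertools.product(rows, repeat=n_classifiers)
        )
    raise ValueError(f"unknown weight mode {mode!r}")


def ensemble_vote(P: np.ndarray, W: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """y_vote = argmax_j sum_i w_ij p_ij; ties break toward the lowest class."""
    P = np.atleast_3d(P)
    if P.shape[1:] != W.shape:
        raise ValueError(f"shape mismatch: P {P.shape} vs W {W.shape}")
    scores = np.einsum("nij,ij->nj", P, W)
    return classes[np.argmax(scores, axis=1)]


def _macro_f1(y_true: np.ndarray, y_pred: np.ndarray, classes: np.ndarray) -> float:
    f1 = _per_class_f1(y_true, y_pred, classes)
    return float(np.mean(f1))


def _per_class_f1(y_true: np.ndarray, y_pred: np.ndarray, classes: np.ndarray) -> np.ndarray:
    f1 = np.zeros(len(classes))
    for j, c in enumerate(classes):
        tp = np.sum((y_true == c) & (y_pred == c))
        denom = np.sum(y_true == c) + np.sum(y_pred == c)  # = 2TP+FP+FN
        f1[j] = 2.0 * tp / denom if denom else 0.0
    return f1


def cross_validated_probs(
    tuned: dict[str, TunedClassifier],
    names: Sequence[str],
    train: pd.DataFrame,
    classes: np.ndarray,
    seed: int = 0,
    n_folds: int = 5,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Held-out probability tensors: for each CV fold of the training split,
    refit the selected base classifiers on the fold-train part and collect
    (P_val, y_val)."""
    X, y = _xy(train)
    cv = _cv(y, n_folds, seed)
    folds = []
    for tr, va in cv.split(X, y):
        fitted = [clone(tuned[n].estimator).fit(X[tr], y[tr]) for n in names]
        folds.append((predict_proba_matrix(fitted, X[va], classes), y[va]))
    return folds


def optimize_weights(
    folds: Sequence[tuple[np.ndarray, np.ndarray]],
    classes: np.ndarray,
    mode: str = "scalar",
    step: float = 0.1,
    exhaustive: bool = False,
    max_sweeps: int = 10,
) -> np.ndarray:
    """Pick the weight matrix maximising mean held-out macro F1.

    Deterministic: grid points are evaluated in enumeration order and the
    first best is kept, so identical classifiers yield the first grid point.
    In ``per_class`` mode the default is coordinate ascent over the 286-row
    simplex per classifier (monotone, converges in a few sweeps);
    ``exhaustive=True`` scans the full cartesian product.
    """
    n_classifiers = folds[0][0].shape[1]

    def score(W: np.ndarray) -> float:
        return float(
            np.mean([_macro_f1(yv, ensemble_vote(P, W, classes), classes) for P, yv in folds])
        )

    if mode == "scalar" or exhaustive:
        grid = enumerate_weight_grid(mode, len(classes), n_classifiers, step)
        best_W, best_s = None, -1.0
        for W in grid:
            s = score(W)
            if s > best_s + 1e-12:
                best_W, best_s = W.copy(), s
        return best_W

    # per-class coordinate ascent
    rows = simplex_grid(len(classes), step)
    W = np.full((n_classifiers, len(classes)), 1.0 / len(classes))
    best = score(W)
    for _ in range(max_sweeps):
        improved = False
        for i in range(n_classifiers):
            for row in rows:
                trial = W.copy()
                trial[i] = row
                s = score(trial)
                if s > best + 1e-12:
                    W, best = trial, s
                    improved = True
        if not improved:
            break
    return W


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def f1_report(y_true, y_pred, K: int) -> F1Report:
    """Per-class F1 (zero-rule when a class has no true or predicted
    instances), their unweighted macro mean, and a support-weighted variant."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    classes = np.arange(1, K + 1)
    f1 = _per_class_f1(y_true, y_pred, classes)
    support = {int(c): int(np.sum(y_true == c)) for c in classes}
    total = sum(support.values())
    weighted = float(sum(f1[j] * support[int(c)] for j, c in enumerate(classes)) / total) if total else 0.0
    return F1Report(
        overall=float(np.mean(f1)),
        per_level={int(c): float(f1[j]) for j, c in enumerate(classes)},
        support=support,
        weighted=weighted,
    )


def expected_random_f1(p: float, K: int) -> float:
    """Closed-form per-class F1 of uniform random prediction: with prevalence
    p, precision -> p and recall = 1/K, so F1 = 2p/(Kp+1)."""
    return 2.0 * p / (K * p + 1.0)


def random_baseline(
    y_test, K: int, seed: int = 0, reps: int = 1000
) -> tuple[np.ndarray, F1Report]:
    """Uniform random predictions over the K levels; the report averages the
    per-class and macro F1 over ``reps`` Monte-Carlo repetitions.  Returns
    the last draw and the averaged report."""
    if K < 2:
        raise ValueError("K must be >= 2")
    y_test = np.asarray(y_test, dtype=int)
    rng = np.random.default_rng(seed)
    classes = np.arange(1, K + 1)
    per_level = np.zeros((reps, K))
    macro = np.zeros(reps)
    draw = None
    for r in range(reps):
        draw = rng.integers(1, K + 1, size=len(y_test))
        f1 = _per_class_f1(y_test, draw, classes)
        per_level[r] = f1
        macro[r] = f1.mean()
    support = {int(c): int(np.sum(y_test == c)) for c in classes}
    total = max(sum(support.values()), 1)
    mean_f1 = per_level.mean(axis=0)
    report = F1Report(
        overall=float(macro.mean()),
        per_level={int(c): float(mean_f1[j]) for j, c in enumerate(classes)},
        support=support,
        weighted=float(sum(mean_f1[j] * support[int(c)] for j, c in enumerate(classes)) / total),
    )
    return draw, report


def relative_improvement(f1_base: float, f1_full: float) -> int:
    """Percent improvement round(100*(full-base)/base), half away from zero."""
    if f1_base <= 0:
        raise ValueError("relative improvement undefined for nonpositive baseline")
    x = 100.0 * (f1_full - f1_base) / f1_base
    # epsilon guards binary-float representation of clean decimal inputs
    return int(math.copysign(math.floor(abs(x) + 0.5 + 1e-9), x))


# ---------------------------------------------------------------------------
# end-to-end harness
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PredictionResult:
    attribute: str
    feature_set: str
    model: EnsembleModel
    cv_accuracy: dict
    report: F1Report
    base_reports: dict


def run_prediction(
    feature_table: pd.DataFrame,
    attribute: str,
    feature_set: str,
    seed: int = 0,
    grid: str = "full",
    weight_mode: str = "scalar",
    split_unit: str = "participant",
    frac: float = 0.75,
    n_folds: int = 5,
    exhaustive_weights: bool = False,
) -> PredictionResult:
    """Tune, select, weight and evaluate the ensemble for one attribute and
    feature set; the single seed drives the split, the CV folds and every
    stochastic learner."""
    K = ORDINAL_RANGES[attribute][1]
    classes = np.arange(1, K + 1)
    instances = assemble_dataset(feature_table, attribute, feature_set)
    train, test = split_train_test(instances, frac=frac, unit=split_unit, seed=seed)
    tuned = tune_base_classifiers(train, grid=grid, seed=seed, n_folds=n_folds)
    top3 = select_top3(tuned)
    folds = cross_validated_probs(tuned, top3, train, classes, seed=seed, n_folds=n_folds)
    W = optimize_weights(
        folds, classes, mode=weight_mode, exhaustive=exhaustive_weights
    )
    X_test, y_test = _xy(test)
    P_test = predict_proba_matrix([tuned[n].estimator for n in top3], X_test, classes)
    y_vote = ensemble_vote(P_test, W, classes)
    base_reports = {
        n: f1_report(y_test, tuned[n].estimator.predict(X_test), K) for n in top3
    }
    model = EnsembleModel(attribute, feature_set, [tuned[n] for n in top3], W, classes)
    return PredictionResult(
        attribute=attribute,
        feature_set=feature_set,
        model=model,
        cv_accuracy={n: t.cv_accuracy for n, t in tuned.items()},
        report=f1_report(y_test, y_vote, K),
        base_reports=base_reports,
    )
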