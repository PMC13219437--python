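"""Cross-validated classifier comparison and the unified Golden Distance.

Five standard classifiers (random forest, C4.5-style pruned decision tree,
inverse-distance-weighted KNN, SGD multilayer perceptron, AdaBoost.M1 over
decision stumps) are trained and tested under k-fold cross-validation.
Held-out predictions are pooled into one confusion matrix per classifier,
from which accuracy, class-weighted precision/recall/F-measure, Cohen's
kappa and ROC AUC are derived.

Golden Distance condenses the two published summary components Av-NAV
(higher is better, ideal 1) and Av-DCO (lower is better, ideal 0) into the
Euclidean distance from the ideal point (1, 0); lower is better.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.tree import DecisionTreeClassifier

from .features import LABEL_COLUMN
from .labeling import NON_STRESSED, STRESSED

#: (actual, predicted) axis order for confusion matrices, ST before NS
CLASS_ORDER = (STRESSED, NON_STRESSED)
CLASS_SHORT = {STRESSED: "ST", NON_STRESSED: "NS"}

CLASSIFIER_NAMES = ("RF", "J48", "KNN", "MLP", "ABM")

#: default hyperparameters per classifier, named after the conventions of
#: the workbench vocabulary they were published in (see docs/methods.md for
#: the mapping onto the scikit-learn back-end)
DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "RF": {"iterations": 100, "max_depth": 10, "seed": 1},
    "J48": {"confidence": 0.15, "min_leaf": 5},
    "KNN": {"k": 5, "weight": "inverse_distance"},
    "MLP": {"learning_rate": 0.3, "momentum": 0.2, "epochs": 500, "seed": 1},
    "ABM": {"iterations": 100, "base_learner": "decision_stump", "seed": 1},
}

#: published benchmark operating points (Av-NAV, Av-DCO) for the five
#: classifiers under the two segmentation schemes; inputs to golden_distance
REFERENCE_OPERATING_POINTS: tuple[tuple[str, str, float, float], ...] = (
    ("KNN", "non_overlapping", 0.9226, 0.0125),
    ("ABM", "non_overlapping", 0.9106, 0.0155),
    ("ABM", "overlapping", 0.8714, 0.0183),
    ("MLP", "non_overlapping", 0.8276, 0.0236),
    ("KNN", "overlapping", 0.8192, 0.0316),
    ("MLP", "overlapping", 0.8131, 0.0325),
    ("RF", "overlapping", 0.8108, 0.0354),
    ("J48", "non_overlapping", 0.6174, 0.0137),
    ("RF", "non_overlapping", 0.6124, 0.0646),
    ("J48", "overlapping", 0.5728, 0.0617),
)


@dataclass(frozen=True)
class ClassifierSpec:
    """A named classifier plus its recorded hyperparameters."""

    name: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise ValueError(
                f"unknown classifier {self.name!r}; choose from {CLASSIFIER_NAMES}"
            )
        merged = dict(DEFAULT_HYPERPARAMETERS[self.name])
        unknown = set(self.hyperparameters) - set(merged)
        if unknown:
            raise ValueError(
                f"unknown hyperparameter(s) {sorted(unknown)} for {self.name}"
            )
        merged.update(self.hyperparameters)
        object.__setattr__(self, "hyperparameters", merged)

    def build(self, n_features: int, seed: int) -> Pipeline:
        """Instantiate the scikit-learn back-end for this spec.

        All estimators sit behind a per-fold min-max scaler so that
        distance- and gradient-based learners see comparable feature
        scales; tree ensembles are unaffected by the monotone rescaling.
        """
        hp = self.hyperparameters
        if self.name == "RF":
            est = RandomForestClassifier(
                n_estimators=int(hp["iterations"]),
                max_depth=int(hp["max_depth"]),
                random_state=int(hp["seed"]) + seed,
            )
        elif self.name == "J48":
            est = DecisionTreeClassifier(
                criterion="entropy",
                min_samples_leaf=int(hp["min_leaf"]),
                ccp_alpha=float(hp["confidence"]) * 0.1,
                random_state=seed,
            )
        elif self.name == "KNN":
            est = KNeighborsClassifier(
                n_neighbors=int(hp["k"]),
                weights="distance"
                if hp["weight"] == "inverse_distance"
                else "uniform",
            )
        elif self.name == "MLP":
            hidden = max(2, (n_features + 2) // 2)
            est = MLPClassifier(
                hidden_layer_sizes=(hidden,),
                solver="sgd",
                learning_rate_init=float(hp["learning_rate"]),
                momentum=float(hp["momentum"]),
                max_iter=int(hp["epochs"]),
                random_state=int(hp["seed"]) + seed,
            )
        else:  # ABM
            est = AdaBoostClassifier(
                estimator=DecisionTreeClassifier(max_depth=1),
                n_estimators=int(hp["iterations"]),
                random_state=int(hp["seed"]) + seed,
            )
        return Pipeline([("scale", MinMaxScaler()), ("clf", est)])


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts over (actual, predicted) in CLASS_ORDER."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (2, 2) or (counts < 0).any():
            raise ValueError("confusion matrix must be 2x2 non-negative counts")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        names = [CLASS_SHORT[c] for c in CLASS_ORDER]
        return pd.DataFrame(
            self.counts,
            index=pd.Index(names, name="actual"),
            columns=pd.Index(names, name="predicted"),
        )


@dataclass(frozen=True)
class MetricsReport:
    """Pooled cross-validation metrics for one classifier run."""

    classifier: str
    accuracy: float  # percent
    precision: float
    recall: float
    f_measure: float
    kappa: float
    roc_auc: float
    confusion: ConfusionMatrix
    seed: int
    hyperparameters: Mapping[str, object]
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class GoldenDistanceRecord:
    av_nav: float
    av_dco: float
    gd: float


def make_folds(
    instance_ids: Sequence, n_folds: int, seed: int,
    stratified: bool = False, labels: Sequence | None = None,
) -> list[np.ndarray]:
    """Deterministic partition of instances into folds of near-equal size.

    Plain mode shuffles once and splits; sizes differ by at most one.
    Stratified mode deals each class round-robin so per-fold class
    proportions stay balanced (requires ``labels``).
    """
    ids = np.asarray(instance_ids)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if ids.size < n_folds:
        raise ValueError("need at least as many instances as folds")
    rng = np.random.default_rng(seed)
    if not stratified:
        perm = rng.permutation(ids.size)
        return [np.sort(chunk) for chunk in np.array_split(perm, n_folds)]
    if labels is None:
        raise ValueError("stratified folds require labels")
    labels = np.asarray(labels)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    cursor = 0
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        idx = rng.permutation(idx)
        for j, i in enumerate(idx):
            folds[(cursor + j) % n_folds].append(int(i))
        cursor += idx.size
    return [np.sort(np.asarray(f, dtype=int)) for f in folds]


def metrics_from_confusion(cm: ConfusionMatrix) -> dict[str, float]:
    """Accuracy (%), weighted precision/recall/F and Cohen's kappa.

    Per-class precision/recall/F are combined weighted by true class
    frequency; a zero denominator yields 0 for that class's value and is
    reported under the "flags" key. kappa falls back to 0 when expected
    agreement is 1.
    """
    c = cm.counts.astype(float)
    total = c.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    diag = np.trace(c)
    accuracy = 100.0 * diag / total
    flags = []
    precisions, recalls, fs, weights = [], [], [], []
    for i in range(2):
        tp = c[i, i]
        col = c[:, i].sum()
        row = c[i, :].sum()
        prec = tp / col if col > 0 else 0.0
        rec = tp / row if row > 0 else 0.0
        if col == 0:
            flags.append(f"no_predictions_{CLASS_SHORT[CLASS_ORDER[i]]}")
        f1 = 2 * prec * rec / (prec + rec) if (prec + rec) > 0 else 0.0
        precisions.append(prec)
        recalls.append(rec)
        fs.append(f1)
        weights.append(row)
    w = np.asarray(weights) / total
    p_o = diag / total
    p_e = float(np.sum(c.sum(axis=0) * c.sum(axis=1)) / total**2)
    kappa = (p_o - p_e) / (1 - p_e) if p_e < 1 else 0.0
    return {
        "accuracy": accuracy,
        "precision": float(np.dot(w, precisions)),
        "recall": float(np.dot(w, recalls)),
        "f_measure": float(np.dot(w, fs)),
        "kappa": kappa,
        "flags": tuple(flags),
    }


def cross_validate(
    table: pd.DataFrame,
    spec: ClassifierSpec,
    n_folds: int = 10,
    seed: int = 1,
    stratified: bool = False,
) -> MetricsReport:
    """k-fold CV of one classifier on a labeled feature table.

    Trains on k-1 folds, predicts the held-out fold, pools all held-out
    predictions into one confusion matrix, and computes the metric suite
    from the pooled matrix (ROC AUC from pooled class scores).
    """
    if LABEL_COLUMN not in table.columns:
        raise ValueError("feature table carries no label column")
    y = table[LABEL_COLUMN].to_numpy()
    present = set(np.unique(y))
    if present != set(CLASS_ORDER):
        raise ValueError(
            f"need both classes {CLASS_ORDER}, got {sorted(present)}"
        )
    X = table.drop(columns=[LABEL_COLUMN]).to_numpy(dtype=float)
    folds = make_folds(
        table.index.to_numpy(), n_folds, seed,
        stratified=stratified, labels=y,
    )
    for f_idx, test_idx in enumerate(folds):
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test_idx] = False
        if set(np.unique(y[train_mask])) != set(CLASS_ORDER):
            raise ValueError(
                f"fold {f_idx}: a class is absent from the training split; "
                "consider stratified=True"
            )
    y_pred = np.empty(len(y), dtype=object)
    score_pos = np.empty(len(y), dtype=float)  # score for the ST class
    for f_idx, test_idx in enumerate(folds):
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test_idx] = False
        # per-fold training seed: folds are independent fits, and a single
        # unlucky initialization must not poison every fold
        model = clone(spec.build(n_features=X.shape[1], seed=seed + f_idx))
        try:
            model.fit(X[train_mask], y[train_mask])
            pred = model.predict(X[test_idx])
            proba = model.predict_proba(X[test_idx])
            pos_col = list(model.classes_).index(STRESSED)
        except Exception as exc:  # surface fold + spec context
            raise RuntimeError(
                f"classifier {spec.name} failed on fold {f_idx}: {exc}"
            ) from exc
        y_pred[test_idx] = pred
        score_pos[test_idx] = proba[:, pos_col]

    counts = np.zeros((2, 2), dtype=int)
    for i, actual in enumerate(CLASS_ORDER):
        for j, predicted in enumerate(CLASS_ORDER):
            counts[i, j] = int(np.sum((y == actual) & (y_pred == predicted)))
    cm = ConfusionMatrix(counts)
    m = metrics_from_confusion(cm)
    roc = _weighted_roc_auc(y, score_pos)
    return MetricsReport(
        classifier=spec.name,
        accuracy=m["accuracy"],
        precision=m["precision"],
        recall=m["recall"],
        f_measure=m["f_measure"],
        kappa=m["kappa"],
        roc_auc=roc,
        confusion=cm,
        seed=seed,
        hyperparameters=dict(spec.hyperparameters),
        flags=m["flags"],
    )


def _weighted_roc_auc(y: np.ndarray, score_pos: np.ndarray) -> float:
    """Class-frequency-weighted one-vs-rest AUC (equal to either class's
    AUC in the binary case, but stated in weighted form for symmetry with
    the other metrics)."""
    from sklearn.metrics import roc_auc_score

    y_bin = (y == STRESSED).astype(int)
    if y_bin.min() == y_bin.max():
        return float("nan")
    auc_pos = roc_auc_score(y_bin, score_pos)
    auc_neg = roc_auc_score(1 - y_bin, -score_pos)
    w_pos = y_bin.mean()
    return float(w_pos * auc_pos + (1 - w_pos) * auc_neg)


def golden_distance(av_nav: float, av_dco: float) -> float:
    """Euclidean distance of (Av-NAV, Av-DCO) from the ideal point (1, 0)."""
    if not (np.isfinite(av_nav) and np.isfinite(av_dco)):
        raise ValueError("Av-NAV and Av-DCO must be finite")
    return float(np.hypot(1.0 - av_nav, av_dco))


def golden_distance_record(av_nav: float, av_dco: float) -> GoldenDistanceRecord:
    return GoldenDistanceRecord(
        av_nav=av_nav, av_dco=av_dco, gd=golden_distance(av_nav, av_dco)
    )


def compare_report(
    results: Mapping[tuple[str, str], MetricsReport],
    operating_points: Mapping[tuple[str, str], tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Summary table over (classifier, segmentation mode) runs.

    Adds Golden Distance where an (Av-NAV, Av-DCO) operating point is
    supplied for a run; sorts by gd ascending (runs without a gd sort
    last), ties broken by accuracy descending then name.
    """
    if not results:
        raise ValueError("no results to compare")
    rows = []
    for (name, mode), rep in results.items():
        row = {
            "classifier": name,
            "technique": mode,
            "accuracy": rep.accuracy,
            "f_measure": rep.f_measure,
            "kappa": rep.kappa,
            "recall": rep.recall,
            "precision": rep.precision,
            "roc_auc": rep.roc_auc,
            "seed": rep.seed,
            "hyperparameters": repr(dict(rep.hyperparameters)),
            "gd": np.nan,
        }
        if operating_points and (name, mode) in operating_points:
            nav, dco = operating_points[(name, mode)]
            row["gd"] = golden_distance(nav, dco)
        rows.append(row)
    df = pd.DataFrame(rows)
    df["_gd_sort"] = df["gd"].fillna(np.inf)
    df = df.sort_values(
        by=["_gd_sort", "accuracy", "classifier", "technique"],
        ascending=[True, False, True, True],
        kind="mergesort",
    ).drop(columns="_gd_sort")
    return df.reset_index(drop=True)
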