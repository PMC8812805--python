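"""Feature selection, stratified splitting, classifier training and evaluation.

Single-feature discrimination is scored with the tie-corrected rank (Mann-
Whitney) AUC; eight classifier families are trained behind one interface and
evaluated with DeLong 95% confidence intervals plus threshold metrics
(sensitivity, specificity, accuracy, precision, confusion matrix).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .globin_features import FEATURE_NAMES

logger = logging.getLogger(__name__)

METHOD_NAMES = ("RF", "LR", "SVM", "KNN", "DT", "NB", "Adaboost", "ANN")

POSITIVE_LABEL = "thalassaemia"


class SingleClassError(ValueError):
    """Both classes are required but only one is present."""


class LeakageError(RuntimeError):
    """Train/test/validation sample sets overlap."""


def _as_binary(labels, positive_label) -> np.ndarray:
    y = np.asarray([1 if l == positive_label else 0 for l in labels])
    if y.min() == y.max():
        raise SingleClassError(
            f"need both classes, got only {'positive' if y[0] else 'negative'} labels"
        )
    return y


def single_feature_auc(values, labels, positive_label=POSITIVE_LABEL) -> float:
    """Tie-corrected rank AUC of one feature for separating the classes.

    Equals the fraction of (positive, negative) pairs in which the positive
    sample has the larger value, counting ties as half.
    """
    y = _as_binary(labels, positive_label)
    v = np.asarray(values, dtype=float)
    if v.shape != y.shape:
        raise ValueError("values and labels must have equal length")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    ranks = rankdata(v)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return float(auc)


def rank_features(
    table: pd.DataFrame,
    labels,
    feature_columns: Sequence[str] = FEATURE_NAMES,
    positive_label=POSITIVE_LABEL,
) -> pd.Series:
    """Per-feature discrimination AUC, sorted descending, canonical tie-break.

    Direction-agnostic: a feature that is consistently *lower* in the
    positive class discriminates just as well, so each feature is scored as
    max(auc, 1 - auc) — the convention of ROC packages that auto-orient the
    comparison direction.
    """
    y = np.asarray(labels)
    aucs = {}
    for col in feature_columns:
        v = table[col].to_numpy(dtype=float)
        ok = ~np.isnan(v)
        a = single_feature_auc(v[ok], y[ok], positive_label)
        aucs[col] = max(a, 1.0 - a)
    order = sorted(
        feature_columns, key=lambda c: (-aucs[c], list(feature_columns).index(c))
    )
    return pd.Series({c: aucs[c] for c in order})


def select_features(
    table: pd.DataFrame,
    labels,
    rule: Mapping[str, float],
    feature_columns: Sequence[str] = FEATURE_NAMES,
    positive_label=POSITIVE_LABEL,
    min_completeness: float = 0.9,
) -> list[str]:
    """Select features by descending single-feature AUC.

    ``rule`` is ``{"top_k": k}`` or ``{"auc_min": t}``. Features observed in
    fewer than ``min_completeness`` of the samples are excluded from
    candidacy (their complete-case AUC would be computed on a biased subset).
    """
    if len(feature_columns) < 2:
        raise ValueError("at least 2 candidate features required")
    complete_enough = [
        c for c in feature_columns
        if table[c].notna().mean() >= min_completeness
    ]
    dropped = set(feature_columns) - set(complete_enough)
    if dropped:
        warnings.warn(
            f"features excluded from selection for completeness < {min_completeness}: "
            f"{sorted(dropped)}",
            stacklevel=2,
        )
    feature_columns = complete_enough
    if len(feature_columns) < 2:
        raise ValueError("fewer than 2 sufficiently complete candidate features")
    ranked = rank_features(table, labels, feature_columns, positive_label)
    if "top_k" in rule:
        k = int(rule["top_k"])
        if k > len(ranked):
            raise ValueError(f"top_k={k} exceeds the {len(ranked)} available features")
        return list(ranked.index[:k])
    if "auc_min" in rule:
        chosen = list(ranked.index[ranked.to_numpy() > float(rule["auc_min"])])
        if not chosen:
            warnings.warn(
                f"no feature exceeds auc_min={rule['auc_min']}; empty selection",
                stacklevel=2,
            )
        return chosen
    raise ValueError(f"selection rule must contain 'top_k' or 'auc_min', got {dict(rule)}")


@dataclasses.dataclass(frozen=True)
class SplitPlan:
    """A stratified train/test partition of sample ids."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    ratio: tuple[int, int]
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test ids overlap")


def stratified_split(
    manifest: pd.DataFrame,
    ratio: tuple[int, int] = (2, 1),
    seed: int = 0,
    stratify_on: str = "class_label",
) -> SplitPlan:
    """Class-stratified random split with nearest-integer per-class allocation.

    With the default 2:1 ratio each class contributes round(2/3 * n) training
    samples; the remainder goes to the test set.
    """
    frac = ratio[0] / (ratio[0] + ratio[1])
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for value in sorted(manifest[stratify_on].unique()):
        ids = manifest.loc[manifest[stratify_on] == value, "sample_id"].tolist()
        if len(ids) < 3:
            raise ValueError(
                f"class {value!r} has only {len(ids)} samples; at least 3 required"
            )
        n_train = int(np.floor(frac * len(ids) + 0.5))  # nearest integer, half up
        perm = rng.permutation(len(ids))
        train.extend(ids[i] for i in perm[:n_train])
        test.extend(ids[i] for i in perm[n_train:])
    return SplitPlan(tuple(train), tuple(test), tuple(ratio), int(seed))


def _build_estimator(method: str, seed: int, hyper: Optional[Mapping] = None):
    hyper = dict(hyper or {})
    if method == "RF":
        clf = RandomForestClassifier(
            n_estimators=hyper.get("n_estimators", 500), random_state=seed
        )
    elif method == "LR":
        # plain maximum likelihood by default; pass a finite C for L2 shrinkage
        clf = LogisticRegression(C=hyper.get("C", np.inf), max_iter=5000)
    elif method == "SVM":
        clf = SVC(kernel=hyper.get("kernel", "rbf"), probability=True, random_state=seed)
    elif method == "KNN":
        clf = KNeighborsClassifier(n_neighbors=hyper.get("n_neighbors", 7))
    elif method == "DT":
        clf = DecisionTreeClassifier(random_state=seed)
    elif method == "NB":
        clf = GaussianNB()
    elif method == "Adaboost":
        clf = AdaBoostClassifier(n_estimators=hyper.get("n_estimators", 100), random_state=seed)
    elif method == "ANN":
        clf = MLPClassifier(
            hidden_layer_sizes=hyper.get("hidden_layer_sizes", (5,)),
            max_iter=2000,
            random_state=seed,
        )
    else:
        raise ValueError(f"unknown method {method!r}; expected one of {METHOD_NAMES}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def train_classifier(
    method: str,
    train_table: pd.DataFrame,
    selected_features: Sequence[str],
    labels,
    hyper: Optional[Mapping] = None,
    seed: int = 0,
    positive_label=POSITIVE_LABEL,
):
    """Fit one classifier family; returns a fitted scorer with predict_proba.

    Feature standardisation is part of the fitted pipeline, so test-time data
    never influences the scaling.
    """
    X = train_table.loc[:, list(selected_features)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("training features contain masked (NaN) values")
    y = _as_binary(labels, positive_label)
    model = _build_estimator(method, seed, hyper)
    model.fit(X, y)
    return model


def score_samples(model, table: pd.DataFrame, selected_features: Sequence[str]) -> np.ndarray:
    """Continuous positive-class scores (probabilities) for each row."""
    X = table.loc[:, list(selected_features)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("features contain masked (NaN) values")
    proba = model.predict_proba(X)
    positive_col = list(model.classes_).index(1)
    return proba[:, positive_col]


def roc_auc_ci(scores, labels, positive_label=1) -> tuple[float, float, float]:
    """AUC with a DeLong 95% confidence interval, truncated to [0, 1]."""
    y = _as_binary(labels, positive_label)
    s = np.asarray(scores, dtype=float)
    pos, neg = s[y == 1], s[y == 0]
    m, n = pos.size, neg.size
    all_ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    # DeLong structural components
    v01 = (all_ranks[:m] - pos_ranks) / n
    v10 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    var = 0.0
    if m > 1:
        var += np.var(v01, ddof=1) / m
    if n > 1:
        var += np.var(v10, ddof=1) / n
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    return float(auc), float(max(0.0, auc - half)), float(min(1.0, auc + half))


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> dict:
    """Rates from confusion counts, as fractions in [0, 1].

    Precision is ``None`` (masked) when no positive calls were made.
    """
    for name, v in (("tp", tp), ("fn", fn), ("tn", tn), ("fp", fp)):
        if v < 0:
            raise ValueError(f"{name} must be nonnegative")
    n = tp + fn + tn + fp
    if n == 0:
        raise ValueError("empty confusion matrix")
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else None,
        "specificity": tn / (tn + fp) if tn + fp else None,
        "accuracy": (tp + tn) / n,
        "precision": tp / (tp + fp) if tp + fp else None,
        "confusion": {"tp": int(tp), "fn": int(fn), "tn": int(tn), "fp": int(fp)},
    }


def to_percent(value: Optional[float]) -> Optional[float]:
    """A fraction as a percentage rounded to one decimal, e.g. 0.98712 -> 98.7."""
    return None if value is None else round(100.0 * value, 1)


def classification_metrics(scores, labels, threshold: float = 0.5, positive_label=1) -> dict:
    """Threshold the scores and compute the confusion-matrix rates."""
    y = _as_binary(labels, positive_label)
    calls = np.asarray(scores, dtype=float) >= threshold
    tp = int(np.sum(calls & (y == 1)))
    fn = int(np.sum(~calls & (y == 1)))
    tn = int(np.sum(~calls & (y == 0)))
    fp = int(np.sum(calls & (y == 0)))
    out = confusion_metrics(tp, fn, tn, fp)
    out["threshold"] = float(threshold)
    return out


def youden_threshold(scores, labels, positive_label=1) -> float:
    """Score cut maximising sensitivity + specificity - 1 on these samples."""
    y = _as_binary(labels, positive_label)
    s = np.asarray(scores, dtype=float)
    best_t, best_j = 0.5, -np.inf
    for t in np.unique(s):
        calls = s >= t
        sens = np.sum(calls & (y == 1)) / max(np.sum(y == 1), 1)
        spec = np.sum(~calls & (y == 0)) / max(np.sum(y == 0), 1)
        j = sens + spec - 1.0
        if j > best_j:
            best_j, best_t = j, float(t)
    return best_t


@dataclasses.dataclass
class ModelReport:
    """Evaluation of one classifier on one sample set."""

    method: str
    eval_set: str
    auc: float
    ci_low: float
    ci_high: float
    sensitivity: Optional[float]
    specificity: Optional[float]
    accuracy: float
    precision: Optional[float]
    confusion: dict[str, int]
    threshold: float
    selected_features: tuple[str, ...]
    n: int
    best: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("auc must lie in [0, 1]")
        if not self.ci_low <= self.auc <= self.ci_high:
            raise ValueError("confidence interval must bracket the AUC")
        if sum(self.confusion.values()) != self.n:
            raise ValueError("confusion counts must sum to the evaluated n")


def _assert_disjoint(tables: Mapping[str, pd.DataFrame]) -> None:
    names = list(tables)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            overlap = set(tables[a]["sample_id"]) & set(tables[b]["sample_id"])
            if overlap:
                raise LeakageError(
                    f"{a} and {b} share {len(overlap)} samples, e.g. {sorted(overlap)[:3]}"
                )


def run_model_suite(
    train_table: pd.DataFrame,
    test_table: pd.DataFrame,
    validation_table: Optional[pd.DataFrame] = None,
    selection_rule: Mapping[str, float] = None,
    methods: Sequence[str] = METHOD_NAMES,
    seed: int = 0,
    threshold: float | str = 0.5,
    label_column: str = "class_label",
    positive_label=POSITIVE_LABEL,
    feature_columns: Sequence[str] = FEATURE_NAMES,
) -> tuple[list[ModelReport], str]:
    """Full protocol: select features on the training set only, fit every
    requested method, and evaluate on train, test and validation sets.

    Samples with masked values among the selected features are dropped per
    evaluation set. Returns the reports and the name of the method with the
    highest AUC on the last evaluation set (validation when given, else test);
    its reports carry ``best=True``.
    """
    selection_rule = dict(selection_rule or {"top_k": 5})
    eval_tables = {"train": train_table, "test": test_table}
    if validation_table is not None:
        eval_tables["validation"] = validation_table
    _assert_disjoint(eval_tables)

    selected = select_features(
        train_table, train_table[label_column], selection_rule, feature_columns, positive_label
    )
    if not selected:
        raise ValueError("feature selection returned an empty set")

    def complete(t: pd.DataFrame) -> pd.DataFrame:
        mask = t.loc[:, selected].notna().all(axis=1)
        dropped = int((~mask).sum())
        if dropped:
            logger.info("dropping %d rows with masked features", dropped)
        return t.loc[mask]

    eval_tables = {name: complete(t) for name, t in eval_tables.items()}
    train_c = eval_tables["train"]

    reports: list[ModelReport] = []
    ranking_set = "validation" if validation_table is not None else "test"
    best_method, best_auc = None, -np.inf
    for method in methods:
        model = train_classifier(
            method, train_c, selected, train_c[label_column], seed=seed,
            positive_label=positive_label,
        )
        if threshold == "youden":
            train_scores = score_samples(model, train_c, selected)
            y_train = _as_binary(train_c[label_column], positive_label)
            thr = youden_threshold(train_scores, y_train)
        else:
            thr = float(threshold)
        for name, table in eval_tables.items():
            scores = score_samples(model, table, selected)
            y = _as_binary(table[label_column], positive_label)
            auc, lo, hi = roc_auc_ci(scores, y)
            m = classification_metrics(scores, y, threshold=thr)
            reports.append(
                ModelReport(
                    method=method,
                    eval_set=name,
                    auc=auc,
                    ci_low=lo,
                    ci_high=hi,
                    sensitivity=m["sensitivity"],
                    specificity=m["specificity"],
                    accuracy=m["accuracy"],
                    precision=m["precision"],
                    confusion=m["confusion"],
                    threshold=thr,
                    selected_features=tuple(selected),
                    n=len(table),
                )
            )
            if name == ranking_set and auc > best_auc:
                best_auc, best_method = auc, method
    for r in reports:
        r.best = r.method == best_method
    return reports, best_method
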