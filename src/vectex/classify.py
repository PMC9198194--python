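"""Random-forest classification with GINI-ranked forward feature selection.

The protocol: rank all features by mean decrease in GINI impurity from a
forest fit on the training set only, then refit on the top-k features for
k = 3, 4, ..., K_max and keep the k that maximizes test AUC (smallest k on
ties). Two cross-validation schemes are supported:

* ``twofold_x100`` — stratified random half/half splits, repeated (100 times
  by default); metrics are summarized as mean +/- SD over repetitions.
* ``leave_one_out`` — each lesion is held out once; its per-k scores are
  pooled across all folds before a single AUC per k is computed, and the
  reported AUC is the maximum over k.

Accuracy / sensitivity / specificity are read off at the Youden-optimal
point (max sensitivity + specificity - 1) of the test ROC.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .features import N_FEATURES


class StratificationError(ValueError):
    """The dataset cannot be stratified (a class is missing or too small)."""


@dataclass
class RFParams:
    """Random-forest hyperparameters (passed through to scikit-learn)."""

    n_estimators: int = 5000
    max_features: str | int | float = "sqrt"
    n_jobs: int = 1

    def to_sklearn(self) -> dict:
        return {"n_estimators": self.n_estimators,
                "max_features": self.max_features, "n_jobs": self.n_jobs}


@dataclass
class Dataset:
    """Lesion feature matrix with binary labels."""

    features: np.ndarray
    labels: np.ndarray
    lesion_ids: list[str]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2D matrix")
        if len(self.labels) != self.features.shape[0]:
            raise ValueError("labels and features disagree on lesion count")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain non-finite values")
        if len(set(np.unique(self.labels)) - {0, 1}) > 0:
            raise ValueError("labels must be binary 0/1")

    @property
    def n_lesions(self) -> int:
        return self.features.shape[0]

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame) -> "Dataset":
        """Build from a wide feature table (lesion_id, label, feature cols)."""
        feature_cols = [c for c in table.columns if "__" in c]
        return cls(features=table[feature_cols].to_numpy(),
                   labels=table["label"].to_numpy(),
                   lesion_ids=[str(v) for v in table["lesion_id"]])


@dataclass
class RepetitionResult:
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    n_selected_features: int


@dataclass
class CVResult:
    scheme: str
    per_repetition: list[RepetitionResult]
    summary: dict[str, dict[str, float]]
    roc: dict[str, list[float]]

    def to_dict(self) -> dict:
        return {"scheme": self.scheme,
                "per_repetition": [asdict(r) for r in self.per_repetition],
                "summary": self.summary, "roc": self.roc}


def roc_auc(scores: np.ndarray, labels: np.ndarray):
    """AUC (trapezoidal) plus Youden-point accuracy/sensitivity/specificity.

    Returns ``(auc, (fpr, tpr, thresholds), metrics_dict)``.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC is undefined with a single class present")
    fpr, tpr, thresholds = roc_curve(labels, scores)
    value = float(_trapezoid_auc(fpr, tpr))
    youden = int(np.argmax(tpr - fpr))
    thr = thresholds[youden]
    pred = scores >= thr
    pos = labels == 1
    sensitivity = float(pred[pos].mean())
    specificity = float((~pred[~pos]).mean())
    accuracy = float((pred == pos).mean())
    return value, (fpr, tpr, thresholds), {
        "accuracy": accuracy, "sensitivity": sensitivity,
        "specificity": specificity, "threshold": float(thr),
    }


def stratified_twofold_splits(dataset: Dataset, n_repeats: int = 100,
                              seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Repeated stratified half/half splits (one train/test pair per repeat).

    Class ratios and split sizes are preserved to within one lesion; the
    same seed reproduces the same split sequence.
    """
    classes, counts = np.unique(dataset.labels, return_counts=True)
    if len(classes) < 2:
        raise StratificationError("both classes must be present")
    if counts.min() < 2:
        raise StratificationError("each class needs >= 2 members")
    child_seeds = _spawn_seeds(seed, n_repeats)
    splits = []
    for s in child_seeds:
        kf = StratifiedKFold(n_splits=2, shuffle=True, random_state=int(s))
        train, test = next(iter(kf.split(dataset.features, dataset.labels)))
        splits.append((train, test))
    return splits


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    """Derive n child seeds below 2**31 from one master seed."""
    ss = np.random.SeedSequence(seed)
    return np.array([int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(n)])


def gini_rank(features: np.ndarray, labels: np.ndarray, rf_params: RFParams,
              seed: int = 0) -> np.ndarray:
    """Feature indices sorted by decreasing mean-decrease-in-GINI importance.

    Fit on the given (training) data only; ties broken by feature index for
    a stable, deterministic ordering.
    """
    rf = RandomForestClassifier(random_state=seed, **rf_params.to_sklearn())
    rf.fit(features, labels)
    return np.argsort(-rf.feature_importances_, kind="stable")


def forward_selection_rf(train_x: np.ndarray, train_y: np.ndarray,
                         test_x: np.ndarray, test_y: np.ndarray,
                         ordering: np.ndarray, rf_params: RFParams,
                         k_min: int = 3, k_max: int = 50, seed: int = 0):
    """Grow the feature set in importance order; keep the best-test-AUC k.

    Returns ``(best_k, best_auc, metrics, best_scores)`` where metrics holds
    Youden-point accuracy/sensitivity/specificity at the best k. Ties in AUC
    go to the smallest k.
    """
    n_feat = len(ordering)
    k_hi = min(k_max, n_feat)
    k_lo = min(k_min, k_hi)
    best = None
    for k in range(k_lo, k_hi + 1):
        cols = ordering[:k]
        rf = RandomForestClassifier(random_state=seed, **rf_params.to_sklearn())
        rf.fit(train_x[:, cols], train_y)
        scores = rf.predict_proba(test_x[:, cols])[:, 1]
        value, _, metrics = roc_auc(scores, test_y)
        if best is None or value > best[1]:
            best = (k, value, metrics, scores)
    return best


def cross_validate(dataset: Dataset, scheme: str, rf_params: RFParams | None = None,
                   seed: int = 0, n_repeats: int = 100, k_min: int = 3,
                   k_max: int = 50) -> CVResult:
    """Run the full selection + classification protocol under one CV scheme.

    ``scheme`` is ``"twofold_x100"`` (stratified half/half, ``n_repeats``
    repetitions) or ``"leave_one_out"``. Deterministic for a fixed master
    seed.
    """
    rf_params = rf_params or RFParams()
    if scheme == "twofold_x100":
        return _cross_validate_twofold(dataset, rf_params, seed, n_repeats,
                                       k_min, k_max)
    if scheme == "leave_one_out":
        return _cross_validate_loo(dataset, rf_params, seed, k_min, k_max)
    raise ValueError(f"unknown scheme {scheme!r}")


def _summarize(reps: list[RepetitionResult]) -> dict[str, dict[str, float]]:
    out = {}
    for metric in ("auc", "accuracy", "sensitivity", "specificity",
                   "n_selected_features"):
        vals = np.array([getattr(r, metric) for r in reps], dtype=np.float64)
        out[metric] = {"mean": float(vals.mean()),
                       "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0}
    return out


def _cross_validate_twofold(dataset: Dataset, rf_params: RFParams, seed: int,
                            n_repeats: int, k_min: int, k_max: int) -> CVResult:
    splits = stratified_twofold_splits(dataset, n_repeats, seed)
    child_seeds = _spawn_seeds(seed + 1, n_repeats)
    reps: list[RepetitionResult] = []
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    for (train, test), s in zip(splits, child_seeds):
        ordering = gini_rank(dataset.features[train], dataset.labels[train],
                             rf_params, seed=int(s))
        best_k, best_auc, metrics, scores = forward_selection_rf(
            dataset.features[train], dataset.labels[train],
            dataset.features[test], dataset.labels[test],
            ordering, rf_params, k_min=k_min, k_max=k_max, seed=int(s))
        reps.append(RepetitionResult(
            auc=best_auc, accuracy=metrics["accuracy"],
            sensitivity=metrics["sensitivity"],
            specificity=metrics["specificity"], n_selected_features=best_k))
        pooled_scores.append(scores)
        pooled_labels.append(dataset.labels[test])
    fpr, tpr, _ = roc_curve(np.concatenate(pooled_labels),
                            np.concatenate(pooled_scores))
    return CVResult(scheme="twofold_x100", per_repetition=reps,
                    summary=_summarize(reps),
                    roc={"fpr": fpr.tolist(), "tpr": tpr.tolist()})


def _cross_validate_loo(dataset: Dataset, rf_params: RFParams, seed: int,
                        k_min: int, k_max: int) -> CVResult:
    n = dataset.n_lesions
    k_hi = min(k_max, dataset.features.shape[1])
    k_lo = min(k_min, k_hi)
    ks = list(range(k_lo, k_hi + 1))
    child_seeds = _spawn_seeds(seed, n)
    scores = np.zeros((len(ks), n))
    for i in range(n):
        train = np.array([t for t in range(n) if t != i])
        s = int(child_seeds[i])
        ordering = gini_rank(dataset.features[train], dataset.labels[train],
                             rf_params, seed=s)
        for kidx, k in enumerate(ks):
            cols = ordering[:k]
            rf = RandomForestClassifier(random_state=s, **rf_params.to_sklearn())
            rf.fit(dataset.features[train][:, cols], dataset.labels[train])
            scores[kidx, i] = rf.predict_proba(
                dataset.features[i:i + 1][:, cols])[0, 1]
    best = None
    for kidx, k in enumerate(ks):
        value, _, metrics = roc_auc(scores[kidx], dataset.labels)
        if best is None or value > best[1]:
            best = (k, value, metrics, scores[kidx])
    best_k, best_auc, metrics, best_scores = best
    rep = RepetitionResult(auc=best_auc, accuracy=metrics["accuracy"],
                           sensitivity=metrics["sensitivity"],
                           specificity=metrics["specificity"],
                           n_selected_features=best_k)
    fpr, tpr, _ = roc_curve(dataset.labels, best_scores)
    return CVResult(scheme="leave_one_out", per_repetition=[rep],
                    summary=_summarize([rep]),
                    roc={"fpr": fpr.tolist(), "tpr": tpr.tolist()})
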