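"""Balance-confidence labeling, CFS feature selection, and the classifier.

Participants are labeled *high confidence* when their ABC score (mean of 16
items, 0-100%) is at least 80%, otherwise *low confidence*.  Dimensionality
is reduced with correlation-based feature selection (CFS): the merit of a
feature subset S with k features is

    merit(S) = k * r_cf / sqrt(k + k (k - 1) * r_ff)

where r_cf is the mean absolute feature-class (point-biserial) correlation
and r_ff the mean absolute pairwise feature-feature correlation within S.
Subsets are explored with best-first forward search, terminating after 5
consecutive non-improving expansions.

Classification uses a random forest (100 trees, floor(log2 p) + 1 candidate
features per split, unlimited depth), evaluated with participant-level
leave-one-out cross-validation: one model per held-out participant.  Vote
ties break toward low confidence, the clinically conservative class.  Fall
history is carried as metadata only, never as a feature.
"""

from __future__ import annotations

import heapq
import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from gaitconf.errors import ValidationError

logger = logging.getLogger(__name__)

HIGH, LOW = "high", "low"
ABC_ITEMS = 16
DEFAULT_ABC_THRESHOLD = 80.0


def abc_total(item_scores) -> float:
    """Total ABC score: arithmetic mean of the 16 item scores (each 0-100%)."""
    items = np.asarray(item_scores, dtype=float)
    if items.shape != (ABC_ITEMS,):
        raise ValidationError(f"ABC needs exactly {ABC_ITEMS} items, got {items.shape}")
    if np.any(items < 0) or np.any(items > 100):
        raise ValidationError("ABC item scores must lie in [0, 100]")
    return float(np.mean(items))


def label_confidence(abc_score: float, threshold: float = DEFAULT_ABC_THRESHOLD) -> str:
    """High confidence iff the ABC score meets the threshold (>= 80% default)."""
    if not 0 <= abc_score <= 100:
        raise ValidationError(f"ABC score {abc_score} outside [0, 100]")
    return HIGH if abc_score >= threshold else LOW


@dataclass
class LabeledCohort:
    """Feature matrix + labels, one row per participant.

    ``features`` is a participants x features DataFrame indexed by
    participant id; labels derive from ``abc_scores`` by threshold only.
    """

    features: pd.DataFrame
    abc_scores: pd.Series
    fall_history: pd.Series | None = None
    threshold: float = DEFAULT_ABC_THRESHOLD

    def __post_init__(self) -> None:
        if self.features.index.has_duplicates:
            raise ValidationError("participant ids must be unique")
        self.abc_scores = self.abc_scores.reindex(self.features.index)
        if self.abc_scores.isna().any():
            missing = list(self.abc_scores.index[self.abc_scores.isna()])
            raise ValidationError(f"missing ABC scores for participants {missing}")
        if self.fall_history is not None:
            self.fall_history = self.fall_history.reindex(self.features.index)

    @property
    def labels(self) -> pd.Series:
        return self.abc_scores.map(lambda s: label_confidence(s, self.threshold))

    def __len__(self) -> int:
        return len(self.features)


def _correlations(X: np.ndarray, y01: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """|feature-class| and |feature-feature| Pearson correlations.

    Features are standardized internally; zero-variance features get
    correlation 0 (logged).
    """
    Xs = X - X.mean(axis=0)
    sd = Xs.std(axis=0)
    zero = sd == 0
    if np.any(zero):
        logger.warning("%d zero-variance features; correlations set to 0", zero.sum())
    sd_safe = np.where(zero, 1.0, sd)
    Z = Xs / sd_safe
    ys = y01 - y01.mean()
    ysd = ys.std()
    if ysd == 0:
        raise ValidationError("labels are degenerate (single class)")
    zy = ys / ysd
    n = X.shape[0]
    r_cf = np.abs(Z.T @ zy) / n
    r_ff = np.abs(Z.T @ Z) / n
    r_cf[zero] = 0.0
    r_ff[zero, :] = 0.0
    r_ff[:, zero] = 0.0
    np.fill_diagonal(r_ff, 1.0)
    return r_cf, r_ff


def merit_from_correlations(
    subset: tuple[int, ...], r_cf: np.ndarray, r_ff: np.ndarray
) -> float:
    k = len(subset)
    if k == 0:
        raise ValidationError("CFS merit requires a non-empty subset")
    idx = np.asarray(subset)
    mean_cf = float(np.mean(r_cf[idx]))
    if k == 1:
        return mean_cf
    off = r_ff[np.ix_(idx, idx)]
    mean_ff = float((off.sum() - k) / (k * (k - 1)))
    return k * mean_cf / np.sqrt(k + k * (k - 1) * mean_ff)


def cfs_merit(subset, X, y) -> float:
    """CFS merit of a feature subset on a labeled dataset.

    ``subset`` holds column indices (or names, for a DataFrame); ``y`` holds
    high/low labels or a binary vector.
    """
    if isinstance(X, pd.DataFrame):
        cols = list(X.columns)
        subset = tuple(c if isinstance(c, (int, np.integer)) else cols.index(c) for c in subset)
        X = X.to_numpy(float)
    y01 = _binary_labels(y)
    r_cf, r_ff = _correlations(np.asarray(X, dtype=float), y01)
    return merit_from_correlations(tuple(subset), r_cf, r_ff)


def _binary_labels(y) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.kind in "OUS":
        return (y == HIGH).astype(float)
    return y.astype(float)


@dataclass
class CfsResult:
    selected: list[str]
    merit: float
    trace: list[tuple[tuple[str, ...], float]] = field(default_factory=list)


def cfs_select(
    X: pd.DataFrame, y, max_stale: int = 5, max_expansions: int = 10_000
) -> CfsResult:
    """Best-first forward search maximizing the CFS merit.

    Starts from the empty set, repeatedly expands the best unexpanded subset
    by one feature, and stops after ``max_stale`` consecutive expansions
    that fail to improve the best merit found.  Deterministic given input
    column order (ties break toward earlier insertion).
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
    y01 = _binary_labels(y)
    classes, counts = np.unique(y01, return_counts=True)
    if classes.size < 2 or counts.min() < 2:
        raise ValidationError("CFS needs >= 2 participants per class")
    r_cf, r_ff = _correlations(X.to_numpy(float), y01)
    p = X.shape[1]
    names = list(X.columns)

    counter = itertools.count()
    open_heap: list[tuple[float, int, tuple[int, ...]]] = [(0.0, next(counter), ())]
    seen: set[tuple[int, ...]] = {()}
    best_subset: tuple[int, ...] = ()
    best_merit = -np.inf
    trace: list[tuple[tuple[str, ...], float]] = []
    stale = 0
    expansions = 0
    while open_heap and stale < max_stale and expansions < max_expansions:
        _, _, node = heapq.heappop(open_heap)
        expansions += 1
        improved = False
        for j in range(p):
            if j in node:
                continue
            child = tuple(sorted(node + (j,)))
            if child in seen:
                continue
            seen.add(child)
            m = merit_from_correlations(child, r_cf, r_ff)
            heapq.heappush(open_heap, (-m, next(counter), child))
            if m > best_merit:
                best_merit, best_subset = m, child
                improved = True
        trace.append((tuple(names[j] for j in node), best_merit))
        stale = 0 if improved else stale + 1
    if not best_subset:
        raise ValidationError("CFS selected no features")
    return CfsResult(
        selected=[names[j] for j in best_subset],
        merit=float(best_merit),
        trace=trace,
    )


@dataclass(frozen=True)
class ForestConfig:
    """Random-forest hyperparameters (100 trees, log2-style split candidates,
    unlimited depth, bootstrap with replacement at full sample size)."""

    n_trees: int = 100
    features_per_split: int | None = None  # default floor(log2 p) + 1
    max_depth: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValidationError("n_trees must be >= 1")

    def resolved_features_per_split(self, p: int) -> int:
        k = self.features_per_split
        if k is None:
            k = int(np.floor(np.log2(p))) + 1
        if not 1 <= k <= p:
            raise ValidationError(f"features_per_split {k} outside [1, {p}]")
        return k


class ForestModel:
    """Random forest with deterministic tie-breaking toward low confidence."""

    def __init__(self, clf: RandomForestClassifier):
        self._clf = clf

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        proba = self._clf.predict_proba(X)
        high_col = list(self._clf.classes_).index(HIGH)
        p_high = proba[:, high_col]
        # strict majority required for "high": ties -> low (conservative)
        return np.where(p_high > 0.5, HIGH, LOW)


def fit_forest(X, y, cfg: ForestConfig | None = None) -> ForestModel:
    """Grow the random-forest ensemble on a labeled feature matrix."""
    cfg = cfg or ForestConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2 or counts.min() < 2:
        raise ValidationError("training data needs >= 2 participants per class")
    clf = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_features=cfg.resolved_features_per_split(X.shape[1]),
        max_depth=cfg.max_depth,
        bootstrap=True,
        random_state=cfg.seed,
    )
    clf.fit(X, y)
    return ForestModel(clf)


@dataclass
class ConfusionMatrix:
    """Counts with positive class = high confidence."""

    tp: int  # true high predicted high
    fn: int  # true high predicted low
    fp: int  # true low predicted high
    tn: int  # true low predicted low

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def correct(self) -> int:
        return self.tp + self.tn


@dataclass
class Metrics:
    """Percentages to 1 decimal; NaN marks an undefined (0/0) ratio."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
        }


def _pct(num: int, den: int, name: str) -> float:
    if den == 0:
        logger.warning("metric %s undefined (zero denominator)", name)
        return float("nan")
    return round(100.0 * num / den, 1)


def compute_metrics(cm: ConfusionMatrix) -> Metrics:
    """Accuracy, sensitivity, specificity, precision (in %, 1 decimal)."""
    if cm.total == 0:
        raise ValidationError("empty confusion matrix")
    return Metrics(
        accuracy=_pct(cm.tp + cm.tn, cm.total, "accuracy"),
        sensitivity=_pct(cm.tp, cm.tp + cm.fn, "sensitivity"),
        specificity=_pct(cm.tn, cm.tn + cm.fp, "specificity"),
        precision=_pct(cm.tp, cm.tp + cm.fp, "precision"),
    )


@dataclass
class LoocvResult:
    confusion: ConfusionMatrix
    metrics: Metrics
    predictions: pd.Series  # per participant
    selected: list[str] | None  # global-selection mode only
    n_models: int


def loocv(
    cohort: LabeledCohort,
    forest_cfg: ForestConfig | None = None,
    selection: str = "global",
) -> LoocvResult:
    """Participant-level leave-one-out cross-validation.

    One model is trained per participant, on all others, and predicts the
    held-out participant; the confusion matrix accumulates over all n folds.
    ``selection`` is ``"global"`` (CFS once on the full cohort, the
    headline mode) or ``"nested"`` (CFS re-run inside each training fold,
    the leakage-safe variant) or ``"none"``.
    """
    if selection not in ("global", "nested", "none"):
        raise ValidationError(f"unknown selection mode {selection!r}")
    forest_cfg = forest_cfg or ForestConfig()
    y = cohort.labels
    counts = y.value_counts()
    if len(counts) < 2 or counts.min() < 3:
        raise ValidationError("LOOCV needs >= 3 participants per class")
    X = cohort.features
    selected: list[str] | None = None
    if selection == "global":
        selected = cfs_select(X, y).selected
        X = X[selected]
    preds = {}
    for fold, pid in enumerate(X.index):
        X_tr = X.drop(index=pid)
        y_tr = y.drop(index=pid)
        X_te = X.loc[[pid]]
        if selection == "nested":
            chosen = cfs_select(X_tr, y_tr).selected
            X_tr, X_te = X_tr[chosen], X_te[chosen]
        fold_cfg = ForestConfig(
            n_trees=forest_cfg.n_trees,
            features_per_split=forest_cfg.features_per_split,
            max_depth=forest_cfg.max_depth,
            seed=forest_cfg.seed + fold,
        )
        model = fit_forest(X_tr, y_tr, fold_cfg)
        preds[pid] = model.predict(X_te)[0]
    predictions = pd.Series(preds).reindex(X.index)
    cm = ConfusionMatrix(
        tp=int(((predictions == HIGH) & (y == HIGH)).sum()),
        fn=int(((predictions == LOW) & (y == HIGH)).sum()),
        fp=int(((predictions == HIGH) & (y == LOW)).sum()),
        tn=int(((predictions == LOW) & (y == LOW)).sum()),
    )
    return LoocvResult(
        confusion=cm,
        metrics=compute_metrics(cm),
        predictions=predictions,
        selected=selected,
        n_models=len(predictions),
    )
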