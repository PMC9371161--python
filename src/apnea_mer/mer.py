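"""Multi-error-reduction (MER) stacked classifier and evaluation metrics.

Four gradient-boosted tree base learners produce out-of-fold probability
scores under patient-grouped stratified k-fold cross-validation; a small
feed-forward neural network (4 inputs, one hidden layer of 4 units, one
sigmoid output) is trained on those scores as the meta-learner. Because
every meta-feature row comes from base models that never saw that row, the
meta-learner learns where the bases err rather than memorising their
training fit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, HistGradientBoostingClassifier
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.neural_network import MLPClassifier

from .psg import APNEA, NORMAL

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "StackedModel",
    "default_base_learners",
    "build_meta_features",
    "train_stacked",
    "predict",
    "confusion",
    "sensitivity",
    "specificity",
    "accuracy",
    "auc",
    "evaluate",
]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def p(self) -> int:
        return self.tp + self.fn

    @property
    def n(self) -> int:
        return self.tn + self.fp


@dataclass
class MetricsReport:
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float
    counts: ConfusionCounts

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "auc": self.auc,
            "tp": self.counts.tp, "tn": self.counts.tn,
            "fp": self.counts.fp, "fn": self.counts.fn,
        }


def _as01(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "UO":
        return (arr == APNEA).astype(int)
    return arr.astype(int)


def confusion(labels_true, labels_pred) -> ConfusionCounts:
    """Confusion counts with apnea as the positive class."""
    yt, yp = _as01(labels_true), _as01(labels_pred)
    if yt.shape != yp.shape:
        raise ValueError("label arrays must share a shape")
    return ConfusionCounts(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        tn=int(np.sum((yt == 0) & (yp == 0))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
        fn=int(np.sum((yt == 1) & (yp == 0))),
    )


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        logger.warning("%s: zero denominator, returning 0", name)
        return 0.0
    return num / den


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN)."""
    return _ratio(c.tp, c.tp + c.fn, "sensitivity")


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP)."""
    return _ratio(c.tn, c.tn + c.fp, "specificity")


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / (P + N)."""
    return _ratio(c.tp + c.tn, c.p + c.n, "accuracy")


def auc(labels_true, scores) -> float:
    """Area under the ROC curve (trapezoidal over all score thresholds);
    degenerate single-class truth returns 0 with a warning."""
    yt = _as01(labels_true)
    scores = np.asarray(scores, dtype=float)
    if yt.min() == yt.max():
        logger.warning("auc: only one class present, returning 0")
        return 0.0
    from sklearn.metrics import roc_auc_score
    return float(roc_auc_score(yt, scores))


# ---------------------------------------------------------------------------
# base learners
# ---------------------------------------------------------------------------

def default_base_learners(seed: int = 0) -> list[tuple]:
    """The four gradient-boosting families used as level-0 learners.

    Each entry is ``(name, factory)`` where the factory builds a fresh
    estimator exposing sklearn's ``fit`` / ``predict_proba``. Any scorer
    satisfying that contract can stand in.
    """
    def gb():
        return GradientBoostingClassifier(
            n_estimators=150, max_depth=3, learning_rate=0.1, random_state=seed)

    def hgb():
        return HistGradientBoostingClassifier(
            max_iter=200, max_depth=6, learning_rate=0.1, random_state=seed)

    def xgb_factory():
        from xgboost import XGBClassifier
        return XGBClassifier(
            n_estimators=200, max_depth=6, learning_rate=0.1,
            eval_metric="logloss", n_jobs=1, random_state=seed,
            verbosity=0, tree_method="hist")

    def lgbm_factory():
        from lightgbm import LGBMClassifier
        return LGBMClassifier(
            n_estimators=200, max_depth=6, learning_rate=0.1,
            n_jobs=1, random_state=seed, verbose=-1)

    return [
        ("gradient_boosting", gb),
        ("hist_gradient_boosting", hgb),
        ("xgboost", xgb_factory),
        ("lightgbm", lgbm_factory),
    ]


@dataclass
class StackedModel:
    """Fitted MER system: four base learners + the meta-ANN."""

    base_names: list
    base_models: list
    meta: MLPClassifier
    feature_names: list
    k: int

    def meta_layer_sizes(self) -> tuple:
        """(inputs, hidden, outputs) of the fitted meta-network."""
        wts = self.meta.coefs_
        return (wts[0].shape[0], wts[0].shape[1], wts[-1].shape[1])


# ---------------------------------------------------------------------------
# stacking
# ---------------------------------------------------------------------------

def _design(table: pd.DataFrame, feature_names: list):
    x = table[feature_names].to_numpy(float)
    y = _as01(table["label"].to_numpy())
    groups = table["patient_id"].to_numpy() if "patient_id" in table.columns else None
    return x, y, groups


def _make_folds(y: np.ndarray, groups, k: int, seed: int) -> list:
    if groups is not None and len(np.unique(groups)) >= k:
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = list(splitter.split(np.zeros_like(y), y, groups))
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = list(splitter.split(np.zeros_like(y), y))
    for _, held in folds:
        if len(np.unique(y[held])) < 2:
            raise ValueError("a cross-validation fold lost one class; "
                             "stratification failed for this table")
    return folds


def build_meta_features(table: pd.DataFrame, base_specs: list | None = None,
                        k: int = 5, seed: int = 0,
                        feature_names: list | None = None,
                        folds: list | None = None) -> pd.DataFrame:
    """Out-of-fold base-learner scores: the meta-training table.

    For each fold, every base learner is trained on the remaining k-1 folds
    and scores the held-out fold, so no row's meta-features were produced by
    a model that saw it. Returns one probability column per base learner
    plus the label (and patient_id when present), aligned with the input
    rows.
    """
    base_specs = base_specs or default_base_learners(seed)
    feats = feature_names or [c for c in table.columns if c not in ("patient_id", "label")]
    x, y, groups = _design(table, feats)
    folds = folds if folds is not None else _make_folds(y, groups, k, seed)
    scores = np.zeros((x.shape[0], len(base_specs)))
    for train_idx, held_idx in folds:
        for j, (_, factory) in enumerate(base_specs):
            model = factory()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(x[train_idx], y[train_idx])
                scores[held_idx, j] = model.predict_proba(x[held_idx])[:, 1]
    meta = pd.DataFrame(scores, columns=[name for name, _ in base_specs],
                        index=table.index)
    meta["label"] = table["label"].to_numpy()
    if "patient_id" in table.columns:
        meta["patient_id"] = table["patient_id"].to_numpy()
    return meta


def train_stacked(table: pd.DataFrame, base_specs: list | None = None,
                  k: int = 5, seed: int = 0,
                  feature_names: list | None = None) -> StackedModel:
    """Train the full MER system on a feature table.

    Builds the out-of-fold meta table, fits the (4, 4, 1) meta-ANN on it
    (cross-entropy loss, full-batch L-BFGS, at most 500 iterations), then
    refits every base learner on the whole table for deployment.
    """
    base_specs = base_specs or default_base_learners(seed)
    feats = feature_names or [c for c in table.columns if c not in ("patient_id", "label")]
    meta = build_meta_features(table, base_specs, k=k, seed=seed, feature_names=feats)
    names = [name for name, _ in base_specs]
    meta_x = meta[names].to_numpy(float)
    meta_y = _as01(meta["label"].to_numpy())
    # a 4-4-1 network is tiny: full-batch L-BFGS on the cross-entropy loss
    # converges deterministically where stochastic optimizers stall on the
    # initial plateau; mild L2 keeps the boundary centred in the margin
    ann = MLPClassifier(
        hidden_layer_sizes=(4,),
        activation="logistic",
        solver="lbfgs",
        alpha=0.01,
        max_iter=500,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ann.fit(meta_x, meta_y)
    x, y, _ = _design(table, feats)
    fitted = []
    for _, factory in base_specs:
        model = factory()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(x, y)
        fitted.append(model)
    return StackedModel(names, fitted, ann, feats, k)


def predict(model: StackedModel, features: pd.DataFrame,
            threshold: float = 0.5):
    """Predict labels and apnea scores for a feature table.

    Base scores are each learner's apnea probability; the meta-ANN maps the
    4-vector of base scores to the final score in [0, 1]; labels use the
    fixed 0.5 threshold.
    """
    x = features[model.feature_names].to_numpy(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        base_scores = np.column_stack(
            [m.predict_proba(x)[:, 1] for m in model.base_models])
        scores = model.meta.predict_proba(base_scores)[:, 1]
    labels = np.where(scores >= threshold, APNEA, NORMAL)
    return labels, scores


def evaluate(model: StackedModel, features: pd.DataFrame) -> MetricsReport:
    """Score a labelled held-out table with the full metric set."""
    labels, scores = predict(model, features)
    c = confusion(features["label"].to_numpy(), labels)
    return MetricsReport(sensitivity(c), specificity(c), accuracy(c),
                         auc(features["label"].to_numpy(), scores), c)
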