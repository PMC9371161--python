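"""Two-stage feature selection.

Stage 1 counts, per feature, the number of patients for whom both a one-way
ANOVA and a Wilcoxon rank-sum test separate apnea from normal segments at
alpha (the count is written λ). Features whose λ exceeds half the number of
processed patients survive, and are grouped into ordered classes by the
largest gaps in their λ values.

Stage 2 is an SVM-wrapped hill climb: cumulative class unions (or λ-ordered
feature prefixes) are scored with a grid of SVM kernels/parameters on a
held-out split, and the subset is adjudicated by accuracy first, mean AUC
among near-ties second.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .mer import confusion, sensitivity, specificity, accuracy, auc
from .psg import APNEA, NORMAL

logger = logging.getLogger(__name__)

__all__ = [
    "SignificanceSummary",
    "ClassGrouping",
    "SvmConfig",
    "SelectionResult",
    "stage1_lambda",
    "threshold_select",
    "group_classes",
    "balance_and_clean",
    "split_patients",
    "default_svm_grid",
    "svm_grid_eval",
    "hill_climb_classes",
    "hill_climb_features",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SignificanceSummary:
    """Stage-1 result: λ per feature plus the per-patient test outcomes."""

    lambda_counts: pd.Series            # feature -> λ
    pair_positive: pd.DataFrame         # patients x features, bool
    anova_p: pd.DataFrame               # patients x features
    ranksum_reject: pd.DataFrame        # patients x features, bool
    skipped_patients: list = field(default_factory=list)

    @property
    def n_processed(self) -> int:
        return self.pair_positive.shape[0]


@dataclass
class ClassGrouping:
    """Ordered feature classes (A = highest λ range, then B, C, ...)."""

    classes: list  # list of (name, [features], (lambda_min, lambda_max))

    def cumulative(self) -> list:
        """Cumulative unions: A, A+B, A+B+C, ... with concatenated names."""
        out, acc, label = [], [], ""
        for name, feats, _ in self.classes:
            acc = acc + list(feats)
            label += name
            out.append((label, list(acc)))
        return out

    def all_features(self) -> list:
        return [f for _, feats, _ in self.classes for f in feats]


@dataclass(frozen=True)
class SvmConfig:
    """One SVM kernel/parameter combination.

    ``R`` is the regularization weight (sklearn's C); the polynomial kernel
    is (x.y + 1)^d; the RBF kernel is exp(-|x-y|^2 / (2 sigma^2)).
    """

    kernel: str
    R: float
    d: int | None = None
    sigma: float | None = None

    def __post_init__(self) -> None:
        if self.kernel not in ("linear", "polynomial", "rbf"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.R <= 0:
            raise ValueError("R must be positive")
        if self.kernel == "polynomial" and self.d not in (2, 3, 4):
            raise ValueError("polynomial degree must be 2, 3 or 4")
        if self.kernel == "rbf" and (self.sigma is None or self.sigma <= 0):
            raise ValueError("RBF width sigma must be positive")

    def estimator(self) -> SVC:
        if self.kernel == "linear":
            svc = SVC(kernel="linear", C=self.R)
        elif self.kernel == "polynomial":
            svc = SVC(kernel="poly", degree=self.d, gamma=1.0, coef0=1.0, C=self.R)
        else:
            svc = SVC(kernel="rbf", gamma=1.0 / (2.0 * self.sigma ** 2), C=self.R)
        return make_pipeline(StandardScaler(), svc)

    def describe(self) -> str:
        if self.kernel == "linear":
            return f"linear R={self.R}"
        if self.kernel == "polynomial":
            return f"poly d={self.d} R={self.R}"
        return f"rbf sigma={self.sigma} R={self.R}"


@dataclass
class SelectionResult:
    """Chosen subset plus the full decision trace of the hill climb."""

    chosen: list
    trace: list                         # one dict per evaluated candidate
    baseline: dict

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"chosen": self.chosen, "baseline": self.baseline, "trace": self.trace},
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


# ---------------------------------------------------------------------------
# Stage 1: λ-counting
# ---------------------------------------------------------------------------

def stage1_lambda(table: pd.DataFrame, alpha: float = 0.05,
                  feature_names: list | None = None) -> SignificanceSummary:
    """Per-patient ANOVA + rank-sum counting.

    For every patient with at least 2 apnea and 2 normal segments, each
    feature is tested apnea-vs-normal with a one-way ANOVA (positive iff
    p < alpha) and a Wilcoxon rank-sum test (positive iff rejected at
    alpha). A pair is positive when both tests are. λ of a feature is the
    number of patients with a positive pair. Patients lacking a class are
    skipped and listed in the summary.
    """
    feats = feature_names or [c for c in table.columns if c not in ("patient_id", "label")]
    anova_rows, rank_rows, pids, skipped = [], [], [], []
    for pid, sub in table.groupby("patient_id", sort=True):
        a = sub.loc[sub["label"] == APNEA, feats].to_numpy(float)
        n = sub.loc[sub["label"] == NORMAL, feats].to_numpy(float)
        if a.shape[0] < 2 or n.shape[0] < 2:
            skipped.append(pid)
            logger.info("stage1_lambda: patient %r skipped (needs >=2 segments per class)", pid)
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p_anova = spstats.f_oneway(a, n, axis=0).pvalue
                p_rank = spstats.ranksums(a, n, axis=0).pvalue
        anova_rows.append(np.where(np.isfinite(p_anova), p_anova, 1.0))
        rank_rows.append(np.where(np.isfinite(p_rank), p_rank, 1.0))
        pids.append(pid)
    anova_p = pd.DataFrame(anova_rows, index=pids, columns=feats)
    rank_p = pd.DataFrame(rank_rows, index=pids, columns=feats)
    rank_reject = rank_p < alpha
    pair = (anova_p < alpha) & rank_reject
    lam = pair.sum(axis=0).astype(int)
    return SignificanceSummary(lam, pair, anova_p, rank_reject, skipped)


def threshold_select(summary: SignificanceSummary, n_patients: int | None = None) -> list:
    """Features with λ strictly greater than half the processed patients."""
    n = summary.n_processed if n_patients is None else n_patients
    thr = n / 2.0
    lam = summary.lambda_counts
    return [f for f in lam.index if lam[f] > thr]


def group_classes(lambdas: pd.Series, selected: list | None = None, k: int = 4) -> ClassGrouping:
    """Split selected features into k classes at the largest λ gaps.

    Features are sorted by λ descending; the k-1 largest gaps between
    consecutive λ values become class boundaries (gap ties broken toward
    the higher class, i.e. the earlier boundary position wins).
    """
    if selected is None:
        selected = list(lambdas.index)
    if not selected:
        raise ValueError("group_classes: no selected features")
    lam = lambdas[selected].sort_values(ascending=False, kind="stable")
    values = lam.to_numpy(float)
    k = max(1, min(k, len(selected)))
    if k == 1 or len(selected) == 1:
        boundaries = []
    else:
        gaps = values[:-1] - values[1:]
        order = sorted(range(gaps.size), key=lambda i: (-gaps[i], i))
        boundaries = sorted(order[:k - 1])
    classes, start = [], 0
    names = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    for j, b in enumerate(boundaries + [len(selected) - 1]):
        feats = list(lam.index[start:b + 1])
        classes.append((names[j], feats, (float(values[b]), float(values[start]))))
        start = b + 1
    return ClassGrouping(classes)


# ---------------------------------------------------------------------------
# data hygiene and splits
# ---------------------------------------------------------------------------

def balance_and_clean(table: pd.DataFrame, seed: int = 0, z_threshold: float = 3.0,
                      feature_names: list | None = None) -> pd.DataFrame:
    """Outlier removal (|z| > 3 on any feature) then random undersampling of
    the majority class to the minority count."""
    feats = feature_names or [c for c in table.columns if c not in ("patient_id", "label")]
    x = table[feats].to_numpy(float)
    mu, sd = x.mean(axis=0), x.std(axis=0)
    sd = np.where(sd < 1e-15, 1.0, sd)
    keep = np.all(np.abs((x - mu) / sd) <= z_threshold, axis=1)
    clean = table.loc[keep].reset_index(drop=True)
    counts = clean["label"].value_counts()
    if len(counts) < 2:
        logger.warning("balance_and_clean: only one class present after cleaning")
        return clean
    minority = counts.min()
    rng = np.random.default_rng(seed)
    parts = []
    for label, sub in clean.groupby("label"):
        idx = rng.choice(sub.index.to_numpy(), size=minority, replace=False)
        parts.append(clean.loc[np.sort(idx)])
    return pd.concat(parts).sort_index().reset_index(drop=True)


def split_patients(table: pd.DataFrame, test_fraction: float = 0.3, seed: int = 0):
    """Patient-level train/test split: no patient appears in both halves."""
    pids = np.array(sorted(table["patient_id"].unique()))
    rng = np.random.default_rng(seed)
    rng.shuffle(pids)
    n_test = max(1, int(round(test_fraction * pids.size)))
    test_ids = set(pids[:n_test])
    test_mask = table["patient_id"].isin(test_ids)
    return (table.loc[~test_mask].reset_index(drop=True),
            table.loc[test_mask].reset_index(drop=True))


# ---------------------------------------------------------------------------
# Stage 2: SVM grid + hill climbing
# ---------------------------------------------------------------------------

def default_svm_grid() -> list[SvmConfig]:
    """The 21-configuration grid: RBF sigma in {1,5,25}, polynomial degree
    in {2,3,4} and linear, each crossed with R in {0.2, 1, 10}."""
    grid: list[SvmConfig] = []
    for sigma in (1.0, 5.0, 25.0):
        for r in (0.2, 1.0, 10.0):
            grid.append(SvmConfig("rbf", r, sigma=sigma))
    for d in (2, 3, 4):
        for r in (0.2, 1.0, 10.0):
            grid.append(SvmConfig("polynomial", r, d=d))
    for r in (0.2, 1.0, 10.0):
        grid.append(SvmConfig("linear", r))
    return grid


def _labels01(table: pd.DataFrame) -> np.ndarray:
    return (table["label"] == APNEA).to_numpy(int)


def svm_grid_eval(train: pd.DataFrame, test: pd.DataFrame, subset: list,
                  grid: list[SvmConfig] | None = None) -> list[dict]:
    """Fit each SVM configuration on the training table and report
    sensitivity/specificity/accuracy/AUC on the held-out table."""
    grid = grid if grid is not None else default_svm_grid()
    xtr, ytr = train[subset].to_numpy(float), _labels01(train)
    xte, yte = test[subset].to_numpy(float), _labels01(test)
    results = []
    for cfg in grid:
        est = cfg.estimator()
        est.fit(xtr, ytr)
        pred = est.predict(xte)
        scores = est.decision_function(xte)
        c = confusion(yte, pred)
        results.append({
            "config": cfg.describe(),
            "sens": sensitivity(c),
            "spec": specificity(c),
            "acc": accuracy(c),
            "auc": auc(yte, scores),
        })
    return results


def _candidate_metrics(train, test, subset, grid):
    rows = svm_grid_eval(train, test, subset, grid)
    best_acc = max(r["acc"] for r in rows)
    mean_auc = float(np.mean([r["auc"] for r in rows]))
    return rows, best_acc, mean_auc


def hill_climb_classes(train: pd.DataFrame, test: pd.DataFrame,
                       grouping: ClassGrouping,
                       grid: list[SvmConfig] | None = None,
                       acc_tolerance: float = 0.01) -> SelectionResult:
    """Evaluate cumulative class unions (A, AB, ABC, ...) plus the
    all-feature baseline; choose the candidate with the highest mean AUC
    among those whose best accuracy is within ``acc_tolerance`` of the
    overall best."""
    grid = grid if grid is not None else default_svm_grid()
    all_feats = [c for c in train.columns if c not in ("patient_id", "label")]
    candidates = grouping.cumulative() + [("all_features", all_feats)]
    trace = []
    for name, feats in candidates:
        rows, best_acc, mean_auc = _candidate_metrics(train, test, feats, grid)
        trace.append({"candidate": name, "features": feats, "n_features": len(feats),
                      "best_acc": best_acc, "mean_auc": mean_auc, "grid": rows})
    top_acc = max(t["best_acc"] for t in trace)
    eligible = [t for t in trace if t["best_acc"] >= top_acc - acc_tolerance]
    chosen = max(eligible, key=lambda t: t["mean_auc"])
    baseline = trace[-1]
    return SelectionResult(chosen["features"], trace,
                           {"candidate": baseline["candidate"],
                            "best_acc": baseline["best_acc"],
                            "mean_auc": baseline["mean_auc"]})


def hill_climb_features(train: pd.DataFrame, test: pd.DataFrame,
                        lambdas: pd.Series,
                        config: SvmConfig | list[SvmConfig] | None = None) -> SelectionResult:
    """Greedy λ-ordered prefix search.

    Features are ordered by λ descending (the single best feature first);
    prefixes of growing length are scored and the shortest prefix whose
    accuracy reaches the all-feature gold standard is chosen.
    """
    if config is None:
        configs = [SvmConfig("rbf", 1.0, sigma=5.0)]
    elif isinstance(config, SvmConfig):
        configs = [config]
    else:
        configs = list(config)
    feats = [c for c in train.columns if c not in ("patient_id", "label")]
    order = list(lambdas[feats].sort_values(ascending=False, kind="stable").index)
    _, base_acc, base_auc = _candidate_metrics(train, test, feats, configs)
    baseline = {"candidate": "all_features", "best_acc": base_acc, "mean_auc": base_auc}
    trace, chosen = [], None
    for k in range(1, len(order) + 1):
        prefix = order[:k]
        _, acc_k, auc_k = _candidate_metrics(train, test, prefix, configs)
        trace.append({"candidate": f"prefix_{k}", "features": prefix,
                      "n_features": k, "best_acc": acc_k, "mean_auc": auc_k})
        if chosen is None and acc_k >= base_acc:
            chosen = prefix
    if chosen is None:
        chosen = order  # no prefix matched: fall back to the full ordering
    return SelectionResult(list(chosen), trace, baseline)
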