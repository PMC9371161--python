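"""Two-stage selection tests: λ-counting, thresholding, class grouping,
balancing, the SVM grid and both hill-climb variants."""

import numpy as np
import pandas as pd
import pytest

from apnea_mer import selection as sel
from apnea_mer import synth
from apnea_mer.selection import SignificanceSummary, SvmConfig


def make_summary(lambdas: dict, n_patients: int) -> SignificanceSummary:
    feats = list(lambdas)
    pair = pd.DataFrame(False, index=range(n_patients), columns=feats)
    for f, lam in lambdas.items():
        pair.loc[: lam - 1, f] = True
    return SignificanceSummary(
        pd.Series(lambdas), pair, pair.astype(float), pair)


# ---------------------------------------------------------------------------
# Stage 1
# ---------------------------------------------------------------------------

def test_lambda_is_near_zero_under_the_null():
    table, informative, noise = synth.synthetic_feature_table(
        n_patients=40, n_informative=0, n_noise=20, seed=3)
    summary = sel.stage1_lambda(table)
    # both tests at alpha=0.05 and strongly correlated: false-positive pairs
    # per patient stay well below 15%
    assert (summary.lambda_counts <= 0.15 * 40).all()


def test_lambda_saturates_under_strong_separation():
    table, informative, _ = synth.synthetic_feature_table(
        n_patients=40, n_informative=3, n_noise=2, separation_sd=5.0, seed=4)
    summary = sel.stage1_lambda(table)
    assert (summary.lambda_counts[informative] == 40).all()


def test_lambda_bounded_by_patient_count():
    table, _, _ = synth.synthetic_feature_table(n_patients=10, seed=5)
    summary = sel.stage1_lambda(table)
    assert (summary.lambda_counts <= summary.n_processed).all()
    assert summary.n_processed == 10


def test_single_class_patient_skipped():
    table, _, _ = synth.synthetic_feature_table(n_patients=4, seed=6)
    table = table[~((table.patient_id == "p000") & (table.label == "apnea"))]
    summary = sel.stage1_lambda(table)
    assert summary.skipped_patients == ["p000"]
    assert summary.n_processed == 3


def test_lambda_invariant_under_monotone_transform():
    table, informative, noise = synth.synthetic_feature_table(
        n_patients=8, n_informative=2, n_noise=2, seed=7)
    feats = informative + noise
    warped = table.copy()
    warped[feats] = np.exp(warped[feats] / 3.0)  # strictly monotone
    r1 = sel.stage1_lambda(table).ranksum_reject
    r2 = sel.stage1_lambda(warped).ranksum_reject
    assert r1.equals(r2)


# ---------------------------------------------------------------------------
# thresholding + grouping
# ---------------------------------------------------------------------------

def test_threshold_is_strict_majority():
    summary = make_summary({"a": 788, "b": 787, "c": 0}, n_patients=1574)
    assert sel.threshold_select(summary, n_patients=1574) == ["a"]


def test_threshold_all_zero_selects_nothing():
    summary = make_summary({"a": 0, "b": 0}, n_patients=10)
    assert sel.threshold_select(summary, n_patients=10) == []


def test_group_classes_splits_at_largest_gaps():
    lam = pd.Series({"f12": 1565, "f48": 1529, "f10": 1509, "f8": 1215,
                     "f7": 997, "f26": 947, "f11": 831})
    grouping = sel.group_classes(lam, k=4)
    members = {name: set(feats) for name, feats, _ in grouping.classes}
    # gaps: 36, 20, 294, 218, 50, 116 -> boundaries after 1509, 1215, 947
    assert members["A"] == {"f12", "f48", "f10"}
    assert members["B"] == {"f8"}
    assert members["C"] == {"f7", "f26"}
    assert members["D"] == {"f11"}


def test_group_classes_single_class():
    lam = pd.Series({"a": 10, "b": 8, "c": 5})
    grouping = sel.group_classes(lam, k=1)
    assert len(grouping.classes) == 1
    assert set(grouping.classes[0][1]) == {"a", "b", "c"}


def test_group_classes_disjoint_and_ordered():
    rng = np.random.default_rng(8)
    lam = pd.Series(rng.integers(100, 1000, 20), index=[f"f{i}" for i in range(20)])
    grouping = sel.group_classes(lam, k=4)
    seen = set()
    prev_min = np.inf
    for _, feats, (lo, hi) in grouping.classes:
        assert not (seen & set(feats))
        seen.update(feats)
        assert hi <= prev_min
        prev_min = lo
    assert seen == set(lam.index)


# ---------------------------------------------------------------------------
# balancing / splits
# ---------------------------------------------------------------------------

def _toy_table(seed=0, n=40):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "patient_id": [f"p{i % 8}" for i in range(n)],
        "label": ["apnea" if i % 3 == 0 else "normal" for i in range(n)],
        "x": rng.standard_normal(n),
        "y": rng.standard_normal(n),
    })


def test_balance_equalizes_classes_deterministically():
    t = _toy_table()
    b1 = sel.balance_and_clean(t, seed=3)
    b2 = sel.balance_and_clean(t, seed=3)
    counts = b1["label"].value_counts()
    assert counts["apnea"] == counts["normal"]
    assert b1.equals(b2)


def test_balance_drops_outlier_rows():
    t = _toy_table()
    t.loc[0, "x"] = 1e6  # ~10 SD outlier
    b = sel.balance_and_clean(t, seed=0)
    assert 1e6 not in b["x"].to_numpy()


def test_split_patients_is_disjoint():
    t = _toy_table(n=80)
    train, test = sel.split_patients(t, test_fraction=0.3, seed=1)
    assert not (set(train.patient_id) & set(test.patient_id))
    assert len(train) + len(test) == len(t)


# ---------------------------------------------------------------------------
# SVM grid + hill climbing
# ---------------------------------------------------------------------------

def test_default_grid_structure():
    grid = sel.default_svm_grid()
    assert len(grid) == 21
    kinds = [(c.kernel, c.d, c.sigma) for c in grid]
    assert kinds.count(("linear", None, None)) == 3
    for d in (2, 3, 4):
        assert kinds.count(("polynomial", d, None)) == 3
    for s in (1.0, 5.0, 25.0):
        assert kinds.count(("rbf", None, s)) == 3
    for c in grid:
        assert c.R in (0.2, 1.0, 10.0)


def test_svm_config_validation():
    with pytest.raises(ValueError):
        SvmConfig("rbf", 1.0)            # missing sigma
    with pytest.raises(ValueError):
        SvmConfig("polynomial", 1.0, d=5)
    with pytest.raises(ValueError):
        SvmConfig("linear", -1.0)


def _separable_tables(seed=0, n=120):
    rng = np.random.default_rng(seed)
    def draw(m):
        y = rng.integers(0, 2, m)
        x = rng.standard_normal((m, 2)) * 0.1 + np.column_stack([y * 4.0, -y * 4.0])
        return pd.DataFrame({
            "patient_id": [f"p{i % 6}" for i in range(m)],
            "label": np.where(y == 1, "apnea", "normal"),
            "g1": x[:, 0], "g2": x[:, 1],
            "n1": rng.standard_normal(m),
        })
    return draw(n), draw(n // 2)


def test_linear_kernel_separates_separable_data():
    train, test = _separable_tables()
    rows = sel.svm_grid_eval(train, test, ["g1", "g2"],
                             grid=[SvmConfig("linear", 1.0)])
    assert rows[0]["acc"] == 1.0
    assert rows[0]["auc"] == 1.0


def test_grid_metrics_in_unit_interval(small_window_table):
    train, test = sel.split_patients(small_window_table, seed=2)
    rows = sel.svm_grid_eval(train, test, ["sao2.min", "sao2.Bel98"],
                             grid=[SvmConfig("rbf", 1.0, sigma=5.0),
                                   SvmConfig("polynomial", 1.0, d=2)])
    for r in rows:
        for key in ("sens", "spec", "acc", "auc"):
            assert 0.0 <= r[key] <= 1.0


def test_hill_climb_classes_candidate_enumeration_and_choice():
    train, test = _separable_tables(seed=1)
    lam = pd.Series({"g1": 10, "g2": 9, "n1": 6})
    grouping = sel.group_classes(lam, k=2)  # A = {g1, g2}, B = {n1}
    result = sel.hill_climb_classes(train, test, grouping,
                                    grid=[SvmConfig("linear", 1.0)])
    assert [t["candidate"] for t in result.trace] == ["A", "AB", "all_features"]
    assert set(result.chosen) == {"g1", "g2"}
    for t in result.trace:
        assert {"best_acc", "mean_auc", "grid"} <= set(t)


def test_hill_climb_features_prefix_rule():
    train, test = _separable_tables(seed=2)
    lam = pd.Series({"g1": 10, "g2": 9, "n1": 6})
    result = sel.hill_climb_features(train, test, lam,
                                     config=SvmConfig("linear", 1.0))
    assert result.trace[0]["features"] == ["g1"]          # argmax λ first
    chosen_acc = next(t["best_acc"] for t in result.trace
                      if t["features"] == result.chosen)
    assert chosen_acc >= result.baseline["best_acc"]
    assert len(result.chosen) <= 3


def test_selection_result_serializes(tmp_path):
    train, test = _separable_tables(seed=3)
    lam = pd.Series({"g1": 10, "g2": 9, "n1": 6})
    result = sel.hill_climb_features(train, test, lam,
                                     config=SvmConfig("linear", 1.0))
    path = tmp_path / "selection.json"
    result.to_json(path)
    import json
    payload = json.loads(path.read_text())
    assert payload["chosen"] == result.chosen
    assert len(payload["trace"]) == len(result.trace)
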