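"""Monte-Carlo evaluation framework: splits, SMOTE, metrics, selection,
and group comparisons — checked against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from somnophen import evaluate
from somnophen.catalog import FEATURE_SETS, SET_ORDER
from somnophen.evaluate import (
    EvalConfig,
    _balance_with_smote,
    _positive_label,
    balanced_exclusion_model,
    bh_adjust,
    cv_fold_data,
    evaluate_task,
    f1_score,
    group_mean_comparison,
    roc_auc,
    select_top_features,
    smote_oversample,
    stratified_mc_split,
)


# ---------------------------------------------------------------- splits

def test_stratified_split_sizes_match_rounding():
    rng = np.random.default_rng(0)
    y = np.array(["a"] * 90 + ["b"] * 41)
    train, test = stratified_mc_split(y, 0.7, rng)
    assert train.size == 63 + 29  # round(0.7*90), round(0.7*41)
    assert test.size == 27 + 12
    assert np.intersect1d(train, test).size == 0
    assert np.union1d(train, test).size == y.size
    assert np.sum(y[train] == "a") == 63 and np.sum(y[train] == "b") == 29


def test_stratified_split_rejects_tiny_classes():
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError):
        stratified_mc_split(np.array(["a"] * 10 + ["b"] * 3), 0.7, rng)


def test_split_varies_with_rng_state():
    y = np.array(["a"] * 20 + ["b"] * 20)
    t1, _ = stratified_mc_split(y, 0.7, np.random.default_rng(1))
    t2, _ = stratified_mc_split(y, 0.7, np.random.default_rng(2))
    assert not np.array_equal(t1, t2)


# ----------------------------------------------------------------- SMOTE

def test_smote_points_lie_on_neighbor_segments():
    minority = np.array([[0.0, 0.0], [1.0, 1.0]])
    synth = smote_oversample(minority, 10, k=1, rng=np.random.default_rng(0))
    assert synth.shape == (10, 2)
    # with two points each synthetic is (u, u) for some u in [0, 1]
    np.testing.assert_allclose(synth[:, 0], synth[:, 1])
    assert np.all((synth >= 0.0) & (synth <= 1.0))


def test_smote_within_minority_bounding_box():
    rng = np.random.default_rng(3)
    minority = rng.normal(size=(20, 5))
    synth = smote_oversample(minority, 200, k=5, rng=rng)
    assert np.all(synth >= minority.min(axis=0) - 1e-12)
    assert np.all(synth <= minority.max(axis=0) + 1e-12)


def test_smote_edge_cases():
    assert smote_oversample(np.zeros((5, 3)), 0, 5, np.random.default_rng(0)).shape == (0, 3)
    dup = np.ones((4, 2))
    synth = smote_oversample(dup, 6, 5, np.random.default_rng(0))
    np.testing.assert_allclose(synth, 1.0)  # duplicates breed duplicates
    with pytest.raises(ValueError):
        smote_oversample(np.zeros((1, 2)), 3, 5, np.random.default_rng(0))


def test_balance_with_smote_equalizes_and_flags():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(30, 4))
    y = np.array(["a"] * 22 + ["b"] * 8, dtype=object)
    X_aug, y_aug, synth = _balance_with_smote(X, y, 5, rng)
    assert np.sum(y_aug == "a") == np.sum(y_aug == "b") == 22
    assert synth.sum() == 14  # exactly the deficit
    assert not synth[: len(y)].any()  # originals are first and unflagged
    np.testing.assert_array_equal(X_aug[: len(y)], X)


def test_cv_validation_folds_contain_only_original_points():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(40, 3))
    y = np.array(["a"] * 28 + ["b"] * 12, dtype=object)
    rows = {tuple(row) for row in X}
    n_val = 0
    for X_tr, y_tr, synth, X_val, y_val in cv_fold_data(X, y, 10, 5, rng):
        assert np.unique(y_val).size == 2
        for row in X_val:
            assert tuple(row) in rows  # never a synthetic point
        # training folds are balanced, synthetic points flagged
        a, b = np.sum(y_tr == "a"), np.sum(y_tr == "b")
        assert a == b
        assert synth.sum() == len(y_tr) - (40 - len(y_val))
        n_val += len(y_val)
    assert n_val == 40


# --------------------------------------------------------------- metrics

def test_roc_auc_worked_example():
    assert roc_auc([0.8, 0.4, 0.6, 0.3], [1, 1, 0, 0]) == pytest.approx(0.75)
    assert roc_auc([1, 1, 1, 1], [1, 0, 1, 0]) == pytest.approx(0.5)
    assert roc_auc([0.9, 0.8, 0.1], [1, 1, 0]) == 1.0
    with pytest.raises(ValueError):
        roc_auc([0.5, 0.5], [1, 1])


def _brute_force_auc(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = sum(1.0 if p > n else 0.5 if p == n else 0.0
                for p, n in itertools.product(pos, neg))
    return total / (len(pos) * len(neg))


@given(
    st.lists(
        st.tuples(st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0]), st.booleans()),
        min_size=2,
        max_size=12,
    )
)
@settings(max_examples=300, deadline=None)
def test_roc_auc_matches_pair_counting(pairs):
    scores = [s for s, _ in pairs]
    labels = [l for _, l in pairs]
    if not (any(labels) and not all(labels)):
        return
    assert abs(roc_auc(scores, labels) - _brute_force_auc(scores, labels)) < 1e-12


def test_f1_worked_example():
    # threshold 0.5: TP=2, FP=1, FN=1 -> precision 2/3, recall 2/3 -> F1 2/3
    scores = [0.9, 0.6, 0.7, 0.2]
    labels = [1, 1, 0, 1]
    assert f1_score(scores, labels) == pytest.approx(2 / 3)
    assert f1_score([0.1, 0.2], [1, 0]) == 0.0  # nothing predicted positive


def test_positive_label_minority_with_lexicographic_tiebreak():
    assert _positive_label(np.array(["a"] * 5 + ["b"] * 3, dtype=object)) == "b"
    assert _positive_label(np.array(["x"] * 2 + ["c"] * 7, dtype=object)) == "x"
    assert _positive_label(np.array(["a", "b", "a", "b"], dtype=object)) == "b"


def test_bh_adjust_worked_example():
    p = np.array([0.005, 0.011, 0.02, 0.04])
    np.testing.assert_allclose(bh_adjust(p), [0.02, 0.022, 0.04 / 1.5, 0.04])


def _bh_oracle(p):
    """Step-up BH written independently of statsmodels."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


@given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=40))
@settings(max_examples=300, deadline=None)
def test_bh_adjust_matches_step_up_oracle(p):
    np.testing.assert_allclose(bh_adjust(np.array(p)), _bh_oracle(p), atol=1e-12)


def test_bh_adjust_passes_nan_through():
    out = bh_adjust(np.array([0.01, np.nan, 0.04]))
    assert np.isnan(out[1])
    np.testing.assert_allclose(out[[0, 2]], multipletests([0.01, 0.04], method="fdr_bh")[1])


# ------------------------------------------------------- evaluation loop

def _toy_table(n_a=12, n_b=12, n_features=6, shift=0.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_a + n_b, n_features))
    X[n_a:, 0] += shift
    cols = [f"f{i}" for i in range(n_features)]
    table = pd.DataFrame(X, columns=cols)
    table.insert(0, "group", ["a"] * n_a + ["b"] * n_b)
    table.insert(0, "participant_id", [f"P{i}" for i in range(n_a + n_b)])
    return table, cols


FAST = EvalConfig(n_runs=4, grid=({"max_depth": None, "max_features": "sqrt"},),
                  n_trees=40, seed=3)


def test_evaluate_task_is_deterministic_and_well_formed():
    table, cols = _toy_table(shift=2.0)
    r1 = evaluate_task(table, cols, FAST)
    r2 = evaluate_task(table, cols, FAST)
    np.testing.assert_array_equal(r1.auc_runs, r2.auc_runs)
    np.testing.assert_array_equal(r1.f1_runs, r2.f1_runs)
    pd.testing.assert_frame_equal(r1.importance, r2.importance)
    assert r1.auc_runs.shape == (4,)
    assert np.all((r1.auc_runs >= 0) & (r1.auc_runs <= 1))
    assert set(r1.importance["feature"]) == set(cols)
    assert r1.importance["mean_rank"].is_monotonic_increasing
    # the shifted feature should rank first on separated data
    assert r1.importance["feature"].iloc[0] == "f0"
    roc = r1.mean_roc
    assert roc["tpr"].iloc[0] >= 0 and roc["tpr"].iloc[-1] == 1.0
    assert roc["tpr"].is_monotonic_increasing


def test_evaluate_task_handles_missing_cells():
    table, cols = _toy_table(shift=2.0, seed=4)
    table.loc[3, "f1"] = np.nan
    table.loc[7, "f2"] = np.nan
    result = evaluate_task(table, cols, FAST)
    assert np.all(np.isfinite(result.auc_runs))


def test_evaluate_task_positive_label_is_minority():
    table, cols = _toy_table(n_a=16, n_b=8, seed=5)
    assert evaluate_task(table, cols, FAST).positive_label == "b"


def test_final_model_is_fit_on_unaugmented_training_data(monkeypatch):
    """Provenance: with a 1-point grid every RF fit is a final fit, and it
    must see exactly the stratified training split — no synthetic rows."""
    table, cols = _toy_table(n_a=20, n_b=8, seed=6)
    seen = []
    original_fit = evaluate.RandomForestClassifier.fit

    def spy(self, X, y, **kw):
        seen.append((len(y), int(np.sum(np.asarray(y, dtype=object) == "b"))))
        return original_fit(self, X, y, **kw)

    monkeypatch.setattr(evaluate.RandomForestClassifier, "fit", spy)
    evaluate_task(table, cols, FAST)
    assert len(seen) == FAST.n_runs
    for n, n_b in seen:
        assert n == round(0.7 * 20) + round(0.7 * 8) == 20
        assert n_b == round(0.7 * 8)  # still imbalanced: SMOTE never applied


def test_tuning_fits_are_smote_balanced(monkeypatch):
    """With a 2-point grid the CV fits appear, each on equalized classes."""
    table, cols = _toy_table(n_a=20, n_b=8, seed=6)
    config = EvalConfig(
        n_runs=1, cv_folds=3, n_trees=10, seed=1,
        grid=({"max_depth": 2, "max_features": "sqrt"},
              {"max_depth": None, "max_features": "sqrt"}),
    )
    sizes = []
    original_fit = evaluate.RandomForestClassifier.fit

    def spy(self, X, y, **kw):
        y = np.asarray(y, dtype=object)
        sizes.append((int(np.sum(y == "a")), int(np.sum(y == "b"))))
        return original_fit(self, X, y, **kw)

    monkeypatch.setattr(evaluate.RandomForestClassifier, "fit", spy)
    evaluate_task(table, cols, config)
    cv_fits, final_fits = sizes[:-1], sizes[-1:]
    assert len(cv_fits) == 2 * 3  # grid points x folds
    assert all(a == b for a, b in cv_fits)  # SMOTE-balanced
    assert final_fits[0] == (14, 6)  # untouched training split


def test_evaluate_task_requires_binary_groups():
    table, cols = _toy_table()
    table.loc[0, "group"] = "c"
    with pytest.raises(ValueError):
        evaluate_task(table, cols, FAST)
    with pytest.raises(ValueError):
        evaluate_task(table, [], FAST)


# ------------------------------------------------------ feature selection

def _synthetic_rankings():
    """One ranking frame per set, ranks in catalog order."""
    rankings = {}
    for name in SET_ORDER:
        feats = list(FEATURE_SETS[name])
        rankings[name] = pd.DataFrame(
            {"feature": feats,
             "mean_importance": np.linspace(1, 0, len(feats)),
             "mean_rank": np.arange(1, len(feats) + 1, dtype=float)}
        )
    return rankings


def test_select_top_features_union_of_per_set_top8():
    rankings = _synthetic_rankings()
    selected = select_top_features(rankings)
    assert len(selected) == 48 == len(set(selected))
    for name in SET_ORDER:
        assert sum(f in FEATURE_SETS[name] for f in selected) == 8
    # best-ranked feature of each set is present
    for name in SET_ORDER:
        assert rankings[name]["feature"].iloc[0] in selected


def test_balanced_exclusion_preserves_total_size():
    rankings = _synthetic_rankings()
    model = balanced_exclusion_model(rankings, excluded_sets=["qeeg"])
    assert len(model) == 48 == len(set(model))
    assert not any(f in FEATURE_SETS["qeeg"] for f in model)


def test_balanced_exclusion_round_robin_counts():
    rankings = _synthetic_rankings()
    model = balanced_exclusion_model(rankings, excluded_sets=["qeeg", "spindle"])
    assert len(model) == 48
    counts = {
        name: sum(f in FEATURE_SETS[name] for f in model) for name in SET_ORDER
    }
    assert counts["qeeg"] == counts["spindle"] == 0
    assert counts["hypnogram"] == 8  # the whole set: only 8 features exist
    # refills distribute one feature per retained set per depth pass
    assert counts["quarter_hypnogram"] == 14
    assert counts["transition"] == 13
    assert counts["hypnodensity"] == 13


def test_balanced_exclusion_reports_shortfall_when_exhausted():
    rankings = _synthetic_rankings()
    model = balanced_exclusion_model(
        rankings,
        excluded_sets=["qeeg", "transition", "hypnodensity", "quarter_hypnogram"],
    )
    assert len(model) == 18  # hypnogram 8 + spindle 10: honest shortfall
    with pytest.raises(ValueError):
        balanced_exclusion_model(rankings, excluded_sets=list(SET_ORDER))


# ------------------------------------------------------ group comparisons

def test_group_mean_comparison_detects_shift_and_pools_bh():
    rng = np.random.default_rng(0)
    table = pd.DataFrame(
        {
            "group": ["a"] * 30 + ["b"] * 30,
            "x": np.r_[rng.normal(0, 1, 30), rng.normal(3, 1, 30)],
            "y": rng.normal(0, 1, 60),
            "z": np.ones(60),
        }
    )
    out = group_mean_comparison(table, [("a", "b")], ["x", "y", "z"])
    assert len(out) == 3
    x_row = out[out["feature"] == "x"].iloc[0]
    assert x_row["p"] < 1e-6 and x_row["p_adj"] >= x_row["p"]
    assert x_row["pct_diff"] == pytest.approx(
        100 * (table.x[:30].mean() - table.x[30:].mean()) / table.x[30:].mean()
    )
    z_row = out[out["feature"] == "z"].iloc[0]
    assert z_row["t"] == 0.0 and z_row["p"] == 1.0  # identical constants
    with pytest.raises(ValueError):
        group_mean_comparison(table, [("a", "missing")], ["x"])
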