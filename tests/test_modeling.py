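"""Split plans, AUC arithmetic, Ridge/MKL training and elimination."""

import numpy as np
import pytest

from artomics.datamodel import FeatureColumn, FeatureTable
from artomics.feature_selection import FSCombination
from artomics.modeling import (
    auc,
    backward_eliminate,
    build_model,
    clinical_factor_tests,
    compare_models,
    make_split_plan,
    summarize,
    train_mkl,
    train_ridge,
)


def labels_135():
    y = np.zeros(135, dtype=int)
    y[:35] = 1
    return y


def test_split_plan_stratified_counts():
    plan = make_split_plan(labels_135(), seed=0)
    y = labels_135()
    assert len(plan.iterations) == 20
    for it in plan.iterations:
        assert len(it.train_idx) in (94, 95)
        assert y[it.train_idx].sum() in (24, 25)
        union = np.sort(np.concatenate([it.train_idx, it.test_idx]))
        np.testing.assert_array_equal(union, np.arange(135))
        assert len(np.intersect1d(it.train_idx, it.test_idx)) == 0
        # every inner fold's training part keeps both classes
        for f in range(10):
            tr_rows = it.train_idx[it.fold_of_train_row != f]
            assert len(np.unique(y[tr_rows])) == 2


def test_split_plan_deterministic_and_diverse():
    plan1 = make_split_plan(labels_135(), seed=3)
    plan2 = make_split_plan(labels_135(), seed=3)
    for a, b in zip(plan1.iterations, plan2.iterations):
        np.testing.assert_array_equal(a.train_idx, b.train_idx)
        np.testing.assert_array_equal(a.fold_of_train_row, b.fold_of_train_row)
    holdouts = {tuple(np.sort(it.test_idx)) for it in plan1.iterations}
    assert len(holdouts) >= 19


def test_split_plan_rejects_tiny_class():
    y = np.zeros(50, dtype=int)
    y[:5] = 1
    with pytest.raises(ValueError, match=">= 10"):
        make_split_plan(y, seed=0)


def test_auc_hand_cases():
    assert auc([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0]) == 0.75
    assert auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0
    assert auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5  # all ties count one half


def test_summary_reproduces_normal_approximation_ci():
    rng = np.random.default_rng(0)
    # vectors constructed to the printed mean/SD, summarised to 3 decimals
    def vector(mean, sd, n=20):
        x = rng.normal(size=n)
        x = (x - x.mean()) / x.std(ddof=1)
        return mean + sd * x

    s = summarize(vector(0.942, 0.009))
    assert (s["ci_low"], s["ci_high"]) == (0.938, 0.946)
    s = summarize(vector(0.918, 0.034))
    assert (s["ci_low"], s["ci_high"]) == (0.903, 0.933)
    s = summarize([0.8] * 20)
    assert s["sd"] == 0.0 and s["ci_low"] == s["ci_high"] == 0.8


def test_compare_models_cases(caplog):
    rng = np.random.default_rng(1)
    a = rng.normal(0.8, 0.02, size=20)
    assert compare_models(a, a) == 1.0
    b = a - 0.1 + rng.normal(0, 1e-4, size=20)
    assert compare_models(a, b) < 1e-6
    assert compare_models(a, b) == compare_models(b, a)  # two-sided symmetry


def test_clinical_factor_tests():
    import pandas as pd

    labels = np.repeat([0, 1], 30)
    cov = pd.DataFrame({
        "sex": ["m", "f"] * 30,          # identical distribution in groups
        "age": np.r_[np.full(30, 50.0), np.full(30, 50.0)],
    })
    out = clinical_factor_tests(cov, {"sex": "categorical", "age": "continuous"}, labels)
    assert out.loc["sex", "statistic"] == pytest.approx(0.0)
    assert out.loc["sex", "p_value"] == pytest.approx(1.0)
    assert out.loc["age", "flag"] == "zero pooled variance"
    # 2x2 table [[10, 20], [20, 10]]: chi-square = 100/15 without correction
    labels2 = np.repeat([0, 1], 30)
    grp = np.array(["a"] * 10 + ["b"] * 20 + ["a"] * 20 + ["b"] * 10)
    out2 = clinical_factor_tests(
        pd.DataFrame({"g": grp}), {"g": "categorical"}, labels2
    )
    assert out2.loc["g", "statistic"] == pytest.approx(100 / 15)


def _folds(y, seed=0, n=10):
    from sklearn.model_selection import StratifiedKFold

    fold = np.empty(len(y), dtype=int)
    for f, (_, v) in enumerate(
        StratifiedKFold(n, shuffle=True, random_state=seed).split(np.zeros(len(y)), y)
    ):
        fold[v] = f
    return fold


def test_ridge_separable_toy_data():
    rng = np.random.default_rng(2)
    y = np.repeat([0, 1], 30)
    X = np.c_[y * 4.0 + rng.normal(0, 0.1, 60), rng.normal(size=60)]
    model = train_ridge(X, y, _folds(y))
    assert auc(model.decision(X), y) == 1.0


def test_ridge_null_on_permuted_labels():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(135, 10))
    y = labels_135()
    tr, te = np.arange(95), np.arange(95, 135)
    aucs = []
    for _ in range(6):
        perm = rng.permutation(y)
        model = train_ridge(X[tr], perm[tr], _folds(perm[tr]))
        aucs.append(auc(model.decision(X[te]), perm[te]))
    assert 0.38 <= np.mean(aucs) <= 0.62


def test_ridge_scale_invariance_after_standardisation():
    rng = np.random.default_rng(4)
    y = np.repeat([0, 1], 25)
    X = rng.normal(size=(50, 5)) + y[:, None]
    m1 = train_ridge(X, y, _folds(y))
    m2 = train_ridge(X * 2.0, y, _folds(y))
    np.testing.assert_allclose(m1.decision(X), m2.decision(X * 2.0), atol=1e-10)


def test_mkl_weights_normalised_and_noise_blocks_downweighted():
    rng = np.random.default_rng(5)
    y = np.repeat([0, 1], 40)
    signal = rng.normal(size=(80, 5)) + 2.0 * y[:, None]
    noise = rng.normal(size=(80, 5))
    model = train_mkl({"S": signal, "N": noise}, y, _folds(y))
    assert model.weights.min() >= 0
    assert model.weights.sum() == pytest.approx(1.0)
    w_noise = sum(
        w for w, s in zip(model.weights, model.specs) if s.block == "N"
    )
    assert w_noise < 0.2


def test_mkl_linear_kernel_matches_ridge():
    """Kernel ridge with a single linear kernel is dual to Ridge."""
    from artomics.modeling import KernelSpec

    rng = np.random.default_rng(6)
    n = 100
    y = (rng.random(n) < 0.35).astype(int)
    X = rng.normal(size=(n, 8)) + 1.2 * y[:, None]
    tr, te = np.arange(70), np.arange(70, 100)
    folds = _folds(y[tr])
    ridge = train_ridge(X[tr], y[tr], folds)
    mkl = train_mkl(
        {"B": X[tr]}, y[tr], folds, specs=[KernelSpec("polynomial", 1, "B")]
    )
    a_r = auc(ridge.decision(X[te]), y[te])
    a_m = auc(mkl.decision({"B": X[te]}), y[te])
    assert abs(a_r - a_m) <= 0.03


def _toy_table(rng, n=100, n_feat=40, n_inf=5, d=1.8):
    y = (rng.random(n) < 0.3).astype(int)
    X = rng.normal(size=(n, n_feat))
    X[:, :n_inf] += d * y[:, None]
    cols = [FeatureColumn("R", "voi", f"{'inf' if j < n_inf else 'noise'}{j}")
            for j in range(n_feat)]
    return FeatureTable(X, cols, [f"P{i}" for i in range(n)]), y


def test_backward_elimination_trajectory_and_recovery():
    rng = np.random.default_rng(7)
    table, y = _toy_table(rng)
    plan = make_split_plan(y, seed=1, n_iterations=8, n_folds=5)
    combo = FSCombination("fisher", "variance")
    from artomics.feature_selection import apply_combination

    selections = [
        apply_combination(table.matrix[it.train_idx], y[it.train_idx], table.keys,
                          combo, k_sup=20, k_final=10)
        for it in plan.iterations
    ]
    best, trajectory, (tr_aucs, te_aucs) = backward_eliminate(table, y, plan, selections)
    assert len(trajectory) == 10  # one retraining per size K..1
    assert [size for size, _ in trajectory] == list(range(10, 0, -1))
    assert sum("inf" in k for k in best) >= 3
    assert len(tr_aucs) == len(te_aucs) == len(plan.iterations)


def test_full_frequency_feature_eliminated_last():
    rng = np.random.default_rng(8)
    table, y = _toy_table(rng, n_feat=6, n_inf=1)
    plan = make_split_plan(y, seed=2, n_iterations=5, n_folds=5)
    keys = table.keys
    # feature 0 selected in all iterations; the rest alternate
    selections = [[keys[0], keys[1 + (i % 2)], keys[3 + (i % 2)]] for i in range(5)]
    best, trajectory, _ = backward_eliminate(table, y, plan, selections)
    assert trajectory[0][0] == 3
    # the always-selected feature outranks all partially selected ones,
    # so it is eliminated last and present in the returned set
    assert keys[0] in best


def test_holdout_rows_never_influence_training():
    """Mutating hold-out rows changes neither selection nor coefficients."""
    rng = np.random.default_rng(9)
    table, y = _toy_table(rng)
    plan = make_split_plan(y, seed=3, n_iterations=5, n_folds=5)
    combo = FSCombination("fisher", "variance")
    it = plan.iterations[0]
    X = table.matrix
    m1 = train_ridge(X[it.train_idx][:, :8], y[it.train_idx], it.fold_of_train_row)
    X2 = X.copy()
    X2[it.test_idx] = rng.normal(size=(len(it.test_idx), X.shape[1])) * 100
    m2 = train_ridge(X2[it.train_idx][:, :8], y[it.train_idx], it.fold_of_train_row)
    np.testing.assert_array_equal(m1.coef, m2.coef)
    assert m1.alpha == m2.alpha


def test_build_model_report_contract():
    rng = np.random.default_rng(10)
    table, y = _toy_table(rng)
    plan = make_split_plan(y, seed=4, n_iterations=6, n_folds=5)
    report = build_model(table, y, plan, FSCombination("fisher", "variance"),
                         "R", k_sup=20, k_final=8)
    assert len(report.train_aucs) == len(report.test_aucs) == 6
    assert report.test_summary["ci_low"] <= report.test_summary["mean"] <= report.test_summary["ci_high"]
    assert report.family_shares == {"R": 1.0}
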