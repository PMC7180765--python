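"""Classifier bench: training, SENS/SPEC evaluation, combination search
and model ranking."""
import numpy as np
import pandas as pd
import pytest

from bulksense import (
    CandidateModel,
    FitMetrics,
    TrainConfig,
    VariableSet,
    combination_search,
    evaluate,
    fixture_table2,
    pareto_front,
    rank_models,
    train_model,
)


class _Fixed:
    """Stub estimator returning canned labels."""

    def __init__(self, labels):
        self.labels = np.asarray(labels)

    def predict(self, X):
        return self.labels[: len(X)]


def _fixed_model(labels):
    return CandidateModel("LR", _Fixed(labels))


SMALL_CFG = TrainConfig(
    rng_seed=0, tree_grid=(25, 50), svm_C_grid=(10.0, 100.0), svm_gamma_grid=(0.1, 0.5)
)


# ---------------------------------------------------------------- evaluate
def test_evaluate_perfect_and_degenerate_predictions():
    y = pd.Series([0] * 5 + [1] * 5)
    X = pd.DataFrame({"a": np.arange(10.0)})
    perfect = evaluate(_fixed_model(y.to_numpy()), X, y)
    assert perfect.sens == perfect.spec == 1.0

    all_nonbulk = evaluate(_fixed_model(np.ones(10, int)), X, y)
    assert all_nonbulk.sens == 1.0 and all_nonbulk.spec == 0.0


def test_evaluate_counts_example():
    # bulking: 8 right / 2 wrong; non-bulking: 9 right / 1 wrong
    y = np.array([0] * 10 + [1] * 10)
    yhat = np.array([0] * 8 + [1] * 2 + [1] * 9 + [0] * 1)
    m = evaluate(_fixed_model(yhat), pd.DataFrame({"a": np.zeros(20)}), y)
    assert m.spec == pytest.approx(0.8) and m.sens == pytest.approx(0.9)
    # count consistency: rates recompute from integer confusion counts
    assert m.n_bulk_correct == 8 and m.n_nonbulk_correct == 9 and m.n_test == 20


def test_evaluate_requires_both_classes():
    with pytest.raises(ValueError):
        evaluate(_fixed_model(np.zeros(4, int)), pd.DataFrame({"a": np.zeros(4)}), np.zeros(4))


def test_fit_metrics_validation():
    with pytest.raises(ValueError):
        FitMetrics(5, 4, 0, 1)


# ------------------------------------------------------------ train_model
def test_lr_separates_toy_data():
    X = np.vstack([np.arange(5), np.arange(10, 15)]).reshape(-1, 1).astype(float)
    y = np.array([0] * 5 + [1] * 5)
    model = train_model("LR", X, y, SMALL_CFG)
    m = evaluate(model, X, y)
    assert m.sens == m.spec == 1.0 and model.converged


def test_single_class_training_is_rejected():
    X = np.random.default_rng(0).normal(size=(20, 2))
    with pytest.raises(ValueError):
        train_model("LR", X, np.ones(20, int), SMALL_CFG)
    with pytest.raises(ValueError):
        train_model("GLM", X, np.tile([0, 1], 10), SMALL_CFG)


@pytest.mark.parametrize("family", ["BT", "RF", "MLP", "SVM"])
def test_nonlinear_families_learn_a_clear_boundary(family):
    rng = np.random.default_rng(2)
    n = 240
    X = rng.normal(size=(n, 2))
    y = (X[:, 0] + X[:, 1] > 0).astype(int)
    model = train_model(family, X[:180], y[:180], SMALL_CFG)
    m = evaluate(model, X[180:], y[180:])
    assert min(m.sens, m.spec) > 0.7, family
    assert model.hyperparam_label() != ""


def test_lr_matches_independent_mle_fit():
    """Dual route: bench LR coefficients against a second maximum
    likelihood implementation on the same data."""
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(5)
    n = 800
    X = rng.normal(size=(n, 2))
    p = 1 / (1 + np.exp(-(0.5 + 1.2 * X[:, 0] - 0.8 * X[:, 1])))
    y = (rng.random(n) < p).astype(int)
    model = train_model("LR", X, y, SMALL_CFG)
    ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
    est = np.r_[model.estimator.intercept_, model.estimator.coef_[0]]
    assert np.allclose(est, ref.params, rtol=1e-3, atol=1e-3)


def test_null_labels_give_chance_level_metrics():
    """Pure-noise labels: test-set balanced accuracy (SENS+SPEC)/2 hovers
    around chance level across seeds."""
    vals = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(400, 2))
        y = rng.integers(0, 2, 400)
        model = train_model("LR", X[:300], y[:300], TrainConfig(rng_seed=seed))
        m = evaluate(model, X[300:], y[300:])
        vals.append((m.sens + m.spec) / 2)
    assert 0.4 < np.mean(vals) < 0.6


# ----------------------------------------------------- combination search
def test_combination_search_table_shape(toy_records):
    tab = combination_search(
        toy_records,
        [VariableSet(("T",)), VariableSet(("T", "MLSS"))],
        families=["LR", "BT"],
        cfg=SMALL_CFG,
    )
    assert list(tab["combo"]) == ["D", "E,D"]
    assert {"LR_SP", "LR_SE", "BT_SP", "BT_SE", "BT_hp"} <= set(tab.columns)
    with pytest.raises(ValueError):
        combination_search(toy_records, [], ["LR"], SMALL_CFG)


def test_adding_a_signal_variable_rarely_hurts(toy_records):
    """Labels depend on both lagged T and MLSS; adding MLSS to a T-only
    model should not reduce min(SENS, SPEC) in the majority of seeds."""
    wins = 0
    n_seeds = 20
    for seed in range(n_seeds):
        cfg = TrainConfig(rng_seed=seed)
        tab = combination_search(
            toy_records,
            [VariableSet(("T",)), VariableSet(("T", "MLSS"))],
            families=["LR"],
            cfg=cfg,
        )
        s1 = min(tab.loc[0, "LR_SP"], tab.loc[0, "LR_SE"])
        s2 = min(tab.loc[1, "LR_SP"], tab.loc[1, "LR_SE"])
        wins += s2 >= s1
    assert wins > n_seeds / 2


def test_search_is_deterministic(toy_records):
    combos = [VariableSet(("T", "MLSS"))]
    a = combination_search(toy_records, combos, ["LR", "BT"], SMALL_CFG)
    b = combination_search(toy_records, combos, ["LR", "BT"], SMALL_CFG)
    pd.testing.assert_frame_equal(a, b)


# ----------------------------------------------------------------- ranking
def test_fixture_best_spec_for_mlss_t_is_svm():
    ranked = rank_models(fixture_table2(), criterion="max_spec")
    row = ranked[ranked["combo"] == "E,D"].iloc[0]
    assert row["best_family"] == "SVM" and row["best_SP"] == 1.00


def test_dominating_family_wins_under_every_criterion():
    tab = pd.DataFrame(
        [{"combo": "D", "LR_SP": 0.5, "LR_SE": 0.6, "BT_SP": 0.9, "BT_SE": 0.95}]
    )
    for crit in ("min_sens_spec", "max_spec", "max_sens"):
        assert rank_models(tab, crit)["best_family"].iloc[0] == "BT"


def test_exact_tie_prefers_simpler_family():
    tab = pd.DataFrame(
        [{"combo": "D", "MLP_SP": 0.9, "MLP_SE": 0.9, "LR_SP": 0.9, "LR_SE": 0.9}]
    )
    assert rank_models(tab)["best_family"].iloc[0] == "LR"


def test_pareto_front_is_nondominated():
    front = pareto_front(fixture_table2())
    nv, sc = front["n_vars"].to_numpy(), front["score"].to_numpy()
    for i in range(len(front)):
        dominated = ((nv <= nv[i]) & (sc >= sc[i]) & ((nv < nv[i]) | (sc > sc[i]))).any()
        assert not dominated
    assert front["n_vars"].is_monotonic_increasing
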