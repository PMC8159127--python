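"""Evaluation protocol and the reduction x classifier grid."""

import numpy as np
import pytest

from biodimred import PatternMatrix, evaluate_protocol, run_reduction_grid


def _two_clusters(n_per=20, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(size=(n_per, 4)),
                   rng.normal(size=(n_per, 4)) + 10.0])
    y = np.array(["a"] * n_per + ["b"] * n_per, dtype=object)
    return PatternMatrix(X, y)


def test_separable_clusters_give_perfect_knn():
    pm = _two_clusters()
    rep = evaluate_protocol(pm, ["Fine KNN", "Medium KNN", "Weighted KNN"],
                            {"kfold": 5}, seed=0)
    assert (rep["accuracy"] == 100.0).all()


def test_permuted_labels_hit_chance_level():
    """8 balanced classes with permuted labels: accuracy within 3 SD of
    12.5% (binomial null over the held-out predictions)."""
    rng = np.random.default_rng(1)
    n_per, K = 25, 8
    X = np.vstack([rng.normal(size=(n_per, 6)) + 5.0 * rng.normal(size=6)
                   for _ in range(K)])
    y = np.repeat([f"c{i}" for i in range(K)], n_per).astype(object)
    y = y[rng.permutation(len(y))]  # labels decoupled from features
    pm = PatternMatrix(X, y)
    rep = evaluate_protocol(pm, ["Fine KNN"], {"kfold": 5}, seed=0)
    n = pm.n_patterns
    sd = 100.0 * np.sqrt(0.125 * 0.875 / n)
    assert abs(rep["accuracy"].iloc[0] - 12.5) <= 3 * sd


def test_report_is_deterministic():
    pm = _two_clusters(seed=3)
    a = evaluate_protocol(pm, ["Fine Tree", "Fine KNN"], {"kfold": 4}, seed=7)
    b = evaluate_protocol(pm, ["Fine Tree", "Fine KNN"], {"kfold": 4}, seed=7)
    assert a.equals(b)


def test_recalls_average_to_accuracy():
    import json
    pm = _two_clusters(seed=5)
    rep = evaluate_protocol(pm, ["Medium Tree"], {"kfold": 4}, seed=2)
    row = rep.iloc[0]
    recalls = json.loads(row["per_class_recall"])
    counts = pm.class_counts()
    weighted = sum(recalls[c] * counts[c] for c in counts) / pm.n_patterns
    np.testing.assert_allclose(weighted, row["accuracy"], atol=1e-9)


def test_protocol_validation():
    pm = _two_clusters(n_per=3)
    with pytest.raises(ValueError, match="fewer than"):
        evaluate_protocol(pm, ["Fine KNN"], {"kfold": 5}, seed=0)
    one_class = PatternMatrix(np.zeros((6, 2)), np.array(["a"] * 6))
    with pytest.raises(ValueError, match="2 classes"):
        evaluate_protocol(one_class, ["Fine KNN"], {"kfold": 2}, seed=0)


def test_grid_row_arithmetic(small_pattern_set):
    specs = ["Fine KNN", "Linear Discriminant", "Fine Tree"]
    rep = run_reduction_grid(small_pattern_set, ["none"], [2, 3], specs, seed=0)
    assert len(rep) == len(specs)
    rep2 = run_reduction_grid(small_pattern_set, ["none", "cs", "le", "lpp"],
                              [2, 3], specs, {"kfold": 3}, seed=0)
    assert len(rep2) == len(specs) + 3 * 2 * len(specs)
    assert set(rep2["representation"]) == {"none", "cs", "le", "lpp"}


def test_grid_determinism(small_pattern_set):
    kwargs = dict(methods=["none", "cs"], dims=[3], specs=["Fine KNN"],
                  protocol={"kfold": 3}, seed=11)
    a = run_reduction_grid(small_pattern_set, **kwargs)
    b = run_reduction_grid(small_pattern_set, **kwargs)
    assert a.equals(b)


def test_grid_rejects_dims_at_feature_count(small_pattern_set):
    with pytest.raises(ValueError, match="below the feature count"):
        run_reduction_grid(small_pattern_set, ["cs"], [301], ["Fine KNN"],
                           seed=0)


def test_holdout_protocol():
    pm = _two_clusters(seed=9)
    rep = evaluate_protocol(pm, ["Fine KNN"], {"holdout": 0.25}, seed=0)
    assert rep["protocol"].iloc[0] == "holdout0.25"


def test_reduced_accuracy_approaches_original_with_dim():
    """Over a dimension sweep the best CS accuracy trends upward toward
    the original-space accuracy (Spearman rho > 0 over seeds)."""
    from scipy.stats import spearmanr

    from biodimred import make_ecg_pattern_set

    dims = [2, 5, 10, 25]
    rhos = []
    for seed in range(3):
        pm = make_ecg_pattern_set(12, seed=seed)
        rep = run_reduction_grid(pm, ["cs"], dims,
                                 ["Fine KNN", "Weighted KNN", "Cubic SVM"],
                                 {"kfold": 3}, seed=seed)
        best = [rep[(rep.representation == "cs") & (rep.dim == d)]
                ["accuracy"].max() for d in dims]
        rhos.append(spearmanr(dims, best).statistic)
    assert np.mean(rhos) > 0
    assert sum(r > 0 for r in rhos) >= 2
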