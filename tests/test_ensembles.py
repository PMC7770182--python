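"""Weighted trees, the four ensemble variants, and importance accounting."""

import numpy as np
import pytest

from grnforest import EnsembleConfig, ValidationError, fit_ensemble, fit_tree
from grnforest.ensembles import node_stats, predict, raw_importance, split_gain

TOY_X = np.array([[0.0], [0.0], [1.0], [1.0]])
TOY_Y = np.array([0.0, 0.0, 2.0, 2.0])


# ---------------------------------------------------------------------------
# weighted node statistics and split gain
# ---------------------------------------------------------------------------


def test_node_stats_hand_values():
    nw, ybar, sq = node_stats(TOY_Y, np.ones(4))
    assert (nw, ybar, sq) == (4.0, 1.0, 4.0)
    nw, ybar, sq = node_stats(TOY_Y, np.array([1.0, 1.0, 1.0, 3.0]))
    assert nw == 6.0
    assert ybar == pytest.approx(4.0 / 3.0, abs=1e-12)
    assert sq == pytest.approx(16.0 / 3.0, abs=1e-12)
    assert node_stats([5.0], [2.0])[2] == 0.0  # single sample
    with pytest.raises(ValidationError):
        node_stats(TOY_Y, np.ones(4), membership=[])


def test_split_gain_hand_values():
    w = np.ones(4)
    parent = node_stats(TOY_Y, w)
    left = node_stats(TOY_Y[:2], w[:2])
    right = node_stats(TOY_Y[2:], w[2:])
    assert split_gain(parent, left, right) == pytest.approx(4.0, abs=1e-12)
    # a split that does not change leaf means has zero gain
    mixed_l = node_stats(TOY_Y[[0, 2]], w[:2])
    mixed_r = node_stats(TOY_Y[[1, 3]], w[2:])
    assert split_gain(parent, mixed_l, mixed_r) == pytest.approx(0.0, abs=1e-12)
    # weighted perfect split
    w3 = np.array([1.0, 1.0, 1.0, 3.0])
    parent = node_stats(TOY_Y, w3)
    left = node_stats(TOY_Y[:2], w3[:2])
    right = node_stats(TOY_Y[2:], w3[2:])
    assert split_gain(parent, left, right) == pytest.approx(16.0 / 3.0, abs=1e-12)
    with pytest.raises(ValidationError):
        split_gain((4.0, 0, 1.0), (1.0, 0, 0.0), (1.0, 0, 0.0))


def test_literal_gain_is_count_weighted():
    w = np.ones(4)
    parent = node_stats(TOY_Y, w)
    left = node_stats(TOY_Y[:2], w[:2])
    right = node_stats(TOY_Y[2:], w[2:])
    assert split_gain(parent, left, right, literal=True) == pytest.approx(16.0)


# ---------------------------------------------------------------------------
# tree fitting
# ---------------------------------------------------------------------------


def test_constant_targets_single_leaf():
    tree = fit_tree(np.random.default_rng(0).random((10, 3)), np.full(10, 2.5), seed=0)
    assert tree.n_nodes == 1
    assert tree.is_leaf(0)
    assert tree.predict(np.zeros((1, 3)))[0] == pytest.approx(2.5)


def test_root_splits_on_determining_input():
    rng = np.random.default_rng(1)
    X = np.column_stack([rng.integers(0, 2, 40).astype(float), rng.random(40), rng.random(40)])
    y = 3.0 * X[:, 0]
    tree = fit_tree(X, y, config=EnsembleConfig(n_test=3), seed=5)
    assert tree.features[0] == 0


def test_height_cap():
    rng = np.random.default_rng(2)
    X, y = rng.random((50, 2)), rng.random(50)
    tree = fit_tree(X, y, config=EnsembleConfig(n_test=2, h_max=1), seed=0)
    assert tree.height <= 1
    deep = fit_tree(X, y, config=EnsembleConfig(n_test=2, h_max=4), seed=0)
    assert deep.height <= 4


def _brute_split_scan(X, y, w, literal=False):
    """All (variable, midpoint-cut, gain) triples from an exhaustive scan."""
    out = []
    parent = node_stats(y, w)
    for v in range(X.shape[1]):
        xs = np.unique(X[:, v])
        for a, b in zip(xs, xs[1:]):
            cut = 0.5 * (a + b)
            mask = X[:, v] <= cut
            g = split_gain(
                parent,
                node_stats(y[mask], w[mask]),
                node_stats(y[~mask], w[~mask]),
                literal=literal,
            )
            out.append((g, v, cut))
    return sorted(out, key=lambda e: -e[0])


@pytest.mark.parametrize("trial", range(25))
def test_chosen_split_matches_bruteforce(trial):
    rng = np.random.default_rng(1000 + trial)
    n = int(rng.integers(5, 31))
    X = rng.random((n, 3))
    y = rng.normal(size=n)
    w = rng.uniform(0.5, 2.0, n)
    tree = fit_tree(X, y, w, config=EnsembleConfig(n_test=3, h_max=1), seed=trial)
    scan = _brute_split_scan(X, y, w)
    g, v, cut = scan[0]
    chosen_gain = tree.sqs[0] - tree.sqs[1] - tree.sqs[2]
    assert chosen_gain == pytest.approx(g, rel=1e-9, abs=1e-9)
    # when the optimum is unique beyond float jitter, identity must hold too
    if g > 0 and (len(scan) == 1 or g - scan[1][0] > 1e-6 * max(g, 1.0)):
        assert tree.features[0] == v
        assert tree.thresholds[0] == pytest.approx(cut, rel=1e-12)


def test_ensemble_determinism_under_seed():
    rng = np.random.default_rng(3)
    X, y = rng.random((60, 5)), rng.random(60)
    a = fit_ensemble(X, y, config=EnsembleConfig(n_tree=3), seed=11)
    b = fit_ensemble(X, y, config=EnsembleConfig(n_tree=3), seed=11)
    np.testing.assert_array_equal(a.features, b.features)
    np.testing.assert_array_equal(a.thresholds, b.thresholds)
    np.testing.assert_array_equal(a.inbag, b.inbag)


def test_oob_fraction_matches_bootstrap_expectation():
    rng = np.random.default_rng(4)
    X, y = rng.random((100, 3)), rng.random(100)
    ens = fit_ensemble(X, y, config=EnsembleConfig(n_tree=200), seed=0)
    frac = ens.oob_mask.mean()
    assert frac == pytest.approx(np.exp(-1), abs=0.05)


def test_extra_cuts_inside_observed_range():
    rng = np.random.default_rng(5)
    X = np.column_stack([rng.uniform(2.0, 3.0, 50)])
    y = rng.random(50)
    ens = fit_ensemble(
        X, y, config=EnsembleConfig(n_tree=5, method="extra", n_test=1), seed=9
    )
    for i in range(ens.n_tree):
        tree = ens.tree(i)
        for node in range(tree.n_nodes):
            if not tree.is_leaf(node):
                assert 2.0 <= tree.thresholds[node] <= 3.0


def test_predict_constant_and_identical_trees():
    X = TOY_X
    yconst = np.full(4, 7.0)
    ens = fit_ensemble(X, yconst, config=EnsembleConfig(n_tree=5, n_test=1), seed=0)
    np.testing.assert_allclose(predict(ens, X), 7.0)
    # all-deterministic single-candidate trees without bootstrap are identical
    ens2 = fit_ensemble(
        TOY_X, TOY_Y, config=EnsembleConfig(n_tree=4, n_test=1, bootstrap=False), seed=0
    )
    single = ens2.tree(0).predict(TOY_X)
    np.testing.assert_allclose(predict(ens2, TOY_X), single)


def test_oob_predictions_match_per_tree_bookkeeping():
    rng = np.random.default_rng(6)
    X, y = rng.random((4, 2)), rng.random(4)
    ens = fit_ensemble(X, y, config=EnsembleConfig(n_tree=50, n_test=2), seed=8)
    pred, fallback = ens.oob_predict(X)
    allpred = np.array([ens.tree(i).predict(X) for i in range(ens.n_tree)])
    for q in range(4):
        oob = ens.oob_mask[:, q]
        if oob.any():
            assert not fallback[q]
            assert pred[q] == pytest.approx(allpred[oob, q].mean(), rel=1e-12)
        else:
            assert fallback[q]
            assert pred[q] == pytest.approx(allpred[:, q].mean(), rel=1e-12)


# ---------------------------------------------------------------------------
# importance
# ---------------------------------------------------------------------------


def test_raw_importance_toy_and_unused_input():
    X = np.column_stack([TOY_X[:, 0], np.zeros(4)])
    ens = fit_ensemble(
        X, TOY_Y, config=EnsembleConfig(n_tree=1, n_test=2, bootstrap=False), seed=0
    )
    assert raw_importance(ens, 0) == pytest.approx(4.0)
    assert raw_importance(ens, 1) == 0.0  # never used
    with pytest.raises(ValidationError):
        raw_importance(ens, 7)


def test_telescoping_identity_per_tree():
    """sum of node gains == root Sq - sum of leaf Sq, for every tree."""
    rng = np.random.default_rng(7)
    X, y = rng.random((40, 4)), rng.normal(size=40)
    w = rng.uniform(0.5, 2.0, 40)
    ens = fit_ensemble(X, y, w, config=EnsembleConfig(n_tree=10), seed=3)
    for i in range(ens.n_tree):
        tree = ens.tree(i)
        leaves = [k for k in range(tree.n_nodes) if tree.is_leaf(k)]
        leaf_sq = sum(tree.sqs[k] for k in leaves)
        assert ens.per_tree_importances_[i].sum() == pytest.approx(
            tree.sqs[0] - leaf_sq, rel=1e-9, abs=1e-9
        )


def test_weight_scaling_leaves_splits_unchanged():
    # power-of-two factor: the whole criterion scales exactly in binary
    # floating point, so even near-tied splits must come out identical
    rng = np.random.default_rng(8)
    X, y = rng.random((50, 4)), rng.normal(size=50)
    w = rng.uniform(0.5, 2.0, 50)
    a = fit_ensemble(X, y, w, config=EnsembleConfig(n_tree=5), seed=2)
    b = fit_ensemble(X, y, 4.0 * w, config=EnsembleConfig(n_tree=5), seed=2)
    np.testing.assert_array_equal(a.features, b.features)
    np.testing.assert_array_equal(a.thresholds, b.thresholds)
    np.testing.assert_allclose(b.importances_, 4.0 * a.importances_, rtol=1e-12)


def test_vr_alpha_one_equals_rf():
    rng = np.random.default_rng(9)
    X, y = rng.random((40, 5)), rng.normal(size=40)
    rf = fit_ensemble(
        X, y, config=EnsembleConfig(n_tree=4, method="rf", n_test=2, bootstrap=True), seed=4
    )
    vr = fit_ensemble(
        X,
        y,
        config=EnsembleConfig(n_tree=4, method="vr", n_test=2, vr_alpha=1.0, bootstrap=True),
        seed=4,
    )
    np.testing.assert_array_equal(rf.features, vr.features)
    np.testing.assert_array_equal(rf.thresholds, vr.thresholds)


def test_rf_paired_needs_pairable_candidates():
    rng = np.random.default_rng(10)
    X, y = rng.random((20, 4)), rng.random(20)
    with pytest.raises(ValidationError, match="rf_paired"):
        fit_ensemble(X, y, config=EnsembleConfig(method="rf_paired", n_test=1))


def test_config_validation():
    with pytest.raises(ValidationError):
        EnsembleConfig(n_tree=0).resolved(3)
    with pytest.raises(ValidationError):
        EnsembleConfig(n_test=9).resolved(3)
    with pytest.raises(ValidationError):
        EnsembleConfig(vr_alpha=1.5).resolved(3)
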