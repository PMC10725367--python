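"""Autograd engine, model layers, training loop, metrics and tuner."""

import numpy as np
import pytest

from lesiongraph import graph as gr
from lesiongraph import metrics as mt
from lesiongraph.nn import autograd as ag
from lesiongraph.nn import layers as ly
from lesiongraph.nn import model as md


# ---------------------------------------------------------------------------
# autograd: finite-difference gradient checks
# ---------------------------------------------------------------------------

def numerical_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps; fp = f(x)
        x[i] -= 2 * eps; fm = f(x)
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g


@pytest.mark.parametrize("expr", [
    lambda t: (t * 2.0 + 1.0).sum(),
    lambda t: ((t @ np.arange(6.0).reshape(3, 2)) ** 2.0).sum(),
    lambda t: (t.tanh() * t.sigmoid()).sum(),
    lambda t: t.elu().mean(),
    lambda t: ((t - t.mean(axis=0, keepdims=True)) ** 2.0).mean(),
    lambda t: ag.concat([t, t * 3.0], axis=-1).sum(),
    lambda t: (t[np.array([0, 2])] * 5.0).sum(),
    lambda t: ag.softmax(t).log().sum() * -1.0,
])
def test_gradients_match_finite_differences(expr, rng):
    x = rng.normal(size=(4, 3))

    def f(arr):
        return float(expr(ag.Tensor(arr)).data.sum())

    t = ag.Tensor(x.copy(), requires_grad=True)
    out = expr(t)
    out.sum().backward() if out.data.size > 1 else out.backward()
    num = numerical_grad(f, x.copy())
    np.testing.assert_allclose(t.grad, num, rtol=1e-5, atol=1e-7)


def test_cross_entropy_gradient(rng):
    x = rng.normal(size=(5, 2))
    labels = np.array([0, 1, 1, 0, 1])

    def f(arr):
        return float(ag.softmax_cross_entropy(ag.Tensor(arr), labels).data)

    t = ag.Tensor(x.copy(), requires_grad=True)
    ag.softmax_cross_entropy(t, labels).backward()
    np.testing.assert_allclose(t.grad, numerical_grad(f, x.copy()),
                               rtol=1e-5, atol=1e-8)


def test_softmax_rows_normalized(rng):
    s = ag.softmax(ag.Tensor(rng.normal(size=(7, 2)) * 10)).data
    np.testing.assert_allclose(s.sum(axis=1), 1.0, atol=1e-12)
    assert (s >= 0).all() and (s <= 1).all()


# ---------------------------------------------------------------------------
# FFN block
# ---------------------------------------------------------------------------

def test_ffn_block_output_width_independent_of_input(rng):
    for in_dim in (10, 32, 64):
        blk = ly.FFNBlock(in_dim, (64, 64), np.random.default_rng(0))
        blk.set_training(False)
        out = blk(ag.Tensor(rng.normal(size=(5, in_dim))))
        assert out.shape == (5, 64)


def test_ffn_block_inference_deterministic(rng):
    blk = ly.FFNBlock(10, (64, 64), np.random.default_rng(1))
    blk.set_training(False)
    x = ag.Tensor(rng.normal(size=(6, 10)))
    np.testing.assert_array_equal(blk(x).data, blk(x).data)


def test_ffn_block_train_eval_agree_when_dropout_off(rng):
    """With dropout 0 and batch-norm stats frozen to the batch, training
    and inference forward passes coincide."""
    blk = ly.FFNBlock(8, (16, 16), np.random.default_rng(2), dropout=0.0)
    x = ag.Tensor(rng.normal(size=(10, 8)))
    blk.bn.momentum = 1.0      # one training pass pins running stats
    blk.set_training(True)
    train_out = blk(x).data
    blk.set_training(False)
    eval_out = blk(x).data
    # batch-norm denominators differ by the biased/eps detail only
    np.testing.assert_allclose(train_out, eval_out, rtol=1e-6, atol=1e-8)


def test_concat_combination_doubles_width(rng):
    blk = ly.FFNBlock(10, (32, 32), np.random.default_rng(3),
                      combination="concat")
    blk.set_training(False)
    out = blk(ag.Tensor(rng.normal(size=(4, 10))))
    assert out.shape == (4, 64)


# ---------------------------------------------------------------------------
# message passing
# ---------------------------------------------------------------------------

def test_isolated_node_has_no_neighbor_term(rng):
    layer = ly.GCNLayer(4, 4, np.random.default_rng(0), aggregation="sum",
                        normalize=False)
    h = ag.Tensor(rng.normal(size=(3, 4)))
    A = np.zeros((3, 3))
    out_empty = layer(h, A).data
    # by hand: sigma(W_self h + b) with zero neighbor contribution
    expected = ly._activation("elu")(layer.W_self(h)).data
    np.testing.assert_allclose(out_empty, expected, atol=1e-12)


def test_two_node_path_identity_weights():
    layer = ly.GCNLayer(2, 2, np.random.default_rng(0), aggregation="sum",
                        normalize=False)
    layer.W_self.W.data = np.eye(2)
    layer.W_self.b.data[:] = 0.0
    layer.W_nei.W.data = np.eye(2)
    h = ag.Tensor(np.array([[1.0, 2.0], [3.0, 4.0]]))
    A = np.array([[0.0, 1.0], [1.0, 0.0]])
    out = layer(h, A).data
    # ELU is the identity on positive values, so h'_0 = h_0 + h_1
    np.testing.assert_allclose(out[0], [4.0, 6.0])
    np.testing.assert_allclose(out[1], [4.0, 6.0])


def test_message_pass_matches_double_loop_oracle(rng):
    n, d = 7, 5
    layer = ly.GCNLayer(d, d, np.random.default_rng(4), aggregation="mean")
    A = np.zeros((n, n))
    for _ in range(8):
        i, j = rng.integers(0, n, 2)
        if i != j:
            A[i, j] = A[j, i] = 1
    h = rng.normal(size=(n, d))
    got = layer(ag.Tensor(h), A).data
    Wn, b = layer.W_self.W.data, layer.W_self.b.data
    Wm = layer.W_nei.W.data
    expected = np.zeros((n, d))
    for u in range(n):
        nbrs = np.flatnonzero(A[u])
        agg = h[nbrs].mean(axis=0) if nbrs.size else np.zeros(d)
        z = h[u] @ Wn + agg @ Wm + b
        z = np.where(z > 0, z, np.exp(z) - 1)
        expected[u] = z / np.sqrt((z**2).sum() + 1e-12)
    np.testing.assert_allclose(got, expected, atol=1e-6)


def test_non_symmetric_adjacency_rejected(rng):
    layer = ly.GCNLayer(3, 3, np.random.default_rng(0))
    A = np.zeros((3, 3)); A[0, 1] = 1
    with pytest.raises(ValueError):
        layer(ag.Tensor(rng.normal(size=(3, 3))), A)


# ---------------------------------------------------------------------------
# full model forward
# ---------------------------------------------------------------------------

def _toy_graph(rng, n=16, p=10, density=0.3):
    X = rng.normal(size=(n, p))
    A = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    on = rng.uniform(size=iu.size) < density
    A[iu[on], ju[on]] = 1
    A += A.T
    labels = rng.integers(0, 2, n)
    edges = gr.EdgeTable(iu[on], ju[on], np.ones(on.sum()), n)
    return gr.Graph(X=X, labels=labels, edges=edges, adjacency=A)


def test_forward_probabilities_normalized(rng):
    g = _toy_graph(rng)
    model = md.GNNModel(10, md.ModelConfig(), np.random.default_rng(0))
    model.set_training(False)
    probs = model.forward(g.X, g.adjacency)
    assert probs.shape == (16, 2)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)


def test_zero_logits_give_half_half(rng):
    g = _toy_graph(rng)
    model = md.GNNModel(10, md.ModelConfig(), np.random.default_rng(0))
    model.set_training(False)
    model.head.W.data[:] = 0.0
    model.head.b.data[:] = 0.0
    probs = model.forward(g.X, g.adjacency)
    np.testing.assert_allclose(probs, 0.5, atol=1e-12)


def test_forward_permutation_equivariant(rng):
    g = _toy_graph(rng)
    model = md.GNNModel(10, md.ModelConfig(), np.random.default_rng(5))
    model.set_training(False)
    probs = model.forward(g.X, g.adjacency)
    perm = rng.permutation(16)
    probs_p = model.forward(g.X[perm], g.adjacency[np.ix_(perm, perm)])
    np.testing.assert_allclose(probs_p, probs[perm], atol=1e-8)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _separable_graph(rng, n_per_class=20):
    """Two feature clusters joined only within class."""
    X = np.vstack([rng.normal(0, 0.3, size=(n_per_class, 10)) + np.arange(10),
                   rng.normal(0, 0.3, size=(n_per_class, 10))
                   + np.arange(10)[::-1]])
    labels = np.repeat([0, 1], n_per_class)
    edges = gr.threshold_edges(gr.build_edge_table(X), 0.7)
    return gr.Graph(X=X, labels=labels, edges=edges,
                    adjacency=gr.to_adjacency(edges))


def test_training_recovers_separable_classes(rng):
    g = _separable_graph(rng)
    cfg = md.ModelConfig(epochs=40, seed=0)
    res = md.train(g, cfg)
    assert res.report.accuracy >= 90.0
    assert set(res.curves.columns) >= {"epoch", "train_loss", "train_acc"}
    assert len(res.curves) == 40


def test_zero_learning_rate_leaves_weights_unchanged(rng):
    g = _separable_graph(rng, n_per_class=10)
    cfg = md.ModelConfig(epochs=3, learning_rate=0.0, seed=1)
    rng_init = np.random.default_rng(1)
    ref = md.GNNModel(10, cfg, rng_init)
    res = md.train(g, cfg)
    for p_ref, p_got in zip(ref.parameters(), res.model.parameters()):
        np.testing.assert_array_equal(p_ref.data, p_got.data)


def test_training_deterministic_under_seed(rng):
    g = _separable_graph(rng, n_per_class=10)
    cfg = md.ModelConfig(epochs=5, seed=7)
    r1 = md.train(g, cfg)
    r2 = md.train(g, cfg)
    assert r1.curves["train_loss"].tolist() == r2.curves["train_loss"].tolist()
    assert (r1.report.tp, r1.report.fp, r1.report.tn, r1.report.fn) == \
           (r2.report.tp, r2.report.fp, r2.report.tn, r2.report.fn)


def test_single_class_training_set_rejected(rng):
    g = _separable_graph(rng, n_per_class=10)
    split = md.Split(train=np.arange(5), val=np.array([], int),
                     test=np.arange(10, 15))
    with pytest.raises(md.DegenerateSplitError):
        md.train(g, md.ModelConfig(epochs=1), split=split)


def test_stratified_split_is_stratified():
    labels = np.repeat([0, 1], 50)
    split = md.stratified_split(labels, seed=3)
    assert len(split.train) == 80 and len(split.val) == 10
    for part in (split.train, split.val, split.test):
        assert np.bincount(labels[part], minlength=2).min() > 0
    all_idx = np.concatenate([split.train, split.val, split.test])
    assert sorted(all_idx) == list(range(100))


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def test_perfect_predictions_metrics():
    rep = mt.evaluate([0, 1, 1, 0], [0, 1, 1, 0])
    assert rep.accuracy == rep.precision == rep.recall == 100.0
    assert rep.specificity == 100.0 and rep.mcc == pytest.approx(100.0)
    assert rep.fpr == rep.fdr == rep.fnr == 0.0


def test_f1_identity_from_printed_precision_sensitivity():
    assert mt.f1_score(100.0, 98.57) == pytest.approx(99.28, abs=0.005)


def test_confusion_69_1_0_122():
    rep = mt.report_from_counts(tp=69, fp=0, tn=122, fn=1)
    assert rep.sensitivity == pytest.approx(98.57, abs=0.005)
    assert rep.npv == pytest.approx(99.19, abs=0.005)
    assert rep.specificity == 100.0


def test_metric_identities_on_random_confusions(rng):
    for _ in range(200):
        tp, fp, tn, fn = rng.integers(0, 50, 4)
        if tp + fp + tn + fn == 0:
            continue
        rep = mt.report_from_counts(int(tp), int(fp), int(tn), int(fn))
        assert rep.n == tp + fp + tn + fn
        if np.isfinite(rep.sensitivity):
            assert rep.fnr == pytest.approx(100 - rep.sensitivity)
        if np.isfinite(rep.specificity):
            assert rep.fpr == pytest.approx(100 - rep.specificity)
        if np.isfinite(rep.precision):
            assert rep.fdr == pytest.approx(100 - rep.precision)
        if np.isfinite(rep.mcc):
            assert -100.0 - 1e-9 <= rep.mcc <= 100.0 + 1e-9


from hypothesis import given, settings
from hypothesis import strategies as hst


@settings(deadline=None, max_examples=100, derandomize=True)
@given(hst.tuples(*(hst.integers(0, 200) for _ in range(4))))
def test_metric_identities_property(counts):
    tp, fp, tn, fn = counts
    if tp + fp + tn + fn == 0:
        return
    rep = mt.report_from_counts(tp, fp, tn, fn)
    assert rep.n == tp + fp + tn + fn
    for rate, comp in ((rep.fnr, rep.sensitivity), (rep.fpr, rep.specificity),
                       (rep.fdr, rep.precision)):
        if np.isfinite(comp):
            assert rate == pytest.approx(100.0 - comp)
        else:
            assert np.isnan(rate)


def test_undefined_metrics_flagged_not_zeroed():
    rep = mt.report_from_counts(tp=0, fp=0, tn=5, fn=0)
    assert np.isnan(rep.precision)
    assert "precision" in rep.undefined


# ---------------------------------------------------------------------------
# k-fold, sweep, tuner
# ---------------------------------------------------------------------------

def test_kfold_mean_is_arithmetic_mean(rng):
    g = _separable_graph(rng, n_per_class=15)
    out = md.kfold_cv(g, k=3, config=md.ModelConfig(epochs=10, seed=2))
    assert out["mean"] == pytest.approx(np.mean(out["fold_accuracies"]),
                                        abs=1e-12)
    assert len(out["fold_accuracies"]) == 3


def test_kfold_identical_fold_content_zero_std(rng):
    # two prototype rows replicated: every fold sees identical data
    proto = np.vstack([np.arange(10.0), np.arange(10.0)[::-1]])
    X = np.repeat(proto, 6, axis=0)
    labels = np.repeat([0, 1], 6)
    edges = gr.build_edge_table(X)
    g = gr.Graph(X=X, labels=labels, edges=edges,
                 adjacency=gr.to_adjacency(edges))
    out = md.kfold_cv(g, k=3, config=md.ModelConfig(epochs=5, seed=0))
    assert out["std"] == pytest.approx(0.0, abs=1e-12)


def test_kfold_rejects_k_above_minority_count(rng):
    g = _separable_graph(rng, n_per_class=3)
    with pytest.raises(md.DegenerateSplitError):
        md.kfold_cv(g, k=5, config=md.ModelConfig(epochs=1))


def test_threshold_sweep_counts_and_monotonicity(rng):
    g = _separable_graph(rng, n_per_class=10)
    edges = gr.build_edge_table(g.X)
    cfg = md.ModelConfig(epochs=5, seed=0)
    sweep = md.threshold_sweep(g.X, g.labels, edges,
                               [None, 0.5, 0.9], cfg)
    assert len(sweep) == 3
    assert sweep["n_edges"].iloc[0] == 20 * 19 // 2
    assert (np.diff(sweep["n_edges"]) <= 0).all()


def test_tuner_single_point_space():
    best, log = md.tune_bayesian(
        objective=lambda cfg: 1.0,
        space={"learning_rate": (0.005, 0.005, False)}, budget=1, seed=0)
    assert best.learning_rate == pytest.approx(0.005)
    assert len(log) == 1


def test_tuner_finds_known_toy_optimum():
    # quadratic with max at lr = 0.0077 inside the box
    target = 0.0077

    def objective(cfg):
        return -((cfg.learning_rate - target) ** 2)

    best, log = md.tune_bayesian(
        objective=objective,
        space={"learning_rate": (0.001, 0.01, False)}, budget=25, seed=3)
    scaled_err = abs(best.learning_rate - target) / (0.01 - 0.001)
    assert scaled_err < 0.05
    assert len(log) == 25


def test_tuner_respects_bounds(rng):
    calls = []

    def objective(cfg):
        calls.append(cfg)
        return float(rng.uniform())

    md.tune_bayesian(objective=objective, budget=12, seed=1)
    for cfg in calls:
        assert 32 <= cfg.hidden_units[0] <= 64
        assert 0.001 <= cfg.learning_rate <= 0.01
        assert 64 <= cfg.batch_size <= 128
        assert 0.3 <= cfg.model_dropout <= 0.7
        assert cfg.hidden_units[0] == int(cfg.hidden_units[0])


def test_tuner_empty_space_rejected():
    with pytest.raises(ValueError):
        md.tune_bayesian(objective=lambda c: 0.0, space={}, budget=1)
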