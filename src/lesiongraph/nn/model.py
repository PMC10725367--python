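"""The skip-connected FFN + GCN node classifier and its training loop.

Architecture: the node feature matrix passes through a stack of
skip-connected FFN blocks, interleaved with three graph-convolution
message-passing layers, then a dropout and a final dense layer whose two
logits are softmaxed into class probabilities.  Training is transductive:
every forward pass sees the full adjacency, while the loss is evaluated on
(mini-batches of) training nodes only.

The block budget ``n_ffn_blocks`` is distributed as evenly as possible
around the GCN layers (extra blocks go to the front), e.g. 9 blocks and 3
GCN layers gives the pattern  FFF G FF G FF G FF.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from ..graph import Graph, EdgeTable, threshold_edges, to_adjacency
from ..metrics import EvalReport, evaluate
from .autograd import Tensor, softmax, softmax_cross_entropy
from .layers import (Dense, Dropout, FFNBlock, GCNLayer, Module,
                     make_optimizer)


class DegenerateSplitError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """All tunable hyperparameters of the classifier and training loop."""

    hidden_units: tuple[int, int] = (64, 64)
    n_gcn_layers: int = 3
    n_ffn_blocks: int = 9
    ffn_dropout: float = 0.2
    model_dropout: float = 0.3
    activation: str = "elu"            # elu | relu | tanh
    optimizer: str = "nadam"           # nadam | adam | adamax | sgd
    learning_rate: float = 0.01
    batch_size: int = 128
    combination_type: str = "conv_recurrent"   # conv_recurrent | concat
    epochs: int = 100
    aggregation: str = "mean"          # mean | sum neighbor aggregation
    grad_clip_norm: float = 5.0        # global-norm clip; stabilizes the
                                       # recurrent combiner at high lr
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.ffn_dropout < 1 and 0 <= self.model_dropout < 1):
            raise ValueError("dropout rates must be in [0, 1)")
        if min(self.n_gcn_layers, self.n_ffn_blocks, self.batch_size,
               self.epochs) < 0 or self.n_gcn_layers < 1:
            raise ValueError("layer counts, batch size and epochs must be positive")
        if self.learning_rate < 0:
            raise ValueError("learning rate must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hidden_units"] = list(self.hidden_units)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "hidden_units" in d:
            d["hidden_units"] = tuple(d["hidden_units"])
        return cls(**d)


def _distribute_blocks(n_blocks: int, n_slots: int) -> list[int]:
    base, extra = divmod(n_blocks, n_slots)
    return [base + (1 if i < extra else 0) for i in range(n_slots)]


class GNNModel(Module):
    """Skip-connected FFN blocks around GCN message-passing layers."""

    def __init__(self, in_dim: int, config: ModelConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.config = config
        h = config.hidden_units[1]
        counts = _distribute_blocks(config.n_ffn_blocks, config.n_gcn_layers + 1)
        self.groups: list[list[FFNBlock]] = []
        self.gcn_layers: list[GCNLayer] = []
        width = in_dim
        for slot, n_in_slot in enumerate(counts):
            blocks = []
            for _ in range(n_in_slot):
                blk = FFNBlock(width, config.hidden_units, rng,
                               dropout=config.ffn_dropout,
                               activation=config.activation,
                               combination=config.combination_type)
                width = blk.out_dim
                blocks.append(blk)
            self.groups.append(blocks)
            if slot < config.n_gcn_layers:
                gcn = GCNLayer(width, h, rng, activation=config.activation,
                               aggregation=config.aggregation)
                self.gcn_layers.append(gcn)
                width = h
        self.dropout = Dropout(config.model_dropout, rng)
        self.head = Dense(width, 2, rng)
        # register lists for parameter collection
        self._all_blocks = [b for grp in self.groups for b in grp]
        self._all_gcn = list(self.gcn_layers)

    def logits(self, X, A) -> Tensor:
        hconst = Tensor(np.asarray(X, dtype=float))
        hcur = hconst
        for slot, blocks in enumerate(self.groups):
            for blk in blocks:
                hcur = blk(hcur)
            if slot < len(self.gcn_layers):
                hcur = self.gcn_layers[slot](hcur, A)
        return self.head(self.dropout(hcur))

    def forward(self, X, A) -> np.ndarray:
        """Class probabilities (n x 2); rows sum to 1."""
        return softmax(self.logits(X, A)).data

    def predict(self, X, A) -> np.ndarray:
        return self.forward(X, A).argmax(axis=1)


@dataclass(frozen=True)
class Split:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray


def stratified_split(labels, fractions=(0.8, 0.1, 0.1), seed: int = 0) -> Split:
    """Seeded stratified train/val/test node partition."""
    labels = np.asarray(labels)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[], [], []]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n = idx.size
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        parts[0].extend(idx[:n_train])
        parts[1].extend(idx[n_train:n_train + n_val])
        parts[2].extend(idx[n_train + n_val:])
    return Split(*(np.sort(np.array(p, dtype=int)) for p in parts))


def _check_split(labels: np.ndarray, split: Split):
    for name, idx in (("train", split.train), ("test", split.test)):
        if idx.size == 0:
            raise DegenerateSplitError(f"{name} split is empty")
    if np.unique(labels[split.train]).size < 2:
        raise DegenerateSplitError("training set contains a single class")


def _clip_gradients(params, max_norm: float | None):
    if not max_norm:
        return
    total = np.sqrt(sum(float((p.grad**2).sum())
                        for p in params if p.grad is not None))
    if total > max_norm:
        scale = max_norm / total
        for p in params:
            if p.grad is not None:
                p.grad *= scale


@dataclass
class TrainResult:
    model: GNNModel
    report: EvalReport
    curves: pd.DataFrame
    split: Split
    train_report: EvalReport
    val_report: EvalReport | None


def train(graph: Graph, config: ModelConfig | None = None,
          split: Split | None = None) -> TrainResult:
    """Train the classifier transductively on one graph.

    Deterministic under a fixed ``config.seed``; returns the trained model,
    the test-set EvalReport and per-epoch loss/accuracy curves.
    """
    config = config or ModelConfig()
    labels = np.asarray(graph.labels, dtype=int)
    if split is None:
        split = stratified_split(labels, seed=config.seed)
    _check_split(labels, split)
    rng = np.random.default_rng(config.seed)
    model = GNNModel(graph.X.shape[1], config, rng)
    opt = make_optimizer(config.optimizer, model.parameters(),
                         lr=config.learning_rate)
    A = graph.adjacency
    X = graph.X
    rows = []
    train_idx = split.train.copy()
    for epoch in range(config.epochs):
        model.set_training(True)
        rng.shuffle(train_idx)
        for start in range(0, train_idx.size, config.batch_size):
            batch = train_idx[start:start + config.batch_size]
            logits = model.logits(X, A)
            loss = softmax_cross_entropy(logits[batch], labels[batch])
            loss.backward()
            _clip_gradients(model.parameters(), config.grad_clip_norm)
            opt.step()
        model.set_training(False)
        logits = model.logits(X, A)
        probs = softmax(logits).data
        pred = probs.argmax(axis=1)
        tr_loss = float(softmax_cross_entropy(
            logits[split.train], labels[split.train]).data)
        row = {"epoch": epoch, "train_loss": tr_loss,
               "train_acc": float((pred[split.train] == labels[split.train]).mean())}
        if split.val.size:
            row["val_loss"] = float(softmax_cross_entropy(
                logits[split.val], labels[split.val]).data)
            row["val_acc"] = float((pred[split.val] == labels[split.val]).mean())
        rows.append(row)
    model.set_training(False)
    pred = model.predict(X, A)
    result = TrainResult(
        model=model,
        report=evaluate(pred[split.test], labels[split.test]),
        curves=pd.DataFrame(rows),
        split=split,
        train_report=evaluate(pred[split.train], labels[split.train]),
        val_report=(evaluate(pred[split.val], labels[split.val])
                    if split.val.size else None),
    )
    return result


def threshold_sweep(X, labels, edges: EdgeTable, taus,
                    config: ModelConfig | None = None,
                    split: Split | None = None) -> pd.DataFrame:
    """Train at each correlation threshold with identical splits and seed.

    Returns a frame with columns threshold, n_edges, test_accuracy.
    """
    config = config or ModelConfig()
    labels = np.asarray(labels, dtype=int)
    if split is None:
        split = stratified_split(labels, seed=config.seed)
    rows = []
    for tau in taus:
        kept = threshold_edges(edges, tau)
        g = Graph(X=np.asarray(X, float), labels=labels, edges=kept,
                  adjacency=to_adjacency(kept))
        res = train(g, config, split=split)
        rows.append({"threshold": np.nan if tau is None else tau,
                     "n_edges": len(kept),
                     "test_accuracy": res.report.accuracy})
    return pd.DataFrame(rows)


def kfold_cv(graph: Graph, k: int = 5,
             config: ModelConfig | None = None) -> dict:
    """Stratified k-fold cross-validation of test accuracy.

    Each fold is the held-out test set once; remaining nodes train.  Returns
    fold accuracies (percent), their arithmetic mean and standard deviation.
    """
    config = config or ModelConfig()
    labels = np.asarray(graph.labels, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = np.bincount(labels)
    if (counts[counts > 0] < k).any():
        raise DegenerateSplitError("k exceeds the minority class count")
    rng = np.random.default_rng(config.seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        for i, chunk in enumerate(np.array_split(idx, k)):
            folds[i].extend(chunk)
    accs = []
    for i in range(k):
        test = np.sort(np.array(folds[i], dtype=int))
        train_idx = np.sort(np.concatenate(
            [np.array(folds[j], dtype=int) for j in range(k) if j != i]))
        split = Split(train=train_idx, val=np.array([], dtype=int), test=test)
        res = train(graph, config, split=split)
        accs.append(res.report.accuracy)
    accs = np.array(accs)
    return {"fold_accuracies": accs.tolist(),
            "mean": float(accs.mean()),
            "std": float(accs.std(ddof=0))}


# ---------------------------------------------------------------------------
# Bayesian hyperparameter tuning (GP surrogate + UCB acquisition)
# ---------------------------------------------------------------------------

DEFAULT_SEARCH_SPACE = {
    "hidden_units": (32, 64, True),
    "learning_rate": (0.001, 0.01, False),
    "batch_size": (64, 128, True),
    "model_dropout": (0.3, 0.7, False),
}


def _config_from_point(base: ModelConfig, names, point) -> ModelConfig:
    updates = {}
    for name, value in zip(names, point):
        if name == "hidden_units":
            updates[name] = (int(value), int(value))
        elif name in ("batch_size",):
            updates[name] = int(value)
        else:
            updates[name] = float(value)
    return replace(base, **updates)


def tune_bayesian(objective=None, space: dict | None = None, budget: int = 20,
                  n_initial: int = 5, kappa: float = 2.0, seed: int = 0,
                  base_config: ModelConfig | None = None,
                  graph: Graph | None = None):
    """Maximize ``objective`` over the hyperparameter box with GP + UCB.

    ``space`` maps name -> (low, high, is_integer).  If ``objective`` is
    None, a ``graph`` must be given and the objective is the validation
    accuracy of :func:`train` under the perturbed config.  Returns
    (best ModelConfig, trials DataFrame).
    """
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import Matern

    space = dict(DEFAULT_SEARCH_SPACE if space is None else space)
    if not space:
        raise ValueError("empty search space")
    base = base_config or ModelConfig()
    names = list(space)
    lows = np.array([space[n][0] for n in names], dtype=float)
    highs = np.array([space[n][1] for n in names], dtype=float)
    is_int = np.array([bool(space[n][2]) for n in names])

    if objective is None:
        if graph is None:
            raise ValueError("either an objective or a graph is required")

        def objective(cfg: ModelConfig) -> float:
            res = train(graph, cfg)
            rep = res.val_report or res.report
            return rep.accuracy

    rng = np.random.default_rng(seed)

    def snap(pt):
        pt = np.clip(pt, lows, highs)
        pt[is_int] = np.rint(pt[is_int])
        return pt

    n_initial = min(n_initial, budget)
    X_obs, y_obs, log_rows = [], [], []
    for trial in range(budget):
        if trial < n_initial:
            pt = snap(rng.uniform(lows, highs))
        else:
            gp = GaussianProcessRegressor(
                kernel=Matern(nu=2.5, length_scale=np.ones(len(names)),
                              length_scale_bounds=(1e-2, 1e2)),
                normalize_y=True, alpha=1e-6,
                random_state=int(rng.integers(2**31 - 1)))
            Xn = (np.array(X_obs) - lows) / np.maximum(highs - lows, 1e-12)
            import warnings
            from sklearn.exceptions import ConvergenceWarning
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                gp.fit(Xn, np.array(y_obs))
            cand = rng.uniform(lows, highs, size=(512, len(names)))
            cand = np.apply_along_axis(snap, 1, cand)
            cn = (cand - lows) / np.maximum(highs - lows, 1e-12)
            mu, sd = gp.predict(cn, return_std=True)
            pt = cand[int(np.argmax(mu + kappa * sd))]
        cfg = _config_from_point(base, names, pt)
        score = float(objective(cfg))
        X_obs.append(pt)
        y_obs.append(score)
        log_rows.append({**{n: v for n, v in zip(names, pt)},
                         "trial": trial, "score": score})
    best = int(np.argmax(y_obs))
    best_config = _config_from_point(base, names, X_obs[best])
    return best_config, pd.DataFrame(log_rows)
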