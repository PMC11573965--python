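"""Multi-head graph attention network for transductive node classification.

Implemented directly on NumPy arrays with analytically derived gradients.
Architecture: input dense layer -> a stack of multi-head attention layers
(head outputs concatenated on hidden layers, averaged on the last) -> output
dense layer with softmax. Per head, the attention score for neighbor j of
node i is

    e_ij = LeakyReLU(a_src . W x_i + a_dst . W x_j)

normalized by a softmax over N(i) (self-loop included), and the node update
is activation(sum_j alpha_ij W x_j). Training is full-graph gradient descent
with momentum on the cross-entropy of a per-step sample of training nodes
("batch size" selects how many labeled training nodes enter each step's
loss; the forward pass is always the whole graph).
"""

from __future__ import annotations

import json
import time
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES
from .graph import SampleGraph

log = logging.getLogger(__name__)

ACTIVATIONS = ("elu", "relu", "tanh")


@dataclass
class GATConfig:
    """Model/training configuration. Defaults are the ablation winners:
    relu activation, 32 hidden units, 4 attention layers, learning rate 1e-6,
    batch size 64, momentum 0.9, 8 heads."""

    activation: str = "relu"
    hidden_units: int = 32
    attention_layers: int = 4
    learning_rate: float = 1e-6
    batch_size: int = 64
    momentum: float = 0.9
    heads: int = 8
    leaky_relu_slope: float = 0.2
    epochs: int = 200
    seed: int = 0
    train_frac: float = 0.70
    val_frac: float = 0.15

    def validate(self) -> None:
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"activation must be one of {ACTIVATIONS}")
        if min(self.hidden_units, self.attention_layers, self.heads,
               self.batch_size, self.epochs) <= 0:
            raise ValueError("hidden_units/attention_layers/heads/batch_size/epochs must be positive")
        if not 0 < self.train_frac + self.val_frac < 1:
            raise ValueError("train_frac + val_frac must leave room for a test split")

    def as_dict(self) -> dict:
        return asdict(self)


def _act(name: str, x: np.ndarray) -> np.ndarray:
    if name == "relu":
        return np.maximum(x, 0.0)
    if name == "elu":
        return np.where(x > 0, x, np.expm1(np.clip(x, None, 0.0)))
    if name == "tanh":
        return np.tanh(x)
    raise ValueError(name)


def _act_grad(name: str, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    if name == "relu":
        return (x > 0).astype(x.dtype)
    if name == "elu":
        return np.where(x > 0, 1.0, y + 1.0)
    if name == "tanh":
        return 1.0 - y * y
    raise ValueError(name)


class EdgeIndex:
    """Directed edge arrays (both directions + self-loops), pre-sorted by
    receiver so neighborhood softmaxes reduce with ``np.*.reduceat``, and with
    fixed CSR sparsity patterns so the attention aggregation runs as sparse
    matrix products (only the data vector changes per step)."""

    def __init__(self, recv: np.ndarray, send: np.ndarray, n_nodes: int):
        order = np.argsort(recv, kind="stable")
        self.recv = recv[order]
        self.send = send[order]
        self.n_nodes = n_nodes
        self.n_edges = len(recv)
        # every node has a self-loop, so both groupings cover all nodes
        self.starts_recv = np.searchsorted(self.recv, np.arange(n_nodes))
        self.perm_send = np.argsort(self.send, kind="stable")
        self.starts_send = np.searchsorted(self.send[self.perm_send], np.arange(n_nodes))
        self._indptr_recv = np.append(self.starts_recv, self.n_edges)
        self._indptr_send = np.append(self.starts_send, self.n_edges)
        self._recv_perm = self.recv[self.perm_send]

    def reduce_by_recv(self, arr: np.ndarray, op=np.add) -> np.ndarray:
        return op.reduceat(arr, self.starts_recv, axis=0)

    def reduce_by_send(self, arr: np.ndarray, op=np.add) -> np.ndarray:
        return op.reduceat(arr[self.perm_send], self.starts_send, axis=0)

    def aggregate(self, weights: np.ndarray, Z: np.ndarray) -> np.ndarray:
        """out[i] = sum over edges (i <- j) of weights_e * Z[j]."""
        from scipy.sparse import csr_matrix

        A = csr_matrix((weights, self.send, self._indptr_recv),
                       shape=(self.n_nodes, self.n_nodes))
        return A @ Z

    def aggregate_t(self, weights: np.ndarray, Z: np.ndarray) -> np.ndarray:
        """out[j] = sum over edges (i <- j) of weights_e * Z[i] (transpose)."""
        from scipy.sparse import csr_matrix

        A = csr_matrix((weights[self.perm_send], self._recv_perm, self._indptr_send),
                       shape=(self.n_nodes, self.n_nodes))
        return A @ Z


def _directed_edges(graph: SampleGraph) -> EdgeIndex:
    """Edge index with both directions of each edge plus self-loops."""
    n = graph.n_nodes
    if graph.n_edges:
        e = graph.edges
        recv = np.concatenate([e[:, 0], e[:, 1], np.arange(n)])
        send = np.concatenate([e[:, 1], e[:, 0], np.arange(n)])
    else:
        recv = send = np.arange(n)
    return EdgeIndex(recv.astype(np.int64), send.astype(np.int64), n)


class GATModel:
    """Parameter container + forward/backward passes."""

    def __init__(self, config: GATConfig, feature_dim: int, n_classes: int = 2):
        config.validate()
        if feature_dim <= 0 or n_classes <= 1:
            raise ValueError("feature_dim must be positive and n_classes >= 2")
        self.config = config
        self.feature_dim = feature_dim
        self.n_classes = n_classes
        self.params: dict[str, np.ndarray] = {}
        self.scaler_mean = np.zeros(feature_dim)
        self.scaler_std = np.ones(feature_dim)
        self._init_params(np.random.default_rng(config.seed))

    def _glorot(self, rng, *shape):
        fan_in, fan_out = shape[-2], shape[-1]
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-lim, lim, size=shape)

    def _init_params(self, rng) -> None:
        c = self.config
        h, H = c.hidden_units, c.heads
        p = self.params
        p["W_in"] = self._glorot(rng, self.feature_dim, h)
        p["b_in"] = np.zeros(h)
        d = h
        for l in range(c.attention_layers):
            p[f"W_att{l}"] = self._glorot(rng, H, d, h)
            p[f"a_src{l}"] = self._glorot(rng, H, h) * 0.5
            p[f"a_dst{l}"] = self._glorot(rng, H, h) * 0.5
            last = l == c.attention_layers - 1
            d = h if last else h * H
        p["W_out"] = self._glorot(rng, d, self.n_classes)
        p["b_out"] = np.zeros(self.n_classes)

    # -- forward -----------------------------------------------------------

    def _attention_forward(self, X, l, ei, average_heads):
        """One multi-head attention layer; returns output and a cache."""
        c = self.config
        W = self.params[f"W_att{l}"]          # (H, d, h)
        a_src = self.params[f"a_src{l}"]      # (H, h)
        a_dst = self.params[f"a_dst{l}"]      # (H, h)
        recv, send = ei.recv, ei.send
        z = np.einsum("nd,Hdh->nHh", X, W)    # (N, H, h)
        f = np.einsum("nHh,Hh->nH", z, a_src)
        g = np.einsum("nHh,Hh->nH", z, a_dst)
        raw = f[recv] + g[send]               # (E, H)
        e = np.where(raw > 0, raw, c.leaky_relu_slope * raw)
        M = ei.reduce_by_recv(e, np.maximum)  # (N, H) per-neighborhood max
        ex = np.exp(e - M[recv])
        S = ei.reduce_by_recv(ex)
        alpha = ex / S[recv]                  # (E, H)
        H = z.shape[1]
        agg = np.empty_like(z)
        for hh in range(H):
            agg[:, hh, :] = ei.aggregate(alpha[:, hh], z[:, hh, :])
        out = _act(c.activation, agg)
        Y = out.mean(axis=1) if average_heads else out.reshape(len(X), -1)
        cache = (X, z, raw, alpha, agg, out, average_heads, l)
        return Y, cache

    def forward(self, X, ei, return_cache=False):
        """Full-graph forward pass; X is (N, feature_dim), standardized."""
        c = self.config
        caches = []
        pre_in = X @ self.params["W_in"] + self.params["b_in"]
        h0 = _act(c.activation, pre_in)
        caches.append((X, pre_in, h0))
        H = h0
        for l in range(c.attention_layers):
            H, cache = self._attention_forward(
                H, l, ei, average_heads=(l == c.attention_layers - 1)
            )
            caches.append(cache)
        logits = H @ self.params["W_out"] + self.params["b_out"]
        m = logits.max(axis=1, keepdims=True)
        ex = np.exp(logits - m)
        probs = ex / ex.sum(axis=1, keepdims=True)
        if return_cache:
            return probs, (caches, H, logits)
        return probs

    def attention_coefficients(self, X, ei):
        """Per-layer list of alpha arrays (E, heads), aligned with ``ei.recv``;
        the softmax over each node's neighborhood sums to 1."""
        c = self.config
        pre_in = X @ self.params["W_in"] + self.params["b_in"]
        H = _act(c.activation, pre_in)
        alphas = []
        for l in range(c.attention_layers):
            H, cache = self._attention_forward(
                H, l, ei, average_heads=(l == c.attention_layers - 1)
            )
            alphas.append(cache[3])
        return alphas

    # -- backward ----------------------------------------------------------

    def _attention_backward(self, dY, cache, ei, grads):
        c = self.config
        X, z, raw, alpha, agg, out, average_heads, l = cache
        recv, send = ei.recv, ei.send
        N, H, h = z.shape
        if average_heads:
            dout = np.repeat(dY[:, None, :], H, axis=1) / H
        else:
            dout = dY.reshape(N, H, h)
        dagg = dout * _act_grad(c.activation, agg, out)
        # through aggregation (per head: sparse products on the fixed pattern)
        dalpha = np.empty_like(alpha)
        dz = np.empty_like(z)
        for hh in range(H):
            dalpha[:, hh] = np.einsum(
                "eh,eh->e", dagg[recv, hh, :], z[send, hh, :]
            )
            dz[:, hh, :] = ei.aggregate_t(alpha[:, hh], dagg[:, hh, :])
        # softmax
        T = ei.reduce_by_recv(alpha * dalpha)
        de = alpha * (dalpha - T[recv])
        draw = de * np.where(raw > 0, 1.0, c.leaky_relu_slope)
        df = ei.reduce_by_recv(draw)
        dg = ei.reduce_by_send(draw)
        a_src = self.params[f"a_src{l}"]
        a_dst = self.params[f"a_dst{l}"]
        grads[f"a_src{l}"] = np.einsum("nH,nHh->Hh", df, z)
        grads[f"a_dst{l}"] = np.einsum("nH,nHh->Hh", dg, z)
        dz += df[:, :, None] * a_src[None] + dg[:, :, None] * a_dst[None]
        grads[f"W_att{l}"] = np.einsum("nd,nHh->Hdh", X, dz)
        return np.einsum("nHh,Hdh->nd", dz, self.params[f"W_att{l}"])

    def backward(self, cache, dlogits, ei) -> dict[str, np.ndarray]:
        c = self.config
        caches, H_last, logits = cache
        grads: dict[str, np.ndarray] = {}
        grads["W_out"] = H_last.T @ dlogits
        grads["b_out"] = dlogits.sum(axis=0)
        dH = dlogits @ self.params["W_out"].T
        for l in range(c.attention_layers - 1, -1, -1):
            dH = self._attention_backward(dH, caches[l + 1], ei, grads)
        X, pre_in, h0 = caches[0]
        dpre = dH * _act_grad(c.activation, pre_in, h0)
        grads["W_in"] = X.T @ dpre
        grads["b_in"] = dpre.sum(axis=0)
        return grads

    # -- persistence -------------------------------------------------------

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "params.npz", **self.params,
                 scaler_mean=self.scaler_mean, scaler_std=self.scaler_std)
        meta = {"config": self.config.as_dict(), "feature_dim": self.feature_dim,
                "n_classes": self.n_classes}
        (directory / "model.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory) -> "GATModel":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        model = cls(GATConfig(**meta["config"]), meta["feature_dim"], meta["n_classes"])
        data = np.load(directory / "params.npz")
        model.scaler_mean = data["scaler_mean"]
        model.scaler_std = data["scaler_std"]
        for k in model.params:
            model.params[k] = data[k]
        return model


def build_model(config: GATConfig, feature_dim: int, n_classes: int = 2) -> GATModel:
    return GATModel(config, feature_dim, n_classes)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Confusion matrix plus the derived binary-classification metrics.

    All rates are percentages; undefined ratios are NaN (reported as null in
    JSON), except MCC which is 0 and flagged when a denominator factor is 0.
    Complement identities hold: sensitivity + FNR = 100,
    specificity + FPR = 100, precision + FDR = 100.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    sensitivity: float
    precision: float
    specificity: float
    npv: float
    fpr: float
    fdr: float
    fnr: float
    f1: float
    mcc: float
    mcc_degenerate: bool = False
    train_accuracy: float | None = None
    validation_accuracy: float | None = None
    test_accuracy: float | None = None

    def as_dict(self) -> dict:
        d = asdict(self)
        return {k: (None if isinstance(v, float) and np.isnan(v) else v)
                for k, v in d.items()}

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2))


def _pct(num: float, den: float) -> float:
    return 100.0 * num / den if den > 0 else float("nan")


def evaluate_metrics(tp: int, tn: int, fp: int, fn: int) -> EvaluationReport:
    """All derived metrics of a binary confusion matrix, in percent."""
    if min(tp, tn, fp, fn) < 0 or tp + tn + fp + fn == 0:
        raise ValueError("counts must be nonnegative with positive total")
    sens = _pct(tp, tp + fn)
    prec = _pct(tp, tp + fp)
    spec = _pct(tn, tn + fp)
    npv = _pct(tn, tn + fn)
    f1 = (2 * prec * sens / (prec + sens)
          if prec + sens > 0 and not (np.isnan(prec) or np.isnan(sens))
          else float("nan"))
    mcc_den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc_degenerate = mcc_den == 0
    mcc = 0.0 if mcc_degenerate else (tp * tn - fp * fn) / np.sqrt(mcc_den)
    return EvaluationReport(
        tp=tp, tn=tn, fp=fp, fn=fn,
        accuracy=_pct(tp + tn, tp + tn + fp + fn),
        sensitivity=sens, precision=prec, specificity=spec, npv=npv,
        fpr=100.0 - spec if not np.isnan(spec) else float("nan"),
        fdr=100.0 - prec if not np.isnan(prec) else float("nan"),
        fnr=100.0 - sens if not np.isnan(sens) else float("nan"),
        f1=f1, mcc=100.0 * mcc, mcc_degenerate=mcc_degenerate,
    )


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def stratified_split(labels: np.ndarray, train_frac: float, val_frac: float,
                     seed: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic stratified train/validation/test index split."""
    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n_tr = int(round(train_frac * len(idx)))
        n_va = int(round(val_frac * len(idx)))
        train.extend(idx[:n_tr])
        val.extend(idx[n_tr:n_tr + n_va])
        test.extend(idx[n_tr + n_va:])
    parts = tuple(np.sort(np.array(p, dtype=np.int64)) for p in (train, val, test))
    for name, part in zip(("train", "validation", "test"), parts):
        if len(np.unique(labels[part])) < 2:
            raise ValueError(f"{name} split does not contain both classes")
    return parts


def _encode_labels(labels: np.ndarray) -> np.ndarray:
    # malignant is the positive class (1)
    return (labels == "malignant").astype(np.int64)


def _standardize(X: np.ndarray, train_idx: np.ndarray):
    mean = X[train_idx].mean(axis=0)
    std = X[train_idx].std(axis=0)
    std = np.where(std == 0, 1.0, std)
    return (X - mean) / std, mean, std


def _accuracy(probs: np.ndarray, y: np.ndarray, idx: np.ndarray) -> float:
    return float(np.mean(probs[idx].argmax(axis=1) == y[idx]))


def train_gat(
    table: pd.DataFrame,
    graph: SampleGraph,
    config: GATConfig | None = None,
    seed: int | None = None,
    model: GATModel | None = None,
    masks: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
    features: list[str] | None = None,
    labels_override: np.ndarray | None = None,
) -> tuple[GATModel, EvaluationReport]:
    """Train a GAT transductively on the sample graph.

    Feature standardization is fitted on the training nodes only; the
    best-validation-accuracy checkpoint is returned, evaluated on all three
    splits (confusion matrix from the test nodes). ``masks`` may override the
    default stratified 70/15/15 split (e.g. for cross-validation);
    ``labels_override`` substitutes the node labels (e.g. permuted labels for
    a null control).
    """
    config = config or GATConfig()
    if seed is not None:
        config = GATConfig(**{**config.as_dict(), "seed": seed})
    config.validate()
    features = features or FEATURE_NAMES

    order = np.argsort(table["unique_id"].to_numpy(), kind="stable")
    table = table.iloc[order]
    if not np.array_equal(table["unique_id"].to_numpy(), graph.node_ids):
        raise ValueError("feature table rows and graph nodes do not align")
    X = table[features].to_numpy(dtype=float)
    labels = labels_override if labels_override is not None else graph.labels
    y = _encode_labels(np.asarray(labels))

    if masks is None:
        train_idx, val_idx, test_idx = stratified_split(
            np.asarray(labels), config.train_frac, config.val_frac, config.seed
        )
    else:
        train_idx, val_idx, test_idx = masks

    Xs, mean, std = _standardize(X, train_idx)
    ei = _directed_edges(graph)

    if model is None:
        model = GATModel(config, feature_dim=X.shape[1], n_classes=2)
    model.scaler_mean, model.scaler_std = mean, std

    rng = np.random.default_rng(config.seed + 1)
    velocity = {k: np.zeros_like(v) for k, v in model.params.items()}
    best_val = -1.0
    best_params = model.copy_params()
    onehot = np.eye(2)[y]

    for epoch in range(config.epochs):
        perm = rng.permutation(train_idx)
        for start in range(0, len(perm), config.batch_size):
            batch = perm[start:start + config.batch_size]
            probs, cache = model.forward(Xs, ei, return_cache=True)
            dlogits = np.zeros_like(probs)
            dlogits[batch] = (probs[batch] - onehot[batch]) / len(batch)
            grads = model.backward(cache, dlogits, ei)
            for k in grads:
                velocity[k] = config.momentum * velocity[k] - config.learning_rate * grads[k]
                model.params[k] += velocity[k]
        probs = model.forward(Xs, ei)
        val_acc = _accuracy(probs, y, val_idx) if len(val_idx) else _accuracy(probs, y, train_idx)
        if val_acc > best_val:
            best_val = val_acc
            best_params = model.copy_params()

    model.params = best_params
    probs = model.forward(Xs, ei)
    pred = probs.argmax(axis=1)
    t = pred[test_idx]
    yt = y[test_idx]
    report = evaluate_metrics(
        tp=int(np.sum((t == 1) & (yt == 1))),
        tn=int(np.sum((t == 0) & (yt == 0))),
        fp=int(np.sum((t == 1) & (yt == 0))),
        fn=int(np.sum((t == 0) & (yt == 1))),
    )
    report.train_accuracy = 100.0 * _accuracy(probs, y, train_idx)
    report.validation_accuracy = (100.0 * _accuracy(probs, y, val_idx)
                                  if len(val_idx) else float("nan"))
    report.test_accuracy = 100.0 * _accuracy(probs, y, test_idx)
    return model, report


def training_loss_curve(table, graph, config, n_epochs: int) -> list[float]:
    """Mean train-node cross-entropy per epoch (diagnostic smoke check)."""
    config = GATConfig(**{**config.as_dict(), "epochs": 1})
    features = FEATURE_NAMES
    order = np.argsort(table["unique_id"].to_numpy(), kind="stable")
    table = table.iloc[order]
    X = table[features].to_numpy(dtype=float)
    y = _encode_labels(graph.labels)
    train_idx, val_idx, test_idx = stratified_split(
        graph.labels, config.train_frac, config.val_frac, config.seed)
    Xs, _, _ = _standardize(X, train_idx)
    ei = _directed_edges(graph)
    model = GATModel(config, X.shape[1], 2)
    rng = np.random.default_rng(config.seed + 1)
    velocity = {k: np.zeros_like(v) for k, v in model.params.items()}
    onehot = np.eye(2)[y]
    losses = []
    for epoch in range(n_epochs):
        probs = model.forward(Xs, ei)
        p = np.clip(probs[train_idx, y[train_idx]], 1e-12, None)
        losses.append(float(-np.mean(np.log(p))))
        perm = rng.permutation(train_idx)
        for start in range(0, len(perm), config.batch_size):
            batch = perm[start:start + config.batch_size]
            probs, cache = model.forward(Xs, ei, return_cache=True)
            dlogits = np.zeros_like(probs)
            dlogits[batch] = (probs[batch] - onehot[batch]) / len(batch)
            grads = model.backward(cache, dlogits, ei)
            for k in grads:
                velocity[k] = config.momentum * velocity[k] - config.learning_rate * grads[k]
                model.params[k] += velocity[k]
    return losses


def kfold_cv(
    table: pd.DataFrame,
    graph: SampleGraph,
    config: GATConfig | None = None,
    k: int = 5,
    seed: int = 0,
) -> dict:
    """Stratified k-fold cross-validation on the fixed graph.

    Each fold serves once as the validation set while the other k-1 folds
    train the model (transductive: edges stay intact, only loss masks change).
    Returns per-fold validation accuracies plus mean and sd.
    """
    from sklearn.model_selection import StratifiedKFold

    config = config or GATConfig()
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = graph.labels
    counts = pd.Series(labels).value_counts()
    if k > counts.min():
        raise ValueError(f"k={k} exceeds smallest class size {counts.min()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    assignments = np.empty(len(labels), dtype=np.int64)
    for fold, (tr, va) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignments[va] = fold
        _, report = train_gat(
            table, graph, config, seed=seed + fold,
            masks=(tr, va, va),  # held-out fold is both monitored and scored
        )
        accs.append(report.validation_accuracy)
    return {
        "fold_accuracies": accs,
        "mean_accuracy": float(np.mean(accs)),
        "sd_accuracy": float(np.std(accs, ddof=1)),
        "fold_assignment": assignments,
    }


ABLATION_AXES_DEFAULT = {
    "activation": ["elu", "relu", "tanh"],
    "hidden_units": [64, 32],
    "attention_layers": [2, 3, 4],
    "learning_rate": [1e-4, 1e-5, 1e-6],
    "batch_size": [32, 64, 128],
    "momentum": [0.5, 0.7, 0.9],
    "heads": [4, 8],
}


def ablation_grid(
    table: pd.DataFrame,
    graph: SampleGraph,
    axes: dict[str, list] | None = None,
    base_config: GATConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, GATConfig]:
    """Sequential one-axis-at-a-time hyperparameter search.

    Stages run in the order of ``axes``; within each stage every value of that
    axis is trained (other fields at the best-so-far configuration) and the
    value with the highest test accuracy is kept for later stages.
    """
    axes = axes or ABLATION_AXES_DEFAULT
    current = (base_config or GATConfig()).as_dict()
    rows = []
    for axis, values in axes.items():
        if not values:
            log.warning("empty ablation axis %s skipped", axis)
            continue
        if axis not in current:
            raise ValueError(f"unknown ablation axis {axis!r}")
        best_val, best_acc = None, -np.inf
        for value in values:
            cfg = GATConfig(**{**current, axis: value})
            t0 = time.perf_counter()
            _, report = train_gat(table, graph, cfg, seed=seed)
            dt = (time.perf_counter() - t0) / cfg.epochs
            rows.append({
                "stage": axis, "value": value,
                "test_accuracy": report.test_accuracy,
                "time_per_epoch_s": dt,
            })
            if report.test_accuracy > best_acc:
                best_acc, best_val = report.test_accuracy, value
        current[axis] = best_val
    return pd.DataFrame(rows), GATConfig(**current)
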