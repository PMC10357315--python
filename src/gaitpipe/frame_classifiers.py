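"""Per-frame gait-state classifiers: RBF-kernel SVM and a Bi-LSTM.

Two first-stage classifiers label every frame with one of the 5 gait
states.  The SVM sees single frames (32 standardized features); the
Bi-LSTM sees consecutive non-overlapping windows of ``seq_len`` frames
(5 by default) and emits one class distribution per slot, integrating
context from both temporal directions.

The Bi-LSTM is implemented here in numpy: one bidirectional layer (64
hidden units per direction), a per-slot 5-way softmax head, cross-entropy
loss, and Adam.  Windows shorter than ``seq_len`` (the tail of each
sequence) are stored padded for layout but are *processed at their valid
length*, so the pad value never enters the network and never influences
training or prediction.  Training shuffles windows each epoch with a fixed
seed; everything is bit-reproducible for a given seed.

Cross-validation splits at the sequence (walk) level so frames of one walk
never appear in both the training and test side of a fold.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .evaluation import ClassificationReport, classification_report
from .features import FeatureMatrix
from .skeleton_io import FrameLabel

__all__ = [
    "WindowConfig",
    "WindowBatch",
    "SVMHyperparams",
    "BiLSTMHyperparams",
    "Standardization",
    "fit_standardization",
    "apply_standardization",
    "make_windows",
    "train_svm",
    "train_bilstm",
    "predict_labels",
    "save_model",
    "load_model",
    "FoldPlan",
    "kfold_plan",
    "run_cv",
]

_CLASSES: tuple[FrameLabel, ...] = tuple(FrameLabel)
_CLASS_INDEX = {c: i for i, c in enumerate(_CLASSES)}

_MODEL_FORMAT_VERSION = 1


def encode_labels(labels: Sequence[FrameLabel]) -> np.ndarray:
    return np.array([_CLASS_INDEX[lab] for lab in labels], dtype=int)


def decode_labels(codes: np.ndarray) -> list[FrameLabel]:
    return [_CLASSES[int(c)] for c in codes]


# ---------------------------------------------------------------------------
# windowing and standardization


@dataclass(frozen=True)
class WindowConfig:
    seq_len: int = 5
    pad_value: float = 0.0

    def __post_init__(self) -> None:
        if self.seq_len < 1:
            raise ValueError("seq_len must be >= 1")


@dataclass
class WindowBatch:
    """Non-overlapping windows of one feature stream.

    ``X`` is (n_windows, seq_len, n_features) with the tail window padded
    by ``pad_value``; ``mask`` marks valid slots; ``y`` holds label codes
    with -1 in padded slots; ``lengths`` gives each window's valid length.
    """

    X: np.ndarray
    mask: np.ndarray
    lengths: np.ndarray
    y: np.ndarray | None = None

    @property
    def n_windows(self) -> int:
        return self.X.shape[0]

    def valid_rows(self) -> np.ndarray:
        """Unpadded feature rows concatenated back in original frame order."""
        return np.concatenate(
            [self.X[i, : self.lengths[i]] for i in range(self.n_windows)], axis=0
        )


def make_windows(
    features: FeatureMatrix | np.ndarray,
    labels: Sequence[FrameLabel] | None = None,
    cfg: WindowConfig = WindowConfig(),
) -> WindowBatch:
    """Partition a feature stream into consecutive fixed-length windows."""
    values = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    n, d = values.shape
    if n == 0:
        raise ValueError("empty feature stream")
    if labels is not None and len(labels) != n:
        raise ValueError("labels length must equal frame count")
    L = cfg.seq_len
    n_win = -(-n // L)  # ceiling division
    X = np.full((n_win, L, d), cfg.pad_value, dtype=float)
    mask = np.zeros((n_win, L), dtype=bool)
    lengths = np.empty(n_win, dtype=int)
    y = np.full((n_win, L), -1, dtype=int) if labels is not None else None
    codes = encode_labels(labels) if labels is not None else None
    for w in range(n_win):
        a, b = w * L, min((w + 1) * L, n)
        X[w, : b - a] = values[a:b]
        mask[w, : b - a] = True
        lengths[w] = b - a
        if y is not None:
            y[w, : b - a] = codes[a:b]
    return WindowBatch(X=X, mask=mask, lengths=lengths, y=y)


@dataclass
class Standardization:
    mean: np.ndarray
    scale: np.ndarray


def fit_standardization(train_features: np.ndarray, scale_floor: float = 1e-8) -> Standardization:
    """Per-feature mean/SD on training data; near-constant columns floored."""
    x = np.asarray(train_features, dtype=float)
    if x.size == 0:
        raise ValueError("empty training features")
    mean = x.mean(axis=0)
    scale = x.std(axis=0)
    scale[scale < scale_floor] = 1.0
    return Standardization(mean=mean, scale=scale)


def apply_standardization(std: Standardization, features: np.ndarray) -> np.ndarray:
    return (np.asarray(features, dtype=float) - std.mean) / std.scale


# ---------------------------------------------------------------------------
# SVM


@dataclass(frozen=True)
class SVMHyperparams:
    C: float = 1.0
    gamma: str | float = "scale"  # 1 / (n_features * feature variance)


@dataclass
class SVMModel:
    kind: str = "svm_rbf"
    fitted: bool = False
    standardization: Standardization | None = None
    hyperparams: SVMHyperparams = SVMHyperparams()
    _svc: SVC | None = None

    def predict_codes(self, features: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("unfitted model")
        x = apply_standardization(self.standardization, features)
        return self._svc.predict(x).astype(int)


def train_svm(
    train_features: np.ndarray,
    train_labels: Sequence[FrameLabel],
    hyperparams: SVMHyperparams = SVMHyperparams(),
) -> SVMModel:
    """Fit the RBF-kernel SVM (one-vs-one multiclass) on single frames."""
    y = encode_labels(train_labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain at least 2 classes")
    std = fit_standardization(train_features)
    x = apply_standardization(std, train_features)
    svc = SVC(C=hyperparams.C, kernel="rbf", gamma=hyperparams.gamma, cache_size=500)
    svc.fit(x, y)
    return SVMModel(fitted=True, standardization=std, hyperparams=hyperparams, _svc=svc)


# ---------------------------------------------------------------------------
# Bi-LSTM in numpy


@dataclass(frozen=True)
class BiLSTMHyperparams:
    hidden_size: int = 64
    epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class _LSTMDirection:
    """One LSTM direction: parameters and vectorized forward/backward."""

    def __init__(self, rng: np.random.Generator, input_size: int, hidden: int):
        k = 1.0 / np.sqrt(hidden)
        self.W = rng.uniform(-k, k, size=(input_size, 4 * hidden))
        self.U = rng.uniform(-k, k, size=(hidden, 4 * hidden))
        self.b = rng.uniform(-k, k, size=4 * hidden)
        self.H = hidden

    def params(self) -> list[np.ndarray]:
        return [self.W, self.U, self.b]

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, dict]:
        """x: (B, T, D) -> hidden states (B, T, H) plus cache for backprop."""
        B, T, _ = x.shape
        H = self.H
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        hs = np.empty((B, T, H))
        cache = {"x": x, "i": [], "f": [], "g": [], "o": [], "tc": [],
                 "h_prev": [], "c_prev": []}
        for t in range(T):
            cache["h_prev"].append(h)
            cache["c_prev"].append(c)
            z = x[:, t] @ self.W + h @ self.U + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            hs[:, t] = h
            cache["i"].append(i)
            cache["f"].append(f)
            cache["g"].append(g)
            cache["o"].append(o)
            cache["tc"].append(tc)
        return hs, cache

    def backward(self, dh_ext: np.ndarray, cache: dict) -> list[np.ndarray]:
        """BPTT given per-step external hidden gradients (B, T, H)."""
        x = cache["x"]
        B, T, _ = x.shape
        H = self.H
        dW = np.zeros_like(self.W)
        dU = np.zeros_like(self.U)
        db = np.zeros_like(self.b)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in reversed(range(T)):
            i, f, g, o, tc = (cache[k][t] for k in ("i", "f", "g", "o", "tc"))
            dh = dh_ext[:, t] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1 - tc**2)
            di = dc * g
            dg = dc * i
            df = dc * cache["c_prev"][t]
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                axis=1,
            )
            dW += x[:, t].T @ dz
            dU += cache["h_prev"][t].T @ dz
            db += dz.sum(axis=0)
            dh_next = dz @ self.U.T
            dc_next = dc * f
        return [dW, dU, db]


class BiLSTMNet:
    """Bidirectional LSTM sequence labeler with a per-slot softmax head."""

    def __init__(self, input_size: int, hidden: int, n_classes: int, seed: int):
        rng = np.random.default_rng(seed)
        self.fwd = _LSTMDirection(rng, input_size, hidden)
        self.bwd = _LSTMDirection(rng, input_size, hidden)
        k = 1.0 / np.sqrt(2 * hidden)
        self.Wo = rng.uniform(-k, k, size=(2 * hidden, n_classes))
        self.bo = rng.uniform(-k, k, size=n_classes)
        self.H = hidden
        self.n_classes = n_classes

    def params(self) -> list[np.ndarray]:
        return self.fwd.params() + self.bwd.params() + [self.Wo, self.bo]

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, tuple]:
        """Logits (B, T, C); all slots of x are treated as valid."""
        hf, cache_f = self.fwd.forward(x)
        hb_rev, cache_b = self.bwd.forward(x[:, ::-1])
        hb = hb_rev[:, ::-1]
        logits = np.einsum("bth,hc->btc", np.concatenate([hf, hb], axis=2), self.Wo) + self.bo
        return logits, (cache_f, cache_b, hf, hb)

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray) -> tuple[float, list[np.ndarray]]:
        """Mean cross-entropy over all slots plus parameter gradients.

        Callers must pass windows whose every slot is valid (short windows
        are processed truncated, never padded).
        """
        B, T, _ = x.shape
        logits, (cache_f, cache_b, hf, hb) = self.forward(x)
        shifted = logits - logits.max(axis=2, keepdims=True)
        expl = np.exp(shifted)
        probs = expl / expl.sum(axis=2, keepdims=True)
        n = B * T
        idx_b, idx_t = np.meshgrid(np.arange(B), np.arange(T), indexing="ij")
        loss = float(-np.log(probs[idx_b, idx_t, y] + 1e-12).sum() / n)
        dlogits = probs.copy()
        dlogits[idx_b, idx_t, y] -= 1.0
        dlogits /= n
        hcat = np.concatenate([hf, hb], axis=2)
        dWo = np.einsum("bth,btc->hc", hcat, dlogits)
        dbo = dlogits.sum(axis=(0, 1))
        dh = np.einsum("btc,hc->bth", dlogits, self.Wo)
        grads_f = self.fwd.backward(dh[:, :, : self.H], cache_f)
        grads_b = self.bwd.backward(dh[:, ::-1, self.H :], cache_b)
        return loss, grads_f + grads_b + [dWo, dbo]


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g**2
            mhat = m / (1 - self.beta1**self.t)
            vhat = v / (1 - self.beta2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class BiLSTMModel:
    kind: str = "bilstm"
    fitted: bool = False
    standardization: Standardization | None = None
    hyperparams: BiLSTMHyperparams = BiLSTMHyperparams()
    window_config: WindowConfig = WindowConfig()
    net: BiLSTMNet | None = None

    def predict_codes(self, features: np.ndarray) -> np.ndarray:
        """One label code per frame: window, classify, unpad, concatenate."""
        if not self.fitted:
            raise RuntimeError("unfitted model")
        x = apply_standardization(self.standardization, features)
        batch = make_windows(x, cfg=self.window_config)
        out = np.empty(len(x), dtype=int)
        pos = 0
        # group windows by valid length so padding never enters the net
        for L in np.unique(batch.lengths):
            idx = np.where(batch.lengths == L)[0]
            logits, _ = self.net.forward(batch.X[idx, :L])
            codes = logits.argmax(axis=2)
            for row, w in enumerate(idx):
                a = w * self.window_config.seq_len
                out[a : a + L] = codes[row]
        return out


def train_bilstm(
    sequences: Sequence[tuple[np.ndarray, Sequence[FrameLabel]]],
    hyperparams: BiLSTMHyperparams = BiLSTMHyperparams(),
    window_config: WindowConfig = WindowConfig(),
) -> BiLSTMModel:
    """Train the Bi-LSTM on (features, labels) pairs, one per walk.

    Windows are built per sequence (never spanning walks), shuffled each
    epoch with the configured seed, and batched by valid length.
    """
    all_feats = np.concatenate([f for f, _ in sequences], axis=0)
    all_labels = [lab for _, labs in sequences for lab in labs]
    if len(np.unique(encode_labels(all_labels))) < 2:
        raise ValueError("training set must contain at least 2 classes")
    std = fit_standardization(all_feats)

    windows: list[tuple[np.ndarray, np.ndarray, int]] = []  # (x, y, length)
    for feats, labs in sequences:
        batch = make_windows(apply_standardization(std, feats), labs, window_config)
        for w in range(batch.n_windows):
            L = int(batch.lengths[w])
            windows.append((batch.X[w, :L], batch.y[w, :L], L))

    net = BiLSTMNet(
        input_size=all_feats.shape[1],
        hidden=hyperparams.hidden_size,
        n_classes=len(_CLASSES),
        seed=hyperparams.seed,
    )
    opt = _Adam(net.params(), hyperparams.learning_rate)
    rng = np.random.default_rng(hyperparams.seed)
    order = np.arange(len(windows))
    for _ in range(hyperparams.epochs):
        rng.shuffle(order)
        # batch together windows of equal length, preserving shuffle order
        by_len: dict[int, list[int]] = {}
        for w in order:
            by_len.setdefault(windows[w][2], []).append(w)
        for L, idxs in sorted(by_len.items()):
            for a in range(0, len(idxs), hyperparams.batch_size):
                chunk = idxs[a : a + hyperparams.batch_size]
                xb = np.stack([windows[w][0] for w in chunk])
                yb = np.stack([windows[w][1] for w in chunk])
                _, grads = net.loss_and_grads(xb, yb)
                opt.step(net.params(), grads)
    return BiLSTMModel(
        fitted=True,
        standardization=std,
        hyperparams=hyperparams,
        window_config=window_config,
        net=net,
    )


def predict_labels(model: SVMModel | BiLSTMModel, features: FeatureMatrix | np.ndarray) -> list[FrameLabel]:
    """One FrameLabel per input frame."""
    values = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    return decode_labels(model.predict_codes(values))


def save_model(model: SVMModel | BiLSTMModel, path: str | Path) -> None:
    with open(path, "wb") as fh:
        pickle.dump({"format_version": _MODEL_FORMAT_VERSION, "model": model}, fh)


def load_model(path: str | Path) -> SVMModel | BiLSTMModel:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("format_version") != _MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model file version: {payload.get('format_version')}")
    return payload["model"]


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class FoldPlan:
    k: int
    assignment: dict[object, int]
    seed: int

    def fold_ids(self, fold: int) -> list[object]:
        return [sid for sid, f in self.assignment.items() if f == fold]


def kfold_plan(sequence_ids: Sequence[object], k: int = 10, seed: int = 0) -> FoldPlan:
    """Assign whole sequences to k folds of near-equal size."""
    ids = list(sequence_ids)
    if k > len(ids):
        raise ValueError(f"cannot make {k} folds from {len(ids)} sequences")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    assignment = {ids[int(j)]: int(i % k) for i, j in enumerate(order)}
    return FoldPlan(k=k, assignment=assignment, seed=seed)


def run_cv(
    dataset: dict[object, tuple[np.ndarray, Sequence[FrameLabel]]],
    model_kind: str,
    plan: FoldPlan,
    svm_hp: SVMHyperparams = SVMHyperparams(),
    bilstm_hp: BiLSTMHyperparams = BiLSTMHyperparams(),
    window_config: WindowConfig = WindowConfig(),
) -> tuple[list[ClassificationReport], dict[object, list[FrameLabel]]]:
    """Sequence-level k-fold cross-validation.

    Each fold trains on the other folds' walks and predicts its own; every
    walk is predicted exactly once.  Returns per-fold reports and the
    out-of-fold predictions per walk.
    """
    reports: list[ClassificationReport] = []
    predictions: dict[object, list[FrameLabel]] = {}
    for fold in range(plan.k):
        test_ids = plan.fold_ids(fold)
        train_ids = [sid for sid in dataset if sid not in set(test_ids)]
        train_pairs = [dataset[sid] for sid in train_ids]
        if model_kind == "svm_rbf":
            feats = np.concatenate([f for f, _ in train_pairs], axis=0)
            labels = [lab for _, labs in train_pairs for lab in labs]
            model = train_svm(feats, labels, svm_hp)
        elif model_kind == "bilstm":
            model = train_bilstm(train_pairs, bilstm_hp, window_config)
        else:
            raise ValueError(f"unknown model kind {model_kind!r}")
        fold_true: list[FrameLabel] = []
        fold_pred: list[FrameLabel] = []
        for sid in test_ids:
            feats, labs = dataset[sid]
            pred = predict_labels(model, feats)
            predictions[sid] = pred
            fold_true.extend(labs)
            fold_pred.extend(pred)
        reports.append(classification_report(fold_true, fold_pred))
    return reports, predictions
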