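"""1D convolutional sentence classifier: systemic vs cellular stress.

The word "stress" is ambiguous in the addiction literature: it can mean
the organism-level response mediated by the HPA axis (restraint,
corticosterone — the *systemic* class, encoded 1) or the response of
cells to perturbation (oxidative/ROS — the *cellular* class, encoded 0).
This module trains a small 1D CNN to separate sentences containing the
word "stress" into those two classes.

Architecture (all sizes are :class:`ModelSpec` defaults):

    token ids (pad 64) -> embedding (32-d)
                       -> 1D convolution (16 filters, kernel 4, ReLU)
                       -> max pooling (window 2, floor on odd lengths)
                       -> flatten (480)
                       -> dense 10 (ReLU) -> dense 1 (sigmoid)

trained with Adamax (lr 0.002, beta1 0.9, beta2 0.999) on binary
cross-entropy, with an unstratified random 80/20 train/validation split.
The returned weights are those of the epoch maximizing validation
accuracy (ties -> earliest), i.e. the pre-overfitting peak. Forward and
backward passes are implemented directly in numpy, which keeps training
bit-reproducible for a given seed.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.stats import rankdata

from .preprocess import PreprocessConfig, preprocess

__all__ = [
    "ModelSpec",
    "VocabularyIndex",
    "TrainReport",
    "ConfusionMatrix",
    "EvalMetrics",
    "StressClassifier",
    "fit_vocabulary",
    "encode",
    "flatten_size",
    "train",
    "label_of",
    "evaluate",
    "metrics_from_confusion",
    "roc_auc",
]

PAD_INDEX = 0
OOV_INDEX = 1
LABEL_SYSTEMIC = "systemic"
LABEL_CELLULAR = "cellular"


@dataclass(frozen=True)
class ModelSpec:
    """Architecture and training hyperparameters."""

    pad_len: int = 64
    embed_dim: int = 32
    conv_filters: int = 16
    kernel_size: int = 4
    pool_window: int = 2
    dense_units: int = 10
    output_units: int = 1
    learning_rate: float = 0.002
    beta1: float = 0.9
    beta2: float = 0.999
    val_fraction: float = 0.20
    decision_threshold: float = 0.5
    batch_size: int = 32


def flatten_size(spec: ModelSpec) -> int:
    """Width of the flatten layer: floor((pad-k+1)/pool) * filters.

    Max pooling floors odd sequence lengths (61 -> 30), which is what
    makes the default spec come out at 480.
    """
    if spec.pad_len < spec.kernel_size:
        raise ValueError(
            f"pad_len {spec.pad_len} shorter than kernel {spec.kernel_size}"
        )
    conv_len = spec.pad_len - spec.kernel_size + 1
    return (conv_len // spec.pool_window) * spec.conv_filters


@dataclass(frozen=True)
class VocabularyIndex:
    """Token -> integer index; 0 is padding, 1 is out-of-vocabulary.

    Content tokens start at index 2, ordered by descending corpus
    frequency with ties broken lexicographically, so the mapping is a
    deterministic function of the corpus.
    """

    token_to_index: dict[str, int]
    vocab_size: int

    def __getitem__(self, token: str) -> int:
        return self.token_to_index.get(token, OOV_INDEX)


def fit_vocabulary(corpus: list[list[str]]) -> VocabularyIndex:
    if not corpus:
        raise ValueError("cannot fit a vocabulary on an empty corpus")
    counts = Counter(tok for sent in corpus for tok in sent)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    mapping = {tok: i + 2 for i, (tok, _) in enumerate(ordered)}
    return VocabularyIndex(token_to_index=mapping, vocab_size=len(mapping) + 2)


def encode(tokens: list[str], vocab: VocabularyIndex, pad_len: int) -> np.ndarray:
    """Integer vector of length pad_len: pre-padded, pre-truncated.

    Unknown tokens map to the OOV index; sequences longer than pad_len
    keep their LAST pad_len tokens.
    """
    if pad_len < 1:
        raise ValueError("pad_len must be >= 1")
    ids = [vocab[t] for t in tokens][-pad_len:]
    out = np.zeros(pad_len, dtype=np.int64)
    if ids:
        out[-len(ids):] = ids
    return out


# ---------------------------------------------------------------------------
# network internals


def _init_weights(spec: ModelSpec, vocab_size: int, rng: np.random.Generator) -> dict:
    def glorot(shape, fan_in, fan_out):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=shape)

    flat = flatten_size(spec)
    k, d, f = spec.kernel_size, spec.embed_dim, spec.conv_filters
    return {
        "E": rng.uniform(-0.05, 0.05, size=(vocab_size, d)),
        "K": glorot((k, d, f), k * d, f),
        "b": np.zeros(f),
        "W1": glorot((flat, spec.dense_units), flat, spec.dense_units),
        "b1": np.zeros(spec.dense_units),
        "W2": glorot((spec.dense_units, spec.output_units), spec.dense_units, spec.output_units),
        "b2": np.zeros(spec.output_units),
    }


def _forward(X: np.ndarray, w: dict, spec: ModelSpec, cache: bool = False):
    emb = w["E"][X]  # (B, P, D)
    win = sliding_window_view(emb, spec.kernel_size, axis=1)  # (B, T, D, k)
    z = np.einsum("btdk,kdf->btf", win, w["K"]) + w["b"]  # (B, T, F)
    a = np.maximum(z, 0.0)
    T = (z.shape[1] // spec.pool_window) * spec.pool_window
    blocks = a[:, :T].reshape(X.shape[0], T // spec.pool_window, spec.pool_window, -1)
    pool_idx = blocks.argmax(axis=2)
    pooled = np.take_along_axis(blocks, pool_idx[:, :, None, :], axis=2)[:, :, 0, :]
    flat = pooled.reshape(X.shape[0], -1)
    h_pre = flat @ w["W1"] + w["b1"]
    h = np.maximum(h_pre, 0.0)
    logit = h @ w["W2"] + w["b2"]
    prob = 1.0 / (1.0 + np.exp(-logit))
    if not cache:
        return prob.ravel()
    return prob.ravel(), {
        "X": X, "win": win, "z": z, "blocks_T": T, "pool_idx": pool_idx,
        "flat": flat, "h_pre": h_pre, "h": h,
    }


def _backward(prob: np.ndarray, y: np.ndarray, w: dict, spec: ModelSpec, c: dict) -> dict:
    B = len(y)
    dlogit = ((prob - y) / B)[:, None]  # BCE + sigmoid
    g = {}
    g["W2"] = c["h"].T @ dlogit
    g["b2"] = dlogit.sum(axis=0)
    dh = (dlogit @ w["W2"].T) * (c["h_pre"] > 0)
    g["W1"] = c["flat"].T @ dh
    g["b1"] = dh.sum(axis=0)
    dflat = dh @ w["W1"].T
    F = spec.conv_filters
    dpool = dflat.reshape(B, -1, F)  # (B, T//pool, F)
    T = c["blocks_T"]
    dblocks = np.zeros((B, T // spec.pool_window, spec.pool_window, F))
    np.put_along_axis(dblocks, c["pool_idx"][:, :, None, :], dpool[:, :, None, :], axis=2)
    da = np.zeros_like(c["z"])
    da[:, :T] = dblocks.reshape(B, T, F)
    dz = da * (c["z"] > 0)
    g["K"] = np.einsum("btdk,btf->kdf", c["win"], dz)
    g["b"] = dz.sum(axis=(0, 1))
    dwin = np.einsum("btf,kdf->btdk", dz, w["K"])  # (B, T, D, k)
    demb = np.zeros((B, spec.pad_len, spec.embed_dim))
    Tconv = dwin.shape[1]
    for k in range(spec.kernel_size):
        demb[:, k : k + Tconv] += dwin[:, :, :, k]
    g["E"] = np.zeros_like(w["E"])
    np.add.at(g["E"], c["X"].ravel(), demb.reshape(-1, spec.embed_dim))
    return g


class _Adamax:
    def __init__(self, params: dict, lr: float, beta1: float, beta2: float, eps: float = 1e-7):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.u = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k, gk in grads.items():
            gk = gk.reshape(params[k].shape)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * gk
            self.u[k] = np.maximum(self.b2 * self.u[k], np.abs(gk))
            params[k] -= (self.lr / (1 - self.b1**self.t)) * self.m[k] / (self.u[k] + self.eps)


def _bce(prob: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(prob, 1e-12, 1 - 1e-12)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


# ---------------------------------------------------------------------------
# training protocol


@dataclass
class TrainReport:
    """Per-epoch curves plus the selected pre-overfitting epoch (1-based)."""

    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    best_epoch: int = 0
    seed: int = 0
    n_train: int = 0
    n_val: int = 0

    @property
    def best_val_acc(self) -> float:
        return self.val_acc[self.best_epoch - 1]


class StressClassifier:
    """A trained model: spec + vocabulary + weights + preprocessing config."""

    def __init__(self, spec: ModelSpec, vocab: VocabularyIndex, weights: dict,
                 pre_cfg: PreprocessConfig | None = None):
        self.spec = spec
        self.vocab = vocab
        self.weights = weights
        self.pre_cfg = pre_cfg or PreprocessConfig()

    def predict(self, sentences: list[str]) -> np.ndarray:
        """Probability of the systemic class for each sentence."""
        if not sentences:
            return np.zeros(0)
        X = np.stack(
            [encode(preprocess(s, self.pre_cfg), self.vocab, self.spec.pad_len) for s in sentences]
        )
        return _forward(X, self.weights, self.spec)

    def classify(self, sentences: list[str]) -> list[tuple[float, str]]:
        return [(float(p), label_of(float(p), self.spec.decision_threshold))
                for p in self.predict(sentences)]

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savez(d / "weights.npz", **self.weights)
        (d / "vocab.json").write_text(json.dumps(
            {"token_to_index": self.vocab.token_to_index, "vocab_size": self.vocab.vocab_size}))
        (d / "manifest.json").write_text(json.dumps(
            {"spec": asdict(self.spec), "preprocess_hash": self.pre_cfg.config_hash}, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "StressClassifier":
        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        pre_cfg = PreprocessConfig()
        if manifest["preprocess_hash"] != pre_cfg.config_hash:
            raise ValueError("model was trained with a different preprocessing configuration")
        vj = json.loads((d / "vocab.json").read_text())
        vocab = VocabularyIndex(vj["token_to_index"], vj["vocab_size"])
        with np.load(d / "weights.npz") as npz:
            weights = {k: npz[k] for k in npz.files}
        return cls(ModelSpec(**manifest["spec"]), vocab, weights, pre_cfg)


def _as_binary(label) -> int:
    if label in (1, LABEL_SYSTEMIC):
        return 1
    if label in (0, LABEL_CELLULAR):
        return 0
    raise ValueError(f"unknown label {label!r}")


def train(
    labeled_corpus: list[tuple[str, object]],
    spec: ModelSpec | None = None,
    seed: int = 0,
    max_epochs: int = 10,
) -> tuple[StressClassifier, TrainReport]:
    """Train the CNN on (sentence, label) pairs; labels are systemic/cellular.

    The vocabulary is fitted on the whole labeled corpus, which is then
    split 80/20 into training and validation sets (unstratified, uniform
    at the given seed). The classifier returned carries the weights of
    the epoch with the highest validation accuracy.
    """
    spec = spec or ModelSpec()
    if len(labeled_corpus) < 10:
        raise ValueError("labeled corpus must contain at least 10 sentences")
    y_all = np.array([_as_binary(lab) for _, lab in labeled_corpus], dtype=float)
    if len(set(y_all)) < 2:
        raise ValueError("labeled corpus must contain both classes")
    cfg = PreprocessConfig()
    token_lists = [preprocess(s, cfg) for s, _ in labeled_corpus]
    vocab = fit_vocabulary(token_lists)
    X_all = np.stack([encode(t, vocab, spec.pad_len) for t in token_lists])

    rng = np.random.default_rng(seed)
    n = len(labeled_corpus)
    n_val = int(round(n * spec.val_fraction))
    if n_val < 1 or n - n_val < 1:
        raise ValueError(f"corpus of size {n} is too small for a {spec.val_fraction:.0%} split")
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    Xtr, ytr = X_all[train_idx], y_all[train_idx]
    Xva, yva = X_all[val_idx], y_all[val_idx]

    w = _init_weights(spec, vocab.vocab_size, rng)
    opt = _Adamax(w, spec.learning_rate, spec.beta1, spec.beta2)
    report = TrainReport(seed=seed, n_train=len(train_idx), n_val=len(val_idx))
    best = {"acc": -1.0, "weights": None, "epoch": 0}
    thr = spec.decision_threshold
    for epoch in range(1, max_epochs + 1):
        order = rng.permutation(len(train_idx))
        for start in range(0, len(order), spec.batch_size):
            idx = order[start : start + spec.batch_size]
            prob, cache = _forward(Xtr[idx], w, spec, cache=True)
            grads = _backward(prob, ytr[idx], w, spec, cache)
            opt.step(w, grads)
        ptr = _forward(Xtr, w, spec)
        pva = _forward(Xva, w, spec)
        report.train_loss.append(_bce(ptr, ytr))
        report.train_acc.append(float(np.mean((ptr > thr) == ytr)))
        report.val_loss.append(_bce(pva, yva))
        va = float(np.mean((pva > thr) == yva))
        report.val_acc.append(va)
        if va > best["acc"]:
            best = {"acc": va, "weights": {k: v.copy() for k, v in w.items()}, "epoch": epoch}
    report.best_epoch = best["epoch"]
    return StressClassifier(spec, vocab, best["weights"], cfg), report


# ---------------------------------------------------------------------------
# evaluation


def label_of(p: float, threshold: float = 0.5) -> str:
    """Systemic iff p > threshold; a tie at the threshold is cellular."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    return LABEL_SYSTEMIC if p > threshold else LABEL_CELLULAR


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with systemic as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class EvalMetrics:
    """Sensitivity, specificity, precision, NPV, accuracy, AUC.

    A metric whose denominator is zero is None ("undefined"), which is
    distinct from 0.
    """

    sensitivity: float | None
    specificity: float | None
    precision: float | None
    npv: float | None
    accuracy: float | None
    auc: float | None = None


def _ratio(num: int, den: int, name: str) -> float | None:
    if den == 0:
        warnings.warn(f"{name} is undefined (zero denominator)", stacklevel=3)
        return None
    return num / den


def metrics_from_confusion(cm: ConfusionMatrix, auc: float | None = None) -> EvalMetrics:
    return EvalMetrics(
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn, "sensitivity"),
        specificity=_ratio(cm.tn, cm.tn + cm.fp, "specificity"),
        precision=_ratio(cm.tp, cm.tp + cm.fp, "precision"),
        npv=_ratio(cm.tn, cm.tn + cm.fn, "npv"),
        accuracy=_ratio(cm.tp + cm.tn, cm.total, "accuracy"),
        auc=auc,
    )


def roc_auc(y_true: np.ndarray, probs: np.ndarray) -> float:
    """Area under the ROC curve by the rank (Mann-Whitney) formulation.

    Exactly equals the threshold-sweep trapezoid AUC, with average ranks
    handling tied probabilities.
    """
    y = np.asarray(y_true, dtype=float)
    p = np.asarray(probs, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes to be present")
    ranks = rankdata(p)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def evaluate(
    true_labels: list[object],
    probs: list[float] | np.ndarray,
    threshold: float = 0.5,
) -> tuple[ConfusionMatrix, EvalMetrics]:
    """Confusion matrix (via the 0.5 rule) and derived metrics, AUC included."""
    if len(true_labels) != len(probs):
        raise ValueError("true_labels and probs must have equal lengths")
    y = np.array([_as_binary(lab) for lab in true_labels])
    pred = np.array([1 if label_of(float(p), threshold) == LABEL_SYSTEMIC else 0 for p in probs])
    cm = ConfusionMatrix(
        tp=int(np.sum((y == 1) & (pred == 1))),
        fn=int(np.sum((y == 1) & (pred == 0))),
        fp=int(np.sum((y == 0) & (pred == 1))),
        tn=int(np.sum((y == 0) & (pred == 0))),
    )
    auc = None
    if 0 < y.sum() < len(y):
        auc = roc_auc(y, np.asarray(probs, dtype=float))
    else:
        warnings.warn("AUC is undefined with a single class", stacklevel=2)
    return cm, metrics_from_confusion(cm, auc=auc)
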