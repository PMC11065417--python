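"""Classifier adapter contract, reference classifiers, and the ID1/2/3 split.

An *adapter* is the seam between a trained classifier and the confidence
scores: it exposes ``features(X)`` — the penultimate ("pre-logit") activations
consumed by the Mahalanobis score — and ``logits(X)`` — the raw class scores
consumed by the softmax and energy scores.  Any model satisfying this contract
can be wrapped; the package ships a linear adapter for feature-level synthetic
data and a small trainable multilayer perceptron for image-level tests.

``split_dataset`` partitions labeled ID data into ID1 (classifier training),
ID2 (detector fitting — only the Mahalanobis score uses it) and ID3 (testing),
by default stratified 70/15/15.
"""

from __future__ import annotations

import json
from abc import ABC, abstractmethod
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .records import FeatureTable


class ClassifierAdapter(ABC):
    """Contract: expose penultimate features and logits for raw inputs.

    Both methods accept a single input vector or an (n, d_in) batch and are
    pure: the same input always yields the same output.
    """

    n_classes: int
    feature_dim: int

    @abstractmethod
    def features(self, X: np.ndarray) -> np.ndarray:
        """Penultimate-layer activations, shape (..., feature_dim)."""

    @abstractmethod
    def logits(self, X: np.ndarray) -> np.ndarray:
        """Raw class scores, shape (..., n_classes)."""

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(np.atleast_2d(self.logits(X)), axis=1)

    def accuracy(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


class LinearAdapter(ClassifierAdapter):
    """logits(x) = W x + b; features(x) = x.

    Lets feature-level synthetic data drive the logit-based scores without an
    image model in the loop.
    """

    def __init__(self, weights: np.ndarray, bias: np.ndarray):
        W = np.atleast_2d(np.asarray(weights, dtype=float))
        b = np.asarray(bias, dtype=float).ravel()
        if W.shape[0] != b.shape[0]:
            raise ValueError(
                f"bias length {b.shape[0]} does not match {W.shape[0]} classes"
            )
        self.weights = W
        self.bias = b
        self.n_classes = W.shape[0]
        self.feature_dim = W.shape[1]

    def features(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.feature_dim:
            raise ValueError("input dimension mismatch")
        return X

    def logits(self, X: np.ndarray) -> np.ndarray:
        return self.features(X) @ self.weights.T + self.bias


class MLPAdapter(ClassifierAdapter):
    """One-hidden-layer ReLU network; hidden activations are the features."""

    def __init__(
        self,
        W1: np.ndarray,
        b1: np.ndarray,
        W2: np.ndarray,
        b2: np.ndarray,
    ):
        self.W1 = np.asarray(W1, dtype=float)
        self.b1 = np.asarray(b1, dtype=float).ravel()
        self.W2 = np.asarray(W2, dtype=float)
        self.b2 = np.asarray(b2, dtype=float).ravel()
        if self.W1.shape[0] != self.b1.shape[0]:
            raise ValueError("hidden bias length mismatch")
        if self.W2.shape[1] != self.W1.shape[0]:
            raise ValueError("layer dimension mismatch")
        if self.W2.shape[0] != self.b2.shape[0]:
            raise ValueError("output bias length mismatch")
        self.n_classes = self.W2.shape[0]
        self.feature_dim = self.W1.shape[0]
        self.input_dim = self.W1.shape[1]

    def features(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.input_dim:
            raise ValueError("input dimension mismatch")
        return np.maximum(X @ self.W1.T + self.b1, 0.0)

    def logits(self, X: np.ndarray) -> np.ndarray:
        return self.features(X) @ self.W2.T + self.b2


def linear_adapter(weight_matrix: np.ndarray, bias_vector: np.ndarray) -> LinearAdapter:
    """Convenience constructor for :class:`LinearAdapter`."""
    return LinearAdapter(weight_matrix, bias_vector)


# ----------------------------------------------------------------- splitting


@dataclass(frozen=True)
class SplitSpec:
    """ID1/ID2/ID3 split ratios (default 70/15/15), seed, stratification."""

    ratios: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        r = tuple(float(x) for x in self.ratios)
        object.__setattr__(self, "ratios", r)
        if len(r) != 3 or any(x < 0 for x in r):
            raise ValueError("ratios must be three nonnegative numbers")
        if abs(sum(r) - 1.0) > 1e-9:
            raise ValueError("ratios must sum to 1")


def _apportion(n: int, ratios: Sequence[float]) -> np.ndarray:
    """Largest-remainder integer split of n by ratios; ties to lower index."""
    quota = np.asarray(ratios, dtype=float) * n
    counts = np.floor(quota).astype(int)
    order = np.argsort(-(quota - counts), kind="stable")
    counts[order[: n - counts.sum()]] += 1
    return counts


def split_dataset(
    records: FeatureTable, spec: SplitSpec = SplitSpec()
) -> tuple[FeatureTable, FeatureTable, FeatureTable]:
    """Partition labeled ID records into (ID1, ID2, ID3).

    The parts are disjoint and exhaustive; sizes follow ``spec.ratios`` via
    largest-remainder rounding, per class when stratified.  Deterministic
    given ``spec.seed``.
    """
    if len(records) == 0:
        raise ValueError("cannot split an empty dataset")
    if not records.is_id.all():
        raise ValueError("split_dataset expects ID records only")
    rng = np.random.default_rng(spec.seed)
    parts: list[list[int]] = [[], [], []]
    if spec.stratified:
        labels = records.label_array()
        for c in np.unique(labels):
            idx = np.flatnonzero(labels == c)
            idx = rng.permutation(idx)
            sizes = _apportion(len(idx), spec.ratios)
            bounds = np.cumsum(sizes)[:-1]
            for part, chunk in zip(parts, np.split(idx, bounds)):
                part.extend(chunk.tolist())
    else:
        idx = rng.permutation(len(records))
        sizes = _apportion(len(records), spec.ratios)
        bounds = np.cumsum(sizes)[:-1]
        for part, chunk in zip(parts, np.split(idx, bounds)):
            part.extend(chunk.tolist())
    return tuple(records.take(sorted(p)) for p in parts)  # type: ignore[return-value]


# ------------------------------------------------------------------ training


@dataclass
class Checkpoint:
    """Adapter snapshot after one training epoch, with held-out accuracy."""

    epoch: int
    adapter: ClassifierAdapter
    val_accuracy: float


@dataclass
class TrainingResult:
    adapter: ClassifierAdapter
    checkpoints: list[Checkpoint]
    seed: int


class _AdamW:
    """Decoupled-weight-decay Adam (AdamW) on a list of numpy parameters."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=1e-2):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def train_reference_classifier(
    records: FeatureTable,
    n_classes: int | None = None,
    *,
    epochs: int = 20,
    learning_rate: float = 1e-3,
    batch_size: int = 256,
    seed: int = 0,
    hidden_dim: int | None = None,
    val_fraction: float = 0.2,
    label_noise: float = 0.0,
    weight_decay: float = 1e-2,
) -> TrainingResult:
    """Train a small cross-entropy classifier; return it plus epoch checkpoints.

    The checkpoint sequence (early to late epochs, each tagged with its
    held-out accuracy) provides a family of classifiers with a range of
    accuracies for the accuracy-sweep experiment.  ``hidden_dim=None`` trains
    multinomial logistic regression (features = inputs); otherwise a
    one-hidden-layer ReLU network whose hidden activations are the
    penultimate features.  ``label_noise`` randomly reassigns that fraction of
    training labels, widening the attainable accuracy range.

    Optimization is AdamW with defaults lr 1e-3 and batch size 256.  With
    ``epochs=0`` the returned adapter is the seeded initialization and the
    checkpoint list is empty.
    """
    X = records.features
    y = records.label_array()
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training data must contain at least 2 classes")
    C = int(n_classes) if n_classes is not None else int(classes.max()) + 1
    if classes.max() >= C:
        raise ValueError("labels exceed declared n_classes")
    d = X.shape[1]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 30]))

    # held-out split for checkpoint accuracies
    n = len(y)
    perm = rng.permutation(n)
    n_val = max(1, int(round(val_fraction * n))) if epochs > 0 else 0
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if epochs > 0 and len(tr_idx) == 0:
        raise ValueError("no training samples left after validation split")
    Xtr, ytr = X[tr_idx], y[tr_idx].copy()
    Xval, yval = X[val_idx], y[val_idx]

    if label_noise > 0:
        flip = rng.random(len(ytr)) < label_noise
        ytr[flip] = rng.integers(C, size=flip.sum())

    if hidden_dim is None:
        W = 0.01 * rng.standard_normal((C, d))
        b = np.zeros(C)
        params = [W, b]

        def make_adapter():
            return LinearAdapter(W.copy(), b.copy())

        def forward(Xb):
            return Xb @ W.T + b

        def backward(Xb, P, Y1):
            G = (P - Y1) / len(Xb)  # (n, C)
            return [G.T @ Xb, G.sum(axis=0)]

    else:
        h = int(hidden_dim)
        W1 = rng.standard_normal((h, d)) * np.sqrt(2.0 / d)
        b1 = np.zeros(h)
        W2 = rng.standard_normal((C, h)) * np.sqrt(2.0 / h)
        b2 = np.zeros(C)
        params = [W1, b1, W2, b2]

        def make_adapter():
            return MLPAdapter(W1.copy(), b1.copy(), W2.copy(), b2.copy())

        def forward(Xb):
            H = np.maximum(Xb @ W1.T + b1, 0.0)
            return H @ W2.T + b2

        def backward(Xb, P, Y1):
            H = np.maximum(Xb @ W1.T + b1, 0.0)
            G = (P - Y1) / len(Xb)
            gW2 = G.T @ H
            gb2 = G.sum(axis=0)
            GH = (G @ W2) * (H > 0)
            return [GH.T @ Xb, GH.sum(axis=0), gW2, gb2]

    opt = _AdamW(params, lr=learning_rate, weight_decay=weight_decay)
    checkpoints: list[Checkpoint] = []
    for epoch in range(int(epochs)):
        order = rng.permutation(len(ytr))
        for start in range(0, len(order), batch_size):
            bidx = order[start : start + batch_size]
            Xb, yb = Xtr[bidx], ytr[bidx]
            P = _softmax(forward(Xb))
            loss = -np.mean(np.log(P[np.arange(len(yb)), yb] + 1e-300))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; "
                    "reduce learning rate or check inputs"
                )
            Y1 = np.zeros_like(P)
            Y1[np.arange(len(yb)), yb] = 1.0
            opt.step(backward(Xb, P, Y1))
        ck = make_adapter()
        acc = ck.accuracy(Xval, yval) if len(yval) else float("nan")
        checkpoints.append(Checkpoint(epoch=epoch + 1, adapter=ck, val_accuracy=acc))

    final = checkpoints[-1].adapter if checkpoints else make_adapter()
    return TrainingResult(adapter=final, checkpoints=checkpoints, seed=seed)


# -------------------------------------------------------------- persistence


def save_adapter(adapter: ClassifierAdapter, path: str | Path) -> None:
    """Serialize an adapter to JSON (weights as nested lists)."""
    path = Path(path)
    if isinstance(adapter, LinearAdapter):
        payload = {
            "kind": "linear",
            "weights": adapter.weights.tolist(),
            "bias": adapter.bias.tolist(),
        }
    elif isinstance(adapter, MLPAdapter):
        payload = {
            "kind": "mlp",
            "W1": adapter.W1.tolist(),
            "b1": adapter.b1.tolist(),
            "W2": adapter.W2.tolist(),
            "b2": adapter.b2.tolist(),
        }
    else:
        raise TypeError(f"cannot serialize adapter of type {type(adapter).__name__}")
    path.write_text(json.dumps(payload))


def load_adapter(path: str | Path) -> ClassifierAdapter:
    payload = json.loads(Path(path).read_text())
    if payload["kind"] == "linear":
        return LinearAdapter(np.asarray(payload["weights"]), np.asarray(payload["bias"]))
    if payload["kind"] == "mlp":
        return MLPAdapter(
            np.asarray(payload["W1"]),
            np.asarray(payload["b1"]),
            np.asarray(payload["W2"]),
            np.asarray(payload["b2"]),
        )
    raise ValueError(f"unknown adapter kind {payload['kind']!r}")


def save_checkpoints(result: TrainingResult, out_dir: str | Path) -> Path:
    """Write checkpoint adapters plus a JSON manifest (epoch, accuracy, seed)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for ck in result.checkpoints:
        fname = f"checkpoint_{ck.epoch:04d}.json"
        save_adapter(ck.adapter, out / fname)
        entries.append(
            {"epoch": ck.epoch, "val_accuracy": ck.val_accuracy, "file": fname}
        )
    manifest = out / "manifest.json"
    manifest.write_text(json.dumps({"seed": result.seed, "checkpoints": entries}, indent=2))
    return manifest
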