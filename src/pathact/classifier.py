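"""Fully connected neural network mapping pathway scores to tumor probability.

The network is deliberately small — the feature space after selection is a
few hundred pathways at most — and is implemented directly on numpy so that
training is bit-reproducible given a seed: input -> 128 (ReLU) -> dropout ->
64 (ReLU) -> dropout -> 1 (sigmoid), trained with Adam on binary
cross-entropy, early-stopped on an internal validation fold.

The trained artifact embeds everything prediction needs: the ordered pathway
list, the per-pathway standardization parameters, the layer weights, the
decision threshold, and the training configuration + seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .io_formats import LabelVector
from .pathway_scoring import NormalizationParams, PathwayScoreMatrix

_BCE_EPS = 1e-7


@dataclass
class TrainingConfig:
    hidden_sizes: list[int] = field(default_factory=lambda: [128, 64])
    dropout_rate: float = 0.3
    learning_rate: float = 1e-3
    batch_size: int = 256
    max_epochs: int = 200
    patience: int = 10
    split_ratio: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden_sizes must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.learning_rate <= 0 or self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("learning_rate, batch_size, max_epochs must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if not 0 < self.split_ratio < 1:
            raise ValueError("split_ratio must lie in (0, 1)")


@dataclass
class MetricsReport:
    f1: float
    accuracy: float
    precision: float
    recall: float
    confusion: tuple[int, int, int, int]  # (TP, FP, TN, FN)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["confusion"] = dict(zip(("TP", "FP", "TN", "FN"), self.confusion))
        return d


def split_data(
    scores: PathwayScoreMatrix,
    labels: LabelVector,
    split_ratio: float = 0.8,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified random train/test split of the cell axis.

    Class proportions are preserved to within one cell; the two index sets
    are disjoint and exhaustive, and deterministic given the seed.
    """
    y = labels.aligned_to(scores.barcodes)
    return _stratified_split(y, split_ratio, seed, min_per_class=2)


def _stratified_split(y: np.ndarray, split_ratio: float, seed: int,
                      min_per_class: int) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        if idx.size < min_per_class:
            raise ValueError(f"class {cls} has only {idx.size} cells")
        idx = rng.permutation(idx)
        n_train = int(round(split_ratio * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        train_parts.append(idx[:n_train])
        test_parts.append(idx[n_train:])
    return np.sort(np.concatenate(train_parts)), np.sort(np.concatenate(test_parts))


def fit_scaler(train_scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pathway mean and population SD over cells; zero-variance -> scale 1."""
    means = train_scores.mean(axis=1)
    scales = train_scores.std(axis=1)
    scales[scales == 0] = 1.0
    return means, scales


def apply_scaler(scores: np.ndarray, means: np.ndarray,
                 scales: np.ndarray) -> np.ndarray:
    return (scores - means[:, None]) / scales[:, None]


def _binary_cross_entropy(prob: np.ndarray, y: np.ndarray) -> float:
    prob = np.clip(prob, _BCE_EPS, 1 - _BCE_EPS)
    return float(-np.mean(y * np.log(prob) + (1 - y) * np.log(1 - prob)))


def _bce_from_logits(logits: np.ndarray, y: np.ndarray) -> float:
    """Numerically exact mean BCE computed from logits.

    softplus(z) - y*z, with the stable softplus max(z,0) + log1p(exp(-|z|));
    unlike the clipped probability form this has no loss floor, so small
    logit perturbations register even when the model is very confident.
    """
    z = np.asarray(logits, dtype=float)
    softplus = np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z)))
    return float(np.mean(softplus - y * z))


class _Network:
    """Plain-numpy MLP with inverted dropout and Adam."""

    def __init__(self, sizes: list[int], dropout_rate: float,
                 rng: np.random.Generator):
        self.dropout_rate = dropout_rate
        self.weights, self.biases = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            # He initialization for the ReLU stack
            self.weights.append(
                rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
            )
            self.biases.append(np.zeros(fan_out))

    def forward(self, x: np.ndarray, rng: np.random.Generator | None = None):
        """x: samples x features. Returns (prob, cache for backward)."""
        cache = []
        a = x
        last = len(self.weights) - 1
        for layer, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ w + b
            if layer < last:
                h = np.maximum(z, 0.0)
                if rng is not None and self.dropout_rate > 0:
                    keep = 1.0 - self.dropout_rate
                    mask = (rng.random(h.shape) < keep) / keep
                    h = h * mask
                else:
                    mask = None
                cache.append((a, z, mask))
                a = h
            else:
                cache.append((a, z, None))
                a = 1.0 / (1.0 + np.exp(-z))
        return a.ravel(), cache

    def backward(self, cache, prob: np.ndarray, y: np.ndarray):
        n = y.size
        grads_w, grads_b = [None] * len(self.weights), [None] * len(self.weights)
        # sigmoid + BCE: dL/dz at output = (p - y) / n
        delta = ((prob - y) / n)[:, None]
        for layer in range(len(self.weights) - 1, -1, -1):
            a_in, _z, _mask = cache[layer]
            grads_w[layer] = a_in.T @ delta
            grads_b[layer] = delta.sum(axis=0)
            if layer > 0:
                delta = delta @ self.weights[layer].T
                _, z_prev, mask_prev = cache[layer - 1]
                if mask_prev is not None:
                    delta = delta * mask_prev
                delta = delta * (z_prev > 0)
        return grads_w, grads_b

    def parameters(self):
        return self.weights + self.biases

    def copy_params(self):
        return [p.copy() for p in self.parameters()]

    def set_params(self, params):
        k = len(self.weights)
        self.weights = [p.copy() for p in params[:k]]
        self.biases = [p.copy() for p in params[k:]]


class _Adam:
    def __init__(self, params, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            m_hat = self.m[i] / (1 - self.beta1**self.t)
            v_hat = self.v[i] / (1 - self.beta2**self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


@dataclass
class TrainedModel:
    """Fitted classifier plus everything needed to reproduce its predictions."""

    pathway_names: list[str]
    scaler_means: np.ndarray
    scaler_scales: np.ndarray
    layer_weights: list[np.ndarray]
    layer_biases: list[np.ndarray]
    threshold: float
    config: TrainingConfig
    seed: int
    normalization: NormalizationParams = field(default_factory=NormalizationParams)

    def __post_init__(self) -> None:
        self.scaler_means = np.asarray(self.scaler_means, dtype=float)
        self.scaler_scales = np.asarray(self.scaler_scales, dtype=float)
        if (self.scaler_scales <= 0).any():
            raise ValueError("scaler scales must all be positive")
        if self.layer_weights[0].shape[0] != len(self.pathway_names):
            raise ValueError("first-layer width does not match pathway count")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")

    # --- prediction -------------------------------------------------------

    def _forward_logits(self, x: np.ndarray) -> np.ndarray:
        a = x
        last = len(self.layer_weights) - 1
        for layer, (w, b) in enumerate(zip(self.layer_weights, self.layer_biases)):
            z = a @ w + b
            a = np.maximum(z, 0.0) if layer < last else z
        return a.ravel()

    def logits_standardized(self, standardized: np.ndarray) -> np.ndarray:
        """Pre-sigmoid outputs from an already-standardized pathways x cells
        matrix in the model's own pathway order (used where exact loss
        values matter, e.g. permutation importance)."""
        if standardized.shape[0] != len(self.pathway_names):
            raise ValueError("standardized matrix row count != model pathways")
        return self._forward_logits(standardized.T)

    def predict_standardized(self, standardized: np.ndarray) -> np.ndarray:
        """Tumor probabilities from an already-standardized pathways x cells
        matrix in the model's own pathway order (low-level entry point used
        by the degradation protocols)."""
        return 1.0 / (1.0 + np.exp(-self.logits_standardized(standardized)))

    def standardize(self, scores: PathwayScoreMatrix) -> np.ndarray:
        """Align a score matrix to the model's pathway order and apply the
        embedded scaler."""
        aligned = scores.subset_pathways(self.pathway_names)
        return apply_scaler(aligned.scores, self.scaler_means, self.scaler_scales)

    def predict(self, scores: PathwayScoreMatrix) -> tuple[np.ndarray, np.ndarray]:
        """Per-cell (tumor probability, binary call).

        Rows are realigned by pathway name; a missing pathway is an error
        naming it. The call is tumor when probability >= threshold.
        """
        index = set(scores.pathway_names)
        missing = [n for n in self.pathway_names if n not in index]
        if missing:
            raise ValueError(f"score matrix is missing model pathways: {missing[:5]}")
        if not np.isfinite(scores.scores).all():
            raise ValueError("non-finite pathway scores")
        prob = self.predict_standardized(self.standardize(scores))
        return prob, (prob >= self.threshold).astype(int)

    # --- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "pathway_names": list(self.pathway_names),
            "scaler_means": self.scaler_means.tolist(),
            "scaler_scales": self.scaler_scales.tolist(),
            "layer_weights": [w.tolist() for w in self.layer_weights],
            "layer_biases": [b.tolist() for b in self.layer_biases],
            "threshold": self.threshold,
            "config": asdict(self.config),
            "seed": self.seed,
            "normalization": asdict(self.normalization),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "TrainedModel":
        return cls(
            pathway_names=list(payload["pathway_names"]),
            scaler_means=np.array(payload["scaler_means"], dtype=float),
            scaler_scales=np.array(payload["scaler_scales"], dtype=float),
            layer_weights=[np.array(w, dtype=float)
                           for w in payload["layer_weights"]],
            layer_biases=[np.array(b, dtype=float)
                          for b in payload["layer_biases"]],
            threshold=float(payload["threshold"]),
            config=TrainingConfig(**payload["config"]),
            seed=int(payload["seed"]),
            normalization=NormalizationParams(**payload["normalization"]),
        )


def train_model(
    train_scores: PathwayScoreMatrix,
    train_labels: LabelVector,
    config: TrainingConfig | None = None,
    threshold: float = 0.5,
    normalization: NormalizationParams | None = None,
) -> TrainedModel:
    """Fit the network on a (pathways x cells) score matrix.

    Fits the per-pathway scaler on the training cells, carves off a
    stratified 10% internal validation fold for early stopping (patience in
    epochs on validation BCE, best weights restored), and embeds scaler,
    pathway order and normalization parameters in the returned model.
    Deterministic given ``config.seed``.
    """
    config = config or TrainingConfig()
    y = train_labels.aligned_to(train_scores.barcodes)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")

    means, scales = fit_scaler(train_scores.scores)
    x_all = apply_scaler(train_scores.scores, means, scales).T  # cells x pathways

    fit_idx, val_idx = _stratified_split(y, 0.9, seed=config.seed,
                                         min_per_class=2)
    x_fit, y_fit = x_all[fit_idx], y[fit_idx]
    x_val, y_val = x_all[val_idx], y[val_idx]

    sizes = [x_all.shape[1], *config.hidden_sizes, 1]
    rng = np.random.default_rng(config.seed)
    net = _Network(sizes, config.dropout_rate, rng)
    optim = _Adam(net.parameters(), config.learning_rate)

    best_val = np.inf
    best_params = net.copy_params()
    stale = 0
    n_fit = x_fit.shape[0]
    for _epoch in range(config.max_epochs):
        order = rng.permutation(n_fit)
        for start in range(0, n_fit, config.batch_size):
            batch = order[start:start + config.batch_size]
            prob, cache = net.forward(x_fit[batch], rng=rng)
            if not np.isfinite(prob).all():
                raise FloatingPointError(
                    "non-finite network output during training; "
                    "try a smaller learning_rate"
                )
            grads_w, grads_b = net.backward(cache, prob, y_fit[batch])
            optim.step(net.parameters(), grads_w + grads_b)
        _, val_cache = net.forward(x_val, rng=None)
        val_loss = _bce_from_logits(val_cache[-1][1].ravel(), y_val)
        if not np.isfinite(val_loss):
            raise FloatingPointError(
                "non-finite validation loss; try a smaller learning_rate"
            )
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_params = net.copy_params()
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    net.set_params(best_params)

    return TrainedModel(
        pathway_names=list(train_scores.pathway_names),
        scaler_means=means,
        scaler_scales=scales,
        layer_weights=[w.copy() for w in net.weights],
        layer_biases=[b.copy() for b in net.biases],
        threshold=threshold,
        config=config,
        seed=config.seed,
        normalization=normalization or NormalizationParams(),
    )


def evaluate(calls: np.ndarray, truth: np.ndarray) -> MetricsReport:
    """Precision/recall/F1/accuracy with tumor (1) as the positive class.

    Zero-denominator conventions: precision, recall and F1 report 0 so that
    degenerate all-negative predictors are penalized, not hidden.
    """
    calls = np.asarray(calls, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if calls.shape != truth.shape:
        raise ValueError("calls and truth have different lengths")
    tp = int(((calls == 1) & (truth == 1)).sum())
    fp = int(((calls == 1) & (truth == 0)).sum())
    tn = int(((calls == 0) & (truth == 0)).sum())
    fn = int(((calls == 0) & (truth == 1)).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    accuracy = (tp + tn) / calls.size
    return MetricsReport(f1=f1, accuracy=accuracy, precision=precision,
                         recall=recall, confusion=(tp, fp, tn, fn))
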