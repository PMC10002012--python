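"""The small patch classifier: a 10-layer convolutional network.

Layer enumeration (kept exactly as designed, including the (1,1) max-pools,
which are identities — all downsampling comes from the stride-2
convolutions): input -> Conv(64,k3,s2,relu) -> Conv(128,k3,s2,relu) ->
MaxPool(1,1) -> Dropout(0.2) -> Conv(256,k3,s2,relu) -> MaxPool(1,1) ->
Dropout(0.2) -> Flatten -> Dense(2).

The output head uses a sigmoid on each of the two class scores, trained
with categorical cross-entropy on one-hot labels; scores are renormalised
to sum to one inside the loss (the convention of mainstream deep-learning
frameworks), so gradients reach both units.  A conventional softmax head is
available via ``head_activation="softmax"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _nn

logger = logging.getLogger(__name__)

_EPS = 1e-7
CNN_FLAT_WIDTH = 8 * 8 * 256  # = 16,384 after three stride-2 convs on 64x64

__all__ = [
    "CnnConfig",
    "CnnModel",
    "build_cnn",
    "categorical_cross_entropy",
    "train_cnn",
    "predict",
    "save_cnn",
    "load_cnn",
]


@dataclass
class CnnConfig:
    learning_rate: float = 5e-4
    dropout_rate: float = 0.2
    epochs: int = 20
    batch_size: int = 64
    seed: int = 0
    head_activation: str = "sigmoid"  # "sigmoid" (as designed) or "softmax"

    def __post_init__(self):
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.head_activation not in ("sigmoid", "softmax"):
            raise ValueError("head_activation must be 'sigmoid' or 'softmax'")


@dataclass
class CnnModel:
    network: _nn.Sequential
    config: CnnConfig
    trained: bool = False
    history: dict = field(default_factory=dict)

    @property
    def layers(self):
        return self.network.layers


def build_cnn(config: CnnConfig = None) -> CnnModel:
    config = config or CnnConfig()
    rng = np.random.default_rng(np.random.SeedSequence((int(config.seed), 10)))
    head_act = "sigmoid" if config.head_activation == "sigmoid" else None
    network = _nn.Sequential(
        [
            _nn.InputLayer((64, 64, 1)),
            _nn.Conv2D(1, 64, kernel=3, stride=2, activation="relu", rng=rng),
            _nn.Conv2D(64, 128, kernel=3, stride=2, activation="relu", rng=rng),
            _nn.MaxPool2D((1, 1)),
            _nn.Dropout(config.dropout_rate),
            _nn.Conv2D(128, 256, kernel=3, stride=2, activation="relu", rng=rng),
            _nn.MaxPool2D((1, 1)),
            _nn.Dropout(config.dropout_rate),
            _nn.Flatten(),
            _nn.Dense(CNN_FLAT_WIDTH, 2, activation=head_act, rng=rng),
        ]
    )
    return CnnModel(network, config)


def _scores_to_probs(scores, head_activation):
    """Class probabilities from head outputs (renormalised sigmoid or softmax)."""
    scores = np.asarray(scores, dtype=np.float64)
    if head_activation == "sigmoid":
        p = np.clip(scores, _EPS, 1.0 - _EPS)
        return p / p.sum(axis=1, keepdims=True)
    a = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(a)
    return e / e.sum(axis=1, keepdims=True)


def categorical_cross_entropy(scores, y_true, head_activation="sigmoid"):
    """Mean -log p(true class); closed forms: 0 for a saturated correct
    prediction, ln 2 per sample on uniform (0.5, 0.5) scores."""
    probs = _scores_to_probs(scores, head_activation)
    probs = np.clip(probs, _EPS, 1.0)
    return float(-np.mean(np.log(probs[np.arange(len(y_true)), np.asarray(y_true)])))


def _loss_grad(scores, y_true, head_activation):
    """Gradient of the mean cross-entropy w.r.t. the head *outputs*.

    For the softmax head the Dense layer is linear and this returns the
    gradient w.r.t. the logits directly (softmax and loss fused)."""
    n = len(y_true)
    onehot = np.zeros((n, 2))
    onehot[np.arange(n), np.asarray(y_true)] = 1.0
    if head_activation == "softmax":
        return ((_scores_to_probs(scores, "softmax") - onehot) / n).astype(np.float32)
    p = np.clip(np.asarray(scores, dtype=np.float64), _EPS, 1.0 - _EPS)
    s = p.sum(axis=1, keepdims=True)
    return ((1.0 / s - onehot / p) / n).astype(np.float32)


def train_cnn(model: CnnModel, data, config: CnnConfig = None):
    """Seeded Adam training on one-hot labels; returns (model, history).

    Records the running training loss/accuracy of each epoch and the full
    validation loss/accuracy computed after it.
    """
    config = config or model.config
    x_train = np.ascontiguousarray(data.train_images, dtype=np.float32)
    y_train = np.asarray(data.train_labels)
    x_val = np.ascontiguousarray(data.val_images, dtype=np.float32)
    y_val = np.asarray(data.val_labels)
    if len(x_train) == 0:
        raise ValueError("empty training set")
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set contains a single class; need both")

    ss = np.random.SeedSequence((int(config.seed), 11))
    rng_shuffle, rng_dropout = (np.random.default_rng(s) for s in ss.spawn(2))
    model.network.set_dropout_rng(rng_dropout)
    optimizer = _nn.Adam(model.network.params, config.learning_rate)
    history = {"loss": [], "accuracy": [], "val_loss": [], "val_accuracy": []}
    bs = config.batch_size
    for epoch in range(config.epochs):
        order = rng_shuffle.permutation(len(x_train))
        loss_sum = correct = 0.0
        for start in range(0, len(order), bs):
            idx = order[start : start + bs]
            xb, yb = x_train[idx], y_train[idx]
            scores = model.network.forward(xb, training=True)
            loss_sum += categorical_cross_entropy(scores, yb, config.head_activation) * len(idx)
            correct += float(np.sum(np.argmax(scores, axis=1) == yb))
            model.network.backward(_loss_grad(scores, yb, config.head_activation))
            optimizer.step(model.network.grads)
        history["loss"].append(loss_sum / len(order))
        history["accuracy"].append(correct / len(order))
        if len(x_val):
            val_scores = _forward_batched(model, x_val)
            history["val_loss"].append(
                categorical_cross_entropy(val_scores, y_val, config.head_activation)
            )
            history["val_accuracy"].append(
                float(np.mean(np.argmax(val_scores, axis=1) == y_val))
            )
        else:
            history["val_loss"].append(history["loss"][-1])
            history["val_accuracy"].append(history["accuracy"][-1])
        logger.info(
            "cnn epoch %d/%d loss=%.4f acc=%.4f val_loss=%.4f val_acc=%.4f",
            epoch + 1, config.epochs, history["loss"][-1], history["accuracy"][-1],
            history["val_loss"][-1], history["val_accuracy"][-1],
        )
    model.trained = True
    model.history = history
    return model, history


def _forward_batched(model, batch):
    bs = model.config.batch_size
    return np.concatenate(
        [model.network.forward(batch[s : s + bs]) for s in range(0, len(batch), bs)]
    )


def predict(model: CnnModel, batch):
    """Per-class scores and hard labels for a batch.

    The hard label is the argmax of the two scores, breaking exact ties in
    favour of the lower index (class 0).  The positive-class probability for
    ROC analysis is ``probs[:, 1]`` of the returned score array after
    normalisation; the raw head scores are returned.
    """
    if not model.trained:
        raise ValueError("model has not been trained; call train_cnn first")
    batch = np.ascontiguousarray(batch, dtype=np.float32)
    if batch.ndim != 4 or batch.shape[1:] != (64, 64, 1):
        raise ValueError(f"expected batch shape (n, 64, 64, 1), got {batch.shape}")
    scores = _forward_batched(model, batch)
    labels = np.argmax(scores, axis=1)
    return scores, labels


def positive_scores(model: CnnModel, scores):
    """Normalised probability of the positive class (for ROC curves)."""
    return _scores_to_probs(scores, model.config.head_activation)[:, 1]


def save_cnn(model: CnnModel, path) -> None:
    import json
    from dataclasses import asdict

    arrays = {f"param_{i}": p for i, p in enumerate(model.network.params)}
    np.savez_compressed(
        path,
        config_json=json.dumps(asdict(model.config)),
        trained=int(model.trained),
        **arrays,
    )


def load_cnn(path) -> CnnModel:
    import json

    with np.load(path, allow_pickle=False) as data:
        config = CnnConfig(**json.loads(str(data["config_json"])))
        model = build_cnn(config)
        for i, p in enumerate(model.network.params):
            p[...] = data[f"param_{i}"]
        model.trained = bool(int(data["trained"]))
    return model
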