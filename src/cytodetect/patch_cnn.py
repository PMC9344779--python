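"""The 96×96 two-class patch classifier, its configuration grid, and overlays.

The classifier takes a 96 × 96 RGB window and emits two softmax
probabilities (nucleus / non-nucleus).  It is built from the classic
convolution → activation → max-pool blocks followed by dropout and two
affine layers; categorical cross-entropy is minimised with Adam.  Network
depth is configurable through a documented layer-counting convention (every
convolution, pooling, activation, dropout, affine and the output softmax
counts as one layer), giving stock depths of 18 and 24.

A grid runner trains one classifier per configuration on shared splits,
flags overlearning as a train-test accuracy gap, and ranks the rest by test
accuracy.  Scored whole images become probability maps that render as the
familiar red (> 90 %) / yellow (> 50 %) overlay.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import _nn
from .windowing import (WINDOW_SIZE, LABEL_NUCLEUS, WindowDataset,
                        WindowSample, tile_image)

SUPPORTED_DEPTHS = (18, 24)
_ACTIVATIONS = {"relu": _nn.ReLU, "sigmoid": _nn.Sigmoid}

#: channel widths of the four pooled convolution blocks (96->48->24->12->6)
_BLOCK_CHANNELS = (8, 16, 32, 32)
#: extra unpooled convolution blocks appended for the deeper variant
_EXTRA_BLOCKS = 3
_HIDDEN_UNITS = 64


@dataclass(frozen=True)
class PatchClassifierConfig:
    """One cell of the configuration grid."""

    activation: str = "relu"  # "relu" | "sigmoid"
    epochs: int = 20
    n_layers: int = 18
    dropout_rate: float = 0.25
    learning_seed: int = 0
    batch_size: int = 32
    learning_rate: float = 1e-3

    def validate(self) -> None:
        if self.activation.lower() not in _ACTIVATIONS:
            raise ValueError(f"activation must be one of {sorted(_ACTIVATIONS)}")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.n_layers not in SUPPORTED_DEPTHS:
            raise ValueError(
                f"unsupported n_layers={self.n_layers}; supported depths: "
                f"{SUPPORTED_DEPTHS}")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class TrainResult:
    config: PatchClassifierConfig
    train_loss: float
    train_accuracy: float
    test_loss: float
    test_accuracy: float
    history: list[dict]  # one entry per epoch


@dataclass
class ProbabilityMap:
    """Per-window nucleus probability for one scored image."""

    probs: dict[tuple[int, int], float]
    source_id: str = ""
    window: int = WINDOW_SIZE


class PatchClassifier:
    """A built (and possibly trained) patch classifier."""

    def __init__(self, config: PatchClassifierConfig) -> None:
        config.validate()
        self.config = config
        self.rng = np.random.default_rng(config.learning_seed)
        act = _ACTIVATIONS[config.activation.lower()]
        gain = 2.0 if config.activation.lower() == "relu" else 1.0
        layers: list[_nn.Layer] = []
        c_in = 3
        for c_out in _BLOCK_CHANNELS:
            layers += [_nn.Conv2D(c_in, c_out, self.rng, gain=gain), act(),
                       _nn.MaxPool2()]
            c_in = c_out
        if config.n_layers == 24:
            for _ in range(_EXTRA_BLOCKS):
                layers += [_nn.Conv2D(c_in, c_in, self.rng, gain=gain), act()]
        spatial = WINDOW_SIZE // (2 ** len(_BLOCK_CHANNELS))
        layers += [
            _nn.Dropout(config.dropout_rate, self.rng),
            _nn.Flatten(),
            _nn.Affine(c_in * spatial * spatial, _HIDDEN_UNITS, self.rng, gain=gain),
            act(),
            _nn.Dropout(config.dropout_rate, self.rng),
            _nn.Affine(_HIDDEN_UNITS, 2, self.rng, gain=gain),
            _nn.Softmax(),
        ]
        self.layers = layers
        self.trained = False

    @property
    def depth(self) -> int:
        """Counted depth: every conv, pool, activation, dropout, affine and
        the output softmax contributes one layer."""
        return sum(1 for lyr in self.layers if lyr.counted)

    # -- internals -------------------------------------------------------
    def _forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for lyr in self.layers:
            x = lyr.forward(x, train)
        return x

    def _backward(self, grad: np.ndarray) -> None:
        for lyr in reversed(self.layers):
            grad = lyr.backward(grad)

    def _parameters(self) -> tuple[list[np.ndarray], list[np.ndarray]]:
        params, grads = [], []
        for lyr in self.layers:
            params += lyr.params
            grads += lyr.grads
        return params, grads

    # -- public API ------------------------------------------------------
    def predict_proba(self, patches: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Softmax probabilities, column 0 = nucleus, for uint8 NHWC patches."""
        x = _to_nchw(patches)
        out = [self._forward(x[i:i + batch_size], train=False)
               for i in range(0, len(x), batch_size)]
        return np.concatenate(out, axis=0)

    def evaluate(self, patches: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
        probs = self.predict_proba(patches)
        loss, _ = _nn.softmax_cross_entropy(probs, labels)
        acc = float((probs.argmax(axis=1) == labels).mean())
        return loss, acc


def _to_nchw(patches: np.ndarray) -> np.ndarray:
    if patches.ndim == 3:
        patches = patches[None]
    return (patches.astype(np.float32) / 255.0).transpose(0, 3, 1, 2)


def _stack(samples: list[WindowSample]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([s.patch for s in samples])
    y = np.array([0 if s.label == LABEL_NUCLEUS else 1 for s in samples])
    return x, y


def build_classifier(config: PatchClassifierConfig) -> PatchClassifier:
    """Construct an untrained classifier; raises on unsupported depths."""
    return PatchClassifier(config)


def train_classifier(clf: PatchClassifier, dataset: WindowDataset) -> TrainResult:
    """Minimise categorical cross-entropy with Adam for ``config.epochs`` passes.

    Per-epoch train and test loss/accuracy are recorded (evaluation mode,
    dropout off).  Fully deterministic under ``config.learning_seed``.
    """
    if not dataset.train or not dataset.test:
        raise ValueError("both train and test splits must be non-empty")
    cfg = clf.config
    x_train, y_train = _stack(dataset.train)
    x_test, y_test = _stack(dataset.test)
    if len(set(y_train.tolist())) < 1:
        raise ValueError("training split has no labels")

    params, grads = clf._parameters()
    opt = _nn.Adam(params, grads, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.learning_seed + 1)
    xtr = _to_nchw(x_train)
    history = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(xtr))
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            probs = clf._forward(xtr[idx], train=True)
            _, grad = _nn.softmax_cross_entropy(probs, y_train[idx])
            clf._backward(grad)
            opt.step()
        tr_loss, tr_acc = clf.evaluate(x_train, y_train)
        te_loss, te_acc = clf.evaluate(x_test, y_test)
        history.append({"epoch": epoch + 1, "train_loss": tr_loss,
                        "train_accuracy": tr_acc, "test_loss": te_loss,
                        "test_accuracy": te_acc})
    clf.trained = True
    last = history[-1]
    return TrainResult(config=cfg, train_loss=last["train_loss"],
                       train_accuracy=last["train_accuracy"],
                       test_loss=last["test_loss"],
                       test_accuracy=last["test_accuracy"], history=history)


def default_table1_grid() -> list[PatchClassifierConfig]:
    """The nine-configuration grid: activation × epochs × depth × dropout."""
    rows = [
        ("relu", 5, 18, 0.25), ("relu", 20, 18, 0.25), ("relu", 50, 18, 0.25),
        ("relu", 5, 24, 0.25), ("relu", 20, 24, 0.25), ("relu", 50, 24, 0.25),
        ("relu", 5, 18, 0.5), ("relu", 20, 18, 0.5), ("sigmoid", 20, 18, 0.25),
    ]
    return [PatchClassifierConfig(activation=a, epochs=e, n_layers=n,
                                  dropout_rate=d) for a, e, n, d in rows]


def is_overlearned(train_accuracy: float, test_accuracy: float,
                   overfit_gap: float = 0.05) -> bool:
    """Overlearning verdict: train accuracy exceeds test accuracy by more
    than ``overfit_gap``."""
    return (train_accuracy - test_accuracy) > overfit_gap


def run_table1_grid(dataset: WindowDataset,
                    grid: list[PatchClassifierConfig] | None = None,
                    overfit_gap: float = 0.05,
                    ) -> tuple[list[TrainResult], pd.DataFrame]:
    """Train every configuration on the same splits and rank the results.

    A configuration is flagged as overlearned when train accuracy exceeds
    test accuracy by more than ``overfit_gap``; non-overlearned rows are
    ranked by test accuracy (rank 1 = best).
    """
    if grid is None:
        grid = default_table1_grid()
    if not grid:
        raise ValueError("grid must be non-empty")
    results = []
    for cfg in grid:
        clf = build_classifier(cfg)
        results.append(train_classifier(clf, dataset))
    rows = []
    for i, res in enumerate(results):
        c = res.config
        rows.append({
            "no": i + 1, "activation": c.activation, "epochs": c.epochs,
            "n_layers": c.n_layers, "dropout": c.dropout_rate,
            "train_loss": res.train_loss, "train_accuracy": res.train_accuracy,
            "test_loss": res.test_loss, "test_accuracy": res.test_accuracy,
            "overlearned": is_overlearned(res.train_accuracy,
                                          res.test_accuracy, overfit_gap),
        })
    report = pd.DataFrame(rows)
    ranked = report.loc[~report["overlearned"]].sort_values(
        "test_accuracy", ascending=False)
    report["rank"] = pd.Series(
        range(1, len(ranked) + 1), index=ranked.index, dtype="float")
    return results, report


def score_image(clf: PatchClassifier, image: np.ndarray,
                window: int = WINDOW_SIZE, stride: int | None = None,
                source_id: str = "") -> ProbabilityMap:
    """Tile the image and record the nucleus-class probability per window."""
    if not clf.trained:
        raise RuntimeError("classifier has not been trained")
    tiles = tile_image(image, window, stride)
    patches = np.stack([p for _, p in tiles])
    probs = clf.predict_proba(patches)[:, 0]
    return ProbabilityMap(
        probs={origin: float(p) for (origin, _), p in zip(tiles, probs)},
        source_id=source_id, window=window)


def render_overlay(image: np.ndarray, pmap: ProbabilityMap,
                   red_threshold: float = 0.9, yellow_threshold: float = 0.5,
                   alpha: float = 0.35) -> np.ndarray:
    """Tint windows by nucleus probability: red above ``red_threshold``,
    yellow above ``yellow_threshold`` (both strict), untouched otherwise."""
    if not 0 <= yellow_threshold < red_threshold <= 1:
        raise ValueError("need 0 <= yellow_threshold < red_threshold <= 1")
    out = image.astype(np.float64).copy()
    w = pmap.window
    for (r, c), p in pmap.probs.items():
        if p > red_threshold:
            color = (255.0, 0.0, 0.0)
        elif p > yellow_threshold:
            color = (255.0, 255.0, 0.0)
        else:
            continue
        region = out[r:r + w, c:c + w]
        region *= (1.0 - alpha)
        region += alpha * np.asarray(color)
    return np.clip(out, 0, 255).round().astype(np.uint8)


def save_checkpoint(clf: PatchClassifier, path: str | Path) -> None:
    """Serialize weights (.npz) with a JSON sidecar holding the config."""
    path = Path(path)
    params, _ = clf._parameters()
    np.savez(path, *params, trained=np.array(clf.trained))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(asdict(clf.config)))


def load_checkpoint(path: str | Path) -> PatchClassifier:
    path = Path(path)
    cfg = PatchClassifierConfig(
        **json.loads(path.with_suffix(path.suffix + ".json").read_text()))
    clf = build_classifier(cfg)
    with np.load(path if path.suffix == ".npz" else f"{path}.npz") as data:
        arrays = [data[k] for k in data.files if k != "trained"]
        params, _ = clf._parameters()
        for p, a in zip(params, arrays):
            p[...] = a
        clf.trained = bool(data["trained"])
    return clf
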