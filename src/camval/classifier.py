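"""Binary montage classifiers: architecture presets, training, evaluation.

All backbones end in a stack of named convolutional blocks followed by the
head used throughout: global average pooling, two fully connected layers
and a 2-way softmax.  Conv-block ReLU outputs are exposed by name
(``block1`` ... ``blockN``) so the saliency stage can read activation maps;
the last block is the conventional choice for class-activation mapping.

Training uses binary cross-entropy with Adam.  A validation split (held out
from the training cases, stratified and seeded) drives early stopping: the
run stops once validation loss has not decreased for ``patience`` epochs
and the weights of the best-validation epoch are restored.

Evaluation reports AUC, accuracy, sensitivity and specificity as bootstrap
means with percentile confidence intervals over seeded case-level
resamples; the decision threshold on the positive-class probability is 0.5.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from . import nn
from .errors import ConfigurationError, DataError
from .montage import Montage, normalize_image

#: conv channels per block; all blocks are conv3x3 -> ReLU -> maxpool2
BACKBONES: dict[str, tuple[int, ...]] = {
    "tiny": (8, 16, 32),
    "alexnet_like": (16, 32, 48),
    "vgg16_like": (8, 16, 32),  # two convs per block, VGG-style
}
_DOUBLE_CONV = {"vgg16_like"}


@dataclass(frozen=True)
class ModelSpec:
    backbone: str = "tiny"
    h1: int = 16
    h2: int = 8
    input_size: tuple[int, int] = (144, 96)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backbone not in BACKBONES:
            raise ConfigurationError(
                f"unknown backbone {self.backbone!r}; choose from {sorted(BACKBONES)}"
            )
        n_pool = len(BACKBONES[self.backbone])
        h, w = self.input_size
        if h % (2 ** n_pool) or w % (2 ** n_pool):
            raise ConfigurationError(
                f"input_size {self.input_size} must be divisible by {2 ** n_pool}"
            )
        if self.h1 < 1 or self.h2 < 1:
            raise ConfigurationError("hidden widths must be >= 1")

    @property
    def last_conv_layer(self) -> str:
        # the last conv block's normalized (pre-ReLU) activations: signed
        # maps keep the Score-CAM ReLU meaningful, so S_o is the genuine
        # attention footprint rather than the whole image
        return f"block{len(BACKBONES[self.backbone])}_bn"

    def to_dict(self) -> dict:
        return {
            "backbone": self.backbone, "h1": self.h1, "h2": self.h2,
            "input_size": list(self.input_size), "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(backbone=d["backbone"], h1=int(d["h1"]), h2=int(d["h2"]),
                   input_size=tuple(d["input_size"]), seed=int(d["seed"]))


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-2
    lr_decay: float = 1e-6
    decay_mode: str = "lr"  # "lr" (legacy inverse-time) or "weight" (L2)
    patience: int = 10
    max_epochs: int = 20
    batch_size: int = 16
    val_fraction: float = 0.15
    #: rebuild with a fresh init (deterministically derived) when training
    #: never left the chance-level plateau; 0 disables
    max_restarts: int = 2
    restart_val_loss: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ConfigurationError("patience must be >= 1")
        if not 0 < self.val_fraction < 1:
            raise ConfigurationError("val_fraction must be in (0, 1)")
        if self.max_epochs < 1 or self.batch_size < 1:
            raise ConfigurationError("max_epochs and batch_size must be >= 1")


#: the published optimizer schedule for the full-scale networks
PAPER_TRAIN_CONFIG = TrainConfig(learning_rate=1e-5, lr_decay=1e-6,
                                 patience=10, max_epochs=500)


def build_model(spec: ModelSpec, dtype=np.float32) -> nn.Sequential:
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed & 0x7FFFFFFF, 17]))
    chans = BACKBONES[spec.backbone]
    # per-image standardization: [0,1] montages are all-positive with small
    # variance, which stalls early ReLU/GAP training; zero-mean/unit-variance
    # inputs break the symmetry quickly
    layers: list[tuple[str, nn.Layer]] = [("standardize", nn.Standardize())]
    in_ch = 1
    for i, c in enumerate(chans, start=1):
        layers.append((f"block{i}_conv", nn.Conv2D(in_ch, c, rng=rng, dtype=dtype)))
        layers.append((f"block{i}_bn", nn.BatchNorm2D(c, dtype=dtype)))
        if spec.backbone in _DOUBLE_CONV:
            layers.append((f"block{i}_relu_a", nn.ReLU()))
            layers.append((f"block{i}_conv_b", nn.Conv2D(c, c, rng=rng, dtype=dtype)))
            layers.append((f"block{i}_bn_b", nn.BatchNorm2D(c, dtype=dtype)))
        layers.append((f"block{i}", nn.ReLU()))
        layers.append((f"block{i}_pool", nn.MaxPool2()))
        in_ch = c
    layers.append(("gap", nn.GlobalAvgPool()))
    layers.append(("fc1", nn.Dense(in_ch, spec.h1, rng=rng, dtype=dtype)))
    layers.append(("fc1_relu", nn.ReLU()))
    layers.append(("fc2", nn.Dense(spec.h1, spec.h2, rng=rng, dtype=dtype)))
    layers.append(("fc2_relu", nn.ReLU()))
    layers.append(("logits", nn.Dense(spec.h2, 2, rng=rng, dtype=dtype)))
    return nn.Sequential(layers)


class EarlyStopper:
    """Stop when the monitored loss has not decreased for `patience` epochs."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = 0
        self.since = 0
        self.epoch = 0

    def update(self, loss: float) -> bool:
        """Record one epoch's validation loss; return True to stop."""
        self.epoch += 1
        if loss < self.best:
            self.best = loss
            self.best_epoch = self.epoch
            self.since = 0
        else:
            self.since += 1
        return self.since >= self.patience


def montages_to_arrays(montages: Sequence[Montage]) -> tuple[np.ndarray, np.ndarray]:
    """Stack montages into (N, 1, H, W) normalized inputs + label vector."""
    x = np.stack([normalize_image(m.image) for m in montages])[:, None, :, :]
    y = np.array([m.label for m in montages], dtype=np.int64)
    return x, y


def _stratified_holdout(y: np.ndarray, fraction: float,
                        rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    train_idx, val_idx = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        n_val = max(1, int(round(fraction * len(idx))))
        if n_val >= len(idx):
            raise DataError(f"class {cls} too small for validation holdout")
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(val_idx))


@dataclass
class TrainResult:
    model: nn.Sequential
    log: pd.DataFrame  # columns: epoch, train_loss, val_loss
    best_epoch: int
    spec: ModelSpec
    config: TrainConfig
    restarts: int = 0


def _calibrate_init(model: nn.Sequential, xb: np.ndarray) -> None:
    """Data-driven init scaling: unit output std per conv/dense layer.

    Layer-sequential rescaling on a calibration batch keeps activation
    magnitudes comparable through the depth, which markedly shortens the
    early symmetry-breaking phase on small, homogeneous image sets.
    """
    h = xb
    for _, layer in model.layers:
        out = layer.forward(h)
        if isinstance(layer, (nn.Conv2D, nn.Dense)):
            s = float(out.std())
            if s > 1e-8:
                layer.params["w"] /= s
                out = out / s
        h = out


def _fit_once(spec: ModelSpec, config: TrainConfig, xt, yt, xv, yv,
              rng: np.random.Generator) -> tuple[nn.Sequential, list[dict], int]:
    model = build_model(spec)
    _calibrate_init(model, xt[: min(32, len(xt))])
    opt = nn.Adam(model.parameters(), lr=config.learning_rate,
                  decay=config.lr_decay, decay_mode=config.decay_mode)
    stopper = EarlyStopper(config.patience)
    best_weights = model.get_weights()
    rows = []
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(xt))
        losses = []
        model.train_mode(True)
        for i in range(0, len(order), config.batch_size):
            bi = order[i:i + config.batch_size]
            logits, _ = model.forward(xt[bi])
            loss, grad = nn.cross_entropy(logits, yt[bi])
            model.backward(grad)
            opt.step()
            losses.append(loss)
        model.train_mode(False)
        val_loss, _ = nn.cross_entropy(model.predict_logits(xv), yv)
        rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                     "val_loss": val_loss})
        stop = stopper.update(val_loss)
        if stopper.best_epoch == epoch:
            best_weights = model.get_weights()
        if stop:
            break
    model.set_weights(best_weights)
    return model, rows, stopper.best_epoch


def train(spec: ModelSpec, config: TrainConfig,
          montages: Sequence[Montage] | None = None,
          x: np.ndarray | None = None, y: np.ndarray | None = None) -> TrainResult:
    """Train a montage classifier; deterministic for fixed spec/config seeds.

    If a fit never leaves the chance-level plateau (best validation loss
    above ``restart_val_loss``), the model is rebuilt with a fresh,
    deterministically derived initialization and retrained, up to
    ``max_restarts`` times; the best fit is returned.
    """
    if montages is not None:
        x, y = montages_to_arrays(montages)
    if x is None or y is None:
        raise DataError("provide montages or x/y arrays")
    if x.ndim == 3:
        x = x[:, None, :, :]
    if len(np.unique(y)) < 2:
        raise DataError("training data contains a single class")
    if x.shape[2:] != tuple(spec.input_size):
        raise ConfigurationError(
            f"input size {x.shape[2:]} does not match spec {spec.input_size}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, 29]))
    tr, va = _stratified_holdout(y, config.val_fraction, rng)
    if len(np.unique(y[tr])) < 2 or len(np.unique(y[va])) < 2:
        raise DataError("both classes required in train and validation partitions")
    xt, yt, xv, yv = x[tr], y[tr], x[va], y[va]

    best: tuple[float, TrainResult] | None = None
    for attempt in range(config.max_restarts + 1):
        attempt_spec = spec if attempt == 0 else dataclasses.replace(
            spec, seed=spec.seed + 1009 * attempt)
        model, rows, best_epoch = _fit_once(attempt_spec, config,
                                            xt, yt, xv, yv, rng)
        log = pd.DataFrame(rows)
        best_val = float(log["val_loss"].min())
        result = TrainResult(model=model, log=log, best_epoch=best_epoch,
                             spec=attempt_spec, config=config,
                             restarts=attempt)
        if best is None or best_val < best[0]:
            best = (best_val, result)
        if best_val <= config.restart_val_loss:
            break
    return best[1]


# ---------------------------------------------------------------------------
# evaluation


@dataclass(frozen=True)
class MetricCI:
    point: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.low <= self.point + 1e-12
                and self.point <= self.high + 1e-12 and self.high <= 1.0 + 1e-12):
            raise ValueError(f"invalid CI triple {self}")


@dataclass
class ClassificationMetrics:
    auc: MetricCI
    accuracy: MetricCI
    sensitivity: MetricCI
    specificity: MetricCI
    counts: dict[str, tuple[int, int]]  # metric -> (correct, total)
    n_boot: int
    ci_level: float

    def to_dict(self) -> dict:
        out: dict = {"n_boot": self.n_boot, "ci_level": self.ci_level,
                     "counts": {k: list(v) for k, v in self.counts.items()}}
        for name in ("auc", "accuracy", "sensitivity", "specificity"):
            m: MetricCI = getattr(self, name)
            out[name] = {"point": m.point, "low": m.low, "high": m.high}
        return out


def _metrics_at_threshold(y: np.ndarray, scores: np.ndarray) -> tuple[float, float, float, float]:
    pred = (scores >= 0.5).astype(int)
    pos, neg = y == 1, y == 0
    auc = roc_auc_score(y, scores)
    acc = float((pred == y).mean())
    sens = float((pred[pos] == 1).mean())
    spec = float((pred[neg] == 0).mean())
    return float(auc), acc, sens, spec


def evaluate(model: nn.Sequential, montages: Sequence[Montage] | None = None,
             x: np.ndarray | None = None, y: np.ndarray | None = None,
             n_boot: int = 2000, ci_level: float = 0.95,
             seed: int = 0) -> ClassificationMetrics:
    """Bootstrap evaluation of a trained classifier on a held-out test set."""
    if montages is not None:
        x, y = montages_to_arrays(montages)
    if x is None or y is None:
        raise DataError("provide montages or x/y arrays")
    if x.ndim == 3:
        x = x[:, None, :, :]
    if len(np.unique(y)) < 2:
        raise DataError("AUC undefined: test set contains a single class")
    scores = model.predict_proba(x)[:, 1]
    point = _metrics_at_threshold(y, scores)

    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 31]))
    n = len(y)
    boots = np.empty((n_boot, 4))
    filled = 0
    while filled < n_boot:
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        if yb.min() == yb.max():  # degenerate resample: no AUC, redraw
            continue
        boots[filled] = _metrics_at_threshold(yb, scores[idx])
        filled += 1
    alpha = (1.0 - ci_level) / 2.0
    lo = np.quantile(boots, alpha, axis=0)
    hi = np.quantile(boots, 1.0 - alpha, axis=0)
    mean = boots.mean(axis=0)
    # percentile intervals are clipped around the bootstrap mean so the
    # reported triple is always ordered
    cis = [MetricCI(float(m), float(min(l, m)), float(max(h, m)))
           for m, l, h in zip(mean, lo, hi)]

    pred = (scores >= 0.5).astype(int)
    pos, neg = y == 1, y == 0
    counts = {
        "accuracy": (int((pred == y).sum()), int(n)),
        "sensitivity": (int((pred[pos] == 1).sum()), int(pos.sum())),
        "specificity": (int((pred[neg] == 0).sum()), int(neg.sum())),
    }
    return ClassificationMetrics(auc=cis[0], accuracy=cis[1], sensitivity=cis[2],
                                 specificity=cis[3], counts=counts,
                                 n_boot=n_boot, ci_level=ci_level)


def predict_scores(model: nn.Sequential, montages: Sequence[Montage]) -> np.ndarray:
    x, _ = montages_to_arrays(montages)
    return model.predict_proba(x)[:, 1]
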