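"""Frame classifiers: the CNN detector and an LSTM baseline.

The CNN follows the published architecture: three building blocks, each of
two same-padded 3x3 convolutions (batch-norm + ReLU after each) followed by
a max-pool, with channel widths 8/16/16, dropout after the third block, and
a fully connected two-way softmax head. Pooling acts on the time axis only
(1x2): the input patch is 3 frequency bands tall, so 2x2 pooling would
collapse the frequency axis before three blocks complete. The time width
follows 11 -> 5 -> 2 -> 1.

The LSTM baseline reads the 11 time columns of a patch as a length-11
sequence of 3-dimensional band vectors through stacked recurrent layers;
the final hidden state feeds the same two-way head.

Training minimizes two-class cross-entropy with mini-batch Adam; everything
is a deterministic function of (config, data, seed).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigError, ValidationError
from .features import FrameGrid
from .intervals import FrameLabels
from . import nn


@dataclass(frozen=True)
class DetectorConfig:
    """All architecture and training hyper-parameters.

    Defaults are the published values where stated (3 blocks x 2 convs,
    channels 8/16/16, 3x3 kernel, batch 32, 100 000 iterations, 3x11 input,
    dropout after block 3); the optimizer, learning rate, dropout rate and
    decision threshold were never published and default to standard choices.
    """

    arch: str = "cnn"
    n_blocks: int = 3
    convs_per_block: int = 2
    channels: Tuple[int, ...] = (8, 16, 16)
    kernel: Tuple[int, int] = (3, 3)
    dropout_rate: float = 0.25
    dropout_after_block: int = 3
    batch_size: int = 32
    iterations: int = 100_000
    learning_rate: float = 1e-3
    threshold: float = 0.5
    seed: int = 0
    input_height: int = 3
    input_width: int = 11
    lstm_hidden: int = 64
    lstm_layers: int = 2
    class_weighting: bool = False

    def __post_init__(self) -> None:
        if self.arch not in ("cnn", "lstm"):
            raise ConfigError(f"arch: {self.arch!r} is not 'cnn' or 'lstm'")
        if len(self.channels) != self.n_blocks:
            raise ConfigError(
                f"channels: got {len(self.channels)} widths for {self.n_blocks} blocks"
            )
        for name in ("n_blocks", "convs_per_block", "batch_size", "input_height",
                     "input_width", "lstm_hidden", "lstm_layers"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name}: must be >= 1")
        if self.iterations < 0:
            raise ConfigError("iterations: must be >= 0")
        if not (0.0 < self.threshold < 1.0):
            raise ConfigError("threshold: must be in (0, 1)")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ConfigError("dropout_rate: must be in [0, 1)")
        if any(c < 1 for c in self.channels):
            raise ConfigError("channels: widths must be positive")

    def pooled_width(self) -> int:
        """Time width after the per-block pools; errors if any pool hits 0."""
        w = self.input_width
        for b in range(self.n_blocks):
            w = w // 2
            if w < 1:
                raise ConfigError(
                    f"input_width {self.input_width} pools below 1 at block {b + 1}"
                )
        return w


class _AddChannel(nn.Layer):
    """[N, H, W] -> [N, 1, H, W]."""

    def forward(self, x, train):
        return x[:, None, :, :]

    def backward(self, dy):
        return dy[:, 0]


class _PatchToSequence(nn.Layer):
    """[N, H, W] patches -> [N, W, H] sequences (time steps of band vectors)."""

    def forward(self, x, train):
        return np.ascontiguousarray(x.transpose(0, 2, 1))

    def backward(self, dy):
        return np.ascontiguousarray(dy.transpose(0, 2, 1))


class Detector:
    """A (possibly trained) frame classifier.

    ``training_log`` holds the per-step loss once :func:`train` has run.
    """

    def __init__(self, config: DetectorConfig, net: nn.Sequential,
                 batch_rng: np.random.Generator):
        self.config = config
        self.net = net
        self.batch_rng = batch_rng
        self.training_log: List[float] = []

    @property
    def n_params(self) -> int:
        return self.net.n_params

    def forward(self, patches: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(patches, train=train)


def build_detector(config: DetectorConfig) -> Detector:
    """Construct an untrained detector with seeded initialization."""
    ss = np.random.SeedSequence(config.seed)
    init_seed, dropout_seed, batch_seed = ss.spawn(3)
    init_rng = np.random.default_rng(init_seed)
    dropout_rng = np.random.default_rng(dropout_seed)

    layers: List[nn.Layer] = []
    if config.arch == "cnn":
        final_w = config.pooled_width()  # validates pooling geometry
        layers.append(_AddChannel())
        in_ch = 1
        for b in range(config.n_blocks):
            out_ch = config.channels[b]
            for _ in range(config.convs_per_block):
                layers.append(nn.Conv2d(in_ch, out_ch, config.kernel, init_rng))
                layers.append(nn.BatchNorm2d(out_ch))
                layers.append(nn.ReLU())
                in_ch = out_ch
            layers.append(nn.MaxPoolTime())
            if b + 1 == config.dropout_after_block and config.dropout_rate > 0:
                layers.append(nn.Dropout(config.dropout_rate, dropout_rng))
        layers.append(nn.Flatten())
        flat = config.channels[-1] * config.input_height * final_w
        layers.append(nn.Linear(flat, 2, init_rng))
    else:
        layers.append(_PatchToSequence())
        layers.append(nn.LSTM(config.input_height, config.lstm_hidden,
                              config.lstm_layers, init_rng))
        layers.append(nn.Linear(config.lstm_hidden, 2, init_rng))

    return Detector(config, nn.Sequential(layers), np.random.default_rng(batch_seed))


def train(
    detector: Detector,
    patches: np.ndarray,
    labels: np.ndarray,
    iterations: Optional[int] = None,
) -> Detector:
    """Mini-batch Adam on two-class cross-entropy; returns the detector.

    ``iterations`` overrides the config count (the published default of
    100 000 is rarely needed at synthetic scale). Same (config, data) twice
    => identical loss trajectory and weights.
    """
    config = detector.config
    x = np.asarray(patches, dtype=np.float64)
    y = np.asarray(labels).astype(np.int64).ravel()
    if x.ndim != 3 or x.shape[1:] != (config.input_height, config.input_width):
        raise ValidationError(
            f"patches: expected [n, {config.input_height}, {config.input_width}], "
            f"got {x.shape}"
        )
    if len(x) != len(y) or len(y) == 0:
        raise ValidationError("patches/labels: empty or mismatched dataset")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValidationError(
            f"dataset contains a single class ({classes.tolist()}); "
            "training needs both bowel-sound and non-bowel-sound frames"
        )

    n_iter = config.iterations if iterations is None else iterations
    weights = None
    if config.class_weighting:
        counts = np.bincount(y, minlength=2)
        weights = len(y) / (2.0 * np.maximum(counts, 1))

    opt = nn.Adam(detector.net, lr=config.learning_rate)
    rng = detector.batch_rng
    for step in range(n_iter):
        idx = rng.integers(0, len(y), size=config.batch_size)
        logits = detector.net.forward(x[idx], train=True)
        loss, dlogits = nn.softmax_cross_entropy(logits, y[idx], weights)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"training diverged: non-finite loss at step {step} "
                f"(lr={config.learning_rate}); lower the learning rate"
            )
        detector.training_log.append(loss)
        detector.net.backward(dlogits)
        opt.step()
    return detector


def predict_frames(detector: Detector, patches: np.ndarray,
                   batch_size: int = 8192) -> np.ndarray:
    """Per-frame bowel-sound probability, eval mode, in [0, 1].

    Constant (zero-contrast) patches — e.g. pure silence, which
    standardizes to all zeros — are defined as non-bowel-sound (p = 0):
    a burst by construction creates spectro-temporal contrast, and a
    featureless patch lies outside anything the classifier was trained on.
    """
    x = np.asarray(patches, dtype=np.float64)
    cfg = detector.config
    if x.ndim != 3 or x.shape[1:] != (cfg.input_height, cfg.input_width):
        raise ValidationError(
            f"patches: expected [n, {cfg.input_height}, {cfg.input_width}], got {x.shape}"
        )
    probs = np.empty(len(x))
    for i in range(0, len(x), batch_size):
        logits = detector.net.forward(x[i : i + batch_size], train=False)
        probs[i : i + batch_size] = nn.softmax(logits)[:, 1]
    probs[x.std(axis=(1, 2)) <= 1e-12] = 0.0
    return probs


def binarize(probs: np.ndarray, threshold: float = 0.5,
             grid: Optional[FrameGrid] = None):
    """Threshold probabilities (``p >= threshold`` is positive).

    Returns a plain uint8 vector, or :class:`FrameLabels` when a grid is given.
    """
    values = (np.asarray(probs) >= threshold).astype(np.uint8)
    if grid is None:
        return values
    return FrameLabels(values=values, grid=grid)


# ---------------------------------------------------------------------------
# Checkpoints: a single .npz holding the config (JSON) + named weight arrays.

def save_detector(detector: Detector, path) -> None:
    arrays = {"__config__": np.frombuffer(
        json.dumps(asdict(detector.config)).encode(), dtype=np.uint8)}
    for i, layer in enumerate(detector.net.layers):
        for name, value in layer.params.items():
            arrays[f"layer{i}.{name}"] = value
        if isinstance(layer, nn.BatchNorm2d):
            arrays[f"layer{i}.running_mean"] = layer.running_mean
            arrays[f"layer{i}.running_var"] = layer.running_var
    np.savez(Path(path), **arrays)


def load_detector(path) -> Detector:
    with np.load(Path(path)) as data:
        cfg_dict = json.loads(bytes(data["__config__"]).decode())
        for key in ("channels", "kernel"):
            cfg_dict[key] = tuple(cfg_dict[key])
        config = DetectorConfig(**cfg_dict)
        detector = build_detector(config)
        for i, layer in enumerate(detector.net.layers):
            for name in layer.params:
                layer.params[name][...] = data[f"layer{i}.{name}"]
            if isinstance(layer, nn.BatchNorm2d):
                layer.running_mean[...] = data[f"layer{i}.running_mean"]
                layer.running_var[...] = data[f"layer{i}.running_var"]
    return detector
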