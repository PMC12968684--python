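"""Detector and classifier architectures behind uniform build/step contracts.

Stage 1 (streaming detection) presets — each a convolutional front-end that
embeds one sliding window, feeding an LSTM whose state persists across the
1 s-shift windows of a chunk and resets at chunk boundaries, ending in a
sigmoid seizure probability:

* ``cnn2d_lstm``                — shallow stack of 2-D convolutions;
* ``resnet_short_lstm``         — full-height stem + 4 residual blocks;
* ``resnet_short_dilation_lstm``— the residual stack with dilated temporal
  convolutions (dilations 1/2/4/8);
* ``mobilenetv3_short_lstm``    — reduced inverted-residual stack with
  squeeze-excitation and hard-swish.

Stage 2 (clip classification) presets — a stem of one-dimensional temporal
filters applied per montage channel, an electrode-mixing convolution, a
convolutional body, global temporal pooling (so variable clip lengths give
fixed-size logits) and a 5-way softmax:

* ``cnn2d_lstm_clf``, ``resnet50_conv`` (bottleneck residual stages
  3/4/6/3), ``mobilenetv3_clf``, ``densenet_clf`` (densely connected
  blocks).

Exact layer counts and filter sizes are this package's own documented
presets; ``width_multiplier`` scales every convolutional width so the same
topology runs at desk scale.  Input layout: montage channels are the 2-D
convolution's height axis, i.e. a raw window is a 1×22×T image and a
frequency-band window a 7×22×frames image.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from ._nn import (
    Adam,  # noqa: F401  (re-exported for training code)
    ChannelNorm,
    Conv2d,
    DepthwiseConv2d,
    LSTMCell,
    Linear,
    Module,
    SqueezeExcite,
    Tensor,
    concat,
    hardswish,
    mean_max_pool,
    mean_pool,
)
from .features import FeatureTensor

__all__ = [
    "DETECTOR_NAMES",
    "CLASSIFIER_NAMES",
    "CLASS_ORDER",
    "ModelConfig",
    "DetectorState",
    "Detector",
    "Classifier",
    "build_detector",
    "build_classifier",
    "detector_step",
    "save_model",
    "load_model",
]

DETECTOR_NAMES = ("cnn2d_lstm", "resnet_short_lstm",
                  "resnet_short_dilation_lstm", "mobilenetv3_short_lstm")
CLASSIFIER_NAMES = ("cnn2d_lstm_clf", "resnet50_conv",
                    "mobilenetv3_clf", "densenet_clf")
#: fixed class order of the 5-way softmax
CLASS_ORDER = ("normal", "CAE", "IESS", "GN", "FC")

N_MONTAGE = 22


@dataclasses.dataclass
class ModelConfig:
    name: str
    width_multiplier: float = 1.0
    recurrent_hidden: int = 64
    dropout: float = 0.0
    extractor: str = "raw"  # raw | frequency_bands
    n_classes: int | None = None  # fixed by stage: 2 detectors, 5 classifiers
    seed: int = 0

    def __post_init__(self):
        if self.name not in DETECTOR_NAMES + CLASSIFIER_NAMES:
            raise ValueError(f"unknown model name {self.name!r}")
        if self.extractor not in ("raw", "frequency_bands"):
            raise ValueError(f"unknown extractor {self.extractor!r}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        expected = 2 if self.name in DETECTOR_NAMES else 5
        if self.n_classes is None:
            self.n_classes = expected
        elif self.n_classes != expected:
            raise ValueError(
                f"{self.name} is fixed at {expected} classes, got {self.n_classes}")

    @property
    def input_channels(self) -> int:
        return 1 if self.extractor == "raw" else 7

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @staticmethod
    def from_json(s: str) -> "ModelConfig":
        return ModelConfig(**json.loads(s))


def _as_image(ft: FeatureTensor) -> np.ndarray:
    """FeatureTensor -> (c_in, 22, T) conv input."""
    if ft.extractor_tag == "raw":
        return ft.data[None, :, :]
    # (channels, frames, bands) -> bands become conv channels
    return ft.data.transpose(2, 0, 1)


def _w(base: int, mult: float) -> int:
    return max(1, int(round(base * mult)))


def _pool_time(x: Tensor, factor: int) -> Tensor:
    """Non-overlapping mean pooling along the time (last) axis."""
    if factor == 1:
        return x
    n, c, h, t = x.shape
    crop = (t // factor) * factor
    if crop == 0:
        return x
    y = x.narrow(3, 0, crop).reshape(n, c, h, crop // factor, factor)
    return y.mean(axis=4)


def _pool_time_to(x: Tensor, max_frames: int) -> Tensor:
    t = x.shape[3]
    if t <= max_frames:
        return x
    return _pool_time(x, -(-t // max_frames))


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

class _ResBlock(Module):
    """Two (1,5) temporal convolutions with channel norm and identity skip."""

    def __init__(self, c_in, c_out, rng, stride=1, dilation=1):
        super().__init__()
        pad = 2 * dilation
        self.conv1 = Conv2d(c_in, c_out, (1, 5), rng, stride=(1, stride),
                            dilation=(1, dilation), padding=(0, pad))
        self.n1 = ChannelNorm(c_out)
        self.conv2 = Conv2d(c_out, c_out, (1, 5), rng,
                            dilation=(1, dilation), padding=(0, pad))
        self.n2 = ChannelNorm(c_out)
        self.proj = (Conv2d(c_in, c_out, (1, 1), rng, stride=(1, stride))
                     if (stride != 1 or c_in != c_out) else None)

    def __call__(self, x):
        y = self.n1(self.conv1(x)).relu()
        y = self.n2(self.conv2(y))
        s = self.proj(x) if self.proj is not None else x
        return (y + s).relu()


class _Bottleneck(Module):
    """1x1 reduce -> (1,3) temporal -> 1x1 expand, expansion 4."""

    EXPANSION = 4

    def __init__(self, c_in, planes, rng, stride=1):
        super().__init__()
        c_out = planes * self.EXPANSION
        self.conv1 = Conv2d(c_in, planes, (1, 1), rng)
        self.n1 = ChannelNorm(planes)
        self.conv2 = Conv2d(planes, planes, (1, 3), rng,
                            stride=(1, stride), padding=(0, 1))
        self.n2 = ChannelNorm(planes)
        self.conv3 = Conv2d(planes, c_out, (1, 1), rng)
        self.n3 = ChannelNorm(c_out)
        self.proj = (Conv2d(c_in, c_out, (1, 1), rng, stride=(1, stride))
                     if (stride != 1 or c_in != c_out) else None)
        # zero-init branch gain: the deep stack starts as (near) identity,
        # which keeps gradients well-conditioned at 16-block depth
        self.branch_gain = Tensor(np.zeros(1), requires_grad=True)

    def __call__(self, x):
        y = self.n1(self.conv1(x)).relu()
        y = self.n2(self.conv2(y)).relu()
        y = self.n3(self.conv3(y)) * self.branch_gain
        s = self.proj(x) if self.proj is not None else x
        return (y + s).relu()


class _InvertedResidual(Module):
    """MobileNetV3 block: expand -> depthwise -> squeeze-excite -> project."""

    def __init__(self, c_in, c_out, c_expand, rng, stride=1, kernel=5):
        super().__init__()
        self.pw1 = Conv2d(c_in, c_expand, (1, 1), rng)
        self.dw = DepthwiseConv2d(c_expand, (1, kernel), rng,
                                  stride=(1, stride), padding=(0, kernel // 2))
        self.se = SqueezeExcite(c_expand, rng)
        self.pw2 = Conv2d(c_expand, c_out, (1, 1), rng)
        self.n = ChannelNorm(c_out)
        self.skip = stride == 1 and c_in == c_out

    def __call__(self, x):
        y = hardswish(self.pw1(x))
        y = hardswish(self.dw(y))
        y = self.se(y)
        y = self.n(self.pw2(y))
        return y + x if self.skip else y


# ---------------------------------------------------------------------------
# Detector front-ends (window -> embedding)
# ---------------------------------------------------------------------------

class _Cnn2dFront(Module):
    def __init__(self, c_in, m, rng):
        super().__init__()
        w1, w2, w3 = _w(16, m), _w(32, m), _w(64, m)
        self.c1 = Conv2d(c_in, w1, (3, 5), rng, stride=(2, 2), padding=(1, 2))
        self.c2 = Conv2d(w1, w2, (3, 5), rng, stride=(2, 2), padding=(1, 2))
        self.c3 = Conv2d(w2, w3, (3, 5), rng, stride=(2, 2), padding=(1, 2))
        self.out_dim = w3

    def __call__(self, x):
        x = self.c1(x).relu()
        x = self.c2(x).relu()
        x = self.c3(x).relu()
        return mean_pool(x)


class _ResNetShortFront(Module):
    def __init__(self, c_in, m, rng, dilated=False, ts=4):
        super().__init__()
        stem_w = _w(32, m)
        self.stem = Conv2d(c_in, stem_w, (N_MONTAGE, 7), rng,
                           stride=(N_MONTAGE, ts), padding=(0, 3))
        widths = [_w(32, m), _w(32, m), _w(64, m), _w(64, m)]
        if dilated:
            dils, strides = [1, 2, 4, 8], [1, 2, 1, 2]
        else:
            dils, strides = [1, 1, 1, 1], [1, 2, 2, 2]
        blocks, c = [], stem_w
        for wd, st, dl in zip(widths, strides, dils):
            blocks.append(_ResBlock(c, wd, rng, stride=st, dilation=dl))
            c = wd
        self.blocks = blocks
        self.out_dim = c

    def __call__(self, x):
        x = self.stem(x).relu()
        for b in self.blocks:
            x = b(x)
        return mean_pool(x)


class _MobileNetFront(Module):
    def __init__(self, c_in, m, rng, ts=4):
        super().__init__()
        w16, w24, w40 = _w(16, m), _w(24, m), _w(40, m)
        self.stem = Conv2d(c_in, w16, (N_MONTAGE, 7), rng,
                           stride=(N_MONTAGE, ts), padding=(0, 3))
        self.blocks = [
            _InvertedResidual(w16, w24, _w(64, m), rng, stride=2),
            _InvertedResidual(w24, w24, _w(72, m), rng, stride=1),
            _InvertedResidual(w24, w40, _w(96, m), rng, stride=2),
        ]
        # final pointwise conv + activation: pooling a bare ChannelNorm
        # output would collapse the (zero-mean) embedding to a constant
        self.final = Conv2d(w40, w40, (1, 1), rng)
        self.out_dim = w40

    def __call__(self, x):
        x = hardswish(self.stem(x))
        for b in self.blocks:
            x = b(x)
        return mean_pool(hardswish(self.final(x)))


def _build_front(config: ModelConfig, rng) -> Module:
    c_in, m = config.input_channels, config.width_multiplier
    # raw runs at 200 samples/s and is downsampled aggressively; band frames
    # arrive at ~2/s and keep their resolution
    ts = 4 if config.extractor == "raw" else 1
    if config.name == "cnn2d_lstm":
        return _Cnn2dFront(c_in, m, rng)
    if config.name == "resnet_short_lstm":
        return _ResNetShortFront(c_in, m, rng, dilated=False, ts=ts)
    if config.name == "resnet_short_dilation_lstm":
        return _ResNetShortFront(c_in, m, rng, dilated=True, ts=ts)
    if config.name == "mobilenetv3_short_lstm":
        return _MobileNetFront(c_in, m, rng, ts=ts)
    raise ValueError(f"{config.name} is not a detector")


# ---------------------------------------------------------------------------
# Classifier bodies (clip -> feature vector)
# ---------------------------------------------------------------------------

class _ClfStem(Module):
    """One-dimensional temporal filters per montage channel (kernel height 1),
    then a full-height electrode-mixing convolution."""

    def __init__(self, c_in, c_temp, c_out, rng, ts=4):
        super().__init__()
        self.temporal = Conv2d(c_in, c_temp, (1, 7), rng, stride=(1, ts),
                               padding=(0, 3))
        self.mix = Conv2d(c_temp, c_out, (N_MONTAGE, 1), rng)

    def __call__(self, x):
        return self.mix(self.temporal(x).relu()).relu()


class _ResNet50Body(Module):
    def __init__(self, c_in, m, rng, ts=4):
        super().__init__()
        self.pool0 = ts
        self.stem = _ClfStem(c_in, _w(32, m), _w(64, m), rng, ts=ts)
        planes = [_w(64, m), _w(128, m), _w(256, m), _w(512, m)]
        layers = [3, 4, 6, 3]
        strides = [1, 2, 2, 2]
        blocks, c = [], _w(64, m)
        for p, n, s in zip(planes, layers, strides):
            for i in range(n):
                blocks.append(_Bottleneck(c, p, rng, stride=s if i == 0 else 1))
                c = p * _Bottleneck.EXPANSION
        self.blocks = blocks
        self.final_norm = ChannelNorm(c)
        self.out_dim = 2 * c

    def __call__(self, x):
        x = _pool_time(self.stem(x), self.pool0)
        for b in self.blocks:
            x = b(x)
        return mean_max_pool(self.final_norm(x))


class _DenseLayer(Module):
    def __init__(self, c_in, growth, rng):
        super().__init__()
        self.n = ChannelNorm(c_in)
        self.conv = Conv2d(c_in, growth, (1, 3), rng, padding=(0, 1))

    def __call__(self, x):
        return concat([x, self.conv(self.n(x).relu())], axis=1)


class _DenseNetBody(Module):
    def __init__(self, c_in, m, rng, n_layers=4, ts=4):
        super().__init__()
        growth = _w(32, m)
        c = _w(64, m)
        self.pool0 = ts
        self.stem = _ClfStem(c_in, _w(32, m), c, rng, ts=ts)
        self.block1 = [_DenseLayer(c + i * growth, growth, rng)
                       for i in range(n_layers)]
        c += n_layers * growth
        self.trans = Conv2d(c, c // 2, (1, 1), rng)
        c = c // 2
        self.block2 = [_DenseLayer(c + i * growth, growth, rng)
                       for i in range(n_layers)]
        c += n_layers * growth
        self.final_norm = ChannelNorm(c)
        self.out_dim = 2 * c

    def __call__(self, x):
        x = _pool_time(self.stem(x), self.pool0)
        for l in self.block1:
            x = l(x)
        x = _pool_time(self.trans(x).relu(), 2 if self.pool0 > 1 else 1)
        for l in self.block2:
            x = l(x)
        return mean_max_pool(self.final_norm(x).relu())


class _MobileNetClfBody(Module):
    def __init__(self, c_in, m, rng, ts=4):
        super().__init__()
        w16, w24, w40, w48 = _w(16, m), _w(24, m), _w(40, m), _w(48, m)
        self.pool0 = 2 if ts > 1 else 1
        self.stem = _ClfStem(c_in, w16, w16, rng, ts=ts)
        self.blocks = [
            _InvertedResidual(w16, w24, _w(64, m), rng, stride=2),
            _InvertedResidual(w24, w24, _w(72, m), rng, stride=1),
            _InvertedResidual(w24, w40, _w(96, m), rng, stride=2),
            _InvertedResidual(w40, w48, _w(120, m), rng, stride=2),
        ]
        self.final = Conv2d(w48, w48, (1, 1), rng)
        self.out_dim = 2 * w48

    def __call__(self, x):
        x = _pool_time(self.stem(x), self.pool0)
        for b in self.blocks:
            x = b(x)
        return mean_max_pool(hardswish(self.final(x)))


class _Cnn2dLstmClfBody(Module):
    """Conv stem, temporal pooling to at most 40 frames, LSTM over frames."""

    MAX_FRAMES = 40

    def __init__(self, c_in, m, rng, hidden, ts=4):
        super().__init__()
        w1, w2 = _w(16, m), _w(48, m)
        self.pool0 = 2 if ts > 1 else 1
        self.stem = _ClfStem(c_in, w1, w1, rng, ts=ts)
        self.conv = Conv2d(w1, w2, (1, 5), rng, stride=(1, 2), padding=(0, 2))
        self.lstm = LSTMCell(w2, hidden, rng)
        self.out_dim = hidden

    def __call__(self, x):
        x = _pool_time(self.stem(x), self.pool0)
        x = self.conv(x).relu()
        x = _pool_time_to(x, self.MAX_FRAMES)  # (N, C, 1, T')
        n, c, _, t = x.shape
        seq = x.reshape(n, c, t)
        h, cell = self.lstm.zero_state(n)
        for j in range(t):
            h, cell = self.lstm(seq.narrow(2, j, 1).reshape(n, c), h, cell)
        return h


def _build_clf_body(config: ModelConfig, rng) -> Module:
    c_in, m = config.input_channels, config.width_multiplier
    ts = 4 if config.extractor == "raw" else 1
    if config.name == "cnn2d_lstm_clf":
        return _Cnn2dLstmClfBody(c_in, m, rng, config.recurrent_hidden, ts=ts)
    if config.name == "resnet50_conv":
        return _ResNet50Body(c_in, m, rng, ts=ts)
    if config.name == "mobilenetv3_clf":
        return _MobileNetClfBody(c_in, m, rng, ts=ts)
    if config.name == "densenet_clf":
        return _DenseNetBody(c_in, m, rng, ts=ts)
    raise ValueError(f"{config.name} is not a classifier")


# ---------------------------------------------------------------------------
# Detector
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DetectorState:
    """Recurrent state carried across the sliding windows of one chunk."""

    h: np.ndarray
    c: np.ndarray
    windows_seen: int = 0


class Detector(Module):
    def __init__(self, config: ModelConfig):
        super().__init__()
        if config.name not in DETECTOR_NAMES:
            raise ValueError(f"{config.name} is not a detector preset")
        rng = np.random.default_rng(config.seed)
        self.config = config
        self.front = _build_front(config, rng)
        self.lstm = LSTMCell(self.front.out_dim, config.recurrent_hidden, rng)
        self.head = Linear(config.recurrent_hidden, 1, rng)
        self._dropout_rng = np.random.default_rng(config.seed + 1)

    # -- streaming ---------------------------------------------------------
    def initial_state(self) -> DetectorState:
        H = self.config.recurrent_hidden
        return DetectorState(np.zeros((1, H)), np.zeros((1, H)), 0)

    def step(self, window: FeatureTensor, state: DetectorState
             ) -> tuple[float, DetectorState]:
        """One streaming inference step; see :func:`detector_step`."""
        img = _as_image(window)
        emb = self.front(Tensor(img[None]))
        h, c = self.lstm(emb, Tensor(state.h), Tensor(state.c))
        logit = float(self.head(h).data[0, 0])
        prob = 1.0 / (1.0 + np.exp(-logit))
        return prob, DetectorState(h.data.copy(), c.data.copy(),
                                   state.windows_seen + 1)

    # -- batch (training / evaluation) -------------------------------------
    def sequence_logits(self, images: np.ndarray, train: bool = False) -> Tensor:
        """Logits for an ordered window sequence (T, c_in, 22, L): the CNN
        runs as one batch, the LSTM scans the embeddings from a fresh state
        (chunk-boundary reset).  Returns a (T, 1) Tensor."""
        emb = self.front(Tensor(images))
        h, c = self.lstm.zero_state(1)
        logits = []
        p = self.config.dropout
        for t in range(images.shape[0]):
            h, c = self.lstm(emb.narrow(0, t, 1), h, c)
            out = h
            if train and p > 0:
                mask = (self._dropout_rng.random(out.shape) >= p) / (1.0 - p)
                out = out * Tensor(mask)
            logits.append(self.head(out))
        return concat(logits, axis=0)

    def predict_chunk(self, windows: list[FeatureTensor]) -> np.ndarray:
        """Per-window seizure probabilities for one chunk (batch path)."""
        images = np.stack([_as_image(w) for w in windows])
        logits = self.sequence_logits(images).data[:, 0]
        return 1.0 / (1.0 + np.exp(-logits))


def build_detector(config: ModelConfig) -> Detector:
    """Deterministic construction under the config's seed."""
    return Detector(config)


def detector_step(detector: Detector, window: FeatureTensor,
                  state: DetectorState) -> tuple[float, DetectorState]:
    """Streaming step: probability that THIS window contains seizure, plus
    the updated recurrent state.  Stateless apart from DetectorState."""
    return detector.step(window, state)


# ---------------------------------------------------------------------------
# Classifier
# ---------------------------------------------------------------------------

class Classifier(Module):
    def __init__(self, config: ModelConfig):
        super().__init__()
        if config.name not in CLASSIFIER_NAMES:
            raise ValueError(f"{config.name} is not a classifier preset")
        rng = np.random.default_rng(config.seed)
        self.config = config
        # standardize each input channel per clip: band magnitudes are
        # heavy-tailed and all-positive, which otherwise kills early ReLUs
        self.input_norm = ChannelNorm(config.input_channels)
        self.body = _build_clf_body(config, rng)
        self.head = Linear(self.body.out_dim, config.n_classes, rng, scale=0.01)
        self._dropout_rng = np.random.default_rng(config.seed + 1)

    def logits(self, clip: FeatureTensor, train: bool = False) -> Tensor:
        x = _as_image(clip)
        feat = self.body(self.input_norm(Tensor(x[None])))
        p = self.config.dropout
        if train and p > 0:
            mask = (self._dropout_rng.random(feat.shape) >= p) / (1.0 - p)
            feat = feat * Tensor(mask)
        return self.head(feat)

    def predict_proba(self, clip: FeatureTensor) -> np.ndarray:
        """Probability 5-vector over CLASS_ORDER (softmax; sums to 1)."""
        z = self.logits(clip).data[0]
        z = z - z.max()
        e = np.exp(z)
        return e / e.sum()


def build_classifier(config: ModelConfig) -> Classifier:
    return Classifier(config)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_model(model: Detector | Classifier, path: str | Path) -> None:
    """Single-file archive: parameters plus the ModelConfig JSON."""
    arrays = {f"p{i:04d}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, __config__=np.frombuffer(
        model.config.to_json().encode(), dtype=np.uint8), **arrays)


def load_model(path: str | Path) -> "Detector | Classifier":
    with np.load(path) as z:
        config = ModelConfig.from_json(bytes(z["__config__"]).decode())
        arrays = [z[k] for k in sorted(k for k in z.files if k != "__config__")]
    model = (build_detector(config) if config.name in DETECTOR_NAMES
             else build_classifier(config))
    model.load_arrays(arrays)
    return model
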