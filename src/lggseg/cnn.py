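"""Patch-classification CNNs and dense full-image inference, in NumPy.

The architecture family follows a small-kernel design: two convolutional
blocks of 3x3 convolutions (2 per block in the base line, 3 in the deeper
variants) each followed by a 2x2 max-pool, then three fully connected
layers ending in a 2-way softmax.  "More fc" variants widen the hidden
fully connected layers from 256 to 4096 neurons.  Optional 3-slice fusion
feeds the slices z-1, z, z+1 either as input channels of one pathway
(early fusion, shared parameters) or through three independent
convolutional pathways concatenated before the fully connected layers
(late fusion).

Convolutions are unpadded (valid).  This makes dense inference — the
fully connected layers applied convolutionally over a whole slice — agree
*exactly* with patch-wise classification at every score-map location,
since a patch classifier with zero padding would see artificial zeros at
its window border that a full image does not have.  Two 2x2 pools give
the dense score map a spatial stride of 4.

Training: mini-batch SGD on softmax cross-entropy, He ("improved
Xavier") initialization, dropout after each hidden fully connected
layer, and a log-spaced learning-rate schedule.  Everything is driven by
a single integer seed and is bit-reproducible on a fixed BLAS.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .imaging_core import ScoreMap, Volume
from .sampler import PATCH_SIZE, HALF, PatchSet

__all__ = [
    "NetworkSpec",
    "TrainConfig",
    "PatchCNN",
    "build_network",
    "lr_schedule",
    "train",
    "dense_inference",
    "save_checkpoint",
    "load_checkpoint",
]

# convolutions per block and hidden fc width for each named variant
_VARIANT_DEPTH = {"base": 2, "deeper": 3, "more_fc": 2, "deeper_more_fc": 3}
_VARIANT_FC = {"base": 256, "deeper": 256, "more_fc": 4096, "deeper_more_fc": 4096}
_DEFAULT_FILTERS = (64, 128)


@dataclass
class NetworkSpec:
    """Declarative description of one architecture + fusion mode.

    ``conv_blocks`` lists, per block, the filter count of each 3x3
    convolution; a 2x2 max-pool follows every block.  ``fc_sizes`` are
    the fully connected layer widths, ending in 2 (softmax classes).
    Filter/neuron counts may be scaled down from the canonical widths
    (e.g. for quick CPU experiments) but the layer structure is fixed by
    the variant.
    """

    variant: str
    fusion: str = "none"
    conv_blocks: list[list[int]] = field(default_factory=list)
    fc_sizes: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.variant not in _VARIANT_DEPTH:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.fusion not in ("none", "early", "late"):
            raise ValueError(f"unknown fusion mode {self.fusion!r}")
        if not self.conv_blocks:
            d = _VARIANT_DEPTH[self.variant]
            self.conv_blocks = [[f] * d for f in _DEFAULT_FILTERS]
        if not self.fc_sizes:
            w = _VARIANT_FC[self.variant]
            self.fc_sizes = (w, w, 2)
        self.conv_blocks = [list(b) for b in self.conv_blocks]
        self.fc_sizes = tuple(int(s) for s in self.fc_sizes)
        if len(self.conv_blocks) != 2:
            raise ValueError("architecture requires exactly two pooled conv blocks")
        d = _VARIANT_DEPTH[self.variant]
        for b in self.conv_blocks:
            if len(b) != d:
                raise ValueError(
                    f"variant {self.variant!r} requires {d} convolutions per block, "
                    f"got block {b}"
                )
        if len(self.fc_sizes) != 3 or self.fc_sizes[-1] != 2:
            raise ValueError("fc_sizes must be three layers ending in 2")

    @classmethod
    def from_variant(
        cls,
        variant: str,
        fusion: str = "none",
        filters: tuple[int, int] | None = None,
        fc_width: int | None = None,
    ) -> "NetworkSpec":
        """Build a spec for a named variant, optionally width-scaled."""
        d = _VARIANT_DEPTH[variant]
        f1, f2 = filters if filters is not None else _DEFAULT_FILTERS
        w = fc_width if fc_width is not None else _VARIANT_FC[variant]
        return cls(variant, fusion, [[f1] * d, [f2] * d], (w, w, 2))

    @property
    def n_conv_layers(self) -> int:
        return sum(len(b) for b in self.conv_blocks)

    @property
    def n_pool_stages(self) -> int:
        return len(self.conv_blocks)

    @property
    def in_channels(self) -> int:
        return 1 if self.fusion == "none" else 3

    def spatial_size_after_convs(self, size: int = PATCH_SIZE) -> int:
        for block in self.conv_blocks:
            size -= 2 * len(block)
            size //= 2
        return size


@dataclass
class TrainConfig:
    epochs: int = 25
    lr_start: float = 3e-3
    lr_end: float = 3e-5
    dropout_rate: float = 0.5
    batch_size: int = 128
    momentum: float = 0.9
    init: str = "he_xavier"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.lr_end <= self.lr_start):
            raise ValueError("require 0 < lr_end <= lr_start")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")


def lr_schedule(epoch: int, config: TrainConfig) -> float:
    """Logarithmic learning-rate descent: log-spaced from lr_start to lr_end.

    ``lr(e) = lr_start * (lr_end/lr_start) ** ((e-1)/(E-1))`` for epoch e
    in 1..E; a single-epoch schedule returns lr_start.
    """
    E = config.epochs
    if not 1 <= epoch <= E:
        raise ValueError(f"epoch must be in 1..{E}, got {epoch}")
    if E == 1:
        return config.lr_start
    return config.lr_start * (config.lr_end / config.lr_start) ** ((epoch - 1) / (E - 1))


# ---------------------------------------------------------------------------
# layers


class _Conv:
    """3x3 valid convolution. Weights (F, C, 3, 3), He-initialized."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in = c_in * 9
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, 3, 3))
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols = None
        self._xshape = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        N, C, H, W = x.shape
        view = np.lib.stride_tricks.sliding_window_view(x, (3, 3), axis=(2, 3))
        cols = view.transpose(0, 2, 3, 1, 4, 5).reshape(N * (H - 2) * (W - 2), C * 9)
        F = self.W.shape[0]
        out = cols @ self.W.reshape(F, -1).T + self.b
        if train:
            self._cols, self._xshape = cols, x.shape
        return out.reshape(N, H - 2, W - 2, F).transpose(0, 3, 1, 2)

    def backward(self, g: np.ndarray) -> np.ndarray:
        N, F, Ho, Wo = g.shape
        gmat = g.transpose(0, 2, 3, 1).reshape(-1, F)
        self.dW += (gmat.T @ self._cols).reshape(self.W.shape)
        self.db += gmat.sum(axis=0)
        _, C, H, W = self._xshape
        dx = np.zeros(self._xshape)
        g_nhwf = g.transpose(0, 2, 3, 1)
        for i in range(3):
            for j in range(3):
                contrib = g_nhwf @ self.W[:, :, i, j]  # (N,Ho,Wo,C)
                dx[:, :, i : i + Ho, j : j + Wo] += contrib.transpose(0, 3, 1, 2)
        self._cols = None
        return dx

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class _ReLU:
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask

    def params(self):
        return []


class _MaxPool2:
    """2x2 max pooling, stride 2, trailing odd row/col dropped."""

    def forward(self, x, train):
        N, C, H, W = x.shape
        ph, pw = H // 2, W // 2
        x4 = x[:, :, : 2 * ph, : 2 * pw].reshape(N, C, ph, 2, pw, 2)
        x4 = x4.transpose(0, 1, 2, 4, 3, 5).reshape(N, C, ph, pw, 4)
        self._argmax = x4.argmax(axis=-1)
        self._xshape = x.shape
        return np.take_along_axis(x4, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, g):
        N, C, H, W = self._xshape
        ph, pw = H // 2, W // 2
        d4 = np.zeros((N, C, ph, pw, 4))
        np.put_along_axis(d4, self._argmax[..., None], g[..., None], axis=-1)
        dx = np.zeros(self._xshape)
        dx[:, :, : 2 * ph, : 2 * pw] = (
            d4.reshape(N, C, ph, pw, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(N, C, 2 * ph, 2 * pw)
        )
        return dx

    def params(self):
        return []


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_out, n_in))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train):
        if train:
            self._x = x
        return x @ self.W.T + self.b

    def backward(self, g):
        self.dW += g.T @ self._x
        self.db += g.sum(axis=0)
        self._x = None
        return g @ self.W

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class _Dropout:
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float):
        self.rate = rate
        self.rng: np.random.Generator | None = None

    def forward(self, x, train):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask

    def params(self):
        return []


class _Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, train):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, g):
        for l in reversed(self.layers):
            g = l.backward(g)
        return g

    def params(self):
        return [p for l in self.layers for p in l.params()]


# ---------------------------------------------------------------------------
# model


class PatchCNN:
    """Two-class patch classifier with optional 3-slice fusion.

    Built by :func:`build_network`.  ``pathways`` is a list of
    convolutional stacks (one for single-slice and early fusion, three
    independent ones for late fusion); their flattened outputs are
    concatenated and fed to the fully connected head.
    """

    def __init__(self, spec: NetworkSpec, seed: int = 0, dropout_rate: float = 0.5):
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        n_pathways = 3 if spec.fusion == "late" else 1
        path_in = 1 if spec.fusion != "early" else 3
        self.pathways = []
        for _ in range(n_pathways):
            layers = []
            c = path_in
            for block in spec.conv_blocks:
                for f in block:
                    layers += [_Conv(c, f, rng), _ReLU()]
                    c = f
                layers.append(_MaxPool2())
            self.pathways.append(_Sequential(layers))
        s = spec.spatial_size_after_convs()
        if s < 1:
            raise ValueError("patch too small for this architecture")
        self._feat_side = s
        self._feat_channels = spec.conv_blocks[-1][-1]
        n_in = n_pathways * self._feat_channels * s * s
        fc_layers = []
        for i, width in enumerate(spec.fc_sizes):
            fc_layers.append(_Dense(n_in, width, rng))
            if i < len(spec.fc_sizes) - 1:
                fc_layers += [_ReLU(), _Dropout(dropout_rate)]
            n_in = width
        self.fc = _Sequential(fc_layers)

    # -- bookkeeping

    def _all_params(self):
        out = []
        for p in self.pathways:
            out += p.params()
        out += self.fc.params()
        return out

    @property
    def n_parameters(self) -> int:
        return int(sum(w.size for w, _ in self._all_params()))

    @property
    def n_conv_parameters(self) -> int:
        return int(sum(w.size for p in self.pathways for w, _ in p.params()))

    def _set_dropout_rng(self, rng: np.random.Generator | None):
        for l in self.fc.layers:
            if isinstance(l, _Dropout):
                l.rng = rng

    def _zero_grad(self):
        for _, g in self._all_params():
            g[:] = 0

    def _sgd_step(self, lr: float, momentum: float = 0.0):
        params = self._all_params()
        if momentum > 0:
            if not hasattr(self, "_velocity") or len(self._velocity) != len(params):
                self._velocity = [np.zeros_like(w) for w, _ in params]
            for v, (w, g) in zip(self._velocity, params):
                v *= momentum
                v -= lr * g
                w += v
        else:
            for w, g in params:
                w -= lr * g

    # -- patch path

    def _split_inputs(self, x: np.ndarray) -> list[np.ndarray]:
        if self.spec.fusion == "late":
            return [x[:, i : i + 1] for i in range(3)]
        return [x]

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a batch of patches, shape (N, C, 33, 33) -> (N, 2)."""
        feats = []
        self._feat_shapes = []
        for p, xp in zip(self.pathways, self._split_inputs(x)):
            f = p.forward(xp, train)
            self._feat_shapes.append(f.shape)
            feats.append(f.reshape(f.shape[0], -1))
        return self.fc.forward(np.concatenate(feats, axis=1), train)

    def backward_from_logits(self, dlogits: np.ndarray) -> None:
        g = self.fc.backward(dlogits)
        sizes = [int(np.prod(s[1:])) for s in self._feat_shapes]
        offset = 0
        for p, shape, size in zip(self.pathways, self._feat_shapes, sizes):
            p.backward(g[:, offset : offset + size].reshape(shape))
            offset += size

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Softmax class probabilities for patches (N, C, 33, 33)."""
        return _softmax(self.forward_logits(np.asarray(x, dtype=np.float64), train=False))

    # -- dense path

    def dense_score_map(self, slice_input: np.ndarray) -> ScoreMap:
        """Score a full slice; ``slice_input`` is (C, H, W), C = in_channels.

        The fully connected layers are applied convolutionally (first fc
        as a valid convolution over the pooled feature map, the rest as
        1x1 convolutions), dropout off, yielding a stride-4 two-class
        probability map whose sample (i, j) is the patch-classifier
        output for the 33x33 window centred at (16 + 4i, 16 + 4j).
        """
        C, H, W = slice_input.shape
        if H < PATCH_SIZE or W < PATCH_SIZE:
            raise ValueError(f"slice {(H, W)} smaller than the receptive field")
        if C != self.spec.in_channels:
            raise ValueError(f"expected {self.spec.in_channels} channels, got {C}")
        x = slice_input[None].astype(np.float64)
        feats = [p.forward(xp, False) for p, xp in zip(self.pathways, self._split_inputs(x))]
        fmap = np.concatenate(feats, axis=1)[0]  # (C_total, h, w)
        s = self._feat_side
        view = np.lib.stride_tricks.sliding_window_view(fmap, (s, s), axis=(1, 2))
        cols = view.transpose(1, 2, 0, 3, 4).reshape(-1, fmap.shape[0] * s * s)
        ho, wo = view.shape[1], view.shape[2]
        h = cols
        for i, l in enumerate(self.fc.layers):
            if isinstance(l, _Dense):
                h = h @ l.W.T + l.b
            elif isinstance(l, _ReLU):
                h = np.maximum(h, 0)
            # dropout removed at test time
        probs = _softmax(h).reshape(ho, wo, 2)
        return ScoreMap(probs, stride=4, origin=(float(HALF), float(HALF)))


def build_network(spec: NetworkSpec, in_channels: int | None = None, seed: int = 0,
                  dropout_rate: float = 0.5) -> PatchCNN:
    """Instantiate a :class:`PatchCNN` from a spec with He initialization."""
    if in_channels is not None and in_channels != spec.in_channels:
        raise ValueError(
            f"fusion {spec.fusion!r} requires {spec.in_channels} input channels, "
            f"got {in_channels}"
        )
    return PatchCNN(spec, seed=seed, dropout_rate=dropout_rate)


# ---------------------------------------------------------------------------
# training


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class TrainHistory:
    epochs: list[int] = field(default_factory=list)
    lrs: list[float] = field(default_factory=list)
    losses: list[float] = field(default_factory=list)
    errors: list[float] = field(default_factory=list)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"epoch": self.epochs, "lr": self.lrs, "loss": self.losses, "error": self.errors}
        ).to_csv(path, index=False)


def train(model: PatchCNN, patches: PatchSet, config: TrainConfig) -> TrainHistory:
    """Mini-batch SGD on softmax cross-entropy with the log lr schedule.

    Returns the per-epoch loss/error curve.  Deterministic given
    ``config.seed`` (data order and dropout masks both derive from it).
    """
    x = patches.windows.astype(np.float64)
    y = patches.labels.astype(np.int64)
    classes = np.unique(y)
    if len(classes) < 2:
        warnings.warn("training set contains a single class; the classifier will be degenerate")
    rng = np.random.default_rng(config.seed)
    model._set_dropout_rng(rng)
    hist = TrainHistory()
    n = len(y)
    for epoch in range(1, config.epochs + 1):
        lr = lr_schedule(epoch, config)
        order = rng.permutation(n)
        losses, n_wrong = [], 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = x[idx], y[idx]
            logits = model.forward_logits(xb, train=True)
            p = _softmax(logits)
            batch_loss = -np.mean(np.log(np.maximum(p[np.arange(len(yb)), yb], 1e-12)))
            if not np.isfinite(batch_loss):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}, batch starting {start}; "
                    f"lr={lr:.2e}; aborting"
                )
            losses.append(batch_loss * len(yb))
            n_wrong += int((p.argmax(axis=1) != yb).sum())
            dlogits = p.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits /= len(yb)
            model._zero_grad()
            model.backward_from_logits(dlogits)
            model._sgd_step(lr, config.momentum)
        hist.epochs.append(epoch)
        hist.lrs.append(lr)
        hist.losses.append(float(np.sum(losses) / n))
        hist.errors.append(n_wrong / n)
    model._set_dropout_rng(None)
    return hist


# ---------------------------------------------------------------------------
# dense inference


def dense_inference(model: PatchCNN, volume: Volume) -> list[ScoreMap]:
    """Score every slice of a (normalized) volume with the dense network.

    Fusion models receive each slice with its (z-1, z, z+1) context,
    edge slices replicated.
    """
    vox = volume.voxels.astype(np.float64)
    ns = vox.shape[0]
    maps = []
    for z in range(ns):
        if model.spec.in_channels == 3:
            zs = [min(max(z + dz, 0), ns - 1) for dz in (-1, 0, 1)]
            inp = np.stack([vox[zz] for zz in zs])
        else:
            inp = vox[z][None]
        maps.append(model.dense_score_map(inp))
    return maps


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: PatchCNN, path, extra: dict | None = None) -> None:
    """Save weights + spec (+ arbitrary JSON-serializable metadata)."""
    arrays = {}
    for i, (w, _) in enumerate(model._all_params()):
        arrays[f"p{i}"] = w
    meta = {
        "spec": {
            "variant": model.spec.variant,
            "fusion": model.spec.fusion,
            "conv_blocks": model.spec.conv_blocks,
            "fc_sizes": list(model.spec.fc_sizes),
        },
        "seed": model.seed,
        "extra": extra or {},
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[PatchCNN, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        spec = NetworkSpec(
            meta["spec"]["variant"],
            meta["spec"]["fusion"],
            meta["spec"]["conv_blocks"],
            tuple(meta["spec"]["fc_sizes"]),
        )
        model = PatchCNN(spec, seed=meta["seed"])
        for i, (w, _) in enumerate(model._all_params()):
            w[:] = data[f"p{i}"]
    return model, meta["extra"]
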