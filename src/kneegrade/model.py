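"""The KL-grade classifier: adapter conv + DenseNet-121 + FC head.

Radiographs are single-channel, but ImageNet-style backbones expect three
channels, so the network opens with a learnable 3x3 convolution mapping
1 -> 3 channels (with ReLU), feeds DenseNet-121 (fully trainable — no
frozen layers), flattens the 7x7x1024 feature map and classifies through a
128/64/16 ReLU stack (L2-regularized, dropout 0.3 after each hidden
activation) into a 5-way softmax over KL grades.

Exact parameter accounting is a first-class output: :func:`summarize`
produces per-layer input/output shapes and trainable/non-trainable counts,
with batch-norm running statistics booked as non-trainable. For the
canonical DenseNet-121 backbone the totals are 13,469,571 parameters
(13,385,923 trainable + 83,648 non-trainable), of which the backbone
contributes 7,037,504 and the adapter conv 30.

A ``tiny`` backbone (stem conv + two small conv stages on a 4x-downsampled
input) is registered for desk-scale CPU training experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn

__all__ = [
    "HeadConfig", "LayerSummary", "ModelSummary", "BACKBONES",
    "conv2d_forward", "fc_forward", "build_backbone", "build_model",
    "KneeGradeModel", "summarize",
]

INPUT_SIZE = 224


@dataclass(frozen=True)
class HeadConfig:
    """Fully connected classification head hyperparameters."""

    fc_widths: tuple[int, ...] = (128, 64, 16)
    n_classes: int = 5
    l2_lambda: float = 1e-4
    dropout_rate: float = 0.3

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.fc_widths):
            raise ValueError("fc widths must be positive")
        if any(a <= b for a, b in zip(self.fc_widths, self.fc_widths[1:])):
            raise ValueError("fc widths must be strictly decreasing")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")


@dataclass(frozen=True)
class LayerSummary:
    name: str
    input_shape: tuple
    output_shape: tuple
    param_count: int
    trainable_count: int

    def __post_init__(self) -> None:
        if self.param_count < 0 or not 0 <= self.trainable_count <= self.param_count:
            raise ValueError("invalid parameter counts")


@dataclass
class ModelSummary:
    layers: list[LayerSummary] = field(default_factory=list)

    @property
    def total_params(self) -> int:
        return sum(l.param_count for l in self.layers)

    @property
    def trainable_params(self) -> int:
        return sum(l.trainable_count for l in self.layers)

    @property
    def non_trainable_params(self) -> int:
        return self.total_params - self.trainable_params

    def to_text(self) -> str:
        rows = [f"{'Layer':<28}{'Input shape':<20}{'Output shape':<20}{'Params':>12}"]
        for l in self.layers:
            rows.append(f"{l.name:<28}{str(l.input_shape):<20}{str(l.output_shape):<20}"
                        f"{l.param_count:>12,}")
        rows.append(f"Total parameters: {self.total_params:,}")
        rows.append(f"Trainable parameters: {self.trainable_params:,}")
        rows.append(f"Non-trainable parameters: {self.non_trainable_params:,}")
        return "\n".join(rows)


def conv2d_forward(x: np.ndarray, weight: np.ndarray, bias: float | np.ndarray = 0.0,
                   padding: str = "valid") -> np.ndarray:
    """Single-channel 2-D convolution, y[i,j] = sum_mn X[i+m, j+n] W[m,n] + b.

    ``x`` is a 2-D image patch, ``weight`` an (M, N) kernel; 'same' padding
    zero-pads symmetrically. Exposed as the scalar-channel reference form of
    the network's convolution stage.
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(weight, dtype=float)
    if x.ndim != 2 or w.ndim != 2:
        raise ValueError("conv2d_forward expects 2-D input and kernel")
    conv = nn.Conv2d(1, 1, w.shape[0], padding=padding, bias=True)
    if w.shape[0] != w.shape[1]:
        # non-square kernels handled by the direct loop (rare, reference only)
        m, n0 = w.shape
        if padding == "same":
            x = np.pad(x, ((m // 2, (m - 1) // 2), (n0 // 2, (n0 - 1) // 2)))
        if x.shape[0] < m or x.shape[1] < n0:
            raise ValueError("kernel larger than (padded) input")
        out = np.empty((x.shape[0] - m + 1, x.shape[1] - n0 + 1))
        for i in range(out.shape[0]):
            for j in range(out.shape[1]):
                out[i, j] = np.sum(x[i : i + m, j : j + n0] * w) + np.asarray(bias)
        return out
    conv.weight.value = w[:, :, None, None]
    conv.bias.value = np.atleast_1d(np.asarray(bias, dtype=float))
    y = conv.forward(x[None, :, :, None])
    return y[0, :, :, 0]


def fc_forward(x: np.ndarray, weight: np.ndarray, bias: np.ndarray,
               activation=None) -> np.ndarray:
    """Fully connected layer y = f(W x + b); ``activation`` may be None,
    'relu', 'softmax' or a callable."""
    x = np.asarray(x, dtype=float)
    w = np.asarray(weight, dtype=float)
    b = np.asarray(bias, dtype=float)
    if w.shape[1] != x.shape[-1]:
        raise ValueError(f"shape mismatch: W {w.shape} @ x {x.shape}")
    y = x @ w.T + b
    if activation is None:
        return y
    if activation == "relu":
        return np.maximum(y, 0.0)
    if activation == "softmax":
        return nn.softmax(y)
    return activation(y)


# ---------------------------------------------------------------------------
# Backbones

def _densenet(blocks: tuple[int, ...], growth: int, rng) -> nn.Sequential:
    layers: list[nn.Module] = [
        nn.Conv2d(3, 64, 7, stride=2, padding="same", bias=False, rng=rng),
        nn.BatchNorm2d(64), nn.ReLU(),
        nn.MaxPool2d(3, 2, padding="same"),
    ]
    ch = 64
    for i, n_layers in enumerate(blocks):
        block = nn.DenseBlock(ch, n_layers, growth, rng)
        layers.append(block)
        ch = block.out_ch
        if i < len(blocks) - 1:
            trans = nn.Transition(ch, rng)
            layers.append(trans)
            ch = trans.out_ch
    layers += [nn.BatchNorm2d(ch), nn.ReLU()]
    return nn.Sequential(layers)


def _tiny(rng) -> nn.Sequential:
    """Desk-scale CPU backbone: 2x input downsample, three BN-conv stages.

    The 2x (not deeper) downsample keeps the ~1-pixel joint gap of a severe
    knee resolvable; batch norm stabilizes small-batch CPU training.
    """
    return nn.Sequential([
        nn.AvgPool2d(2),
        nn.Conv2d(3, 16, 5, stride=2, padding="same", bias=False, rng=rng),
        nn.BatchNorm2d(16), nn.ReLU(),
        nn.MaxPool2d(2, 2),
        nn.Conv2d(16, 32, 3, padding="same", bias=False, rng=rng),
        nn.BatchNorm2d(32), nn.ReLU(),
        nn.MaxPool2d(2, 2),
        nn.Conv2d(32, 32, 3, padding="same", bias=False, rng=rng),
        nn.BatchNorm2d(32), nn.ReLU(),
        nn.MaxPool2d(2, 2),
    ])


BACKBONES = {
    "densenet121": lambda rng: _densenet((6, 12, 24, 16), 32, rng),
    "densenet201": lambda rng: _densenet((6, 12, 48, 32), 32, rng),
    "tiny": lambda rng: _tiny(rng),
}


def build_backbone(name: str, rng: np.random.Generator | None = None) -> nn.Sequential:
    """Instantiate a feature-extractor backbone by registry name.

    Weights are randomly initialized; loading pretrained weights is an
    optional runtime concern and never required here.
    """
    if name not in BACKBONES:
        raise ValueError(f"unknown backbone {name!r}; registry: {sorted(BACKBONES)}")
    return BACKBONES[name](rng or np.random.default_rng(0))


def _module_counts(mod: nn.Module) -> tuple[int, int]:
    total = sum(p.size for p in mod.params())
    trainable = sum(p.size for p in mod.params() if p.trainable)
    return total, trainable


class KneeGradeModel:
    """Adapter conv + backbone + flatten + FC head, with summary accounting."""

    def __init__(self, head: HeadConfig | None = None, backbone: str = "densenet121",
                 seed: int = 0):
        self.head_cfg = head or HeadConfig()
        self.backbone_name = backbone
        rng = np.random.default_rng(seed)
        self.adapter = nn.Conv2d(1, 3, 3, padding="same", bias=True, rng=rng)
        self.adapter_act = nn.ReLU()
        self.backbone = build_backbone(backbone, rng)

        feat_shape = self.backbone.out_shape((INPUT_SIZE, INPUT_SIZE, 3))
        flat_dim = int(np.prod(feat_shape))
        h = self.head_cfg
        head_layers: list[nn.Module] = [nn.Flatten()]
        in_dim = flat_dim
        for width in h.fc_widths:
            head_layers += [
                nn.Dense(in_dim, width, l2=h.l2_lambda, rng=rng),
                nn.ReLU(),
                nn.Dropout(h.dropout_rate, rng=np.random.default_rng(rng.integers(2**31))),
            ]
            in_dim = width
        head_layers.append(nn.Dense(in_dim, h.n_classes, l2=h.l2_lambda, rng=rng))
        self.head = nn.Sequential(head_layers)
        self.net = nn.Sequential([self.adapter, self.adapter_act, self.backbone, self.head])
        self._feat_shape = feat_shape

    # -- inference ---------------------------------------------------------
    def logits(self, x: np.ndarray) -> np.ndarray:
        """Forward pass; ``x`` is (N, 224, 224) or (N, 224, 224, 1) in [0,1]."""
        x = np.asarray(x, dtype=float)
        if x.ndim == 3:
            x = x[..., None]
        return self.net.forward(x)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return nn.softmax(self.logits(x))

    def params(self) -> list[nn.Param]:
        return self.net.params()

    def set_training(self, flag: bool) -> None:
        self.net.set_training(flag)

    # -- accounting --------------------------------------------------------
    def summary(self) -> ModelSummary:
        s = ModelSummary()
        size = (INPUT_SIZE, INPUT_SIZE, 1)
        s.layers.append(LayerSummary("Input layer", size, size, 0, 0))

        conv_out = self.adapter.out_shape(size)
        t, tr = _module_counts(self.adapter)
        s.layers.append(LayerSummary("Convolutional layer", size, conv_out, t, tr))

        t, tr = _module_counts(self.backbone)
        s.layers.append(LayerSummary(f"{self.backbone_name} (BaseNet)",
                                     conv_out, self._feat_shape, t, tr))

        flat = (int(np.prod(self._feat_shape)),)
        s.layers.append(LayerSummary("Flatten", self._feat_shape, flat, 0, 0))
        in_shape = flat
        fc_idx = 0
        for layer in self.head.layers:
            if isinstance(layer, nn.Dense):
                fc_idx += 1
                out_shape = layer.out_shape(in_shape)
                t, tr = _module_counts(layer)
                s.layers.append(LayerSummary(f"FC_{fc_idx}", in_shape, out_shape, t, tr))
                in_shape = out_shape
            elif isinstance(layer, nn.ReLU):
                s.layers.append(LayerSummary("Activation (ReLU)", in_shape, in_shape, 0, 0))
        out = (self.head_cfg.n_classes,)
        s.layers.append(LayerSummary("Activation (SoftMax)", out, out, 0, 0))

        total, trainable = _module_counts(self.net)
        assert s.total_params == total and s.trainable_params == trainable
        return s


def build_model(head: HeadConfig | None = None, backbone: str = "densenet121",
                seed: int = 0) -> tuple[KneeGradeModel, ModelSummary]:
    """Construct the classifier and its layer-by-layer parameter summary."""
    model = KneeGradeModel(head=head, backbone=backbone, seed=seed)
    return model, model.summary()


def summarize(backbone: str = "densenet121") -> ModelSummary:
    return build_model(backbone=backbone)[1]


def save_weights(model: KneeGradeModel, path) -> None:
    """Persist all parameters (trainable and running statistics) as .npz."""
    arrays = {f"p{i}": p.value for i, p in enumerate(model.params())}
    arrays["_meta"] = np.array([model.head_cfg.n_classes])
    np.savez_compressed(path, backbone=np.array(model.backbone_name), **arrays)


def load_model(path, head: HeadConfig | None = None) -> KneeGradeModel:
    with np.load(path, allow_pickle=False) as data:
        backbone = str(data["backbone"])
        model = KneeGradeModel(head=head, backbone=backbone)
        params = model.params()
        for i, p in enumerate(params):
            stored = data[f"p{i}"]
            if stored.shape != p.value.shape:
                raise ValueError(f"weight {i} shape {stored.shape} != {p.value.shape}")
            p.value[...] = stored
    return model
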