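"""3D DenseNet-40 for binary NTCP classification of mandible dose maps.

The network follows the shallow DenseNet recipe: an initial 3x3x3
convolution, three dense blocks of 12 densely-connected layers each
(BN -> ReLU -> 3x3x3 conv -> dropout, growth rate 32), two transition
blocks (BN -> ReLU -> 1x1x1 conv halving the channel count -> 2x2x2
average pooling), a final BN/ReLU, and global average pooling.  With the
default widths this yields a 688-long image feature vector.

Two heads are provided:

- ``dose``: a single fully connected layer to 2 classes (softmax);
- ``fusion``: the 688 image features are concatenated with the 6 clinical
  covariates into a 694-long vector, passed through a 64-unit hidden layer
  and a 2-class output (joint fusion — the clinical branch trains end to
  end with the convolutional trunk).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from dosemap_ntcp.nn import layers as L


@dataclass(frozen=True)
class ArchitectureConfig:
    """Widths and depths of the DenseNet-40 trunk and fusion head.

    Defaults reproduce the published feature dimensions (688 image features,
    694 fused).  ``layers_per_block`` may be shortened/narrowed for
    desk-scale training runs.
    """

    initial_channels: int = 64
    growth_rate: int = 32
    layers_per_block: tuple[int, ...] = (12, 12, 12)
    compression: float = 0.5
    dropout: float = 0.0
    n_clinical: int = 6
    fusion_hidden: int = 64
    n_classes: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.compression <= 1:
            raise ValueError("compression must be in (0, 1]")
        if any(l < 1 for l in self.layers_per_block):
            raise ValueError("every dense block needs at least one layer")


def feature_dimension(config: ArchitectureConfig) -> int:
    """Channel count after the last dense block (= flattened feature length).

    Channels grow by ``growth_rate`` per dense layer and are floor-compressed
    after each transition; global average pooling preserves the count.
    """
    c = config.initial_channels
    for i, n_layers in enumerate(config.layers_per_block):
        c += n_layers * config.growth_rate
        if i < len(config.layers_per_block) - 1:
            c = math.floor(c * config.compression)
    return c


def fused_dimension(config: ArchitectureConfig) -> int:
    """Length of the concatenated image + clinical feature vector."""
    return feature_dimension(config) + config.n_clinical


def parameter_count(config: ArchitectureConfig, modality: str = "dose") -> int:
    """Trainable parameter count from the architecture arithmetic alone."""
    g = config.growth_rate
    count = 1 * config.initial_channels * 27 + config.initial_channels
    c = config.initial_channels
    for i, n_layers in enumerate(config.layers_per_block):
        for _ in range(n_layers):
            count += 2 * c  # BN gamma/beta
            count += c * g * 27 + g
            c += g
        if i < len(config.layers_per_block) - 1:
            out = math.floor(c * config.compression)
            count += 2 * c + c * out + out
            c = out
    count += 2 * c  # final BN
    if modality == "dose":
        count += c * config.n_classes + config.n_classes
    else:
        f = c + config.n_clinical
        count += f * config.fusion_hidden + config.fusion_hidden
        count += config.fusion_hidden * config.n_classes + config.n_classes
    return count


class _DenseLayer:
    """BN -> ReLU -> 3x3x3 conv(growth) -> dropout, concatenated to its input."""

    def __init__(self, in_channels: int, growth: int, dropout: float, rng) -> None:
        self.in_channels = in_channels
        self.bn = L.BatchNorm3d(in_channels)
        self.relu = L.ReLU()
        self.conv = L.Conv3d(in_channels, growth, 3, rng)
        self.drop = L.Dropout(dropout, rng)

    def forward(self, x, train=False):
        h = self.bn.forward(x, train)
        h = self.relu.forward(h, train)
        h = self.conv.forward(h, train)
        h = self.drop.forward(h, train)
        return np.concatenate([x, h], axis=1)

    def backward(self, grad):
        gx = grad[:, : self.in_channels].copy()
        gh = grad[:, self.in_channels :]
        gh = self.drop.backward(gh)
        gh = self.conv.backward(gh)
        gh = self.relu.backward(gh)
        gh = self.bn.backward(gh)
        return gx + gh

    def sublayers(self):
        return [self.bn, self.conv]


class _Transition:
    """BN -> ReLU -> 1x1x1 conv (channel compression) -> 2x2x2 average pool."""

    def __init__(self, in_channels: int, out_channels: int, rng) -> None:
        self.bn = L.BatchNorm3d(in_channels)
        self.relu = L.ReLU()
        self.conv = L.Conv3d(in_channels, out_channels, 1, rng)
        self.pool = L.AvgPool3d()

    def forward(self, x, train=False):
        h = self.bn.forward(x, train)
        h = self.relu.forward(h, train)
        h = self.conv.forward(h, train)
        return self.pool.forward(h, train)

    def backward(self, grad):
        g = self.pool.backward(grad)
        g = self.conv.backward(g)
        g = self.relu.backward(g)
        return self.bn.backward(g)

    def sublayers(self):
        return [self.bn, self.conv]


class IncompatibleInputShapeError(ValueError):
    pass


class DenseNet3D:
    """The assembled classifier; ``modality`` is 'dose' or 'fusion'."""

    def __init__(
        self,
        config: ArchitectureConfig = ArchitectureConfig(),
        modality: str = "dose",
        seed: int = 0,
    ) -> None:
        if modality not in ("dose", "fusion"):
            raise ValueError("modality must be 'dose' or 'fusion'")
        self.config = config
        self.modality = modality
        self.seed = seed
        rng = np.random.default_rng(seed)

        self.initial = L.Conv3d(1, config.initial_channels, 3, rng)
        c = config.initial_channels
        self.blocks: list[list[_DenseLayer]] = []
        self.transitions: list[_Transition] = []
        for i, n_layers in enumerate(config.layers_per_block):
            block = []
            for _ in range(n_layers):
                block.append(_DenseLayer(c, config.growth_rate, config.dropout, rng))
                c += config.growth_rate
            self.blocks.append(block)
            if i < len(config.layers_per_block) - 1:
                out = math.floor(c * config.compression)
                self.transitions.append(_Transition(c, out, rng))
                c = out
        self.final_bn = L.BatchNorm3d(c)
        self.final_relu = L.ReLU()
        self.gap = L.GlobalAvgPool3d()
        self.feature_length = c

        if modality == "dose":
            self.fc = L.Linear(c, config.n_classes, rng)
            self.fc_hidden = None
        else:
            self.fc_hidden = L.Linear(c + config.n_clinical, config.fusion_hidden, rng)
            self.head_relu = L.ReLU()
            self.fc = L.Linear(config.fusion_hidden, config.n_classes, rng)

    # ------------------------------------------------------------------ plumbing

    def set_dropout(self, p: float) -> None:
        for block in self.blocks:
            for layer in block:
                layer.drop.p = p

    def all_layers(self):
        out = [self.initial]
        n_pools = len(self.transitions)
        for i, block in enumerate(self.blocks):
            for lay in block:
                out.extend(lay.sublayers())
            if i < n_pools:
                out.extend(self.transitions[i].sublayers())
        out.append(self.final_bn)
        if self.fc_hidden is not None:
            out.append(self.fc_hidden)
        out.append(self.fc)
        return out

    def n_parameters(self) -> int:
        return sum(lay.n_parameters() for lay in self.all_layers())

    def _check_shape(self, x: np.ndarray) -> None:
        n_pools = len(self.transitions)
        div = 2**n_pools
        spatial = x.shape[2:]
        if x.ndim != 5 or x.shape[1] != 1:
            raise IncompatibleInputShapeError(
                "expected a (batch, 1, D, H, W) dose-map array"
            )
        if any(s < div or s % div for s in spatial):
            raise IncompatibleInputShapeError(
                f"spatial dims {spatial} must be multiples of {div}; "
                f"minimal valid shape is {(div,) * 3}"
            )

    # ------------------------------------------------------------------ passes

    def forward(
        self, x: np.ndarray, clinical: np.ndarray | None = None, train: bool = False
    ) -> np.ndarray:
        """Logits of shape (batch, 2)."""
        self._check_shape(x)
        h = self.initial.forward(x, train)
        for i, block in enumerate(self.blocks):
            for lay in block:
                h = lay.forward(h, train)
            if i < len(self.transitions):
                h = self.transitions[i].forward(h, train)
        h = self.final_bn.forward(h, train)
        h = self.final_relu.forward(h, train)
        feats = self.gap.forward(h, train)  # (N, feature_length)
        if self.modality == "dose":
            return self.fc.forward(feats, train)
        if clinical is None or clinical.shape != (x.shape[0], self.config.n_clinical):
            raise ValueError(
                f"joint fusion requires a (batch, {self.config.n_clinical}) clinical array"
            )
        fused = np.concatenate([feats, clinical], axis=1)
        h = self.fc_hidden.forward(fused, train)
        h = self.head_relu.forward(h, train)
        return self.fc.forward(h, train)

    def backward(self, grad_logits: np.ndarray) -> None:
        g = self.fc.backward(grad_logits)
        if self.modality == "fusion":
            g = self.head_relu.backward(g)
            g = self.fc_hidden.backward(g)
            g = g[:, : self.feature_length]  # clinical inputs carry no gradient
        g = self.gap.backward(g)
        g = self.final_relu.backward(g)
        g = self.final_bn.backward(g)
        for i in range(len(self.blocks) - 1, -1, -1):
            if i < len(self.transitions):
                g = self.transitions[i].backward(g)
            for lay in reversed(self.blocks[i]):
                g = lay.backward(g)
        self.initial.backward(g)

    def predict_proba(
        self,
        x: np.ndarray,
        clinical: np.ndarray | None = None,
        batch_size: int = 16,
    ) -> np.ndarray:
        """Softmax class probabilities, (N, 2), deterministic (eval mode)."""
        out = []
        for i in range(0, x.shape[0], batch_size):
            cl = None if clinical is None else clinical[i : i + batch_size]
            out.append(L.softmax(self.forward(x[i : i + batch_size], cl, train=False)))
        return np.concatenate(out, axis=0)

    # ------------------------------------------------------------------ persistence

    def state_arrays(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, lay in enumerate(self.all_layers()):
            for name, p in lay._params.items():
                state[f"layer{i}:{name}"] = p
            if isinstance(lay, L.BatchNorm3d):
                state[f"layer{i}:running_mean"] = lay.running_mean
                state[f"layer{i}:running_var"] = lay.running_var
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, lay in enumerate(self.all_layers()):
            for name in lay._params:
                lay._params[name][...] = state[f"layer{i}:{name}"]
            if isinstance(lay, L.BatchNorm3d):
                lay.running_mean = np.array(state[f"layer{i}:running_mean"])
                lay.running_var = np.array(state[f"layer{i}:running_var"])


def build_dose_only(
    config: ArchitectureConfig = ArchitectureConfig(), seed: int = 0
) -> DenseNet3D:
    """Single-modality classifier on dose maps only (3D-DN40)."""
    return DenseNet3D(config, modality="dose", seed=seed)


def build_joint_fusion(
    config: ArchitectureConfig = ArchitectureConfig(), seed: int = 0
) -> DenseNet3D:
    """Joint-fusion classifier on dose maps + 6 clinical covariates (3D-mDN40)."""
    if config.n_clinical != 6:
        raise ValueError("the joint-fusion model expects exactly 6 clinical covariates")
    return DenseNet3D(config, modality="fusion", seed=seed)
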