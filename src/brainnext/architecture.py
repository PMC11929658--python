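"""BrainNeXt network construction and summarisation.

The network is a ConvNeXt-style lightweight CNN: a patchifying stem (4x4
convolution, stride 4), four stages of inverted-bottleneck blocks with
depthwise 7x7 convolutions, batch normalisation and leaky-ReLU activations,
max-pool + 1x1-conv depth-concatenation units between stages that halve the
spatial size and double the channel width, and a global-average-pooling +
fully-connected + softmax head.

Two block variants are provided.  The default ``split`` variant splits the
input channels in half, passes one half through untouched, runs the other
half through the bottleneck and depth-concatenates — this is the
channel-economical design that keeps the default four-class network under
ten million trainable parameters.  The ``literal`` variant is the full-width
inverted bottleneck with an additive skip, which is several times heavier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from brainnext.errors import ConfigurationError
from brainnext.nn import (
    BatchNorm2d,
    CompressionUnit,
    Conv2d,
    GlobalAvgPool,
    LeakyReLU,
    Linear,
    Residual,
    Sequential,
    SplitBlock,
    softmax,
)


@dataclass
class ArchSpec:
    """Declarative description of a BrainNeXt variant.

    ``stage_depths``/``stage_widths`` give the number of blocks and channel
    width per stage; ``expansion_factor`` is the hidden-width multiplier of
    the 1x1 expansion inside each block; the stem is a ``stem_kernel`` x
    ``stem_kernel`` convolution with stride ``stem_stride``.
    """

    stage_depths: list[int] = field(default_factory=lambda: [2, 2, 6, 2])
    stage_widths: list[int] = field(default_factory=lambda: [96, 192, 384, 768])
    expansion_factor: int = 4
    stem_kernel: int = 4
    stem_stride: int = 4
    dw_kernel: int = 7
    pool_kernel: int = 3
    pool_stride: int = 2
    leaky_slope: float = 0.1
    block_variant: str = "split"
    num_classes: int = 4
    input_size: int = 224
    seed: int = 0

    def validate(self) -> None:
        if len(self.stage_depths) != len(self.stage_widths):
            raise ConfigurationError(
                "stage_depths and stage_widths must have the same length")
        if any(d < 1 for d in self.stage_depths):
            raise ConfigurationError("stage_depths entries must be >= 1")
        if self.expansion_factor < 1:
            raise ConfigurationError("expansion_factor must be >= 1")
        if any(b >= a for a, b in zip(self.stage_widths[1:], self.stage_widths)):
            raise ConfigurationError("stage_widths must be strictly increasing")
        if self.num_classes < 2:
            raise ConfigurationError("num_classes must be >= 2")
        if self.block_variant not in ("split", "literal"):
            raise ConfigurationError(
                f"unknown block_variant {self.block_variant!r}")
        if self.block_variant == "split" and any(w % 2 for w in self.stage_widths):
            raise ConfigurationError(
                "split block variant requires even stage widths")
        n_comp = max(len(self.stage_widths) - 1, 0)
        divisor = self.stem_stride * self.pool_stride ** n_comp
        if self.input_size % divisor:
            raise ConfigurationError(
                f"input_size {self.input_size} must be divisible by "
                f"stem_stride * pool_stride^{n_comp} = {divisor}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ArchSpec":
        spec = cls(**d)
        spec.validate()
        return spec

    def to_toml(self, path: str | Path) -> None:
        lines = ["[architecture]"]
        for k, v in self.to_dict().items():
            if isinstance(v, list):
                lines.append(f"{k} = {json.dumps(v)}")
            elif isinstance(v, str):
                lines.append(f'{k} = "{v}"')
            else:
                lines.append(f"{k} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_toml(cls, path: str | Path) -> "ArchSpec":
        import tomllib
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls.from_dict(data.get("architecture", data))


@dataclass
class LayerRecord:
    name: str
    out_size: int          # spatial side length
    out_channels: int
    params: int


@dataclass
class NetworkSummary:
    layers: list[LayerRecord]
    total_params: int

    def to_json(self) -> str:
        return json.dumps({
            "layers": [asdict(r) for r in self.layers],
            "total_params": self.total_params,
        }, indent=2)

    def to_text(self) -> str:
        w = max(len(r.name) for r in self.layers) + 2
        lines = [f"{'layer':<{w}}{'out size':>10}{'channels':>10}{'params':>12}"]
        for r in self.layers:
            lines.append(f"{r.name:<{w}}{r.out_size:>10}{r.out_channels:>10}"
                         f"{r.params:>12}")
        lines.append(f"{'total':<{w}}{'':>10}{'':>10}{self.total_params:>12}")
        return "\n".join(lines)


def _bottleneck_branch(width: int, expansion: int, dw_kernel: int,
                       slope: float, rng: np.random.Generator,
                       name: str) -> Sequential:
    """Depthwise 7x7 -> BN -> 1x1 expand -> BN -> leaky ReLU -> 1x1 project
    -> BN, at the given channel width."""
    hidden = width * expansion
    pad = dw_kernel // 2
    return Sequential([
        Conv2d(width, width, dw_kernel, stride=1, pad=pad, groups=width,
               rng=rng, name=f"{name}.dw"),
        BatchNorm2d(width, name=f"{name}.bn1"),
        Conv2d(width, hidden, 1, rng=rng, name=f"{name}.expand"),
        BatchNorm2d(hidden, name=f"{name}.bn2"),
        LeakyReLU(slope),
        Conv2d(hidden, width, 1, rng=rng, name=f"{name}.project"),
        BatchNorm2d(width, name=f"{name}.bn3"),
    ])


class BrainNeXt:
    """A built network: ``features`` (stem + stages + compressions), ``gap``
    and ``fc`` head.  ``forward`` returns logits; ``predict_proba`` applies
    softmax."""

    def __init__(self, spec: ArchSpec):
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        widths = spec.stage_widths
        feats: list = [
            Conv2d(3, widths[0], spec.stem_kernel, stride=spec.stem_stride,
                   rng=rng, name="stem.conv"),
            BatchNorm2d(widths[0], name="stem.bn"),
            LeakyReLU(spec.leaky_slope),
        ]
        self._stage_slices: list[tuple[str, int, int]] = [("stem", 0, 3)]
        for si, (depth, width) in enumerate(zip(spec.stage_depths, widths)):
            start = len(feats)
            for bi in range(depth):
                nm = f"stage{si + 1}.block{bi + 1}"
                if spec.block_variant == "split":
                    half = width // 2
                    branch = _bottleneck_branch(half, spec.expansion_factor,
                                                spec.dw_kernel,
                                                spec.leaky_slope, rng, nm)
                    feats.append(SplitBlock(branch, half))
                else:
                    branch = _bottleneck_branch(width, spec.expansion_factor,
                                                spec.dw_kernel,
                                                spec.leaky_slope, rng, nm)
                    feats.append(Residual(branch))
            self._stage_slices.append((f"stage{si + 1}", start, len(feats)))
            if si < len(widths) - 1:
                start = len(feats)
                feats.append(CompressionUnit(width, rng,
                                             name=f"compress{si + 1}"))
                self._stage_slices.append((f"compress{si + 1}", start,
                                           len(feats)))
        self.features = Sequential(feats, name="features")
        self.gap = GlobalAvgPool()
        self.fc = Linear(widths[-1], spec.num_classes, rng=rng, name="head.fc")
        self._last_feature_map: np.ndarray | None = None

    # ---- inference / training interface ------------------------------------
    def forward_features(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        fmap = self.features.forward(x, train=train)
        self._last_feature_map = fmap
        return fmap

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        fmap = self.forward_features(x, train=train)
        return self.fc.forward(self.gap.forward(fmap, train=train), train=train)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        dpool = self.fc.backward(dlogits)
        dfmap = self.gap.backward(dpool)
        return self.features.backward(dfmap)

    def backward_head(self, dlogits: np.ndarray) -> np.ndarray:
        """Backpropagate only through the head, returning the gradient at the
        final feature map (used by Grad-CAM)."""
        return self.gap.backward(self.fc.backward(dlogits))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, train=False))

    def params(self):
        return self.features.params() + self.fc.params()

    def total_params(self) -> int:
        return sum(p.size for p in self.params())

    def feature_length(self) -> int:
        return self.spec.stage_widths[-1]

    # ---- persistence -------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param.{i}.{p.name}": p.data
                 for i, p in enumerate(self.params())}
        for i, (name, buf) in enumerate(self.features.buffers()):
            state[f"buffer.{i}.{name}"] = buf
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            key = f"param.{i}.{p.name}"
            if state[key].shape != p.data.shape:
                raise ConfigurationError(f"shape mismatch for {key}")
            p.data[:] = state[key]
        for i, (name, buf) in enumerate(self.features.buffers()):
            buf[:] = state[f"buffer.{i}.{name}"]

    def save(self, path: str | Path) -> None:
        np.savez(path, **self.state_dict(),
                 __spec__=json.dumps(self.spec.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "BrainNeXt":
        with np.load(path, allow_pickle=False) as data:
            spec = ArchSpec.from_dict(json.loads(str(data["__spec__"])))
            net = cls(spec)
            net.load_state_dict({k: data[k] for k in data.files
                                 if k != "__spec__"})
        return net


def build_brainnext(spec: ArchSpec | None = None) -> BrainNeXt:
    """Build a BrainNeXt network from a declarative spec (default variant if
    none is given)."""
    return BrainNeXt(spec or ArchSpec())


def summarize(net: BrainNeXt) -> NetworkSummary:
    """Per-layer symbolic shape trace and parameter accounting.

    Spatial sizes are computed with floor-arithmetic convolution/pool
    formulas; no data is run through the network.  ``total_params`` equals
    the sum over layer records, which equals the framework parameter count.
    """
    shape = (3, net.spec.input_size, net.spec.input_size)
    records: list[LayerRecord] = []
    for name, start, stop in net._stage_slices:
        sub = Sequential(net.features.layers[start:stop])
        shape = sub.out_shape(shape)
        records.append(LayerRecord(name, shape[1], shape[0], sub.param_count()))
    shape = net.gap.out_shape(shape)
    records.append(LayerRecord("gap", shape[1], shape[0], 0))
    records.append(LayerRecord("fc", 1, net.spec.num_classes,
                               net.fc.param_count()))
    total = sum(r.params for r in records)
    assert total == net.total_params()
    return NetworkSummary(records, total)


def final_map_side(spec: ArchSpec) -> int:
    """Side length of the feature map entering global average pooling."""
    net_shape = (3, spec.input_size, spec.input_size)
    net = build_brainnext(spec)
    return net.features.out_shape(net_shape)[1]
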