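"""Lightweight Inception-ResNet seed classifier and its parameter accounting.

The network replaces every spatial (>= 3x3) convolution of an
Inception-ResNet block with a depthwise-separable convolution, gates each
stage with efficient channel attention (ECA), and fuses globally pooled
features from the low, middle and high stages before the softmax head.

Parameter arithmetic for the separable replacement: a standard convolution
with an H x W kernel over C input and N output channels carries
``H*W*C*N`` weights; its separable counterpart carries ``H*W*C`` depthwise
plus ``C*N`` pointwise weights, a ratio of exactly ``1/N + 1/(H*W)``.
:func:`count_separable_params` / :func:`param_ratio` compute these exactly,
and :func:`param_report` reconciles them against the weights of the built
network layer by layer.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .synthgen import CLASSES

# ---------------------------------------------------------------------------
# parameter accounting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConvSpec:
    """Geometry of one convolution: H x W kernel, C in / N out channels."""

    H: int
    W: int
    C: int
    N: int

    def __post_init__(self) -> None:
        if min(self.H, self.W, self.C, self.N) < 1:
            raise ValueError("all ConvSpec fields must be >= 1")


def count_standard_params(spec: ConvSpec) -> int:
    """Weight count of the ordinary convolution: H*W*C*N."""
    return spec.H * spec.W * spec.C * spec.N


def count_separable_params(spec: ConvSpec) -> int:
    """Weight count of the depthwise-separable factorisation: H*W*C + C*N.

    One depthwise H x W kernel per input channel plus N pointwise 1x1xC
    kernels; biases and normalisation are excluded on both sides.
    """
    return spec.H * spec.W * spec.C + spec.C * spec.N


def param_ratio(spec: ConvSpec) -> Fraction:
    """Exact separable / standard weight ratio, equal to 1/N + 1/(H*W).

    For 1x1 kernels with N = 1 the ratio exceeds one — the factorisation
    costs *more* there — which is reported as-is rather than clamped.
    """
    return Fraction(count_separable_params(spec), count_standard_params(spec))


@dataclass(frozen=True)
class ParamReport:
    """Standard vs. separable weight counts for one convolution geometry."""

    standard_params: int
    separable_params: int
    ratio: Fraction

    @staticmethod
    def from_spec(spec: ConvSpec) -> "ParamReport":
        return ParamReport(
            standard_params=count_standard_params(spec),
            separable_params=count_separable_params(spec),
            ratio=param_ratio(spec),
        )


# ---------------------------------------------------------------------------
# efficient channel attention
# ---------------------------------------------------------------------------


def eca_kernel_size(C: int, gamma: int = 2, b: int = 1) -> int:
    """Adaptive 1-D kernel size for ECA over ``C`` channels.

    ``k`` is the odd integer nearest to ``|log2(C)/gamma + b/gamma|``
    (ties resolved downward), floored at 1, so wider feature maps get a
    wider cross-channel interaction window.
    """
    if C < 1:
        raise ValueError("C must be >= 1")
    t = abs(math.log2(C) / gamma + b / gamma)
    lo = 2 * math.floor((t + 1) / 2) - 1
    hi = lo + 2
    k = lo if (t - lo) <= (hi - t) else hi
    return max(1, k)


@dataclass(frozen=True)
class ECAConfig:
    channels: int
    gamma: int = 2
    b: int = 1
    kernel_size: int | None = None

    def __post_init__(self) -> None:
        if self.channels < 1:
            raise ValueError("channels must be >= 1")
        if self.gamma < 1:
            raise ValueError("gamma must be a positive integer")
        k = self.resolved_kernel_size
        if k < 1 or k % 2 == 0:
            raise ValueError("kernel_size must be odd and >= 1")

    @property
    def resolved_kernel_size(self) -> int:
        if self.kernel_size is not None:
            return self.kernel_size
        return eca_kernel_size(self.channels, self.gamma, self.b)


def make_eca(config: ECAConfig) -> nn.ECA:
    return nn.ECA(config.channels, config.resolved_kernel_size)


def apply_eca(
    features: np.ndarray, config: ECAConfig, weights: np.ndarray | None = None
) -> np.ndarray:
    """Reweight a feature map channel-by-channel with an ECA gate.

    Accepts a single ``(H, W, C)`` map or an ``(N, C, H, W)`` batch and
    returns the same shape.  ``weights`` optionally overrides the 1-D
    convolution kernel (length ``k``).
    """
    layer = make_eca(config)
    if weights is not None:
        weights = np.asarray(weights, dtype=np.float32)
        if weights.shape != layer.weight.value.shape:
            raise ValueError(f"expected {layer.weight.value.shape} weights")
        layer.weight.value = weights
    if features.ndim == 3:  # H, W, C -> 1, C, H, W
        x = np.ascontiguousarray(features.transpose(2, 0, 1))[None].astype(np.float32)
        y = layer.forward(x)
        return y[0].transpose(1, 2, 0)
    if features.ndim == 4:
        return layer.forward(features.astype(np.float32))
    raise ValueError("features must be (H, W, C) or (N, C, H, W)")


# ---------------------------------------------------------------------------
# Inception-ResNet block with separable convolutions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModuleConfig:
    """Branch widths of one block.

    Branches: 1x1; 1x1 -> 3x3; 1x1 -> 3x3 -> 3x3 (a 5x5 receptive field
    split into two stacked 3x3); 3x3 average pool -> 1x1.  The two- and
    three-conv branches are (reduce, out) channel pairs.  The concatenated
    width must equal ``in_channels`` unless ``residual_projection`` adds a
    1x1 projection on the skip path.
    """

    in_channels: int
    branch1: int
    branch2: tuple[int, int]
    branch3: tuple[int, int]
    branch_pool: int
    residual_projection: bool = False
    activation: str = "relu"

    @property
    def out_channels(self) -> int:
        return self.branch1 + self.branch2[1] + self.branch3[1] + self.branch_pool

    def __post_init__(self) -> None:
        if self.activation != "relu":
            raise ValueError("only relu activation is supported")
        if self.out_channels != self.in_channels and not self.residual_projection:
            raise ValueError(
                f"branch widths sum to {self.out_channels} != in_channels "
                f"{self.in_channels}; set residual_projection"
            )

    @staticmethod
    def default(width: int) -> "ModuleConfig":
        """Equal-width branches summing to ``width`` (width divisible by 4)."""
        if width % 4 or width < 8:
            raise ValueError("default branch layout needs width divisible by 4, >= 8")
        q = width // 4
        return ModuleConfig(
            in_channels=width,
            branch1=q,
            branch2=(q, q),
            branch3=(q, q),
            branch_pool=q,
        )


def _conv_bn_relu(c_in: int, c_out: int, rng: np.random.Generator) -> list[nn.Layer]:
    return [
        nn.Conv2d(c_in, c_out, kernel=1, bias=False, rng=rng),
        nn.BatchNorm2d(c_out),
        nn.ReLU(),
    ]


def _sep_bn_relu(c_in: int, c_out: int, rng: np.random.Generator, stride: int = 1) -> list[nn.Layer]:
    return [
        *nn.separable_conv(c_in, c_out, kernel=3, stride=stride, rng=rng).layers,
        nn.BatchNorm2d(c_out),
        nn.ReLU(),
    ]


class DinceptionResNetBlock(nn.Layer):
    """Four Inception branches, channel concat, residual add, ReLU.

    All spatial convolutions are depthwise-separable; the 5x5 receptive
    field is realised as two stacked 3x3 separable convolutions.  The skip
    path is the identity when the concatenated width equals the input
    width, else a 1x1 projection with batch norm.
    """

    def __init__(self, config: ModuleConfig, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.config = config
        c = config.in_channels
        r2, w2 = config.branch2
        r3, w3 = config.branch3
        self.branches = [
            nn.Sequential(*_conv_bn_relu(c, config.branch1, rng)),
            nn.Sequential(*_conv_bn_relu(c, r2, rng), *_sep_bn_relu(r2, w2, rng)),
            nn.Sequential(
                *_conv_bn_relu(c, r3, rng),
                *_sep_bn_relu(r3, r3, rng),
                *_sep_bn_relu(r3, w3, rng),
            ),
            nn.Sequential(nn.AvgPool2d(3), *_conv_bn_relu(c, config.branch_pool, rng)),
        ]
        self.skip: nn.Sequential | None = None
        if config.residual_projection:
            self.skip = nn.Sequential(
                nn.Conv2d(c, config.out_channels, kernel=1, bias=False, rng=rng),
                nn.BatchNorm2d(config.out_channels),
            )
        self._splits = [config.branch1, w2, w3, config.branch_pool]
        self._mask: np.ndarray | None = None

    def params(self) -> list[nn.Param]:
        out = [p for b in self.branches for p in b.params()]
        if self.skip is not None:
            out += self.skip.params()
        return out

    def named_children(self) -> list[tuple[str, nn.Layer]]:
        out = [(f"branch{i + 1}", b) for i, b in enumerate(self.branches)]
        if self.skip is not None:
            out.append(("skip", self.skip))
        return out

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        outs = [b.forward(x, training=training) for b in self.branches]
        cat = np.concatenate(outs, axis=1)
        res = self.skip.forward(x, training=training) if self.skip is not None else x
        pre = cat + res
        if training:
            self._mask = pre > 0
        return np.maximum(pre, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._mask is not None
        dpre = dy * self._mask
        dx = self.skip.backward(dpre) if self.skip is not None else dpre.copy()
        start = 0
        for b, width in zip(self.branches, self._splits):
            dx += b.backward(dpre[:, start : start + width])
            start += width
        return dx


# ---------------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelConfig:
    """Classifier layout: stem, three stages of blocks, ECA, fused head.

    ``stages`` lists (modules_per_stage, width) for the low / middle / high
    stages; with ``fusion_enabled`` the head consumes the concatenation of
    the three globally pooled stage outputs, otherwise only the last one.
    """

    input_size: int = 128
    stages: tuple[tuple[int, int], ...] = ((2, 32), (2, 64), (2, 128))
    n_classes: int = 2
    fusion_enabled: bool = True
    stem_stride: int = 2
    eca_gamma: int = 2
    eca_b: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.fusion_enabled and len(self.stages) != 3:
            raise ValueError("fusion requires exactly 3 stages (low/mid/high)")
        if self.input_size < 16:
            raise ValueError("input_size too small for three stride-2 reductions")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = [list(s) for s in self.stages]
        return d

    @staticmethod
    def from_dict(d: dict) -> "ModelConfig":
        d = dict(d)
        d["stages"] = tuple(tuple(s) for s in d["stages"])
        return ModelConfig(**d)


class SeedClassifier(nn.Layer):
    """Stem -> [stage -> ECA -> downsample]* -> fused pooled features -> dense.

    The stem is an ordinary 3x3 stride-2 convolution; each stage stacks
    depthwise-separable Inception-ResNet blocks at constant width; a
    stride-2 separable convolution sits between stages; each stage output
    passes an ECA gate whose kernel adapts to the stage width and is then
    globally average pooled for the fusion head.
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.rng_seed)
        widths = [w for _, w in config.stages]
        self.stem = nn.Sequential(
            nn.Conv2d(3, widths[0], kernel=3, stride=config.stem_stride, bias=False, rng=rng),
            nn.BatchNorm2d(widths[0]),
            nn.ReLU(),
        )
        self.stages: list[nn.Sequential] = []
        self.ecas: list[nn.ECA] = []
        self.downs: list[nn.Sequential] = []
        for i, (n_modules, width) in enumerate(config.stages):
            blocks = [
                DinceptionResNetBlock(ModuleConfig.default(width), rng=rng)
                for _ in range(n_modules)
            ]
            self.stages.append(nn.Sequential(*blocks))
            self.ecas.append(
                make_eca(ECAConfig(channels=width, gamma=config.eca_gamma, b=config.eca_b))
            )
            if i + 1 < len(config.stages):
                self.downs.append(
                    nn.Sequential(*_sep_bn_relu(width, widths[i + 1], rng, stride=2))
                )
        self.gaps = [nn.GlobalAvgPool() for _ in config.stages]
        self.fused_width = sum(widths) if config.fusion_enabled else widths[-1]
        self.head = nn.Dense(self.fused_width, config.n_classes, rng=rng)
        self.head.bias.value[...] = 0.0
        self._pooled_widths: list[int] = []

    # -- structure ----------------------------------------------------------

    def named_children(self) -> list[tuple[str, nn.Layer]]:
        out: list[tuple[str, nn.Layer]] = [("stem", self.stem)]
        for i in range(len(self.stages)):
            out.append((f"stage{i + 1}", self.stages[i]))
            out.append((f"eca{i + 1}", self.ecas[i]))
            if i < len(self.downs):
                out.append((f"down{i + 1}", self.downs[i]))
        out.append(("head", self.head))
        return out

    def params(self) -> list[nn.Param]:
        return [p for _, child in self.named_children() for p in child.params()]

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        pooled = []
        h = self.stem.forward(x, training=training)
        for i in range(len(self.stages)):
            h = self.stages[i].forward(h, training=training)
            h = self.ecas[i].forward(h, training=training)
            pooled.append(self.gaps[i].forward(h, training=training))
            if i < len(self.downs):
                h = self.downs[i].forward(h, training=training)
        if self.config.fusion_enabled:
            fused = np.concatenate(pooled, axis=1)
        else:
            fused = pooled[-1]
        self._pooled_widths = [p.shape[1] for p in pooled]
        return self.head.forward(fused, training=training)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        dfused = self.head.backward(dlogits)
        n = dlogits.shape[0]
        if self.config.fusion_enabled:
            dpooled = []
            start = 0
            for w in self._pooled_widths:
                dpooled.append(dfused[:, start : start + w])
                start += w
        else:
            dpooled = [
                np.zeros((n, w), dtype=np.float32) for w in self._pooled_widths[:-1]
            ] + [dfused]
        dh = None
        for i in reversed(range(len(self.stages))):
            de = self.gaps[i].backward(dpooled[i])
            if i < len(self.downs) and dh is not None:
                de = de + self.downs[i].backward(dh)
            dh = self.stages[i].backward(self.ecas[i].backward(de))
        return self.stem.backward(dh)

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Softmax class probabilities for an (N, C, H, W) float batch."""
        out = []
        for i in range(0, x.shape[0], batch_size):
            out.append(nn.softmax(self.forward(x[i : i + batch_size])))
        return np.concatenate(out, axis=0)


def build_model(config: ModelConfig) -> SeedClassifier:
    return SeedClassifier(config)


def build_dinception_module(
    config: ModuleConfig, rng_seed: int = 0
) -> DinceptionResNetBlock:
    return DinceptionResNetBlock(config, rng=np.random.default_rng(rng_seed))


def zero_conv_weights(layer: nn.Layer) -> None:
    """Zero every convolution/dense weight reachable from ``layer`` (test aid)."""
    stack = [layer]
    while stack:
        node = stack.pop()
        if isinstance(node, (nn.Conv2d, nn.Dense)):
            node.weight.value[...] = 0.0
            if getattr(node, "bias", None) is not None:
                node.bias.value[...] = 0.0
        elif isinstance(node, nn.DepthwiseConv2d):
            node.weight.value[...] = 0.0
        if isinstance(node, nn.Sequential):
            stack.extend(node.layers)
        elif hasattr(node, "named_children"):
            stack.extend(child for _, child in node.named_children())


# ---------------------------------------------------------------------------
# per-layer parameter report
# ---------------------------------------------------------------------------


def _leaf_rows(name: str, layer: nn.Layer, rows: list[dict]) -> None:
    if isinstance(layer, nn.Sequential):
        layers = layer.layers
        i = 0
        while i < len(layers):
            child = layers[i]
            # pair depthwise + pointwise into one separable-conv row
            if (
                isinstance(child, nn.DepthwiseConv2d)
                and i + 1 < len(layers)
                and isinstance(layers[i + 1], nn.Conv2d)
                and layers[i + 1].kh == 1
                and layers[i + 1].kw == 1
            ):
                pw = layers[i + 1]
                spec = ConvSpec(child.kh, child.kw, child.c, pw.c_out)
                rows.append(
                    {
                        "layer": f"{name}.{i}:separable{child.kh}x{child.kw}",
                        "kind": "separable_conv",
                        "standard_equiv_params": count_standard_params(spec),
                        "actual_params": count_separable_params(spec)
                        + (pw.bias.size if pw.bias is not None else 0),
                        "non_trainable_params": 0,
                    }
                )
                i += 2
                continue
            _leaf_rows(f"{name}.{i}", child, rows)
            i += 1
        return
    if hasattr(layer, "named_children"):
        for cname, child in layer.named_children():
            _leaf_rows(f"{name}.{cname}", child, rows)
        return
    trainable = sum(p.size for p in layer.params() if p.trainable)
    frozen = sum(p.size for p in layer.params() if not p.trainable)
    if trainable == 0 and frozen == 0:
        return
    rows.append(
        {
            "layer": f"{name}:{type(layer).__name__}",
            "kind": type(layer).__name__.lower(),
            "standard_equiv_params": trainable,
            "actual_params": trainable,
            "non_trainable_params": frozen,
        }
    )


def param_report(model: nn.Layer) -> pd.DataFrame:
    """Per-layer table of standard-equivalent vs. actual weight counts.

    ``actual_params`` counts the trainable weights of the built layers;
    ``standard_equiv_params`` replaces each separable convolution by its
    ordinary H*W*C*N equivalent; ``non_trainable_params`` holds the
    normalisation running statistics.  A ``total`` row closes the table.
    """
    rows: list[dict] = []
    _leaf_rows("model", model, rows)
    df = pd.DataFrame(
        rows,
        columns=[
            "layer",
            "kind",
            "standard_equiv_params",
            "actual_params",
            "non_trainable_params",
        ],
    )
    total = {
        "layer": "total",
        "kind": "",
        "standard_equiv_params": int(df["standard_equiv_params"].sum()),
        "actual_params": int(df["actual_params"].sum()),
        "non_trainable_params": int(df["non_trainable_params"].sum()),
    }
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(
    model: SeedClassifier, prefix: str | Path, classes: tuple[str, ...] = CLASSES
) -> Path:
    """Write ``<prefix>.npz`` weights, a JSON sidecar and the parameter CSV."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    state = nn.get_state(model)
    np.savez(prefix.with_suffix(".npz"), *state)
    sidecar = {"model_config": model.config.to_dict(), "classes": list(classes)}
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    param_report(model).to_csv(prefix.parent / (prefix.name + "_params.csv"), index=False)
    return prefix.with_suffix(".npz")


def load_checkpoint(prefix: str | Path) -> tuple[SeedClassifier, dict]:
    prefix = Path(prefix)
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    model = build_model(ModelConfig.from_dict(sidecar["model_config"]))
    with np.load(prefix.with_suffix(".npz")) as data:
        nn.set_state(model, [data[f"arr_{i}"] for i in range(len(data.files))])
    return model, sidecar
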