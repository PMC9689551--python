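"""IRBOA architecture: a multi-scale Inception/ResNet hybrid.

The network fuses Inception-v3-style multi-branch blocks into a
ResNet34-style backbone: Inception-A (four parallel branches, channel
concatenation) on the 224×224×3 input, a stride-2 max pool, a stack of
residual blocks (identity shortcuts at constant width, 1×1 projection
shortcuts y = F(x) + w_s·x where the width or resolution changes), an
Inception-B block with asymmetric 1×7/7×1 factorized convolutions, then
global average pooling and a small fully connected classifier head.

The model is described declaratively by a `ModelPlan` (kernel size, kernel
count, padding, stride per layer and branch). `shape_trace` propagates
tensor shapes through a plan symbolically, so the layer arithmetic can be
checked without allocating any weights; `build_model` turns the same plan
into a runnable `ricedom.nn.Network`.

Two printed-table inconsistencies are reconciled in the default plan (both
choices are recorded here and in docs/methods.md):

* Inception-B's fourth branch ends at 192 channels so the concatenation
  width is 64+128+128+192 = 512, matching the stated concatenation and
  average-pool width; `literal_table=True` keeps the branch at 128
  channels (concatenation 448) instead.
* Inception-A's max-pool branch 1×1 convolution uses padding 0 — padding 1
  would produce 226×226 and break the concatenation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn

__all__ = [
    "ConvSpec",
    "PoolSpec",
    "InceptionSpec",
    "ResidualSpec",
    "HeadSpec",
    "ModelPlan",
    "ShapeError",
    "default_plan",
    "shape_trace",
    "build_model",
    "conv_unit",
    "inception_a",
    "inception_b",
    "residual_a",
    "residual_b",
]


class ShapeError(ValueError):
    """A plan produces an inconsistent or non-positive tensor shape."""


def _pair(v):
    return (v, v) if isinstance(v, int) else tuple(v)


@dataclass(frozen=True)
class ConvSpec:
    """One convolution unit: conv -> batch norm -> ReLU (BN/ReLU optional)."""

    kernel: tuple[int, int]
    out_channels: int
    padding: tuple[int, int] = (0, 0)
    stride: int = 1
    has_bn: bool = True
    has_relu: bool = True

    def __post_init__(self):
        kh, kw = _pair(self.kernel)
        object.__setattr__(self, "kernel", (kh, kw))
        object.__setattr__(self, "padding", _pair(self.padding))
        if kh < 1 or kw < 1 or self.stride < 1:
            raise ValueError("kernel and stride must be >= 1")
        if min(self.padding) < 0:
            raise ValueError("padding must be >= 0")
        if self.out_channels < 1:
            raise ValueError("out_channels must be >= 1")


@dataclass(frozen=True)
class PoolSpec:
    """Max-pool step inside a branch or backbone."""

    kernel: tuple[int, int]
    padding: tuple[int, int] = (0, 0)
    stride: int = 1

    def __post_init__(self):
        object.__setattr__(self, "kernel", _pair(self.kernel))
        object.__setattr__(self, "padding", _pair(self.padding))


@dataclass(frozen=True)
class InceptionSpec:
    name: str
    branches: tuple[tuple, ...]  # each branch: tuple of ConvSpec | PoolSpec


@dataclass(frozen=True)
class ResidualSpec:
    """Residual block: y = ReLU(F(x) + x) (identity) or
    y = ReLU(F(x) + w_s x) (1×1 projection, stride 2)."""

    name: str
    out_channels: int
    stride: int = 1  # 1 -> identity shortcut, 2 -> projection shortcut

    @property
    def shortcut_kind(self) -> str:
        return "identity" if self.stride == 1 else "projection"


@dataclass(frozen=True)
class HeadSpec:
    """Global average pool -> fully connected logits."""

    num_classes: int


@dataclass
class ModelPlan:
    """Ordered block inventory with the input tensor shape."""

    blocks: list
    in_channels: int = 3
    input_size: int = 224
    meta: dict = field(default_factory=dict)

    @property
    def num_classes(self) -> int:
        return self.blocks[-1].num_classes

    def to_dict(self) -> dict:
        """JSON/YAML-serializable description mirroring the layer table
        (kernel, count, padding, stride per layer and branch)."""
        def enc(step):
            if isinstance(step, ConvSpec):
                return {"conv": {"kernel": list(step.kernel),
                                 "out_channels": step.out_channels,
                                 "padding": list(step.padding),
                                 "stride": step.stride,
                                 "bn": step.has_bn, "relu": step.has_relu}}
            return {"maxpool": {"kernel": list(step.kernel),
                                "padding": list(step.padding),
                                "stride": step.stride}}

        blocks = []
        for b in self.blocks:
            if isinstance(b, InceptionSpec):
                blocks.append({"inception": {
                    "name": b.name,
                    "branches": [[enc(s) for s in br] for br in b.branches]}})
            elif isinstance(b, PoolSpec):
                blocks.append(enc(b))
            elif isinstance(b, ResidualSpec):
                blocks.append({"residual": {"name": b.name,
                                            "out_channels": b.out_channels,
                                            "stride": b.stride}})
            elif isinstance(b, HeadSpec):
                blocks.append({"head": {"num_classes": b.num_classes}})
        return {"in_channels": self.in_channels, "input_size": self.input_size,
                "blocks": blocks}

    def plan_hash(self) -> str:
        """Stable digest of the serialized plan, for checkpoint tagging."""
        import hashlib
        import json

        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _scale(c: int, width_mult: float) -> int:
    return max(1, round(c * width_mult))


def inception_a_spec(width_mult: float = 1.0) -> InceptionSpec:
    """Inception-A: kernel counts 8, 12, 24, 8, 12, 24, 24 across branches
    1–4; spatial dims preserved; concatenation width 64 at full width."""
    s = lambda c: _scale(c, width_mult)
    return InceptionSpec(
        "Inception-A",
        (
            (ConvSpec((1, 1), s(8)),),
            (ConvSpec((1, 1), s(12)), ConvSpec((3, 3), s(24), (1, 1))),
            (PoolSpec((3, 3), (1, 1), 1), ConvSpec((1, 1), s(8))),
            (
                ConvSpec((1, 1), s(12)),
                ConvSpec((3, 3), s(24), (1, 1)),
                ConvSpec((3, 3), s(24), (1, 1)),
            ),
        ),
    )


def inception_b_spec(width_mult: float = 1.0, literal_table: bool = False) -> InceptionSpec:
    """Inception-B with asymmetric 1×7/7×1 factorized convolutions.

    branch4's terminal width is 192 (concatenation 512) by default, or 128
    (concatenation 448) when `literal_table` is set; see the module
    docstring for the reconciliation.
    """
    s = lambda c: _scale(c, width_mult)
    b4_last = s(128) if literal_table else s(192)
    return InceptionSpec(
        "Inception-B",
        (
            (ConvSpec((1, 1), s(64)),),
            (PoolSpec((3, 3), (1, 1), 1), ConvSpec((1, 1), s(128))),
            (
                ConvSpec((1, 1), s(64)),
                ConvSpec((1, 7), s(64), (0, 3)),
                ConvSpec((7, 1), s(128), (3, 0)),
            ),
            (
                ConvSpec((1, 1), s(192)),
                ConvSpec((1, 7), s(192), (0, 3)),
                ConvSpec((7, 1), s(192), (3, 0)),
                ConvSpec((1, 7), s(192), (0, 3)),
                ConvSpec((7, 1), b4_last, (3, 0)),
            ),
        ),
    )


def default_plan(num_classes: int = 3, width_mult: float = 1.0,
                 input_size: int = 224, in_channels: int = 3,
                 literal_table: bool = False) -> ModelPlan:
    """The full backbone: Inception-A, stride-2 max pool, five identity
    residual blocks and two projection residual blocks
    (64,64 | 128→ | 128 | 256→ | 256,256), Inception-B, global average
    pool, FC classifier. `width_mult` scales every kernel count (minimum 1)
    for reduced-width desk-scale runs."""
    inc_a = inception_a_spec(width_mult)
    # the first residual stage continues at the Inception-A concatenation
    # width; deeper stages double it (64 -> 128 -> 256 at full width)
    c1 = sum(br[-1].out_channels for br in inc_a.branches)
    c2, c3 = 2 * c1, 4 * c1
    blocks = [
        inc_a,
        PoolSpec((3, 3), (1, 1), 2),
        ResidualSpec("Residual-A1", c1, 1),
        ResidualSpec("Residual-A2", c1, 1),
        ResidualSpec("Residual-B1", c2, 2),
        ResidualSpec("Residual-A3", c2, 1),
        ResidualSpec("Residual-B2", c3, 2),
        ResidualSpec("Residual-A4", c3, 1),
        ResidualSpec("Residual-A5", c3, 1),
        inception_b_spec(width_mult, literal_table),
        HeadSpec(num_classes),
    ]
    return ModelPlan(blocks, in_channels=in_channels, input_size=input_size,
                     meta={"width_mult": width_mult, "literal_table": literal_table})


# ---------------------------------------------------------------------------
# symbolic shape propagation


def _conv_out(hw, kernel, padding, stride, what):
    out = []
    for dim, k, p in zip(hw, kernel, padding):
        o = (dim + 2 * p - k) // stride + 1
        if o < 1:
            raise ShapeError(f"{what}: non-positive output dim from input {hw}")
        out.append(o)
    return tuple(out)


def _branch_shape(steps, c, hw, what):
    for i, step in enumerate(steps):
        tag = f"{what}[{i}]"
        if isinstance(step, ConvSpec):
            hw = _conv_out(hw, step.kernel, step.padding, step.stride, tag)
            c = step.out_channels
        elif isinstance(step, PoolSpec):
            hw = _conv_out(hw, step.kernel, step.padding, step.stride, tag)
        else:
            raise ShapeError(f"{tag}: unknown step {step!r}")
    return c, hw


def shape_trace(plan: ModelPlan) -> list[tuple[str, tuple[int, int, int]]]:
    """Propagate (channels, height, width) through the plan without
    allocating weights. Raises ShapeError naming the offending block."""
    c, hw = plan.in_channels, (plan.input_size, plan.input_size)
    trace = [("input", (c, *hw))]
    for block in plan.blocks:
        if isinstance(block, InceptionSpec):
            outs = [_branch_shape(br, c, hw, f"{block.name}.branch{i+1}")
                    for i, br in enumerate(block.branches)]
            spatial = {o[1] for o in outs}
            if len(spatial) != 1:
                raise ShapeError(f"{block.name}: branch spatial dims disagree: {sorted(spatial)}")
            c, hw = sum(o[0] for o in outs), outs[0][1]
            trace.append((block.name, (c, *hw)))
        elif isinstance(block, PoolSpec):
            hw = _conv_out(hw, block.kernel, block.padding, block.stride, "MaxPool")
            trace.append(("MaxPool", (c, *hw)))
        elif isinstance(block, ResidualSpec):
            out_hw = _conv_out(hw, (3, 3), (1, 1), block.stride, block.name)
            if block.stride == 1 and block.out_channels != c:
                raise ShapeError(
                    f"{block.name}: identity shortcut needs matching channels "
                    f"({c} in, {block.out_channels} out)"
                )
            c, hw = block.out_channels, out_hw
            trace.append((block.name, (c, *hw)))
        elif isinstance(block, HeadSpec):
            trace.append(("Avg_pool", (c, 1, 1)))
            trace.append(("Fc", (block.num_classes,)))
        else:
            raise ShapeError(f"unknown block {block!r}")
    return trace


# ---------------------------------------------------------------------------
# builders


def conv_unit(spec: ConvSpec, in_channels: int, rng, name: str) -> nn.Sequential:
    """conv -> BN -> ReLU per the spec flags."""
    layers = [nn.Conv2d(in_channels, spec.out_channels, spec.kernel,
                        stride=spec.stride, padding=spec.padding,
                        bias=not spec.has_bn, rng=rng, name=name)]
    if spec.has_bn:
        layers.append(nn.BatchNorm2d(spec.out_channels, name=f"{name}.bn"))
    if spec.has_relu:
        layers.append(nn.ReLU())
    return nn.Sequential(*layers)


def _build_branch(steps, in_channels, rng, name):
    layers, c = [], in_channels
    for i, step in enumerate(steps):
        if isinstance(step, ConvSpec):
            layers.append(conv_unit(step, c, rng, f"{name}.{i}"))
            c = step.out_channels
        else:
            layers.append(nn.MaxPool2d(step.kernel, step.stride, step.padding))
    return nn.Sequential(*layers), c


def _build_inception(spec: InceptionSpec, in_channels, rng) -> nn.ParallelConcat:
    branches = [
        _build_branch(br, in_channels, rng, f"{spec.name}.branch{i+1}")[0]
        for i, br in enumerate(spec.branches)
    ]
    return nn.ParallelConcat(*branches)


def inception_a(in_channels: int, rng=None, width_mult: float = 1.0) -> nn.ParallelConcat:
    return _build_inception(inception_a_spec(width_mult), in_channels, nn.make_rng(rng))


def inception_b(in_channels: int, rng=None, width_mult: float = 1.0,
                literal_table: bool = False) -> nn.ParallelConcat:
    return _build_inception(inception_b_spec(width_mult, literal_table),
                            in_channels, nn.make_rng(rng))


def residual_a(channels: int, rng=None, name: str = "Residual-A") -> nn.Residual:
    """Identity-shortcut block: two 3×3 conv units (second without its
    terminal ReLU), y = ReLU(F(x) + x); shape preserving."""
    rng = nn.make_rng(rng)
    main = nn.Sequential(
        conv_unit(ConvSpec((3, 3), channels, (1, 1)), channels, rng, f"{name}.conv1"),
        conv_unit(ConvSpec((3, 3), channels, (1, 1), has_relu=False), channels, rng,
                  f"{name}.conv2"),
    )
    return nn.Residual(main)


def residual_b(in_channels: int, out_channels: int, rng=None,
               name: str = "Residual-B") -> nn.Residual:
    """Projection-shortcut block: main path 3×3 stride-2 then 3×3 stride-1;
    shortcut 1×1 stride-2 projection w_s; y = ReLU(F(x) + w_s x); spatial
    dims halve."""
    rng = nn.make_rng(rng)
    main = nn.Sequential(
        conv_unit(ConvSpec((3, 3), out_channels, (1, 1), stride=2), in_channels,
                  rng, f"{name}.conv1"),
        conv_unit(ConvSpec((3, 3), out_channels, (1, 1), has_relu=False),
                  out_channels, rng, f"{name}.conv2"),
    )
    shortcut = conv_unit(
        ConvSpec((1, 1), out_channels, (0, 0), stride=2, has_relu=False),
        in_channels, rng, f"{name}.proj",
    )
    return nn.Residual(main, shortcut)


def build_model(plan: ModelPlan, rng=None) -> nn.Network:
    """Assemble a runnable network from a plan. The plan is shape-checked
    first, so inconsistent plans fail before any weight allocation."""
    trace = shape_trace(plan)  # raises ShapeError on a bad plan
    rng = nn.make_rng(rng)
    blocks: list[tuple[str, nn.Layer]] = []
    c = plan.in_channels
    for block, (name, shape) in zip(plan.blocks, trace[1:]):
        if isinstance(block, InceptionSpec):
            blocks.append((block.name, _build_inception(block, c, rng)))
            c = shape[0]
        elif isinstance(block, PoolSpec):
            blocks.append(("MaxPool", nn.MaxPool2d(block.kernel, block.stride,
                                                   block.padding)))
        elif isinstance(block, ResidualSpec):
            if block.stride == 1:
                layer = residual_a(block.out_channels, rng, block.name)
            else:
                layer = residual_b(c, block.out_channels, rng, block.name)
            blocks.append((block.name, layer))
            c = block.out_channels
        elif isinstance(block, HeadSpec):
            blocks.append(("Avg_pool", nn.GlobalAvgPool()))
            blocks.append(("Fc", nn.Linear(c, block.num_classes, rng)))
    return nn.Network(blocks)
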