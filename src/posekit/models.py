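"""Stacked fully-convolutional pose models with intermediate supervision.

Two architectures are provided.  *Stacked DenseNet* arranges densely
connected encoder-decoder subnetworks in sequence: each dense block
concatenates every internal layer's features (``growth_rate`` new channels
per layer), transition-down steps compress with a pointwise convolution and
2x pool, and transition-up steps upsample and re-concatenate the encoder
skip features.  *Stacked Hourglass* uses residual blocks with recursive
pooling to a bottleneck and symmetric upsampling with additive skips.

Both emit one supervised output stack of ``K + G`` confidence maps per
subnetwork (intermediate supervision); each subsequent subnetwork consumes
the previous subnetwork's features concatenated with its output maps.  Only
the final output is decoded at inference.

Images enter as ``(B, H, W, C)`` and are normalised to [0, 1]; outputs are
``(B, H/s, W/s, K+G)`` at output stride ``s``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn
from .confmaps import DEFAULT_SIGMA
from .nn import core
from .peaks import DEFAULT_UPSAMPLE, PeakResult, subpixel_maxima

__all__ = [
    "ModelConfig",
    "PoseModel",
    "build_model",
    "build_stacked_densenet",
    "build_stacked_hourglass",
    "count_parameters",
    "predict",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and capacity description of a pose model.

    The default capacity knobs place the two-stack, stride-4 dense model for
    a 160x160 single-channel input with 9 keypoints (plus its posture-graph
    maps) at roughly 1.5 million trainable parameters.
    """

    arch: str = "stacked_densenet"
    n_stacks: int = 2
    output_stride: int = 4
    n_keypoints: int = 9
    n_graph_maps: int = 12
    input_shape: tuple[int, int, int] = (160, 160, 1)
    sigma: float = DEFAULT_SIGMA
    # dense-net knobs
    growth_rate: int = 15
    n_layers_per_block: int = 3
    n_down: int = 2
    compression: float = 0.5
    front_filters: int = 40
    # hourglass knobs
    base_filters: int = 48
    hourglass_depth: int = 3
    # stacking options
    reinject_input: bool = False
    detach_between_stacks: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arch not in ("stacked_densenet", "stacked_hourglass"):
            raise ValueError(f"unknown arch {self.arch!r}")
        h, w, _ = self.input_shape
        s = self.output_stride
        if s not in (1, 2, 4, 8, 16):
            raise ValueError("output_stride must be one of 1, 2, 4, 8, 16")
        if h % s or w % s:
            raise ValueError(f"stride {s} must divide input shape {(h, w)}")
        if self.n_stacks < 1:
            raise ValueError("n_stacks must be >= 1")
        for knob in ("growth_rate", "n_layers_per_block", "front_filters",
                     "base_filters"):
            if getattr(self, knob) <= 0:
                raise ValueError(f"{knob} must be positive")
        if not 0 < self.compression <= 1:
            raise ValueError("compression must be in (0, 1]")

    @property
    def n_outputs(self) -> int:
        return self.n_keypoints + self.n_graph_maps


# ---------------------------------------------------------------------------
# building blocks


class _DenseBlock(nn.Module):
    def __init__(self, cin: int, n_layers: int, growth: int, rng):
        self.layers = [
            nn.BnReluConv(cin + i * growth, growth, rng=rng)
            for i in range(n_layers)
        ]
        self.cout = cin + n_layers * growth

    def __call__(self, x, train):
        cur = x
        for layer in self.layers:
            cur = core.concat([cur, layer(cur, train)])
        return cur


class _TransitionDown(nn.Module):
    def __init__(self, cin: int, cout: int, rng):
        self.conv = nn.BnReluConv(cin, cout, kernel=1, rng=rng)

    def __call__(self, x, train):
        return core.avg_pool2(self.conv(x, train))


class _TransitionUp(nn.Module):
    def __init__(self, cin: int, cout: int, rng):
        self.conv = nn.BnReluConv(cin, cout, kernel=3, rng=rng)

    def __call__(self, x, train):
        return self.conv(core.upsample2(x), train)


class _DenseStack(nn.Module):
    """One dense encoder-decoder subnetwork plus its output head."""

    def __init__(self, cin: int, cfg: ModelConfig, n_down: int, rng):
        g, nl, comp = cfg.growth_rate, cfg.n_layers_per_block, cfg.compression
        ch = cin
        self.down_blocks, self.down_trans = [], []
        skip_ch = []
        for _ in range(n_down):
            blk = _DenseBlock(ch, nl, g, rng)
            ch = blk.cout
            skip_ch.append(ch)
            td = _TransitionDown(ch, max(int(round(ch * comp)), g), rng)
            ch = td.conv.conv.weight.shape[-1]
            self.down_blocks.append(blk)
            self.down_trans.append(td)
        self.bottleneck = _DenseBlock(ch, nl, g, rng)
        ch = self.bottleneck.cout
        self.up_trans, self.up_blocks = [], []
        for lev in reversed(range(n_down)):
            tu = _TransitionUp(ch, max(int(round(ch * comp)), g), rng)
            ch = tu.conv.conv.weight.shape[-1] + skip_ch[lev]
            blk = _DenseBlock(ch, nl, g, rng)
            ch = blk.cout
            self.up_trans.append(tu)
            self.up_blocks.append(blk)
        self.features_ch = ch
        self.head = nn.Conv2D(ch, cfg.n_outputs, kernel=1, rng=rng)

    def __call__(self, x, train):
        skips = []
        cur = x
        for blk, td in zip(self.down_blocks, self.down_trans):
            cur = blk(cur, train)
            skips.append(cur)
            cur = td(cur, train)
        cur = self.bottleneck(cur, train)
        for tu, blk, skip in zip(self.up_trans, self.up_blocks,
                                 reversed(skips)):
            cur = core.concat([tu(cur, train), skip])
            cur = blk(cur, train)
        return cur, self.head(cur)


class _Residual(nn.Module):
    """Pre-activation residual block; 1x1 projection when widths differ."""

    def __init__(self, cin: int, cout: int, rng):
        self.conv1 = nn.BnReluConv(cin, cout, rng=rng)
        self.conv2 = nn.BnReluConv(cout, cout, rng=rng)
        self.proj = nn.Conv2D(cin, cout, kernel=1, rng=rng) if cin != cout else None

    def __call__(self, x, train):
        y = self.conv2(self.conv1(x, train), train)
        shortcut = self.proj(x) if self.proj is not None else x
        return core.add(shortcut, y)


class _Hourglass(nn.Module):
    def __init__(self, depth: int, filters: int, rng):
        self.up1 = _Residual(filters, filters, rng)
        self.low1 = _Residual(filters, filters, rng)
        self.low2 = (
            _Hourglass(depth - 1, filters, rng)
            if depth > 1
            else _Residual(filters, filters, rng)
        )
        self.low3 = _Residual(filters, filters, rng)

    def __call__(self, x, train):
        up = self.up1(x, train)
        low = self.low1(core.max_pool2(x), train)
        low = self.low2(low, train)
        low = self.low3(low, train)
        return core.add(up, core.upsample2(low))


class _HourglassStack(nn.Module):
    def __init__(self, cin: int, cfg: ModelConfig, depth: int, rng):
        f = cfg.base_filters
        self.pre = _Residual(cin, f, rng)
        self.hourglass = _Hourglass(depth, f, rng)
        self.post = _Residual(f, f, rng)
        self.features_ch = f
        self.head = nn.Conv2D(f, cfg.n_outputs, kernel=1, rng=rng)

    def __call__(self, x, train):
        feats = self.post(self.hourglass(self.pre(x, train), train), train)
        return feats, self.head(feats)


class _FrontEnd(nn.Module):
    """Convolutional downsampler from input resolution to the output stride."""

    def __init__(self, cin: int, filters: int, stride: int, rng):
        self.entry = nn.Conv2D(cin, filters, kernel=3, rng=rng)
        n_steps = int(round(np.log2(stride)))
        self.steps = [
            nn.BnReluConv(filters, filters, rng=rng) for _ in range(n_steps)
        ]
        self.cout = filters

    def __call__(self, x, train):
        cur = self.entry(x)
        for step in self.steps:
            cur = core.avg_pool2(step(cur, train))
        return cur


# ---------------------------------------------------------------------------
# the model


class PoseModel(nn.Module):
    """Stacked encoder-decoder network with one supervised output per stack."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        h, w, c = config.input_shape
        s = config.output_stride
        map_h = h // s

        self.front = _FrontEnd(c, config.front_filters, s, rng)
        cin = self.front.cout

        # never pool below a 4-pixel map inside a subnetwork
        max_inner = max(int(np.log2(max(map_h // 4, 1))), 1)
        self.stacks = []
        for _ in range(config.n_stacks):
            if config.arch == "stacked_densenet":
                depth = min(config.n_down, max_inner)
                stack = _DenseStack(cin, config, depth, rng)
            else:
                depth = min(config.hourglass_depth, max_inner)
                stack = _HourglassStack(cin, config, depth, rng)
            cin = stack.features_ch + config.n_outputs
            if config.reinject_input:
                cin += self.front.cout
            self.stacks.append(stack)

    def __call__(self, images: np.ndarray, train: bool = False):
        """Run the network; returns a list of output tensors, one per stack."""
        x = np.asarray(images)
        if x.ndim != 4 or x.shape[1:] != tuple(self.config.input_shape):
            raise ValueError(
                f"images of shape {x.shape} do not match configured input "
                f"shape {self.config.input_shape}"
            )
        if np.issubdtype(x.dtype, np.integer):
            x = x.astype(np.float32) / 255.0
        front = self.front(core.Tensor(x.astype(np.float32)), train)
        outputs = []
        cur = front
        for stack in self.stacks:
            feats, maps = stack(cur, train)
            outputs.append(maps)
            parts = [feats, maps]
            if self.config.reinject_input:
                parts.append(front)
            if self.config.detach_between_stacks:
                parts = [p.detach() for p in parts]
            cur = core.concat(parts)
        return outputs


def build_stacked_densenet(config: ModelConfig | None = None, **kwargs) -> PoseModel:
    """Build a Stacked DenseNet pose model (see :class:`ModelConfig`)."""
    if config is None:
        config = ModelConfig(arch="stacked_densenet", **kwargs)
    if config.arch != "stacked_densenet":
        raise ValueError("config.arch must be 'stacked_densenet'")
    return PoseModel(config)


def build_stacked_hourglass(config: ModelConfig | None = None, **kwargs) -> PoseModel:
    """Build a Stacked Hourglass pose model (see :class:`ModelConfig`)."""
    if config is None:
        config = ModelConfig(arch="stacked_hourglass", **kwargs)
    if config.arch != "stacked_hourglass":
        raise ValueError("config.arch must be 'stacked_hourglass'")
    return PoseModel(config)


def build_model(config: ModelConfig) -> PoseModel:
    if config.arch == "stacked_densenet":
        return build_stacked_densenet(config)
    return build_stacked_hourglass(config)


def count_parameters(model: PoseModel) -> int:
    """Exact number of trainable scalars in the model."""
    return model.n_parameters()


def predict(
    model: PoseModel,
    images: np.ndarray,
    upsample: int = DEFAULT_UPSAMPLE,
) -> list[PeakResult]:
    """Decode keypoint coordinates for a batch of images.

    Runs the network in eval mode, keeps the final stack's first ``K`` maps
    (posture-graph maps are dropped at inference), and applies subpixel
    peak decoding with the template matched to the training peak width.
    """
    cfg = model.config
    outputs = model(images, train=False)
    maps = outputs[-1].data[..., : cfg.n_keypoints]  # (B, h, w, K)
    kernel_sigma = cfg.sigma / cfg.output_stride
    results = []
    for i in range(maps.shape[0]):
        stack = np.ascontiguousarray(maps[i].transpose(2, 0, 1))
        results.append(
            subpixel_maxima(
                stack,
                stride=cfg.output_stride,
                kernel_sigma=kernel_sigma,
                upsample=upsample,
            )
        )
    return results


def save_model(model: PoseModel, path) -> None:
    """Checkpoint weights (npz) with the config embedded as JSON."""
    state = model.state_arrays()
    state["__config__"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8
    )
    np.savez(path, **state)


def load_model(path) -> PoseModel:
    """Rebuild a model from a checkpoint written by :func:`save_model`."""
    with np.load(path) as data:
        raw = json.loads(bytes(data["__config__"].tobytes()).decode())
        raw["input_shape"] = tuple(raw["input_shape"])
        config = ModelConfig(**raw)
        model = build_model(config)
        state = {k: data[k] for k in data.files if k != "__config__"}
    model.load_state_arrays(state)
    return model
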