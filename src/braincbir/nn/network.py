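"""Multi-scale residual CNN for brain-image descriptors.

The basic building block is a residual module whose main branch stacks three
3x3 convolutions.  Because each convolution operates on the previous one's
output, their effective receptive fields grow progressively (3x3, 5x5, 7x7
on the input for the default kernel), so the three intermediate feature maps
see the image at increasingly global context.  The block concatenates those
three maps, reduces them back to the target width with a 1x1 convolution,
and adds a skip connection (a 1x1 projection when the channel counts differ,
identity otherwise) followed by a ReLU.

The full network applies one basic module at each of three spatial scales —
the original resolution, 1/2 and 1/4 (via 2x2 max pooling) — then globally
average-pools each scale's feature map, concatenates the pooled vectors and
passes them through a fully connected layer to produce the raw visual
descriptor (default 4096-dim, the penultimate activation), topped by a
linear softmax classification head.  Combining all three scales keeps both
the global anatomy and small local lesions represented in the descriptor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .layers import (
    Conv2d,
    Dense,
    FeatureNorm,
    GlobalMaxPool,
    GroupNorm,
    Layer,
    MaxPool2,
    Parameter,
    ReLU,
)

CHECKPOINT_VERSION = "1"

__all__ = [
    "BasicModuleConfig",
    "NetworkConfig",
    "BasicModule",
    "MultiScaleNet",
    "DescriptorVector",
    "ClassProbabilities",
    "build_basic_module",
    "build_network",
    "extract_descriptor",
    "extract_descriptors",
    "softmax",
    "receptive_fields",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class BasicModuleConfig:
    in_channels: int
    out_channels: int
    kernel_size: int = 3

    def __post_init__(self) -> None:
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("in_channels and out_channels must be >= 1")
        if self.kernel_size % 2 != 1:
            raise ValueError(f"kernel_size must be odd, got {self.kernel_size}")


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture parameters.

    ``module_channels`` gives the output width of the basic module at each of
    the three scales; ``input_size`` must be divisible by 4 to survive the
    two pooling halvings; ``feature_dim`` is the raw descriptor length.
    """

    input_size: int = 128
    module_channels: tuple[int, int, int] = (24, 48, 96)
    feature_dim: int = 4096
    n_classes: int = 3
    kernel_size: int = 3
    n_scales: int = 3  # fixed: scales 1, 1/2, 1/4

    def __post_init__(self) -> None:
        if self.input_size % 4 != 0:
            raise ValueError(
                f"input_size must be divisible by 4, got {self.input_size}"
            )
        if self.n_scales != 3:
            raise ValueError("the architecture is defined for exactly 3 scales")
        if len(self.module_channels) != 3:
            raise ValueError("module_channels must list 3 widths, one per scale")
        if self.feature_dim < self.n_classes:
            raise ValueError("feature_dim must be >= n_classes")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")


@dataclass
class DescriptorVector:
    """Raw visual descriptor of one image (length = ``feature_dim``)."""

    values: np.ndarray
    image_id: str = ""


@dataclass
class ClassProbabilities:
    probs: np.ndarray
    logits: np.ndarray


def receptive_fields(n_convs: int, kernel_size: int = 3) -> list[int]:
    """Effective receptive field after each of ``n_convs`` stacked stride-1
    convolutions: r_i = 1 + i*(k-1)."""
    return [1 + i * (kernel_size - 1) for i in range(1, n_convs + 1)]


def softmax(logits: np.ndarray) -> ClassProbabilities:
    """Normalized exponential P(i) = exp(z_i) / sum_k exp(z_k).

    Computed shift-invariantly (max subtracted) for numerical stability;
    accepts a single logit vector or a batch (last axis = classes).
    """
    z = np.asarray(logits, dtype=np.float64)
    if z.size == 0:
        raise ValueError("logits must be non-empty")
    if not np.all(np.isfinite(z)):
        raise ValueError("logits must be finite")
    shifted = z - z.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return ClassProbabilities(probs=e / e.sum(axis=-1, keepdims=True), logits=z)


class BasicModule(Layer):
    """The residual multi-scale block (see module docstring)."""

    def __init__(
        self, cfg: BasicModuleConfig, *, rng: np.random.Generator, name: str = "block"
    ):
        self.cfg = cfg
        m, n, k = cfg.in_channels, cfg.out_channels, cfg.kernel_size
        self.conv1 = Conv2d(m, n, k, rng=rng, name=f"{name}.conv1")
        self.conv2 = Conv2d(n, n, k, rng=rng, name=f"{name}.conv2")
        self.conv3 = Conv2d(n, n, k, rng=rng, name=f"{name}.conv3")
        # group norm after each main-branch convolution keeps activations
        # well scaled; the skip path is left untouched so zeroed main-branch
        # weights still reduce the block to its (projected) input
        self.gn1 = GroupNorm(n, name=f"{name}.gn1")
        self.gn2 = GroupNorm(n, name=f"{name}.gn2")
        self.gn3 = GroupNorm(n, name=f"{name}.gn3")
        self.relu1, self.relu2, self.relu3 = ReLU(), ReLU(), ReLU()
        self.reduce = Conv2d(3 * n, n, 1, rng=rng, name=f"{name}.reduce")
        self.gn_r = GroupNorm(n, name=f"{name}.gn_r")
        self.skip = (
            None if m == n else Conv2d(m, n, 1, rng=rng, name=f"{name}.skip")
        )
        self.relu_out = ReLU()
        self._n = n

    def parameters(self) -> list[Parameter]:
        ps = (
            self.conv1.parameters()
            + self.gn1.parameters()
            + self.conv2.parameters()
            + self.gn2.parameters()
            + self.conv3.parameters()
            + self.gn3.parameters()
            + self.reduce.parameters()
            + self.gn_r.parameters()
        )
        if self.skip is not None:
            ps += self.skip.parameters()
        return ps

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        h1 = self.relu1.forward(
            self.gn1.forward(self.conv1.forward(x, train), train), train
        )
        h2 = self.relu2.forward(
            self.gn2.forward(self.conv2.forward(h1, train), train), train
        )
        h3 = self.relu3.forward(
            self.gn3.forward(self.conv3.forward(h2, train), train), train
        )
        cat = np.concatenate([h1, h2, h3], axis=1)
        main = self.gn_r.forward(self.reduce.forward(cat, train), train)
        shortcut = x if self.skip is None else self.skip.forward(x, train)
        if main.shape[1] != shortcut.shape[1]:  # pragma: no cover - guarded by cfg
            raise ValueError(
                f"skip path ({shortcut.shape[1]} ch) does not match merged main "
                f"path ({main.shape[1]} ch)"
            )
        return self.relu_out.forward(main + shortcut, train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dsum = self.relu_out.backward(dout)
        dcat = self.reduce.backward(self.gn_r.backward(dsum))
        n = self._n
        dh1, dh2, dh3 = dcat[:, :n], dcat[:, n : 2 * n], dcat[:, 2 * n :]
        dh2 = dh2 + self.conv3.backward(
            self.gn3.backward(self.relu3.backward(dh3))
        )
        dh1 = dh1 + self.conv2.backward(
            self.gn2.backward(self.relu2.backward(dh2))
        )
        dx = self.conv1.backward(self.gn1.backward(self.relu1.backward(dh1)))
        if self.skip is None:
            return dx + dsum
        return dx + self.skip.backward(dsum)


class MultiScaleNet(Layer):
    """Three basic modules at scales 1, 1/2, 1/4 feeding pooled, concatenated
    features into the descriptor and classification heads."""

    def __init__(self, cfg: NetworkConfig, *, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        c1, c2, c3 = cfg.module_channels
        k = cfg.kernel_size
        self.block1 = BasicModule(
            BasicModuleConfig(1, c1, k), rng=rng, name="block1"
        )
        self.block2 = BasicModule(
            BasicModuleConfig(c1, c2, k), rng=rng, name="block2"
        )
        self.block3 = BasicModule(
            BasicModuleConfig(c2, c3, k), rng=rng, name="block3"
        )
        self.pool1, self.pool2 = MaxPool2(), MaxPool2()
        # global MAX pooling in the scale merge: a filter that fires on a
        # small lesion keeps its response however small the lesion's area,
        # which a spatial average would dilute away
        self.gap1, self.gap2, self.gap3 = (
            GlobalMaxPool(),
            GlobalMaxPool(),
            GlobalMaxPool(),
        )
        self.feat_norm = FeatureNorm()
        self.fc_feat = Dense(c1 + c2 + c3, cfg.feature_dim, rng=rng, name="fc_feat")
        # start the descriptor head near zero: the descriptor then reflects
        # structure built by training (class-discriminative directions)
        # rather than the random projection of the initial weights, which
        # would otherwise dominate Euclidean distances between descriptors
        self.fc_feat.weight.value *= np.float32(0.05)
        self.relu_feat = ReLU()
        self.fc_cls = Dense(cfg.feature_dim, cfg.n_classes, rng=rng, name="fc_cls")

    def parameters(self) -> list[Parameter]:
        return (
            self.block1.parameters()
            + self.block2.parameters()
            + self.block3.parameters()
            + self.fc_feat.parameters()
            + self.fc_cls.parameters()
        )

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[:, None]
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError(f"expected (N, 1, H, W) input, got shape {x.shape}")
        s = self.cfg.input_size
        if x.shape[2] != s or x.shape[3] != s:
            raise ValueError(
                f"input spatial size {x.shape[2]}x{x.shape[3]} does not match "
                f"configured input_size {s}x{s}"
            )
        # centre [0,1] intensities so first-layer activations are zero-mean
        return x - np.float32(0.5)

    def forward(
        self, x: np.ndarray, train: bool = True, check_finite: bool = False
    ) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(descriptor, logits)`` for a batch."""
        x = self._check_input(x)
        f1 = self.block1.forward(x, train)
        f2 = self.block2.forward(self.pool1.forward(f1, train), train)
        f3 = self.block3.forward(self.pool2.forward(f2, train), train)
        if check_finite:
            for nm, arr in (("scale-1 block", f1), ("scale-1/2 block", f2),
                            ("scale-1/4 block", f3)):
                if not np.isfinite(arr.sum()):
                    raise FloatingPointError(f"non-finite activations in {nm}")
        g = np.concatenate(
            [
                self.gap1.forward(f1, train),
                self.gap2.forward(f2, train),
                self.gap3.forward(f3, train),
            ],
            axis=1,
        )
        g = self.feat_norm.forward(g, train)
        desc = self.relu_feat.forward(self.fc_feat.forward(g, train), train)
        logits = self.fc_cls.forward(desc, train)
        if check_finite and not np.isfinite(logits.sum()):
            raise FloatingPointError("non-finite activations in fully connected head")
        return desc, logits

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        ddesc = self.fc_cls.backward(dlogits)
        dg = self.feat_norm.backward(
            self.fc_feat.backward(self.relu_feat.backward(ddesc))
        )
        c1, c2, _ = self.cfg.module_channels
        dg1, dg2, dg3 = dg[:, :c1], dg[:, c1 : c1 + c2], dg[:, c1 + c2 :]
        df3 = self.gap3.backward(dg3)
        dp2 = self.block3.backward(df3)
        df2 = self.gap2.backward(dg2) + self.pool2.backward(dp2)
        dp1 = self.block2.backward(df2)
        df1 = self.gap1.backward(dg1) + self.pool1.backward(dp1)
        return self.block1.backward(df1)


def build_basic_module(
    cfg: BasicModuleConfig, *, seed: int = 0
) -> BasicModule:
    return BasicModule(cfg, rng=np.random.default_rng(np.random.SeedSequence(seed)))


def build_network(cfg: NetworkConfig, *, seed: int = 0) -> MultiScaleNet:
    return MultiScaleNet(cfg, seed=seed)


def extract_descriptors(
    network: MultiScaleNet,
    images,
    batch_size: int = 32,
) -> list[DescriptorVector]:
    """Run the trained network in inference mode over a collection of images
    (``LabeledImage`` objects or raw 2-D arrays) and return their raw
    descriptors, in input order."""
    out: list[DescriptorVector] = []
    batch, ids = [], []

    def flush() -> None:
        if not batch:
            return
        x = np.stack(batch)[:, None]
        desc, _ = network.forward(x, train=False, check_finite=True)
        for row, iid in zip(desc, ids):
            out.append(DescriptorVector(values=row.copy(), image_id=iid))
        batch.clear()
        ids.clear()

    for im in images:
        pixels = getattr(im, "pixels", im)
        ids.append(getattr(im, "id", ""))
        batch.append(np.asarray(pixels, dtype=np.float32))
        if len(batch) == batch_size:
            flush()
    flush()
    return out


def extract_descriptor(network: MultiScaleNet, image) -> DescriptorVector:
    """Descriptor of a single image (``LabeledImage`` or raw 2-D grid)."""
    return extract_descriptors(network, [image])[0]


def save_checkpoint(network: MultiScaleNet, path: str | Path) -> Path:
    """Persist weights plus the architecture config and a format version."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cfg = network.cfg
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": {
            "input_size": cfg.input_size,
            "module_channels": list(cfg.module_channels),
            "feature_dim": cfg.feature_dim,
            "n_classes": cfg.n_classes,
            "kernel_size": cfg.kernel_size,
        },
    }
    arrays = {p.name: p.value for p in network.parameters()}
    with open(path, "wb") as fh:
        np.savez(fh, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)
    return path


def load_checkpoint(path: str | Path) -> MultiScaleNet:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(
                f"unsupported checkpoint version {meta.get('version')!r}"
            )
        c = meta["config"]
        net = MultiScaleNet(
            NetworkConfig(
                input_size=c["input_size"],
                module_channels=tuple(c["module_channels"]),
                feature_dim=c["feature_dim"],
                n_classes=c["n_classes"],
                kernel_size=c["kernel_size"],
            )
        )
        for p in net.parameters():
            p.value[...] = data[p.name]
    return net
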