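"""CNN feature extraction backbones.

Features are always taken after global average pooling, before any
classification head.  Two families are provided:

* ``surrogate_tiny`` — a small fixed-weight convolutional network (two conv
  blocks + global average pooling) implemented in numpy.  Its weights are
  drawn once from a seeded generator, so extraction is deterministic and fast
  enough for unit tests on a single CPU.  Three differently seeded surrogates
  stand in for the three standard backbones in the default pipeline.
* standard ImageNet backbones (``resnet18``, ``densenet201``,
  ``inception_resnet_v2``) through torchvision, imported lazily; they are an
  optional extra and nothing in the test path depends on them.

Input images are 2-D grayscale or RGB arrays; grayscale is tiled to three
channels on entry.  Images are resized to the backbone's input size and pixel
values are rescaled to [0, 1] before the forward pass.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

__all__ = [
    "BackboneSpec",
    "SurrogateTinyBackbone",
    "get_backbone",
    "extract_features",
    "STANDARD_BACKBONES",
]

STANDARD_BACKBONES = ("resnet18", "densenet201", "inception_resnet_v2")

_DEFAULT_INPUT_SIZE = {
    "resnet18": 224,
    "densenet201": 224,
    "inception_resnet_v2": 299,
    "surrogate_tiny": 64,
}


@dataclass
class BackboneSpec:
    """Declarative description of a feature extractor.

    ``seed`` only matters for ``surrogate_tiny``, whose fixed random weights it
    determines; distinct seeds give distinct surrogate "backbones".
    ``input_size`` defaults to the family's standard size (224 for
    ResNet18/DenseNet201, 299 for Inception-ResNet-v2, 64 for the surrogate)
    but is configurable.
    """

    name: str = "surrogate_tiny"
    input_size: int | None = None
    feature_dim: int = 32
    pretrained: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        known = STANDARD_BACKBONES + ("surrogate_tiny",)
        if self.name not in known:
            raise ValueError(f"unknown backbone {self.name!r}; expected one of {known}")
        if self.input_size is None:
            self.input_size = _DEFAULT_INPUT_SIZE[self.name]
        if self.input_size <= 0:
            raise ValueError("input_size must be positive")
        if self.feature_dim <= 0:
            raise ValueError("feature_dim must be positive")
        if self.seed is None:
            # stable per-name default so distinct names give distinct surrogates
            self.seed = zlib.crc32(self.name.encode()) % (2**31)


def _as_nhwc(images: np.ndarray | list) -> np.ndarray:
    """Coerce input to float (n, H, W, 3), tiling grayscale to three channels."""
    if isinstance(images, (list, tuple)):
        if len(images) == 0:
            raise ValueError("empty image list")
        images = np.stack([np.asarray(im, dtype=float) for im in images])
    images = np.asarray(images, dtype=float)
    if images.ndim == 2:
        images = images[None]
    if images.shape[0] == 0:
        raise ValueError("empty image list")
    if not np.all(np.isfinite(images)):
        raise ValueError("images contain non-finite pixel values")
    if images.ndim == 3:
        images = np.repeat(images[..., None], 3, axis=-1)
    if images.ndim != 4 or images.shape[-1] not in (1, 3):
        raise ValueError("images must be (n, H, W) or (n, H, W, 1|3)")
    if images.shape[-1] == 1:
        images = np.repeat(images, 3, axis=-1)
    if images.max() > 1.0:  # assume 8-bit input; rescale to [0, 1]
        images = images / 255.0
    return images


def _resize(images: np.ndarray, size: int) -> np.ndarray:
    n, h, w, c = images.shape
    if h == size and w == size:
        return images
    zoom = (1.0, size / h, size / w, 1.0)
    return ndimage.zoom(images, zoom, order=1)


def _conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Valid-mode 2-D convolution. x: (n,H,W,Cin); w: (k,k,Cin,Cout)."""
    k = w.shape[0]
    out = np.empty(
        (x.shape[0], x.shape[1] - k + 1, x.shape[2] - k + 1, w.shape[-1]),
        dtype=np.float32,
    )
    # chunk over samples to bound the im2col scratch memory
    step = 16
    w32 = w.astype(np.float32)
    for i in range(0, x.shape[0], step):
        v = sliding_window_view(x[i : i + step].astype(np.float32), (k, k), axis=(1, 2))
        out[i : i + step] = np.einsum(
            "nhwcij,ijco->nhwo", v, w32, optimize=True
        )
    return out + b.astype(np.float32)


def _maxpool2(x: np.ndarray) -> np.ndarray:
    n, h, w, c = x.shape
    x = x[:, : h - h % 2, : w - w % 2]
    return x.reshape(n, h // 2, 2, w // 2, 2, c).max(axis=(2, 4))


class SurrogateTinyBackbone:
    """Two-conv-block network with fixed random weights and global pooling.

    conv(3x3, 8 filters) -> ReLU -> maxpool(2) -> conv(3x3, feature_dim
    filters) -> ReLU -> global average pool.  Weights use He-scaled Gaussian
    initialization from a seeded generator and never change, so the extractor
    is a deterministic random projection of local image structure.
    """

    name = "surrogate_tiny"

    def __init__(self, feature_dim: int = 32, input_size: int = 64, seed: int = 0,
                 hidden_channels: int = 8):
        self.feature_dim = int(feature_dim)
        self.input_size = int(input_size)
        self.seed = int(seed)
        self.hidden_channels = int(hidden_channels)
        rng = np.random.default_rng(self.seed)
        c1 = hidden_channels
        self.w1 = rng.normal(0.0, np.sqrt(2.0 / (3 * 9)), size=(3, 3, 3, c1))
        self.b1 = rng.normal(0.0, 0.05, size=c1)
        self.w2 = rng.normal(0.0, np.sqrt(2.0 / (c1 * 9)), size=(3, 3, c1, feature_dim))
        self.b2 = rng.normal(0.0, 0.05, size=feature_dim)

    def __call__(self, images: np.ndarray | list) -> np.ndarray:
        x = _resize(_as_nhwc(images), self.input_size)
        h = np.maximum(_conv2d(x, self.w1, self.b1), 0.0)
        h = _maxpool2(h)
        h = np.maximum(_conv2d(h, self.w2, self.b2), 0.0)
        return h.mean(axis=(1, 2)).astype(float)


class _TorchBackbone:
    """Adapter around a torchvision model truncated at global average pooling."""

    def __init__(self, spec: BackboneSpec):
        try:
            import torch  # noqa: F401
            import torchvision  # noqa: F401
        except ImportError as exc:  # pragma: no cover - torch optional
            raise ImportError(
                f"backbone {spec.name!r} requires the optional torch/torchvision "
                "extra; install dbofuse[torch] or use the surrogate_tiny backbone"
            ) from exc
        import torch
        from torchvision import models

        self.spec = spec
        weights = "DEFAULT" if spec.pretrained else None
        if spec.name == "resnet18":
            net = models.resnet18(weights=weights)
            self._features = torch.nn.Sequential(*list(net.children())[:-1])
        elif spec.name == "densenet201":
            net = models.densenet201(weights=weights)
            self._features = torch.nn.Sequential(
                net.features, torch.nn.ReLU(inplace=True),
                torch.nn.AdaptiveAvgPool2d(1),
            )
        else:  # inception_resnet_v2 has no torchvision build; inception_v3 head
            net = models.inception_v3(weights=weights, aux_logits=True)
            net.fc = torch.nn.Identity()
            self._features = net
        self._features.eval()

    def __call__(self, images: np.ndarray | list) -> np.ndarray:  # pragma: no cover
        import torch

        x = _resize(_as_nhwc(images), self.spec.input_size)
        t = torch.from_numpy(np.moveaxis(x, -1, 1)).float()
        with torch.no_grad():
            f = self._features(t)
        return f.reshape(f.shape[0], -1).numpy().astype(float)


def get_backbone(spec: BackboneSpec):
    """Instantiate the extractor described by ``spec``."""
    if spec.name == "surrogate_tiny":
        return SurrogateTinyBackbone(
            feature_dim=spec.feature_dim, input_size=spec.input_size, seed=spec.seed
        )
    return _TorchBackbone(spec)


def extract_features(images: np.ndarray | list, spec: BackboneSpec) -> np.ndarray:
    """Extract a (n_samples, feature_dim) matrix of globally pooled activations.

    Deterministic given the backbone's fixed weights: identical images give
    identical rows.
    """
    return get_backbone(spec)(images)
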