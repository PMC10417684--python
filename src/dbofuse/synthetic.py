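"""Synthetic three-class image fixture emulating a small lung CT study.

The generator produces 100 grayscale images (35 normal, 32 benign,
33 malignant by default) whose classes differ in low-level texture and blob
statistics rather than in any radiologically meaningful way:

* **normal** — a smooth low-intensity field;
* **benign** — a single bright Gaussian blob with a regular (isotropic)
  boundary on the same background;
* **malignant** — several small, irregular (anisotropic, rotated) high-gradient
  blobs and a brighter base intensity.

A single ``separability`` knob scales every between-class difference (base
intensity offsets and blob amplitudes); at 0 the three classes are drawn from
one identical distribution, which gives the chance-level null case used in
tests.  Pixel values live in [0, 1] and everything is deterministic under the
spec seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "SplitPlan",
    "generate_dataset",
    "stratified_split",
    "write_image_directory",
    "load_image_directory",
    "CLASS_NAMES",
]

CLASS_NAMES = ("normal", "benign", "malignant")

#: test-set class counts implied by the benchmark tables, per train fraction
TABLE_TEST_COUNTS = {0.8: (8, 5, 7), 0.7: (13, 9, 8)}


@dataclass
class SyntheticSpec:
    """Generator settings; defaults mirror the 100-sample study scale."""

    class_counts: tuple[int, int, int] = (35, 32, 33)
    image_size: int = 64
    separability: float = 1.0
    noise_sd: float = 0.05
    #: None means "derive from the pipeline seed" (0 when used standalone)
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.class_counts) != 3 or any(c <= 0 for c in self.class_counts):
            raise ValueError("class_counts must be three positive integers")
        if self.image_size < 8:
            raise ValueError("image_size must be at least 8 pixels")
        if self.separability < 0:
            raise ValueError("separability must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SyntheticDataset:
    images: np.ndarray  # (n, H, W) in [0, 1]
    labels: np.ndarray  # (n,) integer class indices
    class_names: tuple[str, ...]
    manifest: pd.DataFrame  # sample_id, label, class_name

    @property
    def n_samples(self) -> int:
        return self.images.shape[0]


def _smooth_background(rng: np.random.Generator, size: int, base: float) -> np.ndarray:
    field_noise = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (size, size)), sigma=size / 8)
    return base + 0.04 * field_noise


def _gaussian_blob(
    size: int,
    center: tuple[float, float],
    sigmas: tuple[float, float],
    angle: float,
) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    dy, dx = yy - center[0], xx - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dx + sa * dy
    v = -sa * dx + ca * dy
    return np.exp(-0.5 * ((u / sigmas[0]) ** 2 + (v / sigmas[1]) ** 2))


def _render_class(rng: np.random.Generator, cls: int, spec: SyntheticSpec) -> np.ndarray:
    s = spec.separability
    size = spec.image_size
    # base intensity offsets, scaled by separability
    base = 0.20 + s * (0.0, 0.12, 0.24)[cls]
    img = _smooth_background(rng, size, base)
    if cls == 1:
        # one regular bright blob
        center = rng.uniform(0.3 * size, 0.7 * size, 2)
        sigma = rng.uniform(size / 10, size / 6)
        img += s * 0.5 * _gaussian_blob(size, tuple(center), (sigma, sigma), 0.0)
    elif cls == 2:
        # several small, irregular, high-gradient blobs
        for _ in range(rng.integers(4, 8)):
            center = rng.uniform(0.15 * size, 0.85 * size, 2)
            sigmas = rng.uniform(size / 40, size / 16, 2)
            angle = rng.uniform(0.0, np.pi)
            img += s * 0.6 * _gaussian_blob(size, tuple(center), tuple(sigmas), angle)
    img += rng.normal(0.0, spec.noise_sd, img.shape)
    return np.clip(img, 0.0, 1.0)


def generate_dataset(spec: SyntheticSpec | None = None) -> SyntheticDataset:
    """Deterministically generate the synthetic three-class image set."""
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed if spec.seed is not None else 0)
    images, labels = [], []
    for cls, count in enumerate(spec.class_counts):
        for _ in range(count):
            images.append(_render_class(rng, cls, spec))
            labels.append(cls)
    images = np.stack(images)
    labels = np.asarray(labels)
    manifest = pd.DataFrame(
        {
            "sample_id": [f"sample_{i:04d}" for i in range(len(labels))],
            "label": labels,
            "class_name": [CLASS_NAMES[c] for c in labels],
        }
    )
    return SyntheticDataset(
        images=images, labels=labels, class_names=CLASS_NAMES, manifest=manifest
    )


@dataclass
class SplitPlan:
    """Stratified train/test allocation with per-class index lists."""

    train_fraction: float
    train_by_class: dict[int, np.ndarray]
    test_by_class: dict[int, np.ndarray]
    seed: int
    table_matching: bool = False

    @property
    def train_indices(self) -> np.ndarray:
        return np.sort(np.concatenate(list(self.train_by_class.values())))

    @property
    def test_indices(self) -> np.ndarray:
        return np.sort(np.concatenate(list(self.test_by_class.values())))


def stratified_split(
    labels: Sequence[int],
    train_fraction: float,
    seed: int = 0,
    table_matching: bool = False,
) -> SplitPlan:
    """Per-class shuffled train/test allocation.

    Plain mode rounds each class's training count half-up to
    ``train_fraction * n_class`` (per-class proportions within one sample of
    the global fraction).  Table-matching mode instead reproduces the test-set
    class counts implied by the benchmark tables — (8, 5, 7) at 0.8 and
    (13, 9, 8) at 0.7 — and requires class counts (35, 32, 33).
    """
    labels = np.asarray(labels)
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    classes = np.unique(labels)
    counts = {int(c): int((labels == c).sum()) for c in classes}
    if any(v < 2 for v in counts.values()):
        raise ValueError("every class needs at least 2 samples to split")

    if table_matching:
        frac = round(train_fraction, 2)
        if frac not in TABLE_TEST_COUNTS:
            raise ValueError("table-matching mode supports train fractions 0.8 and 0.7")
        if tuple(counts.get(c, 0) for c in (0, 1, 2)) != (35, 32, 33):
            raise ValueError(
                "table-matching mode requires class counts (35, 32, 33)"
            )
        test_counts = {c: TABLE_TEST_COUNTS[frac][c] for c in (0, 1, 2)}
    else:
        test_counts = {}
        for c, n_c in counts.items():
            n_train = int(np.floor(train_fraction * n_c + 0.5))
            n_train = min(max(n_train, 1), n_c - 1)
            test_counts[c] = n_c - n_train

    rng = np.random.default_rng(seed)
    train_by_class, test_by_class = {}, {}
    for c in sorted(counts):
        idx = np.flatnonzero(labels == c)
        idx = rng.permutation(idx)
        n_test = test_counts[c]
        test_by_class[c] = np.sort(idx[:n_test])
        train_by_class[c] = np.sort(idx[n_test:])
    return SplitPlan(
        train_fraction=train_fraction,
        train_by_class=train_by_class,
        test_by_class=test_by_class,
        seed=seed,
        table_matching=table_matching,
    )


def write_image_directory(dataset: SyntheticDataset, root: str | Path) -> Path:
    """Write ``<root>/<class_name>/<sample>.png`` plus ``manifest.csv``."""
    root = Path(root)
    paths = []
    for i in range(dataset.n_samples):
        cls = dataset.class_names[dataset.labels[i]]
        cls_dir = root / cls
        cls_dir.mkdir(parents=True, exist_ok=True)
        arr = (dataset.images[i] * 255).round().astype(np.uint8)
        path = cls_dir / f"{dataset.manifest.sample_id[i]}.png"
        Image.fromarray(arr, mode="L").save(path)
        paths.append(os.path.relpath(path, root))
    manifest = dataset.manifest.assign(path=paths)
    manifest.to_csv(root / "manifest.csv", index=False)
    return root


def load_image_directory(root: str | Path) -> SyntheticDataset:
    """Load a ``<class_name>/<image>`` tree (or its manifest) back into arrays."""
    root = Path(root)
    manifest_path = root / "manifest.csv"
    records = []
    if manifest_path.exists():
        manifest = pd.read_csv(manifest_path)
        for _, row in manifest.iterrows():
            records.append((row["sample_id"], row["class_name"], root / row["path"]))
    else:
        for cls in sorted(p.name for p in root.iterdir() if p.is_dir()):
            for path in sorted((root / cls).iterdir()):
                records.append((path.stem, cls, path))
    if not records:
        raise ValueError(f"no images found under {root}")
    names = sorted({cls for _, cls, _ in records})
    order = {c: i for i, c in enumerate(names)}
    # keep the canonical ordering when the canonical names are present
    if set(names) <= set(CLASS_NAMES):
        names = [c for c in CLASS_NAMES if c in names]
        order = {c: i for i, c in enumerate(names)}
    images, labels, ids = [], [], []
    for sample_id, cls, path in records:
        images.append(np.asarray(Image.open(path).convert("L"), dtype=float) / 255.0)
        labels.append(order[cls])
        ids.append(sample_id)
    manifest = pd.DataFrame(
        {"sample_id": ids, "label": labels, "class_name": [names[l] for l in labels]}
    )
    return SyntheticDataset(
        images=np.stack(images),
        labels=np.asarray(labels),
        class_names=tuple(names),
        manifest=manifest,
    )
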