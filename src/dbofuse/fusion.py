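"""Entropy-based fusion of multi-backbone features.

Each backbone contributes a feature matrix; the Shannon entropy of its pooled
absolute-activation distribution measures how evenly information is spread
across its feature channels.  Backbones with a richer (higher-entropy)
activation profile receive a larger fusion weight.  Weights are applied as
scalar multipliers on each backbone's block before column-wise concatenation,
so the fused representation keeps every channel while re-balancing the
contribution of each source.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .backbones import BackboneSpec, extract_features, get_backbone

__all__ = [
    "FeatureBundle",
    "entropy_weights",
    "fuse",
    "EntropyFusedFeatures",
    "default_backbone_specs",
    "save_features",
    "load_features",
]


@dataclass
class FeatureBundle:
    """Per-backbone feature matrices together with the fused representation."""

    per_backbone: list[tuple[str, np.ndarray]]
    weights: np.ndarray
    fused: np.ndarray

    def __post_init__(self) -> None:
        if abs(float(self.weights.sum()) - 1.0) > 1e-9:
            raise ValueError("fusion weights must sum to 1")
        if self.fused.shape[1] != sum(m.shape[1] for _, m in self.per_backbone):
            raise ValueError("fused width must equal the sum of backbone widths")


def entropy_weights(per_backbone_features: Sequence[np.ndarray]) -> np.ndarray:
    """Normalized-entropy fusion weights, one per backbone, summing to 1.

    For each backbone the absolute activations are pooled over samples (column
    means of ``|F|``), normalized to a probability vector ``p`` over feature
    channels, and scored by the Shannon entropy ``H = -sum p log p`` divided by
    ``log(dim)`` so that ``H`` is 1 for a perfectly uniform profile and 0 for a
    one-hot profile.  Weights are ``H_b / sum_b H_b``.

    An all-zero feature matrix carries no preference among channels and is
    assigned the uniform-entropy score 1 with a warning.
    """
    mats = [np.asarray(m, dtype=float) for m in per_backbone_features]
    if len(mats) == 0:
        raise ValueError("need at least one backbone feature matrix")
    entropies = []
    for m in mats:
        if m.ndim != 2 or m.shape[1] < 1:
            raise ValueError("each feature matrix must be 2-D with >= 1 column")
        pooled = np.abs(m).mean(axis=0)
        total = pooled.sum()
        if total == 0.0:
            warnings.warn(
                "all-zero feature matrix; assigning uniform entropy", stacklevel=2
            )
            entropies.append(1.0)
            continue
        p = pooled / total
        nz = p[p > 0]
        h = -(nz * np.log(nz)).sum()
        denom = np.log(p.size) if p.size > 1 else 1.0
        entropies.append(float(h / denom) if p.size > 1 else 1.0)
    entropies = np.asarray(entropies)
    if entropies.sum() == 0.0:
        return np.full(len(mats), 1.0 / len(mats))
    return entropies / entropies.sum()


def fuse(
    per_backbone_features: Sequence[np.ndarray], weights: Sequence[float]
) -> np.ndarray:
    """Concatenate backbone feature blocks column-wise after scaling block ``b``
    by ``weights[b]``."""
    mats = [np.asarray(m, dtype=float) for m in per_backbone_features]
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (len(mats),):
        raise ValueError("need exactly one weight per backbone")
    rows = {m.shape[0] for m in mats}
    if len(rows) != 1:
        raise ValueError(f"row-count mismatch across backbones: {sorted(rows)}")
    return np.concatenate([w * m for w, m in zip(weights, mats)], axis=1)


def default_backbone_specs(
    n_backbones: int = 3, feature_dim: int = 32, input_size: int = 64
) -> list[BackboneSpec]:
    """Three differently seeded surrogate backbones, the default desk-scale
    stand-ins for ResNet18 / DenseNet201 / Inception-ResNet-v2."""
    return [
        BackboneSpec(
            name="surrogate_tiny",
            feature_dim=feature_dim,
            input_size=input_size,
            seed=101 + 37 * i,
        )
        for i in range(n_backbones)
    ]


class EntropyFusedFeatures(TransformerMixin, BaseEstimator):
    """Transformer: images -> entropy-weighted fused feature matrix.

    Parameters
    ----------
    backbones : list of BackboneSpec, optional
        Extractors to fuse; defaults to three seeded surrogate backbones.

    Attributes
    ----------
    weights_ : ndarray
        Per-backbone entropy fusion weights learned on the fit images.
    feature_dims_ : list of int
        Width of each backbone block in the fused output.
    backbone_names_ : list of str
    """

    def __init__(self, backbones: list[BackboneSpec] | None = None):
        self.backbones = backbones

    def _specs(self) -> list[BackboneSpec]:
        return self.backbones if self.backbones is not None else default_backbone_specs()

    def _extract(self, X) -> list[np.ndarray]:
        return [extract_features(X, spec) for spec in self._specs()]

    def fit(self, X, y=None):
        mats = self._extract(X)
        self.weights_ = entropy_weights(mats)
        self.feature_dims_ = [m.shape[1] for m in mats]
        self.backbone_names_ = [s.name for s in self._specs()]
        self.n_features_out_ = int(sum(self.feature_dims_))
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "weights_")
        return fuse(self._extract(X), self.weights_)

    def bundle(self, X) -> FeatureBundle:
        """Extract, weight and fuse, returning all intermediate matrices."""
        check_is_fitted(self, "weights_")
        mats = self._extract(X)
        return FeatureBundle(
            per_backbone=list(zip(self.backbone_names_, mats)),
            weights=self.weights_,
            fused=fuse(mats, self.weights_),
        )


def save_features(path, per_backbone: Sequence[tuple[str, np.ndarray]]) -> None:
    """Round-trip feature matrices to a TSV with ``backbone:index`` headers."""
    names, mats = zip(*per_backbone)
    header = "\t".join(
        f"{name}:{j}" for name, m in per_backbone for j in range(m.shape[1])
    )
    full = np.concatenate(mats, axis=1)
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for row in full:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def load_features(path) -> list[tuple[str, np.ndarray]]:
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        data = np.array(
            [[float(v) for v in line.split("\t")] for line in fh if line.strip()]
        )
    out: list[tuple[str, np.ndarray]] = []
    cols: list[int] = []
    current = None
    for j, name_idx in enumerate(header):
        name = name_idx.rsplit(":", 1)[0]
        if name != current:
            if current is not None:
                out.append((current, data[:, cols]))
            current, cols = name, []
        cols.append(j)
    if current is not None:
        out.append((current, data[:, cols]))
    return out
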