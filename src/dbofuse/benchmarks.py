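"""Worked-example confusion matrices for a published three-class lung CT
benchmark (100 samples: 35 normal, 32 benign, 33 malignant).

The benchmark reports per-class one-vs-rest metrics for the training and
testing portions of an 80:20 and a 70:30 split.  Because precision and
sensitivity fix the per-class denominators, those printed percentages uniquely
determine every cell of the underlying confusion matrices; the matrices below
were reconstructed by that enumeration and reproduce all sixty printed values.
They serve as the ground-truth fixture for the evaluation stack.
"""

from __future__ import annotations

import numpy as np

from .evaluation import ConfusionMatrix

__all__ = ["CLASS_NAMES", "BENCHMARK_MATRICES", "benchmark_matrix"]

CLASS_NAMES = ("normal", "benign", "malignant")

#: keyed by (train_fraction, phase); phase is "train" or "test"
BENCHMARK_MATRICES: dict[tuple[float, str], ConfusionMatrix] = {
    (0.8, "train"): ConfusionMatrix(
        counts=np.array([[27, 0, 0], [0, 27, 0], [1, 0, 25]]),
        class_names=CLASS_NAMES,
    ),
    (0.8, "test"): ConfusionMatrix(
        counts=np.array([[7, 0, 1], [0, 5, 0], [0, 0, 7]]),
        class_names=CLASS_NAMES,
    ),
    (0.7, "train"): ConfusionMatrix(
        counts=np.array([[21, 0, 1], [0, 23, 0], [0, 0, 25]]),
        class_names=CLASS_NAMES,
    ),
    (0.7, "test"): ConfusionMatrix(
        counts=np.array([[11, 1, 1], [0, 9, 0], [0, 0, 8]]),
        class_names=CLASS_NAMES,
    ),
}


def benchmark_matrix(train_fraction: float, phase: str) -> ConfusionMatrix:
    """Return the reconstructed benchmark confusion matrix for a split phase."""
    key = (round(train_fraction, 2), phase)
    if key not in BENCHMARK_MATRICES:
        raise KeyError(
            f"no benchmark matrix for fraction {train_fraction} phase {phase!r}"
        )
    return BENCHMARK_MATRICES[key]
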