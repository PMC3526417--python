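"""Presence calling, normalization, and fold-change computation.

Normalization is per-array median scaling: each array (sample column) is
multiplied by a constant so that its median equals the global median of
per-array medians.  This is a deliberate simplification of invariant-set
style array rescaling; it is idempotent and preserves within-array ratios,
which is all the downstream contracts rely on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .formats_io import ExpressionMatrix, FormatError

#: default presence-call threshold on the linear intensity scale
DEFAULT_DETECTION_THRESHOLD = 100.0


@dataclass
class DetectionMatrix:
    """Per-gene, per-sample presence calls at a fixed linear threshold."""

    calls: pd.DataFrame  # boolean, same shape as source matrix
    threshold: float

    def expressed_genes(self) -> list[str]:
        mask = self.calls.any(axis=1)
        return list(self.calls.index[mask])


def detect_expressed(
    matrix: ExpressionMatrix, threshold: float = DEFAULT_DETECTION_THRESHOLD
) -> tuple[DetectionMatrix, list[str]]:
    """Call a gene expressed iff its intensity is >= threshold in >= 1 sample."""
    if matrix.scale != "linear":
        raise FormatError("detect_expressed requires a linear-scale matrix")
    calls = matrix.values >= threshold
    det = DetectionMatrix(calls=calls, threshold=threshold)
    return det, det.expressed_genes()


def normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each array so its median equals the global median of medians."""
    if matrix.scale != "linear":
        raise FormatError("normalize requires a linear-scale matrix")
    vals = matrix.values.to_numpy(dtype=float)
    if (vals <= 0).all(axis=0).any():
        raise FormatError("an array is entirely non-positive; cannot scale")
    medians = np.median(vals, axis=0)
    if (medians <= 0).any():
        raise FormatError("non-positive per-array median; cannot scale")
    target = np.median(medians)
    scaled = vals * (target / medians)
    out = pd.DataFrame(scaled, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(out, matrix.samples, scale="linear")


def fold_change(
    matrix: ExpressionMatrix, group_a: Sequence[str], group_b: Sequence[str]
) -> pd.Series:
    """Per-gene ratio of linear group means, mean_a / mean_b.

    A ratio above 1 reads as induced in group A relative to group B.  A
    zero denominator yields ``inf`` (left to the caller to gate).
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise FormatError("fold_change groups must be non-empty")
    if set(group_a) & set(group_b):
        raise FormatError("fold_change groups must be disjoint")
    if matrix.scale != "linear":
        raise FormatError("fold_change requires a linear-scale matrix")
    mean_a = matrix.values[group_a].mean(axis=1)
    mean_b = matrix.values[group_b].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mean_a / mean_b
    fc = fc.replace(np.nan, 1.0)  # 0/0: no evidence either way
    fc.name = "fold_change"
    return fc
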