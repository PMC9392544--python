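"""Training-set augmentation by random same-class averaging.

Artificial segments are built by averaging a small number of randomly drawn
training segments of the same class and then re-injecting a small fraction
of raw time instances from one parent, so each synthetic epoch stays close
to the data manifold while adding sample diversity. The augmentation budget
is a fixed fraction of the training set per cross-validation fold
(default 2% x 10 folds = +20% total), applied inside each fold and never to
validation or test partitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .recording import SegmentTensor

__all__ = [
    "AugmentConfig", "augmented_total_size", "partition_sizes",
    "make_artificial_segments", "augment_training_partition",
]


@dataclass(frozen=True)
class AugmentConfig:
    """Augmentation parameters.

    fraction_per_fold
        Relative growth contributed per CV fold (default 0.02).
    n_folds
        Number of folds the per-fold fraction accumulates over (default 10).
    n_average
        Segments averaged into one artificial segment (>= 2).
    perturb_fraction
        Fraction of time instances per channel replaced by one parent's raw
        values after averaging (default 0.02).
    """

    fraction_per_fold: float = 0.02
    n_folds: int = 10
    n_average: int = 2
    perturb_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_per_fold <= 1.0:
            raise ValueError("fraction_per_fold must be in [0, 1]")
        if self.n_average < 2:
            raise ValueError("n_average must be >= 2")
        if not 0.0 <= self.perturb_fraction <= 1.0:
            raise ValueError("perturb_fraction must be in [0, 1]")
        if self.n_folds < 1:
            raise ValueError("n_folds must be >= 1")


def augmented_total_size(n_segments: int, cfg: AugmentConfig) -> int:
    """Total dataset size after accumulating the per-fold growth.

    ``ceil(n * (1 + fraction_per_fold * n_folds))``: the growth fraction
    accumulates once per fold, and any fractional segment is rounded up.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    total = n_segments * (1.0 + cfg.fraction_per_fold * cfg.n_folds)
    # round to 1e-6 first so exact products are not pushed up by float noise
    return math.ceil(round(total, 6))


def partition_sizes(total: int, n_folds: int = 10) -> tuple[int, int]:
    """(train+validation, test) sizes for one fold of ``total`` segments."""
    test = round(total / n_folds)
    return total - test, test


def _per_class_counts(labels: np.ndarray, k: int) -> dict[int, int]:
    """Allocate ``k`` artificial segments across classes proportionally
    (largest-remainder rounding)."""
    classes, counts = np.unique(labels, return_counts=True)
    quotas = k * counts / counts.sum()
    base = np.floor(quotas).astype(int)
    remainder = k - base.sum()
    order = np.argsort(-(quotas - base))
    for i in order[:remainder]:
        base[i] += 1
    return dict(zip(classes.tolist(), base.tolist()))


def make_artificial_segments(train: SegmentTensor, k: int,
                             cfg: AugmentConfig) -> SegmentTensor:
    """Create ``k`` artificial segments by same-class random averaging.

    Each artificial segment is the element-wise mean of ``cfg.n_average``
    distinct same-class training segments; then ``cfg.perturb_fraction`` of
    time instances per channel are replaced by the corresponding values of
    one randomly chosen parent. Provenance records the parent row indices.
    Deterministic given ``cfg.seed``.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return SegmentTensor.empty(train.segment_len, train.n_channels)
    labels = train.labels
    class_counts = _per_class_counts(labels, k)
    for cls, _ in class_counts.items():
        if (labels == cls).sum() < cfg.n_average:
            raise ValueError(
                f"class {cls} has fewer than n_average={cfg.n_average} training segments")

    rng = np.random.default_rng(cfg.seed)
    seg_len, n_ch = train.segment_len, train.n_channels
    n_perturb = int(round(cfg.perturb_fraction * seg_len))
    data = np.empty((k, seg_len, n_ch), dtype=train.data.dtype)
    rows = []
    j = 0
    for cls in sorted(class_counts):
        pool = np.flatnonzero(labels == cls)
        for _ in range(class_counts[cls]):
            parents = rng.choice(pool, size=cfg.n_average, replace=False)
            seg = train.data[parents].mean(axis=0)
            if n_perturb:
                donor = train.data[parents[rng.integers(cfg.n_average)]]
                for ch in range(n_ch):
                    idx = rng.choice(seg_len, size=n_perturb, replace=False)
                    seg[idx, ch] = donor[idx, ch]
            data[j] = seg
            rows.append({
                "subject_id": "", "session": "", "condition": "",
                "label": int(cls), "source_offset": -1,
                "is_artificial": True,
                "parent_ids": ";".join(str(p) for p in parents),
            })
            j += 1
    return SegmentTensor(data, pd.DataFrame(rows))


def augment_training_partition(train: SegmentTensor,
                               cfg: AugmentConfig) -> SegmentTensor:
    """Grow a training partition to its augmented total size.

    Appends ``augmented_total_size(n, cfg) - n`` artificial segments,
    allocated across classes proportionally to the training class mix, and
    returns real + artificial segments concatenated (real first).
    """
    if train.n_segments == 0:
        raise ValueError("training partition is empty")
    k = augmented_total_size(train.n_segments, cfg) - train.n_segments
    art = make_artificial_segments(train, k, cfg)
    return SegmentTensor.concatenate([train, art])
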