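"""Calibration/validation splitting and descriptive statistics.

The split is the deterministic rank-ordered 2:1 scheme common in soil
spectroscopy: sort samples by ascending SOM, form consecutive triplets,
send one member of each complete triplet to the validation set and the
other two to calibration.  168 samples thus yield 112 calibration and 56
validation samples, with both sets spanning the full SOM range and no
randomness involved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import SoilDataset

__all__ = ["SplitResult", "DescriptiveStats", "rank_order_split", "describe", "anova_p"]


@dataclass
class SplitResult:
    calibration: SoilDataset
    validation: SoilDataset
    assignment: dict  # sample_id -> "calibration" | "validation"


@dataclass
class DescriptiveStats:
    """Summary statistics in the conventional soil-survey layout."""

    n: int
    min: float
    mean: float
    max: float
    std: float       # n-1 denominator
    iqr: float       # Q3 - Q1, linear-interpolation quantiles
    cv_percent: float  # 100 * std / mean
    skewness: float    # bias-corrected moment skewness
    kurtosis: float    # bias-corrected, non-excess (normal ~ 3)


def rank_order_split(dataset: SoilDataset, validation_member: int = 2) -> SplitResult:
    """Rank-ordered 2:1 split of a dataset by SOM content.

    Samples are sorted ascending by (SOM, sample_id); each complete
    consecutive triplet contributes one member (by default the middle,
    ``validation_member=2``; configurable to 1 or 3) to the validation set
    and two to calibration.  Leftover samples (n mod 3) go to calibration.
    Original sample order is preserved within each output set.
    """
    n = dataset.n_samples
    if n < 3:
        raise ValueError("rank-ordered split needs at least 3 samples")
    if validation_member not in (1, 2, 3):
        raise ValueError("validation_member must be 1, 2 or 3")
    order = sorted(range(n), key=lambda i: (dataset.som[i], dataset.sample_ids[i]))
    val_rows = set()
    for start in range(0, n - n % 3, 3):
        val_rows.add(order[start + validation_member - 1])
    cal_idx = [i for i in range(n) if i not in val_rows]
    val_idx = [i for i in range(n) if i in val_rows]
    assignment = {
        dataset.sample_ids[i]: ("validation" if i in val_rows else "calibration")
        for i in range(n)
    }
    return SplitResult(
        calibration=dataset.subset(cal_idx),
        validation=dataset.subset(val_idx),
        assignment=assignment,
    )


def describe(values: np.ndarray) -> DescriptiveStats:
    """Min / mean / max / SD / IQR / CV% / skewness / kurtosis of a vector.

    SD uses the n-1 denominator; IQR uses linear-interpolation quantiles
    (the "type 7" convention); skewness and kurtosis are bias-corrected
    moment estimators, with kurtosis reported on the non-excess scale
    (normal distribution ~ 3).
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("describe needs at least 2 values")
    mean = float(np.mean(v))
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    std = float(np.std(v, ddof=1))
    q1, q3 = np.percentile(v, [25, 75])
    if std == 0:
        skew = 0.0
        kurt = 0.0
    else:
        skew = float(stats.skew(v, bias=False))
        kurt = float(stats.kurtosis(v, fisher=False, bias=False))
    return DescriptiveStats(
        n=int(v.size),
        min=float(np.min(v)),
        mean=mean,
        max=float(np.max(v)),
        std=std,
        iqr=float(q3 - q1),
        cv_percent=100.0 * std / mean,
        skewness=skew,
        kurtosis=kurt,
    )


def anova_p(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """One-way fixed-effects ANOVA p-value for two groups.

    With two groups this equals the two-sided pooled-variance t-test.
    Degenerate case (zero variance in both groups, equal means) returns
    p = 1 by convention.
    """
    a = np.asarray(group_a, dtype=float).ravel()
    b = np.asarray(group_b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    _, p = stats.f_oneway(a, b)
    return float(p)
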