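"""Inter- and intra-rater agreement: Dice overlap and intraclass correlation.

Manual SN delineation is the main operator-dependent step of the pipeline;
agreement between raters is summarized spatially (Dice coefficient of the
mask pair) and at the measurement level (ICC of the per-subject values
produced by each rater).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["RatingsMatrix", "dice", "icc"]


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|) of two same-shaped boolean masks."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    size = int(a.sum()) + int(b.sum())
    if size == 0:
        raise ValueError("Dice undefined: both masks empty")
    return 2.0 * int((a & b).sum()) / size


@dataclass(frozen=True)
class RatingsMatrix:
    """Subjects x raters grid of one measurement (no missing cells)."""

    values: np.ndarray
    measure_name: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("ratings must be a 2-D subjects x raters array")
        n, k = values.shape
        if n < 2 or k < 2:
            raise ValueError("need at least 2 subjects and 2 raters")
        if not np.all(np.isfinite(values)):
            raise ValueError("ratings contain missing or non-finite cells")
        object.__setattr__(self, "values", values)


def icc(ratings: RatingsMatrix, form: str = "ICC2") -> float:
    """Intraclass correlation of a subjects x raters matrix.

    ``ICC2`` (default) is the two-way random-effects, absolute-agreement,
    single-rater coefficient ICC(2,1); ``ICC3`` is the two-way mixed,
    consistency form ICC(3,1). Both are computed from the two-way ANOVA
    mean squares:

        MSR (rows/subjects), MSC (columns/raters), MSE (residual)

        ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
        ICC(3,1) = (MSR - MSE) / (MSR + (k-1) MSE)

    A degenerate matrix with no between-subject variance yields a value
    <= 0 with a warning rather than an exception.
    """
    x = ratings.values
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    if form == "ICC2":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif form == "ICC3":
        denom = msr + (k - 1) * mse
    else:
        raise ValueError(f"unknown ICC form {form!r}; use 'ICC2' or 'ICC3'")
    if denom <= 0:
        warnings.warn("degenerate ratings matrix: no usable variance; ICC set to 0")
        return 0.0
    value = (msr - mse) / denom
    if value <= 0:
        warnings.warn(
            f"no between-subject variance relative to error (ICC = {value:.3g} <= 0)"
        )
    return float(value)
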