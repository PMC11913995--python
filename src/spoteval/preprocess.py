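"""Normalization and transformation applied before multivariate statistics.

Sum normalization (each sample column divided by its total signal) and a
log10 transform are the standard pre-treatment before PCA and volcano
analysis of feature tables.  Scoring and CV% profiling operate on the raw
intensities and must not receive normalized tables.
"""

from __future__ import annotations

import numpy as np

from .io_model import FeatureTable, ValidationError


def normalize_sum(table: FeatureTable) -> FeatureTable:
    """Divide every sample column by its column sum ("sum of the signals").

    Idempotent in value; scale-invariant per column.  Raises if the table
    is already flagged normalized or if any sample has zero total signal.
    """
    if table.normalized:
        raise ValidationError("table is already normalized")
    sums = table.intensities.sum(axis=0)
    zero = sums.index[sums <= 0].tolist()
    if zero:
        raise ValidationError(f"cannot sum-normalize all-zero sample(s): {zero}")
    return table.with_intensities(table.intensities / sums, normalized=True)


def log10_transform(table: FeatureTable, zero_policy: str = "half_min") -> FeatureTable:
    """log10-transform all intensities.

    Zeros (non-detected features) are handled per ``zero_policy``:

    * ``"half_min"`` — replaced by half the smallest positive value in the
      whole table before taking the log (common metabolomics practice);
    * ``"error"`` — raise, reporting how many cells are zero.
    """
    if table.log_transformed:
        raise ValidationError("table is already log-transformed")
    if zero_policy not in ("half_min", "error"):
        raise ValidationError(f"unknown zero_policy {zero_policy!r}")
    X = table.intensities.to_numpy(dtype=float, copy=True)
    if (X < 0).any():
        raise ValidationError("negative intensities cannot be log-transformed")
    zeros = X == 0
    n_zero = int(zeros.sum())
    if n_zero:
        if zero_policy == "error":
            raise ValidationError(f"{n_zero} zero cell(s) present with zero_policy='error'")
        positive = X[X > 0]
        if positive.size == 0:
            raise ValidationError("table has no positive values to anchor half_min")
        X[zeros] = positive.min() / 2.0
    out = table.intensities.copy()
    out.loc[:, :] = np.log10(X)
    return table.with_intensities(out, log_transformed=True)
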