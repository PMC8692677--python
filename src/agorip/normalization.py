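"""Library-size normalization by median-of-ratios size factors.

Each library's size factor is the median, over reference genes, of the
ratio of its count to the gene's geometric mean across libraries; factors
are then rescaled to geometric mean 1 so normalized counts live on a common
scale.  Reference genes are those with a nonzero count in every library —
important here because IgG-IP libraries can drop many genes to zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import DesignError


class SizeFactorError(ValueError):
    """Raised when size factors cannot be computed."""


def compute_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, geometric mean 1.

    Parameters
    ----------
    counts
        Gene × library integer count matrix.

    Returns
    -------
    pandas.Series
        One strictly positive factor per library, geometric mean 1.

    Raises
    ------
    SizeFactorError
        If the matrix is empty or no gene is nonzero in every library.
    """
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise SizeFactorError("cannot compute size factors of an empty count matrix")
    values = counts.to_numpy(dtype=float)
    reference = (values > 0).all(axis=1)
    if not reference.any():
        raise SizeFactorError(
            "no reference gene with nonzero counts in every library; "
            "median-of-ratios normalization is undefined"
        )
    ref = values[reference]
    geomean = np.exp(np.log(ref).mean(axis=1, keepdims=True))
    factors = np.median(ref / geomean, axis=0)
    factors /= np.exp(np.log(factors).mean())  # rescale to geometric mean 1
    return pd.Series(factors, index=counts.columns, name="size_factor")


def compute_size_factors_per_fraction(
    counts: pd.DataFrame, samples: pd.DataFrame
) -> pd.Series:
    """Median-of-ratios within each fraction's libraries.

    Capture efficiency differs sharply between fractions; per-fraction
    normalization removes it at the size-factor stage instead of relying on
    the contrasts to difference it out.  Factors are rescaled to geometric
    mean 1 within each fraction.
    """
    factors = pd.Series(index=counts.columns, dtype=float, name="size_factor")
    for fraction, group in samples.groupby("fraction"):
        cols = list(group["sample_id"])
        factors[cols] = compute_size_factors(counts[cols])
    if factors.isna().any():
        raise DesignError("sample sheet does not cover all count columns")
    return factors


def normalized_counts(counts: pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    """Counts divided by their library's size factor."""
    return counts / size_factors
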