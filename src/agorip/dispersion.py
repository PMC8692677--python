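"""Gene-wise negative-binomial dispersion estimation.

The count model throughout the package is NB with var = mu + alpha * mu**2.
Per gene, alpha is estimated by method of moments on size-factor-normalized
counts within each design cell (fraction × condition), pooled across cells
with df weights, and then shrunk toward a log-linear mean–dispersion trend
fitted across genes.  The trend is fitted on quantile-bin means of the
*unfloored* moment estimates so that the flooring at zero does not bias it
upward.  This is deliberately lighter-weight than the empirical-Bayes
machinery of the established differential-expression packages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .normalization import normalized_counts

logger = logging.getLogger(__name__)

_ALPHA_MAX = 10.0
_ALPHA_MIN = 1e-8


@dataclass(frozen=True)
class DispersionTrend:
    """Log-linear mean–dispersion trend: alpha(mu) = exp(b0 + b1*log(mu))."""

    intercept: float
    slope: float

    def __call__(self, mean: np.ndarray) -> np.ndarray:
        mean = np.maximum(np.asarray(mean, dtype=float), 1e-8)
        return np.clip(
            np.exp(self.intercept + self.slope * np.log(mean)),
            _ALPHA_MIN,
            _ALPHA_MAX,
        )


def _moment_estimates(
    norm: np.ndarray, cell_columns: list[np.ndarray]
) -> np.ndarray:
    """Unfloored df-weighted method-of-moments alpha per gene.

    For each design cell with r >= 2 libraries: alpha_hat = (v - m) / m^2
    with m, v the mean and unbiased variance of normalized counts; cells
    are combined with weights (r - 1).  Genes with zero mean in every
    multi-library cell get NaN.
    """
    n_genes = norm.shape[0]
    num = np.zeros(n_genes)
    den = np.zeros(n_genes)
    for cols in cell_columns:
        r = len(cols)
        if r < 2:
            continue
        block = norm[:, cols]
        m = block.mean(axis=1)
        v = block.var(axis=1, ddof=1)
        ok = m > 0
        est = np.zeros(n_genes)
        est[ok] = (v[ok] - m[ok]) / m[ok] ** 2
        num += np.where(ok, (r - 1) * est, 0.0)
        den += np.where(ok, r - 1, 0.0)
    with np.errstate(invalid="ignore"):
        raw = num / den
    raw[den == 0] = np.nan
    return raw


def fit_dispersion_trend(
    mean: np.ndarray, raw: np.ndarray, n_bins: int = 20
) -> DispersionTrend:
    """Fit the log-linear trend on quantile-bin means of raw estimates."""
    ok = np.isfinite(raw) & (mean > 0)
    if ok.sum() < 10:
        # too few genes to fit anything; flat trend at the median raw value
        level = float(np.nanmedian(np.clip(raw[ok], _ALPHA_MIN, _ALPHA_MAX))) if ok.any() else 0.05
        return DispersionTrend(np.log(max(level, _ALPHA_MIN)), 0.0)
    m, a = mean[ok], raw[ok]
    order = np.argsort(m)
    bins = np.array_split(order, min(n_bins, max(2, ok.sum() // 20)))
    bx, by = [], []
    for idx in bins:
        if len(idx) == 0:
            continue
        bx.append(np.log(m[idx].mean()))
        by.append(np.log(max(a[idx].mean(), _ALPHA_MIN)))
    if len(bx) < 2 or np.ptp(bx) < 1e-9:
        return DispersionTrend(by[0] if by else np.log(0.05), 0.0)
    slope, intercept = np.polyfit(bx, by, 1)
    return DispersionTrend(float(intercept), float(slope))


def estimate_dispersion(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    size_factors: pd.Series,
    *,
    shrinkage: float = 0.5,
    common_dispersion: float = 0.05,
    n_bins: int = 20,
) -> pd.Series:
    """Per-gene NB dispersion: moment estimates shrunk toward a trend.

    Parameters
    ----------
    shrinkage
        Weight of the trend in the convex combination with the gene-wise
        (floored) moment estimate; 0.5 splits the difference, 0 disables
        shrinkage, 1 uses the trend alone.
    common_dispersion
        Fallback when every design cell has a single library, so no
        empirical variance exists.

    Returns
    -------
    pandas.Series
        Finite nonnegative alpha per gene.
    """
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage weight must be in [0, 1]")
    norm = normalized_counts(counts, size_factors).to_numpy(dtype=float)
    positions = {s: i for i, s in enumerate(counts.columns)}
    cell_columns = [
        np.array([positions[s] for s in group["sample_id"]])
        for _, group in samples.groupby("cell")
    ]
    if all(len(c) < 2 for c in cell_columns):
        logger.warning(
            "every design cell has a single library; falling back to the "
            "common dispersion %.3g for all genes",
            common_dispersion,
        )
        return pd.Series(common_dispersion, index=counts.index, name="dispersion")
    raw = _moment_estimates(norm, cell_columns)
    mean = norm.mean(axis=1)
    trend = fit_dispersion_trend(mean, raw, n_bins=n_bins)
    trended = trend(mean)
    floored = np.clip(np.nan_to_num(raw, nan=0.0), 0.0, _ALPHA_MAX)
    alpha = (1.0 - shrinkage) * floored + shrinkage * trended
    alpha[~np.isfinite(alpha)] = common_dispersion
    return pd.Series(np.clip(alpha, 0.0, _ALPHA_MAX), index=counts.index, name="dispersion")
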