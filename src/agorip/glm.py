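"""Per-gene negative-binomial model of the six design cells.

The model is an NB GLM with log link, an offset of log(size factor), and
one coefficient per fraction × condition cell (a saturated one-hot design,
no intercept).  Because the design is one-hot, the likelihood separates by
cell: each coefficient solves an independent one-dimensional score equation

    sum_j (y_j - mu_j) / (1 + alpha * mu_j) = 0,   mu_j = s_j * exp(eta)

over that cell's libraries, and the expected-information matrix is
diagonal with I_c = sum_j mu_j / (1 + alpha * mu_j).  Fisher scoring on
eta is therefore run vectorized across all genes at once, which is what
makes genome-scale fits fast.  Coefficients and their covariance are
reported on the log2 scale, the unit in which contrasts are read as
log2 fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import CELL_ORDER, require_complete_design

LN2 = float(np.log(2.0))

_ETA_MIN, _ETA_MAX = -350.0, 350.0


@dataclass
class GeneFitTable:
    """Fitted six-cell NB models for a set of genes.

    Attributes
    ----------
    gene_ids
        Index of fitted genes.
    beta
        (n_genes, 6) cell-mean coefficients, log2 scale, columns in
        :data:`agorip.design.CELL_ORDER`.
    var
        (n_genes, 6) coefficient variances (log2 scale).  The one-hot
        design makes the coefficient covariance diagonal, so the variances
        carry the full covariance.
    dispersion
        Per-gene NB dispersion alpha used in the fit.
    converged
        Per-gene convergence flag (all six cells converged).
    zero_cell_adjusted
        Genes that had an all-zero design cell and received the
        stabilizing pseudocount before fitting.
    """

    gene_ids: pd.Index
    beta: np.ndarray
    var: np.ndarray
    dispersion: np.ndarray
    converged: np.ndarray
    zero_cell_adjusted: np.ndarray

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def covariance(self, gene_id: str) -> np.ndarray:
        """6×6 coefficient covariance (log2 scale) for one gene."""
        i = self.gene_ids.get_loc(gene_id)
        return np.diag(self.var[i])

    def beta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.beta, index=self.gene_ids, columns=list(CELL_ORDER))


def fit_gene_models(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    size_factors: pd.Series,
    dispersion: pd.Series,
    *,
    zero_cell_pseudocount: float = 0.5,
    max_iter: int = 100,
    tol: float = 1e-12,
) -> GeneFitTable:
    """Fit the six-cell NB GLM for every gene.

    Genes with an all-zero design cell would have a cell mean of zero
    (coefficient at -infinity); such genes get ``zero_cell_pseudocount``
    added to every library's count before fitting and are flagged, which
    keeps their contrasts finite.  Non-convergence is flagged per gene,
    never fatal.
    """
    require_complete_design(samples)
    y = counts.to_numpy(dtype=float)
    positions = {s: i for i, s in enumerate(counts.columns)}
    cell_cols = {
        cell: np.array([positions[s] for s in group["sample_id"]])
        for cell, group in samples.groupby("cell")
    }
    alpha = dispersion.reindex(counts.index).to_numpy(dtype=float)[:, None]
    sf = size_factors.reindex(counts.columns).to_numpy(dtype=float)

    zero_cell = np.zeros(y.shape[0], dtype=bool)
    for cols in cell_cols.values():
        zero_cell |= (y[:, cols] == 0).all(axis=1)
    y = y.copy()
    y[zero_cell] += zero_cell_pseudocount

    n_genes = y.shape[0]
    beta = np.empty((n_genes, 6))
    var = np.empty((n_genes, 6))
    converged = np.ones(n_genes, dtype=bool)

    for c, cell in enumerate(CELL_ORDER):
        cols = cell_cols[cell]
        yc = y[:, cols]
        s = sf[cols][None, :]
        # Fisher scoring on eta = log(cell mean), vectorized over genes
        eta = np.log(np.maximum(yc.sum(axis=1), 1e-12) / s.sum())
        cell_conv = np.zeros(n_genes, dtype=bool)
        info = np.empty(n_genes)
        for _ in range(max_iter):
            mu = s * np.exp(np.clip(eta, _ETA_MIN, _ETA_MAX))[:, None]
            denom = 1.0 + alpha * mu
            score = ((yc - mu) / denom).sum(axis=1)
            info = (mu / denom).sum(axis=1)
            step = score / np.maximum(info, 1e-300)
            step = np.clip(step, -10.0, 10.0)
            eta = np.clip(eta + step, _ETA_MIN, _ETA_MAX)
            cell_conv = np.abs(step) < tol
            if cell_conv.all():
                break
        converged &= cell_conv
        beta[:, c] = eta / LN2
        var[:, c] = 1.0 / np.maximum(info, 1e-300) / LN2**2

    return GeneFitTable(
        gene_ids=counts.index,
        beta=beta,
        var=var,
        dispersion=alpha[:, 0],
        converged=converged,
        zero_cell_adjusted=zero_cell,
    )
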