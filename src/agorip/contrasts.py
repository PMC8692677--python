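"""The three Ago-RIP contrasts, their Wald tests, and replicate-wise values.

Writing the six cell means (log2 scale) as input_ctrl, input_mir, igg_ctrl,
igg_mir, ago_ctrl, ago_mir, the target-identification contrasts are

* C1 — IgG-adjusted IP enrichment difference:
  (ago_mir − igg_mir) − (ago_ctrl − igg_ctrl).
  Corrects Ago-IP enrichment for nonspecific bead/antibody binding.
* C2 — input-adjusted IP enrichment difference:
  (ago_mir − input_mir) − (ago_ctrl − input_ctrl).
  Corrects IP enrichment for secondary transcriptome changes after mimic
  transfection.
* C3 — total-lysate expression change: input_mir − input_ctrl.
  Direct targets are degraded, so C3 is expected negative.
* D  — IgG condition contrast: igg_ctrl − igg_mir.  With
  condition-independent background D is null, which yields the exact
  algebraic closure C1 = C2 + C3 + D for any coefficient vector.

A direct target is expected to show C1 > 0, C2 > 0, C3 < 0.

Each contrast is a weight vector w over the coefficients; the pooled
estimate is wᵀβ with squared standard error wᵀ Σ w, tested against zero
with an asymptotic (standard normal) Wald test.  Per-replicate values are
the same linear combinations of log2(normalized count + pseudocount) of
the single library in each cell of that replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import CELL_ORDER, replicate_completeness
from .glm import GeneFitTable
from .normalization import normalized_counts


class DegenerateFitError(RuntimeError):
    """A contrast with zero standard error but nonzero estimate."""


@dataclass(frozen=True)
class ContrastSpec:
    """A named linear contrast over the six cell-mean coefficients."""

    name: str
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.weights) != 6:
            raise ValueError("contrast weights must cover the 6 design cells")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)


def _w(**cells: float) -> tuple[float, ...]:
    return tuple(float(cells.get(c, 0.0)) for c in CELL_ORDER)


#: Preset contrasts, keyed by name.
PRESETS: dict[str, ContrastSpec] = {
    "C1": ContrastSpec("C1", _w(ago_mir=1, igg_mir=-1, ago_ctrl=-1, igg_ctrl=1)),
    "C2": ContrastSpec("C2", _w(ago_mir=1, input_mir=-1, ago_ctrl=-1, input_ctrl=1)),
    "C3": ContrastSpec("C3", _w(input_mir=1, input_ctrl=-1)),
    "D": ContrastSpec("D", _w(igg_ctrl=1, igg_mir=-1)),
}

DEFAULT_CONTRASTS = ("C1", "C2", "C3")


def get_contrast(spec: str | ContrastSpec) -> ContrastSpec:
    if isinstance(spec, ContrastSpec):
        return spec
    try:
        return PRESETS[spec]
    except KeyError:
        raise KeyError(
            f"unknown contrast {spec!r}; presets are {sorted(PRESETS)}"
        ) from None


def evaluate_contrasts(
    fit: GeneFitTable,
    specs: tuple[str | ContrastSpec, ...] = DEFAULT_CONTRASTS,
    *,
    on_degenerate: str = "raise",
) -> pd.DataFrame:
    """Pooled contrast estimates with Wald tests, tidy one row per gene×contrast.

    Columns: gene_id, contrast, estimate (log2FC), se, wald_z, p, converged.
    By convention se == 0 with estimate == 0 gives z = 0 and p = 1; se == 0
    with a nonzero estimate is a degenerate fit (raised or NaN-flagged
    according to ``on_degenerate``).
    """
    if on_degenerate not in ("raise", "flag"):
        raise ValueError("on_degenerate must be 'raise' or 'flag'")
    frames = []
    for spec in specs:
        spec = get_contrast(spec)
        w = spec.as_array()
        est = fit.beta @ w
        se = np.sqrt(fit.var @ (w**2))
        degenerate = (se == 0) & (est != 0)
        if degenerate.any():
            if on_degenerate == "raise":
                genes = list(fit.gene_ids[degenerate][:10])
                raise DegenerateFitError(
                    f"zero standard error with nonzero {spec.name} estimate "
                    f"for gene(s) {genes}"
                )
            est = est.copy()
            est[degenerate] = np.nan
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, est / se, 0.0)
        p = 2.0 * stats.norm.sf(np.abs(z))
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": fit.gene_ids,
                    "contrast": spec.name,
                    "estimate": est,
                    "se": se,
                    "wald_z": z,
                    "p": p,
                    "converged": fit.converged,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def per_replicate_contrasts(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    size_factors: pd.Series,
    *,
    pseudocount: float = 1.0,
    specs: tuple[str | ContrastSpec, ...] = DEFAULT_CONTRASTS,
) -> pd.DataFrame:
    """Replicate-wise contrast values from single-library log2 counts.

    For each replicate, each design cell contributes
    log2(normalized count + pseudocount) of its one library; replicates
    missing any required cell yield NaN (non-evaluable).

    Returns a tidy frame: gene_id, contrast, replicate, value.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    norm = normalized_counts(counts, size_factors)
    completeness = replicate_completeness(samples)
    by_rep_cell = {
        (row.replicate, row.cell): row.sample_id for row in samples.itertuples()
    }
    frames = []
    for rep in completeness.index:
        cols = [by_rep_cell.get((rep, cell)) for cell in CELL_ORDER]
        if None in cols:
            x = None  # replicate lacks a design cell: non-evaluable
        else:
            with np.errstate(divide="ignore"):
                x = np.log2(norm[cols].to_numpy() + pseudocount)
        for spec in specs:
            spec = get_contrast(spec)
            if x is None:
                value = np.full(len(counts.index), np.nan)
            else:
                value = x @ spec.as_array()
            frames.append(
                pd.DataFrame(
                    {
                        "gene_id": counts.index,
                        "contrast": spec.name,
                        "replicate": rep,
                        "value": value,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


@dataclass
class ContrastAnalysis:
    """Bundled output of the contrast engine for one dataset."""

    pooled: pd.DataFrame
    per_replicate: pd.DataFrame
    fit: GeneFitTable
    size_factors: pd.Series
    dispersion: pd.Series
    contrasts: tuple[str, ...] = field(default=DEFAULT_CONTRASTS)

    def to_table(self) -> pd.DataFrame:
        """Wide per-gene table: estimate/se/z/p per contrast plus the
        semicolon-joined per-replicate estimates."""
        wide = self.pooled.pivot(index="gene_id", columns="contrast")
        out = pd.DataFrame(index=wide.index)
        for name in self.contrasts:
            out[f"{name}_estimate"] = wide[("estimate", name)]
            out[f"{name}_se"] = wide[("se", name)]
            out[f"{name}_z"] = wide[("wald_z", name)]
            out[f"{name}_p"] = wide[("p", name)]
        reps = (
            self.per_replicate.sort_values("replicate")
            .groupby(["gene_id", "contrast"])["value"]
            .agg(lambda v: ";".join(f"{x:.6g}" for x in v))
            .unstack("contrast")
        )
        for name in self.contrasts:
            out[f"{name}_replicates"] = reps[name]
        out["converged"] = pd.Series(
            self.fit.converged, index=self.fit.gene_ids
        ).reindex(out.index)
        return out.reset_index()
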