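"""End-to-end orchestration: counts + sample sheet -> contrasts -> calls.

:func:`analyze_counts` is the in-memory entry point used by tests and the
acceptance benchmarks; :func:`run_pipeline` wraps it with file input,
validation-before-computation, and a self-describing run directory
(config snapshot, TSV tables, JSON summary, log).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .calling import CascadeReport, call_targets, tumor_overexpression_filter
from .contrasts import (
    DEFAULT_CONTRASTS,
    ContrastAnalysis,
    evaluate_contrasts,
    per_replicate_contrasts,
)
from .design import require_complete_design, validate_counts, validate_samples
from .dispersion import estimate_dispersion
from .glm import fit_gene_models
from .io import (
    load_validated,
    read_cohort,
    read_truth,
    write_json,
    write_yaml,
)
from .normalization import compute_size_factors, compute_size_factors_per_fraction
from .simulate import score_recovery

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run; serialized with every run."""

    counts: str = ""
    sample_sheet: str = ""
    truth: str | None = None
    cohort: str | None = None
    alpha: float = 0.05
    p_contrasts: tuple[str, ...] = ("C1", "C2")
    adjust: str = "none"  # or "bh"
    normalization_scope: str = "global"  # or "per_fraction"
    zero_cell_pseudocount: float = 0.5
    replicate_pseudocount: float = 1.0
    missing_replicate_policy: str = "strict"
    dispersion_shrinkage: float = 0.5
    tumor_test_alpha: float = 0.05
    seed: int = 0
    outdir: str = "agorip_run"

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.normalization_scope not in ("global", "per_fraction"):
            raise ValueError("normalization_scope must be 'global' or 'per_fraction'")
        if self.missing_replicate_policy not in ("strict", "available"):
            raise ValueError("missing_replicate_policy must be 'strict' or 'available'")
        if self.zero_cell_pseudocount <= 0 or self.replicate_pseudocount < 0:
            raise ValueError("pseudocounts must be positive / nonnegative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["p_contrasts"] = list(self.p_contrasts)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "p_contrasts" in d:
            d["p_contrasts"] = tuple(d["p_contrasts"])
        return cls(**d)


@dataclass
class PipelineResult:
    analysis: ContrastAnalysis
    calls: pd.DataFrame
    report: CascadeReport
    summary: dict = field(default_factory=dict)


def analyze_counts(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    *,
    config: PipelineConfig | None = None,
) -> ContrastAnalysis:
    """Run the contrast engine: normalize, estimate dispersion, fit, test."""
    config = config or PipelineConfig()
    config.validate()
    samples = validate_samples(samples)
    counts = validate_counts(counts, samples)
    require_complete_design(samples)
    if config.normalization_scope == "per_fraction":
        size_factors = compute_size_factors_per_fraction(counts, samples)
    else:
        size_factors = compute_size_factors(counts)
    dispersion = estimate_dispersion(
        counts, samples, size_factors, shrinkage=config.dispersion_shrinkage
    )
    fit = fit_gene_models(
        counts,
        samples,
        size_factors,
        dispersion,
        zero_cell_pseudocount=config.zero_cell_pseudocount,
    )
    pooled = evaluate_contrasts(fit, DEFAULT_CONTRASTS)
    per_rep = per_replicate_contrasts(
        counts,
        samples,
        size_factors,
        pseudocount=config.replicate_pseudocount,
        specs=DEFAULT_CONTRASTS,
    )
    return ContrastAnalysis(
        pooled=pooled,
        per_replicate=per_rep,
        fit=fit,
        size_factors=size_factors,
        dispersion=dispersion,
    )


def call_from_analysis(
    analysis: ContrastAnalysis,
    *,
    config: PipelineConfig | None = None,
    cohort: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, CascadeReport]:
    """Apply the calling cascade (and cohort prioritization if given)."""
    config = config or PipelineConfig()
    calls, report = call_targets(
        analysis.pooled,
        analysis.per_replicate,
        alpha=config.alpha,
        p_contrasts=tuple(config.p_contrasts),
        policy=config.missing_replicate_policy,
        adjust=config.adjust,
    )
    if cohort is not None:
        calls = tumor_overexpression_filter(
            calls, cohort, report, test_alpha=config.tumor_test_alpha
        )
    return calls, report


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-based run: validate inputs, compute, write a run directory."""
    config.validate()
    counts, samples = load_validated(config.counts, config.sample_sheet)
    require_complete_design(samples)
    cohort = read_cohort(config.cohort) if config.cohort else None
    truth = read_truth(config.truth) if config.truth else None

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("agorip")
    root.addHandler(handler)
    old_level, old_propagate = root.level, root.propagate
    root.setLevel(logging.INFO)
    root.propagate = False  # run.log carries the detail; the CLI echoes the summary
    try:
        logger.info("agorip %s: %d genes, %d libraries", __version__, *counts.shape)
        analysis = analyze_counts(counts, samples, config=config)
        calls, report = call_from_analysis(analysis, config=config, cohort=cohort)
        logger.info("%s", report)

        summary = {
            "version": __version__,
            "n_genes": int(counts.shape[0]),
            "n_libraries": int(counts.shape[1]),
            "seed": config.seed,
            "cascade": report.counts(),
            "n_not_converged": int((~analysis.fit.converged).sum()),
            "n_zero_cell_adjusted": int(analysis.fit.zero_cell_adjusted.sum()),
        }
        if truth is not None:
            score = score_recovery(calls, truth, tier="significant_target")
            summary["recovery"] = {
                "tier": score.tier,
                "sensitivity": score.sensitivity,
                "precision": score.precision,
                "fdr": score.fdr,
                "n_called": score.n_called,
            }

        analysis.to_table().to_csv(outdir / "contrasts.tsv", sep="\t", index=False)
        calls.to_csv(outdir / "calls.tsv", sep="\t", index=False)
        report.to_frame().to_csv(outdir / "cascade.tsv", sep="\t", index=False)
        write_json(summary, outdir / "summary.json")
        write_yaml({"pipeline": config.to_dict()}, outdir / "config.yaml")
    finally:
        root.removeHandler(handler)
        root.setLevel(old_level)
        root.propagate = old_propagate
        handler.close()
    return PipelineResult(analysis=analysis, calls=calls, report=report, summary=summary)
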