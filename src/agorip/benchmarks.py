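"""Simulation benchmarks of the full pipeline.

The study's raw sequencing libraries are not publicly deposited, so the
pipeline's operating characteristics are established on synthetic
experiments with known truth: null calibration of the Wald test and the
sign rule, recovery of planted targets (effect-size regression,
sensitivity, empirical FDR), rejection of partial-criteria decoys, and
closed-form oracle agreement of the contrast estimates in the
low-dispersion, high-count limit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .contrasts import PRESETS, evaluate_contrasts
from .design import CELL_ORDER, validate_samples
from .normalization import normalized_counts
from .pipeline import analyze_counts, call_from_analysis
from .simulate import SimulationConfig, score_recovery, simulate_experiment


def null_calibration(seed: int, n_genes: int = 5000) -> dict:
    """No planted effects: C2 Wald false-positive rate at p < 0.05 and the
    fraction of genes surviving the replicate sign rule."""
    sim = simulate_experiment(SimulationConfig(n_genes=n_genes, seed=seed))
    analysis = analyze_counts(sim.counts, sim.samples)
    calls, report = call_from_analysis(analysis)
    p2 = analysis.pooled.loc[analysis.pooled["contrast"] == "C2", "p"]
    return {
        "n_genes": n_genes,
        "c2_fpr": float((p2 < 0.05).mean()),
        "step1_fraction": report.counts()["step1_sign_consistent"] / n_genes,
    }


def recovery_benchmark(
    seed: int, n_genes: int = 2000, with_decoys: bool = False
) -> dict:
    """Planted-target benchmark: 5% direct targets (plus optionally 5% of
    each decoy class), depth 2e6 per library, three replicates."""
    config = SimulationConfig(
        n_genes=n_genes,
        depth=2e6,
        target_fraction=0.05,
        decoy_down_fraction=0.05 if with_decoys else 0.0,
        decoy_bound_fraction=0.05 if with_decoys else 0.0,
        seed=seed,
    )
    sim = simulate_experiment(config)
    analysis = analyze_counts(sim.counts, sim.samples)
    calls, report = call_from_analysis(analysis)
    score = score_recovery(calls, sim.truth, tier="significant_target")

    truth = sim.truth.set_index("gene_id")
    c2 = (
        analysis.pooled.loc[analysis.pooled["contrast"] == "C2"]
        .set_index("gene_id")["estimate"]
    )
    targets = truth.index[truth["class"] == "target"]
    slope = float(np.polyfit(truth.loc[targets, "gamma2"], c2[targets], 1)[0])

    out = {
        "n_genes": n_genes,
        "n_targets": int(len(targets)),
        "c2_slope": slope,
        "sensitivity": score.sensitivity,
        "fdr": 0.0 if np.isnan(score.fdr) else score.fdr,
        "n_called": score.n_called,
        "cascade": report.counts(),
    }
    if with_decoys:
        merged = calls.set_index("gene_id").join(truth)
        for cls in ("decoy_down", "decoy_bound"):
            sub = merged[merged["class"] == cls]
            out[f"{cls}_step1_rejection"] = float(
                (~sub["passed_sign_all_reps"]).mean()
            )
    return out


def oracle_equivalence(seed: int, n_genes: int = 300) -> dict:
    """Dispersion-free, high-count limit: pooled contrasts against direct
    log2 ratios of normalized group means, and the algebraic closure
    C1 = C2 + C3 + D of the fitted coefficients."""
    config = SimulationConfig(
        n_genes=n_genes,
        depth=2e6,
        baseline_log2_sd=0.5,
        target_fraction=0.1,
        dispersion_asymptote=0.0,
        dispersion_scale=0.0,
        seed=seed,
    )
    sim = simulate_experiment(config)
    analysis = analyze_counts(sim.counts, sim.samples)
    samples = validate_samples(sim.samples)
    norm = normalized_counts(sim.counts, analysis.size_factors)
    log_means = np.column_stack(
        [
            np.log2(
                norm[samples.loc[samples["cell"] == cell, "sample_id"]]
                .mean(axis=1)
                .to_numpy()
            )
            for cell in CELL_ORDER
        ]
    )
    min_cell_mean = float(
        min(
            norm[samples.loc[samples["cell"] == cell, "sample_id"]].mean(axis=1).min()
            for cell in CELL_ORDER
        )
    )
    max_dev = 0.0
    for name in ("C1", "C2", "C3"):
        oracle = log_means @ PRESETS[name].as_array()
        est = (
            analysis.pooled.loc[analysis.pooled["contrast"] == name]
            .set_index("gene_id")["estimate"]
            .reindex(sim.counts.index)
            .to_numpy()
        )
        max_dev = max(max_dev, float(np.abs(oracle - est).max()))

    pooled = evaluate_contrasts(analysis.fit, ("C1", "C2", "C3", "D"))
    piv = pooled.pivot(index="gene_id", columns="contrast", values="estimate")
    identity_dev = float(
        np.abs(piv["C1"] - (piv["C2"] + piv["C3"] + piv["D"])).max()
    )
    return {
        "n_genes": n_genes,
        "min_cell_mean": min_cell_mean,
        "max_contrast_oracle_dev": max_dev,
        "max_identity_dev": identity_dev,
    }
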