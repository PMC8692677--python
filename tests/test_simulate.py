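import numpy as np
import pandas as pd
import pytest

from agorip.design import CELL_ORDER, validate_counts, validate_samples
from agorip.simulate import (
    CLASSES,
    ConfigError,
    RecoveryScore,
    SimulationConfig,
    score_recovery,
    simulate_experiment,
)


def test_shape_contract_one_gene_one_replicate():
    sim = simulate_experiment(SimulationConfig(n_genes=1, n_replicates=1, seed=0))
    assert sim.counts.shape == (1, 6)
    assert len(sim.samples) == 6
    assert set(sim.samples["fraction"] + "_" + sim.samples["condition"]) == set(
        CELL_ORDER
    )


def test_output_is_valid_pipeline_input():
    sim = simulate_experiment(SimulationConfig(n_genes=50, seed=1))
    samples = validate_samples(sim.samples)
    counts = validate_counts(sim.counts, samples)
    assert counts.shape == (50, 18)


def test_same_seed_reproduces_byte_identical_outputs():
    a = simulate_experiment(SimulationConfig(n_genes=100, target_fraction=0.1, seed=5))
    b = simulate_experiment(SimulationConfig(n_genes=100, target_fraction=0.1, seed=5))
    assert a.counts.to_csv() == b.counts.to_csv()
    assert a.truth.to_csv() == b.truth.to_csv()
    c = simulate_experiment(SimulationConfig(n_genes=100, target_fraction=0.1, seed=6))
    assert a.counts.to_csv() != c.counts.to_csv()


def test_truth_classes_and_gamma_signs():
    sim = simulate_experiment(
        SimulationConfig(
            n_genes=1000,
            target_fraction=0.1,
            decoy_down_fraction=0.1,
            decoy_bound_fraction=0.1,
            seed=2,
        )
    )
    truth = sim.truth
    assert set(truth["class"]) == set(CLASSES)
    t = truth[truth["class"] == "target"]
    assert (t["gamma2"] > 0).all() and (t["gamma3"] < 0).all()
    assert (t["gamma2"] + t["gamma3"] > 0).all()  # planted C1 > 0
    d = truth[truth["class"] == "decoy_down"]
    assert (d["gamma2"] == 0).all() and (d["gamma3"] < 0).all()
    b = truth[truth["class"] == "decoy_bound"]
    assert (b["gamma2"] > 0).all() and (b["gamma3"] == 0).all()
    n = truth[truth["class"] == "null"]
    assert (n[["gamma2", "gamma3"]] == 0).all().all()


def test_generative_mean_fidelity_at_high_depth():
    """Empirical per-cell totals track the generative library means within
    2% at depth 1e7 and dispersion ~0.01."""
    config = SimulationConfig(
        n_genes=500,
        depth=1e7,
        dispersion_asymptote=0.01,
        dispersion_scale=0.0,
        target_fraction=0.1,
        seed=3,
    )
    sim = simulate_experiment(config)
    for sample in sim.counts.columns:
        ratio = sim.counts[sample].sum() / sim.library_means[sample].sum()
        assert abs(ratio - 1.0) < 0.02
    # and per-gene, averaged over the genes: ratio near 1 in every cell
    rel = (sim.counts / sim.library_means).to_numpy()
    assert np.allclose(rel.mean(axis=0), 1.0, atol=0.02)


def test_expected_contrast_structure_in_library_means():
    """E[C2] = gamma2, E[C3] = gamma3, E[C1] = gamma2 + gamma3 at the level
    of generative means (within-library composition)."""
    config = SimulationConfig(n_genes=200, target_fraction=0.25, seed=4,
                              libsize_log2_sd=0.0)
    sim = simulate_experiment(config)
    mu = sim.library_means
    log2 = np.log2(mu[[f"{c}_r1" for c in CELL_ORDER]].to_numpy())
    truth = sim.truth.set_index("gene_id")
    # composition renormalization adds a gene-independent per-library shift;
    # difference it out with the null genes' median
    def contrast(w):
        v = log2 @ np.array(w)
        return v - np.median(v[(truth["class"] == "null").to_numpy()])

    from agorip.contrasts import PRESETS

    c1 = contrast(PRESETS["C1"].weights)
    c2 = contrast(PRESETS["C2"].weights)
    c3 = contrast(PRESETS["C3"].weights)
    is_t = (truth["class"] == "target").to_numpy()
    assert np.allclose(c2[is_t], truth.loc[is_t, "gamma2"], atol=0.02)
    assert np.allclose(c3[is_t], truth.loc[is_t, "gamma3"], atol=0.02)
    assert np.allclose(
        c1[is_t], truth.loc[is_t, "gamma2"] + truth.loc[is_t, "gamma3"], atol=0.02
    )


def test_pool_mass_allocation_shrinks_ip_libraries():
    config = SimulationConfig(n_genes=200, depth=1e5, depth_allocation="pool_mass",
                              seed=5)
    sim = simulate_experiment(config)
    totals = sim.counts.sum()
    igg = totals[[s for s in totals.index if s.startswith("igg")]].mean()
    inp = totals[[s for s in totals.index if s.startswith("input")]].mean()
    assert igg / inp < 0.1  # background_ratio default 0.05, plus noise


@pytest.mark.parametrize(
    "bad",
    [
        dict(target_fraction=0.7, decoy_down_fraction=0.4),
        dict(capture_ratio=0.0),
        dict(depth=-1),
        dict(n_genes=0),
        dict(depth_allocation="even"),
        dict(gamma3_range=(-0.3, -1.5)),
    ],
)
def test_invalid_configs_rejected_before_sampling(bad):
    with pytest.raises(ConfigError):
        simulate_experiment(SimulationConfig(**bad))


# --- recovery scoring -------------------------------------------------------


def _calls(genes, called_genes):
    tier = ["significant_target" if g in called_genes else "rejected" for g in genes]
    return pd.DataFrame({"gene_id": genes, "tier": tier})


def _truth(genes, target_genes):
    cls = ["target" if g in target_genes else "null" for g in genes]
    return pd.DataFrame({"gene_id": genes, "class": cls})


def test_perfect_calls_score_perfectly():
    genes = [f"g{i}" for i in range(10)]
    targets = set(genes[:3])
    score = score_recovery(_calls(genes, targets), _truth(genes, targets))
    assert score.sensitivity == 1.0 and score.fdr == 0.0


def test_calling_everything_has_fdr_one_minus_target_fraction():
    genes = [f"g{i}" for i in range(20)]
    targets = set(genes[:5])
    score = score_recovery(_calls(genes, set(genes)), _truth(genes, targets))
    assert score.sensitivity == 1.0
    assert np.isclose(score.fdr, 1.0 - 5 / 20)


def test_no_calls_yields_nan_fdr():
    genes = [f"g{i}" for i in range(5)]
    score = score_recovery(_calls(genes, set()), _truth(genes, {genes[0]}))
    assert score.n_called == 0
    assert np.isnan(score.fdr) and np.isnan(score.precision)


def test_universe_mismatch_and_empty_truth_raise():
    genes = [f"g{i}" for i in range(5)]
    with pytest.raises(ValueError, match="universe"):
        score_recovery(_calls(genes, set()), _truth(genes[:4], set()))
    with pytest.raises(ValueError, match="empty"):
        score_recovery(_calls(genes, set()), _truth([], set()))


def test_confusion_counts_decoys_separately():
    genes = [f"g{i}" for i in range(6)]
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "class": ["target", "target", "decoy_down", "decoy_bound", "null", "null"],
        }
    )
    score = score_recovery(_calls(genes, {"g0", "g3"}), truth)
    assert isinstance(score, RecoveryScore)
    assert score.confusion.loc["target", True] == 1
    assert score.confusion.loc["decoy_bound", True] == 1
    assert score.confusion.loc["decoy_down", False] == 1
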