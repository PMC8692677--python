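import numpy as np
import pandas as pd
import pytest

from agorip.design import CELL_ORDER, validate_samples
from agorip.pipeline import analyze_counts, call_from_analysis
from agorip.simulate import SimulationConfig, simulate_experiment


def sample_sheet(n_replicates: int = 3) -> pd.DataFrame:
    rows = []
    for rep in range(1, n_replicates + 1):
        for cell in CELL_ORDER:
            fraction, condition = cell.rsplit("_", 1)
            rows.append(
                {
                    "sample_id": f"{cell}_r{rep}",
                    "fraction": fraction,
                    "condition": condition,
                    "replicate": rep,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_benchmark():
    """300-gene seeded experiment with 10% targets, analysed end to end."""
    sim = simulate_experiment(
        SimulationConfig(n_genes=300, target_fraction=0.10, depth=3e5, seed=7)
    )
    analysis = analyze_counts(sim.counts, sim.samples)
    calls, report = call_from_analysis(analysis)
    return sim, analysis, calls, report


@pytest.fixture
def toy_counts():
    """One replicate, one gene per pattern, unit size factors by symmetry."""
    samples = validate_samples(sample_sheet(1))
    counts = pd.DataFrame(
        {s: [100, 200, 50] for s in samples["sample_id"]},
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
    )
    return counts, samples


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)
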