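"""Synthetic Ago-RIP-Seq experiments with planted targets and decoys.

The generator emulates the 3-fraction × 2-condition × R-replicate library
design.  Per gene g with baseline abundance q_g, the pre-sequencing pool
composition of each design cell is

    input_ctrl: q            input_mir: q * 2**gamma3
    igg_ctrl:   q * bbg      igg_mir:   q * bbg   (condition-independent)
    ago_ctrl:   q * rho      ago_mir:   q * rho * 2**(gamma2 + gamma3)

with rho the Ago capture ratio and bbg the IgG background ratio.  Because
normalization and the contrasts remove library- and fraction-level scale,
the expected pooled contrasts are E[C2] = gamma2, E[C3] = gamma3 and
E[C1] = gamma2 + gamma3.

Planted classes: *targets* (gamma2 > 0, gamma3 < 0, gamma2 + gamma3 > 0 so
every contrast carries the expected sign), *decoy_down* (transcript
depleted but not Ago-enriched: gamma2 = 0, gamma3 < 0), *decoy_bound*
(Ago-enriched but not depleted: gamma2 > 0, gamma3 = 0), and *null*.

Counts are negative binomial (var = mu + alpha * mu**2) with dispersion
from a trend alpha(mu) = a0 + a1/mu, scaled by per-library size factors.
By default each library is sequenced to the same expected depth (equimolar
library pooling); ``depth_allocation="pool_mass"`` instead makes library
yield proportional to the immunoprecipitated pool mass, so IgG libraries
return only ~bbg of the input depth.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .design import CELL_ORDER

CLASSES = ("target", "decoy_down", "decoy_bound", "null")


class ConfigError(ValueError):
    """Invalid simulation configuration (raised before any sampling)."""


@dataclass
class SimulationConfig:
    """All knobs of the generator; the seed fixes every random draw."""

    n_genes: int = 2000
    n_replicates: int = 3
    depth: float = 2e6  # expected reads per library
    baseline_log2_mean: float = 4.0
    baseline_log2_sd: float = 1.2
    capture_ratio: float = 0.3  # rho: Ago pool vs input
    background_ratio: float = 0.05  # bbg: IgG pool vs input
    target_fraction: float = 0.0
    decoy_down_fraction: float = 0.0
    decoy_bound_fraction: float = 0.0
    gamma3_range: tuple[float, float] = (-1.5, -0.3)  # log2 input depletion
    gamma2_extra_range: tuple[float, float] = (0.2, 1.2)  # gamma2 = -gamma3 + U(...)
    dispersion_asymptote: float = 0.005  # a0 in alpha(mu) = a0 + a1/mu
    dispersion_scale: float = 1.0  # a1
    libsize_log2_sd: float = 0.2
    depth_allocation: str = "equimolar"  # or "pool_mass"
    igg_condition_log2_sd: float = 0.0  # >0: gene-specific condition-dependent IgG
    seed: int = 0

    def validate(self) -> None:
        fractions = (
            self.target_fraction + self.decoy_down_fraction + self.decoy_bound_fraction
        )
        if not all(
            0.0 <= f <= 1.0
            for f in (
                self.target_fraction,
                self.decoy_down_fraction,
                self.decoy_bound_fraction,
            )
        ) or fractions > 1.0:
            raise ConfigError(
                "class fractions must be in [0, 1] and sum to at most 1 "
                f"(got sum {fractions:g})"
            )
        if self.capture_ratio <= 0 or self.background_ratio <= 0:
            raise ConfigError("capture_ratio and background_ratio must be positive")
        if self.depth <= 0:
            raise ConfigError("depth must be positive")
        if self.n_genes < 1 or self.n_replicates < 1:
            raise ConfigError("need at least one gene and one replicate")
        if self.dispersion_asymptote < 0 or self.dispersion_scale < 0:
            raise ConfigError("dispersion trend parameters must be nonnegative")
        if self.depth_allocation not in ("equimolar", "pool_mass"):
            raise ConfigError(
                f"depth_allocation must be 'equimolar' or 'pool_mass', "
                f"got {self.depth_allocation!r}"
            )
        if not (self.gamma3_range[0] <= self.gamma3_range[1] <= 0):
            raise ConfigError("gamma3 range must be nonpositive and ordered")
        if self.gamma2_extra_range[0] > self.gamma2_extra_range[1]:
            raise ConfigError("gamma2_extra range must be ordered")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gamma3_range"] = list(d["gamma3_range"])
        d["gamma2_extra_range"] = list(d["gamma2_extra_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("gamma3_range", "gamma2_extra_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SimulatedExperiment:
    counts: pd.DataFrame
    samples: pd.DataFrame
    truth: pd.DataFrame
    library_means: pd.DataFrame = field(repr=False, default=None)


def _draw_gammas(
    rng: np.random.Generator, config: SimulationConfig, n: int
) -> tuple[np.ndarray, np.ndarray]:
    g3 = rng.uniform(*config.gamma3_range, n)
    g2 = -g3 + rng.uniform(*config.gamma2_extra_range, n)
    return g2, g3


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Generate counts, sample sheet and truth table for one experiment."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = pd.Index([f"G{i + 1:06d}" for i in range(n)], name="gene_id")

    n_target = int(round(n * config.target_fraction))
    n_down = int(round(n * config.decoy_down_fraction))
    n_bound = int(round(n * config.decoy_bound_fraction))
    cls = np.array(["null"] * n, dtype=object)
    order = rng.permutation(n)
    cls[order[:n_target]] = "target"
    cls[order[n_target : n_target + n_down]] = "decoy_down"
    cls[order[n_target + n_down : n_target + n_down + n_bound]] = "decoy_bound"

    gamma2 = np.zeros(n)
    gamma3 = np.zeros(n)
    is_t = cls == "target"
    g2, g3 = _draw_gammas(rng, config, int(is_t.sum()))
    gamma2[is_t], gamma3[is_t] = g2, g3
    is_d = cls == "decoy_down"
    gamma3[is_d] = rng.uniform(*config.gamma3_range, int(is_d.sum()))
    is_b = cls == "decoy_bound"
    g2b, _ = _draw_gammas(rng, config, int(is_b.sum()))
    gamma2[is_b] = g2b

    q = 2.0 ** rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n)
    rho, bbg = config.capture_ratio, config.background_ratio
    igg_mir_shift = (
        2.0 ** rng.normal(0.0, config.igg_condition_log2_sd, n)
        if config.igg_condition_log2_sd > 0
        else np.ones(n)
    )
    pool = {
        "input_ctrl": q,
        "input_mir": q * 2.0**gamma3,
        "igg_ctrl": q * bbg,
        "igg_mir": q * bbg * igg_mir_shift,
        "ago_ctrl": q * rho,
        "ago_mir": q * rho * 2.0 ** (gamma2 + gamma3),
    }

    n_lib = 6 * config.n_replicates
    libsize = 2.0 ** rng.normal(0.0, config.libsize_log2_sd, n_lib)
    libsize /= np.exp(np.mean(np.log(libsize)))  # geometric mean 1

    samples = []
    mu_cols = {}
    lib = 0
    input_mass = pool["input_ctrl"].sum()
    for rep in range(1, config.n_replicates + 1):
        for cell in CELL_ORDER:
            fraction, condition = cell.rsplit("_", 1)
            sample_id = f"{cell}_r{rep}"
            samples.append(
                {
                    "sample_id": sample_id,
                    "fraction": fraction,
                    "condition": condition,
                    "replicate": rep,
                }
            )
            if config.depth_allocation == "equimolar":
                scale = config.depth / pool[cell].sum()
            else:  # pool_mass: yield proportional to IP'd RNA mass
                scale = config.depth / input_mass
            mu_cols[sample_id] = pool[cell] * scale * libsize[lib]
            lib += 1
    samples = pd.DataFrame(samples)

    mu = pd.DataFrame(mu_cols, index=gene_ids)
    alpha = config.dispersion_asymptote + config.dispersion_scale / np.maximum(
        mu.to_numpy(), 1e-12
    )
    counts = _nb_draw(rng, mu.to_numpy(), alpha)
    counts = pd.DataFrame(counts, index=gene_ids, columns=mu.columns)

    truth = pd.DataFrame(
        {"class": cls, "gamma2": gamma2, "gamma3": gamma3}, index=gene_ids
    ).reset_index()
    return SimulatedExperiment(
        counts=counts, samples=samples, truth=truth, library_means=mu
    )


def _nb_draw(
    rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray
) -> np.ndarray:
    """NB(mu, var = mu + alpha mu^2) draws; alpha -> 0 degenerates to Poisson."""
    out = np.empty(mu.shape, dtype=np.int64)
    poisson = alpha <= 1e-12
    if poisson.any():
        out[poisson] = rng.poisson(mu[poisson])
    nb = ~poisson
    if nb.any():
        size = 1.0 / alpha[nb]
        p = size / (size + mu[nb])
        out[nb] = rng.negative_binomial(size, p)
    return out


@dataclass(frozen=True)
class RecoveryScore:
    """Recovery of planted targets by the calling cascade at a given tier."""

    tier: str
    sensitivity: float
    precision: float
    fdr: float  # NaN when nothing was called
    n_called: int
    confusion: pd.DataFrame  # planted class × called/not-called counts


def score_recovery(
    calls: pd.DataFrame, truth: pd.DataFrame, tier: str = "significant_target"
) -> RecoveryScore:
    """Score calls at ``tier`` (or better) against the planted truth."""
    if len(truth) == 0:
        raise ValueError("truth table is empty")
    from .calling import TIERS

    if tier not in TIERS[1:]:
        raise ValueError(f"tier must be one of {TIERS[1:]}, got {tier!r}")
    calls = calls.set_index("gene_id")
    truth = truth.set_index("gene_id")
    if set(calls.index) != set(truth.index):
        raise ValueError("calls and truth cover different gene universes")
    order = {t: i for i, t in enumerate(TIERS)}
    called = calls["tier"].map(order) >= order[tier]
    called = called.reindex(truth.index)
    is_target = truth["class"] == "target"

    n_called = int(called.sum())
    tp = int((called & is_target).sum())
    sensitivity = tp / int(is_target.sum()) if is_target.any() else float("nan")
    precision = tp / n_called if n_called else float("nan")
    fdr = 1.0 - precision if n_called else float("nan")
    confusion = (
        pd.crosstab(truth["class"], called.rename("called"))
        .reindex(index=list(CLASSES), fill_value=0)
        .reindex(columns=[False, True], fill_value=0)
    )
    return RecoveryScore(
        tier=tier,
        sensitivity=float(sensitivity),
        precision=float(precision),
        fdr=float(fdr),
        n_called=n_called,
        confusion=confusion,
    )
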