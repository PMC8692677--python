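"""Target calling: replicate-wise sign rule, Wald cut, cohort prioritization.

A gene is a *potential* direct target when every replicate shows the
expected contrast signs (C1 > 0, C2 > 0, C3 < 0), a *significant* target
when in addition the pooled Wald p-values of the configured enrichment
contrasts fall below alpha, and a *prioritized* target when it is also
overexpressed in tumor versus adjacent-normal tissue in a cohort table.
Survivor counts along these steps form the cascade report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test
from scipy import stats

logger = logging.getLogger(__name__)

TIERS = ("rejected", "potential_target", "significant_target", "prioritized_target")

#: Expected sign of each contrast for a direct target.
TARGET_SIGNS = {"C1": +1, "C2": +1, "C3": -1}


class CallingError(ValueError):
    """Invalid arguments or inputs to the calling cascade."""


@dataclass
class CascadeReport:
    """Ordered survivor counts of the filter cascade."""

    steps: list[tuple[str, int, str]] = field(default_factory=list)

    def add(self, name: str, survivors: int, criterion: str) -> None:
        if self.steps and survivors > self.steps[-1][1]:
            raise AssertionError(
                "cascade survivor counts must be non-increasing "
                f"({self.steps[-1][1]} -> {survivors} at {name})"
            )
        self.steps.append((name, survivors, criterion))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["step", "survivors", "criterion"])

    def counts(self) -> dict[str, int]:
        return {name: n for name, n, _ in self.steps}

    def __str__(self) -> str:
        lines = ["filter cascade:"]
        for name, n, criterion in self.steps:
            lines.append(f"  {name:<28s} {n:>7d}  ({criterion})")
        return "\n".join(lines)


def _tier_at_least(tier: pd.Series, level: str) -> pd.Series:
    order = {t: i for i, t in enumerate(TIERS)}
    return tier.map(order) >= order[level]


def call_targets(
    pooled: pd.DataFrame,
    per_replicate: pd.DataFrame,
    *,
    alpha: float = 0.05,
    p_contrasts: tuple[str, ...] = ("C1", "C2"),
    policy: str = "strict",
    adjust: str = "none",
) -> tuple[pd.DataFrame, CascadeReport]:
    """Apply the sign rule and the Wald cut; return calls and the cascade.

    Parameters
    ----------
    pooled, per_replicate
        Tidy outputs of the contrast engine.  Genes missing any of C1, C2,
        C3, or flagged non-converged, are excluded with a recorded reason.
    alpha
        Raw p-value cut for the significance step (the cascade's default
        operates on unadjusted p-values; set ``adjust="bh"`` for
        Benjamini–Hochberg).
    p_contrasts
        Which contrasts' Wald p-values must fall below alpha; the sign-only
        contrast C3 is deliberately not in the default set.
    policy
        ``"strict"`` requires every replicate evaluable and sign-consistent;
        ``"available"`` requires only the evaluable replicates (at least one).
    """
    if not 0.0 < alpha < 1.0:
        raise CallingError(f"alpha must be in (0, 1), got {alpha}")
    if policy not in ("strict", "available"):
        raise CallingError(f"unknown missing-replicate policy {policy!r}")
    if adjust not in ("none", "bh"):
        raise CallingError(f"unknown p-value adjustment {adjust!r}")
    needed = set(TARGET_SIGNS)
    if not needed <= set(pooled["contrast"].unique()):
        raise CallingError("pooled results must contain contrasts C1, C2 and C3")
    unknown = [c for c in p_contrasts if c not in set(pooled["contrast"])]
    if unknown:
        raise CallingError(f"p-value contrast(s) {unknown} absent from results")

    genes = pooled["gene_id"].drop_duplicates()
    calls = pd.DataFrame({"gene_id": genes}).set_index("gene_id")
    calls["excluded_reason"] = ""
    converged = pooled.groupby("gene_id")["converged"].all()
    calls.loc[~converged, "excluded_reason"] = "model did not converge"
    for gene in calls.index[~converged]:
        logger.info("gene %s excluded from calling: model did not converge", gene)

    # sign rule per replicate
    sign_ok_all = pd.Series(True, index=calls.index)
    evaluable_all = pd.Series(True, index=calls.index)
    any_evaluable = pd.Series(False, index=calls.index)
    for name, sign in TARGET_SIGNS.items():
        values = (
            per_replicate[per_replicate["contrast"] == name]
            .pivot(index="gene_id", columns="replicate", values="value")
            .reindex(calls.index)
        )
        ok = values * sign > 0
        evaluable = values.notna()
        calls[f"sign_ok_{name}"] = [
            ";".join(str(bool(v)).lower() for v in row) for row in ok.to_numpy()
        ]
        if policy == "strict":
            sign_ok_all &= ok.all(axis=1) & evaluable.all(axis=1)
        else:
            sign_ok_all &= (ok | ~evaluable).all(axis=1)
        evaluable_all &= evaluable.all(axis=1)
        any_evaluable |= evaluable.any(axis=1)
    if policy == "available":
        sign_ok_all &= any_evaluable

    calls["passed_sign_all_reps"] = sign_ok_all & (calls["excluded_reason"] == "")

    # Wald significance on the configured contrast set
    pmat = pooled.pivot(index="gene_id", columns="contrast", values="p").reindex(
        calls.index
    )
    passed_p = pd.Series(True, index=calls.index)
    for name in p_contrasts:
        p = pmat[name]
        if adjust == "bh":
            adj = np.full(len(p), np.nan)
            ok = p.notna().to_numpy()
            adj[ok] = stats.false_discovery_control(p.to_numpy()[ok], method="bh")
            p = pd.Series(adj, index=p.index)
        passed_p &= p < alpha
    calls["passed_pvalue"] = passed_p.fillna(False)
    calls["passed_tumor_filter"] = pd.array([pd.NA] * len(calls), dtype="boolean")

    tier = np.where(
        calls["passed_sign_all_reps"] & calls["passed_pvalue"],
        "significant_target",
        np.where(calls["passed_sign_all_reps"], "potential_target", "rejected"),
    )
    calls["tier"] = pd.Categorical(tier, categories=list(TIERS), ordered=True)

    report = CascadeReport()
    report.add("input", len(calls), "genes with evaluable C1/C2/C3")
    report.add(
        "step1_sign_consistent",
        int(calls["passed_sign_all_reps"].sum()),
        "C1>0, C2>0, C3<0 in every replicate",
    )
    report.add(
        "step2_significant",
        int(_tier_at_least(calls["tier"], "significant_target").sum()),
        f"Wald p < {alpha:g} on {'+'.join(p_contrasts)}"
        + (" (BH-adjusted)" if adjust == "bh" else ""),
    )
    return calls.reset_index(), report


def tumor_overexpression_filter(
    calls: pd.DataFrame,
    cohort: pd.DataFrame,
    report: CascadeReport | None = None,
    *,
    test_alpha: float = 0.05,
    require_significance: bool = True,
) -> pd.DataFrame:
    """Prioritize significant targets overexpressed in tumor tissue.

    ``cohort`` is tidy: columns gene_id, group ("tumor"/"normal"), value.
    A gene passes when mean(tumor) > mean(normal) and (optionally) a
    two-tailed two-sample Student t-test has p < ``test_alpha``.  Genes
    absent from the cohort, or with degenerate expression vectors, pass
    through flagged not-applicable with their tier unchanged.
    """
    if not 0.0 < test_alpha < 1.0:
        raise CallingError(f"test_alpha must be in (0, 1), got {test_alpha}")
    for col in ("gene_id", "group", "value"):
        if col not in cohort.columns:
            raise CallingError(f"cohort table lacks column {col!r}")
    calls = calls.copy().set_index("gene_id")
    grouped = {
        g: frame for g, frame in cohort.groupby("gene_id")
    }
    passed = []
    for gene in calls.index:
        frame = grouped.get(gene)
        if frame is None:
            passed.append(pd.NA)
            continue
        tumor = frame.loc[frame["group"] == "tumor", "value"].to_numpy(float)
        normal = frame.loc[frame["group"] == "normal", "value"].to_numpy(float)
        if len(tumor) < 2 or len(normal) < 2 or (tumor.var() == 0 and normal.var() == 0):
            passed.append(pd.NA)
            continue
        ok = tumor.mean() > normal.mean()
        if ok and require_significance:
            ok = bool(stats.ttest_ind(tumor, normal).pvalue < test_alpha)
        passed.append(bool(ok))
    calls["passed_tumor_filter"] = pd.array(passed, dtype="boolean")

    upgrade = (calls["tier"] == "significant_target") & (
        calls["passed_tumor_filter"].fillna(False).astype(bool)
    )
    tier = calls["tier"].astype(str)
    tier[upgrade] = "prioritized_target"
    calls["tier"] = pd.Categorical(tier, categories=list(TIERS), ordered=True)
    if report is not None:
        report.add(
            "step3_tumor_overexpressed",
            int((calls["tier"] == "prioritized_target").sum()),
            "mean(tumor) > mean(normal)"
            + (f", t-test p < {test_alpha:g}" if require_significance else ""),
        )
    return calls.reset_index()


@dataclass(frozen=True)
class SurvivalSplit:
    """Percentile dichotomization of a cohort plus its log-rank test."""

    labels: pd.Series  # "high"/"low" per patient
    statistic: float
    p_value: float
    threshold: float


def percentile_split_survival(
    table: pd.DataFrame, percentile: float = 50.0
) -> SurvivalSplit:
    """Split patients at an expression percentile; compare survival.

    Patients with expression at or above the percentile threshold are
    labelled ``high`` (ties to high, deterministically), the rest ``low``;
    the two Kaplan-Meier curves are compared with the standard two-group
    log-rank test (chi-square reference, 1 df).
    """
    if not 0.0 < percentile < 100.0:
        raise CallingError(f"percentile must be in (0, 100), got {percentile}")
    for col in ("time", "event", "expression"):
        if col not in table.columns:
            raise CallingError(f"survival table lacks column {col!r}")
    if (table["time"] < 0).any():
        raise CallingError("survival times must be nonnegative")
    if not table["event"].astype(bool).any():
        raise CallingError("log-rank test needs at least one event")
    expr = table["expression"].to_numpy(dtype=float)
    if np.all(expr == expr[0]):
        raise CallingError("all expression values identical; cannot split")
    threshold = float(np.percentile(expr, percentile))
    high = expr >= threshold
    if high.sum() < 2 or (~high).sum() < 2:
        raise CallingError(
            f"percentile {percentile:g} split leaves a group with <2 patients "
            f"({int(high.sum())} high / {int((~high).sum())} low)"
        )
    result = logrank_test(
        table.loc[high, "time"],
        table.loc[~high, "time"],
        event_observed_A=table.loc[high, "event"].astype(bool),
        event_observed_B=table.loc[~high, "event"].astype(bool),
    )
    labels = pd.Series(np.where(high, "high", "low"), index=table.index, name="group")
    return SurvivalSplit(
        labels=labels,
        statistic=float(result.test_statistic),
        p_value=float(result.p_value),
        threshold=threshold,
    )
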