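import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agorip.calling import (
    CallingError,
    call_targets,
    tumor_overexpression_filter,
)
from agorip.pipeline import analyze_counts, call_from_analysis


def make_results(per_rep: dict, p: dict, genes=("g1",)):
    """Build tidy pooled/per-replicate frames for one-gene scenarios."""
    pooled_rows, rep_rows = [], []
    for gene in genes:
        for contrast in ("C1", "C2", "C3"):
            values = per_rep[contrast]
            pooled_rows.append(
                {
                    "gene_id": gene,
                    "contrast": contrast,
                    "estimate": float(np.mean(values)),
                    "se": 0.1,
                    "wald_z": 0.0,
                    "p": p.get(contrast, 0.5),
                    "converged": True,
                }
            )
            for r, v in enumerate(values, start=1):
                rep_rows.append(
                    {"gene_id": gene, "contrast": contrast, "replicate": r, "value": v}
                )
    return pd.DataFrame(pooled_rows), pd.DataFrame(rep_rows)


def test_sign_consistent_significant_gene_reaches_significant_tier():
    pooled, per_rep = make_results(
        {"C1": (0.5, 0.4, 0.6), "C2": (0.3, 0.2, 0.5), "C3": (-0.4, -0.2, -0.1)},
        {"C1": 0.01, "C2": 0.01},
    )
    calls, report = call_targets(pooled, per_rep, alpha=0.05)
    assert calls.loc[0, "tier"] == "significant_target"
    assert report.counts()["step1_sign_consistent"] == 1


def test_single_wrong_sign_replicate_rejects_at_step1():
    pooled, per_rep = make_results(
        {"C1": (0.5, 0.4, 0.6), "C2": (0.3, 0.2, 0.5), "C3": (-0.4, -0.2, 0.05)},
        {"C1": 0.01, "C2": 0.01},
    )
    calls, report = call_targets(pooled, per_rep)
    assert calls.loc[0, "tier"] == "rejected"
    assert not calls.loc[0, "passed_sign_all_reps"]


def test_nonsignificant_sign_consistent_gene_stays_potential():
    pooled, per_rep = make_results(
        {"C1": (0.5, 0.4, 0.6), "C2": (0.3, 0.2, 0.5), "C3": (-0.4, -0.2, -0.1)},
        {"C1": 0.01, "C2": 0.20},
    )
    calls, _ = call_targets(pooled, per_rep, alpha=0.05)
    assert calls.loc[0, "tier"] == "potential_target"
    assert calls.loc[0, "passed_sign_all_reps"] and not calls.loc[0, "passed_pvalue"]


def test_missing_replicate_strict_vs_available_policy():
    pooled, per_rep = make_results(
        {"C1": (0.5, 0.4, np.nan), "C2": (0.3, 0.2, np.nan), "C3": (-0.4, -0.2, np.nan)},
        {"C1": 0.01, "C2": 0.01},
    )
    strict, _ = call_targets(pooled, per_rep, policy="strict")
    assert strict.loc[0, "tier"] == "rejected"
    available, _ = call_targets(pooled, per_rep, policy="available")
    assert available.loc[0, "tier"] == "significant_target"


def test_invalid_alpha_and_policy_raise():
    pooled, per_rep = make_results(
        {"C1": (0.5,), "C2": (0.3,), "C3": (-0.4,)}, {}
    )
    with pytest.raises(CallingError, match="alpha"):
        call_targets(pooled, per_rep, alpha=1.5)
    with pytest.raises(CallingError, match="policy"):
        call_targets(pooled, per_rep, policy="whatever")
    with pytest.raises(CallingError, match="C1, C2 and C3"):
        call_targets(pooled[pooled.contrast != "C3"], per_rep)


def test_cascade_counts_non_increasing(small_benchmark):
    _, _, _, report = small_benchmark
    counts = [n for _, n, _ in report.steps]
    assert counts == sorted(counts, reverse=True)


def test_raising_alpha_never_reduces_step2(small_benchmark):
    _, analysis, _, _ = small_benchmark
    survivors = []
    for alpha in (0.001, 0.01, 0.05, 0.2, 0.5):
        _, report = call_targets(
            analysis.pooled, analysis.per_replicate, alpha=alpha
        )
        survivors.append(report.counts()["step2_significant"])
    assert survivors == sorted(survivors)


def test_condition_swap_flips_all_former_targets(small_benchmark):
    """Relabelling mir <-> ctrl flips contrast signs: no step1 survivor of the
    original run survives the swapped run."""
    sim, _, calls, _ = small_benchmark
    swapped = sim.samples.copy()
    swapped["condition"] = swapped["condition"].map({"mir": "ctrl", "ctrl": "mir"})
    analysis = analyze_counts(sim.counts, swapped)
    swapped_calls, _ = call_from_analysis(analysis)
    before = set(calls.loc[calls["passed_sign_all_reps"], "gene_id"])
    after = set(swapped_calls.loc[swapped_calls["passed_sign_all_reps"], "gene_id"])
    assert not before & after


def test_bh_adjustment_is_more_conservative(small_benchmark):
    _, analysis, _, _ = small_benchmark
    raw, _ = call_targets(analysis.pooled, analysis.per_replicate, adjust="none")
    bh, _ = call_targets(analysis.pooled, analysis.per_replicate, adjust="bh")
    assert bh["passed_pvalue"].sum() <= raw["passed_pvalue"].sum()


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    p1=st.floats(1e-6, 1.0),
    p2=st.floats(1e-6, 1.0),
    signs=st.lists(st.sampled_from([1, -1]), min_size=9, max_size=9),
)
def test_tier_nesting_invariant(p1, p2, signs):
    """Whatever the inputs, tiers are nested: significant implies both
    sign-consistency and the p-value cut."""
    values = {
        "C1": tuple(0.3 * s for s in signs[0:3]),
        "C2": tuple(0.3 * s for s in signs[3:6]),
        "C3": tuple(-0.3 * s for s in signs[6:9]),
    }
    pooled, per_rep = make_results(values, {"C1": p1, "C2": p2})
    calls, report = call_targets(pooled, per_rep)
    row = calls.iloc[0]
    if row["tier"] in ("significant_target", "prioritized_target"):
        assert row["passed_sign_all_reps"] and row["passed_pvalue"]
    counts = [n for _, n, _ in report.steps]
    assert counts == sorted(counts, reverse=True)


# --- tumor overexpression filter -------------------------------------------


def pooled_student_t_oracle(a, b):
    """Two-sample pooled-variance Student t-test, two-tailed, by the direct
    textbook formula."""
    from scipy import stats as sps

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    return 2 * sps.t.sf(abs(t), na + nb - 2)


def cohort_frame(gene, tumor, normal):
    rows = [{"gene_id": gene, "group": "tumor", "value": v} for v in tumor]
    rows += [{"gene_id": gene, "group": "normal", "value": v} for v in normal]
    return pd.DataFrame(rows)


def significant_calls(genes=("g1",)):
    pooled, per_rep = make_results(
        {"C1": (0.5, 0.4, 0.6), "C2": (0.3, 0.2, 0.5), "C3": (-0.4, -0.2, -0.1)},
        {"C1": 0.01, "C2": 0.01},
        genes=genes,
    )
    return call_targets(pooled, per_rep)


def test_overexpressed_gene_is_prioritized():
    tumor, normal = (10, 11, 12, 13), (5, 5, 6, 6)
    assert pooled_student_t_oracle(tumor, normal) < 0.05  # oracle sanity
    calls, report = significant_calls()
    out = tumor_overexpression_filter(calls, cohort_frame("g1", tumor, normal), report)
    assert out.loc[0, "tier"] == "prioritized_target"
    assert report.counts()["step3_tumor_overexpressed"] == 1


def test_identical_tumor_normal_fails_mean_condition():
    calls, report = significant_calls()
    out = tumor_overexpression_filter(
        calls, cohort_frame("g1", (5, 6, 7), (5, 6, 7)), report
    )
    assert out.loc[0, "tier"] == "significant_target"
    assert out.loc[0, "passed_tumor_filter"] == False  # noqa: E712


def test_gene_absent_from_cohort_passes_through_na():
    calls, report = significant_calls()
    out = tumor_overexpression_filter(
        calls, cohort_frame("other_gene", (9, 9, 9), (1, 1, 1)), report
    )
    assert out.loc[0, "tier"] == "significant_target"
    assert pd.isna(out.loc[0, "passed_tumor_filter"])


def test_filter_significance_can_be_disabled():
    calls, _ = significant_calls()
    cohort = cohort_frame("g1", (10, 30), (9, 11))  # higher mean, p > 0.05
    strict = tumor_overexpression_filter(calls.copy(), cohort)
    relaxed = tumor_overexpression_filter(calls.copy(), cohort, require_significance=False)
    assert strict.loc[0, "tier"] == "significant_target"
    assert relaxed.loc[0, "tier"] == "prioritized_target"


def test_t_test_matches_direct_formula_oracle(rng):
    from scipy import stats as sps

    a = rng.normal(10, 2, 15)
    b = rng.normal(9, 2, 12)
    assert np.isclose(
        sps.ttest_ind(a, b).pvalue, pooled_student_t_oracle(a, b), atol=1e-12
    )
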