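# Methods

## Count model and contrasts

Each gene's counts across the 6·R libraries are modeled as negative
binomial with variance μ + αμ² (α ≥ 0 the gene's dispersion; α = 0 is the
Poisson limit). The mean structure is a saturated one-hot design over the
six fraction × condition cells with a log link and an offset of log(size
factor): one coefficient per cell, no intercept. Because the design is
one-hot, the likelihood separates by cell; each coefficient solves an
independent one-dimensional score equation and the coefficient covariance
is exactly diagonal. The fitter runs Fisher scoring on all genes
simultaneously (vectorized over the gene axis), which makes genome-scale
fits take well under a second; an independent cross-check against a
general-purpose GLM implementation (statsmodels, per gene, with offset) is
part of the test suite and agrees to ~1e-11 in both coefficients and
standard errors.

Coefficients are reported in log2 units. A contrast `w` has estimate
`wᵀβ`, standard error `√(wᵀΣw)`, and a two-sided p-value from the
standard-normal reference for `z = estimate/se` (asymptotic Wald; no
small-sample t correction). No multiple-testing adjustment is applied by
default because the cascade's significance step is defined on raw
p-values; Benjamini–Hochberg is available via configuration.

The preset contrasts C1 (IgG-adjusted enrichment difference), C2
(input-adjusted enrichment difference) and C3 (total-lysate change) are
given in the README. A fourth preset D = igg_ctrl − igg_mir (the IgG
condition contrast) completes the exact algebraic closure
C1 = C2 + C3 + D, which holds for any coefficient vector because it holds
for the weight vectors; it is asserted to 1e-8 on every fitted gene. D is
also a useful diagnostic: under condition-independent background binding
its expectation is zero, so a systematically nonzero D indicates
condition-dependent IgG capture.

## Normalization

Size factors use median-of-ratios: the factor of a library is the median,
over reference genes, of the ratio of its count to the gene's geometric
mean across libraries, with the median taken in ratio space and the
factors rescaled to geometric mean 1. Reference genes are those with no
zero count in any library — with IgG-IP libraries in the design this
matters, since many genes drop out of the background fraction.
Normalization is global across all libraries by default: the contrasts
difference out fraction-level capture efficiency, so a common scale is
sufficient and keeps the per-replicate values comparable across fractions.
Per-fraction normalization (median-of-ratios within each fraction,
rescaled to geometric mean 1 within the fraction) is available as a
configuration option for designs where composition differs so strongly
between fractions that a global reference set is thin.

## Dispersion

Per gene, α is estimated by method of moments on normalized counts within
each design cell that has at least two libraries — α̂ = (v − m)/m² with m,
v the cell mean and unbiased variance — pooled across cells with (r − 1)
weights. A log-linear mean–dispersion trend log α = b₀ + b₁ log μ is
fitted to quantile-bin means of the *unfloored* estimates (so that
flooring negative moment estimates at zero does not bias the trend
upward), and the final value is a 50/50 convex combination of the floored
gene-wise estimate and the trend (weight configurable). When every cell is
a singleton no empirical variance exists and a configured common
dispersion (default 0.05) is used with a logged warning. This is
deliberately lighter than the empirical-Bayes shrinkage of the established
differential-expression packages; the null-calibration benchmark (below)
shows it keeps the Wald test's size near nominal at three replicates.

## Replicate-wise sign rule and cascade

Per-replicate contrast values are computed from
log2(normalized count + pseudocount) of the single library in each cell,
combined with the same weight vectors. The pseudocount (default 1.0 on
normalized counts) bounds single-library log-ratios for weakly detected
genes; as it grows all per-replicate values shrink to zero, so it acts as
a damping parameter, and the default is the smallest integer value that
stabilizes IgG-absent genes. Genes with an all-zero design cell receive a
pseudocount of 0.5 on every count before the pooled fit (flagged
`zero_cell_adjusted`), keeping their contrasts finite.

The cascade: step 1 requires C1 > 0, C2 > 0 and C3 < 0 in every replicate
("strict" policy; the "available" policy requires only the evaluable
replicates when a replicate is missing a design cell). Step 2 requires
Wald p < α on C1 and C2 — the two enrichment claims; C3 participates as a
sign condition only, and the contrast set is configurable. Step 3 upgrades
significant targets whose cohort expression is higher in tumor than in
adjacent-normal tissue; "higher" is operationalized as a mean difference
together with a two-tailed pooled-variance Student t-test at α = 0.05 (the
significance requirement can be disabled for a pure mean comparison).
Genes absent from the cohort pass through flagged not-applicable. Survival
annotation splits patients at a configurable expression percentile
(patients exactly at the threshold go to the high group, which keeps the
split deterministic) and compares the groups with the standard two-group
log-rank test.

## Synthetic experiments

The generator emulates the 18-library design. Baseline abundances are
log2-normal (sd 1.2 — a realistic width for the expressed, analyzable
part of a transcriptome); the Ago pool carries ρ = 0.3 of input abundance
and the IgG pool β_bg = 0.05, with condition-independent background by
default (a gene-specific condition-dependent IgG shift is available to
stress-test C1). Planted effects: targets draw γ3 ~ U(−1.5, −0.3) and
γ2 = −γ3 + U(0.2, 1.2), so every target has positive expected C1;
depleted-only decoys have γ2 = 0, bound-only decoys γ3 = 0. Expected
pooled contrasts are E[C2] = γ2, E[C3] = γ3, E[C1] = γ2 + γ3.

Counts are NB draws with dispersion from the trend α(μ) = a₀ + a₁/μ
(defaults a₀ = 0.005, a₁ = 1.0, the regime of well-controlled cell-line
biological triplicates), scaled by per-library size factors (log2-normal,
sd 0.2, geometric mean 1). By default every library is sequenced to the
same expected depth — equimolar library pooling, the way multiplexed
libraries are actually loaded — so the fraction ratios ρ and β_bg shape
within-library composition, not library yield. The alternative
`pool_mass` allocation makes yield proportional to the immunoprecipitated
RNA mass (IgG libraries then return only ~β_bg of the input depth), which
is useful for studying how the pipeline degrades when background
libraries are under-sequenced: at realistic depths the per-replicate C1
sign rule loses substantial power in that regime.

What the generator does *not* emulate: positional binding, seed-match
biophysics, gene length and GC effects, correlated gene modules,
batch/replicate effects, and condition-dependent efficiency of the IP
itself. Passing benchmarks therefore demonstrate that the statistical
machinery recovers the generative model it assumes, not that any
particular biological dataset satisfies that model.

## Benchmarks and numerical choices

The benchmark suite (also recomputed by `scripts/acceptance.py`) runs, on
seeded experiments: (1) a 5000-gene null — the C2 Wald false-positive
rate at p < 0.05 stays within [0.03, 0.07] and fewer than 1 % of genes
survive the three-replicate sign rule; (2) a 2000-gene, 5 %-target
recovery benchmark at depth 2×10⁶ — the regression slope of pooled C2 on
planted γ2 lies in [0.9, 1.1], with sensitivity ≥ 0.80 and empirical
FDR ≤ 0.10 at the significant tier; (3) the same benchmark with 5 % of
each decoy class — ≥ 90 % of each class is rejected by the sign rule
alone (for bound-only decoys this sits near the theoretical value
1 − P(C1,C2 pass)·(1/2)³ ≈ 0.9, so it is the binding constraint of the
design); (4) a dispersion-free, high-count limit in which pooled
contrasts match direct log2 ratios of normalized group means within 0.05.
Problem sizes were chosen so the entire suite runs in seconds: the
vectorized fitter makes larger sizes cheap, but these are already enough
for the binomial error on every reported rate to be well inside the
stated bands.

Other numerical conventions: Fisher scoring runs to a step tolerance of
1e-12 (cap 100 iterations) with the convergence flag recorded per gene
and non-converged genes excluded from calling with a logged reason;
se = 0 with estimate = 0 yields p = 1 by convention, while se = 0 with a
nonzero estimate raises a degenerate-fit error; dispersion estimates are
clipped to [0, 10]; all randomness flows from a single recorded seed, and
identical inputs and configuration produce byte-identical outputs.

## Known limitations

The Wald test with plug-in (shrunken) dispersions is slightly liberal at
three replicates — the null benchmark measures ~5–6 % rejections at
nominal 5 %. The dispersion trend assumes a monotone log-linear
mean–dispersion relationship. The cascade's headline counts depend
strongly on sequencing depth of the IgG libraries; with `pool_mass`
allocation the sign rule on C1 dominates the error budget. The
literature-curation step that a practitioner would apply after
prioritization is intentionally out of scope: the package stops at the
prioritized-target tier.
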