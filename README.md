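# agorip

Identification of direct microRNA target genes from **Ago-RIP-Seq** count
data: negative-binomial linear contrasts over Argonaute-IP, IgG-IP and
input (total-lysate) sequencing fractions, Wald tests, replicate-wise sign
rules, and a prioritization cascade, with a synthetic-experiment generator
for benchmarking the whole pipeline against known truth.

## The problem

RNAs bound by miRNA-loaded Argonaute (RISC) complexes can be enriched by
Ago immunoprecipitation and sequenced. Comparing cells transfected with a
miRNA mimic against a negative-control mimic, a *direct* target of the
miRNA should be

1. more enriched in Ago-IP relative to the nonspecific IgG-IP background
   after mimic transfection (**C1 > 0**),
2. more enriched in Ago-IP relative to its own total-lysate abundance,
   which corrects for secondary transcriptome changes (**C2 > 0**), and
3. reduced in the total lysate, because bound targets are degraded
   (**C3 < 0**).

Writing the six design-cell means on the log2 scale
(`input_ctrl, input_mir, igg_ctrl, igg_mir, ago_ctrl, ago_mir`), the three
contrasts are

```
C1 = (ago_mir − igg_mir)   − (ago_ctrl − igg_ctrl)
C2 = (ago_mir − input_mir) − (ago_ctrl − input_ctrl)
C3 =  input_mir − input_ctrl
```

Genes are modeled per-gene with a negative-binomial GLM (log link, offset
log size factor, one coefficient per fraction × condition cell,
var = μ + αμ²). Each contrast `w` is estimated as `wᵀβ` with standard
error `√(wᵀΣw)` and tested against zero with an asymptotic Wald test. The
calling cascade is: **step 1** — correct contrast signs in *every*
biological replicate; **step 2** — Wald p < α (default 0.05 on C1 and C2);
**step 3** — overexpression in tumor versus adjacent-normal tissue in a
cohort table (mean difference plus two-tailed Student t-test). A
percentile-split Kaplan–Meier log-rank test annotates survival
association.

This is for computational biologists analyzing RIP-seq/CLIP-style
enrichment designs, and for anyone who wants a tested, seedable reference
implementation of the three-contrast logic.

## Worked example

Simulate an 18-library experiment (3 fractions × 2 conditions × 3
replicates, 2000 genes, 5 % planted targets) and run the pipeline:

```bash
agorip simulate --n-genes 2000 --target-fraction 0.05 --seed 42 --outdir simdemo
agorip run --counts simdemo/counts.tsv --samples simdemo/samples.csv \
           --truth simdemo/truth.tsv --outdir rundemo
```

which prints

```
filter cascade:
  input                           2000  (genes with evaluable C1/C2/C3)
  step1_sign_consistent             99  (C1>0, C2>0, C3<0 in every replicate)
  step2_significant                 84  (Wald p < 0.05 on C1+C2)
```

Of 2000 genes, 99 show the full target sign pattern in all three
replicates and 84 of those are significant on both enrichment contrasts.
Because the truth table was supplied, `rundemo/summary.json` also scores
the calls against the 100 planted targets:

```json
"recovery": { "sensitivity": 0.84, "fdr": 0.0, "n_called": 84 }
```

`rundemo/contrasts.tsv` holds per-gene estimates, standard errors, Wald
z/p per contrast and the per-replicate log2 values; `agorip report
rundemo` renders a text report with contrast histograms. The same
machinery is available as a library:

```python
from agorip import SimulationConfig, simulate_experiment, analyze_counts, call_from_analysis
sim = simulate_experiment(SimulationConfig(n_genes=2000, target_fraction=0.05, seed=42))
analysis = analyze_counts(sim.counts, sim.samples)
calls, cascade = call_from_analysis(analysis)
```

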