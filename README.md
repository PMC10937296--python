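# broodmeth

Carry-over effects of early-life brood size on post-fledging phenotypes
and erythrocyte DNA methylation in wild great tits (*Parus major*) —
a tested, reusable implementation of the full statistical pipeline.

## The problem

In a cross-foster experiment, broods matched on hatch date are paired
and one brood of each pair is enlarged by three nestlings while the
other is reduced by three.  Nestlings raised in enlarged broods fledge
nutritionally stressed.  The question this package addresses: once the
birds are independent, do treatment effects *unfold over time* — do
weight, third-primary (P3) length, exploration behaviour and CpG
methylation change with days since fledging differently in the two
treatment groups?

For every CpG site the methylated/total read counts are modelled with a
binomial logit GLMM,

&nbsp;&nbsp;logit p = β₀ + β_T·T + β_D·D + β_TD·T·D + u_origin + u_rearing,

with brood-of-origin and brood-of-rearing random intercepts nested in
cross-foster pair.  A 2-df likelihood-ratio test against the
treatment-only null, Benjamini–Hochberg corrected at q ≤ 0.05, flags
*days-dependent differentially methylated sites* (DMS); overdispersed
sites are removed beforehand via the 95% highest-density interval of the
Pearson dispersion distribution.  Significant sites get per-treatment
slopes (FDR-corrected) and one of six interaction-category labels, then
a strand-aware, priority-ordered gene-region annotation (TSS > promoter
> gene body > UTRs > 10-kb flanks).  Phenotypes are analysed with
Gaussian mixed models, backward elimination, type-III F tests with
Satterthwaite df, and Bonferroni-corrected per-treatment slopes.

The mixed-model engine (Gaussian ML and Laplace binomial GLMM,
likelihood-ratio tests, Satterthwaite df, slope contrasts) is
implemented in this package and cross-checked in the test suite against
adaptive Gauss–Hermite quadrature, closed-form balanced designs, and
statsmodels.  A synthetic-data generator reproduces the study design —
paired broods, ±3 manipulation, treatment-dependent recapture, binomial
counts with planted interaction effects of six shapes — with a truth
table, so every stage is testable without the original sequencing data.

## Worked example

Simulate a 50-bird recaptured cohort, plant 10 sites of each of the six
interaction categories (±0.025 logit/day) among 140 null CpGs, and run
the screen:

```python
from broodmeth.benchmarks import study_cohort, BENCH_BASELINE_MIX
from broodmeth.simulate import SimulationConfig, make_category_plan, simulate_methylation
from broodmeth.dms import run_dms_pipeline, evaluate_recovery

design = study_cohort(seed=1)                      # 25 reduced + 25 enlarged birds
cfg = SimulationConfig(seed=1, n_sites=200,
                       category_plan=make_category_plan(10, 0.025),
                       obs_overdispersion_sd=0.0,
                       baseline_logit_mix=BENCH_BASELINE_MIX)
matrix, truth = simulate_methylation(design, cfg)
table, summary = run_dms_pipeline(matrix, design)
print(summary)
print(evaluate_recovery(table, truth))
```

Output (seed 1):

```
{'n_sites_input': 200, 'n_fit_ok': 200, 'n_omitted': 0, 'n_hdi_removed': 10,
 'n_tested': 190, 'n_significant': 52,
 'hdi_interval': [0.43989395983605745, 1.0356707632584234],
 'q_threshold': 0.05, 'fdr_universe': 'tested', 'posthoc_pool': 'joint',
 'category_counts': {'enlarged_only_up': 10, 'opposing_enlarged_down': 9,
                     'opposing_enlarged_up': 9, 'reduced_only_down': 8,
                     'reduced_only_up': 7, 'enlarged_only_down': 7,
                     'unclassified': 2}}
{'n_planted': 60, 'n_significant': 52, 'sensitivity': 0.8333333333333334,
 'category_accuracy': 0.96, 'fdp': 0.038461538461538464}
```

Reading this: all 200 sites fitted (none errored), 10 fell outside the
95% highest-density interval of the dispersion distribution, 190 were
tested, and 52 were significant at q ≤ 0.05.  Of the 60 planted sites,
83% were detected; 96% of the detected planted sites were assigned their
true interaction category; 3.8% of all significant calls were false
(nominal control is 5%).

The same stages are available from the shell:

```bash
broodmeth simulate --outdir sim --seed 1
broodmeth filter --matrix sim/methylation_matrix.tsv --design sim/design.tsv --outdir filt
broodmeth dms --matrix filt/filtered_matrix.tsv --design sim/design.tsv --outdir dms
broodmeth annotate --sites dms/dms_table.tsv --gff genes.gff3 --out annotated.tsv
broodmeth phenotypes --table sim/phenotypes.tsv --outdir pheno
broodmeth run-all --config pipeline.yaml --seed 1
```

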