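# rareburden

Rare coding-variant burden testing, gene-set enrichment, de novo mutation
enrichment, and case-control–trio meta-analysis for targeted sequencing
studies of candidate gene panels — with a synthetic cohort generator so
every stage runs without access to restricted genotype data.

The package is aimed at statistical geneticists analysing rare-variant
counts from case-control sequencing of a gene panel (for example, synaptic
and ion-channel candidate genes in a psychiatric cohort), and at anyone who
wants to combine such results with published summary tables and trio de
novo data.

## What it computes

**Burden association.** Case status is regressed on an individual's count
of qualifying variant alleles with Firth's penalized-likelihood logistic
regression:

```
logit Pr(case) ~ N_test_variants + baseline_synonymous_count
                 + PC1..PC10 + sex + sequencing_wave
```

The Jeffreys-prior penalty ½·log det I(β) gives finite, bias-reduced
estimates even when every carrier of a rare allele is a case (complete
separation). Qualifying variants are selected by mutation class (LoF,
damaging missense, all nonsynonymous, synonymous; plus composites with
missense variants at paralog-conserved sites) and frequency regime
(frequency < 0.1% in the combined sample, or singletons). Wald odds
ratios, 95% CIs and two-sided p-values are reported; a penalized
likelihood-ratio p is available.

**Empirical nulls.** Case-control label permutation (add-one rule,
`p = (r+1)/(n+1)`) and random gene-set sampling of equally sized sets from
the panel, with or without the focal genes in the pool.

**De novo enrichment.** Expected counts from a per-gene per-class mutation
rate table, `λ = 2 · n_trios · Σμ`, tested with the exact one-sided
Poisson upper tail `P(X ≥ observed)`.

**Meta-analysis and evidence combination.** Pooled individual-level Firth
regression with cohort indicators, or fixed-effects inverse-variance
combination with Cochran's Q heterogeneity; Fisher's method
(`−2Σ ln p ~ χ²(2k)`) to combine one-sided case-control and de novo
evidence; Z-tests for effect-size differences; Bonferroni ledgers for the
standard testing families (6 panel-wide burden tests, 4 primary gene-set
tests, 8 paralog-conserved secondary tests, 12 subunit-dissection tests,
20,000 for the single-gene scan).

**Synthetic cohorts.** `SynthConfig`/`synth_cohort` emulate a 187-gene
panel (ARC 28, NMDAR 61, voltage-gated sodium channels 14 with 10 alpha /
4 beta subunits, calcium channels 26, 58 other candidates) sequenced in
5207 cases and 4991 controls plus 1136 trios, with configurable per-class
carrier rates, injected odds ratios, covariate effects, wave confounding,
paralog-conserved flags and pLi assignments.

## Worked example

`examples/simulate_and_burden.py` generates a 6000-individual cohort over
a 60-gene panel with a panel-wide LoF odds ratio of 1.8 injected in cases,
then runs the six panel-wide burden tests. It prints:

```
9850 variant sites, 6000 individuals, 60 genes

               test     or  ci95_low  ci95_high      p  p_corrected
   panel_LoF_maf_lt 2.1053    1.6540     2.6799 0.0000       0.0000
panel_LoF_singleton 1.6208    1.1340     2.3166 0.0080       0.0483
   panel_NSD_maf_lt 1.0426    0.9919     1.0959 0.1010       0.6062
panel_NSD_singleton 1.0333    0.9532     1.1202 0.4258       1.0000
    panel_NS_maf_lt 1.0281    0.9882     1.0697 0.1699       1.0000
 panel_NS_singleton 1.0270    0.9632     1.0951 0.4153       1.0000
```

Only the LoF rows recover the injected enrichment (the point estimate
2.11 sits within sampling error of the true 1.8); the damaging-missense
and all-nonsynonymous composites are diluted toward 1 because the
enrichment was injected only into LoF sites, and `p_corrected` is
Bonferroni-adjusted for the six tests.

`examples/denovo_enrichment.py` shows the de novo arm at a published
operating point: a gene set whose rates give λ = 1.64 over 1136 trios
yields a one-sided Poisson p of 1.5 × 10⁻³ for 7 observed events — a
roughly four-fold enrichment.

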