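"""Generate a synthetic targeted-sequencing cohort and run the six
panel-wide burden tests (LoF / damaging missense / all nonsynonymous, each
at the rare-variant and singleton frequency regimes)."""

from rareburden import SynthConfig, synth_cohort
from rareburden.genesets import burden_six_test_plan, run_plan

# a down-scaled cohort with a panel-wide LoF enrichment injected in cases
config = SynthConfig(
    n_cases=3000, n_controls=3000,
    gene_set_sizes={"ARC": 10, "NMDAR": 15, "Na": 14, "Ca": 10, "other": 11},
    n_pli_intolerant=30,
    set_class_or={"panel": {"LoF": 1.8}},
    seed=42)
variants, individuals, genes = synth_cohort(config)
print(f"{len(variants)} variant sites, {len(individuals)} individuals, "
      f"{len(genes)} genes\n")

results = run_plan(burden_six_test_plan(), variants, individuals,
                   include_wave=True)
cols = ["test", "or", "ci95_low", "ci95_high", "p", "p_corrected"]
print(results[cols].round(4).to_string(index=False))
print("\nEach row is one burden regression: the odds ratio is the "
      "per-allele effect of carrying one more qualifying variant, adjusted "
      "for the synonymous baseline, ancestry PCs, sex and sequencing wave. "
      "Only the LoF rows should show the injected enrichment (OR ~ 1.8); "
      "p_corrected is Bonferroni-adjusted for the six tests.")
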