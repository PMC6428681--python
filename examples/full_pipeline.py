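"""Run the whole pipeline on a bundled synthetic configuration: synthesize,
filter, test, combine with de novo evidence, and render the text report."""

from rareburden.pipeline import RunConfig, run

config = RunConfig(
    out_dir="scratch/pipeline_demo",
    seed=11,
    n_perm=200,
    plans=("burden_primary", "geneset_primary"),
    synth=dict(
        n_cases=600, n_controls=600, n_trios=300,
        gene_set_sizes={"ARC": 8, "NMDAR": 10, "Na": 14, "Ca": 8,
                        "other": 10},
        n_pli_intolerant=25,
        set_class_or={"NMDAR": {"LoF": 2.5}},
        rate_scale=2e-4))
out_dir = run(config)

print((out_dir / "report.txt").read_text())
print(f"Artifacts (results TSVs, provenance JSON, log) are in {out_dir}/. "
      f"Re-running with the same seed reproduces them byte for byte.")
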