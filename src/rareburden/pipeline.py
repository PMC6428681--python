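"""End-to-end orchestration: synthesize or load, filter, test, report.

A run is described by a :class:`RunConfig` (usually loaded from YAML):
either a ``synth`` block (forwarded to :class:`~rareburden.simulate.SynthConfig`)
or paths to real input tables, plus the plan presets to execute. Outputs are
results TSVs, a text report shaped like the study's burden and gene-set
summary tables, and a provenance JSON (seed, config hash, package version)
so identical config+seed reruns give identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io, simulate
from .denovo import denovo_set_test
from .genesets import PRESET_BUILDERS, run_plan, sets_from_metadata
from .meta import combine_evidence

logger = logging.getLogger(__name__)

#: de novo mutation class tested per synaptic set: the class previously
#: reported as most enriched in each complex
DENOVO_CLASS_CHOICE = {"ARC": ("LoF", "missense"), "NMDAR": ("LoF",)}


class RunConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    out_dir: str = "rareburden_out"
    seed: int = 0
    n_perm: int = 0
    plans: tuple = ("burden_primary", "geneset_primary")
    denovo_sets: tuple = ("ARC", "NMDAR")
    include_wave: bool = True
    synth: dict | None = None
    variants_tsv: str | None = None
    individuals_tsv: str | None = None
    gene_meta_tsv: str | None = None
    genesets_gmt: str | None = None
    rate_table_tsv: str | None = None
    denovo_tsv: str | None = None
    n_trios: int = 1136
    log_level: str = "INFO"

    def __post_init__(self):
        has_real = self.variants_tsv is not None
        if self.synth is None and not has_real:
            raise RunConfigError(
                "config needs either a 'synth' block or input table paths")
        unknown = set(self.plans) - set(PRESET_BUILDERS)
        if unknown:
            raise RunConfigError(f"unknown plan presets: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = io.read_yaml(path)
        try:
            return cls(**raw)
        except TypeError as exc:
            raise RunConfigError(f"bad run config {path}: {exc}") from exc

    def digest(self) -> str:
        blob = yaml.safe_dump(self.__dict__, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_inputs(config: RunConfig):
    if config.synth is not None:
        synth_cfg = simulate.SynthConfig(**{**config.synth,
                                            "seed": config.synth.get(
                                                "seed", config.seed)})
        variants, individuals, gene_meta = simulate.synth_cohort(synth_cfg)
        rate_table = simulate.synth_rate_table(gene_meta, synth_cfg)
        trios = simulate.synth_trios(rate_table, synth_cfg, genes=gene_meta)
        n_trios = synth_cfg.n_trios
        return variants, individuals, gene_meta, rate_table, trios, n_trios
    for name in ("variants_tsv", "individuals_tsv", "gene_meta_tsv"):
        path = getattr(config, name)
        if path is None or not Path(path).exists():
            raise RunConfigError(f"input file for {name!r} missing: {path}")
    variants = io.read_tsv(config.variants_tsv)
    individuals = io.read_tsv(config.individuals_tsv)
    gene_meta = io.read_tsv(config.gene_meta_tsv)
    if config.genesets_gmt:
        # GMT overrides the set column in the metadata
        gmt = io.read_gmt(config.genesets_gmt)
        gene2set = {g: s for s, genes in gmt.items() for g in genes}
        gene_meta = gene_meta.copy()
        gene_meta["set"] = gene_meta["gene"].map(gene2set).fillna("other")
    rate_table = (io.read_rate_table(config.rate_table_tsv)
                  if config.rate_table_tsv else None)
    trios = io.read_tsv(config.denovo_tsv) if config.denovo_tsv else None
    return variants, individuals, gene_meta, rate_table, trios, config.n_trios


def run(config: RunConfig) -> Path:
    """Execute a full pipeline run; returns the output directory."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("loading inputs")
    variants, individuals, gene_meta, rate_table, trios, n_trios = \
        _load_inputs(config)
    io.write_tsv(variants, out / "variants.tsv", seed=config.seed)
    io.write_tsv(individuals, out / "individuals.tsv", seed=config.seed)
    io.write_tsv(gene_meta, out / "genes.tsv", seed=config.seed)
    io.write_gmt({s: d.genes for s, d in
                  sets_from_metadata(gene_meta).items()},
                 out / "genesets.gmt")

    all_results = []
    for preset in config.plans:
        logger.info("running plan %s", preset)
        plan = PRESET_BUILDERS[preset](gene_meta)
        res = run_plan(plan, variants, individuals,
                       include_wave=config.include_wave,
                       n_perm=config.n_perm, seed=config.seed)
        res.insert(0, "seed", config.seed)
        all_results.append(res)
        io.write_tsv(res, out / f"results_{preset}.tsv", seed=config.seed)

    combined_rows = []
    if rate_table is not None and trios is not None:
        sets = sets_from_metadata(gene_meta)
        gs_results = {r["test"]: r for res in all_results
                      for r in res.to_dict("records")}
        for set_name in config.denovo_sets:
            if set_name not in sets:
                logger.warning("de novo set %r absent from panel", set_name)
                continue
            classes = DENOVO_CLASS_CHOICE.get(set_name, ("LoF",))
            dn = denovo_set_test(trios, rate_table, sets[set_name].genes,
                                 classes, n_trios, set_name=set_name)
            row = dn.to_dict()
            cc = gs_results.get(f"{set_name}_LoF_maf_lt")
            if cc is not None and cc.get("status") == "tested":
                from .firth import AssociationResult
                assoc = AssociationResult(
                    log_or=cc["log_or"], se=cc["se"], or_point=cc["or"],
                    ci95_low=cc["ci95_low"], ci95_high=cc["ci95_high"],
                    p_two_sided=cc["p"], n_cases=cc["n_cases"],
                    n_controls=cc["n_controls"])
                row.update(combine_evidence(assoc, dn.p_one_sided,
                                            gene_set=set_name).to_dict())
            combined_rows.append(row)
        if combined_rows:
            io.write_tsv(pd.DataFrame(combined_rows),
                         out / "results_denovo_combined.tsv",
                         seed=config.seed)

    report = render_report(all_results, combined_rows)
    (out / "report.txt").write_text(report, encoding="utf-8")
    provenance = {"seed": config.seed, "config_sha256": config.digest(),
                  "version": __version__, "plans": list(config.plans)}
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2),
                                         encoding="utf-8")
    logger.info("wrote results to %s", out)
    return out


def render_report(plan_results, combined_rows) -> str:
    """Plain-text report mirroring the burden / gene-set summary layout."""
    lines = ["Mutation burden and gene-set association", "=" * 44]
    for res in plan_results:
        lines.append("")
        lines.append(f"Plan: {res['plan'].iloc[0]}")
        for r in res.to_dict("records"):
            if r.get("status") != "tested":
                lines.append(f"  {r['test']:<34} untested")
                continue
            perm = (f"  p_emp={r['p_empirical']:.4g}"
                    if "p_empirical" in r and pd.notna(r.get("p_empirical"))
                    else "")
            lines.append(
                f"  {r['test']:<34} OR={r['or']:.2f} "
                f"({r['ci95_low']:.2f}-{r['ci95_high']:.2f}) "
                f"p={r['p']:.4g}  p_corr={r['p_corrected']:.4g}{perm}")
    if combined_rows:
        lines += ["", "De novo enrichment and combined evidence",
                  "-" * 44]
        for r in combined_rows:
            extra = (f"  p_combined={r['p_combined']:.3g}"
                     if "p_combined" in r else "")
            lines.append(
                f"  {r['gene_set']:<8} observed={r['observed']} "
                f"expected={r['expected']:.2f} p_denovo={r['p']:.3g}{extra}")
    return "\n".join(lines) + "\n"
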