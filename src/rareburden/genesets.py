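"""Named gene-set analyses and the multiple-testing plan.

The study's hypothesis tests fall into fixed families, each with its own
Bonferroni denominator (``meta.CORRECTION_LEDGER``): six panel-wide burden
tests (three mutation classes x two frequency regimes), four primary
gene-set tests (rare LoF in each candidate set), eight secondary
paralog-conserved tests, twelve subunit-dissection tests, and an exome-wide
20,000-test correction for the single-gene scan. ``AnalysisPlan`` encodes a
family as rows of (gene subset, analysis class, frequency regime) sharing a
correction constant, and ``run_plan`` executes it against a variant and
individual table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .filtering import burden_counts, class_mask, frequency_filter
from .firth import DegenerateBurdenError, burden_test
from .meta import CORRECTION_LEDGER, bonferroni
from .resampling import permute_burden_test

logger = logging.getLogger(__name__)


class GeneSetError(ValueError):
    """Invalid gene-set definition or plan."""


@dataclass(frozen=True)
class GeneSetDefinition:
    """A named gene list; per-gene attributes live in the gene metadata."""

    name: str
    genes: tuple
    description: str = ""

    def __post_init__(self):
        if not self.genes:
            raise GeneSetError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise GeneSetError(f"gene set {self.name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class PlanRow:
    """One association test: subset x class x regime, with its correction."""

    name: str
    genes: tuple | None           # None = whole panel
    analysis_class: str
    regime: str                   # "maf_lt" or "singleton"
    m_tests: int
    threshold: float = 0.001
    exclude_lof: bool = False     # sensitivity run without LoF sites


@dataclass
class AnalysisPlan:
    name: str
    rows: list = field(default_factory=list)


def partition_by_pli(gene_meta: pd.DataFrame, threshold: float = 0.9
                     ) -> tuple[list, list]:
    """Split the panel into LoF-intolerant (pLi > threshold) and tolerant.

    The boundary value goes to the tolerant side (pLi <= threshold is
    "not intolerant").
    """
    if len(gene_meta) == 0:
        raise GeneSetError("empty gene panel")
    if "pli" not in gene_meta.columns:
        raise GeneSetError("gene metadata lacks a 'pli' column")
    missing = gene_meta[gene_meta["pli"].isna()]["gene"].tolist()
    if missing:
        raise GeneSetError(f"missing pLi for genes: {', '.join(missing)}")
    intol = gene_meta[gene_meta["pli"] > threshold]["gene"].tolist()
    tol = gene_meta[gene_meta["pli"] <= threshold]["gene"].tolist()
    return intol, tol


def sets_from_metadata(gene_meta: pd.DataFrame) -> dict:
    """GeneSetDefinitions for each named set in the gene metadata."""
    return {s: GeneSetDefinition(name=s, genes=tuple(sub["gene"]))
            for s, sub in gene_meta.groupby("set", sort=False)}


def sodium_subunit_sets(gene_meta: pd.DataFrame) -> dict:
    """Alpha- and beta-subunit subsets of the sodium-channel set."""
    na = gene_meta[gene_meta["set"] == "Na"]
    if len(na) == 0:
        raise GeneSetError("no sodium-channel ('Na') genes in metadata")
    return {sub: GeneSetDefinition(name=f"Na_{sub}",
                                   genes=tuple(na[na["subunit"] == sub]["gene"]))
            for sub in ("alpha", "beta")}


def restrict_paralog_flags(variants: pd.DataFrame,
                           gene_meta: pd.DataFrame) -> pd.DataFrame:
    """Treat missense flags in genes without paralog scores as unavailable.

    Conservation scores exist only for some genes (e.g. two of the four
    sodium-channel beta subunits); missense sites in unscored genes get a
    NA flag, so they contribute only LoF sites to the paralog-conserved
    composite class.
    """
    scored = set(gene_meta[gene_meta["paralog_scores_available"]]["gene"])
    out = variants.copy()
    unscored = ~out["gene"].isin(scored)
    out.loc[unscored & out["paralog_conserved"].notna(),
            "paralog_conserved"] = pd.NA
    return out


def burden_six_test_plan(threshold: float = 0.001) -> AnalysisPlan:
    """Panel-wide burden: {LoF, NSD, NS} x {<0.1%, singleton}, m = 6."""
    m = CORRECTION_LEDGER["burden_primary"]
    rows = [PlanRow(f"panel_{c}_{r}", None, c, r, m, threshold)
            for c in ("LoF", "NSD", "NS")
            for r in ("maf_lt", "singleton")]
    return AnalysisPlan("burden_primary", rows)


def geneset_primary_plan(sets: Mapping[str, GeneSetDefinition],
                         set_names: Sequence[str] = ("ARC", "NMDAR", "Na", "Ca"),
                         threshold: float = 0.001) -> AnalysisPlan:
    """Primary gene-set tests: rare LoF in each candidate set, m = 4."""
    m = CORRECTION_LEDGER["geneset_primary"]
    rows = [PlanRow(f"{s}_LoF_maf_lt", sets[s].genes, "LoF", "maf_lt", m,
                    threshold) for s in set_names]
    return AnalysisPlan("geneset_primary", rows)


def paralog_secondary_plan(sets: Mapping[str, GeneSetDefinition],
                           channel_sets: Sequence[str] = ("Na", "Ca"),
                           threshold: float = 0.001,
                           exclude_lof: bool = False) -> AnalysisPlan:
    """Secondary tests of LoF + paralog-conserved missense, m = 8.

    Only the paralogous channel families can be tested, but the correction
    is for eight potential tests (four sets x two classes). With
    ``exclude_lof`` the composite drops LoF sites (sensitivity run).
    """
    m = CORRECTION_LEDGER["paralog_secondary"]
    rows = [PlanRow(f"{s}_paralog_conserved_maf_lt", sets[s].genes,
                    "paralog_conserved", "maf_lt", m, threshold, exclude_lof)
            for s in channel_sets]
    return AnalysisPlan("paralog_secondary", rows)


def subunit_dissection_plan(gene_meta: pd.DataFrame,
                            threshold: float = 0.001) -> AnalysisPlan:
    """Alpha vs beta sodium-channel dissection, m = 12."""
    m = CORRECTION_LEDGER["subunit_dissection"]
    subs = sodium_subunit_sets(gene_meta)
    rows = [PlanRow(f"Na_{sub}_paralog_conserved_maf_lt",
                    subs[sub].genes, "paralog_conserved", "maf_lt", m,
                    threshold)
            for sub in ("alpha", "beta")]
    return AnalysisPlan("subunit_dissection", rows)


PRESET_BUILDERS = {
    "burden_primary": lambda gene_meta, **kw: burden_six_test_plan(**kw),
    "geneset_primary": lambda gene_meta, **kw: geneset_primary_plan(
        sets_from_metadata(gene_meta), **kw),
    "paralog_secondary": lambda gene_meta, **kw: paralog_secondary_plan(
        sets_from_metadata(gene_meta), **kw),
    "subunit_dissection": lambda gene_meta, **kw: subunit_dissection_plan(
        gene_meta, **kw),
}


def run_plan(plan: AnalysisPlan, variants: pd.DataFrame,
             individuals: pd.DataFrame,
             include_wave: bool = False, hierarchy: str = "nested",
             n_perm: int = 0, seed: int = 0) -> pd.DataFrame:
    """Execute every row of a plan; returns a results table.

    Adds a Bonferroni-corrected p per row and, when ``n_perm > 0``, an
    empirical permutation p. Degenerate rows (no varying burden) are
    reported with status ``untested`` rather than a p-value.
    """
    records = []
    for row in plan.rows:
        rec = {"test": row.name, "plan": plan.name,
               "analysis_class": row.analysis_class, "regime": row.regime,
               "m_tests": row.m_tests, "status": "tested"}
        try:
            table = burden_counts(
                variants, individuals, analysis_class=row.analysis_class,
                gene_subset=row.genes, regime=row.regime,
                threshold=row.threshold, hierarchy=hierarchy,
                exclude_lof=row.exclude_lof)
            res = burden_test(table, include_wave=include_wave,
                              analysis_class=row.analysis_class,
                              regime=row.regime, gene_subset=row.name)
        except DegenerateBurdenError as exc:
            logger.warning("plan row %r: %s", row.name, exc)
            rec["status"] = "untested"
            records.append(rec)
            continue
        rec.update(res.to_dict())
        rec["p_corrected"] = bonferroni(res.p_two_sided, row.m_tests)
        if n_perm > 0:
            perm = permute_burden_test(table, n_perm=n_perm, seed=seed,
                                       include_wave=include_wave)
            rec["p_empirical"] = perm.pvalue
            rec["perm_seed"] = perm.seed
        records.append(rec)
    return pd.DataFrame(records)


def single_gene_scan(variants: pd.DataFrame, individuals: pd.DataFrame,
                     genes: Iterable[str], analysis_class: str = "LoF",
                     regime: str = "maf_lt", threshold: float = 0.001,
                     include_wave: bool = False,
                     m_tests: int = CORRECTION_LEDGER["single_gene"]
                     ) -> pd.DataFrame:
    """Per-gene burden test with exome-wide correction.

    Genes whose qualifying-allele count does not vary across individuals
    (typically zero carriers) are reported with status ``untested``.
    """
    passing = frequency_filter(variants, len(individuals), regime, threshold)
    passing = passing[class_mask(passing, analysis_class)]
    records = []
    for gene in genes:
        rec = {"gene": gene, "analysis_class": analysis_class,
               "regime": regime, "status": "tested"}
        try:
            table = burden_counts(variants, individuals,
                                  analysis_class=analysis_class,
                                  gene_subset=[gene], regime=regime,
                                  threshold=threshold)
            res = burden_test(table, include_wave=include_wave,
                              analysis_class=analysis_class, regime=regime,
                              gene_subset=gene)
        except DegenerateBurdenError:
            rec["status"] = "untested"
            records.append(rec)
            continue
        rec.update(res.to_dict())
        rec["p_corrected"] = bonferroni(res.p_two_sided, m_tests)
        records.append(rec)
    return pd.DataFrame(records)
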