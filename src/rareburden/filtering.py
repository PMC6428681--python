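"""Variant selection by mutation class, frequency regime, and gene subset.

Variant sites are rows of a pandas DataFrame with columns

    variant_id         unique site identifier (one ALT per row; multi-allelic
                       sites are decomposed upstream)
    gene               gene symbol
    mclass             one of ``LoF``, ``NSD``, ``NS_other``, ``synonymous``
    paralog_conserved  True/False for missense sites, NA otherwise
    allele_count       alternate-allele count in the combined case+control
                       sample (one variant allele per carrier)
    carriers           list of individual ids carrying the allele

Analysis classes are composites of the atomic ``mclass`` labels. Under the
default *nested* hierarchy the damaging-missense class includes LoF sites and
the all-nonsynonymous class includes both, so burdens for the three classes
are cumulative; an *exclusive* hierarchy is available as a switch because
published count tables do not always resolve which convention was used.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MUTATION_CLASSES = ("LoF", "NSD", "NS_other", "synonymous")
MISSENSE_CLASSES = ("NSD", "NS_other")

#: composite classes used in the analyses
ANALYSIS_CLASSES = (
    "LoF",
    "NSD",
    "NS",
    "synonymous",
    "paralog_conserved",      # LoF + paralog-conserved missense
    "paralog_nonconserved",   # missense with flag False only
)

VARIANT_COLUMNS = (
    "variant_id",
    "gene",
    "mclass",
    "paralog_conserved",
    "allele_count",
    "carriers",
)


class FilterError(ValueError):
    """Invalid filtering request (bad class label, threshold, regime)."""


def classify_composite(mclass: str, paralog_conserved=None,
                       hierarchy: str = "nested") -> frozenset:
    """Return the set of analysis classes a single site belongs to.

    Parameters
    ----------
    mclass
        Atomic mutation class of the site.
    paralog_conserved
        Whether the (missense) site falls at a position conserved across its
        paralogous gene family; ignored for LoF and synonymous sites.
    hierarchy
        ``"nested"`` (default): NSD-analysis = {LoF, NSD}, NS = all
        nonsynonymous including LoF. ``"exclusive"``: each composite contains
        only its literal atomic classes.
    """
    if mclass not in MUTATION_CLASSES:
        raise FilterError(f"unknown mutation class {mclass!r}; "
                          f"expected one of {MUTATION_CLASSES}")
    if hierarchy not in ("nested", "exclusive"):
        raise FilterError(f"unknown hierarchy {hierarchy!r}")
    out = set()
    nested = hierarchy == "nested"
    if mclass == "LoF":
        out.add("LoF")
        if nested:
            out.update(("NSD", "NS"))
        out.add("paralog_conserved")
    elif mclass in MISSENSE_CLASSES:
        if mclass == "NSD":
            out.add("NSD")
        out.add("NS")
        if paralog_conserved is True:
            out.add("paralog_conserved")
        elif paralog_conserved is False:
            out.add("paralog_nonconserved")
    else:
        out.add("synonymous")
    return frozenset(out)


def class_mask(variants: pd.DataFrame, analysis_class: str,
               hierarchy: str = "nested",
               exclude_lof: bool = False) -> pd.Series:
    """Boolean mask of sites belonging to ``analysis_class``.

    ``exclude_lof`` drops LoF sites from the composite (used by the
    sensitivity run of the paralog-conserved analysis).
    """
    if analysis_class not in ANALYSIS_CLASSES:
        raise FilterError(f"unknown analysis class {analysis_class!r}; "
                          f"expected one of {ANALYSIS_CLASSES}")
    m = variants["mclass"]
    bad = ~m.isin(MUTATION_CLASSES)
    if bad.any():
        raise FilterError(
            f"unknown mutation class labels: {sorted(m[bad].unique())}")
    nested = hierarchy == "nested"
    if hierarchy not in ("nested", "exclusive"):
        raise FilterError(f"unknown hierarchy {hierarchy!r}")
    pc = variants["paralog_conserved"]
    if analysis_class == "LoF":
        mask = m == "LoF"
    elif analysis_class == "NSD":
        mask = m.isin(("LoF", "NSD")) if nested else (m == "NSD")
    elif analysis_class == "NS":
        targets = ("LoF", "NSD", "NS_other") if nested else MISSENSE_CLASSES
        mask = m.isin(targets)
    elif analysis_class == "synonymous":
        mask = m == "synonymous"
    elif analysis_class == "paralog_conserved":
        mask = (m == "LoF") | (m.isin(MISSENSE_CLASSES) & (pc == True))  # noqa: E712
    else:  # paralog_nonconserved
        mask = m.isin(MISSENSE_CLASSES) & (pc == False)  # noqa: E712
    if exclude_lof:
        mask = mask & (m != "LoF")
    return mask


def frequency_filter(variants: pd.DataFrame, n_individuals: int,
                     regime: str = "maf_lt",
                     threshold: float = 0.001) -> pd.DataFrame:
    """Keep sites passing an allele-frequency regime.

    ``maf_lt`` keeps sites with ``allele_count / (2 * n_individuals)``
    strictly below ``threshold`` (default 0.1%); ``singleton`` keeps sites
    whose alternate allele is observed exactly once in the combined sample.
    """
    if regime not in ("maf_lt", "singleton"):
        raise FilterError(f"unknown frequency regime {regime!r}")
    if regime == "singleton":
        return variants[variants["allele_count"] == 1]
    if not (0 < threshold <= 1):
        raise FilterError(f"threshold must be in (0, 1], got {threshold}")
    if n_individuals <= 0:
        raise FilterError("n_individuals must be positive")
    freq = variants["allele_count"] / (2.0 * n_individuals)
    return variants[freq < threshold]


def explode_carriers(variants: pd.DataFrame) -> pd.DataFrame:
    """Long (variant_id, gene, mclass, individual_id) table of carried alleles."""
    if len(variants) == 0:
        return pd.DataFrame(
            columns=["variant_id", "gene", "mclass", "individual_id"])
    out = variants[["variant_id", "gene", "mclass", "carriers"]].explode(
        "carriers").dropna(subset=["carriers"])
    return out.rename(columns={"carriers": "individual_id"})


def burden_counts(variants: pd.DataFrame, individuals: pd.DataFrame,
                  analysis_class: str = "LoF",
                  gene_subset: Iterable[str] | None = None,
                  regime: str = "maf_lt", threshold: float = 0.001,
                  hierarchy: str = "nested",
                  exclude_lof: bool = False) -> pd.DataFrame:
    """Per-individual burden table for one (class, regime, gene subset) cell.

    Returns a copy of ``individuals`` with two added columns:

    ``n_test_variants``
        number of qualifying variant alleles the individual carries in the
        selected class/regime/gene subset;
    ``baseline_synonymous_count``
        the individual's synonymous allele count over *all* targeted genes at
        the same frequency regime, used as the sequencing-quality covariate
        in the burden regression.

    Raises if a carrier id does not appear in the individual table.
    """
    if "individual_id" not in individuals.columns:
        raise FilterError("individual table must have an 'individual_id' column")
    n = len(individuals)
    passing = frequency_filter(variants, n, regime, threshold)

    def _count(sites: pd.DataFrame) -> pd.Series:
        long = explode_carriers(sites)
        unknown = set(long["individual_id"]) - set(individuals["individual_id"])
        if unknown:
            raise FilterError(
                "carrier ids absent from individual table: "
                + ", ".join(sorted(map(str, unknown))[:10]))
        return long.groupby("individual_id").size()

    test_sites = passing[class_mask(passing, analysis_class, hierarchy,
                                    exclude_lof)]
    if gene_subset is not None:
        gene_subset = set(gene_subset)
        test_sites = test_sites[test_sites["gene"].isin(gene_subset)]
    syn_sites = passing[class_mask(passing, "synonymous", hierarchy)]

    out = individuals.copy()
    idx = out["individual_id"]
    out["n_test_variants"] = idx.map(_count(test_sites)).fillna(0).astype(int)
    out["baseline_synonymous_count"] = (
        idx.map(_count(syn_sites)).fillna(0).astype(int))
    return out


def rate_excess(case_count: float, n_cases: int,
                control_count: float, n_controls: int
                ) -> tuple[float, float, float]:
    """Per-person mutation rates and the case-control rate difference.

    Returns ``(case_rate, control_rate, case_rate - control_rate)`` where
    each rate is the mean number of qualifying alleles per person.
    """
    if n_cases <= 0 or n_controls <= 0:
        raise FilterError("sample sizes must be positive")
    case_rate = case_count / n_cases
    control_rate = control_count / n_controls
    return case_rate, control_rate, case_rate - control_rate
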