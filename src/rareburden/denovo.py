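"""De novo mutation enrichment against a per-gene mutation-rate model.

Expected de novo counts follow the standard mutation-rate framework: a rate
table gives, for each gene and mutation class, the probability mu of a de
novo mutation of that class per chromosome per generation. Over a set of
genes sequenced in ``n_trios`` proband-parent trios, the expected count is

    lambda = 2 * n_trios * sum(mu)

(the factor 2 counts the two parental chromosomes), and the observed count
is tested against Poisson(lambda) with the one-sided upper-tail probability
P(X >= observed). The tail is evaluated exactly through the regularized
incomplete gamma function (the Poisson survival function); lambda in these
analyses is far too small for a normal approximation.

The rate table is a DataFrame with columns ``gene``, ``class``, ``mu``;
classes cover at least LoF, missense, synonymous. Published per-gene rate
tables in that layout can be dropped in directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats


class RateTableError(ValueError):
    """Missing genes or invalid parameters in a de novo computation."""


@dataclass
class DeNovoResult:
    """Observed vs expected de novo counts for one gene set and class choice."""

    observed: int
    expected: float
    p_one_sided: float
    gene_set: str = ""
    classes: tuple = ()

    def to_dict(self) -> dict:
        return {"gene_set": self.gene_set,
                "classes": "+".join(self.classes),
                "observed": self.observed,
                "expected": self.expected,
                "p": self.p_one_sided}


def expected_count(rate_table: pd.DataFrame, gene_set: Iterable[str],
                   classes: Sequence[str], n_trios: int) -> float:
    """Expected de novo count lambda = 2 * n_trios * sum of mu over set/classes."""
    if n_trios <= 0:
        raise RateTableError(f"n_trios must be positive, got {n_trios}")
    genes = list(gene_set)
    have = set(rate_table["gene"])
    missing = sorted(set(genes) - have)
    if missing:
        raise RateTableError(
            f"genes absent from the rate table: {', '.join(missing)}")
    if (rate_table["mu"] < 0).any():
        raise RateTableError("mutation rates must be non-negative")
    sel = rate_table[rate_table["gene"].isin(set(genes))
                     & rate_table["class"].isin(set(classes))]
    return float(2.0 * n_trios * sel["mu"].sum())


def poisson_upper_p(observed: int, lam: float) -> float:
    """One-sided Poisson upper-tail p-value, P(X >= observed).

    ``p = 1`` when ``observed == 0``: seeing nothing is never evidence of
    enrichment.
    """
    if observed < 0 or observed != int(observed):
        raise RateTableError(f"observed must be a non-negative integer, "
                             f"got {observed}")
    if lam < 0:
        raise RateTableError(f"lambda must be non-negative, got {lam}")
    if observed == 0:
        return 1.0
    return float(stats.poisson.sf(observed - 1, lam))


def denovo_set_test(trio_summary: pd.DataFrame, rate_table: pd.DataFrame,
                    gene_set: Iterable[str], classes: Sequence[str],
                    n_trios: int, set_name: str = "") -> DeNovoResult:
    """Poisson enrichment test of observed de novo counts in a gene set.

    ``trio_summary`` has columns ``gene``, ``class``, ``count`` (observed de
    novo mutations aggregated over trios). The class selection is per set:
    e.g. all-nonsynonymous for one complex, LoF only for another, following
    whichever class was previously reported as most enriched.
    """
    genes = set(gene_set)
    lam = expected_count(rate_table, genes, classes, n_trios)
    sel = trio_summary[trio_summary["gene"].isin(genes)
                       & trio_summary["class"].isin(set(classes))]
    observed = int(sel["count"].sum())
    return DeNovoResult(observed=observed, expected=lam,
                        p_one_sided=poisson_upper_p(observed, lam),
                        gene_set=set_name, classes=tuple(classes))
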