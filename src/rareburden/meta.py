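"""Meta-analysis and p-value combination across cohorts and evidence types.

Two case-control combination modes are provided. The default pools
individual-level data across cohorts into a single Firth regression with
cohort indicator covariates (a "mega-analysis"); the alternative combines
per-cohort log odds ratios by fixed-effects inverse-variance weighting,
which also supplies Cochran's Q heterogeneity test. Case-control evidence
(made one-sided in the direction of case enrichment) is combined with the
one-sided de novo Poisson p-value by Fisher's method, the two samples being
disjoint and hence independent.

Printed summary tables report odds ratios with 95% confidence intervals;
``se_from_ci`` recovers the log-scale standard error from such a summary so
published results can enter the meta-analysis without raw data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .firth import AssociationResult, burden_test, wald_ci, wald_pvalue

logger = logging.getLogger(__name__)

Z_95 = 1.959964  # two-sided 95% normal quantile

#: Bonferroni denominators for the study's named testing regimes
CORRECTION_LEDGER = {
    "burden_primary": 6,        # 3 classes x 2 frequency regimes, whole panel
    "geneset_primary": 4,       # 4 gene sets x 1 class
    "paralog_secondary": 8,     # 4 gene sets x 2 classes
    "subunit_dissection": 12,   # 2 classes x (4 sets + alpha + beta subsets)
    "single_gene": 20000,       # exome-wide
}


class MetaError(ValueError):
    """Invalid meta-analysis input."""


@dataclass
class CombinedResult:
    """Case-control + de novo evidence for one gene set."""

    p_case_control_two_sided: float
    p_case_control_one_sided: float
    p_denovo_one_sided: float
    p_combined_one_sided: float
    gene_set: str = ""

    def to_dict(self) -> dict:
        return {"gene_set": self.gene_set,
                "p_cc_two_sided": self.p_case_control_two_sided,
                "p_cc_one_sided": self.p_case_control_one_sided,
                "p_denovo": self.p_denovo_one_sided,
                "p_combined": self.p_combined_one_sided}


def pooled_meta(cohort_tables: Sequence[pd.DataFrame], mode: str = "pooled",
                include_wave: bool = False, p_method: str = "wald",
                **labels) -> AssociationResult:
    """Combine per-cohort burden tables into one association result.

    ``mode="pooled"`` (default) concatenates the individual-level tables,
    adds a cohort indicator, and runs a joint Firth burden regression.
    ``mode="fixed"`` fits each cohort separately and combines the log odds
    ratios by inverse-variance weighting. Wave indicators are only
    meaningful for the targeted-sequencing cohort, so ``include_wave``
    applies to pooled mode when all tables share a wave column.
    """
    if mode not in ("pooled", "fixed"):
        raise MetaError(f"unknown meta mode {mode!r}")
    if mode == "fixed" and len(cohort_tables) < 2:
        raise MetaError("fixed-effects combination needs >= 2 cohorts")
    if mode == "pooled":
        frames = []
        for i, t in enumerate(cohort_tables):
            f = t.copy()
            if "cohort" not in f.columns:
                f["cohort"] = f"cohort{i}"
            frames.append(f)
        pooled = pd.concat(frames, ignore_index=True)
        return burden_test(pooled, include_wave=include_wave,
                           include_cohort=pooled["cohort"].nunique() > 1,
                           p_method=p_method, **labels)
    fits = [burden_test(t, include_wave=include_wave, p_method=p_method)
            for t in cohort_tables]
    return fixed_effects([f.log_or for f in fits], [f.se for f in fits],
                         n_cases=sum(f.n_cases for f in fits),
                         n_controls=sum(f.n_controls for f in fits),
                         **labels)


def fixed_effects(betas: Sequence[float], ses: Sequence[float],
                  n_cases: int = 0, n_controls: int = 0,
                  **labels) -> AssociationResult:
    """Fixed-effects inverse-variance combination of log odds ratios."""
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if len(betas) < 2:
        raise MetaError("fixed-effects combination needs >= 2 estimates")
    if (ses <= 0).any():
        raise MetaError("standard errors must be positive")
    w = 1.0 / ses ** 2
    beta = float((w * betas).sum() / w.sum())
    se = float(1.0 / math.sqrt(w.sum()))
    lo, hi = wald_ci(beta, se)
    return AssociationResult(
        log_or=beta, se=se, or_point=math.exp(beta), ci95_low=lo,
        ci95_high=hi, p_two_sided=wald_pvalue(beta, se),
        n_cases=n_cases, n_controls=n_controls, **labels)


def one_sided(p_two_sided: float, enriched: bool) -> float:
    """Convert a two-sided p to one-sided in the case-enrichment direction.

    ``enriched`` is the sign of the log odds ratio: p/2 when the point
    estimate is in the enrichment direction, 1 - p/2 otherwise.
    """
    if not (0 < p_two_sided <= 1):
        raise MetaError(f"p must be in (0, 1], got {p_two_sided}")
    return p_two_sided / 2.0 if enriched else 1.0 - p_two_sided / 2.0


def fisher_combined(p_values: Sequence[float]) -> float:
    """Fisher's method: -2 sum(ln p) against chi-square with 2k df."""
    ps = np.asarray(list(p_values), dtype=float)
    if ps.size == 0:
        raise MetaError("no p-values to combine")
    if (ps <= 0).any() or (ps > 1).any():
        raise MetaError("all p-values must be in (0, 1]")
    x = -2.0 * np.log(ps).sum()
    return float(stats.chi2.sf(x, df=2 * ps.size))


def combine_evidence(cc: AssociationResult, dn_p: float,
                     gene_set: str = "") -> CombinedResult:
    """Fisher combination of case-control and de novo evidence for a set.

    The case-control two-sided p is halved in the direction of its point
    estimate; the de novo p enters as-is (already one-sided).
    """
    p1 = one_sided(cc.p_two_sided, enriched=cc.log_or > 0)
    return CombinedResult(
        p_case_control_two_sided=cc.p_two_sided,
        p_case_control_one_sided=p1,
        p_denovo_one_sided=dn_p,
        p_combined_one_sided=fisher_combined([p1, dn_p]),
        gene_set=gene_set)


def z_difference(beta1: float, se1: float, beta2: float, se2: float,
                 sided: int = 1) -> float:
    """Z-test for a difference between two independent log odds ratios.

    ``sided=1`` tests beta1 > beta2 (upper tail); ``sided=2`` is two-sided.
    """
    if se1 <= 0 or se2 <= 0:
        raise MetaError("standard errors must be positive")
    if sided not in (1, 2):
        raise MetaError("sided must be 1 or 2")
    z = (beta1 - beta2) / math.sqrt(se1 ** 2 + se2 ** 2)
    if sided == 1:
        return float(stats.norm.sf(z))
    return float(2.0 * stats.norm.sf(abs(z)))


def se_from_ci(or_point: float, ci_low: float, ci_high: float) -> float:
    """Log-scale standard error implied by a printed OR (95% CI) summary."""
    if not (0 < ci_low <= or_point <= ci_high):
        raise MetaError(
            f"need 0 < ci_low <= OR <= ci_high, got "
            f"({or_point}, {ci_low}, {ci_high})")
    if ci_low == ci_high:
        logger.warning("degenerate confidence interval; se = 0")
        return 0.0
    return (math.log(ci_high) - math.log(ci_low)) / (2.0 * Z_95)


def cochran_q(betas: Sequence[float], ses: Sequence[float]
              ) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity test across independent effect estimates.

    Returns ``(Q, df, p)`` with Q the inverse-variance weighted sum of
    squared deviations from the fixed-effects mean and df = k - 1.
    """
    betas = np.asarray(list(betas), dtype=float)
    ses = np.asarray(list(ses), dtype=float)
    if betas.size < 2:
        raise MetaError("heterogeneity needs >= 2 estimates")
    if (ses <= 0).any():
        raise MetaError("standard errors must be positive")
    w = 1.0 / ses ** 2
    mean = (w * betas).sum() / w.sum()
    q = float((w * (betas - mean) ** 2).sum())
    df = betas.size - 1
    return q, df, float(stats.chi2.sf(q, df))


def bonferroni(p: float, m: int) -> float:
    """Bonferroni correction: min(1, p * m)."""
    if m < 1:
        raise MetaError(f"number of tests must be >= 1, got {m}")
    if not (0 <= p <= 1):
        raise MetaError(f"p must be in [0, 1], got {p}")
    return min(1.0, p * m)


def exclude_overlap(genes: Sequence[str], overlap: Sequence[str]) -> list:
    """Set-difference preprocessing for overlapping gene sets.

    Used to check that two partially overlapping complexes carry independent
    signal: each set is re-tested after removing the shared genes.
    """
    overlap = set(overlap)
    return [g for g in genes if g not in overlap]
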