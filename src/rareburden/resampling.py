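"""Empirical null distributions by resampling.

Two nulls are used alongside the parametric burden test:

* **label permutation** — case-control labels are shuffled uniformly while
  every covariate stays attached to its individual, the test statistic is
  recomputed per shuffle, and the add-one empirical p-value
  ``(r + 1) / (n_perm + 1)`` is reported (never exactly zero);
* **random gene-set sampling** — the focal set's statistic is compared with
  sets of the same gene count drawn from a background panel, either with the
  focal genes removed from the pool or left in (both modes are used: the
  first asks whether the set beats the rest of the panel, the second whether
  it beats comparable sets drawn from all paralogous genes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .firth import burden_test


@dataclass
class PermutationResult:
    observed: float
    n_permutations: int
    n_as_or_more_extreme: int
    pvalue: float
    seed: int


class ResamplingError(ValueError):
    """Invalid resampling request."""


def permutation_pvalue(stat_fn: Callable[[np.ndarray], float],
                       labels: Sequence[int], n_perm: int, seed: int,
                       greater_is_extreme: bool = True) -> PermutationResult:
    """Empirical p-value from uniform label permutations.

    ``stat_fn`` maps a 0/1 label vector to the test statistic (by default
    larger = more extreme; set ``greater_is_extreme=False`` for statistics
    like p-values where smaller is more extreme). The observed statistic is
    ``stat_fn`` on the labels as given.
    """
    if n_perm < 1:
        raise ResamplingError(f"n_perm must be >= 1, got {n_perm}")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    observed = float(stat_fn(labels))
    r = 0
    for _ in range(n_perm):
        stat = float(stat_fn(rng.permutation(labels)))
        if greater_is_extreme:
            r += stat >= observed
        else:
            r += stat <= observed
    p = (r + 1) / (n_perm + 1)
    return PermutationResult(observed=observed, n_permutations=n_perm,
                             n_as_or_more_extreme=int(r), pvalue=p, seed=seed)


def permute_burden_test(burden: pd.DataFrame, n_perm: int, seed: int,
                        include_wave: bool = False,
                        stratify_by: str | None = None) -> PermutationResult:
    """Permutation p-value for the burden test's |z| statistic.

    The statistic recomputed per shuffle is |log-OR / se| from the Firth
    burden regression, so covariate adjustment is applied identically to
    observed and permuted data. ``stratify_by`` optionally permutes labels
    within levels of a column (e.g. sequencing wave) to preserve a
    confounded batch structure under the null; the default is plain
    unstratified permutation.
    """
    work = burden.copy()

    def stat(labels: np.ndarray) -> float:
        work["is_case"] = labels
        res = burden_test(work, include_wave=include_wave)
        return abs(res.log_or / res.se)

    labels = burden["is_case"].to_numpy()
    if stratify_by is None:
        return permutation_pvalue(stat, labels, n_perm, seed)

    if stratify_by not in burden.columns:
        raise ResamplingError(f"no column {stratify_by!r} to stratify by")
    strata = burden[stratify_by].to_numpy()
    rng = np.random.default_rng(seed)

    def shuffle_within(labels: np.ndarray) -> np.ndarray:
        out = labels.copy()
        for s in np.unique(strata):
            idx = np.flatnonzero(strata == s)
            out[idx] = out[idx][rng.permutation(len(idx))]
        return out

    if n_perm < 1:
        raise ResamplingError(f"n_perm must be >= 1, got {n_perm}")
    observed = stat(labels)
    r = sum(stat(shuffle_within(labels)) >= observed for _ in range(n_perm))
    return PermutationResult(observed=observed, n_permutations=n_perm,
                             n_as_or_more_extreme=int(r),
                             pvalue=(r + 1) / (n_perm + 1), seed=seed)


def random_geneset_null(panel_genes: Sequence[str],
                        observed_set: Sequence[str],
                        stat_fn: Callable[[Sequence[str]], float],
                        n_samples: int, seed: int,
                        exclude_observed: bool = True) -> PermutationResult:
    """Empirical p-value against random gene sets of equal size.

    ``stat_fn`` maps a gene list to the set-level statistic; the default
    choice in this package is the set-level burden log odds ratio, for which
    set size cancels. Larger statistics are more extreme.

    ``exclude_observed=True`` samples from the panel minus the focal genes;
    ``False`` leaves the focal genes in the pool.
    """
    if n_samples < 1:
        raise ResamplingError(f"n_samples must be >= 1, got {n_samples}")
    observed_set = list(observed_set)
    pool = [g for g in panel_genes
            if not (exclude_observed and g in set(observed_set))]
    k = len(observed_set)
    if len(pool) < k:
        raise ResamplingError(
            f"sampling pool ({len(pool)} genes) smaller than set size {k}")
    rng = np.random.default_rng(seed)
    observed = float(stat_fn(observed_set))
    pool = np.asarray(pool, dtype=object)
    r = 0
    for _ in range(n_samples):
        sample = rng.choice(pool, size=k, replace=False)
        r += float(stat_fn(list(sample))) >= observed
    return PermutationResult(observed=observed, n_permutations=n_samples,
                             n_as_or_more_extreme=int(r),
                             pvalue=(r + 1) / (n_samples + 1), seed=seed)
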