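"""Synthetic targeted-sequencing cohorts, rate tables, and trio counts.

The generator emulates the data structure of a targeted case-control
sequencing study of a candidate gene panel: a variant site table (gene,
mutation class, paralog-conservation flag, allele counts, carrier lists), an
individual table (phenotype, sex, ten ancestry principal components,
sequencing wave, cohort), per-gene metadata (set membership, subunit tag,
pLi, paralog-score availability), a per-gene per-class de novo mutation-rate
table, and observed de novo counts from simulated trios.

Default sizes follow the targeted-sequencing study design this package
implements: 5207 cases and 4991 controls over a 187-gene panel comprising
the ARC complex (28 genes), the NMDAR complex (61), voltage-gated sodium
channels (14; 10 alpha and 4 beta subunits), voltage-gated calcium channels
(26), and 58 other candidates, with 1136 trios for the de novo arm.

Generative model, per mutation class c and gene g: each individual carries a
qualifying allele of class c in gene g with probability

    logit(p) = logit(rate_c / n_genes) + 1{case} * ln OR
               + sex * b_sex + PC . b_pc + b_wave * (wave index)

so the case carrier odds are the control odds inflated by the configured
odds ratio, and covariates can shift carrier rates to exercise the
regression adjustment. Carried alleles are grouped into variant sites by a
sequential "new site with probability `site_novelty`, else join an existing
site" process, which produces the singleton-heavy allele-count spectrum of
rare variation; allele counts assume one variant allele per carrier.
Carrier counts are generated per individual per class — rare-variant
linkage is ignored because the burden analysis only consumes counts.
Only single-nucleotide classes are modelled; indels are excluded by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .filtering import MISSENSE_CLASSES, MUTATION_CLASSES

#: per-person mean allele counts in controls by exclusive mutation class,
#: at the rare (<0.1%) regime of a targeted candidate panel
DEFAULT_CLASS_RATES = {
    "LoF": 0.039,
    "NSD": 1.051,
    "NS_other": 0.639,
    "synonymous": 1.0,
}

DEFAULT_SET_SIZES = {"ARC": 28, "NMDAR": 61, "Na": 14, "Ca": 26, "other": 58}

#: de novo rate-table classes and their share of a gene's total point
#: mutation probability (functional spectrum of coding point mutations)
DENOVO_CLASS_FRACTIONS = {"LoF": 0.10, "missense": 0.65, "synonymous": 0.25}


class ConfigError(ValueError):
    """Invalid synthetic-cohort configuration."""


@dataclass
class SynthConfig:
    """Parameters of the synthetic cohort.

    ``class_rates`` are per-person mean qualifying-allele counts in
    controls for each exclusive mutation class, spread uniformly across the
    panel's genes. ``set_class_or`` maps set name (or ``"panel"`` for all
    genes) -> class -> odds ratio injected on the carrier log-odds scale for
    cases. ``rate_scale`` is a gene's total de novo point-mutation
    probability per chromosome per generation, split across classes by the
    functional spectrum.
    """

    n_cases: int = 5207
    n_controls: int = 4991
    n_cohorts: int = 1
    n_waves: int = 3
    gene_set_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SET_SIZES))
    n_na_alpha: int = 10
    class_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_RATES))
    set_class_or: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    sex_effect: float = 0.0
    pc_effects: tuple = (0.0,) * 10
    wave_effect: float = 0.0
    confound_wave: bool = False   # give cases and controls distinct wave mixes
    paralog_fraction: float = 0.3        # missense sites in channel sets
    paralog_fraction_other: float = 0.0  # missense sites elsewhere
    n_pli_intolerant: int = 106
    n_trios: int = 1136
    rate_scale: float = 1.0e-5
    site_novelty: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        for name, v in (("n_cases", self.n_cases),
                        ("n_controls", self.n_controls),
                        ("n_cohorts", self.n_cohorts),
                        ("n_waves", self.n_waves),
                        ("n_trios", self.n_trios)):
            if v < 0:
                raise ConfigError(f"{name} must be >= 0, got {v}")
        if self.n_cohorts < 1 or self.n_waves < 1:
            raise ConfigError("need at least one cohort and one wave")
        for s, k in self.gene_set_sizes.items():
            if k <= 0:
                raise ConfigError(f"gene set {s!r} has no genes")
        for c, r in self.class_rates.items():
            if c not in MUTATION_CLASSES:
                raise ConfigError(f"unknown mutation class {c!r}")
            if r < 0:
                raise ConfigError(f"rate for {c!r} must be >= 0, got {r}")
            if r / self.n_genes > 1:
                raise ConfigError(
                    f"per-gene carrier probability for {c!r} exceeds 1")
        for s, ors in self.set_class_or.items():
            if s != "panel" and s not in self.gene_set_sizes:
                raise ConfigError(f"odds ratio for unknown set {s!r}")
            for c, o in ors.items():
                if o <= 0:
                    raise ConfigError(f"odds ratio must be > 0, got {o}")
        for name, f in (("paralog_fraction", self.paralog_fraction),
                        ("paralog_fraction_other", self.paralog_fraction_other),
                        ("site_novelty", self.site_novelty)):
            if not (0 <= f <= 1):
                raise ConfigError(f"{name} must be in [0, 1], got {f}")
        if self.rate_scale < 0:
            raise ConfigError("rate_scale must be >= 0")
        if not (0 <= self.n_pli_intolerant <= self.n_genes):
            raise ConfigError("n_pli_intolerant out of range")
        if "Na" in self.gene_set_sizes and \
                self.n_na_alpha > self.gene_set_sizes["Na"]:
            raise ConfigError("more alpha subunits than sodium-channel genes")

    @property
    def n_genes(self) -> int:
        return sum(self.gene_set_sizes.values())

    @property
    def n_individuals(self) -> int:
        return self.n_cases + self.n_controls

    def log_or(self, set_name: str, mclass: str) -> float:
        """Total injected log odds ratio for a gene's set and class."""
        total = 0.0
        for key in ("panel", set_name):
            total += np.log(self.set_class_or.get(key, {}).get(mclass, 1.0))
        return total


def synth_genes(config: SynthConfig,
                rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Gene metadata: symbol, set, subunit tag, pLi, paralog-score flag.

    pLi values are drawn so that exactly ``n_pli_intolerant`` randomly
    chosen genes exceed 0.9 (uniform on (0.905, 1)) and the rest fall at or
    below it (uniform on (0, 0.9)). Paralog conservation scores are marked
    available for all sodium-channel alpha subunits, two of the four beta
    subunits, and all calcium-channel genes.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rows = []
    for set_name, size in config.gene_set_sizes.items():
        for i in range(size):
            sub = "none"
            if set_name == "Na":
                sub = "alpha" if i < config.n_na_alpha else "beta"
            rows.append({"gene": f"{set_name}_{i + 1:03d}", "set": set_name,
                         "subunit": sub})
    genes = pd.DataFrame(rows)
    n = len(genes)
    pli = rng.uniform(0.0, 0.9, size=n)
    intolerant = rng.choice(n, size=config.n_pli_intolerant, replace=False)
    pli[intolerant] = rng.uniform(0.905, 1.0, size=config.n_pli_intolerant)
    genes["pli"] = pli

    avail = np.zeros(n, dtype=bool)
    avail |= ((genes["set"] == "Na") & (genes["subunit"] == "alpha")).to_numpy()
    beta_idx = genes.index[(genes["set"] == "Na")
                           & (genes["subunit"] == "beta")][:2]
    avail[beta_idx] = True
    avail |= (genes["set"] == "Ca").to_numpy()
    genes["paralog_scores_available"] = avail
    return genes


def _individuals(config: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_individuals
    is_case = np.zeros(n, dtype=int)
    is_case[:config.n_cases] = 1
    sex = rng.integers(0, 2, size=n)
    pcs = rng.normal(size=(n, 10))
    if config.confound_wave and config.n_waves > 1:
        # cases weighted toward later waves, controls toward earlier ones
        w = np.arange(config.n_waves, dtype=float) + 1.0
        case_p = w / w.sum()
        ctrl_p = case_p[::-1]
        wave = np.where(is_case == 1,
                        rng.choice(config.n_waves, size=n, p=case_p),
                        rng.choice(config.n_waves, size=n, p=ctrl_p))
    else:
        wave = rng.integers(0, config.n_waves, size=n)
    cohort = rng.integers(0, config.n_cohorts, size=n)
    df = pd.DataFrame({
        "individual_id": [f"ind{i:06d}" for i in range(n)],
        "is_case": is_case, "sex": sex,
        "wave": [f"w{w}" for w in wave],
        "cohort": [f"c{c}" for c in cohort],
    })
    for j in range(10):
        df[f"PC{j + 1}"] = pcs[:, j]
    return df


def _carrier_probs(config: SynthConfig, genes: pd.DataFrame,
                   individuals: pd.DataFrame, mclass: str) -> np.ndarray:
    """(n_individuals, n_genes) carrier probability matrix for one class."""
    base = config.class_rates.get(mclass, 0.0) / config.n_genes
    if base <= 0:
        return np.zeros((len(individuals), len(genes)))
    gene_lor = np.array([config.log_or(s, mclass) for s in genes["set"]])
    pcs = individuals[[f"PC{j}" for j in range(1, 11)]].to_numpy()
    wave_idx = individuals["wave"].str.removeprefix("w").astype(int).to_numpy()
    ind_shift = (individuals["sex"].to_numpy() * config.sex_effect
                 + pcs @ np.asarray(config.pc_effects, dtype=float)
                 + config.wave_effect * wave_idx)
    eta = (logit(base)
           + np.outer(individuals["is_case"].to_numpy(), gene_lor)
           + ind_shift[:, None])
    return expit(eta)


def _sites_from_carriers(carrier_idx: np.ndarray, gene: str, mclass: str,
                         flag_p: float, rng: np.random.Generator,
                         novelty: float, counter: list,
                         individuals: pd.DataFrame,
                         cohorts: np.ndarray | None) -> list[dict]:
    """Group carried alleles of one gene x class into variant sites."""
    sites: list[list[int]] = []
    for i in rng.permutation(carrier_idx):
        if not sites or rng.random() < novelty:
            sites.append([i])
        else:
            sites[rng.integers(len(sites))].append(i)
    ids = individuals["individual_id"].to_numpy()
    rows = []
    for members in sites:
        counter[0] += 1
        row = {"variant_id": f"v{counter[0]:07d}", "gene": gene,
               "mclass": mclass,
               "paralog_conserved": (bool(rng.random() < flag_p)
                                     if mclass in MISSENSE_CLASSES else pd.NA),
               "allele_count": len(members),
               "carriers": [ids[i] for i in members]}
        if cohorts is not None:
            for c in np.unique(cohorts):
                row[f"ac_{c}"] = int((cohorts[members] == c).sum())
        rows.append(row)
    return rows


def synth_cohort(config: SynthConfig
                 ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (variant table, individual table, gene metadata).

    Deterministic under ``config.seed``: identical configurations produce
    identical tables.
    """
    rng = np.random.default_rng(config.seed)
    genes = synth_genes(config, rng)
    individuals = _individuals(config, rng)
    cohorts = (individuals["cohort"].to_numpy()
               if config.n_cohorts > 1 else None)
    counter = [0]
    rows: list[dict] = []
    for mclass in MUTATION_CLASSES:
        probs = _carrier_probs(config, genes, individuals, mclass)
        if not probs.any():
            continue
        draws = rng.random(probs.shape) < probs
        for j, g in enumerate(genes.itertuples()):
            carrier_idx = np.flatnonzero(draws[:, j])
            if carrier_idx.size == 0:
                continue
            if mclass in MISSENSE_CLASSES:
                flag_p = (config.paralog_fraction
                          if g.set in ("Na", "Ca")
                          else config.paralog_fraction_other)
            else:
                flag_p = 0.0
            rows.extend(_sites_from_carriers(
                carrier_idx, g.gene, mclass, flag_p, rng,
                config.site_novelty, counter, individuals, cohorts))
    variants = pd.DataFrame(
        rows, columns=None if rows else
        ["variant_id", "gene", "mclass", "paralog_conserved",
         "allele_count", "carriers"])
    return variants, individuals, genes


def expected_case_count(config: SynthConfig, mclass: str,
                        genes: pd.DataFrame | None = None) -> float:
    """Closed-form expected per-case allele count for one class.

    With covariate effects at zero, each gene contributes
    ``expit(logit(rate/n_genes) + ln OR)`` to a case's expected count; this
    is the generative-model expectation the simulation should match.
    """
    if genes is None:
        genes = synth_genes(config)
    base = config.class_rates.get(mclass, 0.0) / config.n_genes
    if base <= 0:
        return 0.0
    lors = np.array([config.log_or(s, mclass) for s in genes["set"]])
    return float(expit(logit(base) + lors).sum())


def synth_rate_table(genes: pd.DataFrame, config: SynthConfig) -> pd.DataFrame:
    """Per-gene per-class de novo mutation probabilities.

    Each gene's total point-mutation probability is ``rate_scale`` with
    mild lognormal gene-to-gene variation (sigma 0.5, emulating gene-length
    and sequence-context variation), split across LoF, missense and
    synonymous classes by the functional spectrum of coding point
    mutations.
    """
    if len(genes) == 0:
        raise ConfigError("gene list is empty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    total = config.rate_scale * rng.lognormal(mean=-0.125, sigma=0.5,
                                              size=len(genes))
    rows = []
    for g, t in zip(genes["gene"], total):
        for cls, frac in DENOVO_CLASS_FRACTIONS.items():
            rows.append({"gene": g, "class": cls, "mu": t * frac})
    return pd.DataFrame(rows)


def synth_trios(rate_table: pd.DataFrame, config: SynthConfig,
                enrichment: Mapping[str, float] | None = None,
                genes: pd.DataFrame | None = None) -> pd.DataFrame:
    """Observed de novo counts: Poisson(2 * n_trios * mu * enrichment).

    ``enrichment`` maps set name -> fold-enrichment applied to every gene in
    the set (requires ``genes`` metadata to resolve membership); unlisted
    sets are unenriched.
    """
    if (rate_table["mu"] < 0).any():
        raise ConfigError("mutation rates must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    factor = np.ones(len(rate_table))
    if enrichment:
        if genes is None:
            raise ConfigError("gene metadata needed to apply set enrichment")
        gene_set = dict(zip(genes["gene"], genes["set"]))
        factor = rate_table["gene"].map(
            lambda g: enrichment.get(gene_set.get(g, ""), 1.0)).to_numpy()
    lam = 2.0 * config.n_trios * rate_table["mu"].to_numpy() * factor
    out = rate_table[["gene", "class"]].copy()
    out["count"] = rng.poisson(lam)
    return out


def synth_burden_table(n_cases: int, n_controls: int, carrier_rate: float,
                       odds_ratio: float, seed: int,
                       syn_rate: float = 1.0,
                       n_pcs: int = 10) -> pd.DataFrame:
    """Count-level fast path: a ready-to-test burden table for one cell.

    Skips site generation entirely: each individual's qualifying-allele
    count is a single Bernoulli carrier draw at ``carrier_rate`` (odds
    multiplied by ``odds_ratio`` for cases), the baseline synonymous count
    is Poisson(``syn_rate``), and covariates are null. Intended for
    replicate-heavy calibration studies where only the regression input
    matters.
    """
    if not (0 < carrier_rate < 1):
        raise ConfigError("carrier_rate must be in (0, 1)")
    if odds_ratio <= 0:
        raise ConfigError("odds_ratio must be > 0")
    rng = np.random.default_rng(seed)
    n = n_cases + n_controls
    is_case = np.zeros(n, dtype=int)
    is_case[:n_cases] = 1
    p = expit(logit(carrier_rate) + np.log(odds_ratio) * is_case)
    df = pd.DataFrame({
        "individual_id": [f"ind{i:06d}" for i in range(n)],
        "is_case": is_case,
        "sex": rng.integers(0, 2, size=n),
        "n_test_variants": (rng.random(n) < p).astype(int),
        "baseline_synonymous_count": rng.poisson(syn_rate, size=n),
    })
    for j in range(1, n_pcs + 1):
        df[f"PC{j}"] = rng.normal(size=n)
    return df
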