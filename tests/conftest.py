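import numpy as np
import pandas as pd
import pytest

from rareburden import SynthConfig, synth_cohort


def make_individuals(n_cases: int, n_controls: int, seed: int = 0
                     ) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    n = n_cases + n_controls
    df = pd.DataFrame({
        "individual_id": [f"ind{i:06d}" for i in range(n)],
        "is_case": [1] * n_cases + [0] * n_controls,
        "sex": rng.integers(0, 2, size=n),
        "wave": [f"w{w}" for w in rng.integers(0, 2, size=n)],
        "cohort": ["c0"] * n,
    })
    for j in range(1, 11):
        df[f"PC{j}"] = rng.normal(size=n)
    return df


@pytest.fixture(scope="session")
def tiny_individuals() -> pd.DataFrame:
    return make_individuals(10, 10, seed=42)


@pytest.fixture(scope="session")
def tiny_variants(tiny_individuals) -> pd.DataFrame:
    """Hand-buildable 20-site fixture spanning every class and flag state."""
    rng = np.random.default_rng(7)
    ids = tiny_individuals["individual_id"].tolist()
    rows = []
    classes = ["LoF"] * 4 + ["NSD"] * 6 + ["NS_other"] * 5 + ["synonymous"] * 5
    for k, mclass in enumerate(classes):
        n_carriers = int(rng.integers(1, 5))
        carriers = list(rng.choice(ids, size=n_carriers, replace=False))
        if mclass in ("NSD", "NS_other"):
            flag = bool(rng.integers(0, 2))
        else:
            flag = pd.NA
        rows.append({"variant_id": f"v{k:03d}",
                     "gene": f"g{k % 5}", "mclass": mclass,
                     "paralog_conserved": flag,
                     "allele_count": n_carriers, "carriers": carriers})
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but structurally complete synthetic cohort."""
    cfg = SynthConfig(
        n_cases=400, n_controls=400, n_waves=2, n_trios=200,
        gene_set_sizes={"ARC": 6, "NMDAR": 8, "Na": 14, "Ca": 6, "other": 6},
        n_pli_intolerant=20, seed=11)
    variants, individuals, genes = synth_cohort(cfg)
    return cfg, variants, individuals, genes
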