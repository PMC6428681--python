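"""Generative-model properties of the synthetic cohort."""

import numpy as np
import pandas as pd
import pytest

from rareburden import (SynthConfig, burden_counts, expected_case_count,
                        synth_burden_table, synth_cohort, synth_genes,
                        synth_rate_table, synth_trios)
from rareburden.filtering import explode_carriers
from rareburden.simulate import ConfigError

SMALL_SETS = {"ARC": 5, "NMDAR": 6, "Na": 14, "Ca": 5, "other": 5}


class TestConfigValidation:
    def test_empty_set_rejected(self):
        with pytest.raises(ConfigError, match="no genes"):
            SynthConfig(gene_set_sizes={"ARC": 0}, n_pli_intolerant=0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ConfigError):
            SynthConfig(class_rates={"LoF": -0.1})

    def test_nonpositive_odds_ratio_rejected(self):
        with pytest.raises(ConfigError):
            SynthConfig(set_class_or={"panel": {"LoF": 0.0}})

    def test_default_panel_is_187_genes(self):
        cfg = SynthConfig()
        assert cfg.n_genes == 187
        assert cfg.n_cases == 5207 and cfg.n_controls == 4991
        assert cfg.n_trios == 1136


class TestSynthCohort:
    def test_seed_determinism(self):
        cfg = SynthConfig(n_cases=80, n_controls=80, n_trios=50,
                          gene_set_sizes=SMALL_SETS, n_pli_intolerant=10,
                          seed=3)
        v1, i1, g1 = synth_cohort(cfg)
        v2, i2, g2 = synth_cohort(cfg)
        pd.testing.assert_frame_equal(v1, v2)
        pd.testing.assert_frame_equal(i1, i2)
        pd.testing.assert_frame_equal(g1, g2)

    def test_null_or_gives_balanced_carrier_rates(self):
        cfg = SynthConfig(n_cases=2000, n_controls=2000, n_trios=10,
                          gene_set_sizes=SMALL_SETS, n_pli_intolerant=10,
                          class_rates={"LoF": 0.5}, seed=5)
        v, ind, _ = synth_cohort(cfg)
        table = burden_counts(v, ind, analysis_class="LoF", threshold=1.0)
        case = table[table["is_case"] == 1]["n_test_variants"].mean()
        ctrl = table[table["is_case"] == 0]["n_test_variants"].mean()
        # MC SD of the rate ratio at rate .5, n=2000 per arm
        sd = np.sqrt(0.5 / 2000 * 2) / 0.5
        assert abs(case / ctrl - 1) < 3 * sd

    def test_injected_or_matches_closed_form_expectation(self):
        cfg = SynthConfig(n_cases=5207, n_controls=4991, n_trios=10,
                          gene_set_sizes=SMALL_SETS, n_pli_intolerant=10,
                          class_rates={"LoF": 0.039},
                          set_class_or={"panel": {"LoF": 1.36}}, seed=8)
        v, ind, genes = synth_cohort(cfg)
        expected = expected_case_count(cfg, "LoF", genes)
        table = burden_counts(v, ind, analysis_class="LoF", threshold=1.0)
        case_mean = table[table["is_case"] == 1]["n_test_variants"].mean()
        sd = np.sqrt(expected / cfg.n_cases)  # Poisson-binomial MC SD
        assert abs(case_mean - expected) < 3 * sd
        # and control mean sits at the baseline rate
        ctrl_mean = table[table["is_case"] == 0]["n_test_variants"].mean()
        assert abs(ctrl_mean - 0.039) < 3 * np.sqrt(0.039 / cfg.n_controls)

    def test_allele_counts_equal_carrier_lists(self):
        cfg = SynthConfig(n_cases=150, n_controls=150, n_trios=10,
                          gene_set_sizes=SMALL_SETS, n_pli_intolerant=10,
                          seed=2)
        v, ind, _ = synth_cohort(cfg)
        assert (v["carriers"].map(len) == v["allele_count"]).all()
        # total alleles = total carried events
        assert len(explode_carriers(v)) == v["allele_count"].sum()

    def test_paralog_flags_only_on_channel_missense(self):
        cfg = SynthConfig(n_cases=300, n_controls=300, n_trios=10,
                          gene_set_sizes=SMALL_SETS, n_pli_intolerant=10,
                          paralog_fraction=0.5, seed=4)
        v, _, genes = synth_cohort(cfg)
        gene_set = dict(zip(genes["gene"], genes["set"]))
        nonmissense = v[v["mclass"].isin(("LoF", "synonymous"))]
        assert nonmissense["paralog_conserved"].isna().all()
        flagged = v[v["paralog_conserved"] == True]  # noqa: E712
        assert all(gene_set[g] in ("Na", "Ca") for g in flagged["gene"])

    def test_degenerate_pcs_detected_downstream(self):
        from rareburden import burden_test
        from rareburden.firth import RankDeficientError
        cfg = SynthConfig(n_cases=100, n_controls=100, n_trios=10,
                          gene_set_sizes=SMALL_SETS, n_pli_intolerant=10,
                          seed=6)
        v, ind, _ = synth_cohort(cfg)
        ind = ind.copy()
        ind["PC1"] = ind["PC2"]  # collinear ancestry covariates
        table = burden_counts(v, ind, analysis_class="NS", threshold=1.0)
        with pytest.raises(RankDeficientError):
            burden_test(table)


class TestGeneMetadata:
    def test_pli_counts_and_subunits(self):
        cfg = SynthConfig(seed=1)
        genes = synth_genes(cfg)
        assert len(genes) == 187
        assert (genes["pli"] > 0.9).sum() == 106
        assert (genes["pli"] <= 0.9).sum() == 81
        na = genes[genes["set"] == "Na"]
        assert (na["subunit"] == "alpha").sum() == 10
        assert (na["subunit"] == "beta").sum() == 4
        # paralog scores: all alphas, exactly two betas
        assert na[na["subunit"] == "alpha"]["paralog_scores_available"].all()
        assert na[na["subunit"] == "beta"]["paralog_scores_available"].sum() == 2


class TestRateTableAndTrios:
    def test_lambda_reproducible_and_linear_in_trios(self):
        from rareburden import expected_count
        cfg = SynthConfig(n_cases=10, n_controls=10, n_trios=1136,
                          gene_set_sizes=SMALL_SETS, n_pli_intolerant=10,
                          seed=9)
        genes = synth_genes(cfg)
        rt = synth_rate_table(genes, cfg)
        assert (rt["mu"] >= 0).all()
        lam = expected_count(rt, genes["gene"], ["LoF", "missense"], 1136)
        assert lam == pytest.approx(2 * 1136 * rt[rt["class"].isin(
            ["LoF", "missense"])]["mu"].sum())
        lam2 = expected_count(rt, genes["gene"], ["LoF", "missense"], 2272)
        assert lam2 == pytest.approx(2 * lam)

    def test_calibrated_rates_reproduce_target_lambda(self):
        # rates scaled so a 28-gene set's LoF+missense mu sums to
        # 7.218e-4 -> mean simulated count over replicates ~ 1.64
        genes = pd.DataFrame({"gene": [f"g{i}" for i in range(28)],
                              "set": "ARC"})
        mu = 7.218e-4 / 28
        rt = pd.DataFrame([{"gene": g, "class": "LoF", "mu": mu}
                           for g in genes["gene"]])
        counts = []
        for seed in range(300):
            cfg = SynthConfig(n_cases=10, n_controls=10, n_trios=1136,
                              gene_set_sizes={"ARC": 28},
                              n_pli_intolerant=5, seed=seed)
            counts.append(synth_trios(rt, cfg)["count"].sum())
        lam = 1.64
        assert np.mean(counts) == pytest.approx(
            lam, abs=3 * np.sqrt(lam / 300))

    def test_zero_rates_give_zero_counts(self):
        cfg = SynthConfig(n_cases=10, n_controls=10, n_trios=500,
                          gene_set_sizes=SMALL_SETS, n_pli_intolerant=10,
                          rate_scale=0.0, seed=1)
        genes = synth_genes(cfg)
        rt = synth_rate_table(genes, cfg)
        assert (synth_trios(rt, cfg)["count"] == 0).all()

    def test_zero_trios_give_zero_counts(self):
        cfg = SynthConfig(n_cases=10, n_controls=10, n_trios=0,
                          gene_set_sizes=SMALL_SETS, n_pli_intolerant=10,
                          seed=1)
        genes = synth_genes(cfg)
        rt = synth_rate_table(genes, cfg)
        assert (synth_trios(rt, cfg)["count"] == 0).all()

    def test_set_enrichment_scales_mean_counts(self):
        genes = pd.DataFrame({"gene": [f"g{i}" for i in range(20)],
                              "set": ["focal"] * 10 + ["rest"] * 10})
        rt = pd.DataFrame([{"gene": g, "class": "LoF", "mu": 2e-4}
                           for g in genes["gene"]])
        focal_counts, rest_counts = [], []
        for seed in range(200):
            cfg = SynthConfig(n_cases=10, n_controls=10, n_trios=500,
                              gene_set_sizes={"focal": 10, "rest": 10},
                              n_pli_intolerant=5, seed=seed)
            tr = synth_trios(rt, cfg, enrichment={"focal": 4.0}, genes=genes)
            focal_counts.append(
                tr[tr["gene"].isin(genes["gene"][:10])]["count"].sum())
            rest_counts.append(
                tr[tr["gene"].isin(genes["gene"][10:])]["count"].sum())
        lam = 2 * 500 * 10 * 2e-4  # 2.0 per replicate, unenriched
        assert np.mean(rest_counts) == pytest.approx(
            lam, abs=3 * np.sqrt(lam / 200))
        assert np.mean(focal_counts) == pytest.approx(
            4 * lam, abs=3 * np.sqrt(4 * lam / 200))


class TestSynthBurdenTable:
    def test_fast_path_counts_match_rates(self):
        df = synth_burden_table(4000, 4000, 0.04, 1.0, seed=12)
        assert df["n_test_variants"].mean() == pytest.approx(
            0.04, abs=3 * np.sqrt(0.04 / 8000))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ConfigError):
            synth_burden_table(10, 10, 1.5, 1.0, seed=0)
        with pytest.raises(ConfigError):
            synth_burden_table(10, 10, 0.1, -1.0, seed=0)
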