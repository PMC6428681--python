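"""Gene-set orchestration: pLi partition, plans, single-gene scan."""

import numpy as np
import pandas as pd
import pytest

from rareburden import (CORRECTION_LEDGER, SynthConfig, partition_by_pli,
                        restrict_paralog_flags, run_plan, single_gene_scan,
                        synth_cohort)
from rareburden.genesets import (GeneSetDefinition, GeneSetError,
                                 PRESET_BUILDERS, burden_six_test_plan,
                                 geneset_primary_plan, paralog_secondary_plan,
                                 sets_from_metadata, sodium_subunit_sets,
                                 subunit_dissection_plan)


class TestGeneSetDefinition:
    def test_empty_and_duplicate_sets_rejected(self):
        with pytest.raises(GeneSetError):
            GeneSetDefinition("empty", ())
        with pytest.raises(GeneSetError):
            GeneSetDefinition("dup", ("a", "a"))


class TestPartitionByPli:
    def test_reproduces_panel_partition_sizes(self):
        meta = pd.DataFrame({
            "gene": [f"g{i}" for i in range(187)],
            "pli": [0.95] * 106 + [0.5] * 81})
        intol, tol = partition_by_pli(meta)
        assert (len(intol), len(tol)) == (106, 81)

    def test_boundary_value_is_tolerant(self):
        meta = pd.DataFrame({"gene": ["a", "b"], "pli": [0.9, 0.91]})
        intol, tol = partition_by_pli(meta)
        assert intol == ["b"] and tol == ["a"]

    def test_empty_panel_and_missing_pli_rejected(self):
        with pytest.raises(GeneSetError):
            partition_by_pli(pd.DataFrame({"gene": [], "pli": []}))
        meta = pd.DataFrame({"gene": ["a"], "pli": [np.nan]})
        with pytest.raises(GeneSetError, match="a"):
            partition_by_pli(meta)


class TestPlans:
    @pytest.fixture
    def gene_meta(self):
        return synth_cohort(SynthConfig(
            n_cases=50, n_controls=50, n_trios=10, n_pli_intolerant=100,
            seed=0))[2]

    def test_correction_constants_appear_once_each(self, gene_meta):
        plans = [b(gene_meta) for b in PRESET_BUILDERS.values()]
        ms = {p.name: {r.m_tests for r in p.rows} for p in plans}
        # each family carries exactly one correction constant
        assert all(len(v) == 1 for v in ms.values())
        seen = sorted(next(iter(v)) for v in ms.values())
        assert seen == [4, 6, 8, 12]
        assert CORRECTION_LEDGER["single_gene"] == 20000

    def test_six_burden_tests(self):
        plan = burden_six_test_plan()
        assert len(plan.rows) == 6
        assert {(r.analysis_class, r.regime) for r in plan.rows} == {
            (c, r) for c in ("LoF", "NSD", "NS")
            for r in ("maf_lt", "singleton")}

    def test_sodium_alpha_subset_has_ten_genes(self, gene_meta):
        subs = sodium_subunit_sets(gene_meta)
        assert len(subs["alpha"]) == 10
        assert len(subs["beta"]) == 4
        plan = subunit_dissection_plan(gene_meta)
        assert all(r.m_tests == 12 for r in plan.rows)

    def test_primary_plan_covers_four_sets(self, gene_meta):
        plan = geneset_primary_plan(sets_from_metadata(gene_meta))
        assert len(plan.rows) == 4
        assert all(r.analysis_class == "LoF" and r.m_tests == 4
                   for r in plan.rows)

    def test_secondary_plan_flags(self, gene_meta):
        plan = paralog_secondary_plan(sets_from_metadata(gene_meta),
                                      exclude_lof=True)
        assert all(r.exclude_lof and r.m_tests == 8 for r in plan.rows)


class TestRunPlan:
    def test_results_shape_and_statuses(self, small_cohort):
        _, variants, individuals, gene_meta = small_cohort
        plan = burden_six_test_plan()
        res = run_plan(plan, variants, individuals, include_wave=True)
        assert len(res) == 6
        tested = res[res["status"] == "tested"]
        assert (tested["p_corrected"] >= tested["p"] - 1e-12).all()
        assert (tested["p_corrected"] <= 1.0).all()

    def test_permutation_columns_added(self, small_cohort):
        _, variants, individuals, gene_meta = small_cohort
        plan = geneset_primary_plan(sets_from_metadata(gene_meta))
        res = run_plan(plan, variants, individuals, n_perm=20, seed=5)
        tested = res[res["status"] == "tested"]
        if len(tested):
            assert tested["p_empirical"].between(1 / 21, 1).all()
            assert (tested["perm_seed"] == 5).all()

    def test_null_calibration_after_correction(self):
        # null generator: corrected p > .05 for all 6 tests in >= 95% of
        # replicates (Bonferroni controls family-wise error below 5%)
        clean = 0
        n_rep = 60
        for seed in range(n_rep):
            cfg = SynthConfig(
                n_cases=150, n_controls=150, n_trios=5, n_waves=1,
                gene_set_sizes={"ARC": 4, "NMDAR": 4, "Na": 14, "Ca": 4,
                                "other": 4},
                n_pli_intolerant=10, seed=seed)
            v, ind, _ = synth_cohort(cfg)
            res = run_plan(burden_six_test_plan(threshold=1.0), v, ind)
            tested = res[res["status"] == "tested"]
            clean += (tested["p_corrected"] > 0.05).all()
        assert clean / n_rep >= 0.90


class TestRestrictParalogFlags:
    def test_unscored_genes_lose_missense_flags(self, small_cohort):
        _, variants, _, gene_meta = small_cohort
        restricted = restrict_paralog_flags(variants, gene_meta)
        unscored = set(gene_meta[~gene_meta["paralog_scores_available"]]
                       ["gene"])
        sub = restricted[restricted["gene"].isin(unscored)]
        assert sub["paralog_conserved"].isna().all()
        # scored genes keep their flags
        scored = set(gene_meta[gene_meta["paralog_scores_available"]]["gene"])
        before = variants[variants["gene"].isin(scored)]["paralog_conserved"]
        after = restricted[restricted["gene"].isin(scored)]["paralog_conserved"]
        assert before.fillna(-1).tolist() == after.fillna(-1).tolist()


class TestSingleGeneScan:
    def test_zero_carrier_genes_untested_and_counts_conserved(
            self, small_cohort):
        _, variants, individuals, gene_meta = small_cohort
        genes = gene_meta["gene"].tolist()[:12] + ["no_such_gene"]
        res = single_gene_scan(variants, individuals, genes,
                               analysis_class="LoF", threshold=1.0)
        assert len(res) == len(genes)
        assert (res[res["gene"] == "no_such_gene"]["status"]
                == "untested").all()
        tested = res[res["status"] == "tested"]
        assert tested["p"].between(0, 1).all()
        # exome-wide correction applied
        assert np.allclose(tested["p_corrected"],
                           np.minimum(1.0, tested["p"] * 20000))

    def test_strong_single_gene_signal_detected(self):
        # power smoke test: one gene with a large injected odds ratio
        rng = np.random.default_rng(13)
        n = 5000
        individuals = pd.DataFrame({
            "individual_id": [f"i{k}" for k in range(2 * n)],
            "is_case": [1] * n + [0] * n})
        rate, or_ = 0.002, 8.0
        p_case = rate * or_ / (1 - rate + rate * or_)
        carriers, rows = [], []
        vid = 0
        for label, p in (("case", p_case), ("ctrl", rate)):
            idx = np.flatnonzero(rng.random(n) < p)
            offset = 0 if label == "case" else n
            for i in idx:
                rows.append({"variant_id": f"v{vid}", "gene": "focal",
                             "mclass": "LoF", "paralog_conserved": pd.NA,
                             "allele_count": 1,
                             "carriers": [f"i{i + offset}"]})
                vid += 1
        # background synonymous sites so the baseline covariate varies
        for k in range(200):
            i = int(rng.integers(2 * n))
            rows.append({"variant_id": f"s{k}", "gene": "bg",
                         "mclass": "synonymous", "paralog_conserved": pd.NA,
                         "allele_count": 1, "carriers": [f"i{i}"]})
        variants = pd.DataFrame(rows)
        res = single_gene_scan(variants, individuals, ["focal"])
        assert (res["status"] == "tested").all()
        assert float(res["p_corrected"].iloc[0]) < 0.05
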