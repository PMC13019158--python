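"""Genotype merging, candidate filtering, DE ranking, and impact scoring."""

import numpy as np
import pandas as pd
import pytest

from popimmune import prioritize as pr
from popimmune.genotypes import MISSING


class TestMergeGenotypeCalls:
    def sources(self):
        idx = ["s1", "s2", "s3"]
        cols = ["c1", "c2"]
        array = pd.DataFrame([[1, MISSING], [MISSING, MISSING], [0, 2]],
                             index=idx, columns=cols)
        wes = pd.DataFrame([[2, 1], [MISSING, MISSING], [1, MISSING]],
                           index=idx, columns=cols)
        imputed = pd.DataFrame([[0, 0], [0, MISSING], [0, 0]],
                               index=idx, columns=cols)
        return {"array": array, "wes": wes, "imputed": imputed}

    def test_priority_order(self):
        merged, prov = pr.merge_genotype_calls(self.sources())
        assert merged.loc["s1", "c1"] == 1          # array beats WES
        assert prov.loc["s1", "c1"] == "array"
        assert merged.loc["s1", "c2"] == 1          # WES beats imputed
        assert prov.loc["s1", "c2"] == "wes"
        assert merged.loc["s2", "c1"] == 0          # imputation fallback
        assert prov.loc["s2", "c1"] == "imputed"

    def test_all_missing_stays_missing(self):
        merged, prov = pr.merge_genotype_calls(self.sources())
        assert merged.loc["s2", "c2"] == MISSING
        assert prov.loc["s2", "c2"] == ""

    def test_conflicting_site_definition_rejected(self):
        info_a = pd.DataFrame({"ref": ["A"], "alt": ["G"]}, index=["s1"])
        info_b = pd.DataFrame({"ref": ["A"], "alt": ["T"]}, index=["s1"])
        with pytest.raises(ValueError, match="s1"):
            pr.merge_genotype_calls(self.sources(),
                                    site_info={"array": info_a, "wes": info_b})

    def test_unknown_source_rejected(self):
        with pytest.raises(ValueError):
            pr.merge_genotype_calls({"typo": pd.DataFrame()})


class TestCandidateFilter:
    def fixture(self):
        """12 SNPs engineered so steps remove 2 / 3 / 1 / 2 -> 4 survive."""
        genes = [f"PRR{i}" for i in range(10)]
        snps = pd.DataFrame({
            "gene": (["OTHER1", "OTHER2"]          # fail step 1
                     + ["PRR0", "PRR1", "PRR2"]    # fail step 2 (not expressed)
                     + ["PRR3"]                    # fail step 3 (low F_ST)
                     + ["PRR4", "PRR5"]            # fail step 4 (low MAF)
                     + ["PRR6", "PRR7", "PRR8", "PRR9"]),
            "maf": [0.4, 0.4, 0.4, 0.4, 0.4, 0.4, 0.15, 0.1, 0.3, 0.35, 0.25, 0.45],
        }, index=[f"snp{i}" for i in range(12)])
        expressed = pd.DataFrame(
            5.0, index=genes + ["OTHER1", "OTHER2"], columns=[f"cl{i}" for i in range(20)])
        expressed.loc[["PRR0", "PRR1", "PRR2"]] = 0.0
        gene_fst = pd.DataFrame({"max_fst": 0.3}, index=genes + ["OTHER1", "OTHER2"])
        gene_fst.loc["PRR3", "max_fst"] = 0.05
        cfg = pr.CandidateFilterConfig(gene_list=frozenset(genes))
        return snps, gene_fst, expressed, cfg

    def test_step_tallies(self):
        snps, gene_fst, expressed, cfg = self.fixture()
        survivors, tallies = pr.candidate_filter(snps, gene_fst, expressed, cfg)
        assert list(tallies["n_removed"]) == [0, 2, 3, 1, 2]
        assert len(survivors) == 4
        assert set(survivors) == {"snp8", "snp9", "snp10", "snp11"}

    def test_tallies_sum(self):
        snps, gene_fst, expressed, cfg = self.fixture()
        survivors, tallies = pr.candidate_filter(snps, gene_fst, expressed, cfg)
        assert len(snps) - tallies["n_removed"].sum() == len(survivors)

    def test_empty_gene_list(self):
        snps, gene_fst, expressed, _ = self.fixture()
        cfg = pr.CandidateFilterConfig(gene_list=frozenset())
        survivors, tallies = pr.candidate_filter(snps, gene_fst, expressed, cfg)
        assert len(survivors) == 0
        assert tallies.loc["prr_gene", "n_remaining"] == 0

    def test_maf_boundary_strict(self):
        snps, gene_fst, expressed, cfg = self.fixture()
        snps.loc["snp11", "maf"] = 0.2  # exactly at the threshold -> excluded
        survivors, _ = pr.candidate_filter(snps, gene_fst, expressed, cfg)
        assert "snp11" not in survivors


class TestDeRank:
    def test_identical_groups_all_zero(self, rng):
        counts = pd.DataFrame(rng.poisson(50, size=(20, 10)),
                              index=[f"g{i}" for i in range(20)])
        counts = pd.concat([counts, counts], axis=1, ignore_index=True)
        mask = np.array([False] * 10 + [True] * 10)
        ranked = pr.de_rank(counts, mask)
        assert np.allclose(ranked.to_numpy(), 0.0, atol=1e-12)

    def test_doubled_gene_ranks_first(self, rng):
        counts = pd.DataFrame(rng.poisson(100, size=(30, 40)).astype(float),
                              index=[f"g{i}" for i in range(30)])
        mask = np.array([False] * 20 + [True] * 20)
        counts.loc["g7", mask] = counts.loc["g7", mask] * 2
        ranked = pr.de_rank(counts, mask)
        assert ranked.index[0] == "g7"
        assert ranked.iloc[0] == pytest.approx(1.0, abs=0.2)

    def test_label_swap_reverses_ranking(self, rng):
        counts = pd.DataFrame(rng.poisson(80, size=(25, 30)).astype(float),
                              index=[f"g{i}" for i in range(25)])
        mask = np.array([False] * 15 + [True] * 15)
        fwd = pr.de_rank(counts, mask)
        rev = pr.de_rank(counts, ~mask)
        assert np.allclose(np.sort(fwd.to_numpy()), np.sort(-rev.to_numpy()),
                           atol=1e-9)

    def test_empty_group_rejected(self, rng):
        counts = pd.DataFrame(rng.poisson(10, size=(5, 4)))
        with pytest.raises(ValueError):
            pr.de_rank(counts, np.array([True] * 4))


class TestRankScale:
    def test_equally_spaced(self):
        assert np.allclose(pr.rank_scale([10, 20, 30]), [0, 0.5, 1.0])

    def test_average_ranks_for_ties(self):
        assert np.allclose(pr.rank_scale([5, 5, 9]), [0, 0, 1.0])

    def test_output_follows_input_order(self):
        z = pr.rank_scale([30, 10, 20])
        assert np.allclose(z, [1.0, 0.0, 0.5])

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pr.rank_scale([3, 3, 3])

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=25)
        assert np.allclose(pr.rank_scale(x), pr.rank_scale(np.exp(x)))


class TestImpactScore:
    def test_extremes(self):
        assert pr.impact_score(1, 1, 1) == pytest.approx(2.5)
        assert pr.impact_score(0, 0, 0) == 0.0

    def test_worked_example(self):
        assert pr.impact_score(0.5, 0.2, 0.8) == pytest.approx(1.1)

    def test_component_bounds_enforced(self):
        with pytest.raises(ValueError):
            pr.impact_score(1.2, 0.0, 0.0)

    def test_monotone_in_each_component(self, rng):
        for _ in range(25):
            z = rng.random(3)
            base = pr.impact_score(*z)
            for i in range(3):
                z2 = z.copy()
                z2[i] = min(1.0, z2[i] + 0.1)
                assert pr.impact_score(*z2) >= base


# ---------------------------------------------------------------- pipeline

def build_cohort(seed, effect_log2, n_snps=20, n_samples=120, n_genes=400):
    """Synthetic cell-line cohort with one engineered causal SNP (index 0)."""
    from popimmune import simulate as sim
    from popimmune.genotypes import SITE_COLUMNS, GenotypeMatrix

    rng = np.random.default_rng(seed)
    isg = tuple(f"ISG{i}" for i in range(38))
    mafs = rng.uniform(0.25, 0.45, n_snps)
    dosages = rng.binomial(2, mafs, size=(n_samples, n_snps))
    snp_ids = [f"snp{i:02d}" for i in range(n_snps)]
    genes = [f"PRRG{i:02d}" for i in range(n_snps)]
    sites = pd.DataFrame(
        {"chrom": "1", "pos": np.arange(1, n_snps + 1) * 1000, "ref": "A",
         "alt": "G", "gene": genes, "consequence": "missense_variant"},
        index=pd.Index(snp_ids, name="site_id"))[SITE_COLUMNS]
    g = GenotypeMatrix([f"CL{i:04d}" for i in range(n_samples)],
                       np.array(["cohort"] * n_samples), sites, dosages)
    spec = sim.ExpressionSimSpec(n_genes, isg, effect_log2, dispersion=0.1,
                                 seed=int(rng.integers(2 ** 31)))
    counts, _ = sim.simulate_expression(dosages[:, 0], spec)
    counts.columns = g.sample_ids
    gene_fst = pd.DataFrame(
        {"mean_fst": rng.uniform(0.08, 0.2, n_snps),
         "max_fst": rng.uniform(0.12, 0.3, n_snps)}, index=genes)
    gene_fst.loc[genes[0], "max_fst"] = 0.5
    site_fst = pd.Series(rng.uniform(0.1, 0.3, n_snps), index=snp_ids)
    site_fst.loc[snp_ids[0]] = 0.5
    pubs = pd.Series(rng.integers(0, 30, n_snps).astype(float), index=snp_ids)
    pubs.loc[snp_ids[0]] = 100.0
    fpkm = pd.DataFrame(5.0, index=genes, columns=counts.columns)
    cfg = pr.CandidateFilterConfig(gene_list=frozenset(genes))
    return dict(genotypes=g, expression=counts, gene_fst=gene_fst,
                publication_counts=pubs, isg_set=set(isg), cfg=cfg,
                site_fst=site_fst, fpkm=fpkm)


class TestPipeline:
    def test_causal_snp_ranks_first(self):
        cohort = build_cohort(seed=101, effect_log2=1.0)
        table, tallies = pr.prioritize_pipeline(n_perm=500, seed=7, **cohort)
        assert table.index[0] == "snp00"
        assert table.loc["snp00", "passed"]
        assert tallies["n_remaining"].iloc[-1] == 20

    def test_null_cohort_no_pass(self):
        cohort = build_cohort(seed=202, effect_log2=0.0)
        table, _ = pr.prioritize_pipeline(n_perm=500, seed=8, **cohort)
        assert not table["passed"].any()

    def test_order_invariance(self):
        cohort = build_cohort(seed=303, effect_log2=1.0)
        table, _ = pr.prioritize_pipeline(n_perm=300, seed=9, **cohort)
        # permute input SNP order: identical output up to the row-order key
        g = cohort["genotypes"]
        perm = np.random.default_rng(1).permutation(g.n_sites)
        from popimmune.genotypes import GenotypeMatrix
        cohort["genotypes"] = GenotypeMatrix(
            g.sample_ids, g.population_labels,
            g.sites.iloc[perm], g.dosages[:, perm])
        table2, _ = pr.prioritize_pipeline(n_perm=300, seed=9, **cohort)
        pd.testing.assert_frame_equal(table.sort_index(), table2.sort_index())

    def test_too_few_candidates_guidance(self):
        cohort = build_cohort(seed=404, effect_log2=0.0)
        cohort["cfg"] = pr.CandidateFilterConfig(gene_list=frozenset(["PRRG00"]))
        with pytest.raises(ValueError, match="rank"):
            pr.prioritize_pipeline(n_perm=300, seed=1, **cohort)

    def test_determinism(self):
        cohort = build_cohort(seed=55, effect_log2=0.5)
        t1, _ = pr.prioritize_pipeline(n_perm=300, seed=4, **cohort)
        t2, _ = pr.prioritize_pipeline(n_perm=300, seed=4, **cohort)
        pd.testing.assert_frame_equal(t1, t2)


class TestRankScaleProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.lists(st.floats(min_value=-1e6, max_value=1e6), min_size=2,
                    max_size=40).filter(lambda xs: len(set(xs)) > 1))
    @settings(derandomize=True, max_examples=100)
    def test_bounds_and_extremes(self, values):
        z = pr.rank_scale(values)
        assert (0.0 <= z).all() and (z <= 1.0).all()
        assert z[int(np.argmin(values))] == 0.0
        assert z[int(np.argmax(values))] == 1.0
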