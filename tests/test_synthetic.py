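import numpy as np
import pandas as pd
import pytest

from medipscape import binning, expression, fst
from medipscape.synthetic import (
    SimulationConfig,
    simulate_expression,
    simulate_genome,
    simulate_haplotypes,
    simulate_reads,
)

from oracles import cpg_oe_naive

TINY = dict(chrom_lengths={"chr1": 45_000}, n_genes=4, reads_per_sample=10_000,
            n_planted_dmrs=8)


class TestGenome:
    def test_seed_determinism_byte_identical(self, small_config):
        g1, genes1, t1 = simulate_genome(small_config)
        g2, genes2, t2 = simulate_genome(small_config)
        assert g1 == g2
        assert genes1 == genes2
        assert t1.propensity.equals(t2.propensity)

    def test_no_islands_means_low_oe_everywhere(self):
        cfg = SimulationConfig(seed=3, cpg_island_fraction=0.0, **{
            k: v for k, v in TINY.items() if k != "n_planted_dmrs"})
        genome, _, _ = simulate_genome(cfg)
        seq = genome["chr1"]
        # brute-force scan: every 200-bp window stays below the island threshold
        step_max = max(
            cpg_oe_naive(seq[i:i + 200]) for i in range(0, len(seq) - 200 + 1, 50)
        )
        assert step_max < 0.6

    def test_no_genes_valid_outputs(self):
        cfg = SimulationConfig(seed=1, n_genes=0, chrom_lengths={"chr1": 30_000},
                               n_planted_dmrs=0)
        genome, genes, truth = simulate_genome(cfg)
        assert genes == []
        assert len(genome["chr1"]) == 30_000
        assert len(truth.bins) == 100

    def test_gene_overflow_rejected(self):
        cfg = SimulationConfig(seed=1, n_genes=50, chrom_lengths={"chr1": 30_000})
        with pytest.raises(ValueError, match="genes"):
            simulate_genome(cfg)

    def test_planted_propensity_ratio_exact(self, small_config):
        _, _, truth = simulate_genome(small_config)
        prop = truth.propensity
        for row in truth.planted.itertuples(index=False):
            others = [b for b in prop.columns if b != row.breed]
            for other in others:
                ratio = prop.loc[row.bin, row.breed] / prop.loc[row.bin, other]
                expected = small_config.dmr_fold if row.direction == "up" \
                    else 1 / small_config.dmr_fold
                assert ratio == pytest.approx(expected)


class TestReads:
    def test_exact_read_count_per_sample(self):
        cfg = SimulationConfig(seed=2, reads_per_sample=1000,
                               chrom_lengths={"chr1": 45_000}, n_genes=4,
                               n_planted_dmrs=0)
        _, _, truth = simulate_genome(cfg)
        reads, totals = simulate_reads(cfg, truth)
        for sample, df in reads.items():
            assert len(df) == 1000
            assert totals[sample] == 1000

    def test_count_conservation_through_binning(self):
        cfg = SimulationConfig(seed=2, **TINY)
        _, _, truth = simulate_genome(cfg)
        reads, _ = simulate_reads(cfg, truth)
        bc = binning.count_reads(truth.bins, reads, cfg.breed_of)
        assert (bc.counts.sum(axis=0) == cfg.reads_per_sample).all()

    def test_noiseless_replicates_highly_correlated(self):
        cfg = SimulationConfig(seed=4, replicate_noise_sd=0.0,
                               chrom_lengths={"chr1": 120_000}, n_genes=8,
                               reads_per_sample=200_000, n_planted_dmrs=0)
        _, _, truth = simulate_genome(cfg)
        reads, _ = simulate_reads(cfg, truth)
        bc = binning.count_reads(truth.bins, reads, cfg.breed_of)
        r = np.corrcoef(bc.counts["UQ_rep1"], bc.counts["UQ_rep2"])[0, 1]
        assert r >= 0.99

    def test_propensity_doubling_doubles_expected_counts(self):
        cfg = SimulationConfig(seed=5, chrom_lengths={"chr1": 30_000}, n_genes=0,
                               reads_per_sample=10_000, n_planted_dmrs=0,
                               replicate_noise_sd=0.0, breeds=("X",),
                               replicates_per_breed=1)
        _, _, truth = simulate_genome(cfg)
        target = truth.bins.index[10]

        def mean_count(truth_obj, offset):
            total = 0
            for rep in range(100):
                cfg_rep = SimulationConfig(**{**cfg.__dict__, "seed": offset + rep})
                reads, _ = simulate_reads(cfg_rep, truth_obj)
                bc = binning.count_reads(truth.bins, reads)
                total += bc.counts.loc[target].iloc[0]
            return total / 100

        before = mean_count(truth, 100)
        truth.propensity.loc[target, "X"] *= 2
        after = mean_count(truth, 300)
        assert after / before == pytest.approx(2.0, rel=0.15)

    def test_planted_enrichment_ratio_near_fold(self):
        # planted bins should realise close to the configured propensity fold
        cfg = SimulationConfig(seed=6, chrom_lengths={"chr1": 60_000}, n_genes=5,
                               reads_per_sample=60_000, n_planted_dmrs=8)
        _, _, truth = simulate_genome(cfg)
        ratios = []
        for rep in range(40):
            cfg_rep = SimulationConfig(**{**cfg.__dict__, "seed": 500 + rep})
            reads, _ = simulate_reads(cfg_rep, truth)
            bc = binning.count_reads(truth.bins, reads, cfg.breed_of)
            scores = binning.enrichment_matrix(bc)
            breed_scores, _ = binning.replicate_qc_and_average(scores, cfg.breed_of)
            for row in truth.planted.itertuples(index=False):
                others = [b for b in breed_scores.columns if b != row.breed]
                num = breed_scores.loc[row.bin, row.breed]
                den = breed_scores.loc[row.bin, others].mean()
                if den > 0:
                    ratios.append(num / den if row.direction == "up" else den / num)
        assert np.mean(ratios) == pytest.approx(cfg.dmr_fold, rel=0.2)

    def test_all_zero_propensity_rejected(self):
        cfg = SimulationConfig(seed=1, **TINY)
        _, _, truth = simulate_genome(cfg)
        truth.propensity[:] = 0.0
        with pytest.raises(ValueError, match="propensity"):
            simulate_reads(cfg, truth)


class TestHaplotypes:
    def test_seed_determinism(self):
        cfg = SimulationConfig(seed=9)
        a = simulate_haplotypes(cfg)
        b = simulate_haplotypes(cfg)
        assert a[0] == b[0] and a[1] == b[1]

    def test_zero_divergence_low_fst(self):
        cfg = SimulationConfig(seed=10, divergence=0.0, individuals_per_population=50)
        seqs, pops, _ = simulate_haplotypes(cfg)
        ds = fst.collapse_haplotypes(seqs, pops)
        res = fst.pairwise_fst(ds)
        off = res.fst.to_numpy()[~np.eye(len(res.fst), dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_full_divergence_fixed_differences(self):
        cfg = SimulationConfig(seed=11, divergence=1.0, n_populations=2,
                               individuals_per_population=10)
        seqs, pops, _ = simulate_haplotypes(cfg)
        ds = fst.collapse_haplotypes(seqs, pops)
        assert fst.pairwise_fst(ds).fst.iloc[0, 1] == pytest.approx(1.0)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            simulate_haplotypes(SimulationConfig(seed=1, n_root_haplotypes=0))
        with pytest.raises(ValueError):
            simulate_haplotypes(SimulationConfig(seed=1, n_populations=1))


class TestExpression:
    def test_noiseless_coupling_perfect_correlation(self):
        cfg = SimulationConfig(
            seed=12,
            expression_coupling=(("AKT1", "1CpG", 3.0, 0.0),),
            reference_ct_noise_sd=0.0,
            well_noise_sd=0.0,
        )
        tables = simulate_expression(cfg)
        samples = tables["breed_of"]["sample"].tolist()
        expr = expression.relative_expression(tables["ct"], calibrator=samples[:3])
        out = expression.methylation_expression_correlation(
            tables["methylation"], expr, [("AKT1", "1CpG", "AKT1")]
        )
        # expression is an exponential transform of methylation, so even the
        # noiseless limit is not exactly linear; r approaches +1
        assert out["r"].iloc[0] > 0.99
        assert out["p_value"].iloc[0] < 1e-6

    def test_zero_slope_mostly_null(self):
        sig = 0
        for seed in range(100):
            cfg = SimulationConfig(seed=seed,
                                   expression_coupling=(("AKT1", "1CpG", 0.0, 0.17),))
            tables = simulate_expression(cfg)
            samples = tables["breed_of"]["sample"].tolist()
            expr = expression.relative_expression(tables["ct"], calibrator=samples[:3])
            out = expression.methylation_expression_correlation(
                tables["methylation"], expr, [("AKT1", "1CpG", "AKT1")]
            )
            sig += out["p_value"].iloc[0] < 0.05
        assert sig <= 10

    def test_zero_reference_noise_identical_reference_cts(self):
        cfg = SimulationConfig(seed=13, reference_ct_noise_sd=0.0, well_noise_sd=0.0)
        ct = simulate_expression(cfg)["ct"]
        refs = ct[ct["role"] == "reference"]
        assert (refs.groupby("gene")["ct"].nunique() == 1).all()

    def test_phenotypes_positive_and_mbmi_consistent(self):
        tables = simulate_expression(SimulationConfig(seed=14))
        pheno = tables["phenotypes"]
        assert (pheno["weight"] > 0).all() and (pheno["length"] > 0).all()
        mb = pheno["weight"] / pheno["length"] ** 2
        assert (mb > 20).all()
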