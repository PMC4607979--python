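import numpy as np
import pandas as pd
import pytest
from scipy import stats

from medipscape import binning, dmr
from medipscape.annotation import GeneModel

from oracles import hypergeom_tail_naive, pearson_naive

BREEDS = {"a1": "A", "a2": "A", "b1": "B", "b2": "B",
          "c1": "C", "c2": "C", "d1": "D", "d2": "D"}


def _scores(rows, columns=tuple(BREEDS)):
    return pd.DataFrame(rows, columns=list(columns))


class TestPairwiseTests:
    def test_four_breeds_six_comparisons(self):
        rng = np.random.default_rng(0)
        res = dmr.pairwise_tests(_scores(rng.random((5, 8))), BREEDS)
        assert len(res.pairs) == 6
        assert res.p.shape == (5, 6)

    def test_identical_groups_null_result(self):
        res = dmr.pairwise_tests(_scores([[3.0] * 8]), BREEDS)
        assert (res.t.iloc[0] == 0).all()
        assert (res.p.iloc[0] == 1).all()
        assert (res.fold_change.iloc[0] == 1).all()

    def test_closed_form_pooled_t(self):
        # groups (10, 10+e) vs (20, 20+e): hand-computed pooled t
        e = 0.01
        rows = [[10.0, 10.0 + e, 20.0, 20.0 + e, 10.0, 10.0, 10.0, 10.0]]
        res = dmr.pairwise_tests(_scores(rows), BREEDS)
        label = "A_vs_B"
        diff = (10 + e / 2) - (20 + e / 2)
        sp2 = (e**2 / 2 + e**2 / 2) / 2
        expected_t = diff / np.sqrt(sp2 * (0.5 + 0.5))
        assert res.t[label].iloc[0] == pytest.approx(expected_t)
        assert res.p[label].iloc[0] == pytest.approx(
            2 * stats.t.sf(abs(expected_t), 2)
        )
        assert res.p[label].iloc[0] < 0.05
        assert res.fold_change[label].iloc[0] == pytest.approx(0.5, rel=1e-3)

    def test_pair_order_symmetry(self):
        rng = np.random.default_rng(1)
        scores = _scores(rng.random((20, 8)))
        res = dmr.pairwise_tests(scores, BREEDS)
        flipped = dmr.pairwise_tests(
            scores.rename(columns={"a1": "z1", "a2": "z2"}),
            {**{k: v for k, v in BREEDS.items() if v != "A"}, "z1": "Z", "z2": "Z"},
        )
        # A_vs_B becomes B_vs_Z: fold change reciprocal, t negated, p equal
        assert np.allclose(flipped.fold_change["B_vs_Z"], 1 / res.fold_change["A_vs_B"])
        assert np.allclose(flipped.t["B_vs_Z"], -res.t["A_vs_B"])
        assert np.allclose(flipped.p["B_vs_Z"], res.p["A_vs_B"])

    def test_single_sample_breed_rejected(self):
        with pytest.raises(ValueError, match="A"):
            dmr.pairwise_tests(_scores([[1.0, 2.0]], columns=("a1", "b1")),
                               {"a1": "A", "b1": "B"})


class TestCallDmrs:
    def _res(self, p_rows):
        pairs = [("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("B", "D"), ("C", "D")]
        cols = [dmr.PairwiseResults.pair_label(a, b) for a, b in pairs]
        p = pd.DataFrame(p_rows, columns=cols)
        ones = pd.DataFrame(1.0, index=p.index, columns=cols)
        means = pd.DataFrame(1.0, index=p.index, columns=list("ABCD"))
        return dmr.PairwiseResults(pairs, ones, p, ones.copy(), means)

    def test_no_significant_pair_no_dmr(self):
        out = dmr.call_dmrs(self._res([[0.2, 0.9, 0.06, 0.5, 1.0, 0.051]]))
        assert not out["is_dmr"].iloc[0]

    def test_single_significant_pair_is_dmr(self):
        out = dmr.call_dmrs(self._res([[0.01, 0.9, 0.9, 0.9, 0.9, 0.9]]))
        assert out["is_dmr"].iloc[0]
        assert out["n_sig_pairs"].iloc[0] == 1
        assert out["sig_A_vs_B"].iloc[0]


class TestFoldChangeFilter:
    def _full(self, fc_row, p=0.01):
        pairs = [("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("B", "D"), ("C", "D")]
        cols = [dmr.PairwiseResults.pair_label(a, b) for a, b in pairs]
        fc = pd.DataFrame([fc_row], columns=cols)
        pv = pd.DataFrame(p, index=fc.index, columns=cols)
        means = pd.DataFrame(1.0, index=fc.index, columns=list("ABCD"))
        res = dmr.PairwiseResults(pairs, pv.copy(), pv, fc, means)
        return dmr.call_dmrs(res), res

    def test_moderate_fold_changes_removed(self):
        dmrs, res = self._full([0.6, 1.8, 1.0, 1.2, 0.9, 1.5])
        assert dmr.fold_change_filter(dmrs, res).empty

    def test_strong_fold_change_kept(self):
        dmrs, res = self._full([2.5, 1.0, 1.0, 1.0, 1.0, 1.0])
        assert len(dmr.fold_change_filter(dmrs, res)) == 1

    def test_boundary_exactly_two_removed(self):
        dmrs, res = self._full([2.0, 1.0, 1.0, 1.0, 0.5, 1.0])
        assert dmr.fold_change_filter(dmrs, res).empty


class TestBreedSpecific:
    def test_elevated_breed_detected(self):
        rng = np.random.default_rng(2)
        base = rng.normal(10, 0.3, (1, 8))
        base[0, :2] *= 4  # breed A elevated in both replicates
        res = dmr.pairwise_tests(_scores(base), BREEDS)
        assert dmr.breed_specific_dmrs(res).iloc[0] == "A"

    def test_jointly_elevated_breeds_specific_to_neither(self):
        rng = np.random.default_rng(3)
        base = rng.normal(10, 0.1, (1, 8))
        base[0, :4] *= 4  # breeds A and B both elevated
        res = dmr.pairwise_tests(_scores(base), BREEDS)
        assert pd.isna(dmr.breed_specific_dmrs(res).iloc[0])

    def test_null_bin_not_specific(self):
        res = dmr.pairwise_tests(_scores([[5.0] * 8]), BREEDS)
        assert pd.isna(dmr.breed_specific_dmrs(res).iloc[0])


class TestGeneMapping:
    def test_intergenic_dmr_no_genes(self):
        bins = binning.make_bins({"c": 60_000}, 300).iloc[:1]
        gene = GeneModel("g", "c", 30_000, 35_000, "+", ((30_000, 35_000),))
        assert dmr.map_dmrs_to_genes(bins, [gene]).iloc[0] == ()

    def test_bin_spanning_two_genes_lists_both(self):
        bins = pd.DataFrame([{"chrom": "c", "start": 9_900, "end": 10_200}])
        g1 = GeneModel("g1", "c", 5_000, 10_000, "+", ((5_000, 10_000),))
        g2 = GeneModel("g2", "c", 10_100, 15_000, "+", ((10_100, 15_000),))
        assert set(dmr.map_dmrs_to_genes(bins, [g1, g2]).iloc[0]) == {"g1", "g2"}

    def test_promoter_overlap_counts(self):
        bins = pd.DataFrame([{"chrom": "c", "start": 8_100, "end": 8_400}])
        gene = GeneModel("g", "c", 10_000, 15_000, "+", ((10_000, 15_000),))
        assert dmr.map_dmrs_to_genes(bins, [gene]).iloc[0] == ("g",)

    def test_matches_brute_force_intersection(self):
        rng = np.random.default_rng(4)
        genes = []
        for i in range(15):
            s = int(rng.integers(3_000, 90_000))
            genes.append(GeneModel(f"g{i}", "c", s, s + 4_000, "+", ((s, s + 4_000),)))
        bins = binning.make_bins({"c": 100_000}, 300).sample(60, random_state=1)
        got = dmr.map_dmrs_to_genes(bins, genes)
        for bin_id, row in bins.iterrows():
            # + strand: extent [start-2200, max(end, start+500))
            expected = {
                g.gene_id for g in genes
                if row["start"] < max(g.end, g.start + 500) and row["end"] > g.start - 2200
            }
            assert set(got.loc[bin_id]) == expected


class TestGeneSetEnrichment:
    def test_dmg_equals_background_p_one(self):
        bg = [f"g{i}" for i in range(20)]
        out = dmr.gene_set_enrichment(bg, bg, {"s": bg[:5]})
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_point_mass_matches_exact_enumeration(self):
        bg = [f"g{i}" for i in range(30)]
        fg = bg[:5]
        out = dmr.gene_set_enrichment(fg, bg, {"s": fg})
        assert out["p_value"].iloc[0] == pytest.approx(
            hypergeom_tail_naive(5, 30, 5, 5), abs=1e-12
        )

    def test_matches_naive_tail_on_random_sets(self):
        rng = np.random.default_rng(5)
        bg = [f"g{i}" for i in range(50)]
        fg = list(rng.choice(bg, 15, replace=False))
        sets = {f"s{j}": list(rng.choice(bg, int(rng.integers(3, 20)), replace=False))
                for j in range(8)}
        out = dmr.gene_set_enrichment(fg, bg, sets).set_index("set")
        for name, members in sets.items():
            K = len(set(members))
            k = len(set(members) & set(fg))
            assert out.loc[name, "p_value"] == pytest.approx(
                hypergeom_tail_naive(k, 50, K, 15), abs=1e-10
            )

    def test_benjamini_hochberg_arithmetic(self):
        bg = [f"g{i}" for i in range(10)]
        out = dmr.gene_set_enrichment(bg[:3], bg, {"a": bg, "b": bg, "c": bg, "d": bg})
        df = pd.DataFrame({"p_value": [0.01, 0.02, 0.03, 0.04]})
        from statsmodels.stats.multitest import multipletests
        adj = multipletests(df["p_value"], method="fdr_bh")[1]
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_foreground_outside_background_rejected(self):
        with pytest.raises(ValueError, match="zzz"):
            dmr.gene_set_enrichment(["zzz"], ["g1"], {"s": ["g1"]})


class TestClustering:
    def test_duplicated_unit_merges_at_height_zero(self):
        rng = np.random.default_rng(6)
        col = rng.random(50)
        scores = pd.DataFrame({"u1": col, "u2": col.copy(), "u3": rng.random(50),
                               "u4": rng.random(50)})
        Z, _ = dmr.cluster_breeds(scores)
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_distances_match_naive_pearson(self):
        rng = np.random.default_rng(7)
        scores = pd.DataFrame(rng.random((50, 3)), columns=["x", "y", "z"])
        Z, _ = dmr.cluster_breeds(scores)
        d_xy = 1 - pearson_naive(scores["x"], scores["y"])
        d_xz = 1 - pearson_naive(scores["x"], scores["z"])
        d_yz = 1 - pearson_naive(scores["y"], scores["z"])
        assert Z[0, 2] == pytest.approx(min(d_xy, d_xz, d_yz), abs=1e-10)

    def test_ultrametric_heights_nondecreasing(self, default_run):
        run = default_run
        breed_scores, _ = binning.replicate_qc_and_average(
            run["scores"], run["config"].breed_of
        )
        Z, newick = dmr.cluster_breeds(breed_scores)
        heights = Z[:, 2]
        assert (np.diff(heights) >= -1e-12).all()
        assert newick.endswith(";")

    def test_too_few_units_rejected(self):
        with pytest.raises(ValueError):
            dmr.cluster_breeds(pd.DataFrame({"u": [1.0, 2.0]}))
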