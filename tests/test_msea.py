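"""Marker-set enrichment: statistic, permutation null, FDR, merging."""

from itertools import combinations

import numpy as np
import pytest

import marknet as mk
from marknet.msea import MseaConfig, _module_marker_idx


class TestBuildIndex:
    def test_many_to_many_propagation(self):
        assoc = mk.MarkerAssociation.from_records(["rs1"], [3.0])
        mapping = mk.MarkerGeneMap.from_pairs([("rs1", "g1"), ("rs1", "g2")])
        idx = mk.build_index(assoc, mapping)
        assert set(idx.genes) == {"g1", "g2"}
        assert idx.n_markers == 1
        assert idx.has_shared_markers

    def test_unscored_mapped_gene_absent(self):
        assoc = mk.MarkerAssociation.from_records(["rs1"], [3.0])
        mapping = mk.MarkerGeneMap.from_pairs([("rs1", "g1"), ("rs9", "g3")])
        idx = mk.build_index(assoc, mapping)
        assert "g3" not in set(idx.genes)

    def test_zero_overlap_errors(self):
        assoc = mk.MarkerAssociation.from_records(["rs1"], [3.0])
        mapping = mk.MarkerGeneMap.from_pairs([("rs9", "g1")])
        with pytest.raises(ValueError, match="overlap"):
            mk.build_index(assoc, mapping)


class TestQuantileCutoffs:
    @pytest.mark.parametrize("level, cutoff, count", [(0.5, 6.0, 5), (0.9, 10.0, 1)])
    def test_hand_enumerated_ladder(self, ladder_index, level, cutoff, count):
        c, m = mk.quantile_cutoffs(ladder_index, [level])
        assert c[0] == cutoff and m[0] == count

    def test_monotone_in_level(self, ladder_index):
        c, _ = mk.quantile_cutoffs(ladder_index, [0.2, 0.5, 0.75, 0.9, 0.95])
        assert np.all(np.diff(c) >= 0)

    def test_constant_universe_errors(self):
        assoc = mk.MarkerAssociation.from_records(["a", "b"], [1.0, 1.0])
        mapping = mk.MarkerGeneMap.from_pairs([("a", "g1"), ("b", "g2")])
        idx = mk.build_index(assoc, mapping)
        with pytest.raises(ValueError, match="degenerate"):
            mk.quantile_cutoffs(idx, [0.5])


class TestEnrichmentStatistic:
    def test_hand_computed_value(self, ladder_index):
        c, m = mk.quantile_cutoffs(ladder_index, [0.5, 0.9])
        x = mk.enrichment_statistic(["g09", "g10"], ladder_index, c, m, kappa=1.0)
        # (2-1)/sqrt(2) + (1-0.2)/sqrt(1.2)
        assert x == pytest.approx(1.437404, abs=1e-6)

    def test_universe_module_is_zero(self, ladder_index):
        c, m = mk.quantile_cutoffs(
            ladder_index, mk.MseaConfig().quantile_levels
        )
        x = mk.enrichment_statistic(list(ladder_index.genes), ladder_index, c, m)
        assert x == pytest.approx(0.0, abs=1e-12)

    def test_shared_marker_counted_once(self):
        assoc = mk.MarkerAssociation.from_records(
            ["rs1", "rs2", "rs3", "rs4"], [4.0, 3.0, 2.0, 1.0]
        )
        mapping = mk.MarkerGeneMap.from_pairs(
            [("rs1", "ga"), ("rs1", "gb"), ("rs2", "gc"), ("rs3", "gd"),
             ("rs4", "ge")]
        )
        idx = mk.build_index(assoc, mapping)
        # module {ga, gb} holds the single unique marker rs1
        assert len(_module_marker_idx(["ga", "gb"], idx)) == 1


class TestPermutationNull:
    def _four_gene_index(self):
        assoc = mk.MarkerAssociation.from_records(
            [f"rs{i}" for i in range(1, 5)], [1.0, 2.0, 3.0, 4.0]
        )
        mapping = mk.MarkerGeneMap.from_pairs(
            [(f"rs{i}", f"g{i}") for i in range(1, 5)]
        )
        return mk.build_index(assoc, mapping)

    def test_gene_null_confined_to_enumerated_support(self):
        idx = self._four_gene_index()
        config = MseaConfig(n_permutations=500, quantile_levels=(0.5,))
        c, m = mk.quantile_cutoffs(idx, config.quantile_levels)
        support = {
            round(mk.enrichment_statistic(list(pair), idx, c, m), 9)
            for pair in combinations(idx.genes, 2)
        }
        assert len(support) <= 6
        null = mk.permutation_null(2, idx, config, np.random.default_rng(0))
        assert {round(v, 9) for v in null} <= support

    def test_marker_null_mean_near_zero(self):
        # under exchangeable values E[O_q] = m*M_q/N exactly, so E[X] = 0
        spec = mk.FixtureSpec(n_markers=500, n_genes=50, seed=5)
        assoc, mapping = mk.gen_null_study(spec)
        idx = mk.build_index(assoc, mapping)
        config = MseaConfig(permutation_type="marker", n_permutations=4000)
        null = mk.permutation_null(40, idx, config, np.random.default_rng(1))
        assert abs(null.mean()) < 4 * null.std(ddof=1) / np.sqrt(len(null))

    def test_seed_reproducibility(self):
        idx = self._four_gene_index()
        config = MseaConfig(n_permutations=200, quantile_levels=(0.5,))
        a = mk.permutation_null(2, idx, config, np.random.default_rng(7))
        b = mk.permutation_null(2, idx, config, np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_module_as_large_as_gene_pool_errors(self):
        idx = self._four_gene_index()
        config = MseaConfig(n_permutations=200)
        with pytest.raises(ValueError, match="below"):
            mk.permutation_null(4, idx, config, np.random.default_rng(0))


class TestPvalueFromNull:
    def test_observed_at_mean_gives_half(self):
        null = np.random.default_rng(0).normal(size=1000)
        gauss, _ = mk.pvalue_from_null(float(null.mean()), null)
        assert gauss == pytest.approx(0.5, abs=1e-12)

    def test_observed_at_95th_gaussian_point(self):
        null = np.random.default_rng(1).normal(size=5000)
        obs = null.mean() + 1.6449 * null.std(ddof=1)
        gauss, _ = mk.pvalue_from_null(float(obs), null)
        assert gauss == pytest.approx(0.05, abs=1e-4)

    def test_observed_below_all_gives_empirical_one(self):
        null = np.random.default_rng(2).normal(size=500)
        _, emp = mk.pvalue_from_null(float(null.min() - 1), null)
        assert emp == 1.0

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            mk.pvalue_from_null(1.0, np.ones(200))


class TestBenjaminiHochberg:
    def test_hand_step_up(self):
        fdr = mk.benjamini_hochberg([0.01, 0.02, 0.04])
        assert np.allclose(fdr, [0.03, 0.03, 0.04])

    def test_single_p_unchanged(self):
        assert mk.benjamini_hochberg([0.2])[0] == pytest.approx(0.2)

    def test_all_ones_stay_one(self):
        assert np.all(mk.benjamini_hochberg([1.0, 1.0, 1.0]) == 1.0)


class TestRunMsea:
    def test_density_ratio_and_tops(self):
        spec = mk.FixtureSpec(
            n_markers=100, n_genes=20, n_modules=4, module_size=10, seed=6
        )
        assoc, mapping = mk.gen_null_study(spec)
        gs, _ = mk.gen_planted_module(spec, (assoc, mapping))
        res = mk.run_msea(
            assoc, mapping, gs, MseaConfig(n_permutations=300, min_genes=2),
            seed=0,
        )
        for r in res:
            assert r.density_ratio == pytest.approx(r.n_markers / 100)
            assert len(r.top_genes) <= 3 and len(r.top_markers) <= 3
            # top markers are this module's strongest, descending
            vals = [v for _, v in r.top_markers]
            assert vals == sorted(vals, reverse=True)

    def test_results_sorted_by_p(self):
        spec = mk.FixtureSpec(n_markers=200, n_genes=40, n_modules=10,
                              module_size=8, seed=7)
        assoc, mapping = mk.gen_null_study(spec)
        gs, _ = mk.gen_planted_module(spec, (assoc, mapping))
        res = mk.run_msea(assoc, mapping, gs,
                          MseaConfig(n_permutations=300, min_genes=2), seed=0)
        ps = [r.p_value for r in res]
        assert ps == sorted(ps)

    def test_seed_determinism(self):
        spec = mk.FixtureSpec(n_markers=200, n_genes=40, n_modules=5,
                              module_size=8, seed=8)
        assoc, mapping = mk.gen_null_study(spec)
        gs, _ = mk.gen_planted_module(spec, (assoc, mapping))
        cfg = MseaConfig(n_permutations=300, min_genes=2)
        r1 = mk.run_msea(assoc, mapping, gs, cfg, seed=42)
        r2 = mk.run_msea(assoc, mapping, gs, cfg, seed=42)
        assert [(a.module_id, a.p_value) for a in r1] == [
            (b.module_id, b.p_value) for b in r2
        ]

    def test_no_module_passes_size_filter_errors(self):
        spec = mk.FixtureSpec(n_markers=100, n_genes=20, n_modules=3,
                              module_size=5, seed=9)
        assoc, mapping = mk.gen_null_study(spec)
        gs, _ = mk.gen_planted_module(spec, (assoc, mapping))
        with pytest.raises(ValueError, match="size filter"):
            mk.run_msea(assoc, mapping, gs,
                        MseaConfig(min_genes=15, n_permutations=200), seed=0)

    def test_planted_module_ranks_first(self):
        spec = mk.FixtureSpec(n_markers=1000, n_genes=100, n_modules=20,
                              module_size=10, seed=10)
        study = mk.gen_null_study(spec)
        gs, truth = mk.gen_planted_module(spec, study)
        res = mk.run_msea(truth.assoc, study[1], gs,
                          MseaConfig(n_permutations=500, min_genes=2), seed=0)
        assert res[0].module_id == truth.module_id

    def test_effect_size_monotonicity_of_statistic(self):
        # larger planted shift never lowers the planted module's statistic
        medians = []
        for shift in (0.5, 1.5, 3.0):
            xs = []
            for rep in range(5):
                spec = mk.FixtureSpec(
                    n_markers=500, n_genes=50, n_modules=10, module_size=10,
                    signal_shift=shift, seed=100 + rep,
                )
                study = mk.gen_null_study(spec)
                gs, truth = mk.gen_planted_module(spec, study)
                idx = mk.build_index(truth.assoc, study[1])
                c, m = mk.quantile_cutoffs(idx, MseaConfig().quantile_levels)
                xs.append(
                    mk.enrichment_statistic(
                        sorted(gs[truth.module_id]), idx, c, m
                    )
                )
            medians.append(np.median(xs))
        assert medians == sorted(medians)


class TestMergeSupersets:
    def _results_for(self, modules, fdrs):
        return [
            mk.EnrichmentResult(
                module_id=m, statistic=1.0, p_value=0.01, empirical_p=0.01,
                fdr=f, n_genes=1, n_markers=1, density_ratio=0.1,
                top_genes=(), top_markers=(),
            )
            for m, f in zip(modules, fdrs)
        ]

    def test_identical_modules_merge(self):
        gs = mk.GeneSetCollection.from_dict({"A": {"g1", "g2"}, "B": {"g1", "g2"}})
        merged = mk.merge_supersets(
            self._results_for(["A", "B"], [0.01, 0.01]), gs
        )
        assert set(merged.sets) == {"A+B"}
        assert merged["A+B"] == frozenset({"g1", "g2"})

    def test_disjoint_modules_unchanged(self):
        gs = mk.GeneSetCollection.from_dict({"A": {"g1"}, "B": {"g2"}})
        merged = mk.merge_supersets(
            self._results_for(["A", "B"], [0.01, 0.01]), gs
        )
        assert set(merged.sets) == {"A", "B"}

    def test_overlap_coefficient_threshold(self):
        gs = mk.GeneSetCollection.from_dict(
            {"A": {f"g{i}" for i in range(1, 7)}, "B": {"g1", "g2", "g7", "g8"}}
        )
        # coefficient 2/4 = 0.5 >= 1/3 -> merged
        merged = mk.merge_supersets(
            self._results_for(["A", "B"], [0.01, 0.01]), gs, merge_overlap=1 / 3
        )
        assert set(merged.sets) == {"A+B"}
        # raising the threshold above 0.5 prevents the merge
        merged = mk.merge_supersets(
            self._results_for(["A", "B"], [0.01, 0.01]), gs, merge_overlap=0.6
        )
        assert set(merged.sets) == {"A", "B"}

    def test_only_significant_modules_considered(self):
        gs = mk.GeneSetCollection.from_dict({"A": {"g1"}, "B": {"g1"}})
        merged = mk.merge_supersets(
            self._results_for(["A", "B"], [0.01, 0.9]), gs, fdr_cutoff=0.25
        )
        assert set(merged.sets) == {"A"}

    def test_final_supersets_pairwise_below_threshold(self):
        gs = mk.GeneSetCollection.from_dict(
            {
                "A": {"g1", "g2", "g3"},
                "B": {"g2", "g3", "g4"},
                "C": {"g9", "g10"},
            }
        )
        merged = mk.merge_supersets(
            self._results_for(["A", "B", "C"], [0.01] * 3), gs,
            merge_overlap=0.5,
        )
        names = sorted(merged.sets)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                inter = len(merged[a] & merged[b])
                assert inter / min(len(merged[a]), len(merged[b])) < 0.5
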