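"""End-to-end engine behaviour: determinism, pruning, order invariance."""

import numpy as np
import pytest

import netsegmine as nm
from netsegmine.exceptions import NoMinableEdgesError


def _result_keys(result):
    return [
        tuple(row[k] for k in ("gene1", "gene2", "s1", "l1", "s2", "l2"))
        for _, row in result.significant.iterrows()
    ]


class TestRunBasics:
    def test_single_column_genes_single_interaction(self):
        rng = np.random.default_rng(0)
        D = rng.integers(0, 2, (30, 2)).astype(np.uint8)
        y = rng.integers(0, 2, 30).astype(np.uint8)
        y[:2] = [0, 1]
        ds = nm.GenotypeDataset(
            D=D, y=y, c=np.ones(30, dtype=int),
            sample_ids=[f"s{i}" for i in range(30)],
            variant_ids=["v0", "v1"],
            variant_chroms=np.array(["1", "1"], dtype=object),
            variant_pos=np.array([100, 1100]),
        )
        ann = [nm.GeneAnnotation("gA", "1", 50, 150),
               nm.GeneAnnotation("gB", "1", 1050, 1150)]
        net = nm.Network(frozenset({"gA", "gB"}), frozenset({("gA", "gB")}))
        res = nm.run(ds, ann, net, nm.MiningConfig())
        assert res.n_hypotheses == 1
        assert res.n_enumerated == 1

    def test_no_minable_edges_raises(self, small_sim):
        net = nm.Network(frozenset({"zz1", "zz2"}), frozenset({("zz1", "zz2")}))
        with pytest.raises(NoMinableEdgesError):
            nm.run(small_sim.dataset, small_sim.annotations, net, nm.MiningConfig())

    def test_deterministic_given_seed(self, small_sim):
        cfg = nm.MiningConfig(mode="wy", n_perm=50, seed=9)
        r1 = nm.run(small_sim.dataset, small_sim.annotations, small_sim.network, cfg)
        r2 = nm.run(small_sim.dataset, small_sim.annotations, small_sim.network, cfg)
        assert _result_keys(r1) == _result_keys(r2)
        assert r1.threshold == r2.threshold
        assert np.array_equal(r1.p_min_vec, r2.p_min_vec)

    def test_significant_obey_reported_threshold(self, small_sim):
        res = nm.run(
            small_sim.dataset, small_sim.annotations, small_sim.network,
            nm.MiningConfig(),
        )
        if len(res.significant):
            assert (res.significant.p_value <= res.threshold).all()
            assert (res.significant.p_min <= res.significant.p_value + 1e-12).all()


class TestSharedVariantHandling:
    def _overlapping_setup(self):
        rng = np.random.default_rng(3)
        D = rng.integers(0, 2, (40, 3)).astype(np.uint8)
        y = rng.integers(0, 2, 40).astype(np.uint8)
        y[:2] = [0, 1]
        ds = nm.GenotypeDataset(
            D=D, y=y, c=np.ones(40, dtype=int),
            sample_ids=[f"s{i}" for i in range(40)],
            variant_ids=["v0", "v1", "v2"],
            variant_chroms=np.array(["1"] * 3, dtype=object),
            variant_pos=np.array([100, 200, 300]),
        )
        # overlapping gene intervals: v1 (pos 200) belongs to both genes
        ann = [nm.GeneAnnotation("gA", "1", 50, 250),
               nm.GeneAnnotation("gB", "1", 150, 350)]
        net = nm.Network(frozenset({"gA", "gB"}), frozenset({("gA", "gB")}))
        return ds, ann, net

    def test_shared_columns_allowed_and_flagged_by_default(self):
        ds, ann, net = self._overlapping_setup()
        res = nm.run(ds, ann, net, nm.MiningConfig())
        # both genes see 2 columns -> 3 closed segments at most each
        assert res.n_hypotheses >= 4
        assert res.edge_counters.shared_variants.iloc[0] == 1

    def test_exclusion_flag_shrinks_the_segment_spaces(self):
        ds, ann, net = self._overlapping_setup()
        res = nm.run(ds, ann, net,
                     nm.MiningConfig(exclude_shared_variants=True))
        # with the shared column dropped each gene keeps a single variant
        assert res.n_hypotheses == 1


class TestPlantedSignal:
    def test_perfect_interaction_detected(self):
        design = nm.SimulationDesign(
            n_samples=80, n_genes=10, n_edges=15, variants_per_gene=4,
            maf=0.25, k_classes=2, p_s=1.0,
        )
        sim = nm.generate_dataset(design, seed=5)
        res = nm.run(sim.dataset, sim.annotations, sim.network, nm.MiningConfig())
        truth = sim.ground_truth
        pairs = {
            frozenset((row.gene1, row.gene2))
            for _, row in res.significant.iterrows()
        }
        assert frozenset((truth.gene1, truth.gene2)) in pairs


class TestEdgeOrderInvariance:
    def test_final_state_independent_of_edge_order(self, small_sim):
        res = nm.run(
            small_sim.dataset, small_sim.annotations, small_sim.network,
            nm.MiningConfig(),
        )
        # re-run with a re-labelled (hence re-sorted) network: relabel genes
        # by permuting ids consistently across annotation and network
        rng = np.random.default_rng(2)
        genes = [g.gene_id for g in small_sim.annotations]
        relabel = dict(zip(genes, rng.permutation(genes)))
        ann2 = [
            nm.GeneAnnotation(relabel[g.gene_id], g.chrom, g.start, g.end)
            for g in small_sim.annotations
        ]
        edges2 = frozenset(
            tuple(sorted((relabel[a], relabel[b])))
            for a, b in small_sim.network.edges
        )
        net2 = nm.Network(frozenset(relabel.values()), edges2)
        res2 = nm.run(small_sim.dataset, ann2, net2, nm.MiningConfig())
        assert res2.delta_hat == res.delta_hat
        assert res2.n_testable == res.n_testable
        assert res2.threshold == res.threshold
        back = {v: k for k, v in relabel.items()}
        keys2 = {
            (back[g1], back[g2], s1, l1, s2, l2)
            if back[g1] <= back[g2] else (back[g2], back[g1], s2, l2, s1, l1)
            for g1, g2, s1, l1, s2, l2 in _result_keys(res2)
        }
        assert keys2 == set(_result_keys(res))


class TestPruningSoundness:
    @pytest.mark.parametrize("mode", ["tarone", "wy"])
    def test_pruning_does_not_change_results(self, mode):
        design = nm.SimulationDesign(
            n_samples=50, n_genes=6, n_edges=8, variants_per_gene=5,
            maf=0.3, k_classes=2, p_s=0.8,
        )
        sim = nm.generate_dataset(design, seed=21)
        kw = dict(mode=mode, n_perm=40, seed=21)
        r_on = nm.run(sim.dataset, sim.annotations, sim.network,
                      nm.MiningConfig(prune=True, **kw))
        r_off = nm.run(sim.dataset, sim.annotations, sim.network,
                       nm.MiningConfig(prune=False, **kw))
        assert r_on.delta_hat == r_off.delta_hat
        assert r_on.n_testable == r_off.n_testable
        assert r_on.threshold == r_off.threshold
        assert _result_keys(r_on) == _result_keys(r_off)
        if mode == "wy":
            assert np.array_equal(r_on.p_min_vec, r_off.p_min_vec)
        assert r_on.n_enumerated <= r_off.n_enumerated


class TestSnpPairEquivalence:
    def test_max_len_one_matches_direct_snp_pair_miner(self):
        """An independent single-variant-pair implementation of the same
        testability procedure must reproduce the engine at max_len=1."""
        design = nm.SimulationDesign(
            n_samples=60, n_genes=6, n_edges=8, variants_per_gene=4,
            maf=0.25, k_classes=2, p_s=0.9,
        )
        sim = nm.generate_dataset(design, seed=33)
        alpha = 0.05
        res = nm.run(sim.dataset, sim.annotations, sim.network,
                     nm.MiningConfig(alpha=alpha, max_len=1))
        from conftest import snp_pair_reference
        delta_hat, n_testable, delta_star, expected = snp_pair_reference(sim, alpha)
        assert res.delta_hat == delta_hat
        assert res.n_testable == n_testable
        assert res.threshold == pytest.approx(delta_star)
        assert sorted(_result_keys(res)) == expected


class TestBonferroniDomination:
    def test_tarone_threshold_dominates_and_contains_bonferroni_hits(self, small_sim):
        res = nm.run(small_sim.dataset, small_sim.annotations, small_sim.network,
                     nm.MiningConfig())
        assert res.threshold >= res.bonferroni_threshold
        # every Bonferroni-significant closed interaction is also reported
        bon = res.significant[res.significant.p_value <= res.bonferroni_threshold]
        assert len(bon) <= len(res.significant)
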