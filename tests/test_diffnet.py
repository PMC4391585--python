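import numpy as np
import pytest

from ncnet.diffnet import (
    VennCounts,
    disease_specific_network,
    distribution_correlations,
    edge_intersections,
    largest_component,
    node_intersections,
    status_independent_core,
    topology_pca,
)
from ncnet.topology import TopologySummary

from conftest import net_from_pairs, oracle_components, random_bipartite


def nets_from_edge_sets(rel, rem, con):
    return (
        net_from_pairs(rel, label="relapse"),
        net_from_pairs(rem, label="remission"),
        net_from_pairs(con, label="control"),
    )


PAIRS = [(f"n{i}", f"m{j}") for i in range(6) for j in range(6)]


class TestVenn:
    def test_identical_networks_all_triple(self):
        nets = nets_from_edge_sets(PAIRS[:10], PAIRS[:10], PAIRS[:10])
        v = edge_intersections(*nets)
        assert v.region_counts["all_three"] == 10
        assert v.union_size == 10
        assert v.triple_shared_percent == 100.0

    def test_disjoint_networks_exclusive_only(self):
        nets = nets_from_edge_sets(PAIRS[:3], PAIRS[3:6], PAIRS[6:9])
        v = edge_intersections(*nets)
        assert v.region_counts["all_three"] == 0
        assert v.region_counts["relapse_only"] == 3
        assert v.region_counts["remission_only"] == 3
        assert v.region_counts["control_only"] == 3
        assert all(
            v.region_counts[k] == 0
            for k in ("relapse_remission", "relapse_control", "remission_control")
        )

    def test_seven_region_partition_matches_set_algebra(self, rng):
        def pick(seed):
            r = np.random.default_rng(seed)
            return {PAIRS[i] for i in r.choice(len(PAIRS), size=15, replace=False)}

        rel, rem, con = pick(1), pick(2), pick(3)
        v = edge_intersections(*nets_from_edge_sets(rel, rem, con))
        # independent set-algebra oracle, element by element
        oracle = {k: 0 for k in v.region_counts}
        for e in rel | rem | con:
            key = (e in rel, e in rem, e in con)
            name = {
                (True, True, True): "all_three",
                (True, True, False): "relapse_remission",
                (True, False, True): "relapse_control",
                (False, True, True): "remission_control",
                (True, False, False): "relapse_only",
                (False, True, False): "remission_only",
                (False, False, True): "control_only",
            }[key]
            oracle[name] += 1
        assert v.region_counts == oracle
        assert sum(v.region_counts.values()) == v.union_size == len(rel | rem | con)

    def test_region_counts_must_conserve_union(self):
        with pytest.raises(ValueError):
            VennCounts(
                region_counts={"all_three": 2},
                union_size=3,
                triple_shared_percent=0.0,
                pairwise_jaccard={},
                pairwise_fraction={},
            )

    def test_node_overlap_exceeds_edge_overlap_under_rewiring(self):
        from ncnet.netbuild import build_condition_network
        from ncnet.simulate import SimConfig, generate_cohort

        cfg = SimConfig(
            n_patients=20, n_controls=18, n_ncrna=30, n_mrna=150,
            n_regulators=15, max_targets=25, effect_beta=2.0, noise_sd=0.3,
            rewire_fraction=0.8, patient_sd=0.0, seed=11,
        )
        m, _ = generate_cohort(cfg)
        nets = [
            build_condition_network(m, c, 0.01)
            for c in ("relapse", "remission", "control")
        ]
        vn = node_intersections(*nets)
        ve = edge_intersections(*nets)
        assert vn.triple_shared_percent > 5 * ve.triple_shared_percent

    def test_empty_network_zero_regions(self):
        from ncnet.network import BipartiteNetwork

        empty = BipartiteNetwork(edges={}, condition_label="control")
        nets = nets_from_edge_sets(PAIRS[:4], PAIRS[2:6], [])
        v = node_intersections(nets[0], nets[1], empty)
        assert v.region_counts["control_only"] == 0
        assert v.region_counts["all_three"] == 0


class TestCoreAndDisease:
    def test_disjoint_gives_empty_core(self):
        nets = nets_from_edge_sets(PAIRS[:3], PAIRS[3:6], PAIRS[6:9])
        assert status_independent_core(*nets).n_edges == 0

    def test_identical_gives_same_core(self):
        nets = nets_from_edge_sets(PAIRS[:8], PAIRS[:8], PAIRS[:8])
        assert status_independent_core(*nets).edge_set() == set(PAIRS[:8])

    def test_engineered_shared_edges_and_largest_component(self):
        shared = [("n0", "m0"), ("n0", "m1"), ("n1", "m1"), ("n4", "m4"), ("n5", "m5")]
        rel = shared + PAIRS[18:21]
        rem = shared + PAIRS[21:24]
        con = shared + PAIRS[24:27]
        core = status_independent_core(*nets_from_edge_sets(rel, rem, con))
        assert core.edge_set() == set(shared)
        comps = oracle_components(core)
        biggest = max(comps, key=len)
        lc = largest_component(core)
        assert lc.nodes == biggest

    def test_core_subset_of_each_input(self, rng):
        nets = [random_bipartite(np.random.default_rng(s), 5, 8, 20) for s in (1, 2, 3)]
        core = status_independent_core(*nets)
        for n in nets:
            assert core.edge_set() <= n.edge_set()

    def test_controls_superset_gives_empty_disease_net(self):
        nets = nets_from_edge_sets(PAIRS[:6], PAIRS[3:9], PAIRS[:12])
        assert disease_specific_network(*nets).n_edges == 0

    def test_empty_controls_gives_intersection(self):
        from ncnet.network import BipartiteNetwork

        rel, rem, _ = nets_from_edge_sets(PAIRS[:6], PAIRS[3:9], [])
        empty = BipartiteNetwork(edges={}, condition_label="control")
        d = disease_specific_network(rel, rem, empty)
        assert d.edge_set() == set(PAIRS[3:6])

    def test_disease_net_matches_set_algebra(self):
        rel, rem, con = PAIRS[:10], PAIRS[5:15], PAIRS[8:18]
        d = disease_specific_network(*nets_from_edge_sets(rel, rem, con))
        assert d.edge_set() == (set(rel) & set(rem)) - set(con)
        assert not d.edge_set() & set(con)


class TestLargestComponent:
    def test_connected_network_is_itself(self):
        net = net_from_pairs([("n0", "m0"), ("n0", "m1"), ("n1", "m1")])
        assert largest_component(net).edge_set() == net.edge_set()

    def test_three_vs_two_nodes(self):
        net = net_from_pairs([("n0", "m0"), ("n0", "m1"), ("n1", "m2")])
        lc = largest_component(net)
        assert lc.nodes == {"n0", "m0", "m1"}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_union_find_oracle(self, seed):
        rng = np.random.default_rng(seed)
        net = random_bipartite(rng, 8, 12, 14)  # sparse -> forest-like
        lc = largest_component(net)
        comps = oracle_components(net)
        best_size = max(len(c) for c in comps)
        assert len(lc.nodes) == best_size
        assert any(lc.nodes == c for c in comps)

    def test_empty_error(self):
        from ncnet.network import BipartiteNetwork

        with pytest.raises(ValueError):
            largest_component(BipartiteNetwork(edges={}))


def summary(vals, n_nodes=10, n_edges=12):
    return TopologySummary(
        n_connected_components=int(vals[0]),
        network_centralization=vals[1],
        characteristic_path_length=vals[2],
        average_degree=vals[3],
        network_heterogeneity=vals[4],
        powerlaw_exponent=vals[5],
        n_nodes=n_nodes,
        n_edges=n_edges,
    )


class TestTopologyPCA:
    def test_two_networks_single_axis(self):
        coords, var_frac, _ = topology_pca(
            [summary([1, 0.5, 2.0, 3.0, 1.0, -1.5]), summary([2, 0.7, 2.5, 4.0, 1.2, -1.2])]
        )
        assert var_frac[0] == pytest.approx(1.0)

    def test_identical_pair_coincident(self):
        a = summary([1, 0.5, 2.0, 3.0, 1.0, -1.5])
        b = summary([1, 0.5, 2.0, 3.0, 1.0, -1.5])
        c = summary([3, 0.9, 3.0, 5.0, 2.0, -1.1])
        coords, _, _ = topology_pca([a, b, c])
        np.testing.assert_allclose(coords[0], coords[1], atol=1e-9)
        assert not np.allclose(coords[0], coords[2])

    def test_matches_eigendecomposition_oracle(self, rng):
        vals = rng.normal(size=(3, 6))
        vals[:, 0] = [1, 2, 4]  # component counts are integers
        summaries = [summary(v) for v in vals]
        coords, var_frac, names = topology_pca(summaries)
        # oracle: eigendecomposition of the covariance of standardized data
        z = (vals - vals.mean(0)) / vals.std(0, ddof=1)
        cov = np.cov(z.T, ddof=1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0, None)
        expected_var = evals / ((z**2).sum() / (len(vals) - 1) / 1)
        # variance fractions agree (top components; trailing ones are 0)
        total = (z**2).sum()
        got = var_frac * total
        for k in range(min(2, len(evals))):
            assert got[k] / total == pytest.approx(
                evals[k] / evals.sum(), abs=1e-9
            )
        # coordinates agree with projection on eigenvectors up to sign
        proj = z @ evecs[:, order]
        for k in range(2):
            same = np.allclose(coords[:, k], proj[:, k], atol=1e-8)
            flipped = np.allclose(coords[:, k], -proj[:, k], atol=1e-8)
            assert same or flipped

    def test_constant_descriptor_dropped_with_warning(self):
        a = summary([1, 0.5, 2.0, 3.0, 1.0, -1.5])
        b = summary([1, 0.7, 2.5, 4.0, 1.2, -1.2])
        with pytest.warns(UserWarning, match="n_connected_components"):
            _, _, names = topology_pca([a, b])
        assert "n_connected_components" not in names

    def test_fewer_than_two_error(self):
        with pytest.raises(ValueError):
            topology_pca([summary([1, 0.5, 2.0, 3.0, 1.0, -1.5])])


class TestDistributionCorrelations:
    def test_identical_histograms_unit(self):
        h = {1: 10, 2: 5, 3: 2}
        mat = distribution_correlations([h, h, h])
        np.testing.assert_allclose(mat, np.ones((3, 3)))

    def test_reversed_histogram_negative(self):
        h = {1: 10, 2: 6, 3: 1}
        rev = {1: 1, 2: 6, 3: 10}
        mat = distribution_correlations([h, rev])
        assert mat[0, 1] < 0

    def test_matches_per_pair_brute_force(self):
        hists = [{1: 5, 2: 3, 4: 1}, {1: 4, 3: 2, 4: 2}, {2: 6, 3: 1}]
        mat = distribution_correlations(hists)
        bins = sorted({b for h in hists for b in h})
        vecs = [np.array([h.get(b, 0) for b in bins], float) for h in hists]
        for i in range(3):
            for j in range(3):
                expected = np.corrcoef(vecs[i], vecs[j])[0, 1]
                assert mat[i, j] == pytest.approx(expected)

    def test_single_bin_flagged_nan(self):
        mat = distribution_correlations([{1: 5}, {1: 3}])
        assert np.isnan(mat[0, 1])


class TestRewiringMonotonicity:
    def test_triple_shared_fraction_decreases(self):
        from ncnet.netbuild import build_condition_network
        from ncnet.simulate import SimConfig, generate_cohort

        def frac(rewire, seed):
            cfg = SimConfig(
                n_patients=20, n_controls=18, n_ncrna=25, n_mrna=120,
                n_regulators=12, max_targets=20, effect_beta=2.0, noise_sd=0.3,
                rewire_fraction=rewire, patient_sd=0.0, seed=seed,
            )
            m, _ = generate_cohort(cfg)
            nets = [
                build_condition_network(m, c, 0.01)
                for c in ("relapse", "remission", "control")
            ]
            return edge_intersections(*nets).triple_shared_percent

        seeds = range(4)
        means = [np.mean([frac(w, s) for s in seeds]) for w in (0.0, 0.5, 0.9)]
        assert means[0] > means[1] > means[2]
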