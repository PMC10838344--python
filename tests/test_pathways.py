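import math
from itertools import combinations

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flipmoa import (
    build_network,
    cluster_pathways,
    enrich_pathways,
    hypergeom_tail,
)
from flipmoa.io import GeneSet, GeneSetCollection


def enum_tail(k, K, n, N):
    """Exact upper tail by integer combinatorics."""
    total = math.comb(N, n)
    acc = 0
    for j in range(k, min(K, n) + 1):
        acc += math.comb(K, j) * math.comb(N - K, n - j)
    return acc / total


class TestHypergeomTail:
    def test_zero_overlap_is_certain(self):
        assert hypergeom_tail(0, 5, 5, 20) == 1.0

    def test_forced_full_overlap_is_certain(self):
        assert hypergeom_tail(4, 4, 4, 4) == pytest.approx(1.0)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_tail(6, 5, 5, 20)
        with pytest.raises(ValueError):
            hypergeom_tail(1, 30, 5, 20)

    def test_monotone_nonincreasing_in_k(self):
        vals = [hypergeom_tail(k, 10, 12, 40) for k in range(11)]
        assert all(a >= b - 1e-15 for a, b in zip(vals, vals[1:]))

    @given(st.integers(1, 30))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_matches_enumeration(self, N):
        rng = np.random.default_rng(N)
        K = int(rng.integers(0, N + 1))
        n = int(rng.integers(0, N + 1))
        for k in range(max(0, K + n - N), min(K, n) + 1):
            assert hypergeom_tail(k, K, n, N) == pytest.approx(
                enum_tail(k, K, n, N), abs=1e-12
            )


class TestEnrichPathways:
    def test_enrichment_factor_arithmetic(self):
        universe = [f"g{i}" for i in range(100)]
        flip = universe[:10]
        sets = GeneSetCollection(
            {"P": GeneSet("", universe[5:15])}  # overlap with flip = 5, size 10
        )
        enr = enrich_pathways(flip, sets, universe)
        assert enr.at["P", "overlap"] == 5
        assert enr.at["P", "ef"] == pytest.approx(5.0)  # expected = 10*10/100 = 1

    def test_disjoint_pathway_scores_zero(self):
        universe = [f"g{i}" for i in range(50)]
        sets = GeneSetCollection({"P": GeneSet("", universe[20:30])})
        enr = enrich_pathways(universe[:5], sets, universe)
        assert enr.at["P", "ef"] == 0.0
        assert enr.at["P", "p"] == 1.0

    def test_flip_gene_outside_universe_rejected(self):
        sets = GeneSetCollection({"P": GeneSet("", ["g1"])})
        with pytest.raises(ValueError, match="absent from the universe"):
            enrich_pathways(["gX"], sets, ["g1", "g2"])

    def test_ef_above_one_iff_observed_exceeds_expected(self, bundle, flipset):
        uni = sorted(bundle["ground_truth"].gene_classes)
        enr = enrich_pathways(flipset.flip_genes, bundle["pathways"], uni)
        assert ((enr["ef"] > 1) == (enr["overlap"] > enr["expected"])).all()

    def test_planted_pathway_has_smallest_p(self, bundle, flipset):
        uni = sorted(bundle["ground_truth"].gene_classes)
        enr = enrich_pathways(flipset.flip_genes, bundle["pathways"], uni)
        assert enr.index[0] in bundle["ground_truth"].planted_pathways


class TestNetwork:
    def _collection(self, memberships):
        return GeneSetCollection(
            {sid: GeneSet("", sorted(m)) for sid, m in memberships.items()}
        )

    def test_full_overlap_gives_unit_jaccard_edge(self):
        flip = [f"f{i}" for i in range(10)]
        universe = flip + [f"g{i}" for i in range(90)]
        sets = self._collection({"A": flip[:6], "B": flip[:6] + ["g1"]})
        enr = enrich_pathways(flip, sets, universe)
        net = build_network(enr, sets, flip, alpha=0.5)
        assert net.graph.has_edge("A", "B")
        assert net.graph.edges["A", "B"]["jaccard"] == pytest.approx(1.0)

    def test_disjoint_flip_membership_gives_no_edge(self):
        flip = [f"f{i}" for i in range(10)]
        universe = flip + [f"g{i}" for i in range(90)]
        sets = self._collection({"A": flip[:5], "B": flip[5:]})
        enr = enrich_pathways(flip, sets, universe)
        net = build_network(enr, sets, flip, alpha=0.5)
        assert not net.graph.has_edge("A", "B")

    def test_edges_match_brute_force_rule(self):
        rng = np.random.default_rng(9)
        universe = [f"g{i}" for i in range(200)]
        flip = list(rng.choice(universe, 60, replace=False))
        sets = self._collection(
            {
                f"P{i:02d}": rng.choice(universe, rng.integers(8, 25), replace=False)
                for i in range(30)
            }
        )
        enr = enrich_pathways(flip, sets, universe)
        net = build_network(enr, sets, flip, alpha=0.9, min_jaccard=0.05)
        flipset_ = set(flip)
        expected_edges = set()
        nodes = set(net.graph.nodes)
        for a, b in combinations(sorted(nodes), 2):
            ma = set(sets.members(a)) & flipset_
            mb = set(sets.members(b)) & flipset_
            union = ma | mb
            if not union:
                continue
            jac = len(ma & mb) / len(union)
            p = hypergeom_tail(len(ma & mb), len(ma), len(mb), len(flipset_))
            if p < 0.05 and jac >= 0.05:
                expected_edges.add(frozenset((a, b)))
        assert set(map(frozenset, net.graph.edges)) == expected_edges

    def test_invariant_under_pathway_relabeling(self, bundle, flipset):
        uni = sorted(bundle["ground_truth"].gene_classes)
        sets = bundle["pathways"]
        enr = enrich_pathways(flipset.flip_genes, sets, uni)
        net1 = build_network(enr, sets, flipset.flip_genes)
        renamed = GeneSetCollection(
            {f"X_{sid}": GeneSet(gs.description, list(gs.members)) for sid, gs in sets.sets.items()}
        )
        enr2 = enr.copy()
        enr2.index = [f"X_{sid}" for sid in enr.index]
        net2 = build_network(enr2, renamed, flipset.flip_genes)
        mapping = {n: f"X_{n}" for n in net1.graph.nodes}
        assert nx.is_isomorphic(nx.relabel_nodes(net1.graph, mapping), net2.graph)


class TestClustering:
    def _net_from(self, sets, flip):
        g = nx.Graph()
        g.add_nodes_from(sets.sets)
        from flipmoa.pathways import PathwayNetwork

        return PathwayNetwork(g)

    def test_separable_blocks_split_exactly(self):
        flip = [f"f{i}" for i in range(20)]
        half1, half2 = flip[:10], flip[10:]
        sets = GeneSetCollection(
            {
                **{f"A{i}": GeneSet("", half1[i : i + 4]) for i in range(4)},
                **{f"B{i}": GeneSet("", half2[i : i + 4]) for i in range(4)},
            }
        )
        net = self._net_from(sets, flip)
        labels = cluster_pathways(net, sets, flip, k=2, seed=0)
        a_labels = {labels[s] for s in labels if s.startswith("A")}
        b_labels = {labels[s] for s in labels if s.startswith("B")}
        assert len(a_labels) == 1 and len(b_labels) == 1 and a_labels != b_labels

    def test_identical_rows_collapse_to_one_cluster(self):
        flip = [f"f{i}" for i in range(6)]
        sets = GeneSetCollection(
            {f"P{i}": GeneSet("", flip[:3]) for i in range(5)}
        )
        net = self._net_from(sets, flip)
        labels = cluster_pathways(net, sets, flip, k="auto", seed=0)
        assert set(labels.values()) == {0}

    def test_k_larger_than_nodes_rejected(self):
        flip = ["f1", "f2"]
        sets = GeneSetCollection({"P": GeneSet("", flip)})
        net = self._net_from(sets, flip)
        with pytest.raises(ValueError, match="exceeds node count"):
            cluster_pathways(net, sets, flip, k=5, seed=0)

    def test_same_seed_is_deterministic(self, bundle, flipset):
        uni = sorted(bundle["ground_truth"].gene_classes)
        sets = bundle["pathways"]
        enr = enrich_pathways(flipset.flip_genes, sets, uni)
        net = build_network(enr, sets, flipset.flip_genes, alpha=0.9)
        runs = [
            cluster_pathways(net, sets, flipset.flip_genes, k="auto", seed=7)
            for _ in range(10)
        ]
        assert all(r == runs[0] for r in runs)
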