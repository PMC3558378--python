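import networkx as nx
import pytest

from triphy.errors import InternalInconsistencyError, NotChordalError
from triphy.matrix_io import MISSING
from triphy.partition_graph import ColoredGraph, StateVertex, build_pig
from triphy.separators import crossing_relation, legal_minimal_separators
from triphy.triangulation import (
    IncompatibilityReport,
    ParallelFamily,
    PerfectPhylogeny,
    assemble_phylogeny,
    construct,
    greedy_parallel_family,
    mcs_clique_tree,
    saturate,
    verify_phylogeny,
)

from conftest import sv, vset


def prepared(M):
    D = legal_minimal_separators(M)
    crossing_relation(M, D)
    return D


class TestGreedyParallelFamily:
    def test_f1_takes_all_five(self, F1):
        D = prepared(F1)
        Q = greedy_parallel_family(D, F1.n)
        assert len(Q) == 5 == 2 * F1.n - 3

    def test_f2_takes_all_three(self, F2):
        Q = greedy_parallel_family(prepared(F2), F2.n)
        assert len(Q) == 3

    def test_empty_separator_family(self, F3):
        Q = greedy_parallel_family(prepared(F3), F3.n)
        assert len(Q) == 1
        assert Q.members[0].vertices == frozenset()

    def test_requires_crossing_relation(self, F1):
        D = legal_minimal_separators(F1)
        with pytest.raises(InternalInconsistencyError):
            greedy_parallel_family(D, F1.n)

    def test_bad_order_rejected(self, F1):
        D = prepared(F1)
        with pytest.raises(InternalInconsistencyError):
            greedy_parallel_family(D, F1.n, order=[0, 0, 1, 2, 3])

    def test_shuffled_orders_all_maximal(self, F1):
        D = prepared(F1)
        for seed in range(10):
            Q = greedy_parallel_family(D, F1.n, order=seed)
            chosen = set(Q.indices)
            for i in range(len(D)):
                if i not in chosen:
                    assert not all(D.parallel[i, j] for j in chosen)


class TestSaturate:
    def test_f1_single_fill_edge(self, F1):
        D = prepared(F1)
        Q = greedy_parallel_family(D, F1.n)
        H = saturate(build_pig(F1), Q)
        assert H.fill_edges == frozenset({vset((1, 0), (2, 0))})
        assert nx.is_chordal(H.graph.graph)

    def test_f2_no_fill(self, F2):
        Q = greedy_parallel_family(prepared(F2), F2.n)
        H = saturate(build_pig(F2), Q)
        assert H.fill_edges == frozenset()

    def test_f3_empty_family_no_fill(self, F3):
        Q = greedy_parallel_family(prepared(F3), F3.n)
        H = saturate(build_pig(F3), Q)
        assert H.fill_edges == frozenset()

    def test_fill_disjoint_from_base(self, F1):
        D = prepared(F1)
        Q = greedy_parallel_family(D, F1.n)
        H = saturate(build_pig(F1), Q)
        base_edges = {frozenset(e) for e in build_pig(F1).edges()}
        assert not (set(H.fill_edges) & base_edges)


class TestMcsCliqueTree:
    def mk(self, edges):
        G = ColoredGraph()
        for i, (u, v) in enumerate(edges):
            G.add_edge(u, v)
        return G

    def test_triangle(self):
        G = self.mk([(sv(0, 0), sv(1, 0)), (sv(1, 0), sv(2, 0)), (sv(2, 0), sv(0, 0))])
        ct = mcs_clique_tree(G)
        assert len(ct.cliques) == 1
        assert ct.edges == []

    def test_path(self):
        u, v, w = sv(0, 0), sv(1, 0), sv(2, 0)
        G = self.mk([(u, v), (v, w)])
        ct = mcs_clique_tree(G)
        assert sorted(map(sorted, ct.cliques)) == [[u, v], [v, w]]
        assert len(ct.edges) == 1
        assert ct.edges[0][2] == frozenset({v})

    def test_not_chordal_raises(self):
        a, b, c, d = sv(0, 0), sv(1, 0), sv(0, 1), sv(1, 1)
        G = self.mk([(a, b), (b, c), (c, d), (d, a)])
        with pytest.raises(NotChordalError):
            mcs_clique_tree(G)

    def test_f1_six_cliques_and_separators(self, F1):
        D = prepared(F1)
        Q = greedy_parallel_family(D, F1.n)
        H = saturate(build_pig(F1), Q)
        ct = mcs_clique_tree(H)
        assert len(ct.cliques) == 6
        # four taxon triangles plus the two Steiner cliques
        expect = {
            vset((0, 0), (1, 0), (2, 1)),
            vset((0, 1), (1, 0), (2, 2)),
            vset((0, 1), (1, 1), (2, 0)),
            vset((0, 0), (1, 2), (2, 0)),
            vset((0, 0), (1, 0), (2, 0)),
            vset((0, 1), (1, 0), (2, 0)),
        }
        assert set(ct.cliques) == expect
        assert {s for s in ct.separators()} == D.vertex_sets()

    def test_cliques_match_networkx(self, fx):
        for name in ("F1", "F2", "F3"):
            M = fx[name]
            D = prepared(M)
            Q = greedy_parallel_family(D, M.n)
            H = saturate(build_pig(M), Q)
            ct = mcs_clique_tree(H)
            assert {frozenset(K) for K in ct.cliques} == {
                frozenset(K) for K in nx.chordal_graph_cliques(H.graph.graph)
            }

    def test_vertex_subtree_connectivity(self, fx):
        for name in ("F1", "F2", "F3"):
            M = fx[name]
            Q = greedy_parallel_family(prepared(M), M.n)
            H = saturate(build_pig(M), Q)
            ct = mcs_clique_tree(H)
            tree = nx.Graph((a, b) for a, b, _, _ in ct.edges)
            tree.add_nodes_from(range(len(ct.cliques)))
            for v in H.graph.graph.nodes:
                holders = [i for i, K in enumerate(ct.cliques) if v in K]
                assert nx.is_connected(tree.subgraph(holders))

    def test_disconnected_forest_joined(self, F3):
        Q = greedy_parallel_family(prepared(F3), F3.n)
        H = saturate(build_pig(F3), Q)
        ct = mcs_clique_tree(H)
        assert len(ct.cliques) == 3
        artificial = [e for e in ct.edges if e[3]]
        assert len(artificial) == 2
        tree = nx.Graph((a, b) for a, b, _, _ in ct.edges)
        assert nx.is_tree(tree)


class TestAssembleAndVerify:
    def test_f1_tree_shape(self, F1):
        T = construct(F1)
        assert isinstance(T, PerfectPhylogeny)
        species = {tuple(sp) for sp in T.node_species}
        assert (0, 0, 0) in species and (1, 0, 0) in species  # Steiner species
        assert MISSING not in [s for sp in T.node_species for s in sp]
        # u=(0,0,0) adjacent to t1 and t4's nodes; v=(1,0,0) to t2, t3
        idx = {tuple(sp): i for i, sp in enumerate(T.node_species)}
        adj = {i: set() for i in range(T.n_nodes)}
        for a, b in T.edges:
            adj[a].add(b)
            adj[b].add(a)
        u, v = idx[(0, 0, 0)], idx[(1, 0, 0)]
        assert v in adj[u]
        assert T.taxon_to_node[0] in adj[u] and T.taxon_to_node[3] in adj[u]
        assert T.taxon_to_node[1] in adj[v] and T.taxon_to_node[2] in adj[v]

    def test_f2_path_all_taxa_labeled(self, F2):
        T = construct(F2)
        assert T.n_nodes == 4
        assert sorted(T.taxon_to_node.values()) == sorted(range(4))
        degrees = {i: 0 for i in range(4)}
        for a, b in T.edges:
            degrees[a] += 1
            degrees[b] += 1
        assert sorted(degrees.values()) == [1, 1, 2, 2]  # a path

    def test_f3_artificial_edges(self, F3):
        T = construct(F3)
        assert T.n_nodes == 3
        assert len(T.artificial_edges) == 2
        ok, violations = verify_phylogeny(F3, T)
        assert ok, violations

    def test_verify_rejects_star(self, F1):
        # star with center (0,0,0): state c0_s1 occupies two non-adjacent leaves
        nodes = [(0, 0, 0)] + [tuple(int(x) for x in F1.states[t]) for t in range(4)]
        T = PerfectPhylogeny(
            nodes,
            [(0, i) for i in range(1, 5)],
            {t: t + 1 for t in range(4)},
            F1.taxa_ids,
        )
        ok, violations = verify_phylogeny(F1, T)
        assert not ok
        assert any("not connected" in v for v in violations)

    def test_single_taxon(self):
        from conftest import matrix_from_columns

        M = matrix_from_columns([(0, 1)])  # 2 taxa is the smallest valid input
        T = construct(M)
        ok, violations = verify_phylogeny(M, T)
        assert ok, violations

    def test_verify_single_node_tree(self):
        from conftest import matrix_from_columns

        M = matrix_from_columns([(0, 0, 1)])
        T = construct(M)
        ok, _ = verify_phylogeny(M, T)
        assert ok

    def test_single_taxon_single_node(self):
        from triphy.matrix_io import CharacterMatrix
        import numpy as np

        M = CharacterMatrix(("t1",), ("c1",), np.array([[0]]))
        T = construct(M)
        assert T.n_nodes == 1
        ok, violations = verify_phylogeny(M, T)
        assert ok, violations


class TestConstruct:
    def test_f4_step1_report(self, F4):
        r = construct(F4)
        assert isinstance(r, IncompatibilityReport)
        assert r.step == 1 and tuple(r.witness) == (0, 1)
        assert r.to_json_dict() == {"compatible": False, "step": 1, "witness": [0, 1]}

    def test_f5_step3_report(self, F5):
        r = construct(F5)
        assert isinstance(r, IncompatibilityReport)
        assert r.step == 3
        u, v = r.witness
        assert u.char == v.char and u.state != v.state

    @pytest.mark.parametrize("name", ["F1", "F2", "F3"])
    def test_compatible_fixtures_verify(self, fx, name):
        M = fx[name]
        T = construct(M)
        ok, violations = verify_phylogeny(M, T)
        assert ok, violations

    def test_seed_changes_only_tree_not_verdict(self, F1):
        for seed in range(5):
            T = construct(F1, seed=seed)
            ok, violations = verify_phylogeny(F1, T)
            assert ok, violations


class TestNewick:
    def test_f1_newick_and_labels(self, F1):
        T = construct(F1)
        nwk = T.to_newick()
        assert nwk.endswith(";") and nwk.count("N") == T.n_nodes
        tsv = T.labels_tsv()
        lines = tsv.strip().splitlines()
        assert lines[0].startswith("node_id")
        assert len(lines) == 1 + T.n_nodes

    def test_newick_parseable_by_dendropy(self, F1):
        import dendropy

        T = construct(F1)
        tree = dendropy.Tree.get(data=T.to_newick(), schema="newick")
        assert len(tree.nodes()) == T.n_nodes
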