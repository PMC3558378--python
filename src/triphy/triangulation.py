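"""Greedy parallel families, saturation, clique trees and phylogeny assembly.

Steps 5-7 of the construction pipeline: choose a maximal pairwise parallel
subset of the legal minimal separators, saturate each chosen separator into
a clique, then read a clique tree off the (now chordal) graph by maximum
cardinality search.  Each maximal clique holds at most one state per
character and so spells a species; the taxon rows are themselves maximal
cliques, which places every taxon on the tree.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence, Union

import networkx as nx

from .errors import InternalInconsistencyError, NotChordalError
from .matrix_io import MISSING, CharacterMatrix, species_string
from .partition_graph import FILL_EDGE, ColoredGraph, StateVertex, build_pig
from .separators import (
    SeparatorSet,
    crossing_relation,
    legal_minimal_separators,
    unseparated_monochromatic_pairs,
)
from . import partition_graph


@dataclass
class ParallelFamily:
    """A maximal pairwise parallel subset of a separator set."""

    source: SeparatorSet
    indices: list[int]

    @property
    def members(self):
        return [self.source[i] for i in self.indices]

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class TriangulatedGraph:
    """A properly colored chordal supergraph of a base graph."""

    base: ColoredGraph
    graph: ColoredGraph
    fill_edges: frozenset[frozenset[StateVertex]]


@dataclass
class CliqueTree:
    """Maximal cliques of a chordal graph, joined into a tree whose edge
    intersections are minimal separators; disconnected inputs yield a
    forest joined by edges flagged artificial."""

    cliques: list[frozenset[StateVertex]]
    edges: list[tuple[int, int, frozenset[StateVertex], bool]]  # (i, j, separator, artificial)

    def separators(self) -> list[frozenset[StateVertex]]:
        return [sep for _, _, sep, art in self.edges if not art]


@dataclass
class PerfectPhylogeny:
    """A tree whose nodes carry species; taxa label nodes injectively."""

    node_species: list[tuple[int, ...]]  # MISSING allowed
    edges: list[tuple[int, int]]
    taxon_to_node: dict[int, int]
    taxa_ids: tuple[str, ...]
    artificial_edges: frozenset[tuple[int, int]] = field(default_factory=frozenset)

    @property
    def n_nodes(self) -> int:
        return len(self.node_species)

    def node_taxa(self, node: int) -> list[int]:
        return sorted(t for t, v in self.taxon_to_node.items() if v == node)

    def to_newick(self) -> str:
        """Plain Newick, nodes named N0..Nk, no branch lengths."""
        adj: dict[int, list[int]] = {i: [] for i in range(self.n_nodes)}
        for a, b in self.edges:
            adj[a].append(b)
            adj[b].append(a)
        if self.n_nodes == 1:
            return "N0;"
        root = 0

        def render(node: int, parent: Optional[int]) -> str:
            children = [c for c in adj[node] if c != parent]
            if not children:
                return f"N{node}"
            inner = ",".join(render(c, node) for c in children)
            return f"({inner})N{node}"

        return render(root, None) + ";"

    def labels_tsv(self) -> str:
        """Sidecar table: node id, species string, taxa, artificial flags."""
        art = {tuple(sorted(e)) for e in self.artificial_edges}
        lines = ["node_id\tspecies\ttaxa\tartificial_edges"]
        adj_art: dict[int, list[str]] = {i: [] for i in range(self.n_nodes)}
        for a, b in self.edges:
            if tuple(sorted((a, b))) in art:
                adj_art[a].append(f"N{b}")
                adj_art[b].append(f"N{a}")
        for i, sp in enumerate(self.node_species):
            taxa = ",".join(self.taxa_ids[t] for t in self.node_taxa(i))
            flags = ",".join(sorted(adj_art[i]))
            lines.append(f"N{i}\t{species_string(sp)}\t{taxa}\t{flags}")
        return "\n".join(lines) + "\n"


@dataclass
class IncompatibilityReport:
    """Certificate that no perfect phylogeny exists; ``step`` names the
    rejecting screen (1: cyclic character pair, 3: unseparated
    monochromatic pair)."""

    step: int
    witness: tuple

    compatible: bool = False

    def to_json_dict(self) -> dict:
        if self.step == 1:
            witness = [int(self.witness[0]), int(self.witness[1])]
        else:
            witness = [str(v) for v in self.witness]
        return {"compatible": False, "step": self.step, "witness": witness}


# ---------------------------------------------------------------------- #

def greedy_parallel_family(
    D: SeparatorSet,
    n_taxa: int,
    order: Union[None, int, Sequence[int]] = None,
) -> ParallelFamily:
    """Scan ``D``, keeping each separator parallel to everything kept.

    ``order`` is either a permutation of indices or a shuffle seed; the
    default is canonical order.  The family is maximal by construction; a
    family larger than ``2n - 3`` signals an implementation bug.
    """
    if D.parallel is None:
        raise InternalInconsistencyError("crossing relation not yet computed")
    k = len(D)
    if order is None:
        perm = list(range(k))
    elif isinstance(order, int):
        perm = list(range(k))
        random.Random(order).shuffle(perm)
    else:
        perm = list(order)
        if sorted(perm) != list(range(k)):
            raise InternalInconsistencyError("order must be a permutation of the separator indices")
    chosen: list[int] = []
    for i in perm:
        if all(D.parallel[i, j] for j in chosen):
            chosen.append(i)
    bound = max(2 * n_taxa - 3, 1)
    if len(chosen) > bound:
        raise InternalInconsistencyError(
            f"parallel family of size {len(chosen)} exceeds 2n-3 = {bound}"
        )
    return ParallelFamily(D, sorted(chosen))


def saturate(G: ColoredGraph, Q: ParallelFamily) -> TriangulatedGraph:
    """Complete every separator of ``Q`` into a clique.

    The result is verified chordal and properly colored; legality of the
    separators means no same-color fill edge can arise.
    """
    H = G.copy()
    fills = set()
    for sep in Q.members:
        for u, v in combinations(sorted(sep.vertices), 2):
            if not H.has_edge(u, v):
                H.add_edge(u, v, FILL_EDGE)
                fills.add(frozenset((u, v)))
    if not H.is_properly_colored():
        raise InternalInconsistencyError("saturation produced a same-color edge")
    if not nx.is_chordal(H.graph):
        raise InternalInconsistencyError("saturated graph is not chordal")
    return TriangulatedGraph(G, H, frozenset(fills))


def mcs_clique_tree(H: Union[TriangulatedGraph, ColoredGraph, nx.Graph]) -> CliqueTree:
    """Clique tree by maximum cardinality search (Blair-Peyton style).

    Ties break on lowest vertex (canonical sort order), so output is
    deterministic.  The fill-in-free test re-verifies chordality; a missing
    chord raises :class:`NotChordalError`.  Disconnected graphs give a
    forest whose components are then joined by artificial edges between
    the lexicographically smallest cliques.
    """
    if isinstance(H, TriangulatedGraph):
        g = H.graph.graph
    elif isinstance(H, ColoredGraph):
        g = H.graph
    else:
        g = H
    nodes = sorted(g.nodes)
    if not nodes:
        raise InternalInconsistencyError("empty graph has no clique tree")
    index = {v: i for i, v in enumerate(nodes)}
    N = len(nodes)
    weight = [0] * N
    numbered: list = []  # MCS order
    number_of: dict = {}
    unnumbered = set(range(N))

    cliques: list[set] = []
    clique_of: dict = {}
    tree_edges: list[tuple[int, int, frozenset, bool]] = []
    current: set = set()
    prev_card = 0

    for step in range(N):
        i = min(unnumbered, key=lambda j: (-weight[j], j))
        v = nodes[i]
        unnumbered.discard(i)
        S = {u for u in g[v] if u in number_of}
        card = len(S)
        if S:
            # chordality (fill-in-free) test: earlier neighbors of v minus
            # its latest-numbered one must already be neighbors of that one
            u = max(S, key=lambda w: number_of[w])
            if not (S - {u}) <= (set(g[u]) | {u}):
                raise NotChordalError(f"missing chord at vertex {v}")
        if step == 0:
            current = {v}
        elif card <= prev_card:
            cliques.append(current)
            current = S | {v}
            if S:
                u = max(S, key=lambda w: number_of[w])
                parent = clique_of[u]
                tree_edges.append((parent, len(cliques), frozenset(S), False))
        else:
            current.add(v)
        clique_of[v] = len(cliques)
        number_of[v] = step
        numbered.append(v)
        for u in g[v]:
            if index[u] in unnumbered:
                weight[index[u]] += 1
        prev_card = card
    cliques.append(current)

    frozen = [frozenset(c) for c in cliques]
    # join forest components
    comp_graph = nx.Graph()
    comp_graph.add_nodes_from(range(len(frozen)))
    comp_graph.add_edges_from((a, b) for a, b, _, _ in tree_edges)
    comps = sorted(nx.connected_components(comp_graph), key=lambda cc: min(cc))
    if len(comps) > 1:
        reps = [
            min(cc, key=lambda i: tuple(sorted(frozen[i])))
            for cc in comps
        ]
        for a, b in zip(reps, reps[1:]):
            tree_edges.append((a, b, frozen[a] & frozen[b], True))
    return CliqueTree(frozen, tree_edges)


def assemble_phylogeny(M: CharacterMatrix, ct: CliqueTree) -> PerfectPhylogeny:
    """Label each clique-tree node with the species its clique spells and
    place every taxon on the node containing its row clique."""
    species = []
    for K in ct.cliques:
        sp = [MISSING] * M.m
        for v in K:
            sp[v.char] = v.state
        species.append(tuple(sp))
    taxon_to_node: dict[int, int] = {}
    for t in range(M.n):
        K_t = {StateVertex(c, int(M.states[t, c])) for c in range(M.m)}
        home = None
        for i, K in enumerate(ct.cliques):
            if K_t <= K:
                home = i
                break
        if home is None:
            raise InternalInconsistencyError(f"taxon {M.taxa_ids[t]} matches no clique")
        taxon_to_node[t] = home
    edges = [(a, b) for a, b, _, _ in ct.edges]
    artificial = frozenset(
        tuple(sorted((a, b))) for a, b, _, art in ct.edges if art
    )
    T = PerfectPhylogeny(species, edges, taxon_to_node, M.taxa_ids, artificial)
    degree: dict[int, int] = {i: 0 for i in range(T.n_nodes)}
    for a, b in edges:
        degree[a] += 1
        degree[b] += 1
    labeled = set(taxon_to_node.values())
    for i in range(T.n_nodes):
        if degree[i] <= 1 and i not in labeled and T.n_nodes > 1:
            raise InternalInconsistencyError(f"leaf node N{i} carries no taxon")
    return T


def verify_phylogeny(
    M: CharacterMatrix, T: PerfectPhylogeny
) -> tuple[bool, list[str]]:
    """Independent check of the four defining conditions.

    Returns (ok, violations); violations are strings describing each
    failure, never exceptions.
    """
    violations: list[str] = []
    adj: dict[int, set[int]] = {i: set() for i in range(T.n_nodes)}
    for a, b in T.edges:
        adj[a].add(b)
        adj[b].add(a)
    # the node set must form one tree
    if T.n_nodes > 0:
        seen = {0}
        stack = [0]
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        if len(seen) != T.n_nodes or len(T.edges) != T.n_nodes - 1:
            violations.append("node/edge structure is not a tree")
    # condition 1: each taxon labels exactly one node, species matches row
    for t in range(M.n):
        node = T.taxon_to_node.get(t)
        if node is None:
            violations.append(f"taxon {M.taxa_ids[t]} labels no node")
            continue
        sp = T.node_species[node]
        if len(sp) != M.m:
            violations.append(f"node N{node} species has wrong length")
            continue
        for c in range(M.m):
            if sp[c] != MISSING and sp[c] != int(M.states[t, c]):
                violations.append(
                    f"taxon {M.taxa_ids[t]} disagrees with node N{node} at character {c}"
                )
                break
    # condition 2: every leaf is taxon-labeled
    labeled = set(T.taxon_to_node.values())
    if T.n_nodes > 1:
        for i in range(T.n_nodes):
            if len(adj[i]) <= 1 and i not in labeled:
                violations.append(f"leaf N{i} carries no taxon")
    # condition 4: each character state occupies a connected subtree
    for c in range(M.m):
        by_state: dict[int, set[int]] = {}
        for i, sp in enumerate(T.node_species):
            if c < len(sp) and sp[c] != MISSING:
                by_state.setdefault(sp[c], set()).add(i)
        for s, occ in by_state.items():
            start = next(iter(occ))
            seen = {start}
            stack = [start]
            while stack:
                x = stack.pop()
                for y in adj[x]:
                    if y in occ and y not in seen:
                        seen.add(y)
                        stack.append(y)
            if seen != occ:
                violations.append(f"state {s} of character {c} is not connected")
    return (not violations, violations)


def construct(
    M: CharacterMatrix, seed: Optional[int] = None
) -> Union[PerfectPhylogeny, IncompatibilityReport]:
    """Run the seven-step pipeline end to end.

    Returns a verified phylogeny, or an incompatibility report naming the
    rejecting step and a witness.  ``seed`` shuffles the greedy order
    (any maximal family is correct; the tree returned may differ).
    """
    # step 1: pairwise screen
    bad_pairs = partition_graph.character_pair_acyclic(M)
    if bad_pairs:
        return IncompatibilityReport(step=1, witness=bad_pairs[0])
    # step 2: legal minimal separators from proper clusters
    D = legal_minimal_separators(M)
    # step 3: monochromatic pair separation
    unsep = unseparated_monochromatic_pairs(M, D)
    if unsep:
        return IncompatibilityReport(step=3, witness=unsep[0])
    # step 4: crossing relations
    crossing_relation(M, D)
    # step 5: greedy maximal parallel family
    Q = greedy_parallel_family(D, M.n, order=seed)
    # step 6: saturation
    G = build_pig(M)
    H = saturate(G, Q)
    # step 7: MCS clique tree and assembly
    ct = mcs_clique_tree(H)
    T = assemble_phylogeny(M, ct)
    ok, violations = verify_phylogeny(M, T)
    if not ok:
        raise InternalInconsistencyError(
            "constructed tree failed verification: " + "; ".join(violations)
        )
    return T
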