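"""Independent brute-force references used by tests and acceptance runs.

Nothing here shares code with the construction path: minimal separators
come from subset scans or neighborhood expansion, triangulations from
exhaustive fill-edge search, and the decision oracle from either that
search or exhaustive leaf-labeled topology enumeration.  Hard size guards
raise rather than silently crawling.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Optional, Union

import networkx as nx

from .errors import SizeLimitError
from .matrix_io import CharacterMatrix
from .partition_graph import ColoredGraph, StateVertex, build_pig

BRUTE_VERTEX_LIMIT = 20
FILL_LIMIT = 14
TREE_TAXA_LIMIT = 8


def _as_nx(G: Union[ColoredGraph, nx.Graph]) -> nx.Graph:
    return G.graph if isinstance(G, ColoredGraph) else G


def is_minimal_separator(g: nx.Graph, S: Iterable) -> bool:
    """Definition check: at least two full components after removal."""
    S = frozenset(S)
    rest = g.subgraph(set(g.nodes) - S)
    n_full = 0
    for comp in nx.connected_components(rest):
        nbhd = set()
        for v in comp:
            nbhd.update(g[v])
        if nbhd - comp == S:
            n_full += 1
            if n_full >= 2:
                return True
    return False


def brute_minimal_separators(G: Union[ColoredGraph, nx.Graph]) -> set[frozenset]:
    """Every vertex subset tested against the two-full-components
    characterization.  Exponential; guarded at 20 vertices."""
    g = _as_nx(G)
    nodes = sorted(g.nodes)
    if len(nodes) > BRUTE_VERTEX_LIMIT:
        raise SizeLimitError(f"{len(nodes)} vertices exceeds the brute-force guard")
    out = set()
    for r in range(len(nodes)):
        for S in combinations(nodes, r):
            if is_minimal_separator(g, S):
                out.add(frozenset(S))
    return out


def all_minimal_separators(G: Union[ColoredGraph, nx.Graph]) -> set[frozenset]:
    """Exact minimal-separator enumeration by neighborhood expansion
    (Berry-Bordat-Cogis style); polynomial per separator, so usable on
    graphs too large for the subset scan.  Validated against
    :func:`brute_minimal_separators` in the test suite."""
    g = _as_nx(G)
    nodes = set(g.nodes)

    def close_separators(removed: set) -> set[frozenset]:
        found = set()
        for comp in nx.connected_components(g.subgraph(nodes - removed)):
            nbhd = set()
            for v in comp:
                nbhd.update(g[v])
            found.add(frozenset(nbhd - comp))
        return found

    todo = set()
    for v in nodes:
        todo |= close_separators(set(g[v]) | {v})
    seen: set[frozenset] = set()
    while todo:
        S = todo.pop()
        if S in seen:
            continue
        seen.add(S)
        for x in S:
            for cand in close_separators(set(S) | set(g[x])):
                if cand not in seen:
                    todo.add(cand)
    return {S for S in seen if is_minimal_separator(g, S)}


def brute_is_parallel(G: Union[ColoredGraph, nx.Graph], S: Iterable, S2: Iterable) -> bool:
    """Direct definition: S is parallel to S2 iff S fits inside one
    component of the graph minus S2, plus S2 itself."""
    g = _as_nx(G)
    S, S2 = frozenset(S), frozenset(S2)
    if S <= S2:
        return True
    for comp in nx.connected_components(g.subgraph(set(g.nodes) - S2)):
        if S <= comp | S2:
            return True
    return False


# ---------------------------------------------------------------------- #
# fill-edge search

def candidate_legal_fills(M: CharacterMatrix) -> list[tuple[StateVertex, StateVertex]]:
    """Non-adjacent, differently colored vertex pairs of the base graph."""
    G = build_pig(M)
    verts = G.vertices
    return [
        (u, v)
        for u, v in combinations(verts, 2)
        if u.color != v.color and not G.has_edge(u, v)
    ]


def _decide_by_fills(M: CharacterMatrix, limit: int) -> bool:
    cands = candidate_legal_fills(M)
    if len(cands) > limit:
        raise SizeLimitError(
            f"{len(cands)} candidate fill edges exceeds the guard ({limit})"
        )
    base = build_pig(M).graph
    if nx.is_chordal(base):
        return True
    for r in range(1, len(cands) + 1):
        for fills in combinations(cands, r):
            h = base.copy()
            h.add_edges_from(fills)
            if nx.is_chordal(h):
                return True
    return False


# ---------------------------------------------------------------------- #
# leaf-labeled topology search

def _binary_topologies(n: int):
    """All unrooted binary tree topologies with leaves 0..n-1.

    Leaves are nodes 0..n-1; internal nodes get ids >= n.  Grown by
    attaching each next leaf to every existing edge ((2n-5)!! trees).
    """
    if n == 2:
        g = nx.Graph()
        g.add_edge(0, 1)
        yield g
        return

    def grow(g: nx.Graph, next_leaf: int, next_internal: int):
        if next_leaf == n:
            yield g
            return
        for u, v in list(g.edges):
            h = g.copy()
            h.remove_edge(u, v)
            w = next_internal
            h.add_edges_from([(u, w), (v, w), (w, next_leaf)])
            yield from grow(h, next_leaf + 1, next_internal + 1)

    start = nx.Graph()
    start.add_edge(0, 1)
    yield from grow(start, 2, n)


def _char_convex_on_tree(tree: nx.Graph, column) -> bool:
    """A character fits a leaf-labeled tree iff the minimal subtrees
    spanning its state classes are pairwise vertex-disjoint."""
    spans = []
    for s in sorted(set(int(x) for x in column)):
        leaves = [t for t, st in enumerate(column) if int(st) == s]
        sub = tree.copy()
        changed = True
        while changed:
            changed = False
            for v in [x for x in sub.nodes if sub.degree(x) <= 1 and x not in leaves]:
                sub.remove_node(v)
                changed = True
        spans.append(set(sub.nodes))
    for a, b in combinations(spans, 2):
        if a & b:
            return False
    return True


def _decide_by_trees(M: CharacterMatrix) -> bool:
    if M.n > TREE_TAXA_LIMIT:
        raise SizeLimitError(f"{M.n} taxa exceeds the topology-search guard")
    if M.n <= 2:
        return True
    if M.n == 3:
        # only the star; every <=3-state character is trivially convex on it
        return True
    for tree in _binary_topologies(M.n):
        if all(_char_convex_on_tree(tree, M.column(c)) for c in range(M.m)):
            return True
    return False


def brute_pp_decide(M: CharacterMatrix, method: str = "auto") -> bool:
    """Exact perfect-phylogeny decision by exhaustive search.

    ``fills``: search all subsets of legal fill edges for a chordal
    supergraph (guarded by candidate count).  ``trees``: search all
    leaf-labeled binary topologies for one on which every character is
    convex (guarded by taxon count).  ``auto`` prefers ``fills`` when it
    fits, falling back to ``trees``.
    """
    if method == "fills":
        return _decide_by_fills(M, FILL_LIMIT)
    if method == "trees":
        return _decide_by_trees(M)
    if method == "auto":
        if len(candidate_legal_fills(M)) <= FILL_LIMIT:
            return _decide_by_fills(M, FILL_LIMIT)
        return _decide_by_trees(M)
    raise ValueError(f"unknown method {method!r}")


def brute_proper_minimal_triangulations(
    M: CharacterMatrix, limit: int = FILL_LIMIT
) -> list[tuple[frozenset, set[frozenset]]]:
    """All inclusion-minimal legal fill sets achieving chordality.

    Returns ``(fill_set, minimal_separators_of_H)`` pairs, in canonical
    order; empty list iff no proper triangulation exists.
    """
    cands = candidate_legal_fills(M)
    if len(cands) > limit:
        raise SizeLimitError(
            f"{len(cands)} candidate fill edges exceeds the guard ({limit})"
        )
    base = build_pig(M).graph
    chordal_sets: list[frozenset] = []
    for r in range(len(cands) + 1):
        for fills in combinations(cands, r):
            fs = frozenset(frozenset(e) for e in fills)
            if any(prev <= fs for prev in chordal_sets):
                continue  # not inclusion-minimal
            h = base.copy()
            h.add_edges_from(fills)
            if nx.is_chordal(h):
                chordal_sets.append(fs)
    out = []
    for fs in sorted(chordal_sets, key=lambda s: sorted(tuple(sorted(e)) for e in s)):
        h = base.copy()
        h.add_edges_from(tuple(e) for e in fs)
        out.append((fs, all_minimal_separators(h)))
    return out
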