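"""The colored partition intersection graph and its forced chords.

Vertices are realized (character, state) pairs, colored by character.
E-edges record co-occurrence of two states in a taxon row; every taxon row
therefore induces an m-clique.  On top of the base graph, each chordless
4-cycle spanning exactly three colors forces a unique legal chord between
its two differently colored "side" vertices; adding all such chords yields
the augmented graph used by the structural property tests.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, NamedTuple, Optional

import networkx as nx

from .errors import ObstructionError
from .matrix_io import CharacterMatrix

E_EDGE = "E"
F_EDGE = "F"
FILL_EDGE = "fill"


class StateVertex(NamedTuple):
    """A character-state vertex; its color is the character index."""

    char: int
    state: int

    @property
    def color(self) -> int:
        return self.char

    def __repr__(self) -> str:
        return f"c{self.char}_s{self.state}"


class ColoredGraph:
    """A properly colored graph over :class:`StateVertex` vertices.

    Thin wrapper around :class:`networkx.Graph`; every edge carries a
    ``kind`` attribute (``E``, ``F`` or ``fill``) and joining two vertices
    of the same color is rejected at insertion time.
    """

    def __init__(self, graph: Optional[nx.Graph] = None):
        self.graph = graph if graph is not None else nx.Graph()

    # -- construction --------------------------------------------------- #

    def add_vertex(self, v: StateVertex) -> None:
        self.graph.add_node(v)

    def add_edge(self, u: StateVertex, v: StateVertex, kind: str = E_EDGE) -> None:
        if u.color == v.color:
            raise ObstructionError(f"same-color edge {u}-{v} is never legal")
        if self.graph.has_edge(u, v):
            return  # first kind wins (E before F before fill)
        self.graph.add_edge(u, v, kind=kind)

    # -- queries -------------------------------------------------------- #

    @property
    def vertices(self) -> list[StateVertex]:
        return sorted(self.graph.nodes)

    def edges(self, kind: Optional[str] = None) -> list[tuple[StateVertex, StateVertex]]:
        out = []
        for u, v, k in self.graph.edges(data="kind"):
            if kind is None or k == kind:
                out.append(tuple(sorted((u, v))))
        return sorted(out)

    def color(self, v: StateVertex) -> int:
        return v.color

    def has_edge(self, u: StateVertex, v: StateVertex) -> bool:
        return self.graph.has_edge(u, v)

    def copy(self) -> "ColoredGraph":
        return ColoredGraph(self.graph.copy())

    def is_properly_colored(self) -> bool:
        return all(u.color != v.color for u, v in self.graph.edges)

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    # -- export --------------------------------------------------------- #

    def to_dot(self) -> str:
        lines = ["graph pig {"]
        for v in self.vertices:
            lines.append(f'  "{v}" [color={v.char}];')
        for u, v, k in sorted(self.graph.edges(data="kind")):
            style = {E_EDGE: "solid", F_EDGE: "dashed", FILL_EDGE: "dotted"}[k]
            lines.append(f'  "{u}" -- "{v}" [style={style}];')
        lines.append("}")
        return "\n".join(lines) + "\n"

    def to_edge_tsv(self) -> str:
        lines = ["u\tv\tkind"]
        for u, v, k in sorted((tuple(sorted((a, b))) + (k,)) for a, b, k in self.graph.edges(data="kind")):
            lines.append(f"{u}\t{v}\t{k}")
        return "\n".join(lines) + "\n"


def build_pig(M: CharacterMatrix) -> ColoredGraph:
    """Partition intersection graph of ``M``.

    One vertex per realized (character, state); an E-edge for every pair of
    states co-occurring in some taxon row.
    """
    G = ColoredGraph()
    for c in range(M.m):
        for s in range(M.num_states(c)):
            G.add_vertex(StateVertex(c, s))
    for t in range(M.n):
        row = M.row(t)
        verts = [StateVertex(c, int(row[c])) for c in range(M.m)]
        for u, v in combinations(verts, 2):
            G.add_edge(u, v, E_EDGE)
    return G


def induced_subgraph(G: ColoredGraph, characters: Iterable[int]) -> ColoredGraph:
    """Restriction of ``G`` to the vertices of the named colors."""
    chars = set(characters)
    keep = [v for v in G.graph.nodes if v.char in chars]
    return ColoredGraph(G.graph.subgraph(keep).copy())


def character_pair_acyclic(M: CharacterMatrix) -> list[tuple[int, int]]:
    """Screen every character pair's two-color subgraph for cycles.

    Returns the (sorted) list of violating pairs; an empty list means the
    pairwise screen passes.  Cycle detection is a union-find pass over the
    deduplicated co-occurrence edges of the pair.
    """
    violations = []
    cols = [M.column(c) for c in range(M.m)]
    for i, j in combinations(range(M.m), 2):
        edges = set(zip(cols[i].tolist(), cols[j].tolist()))
        parent: dict = {}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        cyclic = False
        for a, b in edges:
            u, v = ("i", a), ("j", b)
            for node in (u, v):
                if node not in parent:
                    parent[node] = node
            ru, rv = find(u), find(v)
            if ru == rv:
                cyclic = True
                break
            parent[ru] = rv
        if cyclic:
            violations.append((i, j))
    return violations


def _is_chord_free(G: nx.Graph, cycle: list) -> bool:
    k = len(cycle)
    pos = {v: i for i, v in enumerate(cycle)}
    for u, v in combinations(cycle, 2):
        d = abs(pos[u] - pos[v])
        if d not in (1, k - 1) and G.has_edge(u, v):
            return False
    return True


def chordless_cycles(G: ColoredGraph, max_len: Optional[int] = None) -> list[list[StateVertex]]:
    """All chordless cycles of length >= 4 (diagnostic enumeration).

    Backed by :func:`networkx.chordless_cycles` with an optional length
    bound; every reported cycle is re-verified chord-free.
    """
    out = []
    for cyc in nx.chordless_cycles(G.graph, length_bound=max_len):
        if len(cyc) >= 4:
            assert _is_chord_free(G.graph, list(cyc))
            out.append([StateVertex(*v) for v in cyc])
    return out


def chordless_four_cycles(
    G: ColoredGraph,
) -> list[tuple[StateVertex, StateVertex, StateVertex, StateVertex]]:
    """Chordless 4-cycles ``u-x-v-x'`` with ``u, v`` a monochromatic pair.

    Iterates over same-color vertex pairs (never adjacent in a properly
    colored graph) and their non-adjacent common neighbors.  Exactly the
    chordless 4-cycles on at most three colors are found — the ones that
    force a chord; 4-color chordless 4-cycles have no monochromatic pair
    and are deliberately not reported.
    """
    g = G.graph
    by_color: dict[int, list[StateVertex]] = {}
    for v in g.nodes:
        by_color.setdefault(v.char, []).append(v)
    cycles = []
    seen = set()
    for verts in by_color.values():
        for u, v in combinations(sorted(verts), 2):
            common = sorted(set(g[u]) & set(g[v]))
            for x, xp in combinations(common, 2):
                if not g.has_edge(x, xp):
                    key = frozenset((u, v, x, xp))
                    if key not in seen:
                        seen.add(key)
                        cycles.append((u, x, v, xp))
    return cycles


def build_augmented(M: CharacterMatrix) -> ColoredGraph:
    """Base graph plus the forced chord of every 3-color chordless 4-cycle.

    Precondition: the pairwise screen passed.  A chordless 4-cycle on only
    two colors admits no legal chord and raises :class:`ObstructionError`.
    """
    G = build_pig(M)
    Gp = G.copy()
    for u, x, v, xp in chordless_four_cycles(G):
        if x.color == xp.color:
            raise ObstructionError(
                f"two-color chordless 4-cycle on characters {u.char} and {x.char}"
            )
        Gp.add_edge(x, xp, F_EDGE)
    return Gp
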