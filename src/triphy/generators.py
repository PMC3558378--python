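"""Synthetic inputs: tree-derived random matrices, the interval-character
caterpillar family, and certified-incompatible perturbations.

A character compatible with a tree arises from cutting edges: one cut for
a binary character, two cuts for a ternary one, each resulting subtree
becoming a state.  Matrices built this way carry their generating tree as
a ground-truth phylogeny.
"""

from __future__ import annotations

import random
from itertools import combinations
from math import comb
from typing import Optional

import networkx as nx
import numpy as np

from .errors import ParameterError
from .matrix_io import CharacterMatrix, from_rows
from .triangulation import PerfectPhylogeny


def _random_binary_tree(n: int, rng: random.Random) -> nx.Graph:
    """Uniform random unrooted binary topology; leaves 0..n-1, internal
    nodes >= n (sequential random edge attachment)."""
    g = nx.Graph()
    if n == 2:
        g.add_edge(0, 1)
        return g
    g.add_edge(0, 1)
    next_internal = n
    for leaf in range(2, n):
        u, v = rng.choice(sorted(g.edges))
        w = next_internal
        next_internal += 1
        g.remove_edge(u, v)
        g.add_edges_from([(u, w), (v, w), (w, leaf)])
    return g


def _states_from_cuts(tree: nx.Graph, cut_edges) -> dict[int, int]:
    """Node -> raw state map: one state per component after cutting."""
    h = tree.copy()
    h.remove_edges_from(cut_edges)
    states = {}
    for i, comp in enumerate(sorted(nx.connected_components(h), key=min)):
        for v in comp:
            states[v] = i
    return states


def random_pp_matrix(
    n: int,
    m: int,
    three_state_fraction: float = 0.5,
    seed: Optional[int] = None,
) -> tuple[CharacterMatrix, PerfectPhylogeny]:
    """A compatible matrix drawn from a random tree, plus that tree.

    ``three_state_fraction`` of the ``m`` characters cut two tree edges
    (three states); the rest cut one (two states).  The returned phylogeny
    has the taxa at the leaves and fully specified internal species, and
    satisfies the verifier by construction.
    """
    if n < 2:
        raise ParameterError("need at least two taxa")
    if m < 1:
        raise ParameterError("need at least one character")
    if not 0.0 <= three_state_fraction <= 1.0:
        raise ParameterError("three_state_fraction must be a proportion")
    rng = random.Random(seed)
    tree = _random_binary_tree(n, rng)
    edges = sorted(tree.edges)
    n_three = int(round(m * three_state_fraction))
    if n_three > 0 and len(edges) < 2:
        raise ParameterError("a 3-state character needs a tree with at least two edges")
    arities = [3] * n_three + [2] * (m - n_three)
    rng.shuffle(arities)
    node_states = []
    for r in arities:
        cuts = rng.sample(edges, r - 1)
        node_states.append(_states_from_cuts(tree, cuts))
    # canonicalize states by first appearance down the taxon rows, then
    # carry the same relabeling onto the internal nodes
    raw_rows = [[node_states[c][t] for c in range(m)] for t in range(n)]
    remap = []
    for c in range(m):
        mapping: dict[int, int] = {}
        for t in range(n):
            mapping.setdefault(raw_rows[t][c], len(mapping))
        remap.append(mapping)
    rows = [[remap[c][raw_rows[t][c]] for c in range(m)] for t in range(n)]
    M = from_rows(rows, drop_constant=False)
    nodes = sorted(tree.nodes)
    node_index = {v: i for i, v in enumerate(nodes)}
    species = [
        tuple(remap[c][node_states[c][v]] for c in range(m)) for v in nodes
    ]
    t_edges = [(node_index[a], node_index[b]) for a, b in edges]
    taxon_to_node = {t: node_index[t] for t in range(n)}
    T = PerfectPhylogeny(species, t_edges, taxon_to_node, M.taxa_ids)
    return M, T


def mstar_matrix(n: int) -> CharacterMatrix:
    """The interval-character family on a caterpillar of ``n`` taxa.

    One character per pair ``(i, j)`` with ``1 <= i < j < n`` assigning
    state 0 to taxa ``t1..ti``, state 1 to ``t(i+1)..tj`` and state 2 to
    ``t(j+1)..tn``; ``m = C(n-1, 2)``.  Its graph has quadratically many
    edges, which is what makes the family interesting.
    """
    if n < 4:
        raise ParameterError("the interval family needs n >= 4")
    char_ids = []
    cols = []
    for i, j in combinations(range(1, n), 2):
        char_ids.append(f"chi_{i}_{j}")
        col = [0 if t <= i else (1 if t <= j else 2) for t in range(1, n + 1)]
        cols.append(col)
    states = np.array(cols).T
    assert states.shape[1] == comb(n - 1, 2)
    return CharacterMatrix(
        tuple(f"t{t}" for t in range(1, n + 1)), tuple(char_ids), states
    )


def mstar_vertex_cell_taxa(n: int) -> dict:
    """Taxa (1-based) in each cell of each interval character; keys are
    ``((i, j), state)``.  Companion to :func:`mstar_matrix` for tests."""
    out = {}
    for i, j in combinations(range(1, n), 2):
        out[((i, j), 0)] = frozenset(range(1, i + 1))
        out[((i, j), 1)] = frozenset(range(i + 1, j + 1))
        out[((i, j), 2)] = frozenset(range(j + 1, n + 1))
    return out


def make_incompatible(
    n: int, mode: str = "pair_cycle", seed: Optional[int] = None
) -> CharacterMatrix:
    """A certified-incompatible matrix on ``n`` taxa.

    ``pair_cycle`` embeds a character pair realizing all four state
    combinations (rejected by the pairwise screen); ``long_cycle`` embeds
    the five-taxon chordless 5-cycle pattern with every character pair
    acyclic (rejected by the monochromatic-pair screen).  Extra taxa are
    duplicated rows, which never removes an obstruction.
    """
    if mode == "pair_cycle":
        if n < 4:
            raise ParameterError("pair_cycle needs n >= 4")
        core = [(0, 0), (0, 1), (1, 1), (1, 0)]
    elif mode == "long_cycle":
        if n < 5:
            raise ParameterError("long_cycle needs n >= 5")
        core = [(0, 0, 1), (1, 0, 1), (1, 2, 0), (2, 1, 0), (0, 1, 1)]
    else:
        raise ParameterError(f"unknown mode {mode!r}")
    rows = [list(core[t]) if t < len(core) else list(core[-1]) for t in range(n)]
    if mode == "pair_cycle" and seed is not None and n >= 2:
        # pad with a couple of tree-compatible columns for variety; a
        # superset of an incompatible character set stays incompatible.
        # (long_cycle gets row padding only: extra columns could collide
        # with the core into a pairwise cycle, moving rejection to step 1)
        extra, _ = random_pp_matrix(n, 2, three_state_fraction=0.5, seed=seed)
        rows = [list(r) + [int(extra.states[t, c]) for c in range(extra.m)] for t, r in enumerate(rows)]
    return from_rows(rows, drop_constant=False)


def four_taxon_partitions() -> list[tuple[int, ...]]:
    """The 13 canonical non-constant state columns on four taxa.

    Canonical (first-appearance) 4-tuples over {0,1,2} with two or three
    distinct values: 7 bipartitions plus 6 three-block partitions.
    """
    out = []
    for col in np.ndindex(3, 3, 3, 3):
        k = len(set(col))
        if k not in (2, 3):
            continue
        seen: dict[int, int] = {}
        canonical = True
        for x in col:
            if x not in seen:
                if x != len(seen):
                    canonical = False
                    break
                seen[x] = len(seen)
        if canonical:
            out.append(tuple(int(x) for x in col))
    assert len(out) == 13
    return out
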