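"""Proper clusters and the legal minimal separators they generate.

The separator machinery works from the matrix, never from an all-subset
scan of the graph.  Each character contributes at most three bipartitions
of its state set; a bipartition that splits the taxa so that every
character shares at most one state across the split (and the generating
character shares none) is a proper cluster, and its shared states — the
splitting vector — are the candidate separator.  Grouping taxa by the
transitive closure of "share a state outside the candidate" recovers the
connected components of the graph minus the candidate, and the candidate
is kept exactly when at least two of those components are full.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np

from .matrix_io import CharacterMatrix
from .partition_graph import StateVertex


@dataclass(frozen=True)
class ProperCluster:
    """A taxa bipartition in which every character shares <= 1 state."""

    side_a: frozenset[int]
    side_b: frozenset[int]
    splitting_vector: frozenset[StateVertex]
    witness_character: int

    def __post_init__(self) -> None:
        assert self.side_a and self.side_b and not (self.side_a & self.side_b)


@dataclass(frozen=True)
class Component:
    """One connected component of the graph minus a separator."""

    vertices: frozenset[StateVertex]
    taxa: frozenset[int]
    full: bool


@dataclass(frozen=True)
class Separator:
    """A legal minimal separator with its components and taxon partition."""

    vertices: frozenset[StateVertex]
    components: tuple[Component, ...]

    @property
    def legal(self) -> bool:
        colors = [v.color for v in self.vertices]
        return len(colors) == len(set(colors))

    @property
    def full_components(self) -> tuple[Component, ...]:
        return tuple(c for c in self.components if c.full)

    def taxa_parts(self) -> list[frozenset[int]]:
        """The taxon partition induced by the components."""
        return [c.taxa for c in self.components]

    def sort_key(self) -> tuple:
        return tuple(sorted(self.vertices))

    def component_of(self, v: StateVertex) -> Optional[int]:
        for i, comp in enumerate(self.components):
            if v in comp.vertices:
                return i
        return None


@dataclass
class SeparatorSet:
    """Deduplicated legal minimal separators, in canonical order."""

    separators: list[Separator]
    parallel: Optional[np.ndarray] = field(default=None)

    def __len__(self) -> int:
        return len(self.separators)

    def __iter__(self):
        return iter(self.separators)

    def __getitem__(self, i: int) -> Separator:
        return self.separators[i]

    def vertex_sets(self) -> set[frozenset[StateVertex]]:
        return {s.vertices for s in self.separators}


# ---------------------------------------------------------------------- #

def _state_bipartitions(k: int):
    """Nonempty bipartitions of {0..k-1}: 1 for k=2, 3 for k=3."""
    states = list(range(k))
    for r in range(1, k // 2 + 1):
        for combo in combinations(states, r):
            a = set(combo)
            b = set(states) - a
            if len(a) == len(b) and min(b) < min(a):
                continue  # avoid double-listing complementary halves
            yield a, b


def _taxa_masks(M: CharacterMatrix) -> dict[StateVertex, int]:
    """Bitmask of taxa carrying each realized character state."""
    masks: dict[StateVertex, int] = {}
    for t in range(M.n):
        bit = 1 << t
        for c, s in enumerate(M.row(t)):
            v = StateVertex(c, int(s))
            masks[v] = masks.get(v, 0) | bit
    return masks


def _mask_to_set(mask: int) -> frozenset[int]:
    return frozenset(i for i in range(mask.bit_length()) if mask >> i & 1)


def enumerate_proper_clusters(M: CharacterMatrix) -> list[ProperCluster]:
    """All proper clusters of ``M``, deduplicated by bipartition.

    For each character and each bipartition of its states, the induced taxa
    bipartition is kept iff every character shares at most one state across
    it.  The generating character shares none, so it serves as witness.
    """
    masks = _taxa_masks(M)
    all_mask = (1 << M.n) - 1
    clusters: list[ProperCluster] = []
    seen: set[frozenset[frozenset[int]]] = set()
    for c in range(M.m):
        k = M.num_states(c)
        if k < 2:
            continue
        for a_states, _b_states in _state_bipartitions(k):
            side_a_mask = 0
            for s in a_states:
                side_a_mask |= masks[StateVertex(c, s)]
            side_b_mask = all_mask & ~side_a_mask
            if side_a_mask == 0 or side_b_mask == 0:
                continue
            vector = []
            proper = True
            for d in range(M.m):
                shared = [
                    StateVertex(d, s)
                    for s in range(M.num_states(d))
                    if masks[StateVertex(d, s)] & side_a_mask
                    and masks[StateVertex(d, s)] & side_b_mask
                ]
                if len(shared) > 1:
                    proper = False
                    break
                vector.extend(shared)
            if not proper:
                continue
            side_a = _mask_to_set(side_a_mask)
            side_b = _mask_to_set(side_b_mask)
            key = frozenset((side_a, side_b))
            if key in seen:
                continue
            seen.add(key)
            clusters.append(ProperCluster(side_a, side_b, frozenset(vector), c))
    clusters.sort(key=lambda pc: (sorted(pc.side_a), sorted(pc.side_b)))
    return clusters


def s_partition(M: CharacterMatrix, x: frozenset[StateVertex]) -> list[frozenset[int]]:
    """Taxa classes of the transitive closure of sharing a state outside ``x``.

    Union-find over one pass of the columns; classes are returned sorted by
    smallest member.
    """
    parent = list(range(M.n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for v, mask in _taxa_masks(M).items():
        if v in x:
            continue
        members = [i for i in range(M.n) if mask >> i & 1]
        for i in members[1:]:
            ri, r0 = find(i), find(members[0])
            if ri != r0:
                parent[ri] = r0
    classes: dict[int, set[int]] = {}
    for i in range(M.n):
        classes.setdefault(find(i), set()).add(i)
    return sorted((frozenset(c) for c in classes.values()), key=min)


def separator_from_cluster(
    M: CharacterMatrix, pc: ProperCluster
) -> Optional[Separator]:
    """Certify a proper cluster's splitting vector as a minimal separator.

    Components come from the taxa classes of the splitting vector; a
    component is full iff every separator vertex occurs in some row of its
    class.  Returns the separator iff at least two components are full.
    """
    S = pc.splitting_vector
    masks = _taxa_masks(M)
    comps = []
    n_full = 0
    for cls in s_partition(M, S):
        verts = frozenset(
            StateVertex(c, int(M.states[t, c]))
            for t in cls
            for c in range(M.m)
        ) - S
        cls_mask = 0
        for t in cls:
            cls_mask |= 1 << t
        full = all(masks[v] & cls_mask for v in S)
        n_full += full
        comps.append(Component(verts, cls, full))
    if n_full < 2:
        return None
    return Separator(S, tuple(comps))


def legal_minimal_separators(M: CharacterMatrix) -> SeparatorSet:
    """The separator set Delta*: legal minimal separators with < m vertices.

    Generated from proper clusters and deduplicated by vertex set; every
    member is asserted legal and small, and the whole set is bounded by 3m.
    """
    by_vertices: dict[frozenset[StateVertex], Separator] = {}
    for pc in enumerate_proper_clusters(M):
        sep = separator_from_cluster(M, pc)
        if sep is None or sep.vertices in by_vertices:
            continue
        assert sep.legal, "proper clusters can only yield legal separators"
        assert len(sep.vertices) < M.m
        by_vertices[sep.vertices] = sep
    seps = sorted(by_vertices.values(), key=Separator.sort_key)
    assert len(seps) <= 3 * M.m
    return SeparatorSet(seps)


def unseparated_monochromatic_pairs(
    M: CharacterMatrix, D: SeparatorSet
) -> list[tuple[StateVertex, StateVertex]]:
    """Monochromatic vertex pairs not split apart by any separator in ``D``.

    An empty result (after the pairwise screen) certifies compatibility.
    """
    out = []
    for c in range(M.m):
        k = M.num_states(c)
        for s1, s2 in combinations(range(k), 2):
            u, v = StateVertex(c, s1), StateVertex(c, s2)
            separated = False
            for sep in D:
                iu, iv = sep.component_of(u), sep.component_of(v)
                if iu is not None and iv is not None and iu != iv:
                    separated = True
                    break
            if not separated:
                out.append((u, v))
    return out


def are_parallel(M: CharacterMatrix, S: Separator, S2: Separator) -> bool:
    """True iff some full component of ``S`` has its taxa inside one part
    of the taxon partition of ``S2``."""
    part_of = _part_index(M, S2)
    return _parallel_from_parts(S, part_of)


def _part_index(M: CharacterMatrix, sep: Separator) -> list[int]:
    part_of = [-1] * M.n
    for i, comp in enumerate(sep.components):
        for t in comp.taxa:
            part_of[t] = i
    return part_of


def _parallel_from_parts(S: Separator, part_of: Sequence[int]) -> bool:
    for comp in S.full_components:
        ids = {part_of[t] for t in comp.taxa}
        if len(ids) == 1:
            return True
    return False


def crossing_relation(M: CharacterMatrix, D: SeparatorSet) -> np.ndarray:
    """Symmetric boolean matrix: entry (i, j) true iff separators i and j
    are parallel.  O(n) per pair via taxon part indices."""
    k = len(D)
    parts = [_part_index(M, sep) for sep in D]
    out = np.zeros((k, k), dtype=bool)
    for i in range(k):
        out[i, i] = True
        for j in range(i + 1, k):
            p = _parallel_from_parts(D[i], parts[j])
            out[i, j] = out[j, i] = p
    D.parallel = out
    return out


def separators_tsv(M: CharacterMatrix, D: SeparatorSet) -> str:
    """Human-readable TSV report: one row per separator plus the crossing
    matrix block."""
    lines = ["id\tsize\tvertices\tn_components\tn_full"]
    for i, sep in enumerate(D):
        verts = ",".join(str(v) for v in sorted(sep.vertices)) or "-"
        lines.append(
            f"S{i}\t{len(sep.vertices)}\t{verts}\t{len(sep.components)}\t{len(sep.full_components)}"
        )
    cross = D.parallel if D.parallel is not None else crossing_relation(M, D)
    lines.append("")
    lines.append("crossing\t" + "\t".join(f"S{j}" for j in range(len(D))))
    for i in range(len(D)):
        row = "\t".join("parallel" if cross[i, j] else "cross" for j in range(len(D)))
        lines.append(f"S{i}\t{row}")
    return "\n".join(lines) + "\n"
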