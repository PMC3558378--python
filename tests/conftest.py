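import itertools

import numpy as np
import pytest

from triphy.matrix_io import CharacterMatrix, fixtures
from triphy.partition_graph import StateVertex


@pytest.fixture(scope="session")
def fx():
    return fixtures()


@pytest.fixture(scope="session")
def F1(fx):
    return fx["F1"]


@pytest.fixture(scope="session")
def F2(fx):
    return fx["F2"]


@pytest.fixture(scope="session")
def F3(fx):
    return fx["F3"]


@pytest.fixture(scope="session")
def F4(fx):
    return fx["F4"]


@pytest.fixture(scope="session")
def F5(fx):
    return fx["F5"]


def sv(c, s):
    return StateVertex(c, s)


def vset(*pairs):
    return frozenset(StateVertex(c, s) for c, s in pairs)


def matrix_from_columns(columns, taxa=None):
    """Build a CharacterMatrix from canonical state columns (tuples)."""
    states = np.array(columns, dtype=np.int64).T
    n = states.shape[0]
    taxa = taxa or tuple(f"t{i+1}" for i in range(n))
    chars = tuple(f"c{j+1}" for j in range(states.shape[1]))
    return CharacterMatrix(tuple(taxa), chars, states)


def legal_small(separator_sets, m):
    """Filter a set of vertex-set separators down to legal ones with < m
    vertices (the reference side of the Delta* equivalence)."""
    out = set()
    for S in separator_sets:
        if len(S) >= m:
            continue
        colors = [v.char for v in S]
        if len(colors) == len(set(colors)):
            out.add(frozenset(S))
    return out


def three_taxon_columns():
    """Canonical non-constant columns on 3 taxa (3 bipartitions + 1 full split)."""
    out = []
    for col in itertools.product(range(3), repeat=3):
        k = len(set(col))
        if k == 1:
            continue
        seen = {}
        ok = True
        for x in col:
            if x not in seen:
                if x != len(seen):
                    ok = False
                    break
                seen[x] = len(seen)
        if ok:
            out.append(col)
    return out
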