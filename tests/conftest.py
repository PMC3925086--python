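import numpy as np
import pytest

from pdseq.chem import ModificationTable, ResidueMassTable
from pdseq.graph_builder import ExtendedSpectrumGraph, SpectrumVertex, build_graph
from pdseq.spectra import Peak, Spectrum


@pytest.fixture(scope="session")
def table():
    return ResidueMassTable.standard()


@pytest.fixture(scope="session")
def mods():
    return ModificationTable.default()


def abstract_graph(peak_masses, total_mass, table, tol=0.001):
    """Extended spectrum graph from abstract peak masses."""
    s = Spectrum(tuple(Peak(m) for m in peak_masses), total_mass)
    return build_graph(s, table, tol)


def random_mixed_graph(rng, n_mid=8, edge_p=0.25, comp_p=0.6, chain=False):
    """A random mass-sorted DAG plus random complement pairs.

    Vertices get uniform random masses; any increasing pair may receive a
    directed edge; complement pairs are a random partial matching of the
    middle vertices.  This is the fuzzing substrate for the DP-vs-oracle
    equivalence checks.
    """
    M = 100.0
    masses = sorted(rng.uniform(1, 99, size=n_mid))
    verts = [SpectrumVertex(i, m) for i, m in enumerate([0.0] + list(masses) + [M])]
    n = len(verts)
    directed = {}
    if chain:
        for i in range(n - 1):
            directed[(i, i + 1)] = frozenset({"x"})
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < edge_p:
                directed[(i, j)] = frozenset({"x"})
    comp = set()
    mids = list(range(1, n - 1))
    rng.shuffle(mids)
    for a, b in zip(mids[::2], mids[1::2]):
        if rng.random() < comp_p:
            comp.add(frozenset((min(a, b), max(a, b))))
    return ExtendedSpectrumGraph(verts, directed, comp, M)
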