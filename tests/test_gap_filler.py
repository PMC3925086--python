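import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import abstract_graph
from pdseq.chem import ModificationTable, ResidueMassTable
from pdseq.dp_solver import brute_force_lapp, solve
from pdseq.gap_filler import (
    EXACT,
    Gap,
    MODIFIED,
    UNRESOLVED,
    assemble,
    find_gaps,
    resolve,
    subset_fill,
)
from pdseq.path_decomposition import decompose


def exhaustive_fill(delta, table, tol, max_residues):
    """Independent oracle: enumerate residue multisets directly."""
    codes = sorted(table.residues)
    found = set()
    for k in range(1, max_residues + 1):
        for combo in itertools.combinations_with_replacement(codes, k):
            total = sum(table.mass(c) for c in combo)
            if abs(total - delta) <= tol:
                found.add(tuple(sorted(combo)))
    return found


# ---------------------------------------------------------------------------
# subset_fill
# ---------------------------------------------------------------------------

def test_single_glycine(table):
    fills = subset_fill(57.02146, table, tol=0.01)
    assert fills[0].residues == (("G", None),)
    assert fills[0].status == EXACT


def test_n_vs_gg_ranking(table):
    fills = subset_fill(114.04293, table, tol=0.01)
    comps = [f.residues for f in fills]
    assert (("N", None),) in comps
    assert (("G", None), ("G", None)) in comps
    # fewer residues ranks first
    assert fills[0].residues == (("N", None),)


def test_oxidised_methionine_step_four(table, mods):
    # 147.03540 = M (131.04049) + oxidation (15.99491); no unmodified match
    fills = subset_fill(147.03540, table, mods, tol=0.01)
    assert fills[0].status == MODIFIED
    assert fills[0].residues == (("M", "Ox(M)"),)


def test_below_minimum_residue_unresolvable(table, mods):
    assert subset_fill(30.0, table, mods, tol=0.01) == []


def test_rejects_nonpositive_delta(table):
    with pytest.raises(ValueError):
        subset_fill(-5.0, table)


def test_subset_fill_matches_exhaustive_enumeration(table):
    rng = np.random.default_rng(21)
    for _ in range(20):
        delta = float(rng.uniform(60, 280))
        tol = 0.02
        got = {
            tuple(c for c, _m in f.residues)
            for f in subset_fill(delta, table, tol=tol)
        }
        want = exhaustive_fill(delta, table, tol, int(np.ceil(delta / 57.02146)))
        assert got == want, delta


@settings(derandomize=True, max_examples=40)
@given(
    st.lists(
        st.sampled_from(sorted(ResidueMassTable.standard().residues)),
        min_size=1,
        max_size=4,
    )
)
def test_true_compositions_always_found_unmodified(combo):
    """A delta that is a residue sum is explained without modifications."""
    table = ResidueMassTable.standard()
    mods = ModificationTable.default()
    delta = sum(table.mass(c) for c in combo)
    fills = subset_fill(delta, table, mods, tol=0.001)
    assert fills, combo
    # step order: an unmodified explanation exists, so no fill carries a mod
    assert all(f.status == EXACT for f in fills)
    assert tuple(sorted((c, None) for c in combo)) in {f.residues for f in fills}


# ---------------------------------------------------------------------------
# find_gaps / assemble
# ---------------------------------------------------------------------------

def test_find_gaps_counts(table):
    # single segment -> no gaps
    g1 = abstract_graph([57.02146], 114.04292, table)
    p1 = solve(g1, decompose(g1))
    assert find_gaps(p1, g1) == []
    # missing middle peak -> one gap with the boundary delta
    peaks = [57.02146, 57.02146 + 99.06841 + 57.02146]
    g2 = abstract_graph(peaks, 2 * (57.02146 + 99.06841), table)
    p2 = solve(g2, decompose(g2))
    (gap,) = find_gaps(p2, g2)
    # the missing peak leaves a two-residue gap: G + V
    assert gap.delta == pytest.approx(57.02146 + 99.06841, abs=1e-5)


def test_gap_requires_positive_delta():
    with pytest.raises(ValueError):
        Gap(1, 2, -3.0)


def test_assemble_contiguous_ga(table):
    g = abstract_graph([57.02146, 71.03711], 128.05857, table)
    p = solve(g, decompose(g))
    result = resolve(p, g, table)
    assert str(result) == "GA"
    assert result.mass_error() < 1e-4


def test_assemble_with_gap_fill(table):
    # G [G] A: both middle peaks lost, and the graph (built by hand: with
    # real masses a one-residue gap between surviving peaks is itself an
    # edge) leaves one bracketed glycine between the two called residues
    from pdseq.graph_builder import ExtendedSpectrumGraph, SpectrumVertex

    M = 57.02146 * 2 + 71.03711
    verts = [
        SpectrumVertex(0, 0.0),
        SpectrumVertex(1, 57.02146),
        SpectrumVertex(2, 114.04292),
        SpectrumVertex(3, M),
    ]
    directed = {(0, 1): frozenset({"G"}), (2, 3): frozenset({"A"})}
    g = ExtendedSpectrumGraph(verts, directed, set(), M)
    p = solve(g, decompose(g))
    result = resolve(p, g, table)
    assert str(result) == "G[G]A"
    assert result.mass_error() < 1e-3


def test_assemble_unresolved_gap(table):
    """A gap below the smallest residue mass is reported, not invented."""
    from pdseq.graph_builder import ExtendedSpectrumGraph, SpectrumVertex

    verts = [
        SpectrumVertex(0, 0.0),
        SpectrumVertex(1, 57.02146),
        SpectrumVertex(2, 87.02146),
        SpectrumVertex(3, 87.02146 + 71.03711),
    ]
    directed = {(0, 1): frozenset({"G"}), (2, 3): frozenset({"A"})}
    g = ExtendedSpectrumGraph(verts, directed, set(), 87.02146 + 71.03711)
    p = solve(g, decompose(g))
    result = resolve(p, g, table)
    assert str(result) == "G[Δ30.000]A"
    rec = result.to_record()
    assert rec["elements"][1]["status"] == UNRESOLVED


def test_assemble_requires_one_fill_per_gap(table):
    peaks = [57.02146, 57.02146 + 99.06841 + 57.02146]
    g = abstract_graph(peaks, 2 * (57.02146 + 99.06841), table)
    p = solve(g, decompose(g))
    with pytest.raises(ValueError):
        assemble(p, [], g, table)


def test_mass_conservation_on_random_ladders(table, mods):
    """Sum of element masses equals M within k*tol for assembled results."""
    from pdseq.chem import Peptide
    from pdseq.simulator import ideal_spectrum

    rng = np.random.default_rng(22)
    codes = sorted(table.residues)
    for _ in range(10)    :
        n = int(rng.integers(5, 12))
        seq = "".join(codes[int(i)] for i in rng.integers(0, 20, n - 1)) + "R"
        spec = ideal_spectrum(Peptide(seq), table)
        # drop a random interior peak to force a gap
        peaks = list(spec.peaks)
        del peaks[int(rng.integers(1, len(peaks) - 1))]
        g = abstract_graph([p.mass for p in peaks], spec.total_mass, table)
        p = solve(g, decompose(g))
        result = resolve(p, g, table, mods)
        k = len(result.elements)
        assert result.mass_error() <= k * 0.01
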