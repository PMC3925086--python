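import numpy as np
import pytest

from pdseq.chem import Peptide, prefix_masses
from pdseq.gap_filler import GapFill, ResultElement, SequencingResult
from pdseq.simulator import (
    SimulationConfig,
    TRYPTIC_TERMINI,
    accuracy,
    add_noise,
    apply_ptm,
    drop_peaks,
    ideal_spectrum,
    random_peptides,
)


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(n_peptides=1, seed=0, min_length=0)
    with pytest.raises(ValueError):
        SimulationConfig(n_peptides=1, seed=0, ns_ratio=-1)


def test_random_peptides_respect_study_conditions(table):
    cfg = SimulationConfig(n_peptides=200, seed=3)
    peps = random_peptides(cfg, table)
    assert len(peps) == 200
    assert all(5 <= len(p) <= 24 for p in peps)
    assert all(p.sequence[-1] in TRYPTIC_TERMINI for p in peps)
    # reproducible under the seed; empty request gives empty output
    assert [p.sequence for p in random_peptides(cfg, table)] == [
        p.sequence for p in peps
    ]
    assert random_peptides(
        SimulationConfig(n_peptides=0, seed=3), table
    ) == []


def test_ideal_spectrum_ga(table):
    s = ideal_spectrum(Peptide("GA"), table)
    assert s.total_mass == pytest.approx(128.05857, abs=1e-5)
    assert [p.mass for p in s.peaks] == pytest.approx([57.02146, 71.03711])


def test_ideal_spectrum_pairing_and_count(table):
    p = Peptide("GASPVTLK")
    s = ideal_spectrum(p, table)
    assert len(s) <= 2 * (len(p) - 1)
    M = s.total_mass
    masses = [pk.mass for pk in s.peaks]
    for m in masses:
        assert any(abs(m + m2 - M) < 1e-5 for m2 in masses)


def test_add_noise_count_and_group_structure(table):
    cfg = SimulationConfig(n_peptides=1, seed=5, ns_ratio=1.0)
    rng = np.random.default_rng(5)
    s = ideal_spectrum(Peptide("GASPVTLKYEHK"), table)
    noisy = add_noise(s, cfg, table, rng)
    n_real = len(s)
    assert len(noisy) == 2 * n_real  # N/S = noise / real = 1.0
    # zero ratio leaves the spectrum unchanged
    cfg0 = SimulationConfig(n_peptides=1, seed=5, ns_ratio=0.0)
    assert len(add_noise(s, cfg0, table, np.random.default_rng(5))) == n_real


def test_noise_groups_step_by_residue_masses(table):
    """Consecutive noise peaks within a group differ by residue masses."""
    cfg = SimulationConfig(
        n_peptides=1, seed=6, ns_ratio=3.0, noise_group_min=3, noise_group_max=4
    )
    rng = np.random.default_rng(6)
    s = ideal_spectrum(Peptide("GGGGK"), table)
    noisy = add_noise(s, cfg, table, rng)
    real = {round(p.mass, 6) for p in s.peaks}
    noise = sorted(p.mass for p in noisy.peaks if round(p.mass, 6) not in real)
    residues = {round(m, 5) for m in table.residues.values()}
    # groups interleave in mass, so check each noise peak for a partner at
    # exactly one residue step (group members are contiguous residue ladders)
    stepped = sum(
        1
        for a in noise
        if any(round(abs(b - a), 5) in residues for b in noise if b != a)
    )
    assert stepped >= len(noise) * 0.5


def test_dropout(table):
    s = ideal_spectrum(Peptide("GASPVTLK"), table)
    cfg0 = SimulationConfig(n_peptides=1, seed=7, dropout=0.0)
    assert len(drop_peaks(s, cfg0, np.random.default_rng(7))) == len(s)
    cfg1 = SimulationConfig(n_peptides=1, seed=7, dropout=1.0)
    assert len(drop_peaks(s, cfg1, np.random.default_rng(7))) == 0


def test_apply_ptm_shifts_downstream_prefixes(table, mods):
    cfg = SimulationConfig(n_peptides=1, seed=8, ptm_probability=1.0)
    p = Peptide("GMGGK")
    modified = apply_ptm(p, cfg, mods, np.random.default_rng(8))
    assert modified.mods
    (pos, label) = next(iter(modified.mods.items()))
    delta = mods.by_label(label).delta
    plain = prefix_masses(p, table)
    shifted = prefix_masses(modified, table, mods)
    for i in range(len(plain)):
        expected = plain[i] + (delta if i > pos else 0.0)
        assert shifted[i] == pytest.approx(expected, abs=1e-9)


# ---------------------------------------------------------------------------
# accuracy metric
# ---------------------------------------------------------------------------

def _edge_elements(seq, table, start=0.0):
    els = []
    pos = start
    for c in seq:
        m = table.mass(c)
        els.append(ResultElement("edge", pos, pos + m, labels=(c,)))
        pos += m
    return els, pos


def test_accuracy_identical_sequence(table):
    els, M = _edge_elements("GAVK", table)
    res = SequencingResult(tuple(els), M)
    assert accuracy(res, Peptide("GAVK"), table) == 100.0


def test_accuracy_reversed_reading_counts(table):
    els, M = _edge_elements("KVAG", table)
    res = SequencingResult(tuple(els), M)
    assert accuracy(res, Peptide("GAVK"), table) == 100.0


def test_accuracy_leucine_isoleucine_equivalent(table):
    els, M = _edge_elements("GIK", table)
    els[1] = ResultElement("edge", els[1].start, els[1].end, labels=("I", "L"))
    res = SequencingResult(tuple(els), M)
    assert accuracy(res, Peptide("GLK"), table) == 100.0


def test_accuracy_gap_fill_matches_as_multiset(table):
    # truth GAVK; called G [VA] K: order inside the gap is unknown but the
    # composition matches
    g_end = table.mass("G")
    gap_end = g_end + table.mass("A") + table.mass("V")
    M = gap_end + table.mass("K")
    fill = GapFill((("A", None), ("V", None)), "exact", gap_end - g_end, 0.0)
    els = (
        ResultElement("edge", 0.0, g_end, labels=("G",)),
        ResultElement("gap", g_end, gap_end, fill=fill, delta=gap_end - g_end),
        ResultElement("edge", gap_end, M, labels=("K",)),
    )
    res = SequencingResult(els, M)
    assert accuracy(res, Peptide("GAVK"), table) == 100.0


def test_accuracy_unresolved_gap_scores_zero_for_span(table):
    g_end = table.mass("G")
    gap_end = g_end + table.mass("A") + table.mass("V")
    M = gap_end + table.mass("K")
    els = (
        ResultElement("edge", 0.0, g_end, labels=("G",)),
        ResultElement("gap", g_end, gap_end, fill=None, delta=gap_end - g_end),
        ResultElement("edge", gap_end, M, labels=("K",)),
    )
    res = SequencingResult(els, M)
    assert accuracy(res, Peptide("GAVK"), table) == pytest.approx(50.0)


def test_accuracy_wrong_calls_score_partial(table):
    els, M = _edge_elements("GGK", table)
    res = SequencingResult(tuple(els), M)
    # truth GAK: masses disagree at position 2, so only G and K can match
    assert accuracy(res, Peptide("GAK"), table) < 100.0
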