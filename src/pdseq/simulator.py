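"""Synthetic spectra and the sequencing accuracy metric.

The generator emulates fully tryptic digestion products: random residue
strings of length 5-24 ending in K or R, with uniform residue usage.  Ideal
spectra place a unit-intensity peak at every proper prefix residue sum and
its complement (the b/y ladder); grouped noise peaks start at a uniform
random mass and extend by one to three random residue-mass steps, so that
consecutive noise peaks within a group differ by single residue masses;
dropout removes real peaks independently; a PTM shifts all downstream prefix
masses by its delta.

The accuracy of a sequencing result is the percentage of the true residues
that are correctly recovered, scored against both reading orientations (the
extended spectrum graph cannot distinguish a peptide from its reversal) and
taking the better one.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .chem import (
    ModificationTable,
    Peptide,
    ResidueMassTable,
    peptide_residue_sum,
    prefix_masses,
)
from .gap_filler import SequencingResult
from .spectra import Peak, Spectrum


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for simulated spectra.

    ``ns_ratio`` is the noise/signal ratio: the number of injected noise
    peaks divided by the number of real peaks.  Noise groups contain
    ``noise_group_min``..``noise_group_max`` peaks (i.e. 1-3 residue-mass
    steps from a uniform random start).  ``tolerance`` is the mass tolerance
    used throughout the simulated pipeline; simulated masses are exact, so it
    is tight.
    """

    n_peptides: int
    seed: int
    min_length: int = 5
    max_length: int = 24
    ns_ratio: float = 0.0
    noise_group_min: int = 2
    noise_group_max: int = 4
    dropout: float = 0.0
    ptm_probability: float = 0.0
    tolerance: float = 0.001

    def __post_init__(self) -> None:
        if not 1 <= self.min_length <= self.max_length:
            raise ValueError("invalid length bounds")
        if self.ns_ratio < 0:
            raise ValueError("ns_ratio must be non-negative")
        if not 2 <= self.noise_group_min <= self.noise_group_max:
            raise ValueError("noise groups need at least 2 peaks")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


TRYPTIC_TERMINI = ("K", "R")


def random_peptides(
    cfg: SimulationConfig, table: ResidueMassTable
) -> list[Peptide]:
    """Random tryptic-like peptides: uniform residues, K/R C-terminus."""
    rng = cfg.rng()
    codes = sorted(table.residues)
    peptides = []
    for _ in range(cfg.n_peptides):
        n = int(rng.integers(cfg.min_length, cfg.max_length + 1))
        body = [codes[int(i)] for i in rng.integers(0, len(codes), size=n - 1)]
        last = TRYPTIC_TERMINI[int(rng.integers(2))]
        peptides.append(Peptide("".join(body) + last))
    return peptides


def ideal_spectrum(
    p: Peptide, table: ResidueMassTable, mods: ModificationTable | None = None
) -> Spectrum:
    """Noiseless b/y ladder: every proper prefix sum and its complement."""
    sums = prefix_masses(p, table, mods)
    M = sums[-1]
    masses = set()
    for s in sums[1:-1]:
        masses.add(round(s, 6))
        masses.add(round(M - s, 6))
    peaks = tuple(Peak(m, 1.0) for m in sorted(masses))
    return Spectrum(peaks, M, {"peptide": p.sequence})


def add_noise(
    s: Spectrum, cfg: SimulationConfig, table: ResidueMassTable,
    rng: np.random.Generator,
) -> Spectrum:
    """Inject grouped noise peaks until noise/signal reaches ``ns_ratio``.

    Groups start at a uniform random mass in (0, M) and extend by 1-3 random
    residue-mass steps; members outside (0, M) are clipped away.
    """
    n_noise = round(cfg.ns_ratio * len(s.peaks))
    masses = sorted(table.residues.values())
    M = s.total_mass
    noise: list[Peak] = []
    while len(noise) < n_noise:
        group_size = int(
            rng.integers(cfg.noise_group_min, cfg.noise_group_max + 1)
        )
        m = float(rng.uniform(0, M))
        group = [m]
        for _ in range(group_size - 1):
            m = m + masses[int(rng.integers(len(masses)))]
            if not 0 < m < M:
                break
            group.append(m)
        for gm in group:
            if len(noise) < n_noise and 0 < gm < M:
                noise.append(Peak(gm, 1.0))
    return s.replace_peaks(list(s.peaks) + noise)


def drop_peaks(
    s: Spectrum, cfg: SimulationConfig, rng: np.random.Generator
) -> Spectrum:
    """Independent Bernoulli dropout of peaks."""
    if cfg.dropout <= 0:
        return s
    kept = [p for p in s.peaks if rng.random() >= cfg.dropout]
    return s.replace_peaks(kept)


def apply_ptm(
    p: Peptide, cfg: SimulationConfig, mods: ModificationTable,
    rng: np.random.Generator,
) -> Peptide:
    """With probability ``ptm_probability``, modify one random eligible residue."""
    if rng.random() >= cfg.ptm_probability:
        return p
    eligible = [
        (i, mod)
        for i, code in enumerate(p.sequence)
        for mod in mods.for_target(code)
        if i not in p.mods
    ]
    if not eligible:
        return p
    i, mod = eligible[int(rng.integers(len(eligible)))]
    return replace(p, mods={**p.mods, i: mod.label})


def simulate_spectrum(
    p: Peptide,
    cfg: SimulationConfig,
    table: ResidueMassTable,
    mods: ModificationTable | None,
    rng: np.random.Generator,
) -> Spectrum:
    """Ideal ladder plus configured noise and dropout."""
    s = ideal_spectrum(p, table, mods)
    s = drop_peaks(s, cfg, rng)
    if cfg.ns_ratio > 0:
        s = add_noise(s, cfg, table, rng)
    return s


# ---------------------------------------------------------------------------
# accuracy
# ---------------------------------------------------------------------------

def _score_against(
    predicted: SequencingResult,
    truth: Peptide,
    table: ResidueMassTable,
    mods: ModificationTable | None,
    tol: float,
) -> int:
    sums = prefix_masses(truth, table, mods)
    truth_items = []
    for i, code in enumerate(truth.sequence):
        truth_items.append((sums[i], sums[i + 1], code, truth.mods.get(i)))

    matched = 0
    for el in predicted.elements:
        # true residues wholly inside the element's mass interval
        inside = [
            (c, m)
            for a, b, c, m in truth_items
            if a >= el.start - tol and b <= el.end + tol
        ]
        if el.kind == "edge":
            if len(inside) == 1:
                code, mod = inside[0]
                if mod is None and any(
                    abs(table.mass(lbl) - table.mass(code)) <= tol
                    for lbl in el.labels
                    if lbl in table
                ):
                    matched += 1
            elif len(inside) >= 2:
                # a single edge spanning several true residues is correct only
                # if its call is mass-identical to the spanned composition
                span_mass = sum(
                    table.mass(c) + (0.0 if m is None else 0.0) for c, m in inside
                )
                if any(
                    lbl in table and abs(table.mass(lbl) - span_mass) <= 2 * tol
                    for lbl in el.labels
                ) and all(m is None for _, m in inside):
                    matched += len(inside)
        else:  # gap fill: multiset comparison over the spanned residues
            if el.fill is None:
                continue
            want: dict[tuple[str, str | None], int] = {}
            for c, m in inside:
                want[(c, m)] = want.get((c, m), 0) + 1
            for c, m in el.fill.residues:
                key = (c, m)
                if want.get(key, 0) > 0:
                    want[key] -= 1
                    matched += 1
                else:
                    # mass-identical residue substitution (L/I)
                    for (wc, wm), cnt in want.items():
                        if (
                            cnt > 0
                            and wm == m
                            and abs(table.mass(wc) - table.mass(c)) <= tol
                        ):
                            want[(wc, wm)] -= 1
                            matched += 1
                            break
    return matched


def _reversed_result(
    predicted: SequencingResult, total_mass: float
) -> SequencingResult:
    """The same calls read in the opposite orientation (masses mirrored)."""
    els = []
    for el in reversed(predicted.elements):
        els.append(
            replace(el, start=total_mass - el.end, end=total_mass - el.start)
        )
    return SequencingResult(tuple(els), total_mass, orientation="descending")


def accuracy(
    predicted: SequencingResult,
    truth: Peptide,
    table: ResidueMassTable,
    mods: ModificationTable | None = None,
    tol: float = 0.001,
) -> float:
    """Percentage of true residues correctly recovered, better orientation.

    Edge calls match positionally (mass-identical alternatives such as L/I
    count as correct); gap fills match as multisets against the true residues
    spanned by the gap interval.
    """
    fwd = _score_against(predicted, truth, table, mods, tol)
    rev = _score_against(
        _reversed_result(predicted, predicted.total_mass), truth, table, mods, tol
    )
    return 100.0 * max(fwd, rev) / len(truth)
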