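"""Residue and modification mass bookkeeping.

All other modules work in a single abstract mass coordinate system: a peptide
of residues ``r_1 .. r_n`` has total mass ``M = sum(residue masses)``, a prefix
(b-type) fragment sits at the prefix residue sum, and the complementary suffix
(y-type) fragment sits at ``M - prefix``.  Conversion from observed singly
charged ion m/z values into this coordinate system lives in
:mod:`pdseq.spectra`; everything downstream of it is offset-free.

Masses are monoisotopic and expressed in daltons throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import yaml

#: Monoisotopic mass of a proton (charge carrier), Da.
PROTON = 1.00728

#: Monoisotopic mass of water, Da (difference between a peptide's neutral
#: mass and the sum of its residue masses).
WATER = 18.01056

#: Standard monoisotopic residue masses, Da.
STANDARD_RESIDUE_MASSES: dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}


class UnknownResidueError(KeyError):
    """Raised when a residue code is not present in the active mass table."""


@dataclass(frozen=True)
class ResidueMassTable:
    """A table of one-letter residue codes and their monoisotopic masses.

    Parameters
    ----------
    residues
        Mapping from one-letter code to residue mass in Da.  All masses must
        be strictly positive.

    Notes
    -----
    Two well known near-coincidences are recorded explicitly rather than
    silently tolerated: ``G+G ~ N`` (114.04292 vs 114.04293 Da) and
    ``G+A ~ Q`` (128.05857 vs 128.05858 Da).  They matter both for gap
    filling (a 114 Da gap legitimately has two readings) and for the premise
    that a single residue mass is never a sum of other residue masses, which
    only holds once these pairs are excluded.
    """

    residues: Mapping[str, float]

    #: (composite residues, coincident single residue) pairs known to collide
    #: within ~1e-5 Da in the standard table.
    KNOWN_COINCIDENCES = ((("G", "G"), "N"), (("G", "A"), "Q"))

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("residue table must not be empty")
        for code, mass in self.residues.items():
            if not mass > 0:
                raise ValueError(f"residue {code!r} has non-positive mass {mass}")

    @property
    def min_residue_mass(self) -> float:
        return min(self.residues.values())

    @property
    def max_residue_mass(self) -> float:
        return max(self.residues.values())

    def mass(self, code: str) -> float:
        try:
            return self.residues[code]
        except KeyError:
            raise UnknownResidueError(code) from None

    def __contains__(self, code: str) -> bool:
        return code in self.residues

    def matches(self, delta: float, tol: float) -> tuple[str, ...]:
        """All residue codes whose mass is within ``tol`` of ``delta``."""
        if tol < 0:
            raise ValueError("tolerance must be non-negative")
        return tuple(
            sorted(c for c, m in self.residues.items() if abs(m - delta) <= tol)
        )

    @classmethod
    def standard(cls) -> "ResidueMassTable":
        return cls(dict(STANDARD_RESIDUE_MASSES))

    @classmethod
    def from_file(cls, path) -> "ResidueMassTable":
        """Load a table from a YAML/key-value file of ``code: mass`` entries."""
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls({str(k): float(v) for k, v in data.items()})


@dataclass(frozen=True)
class Modification:
    """A post-translational modification: a mass delta on a target residue."""

    target: str
    delta: float
    label: str

    def __post_init__(self) -> None:
        if self.delta == 0:
            raise ValueError(f"modification {self.label!r} has zero delta")


@dataclass(frozen=True)
class ModificationTable:
    mods: tuple[Modification, ...]

    def __post_init__(self) -> None:
        labels = [m.label for m in self.mods]
        if len(labels) != len(set(labels)):
            raise ValueError("modification labels must be unique")

    def __iter__(self):
        return iter(self.mods)

    def __len__(self) -> int:
        return len(self.mods)

    def by_label(self, label: str) -> Modification:
        for m in self.mods:
            if m.label == label:
                return m
        raise KeyError(label)

    def for_target(self, code: str) -> tuple[Modification, ...]:
        return tuple(m for m in self.mods if m.target == code)

    @classmethod
    def default(cls) -> "ModificationTable":
        """Oxidation, phosphorylation and deamidation with standard deltas."""
        return cls(
            (
                Modification("M", 15.99491, "Ox(M)"),
                Modification("S", 79.96633, "Phos(S)"),
                Modification("T", 79.96633, "Phos(T)"),
                Modification("Y", 79.96633, "Phos(Y)"),
                Modification("N", 0.98402, "Deam(N)"),
                Modification("Q", 0.98402, "Deam(Q)"),
            )
        )

    @classmethod
    def empty(cls) -> "ModificationTable":
        return cls(())

    @classmethod
    def from_file(cls, path) -> "ModificationTable":
        """Load from a YAML list of ``{target, delta, label}`` records."""
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(
            tuple(
                Modification(str(d["target"]), float(d["delta"]), str(d["label"]))
                for d in data
            )
        )


@dataclass(frozen=True)
class Peptide:
    """An ordered residue sequence with optional per-position modifications.

    ``mods`` maps 0-based position to a modification label from the active
    :class:`ModificationTable`.
    """

    sequence: str
    mods: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError("peptide must contain at least one residue")
        for pos in self.mods:
            if not 0 <= pos < len(self.sequence):
                raise ValueError(f"modification position {pos} out of range")

    def __len__(self) -> int:
        return len(self.sequence)

    def reversed(self) -> "Peptide":
        n = len(self.sequence)
        return Peptide(
            self.sequence[::-1], {n - 1 - p: lbl for p, lbl in self.mods.items()}
        )


def residue_mass(code: str, table: ResidueMassTable) -> float:
    """Monoisotopic residue mass of ``code``; raises on unknown codes."""
    return table.mass(code)


def peptide_residue_sum(
    p: Peptide, table: ResidueMassTable, mods: ModificationTable | None = None
) -> float:
    """Total abstract mass M of a peptide: residue masses plus mod deltas."""
    total = sum(table.mass(c) for c in p.sequence)
    if p.mods:
        if mods is None:
            raise ValueError("peptide carries modifications but no mod table given")
        total += sum(mods.by_label(lbl).delta for lbl in p.mods.values())
    return total


def prefix_masses(
    p: Peptide, table: ResidueMassTable, mods: ModificationTable | None = None
) -> list[float]:
    """Cumulative residue sums ``s_0=0, s_1, ..., s_n=M`` (mods included)."""
    sums = [0.0]
    for i, c in enumerate(p.sequence):
        m = table.mass(c)
        if i in p.mods:
            if mods is None:
                raise ValueError("peptide carries modifications but no mod table given")
            m += mods.by_label(p.mods[i]).delta
        sums.append(sums[-1] + m)
    return sums


def is_residue_mass(
    delta: float, table: ResidueMassTable, tol: float
) -> tuple[str, ...]:
    """Residue codes whose mass matches ``delta`` within ``tol`` (may be empty)."""
    return table.matches(delta, tol)


def audit_sum_coincidences(
    table: ResidueMassTable,
    tol: float = 0.01,
    max_summands: int = 3,
    exclude: Iterable[str] = ("N", "Q"),
) -> list[tuple[str, tuple[str, ...]]]:
    """Find residues whose mass equals a sum of >=2 residue masses within ``tol``.

    Returns offending ``(residue, summands)`` pairs not covered by ``exclude``.
    Used to audit the premise behind treating every induced residue-difference
    edge as a genuine single-residue step.
    """
    codes = sorted(table.residues)
    offenders: list[tuple[str, tuple[str, ...]]] = []

    def rec(start: int, count: int, total: float, picked: list[str]) -> None:
        if count >= 2:
            for c in codes:
                if c in exclude or c in picked:
                    continue
                if abs(table.mass(c) - total) <= tol:
                    offenders.append((c, tuple(picked)))
        if count == max_summands:
            return
        for i in range(start, len(codes)):
            rec(i, count + 1, total + table.mass(codes[i]), picked + [codes[i]])

    rec(0, 0, 0.0, [])
    # dedupe (same residue reachable via permuted multisets)
    seen = set()
    out = []
    for c, s in offenders:
        key = (c, tuple(sorted(s)))
        if key not in seen:
            seen.add(key)
            out.append((c, tuple(sorted(s))))
    return out


def format_call(codes: Sequence[str]) -> str:
    """Render an ambiguous residue call, collapsing mass-identical codes.

    A single code renders as itself; Leu/Ile renders as ``L/I``; any other
    ambiguous set joins its codes with ``/``.
    """
    uniq = sorted(set(codes))
    if len(uniq) == 1:
        return uniq[0]
    if set(uniq) == {"I", "L"}:
        return "L/I"
    return "/".join(uniq)
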