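"""Gap resolution: turn a partial path into a full sequencing result.

Each gap between consecutive segments is a mass delta that must be explained
as a multiset of residues (missing peaks) or, failing that, residues plus at
most one modified residue (a PTM).  Compositions are found by subset-sum over
the residue mass table; candidates are ranked by fewer residues, then fewer
modifications, then smaller absolute mass error.  A gap with no explanation
is reported unresolved, carrying its delta.

Gap fills are multisets: the subset-sum determines composition, not order,
and they are rendered in brackets to say so.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from typing import Sequence

from .chem import ModificationTable, Modification, ResidueMassTable, format_call
from .dp_solver import AntisymmetricPartialPath
from .graph_builder import ExtendedSpectrumGraph

EXACT = "exact"
MODIFIED = "modified"
UNRESOLVED = "unresolved"


@dataclass(frozen=True)
class Gap:
    left: int
    right: int
    delta: float

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("gap delta must be positive")


@dataclass(frozen=True)
class GapFill:
    """A candidate composition for one gap.

    ``residues`` is a sorted tuple of ``(code, mod_label_or_None)`` pairs.
    """

    residues: tuple[tuple[str, str | None], ...]
    status: str
    mass: float
    error: float

    @property
    def n_mods(self) -> int:
        return sum(1 for _, m in self.residues if m is not None)

    def render(self) -> str:
        parts = []
        for code, mod in self.residues:
            parts.append(code if mod is None else f"{code}+{mod}")
        return "".join(parts)


def find_gaps(p: AntisymmetricPartialPath, g: ExtendedSpectrumGraph) -> list[Gap]:
    """One gap per consecutive segment pair, ascending in mass."""
    gaps = []
    for seg_a, seg_b in zip(p.segments, p.segments[1:]):
        left, right = seg_a[-1], seg_b[0]
        gaps.append(Gap(left, right, g.mass(right) - g.mass(left)))
    return gaps


def _multisets(
    masses: Sequence[tuple[str, float]],
    delta: float,
    tol: float,
    max_residues: int,
) -> list[tuple[tuple[str, ...], float]]:
    """All residue multisets (codes sorted) whose masses sum to delta±tol."""
    items = sorted(masses, key=lambda cm: cm[1])
    if not items:
        return []
    mmin = items[0][1]
    mmax = items[-1][1]
    out: list[tuple[tuple[str, ...], float]] = []

    def rec(start: int, count: int, total: float, picked: list[str]) -> None:
        if abs(total - delta) <= tol and count >= 1:
            out.append((tuple(picked), total))
        if count == max_residues:
            return
        remaining_min = 1
        for i in range(start, len(items)):
            code, m = items[i]
            t = total + m
            if t > delta + tol:
                break
            # even all-max fills cannot reach the window
            if t + (max_residues - count - remaining_min) * mmax < delta - tol:
                continue
            rec(i, count + 1, t, picked + [code])

    rec(0, 0, 0.0, [])
    return out


def subset_fill(
    delta: float,
    table: ResidueMassTable,
    mods: ModificationTable | None = None,
    tol: float = 0.02,
    max_residues: int | None = None,
    max_mods: int = 1,
) -> list[GapFill]:
    """Ranked compositions for a mass gap.

    Unmodified compositions are searched first; modified ones (at most
    ``max_mods`` modified residues, default one) are considered only when no
    unmodified composition exists.  The default residue budget is
    ``ceil(delta / min residue mass)``.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    if max_residues is None:
        max_residues = ceil(delta / table.min_residue_mass)
    plain = [(c, m) for c, m in table.residues.items()]

    fills: list[GapFill] = []
    for codes, total in _multisets(plain, delta, tol, max_residues):
        residues = tuple(sorted((c, None) for c in codes))
        fills.append(GapFill(residues, EXACT, total, abs(total - delta)))

    if not fills and mods is not None and max_mods >= 1:
        for mod in mods:
            try:
                base = table.mass(mod.target)
            except KeyError:
                continue
            mmass = base + mod.delta
            rest = delta - mmass
            if abs(rest) <= tol:
                residues = ((mod.target, mod.label),)
                fills.append(GapFill(residues, MODIFIED, mmass, abs(mmass - delta)))
                continue
            if rest <= 0:
                continue
            for codes, total in _multisets(
                plain, rest, tol, max_residues - 1
            ):
                residues = tuple(
                    sorted([(c, None) for c in codes] + [(mod.target, mod.label)])
                )
                fills.append(
                    GapFill(
                        residues,
                        MODIFIED,
                        total + mmass,
                        abs(total + mmass - delta),
                    )
                )

    fills.sort(key=lambda f: (len(f.residues), f.n_mods, f.error, f.residues))
    # deduplicate identical compositions reached via different branches
    seen = set()
    unique = []
    for f in fills:
        if f.residues not in seen:
            seen.add(f.residues)
            unique.append(f)
    return unique


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResultElement:
    """One position of a sequencing result: an edge call or a gap fill."""

    kind: str  # "edge" | "gap"
    start: float
    end: float
    labels: tuple[str, ...] = ()  # residue alternatives for edge calls
    fill: GapFill | None = None
    delta: float | None = None

    @property
    def mass(self) -> float:
        return self.end - self.start

    def render(self) -> str:
        if self.kind == "edge":
            return format_call(self.labels)
        if self.fill is None:
            return f"[Δ{self.delta:.3f}]"
        return f"[{self.fill.render()}]"


@dataclass(frozen=True)
class SequencingResult:
    elements: tuple[ResultElement, ...]
    total_mass: float
    orientation: str = "ascending"

    def __str__(self) -> str:
        return "".join(e.render() for e in self.elements)

    @property
    def sequence(self) -> str:
        return str(self)

    def mass_error(self) -> float:
        return abs(sum(e.mass for e in self.elements) - self.total_mass)

    def to_record(self) -> dict:
        """JSON-serialisable structured form."""
        els = []
        for e in self.elements:
            d = {
                "kind": e.kind,
                "start": round(e.start, 5),
                "end": round(e.end, 5),
                "call": e.render(),
            }
            if e.kind == "edge":
                d["alternatives"] = sorted(e.labels)
            elif e.fill is not None:
                d["residues"] = [
                    {"code": c, "mod": m} for c, m in e.fill.residues
                ]
                d["status"] = e.fill.status
            else:
                d["status"] = UNRESOLVED
                d["delta"] = round(e.delta, 5)
            els.append(d)
        return {
            "sequence": str(self),
            "total_mass": round(self.total_mass, 5),
            "elements": els,
        }


def assemble(
    p: AntisymmetricPartialPath,
    fills: Sequence[GapFill | None],
    g: ExtendedSpectrumGraph,
    table: ResidueMassTable,
) -> SequencingResult:
    """Concatenate per-edge residue calls and bracketed gap fills in mass order.

    ``fills`` holds one chosen fill (or None for unresolved) per gap, in the
    order produced by :func:`find_gaps`.
    """
    gaps = find_gaps(p, g)
    if len(fills) != len(gaps):
        raise ValueError("one fill decision required per gap")
    elements: list[ResultElement] = []
    for i, seg in enumerate(p.segments):
        for u, w in zip(seg, seg[1:]):
            elements.append(
                ResultElement(
                    "edge",
                    g.mass(u),
                    g.mass(w),
                    labels=tuple(sorted(g.labels(u, w))),
                )
            )
        if i < len(gaps):
            gap = gaps[i]
            fill = fills[i]
            elements.append(
                ResultElement(
                    "gap",
                    g.mass(gap.left),
                    g.mass(gap.right),
                    fill=fill,
                    delta=gap.delta,
                )
            )
    return SequencingResult(tuple(elements), g.total_mass)


def resolve(
    p: AntisymmetricPartialPath,
    g: ExtendedSpectrumGraph,
    table: ResidueMassTable,
    mods: ModificationTable | None = None,
    tol: float = 0.02,
) -> SequencingResult:
    """Find gaps, pick the top-ranked fill for each, and assemble."""
    gaps = find_gaps(p, g)
    fills: list[GapFill | None] = []
    for gap in gaps:
        candidates = subset_fill(gap.delta, table, mods, tol=tol)
        fills.append(candidates[0] if candidates else None)
    return assemble(p, fills, g, table)
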