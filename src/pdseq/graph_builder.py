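"""Construction of the extended spectrum graph.

Vertices are the spectrum's peaks plus a source at mass 0 and a sink at the
total mass M.  A directed edge joins two vertices whose mass difference
matches at least one residue mass within tolerance (labelled with every
matching residue, so Leu/Ile and similar ambiguities surface at call time).
A non-directed complement edge joins every pair of peaks whose masses sum to
M within tolerance; complement edges never touch the source or the sink, and
a peak at M/2 is not paired with itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .chem import ResidueMassTable, ModificationTable
from .spectra import Spectrum

SOURCE = "source"
SINK = "sink"
PEAK = "peak"


@dataclass(frozen=True)
class SpectrumVertex:
    id: int
    mass: float
    kind: str = PEAK


@dataclass
class ExtendedSpectrumGraph:
    """Mixed graph over spectrum vertices.

    ``directed_edges`` maps ordered vertex-id pairs (u, v) with
    mass(v) > mass(u) to the frozenset of matching residue labels; a label is
    a residue code, or ``code+label`` strings for modified-residue edges when
    those are enabled.  ``complement_edges`` is a set of frozenset pairs.
    Vertex ids are assigned in ascending mass order: 0 is the source and
    ``len(vertices)-1`` the sink.
    """

    vertices: list[SpectrumVertex]
    directed_edges: dict[tuple[int, int], frozenset[str]]
    complement_edges: set[frozenset[int]]
    total_mass: float
    _out: dict[int, list[int]] = field(default_factory=dict, repr=False)
    _in: dict[int, list[int]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._out = {v.id: [] for v in self.vertices}
        self._in = {v.id: [] for v in self.vertices}
        for (u, v) in self.directed_edges:
            self._out[u].append(v)
            self._in[v].append(u)

    # -- basic accessors -------------------------------------------------
    @property
    def source(self) -> int:
        return 0

    @property
    def sink(self) -> int:
        return len(self.vertices) - 1

    def mass(self, vid: int) -> float:
        return self.vertices[vid].mass

    def out_neighbors(self, vid: int) -> list[int]:
        return self._out[vid]

    def in_neighbors(self, vid: int) -> list[int]:
        return self._in[vid]

    def has_edge(self, u: int, v: int) -> bool:
        return (u, v) in self.directed_edges

    def labels(self, u: int, v: int) -> frozenset[str]:
        return self.directed_edges[(u, v)]

    def complement_partners(self, vid: int) -> list[int]:
        out = []
        for pair in self.complement_edges:
            if vid in pair:
                (other,) = pair - {vid}
                out.append(other)
        return out

    def undirected_adjacency(self) -> dict[int, set[int]]:
        """Adjacency of the mixed graph with edge directions dropped."""
        adj: dict[int, set[int]] = {v.id: set() for v in self.vertices}
        for (u, v) in self.directed_edges:
            adj[u].add(v)
            adj[v].add(u)
        for pair in self.complement_edges:
            a, b = tuple(pair)
            adj[a].add(b)
            adj[b].add(a)
        return adj

    def span(self, u: int, v: int) -> range:
        """Vertex ids with mass strictly between u and v (ids are mass-sorted)."""
        lo, hi = (u, v) if u < v else (v, u)
        return range(lo + 1, hi)

    def spell(self, path: Iterable[int]) -> list[frozenset[str]]:
        """Residue label sets along a directed vertex path."""
        path = list(path)
        return [self.labels(u, v) for u, v in zip(path, path[1:])]

    def to_edgelist(self) -> str:
        """Plain-text dump: one edge per line with a type tag."""
        lines = []
        for (u, v), labels in sorted(self.directed_edges.items()):
            lines.append(f"D\t{u}\t{v}\t{','.join(sorted(labels))}")
        for pair in sorted(self.complement_edges, key=sorted):
            a, b = sorted(pair)
            lines.append(f"C\t{a}\t{b}")
        return "\n".join(lines)


def build_graph(
    s: Spectrum,
    table: ResidueMassTable,
    tol: float,
    mods: ModificationTable | None = None,
    allow_modified_edges: bool = False,
) -> ExtendedSpectrumGraph:
    """Build the extended spectrum graph of a preprocessed spectrum.

    With ``allow_modified_edges`` a directed edge is also created when the
    mass gap matches residue+modification for a single modified residue
    (labelled ``code+label``); by default modifications are left to the gap
    filler.
    """
    if s.total_mass <= 0:
        raise ValueError("total mass must be positive")
    M = s.total_mass
    masses = [0.0] + [p.mass for p in s.peaks] + [M]
    vertices = [
        SpectrumVertex(i, m, SOURCE if i == 0 else SINK if i == len(masses) - 1 else PEAK)
        for i, m in enumerate(masses)
    ]

    deltas: list[tuple[float, str]] = [(m, c) for c, m in table.residues.items()]
    if allow_modified_edges and mods is not None:
        deltas += [
            (table.mass(m.target) + m.delta, f"{m.target}+{m.label}") for m in mods
        ]
    max_delta = max(d for d, _ in deltas)

    directed: dict[tuple[int, int], frozenset[str]] = {}
    n = len(vertices)
    for i in range(n):
        mi = masses[i]
        for j in range(i + 1, n):
            gap = masses[j] - mi
            if gap > max_delta + tol:
                break
            labels = frozenset(c for d, c in deltas if abs(d - gap) <= tol)
            if labels:
                directed[(i, j)] = labels

    complement: set[frozenset[int]] = set()
    for i in range(1, n - 1):
        for j in range(i + 1, n - 1):
            total = masses[i] + masses[j]
            if total > M + tol:
                break
            if abs(total - M) <= tol:
                complement.add(frozenset((i, j)))

    return ExtendedSpectrumGraph(vertices, directed, complement, M)


def graph_stats(g: ExtendedSpectrumGraph) -> dict:
    n = len(g.vertices)
    nd = len(g.directed_edges)
    nc = len(g.complement_edges)
    possible = n * (n - 1) / 2
    return {
        "n_vertices": n,
        "n_directed_edges": nd,
        "n_complement_edges": nc,
        "density": (nd + nc) / possible if possible else 0.0,
    }
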