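"""Longest antisymmetric partial path via dynamic programming over a path
decomposition.

Model
-----
An antisymmetric partial path is an ordered set of vertex-disjoint directed
path segments whose mass intervals are pairwise disjoint and ascending, with
no two vertices anywhere in the structure joined by a complement edge; the
first segment starts at the source, the last ends at the sink, and the length
is the total number of edges.  Because every directed edge strictly increases
mass, such a structure is equivalent to a *chain*: sort the selected vertices
by mass; each consecutive pair is either joined by a used directed edge
(within a segment) or is a gap (between segments).  The length is therefore
the number of mass-consecutive selected pairs joined by a directed edge.

This chain reading is also why raw induced-edge counting would be wrong: with
real residue masses an edge can span another selected vertex (the classic
G+G vs N coincidence creates an 'N' edge across a selected glycine peak), and
such an edge is not part of any segment.  The DP counts an edge exactly once,
at the first bag that contains the edge's *closed span* (both endpoints plus
every selectable vertex with mass strictly inside), and only when both
endpoints are selected and nothing inside the span is.  Span-closed
decompositions (see :mod:`pdseq.path_decomposition`) guarantee that this
decision is final: every vertex that could ever sit inside the span is
already introduced when the edge is decided, so later selections cannot
invalidate a counted edge.

Each table entry is keyed by the selection status of the bag's vertices and
carries the furthest vertex reached from the source (the ``L`` field, or
ELSEWHERE once that vertex has been forgotten), the best length, and — for
tie-breaking and trace-back — the full selected set so far.  Entries agreeing
on the bag selection are merged keeping the best (longest, then fewest
selected vertices, then lexicographically earliest mass sequence): future
length increments depend only on bag-visible selections, so the merge is
exact.  Source and sink sit in every bag with their selection bits forced to
one, so a table holds at most ``2**(p-2) * (p+1)`` entries for a bag of size
``p``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .graph_builder import ExtendedSpectrumGraph
from .path_decomposition import (
    PathDecomposition,
    augment_source_sink,
    ensure_span_closed,
    is_span_closed,
    selectable_vertices,
)

#: Sentinel: the furthest vertex reached from the source is not in the bag.
ELSEWHERE = -1


@dataclass(frozen=True)
class AntisymmetricPartialPath:
    """Ordered, disjoint, non-interleaving directed path segments."""

    segments: tuple[tuple[int, ...], ...]
    total_length: int
    diagnostics: dict = field(default_factory=dict, compare=False)

    @property
    def selected(self) -> tuple[int, ...]:
        return tuple(v for seg in self.segments for v in seg)


@dataclass(frozen=True)
class DPEntry:
    sel: frozenset[int]
    L: int
    length: int
    nsel: int
    selected: frozenset[int]


@dataclass
class DPTable:
    node: int
    bag: frozenset[int]
    entries: dict[tuple[frozenset[int], int], DPEntry]

    def size_bound(self) -> int:
        p = len(self.bag)
        return 2 ** max(p - 2, 0) * (p + 1)

    def check_size(self) -> bool:
        return len(self.entries) <= self.size_bound()

    def dump(self) -> str:
        lines = []
        order = sorted(self.bag)
        for e in sorted(
            self.entries.values(), key=lambda e: (-e.length, sorted(e.sel))
        ):
            bits = "".join("1" if v in e.sel else "0" for v in order)
            lfield = "·" if e.L == ELSEWHERE else str(e.L)
            lines.append(f"sel={bits} L={lfield} len={e.length}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# internal mask machinery
# ---------------------------------------------------------------------------

def _next_selected(chosen: int, after: int) -> int | None:
    m = chosen >> (after + 1)
    if not m:
        return None
    return after + 1 + ((m & -m).bit_length() - 1)


def _lex_key(chosen: int) -> tuple[int, ...]:
    out = []
    m = chosen
    while m:
        low = m & -m
        out.append(low.bit_length() - 1)
        m ^= low
    return tuple(out)


def _better(a: tuple, b: tuple) -> bool:
    """True if entry tuple a = (length, nsel, chosen, L) beats b."""
    if a[0] != b[0]:
        return a[0] > b[0]
    if a[1] != b[1]:
        return a[1] < b[1]
    if a[2] != b[2]:
        return _lex_key(a[2]) < _lex_key(b[2])
    return False


def _mask(vs) -> int:
    m = 0
    for v in vs:
        m |= 1 << v
    return m


class _Solver:
    """Streaming left-to-right table filler over a bag sequence.

    With ``strict=True`` every directed edge must have a bag containing its
    closed span and every complement pair a common bag (guaranteed after
    :func:`ensure_span_closed`); with ``strict=False`` (public single-table
    operations on bag fragments) uncoverable edges simply never contribute.
    """

    def __init__(
        self, g: ExtendedSpectrumGraph, bags, strict: bool = True
    ):
        self.g = g
        self.source = g.source
        self.sink = g.sink
        self.selectable = selectable_vertices(g)
        self.bags = [frozenset(b) for b in bags]
        self.bagmasks = [_mask(b) for b in self.bags]
        nb = len(self.bags)
        self.edge_decide: dict[tuple[int, int], int] = {}
        self.edges_at: list[list[tuple[int, int, int]]] = [[] for _ in range(nb)]
        for (u, w) in g.directed_edges:
            span = [x for x in g.span(u, w) if x in self.selectable]
            need = _mask(span) | (1 << u) | (1 << w)
            for t, bm in enumerate(self.bagmasks):
                if need & bm == need:
                    self.edge_decide[(u, w)] = t
                    self.edges_at[t].append((u, w, _mask(span)))
                    break
            else:
                if strict:
                    raise ValueError(
                        f"decomposition is not span-closed for edge {(u, w)}"
                    )
        self.pairs_at: list[list[int]] = [[] for _ in range(nb)]
        for pair in g.complement_edges:
            need = _mask(pair)
            for t, bm in enumerate(self.bagmasks):
                if need & bm == need:
                    self.pairs_at[t].append(need)
                    break
            else:
                if strict:
                    raise ValueError(
                        f"complement pair {sorted(pair)} has no common bag"
                    )
        # settle step of a vertex: once all its incident edges are decided, a
        # selected vertex with no used link can never gain one and every
        # completion of the entry carries an interior singleton
        last_edge: dict[int, int] = {}
        for (u, w), t in self.edge_decide.items():
            last_edge[u] = max(last_edge.get(u, t), t)
            last_edge[w] = max(last_edge.get(w, t), t)
        self.settle_at: list[list[int]] = [[] for _ in range(nb)]
        for v in self.selectable:
            if v in (self.source, self.sink):
                continue
            step = last_edge.get(v)
            if step is not None:
                self.settle_at[step].append(v)

    def _is_linked(self, f: int, chosen: int, t: int) -> bool:
        """Whether selected vertex f has a used edge to a mass-adjacent
        selected neighbour among the edges decided so far.  Decided links are
        final (span closure), so an unlinked vertex being forgotten is an
        interior singleton forever."""
        below = chosen & ((1 << f) - 1)
        if below:
            p = below.bit_length() - 1
            step = self.edge_decide.get((p, f))
            if step is not None and step <= t:
                return True
        q = _next_selected(chosen, f)
        if q is not None:
            step = self.edge_decide.get((f, q))
            if step is not None and step <= t:
                return True
        return False

    def _chase(self, L: int, chosen: int, t: int) -> int:
        """Advance the furthest-from-source vertex along counted links."""
        while True:
            x = _next_selected(chosen, L)
            if x is None:
                return L
            step = self.edge_decide.get((L, x))
            if step is None or step > t:
                return L
            L = x

    def initial_entries(self) -> dict[int, tuple]:
        # entry tuples: (length, nsel, chosen, L); L starts at the source,
        # whose bit is forced as soon as it is introduced.
        return {0: (0, 0, 0, self.source)}

    def run_step(
        self, entries: dict[int, tuple], t: int, prev_mask: int
    ) -> dict[int, tuple]:
        bagmask = self.bagmasks[t]
        src_bit = 1 << self.source
        sink_bit = 1 << self.sink
        # forget: re-key on the new bag, merge keeping the best
        merged: dict[int, tuple] = {}
        for e in entries.values():
            key = e[2] & bagmask
            cur = merged.get(key)
            if cur is None or _better(e, cur):
                merged[key] = e
        entries = merged
        # introduce new vertices (selection branch; source/sink forced on,
        # vertices without any directed edge forced off)
        m = bagmask & ~prev_mask
        while m:
            low = m & -m
            m ^= low
            v = low.bit_length() - 1
            forced1 = low in (src_bit, sink_bit)
            forced0 = v not in self.selectable
            nxt: dict[int, tuple] = {}
            for key, e in entries.items():
                if not forced1:
                    cur = nxt.get(key)
                    if cur is None or _better(e, cur):
                        nxt[key] = e
                if not forced0:
                    e1 = (e[0], e[1] + 1, e[2] | low, e[3])
                    k1 = key | low
                    cur = nxt.get(k1)
                    if cur is None or _better(e1, cur):
                        nxt[k1] = e1
            entries = nxt
        # antisymmetry: drop entries selecting both ends of a complement pair
        for pairmask in self.pairs_at[t]:
            entries = {
                k: e for k, e in entries.items() if e[2] & pairmask != pairmask
            }
        # count edges whose closed span first fits this bag
        if self.edges_at[t]:
            updated: dict[int, tuple] = {}
            for key, e in entries.items():
                length, nsel, chosen, L = e
                for (u, w, spanmask) in self.edges_at[t]:
                    if chosen >> u & 1 and chosen >> w & 1 and not chosen & spanmask:
                        length += 1
                updated[key] = (length, nsel, chosen, L)
            entries = updated
        # prune entries whose selected, fully-settled vertices never found a
        # used link: they are interior singletons in every completion, and no
        # optimal structure contains one
        if self.settle_at[t]:
            pruned: dict[int, tuple] = {}
            for key, e in entries.items():
                chosen = e[2]
                ok = True
                for v in self.settle_at[t]:
                    if chosen >> v & 1 and not self._is_linked(v, chosen, t):
                        ok = False
                        break
                if ok:
                    pruned[key] = e
            entries = pruned
        # advance the furthest-from-source marker
        return {
            key: (e[0], e[1], e[2], self._chase(e[3], e[2], t))
            for key, e in entries.items()
        }

    def run(self, allow_gaps: bool = True) -> tuple[tuple | None, dict]:
        diagnostics = {
            "max_entries": 0,
            "size_bound_ok": True,
            "n_bags": len(self.bags),
        }
        entries = self.initial_entries()
        prev_mask = 0
        for t in range(len(self.bags)):
            entries = self.run_step(entries, t, prev_mask)
            prev_mask = self.bagmasks[t]
            diagnostics["max_entries"] = max(
                diagnostics["max_entries"], len(entries)
            )
            p = len(self.bags[t])
            if len(entries) > 2 ** max(p - 2, 0) * (p + 1):
                diagnostics["size_bound_ok"] = False
        feasible = [e for e in entries.values() if allow_gaps or e[0] == e[1] - 1]
        if not feasible:
            return None, diagnostics
        best = feasible[0]
        for e in feasible[1:]:
            if _better(e, best):
                best = e
        return best, diagnostics


# ---------------------------------------------------------------------------
# trace-back
# ---------------------------------------------------------------------------

def _segments_from_chosen(
    g: ExtendedSpectrumGraph, chosen_ids: list[int]
) -> tuple[tuple[tuple[int, ...], ...], int]:
    """Partition a mass-sorted selection into maximal used-edge runs.

    Interior vertices with no used link (which the composite objective never
    keeps in an optimum) are dropped defensively; an edge between vertices
    that only become adjacent through such a drop is *not* added, so the
    reported length always matches the DP value.
    """
    ids = sorted(chosen_ids)
    linked = [g.has_edge(u, w) for u, w in zip(ids, ids[1:])]
    keep = []
    for i, v in enumerate(ids):
        has_link = (i > 0 and linked[i - 1]) or (i < len(linked) and linked[i])
        if has_link or v in (g.source, g.sink):
            keep.append(v)
    pos = {v: i for i, v in enumerate(ids)}
    segments: list[list[int]] = [[keep[0]]]
    length = 0
    for u, w in zip(keep, keep[1:]):
        if pos[w] == pos[u] + 1 and linked[pos[u]]:
            segments[-1].append(w)
            length += 1
        else:
            segments.append([w])
    return tuple(tuple(s) for s in segments), length


def solve(
    g: ExtendedSpectrumGraph,
    pd: PathDecomposition,
    allow_gaps: bool = True,
) -> AntisymmetricPartialPath | None:
    """Longest antisymmetric partial path between source and sink.

    ``pd`` is augmented with source/sink and span-closed automatically when
    needed.  With ``allow_gaps=False`` only single-segment (gap-free)
    source-to-sink paths qualify and ``None`` is returned when none exists.
    """
    reported_width = pd.width
    if not is_span_closed(pd, g):
        pd = ensure_span_closed(pd, g)
    src, snk = g.source, g.sink
    if not pd.bags or not all(src in b and snk in b for b in pd.bags):
        pd = augment_source_sink(pd, g)
    solver = _Solver(g, pd.bags, strict=True)
    best, diagnostics = solver.run(allow_gaps=allow_gaps)
    if best is None:
        return None
    length, _nsel, chosen, _L = best
    segments, seg_length = _segments_from_chosen(g, list(_lex_key(chosen)))
    assert seg_length == length, "trace-back length mismatch"
    diagnostics["width"] = reported_width
    diagnostics["solver_width"] = pd.width
    return AntisymmetricPartialPath(segments, length, diagnostics)


# ---------------------------------------------------------------------------
# public single-table operations
# ---------------------------------------------------------------------------

def _entries_to_table(node, bag, entries) -> DPTable:
    out = {}
    bagset = frozenset(bag)
    for e in entries.values():
        length, nsel, chosen, L = e
        sel = frozenset(v for v in bagset if chosen >> v & 1)
        Lpub = L if L in bagset else ELSEWHERE
        out[(sel, Lpub)] = DPEntry(sel, Lpub, length, nsel, frozenset(_lex_key(chosen)))
    return DPTable(node, bagset, out)


def _table_to_entries(table: DPTable) -> dict[int, tuple]:
    bagmask = _mask(table.bag)
    entries: dict[int, tuple] = {}
    for e in table.entries.values():
        chosen = _mask(e.selected)
        L = e.L
        if L == ELSEWHERE:
            outside = [v for v in e.selected if v not in table.bag]
            L = max(outside) if outside else ELSEWHERE
        cand = (e.length, e.nsel, chosen, L)
        key = chosen & bagmask
        cur = entries.get(key)
        if cur is None or _better(cand, cur):
            entries[key] = cand
    return entries


def leaf_entries(bag, g: ExtendedSpectrumGraph) -> DPTable:
    """Table of the left-end node: one entry per feasible selection.

    Feasibility at the leaf: no complement pair fully selected; the selected
    vertices induce disjoint chain links; ``L`` is the furthest vertex of the
    source-anchored run (never ELSEWHERE at the leaf).  Only edges whose
    closed span lies inside the bag contribute length here; others are
    counted later, once their span is fully visible.
    """
    bag = frozenset(bag) | {g.source, g.sink}
    solver = _Solver(g, [bag], strict=False)
    entries = solver.run_step(solver.initial_entries(), 0, 0)
    return _entries_to_table(0, bag, entries)


def transition(
    prev: DPTable, bag_prev, bag_next, g: ExtendedSpectrumGraph
) -> DPTable:
    """One left-to-right step between adjacent bags.

    Edges whose closed span first becomes fully visible in ``bag_next`` are
    counted; complement pairs inside ``bag_next`` are enforced; the ``L``
    field advances along counted links or becomes ELSEWHERE when its vertex
    is forgotten.  With ``bag_next == bag_prev`` the table is reproduced
    unchanged.
    """
    bag_prev = frozenset(bag_prev) | {g.source, g.sink}
    bag_next = frozenset(bag_next) | {g.source, g.sink}
    solver = _Solver(g, [bag_prev, bag_next], strict=False)
    entries = _table_to_entries(prev)
    entries = solver.run_step(entries, 1, solver.bagmasks[0])
    return _entries_to_table(prev.node + 1, bag_next, entries)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def induced_length(g: ExtendedSpectrumGraph, selected) -> int:
    """Directed edges with both endpoints selected.

    Equals the partial-path length whenever no selected vertex lies strictly
    inside another induced edge's mass span (the single-residue-step premise).
    """
    sel = set(selected)
    return sum(1 for (u, v) in g.directed_edges if u in sel and v in sel)


def chain_length(g: ExtendedSpectrumGraph, selected) -> int:
    """Edges joining mass-consecutive selected vertices (the used edges)."""
    ids = sorted(selected)
    return sum(1 for u, w in zip(ids, ids[1:]) if g.has_edge(u, w))


def brute_force_lapp(
    g: ExtendedSpectrumGraph,
    allow_gaps: bool = True,
    limit: int = 12,
) -> AntisymmetricPartialPath | None:
    """Exhaustive oracle: best selection over all vertex subsets.

    Checked directly against the segment definitions (disjoint antisymmetric
    directed chains, non-interleaving mass intervals) with the same composite
    objective as the DP, but sharing none of its table machinery.  Guarded to
    ``limit`` vertices.
    """
    n = len(g.vertices)
    if n > limit:
        raise ValueError(f"brute force limited to {limit} vertices, got {n}")
    middle = [v.id for v in g.vertices if v.id not in (g.source, g.sink)]
    pairs = [tuple(p) for p in g.complement_edges]
    best: tuple | None = None
    for r in range(len(middle) + 1):
        for combo in itertools.combinations(middle, r):
            sel = set(combo) | {g.source, g.sink}
            if any(a in sel and b in sel for a, b in pairs):
                continue
            length = chain_length(g, sel)
            if not allow_gaps and length != len(sel) - 1:
                continue
            cand = (length, len(sel), _mask(sel), 0)
            if best is None or _better(cand, best):
                best = cand
    if best is None:
        return None
    segments, length = _segments_from_chosen(g, list(_lex_key(best[2])))
    return AntisymmetricPartialPath(segments, length)


def topological_longest_path(g: ExtendedSpectrumGraph) -> int | None:
    """Longest source-to-sink directed path length by topological-order DP."""
    dist: dict[int, int | None] = {v.id: None for v in g.vertices}
    dist[g.source] = 0
    for v in sorted(dist):
        for u in g.in_neighbors(v):
            if dist[u] is not None:
                d = dist[u] + 1
                if dist[v] is None or d > dist[v]:
                    dist[v] = d
    return dist[g.sink]


def check_partial_path(
    g: ExtendedSpectrumGraph, p: AntisymmetricPartialPath
) -> list[str]:
    """Verify the structural invariants; returns human-readable violations."""
    errors: list[str] = []
    seen: set[int] = set()
    for seg in p.segments:
        for u, w in zip(seg, seg[1:]):
            if not g.has_edge(u, w):
                errors.append(f"segment step {u}->{w} is not a directed edge")
        for v in seg:
            if v in seen:
                errors.append(f"vertex {v} appears in two segments")
            seen.add(v)
    for pair in g.complement_edges:
        if pair <= seen:
            errors.append(f"complement pair {sorted(pair)} fully selected")
    intervals = [(g.mass(seg[0]), g.mass(seg[-1])) for seg in p.segments]
    for (_a1, b1), (a2, _b2) in zip(intervals, intervals[1:]):
        if not b1 < a2:
            errors.append("segment mass intervals interleave or are unordered")
    if not p.segments or p.segments[0][0] != g.source:
        errors.append("first segment does not start at the source")
    if p.segments[-1][-1] != g.sink:
        errors.append("last segment does not end at the sink")
    total = sum(len(s) - 1 for s in p.segments)
    if total != p.total_length:
        errors.append("total_length does not match segment edge counts")
    return errors
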