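"""Path decompositions of extended spectrum graphs.

A path decomposition is an ordered sequence of vertex bags such that every
vertex appears in some bag, every edge (directed or complement) has both
endpoints together in some bag, and the bags containing any fixed vertex form
a contiguous run.  Width is the maximum bag size minus one.

Decompositions here are built from vertex orderings: introduce vertices one
at a time and take as bags the *boundary* sets of vertices that still have
unfinished co-residency obligations.  Besides the two Definition-style
obligations (directed edges and complement pairs), the solver needs a
stronger *span closure* property: for every directed edge (u, w) some bag
must contain u, w, and every selectable vertex with mass strictly between
them.  Span closure is what lets the dynamic program decide, once and
locally, whether an edge joins two mass-consecutive selected vertices; it is
guaranteed here by treating each edge's closed span as an obligation set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .graph_builder import ExtendedSpectrumGraph


@dataclass(frozen=True)
class PathDecomposition:
    bags: tuple[frozenset[int], ...]

    @property
    def width(self) -> int:
        if not self.bags:
            return -1
        return max(len(b) for b in self.bags) - 1

    def __len__(self) -> int:
        return len(self.bags)

    def dump(self) -> str:
        return "\n".join(
            " ".join(str(v) for v in sorted(bag)) for bag in self.bags
        )


# ---------------------------------------------------------------------------
# obligations
# ---------------------------------------------------------------------------

def selectable_vertices(g: ExtendedSpectrumGraph) -> set[int]:
    """Vertices that can ever appear in an optimal partial path.

    A vertex with no incident directed edge contributes no path edge and can
    only block others, so optimal solutions never select it; the solver forces
    its selection bit to zero and spans may ignore it.  Source and sink are
    always selectable.
    """
    out = {g.source, g.sink}
    for (u, v) in g.directed_edges:
        out.add(u)
        out.add(v)
    return out


def edge_obligations(g: ExtendedSpectrumGraph) -> list[frozenset[int]]:
    """Co-residency obligation sets: closed edge spans and complement pairs."""
    sel = selectable_vertices(g)
    obs: list[frozenset[int]] = []
    for (u, v) in g.directed_edges:
        span = {x for x in g.span(u, v) if x in sel}
        obs.append(frozenset({u, v} | span))
    for pair in g.complement_edges:
        obs.append(frozenset(pair))
    return obs


def _plain_obligations(adj: Mapping[int, set[int]]) -> list[frozenset[int]]:
    obs = []
    for u, nbrs in adj.items():
        for v in nbrs:
            if u < v:
                obs.append(frozenset((u, v)))
    return obs


def _as_adjacency(g) -> Mapping[int, set[int]]:
    if isinstance(g, ExtendedSpectrumGraph):
        return g.undirected_adjacency()
    return g


# ---------------------------------------------------------------------------
# boundary construction
# ---------------------------------------------------------------------------

def boundary_decomposition(
    order: Sequence[int], obligations: Iterable[frozenset[int]]
) -> PathDecomposition:
    """Bags of boundary sets along an introduction order.

    Bag t holds the vertex introduced at step t plus every earlier vertex
    with at least one obligation set not yet fully introduced.  Every
    obligation set is fully contained in the bag at the step its last member
    is introduced.
    """
    obs = [set(o) for o in obligations]
    of: dict[int, list[int]] = {v: [] for v in order}
    for i, o in enumerate(obs):
        for v in o:
            of[v].append(i)
    remaining = [len(o) for o in obs]
    pending = {v: len(of[v]) for v in order}
    introduced: list[int] = []
    bags: list[frozenset[int]] = []
    for v in order:
        bag = {u for u in introduced if pending[u] > 0}
        bag.add(v)
        bags.append(frozenset(bag))
        introduced.append(v)
        for i in of[v]:
            remaining[i] -= 1
            if remaining[i] == 0:
                for u in obs[i]:
                    pending[u] -= 1
    # drop bags that are subsets of a neighbour (pure cleanup)
    cleaned: list[frozenset[int]] = []
    for bag in bags:
        if cleaned and (bag <= cleaned[-1] or cleaned[-1] <= bag):
            cleaned[-1] = max(bag, cleaned[-1], key=len)
        else:
            cleaned.append(bag)
    return PathDecomposition(tuple(cleaned))


def _greedy_order(
    vertices: Sequence[int], obligations: list[frozenset[int]]
) -> list[int]:
    """Greedy vertex-separation ordering: next vertex minimises the active
    boundary, ties broken by ascending vertex id (ascending mass for spectrum
    graphs)."""
    obs = [set(o) for o in obligations]
    of: dict[int, list[int]] = {v: [] for v in vertices}
    for i, o in enumerate(obs):
        for v in o:
            of[v].append(i)
    remaining = [len(o) for o in obs]
    pending = {v: len(of[v]) for v in vertices}
    introduced: set[int] = set()
    active: set[int] = set()  # introduced with pending > 0
    order: list[int] = []
    todo = sorted(vertices)
    while todo:
        best = None
        best_score = None
        for v in todo:
            completed = [i for i in of[v] if remaining[i] == 1]
            freed = set()
            drops = {v: 0}
            for i in completed:
                for u in obs[i]:
                    drops[u] = drops.get(u, 0) + 1
            for u, d in drops.items():
                if u != v and u in active and pending[u] - d == 0:
                    freed.add(u)
            v_active = pending[v] - drops.get(v, 0) > 0
            score = len(active) - len(freed) + (1 if v_active else 0)
            if best_score is None or score < best_score:
                best_score = score
                best = v
        order.append(best)
        todo.remove(best)
        introduced.add(best)
        for i in of[best]:
            remaining[i] -= 1
            if remaining[i] == 0:
                for u in obs[i]:
                    pending[u] -= 1
                    if pending[u] == 0:
                        active.discard(u)
        if pending[best] > 0:
            active.add(best)
    return order


def _converging_order(
    g: ExtendedSpectrumGraph, obligations: list[frozenset[int]]
) -> list[int]:
    """Two-pointer greedy: introduce from the mass extremes inward, always
    advancing the frontier whose next vertex leaves the smaller boundary.

    Complement pairs join a light and a heavy vertex, so the two frontiers
    meet each pair from both ends; a dense one-sided noise cluster is swept
    through by its own side while the other side waits, which keeps span
    obligations from stacking both windows into one bag.
    """
    obs = [set(o) for o in obligations]
    vertices = sorted((v.id for v in g.vertices), key=g.mass)
    of: dict[int, list[int]] = {v: [] for v in vertices}
    for i, o in enumerate(obs):
        for v in o:
            of[v].append(i)
    remaining = [len(o) for o in obs]
    pending = {v: len(of[v]) for v in vertices}
    active: set[int] = set()
    order: list[int] = []
    lo, hi = 0, len(vertices) - 1

    def score(v: int) -> int:
        completed = [i for i in of[v] if remaining[i] == 1]
        drops: dict[int, int] = {v: 0}
        for i in completed:
            for u in obs[i]:
                drops[u] = drops.get(u, 0) + 1
        freed = sum(
            1
            for u, d in drops.items()
            if u != v and u in active and pending[u] - d == 0
        )
        v_active = pending[v] - drops.get(v, 0) > 0
        return len(active) - freed + (1 if v_active else 0)

    def take(v: int) -> None:
        order.append(v)
        for i in of[v]:
            remaining[i] -= 1
            if remaining[i] == 0:
                for u in obs[i]:
                    pending[u] -= 1
                    if pending[u] == 0:
                        active.discard(u)
        if pending[v] > 0:
            active.add(v)

    while lo <= hi:
        if lo == hi:
            take(vertices[lo])
            break
        a, b = vertices[lo], vertices[hi]
        if score(a) <= score(b):
            take(a)
            lo += 1
        else:
            take(b)
            hi -= 1
    return order


def _pairing_order(g: ExtendedSpectrumGraph) -> list[int]:
    """Outside-in order: vertices sorted by distance from the mass extremes.

    Complementary peaks (masses m and M-m) get adjacent positions, which keeps
    the boundary of ladder-like spectrum graphs to the current rung pair.
    """
    M = g.total_mass
    return sorted(
        (v.id for v in g.vertices),
        key=lambda i: (min(g.mass(i), M - g.mass(i)), g.mass(i)),
    )


def decompose(g, strategy: str = "greedy") -> PathDecomposition:
    """Build a valid path decomposition of the mixed graph.

    Strategies: ``greedy`` (boundary-minimising vertex separation, ties by
    ascending mass), ``pairing`` (outside-in complement pairing; spectrum
    graphs only), ``mass`` (ascending mass), ``best`` (smallest width of the
    above).  The achieved width is heuristic, not necessarily optimal.  The
    result satisfies the definition conditions (coverage, edge coverage,
    contiguity); the solver widens bags for span closure on its own.
    """
    adj = _as_adjacency(g)
    obligations = _plain_obligations(adj)
    vertices = list(adj)
    orders = {
        "greedy": lambda: _greedy_order(vertices, obligations),
        "mass": lambda: sorted(vertices),
    }
    if isinstance(g, ExtendedSpectrumGraph):
        orders["pairing"] = lambda: _pairing_order(g)
    if strategy == "best":
        pds = [boundary_decomposition(o(), obligations) for o in orders.values()]
        return min(pds, key=lambda pd: pd.width)
    if strategy not in orders:
        raise ValueError(f"unknown strategy {strategy!r}")
    return boundary_decomposition(orders[strategy](), obligations)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate(pd: PathDecomposition, g) -> list[tuple[str, object]]:
    """Check Definition-style conditions; returns violations with witnesses.

    Conditions: every vertex covered; both endpoints of every edge share a
    bag; the bags containing any vertex are contiguous.
    """
    violations: list[tuple[str, object]] = []
    if isinstance(g, ExtendedSpectrumGraph):
        vertices = {v.id for v in g.vertices}
        edges = [frozenset(e) for e in g.directed_edges] + list(g.complement_edges)
    else:
        adj = _as_adjacency(g)
        vertices = set(adj)
        edges = [
            frozenset((u, v)) for u, nbrs in adj.items() for v in nbrs if u < v
        ]
    covered = set().union(*pd.bags) if pd.bags else set()
    for v in vertices - covered:
        violations.append(("coverage", v))
    for e in edges:
        if not any(e <= bag for bag in pd.bags):
            violations.append(("edge-coverage", tuple(sorted(e))))
    for v in covered:
        idx = [i for i, bag in enumerate(pd.bags) if v in bag]
        if idx[-1] - idx[0] + 1 != len(idx):
            violations.append(("contiguity", v))
    return violations


def is_span_closed(pd: PathDecomposition, g: ExtendedSpectrumGraph) -> bool:
    for o in edge_obligations(g):
        if not any(o <= bag for bag in pd.bags):
            return False
    return True


def ensure_span_closed(
    pd: PathDecomposition, g: ExtendedSpectrumGraph
) -> PathDecomposition:
    """Rebuild ``pd`` as a span-closed decomposition with the same character.

    The introduction order implied by ``pd`` (first bag containing each
    vertex, ties by ascending mass) is replayed through the boundary
    construction with the edges' closed spans as obligations, so every edge
    gets a bag containing its endpoints and everything with mass strictly
    between them.  The solver's answer is identical for every span-closed
    decomposition, so when the replayed order closes badly the narrower
    outside-in pairing order is used instead.
    """
    first_bag: dict[int, int] = {}
    for t, bag in enumerate(pd.bags):
        for v in bag:
            first_bag.setdefault(v, t)
    vertices = {v.id for v in g.vertices}
    missing = vertices - set(first_bag)
    if missing:
        raise ValueError(f"decomposition does not cover vertices {sorted(missing)}")
    obligations = edge_obligations(g)
    order = sorted(vertices, key=lambda v: (first_bag[v], v))
    candidates = [
        boundary_decomposition(order, obligations),
        boundary_decomposition(_pairing_order(g), obligations),
        boundary_decomposition(_converging_order(g, obligations), obligations),
    ]
    return min(candidates, key=lambda p: p.width)


def augment_source_sink(
    pd: PathDecomposition, g: ExtendedSpectrumGraph
) -> PathDecomposition:
    """Add the source and sink vertices to every bag (width grows by <= 2)."""
    extra = {g.source, g.sink}
    return PathDecomposition(tuple(frozenset(b | extra) for b in pd.bags))


# ---------------------------------------------------------------------------
# exact pathwidth (small graphs; test oracle)
# ---------------------------------------------------------------------------

def exact_pathwidth(g, limit: int = 14) -> int:
    """Minimum width over all vertex orderings via vertex-separation DP.

    Exponential in the vertex count; guarded to ``limit`` vertices.
    """
    adj = _as_adjacency(g)
    vertices = sorted(adj)
    n = len(vertices)
    if n > limit:
        raise ValueError(f"exact pathwidth limited to {limit} vertices, got {n}")
    if n == 0:
        return -1
    index = {v: i for i, v in enumerate(vertices)}
    nbr_masks = [0] * n
    for v, nbrs in adj.items():
        m = 0
        for u in nbrs:
            if u != v:
                m |= 1 << index[u]
        nbr_masks[index[v]] = m

    full = (1 << n) - 1
    from functools import lru_cache

    def boundary(mask: int) -> int:
        b = 0
        m = mask
        while m:
            low = m & -m
            i = low.bit_length() - 1
            if nbr_masks[i] & ~mask:
                b |= low
            m ^= low
        return b

    @lru_cache(maxsize=None)
    def cost(mask: int) -> int:
        """Min over orderings of ``mask`` of the max bag size along the way."""
        if mask == 0:
            return 0
        best = n + 1
        m = mask
        while m:
            low = m & -m
            i = low.bit_length() - 1
            m ^= low
            prev = mask ^ low
            bag = boundary(prev) | low
            c = max(cost(prev), bag.bit_count())
            if c < best:
                best = c
        return best

    return cost(full) - 1


# ---------------------------------------------------------------------------
# randomised decompositions (fuzzing support)
# ---------------------------------------------------------------------------

def random_decomposition(g, rng, pad: int = 3) -> PathDecomposition:
    """A random valid decomposition: random introduction order, boundary bags,
    plus random run extensions."""
    adj = _as_adjacency(g)
    obligations = _plain_obligations(adj)
    vertices = list(adj)
    order = list(vertices)
    rng.shuffle(order)
    pd = boundary_decomposition(order, obligations)
    bags = [set(b) for b in pd.bags]
    for _ in range(pad):
        v = vertices[int(rng.integers(len(vertices)))]
        idx = [i for i, b in enumerate(bags) if v in b]
        if not idx:
            continue
        if rng.random() < 0.5 and idx[0] > 0:
            bags[idx[0] - 1].add(v)
        elif idx[-1] < len(bags) - 1:
            bags[idx[-1] + 1].add(v)
    return PathDecomposition(tuple(frozenset(b) for b in bags))
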