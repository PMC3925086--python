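# Methods

## Coordinate system and chemistry

All core computation happens on the residue-sum scale: the source sits at
mass 0, the sink at `M = Σ residue masses`, a prefix fragment at its prefix
sum, and complementary fragments sum exactly to M.  Conversion from observed
singly charged ion m/z values (proton and water offsets, precursor charge)
is confined to `spectra.calibrate_ions`; peak lists written in abstract
coordinates bypass it.  The residue table is the 20 standard monoisotopic
residue masses; leucine and isoleucine are distinct entries with one shared
mass and collapse to the call symbol `L/I` in outputs.  Default modification
deltas: oxidation +15.99491 (M), phosphorylation +79.96633 (S/T/Y),
deamidation +0.98402 (N/Q); both tables are user-overridable from YAML files.

Two near-coincidences of the standard table are recorded rather than
tolerated silently: G+G differs from N by 1e-5 Da and G+A from Q by 1e-5 Da.
They are the reason a 114.043 Da gap has two legitimate readings, and the
reason the solver cannot count edges the naive way (below).

## Preprocessing

For experimental spectra: peaks below 0.1 of the maximum intensity are
removed; a peak one C13 spacing (1.00335 Da) above a strictly more intense
peak is removed as an isotope; near-duplicates merge within `merge_tol`
(default 0.3 Da, 0.001 Da in simulation); finally every surviving peak
lacking a complementary partner gets a synthetic one at `M − m` with the same
intensity and a `synthetic` flag.  The step is idempotent.  The simulated
pipeline disables the complement-closure step: simulated ladders already
contain their full pair structure, and mirroring injected noise would only
double the decoy count — closure is a repair for experimental ion series,
not part of the simulation model.

## The partial-path objective, read as a chain

Because every directed edge strictly increases mass, an antisymmetric partial
path (disjoint antisymmetric segments with pairwise disjoint, ascending mass
intervals) is equivalent to a *chain*: sort the selected vertices by mass;
each consecutive pair is either joined by a used directed edge (inside a
segment) or is a gap (between segments).  The length is the number of
consecutive pairs joined by an edge.  This equivalence is what the
brute-force oracle checks directly and what the table DP computes.

Counting *induced* edges (every edge with both endpoints selected) would be
correct only if no residue mass equalled a sum of residue masses.  That
premise fails in practice — at any tolerance above 1e-5 Da the G+G ladder
step also matches an N edge spanning the middle glycine peak — so an induced
edge can cross a selected vertex and belong to no segment.  The implementation
therefore counts an edge only when its endpoints are mass-consecutive among
the selected vertices.

Zero-edge segments are permitted only as source/sink anchors.  Interior
singletons never improve the objective (removing one keeps every used edge
and can only unblock more), so the solver prunes them: exactly, at the moment
a selected vertex has all its incident edges decided and none used.

## Span-closed decompositions and why the DP is exact

Each table entry is keyed by the selection status of the bag's vertices and
stores the best length, the furthest vertex reached from the source (`L`, or
ELSEWHERE once forgotten), and the selected set so far (for tie-breaking and
trace-back; no back pointers are needed because the used edges are a function
of the final selection).  Entries with equal bag selection merge, keeping the
best — valid because all future length increments and feasibility checks
depend only on bag-visible bits.  That locality is *not* automatic: whether
an edge joins mass-consecutive selected vertices depends on every vertex with
mass strictly inside the edge's span, and in an arbitrary valid decomposition
such a vertex may be introduced after the edge has been counted (a five-vertex
counterexample exists).  The solver therefore requires decompositions that are
**span-closed**: for every directed edge some bag contains both endpoints and
every selectable vertex with mass strictly inside the span (selectable =
incident to at least one directed edge; others are never selected by an
optimum and their bits are forced off).  An edge is then decided once, at the
first bag containing its closed span, when every vertex that could ever sit
inside it is present — the decision is final, and the DP is exact for *every*
span-closed decomposition, which the decomposition-independence fuzz tests
exercise.

`decompose` returns an ordinary definition-style decomposition (coverage,
edge coverage, contiguity) whose width is the reported statistic; `solve`
internally rebuilds a span-closed decomposition and widens bags as needed,
reporting both widths in its diagnostics.  The per-bag entry bound
`2^(p−2)·(p+1)` (source/sink bits forced) is asserted on the widened bags
during every run.

Ties between equally long structures break toward fewer selected vertices
first — equivalently fewest segments, since the segment count is the selected
count minus the used-edge count — then toward the lexicographically earliest
mass sequence.  Pure lexicographic tie-breaking (the simpler rule) was
rejected because a single-edge noise pair landing inside a wide residue gap
ties the full ladder and sorts lexicographically earlier, silently corrupting
calls; preferring contiguity is the standard de novo convention.

## Decomposition heuristics

All decompositions come from vertex introduction orders via the boundary
construction: bag *t* holds the vertex introduced at step *t* plus every
earlier vertex with an unfinished co-residency obligation; every obligation
set is complete in the bag where its last member arrives.  Orders available:

- `greedy` (default): repeatedly introduce the vertex minimising the active
  boundary, ties by ascending mass.
- `pairing`: outside-in by `min(m, M − m)`, so complementary peaks are
  introduced together — the natural order for ladder-shaped graphs.
- converging two-pointer (used internally for span closure): advance
  whichever mass frontier leaves the smaller boundary, which sweeps dense
  one-sided noise clusters without stacking both mass windows into one bag.
- `mass`: ascending mass (baseline; poor for complement pairs).

For span closure the solver replays the given decomposition's introduction
order against the span obligations and falls back to the pairing or
converging order when that closes more narrowly; the answer is identical for
any span-closed decomposition, so the choice affects speed only.
`exact_pathwidth` (vertex-separation subset DP, ≤ 14 vertices) serves as the
optimality oracle in tests; the heuristic width is not guaranteed minimal,
and reported width distributions are heuristic-dependent.

## Gap filling

Gaps between consecutive segments are mass deltas explained by depth-first
subset-sum over the residue table (multisets, tolerance window, residue
budget `ceil(delta / min residue mass)`).  Unmodified compositions are
searched first; only when none exists are compositions with at most one
modified residue considered.  Candidates rank by fewer residues, then fewer
modifications, then absolute mass error; the top candidate is reported in
brackets as an unordered multiset — subset-sum determines composition, never
order.  A gap with no explanation (e.g. below the glycine mass) is emitted as
`[Δ…]` with its delta.  Mass conservation (element masses tile (0, M) within
k·tol) is asserted in tests for every emitted result.

## Simulator: what it emulates and what it does not

`random_peptides` draws tryptic-like peptides: lengths uniform on 5–24,
residues uniform over the 20-letter table, last residue K or R.  Ideal
spectra are complete b/y ladders with unit intensities; coincident b/y masses
merge into one peak.  Noise is injected in groups: a uniform random start in
(0, M) extended by 1–3 single-residue steps (group size 2–4, a declared
choice), until the noise count reaches `round(ns_ratio × real peaks)`.
Dropout removes real peaks independently; a PTM modifies one random eligible
residue and shifts all downstream prefix masses.  All randomness flows from
one seed.

Not emulated: intensity structure (all peaks weigh 1, so the intensity floor
never fires in simulation), fragmentation propensities, isotope envelopes,
multiply charged fragments, and real digest composition (residue usage is
uniform, not proteome-weighted).  Passing simulated-accuracy tests therefore
demonstrates the graph algorithm and gap resolution under the stated noise
model, not performance on instrument data.

`accuracy` is per-residue: edge calls match positionally when the call's mass
interval matches a truth residue boundary pair and the residue (or a
mass-identical alternative, L/I) agrees; a single edge spanning several truth
residues counts them all when its label is mass-identical to the spanned
composition (the N vs G+G reading); gap fills match as multisets against the
truth residues inside the gap interval.  The score is the better of the
prediction and its mirror-image reading, because the extended spectrum graph
is symmetric under mass reflection and cannot orient the peptide.

## Observed behaviour and known limitations

- Noiseless spectra are read at or very near 100% per-residue accuracy
  (rare multi-coincidence peptides can lose a residue).  About 5% of
  peptides split into two segments even without noise: when two prefix sums
  are complementary within tolerance (most commonly first residue = last
  residue, so `b1 + b_{n−1} = M` exactly), the ladder carries a complement
  edge inside itself and one peak must be dropped; the gap filler recovers
  the residue, so accuracy is unaffected.
- At N/S = 1.0 the same coincidence becomes the dominant error source: the
  fragmented true ladder can be outscored by noise-assisted partial paths of
  equal or greater length, which is a property of the unweighted
  longest-partial-path objective itself, not of the table DP (the exhaustive
  oracle returns the same structures).  Mean accuracy under the declared
  noise model is ≈ 96% over 500 spectra (seed-to-seed spread ≈ ±0.6).  An edge-scoring scheme would be
  the natural remedy and is deliberately out of scope.
- Problem sizes: the shipped tests and the acceptance script use 500 spectra
  per condition and 200–400 fuzz graphs of ≤ 12 vertices, sizes at which the
  full suite completes in minutes on one CPU.  The rare dense spectrum (a
  186 Da edge span near M/2 holding ~15 selectable vertices) dominates the
  runtime; the singleton pruning keeps it under a minute.
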