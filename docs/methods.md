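# Methods

## Model

A gene network is treated as a finite metric space: nodes are normalized gene
symbols, distance is hop-count shortest-path length (Dijkstra over weights is
supported but off by default — interaction networks here are unweighted, so
filtration values are small integers), and pairs in different connected
components are at +∞. Persistent homology is computed over the Vietoris–Rips
filtration of that metric: a simplex on vertices σ is born at the largest
pairwise distance within σ; vertices at +∞ never share a simplex, so
components remain genuinely separate at every scale.

The quantity the pipeline cares about is the **structure count**
B<sub>k</sub>: the number of positive-persistence intervals of dimension k
anywhere in the filtration, counting finite and essential (infinite) bars
alike. This is a census of every component (B₀), independent cycle (B₁) and
enclosed void (B₂) that ever exists during the filtration — not the Betti
number at one fixed scale. On the dodecahedral skeleton this convention gives
(B₀, B₁, B₂) = (20, 11, 1): all twenty components count although nineteen die
at scale 1; the eleven cycles are |E| − |V| + 1 of the 1-skeleton (the
twelfth pentagonal face is not independent); the single void is the hollow
interior, born at scale 2 when the pentagonal cycles become triangulated.

**Impact.** For each node v, the node-deleted graph's own shortest-path
matrix is rebuilt (paths through v must lengthen or vanish — slicing the
original matrix would silently keep them) and the barcode recomputed with
identical settings; Δ(v) = B₂(G − v) − B₂(G). Genes with Δ < 0 sustain voids
and form the impactful set; positive Δ (removal *creating* voids) is
possible in principle and is recorded and flagged separately rather than
discarded. Reported "impact" follows the sign convention impact = −Δ.

## Algorithmic choices

- **Coefficients: GF(2).** Standard for VR persistence; boundary columns are
  integer bitmasks, reduction is the classic column algorithm (pivot =
  highest set bit, XOR until the pivot is unique). For the complexes
  exercised here Betti counts are field-independent.
- **max_dim = 3 default.** Dimension-3 simplices are required for correct
  dimension-2 deaths; dimension-2 intervals are the scientific target, and
  intervals of dimension = max_dim are suppressed (their deaths cannot be
  resolved without max_dim + 1 simplices). max_dim > 3 is refused as a cost
  guard — it buys nothing for β₂ and the simplex count grows as n^(d+1).
- **max_scale default = largest finite distance** (full-diameter filtration),
  so within-component homology is followed to extinction and no dimension-1
  or -2 bar is left artificially infinite. The cap is user-configurable
  because the number of simplices on dense networks of hundreds of nodes is
  the main operational hazard; every output records the cap used.
- **Tie-breaking.** Simplices with equal filtration value are ordered by
  (dimension, lexicographic vertex tuple). This guarantees faces precede
  cofaces and makes barcodes byte-identical across runs.
- **Zero-persistence pairs are dropped** — they are ordering artifacts, not
  structures.
- **Impact "diameter" scale policy** resolves to the *baseline* graph's
  diameter, applied as the same numeric cap to all node-deleted graphs, so
  every record is computed under literally identical filtration settings
  (a deleted graph's diameter can exceed the baseline's).
- **Independent oracle.** β_k = dim ker ∂_k − rank ∂_{k+1} computed from
  explicit GF(2) boundary matrices of the complex at a fixed scale. It shares
  no code with the reduction path and is capped at 20 vertices (enough to
  cover the dodecahedron); the suite checks barcode-derived Betti numbers
  against it at every distance scale on hundreds of random graphs, plus an
  Euler-characteristic consistency identity on ≤8-vertex instances.

## Consensus parameters

`min_cancers` defaults to 4 with six mutation tables — the canonical
"mutated in at least four of six cancer types" setting; both numbers are
configurable. Support uses presence semantics (a gene counts once per cancer
type regardless of how many samples carry it), so the consensus operator is
monotone in k: k = 1 is the union of the tables' gene sets, k = n the
intersection. Silent variants can be excluded with `nonsilent_only` (off by
default; both behaviors are legitimate readings of MAF preprocessing).

## What the synthetic generator emulates

`make_synthetic_study` emulates the input side of a multi-cancer study: six
per-cancer MAF tables (50 samples each by default), genes planted as
*recurrent* (assigned to ≥ k randomly chosen cancer types) or *sporadic*
(< k), each gene–cancer pair materialized as 1–4 mutated samples, and a
driver catalog drawn from the recurrent genes (fraction 0.5). By construction
consensus at threshold k recovers exactly the recurrent set, which is the
property the pipeline tests lean on. It deliberately does **not** model
mutation signatures, hypermutators, per-sample burden, or degree-distribution
realism of real interactomes — so green tests certify the machinery
(selection, induction, topology, scoring), not biological discovery power.

`make_planted_void_network` builds provable β₂ ground truth: a random-tree
background with chords only between vertices at distance ≥ 3 (keeping the
background triangle-free), plus octahedral gadgets attached by a single
bridge edge or a single shared vertex. The octahedron is the minimal
VR-realizable 2-sphere — a hollow 4-clique fills into a solid simplex under
VR, so no smaller void gadget exists. At filtration scale 1 the complex is
the graph's clique complex: the triangle-free background contributes no
2-simplices, no triangle spans an attachment, and each gadget is exactly one
2-sphere. Hence B₂ = number of gadgets, removing any gadget vertex gives
Δ = −1 (−m for a vertex shared by m gadgets), and every background vertex
gives Δ = 0 — exactly, not statistically. The truth object therefore records
`scale = 1.0`, and impact analyses against planted truth run at that recorded
scale; at larger scales VR complexes of trees-with-chords can carry
higher-dimensional homology of their own and ground truth would no longer be
provable. Generated instances small enough (≤ 12 vertices) are additionally
verified against the rank oracle at generation time; a failure raises
immediately.

All generator randomness flows from a single `numpy.random.default_rng(seed)`;
no global state is touched, and equal seeds give identical studies.

## Degenerate inputs and edge cases

Self-loops are dropped (with a warning) and the node kept; duplicate edges
collapse to the first weight seen. An empty consensus∩SPN intersection yields
an empty network with a warning, not an error. Impact on a ≤1-node network
returns an empty record list. Precision is reported as not-applicable when no
gene is impactful, recall when no positives are supplied. Closeness uses the
Wasserman–Faust component scaling so disconnected consensus networks (which
occur — isolated consensus genes are retained by design) stay comparable;
betweenness excludes endpoints with the 2/((n−1)(n−2)) normalization.
Percentile ranks use mean ranks for ties mapped by (rank − 1)/(n − 1)·100,
placing a unique maximum at 100 and a fully tied column at 50.

## Problem sizes

The default test and acceptance workloads use the closed-form polyhedral
fixtures (≤ 20 nodes), random graphs of ≤ 10 vertices for oracle
equivalence (200 instances), and planted-void networks of ~32 nodes. These
sizes make every expected value either a closed form or independently
verifiable by the brute-force oracle; the engine itself handles networks of a
few hundred nodes at moderate scale caps, with the simplex count (reported at
DEBUG level) as the quantity to watch.

## Known limitations

- Dimensions above 2 are out of scope by design; representative cycles (which
  voids a gene belongs to) are not computed.
- The filtration enumerates simplices explicitly; no sparse/approximate Rips
  construction is provided, so thousand-node networks at large scale caps are
  combinatorially out of reach.
- Identifier mapping (UniProt↔HGNC etc.) is not performed: inputs must
  already share a symbol namespace (symbols are only case/whitespace
  normalized).
- Impact is single-node; pairwise or set removals are not implemented.
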