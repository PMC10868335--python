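# Methods

## The prediction problem

Given an RNA sequence ω (and optionally a starting secondary structure
and/or a multiple sequence alignment containing ω), knotmotif predicts a
secondary structure that may contain pseudoknots — crossing base pairs
i < k < j < l — together with a set of local 3D structural motifs inserted
into its loops. Base pairs are restricted to canonical (G-C, A-U) and
Wobble (G-U) combinations with a minimum hairpin loop of three unpaired
nucleotides (j − i > 3). A crossing structure is represented as an ordered
list of pseudoknot-free *levels*: level 1 holds the dominant nested
structure, each higher level holds pairs that cross the levels below.

## Pseudo-probabilities from per-level constrained folding

The maximum-expected-accuracy score of a candidate pair is its equilibrium
probability over the Boltzmann ensemble of pseudoknot-free structures.
Because that ensemble cannot represent crossings, the current structure is
decomposed into levels and one base-pair probability matrix is computed per
level, with the level's pairs enforced as hard constraints (conditional
probability 1) and every position paired in another level forbidden to
pair. The per-level matrices are summed entrywise into the
pseudo-probability matrix p(i, j); entries may exceed 1 and are
deliberately not renormalized. When no structure is available the loop
starts from a single unconstrained matrix.

### Internal folding engine

The default backend is a self-contained McCaskill-style inside–outside
recursion over a deliberately small energy model:

* **Stacking**: each stacked pair of pairs (i,j)/(i+1,j−1) contributes a
  sequence-dependent stacking free energy from an embedded 36-entry
  nearest-neighbor table (kcal/mol at 37 °C, RT = 0.6163 kcal/mol).
* **Pair initiation**: every pair additionally costs
  `PAIR_PENALTY` = +1.0 kcal/mol. This single term is the model's proxy
  for the loop-closure entropy of the full nearest-neighbor model; without
  it, two-pair helices are thermodynamically free and the ensemble fills
  up with spurious short stems. The value is of the order of per-pair
  loop-penalty shares in the Turner model and is shared by the recursion,
  the alignment consensus model, and the enumeration oracle, so the
  engine/oracle equivalence tests exercise exactly the deployed model.
* Isolated pairs are *permitted* at this stage; the integer program
  forbids them downstream.

Probabilities are obtained by an exact outside pass (no sampling); entries
below 1e−12 are truncated to zero. On sequences up to ~25 nt the matrix is
verified entrywise (≤ 1e−9) against Boltzmann frequencies from exhaustive
enumeration of all constraint-compatible structures — an oracle written
independently of the recursion. The ViennaRNA programs (RNAfold /
RNAalifold with constraint strings) are available as an external backend
when full Turner-model fidelity is wanted; backends are interchangeable
behind one interface.

### Alignment consensus model

With an alignment, the internal model folds the ungapped target sequence
with three modifications per column pair: (i) stacking energies are
averaged over the rows in which the stack is canonical; (ii) a covariance
bonus of −1.0 kcal/mol per distinct additional canonical nucleotide
combination observed across rows (saturating at 2 — further combinations
add no evidence) rewards compensatory substitutions; (iii) a penalty of
+1.0 kcal/mol times the fraction of rows that cannot form the pair
(including gapped rows) punishes unsupported pairs, and pairs canonical in
fewer than half the rows are dropped entirely. An alignment whose rows are
all identical to the target short-circuits to the single-sequence engine,
so the degenerate case is bit-for-bit identical. The external backend
delegates to RNAalifold and projects the consensus matrix onto target
coordinates.

## Motif catalog and matching

A motif is an ordered list of 5′→3′ strand patterns over {A, C, G, U, \*}
(\* matches anything): hairpins have one strand, interior loops and bulges
two, k-way junctions k. Catalogs are tab-separated text (id, provenance
class, comma-separated strands); the provenance class supports
blacklisting, e.g. removing all motifs that originate from the same
nonredundant structure class as a benchmark target. Matching reports every
occurrence of every strand; a motif is a candidate only if *all* its
strands match somewhere. Geometric consistency is left to the optimizer.

In alignment mode a placement is eligible if it perfectly matches the
target (always true for matcher output) or if at least 50% of rows are
within Hamming distance 1 of the strand over those columns (gaps count as
mismatches, wildcards as matches). Its weight is the fraction of rows
within distance 1, floored at ε = 0.05 so that target-supported motifs
without row support keep a positive objective weight; the weight attached
to the strand-1 variable of a multi-strand motif is the mean over strands
of the best weight available for each strand.

## The integer program

Variables, objective and constraints are listed in the README and in
`ip_optimizer`'s module docstring. Points worth recording:

* **Scale and weights.** The factor 10 normalizes pairing-probability mass
  against the |x|² motif bonus so α is easy to calibrate; α defaults to
  0.1; β = (0.5, 0.25, 0.125, 0.0625) geometrically discounts higher
  levels, concentrating pairs at low levels. Up to m = 4 levels are
  supported; the default is m = 3.
* **Hierarchy.** A level-q pair must cross at least one *selected* pair at
  every lower level — not only the level immediately below; crossing is not
  transitive, so the weaker constraint would admit solutions the
  independent validator rejects.
* **Stacking.** No lonely pairs: D_{u,v}^q ≤ D_{u−1,v+1}^q + D_{u+1,v−1}^q
  (missing candidates dropped; a pair with no stacked neighbor in B is
  fixed to 0). This is the per-pair helix form, strictly stronger than a
  per-endpoint neighborhood rule.
* **Coverage.** 2·ΣD ≥ 0.25·n by default; infeasibility is reported, never
  silently relaxed (`--min-paired-fraction 0` is the escape hatch).
* **Motif geometry.** Strand linkage, 5′→3′ ordering, pairwise
  disjointness, and junction anchoring are encoded with auxiliary
  junction-matching binaries Y(p→p′) between placements of consecutive
  strands (cyclically, last strand back to first). Row/column sums tie Y to
  C; order-preservation cuts forbid crossing matches, which makes the
  matching the unique order-preserving one — the r-th selected occurrence
  of each strand belongs to the r-th insertion. Each Y is bounded by its
  junction's level-1 anchor pairs: the stacked pair (a+1, b−1) or the
  one-position overlap (a, b) for an inner junction, and (k−1, l+1) or
  (k, l) enclosing the whole occurrence for the closure (hairpins reduce to
  the closure alone). The motif-clash rule excludes only pair endpoints
  *strictly inside* an inserted interval, so overlap anchors remain legal.
  Multiple simultaneous occurrences of one motif are allowed under these
  rules.
* **Solving.** The model is solver-agnostic (deterministic variable and
  constraint order, LP export for debugging); the default backend is HiGHS
  via `scipy.optimize.milp`, which is deterministic for a fixed model, so
  fixed inputs give byte-identical results. Every returned assignment is
  re-checked by an independent validator that re-implements the feasibility
  rules directly on the solution; the reported objective is recomputed from
  the assignment (tolerance 1e−6). A brute-force optimizer (exhaustive over
  |B| ≤ 18, ≤ 8 placements) provides the exactness oracle; HiGHS matches it
  on 100 random small instances per test run.

## The iteration

Each round feeds the *full layered solution* (all levels) to the next
round's constrained folding; motif insertions influence the next round only
through that structure. Termination: identical consecutive solutions
(compared on canonical pair/insertion serialization, never on floating
objectives), the iteration cap (default 3), or the global time budget
(default 10⁴ s, shared across iterations; a solver timeout with an
incumbent is used and flagged in the trace). The objective is typically
non-decreasing across iterations — constrained probabilities sharpen toward
1 — but this is an observation, not a guarantee, and is asserted only on
fixtures where it holds.

## Synthetic fixtures: what they emulate and what they do not

The generators plant a known structure (default: an H-type pseudoknot of
two crossing 5-pair stems plus a trailing hairpin, n = 42) and build a
sequence around it:

* planted pairs get Watson-Crick combinations, redrawn until all planted
  helices are within 2 kcal/mol of each other — a much weaker stem would
  vanish from the single-sequence ensemble and be unrecoverable by any
  method;
* unpaired positions are purine-rich (70% A), as in GNRA-type loops,
  limiting chance complementarity; positions flanking helix ends are
  de-paired so planted helices do not silently extend;
* whole draws are rejected (up to 40 tries per seed) until every planted
  pair has unconstrained probability ≥ 0.1 and no spurious pair exceeds
  0.2.

These fixtures are *designed recoverability tests*: they certify that the
pipeline finds a dominant pseudoknot, inserts loop motifs where anchors
exist, and converges deterministically. They do not emulate arbitrary
natural sequences, where near-isoenergetic alternatives are common and
pseudoknot levels are typically under-predicted; passing them says nothing
about accuracy on such sequences. The toy catalogs contain the literal
loop sequences of the plant (achievable insertions) plus decoys matching
nowhere (negative controls). Toy alignments mutate rows at a configurable
rate with compensatory double substitutions at paired positions
(probability 0.9).

The compensatory-covariation demonstration (`compensatory_demo_fixture`) is
deterministic by construction: a moderate mixed-strength level-1 stem, a
weak all-A-U level-2 stem about 4 kcal/mol behind it (unconstrained pair
probabilities < 0.01, below the candidate threshold), and alignment rows
that swap every weak-stem pair A-U↔U-A — stacking-neutral, pure covariance.
The 1 kcal/mol-per-pair bonus lifts the weak stem into the candidate set
without burying the strong stem; single-sequence prediction scores F1 0.78
against the plant (0/5 weak-stem pairs), alignment mode 1.00 (5/5).

## Numerical and degenerate-input choices

* 0-based closed intervals internally; 1-based in all documents and
  reports.
* Probabilities < 1e−12 truncated; candidate threshold default 0.01;
  engine/oracle agreement asserted at 1e−9; objective bookkeeping at 1e−6.
* Zero-denominator metrics are 0 by convention; the motif-as-true-positive
  relaxation in scoring is off by default and explicit when on.
* T and lowercase input are normalized to U/uppercase; any other character
  is rejected (no N support — motif matching and canonicity are defined
  only over {A, C, G, U}).
* Dot-bracket supports bracket alphabets `()`, `[]`, `{}`, `<>`, `Aa`…`Zz`
  in that priority order; level decomposition uses exact minimum coloring
  (deterministic backtracking over helices sorted by size then 5′ start),
  with classes ranked so level 1 is the largest.
* Empty candidate sets with a positive coverage bound are reported
  infeasible before the solver is invoked.

## Known limitations

* The internal energy model is stacking + per-pair penalty only — no
  dangles, no loop-length dependence, no coaxial stacking; it is meant to
  be exhaustively verifiable, not to reproduce Turner-parameter
  probabilities (use the ViennaRNA backend for that).
* Double-precision partition functions overflow around n ≈ 130 for
  GC-rich sequences (no log-space rescaling); the intended scale is
  n ≤ ~100.
* The brute-force optimizer and the enumeration oracle are exponential by
  design and bounded accordingly.
* Motif insertion is by exact (wildcard) sequence match; probabilistic
  motif scoring is out of scope.
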