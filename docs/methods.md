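# Methods

This note documents the model implemented by `sepdesign`, the choices made
where the design was genuinely open, the synthetic ensembles used by the
surveys, and known limitations.

## Model

### Structures and trees

A secondary structure is a non-crossing set of base pairs over 1..n (1-based,
closed intervals), each position in at most one pair, and every pair (i, j)
enclosing at least θ positions (j − i − 1 ≥ θ). θ = 0 is the default (it
admits adjacent hairpins `()`, as required by the exhaustive small-length
censuses); θ = 3 is used for the length-100 surveys, matching the minimum
hairpin size of thermodynamically plausible targets. Structures are handled
as loop trees: internal nodes ↔ pairs, leaves ↔ unpaired positions, plus a
Root spanning the whole interval. A *helix* is a maximal chain of pair nodes
in which every non-terminal node has a single pair child and no leaf;
`h_min` is the shortest helix length (reported as `None`, not 0, for a
pair-free structure).

Two motifs make a target undesignable under base-pair maximization and are
screened before any solver runs: a loop carrying ≥ 5 pairs (`m5`) and a loop
carrying ≥ 3 pairs plus ≥ 1 unpaired position (`m3.`). The Root's closing
"pair" is never counted, so a Root loop with four pair children is fine.

### Colorings, levels, separation

Pair contents are encoded as colors: WHITE = C at 5'/G at 3', BLACK = G/C,
GRAY = A·U or U·A; unpaired positions always carry A. (The symmetric
convention — C on unpaired positions, swapped gray orientations — would work
equally well; exactly one convention is fixed and used throughout.) The level
of a node is the sum of δ over its strict ancestors (δ(WHITE) = +1,
δ(BLACK) = −1, δ(GRAY) = 0), with children of Root at level 0.

A coloring is **proper** when, for every loop, the vector made of the
complement of the closing color followed by the children colors contains at
most one WHITE, one BLACK, two GRAY — and no GRAY at all if the loop has an
unpaired position; the Root loop contributes children colors only. This
capacity table is a reconstruction (the original is only available as a
figure) from its documented consequences, all of which it reproduces: loops
with five pairs and loops with three pairs plus a leaf are uncolorable,
no parent or sibling of a leaf may be gray, white–black edges are forbidden
through the complement trick, and a gray node's three chains start with one
white, one black and one gray child. The reconstruction is further validated
by the exhaustive length-12 census, which lands exactly on the published
counts (8,111 separable structures; 7,690 at modulus 2, 420 at modulus 3).

A proper coloring is **separated** when gray-node levels and leaf levels are
disjoint, and **m-separated** when they are disjoint modulo m (negative
levels reduced into [0, m) mathematically). A sequence is m-separated when
its induced coloring is m-separated, unpaired positions are all A, and gray
orientations satisfy: equal for a gray pair stacked directly over a gray
pair, different for gray siblings in a loop. Every m-separated sequence is a
design; the test suite verifies this exhaustively over every structure up to
length 10 and by sampling at length 60.

### Decision DP and the 2^m loop

For a residue subset ξ_L ⊆ [0, m) reserved for leaf levels (gray nodes take
the complement), `d[v, c, l]` records whether the subtree under v can be
properly colored with v at color c and level residue l. Constraints: a gray
node's own residue avoids ξ_L; the children residue l' = (l + δ(c)) mod m
must lie in ξ_L whenever v carries a leaf; children color tuples are
enumerated from the capacity table (≤ 4 children after the motif screen, so
constant work per node). Root children sit at residue 0 and Root leaves force
0 ∈ ξ_L — no special-casing beyond the Root color vector. The DP is
iterative (explicit postorder), so 10⁴-node chains do not hit recursion
limits, and the backtrack picks the first feasible tuple in
WHITE < BLACK < GRAY order, making witnesses deterministic.

`solve` tries all 2^m subsets (all four at m = 2, not only {0} and {1}:
the two degenerate subsets cost nothing and uniformly cover leafless and
grayless inputs). Internally the sweep is a single set-valued DP pass —
each cell holds a bitmask over the 2^m subsets — which collapses the outer
loop into bigint AND/OR operations; a per-subset boolean table is then built
only for the one feasible subset that gets backtracked. The equivalence of
the two routes is tested exhaustively on small structures.

`min_separating_modulus` searches m = 2, 3, … (m-separability is not
monotone in m, so every modulus is tried) up to n, beyond which modulo
separation equals plain separation. The pair-free structure is reported at
m = 1; non-empty structures start at m = 2 because structures without gray
nodes are vacuously 1-separable under the bare definition, which would
collapse the census buckets (`start_at_two=False` exposes the bare
behaviour).

### Counting, uniform sampling, GC control

Replacing booleans by arbitrary-precision counts over pair contents
μ ∈ {CG, GC, AU, UA} gives `p[v, μ, l]`, the number of ξ_L-separated
sequences for the subtree under v (gray-content zero cases exactly as in the
decision DP, plus the gray orientation rules above). Backtracking with
choices weighted by child counts yields exactly uniform ξ_L-separated
sequences (integer arithmetic, `randrange` on exact cumulative weights — no
floating-point bias).

Uniformity over *all* m-separated sequences uses rejection: draw ξ_L with
probability #Designs(ξ_L)/Z_m, draw a sequence, accept with probability
1/Ξ_w where Ξ_w = 2^|Φ_w| and Φ_w collects the residues populated by neither
leaves nor grays. Z_m deliberately counts a sequence once per compatible
subset; the rejection corrects for exactly that multiplicity. The loop
restarts fully on rejection (this is what makes the proof of uniformity go
through) and a safety cap of 2^(m+6) iterations guards the expected ≤ 2^m
rejections.

GC bias multiplies each C·G/G·C choice by e^(2π) (two G+C nucleotides per
such pair). Weighted tables live in the log domain, so |π| up to ~60 is safe
by construction; at π = 0 the integer path is taken and weighted tables are
bit-for-bit the unweighted ones. For calibration, a separate DP computes the
partition function and expected #GC of the Boltzmann distribution over
*distinct* m-separated sequences — its state tracks the pair of (leaf-residue
mask, gray-residue mask), at most 3^m disjoint pairs, so no ξ_L multiplicity
enters — and `calibrate_pi` binary-searches π ∈ [−60, 60] to a default
tolerance of 10⁻³ on the expected GC fraction (E[GC] is nondecreasing in π).
Exactly-fixed-GC sampling calibrates toward the requested count and rejects
off-target draws; within a GC class all sequences share one Boltzmann weight,
so accepted draws are uniform on the class.

### Fold oracle

The verifier is a Nussinov-style DP over {G·C, A·U, G·U} with span
constraint θ (default 0, the strongest check: designs produced here remain
unique optima even without a hairpin-size restriction on competitors). The
co-optimal count uses the unambiguous "last position unpaired or paired at a
unique split" decomposition, so `num_optimal` is a count of distinct
structures; `is_design` then needs no witness comparison — if the target is
compatible, attains the optimum and the optimum is unique, the unique
optimum *is* the target. G·U is legal in folding even though designs never
place it on target pairs (separated designs beat any G·U-containing
alternative on pair count). `exhaustive_scan` streams all 4^n sequences in
base-4 counter order with an optional JSON checkpoint for resumability.

## Synthetic ensembles

The surveys need uniform random targets from three classes:

* **Unconstrained** structures (any θ): counted by the standard recursion and
  sampled by the recursive method with exact integer arithmetic.
* **Motif-free with all helices ≥ h** (h = 1, 2 or 3): counted by an
  unambiguous grammar — a component is a maximal helix (length ≥ h) over a
  loop that is a hairpin (≥ θ unpaired), a bulge/internal loop (one
  component, ≥ 1 unpaired), or a multiloop of 2–3 components with no
  unpaired position; the exterior loop holds ≤ 2 components with any number
  of unpaired positions, or 3–4 components with none. Sampling follows the
  same decomposition. Counts are validated against brute-force enumeration
  for small n. This grammar exists because pure rejection toward
  "all helices ≥ 3" at n = 100 has a vanishing acceptance probability; a
  pure-rejection sampler (`sample_structure_constrained`) is still provided
  for predicates with reasonable acceptance rates.

The **modulus survey** draws motif-free targets with no isolated base pair
and at least one length-2 helix (n = 100, θ = 3) — the "targets featuring
isolated stacks" class; a lax variant admitting isolated base pairs is one
flag away (`strict_helix=False`) but is dominated by isolated pairs and is
far less often 2-separable. The **GC survey** draws motif-free targets with
all helices ≥ 3 and, per target, one 2-separated design at π = 0, one at
π = −48 and one at π = +48. The extreme weights sit deep in saturation: the
sampled sequences are uniform over the minimum-GC (resp. maximum-GC) subsets
of the 2-separated set, and π = +18 was checked to give the same means as
π = +48.

These generators emulate target *shape* classes only. Real design targets
are not uniform random structures — they have correlated helix lengths, loop
size distributions shaped by thermodynamics, and non-A unpaired content — so
passing surveys says nothing about performance in nearest-neighbor energy
models; the guarantees proved here are specific to base-pair maximization.

## Problem sizes used by the checks

The test suite runs the exhaustive length-12 coloring census in full
(15,511 structures), the sequence-folding census at the reduced lengths 6
(cross-checked against structure-enumeration brute force) and 8 (designable
set ≡ separable set); the full 4¹² sequence census is hours-scale and is not
part of the default suite. The modulus survey runs at its full 10,000
targets and the GC survey at its full 1,000 targets. Property checks:
decision DP vs 3^k coloring enumeration (all structures to length 8 plus
random trees with ≤ 7 pairs, m ≤ 3, every ξ_L), counting DP vs 4^k sequence
enumeration (≤ 6 pairs), design certification of every 2-separated sequence
to length 10 and of sampled designs at length 60, 2-separability of 1,000
stable targets to length 120, and chi-square uniformity of the rejection
sampler against exhaustive enumeration at length 8 (10⁴ draws, p > 0.001).

## Numerical and degenerate-input choices

* Counts are Python big integers; weighted counts are log-domain doubles
  (−inf encodes zero); probabilities for weighted backtracking are
  normalized per node after subtracting the maximum log weight.
* Uniform choices use `random.Random.randrange` over exact integer totals;
  float roulette appears only in the weighted (π ≠ 0) path.
* Empty structures: length 0 parses to a valid structure; `h_min` is `None`;
  the minimal separating modulus of any pair-free structure is 1; sampling a
  pair-free target yields the all-A sequence.
* Backtracking ties break on the fixed WHITE < BLACK < GRAY /
  CG < GC < AU < UA enumeration order; gray orientation freedom defaults to
  A·U when no RNG is supplied.
* Dot-bracket enumeration is lexicographic under '.' < '(' < ')' — an
  arbitrary but fixed and tested order.

## Known limitations

* The GC-maximization survey concentrates near 58% mean GC here; the
  corresponding published figure is ~51% while the neutral and minimized
  statistics agree closely. The sampler itself is exact (verified against
  brute-force enumeration of max-GC sequence sets), so the residual gap
  traces to an unreproducible detail of the original positive-weight runs.
* The synchronization/object/hardness gadget builders reconstruct trees whose
  defining figure is not recoverable; they match the prose constraints and
  the checkable consequences (all-length-2 helices; never 2-separable yet
  separable at a larger modulus) and are test fixtures, not reference data.
* Pseudoknots are rejected at parse time; there is no Turner-model scoring,
  no ΔΔG machinery, and no "relaxed/unproper" sampler for multiloops of
  degree > 4 (the sequence-export CLI is the supported extension point).
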