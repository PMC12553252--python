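# sepdesign

Linear-time RNA inverse folding for targets without isolated stacks or base
pairs, via modulo-separated tree colorings, with exact uniform and
GC-controlled sampling of guaranteed designs.

## The problem

RNA *inverse folding* asks, for a target secondary structure *T* (a
non-crossing set of base pairs over positions 1..n), for a sequence
*w* ∈ {A,C,G,U}ⁿ whose **unique** base-pair-maximizing structure is *T*.
Even in this simple energy model the problem is NP-hard in general, yet large
families of targets turn out to be easy.

`sepdesign` works on the loop tree of the target: one internal node per base
pair, one leaf per unpaired position. Each pair node gets a color encoding
its content — **white** = C·G, **black** = G·C, **gray** = A·U/U·A — and
unpaired positions carry A. The *level* L(v) of a node counts white minus
black strict ancestors; it measures the G-vs-C imbalance between the inside
and outside of a pair, so any alternative pair bridging two different levels
loses base pairs. A coloring is *proper* when every loop satisfies the
capacities ≤1 white, ≤1 black, ≤2 gray (complement of the closing color
included), with no gray at all in loops holding an unpaired position; it is
*m-separated* when additionally gray-node levels and leaf levels are disjoint
modulo m. Every m-separated sequence is a design — this is the certificate
the whole toolkit is built on.

Key components:

* **Separability decision.** For a fixed subset ξ_L ⊆ [0, m) of residues
  reserved for leaf levels, a boolean DP over the tree decides feasibility in
  Θ(n·m); sweeping all 2^m subsets decides m-separability, and a set-valued
  (bitmask) variant decides all subsets in a single pass. A backtrack
  reconstructs a witness coloring in linear time.
* **Linear-time design.** Targets avoiding the undesignable motifs (a loop
  with five pairs, or three pairs plus an unpaired position) whose helices
  all have length ≥ 3 are *always* 2-separable: `design_linear` runs the
  m = 2 solver and extracts a certified design in linear time.
* **Exact sampling.** A counting version of the DP (arbitrary-precision)
  counts ξ_L-separated sequences and samples them uniformly; a rejection
  scheme with correction factor Ξ_w = 2^|Φ_w| makes the sampler exactly
  uniform over *all* m-separated sequences. A log-domain Boltzmann weight
  e^(π·#GC) biases the GC content, with exact calibration of π by binary
  search on a distinct-sequence expectation DP.
* **Fold oracle.** An unambiguous Nussinov-style DP (G·C, A·U and wobble G·U
  pairs) computes the optimal pair count *and* the exact number of co-optimal
  structures, certifying uniqueness — the ground truth behind every claim.

## Worked example

Design a sequence for a two-helix target, asking the fold oracle to certify
the result:

```
$ sepdesign design "(((((...)))))..((((....))))" --seed 7
>design m=2 seed=7 gc%=59.3 certified=True
CCCUCAAAGAGGGAAGGGGAAAACCCC
; coloring WWWGW..........BBBB........
```

The coloring line annotates the 5' position of every pair: the first helix is
colored white-white-white-gray-white (so its fourth pair is A·U), the second
helix black. `certified=True` means the Nussinov oracle confirmed the target
is the unique optimum for this sequence. The minimal separating modulus of
this target is 2:

```
$ sepdesign min-modulus "(((((...)))))..((((....))))"
2
```

Sample designs at a target GC fraction (the weight π_GC is calibrated by
binary search, then sequences are drawn from the Boltzmann distribution):

```
$ sepdesign sample "((((...))))" --num 3 --seed 1 --gc-target 0.4
calibrated pi_GC = -0.1758
>sample_0 m=2 xi_L=[0] seed=1 gc%=36.4
GUUCAAAGAAC
>sample_1 m=2 xi_L=[1] seed=1 gc%=54.5
GGAGAAACUCC
>sample_2 m=2 xi_L=[1] seed=1 gc%=54.5
UCCCAAAGGGA
```

Check any sequence/target pair:

```
$ sepdesign check GGGGAAACCCC "((((...))))"
PASS    max_bp=4        num_optimal=1   target_bp=4
```

Exhaustive censuses and the random-target surveys are exposed as
`sepdesign census`, `sepdesign survey-modulus` and `sepdesign survey-gc`
(TSV output, deterministic under `--seed`), or programmatically through
`sepdesign.experiments`.

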