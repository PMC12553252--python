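"""Independent brute-force oracles used to validate the dynamic programs.

Everything here enumerates explicitly (3^k colorings, 4^k content vectors,
all structures) and never calls the DP code paths it is used to check.
"""

from __future__ import annotations

import itertools

from sepdesign.coloring import Color, Coloring, is_proper, levels
from sepdesign.sampling import CONTENTS, is_separated_sequence
from sepdesign.structure import LoopTree


def residues_ok(t: LoopTree, chi: Coloring, m: int, xi: frozenset[int]) -> bool:
    lm = levels(t, chi)
    if any((l % m) not in xi for l in lm.leaf_levels.values()):
        return False
    for v in t.nodes:
        if chi[v.pair] == Color.GRAY and (lm.pair_levels[v.pair] % m) in xi:
            return False
    return True


def brute_decide(t: LoopTree, m: int, xi: frozenset[int]) -> bool:
    """Enumerate all 3^k colorings, filter by is_proper and residue rules."""
    for combo in itertools.product(list(Color), repeat=len(t.nodes)):
        chi = Coloring({v.pair: c for v, c in zip(t.nodes, combo)})
        if is_proper(t, chi) and residues_ok(t, chi, m, xi):
            return True
    return False


def sequences_for(t: LoopTree):
    """All 4^k content assignments rendered as sequences (unpaired = A)."""
    for combo in itertools.product(range(4), repeat=len(t.nodes)):
        bases = ["A"] * (t.n + 1)
        for v, mu in zip(t.nodes, combo):
            b5, b3 = CONTENTS[mu]
            bases[v.i] = b5
            bases[v.j] = b3
        yield "".join(bases[1:])


def brute_count_xi(t: LoopTree, m: int, xi: frozenset[int]) -> int:
    """Number of xi_L-separated sequences by explicit enumeration."""
    from sepdesign.coloring import SequenceError, coloring_from_sequence

    cnt = 0
    for w in sequences_for(t):
        try:
            chi = coloring_from_sequence(t, w)
        except SequenceError:  # pragma: no cover - all contents are legal
            continue
        if not is_proper(t, chi):
            continue
        if not residues_ok(t, chi, m, xi):
            continue
        if not is_separated_sequence(t, w, m):
            continue
        cnt += 1
    return cnt


def all_m_separated_sequences(t: LoopTree, m: int) -> list[str]:
    return [w for w in sequences_for(t) if is_separated_sequence(t, w, m)]


def loop_pair_and_leaf_counts(t: LoopTree):
    """Naive per-loop (pairs, unpaired) counter, Root first."""
    out = [(len(t.root_children), len(t.root_leaves))]
    for v in t.nodes:
        out.append((1 + len(v.children), len(v.leaves)))
    return out
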