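"""Tree colorings, levels, properness and (modulo-)separation predicates.

Each pair node of a loop tree receives one of three colors encoding the pair
content of any derived sequence: WHITE = C at the 5' position / G at the 3'
position, BLACK = G/C, GRAY = A.U or U.A; unpaired positions carry A.  The
*level* of a node is the signed count of WHITE minus BLACK strict ancestors
(Root excluded); it measures the G-vs-C imbalance a pair induces between its
inside and outside intervals, so any alternative pair bridging two levels
loses base pairs.

A coloring is *proper* when, in every loop, the vector formed by the
complement of the closing color and the children colors contains at most one
WHITE, one BLACK and two GRAY entries, and no GRAY at all when the loop holds
an unpaired position (the Root loop has no closing entry).  A proper coloring
is *separated* when gray-node levels and leaf levels are disjoint, and
*m-separated* when they are disjoint modulo ``m`` (negative levels reduced
into ``[0, m)``).  Separation is a sufficient condition for every derived
sequence to be a design under base-pair maximization.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

from .structure import LoopTree, PairNode


class Color(IntEnum):
    WHITE = 0
    BLACK = 1
    GRAY = 2


WHITE, BLACK, GRAY = Color.WHITE, Color.BLACK, Color.GRAY

#: level increment per color (WHITE opens a G-excess, BLACK a C-excess)
DELTA = {WHITE: +1, BLACK: -1, GRAY: 0}

_COMPLEMENT = {WHITE: BLACK, BLACK: WHITE, GRAY: GRAY}

#: pair content (5', 3') for each color; GRAY may also be (U, A)
COLOR_CONTENT = {WHITE: ("C", "G"), BLACK: ("G", "C"), GRAY: ("A", "U")}

_CONTENT_COLOR = {
    ("C", "G"): WHITE,
    ("G", "C"): BLACK,
    ("A", "U"): GRAY,
    ("U", "A"): GRAY,
}


def delta(c: Color) -> int:
    """Level increment induced by color ``c``."""
    return DELTA[Color(c)]


def complement(c: Color) -> Color:
    """Color involution: WHITE <-> BLACK, GRAY fixed."""
    return _COMPLEMENT[Color(c)]


class Coloring(dict):
    """Mapping ``(i, j) pair -> Color`` over a fixed loop tree.

    Plain dict subclass keyed by pair tuples; Root and leaves are never
    assigned.
    """

    def color_of(self, v: PairNode) -> Color:
        return self[v.pair]

    def to_annotation(self, t: LoopTree) -> str:
        """Serialize as a string aligned with the dot-bracket: W/B/G at the 5'
        position of each pair, '.' elsewhere."""
        chars = ["."] * t.n
        letter = {WHITE: "W", BLACK: "B", GRAY: "G"}
        for v in t.nodes:
            chars[v.i - 1] = letter[self[v.pair]]
        return "".join(chars)

    @classmethod
    def from_annotation(cls, t: LoopTree, text: str) -> "Coloring":
        out = cls()
        code = {"W": WHITE, "B": BLACK, "G": GRAY}
        for v in t.nodes:
            out[v.pair] = code[text[v.i - 1]]
        return out


@dataclass
class LevelMap:
    """Levels of pair nodes (keyed by pair) and leaves (keyed by position)."""

    pair_levels: dict[tuple[int, int], int]
    leaf_levels: dict[int, int]

    def gray_levels(self, chi: Coloring) -> set[int]:
        return {
            lvl for pair, lvl in self.pair_levels.items() if chi[pair] == GRAY
        }


def loop_color_vector(
    t: LoopTree, v: PairNode | None, chi: Coloring
) -> list[Color]:
    """Color vector ``C`` of the loop closed by ``v`` (None = Root): the
    complement of the closing color followed by the children colors."""
    if v is None:
        return [chi[c.pair] for c in t.root_children]
    return [complement(chi[v.pair])] + [chi[c.pair] for c in v.children]


def _loop_ok(vector: list[Color], has_leaf: bool) -> bool:
    w = vector.count(WHITE)
    b = vector.count(BLACK)
    g = vector.count(GRAY)
    if has_leaf and g > 0:
        return False
    return w <= 1 and b <= 1 and g <= 2


def is_proper(t: LoopTree, chi: Coloring) -> bool:
    """Per-loop capacity check: <=1 WHITE, <=1 BLACK, <=2 GRAY, and no GRAY in
    a loop containing an unpaired position."""
    if not _loop_ok(loop_color_vector(t, None, chi), bool(t.root_leaves)):
        return False
    for v in t.nodes:
        if not _loop_ok(loop_color_vector(t, v, chi), bool(v.leaves)):
            return False
    return True


def levels(t: LoopTree, chi: Coloring) -> LevelMap:
    """Level of every pair node and leaf: sum of deltas over strict ancestors."""
    pair_levels: dict[tuple[int, int], int] = {}
    leaf_levels: dict[int, int] = {}

    def rec(v: PairNode, lvl: int) -> None:
        pair_levels[v.pair] = lvl
        below = lvl + DELTA[chi[v.pair]]
        for pos in v.leaves:
            leaf_levels[pos] = below
        for c in v.children:
            rec(c, below)

    for c in t.root_children:
        rec(c, 0)
    for pos in t.root_leaves:
        leaf_levels[pos] = 0
    return LevelMap(pair_levels, leaf_levels)


def is_separated(t: LoopTree, chi: Coloring) -> bool:
    """Proper, and gray-node levels disjoint from leaf levels."""
    if not is_proper(t, chi):
        return False
    lm = levels(t, chi)
    return not (lm.gray_levels(chi) & set(lm.leaf_levels.values()))


def is_m_separated(t: LoopTree, chi: Coloring, m: int) -> bool:
    """Proper, and gray levels disjoint from leaf levels modulo ``m``.

    Python's ``%`` already reduces negative levels into ``[0, m)``, which is
    the mathematical convention used here.
    """
    if m < 1:
        raise ValueError("modulus must be >= 1")
    if not is_proper(t, chi):
        return False
    lm = levels(t, chi)
    grays = {lvl % m for lvl in lm.gray_levels(chi)}
    leaves = {lvl % m for lvl in lm.leaf_levels.values()}
    return not (grays & leaves)


class SequenceError(ValueError):
    """Sequence incompatible with the target or the coloring conventions."""


def coloring_from_sequence(t: LoopTree, w: str, strict: bool = True) -> Coloring:
    """Coloring chi_w induced by a sequence compatible with the target.

    Every target pair must carry C.G, G.C, A.U or U.A (G.U is rejected: it is
    never assigned to target pairs, as it loses base pairs against any
    separated design).  In strict mode all unpaired positions must be A.
    """
    w = w.upper().replace("T", "U")
    if len(w) != t.n:
        raise SequenceError(f"sequence length {len(w)} != structure length {t.n}")
    chi = Coloring()
    for v in t.nodes:
        content = (w[v.i - 1], w[v.j - 1])
        color = _CONTENT_COLOR.get(content)
        if color is None:
            raise SequenceError(
                f"pair ({v.i},{v.j}) carries {content[0]}.{content[1]}, "
                "expected one of C.G, G.C, A.U, U.A"
            )
        chi[v.pair] = color
    if strict:
        for v in t.nodes:
            for pos in v.leaves:
                if w[pos - 1] != "A":
                    raise SequenceError(f"unpaired position {pos} is not A")
        for pos in t.root_leaves:
            if w[pos - 1] != "A":
                raise SequenceError(f"unpaired position {pos} is not A")
    return chi


def min_separating_modulus(
    t: LoopTree,
    solver=None,
    max_m: int | None = None,
    start_at_two: bool = True,
) -> int | None:
    """Smallest modulus in the search schedule admitting a separated coloring.

    The schedule reports 1 for the pair-free (empty) structure and otherwise
    starts at m = 2: pair-free targets are the only ones bucketed at m = 1 in
    exhaustive censuses, while structures without gray nodes are vacuously
    1-separable under the bare definition (exposed via ``start_at_two=False``).
    Returns None when no modulus up to ``max_m`` (default: n, beyond which
    modulo separation equals plain separation) works.
    """
    from .separability import solve as _solve

    solver = solver or _solve
    if not t.nodes:
        return 1
    if max_m is None:
        max_m = max(2, t.n)
    start = 2 if start_at_two else 1
    for m in range(start, max_m + 1):
        if solver(t, m) is not None:
            return m
    return None
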