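"""Secondary structures, loop trees, helices, motifs and structure ensembles.

A (pseudoknot-free) secondary structure on ``n`` nucleotides is a set of base
pairs ``(i, j)`` with ``1 <= i < j <= n`` such that every position belongs to at
most one pair, pairs are pairwise non-crossing, and every pair encloses at
least ``theta`` unpaired-or-paired positions (``j - i - 1 >= theta``).

Structures are viewed as rooted ordered trees: one internal node per base pair,
one leaf per unpaired position, plus a special ``Root`` spanning ``[1, n]``.
A *loop* is a node together with its direct children.  A *helix* is a maximal
chain of stacked pairs; ``h_min`` denotes the shortest helix length of a
structure.  Two local motifs make a structure undesignable under base-pair
maximization: a loop carrying five pairs (``m5``) and a loop carrying three
pairs plus an unpaired position (``m3.``); the Root's closing "pair" is never
counted.

The module also provides exact counting, lexicographic enumeration, uniform
sampling (by the recursive method), uniform sampling inside motif-constrained
classes, and the gadget trees used as hardness fixtures.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from functools import lru_cache
from math import comb
from typing import Callable, Iterator, Sequence


class StructureError(ValueError):
    """Raised for malformed dot-bracket input or invalid pair sets."""


# ---------------------------------------------------------------------------
# Core data types
# ---------------------------------------------------------------------------


class SecondaryStructure:
    """An RNA secondary structure: length, non-crossing pair set, theta.

    Positions are 1-based and intervals closed.  ``theta`` is the minimum
    number of positions a pair must enclose (``j - i - 1 >= theta``); the
    default 0 permits adjacent hairpins such as ``()``.
    """

    __slots__ = ("n", "pairs", "theta")

    def __init__(self, n: int, pairs=(), theta: int = 0, validate: bool = True):
        self.n = int(n)
        self.pairs = frozenset((int(i), int(j)) for i, j in pairs)
        self.theta = int(theta)
        if validate:
            self._validate()

    def _validate(self) -> None:
        if self.n < 0:
            raise StructureError("negative length")
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (1 <= i < j <= self.n):
                raise StructureError(f"pair ({i},{j}) out of range 1..{self.n}")
            if j - i - 1 < self.theta:
                raise StructureError(
                    f"pair ({i},{j}) encloses {j - i - 1} < theta={self.theta}"
                )
            if i in seen or j in seen:
                raise StructureError(f"position reused by pair ({i},{j})")
            seen.add(i)
            seen.add(j)
        # non-crossing: scan pairs sorted by opening position with a stack
        stack: list[int] = []
        for i, j in sorted(self.pairs):
            while stack and stack[-1] < i:
                stack.pop()
            if stack and stack[-1] < j:
                raise StructureError(f"crossing pair ({i},{j})")
            stack.append(j)

    # -- serialization ------------------------------------------------------

    @classmethod
    def from_dotbracket(cls, text: str, theta: int = 0) -> "SecondaryStructure":
        return parse_dotbracket(text, theta)

    def to_dotbracket(self) -> str:
        return write_dotbracket(self)

    # -- helpers ------------------------------------------------------------

    def partner(self) -> list[int]:
        """0 for unpaired, else the partner, indexed 1..n (index 0 unused)."""
        p = [0] * (self.n + 1)
        for i, j in self.pairs:
            p[i] = j
            p[j] = i
        return p

    def unpaired_positions(self) -> list[int]:
        p = self.partner()
        return [i for i in range(1, self.n + 1) if p[i] == 0]

    def __len__(self) -> int:
        return len(self.pairs)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SecondaryStructure)
            and self.n == other.n
            and self.pairs == other.pairs
        )

    def __hash__(self) -> int:
        return hash((self.n, self.pairs))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"SecondaryStructure({self.to_dotbracket()!r}, theta={self.theta})"


class PairNode:
    """Internal node of a loop tree: one base pair and its direct loop."""

    __slots__ = ("i", "j", "parent", "children", "leaves")

    def __init__(self, i: int, j: int):
        self.i = i
        self.j = j
        self.parent: "PairNode | None" = None  # None = child of Root
        self.children: list["PairNode"] = []  # pair-node children, 5'->3'
        self.leaves: list[int] = []  # unpaired positions of the loop

    @property
    def pair(self) -> tuple[int, int]:
        return (self.i, self.j)

    def __repr__(self) -> str:  # pragma: no cover
        return f"PairNode({self.i},{self.j})"


class LoopTree:
    """Rooted ordered tree of pair nodes and unpaired leaves.

    ``root_children`` and ``root_leaves`` describe the exterior (Root) loop;
    ``nodes`` lists all pair nodes in preorder (5' order).
    """

    __slots__ = ("structure", "root_children", "root_leaves", "nodes")

    def __init__(self, structure: SecondaryStructure):
        self.structure = structure
        self.root_children: list[PairNode] = []
        self.root_leaves: list[int] = []
        self.nodes: list[PairNode] = []
        self._build()

    def _build(self) -> None:
        partner = self.structure.partner()
        stack: list[PairNode] = []
        i = 1
        while i <= self.structure.n:
            j = partner[i]
            if j == 0:
                if stack:
                    stack[-1].leaves.append(i)
                else:
                    self.root_leaves.append(i)
                i += 1
            elif j > i:
                node = PairNode(i, j)
                if stack:
                    node.parent = stack[-1]
                    stack[-1].children.append(node)
                else:
                    self.root_children.append(node)
                self.nodes.append(node)
                stack.append(node)
                i += 1
            else:  # closing bracket
                stack.pop()
                i += 1

    def to_structure(self) -> SecondaryStructure:
        return self.structure

    @property
    def n(self) -> int:
        return self.structure.n


@dataclass(frozen=True)
class Helix:
    """Maximal chain of stacked pairs, outermost first."""

    nodes: tuple[PairNode, ...]

    @property
    def length(self) -> int:
        return len(self.nodes)


@dataclass(frozen=True)
class MotifReport:
    """Outcome of the forbidden-motif scan (m5 and m3.)."""

    has_m5: bool
    has_m3dot: bool
    witnesses: tuple[tuple[int, int] | None, ...] = ()

    @property
    def designable_by_motifs(self) -> bool:
        """False iff an undesignable motif was found (necessary condition only)."""
        return not (self.has_m5 or self.has_m3dot)


# ---------------------------------------------------------------------------
# Parsing / writing
# ---------------------------------------------------------------------------


def parse_dotbracket(text: str, theta: int = 0) -> SecondaryStructure:
    """Parse a dot-bracket string over ``(``, ``)``, ``.`` (1-based pairs)."""
    text = text.strip()
    pairs = []
    stack = []
    for pos, ch in enumerate(text, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {pos}")
            pairs.append((stack.pop(), pos))
        elif ch != ".":
            raise StructureError(f"illegal character {ch!r} at position {pos}")
    if stack:
        raise StructureError(f"unmatched '(' at position {stack[-1]}")
    return SecondaryStructure(len(text), pairs, theta=theta)


def write_dotbracket(s: SecondaryStructure) -> str:
    chars = ["."] * s.n
    for i, j in s.pairs:
        chars[i - 1] = "("
        chars[j - 1] = ")"
    return "".join(chars)


def read_dotbracket_file(lines) -> list[SecondaryStructure]:
    """Read one structure per line; blank lines and '#' comments are skipped."""
    out = []
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        out.append(parse_dotbracket(line))
    return out


def build_loop_tree(s: SecondaryStructure) -> LoopTree:
    return LoopTree(s)


# ---------------------------------------------------------------------------
# Helices and motifs
# ---------------------------------------------------------------------------


def helices(t: LoopTree) -> list[Helix]:
    """Decompose the pair nodes of ``t`` into maximal helices.

    A node extends the helix of its parent iff it is the parent's only child
    and the parent's loop has no unpaired position.
    """
    out: list[Helix] = []
    def _continues(parent: PairNode) -> bool:
        return len(parent.children) == 1 and not parent.leaves

    starts = [v for v in t.nodes if v.parent is None or not _continues(v.parent)]
    for start in starts:
        chain = [start]
        while _continues(chain[-1]):
            chain.append(chain[-1].children[0])
        out.append(Helix(tuple(chain)))
    return out


def h_min(t: LoopTree) -> int | None:
    """Shortest helix length, or None for a structure without pairs."""
    hs = helices(t)
    if not hs:
        return None
    return min(h.length for h in hs)


def detect_forbidden(t: LoopTree) -> MotifReport:
    """Scan every loop for the undesignable motifs m5 and m3. .

    For an internal loop closed by node ``v``: pairs = closing pair + pair
    children; for the Root loop only the children count.  ``m5`` fires when a
    loop holds >= 5 pairs; ``m3.`` when a loop holds >= 3 pairs and >= 1
    unpaired position.
    """
    has_m5 = False
    has_m3 = False
    witnesses: list[tuple[int, int] | None] = []

    def _check(closing: PairNode | None, n_children: int, n_leaves: int) -> None:
        nonlocal has_m5, has_m3
        k = n_children + (1 if closing is not None else 0)
        if k >= 5:
            has_m5 = True
            witnesses.append(closing.pair if closing else None)
        if k >= 3 and n_leaves >= 1:
            has_m3 = True
            witnesses.append(closing.pair if closing else None)

    _check(None, len(t.root_children), len(t.root_leaves))
    for v in t.nodes:
        _check(v, len(v.children), len(v.leaves))
    return MotifReport(has_m5, has_m3, tuple(witnesses))


def is_motif_free(t: LoopTree) -> bool:
    return detect_forbidden(t).designable_by_motifs


# ---------------------------------------------------------------------------
# Counting / enumeration / uniform sampling (unconstrained ensemble)
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _count_table(n: int, theta: int) -> tuple[int, ...]:
    """s[l] = number of structures on l positions with span constraint theta."""
    s = [0] * (n + 1)
    s[0] = 1
    for length in range(1, n + 1):
        total = s[length - 1]  # first position unpaired
        # first position paired with position d+2 (d enclosed positions)
        for d in range(theta, length - 1):
            total += s[d] * s[length - d - 2]
        s[length] = total
    return tuple(s)


def count_structures(n: int, theta: int = 0) -> int:
    """Exact number of secondary structures of length ``n`` (theta-constrained)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    return _count_table(n, theta)[n]


def enumerate_structures(n: int, theta: int = 0) -> Iterator[SecondaryStructure]:
    """Yield every structure exactly once, in dot-bracket lexicographic order
    with ``.`` < ``(`` < ``)``."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        yield SecondaryStructure(0, (), theta=theta)
        return

    chars: list[str] = []
    pairs: list[tuple[int, int]] = []
    stack: list[int] = []

    def rec(pos: int) -> Iterator[SecondaryStructure]:
        if pos > n:
            if not stack:
                yield SecondaryStructure(n, list(pairs), theta=theta, validate=False)
            return
        remaining = n - pos + 1
        # '.' branch
        if remaining - 1 >= len(stack):
            chars.append(".")
            yield from rec(pos + 1)
            chars.pop()
        # '(' branch: needs at least theta + 1 further positions to close
        if remaining - 1 >= len(stack) + 1 + theta:
            stack.append(pos)
            chars.append("(")
            yield from rec(pos + 1)
            chars.pop()
            stack.pop()
        # ')' branch
        if stack and pos - stack[-1] - 1 >= theta and remaining - 1 >= len(stack) - 1:
            i = stack.pop()
            pairs.append((i, pos))
            chars.append(")")
            yield from rec(pos + 1)
            chars.pop()
            pairs.pop()
            stack.append(i)

    yield from rec(1)


def sample_structure(
    n: int, theta: int, rng: random.Random
) -> SecondaryStructure:
    """Exactly uniform draw by the recursive method over the count table."""
    s = _count_table(n, theta)
    pairs: list[tuple[int, int]] = []

    def rec(lo: int, length: int) -> None:
        # fill positions lo .. lo+length-1
        while length > 0:
            r = rng.randrange(s[length])
            if r < s[length - 1]:
                lo += 1
                length -= 1
                continue
            r -= s[length - 1]
            for d in range(theta, length - 1):
                w = s[d] * s[length - d - 2]
                if r < w:
                    pairs.append((lo, lo + d + 1))
                    rec(lo + 1, d)
                    lo += d + 2
                    length -= d + 2
                    break
                r -= w
            else:  # pragma: no cover - unreachable by construction
                raise AssertionError("sampling overflow")

    rec(1, n)
    return SecondaryStructure(n, pairs, theta=theta, validate=False)


def sample_structure_constrained(
    n: int,
    theta: int,
    predicate: Callable[[SecondaryStructure], bool],
    rng: random.Random,
    max_tries: int = 1_000_000,
) -> SecondaryStructure:
    """Uniform over structures satisfying ``predicate`` via pure rejection."""
    for _ in range(max_tries):
        s = sample_structure(n, theta, rng)
        if predicate(s):
            return s
    raise RuntimeError(
        f"rejection sampling failed: acceptance below 1/{max_tries}; "
        "use a dedicated ensemble for rare classes"
    )


# ---------------------------------------------------------------------------
# Motif-constrained ensembles (exact counting grammar)
# ---------------------------------------------------------------------------


class ConstrainedEnsemble:
    """Uniform ensemble of motif-free structures with a minimum helix length.

    The class of structures avoiding ``m5`` and ``m3.`` whose helices all have
    length >= ``min_helix`` decomposes unambiguously:

    * a *component* is a maximal helix of length ``h >= min_helix`` stacked
      over a loop;
    * a loop under a helix is a hairpin (``u >= theta`` unpaired), a
      bulge/internal loop (one component, ``u >= 1`` unpaired) or a multiloop
      of 2 or 3 components with no unpaired position (3. and m5 exclusion);
      the case "one component, no unpaired" is excluded by helix maximality;
    * the exterior (Root) loop holds ``p`` components and ``u`` unpaired
      positions with ``p <= 2`` (any ``u``) or ``p in {3, 4}`` and ``u = 0``.

    Counting these compositions gives exact uniform sampling by the recursive
    method; this replaces hopeless rejection rates for rare classes such as
    ``min_helix = 3`` at ``n = 100``.
    """

    def __init__(self, n: int, theta: int = 3, min_helix: int = 1):
        if min_helix < 1:
            raise ValueError("min_helix must be >= 1")
        self.n = n
        self.theta = theta
        self.min_helix = min_helix
        self._tables()

    def _tables(self) -> None:
        n, theta, hmin = self.n, self.theta, self.min_helix
        comp = [0] * (n + 1)  # component: maximal helix + its loop
        loop = [0] * (n + 1)  # loop content under the innermost helix pair
        comp2 = [0] * (n + 1)  # ordered pairs of components (convolution)
        comp3 = [0] * (n + 1)
        # loop[L] needs comp[<L] (and comp2/comp3[L], themselves over comp[<L]);
        # comp[L] needs loop[<=L-2*hmin]; so a single ascending pass suffices.
        for L in range(0, n + 1):
            comp2[L] = sum(comp[a] * comp[L - a] for a in range(1, L))
            comp3[L] = sum(comp[a] * comp2[L - a] for a in range(1, L))
            total = 1 if L >= theta else 0  # hairpin
            for c in range(1, L):  # bulge/internal: one component, u >= 1
                if comp[c]:
                    total += comp[c] * (L - c + 1)
            total += comp2[L] + comp3[L]  # multiloops of 2 or 3 components
            loop[L] = total
            comp[L] = sum(
                loop[L - 2 * h] for h in range(hmin, L // 2 + 1)
            )
        self._comp = comp
        self._loop = loop
        self._comp2 = comp2
        self._comp3 = comp3
        comp4 = [0] * (n + 1)
        for L in range(n + 1):
            comp4[L] = sum(comp[a] * comp3[L - a] for a in range(1, L))
        self._comp4 = comp4
        # exterior loop
        ext = 1  # p = 0, all unpaired
        for c in range(1, n + 1):  # p = 1
            if comp[c]:
                u = n - c
                ext += comp[c] * comb(u + 1, 1)
        for c in range(2, n + 1):  # p = 2 (ordered components via comp2)
            if comp2[c]:
                u = n - c
                ext += comp2[c] * comb(u + 2, 2)
        ext += comp3[n] + comp4[n]  # p = 3, 4 with u = 0
        self.count = ext

    # -- sampling -----------------------------------------------------------

    def sample(self, rng: random.Random) -> SecondaryStructure:
        if self.count == 0:
            raise RuntimeError("empty ensemble")
        n, theta = self.n, self.theta
        comp, comp2, comp3, comp4 = self._comp, self._comp2, self._comp3, self._comp4
        pairs: list[tuple[int, int]] = []

        def split_lengths(total: int, parts: int) -> list[int]:
            """Sample ordered component lengths (c_1..c_parts) summing to total,
            weighted by the product of comp counts."""
            out = []
            tables = {1: comp, 2: comp2, 3: comp3, 4: comp4}
            rem = total
            for k in range(parts, 1, -1):
                tab = tables[k - 1]
                r = rng.randrange(tables[k][rem])
                for a in range(1, rem):
                    w = comp[a] * tab[rem - a]
                    if r < w:
                        out.append(a)
                        rem -= a
                        break
                    r -= w
                else:  # pragma: no cover
                    raise AssertionError
            out.append(rem)
            return out

        def emit_component(lo: int, c: int) -> None:
            """Place a component (maximal helix + loop) on positions lo..lo+c-1."""
            # choose helix length h weighted by loop[c - 2h]
            weights = []
            hs = []
            for h in range(self.min_helix, c // 2 + 1):
                w = self._loop[c - 2 * h]
                if w:
                    hs.append(h)
                    weights.append(w)
            r = rng.randrange(sum(weights))
            for h, w in zip(hs, weights):
                if r < w:
                    break
                r -= w
            hi = lo + c - 1
            for k in range(h):
                pairs.append((lo + k, hi - k))
            emit_loop(lo + h, c - 2 * h)

        def emit_loop(lo: int, l: int) -> None:
            """Fill the loop content (length l) under a helix."""
            r = rng.randrange(self._loop[l])
            if l >= theta:  # hairpin
                if r < 1:
                    return
                r -= 1
            for c in range(1, l):  # bulge/internal
                if comp[c]:
                    u = l - c
                    w = comp[c] * (u + 1)
                    if r < w:
                        left = r // comp[c]  # unpaired on the 5' side
                        emit_component(lo + left, c)
                        return
                    r -= w
            if r < comp2[l]:  # multiloop, 2 components
                a, b = split_lengths(l, 2)
                emit_component(lo, a)
                emit_component(lo + a, b)
                return
            r -= comp2[l]
            a, b, c3 = split_lengths(l, 3)
            emit_component(lo, a)
            emit_component(lo + a, b)
            emit_component(lo + a + b, c3)

        def emit_exterior() -> None:
            r = rng.randrange(self.count)
            if r < 1:  # p = 0
                return
            r -= 1
            for c in range(1, n + 1):  # p = 1
                if comp[c]:
                    u = n - c
                    w = comp[c] * (u + 1)
                    if r < w:
                        left = r // comp[c]
                        emit_component(1 + left, c)
                        return
                    r -= w
            for c in range(2, n + 1):  # p = 2
                if comp2[c]:
                    u = n - c
                    w = comp2[c] * comb(u + 2, 2)
                    if r < w:
                        arr = r // comp2[c]
                        # decode arrangement index -> (u1, u2) with u1+u2 <= u
                        # ordered pairs (u1, u2): index = u1*(u+1) - u1(u1-1)/2 + u2 ... use search
                        idx = 0
                        for u1 in range(u + 1):
                            span = u - u1 + 1
                            if arr < idx + span:
                                u2 = arr - idx
                                break
                            idx += span
                        a, b = split_lengths(c, 2)
                        emit_component(1 + u1, a)
                        emit_component(1 + u1 + a + u2, b)
                        return
                    r -= w
            if r < comp3[n]:
                a, b, c3 = split_lengths(n, 3)
                emit_component(1, a)
                emit_component(1 + a, b)
                emit_component(1 + a + b, c3)
                return
            r -= comp3[n]
            a, b, c3, d = split_lengths(n, 4)
            emit_component(1, a)
            emit_component(1 + a, b)
            emit_component(1 + a + b, c3)
            emit_component(1 + a + b + c3, d)

        emit_exterior()
        return SecondaryStructure(n, pairs, theta=theta, validate=False)

    def sample_with(
        self,
        rng: random.Random,
        predicate: Callable[[SecondaryStructure], bool],
        max_tries: int = 200_000,
    ) -> SecondaryStructure:
        """Uniform over ensemble members satisfying ``predicate`` (rejection)."""
        for _ in range(max_tries):
            s = self.sample(rng)
            if predicate(s):
                return s
        raise RuntimeError("rejection sampling failed inside constrained ensemble")


# ---------------------------------------------------------------------------
# Hardness gadget fixtures
# ---------------------------------------------------------------------------


class _Gnode:
    __slots__ = ("children", "leaves")

    def __init__(self):
        self.children: list[_Gnode] = []
        self.leaves: int = 0


def _render(root_children: list[_Gnode], root_leaves: int = 0) -> LoopTree:
    def rec(v: _Gnode) -> str:
        inner = "".join(rec(c) for c in v.children) + "." * v.leaves
        return "(" + inner + ")"

    text = "".join(rec(c) for c in root_children) + "." * root_leaves
    return build_loop_tree(parse_dotbracket(text, theta=0))


def _chain(q: int, leaf_on_odd: bool = False) -> tuple[_Gnode, _Gnode]:
    """Chain of q nodes; optionally a leaf on every odd-index node (1-based)."""
    top = _Gnode()
    cur = top
    if leaf_on_odd:
        cur.leaves = 1
    for k in range(2, q + 1):
        nxt = _Gnode()
        if leaf_on_odd and k % 2 == 1:
            nxt.leaves = 1
        cur.children.append(nxt)
        cur = nxt
    return top, cur


def make_blocking_gadget(q: int) -> LoopTree:
    """Chain of ``q`` pair nodes with a leaf attached to every odd-index node."""
    if q < 1:
        raise ValueError("q must be >= 1")
    top, _ = _chain(q, leaf_on_odd=True)
    return _render([top])


def _sync_subtree(depth_left: int) -> _Gnode:
    """Synthetic reconstruction of the synchronization gadget (figure-only in
    the source literature): node ``r`` carries three chains of four pair nodes,
    each chain with a leaf on its second node; one chain continues into the
    next ``r`` while ``depth_left > 0``, giving total height H = 12."""
    r = _Gnode()
    n_chains = 3
    for c in range(n_chains):
        x1 = _Gnode()
        x2 = _Gnode()
        x2.leaves = 1
        x3 = _Gnode()
        x1.children.append(x2)
        x2.children.append(x3)
        if c == 0 and depth_left > 0:
            x4 = _sync_subtree(depth_left - 1)
        else:
            x4 = _Gnode()
        x3.children.append(x4)
        r.children.append(x1)
    return r


def make_synchronization_gadget() -> LoopTree:
    """Fixed-size tree whose separated colorings always use gray levels of both
    parities (so it is never 2-separable, yet separable at a larger modulus)."""
    return _render([_sync_subtree(2)])


def make_object_gadget(a: int, H: int = 12) -> LoopTree:
    """Chain of ``a + 1`` nodes with synchronization gadgets at both ends and a
    leaf on every even-index node beyond ``H``."""
    if a < H or a % 2 != 0:
        raise ValueError("a must be even and >= H")
    top = _Gnode()
    cur = top
    nodes = [top]
    for _ in range(a):
        nxt = _Gnode()
        cur.children.append(nxt)
        cur = nxt
        nodes.append(nxt)
    for idx in range(H + 2, a + 1, 2):  # even i > H (1-based index idx+? )
        nodes[idx - 1].leaves = 1
    nodes[0].children.append(_sync_subtree(2))
    nodes[-1].children.append(_sync_subtree(2))
    return _render([top])


def make_hardness_T(a: int, b: int) -> LoopTree:
    """Gadget ``T(a, b)``: a length-``a`` path to node ``t`` carrying three
    length-``b`` branches, a leaf on every node at even distance from the root
    except ``t``.  All helices have length 2."""
    if a < 2 or b < 2 or a % 2 or b % 2:
        raise ValueError("a and b must be even and >= 2")
    top = _Gnode()
    cur = top
    path = [top]  # depth 1 .. a; node t at depth a
    for _ in range(a - 1):
        nxt = _Gnode()
        cur.children.append(nxt)
        cur = nxt
        path.append(nxt)
    t = path[-1]
    for depth0, v in enumerate(path[:-1], start=1):
        if depth0 % 2 == 0:
            v.leaves = 1
    for _ in range(3):
        branch_top = _Gnode()
        bcur = branch_top
        if (a + 1) % 2 == 0:
            branch_top.leaves = 1
        for d in range(2, b + 1):
            nxt = _Gnode()
            if (a + d) % 2 == 0:
                nxt.leaves = 1
            bcur.children.append(nxt)
            bcur = nxt
        t.children.append(branch_top)
    return _render([top])


def make_gadget(kind: str, **kwargs) -> LoopTree:
    """Dispatch for the gadget builders: ``blocking(q)``, ``synchronization``,
    ``object(a)``, ``hardness_T(a, b)``."""
    if kind == "blocking":
        return make_blocking_gadget(kwargs["q"])
    if kind == "synchronization":
        return make_synchronization_gadget()
    if kind == "object":
        return make_object_gadget(kwargs["a"], kwargs.get("H", 12))
    if kind == "hardness_T":
        return make_hardness_T(kwargs["a"], kwargs["b"])
    raise ValueError(f"unknown gadget kind {kind!r}")
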