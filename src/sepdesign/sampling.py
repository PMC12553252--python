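"""Counting and sampling of modulo-separated design sequences.

The decision recurrence of :mod:`sepdesign.separability` lifts, by an algebra
change, to a counting recurrence ``p[v, mu, l]``: the number of sequences for
the subtree under ``v`` whose pair contents (``mu`` in {CG, GC, AU, UA}) form
a locally proper, ``xi_L``-consistent coloring with ``v`` at residue ``l``.
Unpaired positions always carry A.  Gray (A.U / U.A) contents obey two extra
rules inside a loop: gray siblings take different orientations, and a gray
pair stacked over a gray child keeps the same orientation.

A weighted variant multiplies each C.G / G.C choice by ``exp(2 * pi_GC)``
(two G+C nucleotides per such pair), giving Boltzmann control of the GC
content; weights are accumulated in the log domain so ``|pi_GC|`` up to ~60 is
safe.  At ``pi_GC = 0`` the integer path is used and counts are exact.

Uniformity over *all* m-separated sequences (not just one ``xi_L``) follows
the rejection scheme: draw ``xi_L`` proportionally to its design count, draw a
sequence, then accept with probability ``1 / Xi_w`` where ``Xi_w = 2^|Phi_w|``
counts the modular assignments compatible with the drawn sequence.
"""

from __future__ import annotations

import math
import random
import warnings
from dataclasses import dataclass
from functools import lru_cache
from itertools import product

from .coloring import (
    BLACK,
    GRAY,
    WHITE,
    Color,
    Coloring,
    is_m_separated,
    levels,
)
from .separability import ModularAssignment
from .structure import LoopTree, PairNode

# pair contents: index -> (5' base, 3' base); 0/1 are the G.C contents
CONTENTS = (("C", "G"), ("G", "C"), ("A", "U"), ("U", "A"))
CONTENT_NAMES = ("CG", "GC", "AU", "UA")
_CONTENT_COLOR = (WHITE, BLACK, GRAY, GRAY)
_CONTENT_DELTA = (1, -1, 0, 0)
_GC_PER_CONTENT = (2, 2, 0, 0)


@dataclass
class DesignSequence:
    """A designed RNA sequence together with its induced coloring."""

    seq: str
    tree: LoopTree
    coloring: Coloring
    m: int | None = None
    xi_L: frozenset[int] | None = None
    certified: bool | None = None  # None = unchecked

    @property
    def gc_count(self) -> int:
        return self.seq.count("G") + self.seq.count("C")

    @property
    def gc_fraction(self) -> float:
        return self.gc_count / len(self.seq) if self.seq else 0.0

    def certify(self, theta: int = 0) -> bool:
        """Check design status with the base-pair-maximization oracle."""
        from .fold import is_design

        self.certified = is_design(self.seq, self.tree.to_structure(), theta)
        return self.certified


@lru_cache(maxsize=None)
def _proper_content_tuples(parent_mu: int | None, num_children: int, has_leaf: bool):
    """Locally proper children content tuples for a loop.

    ``parent_mu`` is the closing pair content (None for Root).  Color
    capacities apply to the complement of the closing color plus children;
    gray orientation rules: a gray child of a gray closing pair repeats the
    parent's orientation, two gray children use different orientations.
    """
    out = []
    if parent_mu is None:
        base = None
    else:
        base = _CONTENT_COLOR[parent_mu]
    for tup in product(range(4), repeat=num_children):
        colors = [_CONTENT_COLOR[mu] for mu in tup]
        w = sum(1 for c in colors if c == WHITE)
        b = sum(1 for c in colors if c == BLACK)
        g = sum(1 for c in colors if c == GRAY)
        if base == WHITE:
            b += 1  # complement of closing WHITE
        elif base == BLACK:
            w += 1
        elif base == GRAY:
            g += 1
        if has_leaf and g > 0:
            continue
        if w > 1 or b > 1 or g > 2:
            continue
        grays = [mu for mu in tup if _CONTENT_COLOR[mu] == GRAY]
        if parent_mu is not None and base == GRAY:
            if any(mu != parent_mu for mu in grays):
                continue
        if len(grays) == 2 and grays[0] == grays[1]:
            continue
        out.append(tup)
    return tuple(out)


def _postorder(tree: LoopTree) -> list[PairNode]:
    order: list[PairNode] = []
    stack = list(tree.root_children)
    while stack:
        v = stack.pop()
        order.append(v)
        stack.extend(v.children)
    order.reverse()
    return order


class CountTable:
    """Tables ``p[v][mu][l]`` for one (tree, assignment) instance.

    Integer counts at ``pi_GC = 0``; log-domain floats otherwise (-inf encodes
    zero).  ``total`` is #Designs for the assignment (a float weighted sum in
    the log-domain case, exposed as ``log_total``).
    """

    __slots__ = ("tree", "assignment", "pi", "tables", "total", "log_total")

    def __init__(self, tree: LoopTree, assignment: ModularAssignment, pi: float = 0.0):
        self.tree = tree
        self.assignment = assignment
        self.pi = float(pi)
        self.tables: dict[int, list[list]] = {}
        if self.pi == 0.0:
            self.total = self._run_int()
            self.log_total = (
                math.log(self.total) if self.total > 0 else -math.inf
            )
        else:
            self.log_total = self._run_log()
            self.total = None

    # -- exact integer counting --------------------------------------------

    def _run_int(self) -> int:
        m = self.assignment.m
        xi_mask = self.assignment.mask
        tables = self.tables
        for v in _postorder(self.tree):
            p = len(v.children)
            has_leaf = bool(v.leaves)
            child_tables = [tables[id(c)] for c in v.children]
            t = [[0] * m for _ in range(4)]
            for mu in range(4):
                dl = _CONTENT_DELTA[mu]
                gray = _CONTENT_COLOR[mu] == GRAY
                for l in range(m):
                    if gray and (xi_mask >> l & 1):
                        continue
                    lc = (l + dl) % m
                    if has_leaf and not (xi_mask >> lc & 1):
                        continue
                    total = 0
                    for tup in _proper_content_tuples(mu, p, has_leaf):
                        prod = 1
                        for k in range(p):
                            prod *= child_tables[k][tup[k]][lc]
                            if not prod:
                                break
                        total += prod
                    t[mu][l] = total
            tables[id(v)] = t
        if self.tree.root_leaves and not (xi_mask & 1):
            return 0
        p = len(self.tree.root_children)
        has_leaf = bool(self.tree.root_leaves)
        child_tables = [tables[id(c)] for c in self.tree.root_children]
        total = 0
        for tup in _proper_content_tuples(None, p, has_leaf):
            prod = 1
            for k in range(p):
                prod *= child_tables[k][tup[k]][0]
                if not prod:
                    break
            total += prod
        return total

    # -- log-domain weighted counting --------------------------------------

    def _run_log(self) -> float:
        m = self.assignment.m
        xi_mask = self.assignment.mask
        tables = self.tables
        logw = [self.pi * g for g in _GC_PER_CONTENT]

        def lse(values):
            mx = max(values)
            if mx == -math.inf:
                return -math.inf
            return mx + math.log(sum(math.exp(x - mx) for x in values))

        for v in _postorder(self.tree):
            p = len(v.children)
            has_leaf = bool(v.leaves)
            child_tables = [tables[id(c)] for c in v.children]
            t = [[-math.inf] * m for _ in range(4)]
            for mu in range(4):
                dl = _CONTENT_DELTA[mu]
                gray = _CONTENT_COLOR[mu] == GRAY
                for l in range(m):
                    if gray and (xi_mask >> l & 1):
                        continue
                    lc = (l + dl) % m
                    if has_leaf and not (xi_mask >> lc & 1):
                        continue
                    terms = []
                    for tup in _proper_content_tuples(mu, p, has_leaf):
                        s = 0.0
                        for k in range(p):
                            s += child_tables[k][tup[k]][lc]
                            if s == -math.inf:
                                break
                        terms.append(s)
                    if terms:
                        t[mu][l] = logw[mu] + lse(terms)
            tables[id(v)] = t
        if self.tree.root_leaves and not (xi_mask & 1):
            return -math.inf
        p = len(self.tree.root_children)
        has_leaf = bool(self.tree.root_leaves)
        child_tables = [tables[id(c)] for c in self.tree.root_children]
        terms = []
        for tup in _proper_content_tuples(None, p, has_leaf):
            s = 0.0
            for k in range(p):
                s += child_tables[k][tup[k]][0]
                if s == -math.inf:
                    break
            terms.append(s)
        return lse(terms) if terms else -math.inf

    # -- backtracking -------------------------------------------------------

    def sample_sequence(self, rng: random.Random) -> DesignSequence:
        """Draw one sequence: uniform at pi = 0, Boltzmann-weighted otherwise."""
        if self.pi == 0.0:
            if not self.total:
                raise RuntimeError("no design for this modular assignment")
        elif self.log_total == -math.inf:
            raise RuntimeError("no design for this modular assignment")
        m = self.assignment.m
        tables = self.tables
        bases = [""] * (self.tree.n + 1)
        chi = Coloring()

        def weight_of(tup, child_tables, lc):
            if self.pi == 0.0:
                prod = 1
                for k, mu in enumerate(tup):
                    prod *= child_tables[k][mu][lc]
                return prod
            s = 0.0
            for k, mu in enumerate(tup):
                s += child_tables[k][mu][lc]
            return s

        def choose(tuples, child_tables, lc):
            weights = [weight_of(tp, child_tables, lc) for tp in tuples]
            if self.pi == 0.0:
                total = sum(weights)
                r = rng.randrange(total)
                for tp, w in zip(tuples, weights):
                    if r < w:
                        return tp
                    r -= w
            else:
                mx = max(weights)
                probs = [math.exp(w - mx) for w in weights]
                r = rng.random() * sum(probs)
                for tp, w in zip(tuples, probs):
                    if r < w:
                        return tp
                    r -= w
                return tuples[-1]
            raise AssertionError  # pragma: no cover

        def expand(v: PairNode, mu: int, l: int) -> None:
            b5, b3 = CONTENTS[mu]
            bases[v.i] = b5
            bases[v.j] = b3
            chi[v.pair] = _CONTENT_COLOR[mu]
            for pos in v.leaves:
                bases[pos] = "A"
            lc = (l + _CONTENT_DELTA[mu]) % m
            if v.children:
                child_tables = [tables[id(c)] for c in v.children]
                tuples = [
                    tp
                    for tp in _proper_content_tuples(
                        mu, len(v.children), bool(v.leaves)
                    )
                    if _tuple_feasible(tp, child_tables, lc, self.pi)
                ]
                tup = choose(tuples, child_tables, lc)
                for node, cmu in zip(v.children, tup):
                    expand(node, cmu, lc)

        roots = self.tree.root_children
        for pos in self.tree.root_leaves:
            bases[pos] = "A"
        if roots:
            child_tables = [tables[id(c)] for c in roots]
            tuples = [
                tp
                for tp in _proper_content_tuples(
                    None, len(roots), bool(self.tree.root_leaves)
                )
                if _tuple_feasible(tp, child_tables, 0, self.pi)
            ]
            tup = choose(tuples, child_tables, 0)
            for node, cmu in zip(roots, tup):
                expand(node, cmu, 0)
        return DesignSequence(
            "".join(bases[1:]),
            self.tree,
            chi,
            m=m,
            xi_L=self.assignment.xi_L,
        )


def _tuple_feasible(tup, child_tables, lc, pi) -> bool:
    if pi == 0.0:
        return all(child_tables[k][mu][lc] > 0 for k, mu in enumerate(tup))
    return all(child_tables[k][mu][lc] > -math.inf for k, mu in enumerate(tup))


# ---------------------------------------------------------------------------
# Public counting / sampling API
# ---------------------------------------------------------------------------


def count_designs(t: LoopTree, a: ModularAssignment) -> int:
    """Exact number of xi_L-separated sequences for ``t``."""
    return CountTable(t, a).total


def count_total(t: LoopTree, m: int) -> int:
    """Z_m: sum of design counts over all 2^m modular assignments.

    Sequences compatible with several assignments are counted once per
    assignment; the rejection step of ``sample_uniform`` corrects for this.
    """
    return sum(
        CountTable(t, ModularAssignment.from_mask(m, mask)).total
        for mask in range(1 << m)
    )


def sample_fixed(
    t: LoopTree, a: ModularAssignment, rng: random.Random, k: int = 1
) -> list[DesignSequence]:
    """k independent, exactly uniform xi_L-separated sequences."""
    table = CountTable(t, a)
    if not table.total:
        raise RuntimeError("no xi_L-separated sequence exists")
    return [table.sample_sequence(rng) for _ in range(k)]


def gc_weighted_sample(
    t: LoopTree,
    a: ModularAssignment,
    pi: float,
    rng: random.Random,
    k: int = 1,
) -> list[DesignSequence]:
    """k draws with probability proportional to exp(pi * #GC(w)) within the
    xi_L-separated set (log-domain; pi = 0 falls back to the exact path)."""
    table = CountTable(t, a, pi=pi)
    if table.log_total == -math.inf:
        raise RuntimeError("no xi_L-separated sequence exists")
    return [table.sample_sequence(rng) for _ in range(k)]


def sequence_from_coloring(
    t: LoopTree,
    chi: Coloring,
    rng: random.Random | None = None,
    m: int | None = None,
) -> DesignSequence:
    """Extract a sequence from a proper coloring.

    WHITE -> C/G, BLACK -> G/C, unpaired -> A.  Gray orientations: inherit the
    parent's orientation in a gray stack, differ from an already-assigned gray
    sibling, otherwise pick uniformly (A.U when ``rng`` is None).
    """
    from .coloring import is_proper

    if not is_proper(t, chi):
        raise ValueError("coloring is not proper")
    bases = [""] * (t.n + 1)
    orientation: dict[tuple[int, int], int] = {}  # gray pair -> content index

    def assign_loop(closing: PairNode | None, children: list[PairNode]) -> None:
        parent_gray = closing is not None and chi[closing.pair] == GRAY
        sibling_orient: int | None = None
        for c in children:
            if chi[c.pair] != GRAY:
                continue
            if parent_gray:
                mu = orientation[closing.pair]
            elif sibling_orient is not None:
                mu = 5 - sibling_orient  # 2 <-> 3
            elif rng is not None:
                mu = rng.choice((2, 3))
            else:
                mu = 2
            orientation[c.pair] = mu
            sibling_orient = mu

    assign_loop(None, t.root_children)
    stack = list(t.root_children)
    while stack:
        v = stack.pop()
        assign_loop(v, v.children)
        stack.extend(v.children)

    for v in t.nodes:
        color = chi[v.pair]
        if color == GRAY:
            mu = orientation[v.pair]
        elif color == WHITE:
            mu = 0
        else:
            mu = 1
        b5, b3 = CONTENTS[mu]
        bases[v.i] = b5
        bases[v.j] = b3
        for pos in v.leaves:
            bases[pos] = "A"
    for pos in t.root_leaves:
        bases[pos] = "A"
    return DesignSequence("".join(bases[1:]), t, chi, m=m)


def xi_freedom(design: DesignSequence, t: LoopTree | None = None, m: int | None = None) -> int:
    """Xi_w = 2^|Phi_w|: the number of modular assignments compatible with the
    drawn sequence; Phi_w collects the residues populated by neither leaves
    nor gray nodes."""
    t = t or design.tree
    m = m or design.m
    if m is None:
        raise ValueError("modulus required")
    chi = design.coloring
    lm = levels(t, chi)
    leaf_res = {lvl % m for lvl in lm.leaf_levels.values()}
    gray_res = {lvl % m for lvl in lm.gray_levels(chi)}
    if leaf_res & gray_res:
        raise ValueError("sequence is not m-separated")
    free = m - len(leaf_res) - len(gray_res)
    return 1 << free


class DesignSampler:
    """Uniform (or Boltzmann-weighted) sampler over all m-separated sequences.

    Precomputes the 2^m count tables once (Theta(n * m * 2^m)), then draws by:
    choose xi_L proportionally to its (weighted) design count, sample a
    sequence for that assignment, accept with probability 1/Xi_w, restart on
    rejection.  The expected number of rejections is bounded by 2^m.
    """

    def __init__(self, tree: LoopTree, m: int, pi: float = 0.0):
        if m < 1:
            raise ValueError("modulus must be >= 1")
        self.tree = tree
        self.m = m
        self.pi = float(pi)
        self.last_attempts = 0  # rejection iterations of the latest draw
        self.tables = [
            CountTable(tree, ModularAssignment.from_mask(m, mask), pi=pi)
            for mask in range(1 << m)
        ]
        self.log_Z = self._log_Z()

    def _log_Z(self) -> float:
        logs = [tb.log_total for tb in self.tables]
        mx = max(logs)
        if mx == -math.inf:
            return -math.inf
        return mx + math.log(sum(math.exp(x - mx) for x in logs))

    @property
    def Z(self) -> int | None:
        """Exact integer Z_m at pi = 0, else None (use log_Z)."""
        if self.pi == 0.0:
            return sum(tb.total for tb in self.tables)
        return None

    def _choose_table(self, rng: random.Random) -> CountTable:
        if self.pi == 0.0:
            r = rng.randrange(self.Z)
            for tb in self.tables:
                if r < tb.total:
                    return tb
                r -= tb.total
        else:
            probs = [math.exp(tb.log_total - self.log_Z) for tb in self.tables]
            r = rng.random() * sum(probs)
            for tb, w in zip(self.tables, probs):
                if r < w:
                    return tb
                r -= w
            return max(self.tables, key=lambda tb: tb.log_total)
        raise AssertionError  # pragma: no cover

    def sample(self, rng: random.Random) -> DesignSequence:
        if self.log_Z == -math.inf:
            raise RuntimeError("no m-separated sequence exists for this target")
        cap = 1 << (self.m + 6)
        for attempt in range(1, cap + 1):
            tb = self._choose_table(rng)
            w = tb.sample_sequence(rng)
            xi = xi_freedom(w, self.tree, self.m)
            if rng.randrange(xi) == 0:
                self.last_attempts = attempt
                return w
        raise RuntimeError(
            f"rejection cap {cap} exceeded; expected rejections are <= 2^m"
        )  # pragma: no cover


def sample_uniform(
    t: LoopTree, m: int, rng: random.Random, k: int = 1
) -> list[DesignSequence]:
    """k exactly uniform draws over all m-separated sequences for ``t``."""
    sampler = DesignSampler(t, m)
    return [sampler.sample(rng) for _ in range(k)]


def calibrate_pi(
    t: LoopTree,
    m: int,
    target_gc: float,
    tol: float = 1e-3,
    lo: float = -60.0,
    hi: float = 60.0,
) -> float:
    """Binary search for pi_GC matching an expected GC fraction.

    The expectation is computed exactly from the distinct-sequence weighted
    tables (the distribution the sampler realizes after rejection).  E[GC%]
    is nondecreasing in pi.  Unreachable targets emit a warning and return
    the boundary weight.
    """
    if not (0.0 <= target_gc <= 1.0):
        raise ValueError("target_gc must be a fraction in [0, 1]")

    def expected(pi: float) -> float:
        return expected_gc_fraction(t, m, pi)

    e_lo, e_hi = expected(lo), expected(hi)
    if target_gc <= e_lo:
        if target_gc < e_lo - tol:
            warnings.warn(
                f"target GC {target_gc:.3f} below attainable minimum "
                f"{e_lo:.3f}; returning pi={lo}"
            )
        return lo
    if target_gc >= e_hi:
        if target_gc > e_hi + tol:
            warnings.warn(
                f"target GC {target_gc:.3f} above attainable maximum "
                f"{e_hi:.3f}; returning pi={hi}"
            )
        return hi
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        e = expected(mid)
        if abs(e - target_gc) <= tol:
            return mid
        if e < target_gc:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _merge_states(acc, child, pi):
    """Convolve two (lmask, gmask) -> stats dictionaries (mask unions)."""
    out: dict[tuple[int, int], list] = {}
    for (lm1, gm1), s1 in acc.items():
        for (lm2, gm2), s2 in child.items():
            lm, gm = lm1 | lm2, gm1 | gm2
            if lm & gm:
                continue  # leaf and gray residues must stay disjoint
            if pi == 0.0:
                cnt = s1[0] * s2[0]
                gcs = s1[1] * s2[0] + s2[1] * s1[0]
                cur = out.get((lm, gm))
                if cur is None:
                    out[(lm, gm)] = [cnt, gcs]
                else:
                    cur[0] += cnt
                    cur[1] += gcs
            else:
                lz = s1[0] + s2[0]
                e = s1[1] + s2[1]
                cur = out.get((lm, gm))
                if cur is None:
                    out[(lm, gm)] = [lz, e]
                else:
                    tot = _logadd(cur[0], lz)
                    w2 = math.exp(lz - tot)
                    cur[1] = cur[1] * (1.0 - w2) + e * w2
                    cur[0] = tot
    return out


def _logadd(a: float, b: float) -> float:
    if a == -math.inf:
        return b
    if b == -math.inf:
        return a
    mx = a if a > b else b
    return mx + math.log(math.exp(a - mx) + math.exp(b - mx))


def _distinct_tables(t: LoopTree, m: int, pi: float):
    """DP over distinct m-separated sequences (no xi_L): per node and
    (content, residue), a dict ``(leaf-residue mask, gray-residue mask) ->
    stats``; disjointness of the two masks is the m-separation constraint.

    Stats are ``[count, gc_sum]`` exact integers at pi = 0, and
    ``[log-weight, expected #GC]`` floats otherwise.
    """
    tables: dict[int, list[list[dict]]] = {}
    for v in _postorder(t):
        p = len(v.children)
        has_leaf = bool(v.leaves)
        child_tables = [tables[id(c)] for c in v.children]
        node_tab = [[{} for _ in range(m)] for _ in range(4)]
        for mu in range(4):
            gc = _GC_PER_CONTENT[mu]
            gray = _CONTENT_COLOR[mu] == GRAY
            for l in range(m):
                lc = (l + _CONTENT_DELTA[mu]) % m
                own_l = (1 << lc) if has_leaf else 0
                own_g = (1 << l) if gray else 0
                if own_l & own_g:
                    continue
                acc_tot: dict[tuple[int, int], list] = {}
                for tup in _proper_content_tuples(mu, p, has_leaf):
                    if pi == 0.0:
                        acc = {(own_l, own_g): [1, gc]}
                    else:
                        acc = {(own_l, own_g): [pi * gc, float(gc)]}
                    ok = True
                    for k in range(p):
                        child = child_tables[k][tup[k]][lc]
                        if not child:
                            ok = False
                            break
                        acc = _merge_states(acc, child, pi)
                        if not acc:
                            ok = False
                            break
                    if not ok:
                        continue
                    for key, s in acc.items():
                        cur = acc_tot.get(key)
                        if cur is None:
                            acc_tot[key] = list(s)
                        elif pi == 0.0:
                            cur[0] += s[0]
                            cur[1] += s[1]
                        else:
                            tot = _logadd(cur[0], s[0])
                            w2 = math.exp(s[0] - tot)
                            cur[1] = cur[1] * (1.0 - w2) + s[1] * w2
                            cur[0] = tot
                node_tab[mu][l] = acc_tot
        tables[id(v)] = node_tab
    # Root: children at residue 0; Root leaves at residue 0
    own_l = 1 if t.root_leaves else 0
    if pi == 0.0:
        base = {(own_l, 0): [1, 0]}
    else:
        base = {(own_l, 0): [0.0, 0.0]}
    total: dict[tuple[int, int], list] = {}
    child_tables = [tables[id(c)] for c in t.root_children]
    for tup in _proper_content_tuples(None, len(t.root_children), bool(t.root_leaves)):
        acc = dict((k, list(v)) for k, v in base.items())
        ok = True
        for k in range(len(t.root_children)):
            child = child_tables[k][tup[k]][0]
            if not child:
                ok = False
                break
            acc = _merge_states(acc, child, pi)
            if not acc:
                ok = False
                break
        if not ok:
            continue
        for key, s in acc.items():
            cur = total.get(key)
            if cur is None:
                total[key] = list(s)
            elif pi == 0.0:
                cur[0] += s[0]
                cur[1] += s[1]
            else:
                tot = _logadd(cur[0], s[0])
                w2 = math.exp(s[0] - tot)
                cur[1] = cur[1] * (1.0 - w2) + s[1] * w2
                cur[0] = tot
    return total


def count_m_separated(t: LoopTree, m: int) -> int:
    """Exact number of *distinct* m-separated sequences for ``t`` (each
    sequence counted once, unlike the per-assignment sum Z_m)."""
    total = _distinct_tables(t, m, 0.0)
    return sum(s[0] for s in total.values())


def distinct_stats(t: LoopTree, m: int, pi: float = 0.0) -> tuple[float, float]:
    """(log Z, E[#GC]) of the Boltzmann distribution over all distinct
    m-separated sequences at weight ``pi``."""
    total = _distinct_tables(t, m, pi)
    if not total:
        return -math.inf, 0.0
    if pi == 0.0:
        z = sum(s[0] for s in total.values())
        if z == 0:
            return -math.inf, 0.0
        return math.log(z), sum(s[1] for s in total.values()) / z
    logz = -math.inf
    e = 0.0
    for s in total.values():
        tot = _logadd(logz, s[0])
        w2 = math.exp(s[0] - tot)
        e = e * (1.0 - w2) + s[1] * w2
        logz = tot
    return logz, e


def expected_gc_fraction(t: LoopTree, m: int, pi: float) -> float:
    """Exact expected GC fraction of the Boltzmann distribution over all
    distinct m-separated sequences (the distribution ``DesignSampler``
    realizes after its rejection step)."""
    if t.n == 0:
        return 0.0
    logz, e = distinct_stats(t, m, pi)
    if logz == -math.inf:
        raise RuntimeError("no m-separated sequence exists for this target")
    return e / t.n


def sample_exact_gc(
    t: LoopTree,
    m: int,
    gc_count: int,
    rng: random.Random,
    max_tries: int = 20_000,
) -> DesignSequence:
    """Uniform among m-separated sequences with exactly ``gc_count`` G+C.

    Calibrates pi_GC toward the target count, then rejects off-target draws;
    within a fixed GC count all sequences share the same Boltzmann weight, so
    accepted draws are uniform on the slice.
    """
    if not (0 <= gc_count <= t.n):
        raise ValueError("gc_count out of range")
    pi = calibrate_pi(t, m, gc_count / t.n if t.n else 0.0, tol=5e-3)
    sampler = DesignSampler(t, m, pi=pi)
    for _ in range(max_tries):
        w = sampler.sample(rng)
        if w.gc_count == gc_count:
            return w
    raise RuntimeError(
        f"no sequence with #GC == {gc_count} found in {max_tries} draws; "
        "the count may be unattainable"
    )


def is_separated_sequence(t: LoopTree, w: str, m: int) -> bool:
    """Full m-separated-sequence check: chi_w proper and m-separated, unpaired
    positions all A, gray orientation rules satisfied."""
    from .coloring import SequenceError, coloring_from_sequence

    try:
        chi = coloring_from_sequence(t, w, strict=True)
    except SequenceError:
        return False
    if not is_m_separated(t, chi, m):
        return False
    # gray orientation rules within every loop
    def orient(v: PairNode) -> int:
        return 2 if w[v.i - 1] == "A" else 3

    def check_loop(closing: PairNode | None, children) -> bool:
        grays = [c for c in children if chi[c.pair] == GRAY]
        if closing is not None and chi[closing.pair] == GRAY:
            if any(orient(c) != orient(closing) for c in grays):
                return False
        if len(grays) == 2 and orient(grays[0]) == orient(grays[1]):
            return False
        return True

    if not check_loop(None, t.root_children):
        return False
    for v in t.nodes:
        if not check_loop(v, v.children):
            return False
    return True
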