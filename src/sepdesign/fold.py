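"""Base-pair-maximization folding with uniqueness certification.

The ground-truth verifier for designs: a Nussinov-style dynamic program
computes the maximum number of non-crossing base pairs a sequence can form
(legal contents G.C, A.U and the wobble G.U, span ``j - i - 1 >= theta``),
together with the exact number of distinct optimal structures.  The counting
recursion is unambiguous — position ``j`` is either unpaired or paired with a
unique split — so every optimal structure is counted exactly once.

A sequence ``w`` is a *design* for a target ``T`` when ``T`` is compatible
with ``w``, reaches the optimal pair count, and the optimum is unique; the
unique optimum is then necessarily ``T`` itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .structure import SecondaryStructure

_PAIRABLE = {
    ("G", "C"), ("C", "G"),
    ("A", "U"), ("U", "A"),
    ("G", "U"), ("U", "G"),
}

_ALPHABET = "ACGU"


@dataclass(frozen=True)
class FoldResult:
    """Optimal pair count, number of co-optimal structures, one witness."""

    max_bp: int
    num_optimal: int
    witness: SecondaryStructure


def _check_sequence(w: str) -> str:
    w = w.upper().replace("T", "U")
    if any(ch not in _ALPHABET for ch in w):
        raise ValueError(f"sequence contains letters outside {{A,C,G,U}}: {w!r}")
    return w


def _dp_tables(w: str, theta: int):
    """Nussinov max table N and unambiguous co-optimal count table C."""
    n = len(w)
    N = [[0] * n for _ in range(n)]
    C = [[1] * n for _ in range(n)]  # empty interval -> 1 (the empty structure)
    can = [[(w[i], w[j]) in _PAIRABLE for j in range(n)] for i in range(n)]
    for span in range(1, n):
        for i in range(n - span):
            j = i + span
            # j unpaired
            best = N[i][j - 1]
            # j paired with k in [i, j - theta - 1]
            for k in range(i, j - theta):
                if can[k][j]:
                    left = N[i][k - 1] if k > i else 0
                    inner = N[k + 1][j - 1] if k + 1 <= j - 1 else 0
                    best = max(best, left + inner + 1)
            N[i][j] = best
            cnt = C[i][j - 1] if N[i][j - 1] == best else 0
            for k in range(i, j - theta):
                if can[k][j]:
                    left = N[i][k - 1] if k > i else 0
                    inner = N[k + 1][j - 1] if k + 1 <= j - 1 else 0
                    if left + inner + 1 == best:
                        cl = C[i][k - 1] if k > i else 1
                        ci = C[k + 1][j - 1] if k + 1 <= j - 1 else 1
                        cnt += cl * ci
            C[i][j] = cnt
    return N, C


def _traceback(w: str, theta: int, N) -> list[tuple[int, int]]:
    """One optimal structure (1-based pairs); deterministic tie-break."""
    n = len(w)
    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j:
            continue
        if N[i][j] == N[i][j - 1]:
            stack.append((i, j - 1))
            continue
        for k in range(i, j - theta):
            if (w[k], w[j]) in _PAIRABLE:
                left = N[i][k - 1] if k > i else 0
                inner = N[k + 1][j - 1] if k + 1 <= j - 1 else 0
                if left + inner + 1 == N[i][j]:
                    pairs.append((k + 1, j + 1))
                    if k > i:
                        stack.append((i, k - 1))
                    if k + 1 <= j - 1:
                        stack.append((k + 1, j - 1))
                    break
    return pairs


def fold(w: str, theta: int = 0) -> FoldResult:
    """Full oracle result: optimum, co-optimal count, one witness structure."""
    w = _check_sequence(w)
    n = len(w)
    if n == 0:
        return FoldResult(0, 1, SecondaryStructure(0, (), theta=theta))
    N, C = _dp_tables(w, theta)
    witness = SecondaryStructure(
        n, _traceback(w, theta, N), theta=theta, validate=False
    )
    return FoldResult(N[0][n - 1], C[0][n - 1], witness)


def nussinov_max(w: str, theta: int = 0) -> int:
    """Maximum number of legal non-crossing base pairs for ``w``."""
    w = _check_sequence(w)
    if len(w) == 0:
        return 0
    N, _ = _dp_tables(w, theta)
    return N[0][-1]


def count_optimal(w: str, theta: int = 0) -> int:
    """Number of distinct structures attaining the optimum (each counted once)."""
    w = _check_sequence(w)
    if len(w) == 0:
        return 1
    _, C = _dp_tables(w, theta)
    return C[0][-1]


def is_compatible(w: str, t: SecondaryStructure) -> bool:
    w = _check_sequence(w)
    if len(w) != t.n:
        raise ValueError("sequence/structure length mismatch")
    return all((w[i - 1], w[j - 1]) in _PAIRABLE for i, j in t.pairs)


def is_design(w: str, t: SecondaryStructure, theta: int = 0) -> bool:
    """True iff ``t`` is the unique base-pair-maximizing structure of ``w``."""
    w = _check_sequence(w)
    if len(w) != t.n:
        raise ValueError("sequence/structure length mismatch")
    if not is_compatible(w, t):
        return False
    res = fold(w, theta)
    return res.max_bp == len(t.pairs) and res.num_optimal == 1


def bp_distance(t1: SecondaryStructure, t2: SecondaryStructure) -> int:
    """Symmetric-difference cardinality of the two pair sets."""
    if t1.n != t2.n:
        raise ValueError("structures must share the same length")
    return len(t1.pairs ^ t2.pairs)


def exhaustive_scan(
    n: int,
    theta: int = 0,
    progress_every: int = 0,
    checkpoint: str | Path | None = None,
) -> dict[str, int]:
    """Fold every sequence of length ``n``; census of designs per structure.

    Returns ``{dot-bracket: number of design sequences}`` over structures that
    admit at least one design.  Streams sequences in base-4 counter order; an
    optional JSON checkpoint makes long scans resumable.
    """
    total = 4 ** n
    census: dict[str, int] = {}
    start = 0
    ckpt = Path(checkpoint) if checkpoint else None
    if ckpt and ckpt.exists():
        state = json.loads(ckpt.read_text())
        if state.get("n") == n and state.get("theta") == theta:
            census = dict(state["census"])
            start = state["next"]
    letters = _ALPHABET
    for idx in range(start, total):
        x = idx
        chars = []
        for _ in range(n):
            chars.append(letters[x & 3])
            x >>= 2
        w = "".join(chars)
        res = fold(w, theta)
        if res.num_optimal == 1:
            db = res.witness.to_dotbracket()
            census[db] = census.get(db, 0) + 1
        if ckpt and progress_every and (idx + 1) % progress_every == 0:
            ckpt.write_text(
                json.dumps(
                    {"n": n, "theta": theta, "next": idx + 1, "census": census}
                )
            )
    if ckpt:
        ckpt.write_text(
            json.dumps({"n": n, "theta": theta, "next": total, "census": census})
        )
    return census


def brute_force_fold(w: str, theta: int = 0) -> FoldResult:
    """Independent oracle by explicit enumeration of all structures (tiny n)."""
    from .structure import enumerate_structures

    w = _check_sequence(w)
    best = -1
    count = 0
    witness = None
    for s in enumerate_structures(len(w), theta):
        if not all((w[i - 1], w[j - 1]) in _PAIRABLE for i, j in s.pairs):
            continue
        k = len(s.pairs)
        if k > best:
            best, count, witness = k, 1, s
        elif k == best:
            count += 1
    return FoldResult(best, count, witness)
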