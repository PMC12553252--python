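"""Reproduction studies: exhaustive censuses and random-target surveys.

Three experiments back the toolkit's empirical claims:

* the exhaustive small-length census enumerates every structure of length
  ``n`` and records its minimal separating modulus (pair-free structures at
  m = 1, all others searched from m = 2 upward after the motif pre-filter);
* the modulus survey measures how often random targets with isolated stacks
  are 2-separable, drawing uniform motif-free targets of length 100
  (theta = 3) that contain at least one length-2 helix;
* the GC survey samples one 2-separated design per random stable target
  (motif-free, all helices >= 3) at a neutral, a strongly negative and a
  strongly positive Boltzmann GC weight.

All experiments are deterministic given a seed.
"""

from __future__ import annotations

import random
import statistics
from dataclasses import dataclass, field

from .coloring import min_separating_modulus
from .fold import exhaustive_scan
from .sampling import DesignSampler
from .structure import (
    ConstrainedEnsemble,
    LoopTree,
    SecondaryStructure,
    build_loop_tree,
    enumerate_structures,
    helices,
    is_motif_free,
)


# ---------------------------------------------------------------------------
# Exhaustive minimal-modulus census
# ---------------------------------------------------------------------------


def minimal_modulus_census(
    n: int, theta: int = 0, max_m: int | None = None
) -> dict[str, int | None]:
    """Minimal separating modulus for every structure of length ``n``.

    Returns ``{dot-bracket: m_minus}`` with None for structures admitting no
    separated coloring (motif hit, or every modulus up to ``max_m`` failing).
    """
    if max_m is None:
        max_m = n
    out: dict[str, int | None] = {}
    for s in enumerate_structures(n, theta):
        t = build_loop_tree(s)
        if t.nodes and not is_motif_free(t):
            out[s.to_dotbracket()] = None
            continue
        out[s.to_dotbracket()] = min_separating_modulus(t, max_m=max_m)
    return out


def modulus_buckets(census: dict[str, int | None]) -> dict[int | None, int]:
    buckets: dict[int | None, int] = {}
    for m in census.values():
        buckets[m] = buckets.get(m, 0) + 1
    return buckets


def designability_census(n: int, theta: int = 0) -> dict[str, int]:
    """Designs per structure via the fold oracle (4^n sequences; small n)."""
    return exhaustive_scan(n, theta)


# ---------------------------------------------------------------------------
# Random-target surveys
# ---------------------------------------------------------------------------


def has_helix_of_length(t: LoopTree, length: int) -> bool:
    return any(h.length == length for h in helices(t))


def sample_survey_target(
    ens: ConstrainedEnsemble, rng: random.Random
) -> SecondaryStructure:
    """One motif-free target containing at least one length-2 helix."""
    return ens.sample_with(
        rng, lambda s: has_helix_of_length(build_loop_tree(s), 2)
    )


@dataclass
class ModulusSurvey:
    """Per-target minimal moduli and their summary statistics."""

    moduli: list[int] = field(default_factory=list)
    n: int = 100
    theta: int = 3

    @property
    def num_targets(self) -> int:
        return len(self.moduli)

    @property
    def pct_two_separable(self) -> float:
        return 100.0 * sum(1 for m in self.moduli if m == 2) / len(self.moduli)

    @property
    def pct_above_six(self) -> float:
        return 100.0 * sum(1 for m in self.moduli if m > 6) / len(self.moduli)

    @property
    def max_modulus(self) -> int:
        return max(self.moduli)


def survey_min_modulus(
    num_targets: int,
    n: int = 100,
    theta: int = 3,
    seed: int = 0,
    strict_helix: bool = True,
    max_m: int | None = None,
) -> ModulusSurvey:
    """Minimal separating modulus over random motif-free targets featuring at
    least one isolated stack (length-2 helix).

    The default (strict) target class excludes isolated base pairs, i.e. all
    helices have length >= 2 and at least one has length exactly 2 -- the
    "targets with isolated stacks" ensemble; ``strict_helix=False`` admits
    isolated base pairs as well.
    """
    rng = random.Random(seed)
    ens = ConstrainedEnsemble(n, theta, min_helix=2 if strict_helix else 1)
    survey = ModulusSurvey(n=n, theta=theta)
    for _ in range(num_targets):
        s = sample_survey_target(ens, rng)
        t = build_loop_tree(s)
        m = min_separating_modulus(t, max_m=max_m)
        if m is None:
            raise RuntimeError(
                f"target {s.to_dotbracket()} not separable up to m={max_m or n}"
            )
        survey.moduli.append(m)
    return survey


@dataclass
class GCSurvey:
    """Per-target GC percentages at neutral / minimizing / maximizing weight."""

    neutral: list[float] = field(default_factory=list)
    minimized: list[float] = field(default_factory=list)
    maximized: list[float] = field(default_factory=list)

    def stats(self, values: list[float]) -> tuple[float, float, float]:
        return (
            statistics.fmean(values),
            statistics.median(values),
            statistics.stdev(values) if len(values) > 1 else 0.0,
        )


def survey_gc(
    num_targets: int,
    n: int = 100,
    theta: int = 3,
    seed: int = 0,
    m: int = 2,
    pi_low: float = -48.0,
    pi_high: float = 48.0,
) -> GCSurvey:
    """GC modulation of 2-separated designs for random stable targets.

    For each motif-free target with all helices >= 3 (grammar-sampled,
    uniform), draw one m-separated design at pi_GC = 0 (uniform), one at a
    strongly negative weight (GC minimized) and one at a strongly positive
    weight (GC maximized).
    """
    rng = random.Random(seed)
    ens = ConstrainedEnsemble(n, theta, min_helix=3)
    survey = GCSurvey()
    for _ in range(num_targets):
        s = ens.sample(rng)
        t = build_loop_tree(s)
        for pi, store in (
            (0.0, survey.neutral),
            (pi_low, survey.minimized),
            (pi_high, survey.maximized),
        ):
            sampler = DesignSampler(t, m, pi=pi)
            w = sampler.sample(rng)
            store.append(100.0 * w.gc_fraction)
    return survey
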