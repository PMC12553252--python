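import random

import pytest

import sepdesign as sd


@pytest.fixture
def rng():
    return random.Random(20260101)


def small_trees(n_max: int, theta: int = 0):
    """Every structure up to length n_max as a loop tree."""
    for n in range(n_max + 1):
        for s in sd.enumerate_structures(n, theta):
            yield sd.build_loop_tree(s)


def random_trees(count: int, n: int, theta: int, seed: int, max_pairs=None):
    rng = random.Random(seed)
    out = []
    while len(out) < count:
        s = sd.sample_structure(n, theta, rng)
        if max_pairs is not None and len(s.pairs) > max_pairs:
            continue
        out.append(sd.build_loop_tree(s))
    return out
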