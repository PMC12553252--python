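import random

import pytest
from hypothesis import given, settings, strategies as st

import sepdesign as sd
from sepdesign.structure import (
    ConstrainedEnsemble,
    StructureError,
    make_blocking_gadget,
    make_hardness_T,
)
from oracles import loop_pair_and_leaf_counts


class TestParseWrite:
    def test_basic_pairs(self):
        s = sd.parse_dotbracket("((...))")
        assert s.pairs == frozenset({(1, 7), (2, 6)})
        assert s.n == 7

    def test_empty(self):
        s = sd.parse_dotbracket("")
        assert s.n == 0 and not s.pairs

    @pytest.mark.parametrize("text", ["()(", ")(", "(()", "(a)"])
    def test_malformed(self, text):
        with pytest.raises(StructureError):
            sd.parse_dotbracket(text)

    def test_theta_violation(self):
        with pytest.raises(StructureError):
            sd.parse_dotbracket("()", theta=1)

    def test_crossing_rejected(self):
        with pytest.raises(StructureError):
            sd.SecondaryStructure(4, [(1, 3), (2, 4)])

    @pytest.mark.parametrize(
        "pairs,n,expected",
        [({(1, 2)}, 2, "()"), (set(), 3, "..."), ({(2, 6), (3, 5)}, 7, ".((.)).")],
    )
    def test_write(self, pairs, n, expected):
        assert sd.write_dotbracket(sd.SecondaryStructure(n, pairs)) == expected

    def test_roundtrip_enumerated(self):
        for n in range(8):
            for s in sd.enumerate_structures(n, 0):
                assert sd.parse_dotbracket(s.to_dotbracket()) == s

    @given(st.integers(0, 2**30))
    @settings(max_examples=40, deadline=None)
    def test_roundtrip_random(self, seed):
        s = sd.sample_structure(40, 3, random.Random(seed))
        assert sd.parse_dotbracket(s.to_dotbracket(), 3) == s


class TestLoopTree:
    def test_single_pair(self):
        t = sd.build_loop_tree(sd.parse_dotbracket("()"))
        assert len(t.root_children) == 1 and not t.root_leaves
        assert not t.root_children[0].children

    def test_hairpin_leaf(self):
        t = sd.build_loop_tree(sd.parse_dotbracket("(.)"))
        assert t.root_children[0].pair == (1, 3)
        assert t.root_children[0].leaves == [2]

    def test_two_children(self):
        t = sd.build_loop_tree(sd.parse_dotbracket("(()())"))
        v = t.root_children[0]
        assert v.pair == (1, 6)
        assert [c.pair for c in v.children] == [(2, 3), (4, 5)]


class TestHelices:
    @pytest.mark.parametrize(
        "db,lengths",
        [
            ("((()))", [3]),
            ("(())(.)", [2, 1]),
            ("((.))", [2]),
            ("((((...))(...)))", [2, 2, 1]),
        ],
    )
    def test_lengths(self, db, lengths):
        t = sd.build_loop_tree(sd.parse_dotbracket(db))
        assert sorted(h.length for h in sd.helices(t)) == sorted(lengths)

    def test_h_min_empty_sentinel(self):
        assert sd.h_min(sd.build_loop_tree(sd.parse_dotbracket("..."))) is None

    def test_partition(self, rng):
        for _ in range(50):
            s = sd.sample_structure(60, 3, rng)
            t = sd.build_loop_tree(s)
            hs = sd.helices(t)
            nodes = [v.pair for h in hs for v in h.nodes]
            assert sorted(nodes) == sorted(v.pair for v in t.nodes)
            assert sum(h.length for h in hs) == len(s.pairs)


class TestMotifs:
    def test_m5(self):
        t = sd.build_loop_tree(sd.parse_dotbracket("(()()()())"))
        assert sd.detect_forbidden(t).has_m5

    def test_m3dot(self):
        t = sd.build_loop_tree(sd.parse_dotbracket("(()().)"))
        assert sd.detect_forbidden(t).has_m3dot

    def test_root_degree_four_fine(self):
        rep = sd.detect_forbidden(sd.build_loop_tree(sd.parse_dotbracket("()()()()")))
        assert not rep.has_m5 and not rep.has_m3dot

    def test_against_naive_counter(self, rng):
        for _ in range(100):
            t = sd.build_loop_tree(sd.sample_structure(40, 0, rng))
            counts = loop_pair_and_leaf_counts(t)
            root, inner = counts[0], counts[1:]
            m5 = root[0] >= 5 or any(k >= 5 for k, _ in inner)
            m3 = (root[0] >= 3 and root[1] >= 1) or any(
                k >= 3 and u >= 1 for k, u in inner
            )
            rep = sd.detect_forbidden(t)
            assert rep.has_m5 == m5 and rep.has_m3dot == m3


class TestCounting:
    @pytest.mark.parametrize("n,theta,expected", [(3, 0, 4), (2, 2, 1), (0, 0, 1)])
    def test_small_counts(self, n, theta, expected):
        assert sd.count_structures(n, theta) == expected

    @pytest.mark.parametrize("theta", [0, 3])
    def test_count_matches_enumeration(self, theta):
        for n in range(11):
            assert sd.count_structures(n, theta) == sum(
                1 for _ in sd.enumerate_structures(n, theta)
            )

    def test_enumeration_unique_and_ordered(self):
        seen = [s.to_dotbracket() for s in sd.enumerate_structures(6, 0)]
        assert len(seen) == len(set(seen))
        key = {".": 0, "(": 1, ")": 2}
        ranked = [[key[c] for c in db] for db in seen]
        assert ranked == sorted(ranked)

    def test_enumerate_n2(self):
        assert {s.to_dotbracket() for s in sd.enumerate_structures(2, 0)} == {
            "..",
            "()",
        }


class TestSampling:
    def test_n1_always_dot(self, rng):
        for _ in range(5):
            assert sd.sample_structure(1, 0, rng).to_dotbracket() == "."

    def test_theta_invariant(self, rng):
        for _ in range(20):
            s = sd.sample_structure(100, 3, rng)
            assert all(j - i - 1 >= 3 for i, j in s.pairs)

    def test_uniformity_chi_square(self, rng):
        from scipy.stats import chisquare

        structs = [s.to_dotbracket() for s in sd.enumerate_structures(4, 0)]
        assert len(structs) == 9
        counts = dict.fromkeys(structs, 0)
        draws = 9000
        for _ in range(draws):
            counts[sd.sample_structure(4, 0, rng).to_dotbracket()] += 1
        assert chisquare(list(counts.values())).pvalue > 0.001

    def test_constrained_rejection(self, rng):
        pred = lambda s: sd.is_motif_free(sd.build_loop_tree(s))
        s = sd.sample_structure_constrained(30, 3, pred, rng)
        assert pred(s)

    def test_constrained_rejection_floor(self, rng):
        with pytest.raises(RuntimeError):
            sd.sample_structure_constrained(
                10, 0, lambda s: False, rng, max_tries=50
            )


class TestConstrainedEnsemble:
    @pytest.mark.parametrize("theta", [0, 3])
    @pytest.mark.parametrize("hmin", [1, 2, 3])
    def test_count_matches_brute_force(self, theta, hmin):
        for n in range(0, 13, 2):
            ens = ConstrainedEnsemble(n, theta, min_helix=hmin)
            brute = 0
            for s in sd.enumerate_structures(n, theta):
                t = sd.build_loop_tree(s)
                hm = sd.h_min(t)
                if sd.is_motif_free(t) and (hm is None or hm >= hmin):
                    brute += 1
            assert ens.count == brute

    def test_sample_members(self, rng):
        ens = ConstrainedEnsemble(80, 3, min_helix=3)
        for _ in range(30):
            s = ens.sample(rng)
            t = sd.build_loop_tree(s)
            assert sd.is_motif_free(t)
            hm = sd.h_min(t)
            assert hm is None or hm >= 3
            assert all(j - i - 1 >= 3 for i, j in s.pairs)

    def test_sample_uniform_small(self, rng):
        from scipy.stats import chisquare

        ens = ConstrainedEnsemble(8, 0, min_helix=2)
        support = {}
        for s in sd.enumerate_structures(8, 0):
            t = sd.build_loop_tree(s)
            hm = sd.h_min(t)
            if sd.is_motif_free(t) and (hm is None or hm >= 2):
                support[s.to_dotbracket()] = 0
        assert ens.count == len(support)
        for _ in range(4000):
            support[ens.sample(rng).to_dotbracket()] += 1
        assert chisquare(list(support.values())).pvalue > 0.001


class TestGadgets:
    def test_blocking_shape(self):
        t = make_blocking_gadget(4)
        chain = []
        v = t.root_children[0]
        while True:
            chain.append(v)
            if not v.children:
                break
            v = v.children[0]
        assert len(chain) == 4
        assert [len(v.leaves) for v in chain] == [1, 0, 1, 0]

    def test_hardness_T_all_helices_length_2(self):
        t = make_hardness_T(2, 4)
        assert {h.length for h in sd.helices(t)} == {2}
        assert sd.is_motif_free(t)

    def test_synchronization_gadget_parity(self):
        # any separated coloring uses gray levels of both parities, so the
        # gadget is never 2-separable but is separable at some larger modulus
        t = sd.make_gadget("synchronization")
        assert sd.is_motif_free(t)
        assert sd.solve(t, 2) is None
        m = sd.min_separating_modulus(t, max_m=12)
        assert m is not None and 2 < m <= 12
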