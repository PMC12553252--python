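import itertools
import random

import pytest

import sepdesign as sd
from sepdesign.coloring import (
    BLACK,
    GRAY,
    WHITE,
    Color,
    Coloring,
    SequenceError,
    loop_color_vector,
)
from conftest import small_trees


class TestColorAlgebra:
    def test_delta_values(self):
        assert sd.delta(WHITE) == 1
        assert sd.delta(BLACK) == -1
        assert sd.delta(GRAY) == 0

    def test_complement_involution(self):
        for c in Color:
            assert sd.complement(sd.complement(c)) == c
            assert sd.delta(c) + sd.delta(sd.complement(c)) == 0

    def test_gray_self_complementary(self):
        assert sd.complement(GRAY) == GRAY


class TestLoopVector:
    def test_pair_node_vector(self):
        t = sd.build_loop_tree(sd.parse_dotbracket("(())"))
        chi = Coloring({(1, 4): WHITE, (2, 3): WHITE})
        assert loop_color_vector(t, t.root_children[0], chi) == [BLACK, WHITE]

    def test_root_vector(self):
        t = sd.build_loop_tree(sd.parse_dotbracket("()()()()"))
        cols = [WHITE, BLACK, GRAY, GRAY]
        chi = Coloring({v.pair: c for v, c in zip(t.root_children, cols)})
        assert loop_color_vector(t, None, chi) == cols

    def test_gray_node_with_three_children(self):
        t = sd.build_loop_tree(sd.parse_dotbracket("(()()())"))
        v = t.root_children[0]
        chi = Coloring({v.pair: GRAY})
        for c, col in zip(v.children, [WHITE, BLACK, GRAY]):
            chi[c.pair] = col
        assert loop_color_vector(t, v, chi) == [GRAY, WHITE, BLACK, GRAY]
        assert sd.is_proper(t, chi)


class TestProperness:
    def test_single_pair_any_color(self):
        t = sd.build_loop_tree(sd.parse_dotbracket("()"))
        for c in Color:
            assert sd.is_proper(t, Coloring({(1, 2): c}))

    def test_gray_parent_of_leaf_improper(self):
        t = sd.build_loop_tree(sd.parse_dotbracket("(.)"))
        assert not sd.is_proper(t, Coloring({(1, 3): GRAY}))

    def test_white_black_edge_improper(self):
        t = sd.build_loop_tree(sd.parse_dotbracket("(())"))
        assert not sd.is_proper(t, Coloring({(1, 4): WHITE, (2, 3): BLACK}))
        assert sd.is_proper(t, Coloring({(1, 4): WHITE, (2, 3): WHITE}))

    def test_m5_loop_has_no_proper_coloring(self):
        t = sd.build_loop_tree(sd.parse_dotbracket("(()()()())"))
        pairs = [v.pair for v in t.nodes]
        for combo in itertools.product(list(Color), repeat=len(pairs)):
            assert not sd.is_proper(t, Coloring(dict(zip(pairs, combo))))

    def test_proper_loops_have_at_most_four_pairs(self, rng):
        # any loop with >= 5 pairs (m5) is uncolorable; cross-check via solve
        for _ in range(100):
            t = sd.build_loop_tree(sd.sample_structure(25, 0, rng))
            chi = sd.solve(t, 3, require_motif_free=False)
            if chi is None:
                continue
            from oracles import loop_pair_and_leaf_counts

            assert all(k <= 4 for k, _ in loop_pair_and_leaf_counts(t)[1:])


class TestLevels:
    def test_root_children_level_zero(self):
        t = sd.build_loop_tree(sd.parse_dotbracket("()()"))
        chi = Coloring({(1, 2): WHITE, (3, 4): BLACK})
        lm = sd.levels(t, chi)
        assert lm.pair_levels == {(1, 2): 0, (3, 4): 0}

    def test_all_white_chain(self):
        t = sd.build_loop_tree(sd.parse_dotbracket("((()))"))
        chi = Coloring({v.pair: WHITE for v in t.nodes})
        lm = sd.levels(t, chi)
        assert sorted(lm.pair_levels.values()) == [0, 1, 2]

    def test_all_gray_chain(self):
        t = sd.build_loop_tree(sd.parse_dotbracket("((()))"))
        chi = Coloring({v.pair: GRAY for v in t.nodes})
        assert set(sd.levels(t, chi).pair_levels.values()) == {0}

    def test_recolor_shifts_only_subtree(self, rng):
        for _ in range(20):
            t = sd.build_loop_tree(sd.sample_structure(30, 0, rng))
            if not t.nodes:
                continue
            chi = Coloring(
                {v.pair: rng.choice(list(Color)) for v in t.nodes}
            )
            before = sd.levels(t, chi)
            v = rng.choice(t.nodes)
            old = chi[v.pair]
            new = rng.choice([c for c in Color if c != old])
            chi[v.pair] = new
            after = sd.levels(t, chi)
            shift = sd.delta(new) - sd.delta(old)
            inside = set()
            stack = list(v.children)
            leaf_inside = set(v.leaves)
            while stack:
                u = stack.pop()
                inside.add(u.pair)
                leaf_inside.update(u.leaves)
                stack.extend(u.children)
            for pair, lvl in before.pair_levels.items():
                expect = lvl + (shift if pair in inside else 0)
                assert after.pair_levels[pair] == expect
            for pos, lvl in before.leaf_levels.items():
                expect = lvl + (shift if pos in leaf_inside else 0)
                assert after.leaf_levels[pos] == expect


class TestSeparation:
    def test_hairpin_white_separated(self):
        t = sd.build_loop_tree(sd.parse_dotbracket("(.)"))
        assert sd.is_separated(t, Coloring({(1, 3): WHITE}))

    def test_gray_leaf_collision(self):
        # leaf (pos 3) and gray node (7,8) both end up at level 1: proper but
        # not separated
        t = sd.build_loop_tree(sd.parse_dotbracket("((.))(())"))
        chi = Coloring(
            {(1, 5): GRAY, (2, 4): WHITE, (6, 9): WHITE, (7, 8): GRAY}
        )
        assert sd.is_proper(t, chi)
        lm = sd.levels(t, chi)
        assert lm.leaf_levels[3] == 1
        assert lm.pair_levels[(7, 8)] == 1
        assert not sd.is_separated(t, chi)
        # recoloring moves the gray to level -1, away from the leaf
        chi2 = Coloring(
            {(1, 5): GRAY, (2, 4): WHITE, (6, 9): BLACK, (7, 8): GRAY}
        )
        assert sd.is_separated(t, chi2)

    def test_m_separated_implies_separated(self, rng):
        for _ in range(50):
            t = sd.build_loop_tree(sd.sample_structure(30, 3, rng))
            for m in (2, 3, 4):
                chi = sd.solve(t, m)
                if chi is not None:
                    assert sd.is_m_separated(t, chi, m)
                    assert sd.is_separated(t, chi)

    def test_separated_is_span_plus_one_separated(self, rng):
        for _ in range(30):
            t = sd.build_loop_tree(sd.sample_structure(24, 0, rng))
            chi = sd.solve(t, 2)
            if chi is None:
                continue
            lm = sd.levels(t, chi)
            used = list(lm.leaf_levels.values()) + list(lm.gray_levels(chi))
            if not used:
                continue
            m_prime = max(used) - min(used) + 1
            assert sd.is_m_separated(t, chi, m_prime)

    def test_m_implies_km(self, rng):
        for _ in range(30):
            t = sd.build_loop_tree(sd.sample_structure(26, 0, rng))
            for m in (2, 3, 4):
                chi = sd.solve(t, m)
                if chi is None:
                    continue
                for k in (2, 3):
                    assert sd.is_m_separated(t, chi, k * m)

    def test_invalid_modulus(self):
        t = sd.build_loop_tree(sd.parse_dotbracket("()"))
        with pytest.raises(ValueError):
            sd.is_m_separated(t, Coloring({(1, 2): WHITE}), 0)


class TestColoringFromSequence:
    def test_white_convention(self):
        t = sd.build_loop_tree(sd.parse_dotbracket("(.)"))
        assert sd.coloring_from_sequence(t, "CAG")[(1, 3)] == WHITE

    def test_gray(self):
        t = sd.build_loop_tree(sd.parse_dotbracket("()"))
        assert sd.coloring_from_sequence(t, "AU")[(1, 2)] == GRAY
        assert sd.coloring_from_sequence(t, "UA")[(1, 2)] == GRAY

    def test_gu_rejected(self):
        t = sd.build_loop_tree(sd.parse_dotbracket("()"))
        with pytest.raises(SequenceError):
            sd.coloring_from_sequence(t, "GU")

    def test_strict_unpaired(self):
        t = sd.build_loop_tree(sd.parse_dotbracket("(.)"))
        with pytest.raises(SequenceError):
            sd.coloring_from_sequence(t, "CCG")
        assert sd.coloring_from_sequence(t, "CCG", strict=False)[(1, 3)] == WHITE

    def test_annotation_roundtrip(self, rng):
        for _ in range(20):
            t = sd.build_loop_tree(sd.sample_structure(30, 3, rng))
            chi = sd.solve(t, 2)
            if chi is None:
                continue
            ann = chi.to_annotation(t)
            assert Coloring.from_annotation(t, ann) == chi


class TestMinModulus:
    def test_empty_structure(self):
        assert sd.min_separating_modulus(sd.build_loop_tree(sd.parse_dotbracket("...."))) == 1
        assert sd.min_separating_modulus(sd.build_loop_tree(sd.parse_dotbracket(""))) == 1

    def test_stable_targets_get_two(self, rng):
        ens = sd.ConstrainedEnsemble(60, 3, min_helix=3)
        for _ in range(20):
            t = sd.build_loop_tree(ens.sample(rng))
            if t.nodes:
                assert sd.min_separating_modulus(t) == 2

    def test_motif_hit_none(self):
        t = sd.build_loop_tree(sd.parse_dotbracket("(()()()())"))
        assert sd.min_separating_modulus(t) is None

    def test_bare_definition_start(self):
        # without the schedule convention, grayless targets are 1-separable
        t = sd.build_loop_tree(sd.parse_dotbracket("((()))"))
        assert sd.min_separating_modulus(t, start_at_two=False) == 1
        assert sd.min_separating_modulus(t) == 2
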