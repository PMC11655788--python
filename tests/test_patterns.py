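"""Patterns of equality, orbits under recodings, invariant partitions."""

import itertools
import math
from fractions import Fraction

import pytest

from neural_automata import (Alphabet, RectangleCell, corner_digits,
                             enumerate_orbit, interval_partition_classes,
                             pattern_of_equality, rectangle_orbit, same_orbit,
                             square_partition_classes)

WORD8 = tuple("aaabcabc")
ORBIT8 = {"bbbacbac", "cccbacba", "aaacbacb", "bbbcabca", "cccabcab", "aaabcabc"}


class TestPatternOfEquality:
    def test_worked_example(self):
        pat = pattern_of_equality(WORD8)
        assert pat.as_sets() == {frozenset({1, 2, 3, 6}),
                                 frozenset({4, 7}), frozenset({5, 8})}

    def test_constant_word(self):
        assert pattern_of_equality("aaaa").blocks == ((1, 2, 3, 4),)

    def test_repeated_first_symbol(self):
        assert pattern_of_equality("abca").as_sets() == \
            {frozenset({1, 4}), frozenset({2}), frozenset({3})}

    def test_anchored_marks_blank_positions(self):
        pat = pattern_of_equality(("_", "a", "_"), blank="_")
        assert pat.zero_block == (1, 3)
        assert pattern_of_equality(("a", "b"), blank="_").zero_block == ()

    def test_empty_word_rejected(self):
        with pytest.raises(ValueError):
            pattern_of_equality(())


class TestSameOrbit:
    def test_printed_pair(self):
        assert same_orbit(WORD8, tuple("bbbacbac"))

    def test_reflexive(self):
        assert same_orbit(WORD8, WORD8)

    def test_pattern_mismatch(self):
        assert not same_orbit(WORD8, tuple("aabbcabc"))

    def test_equivalence_relation_on_samples(self, abc):
        words = list(itertools.product(abc.symbols, repeat=4))
        for w, u, v in zip(words[::7], words[1::7], words[2::7]):
            assert same_orbit(w, w)
            assert same_orbit(w, u) == same_orbit(u, w)
            if same_orbit(w, u) and same_orbit(u, v):
                assert same_orbit(w, v)

    def test_anchored_requires_matching_blank_positions(self):
        # same unanchored pattern, blanks in different position sets
        assert same_orbit(("_", "a"), ("a", "_"))
        assert not same_orbit(("_", "a"), ("a", "_"), blank="_")


class TestEnumerateOrbit:
    def test_printed_example(self, abc):
        orbit = enumerate_orbit(WORD8, abc)
        assert {"".join(w) for w in orbit} == ORBIT8
        assert len(orbit) == 6

    def test_single_symbol_word(self, abc):
        assert enumerate_orbit(("b",), abc) == [("a",), ("b",), ("c",)]

    @pytest.mark.parametrize("m", [2, 3, 4])
    def test_size_formula_exhaustive(self, m):
        """|orbit| = m!/(m-k)! for k distinct symbols; anchored
        (m-1)!/(m-1-k')! over nonblank symbols."""
        alpha = Alphabet(tuple(range(m)), 0)
        for l in range(1, 7):
            # sample the word space at a fixed stride to keep l=6 cheap
            words = list(itertools.product(range(m), repeat=l))
            for w in words[:: max(1, len(words) // 200)]:
                k = len(set(w))
                assert len(enumerate_orbit(w, alpha)) == \
                    math.perm(m, k)
                k_nb = len(set(w) - {0})
                assert len(enumerate_orbit(w, alpha, anchored=True)) == \
                    math.perm(m - 1, k_nb)

    def test_matches_brute_force_filter(self, abc):
        for w in [("a", "b", "b"), ("c", "a", "c"), ("b", "b", "b")]:
            brute = [u for u in itertools.product(abc.symbols, repeat=3)
                     if same_orbit(w, u)]
            assert enumerate_orbit(w, abc) == brute

    def test_recoding_images_oracle(self, abc):
        """Orbit members are exactly the images under alphabet
        bijections (blank-fixing ones in anchored mode)."""
        for l in range(1, 6):
            for w in itertools.product(abc.symbols, repeat=l):
                images = {tuple(dict(zip(abc.symbols, perm))[a] for a in w)
                          for perm in itertools.permutations(abc.symbols)}
                assert set(enumerate_orbit(w, abc)) == images
                anchored_images = {
                    tuple(dict(zip(abc.symbols, ("a",) + perm))[a] for a in w)
                    for perm in itertools.permutations(("b", "c"))}
                assert set(enumerate_orbit(w, abc, anchored=True)) == \
                    anchored_images


class TestCornerDigits:
    @pytest.mark.parametrize("index,m,l,digits", [
        (6, 3, 2, (2, 0)),
        (10, 3, 3, (1, 0, 1)),
        (0, 3, 4, (0, 0, 0, 0)),
    ])
    def test_examples(self, index, m, l, digits):
        assert corner_digits(index, m, l) == digits

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            corner_digits(9, 3, 2)


class TestIntervalPartition:
    def test_two_symbols_depth_one_single_class(self):
        classes = interval_partition_classes(2, 1)
        assert len(classes) == 1
        ivs = next(iter(classes.values()))
        assert {(iv.lower, iv.upper) for iv in ivs} == \
            {(Fraction(0), Fraction(1, 2)), (Fraction(1, 2), Fraction(1))}

    def test_depth3_class_sizes(self):
        classes = interval_partition_classes(3, 3)
        sizes = sorted(len(v) for v in classes.values())
        assert set(sizes) == {3, 6}
        assert sum(sizes) == 27

    @pytest.mark.parametrize("m,l", [(2, 5), (3, 4), (4, 5)])
    @pytest.mark.parametrize("anchored", [False, True])
    def test_conservation(self, m, l, anchored):
        classes = interval_partition_classes(m, l, anchored)
        assert sum(len(v) for v in classes.values()) == m**l
        # disjoint cover
        lowers = [iv.lower for v in classes.values() for iv in v]
        assert len(set(lowers)) == m**l


SIX_CELLS = {(1, 23), (3, 20), (2, 16), (6, 10), (7, 3), (5, 6)}


class TestSquarePartition:
    def test_joint_worked_example(self):
        """Joint-recoding class of the cell [6/9,7/9) x [10/27,11/27)."""
        classes = square_partition_classes(3, 3, 2, 3, mode="joint")
        cell_class = next(v for v in classes.values()
                          if any(c.i == 6 and c.j == 10 for c in v))
        assert {(c.i, c.j) for c in cell_class} == SIX_CELLS
        assert sum(len(v) for v in classes.values()) == 3**5

    def test_joint_worked_example_bounds(self):
        cells = rectangle_orbit(RectangleCell(6, 10, 3, 3, 2, 3), mode="joint")
        bounds = {((c.x.lower, c.x.upper), (c.y.lower, c.y.upper))
                  for c in cells}
        expected = {
            ((Fraction(1, 9), Fraction(2, 9)), (Fraction(23, 27), Fraction(24, 27))),
            ((Fraction(3, 9), Fraction(4, 9)), (Fraction(20, 27), Fraction(21, 27))),
            ((Fraction(2, 9), Fraction(3, 9)), (Fraction(16, 27), Fraction(17, 27))),
            ((Fraction(6, 9), Fraction(7, 9)), (Fraction(10, 27), Fraction(11, 27))),
            ((Fraction(7, 9), Fraction(8, 9)), (Fraction(3, 27), Fraction(4, 27))),
            ((Fraction(5, 9), Fraction(6, 9)), (Fraction(6, 27), Fraction(7, 27))),
        }
        assert bounds == expected

    def test_joint_needs_equal_sizes(self):
        with pytest.raises(ValueError):
            square_partition_classes(5, 3, 2, 3, mode="joint")

    def test_anchored_all_blank_cell_is_singleton(self):
        classes = square_partition_classes(3, 3, 1, 1, anchored=True)
        key = RectangleCell(0, 0, 3, 3, 1, 1).key(anchored=True)
        assert [(c.i, c.j) for c in classes[key]] == [(0, 0)]

    @pytest.mark.parametrize("m_left,m_right", [(3, 3), (3, 4), (4, 3)])
    @pytest.mark.parametrize("anchored", [False, True])
    def test_per_axis_class_is_product_of_1d_orbits(self, m_left, m_right,
                                                    anchored):
        l, r = 2, 2
        classes = square_partition_classes(m_left, m_right, l, r,
                                           "per_axis", anchored)
        assert sum(len(v) for v in classes.values()) == m_left**l * m_right**r
        alpha_l = Alphabet(tuple(range(m_left)), 0)
        alpha_r = Alphabet(tuple(range(m_right)), 0)
        for cells in classes.values():
            c0 = cells[0]
            orb_l = enumerate_orbit(c0.left_digits, alpha_l, anchored)
            orb_r = enumerate_orbit(c0.right_digits, alpha_r, anchored)
            assert len(cells) == len(orb_l) * len(orb_r)
            expected = {(ld, rd) for ld in orb_l for rd in orb_r}
            assert {(c.left_digits, c.right_digits) for c in cells} == expected


class TestRectangleOrbit:
    def test_membership(self):
        cell = RectangleCell(6, 10, 3, 3, 2, 3)
        assert any(c.i == 6 and c.j == 10
                   for c in rectangle_orbit(cell, mode="joint"))

    @pytest.mark.parametrize("mode", ["per_axis", "joint"])
    def test_orbits_tile_the_square(self, mode):
        m, l, r = 3, 2, 2
        seen = set()
        for i in range(m**l):
            for j in range(m**r):
                if (i, j) in seen:
                    continue
                orbit = rectangle_orbit(RectangleCell(i, j, m, m, l, r),
                                        mode=mode)
                cells = {(c.i, c.j) for c in orbit}
                assert (i, j) in cells
                assert not (cells & seen)
                seen |= cells
        assert len(seen) == m**l * m**r

    def test_matches_full_partition_scan(self):
        classes = square_partition_classes(3, 3, 2, 2, "per_axis", True)
        for cells in classes.values():
            c0 = cells[0]
            orbit = rectangle_orbit(c0, mode="per_axis", anchored=True)
            assert {(c.i, c.j) for c in orbit} == {(c.i, c.j) for c in cells}
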