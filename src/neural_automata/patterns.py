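"""Patterns of equality and the invariant partitions they generate.

The *pattern of equality* of a word is the set partition of its positions
induced by symbol identity: positions p and q fall in one block iff the
word carries the same symbol at both.  It is the complete invariant for
the action of alphabet bijections (Gödel recodings) on words of a fixed
length: a word can be recoded into exactly the words sharing its pattern.

In *blank-anchored* mode the recoding group shrinks to the bijections
fixing the blank symbol, and the pattern is augmented with the set of
positions holding the blank (code 0), which must be preserved.

From the patterns of the corner digit words one obtains partitions of the
unit interval (cylinder intervals of one depth) and of the unit square
(rectangle cells of one resolution) into recoding-invariant classes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from .symbolic import Alphabet, Encoding, RationalInterval, Symbol, cylinder_interval

__all__ = [
    "EqualityPattern",
    "RectangleCell",
    "pattern_of_equality",
    "pattern_key",
    "same_orbit",
    "enumerate_orbit",
    "corner_digits",
    "interval_partition_classes",
    "square_partition_classes",
    "rectangle_orbit",
]


@dataclass(frozen=True)
class EqualityPattern:
    """Canonical set partition of {1, ..., l} (blocks sorted by least
    element), optionally marking the block of blank/code-0 positions."""

    blocks: tuple
    zero_block: tuple | None = None  # positions holding the blank; None = unanchored

    def __post_init__(self) -> None:
        blocks = tuple(sorted((tuple(sorted(b)) for b in self.blocks),
                              key=lambda b: b[0]))
        object.__setattr__(self, "blocks", blocks)
        if self.zero_block is not None:
            zb = tuple(sorted(self.zero_block))
            object.__setattr__(self, "zero_block", zb)
            if zb and zb not in blocks:
                raise ValueError("zero_block must be one of the blocks")
        seen = [p for b in blocks for p in b]
        if sorted(seen) != list(range(1, len(seen) + 1)):
            raise ValueError("blocks must partition 1..l")

    @property
    def length(self) -> int:
        return sum(len(b) for b in self.blocks)

    @property
    def anchored(self) -> bool:
        return self.zero_block is not None

    def as_sets(self) -> set:
        return {frozenset(b) for b in self.blocks}


def pattern_of_equality(w: Sequence[Symbol], blank: Symbol | None = None) -> EqualityPattern:
    """Pattern of equality of a nonempty word (positions counted from 1).

    Passing ``blank`` switches to anchored mode: the (possibly empty) set
    of positions holding ``blank`` is marked in the pattern.
    """
    w = tuple(w)
    if not w:
        raise ValueError("pattern of equality needs a nonempty word")
    groups: dict = {}
    for pos, a in enumerate(w, start=1):
        groups.setdefault(a, []).append(pos)
    blocks = tuple(tuple(v) for v in groups.values())
    zero = None
    if blank is not None:
        zero = tuple(groups.get(blank, ()))
    return EqualityPattern(blocks, zero)


def same_orbit(w: Sequence[Symbol], u: Sequence[Symbol],
               blank: Symbol | None = None) -> bool:
    """True iff some alphabet bijection (blank-fixing when ``blank`` is
    given) maps ``w`` to ``u``: equal lengths and equal patterns."""
    w, u = tuple(w), tuple(u)
    if len(w) != len(u):
        return False
    if not w:
        return True
    return pattern_of_equality(w, blank) == pattern_of_equality(u, blank)


def enumerate_orbit(w: Sequence[Symbol], alphabet: Alphabet,
                    anchored: bool = False) -> list:
    """All words of length |w| reachable from ``w`` by alphabet bijections.

    Unanchored: any injection of the distinct symbols of ``w`` into the
    alphabet gives a member, so the orbit has m(m-1)...(m-k+1) elements
    for k distinct symbols.  Anchored: the blank is fixed and the
    nonblank symbols inject into the nonblank alphabet.  The result is
    sorted lexicographically by symbol order in ``alphabet``.
    """
    w = tuple(w)
    for a in w:
        if a not in alphabet:
            raise ValueError(f"symbol {a!r} not in alphabet")
    distinct = list(dict.fromkeys(w))  # in order of first appearance
    if anchored:
        fixed = {alphabet.blank: alphabet.blank}
        movable = [a for a in distinct if a != alphabet.blank]
        targets = [s for s in alphabet.symbols if s != alphabet.blank]
    else:
        fixed = {}
        movable = distinct
        targets = list(alphabet.symbols)
    orbit = set()
    for image in itertools.permutations(targets, len(movable)):
        sub = dict(fixed)
        sub.update(zip(movable, image))
        orbit.add(tuple(sub[a] for a in w))
    return sorted(orbit, key=lambda word: tuple(alphabet.index(a) for a in word))


def corner_digits(index: int, m: int, l: int) -> tuple:
    """Base-m digits c_1..c_l (most significant first) of index / m**l."""
    if not 0 <= index < m**l:
        raise ValueError(f"index {index} out of range 0..{m**l - 1}")
    digits = []
    n = index
    for _ in range(l):
        n, d = divmod(n, m)
        digits.append(d)
    return tuple(reversed(digits))


def pattern_key(left_digits: Sequence[int], right_digits: Sequence[int],
                mode: str = "per_axis", anchored: bool = False):
    """Canonical orbit key of a rectangle cell from its corner digits.

    ``per_axis``: the pair of the two 1-D patterns (independent recoding
    of the two alphabets).  ``joint``: one pattern over the concatenated
    digit word (a single shared recoding; requires equal alphabet sizes,
    which the caller enforces).  Blank anchoring marks the code-0 blocks.
    """
    blank = 0 if anchored else None
    if mode == "per_axis":
        return (pattern_of_equality(left_digits, blank),
                pattern_of_equality(right_digits, blank))
    if mode == "joint":
        return pattern_of_equality(tuple(left_digits) + tuple(right_digits), blank)
    raise ValueError(f"unknown mode {mode!r}")


def interval_partition_classes(m: int, l: int, anchored: bool = False
                               ) -> dict:
    """Recoding-invariant classes of the depth-``l`` cylinder partition.

    Maps each pattern of equality to the list of intervals
    [k/m**l, (k+1)/m**l) whose corner digit words carry that pattern.
    """
    enc = Encoding.canonical(m)
    blank = 0 if anchored else None
    classes: dict = {}
    for k in range(m**l):
        digits = corner_digits(k, m, l)
        key = pattern_of_equality(digits, blank)
        classes.setdefault(key, []).append(cylinder_interval(digits, enc))
    return classes


@dataclass(frozen=True)
class RectangleCell:
    """Cell [i/m_left**l, (i+1)/m_left**l) x [j/m_right**r, (j+1)/m_right**r)
    of the resolution-(l, r) partition of the unit square.  Axis 1 (x)
    carries the left/stack word, axis 2 (y) the right/input word."""

    i: int
    j: int
    m_left: int
    m_right: int
    l: int
    r: int

    def __post_init__(self) -> None:
        if not 0 <= self.i < self.m_left**self.l:
            raise ValueError(f"cell index i={self.i} out of range")
        if not 0 <= self.j < self.m_right**self.r:
            raise ValueError(f"cell index j={self.j} out of range")

    @property
    def x(self) -> RationalInterval:
        d = self.m_left**self.l
        return RationalInterval(Fraction(self.i, d), Fraction(self.i + 1, d))

    @property
    def y(self) -> RationalInterval:
        d = self.m_right**self.r
        return RationalInterval(Fraction(self.j, d), Fraction(self.j + 1, d))

    @property
    def left_digits(self) -> tuple:
        return corner_digits(self.i, self.m_left, self.l)

    @property
    def right_digits(self) -> tuple:
        return corner_digits(self.j, self.m_right, self.r)

    def key(self, mode: str = "per_axis", anchored: bool = False):
        return pattern_key(self.left_digits, self.right_digits, mode, anchored)

    def __str__(self) -> str:
        return f"{self.x}x{self.y}"


def square_partition_classes(m_left: int, m_right: int, l: int, r: int,
                             mode: str = "per_axis", anchored: bool = False
                             ) -> dict:
    """Invariant classes of the m_left**l x m_right**r rectangle partition.

    Every cell is assigned to exactly one class via the pattern key of
    its corner digit words; the classes are the orbits of the recoding
    group (per-axis product group, or the shared joint group).
    """
    if mode == "joint" and m_left != m_right:
        raise ValueError("joint mode requires equal alphabet sizes")
    classes: dict = {}
    for i in range(m_left**l):
        ld = corner_digits(i, m_left, l)
        for j in range(m_right**r):
            rd = corner_digits(j, m_right, r)
            key = pattern_key(ld, rd, mode, anchored)
            classes.setdefault(key, []).append(
                RectangleCell(i, j, m_left, m_right, l, r))
    return classes


def _digit_perms(m: int, anchored: bool) -> Iterable[tuple]:
    base = range(1, m) if anchored else range(m)
    for perm in itertools.permutations(base):
        if anchored:
            mapping = (0,) + perm
        else:
            mapping = perm
        yield mapping


def _digits_to_index(digits: Sequence[int], m: int) -> int:
    n = 0
    for d in digits:
        n = n * m + d
    return n


def rectangle_orbit(cell: RectangleCell, mode: str = "per_axis",
                    anchored: bool = False) -> list:
    """The invariant class containing ``cell``, computed directly from
    its corner digits by applying the recoding group to them."""
    ld, rd = cell.left_digits, cell.right_digits
    cells = set()
    if mode == "joint":
        if cell.m_left != cell.m_right:
            raise ValueError("joint mode requires equal alphabet sizes")
        for pi in _digit_perms(cell.m_left, anchored):
            i = _digits_to_index([pi[d] for d in ld], cell.m_left)
            j = _digits_to_index([pi[d] for d in rd], cell.m_right)
            cells.add((i, j))
    elif mode == "per_axis":
        for pi1 in _digit_perms(cell.m_left, anchored):
            i = _digits_to_index([pi1[d] for d in ld], cell.m_left)
            for pi2 in _digit_perms(cell.m_right, anchored):
                j = _digits_to_index([pi2[d] for d in rd], cell.m_right)
                cells.add((i, j))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return [RectangleCell(i, j, cell.m_left, cell.m_right, cell.l, cell.r)
            for i, j in sorted(cells)]
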