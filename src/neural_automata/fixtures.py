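"""Seeded generators of random words, recodings and small machines.

These generators define the randomized test conditions of the package:
words over small alphabets, blank-fixing code permutations, and small
shift-free versatile shifts (alphabet sizes up to 3 including the blank,
at most 4 rules, DoD (1, 1), F = 0) together with short random initial
tapes.  Same seed, same fixtures.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np

from .shifts import DomainOfDependence, DottedWord, VersatileShift, VSRule
from .symbolic import Alphabet, Encoding

__all__ = [
    "random_words",
    "random_recoding",
    "random_encoding",
    "random_machine",
    "random_initial_states",
]


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def random_words(alphabet: Alphabet, count: int, length_range=(1, 8),
                 rng=0) -> list:
    rng = _rng(rng)
    lo, hi = length_range
    words = []
    for _ in range(count):
        length = int(rng.integers(lo, hi + 1))
        words.append(tuple(alphabet.symbols[int(k)]
                           for k in rng.integers(0, alphabet.size, length)))
    return words


def random_recoding(m: int, anchored: bool = False, rng=0) -> dict:
    """A random code permutation of 0..m-1, fixing 0 when anchored."""
    rng = _rng(rng)
    if anchored:
        perm = [0] + [int(c) for c in rng.permutation(np.arange(1, m))]
    else:
        perm = [int(c) for c in rng.permutation(m)]
    return {c: p for c, p in enumerate(perm)}


def random_encoding(alphabet: Alphabet, anchored: bool = True, rng=0) -> Encoding:
    rng = _rng(rng)
    if anchored:
        rest = [s for s in alphabet.symbols if s != alphabet.blank]
        order = [alphabet.blank] + [rest[int(k)]
                                    for k in rng.permutation(len(rest))]
    else:
        order = [alphabet.symbols[int(k)]
                 for k in rng.permutation(alphabet.size)]
    return Encoding.from_order(alphabet, order, blank_anchored=anchored)


def random_machine(rng=0, max_rules: int = 4) -> VersatileShift:
    """A random small shift-free versatile shift with DoD (1, 1).

    Left and right alphabets have 2 or 3 symbols including their blanks;
    each rule matches one non-blank stack symbol (and, half the time,
    one non-blank input symbol) and rewrites both sides with words of
    length 0..2 over the non-blank symbols.  Rules have distinct match
    patterns, so first-match order never matters.
    """
    rng = _rng(rng)
    m_l = int(rng.integers(2, 4))
    m_r = int(rng.integers(2, 4))
    left = Alphabet(tuple(f"L{k}" for k in range(m_l)), "L0")
    right = Alphabet(tuple(f"R{k}" for k in range(m_r)), "R0")
    nb_left = left.symbols[1:]
    nb_right = right.symbols[1:]
    patterns = [(ls, rs) for ls in nb_left
                for rs in (None,) + nb_right]
    order = rng.permutation(len(patterns))
    n_rules = int(rng.integers(1, max_rules + 1))
    rules = []
    for idx in order[:n_rules]:
        ls, rs = patterns[int(idx)]
        repl_l = tuple(nb_left[int(k)] for k in
                       rng.integers(0, len(nb_left), int(rng.integers(0, 3))))
        repl_r = tuple(nb_right[int(k)] for k in
                       rng.integers(0, len(nb_right), int(rng.integers(0, 3))))
        rules.append(VSRule(
            match_left=(ls,),
            match_right=() if rs is None else (rs,),
            repl_left=repl_l, repl_right=repl_r,
            label=f"r{len(rules)}"))
    return VersatileShift(left, right, DomainOfDependence(1, 1), tuple(rules))


def random_initial_states(vs: VersatileShift, count: int,
                          max_len: int = 4, rng=0) -> list:
    """Short random dotted words over a machine's alphabets (non-blank
    symbols only, so Gödel numbers have full-length expansions)."""
    rng = _rng(rng)
    nb_left = vs.left_alphabet.symbols[1:] or vs.left_alphabet.symbols
    nb_right = vs.right_alphabet.symbols[1:] or vs.right_alphabet.symbols
    states = []
    for _ in range(count):
        ll = int(rng.integers(0, max_len + 1))
        rl = int(rng.integers(0, max_len + 1))
        states.append(vs.trim(DottedWord(
            tuple(nb_left[int(k)] for k in rng.integers(0, len(nb_left), ll)),
            tuple(nb_right[int(k)] for k in rng.integers(0, len(nb_right), rl)),
        )))
    return states
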