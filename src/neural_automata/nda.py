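"""Gödelization of versatile shifts into nonlinear dynamical automata.

A nonlinear dynamical automaton (NDA) is a piecewise affine map on the
unit square.  Gödel-encoding the two sides of a dotted sequence gives a
phase point ``y = (y1, y2)`` with ``y1`` the stack Gödel number (axis 1,
base ``m_left``) and ``y2`` the input Gödel number (axis 2, base
``m_right``).  The DoD windows determine a rectangle partition of the
square — ``m_left**k_l`` intervals on axis 1 times ``m_right**k_r`` on
axis 2 — and on each cell with a matching rewrite rule the VS move
becomes one diagonal affine branch

    y1' = lambda1 * y1 + a1,    lambda1 = m_left**(p - |v|),
                                a1 = psi(v) - lambda1 * psi(u[:p]),

where ``u`` is the cell's stack window, ``p`` the matched prefix length
and ``v`` the (bound) replacement; axis 2 analogously.  The coefficients
are forced by the conjugacy contract

    encode(vs_step(s)) == nda_step(encode(s))

which holds exactly in rational arithmetic because the cell fixes the
DoD digits while the affine map transports the remaining tape tail
untouched.  Cells whose window matches no rule carry no branch: they are
the halting region (the all-blank cell is the accepting corner).

Only shift-free rules (F = 0) can be compiled: a dot shift mixes the two
coordinates in a way that no diagonal affine branch expresses for
arbitrary tape tails.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

from .patterns import corner_digits
from .symbolic import DottedWord, Encoding, godel_encode
from .shifts import VersatileShift, match_rule, _substitute

__all__ = [
    "PhasePoint",
    "AffineBranch",
    "NDA",
    "encode_state",
    "decode_point",
    "build_nda",
    "nda_step",
    "run_nda",
]

PhasePoint = tuple  # (Fraction, Fraction), both in [0, 1)


@dataclass(frozen=True)
class AffineBranch:
    """Diagonal affine map y -> (lambda1*y1 + a1, lambda2*y2 + a2)."""

    a1: Fraction
    a2: Fraction
    lambda1: Fraction
    lambda2: Fraction

    def __call__(self, y: PhasePoint) -> PhasePoint:
        return (self.lambda1 * y[0] + self.a1, self.lambda2 * y[1] + self.a2)


@dataclass(frozen=True)
class NDA:
    """Cell partition of the unit square with one affine branch per
    rule-matching cell.  ``cells`` maps (i, j) to an AffineBranch; cell
    (i, j) covers [i/m_left**k_l, (i+1)/...) x [j/m_right**k_r, ...)."""

    left_encoding: Encoding
    right_encoding: Encoding
    k_l: int
    k_r: int
    cells: dict

    @property
    def m_left(self) -> int:
        return self.left_encoding.m

    @property
    def m_right(self) -> int:
        return self.right_encoding.m

    def cell_of(self, y: PhasePoint) -> tuple:
        i = int(Fraction(y[0]) * self.m_left**self.k_l)
        j = int(Fraction(y[1]) * self.m_right**self.k_r)
        return i, j

    def branch_at(self, y: PhasePoint):
        return self.cells.get(self.cell_of(y))


def encode_state(s: DottedWord, left_encoding: Encoding,
                 right_encoding: Encoding) -> PhasePoint:
    """Gödel-encode a dotted sequence: y1 from the stack side read
    dot-outward, y2 from the input side."""
    return (godel_encode(s.left, left_encoding),
            godel_encode(s.right, right_encoding))


def decode_point(y: PhasePoint, left_encoding: Encoding,
                 right_encoding: Encoding, l: int, r: int) -> DottedWord:
    """Inverse of encode_state at a given pair of tape lengths."""
    from .symbolic import godel_decode

    return DottedWord(godel_decode(y[0], left_encoding, l),
                      godel_decode(y[1], right_encoding, r))


def _psi_digits(digits: Sequence[int], m: int) -> Fraction:
    x = Fraction(0)
    w = Fraction(1, m)
    for d in digits:
        x += d * w
        w /= m
    return x


def build_nda(vs: VersatileShift, left_encoding: Encoding,
              right_encoding: Encoding) -> NDA:
    """Compile a versatile shift and a blank-anchored encoding pair into
    the conjugate NDA.

    Wildcard rules expand into one branch per concrete DoD content.
    Rules with a nonzero dot shift are rejected.
    """
    if not (left_encoding.blank_anchored and right_encoding.blank_anchored):
        raise ValueError("NDA compilation needs blank-anchored encodings")
    if left_encoding.alphabet != vs.left_alphabet or \
       right_encoding.alphabet != vs.right_alphabet:
        raise ValueError("encodings must cover the machine alphabets")
    k_l, k_r = vs.dod.k_l, vs.dod.k_r
    m_l, m_r = left_encoding.m, right_encoding.m
    cells: dict = {}
    for i in range(m_l**k_l):
        lw = tuple(left_encoding.symbol(d) for d in corner_digits(i, m_l, k_l))
        for j in range(m_r**k_r):
            rw = tuple(right_encoding.symbol(d)
                       for d in corner_digits(j, m_r, k_r))
            hit = match_rule(vs, DottedWord(lw, rw))
            if hit is None:
                continue  # halting cell (accept corner or dead end)
            rule, binding = hit
            if rule.shift != 0:
                raise ValueError(
                    "cannot compile a rule with nonzero dot shift into a "
                    "diagonal affine branch")
            p_l, p_r = len(rule.match_left), len(rule.match_right)
            v_l = _substitute(rule.repl_left, binding)
            v_r = _substitute(rule.repl_right, binding)
            lam1 = Fraction(m_l) ** (p_l - len(v_l))
            lam2 = Fraction(m_r) ** (p_r - len(v_r))
            a1 = godel_encode(v_l, left_encoding) - \
                lam1 * godel_encode(lw[:p_l], left_encoding)
            a2 = godel_encode(v_r, right_encoding) - \
                lam2 * godel_encode(rw[:p_r], right_encoding)
            cells[(i, j)] = AffineBranch(a1, a2, lam1, lam2)
    return NDA(left_encoding, right_encoding, k_l, k_r, cells)


def nda_step(nda: NDA, y: PhasePoint):
    """Apply the branch of the cell containing ``y``; ``None`` signals a
    halt (the cell carries no branch)."""
    branch = nda.branch_at(y)
    if branch is None:
        return None
    image = branch(y)
    if not (0 <= image[0] < 1 and 0 <= image[1] < 1):
        raise ValueError(f"branch image {image} escapes the unit square")
    return image


def run_nda(nda: NDA, y0: PhasePoint, steps: int) -> list:
    """Trajectory [y0, y1, ...] of at most ``steps`` moves, truncated at
    the first halt.  Exact rationals throughout."""
    ys = [(Fraction(y0[0]), Fraction(y0[1]))]
    for _ in range(steps):
        nxt = nda_step(nda, ys[-1])
        if nxt is None:
            break
        ys.append(nxt)
    return ys


def nda_to_json(nda: NDA) -> dict:
    """Bit-exact dump: cell bounds and branch coefficients as num/den."""
    def frac(x: Fraction) -> str:
        return f"{x.numerator}/{x.denominator}"

    cells = []
    dx = nda.m_left**nda.k_l
    dy = nda.m_right**nda.k_r
    for (i, j), b in sorted(nda.cells.items()):
        cells.append({
            "i": i, "j": j,
            "x_lo": frac(Fraction(i, dx)), "x_hi": frac(Fraction(i + 1, dx)),
            "y_lo": frac(Fraction(j, dy)), "y_hi": frac(Fraction(j + 1, dy)),
            "a1": frac(b.a1), "a2": frac(b.a2),
            "lambda1": frac(b.lambda1), "lambda2": frac(b.lambda2),
        })
    return {"m_left": nda.m_left, "m_right": nda.m_right,
            "k_l": nda.k_l, "k_r": nda.k_r, "cells": cells}


def save_nda(nda: NDA, path) -> None:
    with open(path, "w") as fh:
        json.dump(nda_to_json(nda), fh, indent=2)
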