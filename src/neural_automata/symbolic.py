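"""Alphabets, encodings, words, dotted words and Gödel arithmetic.

A *Gödel encoding* maps a finite word ``w = a_1 a_2 ... a_l`` over an
``m``-symbol alphabet to the rational number

    psi(w) = sum_k  gamma(a_k) * m**(-k)

where ``gamma`` is a bijection from the alphabet onto ``{0, ..., m-1}``.
Finite words stand in for one-sided infinite sequences padded with a
distinguished *blank* symbol; when the blank is anchored to code 0 the
padding is invisible to the encoding, which makes tape lengths
recoding-stable.

Everything in this module is exact: encodings, interval endpoints and the
boundary ultrametric are :class:`fractions.Fraction` values whose
denominators are powers of the alphabet size.  Floating point only enters
the package in the neural-network layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Hashable, Mapping, Sequence

__all__ = [
    "Symbol",
    "Word",
    "Alphabet",
    "Encoding",
    "DottedWord",
    "RationalInterval",
    "godel_encode",
    "godel_decode",
    "cylinder_interval",
    "tree_distance",
    "recode_word",
]

Symbol = Hashable
Word = tuple  # tuple of symbols; () is the empty word epsilon


@dataclass(frozen=True)
class Alphabet:
    """A finite ordered alphabet with a distinguished blank symbol."""

    symbols: tuple
    blank: Symbol

    def __post_init__(self) -> None:
        object.__setattr__(self, "symbols", tuple(self.symbols))
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be pairwise distinct")
        if self.blank not in self.symbols:
            raise ValueError(f"blank symbol {self.blank!r} not in alphabet")
        if len(self.symbols) < 2:
            raise ValueError("alphabet needs at least 2 symbols")

    @property
    def size(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: Symbol) -> bool:
        return symbol in self.symbols

    def __iter__(self):
        return iter(self.symbols)

    def index(self, symbol: Symbol) -> int:
        return self.symbols.index(symbol)

    @classmethod
    def digits(cls, m: int) -> "Alphabet":
        """The canonical digit alphabet {0, ..., m-1} with blank 0."""
        return cls(tuple(range(m)), 0)


@dataclass(frozen=True)
class Encoding:
    """A bijection from an alphabet onto the codes {0, ..., m-1}.

    ``blank_anchored`` records whether the encoding is required to send
    the blank symbol to 0 (the condition under which tape padding does
    not change Gödel numbers).
    """

    alphabet: Alphabet
    assignment: Mapping[Symbol, int] = field(hash=False)
    blank_anchored: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "assignment", dict(self.assignment))
        m = self.alphabet.size
        if set(self.assignment) != set(self.alphabet.symbols):
            raise ValueError("assignment domain must equal the alphabet")
        if sorted(self.assignment.values()) != list(range(m)):
            raise ValueError("assignment must be a bijection onto 0..m-1")
        if self.blank_anchored and self.assignment[self.alphabet.blank] != 0:
            raise ValueError("blank-anchored encoding must send blank to 0")

    @property
    def m(self) -> int:
        return self.alphabet.size

    def code(self, symbol: Symbol) -> int:
        try:
            return self.assignment[symbol]
        except KeyError:
            raise ValueError(f"symbol {symbol!r} not in alphabet") from None

    def symbol(self, code: int) -> Symbol:
        for sym, c in self.assignment.items():
            if c == code:
                return sym
        raise ValueError(f"code {code} out of range 0..{self.m - 1}")

    def codes(self, word: Sequence[Symbol]) -> tuple:
        return tuple(self.code(a) for a in word)

    @classmethod
    def from_order(cls, alphabet: Alphabet, order: Sequence[Symbol] | None = None,
                   blank_anchored: bool = False) -> "Encoding":
        """Encoding assigning code ``k`` to the ``k``-th symbol of ``order``."""
        if order is None:
            order = alphabet.symbols
        return cls(alphabet, {sym: k for k, sym in enumerate(order)}, blank_anchored)

    @classmethod
    def canonical(cls, m: int) -> "Encoding":
        """Identity encoding of the digit alphabet {0, ..., m-1}."""
        return cls.from_order(Alphabet.digits(m), blank_anchored=True)


@dataclass(frozen=True)
class RationalInterval:
    """Half-open interval [lower, upper) with exact rational endpoints."""

    lower: Fraction
    upper: Fraction

    def __post_init__(self) -> None:
        object.__setattr__(self, "lower", Fraction(self.lower))
        object.__setattr__(self, "upper", Fraction(self.upper))
        if not 0 <= self.lower < self.upper <= 1:
            raise ValueError(f"invalid interval [{self.lower}, {self.upper})")

    def __contains__(self, x) -> bool:
        return self.lower <= x < self.upper

    def contains_interval(self, other: "RationalInterval") -> bool:
        return self.lower <= other.lower and other.upper <= self.upper

    def __str__(self) -> str:
        return f"[{self.lower},{self.upper})"


@dataclass(frozen=True)
class DottedWord:
    """A two-sided tape around the dot.

    ``left`` is the stack side stored dot-outward (index 0 is the symbol
    adjacent to the dot), ``right`` the input side (index 0 adjacent to
    the dot).  The represented bi-infinite sequence is the finite dotted
    word padded with blanks on both far ends, so trailing blanks are
    trimmed on construction.
    """

    left: tuple = ()
    right: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "left", tuple(self.left))
        object.__setattr__(self, "right", tuple(self.right))

    def trimmed(self, left_blank: Symbol, right_blank: Symbol) -> "DottedWord":
        left, right = list(self.left), list(self.right)
        while left and left[-1] == left_blank:
            left.pop()
        while right and right[-1] == right_blank:
            right.pop()
        return DottedWord(tuple(left), tuple(right))

    @property
    def is_empty(self) -> bool:
        return not self.left and not self.right

    def window(self, k_l: int, k_r: int, left_blank: Symbol,
               right_blank: Symbol) -> tuple:
        """The DoD content: ``k_l`` symbols left of the dot (dot-outward)
        and ``k_r`` symbols right of it, blank-padded as needed."""
        lw = self.left[:k_l] + (left_blank,) * max(0, k_l - len(self.left))
        rw = self.right[:k_r] + (right_blank,) * max(0, k_r - len(self.right))
        return lw, rw

    def display(self, sep: str = " ") -> str:
        """Tape order: stack reversed (outermost first), dot, input."""
        ls = sep.join(str(a) for a in reversed(self.left))
        rs = sep.join(str(a) for a in self.right)
        return f"{ls}.{rs}"

    def __str__(self) -> str:
        return self.display()


def godel_encode(w: Sequence[Symbol], e: Encoding) -> Fraction:
    """Gödel number psi(w) = sum_k code(a_k) * m**(-k), an exact rational.

    Trailing code-0 symbols do not change the value; the empty word maps
    to 0.
    """
    m = e.m
    x = Fraction(0)
    weight = Fraction(1, m)
    for a in w:
        x += e.code(a) * weight
        weight /= m
    return x


def godel_decode(x, e: Encoding, l: int) -> tuple:
    """The length-``l`` word whose base-m digit sequence encodes ``x``.

    ``x * m**l`` must be an integer (``x`` a corner of the depth-``l``
    cylinder partition); otherwise a :class:`ValueError` is raised.
    """
    m = e.m
    x = Fraction(x)
    scaled = x * m**l
    if scaled.denominator != 1 or not 0 <= scaled < m**l:
        raise ValueError(
            f"{x} is not a depth-{l} corner of the base-{m} partition")
    digits = []
    n = int(scaled)
    for _ in range(l):
        n, d = divmod(n, m)
        digits.append(d)
    return tuple(e.symbol(d) for d in reversed(digits))


def cylinder_interval(w: Sequence[Symbol], e: Encoding) -> RationalInterval:
    """Gödel image of the cylinder set of all infinite extensions of ``w``:
    the half-open interval [psi(w), psi(w) + m**(-|w|))."""
    w = tuple(w)
    if not w:
        raise ValueError("cylinder interval needs a nonempty word")
    lo = godel_encode(w, e)
    return RationalInterval(lo, lo + Fraction(1, e.m ** len(w)))


def tree_distance(p: Sequence[Symbol], q: Sequence[Symbol], m: int,
                  blank: Symbol | None = None) -> Fraction:
    """Ultrametric on the boundary of the rooted m-ary tree.

    Words are read as blank-padded infinite rays: distance 0 iff the rays
    agree everywhere, 1 if they differ at the first symbol, and m**(-n)
    if they share exactly an n-symbol prefix.  Satisfies the strong
    triangle inequality d(p,q) <= max(d(p,r), d(r,q)).
    """
    p, q = tuple(p), tuple(q)
    depth = max(len(p), len(q))
    if blank is not None:
        p += (blank,) * (depth - len(p))
        q += (blank,) * (depth - len(q))
    elif len(p) != len(q):
        raise ValueError("pass blank= to compare words of different length")
    n = 0
    for a, b in zip(p, q):
        if a != b:
            break
        n += 1
    else:
        return Fraction(0)
    if n == 0:
        return Fraction(1)
    return Fraction(1, m**n)


def recode_word(w: Sequence[Symbol], pi: Mapping[int, int],
                e_from: Encoding, e_to: Encoding) -> tuple:
    """Relabel ``w`` through the code permutation ``pi``.

    The result is the word whose code sequence under ``e_to`` equals
    ``pi`` applied to ``w``'s code sequence under ``e_from``.  When
    ``e_to = pi o e_from`` this fixes the symbols and permutes only the
    codes; applied with canonical encodings it permutes digits in place.
    """
    m = e_from.m
    if e_to.m != m:
        raise ValueError("encodings must share one alphabet size")
    if sorted(pi.keys()) != list(range(m)) or sorted(pi.values()) != list(range(m)):
        raise ValueError("pi must be a permutation of 0..m-1")
    if e_from.blank_anchored and e_to.blank_anchored and pi[0] != 0:
        raise ValueError("blank-anchored recoding must fix code 0")
    return tuple(e_to.symbol(pi[e_from.code(a)]) for a in w)
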