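"""Versatile shifts: dotted-sequence rewriting machines.

A versatile shift (VS) acts on dotted sequences — two-sided tapes split
by a dot into a stack side (left, read dot-outward) and an input side
(right).  Its next move is fully determined by the tape content inside a
finite *domain of dependence* (DoD) of ``k_l`` symbols left and ``k_r``
symbols right of the dot: the matched dotted prefix is replaced by a
dotted word of arbitrary length and the dot is then shifted ``F``
positions.  Generalized shifts (symbol-for-symbol substitution, Moore's
Turing-universal construction) are the equal-length special case.

A context-free grammar compiles into a VS implementing a top-down
recognizer: one *predict* rule per production (expanding the stack-top
nonterminal, first right-hand symbol adjacent to the dot) plus a single
*attach* rule cancelling equal terminals from stack and input.  The
machine accepts when both tape sides are empty.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .symbolic import Alphabet, DottedWord, Symbol

__all__ = [
    "Var",
    "DomainOfDependence",
    "VSRule",
    "VersatileShift",
    "Trace",
    "NoMatchingRule",
    "match_rule",
    "vs_step",
    "run",
    "build_topdown_recognizer",
    "compile_generalized_shift",
    "machine_to_config",
    "machine_from_config",
]


@dataclass(frozen=True)
class Var:
    """A wildcard pattern variable binding one non-blank symbol; the same
    variable may appear on both sides of a rule and in replacements."""

    name: str

    def __str__(self) -> str:
        return f"?{self.name}"


@dataclass(frozen=True)
class DomainOfDependence:
    k_l: int
    k_r: int

    def __post_init__(self) -> None:
        if self.k_l < 0 or self.k_r < 0 or self.k_l + self.k_r == 0:
            raise ValueError("DoD needs nonnegative windows, at least one positive")


@dataclass(frozen=True)
class VSRule:
    """Rewrite rule: match the dotted prefix (match_left . match_right)
    inside the DoD windows, substitute (repl_left . repl_right), then
    shift the dot ``shift`` positions (positive = left shift sigma).

    Pattern words are stored dot-outward like tape sides.  Literal
    symbols match themselves; :class:`Var` matches any non-blank symbol,
    consistently across both sides.
    """

    match_left: tuple = ()
    match_right: tuple = ()
    repl_left: tuple = ()
    repl_right: tuple = ()
    shift: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        for part in ("match_left", "match_right", "repl_left", "repl_right"):
            object.__setattr__(self, part, tuple(getattr(self, part)))
        bound = {t.name for t in self.match_left + self.match_right
                 if isinstance(t, Var)}
        used = {t.name for t in self.repl_left + self.repl_right
                if isinstance(t, Var)}
        if not used <= bound:
            raise ValueError(f"unbound wildcard(s) {used - bound} in replacement")


@dataclass(frozen=True)
class VersatileShift:
    left_alphabet: Alphabet
    right_alphabet: Alphabet
    dod: DomainOfDependence
    rules: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "rules", tuple(self.rules))
        for rule in self.rules:
            if len(rule.match_left) > self.dod.k_l:
                raise ValueError("left match pattern exceeds DoD window")
            if len(rule.match_right) > self.dod.k_r:
                raise ValueError("right match pattern exceeds DoD window")

    def trim(self, s: DottedWord) -> DottedWord:
        return s.trimmed(self.left_alphabet.blank, self.right_alphabet.blank)

    def window(self, s: DottedWord) -> tuple:
        return s.window(self.dod.k_l, self.dod.k_r,
                        self.left_alphabet.blank, self.right_alphabet.blank)


@dataclass(frozen=True)
class Trace:
    """A run transcript: (time, state, operation label) triples.  The
    label at time t names the operation applied to reach time t+1; the
    final row is labelled Accept, Reject or MaxSteps."""

    steps: tuple
    halt_status: str  # accepted | rejected | max_steps

    @property
    def states(self) -> list:
        return [s for _, s, _ in self.steps]

    @property
    def operations(self) -> list:
        return [op for _, _, op in self.steps]

    def __len__(self) -> int:
        return len(self.steps)


class NoMatchingRule(Exception):
    """Raised by vs_step when no rule matches (the machine halts)."""


def _match_side(pattern: tuple, window: tuple, blank: Symbol,
                binding: dict) -> bool:
    for tok, sym in zip(pattern, window):
        if isinstance(tok, Var):
            if sym == blank:
                return False
            if binding.setdefault(tok.name, sym) != sym:
                return False
        elif tok != sym:
            return False
    return True


def match_rule(vs: VersatileShift, s: DottedWord):
    """First rule (in list order) matching the DoD windows of ``s``,
    returned with its wildcard binding; ``None`` if no rule matches.

    The all-blank window matches no rule: the empty dotted sequence is
    the halting (accepting) configuration.
    """
    lw, rw = vs.window(s)
    if all(a == vs.left_alphabet.blank for a in lw) and \
       all(a == vs.right_alphabet.blank for a in rw):
        return None
    for rule in vs.rules:
        binding: dict = {}
        if _match_side(rule.match_left, lw, vs.left_alphabet.blank, binding) and \
           _match_side(rule.match_right, rw, vs.right_alphabet.blank, binding):
            return rule, binding
    return None


def _substitute(part: tuple, binding: Mapping[str, Symbol]) -> tuple:
    return tuple(binding[t.name] if isinstance(t, Var) else t for t in part)


def vs_step(vs: VersatileShift, s: DottedWord) -> DottedWord:
    """One move: replace the matched dotted prefix, then shift the dot.

    Raises :class:`NoMatchingRule` when the machine halts at ``s``.
    """
    hit = match_rule(vs, s)
    if hit is None:
        raise NoMatchingRule(str(s))
    rule, binding = hit
    s = vs.trim(s)
    left = _substitute(rule.repl_left, binding) + s.left[len(rule.match_left):]
    right = _substitute(rule.repl_right, binding) + s.right[len(rule.match_right):]
    # positive shift = left shift sigma: the dot moves right, carrying
    # symbols from the input side onto the stack side
    f = rule.shift
    lb, rb = vs.left_alphabet.blank, vs.right_alphabet.blank
    while f > 0:
        head = right[0] if right else rb
        left = (head,) + left
        right = right[1:]
        f -= 1
    while f < 0:
        head = left[0] if left else lb
        right = (head,) + right
        left = left[1:]
        f += 1
    return vs.trim(DottedWord(left, right))


def run(vs: VersatileShift, s0: DottedWord, max_steps: int = 1000) -> Trace:
    """Iterate vs_step from ``s0`` until the empty dotted sequence
    (accepted), a state with no matching rule (rejected), or the step
    budget runs out."""
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    s = vs.trim(s0)
    steps = []
    for t in range(max_steps + 1):
        if s.is_empty:
            steps.append((t, s, "Accept"))
            return Trace(tuple(steps), "accepted")
        hit = match_rule(vs, s)
        if hit is None:
            steps.append((t, s, "Reject"))
            return Trace(tuple(steps), "rejected")
        rule, binding = hit
        steps.append((t, s, rule.label or "Rewrite"))
        if t == max_steps:
            return Trace(tuple(steps), "max_steps")
        s = vs_step(vs, s)
    return Trace(tuple(steps), "max_steps")


def build_topdown_recognizer(productions: Sequence[tuple],
                             terminals: Sequence[Symbol],
                             nonterminals: Sequence[Symbol],
                             blank: Symbol = "_") -> VersatileShift:
    """Compile a context-free grammar into a top-down recognizer VS.

    ``productions`` maps nonterminals to nonempty right-hand strings,
    e.g. ``[("S", ("NP", "VP"))]``.  The machine has DoD (1, 1); each
    production X -> Y1...Yp yields a predict rule rewriting stack-top X
    to Y1...Yp with Y1 adjacent to the dot and the input untouched, and
    a single shared-wildcard attach rule cancels any terminal appearing
    on both stack top and input front.  All shifts are 0.

    Epsilon productions and left recursion are accepted syntactically;
    termination is then only guarded by the run's step budget.
    """
    terminals = tuple(terminals)
    nonterminals = tuple(nonterminals)
    stack_alphabet = Alphabet((blank,) + terminals + nonterminals, blank)
    input_alphabet = Alphabet((blank,) + terminals, blank)
    rules = []
    for lhs, rhs in productions:
        rhs = tuple(rhs)
        if lhs not in nonterminals:
            raise ValueError(f"production head {lhs!r} is not a nonterminal")
        for sym in rhs:
            if sym not in stack_alphabet:
                raise ValueError(f"production symbol {sym!r} unknown")
        label = f"Predict ({lhs} -> {' '.join(str(a) for a in rhs)})"
        rules.append(VSRule(match_left=(lhs,), repl_left=rhs, label=label))
    a = Var("a")
    rules.append(VSRule(match_left=(a,), match_right=(a,), label="Attach"))
    return VersatileShift(stack_alphabet, input_alphabet,
                          DomainOfDependence(1, 1), tuple(rules))


def compile_generalized_shift(rules: Sequence[VSRule], left_alphabet: Alphabet,
                              right_alphabet: Alphabet,
                              dod: DomainOfDependence) -> VersatileShift:
    """A generalized shift as a VS: every rule must substitute the DoD
    content symbol-for-symbol (equal lengths); length-changing rules are
    rejected."""
    for rule in rules:
        if len(rule.repl_left) != len(rule.match_left) or \
           len(rule.repl_right) != len(rule.match_right):
            raise ValueError("generalized shift rules must preserve lengths")
    return VersatileShift(left_alphabet, right_alphabet, dod, tuple(rules))


# -- machine config (JSON/YAML) ----------------------------------------------

def _token_to_json(tok):
    return str(tok) if isinstance(tok, Var) else tok


def _token_from_json(tok):
    if isinstance(tok, str) and tok.startswith("?"):
        return Var(tok[1:])
    return tok


def machine_to_config(vs: VersatileShift) -> dict:
    return {
        "left_alphabet": list(vs.left_alphabet.symbols),
        "right_alphabet": list(vs.right_alphabet.symbols),
        "blank": vs.left_alphabet.blank,
        "right_blank": vs.right_alphabet.blank,
        "dod": [vs.dod.k_l, vs.dod.k_r],
        "rules": [
            {
                "left": [_token_to_json(t) for t in r.match_left],
                "right": [_token_to_json(t) for t in r.match_right],
                "new_left": [_token_to_json(t) for t in r.repl_left],
                "new_right": [_token_to_json(t) for t in r.repl_right],
                "shift": r.shift,
                "label": r.label,
            }
            for r in vs.rules
        ],
    }


def machine_from_config(cfg: Mapping) -> VersatileShift:
    blank = cfg["blank"]
    right_blank = cfg.get("right_blank", blank)
    left_alphabet = Alphabet(tuple(cfg["left_alphabet"]), blank)
    right_alphabet = Alphabet(tuple(cfg["right_alphabet"]), right_blank)
    k_l, k_r = cfg["dod"]
    rules = tuple(
        VSRule(
            match_left=tuple(_token_from_json(t) for t in r.get("left", [])),
            match_right=tuple(_token_from_json(t) for t in r.get("right", [])),
            repl_left=tuple(_token_from_json(t) for t in r.get("new_left", [])),
            repl_right=tuple(_token_from_json(t) for t in r.get("new_right", [])),
            shift=r.get("shift", 0),
            label=r.get("label", ""),
        )
        for r in cfg["rules"]
    )
    return VersatileShift(left_alphabet, right_alphabet,
                          DomainOfDependence(k_l, k_r), rules)


def save_machine(vs: VersatileShift, path) -> None:
    with open(path, "w") as fh:
        json.dump(machine_to_config(vs), fh, indent=2)


def load_machine(path) -> VersatileShift:
    text = open(path).read()
    try:
        cfg = json.loads(text)
    except json.JSONDecodeError:
        import yaml

        cfg = yaml.safe_load(text)
    return machine_from_config(cfg)
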