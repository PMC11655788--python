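"""Macroscopic observables on the neural-automaton phase space.

A macroscopic observable is a bounded real function of the full network
activation vector.  The package contrasts two families:

* classical mean-field observables — Amari's mean activity, Smolensky's
  harmony, and the dissimilarity between successive states — which
  depend on the arbitrary Gödel encoding of the symbols; and
* the *step observable*: a weighted sum of indicator functions of the
  recoding-invariant rectangle-cell classes given by blank-anchored
  patterns of equality at a chosen resolution (l, r).  One coefficient
  is drawn per class, so the observable separates classes while taking
  the same value on every cell of one class — which is exactly what
  makes it invariant under the group S_{m_left-1} x S_{m_right-1} of
  blank-fixing recodings of the two tape alphabets.

The recoding symmetry acts on phase points by rigidly transporting each
rectangle cell onto the cell whose corner digits are relabelled by the
permutation pair (``rho_pi``), and on observables by pull-back
(``alpha_pi``).  ``verify_invariance`` runs one machine under several
encodings and reports whether an observable's per-step series agree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Mapping, Sequence

import numpy as np

from .patterns import corner_digits, pattern_key, square_partition_classes
from .nda import build_nda
from .network import build_na, run_na
from .shifts import VersatileShift
from .symbolic import DottedWord

__all__ = [
    "amari_mean",
    "harmony",
    "dissimilarity",
    "StepObservable",
    "build_step_observable",
    "evaluate_step",
    "RecodingAction",
    "rho_pi",
    "alpha_pi",
    "InvarianceReport",
    "verify_invariance",
]

#: two float series are "invariant" if they agree within this bound;
#: the symbolic layer is exact, so the slack only absorbs the float
#: execution of the network
INVARIANCE_TOL = 1e-9


def amari_mean(state: Sequence[float]) -> float:
    """Mean network activity (1/n) sum_i x_i — the synthetic-ERP
    observable.  Not invariant under Gödel recoding."""
    x = np.asarray(state, dtype=float)
    if x.size == 0:
        raise ValueError("empty state")
    return float(x.mean())


def harmony(state: Sequence[float], W: np.ndarray) -> float:
    """Smolensky's harmony x^T W x for a weight matrix W."""
    x = np.asarray(state, dtype=float)
    W = np.asarray(W, dtype=float)
    if W.shape != (x.size, x.size):
        raise ValueError(f"weight matrix shape {W.shape} does not match "
                         f"state of size {x.size}")
    return float(x @ W @ x)


def dissimilarity(x_t: Sequence[float], x_prev: Sequence[float]) -> float:
    """1 - cosine similarity between a state and its precursor."""
    a = np.asarray(x_t, dtype=float)
    b = np.asarray(x_prev, dtype=float)
    na_, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na_ == 0 or nb == 0:
        raise ValueError("dissimilarity undefined for zero-norm states")
    return float(1.0 - (a @ b) / (na_ * nb))


@dataclass(frozen=True)
class StepObservable:
    """Step function over the invariant cell classes of one resolution.

    ``class_map`` sends each (blank-anchored, per-axis by default)
    pattern key to a class index; ``coefficients[k]`` is the value taken
    on class k.  Only the two MCL coordinates of a state matter: the
    cell classes extend cylindrically over the remaining units.
    """

    m_left: int
    m_right: int
    l: int
    r: int
    mode: str
    class_map: Mapping = field(hash=False)
    coefficients: tuple
    seed: int

    @property
    def n_classes(self) -> int:
        return len(self.coefficients)

    def __call__(self, state) -> float:
        return evaluate_step(self, state)


def build_step_observable(m_left: int, m_right: int, l: int, r: int,
                          seed: int = 0, mode: str = "per_axis"
                          ) -> StepObservable:
    """Partition the square at resolution (l, r) into blank-anchored
    pattern classes and draw one distinct random coefficient per class
    from the seeded generator."""
    classes = square_partition_classes(m_left, m_right, l, r,
                                       mode=mode, anchored=True)
    keys = sorted(classes.keys(), key=repr)
    class_map = {key: k for k, key in enumerate(keys)}
    rng = np.random.default_rng(seed)
    coeffs = rng.uniform(0.0, 1.0, size=len(keys))
    while len(set(coeffs.tolist())) < len(keys):  # pragma: no cover
        coeffs = rng.uniform(0.0, 1.0, size=len(keys))
    return StepObservable(m_left, m_right, l, r, mode, class_map,
                          tuple(coeffs.tolist()), seed)


def _cell_index(y, m: int, l: int, tol: float = 1e-7) -> int:
    """Index of the depth-l interval containing y, snapping float values
    that sit within ``tol`` (on the scaled axis) below a grid corner."""
    if isinstance(y, Fraction):
        return min(int(y * m**l), m**l - 1)
    scaled = float(y) * m**l
    idx = int(math.floor(scaled))
    if math.ceil(scaled) - scaled < tol:
        idx = int(round(scaled))
    return min(max(idx, 0), m**l - 1)


def evaluate_step(obs: StepObservable, state) -> float:
    """Value of the step observable at a network state or phase point.

    ``state`` may be a full activation vector (the first two entries are
    the MCL), a bare phase point (pair of floats or Fractions), or a
    :class:`~neural_automata.nda.PhasePoint`.
    """
    y1, y2 = state[0], state[1]
    i = _cell_index(y1, obs.m_left, obs.l)
    j = _cell_index(y2, obs.m_right, obs.r)
    key = pattern_key(corner_digits(i, obs.m_left, obs.l),
                      corner_digits(j, obs.m_right, obs.r),
                      mode=obs.mode, anchored=True)
    return obs.coefficients[obs.class_map[key]]


@dataclass(frozen=True)
class RecodingAction:
    """A pair of code permutations (each fixing 0) acting on the two
    axes of a resolution-(l, r) rectangle partition."""

    pi1: tuple  # pi1[c] = image of code c, pi1[0] == 0
    pi2: tuple
    m_left: int
    m_right: int
    l: int
    r: int

    def __post_init__(self) -> None:
        for pi, m in ((tuple(self.pi1), self.m_left),
                      (tuple(self.pi2), self.m_right)):
            if sorted(pi) != list(range(m)) or pi[0] != 0:
                raise ValueError("permutations must be bijections of "
                                 "0..m-1 fixing 0")
        object.__setattr__(self, "pi1", tuple(self.pi1))
        object.__setattr__(self, "pi2", tuple(self.pi2))

    def inverse(self) -> "RecodingAction":
        inv1 = tuple(np.argsort(self.pi1).tolist())
        inv2 = tuple(np.argsort(self.pi2).tolist())
        return RecodingAction(inv1, inv2, self.m_left, self.m_right,
                              self.l, self.r)

    def compose(self, other: "RecodingAction") -> "RecodingAction":
        """self o other (apply ``other`` first)."""
        pi1 = tuple(self.pi1[c] for c in other.pi1)
        pi2 = tuple(self.pi2[c] for c in other.pi2)
        return RecodingAction(pi1, pi2, self.m_left, self.m_right,
                              self.l, self.r)


def rho_pi(point, action: RecodingAction):
    """Rigidly transport a phase point to the cell whose corner digits
    are relabelled by the permutation pair; the offset within the cell
    is preserved."""
    y1, y2 = Fraction(point[0]), Fraction(point[1])
    dx = action.m_left**action.l
    dy = action.m_right**action.r
    i = min(int(y1 * dx), dx - 1)
    j = min(int(y2 * dy), dy - 1)
    di = corner_digits(i, action.m_left, action.l)
    dj = corner_digits(j, action.m_right, action.r)
    i2 = 0
    for d in di:
        i2 = i2 * action.m_left + action.pi1[d]
    j2 = 0
    for d in dj:
        j2 = j2 * action.m_right + action.pi2[d]
    return (y1 + Fraction(i2 - i, dx), y2 + Fraction(j2 - j, dy))


def alpha_pi(observable: Callable, action: RecodingAction) -> Callable:
    """Pull-back of an observable along the recoding action:
    alpha_pi(f)(x) = f(rho_pi(x)).  The two MCL coordinates are
    transported; the remaining units are untouched."""

    def pulled(state):
        y = rho_pi((state[0], state[1]), action)
        if len(state) > 2:
            return observable([float(y[0]), float(y[1]), *state[2:]])
        return observable(y)

    return pulled


@dataclass(frozen=True)
class InvarianceReport:
    observable: str
    encodings: tuple
    series: tuple          # one value sequence per encoding
    max_diff_per_step: tuple
    max_diff: float
    invariant: bool
    threshold: float


def _series_for(name_or_obs, states: list, na) -> list:
    if isinstance(name_or_obs, StepObservable):
        return [evaluate_step(name_or_obs, x) for x in states]
    if callable(name_or_obs):
        return [name_or_obs(x) for x in states]
    if name_or_obs == "amari":
        return [amari_mean(x) for x in states]
    if name_or_obs == "harmony":
        return [harmony(x, na.weight_matrix) for x in states]
    if name_or_obs == "dissimilarity":
        return [float("nan")] + [dissimilarity(b, a) for a, b
                                 in zip(states, states[1:])]
    raise ValueError(f"unknown observable {name_or_obs!r}")


def verify_invariance(observable, vs: VersatileShift, s0: DottedWord,
                      encoding_pairs: Sequence[tuple], steps: int = 100,
                      threshold: float = INVARIANCE_TOL,
                      label: str | None = None) -> InvarianceReport:
    """Run the neural automaton under each encoding pair and compare the
    observable's per-step series.

    ``encoding_pairs`` is a sequence of (left_encoding, right_encoding),
    all blank-anchored.  The verdict is invariant iff the maximum
    absolute pairwise difference at every step stays below ``threshold``.
    """
    all_series = []
    names = []
    for enc_l, enc_r in encoding_pairs:
        nda = build_nda(vs, enc_l, enc_r)
        na = build_na(nda)
        states = run_na(na, s0, steps)
        all_series.append(_series_for(observable, states, na))
        names.append(f"{enc_l.assignment}/{enc_r.assignment}")
    lengths = {len(s) for s in all_series}
    if len(lengths) != 1:
        raise RuntimeError("runs under different encodings halted at "
                           "different times")
    per_step = []
    for t in range(lengths.pop()):
        vals = [s[t] for s in all_series]
        finite = [v for v in vals if not math.isnan(v)]
        per_step.append(max(finite) - min(finite) if finite else 0.0)
    max_diff = max(per_step) if per_step else 0.0
    if label is None:
        label = observable if isinstance(observable, str) else \
            type(observable).__name__
    return InvarianceReport(
        observable=str(label), encodings=tuple(names),
        series=tuple(tuple(s) for s in all_series),
        max_diff_per_step=tuple(per_step), max_diff=max_diff,
        invariant=max_diff <= threshold, threshold=threshold)
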