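"""Neural automata: modular recurrent networks realizing an NDA.

The network carries three kinds of units on one activation vector
``x in [0,1]^n``:

* **MCL** (machine configuration layer) — two saturated-linear units
  holding the NDA phase point ``(y1, y2)``.
* **BSL** (branch selection layer) — per branch group, two threshold
  units detecting the lower cell edges on each axis and one gate unit
  conjoining the four edge tests (the upper tests are read from the
  neighbouring groups' edge units).
* **LTL** (linear transformation layer) — per branch group, two
  saturated-linear units computing the gated affine image of the MCL.

One *branch group* of 5 units (2 edge + 1 gate + 2 affine) is allocated
for every cell of the DoD partition except the all-blank accepting
corner, whether or not the cell carries a rewrite rule: branch-selection
hardware covers the whole partition, while groups of rule-less cells
have zero transformation weights and halt the run when their gate fires.
The unit count is therefore the deterministic function

    n = 2 + 5 * (m_left**k_l * m_right**k_r - 1)

of the partition size — 72 for the grammar demo (15 cells, 14 groups).

A macro step is a fixed four-phase micro schedule (edge tests, gate,
gated affine, MCL write-back); at most one gate is active per macro
step, so the MCL exactly reproduces the NDA map (up to float rounding;
thresholds carry a 1e-9 guard band so that grid corners computed in
floating point fall into the correct half-open cell).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np

from .nda import NDA, AffineBranch, encode_state
from .symbolic import DottedWord

__all__ = [
    "BranchGroup",
    "NeuralAutomaton",
    "build_na",
    "na_macro_step",
    "run_na",
    "read_mcl",
    "HaltSignal",
]

#: guard band subtracted from threshold biases.  It must sit strictly
#: between the float drift of the MCL (~1e-14 over the runs supported
#: here) and the smallest gap between a reachable exact phase point and
#: a cell corner (>= m**-(l0+T) for initial tape length l0 and T macro
#: steps; >= 3**-24 ~ 3.5e-12 for the run lengths this package uses).
EDGE_EPS = 5e-13


class HaltSignal(Exception):
    """Raised when the MCL leaves the region of defined branches."""


@dataclass(frozen=True)
class BranchGroup:
    """Unit bookkeeping for one partition cell (i, j)."""

    cell: tuple
    base: int  # index of the first of the 5 units
    x_lo: Fraction
    y_lo: Fraction
    branch: AffineBranch | None  # None: structural group of a halting cell

    @property
    def idx_edge_x(self) -> int:
        return self.base

    @property
    def idx_edge_y(self) -> int:
        return self.base + 1

    @property
    def idx_gate(self) -> int:
        return self.base + 2

    @property
    def idx_t1(self) -> int:
        return self.base + 3

    @property
    def idx_t2(self) -> int:
        return self.base + 4


@dataclass(frozen=True)
class NeuralAutomaton:
    nda: NDA
    groups: tuple
    n: int
    weight_matrix: np.ndarray = field(hash=False, compare=False)
    bias: np.ndarray = field(hash=False, compare=False)
    activation: tuple = ()  # per unit: "sat" | "threshold"
    micro_steps_per_macro: int = 4

    @property
    def group_by_cell(self) -> dict:
        return {g.cell: g for g in self.groups}

    def layer_sizes(self) -> dict:
        return {"MCL": 2, "BSL": 3 * len(self.groups),
                "LTL": 2 * len(self.groups)}


def _sat(z: np.ndarray) -> np.ndarray:
    return np.clip(z, 0.0, 1.0)


def build_na(nda: NDA) -> NeuralAutomaton:
    """Compile an NDA into a neural automaton.

    Reproducible: the same NDA yields the same unit layout and weights.
    """
    dx = nda.m_left**nda.k_l
    dy = nda.m_right**nda.k_r
    cells = [(i, j) for i in range(dx) for j in range(dy) if (i, j) != (0, 0)]
    groups = []
    for g_idx, (i, j) in enumerate(cells):
        groups.append(BranchGroup(
            cell=(i, j),
            base=2 + 5 * g_idx,
            x_lo=Fraction(i, dx),
            y_lo=Fraction(j, dy),
            branch=nda.cells.get((i, j)),
        ))
    n = 2 + 5 * len(groups)
    by_cell = {g.cell: g for g in groups}

    W = np.zeros((n, n))
    b = np.zeros(n)
    activation = ["sat", "sat"] + ["threshold", "threshold", "threshold",
                                   "sat", "sat"] * len(groups)
    for g in groups:
        i, j = g.cell
        # edge units: theta(y - (corner - eps))
        W[g.idx_edge_x, 0] = 1.0
        b[g.idx_edge_x] = -(float(g.x_lo) - EDGE_EPS)
        W[g.idx_edge_y, 1] = 1.0
        b[g.idx_edge_y] = -(float(g.y_lo) - EDGE_EPS)
        # gate: lower tests minus the neighbours' (upper) tests >= threshold
        need = 0
        W[g.idx_gate, g.idx_edge_x] = 1.0
        W[g.idx_gate, g.idx_edge_y] = 1.0
        need += 2
        up_x = by_cell.get((i + 1, j))
        if i + 1 < dx:
            W[g.idx_gate, up_x.idx_edge_x] = -1.0
        up_y = by_cell.get((i, j + 1))
        if j + 1 < dy:
            W[g.idx_gate, up_y.idx_edge_y] = -1.0
        b[g.idx_gate] = -need + 0.5  # fires iff sum >= need
        # gated affine units
        if g.branch is not None:
            lam1, lam2 = float(g.branch.lambda1), float(g.branch.lambda2)
            a1, a2 = float(g.branch.a1), float(g.branch.a2)
            M1 = lam1 + max(a1, 0.0) + 1.0
            M2 = lam2 + max(a2, 0.0) + 1.0
            W[g.idx_t1, 0] = lam1
            W[g.idx_t1, g.idx_gate] = M1
            b[g.idx_t1] = a1 - M1
            W[g.idx_t2, 1] = lam2
            W[g.idx_t2, g.idx_gate] = M2
            b[g.idx_t2] = a2 - M2
        # write-back
        W[0, g.idx_t1] = 1.0
        W[1, g.idx_t2] = 1.0
    return NeuralAutomaton(nda=nda, groups=tuple(groups), n=n,
                           weight_matrix=W, bias=b,
                           activation=tuple(activation))


def na_macro_step(na: NeuralAutomaton, state: np.ndarray) -> np.ndarray:
    """One macro step (four micro phases) of the network.

    Raises :class:`HaltSignal` when no gate fires (the MCL sits in the
    accepting corner) or the firing gate belongs to a rule-less cell.
    """
    W, b = na.weight_matrix, na.bias
    x = np.array(state, dtype=float)
    y = x[:2]
    # phase 1: edge threshold units read the MCL
    for g in na.groups:
        x[g.idx_edge_x] = 1.0 if W[g.idx_edge_x, 0] * y[0] + b[g.idx_edge_x] >= 0 else 0.0
        x[g.idx_edge_y] = 1.0 if W[g.idx_edge_y, 1] * y[1] + b[g.idx_edge_y] >= 0 else 0.0
    # phase 2: gates conjoin the edge tests
    active = None
    for g in na.groups:
        z = W[g.idx_gate] @ x + b[g.idx_gate]
        x[g.idx_gate] = 1.0 if z >= 0 else 0.0
        if x[g.idx_gate] > 0:
            if active is not None:
                raise RuntimeError("more than one branch gate active")
            active = g
    if active is None or active.branch is None:
        raise HaltSignal(f"MCL {tuple(y)} is in a halting cell")
    # phase 3: gated affine units (x[:2] still holds the old MCL)
    for g in na.groups:
        x[g.idx_t1] = _sat(W[g.idx_t1] @ x + b[g.idx_t1])
        x[g.idx_t2] = _sat(W[g.idx_t2] @ x + b[g.idx_t2])
    # phase 4: MCL write-back
    x[0] = _sat(W[0] @ x + b[0])
    x[1] = _sat(W[1] @ x + b[1])
    return x


def run_na(na: NeuralAutomaton, s0: DottedWord, steps: int) -> list:
    """Run the network from a symbolic initial state.

    The MCL is initialized from the Gödel encoding of ``s0``; all other
    units start at 0.  Returns the full activation vector at every macro
    step (including t = 0), truncated at the first halt.
    """
    y0 = encode_state(s0, na.nda.left_encoding, na.nda.right_encoding)
    x = np.zeros(na.n)
    x[0], x[1] = float(y0[0]), float(y0[1])
    states = [x]
    for _ in range(steps):
        try:
            x = na_macro_step(na, states[-1])
        except HaltSignal:
            break
        states.append(x)
    return states


def na_to_json(na: NeuralAutomaton) -> dict:
    """Serializable dump: layer sizes, float weights/biases, activation
    kinds, and the exact rational branch parameters per group."""
    def frac(x: Fraction) -> str:
        return f"{x.numerator}/{x.denominator}"

    groups = []
    for g in na.groups:
        entry = {"cell": list(g.cell), "base": g.base,
                 "x_lo": frac(g.x_lo), "y_lo": frac(g.y_lo),
                 "halting": g.branch is None}
        if g.branch is not None:
            entry["branch"] = {"a1": frac(g.branch.a1), "a2": frac(g.branch.a2),
                               "lambda1": frac(g.branch.lambda1),
                               "lambda2": frac(g.branch.lambda2)}
        groups.append(entry)
    return {"n": na.n, "layer_sizes": na.layer_sizes(),
            "micro_steps_per_macro": na.micro_steps_per_macro,
            "activation": list(na.activation),
            "weights": na.weight_matrix.tolist(),
            "bias": na.bias.tolist(),
            "groups": groups}


def read_mcl(state: Sequence[float], m_left: int, m_right: int,
             max_depth: int = 12, tol: float = 1e-9) -> tuple:
    """Snap the two MCL activations back to exact Gödel rationals.

    Each coordinate is matched to the nearest fraction with denominator
    ``m**max_depth``; a coordinate further than ``tol`` from every grid
    point raises a :class:`ValueError`.
    """
    out = []
    for y, m in ((state[0], m_left), (state[1], m_right)):
        d = m**max_depth
        num = round(float(y) * d)
        if abs(float(y) - num / d) > tol:
            raise ValueError(f"activation {y} is not within {tol} of the "
                             f"base-{m} depth-{max_depth} grid")
        out.append(Fraction(num, d))
    return tuple(out)
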