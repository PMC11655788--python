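# neural-automata

Symbolic computation embedded in neural phase space — and the question of
which measurements on such a system actually mean anything.

In computational cognitive neurodynamics, symbol processing (e.g. the
parser states of a sentence-processing model) is often mapped into the
activation space of a recurrent neural network through a **Gödel
encoding**: pick a bijection γ from the alphabet **A** (m symbols,
including a distinguished blank ⊔ with γ(⊔)=0) onto {0,…,m−1} and send a
word w = a₁a₂…a_l to

    ψ_γ(w) = Σ_k γ(a_k) · m^(−k)  ∈ [0, 1).

A two-sided tape (a *dotted sequence*, stack side · input side) becomes a
point (y₁, y₂) in the unit square; a tape-rewriting machine — a
**versatile shift** with a finite domain of dependence — becomes a
**nonlinear dynamical automaton** (NDA), a piecewise affine map with one
diagonal branch per DoD cell; and the NDA compiles into a **neural
automaton** (NA), a modular recurrent network of threshold and
saturated-linear units whose two machine-configuration units carry the
phase point.

The encoding γ is arbitrary. The package therefore implements the
symmetry analysis of what survives a *recoding* π∘γ: the complete
invariant is the **pattern of equality** P_w — the set partition of
positions of w induced by symbol identity — and the recoding-invariant
macroscopic observables are exactly the step functions

    f(x) = Σ_k c_k · χ_k(x)

over the classes of rectangle cells sharing (blank-anchored) patterns of
equality of their corner digits. Mean-field observables such as Amari's
mean activity A(t) = (1/n)Σᵢ xᵢ(t), a common "synthetic ERP", are *not*
invariant: two simulations of the same machine under different encodings
produce different Amari traces but identical step-observable traces.
That distinction matters whenever simulated activations are regressed
against real measurements (ERPs, reading times): a correlation that
changes under recoding is an artifact of the encoding, not a property of
the computation.

## What's in the box

| module | contents |
| --- | --- |
| `neural_automata.symbolic` | alphabets, encodings, dotted words, exact Gödel encode/decode, cylinder intervals, boundary ultrametric, recodings |
| `neural_automata.patterns` | patterns of equality, orbit enumeration, invariant partitions of the interval and the unit square |
| `neural_automata.shifts` | versatile shifts / generalized shifts, rule matching, traces, CFG → top-down recognizer |
| `neural_automata.nda` | compilation of a shift machine + encoding pair into a piecewise affine NDA (exact rationals) |
| `neural_automata.network` | NDA → recurrent network (MCL/BSL/LTL), macro-step execution, MCL readout |
| `neural_automata.observables` | Amari mean, harmony, dissimilarity, step observables, the recoding group action ρ_π/α_π, invariance reports |
| `neural_automata.demo`, `.fixtures`, `.cli` | the grammar demo, seeded random generators, `neural-automata` command line |

Everything symbolic is exact (`fractions.Fraction` with denominators
mᵏ); floating point appears only inside the network execution.

## Worked example

The toy grammar S → NP VP, VP → V NP (NP, V treated as terminals)
compiles into a recognizer with stack alphabet {⊔, NP, V, VP, S} and
input alphabet {⊔, NP, V}:

```python
from neural_automata import *
from neural_automata.demo import demo_machine, demo_encodings, demo_initial_state

vs = demo_machine()
trace = run(vs, demo_initial_state(), 100)
for t, s, op in trace.steps:
    print(t, s.display(), op)
```

```
0 S.NP V NP      Predict (S -> NP VP)
1 VP NP.NP V NP  Attach
2 VP.V NP        Predict (VP -> V NP)
3 NP V.V NP      Attach
4 NP.NP          Attach
5 .              Accept
```

The sentence "NP V NP" is accepted at time 5. Under the encoding pair
γ (stack: ⊔0 NP1 V2 VP3 S4; input: ⊔0 NP1 V2) the initial state encodes
to (4/5, 16/27), and the compiled network has **72 units** (2 MCL + 14
branch groups of 5):

```python
gamma, delta = demo_encodings()["gamma"], demo_encodings()["delta"]
na = build_na(build_nda(vs, *gamma))
print(na.n)                      # 72

obs = build_step_observable(5, 3, 2, 3, seed=17)   # resolution (l,r)=(2,3)
s0 = demo_initial_state()
print(verify_invariance(obs, vs, s0, [gamma, delta], 20).max_diff)      # 0.0
print(verify_invariance("amari", vs, s0, [gamma, delta], 20).invariant) # False
```

The step-observable series is bit-identical under both encodings
(max difference 0.0 across all 6 iterations), while the Amari series
differ — e.g. 0.208 (γ) vs 0.403 (δ) at the final iteration, a gap of
0.19.
The whole demo, with TSV/JSON artifacts, is one command:

```
neural-automata demo-cfg --encoding both --out demo_out --seed 17
```

Other subcommands: `orbit`, `partition`, `parse`, `simulate`,
`invariance`, `fixtures` (see `neural-automata --help`). Rationals in
all tabular outputs are printed as `num/den`.

### Config schemas

Machine config (JSON; YAML accepted and normalized):

```json
{"left_alphabet": ["_", "NP", "V", "VP", "S"],
 "right_alphabet": ["_", "NP", "V"],
 "blank": "_",
 "dod": [1, 1],
 "rules": [{"left": ["S"], "right": [], "new_left": ["NP", "VP"],
            "new_right": [], "shift": 0, "label": "Predict (S -> NP VP)"},
           {"left": ["?a"], "right": ["?a"], "new_left": [],
            "new_right": [], "shift": 0, "label": "Attach"}]}
```

Wildcards are spelled `?name` and bind one non-blank symbol. An
encoding-pair config maps each symbol to its code on both sides; the
blank must get code 0:

```json
{"left": {"_": 0, "NP": 1, "V": 2, "VP": 3, "S": 4},
 "right": {"_": 0, "NP": 1, "V": 2}}
```

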