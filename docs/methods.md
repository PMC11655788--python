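# Methods

This note records the model, the numerical choices, and the design
decisions behind `neural_automata`, in the order the computation flows:
symbols → unit interval → unit square → network → observables.

## Gödel encodings and exact arithmetic

A word w = a₁…a_l over an m-symbol alphabet encodes as
ψ_γ(w) = Σ γ(a_k)·m^(−k). Only finite words with implicit blank padding
are encoded; since the blank is anchored to code 0 wherever dynamics are
involved, padding never changes a value and no encoded number has two
base-m expansions (no tail of (m−1)s ever arises). All encodings,
interval endpoints, partition corners and NDA coefficients are
`fractions.Fraction` values with denominators mᵏ. This is not a luxury:
cell membership is decided against *half-open* intervals
[k/mⁿ, (k+1)/mⁿ), and a state frequently sits exactly on a corner, where
any float comparison would be a coin flip. Floating point enters the
package exactly once, in the network execution layer (below).

Decoding ψ⁻¹ requires a target length l and demands x·mˡ ∈ ℤ; anything
else is a precision error, not a nearest-guess.

**Boundary metric.** On blank-padded rays we use the ultrametric
d(p,q) = 0 if p = q, 1 if the first symbols differ, m^(−n) if exactly an
n-prefix is shared. With this orientation d is a genuine ultrametric and
satisfies the interval equivalence d(p,q) ≤ m^(−n) ⇔ ψ(p), ψ(q) lie in
one depth-n interval, for every encoding — both are property-tested.

## Patterns of equality and orbits

The pattern of equality P_w (positions partitioned by symbol identity)
is the complete invariant for the action of alphabet bijections: the
orbit of w consists exactly of the words of the same length with the
same pattern, and has m!/(m−k)! members for k distinct symbols. In
blank-anchored mode the group shrinks to blank-fixing bijections, the
pattern additionally records the (possibly empty) set of blank
positions, and the count becomes (m−1)!/(m−1−k′)! over the k′ distinct
non-blank symbols. `enumerate_orbit` generates orbits directly from
symbol injections rather than filtering all mˡ words; the brute-force
filter is kept in the tests as the oracle.

Partitions of the square are parameterized by independent alphabet
sizes per axis (the application uses 5 for the stack and 3 for the
input). Two class notions are implemented:

* **per-axis** (default): the key is the *pair* of 1-D anchored
  patterns; the group is the product S_{m₁−1} × S_{m₂−1} acting
  independently per side. This is the mode the invariance theorem and
  the application use, and the only choice available when the two
  alphabets differ in size.
* **joint**: one pattern over the concatenated corner digit words; a
  single shared permutation relabels both axes (requires equal sizes).
  This mode reproduces the worked six-rectangle class of the cell
  [6/9,7/9)×[10/27,11/27) at m=3, (l,r)=(2,3).

Axis convention, fixed once and used everywhere: **axis 1 = left/stack
word (length l, base m_left), axis 2 = right/input word (length r, base
m_right)**, with zero-based cell indices.

## Versatile shifts

A machine is (left alphabet, right alphabet, DoD (k_l, k_r), ordered
rule list). Matching is first-match over the blank-padded DoD windows;
a rule's pattern may be shorter than the window, in which case only the
matched dotted prefix is rewritten and the rest of the tape is carried
along. Wildcards (`?a`) bind a single non-blank symbol, consistently
across both sides of one rule — the attach rule `?a . ?a ↦ ε . ε` is the
motivating case. The all-blank window matches no rule by definition, so
the empty dotted sequence ε.ε is the unique accepting halt; any other
ruleless configuration is a rejecting halt. Dot shifts (F) move symbols
across the dot with blank materialization; the grammar machines use
F = 0 throughout.

CFG compilation: each production X → Y₁…Y_p becomes a predict rule
rewriting stack-top X to Y₁…Y_p with Y₁ adjacent to the dot
(stack stored dot-outward = reversed tape order) and an *empty* input
pattern — the rule fires whatever the input window holds, including
blank, and leaves it untouched. ε-productions and left recursion are
legal syntax; termination is then the step budget's problem, by design.

## NDA compilation

The branch on the cell with stack window u and replacement v (after
wildcard binding) is forced by the conjugacy contract
encode∘step = branch∘encode:

    λ₁ = m_left^(p − |v|),   a₁ = ψ(v) − λ₁·ψ(u[:p]),

(p the matched prefix length; axis 2 analogous). The derivation is one
line: within a cell the window digits are fixed, and the affine map
transports the tape tail ψ-weight from depth p to depth |v|. This is
also why a *diagonal* affine form suffices only for F = 0: a dot shift
moves weight between the two coordinates, so `build_nda` rejects
shifting rules. Wildcard rules are expanded into one branch per concrete
window content at build time. Cells with no matching rule carry no
branch and constitute the halting region; halting times of the symbolic
machine and the NDA agree exactly (tested, including on random
machines).

## Network construction

One branch group of five units serves each partition cell except the
accepting corner (0,0):

* two **edge units** (Heaviside) testing y₁ ≥ i/m^l and y₂ ≥ j/m^r —
  each group tests its own lower edges; the upper-edge tests are read
  from the neighbouring groups' edge units, which is what makes the
  five-unit budget close;
* one **gate unit** (Heaviside) conjoining the four edge tests;
* two **affine units** (saturated-linear) computing
  sat(λ·y + a + M·g − M), where the gate g and a constant
  M ≥ λ + max(a, 0) guarantee exact zero when the gate is closed.

A macro step is the fixed micro schedule edges → gate → affine → MCL
write-back (4 micro steps); the MCL units are saturated-linear and sum
the affine units, of which at most one group is nonzero. Unit count:
n = 2 + 5·(m_left^{k_l}·m_right^{k_r} − 1); the grammar demo has 15
cells, hence 72 units. Groups exist for *every* non-accept cell —
branch-selection hardware covers the whole partition — but groups of
rule-less cells have zero transformation weights; when such a gate
fires, or no gate fires at all, the run halts. Weights are stored as
exact rationals and executed in float64; both are serialized.

**Float guard band.** Threshold biases are shifted down by
EDGE_EPS = 5·10⁻¹³, so cell membership in the network is effectively
[corner − ε, next corner − ε). The constant must sit strictly between
two scales: (i) the float drift of the MCL, which is bounded by the
rounding per step times the total contraction/expansion factor
m^(l₀ − l_t) of the tape length and stays below ~10⁻¹³ for the run
lengths used here (measured ≲ 10⁻¹⁴ on the demo); and (ii) the smallest
gap between a *reachable exact* phase point and a cell corner, which is
at least m^−(l₀+T) for initial tape length l₀ and T macro steps
(≥ 3⁻²⁴ ≈ 3.5·10⁻¹² under the fixture conditions below). Runs much
longer than ~25 steps on machines that grow a constant-digit tape can
exhaust window (ii); the exact NDA has no such limit, and `read_mcl`
snaps MCL activations back onto the rational grid (tolerance 10⁻⁹,
depth 12 by default) for observable evaluation.

## Observables and the recoding action

Amari mean, harmony (x·W·x against the network's full weight matrix)
and dissimilarity (1 − cosine to the precursor state) are plain
mean-field functionals of the full 72-dimensional activation vector.

The step observable at resolution (l, r) assigns one coefficient per
per-axis blank-anchored pattern class; coefficients are drawn uniformly
from a seeded generator (default seed exposed as a flag) and are
pairwise distinct with probability 1 — distinctness is asserted, so the
observable *separates* classes as well as being constant on them. Only
the two MCL coordinates enter: the classes extend cylindrically over
the remaining units, which is precisely why the observable transfers
from the NDA square to the full network state.

The recoding action ρ_π rigidly translates each cell onto the cell with
π-relabelled corner digits, preserving the in-cell offset; α_π pulls
observables back along it and is a group homomorphism (tested
exhaustively for the size-(3,3) group). Invariance of the step
observable under the full blank-fixing product group is tested exactly,
in rationals, at sizes (3,3), (3,5), (5,3) on 10³ random points each.
The theorem is stated per-axis; its use with two different alphabet
sizes is the evident generalization to S_{m₁−1} × S_{m₂−1}.

`verify_invariance` compares per-step series across encoding runs with
threshold 10⁻⁹: true invariants are exactly 0 through the rational
layer, and the threshold only absorbs the float execution of the
network. The demo's non-invariance witness (Amari) exceeds 10⁻⁶ by five
orders of magnitude, so the verdicts are not tolerance-sensitive.

## Fixture conditions (what the random suites cover, and what not)

The seeded generators produce: words over 2–5 symbol alphabets;
blank-fixing recodings; and small shift-free machines — 2–3 symbols per
side including the blank, DoD (1,1), 1–4 rules with distinct match
patterns (so first-match order is immaterial), replacement lengths 0–2
over non-blank symbols, initial tapes of length ≤ 4 per side, runs of
≤ 20 steps. Within these conditions the conjugacy suite checks the
machine↔NDA correspondence *exactly* and the NDA↔network correspondence
to 10⁻⁹ on a fleet of 50 machines. These are desk-scale automata: the
suites say nothing about large alphabets (orbit enumeration is
factorial in m), rules with long matched prefixes, F ≠ 0 dynamics
(excluded from NDA compilation by design), or float behaviour over
hundreds of steps.

Problem sizes used in the exhaustive suites (the package's choice of
desk scale): orbit-formula and image-oracle checks up to m = 4, l = 6
(strided sampling above ~300 words per length); ultrametric axioms on
all triples of digit words up to length 3 plus seeded pairs at length
10; partition conservation up to m = 4, l = 5.

## Known limitations

* The network executes in float64; bit-exactness claims live in the
  rational NDA layer, and the guard-band analysis above bounds the
  float layer instead.
* Joint-mode classes require equal alphabet sizes; there is no notion
  of a shared permutation between alphabets of different cardinality.
* No Turing-machine front end and no F ≠ 0 Gödelization; generalized
  shifts are supported symbolically as equal-length versatile shifts.
* Plotting helpers are deliberately thin wrappers over the written TSV
  files; all numeric artifacts are plot-library-independent.
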