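"""End-to-end syntactic-processing demo.

A toy context-free grammar (S -> NP VP, VP -> V NP, with the lexical
categories NP and V treated as terminals) is compiled into a top-down
recognizer versatile shift, Gödelized into an NDA under two different
blank-anchored encoding pairs (gamma and delta), realized as a 72-unit
neural automaton, and run on the pre-tokenized sentence "NP V NP".
The step observable built on blank-anchored patterns of equality at
resolution (l, r) = (2, 3) produces identical series under both
encodings, while Amari's mean activity does not.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .nda import build_nda, encode_state, run_nda, save_nda
from .network import build_na, run_na
from .observables import (amari_mean, build_step_observable, evaluate_step,
                          verify_invariance)
from .shifts import DottedWord, VersatileShift, build_topdown_recognizer, run, save_machine
from .symbolic import Encoding

__all__ = [
    "BLANK",
    "GRAMMAR",
    "TERMINALS",
    "NONTERMINALS",
    "SENTENCE",
    "demo_machine",
    "demo_encodings",
    "demo_initial_state",
    "run_demo",
]

BLANK = "_"
GRAMMAR = (("S", ("NP", "VP")), ("VP", ("V", "NP")))
TERMINALS = ("NP", "V")
NONTERMINALS = ("VP", "S")
SENTENCE = ("NP", "V", "NP")
RESOLUTION = (2, 3)  # (l, r) of the demo step observable


def demo_machine() -> VersatileShift:
    """The top-down recognizer for the demo grammar: stack alphabet
    {_, NP, V, VP, S}, input alphabet {_, NP, V}, DoD (1, 1)."""
    return build_topdown_recognizer(GRAMMAR, TERMINALS, NONTERMINALS, BLANK)


def demo_encodings() -> dict:
    """The two printed encoding pairs, as (stack, input) tuples."""
    vs = demo_machine()
    stack_a, input_a = vs.left_alphabet, vs.right_alphabet
    gamma = (Encoding.from_order(stack_a, (BLANK, "NP", "V", "VP", "S"), True),
             Encoding.from_order(input_a, (BLANK, "NP", "V"), True))
    delta = (Encoding.from_order(stack_a, (BLANK, "VP", "S", "V", "NP"), True),
             Encoding.from_order(input_a, (BLANK, "V", "NP"), True))
    return {"gamma": gamma, "delta": delta}


def demo_initial_state() -> DottedWord:
    """Start symbol on the stack, the sentence on the input side."""
    return DottedWord(("S",), SENTENCE)


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def plot_series(out_dir, encodings=("gamma", "delta")) -> list:
    """Render the already-written observable TSVs as PNG figures.

    Purely cosmetic and optional: reads only the TSV artifacts, so the
    numeric outputs stay plot-library-independent.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    written = []
    for stem, column in (("step_series", "step_observable"),
                         ("amari_series", "amari_mean")):
        fig, axes = plt.subplots(len(encodings), 1, sharex=True,
                                 figsize=(6, 2.2 * len(encodings)))
        for ax, name in zip(np.atleast_1d(axes), encodings):
            frame = pd.read_csv(out / f"{stem}_{name}.tsv", sep="\t")
            ax.step(frame["t"], frame[column], where="post", marker="o")
            ax.set_ylabel(name)
        fig.suptitle(column)
        fig.supxlabel("iteration")
        path = out / f"{stem}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written


def run_demo(encoding_choice: str = "both", out_dir="demo_out",
             seed: int = 17, max_steps: int = 20) -> dict:
    """Run the full demo and write its artifacts.

    Writes the symbolic trace, and per chosen encoding the NDA and NA
    trajectories plus the step-observable and Amari series; with
    ``both`` also an invariance report.  Returns the paths written.
    Outputs are deterministic given the flags and the seed.
    """
    if encoding_choice not in ("gamma", "delta", "both"):
        raise ValueError("encoding_choice must be gamma, delta or both")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vs = demo_machine()
    s0 = demo_initial_state()
    encs = demo_encodings()
    chosen = ["gamma", "delta"] if encoding_choice == "both" else [encoding_choice]
    l, r = RESOLUTION
    written = {}

    save_machine(vs, out / "machine.json")
    written["machine"] = out / "machine.json"

    trace = run(vs, s0, max_steps)
    _write_tsv(pd.DataFrame(
        [(t, s.display(), op) for t, s, op in trace.steps],
        columns=["t", "state", "operation"]), out / "trace.tsv")
    written["trace"] = out / "trace.tsv"

    obs = build_step_observable(5, 3, l, r, seed=seed)
    for name in chosen:
        enc_l, enc_r = encs[name]
        nda = build_nda(vs, enc_l, enc_r)
        save_nda(nda, out / f"nda_{name}.json")
        ys = run_nda(nda, encode_state(s0, enc_l, enc_r), max_steps)
        _write_tsv(pd.DataFrame(
            [(t, str(y[0]), str(y[1])) for t, y in enumerate(ys)],
            columns=["t", "y1", "y2"]), out / f"nda_trajectory_{name}.tsv")
        na = build_na(nda)
        states = run_na(na, s0, max_steps)
        _write_tsv(pd.DataFrame(
            [[t] + list(x) for t, x in enumerate(states)],
            columns=["t"] + [f"x{i}" for i in range(na.n)]),
            out / f"na_trajectory_{name}.tsv")
        _write_tsv(pd.DataFrame(
            [(t, evaluate_step(obs, x)) for t, x in enumerate(states)],
            columns=["t", "step_observable"]),
            out / f"step_series_{name}.tsv")
        _write_tsv(pd.DataFrame(
            [(t, amari_mean(x)) for t, x in enumerate(states)],
            columns=["t", "amari_mean"]),
            out / f"amari_series_{name}.tsv")
        written[name] = out / f"na_trajectory_{name}.tsv"

    if encoding_choice == "both":
        pairs = [encs["gamma"], encs["delta"]]
        reports = {
            "step": verify_invariance(obs, vs, s0, pairs, max_steps,
                                      label="step"),
            "amari": verify_invariance("amari", vs, s0, pairs, max_steps),
        }
        payload = {name: dataclasses.asdict(rep)
                   for name, rep in reports.items()}
        with open(out / "invariance_report.json", "w") as fh:
            json.dump(payload, fh, indent=2)
        written["invariance"] = out / "invariance_report.json"
    return written
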