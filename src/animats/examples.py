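"""Worked-example networks and random network generators.

Two hand-transcribed example systems anchor the IIT engine:

* :func:`xor_loop_system` — a three-node deterministic system
  (A = B AND NOT C, B = NOR(A,C), C = XOR(A,B), all recurrently coupled)
  analyzed in state ABC = 101.  Its conceptual structure has exactly four
  concepts (A, B, C and the second-order AB), with φ^Max(AB) = 1/3 (cause
  side, over ABC), a maximally irreducible effect of AB on C alone
  (φ = 1/2, versus 1/4 over ABC), and system-level Φ = 11/12 ≈ 0.92.

* :func:`demo_animat` — an 8-element animat brain (2 sensors, hidden
  A-D, 2 motors) whose hidden core ABC is the three-node system above,
  with D recurrently attached (reading hidden elements, feeding back into
  the core only when on — so clamping D = 0 as background leaves the core
  untouched) and sensors driving the motors.  Analyzed in state
  00-1010-10 it specifies 6 whole-brain concepts (A, B, C, D, AB, AC),
  and its main complex is ABC with Φ^Max ≈ 0.92 and 4 concepts.  The node
  logic is a reconstruction: only the reference measure values constrain
  it, and those values are what the test suite checks the transcription
  against.

Both networks are also shipped as JSON under ``animats/data/``.

The random generators produce structurally valid brains of controlled
wiring classes for property tests (recurrent, feed-forward — acyclic
among hidden elements, hence never a complex — and self-loop-only).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .brain import BrainNetwork, build_brain, state_from_string
from .genome import GateSpec, HIDDEN_IDS, INPUT_MAP, MOTOR_IDS, OUTPUT_MAP


@dataclass(frozen=True)
class ExampleNetwork:
    """A transcribed example system with its designated analysis state and
    the reference measure values the engine is expected to reproduce
    (2-decimal reference precision, hence the 0.005 comparison tolerance)."""

    name: str
    network: BrainNetwork
    state: int
    expected: dict[str, float]


def _net_from_functions(n_sensors, n_hidden, n_motors, funcs, inputs):
    n = n_sensors + n_hidden + n_motors
    tpm = np.zeros(1 << n, dtype=np.int64)
    for s in range(1 << n):
        bits = [(s >> i) & 1 for i in range(n)]
        nxt = 0
        for el, f in funcs.items():
            nxt |= f(bits) << el
        tpm[s] = nxt
    cm = np.zeros((n, n), dtype=np.int8)
    for el, ins in inputs.items():
        for i in ins:
            cm[i, el] = 1
    return BrainNetwork(n_sensors, n_hidden, n_motors, tpm, cm)


def xor_loop_system() -> ExampleNetwork:
    """Three recurrently coupled logic gates analyzed in state ABC = 101.

    A = B AND NOT C; B = NOR(A, C); C = XOR(A, B).  In state 101 this
    system is maximally integrated as a whole: every 2-element candidate
    subset (remaining element clamped as background) has Φ = 0, so the
    main complex is ABC itself.
    """
    A, B, C = 0, 1, 2
    net = _net_from_functions(
        0, 3, 0,
        funcs={A: lambda b: b[B] & (1 - b[C]),
               B: lambda b: 1 - (b[A] | b[C]),
               C: lambda b: b[A] ^ b[B]},
        inputs={A: (B, C), B: (A, C), C: (A, B)},
    )
    return ExampleNetwork(
        name="xor_loop_system",
        network=net,
        state=state_from_string("101"),
        expected={
            "phi_effect_AB_over_ABC": 0.25,
            "phi_cause_AB_max": 0.33,      # attained over purview ABC
            "phi_effect_AB_max": 0.5,      # attained over purview C
            "phi_max_AB": 0.33,
            "n_concepts": 4,               # A, B, C, AB
            "big_phi": 0.92,
            "n_mc_elements": 3,
            "n_mc_concepts": 4,
        },
    )


def demo_animat() -> ExampleNetwork:
    """The 8-element example animat, analyzed in state 00-1010-10.

    Hidden wiring: the triad of :func:`xor_loop_system` forms the core
    A, B, C, except that C also fires whenever D is on
    (C = (A XOR B) OR D, so clamping D = 0 as background leaves the core
    untouched); D = AND(A, B, C) closes the recurrent loop and gives the
    second-order mechanism AC its effect.  Sensors drive the motors
    directly (M1 = S1, M2 = S2), which gives every element a causal role
    without altering any hidden-mechanism measure (motors receive nothing
    from the hidden layer, so they enter no purview of a hidden
    mechanism).

    In the analyzed state the brain specifies 6 whole-brain concepts
    (A, B, C, D, AB, AC) with Σφ^Max = 1.0714, and its main complex is
    ABC with Φ^Max = 11/12 ≈ 0.92 and 4 concepts; the enclosing set ABCD
    is also integrated (Φ ≈ 0.09) but excluded by ABC.
    """
    S1, S2, A, B, C, D, M1, M2 = range(8)
    net = _net_from_functions(
        2, 4, 2,
        funcs={
            A: lambda b: b[B] & (1 - b[C]),
            B: lambda b: 1 - (b[A] | b[C]),
            C: lambda b: (b[A] ^ b[B]) | b[D],
            D: lambda b: b[A] & b[B] & b[C],
            M1: lambda b: b[S1],
            M2: lambda b: b[S2],
        },
        inputs={A: (B, C), B: (A, C), C: (A, B, D), D: (A, B, C),
                M1: (S1,), M2: (S2,)},
    )
    return ExampleNetwork(
        name="demo_animat",
        network=net,
        state=state_from_string("00-1010-10"),
        expected={
            "whole_brain_n_concepts": 6,   # A, B, C, D, AB, AC
            "whole_brain_sum_phi": 1.0714,
            "mc_elements": 3,              # the hidden core ABC
            "mc_big_phi": 0.92,
            "mc_n_concepts": 4,
        },
    )


def write_example_json(directory: str) -> None:
    """Write both example networks to ``<directory>/<name>.json``."""
    import json, os

    for ex in (xor_loop_system(), demo_animat()):
        d = ex.network.to_dict()
        d["state"] = ex.state
        d["expected"] = ex.expected
        with open(os.path.join(directory, ex.name + ".json"), "w",
                  encoding="utf-8") as fh:
            json.dump(d, fh, indent=1)


def load_example_json(name: str) -> ExampleNetwork:
    import json

    text = resources.files("animats.data").joinpath(name + ".json").read_text()
    d = json.loads(text)
    return ExampleNetwork(name=name, network=BrainNetwork.from_dict(d),
                          state=int(d["state"]), expected=d["expected"])


# ---------------------------------------------------------------------------
# random brains for property tests
# ---------------------------------------------------------------------------

def random_gate(rng: np.random.Generator,
                input_pool=INPUT_MAP, output_pool=OUTPUT_MAP) -> GateSpec:
    n_in = int(rng.integers(1, 5))
    n_out = int(rng.integers(1, 5))
    inputs = tuple(sorted(rng.choice(input_pool, size=n_in, replace=True)))
    outputs = tuple(sorted(rng.choice(output_pool, size=n_out, replace=True)))
    table = tuple(int(x) for x in rng.integers(0, 1 << n_out, size=1 << n_in))
    return GateSpec(inputs, outputs, table)


def random_brain(rng: np.random.Generator, wiring: str = "recurrent",
                 n_gates: int = 6) -> BrainNetwork:
    """A structurally valid random animat brain of a given wiring class.

    ``feedforward`` guarantees an acyclic graph among hidden elements
    (each gate's hidden inputs have strictly lower indices than every
    hidden element it writes); ``self-loop-only`` allows a hidden element
    to read only itself among hidden elements.  Both classes therefore
    admit no complex.
    """
    gates = []
    for _ in range(n_gates):
        if wiring == "recurrent":
            gates.append(random_gate(rng))
        elif wiring == "feedforward":
            n_in = int(rng.integers(1, 4))
            n_out = int(rng.integers(1, 4))
            out_pool = HIDDEN_IDS[1:] + MOTOR_IDS
            outputs = tuple(sorted(rng.choice(out_pool, size=n_out, replace=True)))
            lowest_hidden = min([o for o in outputs if o in HIDDEN_IDS],
                                default=None)
            in_pool = [e for e in INPUT_MAP
                       if e < (lowest_hidden if lowest_hidden is not None
                               else HIDDEN_IDS[-1] + 1)]
            inputs = tuple(sorted(rng.choice(in_pool, size=n_in, replace=True)))
            table = tuple(int(x) for x in rng.integers(0, 1 << n_out,
                                                       size=1 << n_in))
            gates.append(GateSpec(inputs, outputs, table))
        elif wiring == "self-loop-only":
            hid = int(rng.choice(HIDDEN_IDS))
            sensor = int(rng.choice((0, 1)))
            table = tuple(int(x) for x in rng.integers(0, 2, size=4))
            gates.append(GateSpec(tuple(sorted((sensor, hid))), (hid,), table))
            if rng.random() < 0.5:
                motor = int(rng.choice(MOTOR_IDS))
                mtable = tuple(int(x) for x in rng.integers(0, 2, size=2))
                gates.append(GateSpec((hid,), (motor,), mtable))
        else:
            raise ValueError(f"unknown wiring class {wiring!r}")
    return build_brain(gates)


def random_small_network(rng: np.random.Generator, n_nodes: int) -> BrainNetwork:
    """A random fully specified deterministic hidden-only network.

    Each node's next state is a random function of a random non-empty
    input set; the connectivity matrix records the actual functional
    dependencies.  Used for oracle-equivalence testing of the IIT engine.
    """
    n = int(n_nodes)
    tpm = np.zeros(1 << n, dtype=np.int64)
    cm = np.zeros((n, n), dtype=np.int8)
    for el in range(n):
        k = int(rng.integers(1, n + 1))
        ins = sorted(rng.choice(n, size=k, replace=False))
        table = rng.integers(0, 2, size=1 << k)
        # drop fictitious dependencies so cm is exact
        real = []
        for j, src in enumerate(ins):
            rows = np.arange(1 << k)
            if np.any(table[rows & ~(1 << j)] != table[rows | (1 << j)]):
                real.append((j, src))
        for _, src in real:
            cm[src, el] = 1
        for s in range(1 << n):
            r = sum(((s >> src) & 1) << j for j, src in enumerate(ins))
            tpm[s] |= int(table[r]) << el
    return BrainNetwork(0, n, 0, tpm, cm)
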