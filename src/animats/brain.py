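"""Deterministic brain networks built from hidden Markov gates.

A :class:`BrainNetwork` is a set of binary elements — sensors, hidden
elements, and motors, indexed in that order — together with a deterministic
transition probability matrix (TPM) mapping each of the ``2**n`` element
states to the next state, and a binary connectivity matrix ``cm`` with
``cm[i, j] = 1`` iff element ``i`` is an input of some gate writing ``j``.

States are packed into integers with bit ``i`` holding element ``i``'s
value, so the state string "00-1010-10" (sensors-hidden-motors, read left
to right) has element 0 as its leftmost character.

Conventions baked into the TPM:

* sensors are exogenous: their next state is always 0 (the environment
  overwrites them after each transition), and nothing may write to them;
* motors have no effects inside the brain: no gate reads them, so the TPM
  never depends on motor bits (their state is read out for movement and
  then effectively zeroed);
* elements written by no gate fall to 0;
* when several gates write the same element, their outputs combine by OR
  (the standard Markov-brain convention; isolated in
  :func:`_combine_gate_outputs` so a variant rule could be swapped in).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import permutations
from typing import Iterable, Sequence

import numpy as np

from .genome import GateSpec


class BrainError(ValueError):
    """Raised for structurally invalid networks."""


def state_to_string(state: int, n_sensors: int, n_hidden: int, n_motors: int) -> str:
    """Render a packed state as e.g. ``"00-1010-10"`` (element 0 leftmost)."""
    n = n_sensors + n_hidden + n_motors
    bits = "".join(str((state >> i) & 1) for i in range(n))
    parts = [bits[:n_sensors], bits[n_sensors : n_sensors + n_hidden],
             bits[n_sensors + n_hidden :]]
    return "-".join(p for p in parts if p)


def state_from_string(text: str) -> int:
    """Parse ``"00-1010-10"`` (dashes optional) into a packed state integer."""
    bits = text.replace("-", "")
    if not set(bits) <= {"0", "1"}:
        raise BrainError(f"not a binary state string: {text!r}")
    return sum(int(b) << i for i, b in enumerate(bits))


@dataclass(frozen=True)
class BrainNetwork:
    """A deterministic binary network of sensors, hidden elements and motors."""

    n_sensors: int
    n_hidden: int
    n_motors: int
    tpm: np.ndarray  # shape (2**n,), next-state integers
    cm: np.ndarray  # shape (n, n), binary

    def __post_init__(self) -> None:
        n = self.n_elements
        tpm = np.asarray(self.tpm, dtype=np.int64)
        cm = np.asarray(self.cm, dtype=np.int8)
        if tpm.shape != (1 << n,):
            raise BrainError(f"TPM must have {1 << n} rows")
        if tpm.min(initial=0) < 0 or tpm.max(initial=0) >= (1 << n):
            raise BrainError("TPM entries must be valid states")
        if cm.shape != (n, n):
            raise BrainError(f"connectivity matrix must be {n}x{n}")
        sensor_mask = (1 << self.n_sensors) - 1
        if np.any(tpm & sensor_mask):
            raise BrainError("sensors must transition to 0 (they are exogenous)")
        if np.any(cm[:, : self.n_sensors]):
            raise BrainError("no connection may target a sensor")
        if self.n_motors and np.any(cm[self.n_sensors + self.n_hidden :, :]):
            raise BrainError("no connection may originate at a motor")
        object.__setattr__(self, "tpm", tpm)
        object.__setattr__(self, "cm", cm)

    @property
    def n_elements(self) -> int:
        return self.n_sensors + self.n_hidden + self.n_motors

    @property
    def sensor_ids(self) -> tuple[int, ...]:
        return tuple(range(self.n_sensors))

    @property
    def hidden_ids(self) -> tuple[int, ...]:
        return tuple(range(self.n_sensors, self.n_sensors + self.n_hidden))

    @property
    def motor_ids(self) -> tuple[int, ...]:
        return tuple(range(self.n_sensors + self.n_hidden, self.n_elements))

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_sensors": self.n_sensors,
            "n_hidden": self.n_hidden,
            "n_motors": self.n_motors,
            "tpm": [int(x) for x in self.tpm],
            "cm": [[int(x) for x in row] for row in self.cm],
        }

    def to_json(self, path: str | None = None) -> str:
        text = json.dumps(self.to_dict())
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "BrainNetwork":
        return cls(
            n_sensors=int(d["n_sensors"]),
            n_hidden=int(d["n_hidden"]),
            n_motors=int(d["n_motors"]),
            tpm=np.asarray(d["tpm"], dtype=np.int64),
            cm=np.asarray(d["cm"], dtype=np.int8),
        )

    @classmethod
    def from_json(cls, text_or_path: str) -> "BrainNetwork":
        if text_or_path.lstrip().startswith("{"):
            return cls.from_dict(json.loads(text_or_path))
        with open(text_or_path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def _combine_gate_outputs(acc: np.ndarray, new: np.ndarray) -> np.ndarray:
    """OR-combination of two gates' outputs to the same element."""
    return acc | new


def build_brain(
    gates: Iterable[GateSpec],
    n_sensors: int = 2,
    n_hidden: int = 4,
    n_motors: int = 2,
) -> BrainNetwork:
    """Assemble the deterministic TPM and connectivity matrix from gates."""
    n = n_sensors + n_hidden + n_motors
    states = np.arange(1 << n, dtype=np.int64)
    bits = [(states >> i) & 1 for i in range(n)]
    next_bits = [np.zeros(1 << n, dtype=np.int64) for _ in range(n)]
    cm = np.zeros((n, n), dtype=np.int8)
    legal_inputs = set(range(n_sensors + n_hidden))
    legal_outputs = set(range(n_sensors, n))
    for gate in gates:
        if not set(gate.input_ids) <= legal_inputs:
            raise BrainError(f"gate reads from illegal elements: {gate.input_ids}")
        if not set(gate.output_ids) <= legal_outputs:
            raise BrainError(f"gate writes to illegal elements: {gate.output_ids}")
        row = np.zeros(1 << n, dtype=np.int64)
        for k, el in enumerate(gate.input_ids):
            row |= bits[el] << k
        patterns = np.asarray(gate.table, dtype=np.int64)[row]
        for k, el in enumerate(gate.output_ids):
            next_bits[el] = _combine_gate_outputs(next_bits[el], (patterns >> k) & 1)
        for i in gate.input_ids:
            for o in gate.output_ids:
                cm[i, o] = 1
    tpm = np.zeros(1 << n, dtype=np.int64)
    for el in range(n_sensors, n):  # sensors stay 0 by construction
        tpm |= next_bits[el] << el
    return BrainNetwork(n_sensors, n_hidden, n_motors, tpm, cm)


def step(brain: BrainNetwork, state: int, sensor_values: Sequence[int]) -> int:
    """One synchronous update; sensor bits are then overwritten by the input."""
    if not 0 <= state < (1 << brain.n_elements):
        raise BrainError(f"state {state} out of range")
    if len(sensor_values) != brain.n_sensors:
        raise BrainError("wrong number of sensor values")
    nxt = int(brain.tpm[state])
    for i, v in enumerate(sensor_values):
        if v:
            nxt |= 1 << i
    return nxt


# ---------------------------------------------------------------------------
# Normal form: canonical (tpm, cm) invariant to element relabeling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalForm:
    """Canonical TPM/cm pair of the causally active part of a network.

    ``active_mask`` records which original elements survive the masking of
    hidden elements lacking inputs or lacking outputs; ``class_sizes`` are
    the (sensors, hidden, motors) counts of the reduced network.  ``key`` is
    a hashable canonical fingerprint: two networks have equal normal forms
    iff one is a within-class relabeling of the other's active part.
    """

    class_sizes: tuple[int, int, int]
    tpm_bits: bytes  # 2**m x m bit matrix, row-major
    cm_bits: bytes  # m x m
    active_mask: tuple[bool, ...]

    @property
    def key(self) -> tuple:
        return (self.class_sizes, self.tpm_bits)

    @property
    def wiring_key(self) -> tuple:
        """Fingerprint of the wiring diagram alone (connectivity, no logic)."""
        return (self.class_sizes, self.cm_bits)


def _active_elements(brain: BrainNetwork) -> list[int]:
    """Elements kept for canonicalization.

    Hidden elements need at least one input and one output connection
    (self-loops count); removal is iterated to a fixed point since dropping
    an element can strand its neighbours.  Sensors need an output and motors
    an input to be potentially causal.
    """
    cm = brain.cm.copy()
    n = brain.n_elements
    keep = np.ones(n, dtype=bool)
    changed = True
    while changed:
        changed = False
        sub = cm * np.outer(keep, keep)
        for el in range(n):
            if not keep[el]:
                continue
            has_in = bool(sub[:, el].any())
            has_out = bool(sub[el, :].any())
            if el in brain.hidden_ids:
                ok = has_in and has_out
            elif el in brain.sensor_ids:
                ok = has_out
            else:
                ok = has_in
            if not ok:
                keep[el] = False
                changed = True
    return [int(e) for e in np.flatnonzero(keep)]


def _project_tpm(brain: BrainNetwork, elements: list[int]) -> np.ndarray:
    """TPM over ``elements`` with all dropped elements clamped to 0."""
    m = len(elements)
    sub_states = np.arange(1 << m, dtype=np.int64)
    full = np.zeros(1 << m, dtype=np.int64)
    for k, el in enumerate(elements):
        full |= ((sub_states >> k) & 1) << el
    nxt = brain.tpm[full]
    out = np.zeros(1 << m, dtype=np.int64)
    for k, el in enumerate(elements):
        out |= ((nxt >> el) & 1) << k
    return out


def _class_permutations(sizes: tuple[int, int, int]):
    """All within-class permutations as full index maps old->new."""
    s, h, m = sizes
    for ps in permutations(range(s)):
        for ph in permutations(range(h)):
            for pm in permutations(range(m)):
                yield tuple(ps) + tuple(s + i for i in ph) + tuple(
                    s + h + i for i in pm
                )


def _permute(tpm: np.ndarray, cm: np.ndarray, perm: tuple[int, ...]):
    """Relabel elements: new index of old element ``e`` is ``perm[e]``."""
    m = len(perm)
    states = np.arange(1 << m, dtype=np.int64)
    remap = np.zeros(1 << m, dtype=np.int64)
    for old, new in enumerate(perm):
        remap |= ((states >> old) & 1) << new
    inv = np.empty(1 << m, dtype=np.int64)
    inv[remap] = states
    new_tpm = remap[tpm[inv]]
    idx = np.argsort(np.asarray(perm))
    new_cm = cm[np.ix_(idx, idx)]
    return new_tpm, new_cm


def _bitmatrix(tpm: np.ndarray, m: int) -> bytes:
    cols = [((tpm >> k) & 1).astype(np.uint8) for k in range(m)]
    return np.stack(cols, axis=1).tobytes() if m else b""


def normal_form(brain: BrainNetwork) -> NormalForm:
    """Lexicographically minimal within-class relabeling of the active part."""
    elements = _active_elements(brain)
    keep = [e in elements for e in range(brain.n_elements)]
    sizes = (
        sum(1 for e in elements if e in brain.sensor_ids),
        sum(1 for e in elements if e in brain.hidden_ids),
        sum(1 for e in elements if e in brain.motor_ids),
    )
    tpm = _project_tpm(brain, elements)
    m = len(elements)
    cm = brain.cm[np.ix_(elements, elements)]
    best = None
    for perm in _class_permutations(sizes):
        ptpm, pcm = _permute(tpm, cm, perm)
        key = (_bitmatrix(ptpm, m), pcm.astype(np.uint8).tobytes())
        if best is None or key < best:
            best = key
    assert best is not None
    return NormalForm(sizes, best[0], best[1], tuple(keep))


def tpm_hamming(a: NormalForm, b: NormalForm) -> int:
    """Number of TPM bit entries in which two canonical TPMs differ."""
    if a.class_sizes != b.class_sizes:
        raise BrainError(
            f"incompatible normal forms: {a.class_sizes} vs {b.class_sizes}"
        )
    xa = np.frombuffer(a.tpm_bits, dtype=np.uint8)
    xb = np.frombuffer(b.tpm_bits, dtype=np.uint8)
    return int(np.sum(xa != xb))
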