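"""Integrated-information (IIT 3.0) analysis of deterministic binary networks.

Given a network in a state, the engine computes, from the intrinsic
perspective of a candidate set of elements (everything outside is clamped
to its current state as background):

* cause and effect repertoires of a mechanism over a purview — the
  distributions of past/future purview states compatible with the
  mechanism's current state under uniform perturbation of all other inputs;
* integrated information φ of a mechanism: the earth-mover's distance
  (Hamming ground metric) between the intact repertoire and that of the
  minimum-information partition (MIP) of (mechanism, purview);
* concepts: a mechanism's maximally irreducible cause and effect
  (φ^Max = min of the two maxima over purviews; a concept exists iff
  φ^Max > 0);
* the conceptual structure of a candidate set (all concepts over its
  mechanisms) and its integrated conceptual information Φ: the extended
  EMD between the whole structure and that of the minimal unidirectional
  partition, with surplus φ^Max mass transported to the "null" concept
  (the unconstrained repertoires);
* the main complex: the candidate subset with maximal Φ.

Conventions (the standard IIT 3.0 / Markov-brain choices):

* effect repertoires factorize over purview elements (independent noise);
  cause repertoires factorize over mechanism elements ("virtual elements")
  and are undefined (φ = 0) when the mechanism state is unreachable;
* mechanism partitions are all bipartitions of (mechanism, purview) with
  two non-degenerate parts; an empty mechanism part leaves its purview
  part unconstrained;
* φ and Φ carry no partition-size normalization;
* ties in φ between purviews are broken toward the larger purview, then
  lexicographically by element indices;
* system partitions are unidirectional: connections from one part to the
  other are replaced by independent uniform noise.

Mechanisms are restricted to hidden elements (sensors lack causes and
motors lack effects within the system, so neither can be part of a
concept), while purviews may range over any candidate elements; purviews
are pruned to elements actually connected to the mechanism, which cannot
change any φ^Max because unconnected purview elements only contribute
unconstrained factors.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .brain import BrainNetwork
from .emd import hamming_emd, product_emd, _transport_lp

#: values of phi below this are treated as exactly zero (LP noise floor)
PHI_EPS = 1e-9


# ---------------------------------------------------------------------------
# bitmask helpers (element subsets inside a candidate set are int masks)
# ---------------------------------------------------------------------------

def _mask_of(locals_: Iterable[int]) -> int:
    m = 0
    for k in locals_:
        m |= 1 << k
    return m


def _bits_of(mask: int) -> tuple[int, ...]:
    out = []
    k = 0
    while mask:
        if mask & 1:
            out.append(k)
        mask >>= 1
        k += 1
    return tuple(out)


def _submasks(mask: int):
    """All submasks of ``mask`` including 0 and ``mask`` itself."""
    sub = mask
    while True:
        yield sub
        if sub == 0:
            return
        sub = (sub - 1) & mask


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Repertoire:
    """A probability distribution over the states of a purview.

    ``probs[u]`` is the probability of the purview state ``u`` packed with
    bit ``j`` holding element ``purview[j]`` (purview sorted ascending).
    ``defined`` is False when the conditioning mechanism state is
    unreachable under every perturbation (all-zero likelihood).
    """

    purview: tuple[int, ...]
    probs: np.ndarray
    defined: bool = True

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if self.defined and probs.size and abs(probs.sum() - 1.0) > 1e-8:
            raise ValueError("repertoire probabilities must sum to 1")


def repertoire_emd(p: Repertoire, q: Repertoire) -> float:
    """EMD between two repertoires over the same purview."""
    if p.purview != q.purview:
        raise ValueError(f"mismatched purviews: {p.purview} vs {q.purview}")
    return hamming_emd(p.probs, q.probs)


Partition = tuple[tuple[tuple[int, ...], tuple[int, ...]],
                  tuple[tuple[int, ...], tuple[int, ...]]]


@dataclass(frozen=True)
class MaximallyIrreducible:
    """One side (cause or effect) of a concept."""

    side: str
    purview: tuple[int, ...]
    repertoire: Repertoire
    phi: float
    mip: Partition | None


@dataclass(frozen=True)
class Concept:
    """A mechanism's maximally irreducible cause-effect repertoire."""

    mechanism: tuple[int, ...]
    mechanism_state: tuple[int, ...]
    cause: MaximallyIrreducible
    effect: MaximallyIrreducible
    phi: float
    # repertoires expanded over the full candidate set, used by the
    # extended EMD: joint cause distribution and per-element effect P(on)
    expanded_cause: np.ndarray = field(repr=False, compare=False, default=None)
    expanded_effect_marginals: np.ndarray = field(
        repr=False, compare=False, default=None
    )


@dataclass(frozen=True)
class ConceptualStructure:
    """All concepts specified by a candidate set in a state."""

    concepts: tuple[Concept, ...]

    @property
    def n_concepts(self) -> int:
        return len(self.concepts)

    @property
    def sum_phi(self) -> float:
        return float(sum(c.phi for c in self.concepts))


@dataclass(frozen=True)
class SystemIrreducibility:
    """Φ of a candidate set at its minimal unidirectional partition."""

    candidate: tuple[int, ...]
    phi: float
    cut: tuple[tuple[int, ...], tuple[int, ...]] | None  # (from, to)
    structure: ConceptualStructure
    partitioned_structure: ConceptualStructure | None


@dataclass(frozen=True)
class ComplexResult:
    """The main complex of a network in a state (or none)."""

    elements: tuple[int, ...] | None
    phi: float
    structure: ConceptualStructure | None
    candidates: Mapping[tuple[int, ...], float]

    @property
    def n_elements(self) -> int:
        return 0 if self.elements is None else len(self.elements)

    @property
    def n_concepts(self) -> int:
        return 0 if self.structure is None else self.structure.n_concepts


# ---------------------------------------------------------------------------
# subsystem core: node conditionals + caches, shared across analysis states
# ---------------------------------------------------------------------------

class _Core:
    """Conditional next-state probabilities of a candidate set.

    ``node_on[k, s]`` is P(candidate element k is on at t+1 | candidate
    state s at t), with background elements clamped to their current state.
    For deterministic networks the entries are 0/1 until a system cut
    replaces severed inputs with uniform noise.
    """

    def __init__(self, node_on: np.ndarray, in_masks: tuple[int, ...],
                 out_masks: tuple[int, ...]):
        self.node_on = node_on
        self.n = node_on.shape[0]
        self.in_masks = in_masks  # in_masks[k): mask of inputs of element k
        self.out_masks = out_masks
        self._states = np.arange(1 << self.n)
        self._eff: dict = {}
        self._cause: dict = {}
        self._pidx: dict = {}
        self._concepts: dict = {}
        self._cuts: dict = {}

    # -- index helpers ---------------------------------------------------
    def _purview_index(self, pmask: int) -> np.ndarray:
        """Map each candidate state to its packed purview sub-state."""
        idx = self._pidx.get(pmask)
        if idx is None:
            idx = np.zeros(1 << self.n, dtype=np.int64)
            for j, k in enumerate(_bits_of(pmask)):
                idx |= ((self._states >> k) & 1) << j
            self._pidx[pmask] = idx
        return idx

    # -- repertoires -----------------------------------------------------
    def effect_marginals(self, mech_mask: int, mstate: int, pmask: int) -> np.ndarray:
        """P(el on at t+1) for each purview element, mechanism clamped."""
        key = (mech_mask, mstate, pmask)
        out = self._eff.get(key)
        if out is None:
            sel = (self._states & mech_mask) == mstate
            out = np.array(
                [self.node_on[k, sel].mean() for k in _bits_of(pmask)]
            )
            self._eff[key] = out
        return out

    def cause_joint(self, mech_mask: int, mstate: int, pmask: int) -> np.ndarray | None:
        """Joint cause repertoire over the purview, or None if undefined.

        Factorizes over mechanism elements: each element's likelihood over
        past candidate states is marginalized onto the purview before the
        product is taken (the virtual-element convention).
        """
        key = (mech_mask, mstate, pmask)
        if key in self._cause:
            return self._cause[key]
        np_bits = 1 << bin(pmask).count("1")
        if mech_mask == 0:
            joint = np.full(np_bits, 1.0 / np_bits)
        else:
            pidx = self._purview_index(pmask)
            joint = np.ones(np_bits)
            for k in _bits_of(mech_mask):
                on = self.node_on[k]
                lik = on if (mstate >> k) & 1 else 1.0 - on
                marg = np.bincount(pidx, weights=lik, minlength=np_bits)
                joint = joint * marg
            total = joint.sum()
            joint = joint / total if total > PHI_EPS else None
        self._cause[key] = joint
        return joint

    # -- system cuts -----------------------------------------------------
    def cut(self, from_mask: int, to_mask: int) -> "_Core":
        """Replace connections from ``from_mask`` to ``to_mask`` by noise."""
        key = (from_mask, to_mask)
        core = self._cuts.get(key)
        if core is not None:
            return core
        node_on = self.node_on.copy()
        in_masks = list(self.in_masks)
        for k in _bits_of(to_mask):
            severed = self.in_masks[k] & from_mask
            if severed:
                acc = np.zeros(1 << self.n)
                patterns = [p for p in _submasks(severed)]
                for pat in patterns:
                    acc += self.node_on[k, (self._states & ~severed) | pat]
                node_on[k] = acc / len(patterns)
                in_masks[k] &= ~severed
        out_masks = [0] * self.n
        for k in range(self.n):
            for j in _bits_of(in_masks[k]):
                out_masks[j] |= 1 << k
        core = _Core(node_on, tuple(in_masks), tuple(out_masks))
        self._cuts[key] = core
        return core


_CORE_CACHE: dict = {}
_CORE_CACHE_MAX = 4096


def _brain_fingerprint(brain: BrainNetwork) -> int:
    fp = getattr(brain, "_fp", None)
    if fp is None:
        fp = hash((brain.n_sensors, brain.n_hidden, brain.n_motors,
                   brain.tpm.tobytes(), brain.cm.tobytes()))
        object.__setattr__(brain, "_fp", fp)
    return fp


def _build_core(brain: BrainNetwork, candidate: tuple[int, ...], bg_state: int) -> _Core:
    key = (_brain_fingerprint(brain), candidate, bg_state)
    core = _CORE_CACHE.get(key)
    if core is not None:
        return core
    n = len(candidate)
    sub_states = np.arange(1 << n, dtype=np.int64)
    full = np.full(1 << n, bg_state, dtype=np.int64)
    for k, el in enumerate(candidate):
        full |= ((sub_states >> k) & 1) << el
    nxt = brain.tpm[full]
    node_on = np.stack(
        [((nxt >> el) & 1).astype(float) for el in candidate]
    )
    in_masks = []
    for el in candidate:
        in_masks.append(_mask_of(k for k, src in enumerate(candidate)
                                 if brain.cm[src, el]))
    out_masks = [0] * n
    for k in range(n):
        for j in _bits_of(in_masks[k]):
            out_masks[j] |= 1 << k
    core = _Core(node_on, tuple(in_masks), tuple(out_masks))
    if len(_CORE_CACHE) < _CORE_CACHE_MAX:
        _CORE_CACHE[key] = core
    return core


@dataclass
class Subsystem:
    """A candidate set of elements of a brain in a state.

    Elements outside ``candidate`` are background conditions, clamped to
    their value in ``state``.  ``mechanisms`` lists the elements allowed to
    form mechanisms (defaults to the hidden elements in the candidate set).
    """

    brain: BrainNetwork
    state: int
    candidate: tuple[int, ...]
    mechanisms: tuple[int, ...]
    core: _Core = field(repr=False)

    def __init__(self, brain: BrainNetwork, state: int,
                 candidate: Sequence[int] | None = None,
                 mechanisms: Sequence[int] | None = None):
        if candidate is None:
            candidate = range(brain.n_elements)
        candidate = tuple(sorted(int(e) for e in candidate))
        if not candidate:
            raise ValueError("candidate set must be non-empty")
        if len(set(candidate)) != len(candidate):
            raise ValueError("candidate set has duplicate elements")
        if mechanisms is None:
            mechanisms = tuple(e for e in candidate if e in brain.hidden_ids)
        else:
            mechanisms = tuple(sorted(int(e) for e in mechanisms))
            if not set(mechanisms) <= set(candidate):
                raise ValueError("mechanism elements must be in the candidate set")
        cand_mask_global = _mask_of(candidate)
        bg_state = state & ~cand_mask_global
        self.brain = brain
        self.state = int(state)
        self.candidate = candidate
        self.mechanisms = mechanisms
        self.core = _build_core(brain, candidate, bg_state)

    # -- local/global conversions ---------------------------------------
    def _local_mask(self, elements: Iterable[int]) -> int:
        lookup = {el: k for k, el in enumerate(self.candidate)}
        try:
            return _mask_of(lookup[int(e)] for e in elements)
        except KeyError as exc:
            raise ValueError(f"element {exc} not in candidate set") from exc

    def _globals(self, mask: int) -> tuple[int, ...]:
        return tuple(self.candidate[k] for k in _bits_of(mask))

    def _local_state(self, mask: int) -> int:
        """Current values of the masked elements, packed on the mask bits."""
        out = 0
        for k in _bits_of(mask):
            out |= ((self.state >> self.candidate[k]) & 1) << k
        return out

    def mechanism_state(self, mechanism: Sequence[int]) -> tuple[int, ...]:
        return tuple((self.state >> int(e)) & 1 for e in sorted(mechanism))


# ---------------------------------------------------------------------------
# repertoires (public API)
# ---------------------------------------------------------------------------

def _joint_from_marginals(marginals: np.ndarray) -> np.ndarray:
    # each step doubles the array, placing element j at bit j
    joint = np.array([1.0])
    for m in marginals:
        joint = np.concatenate([joint * (1.0 - m), joint * m])
    return joint


def effect_repertoire(sub: Subsystem, mechanism: Sequence[int],
                      purview: Sequence[int]) -> Repertoire:
    """Distribution of the purview's next state given the mechanism state.

    The mechanism is clamped to its current value in ``sub.state``; all
    other candidate inputs are uniformly perturbed, background is clamped.
    Factorizes over purview elements.
    """
    mmask = sub._local_mask(mechanism)
    pmask = sub._local_mask(purview)
    if pmask == 0:
        raise ValueError("purview must be non-empty")
    marg = sub.core.effect_marginals(mmask, sub._local_state(mmask), pmask)
    return Repertoire(sub._globals(pmask), _joint_from_marginals(marg))


def cause_repertoire(sub: Subsystem, mechanism: Sequence[int],
                     purview: Sequence[int]) -> Repertoire:
    """Bayesian inversion: distribution of purview past states that are
    compatible with the mechanism's current state under a uniform
    perturbation prior, factorized over mechanism elements."""
    mmask = sub._local_mask(mechanism)
    pmask = sub._local_mask(purview)
    if pmask == 0:
        raise ValueError("purview must be non-empty")
    joint = sub.core.cause_joint(mmask, sub._local_state(mmask), pmask)
    pv = sub._globals(pmask)
    if joint is None:
        k = 1 << len(pv)
        return Repertoire(pv, np.zeros(k), defined=False)
    return Repertoire(pv, joint)


# ---------------------------------------------------------------------------
# mechanism-level phi
# ---------------------------------------------------------------------------

def _mip_bipartitions(mmask: int, pmask: int):
    """Non-degenerate unordered bipartitions of (mechanism, purview)."""
    seen = set()
    for m1 in _submasks(mmask):
        m2 = mmask & ~m1
        for p1 in _submasks(pmask):
            p2 = pmask & ~p1
            if (m1 == 0 and p1 == 0) or (m2 == 0 and p2 == 0):
                continue
            key = frozenset(((m1, p1), (m2, p2)))
            if key in seen:
                continue
            seen.add(key)
            yield (m1, p1), (m2, p2)


def _partitioned_effect(core: _Core, parts, mstate_of) -> np.ndarray | None:
    """Per-element marginals of the partitioned effect repertoire."""
    els: list[int] = []
    vals: list[float] = []
    for m_i, p_i in parts:
        if p_i == 0:
            continue
        marg = core.effect_marginals(m_i, mstate_of(m_i), p_i)
        els.extend(_bits_of(p_i))
        vals.extend(marg)
    order = np.argsort(els)
    return np.asarray(vals)[order]


def _partitioned_cause(core: _Core, parts, mstate_of, pmask: int) -> np.ndarray | None:
    """Joint partitioned cause repertoire over the full purview."""
    pbits = _bits_of(pmask)
    pos = {k: j for j, k in enumerate(pbits)}
    joint = np.ones(1 << len(pbits))
    u = np.arange(1 << len(pbits))
    for m_i, p_i in parts:
        if p_i == 0:
            continue
        r = core.cause_joint(m_i, mstate_of(m_i), p_i)
        if r is None:
            return None
        sub_idx = np.zeros_like(u)
        for jj, k in enumerate(_bits_of(p_i)):
            sub_idx |= ((u >> pos[k]) & 1) << jj
        joint = joint * r[sub_idx]
    return joint


def _phi_side(core: _Core, mmask: int, mstate: int, pmask: int, side: str):
    """(phi, mip) of a mechanism over one purview on one side.

    ``mstate`` is the mechanism's current value packed on the mask bits.
    """
    if side == "effect":
        whole = core.effect_marginals(mmask, mstate, pmask)
        best_phi, best_mip = np.inf, None
        for parts in _mip_bipartitions(mmask, pmask):
            part_marg = _partitioned_effect(core, parts, lambda m: mstate & m)
            d = product_emd(whole, part_marg)
            if d < best_phi - PHI_EPS:
                best_phi, best_mip = d, parts
            if best_phi <= PHI_EPS:
                return 0.0, None
        return float(best_phi), best_mip
    else:
        whole = core.cause_joint(mmask, mstate, pmask)
        if whole is None:
            return 0.0, None
        best_phi, best_mip = np.inf, None
        for parts in _mip_bipartitions(mmask, pmask):
            part = _partitioned_cause(core, parts, lambda m: mstate & m, pmask)
            if part is None:
                continue
            d = hamming_emd(whole, part)
            if d < best_phi - PHI_EPS:
                best_phi, best_mip = d, parts
            if best_phi <= PHI_EPS:
                return 0.0, None
        if best_mip is None:
            return 0.0, None
        return float(best_phi), best_mip


def mechanism_phi(sub: Subsystem, mechanism: Sequence[int],
                  purview: Sequence[int], side: str):
    """φ of a mechanism over a fixed purview: EMD(whole, MIP repertoire).

    Returns ``(phi, mip)`` where ``mip`` is the minimizing bipartition as
    ``((mech_part1, purv_part1), (mech_part2, purv_part2))`` in global
    element ids, or None when φ = 0.
    """
    if side not in ("cause", "effect"):
        raise ValueError("side must be 'cause' or 'effect'")
    mmask = sub._local_mask(mechanism)
    pmask = sub._local_mask(purview)
    phi, mip = _phi_side(sub.core, mmask, sub._local_state(mmask), pmask, side)
    if mip is None:
        return phi, None
    gmip = tuple(
        (sub._globals(m_i), sub._globals(p_i)) for m_i, p_i in mip
    )
    return phi, gmip


# ---------------------------------------------------------------------------
# concepts
# ---------------------------------------------------------------------------

def _popcount_int(x: int) -> int:
    return bin(x).count("1")


def _better_purview(phi: float, pmask: int, best_phi: float, best_pmask: int) -> bool:
    """Tie-break: larger purview first, then lexicographically smaller."""
    if phi > best_phi + PHI_EPS:
        return True
    if phi < best_phi - PHI_EPS:
        return False
    a, b = _popcount_int(pmask), _popcount_int(best_pmask)
    if a != b:
        return a > b
    return _bits_of(pmask) < _bits_of(best_pmask)


def _core_side(core: _Core, mmask: int, mstate: int, side: str):
    """Maximally irreducible side over all connected purviews.

    Returns ``(phi, pmask, mip)`` with ``phi = 0`` when no purview is
    irreducible (or none is connected to the mechanism).
    """
    space = 0
    for k in _bits_of(mmask):
        space |= core.in_masks[k] if side == "cause" else core.out_masks[k]
    best = (0.0, 0, None)
    for pmask in _submasks(space):
        if pmask == 0:
            continue
        phi, mip = _phi_side(core, mmask, mstate, pmask, side)
        if phi > PHI_EPS and _better_purview(phi, pmask, best[0], best[1]):
            best = (phi, pmask, mip)
    return best


def _expand_cause(core: _Core, joint: np.ndarray, pmask: int) -> np.ndarray:
    """Expand a cause repertoire over the full candidate set (uniform rest)."""
    n = core.n
    pidx = core._purview_index(pmask)
    scale = 1.0 / (1 << (n - _popcount_int(pmask)))
    return joint[pidx] * scale


def _expand_effect(core: _Core, marg: np.ndarray, pmask: int) -> np.ndarray:
    """Per-element effect marginals over the full candidate set."""
    out = np.empty(core.n)
    pv = set(_bits_of(pmask))
    j = 0
    for k in range(core.n):
        if k in pv:
            out[k] = marg[j]
            j += 1
        else:
            out[k] = core.effect_marginals(0, 0, 1 << k)[0]
    return out


def _concept_local(core: _Core, mmask: int, mstate: int):
    """Concept of one mechanism in local terms, or None (cached on core)."""
    key = (mmask, mstate)
    if key in core._concepts:
        return core._concepts[key]
    result = None
    phi_c, pmask_c, mip_c = _core_side(core, mmask, mstate, "cause")
    if phi_c > PHI_EPS:
        phi_e, pmask_e, mip_e = _core_side(core, mmask, mstate, "effect")
        if phi_e > PHI_EPS:
            cause_rep = core.cause_joint(mmask, mstate, pmask_c)
            eff_marg = core.effect_marginals(mmask, mstate, pmask_e)
            result = {
                "phi": min(phi_c, phi_e),
                "cause": (phi_c, pmask_c, mip_c, cause_rep),
                "effect": (phi_e, pmask_e, mip_e, eff_marg),
                "expanded_cause": _expand_cause(core, cause_rep, pmask_c),
                "expanded_effect": _expand_effect(core, eff_marg, pmask_e),
            }
    core._concepts[key] = result
    return result


def _globalize_mip(candidate: tuple[int, ...], mip) -> Partition | None:
    if mip is None:
        return None
    return tuple(
        (tuple(candidate[k] for k in _bits_of(m_i)),
         tuple(candidate[k] for k in _bits_of(p_i)))
        for m_i, p_i in mip
    )


def _concept_global(candidate: tuple[int, ...], mmask: int, mstate: int,
                    local) -> Concept:
    mech = tuple(candidate[k] for k in _bits_of(mmask))
    mstate_bits = tuple((mstate >> k) & 1 for k in _bits_of(mmask))
    phi_c, pmask_c, mip_c, cause_rep = local["cause"]
    phi_e, pmask_e, mip_e, eff_marg = local["effect"]
    pv_c = tuple(candidate[k] for k in _bits_of(pmask_c))
    pv_e = tuple(candidate[k] for k in _bits_of(pmask_e))
    cause = MaximallyIrreducible(
        "cause", pv_c, Repertoire(pv_c, cause_rep), phi_c,
        _globalize_mip(candidate, mip_c),
    )
    effect = MaximallyIrreducible(
        "effect", pv_e, Repertoire(pv_e, _joint_from_marginals(eff_marg)),
        phi_e, _globalize_mip(candidate, mip_e),
    )
    return Concept(
        mechanism=mech, mechanism_state=mstate_bits, cause=cause,
        effect=effect, phi=local["phi"],
        expanded_cause=local["expanded_cause"],
        expanded_effect_marginals=local["expanded_effect"],
    )


def compute_concept(sub: Subsystem, mechanism: Sequence[int]) -> Concept | None:
    """The concept of a mechanism in the subsystem's current state.

    φ is maximized over cause purviews and effect purviews separately;
    φ^Max is the minimum of the two maxima.  Returns None when the
    mechanism is reducible on either side (φ^Max = 0).
    """
    mmask = sub._local_mask(mechanism)
    if mmask == 0:
        raise ValueError("mechanism must be non-empty")
    local = _concept_local(sub.core, mmask, sub._local_state(mmask))
    if local is None:
        return None
    return _concept_global(sub.candidate, mmask, sub._local_state(mmask), local)


def _structure_from_core(core: _Core, candidate: tuple[int, ...],
                         mech_space: int, full_state: int) -> ConceptualStructure:
    concepts = []
    order = sorted(
        (m for m in _submasks(mech_space) if m),
        key=lambda m: (_popcount_int(m), _bits_of(m)),
    )
    for mmask in order:
        local = _concept_local(core, mmask, full_state & mmask)
        if local is not None:
            concepts.append(
                _concept_global(candidate, mmask, full_state & mmask, local)
            )
    return ConceptualStructure(tuple(concepts))


def conceptual_structure(sub: Subsystem) -> ConceptualStructure:
    """All concepts over the subsystem's mechanisms in the current state."""
    mech_space = sub._local_mask(sub.mechanisms)
    full_state = sub._local_state((1 << len(sub.candidate)) - 1)
    return _structure_from_core(sub.core, sub.candidate, mech_space, full_state)


# ---------------------------------------------------------------------------
# system-level Phi (extended EMD between conceptual structures)
# ---------------------------------------------------------------------------

def _ces_distance(c1: ConceptualStructure, c2: ConceptualStructure,
                  null_cause: np.ndarray, null_effect: np.ndarray) -> float:
    """Extended EMD: transport φ mass from the concepts of ``c1`` to those
    of ``c2``; surplus mass on either side goes to the null concept."""

    def dist(a_cause, a_eff, b_cause, b_eff) -> float:
        return hamming_emd(a_cause, b_cause) + product_emd(a_eff, b_eff)

    src = [(c.phi, c.expanded_cause, c.expanded_effect_marginals)
           for c in c1.concepts]
    dst = [(c.phi, c.expanded_cause, c.expanded_effect_marginals)
           for c in c2.concepts]
    sum1 = sum(s[0] for s in src)
    sum2 = sum(d[0] for d in dst)
    if sum1 + sum2 <= PHI_EPS:
        return 0.0
    if sum1 > sum2 + PHI_EPS:
        dst.append((sum1 - sum2, null_cause, null_effect))
    elif sum2 > sum1 + PHI_EPS:
        src.append((sum2 - sum1, null_cause, null_effect))
    if not src or not dst:
        return 0.0
    cost = np.array(
        [[dist(sc, se, dc, de) for _, dc, de in dst] for _, sc, se in src]
    )
    a = np.array([m for m, _, _ in src])
    b = np.array([m for m, _, _ in dst])
    # rebalance float drift
    b *= a.sum() / b.sum()
    if len(src) == 1:
        return float(np.dot(b, cost[0]))
    if len(dst) == 1:
        return float(np.dot(a, cost[:, 0]))
    return _transport_lp(a, b, cost)


def _strongly_connected(core: _Core) -> bool:
    n = core.n
    rows, cols = [], []
    for k in range(n):
        for j in _bits_of(core.in_masks[k]):
            rows.append(j)
            cols.append(k)
    if not rows:
        return n == 1
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    ncomp, _ = connected_components(adj, directed=True, connection="strong")
    return ncomp == 1


def _witness_cut(core: _Core) -> tuple[int, int]:
    """A directed bipartition with no crossing connections (Φ = 0 witness).

    Exists whenever the candidate graph is not strongly connected: take a
    source component of the condensation as the 'to' part.
    """
    n = core.n
    rows, cols = [], []
    for k in range(n):
        for j in _bits_of(core.in_masks[k] & ~(1 << k)):
            rows.append(j)
            cols.append(k)
    adj = csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    ) if rows else csr_matrix((n, n))
    ncomp, labels = connected_components(adj, directed=True, connection="strong")
    # find a component with no incoming edges from other components
    incoming = [False] * ncomp
    for j, k in zip(rows, cols):
        if labels[j] != labels[k]:
            incoming[labels[k]] = True
    source = next(c for c in range(ncomp) if not incoming[c])
    to_mask = _mask_of(k for k in range(n) if labels[k] == source)
    from_mask = ((1 << n) - 1) & ~to_mask
    if from_mask == 0:  # single SCC of the loop-free graph, n == 1 impossible here
        from_mask, to_mask = to_mask, from_mask
    return from_mask, to_mask


def system_phi(sub: Subsystem) -> SystemIrreducibility:
    """Integrated conceptual information Φ of the candidate set.

    Evaluates every unidirectional bipartition (connections from one part
    to the other replaced by noise) and returns the minimal extended-EMD
    distance between the whole and partitioned conceptual structures.
    """
    n = len(sub.candidate)
    if n < 2:
        raise ValueError("a candidate complex needs at least 2 elements")
    whole = conceptual_structure(sub)
    core = sub.core
    full_mask = (1 << n) - 1
    full_state = sub._local_state(full_mask)
    mech_space = sub._local_mask(sub.mechanisms)
    if not whole.concepts:
        return SystemIrreducibility(sub.candidate, 0.0, None, whole, whole)
    if not _strongly_connected(core):
        # some unidirectional cut severs nothing, so Φ = 0 exactly
        return SystemIrreducibility(
            sub.candidate, 0.0,
            tuple(sub._globals(m) for m in _witness_cut(core)),
            whole, whole,
        )
    null_cause = np.full(1 << n, 1.0 / (1 << n))
    null_effect = np.array(
        [core.effect_marginals(0, 0, 1 << k)[0] for k in range(n)]
    )
    best = None
    for from_mask in range(1, full_mask):
        to_mask = full_mask & ~from_mask
        cut_core = core.cut(from_mask, to_mask)
        c_cut = _structure_from_core(cut_core, sub.candidate, mech_space,
                                     full_state)
        d = _ces_distance(whole, c_cut, null_cause, null_effect)
        if best is None or d < best[0] - PHI_EPS:
            best = (d, (from_mask, to_mask), c_cut)
        if best[0] <= PHI_EPS:
            break
    phi, (fm, tm), c_mip = best
    return SystemIrreducibility(
        sub.candidate, max(float(phi), 0.0),
        (sub._globals(fm), sub._globals(tm)), whole, c_mip,
    )


# ---------------------------------------------------------------------------
# complexes and whole-brain summaries
# ---------------------------------------------------------------------------

def find_main_complex(brain: BrainNetwork, state: int) -> ComplexResult:
    """Search all candidate complexes and return the maximally integrated one.

    Candidates are subsets of the hidden elements with at least two
    members: any set containing a sensor or motor is connected to the rest
    in a feed-forward way and has Φ = 0 a priori, and a single element
    cannot be partitioned.
    """
    hidden = brain.hidden_ids
    candidates: dict[tuple[int, ...], float] = {}
    best: SystemIrreducibility | None = None
    for size in range(2, len(hidden) + 1):
        for cand in itertools.combinations(hidden, size):
            sub = Subsystem(brain, state, candidate=cand)
            res = system_phi(sub)
            candidates[cand] = res.phi
            if res.phi > PHI_EPS:
                if (best is None or res.phi > best.phi + PHI_EPS
                        or (abs(res.phi - best.phi) <= PHI_EPS
                            and (len(cand), cand) > (len(best.candidate),
                                                     best.candidate))):
                    best = res
    if best is None:
        return ComplexResult(None, 0.0, None, candidates)
    return ComplexResult(best.candidate, best.phi, best.structure, candidates)


def whole_brain_concepts(brain: BrainNetwork, state: int) -> dict:
    """Concepts of the entire brain: mechanisms over hidden elements,
    purviews over any elements (sensors for causes, motors for effects)."""
    sub = Subsystem(brain, state)
    cs = conceptual_structure(sub)
    return {"n_concepts": cs.n_concepts, "sum_phi": cs.sum_phi, "structure": cs}


def state_weighted_summary(brain: BrainNetwork, task=None, rng=None,
                           record=None) -> dict:
    """Causal measures averaged over experienced states.

    Runs the task's 128 trials (unless a FitnessRecord is supplied),
    computes the whole-brain concept measures and the main complex for
    every distinct visited brain state, and averages each measure weighted
    by the state's visit probability.
    """
    if record is None:
        if task is None:
            raise ValueError("either a task or a FitnessRecord is required")
        from .environment import evaluate
        record = evaluate(brain, task, rng)
    totals = {"n_concepts": 0.0, "sum_phi_max": 0.0, "n_mc_elements": 0.0,
              "n_mc_concepts": 0.0, "big_phi_max": 0.0}
    for state, w in sorted(record.state_distribution.items()):
        wb = whole_brain_concepts(brain, state)
        mc = find_main_complex(brain, state)
        totals["n_concepts"] += w * wb["n_concepts"]
        totals["sum_phi_max"] += w * wb["sum_phi"]
        totals["n_mc_elements"] += w * mc.n_elements
        totals["n_mc_concepts"] += w * mc.n_concepts
        totals["big_phi_max"] += w * mc.phi
    return totals
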