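"""Independent reference implementation of the IIT 3.0 measures.

A deliberately simple, slow re-derivation used only as a test oracle for
the engine in ``animats.iit``.  It shares the mathematical conventions
(factorized repertoires, non-degenerate bipartitions, Hamming-ground EMD,
unidirectional system cuts, null-concept transport) but none of the code:
states are tuples, distributions are dicts, purviews are enumerated
without connectivity pruning, nothing is cached, and every earth-mover's
distance is solved as a dense transportation LP over the full state
spaces.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linprog

EPS = 1e-9


def states_of(elements):
    return list(itertools.product((0, 1), repeat=len(elements)))


def node_function(net, candidate, bg_state):
    """P(element on at t+1 | candidate state), background clamped.

    Returns {element: {candidate_state_tuple: prob}}.
    """
    cand = list(candidate)
    out = {el: {} for el in cand}
    for s in states_of(cand):
        full = 0
        for el in range(net.n_elements):
            if el in cand:
                if s[cand.index(el)]:
                    full |= 1 << el
            elif (bg_state >> el) & 1:
                full |= 1 << el
        nxt = int(net.tpm[full])
        for el in cand:
            out[el][s] = float((nxt >> el) & 1)
    return out


def cut_node_function(nf, candidate, from_part, to_part):
    """Replace dependence of ``to_part`` elements on ``from_part`` inputs
    by averaging over them (independent uniform noise)."""
    cand = list(candidate)
    new = {}
    for el, table in nf.items():
        if el not in to_part:
            new[el] = dict(table)
            continue
        new_table = {}
        sever = [i for i, src in enumerate(cand) if src in from_part]
        for s in table:
            vals = []
            for repl in itertools.product((0, 1), repeat=len(sever)):
                t = list(s)
                for i, v in zip(sever, repl):
                    t[i] = v
                vals.append(table[tuple(t)])
            new_table[s] = float(np.mean(vals))
        new[el] = new_table
    return new


_MEMO: dict = {}
_NF_KEYS: dict = {}


def _nf_key(nf):
    pinned = _NF_KEYS.get(id(nf))
    if pinned is not None and pinned[0] is nf:
        return pinned[1]
    key = tuple((el, tuple(v for _, v in sorted(t.items())))
                for el, t in sorted(nf.items()))
    _NF_KEYS[id(nf)] = (nf, key)
    return key


def effect_repertoire(nf, candidate, mechanism, mstate, purview):
    """Product over purview elements of P(el on | mechanism clamped)."""
    cand = list(candidate)
    key = ("eff", _nf_key(nf), tuple(mechanism), tuple(mstate), tuple(purview))
    if key in _MEMO:
        return _MEMO[key]
    p_on = {}
    for el in purview:
        num, cnt = 0.0, 0
        for s in states_of(cand):
            if all(s[cand.index(m)] == mv for m, mv in zip(mechanism, mstate)):
                num += nf[el][s]
                cnt += 1
        p_on[el] = num / cnt
    rep = {}
    for p_state in states_of(purview):
        prob = 1.0
        for j, el in enumerate(purview):
            prob *= p_on[el] if p_state[j] else 1.0 - p_on[el]
        rep[p_state] = prob
    _MEMO[key] = rep
    return rep


def cause_repertoire(nf, candidate, mechanism, mstate, purview):
    """Factorized Bayesian inversion; None when the state is unreachable."""
    cand = list(candidate)
    key = ("cause", _nf_key(nf), tuple(mechanism), tuple(mstate), tuple(purview))
    if key in _MEMO:
        return _MEMO[key]
    if not mechanism:
        u = 1.0 / len(states_of(purview))
        return {s: u for s in states_of(purview)}
    factors = []
    for m, mv in zip(mechanism, mstate):
        marg = {p: 0.0 for p in states_of(purview)}
        for s in states_of(cand):
            lik = nf[m][s] if mv else 1.0 - nf[m][s]
            key = tuple(s[cand.index(el)] for el in purview)
            marg[key] += lik
        factors.append(marg)
    rep = {}
    for p in states_of(purview):
        v = 1.0
        for f in factors:
            v *= f[p]
        rep[p] = v
    total = sum(rep.values())
    out = None if total <= EPS else {p: v / total for p, v in rep.items()}
    _MEMO[key] = out
    return out


_LP_PARTS: dict = {}


def _lp_parts(k: int):
    """Hamming cost vector and constraint matrix for a k-element space."""
    if k not in _LP_PARTS:
        sts = states_of(range(k))
        n = len(sts)
        cost = np.array([[sum(a != b for a, b in zip(si, sj)) for sj in sts]
                         for si in sts], dtype=float)
        rows = []
        for i in range(n):
            row = np.zeros(n * n)
            row[i * n:(i + 1) * n] = 1
            rows.append(row)
        for j in range(n - 1):
            row = np.zeros(n * n)
            row[j::n] = 1
            rows.append(row)
        _LP_PARTS[k] = (cost.ravel(), np.array(rows))
    return _LP_PARTS[k]


def emd(p_dict, q_dict, elements):
    """Dense transportation LP over all states of ``elements``."""
    sts = states_of(elements)
    p = np.array([p_dict[s] for s in sts])
    q = np.array([q_dict[s] for s in sts])
    if np.allclose(p, q, atol=1e-12):
        return 0.0
    if len(elements) == 1:  # two states at distance 1
        return float(abs(p[0] - q[0]))
    key = (len(elements), np.round(p - q, 12).tobytes())
    if key in _MEMO:
        return _MEMO[key]
    r = p - q
    src = [i for i in range(len(sts)) if r[i] > 1e-12]
    dst = [j for j in range(len(sts)) if r[j] < -1e-12]
    if len(src) == 1:
        val = sum(-r[j] * sum(a != b for a, b in zip(sts[src[0]], sts[j]))
                  for j in dst)
    elif len(dst) == 1:
        val = sum(r[i] * sum(a != b for a, b in zip(sts[i], sts[dst[0]]))
                  for i in src)
    elif len(src) == 2 and len(dst) == 2:
        # one-degree-of-freedom transportation: optimum at an endpoint
        a1, a2 = r[src[0]], r[src[1]]
        b1, b2 = -r[dst[0]], -r[dst[1]]
        c = [[sum(x != y for x, y in zip(sts[i], sts[j])) for j in dst]
             for i in src]
        lo, hi = max(0.0, a1 - b2), min(a1, b1)
        def tcost(x):
            return (c[0][0] * x + c[0][1] * (a1 - x) + c[1][0] * (b1 - x)
                    + c[1][1] * (a2 - b1 + x))
        val = min(tcost(lo), tcost(hi))
    else:
        cost, A_eq = _lp_parts(len(elements))
        b_eq = np.concatenate([p, q[:-1]])
        res = linprog(cost, A_eq=A_eq, b_eq=b_eq, method="highs")
        assert res.success
        val = float(res.fun)
    _MEMO[key] = float(val)
    return float(val)


def product_rep(r1, p1, r2, p2, purview):
    """Combine part repertoires onto the full purview."""
    out = {}
    for s in states_of(purview):
        v = 1.0
        if p1:
            v *= r1[tuple(s[purview.index(el)] for el in p1)]
        if p2:
            v *= r2[tuple(s[purview.index(el)] for el in p2)]
        out[s] = v
    return out


def bipartitions(mechanism, purview):
    seen = []
    for m1 in all_subsets(mechanism, empty=True):
        m2 = tuple(x for x in mechanism if x not in m1)
        for p1 in all_subsets(purview, empty=True):
            p2 = tuple(x for x in purview if x not in p1)
            if (not m1 and not p1) or (not m2 and not p2):
                continue
            key = frozenset([(m1, p1), (m2, p2)])
            if key in seen:
                continue
            seen.append(key)
            yield (m1, p1), (m2, p2)


def all_subsets(xs, empty=False):
    start = 0 if empty else 1
    for r in range(start, len(xs) + 1):
        for c in itertools.combinations(xs, r):
            yield c


def phi_side(nf, candidate, mechanism, mstate, purview, side):
    if side == "effect":
        whole = effect_repertoire(nf, candidate, mechanism, mstate, purview)
    else:
        whole = cause_repertoire(nf, candidate, mechanism, mstate, purview)
        if whole is None:
            return 0.0
    best = np.inf
    for (m1, p1), (m2, p2) in bipartitions(mechanism, purview):
        ms1 = tuple(mstate[mechanism.index(m)] for m in m1)
        ms2 = tuple(mstate[mechanism.index(m)] for m in m2)
        if side == "effect":
            r1 = effect_repertoire(nf, candidate, m1, ms1, p1) if p1 else None
            r2 = effect_repertoire(nf, candidate, m2, ms2, p2) if p2 else None
        else:
            r1 = cause_repertoire(nf, candidate, m1, ms1, p1) if p1 else None
            r2 = cause_repertoire(nf, candidate, m2, ms2, p2) if p2 else None
            if (p1 and r1 is None) or (p2 and r2 is None):
                continue
        part = product_rep(r1, list(p1), r2, list(p2), list(purview))
        best = min(best, emd(whole, part, list(purview)))
        if best <= EPS:
            return 0.0
    return 0.0 if best is np.inf else float(best)


def max_phi_side(nf, candidate, mechanism, mstate, side):
    """(phi_max, best purview) over every non-empty purview (no pruning).

    Ties in phi go to the larger purview, then to the lexicographically
    first (the convention the engine uses; the choice feeds into the
    extended EMD through the winning purview's repertoires).
    """
    best, best_pv = 0.0, None
    for pv in all_subsets(tuple(candidate)):
        phi = phi_side(nf, candidate, mechanism, mstate, tuple(pv), side)
        if phi <= EPS:
            continue
        if (phi > best + EPS
                or (phi > best - EPS and best_pv is not None
                    and len(pv) > len(best_pv))):
            best, best_pv = phi, pv
    return best, best_pv


def concept(nf, candidate, mechanism, mstate):
    """(phi_max, cause side, effect side) or None."""
    phi_c, pv_c = max_phi_side(nf, candidate, mechanism, mstate, "cause")
    if phi_c <= EPS:
        return None
    phi_e, pv_e = max_phi_side(nf, candidate, mechanism, mstate, "effect")
    if phi_e <= EPS:
        return None
    return min(phi_c, phi_e), (phi_c, pv_c), (phi_e, pv_e)


def conceptual_structure(nf, candidate, state, mechanisms):
    out = {}
    for mech in all_subsets(tuple(mechanisms)):
        mstate = tuple((state >> m) & 1 for m in mech)
        c = concept(nf, candidate, mech, mstate)
        if c is not None:
            out[mech] = c
    return out


def expand_cause(rep, purview, candidate):
    full = {}
    scale = 1.0 / (1 << (len(candidate) - len(purview)))
    for s in states_of(candidate):
        key = tuple(s[list(candidate).index(el)] for el in purview)
        full[s] = rep[key] * scale
    return full


def expanded_concept_reps(nf, candidate, mech, mstate, cause_pv, effect_pv):
    cr = cause_repertoire(nf, candidate, mech, mstate, tuple(cause_pv))
    er_m = {}
    for el in candidate:
        if el in effect_pv:
            r = effect_repertoire(nf, candidate, mech, mstate, (el,))
        else:
            r = effect_repertoire(nf, candidate, (), (), (el,))
        er_m[el] = r[(1,)]
    return expand_cause(cr, list(cause_pv), list(candidate)), er_m


def ces_distance(concepts1, concepts2, null_cause, null_eff, candidate):
    def cdist(a, b):
        d_cause = emd(a[0], b[0], list(candidate))
        d_eff = sum(abs(a[1][el] - b[1][el]) for el in candidate)
        return d_cause + d_eff

    src = [(phi, reps) for phi, reps in concepts1]
    dst = [(phi, reps) for phi, reps in concepts2]
    s1 = sum(p for p, _ in src)
    s2 = sum(p for p, _ in dst)
    if s1 + s2 <= EPS:
        return 0.0
    null = (null_cause, null_eff)
    if s1 > s2 + EPS:
        dst.append((s1 - s2, null))
    elif s2 > s1 + EPS:
        src.append((s2 - s1, null))
    a = np.array([p for p, _ in src])
    b = np.array([p for p, _ in dst])
    b *= a.sum() / b.sum()
    cost = np.array([[cdist(ra, rb) for _, rb in dst] for _, ra in src])
    ns, nd = len(a), len(b)
    A_eq, b_eq = [], []
    for i in range(ns):
        row = np.zeros(ns * nd)
        row[i * nd:(i + 1) * nd] = 1
        A_eq.append(row)
        b_eq.append(a[i])
    for j in range(nd - 1):
        row = np.zeros(ns * nd)
        row[j::nd] = 1
        A_eq.append(row)
        b_eq.append(b[j])
    res = linprog(cost.ravel(), A_eq=np.array(A_eq), b_eq=np.array(b_eq),
                  method="highs")
    assert res.success
    return float(res.fun)


def _structure_with_reps(nf, candidate, state, mechanisms):
    cs = conceptual_structure(nf, candidate, state, mechanisms)
    out = []
    for mech, (phi, (phi_c, pv_c), (phi_e, pv_e)) in cs.items():
        mstate = tuple((state >> m) & 1 for m in mech)
        reps = expanded_concept_reps(nf, candidate, mech, mstate, pv_c, pv_e)
        out.append((phi, reps))
    return cs, out


def system_phi(net, candidate, state, mechanisms=None):
    """(Phi, whole conceptual structure dict) of one candidate set."""
    candidate = tuple(sorted(candidate))
    mechanisms = tuple(sorted(mechanisms or candidate))
    cand_mask = sum(1 << e for e in candidate)
    nf = node_function(net, candidate, state & ~cand_mask)
    cs, whole = _structure_with_reps(nf, candidate, state, mechanisms)
    if not whole:
        return 0.0, cs
    u = 1.0 / (1 << len(candidate))
    null_cause = {s: u for s in states_of(candidate)}
    null_eff = {el: effect_repertoire(nf, candidate, (), (), (el,))[(1,)]
                for el in candidate}
    best = np.inf
    # every ordered (from, to) bipartition appears exactly once across r
    for r in range(1, len(candidate)):
        for frm in itertools.combinations(candidate, r):
            to = tuple(e for e in candidate if e not in frm)
            nf_cut = cut_node_function(nf, candidate, frm, to)
            _, cut_struct = _structure_with_reps(nf_cut, candidate, state,
                                                 mechanisms)
            d = ces_distance(whole, cut_struct, null_cause, null_eff,
                             candidate)
            best = min(best, d)
            if best <= EPS:
                return 0.0, cs
    return float(best), cs


def main_complex(net, state):
    """(elements, Phi, n_concepts) of the maximally integrated subset.

    Ties in Phi go to the larger candidate set, then lexicographically
    (the same convention as the engine under test).
    """
    hidden = net.hidden_ids
    best = (None, 0.0, 0)
    for r in range(2, len(hidden) + 1):
        for cand in itertools.combinations(hidden, r):
            phi, cs = system_phi(net, cand, state)
            if phi <= EPS:
                continue
            better = phi > best[1] + EPS or (
                phi > best[1] - EPS and best[0] is not None
                and (len(cand), cand) > (len(best[0]), best[0])
            )
            if better:
                best = (cand, phi, len(cs))
    return best
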