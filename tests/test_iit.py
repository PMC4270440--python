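import numpy as np
import pytest

import reference_iit as ref
from animats.brain import build_brain, state_from_string
from animats.examples import random_brain, random_small_network, xor_loop_system
from animats.genome import GateSpec
from animats.iit import (PHI_EPS, Subsystem, cause_repertoire, compute_concept,
                         conceptual_structure, effect_repertoire,
                         find_main_complex, mechanism_phi, repertoire_emd,
                         system_phi, whole_brain_concepts)

A, B, C = 0, 1, 2


@pytest.fixture(scope="module")
def xor_sub():
    ex = xor_loop_system()
    return Subsystem(ex.network, ex.state)


class TestRepertoires:
    def test_xor_cause_repertoire_only_odd_parity_states(self, xor_sub):
        # C = XOR(A,B) in state 1: only past AB in {10, 01} are possible
        rep = cause_repertoire(xor_sub, [C], [A, B])
        assert rep.probs == pytest.approx([0, 0.5, 0.5, 0], abs=1e-12)

    def test_empty_mechanism_gives_uniform_cause(self, xor_sub):
        rep = cause_repertoire(xor_sub, [], [A, B, C])
        assert rep.probs == pytest.approx(np.full(8, 1 / 8), abs=1e-12)

    def test_xor_output_with_uniform_inputs_is_fair_coin(self, xor_sub):
        rep = effect_repertoire(xor_sub, [], [C])
        assert rep.probs == pytest.approx([0.5, 0.5], abs=1e-12)

    def test_full_input_clamp_gives_degenerate_effect(self, xor_sub):
        # A=1, B=0 fully determine C's next state (XOR -> 1)
        rep = effect_repertoire(xor_sub, [A, B], [C])
        assert rep.probs == pytest.approx([0.0, 1.0], abs=1e-12)

    def test_unreachable_mechanism_state_flagged_undefined(self):
        # element 1 copies element 0; mechanism (0=1, 1-as-copy...) choose
        # a state where a COPY target disagrees with every possible source
        net = build_brain([GateSpec((2,), (4,), (1, 1))])  # el 4 := const 1
        sub = Subsystem(net, 0)  # el 4 currently 0: impossible outcome
        rep = cause_repertoire(sub, [4], [2])
        assert not rep.defined
        c = compute_concept(sub, [4])
        assert c is None

    def test_repertoire_probabilities_sum_to_one(self, rng):
        net = random_small_network(rng, 4)
        sub = Subsystem(net, int(rng.integers(16)))
        for mech in ([0], [1, 2], [0, 3]):
            for pv in ([0], [1, 3], [0, 1, 2, 3]):
                r = cause_repertoire(sub, mech, pv)
                if r.defined:
                    assert r.probs.sum() == pytest.approx(1.0, abs=1e-9)
                assert effect_repertoire(sub, mech, pv).probs.sum() == \
                    pytest.approx(1.0, abs=1e-9)

    def test_emd_requires_matching_purviews(self, xor_sub):
        p = cause_repertoire(xor_sub, [C], [A, B])
        q = cause_repertoire(xor_sub, [C], [A, C])
        with pytest.raises(ValueError):
            repertoire_emd(p, q)


class TestWorkedExample:
    """Printed values of the three-node example (2-decimal rounding)."""

    def test_effect_phi_of_AB_over_full_purview(self, xor_sub):
        phi, _ = mechanism_phi(xor_sub, [A, B], [A, B, C], "effect")
        assert phi == pytest.approx(0.25, abs=0.005)

    def test_core_cause_of_AB(self, xor_sub):
        c = compute_concept(xor_sub, [A, B])
        assert c.cause.purview == (A, B, C)
        assert c.cause.phi == pytest.approx(1 / 3, abs=1e-9)

    def test_core_effect_of_AB_is_C_alone(self, xor_sub):
        c = compute_concept(xor_sub, [A, B])
        assert c.effect.purview == (C,)
        assert c.effect.phi == pytest.approx(0.5, abs=1e-9)

    def test_phi_max_is_min_of_sides(self, xor_sub):
        c = compute_concept(xor_sub, [A, B])
        assert c.phi == pytest.approx(min(c.cause.phi, c.effect.phi), abs=1e-12)
        assert c.phi == pytest.approx(1 / 3, abs=0.005)

    def test_conceptual_structure_has_exactly_four_concepts(self, xor_sub):
        cs = conceptual_structure(xor_sub)
        assert {c.mechanism for c in cs.concepts} == {(A,), (B,), (C,), (A, B)}

    def test_system_phi_is_0_92(self, xor_sub):
        res = system_phi(xor_sub)
        assert res.phi == pytest.approx(0.92, abs=0.005)
        assert res.phi == pytest.approx(11 / 12, abs=1e-9)

    def test_main_complex_is_whole_triad(self):
        ex = xor_loop_system()
        mc = find_main_complex(ex.network, ex.state)
        assert mc.elements == (A, B, C)
        assert mc.n_concepts == 4
        assert mc.phi == pytest.approx(0.92, abs=0.005)


class TestReducibility:
    def test_two_independent_elements_are_reducible(self):
        # X and Y in separate loops: joint mechanism XY has phi = 0
        net = build_brain([GateSpec((2,), (3,), (0, 1)),
                           GateSpec((3,), (2,), (0, 1)),
                           GateSpec((4,), (5,), (0, 1)),
                           GateSpec((5,), (4,), (0, 1))])
        sub = Subsystem(net, 0)
        assert compute_concept(sub, [2, 4]) is None

    def test_two_disconnected_pairs_jointly_have_zero_big_phi(self):
        # WXYZ made of two coupled pairs: reducible, Phi = 0
        net = build_brain([GateSpec((2,), (3,), (0, 1)),
                           GateSpec((3,), (2,), (0, 1)),
                           GateSpec((4,), (5,), (0, 1)),
                           GateSpec((5,), (4,), (0, 1))])
        sub = Subsystem(net, 0, candidate=(2, 3, 4, 5))
        assert system_phi(sub).phi == 0.0

    def test_feedforward_brains_never_form_a_complex(self, rng):
        for _ in range(30):
            brain = random_brain(rng, "feedforward", int(rng.integers(2, 8)))
            state = int(rng.integers(256)) & ~0b11
            mc = find_main_complex(brain, state)
            assert mc.elements is None and mc.phi == 0.0

    def test_self_loop_only_brains_never_form_a_complex(self, rng):
        for _ in range(30):
            brain = random_brain(rng, "self-loop-only", int(rng.integers(2, 6)))
            mc = find_main_complex(brain, int(rng.integers(256)) & ~0b11)
            assert mc.elements is None

    def test_gate_free_brain_has_no_concepts(self):
        brain = build_brain([])
        wb = whole_brain_concepts(brain, 0)
        assert wb["n_concepts"] == 0 and wb["sum_phi"] == 0.0

    def test_single_element_cannot_be_a_complex(self):
        # one hidden element with a self-loop: memory but no partitions
        net = build_brain([GateSpec((2,), (2,), (0, 1))])
        mc = find_main_complex(net, 0b100)
        assert mc.elements is None


class TestInvariants:
    def test_phi_nonnegative_and_exclusion_consistency(self, rng):
        for _ in range(10):
            net = random_small_network(rng, int(rng.integers(3, 5)))
            s = int(rng.integers(1 << net.n_hidden))
            mc = find_main_complex(net, s)
            assert mc.phi >= 0.0
            for cand, phi in mc.candidates.items():
                assert phi >= -PHI_EPS
                assert mc.phi >= phi - PHI_EPS  # reported MC is maximal

    def test_whole_brain_concept_ceiling(self, rng):
        for _ in range(5):
            brain = random_brain(rng, "recurrent", 8)
            wb = whole_brain_concepts(brain, int(rng.integers(256)) & ~0b11)
            assert wb["n_concepts"] <= 15

    def test_subsystem_rejects_small_candidate_for_system_phi(self):
        net = build_brain([GateSpec((2,), (3,), (0, 1))])
        with pytest.raises(ValueError):
            system_phi(Subsystem(net, 0, candidate=(2,)))


class TestOracleEquivalence:
    """The engine against the independent dictionary-based reference."""

    @pytest.mark.parametrize("seed", range(6))
    def test_concepts_and_complex_match_reference(self, seed):
        rng = np.random.default_rng(seed + 100)
        n = 3 if seed < 4 else 4
        net = random_small_network(rng, n)
        state = int(rng.integers(1 << n))
        sub = Subsystem(net, state)
        cs = {c.mechanism: c.phi for c in conceptual_structure(sub).concepts}
        nf = ref.node_function(net, list(range(n)), 0)
        cs_ref = ref.conceptual_structure(nf, tuple(range(n)), state,
                                          tuple(range(n)))
        assert set(cs) == set(cs_ref)
        for mech, phi in cs.items():
            assert phi == pytest.approx(cs_ref[mech][0], abs=1e-6)
        mc = find_main_complex(net, state)
        mc_ref = ref.main_complex(net, state)
        assert mc.elements == mc_ref[0]
        assert mc.phi == pytest.approx(mc_ref[1], abs=1e-6)

    def test_worked_example_phi_matches_reference(self):
        ex = xor_loop_system()
        phi_ref, cs_ref = ref.system_phi(ex.network, (0, 1, 2), ex.state)
        res = system_phi(Subsystem(ex.network, ex.state))
        assert res.phi == pytest.approx(phi_ref, abs=1e-9)


class TestStateWeighting:
    def test_weights_average_per_state_values(self, rng, task1):
        from animats.environment import evaluate
        from animats.iit import state_weighted_summary

        brain = random_brain(rng, "recurrent", 5)
        rec = evaluate(brain, task1)
        summary = state_weighted_summary(brain, record=rec)
        per_state = [whole_brain_concepts(brain, s)["n_concepts"]
                     for s in rec.state_distribution]
        assert min(per_state) - 1e-9 <= summary["n_concepts"] <= max(per_state) + 1e-9

    def test_single_state_brain_summary_equals_that_state(self, task1):
        brain = build_brain([])  # only experiences sensor-driven states
        from animats.iit import state_weighted_summary

        summary = state_weighted_summary(brain, task1)
        assert summary["n_concepts"] == 0.0
        assert summary["big_phi_max"] == 0.0


def test_shipped_example_json_matches_builder():
    import numpy as np

    from animats.examples import load_example_json

    built = xor_loop_system()
    shipped = load_example_json("xor_loop_system")
    assert np.array_equal(shipped.network.tpm, built.network.tpm)
    assert np.array_equal(shipped.network.cm, built.network.cm)
    assert shipped.state == built.state
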