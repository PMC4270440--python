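import numpy as np
import pandas as pd
import pytest

from animats.analysis import (average_correlations, behavior_fingerprint,
                              compare_conditions, compute_lod_measures,
                              count_distinct_structures,
                              fitness_matched_subset, lod_correlations,
                              window_means)
from animats.brain import BrainNetwork, build_brain
from animats.environment import TaskSpec
from animats.evolution import EvolutionConfig, run_evolution
from animats.examples import random_brain
from animats.genome import GateSpec


def fake_table(gens, F, **measures):
    df = pd.DataFrame({"generation": gens, "F": F})
    for k, v in measures.items():
        df[k] = v
    return df.set_index("generation")


@pytest.fixture(scope="module")
def measures():
    task = TaskSpec.task(1)
    cfg = EvolutionConfig(generations=40, seed=5, lod_sample_interval=20,
                          ancestral_length=1000)
    arch = run_evolution(task, cfg)
    return compute_lod_measures(arch)


class TestLodMeasures:

    def test_ancestral_row_is_baseline_with_zero_causal_measures(self, measures):
        row0 = measures.loc[0]
        assert row0["F"] == 0.4375
        for col in ("n_concepts", "sum_phi_max", "n_mc_elements",
                    "n_mc_concepts", "big_phi_max"):
            assert row0[col] == 0.0

    def test_rows_at_sample_interval(self, measures):
        assert list(measures.index) == [0, 20, 40]

    def test_measures_finite_and_nonnegative(self, measures):
        assert np.isfinite(measures.to_numpy()).all()
        assert (measures.to_numpy() >= -1e-9).all()

    def test_end_to_end_determinism(self):
        task = TaskSpec.task(1)
        cfg = EvolutionConfig(generations=20, seed=6, lod_sample_interval=10,
                              ancestral_length=1000)
        t1 = compute_lod_measures(run_evolution(task, cfg))
        t2 = compute_lod_measures(run_evolution(task, cfg))
        pd.testing.assert_frame_equal(t1, t2)


class TestCorrelations:
    def test_comonotone_gives_plus_one(self):
        t = fake_table([0, 512, 1024, 1536], [0.4, 0.5, 0.6, 0.9],
                       m=[1, 2, 3, 7])
        assert lod_correlations(t)["m"] == pytest.approx(1.0)

    def test_antimonotone_gives_minus_one(self):
        t = fake_table([0, 512, 1024, 1536], [0.4, 0.5, 0.6, 0.9],
                       m=[4, 3, 2, 1])
        assert lod_correlations(t)["m"] == pytest.approx(-1.0)

    def test_independent_measure_centered_on_zero(self):
        rng = np.random.default_rng(0)
        rs = []
        for _ in range(200):
            t = fake_table(range(0, 512 * 10, 512),
                           rng.random(10), m=rng.random(10))
            rs.append(lod_correlations(t)["m"])
        assert abs(np.mean(rs)) < 0.05

    def test_constant_column_reported_nan_and_excluded_from_average(self):
        t1 = fake_table([0, 512, 1024], [0.4, 0.5, 0.6], m=[1.0, 1.0, 1.0])
        t2 = fake_table([0, 512, 1024], [0.4, 0.5, 0.6], m=[1.0, 2.0, 3.0])
        assert np.isnan(lod_correlations(t1)["m"])
        avg = average_correlations([t1, t2])
        assert avg.loc["m", "n"] == 1
        assert avg.loc["m", "R"] == pytest.approx(1.0)

    def test_needs_three_rows(self):
        t = fake_table([0, 512], [0.4, 0.5], m=[1, 2])
        with pytest.raises(ValueError):
            lod_correlations(t)


class TestCompareConditions:
    def _tables(self, rng, offset=0.0, n=8):
        out = []
        for _ in range(n):
            gens = range(0, 512 * 12, 512)
            out.append(fake_table(gens, rng.random(12),
                                  m=rng.random(12) + offset))
        return out

    def test_window_of_3000_covers_six_samples(self):
        t = fake_table(range(0, 512 * 12, 512), np.arange(12) / 12.0,
                       m=np.arange(12))
        sel = t.loc[t.index > t.index.max() - 3000]
        assert len(sel) == 6
        assert window_means(t, 3000)["m"] == pytest.approx(np.mean(range(6, 12)))

    def test_identical_conditions_not_significant(self):
        rng = np.random.default_rng(1)
        ps = []
        for _ in range(40):
            a = self._tables(rng)
            b = self._tables(rng)
            rep = compare_conditions([a, b], measures=["m"])
            ps.append(rep.kruskal["m"][1])
        # under the null, p-values should not pile up near zero
        assert np.mean(np.array(ps) < 0.05) < 0.2

    def test_large_offset_is_significant(self):
        rng = np.random.default_rng(2)
        rep = compare_conditions([self._tables(rng), self._tables(rng, 5.0)],
                                 measures=["m"])
        assert rep.kruskal["m"][1] < 1e-3
        (u, z, p), = [rep.pairwise[(0, 1, "m")]]
        assert p < 1e-3 and abs(z) > 3

    def test_needs_two_conditions(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            compare_conditions([self._tables(rng)])


class TestFitnessMatching:
    def test_reference_equal_to_collection_returns_everything(self):
        rng = np.random.default_rng(0)
        tables = [fake_table(range(0, 512 * 12, 512), np.full(12, 0.8))
                  for _ in range(6)]
        assert fitness_matched_subset(tables, tables) == list(range(6))

    def test_exact_match_subset_found(self):
        gens = range(0, 512 * 12, 512)
        # 3 LODs at the reference mean 0.9, 7 below it
        tables = ([fake_table(gens, np.full(12, 0.9)) for _ in range(3)]
                  + [fake_table(gens, np.full(12, 0.5)) for _ in range(7)])
        ref = [fake_table(gens, np.full(12, 0.9)) for _ in range(4)]
        assert fitness_matched_subset(tables, ref) == [0, 1, 2]

    def test_brute_force_prefix_agreement(self):
        rng = np.random.default_rng(4)
        gens = range(0, 512 * 12, 512)
        fits = rng.random(10)
        tables = [fake_table(gens, np.full(12, f)) for f in fits]
        ref_val = 0.7
        ref = [fake_table(gens, np.full(12, ref_val))]
        got = fitness_matched_subset(tables, ref)
        order = np.argsort(-fits)
        best = min(range(1, 11),
                   key=lambda k: abs(fits[order[:k]].mean() - ref_val))
        assert got == sorted(int(i) for i in order[:best])


class TestDistinctStructures:
    def test_identical_brains_count_once(self, rng, task1):
        brain = random_brain(rng, "recurrent", 5)
        out = count_distinct_structures([(brain, task1)] * 4)
        assert out == {"n_TPMs": 1, "n_wirings": 1, "n_behaviors": 1}

    def test_same_wiring_different_logic(self, task1):
        g1 = [GateSpec((2, 3), (4,), (0, 1, 1, 0)),
              GateSpec((4,), (2, 3), (0, 3))]
        g2 = [GateSpec((2, 3), (4,), (1, 1, 1, 0)),  # one row differs
              GateSpec((4,), (2, 3), (0, 3))]
        out = count_distinct_structures(
            [(build_brain(g1), task1), (build_brain(g2), task1)]
        )
        assert out["n_TPMs"] == 2
        assert out["n_wirings"] == 1

    def test_wirings_never_exceed_tpms(self, rng, task1):
        animats = [(random_brain(rng, "recurrent", 4), task1)
                   for _ in range(12)]
        out = count_distinct_structures(animats)
        assert out["n_wirings"] <= out["n_TPMs"]

    def test_behavior_fingerprint_deterministic(self, rng, task1):
        brain = random_brain(rng, "recurrent", 5)
        assert behavior_fingerprint(brain, task1) == \
            behavior_fingerprint(brain, task1)
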