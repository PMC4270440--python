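import numpy as np
import pytest

from animats.genome import (GENE_LENGTH, Genome, GenomeError, MutationConfig,
                            START_CODON, ancestral_genome, decode_genome,
                            mutate)


def straight_line_decode(loci):
    """Independent oracle: decode one gene per codon by direct rule
    application, without the library's helper structure."""
    in_map = [0, 1, 2, 3, 4, 5]
    out_map = [2, 3, 4, 5, 6, 7]
    L = len(loci)
    gates = []
    for i in range(L):
        if loci[i] == 42 and loci[(i + 1) % L] == 213:
            gene = [loci[(i + k) % L] for k in range(GENE_LENGTH)]
            n_in = 1 + gene[2] % 4
            n_out = 1 + gene[3] % 4
            ins = sorted(in_map[a % 6] for a in gene[4:4 + n_in])
            outs = sorted(out_map[a % 6] for a in gene[8:8 + n_out])
            table = [gene[12 + r] % (1 << n_out) for r in range(1 << n_in)]
            gates.append((tuple(ins), tuple(outs), tuple(table)))
    return gates


class TestGenomeInvariants:
    def test_locus_range_enforced(self):
        with pytest.raises(GenomeError):
            Genome([300] * 1000)
        with pytest.raises(GenomeError):
            Genome([-1] * 1000)

    def test_length_bounds_enforced(self):
        with pytest.raises(GenomeError):
            Genome([0] * 999)
        with pytest.raises(GenomeError):
            Genome([0] * 20001)

    def test_serialization_roundtrip(self, rng):
        g = Genome(rng.integers(0, 256, 1200))
        assert Genome.from_json(g.to_json()) == g
        assert Genome.from_line(g.to_line()) == g


class TestDecode:
    def test_all_zero_genome_has_no_gates(self):
        assert decode_genome(ancestral_genome(1000)) == []

    def test_single_gene_decodes_per_rules(self):
        loci = np.zeros(1000, dtype=int)
        gene = [42, 213, 6, 9, 17, 3, 250, 8, 11, 4, 0, 200] + list(range(100, 116))
        loci[100:100 + GENE_LENGTH] = gene
        gates = decode_genome(Genome(loci))
        assert len(gates) == 1
        gate = gates[0]
        assert gate.n_inputs == 1 + 6 % 4 == 3
        assert gate.n_outputs == 1 + 9 % 4 == 2
        (ins, outs, table), = straight_line_decode(list(loci))
        assert gate.input_ids == ins
        assert gate.output_ids == outs
        assert gate.table == table

    def test_overlapping_codons_yield_two_gates(self):
        loci = np.zeros(1000, dtype=int)
        loci[10:14] = [42, 213, 42, 213]
        assert len(decode_genome(Genome(loci))) == 2

    def test_codon_wrapping_origin_is_read(self):
        loci = np.zeros(1000, dtype=int)
        loci[-1], loci[0] = START_CODON
        assert len(decode_genome(Genome(loci))) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_straight_line_oracle_on_random_genomes(self, seed):
        rng = np.random.default_rng(seed)
        loci = rng.integers(0, 256, 3000)
        gates = decode_genome(Genome(loci))
        expected = straight_line_decode(list(loci))
        assert [(g.input_ids, g.output_ids, g.table) for g in gates] == expected

    def test_label_stability_under_noncoding_prefix(self, rng):
        # inserting non-codon loci before the first codon leaves the
        # decoded gate set size unchanged
        loci = list(rng.integers(0, 212, 1500))  # no 213 anywhere: no codon
        loci[700:702] = START_CODON
        base = len(decode_genome(Genome(loci)))
        padded = [7, 9, 11] + loci
        assert len(decode_genome(Genome(padded))) == base


class TestMutate:
    def test_zero_rates_identity(self, rng):
        g = Genome(rng.integers(0, 256, 2000))
        cfg = MutationConfig(point_rate=0, deletion_prob=0, duplication_prob=0)
        assert mutate(g, cfg, rng) == g

    def test_point_rate_one_leaves_one_in_256_unchanged(self):
        rng = np.random.default_rng(0)
        g = Genome(np.zeros(20000, dtype=int))
        cfg = MutationConfig(point_rate=1.0, deletion_prob=0, duplication_prob=0)
        out = mutate(g, cfg, rng)
        frac_same = float(np.mean(out.loci == g.loci))
        # binomial(20000, 1/256): 3 sigma is about 0.0015
        assert abs(frac_same - 1 / 256) < 3 * np.sqrt((1 / 256) * (255 / 256) / 20000)

    def test_deletion_suppressed_at_minimum_length(self):
        rng = np.random.default_rng(0)
        g = ancestral_genome(1000)
        cfg = MutationConfig(point_rate=0, deletion_prob=1.0, duplication_prob=0)
        assert len(mutate(g, cfg, rng)) == 1000

    def test_duplication_suppressed_at_maximum_length(self):
        rng = np.random.default_rng(0)
        g = ancestral_genome(20000)
        cfg = MutationConfig(point_rate=0, deletion_prob=0, duplication_prob=1.0)
        assert len(mutate(g, cfg, rng)) == 20000

    def test_fragment_lengths_within_range(self):
        rng = np.random.default_rng(7)
        g = ancestral_genome(5000)
        cfg = MutationConfig(point_rate=0, deletion_prob=1.0, duplication_prob=0)
        for _ in range(50):
            out = mutate(g, cfg, rng)
            assert 16 <= 5000 - len(out) <= 512

    def test_bounds_always_hold_under_heavy_mutation(self):
        rng = np.random.default_rng(3)
        g = ancestral_genome(1200)
        cfg = MutationConfig()
        for _ in range(300):
            g = mutate(g, cfg, rng)
            assert 1000 <= len(g) <= 20000
            assert g.loci.max() <= 255

    def test_invalid_config_rejected(self):
        with pytest.raises(GenomeError):
            MutationConfig(point_rate=1.5)

    def test_duplication_grows_expected_gate_count(self):
        # duplication copies coding material: decoding after duplication
        # never decreases the expected gate count (statistically)
        rng = np.random.default_rng(11)
        base = np.zeros(2000, dtype=int)
        for pos in (100, 600, 1100):
            base[pos:pos + 2] = START_CODON
        g = Genome(base)
        cfg_dup = MutationConfig(point_rate=0, deletion_prob=0, duplication_prob=1.0)
        cfg_del = MutationConfig(point_rate=0, deletion_prob=1.0, duplication_prob=0)
        n0 = len(decode_genome(g))
        dups = [len(decode_genome(mutate(g, cfg_dup, rng))) for _ in range(200)]
        dels = [len(decode_genome(mutate(g, cfg_del, rng))) for _ in range(200)]
        assert np.mean(dups) >= n0
        assert np.mean(dels) <= n0


class TestAncestral:
    def test_no_gates_and_empty_connectivity(self):
        from animats.brain import build_brain

        g = ancestral_genome(5000)
        gates = decode_genome(g)
        assert gates == []
        brain = build_brain(gates)
        assert not brain.cm.any()
        assert (brain.tpm == 0).all()

    def test_length_out_of_bounds_rejected(self):
        with pytest.raises(GenomeError):
            ancestral_genome(999)


def test_decode_after_mutation_is_always_structurally_valid():
    # fuzz: every decoded gate satisfies the GateSpec invariants
    rng = np.random.default_rng(42)
    cfg = MutationConfig(point_rate=0.02)
    g = ancestral_genome(1500)
    for _ in range(200):
        g = mutate(g, cfg, rng)
        for gate in decode_genome(g):  # GateSpec validates in __post_init__
            assert 1 <= gate.n_inputs <= 4
            assert 1 <= gate.n_outputs <= 4
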