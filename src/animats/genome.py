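"""Genome encoding of animat brains.

An animat genome is a circular sequence of integer loci in [0, 255].  Each
occurrence of the start codon (42, 213) marks the beginning of a gene that
encodes one hidden Markov gate (HMG): a deterministic logic gate with 1-4
inputs (read from sensors or hidden elements) and 1-4 outputs (written to
hidden elements or motors).

Gene layout (28 loci per gene)::

    [42, 213] [n_in] [n_out] [4 input-address loci] [4 output-address loci]
              [16 table loci]

* ``n_in = 1 + (locus mod 4)``, likewise ``n_out``.
* The first ``n_in`` of the 4 input-address loci select input elements via
  ``locus mod 6`` over the 6 legal inputs (2 sensors + 4 hidden); the first
  ``n_out`` of the 4 output-address loci select outputs via ``locus mod 6``
  over the 6 legal outputs (4 hidden + 2 motors).
* All 16 table loci are always reserved (the 2**4 = 16 possible rows); only
  the first ``2**n_in`` rows are active, and each row's output pattern is
  ``locus mod 2**n_out``.  Reserving the full table makes the encoding
  robust: a mutation of ``n_in``/``n_out`` only adds or removes the
  corresponding part of the logic table and leaves the rest intact.

Input bit order for table rows is ascending element index (bit 0 = lowest
input element index); output pattern bits map to output elements the same
way.  Duplicate addresses are kept, so the effective fan-in/out may shrink.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

START_CODON = (42, 213)
GENE_LENGTH = 28  # codon(2) + counts(2) + addresses(8) + table(16)

MIN_GENOME_LENGTH = 1_000
MAX_GENOME_LENGTH = 20_000

# Element index layout of the 8-element brain.
N_SENSORS = 2
N_HIDDEN = 4
N_MOTORS = 2
N_ELEMENTS = N_SENSORS + N_HIDDEN + N_MOTORS
SENSOR_IDS = tuple(range(N_SENSORS))  # 0, 1
HIDDEN_IDS = tuple(range(N_SENSORS, N_SENSORS + N_HIDDEN))  # 2..5
MOTOR_IDS = tuple(range(N_SENSORS + N_HIDDEN, N_ELEMENTS))  # 6, 7

#: legal gate input elements, in the order addressed by ``locus mod 6``
INPUT_MAP = SENSOR_IDS + HIDDEN_IDS
#: legal gate output elements, in the order addressed by ``locus mod 6``
OUTPUT_MAP = HIDDEN_IDS + MOTOR_IDS


class GenomeError(ValueError):
    """Raised for structurally invalid genomes or mutation configs."""


@dataclass(frozen=True)
class GateSpec:
    """A decoded hidden Markov gate.

    ``input_ids`` and ``output_ids`` are stored sorted ascending (possibly
    with duplicates); ``table[r]`` is the output bit pattern (an integer in
    ``[0, 2**n_outputs)``) for input row ``r``, where bit ``k`` of ``r`` is
    the state of ``input_ids[k]`` and bit ``k`` of the pattern drives
    ``output_ids[k]``.
    """

    input_ids: tuple[int, ...]
    output_ids: tuple[int, ...]
    table: tuple[int, ...]

    @property
    def n_inputs(self) -> int:
        return len(self.input_ids)

    @property
    def n_outputs(self) -> int:
        return len(self.output_ids)

    def __post_init__(self) -> None:
        if not 1 <= self.n_inputs <= 4 or not 1 <= self.n_outputs <= 4:
            raise GenomeError("gates have 1-4 inputs and 1-4 outputs")
        if any(i not in INPUT_MAP for i in self.input_ids):
            raise GenomeError(f"illegal gate input elements: {self.input_ids}")
        if any(o not in OUTPUT_MAP for o in self.output_ids):
            raise GenomeError(f"illegal gate output elements: {self.output_ids}")
        if len(self.table) != 2 ** self.n_inputs:
            raise GenomeError("logic table must have one row per input pattern")
        if any(not 0 <= row < 2 ** self.n_outputs for row in self.table):
            raise GenomeError("table rows must be output bit patterns")


@dataclass
class MutationConfig:
    """Per-generation mutation rates.

    Defaults are the standard Markov-brain settings: 0.5% point mutations
    per locus, 2% chance of deleting and 5% chance of duplicating a fragment
    of 16-512 adjacent loci, with the genome length clamped to
    [1,000, 20,000] (length-violating deletions/duplications are suppressed).
    """

    point_rate: float = 0.005
    deletion_prob: float = 0.02
    duplication_prob: float = 0.05
    fragment_len_range: tuple[int, int] = (16, 512)
    genome_len_range: tuple[int, int] = (MIN_GENOME_LENGTH, MAX_GENOME_LENGTH)

    def __post_init__(self) -> None:
        for p in (self.point_rate, self.deletion_prob, self.duplication_prob):
            if not 0.0 <= p <= 1.0:
                raise GenomeError(f"mutation probability {p} outside [0, 1]")
        lo, hi = self.fragment_len_range
        if not (1 <= lo <= hi):
            raise GenomeError("invalid fragment length range")
        if hi > self.genome_len_range[1]:
            raise GenomeError("fragment range exceeds genome bounds")


@dataclass
class Genome:
    """An integer-locus genome; loci are a 1-D uint8-valued array."""

    loci: np.ndarray

    def __init__(self, loci: Iterable[int] | np.ndarray):
        arr = np.asarray(loci, dtype=np.int64)
        if arr.ndim != 1:
            raise GenomeError("loci must be a flat sequence")
        if arr.size and (arr.min() < 0 or arr.max() > 255):
            raise GenomeError("every locus must be in [0, 255]")
        if not MIN_GENOME_LENGTH <= arr.size <= MAX_GENOME_LENGTH:
            raise GenomeError(
                f"genome length {arr.size} outside "
                f"[{MIN_GENOME_LENGTH}, {MAX_GENOME_LENGTH}]"
            )
        object.__setattr__(self, "loci", arr.astype(np.uint8))

    def __len__(self) -> int:
        return int(self.loci.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genome):
            return NotImplemented
        return self.loci.shape == other.loci.shape and bool(
            np.all(self.loci == other.loci)
        )

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps([int(x) for x in self.loci])

    @classmethod
    def from_json(cls, text: str) -> "Genome":
        return cls(json.loads(text))

    def to_line(self) -> str:
        """One-genome-per-line text format: comma-separated loci."""
        return ",".join(str(int(x)) for x in self.loci)

    @classmethod
    def from_line(cls, line: str) -> "Genome":
        return cls([int(tok) for tok in line.strip().split(",")])


def _decode_gene(loci: np.ndarray, start: int) -> GateSpec:
    """Decode the gene whose start codon begins at circular position ``start``."""
    L = loci.size
    idx = (start + np.arange(GENE_LENGTH)) % L
    gene = loci[idx].astype(int)
    n_in = 1 + gene[2] % 4
    n_out = 1 + gene[3] % 4
    in_addr = gene[4 : 4 + 4]
    out_addr = gene[8 : 8 + 4]
    inputs = sorted(INPUT_MAP[a % 6] for a in in_addr[:n_in])
    outputs = sorted(OUTPUT_MAP[a % 6] for a in out_addr[:n_out])
    table_loci = gene[12 : 12 + 16]
    table = tuple(int(t) % (1 << n_out) for t in table_loci[: 1 << n_in])
    return GateSpec(tuple(inputs), tuple(outputs), table)


def decode_genome(genome: Genome) -> list[GateSpec]:
    """Decode every gene in the (circular) genome into a :class:`GateSpec`.

    One gate is produced per start-codon occurrence; overlapping codons each
    count.  Decoding is a pure function of the loci.
    """
    loci = genome.loci
    nxt = np.roll(loci, -1)
    starts = np.flatnonzero((loci == START_CODON[0]) & (nxt == START_CODON[1]))
    return [_decode_gene(loci, int(s)) for s in starts]


def ancestral_genome(length: int = 5_000, rng: np.random.Generator | None = None) -> Genome:
    """All-zero genome of the given length: encodes no gate at all.

    The resulting brain has no connections between elements (generation
    zero is not jump-started).  ``rng`` is accepted for interface symmetry
    but unused, since the ancestral genome is deterministic.
    """
    if not MIN_GENOME_LENGTH <= length <= MAX_GENOME_LENGTH:
        raise GenomeError(f"ancestral genome length {length} out of bounds")
    return Genome(np.zeros(length, dtype=np.uint8))


def mutate(genome: Genome, config: MutationConfig, rng: np.random.Generator) -> Genome:
    """Apply point mutations, then deletion, then duplication.

    Point mutations replace each locus independently with probability
    ``point_rate`` by a uniform random integer in [0, 255].  With
    ``deletion_prob`` a fragment of uniform length in ``fragment_len_range``
    is deleted; with ``duplication_prob`` such a fragment is copied and
    inserted at a random position.  Any deletion/duplication that would push
    the genome outside ``genome_len_range`` is suppressed.
    """
    lo_frag, hi_frag = config.fragment_len_range
    min_len, max_len = config.genome_len_range
    loci = genome.loci.copy()

    if config.point_rate > 0:
        # per-locus independent mutation, sampled as count + positions
        n = rng.binomial(loci.size, config.point_rate)
        if n:
            where = rng.choice(loci.size, size=n, replace=False)
            loci[where] = rng.integers(0, 256, size=n, dtype=np.uint8)

    if config.deletion_prob > 0 and rng.random() < config.deletion_prob:
        frag = int(rng.integers(lo_frag, hi_frag + 1))
        if loci.size - frag >= min_len:
            start = int(rng.integers(0, loci.size - frag + 1))
            loci = np.delete(loci, np.s_[start : start + frag])

    if config.duplication_prob > 0 and rng.random() < config.duplication_prob:
        frag = int(rng.integers(lo_frag, hi_frag + 1))
        if loci.size + frag <= max_len and frag <= loci.size:
            start = int(rng.integers(0, loci.size - frag + 1))
            piece = loci[start : start + frag]
            at = int(rng.integers(0, loci.size + 1))
            loci = np.insert(loci, at, piece)

    # mutation preserves the locus range and the length bounds by
    # construction, so skip revalidation on this hot path
    out = object.__new__(Genome)
    object.__setattr__(out, "loci", loci)
    return out


def save_genomes(genomes: Sequence[Genome], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genomes:
            fh.write(g.to_line() + "\n")


def load_genomes(path: str) -> list[Genome]:
    with open(path, encoding="utf-8") as fh:
        return [Genome.from_line(line) for line in fh if line.strip()]
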