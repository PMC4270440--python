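"""Genetic algorithm with roulette-wheel selection and line-of-descent tracing.

A population of 100 genomes evolves by fitness-proportional selection with
the exponential score ``S = 1.02**(128*F)`` (every correct trial multiplies
the score by 1.02), followed by per-offspring mutation.  Reproduction is
asexual, so every final-generation animat has a unique line of descent
(LOD) back to generation 0; LODs of different picks coalesce quickly.

The per-generation inner loop (genome decoding, TPM assembly, and the 128
trials for each of the 100 candidates) is compiled with numba; a pure
numpy/python reference path (``use_numba=False``) computes bit-identical
fitness and is cross-checked in the test suite.

Randomness is split into named substreams per generation (selection vs
mutation), so archives are exactly reproducible from the seed and mutation
draws do not depend on the order of selection draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import genome as genome_mod
from .brain import build_brain
from .environment import (N_TRIALS, TaskSpec, _run_trials,
                          enumerate_trials)
from .genome import (Genome, MutationConfig, ancestral_genome, decode_genome,
                     mutate)

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap if not (a and callable(a[0])) else a[0]


@dataclass
class EvolutionConfig:
    population_size: int = 100
    generations: int = 1000
    selection_base: float = 1.02
    mutation: MutationConfig = field(default_factory=MutationConfig)
    lod_sample_interval: int = 512
    ancestral_length: int = 5_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population size must be >= 2")
        if self.selection_base <= 1.0:
            raise ValueError("selection base must exceed 1")


@dataclass(frozen=True)
class LODRecord:
    generation: int
    genome: Genome
    fitness: float


# ---------------------------------------------------------------------------
# fast population evaluation
# ---------------------------------------------------------------------------

_IN_MAP = np.array(genome_mod.INPUT_MAP, dtype=np.int64)
_OUT_MAP = np.array(genome_mod.OUTPUT_MAP, dtype=np.int64)


@njit(cache=True)
def _decode_build_kernel(loci_flat, offsets, in_map, out_map,
                         n_brains):  # pragma: no cover - numba
    """Scan genomes for start codons, decode genes, and OR-combine the
    gates into deterministic TPMs — one pass, semantics identical to
    decode_genome + build_brain (verified against them in the tests)."""
    tpms = np.zeros((n_brains, 256), dtype=np.int64)
    ins = np.empty(4, np.int64)
    outs = np.empty(4, np.int64)
    for b in range(n_brains):
        lo, hi = offsets[b], offsets[b + 1]
        L = hi - lo
        for i in range(L):
            if loci_flat[lo + i] != 42:
                continue
            if loci_flat[lo + (i + 1) % L] != 213:
                continue
            n_in = 1 + loci_flat[lo + (i + 2) % L] % 4
            n_out = 1 + loci_flat[lo + (i + 3) % L] % 4
            for k in range(n_in):
                ins[k] = in_map[loci_flat[lo + (i + 4 + k) % L] % 6]
            ins[:n_in].sort()
            for k in range(n_out):
                outs[k] = out_map[loci_flat[lo + (i + 8 + k) % L] % 6]
            outs[:n_out].sort()
            out_mask = (1 << n_out) - 1
            for s in range(256):
                r = 0
                for k in range(n_in):
                    r |= ((s >> ins[k]) & 1) << k
                pat = loci_flat[lo + (i + 12 + r) % L] & out_mask
                for k in range(n_out):
                    if (pat >> k) & 1:
                        tpms[b, s] |= 1 << outs[k]
    return tpms


@njit(cache=True)
def _fitness_kernel(tpms, sizes, dirs, starts, is_catch, dis_sensor,
                    dis_motor, noise, reps, seed):  # pragma: no cover - numba
    P = tpms.shape[0]
    T = sizes.size
    F = np.zeros(P)
    if noise > 0:
        np.random.seed(seed)
    for p in range(P):
        ncorr = 0.0
        for _ in range(reps):
            for tr in range(T):
                a = 0
                block = starts[tr]
                state = 0
                for _t in range(36):
                    s1 = 1 if ((a - block) % 16) < sizes[tr] else 0
                    s2 = 1 if ((a + 2 - block) % 16) < sizes[tr] else 0
                    if noise > 0:
                        if np.random.random() < noise:
                            s1 = 1 - s1
                        if np.random.random() < noise:
                            s2 = 1 - s2
                    if dis_sensor == 0:
                        s1 = 0
                    elif dis_sensor == 1:
                        s2 = 0
                    x = state | s1 | (s2 << 1)
                    nxt = tpms[p, x]
                    if dis_motor == 0:
                        nxt &= ~(1 << 6)
                    elif dis_motor == 1:
                        nxt &= ~(1 << 7)
                    m1 = (nxt >> 6) & 1
                    m2 = (nxt >> 7) & 1
                    a = (a + m2 - m1) % 16
                    state = nxt
                    block = (block + dirs[tr]) % 16
                caught = False
                for off in range(3):
                    if ((a + off - block) % 16) < sizes[tr]:
                        caught = True
                ok = caught if is_catch[tr] else not caught
                if ok:
                    ncorr += 1.0
        F[p] = ncorr / (T * reps)
    return F


def population_tpms(population: Sequence[Genome], use_numba: bool = True) -> np.ndarray:
    """Deterministic 256-row TPMs for every genome in the population."""
    P = len(population)
    if use_numba and HAVE_NUMBA:
        lengths = np.array([g.loci.size for g in population], dtype=np.int64)
        offsets = np.concatenate([[0], np.cumsum(lengths)])
        flat = np.concatenate([g.loci for g in population]).astype(np.int64)
        return _decode_build_kernel(flat, offsets, _IN_MAP, _OUT_MAP, P)
    tpms = np.zeros((P, 256), dtype=np.int64)
    for i, g in enumerate(population):
        tpms[i] = build_brain(decode_genome(g)).tpm
    return tpms


def _trial_arrays(task: TaskSpec):
    trials = enumerate_trials(task)
    sizes = np.array([t.block_size for t in trials], dtype=np.int64)
    dirs = np.array([t.direction for t in trials], dtype=np.int64)
    starts = np.array([t.start_column for t in trials], dtype=np.int64)
    is_catch = np.array([task.is_catch(t.block_size) for t in trials])
    return sizes, dirs, starts, is_catch


def population_fitness(tpms: np.ndarray, task: TaskSpec, noise_seed: int = 0,
                       use_numba: bool = True) -> np.ndarray:
    """Fitness of every TPM on the task's 128 trials (x noise repetitions)."""
    reps = task.noise_repetitions if task.sensor_noise > 0 else 1
    if use_numba and HAVE_NUMBA:
        sizes, dirs, starts, is_catch = _trial_arrays(task)
        ds = -1 if task.disabled_sensor is None else task.disabled_sensor
        dm = -1 if task.disabled_motor is None else task.disabled_motor
        return _fitness_kernel(
            tpms, sizes, dirs, starts, is_catch, ds, dm,
            float(task.sensor_noise), reps, noise_seed % (2**31),
        )
    rng = np.random.default_rng(noise_seed)
    trials = enumerate_trials(task)
    F = np.zeros(tpms.shape[0])
    for i in range(tpms.shape[0]):
        fracs = []
        for _ in range(reps):
            correct, _, _, _, _ = _run_trials(tpms[i], trials, task, rng,
                                              record_states=False)
            fracs.append(correct.mean())
        F[i] = float(np.mean(fracs))
    return F


# ---------------------------------------------------------------------------
# the genetic algorithm
# ---------------------------------------------------------------------------

def selection_probabilities(fitness: np.ndarray, base: float = 1.02) -> np.ndarray:
    """Roulette-wheel weights proportional to S = base**(F*128)."""
    S = np.power(base, np.asarray(fitness) * N_TRIALS)
    return S / S.sum()


def step_generation(population: list[Genome], fitness: np.ndarray,
                    config: EvolutionConfig, sel_rng: np.random.Generator,
                    mut_rng: np.random.Generator):
    """One generation: select 100 parents with replacement, mutate offspring.

    Returns (offspring, parent_indices).
    """
    P = config.population_size
    probs = selection_probabilities(fitness, config.selection_base)
    parents = sel_rng.choice(len(population), size=P, replace=True, p=probs)
    offspring = [mutate(population[i], config.mutation, mut_rng)
                 for i in parents]
    return offspring, parents.astype(np.int32)


@dataclass
class Archive:
    """Everything needed to trace and re-analyze an evolutionary run."""

    task: TaskSpec
    config: EvolutionConfig
    fitness: np.ndarray  # (generations+1, population)
    parents: np.ndarray  # (generations, population)
    snapshots: dict[int, list[Genome]]

    @property
    def generations(self) -> int:
        return self.parents.shape[0]

    # -- JSON-lines serialization (one generation per line) --------------
    def save(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            header = {
                "task": {"catch_sizes": list(self.task.catch_sizes),
                         "avoid_sizes": list(self.task.avoid_sizes),
                         "disabled_sensor": self.task.disabled_sensor,
                         "disabled_motor": self.task.disabled_motor,
                         "sensor_noise": self.task.sensor_noise,
                         "noise_repetitions": self.task.noise_repetitions},
                "population_size": self.config.population_size,
                "generations": self.config.generations,
                "lod_sample_interval": self.config.lod_sample_interval,
                "seed": self.config.seed,
            }
            fh.write(json.dumps(header) + "\n")
            for g in range(self.generations + 1):
                line = {"generation": g,
                        "fitness": [round(float(f), 10) for f in self.fitness[g]]}
                if g > 0:
                    line["parents"] = [int(i) for i in self.parents[g - 1]]
                if g in self.snapshots:
                    line["genomes"] = [[int(x) for x in gen.loci]
                                       for gen in self.snapshots[g]]
                fh.write(json.dumps(line) + "\n")

    @classmethod
    def load(cls, path: str) -> "Archive":
        with open(path, encoding="utf-8") as fh:
            header = json.loads(fh.readline())
            t = header["task"]
            task = TaskSpec(
                catch_sizes=tuple(t["catch_sizes"]),
                avoid_sizes=tuple(t["avoid_sizes"]),
                disabled_sensor=t["disabled_sensor"],
                disabled_motor=t["disabled_motor"],
                sensor_noise=t["sensor_noise"],
                noise_repetitions=t["noise_repetitions"],
            )
            config = EvolutionConfig(
                population_size=header["population_size"],
                generations=header["generations"],
                lod_sample_interval=header["lod_sample_interval"],
                seed=header["seed"],
            )
            fitness, parents, snapshots = [], [], {}
            for line in fh:
                d = json.loads(line)
                fitness.append(d["fitness"])
                if "parents" in d:
                    parents.append(d["parents"])
                if "genomes" in d:
                    snapshots[d["generation"]] = [Genome(g) for g in d["genomes"]]
        return cls(task, config, np.array(fitness), np.array(parents, np.int32),
                   snapshots)


def run_evolution(task: TaskSpec, config: EvolutionConfig,
                  use_numba: bool = True, progress=None) -> Archive:
    """Evolve a population from unconnected ancestors; archive the run.

    Population genomes are snapshotted at every LOD sample interval (and at
    the final generation), which together with the full parent chain is
    sufficient to trace any final animat back to generation 0.
    """
    P = config.population_size
    seed = int(config.seed)
    population = [ancestral_genome(config.ancestral_length) for _ in range(P)]
    snapshots: dict[int, list[Genome]] = {}
    fitness = np.zeros((config.generations + 1, P))
    parents = np.zeros((config.generations, P), dtype=np.int32)

    tpms = population_tpms(population, use_numba)
    fitness[0] = population_fitness(tpms, task, seed, use_numba)
    snapshots[0] = list(population)
    for g in range(1, config.generations + 1):
        sel_rng = np.random.default_rng([seed, g, 0])
        mut_rng = np.random.default_rng([seed, g, 1])
        population, parents[g - 1] = step_generation(
            population, fitness[g - 1], config, sel_rng, mut_rng
        )
        tpms = population_tpms(population, use_numba)
        noise_seed = abs(hash((seed, g, 2))) % (2**31)
        fitness[g] = population_fitness(tpms, task, noise_seed, use_numba)
        if g % config.lod_sample_interval == 0 or g == config.generations:
            snapshots[g] = list(population)
        if progress is not None and g % max(1, config.generations // 20) == 0:
            progress(g, float(fitness[g].mean()), float(fitness[g].max()))
    return Archive(task, config, fitness, parents, snapshots)


def trace_lod(archive: Archive, pick: int = 0,
              interval: int | None = None) -> list[LODRecord]:
    """Line of descent of a final-generation animat, subsampled for analysis.

    Walks the parent chain from the chosen final animat back to generation
    0 and returns one record per sampled generation (multiples of the LOD
    sample interval), each carrying the archived genome and fitness.
    """
    interval = interval or archive.config.lod_sample_interval
    G = archive.generations
    idx = int(pick)
    lineage = {G: idx}
    for g in range(G, 0, -1):
        idx = int(archive.parents[g - 1, idx])
        lineage[g - 1] = idx
    records = []
    for g in range(0, G + 1, interval):
        if g not in archive.snapshots:
            raise ValueError(f"generation {g} not snapshotted in archive")
        i = lineage[g]
        records.append(LODRecord(g, archive.snapshots[g][i],
                                 float(archive.fitness[g, i])))
    return records
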