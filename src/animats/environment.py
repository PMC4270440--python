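"""The Active Categorical Perception world: falling blocks to catch or avoid.

The world is 16 columns wide with periodic boundaries.  The animat sits on
the bottom row, 3 units wide, with sensors on its outer units (the middle
unit is a blind spot).  Per trial one block of a task-specific width starts
36 rows up in one of 16 columns and moves one unit down and one unit
sideways (left or right) per time step.  Each step the animat senses the
block (a sensor is on iff a block unit is directly above it), updates its
brain, and moves according to its motor state (M1M2 = 01 moves right, 10
moves left, 00 and 11 stand still).  After 36 steps the block reaches the
bottom row; if it overlaps any of the animat's three units it is caught,
otherwise avoided.  Fitness is the fraction of the 128 test trials (16
starts x 2 directions x 4 block-size slots) handled correctly: catch-type
blocks caught and avoid-type blocks avoided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .brain import BrainNetwork

WORLD_WIDTH = 16
FALL_STEPS = 36
N_TRIALS = 128

#: block sizes (catch, avoid) per task number
TASK_SIZES = {
    1: ((1,), (3,)),
    2: ((1,), (2,)),
    3: ((1, 4), (2, 3)),
    4: ((3, 6), (4, 5)),
}


class EnvironmentError_(ValueError):
    pass


@dataclass(frozen=True)
class TaskSpec:
    """One task condition: block categories plus sensor/motor variants."""

    catch_sizes: tuple[int, ...]
    avoid_sizes: tuple[int, ...]
    world_width: int = WORLD_WIDTH
    fall_steps: int = FALL_STEPS
    disabled_sensor: int | None = None
    disabled_motor: int | None = None
    sensor_noise: float = 0.0
    noise_repetitions: int = 1

    def __post_init__(self) -> None:
        if not self.catch_sizes or not self.avoid_sizes:
            raise EnvironmentError_("need at least one catch and one avoid size")
        if any(s <= 0 for s in self.catch_sizes + self.avoid_sizes):
            raise EnvironmentError_("block sizes must be positive")
        if not 0.0 <= self.sensor_noise <= 1.0:
            raise EnvironmentError_("sensor noise must be a probability")
        if self.noise_repetitions < 1:
            raise EnvironmentError_("noise_repetitions must be >= 1")

    @classmethod
    def task(cls, number: int, **overrides) -> "TaskSpec":
        """The standard Tasks 1-4 (e.g. Task 1: catch size 1, avoid size 3)."""
        try:
            catch, avoid = TASK_SIZES[number]
        except KeyError:
            raise EnvironmentError_(f"unknown task {number}") from None
        return cls(catch_sizes=catch, avoid_sizes=avoid, **overrides)

    @property
    def size_slots(self) -> tuple[int, ...]:
        """The four block-size slots of an evaluation.

        Two-size tasks show each size twice; four-size tasks each once.
        """
        sizes = tuple(sorted(self.catch_sizes + self.avoid_sizes))
        if len(sizes) == 2:
            return (sizes[0], sizes[0], sizes[1], sizes[1])
        if len(sizes) == 4:
            return sizes
        raise EnvironmentError_("tasks use exactly 2 or 4 block sizes")

    def is_catch(self, size: int) -> bool:
        return size in self.catch_sizes


@dataclass(frozen=True)
class Trial:
    block_size: int
    direction: int  # +1 right, -1 left
    start_column: int

    def __post_init__(self) -> None:
        if self.direction not in (-1, 1):
            raise EnvironmentError_("direction must be +1 or -1")
        if not 0 <= self.start_column < WORLD_WIDTH:
            raise EnvironmentError_("start column out of range")


@dataclass(frozen=True)
class TrialResult:
    trial: Trial
    caught: bool
    correct: bool
    trajectory: tuple[int, ...]  # 36 brain states (one per update)
    final_animat_column: int
    final_block_column: int


@dataclass(frozen=True)
class FitnessRecord:
    """Fitness plus the distribution of experienced brain states."""

    F: float
    n_correct: float
    state_distribution: dict[int, float] = field(repr=False)

    def __post_init__(self) -> None:
        total = sum(self.state_distribution.values())
        if self.state_distribution and abs(total - 1.0) > 1e-9:
            raise EnvironmentError_("state distribution must sum to 1")


def enumerate_trials(task: TaskSpec) -> list[Trial]:
    """All 128 trials: 4 size slots x 2 directions x 16 start columns."""
    return [
        Trial(size, direction, start)
        for size in task.size_slots
        for direction in (1, -1)
        for start in range(WORLD_WIDTH)
    ]


# ---------------------------------------------------------------------------
# vectorized trial engine
# ---------------------------------------------------------------------------

def _run_trials(tpm: np.ndarray, trials: Sequence[Trial], task: TaskSpec,
                rng: np.random.Generator | None,
                record_states: bool = True):
    """Simulate trials against one deterministic brain TPM (256 rows).

    Returns (correct, caught, states, animat_cols, block_cols) where
    ``states`` has shape (n_trials, 36): the state the brain update acted
    on at each step (new sensor reading written into the previous output
    state), which is the state sequence used for all observational
    measures.  The animat starts at column 0; start columns are relative.
    """
    trials = list(trials)
    T = len(trials)
    sizes = np.array([t.block_size for t in trials])
    dirs = np.array([t.direction for t in trials])
    block = np.array([t.start_column for t in trials]) % WORLD_WIDTH
    animat = np.zeros(T, dtype=np.int64)
    state = np.zeros(T, dtype=np.int64)
    states = np.zeros((T, FALL_STEPS), dtype=np.int64) if record_states else None
    noisy = task.sensor_noise > 0 and rng is not None
    for t in range(FALL_STEPS):
        # sensors: animat's outer units are at columns a and a+2
        s1 = ((animat - block) % WORLD_WIDTH) < sizes
        s2 = (((animat + 2) - block) % WORLD_WIDTH) < sizes
        if noisy:
            s1 = s1 ^ (rng.random(T) < task.sensor_noise)
            s2 = s2 ^ (rng.random(T) < task.sensor_noise)
        if task.disabled_sensor == 0:
            s1 = np.zeros(T, dtype=bool)
        elif task.disabled_sensor == 1:
            s2 = np.zeros(T, dtype=bool)
        x = state | s1.astype(np.int64) | (s2.astype(np.int64) << 1)
        if record_states:
            states[:, t] = x
        nxt = tpm[x]
        if task.disabled_motor == 0:
            nxt = nxt & ~(1 << 6)
        elif task.disabled_motor == 1:
            nxt = nxt & ~(1 << 7)
        m1 = (nxt >> 6) & 1
        m2 = (nxt >> 7) & 1
        animat = (animat + (m2 - m1)) % WORLD_WIDTH
        state = nxt
        block = (block + dirs) % WORLD_WIDTH
    # overlap test at step 36: any of the animat's three units on a block unit
    caught = np.zeros(T, dtype=bool)
    for off in range(3):
        caught |= (((animat + off) - block) % WORLD_WIDTH) < sizes
    is_catch = np.array([task.is_catch(t.block_size) for t in trials])
    correct = np.where(is_catch, caught, ~caught)
    return correct, caught, states, animat, block


def run_trial(brain: BrainNetwork, trial: Trial, task: TaskSpec,
              rng: np.random.Generator | None = None) -> TrialResult:
    """Run a single trial and return its full result."""
    correct, caught, states, acol, bcol = _run_trials(
        brain.tpm, [trial], task, rng
    )
    return TrialResult(
        trial=trial, caught=bool(caught[0]), correct=bool(correct[0]),
        trajectory=tuple(int(s) for s in states[0]),
        final_animat_column=int(acol[0]), final_block_column=int(bcol[0]),
    )


def evaluate(brain: BrainNetwork, task: TaskSpec,
             rng: np.random.Generator | None = None,
             return_trajectories: bool = False):
    """Fitness over all 128 trials plus the experienced-state distribution.

    With sensor noise the 128 trials are repeated ``noise_repetitions``
    times and fitness is the average fraction of correct trials; the state
    distribution is likewise averaged over repetitions.
    """
    trials = enumerate_trials(task)
    reps = task.noise_repetitions if task.sensor_noise > 0 else 1
    if task.sensor_noise > 0 and rng is None:
        rng = np.random.default_rng(0)
    all_correct = []
    counts = np.zeros(1 << brain.n_elements)
    trajs = []
    for _ in range(reps):
        correct, _, states, _, _ = _run_trials(brain.tpm, trials, task, rng)
        all_correct.append(correct)
        counts += np.bincount(states.ravel(), minlength=counts.size)
        if return_trajectories:
            trajs.append(states)
    frac = float(np.mean(all_correct))
    dist = counts / counts.sum()
    record = FitnessRecord(
        F=frac, n_correct=frac * len(trials),
        state_distribution={int(s): float(p) for s, p in enumerate(dist) if p > 0},
    )
    if return_trajectories:
        return record, np.concatenate(trajs, axis=0)
    return record


def trials_to_csv(results: Iterable[TrialResult], path: str) -> None:
    """One row per trial: size, direction, start, caught, correct."""
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["block_size", "direction", "start_column", "caught", "correct"])
        for r in results:
            w.writerow([r.trial.block_size, r.trial.direction,
                        r.trial.start_column, int(r.caught), int(r.correct)])
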