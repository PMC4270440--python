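"""Pipeline orchestration and statistics over lines of descent.

For each sampled generation of a LOD the animat's brain is rebuilt from
its genome, evaluated on the task, and summarized by the state-weighted
causal measures (number of concepts, Σφ^Max, main-complex size/concepts,
Φ^Max) plus the observational Shannon measures.  Across LODs and task
conditions the measures are compared with Spearman rank correlations
against fitness, a Kruskal-Wallis omnibus test, and pairwise Mann-Whitney
U tests on per-LOD scalars averaged over a terminal window of generations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .brain import BrainNetwork, build_brain, normal_form
from .environment import TaskSpec, enumerate_trials, evaluate
from .evolution import Archive, trace_lod
from .genome import decode_genome
from .iit import state_weighted_summary
from .infodynamics import shannon_summary

MEASURE_COLUMNS = ["F", "n_concepts", "sum_phi_max", "n_mc_elements",
                   "n_mc_concepts", "big_phi_max", "I_SMMI", "I_Pred",
                   "H_Sen", "H_Mot", "H_State"]

CAUSAL_COLUMNS = MEASURE_COLUMNS[1:6]


def brain_from_genome(genome) -> BrainNetwork:
    return build_brain(decode_genome(genome))


def compute_lod_measures(archive: Archive, task: TaskSpec | None = None,
                         interval: int | None = None, pick: int = 0,
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Causal and Shannon measures along one line of descent.

    Returns a DataFrame indexed by sampled generation with the fitness and
    all measure columns.  Measures are evaluated in the archive's task
    unless another task is given (e.g. noise-free testing of animats that
    evolved under sensor noise).
    """
    task = task or archive.task
    records = trace_lod(archive, pick=pick, interval=interval)
    rows = []
    for rec in records:
        brain = brain_from_genome(rec.genome)
        record, traj = evaluate(brain, task, rng, return_trajectories=True)
        causal = state_weighted_summary(brain, record=record)
        info = shannon_summary(traj)
        rows.append({"generation": rec.generation, "F": record.F,
                     **causal, **info.as_dict()})
    return pd.DataFrame(rows).set_index("generation")


def lod_correlations(table: pd.DataFrame) -> dict[str, float]:
    """Spearman rank correlation of each measure against fitness.

    Constant measure series have undefined rank correlation and are
    reported as NaN (and excluded from any cross-LOD averaging).
    Also returns the p-value per measure under key ``<name>_p``.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 sampled generations")
    out: dict[str, float] = {}
    F = table["F"].to_numpy()
    for col in table.columns:
        if col == "F":
            continue
        y = table[col].to_numpy()
        if np.ptp(F) == 0 or np.ptp(y) == 0:
            out[col], out[col + "_p"] = float("nan"), float("nan")
            continue
        r, p = stats.spearmanr(F, y)
        out[col], out[col + "_p"] = float(r), float(p)
    return out


def average_correlations(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Mean and SEM of per-LOD Spearman correlations (NaNs excluded)."""
    rows = [lod_correlations(t) for t in tables]
    cols = [c for c in tables[0].columns if c != "F"]
    data = {}
    for c in cols:
        vals = np.array([r[c] for r in rows])
        vals = vals[~np.isnan(vals)]
        data[c] = {"R": vals.mean() if vals.size else float("nan"),
                   "SEM": (vals.std(ddof=1) / np.sqrt(vals.size)
                           if vals.size > 1 else float("nan")),
                   "n": int(vals.size)}
    return pd.DataFrame(data).T


def window_means(table: pd.DataFrame, window: int = 3_000) -> pd.Series:
    """Per-measure mean over the final ``window`` generations of a LOD.

    With the standard 512-generation sampling, a 3,000-generation window
    covers exactly 6 data points.
    """
    gens = table.index.to_numpy()
    last = gens.max()
    sel = table.loc[gens > last - window]
    if sel.empty:
        raise ValueError("window does not cover any sampled generation")
    return sel.mean()


@dataclass
class ComparisonReport:
    measures: list[str]
    kruskal: dict[str, tuple[float, float]]  # measure -> (H, p)
    pairwise: dict[tuple[int, int, str], tuple[float, float, float]]
    # (cond_i, cond_j, measure) -> (U, Z, p)

    def to_json(self) -> dict:
        return {
            "kruskal": {m: {"H": h, "p": p} for m, (h, p) in self.kruskal.items()},
            "pairwise": [
                {"conditions": [i, j], "measure": m, "U": u, "Z": z, "p": p}
                for (i, j, m), (u, z, p) in self.pairwise.items()
            ],
        }


def _mann_whitney(x: np.ndarray, y: np.ndarray):
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    U = float(res.statistic)
    n1, n2 = len(x), len(y)
    mu = n1 * n2 / 2.0
    # normal approximation with tie correction for the Z score
    allv = np.concatenate([x, y])
    _, counts = np.unique(allv, return_counts=True)
    n = n1 + n2
    tie = ((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    sigma = np.sqrt(n1 * n2 / 12.0 * ((n + 1) - tie))
    Z = (U - mu) / sigma if sigma > 0 else 0.0
    return U, float(Z), float(res.pvalue)


def compare_conditions(condition_tables: list[list[pd.DataFrame]],
                       window: int = 3_000,
                       measures: list[str] | None = None) -> ComparisonReport:
    """Omnibus and pairwise tests across task conditions.

    ``condition_tables[c]`` holds the per-LOD measure tables of condition
    ``c``.  Each LOD is reduced to its mean over the final window; a
    Kruskal-Wallis test per measure is followed by pairwise two-sided
    Mann-Whitney U tests (no multiple-testing correction, reported as is).
    """
    if len(condition_tables) < 2:
        raise ValueError("need at least two conditions")
    measures = measures or MEASURE_COLUMNS
    scalars = [
        pd.DataFrame([window_means(t, window) for t in tables])
        for tables in condition_tables
    ]
    kruskal, pairwise = {}, {}
    for m in measures:
        groups = [s[m].to_numpy() for s in scalars]
        try:
            H, p = stats.kruskal(*groups)
        except ValueError:  # all values identical
            H, p = 0.0, 1.0
        kruskal[m] = (float(H), float(p))
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                pairwise[(i, j, m)] = _mann_whitney(groups[i], groups[j])
    return ComparisonReport(measures, kruskal, pairwise)


def fitness_matched_subset(lod_tables: list[pd.DataFrame],
                           reference_tables: list[pd.DataFrame],
                           window: int = 5_000) -> list[int]:
    """Fittest LODs whose windowed mean fitness best matches a reference.

    Ranks LODs by mean fitness over the final window and greedily grows
    the subset from the fittest down, keeping the prefix whose mean is
    closest to the reference collection's mean (so matching stops before
    the subset mean would drop below a closer match).
    """
    if not lod_tables or not reference_tables:
        raise ValueError("both collections must be non-empty")
    ref = float(np.mean([window_means(t, window)["F"] for t in reference_tables]))
    fits = np.array([window_means(t, window)["F"] for t in lod_tables])
    order = np.argsort(-fits)
    best_k, best_err = 1, np.inf
    for k in range(1, len(fits) + 1):
        err = abs(fits[order[:k]].mean() - ref)
        if err < best_err - 1e-12 or (err <= best_err + 1e-12 and k > best_k):
            best_err, best_k = err, k
    return sorted(int(i) for i in order[:best_k])


def behavior_fingerprint(brain: BrainNetwork, task: TaskSpec) -> bytes:
    """Noise-free behavioral pattern: the animat's position at every step
    of every test trial (captures what the animat does, not how)."""
    trials = enumerate_trials(task)
    sizes = np.array([t.block_size for t in trials])
    dirs = np.array([t.direction for t in trials])
    block = np.array([t.start_column for t in trials])
    T = len(trials)
    animat = np.zeros(T, dtype=np.int64)
    state = np.zeros(T, dtype=np.int64)
    pos = np.zeros((T, 36), dtype=np.int8)
    clean = TaskSpec(task.catch_sizes, task.avoid_sizes)
    tpm = brain.tpm
    for t in range(36):
        s1 = ((animat - block) % 16) < sizes
        s2 = ((animat + 2 - block) % 16) < sizes
        x = state | s1.astype(np.int64) | (s2.astype(np.int64) << 1)
        nxt = tpm[x]
        animat = (animat + ((nxt >> 7) & 1) - ((nxt >> 6) & 1)) % 16
        state = nxt
        block = (block + dirs) % 16
        pos[:, t] = animat
    return pos.tobytes()


def count_distinct_structures(animats: list[tuple[BrainNetwork, TaskSpec]]
                              ) -> dict[str, int]:
    """Distinct TPMs, wiring diagrams, and behaviors in a set of animats.

    TPM and wiring distinctness are judged on the normal form (label-
    permuted copies count once); behavior is the per-trial position trace.
    """
    if not animats:
        raise ValueError("empty animat list")
    tpms, wirings, behaviors = set(), set(), set()
    for brain, task in animats:
        nf = normal_form(brain)
        tpms.add(nf.key)
        wirings.add(nf.wiring_key)
        behaviors.add(behavior_fingerprint(brain, task))
    return {"n_TPMs": len(tpms), "n_wirings": len(wirings),
            "n_behaviors": len(behaviors)}


def plot_measures(tables, labels=None, columns=None, ax=None):
    """Simple overview plot: mean measure trajectories across LODs.

    ``tables`` is a list of per-LOD measure DataFrames (one condition).
    Returns the matplotlib figure.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    columns = columns or ["F", "n_concepts", "sum_phi_max", "big_phi_max"]
    fig, axes = plt.subplots(1, len(columns), figsize=(4 * len(columns), 3))
    stacked = pd.concat(tables).groupby(level=0)
    mean, sem = stacked.mean(), stacked.sem()
    for ax_, col in zip(np.atleast_1d(axes), columns):
        ax_.plot(mean.index, mean[col])
        if len(tables) > 1:
            ax_.fill_between(mean.index, mean[col] - sem[col],
                             mean[col] + sem[col], alpha=0.3)
        ax_.set_xlabel("generation")
        ax_.set_title(col)
    fig.tight_layout()
    return fig
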