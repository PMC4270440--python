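"""Observational Shannon measures along brain-state trajectories.

Plug-in (empirical) entropies and mutual informations over consecutive
state pairs pooled across trials, with transitions never spanning trial
boundaries:

* ``I_SMMI`` — sensory-motor mutual information: MI between the sensor
  state at t and the motor state at t+1 (behavioral differentiation);
* ``I_Pred`` — predictive information: MI between the full brain state at
  t and at t+1 (dynamical differentiation; for deterministic dynamics it
  equals the entropy of the t+1 marginal);
* ``H_Sen``, ``H_Mot``, ``H_State`` — the corresponding marginal
  entropies, which bound the two mutual informations.

All quantities are in bits.  No bias correction is applied: with 128
trials of 36 steps the sample size is large relative to the <= 256
possible states, and the measures are used comparatively along a lineage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class InfoSummary:
    I_SMMI: float
    I_Pred: float
    H_Sen: float
    H_Mot: float
    H_State: float

    def as_dict(self) -> dict[str, float]:
        return {"I_SMMI": self.I_SMMI, "I_Pred": self.I_Pred,
                "H_Sen": self.H_Sen, "H_Mot": self.H_Mot,
                "H_State": self.H_State}


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0].astype(float)
    p /= p.sum()
    return float(-(p * np.log2(p)).sum())


def _mutual_information(x: np.ndarray, y: np.ndarray, nx: int, ny: int) -> float:
    joint = np.bincount(x * ny + y, minlength=nx * ny).astype(float)
    joint = joint.reshape(nx, ny)
    return (_entropy(joint.sum(axis=1)) + _entropy(joint.sum(axis=0))
            - _entropy(joint.ravel()))


def shannon_summary(trajectories: np.ndarray,
                    n_sensors: int = 2, n_hidden: int = 4,
                    n_motors: int = 2) -> InfoSummary:
    """Empirical information measures from an array of state trajectories.

    ``trajectories`` has shape (n_trials, n_steps); entries are packed
    brain states (sensors in the low bits, motors in the high bits).
    """
    traj = np.asarray(trajectories)
    if traj.ndim != 2 or traj.size == 0:
        raise ValueError("need a non-empty (trials, steps) state array")
    n = n_sensors + n_hidden + n_motors
    x0 = traj[:, :-1].ravel()
    x1 = traj[:, 1:].ravel()
    sensors0 = x0 & ((1 << n_sensors) - 1)
    motors1 = x1 >> (n_sensors + n_hidden)
    n_states = 1 << n
    i_smmi = _mutual_information(sensors0, motors1, 1 << n_sensors, 1 << n_motors)
    i_pred = _mutual_information(x0 % n_states, x1 % n_states, n_states, n_states)
    return InfoSummary(
        I_SMMI=i_smmi,
        I_Pred=i_pred,
        H_Sen=_entropy(np.bincount(sensors0, minlength=1 << n_sensors)),
        H_Mot=_entropy(np.bincount(motors1, minlength=1 << n_motors)),
        H_State=_entropy(np.bincount(x0, minlength=n_states)),
    )
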