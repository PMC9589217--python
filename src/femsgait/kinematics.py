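"""Inverse kinematics: marker trajectories -> primary joint angles.

Each frame is solved independently (warm-started from the previous
frame) as a nonlinear least-squares fit of the linkage's model markers
to the measured markers over the 11 primary DOFs (pelvis pose, hip 3,
knee flexion, ankle).  Knee secondary kinematics are never tracked from
markers; they stay at whatever values the caller supplies (zero by
default) and are reported through to downstream stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .linkage import LinkageModel, marker_positions, marker_order


@dataclass
class JointState:
    """Primary DOFs + knee secondary kinematics at one instant."""

    q: np.ndarray                       # (11,) primary DOFs (mm / rad)
    e_s: np.ndarray = field(default_factory=lambda: np.zeros(5))  # tx,ty,tz (mm), varus, introt (rad)
    percent_stance: float = 0.0
    time: float = 0.0
    rms_residual: float = 0.0           # mm

    @property
    def hip_angles(self) -> np.ndarray:
        return self.q[6:9]

    @property
    def knee_flexion(self) -> float:
        return float(self.q[9])

    @property
    def ankle_angle(self) -> float:
        return float(self.q[10])


def _interpolate_gaps(arr: np.ndarray, max_gap: int) -> np.ndarray:
    """Linear interpolation of NaN runs up to max_gap frames long."""
    arr = arr.copy()
    for j in range(arr.shape[1]):
        col = arr[:, j]
        bad = np.isnan(col)
        if not bad.any():
            continue
        runs = np.flatnonzero(np.diff(np.concatenate(([0], bad.view(np.int8), [0]))))
        for s, e in zip(runs[::2], runs[1::2]):
            if e - s > max_gap or s == 0 or e == len(col):
                raise ValueError(f"marker gap of {e - s} frames exceeds limit {max_gap}")
        good = ~bad
        col[bad] = np.interp(np.flatnonzero(bad), np.flatnonzero(good), col[good])
    return arr


def inverse_kinematics(trial, model: LinkageModel, max_gap: int = 10,
                       q0: np.ndarray | None = None) -> list[JointState]:
    """Fit primary joint angles to every marker frame of a trial.

    Returns one :class:`JointState` per marker frame with the RMS marker
    residual; raises on over-long marker gaps or a singular frame.
    """
    names = marker_order(model)
    n = len(trial.marker_times)
    meas = np.stack([trial.markers[name] for name in names], axis=1)  # (n, nm, 3)
    meas = _interpolate_gaps(meas.reshape(n, -1), max_gap).reshape(n, -1, 3)

    duration = trial.marker_times[-1] - trial.marker_times[0]
    states: list[JointState] = []
    q_guess = np.zeros(11) if q0 is None else np.asarray(q0, dtype=float).copy()
    if q0 is None:
        # centre the initial pelvis guess on the measured pelvis markers
        q_guess[0:3] = meas[0, :4].mean(axis=0)

    for i in range(n):
        target = meas[i]

        def resid(q):
            pos = marker_positions(model, q)
            return np.concatenate([pos[name] - target[k] for k, name in enumerate(names)])

        sol = least_squares(resid, q_guess, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if not np.all(np.isfinite(sol.x)):
            raise RuntimeError(f"inverse kinematics failed at frame {i}")
        rms = float(np.sqrt(np.mean(np.sum(sol.fun.reshape(-1, 3) ** 2, axis=1))))
        t = float(trial.marker_times[i])
        states.append(JointState(
            q=sol.x.copy(),
            percent_stance=100.0 * (t - trial.marker_times[0]) / max(duration, 1e-12),
            time=t,
            rms_residual=rms,
        ))
        q_guess = sol.x.copy()
    return states
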