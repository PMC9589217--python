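"""Inverse dynamics: joint angles + ground reaction force -> joint moments.

Bottom-up Newton-Euler recursion over foot -> shank -> thigh.  Segment
kinematics are differentiated numerically (central differences) after an
optional zero-phase low-pass filter on the DOF time series; the 1000 Hz
GRF is low-pass filtered and resampled onto the 100 Hz marker time base.

Conventions: lengths mm, forces N, moments N mm, masses kg.  The
returned net joint moment is the moment exerted on the distal segment
by everything proximal (muscles + joint structures); projecting it onto
the instantaneous DOF axes gives the generalized torque conjugate to
each primary DOF, which is what the static muscle optimization must
reproduce.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

from .frames import unskew
from .kinematics import JointState
from .linkage import LinkageModel, MOMENT_DOF_NAMES, dof_axes, forward_kinematics, joint_centers

G_MMS2 = 9810.0  # mm/s^2


@dataclass
class JointLoads:
    """Net intersegmental loads at one instant (global frame)."""

    time: float
    percent_stance: float
    forces: dict                        # joint -> (3,) N, on the distal segment
    moments: dict                       # joint -> (3,) N mm, about the joint centre
    generalized: dict                   # DOF name -> N mm
    grf: np.ndarray = field(default_factory=lambda: np.zeros(3))
    cop: np.ndarray = field(default_factory=lambda: np.zeros(3))


def _lowpass(arr: np.ndarray, fs: float, cutoff: float | None, order: int = 4) -> np.ndarray:
    if cutoff is None or arr.shape[0] < 3 * order:
        return arr
    b, a = butter(order, cutoff / (fs / 2.0), btype="low")
    return filtfilt(b, a, arr, axis=0)


def resample_grf(trial, angle_times: np.ndarray, cutoff: float | None = 20.0):
    """Anti-alias filter the force-plate channels and sample them at the
    marker time base."""
    fs = 1.0 / np.median(np.diff(trial.grf_times))
    force = _lowpass(trial.grf_force, fs, cutoff)
    cop = _lowpass(trial.grf_cop, fs, cutoff)
    f = np.stack([np.interp(angle_times, trial.grf_times, force[:, j]) for j in range(3)], axis=-1)
    c = np.stack([np.interp(angle_times, trial.grf_times, cop[:, j]) for j in range(3)], axis=-1)
    return f, c


def _segment_kinematics(model: LinkageModel, q_series: np.ndarray,
                        es_series: np.ndarray, times: np.ndarray):
    """Per-frame segment poses and their derivatives.

    Returns dicts keyed by segment with poses (R, p), COM accelerations
    (mm/s^2), angular velocities and accelerations (rad/s, rad/s^2).
    """
    n = len(times)
    segs = ("pelvis", "thigh", "shank", "foot")
    R = {s: np.empty((n, 3, 3)) for s in segs}
    com = {s: np.empty((n, 3)) for s in segs}
    for i in range(n):
        poses = forward_kinematics(model, q_series[i], es_series[i])
        for s in segs:
            Ri, pi = poses[s]
            R[s][i] = Ri
            com[s][i] = Ri @ model.segments[s].com_local + pi

    dt = float(np.median(np.diff(times)))
    acc = {s: np.gradient(np.gradient(com[s], dt, axis=0), dt, axis=0) for s in segs}
    omega = {}
    alpha = {}
    for s in segs:
        Rdot = np.gradient(R[s], dt, axis=0)
        w = np.empty((n, 3))
        for i in range(n):
            w[i] = unskew(Rdot[i] @ R[s][i].T)
        omega[s] = w
        alpha[s] = np.gradient(w, dt, axis=0)
    return R, com, acc, omega, alpha


def inverse_dynamics(states: list[JointState], trial, model: LinkageModel,
                     angle_cutoff: float | None = 6.0,
                     grf_cutoff: float | None = 20.0) -> list[JointLoads]:
    """Newton-Euler net joint moments for a time series of joint states."""
    times = np.array([s.time for s in states])
    if np.any(np.diff(times) <= 0):
        raise ValueError("non-monotone time stamps")
    q_series = np.stack([s.q for s in states])
    es_series = np.stack([s.e_s for s in states])
    fs = 1.0 / np.median(np.diff(times))
    q_series = _lowpass(q_series, fs, angle_cutoff)

    grf, cop = resample_grf(trial, times, grf_cutoff)
    R, com, acc, omega, alpha = _segment_kinematics(model, q_series, es_series, times)

    g_vec = np.array([0.0, -G_MMS2, 0.0])
    out: list[JointLoads] = []
    for i in range(len(times)):
        poses = {s: (R[s][i], None) for s in R}
        fk = forward_kinematics(model, q_series[i], es_series[i])
        jc = joint_centers(model, fk)
        forces = {}
        moments = {}

        f_dist = np.zeros(3)        # force on the current segment from its distal joint
        m_dist = np.zeros(3)
        p_dist = None
        ext_f = grf[i]
        ext_p = cop[i]
        for seg, joint in (("foot", "ankle"), ("shank", "knee"), ("thigh", "hip")):
            sg = model.segments[seg]
            m = sg.mass
            Rg = R[seg][i]
            I_g = Rg @ sg.inertia @ Rg.T
            c = com[seg][i]
            # linear: m a = F_joint + F_dist_reaction + m g + F_ext
            f_ext = ext_f if seg == "foot" else np.zeros(3)
            f_joint = m * (acc[seg][i] - g_vec) / 1000.0 - (-f_dist) - f_ext
            # angular about COM (inertial torque in N mm)
            h = (I_g @ alpha[seg][i] + np.cross(omega[seg][i], I_g @ omega[seg][i])) / 1000.0
            m_joint = h.copy()
            m_joint -= np.cross(jc[joint] - c, f_joint)
            if p_dist is not None:
                m_joint -= np.cross(p_dist - c, -f_dist)
                m_joint -= (-m_dist)
            if seg == "foot":
                m_joint -= np.cross(ext_p - c, f_ext)
            forces[joint] = f_joint
            moments[joint] = m_joint
            f_dist, m_dist, p_dist = f_joint, m_joint, jc[joint]

        axes = dof_axes(model, q_series[i])
        gen = {}
        for name in MOMENT_DOF_NAMES:
            joint = {"hip_flex": "hip", "hip_add": "hip", "hip_rot": "hip",
                     "knee_flex": "knee", "ankle_df": "ankle"}[name]
            gen[name] = float(moments[joint] @ axes[name])

        out.append(JointLoads(
            time=float(times[i]),
            percent_stance=states[i].percent_stance,
            forces=forces, moments=moments, generalized=gen,
            grf=grf[i], cop=cop[i],
        ))
    return out
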