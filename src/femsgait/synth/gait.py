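"""Synthetic single-stance gait trial.

A stance-phase trial consists of marker trajectories sampled at 100 Hz
and a ground reaction force (GRF) sampled at 1000 Hz.  Marker positions
are produced by forward kinematics of the linkage under smooth template
joint-angle curves (typical level-walking shapes) plus optional seeded
Gaussian noise, so inverse kinematics has an exact known answer at zero
noise.  The vertical GRF is the classic double-hump curve (weight
acceptance and push-off peaks with a mid-stance valley), with smaller
anterior-posterior braking/propulsion and mediolateral components, and
a centre of pressure that progresses from heel to toe under the foot.

Angle conventions follow :mod:`femsgait.linkage`; the default subject
(mass 80 kg, height 1.75 m) matches the study conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..linkage import LinkageModel, build_linkage, forward_kinematics, marker_positions, marker_order

G_MS2 = 9.81  # m/s^2


@dataclass
class GaitTrialSpec:
    """Parameters of a synthetic stance-phase trial."""

    subject_mass: float = 80.0        # kg
    subject_height: float = 1.75      # m
    stance_duration: float = 0.65     # s
    marker_rate: float = 100.0        # Hz
    grf_rate: float = 1000.0          # Hz
    grf_peak1: float = 1.10           # BW, weight acceptance
    grf_peak2: float = 1.05           # BW, push-off
    grf_peak1_frac: float = 0.25      # % stance / 100
    grf_peak2_frac: float = 0.75
    grf_valley: float = 0.75          # BW, mid-stance
    walking_speed: float = 1.25       # m/s (nominal; progression emerges from the templates)
    cop_medial_offset: float = 10.0   # mm, medial shift of the COP track
    marker_noise_sd: float = 0.0      # mm
    seed: int = 0

    def validate(self) -> None:
        if self.stance_duration <= 0:
            raise ValueError("stance_duration must be positive")
        for nm in ("grf_peak1", "grf_peak2"):
            v = getattr(self, nm)
            if not 0.0 < v < 3.0:
                raise ValueError(f"{nm} must lie in (0, 3) BW")
        if self.marker_noise_sd < 0:
            raise ValueError("marker_noise_sd must be >= 0")
        if not (0.0 < self.grf_peak1_frac < self.grf_peak2_frac < 1.0):
            raise ValueError("GRF peak timings must be ordered in (0, 1)")


@dataclass
class GaitTrial:
    """One synthetic stance phase: markers at 100 Hz, GRF at 1000 Hz."""

    spec: GaitTrialSpec
    linkage: LinkageModel
    marker_times: np.ndarray                  # s
    markers: dict[str, np.ndarray]            # name -> (n, 3) mm
    grf_times: np.ndarray                     # s
    grf_force: np.ndarray                     # (m, 3) N
    grf_cop: np.ndarray                       # (m, 3) mm
    template_q: np.ndarray                    # (n, 11) generating DOFs (rad/mm)

    @property
    def body_weight(self) -> float:
        """Subject weight in N."""
        return self.spec.subject_mass * G_MS2

    def markers_frame(self, i: int) -> dict[str, np.ndarray]:
        return {k: v[i] for k, v in self.markers.items()}

    def to_marker_csv(self, path) -> None:
        cols = {"time": self.marker_times}
        for name in marker_order(self.linkage):
            xyz = self.markers[name]
            for j, ax in enumerate("XYZ"):
                cols[f"{name}_{ax}"] = xyz[:, j]
        pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6f")

    def to_grf_csv(self, path) -> None:
        pd.DataFrame({
            "time": self.grf_times,
            "Fx": self.grf_force[:, 0],
            "Fy": self.grf_force[:, 1],
            "Fz": self.grf_force[:, 2],
            "COPx": self.grf_cop[:, 0],
            "COPy": self.grf_cop[:, 1],
            "COPz": self.grf_cop[:, 2],
        }).to_csv(path, index=False, float_format="%.6f")


def _bump(tau: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-((tau - center) / width) ** 2)


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def template_primary_angles(tau: float | np.ndarray, spec: GaitTrialSpec,
                            linkage: LinkageModel) -> np.ndarray:
    """Template primary DOFs q(tau) for tau in [0, 1] (fraction of stance).

    The construction starts from the planted foot and closes the chain
    upward, so the kinematics are consistent with a stationary support:
    the foot is flat (toe fixed) with a late heel rise about the toe,
    the shank rolls forward over the ankle (the ankle rocker), and the
    knee shows the loading-response flexion wave plus pre-swing flexion.
    The pelvis pose is whatever closes the chain with a level pelvis, so
    hip flexion emerges with the classic flexion -> extension -> flexion
    profile and forward progression emerges at a realistic walking
    speed.  The stance-leg plane is z = 0 with the pelvis centred over
    it (frontal alignment of normal single support).
    """
    from scipy.spatial.transform import Rotation
    from ..frames import rot_z

    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    d2r = np.pi / 180.0

    shank_tilt = (-12.0 + 46.0 * _smoothstep(tau)) * d2r          # forward +
    knee_flex = (6.0 + 12.0 * _bump(tau, 0.22, 0.15)
                 + 28.0 * _bump(tau, 1.05, 0.22)) * d2r
    heel_rise = 24.0 * _smoothstep((tau - 0.6) / 0.4) * d2r

    seg_f = linkage.segments["foot"]
    toe_local = seg_f.markers["RTOE"].copy()
    toe_local[2] = 0.0                       # keep the chain in the leg plane
    L_sh = linkage.segments["shank"].length
    L_th = linkage.segments["thigh"].length

    q = np.zeros((tau.size, 11))
    for i in range(tau.size):
        R_ft = rot_z(-heel_rise[i])
        toe_anchor = np.array([toe_local[0], 0.0, 0.0])
        ankle_pos = toe_anchor + R_ft @ (-toe_local)
        R_sh = rot_z(-shank_tilt[i])
        knee_pos = ankle_pos + R_sh @ np.array([0.0, L_sh, 0.0])
        R_th = R_sh @ rot_z(knee_flex[i])
        hip_pos = knee_pos + R_th @ np.array([0.0, L_th, 0.0])
        R_pel = np.eye(3)
        p_pel = hip_pos - R_pel @ linkage.hip_local
        R_hip = R_pel.T @ R_th
        a, b, c = Rotation.from_matrix(R_hip).as_euler("ZXY")
        M = R_sh.T @ R_ft
        ankle_df = np.arctan2(M[1, 0], M[0, 0])
        q[i] = [p_pel[0], p_pel[1], p_pel[2], 0.0, 0.0, 0.0,
                a, b, c, knee_flex[i], ankle_df]
    return q


def template_grf_bw(tau: np.ndarray, spec: GaitTrialSpec) -> np.ndarray:
    """Template GRF in BW, columns (Fx anterior, Fy vertical, Fz lateral)."""
    tau = np.asarray(tau, dtype=float)
    env = np.clip(np.sin(np.pi * np.clip(tau, 0.0, 1.0)), 0.0, None) ** 0.5
    fy = (spec.grf_peak1 * _bump(tau, spec.grf_peak1_frac, 0.14)
          + spec.grf_peak2 * _bump(tau, spec.grf_peak2_frac, 0.14)
          + spec.grf_valley * _bump(tau, 0.5, 0.10))
    fy = fy * env
    dense = np.linspace(0.0, 1.0, 2001)
    env_d = np.clip(np.sin(np.pi * dense), 0.0, None) ** 0.5
    fy_d = (spec.grf_peak1 * _bump(dense, spec.grf_peak1_frac, 0.14)
            + spec.grf_peak2 * _bump(dense, spec.grf_peak2_frac, 0.14)
            + spec.grf_valley * _bump(dense, 0.5, 0.10)) * env_d
    fy = fy * max(spec.grf_peak1, spec.grf_peak2) / fy_d.max()
    fx = -0.14 * np.sin(2 * np.pi * tau) * env
    fz = np.zeros_like(tau)                # ML shear left out of the template
    return np.stack([fx, fy, fz], axis=-1)


def generate_gait_trial(spec: GaitTrialSpec | None = None,
                        linkage: LinkageModel | None = None) -> GaitTrial:
    """Generate one synthetic stance-phase trial (seed-deterministic)."""
    spec = spec or GaitTrialSpec()
    spec.validate()
    if linkage is None:
        linkage = build_linkage(spec.subject_mass, spec.subject_height)
    rng = np.random.default_rng(spec.seed)

    n_m = int(round(spec.marker_rate * spec.stance_duration)) + 1
    t_m = np.arange(n_m) / spec.marker_rate
    tau_m = t_m / spec.stance_duration
    q = template_primary_angles(tau_m, spec, linkage)

    names = marker_order(linkage)
    markers = {name: np.empty((n_m, 3)) for name in names}
    for i in range(n_m):
        pos = marker_positions(linkage, q[i])
        for name in names:
            markers[name][i] = pos[name]
    if spec.marker_noise_sd > 0:
        for name in names:
            markers[name] += rng.normal(0.0, spec.marker_noise_sd, size=(n_m, 3))

    n_g = int(round(spec.grf_rate * spec.stance_duration)) + 1
    t_g = np.arange(n_g) / spec.grf_rate
    tau_g = t_g / spec.stance_duration
    bw = spec.subject_mass * G_MS2
    grf = template_grf_bw(tau_g, spec) * bw

    # centre of pressure: heel-to-toe progression under the foot
    heel = np.empty((n_m, 3))
    toe = np.empty((n_m, 3))
    for i in range(n_m):
        pos = marker_positions(linkage, q[i])
        heel[i], toe[i] = pos["RHEE"], pos["RTOE"]
    heel_g = np.stack([np.interp(t_g, t_m, heel[:, j]) for j in range(3)], axis=-1)
    toe_g = np.stack([np.interp(t_g, t_m, toe[:, j]) for j in range(3)], axis=-1)
    s = np.clip(tau_g, 0.0, 1.0)[:, None]
    cop = (1.0 - s) * heel_g + s * toe_g
    cop[:, 1] = 0.0
    cop[:, 2] -= spec.cop_medial_offset

    return GaitTrial(
        spec=spec, linkage=linkage,
        marker_times=t_m, markers=markers,
        grf_times=t_g, grf_force=grf, grf_cop=cop,
        template_q=q,
    )


def load_trial_csv(marker_path, grf_path, spec: GaitTrialSpec | None = None,
                   linkage: LinkageModel | None = None) -> GaitTrial:
    """Rebuild a GaitTrial from the wide CSV files written by ``to_*_csv``."""
    spec = spec or GaitTrialSpec()
    if linkage is None:
        linkage = build_linkage(spec.subject_mass, spec.subject_height)
    mk = pd.read_csv(marker_path)
    gr = pd.read_csv(grf_path)
    names = sorted({c[:-2] for c in mk.columns if c != "time"})
    markers = {
        name: np.stack([mk[f"{name}_{ax}"].to_numpy() for ax in "XYZ"], axis=-1)
        for name in names
    }
    return GaitTrial(
        spec=spec, linkage=linkage,
        marker_times=mk["time"].to_numpy(), markers=markers,
        grf_times=gr["time"].to_numpy(),
        grf_force=gr[["Fx", "Fy", "Fz"]].to_numpy(),
        grf_cop=gr[["COPx", "COPy", "COPz"]].to_numpy(),
        template_q=np.zeros((len(mk), 11)),
    )
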