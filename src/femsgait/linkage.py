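"""Right-lower-limb linkage: segments, joints, forward kinematics, markers.

The chain is pelvis (6-DOF root) -> hip (3-DOF spherical:
flexion-extension about Z, adduction-abduction about X, internal-external
rotation about Y, applied in that order) -> tibiofemoral joint (primary
flexion hinge about -Z plus five secondary DOFs: three translations and
internal-external / varus-valgus rotations) -> ankle (1-DOF
dorsiflexion-plantarflexion hinge about Z).  The patella is handled by
the extensor-mechanism path in the muscle module rather than as a chain
segment.

Generalized-coordinate vector ``q`` (11 primary DOFs)::

    [px, py, pz, p_rz, p_rx, p_ry,      pelvis translation (mm) + ZXY Euler (rad)
     hip_flex, hip_add, hip_rot,        rad
     knee_flex,                         rad, flexion positive
     ankle_df]                          rad, dorsiflexion positive

Knee secondary kinematics ``e_s = [tx, ty, tz, varus, introt]`` are
tibial translations (mm, femur frame at current flexion) and rotations
(rad) inserted between the flexion hinge and the shank.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .frames import rot_x, rot_y, rot_z

PRIMARY_DOF_NAMES = (
    "pelvis_tx", "pelvis_ty", "pelvis_tz",
    "pelvis_rz", "pelvis_rx", "pelvis_ry",
    "hip_flex", "hip_add", "hip_rot",
    "knee_flex", "ankle_df",
)
MOMENT_DOF_NAMES = ("hip_flex", "hip_add", "hip_rot", "knee_flex", "ankle_df")
SEGMENTS = ("pelvis", "thigh", "shank", "foot")


@dataclass
class Segment:
    name: str
    length: float                  # mm (longitudinal)
    mass: float                    # kg
    com_local: np.ndarray          # mm, segment frame
    inertia: np.ndarray            # kg mm^2, about COM, segment frame
    markers: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class LinkageModel:
    """Scaled lower-limb linkage for one subject."""

    subject_mass: float            # kg
    subject_height: float          # m
    segments: dict[str, Segment]
    hip_local: np.ndarray          # pelvis-frame hip centre (mm)
    knee_local: np.ndarray         # thigh-frame knee centre (mm)
    ankle_local: np.ndarray        # shank-frame ankle centre (mm)

    def n_dofs(self) -> int:
        return len(PRIMARY_DOF_NAMES)


def _default_markers(seg: str, L: float, heel: float, ankle_h: float) -> dict[str, np.ndarray]:
    """Four non-collinear markers per segment, segment-local mm."""
    if seg == "pelvis":
        return {
            "RASI": np.array([60.0, 0.0, 120.0]),
            "LASI": np.array([60.0, 0.0, -120.0]),
            "RPSI": np.array([-80.0, 20.0, 50.0]),
            "LPSI": np.array([-80.0, 20.0, -50.0]),
        }
    if seg == "thigh":
        return {
            "RTHI1": np.array([40.0, -0.3 * L, 30.0]),
            "RTHI2": np.array([20.0, -0.55 * L, 45.0]),
            "RTHI3": np.array([-20.0, -0.45 * L, 35.0]),
            "RKNE": np.array([0.0, -L, 55.0]),
        }
    if seg == "shank":
        return {
            "RTIB1": np.array([30.0, -0.3 * L, 25.0]),
            "RTIB2": np.array([10.0, -0.55 * L, 40.0]),
            "RTIB3": np.array([-15.0, -0.45 * L, 30.0]),
            "RANK": np.array([0.0, -L, 45.0]),
        }
    if seg == "foot":
        return {
            "RHEE": np.array([-heel, -ankle_h, 0.0]),
            "RTOE": np.array([L - heel, -ankle_h, -10.0]),
            "RMT5": np.array([0.6 * L - heel, -ankle_h, 35.0]),
            "RMT1": np.array([0.6 * L - heel, -ankle_h, -30.0]),
        }
    raise ValueError(seg)


def build_linkage(subject_mass: float = 80.0, subject_height: float = 1.75,
                  anthropometry_path=None) -> LinkageModel:
    """Scale the anthropometric table to one subject.

    Masses, segment lengths, COM offsets and gyration radii come from
    the packaged fraction table; inertia tensors are transverse-isotropic
    cylinders (longitudinal moment taken as 30% of transverse).
    """
    if subject_mass <= 0 or subject_height <= 0:
        raise ValueError("subject mass and height must be positive")
    if anthropometry_path is None:
        text = resources.files("femsgait.data").joinpath("anthropometry.yaml").read_text()
    else:
        with open(anthropometry_path) as fh:
            text = fh.read()
    tab = yaml.safe_load(text)
    H_mm = subject_height * 1000.0
    heel = tab["heel_frac"] * H_mm
    ankle_h = tab["ankle_height_frac"] * H_mm

    segments: dict[str, Segment] = {}
    for name in SEGMENTS:
        row = tab["segments"][name]
        L = row["length_frac"] * H_mm
        m = row["mass_frac"] * subject_mass
        if name == "pelvis":
            com = np.array([0.0, -row["com_frac"] * L, 0.0])
        elif name == "foot":
            com = np.array([row["com_frac"] * L - heel, -ankle_h, 0.0])
        else:
            com = np.array([0.0, -row["com_frac"] * L, 0.0])
        r_g = row["gyration_frac"] * L
        i_t = m * r_g**2
        inertia = np.diag([i_t, 0.3 * i_t, i_t])
        if name == "foot":
            inertia = np.diag([0.3 * i_t, i_t, i_t])
        segments[name] = Segment(
            name=name, length=L, mass=m, com_local=com, inertia=inertia,
            markers=_default_markers(name, L, heel, ankle_h),
        )

    return LinkageModel(
        subject_mass=subject_mass,
        subject_height=subject_height,
        segments=segments,
        hip_local=np.array([0.0, -tab["hip_drop_frac"] * H_mm,
                            tab["hip_half_spacing_frac"] * H_mm]),
        knee_local=np.array([0.0, -segments["thigh"].length, 0.0]),
        ankle_local=np.array([0.0, -segments["shank"].length, 0.0]),
    )


def forward_kinematics(model: LinkageModel, q: np.ndarray,
                       e_s: np.ndarray | None = None) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Global pose ``(R, p)`` of every segment for DOFs ``q`` (+ knee ``e_s``)."""
    q = np.asarray(q, dtype=float)
    if q.shape != (11,):
        raise ValueError("q must have 11 primary DOFs")
    if e_s is None:
        e_s = np.zeros(5)
    e_s = np.asarray(e_s, dtype=float)

    p_pel = q[0:3]
    R_pel = rot_z(q[3]) @ rot_x(q[4]) @ rot_y(q[5])

    R_hip = rot_z(q[6]) @ rot_x(q[7]) @ rot_y(q[8])
    R_th = R_pel @ R_hip
    p_th = p_pel + R_pel @ model.hip_local

    # tibiofemoral: flexion hinge, then secondary translations (femur
    # frame at current flexion) and rotations (varus about X, then
    # internal rotation about Y)
    R_flex = rot_z(-q[9])
    R_sec = rot_x(e_s[3]) @ rot_y(e_s[4])
    R_sh = R_th @ R_flex @ R_sec
    p_sh = p_th + R_th @ model.knee_local + (R_th @ R_flex) @ e_s[0:3]

    R_ft = R_sh @ rot_z(q[10])
    p_ft = p_sh + R_sh @ model.ankle_local

    return {
        "pelvis": (R_pel, p_pel),
        "thigh": (R_th, p_th),
        "shank": (R_sh, p_sh),
        "foot": (R_ft, p_ft),
    }


def joint_centers(model: LinkageModel, poses) -> dict[str, np.ndarray]:
    R_pel, p_pel = poses["pelvis"]
    R_th, p_th = poses["thigh"]
    R_sh, p_sh = poses["shank"]
    return {
        "hip": p_th,
        "knee": p_th + R_th @ model.knee_local,
        "ankle": p_sh + R_sh @ model.ankle_local,
    }


def dof_axes(model: LinkageModel, q: np.ndarray) -> dict[str, np.ndarray]:
    """Global rotation axis of each moment-bearing DOF at configuration q.

    These are the instantaneous axes of the Euler sequence, so the
    projection of an intersegmental moment onto them is the generalized
    torque conjugate to that DOF.
    """
    R_pel = rot_z(q[3]) @ rot_x(q[4]) @ rot_y(q[5])
    z, x, y = np.eye(3)[:, 2], np.eye(3)[:, 0], np.eye(3)[:, 1]
    A_f = R_pel @ z
    A_a = R_pel @ rot_z(q[6]) @ x
    A_r = R_pel @ rot_z(q[6]) @ rot_x(q[7]) @ y
    R_th = R_pel @ rot_z(q[6]) @ rot_x(q[7]) @ rot_y(q[8])
    A_k = R_th @ (-z)                       # knee flexion positive about -Z
    R_sh = R_th @ rot_z(-q[9])
    A_ank = R_sh @ z
    return {
        "hip_flex": A_f, "hip_add": A_a, "hip_rot": A_r,
        "knee_flex": A_k, "ankle_df": A_ank,
    }


def marker_positions(model: LinkageModel, q: np.ndarray,
                     e_s: np.ndarray | None = None) -> dict[str, np.ndarray]:
    poses = forward_kinematics(model, q, e_s)
    out = {}
    for seg_name, (R, p) in poses.items():
        for mname, local in model.segments[seg_name].markers.items():
            out[mname] = R @ local + p
    return out


def marker_order(model: LinkageModel) -> list[str]:
    names = []
    for seg in SEGMENTS:
        names.extend(model.segments[seg].markers.keys())
    return names
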