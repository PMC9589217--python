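"""Hill-type muscles: paths, cylinder wrapping, moment arms, forces.

Each of the 20 one-dimensional muscle units is a polyline of via points
attached to linkage segments, optionally wrapping a cylinder (the
tangent-arc-tangent shortest path when a straight piece penetrates the
surface).  Force follows the rigid-tendon Hill model

    f = Fmax * [a * f_act(l~) + f_pass(l~)],      0 <= a <= 1,

with normalized fiber length ``l~ = (L_path - L_slack) / l_opt``; the
tendon slack length is calibrated once per subject so ``l~ = 1`` at the
standing reference pose.  Velocity dependence and activation dynamics
are deliberately absent: the framework resolves muscle redundancy by a
per-time-point static optimization.

Moment arms use the tendon-excursion definition ``r = -dL/dq``,
evaluated analytically from the motion of path points that are distal
to each DOF (wrap tangent points contribute as material points of the
obstacle's host segment, by the envelope theorem).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .frames import rot_x, rot_z
from .linkage import LinkageModel, MOMENT_DOF_NAMES, dof_axes, forward_kinematics, joint_centers

SEG_RANK = {"pelvis": 0, "thigh": 1, "shank": 2, "foot": 3}
# segments moved by each moment-bearing DOF
DOF_MIN_RANK = {"hip_flex": 1, "hip_add": 1, "hip_rot": 1, "knee_flex": 2, "ankle_df": 3}


@dataclass
class WrapCylinder:
    segment: str
    point: np.ndarray        # segment-local point on the axis (mm)
    axis: np.ndarray         # segment-local axis direction
    radius: float


@dataclass
class MuscleUnit:
    name: str
    fmax: float                      # N
    l_opt: float                     # mm
    path_segments: list[str]
    path_points: np.ndarray          # (n, 3) segment-local mm
    wrap: WrapCylinder | None = None
    act_width: float = 0.55          # active force-length Gaussian width
    pass_exp: float = 4.0            # passive exponential steepness
    l_slack: float = 0.0             # mm, calibrated tendon slack length
    l_opt_eff: float = 0.0           # mm, effective normalizing length (see calibrate_slack)

    def __post_init__(self) -> None:
        if self.fmax <= 0 or self.l_opt <= 0:
            raise ValueError(f"{self.name}: force parameters must be positive")
        if len(self.path_segments) < 2 or len(set(self.path_segments)) < 2:
            raise ValueError(f"{self.name}: path must span at least two segments")

    def f_active(self, lnorm: float) -> float:
        return float(np.exp(-(((lnorm - 1.0) / self.act_width) ** 2)))

    # passive element engages beyond pass_slack stretch and reaches Fmax
    # at 1.5 normalized length
    pass_slack = 1.15

    def f_passive(self, lnorm: float) -> float:
        if lnorm <= self.pass_slack:
            return 0.0
        k = self.pass_exp
        return float((np.exp(k * (lnorm - self.pass_slack)) - 1.0)
                     / (np.exp(k * (1.5 - self.pass_slack)) - 1.0))


def hill_force(muscle: MuscleUnit, activation: float, lnorm: float) -> float:
    """Rigid-tendon Hill force (N) at activation and normalized length."""
    if not 0.0 <= activation <= 1.0:
        raise ValueError("activation must lie in [0, 1]")
    if lnorm <= 0:
        raise ValueError("normalized length must be positive")
    return muscle.fmax * (activation * muscle.f_active(lnorm) + muscle.f_passive(lnorm))


def load_muscle_set(path=None, subject_height: float = 1.75) -> list[MuscleUnit]:
    """Load the packaged (or a custom) muscle YAML, scaled to a subject."""
    if path is None:
        text = resources.files("femsgait.data").joinpath("muscles.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    scale = subject_height / float(doc.get("reference_height", 1.75))
    muscles = []
    for row in doc["muscles"]:
        segs = [p[0] for p in row["path"]]
        pts = np.array([[float(v) for v in p[1:]] for p in row["path"]]) * scale
        wrap = None
        if row.get("wrap"):
            w = row["wrap"]
            wrap = WrapCylinder(
                segment=w["segment"],
                point=np.asarray(w["point"], dtype=float) * scale,
                axis=np.asarray(w["axis"], dtype=float),
                radius=float(w["radius"]) * scale,
            )
        muscles.append(MuscleUnit(
            name=row["name"], fmax=float(row["fmax"]),
            l_opt=float(row["l_opt"]) * scale,
            path_segments=segs, path_points=pts, wrap=wrap,
        ))
    return muscles


# ---------------------------------------------------------------------------
# wrapping geometry

def cylinder_wrap_path(p1: np.ndarray, p2: np.ndarray, axis_point: np.ndarray,
                       axis_dir: np.ndarray, radius: float):
    """Shortest path from p1 to p2 around an infinite cylinder.

    Returns ``(length, tangent_a, tangent_b, wrapped)``; when the
    straight segment clears the cylinder the tangent points are None.
    The wrapped length uses the standard obstacle-set construction:
    planar tangent-arc-tangent in the cross-section, with the axial
    travel distributed along the path (helical arc).
    """
    a = np.asarray(axis_dir, dtype=float)
    a = a / np.linalg.norm(a)
    # orthonormal cross-section basis
    tmp = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(a, tmp)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)

    def to2d(p):
        d = p - axis_point
        return np.array([d @ e1, d @ e2]), d @ a

    P1, z1 = to2d(p1)
    P2, z2 = to2d(p2)
    d1, d2 = np.linalg.norm(P1), np.linalg.norm(P2)
    if d1 <= radius or d2 <= radius:
        raise ValueError("path point inside wrapping cylinder")

    # does the planar segment cut the circle?
    seg = P2 - P1
    t = np.clip(-(P1 @ seg) / max(seg @ seg, 1e-300), 0.0, 1.0)
    if np.linalg.norm(P1 + t * seg) >= radius:
        return float(np.linalg.norm(p2 - p1)), None, None, False

    ang = np.arctan2(np.cross(P1, P2), P1 @ P2)  # signed angle P1 -> P2
    tau = abs(ang) - np.arccos(radius / d1) - np.arccos(radius / d2)
    if tau <= 0.0:
        return float(np.linalg.norm(p2 - p1)), None, None, False

    lt1 = np.sqrt(d1**2 - radius**2)
    lt2 = np.sqrt(d2**2 - radius**2)
    l2d = lt1 + radius * tau + lt2
    dz = z2 - z1
    length = float(np.hypot(l2d, dz))

    # tangent points (wrap on the side of the straight segment)
    s = np.sign(ang) if ang != 0 else 1.0
    th1 = np.arctan2(P1[1], P1[0]) + s * np.arccos(radius / d1)
    th2 = np.arctan2(P2[1], P2[0]) - s * np.arccos(radius / d2)
    frac1 = lt1 / l2d
    frac2 = (lt1 + radius * tau) / l2d
    qa = axis_point + radius * (np.cos(th1) * e1 + np.sin(th1) * e2) + (z1 + dz * frac1) * a
    qb = axis_point + radius * (np.cos(th2) * e1 + np.sin(th2) * e2) + (z1 + dz * frac2) * a
    return length, qa, qb, True


# ---------------------------------------------------------------------------
# geometry over the linkage

@dataclass
class MuscleGeometry:
    """Current lengths, moment arms and knee-crossing force carriers."""

    names: list[str]
    lengths: np.ndarray              # (n_m,) mm
    lnorm: np.ndarray                # (n_m,) normalized fiber lengths
    arms: np.ndarray                 # (5, n_m) mm; rows follow MOMENT_DOF_NAMES
    knee_cross_point: np.ndarray     # (n_m, 3) global application point on the distal system
    knee_cross_dir: np.ndarray       # (n_m, 3) global unit pull direction (toward femur side)
    crosses_knee: np.ndarray         # (n_m,) bool


def _expanded_path(muscle: MuscleUnit, poses) -> tuple[list[str], list[np.ndarray]]:
    """Global path points including wrap tangent points (hosted on the
    wrap segment).  Raises if a wrap construction is ambiguous."""
    segs = list(muscle.path_segments)
    pts = [poses[s][0] @ p + poses[s][1] for s, p in zip(segs, muscle.path_points)]
    if muscle.wrap is None:
        return segs, pts
    w = muscle.wrap
    Rw, pw = poses[w.segment]
    axis_point = Rw @ w.point + pw
    axis_dir = Rw @ w.axis
    out_segs, out_pts = [segs[0]], [pts[0]]
    for i in range(len(pts) - 1):
        _, qa, qb, wrapped = cylinder_wrap_path(pts[i], pts[i + 1], axis_point,
                                                axis_dir, w.radius)
        if wrapped:
            out_segs.extend([w.segment, w.segment])
            out_pts.extend([qa, qb])
        out_segs.append(segs[i + 1])
        out_pts.append(pts[i + 1])
    return out_segs, out_pts


def _path_length_from_points(muscle: MuscleUnit, poses) -> float:
    segs = list(muscle.path_segments)
    pts = [poses[s][0] @ p + poses[s][1] for s, p in zip(segs, muscle.path_points)]
    if muscle.wrap is None:
        return float(sum(np.linalg.norm(b - a) for a, b in zip(pts[:-1], pts[1:])))
    w = muscle.wrap
    Rw, pw = poses[w.segment]
    axis_point = Rw @ w.point + pw
    axis_dir = Rw @ w.axis
    total = 0.0
    for a, b in zip(pts[:-1], pts[1:]):
        L, *_ = cylinder_wrap_path(a, b, axis_point, axis_dir, w.radius)
        total += L
    return float(total)


def muscle_path_length(muscle: MuscleUnit, linkage: LinkageModel, q: np.ndarray,
                       e_s: np.ndarray | None = None) -> float:
    """Total origin-to-insertion path length (mm) at a configuration."""
    poses = forward_kinematics(linkage, q, e_s)
    return _path_length_from_points(muscle, poses)


def _dof_axis_center(linkage: LinkageModel, q: np.ndarray, poses):
    axes = dof_axes(linkage, q)
    jc = joint_centers(linkage, poses)
    centers = {"hip_flex": jc["hip"], "hip_add": jc["hip"], "hip_rot": jc["hip"],
               "knee_flex": jc["knee"], "ankle_df": jc["ankle"]}
    return axes, centers


def compute_muscle_geometry(linkage: LinkageModel, q: np.ndarray,
                            muscles: list[MuscleUnit],
                            e_s: np.ndarray | None = None) -> MuscleGeometry:
    """Lengths, tendon-excursion moment arms and knee-crossing carriers.

    The analytic arm for DOF k sums ``u . (a_k x (p - c_k))`` over the
    ends of every straight path piece whose endpoint is distal to the
    DOF; this equals ``-dL/dq_k`` exactly for via-point paths and to
    envelope-theorem accuracy for wrapped paths.
    """
    poses = forward_kinematics(linkage, q, e_s)
    axes, centers = _dof_axis_center(linkage, q, poses)

    n_m = len(muscles)
    lengths = np.empty(n_m)
    arms = np.zeros((len(MOMENT_DOF_NAMES), n_m))
    cross_pt = np.zeros((n_m, 3))
    cross_dir = np.zeros((n_m, 3))
    crosses = np.zeros(n_m, dtype=bool)

    for im, mu in enumerate(muscles):
        segs, pts = _expanded_path(mu, poses)
        lengths[im] = _path_length_from_points(mu, poses)
        for ik, dof in enumerate(MOMENT_DOF_NAMES):
            min_rank = DOF_MIN_RANK[dof]
            a_k, c_k = axes[dof], centers[dof]
            dL = 0.0
            for (sa, pa), (sb, pb) in zip(zip(segs[:-1], pts[:-1]), zip(segs[1:], pts[1:])):
                piece = pb - pa
                ln = np.linalg.norm(piece)
                if ln < 1e-12:
                    continue
                u = piece / ln
                if SEG_RANK[sb] >= min_rank:
                    dL += u @ np.cross(a_k, pb - c_k)
                if SEG_RANK[sa] >= min_rank:
                    dL -= u @ np.cross(a_k, pa - c_k)
            arms[ik, im] = -dL
        # knee-crossing piece: last proximal point -> first distal point
        for (sa, pa), (sb, pb) in zip(zip(segs[:-1], pts[:-1]), zip(segs[1:], pts[1:])):
            if SEG_RANK[sa] <= 1 and SEG_RANK[sb] >= 2:
                d = pa - pb
                ln = np.linalg.norm(d)
                cross_pt[im] = pb
                cross_dir[im] = d / max(ln, 1e-12)
                crosses[im] = True
                break

    lnorm = (lengths - np.array([m.l_slack for m in muscles])) / \
        np.array([m.l_opt_eff if m.l_opt_eff > 0 else m.l_opt for m in muscles])
    return MuscleGeometry(
        names=[m.name for m in muscles], lengths=lengths, lnorm=lnorm,
        arms=arms, knee_cross_point=cross_pt, knee_cross_dir=cross_dir,
        crosses_knee=crosses,
    )


def reference_pose(linkage: LinkageModel) -> np.ndarray:
    """Calibration reference: a mid-stance-like posture.

    Slightly flexed hip and knee centre every muscle's operating range
    on the gait excursions (a neutral standing pose would park the
    two-joint muscles near their passive toe region at the flexed
    extremes of stance)."""
    H = linkage.subject_height * 1000.0
    q = np.zeros(11)
    q[1] = (-linkage.hip_local[1] + linkage.segments["thigh"].length
            + linkage.segments["shank"].length + 0.039 * H)
    q[6] = 0.26     # hip flexion ~15 deg
    q[9] = 0.35     # knee flexion ~20 deg
    return q


def calibrate_slack(muscles: list[MuscleUnit], linkage: LinkageModel,
                    lnorm_ref: float = 1.0, min_opt_frac: float = 0.2) -> None:
    """Calibrate normalization so ``l~ = lnorm_ref`` at the standing pose.

    With a rigid tendon the whole musculotendon excursion lands on the
    fiber, so short-fibered long muscles would see wildly
    unphysiological normalized strains.  The effective normalizing
    length is therefore floored at ``min_opt_frac`` of the reference
    musculotendon length (a stand-in for the series elasticity that the
    static per-time-point formulation omits)."""
    q0 = reference_pose(linkage)
    for mu in muscles:
        L = muscle_path_length(mu, linkage, q0)
        mu.l_opt_eff = max(mu.l_opt, min_opt_frac * L)
        mu.l_slack = max(L - lnorm_ref * mu.l_opt_eff, 0.0)


def update_geometry_with_secondary(linkage: LinkageModel, q: np.ndarray,
                                   muscles: list[MuscleUnit],
                                   e_s: np.ndarray) -> MuscleGeometry:
    """Muscle lengths/arms with the tibia repositioned by the knee
    secondary kinematics (pure function of its inputs)."""
    return compute_muscle_geometry(linkage, q, muscles, e_s=e_s)
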