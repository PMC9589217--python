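"""Knee-specific assembly of the deformable contact problem.

Builds a :class:`PenaltyContactSolver` from a parametric knee model:

* deformable bodies: medial/lateral meniscus (fully free, anchored by
  horn springs and contact) and medial/lateral tibial cartilage (base
  bonded to the tibia);
* contact sets per the model's pair list: femoral condyle surfaces
  (offset by the femoral cartilage thickness, fixed in the flexed-femur
  frame) against meniscus and tibial-cartilage superior nodes, and the
  tibia-mounted plateau surface against meniscus inferior nodes.  The
  femoral cartilage mesh is carried for geometry/export; its compliance
  is not part of the contact kinematics (rigid-backed master), which is
  a documented desk-scale simplification.  The patellofemoral pair is
  handled by the extensor-mechanism path in the muscle stage;
* meniscal horn springs, the transverse ligament, and the nonlinear
  ligament bundles (origins rotated about the condylar axis by the
  current knee flexion).

Because the condyle surfaces are surfaces of revolution about the
condylar axis, the contact geometry itself is flexion-invariant; only
ligament origins move with flexion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..frames import axis_angle
from .contact import (
    ContactSet,
    InterSpring,
    LigamentElement,
    NodeSpring,
    PenaltyContactSolver,
    RigidPlane,
    tributary_areas,
)
from .elements import assemble_stiffness
from .materials import MaterialSpec, rotate_stiffness
from .stress import recover_stress, tag_tear_tip_stress
from ..passive import build_horn_springs

G_MS2 = 9.81


@dataclass
class ContactResult:
    """Converged knee contact state at one time point."""

    e_s: np.ndarray                      # [tx, ty, tz, varus, introt] (mm, rad)
    forces: dict                         # pair name -> (3,) N (femur frame, on tibia side)
    forces_bw: dict                      # pair name -> |F| / BW
    medial_ratio: float                  # meniscal share of the medial load (nan if unloaded)
    peak_pressure: dict                  # pair name -> MPa
    max_penetration: float               # mm
    residual_norm: float
    iterations: int
    converged: bool
    ligament_forces: dict = field(default_factory=dict)


def partition_contact_forces(sets: dict, subject_mass: float):
    """Per-pair resultants in N and BW plus the medial meniscal share.

    The medial ratio is |F(femur -> medial meniscus)| over the medial
    total (meniscal + direct tibial-cartilage path); an unloaded medial
    compartment yields NaN rather than zero.
    """
    bw = subject_mass * G_MS2
    forces = {name: rs.force for name, rs in sets.items()}
    forces_bw = {name: float(np.linalg.norm(f)) / bw for name, f in forces.items()}
    f_men = np.linalg.norm(forces.get("femoral_cartilage-medial_meniscus", np.zeros(3)))
    f_cart = np.linalg.norm(forces.get("femoral_cartilage-medial_tibial_cartilage", np.zeros(3)))
    total = f_men + f_cart
    ratio = float(f_men / total) if total > 1e-9 else float("nan")
    return forces, forces_bw, ratio


class KneeContactSession:
    """Caches the per-variant assembly; solves one time point at a time."""

    def __init__(self, model, materials: MaterialSpec | None = None,
                 subject_mass: float = 80.0,
                 penalty_per_area: float = 400.0,
                 pose_regularization: float = 25.0):
        self.model = model
        self.materials = materials or MaterialSpec()
        self.subject_mass = subject_mass

        bodies = {}
        self.C_per_body = {}
        C_cart = self.materials.cartilage_stiffness()
        C_men_local = self.materials.meniscus_stiffness_local()

        for side in ("medial", "lateral"):
            mesh = model.menisci.get(side)
            if mesh is None:
                continue
            triads = model.meniscus_frames[side]
            C_el = np.empty((mesh.n_elems, 6, 6))
            for e in range(mesh.n_elems):
                C_el[e] = rotate_stiffness(C_men_local, triads[e].T)
            K = assemble_stiffness(mesh.nodes, mesh.elems, C_el)
            bodies[f"{side}_meniscus"] = {
                "nodes": mesh.nodes, "K": K,
                "free_mask": np.ones(mesh.n_nodes, bool),
            }
            self.C_per_body[f"{side}_meniscus"] = C_el
        for side in ("medial", "lateral"):
            mesh = model.tibial_cartilage[side]
            K = assemble_stiffness(mesh.nodes, mesh.elems, C_cart)
            mask = np.ones(mesh.n_nodes, bool)
            mask[mesh.node_sets["bottom"]] = False
            bodies[f"{side}_cartilage"] = {
                "nodes": mesh.nodes, "K": K, "free_mask": mask,
            }
            self.C_per_body[f"{side}_cartilage"] = C_cart

        t_c = model.spec.tibial_cartilage_thickness
        plane = RigidPlane(point=np.array([0.0, t_c, 0.0]), normal=np.array([0.0, 1.0, 0.0]))
        contact_sets = []
        for side in ("medial", "lateral"):
            mesh = model.menisci.get(side)
            cart = model.tibial_cartilage[side]
            condyle = model.condyles[side]
            if mesh is not None and f"femoral_cartilage-{side}_meniscus" in model.contact_pairs:
                ids = mesh.node_sets["top"]
                contact_sets.append(ContactSet(
                    f"femoral_cartilage-{side}_meniscus", f"{side}_meniscus",
                    ids, tributary_areas(mesh.nodes, mesh.elems, ids),
                    condyle, "femur"))
            if f"femoral_cartilage-{side}_tibial_cartilage" in model.contact_pairs:
                ids = cart.node_sets["top"]
                contact_sets.append(ContactSet(
                    f"femoral_cartilage-{side}_tibial_cartilage", f"{side}_cartilage",
                    ids, tributary_areas(cart.nodes, cart.elems, ids),
                    condyle, "femur"))
            if mesh is not None and f"{side}_meniscus-{side}_tibial_cartilage" in model.contact_pairs:
                ids = mesh.node_sets["bottom"]
                contact_sets.append(ContactSet(
                    f"{side}_meniscus-{side}_tibial_cartilage", f"{side}_meniscus",
                    ids, tributary_areas(mesh.nodes, mesh.elems, ids),
                    plane, "tibia"))

        springs = []
        for horn in self.model.horns:
            side = "medial" if horn.horn.startswith("medial") else "lateral"
            if model.menisci.get(side) is None:
                continue
            for hs, nid in zip(build_horn_springs(horn), horn.node_ids):
                springs.append(NodeSpring(
                    body=f"{side}_meniscus", node_id=int(nid),
                    anchor=hs.tibia_node, stiffness=hs.stiffness,
                    rest_length=hs.rest_length))
        inter = []
        for side_a, na, side_b, nb, k in model.transverse_pairs:
            pa = model.menisci[side_a].nodes[na]
            pb = model.menisci[side_b].nodes[nb]
            inter.append(InterSpring(
                body_a=f"{side_a}_meniscus", node_a=int(na),
                body_b=f"{side_b}_meniscus", node_b=int(nb),
                stiffness=k, rest_length=float(np.linalg.norm(pa - pb))))

        self._bodies = bodies
        self._contact_sets = contact_sets
        self._springs = springs
        self._inter = inter
        self._pen = penalty_per_area
        self._pose_reg = pose_regularization
        self._solver = None
        self._last_x = None

    def _ligament_elements(self, flexion: float):
        model = self.model
        R = axis_angle(model.condylar_axis, flexion)
        k = model.knee_center
        out = []
        for b, o, ins in zip(model.ligaments, model.ligament_origins,
                             model.ligament_insertions):
            o_flex = k + R @ (o - k)
            out.append(LigamentElement(bundle=b, origin_femur=o_flex,
                                       insertion_tibia=ins))
        return out

    def solve(self, flexion: float, wrench, pose0: np.ndarray | None = None,
              warm_start: bool = True, tol_force: float = 0.2,
              max_iter: int = 150):
        """Solve one time point.

        ``wrench = (F(3,), M_varus, M_introt)`` is the required reaction
        on the tibia in the flexed-femur (solve) frame.  Returns
        ``(ContactResult, SolveResult)``.
        """
        solver = PenaltyContactSolver(
            bodies=self._bodies,
            contact_sets=self._contact_sets,
            springs=self._springs,
            inter_springs=self._inter,
            ligaments=self._ligament_elements(flexion),
            knee_center=self.model.knee_center,
            penalty_per_area=self._pen,
            friction=self.materials.friction,
            pose_free=True,
            pose_regularization=self._pose_reg,
        )
        u0 = None
        if warm_start and self._last_x is not None:
            u0 = self._last_x[:solver.n_u]
            if pose0 is None:
                pose0 = self._last_x[solver.n_u:]
        res = solver.solve(wrench=wrench, pose0=pose0, u0=u0,
                           tol_force=tol_force, max_iter=max_iter)
        x = np.concatenate([
            np.concatenate([res.u[name][solver.bodies[name]["free_nodes"]].ravel()
                            for name in solver.bodies]) if solver.n_u else np.zeros(0),
            res.pose])
        self._last_x = x
        forces, forces_bw, ratio = partition_contact_forces(res.sets, self.subject_mass)
        cr = ContactResult(
            e_s=res.pose.copy(),
            forces=forces, forces_bw=forces_bw, medial_ratio=ratio,
            peak_pressure={n: rs.peak_pressure for n, rs in res.sets.items()},
            max_penetration=max((rs.max_penetration for rs in res.sets.values()),
                                default=0.0),
            residual_norm=res.residual_norm,
            iterations=res.iterations,
            converged=res.converged,
            ligament_forces=res.ligament_forces,
        )
        return cr, res

    def stress(self, res, side: str = "medial"):
        """Stress field of one meniscus from a converged solve."""
        name = f"{side}_meniscus"
        mesh = self.model.menisci[side]
        return recover_stress(mesh, self.C_per_body[name], res.u[name],
                              frames=self.model.meniscus_frames[side])

    def tear_tip_series_ids(self):
        """Element ids matching the model's tear-tip grid tags."""
        from ..synth.geometry import matched_elements
        return matched_elements(self.model, self.model.tear_tip_grid)
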