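"""Quasi-static penalty contact solver for the tibiofemoral joint.

The solver finds elastic displacement fields for the deformable bodies
(menisci, tibial cartilage) together with the five knee secondary
kinematics (three tibial translations, varus-valgus and
internal-external rotation) such that the total potential is stationary:

* elastic strain energy of every body (small strain, B-bar hexahedra),
* node-to-rigid-surface penalty contact: femoral condyle surfaces
  (fixed in the flexed-femur frame) against meniscus/tibial-cartilage
  superior nodes, and the tibia-mounted plateau surface against the
  meniscus inferior nodes,
* regularized Coulomb friction (mu from the material spec) opposing
  tangential node motion,
* linear horn-attachment and transverse-ligament springs,
* tension-only nonlinear ligament bundles between femur and tibia,
* the external knee reaction wrench from the musculoskeletal stage.

Frames: the computation frame is the tibia reference frame (elastic
DOFs, tibia-mounted masters); the femur-frame masters and ligament
origins see slave points mapped by the current secondary kinematics,
``p_F = k + t + R(vv, ie) (p - k)`` about the knee centre ``k``.
Newton iterations use a Gauss-Newton contact Hessian, sparse
factorization of the elastic block and dense bordering for the five
pose DOFs, with a backtracking line search on the residual norm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spl

from ..frames import rot_x, rot_y
from ..passive import LigamentBundle, ligament_force, ligament_stiffness


@dataclass
class RigidSphere:
    center: np.ndarray
    radius: float

    def gap_normal(self, points: np.ndarray):
        d = np.atleast_2d(points) - self.center
        r = np.maximum(np.linalg.norm(d, axis=1), 1e-12)
        return r - self.radius, d / r[:, None]


@dataclass
class RigidPlane:
    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.normal = np.asarray(self.normal, float)
        self.normal = self.normal / np.linalg.norm(self.normal)

    def gap_normal(self, points: np.ndarray):
        g = (np.atleast_2d(points) - self.point) @ self.normal
        n = np.broadcast_to(self.normal, (len(np.atleast_2d(points)), 3)).copy()
        return g, n


@dataclass
class ContactSet:
    """One contact pair: slave nodes of a deformable body against a
    rigid master surface."""

    name: str
    body: str
    node_ids: np.ndarray
    areas: np.ndarray                  # tributary areas, mm^2
    master: object                     # needs .gap_normal(points)
    master_frame: str = "tibia"        # "tibia" (fixed) or "femur" (pose-mapped)


@dataclass
class NodeSpring:
    body: str
    node_id: int
    anchor: np.ndarray
    stiffness: float
    rest_length: float


@dataclass
class InterSpring:
    body_a: str
    node_a: int
    body_b: str
    node_b: int
    stiffness: float
    rest_length: float


@dataclass
class LigamentElement:
    bundle: LigamentBundle
    origin_femur: np.ndarray          # flexed-femur frame
    insertion_tibia: np.ndarray       # tibia frame


@dataclass
class ContactResultSet:
    force: np.ndarray                 # (3,) resultant on the slave body, femur frame
    peak_pressure: float              # MPa
    contact_area: float               # mm^2 of nodes in contact
    max_penetration: float            # mm
    pressures: np.ndarray             # per-slave-node MPa


@dataclass
class SolveResult:
    u: dict                           # body -> (n, 3) displacements (tibia frame)
    pose: np.ndarray                  # (5,) [tx, ty, tz, varus, introt]
    sets: dict                        # name -> ContactResultSet
    ligament_forces: dict             # label -> N
    converged: bool
    iterations: int
    residual_norm: float
    residual_history: list = field(default_factory=list)


def _pose_rotation(pose: np.ndarray):
    R = rot_x(pose[3]) @ rot_y(pose[4])
    dRdv = _drot_x(pose[3]) @ rot_y(pose[4])
    dRdi = rot_x(pose[3]) @ _drot_y(pose[4])
    return R, dRdv, dRdi


def _drot_x(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[0.0, 0.0, 0.0], [0.0, -s, -c], [0.0, c, -s]])


def _drot_y(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[-s, 0.0, c], [0.0, 0.0, 0.0], [-c, 0.0, -s]])


def tributary_areas(nodes: np.ndarray, elems: np.ndarray,
                    node_set: np.ndarray) -> np.ndarray:
    """Tributary area per node of a boundary patch.

    Boundary faces (element faces not shared by two elements) whose four
    corners all belong to ``node_set`` contribute a quarter of their
    area to each corner.  Returns areas aligned with ``node_set``.
    """
    face_local = [
        (0, 1, 2, 3), (4, 5, 6, 7), (0, 1, 5, 4),
        (2, 3, 7, 6), (1, 2, 6, 5), (0, 3, 7, 4),
    ]
    count: dict[tuple, tuple] = {}
    for conn in elems:
        for fl in face_local:
            quad = tuple(int(conn[a]) for a in fl)
            key = tuple(sorted(quad))
            if key in count:
                count[key] = (count[key][0] + 1, quad)
            else:
                count[key] = (1, quad)
    in_set = np.zeros(nodes.shape[0], dtype=bool)
    in_set[node_set] = True
    areas = np.zeros(nodes.shape[0])
    for key, (c, quad) in count.items():
        if c != 1 or not all(in_set[q] for q in quad):
            continue
        p = nodes[list(quad)]
        a = 0.5 * np.linalg.norm(np.cross(p[2] - p[0], p[3] - p[1]))
        for q in quad:
            areas[q] += a / 4.0
    return areas[node_set]


class PenaltyContactSolver:
    """Assembles and solves one quasi-static knee (or test) contact problem."""

    def __init__(self, bodies: dict, contact_sets: list, springs: list = (),
                 inter_springs: list = (), ligaments: list = (),
                 knee_center: np.ndarray | None = None,
                 penalty_per_area: float = 250.0,       # N/mm^2 per mm penetration (MPa/mm)
                 friction: float = 0.0,
                 friction_reg: float = 0.6,             # mm slip regularization
                 pose_free: bool = False,
                 pose_regularization: float = 1e-2):
        self.bodies = bodies            # name -> dict(nodes, K (csr), free_mask (n,) bool)
        self.contact_sets = list(contact_sets)
        self.springs = list(springs)
        self.inter_springs = list(inter_springs)
        self.ligaments = list(ligaments)
        self.knee_center = np.zeros(3) if knee_center is None else np.asarray(knee_center, float)
        self.penalty = penalty_per_area
        self.mu = friction
        self.friction_reg = friction_reg
        self.pose_free = pose_free
        self.pose_reg = pose_regularization

        # dof layout: per body, free nodes only
        self.offsets = {}
        off = 0
        for name, b in self.bodies.items():
            free = np.flatnonzero(b["free_mask"])
            b["free_nodes"] = free
            b["dof_of_node"] = -np.ones(b["nodes"].shape[0], dtype=int)
            b["dof_of_node"][free] = off + 3 * np.arange(free.size)
            self.offsets[name] = off
            off += 3 * free.size
        self.n_u = off
        self.n_q = 5 if pose_free else 0

        # reduced elastic stiffness blocks
        blocks = []
        for name, b in self.bodies.items():
            free = b["free_nodes"]
            dofs = (3 * free[:, None] + np.arange(3)[None, :]).ravel()
            blocks.append(b["K"][np.ix_(dofs, dofs)])
        self.K_red = sp.block_diag(blocks, format="csr") if blocks else sp.csr_matrix((0, 0))

    # -- geometry helpers ---------------------------------------------------

    def _positions(self, name: str, u: np.ndarray) -> np.ndarray:
        b = self.bodies[name]
        pos = b["nodes"].copy()
        dof = b["dof_of_node"]
        has = dof >= 0
        pos[has] += u[dof[has][:, None] + np.arange(3)].reshape(-1, 3)
        return pos

    def node_disp(self, name: str, u: np.ndarray) -> np.ndarray:
        b = self.bodies[name]
        out = np.zeros_like(b["nodes"])
        dof = b["dof_of_node"]
        has = dof >= 0
        out[has] = u[dof[has][:, None] + np.arange(3)].reshape(-1, 3)
        return out

    # -- assembly -----------------------------------------------------------

    def friction_forces(self, x: np.ndarray) -> np.ndarray:
        """Regularized Coulomb friction nodal forces at state ``x``.

        Friction enters the solve as a frozen external force updated in
        an outer fixed point (Jacobi style), so the inner Newton
        iteration minimizes an exact potential.  Slip is the tangential
        nodal displacement accumulated in this solve.
        """
        u = x[:self.n_u]
        pose = x[self.n_u:] if self.pose_free else np.zeros(5)
        R, _, _ = _pose_rotation(pose)
        out = np.zeros(self.n_u)
        if self.mu <= 0:
            return out
        for cs in self.contact_sets:
            body = self.bodies[cs.body]
            dof = body["dof_of_node"][cs.node_ids]
            pos_t = self._positions(cs.body, u)[cs.node_ids]
            if cs.master_frame == "femur" and self.pose_free:
                pos_m = self.knee_center + pose[0:3] + (pos_t - self.knee_center) @ R.T
            else:
                pos_m = pos_t
            gaps, normals = cs.master.gap_normal(pos_m)
            pen = np.maximum(-gaps, 0.0)
            fmag = self.penalty * cs.areas * pen
            for i in np.flatnonzero(pen > 0):
                if dof[i] < 0:
                    continue
                n = normals[i]
                v_u = (R.T @ n) if (cs.master_frame == "femur" and self.pose_free) else n
                ut = u[dof[i]:dof[i] + 3]
                ut_t = ut - (ut @ v_u) * v_u
                nrm = np.sqrt(ut_t @ ut_t + self.friction_reg**2)
                out[dof[i]:dof[i] + 3] += -self.mu * fmag[i] * ut_t / nrm
        return out

    def _grad_hess(self, x: np.ndarray, wrench=None, collect=False,
                   fric: np.ndarray | None = None):
        u = x[:self.n_u]
        pose = x[self.n_u:] if self.pose_free else np.zeros(5)
        k_c = self.knee_center
        R, dRdv, dRdi = _pose_rotation(pose)

        grad = np.zeros_like(x)
        H_extra_rows, H_extra_cols, H_extra_vals = [], [], []
        Hq = np.zeros((self.n_q, self.n_q))
        Cuq = np.zeros((self.n_u, self.n_q)) if self.pose_free else None
        set_results = {}

        # elastic
        grad[:self.n_u] += self.K_red @ u

        # contact
        for cs in self.contact_sets:
            body = self.bodies[cs.body]
            dof = body["dof_of_node"][cs.node_ids]
            pos_t = self._positions(cs.body, u)[cs.node_ids]
            if cs.master_frame == "femur" and self.pose_free:
                rel = pos_t - k_c
                pos_m = k_c + pose[0:3] + rel @ R.T
            elif cs.master_frame == "femur":
                pos_m = pos_t
            else:
                pos_m = pos_t
            gaps, normals = cs.master.gap_normal(pos_m)
            pen = np.maximum(-gaps, 0.0)
            kappa = self.penalty * cs.areas
            fmag = kappa * pen
            active = pen > 0

            force_sum = np.zeros(3)
            for i in np.flatnonzero(active):
                n = normals[i]
                f = fmag[i]
                force_sum += f * n
                # derivative of gap wrt u: n . R du ; wrt pose: [n, n.(dR rel)]
                v_u = (R.T @ n) if (cs.master_frame == "femur" and self.pose_free) else n
                if dof[i] >= 0:
                    grad[dof[i]:dof[i] + 3] += -f * v_u
                    blk = kappa[i] * np.outer(v_u, v_u)
                    H_extra_rows.append(dof[i]); H_extra_vals.append(blk)
                if cs.master_frame == "femur" and self.pose_free:
                    rel_i = pos_t[i] - k_c
                    v_q = np.array([n[0], n[1], n[2],
                                    n @ (dRdv @ rel_i), n @ (dRdi @ rel_i)])
                    grad[self.n_u:] += -f * v_q
                    Hq += kappa[i] * np.outer(v_q, v_q)
                    if dof[i] >= 0:
                        Cuq[dof[i]:dof[i] + 3] += kappa[i] * np.outer(v_u, v_q)
            if collect:
                pressures = self.penalty * pen
                set_results[cs.name] = ContactResultSet(
                    force=force_sum,
                    peak_pressure=float(pressures.max(initial=0.0)),
                    contact_area=float(cs.areas[active].sum()),
                    max_penetration=float(pen.max(initial=0.0)),
                    pressures=pressures,
                )

        # node springs (tibia-frame anchors)
        for s in self.springs:
            body = self.bodies[s.body]
            d = body["dof_of_node"][s.node_id]
            p = body["nodes"][s.node_id] + (u[d:d + 3] if d >= 0 else 0.0)
            dvec = p - s.anchor
            l = max(np.linalg.norm(dvec), 1e-9)
            e = dvec / l
            f = s.stiffness * (l - s.rest_length)
            if d >= 0:
                grad[d:d + 3] += f * e
                Hb = s.stiffness * np.outer(e, e)
                if l > 1e-6:
                    Hb += (f / l) * (np.eye(3) - np.outer(e, e))
                H_extra_rows.append(d); H_extra_vals.append(Hb)

        for s in self.inter_springs:
            ba, bb = self.bodies[s.body_a], self.bodies[s.body_b]
            da, db = ba["dof_of_node"][s.node_a], bb["dof_of_node"][s.node_b]
            pa = ba["nodes"][s.node_a] + (u[da:da + 3] if da >= 0 else 0.0)
            pb = bb["nodes"][s.node_b] + (u[db:db + 3] if db >= 0 else 0.0)
            dvec = pa - pb
            l = max(np.linalg.norm(dvec), 1e-9)
            e = dvec / l
            f = s.stiffness * (l - s.rest_length)
            Hb = s.stiffness * np.outer(e, e) + (f / l) * (np.eye(3) - np.outer(e, e))
            if da >= 0:
                grad[da:da + 3] += f * e
                H_extra_rows.append(da); H_extra_vals.append(Hb)
            if db >= 0:
                grad[db:db + 3] += -f * e
                H_extra_rows.append(db); H_extra_vals.append(Hb)
            # cross coupling neglected in the Hessian (kept SPD; Newton still converges)

        lig_forces = {}
        if self.ligaments and self.pose_free:
            for le in self.ligaments:
                ins = k_c + pose[0:3] + R @ (le.insertion_tibia - k_c)
                dvec = le.origin_femur - ins
                l = max(np.linalg.norm(dvec), 1e-9)
                e = dvec / l
                f = ligament_force(le.bundle, l)
                lig_forces[le.bundle.label] = f
                if f == 0.0 and ligament_stiffness(le.bundle, l) == 0.0:
                    continue
                rel = le.insertion_tibia - k_c
                # dl/dq = -e . d(ins)/dq
                dins = np.zeros((3, 5))
                dins[:, 0:3] = np.eye(3)
                dins[:, 3] = dRdv @ rel
                dins[:, 4] = dRdi @ rel
                dldq = -(e @ dins)
                grad[self.n_u:] += f * dldq
                kq = ligament_stiffness(le.bundle, l)
                Hq += kq * np.outer(dldq, dldq) + (f / l) * (dins.T @ dins - np.outer(dldq, dldq))

        # external wrench on the tibia (femur/solve frame)
        if wrench is not None and self.pose_free:
            F, m_vv, m_ie = wrench
            grad[self.n_u:self.n_u + 3] += -np.asarray(F, float)
            grad[self.n_u + 3] += -m_vv
            grad[self.n_u + 4] += -m_ie

        if self.pose_free:
            reg = np.array([self.pose_reg] * 3 + [self.pose_reg * 1e4] * 2)
            grad[self.n_u:] += reg * pose
            Hq += np.diag(reg)

        if fric is not None and self.n_u:
            grad[:self.n_u] -= fric

        return grad, (H_extra_rows, H_extra_vals), Hq, Cuq, set_results, lig_forces

    def _ligament_energy(self, bundle: LigamentBundle, l: float) -> float:
        l0, eps_l = bundle.l0, bundle.eps_l
        if l <= l0:
            return 0.0
        l_t = l0 * (1.0 + 2.0 * eps_l)
        a = (1.0 + eps_l) * l0
        if l <= l_t:
            return bundle.k1 * (l - l0) ** 3 / 3.0
        e_t = bundle.k1 * (l_t - l0) ** 3 / 3.0
        return e_t + 0.5 * bundle.k2 * ((l - a) ** 2 - (l_t - a) ** 2)

    def _energy(self, x: np.ndarray, wrench=None,
                fric: np.ndarray | None = None) -> float:
        """Total potential (friction excluded): the line-search merit."""
        u = x[:self.n_u]
        pose = x[self.n_u:] if self.pose_free else np.zeros(5)
        k_c = self.knee_center
        R, _, _ = _pose_rotation(pose)
        E = 0.5 * float(u @ (self.K_red @ u)) if self.n_u else 0.0

        for cs in self.contact_sets:
            pos_t = self._positions(cs.body, u)[cs.node_ids]
            if cs.master_frame == "femur" and self.pose_free:
                pos_m = k_c + pose[0:3] + (pos_t - k_c) @ R.T
            else:
                pos_m = pos_t
            gaps, _ = cs.master.gap_normal(pos_m)
            pen = np.maximum(-gaps, 0.0)
            E += 0.5 * float(np.sum(self.penalty * cs.areas * pen**2))

        for s in self.springs:
            body = self.bodies[s.body]
            d = body["dof_of_node"][s.node_id]
            p = body["nodes"][s.node_id] + (u[d:d + 3] if d >= 0 else 0.0)
            l = np.linalg.norm(p - s.anchor)
            E += 0.5 * s.stiffness * (l - s.rest_length) ** 2
        for s in self.inter_springs:
            ba, bb = self.bodies[s.body_a], self.bodies[s.body_b]
            da, db = ba["dof_of_node"][s.node_a], bb["dof_of_node"][s.node_b]
            pa = ba["nodes"][s.node_a] + (u[da:da + 3] if da >= 0 else 0.0)
            pb = bb["nodes"][s.node_b] + (u[db:db + 3] if db >= 0 else 0.0)
            l = np.linalg.norm(pa - pb)
            E += 0.5 * s.stiffness * (l - s.rest_length) ** 2

        if self.pose_free:
            for le in self.ligaments:
                ins = k_c + pose[0:3] + R @ (le.insertion_tibia - k_c)
                l = float(np.linalg.norm(le.origin_femur - ins))
                E += self._ligament_energy(le.bundle, l)
            if wrench is not None:
                F, m_vv, m_ie = wrench
                E -= float(np.asarray(F, float) @ pose[0:3])
                E -= m_vv * pose[3] + m_ie * pose[4]
            reg = np.array([self.pose_reg] * 3 + [self.pose_reg * 1e4] * 2)
            E += 0.5 * float(reg @ pose**2)
        if fric is not None and self.n_u:
            E -= float(fric @ u)
        return E

    def _build_Huu(self, extra):
        rows, vals = extra
        if not rows:
            return self.K_red.copy()
        n = self.n_u
        r_idx, c_idx, v = [], [], []
        for d, blk in zip(rows, vals):
            for a in range(3):
                for b in range(3):
                    r_idx.append(d + a); c_idx.append(d + b); v.append(blk[a, b])
        A = sp.coo_matrix((v, (r_idx, c_idx)), shape=(n, n)).tocsr()
        return self.K_red + A

    def solve(self, wrench=None, pose0: np.ndarray | None = None,
              u0: np.ndarray | None = None, tol_force: float = 0.05,
              max_iter: int = 60) -> SolveResult:
        """Solve the quasi-static problem.

        Friction is handled as an outer fixed point: the inner Newton
        iteration (Armijo line search on the exact potential, with the
        current friction forces frozen as external loads) is wrapped in
        a few updates of those forces.  ``tol_force`` is the residual
        infinity-norm tolerance in N (pose-moment rows scaled by a
        characteristic 30 mm arm).  Raises on gross non-convergence,
        reporting the residual history.
        """
        x = np.zeros(self.n_u + self.n_q)
        if u0 is not None:
            x[:self.n_u] = u0
        if self.pose_free and pose0 is not None:
            x[self.n_u:] = pose0
        if self.pose_free:
            x = self._approach(x)

        scale = np.ones_like(x)
        if self.pose_free:
            scale[self.n_u + 3:] = 1.0 / 30.0       # N mm -> comparable N

        hist: list[float] = []
        total_it = 0
        fric = np.zeros(self.n_u)
        n_fp = 3 if self.mu > 0 else 1
        for fp in range(n_fp):
            x, inner_hist, inner_it = self._newton(x, wrench, fric, scale,
                                                   tol_force, max_iter)
            hist.extend(inner_hist)
            total_it += inner_it
            if self.mu <= 0:
                break
            f_new = self.friction_forces(x)
            df = float(np.max(np.abs(f_new - fric))) if self.n_u else 0.0
            # under-relaxed update keeps the fixed point contractive
            fric = 0.5 * fric + 0.5 * f_new
            if df < max(tol_force, 0.1):
                break

        grad, extra, Hq, Cuq, sets, ligf = self._grad_hess(
            x, wrench, collect=True, fric=self.friction_forces(x) if self.mu > 0 else None)
        res = float(np.max(np.abs(grad * scale)))
        converged = res <= tol_force * 20
        if res > tol_force * 100:
            raise RuntimeError(
                f"contact solve did not converge: residual {res:.3g} N after "
                f"{total_it} iterations; history {['%.3g' % h for h in hist[-8:]]}")
        u_out = {name: self.node_disp(name, x[:self.n_u]) for name in self.bodies}
        return SolveResult(
            u=u_out,
            pose=x[self.n_u:] if self.pose_free else np.zeros(5),
            sets=sets,
            ligament_forces=ligf,
            converged=converged,
            iterations=total_it,
            residual_norm=res,
            residual_history=hist,
        )

    def _newton(self, x: np.ndarray, wrench, fric: np.ndarray,
                scale: np.ndarray, tol_force: float, max_iter: int):
        """Inner Newton minimization at frozen friction forces."""
        hist = []
        best_x, best_res = x.copy(), np.inf
        fr = fric if self.mu > 0 else None
        it = 0
        for it in range(1, max_iter + 1):
            grad, extra, Hq, Cuq, _, _ = self._grad_hess(x, wrench, fric=fr)
            res = float(np.max(np.abs(grad * scale))) if grad.size else 0.0
            hist.append(res)
            if res < best_res:
                best_res, best_x = res, x.copy()
            if res < tol_force:
                return x, hist, it
            Huu = self._build_Huu(extra)
            lu = spl.splu(Huu.tocsc())
            gu = grad[:self.n_u]
            if self.pose_free:
                gq = grad[self.n_u:]
                Y = np.column_stack([lu.solve(Cuq[:, j]) for j in range(self.n_q)]) \
                    if self.n_u else np.zeros((0, self.n_q))
                S = Hq - (Cuq.T @ Y if self.n_u else 0.0)
                rhs_q = gq - (Cuq.T @ lu.solve(gu) if self.n_u else 0.0)
                dq = np.linalg.solve(S, rhs_q)
                du = lu.solve(gu - Cuq @ dq) if self.n_u else np.zeros(0)
                step = -np.concatenate([du, dq])
            else:
                step = -lu.solve(gu)

            cap = 1.0
            if self.pose_free:
                rot = np.abs(step[self.n_u + 3:])
                if rot.size and rot.max() > 0.1:
                    cap = min(cap, 0.1 / rot.max())
                tr = np.abs(step[self.n_u:self.n_u + 3])
                if tr.size and tr.max() > 5.0:
                    cap = min(cap, 5.0 / tr.max())
            step = step * cap

            e0 = self._energy(x, wrench, fric=fr)
            slope = float(grad @ step)
            alpha = 1.0
            for _ in range(22):
                if self._energy(x + alpha * step, wrench, fric=fr) \
                        <= e0 + 1e-4 * alpha * slope:
                    break
                alpha *= 0.5
            x = x + alpha * step
        # max_iter reached: keep the best iterate seen
        return (best_x if best_res < hist[-1] else x), hist, it

    def _approach(self, x: np.ndarray, target: float = 0.05) -> np.ndarray:
        """Translate the tibia along y so the femoral masters start just
        engaged (about ``target`` mm of penetration): backs off gross
        initial penetration and closes large initial gaps, both of which
        defeat the Newton iteration."""
        for _ in range(25):
            u = x[:self.n_u]
            pose = x[self.n_u:]
            R, _, _ = _pose_rotation(pose)
            gmin = None
            for cs in self.contact_sets:
                if cs.master_frame != "femur":
                    continue
                pos_t = self._positions(cs.body, u)[cs.node_ids]
                pos_m = self.knee_center + pose[0:3] + (pos_t - self.knee_center) @ R.T
                gaps, _ = cs.master.gap_normal(pos_m)
                g = float(gaps.min())
                gmin = g if gmin is None else min(gmin, g)
            if gmin is None or abs(gmin + target) < 0.02:
                break
            x[self.n_u + 1] += (gmin + target)
        return x
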