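"""Penalty contact solver: analytic oracles and equilibrium invariants."""

import numpy as np
import pytest

from femsgait.fe.contact import (
    ContactSet,
    PenaltyContactSolver,
    RigidPlane,
    RigidSphere,
    tributary_areas,
)
from femsgait.fe.elements import assemble_stiffness
from femsgait.fe.knee import KneeContactSession
from femsgait.fe.materials import isotropic_stiffness
from femsgait.synth.geometry import _box_mesh, build_knee_geometry


@pytest.fixture(scope="module")
def layer():
    """Bonded elastic layer (cartilage material) with its stiffness."""
    E, nu, h = 5.0, 0.46, 1.0
    mesh = _box_mesh(-12, 12, 0, h, -12, 12, 24, 2, 24)
    K = assemble_stiffness(mesh.nodes, mesh.elems, isotropic_stiffness(E, nu))
    free = np.ones(mesh.n_nodes, bool)
    free[mesh.node_sets["bottom"]] = False
    top = mesh.node_sets["top"]
    areas = tributary_areas(mesh.nodes, mesh.elems, top)
    return mesh, K, free, top, areas, h


def _solve_sphere(layer, delta, R=120.0, pen=2000.0):
    mesh, K, free, top, areas, h = layer
    sph = RigidSphere(center=np.array([0.0, h + R - delta, 0.0]), radius=R)
    solver = PenaltyContactSolver(
        bodies={"layer": {"nodes": mesh.nodes.copy(), "K": K,
                          "free_mask": free}},
        contact_sets=[ContactSet("s", "layer", top, areas, sph, "tibia")],
        penalty_per_area=pen, friction=0.0, pose_free=False)
    return solver.solve(tol_force=0.02)


def test_sphere_indentation_tracks_foundation_model(layer):
    """Force-indentation of a rigid sphere on the bonded thin layer follows
    the elastic-foundation closed form (within the finite a/h band)."""
    E, nu, h, R = 5.0, 0.46, 1.0, 120.0
    Ec = E * (1 - nu) / ((1 + nu) * (1 - 2 * nu))
    for delta in (0.25, 0.4):
        res = _solve_sphere(layer, delta)
        F = np.linalg.norm(res.sets["s"].force)
        Fa = np.pi * Ec * R * delta**2 / h
        assert F == pytest.approx(Fa, rel=0.25)   # coarse grid; the tight
        # tolerance case lives in the acceptance suite with a finer mesh


def test_no_load_means_no_contact(layer):
    res = _solve_sphere(layer, -0.5)      # sphere lifted clear of the layer
    assert np.linalg.norm(res.sets["s"].force) == 0.0
    assert res.sets["s"].max_penetration == 0.0
    for u in res.u.values():
        assert np.abs(u).max() < 1e-12


def test_force_scales_linearly_in_small_strain(layer):
    """Doubling indentation depth of a flat punch (plane master) doubles
    the force exactly in the linear small-strain regime."""
    mesh, K, free, top, areas, h = layer
    def punch(depth):
        plane = RigidPlane(point=np.array([0.0, h - depth, 0.0]),
                           normal=np.array([0.0, -1.0, 0.0]))
        solver = PenaltyContactSolver(
            bodies={"layer": {"nodes": mesh.nodes.copy(), "K": K,
                              "free_mask": free}},
            contact_sets=[ContactSet("p", "layer", top, areas, plane, "tibia")],
            penalty_per_area=2000.0, friction=0.0, pose_free=False)
        return np.linalg.norm(solver.solve(tol_force=0.01).sets["p"].force)
    f1 = punch(0.01)
    f2 = punch(0.02)
    assert f2 == pytest.approx(2.0 * f1, rel=0.02)


def test_flat_punch_stiffness_is_confined_modulus(layer):
    """Uniform compression against the rigid plane reproduces E_c A / h."""
    mesh, K, free, top, areas, h = layer
    E, nu = 5.0, 0.46
    Ec = E * (1 - nu) / ((1 + nu) * (1 - 2 * nu))
    depth = 0.02
    plane = RigidPlane(point=np.array([0.0, h - depth, 0.0]),
                       normal=np.array([0.0, -1.0, 0.0]))
    solver = PenaltyContactSolver(
        bodies={"layer": {"nodes": mesh.nodes.copy(), "K": K, "free_mask": free}},
        contact_sets=[ContactSet("p", "layer", top, areas, plane, "tibia")],
        penalty_per_area=5000.0, friction=0.0, pose_free=False)
    F = np.linalg.norm(solver.solve(tol_force=0.01).sets["p"].force)
    A = areas.sum()
    # free lateral edges leave a ~h-wide relaxed perimeter band
    assert F == pytest.approx(Ec * A * depth / h, rel=0.25)


# ---------------------------------------------------------------------------
# knee-level equilibrium invariants

@pytest.fixture(scope="module")
def knee_session(knee_model):
    return KneeContactSession(knee_model)


def test_knee_solve_satisfies_global_equilibrium(knee_session):
    W = np.array([30.0, 1500.0, -20.0])
    cr, res = knee_session.solve(flexion=np.deg2rad(15.0),
                                 wrench=(W, 8000.0, 1000.0))
    assert cr.converged
    # residual norm is the out-of-balance force on every node and on the
    # tibia pose DOFs
    assert cr.residual_norm < 4.0
    # vertical equilibrium of the tibia: femoral-side contact carries the
    # applied vertical load (ligaments/capsule take the remainder)
    fy = sum(f[1] for n, f in cr.forces.items() if n.startswith("femoral"))
    assert fy < 0 and abs(fy) > 0.7 * W[1]


def test_zero_wrench_leaves_joint_nearly_unloaded(knee_session):
    cr, res = knee_session.solve(flexion=np.deg2rad(10.0),
                                 wrench=(np.zeros(3), 0.0, 0.0),
                                 warm_start=False)
    total = sum(np.linalg.norm(f) for f in cr.forces.values())
    # only ligament pretension holds the joint together: small forces,
    # near-reference secondary kinematics
    assert total < 250.0
    assert np.abs(cr.e_s[:3]).max() < 2.0
    assert np.abs(cr.e_s[3:]).max() < 0.05


def test_contact_pressures_are_nonnegative_and_penetration_bounded(knee_session):
    cr, res = knee_session.solve(flexion=np.deg2rad(15.0),
                                 wrench=(np.array([0.0, 2000.0, 0.0]), 10000.0, 0.0))
    for name, rs in res.sets.items():
        assert np.all(rs.pressures >= 0.0)
    # penalty-consistent bound: pressure / penalty
    max_p = max(rs.peak_pressure for rs in res.sets.values())
    assert cr.max_penetration <= max_p / 400.0 + 1e-9


def test_varus_moment_shifts_load_medially(knee_session):
    lo, _ = knee_session.solve(flexion=np.deg2rad(15.0),
                               wrench=(np.array([0.0, 1600.0, 0.0]), 0.0, 0.0),
                               warm_start=False)
    hi, _ = knee_session.solve(flexion=np.deg2rad(15.0),
                               wrench=(np.array([0.0, 1600.0, 0.0]), 15000.0, 0.0),
                               warm_start=False)
    def med(c):
        return (np.linalg.norm(c.forces["femoral_cartilage-medial_meniscus"])
                + np.linalg.norm(c.forces["femoral_cartilage-medial_tibial_cartilage"]))
    assert med(hi) > med(lo)


def test_total_contact_force_stable_under_mesh_refinement():
    """Refining the knee mesh ~3x changes the total femoral contact force
    by well under 5% on the standard load case."""
    from femsgait.synth.geometry import KneeGeometrySpec
    W = (np.array([0.0, 1600.0, 0.0]), 10000.0, 0.0)
    totals = []
    for spec in (KneeGeometrySpec(),
                 KneeGeometrySpec(n_circ=27, n_rad=6, n_ax=3,
                                  cart_nx=9, cart_nz=10, cart_ny=3)):
        sess = KneeContactSession(build_knee_geometry(spec))
        cr, _ = sess.solve(flexion=np.deg2rad(15.0), wrench=W)
        totals.append(sum(np.linalg.norm(f) for n, f in cr.forces.items()
                          if n.startswith("femoral")))
    assert abs(totals[1] - totals[0]) / totals[0] < 0.05
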