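"""Muscle paths, wrapping, moment arms, Hill force, static optimization."""

import numpy as np
import pytest

from femsgait.linkage import MOMENT_DOF_NAMES
from femsgait.muscles import (
    MuscleGeometry,
    MuscleUnit,
    compute_muscle_geometry,
    cylinder_wrap_path,
    hill_force,
    muscle_path_length,
    reference_pose,
    update_geometry_with_secondary,
)
from femsgait.staticopt import (
    activation_lp_matrices,
    kkt_residual,
    solve_static_optimization,
)

DOF_IDX = {"hip_flex": 6, "hip_add": 7, "hip_rot": 8, "knee_flex": 9, "ankle_df": 10}


def test_muscle_set_has_the_twenty_units(muscles):
    assert len(muscles) == 20
    names = [m.name for m in muscles]
    assert sum(n.startswith("gluteus_maximus") for n in names) == 3
    for required in ("iliopsoas", "pectineus", "rectus_femoris", "soleus",
                     "semimembranosus", "semitendinosus", "tibialis_anterior",
                     "tibialis_posterior", "extensor_hallucis_longus",
                     "extensor_digitorum_longus"):
        assert required in names
    assert sum(n.startswith("biceps_femoris") for n in names) == 2
    assert sum(n.startswith("gastrocnemius") for n in names) == 2
    assert sum(n.startswith("vastus") for n in names) == 3


# ---------------------------------------------------------------------------
# wrapping

def test_planar_wrap_matches_tangent_arc_formula():
    R, d = 10.0, 30.0
    p1 = np.array([-d, 0.0, 0.0])
    p2 = np.array([d, 0.0, 0.0])
    axis_p = np.array([0.0, 5.0, 0.0])   # segment passes 5 under the axis
    L, qa, qb, wrapped = cylinder_wrap_path(p1, p2, axis_p, np.array([0, 0, 1.0]), R)
    assert wrapped
    # closed form: both points at distance sqrt(d^2+25) from the axis
    dd = np.hypot(d, 5.0)
    alpha = 2.0 * np.arctan2(d, 5.0)               # angle between P1, P2 about axis
    tau = alpha - 2.0 * np.arccos(R / dd)
    L_ref = 2.0 * np.sqrt(dd**2 - R**2) + R * tau
    assert L == pytest.approx(L_ref, rel=1e-9)
    assert np.linalg.norm(qa - axis_p) == pytest.approx(R, rel=1e-9)


def test_clearing_segment_is_straight():
    L, qa, qb, wrapped = cylinder_wrap_path(
        np.array([-30.0, 20.0, 0.0]), np.array([30.0, 20.0, 0.0]),
        np.zeros(3), np.array([0, 0, 1.0]), 10.0)
    assert not wrapped and L == pytest.approx(60.0)


def test_point_inside_cylinder_raises():
    with pytest.raises(ValueError, match="inside"):
        cylinder_wrap_path(np.array([1.0, 0, 0]), np.array([30.0, 0, 0]),
                           np.zeros(3), np.array([0, 0, 1.0]), 10.0)


# ---------------------------------------------------------------------------
# moment arms

def test_straight_muscle_over_hinge_has_arm_equal_to_offset(linkage):
    # two-point muscle crossing the ankle hinge at a known perpendicular
    # distance: tendon-excursion arm equals that distance
    mu = MuscleUnit("toy", 100.0, 50.0, ["shank", "foot"],
                    np.array([[0.0, -100.0, 0.0],
                              [60.0, -linkage.segments["shank"].length, 0.0]]))
    mu.l_opt_eff = mu.l_opt
    q = reference_pose(linkage)
    geom = compute_muscle_geometry(linkage, q, [mu])
    # the geometric arm about the ankle: perpendicular distance of the
    # line of action from the joint centre
    i = DOF_IDX["ankle_df"]
    h = 1e-5
    qa, qb = q.copy(), q.copy()
    qa[i] += h
    qb[i] -= h
    fd = -(muscle_path_length(mu, linkage, qa) - muscle_path_length(mu, linkage, qb)) / (2 * h)
    assert geom.arms[4, 0] == pytest.approx(fd, abs=1e-6)


@pytest.mark.parametrize("seed", range(3))
def test_arms_match_central_difference_of_length(muscles, linkage, seed):
    rng = np.random.default_rng(seed)
    q = reference_pose(linkage)
    q[6:11] += rng.uniform(-0.25, 0.25, 5)
    geom = compute_muscle_geometry(linkage, q, muscles)
    h = 1e-5
    for im in rng.choice(len(muscles), 6, replace=False):
        for ik, dof in enumerate(MOMENT_DOF_NAMES):
            qa, qb = q.copy(), q.copy()
            qa[DOF_IDX[dof]] += h
            qb[DOF_IDX[dof]] -= h
            fd = -(muscle_path_length(muscles[im], linkage, qa)
                   - muscle_path_length(muscles[im], linkage, qb)) / (2 * h)
            assert geom.arms[ik, im] == pytest.approx(fd, abs=1e-6)


def test_secondary_kinematics_update_is_stateless(muscles, linkage):
    q = reference_pose(linkage)
    base = compute_muscle_geometry(linkage, q, muscles)
    zero = update_geometry_with_secondary(linkage, q, muscles, np.zeros(5))
    np.testing.assert_allclose(zero.lengths, base.lengths, atol=1e-12)
    shifted = update_geometry_with_secondary(
        linkage, q, muscles, np.array([5.0, 0, 0, 0, 0]))
    back = update_geometry_with_secondary(linkage, q, muscles, np.zeros(5))
    np.testing.assert_allclose(back.lengths, base.lengths, atol=1e-12)
    # anterior tibial translation lengthens the hamstrings
    for nm in ("semimembranosus", "semitendinosus", "biceps_femoris_long"):
        im = base.names.index(nm)
        assert shifted.lengths[im] > base.lengths[im]
        assert shifted.lengths[im] - base.lengths[im] < 5.0 + 1e-9


# ---------------------------------------------------------------------------
# Hill force

def test_hill_force_definition_and_slack():
    mu = MuscleUnit("toy", 500.0, 100.0, ["thigh", "shank"],
                    np.zeros((2, 3)) + [[0, 0, 0], [0, -100, 0]])
    assert hill_force(mu, 0.0, 0.9) == 0.0                      # passive slack
    at_opt = hill_force(mu, 1.0, 1.0)
    assert at_opt == pytest.approx(500.0 * (mu.f_active(1.0) + mu.f_passive(1.0)))
    rng = np.random.default_rng(0)
    for _ in range(50):
        a = rng.uniform(0, 1)
        l = rng.uniform(0.7, 1.4)
        want = 500.0 * (a * mu.f_active(l) + mu.f_passive(l))
        assert hill_force(mu, a, l) == pytest.approx(want, rel=1e-12)
    # monotone non-decreasing in activation
    assert hill_force(mu, 0.8, 1.1) >= hill_force(mu, 0.3, 1.1)


# ---------------------------------------------------------------------------
# static optimization

def _toy_problem(n_m, n_c, rng, feasible=True):
    muscles = []
    for i in range(n_m):
        mu = MuscleUnit(f"m{i}", float(rng.uniform(200, 1500)), 100.0,
                        ["thigh", "shank"],
                        np.array([[0.0, 0.0, 0.0], [0.0, -100.0, 0.0]]))
        mu.l_opt_eff = mu.l_opt
        mu.l_slack = 0.0
        muscles.append(mu)
    arms = np.zeros((5, n_m))
    arms[:n_c] = rng.uniform(-50, 50, size=(n_c, n_m))
    geom = MuscleGeometry(
        names=[m.name for m in muscles],
        lengths=np.full(n_m, 100.0), lnorm=np.ones(n_m),
        arms=arms, knee_cross_point=np.zeros((n_m, 3)),
        knee_cross_dir=np.zeros((n_m, 3)), crosses_knee=np.zeros(n_m, bool))
    s_star = rng.uniform(0.05, 0.6, n_m)
    A, b0, gain, fp = activation_lp_matrices(geom, muscles, np.zeros(5))
    tau = np.zeros(5)
    tau[:n_c] = (A @ s_star)[:n_c]
    return muscles, geom, tau


def test_single_muscle_equality_recovers_activation():
    rng = np.random.default_rng(1)
    muscles, geom, _ = _toy_problem(1, 1, rng)
    r = geom.arms[0, 0]
    fmax = muscles[0].fmax
    target_s = 0.37
    tau = np.zeros(5)
    tau[0] = r * fmax * muscles[0].f_active(1.0) * target_s
    sol = solve_static_optimization(tau, geom, muscles, moment_tol=1e-6)
    assert sol.feasible
    assert sol.activations[0] == pytest.approx(target_s, abs=1e-8)


def test_zero_moments_give_zero_activations(muscles, linkage):
    q = reference_pose(linkage)
    geom = compute_muscle_geometry(linkage, q, muscles)
    # at the calibration pose all passive forces vanish
    sol = solve_static_optimization(np.zeros(5), geom, muscles, moment_tol=1e-6)
    assert sol.feasible
    assert sol.objective == pytest.approx(0.0, abs=1e-9)
    assert np.all(sol.activations <= 1e-4)


def test_two_synergists_match_grid_search():
    rng = np.random.default_rng(3)
    muscles, geom, tau = _toy_problem(2, 1, rng)
    sol = solve_static_optimization(tau, geom, muscles, moment_tol=1e-6)
    assert sol.feasible
    A, b, gain, fp = activation_lp_matrices(geom, muscles, tau)
    # brute-force 1e-3 grid on s1, s2 solved from the constraint
    best = None
    for s1 in np.arange(0.0, 1.0 + 1e-9, 1e-3):
        if abs(A[0, 1]) < 1e-12:
            continue
        s2 = (b[0] - A[0, 0] * s1) / A[0, 1]
        if not 0.0 <= s2 <= 1.0:
            continue
        c = s1**3 + s2**3
        if best is None or c < best[0]:
            best = (c, s1, s2)
    assert best is not None
    assert sol.objective == pytest.approx(best[0], abs=5e-5)
    assert sol.activations[0] == pytest.approx(best[1], abs=2e-3)


@pytest.mark.parametrize("seed", range(8))
def test_random_toy_problems_satisfy_kkt(seed):
    rng = np.random.default_rng(100 + seed)
    n_m = rng.integers(2, 6)
    n_c = rng.integers(1, min(3, n_m) + 1)
    muscles, geom, tau = _toy_problem(int(n_m), int(n_c), rng)
    sol = solve_static_optimization(tau, geom, muscles, moment_tol=1e-6)
    assert sol.feasible
    assert sol.kkt_residual <= 1e-6
    A, b, gain, fp = activation_lp_matrices(geom, muscles, tau)
    assert np.max(np.abs(A @ sol.activations - b)) <= 1e-6
    assert np.all(sol.activations >= -1e-12) and np.all(sol.activations <= 1 + 1e-12)


def test_null_space_perturbations_never_decrease_objective():
    rng = np.random.default_rng(11)
    muscles, geom, tau = _toy_problem(5, 2, rng)
    sol = solve_static_optimization(tau, geom, muscles, moment_tol=1e-6)
    A, b, gain, fp = activation_lp_matrices(geom, muscles, tau)
    _, _, vt = np.linalg.svd(A[:2])
    null = vt[2:]
    s0 = sol.activations
    for _ in range(40):
        d = null.T @ rng.normal(size=null.shape[0])
        for eps in (1e-4, 1e-3):
            s = s0 + eps * d
            if np.any(s < 0) or np.any(s > 1):
                continue
            assert np.sum(s**3) >= sol.objective - 1e-9


def test_doubling_strength_never_increases_cost():
    rng = np.random.default_rng(13)
    muscles, geom, tau = _toy_problem(4, 2, rng)
    sol1 = solve_static_optimization(tau, geom, muscles, moment_tol=1e-6)
    for m in muscles:
        m.fmax *= 2.0
    sol2 = solve_static_optimization(tau, geom, muscles, moment_tol=1e-6)
    assert sol2.feasible
    assert sol2.objective <= sol1.objective + 1e-9


def test_infeasible_demand_is_flagged_with_residual():
    rng = np.random.default_rng(17)
    muscles, geom, _ = _toy_problem(2, 1, rng)
    tau = np.zeros(5)
    tau[0] = 1e9                                  # beyond any capacity
    sol = solve_static_optimization(tau, geom, muscles, moment_tol=1e-3)
    assert not sol.feasible
    assert np.max(np.abs(sol.moment_residual)) > 1.0
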