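"""Ligament bundle law, stiffness table, horn springs, transverse ligament."""

import numpy as np
import pytest

from femsgait.passive import (
    HornAttachment,
    LigamentBundle,
    branch_jump,
    build_horn_springs,
    horn_spring_force,
    ligament_force,
    ligament_stiffness,
    ligament_wrench,
    load_ligament_table,
)


def eq1_reference(k1, k2, l0, eps_l, l):
    """Independent hand evaluation of the piecewise bundle law."""
    eps = (l - l0) / l0
    if eps <= 0:
        return 0.0
    if eps <= 2 * eps_l:
        return k1 * (l - l0) ** 2
    return k2 * (l - (1 + eps_l) * l0)


def test_table_loads_twenty_bundles_with_printed_constants():
    bundles = load_ligament_table()
    assert len(bundles) == 23   # Table row replica counts: 4+4+3+3+3+3+3
    by = {(b.name, b.bundle): (b.k1, b.k2) for b in bundles}
    assert by[("ACL", "anterior")] == (22.48, 83.15)
    assert by[("PCL", "anterior")] == (31.26, 125.00)
    assert by[("MCL", "deep")] == (5.00, 21.07)
    assert by[("OPL", "main")] == (3.00, 21.42)
    names = {b.name for b in bundles}
    assert names == {"ACL", "PCL", "MCL", "PMC", "LCL", "ALS", "OPL"}
    assert all(b.eps_l == 0.03 for b in bundles)


def test_acl_anterior_worked_values():
    b = LigamentBundle("ACL", "anterior", 0, k1=22.48, k2=83.15, l0=30.0)
    # toe region: eps = 0.05 <= 2*eps_l
    assert ligament_force(b, 31.5) == pytest.approx(22.48 * 1.5**2, rel=1e-12)
    assert ligament_force(b, 31.5) == pytest.approx(50.58, rel=1e-3)
    # linear region: eps = 0.10
    assert ligament_force(b, 33.0) == pytest.approx(83.15 * (33.0 - 1.03 * 30.0), rel=1e-12)
    assert ligament_force(b, 33.0) == pytest.approx(174.6, rel=1e-3)
    assert ligament_force(b, 30.0) == 0.0
    assert ligament_force(b, 25.0) == 0.0


def test_random_draws_match_hand_evaluation():
    rng = np.random.default_rng(7)
    for _ in range(1000):
        k1 = rng.uniform(1.0, 50.0)
        k2 = rng.uniform(10.0, 150.0)
        l0 = rng.uniform(10.0, 60.0)
        l = l0 * rng.uniform(0.8, 1.3)
        b = LigamentBundle("X", "y", 0, k1=k1, k2=k2, l0=l0)
        want = eq1_reference(k1, k2, l0, 0.03, l)
        got = ligament_force(b, l)
        assert got == pytest.approx(want, rel=1e-10, abs=1e-12)


def test_force_continuous_at_zero_strain_and_monotone_within_branches():
    b = LigamentBundle("X", "y", 0, k1=20.0, k2=80.0, l0=40.0)
    eps = 1e-9
    assert ligament_force(b, 40.0 + eps) < 1e-10
    ls = np.linspace(40.0, 40.0 * 1.06 - 1e-9, 200)
    f = [ligament_force(b, l) for l in ls]
    assert np.all(np.diff(f) >= 0)
    ls2 = np.linspace(40.0 * 1.061, 48.0, 200)
    f2 = [ligament_force(b, l) for l in ls2]
    assert np.all(np.diff(f2) >= 0)
    assert ligament_stiffness(b, 39.0) == 0.0


def test_branch_jump_is_reported_not_smoothed():
    # the printed constants do not generally meet at eps = 2 eps_l
    b = LigamentBundle("ACL", "anterior", 0, k1=22.48, k2=83.15, l0=30.0)
    l_t = 30.0 * 1.06
    below = ligament_force(b, l_t - 1e-6)
    above = ligament_force(b, l_t + 1e-6)
    assert branch_jump(b) == pytest.approx(above - below, abs=1e-3)
    assert abs(branch_jump(b)) > 0.1


def test_horn_springs_reproduce_rod_stiffness():
    # n parallel springs of equal length: total stiffness = E a / l exactly
    n, E, a, l = 6, 100.0, 10.0, 5.0
    horn = np.array([[0.0, 0.0, z] for z in range(n)], dtype=float)
    anchor = horn + np.array([l, 0.0, 0.0])
    att = HornAttachment("medial_anterior", E, a, horn, anchor)
    springs = build_horn_springs(att)
    assert len(springs) == n
    k_total = sum(s.stiffness for s in springs)
    assert k_total == pytest.approx(E * a / l, rel=1e-12)
    # single spring: k = E a / l
    att1 = HornAttachment("h", E, a, horn[:1], anchor[:1])
    (s1,) = build_horn_springs(att1)
    assert s1.stiffness == pytest.approx(200.0, rel=1e-12)
    # doubling length halves stiffness
    att2 = HornAttachment("h", E, a, horn[:1], horn[:1] + np.array([2 * l, 0, 0]))
    (s2,) = build_horn_springs(att2)
    assert s2.stiffness == pytest.approx(s1.stiffness / 2.0, rel=1e-12)


def test_horn_single_axis_pull_test_within_one_percent():
    n, E, a, l = 4, 600.0, 40.0, 6.0
    horn = np.array([[0.0, float(i), 0.0] for i in range(n)])
    anchor = horn + np.array([l, 0.0, 0.0])
    att = HornAttachment("h", E, a, horn, anchor)
    springs = build_horn_springs(att)
    dx = 0.01
    f = sum(horn_spring_force(s, s.horn_node + np.array([dx, 0, 0]))[0]
            for s in springs)
    assert -f / dx == pytest.approx(E * a / l, rel=0.01)


def test_ligament_wrench_matches_cross_product_and_cancels_pairwise():
    b = LigamentBundle("X", "y", 0, k1=20.0, k2=80.0, l0=30.0)
    o = np.array([[5.0, 40.0, 2.0]])
    ins = np.array([[1.0, 8.0, -3.0]])
    about = np.array([0.0, 10.0, 0.0])
    f_t, m_t = ligament_wrench([b], o, ins, about)
    d = o[0] - ins[0]
    l = np.linalg.norm(d)
    f_expect = ligament_force(b, l) * d / l
    np.testing.assert_allclose(f_t, f_expect, rtol=1e-12)
    np.testing.assert_allclose(m_t, np.cross(ins[0] - about, f_expect), rtol=1e-12)
    # femur sees the opposite: internal forces cancel
    f_f, m_f = ligament_wrench([b], o, ins, about)
    np.testing.assert_allclose(f_t + -f_f, 0.0, atol=1e-12)


def test_slack_bundles_produce_zero_wrench():
    b = LigamentBundle("X", "y", 0, k1=20.0, k2=80.0, l0=100.0)
    f, m = ligament_wrench([b], np.array([[0.0, 10.0, 0.0]]),
                           np.array([[0.0, 0.0, 0.0]]), np.zeros(3))
    assert np.allclose(f, 0) and np.allclose(m, 0)
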