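"""Finite-element layer: materials, single-hex responses, stress recovery."""

import numpy as np
import pytest

from femsgait.fe.elements import (
    assemble_stiffness,
    element_stress,
    hex_volumes,
    voigt_to_tensor,
)
from femsgait.fe.materials import (
    MaterialSpec,
    isotropic_stiffness,
    rotate_stiffness,
    transverse_isotropic_stiffness,
)
from femsgait.fe.stress import StressField, recover_stress, tag_tear_tip_stress
from femsgait.frames import axis_angle
from femsgait.synth.geometry import HexMesh

UNIT_NODES = np.array([[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)],
                      dtype=float)
UNIT_CONN = np.array([[0, 4, 6, 2, 1, 5, 7, 3]])


def _uniaxial(C, eps=0.01, axis=0):
    """Stretch the unit cube along `axis` with free lateral faces; return
    (stress Voigt, strain of the two lateral directions)."""
    K = assemble_stiffness(UNIT_NODES, UNIT_CONN, C)
    fixed = {}
    for i, p in enumerate(UNIT_NODES):
        fixed[3 * i + axis] = 0.0 if p[axis] == 0 else eps
    # pin remaining rigid modes at the three origin-edge nodes
    others = [a for a in range(3) if a != axis]
    fixed[3 * 0 + others[0]] = 0.0
    fixed[3 * 0 + others[1]] = 0.0
    second = [i for i, p in enumerate(UNIT_NODES)
              if p[axis] == 1 and p[others[0]] == 0 and p[others[1]] == 0][0]
    fixed[3 * second + others[0]] = 0.0
    u = np.zeros(24)
    for d, v in fixed.items():
        u[d] = v
    free = [d for d in range(24) if d not in fixed]
    rhs = -K[:, list(fixed)].toarray() @ np.array(list(fixed.values()))
    u[free] = np.linalg.solve(K[np.ix_(free, free)].toarray(), rhs[free])
    ue = np.concatenate([u[3 * n:3 * n + 3] for n in UNIT_CONN[0]])
    s = element_stress(UNIT_NODES[UNIT_CONN[0]], C, ue)
    lat = []
    for o in others:
        node1 = [i for i, p in enumerate(UNIT_NODES)
                 if p[o] == 1 and p[axis] == 0 and p[[a for a in others if a != o][0]] == 0][0]
        lat.append(u[3 * node1 + o])
    return s, lat


def test_isotropic_uniaxial_matches_hooke():
    E, nu = 5.0, 0.46
    s, lat = _uniaxial(isotropic_stiffness(E, nu), eps=0.01)
    assert s[0] == pytest.approx(E * 0.01, rel=1e-8)
    assert np.abs(s[1:]).max() < 1e-10
    for strain in lat:
        assert strain == pytest.approx(-nu * 0.01, rel=1e-8)


def test_transversely_isotropic_uniaxial_matches_compliance_matrix():
    C = transverse_isotropic_stiffness(140.0, 20.0, 0.2, 0.3, 10.0)
    S = np.linalg.inv(C)
    eps = 0.01
    # stiff (circumferential) axis
    s_ax, lat_ax = _uniaxial(C, eps, axis=0)
    assert s_ax[0] == pytest.approx(eps / S[0, 0], rel=1e-8)
    assert eps / s_ax[0] == pytest.approx(1.0 / 140.0, rel=1e-8)
    for strain in lat_ax:
        assert strain == pytest.approx(S[1, 0] * s_ax[0], rel=1e-8)
    # transverse axis: modulus ratio is 140/20
    s_tr, _ = _uniaxial(C, eps, axis=1)
    assert s_ax[0] / s_tr[1] == pytest.approx(140.0 / 20.0, rel=1e-8)


def test_rigid_body_motion_carries_zero_energy():
    C = isotropic_stiffness(5.0, 0.46)
    K = assemble_stiffness(UNIT_NODES, UNIT_CONN, C)
    u_t = np.tile([1.0, -2.0, 3.0], 8)
    assert abs(u_t @ (K @ u_t)) < 1e-12
    # small rigid rotation about an arbitrary axis
    R = axis_angle(np.array([1.0, 1.0, 0.3]), 1e-6)
    u_r = ((UNIT_NODES @ R.T) - UNIT_NODES).ravel()[
        np.argsort(np.argsort(np.arange(24)))]
    u_r = np.concatenate([(R @ p - p) for p in UNIT_NODES])
    assert u_r @ (K @ u_r) < 1e-12 * 5.0


def test_rotated_stiffness_preserves_spectrum_and_symmetry():
    C = transverse_isotropic_stiffness(140.0, 20.0, 0.2, 0.3, 10.0)
    R = axis_angle(np.array([0.2, 0.9, 0.4]), 1.1)
    Cr = rotate_stiffness(C, R)
    np.testing.assert_allclose(Cr, Cr.T, atol=1e-9)
    # rotating back recovers the original
    np.testing.assert_allclose(rotate_stiffness(Cr, R.T), C, atol=1e-8)


def test_material_spec_validates_spd_and_friction():
    MaterialSpec()   # defaults are valid
    with pytest.raises(ValueError):
        MaterialSpec(friction=1.5)
    with pytest.raises(ValueError):
        MaterialSpec(cartilage_nu=0.7)


def test_hex_volumes_of_unit_cube():
    assert hex_volumes(UNIT_NODES, UNIT_CONN)[0] == pytest.approx(1.0, rel=1e-12)


# ---------------------------------------------------------------------------
# stress recovery

def test_hydrostatic_state_has_zero_max_shear():
    t = np.eye(3) * -3.7
    field = StressField(tensors=t[None], max_shear=np.array([0.0]))
    w = np.linalg.eigvalsh(t)
    assert 0.5 * (w[2] - w[0]) == pytest.approx(0.0, abs=1e-14)


def test_uniaxial_along_circumferential_axis_projections():
    mesh = HexMesh(nodes=UNIT_NODES, elems=UNIT_CONN)
    C = isotropic_stiffness(10.0, 0.3)
    # impose a pure uniaxial stress state numerically
    E, nu = 10.0, 0.3
    eps = 0.02
    u = np.stack([eps * UNIT_NODES[:, 0],
                  -nu * eps * UNIT_NODES[:, 1],
                  -nu * eps * UNIT_NODES[:, 2]], axis=1)
    frames = np.broadcast_to(np.eye(3), (1, 3, 3))   # c = x
    field = recover_stress(mesh, C, u, frames=frames)
    sigma = E * eps
    assert field.sigma_cc[0] == pytest.approx(sigma, rel=1e-9)
    assert field.max_shear[0] == pytest.approx(sigma / 2.0, rel=1e-9)


def test_principal_decomposition_matches_numpy_eigensolver():
    rng = np.random.default_rng(5)
    tensors = rng.normal(size=(30, 3, 3))
    tensors = 0.5 * (tensors + tensors.transpose(0, 2, 1))
    w = np.linalg.eigvalsh(tensors)
    ms = 0.5 * (w[:, 2] - w[:, 0])
    # independent per-tensor eigen solve
    for t, m in zip(tensors, ms):
        vals = sorted(np.linalg.eigvals(t).real)
        assert m == pytest.approx(0.5 * (vals[2] - vals[0]), abs=1e-10)
        assert m >= 0.0


def test_tear_tip_tagging_scales_linearly_and_rejects_empty():
    field = StressField(tensors=np.zeros((4, 3, 3)),
                        max_shear=np.array([1.0, 3.0, 2.0, 5.0]))
    mx, mn = tag_tear_tip_stress(field, np.array([1, 3]))
    assert (mx, mn) == (5.0, 4.0)
    doubled = StressField(tensors=np.zeros((4, 3, 3)),
                          max_shear=field.max_shear * 2.0)
    mx2, mn2 = tag_tear_tip_stress(doubled, np.array([1, 3]))
    assert (mx2, mn2) == (10.0, 8.0)
    one = tag_tear_tip_stress(field, np.array([2]))
    assert one == (2.0, 2.0)
    with pytest.raises(ValueError):
        tag_tear_tip_stress(field, np.array([], dtype=int))
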