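"""Parametric knee geometry: meshes, tears, material frames."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from femsgait.frames import axis_angle
from femsgait.synth.geometry import (
    KneeGeometrySpec,
    TearSpec,
    apply_radial_tear,
    assign_material_frames,
    audit_mesh,
    build_knee_geometry,
    compute_annulus_frames,
    hex_jacobians,
    matched_elements,
    _connected,
)


def test_default_model_has_all_bodies_and_contact_pairs(knee_model):
    m = knee_model
    assert m.menisci["medial"] is not None and m.menisci["lateral"] is not None
    # five elastic cartilage/meniscus bodies + patellar cartilage
    assert set(m.tibial_cartilage) == {"medial", "lateral"}
    assert m.femoral_cartilage.n_elems > 0
    assert m.patellar_cartilage.n_elems > 0
    assert set(m.rigid_surfaces) == {"femur", "tibia", "patella"}
    assert set(m.contact_pairs) == {
        "femoral_cartilage-medial_meniscus",
        "femoral_cartilage-lateral_meniscus",
        "femoral_cartilage-medial_tibial_cartilage",
        "femoral_cartilage-lateral_tibial_cartilage",
        "femoral_cartilage-patellar_cartilage",
        "medial_meniscus-medial_tibial_cartilage",
        "lateral_meniscus-lateral_tibial_cartilage",
    }
    assert len(m.ligaments) == 23
    assert len(m.horns) == 4
    rep = audit_mesh(m)
    assert all(v["min_jacobian"] > 0 for v in rep.values())


def test_minimal_density_mesh_still_valid():
    spec = KneeGeometrySpec(n_circ=2, n_rad=2, n_ax=2, cart_nx=2, cart_nz=2,
                            cart_ny=2)
    m = build_knee_geometry(spec)
    rep = audit_mesh(m)
    assert all(v["min_jacobian"] > 0 for v in rep.values())


def test_doubling_lengths_scales_nodes_exactly():
    spec = KneeGeometrySpec()
    m1 = build_knee_geometry(spec)
    m2 = build_knee_geometry(spec.scaled(2.0))
    for side in ("medial", "lateral"):
        a, b = m1.menisci[side], m2.menisci[side]
        np.testing.assert_array_equal(a.elems, b.elems)
        np.testing.assert_allclose(b.nodes, 2.0 * a.nodes, rtol=1e-12)


def test_invalid_specs_name_the_field():
    with pytest.raises(ValueError, match="meniscus_inner_radius"):
        KneeGeometrySpec(meniscus_inner_radius=30.0).validate()
    with pytest.raises(ValueError, match="n_circ"):
        KneeGeometrySpec(n_circ=1).validate()
    with pytest.raises(ValueError, match="horn_modulus"):
        KneeGeometrySpec(horn_modulus=-1.0).validate()


@settings(max_examples=8, deadline=None, derandomize=True)
@given(
    ri=st.floats(8.0, 12.0), width=st.floats(8.0, 14.0),
    h=st.floats(4.0, 7.0), nc=st.integers(6, 20), nr=st.integers(2, 5),
)
def test_randomized_spec_sweep_passes_mesh_audit(ri, width, h, nc, nr):
    spec = KneeGeometrySpec(meniscus_inner_radius=ri,
                            meniscus_outer_radius=ri + width,
                            meniscus_height_outer=h,
                            n_circ=nc, n_rad=nr)
    m = build_knee_geometry(spec)
    rep = audit_mesh(m)
    assert all(v["min_jacobian"] > 0 for v in rep.values())


# ---------------------------------------------------------------------------
# tears

def test_tear_removes_elements_monotonically(knee_model):
    counts = []
    for w in (0.33, 0.50, 0.83):
        t = apply_radial_tear(knee_model, TearSpec("midbody", w))
        counts.append(t.menisci["medial"].n_elems)
        assert _connected(t.menisci["medial"])
        assert t.tear_tip_grid is not None and len(t.tear_tip_grid) > 0
    n0 = knee_model.menisci["medial"].n_elems
    assert n0 > counts[0] >= counts[1] >= counts[2]


def test_tear_is_idempotent_in_element_count(knee_model):
    t1 = apply_radial_tear(knee_model, TearSpec("anterior_horn", 0.5))
    t2 = apply_radial_tear(knee_model, TearSpec("anterior_horn", 0.5))
    np.testing.assert_array_equal(t1.menisci["medial"].elems,
                                  t2.menisci["medial"].elems)


def test_zero_width_limit_leaves_mesh_unchanged(knee_model):
    t = apply_radial_tear(knee_model, TearSpec("midbody", 0.05))
    # 0.05 of 4 radial rings rounds to zero removal
    assert t.menisci["medial"].n_elems == knee_model.menisci["medial"].n_elems


def test_tear_width_validation():
    with pytest.raises(ValueError):
        TearSpec("midbody", 1.2).validate()
    with pytest.raises(ValueError):
        TearSpec("lateral_body", 0.5).validate()
    TearSpec(total_meniscectomy=True, width_fraction=5.0).validate()  # flag wins


def test_meniscectomy_removes_body_pairs_horns_and_transverse(knee_model):
    m = apply_radial_tear(knee_model, TearSpec(total_meniscectomy=True))
    assert m.menisci["medial"] is None
    assert all("medial_meniscus" not in p for p in m.contact_pairs)
    assert all(not h.horn.startswith("medial") for h in m.horns)
    assert m.transverse_pairs == []
    assert m.menisci["lateral"] is not None


def test_matched_elements_find_tip_locations_on_intact(knee_model):
    t = apply_radial_tear(knee_model, TearSpec("midbody", 0.83))
    ids = matched_elements(knee_model, t.tear_tip_grid)
    assert len(ids) == len(t.tear_tip_grid)


# ---------------------------------------------------------------------------
# material frames

def test_frames_are_orthonormal_and_tangent(knee_model):
    for side in ("medial", "lateral"):
        triads = knee_model.meniscus_frames[side]
        eye = np.einsum("eij,ekj->eik", triads, triads)
        np.testing.assert_allclose(eye, np.broadcast_to(np.eye(3), eye.shape),
                                   atol=1e-12)
        # axial = circumferential x radial (right-handed)
        np.testing.assert_allclose(np.cross(triads[:, 0], triads[:, 1]),
                                   triads[:, 2], atol=1e-12)


def test_most_anterior_element_tangent_is_mediolateral():
    # at the most anterior point of the ring, the circumferential tangent
    # must align with the Z (mediolateral) axis
    centroids = np.array([[30.0, 0.0, 0.0]])      # anterior of the axis
    triads = compute_annulus_frames(centroids, np.zeros(3), np.array([0.0, 1.0, 0.0]))
    c = triads[0, 0]
    angle = np.degrees(np.arccos(abs(c @ np.array([0.0, 0.0, 1.0]))))
    assert angle < 1.0


def test_frames_rotate_with_the_mesh():
    rng = np.random.default_rng(3)
    centroids = rng.normal(size=(40, 3)) * 10 + np.array([20.0, 0.0, 0.0])
    center = np.zeros(3)
    axis = np.array([0.0, 1.0, 0.0])
    t0 = compute_annulus_frames(centroids, center, axis)
    R = axis_angle(np.array([0.3, 0.5, 0.8]), 0.7)
    t1 = compute_annulus_frames(centroids @ R.T, R @ center, R @ axis)
    np.testing.assert_allclose(t1, np.einsum("ij,ekj->eki", R, t0), atol=1e-10)


def test_degenerate_element_on_axis_raises():
    with pytest.raises(ValueError):
        compute_annulus_frames(np.array([[0.0, 5.0, 0.0]]), np.zeros(3),
                               np.array([0.0, 1.0, 0.0]))
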