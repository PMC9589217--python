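"""Parametric knee geometry.

A fully parametric stand-in for subject-specific, image-derived knee
geometry: femoral condyles are (bi-radius) ellipsoidal caps, the tibial
plateau is a plane with thin elastic cartilage slabs, and each meniscus
is a C-shaped swept wedge meshed with 8-node hexahedra.  The meniscal
superior surface is shaped congruent to the overlying condyle (constant
clearance, clipped between a minimum and maximum wedge height) so both
the direct femur-cartilage path and the meniscal path carry load, as in
the natural joint.

Model frame (also the tibia segment frame, shifted so the plateau bone
surface is at y = 0): X anterior, Y superior, Z lateral, right knee;
medial is -Z.  All lengths mm.

Radial tears are produced exactly the way the source meshes are edited
in practice: by deleting elements of the intact medial meniscus mesh in
one circumferential element column, from the inner rim outward over the
requested fraction of the local width.  Total meniscectomy removes the
medial meniscus body, its horn attachments, the transverse ligament and
the medial meniscal contact pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ..passive import (
    HornAttachment,
    LigamentBundle,
    TRANSVERSE_LIGAMENT_STIFFNESS,
    load_ligament_table,
)

SECTORS = ("posterior_horn", "midbody", "anterior_horn")


@dataclass
class KneeGeometrySpec:
    """Parametric knee dimensions (mm, deg) and mesh density controls."""

    # femoral condyles (sphere/ellipsoid caps); medial/lateral
    condyle_radius_sag_med: float = 25.0
    condyle_radius_sag_lat: float = 24.0
    condyle_radius_frontal_med: float = 25.0
    condyle_radius_frontal_lat: float = 24.0
    condyle_offset_z: float = 23.0          # half distance between condyle axes
    femoral_cartilage_thickness: float = 2.2

    # tibial plateau + cartilage
    plateau_halfwidth_x: float = 24.0
    plateau_halfwidth_z: float = 38.0
    tibial_cartilage_thickness: float = 2.0
    cartilage_pad_x: float = 22.0           # cartilage slab half extents
    cartilage_pad_z: float = 16.0
    cartilage_dish_depth: float = 0.8       # mild concavity of the plateau surface

    # meniscus annulus (per compartment, centred on the condyle axis)
    meniscus_inner_radius: float = 10.5
    meniscus_outer_radius: float = 21.0
    meniscus_height_outer: float = 6.0
    meniscus_height_inner: float = 1.2
    meniscus_clearance: float = 1.8         # superior clearance to the condyle
    meniscus_arc_deg: float = 270.0         # C-shape total arc
    sector_extent_deg: tuple = (90.0, 90.0, 90.0)  # posterior horn, midbody, anterior horn
    horn_anchor_length: float = 6.0         # horn spring nominal length
    horn_modulus: float = 600.0             # MPa, horn attachment Young's modulus

    # mesh density
    n_circ: int = 18
    n_rad: int = 4
    n_ax: int = 2
    cart_nx: int = 6
    cart_nz: int = 7
    cart_ny: int = 2

    def validate(self) -> None:
        for nm in ("condyle_radius_sag_med", "condyle_radius_sag_lat",
                   "condyle_radius_frontal_med", "condyle_radius_frontal_lat",
                   "femoral_cartilage_thickness", "tibial_cartilage_thickness",
                   "meniscus_inner_radius", "meniscus_outer_radius",
                   "meniscus_height_outer", "meniscus_height_inner",
                   "plateau_halfwidth_x", "plateau_halfwidth_z",
                   "cartilage_pad_x", "cartilage_pad_z", "horn_anchor_length",
                   "horn_modulus"):
            if getattr(self, nm) <= 0:
                raise ValueError(f"KneeGeometrySpec.{nm} must be positive")
        if self.meniscus_inner_radius >= self.meniscus_outer_radius:
            raise ValueError("meniscus_inner_radius must be < meniscus_outer_radius")
        if abs(sum(self.sector_extent_deg) - self.meniscus_arc_deg) > 1e-9:
            raise ValueError("sector extents must partition the meniscus arc")
        for nm in ("n_circ", "n_rad", "n_ax", "cart_nx", "cart_nz", "cart_ny"):
            if getattr(self, nm) < 2:
                raise ValueError(f"KneeGeometrySpec.{nm} must be >= 2")

    def scaled(self, factor: float) -> "KneeGeometrySpec":
        """Uniformly scale every length field (topology unchanged)."""
        kw = {}
        for nm in ("condyle_radius_sag_med", "condyle_radius_sag_lat",
                   "condyle_radius_frontal_med", "condyle_radius_frontal_lat",
                   "condyle_offset_z", "femoral_cartilage_thickness",
                   "plateau_halfwidth_x", "plateau_halfwidth_z",
                   "tibial_cartilage_thickness", "cartilage_pad_x",
                   "cartilage_pad_z", "meniscus_inner_radius",
                   "meniscus_outer_radius", "meniscus_height_outer",
                   "meniscus_height_inner", "meniscus_clearance",
                   "horn_anchor_length"):
            kw[nm] = getattr(self, nm) * factor
        return replace(self, **kw)


@dataclass
class TearSpec:
    """A radial tear of the medial meniscus, or total meniscectomy."""

    location: str = "midbody"          # posterior_horn | midbody | anterior_horn
    width_fraction: float = 0.33       # fraction of local meniscus width torn
    position_deg: float = 50.0         # angular position within the sector (%-like, deg from sector start)
    total_meniscectomy: bool = False

    def validate(self) -> None:
        if self.total_meniscectomy:
            return
        if self.location not in SECTORS:
            raise ValueError(f"unknown tear location {self.location!r}")
        if not 0.0 < self.width_fraction < 1.0:
            raise ValueError("width_fraction must lie in (0, 1) unless total_meniscectomy")

    @property
    def label(self) -> str:
        if self.total_meniscectomy:
            return "meniscectomy"
        return f"{self.location}_{int(round(self.width_fraction * 100))}"


@dataclass
class HexMesh:
    """8-node hexahedral mesh with an (i, j, k) structured-grid id per element."""

    nodes: np.ndarray                 # (n, 3)
    elems: np.ndarray                 # (m, 8) int
    grid_index: np.ndarray | None = None   # (m, 3) structured ids (circ, rad, ax)
    node_sets: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elems(self) -> int:
        return self.elems.shape[0]


@dataclass
class TriMesh:
    nodes: np.ndarray
    tris: np.ndarray


@dataclass
class CondyleSurface:
    """Rigid femoral contact surface: condyle cap offset by the femoral
    cartilage thickness (an ellipsoid; a sphere when the radii agree)."""

    center: np.ndarray        # model frame at full extension
    r_sag: float              # effective sagittal radius (incl. cartilage)
    r_frontal: float

    def gap_normal(self, points: np.ndarray):
        """Signed gap (>= 0 outside) and outward normal at slave points.

        For the spherical default this is the exact distance; for the
        ellipsoid it is the standard scaled-radius approximation.
        """
        points = np.atleast_2d(points)
        d = points - self.center
        if abs(self.r_sag - self.r_frontal) < 1e-12:
            r = np.linalg.norm(d, axis=1)
            r = np.maximum(r, 1e-12)
            normal = d / r[:, None]
            return r - self.r_sag, normal
        scale = np.array([self.r_sag, self.r_sag, self.r_frontal])
        dt = d / scale
        rho = np.maximum(np.linalg.norm(dt, axis=1), 1e-12)
        grad = dt / scale
        gn = np.linalg.norm(grad, axis=1)
        gap = (rho - 1.0) * rho / gn        # first-order distance estimate
        normal = grad / gn[:, None]
        return gap, normal


@dataclass
class KneeModel:
    """Geometry + passive structures + contact pairs for one knee variant."""

    spec: KneeGeometrySpec
    variant: str                                       # "intact", "midbody_83", ...
    menisci: dict                                      # side -> HexMesh | None
    meniscus_frames: dict                              # side -> (m, 3, 3) triads (c, r, a)
    meniscus_axis: dict                                # side -> (center, axis_dir)
    tibial_cartilage: dict                             # side -> HexMesh
    femoral_cartilage: HexMesh
    patellar_cartilage: HexMesh
    rigid_surfaces: dict                               # name -> TriMesh
    condyles: dict                                     # side -> CondyleSurface
    knee_center: np.ndarray
    condylar_axis: np.ndarray                          # unit vector through condyle centers
    ligaments: list
    ligament_origins: np.ndarray                       # (nb, 3) femur frame (at extension)
    ligament_insertions: np.ndarray                    # (nb, 3) tibia/model frame
    horns: list                                        # HornAttachment
    transverse_pairs: list                             # [(side_a, node_a, side_b, node_b, k)]
    contact_pairs: list
    tear: TearSpec | None = None
    tear_tip_grid: np.ndarray | None = None            # (n, 3) structured ids of tip elements

    def meniscus_present(self, side: str) -> bool:
        return self.menisci.get(side) is not None


# ---------------------------------------------------------------------------
# mesh construction helpers

def _grid_hex_elems(ni: int, nj: int, nk: int):
    """Element connectivity of an (ni, nj, nk)-cell structured grid with
    node id = (i * (nj+1) + j) * (nk+1) + k.  Returns (elems, grid_index)."""

    def nid(i, j, k):
        return (i * (nj + 1) + j) * (nk + 1) + k

    elems, gidx = [], []
    for i in range(ni):
        for j in range(nj):
            for k in range(nk):
                elems.append([
                    nid(i, j, k), nid(i + 1, j, k), nid(i + 1, j + 1, k), nid(i, j + 1, k),
                    nid(i, j, k + 1), nid(i + 1, j, k + 1), nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1),
                ])
                gidx.append([i, j, k])
    return np.array(elems, dtype=int), np.array(gidx, dtype=int)


def _fix_orientation(nodes: np.ndarray, elems: np.ndarray) -> np.ndarray:
    """Flip left-handed hexahedra (swap bottom/top faces) so all Jacobians
    are positive; structured sweeps can come out uniformly inverted."""
    dets = hex_jacobians(nodes, elems)
    flip = dets.min(axis=1) <= 0
    if flip.any():
        elems = elems.copy()
        elems[flip] = elems[flip][:, [4, 5, 6, 7, 0, 1, 2, 3]]
    return elems


def _meniscus_mesh(spec: KneeGeometrySpec, side: str) -> tuple[HexMesh, np.ndarray, np.ndarray]:
    """Swept C-shaped wedge mesh for one compartment.

    Returns (mesh, center, phi_nodes).  The sweep parameter phi runs
    from the posterior-horn end to the anterior-horn end; for the
    medial side phi is measured about +Y from +X toward +Z, for the
    lateral side the construction is mirrored in z.
    """
    sgn = -1.0 if side == "medial" else 1.0
    zc = sgn * spec.condyle_offset_z
    center = np.array([0.0, 0.0, zc])
    r_eff = (spec.condyle_radius_sag_med if side == "medial" else spec.condyle_radius_sag_lat) \
        + spec.femoral_cartilage_thickness
    y_c = spec.tibial_cartilage_thickness + r_eff

    # C opens toward the intercondylar eminence (z = 0 side)
    arc = np.deg2rad(spec.meniscus_arc_deg)
    phi0 = np.deg2rad(135.0)
    phi = phi0 + np.linspace(0.0, arc, spec.n_circ + 1)

    t_c = spec.tibial_cartilage_thickness
    radii = np.linspace(spec.meniscus_inner_radius, spec.meniscus_outer_radius,
                        spec.n_rad + 1)

    nodes = np.empty(((spec.n_circ + 1), (spec.n_rad + 1), (spec.n_ax + 1), 3))
    for i, ph in enumerate(phi):
        d = np.array([np.cos(ph), 0.0, sgn * np.sin(ph)])
        for j, r in enumerate(radii):
            under = max(r_eff**2 - r**2, 0.0)
            y_sph = y_c - np.sqrt(under)
            h = np.clip(y_sph - t_c - spec.meniscus_clearance,
                        spec.meniscus_height_inner, spec.meniscus_height_outer)
            base = center + r * d + np.array([0.0, t_c, 0.0])
            for k in range(spec.n_ax + 1):
                nodes[i, j, k] = base + np.array([0.0, h * k / spec.n_ax, 0.0])
    flat = nodes.reshape(-1, 3)
    elems, gidx = _grid_hex_elems(spec.n_circ, spec.n_rad, spec.n_ax)
    elems = _fix_orientation(flat, elems)

    n_j, n_k = spec.n_rad + 1, spec.n_ax + 1

    def nid(i, j, k):
        return (i * n_j + j) * n_k + k

    top = [nid(i, j, spec.n_ax) for i in range(spec.n_circ + 1) for j in range(n_j)]
    bottom = [nid(i, j, 0) for i in range(spec.n_circ + 1) for j in range(n_j)]
    post_horn = [nid(0, j, k) for j in range(n_j) for k in range(n_k)]
    ant_horn = [nid(spec.n_circ, j, k) for j in range(n_j) for k in range(n_k)]
    mesh = HexMesh(
        nodes=flat, elems=elems, grid_index=gidx,
        node_sets={
            "top": np.array(top), "bottom": np.array(bottom),
            "posterior_horn_face": np.array(post_horn),
            "anterior_horn_face": np.array(ant_horn),
        },
    )
    return mesh, center, phi


def _box_mesh(x0, x1, y0, y1, z0, z1, nx, ny, nz) -> HexMesh:
    xs, ys, zs = (np.linspace(x0, x1, nx + 1), np.linspace(y0, y1, ny + 1),
                  np.linspace(z0, z1, nz + 1))
    nodes = np.array([[x, y, z] for x in xs for z in zs for y in ys])

    def nid(i, j, k):       # i over x, j over z, k over y
        return (i * (nz + 1) + j) * (ny + 1) + k

    elems, gidx = _grid_hex_elems(nx, nz, ny)
    elems = _fix_orientation(nodes, elems)
    top = [nid(i, j, ny) for i in range(nx + 1) for j in range(nz + 1)]
    bottom = [nid(i, j, 0) for i in range(nx + 1) for j in range(nz + 1)]
    return HexMesh(nodes=nodes, elems=elems, grid_index=gidx,
                   node_sets={"top": np.array(top), "bottom": np.array(bottom)})


def _femoral_cartilage_mesh(spec: KneeGeometrySpec) -> HexMesh:
    """Thin spherical-shell caps over both condyles (one radial layer)."""
    meshes = []
    for side in ("medial", "lateral"):
        sgn = -1.0 if side == "medial" else 1.0
        r_bone = spec.condyle_radius_sag_med if side == "medial" else spec.condyle_radius_sag_lat
        y_c = spec.tibial_cartilage_thickness + r_bone + spec.femoral_cartilage_thickness
        center = np.array([0.0, y_c, sgn * spec.condyle_offset_z])
        n_th, n_ps = 4, 10
        thetas = np.linspace(0.0, np.deg2rad(65.0), n_th + 1)   # from the distal pole
        psis = np.linspace(0.0, 2 * np.pi, n_ps + 1)[:-1]
        nodes = []
        for layer, r in enumerate((r_bone, r_bone + spec.femoral_cartilage_thickness)):
            for th in thetas:
                for ps in psis:
                    nodes.append(center + r * np.array([
                        np.sin(th) * np.cos(ps), -np.cos(th), np.sin(th) * np.sin(ps)]))
        nodes = np.array(nodes)
        n_ring = len(psis)

        def nid(layer, it, ip):
            return layer * (n_th + 1) * n_ring + it * n_ring + (ip % n_ring)

        elems = []
        for it in range(1, n_th):       # skip the degenerate pole ring
            for ip in range(n_ring):
                elems.append([
                    nid(0, it, ip), nid(0, it + 1, ip), nid(0, it + 1, ip + 1), nid(0, it, ip + 1),
                    nid(1, it, ip), nid(1, it + 1, ip), nid(1, it + 1, ip + 1), nid(1, it, ip + 1),
                ])
        el = _fix_orientation(nodes, np.array(elems, dtype=int))
        meshes.append(HexMesh(nodes=nodes, elems=el))
    off = meshes[0].n_nodes
    return HexMesh(
        nodes=np.vstack([meshes[0].nodes, meshes[1].nodes]),
        elems=np.vstack([meshes[0].elems, meshes[1].elems + off]),
    )


def _rigid_surfaces(spec: KneeGeometrySpec) -> dict:
    """Rigid triangular shells for femur (condyle caps), tibia, patella."""
    out = {}
    # femur: both condyle caps, triangulated lat-long
    nodes, tris = [], []
    for side in ("medial", "lateral"):
        sgn = -1.0 if side == "medial" else 1.0
        r = spec.condyle_radius_sag_med if side == "medial" else spec.condyle_radius_sag_lat
        y_c = spec.tibial_cartilage_thickness + r + spec.femoral_cartilage_thickness
        center = np.array([0.0, y_c, sgn * spec.condyle_offset_z])
        n_th, n_ps = 5, 12
        base = len(nodes)
        for th in np.linspace(0.0, np.deg2rad(80.0), n_th + 1):
            for ps in np.linspace(0.0, 2 * np.pi, n_ps + 1)[:-1]:
                nodes.append(center + r * np.array([
                    np.sin(th) * np.cos(ps), -np.cos(th), np.sin(th) * np.sin(ps)]))
        for it in range(n_th):
            for ip in range(n_ps):
                a = base + it * n_ps + ip
                b = base + it * n_ps + (ip + 1) % n_ps
                c = base + (it + 1) * n_ps + ip
                d = base + (it + 1) * n_ps + (ip + 1) % n_ps
                tris.append([a, b, c])
                tris.append([b, d, c])
    out["femur"] = TriMesh(np.array(nodes), np.array(tris, dtype=int))

    # tibia: plateau rectangle at y = 0
    hx, hz = spec.plateau_halfwidth_x, spec.plateau_halfwidth_z
    pn = np.array([[-hx, 0, -hz], [hx, 0, -hz], [hx, 0, hz], [-hx, 0, hz]])
    out["tibia"] = TriMesh(pn, np.array([[0, 1, 2], [0, 2, 3]], dtype=int))

    # patella: small anterior plate
    yc = spec.tibial_cartilage_thickness + spec.condyle_radius_sag_med
    qn = np.array([[40.0, yc - 15, -12], [40.0, yc - 15, 12],
                   [42.0, yc + 15, 12], [42.0, yc + 15, -12]])
    out["patella"] = TriMesh(qn, np.array([[0, 1, 2], [0, 2, 3]], dtype=int))
    return out


def _sector_of(phi_deg_from_start: float, spec: KneeGeometrySpec) -> str:
    bounds = np.cumsum([0.0, *spec.sector_extent_deg])
    for name, lo, hi in zip(SECTORS, bounds[:-1], bounds[1:]):
        if lo <= phi_deg_from_start <= hi:
            return name
    return SECTORS[-1]


def _ligament_attachments(spec: KneeGeometrySpec):
    """Plausible femoral/tibial attachment points per bundle (model frame)."""
    y_m = spec.tibial_cartilage_thickness + spec.condyle_radius_sag_med \
        + spec.femoral_cartilage_thickness
    sites = {
        ("ACL", "anterior"): ((-6.0, y_m, 8.0), (12.0, 0.0, -3.0)),
        ("ACL", "posterior"): ((-10.0, y_m - 3.0, 8.0), (8.0, 0.0, 1.0)),
        ("PCL", "anterior"): ((-2.0, y_m - 5.0, -8.0), (-26.0, -8.0, 1.0)),
        ("PCL", "posterior"): ((-6.0, y_m - 2.0, -8.0), (-28.0, -10.0, -2.0)),
        ("MCL", "anterior"): ((2.0, y_m + 2.0, -45.0), (8.0, -55.0, -40.0)),
        ("MCL", "oblique"): ((-4.0, y_m + 2.0, -45.0), (-8.0, -45.0, -40.0)),
        ("MCL", "deep"): ((0.0, y_m, -44.0), (0.0, -14.0, -41.0)),
        ("PMC", "main"): ((-14.0, y_m - 3.0, -36.0), (-18.0, -14.0, -30.0)),
        ("LCL", "main"): ((0.0, y_m + 2.0, 44.0), (-4.0, -50.0, 42.0)),
        ("ALS", "main"): ((5.0, y_m, 40.0), (16.0, -18.0, 30.0)),
        ("OPL", "main"): ((-18.0, y_m - 4.0, 18.0), (-24.0, -16.0, -12.0)),
    }
    bundles = load_ligament_table()
    origins, insertions = [], []
    for b in bundles:
        o, ins = sites[(b.name, b.bundle)]
        dz = 2.0 * (b.index - 0.5) if b.name in ("ACL", "PCL") else 3.0 * (b.index - 1.0)
        origins.append(np.array(o) + np.array([0.0, 0.0, dz]))
        insertions.append(np.array(ins) + np.array([0.0, 0.0, dz]))
    return bundles, np.array(origins), np.array(insertions)


DEFAULT_REFERENCE_STRAIN = {
    "ACL": 0.04, "PCL": 0.01, "MCL": 0.03, "PMC": 0.02,
    "LCL": 0.03, "ALS": 0.02, "OPL": 0.02,
}


def calibrate_slack_lengths(model: "KneeModel", reference_strain: dict | None = None) -> None:
    """Set each bundle's slack length from the full-extension pose.

    With reference strain r the slack length becomes l_ref / (1 + r), so
    the bundle carries strain r at the reference pose.  The shipped
    defaults pretension every ligament slightly, which keeps the joint
    centred under load (all-zero strains leave the tibia free to slide
    several mm before any restraint engages).
    """
    reference_strain = DEFAULT_REFERENCE_STRAIN if reference_strain is None else reference_strain
    for b, o, ins in zip(model.ligaments, model.ligament_origins, model.ligament_insertions):
        r = float(reference_strain.get(b.name, 0.0))
        l_ref = float(np.linalg.norm(o - ins))
        b.l0 = l_ref / (1.0 + r)


def build_horns(spec: KneeGeometrySpec, menisci: dict) -> list:
    """Horn attachments for every present meniscus, from the current mesh
    node sets (safe to call again after element removal)."""
    arc = np.deg2rad(spec.meniscus_arc_deg)
    phi0 = np.deg2rad(135.0)
    t_c = spec.tibial_cartilage_thickness
    horns = []
    for side in ("medial", "lateral"):
        mesh = menisci.get(side)
        if mesh is None:
            continue
        sgn = -1.0 if side == "medial" else 1.0
        for face, phi_end, direction in (
            ("posterior_horn_face", phi0, -1.0),
            ("anterior_horn_face", phi0 + arc, +1.0),
        ):
            nids = mesh.node_sets[face]
            pts = mesh.nodes[nids]
            tang = np.array([-np.sin(phi_end), 0.0, sgn * np.cos(phi_end)]) * direction
            anchors = pts + spec.horn_anchor_length * tang
            anchors[:, 1] = 1.0
            width = spec.meniscus_outer_radius - spec.meniscus_inner_radius
            area = width * max(pts[:, 1].max() - t_c, spec.meniscus_height_inner)
            horns.append(HornAttachment(
                horn=f"{side}_{face.split('_')[0]}",
                youngs_modulus=spec.horn_modulus,
                face_area=area, horn_nodes=pts, tibia_nodes=anchors,
                node_ids=np.asarray(nids, dtype=int),
            ))
    return horns


def build_transverse(menisci: dict, n_tl: int = 4) -> list:
    """Transverse-ligament spring pairings between the anterior horns."""
    if menisci.get("medial") is None or menisci.get("lateral") is None:
        return []
    med_n = menisci["medial"].node_sets["anterior_horn_face"]
    lat_n = menisci["lateral"].node_sets["anterior_horn_face"]
    med_pts = menisci["medial"].nodes[med_n]
    lat_pts = menisci["lateral"].nodes[lat_n]
    sel_m = med_n[np.argsort(med_pts[:, 2])[-n_tl:]]     # most lateral medial nodes
    sel_l = lat_n[np.argsort(lat_pts[:, 2])[:n_tl]]      # most medial lateral nodes
    k_each = TRANSVERSE_LIGAMENT_STIFFNESS / n_tl
    return [("medial", int(a), "lateral", int(b), k_each)
            for a, b in zip(sel_m, sel_l)]


FULL_CONTACT_PAIRS = (
    "femoral_cartilage-medial_meniscus",
    "femoral_cartilage-lateral_meniscus",
    "femoral_cartilage-medial_tibial_cartilage",
    "femoral_cartilage-lateral_tibial_cartilage",
    "femoral_cartilage-patellar_cartilage",
    "medial_meniscus-medial_tibial_cartilage",
    "lateral_meniscus-lateral_tibial_cartilage",
)


def build_knee_geometry(spec: KneeGeometrySpec | None = None) -> KneeModel:
    """Construct the intact knee model for a geometry spec (deterministic)."""
    spec = spec or KneeGeometrySpec()
    spec.validate()

    menisci, axes, phis = {}, {}, {}
    for side in ("medial", "lateral"):
        mesh, center, phi = _meniscus_mesh(spec, side)
        menisci[side] = mesh
        axes[side] = (center, np.array([0.0, 1.0, 0.0]))
        phis[side] = phi

    t_c = spec.tibial_cartilage_thickness
    cart = {}
    for side, sgn in (("medial", -1.0), ("lateral", 1.0)):
        zc = sgn * spec.condyle_offset_z
        mesh = _box_mesh(
            -spec.cartilage_pad_x, spec.cartilage_pad_x, 0.0, t_c,
            zc - spec.cartilage_pad_z, zc + spec.cartilage_pad_z,
            spec.cart_nx, spec.cart_ny, spec.cart_nz,
        )
        # mildly dished superior surface centred under the condyle: the
        # rim stays at full thickness, the centre sits dish_depth lower
        d = spec.cartilage_dish_depth
        if d > 0:
            pad = min(spec.cartilage_pad_x, spec.cartilage_pad_z)
            rho2 = mesh.nodes[:, 0] ** 2 + (mesh.nodes[:, 2] - zc) ** 2
            h_local = t_c - d + np.minimum(d, d * rho2 / pad**2)
            mesh.nodes[:, 1] *= h_local / t_c
        cart[side] = mesh

    condyles = {}
    for side in ("medial", "lateral"):
        sgn = -1.0 if side == "medial" else 1.0
        r_s = (spec.condyle_radius_sag_med if side == "medial"
               else spec.condyle_radius_sag_lat) + spec.femoral_cartilage_thickness
        r_f = (spec.condyle_radius_frontal_med if side == "medial"
               else spec.condyle_radius_frontal_lat) + spec.femoral_cartilage_thickness
        condyles[side] = CondyleSurface(
            center=np.array([0.0, t_c + r_s, sgn * spec.condyle_offset_z]),
            r_sag=r_s, r_frontal=r_f,
        )
    knee_center = 0.5 * (condyles["medial"].center + condyles["lateral"].center)
    axis = condyles["lateral"].center - condyles["medial"].center
    axis = axis / np.linalg.norm(axis)

    bundles, origins, insertions = _ligament_attachments(spec)

    horns = build_horns(spec, menisci)
    transverse = build_transverse(menisci)

    model = KneeModel(
        spec=spec, variant="intact",
        menisci=menisci, meniscus_frames={}, meniscus_axis=axes,
        tibial_cartilage=cart,
        femoral_cartilage=_femoral_cartilage_mesh(spec),
        patellar_cartilage=_box_mesh(38.0, 42.0, t_c + 10.0, t_c + 30.0, -10.0, 10.0, 2, 2, 2),
        rigid_surfaces=_rigid_surfaces(spec),
        condyles=condyles, knee_center=knee_center, condylar_axis=axis,
        ligaments=bundles, ligament_origins=origins, ligament_insertions=insertions,
        horns=horns, transverse_pairs=transverse,
        contact_pairs=list(FULL_CONTACT_PAIRS),
    )
    calibrate_slack_lengths(model)
    assign_material_frames(model)
    audit_mesh(model)
    return model


def compute_annulus_frames(centroids: np.ndarray, center: np.ndarray,
                           axis: np.ndarray) -> np.ndarray:
    """Orthonormal (circumferential, radial, axial) triads for element
    centroids of an annulus with the given center and axis.

    The radial vector points outward from the axis, the axial vector is
    the annulus axis, and circumferential = axial x radial completes a
    right-handed triad tangent to the centroid ring.
    """
    axis = np.asarray(axis, dtype=float)
    a = axis / np.linalg.norm(axis)
    d = centroids - center
    d = d - np.outer(d @ a, a)
    norms = np.linalg.norm(d, axis=1)
    if np.any(norms < 1e-9):
        raise ValueError("degenerate element on the annulus axis")
    r = d / norms[:, None]
    c = np.cross(r, np.broadcast_to(a, r.shape))   # right-handed: c x r = a
    triads = np.stack([c, r, np.broadcast_to(a, r.shape)], axis=1)
    return triads


def assign_material_frames(model: KneeModel) -> KneeModel:
    """Attach a local (circumferential, radial, axial) triad to every
    meniscus element; the circumferential axis is the stiff direction."""
    for side, mesh in model.menisci.items():
        if mesh is None:
            continue
        center, axis = model.meniscus_axis[side]
        centroids = mesh.nodes[mesh.elems].mean(axis=1)
        model.meniscus_frames[side] = compute_annulus_frames(centroids, center, axis)
    return model


# ---------------------------------------------------------------------------
# tears and meniscectomy

def apply_radial_tear(model: KneeModel, tear: TearSpec) -> KneeModel:
    """Derive a torn (or meniscectomised) variant from an intact model.

    Element removal follows the structured grid: the tear occupies one
    circumferential element column at the requested angular position and
    removes the inner ``round(width_fraction * n_rad)`` radial element
    rings (at least one, never all).  The deepest remaining ring of that
    column is tagged as the tear tip.
    """
    tear.validate()
    if model.menisci.get("medial") is None:
        raise ValueError("model has no medial meniscus to tear")
    spec = model.spec

    if tear.total_meniscectomy:
        new = _clone(model)
        new.variant = "meniscectomy"
        new.tear = tear
        new.menisci = dict(model.menisci)
        new.menisci["medial"] = None
        new.meniscus_frames = {k: v for k, v in model.meniscus_frames.items() if k != "medial"}
        new.horns = [h for h in model.horns if not h.horn.startswith("medial")]
        new.transverse_pairs = []
        new.contact_pairs = [p for p in model.contact_pairs if "medial_meniscus" not in p]
        return new

    # angular slot: position within the sector, sectors ordered from the
    # posterior-horn end of the sweep
    bounds = np.cumsum([0.0, *spec.sector_extent_deg])
    sector_idx = SECTORS.index(tear.location)
    lo = bounds[sector_idx]
    pos = lo + np.clip(tear.position_deg, 0.0, spec.sector_extent_deg[sector_idx])
    if pos > spec.meniscus_arc_deg:
        raise ValueError("tear sector position outside the annulus arc")
    col = int(np.clip(np.floor(pos / spec.meniscus_arc_deg * spec.n_circ),
                      0, spec.n_circ - 1))

    n_cut = int(np.clip(round(tear.width_fraction * spec.n_rad), 0, spec.n_rad - 1))
    mesh = model.menisci["medial"]
    gidx = mesh.grid_index
    if n_cut == 0:
        new = _clone(model)
        new.variant = tear.label
        new.tear = tear
        new.tear_tip_grid = gidx[(gidx[:, 0] == col) & (gidx[:, 1] == 0)].copy()
        return new

    keep = ~((gidx[:, 0] == col) & (gidx[:, 1] < n_cut))
    new_mesh = _subset_mesh(mesh, keep)
    tip = gidx[(gidx[:, 0] == col) & (gidx[:, 1] == n_cut)].copy()

    new = _clone(model)
    new.variant = tear.label
    new.tear = tear
    new.menisci = dict(model.menisci)
    new.menisci["medial"] = new_mesh
    new.tear_tip_grid = tip
    new.horns = build_horns(spec, new.menisci)
    new.transverse_pairs = build_transverse(new.menisci)
    new.meniscus_frames = dict(model.meniscus_frames)
    assign_material_frames(new)
    if not _connected(new_mesh):
        raise RuntimeError("torn medial meniscus is not a single connected component")
    return new


def _clone(model: KneeModel) -> KneeModel:
    return replace(model)


def _subset_mesh(mesh: HexMesh, keep: np.ndarray) -> HexMesh:
    elems = mesh.elems[keep]
    used = np.unique(elems)
    remap = -np.ones(mesh.n_nodes, dtype=int)
    remap[used] = np.arange(used.size)
    node_sets = {}
    for name, ids in mesh.node_sets.items():
        kept = ids[np.isin(ids, used)]
        node_sets[name] = remap[kept]
    return HexMesh(
        nodes=mesh.nodes[used].copy(),
        elems=remap[elems],
        grid_index=mesh.grid_index[keep].copy() if mesh.grid_index is not None else None,
        node_sets=node_sets,
    )


def _connected(mesh: HexMesh) -> bool:
    """Element-adjacency (shared node) connectivity check."""
    n = mesh.n_elems
    if n == 0:
        return False
    node2el: dict[int, list[int]] = {}
    for e, conn in enumerate(mesh.elems):
        for nd in conn:
            node2el.setdefault(int(nd), []).append(e)
    seen = np.zeros(n, dtype=bool)
    stack = [0]
    seen[0] = True
    while stack:
        e = stack.pop()
        for nd in mesh.elems[e]:
            for o in node2el[int(nd)]:
                if not seen[o]:
                    seen[o] = True
                    stack.append(o)
    return bool(seen.all())


def matched_elements(model: KneeModel, grid_ids: np.ndarray) -> np.ndarray:
    """Element indices of the medial meniscus whose structured (i, j, k)
    ids match ``grid_ids`` (used to evaluate the intact model at the
    tear-tip location of a torn variant)."""
    mesh = model.menisci["medial"]
    if mesh is None:
        raise ValueError("no medial meniscus in this model")
    gidx = mesh.grid_index
    out = []
    want = {tuple(g) for g in np.atleast_2d(grid_ids)}
    for e, g in enumerate(gidx):
        if tuple(g) in want:
            out.append(e)
    if not out:
        raise ValueError("no elements match the requested grid ids")
    return np.array(out, dtype=int)


# ---------------------------------------------------------------------------
# mesh audit

def hex_jacobians(nodes: np.ndarray, elems: np.ndarray) -> np.ndarray:
    """Jacobian determinant at the 2x2x2 Gauss points of every element."""
    g = 1.0 / np.sqrt(3.0)
    pts = np.array([[sx * g, sy * g, sz * g]
                    for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)])
    # trilinear shape function derivative helper
    signs = np.array([
        [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
        [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
    ], dtype=float)
    dets = np.empty((elems.shape[0], 8))
    for ig, (xi, eta, zeta) in enumerate(pts):
        dn = np.empty((8, 3))
        for a in range(8):
            sx, sy, sz = signs[a]
            dn[a, 0] = 0.125 * sx * (1 + sy * eta) * (1 + sz * zeta)
            dn[a, 1] = 0.125 * sy * (1 + sx * xi) * (1 + sz * zeta)
            dn[a, 2] = 0.125 * sz * (1 + sx * xi) * (1 + sy * eta)
        for e in range(elems.shape[0]):
            J = nodes[elems[e]].T @ dn
            dets[e, ig] = np.linalg.det(J)
    return dets


def audit_mesh(model: KneeModel) -> dict:
    """Positive-Jacobian and per-compartment watertightness audit.

    Raises on an inverted element; returns summary statistics.
    """
    report = {}
    bodies = {f"meniscus_{s}": m for s, m in model.menisci.items() if m is not None}
    bodies.update({f"tibial_cartilage_{s}": m for s, m in model.tibial_cartilage.items()})
    bodies["femoral_cartilage"] = model.femoral_cartilage
    for name, mesh in bodies.items():
        dets = hex_jacobians(mesh.nodes, mesh.elems)
        if dets.min() <= 0:
            bad = int(np.argwhere(dets.min(axis=1) <= 0)[0][0])
            raise ValueError(f"{name}: non-positive Jacobian in element {bad}")
        faces: dict[tuple, int] = {}
        face_local = [
            (0, 1, 2, 3), (4, 5, 6, 7), (0, 1, 5, 4),
            (2, 3, 7, 6), (1, 2, 6, 5), (0, 3, 7, 4),
        ]
        for conn in mesh.elems:
            for fl in face_local:
                key = tuple(sorted(int(conn[a]) for a in fl))
                faces[key] = faces.get(key, 0) + 1
        if any(c > 2 for c in faces.values()):
            raise ValueError(f"{name}: face shared by more than two elements")
        report[name] = {
            "min_jacobian": float(dets.min()),
            "boundary_faces": sum(1 for c in faces.values() if c == 1),
        }
    return report
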