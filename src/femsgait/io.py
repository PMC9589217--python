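"""Mesh and result file output.

Plain-text writers for the two interchange formats the package emits:
legacy ASCII VTK unstructured grids (hexahedra and triangles, with
optional cell/point data such as stress scalars or tensors) and the
NODE/ELEMENT/ELSET subset of the Abaqus ``.inp`` format.  Summary time
series are written as tidy CSV by the driver.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

VTK_HEX = 12
VTK_TRI = 5


def write_vtk_unstructured(path, nodes: np.ndarray, cells: dict,
                           cell_data: dict | None = None,
                           point_data: dict | None = None) -> None:
    """Write a legacy ASCII VTK unstructured grid.

    ``cells``: {"hexahedron": (m, 8) array, "triangle": (k, 3) array}
    (either may be absent).  ``cell_data``/``point_data`` map names to
    per-cell/per-point scalars (n,), vectors (n, 3) or tensors
    (n, 3, 3).
    """
    nodes = np.asarray(nodes, dtype=float)
    blocks = []
    types = []
    for kind, conn in cells.items():
        conn = np.asarray(conn, dtype=int)
        if conn.size == 0:
            continue
        vtk_type = {"hexahedron": VTK_HEX, "triangle": VTK_TRI}[kind]
        blocks.append(conn)
        types.extend([vtk_type] * conn.shape[0])
    n_cells = sum(b.shape[0] for b in blocks)
    size = sum(b.shape[0] * (b.shape[1] + 1) for b in blocks)

    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nfemsgait mesh\nASCII\n"
                 "DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {nodes.shape[0]} double\n")
        for p in nodes:
            fh.write(f"{p[0]:.8g} {p[1]:.8g} {p[2]:.8g}\n")
        fh.write(f"CELLS {n_cells} {size}\n")
        for b in blocks:
            for conn in b:
                fh.write(str(len(conn)) + " " + " ".join(map(str, conn)) + "\n")
        fh.write(f"CELL_TYPES {n_cells}\n")
        fh.write("\n".join(map(str, types)) + "\n")

        for title, data in (("CELL_DATA", cell_data), ("POINT_DATA", point_data)):
            if not data:
                continue
            n = n_cells if title == "CELL_DATA" else nodes.shape[0]
            fh.write(f"{title} {n}\n")
            for name, arr in data.items():
                arr = np.asarray(arr, dtype=float)
                if arr.ndim == 1:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    fh.write("\n".join(f"{v:.8g}" for v in arr) + "\n")
                elif arr.ndim == 2 and arr.shape[1] == 3:
                    fh.write(f"VECTORS {name} double\n")
                    for v in arr:
                        fh.write(f"{v[0]:.8g} {v[1]:.8g} {v[2]:.8g}\n")
                elif arr.ndim == 3:
                    fh.write(f"TENSORS {name} double\n")
                    for t in arr:
                        for row in t:
                            fh.write(f"{row[0]:.8g} {row[1]:.8g} {row[2]:.8g}\n")
                        fh.write("\n")
                else:
                    raise ValueError(f"unsupported data shape for {name}: {arr.shape}")


def write_abaqus_inp(path, nodes: np.ndarray, hexes: np.ndarray,
                     elsets: dict | None = None, part_name: str = "PART") -> None:
    """Write the NODE/ELEMENT/ELSET subset of an Abaqus input deck
    (1-based ids, C3D8 elements)."""
    with open(path, "w") as fh:
        fh.write(f"*HEADING\nfemsgait export: {part_name}\n")
        fh.write("*NODE\n")
        for i, p in enumerate(np.asarray(nodes, float), start=1):
            fh.write(f"{i}, {p[0]:.8g}, {p[1]:.8g}, {p[2]:.8g}\n")
        fh.write("*ELEMENT, TYPE=C3D8\n")
        for e, conn in enumerate(np.asarray(hexes, int), start=1):
            fh.write(f"{e}, " + ", ".join(str(c + 1) for c in conn) + "\n")
        for name, ids in (elsets or {}).items():
            fh.write(f"*ELSET, ELSET={name}\n")
            ids = [str(int(i) + 1) for i in ids]
            for k in range(0, len(ids), 16):
                fh.write(", ".join(ids[k:k + 16]) + "\n")


def export_knee_model(model, out_dir) -> None:
    """Write every body of a knee model as VTK (and the menisci as inp)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for side, mesh in model.menisci.items():
        if mesh is None:
            continue
        frames = model.meniscus_frames.get(side)
        cd = {}
        if frames is not None:
            cd["circumferential"] = frames[:, 0, :]
        write_vtk_unstructured(out_dir / f"meniscus_{side}.vtk", mesh.nodes,
                               {"hexahedron": mesh.elems}, cell_data=cd)
        elsets = {}
        if model.tear_tip_grid is not None and side == "medial":
            from .synth.geometry import matched_elements
            elsets["TEAR_TIP"] = matched_elements(model, model.tear_tip_grid)
        write_abaqus_inp(out_dir / f"meniscus_{side}.inp", mesh.nodes, mesh.elems,
                         elsets=elsets, part_name=f"MENISCUS_{side.upper()}")
    for side, mesh in model.tibial_cartilage.items():
        write_vtk_unstructured(out_dir / f"tibial_cartilage_{side}.vtk",
                               mesh.nodes, {"hexahedron": mesh.elems})
    write_vtk_unstructured(out_dir / "femoral_cartilage.vtk",
                           model.femoral_cartilage.nodes,
                           {"hexahedron": model.femoral_cartilage.elems})
    for name, tm in model.rigid_surfaces.items():
        write_vtk_unstructured(out_dir / f"{name}.vtk", tm.nodes,
                               {"triangle": tm.tris})


def export_stress_field(model, side: str, field, path) -> None:
    """Write one meniscus stress field as VTK cell data."""
    mesh = model.menisci[side]
    cd = {"max_shear_MPa": field.max_shear, "stress_MPa": field.tensors}
    if field.sigma_cc is not None:
        cd["sigma_cc_MPa"] = field.sigma_cc
    write_vtk_unstructured(path, mesh.nodes, {"hexahedron": mesh.elems},
                           cell_data=cd)
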