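"""8-node hexahedral elements with mean-dilatation (B-bar) integration.

Small-strain displacement elements on 2x2x2 Gauss quadrature; the
volumetric part of the strain-displacement operator is replaced by its
element average, which removes volumetric locking for the nearly
incompressible cartilage (nu = 0.46) while full deviatoric quadrature
keeps the element free of hourglass modes.  Per-element anisotropy is
handled by rotating the material stiffness into each element's local
frame before assembly.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

_SIGNS = np.array([
    [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
    [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
], dtype=float)
_G = 1.0 / np.sqrt(3.0)
_GAUSS = np.array([[sx * _G, sy * _G, sz * _G]
                   for sz in (-1, 1) for sy in (-1, 1) for sx in (-1, 1)])
_M_VOIGT = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])


def _shape_derivs(xi, eta, zeta) -> np.ndarray:
    dn = np.empty((8, 3))
    for a in range(8):
        sx, sy, sz = _SIGNS[a]
        dn[a, 0] = 0.125 * sx * (1 + sy * eta) * (1 + sz * zeta)
        dn[a, 1] = 0.125 * sy * (1 + sx * xi) * (1 + sz * zeta)
        dn[a, 2] = 0.125 * sz * (1 + sx * xi) * (1 + sy * eta)
    return dn


def _b_matrix(dndx: np.ndarray) -> np.ndarray:
    B = np.zeros((6, 24))
    for a in range(8):
        bx, by, bz = dndx[a]
        c = 3 * a
        B[0, c] = bx
        B[1, c + 1] = by
        B[2, c + 2] = bz
        B[3, c + 1] = bz
        B[3, c + 2] = by
        B[4, c] = bz
        B[4, c + 2] = bx
        B[5, c] = by
        B[5, c + 1] = bx
    return B


def element_bbar(coords: np.ndarray):
    """B-bar operators and weights at the 8 Gauss points of one element.

    Returns (Bbar list, w·detJ list, volume).  Raises on an inverted
    element.
    """
    Bs, wd = [], []
    vol_rows = []
    for gp in _GAUSS:
        dn = _shape_derivs(*gp)
        J = coords.T @ dn
        det = np.linalg.det(J)
        if det <= 0:
            raise ValueError("inverted hexahedral element")
        dndx = dn @ np.linalg.inv(J)
        Bs.append(_b_matrix(dndx))
        wd.append(det)
        vol_rows.append(Bs[-1][:3].sum(axis=0))     # divergence row
    wd = np.array(wd)
    vol = wd.sum()
    div_bar = np.einsum("g,gi->i", wd, np.array(vol_rows)) / vol
    out = []
    for B, row in zip(Bs, vol_rows):
        Bb = B + np.outer(_M_VOIGT, (div_bar - row)) / 3.0
        out.append(Bb)
    return out, wd, vol


def element_stiffness(coords: np.ndarray, C: np.ndarray) -> np.ndarray:
    Bs, wd, _ = element_bbar(coords)
    K = np.zeros((24, 24))
    for B, w in zip(Bs, wd):
        K += B.T @ C @ B * w
    return K


def assemble_stiffness(nodes: np.ndarray, elems: np.ndarray,
                       C_elems) -> sp.csr_matrix:
    """Assemble the global stiffness.  ``C_elems`` is a single 6x6 matrix
    or a per-element array (m, 6, 6) for heterogeneous/rotated material."""
    n_dof = 3 * nodes.shape[0]
    C_arr = np.asarray(C_elems, dtype=float)
    per_elem = C_arr.ndim == 3
    rows, cols, vals = [], [], []
    for e, conn in enumerate(elems):
        C = C_arr[e] if per_elem else C_arr
        Ke = element_stiffness(nodes[conn], C)
        dofs = np.repeat(conn * 3, 3) + np.tile([0, 1, 2], 8)
        rows.append(np.repeat(dofs, 24))
        cols.append(np.tile(dofs, 24))
        vals.append(Ke.ravel())
    K = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_dof, n_dof),
    )
    return K.tocsr()


def element_stress(coords: np.ndarray, C: np.ndarray, u_e: np.ndarray) -> np.ndarray:
    """Centroid Cauchy stress (Voigt, MPa) of one element: the Gauss-point
    stresses of the B-bar element volume-averaged to the centroid."""
    Bs, wd, vol = element_bbar(coords)
    s = np.zeros(6)
    for B, w in zip(Bs, wd):
        s += (C @ (B @ u_e)) * w
    return s / vol


def hex_volumes(nodes: np.ndarray, elems: np.ndarray) -> np.ndarray:
    out = np.empty(elems.shape[0])
    for e, conn in enumerate(elems):
        _, wd, vol = element_bbar(nodes[conn])
        out[e] = vol
    return out


def voigt_to_tensor(s: np.ndarray) -> np.ndarray:
    return np.array([
        [s[0], s[5], s[4]],
        [s[5], s[1], s[3]],
        [s[4], s[3], s[2]],
    ])


def strain_energy(K: sp.csr_matrix, u: np.ndarray) -> float:
    return float(0.5 * u @ (K @ u))
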