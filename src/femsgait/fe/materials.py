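"""Elastic material models for the knee soft tissues.

Articular cartilage is linear elastic isotropic (E = 5 MPa, nu = 0.46).
The meniscus is transversely isotropic with the stiff axis along the
circumferential fiber direction: E_circ = 140 MPa against 20 MPa radial
and axial, in-plane (radial-axial) Poisson ratio 0.2 and out-of-plane
0.3.  The out-of-plane shear modulus is not derivable from those
constants and defaults to 10 MPa (configuration).

Voigt order: (xx, yy, zz, yz, xz, xy) with engineering shear strains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class MaterialSpec:
    """Material constants for the deformable knee tissues (MPa)."""

    cartilage_E: float = 5.0
    cartilage_nu: float = 0.46
    meniscus_E_circ: float = 140.0
    meniscus_E_trans: float = 20.0      # radial and axial
    meniscus_nu_inplane: float = 0.2    # radial-axial plane
    meniscus_nu_outplane: float = 0.3   # circ-transverse
    meniscus_G_outplane: float = 10.0   # not stated by the constants above
    friction: float = 0.04

    def __post_init__(self) -> None:
        if not 0.0 <= self.friction < 1.0:
            raise ValueError("friction coefficient must lie in [0, 1)")
        # SPD checks at load time
        for C in (self.cartilage_stiffness(), self.meniscus_stiffness_local()):
            w = np.linalg.eigvalsh(C)
            if w.min() <= 0:
                raise ValueError("material stiffness tensor is not positive definite")

    def cartilage_stiffness(self) -> np.ndarray:
        return isotropic_stiffness(self.cartilage_E, self.cartilage_nu)

    def meniscus_stiffness_local(self) -> np.ndarray:
        """Stiffness in the local frame with axis 1 = circumferential."""
        return transverse_isotropic_stiffness(
            e_axis=self.meniscus_E_circ,
            e_trans=self.meniscus_E_trans,
            nu_trans=self.meniscus_nu_inplane,
            nu_axis=self.meniscus_nu_outplane,
            g_axis=self.meniscus_G_outplane,
        )


def isotropic_stiffness(E: float, nu: float) -> np.ndarray:
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.diag_indices(3)] = lam + 2 * mu
    C[3, 3] = C[4, 4] = C[5, 5] = mu
    return C


def transverse_isotropic_stiffness(e_axis: float, e_trans: float,
                                   nu_trans: float, nu_axis: float,
                                   g_axis: float) -> np.ndarray:
    """Stiffness with symmetry axis along local x (axis 1).

    ``nu_axis`` is the major Poisson ratio (axial load, transverse
    contraction); ``nu_trans`` acts in the isotropy plane.  Built by
    inverting the compliance matrix.
    """
    S = np.zeros((6, 6))
    S[0, 0] = 1.0 / e_axis
    S[1, 1] = S[2, 2] = 1.0 / e_trans
    S[0, 1] = S[0, 2] = S[1, 0] = S[2, 0] = -nu_axis / e_axis
    S[1, 2] = S[2, 1] = -nu_trans / e_trans
    g_trans = e_trans / (2.0 * (1.0 + nu_trans))
    S[3, 3] = 1.0 / g_trans          # shear in the isotropy (2-3) plane
    S[4, 4] = S[5, 5] = 1.0 / g_axis
    return np.linalg.inv(S)


def _bond_matrix(R: np.ndarray) -> np.ndarray:
    """Voigt (Bond) transformation matrix for stiffness rotation.

    ``R`` maps local to global vectors (columns = local axes in global
    coordinates); returns M with C_global = M C_local M^T.
    """
    r = R
    M = np.zeros((6, 6))
    pairs = [(1, 2), (0, 2), (0, 1)]
    for i in range(3):
        for j in range(3):
            M[i, j] = r[i, j] ** 2
        for k, (a, b) in enumerate(pairs):
            M[i, 3 + k] = r[i, a] * r[i, b]
    for k, (i, j) in enumerate(pairs):
        for m in range(3):
            M[3 + k, m] = 2.0 * r[i, m] * r[j, m]
        for l, (a, b) in enumerate(pairs):
            M[3 + k, 3 + l] = r[i, a] * r[j, b] + r[i, b] * r[j, a]
    return M


def rotate_stiffness(C_local: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Rotate a Voigt stiffness matrix: columns of R are the local axes."""
    M = _bond_matrix(R)
    return M @ C_local @ M.T
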