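"""Stress recovery and the derived scalar fields.

Per-element centroid Cauchy stress from a converged displacement field;
maximum shear stress (half the difference of the extreme principal
stresses, the Tresca/2 scalar) and the circumferential normal stress
``sigma_cc = c . sigma c`` (tension positive) with ``c`` the element's
local circumferential fiber direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .elements import element_stress, voigt_to_tensor


@dataclass
class StressField:
    """Per-element stress state of one deformable body."""

    tensors: np.ndarray        # (m, 3, 3) MPa, symmetric
    max_shear: np.ndarray      # (m,) MPa
    sigma_cc: np.ndarray | None = None   # (m,) MPa, meniscus only


def principal_stresses(t: np.ndarray) -> np.ndarray:
    return np.linalg.eigvalsh(t)


def recover_stress(mesh, C_elems, u: np.ndarray,
                   frames: np.ndarray | None = None) -> StressField:
    """Centroid stresses for one body.

    ``C_elems`` is a (m, 6, 6) per-element (already rotated) or single
    6x6 stiffness; ``u`` the (n, 3) nodal displacement field; ``frames``
    the (m, 3, 3) local triads (rows c, r, a) if circumferential
    projections are wanted.
    """
    C_arr = np.asarray(C_elems, dtype=float)
    per_elem = C_arr.ndim == 3
    m = mesh.elems.shape[0]
    tensors = np.empty((m, 3, 3))
    for e, conn in enumerate(mesh.elems):
        C = C_arr[e] if per_elem else C_arr
        u_e = u[conn].ravel()
        tensors[e] = voigt_to_tensor(element_stress(mesh.nodes[conn], C, u_e))
    w = np.linalg.eigvalsh(tensors)
    max_shear = 0.5 * (w[:, 2] - w[:, 0])
    sigma_cc = None
    if frames is not None:
        c = frames[:, 0, :]
        sigma_cc = np.einsum("ei,eij,ej->e", c, tensors, c)
    return StressField(tensors=tensors, max_shear=max_shear, sigma_cc=sigma_cc)


def tag_tear_tip_stress(field: StressField, element_ids: np.ndarray):
    """Max and mean of the max-shear scalar over the tagged element set."""
    ids = np.asarray(element_ids, dtype=int)
    if ids.size == 0:
        raise ValueError("empty tear-tip element set")
    vals = field.max_shear[ids]
    return float(vals.max()), float(vals.mean())
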