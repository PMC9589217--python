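"""Static muscle-force optimization: minimum sum of cubed activations.

At each time point the redundant muscle set must reproduce the
generalized joint moments from inverse dynamics:

    tau_j = sum_m r_jm * f_m(s_m),      f_m(s) = Fmax_m [s f_act + f_pass]

over the five constrained DOFs (hip flexion-extension,
abduction-adduction, internal-external rotation; knee
flexion-extension; ankle dorsiflexion-plantarflexion).  The knee's
remaining components are left to the contact/ligament solve.  Because
the Hill force is affine in activation, the constraints are linear and

    min C = sum_m s_m^3,   0 <= s_m <= 1

is a smooth convex program; it is solved with scipy's interior-point
style trust-constr solver from a deterministic cold start (s = 0.1).
Infeasible moment demands are reported explicitly (bounded least-squares
fallback with its residual), never silently relaxed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, lsq_linear, minimize

from .muscles import MuscleGeometry, MuscleUnit


@dataclass
class ActivationSolution:
    activations: np.ndarray          # (n_m,) in [0, 1]
    forces: np.ndarray               # (n_m,) N
    objective: float                 # sum s^3
    moment_residual: np.ndarray      # (n_c,) N mm
    converged: bool
    feasible: bool
    iterations: int
    kkt_residual: float
    names: list = field(default_factory=list)


def activation_lp_matrices(geom: MuscleGeometry, muscles: list[MuscleUnit],
                           tau: np.ndarray):
    """Linear constraint data ``A s = b`` of the moment-equilibrium set.

    ``A[j, m] = r_jm Fmax_m f_act(l~_m)``; the passive forces are moved
    into ``b``.
    """
    fmax = np.array([m.fmax for m in muscles])
    fact = np.array([m.f_active(l) for m, l in zip(muscles, geom.lnorm)])
    fpas = np.array([m.f_passive(l) for m, l in zip(muscles, geom.lnorm)])
    gain = fmax * fact
    A = geom.arms * gain[None, :]
    b = np.asarray(tau, dtype=float) - geom.arms @ (fmax * fpas)
    return A, b, gain, fmax * fpas


def kkt_residual(A: np.ndarray, s: np.ndarray, tol: float = 1e-7) -> float:
    """Stationarity residual of the cubic program at a feasible point.

    Multipliers for the equality block are fitted by least squares on
    the strictly interior coordinates; bound multipliers must carry the
    right sign on the active coordinates.
    """
    g = 3.0 * s**2
    interior = (s > tol) & (s < 1.0 - tol)
    if interior.any():
        lam, *_ = np.linalg.lstsq(A[:, interior].T, g[interior], rcond=None)
    else:
        lam = np.zeros(A.shape[0])
    r = g - A.T @ lam
    res = 0.0
    for m in range(len(s)):
        if interior[m]:
            res = max(res, abs(r[m]))
        elif s[m] <= tol:
            res = max(res, max(0.0, -r[m]))        # mu_lo = r >= 0 required
        else:
            res = max(res, max(0.0, r[m]))         # mu_up = -r >= 0 required
    return float(res)


def solve_static_optimization(tau: np.ndarray, geom: MuscleGeometry,
                              muscles: list[MuscleUnit],
                              tol: float = 1e-10,
                              moment_tol: float = 1.0) -> ActivationSolution:
    """Resolve activations for generalized moments ``tau`` (N mm).

    ``moment_tol`` (N mm) decides whether the equality constraints were
    met; a demand beyond muscle capacity yields ``feasible=False`` with
    the bounded least-squares activations and their moment residual.
    """
    tau = np.asarray(tau, dtype=float)
    A_full, b_full, gain, fpass_force = activation_lp_matrices(geom, muscles, tau)
    n = A_full.shape[1]

    # drop degenerate rows (no muscle acts on that DOF); a non-zero
    # demand on such a row is an immediate infeasibility
    row_norm = np.linalg.norm(A_full, axis=1)
    active = row_norm > 1e-9
    A, b = A_full[active], b_full[active]

    # row-normalize the equality block for solver conditioning
    sc = np.maximum(np.linalg.norm(A, axis=1), 1e-9)
    As, bs = A / sc[:, None], b / sc

    x0 = np.full(n, 0.1)
    res = minimize(
        lambda s: float(np.sum(s**3)), x0, jac=lambda s: 3.0 * s**2,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * n,
        constraints=[{"type": "eq", "fun": lambda s: As @ s - bs, "jac": lambda s: As}],
        options={"maxiter": 500, "ftol": 1e-16},
    )
    s = np.clip(res.x, 0.0, 1.0)
    niter = int(res.nit)
    if not res.success or np.max(np.abs(A @ s - b)) > moment_tol:
        res2 = minimize(
            lambda s: float(np.sum(s**3)), x0, jac=lambda s: 3.0 * s**2,
            hess=lambda s: np.diag(6.0 * s),
            method="trust-constr",
            bounds=Bounds(np.zeros(n), np.ones(n)),
            constraints=[LinearConstraint(As, bs, bs)],
            options={"gtol": tol, "xtol": 1e-12, "maxiter": 600, "verbose": 0},
        )
        s2 = np.clip(res2.x, 0.0, 1.0)
        if np.max(np.abs(A @ s2 - b)) < np.max(np.abs(A @ s - b)):
            s = s2
            niter = int(res2.niter)
    resid = A_full @ s - b_full
    feasible = bool(np.max(np.abs(resid)) <= moment_tol)

    if not feasible:
        # prioritized fallback: sagittal (producible) rows weighted up so
        # an unproducible frontal/transverse demand cannot corrupt the
        # knee and ankle balance; residual reported, never hidden
        w_full = np.array([10.0, 1.0, 1.0, 100.0, 10.0])[: A_full.shape[0]] \
            if A_full.shape[0] == 5 else np.ones(A_full.shape[0])
        w = w_full[active]
        ls = lsq_linear(As * w[:, None], bs * w, bounds=(0.0, 1.0))
        s = np.clip(ls.x, 0.0, 1.0)
        resid = A_full @ s - b_full

    forces = gain * s + fpass_force
    return ActivationSolution(
        activations=s,
        forces=forces,
        objective=float(np.sum(s**3)),
        moment_residual=resid,
        converged=bool(feasible),
        feasible=feasible,
        iterations=niter,
        kkt_residual=kkt_residual(A, s) if feasible else float("nan"),
        names=list(geom.names),
    )
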