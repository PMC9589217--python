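"""Concurrent simulation driver for the stance phase.

Pipeline per variant: inverse kinematics (markers -> primary angles),
inverse dynamics (angles + GRF -> generalized joint moments), then per
stance time point a fixed-point loop that couples the static muscle
optimization with the deformable knee contact solve:

    1. muscle lengths / moment arms at the current knee secondary
       kinematics ``e_s``,
    2. cubed-activation static optimization against the (fixed, marker-
       derived) generalized moments,
    3. knee joint reaction wrench from the distal free body (inverse-
       dynamics intersegmental load minus the muscle forces crossing the
       knee),
    4. contact solve -> new ``e_s``,

iterated until the knee flexion-extension muscle moment, re-evaluated
with the updated moment arms, matches the required moment within the
configured tolerance.  Each time point warm-starts from the previous
one.  Secondary kinematics feed back into muscle geometry and the
reaction wrench; their sub-millimetre effect on segment inertial
kinematics is neglected.

The experiment matrix runs the intact knee, nine radial-tear variants
(33/50/83% width at anterior horn, midbody, posterior horn) and total
medial meniscectomy under identical marker and GRF input.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import inverse_dynamics
from .fe.knee import KneeContactSession
from .fe.materials import MaterialSpec
from .fe.stress import tag_tear_tip_stress
from .frames import rot_z
from .kinematics import inverse_kinematics
from .linkage import MOMENT_DOF_NAMES, forward_kinematics, joint_centers
from .muscles import calibrate_slack, compute_muscle_geometry, load_muscle_set
from .staticopt import solve_static_optimization
from .synth.gait import GaitTrialSpec, generate_gait_trial
from .synth.geometry import (
    KneeGeometrySpec,
    TearSpec,
    apply_radial_tear,
    build_knee_geometry,
    matched_elements,
)

DEFAULT_TIME_POINTS = tuple(np.round(np.linspace(0.0, 100.0, 16), 2))


def default_variants() -> list[TearSpec | None]:
    """Intact + 9 radial tears + total meniscectomy."""
    out: list[TearSpec | None] = [None]
    for loc in ("anterior_horn", "midbody", "posterior_horn"):
        for w in (0.33, 0.50, 0.83):
            out.append(TearSpec(location=loc, width_fraction=w))
    out.append(TearSpec(total_meniscectomy=True))
    return out


@dataclass
class SimulationConfig:
    time_points: tuple = DEFAULT_TIME_POINTS          # % stance
    outer_max_iter: int = 10
    knee_moment_tol: float = 500.0                    # N mm
    subject_mass: float = 80.0                        # kg
    subject_height: float = 1.75                      # m
    seed: int = 0
    marker_noise_sd: float = 0.0                      # mm
    penalty_per_area: float = 400.0
    contact_tol: float = 0.2                          # N
    freeze_secondary_feedback: bool = False           # ablation switch
    output_dir: str = "results"

    def validate(self) -> None:
        tp = np.asarray(self.time_points, float)
        if np.any(np.diff(tp) <= 0) or tp.min() < 0 or tp.max() > 100:
            raise ValueError("time points must be strictly increasing within [0, 100]")
        if self.knee_moment_tol <= 0 or self.contact_tol <= 0:
            raise ValueError("tolerances must be positive")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class TimePointSolution:
    percent_stance: float
    frame_index: int
    state_q: np.ndarray
    e_s: np.ndarray
    tau: np.ndarray
    activations: np.ndarray
    muscle_forces: np.ndarray
    opt_feasible: bool
    contact: object                      # fe.knee.ContactResult
    outer_iterations: int
    outer_converged: bool
    moment_residual: float               # N mm, knee row, updated-arms check
    es_history: list = field(default_factory=list)
    tear_tip_max_shear: float = float("nan")
    tear_tip_mean_shear: float = float("nan")
    meniscus_max_shear: float = float("nan")
    sigma_cc_min: float = float("nan")
    sigma_cc_max: float = float("nan")


@dataclass
class StanceSolution:
    variant: str
    config: SimulationConfig
    points: list                          # of TimePointSolution
    matched_tip_series: dict = field(default_factory=dict)
    # label -> list of (max, mean) max-shear at another variant's
    # tear-tip element locations, evaluated on THIS model's mesh

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.points:
            c = p.contact
            rows.append({
                "percent_stance": p.percent_stance,
                "knee_flexion_deg": np.degrees(p.state_q[9]),
                "tau_knee_Nmm": p.tau[3],
                "outer_iters": p.outer_iterations,
                "outer_converged": int(p.outer_converged),
                "moment_residual_Nmm": p.moment_residual,
                "opt_feasible": int(p.opt_feasible),
                "es_tx_mm": p.e_s[0], "es_ty_mm": p.e_s[1], "es_tz_mm": p.e_s[2],
                "es_varus_rad": p.e_s[3], "es_introt_rad": p.e_s[4],
                "F_med_cart_N": np.linalg.norm(
                    c.forces.get("femoral_cartilage-medial_tibial_cartilage", np.zeros(3))),
                "F_med_men_N": np.linalg.norm(
                    c.forces.get("femoral_cartilage-medial_meniscus", np.zeros(3))),
                "F_lat_cart_N": np.linalg.norm(
                    c.forces.get("femoral_cartilage-lateral_tibial_cartilage", np.zeros(3))),
                "F_lat_men_N": np.linalg.norm(
                    c.forces.get("femoral_cartilage-lateral_meniscus", np.zeros(3))),
                "F_med_cart_BW": c.forces_bw.get(
                    "femoral_cartilage-medial_tibial_cartilage", 0.0),
                "medial_ratio": c.medial_ratio,
                "peak_pressure_med_cart_MPa": c.peak_pressure.get(
                    "femoral_cartilage-medial_tibial_cartilage", 0.0),
                "peak_pressure_med_men_MPa": c.peak_pressure.get(
                    "femoral_cartilage-medial_meniscus", 0.0),
                "tear_tip_max_shear_MPa": p.tear_tip_max_shear,
                "tear_tip_mean_shear_MPa": p.tear_tip_mean_shear,
                "meniscus_max_shear_MPa": p.meniscus_max_shear,
                "sigma_cc_min_MPa": p.sigma_cc_min,
                "sigma_cc_max_MPa": p.sigma_cc_max,
            })
        return pd.DataFrame(rows)


def grf_peak_indices(trial, time_points) -> tuple[int, int]:
    """Indices (into the stance grid) of the two vertical-GRF peaks."""
    tau = trial.grf_times / trial.grf_times[-1]
    fy = trial.grf_force[:, 1]
    mid = len(fy) // 2
    t1 = tau[np.argmax(fy[:mid])]
    t2 = tau[mid + np.argmax(fy[mid:])]
    tp = np.asarray(time_points, float) / 100.0
    return int(np.argmin(np.abs(tp - t1))), int(np.argmin(np.abs(tp - t2)))


def _knee_reaction_wrench(load, geom, forces, poses, knee_center):
    """Applied wrench for the contact solve, in the flexed-femur frame.

    The structures (contact + ligaments + horns) must balance the
    inverse-dynamics intersegmental knee load minus the muscle forces
    crossing the joint; the solver receives the negative of that
    requirement as the external load on the tibia.
    """
    F_id = load.forces["knee"]
    M_id = load.moments["knee"]
    F_cross = np.zeros(3)
    M_cross = np.zeros(3)
    for im in np.flatnonzero(geom.crosses_knee):
        fv = forces[im] * geom.knee_cross_dir[im]
        F_cross += fv
        M_cross += np.cross(geom.knee_cross_point[im] - knee_center, fv)
    F_str = F_id - F_cross
    M_str = M_id - M_cross
    return -F_str, -M_str


def run_stance(model, trial, config: SimulationConfig,
               muscles=None, states=None, loads=None,
               materials: MaterialSpec | None = None,
               extra_tip_grids: dict | None = None) -> StanceSolution:
    """Run the concurrent loop over all stance time points for one variant."""
    config.validate()
    linkage = trial.linkage
    if muscles is None:
        muscles = load_muscle_set(subject_height=linkage.subject_height)
        calibrate_slack(muscles, linkage)
    if states is None:
        states = inverse_kinematics(trial, linkage)
    if loads is None:
        loads = inverse_dynamics(states, trial, linkage)

    session = KneeContactSession(
        model, materials=materials, subject_mass=config.subject_mass,
        penalty_per_area=config.penalty_per_area)

    tip_ids = None
    if model.tear_tip_grid is not None and model.menisci.get("medial") is not None:
        tip_ids = matched_elements(model, model.tear_tip_grid)
    extra_ids = {}
    if extra_tip_grids and model.menisci.get("medial") is not None:
        for label, grid in extra_tip_grids.items():
            if grid is not None:
                extra_ids[label] = matched_elements(model, grid)
    matched_series: dict = {label: [] for label in extra_ids}

    frame_pct = np.array([s.percent_stance for s in states])
    points = []
    e_s = np.zeros(5)
    for pct in config.time_points:
        i = int(np.argmin(np.abs(frame_pct - pct)))
        st, ld = states[i], loads[i]
        tau = np.array([ld.generalized[nm] for nm in MOMENT_DOF_NAMES])

        es_hist = []
        m_resid = np.inf
        converged = False
        sol = None
        cr = None
        for it in range(1, config.outer_max_iter + 1):
            es_geom = np.zeros(5) if config.freeze_secondary_feedback else e_s
            geom = compute_muscle_geometry(linkage, st.q, muscles, e_s=es_geom)
            sol = solve_static_optimization(tau, geom, muscles,
                                            moment_tol=config.knee_moment_tol)
            poses = forward_kinematics(linkage, st.q, es_geom)
            jc = joint_centers(linkage, poses)
            F_app_g, M_app_g = _knee_reaction_wrench(ld, geom, sol.forces, poses,
                                                     jc["knee"])
            R_solve = poses["thigh"][0] @ rot_z(-st.q[9])
            F_app = R_solve.T @ F_app_g
            M_app = R_solve.T @ M_app_g
            cr, _res = session.solve(
                flexion=st.q[9],
                wrench=(F_app, float(M_app[0]), float(M_app[1])),
                tol_force=config.contact_tol)
            self_res = _res
            e_s_new = cr.e_s.copy()
            es_hist.append(e_s_new.copy())
            # convergence: the knee moment the solved activations produce
            # with the moment arms at the *contact-solved* secondary
            # kinematics must still match the demand (for the frozen-
            # feedback ablation this measures the inconsistency left by
            # not feeding e_s back)
            geom_new = compute_muscle_geometry(linkage, st.q, muscles, e_s=e_s_new)
            from .staticopt import activation_lp_matrices
            A, b, gain, fp = activation_lp_matrices(geom_new, muscles, tau)
            m_resid = float(abs((A @ sol.activations - b)[3]))
            # under-relax the secondary-kinematics update: the
            # activation <-> contact fixed point can otherwise cycle
            e_s = 0.5 * e_s + 0.5 * e_s_new if it > 1 else e_s_new
            if config.freeze_secondary_feedback or m_resid < config.knee_moment_tol:
                converged = True
                break

        tp = TimePointSolution(
            percent_stance=float(pct), frame_index=i,
            state_q=st.q.copy(), e_s=e_s.copy(), tau=tau,
            activations=sol.activations.copy(),
            muscle_forces=sol.forces.copy(),
            opt_feasible=sol.feasible,
            contact=cr, outer_iterations=it, outer_converged=converged,
            moment_residual=m_resid, es_history=es_hist,
        )
        if model.menisci.get("medial") is not None:
            sf = session.stress(self_res, "medial")
            tp.meniscus_max_shear = float(sf.max_shear.max())
            tp.sigma_cc_min = float(sf.sigma_cc.min())
            tp.sigma_cc_max = float(sf.sigma_cc.max())
            if tip_ids is not None:
                mx, mn = tag_tear_tip_stress(sf, tip_ids)
                tp.tear_tip_max_shear = mx
                tp.tear_tip_mean_shear = mn
            for label, ids in extra_ids.items():
                matched_series[label].append(tag_tear_tip_stress(sf, ids))
        points.append(tp)

    return StanceSolution(variant=model.variant, config=config, points=points,
                          matched_tip_series=matched_series)


def run_experiment_matrix(config: SimulationConfig,
                          variants=None,
                          geometry_spec: KneeGeometrySpec | None = None,
                          trial=None, out_dir=None) -> dict:
    """Run all variants under identical inputs and write summary CSVs.

    Returns {variant label: StanceSolution}; tear-tip series of torn
    variants are also evaluated on the intact knee at matched element
    locations for comparability.
    """
    config.validate()
    if variants is None:
        variants = default_variants()
    if trial is None:
        trial = generate_gait_trial(GaitTrialSpec(
            subject_mass=config.subject_mass,
            subject_height=config.subject_height,
            marker_noise_sd=config.marker_noise_sd,
            seed=config.seed,
        ))
    linkage = trial.linkage
    muscles = load_muscle_set(subject_height=linkage.subject_height)
    calibrate_slack(muscles, linkage)
    states = inverse_kinematics(trial, linkage)
    loads = inverse_dynamics(states, trial, linkage)

    intact = build_knee_geometry(geometry_spec)
    models = []
    for tear in variants:
        models.append(intact if tear is None else apply_radial_tear(intact, tear))
    tip_grids = {m.variant: m.tear_tip_grid for m in models
                 if m.tear_tip_grid is not None}
    out = {}
    failed = []
    for model in models:
        label = model.variant
        try:
            out[label] = run_stance(
                model, trial, config, muscles=muscles,
                states=states, loads=loads,
                extra_tip_grids=tip_grids if label == "intact" else None)
        except Exception as exc:      # a failed variant is flagged, not fatal
            failed.append((label, str(exc)))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_matrix_report(out, config, trial, out_dir, failed)
    return out


def write_matrix_report(solutions: dict, config: SimulationConfig, trial,
                        out_dir: Path, failed=()) -> None:
    """Summary CSVs + comparison table + plain-text run report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for label, sol in sorted(solutions.items()):
        df = sol.summary_frame()
        df.to_csv(out_dir / f"summary_{label}.csv", index=False,
                  float_format="%.6f")

    i1, i2 = grf_peak_indices(trial, config.time_points)
    rows = []
    intact = solutions.get("intact")
    for label, sol in sorted(solutions.items()):
        df = sol.summary_frame()
        row = {
            "variant": label,
            "peak_F_med_cart_BW": df["F_med_cart_BW"].max(),
            "mean_medial_ratio": df["medial_ratio"].mean(),
            "peakP_wa_MPa": df["peak_pressure_med_cart_MPa"].iloc[i1],
            "peakP_po_MPa": df["peak_pressure_med_cart_MPa"].iloc[i2],
            "tear_tip_shear_wa_MPa": df["tear_tip_max_shear_MPa"].iloc[i1],
            "tear_tip_shear_po_MPa": df["tear_tip_max_shear_MPa"].iloc[i2],
        }
        if intact is not None:
            dfi = intact.summary_frame()
            denom = max(dfi["F_med_cart_BW"].max(), 1e-12)
            row["pct_change_F_med_cart"] = 100.0 * (row["peak_F_med_cart_BW"] - denom) / denom
        rows.append(row)
    pd.DataFrame(rows).to_csv(out_dir / "comparison.csv", index=False,
                              float_format="%.6f")

    lines = [
        "femsgait experiment matrix report",
        f"config digest: {config.digest()}",
        f"variants completed: {sorted(solutions.keys())}",
        f"variants failed: {list(failed)}",
        f"GRF peak grid indices: {grf_peak_indices(trial, config.time_points)}",
    ]
    for label, sol in sorted(solutions.items()):
        n_conv = sum(p.outer_converged for p in sol.points)
        lines.append(f"{label}: {n_conv}/{len(sol.points)} time points converged; "
                     f"max outer iters {max(p.outer_iterations for p in sol.points)}")
    (out_dir / "report.txt").write_text("\n".join(lines) + "\n")
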