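"""Quasi-static hybrid position/force equilibrium of the implanted knee.

Software re-expression of a hardware-in-the-loop knee rig: flexion is
prescribed stepwise (position loop) while the five remaining tibiofemoral
degrees of freedom (AP, SI, ML translation, adduction, internal rotation)
are driven to static equilibrium between the implant contact loads and the
musculoskeletal loads (force/torque loop).  The femur (and pelvis) is fixed,
the tibia+fibula(+foot) is one rigid unit with the ankle fixed, and the
patella rides its femur-fixed path.  Each flexion step is solved by a
damped Newton iteration with a finite-difference Jacobian and warm-start
continuation along the movement.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contact import (ContactParams, RelativeMotion, elastic_foundation,
                      friction_torque, friction_wrench, penetration_field)
from .errors import ContactInfeasibleError, ParameterError, SolverStepError
from .geometry import ImplantParams, SurfaceMesh, nominal_tibia_pose
from .metrics import grood_suntay, tibia_pose_from_q
from .pose import Pose
from .soft_tissue import (Wrench, bundle_wrenches, muscle_wrenches,
                          patella_pose)

DOF_NAMES = ("ap_mm", "si_mm", "ml_mm", "adduction_deg", "rotation_deg")


@dataclass
class ConstrainedDofs:
    """The five force-controlled dofs of the tibia relative to the femur;
    flexion is never a member."""

    ap: float = 0.0
    si: float = 0.0
    ml: float = 0.0
    adduction: float = 0.0
    rotation: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.ap, self.si, self.ml,
                         self.adduction, self.rotation])

    @staticmethod
    def from_array(q) -> "ConstrainedDofs":
        q = np.asarray(q, dtype=float)
        return ConstrainedDofs(*[float(v) for v in q])


@dataclass
class NoiseSettings:
    """Emulated sensor noise added to the fed-back dofs between steps."""

    sigma_trans_mm: float = 0.01
    sigma_rot_deg: float = 0.01


@dataclass
class MovementSchedule:
    """Prescribed flexion schedule of one movement."""

    kind: str = "flexion"            # 'flexion' or 'extension'
    start: float | None = None
    end: float | None = None
    step: float = 1.0
    repetitions: int = 3
    noise: NoiseSettings | None = None
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("flexion", "extension"):
            raise ParameterError(f"unknown movement kind '{self.kind}'")
        if self.start is None:
            self.start = 10.0 if self.kind == "flexion" else 60.0
        if self.end is None:
            self.end = 120.0 if self.kind == "flexion" else -10.0
        if self.step <= 0:
            raise ParameterError("schedule step must be positive")
        if self.repetitions < 1:
            raise ParameterError("at least one repetition required")

    def angles(self) -> np.ndarray:
        if self.kind == "flexion":
            a = np.arange(self.start, self.end + 0.5 * self.step, self.step)
            return a[a <= self.end + 1e-9]
        a = np.arange(self.start, self.end - 0.5 * self.step, -self.step)
        return a[a >= self.end - 1e-9]

    @property
    def rate_sign(self) -> float:
        return 1.0 if self.kind == "flexion" else -1.0


@dataclass
class SolverSettings:
    tolerance: float = 1e-3      # residual norm, N / N mm
    max_iterations: int = 50
    fd_step: float = 1e-4        # mm / deg
    min_line_search: float = 1.0 / 256.0
    max_step: float = 3.0        # per-iteration dof step cap (mm / deg)


@dataclass
class KneeModel:
    """Everything the equilibrium solver needs, bundled.

    Bodies: femur (fixed, world frame), tibia+fibula+foot rigid unit,
    patella on its femur-fixed path.  Segment mass defaults are the standard
    anthropometric shank+foot fraction (6.1 %) of the 80 kg donor mass, with
    the combined centre of mass 250 mm distal of the knee on the tibial axis.
    Gravity points along -x of the femur frame (seated posture, femoral
    anterior axis up).
    """

    femoral_mesh: SurfaceMesh
    insert_mesh: SurfaceMesh
    pose_implant_femur: Pose
    pose_insert_tibia: Pose
    bundles: list
    muscles: list
    patella_path: object
    contact: ContactParams = field(default_factory=ContactParams)
    shank_mass_kg: float = 4.88
    shank_com: np.ndarray = field(
        default_factory=lambda: np.array([0.0, -250.0, 0.0]))
    gravity_dir: np.ndarray = field(
        default_factory=lambda: np.array([-1.0, 0.0, 0.0]))
    g: float = 9.81
    solver: SolverSettings = field(default_factory=SolverSettings)
    flexion_axis_dir: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    flexion_axis_point: np.ndarray = field(
        default_factory=lambda: np.zeros(3))

    @property
    def implant_params(self) -> ImplantParams:
        return self.insert_mesh.metadata.get("params", ImplantParams())

    def copy(self) -> "KneeModel":
        return copy.deepcopy(self)

    def body_poses(self, flexion: float, q) -> dict:
        return {
            "femur": Pose.identity(),
            "tibia": tibia_pose_from_q(flexion, q),
            "patella": patella_pose(self.patella_path, flexion),
        }

    def initial_guess(self, flexion: float) -> np.ndarray:
        pose = nominal_tibia_pose(flexion, self.implant_params)
        st = grood_suntay(Pose.identity(), pose)
        return np.array([st.ap, st.si, st.ml, st.adduction, st.rotation])


# ---------------------------------------------------------------------------
# residual: generalized forces on the five constrained directions
# ---------------------------------------------------------------------------

def _gs_directions(pose_tibia: Pose):
    e1 = np.array([0.0, 0.0, 1.0])           # femoral ML (flexion) axis
    e3 = pose_tibia.R[:, 1]                   # tibial long axis
    e2 = np.cross(e3, e1)
    e2 = e2 / np.linalg.norm(e2)
    return e1, e2, e3


def body_wrenches(model: KneeModel, flexion: float, q,
                  rate_sign: float = 0.0,
                  include_gravity: bool = True) -> tuple[dict, dict]:
    """Per-body wrenches of all force elements plus a diagnostics dict."""
    poses = model.body_poses(flexion, q)
    wrenches = {b: Wrench() for b in poses}
    diag: dict = {"tensions": {}, "poses": poses}

    # ligaments
    total_tension = 0.0
    for b in model.bundles:
        T, ws = bundle_wrenches(b, poses)
        diag["tensions"][b.name] = T
        total_tension += T
        for body, w in ws.items():
            wrenches[body] += w
    diag["total_ligament_tension"] = total_tension

    # muscles (quadriceps over the trochlear ellipsoid)
    for body, w in muscle_wrenches(model.muscles, poses).items():
        wrenches[body] += w

    # implant contact (+ sliding friction)
    pose_f = model.pose_implant_femur
    pose_i = poses["tibia"] @ model.pose_insert_tibia
    fld = penetration_field(model.femoral_mesh, pose_f,
                            model.insert_mesh, pose_i, model.contact)
    res = elastic_foundation(fld, model.contact)
    motion = RelativeMotion(axis_point=model.flexion_axis_point,
                            axis_dir=model.flexion_axis_dir,
                            rate_sign=rate_sign)
    fw = friction_wrench(res, motion, model.contact)
    wrenches["tibia"] += Wrench(res.force + fw.force, res.torque + fw.torque)
    # the femoral side receives the exact reaction
    wrenches["femur"] += Wrench(-(res.force + fw.force),
                                -(res.torque + fw.torque))
    diag["contact"] = res
    diag["friction_torque"] = friction_torque(res, motion, model.contact)

    # gravity on the shank unit (external load, excluded from conservation)
    if include_gravity:
        com_w = poses["tibia"].apply(model.shank_com)
        weight = model.shank_mass_kg * model.g
        g_dir = model.gravity_dir / np.linalg.norm(model.gravity_dir)
        wrenches["tibia"] += Wrench.from_point_force(com_w, weight * g_dir)

    return wrenches, diag


def residual(model: KneeModel, flexion: float, q,
             rate_sign: float = 0.0, return_diag: bool = False):
    """5-vector of generalized forces on the constrained directions.

    Components: force along the floating AP axis, the tibial long axis and
    the femoral ML axis, and torque (about the femoral origin) about the
    floating and tibial-long axes.  The remaining torque component, about
    the flexion axis, is the unconstrained direction held by the position
    loop.  Zero vector <=> equilibrium.
    """
    q = np.asarray(q, dtype=float)
    wrenches, diag = body_wrenches(model, flexion, q, rate_sign)
    w = wrenches["tibia"]
    e1, e2, e3 = _gs_directions(diag["poses"]["tibia"])
    r = np.array([w.force @ e2, w.force @ e3, w.force @ e1,
                  w.torque @ e2, w.torque @ e3])
    if return_diag:
        diag["wrenches"] = wrenches
        return r, diag
    return r


def soft_tissue_contact_balance(model: KneeModel, flexion: float, q) -> Wrench:
    """Total soft-tissue + contact wrench summed over all bodies.

    Action-reaction demands this be zero at any pose; gravity (an external
    load) is excluded.
    """
    wrenches, _ = body_wrenches(model, flexion, q, rate_sign=0.0,
                                include_gravity=False)
    out = Wrench()
    for w in wrenches.values():
        out += w
    return out


# ---------------------------------------------------------------------------
# Newton solve and movement continuation
# ---------------------------------------------------------------------------

def _try_residual(model, flexion, q, rate_sign):
    try:
        return residual(model, flexion, q, rate_sign)
    except ContactInfeasibleError:
        return None


def solve_equilibrium(model: KneeModel, flexion: float, guess,
                      rate_sign: float = 0.0):
    """Damped Newton iteration on the five constrained dofs.

    Converged when the residual norm drops below the solver tolerance
    (default 1e-3 N / N mm).  Raises :class:`SolverStepError` carrying the
    best iterate on non-convergence (e.g. gross slope-induced subluxation).
    """
    s = model.solver
    q = np.asarray(guess, dtype=float).copy()
    r = residual(model, flexion, q, rate_sign)
    norm = float(np.linalg.norm(r))
    best_q, best_norm = q.copy(), norm
    iterations = 0

    for iterations in range(s.max_iterations):
        if norm < s.tolerance:
            return q, {"iterations": iterations, "residual_norm": norm}
        # forward-difference Jacobian
        J = np.empty((5, 5))
        for j in range(5):
            qp = q.copy()
            qp[j] += s.fd_step
            rp = _try_residual(model, flexion, qp, rate_sign)
            if rp is None:
                qp[j] -= 2 * s.fd_step
                rm = _try_residual(model, flexion, qp, rate_sign)
                if rm is None:
                    raise SolverStepError(
                        "contact infeasible in Jacobian evaluation",
                        best_q=best_q, best_residual=best_norm,
                        iterations=iterations)
                J[:, j] = (r - rm) / s.fd_step
            else:
                J[:, j] = (rp - r) / s.fd_step
        # truncated least squares: exact Newton step for well-conditioned J,
        # minimum-norm step along indifferent (singular) directions
        dq = np.linalg.lstsq(J, -r, rcond=1e-10)[0]
        big = np.max(np.abs(dq))
        if big > s.max_step:
            dq *= s.max_step / big

        t = 1.0
        accepted = False
        while t >= s.min_line_search:
            r_new = _try_residual(model, flexion, q + t * dq, rate_sign)
            if r_new is not None:
                n_new = float(np.linalg.norm(r_new))
                if n_new < norm * (1.0 - 1e-4 * t) or n_new < s.tolerance:
                    q = q + t * dq
                    r, norm = r_new, n_new
                    accepted = True
                    break
            t *= 0.5
        if not accepted:
            break
        if norm < best_norm:
            best_q, best_norm = q.copy(), norm

    if norm < s.tolerance:
        return q, {"iterations": iterations + 1, "residual_norm": norm}
    raise SolverStepError(
        f"no equilibrium at flexion {flexion:.1f} deg "
        f"(residual {best_norm:.3g})",
        best_q=best_q, best_residual=best_norm, iterations=iterations + 1)


@dataclass
class FlexionTrace:
    """Per-step record of a movement (all repetitions stacked)."""

    df: pd.DataFrame
    schedule: MovementSchedule
    stable: bool = True
    metadata: dict = field(default_factory=dict)

    def repetition(self, i: int) -> pd.DataFrame:
        return self.df[self.df["repetition"] == i].reset_index(drop=True)

    def to_csv(self, path):
        self.df.to_csv(path, index=False)


def _record_step(model, flexion, q, rate_sign, solve_info, rep):
    r, diag = residual(model, flexion, q, rate_sign, return_diag=True)
    res = diag["contact"]
    pose_t = diag["poses"]["tibia"]
    pose_insert_world = pose_t @ model.pose_insert_tibia
    inv_ins = pose_insert_world.inverse()
    pf = model.pose_implant_femur
    meta = model.femoral_mesh.metadata
    ffc_med = inv_ins.apply(pf.apply(meta["ffc_medial"]))
    ffc_lat = inv_ins.apply(pf.apply(meta["ffc_lateral"]))
    fem_in_tibia = pose_t.inverse().apply(np.zeros(3))

    row = {
        "repetition": rep,
        "flexion_deg": flexion,
        "ap_mm": q[0], "si_mm": q[1], "ml_mm": q[2],
        "adduction_deg": q[3], "rotation_deg": q[4],
        "contact_force_n": res.force_magnitude,
        "medial_force_n": res.normal_force_medial,
        "lateral_force_n": res.normal_force_lateral,
        "friction_torque_nmm": diag["friction_torque"],
        "max_penetration_mm": res.max_penetration,
        "residual_norm": solve_info["residual_norm"],
        "iterations": solve_info["iterations"],
        "ffc_med_ap_mm": ffc_med[0], "ffc_med_si_mm": ffc_med[1],
        "ffc_lat_ap_mm": ffc_lat[0], "ffc_lat_si_mm": ffc_lat[1],
        "fem_ap_in_tibia_mm": fem_in_tibia[0],
        "total_lig_tension_n": diag["total_ligament_tension"],
    }
    by_structure: dict = {}
    for b in model.bundles:
        by_structure.setdefault(b.structure, 0.0)
        by_structure[b.structure] += diag["tensions"][b.name]
    for s, v in sorted(by_structure.items()):
        row[f"lig_{s}_n"] = v
    return row


def run_movement(model: KneeModel, schedule: MovementSchedule) -> FlexionTrace:
    """Continuation over the flexion schedule with warm starts.

    With noise magnitudes set, seeded Gaussian perturbations are added to
    the fed-back (recorded) dofs between steps, one RNG stream per
    repetition; with noise off, repetitions are bit-identical.  A step
    error aborts the movement and flags the partial trace unstable.
    """
    angles = schedule.angles()
    rows = []
    stable = True
    for rep in range(schedule.repetitions):
        rng = np.random.default_rng(schedule.seed + rep)
        q = model.initial_guess(angles[0])
        q_prev = None
        try:
            for flexion in angles:
                guess = q if q_prev is None else q + (q - q_prev)
                try:
                    q_new, info = solve_equilibrium(model, flexion, guess,
                                                    schedule.rate_sign)
                except (SolverStepError, ContactInfeasibleError):
                    # retry once from the cold geometric guess
                    q_new, info = solve_equilibrium(
                        model, flexion, model.initial_guess(flexion),
                        schedule.rate_sign)
                q_prev, q = q.copy(), q_new
                q_rec = q
                if schedule.noise is not None:
                    n = schedule.noise
                    q_rec = q + np.concatenate([
                        rng.normal(0.0, n.sigma_trans_mm, 3),
                        rng.normal(0.0, n.sigma_rot_deg, 2)])
                rows.append(_record_step(model, flexion, q_rec,
                                         schedule.rate_sign, info, rep))
                if schedule.noise is not None:
                    q = q_rec
        except (SolverStepError, ContactInfeasibleError):
            stable = False
            break
    df = pd.DataFrame(rows)
    return FlexionTrace(df=df, schedule=schedule, stable=stable,
                        metadata={"pose_implant_femur": model.pose_implant_femur,
                                  "pose_insert_tibia": model.pose_insert_tibia})
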