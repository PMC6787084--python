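"""Elastic-foundation (Winkler) implant-on-implant contact.

The polyethylene insert carries a one-sided elastic foundation: each
articular surface element of the insert exerts a pressure proportional to
its penetration into the rigid femoral component, p = k_c * depth.  Sliding
friction is Coulomb-type, opposing the relative surface motion produced by
the flexion rate; its resultant about the flexion axis is the resisting
torque that the physical test rig measures and feeds back.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ContactInfeasibleError
from .geometry import SurfaceMesh
from .pose import Pose
from .soft_tissue import Wrench


@dataclass(frozen=True)
class ContactParams:
    """Foundation stiffness k_c (N/mm^3), friction coefficient, guard cap."""

    k_c: float = 30.0
    mu: float = 0.04
    penetration_cap: float = 2.0

    def validate(self):
        if self.k_c <= 0:
            raise ValueError("foundation stiffness must be positive")
        if not (0 <= self.mu < 0.2):
            raise ValueError("friction coefficient must lie in [0, 0.2)")
        if self.penetration_cap <= 0:
            raise ValueError("penetration cap must be positive")
        return self


@dataclass
class PenetrationField:
    """Per-element penetration of the insert foundation into the femur."""

    depths: np.ndarray        # (m,) signed depth, positive = overlap
    centroids: np.ndarray     # (m, 3) world
    normals: np.ndarray       # (m, 3) world, insert outward
    areas: np.ndarray         # (m,)
    compartment: np.ndarray   # (m,) +1 lateral / -1 medial
    capped: np.ndarray        # (m,) bool


@dataclass
class RelativeMotion:
    """Flexion-axis screw motion of the femur relative to the tibia."""

    axis_point: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis_dir: np.ndarray = field(default_factory=lambda: np.array([0., 0., 1.]))
    rate_sign: float = 1.0    # +1 flexing, -1 extending, 0 static


@dataclass
class ContactResult:
    """Resultant of one contact evaluation (forces on the tibia side)."""

    force: np.ndarray                 # N, world, on tibia/insert
    torque: np.ndarray                # N mm about the reference point
    reference_point: np.ndarray
    cop_medial: np.ndarray | None
    cop_lateral: np.ndarray | None
    normal_force_medial: float
    normal_force_lateral: float
    max_penetration: float
    field: PenetrationField | None = None

    @property
    def force_magnitude(self) -> float:
        return float(np.linalg.norm(self.force))


def _mesh_signed_depth(femoral: SurfaceMesh, points_body: np.ndarray):
    """Fallback signed depth via nearest-point queries on the mesh."""
    import trimesh
    tm = femoral.to_trimesh()
    closest, dist, fid = trimesh.proximity.closest_point(tm, points_body)
    # sign via the dot product with the outward normal of the nearest face
    n = tm.face_normals[fid]
    inside = np.einsum("ij,ij->i", points_body - closest, n) < 0
    return np.where(inside, dist, -dist)


def penetration_field(femoral: SurfaceMesh, pose_f: Pose,
                      insert: SurfaceMesh, pose_t: Pose,
                      params: ContactParams | None = None) -> PenetrationField:
    """Signed penetration of each insert articular element into the femur.

    Depths are evaluated at element centroids, measured as depth into the
    femoral solid (positive = overlap), with forces later applied along the
    insert element normals (one-sided foundation convention).  Elements
    beyond the solver cap raise :class:`ContactInfeasibleError`.
    """
    params = (params or ContactParams()).validate()
    art = (insert.articular if insert.articular is not None
           else np.ones(len(insert.faces), bool))
    cent_local = insert.face_centroids()[art]
    n_local, a_local = insert.face_normals_areas()
    n_local, a_local = n_local[art], a_local[art]
    comp = (insert.compartment[art] if insert.compartment is not None
            else np.zeros(art.sum(), dtype=int))

    cent_w = pose_t.apply(cent_local)
    n_w = pose_t.apply_vector(n_local)

    pts_f = pose_f.inverse().apply(cent_w)
    if femoral.distance_field is not None:
        depths = np.asarray(femoral.distance_field(pts_f), dtype=float)
    else:
        depths = _mesh_signed_depth(femoral, pts_f)

    capped = depths > params.penetration_cap
    if np.any(capped):
        raise ContactInfeasibleError(depths.max(), params.penetration_cap)
    return PenetrationField(depths=depths, centroids=cent_w, normals=n_w,
                            areas=a_local, compartment=comp, capped=capped)


def elastic_foundation(field: PenetrationField,
                       params: ContactParams | None = None,
                       reference_point=(0.0, 0.0, 0.0)) -> ContactResult:
    """Integrate the foundation pressure p = k_c * depth over the insert.

    Element force on the insert is -p*A*n (the femur pushes the insert away
    along the element normal); the femur receives the exact opposite.
    """
    params = (params or ContactParams()).validate()
    ref = np.asarray(reference_point, dtype=float)
    pen = np.maximum(field.depths, 0.0)
    p = params.k_c * pen
    f_el = -(p * field.areas)[:, None] * field.normals      # on insert
    force = f_el.sum(axis=0)
    torque = np.cross(field.centroids - ref, f_el).sum(axis=0)

    def compartment(side):
        m = (field.compartment == side) & (pen > 0)
        w = (p * field.areas)[m]
        if w.sum() == 0:
            return None, 0.0
        cop = (w[:, None] * field.centroids[m]).sum(axis=0) / w.sum()
        return cop, float(w.sum())

    cop_med, n_med = compartment(-1)
    cop_lat, n_lat = compartment(+1)
    return ContactResult(force=force, torque=torque, reference_point=ref,
                         cop_medial=cop_med, cop_lateral=cop_lat,
                         normal_force_medial=n_med, normal_force_lateral=n_lat,
                         max_penetration=float(pen.max(initial=0.0)),
                         field=field)


def friction_torque(result: ContactResult, relative_motion: RelativeMotion,
                    params: ContactParams | None = None) -> float:
    """Coulomb resisting torque about the flexion axis (N mm).

    mu * sum(element normal force * moment arm about the axis), signed to
    oppose the flexion rate; zero for mu = 0 or no contact.
    """
    params = (params or ContactParams()).validate()
    if params.mu == 0.0 or result.field is None:
        return 0.0
    f = result.field
    pen = np.maximum(f.depths, 0.0)
    if relative_motion.rate_sign == 0 or not np.any(pen > 0):
        return 0.0
    n_el = params.k_c * pen * f.areas
    r = f.centroids - np.asarray(relative_motion.axis_point, dtype=float)
    a = np.asarray(relative_motion.axis_dir, dtype=float)
    a = a / np.linalg.norm(a)
    r_perp = np.linalg.norm(r - np.outer(r @ a, a), axis=1)
    return float(-np.sign(relative_motion.rate_sign) * params.mu
                 * (n_el * r_perp).sum())


def friction_wrench(result: ContactResult, relative_motion: RelativeMotion,
                    params: ContactParams | None = None) -> Wrench:
    """Tangential Coulomb friction wrench on the tibia (femur gets -this).

    Each loaded element receives mu * p * A along the tangential direction
    of the femoral surface velocity (the femur drags the insert with it), so
    friction power on the moving side is non-positive.
    """
    params = (params or ContactParams()).validate()
    if params.mu == 0.0 or result.field is None:
        return Wrench()
    f = result.field
    pen = np.maximum(f.depths, 0.0)
    loaded = pen > 0
    if relative_motion.rate_sign == 0 or not np.any(loaded):
        return Wrench()
    a = np.asarray(relative_motion.axis_dir, dtype=float)
    a = a / np.linalg.norm(a)
    omega = np.sign(relative_motion.rate_sign) * a
    r = f.centroids[loaded] - np.asarray(relative_motion.axis_point, float)
    v = np.cross(omega, r)                                   # femur surface vel
    n = f.normals[loaded]
    v_t = v - n * np.einsum("ij,ij->i", v, n)[:, None]
    speed = np.linalg.norm(v_t, axis=1)
    ok = speed > 1e-12
    v_hat = np.zeros_like(v_t)
    v_hat[ok] = v_t[ok] / speed[ok, None]
    f_el = (params.mu * params.k_c * pen[loaded] * f.areas[loaded])[:, None] * v_hat
    force = f_el.sum(axis=0)
    torque = np.cross(f.centroids[loaded], f_el).sum(axis=0)
    return Wrench(force, torque)
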