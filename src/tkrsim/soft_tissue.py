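"""Passive and active force elements of the virtual knee.

Ligaments are one-dimensional tension-only springs with the standard
slack-region / quadratic-toe / linear force law.  The four quadriceps heads
carry a constant total tension (default 120 N) and wrap over a femur-fixed
trochlear ellipsoid.  The patella rides a femur-fixed one-degree-of-freedom
path parameterized by arc length; it only routes the extensor mechanism, no
patellofemoral contact force is computed.  Ligaments are straight-line
elements (no wrapping).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, ParameterError
from .pose import Pose


# ---------------------------------------------------------------------------
# wrenches
# ---------------------------------------------------------------------------

@dataclass
class Wrench:
    """Force and torque about the world origin (N, N mm)."""

    force: np.ndarray = field(default_factory=lambda: np.zeros(3))
    torque: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __iadd__(self, other: "Wrench"):
        self.force = self.force + other.force
        self.torque = self.torque + other.torque
        return self

    @staticmethod
    def from_point_force(point, force) -> "Wrench":
        point = np.asarray(point, dtype=float)
        force = np.asarray(force, dtype=float)
        return Wrench(force, np.cross(point, force))


def total_wrench(wrenches: dict) -> Wrench:
    out = Wrench()
    for w in wrenches.values():
        out += w
    return out


# ---------------------------------------------------------------------------
# ligament bundles
# ---------------------------------------------------------------------------

@dataclass
class LigamentBundle:
    """Tension-only bundle between two body-fixed attachment points.

    ``stiffness`` is force per unit strain (N); ``reference_length`` L0 is
    the slack length (mm); ``eps_l`` is the slack-transition strain of the
    quadratic toe region.
    """

    name: str
    structure: str
    origin_body: str
    origin: np.ndarray
    insertion_body: str
    insertion: np.ndarray
    stiffness: float
    reference_length: float
    eps_l: float = 0.03
    active: bool = True

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.insertion = np.asarray(self.insertion, dtype=float).reshape(3)
        if self.stiffness <= 0:
            raise ParameterError(f"bundle '{self.name}': stiffness must be > 0")
        if self.reference_length <= 0:
            raise ParameterError(f"bundle '{self.name}': L0 must be > 0")
        if not (0 < self.eps_l < 0.2):
            raise ParameterError(
                f"bundle '{self.name}': eps_l must lie in (0, 0.2)")


def ligament_force(bundle: LigamentBundle, current_length: float) -> float:
    """Tension (N) of a bundle at the given straight-line length (mm).

    strain eps = (L - L0)/L0; zero in the slack region (eps <= 0), quadratic
    toe k eps^2 / (4 eps_l) for 0 < eps <= 2 eps_l, linear k (eps - eps_l)
    beyond; continuous and once-differentiable at the branch point.
    """
    if current_length <= 0:
        raise ParameterError("ligament length must be positive")
    if not bundle.active:
        return 0.0
    eps = (current_length - bundle.reference_length) / bundle.reference_length
    if eps <= 0.0:
        return 0.0
    if eps <= 2.0 * bundle.eps_l:
        return bundle.stiffness * eps * eps / (4.0 * bundle.eps_l)
    return bundle.stiffness * (eps - bundle.eps_l)


def bundle_endpoints(bundle: LigamentBundle, poses: dict) -> tuple:
    """World positions of (origin, insertion) given body poses."""
    p_o = poses[bundle.origin_body].apply(bundle.origin)
    p_i = poses[bundle.insertion_body].apply(bundle.insertion)
    return p_o, p_i


def bundle_length(bundle: LigamentBundle, poses: dict) -> float:
    p_o, p_i = bundle_endpoints(bundle, poses)
    return float(np.linalg.norm(p_i - p_o))


def bundle_wrenches(bundle: LigamentBundle, poses: dict) -> tuple:
    """(tension, {body: Wrench}) for one bundle at the given poses."""
    p_o, p_i = bundle_endpoints(bundle, poses)
    d = p_o - p_i
    L = float(np.linalg.norm(d))
    T = ligament_force(bundle, L)
    if T == 0.0:
        return 0.0, {}
    u = d / L
    w = {
        bundle.insertion_body: Wrench.from_point_force(p_i, T * u),
        bundle.origin_body: Wrench.from_point_force(p_o, -T * u),
    }
    return T, w


def resect(bundles: list, names) -> list:
    """Deactivate bundles by structure name or bundle id (returns new list).

    Deactivation is reversible via :func:`reactivate`; inactive bundles
    produce exactly zero force and no other bundle is touched.
    """
    if isinstance(names, str):
        names = [names]
    known = set()
    for b in bundles:
        known.add(b.structure)
        known.add(b.name)
    unknown = [n for n in names if n not in known]
    if unknown:
        raise ConfigurationError(f"unknown ligament name(s): {unknown}")
    return [replace(b, active=False)
            if (b.structure in names or b.name in names) else b
            for b in bundles]


def reactivate(bundles: list, names) -> list:
    if isinstance(names, str):
        names = [names]
    return [replace(b, active=True)
            if (b.structure in names or b.name in names) else b
            for b in bundles]


# ---------------------------------------------------------------------------
# muscle elements with ellipsoid wrapping
# ---------------------------------------------------------------------------

@dataclass
class WrapEllipsoid:
    """Body-fixed wrapping obstacle."""

    body: str
    centre: np.ndarray
    semi_axes: np.ndarray
    R: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.centre = np.asarray(self.centre, dtype=float).reshape(3)
        self.semi_axes = np.asarray(self.semi_axes, dtype=float).reshape(3)
        self.R = np.asarray(self.R, dtype=float).reshape(3, 3)
        if np.any(self.semi_axes <= 0):
            raise ParameterError("ellipsoid semi-axes must be positive")


@dataclass
class MuscleElement:
    """Constant-tension line element between two body-fixed points."""

    name: str
    origin_body: str
    origin: np.ndarray
    insertion_body: str
    insertion: np.ndarray
    tension: float
    obstacle: WrapEllipsoid | None = None

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.insertion = np.asarray(self.insertion, dtype=float).reshape(3)
        if self.tension < 0:
            raise ParameterError(f"muscle '{self.name}': tension must be >= 0")


def _sphere_space(obstacle: WrapEllipsoid, poses: dict):
    """Affine map world -> unit-sphere space of the obstacle and back."""
    pose = poses[obstacle.body]
    R_w = pose.R @ obstacle.R
    c_w = pose.apply(obstacle.centre)

    def to_s(p):
        return (np.asarray(p, dtype=float) - c_w) @ R_w / obstacle.semi_axes

    def from_s(p):
        return (np.asarray(p, dtype=float) * obstacle.semi_axes) @ R_w.T + c_w

    return to_s, from_s


def wrap_path(element: MuscleElement, poses: dict, n_arc: int = 16):
    """Polyline path and effective length of a (possibly wrapped) element.

    If the straight segment misses the obstacle the path is that segment.
    Otherwise a tangent-arc via-point path is constructed in the affinely
    scaled (unit-sphere) space of the ellipsoid and mapped back; exact for
    spherical obstacles, an approximation of the geodesic for ellipsoids.
    """
    p0 = poses[element.origin_body].apply(element.origin)
    p1 = poses[element.insertion_body].apply(element.insertion)
    straight = np.vstack([p0, p1])
    if element.obstacle is None:
        return straight, float(np.linalg.norm(p1 - p0))

    to_s, from_s = _sphere_space(element.obstacle, poses)
    a, b = to_s(p0), to_s(p1)
    ra, rb = np.linalg.norm(a), np.linalg.norm(b)
    if ra <= 1.0 or rb <= 1.0:
        raise ConfigurationError(
            f"muscle '{element.name}': endpoint inside wrapping obstacle")

    # closest approach of the scaled segment to the sphere centre
    ab = b - a
    t = np.clip(-a @ ab / (ab @ ab), 0.0, 1.0)
    closest = a + t * ab
    if np.linalg.norm(closest) >= 1.0:
        return straight, float(np.linalg.norm(p1 - p0))

    # wrap in the plane through a, b and the centre, on the side of the
    # segment's closest-approach direction
    e1 = a / ra
    e2 = ab - (ab @ e1) * e1
    e2 = e2 / np.linalg.norm(e2)

    def plane(p):
        return np.array([p @ e1, p @ e2])

    def unplane(q):
        return q[0] * e1 + q[1] * e2

    a2, b2 = plane(a), plane(b)
    d2 = plane(closest)
    d2 = d2 / np.linalg.norm(d2)

    def tangent_point(p2):
        r = np.linalg.norm(p2)
        alpha = np.arccos(1.0 / r)
        base = np.arctan2(p2[1], p2[0])
        cands = [np.array([np.cos(base + s * alpha), np.sin(base + s * alpha)])
                 for s in (+1.0, -1.0)]
        return max(cands, key=lambda tpt: tpt @ d2)

    ta, tb = tangent_point(a2), tangent_point(b2)
    ang_a, ang_b = np.arctan2(ta[1], ta[0]), np.arctan2(tb[1], tb[0])
    dang = np.arctan2(np.sin(ang_b - ang_a), np.cos(ang_b - ang_a))
    angles = ang_a + np.linspace(0.0, dang, n_arc + 1)
    arc2 = np.stack([np.cos(angles), np.sin(angles)], axis=1)
    pts_s = [a] + [unplane(q) for q in arc2] + [b]
    path = np.array([from_s(p) for p in pts_s])
    length = float(np.linalg.norm(np.diff(path, axis=0), axis=1).sum())
    return path, length


def muscle_wrenches(elements: list, poses: dict) -> dict:
    """Per-body wrenches of all muscle elements (sums exactly to zero).

    Tension acts along the terminal path tangents at the two attachments;
    the obstacle body receives the net reaction of the wrapped segment.
    """
    out: dict = {}

    def add(body, w):
        if body not in out:
            out[body] = Wrench()
        out[body] += w

    for el in elements:
        path, _ = wrap_path(el, poses)
        u0 = path[1] - path[0]
        u0 = u0 / np.linalg.norm(u0)
        u1 = path[-2] - path[-1]
        u1 = u1 / np.linalg.norm(u1)
        w0 = Wrench.from_point_force(path[0], el.tension * u0)
        w1 = Wrench.from_point_force(path[-1], el.tension * u1)
        add(el.origin_body, w0)
        add(el.insertion_body, w1)
        if el.obstacle is not None and len(path) > 2:
            add(el.obstacle.body,
                Wrench(-(w0.force + w1.force), -(w0.torque + w1.torque)))
    return out


# ---------------------------------------------------------------------------
# patella path joint
# ---------------------------------------------------------------------------

class CircularArcPath:
    """Analytic femur-fixed trochlear arc, the default patella path.

    The patella centre travels on a circle of radius ``radius`` about
    ``centre`` in the sagittal plane; path angle beta (from the anterior
    direction, towards distal) maps linearly to flexion:
    ``beta = beta0 + gain * flexion``.
    """

    def __init__(self, centre=(0.0, 25.0, 0.0), radius=45.0,
                 beta0_deg=-10.0, gain=0.7,
                 flexion_range=(-15.0, 125.0)):
        self.centre = np.asarray(centre, dtype=float)
        self.radius = float(radius)
        self.beta0 = float(beta0_deg)
        self.gain = float(gain)
        self.flexion_range = tuple(flexion_range)
        if radius <= 0 or gain == 0:
            raise ParameterError("arc path needs radius > 0 and gain != 0")

    def arc_length(self, flexion_deg: float) -> float:
        beta = np.deg2rad(self.beta0 + self.gain * flexion_deg)
        beta0 = np.deg2rad(self.beta0)
        return self.radius * (beta - beta0)

    def pose(self, flexion_deg: float) -> Pose:
        beta = np.deg2rad(self.beta0 + self.gain * flexion_deg)
        radial = np.array([np.cos(beta), -np.sin(beta), 0.0])
        tangent = np.array([-np.sin(beta), -np.cos(beta), 0.0])
        pos = self.centre + self.radius * radial
        R = np.column_stack([radial, -tangent, np.array([0.0, 0.0, 1.0])])
        return Pose(R, pos)


class TabulatedPath:
    """Patella path from a calibration table (flexion -> pose)."""

    def __init__(self, flexion_deg, positions, rotations=None):
        self.flexion = np.asarray(flexion_deg, dtype=float)
        self.positions = np.asarray(positions, dtype=float)
        if np.any(np.diff(self.flexion) <= 0):
            raise ConfigurationError("path table flexion must be increasing")
        self.rotations = (np.asarray(rotations, dtype=float)
                          if rotations is not None
                          else np.tile(np.eye(3), (len(self.flexion), 1, 1)))
        self.flexion_range = (float(self.flexion[0]), float(self.flexion[-1]))
        seg = np.linalg.norm(np.diff(self.positions, axis=0), axis=1)
        if np.any(seg == 0):
            raise ConfigurationError("path table has coincident knots")
        self._arclen = np.concatenate([[0.0], np.cumsum(seg)])

    def arc_length(self, flexion_deg: float) -> float:
        return float(np.interp(flexion_deg, self.flexion, self._arclen))

    def pose(self, flexion_deg: float) -> Pose:
        i = int(np.searchsorted(self.flexion, flexion_deg, side="right") - 1)
        i = np.clip(i, 0, len(self.flexion) - 2)
        f0, f1 = self.flexion[i], self.flexion[i + 1]
        w = (flexion_deg - f0) / (f1 - f0)
        pos = (1 - w) * self.positions[i] + w * self.positions[i + 1]
        from scipy.spatial.transform import Rotation, Slerp
        sl = Slerp([0.0, 1.0],
                   Rotation.from_matrix([self.rotations[i],
                                         self.rotations[i + 1]]))
        return Pose(sl(np.clip(w, 0, 1)).as_matrix(), pos)


def default_patella_path() -> CircularArcPath:
    return CircularArcPath()


def load_patella_path_csv(path_or_buf) -> TabulatedPath:
    """Load a calibrated patella path table.

    Columns: flexion_deg, x_mm, y_mm, z_mm, qw, qx, qy, qz (orientation as
    a unit quaternion of the patella frame in the femur frame).
    """
    import pandas as pd
    from scipy.spatial.transform import Rotation
    df = pd.read_csv(path_or_buf)
    required = {"flexion_deg", "x_mm", "y_mm", "z_mm", "qw", "qx", "qy", "qz"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(
            f"patella path CSV missing columns: {sorted(missing)}")
    pos = df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    quat_xyzw = df[["qx", "qy", "qz", "qw"]].to_numpy(dtype=float)
    rot = Rotation.from_quat(quat_xyzw).as_matrix()
    return TabulatedPath(df["flexion_deg"].to_numpy(dtype=float), pos, rot)


def export_patella_path_csv(path_obj, flexion_grid, path_or_buf):
    """Sample any patella path onto a flexion grid and write the CSV table."""
    import pandas as pd
    from scipy.spatial.transform import Rotation
    rows = []
    for a in np.asarray(flexion_grid, dtype=float):
        pose = path_obj.pose(a)
        qx, qy, qz, qw = Rotation.from_matrix(pose.R).as_quat()
        rows.append({"flexion_deg": a, "x_mm": pose.t[0], "y_mm": pose.t[1],
                     "z_mm": pose.t[2], "qw": qw, "qx": qx, "qy": qy,
                     "qz": qz})
    pd.DataFrame(rows).to_csv(path_or_buf, index=False)


def patella_pose(path, flexion_deg: float) -> Pose:
    """Patella pose on the femur-fixed path at the given flexion angle."""
    lo, hi = path.flexion_range
    if flexion_deg < lo or flexion_deg > hi:
        warnings.warn(
            f"flexion {flexion_deg:.1f} deg outside calibrated patella path "
            f"range [{lo:.1f}, {hi:.1f}]; clamped", stacklevel=2)
        flexion_deg = float(np.clip(flexion_deg, lo, hi))
    return path.pose(flexion_deg)
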