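"""Parametric surrogate geometry for a cruciate-retaining TKR.

Generates every geometric input the simulator needs: a symmetric multi-radius
bicondylar femoral component, a fixed-bearing dished tibial insert with a
built-in posterior slope, anatomical reference frames, implant placement
(including slope / axial-rotation offsets) and the ligament attachment set.

Coordinate convention (right knee, all lengths mm):
    x = anterior, y = proximal, z = lateral; right-handed.
The femoral bone frame is the world frame (the femur is fixed).  The femoral
component's sagittal profile of each condyle is a large distal arc blending
tangentially into a smaller posterior arc; the condyle surface is the channel
(tube) surface of coronal radius ``coronal_radius`` swept along that profile,
so an exact signed-distance field is available for the contact model.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParameterError
from .pose import Pose

# fixed angular extents of the parametric condyle (deg, from the distal pole)
PHI_MIN = -30.0
PHI_BLEND = 40.0
PHI_MAX = 150.0
PSI_MAX = 80.0          # coronal half-extent of the condylar tube (deg)
DISH_X0 = -2.0          # AP offset of the dish floor in the insert frame (mm)


# ---------------------------------------------------------------------------
# parameters and basic containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImplantParams:
    """Geometry of the parametric size-#3-like CR implant pair.

    The femoral component is a symmetric multi-radius design: the sagittal
    profile has a large distal radius and a smaller posterior radius.  The
    insert is non-conforming: its dish radii exceed the matching femoral
    radii.  The insert carries a built-in posterior slope (default +7 deg).
    """

    distal_radius: float = 35.0          # femoral distal sagittal radius
    posterior_radius: float = 22.0       # femoral posterior sagittal radius
    coronal_radius: float = 15.0         # condylar coronal radius
    half_spacing: float = 22.0           # intercondylar half-spacing
    dish_sagittal_radius: float = 60.0   # insert dish sagittal radius
    dish_coronal_radius: float = 22.0    # insert dish coronal radius
    slope_deg: float = 7.0               # built-in posterior slope
    thickness: float = 10.0              # insert thickness
    mesh_edge: float = 1.5               # target mesh edge length

    def validate(self) -> "ImplantParams":
        radii = (self.distal_radius, self.posterior_radius, self.coronal_radius,
                 self.dish_sagittal_radius, self.dish_coronal_radius)
        if any(r <= 0 for r in radii):
            raise ParameterError("all radii must be positive")
        if self.posterior_radius >= self.distal_radius:
            raise ParameterError(
                "posterior radius must be smaller than distal radius "
                "(multi-radius design)")
        if self.posterior_radius <= self.coronal_radius:
            raise ParameterError(
                "posterior sagittal radius must exceed the coronal radius")
        if self.dish_sagittal_radius <= self.distal_radius:
            raise ParameterError(
                "dish sagittal radius must exceed the femoral distal radius "
                "(conforming designs are not modelled)")
        if self.dish_coronal_radius <= self.coronal_radius:
            raise ParameterError(
                "dish coronal radius must exceed the femoral coronal radius")
        if self.slope_deg < 0:
            raise ParameterError("built-in slope must be >= 0")
        if self.thickness <= 0 or self.mesh_edge <= 0:
            raise ParameterError("thickness and mesh edge must be positive")
        return self


@dataclass
class SurfaceMesh:
    """Triangle surface mesh in a body frame, with optional analytic field.

    ``distance_field(points)`` returns the signed depth of body-frame points
    into the solid bounded by the surface (positive inside).  For the
    parametric components it is exact; generic meshes fall back to
    nearest-point queries in the contact module.
    """

    vertices: np.ndarray                 # (n, 3)
    faces: np.ndarray                    # (m, 3) int
    articular: np.ndarray | None = None  # (m,) bool, contact-carrying faces
    compartment: np.ndarray | None = None  # (m,) int: +1 lateral, -1 medial
    distance_field: object | None = None
    metadata: dict = field(default_factory=dict)

    # -- derived quantities -------------------------------------------------
    def face_centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    def face_normals_areas(self):
        v = self.vertices[self.faces]
        c = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
        a2 = np.linalg.norm(c, axis=1)
        return c / a2[:, None], 0.5 * a2

    def area(self) -> float:
        _, a = self.face_normals_areas()
        return float(a.sum())

    def to_trimesh(self):
        import trimesh
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(),
                               process=False)

    def export(self, path: str):
        self.to_trimesh().export(path)


@dataclass(frozen=True)
class AnatomicalFrame:
    """Orthonormal right-handed frame with anatomical axis labels."""

    origin: np.ndarray
    axes: np.ndarray   # columns: anterior, proximal, lateral

    def __post_init__(self):
        object.__setattr__(self, "origin",
                           np.asarray(self.origin, dtype=float).reshape(3))
        object.__setattr__(self, "axes",
                           np.asarray(self.axes, dtype=float).reshape(3, 3))
        if np.abs(self.axes.T @ self.axes - np.eye(3)).max() > 1e-10:
            raise ParameterError("frame axes must be orthonormal to 1e-10")
        if np.linalg.det(self.axes) < 0:
            raise ParameterError("frame must be right-handed")

    @staticmethod
    def identity(origin=(0.0, 0.0, 0.0)) -> "AnatomicalFrame":
        return AnatomicalFrame(np.asarray(origin, dtype=float), np.eye(3))

    @property
    def anterior(self):
        return self.axes[:, 0]

    @property
    def proximal(self):
        return self.axes[:, 1]

    @property
    def lateral(self):
        return self.axes[:, 2]

    def as_pose(self) -> Pose:
        return Pose(self.axes, self.origin)


@dataclass(frozen=True)
class PlacementOffsets:
    """Surgical placement variation relative to the reference placement.

    ``slope_deg``    : + increases posterior slope (posterior-distal tilt).
    ``rotation_deg`` : + internal rotation of the tibial component.
    """

    slope_deg: float = 0.0
    rotation_deg: float = 0.0
    override: bool = False   # allow offsets outside the study range [-6, +6]

    def validate(self):
        if not self.override:
            for v in (self.slope_deg, self.rotation_deg):
                if abs(v) > 6.0 + 1e-12:
                    raise ParameterError(
                        f"offset {v:+g} deg outside study range [-6, +6]; "
                        "set override=True to force")
        return self


# ---------------------------------------------------------------------------
# femoral component: multi-radius condylar channel surface
# ---------------------------------------------------------------------------

def _profile_dir(phi_rad):
    """In-plane radial direction of the sagittal profile.

    phi = 0 points distally (-y); phi > 0 rotates towards posterior (-x).
    """
    phi_rad = np.asarray(phi_rad, dtype=float)
    return np.stack([-np.sin(phi_rad), -np.cos(phi_rad)], axis=-1)


def _spine_arcs(params: ImplantParams):
    """Arc centres/radii of the condylar spine (coronal-centre curve).

    The distal spine arc (radius R_d - r_c) is centred at O_d; the posterior
    arc (radius R_p - r_c) at O_p, placed on the blend direction so that the
    two sagittal profile circles share a tangent at the blend angle.
    """
    rd = params.distal_radius - params.coronal_radius
    rp = params.posterior_radius - params.coronal_radius
    o_d = np.array([5.0, params.distal_radius])          # sagittal plane (x, y)
    u = _profile_dir(np.deg2rad(PHI_BLEND))
    o_p = o_d + (rd - rp) * u
    return o_d, rd, o_p, rp


def _spine_point(phi_deg, params: ImplantParams):
    """Spine point(s) in the sagittal plane for profile angle(s) in deg."""
    o_d, rd, o_p, rp = _spine_arcs(params)
    phi = np.atleast_1d(np.asarray(phi_deg, dtype=float))
    d = _profile_dir(np.deg2rad(phi))
    pts = np.where((phi <= PHI_BLEND)[:, None], o_d + rd * d, o_p + rp * d)
    return pts


def _condyle_sdf_factory(params: ImplantParams):
    """Exact signed depth into the two-condyle solid (positive inside)."""
    o_d, rd, o_p, rp = _spine_arcs(params)
    rc = params.coronal_radius
    c = params.half_spacing
    arcs = [(o_d, rd, PHI_MIN, PHI_BLEND), (o_p, rp, PHI_BLEND, PHI_MAX)]
    # arc endpoints (3D, per condyle handled by z offset)
    ends = [_spine_point(PHI_MIN, params)[0], _spine_point(PHI_MAX, params)[0]]

    def sdf(points):
        p = np.atleast_2d(np.asarray(points, dtype=float))
        best = np.full(len(p), np.inf)
        for z0 in (c, -c):
            dz = p[:, 2] - z0
            for (o, rho, lo, hi) in arcs:
                vx = p[:, 0] - o[0]
                vy = p[:, 1] - o[1]
                r = np.hypot(vx, vy)
                phi = np.degrees(np.arctan2(-vx, -vy))
                inside = (phi >= lo) & (phi <= hi)
                d_arc = np.hypot(r - rho, dz)
                best = np.where(inside, np.minimum(best, d_arc), best)
            for e in ends:
                d_end = np.sqrt((p[:, 0] - e[0]) ** 2 + (p[:, 1] - e[1]) ** 2
                                + dz ** 2)
                best = np.minimum(best, d_end)
        return rc - best

    return sdf


def _orient_faces(vertices, faces, outward_at):
    """Flip triangles whose normal disagrees with the analytic outward field."""
    v = vertices[faces]
    n = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    want = outward_at(v.mean(axis=1))
    flip = np.einsum("ij,ij->i", n, want) < 0
    faces = faces.copy()
    faces[flip] = faces[flip][:, ::-1]
    return faces


def make_femoral_component(params: ImplantParams | None = None) -> SurfaceMesh:
    """Mesh the symmetric bicondylar femoral component.

    The posterior-arc centre of each condyle is recorded in the metadata and
    serves as that condyle's flexion facet centre (FFC).
    """
    params = (params or ImplantParams()).validate()
    o_d, rd, o_p, rp = _spine_arcs(params)
    rc, c = params.coronal_radius, params.half_spacing

    # grid resolution from the target edge length
    arc_len = np.deg2rad(PHI_MAX - PHI_MIN) * params.distal_radius
    n_phi = max(8, int(np.ceil(arc_len / params.mesh_edge)))
    n_psi = max(6, int(np.ceil(np.deg2rad(2 * PSI_MAX) * rc / params.mesh_edge)))
    phi = np.linspace(PHI_MIN, PHI_MAX, n_phi + 1)
    psi = np.deg2rad(np.linspace(-PSI_MAX, PSI_MAX, n_psi + 1))

    spine = _spine_point(phi, params)                      # (n_phi+1, 2)
    d2 = _profile_dir(np.deg2rad(phi))                     # (n_phi+1, 2)

    # lateral condyle (z0 = +c); the tube cross-section circle spans the
    # in-plane radial direction and the out-of-plane (z) direction
    cos_p, sin_p = np.cos(psi), np.sin(psi)
    vx = spine[:, None, 0] + rc * cos_p[None, :] * d2[:, None, 0]
    vy = spine[:, None, 1] + rc * cos_p[None, :] * d2[:, None, 1]
    vz = c + rc * sin_p[None, :] * np.ones((len(phi), 1))
    lat = np.stack([vx, vy, vz], axis=-1).reshape(-1, 3)
    med = lat * np.array([1.0, 1.0, -1.0])                 # exact mirror

    def grid_faces(nu, nv, offset):
        idx = np.arange((nu + 1) * (nv + 1)).reshape(nu + 1, nv + 1) + offset
        a, b = idx[:-1, :-1].ravel(), idx[1:, :-1].ravel()
        cidx, d_ = idx[1:, 1:].ravel(), idx[:-1, 1:].ravel()
        return np.concatenate([np.stack([a, b, cidx], axis=1),
                               np.stack([a, cidx, d_], axis=1)])

    f_lat = grid_faces(n_phi, n_psi, 0)
    f_med = grid_faces(n_phi, n_psi, len(lat))
    vertices = np.vstack([lat, med])
    faces = np.vstack([f_lat, f_med])

    sdf = _condyle_sdf_factory(params)

    def outward(pts):
        # gradient direction of the channel SDF: away from the nearest spine
        eps = 1e-4
        g = np.stack([
            sdf(pts + [eps, 0, 0]) - sdf(pts - [eps, 0, 0]),
            sdf(pts + [0, eps, 0]) - sdf(pts - [0, eps, 0]),
            sdf(pts + [0, 0, eps]) - sdf(pts - [0, 0, eps])], axis=1)
        return -g

    faces = _orient_faces(vertices, faces, outward)
    compartment = np.concatenate([np.ones(len(f_lat), dtype=int),
                                  -np.ones(len(f_med), dtype=int)])

    ffc_lat = np.array([o_p[0], o_p[1], c])
    ffc_med = np.array([o_p[0], o_p[1], -c])
    meta = {
        "kind": "femoral_component",
        "open_boundary": True,
        "O_distal": o_d, "O_posterior": o_p,
        "spine_radius_distal": rd, "spine_radius_posterior": rp,
        "phi_blend": PHI_BLEND,
        "ffc_medial": ffc_med, "ffc_lateral": ffc_lat,
        "params": params,
    }
    return SurfaceMesh(vertices, faces, articular=np.ones(len(faces), bool),
                       compartment=compartment, distance_field=sdf,
                       metadata=meta)


# ---------------------------------------------------------------------------
# tibial insert: dished, fixed bearing, built-in posterior slope
# ---------------------------------------------------------------------------

def _slope_pose(slope_deg: float) -> Pose:
    """Built-in posterior slope: rotation about the ML axis through the
    dish floor reference point; + lowers the posterior side."""
    return Pose.from_axis_angle([0, 0, 1], slope_deg, point=[DISH_X0, 0.0, 0.0])


def make_tibial_insert(params: ImplantParams | None = None) -> SurfaceMesh:
    """Mesh the fixed-bearing dished insert (two watertight compartments).

    The articular dish of each compartment is the sum-of-sagittae surface of
    the sagittal and coronal dish radii; the whole solid is tilted by the
    built-in posterior slope about the medial-lateral axis.
    """
    params = (params or ImplantParams()).validate()
    r_s, r_c = params.dish_sagittal_radius, params.dish_coronal_radius
    hx = min(25.0, 0.8 * r_s)
    hz = min(14.0, 0.8 * r_c)
    c = params.half_spacing

    nx = max(6, int(np.ceil(2 * hx / params.mesh_edge)))
    nz = max(4, int(np.ceil(2 * hz / params.mesh_edge)))

    verts, faces, art, comp = [], [], [], []
    slope = _slope_pose(params.slope_deg)

    for side in (+1, -1):   # +1 lateral, -1 medial
        x = np.linspace(DISH_X0 - hx, DISH_X0 + hx, nx + 1)
        z = np.linspace(side * c - hz, side * c + hz, nz + 1)
        X, Z = np.meshgrid(x, z, indexing="ij")
        Y = ((r_s - np.sqrt(r_s ** 2 - (X - DISH_X0) ** 2))
             + (r_c - np.sqrt(r_c ** 2 - (Z - side * c) ** 2)))
        top = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
        y_bot = -params.thickness
        bot = top.copy()
        bot[:, 1] = y_bot

        n_grid = len(top)
        offset = sum(len(v) for v in verts)
        idx = np.arange(n_grid).reshape(nx + 1, nz + 1)

        def quads(ii, flip=False):
            a, b = ii[:-1, :-1].ravel(), ii[1:, :-1].ravel()
            cc, d_ = ii[1:, 1:].ravel(), ii[:-1, 1:].ravel()
            f = np.concatenate([np.stack([a, b, cc], axis=1),
                                np.stack([a, cc, d_], axis=1)])
            return f[:, ::-1] if flip else f

        f_top = quads(idx) + offset
        f_bot = quads(idx, flip=True) + offset + n_grid
        # side walls stitching top boundary to bottom boundary
        boundary = np.concatenate([idx[:, 0], idx[-1, 1:], idx[-2::-1, -1],
                                   idx[0, -2::-1]])
        walls = []
        for k in range(len(boundary) - 1):
            i0, i1 = boundary[k], boundary[k + 1]
            walls.append([i0 + offset, i1 + offset, i1 + offset + n_grid])
            walls.append([i0 + offset, i1 + offset + n_grid,
                          i0 + offset + n_grid])
        f_wall = np.asarray(walls, dtype=int)

        verts.extend([top, bot])
        faces.extend([f_top, f_bot, f_wall])
        art.extend([np.ones(len(f_top), bool), np.zeros(len(f_bot), bool),
                    np.zeros(len(f_wall), bool)])
        comp.extend([np.full(len(f_top), side), np.full(len(f_bot), side),
                     np.full(len(f_wall), side)])

    vertices = np.vstack(verts)
    faces_all = np.vstack(faces)
    art = np.concatenate(art)
    comp = np.concatenate(comp)

    # orient the top faces outward (upwards) before tilting
    v = vertices[faces_all]
    n = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    flip = art & (n[:, 1] < 0)
    faces_all[flip] = faces_all[flip][:, ::-1]

    vertices = slope.apply(vertices)

    floor_lat = slope.apply([DISH_X0, 0.0, c])
    floor_med = slope.apply([DISH_X0, 0.0, -c])
    meta = {
        "kind": "tibial_insert",
        "open_boundary": False,
        "dish_floor_normal": slope.apply_vector([0.0, 1.0, 0.0]),
        "dish_floor_medial": floor_med,
        "dish_floor_lateral": floor_lat,
        "built_in_slope_deg": params.slope_deg,
        "params": params,
    }
    return SurfaceMesh(vertices, faces_all, articular=art, compartment=comp,
                       metadata=meta)


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------

def make_reference_placement(femoral_frame: AnatomicalFrame,
                             tibial_frame: AnatomicalFrame) -> tuple[Pose, Pose]:
    """Reference placement: implant frames aligned with the mechanical axes.

    Returns (femoral component pose in the femur bone frame, insert pose in
    the tibia bone frame).  Zero axial rotation offset; slope equals the
    built-in insert slope only.
    """
    return femoral_frame.as_pose(), tibial_frame.as_pose()


def apply_offsets(reference: Pose, offsets: PlacementOffsets,
                  tibial_frame: AnatomicalFrame,
                  about=None) -> Pose:
    """Apply slope and axial-rotation offsets to the insert's reference pose.

    Order of application is fixed: slope (about the tibial medial-lateral
    axis) first, then axial rotation (about the tibial proximal axis); both
    about the insert centroid (default: the reference pose origin).
    Positive slope increases posterior slope; positive rotation is internal.
    """
    offsets.validate()
    pt = np.asarray(about, dtype=float) if about is not None else reference.t
    slope = Pose.from_axis_angle(tibial_frame.lateral, offsets.slope_deg, pt)
    axial = Pose.from_axis_angle(tibial_frame.proximal, offsets.rotation_deg, pt)
    return axial @ slope @ reference


def nominal_tibia_pose(flexion_deg: float,
                       params: ImplantParams | None = None,
                       settle: float = 0.05) -> Pose:
    """Geometric (pre-equilibrium) tibia pose at a given flexion angle.

    Places the insert dish floor on the femoral surface point directly
    "below" (along the tibial proximal axis) the active sagittal arc centre,
    with a small settle penetration.  Used for solver initial guesses and as
    the nominal kinematic sweep for ligament reference-length calibration.
    """
    params = params or ImplantParams()
    o_d, rd, o_p, rp = _spine_arcs(params)
    th = float(flexion_deg)
    if th <= PHI_BLEND:
        centre2 = o_d
        r_act = params.distal_radius
    else:
        centre2 = o_p
        r_act = params.posterior_radius
    thr = np.deg2rad(th)
    rot = Pose.from_axis_angle([0, 0, 1], -th)
    y_t = np.array([np.sin(thr), np.cos(thr), 0.0])      # tibial proximal axis
    f_pt = np.array([centre2[0], centre2[1], 0.0]) - r_act * y_t
    floor_local = np.array([DISH_X0, 0.0, 0.0])
    t = f_pt + settle * y_t - rot.R @ floor_local
    return Pose(rot.R, t)


# ---------------------------------------------------------------------------
# ligament attachment set
# ---------------------------------------------------------------------------

#: structures of the implanted (CR) tibiofemoral set and their bundle counts
TIBIOFEMORAL_STRUCTURES = {
    "PCL": 2, "MCL": 3, "LCL": 3, "opMCL": 1, "dMCL": 2,
    "OPL": 2, "APL": 1, "pCAP": 2,
}
PATELLAR_STRUCTURES = {"LPFL": 3, "MPFL": 3, "PL": 3}
NATIVE_ONLY_STRUCTURES = {"ACL": 2}


def make_ligament_set(tibial_frame: AnatomicalFrame,
                      femoral_frame: AnatomicalFrame,
                      parameter_table: pd.DataFrame | None = None,
                      include_acl: bool = False,
                      params: ImplantParams | None = None,
                      patella_path=None) -> list:
    """Build the ligament bundle set from a parameter table.

    The table may either specify explicit reference lengths, or calibration
    rules: ``prestrain_ref`` (strain at the 10-deg nominal pose) or
    ``engagement_deg`` (flexion angle at which the bundle becomes taut under
    the nominal kinematic sweep).  Attachment coordinates are expressed in
    the femoral / tibial / patellar body frames.
    """
    from .soft_tissue import LigamentBundle, default_patella_path, patella_pose

    if parameter_table is None:
        from .config import default_ligament_rules
        parameter_table = default_ligament_rules()
    params = params or ImplantParams()
    path = patella_path if patella_path is not None else default_patella_path()

    table = parameter_table.copy()
    expected = dict(TIBIOFEMORAL_STRUCTURES)
    expected.update(PATELLAR_STRUCTURES)
    if include_acl:
        expected.update(NATIVE_ONLY_STRUCTURES)
    else:
        table = table[table["structure"] != "ACL"]

    counts = table["structure"].value_counts().to_dict()
    missing = {s: n for s, n in expected.items() if counts.get(s, 0) != n}
    if missing:
        raise ConfigurationError(
            f"bundle inventory mismatch for structures: {sorted(missing)}")

    # nominal kinematic sweep for rule-based reference lengths
    sweep = np.arange(-15.0, 126.0, 2.5)
    tib_poses = [nominal_tibia_pose(a, params) for a in sweep]
    pat_poses = [patella_pose(path, a) for a in sweep]
    fem_pose = femoral_frame.as_pose()
    tib_bone = tibial_frame.as_pose()

    def body_pose(body, i):
        if body == "femur":
            return fem_pose
        if body == "patella":
            return pat_poses[i]
        if body == "tibia":
            return tib_poses[i] @ tib_bone
        raise ConfigurationError(f"unknown body '{body}'")

    bundles = []
    for _, row in table.iterrows():
        name = row["bundle_id"]
        o = np.array([row["origin_x"], row["origin_y"], row["origin_z"]],
                     dtype=float)
        ins = np.array([row["insertion_x"], row["insertion_y"],
                        row["insertion_z"]], dtype=float)
        k = float(row["stiffness"])
        eps_l = row.get("slack_transition_strain", np.nan)
        eps_l = 0.03 if pd.isna(eps_l) else float(eps_l)

        L0 = row.get("reference_length", np.nan)
        if pd.isna(L0):
            lengths = np.array([
                np.linalg.norm(body_pose(row["origin_body"], i).apply(o)
                               - body_pose(row["insertion_body"], i).apply(ins))
                for i in range(len(sweep))])
            if not pd.isna(row.get("engagement_deg", np.nan)):
                L0 = float(np.interp(float(row["engagement_deg"]),
                                     sweep, lengths))
            elif not pd.isna(row.get("prestrain_ref", np.nan)):
                L_ref = float(np.interp(10.0, sweep, lengths))
                L0 = L_ref / (1.0 + float(row["prestrain_ref"]))
            else:
                raise ConfigurationError(
                    f"bundle '{name}': no reference_length, engagement_deg "
                    "or prestrain_ref given")
        bundles.append(LigamentBundle(
            name=name, structure=row["structure"],
            origin_body=row["origin_body"], origin=o,
            insertion_body=row["insertion_body"], insertion=ins,
            stiffness=k, reference_length=float(L0), eps_l=eps_l))
    return bundles


def load_surface_mesh(path, articular=None, compartment=None) -> SurfaceMesh:
    """Load a user-supplied implant surface (STL/OBJ) as a SurfaceMesh.

    Loaded meshes carry no analytic distance field; the contact module
    falls back to nearest-point queries for them.  ``articular`` and
    ``compartment`` default to all-faces / lateral-medial split by the
    sign of the face-centroid z coordinate.
    """
    import trimesh
    tm = trimesh.load_mesh(path)
    faces = np.asarray(tm.faces)
    if articular is None:
        articular = np.ones(len(faces), dtype=bool)
    if compartment is None:
        cz = np.asarray(tm.triangles_center)[:, 2]
        compartment = np.where(cz >= 0, 1, -1)
    return SurfaceMesh(np.asarray(tm.vertices), faces,
                       articular=np.asarray(articular, dtype=bool),
                       compartment=np.asarray(compartment, dtype=int),
                       metadata={"kind": "user_mesh", "source": str(path)})


# ---------------------------------------------------------------------------
# ligament CSV interchange (explicit reference lengths)
# ---------------------------------------------------------------------------

_CSV_COLS = ["bundle_id", "structure", "origin_body", "origin_xyz",
             "insertion_body", "insertion_xyz", "stiffness",
             "reference_length", "slack_transition_strain"]


def export_ligament_csv(bundles, path_or_buf):
    rows = []
    for b in bundles:
        rows.append({
            "bundle_id": b.name, "structure": b.structure,
            "origin_body": b.origin_body,
            "origin_xyz": " ".join(f"{v:.6g}" for v in b.origin),
            "insertion_body": b.insertion_body,
            "insertion_xyz": " ".join(f"{v:.6g}" for v in b.insertion),
            "stiffness": b.stiffness,
            "reference_length": b.reference_length,
            "slack_transition_strain": b.eps_l,
        })
    pd.DataFrame(rows, columns=_CSV_COLS).to_csv(path_or_buf, index=False)


def load_ligament_csv(path_or_buf):
    from .soft_tissue import LigamentBundle
    df = pd.read_csv(path_or_buf)
    missing = set(_CSV_COLS) - set(df.columns)
    if missing:
        raise ConfigurationError(f"ligament CSV missing columns: {sorted(missing)}")
    bundles = []
    for _, r in df.iterrows():
        bundles.append(LigamentBundle(
            name=r["bundle_id"], structure=r["structure"],
            origin_body=r["origin_body"],
            origin=np.fromstring(r["origin_xyz"], sep=" "),
            insertion_body=r["insertion_body"],
            insertion=np.fromstring(r["insertion_xyz"], sep=" "),
            stiffness=float(r["stiffness"]),
            reference_length=float(r["reference_length"]),
            eps_l=float(r["slack_transition_strain"])))
    return bundles
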