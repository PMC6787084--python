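"""Joint coordinate system kinematics and all reported outcome metrics.

The tibiofemoral motion is decomposed in the Grood-Suntay floating-axis
convention: flexion about the femoral medial-lateral axis, axial rotation
about the tibial long axis, adduction about the mutual perpendicular, with
clinical translations along the same three axes.  Right-knee signs: flexion
positive, internal tibial rotation positive, adduction (varus) positive.

Reported outcomes: femoral rollback (posterior negative, relative to the
first step of a movement), medial/lateral flexion-facet-centre (FFC)
translation in the insert frame, screw-home detection on extension traces,
paradoxical anterior translation on flexion traces, and RMSE comparisons
between a reference and a variant trace.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import ComparisonError, ConfigurationError, DegenerateRotationError
from .pose import Pose


@dataclass(frozen=True)
class JointState:
    """Grood-Suntay angles (deg) and translations (mm) of tibia vs femur."""

    flexion: float
    adduction: float
    rotation: float     # internal (+) / external (-)
    ap: float           # anterior (+)
    si: float           # along the tibial long axis, proximal (+)
    ml: float           # lateral (+)

    def as_array(self):
        return np.array([self.flexion, self.adduction, self.rotation,
                         self.ap, self.si, self.ml])


def _gs_axes(R_rel: np.ndarray):
    """(e1, e2, e3): femoral ML axis, floating axis, tibial long axis."""
    e1 = np.array([0.0, 0.0, 1.0])
    e3 = R_rel[:, 1]
    e2 = np.cross(e3, e1)
    n = np.linalg.norm(e2)
    if n < 1e-9:
        raise DegenerateRotationError("floating axis undefined (gimbal lock)")
    return e1, e2 / n, e3


def compose_pose(state: JointState) -> Pose:
    """Tibia pose in the femur frame from a joint state (inverse of
    :func:`grood_suntay`)."""
    R = Rotation.from_euler(
        "ZXY", [-state.flexion, state.adduction, state.rotation],
        degrees=True).as_matrix()
    e1, e2, e3 = _gs_axes(R)
    t = state.ap * e2 + state.si * e3 + state.ml * e1
    return Pose(R, t)


def grood_suntay(pose_femur: Pose, pose_tibia: Pose) -> JointState:
    """Decompose the relative pose into the clinical joint state.

    Raises :class:`DegenerateRotationError` near |adduction| = 90 deg.
    """
    rel = pose_femur.inverse() @ pose_tibia
    ang = Rotation.from_matrix(rel.R).as_euler("ZXY", degrees=True)
    flexion, adduction, rotation = -ang[0], ang[1], ang[2]
    if abs(abs(adduction) - 90.0) < 1e-6:
        raise DegenerateRotationError("adduction at gimbal lock")
    e1, e2, e3 = _gs_axes(rel.R)
    M = np.column_stack([e2, e3, e1])
    ap, si, ml = np.linalg.solve(M, rel.t)
    return JointState(flexion=flexion, adduction=adduction, rotation=rotation,
                      ap=float(ap), si=float(si), ml=float(ml))


def tibia_pose_from_q(flexion: float, q) -> Pose:
    """Pose from prescribed flexion and the five constrained dofs
    (ap, si, ml, adduction, rotation)."""
    ap, si, ml, add, rot = [float(v) for v in q]
    return compose_pose(JointState(flexion=flexion, adduction=add,
                                   rotation=rot, ap=ap, si=si, ml=ml))


# ---------------------------------------------------------------------------
# outcome metrics on traces
# ---------------------------------------------------------------------------

@dataclass
class FfcPair:
    """Medial/lateral flexion facet centre positions in the insert frame."""

    flexion: np.ndarray
    medial: np.ndarray    # (n, 3)
    lateral: np.ndarray   # (n, 3)

    @property
    def medial_ap(self):
        return self.medial[:, 0]

    @property
    def lateral_ap(self):
        return self.lateral[:, 0]


@dataclass
class ComparisonResult:
    metric: str
    rmse: float
    flexion: np.ndarray
    difference: np.ndarray


def _trace_df(trace) -> pd.DataFrame:
    df = trace.df if hasattr(trace, "df") else trace
    if "repetition" in df.columns:
        df = df.groupby("flexion_deg", as_index=False, sort=False).mean(
            numeric_only=True)
    return df


def femoral_rollback(trace) -> pd.Series:
    """AP translation of the femur relative to the tibia, posterior negative,
    reported relative to the value at the first step of the movement."""
    df = _trace_df(trace)
    if len(df) == 0:
        raise ComparisonError("empty trace")
    ap = df["fem_ap_in_tibia_mm"].to_numpy(dtype=float)
    return pd.Series(ap - ap[0], index=df["flexion_deg"].to_numpy(),
                     name="rollback_mm")


def ffc_positions(trace, femoral_metadata: dict,
                  pose_implant_f: Pose | None = None,
                  pose_insert_t: Pose | None = None) -> FfcPair:
    """Condylar posterior-arc centres transformed into the insert frame.

    ``femoral_metadata`` must carry the analytic posterior-arc centres
    ('ffc_medial'/'ffc_lateral') recorded by the femoral component generator.
    """
    if ("ffc_medial" not in femoral_metadata
            or "ffc_lateral" not in femoral_metadata):
        raise ConfigurationError(
            "femoral metadata lacks posterior-arc centres (ffc_medial/"
            "ffc_lateral)")
    df = _trace_df(trace)
    pf = pose_implant_f if pose_implant_f is not None else Pose.identity()
    pt = pose_insert_t if pose_insert_t is not None else Pose.identity()
    med_w = pf.apply(femoral_metadata["ffc_medial"])
    lat_w = pf.apply(femoral_metadata["ffc_lateral"])
    med, lat = [], []
    for _, row in df.iterrows():
        pose_tibia = tibia_pose_from_q(
            row["flexion_deg"],
            [row["ap_mm"], row["si_mm"], row["ml_mm"],
             row["adduction_deg"], row["rotation_deg"]])
        inv = (pose_tibia @ pt).inverse()
        med.append(inv.apply(med_w))
        lat.append(inv.apply(lat_w))
    return FfcPair(flexion=df["flexion_deg"].to_numpy(dtype=float),
                   medial=np.asarray(med), lateral=np.asarray(lat))


def detect_screw_home(trace, window_deg: float = 20.0,
                      threshold_deg: float = 0.5):
    """Detect terminal-extension external rotation on an extension trace.

    Present iff the net external rotation over the terminal ``window_deg``
    of extension exceeds ``threshold_deg``; magnitude is that net rotation.
    Returns (present, magnitude) or (None, nan) if the trace does not reach
    below 20 deg flexion.
    """
    df = _trace_df(trace)
    flex = df["flexion_deg"].to_numpy(dtype=float)
    rot = df["rotation_deg"].to_numpy(dtype=float)
    if flex.min() > 20.0 or len(flex) < 2:
        return None, float("nan")
    end = flex.min()
    start = end + window_deg
    m = flex <= start
    if m.sum() < 2:
        return None, float("nan")
    rot_w = rot[m]
    flex_w = flex[m]
    # net external (negative) rotation from window start to end of extension
    i0 = int(np.argmax(flex_w))
    i1 = int(np.argmin(flex_w))
    net_external = rot_w[i0] - rot_w[i1]
    present = bool(net_external > threshold_deg)
    return present, float(net_external if present else 0.0)


def detect_paradoxical_anterior(ffc: FfcPair, guard: float = 1e-6):
    """Flag flexion ranges where the medial FFC moves anteriorly with
    increasing flexion; returns (present, upper flexion bound in deg)."""
    flex = np.asarray(ffc.flexion, dtype=float)
    ap = np.asarray(ffc.medial_ap, dtype=float)
    order = np.argsort(flex)
    flex, ap = flex[order], ap[order]
    rising = np.diff(ap) > guard
    if not np.any(rising):
        return False, float("nan")
    last = np.max(np.nonzero(rising)[0])
    return True, float(flex[last + 1])


_METRIC_COLUMNS = {
    "contact_force": "contact_force_n",
    "rotation": "rotation_deg",
    "rollback": None,      # derived via femoral_rollback
    "ffc_medial": "ffc_med_ap_mm",
    "ffc_lateral": "ffc_lat_ap_mm",
}


def _metric_series(trace, metric: str) -> pd.Series:
    if metric == "rollback":
        return femoral_rollback(trace)
    col = _METRIC_COLUMNS.get(metric, metric)
    df = _trace_df(trace)
    if col not in df.columns:
        raise ComparisonError(f"trace lacks metric column '{col}'")
    return pd.Series(df[col].to_numpy(dtype=float),
                     index=df["flexion_deg"].to_numpy(), name=metric)


def rmse(reference_trace, variant_trace, metric: str) -> ComparisonResult:
    """Root mean square difference of a metric over the common flexion grid.

    Traces on different grids are linearly resampled onto the overlap of
    their flexion ranges; disjoint ranges raise :class:`ComparisonError`.
    """
    a = _metric_series(reference_trace, metric)
    b = _metric_series(variant_trace, metric)
    fa, fb = a.index.to_numpy(float), b.index.to_numpy(float)
    lo = max(fa.min(), fb.min())
    hi = min(fa.max(), fb.max())
    if hi < lo:
        raise ComparisonError("traces cover disjoint flexion ranges")
    if np.array_equal(fa, fb):
        grid = fa
        da, db = a.to_numpy(), b.to_numpy()
    else:
        grid = np.union1d(fa[(fa >= lo) & (fa <= hi)],
                          fb[(fb >= lo) & (fb <= hi)])
        oa, ob = np.argsort(fa), np.argsort(fb)
        da = np.interp(grid, fa[oa], a.to_numpy()[oa])
        db = np.interp(grid, fb[ob], b.to_numpy()[ob])
    diff = db - da
    return ComparisonResult(metric=metric,
                            rmse=float(np.sqrt(np.mean(diff ** 2))),
                            flexion=np.asarray(grid), difference=diff)
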