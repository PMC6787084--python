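"""Configuration loading and default model construction.

The packaged ``data/defaults.yaml`` is the single source of every surrogate
default (implant geometry, contact and solver settings, segment masses,
extensor mechanism, ligament attachment rules, study matrix).  Users may
load an edited copy via :func:`load_config` and pass it anywhere a config
dict is accepted.
"""
from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .contact import ContactParams
from .errors import ConfigurationError
from .geometry import (AnatomicalFrame, ImplantParams, PlacementOffsets,
                       apply_offsets, make_femoral_component,
                       make_ligament_set, make_reference_placement,
                       make_tibial_insert)
from .soft_tissue import CircularArcPath, MuscleElement, WrapEllipsoid
from .solver import KneeModel, MovementSchedule, NoiseSettings, SolverSettings


def default_config() -> dict:
    with resources.files("tkrsim.data").joinpath("defaults.yaml").open() as fh:
        return yaml.safe_load(fh)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    base = default_config()
    base.update(cfg or {})
    return base


def save_config(cfg: dict, path):
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def default_ligament_rules(cfg: dict | None = None) -> pd.DataFrame:
    """Ligament rule table as a flat DataFrame (coordinates exploded)."""
    cfg = cfg or default_config()
    rows = []
    for entry in cfg["ligaments"]:
        row = dict(entry)
        for key, prefix in (("origin", "origin"), ("insertion", "insertion")):
            x, y, z = row.pop(key)
            row[f"{prefix}_x"], row[f"{prefix}_y"], row[f"{prefix}_z"] = x, y, z
        rows.append(row)
    df = pd.DataFrame(rows)
    for opt in ("prestrain_ref", "engagement_deg", "reference_length",
                "slack_transition_strain"):
        if opt not in df.columns:
            df[opt] = np.nan
    return df


def implant_params(cfg: dict | None = None) -> ImplantParams:
    cfg = cfg or default_config()
    return ImplantParams(**cfg["implant"]).validate()


def patella_path_from_config(cfg: dict | None = None) -> CircularArcPath:
    cfg = cfg or default_config()
    p = cfg["patella_path"]
    return CircularArcPath(centre=p["centre"], radius=p["radius"],
                           beta0_deg=p["beta0_deg"], gain=p["gain"],
                           flexion_range=tuple(p["flexion_range"]))


def quadriceps_from_config(cfg: dict | None = None) -> list:
    cfg = cfg or default_config()
    q = cfg["quadriceps"]
    split = np.asarray(q["split"], dtype=float)
    total = float(q["total_force_n"])
    if abs(split.sum() - 1.0) > 1e-9:
        raise ConfigurationError("quadriceps split fractions must sum to 1")
    ell = WrapEllipsoid(body="femur", centre=q["wrap_ellipsoid"]["centre"],
                        semi_axes=q["wrap_ellipsoid"]["semi_axes"])
    elements = []
    for frac, (name, origin) in zip(split, q["origins"].items()):
        elements.append(MuscleElement(
            name=name, origin_body="femur", origin=origin,
            insertion_body="patella", insertion=q["patella_insertion"],
            tension=total * frac, obstacle=ell))
    return elements


def build_model(cfg: dict | None = None,
                offsets: PlacementOffsets | None = None,
                pcl_resected: bool = False,
                ligament_table: pd.DataFrame | None = None) -> KneeModel:
    """Assemble a ready-to-run knee model from a config dict.

    ``offsets`` applies a surgical placement variation of the tibial
    component relative to the reference placement.
    """
    cfg = cfg or default_config()
    params = implant_params(cfg)
    femoral = make_femoral_component(params)
    insert = make_tibial_insert(params)

    fem_frame = AnatomicalFrame.identity()
    tib_frame = AnatomicalFrame.identity()
    pose_f, pose_t = make_reference_placement(fem_frame, tib_frame)
    if offsets is not None:
        pose_t = apply_offsets(pose_t, offsets, tib_frame)

    path = patella_path_from_config(cfg)
    table = (ligament_table if ligament_table is not None
             else default_ligament_rules(cfg))
    bundles = make_ligament_set(tib_frame, fem_frame, table,
                                params=params, patella_path=path)
    if pcl_resected:
        from .soft_tissue import resect
        bundles = resect(bundles, "PCL")

    seg = cfg["segment"]
    sol = cfg["solver"]
    model = KneeModel(
        femoral_mesh=femoral, insert_mesh=insert,
        pose_implant_femur=pose_f, pose_insert_tibia=pose_t,
        bundles=bundles, muscles=quadriceps_from_config(cfg),
        patella_path=path,
        contact=ContactParams(**cfg["contact"]).validate(),
        shank_mass_kg=float(seg["shank_mass_kg"]),
        shank_com=np.asarray(seg["shank_com"], dtype=float),
        gravity_dir=np.asarray(seg["gravity_dir"], dtype=float),
        solver=SolverSettings(
            tolerance=float(sol["tolerance"]),
            max_iterations=int(sol["max_iterations"]),
            fd_step=float(sol["fd_step"]),
            max_step=float(sol["max_step"])),
    )
    return model


def movement_schedule(kind: str, cfg: dict | None = None,
                      repetitions: int | None = None,
                      noise: NoiseSettings | None = None,
                      seed: int = 0, step: float | None = None
                      ) -> MovementSchedule:
    cfg = cfg or default_config()
    mv = cfg["movements"][kind]
    reps = repetitions if repetitions is not None else cfg["movements"]["repetitions"]
    n = noise
    if n is None and cfg["movements"].get("noise"):
        n = NoiseSettings(**cfg["movements"]["noise"])
    return MovementSchedule(kind=kind, start=float(mv["start"]),
                            end=float(mv["end"]),
                            step=float(step if step is not None else mv["step"]),
                            repetitions=reps, noise=n, seed=seed)
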