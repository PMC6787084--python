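"""Surgical-parameter study driver.

Reproduces the single-factor test matrix (reference, tibial component
rotation ±3/±6 deg, tibial slope -3/+3/+6 deg, PCL resection) end to end:
builds each model variant, runs the scheduled flexion/extension movements
with repetitions, computes the outcome metrics and RMSE comparisons against
the reference configuration, and writes the result tables.
"""
from __future__ import annotations

import json
import os
from dataclasses import dataclass

import pandas as pd

from . import __version__
from .config import default_config, movement_schedule
from .errors import ConfigurationError
from .geometry import PlacementOffsets, apply_offsets, AnatomicalFrame
from .metrics import rmse
from .soft_tissue import resect
from .solver import FlexionTrace, KneeModel, NoiseSettings, run_movement

RMSE_METRICS = ("contact_force", "rollback", "rotation",
                "ffc_medial", "ffc_lateral")

VARIANT_KINDS = ("reference", "tibial_rotation", "tibial_slope",
                 "pcl_resection")


@dataclass
class VariantSpec:
    id: str
    kind: str
    value: float = 0.0
    movements: tuple = ("flexion",)

    def __post_init__(self):
        if self.kind not in VARIANT_KINDS:
            raise ConfigurationError(f"unknown variant kind '{self.kind}'")


@dataclass
class StudyConfig:
    """Study setup: variant list, repetitions, noise, flexion step, seed."""

    variants: list
    repetitions: int = 3
    noise: NoiseSettings | None = None
    flexion_step: float = 1.0
    seed: int = 0
    output_dir: str | None = None

    @staticmethod
    def from_config(cfg: dict | None = None, **overrides) -> "StudyConfig":
        cfg = cfg or default_config()
        variants = [VariantSpec(id=v["id"], kind=v["kind"],
                                value=float(v.get("value", 0.0)),
                                movements=tuple(v["movements"]))
                    for v in cfg["study"]]
        noise = (NoiseSettings(**cfg["movements"]["noise"])
                 if cfg["movements"].get("noise") else None)
        sc = StudyConfig(variants=variants,
                         repetitions=int(cfg["movements"]["repetitions"]),
                         noise=noise,
                         flexion_step=float(cfg["movements"]["flexion"]["step"]))
        for k, v in overrides.items():
            setattr(sc, k, v)
        return sc


@dataclass
class StudyResult:
    traces: dict                 # variant id -> {movement kind -> FlexionTrace}
    rmse_table: pd.DataFrame     # variant x metric
    summary: pd.DataFrame        # per-variant repetition spread statistics
    config: StudyConfig = None


def build_variant(base: KneeModel, entry: VariantSpec) -> KneeModel:
    """Deep-copy the reference model and change exactly one parameter."""
    model = base.copy()
    if entry.kind == "reference":
        return model
    if entry.kind == "tibial_rotation":
        off = PlacementOffsets(rotation_deg=entry.value)
    elif entry.kind == "tibial_slope":
        off = PlacementOffsets(slope_deg=entry.value)
    elif entry.kind == "pcl_resection":
        model.bundles = resect(model.bundles, "PCL")
        return model
    model.pose_insert_tibia = apply_offsets(
        model.pose_insert_tibia, off, AnatomicalFrame.identity())
    return model


def run_study(base: KneeModel, study: StudyConfig) -> StudyResult:
    """Run the full matrix; the reference runs first and is reused for all
    comparisons.  Deterministic given the study seed."""
    ids = [v.id for v in study.variants]
    ref_entries = [v for v in study.variants if v.kind == "reference"]
    if not ref_entries:
        raise ConfigurationError("study matrix must contain the reference")
    ordered = ref_entries + [v for v in study.variants
                             if v.kind != "reference"]

    traces: dict = {}
    for vi, entry in enumerate(ordered):
        model = build_variant(base, entry)
        traces[entry.id] = {}
        for mi, movement in enumerate(entry.movements):
            sched = movement_schedule(
                movement, repetitions=study.repetitions, noise=study.noise,
                seed=study.seed + 1000 * vi + 100 * mi,
                step=study.flexion_step)
            traces[entry.id][movement] = run_movement(model, sched)

    ref = traces[ref_entries[0].id]
    rows = []
    for entry in ordered:
        if entry.kind == "reference":
            continue
        for movement in entry.movements:
            if movement not in ref:
                continue
            for metric in RMSE_METRICS:
                cmp_ = rmse(ref[movement], traces[entry.id][movement], metric)
                rows.append({"variant": entry.id, "movement": movement,
                             "metric": metric, "rmse": cmp_.rmse})
    rmse_table = pd.DataFrame(rows,
                              columns=["variant", "movement", "metric", "rmse"])
    return StudyResult(traces=traces, rmse_table=rmse_table,
                       summary=summarize_traces(traces), config=study)


def summarize_traces(traces: dict) -> pd.DataFrame:
    """Per-variant repetition spread: maximum over flexion steps of the
    between-repetition standard deviation of internal/external rotation,
    femoral rollback (AP position) and tibiofemoral contact force."""
    rows = []
    for vid, movements in traces.items():
        for movement, trace in movements.items():
            df = trace.df
            if len(df) == 0:
                continue
            sd = df.groupby("flexion_deg")[
                ["rotation_deg", "fem_ap_in_tibia_mm", "contact_force_n"]
            ].std(ddof=0).fillna(0.0)
            rows.append({
                "variant": vid, "movement": movement,
                "stable": trace.stable,
                "max_sd_rotation_deg": float(sd["rotation_deg"].max()),
                "max_sd_rollback_mm": float(sd["fem_ap_in_tibia_mm"].max()),
                "max_sd_contact_force_n": float(sd["contact_force_n"].max()),
            })
    return pd.DataFrame(rows)


def summarize(result: StudyResult) -> dict:
    """Mean/SD traces per variant plus the scalar spread and RMSE tables."""
    mean_traces = {}
    for vid, movements in result.traces.items():
        for movement, trace in movements.items():
            if len(trace.df) == 0:
                continue
            df = trace.df.drop(columns=["repetition"])
            g = df.groupby("flexion_deg", sort=False)
            mean_traces[(vid, movement)] = {
                "mean": g.mean(numeric_only=True).reset_index(),
                "sd": g.std(ddof=0, numeric_only=True).fillna(0.0).reset_index(),
            }
    return {"mean_traces": mean_traces,
            "spread": result.summary,
            "rmse": result.rmse_table}


def save_study(result: StudyResult, out_dir: str, manifest_extra=None):
    """One directory per variant with trace CSVs; RMSE/summary tables and a
    reproducibility manifest at the top level."""
    os.makedirs(out_dir, exist_ok=True)
    for vid, movements in result.traces.items():
        vdir = os.path.join(out_dir, vid)
        os.makedirs(vdir, exist_ok=True)
        for movement, trace in movements.items():
            trace.to_csv(os.path.join(vdir, f"trace_{movement}.csv"))
    result.rmse_table.to_csv(os.path.join(out_dir, "rmse.csv"), index=False)
    result.summary.to_csv(os.path.join(out_dir, "summary.csv"), index=False)
    manifest = {
        "package": "tkrsim", "version": __version__,
        "seed": result.config.seed if result.config else None,
        "repetitions": result.config.repetitions if result.config else None,
        "flexion_step": result.config.flexion_step if result.config else None,
        "variants": [v.id for v in (result.config.variants
                                    if result.config else [])],
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
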