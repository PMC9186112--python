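"""End-to-end orchestration: load -> classify -> repair -> segment ->
measure -> statistics -> resistance, with provenance and determinism.

Every spine from the manifest ends up exactly once in either the
morphometry table or the exclusion log; the completeness census (A-E
counts and fractions) is always reported.  One master seed is stretched
to a per-spine seed by stable hashing of the spine id, so results do not
depend on processing order.
"""
from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import biophysics, mesh_io, morphometry, population_stats
from .head_neck_segmentation import SegmentationParams, oriented, separate, skeletonize
from .mesh_io import load_entry, load_manifest, write_records
from .spine_repair import (DiscardSpine, RepairParams, classify_pre_segmentation,
                           repair)

log = logging.getLogger(__name__)

GROUPS = ("A", "B", "C", "D", "E")
SCOPES = ("A", "ACD")


@dataclass
class PipelineConfig:
    manifest_path: str = ""
    output_dir: str = "out"
    repair_params: RepairParams | None = None        # None -> per-species default
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    histogram: population_stats.HistogramSpec = field(
        default_factory=population_stats.HistogramSpec)
    n_boot: int = 2000
    master_seed: int = 0
    scopes: tuple = ("A", "ACD")


def validate_config(config: PipelineConfig) -> list[str]:
    """All violations, not just the first; empty list means runnable."""
    issues = []
    if not config.manifest_path:
        issues.append("manifest_path is empty")
    elif not Path(config.manifest_path).exists():
        issues.append(f"manifest not found: {config.manifest_path}")
    lam = config.segmentation.smoothing_lambda
    if not 0.0 <= lam <= 1.0:
        issues.append(f"smoothing_lambda out of [0,1]: {lam}")
    if config.n_boot < 1:
        issues.append("n_boot must be >= 1")
    for s in config.scopes:
        if s not in SCOPES:
            issues.append(f"unknown scope {s!r}")
    return issues


def spine_seed(master_seed: int, spine_id: str) -> int:
    """Stable per-spine seed independent of processing order."""
    return (master_seed * 1_000_003 + zlib.crc32(spine_id.encode())) % (2**31)


def process_spine(spine: mesh_io.SpineMesh, repair_params: RepairParams,
                  seg_params: SegmentationParams):
    """Classify, repair if needed, segment, and measure one spine.

    Returns (record, provenance) or raises DiscardSpine for group E.
    """
    prov = {"spine_id": spine.spine_id}
    group = classify_pre_segmentation(spine, repair_params)
    repaired = False
    operations = ""
    if group == "E":
        raise DiscardSpine("three or more components")
    if group in ("C", "D"):
        res = repair(spine, repair_params)
        spine = spine.with_mesh(res.mesh)
        repaired = True
        operations = "+".join(sorted(res.operations_applied))
        prov["repair_operations"] = sorted(res.operations_applied)
        prov["added_faces"] = len(res.added_face_ids)
    mesh = oriented(spine.mesh)
    spine = spine.with_mesh(mesh)
    skeleton = skeletonize(mesh, source_point=spine.insertion_point)
    labels = separate(spine, seg_params, skeleton=skeleton)
    if group == "pending":
        group = "A" if labels.separable else "B"
    elif not labels.separable:
        # a repaired spine that still cannot be separated keeps its group
        prov["post_repair_separable"] = False
    prov["group"] = group
    prov["separable"] = bool(labels.separable)
    rec = morphometry.measure(spine, labels, skeleton, group,
                              repaired=repaired, operations=operations,
                              params=seg_params)
    return rec, prov


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline; returns the run summary (also written as JSON)."""
    issues = validate_config(config)
    if issues:
        raise ValueError("invalid config: " + "; ".join(issues))
    manifest = load_manifest(config.manifest_path)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    records, provenance, exclusions = [], [], []
    census = {g: 0 for g in GROUPS}
    for entry in sorted(manifest.spines, key=lambda e: str(e["id"])):
        sid = str(entry["id"])
        try:
            spine = load_entry(manifest, entry)
            params = config.repair_params or RepairParams.for_species(spine.species)
            seg = SegmentationParams(**{
                **asdict(config.segmentation),
                "seed": spine_seed(config.master_seed, sid)})
            rec, prov = process_spine(spine, params, seg)
            census[rec.group] += 1
            records.append(rec)
            provenance.append(prov)
        except DiscardSpine as e:
            census["E"] += 1
            exclusions.append({"spine_id": sid, "reason": str(e)})
        except Exception as e:   # stage failure: flag and continue
            log.warning("spine %s failed: %s", sid, e)
            exclusions.append({"spine_id": sid, "reason": f"error: {e}"})

    n_total = len(manifest.spines)
    summary = {
        "n_spines": n_total,
        "census": census,
        "census_fractions": {g: census[g] / n_total for g in GROUPS} if n_total else {},
        "n_measured": len(records),
        "n_excluded": len(exclusions),
        "exclusions": exclusions,
        "master_seed": config.master_seed,
    }

    if records:
        write_records([r.as_dict() for r in records], out / "morphometry.csv")
        table = mesh_io.records_to_frame([r.as_dict() for r in records])
        summary["stats"] = {}
        for scope in config.scopes:
            mask = (table["group"] == "A") if scope == "A" \
                else table["group"].isin(["A", "C", "D"])
            sub = table[mask]
            summary["stats"][scope] = _scope_stats(sub, config)
    (out / "census.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1,
                                                    sort_keys=True))
    return summary


def _scope_stats(table, config: PipelineConfig) -> dict:
    import pandas as pd

    feats = ["head_volume_um3", "neck_length_um", "neck_diameter_nm"]
    stats: dict = {"n": int(len(table))}
    for feat in feats:
        vals = pd.to_numeric(table[feat], errors="coerce").dropna().values
        if len(vals) >= 4:
            dr = population_stats.dip_test(vals, n_boot=config.n_boot,
                                           seed=config.master_seed)
            stats[feat] = {"n": int(len(vals)), "median": float(np.median(vals)),
                           "mean": float(np.mean(vals)),
                           "dip": dr.statistic, "dip_p": dr.p_value}
    # resistance summary per species where neck diameter is available
    res = {}
    for species in table["species"].dropna().unique():
        mask = (table["species"] == species) & table["neck_diameter_nm"].notna() \
            & table["neck_length_um"].notna()
        if mask.sum() >= 2:
            g = biophysics.group_median_geometry(table, mask)
            res[str(species)] = {"median_length_um": g.length_um,
                                 "median_radius_um": g.radius_um,
                                 "resistance_index_per_um": biophysics.resistance_index(g)}
    if res:
        stats["resistance"] = res
        if {"human", "mouse"} <= set(res):
            gh = biophysics.NeckGeometry(res["human"]["median_length_um"],
                                         res["human"]["median_radius_um"])
            gm = biophysics.NeckGeometry(res["mouse"]["median_length_um"],
                                         res["mouse"]["median_radius_um"])
            stats["resistance"]["mouse_over_human_ratio"] = \
                biophysics.resistance_ratio(gm, gh)
    return stats
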