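"""Stage orchestration: YAML config → seeded stages → TSV outputs + JSON
manifest.

A pipeline reproduces the three-stage analysis layout at desk scale:
generate a synthetic system, census its aggregates, measure water
structure/order, solvate with region density targets, verify densities and
summarize.  Every stage logs its parameters, inputs, outputs and seed to the
manifest, and a rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Optional

import numpy as np
import yaml

from . import __version__
from .assembly import (classify_aggregate, cluster_molecules, fibre_metrics,
                       lattice_spacing)
from .core import Topology, Frame, Trajectory
from .io import write_structure, write_trajectory
from .mapping import RegionSpec, measure_region_density, reinsert_water
from .synth import SyntheticSpec, generate
from .water import (compute_density_profile, compute_q6, compute_rdf,
                    compute_translational_order)

logger = logging.getLogger(__name__)


class PipelineConfigError(ValueError):
    """Config fails schema validation; message lists the offending keys."""


@dataclass
class PipelineConfig:
    stages: List[dict]
    seed: int = 0
    outdir: str = "pipeline_out"
    extras: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        if not isinstance(raw, dict):
            raise PipelineConfigError("config must be a mapping")
        problems = []
        if "stages" not in raw or not isinstance(raw["stages"], list) \
                or not raw["stages"]:
            problems.append("stages: required non-empty list")
            stages = []
        else:
            stages = raw["stages"]
        seed = raw.get("seed", 0)
        if not isinstance(seed, int):
            problems.append("seed: must be an integer")
        for k, st in enumerate(stages):
            if not isinstance(st, dict) or "name" not in st:
                problems.append(f"stages[{k}]: needs a 'name'")
                continue
            name = st["name"]
            if name not in STAGES:
                problems.append(
                    f"stages[{k}].name: unknown stage {name!r} "
                    f"(available: {sorted(STAGES)})")
                continue
            missing = [p for p in STAGES[name].required
                       if p not in st.get("params", {})]
            if missing:
                problems.append(
                    f"stages[{k}] ({name}): missing params {missing}")
        if problems:
            raise PipelineConfigError(
                "invalid pipeline config:\n  " + "\n  ".join(problems))
        return cls(stages=stages, seed=seed,
                   outdir=raw.get("outdir", "pipeline_out"),
                   extras={k: v for k, v in raw.items()
                           if k not in ("stages", "seed", "outdir")})


@dataclass
class _Stage:
    fn: Callable
    required: tuple = ()


STAGES: Dict[str, _Stage] = {}


def _stage(name, required=()):
    def deco(fn):
        STAGES[name] = _Stage(fn, tuple(required))
        return fn
    return deco


class _Context:
    """Carries in-memory objects between stages."""

    def __init__(self, config: PipelineConfig, outdir: Path):
        self.config = config
        self.outdir = outdir
        self.topology: Optional[Topology] = None
        self.frame: Optional[Frame] = None
        self.assignment = None
        self.fibre_centroids = None
        self.fibre_axis = None


def _tsv_header(stage: str, seed: int, params: dict) -> str:
    items = " ".join(f"{k}={v}" for k, v in sorted(params.items()))
    return f"# stage={stage} seed={seed} {items}\n"


@_stage("synth")
def _run_synth(ctx: _Context, params: dict, seed: int) -> dict:
    kind = params.get("kind", "pa_bundle")
    gen_params = {k: v for k, v in params.items() if k != "kind"}
    out = generate(SyntheticSpec(seed=seed, kind=kind, parameters=gen_params))
    if isinstance(out, Trajectory):
        ctx.topology, ctx.frame = out.topology, out.frames[0]
        traj_path = ctx.outdir / "synth.xyz"
        write_trajectory(traj_path, out, format="xyz-multi")
        files = [str(traj_path)]
    else:
        ctx.topology, ctx.frame = out
        path = ctx.outdir / "synth.xyz"
        write_structure(path, ctx.topology, ctx.frame, format="xyz")
        files = [str(path)]
    sidecar = ctx.outdir / "synth.json"
    sidecar.write_text(json.dumps(
        {"seed": seed, "kind": kind, "parameters": gen_params}, indent=1))
    return {"outputs": files + [str(sidecar)],
            "n_atoms": int(ctx.topology.n_atoms)}


@_stage("census")
def _run_census(ctx: _Context, params: dict, seed: int) -> dict:
    if ctx.topology is None:
        raise RuntimeError("census: no structure in context (run synth "
                           "first)")
    sel = params.get("selection", "group hydrophobic_tail")
    cutoff = params.get("cutoff", 6.0)
    asn = cluster_molecules(ctx.topology, ctx.frame, sel, cutoff=cutoff)
    rows = []
    centroids = []
    axes = []
    for lab in range(asn.n_clusters):
        info = classify_aggregate(asn, ctx.topology, ctx.frame, lab)
        row = {"cluster": lab, "n_agg": info.size, "class": info.kind,
               "radius_A": round(info.radius, 3),
               "axial_extent_A": round(info.axial_extent, 3)}
        if info.kind == "fibre":
            ld, diam = fibre_metrics(asn, ctx.topology, ctx.frame, lab)
            row["linear_density_per_nm"] = round(ld, 3)
            row["diameter_A"] = round(diam, 3)
            centroids.append(info.centroid)
            axes.append(info.axis)
        rows.append(row)
    ctx.assignment = asn
    spacing = None
    if len(centroids) >= 2:
        axis = np.mean(axes, axis=0)
        spacing, coordination = lattice_spacing(
            np.array(centroids), ctx.frame.box, axis=axis)
        ctx.fibre_centroids = np.array(centroids)
        ctx.fibre_axis = axis
    path = ctx.outdir / "census.tsv"
    keys = ["cluster", "n_agg", "class", "radius_A", "axial_extent_A",
            "linear_density_per_nm", "diameter_A"]
    with open(path, "w") as fh:
        fh.write(_tsv_header("census", seed,
                             {"cutoff": cutoff, "selection": sel}))
        fh.write("\t".join(keys) + "\n")
        for row in rows:
            fh.write("\t".join(str(row.get(k, "")) for k in keys) + "\n")
    result = {"outputs": [str(path)], "n_clusters": asn.n_clusters,
              "mean_n_agg": float(np.mean(asn.sizes))}
    if spacing is not None:
        result["lattice_spacing_A"] = float(spacing)
    return result


@_stage("rdf", required=("sel_a", "sel_b"))
def _run_rdf(ctx: _Context, params: dict, seed: int) -> dict:
    traj = Trajectory.from_single(ctx.topology, ctx.frame)
    rdf = compute_rdf(traj, params["sel_a"], params["sel_b"],
                      r_max=params.get("r_max", 10.0),
                      dr=params.get("dr", 0.05))
    path = ctx.outdir / "rdf.tsv"
    with open(path, "w") as fh:
        fh.write(_tsv_header("rdf", seed, params))
        fh.write("r_A\tg\tpair_count\n")
        for r, g, c in zip(rdf.r, rdf.g, rdf.pair_counts):
            fh.write(f"{r:.5f}\t{g:.6f}\t{c}\n")
    return {"outputs": [str(path)],
            "first_peak_A": float(rdf.first_peak())}


@_stage("order", required=("selection",))
def _run_order(ctx: _Context, params: dict, seed: int) -> dict:
    traj = Trajectory.from_single(ctx.topology, ctx.frame)
    sel = params["selection"]
    neighbours = params.get("neighbours", {"cutoff": 6.5})
    q6 = compute_q6(traj, sel, neighbours=neighbours)
    result = {"q6": float(q6.values[0])}
    if params.get("translational", False):
        t = compute_translational_order(traj, sel)
        result["t_trans"] = float(t.values[0])
    path = ctx.outdir / "order.tsv"
    with open(path, "w") as fh:
        fh.write(_tsv_header("order", seed, {"selection": sel,
                                             **neighbours}))
        fh.write("metric\tvalue\n")
        for k, v in result.items():
            fh.write(f"{k}\t{v:.6f}\n")
    result["outputs"] = [str(path)]
    return result


@_stage("solvate")
def _run_solvate(ctx: _Context, params: dict, seed: int) -> dict:
    if ctx.topology is None:
        raise RuntimeError("solvate: no structure in context")
    regions = []
    target = params.get("inter_fibre_target")
    if target is not None:
        if ctx.fibre_centroids is None or len(ctx.fibre_centroids) < 2:
            raise RuntimeError("solvate: inter_fibre target needs >= 2 "
                               "classified fibres (run census first)")
        region = RegionSpec("inter_fibre", {
            "c1": tuple(ctx.fibre_centroids[0][:2]),
            "c2": tuple(ctx.fibre_centroids[1][:2]),
            "fibre_radius": params.get("fibre_radius", 12.0),
            "width": params.get("width", 12.0)})
        regions.append((region, float(target)))
    top, frame = reinsert_water(
        ctx.topology, ctx.frame,
        overall_density=params.get("overall_density", 1.0),
        regions=regions,
        exclusion_radius=params.get("exclusion_radius", 2.4),
        seed=seed)
    ctx.topology, ctx.frame = top, frame
    ctx.solvate_regions = regions
    path = ctx.outdir / "solvated.xyz"
    write_structure(path, top, frame, format="xyz")
    out = {"outputs": [str(path)], "n_waters_added": int(
        (top.group_tags == "water").sum() // 3)}
    return out


@_stage("density_check")
def _run_density_check(ctx: _Context, params: dict, seed: int) -> dict:
    if ctx.topology is None:
        raise RuntimeError("density_check: no structure in context")
    rows = {"box": measure_region_density(
        ctx.topology, ctx.frame, RegionSpec("box"), "group water")}
    for k, (region, target) in enumerate(getattr(ctx, "solvate_regions",
                                                 [])):
        rows[f"region_{k}_{region.kind}"] = measure_region_density(
            ctx.topology, ctx.frame, region, "group water")
    path = ctx.outdir / "densities.tsv"
    with open(path, "w") as fh:
        fh.write(_tsv_header("density_check", seed, params))
        fh.write("region\tdensity_g_cc\n")
        for k, v in rows.items():
            fh.write(f"{k}\t{v:.5f}\n")
    return {"outputs": [str(path)],
            **{k: float(v) for k, v in rows.items()}}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute stages in order; returns (and writes) the JSON manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ctx = _Context(config, outdir)
    manifest = {"version": __version__, "seed": config.seed,
                "outdir": str(outdir), "stages": []}
    for k, st in enumerate(config.stages):
        name = st["name"]
        params = st.get("params", {})
        stage_seed = int((config.seed * 1000003 + k * 8191) % (2 ** 31))
        t0 = _time.time()
        logger.info("stage %d: %s", k, name)
        try:
            result = STAGES[name].fn(ctx, params, stage_seed)
        except Exception as exc:
            manifest["failed_stage"] = name
            manifest["error"] = str(exc)
            (outdir / "manifest.json").write_text(
                json.dumps(manifest, indent=1))
            raise RuntimeError(f"pipeline halted at stage {name!r}: {exc}") \
                from exc
        manifest["stages"].append({
            "index": k, "name": name, "params": params,
            "seed": stage_seed, "result": result,
            "wall_time_s": round(_time.time() - t0, 3)})
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def report(manifest: dict) -> dict:
    """Aggregate stage results into one summary (TSV + JSON)."""
    outdir = Path(manifest["outdir"])
    summary = {"seed": manifest["seed"]}
    stages_by_name = {}
    for st in manifest["stages"]:
        stages_by_name.setdefault(st["name"], st)
    census = stages_by_name.get("census")
    if census:
        res = census["result"]
        summary["n_clusters"] = res.get("n_clusters")
        summary["mean_n_agg"] = res.get("mean_n_agg")
        if "lattice_spacing_A" in res:
            summary["lattice_spacing_A"] = res["lattice_spacing_A"]
    elif "census" not in stages_by_name:
        summary["aggregates"] = "no aggregates"
    for name in ("rdf", "order", "density_check"):
        st = stages_by_name.get(name)
        if st:
            for key, val in st["result"].items():
                if key != "outputs":
                    summary[f"{name}.{key}"] = val
    missing = [st["name"] for st in manifest["stages"]
               if "result" not in st]
    if missing:
        raise RuntimeError(f"missing stage outputs: {missing}")
    path_tsv = outdir / "summary.tsv"
    with open(path_tsv, "w") as fh:
        fh.write("key\tvalue\n")
        for k, v in summary.items():
            fh.write(f"{k}\t{v}\n")
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary
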