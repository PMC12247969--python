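"""End-to-end orchestration: load → edge-filter → measure → classify → report.

Each stage writes plain-text artifacts (per-face CSV, PLY with thickness,
per-surface JSON summary) into the configured output directory along with
the resolved configuration, so any run can be regenerated from config +
seed + inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import compartments, patches as patches_mod, profiling, stats
from .config import RunConfig
from .mesh import (FaceGraph, SurfaceMesh, build_face_graph, edge_exclusion_mask,
                   load_mesh, save_face_table, save_mesh)
from .volume import DensityVolume, load_volume, normalize_polarity

logger = logging.getLogger(__name__)

__all__ = ["SurfaceResult", "run_thickness", "run_patch_analysis"]


@dataclass
class SurfaceResult:
    """In-memory bundle for one measured surface."""

    name: str
    label: str
    mesh: SurfaceMesh
    graph: FaceGraph
    edge_excluded: np.ndarray
    thickness_map: profiling.ThicknessMap
    global_thickness: float
    global_fit: profiling.DualGaussianFit
    summary: stats.SurfaceSummary | None = None
    outputs: dict = field(default_factory=dict)


def _echo_params(cfg: RunConfig) -> None:
    logger.info(
        "parameters: scan [%g, %g] nm step %g, averaging radius %g nm, "
        "edge margin %g nm (%s), weight law %s, seed %d",
        cfg.scan_lo_nm, cfg.scan_hi_nm, cfg.scan_step_nm, cfg.avg_radius_nm,
        cfg.edge_margin_nm, cfg.edge_margin_metric, cfg.weight_law, cfg.seed,
    )


def _load_inputs(cfg: RunConfig) -> tuple[DensityVolume, list]:
    if not cfg.volume or not Path(cfg.volume).exists():
        raise FileNotFoundError(f"volume not found: {cfg.volume!r}")
    for s in cfg.surfaces:
        if not Path(s.path).exists():
            raise FileNotFoundError(f"surface mesh not found: {s.path!r}")
    vol = load_volume(cfg.volume, voxel_size_nm=cfg.voxel_size_nm,
                      polarity=cfg.polarity if cfg.polarity != "auto"
                      else "peaks_bright")
    meshes = [(s, load_mesh(s.path, attribute_table=s.attribute_table))
              for s in cfg.surfaces]
    if cfg.polarity == "auto":
        if not meshes:
            raise ValueError("polarity auto-detection requires a surface mesh")
        vol = normalize_polarity(vol, mesh=meshes[0][1], seed=cfg.seed)
    else:
        vol = normalize_polarity(vol)
    return vol, meshes


def measure_surface(vol: DensityVolume, mesh: SurfaceMesh, cfg: RunConfig,
                    name: str = "", label: str = "") -> SurfaceResult:
    """Edge-filter, then global and local thickness for one surface."""
    graph = build_face_graph(mesh)
    excluded = edge_exclusion_mask(mesh, graph, margin=cfg.edge_margin_nm,
                                   metric=cfg.edge_margin_metric)
    mesh.face_attributes["edge_excluded"] = excluded
    g_thick, g_fit = profiling.measure_global_thickness(
        vol, mesh, graph, mask=excluded,
        lo=cfg.scan_lo_nm, hi=cfg.scan_hi_nm, step=cfg.scan_step_nm)
    tmap = profiling.measure_local_thickness(
        vol, mesh, graph, radius=cfg.avg_radius_nm, mask=excluded,
        lo=cfg.scan_lo_nm, hi=cfg.scan_hi_nm, step=cfg.scan_step_nm)
    summary = stats.summarize_surface(
        tmap.thickness, mesh.face_areas, surface_id=name, label=label,
        convergence_fraction=tmap.convergence_fraction)
    return SurfaceResult(name=name, label=label, mesh=mesh, graph=graph,
                         edge_excluded=excluded, thickness_map=tmap,
                         global_thickness=g_thick, global_fit=g_fit,
                         summary=summary)


def run_thickness(cfg: RunConfig) -> list[SurfaceResult]:
    """Measure every configured surface and write per-surface outputs."""
    _echo_params(cfg)
    vol, meshes = _load_inputs(cfg)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "resolved_config.yaml")
    results = []
    for entry, mesh in meshes:
        name = Path(entry.path).stem
        res = measure_surface(vol, mesh, cfg, name=name, label=entry.label)
        faces_csv = out / f"{name}_faces.csv"
        ply = out / f"{name}_thickness.ply"
        summary_json = out / f"{name}_summary.json"
        save_face_table(mesh, faces_csv)
        save_mesh(mesh, ply)
        fit = res.global_fit
        summary_json.write_text(json.dumps({
            "surface": name,
            "label": entry.label,
            "global_thickness_nm": res.global_thickness,
            "global_fit": {"mu1": fit.mu1, "mu2": fit.mu2,
                           "sigma1": fit.sigma1, "sigma2": fit.sigma2,
                           "converged": fit.converged, "rss": fit.rss},
            "median_thickness_nm": res.summary.median_thickness_nm,
            "n_faces_included": res.summary.n_faces,
            "convergence_fraction": res.thickness_map.convergence_fraction,
            "n_edge_excluded": int(res.edge_excluded.sum()),
            "parameters": {k: v for k, v in res.thickness_map.params.items()
                           if k != "measured_faces"},
        }, indent=2))
        res.outputs = {"faces_csv": str(faces_csv), "ply": str(ply),
                       "summary_json": str(summary_json)}
        results.append(res)
    return results


def classify_imm_surfaces(imm: SurfaceMesh, omm: SurfaceMesh,
                          bin_width: float = 1.0) -> np.ndarray:
    """Mode-relative OMM-distance classification of IMM faces."""
    d = compartments.surface_to_surface_distance(imm, omm)
    mode = compartments.mode_distance(d, bin_width=bin_width)
    labels = compartments.classify_imm(d, mode)
    compartments.attach_labels(imm, labels)
    return labels


def run_patch_analysis(cfg: RunConfig,
                       surface_results: list[SurfaceResult] | None = None,
                       ) -> dict:
    """Particle-patch analysis on the first configured surface.

    Requires a completed (or chained) thickness run and a particle file.
    Writes the per-patch table, averaged particle/random profiles, the
    patch-vs-random thickness comparison, and the thickness-vs-curvedness
    2D histogram.
    """
    if cfg.particles is None:
        raise ValueError("no particle file configured")
    if surface_results is None:
        surface_results = run_thickness(cfg)
    res = surface_results[0]
    vol, _ = _load_inputs(cfg)
    particles = patches_mod.load_particles(
        cfg.particles, particle_pixel_size_a=cfg.particle_pixel_size_a)
    accepted, rejected = patches_mod.assign_particles(
        particles, res.mesh, max_dist=cfg.assign_cutoff_nm)
    if not accepted:
        raise ValueError(
            f"no particles within {cfg.assign_cutoff_nm} nm of the surface "
            f"({len(rejected)} rejected)")

    mesh, graph = res.mesh, res.graph
    thick = res.thickness_map.thickness
    curved = mesh.face_attributes.get("curvedness")
    region_mask = None
    if cfg.particle_region_label is not None:
        labels = mesh.face_attributes.get("compartment_label")
        if labels is None:
            raise ValueError("particle_region_label set but the mesh has no "
                             "compartment labels")
        region_mask = np.asarray(labels) == cfg.particle_region_label

    particle_patches = []
    for p_idx, face, _d in accepted:
        patch = patches_mod.extract_patch(mesh, graph, face,
                                          radius=cfg.patch_radius_nm,
                                          particle=p_idx)
        particle_patches.append(
            patches_mod.curate_patch_normals(patch, particles.centers[p_idx], mesh))
    random_patches = patches_mod.randomized_patches(
        mesh, graph, n=len(particle_patches),
        min_center_sep=cfg.random_patch_min_sep_nm,
        region_mask=region_mask, seed=cfg.seed, radius=cfg.patch_radius_nm)

    rows = []
    for i, patch in enumerate(particle_patches + random_patches):
        rows.append({
            "patch_id": i, "kind": patch.kind, "center_face": patch.center_face,
            "particle_id": patch.particle,
            "mean_thickness_nm": patches_mod.patch_mean(patch, thick, mesh.face_areas),
            "mean_curvedness": (patches_mod.patch_mean(patch, curved, mesh.face_areas)
                                if curved is not None else np.nan),
            "n_faces": len(patch.member_faces),
        })
    table = pd.DataFrame(rows)

    prof_p = patches_mod.average_profiles(
        [patches_mod.patch_profile(vol, mesh, p, cfg.profile_lo_nm,
                                   cfg.profile_hi_nm, cfg.scan_step_nm)
         for p in particle_patches])
    prof_r = patches_mod.average_profiles(
        [patches_mod.patch_profile(vol, mesh, p, cfg.profile_lo_nm,
                                   cfg.profile_hi_nm, cfg.scan_step_nm)
         for p in random_patches])

    tp = table[table["kind"] == "particle"]["mean_thickness_nm"].dropna()
    tr = table[table["kind"] == "random"]["mean_thickness_nm"].dropna()
    u, p = stats.mann_whitney_u(tp, tr)

    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "patches.csv", index=False)
    pd.DataFrame({"offset_nm": prof_p.offsets,
                  "particle_mean_density": prof_p.values,
                  "random_mean_density": prof_r.values,
                  }).to_csv(out / "patch_profiles.csv", index=False)
    comparison = {"n_particle_patches": len(particle_patches),
                  "n_random_patches": len(random_patches),
                  "n_rejected_particles": len(rejected),
                  "U": u, "p": p}
    (out / "patch_comparison.json").write_text(json.dumps(comparison, indent=2))
    counts, te, ce, _ = stats.hist2d_thickness_curvedness(
        table["mean_thickness_nm"], table["mean_curvedness"])
    np.savetxt(out / "hist2d_thickness_curvedness.csv", counts, delimiter=",")
    return {"table": table, "particle_profile": prof_p,
            "random_profile": prof_r, "comparison": comparison,
            "patches": (particle_patches, random_patches)}
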